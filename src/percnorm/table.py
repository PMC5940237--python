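"""Feature tables, sample metadata and taxonomy handling.

The canonical in-memory container is a pandas DataFrame with features as
rows and samples as columns (the MicrobiomeHD convention), wrapped in
:class:`FeatureTable` together with a normalization *state* that records
what the numbers mean (raw counts, relative abundances, log abundances,
or percentiles of a control distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "TaxonomyAnnotation",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "read_id_list",
    "to_relative_abundance",
    "collapse_to_genus",
    "split_by_design",
]

#: Recognized normalization states, in the order a table moves through them.
STATES = ("counts", "relative", "log", "percentile", "unknown")

#: Ranks of a bacterial lineage from least to most resolved (genus-level data).
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


class TableError(ValueError):
    """Raised for malformed tables, metadata or taxonomy inputs."""


@dataclass
class FeatureTable:
    """A features x samples abundance matrix with a normalization state.

    Parameters
    ----------
    data
        DataFrame with feature identifiers as the index and sample
        identifiers as columns.  Values are real numbers; NaN is permitted
        only in ``percentile`` state, where it marks a feature absent from
        a sample's study after pooling.
    state
        One of ``counts``, ``relative``, ``log``, ``percentile`` or
        ``unknown``.
    """

    data: pd.DataFrame
    state: str = "unknown"
    # free-form provenance (seed, method, per-study control counts ...)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise TableError(f"unknown table state {self.state!r}")
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise TableError(f"duplicate feature ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        nan = np.isnan(values)
        if nan.any() and self.state != "percentile":
            raise TableError("NaN entries are only allowed in percentile state")
        finite = values[~nan]
        if self.state in ("counts", "relative", "percentile") and (finite < 0).any():
            raise TableError(f"negative values not allowed in state {self.state!r}")
        if self.state == "percentile" and (finite > 100).any():
            raise TableError("percentile values must lie in [0, 100]")
        if self.state == "relative":
            sums = values.sum(axis=0)
            # zero replacement inflates each column by at most n_features
            # times the pseudo-abundance upper bound
            slack = 1e-9 + values.shape[0] * float(self.meta.get("zero_upper_bound", 0.0))
            bad = np.flatnonzero(np.abs(sums - 1.0) > slack)
            if bad.size:
                raise TableError(
                    "relative-abundance columns must sum to 1; offenders: "
                    f"{list(cols[bad[:5]])}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def select_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        """Sub-table restricted to ``sample_ids`` (order preserved)."""
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.columns]
        if missing:
            raise TableError(f"unknown sample ids: {missing}")
        return FeatureTable(self.data[ids], state=self.state, meta=dict(self.meta))

    def with_state(self, state: str) -> "FeatureTable":
        return FeatureTable(self.data, state=state, meta=dict(self.meta))


@dataclass
class SampleMetadata:
    """Per-sample study/batch label and case-control group label."""

    frame: pd.DataFrame  # index = sample_id; columns: study_id, group

    def __post_init__(self) -> None:
        need = {"study_id", "group"}
        if not need.issubset(self.frame.columns):
            raise TableError(f"metadata needs columns {sorted(need)}")
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ids in metadata: {dups}")
        bad = set(self.frame["group"]) - {"case", "control"}
        if bad:
            raise TableError(
                f"group labels must be 'case' or 'control'; found {sorted(bad)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def studies(self) -> list[str]:
        # first-appearance order
        return list(dict.fromkeys(self.frame["study_id"]))

    def group_ids(self, study_id: str, group: str) -> list[str]:
        mask = (self.frame["study_id"] == study_id) & (self.frame["group"] == group)
        return list(self.frame.index[mask])

    @classmethod
    def from_mappings(
        cls, study_of: Mapping[str, str], group_of: Mapping[str, str]
    ) -> "SampleMetadata":
        if set(study_of) != set(group_of):
            raise TableError("study and group mappings cover different samples")
        frame = pd.DataFrame(
            {"study_id": pd.Series(study_of), "group": pd.Series(group_of)}
        )
        frame.index.name = "sample_id"
        return cls(frame)


@dataclass
class TaxonomyAnnotation:
    """Ranked lineages (kingdom..genus) keyed by feature id.

    A lineage is a tuple of up to six names ordered kingdom -> genus; a
    missing rank is an empty string.  A missing genus is therefore
    representable and distinct from any named genus.
    """

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for fid, lin in self.lineages.items():
            if len(lin) > len(RANKS):
                raise TableError(f"lineage for {fid!r} has more than {len(RANKS)} ranks")

    def genus_label(self, feature_id: str) -> str:
        """Collapse label for a feature: its genus, or the most resolved
        named rank prefixed by the rank name (so unannotated features are
        never merged with a named genus)."""
        if feature_id not in self.lineages:
            raise TableError(f"feature {feature_id!r} missing from taxonomy")
        lin = self.lineages[feature_id]
        padded = tuple(lin) + ("",) * (len(RANKS) - len(lin))
        if padded[-1]:
            return padded[-1]
        for rank, name in zip(reversed(RANKS[:-1]), reversed(padded[:-1])):
            if name:
                return f"{rank}__{name}"
        return "unclassified"

    @classmethod
    def from_lineage_strings(
        cls, lineage_of: Mapping[str, str], sep: str = ";"
    ) -> "TaxonomyAnnotation":
        """Parse ``k__Bacteria;p__Firmicutes;...`` style strings.

        Rank prefixes (``k__`` etc.) are stripped if present; empty fields
        mark missing ranks.
        """
        out = {}
        for fid, text in lineage_of.items():
            names = []
            for part in text.split(sep):
                part = part.strip()
                if len(part) >= 3 and part[1:3] == "__":
                    part = part[3:]
                names.append(part)
            out[fid] = tuple(names)
        return cls(out)


# ---------------------------------------------------------------------------
# I/O


def _is_number(cell: str) -> bool:
    try:
        float(cell)
    except (TypeError, ValueError):
        return False
    return True


def read_feature_table(
    path, orientation: str = "features_as_rows", state: str = "unknown"
) -> FeatureTable:
    """Read a tab-separated feature table.

    The file has one header row of identifiers and one identifier column;
    the body is numeric.  ``orientation`` says whether rows are features
    or samples; the table is stored features-as-rows either way.  The
    state is ``counts`` when every entry is a whole number, otherwise the
    caller-supplied ``state`` (default ``unknown`` — relative abundance is
    never silently assumed).
    """
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise TableError(f"unknown orientation {orientation!r}")
    # pandas silently renames duplicate header fields; check them first
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            header = line.rstrip("\n").split("\t")[1:]
            if len(set(header)) != len(header):
                dups = sorted({h for h in header if header.count(h) > 1})
                raise TableError(f"duplicate identifiers in header: {dups}")
            break
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TableError(f"cannot parse {path}: {exc}") from exc
    if "taxonomy" in frame.columns:  # optional annotation column, not numeric
        frame = frame.drop(columns=["taxonomy"])
    numeric = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for col in frame.columns:
        cells = frame[col]
        if cells.isna().any():
            raise TableError(f"missing value in column {col!r}")
        try:
            # numpy's parser is correctly rounded (full round-trip precision)
            converted = cells.to_numpy(dtype=str).astype(float)
        except ValueError:
            bad = [
                row
                for row, cell in zip(frame.index, cells)
                if not _is_number(cell)
            ]
            raise TableError(
                f"non-numeric cell at row {bad[0]!r}, column {col!r}"
            ) from None
        numeric[col] = converted
    if orientation == "samples_as_rows":
        numeric = numeric.T
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    vals = numeric.to_numpy()
    if np.all(vals == np.floor(vals)) and np.all(vals >= 0):
        state = "counts"
    return FeatureTable(numeric, state=state)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a table as TSV with provenance recorded in ``#`` header comments."""
    with open(path, "w") as fh:
        fh.write(f"# state={table.state}\n")
        for key, val in table.meta.items():
            fh.write(f"# {key}={val}\n")
        frame = table.data.copy()
        frame.index.name = "feature_id"
        # repeatable full precision (>= 12 significant digits)
        frame.to_csv(fh, sep="\t", float_format="%.17g")


def read_metadata(path) -> SampleMetadata:
    """Read TSV metadata with columns sample_id, study_id, group."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    need = {"sample_id", "study_id", "group"}
    if not need.issubset(frame.columns):
        raise TableError(f"metadata file needs columns {sorted(need)}")
    frame = frame.set_index("sample_id")
    return SampleMetadata(frame[["study_id", "group"]])


def read_id_list(path) -> list[str]:
    """Plain-text sample-ID list, one per line, blank lines ignored."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if len(set(ids)) != len(ids):
        raise TableError(f"duplicate ids in {path}")
    return ids


# ---------------------------------------------------------------------------
# Transformations


def to_relative_abundance(table: FeatureTable) -> FeatureTable:
    """Divide each sample column by its total, giving relative abundances.

    Idempotent on already-normalized columns; zero entries remain zero.
    """
    values = table.values
    sums = values.sum(axis=0)
    zero_cols = np.flatnonzero(sums <= 0)
    if zero_cols.size:
        raise TableError(
            f"all-zero sample columns: {list(table.data.columns[zero_cols])}"
        )
    out = pd.DataFrame(
        values / sums, index=table.data.index, columns=table.data.columns
    )
    return FeatureTable(out, state="relative", meta=dict(table.meta))


def collapse_to_genus(table: FeatureTable, taxonomy: TaxonomyAnnotation) -> FeatureTable:
    """Sum rows sharing a genus-level annotation.

    Column sums are conserved exactly.  Features without a genus collapse
    under their most resolved annotation (rank-prefixed), never into a
    named genus.
    """
    labels = [taxonomy.genus_label(fid) for fid in table.feature_ids]
    grouped = table.data.groupby(pd.Index(labels, name="genus"), sort=False).sum()
    return FeatureTable(grouped, state=table.state, meta=dict(table.meta))


def split_by_design(
    table: FeatureTable, metadata: SampleMetadata
) -> dict[str, tuple[FeatureTable, FeatureTable]]:
    """Partition samples into per-study (control, case) sub-tables.

    Every sample of ``table`` lands in exactly one sub-table; column order
    within each sub-table follows the input order.
    """
    missing = [s for s in table.sample_ids if s not in metadata.frame.index]
    if missing:
        raise TableError(f"samples without metadata: {missing}")
    out: dict[str, tuple[FeatureTable, FeatureTable]] = {}
    meta = metadata.frame.loc[table.sample_ids]
    for study in dict.fromkeys(meta["study_id"]):
        in_study = meta["study_id"] == study
        controls = list(meta.index[in_study & (meta["group"] == "control")])
        cases = list(meta.index[in_study & (meta["group"] == "case")])
        out[study] = (
            FeatureTable(table.data[controls], state=table.state),
            FeatureTable(table.data[cases], state=table.state),
        )
    return out
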