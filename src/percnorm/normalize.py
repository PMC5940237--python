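"""Percentile normalization of case-control feature tables.

The idea: within a study, each feature's control abundances are converted
to percentiles of themselves (which yields a uniform grid on [0, 100])
and each case abundance is converted to its percentile within the same
control distribution.  Because any study-specific batch effect shifts
case and control samples alike, placing both on the control-percentile
axis removes it without a parametric model, and normalized studies can be
pooled for a single rank-based test.

Zeros are ubiquitous in microbiome relative-abundance data and would pile
up at a single rank; before ranking they are replaced by independent
pseudo-abundances drawn uniformly from (0, ``upper_bound``], a range below
any observable true relative abundance, so tied zeros are broken at
random.  The draw is seeded and recorded because re-analysis with a
different draw can move p-values slightly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table import FeatureTable, SampleMetadata, TableError

__all__ = [
    "ZeroReplacementPolicy",
    "replace_zeros",
    "percentile_of_score",
    "percentile_normalize",
    "pool_studies",
]


@dataclass(frozen=True)
class ZeroReplacementPolicy:
    """How zeros are replaced before ranking.

    ``upper_bound`` is in relative-abundance units and must sit below the
    smallest true nonzero abundance in the data (1e-9 is below 1/reads for
    any realistic sequencing depth); ``seed`` drives the uniform draws.
    """

    upper_bound: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.upper_bound:
            raise ValueError("upper_bound must be positive")


def replace_zeros(table: FeatureTable, policy: ZeroReplacementPolicy) -> FeatureTable:
    """Replace every zero entry with an i.i.d. draw from (0, upper_bound].

    Nonzero entries are untouched; the same seed gives bit-identical
    output.  All zero cells of the table share one seeded stream.
    """
    values = table.values
    if np.isnan(values).any():
        raise TableError("cannot replace zeros in a table with missing entries")
    if (values < 0).any():
        raise TableError("negative entries are not valid abundances")
    rng = np.random.default_rng(policy.seed)
    out = values.copy()
    zeros = out == 0
    # (1 - U[0,1)) * bound lies in (0, bound] — draws are strictly positive
    out[zeros] = (1.0 - rng.random(int(zeros.sum()))) * policy.upper_bound
    frame = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    meta = dict(table.meta)
    meta.update(zero_upper_bound=policy.upper_bound, zero_seed=policy.seed)
    state = table.state if table.state in ("relative", "unknown") else "unknown"
    return FeatureTable(frame, state=state, meta=meta)


def percentile_of_score(reference, score: float) -> float:
    """Percentile of ``score`` within ``reference``, mean-of-strict-and-weak.

    Returns ``100 * (#(ref < s) + #(ref <= s)) / (2 * n)`` — the midpoint
    of the strict and weak counting conventions, so a score tied with
    reference values lands halfway through its tie block.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("reference must be non-empty")
    strict = np.count_nonzero(ref < score)
    weak = np.count_nonzero(ref <= score)
    return 100.0 * (strict + weak) / (2 * ref.size)


def _percentile_rows(reference: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Row-wise percentiles of ``query`` within ``reference``.

    Both arrays are (n_features, n_samples); each row of ``query`` is
    scored against the matching row of ``reference``.
    """
    n = reference.shape[1]
    out = np.empty_like(query)
    for g in range(reference.shape[0]):
        ref = np.sort(reference[g])
        strict = np.searchsorted(ref, query[g], side="left")
        weak = np.searchsorted(ref, query[g], side="right")
        out[g] = 100.0 * (strict + weak) / (2 * n)
    return out


def percentile_normalize(
    study_table: FeatureTable,
    control_ids,
    case_ids,
    policy: ZeroReplacementPolicy | None = None,
) -> FeatureTable:
    """Convert one study's case and control values to control percentiles.

    Zeros are replaced per ``policy`` first; then, feature by feature,
    controls are scored against themselves and cases against the controls.
    The output has state ``percentile`` and carries the policy parameters
    plus the control count in its metadata.
    """
    policy = policy or ZeroReplacementPolicy()
    control_ids = list(control_ids)
    case_ids = list(case_ids)
    if not control_ids:
        raise TableError("control set is empty — percentile normalization needs controls")
    overlap = set(control_ids) & set(case_ids)
    if overlap:
        raise TableError(f"samples listed as both case and control: {sorted(overlap)}")
    unknown = [s for s in control_ids + case_ids if s not in study_table.data.columns]
    if unknown:
        raise TableError(f"unknown sample ids: {unknown}")

    replaced = replace_zeros(study_table, policy)
    ctrl = replaced.data[control_ids].to_numpy(dtype=float)
    case = replaced.data[case_ids].to_numpy(dtype=float)
    ctrl_pct = _percentile_rows(ctrl, ctrl)
    case_pct = _percentile_rows(ctrl, case) if case_ids else np.empty((ctrl.shape[0], 0))
    frame = pd.DataFrame(
        np.hstack([ctrl_pct, case_pct]),
        index=study_table.data.index,
        columns=control_ids + case_ids,
    )
    meta = dict(study_table.meta)
    meta.update(
        zero_upper_bound=policy.upper_bound,
        zero_seed=policy.seed,
        n_controls=len(control_ids),
        control_ids=tuple(control_ids),
        case_ids=tuple(case_ids),
    )
    return FeatureTable(frame, state="percentile", meta=meta)


def pool_studies(
    normalized: list[FeatureTable], absent_as_zero: bool = False
) -> FeatureTable:
    """Concatenate percentile-normalized studies over the union of features.

    A feature absent from a study is marked NaN for that study's samples
    (excluded pairwise from downstream tests: a feature never observed in
    a study carries no rank information there), or filled with percentile
    0 when ``absent_as_zero`` is set.
    """
    if len(normalized) < 2:
        raise TableError("pooling requires at least two normalized studies")
    for tab in normalized:
        if tab.state != "percentile":
            raise TableError("pool_studies expects percentile-normalized tables")
    all_samples: list[str] = []
    for tab in normalized:
        all_samples.extend(tab.sample_ids)
    if len(set(all_samples)) != len(all_samples):
        counts = pd.Series(all_samples).value_counts()
        dups = sorted(counts.index[counts > 1])
        raise TableError(f"duplicate sample ids across studies: {dups}")
    features: list[str] = []
    for tab in normalized:
        features.extend(f for f in tab.feature_ids if f not in set(features))
    frames = [tab.data.reindex(features) for tab in normalized]
    pooled = pd.concat(frames, axis=1)
    if absent_as_zero:
        pooled = pooled.fillna(0.0)
    control_ids: list[str] = []
    case_ids: list[str] = []
    for tab in normalized:
        control_ids.extend(tab.meta.get("control_ids", ()))
        case_ids.extend(tab.meta.get("case_ids", ()))
    meta = {
        "pooled_from": tuple(
            tab.meta.get("study_id", f"study{i}") for i, tab in enumerate(normalized)
        ),
        "control_ids": tuple(control_ids),
        "case_ids": tuple(case_ids),
    }
    return FeatureTable(pooled, state="percentile", meta=meta)
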