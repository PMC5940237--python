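"""Synthetic case-control studies and the in-silico validation experiments.

The generator emulates the lognormal picture used to illustrate the
method: a feature's abundance in a sample is ``exp(Normal(mu, sigma))``,
with the (mu, sigma) of the generating distribution depending on the
study (batch shift, shared across features) and on the group (disease
shift, applied to a configurable subset of features).  Zero inflation —
the hallmark sparsity of microbiome tables — is applied after the draw by
zeroing each cell independently with fixed probability.

Two experiments probe batch robustness:

* the *titration* experiment gradually substitutes one study's control
  group with controls from another study and counts features called
  significant (q <= 0.05) between cases and the mixed control group —
  with raw pooling the count climbs with the mixing fraction purely from
  batch effects, while percentile normalization stays flat;
* the *null false-positive* experiment tests controls from one study
  against controls from another as artificial cases and records the
  fraction of features with p <= 0.05, which should sit near 0.05 when a
  correction works.

Both default to 40-sample groups and 20 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import FeatureTable, SampleMetadata, TableError
from .normalize import ZeroReplacementPolicy, percentile_normalize, pool_studies
from .correct import BatchDesign, back_transform, eb_batch_adjust, linear_batch_remove, log_transform
from .stats import abundance_filter, bh_fdr, fisher_combine, rank_sum_table, stouffer_combine, opposing_direction_screen

__all__ = [
    "LognormalGroupSpec",
    "SyntheticStudySpec",
    "TitrationConfig",
    "ExperimentResult",
    "simulate_group",
    "simulate_two_study_dataset",
    "simulate_study_pair",
    "titration_experiment",
    "null_fp_experiment",
    "meta_analysis_pipeline",
    "METHODS",
]

METHODS = ("raw", "percentile", "eb_adjust", "linear_remove")


@dataclass(frozen=True)
class LognormalGroupSpec:
    """One group's generating distribution: exp(Normal(mu, sigma)), n draws."""

    mu: float
    sigma: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Per-feature case and control lognormal specs for one study."""

    study_id: str
    control: tuple[LognormalGroupSpec, ...]
    case: tuple[LognormalGroupSpec, ...]
    zero_inflation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.zero_inflation <= 1:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if len(self.control) != len(self.case) or not self.control:
            raise ValueError("control and case specs must cover the same features")


@dataclass(frozen=True)
class TitrationConfig:
    """Shared knobs of the titration / null experiments."""

    fractions: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    group_size: int = 40
    iterations: int = 20
    alpha: float = 0.05
    seed: int = 0
    filter_fraction: float = 1.0 / 3.0
    zero_upper_bound: float = 1e-9

    def __post_init__(self) -> None:
        object.__setattr__(self, "fractions", tuple(self.fractions))
        fr = self.fractions
        if tuple(sorted(fr)) != fr or fr[0] != 0.0 or fr[-1] != 1.0:
            raise ValueError("fractions must be ascending and include 0 and 1")
        if self.group_size <= 0 or self.iterations <= 0:
            raise ValueError("group_size and iterations must be positive")


@dataclass
class ExperimentResult:
    """Tidy per-iteration experiment outcomes plus per-condition means."""

    records: pd.DataFrame  # columns: method, fraction, iteration, value

    def means(self) -> pd.DataFrame:
        return (
            self.records.groupby(["method", "fraction"], sort=True)["value"]
            .mean()
            .reset_index()
        )

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generators


def simulate_group(spec: LognormalGroupSpec, rng: np.random.Generator) -> np.ndarray:
    return np.exp(rng.normal(spec.mu, spec.sigma, size=spec.n_samples))


def simulate_two_study_dataset(
    specs: list[SyntheticStudySpec],
) -> tuple[dict[str, FeatureTable], SampleMetadata]:
    """Draw per-study feature tables and matching metadata.

    Feature g of study s is drawn from the study's control spec for
    control samples and case spec for case samples; zero inflation then
    zeroes each cell with the configured probability.  Deterministic under
    each study's seed.
    """
    tables: dict[str, FeatureTable] = {}
    study_of: dict[str, str] = {}
    group_of: dict[str, str] = {}
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        n_ctrl = spec.control[0].n_samples
        n_case = spec.case[0].n_samples
        rows = []
        for ctrl_spec, case_spec in zip(spec.control, spec.case):
            if ctrl_spec.n_samples != n_ctrl or case_spec.n_samples != n_case:
                raise ValueError("all features of a study must share sample counts")
            rows.append(
                np.concatenate(
                    [simulate_group(ctrl_spec, rng), simulate_group(case_spec, rng)]
                )
            )
        values = np.vstack(rows)
        if spec.zero_inflation > 0:
            values = np.where(
                rng.random(values.shape) < spec.zero_inflation, 0.0, values
            )
        samples = [f"{spec.study_id}_ctrl{i}" for i in range(n_ctrl)] + [
            f"{spec.study_id}_case{i}" for i in range(n_case)
        ]
        features = [f"F{g}" for g in range(len(spec.control))]
        frame = pd.DataFrame(values, index=features, columns=samples)
        tables[spec.study_id] = FeatureTable(
            frame, state="unknown", meta={"study_id": spec.study_id}
        )
        for i, s in enumerate(samples):
            study_of[s] = spec.study_id
            group_of[s] = "control" if i < n_ctrl else "case"
    return tables, SampleMetadata.from_mappings(study_of, group_of)


def simulate_study_pair(
    n_features: int = 2000,
    n_controls: int | tuple[int, int] = (500, 500),
    n_cases: int | tuple[int, int] = (30, 100),
    base_mu: float = 0.1,
    base_sigma: float = 0.7,
    batch_mu_shift: float = 1.4,
    batch_sigma_scale: float = 0.3,
    effect_mu_shift: float = 0.7,
    effect_fraction: float = 0.0,
    zero_inflation: float = 0.3,
    seed: int = 0,
) -> tuple[dict[str, FeatureTable], SampleMetadata, list[str]]:
    """Two studies with identical biology but a strong batch difference.

    Study A draws every feature from ``exp(N(base_mu, base_sigma))``;
    study B shifts the location by ``batch_mu_shift`` and rescales sigma
    by ``batch_sigma_scale`` for all features (the batch effect, shared
    across features, mirroring the two-study lognormal illustration whose
    control parameters differ by Delta-mu = 1.4 and a sigma ratio near
    0.3).  A fraction of features additionally receives a case-group
    location shift of ``effect_mu_shift`` in both studies (the consistent
    disease signal).  Returns the tables, metadata and the list of planted
    effect features.

    Default sample sizes give control-rich cohorts (the regime where
    percentile normalization is meant to operate — the control pool sets
    the resolution of the percentile axis) whose case:control ratios
    differ between studies, as they do across real cohorts; a pooled
    group contrast then weights the two batches unequally, which is what
    lets batch effects masquerade as group differences in raw pooling.
    """
    rng = np.random.default_rng(seed)
    n_effect = int(round(effect_fraction * n_features))
    effect_idx = rng.choice(n_features, size=n_effect, replace=False)
    effect = np.zeros(n_features)
    effect[effect_idx] = effect_mu_shift
    if isinstance(n_controls, int):
        n_controls = (n_controls, n_controls)
    if isinstance(n_cases, int):
        n_cases = (n_cases, n_cases)

    specs = []
    for (study, mu0, sig0), nc, nk in zip(
        (
            ("studyA", base_mu, base_sigma),
            ("studyB", base_mu + batch_mu_shift, base_sigma * batch_sigma_scale),
        ),
        n_controls,
        n_cases,
    ):
        control = tuple(LognormalGroupSpec(mu0, sig0, nc) for _ in range(n_features))
        case = tuple(
            LognormalGroupSpec(mu0 + effect[g], sig0, nk) for g in range(n_features)
        )
        specs.append(
            SyntheticStudySpec(
                study_id=study,
                control=control,
                case=case,
                zero_inflation=zero_inflation,
                seed=int(rng.integers(2**31)),
            )
        )
    tables, metadata = simulate_two_study_dataset(specs)
    planted = [f"F{g}" for g in sorted(effect_idx)]
    return tables, metadata, planted


# ---------------------------------------------------------------------------
# Treatments


def _correct_combined(
    combined: FeatureTable, batch_of: dict[str, str], method: str
) -> FeatureTable:
    """Log -> batch-correct -> exp for the model-based comparators."""
    design = BatchDesign(batch_of)
    logged = log_transform(combined)
    if method == "eb_adjust":
        corrected = eb_batch_adjust(logged, design)
    elif method == "linear_remove":
        corrected = linear_batch_remove(logged, design)
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown correction {method!r}")
    return back_transform(corrected)


def _concat(tables: list[FeatureTable]) -> FeatureTable:
    frames = [t.data for t in tables]
    return FeatureTable(pd.concat(frames, axis=1), state="unknown")


# ---------------------------------------------------------------------------
# Experiments


def _treat_pools(
    case_tab: FeatureTable | None,
    controls_a: FeatureTable,
    controls_b: FeatureTable,
    method: str,
    policy: ZeroReplacementPolicy,
) -> FeatureTable:
    """Apply a data treatment once to the full sample pools.

    Treatments operate on whole studies before any subsampling, matching
    how the corrections are used in practice: percentile normalization
    converts each study against its own full control pool; the
    model-based corrections fit the combined table with batch = source
    study; raw data only gets zero replacement so tied zeros do not pile
    up at a single rank.
    """
    from .normalize import replace_zeros

    a_parts = [t for t in (case_tab, controls_a) if t is not None]
    full = _concat(a_parts + [controls_b])
    if method == "raw":
        return replace_zeros(full, policy)
    if method == "percentile":
        part_a = percentile_normalize(
            _concat(a_parts),
            control_ids=controls_a.sample_ids,
            case_ids=case_tab.sample_ids if case_tab is not None else [],
            policy=policy,
        )
        part_b = percentile_normalize(
            controls_b,
            control_ids=controls_b.sample_ids,
            case_ids=[],
            policy=ZeroReplacementPolicy(policy.upper_bound, policy.seed + 1),
        )
        return FeatureTable(
            pd.concat([part_a.data, part_b.data], axis=1), state="percentile"
        )
    batch_of = {s: "A" for t in a_parts for s in t.sample_ids}
    batch_of.update({s: "B" for s in controls_b.sample_ids})
    return _correct_combined(full, batch_of, method)


def titration_experiment(
    cases: FeatureTable,
    controls_a: FeatureTable,
    controls_b: FeatureTable,
    config: TitrationConfig,
    method: str,
    percentile_mode: str = "per_study",
) -> ExperimentResult:
    """Mix foreign controls into the control group and count significants.

    The treatment is applied to the full pools first (see
    :func:`_treat_pools`).  Then, per iteration and mixing fraction f:
    draw ``group_size`` cases (study A) and a control group of
    ``round(f * group_size)`` study-B controls plus study-A controls for
    the remainder (without replacement), abundance-filter on the
    pre-treatment values of the drawn samples, rank-sum test each kept
    feature and count q <= ``alpha``.

    ``percentile_mode='after_mixing'`` demonstrates misuse of the method:
    cases are normalized per draw against the already-mixed control
    group instead of their own study's controls.
    """
    if method not in METHODS:
        raise TableError(f"method must be one of {METHODS}")
    if percentile_mode not in ("per_study", "after_mixing"):
        raise TableError("percentile_mode must be 'per_study' or 'after_mixing'")
    gs = config.group_size
    n_mix = {f: int(np.round(f * gs)) for f in config.fractions}
    if cases.shape[1] < gs:
        raise TableError("case pool smaller than group_size")
    if max(n_mix.values()) > controls_b.shape[1] or gs > controls_a.shape[1]:
        raise TableError("control pools smaller than required draws")
    rng = np.random.default_rng(config.seed)
    policy = ZeroReplacementPolicy(config.zero_upper_bound, int(rng.integers(2**31)))
    mix_per_draw = method == "percentile" and percentile_mode == "after_mixing"
    raw_full = _concat([cases, controls_a, controls_b])
    treated = (
        raw_full
        if mix_per_draw
        else _treat_pools(cases, controls_a, controls_b, method, policy)
    )
    rows = []
    for it in range(config.iterations):
        for f in config.fractions:
            k = n_mix[f]
            case_ids = list(rng.choice(cases.sample_ids, size=gs, replace=False))
            a_ids = list(rng.choice(controls_a.sample_ids, size=gs - k, replace=False))
            b_ids = list(rng.choice(controls_b.sample_ids, size=k, replace=False))
            ctrl_ids = a_ids + b_ids
            keep = abundance_filter(
                raw_full.select_samples(case_ids + ctrl_ids),
                case_ids,
                ctrl_ids,
                config.filter_fraction,
            )
            if not keep:
                rows.append((method, f, it, 0))
                continue
            if mix_per_draw:
                draw_policy = ZeroReplacementPolicy(
                    config.zero_upper_bound, int(rng.integers(2**31))
                )
                tested = percentile_normalize(
                    raw_full.select_samples(case_ids + ctrl_ids),
                    control_ids=ctrl_ids,
                    case_ids=case_ids,
                    policy=draw_policy,
                )
            else:
                tested = treated.select_samples(case_ids + ctrl_ids)
            results = rank_sum_table(tested, case_ids, ctrl_ids, feature_ids=keep)
            rows.append(
                (method, f, it, sum(1 for r in results if r.q <= config.alpha))
            )
    return ExperimentResult(
        pd.DataFrame(rows, columns=["method", "fraction", "iteration", "value"])
    )


def null_fp_experiment(
    controls_a: FeatureTable,
    controls_b: FeatureTable,
    config: TitrationConfig,
    method: str,
) -> ExperimentResult:
    """Controls vs controls across studies: fraction of p <= alpha.

    Per iteration: 40 artificial controls from pool A and 40 artificial
    cases from pool B (sizes from ``config``), treatment, abundance
    filter, rank-sum per feature; the recorded value is the fraction of
    tested features with p <= ``alpha``.
    """
    if method not in METHODS:
        raise TableError(f"method must be one of {METHODS}")
    gs = config.group_size
    if controls_a.shape[1] < gs or controls_b.shape[1] < gs:
        raise TableError("control pools smaller than group_size")
    rng = np.random.default_rng(config.seed)
    policy = ZeroReplacementPolicy(config.zero_upper_bound, int(rng.integers(2**31)))
    raw_full = _concat([controls_a, controls_b])
    treated = _treat_pools(None, controls_a, controls_b, method, policy)
    rows = []
    for it in range(config.iterations):
        a_ids = list(rng.choice(controls_a.sample_ids, size=gs, replace=False))
        b_ids = list(rng.choice(controls_b.sample_ids, size=gs, replace=False))
        keep = abundance_filter(
            raw_full.select_samples(b_ids + a_ids), b_ids, a_ids, config.filter_fraction
        )
        if not keep:
            rows.append((method, np.nan, it, np.nan))
            continue
        results = rank_sum_table(
            treated.select_samples(b_ids + a_ids), b_ids, a_ids, feature_ids=keep
        )
        frac = float(np.mean([r.p <= config.alpha for r in results]))
        rows.append((method, np.nan, it, frac))
    return ExperimentResult(
        pd.DataFrame(rows, columns=["method", "fraction", "iteration", "value"])
    )


# ---------------------------------------------------------------------------
# Meta-analysis workflow


def meta_analysis_pipeline(
    studies: list[tuple[FeatureTable, SampleMetadata]],
    method: str,
    alpha: float = 0.05,
    filter_fraction: float = 1.0 / 3.0,
    zero_upper_bound: float = 1e-9,
    seed: int = 0,
    screen_use: str = "q",
) -> dict:
    """Full cross-study workflow for one treatment.

    Returns a dict with a per-feature results DataFrame and the summary
    counts at q <= ``alpha``: ``pooled`` (significant after pooling or
    combining), ``union`` / ``intersection`` / ``two_or_more`` over the
    within-study significant sets.
    """
    if method not in ("percentile", "fisher", "stouffer", "eb_adjust", "linear_remove"):
        raise TableError(f"unknown method {method!r}")
    if len(studies) < 2:
        raise TableError("meta-analysis needs at least two studies")
    rng = np.random.default_rng(seed)

    per_study: dict[str, list] = {}
    study_tables: dict[str, tuple[FeatureTable, list[str], list[str]]] = {}
    for table, metadata in studies:
        study_ids = metadata.studies
        if len(study_ids) != 1:
            raise TableError("each study entry must carry exactly one study_id")
        sid = study_ids[0]
        ctrl = metadata.group_ids(sid, "control")
        case = metadata.group_ids(sid, "case")
        if not ctrl or not case:
            raise TableError(f"study {sid!r} lacks a case or control group")
        keep = abundance_filter(table, case, ctrl, filter_fraction)
        policy = ZeroReplacementPolicy(zero_upper_bound, int(rng.integers(2**31)))
        norm = percentile_normalize(table, ctrl, case, policy)
        norm.meta["study_id"] = sid
        per_study[sid] = rank_sum_table(norm, case, ctrl, feature_ids=keep)
        study_tables[sid] = (table, ctrl, case)

    sig_sets = {
        sid: {r.feature_id for r in res if r.q <= alpha}
        for sid, res in per_study.items()
    }
    union = set().union(*sig_sets.values())
    intersection = set.intersection(*sig_sets.values())
    counts = pd.Series([f for s in sig_sets.values() for f in s]).value_counts()
    two_or_more = set(counts.index[counts >= 2]) if len(counts) else set()

    if method in ("fisher", "stouffer"):
        excluded = opposing_direction_screen(per_study, threshold=alpha, use=screen_use)
        by_feature: dict[str, list] = {}
        for sid, res in per_study.items():
            for r in res:
                by_feature.setdefault(r.feature_id, []).append(r)
        records = []
        for fid, rs in by_feature.items():
            if fid in excluded:
                records.append((fid, np.nan, np.nan, True))
                continue
            ps = np.clip([r.p for r in rs], 1e-15, 1 - 1e-15)
            if method == "fisher":
                comb = fisher_combine(ps)
            else:
                w = [np.sqrt(r.n_case + r.n_control) for r in rs]
                comb = stouffer_combine(ps, w)
            records.append((fid, comb, np.nan, False))
        frame = pd.DataFrame(records, columns=["feature_id", "p", "q", "excluded"])
        ok = ~frame["excluded"]
        frame.loc[ok, "q"] = bh_fdr(frame.loc[ok, "p"].to_numpy())
        pooled_sig = set(frame.loc[ok & (frame["q"] <= alpha), "feature_id"])
    else:
        if method == "percentile":
            normalized = []
            for sid, (table, ctrl, case) in study_tables.items():
                policy = ZeroReplacementPolicy(zero_upper_bound, int(rng.integers(2**31)))
                norm = percentile_normalize(table, ctrl, case, policy)
                norm.meta["study_id"] = sid
                normalized.append(norm)
            pooled = pool_studies(normalized)
        else:
            combined = _concat([tab for tab, _, _ in study_tables.values()])
            batch_of = {
                s: sid
                for sid, (tab, _, _) in study_tables.items()
                for s in tab.sample_ids
            }
            pooled = _correct_combined(combined, batch_of, method)
        all_ctrl = [s for _, c, _ in study_tables.values() for s in c]
        all_case = [s for _, _, c in study_tables.values() for s in c]
        raw_combined = _concat([tab for tab, _, _ in study_tables.values()])
        keep = abundance_filter(raw_combined, all_case, all_ctrl, filter_fraction)
        keep = [f for f in keep if f in set(pooled.feature_ids)]
        pooled_res = rank_sum_table(pooled, all_case, all_ctrl, feature_ids=keep)
        frame = pd.DataFrame(
            [(r.feature_id, r.z, r.p, r.q, r.direction) for r in pooled_res],
            columns=["feature_id", "z", "p", "q", "direction"],
        )
        pooled_sig = {r.feature_id for r in pooled_res if r.q <= alpha}

    return {
        "method": method,
        "results": frame,
        "per_study": per_study,
        "pooled": len(pooled_sig),
        "pooled_features": pooled_sig,
        "union": len(union),
        "intersection": len(intersection),
        "two_or_more": len(two_or_more),
    }
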