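"""Differential-abundance statistics and meta-analysis combiners.

Per-feature testing is the two-sample Wilcoxon rank-sum test (normal
approximation, midranks, no tie or continuity correction) with
Benjamini-Hochberg FDR control.  Cross-study evidence is combined either
by pooling normalized samples into one test, or by Fisher's / Stouffer's
methods on per-study p-values (Stouffer weights sqrt(n_case + n_control)
per study), after excluding features that are significant in opposite
directions in different studies.  Community-level contrasts use
Bray-Curtis dissimilarities and PERMANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import squareform, pdist
import skbio
from statsmodels.stats.multitest import multipletests

from .table import FeatureTable, TableError

__all__ = [
    "FeatureTestResult",
    "PermanovaResult",
    "abundance_filter",
    "wilcoxon_ranksum",
    "rank_sum_table",
    "bh_fdr",
    "fisher_combine",
    "stouffer_combine",
    "opposing_direction_screen",
    "bray_curtis",
    "permanova",
]


@dataclass(frozen=True)
class FeatureTestResult:
    """Per-feature rank-sum test outcome within one comparison."""

    feature_id: str
    n_case: int
    n_control: int
    z: float
    p: float
    q: float = float("nan")
    # case_enriched when the case group ranks higher than controls
    direction: str = "tied"

    @staticmethod
    def direction_of(z: float) -> str:
        if z > 0:
            return "case_enriched"
        if z < 0:
            return "control_enriched"
        return "tied"


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p: float
    r2: float
    n_permutations: int
    seed: int


def abundance_filter(
    table: FeatureTable, group_a_ids, group_b_ids, fraction: float = 1.0 / 3.0
) -> list[str]:
    """Features present (> 0) in at least ``fraction`` of either group.

    Applied to pre-replacement abundances: a pseudo-abundance would make
    every feature "present" everywhere and defeat the filter's purpose of
    trimming the multiple-testing burden.
    """
    a = list(group_a_ids)
    b = list(group_b_ids)
    if not a or not b:
        raise TableError("abundance filter needs two non-empty groups")
    da = table.select_samples(a).values
    db = table.select_samples(b).values
    frac_a = (da > 0).sum(axis=1) / len(a)
    frac_b = (db > 0).sum(axis=1) / len(b)
    keep = (frac_a >= fraction) | (frac_b >= fraction)
    return [fid for fid, k in zip(table.feature_ids, keep) if k]


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Two-sample rank-sum z and two-sided normal p.

    Midranks over the pooled sample; z = (R_x - n_x(N+1)/2) /
    sqrt(n_x n_y (N+1)/12), with no tie correction and no continuity
    correction; p is the two-sided normal tail.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise TableError("rank-sum test needs non-empty samples")
    z, p = sps.ranksums(x, y)
    return float(z), float(p)


def _ranksum_rows(case: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized rank-sum z/p per row: case columns vs control columns.

    Rows with NaN entries (pooled features absent from a study) are
    handled pairwise: the NaN samples are dropped for that feature.
    """
    n_feat = case.shape[0]
    z = np.empty(n_feat)
    p = np.empty(n_feat)
    pooled = np.hstack([case, ctrl])
    has_nan = np.isnan(pooled).any(axis=1)
    nx = case.shape[1]
    if (~has_nan).any():
        sub = pooled[~has_nan]
        ranks = sps.rankdata(sub, axis=1)
        N = sub.shape[1]
        ny = N - nx
        rx = ranks[:, :nx].sum(axis=1)
        expected = nx * (N + 1) / 2.0
        sd = np.sqrt(nx * ny * (N + 1) / 12.0)
        zz = (rx - expected) / sd
        z[~has_nan] = zz
        p[~has_nan] = 2 * sps.norm.sf(np.abs(zz))
    for i in np.flatnonzero(has_nan):
        cx = case[i][~np.isnan(case[i])]
        cy = ctrl[i][~np.isnan(ctrl[i])]
        if cx.size == 0 or cy.size == 0:
            z[i], p[i] = np.nan, np.nan
        else:
            z[i], p[i] = sps.ranksums(cx, cy)
    return z, p


def rank_sum_table(
    table: FeatureTable, case_ids, control_ids, feature_ids=None
) -> list[FeatureTestResult]:
    """Rank-sum test per feature (cases vs controls) with BH q-values.

    ``feature_ids`` restricts testing to a filtered set.  Features absent
    from some samples (NaN after pooling) are tested on the samples where
    they are observed.
    """
    case_ids = list(case_ids)
    control_ids = list(control_ids)
    sub = table.data
    if feature_ids is not None:
        sub = sub.loc[list(feature_ids)]
    case = sub[case_ids].to_numpy(dtype=float)
    ctrl = sub[control_ids].to_numpy(dtype=float)
    z, p = _ranksum_rows(case, ctrl)
    ok = ~np.isnan(p)
    q = np.full(p.shape, np.nan)
    if ok.any():
        q[ok] = bh_fdr(p[ok])
    out = []
    for i, fid in enumerate(sub.index):
        out.append(
            FeatureTestResult(
                feature_id=str(fid),
                n_case=int(np.sum(~np.isnan(case[i]))),
                n_control=int(np.sum(~np.isnan(ctrl[i]))),
                z=float(z[i]),
                p=float(p[i]),
                q=float(q[i]),
                direction=FeatureTestResult.direction_of(z[i]),
            )
        )
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise TableError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_combine(pvalues) -> float:
    """Fisher's method: -2 sum(ln p) on chi-square with 2k df."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise TableError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise TableError("p-values must lie in (0, 1] (floor zeros before combining)")
    return float(sps.combine_pvalues(p, method="fisher").pvalue)


def stouffer_combine(pvalues, weights) -> float:
    """Stouffer's method with caller-supplied weights.

    z_i = Phi^{-1}(1 - p_i); Z = sum(w_i z_i)/sqrt(sum w_i^2); the
    combined p is the upper normal tail of Z.  Weights here are
    sqrt(n_case + n_control) per study.
    """
    p = np.asarray(pvalues, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape:
        raise TableError("weights must match p-values")
    if np.any((p <= 0) | (p >= 1)):
        raise TableError("p-values must lie strictly in (0, 1) for Stouffer's method")
    if np.any(w <= 0):
        raise TableError("weights must be positive")
    return float(sps.combine_pvalues(p, method="stouffer", weights=w).pvalue)


def opposing_direction_screen(
    per_study: dict[str, list[FeatureTestResult]],
    threshold: float = 0.05,
    use: str = "q",
) -> set[str]:
    """Features significant in opposite directions in >= 2 studies.

    These are excluded from Fisher/Stouffer combination: a feature that is
    confidently enriched in cases in one study and in controls in another
    has no single cross-study direction to combine evidence for.  ``use``
    selects the within-study significance measure (``q`` default, ``p``,
    or ``none`` to exclude on any sign conflict regardless of
    significance).
    """
    if use not in ("q", "p", "none"):
        raise TableError("use must be 'q', 'p' or 'none'")
    excluded: set[str] = set()
    directions: dict[str, set[str]] = {}
    for results in per_study.values():
        for r in results:
            if r.direction == "tied":
                continue
            if use == "q" and not (r.q <= threshold):
                continue
            if use == "p" and not (r.p <= threshold):
                continue
            directions.setdefault(r.feature_id, set()).add(r.direction)
    for fid, dirs in directions.items():
        if len(dirs) > 1:
            excluded.add(fid)
    return excluded


def bray_curtis(table: FeatureTable) -> skbio.DistanceMatrix:
    """Bray-Curtis dissimilarities between sample columns."""
    values = table.values
    if (values < 0).any():
        raise TableError("Bray-Curtis requires non-negative abundances")
    sums = values.sum(axis=0)
    if (sums <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, sums) if t <= 0]
        raise TableError(f"all-zero samples have no Bray-Curtis distance: {bad}")
    dm = pdist(values.T, metric="braycurtis")
    return skbio.DistanceMatrix(squareform(dm), ids=table.sample_ids)


def permanova(
    dist: skbio.DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA with a mandatory seed.

    pseudo-F = (SS_among/(a-1)) / (SS_within/(N-a)) from squared
    distances; p = (1 + #{F* >= F}) / (1 + n_permutations) under label
    permutation; r2 = SS_among / SS_total.
    """
    labels = np.asarray(labels)
    ids = list(dist.ids)
    if labels.shape[0] != len(ids):
        raise TableError("one label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise TableError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise TableError(f"groups with fewer than two samples: {small}")
    res = skbio.stats.distance.permanova(
        dist, labels, permutations=n_permutations, seed=seed
    )
    # r2 from the sums of squares identity: F = (SS_a/(a-1))/(SS_w/(N-a))
    a = uniq.size
    N = len(ids)
    F = float(res["test statistic"])
    ratio = F * (a - 1) / (N - a)  # SS_among / SS_within
    r2 = ratio / (1.0 + ratio)
    return PermanovaResult(
        pseudo_F=F,
        p=float(res["p-value"]),
        r2=r2,
        n_permutations=n_permutations,
        seed=seed,
    )
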