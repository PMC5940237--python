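"""Model-based batch corrections used as comparators.

Two corrections operating on log-transformed relative abundances:

* :func:`eb_batch_adjust` — the parametric empirical-Bayes location/scale
  adjustment popularized for microarray data: per-feature batch means and
  variances are estimated, shrunk toward normal / inverse-gamma priors
  whose hyperparameters come from method-of-moments fits across features,
  and then removed.
* :func:`linear_batch_remove` — per-feature ordinary least squares on
  batch indicators with sum-to-zero contrasts; the fitted batch component
  is subtracted, the intercept kept.

Zeros are replaced by half the minimum positive value of the whole matrix
before the natural log; the corrected matrix is exponentiated back with
:func:`back_transform` (columns are not re-normalized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table import FeatureTable, TableError

__all__ = [
    "BatchDesign",
    "log_transform",
    "eb_batch_adjust",
    "linear_batch_remove",
    "back_transform",
]


@dataclass
class BatchDesign:
    """Batch label per sample, with >= 2 batches of >= 2 samples each."""

    batch_of: dict[str, str]

    @property
    def batches(self) -> list[str]:
        return list(dict.fromkeys(self.batch_of.values()))

    def indicator(self, sample_ids: list[str]) -> tuple[np.ndarray, list[str]]:
        """(n_samples x n_batches) one-hot matrix in input sample order."""
        missing = [s for s in sample_ids if s not in self.batch_of]
        if missing:
            raise TableError(f"samples without a batch label: {missing}")
        batches = list(dict.fromkeys(self.batch_of[s] for s in sample_ids))
        onehot = np.zeros((len(sample_ids), len(batches)))
        for i, s in enumerate(sample_ids):
            onehot[i, batches.index(self.batch_of[s])] = 1.0
        return onehot, batches


def _check_design(table: FeatureTable, design: BatchDesign) -> tuple[np.ndarray, list[str]]:
    onehot, batches = design.indicator(table.sample_ids)
    if len(batches) < 2:
        raise TableError("batch adjustment needs at least two batches")
    n_b = onehot.sum(axis=0)
    small = [b for b, n in zip(batches, n_b) if n < 2]
    if small:
        raise TableError(f"batches with fewer than two samples: {small}")
    return onehot, batches


def log_transform(table: FeatureTable) -> FeatureTable:
    """Natural log after replacing zeros with half the matrix-wide minimum
    positive value (the pseudo-abundance is applied to zeros only)."""
    values = table.values
    if (values < 0).any():
        raise TableError("negative entries are not valid abundances")
    positive = values[values > 0]
    if positive.size == 0:
        raise TableError("all-zero matrix cannot be log-transformed")
    half_min = positive.min() / 2.0
    out = np.where(values == 0, half_min, values)
    frame = pd.DataFrame(np.log(out), index=table.data.index, columns=table.data.columns)
    meta = dict(table.meta)
    meta["pseudo_abundance"] = half_min
    return FeatureTable(frame, state="log", meta=meta)


def back_transform(table: FeatureTable) -> FeatureTable:
    """Elementwise exponential; columns are not re-normalized to sum 1."""
    if table.state != "log":
        raise TableError("back_transform expects a log-state table")
    frame = pd.DataFrame(
        np.exp(table.values), index=table.data.index, columns=table.data.columns
    )
    meta = {k: v for k, v in table.meta.items() if k != "pseudo_abundance"}
    return FeatureTable(frame, state="unknown", meta=meta)


# ---------------------------------------------------------------------------
# Empirical-Bayes location/scale adjustment


def _postmean(g_hat, g_bar, n, d_old, t2):
    return (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(s_data, g_hat, d_hat, g_bar, t2, a, b, conv=1e-6, max_iter=500):
    """Fixed-point solution of the EB posterior means for one batch."""
    n = (~np.isnan(s_data)).sum(axis=1)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = np.nansum((s_data - g_new[:, None]) ** 2, axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def _aprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def eb_batch_adjust(
    table: FeatureTable,
    design: BatchDesign,
    conv: float = 1e-6,
    max_iter: int = 500,
) -> FeatureTable:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per feature: fit grand and batch means by least squares and
    standardize by the pooled variance; per batch: shrink the feature-wise
    additive effects toward a normal prior and the multiplicative effects
    toward an inverse-gamma prior (method-of-moments hyperparameters,
    fixed-point iteration); then subtract/divide the shrunken effects and
    restore the grand mean and scale.  No biological covariates are
    modeled.  Features with zero pooled variance are passed through
    unadjusted with a warning.
    """
    onehot, batches = _check_design(table, design)
    X = table.values  # G x N
    G, N = X.shape
    n_b = onehot.sum(axis=0)  # per-batch counts

    # least-squares batch means; grand mean weighted by batch sizes
    batch_means = (X @ onehot) / n_b  # G x B
    grand_mean = batch_means @ (n_b / N)  # G
    var_pooled = ((X - batch_means @ onehot.T) ** 2).sum(axis=1) / N  # G

    degenerate = var_pooled <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero pooled variance "
            "passed through unadjusted",
            RuntimeWarning,
        )
    safe_var = np.where(degenerate, 1.0, var_pooled)

    s_data = (X - grand_mean[:, None]) / np.sqrt(safe_var)[:, None]

    adjusted = s_data.copy()
    for j, batch in enumerate(batches):
        members = onehot[:, j] == 1
        sb = s_data[:, members]
        gamma_hat = sb.mean(axis=1)
        delta_hat = sb.var(axis=1, ddof=1)
        if G > 1:
            g_bar, t2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
            a, b = _aprior(delta_hat), _bprior(delta_hat)
            g_star, d_star = _it_sol(
                sb, gamma_hat, delta_hat, g_bar, t2, a, b, conv=conv, max_iter=max_iter
            )
        else:
            # a single feature gives the prior nothing to borrow from:
            # shrinkage targets collapse onto the feature's own estimates
            g_star, d_star = gamma_hat, delta_hat
        adjusted[:, members] = (sb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = adjusted * np.sqrt(safe_var)[:, None] + grand_mean[:, None]
    out[degenerate, :] = X[degenerate, :]
    frame = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    meta = dict(table.meta)
    meta["batch_correction"] = f"eb_adjust(batches={batches})"
    return FeatureTable(frame, state="log", meta=meta)


def linear_batch_remove(table: FeatureTable, design: BatchDesign) -> FeatureTable:
    """Subtract per-feature OLS batch effects (sum-to-zero contrasts).

    After removal every feature has equal batch means (the unweighted mean
    of the original batch means); idempotent.
    """
    onehot, batches = _check_design(table, design)
    X = table.values
    n_b = onehot.sum(axis=0)
    batch_means = (X @ onehot) / n_b  # G x B
    # sum-to-zero contrasts: batch effect = batch mean - unweighted mean of
    # batch means; subtracting it leaves the intercept
    effects = batch_means - batch_means.mean(axis=1, keepdims=True)
    out = X - effects @ onehot.T
    frame = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    meta = dict(table.meta)
    meta["batch_correction"] = f"linear_remove(batches={batches})"
    return FeatureTable(frame, state="log", meta=meta)
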