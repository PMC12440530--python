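"""MR-PRESSO: pleiotropy residual sum and outlier test.

A simulation-based test for horizontal pleiotropy built on leave-one-out
fixed-effects IVW residuals:

* **global test** — the observed leave-one-out residual sum of squares (RSS)
  is compared with its Monte-Carlo distribution under the no-pleiotropy model;
* **outlier test** — each variant's observed squared residual is compared
  with its own simulated distribution, Bonferroni-corrected;
* **outlier correction** — IVW recomputed on the non-outlying variants;
* **distortion test** — the raw-vs-corrected estimate shift compared with the
  shift from removing equally many random variants.

At least 4 instruments are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mr import MREstimate, ivw

__all__ = ["PressoReport", "presso_global", "presso_outlier_correct"]

MIN_SNPS = 4


@dataclass
class PressoReport:
    """MR-PRESSO results: global p, per-variant outlier p-values, corrected estimate."""

    rss_obs: float
    global_p: float
    n_sim: int
    outlier_p: np.ndarray | None = None      # Bonferroni-adjusted, per variant
    outliers: list = field(default_factory=list)  # indices removed
    beta_raw: MREstimate | None = None
    beta_corrected: MREstimate | None = None
    distortion_p: float | None = None
    degenerate: bool = False


def _loo_slopes(bx, by, w):
    """Leave-one-out fixed-effects IVW slopes, one per variant.

    Supports batched input: bx/by of shape (..., k) with weights w of shape (k,).
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _rss_and_residuals(bx, by, w):
    slopes = _loo_slopes(bx, by, w)
    resid2 = (by - slopes * bx) ** 2
    return np.sum(resid2, axis=-1), resid2


def _canonicalize(bx, sx, by, sy):
    """Orient each variant so beta_exp >= 0 and sort into a canonical order.

    Every PRESSO statistic is analytically invariant to variant order and to
    joint sign flips; canonicalizing before the Monte-Carlo draws makes the
    simulated p-values exactly invariant too.  Returns the reordered arrays
    and the permutation mapping canonical positions to input positions.
    """
    sign = np.where(bx < 0, -1.0, 1.0)
    bx = bx * sign
    by = by * sign
    order = np.lexsort((sy, sx, by, bx))
    return bx[order], sx[order], by[order], sy[order], order


def _simulate(bx, sx, by, sy, w, n_sim, rng):
    """Null-model parametric simulations of (RSS, per-variant residual²)."""
    k = bx.size
    loo = _loo_slopes(bx, by, w)          # expected outcome effect per variant
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(loo * bx, sy, size=(n_sim, k))
    return _rss_and_residuals(bx_sim, by_sim, w)


def presso_global(hset, n_sim: int = 1000, seed: int | None = None) -> PressoReport:
    """MR-PRESSO global pleiotropy test.

    ``rss_obs`` sums squared residuals beta_out_j - b(-j)*beta_exp_j where
    b(-j) is the fixed-effects IVW slope excluding variant j.  Each simulation
    redraws beta_exp* ~ N(beta_exp, se_exp) and beta_out* ~ N(b(-j)*beta_exp,
    se_out) and recomputes the RSS the same way; the Monte-Carlo p uses the +1
    correction so global_p >= 1/(n_sim+1).
    """
    if seed is None:
        raise ValueError("presso_global requires an explicit seed")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    if hasattr(hset, "arrays"):
        bx, sx, by, sy = hset.arrays()
    else:
        bx, sx, by, sy = (np.asarray(a, float) for a in hset)
    k = bx.size
    if k < MIN_SNPS:
        raise ValueError(
            f"insufficient instruments for MR-PRESSO: k = {k} < {MIN_SNPS}"
        )
    bx, sx, by, sy, _ = _canonicalize(bx, sx, by, sy)
    w = 1.0 / sy**2
    rss_obs, _ = _rss_and_residuals(bx, by, w)
    rng = np.random.default_rng(seed)
    rss_sim, _ = _simulate(bx, sx, by, sy, w, n_sim, rng)
    global_p = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)
    return PressoReport(float(rss_obs), float(global_p), n_sim)


def presso_outlier_correct(hset, n_sim: int = 1000, seed: int | None = None,
                           alpha_outlier: float = 0.05,
                           n_distortion: int = 1000) -> PressoReport:
    """Full MR-PRESSO: global test, outlier flags, corrected estimate, distortion.

    Per-variant outlier p is the Monte-Carlo tail fraction of simulated
    squared residuals at or above the observed one, Bonferroni-multiplied by
    k; variants below ``alpha_outlier`` are removed and fixed-effects IVW is
    recomputed on the remainder.  The distortion p compares the raw-minus-
    corrected slope shift against shifts from removing the same number of
    randomly chosen variants (two-sided, by absolute value).  With no
    outliers flagged the corrected estimate equals the raw one and
    distortion_p = 1 by convention; with every variant flagged the report is
    marked degenerate.
    """
    if seed is None:
        raise ValueError("presso_outlier_correct requires an explicit seed")
    if hasattr(hset, "arrays"):
        bx, sx, by, sy = hset.arrays()
    else:
        bx, sx, by, sy = (np.asarray(a, float) for a in hset)
    k = bx.size
    if k < MIN_SNPS:
        raise ValueError(
            f"insufficient instruments for MR-PRESSO: k = {k} < {MIN_SNPS}"
        )
    bx, sx, by, sy, perm = _canonicalize(bx, sx, by, sy)
    w = 1.0 / sy**2
    rss_obs, resid2_obs = _rss_and_residuals(bx, by, w)
    rng = np.random.default_rng(seed)
    rss_sim, resid2_sim = _simulate(bx, sx, by, sy, w, n_sim, rng)
    global_p = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)

    tail = (1.0 + np.sum(resid2_sim >= resid2_obs, axis=0)) / (n_sim + 1.0)
    outlier_p_canon = np.minimum(tail * k, 1.0)  # Bonferroni by k
    outlier_p = np.empty(k)
    outlier_p[perm] = outlier_p_canon  # report in input order
    outliers = sorted(int(i) for i in np.flatnonzero(outlier_p < alpha_outlier))
    # remaining computations use the original input order
    if hasattr(hset, "arrays"):
        bx, sx, by, sy = hset.arrays()
    else:
        bx, sx, by, sy = (np.asarray(a, float) for a in hset)
    w = 1.0 / sy**2

    raw = ivw((bx, sx, by, sy), mode="fe")
    report = PressoReport(
        float(rss_obs), float(global_p), n_sim,
        outlier_p=outlier_p, outliers=outliers, beta_raw=raw,
    )
    if not outliers:
        report.beta_corrected = raw
        report.distortion_p = 1.0
        return report
    keep = np.setdiff1d(np.arange(k), outliers)
    if keep.size < 2:
        report.degenerate = True
        return report
    corrected = ivw((bx[keep], sx[keep], by[keep], sy[keep]), mode="fe")
    report.beta_corrected = corrected

    # distortion: slope shift under random removal of the same number of SNPs
    n_out = len(outliers)
    obs_shift = raw.beta - corrected.beta
    shifts = np.empty(n_distortion)
    idx = np.arange(k)
    for b in range(n_distortion):
        drop = rng.choice(idx, size=n_out, replace=False)
        sub = np.setdiff1d(idx, drop)
        ws = w[sub]
        shifts[b] = raw.beta - np.sum(ws * bx[sub] * by[sub]) / np.sum(ws * bx[sub] ** 2)
    report.distortion_p = float(
        (1.0 + np.sum(np.abs(shifts) >= abs(obs_shift))) / (n_distortion + 1.0)
    )
    return report
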