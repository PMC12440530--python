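"""Causal-effect estimators for two-sample MR on harmonized summary statistics.

All estimators consume per-variant (beta_exp, se_exp, beta_out, se_out)
quadruples — either a :class:`~mrchain.sumstats_io.HarmonizedSet` or four
arrays.  Estimates are on the outcome scale per SD of exposure (log-odds for
binary outcomes, so ``exp(beta)`` is an odds ratio).

Methods
-------
wald_ratio        single-variant ratio estimate (first-order SE)
ivw               inverse-variance weighting, fixed or multiplicative
                  random effects (primary estimator)
egger             weighted regression with a free intercept; a nonzero
                  intercept indicates directional pleiotropy
weighted_median   50th percentile of the weight-ordered ratio estimates;
                  robust to <50% invalid weight
cochran_q         between-variant heterogeneity of the ratio estimates
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MREstimate",
    "HeterogeneityReport",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_median_point",
    "cochran_q",
    "odds_ratio_ci",
]


@dataclass
class MREstimate:
    """One method's causal estimate.

    ``beta`` is on the outcome scale (log-odds per SD of exposure for a
    binary outcome); ``extras`` carries per-method diagnostics such as the
    Egger intercept.
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    extras: dict = field(default_factory=dict)

    def odds_ratio(self, level: float = 0.95) -> tuple[float, float, float]:
        """(OR, lower, upper) — meaningful when the outcome is binary."""
        return odds_ratio_ci(self.beta, self.se, level)


@dataclass
class HeterogeneityReport:
    """Cochran's Q heterogeneity of per-variant ratio estimates."""

    Q: float
    df: int
    p_q: float


def odds_ratio_ci(beta: float, se: float, level: float = 0.95):
    z = stats.norm.ppf(0.5 + level / 2)
    return (float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))


def _unpack(hset_or_arrays):
    if hasattr(hset_or_arrays, "arrays"):
        bx, sx, by, sy = hset_or_arrays.arrays()
    else:
        bx, sx, by, sy = hset_or_arrays
    bx = np.asarray(bx, float)
    sx = np.asarray(sx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("standard errors must be strictly positive")
    return bx, sx, by, sy


def _norm_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-variant ratio estimate beta_out/beta_exp with first-order SE."""
    if beta_exp == 0:
        raise ValueError("Wald ratio undefined for beta_exp = 0")
    if se_exp <= 0 or se_out <= 0:
        raise ValueError("standard errors must be strictly positive")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MREstimate("wald", float(beta), float(se), _norm_p(beta / se), 1)


def ivw(hset, mode: str = "mre") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Equivalent to weighted least squares of beta_out on beta_exp through the
    origin with weights 1/se_out².  ``mode="fe"`` is the fixed-effects SE;
    ``mode="mre"`` multiplies it by max(1, sqrt(Q/(k-1))) (multiplicative
    random effects with an inflation floor of 1), the primary model.
    """
    if mode not in ("fe", "mre"):
        raise ValueError("mode must be 'fe' or 'mre'")
    bx, sx, by, sy = _unpack(hset)
    k = bx.size
    if k < 2:
        raise ValueError("IVW needs k >= 2 instruments; use wald_ratio for k = 1")
    w = 1.0 / sy**2
    sxx = np.sum(w * bx**2)
    beta = np.sum(w * bx * by) / sxx
    se = np.sqrt(1.0 / sxx)
    extras = {}
    if mode == "mre":
        het = cochran_q(hset, beta)
        infl = max(1.0, np.sqrt(het.Q / het.df))
        se = se * infl
        extras["mre_inflation"] = float(infl)
    return MREstimate(f"ivw_{mode}", float(beta), float(se), _norm_p(beta / se), int(k), extras)


def egger(hset) -> MREstimate:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Each variant is first oriented so beta_exp >= 0 (both betas flipped when
    negative).  Weights 1/se_out²; slope and intercept p-values from the t
    distribution with k-2 df.  A significant intercept indicates unbalanced
    (directional) pleiotropy.
    """
    bx, sx, by, sy = _unpack(hset)
    k = bx.size
    if k < 3:
        raise ValueError("MR-Egger needs k >= 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx <= 0:
        raise ValueError("degenerate exposure effects: no spread in |beta_exp|")
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    dof = k - 2
    # weighted residual variance (sigma^2 of the multiplicative error model)
    s2 = np.sum(w * resid**2) / dof
    slope_se = np.sqrt(s2 / sxx)
    int_se = np.sqrt(s2 * (1.0 / sw + xbar**2 / sxx))

    def _t_p(stat, se):
        # degenerate exact fit: zero residual variance
        if se == 0:
            return 1.0 if stat == 0 else float(np.nextafter(0, 1))
        return float(2 * stats.t.sf(abs(stat / se), dof))

    slope_p = _t_p(slope, slope_se)
    int_p = _t_p(intercept, int_se)
    return MREstimate(
        "egger", float(slope), float(slope_se), slope_p, int(k),
        extras={
            "intercept": float(intercept),
            "intercept_se": float(int_se),
            "intercept_p": int_p,
        },
    )


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the weighted CDF at 0.5."""
    order = np.argsort(ratios, kind="mergesort")
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    cum = np.cumsum(w)
    s = (cum - w / 2.0) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(hset, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Ratio estimates r_j = beta_out_j/beta_exp_j carry first-order inverse-
    variance weights w_j = beta_exp_j²/se_out_j².  The SE is the standard
    deviation of the estimate over ``n_boot`` parametric resamples
    (beta_exp_j, beta_out_j redrawn from normals with their reported SEs);
    ``seed`` is mandatory so results are reproducible.
    """
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    bx, sx, by, sy = _unpack(hset)
    k = bx.size
    if k < 3:
        raise ValueError("weighted median needs k >= 3 instruments")
    if np.any(bx == 0):
        raise ValueError("beta_exp must be nonzero for ratio estimates")
    ratios = by / bx
    weights = bx**2 / sy**2
    beta = weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, k))
    bys = rng.normal(by, sy, size=(n_boot, k))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bxs[b]
        if np.any(bxb == 0):  # pathological resample; nudge off zero
            bxb = np.where(bxb == 0, np.finfo(float).tiny, bxb)
        boots[b] = weighted_median_point(bys[b] / bxb, bxb**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    if se <= 0:
        raise ValueError("degenerate bootstrap: zero spread")
    return MREstimate("weighted_median", float(beta), se, _norm_p(beta / se), int(k),
                      extras={"n_boot": n_boot})


def cochran_q(hset, ref_beta: float | None = None) -> HeterogeneityReport:
    """Cochran's Q: weighted squared deviation of ratio estimates from a reference.

    Q = sum_j w_j (r_j - ref)² with w_j = beta_exp_j²/se_out_j²; df = k-1;
    p from the upper chi-square tail.  ``ref_beta`` defaults to the
    fixed-effects IVW estimate.
    """
    bx, sx, by, sy = _unpack(hset)
    k = bx.size
    if k < 2:
        raise ValueError("Cochran's Q needs k >= 2 instruments")
    if ref_beta is None:
        w_ivw = 1.0 / sy**2
        ref_beta = np.sum(w_ivw * bx * by) / np.sum(w_ivw * bx**2)
    # w_j (r_j - ref)^2 with w_j = bx_j^2/sy_j^2 equals ((by_j - ref*bx_j)/sy_j)^2,
    # which stays defined for a zero exposure effect
    q = float(np.sum(((by - ref_beta * bx) / sy) ** 2))
    dof = k - 1
    return HeterogeneityReport(q, dof, float(stats.chi2.sf(q, dof)))
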