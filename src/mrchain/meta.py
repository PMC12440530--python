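"""Fixed-effects meta-analysis, the exclusion cascade, Bonferroni
classification, and product-of-coefficients mediation.

Cohort-level MR estimates are pooled per method with inverse-variance
fixed-effects weights.  Before pooling, any cohort analysis with a
significant Egger intercept (p < .05), a significant MR-PRESSO global test
(p < .05), or fewer than 4 instruments is excluded; after pooling, an IVW
meta-estimate whose sign disagrees with a nominally significant sensitivity
meta-estimate is flagged as inconsistent.

Mediation of an exposure's total effect on the outcome (EO) through a
mediator follows the product-of-coefficients rule: the mediation effect is
ME = EM × MO (exposure→mediator times mediator→outcome), with a first-order
delta-method SE

    se(ME) = sqrt(MO²·se(EM)² + EM²·se(MO)²)

and the mediated proportion ME / EO.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PathEstimate",
    "MetaResult",
    "MediationResult",
    "SignificanceRule",
    "CohortDiagnostics",
    "fixed_effect_meta",
    "exclusion_filter",
    "sensitivity_consistent",
    "classify",
    "mediate",
    "se_from_ci",
    "replay_table",
]

Z95 = 1.959963984540054  # stats.norm.ppf(0.975)


class PathEstimate(NamedTuple):
    """A (beta, se) pair for one causal path."""

    beta: float
    se: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - Z95 * self.se, self.beta + Z95 * self.se)


@dataclass
class MetaResult:
    unit_id: str
    method: str
    pooled_beta: float
    pooled_se: float
    pooled_p: float
    q_meta: float      # nan when k_inputs == 1
    p_het: float       # nan when k_inputs == 1
    k_inputs: int
    excluded_inputs: list = field(default_factory=list)  # (input_id, reason)


@dataclass
class MediationResult:
    """One exposure→mediator→outcome row: paths, ME, delta-method CI, proportion."""

    exposure: str
    mediator: str
    outcome: str
    te: PathEstimate
    em: PathEstimate
    mo: PathEstimate
    me: float
    me_se: float
    me_ci: tuple
    me_p: float
    prop_mediated: float  # ME / total effect; nan when te.beta == 0
    flags: list = field(default_factory=list)


@dataclass(frozen=True)
class SignificanceRule:
    """Bonferroni family rule: significant below alpha/m, suggestive below alpha."""

    m_tests: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.m_tests < 1:
            raise ValueError("m_tests must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0,1)")

    @property
    def strict_threshold(self) -> float:
        return self.alpha / self.m_tests


@dataclass
class CohortDiagnostics:
    """What the exclusion cascade needs from one cohort-level analysis."""

    cohort_id: str
    n_snp: int
    egger_intercept_p: float | None = None
    presso_global_p: float | None = None


def fixed_effect_meta(estimates: Sequence, unit_id: str = "", method: str = "") -> MetaResult:
    """Inverse-variance fixed-effects pooling with Cochran heterogeneity.

    ``estimates`` is a sequence of (beta, se) pairs (PathEstimate or tuples).
    A single input passes through with undefined heterogeneity.
    """
    if len(estimates) == 0:
        raise ValueError("cannot meta-analyze an empty list")
    beta = np.array([e[0] for e in estimates], float)
    se = np.array([e[1] for e in estimates], float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    pooled_p = float(2 * stats.norm.sf(abs(pooled) / pooled_se))
    k = len(estimates)
    if k > 1:
        q = float(np.sum(w * (beta - pooled) ** 2))
        p_het = float(stats.chi2.sf(q, k - 1))
    else:
        q = float("nan")
        p_het = float("nan")
    return MetaResult(unit_id, method, pooled, pooled_se, pooled_p, q, p_het, k)


def exclusion_filter(per_cohort: Sequence[CohortDiagnostics],
                     alpha: float = 0.05, min_snps: int = 4):
    """Apply the pre-meta exclusion cascade to cohort-level analyses.

    A cohort analysis is dropped when its Egger intercept p < alpha, its
    MR-PRESSO global p < alpha, or it used fewer than ``min_snps``
    instruments.  Returns (retained cohort_ids, exclusion log of
    (cohort_id, reason)); deterministic and order-independent.
    """
    retained = []
    log = []
    for diag in per_cohort:
        if diag.n_snp < min_snps:
            log.append((diag.cohort_id, "fewer_than_4_snps"))
        elif diag.egger_intercept_p is not None and diag.egger_intercept_p < alpha:
            log.append((diag.cohort_id, "egger_intercept_p<.05"))
        elif diag.presso_global_p is not None and diag.presso_global_p < alpha:
            log.append((diag.cohort_id, "presso_global_p<.05"))
        else:
            retained.append(diag.cohort_id)
    return retained, log


def sensitivity_consistent(ivw_meta: MetaResult,
                           sensitivity_metas: Sequence[MetaResult],
                           alpha: float = 0.05) -> bool:
    """Check the IVW meta-sign against nominally significant sensitivity metas.

    The unit is inconsistent when any sensitivity meta-estimate (weighted
    median, Egger, PRESSO-corrected) is significant at ``alpha`` with the
    opposite sign to the IVW meta-estimate.
    """
    for m in sensitivity_metas:
        if m.pooled_p < alpha and np.sign(m.pooled_beta) != np.sign(ivw_meta.pooled_beta):
            return False
    return True


def classify(pval: float, rule: SignificanceRule) -> str:
    """Bonferroni label: significant / suggestive / null."""
    if not (0 < pval <= 1):
        raise ValueError("pval must lie in (0,1]")
    if pval < rule.strict_threshold:
        return "significant"
    if pval < rule.alpha:
        return "suggestive"
    return "null"


def mediate(em, mo, te, exposure: str = "", mediator: str = "",
            outcome: str = "") -> MediationResult:
    """Product-of-coefficients mediation with a first-order delta-method CI.

    ME = em.beta × mo.beta; se(ME) = sqrt(mo.beta²·em.se² + em.beta²·mo.se²);
    Wald 95% CI and two-sided normal p.  The mediated proportion is
    ME / te.beta (undefined, flagged, when the total effect is zero); a
    proportion is never clipped — sign-discordant ME/TE or proportion > 1 is
    flagged instead.
    """
    em = PathEstimate(*em)
    mo = PathEstimate(*mo)
    te = PathEstimate(*te)
    for p in (em, mo, te):
        if p.se <= 0:
            raise ValueError("all path standard errors must be positive")
    me = em.beta * mo.beta
    me_se = float(np.sqrt(mo.beta**2 * em.se**2 + em.beta**2 * mo.se**2))
    flags = []
    if me_se > 0:
        me_p = float(2 * stats.norm.sf(abs(me) / me_se))
    else:
        me_p = 1.0
        flags.append("degenerate_se")
    ci = (me - Z95 * me_se, me + Z95 * me_se)
    if te.beta != 0:
        prop = me / te.beta
        if me != 0 and np.sign(me) != np.sign(te.beta):
            flags.append("sign_discordant")
        if prop > 1:
            flags.append("proportion>1")
    else:
        prop = float("nan")
        flags.append("total_effect_zero")
    return MediationResult(exposure, mediator, outcome, te, em, mo,
                           float(me), me_se, ci, me_p, float(prop), flags)


def se_from_ci(lower: float, upper: float, level: float = 0.95) -> float:
    """Recover a standard error from a printed Wald interval: half-width / 1.96."""
    z = stats.norm.ppf(0.5 + level / 2)
    return (upper - lower) / (2 * z)


def replay_table(rows: Sequence[dict]) -> list[dict]:
    """Recompute mediation columns from printed total/path estimates.

    Each row supplies the published point estimates and 95% CIs for the total
    effect (eo, eo_lo, eo_hi), exposure→mediator path (em, em_lo, em_hi) and
    mediator→outcome path (mo, mo_lo, mo_hi), plus identifier fields.  Path
    SEs are recovered as CI half-width / 1.96 and the mediation effect, its
    delta-method CI and p, and the mediated proportion are recomputed.  To
    match a published table's rounding chain, the proportion divides the
    4-dp-rounded mediation effect by the printed total effect.
    """
    out = []
    for row in rows:
        em = PathEstimate(row["em"], se_from_ci(row["em_lo"], row["em_hi"]))
        mo = PathEstimate(row["mo"], se_from_ci(row["mo_lo"], row["mo_hi"]))
        te = PathEstimate(row["eo"], se_from_ci(row["eo_lo"], row["eo_hi"]))
        res = mediate(em, mo, te,
                      exposure=row.get("exposure", ""),
                      mediator=row.get("mediator", ""),
                      outcome=row.get("outcome", ""))
        prop_printed = round(res.me, 4) / te.beta * 100.0
        out.append({
            "exposure": res.exposure,
            "mediator": res.mediator,
            "me": res.me,
            "me_lo": res.me_ci[0],
            "me_hi": res.me_ci[1],
            "me_p": res.me_p,
            "prop_pct": res.prop_mediated * 100.0,
            "prop_pct_printed": round(prop_printed, 2),
            "flags": ";".join(res.flags),
        })
    return out
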