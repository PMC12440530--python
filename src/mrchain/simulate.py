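"""Seeded generators of synthetic GWAS summary statistics.

These generators produce the statistical structure every pipeline stage
assumes, so the full analysis can run and be validated without any external
download:

* per-variant exposure effects strong enough to reach genome-wide
  significance, with exposure estimates on the SD scale and outcome estimates
  on the log-odds scale;
* outcome effects under a linear causal model with configurable horizontal
  pleiotropy — none, balanced, directional, or planted outliers;
* several independent outcome cohorts per exposure;
* deterministic structural test variants (an ambiguous palindrome, a swapped
  allele orientation, an LD-correlated duplicate) planted at fixed indices so
  harmonization and clumping are exercised exactly;
* a three-layer exposure→mediator→outcome chain with known path effects;
* LD-block z-scores with known heritabilities and genetic correlation.

Default sample sizes mirror the study layout the pipeline targets: a
microbiome-scale exposure GWAS (n ≈ 6000), a metabolite-scale mediator GWAS
(n ≈ 8300), and large binary outcome cohorts (n ≈ 420,000 with per-variant
log-odds SE ≈ 0.02).  Every generator takes a mandatory seed and is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ldsc import LdscVariantTable
from .sumstats_io import LDMatrix, SummaryStatsTable

__all__ = [
    "Pleiotropy",
    "SimulationConfig",
    "MediationTruth",
    "MRPairData",
    "MediationChainData",
    "simulate_mr_pair",
    "simulate_effect_arrays",
    "simulate_mediation_chain",
    "simulate_ldsc_traits",
]

# non-palindromic allele pairs used for bulk variants
_SAFE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
               ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class Pleiotropy:
    """Horizontal-pleiotropy scenario for the outcome model.

    kind "none": no pleiotropic effects.  "balanced": per-variant effects
    N(0, sd).  "directional": N(mean, sd).  "outliers": zero except ``count``
    planted variants with effect ``magnitude`` × the outcome SE (alternating
    sign across planted variants).
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    count: int = 0
    magnitude: float = 0.0

    @classmethod
    def none(cls) -> "Pleiotropy":
        return cls("none")

    @classmethod
    def balanced(cls, sd: float) -> "Pleiotropy":
        return cls("balanced", sd=sd)

    @classmethod
    def directional(cls, mean: float, sd: float) -> "Pleiotropy":
        return cls("directional", mean=mean, sd=sd)

    @classmethod
    def outliers(cls, count: int, magnitude: float) -> "Pleiotropy":
        return cls("outliers", count=count, magnitude=magnitude)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated two-sample MR experiment.

    ``n_exp`` defaults to the size of a microbiome-scale exposure GWAS,
    ``n_out`` to a large case-control outcome GWAS analyzed on the log-odds
    scale with constant per-variant SE ``se_out``; exposures are in SD units
    with SE 1/sqrt(2·n·eaf·(1−eaf)).  ``plant_structure`` adds the fixed
    structural variants (palindrome / swapped orientation / LD duplicate)
    at indices 0–2.
    """

    seed: int
    n_snp: int = 30
    n_exp: int = 5959
    n_out: int = 420_000
    se_out: float = 0.02
    true_beta: float = 0.3
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy.none)
    n_cohorts: int = 3
    plant_structure: bool = True

    def __post_init__(self) -> None:
        if self.n_snp < (6 if self.plant_structure else 2):
            raise ValueError("n_snp too small for the requested structure")
        if self.pleiotropy.kind == "outliers" and self.pleiotropy.count > self.n_snp - (3 if self.plant_structure else 0):
            raise ValueError("more planted outliers than available variants")
        if self.se_out <= 0 or self.n_exp <= 0 or self.n_out <= 0:
            raise ValueError("sample sizes and se_out must be positive")


@dataclass(frozen=True)
class MediationTruth:
    """Ground-truth path effects of the exposure→mediator→outcome chain."""

    beta_xm: float
    beta_my: float
    beta_xy_direct: float

    @property
    def te(self) -> float:
        """Implied total effect: direct + indirect."""
        return self.beta_xy_direct + self.beta_xm * self.beta_my

    @property
    def me(self) -> float:
        return self.beta_xm * self.beta_my

    @property
    def proportion(self) -> float:
        if self.te == 0:
            raise ValueError("proportion undefined for a zero total effect")
        return self.me / self.te


@dataclass
class MRPairData:
    """One simulated exposure with its outcome cohorts and the planted truth."""

    exposure: SummaryStatsTable
    outcomes: list
    ld: LDMatrix
    truth: dict


@dataclass
class MediationChainData:
    exposure: SummaryStatsTable
    mediator: SummaryStatsTable
    outcomes: list
    ld: LDMatrix
    truth: MediationTruth

    @property
    def outcome(self) -> SummaryStatsTable:
        """First outcome cohort (convenience for single-cohort use)."""
        return self.outcomes[0]


def _pleio_effects(pleio: Pleiotropy, k: int, se_out: float, rng) -> tuple[np.ndarray, list]:
    alpha = np.zeros(k)
    planted: list[int] = []
    if pleio.kind == "none":
        pass
    elif pleio.kind == "balanced":
        alpha = rng.normal(0.0, pleio.sd, k)
    elif pleio.kind == "directional":
        alpha = rng.normal(pleio.mean, pleio.sd, k)
    elif pleio.kind == "outliers":
        planted = list(range(k - pleio.count, k))
        for i, j in enumerate(planted):
            alpha[j] = (1 if i % 2 == 0 else -1) * pleio.magnitude * se_out
    else:
        raise ValueError(f"unknown pleiotropy kind {pleio.kind!r}")
    return alpha, planted


def simulate_effect_arrays(config: SimulationConfig, rng=None):
    """Fast array-level generator: (beta_exp, se_exp, beta_out, se_out, truth).

    The statistical core of :func:`simulate_mr_pair` without table plumbing
    or planted structural variants — per-variant true exposure effects drawn
    to clear genome-wide significance, estimates perturbed by their SEs, and
    outcome effects ``true_beta × gamma + pleiotropy`` per variant.  Intended
    for calibration studies that need many replicates; one outcome draw.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k = config.n_snp
    eaf = rng.uniform(0.1, 0.9, k)
    se_exp = 1.0 / np.sqrt(2.0 * config.n_exp * eaf * (1.0 - eaf))
    gamma = rng.uniform(6.5, 11.0, k) * se_exp * rng.choice([-1.0, 1.0], k)
    bx = gamma + rng.normal(0.0, se_exp)
    alpha, planted = _pleio_effects(config.pleiotropy, k, config.se_out, rng)
    sy = np.full(k, config.se_out)
    by = config.true_beta * gamma + alpha + rng.normal(0.0, sy)
    truth = {"gamma": gamma, "alpha": alpha, "outlier_indices": planted,
             "true_beta": config.true_beta, "eaf": eaf}
    return bx, se_exp, by, sy, truth


def _assign_positions(k: int):
    """Spread variants far apart (one per 25 Mb, cycling chromosomes)."""
    chrom = [str(1 + (i % 22)) for i in range(k)]
    pos = [25_000_000 * (1 + i // 22) + 1_000_000 * (i % 22) for i in range(k)]
    return chrom, pos


def _table(trait_id, trait_type, rsid, chrom, pos, ea, oa, eaf, beta, se, n):
    z = np.abs(np.asarray(beta) / np.asarray(se))
    pval = np.clip(2 * stats.norm.sf(z), np.nextafter(0, 1), 1.0)
    df = pd.DataFrame({
        "rsid": rsid, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pval": pval,
        "n": float(n),
    })
    return SummaryStatsTable(trait_id, trait_type, df)


def simulate_mr_pair(config: SimulationConfig, exposure_id: str = "exposure",
                     outcome_id: str = "osteoporosis",
                     rsid_start: int = 1000) -> MRPairData:
    """Simulate one exposure GWAS and its outcome cohorts under a linear model.

    Per-variant true exposure effects gamma_j are drawn large enough to pass
    p < 5e-8 with high probability at ``n_exp``; exposure estimates add
    N(0, se_exp) noise; each outcome cohort independently observes
    ``true_beta·gamma_j + pleiotropy_j`` with N(0, se_out) noise (pleiotropic
    effects are variant properties shared across cohorts).  With
    ``plant_structure`` the first three variants exercise harmonization and
    clumping deterministically: index 0 is an ambiguous A/T palindrome at
    eaf 0.5 (dropped), index 1 has swapped alleles in every outcome table
    (orientation flip recovered), and index 2 sits in strong LD (r² = 0.95)
    with index 3 inside the clumping window (clumped away).  The truth record
    lists the rsids expected to survive selection + harmonization.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_snp
    rsid = [f"rs{rsid_start + i}" for i in range(k)]
    chrom, pos = _assign_positions(k)
    pair_idx = rng.integers(0, len(_SAFE_PAIRS), k)
    ea = [_SAFE_PAIRS[i][0] for i in pair_idx]
    oa = [_SAFE_PAIRS[i][1] for i in pair_idx]

    eaf = rng.uniform(0.1, 0.9, k)
    se_exp = 1.0 / np.sqrt(2.0 * config.n_exp * eaf * (1.0 - eaf))
    gamma = rng.uniform(6.5, 11.0, k) * se_exp * rng.choice([-1.0, 1.0], k)
    bx = gamma + rng.normal(0.0, se_exp)

    ld = LDMatrix.identity(rsid)
    dropped_structural: list[str] = []
    if config.plant_structure:
        ea[0], oa[0] = "A", "T"          # ambiguous palindrome
        eaf[0] = 0.5
        se_exp[0] = 1.0 / np.sqrt(2.0 * config.n_exp * 0.25)
        # index 2 duplicates index 3's signal inside the window, worse p
        chrom[2] = chrom[3]
        pos[2] = pos[3] + 50_000
        gamma[2] = gamma[3]
        bx[2] = gamma[3] + rng.normal(0.0, se_exp[2])
        if abs(bx[2] / se_exp[2]) > abs(bx[3] / se_exp[3]):
            bx[2], bx[3] = gamma[3] + (bx[3] - gamma[3]), gamma[3] + (bx[2] - gamma[2])
        mat = ld._r2.copy()
        mat.loc[rsid[2], rsid[3]] = mat.loc[rsid[3], rsid[2]] = 0.95
        ld = LDMatrix(mat)
        dropped_structural = [rsid[0], rsid[2]]

    exposure = _table(exposure_id, "quantitative", rsid, chrom, pos, ea, oa,
                      eaf, bx, se_exp, config.n_exp)

    alpha, planted = _pleio_effects(config.pleiotropy, k, config.se_out, rng)
    sy = np.full(k, config.se_out)
    outcomes = []
    for c in range(config.n_cohorts):
        by = config.true_beta * gamma + alpha + rng.normal(0.0, sy)
        ea_o, oa_o, by_o = list(ea), list(oa), by.copy()
        eaf_o = np.clip(eaf + rng.normal(0.0, 0.01, k), 0.01, 0.99)
        if config.plant_structure:
            ea_o[1], oa_o[1] = oa[1], ea[1]   # swapped orientation
            by_o[1] = -by_o[1]
            eaf_o[1] = 1.0 - eaf_o[1]
        outcomes.append(_table(f"{outcome_id}_cohort{c + 1}", "binary",
                               rsid, chrom, pos, ea_o, oa_o, eaf_o, by_o, sy,
                               config.n_out))

    expected = [r for i, r in enumerate(rsid) if r not in dropped_structural]
    truth = {
        "gamma": gamma, "alpha": alpha, "true_beta": config.true_beta,
        "outlier_rsids": [rsid[j] for j in planted],
        "outlier_indices": planted,
        "dropped_structural": dropped_structural,
        "expected_instruments": expected,
    }
    return MRPairData(exposure, outcomes, ld, truth)


def simulate_mediation_chain(truth: MediationTruth, config: SimulationConfig,
                             n_mediator: int = 8299,
                             exposure_id: str = "taxon",
                             mediator_id: str = "metabolite",
                             outcome_id: str = "osteoporosis",
                             rsid_start: int = 1000) -> MediationChainData:
    """Simulate GWAS tables for a three-layer causal chain.

    Two disjoint instrument sets: G_X (the exposure's instruments) and G_M
    (the mediator's own instruments, null for the exposure).  The mediator
    GWAS reflects ``beta_xm`` over G_X; the outcome GWAS reflects the total
    effect ``beta_xy_direct + beta_xm·beta_my`` over G_X and ``beta_my`` over
    G_M (mediator instruments reach the outcome only through the mediator).
    Two-step MR on these tables recovers em ≈ beta_xm, mo ≈ beta_my and
    te ≈ total.  Structural planting is disabled here; all variants are
    mutually independent.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_snp
    total = 2 * k
    rsid = [f"rs{rsid_start + i}" for i in range(total)]
    chrom, pos = _assign_positions(total)
    pair_idx = rng.integers(0, len(_SAFE_PAIRS), total)
    ea = [_SAFE_PAIRS[i][0] for i in pair_idx]
    oa = [_SAFE_PAIRS[i][1] for i in pair_idx]
    eaf = rng.uniform(0.1, 0.9, total)

    gx = slice(0, k)
    gm = slice(k, total)
    se_x = 1.0 / np.sqrt(2.0 * config.n_exp * eaf * (1.0 - eaf))
    se_m = 1.0 / np.sqrt(2.0 * n_mediator * eaf * (1.0 - eaf))
    se_y = np.full(total, config.se_out)

    gamma_x = rng.uniform(6.5, 11.0, total) * se_x * rng.choice([-1.0, 1.0], total)
    gamma_m = rng.uniform(6.5, 11.0, total) * se_m * rng.choice([-1.0, 1.0], total)

    # true per-variant effects on each trait
    exp_true = np.zeros(total)
    exp_true[gx] = gamma_x[gx]
    med_true = np.zeros(total)
    med_true[gx] = truth.beta_xm * gamma_x[gx]
    med_true[gm] = gamma_m[gm]
    out_true = np.zeros(total)
    out_true[gx] = truth.te * gamma_x[gx]
    out_true[gm] = truth.beta_my * gamma_m[gm]

    exposure = _table(exposure_id, "quantitative", rsid, chrom, pos, ea, oa, eaf,
                      exp_true + rng.normal(0.0, se_x), se_x, config.n_exp)
    mediator = _table(mediator_id, "quantitative", rsid, chrom, pos, ea, oa, eaf,
                      med_true + rng.normal(0.0, se_m), se_m, n_mediator)
    outcomes = [
        _table(f"{outcome_id}_cohort{c + 1}", "binary", rsid, chrom, pos, ea, oa,
               eaf, out_true + rng.normal(0.0, se_y), se_y, config.n_out)
        for c in range(config.n_cohorts)
    ]
    return MediationChainData(exposure, mediator, outcomes,
                              LDMatrix.identity(rsid), truth)


def simulate_ldsc_traits(h2_1: float, h2_2: float, rg: float, M: int,
                         n1: float, n2: float, seed: int,
                         trait1: str = "trait1", trait2: str = "trait2"):
    """Simulate per-variant z-score pairs obeying the LD-score model.

    LD scores are drawn from 1 + Exponential(mean 30); for each variant the
    z-pair is bivariate normal with E[z1²] = n1·h2_1·ℓ/M + 1 (trait 2
    analogous) and E[z1·z2] = sqrt(n1·n2)·rg·sqrt(h2_1·h2_2)·ℓ/M.  Returns
    the regression-ready table and the truth record.
    """
    if not (0 < h2_1 < 1 and 0 < h2_2 < 1):
        raise ValueError("heritabilities must lie in (0,1)")
    if abs(rg) > 1:
        raise ValueError("genetic correlation must lie in [-1,1]")
    if M < 1 or n1 <= 0 or n2 <= 0:
        raise ValueError("M and sample sizes must be positive")
    rng = np.random.default_rng(seed)
    ell = 1.0 + rng.exponential(30.0, M)
    v1 = n1 * h2_1 * ell / M + 1.0
    v2 = n2 * h2_2 * ell / M + 1.0
    cov = np.sqrt(n1 * n2 * h2_1 * h2_2) * rg * ell / M
    u1 = rng.standard_normal(M)
    u2 = rng.standard_normal(M)
    z1 = np.sqrt(v1) * u1
    resid_var = np.maximum(v2 - cov**2 / v1, 0.0)
    z2 = cov / np.sqrt(v1) * u1 + np.sqrt(resid_var) * u2
    df = pd.DataFrame({
        "rsid": [f"rs{i}" for i in range(M)],
        "z1": z1, "z2": z2, "ld_score": ell,
        "n1": float(n1), "n2": float(n2),
    })
    table = LdscVariantTable(df, M=M, trait1=trait1, trait2=trait2)
    truth = {"h2_1": h2_1, "h2_2": h2_2, "rg": rg, "M": M, "n1": n1, "n2": n2}
    return table, truth
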