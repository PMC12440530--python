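"""Cross-trait LD-score regression for genetic correlation.

Under a polygenic model, the expected squared z-score of variant j grows
linearly in its LD score ℓ_j: E[z²] = n·h²·ℓ/M + 1, and the cross-trait
product obeys E[z1·z2] = sqrt(n1·n2)·rho_g·ℓ/M + intercept, where M is the
number of variants the heritability is normalized over.  Regressing z², z²
and z1·z2 on ℓ (free intercepts, weights 1/max(ℓ,1)) yields heritability and
genetic-covariance slopes, hence the genetic correlation

    rg = gcov / sqrt(h2_1 · h2_2)

with a delete-one block jackknife over contiguous variant blocks for the SE.
QC mirrors common practice: non-SNP alleles, MAF < 0.01, duplicates, and
strand-ambiguous (A/T, G/C) variants are removed before merging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import COMPLEMENT, VALID_ALLELES, SummaryStatsTable, is_palindromic

__all__ = ["LdscVariantTable", "LdscResult", "qc_merge", "ldsc_rg"]


@dataclass
class LdscVariantTable:
    """Merged per-variant z-scores for two traits plus LD scores.

    ``df`` columns: rsid, z1, z2, ld_score, n1, n2.  ``M`` is the variant
    count used as the normalizing denominator of the heritability slopes
    (at least the number of rows).
    """

    df: pd.DataFrame
    M: int
    trait1: str = "trait1"
    trait2: str = "trait2"

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class LdscResult:
    """Heritabilities, genetic covariance and correlation with jackknife SE."""

    h2_1: float
    h2_2: float
    gcov: float
    rg: float
    rg_se: float
    rg_p: float
    intercepts: tuple  # (z1² regression, z2² regression, z1·z2 regression)
    n_blocks: int
    flags: list = field(default_factory=list)


def qc_merge(sumstats1: SummaryStatsTable, sumstats2: SummaryStatsTable,
             ld_scores: pd.DataFrame, snp_whitelist=None,
             n1: float | None = None, n2: float | None = None,
             M: int | None = None, maf_min: float = 0.01) -> LdscVariantTable:
    """Merge two GWAS with LD scores into the regression input table.

    Variants are intersected on rsid (and an optional whitelist), trait 2's z
    sign-flipped where its alleles are swapped (or strand-complement-swapped)
    relative to trait 1, and standard QC applied: non-SNP alleles, MAF below
    ``maf_min`` in either trait, duplicate rsids (first kept), and
    strand-ambiguous variants are removed.  ``n1``/``n2`` override per-variant
    sample sizes when the tables lack them.  z = beta/se.
    """

    def _clean(df: pd.DataFrame, n_const) -> pd.DataFrame:
        d = df.copy()
        d = d[~d.duplicated(subset="rsid", keep="first")]
        ok_allele = d["effect_allele"].isin(VALID_ALLELES) & d["other_allele"].isin(VALID_ALLELES)
        d = d[ok_allele & (d["effect_allele"] != d["other_allele"])]
        ambiguous = d.apply(lambda r: is_palindromic(r["effect_allele"], r["other_allele"]), axis=1)
        d = d[~ambiguous]
        maf = np.minimum(d["eaf"], 1 - d["eaf"])
        d = d[maf.isna() | (maf >= maf_min)]
        if d["n"].isna().any():
            if n_const is None:
                raise ValueError("sample size missing and no constant n supplied")
            d["n"] = d["n"].fillna(float(n_const))
        return d

    d1 = _clean(sumstats1.df, n1)
    d2 = _clean(sumstats2.df, n2)
    if snp_whitelist is not None:
        wl = set(snp_whitelist)
        d1 = d1[d1["rsid"].isin(wl)]
    ld = ld_scores[["rsid", "ld_score"]].drop_duplicates(subset="rsid")

    merged = d1.merge(d2, on="rsid", suffixes=("_1", "_2")).merge(ld, on="rsid")
    if len(merged) == 0:
        raise ValueError("empty intersection between the two GWAS and the LD scores")

    same = (merged["effect_allele_2"] == merged["effect_allele_1"]) & \
           (merged["other_allele_2"] == merged["other_allele_1"])
    swap = (merged["effect_allele_2"] == merged["other_allele_1"]) & \
           (merged["other_allele_2"] == merged["effect_allele_1"])
    c_ea = merged["effect_allele_2"].map(COMPLEMENT)
    c_oa = merged["other_allele_2"].map(COMPLEMENT)
    comp_same = (c_ea == merged["effect_allele_1"]) & (c_oa == merged["other_allele_1"])
    comp_swap = (c_ea == merged["other_allele_1"]) & (c_oa == merged["effect_allele_1"])
    sign = np.where(same | comp_same, 1.0, np.where(swap | comp_swap, -1.0, np.nan))
    merged = merged[~np.isnan(sign)]
    sign = sign[~np.isnan(sign)]

    out = pd.DataFrame({
        "rsid": merged["rsid"].to_numpy(),
        "z1": (merged["beta_1"] / merged["se_1"]).to_numpy(float),
        "z2": sign * (merged["beta_2"] / merged["se_2"]).to_numpy(float),
        "ld_score": merged["ld_score"].to_numpy(float),
        "n1": merged["n_1"].to_numpy(float),
        "n2": merged["n_2"].to_numpy(float),
    })
    if np.any(out["ld_score"] < 0):
        raise ValueError("LD scores must be nonnegative")
    return LdscVariantTable(out.reset_index(drop=True), M=int(M or len(out)),
                            trait1=sumstats1.trait_id, trait2=sumstats2.trait_id)


def _wls_slope_intercept(x, y, w):
    """Weighted least squares of y on x with intercept, from sufficient stats."""
    sw = np.sum(w)
    sx = np.sum(w * x)
    sy_ = np.sum(w * y)
    sxx = np.sum(w * x * x)
    sxy = np.sum(w * x * y)
    denom = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy_) / denom
    intercept = (sy_ - slope * sx) / sw
    return slope, intercept


def _rg_from_sums(stats6, M, nbar1, nbar2):
    """(h2_1, h2_2, gcov, rg, intercepts) from the six weighted sums per target."""
    out = []
    intercepts = []
    scale = (M / nbar1, M / nbar2, M / np.sqrt(nbar1 * nbar2))
    for t in range(3):
        sw, sx, sy_, sxx, sxy = stats6[t]
        denom = sw * sxx - sx * sx
        slope = (sw * sxy - sx * sy_) / denom
        intercepts.append((sy_ - slope * sx) / sw)
        out.append(slope * scale[t])
    h2_1, h2_2, gcov = out
    prod = h2_1 * h2_2
    rg = gcov / np.sqrt(prod) if prod > 0 else np.nan
    return h2_1, h2_2, gcov, rg, tuple(intercepts)


def ldsc_rg(table: LdscVariantTable, n_blocks: int = 200) -> LdscResult:
    """Genetic correlation via three LD-score regressions + block jackknife.

    Requires at least ``10 * n_blocks`` variants.  Weights are the
    heteroskedasticity heuristic 1/max(ℓ, 1); intercepts are unconstrained.
    The jackknife deletes one of ``n_blocks`` contiguous blocks at a time and
    re-runs the full rg pipeline; the SE is the usual delete-one estimate.  A
    nonpositive heritability leaves rg undefined and flags "unstable_h2";
    out-of-range rg is flagged, never truncated.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    d = table.df
    m = len(d)
    if m < 10 * n_blocks:
        raise ValueError(f"need at least {10 * n_blocks} variants for {n_blocks} blocks")
    ell = d["ld_score"].to_numpy(float)
    z1 = d["z1"].to_numpy(float)
    z2 = d["z2"].to_numpy(float)
    w = 1.0 / np.maximum(ell, 1.0)
    nbar1 = float(d["n1"].mean())
    nbar2 = float(d["n2"].mean())
    M = table.M

    targets = (z1 * z1, z2 * z2, z1 * z2)
    # per-block sufficient statistics for each of the three regressions
    bounds = np.linspace(0, m, n_blocks + 1).astype(int)
    block_stats = np.zeros((3, n_blocks, 5))
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        xw, ww = ell[sl], w[sl]
        for t, y in enumerate(targets):
            yw = y[sl]
            block_stats[t, b] = (
                np.sum(ww), np.sum(ww * xw), np.sum(ww * yw),
                np.sum(ww * xw * xw), np.sum(ww * xw * yw),
            )
    totals = block_stats.sum(axis=1)  # (3, 5)

    h2_1, h2_2, gcov, rg, intercepts = _rg_from_sums(totals, M, nbar1, nbar2)
    flags = []
    if not (h2_1 > 0 and h2_2 > 0):
        flags.append("unstable_h2")
        return LdscResult(h2_1, h2_2, gcov, float("nan"), float("nan"), float("nan"),
                          intercepts, n_blocks, flags)

    jk = np.empty(n_blocks)
    for b in range(n_blocks):
        sums = totals - block_stats[:, b, :]
        jk[b] = _rg_from_sums(sums, M, nbar1, nbar2)[3]
    if np.any(np.isnan(jk)):
        flags.append("unstable_h2_jackknife")
        jk = jk[~np.isnan(jk)]
    nb = len(jk)
    rg_se = float(np.sqrt((nb - 1) / nb * np.sum((jk - np.mean(jk)) ** 2)))
    rg_p = float(2 * stats.norm.sf(abs(rg) / rg_se)) if rg_se > 0 else float("nan")
    if abs(rg) > 1:
        flags.append("rg_out_of_range")
    return LdscResult(float(h2_1), float(h2_2), float(gcov), float(rg), rg_se, rg_p,
                      tuple(float(i) for i in intercepts), n_blocks, flags)
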