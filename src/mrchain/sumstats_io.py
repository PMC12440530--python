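"""GWAS summary-statistics I/O, instrument selection, and allele harmonization.

Summary statistics are one row per variant: identifier, chromosome, position,
effect/other allele, effect-allele frequency, effect size (SD units for
quantitative traits, log-odds for binary traits), standard error, p-value and
sample size.  Instruments are selected by p-value thresholding, greedy LD
clumping, and an F-statistic strength filter, then harmonized against an
outcome GWAS onto a common effect allele.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VALID_ALLELES",
    "COMPLEMENT",
    "DEFAULT_COLUMN_MAP",
    "InstrumentConfig",
    "SummaryStatsTable",
    "InstrumentSelection",
    "HarmonizedSet",
    "LDMatrix",
    "read_sumstats",
    "write_sumstats",
    "compute_f_statistic",
    "clump",
    "select_instruments",
    "harmonize",
    "is_palindromic",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default mapping from canonical field name -> column header in the file
DEFAULT_COLUMN_MAP = {
    "rsid": "rsid",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

MANDATORY = ("rsid", "effect_allele", "other_allele", "beta", "se", "pval")

CANONICAL_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]


@dataclass(frozen=True)
class InstrumentConfig:
    """Thresholds of the instrument filtering cascade.

    Defaults: genome-wide significance 5e-8 with fallback to 5e-6 when fewer
    than ``min_snps_for_relaxation`` instruments survive; clumping window
    10,000 kb at r² < 0.001; weak-instrument cutoff F ≥ 10; instruments
    associated with the outcome at p < 5e-6 are removed; palindromic variants
    with effect-allele frequency in the ambiguity band are dropped.
    """

    p_primary: float = 5e-8
    p_relaxed: float = 5e-6
    clump_window_kb: int = 10_000
    clump_r2: float = 0.001
    f_min: float = 10.0
    outcome_p_exclude: float = 5e-6
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58)
    min_snps_for_relaxation: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.p_primary <= self.p_relaxed < 1.0):
            raise ValueError("need 0 < p_primary <= p_relaxed < 1")
        if not (0.0 < self.clump_r2 < 1.0):
            raise ValueError("clump_r2 must lie in (0, 1)")
        if self.f_min <= 0:
            raise ValueError("f_min must be positive")
        lo, hi = self.palindrome_eaf_band
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("palindrome_eaf_band must be an increasing pair in [0,1]")


@dataclass
class SummaryStatsTable:
    """One trait's GWAS summary statistics with canonical column names.

    ``df`` columns: rsid, chrom, pos, effect_allele, other_allele, eaf, beta,
    se, pval, n.  rsids are unique; alleles upper-case single bases; se > 0;
    pval in (0, 1].
    """

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    df: pd.DataFrame
    n_dropped: int = 0
    drop_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, rsids) -> "SummaryStatsTable":
        sub = self.df[self.df["rsid"].isin(set(rsids))].reset_index(drop=True)
        return replace(self, df=sub, n_dropped=0, drop_log={})


@dataclass
class InstrumentSelection:
    """Instruments retained for one exposure, with the selection tier used."""

    exposure_id: str
    trait_type: str
    records: pd.DataFrame        # canonical columns, ordered by p ascending
    tier: str                    # "primary" | "relaxed" | "none"

    def __len__(self) -> int:
        return len(self.records)

    @property
    def is_empty(self) -> bool:
        return len(self.records) == 0


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to a common effect allele.

    ``df`` columns: rsid, beta_exp, se_exp, beta_out, se_out, eaf_exp, flipped.
    ``drops`` records every excluded instrument with a reason flag, one of
    not_in_outcome / dropped_palindrome / dropped_mismatch /
    dropped_outcome_assoc / dropped_weak.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    drops: pd.DataFrame  # columns: rsid, reason
    outcome_trait_type: str = "binary"

    def __len__(self) -> int:
        return len(self.df)

    @property
    def k(self) -> int:
        return len(self.df)

    def arrays(self):
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        d = self.df
        return (
            d["beta_exp"].to_numpy(float),
            d["se_exp"].to_numpy(float),
            d["beta_out"].to_numpy(float),
            d["se_out"].to_numpy(float),
        )

    def to_table(self) -> pd.DataFrame:
        out = self.df.copy()
        out.insert(0, "exposure", self.exposure_id)
        out.insert(1, "outcome", self.outcome_id)
        return out


class LDMatrix:
    """Pairwise r² lookup backed by a square matrix with an rsid index.

    Pairs absent from the matrix resolve to NaN; the clumping rule treats a
    missing within-window pair as fully correlated (r² = 1), the conservative
    choice for stringent clumping.
    """

    def __init__(self, r2: pd.DataFrame):
        if not r2.index.equals(r2.columns):
            raise ValueError("r² matrix must be square with identical index/columns")
        self._r2 = r2
        self._index = {rs: i for i, rs in enumerate(r2.index)}
        self._values = r2.to_numpy(float)

    @classmethod
    def identity(cls, rsids) -> "LDMatrix":
        """All pairs independent (r² = 0 off-diagonal)."""
        rsids = list(rsids)
        mat = pd.DataFrame(np.eye(len(rsids)), index=rsids, columns=rsids)
        return cls(mat)

    @classmethod
    def from_file(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        df.columns = [str(c) for c in df.columns]
        df.index = [str(i) for i in df.index]
        return cls(df)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return float("nan")
        return float(self._values[ia, ib])


def _detect_sep(path) -> str:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_sumstats(path, *, trait_id: str, trait_type: str = "quantitative",
                  column_map: dict | None = None) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    The delimiter (tab or comma) is auto-detected from the header; gzip input
    is supported.  Rows violating per-variant invariants (se <= 0, p outside
    (0,1], invalid alleles, eaf outside [0,1], duplicate rsid) are dropped and
    counted in ``drop_log``; a missing mandatory column is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype={cmap["rsid"]: str})

    def _resolve(canon):
        # mapped header first, canonical field name as fallback
        for cand in (cmap.get(canon), canon):
            if cand is not None and cand in raw.columns:
                return cand
        return None

    for field_name in MANDATORY:
        if _resolve(field_name) is None:
            raise ValueError(
                f"missing mandatory column {cmap[field_name]!r} (field {field_name})"
            )

    df = pd.DataFrame()
    for canon in CANONICAL_COLUMNS:
        col = _resolve(canon)
        if col is not None:
            df[canon] = raw[col]
        else:
            df[canon] = np.nan
    df["rsid"] = df["rsid"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    drop_log: dict[str, int] = {}

    def _drop(mask: pd.Series, reason: str):
        nonlocal df
        n = int(mask.sum())
        if n:
            drop_log[reason] = drop_log.get(reason, 0) + n
            df = df[~mask]

    _drop(~df["effect_allele"].isin(VALID_ALLELES)
          | ~df["other_allele"].isin(VALID_ALLELES), "invalid_allele")
    _drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    _drop(df["beta"].isna() | df["se"].isna() | (df["se"] <= 0), "bad_se_or_beta")
    _drop(df["pval"].isna() | (df["pval"] <= 0) | (df["pval"] > 1), "bad_pval")
    _drop(df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1)), "bad_eaf")
    _drop(df.duplicated(subset="rsid", keep="first"), "duplicate_rsid")

    df = df.reset_index(drop=True)
    return SummaryStatsTable(
        trait_id=trait_id,
        trait_type=trait_type,
        df=df,
        n_dropped=sum(drop_log.values()),
        drop_log=drop_log,
    )


def write_sumstats(table: SummaryStatsTable, path, sep: str = "\t") -> None:
    table.df.to_csv(path, sep=sep, index=False)


def compute_f_statistic(beta, se):
    """Instrument-strength F statistic, F = beta² / se².

    Sign-invariant in beta; values below 10 conventionally flag weak
    instruments.  Accepts scalars or arrays; se must be strictly positive.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0 to compute an F statistic")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def is_palindromic(ea: str, oa: str) -> bool:
    """A/T or G/C pairs cannot be strand-resolved from alleles alone."""
    return COMPLEMENT.get(ea) == oa


def clump(records: pd.DataFrame, ld: LDMatrix, window_kb: int = 10_000,
          r2_max: float = 0.001) -> list[str]:
    """Greedy LD clumping: retain the best p-value, retire LD neighbours.

    Repeatedly take the unretired record with the smallest p-value (ties on p
    broken by position then rsid), retain it, and retire all records on the
    same chromosome within ``window_kb`` kilobases whose r² with it is >=
    ``r2_max``.  A missing r² for a within-window pair is treated as r² = 1
    (retired).  Cross-chromosome pairs are always independent.  Returns the
    retained rsids in retention order.
    """
    if len(records) == 0:
        return []
    cols = records[["rsid", "chrom", "pos", "pval"]].copy()
    cols = cols.sort_values(["pval", "pos", "rsid"], kind="mergesort").reset_index(drop=True)
    window_bp = window_kb * 1000
    retired = np.zeros(len(cols), dtype=bool)
    retained: list[str] = []
    rsid = cols["rsid"].to_numpy()
    chrom = cols["chrom"].to_numpy()
    pos = cols["pos"].to_numpy(float)
    for i in range(len(cols)):
        if retired[i]:
            continue
        retained.append(rsid[i])
        retired[i] = True
        for j in range(len(cols)):
            if retired[j] or chrom[j] != chrom[i]:
                continue
            if abs(pos[j] - pos[i]) > window_bp:
                continue
            r2 = ld.r2(rsid[i], rsid[j])
            if np.isnan(r2):
                r2 = 1.0  # stringent: unknown LD within window -> drop
            if r2 >= r2_max:
                retired[j] = True
    return retained


def _select_at(exposure: SummaryStatsTable, p_thresh: float,
               config: InstrumentConfig, ld: LDMatrix) -> pd.DataFrame:
    cand = exposure.df[exposure.df["pval"] < p_thresh]
    if len(cand) == 0:
        return cand
    kept = clump(cand, ld, config.clump_window_kb, config.clump_r2)
    cand = cand[cand["rsid"].isin(set(kept))]
    f = compute_f_statistic(cand["beta"].to_numpy(), cand["se"].to_numpy())
    cand = cand[np.asarray(f) >= config.f_min]
    return cand.sort_values(["pval", "pos", "rsid"], kind="mergesort").reset_index(drop=True)


def select_instruments(exposure: SummaryStatsTable, config: InstrumentConfig,
                       ld: LDMatrix) -> InstrumentSelection:
    """Select instruments at genome-wide significance, relaxing if too few.

    Filter at ``p_primary``, clump, drop F < f_min.  If fewer than
    ``min_snps_for_relaxation`` survive, restart from scratch at
    ``p_relaxed``.  An exposure with zero instruments after relaxation is
    returned empty with tier "none" (the pipeline skips it).
    """
    primary = _select_at(exposure, config.p_primary, config, ld)
    if len(primary) >= config.min_snps_for_relaxation:
        return InstrumentSelection(exposure.trait_id, exposure.trait_type, primary, "primary")
    relaxed = _select_at(exposure, config.p_relaxed, config, ld)
    if len(relaxed) == 0:
        return InstrumentSelection(exposure.trait_id, exposure.trait_type, relaxed, "none")
    # the relaxed set supersedes (it contains every primary instrument)
    tier = "relaxed" if len(relaxed) > len(primary) else "primary"
    return InstrumentSelection(exposure.trait_id, exposure.trait_type, relaxed, tier)


def _orient(ea_x, oa_x, ea_y, oa_y):
    """How outcome alleles map onto exposure alleles.

    Returns "same", "flip", or None (irreconcilable).  Strand-complement
    resolution is attempted only for non-palindromic pairs; for a palindromic
    pair complementing is indistinguishable from swapping, so label matching
    alone decides and frequency evidence is handled by the caller.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "flip"
    if not is_palindromic(ea_x, oa_x):
        cea, coa = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
        if (cea, coa) == (ea_x, oa_x):
            return "same"
        if (cea, coa) == (oa_x, ea_x):
            return "flip"
    return None


def harmonize(instruments, outcome: SummaryStatsTable,
              config: InstrumentConfig | None = None) -> HarmonizedSet:
    """Align exposure instruments and outcome effects to a common effect allele.

    Rules, per instrument found in the outcome GWAS:

    * same allele orientation -> keep as-is;
    * swapped orientation -> negate the outcome beta, flip the outcome eaf;
    * strand-complement pair (non-palindromic only) -> complement, then the
      same rules;
    * palindromic (A/T, G/C) with exposure eaf inside the ambiguity band, or
      with missing eaf -> dropped (strand unresolvable);
    * palindromic outside the band: orientation from allele labels, then a
      strand flip is inferred when the aligned outcome eaf sits on the
      opposite side of 0.5 from the exposure eaf;
    * irreconcilable allele sets -> dropped as mismatch;
    * absent from the outcome -> dropped (no proxy variants are used);
    * outcome association p below the exclusion threshold -> dropped;
    * F = beta_exp²/se_exp² below f_min -> dropped as weak.
    """
    if config is None:
        config = InstrumentConfig()
    if isinstance(instruments, InstrumentSelection):
        exp_df = instruments.records
        exposure_id = instruments.exposure_id
    elif isinstance(instruments, SummaryStatsTable):
        exp_df = instruments.df
        exposure_id = instruments.trait_id
    else:
        exp_df = instruments
        exposure_id = "exposure"
    if len(exp_df) == 0:
        raise ValueError("instrument set is empty")

    out_idx = outcome.df.set_index("rsid")
    lo, hi = config.palindrome_eaf_band
    kept_rows = []
    drops = []
    for row in exp_df.itertuples(index=False):
        rsid = row.rsid
        if rsid not in out_idx.index:
            drops.append((rsid, "not_in_outcome"))
            continue
        orow = out_idx.loc[rsid]
        ea_x, oa_x = row.effect_allele, row.other_allele
        ea_y, oa_y = orow["effect_allele"], orow["other_allele"]
        eaf_x = row.eaf
        palindromic = is_palindromic(ea_x, oa_x)
        if palindromic and (pd.isna(eaf_x) or lo <= eaf_x <= hi):
            drops.append((rsid, "dropped_palindrome"))
            continue
        orient = _orient(ea_x, oa_x, ea_y, oa_y)
        if orient is None:
            drops.append((rsid, "dropped_mismatch"))
            continue
        beta_out = float(orow["beta"])
        eaf_out = orow["eaf"]
        flipped = orient == "flip"
        if flipped:
            beta_out = -beta_out
            if pd.notna(eaf_out):
                eaf_out = 1.0 - eaf_out
        if palindromic and pd.notna(eaf_out):
            # frequency evidence of a strand flip after label alignment
            if (eaf_out > 0.5) != (eaf_x > 0.5):
                beta_out = -beta_out
                flipped = not flipped
        if float(orow["pval"]) < config.outcome_p_exclude:
            drops.append((rsid, "dropped_outcome_assoc"))
            continue
        if compute_f_statistic(row.beta, row.se) < config.f_min:
            drops.append((rsid, "dropped_weak"))
            continue
        kept_rows.append({
            "rsid": rsid,
            "beta_exp": float(row.beta),
            "se_exp": float(row.se),
            "beta_out": beta_out,
            "se_out": float(orow["se"]),
            "eaf_exp": float(eaf_x) if pd.notna(eaf_x) else np.nan,
            "flipped": flipped,
        })
    df = pd.DataFrame(kept_rows, columns=[
        "rsid", "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp", "flipped",
    ])
    drops_df = pd.DataFrame(drops, columns=["rsid", "reason"])
    return HarmonizedSet(
        exposure_id=exposure_id,
        outcome_id=outcome.trait_id,
        df=df,
        drops=drops_df,
        outcome_trait_type=outcome.trait_type,
    )
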