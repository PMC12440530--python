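"""End-to-end orchestration of the two-phase study design.

Phase 1: forward MR of every exposure against every outcome cohort (with the
full estimator battery and diagnostics), reverse MR with roles swapped,
cross-trait LD-score genetic correlation, and fixed-effects meta-analysis
across cohorts with the exclusion cascade and Bonferroni classification.
Phase 2: a mediator screen (exposure→mediator and mediator→outcome MR) and
product-of-coefficients mediation against the exposure's total-effect
meta-estimate.

A run is driven by a YAML study config, writes delimited result tables, a
skip/exclusion log, and a manifest recording package version, config hash
and seeds; identical config + seeds reproduce every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ldsc import ldsc_rg, qc_merge
from .meta import (CohortDiagnostics, SignificanceRule, classify,
                   exclusion_filter, fixed_effect_meta, mediate, replay_table,
                   sensitivity_consistent)
from .mr import cochran_q, egger, ivw, odds_ratio_ci, wald_ratio, weighted_median
from .presso import presso_global
from .sumstats_io import (HarmonizedSet, InstrumentConfig, LDMatrix,
                          SummaryStatsTable, harmonize, read_sumstats,
                          select_instruments, write_sumstats)

__all__ = [
    "StudyConfig",
    "PairAnalysis",
    "analyze_pair",
    "run_forward_mr",
    "run_reverse_mr",
    "run_ldsc",
    "run_mediation",
    "replay_mediation_file",
    "materialize_fixtures",
    "write_manifest",
]


@dataclass
class TraitSpec:
    trait_id: str
    path: str
    trait_type: str = "quantitative"
    column_map: dict | None = None

    def load(self) -> SummaryStatsTable:
        return read_sumstats(self.path, trait_id=self.trait_id,
                             trait_type=self.trait_type,
                             column_map=self.column_map)


@dataclass
class StudyConfig:
    """Paths, thresholds and seeds for one pipeline run."""

    exposures: list
    outcomes: list
    mediators: list = field(default_factory=list)
    ld_matrix: str | None = None         # square r² matrix; None -> all independent
    ld_scores: str | None = None         # rsid, ld_score table for LDSC
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    m_tests_exposures: int = 416
    m_tests_mediators: int = 1178
    alpha: float = 0.05
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 1
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def _traits(key):
            out = []
            for item in raw.get(key, []):
                item = dict(item)
                item["path"] = str((base / item["path"]).resolve())
                out.append(TraitSpec(**item))
            return out

        icfg = InstrumentConfig(**raw.get("instrument", {}))
        kwargs = {k: raw[k] for k in ("m_tests_exposures", "m_tests_mediators",
                                      "alpha", "n_boot", "n_sim", "seed", "out_dir")
                  if k in raw}
        for k in ("ld_matrix", "ld_scores"):
            if raw.get(k):
                kwargs[k] = str((base / raw[k]).resolve())
        return cls(exposures=_traits("exposures"), outcomes=_traits("outcomes"),
                   mediators=_traits("mediators"), instrument=icfg, **kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class PairAnalysis:
    """Every estimator + diagnostic for one exposure × outcome-cohort pair."""

    exposure_id: str
    outcome_id: str
    hset: HarmonizedSet | None
    tier: str
    estimates: dict            # method -> MREstimate
    q: object | None = None    # HeterogeneityReport at the FE-IVW estimate
    presso_global_p: float | None = None
    skip_reason: str | None = None

    @property
    def n_snp(self) -> int:
        return 0 if self.hset is None else self.hset.k

    def diagnostics(self) -> CohortDiagnostics:
        eg = self.estimates.get("egger")
        return CohortDiagnostics(
            cohort_id=self.outcome_id,
            n_snp=self.n_snp,
            egger_intercept_p=None if eg is None else eg.extras["intercept_p"],
            presso_global_p=self.presso_global_p,
        )


def _derive_seed(base: int, *labels) -> int:
    h = hashlib.sha256(":".join([str(base), *map(str, labels)]).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def analyze_pair(exposure: SummaryStatsTable, outcome: SummaryStatsTable,
                 ld: LDMatrix, icfg: InstrumentConfig, seed: int,
                 n_boot: int = 1000, n_sim: int = 1000) -> PairAnalysis:
    """Instrument selection, harmonization and the full estimator battery.

    Methods run by instrument count: Wald ratio at k = 1, IVW (FE + MRE) and
    Cochran's Q at k >= 2, MR-Egger and weighted median at k >= 3, the
    MR-PRESSO global test at k >= 4.  A pair with no instruments or an empty
    harmonized set is returned skipped, never raised.
    """
    sel = select_instruments(exposure, icfg, ld)
    if sel.is_empty:
        return PairAnalysis(exposure.trait_id, outcome.trait_id, None, "none",
                            {}, skip_reason="no_instrument_exposure")
    hset = harmonize(sel, outcome, icfg)
    k = hset.k
    if k == 0:
        return PairAnalysis(exposure.trait_id, outcome.trait_id, hset, sel.tier,
                            {}, skip_reason="empty_harmonized_set")
    est: dict = {}
    q = None
    presso_p = None
    bx, sx, by, sy = hset.arrays()
    if k == 1:
        est["wald"] = wald_ratio(bx[0], sx[0], by[0], sy[0])
    else:
        est["ivw_fe"] = ivw(hset, "fe")
        est["ivw_mre"] = ivw(hset, "mre")
        q = cochran_q(hset, est["ivw_fe"].beta)
    if k >= 3:
        est["egger"] = egger(hset)
        est["weighted_median"] = weighted_median(
            hset, n_boot=n_boot,
            seed=_derive_seed(seed, "wm", exposure.trait_id, outcome.trait_id))
    if k >= 4:
        presso_p = presso_global(
            hset, n_sim=n_sim,
            seed=_derive_seed(seed, "presso", exposure.trait_id, outcome.trait_id),
        ).global_p
    return PairAnalysis(exposure.trait_id, outcome.trait_id, hset, sel.tier,
                        est, q, presso_p)


def _meta_rows(exposure_id: str, analyses: list, rule: SignificanceRule,
               alpha: float):
    """Exclusion cascade + per-method fixed-effects meta for one exposure."""
    rows = []
    exclusions = []
    usable = [a for a in analyses if a.skip_reason is None]
    for a in analyses:
        if a.skip_reason is not None:
            exclusions.append((exposure_id, a.outcome_id, a.skip_reason))
    retained_ids, log = exclusion_filter([a.diagnostics() for a in usable],
                                         alpha=alpha)
    exclusions.extend((exposure_id, cid, reason) for cid, reason in log)
    retained = [a for a in usable if a.outcome_id in retained_ids]
    if not retained:
        return rows, exclusions, None

    method_names = ("ivw_mre", "ivw_fe", "egger", "weighted_median", "wald")
    metas = {}
    for m in method_names:
        inputs = [(a.estimates[m].beta, a.estimates[m].se)
                  for a in retained if m in a.estimates]
        if inputs:
            metas[m] = fixed_effect_meta(inputs, unit_id=exposure_id, method=m)
    headline = metas.get("ivw_mre") or metas.get("wald")
    if headline is None:
        return rows, exclusions, None
    sens = [metas[m] for m in ("weighted_median", "egger") if m in metas]
    consistent = sensitivity_consistent(headline, sens, alpha=alpha)
    if not consistent:
        exclusions.append((exposure_id, "meta", "inconsistent_with_sensitivity"))
    label = classify(float(np.clip(headline.pooled_p, np.nextafter(0, 1), 1.0)), rule)
    nsnp_total = sum(a.n_snp for a in retained)
    for m, meta_res in metas.items():
        or_, lo, hi = odds_ratio_ci(meta_res.pooled_beta, meta_res.pooled_se)
        rows.append({
            "exposure": exposure_id,
            "outcome": "meta",
            "method": m,
            "k_cohorts": meta_res.k_inputs,
            "nsnp_total": nsnp_total,
            "beta": meta_res.pooled_beta,
            "se": meta_res.pooled_se,
            "pval": meta_res.pooled_p,
            "or_": or_, "or_lci": lo, "or_uci": hi,
            "q_meta": meta_res.q_meta,
            "p_heterogeneity": meta_res.p_het,
            "label": label if m == headline.method else "",
            "consistent_with_sensitivity": consistent,
        })
    return rows, exclusions, headline


def _cohort_rows(analyses: list):
    rows = []
    for a in analyses:
        if a.skip_reason is not None:
            continue
        for m, e in a.estimates.items():
            or_, lo, hi = odds_ratio_ci(e.beta, e.se)
            rows.append({
                "exposure": a.exposure_id, "outcome": a.outcome_id,
                "method": m, "nsnp": e.n_snp, "tier": a.tier,
                "beta": e.beta, "se": e.se, "pval": e.pval,
                "or_": or_, "or_lci": lo, "or_uci": hi,
                "egger_intercept": e.extras.get("intercept", np.nan),
                "egger_intercept_p": e.extras.get("intercept_p", np.nan),
                "q": np.nan if a.q is None else a.q.Q,
                "q_df": np.nan if a.q is None else a.q.df,
                "q_p": np.nan if a.q is None else a.q.p_q,
                "presso_global_p": np.nan if a.presso_global_p is None else a.presso_global_p,
            })
    return rows


def _run_direction(exposures, outcomes, ld, config: StudyConfig, rule):
    cohort_rows, meta_rows, exclusion_rows = [], [], []
    headlines = {}
    for exp in exposures:
        analyses = [
            analyze_pair(exp, out, ld, config.instrument, config.seed,
                         config.n_boot, config.n_sim)
            for out in outcomes
        ]
        cohort_rows.extend(_cohort_rows(analyses))
        rows, excl, headline = _meta_rows(exp.trait_id, analyses, rule, config.alpha)
        meta_rows.extend(rows)
        exclusion_rows.extend(excl)
        if headline is not None:
            headlines[exp.trait_id] = headline
    return (pd.DataFrame(cohort_rows), pd.DataFrame(meta_rows),
            pd.DataFrame(exclusion_rows, columns=["exposure", "outcome", "reason"]),
            headlines)


def _load_ld(config: StudyConfig, tables) -> LDMatrix:
    if config.ld_matrix:
        return LDMatrix.from_file(config.ld_matrix)
    rsids = sorted(set().union(*(set(t.df["rsid"]) for t in tables)))
    return LDMatrix.identity(rsids)


def run_forward_mr(config: StudyConfig):
    """Exposure → outcome-cohort MR, exclusion cascade, meta, classification."""
    exposures = [t.load() for t in config.exposures]
    outcomes = [t.load() for t in config.outcomes]
    ld = _load_ld(config, exposures)
    rule = SignificanceRule(config.m_tests_exposures, config.alpha)
    return _run_direction(exposures, outcomes, ld, config, rule)


def run_reverse_mr(config: StudyConfig):
    """Outcome cohorts as exposures against each original exposure trait."""
    exposures = [t.load() for t in config.outcomes]
    targets = [t.load() for t in config.exposures]
    ld = _load_ld(config, exposures)
    rule = SignificanceRule(config.m_tests_exposures, config.alpha)
    cohort_rows, meta_rows, excl_rows = [], [], []
    for target in targets:
        analyses = [
            analyze_pair(exp, target, ld, config.instrument, config.seed,
                         config.n_boot, config.n_sim)
            for exp in exposures
        ]
        cohort_rows.extend(_cohort_rows(analyses))
        for a in analyses:
            if a.skip_reason is not None:
                excl_rows.append((a.exposure_id, target.trait_id, a.skip_reason))
        usable = [a for a in analyses if a.skip_reason is None]
        # the "cohort" of the exclusion cascade is the cohort-level *exposure* here
        diags = [CohortDiagnostics(
                     cohort_id=a.exposure_id, n_snp=a.n_snp,
                     egger_intercept_p=(a.estimates["egger"].extras["intercept_p"]
                                        if "egger" in a.estimates else None),
                     presso_global_p=a.presso_global_p)
                 for a in usable]
        retained_ids, log = exclusion_filter(diags, alpha=config.alpha)
        excl_rows.extend((cid, target.trait_id, reason) for cid, reason in log)
        retained = [a for a in usable if a.exposure_id in retained_ids]
        inputs = [(a.estimates.get("ivw_mre") or a.estimates.get("wald"))
                  for a in retained]
        inputs = [(e.beta, e.se) for e in inputs if e is not None]
        if inputs:
            meta_res = fixed_effect_meta(inputs, unit_id=target.trait_id,
                                         method="ivw_mre")
            meta_rows.append({
                "exposure": "osteoporosis", "outcome": target.trait_id,
                "method": "ivw_mre", "k_cohorts": meta_res.k_inputs,
                "beta": meta_res.pooled_beta, "se": meta_res.pooled_se,
                "pval": meta_res.pooled_p, "q_meta": meta_res.q_meta,
                "p_heterogeneity": meta_res.p_het,
                "label": classify(float(np.clip(meta_res.pooled_p, np.nextafter(0, 1), 1.0)), rule),
            })
    return (pd.DataFrame(cohort_rows), pd.DataFrame(meta_rows),
            pd.DataFrame(excl_rows, columns=["exposure", "outcome", "reason"]))


def run_ldsc(config: StudyConfig, n_blocks: int = 200):
    """Cross-trait genetic correlation for every exposure × outcome cohort."""
    if not config.ld_scores:
        raise ValueError("LDSC requires an ld_scores table in the config")
    ld_scores = pd.read_csv(config.ld_scores, sep=None, engine="python")
    rows = []
    for espec in config.exposures:
        exp = espec.load()
        for ospec in config.outcomes:
            out = ospec.load()
            try:
                table = qc_merge(exp, out, ld_scores)
                res = ldsc_rg(table, n_blocks=n_blocks)
            except ValueError as err:
                rows.append({"trait1": exp.trait_id, "trait2": out.trait_id,
                             "rg": np.nan, "rg_se": np.nan, "rg_p": np.nan,
                             "h2_1": np.nan, "h2_2": np.nan,
                             "flags": f"error:{err}"})
                continue
            rows.append({"trait1": exp.trait_id, "trait2": out.trait_id,
                         "rg": res.rg, "rg_se": res.rg_se, "rg_p": res.rg_p,
                         "h2_1": res.h2_1, "h2_2": res.h2_2,
                         "flags": ";".join(res.flags)})
    return pd.DataFrame(rows)


def run_mediation(config: StudyConfig, forward_headlines: dict,
                  gate_alpha: float = 0.05):
    """Two-step MR mediation for every exposure × mediator pair.

    The qualification gate requires nominal significance (p < ``gate_alpha``)
    on both the exposure→mediator and mediator→outcome legs, with clean
    diagnostics (the legs run through the same exclusion cascade as the
    forward analysis).  The total effect is the exposure's forward IVW
    meta-estimate.  Returns (mediation table, skip log).
    """
    exposures = [t.load() for t in config.exposures]
    mediators = [t.load() for t in config.mediators]
    outcomes = [t.load() for t in config.outcomes]
    ld = _load_ld(config, exposures + mediators)
    rows, skips = [], []
    for exp in exposures:
        headline = forward_headlines.get(exp.trait_id)
        if headline is None:
            skips.append((exp.trait_id, "", "no_total_effect_meta"))
            continue
        te = (headline.pooled_beta, headline.pooled_se)
        for med in mediators:
            em_pair = analyze_pair(exp, med, ld, config.instrument, config.seed,
                                   config.n_boot, config.n_sim)
            em_est = em_pair.estimates.get("ivw_mre") or em_pair.estimates.get("wald")
            if em_est is None or em_est.pval >= gate_alpha:
                skips.append((exp.trait_id, med.trait_id, "exposure_mediator_leg_failed"))
                continue
            mo_analyses = [
                analyze_pair(med, out, ld, config.instrument, config.seed,
                             config.n_boot, config.n_sim)
                for out in outcomes
            ]
            mo_rows, mo_excl, mo_headline = _meta_rows(
                med.trait_id, mo_analyses,
                SignificanceRule(config.m_tests_mediators, config.alpha),
                config.alpha)
            if mo_headline is None or mo_headline.pooled_p >= gate_alpha:
                skips.append((exp.trait_id, med.trait_id, "mediator_outcome_leg_failed"))
                continue
            res = mediate((em_est.beta, em_est.se),
                          (mo_headline.pooled_beta, mo_headline.pooled_se),
                          te, exposure=exp.trait_id, mediator=med.trait_id,
                          outcome="osteoporosis_meta")
            rows.append({
                "exposure": res.exposure, "mediator": res.mediator,
                "eo_beta": res.te.beta, "eo_lci": res.te.ci[0], "eo_uci": res.te.ci[1],
                "em_beta": res.em.beta, "em_lci": res.em.ci[0], "em_uci": res.em.ci[1],
                "mo_beta": res.mo.beta, "mo_lci": res.mo.ci[0], "mo_uci": res.mo.ci[1],
                "me": res.me, "me_lci": res.me_ci[0], "me_uci": res.me_ci[1],
                "me_se": res.me_se, "me_p": res.me_p,
                "proportion_pct": res.prop_mediated * 100.0,
                "flags": ";".join(res.flags),
            })
    return (pd.DataFrame(rows),
            pd.DataFrame(skips, columns=["exposure", "mediator", "reason"]))


def replay_mediation_file(path) -> pd.DataFrame:
    """Recompute mediation columns from a file of printed EO/EM/MO values.

    Input: delimited text with columns exposure, mediator, eo, eo_lo, eo_hi,
    em, em_lo, em_hi, mo, mo_lo, mo_hi (point estimates and 95% CI bounds).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    return pd.DataFrame(replay_table(df.to_dict("records")))


def write_manifest(config: StudyConfig, out_dir: Path) -> None:
    manifest = {
        "package": "mrchain",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_boot": config.n_boot,
        "n_sim": config.n_sim,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def materialize_fixtures(out_dir, seed: int = 7, n_snp: int = 12) -> Path:
    """Write a complete toy study to disk: tables, LD inputs, study config.

    Two exposures (one with a planted mediation path through the shared
    mediator, one plain), three outcome cohorts containing both exposures'
    variants, one mediator, identity LD with the planted correlated pair,
    plus LD scores.  Returns the path to ``study.yaml``.
    """
    from .simulate import (MediationTruth, Pleiotropy, SimulationConfig,
                           simulate_mediation_chain, simulate_mr_pair)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = MediationTruth(beta_xm=-0.3, beta_my=-0.05, beta_xy_direct=0.13)
    chain = simulate_mediation_chain(
        truth,
        SimulationConfig(seed=seed, n_snp=n_snp, plant_structure=False),
        exposure_id="taxon_a", mediator_id="metabolite_1", rsid_start=1000)
    pair = simulate_mr_pair(
        SimulationConfig(seed=seed + 1, n_snp=n_snp, true_beta=0.2),
        exposure_id="taxon_b", rsid_start=5000)

    # merge outcome cohorts so each carries both exposures' variants
    outcome_paths = []
    for i, (o_chain, o_pair) in enumerate(zip(chain.outcomes, pair.outcomes), 1):
        merged = pd.concat([o_chain.df, o_pair.df], ignore_index=True)
        path = out_dir / f"osteoporosis_cohort{i}.tsv"
        merged.to_csv(path, sep="\t", index=False)
        outcome_paths.append(path.name)

    write_sumstats(chain.exposure, out_dir / "taxon_a.tsv")
    write_sumstats(pair.exposure, out_dir / "taxon_b.tsv")
    write_sumstats(chain.mediator, out_dir / "metabolite_1.tsv")

    all_rsids = sorted(set(chain.exposure.df["rsid"]) | set(pair.exposure.df["rsid"]))
    ld = LDMatrix.identity(all_rsids)._r2
    for a in pair.ld._r2.index:
        for b in pair.ld._r2.columns:
            if a != b and pair.ld.r2(a, b) > 0:
                ld.loc[a, b] = pair.ld.r2(a, b)
    ld.to_csv(out_dir / "ld_matrix.csv")

    rng = np.random.default_rng(seed + 2)
    pd.DataFrame({
        "rsid": all_rsids,
        "ld_score": 1.0 + rng.exponential(30.0, len(all_rsids)),
    }).to_csv(out_dir / "ld_scores.tsv", sep="\t", index=False)

    study = {
        "exposures": [
            {"trait_id": "taxon_a", "path": "taxon_a.tsv", "trait_type": "quantitative"},
            {"trait_id": "taxon_b", "path": "taxon_b.tsv", "trait_type": "quantitative"},
        ],
        "mediators": [
            {"trait_id": "metabolite_1", "path": "metabolite_1.tsv",
             "trait_type": "quantitative"},
        ],
        "outcomes": [
            {"trait_id": f"osteoporosis_cohort{i}", "path": p, "trait_type": "binary"}
            for i, p in enumerate(outcome_paths, 1)
        ],
        "ld_matrix": "ld_matrix.csv",
        "ld_scores": "ld_scores.tsv",
        "seed": seed,
        "n_boot": 200,
        "n_sim": 200,
        "out_dir": "results",
    }
    cfg_path = out_dir / "study.yaml"
    cfg_path.write_text(yaml.safe_dump(study, sort_keys=False))
    return cfg_path
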