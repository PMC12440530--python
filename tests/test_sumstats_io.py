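"""Summary-statistics I/O, F filtering, clumping and harmonization."""

import numpy as np
import pandas as pd
import pytest

from mrchain import (InstrumentConfig, LDMatrix, clump, compute_f_statistic,
                     harmonize, read_sumstats, select_instruments)
from mrchain.sumstats_io import is_palindromic

from conftest import make_table

HEADER = "rsid\tchr\tpos\tea\toa\teaf\tbeta\tse\tpval\tn\n"


def _write(tmp_path, body, name="ss.tsv", header=HEADER):
    p = tmp_path / name
    p.write_text(header + body)
    return p


class TestReadSumstats:
    def test_well_formed_table_read_intact(self, tmp_path):
        p = _write(tmp_path,
                   "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.02\t1e-9\t5000\n"
                   "rs2\t2\t200\tC\tT\t0.4\t-0.2\t0.03\t1e-10\t5000\n"
                   "rs3\t3\t300\tG\tA\t0.5\t0.05\t0.01\t1e-8\t5000\n")
        t = read_sumstats(p, trait_id="x")
        assert len(t) == 3 and t.n_dropped == 0

    def test_zero_se_row_dropped_and_counted(self, tmp_path):
        p = _write(tmp_path,
                   "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.0\t1e-9\t5000\n"
                   "rs2\t2\t200\tC\tT\t0.4\t-0.2\t0.03\t1e-10\t5000\n")
        t = read_sumstats(p, trait_id="x")
        assert len(t) == 1 and t.n_dropped == 1
        assert t.drop_log == {"bad_se_or_beta": 1}

    def test_lowercase_alleles_normalized(self, tmp_path):
        p = _write(tmp_path, "rs1\t1\t100\ta\tt\t0.2\t0.1\t0.02\t1e-9\t5000\n")
        t = read_sumstats(p, trait_id="x")
        row = t.df.iloc[0]
        assert (row["effect_allele"], row["other_allele"]) == ("A", "T")

    def test_comma_delimiter_autodetected(self, tmp_path):
        p = _write(tmp_path, "rs1,1,100,A,G,0.2,0.1,0.02,1e-9,5000\n",
                   name="ss.csv", header=HEADER.replace("\t", ","))
        assert len(read_sumstats(p, trait_id="x")) == 1

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("rsid\tchr\tpos\toa\teaf\tbeta\tse\tpval\tn\n"
                     "rs1\t1\t100\tG\t0.2\t0.1\t0.02\t1e-9\t5000\n")
        with pytest.raises(ValueError, match="ea"):
            read_sumstats(p, trait_id="x")

    @pytest.mark.parametrize("bad_row,reason", [
        ("rs9\t1\t90\tA\tA\t0.2\t0.1\t0.02\t1e-9\t5000\n", "identical_alleles"),
        ("rs9\t1\t90\tA\tN\t0.2\t0.1\t0.02\t1e-9\t5000\n", "invalid_allele"),
        ("rs9\t1\t90\tA\tG\t0.2\t0.1\t0.02\t0.0\t5000\n", "bad_pval"),
        ("rs9\t1\t90\tA\tG\t1.2\t0.1\t0.02\t1e-9\t5000\n", "bad_eaf"),
    ])
    def test_invariant_violations_dropped_with_reason(self, tmp_path, bad_row, reason):
        p = _write(tmp_path, bad_row)
        t = read_sumstats(p, trait_id="x")
        assert t.drop_log == {reason: 1}


class TestFStatistic:
    @pytest.mark.parametrize("beta,se,expected", [
        (0.10, 0.02, 25.0),
        (0.03, 0.01, 9.0),
        (-0.10, 0.02, 25.0),  # sign-invariant
    ])
    def test_arithmetic(self, beta, se, expected):
        assert compute_f_statistic(beta, se) == pytest.approx(expected)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            compute_f_statistic(0.1, 0.0)


def _ld_from_matrix(rsids, mat):
    return LDMatrix(pd.DataFrame(mat, index=rsids, columns=rsids))


def greedy_clump_oracle(records, ld, window_kb, r2_max):
    """Literal restatement of the greedy rule, checked pair by pair."""
    recs = records.sort_values(["pval", "pos", "rsid"], kind="mergesort")
    recs = list(recs.itertuples(index=False))
    retained, retired = [], set()
    for r in recs:
        if r.rsid in retired:
            continue
        retained.append(r.rsid)
        for s in recs:
            if s.rsid in retired or s.rsid == r.rsid or s.chrom != r.chrom:
                continue
            if abs(s.pos - r.pos) > window_kb * 1000:
                continue
            r2 = ld.r2(r.rsid, s.rsid)
            if np.isnan(r2) or r2 >= r2_max:
                retired.add(s.rsid)
        retired.add(r.rsid)
    return retained


class TestClump:
    def _records(self, n, rng):
        return pd.DataFrame({
            "rsid": [f"rs{i}" for i in range(n)],
            "chrom": rng.choice(["1", "2"], n),
            "pos": rng.integers(1, 30_000_000, n),
            "pval": rng.uniform(1e-12, 1e-6, n),
        })

    def test_fully_correlated_block_keeps_best_p(self):
        rec = pd.DataFrame({
            "rsid": ["a", "b", "c"], "chrom": "1",
            "pos": [100, 200, 300], "pval": [1e-12, 1e-10, 1e-9],
        })
        ld = _ld_from_matrix(["a", "b", "c"], np.full((3, 3), 0.9) + 0.1 * np.eye(3))
        assert clump(rec, ld, 10_000, 0.001) == ["a"]

    def test_independent_block_keeps_all(self):
        rec = pd.DataFrame({
            "rsid": ["a", "b", "c"], "chrom": "1",
            "pos": [100, 200, 300], "pval": [1e-12, 1e-10, 1e-9],
        })
        ld = _ld_from_matrix(["a", "b", "c"], np.eye(3))
        assert sorted(clump(rec, ld, 10_000, 0.001)) == ["a", "b", "c"]

    def test_matches_greedy_oracle_on_random_instances(self, rng):
        for _ in range(20):
            rec = self._records(20, rng)
            mat = rng.uniform(0, 1, (20, 20))
            mat = (mat + mat.T) / 2
            np.fill_diagonal(mat, 1.0)
            ld = _ld_from_matrix(rec["rsid"], mat)
            assert clump(rec, ld, 5000, 0.1) == greedy_clump_oracle(rec, ld, 5000, 0.1)

    def test_order_independent_and_retained_pairs_below_threshold(self, rng):
        rec = self._records(15, rng)
        mat = rng.uniform(0, 0.5, (15, 15))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 1.0)
        ld = _ld_from_matrix(rec["rsid"], mat)
        kept = clump(rec, ld, 5000, 0.1)
        shuffled = rec.sample(frac=1, random_state=0)
        assert clump(shuffled, ld, 5000, 0.1) == kept
        for i, a in enumerate(kept):
            arow = rec[rec.rsid == a].iloc[0]
            for b in kept[i + 1:]:
                brow = rec[rec.rsid == b].iloc[0]
                if arow.chrom == brow.chrom and abs(arow.pos - brow.pos) <= 5_000_000:
                    assert ld.r2(a, b) < 0.1

    def test_empty_input(self):
        rec = pd.DataFrame(columns=["rsid", "chrom", "pos", "pval"])
        assert clump(rec, LDMatrix.identity([]), 10_000, 0.001) == []

    def test_missing_r2_within_window_treated_as_correlated(self):
        rec = pd.DataFrame({
            "rsid": ["a", "zz"], "chrom": "1", "pos": [100, 200],
            "pval": [1e-12, 1e-10],
        })
        ld = LDMatrix.identity(["a"])  # "zz" unknown to the matrix
        assert clump(rec, ld, 10_000, 0.001) == ["a"]


def _instrument_rows(n, p, start=0, f_strong=True):
    rows = []
    for i in range(n):
        se = 0.02
        beta = 0.2 if f_strong else 0.05  # F = 100 vs 6.25
        rows.append({"rsid": f"rs{start + i}", "chrom": str(1 + i % 22),
                     "pos": 1_000_000 * (1 + i), "effect_allele": "A",
                     "other_allele": "G", "eaf": 0.3, "beta": beta,
                     "se": se, "pval": p})
    return rows


class TestSelectInstruments:
    def test_primary_tier_when_enough_genomewide_hits(self):
        t = make_table(_instrument_rows(5, 1e-9))
        sel = select_instruments(t, InstrumentConfig(), LDMatrix.identity(t.df["rsid"]))
        assert len(sel) == 5 and sel.tier == "primary"

    def test_relaxed_tier_when_too_few_genomewide_hits(self):
        rows = _instrument_rows(1, 1e-9) + _instrument_rows(5, 1e-6, start=10)
        t = make_table(rows)
        sel = select_instruments(t, InstrumentConfig(), LDMatrix.identity(t.df["rsid"]))
        assert len(sel) == 6 and sel.tier == "relaxed"

    def test_weak_instrument_filtered(self):
        rows = _instrument_rows(5, 1e-9)
        rows.append({"rsid": "rs_weak", "chrom": "9", "pos": 90_000_000,
                     "effect_allele": "A", "other_allele": "G", "eaf": 0.3,
                     "beta": 0.0995, "se": 0.0316, "pval": 1e-9})  # F = 9.9
        t = make_table(rows)
        sel = select_instruments(t, InstrumentConfig(), LDMatrix.identity(t.df["rsid"]))
        assert "rs_weak" not in set(sel.records["rsid"])

    def test_no_instrument_exposure_flagged_not_raised(self):
        t = make_table(_instrument_rows(3, 0.5))
        sel = select_instruments(t, InstrumentConfig(), LDMatrix.identity(t.df["rsid"]))
        assert sel.is_empty and sel.tier == "none"

    def test_results_ordered_by_p(self):
        rows = _instrument_rows(5, 1e-9)
        for i, r in enumerate(rows):
            r["pval"] = [5e-9, 1e-12, 3e-10, 2e-9, 1e-11][i]
        t = make_table(rows)
        sel = select_instruments(t, InstrumentConfig(), LDMatrix.identity(t.df["rsid"]))
        assert list(sel.records["pval"]) == sorted(sel.records["pval"])


def _exp_row(rsid="rs1", ea="A", oa="G", beta=0.1, se=0.02, eaf=0.3):
    return {"rsid": rsid, "effect_allele": ea, "other_allele": oa,
            "beta": beta, "se": se, "pval": 1e-9, "eaf": eaf}


def _out_row(rsid="rs1", ea="A", oa="G", beta=0.05, se=0.02, eaf=0.3, pval=0.01):
    return {"rsid": rsid, "effect_allele": ea, "other_allele": oa,
            "beta": beta, "se": se, "pval": pval, "eaf": eaf}


class TestHarmonize:
    def test_swapped_orientation_negates_outcome_beta(self):
        exp = make_table([_exp_row(ea="A", oa="G", beta=0.1)])
        out = make_table([_out_row(ea="G", oa="A", beta=0.05, eaf=0.7)], trait_id="y")
        hs = harmonize(exp, out)
        assert hs.k == 1
        assert hs.df.iloc[0]["beta_out"] == pytest.approx(-0.05)
        assert bool(hs.df.iloc[0]["flipped"])

    def test_ambiguous_palindrome_dropped(self):
        exp = make_table([_exp_row(ea="A", oa="T", eaf=0.50)])
        out = make_table([_out_row(ea="A", oa="T", eaf=0.50)], trait_id="y")
        hs = harmonize(exp, out)
        assert hs.k == 0
        assert list(hs.drops["reason"]) == ["dropped_palindrome"]

    def test_palindrome_missing_eaf_dropped(self):
        exp = make_table([_exp_row(ea="G", oa="C", eaf=np.nan)])
        out = make_table([_out_row(ea="G", oa="C")], trait_id="y")
        assert list(harmonize(exp, out).drops["reason"]) == ["dropped_palindrome"]

    def test_unambiguous_palindrome_retained(self):
        exp = make_table([_exp_row(ea="A", oa="T", eaf=0.10)])
        out = make_table([_out_row(ea="A", oa="T", eaf=0.11)], trait_id="y")
        hs = harmonize(exp, out)
        assert hs.k == 1 and hs.df.iloc[0]["beta_out"] == pytest.approx(0.05)

    def test_allele_mismatch_dropped(self):
        exp = make_table([_exp_row(ea="A", oa="G")])
        out = make_table([_out_row(ea="A", oa="C")], trait_id="y")
        assert list(harmonize(exp, out).drops["reason"]) == ["dropped_mismatch"]

    def test_outcome_associated_variant_dropped(self):
        exp = make_table([_exp_row()])
        out = make_table([_out_row(pval=1e-7)], trait_id="y")
        assert list(harmonize(exp, out).drops["reason"]) == ["dropped_outcome_assoc"]

    def test_strand_complement_resolved(self):
        # exposure A/G; outcome reported on the other strand as T/C
        exp = make_table([_exp_row(ea="A", oa="G", beta=0.1)])
        out = make_table([_out_row(ea="T", oa="C", beta=0.05)], trait_id="y")
        hs = harmonize(exp, out)
        assert hs.k == 1
        assert hs.df.iloc[0]["beta_out"] == pytest.approx(0.05)
        assert not bool(hs.df.iloc[0]["flipped"])

    def test_instrument_absent_from_outcome_dropped(self):
        exp = make_table([_exp_row(rsid="rs1"), _exp_row(rsid="rs2")])
        out = make_table([_out_row(rsid="rs1")], trait_id="y")
        hs = harmonize(exp, out)
        assert hs.k == 1
        assert list(hs.drops["reason"]) == ["not_in_outcome"]

    def test_weak_instrument_dropped_at_harmonization(self):
        exp = make_table([_exp_row(beta=0.03, se=0.01)])  # F = 9
        out = make_table([_out_row()], trait_id="y")
        assert list(harmonize(exp, out).drops["reason"]) == ["dropped_weak"]

    def test_idempotent_on_aligned_set(self):
        exp = make_table([_exp_row(rsid=f"rs{i}", beta=0.1 + 0.01 * i)
                          for i in range(4)])
        out = make_table([_out_row(rsid=f"rs{i}", beta=0.05) for i in range(4)],
                         trait_id="y")
        h1 = harmonize(exp, out)
        assert h1.k == 4
        assert not h1.df["flipped"].any()
        assert np.allclose(h1.df["beta_out"], 0.05)

    def test_double_flip_is_identity(self):
        exp = make_table([_exp_row(ea="A", oa="G", beta=0.1)])
        out_flipped = make_table([_out_row(ea="G", oa="A", beta=-0.05, eaf=0.7)],
                                 trait_id="y")
        out_plain = make_table([_out_row(ea="A", oa="G", beta=0.05, eaf=0.3)],
                               trait_id="y")
        b1 = harmonize(exp, out_flipped).df.iloc[0]["beta_out"]
        b2 = harmonize(exp, out_plain).df.iloc[0]["beta_out"]
        assert b1 == pytest.approx(b2)

    def test_retained_records_satisfy_invariants(self):
        cfg = InstrumentConfig()
        exp = make_table([_exp_row(rsid=f"rs{i}", beta=0.1 + 0.02 * i)
                          for i in range(5)])
        out = make_table(
            [_out_row(rsid=f"rs{i}", pval=(1e-7 if i == 2 else 0.01))
             for i in range(5)], trait_id="y")
        hs = harmonize(exp, out, cfg)
        f = hs.df["beta_exp"] ** 2 / hs.df["se_exp"] ** 2
        assert (f >= cfg.f_min).all()
        assert hs.k + len(hs.drops) == 5

    def test_empty_instruments_rejected(self):
        out = make_table([_out_row()], trait_id="y")
        with pytest.raises(ValueError):
            harmonize(make_table([]), out)


def test_palindrome_detection():
    assert is_palindromic("A", "T") and is_palindromic("G", "C")
    assert not is_palindromic("A", "G")
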