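import pandas as pd
import pytest

from mrscreen.errors import NoHarmonizableInstrumentsError
from mrscreen.harmonize import COMPLEMENT, harmonize, is_palindromic
from mrscreen.instruments import InstrumentSet
from mrscreen.mr import ivw

from conftest import make_table, snp


def instruments_from(rows, exposure_id="prot"):
    t = make_table(rows, trait_id=exposure_id)
    return InstrumentSet(exposure_id=exposure_id, variants=t.records)


def one_pair(exp_alleles, out_alleles, beta_exp=0.10, beta_out=-0.05):
    instr = instruments_from([snp("rs1", beta=beta_exp,
                                  effect_allele=exp_alleles[0], other_allele=exp_alleles[1])])
    out = make_table([snp("rs1", beta=beta_out,
                          effect_allele=out_alleles[0], other_allele=out_alleles[1])],
                     trait_id="asthma")
    return instr, out


class TestAlleleResolution:
    def test_identical_alleles_kept_unchanged(self):
        instr, out = one_pair("AG", "AG")
        h = harmonize(instr, out)
        row = h.rows.iloc[0]
        assert row["action"] == "none"
        assert row["beta_outcome"] == -0.05
        assert (row["effect_allele"], row["other_allele"]) == ("A", "G")

    def test_swapped_alleles_flip_outcome_sign(self):
        instr, out = one_pair("AG", "GA")
        row = harmonize(instr, out).rows.iloc[0]
        assert row["action"] == "outcome_sign_flipped"
        assert row["beta_outcome"] == 0.05

    def test_palindromic_dropped_unconditionally(self):
        instr, out = one_pair("AT", "AT", beta_out=0.05)
        with pytest.raises(NoHarmonizableInstrumentsError):
            harmonize(instr, out)
        h = harmonize(instr, out, allow_empty=True)
        assert list(h.audit["reason"]) == ["dropped_palindromic"]

    def test_strand_complement_resolved_then_kept(self):
        instr, out = one_pair("AG", "TC", beta_out=0.05)
        row = harmonize(instr, out).rows.iloc[0]
        assert row["action"] == "none"
        assert row["beta_outcome"] == 0.05
        assert (row["effect_allele"], row["other_allele"]) == ("A", "G")

    def test_complement_swapped_flips_sign(self):
        instr, out = one_pair("AG", "CT", beta_out=0.05)
        row = harmonize(instr, out).rows.iloc[0]
        assert row["action"] == "outcome_sign_flipped"
        assert row["beta_outcome"] == -0.05

    def test_irreconcilable_alleles_dropped_incompatible(self):
        instr, out = one_pair("AG", "AC")
        h = harmonize(instr, out, allow_empty=True)
        assert list(h.audit["reason"]) == ["dropped_incompatible"]

    @pytest.mark.parametrize("pair", ["AT", "TA", "CG", "GC"])
    def test_palindromic_detector(self, pair):
        assert is_palindromic(pair[0], pair[1])

    @pytest.mark.parametrize("pair", ["AG", "AC", "TC", "TG"])
    def test_non_palindromic_detector(self, pair):
        assert not is_palindromic(pair[0], pair[1])


class TestJoinSemantics:
    def test_duplicated_id_in_outcome_removes_every_copy(self):
        instr = instruments_from([snp("rs1"), snp("rs2", pos=2_000_000)])
        out = make_table([snp("rs1"), snp("rs1"), snp("rs2", pos=2_000_000)], trait_id="o")
        h = harmonize(instr, out)
        assert list(h.rows["variant_id"]) == ["rs2"]
        assert ("rs1", "dropped_duplicate") in list(h.audit.itertuples(index=False, name=None))

    def test_duplicated_id_in_exposure_removes_every_copy(self):
        instr = instruments_from([snp("rs1"), snp("rs1"), snp("rs2", pos=2_000_000)])
        out = make_table([snp("rs1"), snp("rs2", pos=2_000_000)], trait_id="o")
        h = harmonize(instr, out)
        assert list(h.rows["variant_id"]) == ["rs2"]

    def test_instrument_absent_from_outcome_audited(self):
        instr = instruments_from([snp("rs1"), snp("rs9", pos=2_000_000)])
        out = make_table([snp("rs1")], trait_id="o")
        h = harmonize(instr, out)
        assert h.n_snps == 1
        assert ("rs9", "absent_from_outcome") in list(h.audit.itertuples(index=False, name=None))

    def test_zero_shared_variants_raises_typed_condition(self):
        instr = instruments_from([snp("rs1")])
        out = make_table([snp("rs2")], trait_id="o")
        with pytest.raises(NoHarmonizableInstrumentsError, match="no harmonizable"):
            harmonize(instr, out)


class TestInvariance:
    def _random_setup(self, rng, n=12):
        pairs = ["AG", "AC", "TC", "TG", "GA", "CA", "CT", "GT"]
        exp_rows, out_rows = [], []
        for i in range(n):
            p = pairs[int(rng.integers(len(pairs)))]
            beta_x = float(rng.normal(0.3, 0.05))
            beta_y = float(rng.normal(0.05, 0.01))
            exp_rows.append(snp(f"rs{i:02d}", beta=beta_x, se=0.02, pos=10**6 + i * 10**6,
                                effect_allele=p[0], other_allele=p[1]))
            out_rows.append(snp(f"rs{i:02d}", beta=beta_y, se=0.01, pos=10**6 + i * 10**6,
                                effect_allele=p[0], other_allele=p[1]))
        return exp_rows, out_rows

    @staticmethod
    def _reorient(row, rng):
        """Randomly swap allele order (negating beta) and/or strand-complement."""
        row = dict(row)
        if rng.random() < 0.5:
            row["effect_allele"], row["other_allele"] = row["other_allele"], row["effect_allele"]
            row["beta"] = -row["beta"]
        if rng.random() < 0.5:
            row["effect_allele"] = COMPLEMENT[row["effect_allele"]]
            row["other_allele"] = COMPLEMENT[row["other_allele"]]
        return row

    def test_estimates_invariant_under_allele_reorientation(self, rng):
        exp_rows, out_rows = self._random_setup(rng)
        ref = ivw(harmonize(instruments_from(exp_rows),
                            make_table(out_rows, trait_id="o")))
        for _ in range(10):
            exp_v = [self._reorient(r, rng) for r in exp_rows]
            out_v = [self._reorient(r, rng) for r in out_rows]
            est = ivw(harmonize(instruments_from(exp_v),
                                make_table(out_v, trait_id="o")))
            assert est.beta == ref.beta
            assert est.se == ref.se
            assert est.pval == ref.pval

    def test_double_flip_yields_identical_numbers(self, rng):
        exp_rows, out_rows = self._random_setup(rng)
        flipped = []
        for r in out_rows:
            r = dict(r)
            r["effect_allele"], r["other_allele"] = r["other_allele"], r["effect_allele"]
            r["beta"] = -r["beta"]
            flipped.append(r)
        h1 = harmonize(instruments_from(exp_rows), make_table(out_rows, trait_id="o"))
        h2 = harmonize(instruments_from(exp_rows), make_table(flipped, trait_id="o"))
        num_cols = ["beta_exposure", "se_exposure", "beta_outcome", "se_outcome"]
        pd.testing.assert_frame_equal(h1.rows[["variant_id", "effect_allele", "other_allele"] + num_cols],
                                      h2.rows[["variant_id", "effect_allele", "other_allele"] + num_cols])

    def test_palindromic_never_among_retained(self, rng):
        pairs = ["AG", "AT", "CG", "TC", "GC", "TA"]
        exp_rows, out_rows = [], []
        for i in range(20):
            p = pairs[int(rng.integers(len(pairs)))]
            exp_rows.append(snp(f"rs{i:02d}", effect_allele=p[0], other_allele=p[1],
                                pos=10**6 + i * 10**6))
            out_rows.append(snp(f"rs{i:02d}", effect_allele=p[0], other_allele=p[1],
                                pos=10**6 + i * 10**6))
        h = harmonize(instruments_from(exp_rows), make_table(out_rows, trait_id="o"))
        retained_pairs = set(zip(h.rows["effect_allele"], h.rows["other_allele"]))
        assert all(not is_palindromic(a, b) for a, b in retained_pairs)
        assert (h.audit["reason"] == "dropped_palindromic").sum() > 0
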