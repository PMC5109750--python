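"""The selection-mutation-translation model: biases, probabilities,
likelihood, tAI and brute-force maximum-likelihood fitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nitrocodon as nc
from nitrocodon.errors import DegenerateDataError, MissingTaiError, NitrocodonError
from nitrocodon.model import GridSpec, ModelParams, canonical_variant

from conftest import make_table


class TestBiases:
    def test_neutral_selection_bias_is_one(self):
        assert nc.selection_bias("GGG", 0.0) == 1.0

    @pytest.mark.parametrize(
        "codon,expected", [("TGC", math.exp(-1.0)), ("TGT", math.exp(-0.9))]
    )
    def test_selection_bias_closed_form(self, codon, expected):
        assert nc.selection_bias(codon, -0.1) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("m,delta", [(3.0, 0.75), (1.0, 0.5), (0.25, 0.2)])
    def test_mutation_delta(self, m, delta):
        assert nc.mutation_delta(m) == pytest.approx(delta, rel=1e-12)

    def test_mutation_delta_rejects_nonpositive(self):
        with pytest.raises(NitrocodonError):
            nc.mutation_delta(0.0)

    def test_mutation_bias_worked_example(self):
        # at m = 3: delta = 0.75, so TGC -> 0.75*0.25^2, TGT -> 0.75^2*0.25
        assert round(nc.mutation_bias("TGC", 3.0), 3) == 0.047
        assert round(nc.mutation_bias("TGT", 3.0), 3) == 0.141
        assert nc.mutation_bias("TGC", 3.0) == pytest.approx(0.046875)
        assert nc.mutation_bias("TGT", 3.0) == pytest.approx(0.140625)

    def test_no_mutation_bias_is_uniform_eighth(self):
        for codon in ("AAA", "GCG", "ATG"):
            assert nc.mutation_bias(codon, 1.0) == pytest.approx(0.125)


class TestCodonProbs:
    def test_mutation_only_cysteine_family(self, code):
        table = make_table(mut_m=3.0, variant="mutation_only")
        assert table.probs["TGT"] == pytest.approx(0.75, rel=1e-12)
        assert table.probs["TGC"] == pytest.approx(0.25, rel=1e-12)

    def test_selection_only_cysteine_family(self, code):
        table = make_table(sel_n=-0.1, variant="selection_only")
        assert table.probs["TGC"] == pytest.approx(1.0 / (1.0 + math.exp(0.1)), rel=1e-12)

    def test_neutral_params_uniform_within_families(self, code):
        table = make_table()
        for fam in code.families.values():
            for c in fam:
                assert table.probs[c] == pytest.approx(1.0 / len(fam), rel=1e-12)

    def test_tai_required_when_variant_includes_translation(self, code):
        with pytest.raises(MissingTaiError):
            nc.codon_probs(ModelParams(variant="tai_only"), code)

    @given(
        sel=st.floats(-1.0, 1.0),
        m=st.floats(0.05, 20.0),
    )
    def test_family_normalization_within_1e12(self, sel, m):
        table = nc.codon_probs(
            ModelParams(variant="selection_mutation", sel_n=sel, mut_m=m)
        )
        for total in table.family_sums().values():
            assert abs(total - 1.0) <= 1e-12

    def test_limit_equivalences(self, code):
        joint_no_sel = make_table(sel_n=0.0, mut_m=2.7)
        mut = make_table(mut_m=2.7, variant="mutation_only")
        joint_no_mut = make_table(sel_n=-0.2, mut_m=1.0)
        sel = make_table(sel_n=-0.2, variant="selection_only")
        for c in code.sense_codons:
            assert joint_no_sel.probs[c] == pytest.approx(mut.probs[c], rel=1e-12)
            assert joint_no_mut.probs[c] == pytest.approx(sel.probs[c], rel=1e-12)

    def test_increasing_m_favours_most_at_rich_codon(self, code):
        def at(c):
            return sum(1 for b in c if b in "AT")

        for m_lo, m_hi in [(0.5, 1.0), (1.0, 3.0), (3.0, 8.0)]:
            lo, hi = (make_table(mut_m=m, variant="mutation_only") for m in (m_lo, m_hi))
            for fam in code.families.values():
                ats = [at(c) for c in fam]
                if len(set(ats)) < 2:
                    continue
                richest = fam[int(np.argmax(ats))]
                assert hi.probs[richest] > lo.probs[richest]

    def test_variant_aliases(self):
        assert canonical_variant("selection+mutation") == "selection_mutation"
        with pytest.raises(ValueError):
            canonical_variant("nonsense")


class TestTai:
    def test_single_isoacceptor(self, code):
        # codon TTT read by anticodon AAA (Watson-Crick); s = 0.5, tGCN = 2
        table = nc.tai_omega({"AAA": 2}, sij={"A:T": 0.5}, code=code)
        assert table.omega["TTT"] == pytest.approx(1.0)

    def test_two_isoacceptors_sum(self, code):
        # codon TTC: Watson-Crick anticodon GAA (s=0), wobble AAA->inosine (s=0.28)
        table = nc.tai_omega({"GAA": 1, "AAA": 1}, code=code)
        assert table.omega["TTC"] == pytest.approx(1.72)

    def test_unrecognized_codons_flagged_zero(self, code):
        table = nc.tai_omega({"GAA": 1}, code=code)
        assert table.omega["GGG"] == 0.0
        assert "GGG" in table.unrecognized

    def test_negative_copy_number_rejected(self, code):
        with pytest.raises(NitrocodonError):
            nc.tai_omega({"GAA": -1}, code=code)


class TestLogLikelihood:
    def test_hand_computed_value(self, code):
        params = ModelParams(variant="mutation_only", mut_m=3.0)
        ll = nc.log_likelihood(params, {"TGC": 2, "TGT": 3}, code)
        assert ll == pytest.approx(2 * math.log(0.25) + 3 * math.log(0.75), rel=1e-12)

    def test_empty_counts_zero(self, code):
        assert nc.log_likelihood(ModelParams(), {}, code) == 0.0

    def test_single_codon_family_contributes_zero(self, code):
        assert nc.log_likelihood(ModelParams(), {"ATG": 100}, code) == 0.0

    def test_depends_only_on_pooled_counts(self, code):
        params = ModelParams(variant="selection_mutation", sel_n=-0.1, mut_m=2.0)
        pooled = {"TGC": 5, "TGT": 7, "GCA": 3, "GCC": 2}
        split = nc.CodonCounts(
            species_id="s",
            per_gene={"g1": {"TGC": 5, "GCA": 3}, "g2": {"TGT": 7, "GCC": 2}},
            pooled=pooled,
            n_genes=2,
        )
        assert nc.log_likelihood(params, split, code) == pytest.approx(
            nc.log_likelihood(params, pooled, code), rel=1e-14
        )


class TestFit:
    def test_neutral_data_recovers_neutral_params(self, code):
        counts = {c: 1000.0 / len(code.family_of(c)) for c in code.sense_codons}
        res = nc.fit(counts, "selection_mutation", code)
        assert abs(res.params.sel_n) <= 0.002
        assert abs(math.log(res.params.mut_m)) <= 0.01

    def test_exact_recovery_from_expected_counts(self, code):
        """Counts exactly proportional to the model distribution are refitted
        to within one refinement-grid step of the generating parameters."""
        gen = make_table(sel_n=-0.09, mut_m=0.67)
        counts = nc.expected_codon_counts(gen, 1_000_000)
        res = nc.fit(counts, "selection_mutation", code)
        steps = res.grid_meta["refined_steps"]
        assert abs(res.params.sel_n - (-0.09)) <= steps["sel_n"]
        assert abs(math.log(res.params.mut_m / 0.67)) <= steps["log_m"]

    def test_two_codon_family_closed_forms(self, code):
        """On a lone two-codon family the grid MLE matches the closed-form
        solutions: m* = n(TGT)/n(TGC) and sel* = ln(n(TGC)/n(TGT))."""
        counts = {"TGC": 2000, "TGT": 3000}
        m_fit = nc.fit(counts, "mutation_only", code).params.mut_m
        assert m_fit == pytest.approx(1.5, rel=0.005)
        s_fit = nc.fit(counts, "selection_only", code).params.sel_n
        assert s_fit == pytest.approx(math.log(2000 / 3000), abs=0.002)

    def test_stochastic_recovery_of_mutation_bias(self, code):
        gen = make_table(mut_m=3.0, variant="mutation_only")
        counts = nc.sample_codon_counts(gen, 100_000, np.random.default_rng(17))
        res = nc.fit(counts, "mutation_only", code)
        assert abs(res.params.mut_m - 3.0) <= 0.1

    def test_fixed_parameter_grid(self, code):
        gen = make_table(sel_n=-0.2, mut_m=2.0)
        counts = nc.expected_codon_counts(gen, 100_000)
        res = nc.fit(
            counts, "selection_mutation", code, grid=GridSpec(fixed={"mut_m": 2.0})
        )
        assert res.params.mut_m == 2.0
        assert res.params.sel_n == pytest.approx(-0.2, abs=0.002)

    def test_degenerate_counts_rejected(self, code):
        with pytest.raises(DegenerateDataError):
            nc.fit({"ATG": 50, "TGG": 20}, "selection_mutation", code)

    def test_deterministic(self, code):
        gen = make_table(sel_n=-0.1, mut_m=1.5)
        counts = nc.sample_codon_counts(gen, 50_000, np.random.default_rng(3))
        r1 = nc.fit(counts, "selection_mutation", code)
        r2 = nc.fit(counts, "selection_mutation", code)
        assert r1.params == r2.params and r1.loglik == r2.loglik


class TestAic:
    def test_formula(self, code):
        gen = make_table(mut_m=3.0, variant="mutation_only")
        counts = nc.sample_codon_counts(gen, 10_000, np.random.default_rng(1))
        res = nc.fit(counts, "mutation_only", code)
        assert nc.aic(res) == pytest.approx(2 * 1 - 2 * res.loglik)
        res2 = nc.fit(counts, "selection_mutation", code)
        assert nc.aic(res2) == pytest.approx(2 * 2 - 2 * res2.loglik)

    def test_selection_improves_aic_on_selected_data(self, code):
        gen = make_table(sel_n=-0.3, mut_m=1.0)
        counts = nc.sample_codon_counts(gen, 100_000, np.random.default_rng(2))
        full = nc.fit(counts, "selection_mutation", code)
        mut = nc.fit(counts, "mutation_only", code)
        assert full.aic < mut.aic
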