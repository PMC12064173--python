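"""Codon-level quantities (coding probability, expected CAI) against
analytic values and enumeration, decoding guarantees, and the stability-CAI
optimization's non-degradation contract."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psifold import PsifoldError, default_model, one_hot, partition_discrete
from psifold.fixtures import random_distribution
from psifold.mrna import (
    CODONS,
    CAIWeights,
    CodonDesignSpec,
    classical_cai,
    codon_marginal,
    coding_probability,
    decode_coding,
    default_cai_weights,
    expected_cai,
    mrna_loss,
    optimize_mrna,
    random_coding_sequence,
    repair_cai,
    standard_genetic_code,
    translate,
    warm_start,
)


@pytest.fixture(scope="module")
def weights():
    return default_cai_weights()


class TestGeneticCode:
    def test_standard_code_has_61_sense_codons(self):
        code = standard_genetic_code()
        sense = [c for c in CODONS if code.translate_codon(c) != "*"]
        assert len(sense) == 61
        assert len(code.stops) == 3

    def test_translate(self):
        assert translate("AUGGGCCGC") == "MGR"
        assert translate("ATGGGCCGC") == "MGR"  # DNA accepted

    def test_translate_rejects_partial_codon(self):
        with pytest.raises(PsifoldError):
            translate("AUGG")


class TestCAIWeights:
    def test_every_family_has_a_unit_weight_codon(self, weights):
        code = weights.code
        for aa in code.amino_acids:
            assert max(weights[c] for c in code.codons_for(aa)) == pytest.approx(1.0)

    def test_weights_are_positive_and_bounded(self, weights):
        assert all(0 < w <= 1 for w in weights.w.values())

    def test_tsv_round_trip(self, weights, tmp_path):
        path = tmp_path / "cai.tsv"
        weights.to_tsv(path)
        loaded = CAIWeights.from_tsv(path)
        assert loaded.w == weights.w

    def test_unnormalized_table_rejected(self):
        w = {c: 0.5 for c in CODONS if standard_genetic_code().translate_codon(c) != "*"}
        with pytest.raises(PsifoldError):
            CAIWeights(w)


class TestCodonMarginal:
    def test_one_hot_is_indicator(self):
        marg = codon_marginal(one_hot("AUG"), 0)
        assert marg[CODONS.index("AUG")] == 1.0
        assert marg.sum() == pytest.approx(1.0)

    def test_uniform_is_flat(self):
        marg = codon_marginal(np.full((3, 4), 0.25), 0)
        np.testing.assert_allclose(marg, 1 / 64)

    def test_product_structure(self):
        psi = np.zeros((3, 4))
        psi[0, [0, 2]] = 0.5  # A or G
        psi[1, 3] = 1.0       # U
        psi[2, 2] = 1.0       # G
        marg = codon_marginal(psi, 0)
        assert marg[CODONS.index("AUG")] == pytest.approx(0.5)
        assert marg[CODONS.index("GUG")] == pytest.approx(0.5)


class TestCodingProbability:
    def test_one_hot_coding_sequence(self):
        spec = CodonDesignSpec("MGR")
        assert coding_probability(one_hot("AUGGGCCGC"), spec) == pytest.approx(1.0)

    def test_uniform_methionine(self):
        assert coding_probability(np.full((3, 4), 0.25), CodonDesignSpec("M")) == (
            pytest.approx(1 / 64)
        )

    def test_uniform_met_leu(self):
        # Leu has 6 codons under the standard code
        assert coding_probability(np.full((6, 4), 0.25), CodonDesignSpec("ML")) == (
            pytest.approx((1 / 64) * (6 / 64))
        )

    def test_stop_symbol_rejected(self):
        with pytest.raises(PsifoldError):
            CodonDesignSpec("M*")


class TestExpectedCAI:
    @pytest.mark.parametrize("seed", range(20))
    def test_one_hot_recovers_classical_cai(self, weights, seed):
        spec = CodonDesignSpec("MGRAL")
        seq = random_coding_sequence(spec, seed=seed)
        assert expected_cai(one_hot(seq), spec, weights) == pytest.approx(
            classical_cai(seq, weights), rel=1e-12
        )

    def test_unit_weights_give_unit_cai(self):
        code = standard_genetic_code()
        flat = CAIWeights({c: 1.0 for c in CODONS if code.translate_codon(c) != "*"})
        spec = CodonDesignSpec("MGR")
        psi = random_distribution(9, 3)
        assert expected_cai(psi, spec, flat) == pytest.approx(1.0)

    def test_matches_bruteforce_conditional_expectation(self, weights):
        spec = CodonDesignSpec("LR")  # 6 x 6 coding sequences
        psi = random_distribution(6, 3)
        num = den = 0.0
        code = spec.code
        for c1, c2 in itertools.product(code.codons_for("L"), code.codons_for("R")):
            seq = c1 + c2
            p = np.prod([psi[i, "ACGU".index(ch)] for i, ch in enumerate(seq)])
            den += p
            num += p * classical_cai(seq, weights)
        assert expected_cai(psi, spec, weights) == pytest.approx(num / den, rel=1e-10)

    def test_zero_coding_probability_is_an_error(self, weights):
        spec = CodonDesignSpec("M")
        psi = one_hot("AAA")  # zero mass on AUG
        with pytest.raises(PsifoldError):
            expected_cai(psi, spec, weights)


class TestDecoding:
    def test_one_hot_coding_round_trip(self):
        spec = CodonDesignSpec("MGR")
        assert decode_coding(one_hot("AUGGGCCGC"), spec) == "AUGGGCCGC"

    def test_uniform_methionine_decodes_to_aug(self):
        assert decode_coding(np.full((3, 4), 0.25), CodonDesignSpec("M")) == "AUG"

    def test_ties_break_to_lexicographically_smallest_codon(self):
        # all Leu codons equally likely under uniform rows
        assert decode_coding(np.full((3, 4), 0.25), CodonDesignSpec("L")) == "CUA"

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_decode_always_translates_to_target(self, seed):
        rng = np.random.default_rng(seed)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=4))
        spec = CodonDesignSpec(protein)
        psi = rng.dirichlet(np.ones(4), size=spec.n)
        assert translate(decode_coding(psi, spec)) == protein

    def test_repair_reaches_floor_and_preserves_coding(self, weights):
        spec = CodonDesignSpec("MGRAL")
        seq = min(
            (random_coding_sequence(spec, s) for s in range(50)),
            key=lambda q: classical_cai(q, weights),
        )
        repaired = repair_cai(seq, spec, weights, floor=0.9)
        assert classical_cai(repaired, weights) >= 0.9
        assert translate(repaired) == "MGRAL"


class TestWarmStart:
    def test_decoding_recovers_the_seed_sequence(self):
        spec = CodonDesignSpec("MGR")
        psi = warm_start("AUGGGCCGC", spec)
        assert decode_coding(psi, spec) == "AUGGGCCGC"

    def test_non_coding_sequence_rejected(self):
        with pytest.raises(PsifoldError):
            warm_start("AUGAUGAUG", CodonDesignSpec("MGR"))

    def test_zero_eps_is_exact_one_hot(self):
        spec = CodonDesignSpec("MG")
        psi = warm_start("AUGGGC", spec, eps=0.0)
        np.testing.assert_array_equal(psi, one_hot("AUGGGC"))


class TestLoss:
    def test_satisfied_constraints_leave_pure_efe(self, weights, model):
        spec = CodonDesignSpec("MGRAL", cai_floor=0.8)
        # all-best-codon sequence: CAI = 1, one-hot coding
        code = spec.code
        seq = "".join(
            next(c for c in code.codons_for(aa) if weights[c] == 1.0)
            for aa in spec.protein
        )
        loss = mrna_loss(one_hot(seq), spec, model, weights)
        efe = partition_discrete(seq, model).efe(model)
        assert loss == pytest.approx(efe, abs=1e-9)

    def test_zero_lambdas_reduce_to_expected_efe(self, weights, model):
        spec = CodonDesignSpec("MGR", cai_floor=0.9, lambda_cai=0.0, lambda_code=0.0)
        psi = warm_start("AUGGGCCGC", spec)
        from psifold import expected_partition

        loss = mrna_loss(psi, spec, model, weights)
        assert loss == pytest.approx(expected_partition(psi, model).efe(model), abs=1e-12)


class TestOptimization:
    def test_never_degrades_warm_start_and_meets_constraints(self, weights, model):
        spec = CodonDesignSpec("MGRAL", cai_floor=0.8)
        res = optimize_mrna(spec, model, weights, steps=120, seed=3)
        assert res.efe_discrete <= res.warm_efe + 1e-9
        assert res.cai_discrete >= 0.8
        assert translate(res.sequence) == "MGRAL"

    def test_deterministic_given_seed(self, weights, model):
        spec = CodonDesignSpec("MGR", cai_floor=0.8)
        a = optimize_mrna(spec, model, weights, steps=30, seed=5)
        b = optimize_mrna(spec, model, weights, steps=30, seed=5)
        assert a.sequence == b.sequence
        assert a.trace.losses == b.trace.losses
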