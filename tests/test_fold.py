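"""Partition-function DPs against the enumeration oracles, the one-hot
bridge between the discrete and expected code paths, multilinearity, and
the scaling/checkpointing invariances."""

import itertools
import math

import numpy as np
import pytest

from psifold import (
    NumericalError,
    PsifoldError,
    SecondaryStructure,
    expected_partition,
    expected_structure_weight,
    one_hot,
    partition_discrete,
    structure_energy,
    target_structure_probability,
    uniform,
)
from psifold.alphabet import ALLOWED_PAIRS
from psifold.fixtures import random_distribution, random_sequence
from psifold.oracles import brute_expected_partition, brute_partition


class TestDiscrete:
    @pytest.mark.parametrize("seq", ["AAAA", "ACGU", "UUU"])
    def test_too_short_or_unpairable_gives_unit_z(self, model, seq):
        assert partition_discrete(seq, model).log_z == 0.0

    def test_dna_input_mapped_to_rna(self, model):
        assert partition_discrete("GGGAAAACCT", model).log_z == pytest.approx(
            partition_discrete("GGGAAAACCU", model).log_z
        )

    def test_invalid_character_rejected(self, model):
        with pytest.raises(PsifoldError):
            partition_discrete("ACGX", model)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, model, seed):
        n = 5 + (seed % 4) * 2  # 5..11
        seq = random_sequence(n, 1000 + seed)
        dp = partition_discrete(seq, model).log_z
        brute = brute_partition(seq, model)
        assert dp == pytest.approx(brute, rel=1e-10, abs=1e-12)

    def test_scale_constant_does_not_change_log_z(self, model):
        seq = random_sequence(40, 3)
        base = partition_discrete(seq, model).log_z
        for scale in (0.5, 2.0):
            assert partition_discrete(seq, model, scale=scale).log_z == pytest.approx(
                base, rel=1e-12
            )

    def test_ensemble_free_energy_is_nonpositive(self, model):
        # the empty structure contributes weight 1, so Z >= 1
        for seed in range(5):
            res = partition_discrete(random_sequence(30, seed), model)
            assert res.efe(model) <= 0.0


class TestExpected:
    def test_uniform_short_sequence_has_unit_z(self, model):
        assert expected_partition(uniform(4), model).log_z == 0.0

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_degenerate_lengths_are_not_errors(self, model, n):
        assert expected_partition(uniform(n), model).log_z == 0.0

    @pytest.mark.parametrize("seed,n", [(0, 5), (1, 6), (2, 7)])
    def test_matches_sequence_brute_force(self, model, seed, n):
        psi = random_distribution(n, seed)
        dp = expected_partition(psi, model).log_z
        brute = brute_expected_partition(psi, model)
        assert dp == pytest.approx(brute, rel=1e-9)

    @pytest.mark.parametrize("seed,n", [(0, 10), (1, 25), (2, 40)])
    def test_one_hot_reduces_to_discrete(self, model, seed, n):
        seq = random_sequence(n, 2000 + seed)
        a = partition_discrete(seq, model).log_z
        b = expected_partition(one_hot(seq), model).log_z
        assert b == pytest.approx(a, rel=1e-10, abs=1e-12)

    def test_off_simplex_rows_rejected_when_validating(self, model):
        psi = uniform(8)
        psi[3] *= 0.9
        with pytest.raises(PsifoldError, match="row 3"):
            expected_partition(psi, model)
        expected_partition(psi, model, validate=False)  # multilinear extension

    def test_multilinearity_in_each_row(self, model):
        # Z is affine in every row: mixing rows mixes Z linearly
        rng = np.random.default_rng(7)
        psi = random_distribution(8, 77)
        for _ in range(5):
            i = int(rng.integers(8))
            u = rng.dirichlet(np.ones(4))
            v = rng.dirichlet(np.ones(4))
            lam = float(rng.uniform())
            z = {}
            for name, row in (("u", u), ("v", v), ("mix", lam * u + (1 - lam) * v)):
                q = psi.copy()
                q[i] = row
                z[name] = math.exp(expected_partition(q, model).log_z)
            assert z["mix"] == pytest.approx(
                lam * z["u"] + (1 - lam) * z["v"], rel=1e-9
            )

    def test_scale_and_checkpoint_leave_results_unchanged(self, model):
        psi = random_distribution(30, 5)
        base = expected_partition(psi, model, grad=True)
        for scale in (0.5, 2.0):
            r = expected_partition(psi, model, scale=scale, grad=True)
            assert r.log_z == pytest.approx(base.log_z, rel=1e-10)
            np.testing.assert_allclose(r.grad_psi, base.grad_psi, rtol=1e-8, atol=1e-12)
        for k in (1, 6, 30):
            r = expected_partition(psi, model, checkpoint_every=k, grad=True)
            assert r.log_z == pytest.approx(base.log_z, rel=1e-12)
            np.testing.assert_allclose(r.grad_psi, base.grad_psi, rtol=1e-10, atol=0)

    def test_unworkable_scale_raises_numerical_error(self, model):
        psi = random_distribution(50, 1)
        with pytest.raises(NumericalError):
            expected_partition(psi, model, scale=1e-6)

    def test_bad_checkpoint_interval_rejected(self, model):
        with pytest.raises(PsifoldError):
            expected_partition(uniform(10), model, checkpoint_every=0)


class TestStructureWeight:
    def test_empty_structure_has_unit_weight(self, model):
        psi = random_distribution(8, 1)
        assert expected_structure_weight(psi, SecondaryStructure(8, []), model) == (
            pytest.approx(1.0)
        )

    def test_one_hot_recovers_boltzmann_factor(self, model):
        s = SecondaryStructure(9, [(0, 8), (1, 7), (2, 6)])
        w = expected_structure_weight(one_hot("GGGAAACCC"), s, model)
        e = structure_energy("GGGAAACCC", s, model)
        assert w == pytest.approx(math.exp(-e / model.kT), rel=1e-12)

    def test_unformable_structure_has_zero_weight(self, model):
        s = SecondaryStructure(9, [(0, 8)])
        assert expected_structure_weight(one_hot("AAAAAAAAA"), s, model) == 0.0

    def test_matches_sequence_brute_force(self, model):
        s = SecondaryStructure(7, [(0, 6), (1, 5)])
        psi = random_distribution(7, 42)
        total = 0.0
        for pi in itertools.product(range(4), repeat=7):
            p = float(np.prod([psi[i, c] for i, c in enumerate(pi)]))
            idx = np.array(pi)
            if all((int(idx[i]), int(idx[j])) in ALLOWED_PAIRS for i, j in s.pairs):
                total += p * model.boltzmann_weight(structure_energy(idx, s, model))
        w = expected_structure_weight(psi, s, model)
        assert w == pytest.approx(total, rel=1e-10)


class TestTargetProbability:
    def test_trivial_sequence_with_empty_target(self, model):
        s = SecondaryStructure(4, [])
        assert target_structure_probability(one_hot("AAAA"), s, model) == (
            pytest.approx(1.0)
        )

    def test_one_hot_equals_discrete_boltzmann_probability(self, model):
        seq = "GGGAAAACCC"
        s = SecondaryStructure(10, [(0, 9), (1, 8), (2, 7)])
        p = target_structure_probability(one_hot(seq), s, model)
        oracle = model.boltzmann_weight(structure_energy(seq, s, model)) / math.exp(
            brute_partition(seq, model)
        )
        assert p == pytest.approx(oracle, rel=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_never_exceeds_one(self, model, seed):
        psi = random_distribution(9, 300 + seed)
        s = SecondaryStructure(9, [(0, 8), (1, 7)])
        assert target_structure_probability(psi, s, model) <= 1.0 + 1e-12
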