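"""Energy-model lookups, Boltzmann weights, and parameter-file round trips."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psifold import PsifoldError, default_model, load_params, write_params
from psifold.alphabet import parse_pair
from psifold.errors import ParseError

GC = parse_pair("GC")
CG = parse_pair("CG")
AU = parse_pair("AU")
UA = parse_pair("UA")


class TestLoopEnergies:
    def test_hairpin_gc_closing_has_no_penalty(self, model):
        assert model.hairpin_energy(GC, 3) == pytest.approx(5.4)

    def test_hairpin_au_closing_pays_terminal_penalty(self, model):
        assert model.hairpin_energy(AU, 3) == pytest.approx(5.9)

    def test_hairpin_below_minimum_loop_size_rejected(self, model):
        with pytest.raises(PsifoldError):
            model.hairpin_energy(GC, 2)

    def test_hairpin_sizes_beyond_table_extrapolate_monotonically(self, model):
        e50 = model.hairpin_energy(GC, 50)
        e100 = model.hairpin_energy(GC, 100)
        assert e100 > e50 > model.hairpin_energy(GC, 30)

    @pytest.mark.parametrize(
        "outer,inner,expected",
        [(GC, GC, -3.3), (AU, UA, -1.1), (GC, CG, -3.4)],
    )
    def test_stack_lookup(self, model, outer, inner, expected):
        assert model.stack_energy(outer, inner) == pytest.approx(expected)

    def test_stack_rejects_unpairable_nucleotides(self, model):
        with pytest.raises(PsifoldError):
            model.stack_energy(GC, (0, 0))  # AA

    def test_bulge_of_size_one(self, model):
        # both closing pairs GC: no terminal penalties
        assert model.internal_or_bulge_energy(GC, GC, 1, 0) == pytest.approx(3.8)

    def test_internal_2x2(self, model):
        assert model.internal_or_bulge_energy(GC, GC, 2, 2) == pytest.approx(1.7)

    def test_internal_terminal_penalties_on_both_closing_pairs(self, model):
        base = model.internal_or_bulge_energy(GC, GC, 2, 2)
        both_au = model.internal_or_bulge_energy(AU, UA, 2, 2)
        assert both_au == pytest.approx(base + 2 * model.terminal_au)

    def test_loop_over_size_cap_is_forbidden(self, model):
        assert model.internal_or_bulge_energy(GC, GC, 31, 0) == math.inf

    @pytest.mark.parametrize(
        "branches,unpaired,abc,expected",
        [(3, 0, (3.4, 0.4, 0.0), 4.6), (3, 5, (3.4, 0.4, 0.0), 4.6),
         (4, 2, (3.4, 0.4, 0.1), 5.2)],
    )
    def test_multiloop_affine(self, model, branches, unpaired, abc, expected):
        m = model.copy(multiloop_affine=abc)
        assert m.multiloop_energy(branches, unpaired) == pytest.approx(expected)

    def test_multiloop_needs_three_branches(self, model):
        with pytest.raises(PsifoldError):
            model.multiloop_energy(2, 0)


class TestBoltzmann:
    def test_zero_energy_gives_unit_weight(self, model):
        assert model.boltzmann_weight(0.0) == 1.0

    def test_forbidden_loop_gives_zero_weight(self, model):
        assert model.boltzmann_weight(math.inf) == 0.0

    def test_minus_kt_gives_e(self, model):
        assert model.boltzmann_weight(-model.kT) == pytest.approx(math.e)

    @given(e1=st.floats(-50, 50), de=st.floats(1e-6, 10))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_strictly_positive_and_decreasing(self, e1, de):
        m = default_model()
        w1, w2 = m.boltzmann_weight(e1), m.boltzmann_weight(e1 + de)
        assert w2 > 0
        assert w1 > w2


class TestParameterIO:
    def test_round_trip_preserves_all_values(self, model, tmp_path):
        path = tmp_path / "params.txt"
        write_params(model, path)
        loaded = load_params(path)
        assert loaded.kT == model.kT
        assert loaded.theta == model.theta
        assert loaded.multiloop_affine == model.multiloop_affine
        for table in ("hairpin_init", "bulge_init", "internal_init", "stack"):
            a, b = getattr(model, table), getattr(loaded, table)
            assert set(a) == set(b)
            assert all(abs(a[k] - b[k]) < 1e-12 for k in a)

    def test_empty_file_falls_back_to_defaults_with_warning(self, model, tmp_path, caplog):
        path = tmp_path / "empty.txt"
        path.write_text("")
        with caplog.at_level("WARNING", logger="psifold"):
            loaded = load_params(path)
        assert loaded.stack == model.stack
        assert "defaults" in caplog.text

    def test_partial_file_overrides_only_named_entries(self, model, tmp_path):
        path = tmp_path / "partial.txt"
        path.write_text("# comment\nstack GC GC -9.9\nkT 1.0\n")
        loaded = load_params(path)
        assert loaded.stack[(GC, GC)] == -9.9
        assert loaded.kT == 1.0
        assert loaded.stack[(AU, UA)] == model.stack[(AU, UA)]

    def test_malformed_pair_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("kT 0.6\nstack GC XX -1\n")
        with pytest.raises(ParseError, match="line 2"):
            load_params(path)

    def test_non_numeric_energy_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("hairpin 3 abc\n")
        with pytest.raises(ParseError):
            load_params(path)
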