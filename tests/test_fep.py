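"""Zwanzig accumulation, hysteresis, cycle algebra and mutation combination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liefep.fep import (
    FEPLeg,
    FEPWindow,
    IncompleteLegError,
    InvalidCycleError,
    Subperturbation,
    TransformationResult,
    accumulate_leg,
    check_residue_stage_count,
    combine_mutation_cycles,
    cycle_closure,
    hysteresis,
    lambda_schedule,
    relative_binding,
    residue_ddg,
    zwanzig_increment,
)
from liefep.thermo import InvalidInputError, ThermoParams

from conftest import thermo_from_kT


def _const_leg(stage_gaps, with_reverse=True):
    """Leg with one stage per entry; each stage has constant window gaps."""
    subs = []
    for label, gaps in stage_gaps:
        lams = lambda_schedule(len(gaps) + 1)
        windows = []
        for m, lam in enumerate(lams):
            fwd = np.full(4, gaps[m]) if m < len(gaps) else None
            rev = np.full(4, -gaps[m - 1]) if (with_reverse and m > 0) else None
            windows.append(FEPWindow(lambda_m=float(lam), gaps_forward=fwd, gaps_reverse=rev))
        subs.append(Subperturbation(label=label, windows=windows))
    return FEPLeg("A->B", "bound", 0, subs)


class TestZwanzigIncrement:
    def test_constant_gaps_return_the_constant(self, thermo_kT0596):
        assert zwanzig_increment([0.7, 0.7, 0.7], thermo_kT0596) == pytest.approx(0.7)

    def test_matches_brute_force_direct_evaluation(self, thermo_kT0596):
        rng = np.random.default_rng(0)
        kT = thermo_kT0596.kT
        for _ in range(20):
            gaps = rng.normal(0, 2, size=rng.integers(1, 50))
            brute = -kT * math.log(np.mean(np.exp(-gaps / kT)))
            assert zwanzig_increment(gaps, thermo_kT0596) == pytest.approx(brute, rel=1e-12)

    def test_stable_for_extreme_gaps(self, thermo_kT0596):
        """log-sum-exp keeps huge |ΔU|/kT finite where the naive form overflows."""
        out = zwanzig_increment([-5000.0, -4990.0], thermo_kT0596)
        assert np.isfinite(out)
        # dominated by the lowest gap, offset by -kT·ln(1/2) for the 2-sample mean
        assert out == pytest.approx(-5000.0 + 0.596 * math.log(2), abs=1e-6)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_jensen_bound(self, gaps):
        """Exponential averaging never exceeds the arithmetic mean of the gaps."""
        t = ThermoParams(temperature=300.0)
        assert zwanzig_increment(gaps, t) <= np.mean(gaps) + 1e-9

    def test_gaussian_closed_form(self):
        """At large n the estimate approaches μ − σ²/(2kT) for Gaussian gaps."""
        kT = 0.5925
        t = thermo_from_kT(kT)
        rng = np.random.default_rng(123)
        gaps = rng.normal(1.0, 0.5, 100_000)
        expected = 1.0 - 0.5**2 / (2 * kT)
        assert expected == pytest.approx(0.789, abs=5e-4)
        w = np.exp(-gaps / kT)
        se = kT * w.std() / (w.mean() * math.sqrt(w.size))
        assert abs(zwanzig_increment(gaps, t) - expected) < 3 * se

    @pytest.mark.parametrize("bad", [[], [np.nan], [1.0, np.inf]])
    def test_invalid_samples_rejected(self, bad, thermo_kT0596):
        with pytest.raises(InvalidInputError):
            zwanzig_increment(bad, thermo_kT0596)


class TestAccumulateLeg:
    def test_constant_gap_additivity(self, thermo_kT0596):
        leg = _const_leg([("s", [0.5, 0.3])])
        assert accumulate_leg(leg, thermo_kT0596) == pytest.approx(0.8)

    def test_invariant_to_stage_splitting(self, thermo_kT0596):
        one = _const_leg([("s", [0.5, 0.3, -0.2, 0.1])])
        split = _const_leg([("s1", [0.5, 0.3]), ("s2", [-0.2, 0.1])])
        assert accumulate_leg(one, thermo_kT0596) == pytest.approx(
            accumulate_leg(split, thermo_kT0596))

    def test_reverse_equals_forward_for_exact_gaps(self, thermo_kT0596):
        """Zero-variance gaps make reverse accumulation exactly match forward."""
        leg = _const_leg([("s", [0.4, -0.1, 0.2])])
        fwd = accumulate_leg(leg, thermo_kT0596, "forward")
        rev = accumulate_leg(leg, thermo_kT0596, "reverse")
        assert rev == pytest.approx(fwd, abs=1e-12)

    def test_missing_direction_raises(self, thermo_kT0596):
        leg = _const_leg([("s", [0.5, 0.3])], with_reverse=False)
        with pytest.raises(IncompleteLegError):
            accumulate_leg(leg, thermo_kT0596, "reverse")

    def test_unknown_direction_rejected(self, thermo_kT0596):
        leg = _const_leg([("s", [0.5])])
        with pytest.raises(InvalidInputError):
            accumulate_leg(leg, thermo_kT0596, "sideways")


class TestHysteresis:
    def test_zero_for_exact_gaps(self, thermo_kT0596):
        per_stage, total = hysteresis(_const_leg([("s1", [0.5, 0.3]), ("s2", [0.1])]),
                                      thermo_kT0596)
        assert total == pytest.approx(0.0, abs=1e-12)
        assert set(per_stage) == {"s1", "s2"}

    def test_definition_arithmetic(self, thermo_kT0596):
        """Forward 1.00 with B→A −0.90 leaves a per-stage hysteresis of 0.10."""
        lams = lambda_schedule(2)
        windows = [
            FEPWindow(lams[0], gaps_forward=np.full(3, 1.00)),
            FEPWindow(lams[1], gaps_reverse=np.full(3, -0.90)),
        ]
        leg = FEPLeg("A->B", "bound", 0, [Subperturbation("s", windows)])
        per_stage, total = hysteresis(leg, thermo_kT0596)
        assert per_stage["s"] == pytest.approx(0.10)
        assert total == pytest.approx(0.10)

    def test_total_is_sum_of_stages(self, thermo_kT0596):
        leg = _const_leg([("a", [0.5]), ("b", [0.2]), ("c", [-0.1])])
        per_stage, total = hysteresis(leg, thermo_kT0596)
        assert total == pytest.approx(sum(per_stage.values()))

    def test_single_direction_flagged(self, thermo_kT0596):
        leg = _const_leg([("s", [0.5])], with_reverse=False)
        with pytest.raises(IncompleteLegError):
            hysteresis(leg, thermo_kT0596)


class TestRelativeBinding:
    def test_equal_environments_cancel(self):
        r = relative_binding("A", "B", [1.2, 1.3], [1.2, 1.3])
        assert r.ddg == pytest.approx(0.0)

    def test_bound_minus_free(self):
        r = relative_binding("9", "7", [2.0, 2.0], [0.6, 0.6])
        assert r.ddg == pytest.approx(1.4)

    def test_sem_quadrature(self):
        r = relative_binding("A", "B", [0.0, 2.0], [0.0, 2.0])
        assert r.ddg_sem == pytest.approx(math.sqrt(2.0))

    def test_empty_replicates_rejected(self):
        with pytest.raises(InvalidInputError):
            relative_binding("A", "B", [], [1.0])

    def test_destabilizing_mutation_is_positive(self):
        r = residue_ddg("F544", "A544", holo_dgs=[1.5], apo_dgs=[0.6], compound_id="8")
        assert r.ddg == pytest.approx(0.9)
        assert r.ddg > 0


class TestCombineMutationCycles:
    def test_published_scan_arithmetic(self):
        wt = TransformationResult("F544", "A544", 0.93, 0.20, compound_id="6")
        mut = TransformationResult("I544", "A544", -0.35, 0.19, compound_id="6")
        res = combine_mutation_cycles(wt, mut)
        assert res.combined_wt_to_mut == pytest.approx(1.28)
        assert res.combined_sem == pytest.approx(math.hypot(0.20, 0.19))

    def test_second_published_value(self):
        wt = TransformationResult("F544", "A544", 1.10, 0.22, compound_id="9")
        mut = TransformationResult("V544", "A544", -0.48, 0.15, compound_id="9")
        assert combine_mutation_cycles(wt, mut).combined_wt_to_mut == pytest.approx(1.58)

    def test_identity_mutation_is_zero(self):
        wt = TransformationResult("F544", "A544", 0.7, 0.1)
        assert combine_mutation_cycles(wt, wt).combined_wt_to_mut == 0.0

    def test_antisymmetric_under_swap(self):
        a = TransformationResult("F544", "A544", 0.93, 0.1)
        b = TransformationResult("I544", "A544", -0.35, 0.1)
        assert combine_mutation_cycles(a, b).combined_wt_to_mut == pytest.approx(
            -combine_mutation_cycles(b, a).combined_wt_to_mut)

    def test_mismatched_intermediate_rejected(self):
        a = TransformationResult("F544", "A544", 0.9)
        b = TransformationResult("I544", "A545", -0.3)
        with pytest.raises(InvalidInputError):
            combine_mutation_cycles(a, b)

    def test_mismatched_ligand_rejected(self):
        a = TransformationResult("F544", "A544", 0.9, compound_id="6")
        b = TransformationResult("I544", "A544", -0.3, compound_id="7")
        with pytest.raises(InvalidInputError):
            combine_mutation_cycles(a, b)


def _edges(vals):
    return [TransformationResult(a, b, v) for (a, b), v in vals.items()]


class TestCycleClosure:
    def test_exact_edges_telescope_to_zero(self):
        dg = {"6": -8.0, "7": -8.8, "8": -8.5, "9": -9.1}
        edges = _edges({("9", "8"): dg["8"] - dg["9"], ("8", "6"): dg["6"] - dg["8"],
                        ("9", "7"): dg["7"] - dg["9"], ("7", "6"): dg["6"] - dg["7"]})
        assert cycle_closure(edges) == pytest.approx(0.0, abs=1e-12)

    def test_orientation_signs(self):
        """Closure of the 4-compound diamond equals (9→8→6) − (9→7→6)."""
        edges = _edges({("9", "8"): 1.39, ("8", "6"): 1.44,
                        ("9", "7"): 0.74, ("7", "6"): 0.87})
        assert cycle_closure(edges) == pytest.approx((1.39 + 1.44) - (0.74 + 0.87))

    def test_open_path_rejected(self):
        edges = _edges({("a", "b"): 1.0, ("b", "c"): 2.0})
        with pytest.raises(InvalidCycleError):
            cycle_closure(edges)

    def test_branching_rejected(self):
        edges = _edges({("a", "b"): 1.0, ("b", "c"): 1.0, ("c", "a"): 1.0, ("b", "d"): 1.0})
        with pytest.raises(InvalidCycleError):
            cycle_closure(edges)

    def test_disconnected_pair_of_cycles_rejected(self):
        edges = _edges({("a", "b"): 1.0, ("b", "a"): 1.0,
                        ("c", "d"): 1.0, ("d", "c"): 1.0})
        with pytest.raises(InvalidCycleError):
            cycle_closure(edges)


def test_residue_stage_count_window():
    assert check_residue_stage_count(4)
    assert check_residue_stage_count(11)
    assert not check_residue_stage_count(3)
    assert not check_residue_stage_count(12)


def test_subperturbation_validation():
    lams = lambda_schedule(3)
    wins = [FEPWindow(float(l), gaps_forward=np.ones(2)) for l in lams]
    with pytest.raises(InvalidInputError):
        Subperturbation("bad", windows=wins[:2][::-1])  # decreasing λ
    with pytest.raises(InvalidInputError):
        Subperturbation("bad", windows=wins[:-1])  # does not end at λ=1
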