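"""Three-equation survivors model: arithmetic oracles, time composition,
shift semantics and structural invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emsurv.curves import CurveParams, HazardCurves, generate_curves
from emsurv.drivetime import ReachCurve
from emsurv.region import AMBULANCE, FIRE, generate_region
from emsurv.survival import (IncidenceModel, StaticIntervals, compose_total_time,
                             eligible_patients, expected_survivors,
                             marginal_effects, run_scenario, shift_reach_curve,
                             survival_rate)

from conftest import constant_curves


# -- step 1: eligible patients ------------------------------------------------

@pytest.mark.parametrize("incidence,p_a,expected", [
    (816, 0.15, 693.6),   # study-region values
    (100, 0.0, 100.0),
    (100, 1.0, 0.0),
])
def test_eligible_patients(incidence, p_a, expected):
    assert eligible_patients(IncidenceModel(incidence, p_a)) == pytest.approx(expected)


def test_incidence_model_validation():
    with pytest.raises(ValueError):
        IncidenceModel(-1, 0.1)
    with pytest.raises(ValueError):
        IncidenceModel(100, 1.5)


# -- time composition ---------------------------------------------------------

@pytest.mark.parametrize("simulated,statics,expected", [
    (1.5, StaticIntervals(), 6.5),   # floor: minimum reaction, zero drive
    (0.0, StaticIntervals(), 5.0),   # pure static overhead
    (3.2, StaticIntervals(0, 0, 0), 3.2),
])
def test_compose_total_time(simulated, statics, expected):
    assert compose_total_time(simulated, statics) == pytest.approx(expected)


def test_compose_rejects_negative_input():
    with pytest.raises(ValueError):
        compose_total_time(-0.1, StaticIntervals())
    with pytest.raises(ValueError):
        StaticIntervals(call_handling=-1.0)


# -- reach-curve shifts -------------------------------------------------------

def _curve(masses: dict, pop=None, n=31, unreached=0):
    b = [0] * n
    for t, m in masses.items():
        b[t - 1] = m
    return ReachCurve(b=tuple(b), pop=pop or sum(b) + unreached, unreached=unreached)


def test_shift_zero_is_identity():
    curve = _curve({3: 100})
    assert shift_reach_curve(curve, 0) == curve


def test_shift_translates_mass():
    assert shift_reach_curve(_curve({3: 100}), -1).b[1] == 100
    assert shift_reach_curve(_curve({3: 100}), +2).b[4] == 100


def test_shift_clamps_at_both_ends():
    assert shift_reach_curve(_curve({1: 100}), -2).b[0] == 100
    assert shift_reach_curve(_curve({31: 100}), +3).b[30] == 100


@settings(derandomize=True, max_examples=60)
@given(masses=st.dictionaries(st.integers(1, 31), st.integers(0, 10_000),
                              min_size=1, max_size=8),
       shift=st.integers(-35, 35),
       unreached=st.integers(0, 500))
def test_shift_conserves_population(masses, shift, unreached):
    curve = _curve(masses, unreached=unreached)
    shifted = shift_reach_curve(curve, shift)
    assert sum(shifted.b) == sum(curve.b)
    assert shifted.unreached == curve.unreached
    assert shifted.pop == curve.pop


# -- step 2: survival rate ----------------------------------------------------

def test_single_bin_population_is_pure_product():
    s, per_bin = survival_rate(_curve({7: 1000}), constant_curves(0.3, 0.2))
    assert s == pytest.approx(0.06, abs=1e-15)
    assert per_bin[6] == s and per_bin.sum() == s


def test_all_unreached_gives_zero_survival():
    curve = ReachCurve(b=(0,) * 31, pop=500, unreached=500)
    s, per_bin = survival_rate(curve, constant_curves())
    assert s == 0.0 and not per_bin.any()


def test_two_term_hand_summed_oracle():
    """b = {600 @ bin 7, 400 @ bin 9}, POP 1000, vf flat 0.25, surv 0.30/0.20
    at those bins: S = 0.6*0.25*0.30 + 0.4*0.25*0.20 = 0.065."""
    surv = [0.3] * 31
    for t in range(9, 32):
        surv[t - 1] = 0.2
    curves = HazardCurves(vf=(0.25,) * 31, surv=tuple(surv))
    s, per_bin = survival_rate(_curve({7: 600, 9: 400}), curves)
    assert s == pytest.approx(0.065, abs=1e-15)
    assert per_bin[6] == pytest.approx(0.045) and per_bin[8] == pytest.approx(0.020)


def test_survival_rejects_empty_population():
    with pytest.raises(ValueError):
        survival_rate(ReachCurve(b=(0,) * 31, pop=0, unreached=0), constant_curves())


def test_tail_modes_differ_only_beyond_horizon():
    """Mass past 31 minutes earns the 31+ curve values by default and nothing
    under the hard-zero sensitivity option."""
    curve32 = ReachCurve(b=(0,) * 30 + (100, 900), pop=1000, unreached=0)
    s_tail, _ = survival_rate(curve32, constant_curves(0.3, 0.2), tail="31plus")
    s_zero, _ = survival_rate(curve32, constant_curves(0.3, 0.2), tail="zero")
    assert s_tail == pytest.approx(0.06)          # every bin uses 31+ values
    assert s_zero == pytest.approx(0.1 * 0.06)    # only the true bin-31 mass


# -- step 3 and the full chain ------------------------------------------------

def test_expected_survivors_product_and_edges():
    assert expected_survivors(693.6, 0.06) == pytest.approx(41.616)
    assert expected_survivors(10.0, 0.0) == 0.0
    assert expected_survivors(0.0, 0.9) == 0.0
    with pytest.raises(ValueError):
        expected_survivors(-1.0, 0.5)
    with pytest.raises(ValueError):
        expected_survivors(1.0, 1.5)


def test_degenerate_region_full_chain(single_node_region):
    """Station on the home's node: total time 1.5 + 5.0 statics = 6.5 -> bin 7;
    with flat 0.3/0.2 curves S = 0.06 and beta = 693.6 * 0.06."""
    res = run_scenario(single_node_region, constant_curves(0.3, 0.2),
                       StaticIntervals(), IncidenceModel(), {AMBULANCE})
    assert res.reach.b[6] == 100
    assert res.s == pytest.approx(0.06, abs=1e-15)
    assert res.r == pytest.approx(693.6)
    assert res.beta == pytest.approx(693.6 * 0.06)
    assert res.beta == res.r * res.s          # identity to full precision
    assert sum(res.per_bin) == pytest.approx(res.s, abs=1e-15)


def test_run_scenario_is_deterministic(tiny_region):
    curves = generate_curves(CurveParams())
    args = (tiny_region, curves, StaticIntervals(), IncidenceModel(), {AMBULANCE})
    assert run_scenario(*args) == run_scenario(*args)


@pytest.mark.parametrize("seed", range(6))
def test_dual_dispatch_dominates_on_small_regions(seed, tiny_config):
    region = generate_region(tiny_config, seed)
    curves = generate_curves(CurveParams())
    a = run_scenario(region, curves, StaticIntervals(), IncidenceModel(), {AMBULANCE})
    d = run_scenario(region, curves, StaticIntervals(), IncidenceModel(),
                     {AMBULANCE, FIRE})
    assert d.beta >= a.beta
    assert np.all(d.reach.cumulative() >= a.reach.cumulative())


# -- marginal effects ---------------------------------------------------------

def test_marginal_effects_baseline_row_matches_run_scenario(tiny_region):
    curves = generate_curves(CurveParams())
    base = run_scenario(tiny_region, curves, StaticIntervals(), IncidenceModel(),
                        {AMBULANCE})
    table = marginal_effects(tiny_region, curves, StaticIntervals(), IncidenceModel(),
                             [{AMBULANCE}], shifts=[0])
    assert len(table) == 1
    assert table.beta.iloc[0] == base.beta
    assert table.delta_beta.iloc[0] == 0.0


def test_marginal_effects_row_cardinality(tiny_region):
    curves = generate_curves(CurveParams())
    table = marginal_effects(tiny_region, curves, StaticIntervals(), IncidenceModel(),
                             [{AMBULANCE}, {AMBULANCE, FIRE}], shifts=[-1, 0, 1])
    assert len(table) == 6
    assert set(table.resource_set) == {"ambulance", "ambulance+fire"}


def test_marginal_effects_require_baseline_shift(tiny_region):
    curves = generate_curves(CurveParams())
    with pytest.raises(ValueError, match="include 0"):
        marginal_effects(tiny_region, curves, StaticIntervals(), IncidenceModel(),
                         [{AMBULANCE}], shifts=[1, 2])


def test_beta_non_increasing_in_shift_under_monotone_curves(tiny_region):
    """With a non-increasing treatable product, every added static minute can
    only push population into worse bins."""
    curves = generate_curves(CurveParams())  # monotone product by construction
    table = marginal_effects(tiny_region, curves, StaticIntervals(), IncidenceModel(),
                             [{AMBULANCE}], shifts=list(range(-3, 4)))
    betas = table.sort_values("shift_minutes").beta.to_numpy()
    assert np.all(np.diff(betas) <= 1e-12)
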