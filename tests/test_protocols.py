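import numpy as np
import pytest

from paraflux import (
    ConfigurationError,
    DualSubstrateParams,
    InfeasibleError,
    MediumSpec,
    activation_threshold,
    anoxic_yield,
    atp_yield,
    batch_yield,
    estimate_maintenance,
    find_maintenance_reaction,
    leak_check,
    max_theoretical_yield,
    ratio_scan,
    scenario_compare,
    toy_dual_substrate,
    toy_respiratory,
)
from paraflux.constants import MANNITOL_ATP_PER_MOL_EQ2, METHANOL_ATP_PER_MOL


# ---------------------------------------------------------------------------
# maximal and batch yields
# ---------------------------------------------------------------------------


def test_max_theoretical_yield_on_linear_chain(linear_model, empty_medium):
    pred = max_theoretical_yield(linear_model, "EX_S", empty_medium)
    assert pred.yield_g_per_mol == pytest.approx(200.0, abs=1e-6)
    assert pred.uptake == 1.0
    assert pred.grew


def test_no_growth_gives_zero_yield_with_diagnostic(respiratory_model):
    # without O2 in the medium the respiratory toy cannot grow
    pred = max_theoretical_yield(respiratory_model, "EX_S", MediumSpec())
    assert pred.yield_g_per_mol == 0.0
    assert not pred.grew
    assert pred.diagnostic is not None


def test_batch_equals_max_yield_at_zero_maintenance(respiratory_model, aerobic_medium):
    ymax = max_theoretical_yield(respiratory_model, "EX_S", aerobic_medium)
    mu = 0.5 * ymax.growth_rate
    batch = batch_yield(respiratory_model, "EX_S", mu, 0.0, aerobic_medium)
    assert batch.yield_g_per_mol == pytest.approx(ymax.yield_g_per_mol, rel=1e-9)


@pytest.mark.parametrize("m_atp", [0.0, 1.0, 5.5, 7.5, 20.0])
def test_batch_yield_never_exceeds_max_yield(respiratory_model, aerobic_medium, m_atp):
    ymax = max_theoretical_yield(respiratory_model, "EX_S", aerobic_medium)
    batch = batch_yield(respiratory_model, "EX_S", 0.2, m_atp, aerobic_medium)
    assert batch.yield_g_per_mol <= ymax.yield_g_per_mol + 1e-9
    if m_atp > 0:
        assert batch.yield_g_per_mol < ymax.yield_g_per_mol


def test_pirt_consistency_loop(respiratory_model, aerobic_medium):
    """q_s(mu) from the batch protocol must follow Pirt's law with
    m_s = m_ATP / ATP-yield and slope 1000 / Y^max."""
    m_atp = 5.5
    y_atp = atp_yield(respiratory_model, "EX_S", aerobic_medium)
    y_max = max_theoretical_yield(respiratory_model, "EX_S", aerobic_medium).yield_g_per_mol
    for mu in (0.05, 0.1, 0.2, 0.4):
        q = batch_yield(respiratory_model, "EX_S", mu, m_atp, aerobic_medium).uptake
        expected = m_atp / y_atp + 1000.0 * mu / y_max
        assert q == pytest.approx(expected, rel=1e-4)


def test_infeasible_growth_rate_names_mu(respiratory_model, aerobic_medium):
    # oxidative capacity caps ATP regeneration well below this demand
    with pytest.raises(InfeasibleError, match="mu=9999"):
        batch_yield(respiratory_model, "EX_S", 9999.0, 5.5, aerobic_medium)


# ---------------------------------------------------------------------------
# anoxic protocol
# ---------------------------------------------------------------------------


def test_anoxic_protocol_closes_oxygen(respiratory_model, aerobic_medium):
    """The respiratory toy has no anaerobic ATP route: denitrifying growth
    must be infeasible while aerobic growth is fine."""
    assert batch_yield(respiratory_model, "EX_S", 0.1, 5.5, aerobic_medium).grew
    with pytest.raises(InfeasibleError):
        anoxic_yield(respiratory_model, "EX_S", 0.1, 5.5, aerobic_medium)


def test_anoxic_medium_opens_nitrate(respiratory_model):
    medium = MediumSpec(
        uptakes={"EX_O2": None, "EX_H2O": None},
        o2_exchange="EX_O2",
        nitrate_exchange="EX_NO3",
    ).anoxic()
    assert "EX_O2" not in medium.uptakes
    assert medium.uptakes["EX_NO3"] is None


# ---------------------------------------------------------------------------
# ATP yields and scenarios
# ---------------------------------------------------------------------------


def test_atp_yield_takes_best_route(aerobic_medium):
    model = toy_respiratory({"a": 10.0, "b": 6.0})
    assert atp_yield(model, "EX_S", aerobic_medium) == pytest.approx(10.0, abs=1e-8)
    single = toy_respiratory({"only": 2.5})
    assert atp_yield(single, "EX_S", MediumSpec.inorganic(single)) == pytest.approx(2.5)


def test_atp_yield_requires_maintenance_reaction(linear_model, empty_medium):
    with pytest.raises(ConfigurationError, match="ATP"):
        atp_yield(linear_model, "EX_S", empty_medium)


def test_scenario_compare_disables_routes(aerobic_medium):
    model = toy_respiratory({"a": 10.0, "b": 6.0})
    preds = scenario_compare(
        model,
        "EX_S",
        {"all": [], "no_a": ["OXID_a"], "no_b": ["OXID_b"]},
        aerobic_medium,
    )
    assert preds["all"].yield_g_per_mol == pytest.approx(preds["no_b"].yield_g_per_mol)
    # yields ordered with the ATP stoichiometry of the remaining route
    assert preds["no_a"].yield_g_per_mol < preds["no_b"].yield_g_per_mol
    assert preds["no_a"].yield_g_per_mol == pytest.approx(1000.0 * 6.0 / 20.0)
    # input model untouched
    assert model.reactions["OXID_a"].upper_bound > 0


def test_scenario_compare_refuses_disabling_biomass(respiratory_model, aerobic_medium):
    with pytest.raises(ValueError):
        scenario_compare(respiratory_model, "EX_S", {"bad": ["BIOMASS"]}, aerobic_medium)


def test_dual_pathway_degeneracy(dual_pathway_model, empty_medium):
    """Closing either of two equivalent branches leaves the yield unchanged;
    closing both abolishes growth."""
    preds = scenario_compare(
        dual_pathway_model,
        "EX_S",
        {"full": [], "no_b1": ["B1A"], "no_b2": ["B2A"], "none": ["B1A", "B2A"]},
        empty_medium,
    )
    assert preds["full"].yield_g_per_mol == pytest.approx(100.0, abs=1e-8)
    assert preds["no_b1"].yield_g_per_mol == pytest.approx(100.0, abs=1e-8)
    assert preds["no_b2"].yield_g_per_mol == pytest.approx(100.0, abs=1e-8)
    assert preds["none"].yield_g_per_mol == 0.0


# ---------------------------------------------------------------------------
# ratio scan and activation threshold
# ---------------------------------------------------------------------------


def test_ratio_scan_threshold_matches_oracle(dual_substrate):
    model, oracle_thr = dual_substrate
    medium = MediumSpec.inorganic(model)
    scan = ratio_scan(
        model, "meoh", "mann", list(np.arange(0.0, 5.01, 0.1)), 0.3, 7.5,
        "FIX", medium,
    )
    assert oracle_thr is not None and scan.threshold is not None
    assert scan.threshold == pytest.approx(oracle_thr, abs=0.01)
    # forced flux is zero below and strictly increasing above the threshold
    below = [f for r, f in zip(scan.ratios, scan.min_flux) if r < oracle_thr - 0.1]
    above = [f for r, f in zip(scan.ratios, scan.min_flux) if r > oracle_thr + 0.1]
    assert all(abs(f) <= 1e-6 for f in below)
    assert all(b > 1e-6 for b in above)
    assert all(b2 > b1 for b1, b2 in zip(above, above[1:]))


def test_ratio_scan_with_disabled_target_has_no_threshold(dual_substrate):
    model, _ = dual_substrate
    model = model.with_bounds("FIX", lower=0.0, upper=0.0)
    medium = MediumSpec.inorganic(model)
    scan = ratio_scan(
        model, "meoh", "mann", [0.0, 0.5, 1.0, 1.5, 2.0], 0.3, 7.5, "FIX", medium
    )
    feasible_fluxes = [
        (lo, hi)
        for ok, lo, hi in zip(scan.feasible, scan.min_flux, scan.max_flux)
        if ok
    ]
    assert feasible_fluxes  # low ratios remain feasible without fixation
    assert all(abs(lo) <= 1e-9 and abs(hi) <= 1e-9 for lo, hi in feasible_fluxes)
    assert scan.threshold is None


def test_ratio_scan_flags_infeasible_points_and_continues(dual_substrate):
    model, _ = dual_substrate
    # cap the carbon substrate's energy route: pure-base feed can no longer
    # cover the ATP demand, but co-feeding the energy substrate can
    model = model.with_bounds("OXID_C", upper=0.2)
    medium = MediumSpec.inorganic(model)
    scan = ratio_scan(
        model, "meoh", "mann", [0.0, 2.0, 4.0], 0.3, 7.5, "FIX", medium
    )
    assert scan.feasible == [False, True, True]


def test_threshold_scale_invariance(dual_substrate):
    """Doubling both mixture coefficients rescales the supply flux but not
    the ratio at which fixation becomes forced."""
    from paraflux.fba import Constraint, solve, with_mixture_supply

    model, _ = dual_substrate
    medium = MediumSpec.inorganic(model)
    base = medium.apply(model).close_uptake("EX_MEOH").close_uptake("EX_MANN")
    cons = [
        Constraint("ATPM", "fix", 7.5),
        Constraint("BIOMASS", "fix", 0.3),
    ]
    r = 3.0
    results = []
    for scale in (1.0, 2.0):
        mdl = with_mixture_supply(base, {"meoh": scale * r, "mann": scale})
        state = solve(mdl, "SUPPLY_MIXTURE", "minimize", cons)
        results.append(state.objective_value * scale)  # mol mann per time
    assert results[0] == pytest.approx(results[1], rel=1e-8)


def test_activation_threshold_needs_two_points(dual_substrate):
    from paraflux.protocols import RatioScanResult

    scan = RatioScanResult([1.0], [1.0], [0.0], [0.0], [True], target_id="FIX")
    with pytest.raises(ValueError):
        activation_threshold(scan)


def test_prohibitive_fixation_cost_has_no_threshold():
    _, thr = toy_dual_substrate(DualSubstrateParams(fixation_atp_cost=1e9))
    assert thr is None


# ---------------------------------------------------------------------------
# maintenance estimation
# ---------------------------------------------------------------------------


def test_maintenance_combination_arithmetic():
    est = estimate_maintenance(
        {"methanol": METHANOL_ATP_PER_MOL, "mannitol": MANNITOL_ATP_PER_MOL_EQ2},
        [{"methanol": 1.0, "mannitol": 0.1}],
    )
    assert est.per_condition == (pytest.approx(7.81),)
    assert est.mean == pytest.approx(7.81)
    assert est.sd == 0.0


def test_maintenance_zero_uptakes_and_identical_conditions():
    est = estimate_maintenance(
        {"a": 4.0}, [{"a": 0.0}, {"a": 0.0}, {"a": 0.0}]
    )
    assert est.mean == 0.0 and est.sd == 0.0
    est = estimate_maintenance({"a": 4.0}, [{"a": 2.0}] * 3)
    assert est.mean == pytest.approx(8.0) and est.sd == 0.0


def test_maintenance_estimation_input_errors():
    with pytest.raises(ValueError):
        estimate_maintenance({"a": 1.0}, [])
    with pytest.raises(ValueError, match="unknown"):
        estimate_maintenance({"a": 1.0}, [{"unknown": 1.0}])


def test_maintenance_sd_recomputable():
    conds = [{"a": 1.0}, {"a": 2.0}, {"a": 4.0}]
    est = estimate_maintenance({"a": 3.0}, conds)
    assert est.mean == pytest.approx(np.mean(est.per_condition))
    assert est.sd == pytest.approx(np.std(est.per_condition, ddof=1))


# ---------------------------------------------------------------------------
# leak check and maintenance lookup
# ---------------------------------------------------------------------------


def test_leak_check_passes_on_sound_models(linear_model, respiratory_model):
    assert leak_check(linear_model, []).passed
    res = leak_check(respiratory_model, ["EX_O2", "EX_H2O"])
    assert res.passed
    assert res.max_carbonless_growth <= 1e-6


def test_leak_check_detects_mass_creation(leaky_model):
    res = leak_check(leaky_model, ["EX_H2O"])
    assert not res.passed
    assert res.max_carbonless_growth > 1e-3


def test_find_maintenance_reaction_by_annotation_and_pattern(respiratory_model):
    assert find_maintenance_reaction(respiratory_model) == "ATPM"
    # strip the annotation and the id hint: the stoichiometric pattern
    # ATP + H2O -> ADP + Pi must still be found
    stripped = respiratory_model.copy()
    stripped.annotations.pop("maintenance_reaction")
    renamed = stripped.reactions.pop("ATPM")
    from dataclasses import replace

    stripped.reactions["R_ngam"] = replace(renamed, id="R_ngam", name="")
    assert find_maintenance_reaction(stripped) == "R_ngam"
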