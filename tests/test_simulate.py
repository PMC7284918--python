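"""Simulator mechanics: mass balance, symmetry, noise and scenarios."""

import numpy as np
import pytest

from gutpass.simulate import (
    CascadeParams,
    DosingScheme,
    SimParams,
    SimulationError,
    TimeCourse,
    TranswellGeometry,
    apply_measurement_noise,
    geometry_preset,
    simulate_cascade,
    simulate_timecourse,
)
from gutpass.scenarios import SCENARIOS, generate_scenario


def test_geometry_presets_match_assay_formats():
    epi = geometry_preset("EpiIntestinal-24")
    assert (epi.surface_area, epi.apical_volume, epi.basal_volume) == (0.6, 100.0, 5000.0)
    caco = geometry_preset("Caco2-24")
    assert (caco.apical_volume, caco.basal_volume) == (200.0, 800.0)
    well96 = geometry_preset("96-well")
    assert (well96.apical_volume, well96.basal_volume) == (100.0, 250.0)
    with pytest.raises(ValueError, match="unknown geometry"):
        geometry_preset("6-well")


def test_geometry_rejects_nonpositive_volumes():
    with pytest.raises(ValueError):
        TranswellGeometry(0.6, 0.0, 5000.0)


@pytest.mark.parametrize("bad_kwargs", [
    {"passive_permeability": -1e-6},
    {"efflux_Jmax": 0.1, "efflux_Km": 0.0},
    {"enzyme_Vmax": 0.1, "enzyme_Km": -1.0},
    {"noise_cv": 1.0},
])
def test_invalid_sim_params_rejected(bad_kwargs):
    with pytest.raises(ValueError):
        SimParams(**bad_kwargs)


def test_dosing_requires_increasing_times():
    with pytest.raises(ValueError):
        DosingScheme(sample_times=(0.0, 1.0, 1.0))


def test_sink_receiver_amount_near_closed_form(epi_geometry):
    """P=1e-6 cm/s, C0=10 µM, 2 h: the idealized sink expression
    Q = Papp*C0*s*t gives 43.2 pmol; the full model falls a few percent
    short through donor depletion and the cell-loading lag."""
    dosing = DosingScheme("apical", 10.0, (0.5, 1.0, 2.0), sample_volume=0.0)
    res = simulate_timecourse(SimParams(passive_permeability=1e-6), epi_geometry, dosing)
    q = res.receiver().amounts[-1]
    assert q == pytest.approx(43.2, rel=0.07)
    assert q < 43.2  # the closed form is an upper bound


def test_symmetric_geometry_gives_equal_bidirectional_amounts():
    geometry = TranswellGeometry(0.6, 300.0, 300.0, format_label="symmetric")
    params = SimParams(passive_permeability=2e-6)
    amounts = {}
    for donor in ("apical", "basal"):
        dosing = DosingScheme(donor, 10.0, (0.5, 1.0, 2.0), sample_volume=0.0)
        amounts[donor] = simulate_timecourse(params, geometry, dosing).receiver().amounts
    np.testing.assert_allclose(amounts["apical"], amounts["basal"], rtol=1e-9)


@pytest.mark.parametrize("params", [
    SimParams(passive_permeability=1e-6),
    SimParams(passive_permeability=1e-6, efflux_Jmax=0.05, efflux_Km=5.0),
    SimParams(passive_permeability=2e-6, enzyme_Vmax=0.04, enzyme_Km=5.0,
              metabolite_permeability=2e-6),
])
def test_mass_conservation_with_withdrawal(params, epi_geometry):
    """Dose = compartments + withdrawn aliquots (parent + metabolite) at
    every sample time, within 0.1%."""
    dosing = DosingScheme("apical", 10.0, (0.0, 0.5, 1.0, 2.0, 4.0), sample_volume=50.0)
    res = simulate_timecourse(params, epi_geometry, dosing)
    assert res.mass_balance_error() < 1e-3


def test_cascade_mass_conservation(epi_geometry):
    dosing = DosingScheme("apical", 10.0, (2.0, 4.0, 6.0, 24.0), sample_volume=50.0)
    res = simulate_cascade(CascadeParams(), epi_geometry, dosing)
    assert res.mass_balance_error() < 1e-3


def test_receiver_amount_monotone_in_permeability(epi_geometry):
    dosing = DosingScheme("apical", 10.0, (1.0, 2.0), sample_volume=0.0)
    finals = [
        simulate_timecourse(SimParams(passive_permeability=p), epi_geometry, dosing)
        .receiver().amounts[-1]
        for p in (1e-7, 3e-7, 1e-6, 3e-6, 1e-5)
    ]
    assert np.all(np.diff(finals) > 0)


def test_sample_volume_exceeding_receiver_errors():
    geometry = TranswellGeometry(0.6, 100.0, 200.0)
    dosing = DosingScheme("apical", 10.0, (1.0,), sample_volume=250.0)
    with pytest.raises(SimulationError, match="receiver volume"):
        simulate_timecourse(SimParams(), geometry, dosing)


# -- measurement noise -------------------------------------------------------

def _flat_series(value=100.0, n=5):
    return TimeCourse("parent", "basal", np.arange(1, n + 1, dtype=float),
                      np.full(n, value))


def test_noise_identity_when_cv_and_loq_zero():
    series = _flat_series()
    out = apply_measurement_noise(series, SimParams(noise_cv=0.0, loq=0.0))
    np.testing.assert_array_equal(out.amounts, series.amounts)
    assert not out.censored.any()


def test_noise_deterministic_under_fixed_seed():
    series = _flat_series()
    params = SimParams(noise_cv=0.2, loq=1.0, seed=42)
    a = apply_measurement_noise(series, params)
    b = apply_measurement_noise(series, params)
    np.testing.assert_array_equal(a.amounts, b.amounts)
    np.testing.assert_array_equal(a.censored, b.censored)


def test_noise_monte_carlo_recovers_cv():
    """1000 noisy replicates of a point with true value 100 at CV=0.1 show
    a sample CV inside [0.08, 0.12]."""
    series = TimeCourse("parent", "basal", np.array([1.0]), np.array([100.0]))
    params = SimParams(noise_cv=0.1, seed=7)
    rng = np.random.default_rng(7)
    draws = np.array([
        apply_measurement_noise(series, params, rng=rng).amounts[0]
        for _ in range(1000)
    ])
    cv = draws.std() / draws.mean()
    assert 0.08 < cv < 0.12
    assert abs(draws.mean() / 100.0 - 1) < 0.02  # mean-one multiplier


def test_blq_censoring_flags_sub_loq_points():
    series = TimeCourse("parent", "basal", np.array([0.5, 1.0, 2.0]),
                        np.array([0.2, 0.8, 5.0]))
    out = apply_measurement_noise(series, SimParams(noise_cv=0.0, loq=1.0))
    np.testing.assert_array_equal(out.censored, [True, True, False])


# -- scenarios ---------------------------------------------------------------

def test_unknown_scenario_raises():
    with pytest.raises(ValueError, match="unknown scenario"):
        generate_scenario("no-such-assay", seed=1)


def test_scenario_is_deterministic_and_replicated():
    a = generate_scenario("passive-only", config={"replicates": 2}, seed=3)
    b = generate_scenario("passive-only", config={"replicates": 2}, seed=3)
    assert len(a.runs) == 2 * len(a.arms)
    for run_a, run_b in zip(a.runs, b.runs):
        assert run_a.run_id == run_b.run_id
        for key in run_a.timecourses:
            np.testing.assert_array_equal(run_a.timecourses[key].amounts,
                                          run_b.timecourses[key].amounts)


def test_scenario_ground_truth_is_exposed():
    scenario = generate_scenario("efflux", config={"replicates": 1}, seed=1)
    assert scenario.truth("AB").efflux_Jmax > 0


def test_every_scenario_conserves_mass():
    for name in SCENARIOS:
        scenario = generate_scenario(name, config={"replicates": 1}, seed=0)
        for arm, result in scenario.base.items():
            assert result.mass_balance_error() < 1e-3, (name, arm)
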