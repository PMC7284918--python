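"""Papp, efflux ratio, recovery, sampling correction and QC gates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutpass.permeability import (
    DEFAULT_QC_THRESHOLDS,
    QCRecord,
    UndefinedEffluxRatioError,
    calc_efflux_ratio,
    calc_papp,
    calc_papp_series,
    calc_recovery,
    cumulative_receiver_amount,
    qc_evaluate,
)
from gutpass.scenarios import generate_scenario
from gutpass.simulate import DosingScheme, SimParams, TimeCourse, simulate_timecourse


def test_calc_papp_unit_conversion_oracle():
    # 43.2 pmol over 2 h through 0.6 cm² from 10 µM donor -> 1e-6 cm/s
    assert calc_papp(43.2, 10.0, 0.6, 2.0) == pytest.approx(1.0e-6, rel=1e-12)
    assert calc_papp(0.0, 10.0, 0.6, 2.0) == 0.0


def test_calc_papp_rejects_nonpositive_denominators():
    with pytest.raises(ValueError):
        calc_papp(1.0, 0.0, 0.6, 2.0)
    with pytest.raises(ValueError):
        calc_papp(-1.0, 10.0, 0.6, 2.0)


@settings(derandomize=True, max_examples=50)
@given(q=st.floats(0.1, 1e4), c0=st.floats(0.1, 100.0),
       s=st.floats(0.1, 5.0), t=st.floats(0.1, 24.0),
       k=st.floats(1.5, 10.0))
def test_calc_papp_scaling_laws(q, c0, s, t, k):
    """Papp is linear in Q and inverse-linear in C0, s and t."""
    base = calc_papp(q, c0, s, t)
    assert calc_papp(k * q, c0, s, t) == pytest.approx(k * base, rel=1e-9)
    assert calc_papp(q, k * c0, s, t) == pytest.approx(base / k, rel=1e-9)
    assert calc_papp(q, c0, k * s, t) == pytest.approx(base / k, rel=1e-9)
    assert calc_papp(q, c0, s, k * t) == pytest.approx(base / k, rel=1e-9)


def test_cumulative_correction_hand_bookkeeping():
    """1 µM in an 800 µL receiver at t=1 and t=2 h with a 50 µL aliquot
    taken at each sample time: the t=2 cumulative amount is
    800 + 50*1 = 850 pmol."""
    series = TimeCourse("parent", "basal", np.array([1.0, 2.0]),
                        np.array([800.0, 800.0]))
    dosing = DosingScheme("apical", 10.0, (1.0, 2.0), sample_volume=50.0)
    cumulative = cumulative_receiver_amount(series, dosing, receiver_volume=800.0)
    np.testing.assert_allclose(cumulative, [800.0, 850.0])


def test_cumulative_correction_is_identity_without_withdrawal():
    series = TimeCourse("parent", "basal", np.array([1.0, 2.0]),
                        np.array([10.0, 20.0]))
    dosing = DosingScheme("apical", 10.0, (1.0, 2.0), sample_volume=0.0)
    np.testing.assert_array_equal(
        cumulative_receiver_amount(series, dosing, 800.0), series.amounts)


def test_cumulative_correction_matches_unsampled_simulation(epi_geometry):
    """Sampling-corrected receiver amounts agree with a simulation that
    never withdraws aliquots, within 1%."""
    params = SimParams(passive_permeability=1e-6)
    sampled = DosingScheme("apical", 10.0, (0.5, 1.0, 2.0), sample_volume=50.0)
    unsampled = DosingScheme("apical", 10.0, (0.5, 1.0, 2.0), sample_volume=0.0)
    corrected = cumulative_receiver_amount(
        simulate_timecourse(params, epi_geometry, sampled).receiver(),
        sampled, epi_geometry.basal_volume)
    reference = simulate_timecourse(params, epi_geometry, unsampled).receiver().amounts
    np.testing.assert_allclose(corrected, reference, rtol=0.01)


def test_papp_series_recovers_simulated_permeability(epi_geometry):
    params = SimParams(passive_permeability=1e-6)
    dosing = DosingScheme("apical", 10.0, (0.5, 1.0, 1.5, 2.0), sample_volume=50.0)
    res = simulate_timecourse(params, epi_geometry, dosing)
    est = calc_papp_series(res.receiver(), dosing, epi_geometry)
    assert est.papp == pytest.approx(1e-6, rel=0.10)
    assert est.linear_range_flag


def test_papp_series_ab_ba_agree_without_efflux(epi_geometry):
    """No efflux, no metabolism: Papp estimated from the two directions
    agrees within 2% despite the asymmetric compartment volumes."""
    params = SimParams(passive_permeability=1e-6)
    papps = {}
    for donor in ("apical", "basal"):
        dosing = DosingScheme(donor, 10.0, (0.25, 0.5, 1.0), sample_volume=0.0)
        res = simulate_timecourse(params, epi_geometry, dosing)
        papps[donor] = calc_papp_series(res.receiver(), dosing, epi_geometry).papp
    assert papps["apical"] == pytest.approx(papps["basal"], rel=0.02)


def test_low_permeability_marker_recovered(epi_geometry):
    """A 3e-7 cm/s low-permeability QC compound is estimated within 10%
    when sampled over a full day."""
    params = SimParams(passive_permeability=3e-7)
    dosing = DosingScheme("apical", 10.0, (4.0, 8.0, 12.0, 24.0), sample_volume=50.0)
    res = simulate_timecourse(params, epi_geometry, dosing)
    est = calc_papp_series(res.receiver(), dosing, epi_geometry)
    assert est.papp == pytest.approx(3e-7, rel=0.10)


def test_papp_series_endpoint_mode(epi_geometry):
    dosing = DosingScheme("apical", 10.0, (0.5, 1.0, 2.0), sample_volume=0.0)
    res = simulate_timecourse(SimParams(passive_permeability=1e-6), epi_geometry, dosing)
    est = calc_papp_series(res.receiver(), dosing, epi_geometry, endpoint=True)
    assert est.n_points == 1
    assert est.papp == pytest.approx(1e-6, rel=0.10)


def test_papp_series_flags_saturated_transfer(epi_geometry):
    """When every point exceeds 10% of the dose the estimate is still
    returned but flagged out of the linear range."""
    dosing = DosingScheme("apical", 10.0, (1.0, 2.0), sample_volume=0.0)
    series = TimeCourse("parent", "basal", np.array([1.0, 2.0]),
                        np.array([300.0, 500.0]))  # dose is 1000 pmol
    with pytest.warns(UserWarning, match="fewer than 2"):
        est = calc_papp_series(series, dosing, epi_geometry)
    assert not est.linear_range_flag
    assert est.papp > 0


def test_efflux_ratio_quotient_and_inverse_check():
    assert calc_efflux_ratio(1e-6, 1e-6) == pytest.approx(1.0)
    # a 0.3e-6 cm/s A->B permeability with ratio 100 implies 30e-6 B->A
    assert calc_efflux_ratio(30e-6, 0.3e-6) == pytest.approx(100.0)


def test_efflux_ratio_undefined_when_ab_zero():
    with pytest.raises(UndefinedEffluxRatioError) as err:
        calc_efflux_ratio(5e-6, 0.0)
    assert err.value.papp_ba == 5e-6


def test_recovery_arithmetic():
    assert calc_recovery(1000.0, 0.0, dose=1000.0) == pytest.approx(1.0)
    assert calc_recovery(400.0, 350.0, 50.0, dose=1000.0) == pytest.approx(0.80)


def test_recovery_of_noiseless_simulation(epi_geometry):
    """Non-metabolized run recovers the full dose within 0.5% when the
    withdrawn aliquots are added back; with metabolism the parent-only
    recovery falls below 1."""
    dosing = DosingScheme("apical", 10.0, (0.5, 1.0, 2.0), sample_volume=50.0)
    res = simulate_timecourse(SimParams(passive_permeability=1e-6), epi_geometry, dosing)
    corrected = cumulative_receiver_amount(res.receiver(), dosing,
                                           epi_geometry.basal_volume)
    rec = calc_recovery(res.series("parent", "apical").amounts[-1], corrected[-1],
                        res.series("parent", "cell").amounts[-1], res.dose_pmol)
    assert rec == pytest.approx(1.0, abs=0.005)

    metab = SimParams(passive_permeability=2e-6, enzyme_Vmax=0.04, enzyme_Km=1.0)
    res_m = simulate_timecourse(metab, epi_geometry, dosing)
    corrected_m = cumulative_receiver_amount(res_m.receiver(), dosing,
                                             epi_geometry.basal_volume)
    rec_m = calc_recovery(res_m.series("parent", "apical").amounts[-1], corrected_m[-1],
                          res_m.series("parent", "cell").amounts[-1], res_m.dose_pmol)
    assert rec_m < 0.99


def test_passive_only_scenario_has_unit_efflux_ratio(epi_geometry):
    scenario = generate_scenario("passive-only", config={"replicates": 1}, seed=2)
    papps = {}
    for arm in ("AB", "BA"):
        result = scenario.base[arm]
        papps[arm] = calc_papp_series(result.receiver(), result.dosing,
                                      result.geometry).papp
    ratio = calc_efflux_ratio(papps["BA"], papps["AB"])
    assert 0.8 <= ratio <= 1.25


# -- QC ----------------------------------------------------------------------

def _good_record():
    return QCRecord(teer=450.0, reference_efflux=8.0, low_perm_papp=3e-7,
                    recovery=0.95)


def test_qc_all_criteria_met():
    report = qc_evaluate(_good_record())
    assert report.passed
    assert all(v is True for v in report.flags.values())


def test_qc_single_criterion_failure_is_localised():
    record = _good_record()
    record.reference_efflux = 1.0  # below the 2.0 floor
    report = qc_evaluate(record)
    assert not report.passed
    assert report.flags["reference_efflux"] is False
    assert report.flags["teer"] is True


def test_qc_missing_criterion_fails_closed():
    record = _good_record()
    record.teer = None
    report = qc_evaluate(record)
    assert report.flags["teer"] is None
    assert not report.passed


def test_qc_on_simulated_passive_bundle(epi_geometry):
    """A QC bundle measured on the passive-only scenario passes the
    default gates (the reference efflux is taken from an efflux run)."""
    scenario = generate_scenario("passive-only", config={"replicates": 1}, seed=4)
    ab = scenario.base["AB"]
    papp_ab = calc_papp_series(ab.receiver(), ab.dosing, ab.geometry).papp
    corrected = cumulative_receiver_amount(ab.receiver(), ab.dosing,
                                           ab.geometry.basal_volume)
    recovery = calc_recovery(ab.series("parent", "apical").amounts[-1],
                             corrected[-1],
                             ab.series("parent", "cell").amounts[-1],
                             ab.dose_pmol)
    efflux_scn = generate_scenario("efflux", config={"replicates": 1}, seed=4)
    ref_er = calc_efflux_ratio(
        calc_papp_series(efflux_scn.base["BA"].receiver(),
                         efflux_scn.base["BA"].dosing, epi_geometry).papp,
        calc_papp_series(efflux_scn.base["AB"].receiver(),
                         efflux_scn.base["AB"].dosing, epi_geometry).papp)
    record = QCRecord(teer=400.0, reference_efflux=ref_er,
                      low_perm_papp=papp_ab, recovery=recovery)
    assert qc_evaluate(record).passed
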