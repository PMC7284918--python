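"""Apparent permeability, efflux ratio, recovery and assay QC.

The endpoint definition of the apparent permeability coefficient is

    Papp = Q / (C0 * s * t)

with Q the amount recovered in the receiver compartment (pmol), C0 the
initial donor concentration (pmol/cm³), s the insert area (cm²) and t the
incubation time (s).  For multi-timepoint data the default estimator is an
origin-constrained regression of the sampling-corrected cumulative
receiver amount on time, restricted to the pseudo-linear (sink) window
where less than 10% of the dose has transferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from gutpass.simulate import (
    HOUR_S,
    UM_TO_PMOL_CM3,
    DosingScheme,
    TimeCourse,
    TranswellGeometry,
)

#: fraction of the dose beyond which transfer is no longer pseudo-linear
SINK_FRACTION = 0.10


class UndefinedEffluxRatioError(ValueError):
    """Papp(A→B) is zero, so the efflux ratio is unbounded."""

    def __init__(self, papp_ba: float):
        self.papp_ba = papp_ba
        super().__init__(
            f"efflux ratio undefined: Papp,AB = 0 (Papp,BA = {papp_ba:g} cm/s "
            "is only a lower-bound context)"
        )


@dataclass
class PappEstimate:
    """Papp from one receiver time course."""

    papp: float                 # cm/s
    linear_range_flag: bool     # True when fit used only sink-window points
    n_points: int               # points entering the fit


@dataclass
class PermeabilityResult:
    """Bidirectional permeability summary for one compound."""

    papp_ab: float
    papp_ba: float | None = None
    efflux_ratio: float | None = None
    recovery: float | None = None
    linear_range_flag: bool = True

    def __post_init__(self) -> None:
        if self.papp_ab < 0 or (self.papp_ba is not None and self.papp_ba < 0):
            raise ValueError("Papp values must be non-negative")
        if self.efflux_ratio is not None and self.papp_ba is None:
            raise ValueError("efflux_ratio requires both directions")
        if self.recovery is not None and not 0 <= self.recovery <= 1.2:
            raise ValueError("recovery must lie in [0, 1.2]")


def cumulative_receiver_amount(
    series: TimeCourse,
    dosing: DosingScheme,
    receiver_volume: float,
) -> np.ndarray:
    """Cumulative amount transferred to the receiver, corrected for sampling.

    Adds back the analyte removed in prior aliquot withdrawals (an aliquot
    of ``sample_volume`` µL taken at every sample time).  Without
    withdrawals this is the identity.  BLQ points contribute 0.
    """
    if dosing.sample_volume >= receiver_volume:
        raise ValueError(
            f"sample_volume {dosing.sample_volume} µL must be smaller than "
            f"the receiver volume {receiver_volume} µL"
        )
    amounts = series.quantified_amounts()
    if dosing.sample_volume == 0:
        return amounts.copy()
    cumulative = np.empty_like(amounts)
    removed_so_far = 0.0
    volume = receiver_volume
    for i, amount in enumerate(amounts):
        cumulative[i] = amount + removed_so_far
        removed_so_far += amount * dosing.sample_volume / volume
        if not dosing.replace_with_buffer:
            volume -= dosing.sample_volume
    return cumulative


def calc_papp(q_pmol: float, c0_um: float, area_cm2: float, t_h: float) -> float:
    """Endpoint Papp (cm/s) from a single receiver amount.

    ``c0_um`` is converted to pmol/cm³ and ``t_h`` to seconds internally.
    """
    if c0_um <= 0 or area_cm2 <= 0 or t_h <= 0:
        raise ValueError("C0, area and time must be strictly positive")
    if q_pmol < 0:
        raise ValueError("receiver amount must be non-negative")
    return q_pmol / (c0_um * UM_TO_PMOL_CM3 * area_cm2 * t_h * HOUR_S)


def calc_papp_series(
    series: TimeCourse,
    dosing: DosingScheme,
    geometry: TranswellGeometry,
    endpoint: bool = False,
    sink_fraction: float = SINK_FRACTION,
) -> PappEstimate:
    """Papp from a receiver time course with sampling correction.

    Default mode regresses the cumulative receiver amount on time through
    the origin, using quantifiable points with less than ``sink_fraction``
    of the dose transferred; ``linear_range_flag`` records whether such a
    window existed.  ``endpoint=True`` instead applies the single-timepoint
    formula at the last quantifiable point.
    """
    if series.compartment != dosing.receiver_side:
        raise ValueError(
            f"series compartment {series.compartment!r} is not the receiver "
            f"({dosing.receiver_side!r}) for donor side {dosing.donor_side!r}"
        )
    area = geometry.surface_area
    receiver_volume = geometry.volume(dosing.receiver_side)
    dose = dosing.dose_conc * geometry.volume(dosing.donor_side)
    cumulative = cumulative_receiver_amount(series, dosing, receiver_volume)
    times_s = series.times * HOUR_S

    usable = (~series.censored) & (times_s > 0)
    if endpoint:
        idx = np.nonzero(usable)[0]
        if idx.size == 0:
            raise ValueError("no quantifiable nonzero-time point for endpoint Papp")
        last = idx[-1]
        in_range = cumulative[last] < sink_fraction * dose
        if not in_range:
            warnings.warn("endpoint beyond the pseudo-linear (<10% transferred) range")
        return PappEstimate(
            papp=calc_papp(cumulative[last], dosing.dose_conc, area, series.times[last]),
            linear_range_flag=bool(in_range), n_points=1,
        )

    sink = usable & (cumulative < sink_fraction * dose)
    if np.count_nonzero(sink) >= 2:
        mask, flag = sink, True
    else:
        mask, flag = usable, False
        warnings.warn(
            "fewer than 2 quantifiable points below "
            f"{sink_fraction:.0%} of dose; regressing over all points"
        )
    if np.count_nonzero(mask) == 0:
        raise ValueError("no quantifiable points to estimate Papp from")
    t = times_s[mask]
    q = cumulative[mask]
    slope = float(np.sum(t * q) / np.sum(t * t))  # pmol/s, through origin
    papp = max(slope, 0.0) / (dosing.dose_conc * UM_TO_PMOL_CM3 * area)
    return PappEstimate(papp=papp, linear_range_flag=flag,
                        n_points=int(np.count_nonzero(mask)))


def calc_efflux_ratio(papp_ba: float, papp_ab: float) -> float:
    """Efflux ratio Papp(B→A) / Papp(A→B)."""
    if papp_ab <= 0:
        raise UndefinedEffluxRatioError(papp_ba)
    if papp_ba < 0:
        raise ValueError("Papp,BA must be non-negative")
    return papp_ba / papp_ab


def calc_recovery(
    donor_end: float,
    receiver_end: float,
    lysate: float = 0.0,
    dose: float = 1.0,
) -> float:
    """Total recovery (donor + receiver + optional lysate) / dose."""
    if dose <= 0:
        raise ValueError("dose must be strictly positive")
    return (donor_end + receiver_end + lysate) / dose


# ---------------------------------------------------------------------------
# assay quality control
# ---------------------------------------------------------------------------

@dataclass
class QCRecord:
    """Plate-level QC measurements; ``None`` = not measured."""

    teer: float | None = None                  # Ω·cm²
    reference_efflux: float | None = None      # efflux ratio of P-gp reference
    low_perm_papp: float | None = None         # cm/s
    recovery: float | None = None              # fraction of dose


#: default acceptance thresholds (cut-offs are a package choice)
DEFAULT_QC_THRESHOLDS = {
    "teer_min": 200.0,
    "reference_efflux_min": 2.0,
    "low_perm_papp_max": 1e-6,
    "recovery_min": 0.7,
    "recovery_max": 1.2,
}


@dataclass
class QCReport:
    flags: dict[str, bool | None]
    passed: bool


def qc_evaluate(record: QCRecord, thresholds: dict | None = None) -> QCReport:
    """Evaluate plate QC criteria; a missing criterion fails closed.

    Criteria: monolayer integrity (TEER above a floor), functional efflux
    of the P-gp reference substrate, tightness against paracellular leak
    (low-permeability marker below a ceiling) and mass-balance recovery
    within a band.
    """
    th = dict(DEFAULT_QC_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    flags: dict[str, bool | None] = {
        "teer": None if record.teer is None else bool(record.teer >= th["teer_min"]),
        "reference_efflux": (None if record.reference_efflux is None
                             else bool(record.reference_efflux >= th["reference_efflux_min"])),
        "low_perm_papp": (None if record.low_perm_papp is None
                          else bool(record.low_perm_papp <= th["low_perm_papp_max"])),
        "recovery": (None if record.recovery is None
                     else bool(th["recovery_min"] <= record.recovery <= th["recovery_max"])),
    }
    passed = all(v is True for v in flags.values())
    return QCReport(flags=flags, passed=passed)


# ---------------------------------------------------------------------------
# convenience: bidirectional summary from simulated/parsed runs
# ---------------------------------------------------------------------------

def bidirectional_result(
    ab_series: TimeCourse,
    ab_dosing: DosingScheme,
    ba_series: TimeCourse,
    ba_dosing: DosingScheme,
    geometry: TranswellGeometry,
    endpoint: bool = False,
) -> PermeabilityResult:
    """Papp both directions plus efflux ratio for one compound."""
    ab = calc_papp_series(ab_series, ab_dosing, geometry, endpoint=endpoint)
    ba = calc_papp_series(ba_series, ba_dosing, geometry, endpoint=endpoint)
    return PermeabilityResult(
        papp_ab=ab.papp, papp_ba=ba.papp,
        efflux_ratio=calc_efflux_ratio(ba.papp, ab.papp),
        linear_range_flag=ab.linear_range_flag and ba.linear_range_flag,
    )
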