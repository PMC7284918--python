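"""Mechanistic simulation of bidirectional Transwell assays.

The model is a three-compartment (apical / cell / basal) ODE system for a
drug dosed into one compartment of a Transwell insert:

* passive transcellular diffusion across the apical and basolateral
  membranes — the nominal ``passive_permeability`` is the *overall*
  transcellular permeability, so each of the two membranes in series is
  assigned a conductance of ``2 P`` (two equal resistances in series halve
  the overall conductance);
* saturable apical efflux out of the cell (P-gp/BCRP-like),
  ``Jmax * S * C_cell / (Km_eff + C_cell)``;
* saturable intracellular metabolite formation (CYP/UGT/CES-like),
  ``Vmax * S * C_cell / (Km_m_eff + C_cell)``;
* competitive inhibition of either process: the relevant Km is scaled by
  ``1 + I / Ki``;
* repeated sampling: at every sample time an aliquot is withdrawn from the
  receiver compartment (optionally replaced by blank buffer) and the
  withdrawn amounts are carried in the mass balance.

Amounts are in pmol, volumes in µL (so amount/volume is directly µM),
areas in cm², permeabilities in cm/s and times in hours at the interface
(seconds internally).  The unit bridge is 1 µM = 1 pmol/µL = 1000 pmol/cm³.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

HOUR_S = 3600.0
#: 1 µM expressed in pmol/cm³ (permeability formulas use pmol/cm³).
UM_TO_PMOL_CM3 = 1000.0
#: Assumed epithelial monolayer volume per insert area (µL/cm²).
CELL_VOLUME_PER_CM2 = 1.0

COMPARTMENTS = ("apical", "cell", "basal")


class SimulationError(RuntimeError):
    """Raised when the ODE integration fails or produces invalid state."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranswellGeometry:
    """Insert surface area (cm²) and compartment volumes (µL)."""

    surface_area: float
    apical_volume: float
    basal_volume: float
    cell_volume: float | None = None
    format_label: str = "custom"

    def __post_init__(self) -> None:
        if self.cell_volume is None:
            object.__setattr__(
                self, "cell_volume", self.surface_area * CELL_VOLUME_PER_CM2
            )
        for name in ("surface_area", "apical_volume", "basal_volume", "cell_volume"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")

    def volume(self, compartment: str) -> float:
        """Volume (µL) of ``apical``, ``cell`` or ``basal``."""
        try:
            return {
                "apical": self.apical_volume,
                "cell": self.cell_volume,
                "basal": self.basal_volume,
            }[compartment]
        except KeyError:
            raise ValueError(f"unknown compartment {compartment!r}") from None


GEOMETRY_PRESETS: dict[str, TranswellGeometry] = {
    # EpiIntestinal 24-well: 0.6 cm² insert, 100 µL apical / 5000 µL basal
    "EpiIntestinal-24": TranswellGeometry(0.6, 100.0, 5000.0, format_label="EpiIntestinal-24"),
    # Caco-2 24-well Transwell (Corning 3379): 0.33 cm², 200/800 µL
    "Caco2-24": TranswellGeometry(0.33, 200.0, 800.0, format_label="Caco2-24"),
    # 96-well Transwell (Corning 3391): 0.143 cm², 100/250 µL
    "96-well": TranswellGeometry(0.143, 100.0, 250.0, format_label="96-well"),
}


def geometry_preset(name: str) -> TranswellGeometry:
    try:
        return GEOMETRY_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown geometry preset {name!r}; available: {sorted(GEOMETRY_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class SimParams:
    """Mechanistic rates driving the parent/metabolite Transwell model.

    ``passive_permeability`` and ``metabolite_permeability`` are overall
    transcellular permeabilities (cm/s).  ``metabolite_apical_permeability``
    may be set separately to model basolateral-dominant metabolite export
    (e.g. MRP3-mediated glucuronide efflux); ``None`` means symmetric.
    ``efflux_Jmax`` / ``enzyme_Vmax`` are in pmol/s per cm² of insert area,
    Km/Ki in µM, inhibitor concentration in µM.
    """

    passive_permeability: float = 1e-6
    metabolite_permeability: float = 1e-6
    metabolite_apical_permeability: float | None = None
    efflux_Jmax: float = 0.0
    efflux_Km: float = 5.0
    inhibitor_conc: float = 0.0
    inhibitor_Ki_efflux: float = np.inf
    enzyme_Vmax: float = 0.0
    enzyme_Km: float = 5.0
    inhibitor_Ki_enzyme: float = np.inf
    noise_cv: float = 0.0
    loq: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        nonneg = (
            "passive_permeability", "metabolite_permeability", "efflux_Jmax",
            "inhibitor_conc", "enzyme_Vmax", "loq",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.metabolite_apical_permeability is not None and self.metabolite_apical_permeability < 0:
            raise ValueError("metabolite_apical_permeability must be non-negative")
        if self.efflux_Jmax > 0 and self.efflux_Km <= 0:
            raise ValueError("efflux_Km must be > 0 when efflux_Jmax > 0")
        if self.enzyme_Vmax > 0 and self.enzyme_Km <= 0:
            raise ValueError("enzyme_Km must be > 0 when enzyme_Vmax > 0")
        if not 0 <= self.noise_cv < 1:
            raise ValueError("noise_cv must lie in [0, 1)")


@dataclass(frozen=True)
class CascadeParams:
    """Dual-esterase prodrug cascade (dabigatran-etexilate-like).

    The parent ester is hydrolysed along two branches inside the cell:
    CES1 forms the first intermediate from the parent and converts the
    second intermediate to the active drug; CES2 forms the second
    intermediate and converts the first one to the active drug.  Rates are
    first-order in the intracellular amount (s⁻¹), i.e. far below the
    esterase Km.
    """

    parent_permeability: float = 5e-6
    metabolite_permeability: float = 1e-6
    ces1_rate: float = 4e-3
    ces2_rate: float = 4e-3
    noise_cv: float = 0.0
    loq: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("parent_permeability", "metabolite_permeability",
                     "ces1_rate", "ces2_rate", "loq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.noise_cv < 1:
            raise ValueError("noise_cv must lie in [0, 1)")


CASCADE_ANALYTES = ("parent", "m_ces1", "m_ces2", "active")


@dataclass(frozen=True)
class DosingScheme:
    """Dose placement, sampling grid and withdrawal handling.

    ``dose_conc`` is the initial donor concentration C0 (µM); sample times
    are hours; ``sample_volume`` (µL) is withdrawn from the receiver at
    every sample time and replaced by blank buffer when
    ``replace_with_buffer`` is true.
    """

    donor_side: str = "apical"
    dose_conc: float = 10.0
    sample_times: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)
    sample_volume: float = 50.0
    replace_with_buffer: bool = True

    def __post_init__(self) -> None:
        if self.donor_side not in ("apical", "basal"):
            raise ValueError("donor_side must be 'apical' or 'basal'")
        times = np.asarray(self.sample_times, dtype=float)
        if times.size == 0 or times[0] < 0:
            raise ValueError("sample_times must be non-empty with first >= 0")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("sample_times must be strictly increasing")
        if self.dose_conc <= 0:
            raise ValueError("dose_conc must be > 0")
        if self.sample_volume < 0:
            raise ValueError("sample_volume must be non-negative")

    @property
    def receiver_side(self) -> str:
        return "basal" if self.donor_side == "apical" else "apical"


@dataclass
class TimeCourse:
    """Sampled amounts (pmol) of one analyte in one compartment."""

    analyte: str
    compartment: str
    times: np.ndarray
    amounts: np.ndarray
    censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amounts = np.asarray(self.amounts, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(self.times.shape, dtype=bool)
        else:
            self.censored = np.asarray(self.censored, dtype=bool)
        if not (self.times.shape == self.amounts.shape == self.censored.shape):
            raise ValueError("times, amounts and censored must share one length")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if np.any(self.amounts < 0):
            raise ValueError("amounts must be non-negative")

    def quantified_amounts(self) -> np.ndarray:
        """Amounts with censored (BLQ) entries replaced by 0."""
        return np.where(self.censored, 0.0, self.amounts)

    def __len__(self) -> int:
        return self.times.size


@dataclass
class SimulationResult:
    """Noiseless output of one simulated Transwell run."""

    timecourses: dict[tuple[str, str], TimeCourse]
    withdrawn: dict[str, np.ndarray]
    dose_pmol: float
    geometry: TranswellGeometry
    dosing: DosingScheme
    params: object

    def series(self, analyte: str, compartment: str) -> TimeCourse:
        return self.timecourses[(analyte, compartment)]

    def receiver(self, analyte: str = "parent") -> TimeCourse:
        return self.series(analyte, self.dosing.receiver_side)

    @property
    def analytes(self) -> list[str]:
        return sorted({a for a, _ in self.timecourses})

    def total_per_time(self) -> np.ndarray:
        """Total amount (all analytes, compartments and withdrawn aliquots)."""
        total = np.zeros(len(next(iter(self.timecourses.values()))))
        for tc in self.timecourses.values():
            total += tc.amounts
        for cum in self.withdrawn.values():
            total += cum
        return total

    def mass_balance_error(self) -> float:
        """Worst relative deviation of total moles from the dose."""
        return float(np.max(np.abs(self.total_per_time() - self.dose_pmol)) / self.dose_pmol)


# ---------------------------------------------------------------------------
# core integrator
# ---------------------------------------------------------------------------

def _integrate_with_sampling(
    rhs: Callable,
    y0: np.ndarray,
    analytes: Sequence[str],
    state_index: Mapping[tuple[str, str], int],
    geometry: TranswellGeometry,
    dosing: DosingScheme,
    volumes: np.ndarray,
    dose_pmol: float,
    label: str,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Piecewise ODE integration with receiver-aliquot withdrawal.

    Returns recorded states (pre-withdrawal) at every sample time and the
    cumulative withdrawn amount per analyte.
    """
    receiver = dosing.receiver_side
    recv_vol_idx = COMPARTMENTS.index(receiver)
    recv_states = [state_index[(a, receiver)] for a in analytes]

    times_s = np.asarray(dosing.sample_times, dtype=float) * HOUR_S
    y = y0.astype(float).copy()
    t_cursor = 0.0
    atol = 1e-10 * max(dose_pmol, 1.0)
    neg_tol = 1e-9 * max(dose_pmol, 1.0)

    recorded = np.empty((times_s.size, y.size))
    withdrawn_cum = np.zeros(len(analytes))
    withdrawn_rec = np.empty((times_s.size, len(analytes)))

    for i, t in enumerate(times_s):
        if t > t_cursor:
            sol = solve_ivp(
                rhs, (t_cursor, t), y, method="LSODA",
                rtol=1e-8, atol=atol, dense_output=False,
            )
            if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
                raise SimulationError(
                    f"ODE integration failed for {label} over "
                    f"[{t_cursor / HOUR_S:.3g}, {t / HOUR_S:.3g}] h: {sol.message}"
                )
            y = sol.y[:, -1]
            t_cursor = t
        if np.any(y < -neg_tol):
            raise SimulationError(
                f"negative state beyond solver tolerance for {label}: min={y.min():.3g} pmol"
            )
        y = np.clip(y, 0.0, None)
        recorded[i] = y
        withdrawn_rec[i] = withdrawn_cum
        if dosing.sample_volume > 0:
            v_recv = volumes[recv_vol_idx]
            if dosing.sample_volume >= v_recv:
                raise SimulationError(
                    f"sample_volume {dosing.sample_volume} µL >= receiver volume {v_recv} µL"
                )
            frac = dosing.sample_volume / v_recv
            for k, idx in enumerate(recv_states):
                removed = y[idx] * frac
                y[idx] -= removed
                withdrawn_cum[k] += removed
            if not dosing.replace_with_buffer:
                volumes[recv_vol_idx] = v_recv - dosing.sample_volume

    withdrawn = {a: withdrawn_rec[:, k].copy() for k, a in enumerate(analytes)}
    return recorded, withdrawn


def _package_result(
    recorded: np.ndarray,
    withdrawn: dict[str, np.ndarray],
    analytes: Sequence[str],
    state_index: Mapping[tuple[str, str], int],
    dose_pmol: float,
    geometry: TranswellGeometry,
    dosing: DosingScheme,
    params: object,
) -> SimulationResult:
    times = np.asarray(dosing.sample_times, dtype=float)
    timecourses: dict[tuple[str, str], TimeCourse] = {}
    for analyte in analytes:
        for comp in COMPARTMENTS:
            idx = state_index[(analyte, comp)]
            timecourses[(analyte, comp)] = TimeCourse(
                analyte=analyte, compartment=comp,
                times=times.copy(), amounts=recorded[:, idx].copy(),
            )
    return SimulationResult(
        timecourses=timecourses, withdrawn=withdrawn, dose_pmol=dose_pmol,
        geometry=geometry, dosing=dosing, params=params,
    )


# ---------------------------------------------------------------------------
# parent/metabolite model
# ---------------------------------------------------------------------------

def simulate_timecourse(
    params: SimParams,
    geometry: TranswellGeometry,
    dosing: DosingScheme,
) -> SimulationResult:
    """Simulate parent drug and one metabolite in all three compartments.

    Returns noiseless amounts at every sample time; total moles (parent +
    metabolite over all compartments plus withdrawn aliquots) are conserved
    to solver tolerance.
    """
    S = geometry.surface_area
    volumes = np.array([geometry.apical_volume, geometry.cell_volume,
                        geometry.basal_volume])
    # per-membrane conductance (µL/s): 2 P (series membranes) * S * 1000
    kp = 2.0 * params.passive_permeability * S * UM_TO_PMOL_CM3
    p_m_ap = (params.metabolite_apical_permeability
              if params.metabolite_apical_permeability is not None
              else params.metabolite_permeability)
    km_ap = 2.0 * p_m_ap * S * UM_TO_PMOL_CM3
    km_ba = 2.0 * params.metabolite_permeability * S * UM_TO_PMOL_CM3

    i_conc = params.inhibitor_conc
    km_eff = params.efflux_Km
    if np.isfinite(params.inhibitor_Ki_efflux) and params.inhibitor_Ki_efflux > 0:
        km_eff = params.efflux_Km * (1.0 + i_conc / params.inhibitor_Ki_efflux)
    kmm_eff = params.enzyme_Km
    if np.isfinite(params.inhibitor_Ki_enzyme) and params.inhibitor_Ki_enzyme > 0:
        kmm_eff = params.enzyme_Km * (1.0 + i_conc / params.inhibitor_Ki_enzyme)
    jmax_s = params.efflux_Jmax * S
    vmax_s = params.enzyme_Vmax * S

    analytes = ("parent", "metabolite")
    state_index = {
        (a, c): 3 * ia + ic
        for ia, a in enumerate(analytes)
        for ic, c in enumerate(COMPARTMENTS)
    }

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        ca_p, cc_p, cb_p = y[0] / volumes[0], y[1] / volumes[1], y[2] / volumes[2]
        ca_m, cc_m, cb_m = y[3] / volumes[0], y[4] / volumes[1], y[5] / volumes[2]
        j_ac = kp * (ca_p - cc_p)
        j_bc = kp * (cb_p - cc_p)
        cc_pos = max(cc_p, 0.0)
        efflux = jmax_s * cc_pos / (km_eff + cc_pos) if jmax_s > 0 else 0.0
        met = vmax_s * cc_pos / (kmm_eff + cc_pos) if vmax_s > 0 else 0.0
        jm_ac = km_ap * (ca_m - cc_m)
        jm_bc = km_ba * (cb_m - cc_m)
        return np.array([
            -j_ac + efflux,
            j_ac + j_bc - efflux - met,
            -j_bc,
            -jm_ac,
            met + jm_ac + jm_bc,
            -jm_bc,
        ])

    donor_volume = geometry.volume(dosing.donor_side)
    dose_pmol = dosing.dose_conc * donor_volume
    y0 = np.zeros(6)
    y0[state_index[("parent", dosing.donor_side)]] = dose_pmol

    label = f"SimParams(P={params.passive_permeability:g}, Jmax={params.efflux_Jmax:g}, Vmax={params.enzyme_Vmax:g})"
    recorded, withdrawn = _integrate_with_sampling(
        rhs, y0, analytes, state_index, geometry, dosing,
        volumes.copy(), dose_pmol, label,
    )
    return _package_result(recorded, withdrawn, analytes, state_index,
                           dose_pmol, geometry, dosing, params)


def simulate_cascade(
    params: CascadeParams,
    geometry: TranswellGeometry,
    dosing: DosingScheme,
) -> SimulationResult:
    """Simulate the dual-esterase prodrug cascade in a Transwell.

    Species: ``parent`` (double prodrug), ``m_ces1`` (intermediate formed
    by CES1), ``m_ces2`` (intermediate formed by CES2) and ``active``.
    CES1 catalyses parent→m_ces1 and m_ces2→active; CES2 catalyses
    parent→m_ces2 and m_ces1→active.  All hydrolysis occurs in the cell
    compartment, first-order in intracellular amount.
    """
    S = geometry.surface_area
    volumes = np.array([geometry.apical_volume, geometry.cell_volume,
                        geometry.basal_volume])
    kp = 2.0 * params.parent_permeability * S * UM_TO_PMOL_CM3
    km = 2.0 * params.metabolite_permeability * S * UM_TO_PMOL_CM3
    k1, k2 = params.ces1_rate, params.ces2_rate

    analytes = CASCADE_ANALYTES
    state_index = {
        (a, c): 3 * ia + ic
        for ia, a in enumerate(analytes)
        for ic, c in enumerate(COMPARTMENTS)
    }
    cond = {"parent": kp, "m_ces1": km, "m_ces2": km, "active": km}

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        conc = np.empty(3)
        for ia, a in enumerate(analytes):
            base = 3 * ia
            conc[:] = y[base:base + 3] / volumes
            j_ac = cond[a] * (conc[0] - conc[1])
            j_bc = cond[a] * (conc[2] - conc[1])
            dy[base] += -j_ac
            dy[base + 1] += j_ac + j_bc
            dy[base + 2] += -j_bc
        parent_c = y[state_index[("parent", "cell")]]
        m1_c = y[state_index[("m_ces1", "cell")]]
        m2_c = y[state_index[("m_ces2", "cell")]]
        r_p1 = k1 * parent_c      # CES1: parent -> m_ces1
        r_p2 = k2 * parent_c      # CES2: parent -> m_ces2
        r_1a = k2 * m1_c          # CES2: m_ces1 -> active
        r_2a = k1 * m2_c          # CES1: m_ces2 -> active
        dy[state_index[("parent", "cell")]] += -(r_p1 + r_p2)
        dy[state_index[("m_ces1", "cell")]] += r_p1 - r_1a
        dy[state_index[("m_ces2", "cell")]] += r_p2 - r_2a
        dy[state_index[("active", "cell")]] += r_1a + r_2a
        return dy

    donor_volume = geometry.volume(dosing.donor_side)
    dose_pmol = dosing.dose_conc * donor_volume
    y0 = np.zeros(12)
    y0[state_index[("parent", dosing.donor_side)]] = dose_pmol

    label = f"CascadeParams(ces1={k1:g}/s, ces2={k2:g}/s)"
    recorded, withdrawn = _integrate_with_sampling(
        rhs, y0, analytes, state_index, geometry, dosing,
        volumes.copy(), dose_pmol, label,
    )
    return _package_result(recorded, withdrawn, analytes, state_index,
                           dose_pmol, geometry, dosing, params)


# ---------------------------------------------------------------------------
# measurement noise and BLQ censoring
# ---------------------------------------------------------------------------

def _series_rng(seed: int, series: TimeCourse) -> np.random.Generator:
    tag = zlib.crc32(f"{series.analyte}|{series.compartment}".encode())
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, tag])


def apply_measurement_noise(
    series: TimeCourse,
    params: SimParams | CascadeParams,
    rng: np.random.Generator | None = None,
) -> TimeCourse:
    """Multiplicative lognormal noise (CV = ``noise_cv``) plus BLQ flags.

    The lognormal multiplier is mean-one, so noise is unbiased in
    expectation.  Amounts below ``loq`` (pmol) are flagged censored.
    Deterministic under a fixed seed; when ``rng`` is not given, one is
    derived from ``params.seed`` and the series identity.
    """
    if rng is None:
        rng = _series_rng(params.seed, series)
    amounts = series.amounts.copy()
    if params.noise_cv > 0:
        sigma = np.sqrt(np.log1p(params.noise_cv ** 2))
        factors = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                                size=amounts.shape)
        amounts = amounts * factors
    censored = amounts < params.loq
    return TimeCourse(
        analyte=series.analyte, compartment=series.compartment,
        times=series.times.copy(), amounts=amounts, censored=censored,
    )


def noisy_timecourses(
    result: SimulationResult,
    params: SimParams | CascadeParams,
    rng: np.random.Generator,
) -> dict[tuple[str, str], TimeCourse]:
    """Apply measurement noise to every series of a simulation (sorted order
    so the draw sequence is reproducible)."""
    out = {}
    for key in sorted(result.timecourses):
        out[key] = apply_measurement_noise(result.timecourses[key], params, rng=rng)
    return out
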