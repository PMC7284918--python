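"""Bundled simulation scenarios emulating the characterization assays.

Each scenario describes one or more experimental *arms* (e.g. with and
without an inhibitor, or both transport directions), simulates each arm
once noiselessly and then draws replicate noisy datasets.  The returned
object keeps the ground-truth parameters so downstream estimators can be
checked for parameter recovery.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from gutpass.simulate import (
    CascadeParams,
    DosingScheme,
    SimParams,
    SimulationResult,
    TimeCourse,
    TranswellGeometry,
    geometry_preset,
    noisy_timecourses,
    simulate_cascade,
    simulate_timecourse,
)

DEFAULT_REPLICATES = 3


@dataclass(frozen=True)
class ArmSpec:
    """One experimental condition of a scenario."""

    name: str
    params: SimParams | CascadeParams
    geometry: TranswellGeometry
    dosing: DosingScheme
    kind: str = "transport"  # "transport" -> parent/metabolite model, "cascade"

    def simulate(self) -> SimulationResult:
        if self.kind == "cascade":
            return simulate_cascade(self.params, self.geometry, self.dosing)
        return simulate_timecourse(self.params, self.geometry, self.dosing)


@dataclass
class Run:
    """One replicate (noisy) dataset of one arm."""

    run_id: str
    arm: str
    replicate: int
    timecourses: dict[tuple[str, str], TimeCourse]
    dosing: DosingScheme
    geometry: TranswellGeometry


@dataclass
class Scenario:
    """Simulated datasets plus ground truth for one named scenario."""

    name: str
    arms: dict[str, ArmSpec]
    base: dict[str, SimulationResult]
    runs: list[Run]
    seed: int
    replicates: int

    def truth(self, arm: str) -> SimParams | CascadeParams:
        return self.arms[arm].params

    def arm_runs(self, arm: str) -> list[Run]:
        return [r for r in self.runs if r.arm == arm]


def _cfg(config: Mapping | None, key: str, default):
    if config is None:
        return default
    return config.get(key, default)


# ---------------------------------------------------------------------------
# scenario builders: return dict arm_name -> ArmSpec
# ---------------------------------------------------------------------------

def _bidirectional(params: SimParams, geometry: TranswellGeometry,
                   times: tuple[float, ...], c0: float,
                   prefix: str = "") -> dict[str, ArmSpec]:
    arms = {}
    for direction, donor in (("AB", "apical"), ("BA", "basal")):
        name = f"{prefix}{direction}" if prefix else direction
        arms[name] = ArmSpec(
            name=name, params=params, geometry=geometry,
            dosing=DosingScheme(donor_side=donor, dose_conc=c0,
                                sample_times=times, sample_volume=50.0),
        )
    return arms


def _scenario_passive_only(config, seed):
    p = _cfg(config, "passive_permeability", 1e-6)
    geometry = geometry_preset(_cfg(config, "geometry", "EpiIntestinal-24"))
    params = SimParams(passive_permeability=p,
                       noise_cv=_cfg(config, "noise_cv", 0.05),
                       loq=_cfg(config, "loq", 0.5), seed=seed)
    times = tuple(_cfg(config, "sample_times", (0.25, 0.5, 1.0, 1.5)))
    return _bidirectional(params, geometry, times, _cfg(config, "dose_conc", 10.0))


def _efflux_params(config, seed, inhibitor_conc=0.0):
    return SimParams(
        passive_permeability=_cfg(config, "passive_permeability", 1e-6),
        efflux_Jmax=_cfg(config, "efflux_Jmax", 0.05),
        efflux_Km=_cfg(config, "efflux_Km", 5.0),
        inhibitor_conc=inhibitor_conc,
        inhibitor_Ki_efflux=_cfg(config, "inhibitor_Ki_efflux", 1.0),
        noise_cv=_cfg(config, "noise_cv", 0.05),
        loq=_cfg(config, "loq", 0.5), seed=seed,
    )


def _scenario_efflux(config, seed):
    geometry = geometry_preset(_cfg(config, "geometry", "EpiIntestinal-24"))
    times = tuple(_cfg(config, "sample_times", (0.25, 0.5, 1.0)))
    return _bidirectional(_efflux_params(config, seed), geometry, times,
                          _cfg(config, "dose_conc", 10.0))


def _scenario_efflux_inhibitor(config, seed):
    geometry = geometry_preset(_cfg(config, "geometry", "EpiIntestinal-24"))
    times = tuple(_cfg(config, "sample_times", (0.25, 0.5, 1.0)))
    c0 = _cfg(config, "dose_conc", 10.0)
    ki = _cfg(config, "inhibitor_Ki_efflux", 1.0)
    i_conc = _cfg(config, "inhibitor_conc", 100.0 * ki)
    arms = _bidirectional(_efflux_params(config, seed), geometry, times, c0,
                          prefix="control-")
    arms.update(_bidirectional(_efflux_params(config, seed, i_conc),
                               geometry, times, c0, prefix="inhibited-"))
    return arms


def _scenario_rosuvastatin_bcrp(config, seed):
    """Rosuvastatin-like low-permeability BCRP substrate, probed with a
    selective BCRP inhibitor (strong, I/Ki = 100) and a selective P-gp
    inhibitor (off-target, I/Ki = 0.1)."""
    geometry = geometry_preset(_cfg(config, "geometry", "EpiIntestinal-24"))
    times = tuple(_cfg(config, "sample_times", (0.25, 0.5, 1.0)))
    c0 = _cfg(config, "dose_conc", 10.0)
    base = dict(
        passive_permeability=_cfg(config, "passive_permeability", 3e-7),
        efflux_Jmax=_cfg(config, "efflux_Jmax", 0.3),
        efflux_Km=_cfg(config, "efflux_Km", 5.0),
        noise_cv=_cfg(config, "noise_cv", 0.05),
        loq=_cfg(config, "loq", 0.1), seed=seed,
    )
    arms = {}
    for label, i_conc, ki in (
        ("none", 0.0, np.inf),
        ("ko143", 3.0, 0.03),       # BCRP inhibitor, I/Ki = 100
        ("zosuquidar", 5.0, 50.0),  # P-gp inhibitor, I/Ki = 0.1 on BCRP
    ):
        params = SimParams(inhibitor_conc=i_conc, inhibitor_Ki_efflux=ki, **base)
        arms.update(_bidirectional(params, geometry, times, c0,
                                   prefix=f"{label}-"))
    return arms


def _metabolism_arm(config, seed, name, i_conc, geometry, times, c0):
    params = SimParams(
        passive_permeability=_cfg(config, "passive_permeability", 2e-6),
        metabolite_permeability=_cfg(config, "metabolite_permeability", 2e-6),
        enzyme_Vmax=_cfg(config, "enzyme_Vmax", 0.04),
        enzyme_Km=_cfg(config, "enzyme_Km", 5.0),
        inhibitor_conc=i_conc,
        inhibitor_Ki_enzyme=_cfg(config, "inhibitor_Ki_enzyme", 0.01),
        noise_cv=_cfg(config, "noise_cv", 0.05),
        loq=_cfg(config, "loq", 0.5), seed=seed,
    )
    return ArmSpec(name=name, params=params, geometry=geometry,
                   dosing=DosingScheme(donor_side="apical", dose_conc=c0,
                                       sample_times=times, sample_volume=50.0))


def _scenario_midazolam_cyp3a4(config, seed):
    """CYP3A4 substrate, apical-to-basal, ± covalent CYP3A inhibitor
    (modelled competitively at fixed concentration, I/Ki = 100)."""
    geometry = geometry_preset(_cfg(config, "geometry", "EpiIntestinal-24"))
    times = tuple(_cfg(config, "sample_times", (2.0, 4.0, 6.0, 24.0)))
    c0 = _cfg(config, "dose_conc", 10.0)
    i_conc = _cfg(config, "inhibitor_conc", 1.0)
    return {
        "control": _metabolism_arm(config, seed, "control", 0.0, geometry, times, c0),
        "inhibited": _metabolism_arm(config, seed, "inhibited", i_conc, geometry, times, c0),
    }


def _scenario_astemizole_cyp2j2(config, seed):
    """CYP2J2 substrate ± competitive inhibitor (50 µM, I/Ki = 100)."""
    merged = dict(config or {})
    merged.setdefault("enzyme_Vmax", 0.01)
    merged.setdefault("inhibitor_conc", 50.0)
    merged.setdefault("inhibitor_Ki_enzyme", 0.5)
    return _scenario_midazolam_cyp3a4(merged, seed)


def _scenario_linear_formation(config, seed):
    """Saturated enzyme producing a basolaterally exported metabolite at a
    near-constant rate — for formation-rate recovery checks."""
    geometry = geometry_preset(_cfg(config, "geometry", "96-well"))
    times = tuple(_cfg(config, "sample_times", (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)))
    params = SimParams(
        passive_permeability=_cfg(config, "passive_permeability", 1e-5),
        metabolite_permeability=_cfg(config, "metabolite_permeability", 1e-5),
        metabolite_apical_permeability=_cfg(config, "metabolite_apical_permeability", 0.0),
        enzyme_Vmax=_cfg(config, "enzyme_Vmax", 0.05),
        enzyme_Km=_cfg(config, "enzyme_Km", 0.1),
        noise_cv=_cfg(config, "noise_cv", 0.05),
        loq=_cfg(config, "loq", 0.1), seed=seed,
    )
    dosing = DosingScheme(donor_side="apical",
                          dose_conc=_cfg(config, "dose_conc", 10.0),
                          sample_times=times, sample_volume=10.0)
    return {"formation": ArmSpec("formation", params, geometry, dosing)}


def _scenario_ces_cascade(config, seed):
    geometry = geometry_preset(_cfg(config, "geometry", "EpiIntestinal-24"))
    times = tuple(_cfg(config, "sample_times", (2.0, 4.0, 6.0, 24.0)))
    params = CascadeParams(
        parent_permeability=_cfg(config, "parent_permeability", 5e-6),
        metabolite_permeability=_cfg(config, "metabolite_permeability", 1e-6),
        ces1_rate=_cfg(config, "ces1_rate", 4e-3),
        ces2_rate=_cfg(config, "ces2_rate", 4e-3),
        noise_cv=_cfg(config, "noise_cv", 0.1),
        loq=_cfg(config, "loq", 0.5), seed=seed,
    )
    dosing = DosingScheme(donor_side="apical",
                          dose_conc=_cfg(config, "dose_conc", 10.0),
                          sample_times=times, sample_volume=50.0)
    return {"cascade": ArmSpec("cascade", params, geometry, dosing, kind="cascade")}


SCENARIOS: dict[str, Callable] = {
    "passive-only": _scenario_passive_only,
    "efflux": _scenario_efflux,
    "efflux+inhibitor": _scenario_efflux_inhibitor,
    "rosuvastatin-bcrp": _scenario_rosuvastatin_bcrp,
    "midazolam-cyp3a4": _scenario_midazolam_cyp3a4,
    "astemizole-cyp2j2": _scenario_astemizole_cyp2j2,
    "linear-formation": _scenario_linear_formation,
    "ces-cascade": _scenario_ces_cascade,
}


def generate_scenario(
    name: str,
    config: Mapping | None = None,
    seed: int | None = None,
) -> Scenario:
    """Simulate a named scenario and draw replicate noisy datasets.

    ``config`` overrides scenario parameters (see each builder);
    ``replicates`` (default 3) and ``seed`` may be given in ``config`` or
    as the keyword argument.  Identical inputs give identical outputs.
    """
    try:
        builder = SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
    if seed is None:
        seed = int(_cfg(config, "seed", 0))
    replicates = int(_cfg(config, "replicates", DEFAULT_REPLICATES))
    arms = builder(config, seed)

    base: dict[str, SimulationResult] = {}
    runs: list[Run] = []
    for arm_name in sorted(arms):
        arm = arms[arm_name]
        result = arm.simulate()
        base[arm_name] = result
        for rep in range(replicates):
            rng = np.random.default_rng(
                [int(seed) & 0x7FFFFFFF, zlib.crc32(arm_name.encode()), rep]
            )
            runs.append(Run(
                run_id=f"{arm_name}:rep{rep + 1}",
                arm=arm_name, replicate=rep + 1,
                timecourses=noisy_timecourses(result, arm.params, rng),
                dosing=arm.dosing, geometry=arm.geometry,
            ))
    return Scenario(name=name, arms=dict(arms), base=base, runs=runs,
                    seed=seed, replicates=replicates)
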