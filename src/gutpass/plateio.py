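"""Plate-data CSV dialect, packaged fixtures and config I/O.

All modules share one long-format CSV dialect with columns
``run_id, analyte, compartment, time_h, amount_pmol, censored`` — one row
per sampled point.  Fixtures (the DME substrate/metabolite map, the
clinical PK panel and the published in-vitro/clinical comparison values)
ship inside the package and load without network access.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from gutpass.ivive import ClinicalPK
from gutpass.scenarios import Run, Scenario
from gutpass.simulate import COMPARTMENTS, TimeCourse

PLATE_COLUMNS = ("run_id", "analyte", "compartment", "time_h",
                 "amount_pmol", "censored")

FIXTURE_FILES = {
    "clinical_pk": "clinical_pk.csv",
    "dme_map": "dme_map.csv",
    "invitro_clinical_reference": "invitro_clinical_reference.csv",
}


class PlateValidationError(ValueError):
    """Malformed plate CSV; carries one message per offending row."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid plate data:\n" + "\n".join(problems))


@dataclass
class PlateDataset:
    """Long-format plate data plus per-run metadata."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def run_ids(self) -> list[str]:
        return sorted(self.frame["run_id"].unique())

    def timecourses(self, run_id: str) -> dict[tuple[str, str], TimeCourse]:
        sub = self.frame[self.frame["run_id"] == run_id]
        out = {}
        for (analyte, comp), grp in sub.groupby(["analyte", "compartment"], sort=True):
            grp = grp.sort_values("time_h")
            out[(analyte, comp)] = TimeCourse(
                analyte=analyte, compartment=comp,
                times=grp["time_h"].to_numpy(),
                amounts=grp["amount_pmol"].to_numpy(),
                censored=grp["censored"].to_numpy(dtype=bool),
            )
        return out


def read_plate_csv(path: str | Path) -> PlateDataset:
    """Read and validate a long-format plate CSV.

    Raises :class:`PlateValidationError` listing each malformed row
    (negative amounts, unknown compartments, duplicated sample keys) with
    its line number; missing columns fail immediately.
    """
    frame = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in frame.columns]
    if missing:
        raise PlateValidationError([f"missing required columns: {missing}"])

    problems: list[str] = []
    # header is line 1, first data row line 2
    lines = frame.index.to_numpy() + 2
    bad_amount = frame["amount_pmol"].to_numpy() < 0
    for line in lines[bad_amount]:
        problems.append(f"line {line}: negative amount_pmol")
    bad_comp = ~frame["compartment"].isin(COMPARTMENTS).to_numpy()
    for line in lines[bad_comp]:
        problems.append(f"line {line}: unknown compartment")
    dup = frame.duplicated(subset=["run_id", "analyte", "compartment", "time_h"],
                           keep=False).to_numpy()
    first_dup = frame.duplicated(subset=["run_id", "analyte", "compartment", "time_h"],
                                 keep="first").to_numpy()
    for line in lines[dup & first_dup]:
        problems.append(f"line {line}: duplicate (run_id, analyte, compartment, time_h) key")
    if problems:
        raise PlateValidationError(problems)

    frame = frame.copy()
    frame["censored"] = frame["censored"].astype(bool)
    return PlateDataset(frame=frame[list(PLATE_COLUMNS)])


def write_plate_csv(dataset: PlateDataset | pd.DataFrame, path: str | Path) -> None:
    """Write plate data; amounts keep 9 significant digits (lossless well
    beyond the 6 significant figures of typical bioanalytics)."""
    frame = dataset.frame if isinstance(dataset, PlateDataset) else dataset
    frame.to_csv(path, index=False, float_format="%.9g")


def scenario_to_dataset(scenario: Scenario) -> PlateDataset:
    """Flatten the replicate runs of a scenario into one plate dataset."""
    records = []
    for run in scenario.runs:
        for (analyte, comp), tc in sorted(run.timecourses.items()):
            for t, a, c in zip(tc.times, tc.amounts, tc.censored):
                records.append((run.run_id, analyte, comp, t, a, bool(c)))
    frame = pd.DataFrame.from_records(records, columns=PLATE_COLUMNS)
    metadata = {
        "scenario": scenario.name,
        "seed": scenario.seed,
        "replicates": scenario.replicates,
        "runs": {run.run_id: {"arm": run.arm,
                              "donor_side": run.dosing.donor_side,
                              "dose_conc_um": run.dosing.dose_conc,
                              "geometry": run.geometry.format_label}
                 for run in scenario.runs},
    }
    return PlateDataset(frame=frame, metadata=metadata)


def scenario_truth(scenario: Scenario) -> dict:
    """Ground-truth parameters per arm, YAML-serialisable."""
    truth = {}
    for arm_name, arm in scenario.arms.items():
        p = arm.params
        truth[arm_name] = {
            k: (None if v is None else float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in vars(p).items()
        }
    return {"scenario": scenario.name, "seed": scenario.seed, "arms": truth}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def _fixture_path(name: str):
    try:
        filename = FIXTURE_FILES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURE_FILES)}"
        ) from None
    return resources.files("gutpass").joinpath("fixtures", filename)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table.

    ``clinical_pk`` — the 12-drug clinical panel (F, RB, CLp, fe) with an
    ``expected_match`` flag marking drugs whose published Fa·Fg the
    clearance chain does not reproduce; ``dme_map`` — substrate/metabolite
    pairs and tested concentration ranges per enzyme;
    ``invitro_clinical_reference``
    — published 24 h basal recovery vs clinical Fa·Fg percentages.
    """
    with resources.as_file(_fixture_path(name)) as path:
        frame = pd.read_csv(path, comment="#")
    if name == "clinical_pk":
        for _, r in frame.iterrows():   # validates invariants row-wise
            ClinicalPK(drug=str(r["drug"]), F=float(r["F"]), RB=float(r["RB"]),
                       CLp=float(r["CLp_mL_min_kg"]), fe=float(r["fe"]))
        frame["expected_match"] = frame["expected_match"].astype(bool)
    return frame
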