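"""Intestinal first-pass availability (Fa·Fg) from clinical pharmacokinetics.

With the well-stirred liver model, the intestinal first-pass availability
of an orally dosed drug follows from systemic data alone:

    CLb   = CLp / RB              blood clearance from plasma clearance
    CLh   = CLb * (1 - fe)        hepatic clearance (non-renal share)
    Fh    = 1 - CLh / QH          hepatic availability, QH = 20.7 mL/min/kg
    Fa*Fg = F / Fh                oral availability stripped of the liver

F is the absolute oral bioavailability, RB the blood-to-plasma ratio, fe
the renally excreted fraction of systemic clearance.  The chain assumes
hepatic + renal clearance only and linear kinetics; drugs whose printed
Fa·Fg cannot be reproduced from these inputs should carry an
``expected_match=False`` flag so reports surface the mismatch instead of
hiding it.

The counterpart in vitro quantity is the percent of the apical dose
recovered in the basal (portal-vein-equivalent) compartment of a Transwell
culture after 24 h.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: human hepatic blood flow, mL/min/kg
QH_DEFAULT = 20.7


class HepaticExtractionError(ValueError):
    """Hepatic clearance meets or exceeds hepatic blood flow (Fh <= 0)."""


@dataclass(frozen=True)
class ClinicalPK:
    """Per-drug clinical inputs to the Fa·Fg back-calculation."""

    drug: str
    F: float       # absolute oral bioavailability, fraction
    RB: float      # blood-to-plasma concentration ratio
    CLp: float     # plasma clearance, mL/min/kg
    fe: float      # fraction of clearance that is renal
    QH: float = QH_DEFAULT

    def __post_init__(self) -> None:
        if not 0 < self.F <= 1:
            raise ValueError(f"{self.drug}: F must lie in (0, 1]")
        if self.RB <= 0:
            raise ValueError(f"{self.drug}: RB must be > 0")
        if self.CLp < 0:
            raise ValueError(f"{self.drug}: CLp must be >= 0")
        if not 0 <= self.fe <= 1:
            raise ValueError(f"{self.drug}: fe must lie in [0, 1]")
        if self.QH <= 0:
            raise ValueError(f"{self.drug}: QH must be > 0")


@dataclass
class FaFgResult:
    drug: str
    CLb: float
    CLh: float
    Fh: float
    fafg: float                # capped value when cap applied
    fafg_uncapped: float
    capped: bool


def blood_clearance(CLp: float, RB: float) -> float:
    """Blood clearance CLb = CLp / RB (mL/min/kg)."""
    if RB <= 0:
        raise ValueError("blood-to-plasma ratio RB must be > 0")
    return CLp / RB


def hepatic_clearance(CLb: float, fe: float) -> float:
    """Hepatic clearance CLh = CLb * (1 - fe)."""
    if not 0 <= fe <= 1:
        raise ValueError("fe must lie in [0, 1]")
    return CLb * (1.0 - fe)


def hepatic_availability(CLh: float, QH: float = QH_DEFAULT) -> float:
    """Well-stirred hepatic availability Fh = 1 - CLh / QH."""
    if QH <= 0:
        raise ValueError("hepatic blood flow QH must be > 0")
    fh = 1.0 - CLh / QH
    if fh <= 0:
        raise HepaticExtractionError(
            f"hepatic extraction >= 1 (CLh = {CLh:g} >= QH = {QH:g}); "
            "Fa x Fg is undefined"
        )
    return fh


def fafg(F: float, Fh: float, cap: bool = True) -> FaFgResult:
    """Fa·Fg = F / Fh, optionally capped at 1.

    Physically Fa·Fg is a fraction; uncapped values above 1 indicate
    inconsistent inputs (or a mildly over-estimated hepatic extraction)
    and are retained alongside the capped value.
    """
    if not 0 < Fh <= 1:
        raise ValueError("Fh must lie in (0, 1]")
    raw = F / Fh
    capped = cap and raw > 1.0
    return FaFgResult(drug="", CLb=math.nan, CLh=math.nan, Fh=Fh,
                      fafg=1.0 if capped else raw,
                      fafg_uncapped=raw, capped=capped)


def fafg_chain(pk: ClinicalPK, cap: bool = True) -> FaFgResult:
    """Full clearance chain for one drug."""
    clb = blood_clearance(pk.CLp, pk.RB)
    clh = hepatic_clearance(clb, pk.fe)
    fh = hepatic_availability(clh, pk.QH)
    res = fafg(pk.F, fh, cap=cap)
    res.drug = pk.drug
    res.CLb = clb
    res.CLh = clh
    return res


def fafg_table(
    rows: list[ClinicalPK] | pd.DataFrame,
    QH: float = QH_DEFAULT,
    cap: bool = True,
) -> pd.DataFrame:
    """Fa·Fg report for a panel of drugs (integer-percent column included).

    Accepts a list of :class:`ClinicalPK` or a DataFrame with columns
    ``drug, F, RB, CLp_mL_min_kg, fe`` (an ``expected_match`` column, when
    present, is carried through).  Drugs whose hepatic extraction reaches
    1 are flagged in the ``note`` column rather than dropped.
    """
    extra: dict[str, dict] = {}
    if isinstance(rows, pd.DataFrame):
        pk_rows = []
        for _, r in rows.iterrows():
            pk_rows.append(ClinicalPK(drug=str(r["drug"]), F=float(r["F"]),
                                      RB=float(r["RB"]),
                                      CLp=float(r["CLp_mL_min_kg"]),
                                      fe=float(r["fe"]), QH=QH))
            if "expected_match" in rows.columns:
                extra[str(r["drug"])] = {"expected_match": bool(r["expected_match"])}
    else:
        pk_rows = [ClinicalPK(drug=p.drug, F=p.F, RB=p.RB, CLp=p.CLp,
                              fe=p.fe, QH=QH) for p in rows]

    records = []
    for pk in pk_rows:
        rec = {"drug": pk.drug, "F": pk.F, "RB": pk.RB,
               "CLp_mL_min_kg": pk.CLp, "fe": pk.fe}
        try:
            res = fafg_chain(pk, cap=cap)
            rec.update(CLb=res.CLb, CLh=res.CLh, Fh=res.Fh,
                       fafg=res.fafg, fafg_uncapped=res.fafg_uncapped,
                       fafg_pct=int(round(100.0 * res.fafg)),
                       capped=res.capped, note="")
        except HepaticExtractionError as err:
            rec.update(CLb=blood_clearance(pk.CLp, pk.RB),
                       CLh=hepatic_clearance(blood_clearance(pk.CLp, pk.RB), pk.fe),
                       Fh=math.nan, fafg=math.nan, fafg_uncapped=math.nan,
                       fafg_pct=pd.NA, capped=False, note=str(err))
        rec.update(extra.get(pk.drug, {}))
        records.append(rec)
    return pd.DataFrame.from_records(records)


def invitro_availability(receiver_amount_24h: float, dose: float) -> float:
    """In vitro availability: percent of the dose recovered basally.

    Values above 100% are permitted (measurement noise on highly permeable
    drugs can overshoot the dose).
    """
    if dose <= 0:
        raise ValueError("dose must be strictly positive")
    if receiver_amount_24h < 0:
        raise ValueError("receiver amount must be non-negative")
    return 100.0 * receiver_amount_24h / dose


@dataclass
class ComparisonRow:
    drug: str
    invitro_recovery_pct: float
    clinical_fafg_pct: float

    @property
    def fold_error(self) -> float:
        r, c = self.invitro_recovery_pct, self.clinical_fafg_pct
        return max(r / c, c / r)


def compare_invitro_clinical(
    rows: list[ComparisonRow] | pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Per-drug fold error between in vitro recovery and clinical Fa·Fg.

    Returns the per-drug table and a summary with the geometric mean fold
    error, the fraction of drugs within 2-fold and the worst drug.
    Non-positive values are excluded with a warning.
    """
    if isinstance(rows, pd.DataFrame):
        rows = [ComparisonRow(str(r["drug"]),
                              float(r["invitro_recovery_pct"]),
                              float(r["clinical_fafg_pct"]))
                for _, r in rows.iterrows()]
    if not rows:
        raise ValueError("at least one comparison row is required")

    usable = []
    for row in rows:
        if row.invitro_recovery_pct <= 0 or row.clinical_fafg_pct <= 0:
            warnings.warn(f"{row.drug}: non-positive value excluded from comparison")
            continue
        usable.append(row)
    if not usable:
        raise ValueError("no rows with positive values in both columns")

    table = pd.DataFrame({
        "drug": [r.drug for r in usable],
        "invitro_recovery_pct": [r.invitro_recovery_pct for r in usable],
        "clinical_fafg_pct": [r.clinical_fafg_pct for r in usable],
        "fold_error": [r.fold_error for r in usable],
        "within_2fold": [r.fold_error <= 2.0 for r in usable],
    })
    folds = table["fold_error"].to_numpy()
    summary = {
        "n": len(usable),
        "gmfe": float(np.exp(np.mean(np.log(folds)))),
        "n_within_2fold": int(table["within_2fold"].sum()),
        "frac_within_2fold": float(table["within_2fold"].mean()),
        "worst_drug": table.loc[table["fold_error"].idxmax(), "drug"],
    }
    return table, summary
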