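"""Drug-metabolizing-enzyme activity quantification and CES profiling.

Activities are expressed as metabolite-formation rates in the basal
supernatant (pmol/h/cm²), obtained by origin-constrained regression of the
receiver metabolite amount on time.  Intracellular metabolite is reported
as a separate percentage and never folded into the rate, so model-to-model
comparisons stay on the supernatant scale.

The carboxylesterase (CES1/CES2) profile of a dual-ester prodrug is read
from the relative abundance of its three metabolites: the CES1-path
intermediate, the CES2-path intermediate and the fully hydrolysed active
drug.  CES1-dominant tissue (liver-like) accumulates the CES1-path
intermediate, CES2-dominant tissue (intestinal-mucosa-like) the CES2-path
intermediate, and balanced activity pushes material through to the active
drug.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from gutpass.simulate import TimeCourse

#: relative margin below which the top two metabolite fractions tie
TIE_MARGIN = 0.10
#: fraction of the maximal observed rate taken as "approaching saturation"
SATURATION_THRESHOLD = 0.8

CES_ROLES = ("m_ces1", "m_ces2", "active")


@dataclass
class ActivityCurve:
    """Formation rate versus substrate concentration for one enzyme."""

    substrate: str
    enzyme: str
    concentrations: np.ndarray   # µM, strictly increasing
    rates: np.ndarray            # pmol/h/cm²
    blq_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.blq_flags is None:
            self.blq_flags = np.zeros(self.concentrations.shape, dtype=bool)
        else:
            self.blq_flags = np.asarray(self.blq_flags, dtype=bool)
        if not (self.concentrations.shape == self.rates.shape == self.blq_flags.shape):
            raise ValueError("concentrations, rates and blq_flags must share one length")
        if self.concentrations.size > 1 and not np.all(np.diff(self.concentrations) > 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.rates[~self.blq_flags] < 0):
            raise ValueError("rates must be non-negative where quantified")


@dataclass
class ActivityResult:
    """Supernatant-based formation rate for one enzyme in one model."""

    rate: float | None = None        # pmol/h/cm²
    rate_sd: float | None = None
    intracellular_pct: float | None = None
    blq: bool = False

    def __post_init__(self) -> None:
        if self.blq and self.rate is not None:
            raise ValueError("a BLQ result carries no rate")
        if self.intracellular_pct is not None and not 0 <= self.intracellular_pct <= 100:
            raise ValueError("intracellular_pct must lie in [0, 100]")


@dataclass
class CESProfile:
    """Metabolite fractions and CES-dominance call for a dual-ester prodrug."""

    fractions: dict[str, float]
    classification: str          # CES1-dominant | CES2-dominant | balanced | indeterminate

    def __post_init__(self) -> None:
        detected = [v for v in self.fractions.values() if v > 0]
        if detected and abs(sum(self.fractions.values()) - 1.0) > 1e-6:
            raise ValueError("fractions must sum to 1 over detected metabolites")


def fit_formation_rate(
    series: TimeCourse,
    area_cm2: float,
    min_points: int = 3,
) -> ActivityResult:
    """Metabolite-formation rate (pmol/h/cm²) from a basal time course.

    Origin-constrained least squares of amount on time; BLQ points are
    excluded, and fewer than ``min_points`` quantifiable points yields a
    BLQ result.  A negative fitted slope is reported as rate 0 with a
    warning (gross outlier handling is not attempted).
    """
    if area_cm2 <= 0:
        raise ValueError("area must be strictly positive")
    mask = (~series.censored) & (series.times > 0)
    if np.count_nonzero(mask) < min_points:
        return ActivityResult(blq=True)
    t = series.times[mask]
    q = series.amounts[mask]
    slope = float(np.sum(t * q) / np.sum(t * t))   # pmol/h
    if slope < 0:
        warnings.warn("negative fitted formation slope; reporting rate 0")
        slope = 0.0
    return ActivityResult(rate=slope / area_cm2)


def activity_from_replicates(
    replicate_series: list[TimeCourse],
    area_cm2: float,
    lysate_amounts: list[float] | None = None,
) -> ActivityResult:
    """Mean/SD formation rate over replicate wells, optionally with the
    intracellular metabolite percentage from end-of-incubation lysates."""
    rates = []
    for series in replicate_series:
        res = fit_formation_rate(series, area_cm2)
        if not res.blq:
            rates.append(res.rate)
    if not rates:
        return ActivityResult(blq=True)
    intracellular = None
    if lysate_amounts is not None:
        supernatant = [
            float(s.quantified_amounts()[-1]) for s in replicate_series
        ]
        lys, sup = float(np.mean(lysate_amounts)), float(np.mean(supernatant))
        if lys + sup > 0:
            intracellular = intracellular_fraction(lys, sup)
    return ActivityResult(
        rate=float(np.mean(rates)),
        rate_sd=float(np.std(rates, ddof=1)) if len(rates) > 1 else None,
        intracellular_pct=intracellular,
    )


def intracellular_fraction(lysate_amount: float, supernatant_amount: float) -> float:
    """Intracellular metabolite as percent of total (lysate + supernatant).

    Returns NaN (indeterminate) when both amounts are zero.
    """
    if lysate_amount < 0 or supernatant_amount < 0:
        raise ValueError("amounts must be non-negative")
    total = lysate_amount + supernatant_amount
    if total == 0:
        warnings.warn("no metabolite detected in lysate or supernatant")
        return math.nan
    return 100.0 * lysate_amount / total


def select_saturating_concentration(
    curve: ActivityCurve,
    threshold: float = SATURATION_THRESHOLD,
) -> float:
    """Lowest tested concentration whose rate reaches ``threshold`` of the
    maximal observed rate — the working concentration for activity
    comparisons.  Warns when no plateau is apparent (the selected point is
    the highest tested concentration) or only one point is quantifiable.
    """
    mask = ~curve.blq_flags
    if not mask.any():
        raise ValueError("all points are below the limit of quantification")
    conc = curve.concentrations[mask]
    rates = curve.rates[mask]
    if conc.size == 1:
        warnings.warn("single quantifiable point; returning its concentration")
        return float(conc[0])
    cutoff = threshold * rates.max()
    selected = float(conc[np.nonzero(rates >= cutoff)[0][0]])
    if selected == float(conc[-1]):
        warnings.warn("no saturation plateau detected; returning the highest "
                      "tested concentration")
    return selected


@dataclass
class FoldDifference:
    enzyme: str
    fold: float | None           # rate_a / rate_b, None when not computable
    qualitative: str | None = None
    comparable: bool = True


def compare_activities(
    model_a: dict[str, ActivityResult],
    model_b: dict[str, ActivityResult],
    loq_rate: float | None = None,
) -> dict[str, FoldDifference]:
    """Per-enzyme fold difference (model_a / model_b) over shared enzymes.

    A BLQ denominator gives a qualitative lower bound (``> rate_a / LOQ``
    when ``loq_rate`` is known); BLQ in both models is flagged
    not-compared.
    """
    out: dict[str, FoldDifference] = {}
    for enzyme in sorted(set(model_a) & set(model_b)):
        a, b = model_a[enzyme], model_b[enzyme]
        if a.blq and b.blq:
            out[enzyme] = FoldDifference(enzyme, None, "both BLQ", comparable=False)
        elif b.blq:
            qual = (f"> {a.rate / loq_rate:.1f}-fold" if loq_rate
                    else "denominator BLQ")
            out[enzyme] = FoldDifference(enzyme, None, qual, comparable=False)
        elif a.blq:
            qual = (f"< {loq_rate / b.rate:.2g}-fold" if loq_rate
                    else "numerator BLQ")
            out[enzyme] = FoldDifference(enzyme, None, qual, comparable=False)
        else:
            out[enzyme] = FoldDifference(enzyme, a.rate / b.rate)
    return out


def classify_ces_profile(
    metabolite_series: dict[str, TimeCourse] | list[TimeCourse],
    roles: dict[str, str] | None = None,
    mode: str = "final",
    tie_margin: float = TIE_MARGIN,
) -> CESProfile:
    """Classify the CES1/CES2 pattern from receiver metabolite time courses.

    ``metabolite_series`` maps role names (``m_ces1``, ``m_ces2``,
    ``active``) to time courses, or is a list whose analyte names are the
    roles (``roles`` may translate analyte names to roles).  ``mode`` is
    ``"final"`` (amounts at the last common timepoint, the default) or
    ``"auc"`` (trapezoidal area under the amount curve).

    Classification: CES1-dominant when the CES1-path intermediate is
    strictly largest, CES2-dominant when the CES2-path intermediate is
    largest, balanced when the active drug is largest, indeterminate when
    everything is zero or the top two fractions are within ``tie_margin``
    relative difference.
    """
    if isinstance(metabolite_series, dict):
        by_role = dict(metabolite_series)
    else:
        mapping = roles or {}
        by_role = {mapping.get(s.analyte, s.analyte): s for s in metabolite_series}
    missing = [r for r in CES_ROLES if r not in by_role]
    if missing:
        raise ValueError(f"missing metabolite series for roles: {missing}")

    values: dict[str, float] = {}
    for role in CES_ROLES:
        series = by_role[role]
        amounts = series.quantified_amounts()
        if mode == "final":
            values[role] = float(amounts[-1])
        elif mode == "auc":
            values[role] = float(np.trapezoid(amounts, series.times))
        else:
            raise ValueError("mode must be 'final' or 'auc'")

    total = sum(values.values())
    if total <= 0:
        return CESProfile(fractions={r: 0.0 for r in CES_ROLES},
                          classification="indeterminate")
    fractions = {r: v / total for r, v in values.items()}
    ranked = sorted(fractions.items(), key=lambda kv: kv[1], reverse=True)
    top, second = ranked[0], ranked[1]
    if top[1] > 0 and (top[1] - second[1]) / top[1] < tie_margin:
        classification = "indeterminate"
    else:
        classification = {
            "m_ces1": "CES1-dominant",
            "m_ces2": "CES2-dominant",
            "active": "balanced",
        }[top[0]]
    return CESProfile(fractions=fractions, classification=classification)
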