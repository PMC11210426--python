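"""Domain types for population-level infant-feeding footprint accounting.

The model partitions infants under 6 months into three mutually exclusive
feeding categories:

* **exclusively or predominantly breastfed** (EBF+PBF) — breastmilk only, or
  breastmilk plus water; these infants consume no commercial milk formula
  (CMF);
* **partially breastfed** — mixed feeding, assumed to draw one third of
  intake from CMF;
* **non-breastfed** — fully CMF-fed.

Prevalences are handled on the 0–100 percentage scale end to end; conversion
to fractions happens only inside arithmetic.  All annual quantities are
driven by the cohort's annual live births, which approximate the population
of infants aged 0 to under 6 months in any given year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

__all__ = [
    "ValidationError",
    "FeedingPrevalence",
    "AgeBandPrevalence",
    "CohortSpec",
    "FootprintParams",
    "FootprintResult",
    "ScenarioComparison",
    "normalize_prevalence",
    "aggregate_bands",
    "round_half_up",
    "AGE_BANDS",
    "SUM_TOLERANCE",
]

#: Permitted deviation of a complete prevalence record from 100 %, in
#: percentage points.
SUM_TOLERANCE = 0.1

#: Maximum disagreement allowed between an aggregate prevalence and the
#: unweighted mean of its age bands, in percentage points per category.
BAND_AGREEMENT_TOLERANCE = 0.5

#: Canonical age-band labels for infants under 6 months.
AGE_BANDS = ("0-1", "2-3", "4-5")


class ValidationError(ValueError):
    """Raised when an input record violates a model invariant."""


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round ``value`` half away from zero to ``ndigits`` decimals.

    This is the single display-rounding routine used everywhere a number is
    rendered, so reports cannot drift apart in their last digit.  Python's
    built-in ``round`` uses banker's rounding, which turns 7.465 × 10 into
    74.6 rather than the conventionally printed 74.7.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _check_pct(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value}")
    if value > 100:
        raise ValidationError(f"{name} must be <= 100, got {value}")


@dataclass(frozen=True)
class FeedingPrevalence:
    """Complete feeding-category shares for infants under 6 months.

    Parameters
    ----------
    ebf_pbf:
        Percentage exclusively or predominantly breastfed.
    partial:
        Percentage partially breastfed (mixed feeding).
    non_bf:
        Percentage non-breastfed (fully CMF-fed).

    The three shares must each lie in [0, 100] and sum to 100 within
    ``SUM_TOLERANCE`` percentage points.  Use :func:`normalize_prevalence`
    to build a record from a survey row that omits one category.
    """

    ebf_pbf: float
    partial: float
    non_bf: float

    def __post_init__(self) -> None:
        for name in ("ebf_pbf", "partial", "non_bf"):
            _check_pct(name, getattr(self, name))
        total = self.ebf_pbf + self.partial + self.non_bf
        if abs(total - 100.0) > SUM_TOLERANCE:
            raise ValidationError(
                f"prevalence sum {total:g} differs from 100 by more than "
                f"{SUM_TOLERANCE} points ({self.ebf_pbf}/{self.partial}/{self.non_bf})"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.ebf_pbf, self.partial, self.non_bf)

    def delta(self, other: "FeedingPrevalence") -> dict[str, float]:
        """Per-category percentage-point change ``self − other``."""
        return {
            "ebf_pbf": self.ebf_pbf - other.ebf_pbf,
            "partial": self.partial - other.partial,
            "non_bf": self.non_bf - other.non_bf,
        }


def normalize_prevalence(
    ebf_pbf: float | None = None,
    partial: float | None = None,
    non_bf: float | None = None,
    *,
    label: str = "",
) -> FeedingPrevalence:
    """Complete a partial prevalence record.

    At least two of the three categories must be supplied; the missing one is
    derived as the complement to 100 %.  Survey rows routinely report only
    the breastfeeding categories (with predominant breastfeeding taken as
    zero when unavailable), leaving the non-breastfed share implicit.

    A derived complement that is negative by at most ``SUM_TOLERANCE``
    points — a rounding artefact of 1-decimal survey percentages — is clamped
    to zero.  A larger deficit is treated as a data-entry error and raised,
    never silently corrected.

    Already-complete records pass through unchanged (idempotence), subject to
    the sum check.
    """
    where = f" in {label!r}" if label else ""
    supplied = {
        name: value
        for name, value in (
            ("ebf_pbf", ebf_pbf),
            ("partial", partial),
            ("non_bf", non_bf),
        )
        if value is not None
    }
    if len(supplied) < 2:
        raise ValidationError(
            f"at least two of ebf_pbf/partial/non_bf required{where}, "
            f"got {sorted(supplied)}"
        )
    for name, value in supplied.items():
        _check_pct(f"{name}{where}", value)

    total = sum(supplied.values())
    if len(supplied) == 3:
        if abs(total - 100.0) > SUM_TOLERANCE:
            raise ValidationError(
                f"prevalence sum {total:g} != 100 (+/- {SUM_TOLERANCE}){where}"
            )
        return FeedingPrevalence(ebf_pbf, partial, non_bf)  # type: ignore[arg-type]

    complement = 100.0 - total
    if complement < -SUM_TOLERANCE:
        raise ValidationError(f"prevalence sum {total:g} > 100{where}")
    complement = max(complement, 0.0)
    values = dict(supplied)
    (missing,) = {"ebf_pbf", "partial", "non_bf"} - set(supplied)
    values[missing] = complement
    return FeedingPrevalence(**values)


@dataclass(frozen=True)
class AgeBandPrevalence:
    """Feeding prevalence within one of the three under-6-month age bands."""

    band: str
    prevalence: FeedingPrevalence

    def __post_init__(self) -> None:
        if self.band not in AGE_BANDS:
            raise ValidationError(
                f"unknown age band {self.band!r}; expected one of {AGE_BANDS}"
            )


def aggregate_bands(bands: Sequence[AgeBandPrevalence]) -> FeedingPrevalence:
    """Collapse three age-band records into an under-6-months aggregate.

    The aggregate is the unweighted arithmetic mean of the band shares — the
    age bands are equal two-month slices of the cohort, so under the
    uniform-births assumption each carries the same population weight.
    """
    seen = [b.band for b in bands]
    if sorted(seen) != sorted(AGE_BANDS):
        raise ValidationError(
            f"need exactly the three bands {AGE_BANDS}, got {seen}"
        )
    n = len(bands)
    return FeedingPrevalence(
        ebf_pbf=sum(b.prevalence.ebf_pbf for b in bands) / n,
        partial=sum(b.prevalence.partial for b in bands) / n,
        non_bf=sum(b.prevalence.non_bf for b in bands) / n,
    )


@dataclass(frozen=True)
class CohortSpec:
    """A population of infants under 6 months to evaluate.

    ``annual_births`` stands in for the size of the 0-to-under-6-months
    population: each year's births spend six months in the age window, and
    the published country estimates are reproduced only when the full annual
    birth count (not half of it) enters the footprint formulas.

    Prevalence may be given as an aggregate, as three age bands, or both; if
    both, they must agree (aggregate within ``BAND_AGREEMENT_TOLERANCE``
    points of the unweighted band mean, per category).
    """

    label: str
    annual_births: float
    prevalence: FeedingPrevalence | None = None
    bands: tuple[AgeBandPrevalence, ...] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.annual_births) or self.annual_births < 0:
            raise ValidationError(
                f"annual_births must be >= 0, got {self.annual_births!r}"
            )
        if self.bands is not None and not isinstance(self.bands, tuple):
            object.__setattr__(self, "bands", tuple(self.bands))
        if self.prevalence is None and self.bands is None:
            raise ValidationError(
                f"cohort {self.label!r}: aggregate or band prevalence required"
            )
        if self.prevalence is not None and self.bands is not None:
            mean = aggregate_bands(self.bands)
            for cat, agg, bm in zip(
                ("ebf_pbf", "partial", "non_bf"),
                self.prevalence.as_tuple(),
                mean.as_tuple(),
            ):
                if abs(agg - bm) > BAND_AGREEMENT_TOLERANCE:
                    raise ValidationError(
                        f"cohort {self.label!r}: aggregate {cat} {agg:g} "
                        f"disagrees with band mean {bm:g} by more than "
                        f"{BAND_AGREEMENT_TOLERANCE} points"
                    )

    @property
    def effective_prevalence(self) -> FeedingPrevalence:
        """Aggregate prevalence, derived from bands when only bands exist."""
        if self.prevalence is not None:
            return self.prevalence
        assert self.bands is not None
        return aggregate_bands(self.bands)

    def with_prevalence(self, prevalence: FeedingPrevalence) -> "CohortSpec":
        """Same population under different feeding practices (bands dropped)."""
        return replace(self, prevalence=prevalence, bands=None)


@dataclass(frozen=True)
class FootprintParams:
    """All model constants, with units and provenance.

    CMF mass and emission factors are literature values: 20 kg of powder
    feeds a non-breastfed infant for the first 6 months (UNHCR protocol,
    including stock waste) and a partially breastfed infant draws one third
    of that intake (6.7 kg); lifecycle analyses put emissions per kg of
    powder between 11 kg CO₂e (lower bound) and 14 kg CO₂e (upper bound).

    The water intensity and the lost-milk constants are calibration values:
    published country tabulations of this accounting method never state them
    directly, so they are back-derived here from the printed outputs.
    4,752.7 L/kg sits inside the 4,700–7,430 L/kg total-water-footprint
    literature range (plus ~7 L reconstitution and ~56 L washing per kg) and
    reproduces every published water cell to the printed digit.  Likewise
    45 L of lost milk per fully non-breastfed infant over 6 months, with a
    partially breastfed infant counted at fraction 0.12, reproduces the
    published lost-milk cells for own-data cohorts.

    The maternal-diet factors cover the *optional* add-on for interventions
    that include enhanced nutrition for breastfeeding mothers: 69 kg CO₂e
    per mother per 6 months for a mainly plant-based diet, 218 kg CO₂e for a
    mixed plant/animal diet.  They are reported separately and never folded
    into a cohort footprint.

    The equivalence factors convert emissions to average-vehicle miles
    (19.3 billion miles per 7.5 billion kg CO₂e) and water to Olympic
    swimming pools (3,125,000 L per pool); both quotients are fixed so that
    reported equivalents match the published headline comparisons.
    """

    m_full: float = 20.0        # kg CMF powder per non-breastfed infant / 6 mo
    m_partial: float = 6.7      # kg CMF powder per partially breastfed infant
    e_low: float = 11.0         # kg CO2e per kg powder, lower bound
    e_high: float = 14.0        # kg CO2e per kg powder, upper bound
    w_intensity: float = 4752.7  # liters of water per kg powder
    v_milk: float = 45.0        # liters lost milk per non-breastfed infant / 6 mo
    alpha_partial: float = 0.12  # lost-milk fraction for a partial infant
    diet_plant: float = 69.0    # kg CO2e per mother / 6 mo, plant-based diet
    diet_mixed: float = 218.0   # kg CO2e per mother / 6 mo, mixed diet
    miles_per_kg: float = 19.3 / 7.5   # vehicle miles per kg CO2e
    pool_volume: float = 3_125_000.0   # liters per Olympic pool

    def __post_init__(self) -> None:
        for name in (
            "m_full", "m_partial", "e_low", "e_high", "w_intensity",
            "v_milk", "alpha_partial", "diet_plant", "diet_mixed",
            "miles_per_kg", "pool_volume",
        ):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValidationError(f"{name} must be strictly positive, got {value!r}")
        if self.e_low > self.e_high:
            raise ValidationError(
                f"e_low ({self.e_low}) must not exceed e_high ({self.e_high})"
            )
        if self.m_partial > self.m_full:
            raise ValidationError(
                f"m_partial ({self.m_partial}) must not exceed m_full ({self.m_full})"
            )


#: Module-level default parameter set; every published headline number is
#: reproduced with these values, no override needed.
DEFAULT_PARAMS = FootprintParams()


@dataclass(frozen=True)
class FootprintResult:
    """Annual footprint of one cohort, in the units the method reports.

    ``cmf_kg`` is raw kilograms of powder per year; the greenhouse-gas
    fields are million kg CO₂e per year and the water and lost-milk fields
    million liters per year.  Difference records (counterfactual − baseline)
    reuse this shape and may carry negative fields.
    """

    cmf_kg: float
    ghg_low: float
    ghg_high: float
    water: float
    lost_milk: float

    # raw-unit accessors for the equivalence converter
    @property
    def ghg_low_kg(self) -> float:
        return self.ghg_low * 1e6

    @property
    def ghg_high_kg(self) -> float:
        return self.ghg_high * 1e6

    @property
    def water_liters(self) -> float:
        return self.water * 1e6

    @property
    def lost_milk_liters(self) -> float:
        return self.lost_milk * 1e6

    def __sub__(self, other: "FootprintResult") -> "FootprintResult":
        return FootprintResult(
            cmf_kg=self.cmf_kg - other.cmf_kg,
            ghg_low=self.ghg_low - other.ghg_low,
            ghg_high=self.ghg_high - other.ghg_high,
            water=self.water - other.water,
            lost_milk=self.lost_milk - other.lost_milk,
        )

    def scaled(self, factor: float) -> "FootprintResult":
        """Every field multiplied by ``factor`` (coverage scaling)."""
        return FootprintResult(
            cmf_kg=self.cmf_kg * factor,
            ghg_low=self.ghg_low * factor,
            ghg_high=self.ghg_high * factor,
            water=self.water * factor,
            lost_milk=self.lost_milk * factor,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "cmf_kg": self.cmf_kg,
            "ghg_low": self.ghg_low,
            "ghg_high": self.ghg_high,
            "water": self.water,
            "lost_milk": self.lost_milk,
        }


@dataclass(frozen=True)
class ScenarioComparison:
    """Baseline vs counterfactual footprints and their signed differences.

    ``difference`` is exactly ``counterfactual − baseline`` fieldwise; a
    negative entry is an avoided emission or avoided water use, the
    "additionality" a carbon-offset certification is based on.
    ``prevalence_delta`` carries the per-category percentage-point changes
    (counterfactual − baseline).
    """

    baseline: FootprintResult
    counterfactual: FootprintResult
    difference: FootprintResult
    prevalence_delta: dict[str, float] = field(default_factory=dict)
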