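"""Closed-form footprint computations for one cohort.

All quantities are linear in the number of infants, so each operation is a
single closed-form product:

* annual CMF powder requirement (kg),
    ``births × (partial% × 6.7 kg + non_bf% × 20 kg)``;
* greenhouse-gas range (million kg CO₂e),
    ``CMF kg × emission factor`` with the 11/14 kg CO₂e per kg bounds;
* water footprint (million L), ``CMF kg × water intensity``;
* lost breastmilk (million L),
    ``births × (non_bf% + α × partial%) × 45 L``;
* the optional maternal-diet add-on and the miles / swimming-pool
  equivalence conversions.
"""

from __future__ import annotations

from .model import (
    DEFAULT_PARAMS,
    CohortSpec,
    FootprintParams,
    FootprintResult,
    ValidationError,
)

__all__ = [
    "cmf_requirement",
    "ghg_range",
    "water_use",
    "lost_milk",
    "maternal_diet_ghg",
    "compute_footprint",
    "equivalents",
    "DIET_PATTERNS",
]

#: Recognized maternal dietary patterns for the nutrition add-on.
DIET_PATTERNS = ("plant", "mixed")


def _check_mass(cmf_kg: float) -> None:
    if cmf_kg < 0:
        raise ValidationError(f"CMF mass must be >= 0, got {cmf_kg}")


def cmf_requirement(
    cohort: CohortSpec, params: FootprintParams = DEFAULT_PARAMS
) -> float:
    """Annual commercial-milk-formula powder requirement in kilograms.

    A non-breastfed infant consumes ``m_full`` kg of powder over the 6-month
    window and a partially breastfed infant ``m_partial`` kg; exclusively or
    predominantly breastfed infants consume none.
    """
    p = cohort.effective_prevalence
    per_infant = (
        p.partial / 100.0 * params.m_partial + p.non_bf / 100.0 * params.m_full
    )
    return cohort.annual_births * per_infant


def ghg_range(
    cmf_kg: float, params: FootprintParams = DEFAULT_PARAMS
) -> tuple[float, float]:
    """(lower, upper) greenhouse-gas emissions in million kg CO₂e per year."""
    _check_mass(cmf_kg)
    return (cmf_kg * params.e_low / 1e6, cmf_kg * params.e_high / 1e6)


def water_use(cmf_kg: float, params: FootprintParams = DEFAULT_PARAMS) -> float:
    """Water footprint in million liters per year.

    Covers the full production-and-use intensity per kg of powder (blue,
    green and grey production water plus hygienic reconstitution and bottle
    washing).
    """
    _check_mass(cmf_kg)
    return cmf_kg * params.w_intensity / 1e6


def lost_milk(
    cohort: CohortSpec, params: FootprintParams = DEFAULT_PARAMS
) -> float:
    """Breastmilk not produced because of CMF feeding, million L per year.

    A fully non-breastfed infant forgoes ``v_milk`` liters over 6 months; a
    partially breastfed infant is counted at fraction ``alpha_partial`` of
    that volume.
    """
    p = cohort.effective_prevalence
    displaced = p.non_bf / 100.0 + params.alpha_partial * p.partial / 100.0
    return cohort.annual_births * displaced * params.v_milk / 1e6


def maternal_diet_ghg(
    n_mothers: float,
    pattern: str,
    params: FootprintParams = DEFAULT_PARAMS,
) -> float:
    """GHG cost (kg CO₂e per 6 months) of extra food for breastfeeding mothers.

    This is a deliberately separate add-on for interventions that include
    enhanced maternal nutrition; it is never folded into a cohort
    :class:`~cmfootprint.model.FootprintResult`.  ``pattern`` selects a
    mainly plant-based diet or a mixed plant/animal diet.
    """
    if n_mothers < 0:
        raise ValidationError(f"n_mothers must be >= 0, got {n_mothers}")
    if pattern == "plant":
        factor = params.diet_plant
    elif pattern == "mixed":
        factor = params.diet_mixed
    else:
        raise ValidationError(
            f"unknown diet pattern {pattern!r}; expected one of {DIET_PATTERNS}"
        )
    return n_mothers * factor


def compute_footprint(
    cohort: CohortSpec, params: FootprintParams = DEFAULT_PARAMS
) -> FootprintResult:
    """Full annual footprint of one cohort.

    The fields are mutually consistent by construction: the GHG bounds and
    the water volume are fixed multiples of the CMF mass
    (``ghg_high/ghg_low == e_high/e_low`` and
    ``water liters / cmf_kg == w_intensity`` whenever the mass is nonzero).
    """
    kg = cmf_requirement(cohort, params)
    low, high = ghg_range(kg, params)
    return FootprintResult(
        cmf_kg=kg,
        ghg_low=low,
        ghg_high=high,
        water=water_use(kg, params),
        lost_milk=lost_milk(cohort, params),
    )


def equivalents(
    result: FootprintResult,
    params: FootprintParams = DEFAULT_PARAMS,
    basis: str = "high",
) -> tuple[float, float]:
    """Translate a footprint into (vehicle miles driven, Olympic pools).

    ``basis`` selects which GHG bound supplies the emission mass; the upper
    bound is the default, matching the headline comparisons published for
    this accounting method.
    """
    if basis == "high":
        kg = result.ghg_high_kg
    elif basis == "low":
        kg = result.ghg_low_kg
    else:
        raise ValidationError(f"basis must be 'low' or 'high', got {basis!r}")
    if kg < 0 or result.water_liters < 0:
        raise ValidationError("equivalents are defined for nonnegative footprints")
    miles = kg * params.miles_per_kg
    pools = result.water_liters / params.pool_volume
    return miles, pools
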