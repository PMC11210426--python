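"""Baseline-vs-counterfactual scenario engine.

A scenario pairs a cohort with an optional coverage fraction (the share of
births an intervention actually reaches).  Comparing a baseline against a
counterfactual yields the signed fieldwise difference — the "additionality"
that carbon-offset certification under the Clean Development Mechanism is
based on.  Helpers construct counterfactual prevalences from an
exclusive-breastfeeding uplift, scale results to partial coverage, and build
the extreme "extinction" scenario in which all breastfeeding is displaced by
formula feeding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, NamedTuple

import yaml

from .engine import DIET_PATTERNS, compute_footprint
from .model import (
    DEFAULT_PARAMS,
    CohortSpec,
    FeedingPrevalence,
    FootprintParams,
    FootprintResult,
    ScenarioComparison,
    ValidationError,
    normalize_prevalence,
)

__all__ = [
    "ScenarioSpec",
    "CoverageResult",
    "compare",
    "apply_uplift",
    "scale_coverage",
    "avoided_under_coverage",
    "extinction",
    "scenario_from_config",
    "load_comparison_config",
    "ComparisonConfig",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A cohort to evaluate, with a coverage fraction in (0, 1].

    ``coverage`` is the fraction of annual births affected by the scenario
    (e.g. the share of births in hospitals implementing a maternity-services
    intervention); 1 means the whole cohort.
    """

    cohort: CohortSpec
    description: str = ""
    coverage: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage <= 1.0:
            raise ValidationError(
                f"coverage must be in (0, 1], got {self.coverage}"
            )


class CoverageResult(NamedTuple):
    """A coverage-scaled footprint plus the number of births covered."""

    result: FootprintResult
    covered_births: float


def compare(
    baseline: ScenarioSpec,
    counterfactual: ScenarioSpec,
    params: FootprintParams = DEFAULT_PARAMS,
) -> ScenarioComparison:
    """Footprints of both scenarios and their signed difference.

    Both cohorts are evaluated in full (coverage is applied separately by
    :func:`scale_coverage`, never implicitly here).  The difference is
    ``counterfactual − baseline`` fieldwise, so avoided emissions and water
    appear as negative numbers.  Differing birth counts are unusual but
    legitimate (e.g. a demographic projection), so they warn rather than
    fail.
    """
    if baseline.cohort.annual_births != counterfactual.cohort.annual_births:
        warnings.warn(
            "baseline and counterfactual have different annual_births "
            f"({baseline.cohort.annual_births:g} vs "
            f"{counterfactual.cohort.annual_births:g}); differences mix "
            "population change with practice change",
            stacklevel=2,
        )
    base = compute_footprint(baseline.cohort, params)
    cf = compute_footprint(counterfactual.cohort, params)
    return ScenarioComparison(
        baseline=base,
        counterfactual=cf,
        difference=cf - base,
        prevalence_delta=counterfactual.cohort.effective_prevalence.delta(
            baseline.cohort.effective_prevalence
        ),
    )


def apply_uplift(
    base: FeedingPrevalence, ebf_increase: float
) -> FeedingPrevalence:
    """Raise the EBF+PBF share by ``ebf_increase`` percentage points.

    The remaining non-(EBF+PBF) share is split with the two-thirds rule used
    when a survey reports only exclusive breastfeeding: two thirds of it is
    taken as partial breastfeeding and one third as non-breastfed.  Note the
    rule re-splits the *whole* remainder, so the output partial/non-breastfed
    shares follow the new EBF+PBF level, not the baseline split.
    """
    new_ebf = base.ebf_pbf + ebf_increase
    if new_ebf > 100.0 + 1e-9:
        raise ValidationError(
            f"uplift of {ebf_increase:g} points pushes ebf_pbf to "
            f"{new_ebf:g} > 100"
        )
    new_ebf = min(new_ebf, 100.0)
    remainder = 100.0 - new_ebf
    return FeedingPrevalence(
        ebf_pbf=new_ebf,
        partial=2.0 / 3.0 * remainder,
        non_bf=1.0 / 3.0 * remainder,
    )


def scale_coverage(
    scenario_result: FootprintResult, coverage: float, births: float
) -> CoverageResult:
    """Footprint of the covered subpopulation at the scenario's rates.

    Every footprint field is multiplied by ``coverage`` and the covered
    births are ``coverage × births``.  This reports what the covered
    subpopulation emits and consumes under the scenario — not the avoided
    amount relative to a baseline, for which see
    :func:`avoided_under_coverage`.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValidationError(f"coverage must be in (0, 1], got {coverage}")
    return CoverageResult(
        result=scenario_result.scaled(coverage),
        covered_births=coverage * births,
    )


def avoided_under_coverage(
    comparison: ScenarioComparison, coverage: float
) -> FootprintResult:
    """Signed difference attributable to the covered fraction of births.

    ``coverage × (counterfactual − baseline)`` fieldwise: the additionality
    achieved when the intervention reaches only part of the cohort.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValidationError(f"coverage must be in (0, 1], got {coverage}")
    return comparison.difference.scaled(coverage)


#: Prevalence of the all-formula-feeding extreme.
EXTINCTION_PREVALENCE = FeedingPrevalence(ebf_pbf=0.0, partial=0.0, non_bf=100.0)


def extinction(cohort: CohortSpec) -> CohortSpec:
    """The same population with breastfeeding entirely displaced by CMF.

    Returns a cohort with prevalence 0/0/100 (idempotent: an already
    fully-formula-fed cohort is returned unchanged).
    """
    if cohort.prevalence == EXTINCTION_PREVALENCE and cohort.bands is None:
        return cohort
    return cohort.with_prevalence(EXTINCTION_PREVALENCE)


# ---------------------------------------------------------------------------
# Structured scenario configuration
#
# A scenario mapping has the keys:
#   births:      annual live births (required unless inherited)
#   label:       free text (optional)
#   source:      survey provenance text (optional)
#   prevalence:  {ebf_pbf:, partial:[, non_bf:]}   -- direct entry, or
#   uplift:      percentage-point EBF+PBF increase applied to a base
#                prevalence (the baseline's, for counterfactual entries)
#   coverage:    fraction in (0, 1], default 1
#
# A comparison file has:
#   baseline:       scenario mapping (prevalence required)
#   counterfactual: scenario mapping (prevalence or uplift; births inherited)
#   coverages:      optional list of fractions for coverage sub-rows
#   diet:           optional {pattern: plant|mixed, mothers: count}
# ---------------------------------------------------------------------------


def _prevalence_from_mapping(m: Mapping[str, Any], label: str) -> FeedingPrevalence:
    if not isinstance(m, Mapping):
        raise ValidationError(f"{label}: prevalence must be a mapping, got {m!r}")
    unknown = set(m) - {"ebf_pbf", "partial", "non_bf"}
    if unknown:
        raise ValidationError(f"{label}: unknown prevalence keys {sorted(unknown)}")
    return normalize_prevalence(
        ebf_pbf=m.get("ebf_pbf"),
        partial=m.get("partial"),
        non_bf=m.get("non_bf"),
        label=label,
    )


def scenario_from_config(
    cfg: Mapping[str, Any],
    *,
    default_label: str = "scenario",
    base_prevalence: FeedingPrevalence | None = None,
    inherit_births: float | None = None,
) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from a configuration mapping.

    ``base_prevalence`` supplies the starting point for an ``uplift`` entry;
    ``inherit_births`` fills in ``births`` when the mapping omits it (the
    normal case for a counterfactual sharing the baseline's population).
    """
    if not isinstance(cfg, Mapping):
        raise ValidationError(f"scenario config must be a mapping, got {cfg!r}")
    label = str(cfg.get("label", default_label))
    births = cfg.get("births", inherit_births)
    if births is None:
        raise ValidationError(f"{label}: 'births' is required")

    has_prev = "prevalence" in cfg
    has_uplift = "uplift" in cfg
    if has_prev == has_uplift:
        raise ValidationError(
            f"{label}: exactly one of 'prevalence' or 'uplift' is required"
        )
    if has_prev:
        prevalence = _prevalence_from_mapping(cfg["prevalence"], label)
    else:
        if base_prevalence is None:
            raise ValidationError(
                f"{label}: 'uplift' needs a baseline prevalence to start from"
            )
        prevalence = apply_uplift(base_prevalence, float(cfg["uplift"]))

    cohort = CohortSpec(
        label=label,
        annual_births=float(births),
        prevalence=prevalence,
        source=str(cfg.get("source", "")),
    )
    return ScenarioSpec(
        cohort=cohort,
        description=str(cfg.get("description", "")),
        coverage=float(cfg.get("coverage", 1.0)),
    )


@dataclass(frozen=True)
class ComparisonConfig:
    """A parsed comparison file: scenarios, coverage list, diet add-on."""

    baseline: ScenarioSpec
    counterfactual: ScenarioSpec
    coverages: tuple[float, ...] = ()
    diet_pattern: str | None = None
    diet_mothers: float = 0.0


def load_comparison_config(source: str | Path | Mapping[str, Any]) -> ComparisonConfig:
    """Read a baseline/counterfactual definition from YAML or JSON.

    ``source`` may be a path or an already-parsed mapping (JSON files parse
    with the same loader, JSON being a YAML subset).
    """
    if isinstance(source, Mapping):
        cfg = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValidationError("comparison config must be a mapping")
    unknown = set(cfg) - {"baseline", "counterfactual", "coverages", "diet"}
    if unknown:
        raise ValidationError(f"unknown comparison keys {sorted(unknown)}")
    if "baseline" not in cfg or "counterfactual" not in cfg:
        raise ValidationError("comparison config needs 'baseline' and 'counterfactual'")

    baseline = scenario_from_config(cfg["baseline"], default_label="baseline")
    counterfactual = scenario_from_config(
        cfg["counterfactual"],
        default_label="counterfactual",
        base_prevalence=baseline.cohort.effective_prevalence,
        inherit_births=baseline.cohort.annual_births,
    )

    coverages = tuple(float(c) for c in cfg.get("coverages", ()))
    for c in coverages:
        if not 0.0 < c <= 1.0:
            raise ValidationError(f"coverage must be in (0, 1], got {c}")

    diet_pattern: str | None = None
    diet_mothers = 0.0
    if "diet" in cfg:
        diet = cfg["diet"]
        if not isinstance(diet, Mapping) or set(diet) - {"pattern", "mothers"}:
            raise ValidationError(
                "diet config must be a mapping with keys 'pattern' and 'mothers'"
            )
        diet_pattern = str(diet.get("pattern", ""))
        if diet_pattern not in DIET_PATTERNS:
            raise ValidationError(
                f"diet pattern must be one of {DIET_PATTERNS}, got {diet_pattern!r}"
            )
        diet_mothers = float(diet.get("mothers", 0.0))
        if diet_mothers < 0:
            raise ValidationError(f"diet mothers must be >= 0, got {diet_mothers}")

    return ComparisonConfig(
        baseline=baseline,
        counterfactual=counterfactual,
        coverages=coverages,
        diet_pattern=diet_pattern,
        diet_mothers=diet_mothers,
    )
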