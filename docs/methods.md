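# Methods

## Model

The accounting is a linear, closed-form model of one cohort of infants under
6 months. The cohort is described by annual live births `B` and a complete
partition of infants into three feeding categories: exclusively or
predominantly breastfed (EBF+PBF), partially breastfed, and non-breastfed.
All downstream quantities are products of `B`, per-category per-infant
constants, and the category shares:

| quantity | formula | units |
|---|---|---|
| CMF powder | `M = B (p_partial m_partial + p_non m_full) / 100` | kg/yr |
| GHG (low, high) | `M e_low`, `M e_high` | million kg CO₂e/yr |
| water | `M w_intensity` | million L/yr |
| lost milk | `B (p_non + α p_partial) v_milk / 100` | million L/yr |

Linearity is the central structural assumption: footprints are exactly
homogeneous in births, category contributions add, and the all-formula
("extinction") prevalence 0/0/100 maximizes every field. These properties
are enforced by the property-based tests.

### Assumptions

- **Births stand in for the under-6-month population.** Each annual birth
  cohort spends six months in the age window, and the per-infant masses are
  already six-month totals, so the full annual birth count multiplies them.
  This is deliberate — halving births does not reproduce any published
  tabulation of this accounting.
- **Exclusive and predominant breastfeeding are merged** and consume no
  formula. Partially breastfed infants take one third of their intake from
  formula. Infants receiving animal milk or other foods are still counted in
  their survey category.
- **Uniform age structure**: when age-band data (0–1, 2–3, 4–5 months) is
  supplied, the aggregate is the unweighted band mean; no band-specific
  formula volumes are modelled.

## Parameters

| name | default | units | provenance |
|---|---|---|---|
| `m_full` | 20 | kg powder / infant / 6 mo | UNHCR feeding protocol incl. stock waste |
| `m_partial` | 6.7 | kg powder / infant / 6 mo | one third of `m_full` |
| `e_low`, `e_high` | 11, 14 | kg CO₂e / kg powder | lifecycle-analysis bounds |
| `w_intensity` | 4,752.7 | L / kg powder | calibrated (see below) |
| `v_milk` | 45 | L / non-breastfed infant / 6 mo | calibrated (see below) |
| `alpha_partial` | 0.12 | — | calibrated (see below) |
| `diet_plant`, `diet_mixed` | 69, 218 | kg CO₂e / mother / 6 mo | dietary-study values |
| `miles_per_kg` | 19.3/7.5 | miles / kg CO₂e | quotient of published equivalence |
| `pool_volume` | 3,125,000 | L / pool | quotient of published equivalence |

**Calibrated constants.** Published country tabulations of this accounting
print their water and lost-milk outputs but not the operative constants.
`w_intensity` is back-derived as the extinction-scenario water volume
divided by its formula mass (12,488,803.0 × 10⁶ L ÷ 131,386,401 × 20 kg =
4,752.7 L/kg) and cross-validates against every other published water cell
to the printed digit; it lies inside the 4,700–7,430 L/kg total water
footprint literature range plus ~63 L/kg of preparation water, though it
matches no stated combination exactly. `v_milk` = 45 L follows the same way
from the extinction lost-milk cell under 100 % non-breastfeeding, and
`alpha_partial` = 0.12 validates against the remaining own-data lost-milk
cells. One published preloaded-data lost-milk figure (Indonesia, 96.1)
cannot be reproduced from aggregate prevalence with these constants; it
appears to use unpublished age-band survey detail, so the preloaded path is
out of scope here.

**Equivalence factors** are defined as the quotients of the published
headline pair (miles per kg CO₂e, liters per pool) rather than taken from
external converters, so rendered equivalents agree with the published
comparisons by construction. The upper GHG bound is the default basis for
the miles conversion, matching the published example.

## Numerical choices

- Percentages stay on the 0–100 scale throughout; division by 100 happens
  only inside the closed forms. Internal arithmetic is full-precision
  float64.
- Display rounding is half away from zero to one decimal, in millions,
  through a single shared routine (`round_half_up`); files written for
  machines carry full precision (`%.17g` CSV floats, round-trip parsing).
- A prevalence record must sum to 100 ± 0.1 points. A derived complement
  that is negative by at most 0.1 points (a 1-decimal survey rounding
  artefact) clamps to zero; a larger deficit raises — a typo should fail
  loudly, not be silently corrected.
- Differences are exact fieldwise deltas at full precision. Published
  difference rows occasionally subtract already-rounded row values (e.g. a
  GHG delta printed 3.9 where full precision gives 3.846); this package
  never does.
- Coverage scaling multiplies the *scenario* footprint by the covered
  fraction of births — the footprint of the covered subpopulation at
  scenario rates, which is how published coverage rows are constructed. The
  avoided amount relative to baseline is the separate
  `avoided_under_coverage` helper (coverage × difference).
- The uplift rule re-splits the whole non-(EBF+PBF) remainder 2:1 into
  partial and non-breastfed; it is a fixed point exactly on prevalences
  already in that ratio.
- Degenerate inputs: zero births yield an all-zero result; zero coverage is
  rejected (an intervention reaching nobody is a configuration error);
  unknown diet patterns, negative masses and out-of-range percentages raise
  `ValidationError`.

## Synthetic data

`generate_fixtures` emulates the shape of UNICEF-style infant-feeding
country tables: births log-uniform over 10⁴–3 × 10⁷ (small states to the
largest birth cohorts), category shares drawn Dirichlet(6, 3, 1) — mean
60/30/10 with realistic cross-country spread — rounded to the 1-decimal
precision of source surveys, and a configurable fraction of rows carrying
births but no prevalence, mirroring countries without suitable surveys.
Four published own-data cohorts (China 2018, Canada before/after 2008, the
all-LMIC extinction population) are embedded verbatim as known-answer rows.

What the generator does **not** emulate: correlation between births and
feeding practice, age-band structure, survey-year drift, or the actual
preloaded survey database — so passing tests demonstrate correct arithmetic
and IO on realistic shapes, not agreement with any real country's current
data.

## Limitations

- Children 6–36 months, follow-on formula and growing-up milks are excluded;
  in some markets they dominate total formula-related emissions.
- No fertility/child-spacing adjustment and no emissions charged to
  breastfeeding itself; the maternal-diet add-on is optional, user-sized and
  reported separately, never netted into a cohort footprint.
- No blue/green/grey water decomposition; one aggregate intensity.
- The calibrated constants inherit any error in the published tabulations
  they were derived from.
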