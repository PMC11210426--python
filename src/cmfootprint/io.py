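"""Country-table and result IO, plus the synthetic fixture generator.

Country tables are comma-separated UTF-8 text with a header row, one row per
country/survey, emulating the shape of UNICEF-style infant-and-young-child-
feeding country tabulations: identifier, name, survey provenance, annual
live births, and the feeding-category percentages.  Rows for countries that
collect no suitable survey data keep their birth counts but carry empty
prevalence cells ("no data"); they are retained and flagged, never dropped.

Numbers on input may use thousands separators ("11,501,936"); machine
output never emits them.
"""

from __future__ import annotations

import io as _io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    CohortSpec,
    FeedingPrevalence,
    FootprintResult,
    ScenarioComparison,
    ValidationError,
    normalize_prevalence,
)

__all__ = [
    "CountryRow",
    "CountryTable",
    "read_country_table",
    "write_country_table",
    "write_results",
    "read_results",
    "generate_fixtures",
    "REFERENCE_COHORTS",
    "COUNTRY_COLUMNS",
    "RESULT_COLUMNS",
]

#: Canonical column names of a country table, in file order.
COUNTRY_COLUMNS = (
    "country_id",
    "country_name",
    "source",
    "births",
    "ebf_pbf",
    "partial",
    "non_bf",
)
_REQUIRED_COLUMNS = COUNTRY_COLUMNS[:6]  # non_bf may be derived

#: Fixed column order of a results file: identification, inputs, then the
#: output columns in published-table order (lost milk, carbon low/high,
#: water), with the raw powder mass last.
RESULT_COLUMNS = (
    "label",
    "role",
    "births",
    "ebf_pbf",
    "partial",
    "non_bf",
    "lost_milk_million_l",
    "ghg_low_million_kg",
    "ghg_high_million_kg",
    "water_million_l",
    "cmf_kg",
)


@dataclass(frozen=True)
class CountryRow:
    """One validated row of a country table.

    Exactly one of three states: a usable cohort (``cohort`` set), a
    "no data" row (births known, prevalence absent), or an invalid row
    (``invalid_reason`` set) retained for diagnostics.
    """

    country_id: str
    country_name: str
    source: str = ""
    births: float | None = None
    prevalence: FeedingPrevalence | None = None
    invalid_reason: str | None = None

    @property
    def no_data(self) -> bool:
        return self.invalid_reason is None and self.prevalence is None

    @property
    def is_valid(self) -> bool:
        return self.invalid_reason is None and self.prevalence is not None

    def cohort(self) -> CohortSpec:
        if not self.is_valid:
            raise ValidationError(
                f"row {self.country_id!r} has no usable data "
                f"({self.invalid_reason or 'no prevalence data'})"
            )
        assert self.births is not None
        return CohortSpec(
            label=self.country_name or self.country_id,
            annual_births=self.births,
            prevalence=self.prevalence,
            source=self.source,
        )


@dataclass
class CountryTable:
    """A collection of country rows plus per-row diagnostics."""

    rows: list[CountryRow] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.country_id for r in self.rows]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(f"duplicate country ids: {dupes}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def get(self, country_id: str) -> CountryRow | None:
        for row in self.rows:
            if row.country_id == country_id:
                return row
        return None

    def valid_rows(self) -> list[CountryRow]:
        return [r for r in self.rows if r.is_valid]

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            p = r.prevalence
            records.append(
                {
                    "country_id": r.country_id,
                    "country_name": r.country_name,
                    "source": r.source,
                    "births": r.births,
                    "ebf_pbf": p.ebf_pbf if p else None,
                    "partial": p.partial if p else None,
                    "non_bf": p.non_bf if p else None,
                }
            )
        return pd.DataFrame.from_records(records, columns=list(COUNTRY_COLUMNS))


def _parse_number(text: Any) -> float | None:
    """Parse a cell that may carry thousands separators; None if empty."""
    if text is None:
        return None
    s = str(text).strip()
    if s == "" or s.lower() in {"nan", "na", "-", "–"}:
        return None
    try:
        return float(s.replace(",", "").replace(" ", ""))
    except ValueError:
        raise ValueError(f"unparseable number {text!r}") from None


def read_country_table(
    source: str | Path | _io.TextIOBase,
    column_map: Mapping[str, str] | None = None,
) -> CountryTable:
    """Read and validate a delimited country table.

    ``column_map`` maps canonical names (:data:`COUNTRY_COLUMNS`) to the
    header names actually present, for tables using a different vocabulary.
    A missing required column is a hard error; problems on individual rows
    (unparseable births, prevalence summing past 100, …) flag that row
    invalid with a reason and are collected in ``diagnostics`` rather than
    raised, so one bad row never aborts a batch run.
    """
    mapping = dict(zip(COUNTRY_COLUMNS, COUNTRY_COLUMNS))
    if column_map:
        mapping.update(column_map)

    df = pd.read_csv(source, dtype=str, keep_default_na=False, skipinitialspace=True)
    missing = [mapping[c] for c in _REQUIRED_COLUMNS if mapping[c] not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")

    rows: list[CountryRow] = []
    diagnostics: list[str] = []
    for idx, rec in df.iterrows():
        lineno = int(idx) + 2  # header is line 1
        country_id = str(rec[mapping["country_id"]]).strip()
        name = str(rec[mapping["country_name"]]).strip()
        src = str(rec[mapping["source"]]).strip()

        def _invalid(reason: str) -> CountryRow:
            diagnostics.append(f"line {lineno} ({country_id or '?'}): {reason}")
            return CountryRow(country_id, name, src, invalid_reason=reason)

        try:
            births = _parse_number(rec[mapping["births"]])
        except ValueError as exc:
            rows.append(_invalid(f"births: {exc}"))
            continue
        if births is None:
            rows.append(_invalid("births missing"))
            continue
        if births < 0:
            rows.append(_invalid(f"births {births:g} < 0"))
            continue

        try:
            ebf = _parse_number(rec[mapping["ebf_pbf"]])
            part = _parse_number(rec[mapping["partial"]])
            non_col = mapping["non_bf"]
            non = _parse_number(rec[non_col]) if non_col in df.columns else None
        except ValueError as exc:
            rows.append(_invalid(f"prevalence: {exc}"))
            continue

        supplied = sum(v is not None for v in (ebf, part, non))
        if supplied == 0:
            rows.append(CountryRow(country_id, name, src, births=births))
            continue
        if supplied < 2:
            rows.append(_invalid("prevalence incomplete: need at least two categories"))
            continue
        try:
            prevalence = normalize_prevalence(
                ebf_pbf=ebf, partial=part, non_bf=non, label=country_id
            )
        except ValidationError as exc:
            total = sum(v for v in (ebf, part, non) if v is not None)
            if total > 100.0:
                rows.append(_invalid(f"prevalence sum {total:g} > 100"))
            else:
                rows.append(_invalid(str(exc)))
            continue
        rows.append(
            CountryRow(country_id, name, src, births=births, prevalence=prevalence)
        )

    return CountryTable(rows=rows, diagnostics=diagnostics)


def write_country_table(table: CountryTable, path_or_buf) -> None:
    """Write a country table as canonical CSV (empty cells for "no data")."""
    table.to_dataframe().to_csv(path_or_buf, index=False)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


def _result_record(
    label: str,
    role: str,
    result: FootprintResult,
    births: float | None = None,
    prevalence: FeedingPrevalence | None = None,
) -> dict[str, Any]:
    return {
        "label": label,
        "role": role,
        "births": births,
        "ebf_pbf": prevalence.ebf_pbf if prevalence else None,
        "partial": prevalence.partial if prevalence else None,
        "non_bf": prevalence.non_bf if prevalence else None,
        "lost_milk_million_l": result.lost_milk,
        "ghg_low_million_kg": result.ghg_low,
        "ghg_high_million_kg": result.ghg_high,
        "water_million_l": result.water,
        "cmf_kg": result.cmf_kg,
    }


def write_results(
    results: Sequence[tuple],
    path_or_buf,
    fmt: str = "csv",
) -> None:
    """Write labelled results to ``path_or_buf`` in ``fmt`` (csv or json).

    ``results`` is a nonempty sequence of tuples: either
    ``(label, FootprintResult)`` / ``(label, ScenarioComparison)`` or the
    richer ``(label, result, births, prevalence)`` carrying the input
    columns.  A comparison expands into baseline/counterfactual/difference
    rows.  Numeric fields are written at full precision, so parsing the
    output recovers them exactly; display rounding belongs to the report
    renderer, not to files.
    """
    if not results:
        raise ValidationError("nothing to write: results list is empty")

    records: list[dict[str, Any]] = []
    for item in results:
        label, result = item[0], item[1]
        births = item[2] if len(item) > 2 else None
        prevalence = item[3] if len(item) > 3 else None
        if isinstance(result, ScenarioComparison):
            records.append(
                _result_record(label, "baseline", result.baseline, births, prevalence)
            )
            records.append(
                _result_record(label, "counterfactual", result.counterfactual, births)
            )
            records.append(_result_record(label, "difference", result.difference))
        elif isinstance(result, FootprintResult):
            records.append(_result_record(label, "result", result, births, prevalence))
        else:
            raise ValidationError(
                f"cannot write result of type {type(result).__name__}"
            )

    df = pd.DataFrame.from_records(records, columns=list(RESULT_COLUMNS))
    if fmt == "csv":
        # 17 significant digits guarantee an exact float round trip
        df.to_csv(path_or_buf, index=False, float_format="%.17g")
    elif fmt == "json":
        payload = df.where(df.notna(), None).to_dict(orient="records")
        text = json.dumps(payload, indent=2)
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text + "\n")
        else:
            Path(path_or_buf).write_text(text + "\n", encoding="utf-8")
    else:
        raise ValidationError(f"unknown results format {fmt!r}")


def read_results(source, fmt: str = "csv") -> pd.DataFrame:
    """Read a results file back into a DataFrame (round-trip of write_results)."""
    if fmt == "csv":
        return pd.read_csv(source, float_precision="round_trip")
    if fmt == "json":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            payload = json.loads(Path(source).read_text(encoding="utf-8"))
        return pd.DataFrame.from_records(payload, columns=list(RESULT_COLUMNS))
    raise ValidationError(f"unknown results format {fmt!r}")


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

#: Known-answer cohorts from published own-data tabulations, embedded
#: verbatim in every fixture table so downstream code always has rows with
#: externally checkable footprints.
REFERENCE_COHORTS: tuple[CountryRow, ...] = (
    CountryRow(
        "CHN-2018", "China", "national survey 2018",
        births=11_501_936,
        prevalence=normalize_prevalence(ebf_pbf=61.3, partial=32.2),
    ),
    CountryRow(
        "CAN-PRE", "Canada (before 2008)", "maternity-leave study, pre-policy",
        births=373_864,
        prevalence=normalize_prevalence(ebf_pbf=23.1, partial=51.3),
    ),
    CountryRow(
        "CAN-POST", "Canada (after 2008)", "maternity-leave study, post-policy",
        births=373_864,
        prevalence=normalize_prevalence(ebf_pbf=31.5, partial=45.7),
    ),
    CountryRow(
        "LMIC-EXT", "All LMICs (extinction)", "hypothetical all-formula scenario",
        births=131_386_401,
        prevalence=FeedingPrevalence(0.0, 0.0, 100.0),
    ),
)

#: Dirichlet concentration for synthetic prevalence draws.  Mean shares
#: 60/30/10 (EBF+PBF / partial / non-breastfed) with realistic survey-to-
#: survey spread, roughly matching the mix seen across LMIC tabulations.
_DIRICHLET_ALPHA = (6.0, 3.0, 1.0)


def _round_shares(shares: np.ndarray) -> tuple[float, float, float]:
    """Round shares to 1 decimal while keeping the sum exactly 100."""
    rounded = np.round(shares, 1)
    residual = 100.0 - rounded.sum()
    rounded[int(np.argmax(rounded))] += residual
    return tuple(float(np.round(v, 1)) for v in rounded)


def generate_fixtures(
    n_countries: int,
    seed: int,
    no_data_fraction: float = 0.1,
) -> CountryTable:
    """Generate a deterministic synthetic country table.

    Emits the four reference cohorts first, then ``n_countries`` synthetic
    rows: births log-uniform in [10⁴, 3 × 10⁷], prevalence drawn
    Dirichlet(6, 3, 1) and rounded to 1 decimal (renormalized to sum to
    exactly 100), and a ``no_data_fraction`` share of rows carrying births
    but no prevalence, mirroring countries without suitable surveys.
    A pure function of its arguments: the same seed yields the same table.
    """
    if n_countries < 1:
        raise ValidationError(f"n_countries must be >= 1, got {n_countries}")
    if not 0.0 <= no_data_fraction < 1.0:
        raise ValidationError(
            f"no_data_fraction must be in [0, 1), got {no_data_fraction}"
        )
    rng = np.random.default_rng(seed)
    rows = list(REFERENCE_COHORTS)
    for i in range(n_countries):
        births = float(np.round(10 ** rng.uniform(4.0, math.log10(3e7))))
        country_id = f"SYN-{i + 1:03d}"
        name = f"Synthetic country {i + 1}"
        src = f"synthetic fixture seed={seed}"
        if rng.random() < no_data_fraction:
            rows.append(CountryRow(country_id, name, src, births=births))
            continue
        ebf, part, non = _round_shares(rng.dirichlet(_DIRICHLET_ALPHA) * 100.0)
        rows.append(
            CountryRow(
                country_id, name, src,
                births=births,
                prevalence=FeedingPrevalence(ebf, part, non),
            )
        )
    return CountryTable(rows=rows)
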