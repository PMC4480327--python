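"""Data model, I/O and aggregation for the weed-traits database.

Records are kept in a long ("tidy") layout: one row per (species,
field_code, value) observation, with provenance metadata.  Multiple
records per species/field are the norm — aggregation to species-level
summaries is explicit via :func:`summarize_species`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, InfeasibleError, ValidationError

# ---------------------------------------------------------------------------
# Field-code vocabulary

FIELD_CODES: frozenset[str] = frozenset(
    ["GERMBASE", "GERMCHILL", "GERMLIGHT", "COMPHEIGHT", "SEEDWEIGHT", "SEEDCOAT"]
    + [f"EMCAL_{m}" for m in range(1, 13)]
    + [f"EMTOT_{k}" for k in (1, 2)]
    + [f"COMPHYP_{k}" for k in (1, 2)]
    + [f"PHENJUV_{k}" for k in (1, 2, 3, 4)]
    + [f"FECUNDITY_{k}" for k in (1, 2)]
    + [f"PHENFLO_{k}" for k in (1, 2, 3, 4)]
    + [f"PHENMAT_{k}" for k in (1, 2, 3, 4)]
    + [f"SEEDPER_{k}" for k in (1, 2)]
    + [f"EMDEPTH_{k}" for k in (1, 2)]
)

#: Codes whose value is a category token rather than a number.
CATEGORICAL_CODES: frozenset[str] = frozenset({"GERMCHILL", "GERMLIGHT"})
CATEGORY_LEVELS: frozenset[str] = frozenset({"absolute", "partial", "none"})

#: Codes whose numeric value must be strictly positive.
_POSITIVE_PREFIXES = ("SEEDWEIGHT", "COMPHEIGHT", "EMDEPTH_", "SEEDPER_")

SOURCE_QUALITIES: frozenset[str] = frozenset(
    {"peer_reviewed", "conference", "report", "unpublished", "expert_opinion"}
)

#: Conventional units per field code (used by generators and exports).
UNITS: dict[str, str] = {
    "GERMBASE": "degC",
    "GERMCHILL": "category",
    "GERMLIGHT": "category",
    "COMPHEIGHT": "cm",
    "SEEDWEIGHT": "mg",
    "SEEDCOAT": "%",
    "COMPHYP_1": "% yield loss per plant m-2",
    "COMPHYP_2": "%",
    "FECUNDITY_1": "dimensionless",
    "FECUNDITY_2": "ln(seeds per g)",
    "EMTOT_1": "%",
    "EMTOT_2": "%",
    "SEEDPER_1": "years",
    "SEEDPER_2": "years",
    "EMDEPTH_1": "cm",
    "EMDEPTH_2": "cm",
}
UNITS.update({f"EMCAL_{m}": "%" for m in range(1, 13)})
for _grp in ("PHENJUV", "PHENFLO", "PHENMAT"):
    UNITS.update({f"{_grp}_{k}": "days or day-degrees" for k in (1, 2, 3, 4)})


def _is_positive_code(code: str) -> bool:
    return any(
        code == p or (p.endswith("_") and code.startswith(p)) for p in _POSITIVE_PREFIXES
    )


# ---------------------------------------------------------------------------
# Records


@dataclass
class TraitRecord:
    """One observation of one trait/parameter for one species."""

    species: str
    field_code: str
    value: Union[float, str]
    units: str = ""
    source_quality: str = "unpublished"
    crop: Optional[str] = None
    location: Optional[str] = None
    disturbed: Optional[bool] = None
    notes: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.species or not str(self.species).strip():
            raise ValidationError("species name must be non-empty")
        self.species = str(self.species).strip()
        code = str(self.field_code).strip()
        if code not in FIELD_CODES:
            raise ValidationError(
                f"unknown field_code {code!r}; legal codes: {sorted(FIELD_CODES)}"
            )
        self.field_code = code
        if self.source_quality not in SOURCE_QUALITIES:
            raise ValidationError(
                f"unknown source_quality {self.source_quality!r}; "
                f"expected one of {sorted(SOURCE_QUALITIES)}"
            )
        if code in CATEGORICAL_CODES:
            token = str(self.value).strip().lower()
            if token not in CATEGORY_LEVELS:
                raise ValidationError(
                    f"{code} takes a category in {sorted(CATEGORY_LEVELS)}, got {self.value!r}"
                )
            self.value = token
        else:
            try:
                self.value = float(self.value)
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{code} requires a numeric value, got {self.value!r}"
                ) from exc
            if not math.isfinite(self.value):
                raise ValidationError(f"{code} value must be finite")
            if _is_positive_code(code) and self.value <= 0:
                raise ValidationError(
                    f"{code} must be strictly positive, got {self.value}"
                )

    @property
    def is_categorical(self) -> bool:
        return self.field_code in CATEGORICAL_CODES


_COLUMNS = [f.name for f in dc_fields(TraitRecord)]
_MANDATORY = ["species", "field_code", "value", "units", "source_quality"]

#: Source-identity key for grouping multi-row entries (e.g. emergence calendars).
_SOURCE_KEY = ("species", "source_quality", "crop", "location")


def validate_emcal_sums(records: Sequence[TraitRecord], tol: float = 0.5) -> None:
    """Check that monthly emergence-calendar percentages total 100 per source.

    Records are grouped by (species, source_quality, crop, location); every
    group containing EMCAL rows must have its 12-month sum within ``tol`` of
    100.  Raises :class:`ValidationError` naming the offending group.
    """
    groups: dict[tuple, float] = {}
    for r in records:
        if r.field_code.startswith("EMCAL_"):
            key = tuple(getattr(r, k) for k in _SOURCE_KEY)
            groups[key] = groups.get(key, 0.0) + float(r.value)
    bad = {k: s for k, s in groups.items() if abs(s - 100.0) > tol}
    if bad:
        msgs = ", ".join(f"{k[0]} ({k[1]}): sum={s:.2f}" for k, s in bad.items())
        raise ValidationError(f"EMCAL percentages must sum to 100 +/- {tol}: {msgs}")


def read_trait_table(path) -> list[TraitRecord]:
    """Read a long-format trait table (CSV, UTF-8, header mandatory).

    Every row becomes a validated :class:`TraitRecord`.  Invalid rows are
    collected and reported together in a single :class:`ValidationError`
    carrying 1-based data-row numbers.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")

    records: list[TraitRecord] = []
    problems: list[str] = []
    for idx, row in frame.iterrows():
        kwargs = {}
        for col in _COLUMNS:
            if col in frame.columns:
                raw = row[col]
                kwargs[col] = None if raw == "" else raw
        if kwargs.get("disturbed") is not None:
            kwargs["disturbed"] = str(kwargs["disturbed"]).strip().lower() in (
                "true", "1", "yes",
            )
        kwargs["units"] = kwargs.get("units") or ""
        kwargs["source_quality"] = kwargs.get("source_quality") or "unpublished"
        try:
            records.append(TraitRecord(**kwargs))
        except ValidationError as exc:
            problems.append(f"row {idx + 1}: {exc}")
    if problems:
        raise ValidationError(
            f"{path}: {len(problems)} invalid row(s):\n" + "\n".join(problems)
        )
    validate_emcal_sums(records)
    return records


def write_trait_table(records: Iterable[TraitRecord], path) -> None:
    """Write records to CSV such that :func:`read_trait_table` round-trips."""
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in _COLUMNS}
        rows.append(d)
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    frame.to_csv(path, index=False, encoding="utf-8")


def records_to_frame(records: Iterable[TraitRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in _COLUMNS} for r in records])


# ---------------------------------------------------------------------------
# Aggregation


@dataclass
class SpeciesTraitSummary:
    """Per-(species, field) aggregate over all database records."""

    species: str
    field_code: str
    n_records: int
    mean: Optional[float] = None
    median: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None
    variability_pct: Optional[float] = None  # 100 * max / min, when min > 0
    modal_category: Optional[str] = None
    basis: str = "raw"  # "raw" for full records, "endpoint-only" for range fixtures

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValidationError("summary needs at least one record")
        if self.min is not None and self.max is not None:
            if not (self.min <= (self.median if self.median is not None else self.max) <= self.max):
                raise ValidationError("expected min <= median <= max")


ENDPOINT_TAG = "endpoint-only"


def summarize_species(records: Sequence[TraitRecord]) -> list[SpeciesTraitSummary]:
    """One summary per (species, field_code).

    Numeric fields carry mean/median/min/max and ``variability_pct``
    (maximum as a percentage of the minimum, defined when min > 0).
    Categorical fields carry the modal category and no numeric stats.
    Summaries computed from endpoint-tagged records (published min/max
    ranges rather than raw observations) are labelled ``endpoint-only``.
    """
    if not records:
        raise ValidationError("summarize_species requires at least one record")
    out: list[SpeciesTraitSummary] = []
    by_key: dict[tuple[str, str], list[TraitRecord]] = {}
    for r in records:
        by_key.setdefault((r.species, r.field_code), []).append(r)
    for (species, code), recs in sorted(by_key.items()):
        basis = (
            ENDPOINT_TAG
            if all(r.notes and ENDPOINT_TAG in r.notes for r in recs)
            else "raw"
        )
        if code in CATEGORICAL_CODES:
            modal, _ = Counter(str(r.value) for r in recs).most_common(1)[0]
            out.append(
                SpeciesTraitSummary(
                    species=species, field_code=code, n_records=len(recs),
                    modal_category=modal, basis=basis,
                )
            )
            continue
        vals = np.asarray([float(r.value) for r in recs], dtype=float)
        vmin, vmax = float(vals.min()), float(vals.max())
        out.append(
            SpeciesTraitSummary(
                species=species,
                field_code=code,
                n_records=len(recs),
                mean=float(vals.mean()),
                median=float(np.median(vals)),
                min=vmin,
                max=vmax,
                variability_pct=(100.0 * vmax / vmin) if vmin > 0 else None,
                basis=basis,
            )
        )
    return out


#: fields aggregated by median (right-skewed distributions); all others by mean
_MEDIAN_FIELDS = ("EMTOT_", "SEEDPER_")


def species_value_table(
    summaries: Sequence[SpeciesTraitSummary], fields: Sequence[str]
) -> pd.DataFrame:
    """Species x field table of model-input values.

    Uses the mean per species, except EMTOT/SEEDPER fields which use the
    median (their across-source distributions are strongly right-skewed).
    """
    tbl = pd.DataFrame(index=sorted({s.species for s in summaries}),
                       columns=list(fields), dtype=float)
    for s in summaries:
        if s.field_code in fields and s.mean is not None:
            use_median = any(s.field_code.startswith(p) for p in _MEDIAN_FIELDS)
            tbl.loc[s.species, s.field_code] = s.median if use_median else s.mean
    return tbl


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations over species-level values.

    ``status`` distinguishes computed pairs ("ok") from pairs with fewer
    than three shared species ("insufficient_n") and degenerate pairs
    ("zero_variance"); flagged pairs carry NaN in ``r`` by construction,
    never by silent propagation.
    """

    fields: list[str]
    r: pd.DataFrame
    n: pd.DataFrame
    status: pd.DataFrame


def correlation_matrix(
    summaries: Sequence[SpeciesTraitSummary],
    fields: Sequence[str],
    extra_columns: Optional[pd.DataFrame] = None,
) -> CorrelationResult:
    """Correlation matrix of species-level trait/parameter values.

    ``extra_columns`` allows derived per-species quantities (e.g. the
    density for 5% yield loss computed from the hyperbola parameters) to
    join the matrix alongside raw database fields.
    """
    tbl = species_value_table(summaries, [f for f in fields if f in FIELD_CODES])
    if extra_columns is not None:
        tbl = tbl.join(extra_columns, how="outer")
    cols = [f for f in fields if f in tbl.columns]
    k = len(cols)
    r = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=cols, columns=cols)
    status = pd.DataFrame([["ok"] * k for _ in range(k)], index=cols, columns=cols)
    for a_i, a in enumerate(cols):
        for b in cols[a_i:]:
            shared = tbl[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(shared)
            if a == b:
                r.loc[a, b] = 1.0
                if len(shared) == 0:
                    status.loc[a, b] = "insufficient_n"
                    r.loc[a, b] = np.nan
                continue
            if len(shared) < 3:
                status.loc[a, b] = status.loc[b, a] = "insufficient_n"
                continue
            xa = shared[a].to_numpy(dtype=float)
            xb = shared[b].to_numpy(dtype=float)
            if np.ptp(xa) == 0.0 or np.ptp(xb) == 0.0:
                status.loc[a, b] = status.loc[b, a] = "zero_variance"
                continue
            val = float(np.corrcoef(xa, xb)[0, 1])
            r.loc[a, b] = r.loc[b, a] = val
    return CorrelationResult(fields=cols, r=r, n=n, status=status)


# ---------------------------------------------------------------------------
# Hyperbolic yield-loss helpers


def cousens_yield_loss(density: float, i: float, m: float) -> float:
    """Percent yield loss at ``density`` plants m^-2: i*D / (1 + i*D/m)."""
    if density < 0:
        raise DomainError("density must be >= 0")
    if i <= 0 or m <= 0:
        raise DomainError("i and m must be > 0")
    return i * density / (1.0 + i * density / m)


def d5_from_comphyp(i: float, m: float) -> float:
    """Weed density (plants m^-2) producing exactly 5% yield loss.

    Inverts the rectangular hyperbola at 5%: D = 5 / (i * (1 - 5/m)).
    A 5% loss is unreachable when the asymptote m is at or below 5%.
    """
    if i <= 0:
        raise DomainError(f"i must be > 0, got {i}")
    if m <= 5.0:
        raise InfeasibleError(
            f"maximum yield loss m={m} <= 5%: a 5% loss is unreachable"
        )
    return 5.0 / (i * (1.0 - 5.0 / m))


def d5_table(summaries: Sequence[SpeciesTraitSummary]) -> pd.DataFrame:
    """Per-species D5% computed from mean COMPHYP_1 (i) and COMPHYP_2 (m).

    Species lacking either parameter, or with infeasible m <= 5, are omitted.
    Returned as a one-column frame ("D5") suitable for ``extra_columns``.
    """
    tbl = species_value_table(summaries, ["COMPHYP_1", "COMPHYP_2"])
    vals = {}
    for sp, row in tbl.iterrows():
        i, m = row.get("COMPHYP_1"), row.get("COMPHYP_2")
        if pd.notna(i) and pd.notna(m) and i > 0 and m > 5.0:
            vals[sp] = d5_from_comphyp(float(i), float(m))
    return pd.DataFrame({"D5": pd.Series(vals, dtype=float)})
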