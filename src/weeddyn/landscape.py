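"""Fitness landscapes over trait space and species viability projection.

``sweep`` evaluates the single-season growth rate lambda at every node of
a (height x seed weight) grid for one management scenario; contour
extraction (marching squares) locates the lambda = 1 boundary between
predicted population growth and decline.  Real or virtual species are
projected at their *exact* trait values — the grid exists only for
contours — and classified viable when lambda meets the threshold.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .errors import DomainError, FormatError, ValidationError
from .lifecycle import (
    LifecycleParams,
    Scenario,
    VirtualWeed,
    run_lifecycle,
)
from .relationships import HEIGHT_DOMAIN, ModelSet, SEED_WEIGHT_DOMAIN


@dataclass
class TraitGrid:
    """Ordered axes of the sweep: heights (cm) and seed weights (mg)."""

    heights: np.ndarray
    seed_weights: np.ndarray

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        self.seed_weights = np.asarray(self.seed_weights, dtype=float)
        for name, ax in (("heights", self.heights), ("seed_weights", self.seed_weights)):
            if ax.ndim != 1 or len(ax) < 2:
                raise DomainError(f"{name} must be 1-D with >= 2 values")
            if np.any(np.diff(ax) <= 0):
                raise DomainError(f"{name} must be strictly increasing")
            if np.any(ax <= 0):
                raise DomainError(f"{name} must be positive")

    @classmethod
    def default(cls) -> "TraitGrid":
        """10–200 cm in 10 cm steps x 0.01–20 mg in 0.01 mg steps (20 x 2000)."""
        heights = np.arange(10.0, 200.0 + 1e-9, 10.0)
        seed_weights = np.round(np.arange(1, 2001) * 0.01, 2)
        return cls(heights=heights, seed_weights=seed_weights)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.heights), len(self.seed_weights)


@dataclass
class FitnessSurface:
    """lambda over the grid for one scenario; rows = heights, cols = seed weights."""

    grid: TraitGrid
    scenario: Scenario
    lambda_values: np.ndarray

    def __post_init__(self) -> None:
        self.lambda_values = np.asarray(self.lambda_values, dtype=float)
        if self.lambda_values.shape != self.grid.shape:
            raise DomainError(
                f"lambda matrix shape {self.lambda_values.shape} != grid {self.grid.shape}"
            )
        if np.any(self.lambda_values <= 0):
            raise ValidationError("lambda must be strictly positive everywhere")


def sweep(
    grid: TraitGrid,
    scenario: Scenario,
    params: LifecycleParams,
    models: ModelSet,
) -> FitnessSurface:
    """Run the life cycle at every grid node. Deterministic."""
    lam = np.empty(grid.shape, dtype=float)
    for hi, h in enumerate(grid.heights):
        for si, sw in enumerate(grid.seed_weights):
            lam[hi, si] = run_lifecycle(
                VirtualWeed(float(h), float(sw)), scenario, params, models
            ).lam
    return FitnessSurface(grid=grid, scenario=scenario, lambda_values=lam)


# ---------------------------------------------------------------------------
# Export


def export_surface(surface: FitnessSurface, path) -> None:
    """Delimited matrix: first row the seed-weight axis, first column heights."""
    frame = pd.DataFrame(
        surface.lambda_values,
        index=pd.Index(surface.grid.heights, name="height_cm"),
        columns=surface.grid.seed_weights,
    )
    frame.to_csv(path, float_format="%.12g", encoding="utf-8")


def read_surface(path, scenario: Scenario) -> FitnessSurface:
    """Inverse of :func:`export_surface`."""
    frame = pd.read_csv(path, index_col=0, encoding="utf-8")
    grid = TraitGrid(
        heights=frame.index.to_numpy(dtype=float),
        seed_weights=np.asarray([float(c) for c in frame.columns]),
    )
    return FitnessSurface(grid=grid, scenario=scenario,
                          lambda_values=frame.to_numpy(dtype=float))


def extract_contours(
    surface: FitnessSurface, level: float
) -> list[np.ndarray]:
    """Marching-squares contours of lambda at ``level``.

    Returns a list of (n, 2) arrays with columns (height_cm,
    seed_weight_mg); fractional grid indices are mapped onto the axes by
    linear interpolation.  Constant surfaces yield an empty list.
    """
    curves = measure.find_contours(surface.lambda_values, level)
    out = []
    h_idx = np.arange(len(surface.grid.heights))
    s_idx = np.arange(len(surface.grid.seed_weights))
    for c in curves:
        heights = np.interp(c[:, 0], h_idx, surface.grid.heights)
        sws = np.interp(c[:, 1], s_idx, surface.grid.seed_weights)
        out.append(np.column_stack([heights, sws]))
    return out


def export_contours(
    surface: FitnessSurface, levels: Sequence[float] = (1.0,), path=None
) -> None:
    """Write contour polylines as (level, contour, vertex, height, seed weight)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["level", "contour_id", "vertex", "height_cm", "seed_weight_mg"])
        for level in levels:
            for cid, curve in enumerate(extract_contours(surface, level)):
                for vid, (h, sw) in enumerate(curve):
                    writer.writerow([level, cid, vid, f"{h:.6f}", f"{sw:.6f}"])


# ---------------------------------------------------------------------------
# Species projection


VALID_STATUSES = ("common", "rare_declining")


@dataclass
class SpeciesRecord:
    name: str
    height: float
    seed_weight: float
    status: str

    def __post_init__(self) -> None:
        if self.height <= 0 or self.seed_weight <= 0:
            raise ValidationError(f"{self.name}: traits must be positive")
        if self.status not in VALID_STATUSES:
            raise ValidationError(
                f"{self.name}: status must be one of {VALID_STATUSES}, got {self.status!r}"
            )


def read_species_table(path) -> tuple[list[SpeciesRecord], list[str]]:
    """Read a species list (columns name, height_cm, seed_weight_mg, status).

    Rows with missing or invalid trait values are skipped with a warning
    and returned as diagnostics (second element) so callers can report a
    warning count; the reader itself does not fail on bad rows.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    required = ["name", "height_cm", "seed_weight_mg", "status"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    records: list[SpeciesRecord] = []
    skipped: list[str] = []
    for idx, row in frame.iterrows():
        try:
            records.append(
                SpeciesRecord(
                    name=row["name"].strip(),
                    height=float(row["height_cm"]),
                    seed_weight=float(row["seed_weight_mg"]),
                    status=row["status"].strip(),
                )
            )
        except (ValueError, ValidationError) as exc:
            msg = f"row {idx + 1} ({row.get('name', '?')!r}): {exc}"
            skipped.append(msg)
            warnings.warn(f"{path}: skipping {msg}")
    return records, skipped


@dataclass
class SpeciesProjection:
    """Per-species lambda and viability call under each scenario."""

    species: SpeciesRecord
    lambdas: dict[str, float] = field(default_factory=dict)
    viable: dict[str, bool] = field(default_factory=dict)
    clamped: bool = False


def project_species(
    species: Iterable[SpeciesRecord],
    scenarios: Iterable[Scenario],
    params: LifecycleParams,
    models: ModelSet,
    threshold: float = 1.0,
    strict: bool = False,
) -> list[SpeciesProjection]:
    """Run the life cycle at each species' exact trait values.

    Trait values outside the fitted sweep domain are clamped (and the
    projection flagged).  Viability uses lambda >= threshold by default;
    ``strict=True`` switches to a strict inequality.
    """
    scenarios = list(scenarios)
    out: list[SpeciesProjection] = []
    for sp in species:
        h = min(max(sp.height, HEIGHT_DOMAIN[0]), HEIGHT_DOMAIN[1])
        sw = min(max(sp.seed_weight, SEED_WEIGHT_DOMAIN[0]), SEED_WEIGHT_DOMAIN[1])
        clamped = (h, sw) != (sp.height, sp.seed_weight)
        if clamped:
            warnings.warn(
                f"{sp.name}: traits ({sp.height:g} cm, {sp.seed_weight:g} mg) "
                f"clamped to the sweep domain ({h:g} cm, {sw:g} mg)"
            )
        proj = SpeciesProjection(species=sp, clamped=clamped)
        weed = VirtualWeed(h, sw)
        for sc in scenarios:
            lam = run_lifecycle(weed, sc, params, models, clamp=True).lam
            proj.lambdas[sc.name] = lam
            proj.viable[sc.name] = (lam > threshold) if strict else (lam >= threshold)
        out.append(proj)
    return out


def projections_to_frame(projections: Sequence[SpeciesProjection]) -> pd.DataFrame:
    rows = []
    for p in projections:
        row = {
            "name": p.species.name,
            "height_cm": p.species.height,
            "seed_weight_mg": p.species.seed_weight,
            "status": p.species.status,
            "clamped": p.clamped,
        }
        for name, lam in p.lambdas.items():
            row[f"lambda_{name}"] = lam
            row[f"viable_{name}"] = p.viable[name]
        rows.append(row)
    return pd.DataFrame(rows)


def viability_summary(
    projections: Sequence[SpeciesProjection], scenario_name: str
) -> dict[str, dict]:
    """Counts and integer percentages of viable species per status group.

    percent = round(100 * n_viable / n); None for empty groups.
    """
    if not projections:
        raise ValidationError("viability_summary requires at least one projection")
    groups: dict[str, dict] = {}
    for status in VALID_STATUSES:
        members = [p for p in projections if p.species.status == status]
        n = len(members)
        n_viable = sum(1 for p in members if p.viable.get(scenario_name, False))
        groups[status] = {
            "n": n,
            "n_viable": n_viable,
            "percent": int(round(100.0 * n_viable / n)) if n else None,
        }
    return groups
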