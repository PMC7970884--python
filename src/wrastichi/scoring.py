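"""WRASTIC criterion scoring, the WRASTIC-HI composite, and the three-level
degradation classification.

Each of the seven watershed-pressure criteria — Wastewater (W),
Recreational (R), Agricultural (A), Size of watershed (S), Transportation
(T), Industrial (I) and vegetative Cover (C) — is scored on an integer
scale n from its raw basin metric and carries a weight p; the weights sum
to 1.  The composite index multiplies the weighted criterion sum by the
basin Hazard Index::

    WRASTIC-HI = (Wn*Wp + Rn*Rp + An*Ap + Sn*Sp + Tn*Tp + In*Ip + Cn*Cp)
                 * (Sn + En + Pn)

The higher the value, the higher the degradation level; lakes are divided
into natural, semi-degraded and degraded classes by two thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import box

from .config import CRITERION_METRIC, LETTERS, WrasticConfig
from .geodata_io import zonal_fraction
from .grid import FeatureLayer, Grid
from .hazard import ReclassTable

__all__ = [
    "CriterionScore",
    "BasinAttributes",
    "LakeAssessment",
    "basin_polygon",
    "derive_basin_attributes",
    "score_criterion",
    "wrastic_weighted_sum",
    "wrastic_hi",
    "classify",
    "assess_lake",
]

CLASS_NAMES = ("natural", "semi_degraded", "degraded")


@dataclass(frozen=True)
class CriterionScore:
    letter: str       # one of W R A S T I C
    raw: float        # criterion-specific units: counts, fractions, km2, km
    n: int            # banded integer score
    p: float          # weight in [0, 1]


@dataclass
class BasinAttributes:
    """Per-lake aggregation of the pressure metrics feeding the criteria."""

    lake_id: int
    basin_area_km2: float
    frac_agricultural: float = 0.0
    frac_irrigated: float = 0.0
    frac_vegetated_cover: float = 0.0
    frac_recreational: float = 0.0
    n_industrial_sites: int = 0
    n_wastewater_discharges: int = 0
    treatment_level: str = "secondary"        # none | primary | secondary
    transport_length_km: float = 0.0
    population_density: float = 0.0
    pop_without_sewage: float = 0.0
    frac_protected: float = 0.0
    frac_natura2000: float = 0.0

    def __post_init__(self) -> None:
        if not self.basin_area_km2 > 0:
            raise ValueError("basin_area_km2 must be > 0")
        for name in ("frac_agricultural", "frac_irrigated", "frac_vegetated_cover",
                     "frac_recreational", "frac_protected", "frac_natura2000"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class LakeAssessment:
    lake_id: int
    scores: dict[str, CriterionScore]
    weighted_sum: float
    hi_basin: float
    wrastic_hi: float
    degradation_class: str = ""


def basin_polygon(basin_mask: Grid) -> shapely.Geometry:
    """Union of the basin's cell squares as one polygon (map coordinates)."""
    rows, cols = np.nonzero(basin_mask.values.astype(bool) & basin_mask.valid_mask())
    if rows.size == 0:
        raise ValueError("basin mask has zero cells")
    cs = basin_mask.cell_size
    cells = [
        box(basin_mask.origin_x + c * cs, basin_mask.origin_y - (r + 1) * cs,
            basin_mask.origin_x + (c + 1) * cs, basin_mask.origin_y - r * cs)
        for r, c in zip(rows, cols)
    ]
    return shapely.unary_union(cells)


def derive_basin_attributes(
    landuse: Grid,
    basin_mask: Grid,
    facilities: FeatureLayer,
    routes: FeatureLayer,
    config: WrasticConfig,
    lake_id: int = 1,
    **extra: float,
) -> BasinAttributes:
    """Aggregate one basin's pressure metrics from the layers.

    Land-use fractions come from zonal statistics over the configured
    category codes; facility counts from point-in-basin tests against the
    mask; transport length from clipping the route polylines to the basin
    polygon; the area from cell count times cell size squared.  Extra
    keyword metrics (population density etc.) pass through unchanged.
    """
    landuse.require_aligned(basin_mask, "land use and basin mask")
    basin = basin_mask.values.astype(bool) & basin_mask.valid_mask()
    n_cells = int(basin.sum())
    if n_cells == 0:
        raise ValueError(f"basin for lake {lake_id} has zero cells")
    area_km2 = n_cells * (basin_mask.cell_size / 1000.0) ** 2

    codes = config.landuse_codes
    fr = lambda key: zonal_fraction(landuse, basin_mask, codes[key])
    frac_veg = fr("natural_vegetation")
    frac_agr = fr("agricultural")
    frac_irr = fr("irrigated")
    frac_rec = fr("recreational")
    # irrigated land is agriculture too; A covers both categories
    frac_agr_total = min(1.0, frac_agr + frac_irr)

    def cell_of(pt) -> tuple[int, int]:
        col = int((pt.x - basin_mask.origin_x) // basin_mask.cell_size)
        row = int((basin_mask.origin_y - pt.y) // basin_mask.cell_size)
        return row, col

    n_ind = 0
    n_ww = 0
    treatments: list[str] = []
    for geom, attrs in facilities:
        pt = geom.centroid
        r, c = cell_of(pt)
        if 0 <= r < basin_mask.n_rows and 0 <= c < basin_mask.n_cols and basin[r, c]:
            kind = attrs.get("kind", "industrial")
            if kind == "industrial":
                n_ind += 1
            elif kind == "wastewater":
                n_ww += 1
                treatments.append(attrs.get("treatment", "none"))
    # the basin is only as protected as its least-treated discharge
    order = {"none": 0, "primary": 1, "secondary": 2}
    treatment = min(treatments, key=order.__getitem__) if treatments else "secondary"

    transport_km = 0.0
    if len(routes):
        poly = basin_polygon(basin_mask)
        for geom, _ in routes:
            transport_km += geom.intersection(poly).length / 1000.0

    return BasinAttributes(
        lake_id=lake_id,
        basin_area_km2=area_km2,
        frac_agricultural=frac_agr_total,
        frac_irrigated=frac_irr,
        frac_vegetated_cover=frac_veg,
        frac_recreational=frac_rec,
        n_industrial_sites=n_ind,
        n_wastewater_discharges=n_ww,
        treatment_level=treatment,
        transport_length_km=transport_km,
        **extra,
    )


def score_criterion(
    letter: str,
    raw: float,
    banding: ReclassTable,
    treatment_level: str | None = None,
    treatment_modifier: dict[str, int] | None = None,
) -> int:
    """Banded lookup of one criterion's integer score.

    Bands are half-open [lo, hi) with the top band closed.  The cover
    criterion C uses a descending class vector (inverse scoring: more
    vegetated cover means less pressure).  For W, the wastewater treatment
    level shifts the score (untreated +1, secondary -1 by default), clamped
    to the class range.
    """
    if letter not in LETTERS:
        raise ValueError(f"unknown criterion {letter!r}")
    n = int(banding.lookup(float(raw)))
    if letter == "W" and treatment_level is not None and treatment_modifier:
        lo, hi = min(banding.classes), max(banding.classes)
        n = int(np.clip(n + treatment_modifier[treatment_level], lo, hi))
    return n


def wrastic_weighted_sum(scores: Sequence[CriterionScore] | dict[str, CriterionScore]) -> float:
    """Sum of n_i * p_i over the seven criteria; each letter exactly once."""
    items = list(scores.values()) if isinstance(scores, dict) else list(scores)
    letters = [s.letter for s in items]
    if sorted(letters) != sorted(LETTERS):
        raise ValueError(f"need each of {LETTERS} exactly once, got {letters}")
    return float(sum(s.n * s.p for s in items))


def wrastic_hi(weighted_sum: float, hi_basin: float) -> float:
    """The composite index: weighted criterion sum times the basin hazard."""
    if weighted_sum < 0 or hi_basin < 0:
        raise ValueError("weighted sum and hazard index must be non-negative")
    return float(weighted_sum) * float(hi_basin)


def classify(
    values: Sequence[float],
    thresholds: tuple[float, float] | None = None,
    mode: str = "fixed",
) -> list[str]:
    """Assign each WRASTIC-HI value a degradation class.

    ``fixed`` mode uses the two given breakpoints t1 < t2:
    value <= t1 -> natural, t1 < value <= t2 -> semi_degraded,
    value > t2 -> degraded (lower bands closed above).  ``tertile`` mode
    derives t1, t2 as the cohort's 1/3 and 2/3 quantiles.
    """
    vals = np.asarray(values, dtype=float)
    if mode == "tertile":
        if vals.size == 0:
            return []
        t1, t2 = np.quantile(vals, [1 / 3, 2 / 3])
    elif mode == "fixed":
        if thresholds is None:
            raise ValueError("fixed mode needs thresholds")
        t1, t2 = thresholds
    else:
        raise ValueError(f"unknown classification mode {mode!r}")
    if not t1 < t2:
        raise ValueError(f"need t1 < t2, got {t1} >= {t2}")
    out = np.full(vals.shape, "semi_degraded", dtype=object)
    out[vals <= t1] = "natural"
    out[vals > t2] = "degraded"
    return list(out)


def assess_lake(attrs: BasinAttributes, hi_basin: float, config: WrasticConfig) -> LakeAssessment:
    """Score the seven criteria for one lake and form its WRASTIC-HI."""
    scores: dict[str, CriterionScore] = {}
    for letter in LETTERS:
        raw = float(getattr(attrs, CRITERION_METRIC[letter]))
        n = score_criterion(
            letter, raw, config.score_bands[letter],
            treatment_level=attrs.treatment_level if letter == "W" else None,
            treatment_modifier=config.treatment_modifier,
        )
        scores[letter] = CriterionScore(letter, raw, n, config.weights[letter])
    ws = wrastic_weighted_sum(scores)
    return LakeAssessment(
        lake_id=attrs.lake_id,
        scores=scores,
        weighted_sum=ws,
        hi_basin=float(hi_basin),
        wrastic_hi=wrastic_hi(ws, hi_basin),
    )
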