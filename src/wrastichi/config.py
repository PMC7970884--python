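"""Configuration: criterion weights, score bands, hazard reclass tables,
classification thresholds, and the land-use category-code mapping.

Defaults follow the WRASTIC literature (criterion weights W .25, R .10,
A .20, S .05, T .10, I .20, C .10; scores on a 1-5 scale) and three-level
1/3/5 hazard classes.  Every table is overridable from a YAML/JSON file;
the class-band tables in particular are documented placeholders a user
with calibrated regional tables should replace.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml

from .hazard import ReclassTable

__all__ = ["WrasticConfig", "load_config", "validate_config", "ConfigError",
           "LETTERS", "DEFAULT_CONFIG"]

LETTERS = ("W", "R", "A", "S", "T", "I", "C")

# raw metric feeding each criterion (a BasinAttributes field)
CRITERION_METRIC = {
    "W": "n_wastewater_discharges",
    "R": "frac_recreational",
    "A": "frac_agricultural",
    "S": "basin_area_km2",
    "T": "transport_length_km",
    "I": "n_industrial_sites",
    "C": "frac_vegetated_cover",
}

DEFAULT_CONFIG: dict[str, Any] = {
    "weights": {"W": 0.25, "R": 0.10, "A": 0.20, "S": 0.05,
                "T": 0.10, "I": 0.20, "C": 0.10},
    # score bands: half-open [lo, hi), value on a breakpoint -> upper band
    "score_bands": {
        "W": {"breakpoints": [1, 2, 4, 6], "classes": [1, 2, 3, 4, 5]},
        "R": {"breakpoints": [0.05, 0.10, 0.20, 0.35], "classes": [1, 2, 3, 4, 5]},
        "A": {"breakpoints": [0.10, 0.25, 0.50, 0.75], "classes": [1, 2, 3, 4, 5]},
        "S": {"breakpoints": [5, 25, 100, 500], "classes": [1, 2, 3, 4, 5]},
        "T": {"breakpoints": [1, 5, 15, 50], "classes": [1, 2, 3, 4, 5]},
        "I": {"breakpoints": [1, 2, 4, 7], "classes": [1, 2, 3, 4, 5]},
        # C is inverse-scored: more vegetative cover -> lower pressure score
        "C": {"breakpoints": [0.20, 0.40, 0.60, 0.80], "classes": [5, 4, 3, 2, 1],
              "inverse": True},
    },
    # wastewater treatment level shifts the W score: untreated discharges
    # are worse than primary, primary worse than secondary treatment
    "treatment_modifier": {"none": 1, "primary": 0, "secondary": -1},
    # hazard tables (three 1/3/5 classes each)
    "slope_bands": {"breakpoints": [2.0, 8.0], "classes": [1, 3, 5]},
    "permeability_map": {1: 1, 2: 3, 3: 5},   # texture code -> Pn
    "exposure_flat_tol": 0.01,                # deg; slope below -> flat aspect
    "hazard_aggregate": "mean",               # per-basin HI: mean|median|mode
    # classification: fixed WRASTIC-HI breakpoints, or "tertile" cohort mode
    "class_mode": "fixed",                    # fixed | tertile
    "class_thresholds": [20.0, 40.0],         # natural <= t1 < semi <= t2 < degraded
    # land-use category codes -> criterion role
    "landuse_codes": {
        "natural_vegetation": 1,
        "agricultural": 2,
        "industrial": 3,
        "urban": 4,
        "recreational": 5,
        "irrigated": 6,
        "water": 7,
    },
    "water_ndwi_threshold": 0.0,              # cluster-mean NDWI to call water
    "min_lake_cells": 3,
}


class ConfigError(ValueError):
    pass


@dataclass
class WrasticConfig:
    """Validated, normalized run configuration."""

    weights: dict[str, float]
    score_bands: dict[str, ReclassTable]
    treatment_modifier: dict[str, int]
    slope_bands: ReclassTable
    permeability_map: dict[int, int]
    exposure_flat_tol: float
    hazard_aggregate: str
    class_mode: str
    class_thresholds: tuple[float, float]
    landuse_codes: dict[str, int]
    water_ndwi_threshold: float
    min_lake_cells: int
    raw: dict[str, Any] = field(default_factory=dict, repr=False)


def _merged(overrides: Mapping[str, Any] | None) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in (overrides or {}).items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def validate_config(data: Mapping[str, Any] | None = None) -> WrasticConfig:
    """Merge overrides onto defaults and validate; raises ConfigError listing
    every problem found rather than stopping at the first."""
    cfg = _merged(data)
    errors: list[str] = []

    weights = {k: float(v) for k, v in cfg["weights"].items()}
    if set(weights) != set(LETTERS):
        errors.append(f"weights must cover exactly {LETTERS}, got {sorted(weights)}")
    elif not np.isclose(sum(weights.values()), 1.0):
        errors.append(f"weights must sum to 1, got {sum(weights.values()):.4f}")
    if any(w < 0 for w in weights.values()):
        errors.append("weights must be non-negative")

    bands: dict[str, ReclassTable] = {}
    for letter in LETTERS:
        entry = cfg["score_bands"].get(letter)
        if entry is None:
            errors.append(f"score_bands missing criterion {letter}")
            continue
        try:
            bands[letter] = ReclassTable.from_config(entry)
        except (ValueError, KeyError) as exc:
            errors.append(f"score_bands[{letter}]: {exc}")

    try:
        slope_bands = ReclassTable.from_config(cfg["slope_bands"])
    except (ValueError, KeyError) as exc:
        slope_bands = None  # type: ignore[assignment]
        errors.append(f"slope_bands: {exc}")

    t = cfg["class_thresholds"]
    if len(t) != 2 or not float(t[0]) < float(t[1]):
        errors.append(f"class_thresholds must be two increasing values, got {t}")
    if cfg["class_mode"] not in ("fixed", "tertile"):
        errors.append(f"class_mode must be 'fixed' or 'tertile', got {cfg['class_mode']!r}")
    if cfg["hazard_aggregate"] not in ("mean", "median", "mode"):
        errors.append(f"hazard_aggregate must be mean|median|mode, got {cfg['hazard_aggregate']!r}")

    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))

    return WrasticConfig(
        weights=weights,
        score_bands=bands,
        treatment_modifier={k: int(v) for k, v in cfg["treatment_modifier"].items()},
        slope_bands=slope_bands,
        permeability_map={int(k): int(v) for k, v in cfg["permeability_map"].items()},
        exposure_flat_tol=float(cfg["exposure_flat_tol"]),
        hazard_aggregate=cfg["hazard_aggregate"],
        class_mode=cfg["class_mode"],
        class_thresholds=(float(t[0]), float(t[1])),
        landuse_codes={k: int(v) for k, v in cfg["landuse_codes"].items()},
        water_ndwi_threshold=float(cfg["water_ndwi_threshold"]),
        min_lake_cells=int(cfg["min_lake_cells"]),
        raw=cfg,
    )


def load_config(path: str | os.PathLike | None = None) -> WrasticConfig:
    """Load a YAML/JSON config file (or the defaults when path is None)."""
    if path is None:
        return validate_config(None)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return validate_config(data or {})
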