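"""Stem-level and species-level summaries of xylem vessel populations.

Vessel lumen areas measured in cross-section are converted to equivalent
circular diameters, stems are summarized by their mean vessel diameter and
the fraction of vessels above the freezing-induced-embolism threshold
(~30 μm in deciduous angiosperms at moderate water potential), and species
traits are species means of stem means with a majority-rule porosity label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POROSITY_CLASSES = ("diffuse", "semi-ring", "ring")
EMBOLISM_THRESHOLD_UM = 30.0

__all__ = [
    "StemSample",
    "POROSITY_CLASSES",
    "EMBOLISM_THRESHOLD_UM",
    "diameter_from_area",
    "pct_over_threshold",
    "stem_summary",
    "species_summary",
]


@dataclass
class StemSample:
    """One stem's vessel population plus dye-perfusion areas.

    ``diameters_um`` are equivalent circular diameters of the vessel lumina
    from the most recent complete growth ring; dyed areas refer to the
    previous growing season's xylem cross-section.
    """

    stem_id: str
    species_id: str
    porosity: str
    diameters_um: np.ndarray
    garden_id: str = ""
    ring_year: int = 1
    dyed: np.ndarray | None = None      # per-vessel conductive flag
    xylem_area_total_prev_year: float = np.nan  # μm²
    xylem_area_dyed_prev_year: float = np.nan   # μm²

    def __post_init__(self):
        self.diameters_um = np.asarray(self.diameters_um, dtype=float)
        if self.porosity not in POROSITY_CLASSES:
            raise ValueError(
                f"unknown porosity {self.porosity!r}; expected one of {POROSITY_CLASSES}"
            )
        if self.diameters_um.size == 0:
            raise ValueError(f"stem {self.stem_id}: no vessels")
        if (self.diameters_um < 0).any():
            raise ValueError(f"stem {self.stem_id}: negative vessel diameter")
        if self.dyed is not None:
            self.dyed = np.asarray(self.dyed, dtype=bool)
            if self.dyed.shape != self.diameters_um.shape:
                raise ValueError("dyed flags must match vessel count")
        a_tot = self.xylem_area_total_prev_year
        a_dye = self.xylem_area_dyed_prev_year
        if np.isfinite(a_tot) and a_tot < 0:
            raise ValueError("negative total xylem area")
        if np.isfinite(a_dye) and np.isfinite(a_tot) and a_dye > a_tot:
            raise ValueError("dyed area exceeds total xylem area")

    @property
    def mean_diameter_um(self) -> float:
        return float(self.diameters_um.mean())


def diameter_from_area(lumen_area):
    """Equivalent circular diameter (μm) of a vessel lumen area (μm²).

    ``d = 2 * sqrt(A / pi)``, treating the lumen as round in cross-section.
    """
    area = np.asarray(lumen_area, dtype=float)
    if (area < 0).any():
        raise ValueError("lumen area must be non-negative")
    d = 2.0 * np.sqrt(area / np.pi)
    return float(d) if np.isscalar(lumen_area) or area.ndim == 0 else d


def pct_over_threshold(diameters_um, threshold_um: float = EMBOLISM_THRESHOLD_UM) -> float:
    """Percent of vessels strictly wider than the embolism threshold.

    The boundary is strict: a vessel exactly at the threshold does not count.
    """
    d = np.asarray(diameters_um, dtype=float)
    if d.size == 0:
        raise ValueError("empty vessel list")
    return 100.0 * float(np.count_nonzero(d > threshold_um)) / d.size


def stem_summary(vessels: pd.DataFrame,
                 threshold_um: float = EMBOLISM_THRESHOLD_UM) -> pd.DataFrame:
    """Per-stem mean diameter and threshold fraction from a vessel table.

    ``vessels`` needs columns stem_id, species_id, porosity and either
    diameter_um or lumen_area_um2 (converted if only the area is present).
    """
    df = vessels.copy()
    if "diameter_um" not in df:
        if "lumen_area_um2" not in df:
            raise ValueError("need diameter_um or lumen_area_um2 column")
        df["diameter_um"] = diameter_from_area(df["lumen_area_um2"].to_numpy())
    if (df["diameter_um"] <= 0).any():
        raise ValueError("non-positive vessel diameter in table")
    g = df.groupby(["stem_id", "species_id", "porosity"], observed=True)
    out = g["diameter_um"].agg(
        mean_vessel_diameter="mean",
        n_vessels="size",
        pct_over_threshold=lambda d: pct_over_threshold(d, threshold_um),
    ).reset_index()
    return out


def _majority_porosity(porosities: pd.Series) -> str:
    """Majority porosity of a species' stems; deterministic tie-break.

    Ties are broken toward the earlier class in (diffuse, semi-ring, ring),
    i.e. the narrower-vesseled interpretation.
    """
    counts = porosities.value_counts()
    top = counts[counts == counts.max()].index
    for cls in POROSITY_CLASSES:
        if cls in top:
            return cls
    return str(top[0])


def species_summary(vessels: pd.DataFrame,
                    phenology: pd.DataFrame | None = None,
                    threshold_um: float = EMBOLISM_THRESHOLD_UM) -> pd.DataFrame:
    """Species-level trait table: means of stem means, equal stem weights.

    Each stem contributes one observation regardless of how many vessels it
    holds, so heavily sampled ring-porous stems do not dominate the species
    average.  Porosity is assigned by majority rule over stems.  If a
    phenology table (per-plant leaf-out with species_id, leafout_doy,
    leafout_gdd and optional height_m) is given, its species means are merged.
    """
    stems = stem_summary(vessels, threshold_um)
    agg = stems.groupby("species_id").agg(
        mean_vessel_diameter=("mean_vessel_diameter", "mean"),
        pct_over_threshold=("pct_over_threshold", "mean"),
        n_stems=("stem_id", "size"),
        porosity=("porosity", _majority_porosity),
    ).reset_index()
    empty = agg[agg["n_stems"] == 0]
    if len(empty):
        logger.warning("species without stems excluded: %s",
                       list(empty["species_id"]))
        agg = agg[agg["n_stems"] > 0]
    if phenology is not None:
        keep = [c for c in ("leafout_doy", "leafout_gdd", "height_m",
                            "max_leaf_length_cm") if c in phenology.columns]
        pheno = phenology.groupby("species_id")[keep].mean().reset_index()
        agg = agg.merge(pheno, on="species_id", how="left")
    return agg
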