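"""Theoretical xylem conductivity of dye-conductive vessels (Poiseuille law).

Two equivalent mass-flow formulations are used, matching how ring/semi-ring
versus diffuse porous stems are measured:

* per-vessel, summing the fourth powers of individually measured conductive
  vessel diameters::

      K = (pi * rho_w / (128 * eta)) * sum(d_i ** 4)

* bulk, for diffuse-porous stems where vessel width and density are assumed
  uniform across the dyed area ``A`` with vessel density ``D``::

      K = pi * rho_w * D * A * dbar ** 4 / (128 * eta)

Diameters enter in meters; helpers accept μm and convert.  K carries units
kg m s^-1 Pa^-1 (mass flow rate per pressure gradient) and refers to a stem
segment — the equations carry no segment-length or sapwood-area
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anatomy import StemSample

UM_PER_M = 1.0e6

__all__ = [
    "WaterProperties",
    "k_per_vessel",
    "k_bulk_diffuse",
    "functional_fraction",
    "impute_missing_stems",
    "conductivity_table",
]


@dataclass(frozen=True)
class WaterProperties:
    """Density and dynamic viscosity of water; defaults are the 20 °C values."""

    rho_w: float = 998.2        # kg m^-3
    eta: float = 1.002e-3       # Pa s
    temperature_c: float = 20.0

    def __post_init__(self):
        if self.rho_w <= 0 or self.eta <= 0:
            raise ValueError("water density and viscosity must be positive")

    @property
    def poiseuille_factor(self) -> float:
        """pi * rho_w / (128 * eta)."""
        return np.pi * self.rho_w / (128.0 * self.eta)


def k_per_vessel(diameters_m, props: WaterProperties = WaterProperties()) -> float:
    """Per-vessel theoretical conductivity from conductive-vessel diameters (m)."""
    d = np.asarray(diameters_m, dtype=float)
    if (d < 0).any():
        raise ValueError("vessel diameters must be non-negative")
    return float(props.poiseuille_factor * np.sum(d ** 4))


def k_bulk_diffuse(mean_diameter_m: float, density_per_m2: float, dyed_area_m2: float,
                   props: WaterProperties = WaterProperties()) -> float:
    """Bulk theoretical conductivity for a homogeneous diffuse-porous stem.

    With ``D * A`` equal to the vessel count and all vessels at the mean
    diameter this is exactly :func:`k_per_vessel`; on heterogeneous
    populations it underestimates it (Jensen's inequality on d^4).
    """
    if mean_diameter_m < 0 or density_per_m2 < 0 or dyed_area_m2 < 0:
        raise ValueError("inputs must be non-negative")
    return float(props.poiseuille_factor * density_per_m2 * dyed_area_m2
                 * mean_diameter_m ** 4)


def functional_fraction(sample: StemSample) -> float:
    """Percent of previous-year xylem cross-section that conducted dye."""
    total = sample.xylem_area_total_prev_year
    dyed = sample.xylem_area_dyed_prev_year
    if not np.isfinite(total) or total <= 0:
        raise ValueError(f"stem {sample.stem_id}: total previous-year area must be > 0")
    return 100.0 * dyed / total


def impute_missing_stems(stems: pd.DataFrame) -> pd.DataFrame:
    """Fill missing mean diameter/density from species means of complete stems.

    Mirrors the treatment of stems lacking high-resolution images: their mean
    vessel diameter and vessel density are replaced by the averages of the
    species' fully measured stems before the bulk conductivity is computed.
    Requires columns species_id, stem_id, mean_diameter_um, density_per_mm2.
    """
    out = stems.copy()
    need = ["mean_diameter_um", "density_per_mm2"]
    for species, sub in out.groupby("species_id"):
        incomplete = sub[need].isna().any(axis=1)
        if not incomplete.any():
            continue
        complete = sub[~incomplete]
        if complete.empty:
            raise ValueError(
                f"species {species}: no completely measured stems to impute from"
            )
        for col in need:
            fill = complete[col].mean()
            out.loc[sub.index[incomplete], col] = out.loc[
                sub.index[incomplete], col
            ].fillna(fill)
    return out


def conductivity_table(vessels: pd.DataFrame, areas: pd.DataFrame,
                       props: WaterProperties = WaterProperties()) -> pd.DataFrame:
    """Per-stem conductivity using the porosity-appropriate formula.

    Ring and semi-ring porous stems use the per-vessel sum over dyed vessels;
    diffuse porous stems use the bulk formula from the stem's mean conductive
    diameter, vessel density and dyed area.

    Parameters
    ----------
    vessels : DataFrame
        stem_id, species_id, porosity, diameter_um, dyed (bool).
    areas : DataFrame
        stem_id, xylem_area_total_prev_year_mm2, xylem_area_dyed_prev_year_mm2,
        optionally density_per_mm2 (required for diffuse stems).
    """
    rows = []
    area_idx = areas.set_index("stem_id")
    for (stem_id, species, porosity), sub in vessels.groupby(
            ["stem_id", "species_id", "porosity"], observed=True):
        dyed_mask = sub["dyed"].astype(bool) if "dyed" in sub else pd.Series(
            True, index=sub.index)
        dyed_d_um = sub.loc[dyed_mask, "diameter_um"].to_numpy(float)
        try:
            a = area_idx.loc[stem_id]
        except KeyError:
            raise ValueError(f"stem {stem_id} missing from areas table") from None
        a_tot = float(a["xylem_area_total_prev_year_mm2"])
        a_dye = float(a["xylem_area_dyed_prev_year_mm2"])
        if porosity == "diffuse":
            dbar_m = dyed_d_um.mean() / UM_PER_M if dyed_d_um.size else 0.0
            dens_mm2 = float(a.get("density_per_mm2", np.nan))
            if not np.isfinite(dens_mm2):
                raise ValueError(f"diffuse stem {stem_id} needs density_per_mm2")
            k = k_bulk_diffuse(dbar_m, dens_mm2 * 1e6, a_dye * 1e-6, props)
            method = "bulk-diffuse"
        else:
            k = k_per_vessel(dyed_d_um / UM_PER_M, props)
            method = "per-vessel"
        rows.append({
            "stem_id": stem_id,
            "species_id": species,
            "porosity": porosity,
            "method": method,
            "n_conductive": int(dyed_mask.sum()),
            "mean_conductive_diameter_um": float(dyed_d_um.mean())
            if dyed_d_um.size else np.nan,
            "K_kg_m_s_Pa": k,
            "pct_prev_year_functional": 100.0 * a_dye / a_tot if a_tot > 0 else np.nan,
        })
    return pd.DataFrame(rows)
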