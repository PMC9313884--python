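"""Degree-day accumulation and freeze-risk dates from daily temperatures.

Growing degree days (GDD) are the cumulative sum of daily mean temperatures
above 0 °C starting January 1 — a thermal-time axis for leaf-out.  The
freeze-safe date is the first spring calendar day from which, across the
years of a climate-normals table, the fraction of years with a minimum
temperature at or below 0 °C stays under the risk threshold (10% by
default) for the rest of spring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "degree_days",
    "cumulative_degree_days",
    "freeze_safe_date",
    "FreezeSafeResult",
    "attach_phenology",
]


def _year_slice(weather: pd.DataFrame, year: int) -> pd.DataFrame:
    sub = weather[weather["year"] == year].sort_values("doy")
    if sub.empty:
        raise ValueError(f"no weather records for year {year}")
    doys = sub["doy"].to_numpy()
    expected = np.arange(1, doys.max() + 1)
    if doys.size != expected.size or (doys != expected).any():
        missing = sorted(int(d) for d in set(expected) - set(doys))
        raise ValueError(f"year {year}: missing days {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    return sub


def degree_days(weather: pd.DataFrame, year: int, doy: int,
                base_c: float = 0.0, statistic: str = "tmean_c") -> float:
    """Thermal sum of daily ``statistic`` above ``base_c`` from Jan 1 to ``doy``.

    ``weather`` needs columns year, doy and the chosen statistic (daily mean
    temperature by default).  All days from January 1 through ``doy`` must be
    present; gaps are reported.
    """
    if doy < 1:
        raise ValueError("doy must be >= 1")
    sub = _year_slice(weather, year)
    if doy > sub["doy"].max():
        raise ValueError(f"year {year} ends at doy {sub['doy'].max()}, need {doy}")
    t = sub.loc[sub["doy"] <= doy, statistic].to_numpy(float)
    return float(np.sum(np.clip(t - base_c, 0.0, None)))


def cumulative_degree_days(weather: pd.DataFrame, year: int,
                           base_c: float = 0.0,
                           statistic: str = "tmean_c") -> pd.Series:
    """Running GDD indexed by day of year for one year."""
    sub = _year_slice(weather, year)
    gdd = np.cumsum(np.clip(sub[statistic].to_numpy(float) - base_c, 0.0, None))
    return pd.Series(gdd, index=sub["doy"].to_numpy(), name="gdd")


@dataclass
class FreezeSafeResult:
    """Outcome of the freeze-risk scan; ``safe_doy`` is None when no day
    within the spring window stays below the risk threshold."""

    safe_doy: int | None
    prob: float
    n_years: int
    freeze_fraction: pd.Series  # per-calendar-day fraction of years with frost

    @property
    def never_safe(self) -> bool:
        return self.safe_doy is None


def freeze_safe_date(normals: pd.DataFrame, prob: float = 0.10,
                     spring_end_doy: int = 181) -> FreezeSafeResult:
    """Earliest calendar day from which frost probability stays below ``prob``.

    For each day of year the frost probability is the across-years fraction
    with ``tmin_c`` <= 0 °C.  The safe date is the earliest day D such that
    every day from D through ``spring_end_doy`` is below ``prob`` — isolated
    safe days followed by risky ones do not qualify.  Needs >= 2 years.
    """
    years = normals["year"].unique()
    if len(years) < 2:
        raise ValueError("need at least two years of normals")
    sub = normals[normals["doy"] <= spring_end_doy]
    frac = (sub.assign(frost=sub["tmin_c"] <= 0.0)
            .groupby("doy")["frost"].mean())
    frac = frac.reindex(np.arange(1, spring_end_doy + 1)).dropna()
    unsafe = frac[frac >= prob]
    if unsafe.empty:
        safe = int(frac.index.min())
    else:
        last_risky = int(unsafe.index.max())
        safe = last_risky + 1 if last_risky < int(frac.index.max()) else None
    return FreezeSafeResult(safe_doy=safe, prob=prob, n_years=len(years),
                            freeze_fraction=frac)


def attach_phenology(observations: pd.DataFrame,
                     weather: pd.DataFrame,
                     site_column: str = "site_id") -> pd.DataFrame:
    """Populate per-plant leaf-out events with day of year and degree days.

    ``observations`` needs plant_id, species_id, year, doy (or a date column)
    and optionally dieback/basal_sprout flags, which are carried through.
    ``weather`` needs year, doy, tmean_c and, if per-site, a site column
    matching ``observations``.
    """
    obs = observations.copy()
    if "doy" not in obs:
        if "date" not in obs:
            raise ValueError("observations need a doy or date column")
        dt = pd.to_datetime(obs["date"])
        obs["doy"] = dt.dt.dayofyear
        obs["year"] = dt.dt.year
    per_site = site_column in obs.columns and site_column in weather.columns
    gdd = np.empty(len(obs))
    cache: dict[tuple, pd.Series] = {}
    for i, row in enumerate(obs.itertuples(index=False)):
        site = getattr(row, site_column) if per_site else None
        key = (site, row.year)
        if key not in cache:
            w = weather[weather[site_column] == site] if per_site else weather
            if w.empty:
                raise ValueError(f"no weather series for site {site!r}")
            cache[key] = cumulative_degree_days(w, row.year)
        series = cache[key]
        if row.doy not in series.index:
            raise ValueError(
                f"plant {row.plant_id}: doy {row.doy} outside weather coverage")
        gdd[i] = series.loc[row.doy]
    obs["leafout_doy"] = obs["doy"].astype(int)
    obs["leafout_gdd"] = gdd
    return obs
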