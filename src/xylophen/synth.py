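"""Synthetic common-garden generator with known ground truth.

Emulates the three kinds of data the analysis consumes: per-stem vessel
populations with porosity-specific diameter distributions, species-level
leaf-out phenology generated from a linear (or exponential) model on mean
vessel diameter with optionally phylogenetically correlated residuals,
multi-year daily temperature normals with stochastic spring frost, and
birth–death phylogenies rescaled to unit depth.  Every generating parameter
is recorded in a ground-truth sidecar so downstream stages can be tested by
parameter recovery.

Vessel diameters are lognormal (diameters are positive and multiplicative),
parameterized by an arithmetic mean and coefficient of variation:

* diffuse porous — one unimodal component around ``diffuse_mean_diam``;
* ring porous — a two-component mixture: a fraction ``earlywood_fraction``
  of wide earlywood vessels plus narrow latewood vessels;
* semi-ring porous — mean declining linearly from the earlywood to the
  latewood mean across a uniform within-ring position.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .anatomy import POROSITY_CLASSES
from .phylo import pagel_transform, vcv_matrix, write_tree

__all__ = [
    "SynthConfig",
    "simulate_vessels",
    "simulate_tree",
    "simulate_traits",
    "simulate_weather",
    "simulate_garden",
    "GardenData",
]

_CLASS_MEAN_N = {"diffuse": 100, "semi-ring": 100, "ring": 200}


@dataclass
class SynthConfig:
    """Ground-truth parameters of one synthetic common garden.

    Defaults emulate the study conditions: a diverse garden of 64 focal
    taxa, porosity mix proportional to the 41/19/27
    diffuse/semi-ring/ring sample, vessel means spanning the observed
    15–55 μm range, leaf-out degree days linear in mean vessel diameter, no
    phylogenetic signal in the residuals (the observed outcome), and
    15 years of daily climate normals.
    """

    n_species: int = 64
    n_stems_per_species: int = 4
    porosity_mix: tuple[float, float, float] = (41 / 87, 19 / 87, 27 / 87)
    diffuse_mean_diam: float = 20.0      # μm
    ring_earlywood_mean: float = 55.0    # μm
    ring_latewood_mean: float = 18.0     # μm
    earlywood_fraction: float = 0.3
    diam_cv: float = 0.2                 # within-stem vessel spread
    species_diam_cv: float = 0.15        # between-species spread within a class
    stem_diam_cv: float = 0.05           # between-stem spread within a species
    # leaf-out model: gdd = beta0 + beta1 * mean_diam + eps
    beta0: float = 50.0                  # degree days
    beta1: float = 9.0                   # degree days per μm
    resid_sd: float = 60.0               # degree days
    lambda_true: float = 0.0
    relation: str = "linear"             # or "exponential" (y0, a, b below)
    exp_y0: float = 180.0
    exp_a: float = 0.5
    exp_b: float = 0.2
    # tree
    tree_birth_rate: float = 1.0
    tree_death_rate: float = 0.5
    # weather
    n_weather_years: int = 15
    weather_tmid: float = 6.0            # annual mean of daily means, °C
    weather_amp: float = 18.0            # seasonal half-amplitude, °C
    weather_noise_sd: float = 3.0
    tmin_offset: float = 5.0             # tmean minus tmin
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.porosity_mix) - 1.0) > 1e-9:
            raise ValueError("porosity_mix must sum to 1")
        if min(self.porosity_mix) < 0:
            raise ValueError("porosity_mix proportions must be non-negative")
        for name in ("diffuse_mean_diam", "ring_earlywood_mean",
                     "ring_latewood_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")
        if not 0.0 <= self.earlywood_fraction <= 1.0:
            raise ValueError("earlywood_fraction must be in [0, 1]")
        if self.n_species < 1 or self.n_stems_per_species < 1:
            raise ValueError("need at least one species and one stem")
        if self.relation not in ("linear", "exponential"):
            raise ValueError("relation must be 'linear' or 'exponential'")

    def class_mean_diameter(self, porosity: str) -> float:
        """Expected vessel diameter of a porosity class under this config."""
        if porosity == "diffuse":
            return self.diffuse_mean_diam
        ew, lw = self.ring_earlywood_mean, self.ring_latewood_mean
        if porosity == "ring":
            f = self.earlywood_fraction
            return f * ew + (1 - f) * lw
        if porosity == "semi-ring":
            return 0.5 * (ew + lw)
        raise ValueError(f"unknown porosity {porosity!r}")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean and CV; cv=0 is exact."""
    if cv == 0:
        return np.full(n, mean)
    s2 = np.log1p(cv * cv)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(s2), size=n)


def simulate_vessels(cfg: SynthConfig, porosity: str, n: int | None = None,
                     scale: float = 1.0,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw one stem's vessel diameters (μm) for a porosity class.

    ``scale`` multiplies all class means (species- or stem-level variation).
    Diffuse and semi-ring stems default to 100 vessels, ring-porous stems to
    200; fewer than 100 diffuse vessels are refused to keep the bulk-formula
    mean stable.
    """
    if porosity not in POROSITY_CLASSES:
        raise ValueError(
            f"unknown porosity {porosity!r}; expected one of {POROSITY_CLASSES}")
    rng = rng or np.random.default_rng(cfg.seed)
    n = n if n is not None else _CLASS_MEAN_N[porosity]
    if porosity == "diffuse" and n < 100:
        raise ValueError("diffuse stems need at least 100 vessels")
    if n < 1:
        raise ValueError("need at least one vessel")
    ew = cfg.ring_earlywood_mean * scale
    lw = cfg.ring_latewood_mean * scale
    if porosity == "diffuse":
        d = _lognormal(rng, cfg.diffuse_mean_diam * scale, cfg.diam_cv, n)
    elif porosity == "ring":
        is_ew = rng.random(n) < cfg.earlywood_fraction
        d = np.where(is_ew,
                     _lognormal(rng, ew, cfg.diam_cv, n),
                     _lognormal(rng, lw, cfg.diam_cv, n))
    else:  # semi-ring: mean declines linearly across within-ring position
        u = rng.random(n)
        means = ew - (ew - lw) * u
        d = means * _lognormal(rng, 1.0, cfg.diam_cv, n)
    return d


def simulate_tree(cfg: SynthConfig,
                  rng: np.random.Generator | None = None) -> dendropy.Tree:
    """Birth–death tree with ``n_species`` extant tips, unit root-to-tip depth.

    Rescaling to unit depth makes Pagel-lambda transforms comparable across
    replicate trees.  Tips are labeled sp001, sp002, ...
    """
    rng = rng or np.random.default_rng(cfg.seed)
    seed_int = int(rng.integers(0, 2**31 - 1))
    tree = treesim.birth_death_tree(
        birth_rate=cfg.tree_birth_rate,
        death_rate=cfg.tree_death_rate,
        num_extant_tips=cfg.n_species,
        rng=random.Random(seed_int),
    )
    tree.purge_taxon_namespace()
    # the simulator stops exactly at the n-th speciation, leaving the newborn
    # sister pair with zero-length edges (and a singular VCV); extend every
    # extant tip by the waiting time to the next birth/death event
    total_rate = cfg.n_species * (cfg.tree_birth_rate + cfg.tree_death_rate)
    extra = rng.exponential(1.0 / total_rate)
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:03d}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # drop the stem edge above the root: it contributes no between-tip
    # contrast and would keep the VCV diagonal short of unit depth
    tree.seed_node.edge.length = None
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    if depth <= 0:
        raise RuntimeError("degenerate tree depth")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return tree


def simulate_traits(cfg: SynthConfig, tree: dendropy.Tree,
                    rng: np.random.Generator | None = None,
                    weather: pd.DataFrame | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Species trait table with phylogenetically correlated leaf-out residuals.

    Leaf-out degree days are ``beta0 + beta1 * diam + eps`` (or the
    exponential variant) with ``eps ~ MVN(0, resid_sd^2 * V(lambda_true))``,
    where V is the tree's lambda-transformed correlation matrix (unit
    diagonal after depth rescaling).  If a weather table is given, each
    species' leaf-out day of year is the day its degree-day sum is reached
    in the first weather year.

    Returns the trait table and a ground-truth dict (kept separate from the
    data on purpose).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != cfg.n_species:
        raise ValueError("tree tip count does not match n_species")
    n = len(labels)
    porosity = rng.choice(POROSITY_CLASSES, size=n, p=cfg.porosity_mix)
    species_scale = _lognormal(rng, 1.0, cfg.species_diam_cv, n)
    diam = np.array([cfg.class_mean_diameter(p) for p in porosity]) * species_scale

    V, _ = vcv_matrix(tree, order=labels)
    # normalize to a correlation matrix so resid_sd is the marginal SD
    dV = np.sqrt(np.diag(V))
    C = V / np.outer(dV, dV)
    Clam = pagel_transform(C, cfg.lambda_true)
    z = rng.standard_normal(n)
    eps = cfg.resid_sd * (np.linalg.cholesky(Clam) @ z) if cfg.resid_sd > 0 \
        else np.zeros(n)
    if cfg.relation == "linear":
        expected = cfg.beta0 + cfg.beta1 * diam
    else:
        expected = cfg.exp_y0 + cfg.exp_a * np.exp(cfg.exp_b * diam)
    gdd = expected + eps

    height = _lognormal(rng, 8.0, 0.5, n)          # m
    leaf_len = _lognormal(rng, 10.0, 0.4, n)       # cm

    traits = pd.DataFrame({
        "species_id": labels,
        "porosity": porosity,
        "mean_vessel_diameter": diam,
        "leafout_gdd": gdd,
        "height_m": height,
        "max_leaf_length_cm": leaf_len,
    })
    if weather is not None:
        from .phenology import cumulative_degree_days

        year = int(weather["year"].min())
        cum = cumulative_degree_days(weather, year)
        doy = np.array([
            int(cum.index[np.searchsorted(cum.to_numpy(), g)])
            if g <= cum.iloc[-1] else int(cum.index[-1])
            for g in gdd
        ])
        traits["leafout_doy"] = doy
    truth = {
        "relation": cfg.relation,
        "beta0": cfg.beta0,
        "beta1": cfg.beta1,
        "exp_y0": cfg.exp_y0,
        "exp_a": cfg.exp_a,
        "exp_b": cfg.exp_b,
        "resid_sd": cfg.resid_sd,
        "lambda_true": cfg.lambda_true,
        "species_diameters": dict(zip(labels, diam.tolist())),
    }
    return traits, truth


def simulate_weather(cfg: SynthConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Multi-year daily temperature normals: sinusoidal cycle plus noise.

    Daily mean temperature follows
    ``tmid - amp * cos(2 pi (doy - 15) / 365)`` with Gaussian noise; the
    daily minimum sits ``tmin_offset`` below it with its own noise.  Deep
    winter is reliably below freezing and spring frost dates become
    progressively rarer as the cycle climbs, which is what makes the
    freeze-safe-date scan meaningful.
    """
    if cfg.n_weather_years < 1:
        raise ValueError("need at least one weather year")
    rng = rng or np.random.default_rng(cfg.seed)
    doy = np.arange(1, 366)
    frames = []
    for y in range(cfg.n_weather_years):
        base = cfg.weather_tmid - cfg.weather_amp * np.cos(
            2 * np.pi * (doy - 15) / 365.0)
        tmean = base + rng.normal(0.0, cfg.weather_noise_sd, doy.size)
        tmin = tmean - cfg.tmin_offset + rng.normal(
            0.0, cfg.weather_noise_sd / 2.0, doy.size)
        frames.append(pd.DataFrame({
            "year": 2006 + y, "doy": doy, "tmean_c": tmean, "tmin_c": tmin,
        }))
    out = pd.concat(frames, ignore_index=True)
    out["date"] = (pd.to_datetime(out["year"].astype(str) + "-01-01")
                   + pd.to_timedelta(out["doy"] - 1, unit="D")).dt.date
    return out[["date", "year", "doy", "tmin_c", "tmean_c"]]


@dataclass
class GardenData:
    """One simulated garden: data tables, tree, and the ground-truth sidecar."""

    config: SynthConfig
    tree: dendropy.Tree
    traits: pd.DataFrame
    vessels: pd.DataFrame
    weather: pd.DataFrame
    areas: pd.DataFrame
    truth: dict = field(repr=False)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.vessels.to_csv(out / "vessels.csv", index=False)
        self.traits.to_csv(out / "traits.csv", index=False)
        self.weather.to_csv(out / "weather.csv", index=False)
        self.areas.to_csv(out / "areas.csv", index=False)
        write_tree(self.tree, out / "tree.nwk")
        (out / "truth.json").write_text(json.dumps(
            {"config": asdict(self.config), **self.truth}, indent=2,
            default=float))


# dye-perfusion emulation: diffuse-porous stems rely heavily on previous-year
# vessels at leaf out, ring-porous stems hardly at all
_DYE_PROB = {"diffuse": 0.85, "semi-ring": 0.55, "ring": 0.30}
_FUNCTIONAL_FRACTION = {"diffuse": 0.80, "semi-ring": 0.45, "ring": 0.10}


def simulate_garden(cfg: SynthConfig) -> GardenData:
    """Generate a complete garden: tree, traits, stems/vessels, weather.

    A single seed fans out into independent child streams for each stage, so
    the same config is byte-identical on rerun and changing one stage's
    draws does not perturb the others.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_tree, rng_traits, rng_vessels, rng_weather, rng_dye = (
        np.random.default_rng(s) for s in streams)
    tree = simulate_tree(cfg, rng_tree)
    weather = simulate_weather(cfg, rng_weather)
    traits, truth = simulate_traits(cfg, tree, rng_traits, weather=weather)

    rows = []
    class_means = {p: cfg.class_mean_diameter(p) for p in POROSITY_CLASSES}
    for _, sp in traits.iterrows():
        species_scale = sp["mean_vessel_diameter"] / class_means[sp["porosity"]]
        for s in range(cfg.n_stems_per_species):
            stem_scale = species_scale * _lognormal(
                rng_vessels, 1.0, cfg.stem_diam_cv, 1)[0]
            d = simulate_vessels(cfg, sp["porosity"], scale=stem_scale,
                                 rng=rng_vessels)
            stem_id = f"{sp['species_id']}_s{s + 1}"
            rows.append(pd.DataFrame({
                "stem_id": stem_id,
                "species_id": sp["species_id"],
                "porosity": sp["porosity"],
                "ring_year": 1,
                "diameter_um": d,
            }))
    vessels = pd.concat(rows, ignore_index=True)

    # dye flags per vessel and previous-year cross-section areas per stem
    prob = vessels["porosity"].map(_DYE_PROB).to_numpy(float)
    vessels["dyed"] = rng_dye.random(len(vessels)) < prob
    area_rows = []
    for (stem_id, porosity), _ in vessels.groupby(["stem_id", "porosity"],
                                                  observed=True):
        total = _lognormal(rng_dye, 3.0, 0.3, 1)[0]  # mm²
        frac = np.clip(_FUNCTIONAL_FRACTION[porosity]
                       + rng_dye.normal(0.0, 0.08), 0.0, 1.0)
        area_rows.append({
            "stem_id": stem_id,
            "xylem_area_total_prev_year_mm2": total,
            "xylem_area_dyed_prev_year_mm2": total * frac,
            "density_per_mm2": _lognormal(rng_dye, 80.0, 0.2, 1)[0],
        })
    areas = pd.DataFrame(area_rows)
    return GardenData(config=cfg, tree=tree, traits=traits, vessels=vessels,
                      weather=weather, areas=areas, truth=truth)
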