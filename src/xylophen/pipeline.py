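"""End-to-end orchestration: simulate -> anatomy -> phenology -> hydraulics
-> comparative, with a reproducibility manifest.

One global seed fans out deterministically to the per-stage generators, so a
rerun with the same config is identical; every output directory carries a
``manifest.json`` recording the seed and a hash of the configuration that
produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anatomy import species_summary
from .comparative import (
    anova_tukey,
    blomberg_k,
    fit_exponential,
    lrt_lambda_zero,
    ols_fit,
    pagel_lambda_signal,
    pgls_fit,
    select_model,
)
from .hydraulics import WaterProperties, conductivity_table
from .phenology import freeze_safe_date
from .synth import GardenData, SynthConfig, simulate_garden

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    outdir: str = "results"
    seed: int = 0
    freeze_prob: float = 0.10
    embolism_threshold_um: float = 30.0
    alpha_letters: float = 0.01     # Tukey letter display
    alpha_interaction: float = 0.05
    n_signal_randomizations: int = 999
    water: WaterProperties = field(default_factory=WaterProperties)
    synth: SynthConfig = field(default_factory=SynthConfig)
    run_signal_tests: bool = True
    run_hydraulics: bool = True

    def config_hash(self) -> str:
        # identifies the analysis configuration; where it is written is not
        # part of the science
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    outdir: Path
    garden: GardenData
    traits: pd.DataFrame
    conductivity: pd.DataFrame | None
    fits: dict
    signal: dict
    manifest: dict


def _fit_to_dict(fit) -> dict:
    return {
        "names": fit.names,
        "coef": [float(v) for v in fit.params],
        "se": [float(v) for v in fit.bse],
        "p": [float(v) for v in fit.pvalues],
        "fstat": float(fit.fstat),
        "df": [fit.df_num, fit.df_den],
        "r2": float(fit.r2),
        "loglik": float(fit.loglik),
        "aic": float(fit.aic),
        "lambda_hat": fit.lambda_hat,
        "n": fit.n,
        "method": fit.method,
    }


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full synthetic-garden analysis and write all outputs.

    Stages run in order and a failure names its stage; outputs written
    before the failure are preserved for inspection.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        synth_cfg = cfg.synth
        if synth_cfg.seed != cfg.seed:
            synth_cfg = SynthConfig(**{**asdict(synth_cfg), "seed": cfg.seed})
        garden = simulate_garden(synth_cfg)
        garden.write(out / "inputs")

        stage = "anatomy"
        traits = species_summary(
            garden.vessels,
            garden.traits[["species_id", "leafout_doy", "leafout_gdd",
                           "height_m", "max_leaf_length_cm"]]
            .rename(columns={"leafout_doy": "leafout_doy",
                             "leafout_gdd": "leafout_gdd"}),
            threshold_um=cfg.embolism_threshold_um,
        )
        traits.to_csv(out / "traits.csv", index=False)

        stage = "phenology"
        freeze = freeze_safe_date(garden.weather, prob=cfg.freeze_prob)

        stage = "hydraulics"
        conductivity = None
        if cfg.run_hydraulics:
            conductivity = conductivity_table(garden.vessels, garden.areas,
                                              cfg.water)
            conductivity.to_csv(out / "conductivity.csv", index=False)

        stage = "comparative"
        y = traits["leafout_gdd"].to_numpy(float)
        taxa = list(traits["species_id"])
        diam = traits["mean_vessel_diameter"].to_numpy(float)
        height = traits["height_m"].to_numpy(float)
        candidates = [
            ols_fit(y, diam, names=["diam"], response="leafout_gdd"),
            ols_fit(y, height, names=["height"], response="leafout_gdd"),
            ols_fit(y, np.column_stack([diam, height]),
                    names=["diam", "height"], response="leafout_gdd"),
        ]
        best, aic_table = select_model(candidates)
        aic_table.to_csv(out / "aic_table.csv", index=False)

        pgls = pgls_fit(y, diam, garden.tree, taxa, lam="ml",
                        names=["diam"], response="leafout_gdd")
        pgls0 = pgls_fit(y, diam, garden.tree, taxa, lam=0.0,
                         names=["diam"], response="leafout_gdd")
        lrt_stat, lrt_p = lrt_lambda_zero(pgls, pgls0)

        fits = {
            "ols_best": _fit_to_dict(best),
            "pgls": _fit_to_dict(pgls),
            "pgls_lambda0": _fit_to_dict(pgls0),
            "lrt_lambda_zero": {"statistic": lrt_stat, "p": lrt_p},
            "freeze_safe_doy": freeze.safe_doy,
        }
        if synth_cfg.relation == "exponential":
            fits["exponential"] = fit_exponential(diam, y)

        anova = anova_tukey(
            traits.rename(columns={"mean_vessel_diameter": "diam"}),
            value="diam", group="porosity", alpha=cfg.alpha_letters,
        ) if traits["porosity"].nunique() >= 2 else None
        if anova is not None:
            fits["anova_porosity"] = {
                "fstat": anova.fstat, "p": anova.pvalue,
                "letters": anova.letters,
            }
        (out / "fits.json").write_text(json.dumps(fits, indent=2, default=float))

        stage = "signal"
        signal = {}
        if cfg.run_signal_tests:
            rng = np.random.default_rng(
                np.random.SeedSequence(cfg.seed).spawn(6)[5])
            trait_map = dict(zip(taxa, y))
            diam_map = dict(zip(taxa, diam))
            for name, tm in (("leafout_gdd", trait_map), ("diam", diam_map)):
                k = blomberg_k(tm, garden.tree,
                               n_rand=cfg.n_signal_randomizations, rng=rng)
                lam = pagel_lambda_signal(tm, garden.tree)
                signal[name] = {
                    "blomberg_K": k.statistic, "K_p": k.pvalue,
                    "pagel_lambda": lam.statistic, "lambda_p": lam.pvalue,
                }
            (out / "signal.json").write_text(
                json.dumps(signal, indent=2, default=float))

        stage = "manifest"
        manifest = {
            "package": "xylophen",
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": json.loads(json.dumps(asdict(cfg), default=str)),
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    return PipelineResult(outdir=out, garden=garden, traits=traits,
                          conductivity=conductivity, fits=fits,
                          signal=signal, manifest=manifest)
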