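"""End-to-end orchestration: synthetic (or file) inputs to analysis tables.

``run_pipeline`` composes the modules in measurement order — optical
embolism quantification, vulnerability-curve fitting, Pressure-Volume trait
extraction, safety margins and predicted percent embolism, damage statistics,
and the precipitation index — and emits the same tables the field study
reports: species vulnerability curves, PV traits, safety margins,
single-trait linear models, GLM model rankings, and an SPI trace.

Every run is deterministic given the seed (independent substreams per stage),
and a :class:`RunReport` records per-stage record counts and every warning
(poorly constrained fits, saturated-regime GLMs, response clamps) — no row is
dropped silently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hydraulics, optical, spi as spi_mod, stats as dstats, vulnerability
from .io import read_table, write_table
from .pressure_volume import closed_form_tlp, pv_traits_table
from .reference import PERIODS, REFERENCE_TRAITS
from .synthetic import (
    DAMAGE_METRICS,
    GeneratorConfig,
    SpeciesParams,
    gen_damage_survey,
    gen_embolism_campaign,
    gen_field_campaign,
    gen_precip,
    gen_pv_series,
)

GLM_PREDICTORS = ["p50", "tlp", "eps", "psi_osm", "lma", "height", "huber", "ppe"]

#: log-scale coefficients of the default damage generative model; signs chosen
#: so that more vulnerable xylem / less negative TLP produce more damage
DEFAULT_DAMAGE_COEFS = {
    "crown_extent": {"intercept": 3.8, "p50": -0.10},
    "foliage": {"intercept": 4.5, "ppe": -0.008},
    "dead_leaves": {"intercept": 3.4, "p50": 0.35},
    "discoloration": {"intercept": 4.8, "tlp": 0.45},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def default_species_params() -> list[SpeciesParams]:
    """The six-species thicket community, parameterised from the published traits."""
    params = []
    for name, row in REFERENCE_TRAITS.iterrows():
        params.append(
            SpeciesParams(
                name=name,
                a=row["slope_a"],
                b=row["p50"],
                psi_osm_ft=row["psi_osm"],
                eps=row["eps"],
                psi_min_by_period={
                    PERIODS[0]: (row["psi_min_2020"], row["psi_min_2020_sd"]),
                    PERIODS[1]: (row["psi_min_2022"], row["psi_min_2022_sd"]),
                },
                damage_coefs=DEFAULT_DAMAGE_COEFS,
                lma=row["lma"],
                height=row["height"],
                huber=row["huber"],
            )
        )
    return params


@dataclass
class PipelineConfig:
    species: list[SpeciesParams] = field(default_factory=default_species_params)
    periods: tuple[str, ...] = PERIODS
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    n_leaves: int = 3  # leaves per species for OV and PV campaigns
    n_trees: int = 10  # individuals per species in the damage survey
    damage_noise_sd: float = 3.0  # percent, per observer
    r2_min: float = 0.99
    min_event_size: int = 0
    max_size_quantile: float = 1.0
    max_k: int = 3
    vif_threshold: float = 10.0
    spi_window: int = 12
    out_dir: str | Path | None = None
    #: optional file inputs replacing generation: keys "field", "precip",
    #: "damage" map to CSV paths; missing files abort with the stage name
    inputs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.periods:
            raise ValueError("periods must be nonempty")
        if not 0 < self.r2_min <= 1:
            raise ValueError("r2_min must be in (0, 1]")
        if self.max_k < 1 or self.vif_threshold <= 0:
            raise ValueError("invalid selection thresholds")


@dataclass
class StageRecord:
    name: str
    n_records: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    stages: list[StageRecord] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    version: str = ""

    def add(self, name: str, n: int, warnings: list[str] | None = None):
        self.stages.append(StageRecord(name, n, warnings or []))

    @property
    def all_warnings(self) -> list[str]:
        return [w for s in self.stages for w in s.warnings]


def _config_echo(cfg: PipelineConfig) -> dict:
    echo = dataclasses.asdict(cfg)
    echo["out_dir"] = str(cfg.out_dir) if cfg.out_dir else None
    return json.loads(json.dumps(echo, default=str))


def _true_trait_table(cfg: PipelineConfig, period: str) -> pd.DataFrame:
    """Ground-truth species trait table driving the damage generative model."""
    rows = []
    for sp in cfg.species:
        mean_psi, _ = sp.psi_min_by_period[period]
        rows.append(
            {
                "species": sp.name,
                "p50": sp.b,
                "tlp": sp.tlp_true,
                "eps": sp.eps,
                "psi_osm": sp.psi_osm_ft,
                "lma": sp.lma,
                "height": sp.height,
                "huber": sp.huber,
                "ppe": vulnerability.sigmoid_pe(mean_psi, sp.a, sp.b),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> tuple[RunReport, dict[str, pd.DataFrame]]:
    """Run the full analysis; returns (report, tables) and writes CSVs if configured.

    Tables: vc_fits, species_curves, pv_traits, pv_species, field, margins,
    damage, damage_tests, lm_results, model_ranking, best_models, precip, spi.
    """
    report = RunReport(config=_config_echo(cfg))
    from . import __version__

    report.version = __version__
    tables: dict[str, pd.DataFrame] = {}
    root = np.random.SeedSequence(cfg.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["ov", "pv", "field", "damage", "precip"], root.spawn(5)
        )
    }

    # ------------------------------------------------------------------ OV
    stage = "optical_embolism"
    warns: list[str] = []
    fits_rows = []
    fits_by_species: dict[str, list[vulnerability.SigmoidFit]] = {}
    try:
        for sp in cfg.species:
            fits_by_species[sp.name] = []
            for leaf in range(1, cfg.n_leaves + 1):
                events, psych, meta = gen_embolism_campaign(
                    sp, cfg.generator, rng=streams["ov"]
                )
                trace = optical.trace_from_events(
                    events,
                    psych,
                    min_size=cfg.min_event_size,
                    max_size_quantile=cfg.max_size_quantile,
                )
                fit = vulnerability.fit_sigmoid(
                    trace["psi_mpa"], trace["cum_pct"],
                    n_events=meta["n_events"],
                )
                if fit.poorly_constrained:
                    warns.append(
                        f"poorly constrained fit: {sp.name} leaf{leaf}"
                    )
                fits_by_species[sp.name].append(fit)
                fits_rows.append(
                    {
                        "species": sp.name,
                        "leaf_id": f"{sp.name}_leaf{leaf}",
                        "a": fit.a,
                        "b": fit.b,
                        "b_se": fit.b_se,
                        "rss": fit.rss,
                        "n_points": fit.n_points,
                        "converged": fit.converged,
                    }
                )
    except Exception as err:
        raise PipelineError(stage, str(err)) from err
    tables["vc_fits"] = pd.DataFrame(fits_rows)
    report.add(stage, len(fits_rows), warns)

    # ------------------------------------------------------------------ VC
    stage = "vulnerability_curves"
    try:
        curves = {
            name: vulnerability.species_curve(fits, species=name)
            for name, fits in fits_by_species.items()
        }
    except Exception as err:
        raise PipelineError(stage, str(err)) from err
    tables["species_curves"] = pd.DataFrame(
        [dataclasses.asdict(c) for c in curves.values()]
    ).rename(columns={"n_individuals": "n"})
    report.add(stage, len(curves))

    # ------------------------------------------------------------------ PV
    stage = "pressure_volume"
    pv_rows = []
    try:
        for sp in cfg.species:
            for leaf in range(1, cfg.n_leaves + 1):
                table, meta = gen_pv_series(
                    sp, cfg.generator, rng=streams["pv"],
                    leaf_id=f"{sp.name}_leaf{leaf}",
                )
                traits = pv_traits_table(
                    table, dry_mass=meta["dry_mass"], r2_min=cfg.r2_min
                )
                traits.insert(0, "species", sp.name)
                pv_rows.append(traits)
        pv_traits = pd.concat(pv_rows, ignore_index=True)
    except Exception as err:
        raise PipelineError(stage, str(err)) from err
    pv_species = (
        pv_traits.groupby("species", sort=False)
        .agg(
            tlp=("tlp", "mean"),
            tlp_se=("tlp", "sem"),
            psi_osm_ft=("psi_osm_ft", "mean"),
            eps=("eps", "mean"),
            n=("tlp", "size"),
        )
        .reset_index()
    )
    tables["pv_traits"] = pv_traits
    tables["pv_species"] = pv_species
    report.add(stage, len(pv_traits))

    # --------------------------------------------------------------- field
    stage = "field_campaign"
    try:
        if "field" in cfg.inputs:
            field_df = read_table(
                cfg.inputs["field"],
                required=["species", "individual", "period", "psi_md_mpa"],
                numeric=["psi_md_mpa"],
            )
        else:
            field_df = gen_field_campaign(
                cfg.species, cfg.periods, cfg.generator, rng=streams["field"]
            )
    except Exception as err:
        raise PipelineError(stage, str(err)) from err
    tables["field"] = field_df
    report.add(stage, len(field_df))

    # ------------------------------------------------------------- margins
    stage = "safety_margins"
    try:
        margins = hydraulics.safety_margin_table(curves, pv_species, field_df)
    except Exception as err:
        raise PipelineError(stage, str(err)) from err
    tables["margins"] = margins
    report.add(stage, len(margins))

    # -------------------------------------------------------------- damage
    stage = "damage_survey"
    warns = []
    try:
        if "damage" in cfg.inputs:
            damage = read_table(
                cfg.inputs["damage"],
                required=["species", "individual", "period", *DAMAGE_METRICS],
                numeric=list(DAMAGE_METRICS),
            )
        else:
            frames = []
            for period in cfg.periods:
                traits_true = _true_trait_table(cfg, period)
                per_tree = traits_true.loc[
                    traits_true.index.repeat(cfg.n_trees)
                ].reset_index(drop=True)
                per_tree["individual"] = np.tile(
                    np.arange(1, cfg.n_trees + 1), len(traits_true)
                )
                surveyed = gen_damage_survey(
                    per_tree,
                    cfg.species[0].damage_coefs or DEFAULT_DAMAGE_COEFS,
                    noise_sd=cfg.damage_noise_sd,
                    cfg=cfg.generator,
                    rng=streams["damage"],
                )
                surveyed["period"] = period
                frames.append(
                    surveyed[["species", "individual", "period", *DAMAGE_METRICS]]
                )
            damage = pd.concat(frames, ignore_index=True)
    except Exception as err:
        raise PipelineError(stage, str(err)) from err
    tables["damage"] = damage

    # paired period comparisons per species and metric
    test_rows = []
    if len(cfg.periods) >= 2:
        p1, p2 = cfg.periods[0], cfg.periods[1]
        for sp_name, grp in damage.groupby("species", sort=False):
            wide = grp.pivot_table(
                index="individual", columns="period", values=list(DAMAGE_METRICS)
            )
            for metric in DAMAGE_METRICS:
                try:
                    t, p = dstats.paired_t(wide[(metric, p1)], wide[(metric, p2)])
                except (ValueError, KeyError) as err:
                    warns.append(f"paired test skipped ({sp_name}/{metric}): {err}")
                    continue
                test_rows.append(
                    {"species": sp_name, "metric": metric, "t": t, "p_value": p}
                )
    tables["damage_tests"] = pd.DataFrame(test_rows)
    report.add(stage, len(damage), warns)

    # ------------------------------------------------------ trait statistics
    stage = "trait_statistics"
    warns = []
    # estimated species-level trait table joining every upstream product
    est = (
        tables["species_curves"][["species", "a_mean", "b_mean"]]
        .rename(columns={"b_mean": "p50"})
        .merge(pv_species[["species", "tlp", "psi_osm_ft", "eps"]], on="species")
        .rename(columns={"psi_osm_ft": "psi_osm"})
    )
    morph = pd.DataFrame(
        {
            "species": [sp.name for sp in cfg.species],
            "lma": [sp.lma for sp in cfg.species],
            "height": [sp.height for sp in cfg.species],
            "huber": [sp.huber for sp in cfg.species],
        }
    )
    est = est.merge(morph, on="species")

    lm_rows = []
    try:
        res = dstats.fit_lm_single(np.log(est["eps"]), est["tlp"])
        lm_rows.append(
            {
                "response": "tlp",
                "predictor": "log_eps",
                "period": "",
                "slope": res.slope,
                "r2": res.r2,
                "p_value": res.p_value,
                "n": res.n,
            }
        )
    except ValueError as err:
        warns.append(f"tlp~log(eps) skipped: {err}")

    damage_means = (
        damage.groupby(["species", "period"])[list(DAMAGE_METRICS)]
        .mean()
        .reset_index()
    )
    rankings = []
    best_rows = []
    for period in cfg.periods:
        ppe_period = margins.loc[
            margins["period"] == period, ["species", "ppe_mean"]
        ].rename(columns={"ppe_mean": "ppe"})
        traits_period = est.merge(ppe_period, on="species")
        dmg = damage_means[damage_means["period"] == period]
        merged = traits_period.merge(dmg, on="species")
        for metric in DAMAGE_METRICS:
            try:
                res = dstats.fit_lm_single(merged["ppe"], merged[metric])
                lm_rows.append(
                    {
                        "response": metric,
                        "predictor": "ppe",
                        "period": period,
                        "slope": res.slope,
                        "r2": res.r2,
                        "p_value": res.p_value,
                        "n": res.n,
                    }
                )
            except ValueError as err:
                warns.append(f"lm {metric}~ppe skipped ({period}): {err}")
            try:
                ranking = dstats.run_model_selection(
                    merged[metric],
                    merged[GLM_PREDICTORS],
                    max_k=cfg.max_k,
                    vif_threshold=cfg.vif_threshold,
                )
            except ValueError as err:
                warns.append(f"GLM selection failed ({period}/{metric}): {err}")
                continue
            tab = dstats.ranking_table(ranking)
            tab.insert(0, "metric", metric)
            tab.insert(0, "period", period)
            rankings.append(tab)
            if any(f.saturated for f in ranking.fits):
                warns.append(f"saturated-regime fits in {period}/{metric}")
            best = ranking.best
            best_rows.append(
                {
                    "period": period,
                    "metric": metric,
                    "formula": "+".join(best.formula),
                    "aic": best.aic,
                    "akaike_weight": best.akaike_weight,
                    "mcfadden_r2": best.mcfadden_r2,
                    "deviance_explained": best.deviance_explained,
                    "max_vif": best.max_vif,
                    "saturated": best.saturated,
                }
            )
    tables["lm_results"] = pd.DataFrame(lm_rows)
    tables["model_ranking"] = (
        pd.concat(rankings, ignore_index=True) if rankings else pd.DataFrame()
    )
    tables["best_models"] = pd.DataFrame(best_rows)
    report.add(stage, len(tables["model_ranking"]), warns)

    # ----------------------------------------------------------------- SPI
    stage = "climate_spi"
    try:
        if "precip" in cfg.inputs:
            precip = read_table(
                cfg.inputs["precip"],
                required=["year", "month", "mm"],
                numeric=["mm"],
            )
        else:
            precip = gen_precip(
                cfg.generator,
                rng=streams["precip"],
                drought_block=(12 * (cfg.generator.n_years - 3), 12),
            )
        spi_table = spi_mod.spi_series(precip, window=cfg.spi_window)
    except Exception as err:
        raise PipelineError(stage, str(err)) from err
    tables["precip"] = precip
    tables["spi"] = spi_table
    report.add(stage, len(spi_table))

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            write_table(df, out / f"{name}.csv")
        (out / "run_report.json").write_text(
            json.dumps(
                {
                    "version": report.version,
                    "stages": [dataclasses.asdict(s) for s in report.stages],
                    "config": report.config,
                },
                indent=2,
            )
        )
    return report, tables
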