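"""Configuration-driven orchestration of the full two-stage pipeline.

Stages: simulate (synthetic world + surveys) -> stage 1 (bias-model fits and
holdout validation) -> imputation -> cell building -> stage 2 (small-area
fits per sex x outcome x imputation) -> post-estimation (standardised
county-year estimates and summaries) -> validation. Every stage writes its
tables under the output directory and the run ends with a JSON manifest
listing outputs, content hashes, seeds, and diagnostics. A single global
seed is expanded into independent per-stage substreams, so identical
configs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bias import default_spec_set, fit_bias_models, holdout_accuracy, impute_uncontrolled
from .postestimate import (
    StandardPopulation,
    summarize_counties,
    summarize_draws,
    within_state_spread,
)
from .smallarea import (
    SmallAreaSpec,
    build_cells,
    complete_cell_grid,
    fit_small_area,
    predict_cells,
)
from .synthetic import (
    World,
    WorldConfig,
    generate_world,
    sample_exam_survey,
    sample_phone_survey,
)
from .validation import (
    pooled_gold_standard,
    reports_to_frame,
    single_year_direct,
    validate_by_sample_size,
)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    world: dict = field(default_factory=dict)
    n_exam: int = 20_000
    n_phone_per_county_year: int = 20
    n_imputations: int = 2
    holdout_k: int = 5
    outcomes: tuple[str, ...] = ("self_report", "prevalence", "awareness", "treatment", "control")
    sexes: tuple[str, ...] = ("male", "female")
    smallarea: dict = field(default_factory=dict)
    validation: dict | None = field(
        default_factory=lambda: {"min_n": 50, "bins": [[0, 10], [10, float("inf")]]}
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def world_config(self, seed: int) -> WorldConfig:
        return WorldConfig(seed=seed, **self.world)


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(ss.generate_state(1)[0] % (2**31))
        for name, ss in zip(names, children)
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    skip_validation: bool = False,
    stop_after: str | None = None,
) -> dict:
    """Execute the pipeline end to end; returns the output manifest.

    ``stop_after`` names a stage (simulate, stage1, impute, stage2,
    postprocess, validate) after which the run ends, for partial reruns.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(
        config.seed, ["world", "exam", "phone", "holdout", "impute", "stage2"]
    )
    manifest: dict = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "seeds": seeds,
        "stages": [],
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame):
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)

    def finish_stage(name: str) -> bool:
        manifest["stages"].append(name)
        _write_manifest(manifest, written, outdir)
        return stop_after == name

    def done() -> dict:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        _write_manifest(manifest, written, outdir)
        return manifest

    try:
        stage = "simulate"
        world = generate_world(config.world_config(seeds["world"]))
        world.save(outdir / "world")
        written.extend((outdir / "world").glob("*"))
        exam = sample_exam_survey(world, config.n_exam, seeds["exam"])
        phone = sample_phone_survey(world, config.n_phone_per_county_year, seeds["phone"])
        emit("exam_survey.csv", exam)
        emit("phone_survey.csv", phone.records)
        if finish_stage(stage):
            return done()

        stage = "stage1"
        spec_set = default_spec_set(world.config.waves)
        fits = fit_bias_models(exam, spec_set)
        accuracy = holdout_accuracy(
            exam, spec_set, k=config.holdout_k, seed=seeds["holdout"]
        )
        fit_path = outdir / "stage1_fits.json"
        fit_path.write_text(
            json.dumps(
                {
                    "models": [f.to_dict() for f in fits.values()],
                    "holdout_accuracy": {
                        "overall": accuracy.overall,
                        "per_stratum": {
                            f"{s[0]}|{'diagnosed' if s[1] else 'never'}": v
                            for s, v in accuracy.per_stratum.items()
                        },
                        "replicates": accuracy.replicates,
                        "range": list(accuracy.replicate_range),
                    },
                },
                indent=2,
            )
        )
        written.append(fit_path)
        if finish_stage(stage):
            return done()

        stage = "impute"
        imputed = impute_uncontrolled(
            phone.records, fits, M=config.n_imputations, seed=seeds["impute"]
        )
        stacked = pd.concat(
            [d.records.assign(imputation=d.m) for d in imputed], ignore_index=True
        )
        emit("imputed_phone.csv", stacked)
        if finish_stage(stage):
            return done()

        stage = "stage2"
        estimates, fit_diagnostics = estimate_county_year(
            world, imputed, config, seeds["stage2"]
        )
        emit("county_estimates.csv", estimates)
        diag_path = outdir / "stage2_diagnostics.json"
        diag_path.write_text(json.dumps(fit_diagnostics, indent=2))
        written.append(diag_path)
        if finish_stage(stage):
            return done()

        stage = "postprocess"
        emit("summary_by_sex_year.csv", summarize_counties(estimates, by=["sex", "year"]))
        state_map = dict(
            zip(world.county_table["county_id"], world.county_table["state_id"])
        )
        emit("within_state_spread.csv", within_state_spread(estimates, state_map))
        if finish_stage(stage):
            return done()

        if config.validation is not None and not skip_validation:
            stage = "validate"
            emit("validation.csv", _validate(world, imputed, estimates, config))
            finish_stage(stage)
    except Exception as err:  # persist what completed, then surface the stage
        _write_manifest(manifest, written, outdir)
        raise PipelineStageError(stage, err) from err

    return done()


def _write_manifest(manifest: dict, written: list[Path], outdir: Path) -> None:
    manifest["outputs"] = {
        str(p.relative_to(outdir)): _sha256(p) for p in written if p.is_file()
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def estimate_county_year(
    world: World,
    imputed: list,
    config: PipelineConfig,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Fit stage 2 per sex x outcome x imputation and post-process draws.

    Returns the tidy county-year estimate table (age-standardised to the
    world's own standard population, race-weighted by county shares) and a
    dict of MCMC diagnostics per fit.
    """
    cfg_world = world.config
    age_labels = cfg_world.age_group_labels()
    races = list(cfg_world.race_levels)
    county_ids = np.sort(world.county_table["county_id"].to_numpy())
    years = np.asarray(cfg_world.years)
    std = StandardPopulation(world.standard_population())
    std_w = np.array([std.weights[a] for a in age_labels])
    shares_df = world.race_shares()
    C, T, A, R = len(county_ids), len(years), len(age_labels), len(races)
    share_mat = shares_df.loc[county_ids, races].to_numpy()  # (C, R)

    sa_kwargs = dict(config.smallarea)
    diagnostics: dict = {}
    frames = []
    fit_seed_root = np.random.SeedSequence(seed)
    for sex in config.sexes:
        for outcome in config.outcomes:
            pooled = []
            for dset in imputed:
                sub = dset.records.loc[dset.records["sex"] == sex]
                cells = build_cells(sub, outcome, cfg_world.age_groups)
                fit_seed = int(fit_seed_root.spawn(1)[0].generate_state(1)[0] % 2**31)
                spec = SmallAreaSpec(outcome=outcome, seed=fit_seed, **sa_kwargs)
                fit = fit_small_area(cells, world.county_table, world.adjacency, spec)
                grid = complete_cell_grid(county_ids, years, sex, age_labels, races)
                probs = predict_cells(fit, grid, world.county_table)
                pooled.append(probs.reshape(-1, C, T, A, R))
                diagnostics[f"{sex}|{outcome}|m{dset.m}"] = {
                    k: v
                    for k, v in fit.diagnostics.items()
                    if not isinstance(v, np.ndarray)
                }
            draws = np.concatenate(pooled, axis=0)  # (Dtot, C, T, A, R)
            by_race = np.einsum("dctar,a->dctr", draws, std_w)
            county_year = np.einsum("dctr,cr->dct", by_race, share_mat)
            meta = pd.DataFrame(
                [(c, y) for c in county_ids for y in years],
                columns=["county_id", "year"],
            )
            meta["sex"] = sex
            frames.append(
                summarize_draws(
                    county_year.reshape(len(draws), -1), meta, outcome
                )
            )
    return pd.concat(frames, ignore_index=True), diagnostics


def _validate(
    world: World, imputed: list, estimates: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Model-vs-gold and direct-vs-gold comparison on total prevalence."""
    vcfg = dict(config.validation or {})
    years = np.asarray(world.config.years)
    window = tuple(vcfg.get("window", (int(years.min()), int(years.max()))))
    # central-year rule, snapped to the nearest year actually sampled
    central_year = vcfg.get(
        "central_year",
        int(years[np.argmin(np.abs(years - np.mean(window)))]),
    )
    min_n = int(vcfg.get("min_n", 50))
    bins = [tuple(b) for b in vcfg.get("bins", [(0, 10), (10, float("inf"))])]

    from .outcomes import classify_frame

    rec = classify_frame(imputed[0].records)
    rec["in_population"] = rec["in_population"].astype(float)
    gold = pooled_gold_standard(rec, "in_population", window, min_n=min_n)
    direct = single_year_direct(rec, "in_population", central_year)
    model = (
        estimates.loc[
            (estimates["outcome"] == "prevalence")
            & (estimates["year"] == central_year)
        ]
        .groupby("county_id", observed=True)["point"]
        .mean()
        .rename("proportion")
        .reset_index()
    )
    reports = validate_by_sample_size(model, gold, direct, bins)
    return reports_to_frame(reports)
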