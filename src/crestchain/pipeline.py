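"""End-to-end pipeline runner.

A top-level JSON config names an ordered list of stages (synthetic-data
generation, simulation, scoring, track metrics, LDA, cell-cycle analysis,
parameter sweep); each stage may consume a previous stage's declared
output.  All randomness derives from the manifest's master seed by stable
hashing, so reruns with an identical config are reproducible.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import cellcycle as cc
from . import lda as lda_mod
from . import synth
from .errors import ConfigurationError
from .io import (
    RunManifest,
    read_json,
    read_sequences_csv,
    read_track_table,
    read_trajectory_csv,
    write_json,
    write_sequences_csv,
    write_track_table,
    write_trajectory_csv,
)
from .metrics import summarize
from .model import Arena, Composition, ModelParams, simulate
from .scoring import ScoreConfig, score_all
from .seeds import derive_seed
from .sweep import DEFAULT_LEVELS, count_passing, enumerate_grid, run_sweep

__all__ = ["run_pipeline", "STAGE_KINDS"]

STAGE_KINDS = (
    "synth_tracks",
    "synth_cellcycle",
    "synth_areas",
    "simulate",
    "score",
    "metrics",
    "lda",
    "cellcycle",
    "sweep",
)

_NEEDS_INPUT = {"score", "metrics", "lda", "cellcycle"}


def _build_arena(cfg: dict) -> Arena:
    return Arena(**cfg) if cfg else Arena()


def _build_params(cfg: dict) -> ModelParams:
    if not cfg:
        return ModelParams()
    cfg = dict(cfg)
    from .model import Identity

    for key in ("cil_intensity", "cell_radius", "base_speed"):
        if key in cfg:
            cfg[key] = {Identity(k): v for k, v in cfg[key].items()}
    return ModelParams(**cfg)


def _validate_config(config: dict) -> None:
    if "stages" not in config or not isinstance(config["stages"], list):
        raise ConfigurationError("config must contain a 'stages' list")
    names = set()
    for stage in config["stages"]:
        name, kind = stage.get("name"), stage.get("kind")
        if not name or not kind:
            raise ConfigurationError("every stage needs 'name' and 'kind'")
        if kind not in STAGE_KINDS:
            raise ConfigurationError(f"unknown stage kind {kind!r} in {name!r}")
        if name in names:
            raise ConfigurationError(f"duplicate stage name {name!r}")
        if kind in _NEEDS_INPUT:
            ref = stage.get("input")
            if not ref:
                raise ConfigurationError(
                    f"stage {name!r} ({kind}) requires an 'input' stage reference"
                )
            if ref not in names:
                raise ConfigurationError(
                    f"stage {name!r} consumes {ref!r} which is not an earlier stage"
                )
        names.add(name)


def run_pipeline(config, out_dir, master_seed: int | None = None) -> RunManifest:
    """Execute the configured stages in order under ``out_dir``.

    ``config`` is a dict or a path to a JSON file.  Configuration is fully
    validated before any compute; a stage failure raises with the failing
    stage named.
    """
    if not isinstance(config, dict):
        config = read_json(config)
    _validate_config(config)
    seed = int(config.get("seed", 0) if master_seed is None else master_seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    primary: dict[str, Path] = {}  # stage name -> main output file
    outputs: list[Path] = []

    for index, stage in enumerate(config["stages"]):
        name, kind = stage["name"], stage["kind"]
        stage_dir = out_dir / name
        stage_dir.mkdir(exist_ok=True)
        stage_seed = derive_seed(seed, "stage", index, name)
        try:
            main = _run_stage(stage, kind, stage_dir, stage_seed, primary)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} ({kind}) failed: {exc}") from exc
        primary[name] = main
        outputs.append(main)

    manifest = RunManifest.create(
        command="run", config=config, master_seed=seed,
        inputs=[], outputs=outputs,
    )
    manifest.write(out_dir)
    return manifest


def _run_stage(stage, kind, stage_dir: Path, seed: int, primary) -> Path:
    p = stage.get("params", {})
    if kind == "synth_tracks":
        table = synth.gen_tracks(
            n_leaders=int(p.get("n_leaders", 8)),
            n_followers=int(p.get("n_followers", 24)),
            n_frames=int(p.get("n_frames", 192)),
            seed=seed,
        )
        out = stage_dir / "tracks.csv"
        write_track_table(table, out)
        return out
    if kind == "synth_cellcycle":
        sequences = []
        for identity in ("leader", "follower"):
            sequences += synth.gen_phase_sequences(
                identity,
                int(p.get("n_cells", 20)),
                frame_interval=float(p.get("frame_interval", 5.0)),
                seed=derive_seed(seed, identity),
                with_onset=bool(p.get("with_onset", True)),
            )
        out = stage_dir / "sequences.csv"
        write_sequences_csv(sequences, out)
        return out
    if kind == "synth_areas":
        table = synth.gen_division_areas(
            p.get("kind", "asym"), int(p.get("n_pairs", 9)), seed=seed
        )
        out = stage_dir / "areas.csv"
        table.to_csv(out, index=False)
        return out
    if kind == "simulate":
        comp = p.get("composition", "1:3")
        composition = (
            Composition.preset(comp, int(p.get("chain_length", 8)))
            if ":" in comp or comp.replace("-", "_") in
            ("all_leader", "all_follower", "single_leader")
            else Composition.from_string(comp)
        )
        arena = _build_arena(p.get("arena", {}))
        params = _build_params(p.get("model", {}))
        traj = simulate(composition, arena, params, seed=seed)
        out = stage_dir / "trajectory.csv"
        write_trajectory_csv(traj, out)
        return out
    if kind == "score":
        traj = read_trajectory_csv(primary[stage["input"]])
        arena = _build_arena(p.get("arena", {}))
        report = score_all(traj, arena, ScoreConfig(**p.get("score", {})))
        out = stage_dir / "score.json"
        write_json(report.to_dict(), out)
        return out
    if kind == "metrics":
        table = read_track_table(primary[stage["input"]])
        per_cell, aggregates = summarize(table)
        out = stage_dir / "per_cell.csv"
        per_cell.to_csv(out, index=False)
        write_json(aggregates, stage_dir / "aggregates.json")
        return out
    if kind == "lda":
        per_cell = pd.read_csv(primary[stage["input"]])
        features = p.get(
            "features", ["ventral_distance", "mean_speed", "directionality"]
        )
        table = per_cell[features + ["identity"]].dropna()
        model = lda_mod.fit_lda(table)
        model.coefficients().to_csv(stage_dir / "coefficients.csv", index=False)
        out = stage_dir / "lda.json"
        write_json(
            {
                "features": model.features,
                "ranking": lda_mod.rank_features(model),
                "coef_standardized": model.coef_standardized,
                "coef_raw": model.coef_raw,
                "separation": model.separation,
            },
            out,
        )
        return out
    if kind == "cellcycle":
        sequences = read_sequences_csv(
            primary[stage["input"]], frame_interval=float(p.get("frame_interval", 5.0))
        )
        rows = []
        for seq in sequences:
            d = cc.durations_from_states(seq)
            row = {"cell_id": d.cell_id, "identity": d.identity, "total": d.total}
            row.update({ph: d.durations.get(ph) for ph in cc.PHASES})
            rows.append(row)
        durations = pd.DataFrame(rows)
        durations.to_csv(stage_dir / "durations.csv", index=False)

        mixtures = {}
        for identity in durations["identity"].unique():
            for phase in ("G1", "S"):
                sample = durations.loc[
                    durations["identity"] == identity, phase
                ].dropna()
                if len(sample) >= 10:
                    fit = cc.fit_mixture(sample.to_numpy(), seed=seed)
                    mixtures[f"{identity}_{phase}"] = {
                        "k": fit.k,
                        "weights": fit.weights,
                        "means": fit.means,
                        "sds": fit.sds,
                        "minor_weight": fit.minor_weight,
                    }
        write_json(mixtures, stage_dir / "mixtures.json")

        comparisons = {}
        for phase in cc.PHASES:
            groups = [
                durations.loc[durations["identity"] == ident, phase].dropna().to_numpy()
                for ident in ("leader", "follower")
            ]
            if all(len(g) >= 3 for g in groups):
                comparisons[phase] = cc.auto_compare(*groups)
        out = stage_dir / "comparisons.json"
        write_json(comparisons, out)
        return out
    if kind == "sweep":
        composition = Composition.preset(
            p.get("composition", "1:3"), int(p.get("chain_length", 8))
        )
        grid = enumerate_grid(
            DEFAULT_LEVELS,
            p.get("swept", ["cil_intensity", "coattraction", "cell_size"]),
            composition,
        )
        result = run_sweep(
            grid,
            _build_arena(p.get("arena", {})),
            n_reps=int(p.get("n_reps", 20)),
            master_seed=seed,
        )
        result.to_frame().to_csv(stage_dir / "replicates.csv", index=False)
        out = stage_dir / "sweep.json"
        write_json(
            {
                "counts": {
                    s: count_passing(result, s)
                    for s in ("cohesion", "single_file", "follower_rearrangement",
                              "leader_front", "path_completion", "all")
                },
                "combinations": [
                    {k: c[k] for k in ("index", "levels", "composition",
                                       "pass_fractions", "combination_matches")}
                    for c in result.combinations
                ],
            },
            out,
        )
        return out
    raise ConfigurationError(f"unknown stage kind {kind!r}")
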