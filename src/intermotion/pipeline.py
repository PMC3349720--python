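"""Orchestration: generate -> discretize -> analyse, with a click CLI.

A single YAML/JSON config file drives all stages; every stage writes plain
CSV/JSON artifacts plus a run manifest (seed, parameters, per-stage counts)
so any run is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlations import cross_correlation, move_pause_series, partial_autocorrelation
from .discretize import BoutDiscretizer, BoutSequence
from .distfit import pooled_fit, spwmc, gof_test
from .modes import mode_probability_curve, partial_sums_segment, signed_series
from .synthetic import BoutLawParams, GeneratorConfig, PiecewiseLogCurve, generate_cohort
from .turning import default_log_bins, turn_after_pause, turn_influence, turn_probability_curve

__all__ = ["load_config", "run_pipeline", "cli"]

DEFAULTS = {
    "generate": {
        "n_individuals": 5,
        "duration_s": 1800.0,
        "seed": 0,
        "move_law": {"mu": 1.49, "beta": 0.55, "theta": 8.0},
        "pause_law": {"mu": 1.67, "beta": 0.23, "theta": 15.27},
    },
    "discretize": {"move_threshold_cm": 0.3, "edge_margin_cm": 3.0},
    "turning": {},
    "distfit": {"pause_cap_s": 1000.0, "run_gof": False},
    "correlate": {"max_lag": 10},
    "modes": {"epsilon_s": 300.0, "grid_step_s": 300.0},
}


def load_config(path: str | Path | None) -> dict:
    cfg = {k: dict(v) for k, v in DEFAULTS.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, vals in user.items():
            cfg.setdefault(section, {}).update(vals or {})
    return cfg


def _generator_config(gen: dict) -> GeneratorConfig:
    return GeneratorConfig(
        duration=float(gen["duration_s"]),
        move_dist_params=BoutLawParams(**gen["move_law"]),
        pause_dist_params=BoutLawParams(**gen["pause_law"]),
        seed=int(gen["seed"]),
    )


def _stage_generate(cfg: dict, outdir: Path, log: dict) -> None:
    gen = cfg["generate"]
    gc = _generator_config(gen)
    trajs, truths = generate_cohort(gc, int(gen["n_individuals"]), return_truth=True)
    pd.concat([t.to_frame() for t in trajs]).to_csv(outdir / "trajectories.csv", index=False)
    ledger = {t.individual_id: json.loads(tr.to_json()) for t, tr in zip(trajs, truths)}
    (outdir / "ground_truth.json").write_text(json.dumps(ledger))
    log["generate"] = {"n_individuals": len(trajs), "n_frames": int(sum(len(t.times) for t in trajs))}


def _load_sequences(cfg: dict, outdir: Path) -> list[BoutSequence]:
    path = outdir / "trajectories.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing upstream artifact: {path}")
    from .synthetic import Trajectory

    df = pd.read_csv(path)
    disc = BoutDiscretizer(
        move_threshold=cfg["discretize"]["move_threshold_cm"],
        edge_margin=cfg["discretize"]["edge_margin_cm"],
    )
    trajs = [Trajectory.from_frame(g) for _, g in df.groupby("individual_id", sort=True)]
    return disc.transform(trajs)


def _stage_discretize(cfg: dict, outdir: Path, log: dict) -> list[BoutSequence]:
    seqs = _load_sequences(cfg, outdir)
    rows = []
    for seq in seqs:
        for b in seq.bouts:
            d = b.directions
            rows.append(
                {
                    "individual_id": seq.individual_id,
                    "state": b.state,
                    "start_s": b.start_frame * seq.frame_dt,
                    "duration_s": b.duration,
                    "n_turns": int(np.sum(d[1:] != d[:-1])) if len(d) > 1 else 0,
                    "edge_censored": b.edge_censored,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "bouts.csv", index=False)
    kept = sum(1 for r in rows if not r["edge_censored"])
    log["discretize"] = {"bouts_total": len(rows), "bouts_kept": kept}
    return seqs


def _stage_turning(cfg: dict, outdir: Path, seqs: list[BoutSequence], log: dict) -> None:
    durs, turned = [], []
    for seq in seqs:
        d, t = turn_after_pause(seq)
        durs.append(d)
        turned.append(t)
    d = np.concatenate(durs)
    t = np.concatenate(turned)
    bins = default_log_bins(max(float(d.max()) if d.size else 1.0, 1.0))
    curve = turn_probability_curve(d, t, bins)
    infl = turn_influence(curve)
    pd.DataFrame(
        {
            "bin_left_s": curve.bin_edges[:-1],
            "bin_right_s": curve.bin_edges[1:],
            "value": curve.mean_probability,
            "ci_lo": curve.ci_lo,
            "ci_hi": curve.ci_hi,
            "n": curve.n_obs,
            "influence": infl,
        }
    ).to_csv(outdir / "turn_curve.csv", index=False)
    log["turning"] = {"n_pauses_used": int(d.size)}


def _stage_distfit(cfg: dict, outdir: Path, seqs: list[BoutSequence], log: dict) -> None:
    out = {}
    for state in ("move", "pause"):
        pooled = [seq.durations(state) for seq in seqs]
        cap = float(cfg["distfit"]["pause_cap_s"]) if state == "pause" else np.inf
        fit = pooled_fit(pooled, exclusion_cap=cap)
        entry = {
            "Model": fit.model.family,
            "N": fit.n,
            "Max": float(max(float(np.max(p)) for p in pooled if len(p))),
            "mu": fit.params.get("mu"),
            "beta": fit.params.get("beta"),
            "theta": fit.params.get("theta"),
            "x2": fit.params.get("x2"),
            "x3": fit.params.get("x3"),
            "NegLogLik": fit.neg_loglik,
        }
        if cfg["distfit"].get("run_gof"):
            g = gof_test(np.concatenate(pooled), fit, n_boot=int(cfg["distfit"].get("n_boot", 200)))
            entry["GOF"] = g["statistic"]
            entry["p"] = g["p_value"]
        out[state] = entry
        prof = spwmc(np.concatenate([p for p in pooled if len(p)]))
        pd.DataFrame(
            {"truncation_s": prof.truncation_points, "n": prof.n_obs}
            | {f"waic_{f}": prof.waic[:, i] for i, f in enumerate(prof.families)}
        ).to_csv(outdir / f"spwmc_{state}.csv", index=False)
    (outdir / "fits.json").write_text(json.dumps(out, indent=2))
    log["distfit"] = {k: v["N"] for k, v in out.items()}


def _stage_correlate(cfg: dict, outdir: Path, seqs: list[BoutSequence], log: dict) -> None:
    max_lag = int(cfg["correlate"]["max_lag"])
    rows = []
    for seq in seqs:
        for ms, ps in move_pause_series(seq):
            if ms.size <= max_lag + 10:
                continue
            cc = cross_correlation(ms, ps, max_lag)
            pm = partial_autocorrelation(ms, max_lag)
            pp = partial_autocorrelation(ps, max_lag)
            for lag, r in zip(cc["lags"], cc["corr"]):
                rows.append({"individual_id": seq.individual_id, "stat": "xcorr", "lag": int(lag), "value": r})
            for lag, r in zip(pm["lags"], pm["pacf"]):
                rows.append({"individual_id": seq.individual_id, "stat": "pacf_move", "lag": int(lag), "value": r})
            for lag, r in zip(pp["lags"], pp["pacf"]):
                rows.append({"individual_id": seq.individual_id, "stat": "pacf_pause", "lag": int(lag), "value": r})
    pd.DataFrame(rows).to_csv(outdir / "correlations.csv", index=False)
    log["correlate"] = {"n_rows": len(rows)}


def _stage_modes(cfg: dict, outdir: Path, seqs: list[BoutSequence], log: dict) -> None:
    eps = float(cfg["modes"]["epsilon_s"])
    segs = []
    for seq in seqs:
        try:
            segs.append(partial_sums_segment(signed_series(seq), epsilon=eps))
        except ValueError:
            continue  # block shorter than two modes: reported separately
    t_max = max(s.segment_times[-1][1] for s in segs)
    grid = np.arange(0.0, t_max, float(cfg["modes"]["grid_step_s"]))
    curve = mode_probability_curve(segs, grid)
    pd.DataFrame(
        {
            "t_s": curve["t"],
            "p_relocation": curve["p_relocation"],
            "p_local_search": curve["p_local_search"],
            "n": curve["n"],
        }
    ).to_csv(outdir / "mode_probability.csv", index=False)
    log["modes"] = {"n_segmented": len(segs), "n_skipped": len(seqs) - len(segs)}


_STAGES = ("generate", "discretize", "turning", "distfit", "correlate", "modes")


def run_pipeline(
    config_path: str | Path | None,
    outdir: str | Path,
    stages: tuple[str, ...] = _STAGES,
) -> dict:
    """Run the requested stages in order and write artifacts plus a manifest."""
    cfg = load_config(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {}
    seqs: list[BoutSequence] | None = None
    for stage in _STAGES:
        if stage not in stages:
            continue
        if stage == "generate":
            _stage_generate(cfg, outdir, log)
        else:
            if seqs is None:
                seqs = _stage_discretize(cfg, outdir, log) if stage == "discretize" else _load_sequences(cfg, outdir)
            if stage == "discretize" and "discretize" not in log:
                _stage_discretize(cfg, outdir, log)
            elif stage == "turning":
                _stage_turning(cfg, outdir, seqs, log)
            elif stage == "distfit":
                _stage_distfit(cfg, outdir, seqs, log)
            elif stage == "correlate":
                _stage_correlate(cfg, outdir, seqs, log)
            elif stage == "modes":
                _stage_modes(cfg, outdir, seqs, log)
    manifest = {"version": __version__, "config": cfg, "stages": list(stages), "log": log}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


@click.group()
def cli() -> None:
    """Bout-level analysis of intermittent locomotion."""


def _stage_command(name: str):
    @cli.command(name=name)
    @click.option("--config", "config_path", type=click.Path(exists=True), default=None)
    @click.option("--outdir", type=click.Path(), required=True)
    def _cmd(config_path, outdir, _name=name):
        run_pipeline(config_path, outdir, stages=(_name,))

    return _cmd


for _name in _STAGES:
    _stage_command(_name)


@cli.command(name="all")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--outdir", type=click.Path(), required=True)
def _all(config_path, outdir):
    run_pipeline(config_path, outdir)
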