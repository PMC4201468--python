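"""End-to-end orchestration: generate -> simulate -> evaluate (-> optimize).

Every random draw flows from the single config seed through named, spawned
substreams (scenes, occlusions and clutter consume the per-scene stream; the
optimizer has its own).  Outputs are plain-text artifacts plus a JSON
manifest recording the config, seed, kernel mode, and package version, so a
run is reproducible byte-for-byte from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig, serialize_config
from .dynamics import ModelParams, build_kernel_bank, run
from .evaluate import pr_curve
from .io import model_params_to_dict, save_scene, save_trajectory
from .optimize import anneal, init_params
from .scenes import compose_scene, scene_stats

__all__ = ["run_pipeline", "resolve_params", "scene_rng", "PipelineError"]

log = logging.getLogger("directorfield")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def scene_rng(seed: int, index: int) -> np.random.Generator:
    """Per-scene generator: substream ``index`` of the root scene stream."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 1, index])))


def resolve_params(cfg: RunConfig, *, optimize: bool = False) -> ModelParams:
    """Model parameters from the config, deriving unset ones from scene stats.

    With ``optimize=True`` the steady-state initialization is refined by the
    Metropolis search configured in ``cfg``.
    """
    params = cfg.model_params_explicit()
    if params is None:
        stats_gen = np.random.Generator(np.random.PCG64(np.random.SeedSequence([cfg.seed, 2])))
        stats = scene_stats(stats_gen, cfg.scene_config())
        log.info("scene stats: %s", stats)
        params = init_params(stats, dt=cfg.dt, n_angle_bins=cfg.n_angle_bins)
        overrides = {
            k: cfg.values[k]
            for k in ("sigma", "R_min", "zeta", "E_th", "g1", "g2")
            if cfg.values[k] is not None
        }
        if overrides:
            from .optimize import _set_params

            params = _set_params(params, overrides)
    if optimize and cfg.n_iterations > 0:
        params, _trace = anneal(params, cfg.optimizer_config())
    return params


def run_pipeline(cfg: RunConfig, out_dir, *, optimize: bool = False) -> dict:
    """Run the full flow and write artifacts under ``out_dir``.

    Writes per-scene directories (stimulus + ground truth + trajectory), an
    aggregate mean PR table (TSV), and ``manifest.json``.  Identical config
    and seed give byte-identical numeric tables.  Returns a summary dict.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise PipelineError(f"stage=setup: cannot create output dir {out}: {exc}") from exc

    cfg_text = serialize_config(cfg)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": cfg.seed,
        "version": __version__,
        "kernel_mode": "bank (analytic rotation)",
        "n_scenes": cfg.n_scenes,
    }
    (out / "config.txt").write_text(cfg_text)

    summary: dict = {"out": str(out), "n_scenes": cfg.n_scenes}
    if cfg.n_scenes == 0:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return summary

    try:
        params = resolve_params(cfg, optimize=optimize)
    except Exception as exc:
        raise PipelineError(f"stage=parameters: {exc}") from exc
    manifest["params"] = model_params_to_dict(params)

    try:
        bank = build_kernel_bank(params.kernel)
    except Exception as exc:
        raise PipelineError(f"stage=kernel: {exc}") from exc

    cutoffs = cfg.cutoffs()
    scfg = cfg.scene_config()
    all_curves = []
    try:
        for i in range(cfg.n_scenes):
            rng = scene_rng(cfg.seed, i)
            scene = compose_scene(rng, scfg)
            scene.provenance = {"seed": cfg.seed, "scene_index": i}
            sdir = out / f"scene_{i:03d}"
            save_scene(sdir, scene)
            traj = run(
                scene.input, params, cfg.n_steps, cfg.record_every,
                bank=bank, provenance=scene.provenance,
            )
            save_trajectory(sdir / "trajectory", traj)
            all_curves.append(pr_curve(traj, scene, cutoffs, cfg.cutoff_mode, cfg.tol))
            log.info("scene %d done", i)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage=simulate: {exc}") from exc

    try:
        table_path = out / "pr_table.tsv"
        with open(table_path, "w") as fh:
            fh.write("time\tcutoff\tmode\tprecision\trecall\tauc\n")
            n_times = len(all_curves[0])
            for ti in range(n_times):
                t = all_curves[0][ti].time_step
                mean_auc = float(np.mean([c[ti].auc for c in all_curves]))
                for ci, cut in enumerate(cutoffs):
                    ps = [c[ti].points[ci].precision for c in all_curves]
                    rs = [c[ti].points[ci].recall for c in all_curves]
                    p = float(np.nanmean(ps)) if not all(np.isnan(ps)) else float("nan")
                    r = float(np.mean(rs))
                    fh.write(
                        f"{t}\t{cut:.10g}\t{cfg.cutoff_mode}\t{p:.10g}\t{r:.10g}\t{mean_auc:.10g}\n"
                    )
        mean_aucs = [float(np.mean([c[ti].auc for c in all_curves])) for ti in range(len(all_curves[0]))]
        times = [all_curves[0][ti].time_step for ti in range(len(all_curves[0]))]
        t_opt = times[int(np.argmax(mean_aucs))]
        summary.update(
            {
                "pr_table": str(table_path),
                "optimal_time": int(t_opt),
                "best_mean_auc": max(mean_aucs),
                "params": model_params_to_dict(params),
            }
        )
        manifest["optimal_time"] = int(t_opt)
    except Exception as exc:
        raise PipelineError(f"stage=evaluate: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return summary
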