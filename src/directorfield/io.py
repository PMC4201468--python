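"""Plain-text serialization of fields, kernel banks, trajectories, scenes.

Complex lattices are stored as a *two-plane container*: a small ``#``-header
(lattice size, plane count, metadata) followed by the real planes and then
the imaginary planes, all as whitespace-separated text readable with
``numpy.loadtxt``.  Numeric tables are TSV with a header row; manifests are
JSON.  Everything round-trips exactly at float64 precision (``%.17g``).
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np

from .dynamics import ModelParams, Trajectory
from .field import DirectorField
from .kernel import KernelBank, KernelParams
from .scenes import Contour, Scene, SceneConfig, AmoebaSpec

__all__ = [
    "save_planes",
    "load_planes",
    "save_field",
    "load_field",
    "save_bank",
    "load_bank",
    "save_trajectory",
    "load_trajectory",
    "save_scene",
    "load_scene",
    "field_to_png",
    "model_params_to_dict",
    "model_params_from_dict",
]

_FMT = "%.17g"


def save_planes(path, planes: np.ndarray, meta: dict | None = None) -> None:
    """Write a stack of real planes with a small text header."""
    planes = np.asarray(planes, dtype=float)
    if planes.ndim == 2:
        planes = planes[None]
    header = [
        "directorfield planes v1",
        f"planes={planes.shape[0]} rows={planes.shape[1]} cols={planes.shape[2]}",
        "meta=" + json.dumps(meta or {}, sort_keys=True),
    ]
    np.savetxt(path, planes.reshape(-1, planes.shape[2]), fmt=_FMT, header="\n".join(header))


def load_planes(path):
    with open(path) as fh:
        lines = [ln[2:].strip() for ln in fh if ln.startswith("#")]
    dims = dict(kv.split("=") for kv in lines[1].split())
    meta = json.loads(lines[2].split("=", 1)[1])
    n, r, c = int(dims["planes"]), int(dims["rows"]), int(dims["cols"])
    data = np.loadtxt(path).reshape(n, r, c)
    return data, meta


def save_field(path, f: DirectorField) -> None:
    save_planes(path, np.stack([f.values.real, f.values.imag]), {"kind": "field", **f.meta})


def load_field(path) -> DirectorField:
    planes, meta = load_planes(path)
    meta.pop("kind", None)
    return DirectorField(planes[0] + 1j * planes[1], meta)


def save_bank(path, bank: KernelBank) -> None:
    p = bank.params
    meta = {
        "kind": "kernel_bank",
        "sigma": p.sigma,
        "R_min": p.R_min,
        "half_width": p.M,
        "n_angle_bins": p.n_angle_bins,
    }
    planes = np.concatenate([bank.rotated.real, bank.rotated.imag])
    save_planes(path, planes, meta)


def load_bank(path) -> KernelBank:
    planes, meta = load_planes(path)
    params = KernelParams(
        sigma=meta["sigma"],
        R_min=meta["R_min"],
        half_width=meta["half_width"],
        n_angle_bins=meta["n_angle_bins"],
    )
    n = params.n_angle_bins
    rotated = planes[:n] + 1j * planes[n:]
    return KernelBank(params, rotated)


def model_params_to_dict(p: ModelParams) -> dict:
    return {
        "sigma": p.kernel.sigma,
        "R_min": p.kernel.R_min,
        "half_width": p.kernel.half_width,
        "n_angle_bins": p.kernel.n_angle_bins,
        "zeta": p.zeta,
        "E_th": p.E_th,
        "g1": p.g1,
        "g2": p.g2,
        "dt": p.dt,
        "inhibition_radius": p.inhibition_radius,
    }


def model_params_from_dict(d: dict) -> ModelParams:
    kernel = KernelParams(
        sigma=d["sigma"],
        R_min=d["R_min"],
        half_width=d.get("half_width"),
        n_angle_bins=d.get("n_angle_bins", 64),
    )
    return ModelParams(
        kernel=kernel,
        zeta=d["zeta"],
        E_th=d["E_th"],
        g1=d["g1"],
        g2=d["g2"],
        dt=d.get("dt", 1.0),
        inhibition_radius=d.get("inhibition_radius"),
    )


def save_trajectory(directory, traj: Trajectory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s, f in traj:
        save_field(directory / f"step_{s:05d}.txt", f)
    manifest = {
        "kind": "trajectory",
        "steps": traj.steps,
        "params": model_params_to_dict(traj.params),
        "provenance": traj.provenance,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def load_trajectory(directory) -> Trajectory:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    steps = manifest["steps"]
    fields = [load_field(directory / f"step_{s:05d}.txt") for s in steps]
    return Trajectory(steps, fields, model_params_from_dict(manifest["params"]), manifest.get("provenance", {}))


# --------------------------------------------------------------------------- #
# scenes
# --------------------------------------------------------------------------- #
def _contour_rows(t: Contour, contour_id: int):
    for (r, c), tan, vis in zip(t.points, t.tangents, t.visible):
        yield c, r, np.degrees(tan), int(vis), contour_id


def save_scene(directory, scene: Scene) -> None:
    """stimulus.txt (field container) + truth.tsv + clutter.tsv + scene.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_field(directory / "stimulus.txt", scene.input)
    with open(directory / "truth.tsv", "w") as fh:
        fh.write("x\ty\ttangent_deg\tvisible\tcontour_id\n")
        for i, t in enumerate(scene.targets):
            for x, y, td, vis, cid in _contour_rows(t, i):
                fh.write(f"{x}\t{y}\t{td:.10g}\t{vis}\t{cid}\n")
    with open(directory / "clutter.tsv", "w") as fh:
        fh.write("x\ty\torientation_deg\n")
        for (r, c), o in zip(scene.clutter_sites, scene.clutter_orients):
            fh.write(f"{c}\t{r}\t{np.degrees(o):.10g}\n")
    contours = [
        {
            "center": list(map(float, t.center)),
            "coeffs": list(map(float, t.coeffs)),
            "phases": list(map(float, t.phases)),
            "total_length": t.total_length,
            "arclength": list(map(float, t.arclength)),
            "occluded_segments": [list(seg) for seg in t.occluded_segments],
        }
        for t in scene.targets
    ]
    meta = {
        "kind": "scene",
        "config": _scene_config_to_dict(scene.config),
        "provenance": scene.provenance,
        "contours": contours,
    }
    (directory / "scene.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def _scene_config_to_dict(c: SceneConfig) -> dict:
    d = {
        k: getattr(c, k)
        for k in (
            "L", "n_targets", "n_clutter_sources", "occlusion_fraction",
            "region_size", "neighbor_margin_deg", "exclusion_radius",
            "parallel_margin_deg", "s0",
        )
    }
    d["occlusion_segments"] = list(c.occlusion_segments)
    d["amoeba"] = {
        "k_max": c.amoeba.k_max,
        "coeff_sd": c.amoeba.coeff_sd,
        "r_min_frac": c.amoeba.r_min_frac,
        "r_max_frac": c.amoeba.r_max_frac,
        "ratio_min": c.amoeba.ratio_min,
        "center": list(c.amoeba.center) if c.amoeba.center is not None else None,
    }
    return d


def _scene_config_from_dict(d: dict) -> SceneConfig:
    a = d["amoeba"]
    spec = AmoebaSpec(
        k_max=a["k_max"],
        coeff_sd=a["coeff_sd"],
        r_min_frac=a["r_min_frac"],
        r_max_frac=a["r_max_frac"],
        ratio_min=a["ratio_min"],
        center=tuple(a["center"]) if a["center"] is not None else None,
    )
    kw = {k: v for k, v in d.items() if k not in ("amoeba", "occlusion_segments")}
    return SceneConfig(amoeba=spec, occlusion_segments=tuple(d["occlusion_segments"]), **kw)


def load_scene(directory) -> Scene:
    directory = Path(directory)
    meta = json.loads((directory / "scene.json").read_text())
    config = _scene_config_from_dict(meta["config"])
    stim = load_field(directory / "stimulus.txt")
    truth = np.loadtxt(directory / "truth.tsv", skiprows=1, ndmin=2)
    targets = []
    for i, cmeta in enumerate(meta["contours"]):
        rows = truth[truth[:, 4] == i] if truth.size else np.empty((0, 5))
        targets.append(
            Contour(
                points=np.stack([rows[:, 1], rows[:, 0]], axis=1).astype(int),
                tangents=np.radians(rows[:, 2]),
                visible=rows[:, 3].astype(bool),
                arclength=np.asarray(cmeta["arclength"], dtype=float),
                total_length=cmeta["total_length"],
                center=np.asarray(cmeta["center"], dtype=float),
                coeffs=np.asarray(cmeta["coeffs"], dtype=float),
                phases=np.asarray(cmeta["phases"], dtype=float),
                L=config.L,
                occluded_segments=[tuple(s) for s in cmeta["occluded_segments"]],
            )
        )
    clutter = np.loadtxt(directory / "clutter.tsv", skiprows=1, ndmin=2)
    if clutter.size:
        sites = np.stack([clutter[:, 1], clutter[:, 0]], axis=1).astype(int)
        orients = np.radians(clutter[:, 2])
    else:
        sites, orients = np.empty((0, 2), dtype=int), np.empty(0)
    return Scene(stim, targets, sites, orients, config, meta.get("provenance", {}))


# --------------------------------------------------------------------------- #
# rendering
# --------------------------------------------------------------------------- #
def field_to_png(path, f: DirectorField) -> None:
    """Render magnitude as brightness and orientation as hue (inspection aid)."""
    from matplotlib.colors import hsv_to_rgb
    from PIL import Image

    om = f.orientation_map()
    v = om.rate / om.rate.max() if om.rate.max() > 0 else om.rate
    h = np.where(np.isnan(om.orientation), 0.0, om.orientation) / np.pi
    s = np.where(np.isnan(om.orientation), 0.0, 1.0)
    rgb = hsv_to_rgb(np.stack([h, s, v], axis=-1))
    Image.fromarray((rgb * 255).astype(np.uint8)).save(os.fspath(path))
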