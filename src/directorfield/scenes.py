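"""Synthetic test scenes: amoeba targets, occlusions, and matched clutter.

A *target* is an "amoeba": a closed contour whose radius around a random
center is a low-frequency random Fourier series in the polar angle,

    r(phi) = a_0 + sum_{k=1..k_max} a_k cos(k phi + phi_k),

with normally distributed amplitudes and uniform phases, rejection-sampled
until the radius stays inside a configured band and the min/max radius ratio
is bounded below (amoebas of "about the same size").  The stimulus paints
every lattice site within one lattice spacing of the continuous curve with a
unit-magnitude director along the local tangent.

*Occlusions* hide 2-4 random arcs totalling a configured fraction of the
contour length: the stimulus there is zeroed but the ground truth keeps the
full contour (with tangents), so occluded points count toward recall.

*Clutter* must be locally indistinguishable from targets, so it is literally
made of targets: one or more extra amoebas are rasterized, the lattice is
tiled into square regions, the regions are randomly permuted, and each region
is rigidly rotated about the center of mass of its active sites - subject to
the constraint that neighbouring regions end up with clearly different
dominant orientations, which prevents accidental long-range target-like
structures.  Rigid motions preserve curvature, segment length, and brightness
exactly; only long-range continuity is destroyed.

An *exclusion zone* deletes clutter sites close to a target and nearly
parallel to its nearest tangent: such sites could help detection and would
bias performance upward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dc_field, replace

import numpy as np
from scipy.spatial import cKDTree

from .field import DirectorField
from .kernel import KernelParams  # noqa: F401  (re-exported convenience)

__all__ = [
    "AmoebaSpec",
    "Contour",
    "Scene",
    "SceneConfig",
    "SceneStats",
    "generate_amoeba",
    "apply_occlusions",
    "generate_clutter",
    "apply_exclusion_zone",
    "compose_scene",
    "scene_stats",
    "dominant_orientation",
    "angular_difference",
]


# --------------------------------------------------------------------------- #
# specs
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class AmoebaSpec:
    """Shape distribution of amoeba targets.

    k_max      : highest radial Fourier frequency.
    coeff_sd   : standard deviation (lattice units) of the k=1 amplitude;
                 higher frequencies fall off as coeff_sd / k.
    r_min_frac, r_max_frac : allowed radius band as fractions of L.
    ratio_min  : lower bound on (min radius) / (max radius).
    center     : fixed (row, col) center, or None for uniformly random.
    """

    k_max: int = 5
    coeff_sd: float = 3.0
    r_min_frac: float = 0.10
    r_max_frac: float = 0.25
    ratio_min: float = 0.5
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.r_min_frac < self.r_max_frac < 0.5):
            raise ValueError("need 0 < r_min_frac < r_max_frac < 0.5")
        if not (0 < self.ratio_min <= 1):
            raise ValueError("need 0 < ratio_min <= 1")
        if self.k_max < 0:
            raise ValueError("k_max must be >= 0")


@dataclass
class Contour:
    """Rasterized closed contour with analytic provenance.

    points    : (N, 2) int lattice sites (row, col), wrapped mod L, ordered
                by polar angle; every site is within 1 lattice spacing of the
                continuous curve.
    tangents  : orientation in [0, pi) of the curve tangent at each point.
    visible   : stimulus-visibility mask (occlusion hides points here only).
    arclength : continuous arclength coordinate of each point.
    """

    points: np.ndarray
    tangents: np.ndarray
    visible: np.ndarray
    arclength: np.ndarray
    total_length: float
    center: np.ndarray
    coeffs: np.ndarray  # a_0 .. a_kmax
    phases: np.ndarray  # phi_1 .. phi_kmax (phi_0 unused, kept 0)
    L: int
    occluded_segments: list = _dc_field(default_factory=list)  # (start, length)

    def __len__(self) -> int:
        return len(self.points)

    def radius(self, phi: np.ndarray) -> np.ndarray:
        k = np.arange(len(self.coeffs))
        return np.sum(self.coeffs[:, None] * np.cos(k[:, None] * phi[None, :] + self.phases[:, None]), axis=0)

    def radius_derivatives(self, phi: np.ndarray):
        k = np.arange(len(self.coeffs))
        arg = k[:, None] * phi[None, :] + self.phases[:, None]
        r = np.sum(self.coeffs[:, None] * np.cos(arg), axis=0)
        r1 = np.sum(-self.coeffs[:, None] * k[:, None] * np.sin(arg), axis=0)
        r2 = np.sum(-self.coeffs[:, None] * k[:, None] ** 2 * np.cos(arg), axis=0)
        return r, r1, r2

    def curvature_radius(self, n: int = 1024) -> np.ndarray:
        """Radius of curvature 1/kappa sampled uniformly in polar angle."""
        phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r, r1, r2 = self.radius_derivatives(phi)
        num = np.abs(r**2 + 2 * r1**2 - r * r2)
        den = (r**2 + r1**2) ** 1.5
        with np.errstate(divide="ignore"):
            return np.where(num > 0, den / num, np.inf)


def _wrap_sites(sites: np.ndarray, L: int) -> np.ndarray:
    return np.mod(sites, L)


def generate_amoeba(rng: np.random.Generator, spec: AmoebaSpec, L: int, max_tries: int = 2000) -> Contour:
    """Sample one amoeba and rasterize it to the lattice (all points visible).

    Radii are rejection-sampled until they lie in
    [r_min_frac*L, r_max_frac*L] with min/max >= ratio_min.  Raises when the
    rejection budget is exhausted (infeasible spec).
    """
    r_lo = spec.r_min_frac * L
    r_hi = spec.r_max_frac * L
    n_dense = 4096
    phi = np.linspace(0, 2 * np.pi, n_dense, endpoint=False)
    k = np.arange(spec.k_max + 1)
    for _ in range(max_tries):
        a = np.empty(spec.k_max + 1)
        a[0] = rng.uniform(r_lo + 0.15 * (r_hi - r_lo), r_hi - 0.1 * (r_hi - r_lo))
        ph = np.zeros(spec.k_max + 1)
        if spec.k_max >= 1:
            a[1:] = rng.normal(0.0, spec.coeff_sd / k[1:])
            ph[1:] = rng.uniform(0, 2 * np.pi, spec.k_max)
        arg = k[:, None] * phi[None, :] + ph[:, None]
        r = np.sum(a[:, None] * np.cos(arg), axis=0)
        if r.min() < r_lo or r.max() > r_hi:
            continue
        if r.min() / r.max() < spec.ratio_min:
            continue
        break
    else:
        raise RuntimeError(
            f"could not sample an amoeba satisfying {spec} within {max_tries} tries"
        )

    center = np.asarray(spec.center, dtype=float) if spec.center is not None else rng.uniform(0, L, size=2)
    crow, ccol = center
    r1 = np.sum(-a[:, None] * k[:, None] * np.sin(arg), axis=0)
    x = ccol + r * np.cos(phi)  # col coordinate (real axis)
    y = crow + r * np.sin(phi)  # row coordinate (imaginary axis)
    dx = r1 * np.cos(phi) - r * np.sin(phi)
    dy = r1 * np.sin(phi) + r * np.cos(phi)
    speed = np.hypot(dx, dy)
    # cumulative arclength, closing the loop
    seglen = 0.5 * (speed + np.roll(speed, -1)) * (2 * np.pi / n_dense)
    s = np.concatenate(([0.0], np.cumsum(seglen)))[:-1]
    total_length = float(np.cumsum(seglen)[-1])
    tangent = np.mod(np.arctan2(dy, dx), np.pi)

    # candidate sites: the 3x3 neighbourhood of each dense sample
    base = np.stack([np.rint(y), np.rint(x)], axis=1).astype(int)
    offs = np.array([(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)])
    cand = (base[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    cand = np.unique(cand, axis=0)
    tree = cKDTree(np.stack([y, x], axis=1))
    dist, idx = tree.query(cand.astype(float), k=1)
    keep = dist <= 1.0
    sites = cand[keep]
    near = idx[keep]
    order = np.argsort(phi[near], kind="stable")
    sites, near = sites[order], near[order]
    # dedupe wrapped duplicates, keeping first occurrence in angular order
    wrapped = _wrap_sites(sites, L)
    _, first = np.unique(wrapped, axis=0, return_index=True)
    first = np.sort(first)
    wrapped, near = wrapped[first], near[first]

    return Contour(
        points=wrapped,
        tangents=tangent[near].copy(),
        visible=np.ones(len(wrapped), dtype=bool),
        arclength=s[near].copy(),
        total_length=total_length,
        center=center,
        coeffs=a,
        phases=ph,
        L=L,
    )


# --------------------------------------------------------------------------- #
# occlusions
# --------------------------------------------------------------------------- #
def apply_occlusions(
    c: Contour,
    rng: np.random.Generator,
    n_segments_range: tuple[int, int] = (2, 4),
    total_fraction: float = 0.25,
    max_tries: int = 200,
) -> Contour:
    """Hide random arcs totalling ``total_fraction`` of the contour length.

    The number of hidden segments is uniform over ``n_segments_range``
    (inclusive); segment lengths are a uniform random partition of the total.
    Hidden points keep their ground-truth tangents but are marked invisible.
    """
    if not (0 <= total_fraction < 1):
        raise ValueError("total_fraction must be in [0, 1)")
    out = replace(c, visible=np.ones(len(c), dtype=bool), occluded_segments=[])
    if total_fraction == 0:
        return out
    n = int(rng.integers(n_segments_range[0], n_segments_range[1] + 1))
    total = total_fraction * c.total_length
    for _ in range(max_tries):
        lengths = rng.dirichlet(np.ones(n)) * total
        starts = np.sort(rng.uniform(0, c.total_length, size=n))
        ends = starts + lengths
        # non-overlap on the circle: each segment must end before the next
        # starts, and the last must not wrap into the first
        ok = all(ends[i] < starts[i + 1] for i in range(n - 1))
        ok = ok and (ends[-1] < starts[0] + c.total_length)
        if ok:
            break
    else:
        raise RuntimeError("could not place non-overlapping occlusion segments")
    visible = np.ones(len(c), dtype=bool)
    s = c.arclength
    segs = []
    for s0, ln in zip(starts, lengths):
        rel = np.mod(s - s0, c.total_length)
        visible &= ~(rel <= ln)
        segs.append((float(s0 % c.total_length), float(ln)))
    out.visible = visible
    out.occluded_segments = segs
    return out


# --------------------------------------------------------------------------- #
# clutter
# --------------------------------------------------------------------------- #
def angular_difference(a, b) -> np.ndarray:
    """Distance between orientations modulo pi, in [0, pi/2]."""
    d = np.mod(np.asarray(a) - np.asarray(b), np.pi)
    return np.minimum(d, np.pi - d)


def dominant_orientation(points: np.ndarray) -> float | None:
    """Principal-axis orientation of a site set via second moments.

    Returns None when undefined (fewer than 2 points or isotropic cloud).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return None
    centered = pts - pts.mean(axis=0)
    # (row, col) -> (x, y) = (col, row)
    x, y = centered[:, 1], centered[:, 0]
    mu20, mu02, mu11 = np.mean(x * x), np.mean(y * y), np.mean(x * y)
    if abs(mu20 - mu02) < 1e-12 and abs(mu11) < 1e-12:
        return None
    return float(np.mod(0.5 * np.arctan2(2 * mu11, mu20 - mu02), np.pi))


def _rotate_region(pos: np.ndarray, orients: np.ndarray, angle: float):
    com = pos.mean(axis=0)
    c, s = math.cos(angle), math.sin(angle)
    d = pos - com
    # rotate in the (x, y) = (col, row) plane, counterclockwise
    dx, dy = d[:, 1], d[:, 0]
    nx = c * dx - s * dy
    ny = s * dx + c * dy
    newpos = np.stack([com[0] + ny, com[1] + nx], axis=1)
    return newpos, np.mod(orients + angle, np.pi)


def generate_clutter(
    rng: np.random.Generator,
    L: int,
    spec: AmoebaSpec,
    region_size: int = 16,
    n_source_amoebas: int = 1,
    neighbor_margin_deg: float = 20.0,
    shuffle: bool = True,
    rotate: bool = True,
    retry_budget: int = 60,
    debug: bool = False,
):
    """Break one or more amoebas into statistically matched clutter.

    Returns ``(sites, orientations)``: int (K, 2) lattice sites and their
    edge orientations.  With ``shuffle=False, rotate=False`` the clutter is
    exactly the source amoeba sites (no-op test mode).  ``debug=True``
    additionally returns the accepted per-region dominant orientations for
    auditing the neighbour constraint.
    """
    if L % region_size != 0:
        raise ValueError("region_size must divide L")
    margin = math.radians(neighbor_margin_deg)
    pos_list, ori_list = [], []
    for _ in range(n_source_amoebas):
        src = generate_amoeba(rng, spec, L)
        pos_list.append(src.points.astype(float))
        ori_list.append(src.tangents.copy())
    pos = np.concatenate(pos_list)
    ori = np.concatenate(ori_list)

    nt = L // region_size
    tile = (pos // region_size).astype(int)  # (row_tile, col_tile)
    tile_id = tile[:, 0] * nt + tile[:, 1]
    perm = rng.permutation(nt * nt) if shuffle else np.arange(nt * nt)

    # translate each populated source tile to its destination tile
    dest_of = perm  # dest_of[src_tile] = dest tile
    new_pos = pos.copy()
    for t in np.unique(tile_id):
        d = dest_of[t]
        dr = (d // nt - t // nt) * region_size
        dc = (d % nt - t % nt) * region_size
        sel = tile_id == t
        new_pos[sel, 0] += dr
        new_pos[sel, 1] += dc

    dest_tile_id = np.zeros(len(new_pos), dtype=int)
    for t in np.unique(tile_id):
        dest_tile_id[tile_id == t] = dest_of[t]

    # rotate each populated destination tile about its CoM, constraining the
    # dominant orientation against already-processed 8-connected neighbours
    dom: dict[int, float | None] = {}
    if rotate:
        for d in sorted(np.unique(dest_tile_id)):
            sel = dest_tile_id == d
            drow, dcol = d // nt, d % nt
            neighbours = []
            for rr in (-1, 0, 1):
                for cc in (-1, 0, 1):
                    if rr == cc == 0:
                        continue
                    nb = ((drow + rr) % nt) * nt + (dcol + cc) % nt
                    if nb in dom and dom[nb] is not None:
                        neighbours.append(dom[nb])

            def admissible(theta_dom):
                return theta_dom is None or all(
                    angular_difference(theta_dom, nb) > margin for nb in neighbours
                )

            best, best_sep = None, -1.0
            chosen = None
            stream = rng
            for attempt in range(2 * retry_budget):
                if attempt == retry_budget:  # fresh angle stream
                    stream = rng.spawn(1)[0]
                ang = stream.uniform(0, 2 * np.pi)
                p2, o2 = _rotate_region(new_pos[sel], ori[sel], ang)
                th = dominant_orientation(p2)
                if admissible(th):
                    chosen = (p2, o2, th)
                    break
                sep = min(angular_difference(th, nb) for nb in neighbours) if neighbours else np.inf
                if sep > best_sep:
                    best_sep, best = sep, (p2, o2, th)
            if chosen is None:
                chosen = best
            new_pos[sel], ori[sel] = chosen[0], chosen[1]
            dom[d] = chosen[2]

    sites = _wrap_sites(np.rint(new_pos).astype(int), L)
    # dedupe collided sites (re-rasterization losses are audited in tests)
    _, first = np.unique(sites, axis=0, return_index=True)
    first = np.sort(first)
    if debug:
        return sites[first], ori[first], {"dominant": dom, "n_tiles": nt}
    return sites[first], ori[first]


# --------------------------------------------------------------------------- #
# exclusion zone
# --------------------------------------------------------------------------- #
def apply_exclusion_zone(
    targets: "Contour | list[Contour]",
    clutter_sites: np.ndarray,
    clutter_orients: np.ndarray,
    L: int,
    radius: float = 8.0,
    parallel_margin_deg: float = 15.0,
):
    """Remove clutter near a target and nearly parallel to its tangent.

    A clutter site is deleted when it lies within ``radius`` (periodic
    Euclidean distance) of any target point *and* its orientation is within
    ``parallel_margin_deg`` of the tangent at the nearest target point.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if len(clutter_sites) == 0 or radius == 0:
        return clutter_sites.copy(), clutter_orients.copy()
    if isinstance(targets, Contour):
        targets = [targets]
    pts = np.concatenate([t.points for t in targets]).astype(float)
    tans = np.concatenate([t.tangents for t in targets])
    tree = cKDTree(np.mod(pts, L), boxsize=L)
    dist, idx = tree.query(np.mod(clutter_sites.astype(float), L), k=1)
    parallel = angular_difference(clutter_orients, tans[idx]) <= math.radians(parallel_margin_deg)
    drop = (dist <= radius) & parallel
    return clutter_sites[~drop], clutter_orients[~drop]


# --------------------------------------------------------------------------- #
# composition
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class SceneConfig:
    """Full recipe for one synthetic scene."""

    L: int = 128
    n_targets: int = 1
    n_clutter_sources: int = 1
    amoeba: AmoebaSpec = _dc_field(default_factory=AmoebaSpec)
    occlusion_fraction: float = 0.25
    occlusion_segments: tuple[int, int] = (2, 4)
    region_size: int = 16
    neighbor_margin_deg: float = 20.0
    exclusion_radius: float = 8.0
    parallel_margin_deg: float = 15.0
    s0: float = 1.0

    def __post_init__(self) -> None:
        if self.L % self.region_size != 0:
            raise ValueError("region_size must divide L")
        if self.n_targets < 1:
            raise ValueError("need at least one target")
        if self.s0 <= 0:
            raise ValueError("s0 must be > 0")


@dataclass
class Scene:
    """Stimulus plus ground truth."""

    input: DirectorField
    targets: list
    clutter_sites: np.ndarray
    clutter_orients: np.ndarray
    config: SceneConfig
    provenance: dict = _dc_field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.config.L

    def truth_points(self) -> np.ndarray:
        """All ground-truth contour sites (visible and occluded)."""
        return np.concatenate([t.points for t in self.targets])

    def visible_points(self) -> np.ndarray:
        return np.concatenate([t.points[t.visible] for t in self.targets])


def _contours_intersect(a: Contour, b: Contour, L: int, min_sep: float = 2.0) -> bool:
    tree = cKDTree(np.mod(a.points.astype(float), L), boxsize=L)
    d, _ = tree.query(np.mod(b.points.astype(float), L), k=1)
    return bool(np.min(d) < min_sep)


def compose_scene(rng: np.random.Generator, config: SceneConfig = SceneConfig()) -> Scene:
    """Draw targets and clutter, occlude, exclude, and paint the stimulus.

    The stimulus has magnitude s0 at visible target points and surviving
    clutter sites (director phase = 2 x local orientation) and 0 elsewhere;
    targets are painted last and win collisions.  Ground truth keeps the full
    contours.  Bit-reproducible for a given generator state.
    """
    targets: list[Contour] = []
    for _ in range(config.n_targets):
        for _attempt in range(100):
            cand = generate_amoeba(rng, config.amoeba, config.L)
            if not any(_contours_intersect(cand, t, config.L) for t in targets):
                targets.append(cand)
                break
        else:
            raise RuntimeError("could not place non-intersecting targets")
    targets = [
        apply_occlusions(t, rng, config.occlusion_segments, config.occlusion_fraction)
        for t in targets
    ]

    if config.n_clutter_sources > 0:
        sites, orients = generate_clutter(
            rng,
            config.L,
            config.amoeba,
            region_size=config.region_size,
            n_source_amoebas=config.n_clutter_sources,
            neighbor_margin_deg=config.neighbor_margin_deg,
        )
        sites, orients = apply_exclusion_zone(
            targets, sites, orients, config.L,
            radius=config.exclusion_radius,
            parallel_margin_deg=config.parallel_margin_deg,
        )
    else:
        sites = np.empty((0, 2), dtype=int)
        orients = np.empty(0)

    values = np.zeros((config.L, config.L), dtype=complex)
    if len(sites):
        values[sites[:, 0], sites[:, 1]] = config.s0 * np.exp(2j * orients)
    for t in targets:
        vis = t.visible
        values[t.points[vis, 0], t.points[vis, 1]] = config.s0 * np.exp(2j * t.tangents[vis])

    return Scene(
        input=DirectorField(values),
        targets=targets,
        clutter_sites=sites,
        clutter_orients=orients,
        config=config,
    )


# --------------------------------------------------------------------------- #
# statistics for parameter initialization
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class SceneStats:
    """Summary statistics driving parameter initialization.

    mean_curvature_radius : typical radius of curvature of amoeba contours
        (median over each contour, averaged over samples).
    mean_occlusion_extent : mean arc length of a single occluded segment.
    expected_active_sites : mean number of sites on a full target band (the
        intended asymptotic active set after clutter suppression and
        occlusion filling).
    mean_radius : mean amoeba radius (polar average, lattice units).
    """

    mean_curvature_radius: float
    mean_occlusion_extent: float
    expected_active_sites: float
    mean_radius: float = 0.0
    band_width: float = 2.0  # mean stimulus sites per unit arc length


def scene_stats(rng: np.random.Generator, config: SceneConfig = SceneConfig(), n_samples: int = 20) -> SceneStats:
    """Measure :class:`SceneStats` from freshly sampled amoebas."""
    radii, extents, counts, widths, mean_r = [], [], [], [], []
    phi = np.linspace(0, 2 * np.pi, 512, endpoint=False)
    for _ in range(n_samples):
        c = generate_amoeba(rng, config.amoeba, config.L)
        rc = np.clip(c.curvature_radius(), 0, config.L)
        radii.append(np.median(rc))
        counts.append(len(c))
        widths.append(len(c) / c.total_length)
        mean_r.append(float(np.mean(c.radius(phi))))
        if config.occlusion_fraction > 0:
            occ = apply_occlusions(c, rng, config.occlusion_segments, config.occlusion_fraction)
            extents.extend(ln for _, ln in occ.occluded_segments)
    mean_extent = float(np.mean(extents)) if extents else 0.0
    return SceneStats(
        mean_curvature_radius=float(np.mean(radii)),
        mean_occlusion_extent=mean_extent,
        expected_active_sites=float(np.mean(counts)) * config.n_targets,
        mean_radius=float(np.mean(mean_r)),
        band_width=float(np.mean(widths)),
    )
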