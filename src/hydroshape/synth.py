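"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be produced here with its
answer planted: water-like packings around parametric solutes (a geometric
stand-in for a simulated water box, not a physical water model), harmonically
biased Metropolis samples from a specified ground-truth PMF for WHAM
validation, and association trajectories in which the generator itself
relocates interfacial water to the bulk as two solutes approach, recording
the transition count it planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import qmc

from .constants import GAS_CONSTANT_KJ_MOL_K
from .errors import ConfigurationError, DomainError, PackingError, StepSizeError
from .frames import WaterFrame
from .layers import DEFAULT_LAYER_CUTOFF
from .pmf import UmbrellaWindow
from .shapes import Composite, ConcavePocket, ConvexBump, Slab, SoluteShape, Sphere

__all__ = [
    "GroundTruthPMF",
    "default_double_well",
    "harmonic_truth",
    "generate_water_box",
    "generate_umbrella_samples",
    "AssociationSchedule",
    "generate_association_trajectory",
    "BULK_WATER_DENSITY",
]

#: Ambient number density of liquid water, molecules/Å³.
BULK_WATER_DENSITY = 0.0334

_OH_BOND = 0.96  # Å
_HOH_ANGLE_DEG = 104.5


# ---------------------------------------------------------------------------
# Ground-truth PMFs


@dataclass
class GroundTruthPMF:
    """An analytic reaction-coordinate free-energy curve with located extrema.

    ``fn`` maps separation (Å) to free energy (kJ/mol) on ``domain``;
    ``extrema`` lists (position, "min"|"max") pairs refined by root-finding
    on the derivative, so they are exact to solver precision.
    """

    fn: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float]
    extrema: list[tuple[float, str]] = field(default_factory=list)

    def __call__(self, r):
        return self.fn(np.asarray(r, dtype=float))

    @classmethod
    def from_callable(
        cls, fn: Callable, domain: tuple[float, float], n_grid: int = 4001
    ) -> "GroundTruthPMF":
        """Wrap a callable and locate its interior extrema by sign changes of f'."""
        lo, hi = domain
        if not (hi > lo):
            raise DomainError(f"empty domain {domain}")
        h = (hi - lo) * 1e-7

        def deriv(r):
            return (fn(np.asarray(r) + h) - fn(np.asarray(r) - h)) / (2 * h)

        grid = np.linspace(lo + 2 * h, hi - 2 * h, n_grid)
        d = deriv(grid)
        extrema: list[tuple[float, str]] = []
        sign = np.sign(d)

        def classify(pos: float) -> str:
            curv = float(fn(pos + h) - 2.0 * fn(pos) + fn(pos - h))
            return "min" if curv > 0 else "max"

        # a grid point may land exactly on a stationary point (derivative 0)
        for i in np.flatnonzero(sign[1:-1] == 0) + 1:
            extrema.append((float(grid[i]), classify(float(grid[i]))))
        for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
            root = brentq(lambda r: float(deriv(r)), grid[i], grid[i + 1])
            extrema.append((float(root), classify(root)))
        extrema.sort()
        return cls(fn=fn, domain=domain, extrema=extrema)


def default_double_well(
    tail_amplitude: float = 25.0,
    tail_origin: float = 2.0,
    well1: tuple[float, float, float] = (3.2, 12.0, 0.45),
    well2: tuple[float, float, float] = (5.8, 5.0, 0.6),
    domain: tuple[float, float] = (2.4, 13.0),
) -> GroundTruthPMF:
    """Default ground truth: two Gaussian wells on a repulsive 1/(r − r0) tail.

    The shape mimics a water-induced PMF with a contact and a
    solvent-separated minimum separated by a barrier; every extremum is known
    analytically (via derivative root-finding), so it exercises the WHAM
    solver and the minima/barrier detector with checkable answers.
    """
    c1, d1, s1 = well1
    c2, d2, s2 = well2

    def fn(r):
        r = np.asarray(r, dtype=float)
        return (
            tail_amplitude / (r - tail_origin)
            - d1 * np.exp(-((r - c1) ** 2) / (2 * s1**2))
            - d2 * np.exp(-((r - c2) ** 2) / (2 * s2**2))
        )

    return GroundTruthPMF.from_callable(fn, domain)


def harmonic_truth(
    spring_k: float, center: float, domain: tuple[float, float]
) -> GroundTruthPMF:
    """Harmonic ground truth ½·k·(r − c)²; closed-form Gaussian statistics."""

    def fn(r):
        return 0.5 * spring_k * (np.asarray(r, dtype=float) - center) ** 2

    return GroundTruthPMF.from_callable(fn, domain)


# ---------------------------------------------------------------------------
# Water-like packings


def _random_water_orientations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Two O→H unit vectors per molecule at the fixed internal angle, (n, 2, 3)."""
    u1 = rng.standard_normal((n, 3))
    u1 /= np.linalg.norm(u1, axis=1, keepdims=True)
    helper = np.where(np.abs(u1[:, :1]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    e1 = np.cross(u1, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(u1, e1)
    phi = rng.uniform(0, 2 * math.pi, n)[:, None]
    theta = math.radians(_HOH_ANGLE_DEG)
    u2 = math.cos(theta) * u1 + math.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
    return np.stack([u1, u2], axis=1)


class _CellGrid:
    """Spatial hash for min-distance rejection packing (optionally periodic)."""

    def __init__(self, box: np.ndarray | None, min_dist: float, extent: np.ndarray):
        self.box = box
        self.min_dist = min_dist
        self.extent = extent  # (lo, hi) rows when aperiodic
        if box is not None:
            self.ncell = np.maximum((box // min_dist).astype(int), 1)
            self.cell = box / self.ncell
        else:
            span = extent[1] - extent[0]
            self.ncell = np.maximum((span // min_dist).astype(int), 1)
            self.cell = span / self.ncell
        self.cells: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def _index(self, p: np.ndarray) -> np.ndarray:
        origin = 0.0 if self.box is not None else self.extent[0]
        idx = np.floor((p - origin) / self.cell).astype(int)
        return np.clip(idx, 0, self.ncell - 1)

    def ok(self, p: np.ndarray) -> bool:
        idx = self._index(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    j = idx + (dx, dy, dz)
                    if self.box is not None:
                        j = tuple(j % self.ncell)
                    else:
                        if np.any(j < 0) or np.any(j >= self.ncell):
                            continue
                        j = tuple(j)
                    for q in self.cells.get(j, ()):
                        d = p - q
                        if self.box is not None:
                            d = d - self.box * np.round(d / self.box)
                        if float(d @ d) < self.min_dist**2:
                            return False
        return True

    def add(self, p: np.ndarray) -> None:
        self.cells.setdefault(tuple(self._index(p)), []).append(p)


def generate_water_box(
    shape: SoluteShape | None,
    box: Sequence[float] | float,
    density: float = BULK_WATER_DENSITY,
    min_oo: float = 2.4,
    seed: int | None = None,
    frame_index: int = 0,
) -> WaterFrame:
    """Rejection-pack a periodic water-like box around an optional solute.

    Oxygen positions are uniform outside the solute with pairwise (minimum
    image) O–O distance ≥ ``min_oo``; hydrogens sit at the fixed bond length
    with uniformly random orientations.  The target count is
    density × (box volume − solute volume); the solute is assumed to lie
    inside the box.  Deterministic under ``seed``.  Raises PackingError when
    the density is not achievable within the attempt budget.
    """
    if density < 0:
        raise DomainError(f"density must be >= 0, got {density}")
    if min_oo <= 0:
        raise DomainError(f"min_oo must be > 0, got {min_oo}")
    box_arr = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    if np.any(box_arr <= 0):
        raise DomainError(f"box lengths must be positive, got {box_arr}")
    free_volume = float(np.prod(box_arr)) - (shape.volume() if shape is not None else 0.0)
    n_target = int(round(density * max(free_volume, 0.0)))
    rng = np.random.default_rng(seed)
    meta = {
        "generator": "generate_water_box",
        "seed": seed,
        "density": density,
        "min_oo": min_oo,
        "n_target": n_target,
    }
    if n_target == 0:
        return WaterFrame(frame_index, np.empty((0, 3)), np.empty((0, 2, 3)),
                          box=box_arr, metadata=meta)

    grid = _CellGrid(box_arr, min_oo, extent=np.array([[0.0, 0.0, 0.0], box_arr]))
    placed: list[np.ndarray] = []
    budget = 200 * n_target + 1000
    attempts = 0
    while len(placed) < n_target and attempts < budget:
        cand = rng.uniform(0.0, box_arr, size=(64, 3))
        if shape is not None:
            sd = np.atleast_1d(shape.signed_distance(cand))
            cand = cand[sd > 0]
        for p in cand:
            attempts += 1
            if grid.ok(p):
                grid.add(p)
                placed.append(p)
                if len(placed) == n_target:
                    break
            if attempts >= budget:
                break
    if len(placed) < n_target:
        raise PackingError(
            f"placed only {len(placed)}/{n_target} waters in {attempts} attempts; "
            f"lower the density or min_oo"
        )
    oxy = np.array(placed)
    hyd = oxy[:, None, :] + _OH_BOND * _random_water_orientations(n_target, rng)
    return WaterFrame(frame_index, oxy, hyd, box=box_arr, metadata=meta)


# ---------------------------------------------------------------------------
# Biased umbrella samples


def _metropolis_window(
    truth: GroundTruthPMF,
    center: float,
    spring_k: float,
    n_samples: int,
    beta: float,
    rng: np.random.Generator,
    n_walkers: int,
    burn_in: int,
    stride: int,
) -> tuple[np.ndarray, dict]:
    lo, hi = truth.domain

    def energy(r):
        return truth(r) + 0.5 * spring_k * (r - center) ** 2

    n_walkers = max(1, min(n_walkers, n_samples))
    x = np.clip(center + 0.05 * rng.standard_normal(n_walkers), lo + 1e-9, hi - 1e-9)
    e = energy(x)
    step = 0.5
    acc_window, tried_window, acc_burn = 0, 0, 0

    def sweep(x, e, step):
        prop = x + rng.uniform(-step, step, x.size)
        inside = (prop > lo) & (prop < hi)
        e_prop = np.where(inside, energy(np.clip(prop, lo, hi)), np.inf)
        with np.errstate(over="ignore", invalid="ignore"):
            accept = rng.random(x.size) < np.exp(np.minimum(0.0, -beta * (e_prop - e)))
        accept &= inside
        return np.where(accept, prop, x), np.where(accept, e_prop, e), int(accept.sum())

    for it in range(burn_in):
        x, e, n_acc = sweep(x, e, step)
        acc_burn += n_acc
        acc_window += n_acc
        tried_window += n_walkers
        if (it + 1) % 100 == 0:
            frac = acc_window / tried_window
            if frac > 0.5:
                step = min(step * 1.15, 5.0)
            elif frac < 0.3:
                step = max(step * 0.85, 1e-3)
            acc_window, tried_window = 0, 0
    if burn_in > 0 and acc_burn == 0:
        raise StepSizeError(
            f"window at center {center}: no accepted moves in {burn_in} burn-in steps"
        )

    per_walker = math.ceil(n_samples / n_walkers)
    collected = np.empty((per_walker, n_walkers))
    acc_prod = 0
    for j in range(per_walker):
        for _ in range(stride):
            x, e, n_acc = sweep(x, e, step)
            acc_prod += n_acc
        collected[j] = x
    samples = collected.ravel()[:n_samples]
    meta = {
        "burn_in": burn_in,
        "stride": stride,
        "n_walkers": n_walkers,
        "step": step,
        "acceptance": acc_prod / max(per_walker * stride * n_walkers, 1),
    }
    return samples, meta


def generate_umbrella_samples(
    truth: GroundTruthPMF,
    centers: Sequence[float],
    spring_k: float = 15.0,
    n_samples: int = 5000,
    temperature: float = 300.0,
    seed: int | None = None,
    n_walkers: int = 64,
    burn_in: int = 5000,
    stride: int = 10,
) -> list[UmbrellaWindow]:
    """Draw biased samples per window from a ground-truth PMF via Metropolis.

    Each window samples the density ∝ exp(−[U(r) + ½k(r−c)²]/k_BT) with a
    batch of independent walkers; the step size is auto-tuned toward 30–50%
    acceptance during burn-in, and every ``stride``-th sweep is collected.
    Burn-in, stride, walker count and acceptance rate are recorded in each
    window's metadata.  Deterministic under ``seed``.
    """
    lo, hi = truth.domain
    centers = [float(c) for c in centers]
    if any(not (lo <= c <= hi) for c in centers):
        raise DomainError(f"all centers must lie in the truth domain [{lo}, {hi}]")
    beta = 1.0 / (GAS_CONSTANT_KJ_MOL_K * temperature)
    children = np.random.SeedSequence(seed).spawn(len(centers))
    windows = []
    for c, child in zip(centers, children):
        rng = np.random.default_rng(child)
        samples, meta = _metropolis_window(
            truth, c, spring_k, n_samples, beta, rng, n_walkers, burn_in, stride
        )
        meta["seed"] = seed
        windows.append(
            UmbrellaWindow(
                center=c,
                spring_k=spring_k,
                samples=samples,
                temperature=temperature,
                metadata=meta,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# Association trajectories with planted transitions


@dataclass
class AssociationSchedule:
    """Bookkeeping planted by :func:`generate_association_trajectory`.

    ``separations`` are non-increasing surface-to-surface gaps (Å);
    ``planted_labels[i]`` is the interfacial mask of frame i;
    ``cumulative_transitions[i]`` the planted number of interfacial→bulk
    moves up to frame i (non-decreasing); ``gap_region_counts[i]`` the count
    restricted to waters within one layer of *both* solutes (the inter-solute
    convention); ``sphere_centers`` the probe positions.
    """

    separations: np.ndarray
    planted_labels: list[np.ndarray]
    cumulative_transitions: np.ndarray
    gap_region_counts: np.ndarray
    sphere_centers: np.ndarray
    layer_cutoff: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.separations.size

    @property
    def total_transitions(self) -> int:
        return int(self.cumulative_transitions[-1])


def _sphere_center_height(target: SoluteShape, sphere_radius: float, sep: float) -> float:
    """Axial sphere-center height giving surface-to-surface gap ``sep``.

    Uses the true geometry of each target kind: flat face, pocket wall/rim,
    or bump cap, with the probe approaching along the +normal axis through
    the patch center.
    """
    if isinstance(target, ConcavePocket):
        top = float(target.top_center[2])
        r_p, depth = target.pocket_radius, target.pocket_depth
        z_cp = top + (r_p - depth)
        a = math.sqrt(depth * (2 * r_p - depth))  # rim radius
        if sphere_radius + sep <= r_p:
            # nested: nearest surface is the pocket wall below the carve center
            return z_cp - (r_p - sphere_radius - sep)
        reach = sphere_radius + sep
        if reach <= a:
            raise ConfigurationError(
                f"separation {sep} unreachable on the pocket axis (rim radius {a:.2f})"
            )
        return top + math.sqrt(reach**2 - a**2)
    if isinstance(target, ConvexBump):
        z_bc = float(target._bump_center[2])
        return z_bc + target.bump_radius + sphere_radius + sep
    if isinstance(target, Slab):
        return float(target.top_center[2]) + sphere_radius + sep
    raise DomainError(f"unsupported target shape kind {target.kind!r}")


def generate_association_trajectory(
    target: SoluteShape,
    sphere_radius: float = 3.5,
    separations: Sequence[float] | None = None,
    layer_cutoff: float = DEFAULT_LAYER_CUTOFF,
    density: float = BULK_WATER_DENSITY,
    packing_fraction: float = 0.8,
    n_shell: int = 40,
    n_bulk: int = 80,
    min_oo: float = 2.4,
    margin: float = 0.3,
    seed: int | None = None,
) -> tuple[list[WaterFrame], AssociationSchedule]:
    """Frames of a probe sphere approaching a target surface, with planted labels.

    The generator tracks the capacity of the shared interfacial shell (points
    within one layer of the union surface inside an axial corridor around the
    approach path) by quasi-Monte-Carlo volume bookkeeping.  As the
    separation shrinks, the capacity drops and the excess "mobile" waters are
    relocated from the shell to the bulk region; the cumulative relocation
    count is the planted interfacial→bulk transition count.  Static shell
    waters away from the corridor and static bulk waters complete the frame.
    Applying :func:`hydroshape.layers.classify_layers` with the union shape
    of each frame reproduces the planted labels exactly, because every water
    is placed with a safety margin inside its band of the same
    signed-distance field the classifier uses.

    Concave targets wrap the probe and lose the most shell volume by contact,
    flat ones less, convex ones least — which is what makes the planted
    transition counts order concave ≥ flat ≥ convex on matched schedules.
    """
    seps = (
        np.linspace(8.0, 1.0, 8)
        if separations is None
        else np.asarray(separations, dtype=float)
    )
    if seps.size < 1:
        raise ConfigurationError("need at least one separation")
    if np.any(np.diff(seps) > 0):
        raise ConfigurationError("separations must be non-increasing")
    if seps[-1] < 0:
        raise ConfigurationError("final separation must be >= 0 (contact)")
    if layer_cutoff > seps[0]:
        raise ConfigurationError(
            f"layer_cutoff {layer_cutoff} exceeds the initial gap {seps[0]}"
        )
    if not isinstance(target, Slab):
        raise DomainError("target must be a slab-based surface (flat, pocket, or bump)")
    if not (0 < margin < layer_cutoff / 2):
        raise ConfigurationError("margin must be in (0, layer_cutoff/2)")

    ss = np.random.SeedSequence(seed)
    s_static, s_qmc, *s_frames = ss.spawn(2 + seps.size)

    top = float(target.top_center[2])
    z_centers = np.array(
        [_sphere_center_height(target, sphere_radius, s) for s in seps]
    )
    spheres = [Sphere(sphere_radius, (0.0, 0.0, zc)) for zc in z_centers]
    unions = [Composite([target, sp]) for sp in spheres]

    r_corr = sphere_radius + layer_cutoff + 1.0
    z_lo = top - (target.pocket_depth if isinstance(target, ConcavePocket) else 0.0) - (
        layer_cutoff + 1.0
    )
    z_hi = float(z_centers[0]) + sphere_radius + layer_cutoff + 1.0
    corr_lo = np.array([-r_corr, -r_corr, z_lo])
    corr_hi = np.array([r_corr, r_corr, z_hi])

    # Fixed Sobol cloud shared by every frame: capacity differences between
    # frames then reflect geometry, not sampling noise.
    sob = qmc.Sobol(d=3, scramble=True, seed=np.random.default_rng(s_qmc))
    pts = corr_lo + sob.random(2**15) * (corr_hi - corr_lo)
    in_corr = pts[:, 0] ** 2 + pts[:, 1] ** 2 <= r_corr**2
    cell_vol = float(np.prod(corr_hi - corr_lo)) / pts.shape[0]

    def shell_capacity(union: SoluteShape) -> float:
        sd = np.atleast_1d(union.signed_distance(pts))
        return float(np.sum(in_corr & (sd >= 0.0) & (sd <= layer_cutoff))) * cell_vol

    rho = density * packing_fraction
    capacities = np.array([shell_capacity(u) for u in unions])
    n_gap = np.minimum.accumulate(np.floor(rho * capacities).astype(int))
    n_mobile = int(n_gap[0])
    cumulative = n_mobile - n_gap

    rng_static = np.random.default_rng(s_static)
    annulus = (r_corr + 1.5, r_corr + 8.0)
    half_patch = min(target.patch) / 2.0
    if annulus[1] > half_patch:
        raise ConfigurationError(
            f"target patch {target.patch} too small for the static annulus "
            f"(needs lateral extent {2 * annulus[1]:.1f} Å)"
        )

    def sample_region(rng, n, accept_fn, grid, z_range, r_xy_range, budget_factor=4000):
        out = []
        attempts, budget = 0, budget_factor * max(n, 1)
        while len(out) < n and attempts < budget:
            m = 256
            r_xy = np.sqrt(rng.uniform(r_xy_range[0] ** 2, r_xy_range[1] ** 2, m))
            phi = rng.uniform(0, 2 * math.pi, m)
            z = rng.uniform(z_range[0], z_range[1], m)
            cand = np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])
            ok = accept_fn(cand)
            for p in cand[ok]:
                attempts += 1
                if grid.ok(p):
                    grid.add(p)
                    out.append(p)
                    if len(out) == n:
                        break
            attempts += int(np.sum(~ok))
        if len(out) < n:
            raise PackingError(
                f"placed only {len(out)}/{n} waters in region after {attempts} attempts"
            )
        return np.array(out)

    extent = np.array([[-annulus[1], -annulus[1], z_lo], [annulus[1], annulus[1], z_hi + 10.0]])
    static_grid = _CellGrid(None, min_oo, extent=extent)

    def shell_accept(p):
        sd = np.atleast_1d(target.signed_distance(p))
        return (sd >= margin) & (sd <= layer_cutoff - margin)

    def bulk_accept(p):
        sd = np.atleast_1d(target.signed_distance(p))
        return sd >= layer_cutoff + margin

    shell_pos = sample_region(
        rng_static, n_shell, shell_accept, static_grid,
        (top - layer_cutoff, top + layer_cutoff), annulus,
    )
    bulk_pos = sample_region(
        rng_static, n_bulk, bulk_accept, static_grid,
        (top + layer_cutoff + margin, z_hi + 10.0), annulus,
    )

    frames: list[WaterFrame] = []
    planted: list[np.ndarray] = []
    gap_counts = np.zeros(seps.size, dtype=int)
    for i, (sep, union, child) in enumerate(zip(seps, unions, s_frames)):
        rng = np.random.default_rng(child)
        frame_grid = _CellGrid(None, min_oo, extent=extent)
        for p in np.vstack([shell_pos, bulk_pos]):
            frame_grid.add(p)

        def union_shell_accept(p, union=union):
            sd = np.atleast_1d(union.signed_distance(p))
            return (p[:, 0] ** 2 + p[:, 1] ** 2 <= r_corr**2) & (sd >= margin) & (
                sd <= layer_cutoff - margin
            )

        gap_pos = sample_region(
            rng, int(n_gap[i]), union_shell_accept, frame_grid,
            (z_lo, z_hi), (0.0, r_corr),
        )
        displaced_pos = sample_region(
            rng, n_mobile - int(n_gap[i]), bulk_accept, frame_grid,
            (top + layer_cutoff + margin, z_hi + 10.0), annulus,
        ) if n_mobile - int(n_gap[i]) > 0 else np.empty((0, 3))

        mobile_pos = np.vstack([gap_pos, displaced_pos]) if n_mobile else np.empty((0, 3))
        oxy = np.vstack([shell_pos, bulk_pos, mobile_pos])
        hyd = oxy[:, None, :] + _OH_BOND * _random_water_orientations(oxy.shape[0], rng)
        frames.append(
            WaterFrame(
                i, oxy, hyd, box=None,
                metadata={"separation": float(sep), "sphere_center_z": float(z_centers[i])},
            )
        )
        labels = np.concatenate(
            [
                np.ones(n_shell, dtype=bool),
                np.zeros(n_bulk, dtype=bool),
                np.ones(int(n_gap[i]), dtype=bool),
                np.zeros(n_mobile - int(n_gap[i]), dtype=bool),
            ]
        )
        planted.append(labels)
        if oxy.shape[0]:
            sd_t = np.atleast_1d(target.signed_distance(oxy))
            sd_s = np.atleast_1d(spheres[i].signed_distance(oxy))
            gap_counts[i] = int(np.sum((sd_t <= layer_cutoff) & (sd_s <= layer_cutoff)))

    schedule = AssociationSchedule(
        separations=seps,
        planted_labels=planted,
        cumulative_transitions=cumulative,
        gap_region_counts=gap_counts,
        sphere_centers=np.column_stack(
            [np.zeros_like(z_centers), np.zeros_like(z_centers), z_centers]
        ),
        layer_cutoff=layer_cutoff,
        metadata={
            "seed": seed,
            "target_kind": target.kind,
            "sphere_radius": sphere_radius,
            "density": density,
            "packing_fraction": packing_fraction,
            "n_shell": n_shell,
            "n_bulk": n_bulk,
            "capacities_A3": capacities.tolist(),
        },
    )
    return frames, schedule
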