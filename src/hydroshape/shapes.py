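"""Implicit solute-surface geometry.

Solutes are represented by signed-distance functions (negative inside the
solid), replacing atomistic graphite/fullerene systems with parametric
convex, flat, and concave surfaces.  Primitives (sphere, slab, pocket, bump)
have exact sign-correct distance fields and closed-form surface area and
volume; arbitrary unions fall back to quasi-Monte-Carlo estimators with a
reported standard error.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.stats import qmc

from .errors import DomainError

__all__ = [
    "SoluteShape",
    "Sphere",
    "Slab",
    "ConcavePocket",
    "ConvexBump",
    "Composite",
    "make_shape",
]


def _cap_volume(r: float, h: float) -> float:
    """Volume of a spherical cap of height h on a sphere of radius r."""
    return math.pi * h * h * (3.0 * r - h) / 3.0


def _cap_area(r: float, h: float) -> float:
    """Lateral (curved) surface area of a spherical cap."""
    return 2.0 * math.pi * r * h


def _cap_base_radius_sq(r: float, h: float) -> float:
    return h * (2.0 * r - h)


class SoluteShape:
    """Base class: an implicit solid with SA/V estimators.

    ``signed_distance`` is negative inside the solid, zero on the surface,
    positive outside.  ``curvature_sign`` characterises the working surface
    patch: +1 convex, 0 flat, −1 concave.
    """

    kind: str = "abstract"
    curvature_sign: int = 0

    def signed_distance(self, points) -> np.ndarray:
        raise NotImplementedError

    def surface_area(self) -> float:
        raise NotImplementedError

    def volume(self) -> float:
        raise NotImplementedError

    def sa_over_v(self) -> float:
        return self.surface_area() / self.volume()

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (lo, hi) of the solid."""
        raise NotImplementedError

    @staticmethod
    def _pts(points) -> tuple[np.ndarray, bool]:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if p.shape[-1] != 3:
            raise DomainError("points must have shape (..., 3)")
        scalar = np.asarray(points).ndim == 1
        return p, scalar

    @staticmethod
    def _ret(values: np.ndarray, scalar: bool):
        return float(values[0]) if scalar else values


class Sphere(SoluteShape):
    """Solid sphere; the convex reference solute (SA/V = 3/R)."""

    kind = "sphere"
    curvature_sign = +1

    def __init__(self, radius: float, center: Sequence[float] = (0.0, 0.0, 0.0)):
        if radius <= 0:
            raise DomainError(f"radius must be > 0, got {radius}")
        self.radius = float(radius)
        self.center = np.asarray(center, dtype=float)

    def signed_distance(self, points):
        p, scalar = self._pts(points)
        d = np.linalg.norm(p - self.center, axis=-1) - self.radius
        return self._ret(d, scalar)

    def surface_area(self) -> float:
        return 4.0 * math.pi * self.radius**2

    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3

    def bounds(self):
        r = self.radius
        return self.center - r, self.center + r


def _orthonormal_frame(normal: Sequence[float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise DomainError("normal must be nonzero")
    n = n / norm
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v, n


class Slab(SoluteShape):
    """Finite rectangular slab (flat reference surface).

    The slab solid is a box: ``patch`` gives the lateral extents (Lx, Ly) in
    the plane perpendicular to ``normal``, ``thickness`` the extent along it.
    The exact box signed distance is used, so edges and corners are metrically
    correct.
    """

    kind = "slab"
    curvature_sign = 0

    def __init__(
        self,
        thickness: float,
        patch: Sequence[float] = (30.0, 30.0),
        center: Sequence[float] = (0.0, 0.0, 0.0),
        normal: Sequence[float] = (0.0, 0.0, 1.0),
    ):
        if thickness <= 0:
            raise DomainError(f"thickness must be > 0, got {thickness}")
        if patch[0] <= 0 or patch[1] <= 0:
            raise DomainError("patch extents must be > 0")
        self.thickness = float(thickness)
        self.patch = (float(patch[0]), float(patch[1]))
        self.center = np.asarray(center, dtype=float)
        self.u, self.v, self.n = _orthonormal_frame(normal)
        self.half = np.array([self.patch[0] / 2.0, self.patch[1] / 2.0, self.thickness / 2.0])

    def _local(self, p: np.ndarray) -> np.ndarray:
        rel = p - self.center
        return np.stack([rel @ self.u, rel @ self.v, rel @ self.n], axis=-1)

    def signed_distance(self, points):
        p, scalar = self._pts(points)
        q = np.abs(self._local(p)) - self.half
        outside = np.linalg.norm(np.maximum(q, 0.0), axis=-1)
        inside = np.minimum(np.max(q, axis=-1), 0.0)
        return self._ret(outside + inside, scalar)

    def surface_area(self) -> float:
        lx, ly = self.patch
        t = self.thickness
        return 2.0 * (lx * ly + t * lx + t * ly)

    def volume(self) -> float:
        return self.patch[0] * self.patch[1] * self.thickness

    def bounds(self):
        corners = []
        for sx in (-1, 1):
            for sy in (-1, 1):
                for sz in (-1, 1):
                    corners.append(
                        self.center
                        + sx * self.half[0] * self.u
                        + sy * self.half[1] * self.v
                        + sz * self.half[2] * self.n
                    )
        c = np.array(corners)
        return c.min(axis=0), c.max(axis=0)

    @property
    def top_center(self) -> np.ndarray:
        """Center of the +normal face (the working patch)."""
        return self.center + self.half[2] * self.n


class ConcavePocket(Slab):
    """Slab with a spherical pocket carved into the +normal face (concave patch).

    The pocket is a cap of depth ``pocket_depth`` cut by a sphere of radius
    ``pocket_radius`` centred on the slab axis.  Closed-form SA/V via
    spherical-cap formulas.
    """

    kind = "concave_pocket"
    curvature_sign = -1

    def __init__(
        self,
        thickness: float,
        pocket_radius: float,
        pocket_depth: float,
        patch: Sequence[float] = (30.0, 30.0),
        center: Sequence[float] = (0.0, 0.0, 0.0),
        normal: Sequence[float] = (0.0, 0.0, 1.0),
    ):
        super().__init__(thickness, patch, center, normal)
        if pocket_radius <= 0:
            raise DomainError("pocket_radius must be > 0")
        if not (0 < pocket_depth <= pocket_radius):
            raise DomainError("pocket_depth must be in (0, pocket_radius]")
        if pocket_depth >= thickness:
            raise DomainError("pocket_depth must be smaller than the slab thickness")
        a2 = _cap_base_radius_sq(pocket_radius, pocket_depth)
        if a2 > (min(self.patch) / 2.0) ** 2:
            raise DomainError("pocket opening exceeds the slab patch")
        self.pocket_radius = float(pocket_radius)
        self.pocket_depth = float(pocket_depth)
        # Carving sphere centred above the face so the removed cap has the
        # requested depth below the face plane.
        self._carve_center = self.top_center + (pocket_radius - pocket_depth) * self.n
        self._carve = Sphere(pocket_radius, self._carve_center)

    def signed_distance(self, points):
        p, scalar = self._pts(points)
        box = np.atleast_1d(Slab.signed_distance(self, p))
        sph = np.atleast_1d(self._carve.signed_distance(p))
        return self._ret(np.maximum(box, -sph), scalar)

    def surface_area(self) -> float:
        r, h = self.pocket_radius, self.pocket_depth
        return Slab.surface_area(self) - math.pi * _cap_base_radius_sq(r, h) + _cap_area(r, h)

    def volume(self) -> float:
        return Slab.volume(self) - _cap_volume(self.pocket_radius, self.pocket_depth)


class ConvexBump(Slab):
    """Slab with a spherical bump protruding from the +normal face (convex patch)."""

    kind = "convex_bump"
    curvature_sign = +1

    def __init__(
        self,
        thickness: float,
        bump_radius: float,
        bump_height: float,
        patch: Sequence[float] = (30.0, 30.0),
        center: Sequence[float] = (0.0, 0.0, 0.0),
        normal: Sequence[float] = (0.0, 0.0, 1.0),
    ):
        super().__init__(thickness, patch, center, normal)
        if bump_radius <= 0:
            raise DomainError("bump_radius must be > 0")
        if not (0 < bump_height <= bump_radius):
            raise DomainError("bump_height must be in (0, bump_radius]")
        a2 = _cap_base_radius_sq(bump_radius, bump_height)
        if a2 > (min(self.patch) / 2.0) ** 2:
            raise DomainError("bump base exceeds the slab patch")
        self.bump_radius = float(bump_radius)
        self.bump_height = float(bump_height)
        self._bump_center = self.top_center - (bump_radius - bump_height) * self.n
        self._bump = Sphere(bump_radius, self._bump_center)

    def signed_distance(self, points):
        p, scalar = self._pts(points)
        box = np.atleast_1d(Slab.signed_distance(self, p))
        sph = np.atleast_1d(self._bump.signed_distance(p))
        return self._ret(np.minimum(box, sph), scalar)

    def surface_area(self) -> float:
        r, h = self.bump_radius, self.bump_height
        return Slab.surface_area(self) - math.pi * _cap_base_radius_sq(r, h) + _cap_area(r, h)

    def volume(self) -> float:
        return Slab.volume(self) + _cap_volume(self.bump_radius, self.bump_height)

    def bounds(self):
        lo, hi = Slab.bounds(self)
        blo, bhi = self._bump.bounds()
        return np.minimum(lo, blo), np.maximum(hi, bhi)


class Composite(SoluteShape):
    """Union of shapes via the pointwise minimum of signed distances.

    The union field is sign-correct everywhere but only approximately metric
    near re-entrant intersections, which is sufficient for layer
    classification and shell-volume bookkeeping.  SA/V are estimated by
    scrambled-Sobol quasi-Monte-Carlo over the joint bounding box; estimates
    carry a standard error from independent scrambles, and the sample size
    grows until the relative standard error target is met (or a cap is hit).
    """

    kind = "composite"

    def __init__(
        self,
        parts: Sequence[SoluteShape],
        seed: int | None = None,
        rel_se_target: float = 0.005,
        shell_half_width: float = 0.25,
        n_replicates: int = 8,
        max_log2_per_replicate: int = 16,
    ):
        if not parts:
            raise DomainError("composite needs at least one part")
        self.parts = list(parts)
        self.seed = seed
        self.rel_se_target = rel_se_target
        self.shell_half_width = shell_half_width
        self.n_replicates = n_replicates
        self.max_log2_per_replicate = max_log2_per_replicate
        self._estimates: dict | None = None
        signs = {p.curvature_sign for p in parts}
        self.curvature_sign = signs.pop() if len(signs) == 1 else 0

    def signed_distance(self, points):
        p, scalar = self._pts(points)
        d = np.min(
            np.stack([np.atleast_1d(part.signed_distance(p)) for part in self.parts]), axis=0
        )
        return self._ret(d, scalar)

    def bounds(self):
        los, his = zip(*(part.bounds() for part in self.parts))
        return np.min(np.array(los), axis=0), np.max(np.array(his), axis=0)

    def _estimate(self) -> dict:
        if self._estimates is not None:
            return self._estimates
        lo, hi = self.bounds()
        pad = self.shell_half_width * 2.0
        lo, hi = lo - pad, hi + pad
        vol_box = float(np.prod(hi - lo))
        eps = self.shell_half_width
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(self.n_replicates)
        m = 12  # starting 2^m points per replicate
        while True:
            vols, areas = [], []
            for child in children:
                sob = qmc.Sobol(d=3, scramble=True, seed=np.random.default_rng(child))
                pts = lo + sob.random(2**m) * (hi - lo)
                sd = np.atleast_1d(self.signed_distance(pts))
                vols.append(np.mean(sd < 0.0) * vol_box)
                shell = np.mean(np.abs(sd) <= eps) * vol_box
                areas.append(shell / (2.0 * eps))
            v, a = float(np.mean(vols)), float(np.mean(areas))
            v_se = float(np.std(vols, ddof=1) / math.sqrt(self.n_replicates))
            a_se = float(np.std(areas, ddof=1) / math.sqrt(self.n_replicates))
            ok = (v <= 0 or v_se <= self.rel_se_target * abs(v)) and (
                a <= 0 or a_se <= self.rel_se_target * abs(a)
            )
            if ok or m >= self.max_log2_per_replicate:
                break
            m += 1
        self._estimates = {
            "volume": v,
            "volume_se": v_se,
            "surface_area": a,
            "surface_area_se": a_se,
            "n_points": self.n_replicates * 2**m,
        }
        return self._estimates

    def volume(self) -> float:
        return self._estimate()["volume"]

    def surface_area(self) -> float:
        return self._estimate()["surface_area"]

    @property
    def volume_standard_error(self) -> float:
        return self._estimate()["volume_se"]

    @property
    def surface_area_standard_error(self) -> float:
        return self._estimate()["surface_area_se"]


def make_shape(kind: str, seed: int | None = None, **params) -> SoluteShape:
    """Factory for solute shapes.

    ``kind`` is one of ``sphere``, ``slab``, ``concave_pocket``,
    ``convex_bump``, ``composite``.  ``seed`` controls the quasi-Monte-Carlo
    scrambling of composite SA/V estimators; primitives ignore it.
    """
    kinds = {
        "sphere": Sphere,
        "slab": Slab,
        "concave_pocket": ConcavePocket,
        "convex_bump": ConvexBump,
    }
    if kind == "composite":
        return Composite(seed=seed, **params)
    if kind not in kinds:
        raise DomainError(f"unknown shape kind {kind!r}; expected one of "
                          f"{sorted(kinds) + ['composite']}")
    return kinds[kind](**params)
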