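"""Umbrella-sampling PMF reconstruction and water-induced decomposition.

Harmonically biased window samples are combined into one unbiased potential
of mean force with the weighted histogram analysis method (WHAM): the
self-consistent equations

    p(b) ∝ Σ_k n_k(b) / Σ_k N_k exp(β f_k − β u_k(b)),
    exp(−β f_k) = Σ_b p(b) exp(−β u_k(b))

are iterated (in log space) until the window free-energy constants f_k move
by less than a tolerance.  PMFs are defined up to a constant and pinned to
zero at the largest sampled separation.  Subtracting the vacuum profile of
the same solutes isolates the water-induced contribution; its contact
minimum and first barrier order the strength of hydrophobic attraction
across surface shapes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.special import logsumexp
from scipy.stats import linregress

from .constants import GAS_CONSTANT_KJ_MOL_K
from .errors import (
    ConnectivityError,
    ConvergenceError,
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
)

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "PMFFeatures",
    "Minimum",
    "Barrier",
    "wham_solve",
    "water_induced_pmf",
    "find_minima_barriers",
    "correlate_energy_transitions",
    "CorrelationResult",
    "rank_surface_interactions",
    "SurfaceRanking",
]


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias plus reaction-coordinate samples.

    ``center`` (Å) and ``spring_k`` (kJ/mol/Å²) define the bias
    u(r) = ½·k·(r − center)²; ``samples`` are the observed reaction-coordinate
    values (Å) under that bias at ``temperature`` (K).
    """

    center: float
    spring_k: float
    samples: np.ndarray
    temperature: float = 300.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.spring_k <= 0:
            raise DomainError(f"spring_k must be > 0, got {self.spring_k}")
        if self.temperature <= 0:
            raise DomainError(f"temperature must be > 0, got {self.temperature}")
        if self.samples.size < 1:
            raise DomainError("window needs at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise DomainError("window samples must all be finite")

    def bias_energy(self, r) -> np.ndarray:
        return 0.5 * self.spring_k * (np.asarray(r, dtype=float) - self.center) ** 2


@dataclass
class PMFProfile:
    """A free-energy profile on a reaction-coordinate grid.

    ``grid`` holds strictly increasing bin centers (Å); ``values`` the free
    energy per bin (kJ/mol, NaN on bins with no samples); ``provenance`` one
    of ``total``, ``vacuum``, ``water_induced``, ``ground_truth``;
    ``reference_point`` the grid location where the profile is pinned to 0.
    """

    grid: np.ndarray
    values: np.ndarray
    provenance: str = "total"
    reference_point: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.grid.size != self.values.size:
            raise DomainError("grid and values must have the same length")
        if self.grid.size > 1 and not np.all(np.diff(self.grid) > 0):
            raise DomainError("grid must be strictly increasing")

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def pinned(self, at: float | None = None) -> "PMFProfile":
        """Return a copy shifted so the value at ``at`` is zero.

        ``at`` defaults to the largest grid point with a finite value; it is
        snapped to the nearest finite bin.
        """
        mask = self.finite_mask
        if not np.any(mask):
            raise DomainError("profile has no finite values to pin")
        finite_grid = self.grid[mask]
        ref = finite_grid[-1] if at is None else finite_grid[np.argmin(np.abs(finite_grid - at))]
        ref_value = self.values[mask][np.argmin(np.abs(finite_grid - ref))]
        return PMFProfile(
            grid=self.grid.copy(),
            values=self.values - ref_value,
            provenance=self.provenance,
            reference_point=float(ref),
        )


def _check_connectivity(windows: Sequence[UmbrellaWindow]) -> None:
    ordered = sorted(windows, key=lambda w: w.center)
    ranges = [(w.samples.min(), w.samples.max(), w.center) for w in ordered]
    reach = ranges[0][1]
    for lo, hi, center in ranges[1:]:
        if lo > reach:
            raise ConnectivityError(
                f"sampled ranges do not overlap: gap between r = {reach:.4f} Å and "
                f"r = {lo:.4f} Å (window centered at {center:.4f} Å)"
            )
        reach = max(reach, hi)


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    bin_width: float = 0.1,
    tolerance: float = 1e-7,
    max_iter: int = 100_000,
    reference_point: float | None = None,
    provenance: str = "total",
) -> PMFProfile:
    """Self-consistent WHAM estimate of the unbiased PMF.

    Iteration stops when the window free-energy constants change by less than
    ``tolerance`` (kJ/mol) between successive iterations.  Empty bins inside
    the sampled range are masked (NaN), not interpolated.  All windows must
    share one temperature.  Raises ConnectivityError when sampled ranges do
    not chain together, and ConvergenceError (carrying the residual) when
    ``max_iter`` is exhausted.
    """
    if len(windows) == 0:
        raise DomainError("need at least one window")
    if bin_width <= 0:
        raise DomainError(f"bin_width must be > 0, got {bin_width}")
    temperatures = {w.temperature for w in windows}
    if len(temperatures) > 1:
        raise DomainError(f"all windows must share one temperature, got {sorted(temperatures)}")
    if len(windows) > 1:
        _check_connectivity(windows)

    temperature = windows[0].temperature
    beta = 1.0 / (GAS_CONSTANT_KJ_MOL_K * temperature)
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    # Divide [lo, hi] evenly at the width closest to the nominal bin_width:
    # a trailing partial bin would under-count and distort the boundary bin.
    span = max(hi - lo, bin_width)
    n_bins = max(int(round(span / bin_width)), 1)
    edges = np.linspace(lo, lo + span, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    n_k = counts.sum(axis=1).astype(float)
    total_b = counts.sum(axis=0).astype(float)
    mask = total_b > 0

    bias = np.stack([w.bias_energy(centers[mask]) for w in windows])  # (K, B')
    bu = beta * bias
    log_nk = np.log(n_k)
    log_num = np.log(total_b[mask])

    g = np.zeros(len(windows))  # β·f_k
    residual = np.inf
    for _ in range(max_iter):
        denom = logsumexp(log_nk[:, None] + g[:, None] - bu, axis=0)
        logp = log_num - denom
        g_new = -logsumexp(logp[None, :] - bu, axis=1)
        g_new -= g_new[0]
        residual = float(np.max(np.abs(g_new - g)) / beta)
        g = g_new
        if residual < tolerance:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} kJ/mol > tolerance {tolerance:.3e})",
            residual=residual,
        )

    values = np.full(n_bins, np.nan)
    values[mask] = -logp / beta
    profile = PMFProfile(grid=centers, values=values, provenance=provenance)
    return profile.pinned(at=reference_point)


def water_induced_pmf(total: PMFProfile, vacuum: PMFProfile) -> PMFProfile:
    """Water-induced PMF: total (in-solvent) minus vacuum profile.

    The vacuum profile is linearly interpolated onto the total profile's grid
    over the overlapping range; the difference is re-pinned to zero at its
    largest finite separation.
    """
    t_mask, v_mask = total.finite_mask, vacuum.finite_mask
    if not np.any(t_mask) or not np.any(v_mask):
        raise DomainError("both profiles need finite values")
    lo = max(total.grid[t_mask].min(), vacuum.grid[v_mask].min())
    hi = min(total.grid[t_mask].max(), vacuum.grid[v_mask].max())
    if lo > hi:
        raise DomainError(
            f"profiles do not overlap: total spans "
            f"[{total.grid[t_mask].min():.3f}, {total.grid[t_mask].max():.3f}] Å, vacuum "
            f"[{vacuum.grid[v_mask].min():.3f}, {vacuum.grid[v_mask].max():.3f}] Å"
        )
    sel = (total.grid >= lo) & (total.grid <= hi)
    grid = total.grid[sel]
    vac = np.interp(grid, vacuum.grid[v_mask], vacuum.values[v_mask])
    diff = total.values[sel] - vac
    profile = PMFProfile(grid=grid, values=diff, provenance="water_induced")
    return profile.pinned()


@dataclass(frozen=True)
class Minimum:
    position: float
    depth: float
    rank: int


@dataclass(frozen=True)
class Barrier:
    position: float
    height: float  # above the preceding (smaller-r) minimum


@dataclass
class PMFFeatures:
    """Located minima (ordered by position) and the barriers between them."""

    minima: list[Minimum]
    barriers: list[Barrier]


def find_minima_barriers(profile: PMFProfile, prominence_min: float = 0.5) -> PMFFeatures:
    """Locate local PMF minima and inter-minima barriers.

    Minima are interior local minima with topographic prominence of at least
    ``prominence_min`` (kJ/mol), reported in order of position (rank 1 is the
    smallest separation — the contact minimum when the profile has one).
    Each barrier is the highest point between two adjacent minima, with its
    height measured above the left (preceding) minimum.
    """
    if profile.grid.size < 5:
        raise DomainError(f"profile needs >= 5 grid points, got {profile.grid.size}")
    v = profile.values.copy()
    v[~np.isfinite(v)] = np.inf  # masked bins can be neither minima nor counted twice
    idx, _ = find_peaks(-v, prominence=prominence_min)
    minima = [
        Minimum(position=float(profile.grid[i]), depth=float(profile.values[i]), rank=r + 1)
        for r, i in enumerate(idx)
    ]
    barriers = []
    for left, right in zip(idx[:-1], idx[1:]):
        seg = profile.values[left + 1 : right]
        if seg.size == 0 or not np.any(np.isfinite(seg)):
            continue
        j = int(np.nanargmax(seg)) + left + 1
        barriers.append(
            Barrier(
                position=float(profile.grid[j]),
                height=float(profile.values[j] - profile.values[left]),
            )
        )
    return PMFFeatures(minima=minima, barriers=barriers)


@dataclass(frozen=True)
class CorrelationResult:
    """OLS line and Pearson correlation of ΔG_water_induced vs. transition count."""

    slope: float
    intercept: float
    r_value: float
    stderr: float
    n_pairs: int


def correlate_energy_transitions(
    pairs: Sequence[tuple[float, int]] | np.ndarray,
) -> CorrelationResult:
    """Regress water-induced free energy on interfacial→bulk counts.

    ``pairs`` holds (ΔG_water_induced kJ/mol, n_interfacial_to_bulk) rows.
    When each expelled molecule is worth ΔG_DDAA, the slope recovers
    ΔG_DDAA.  Fewer than 3 pairs, or counts with no variance, are degenerate.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("pairs must be rows of (dG_water_induced, n_interfacial_to_bulk)")
    if arr.shape[0] < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {arr.shape[0]}")
    dg, n = arr[:, 0], arr[:, 1]
    if np.ptp(n) == 0:
        raise DegenerateDataError("transition counts have zero variance")
    res = linregress(n, dg)
    return CorrelationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_value=float(res.rvalue),
        stderr=float(res.stderr),
        n_pairs=arr.shape[0],
    )


@dataclass
class SurfaceRanking:
    """Surface-shape ordering by contact-minimum depth and first-barrier height.

    ``by_contact_depth`` lists (label, depth) ascending in depth — the most
    negative (strongest attraction) first.  ``by_first_barrier`` lists
    (label, height) descending.  Exact ties are reported as groups of labels.
    """

    by_contact_depth: list[tuple[str, float]]
    by_first_barrier: list[tuple[str, float]]
    depth_ties: list[tuple[str, ...]]
    barrier_ties: list[tuple[str, ...]]
    excluded: list[str]


def _tie_groups(items: list[tuple[str, float]]) -> list[tuple[str, ...]]:
    groups: dict[float, list[str]] = {}
    for label, value in items:
        groups.setdefault(value, []).append(label)
    return [tuple(labels) for labels in groups.values() if len(labels) > 1]


def rank_surface_interactions(
    profiles: Mapping[str, PMFProfile], prominence_min: float = 0.5
) -> SurfaceRanking:
    """Order labelled water-induced profiles by hydrophobic-attraction strength.

    Profiles with no detected minimum are excluded with a warning.  Deeper
    contact minima and higher first barriers indicate stronger water-mediated
    attraction; concave targets engulf more interfacial water than flat or
    convex ones and so rank first under both orderings.
    """
    depths, barriers, excluded = [], [], []
    for label, profile in profiles.items():
        feats = find_minima_barriers(profile, prominence_min=prominence_min)
        if not feats.minima:
            warnings.warn(f"profile {label!r} has no detected minimum; excluded from ranking")
            excluded.append(label)
            continue
        depths.append((label, feats.minima[0].depth))
        if feats.barriers:
            barriers.append((label, feats.barriers[0].height))
    by_depth = sorted(depths, key=lambda t: t[1])
    by_barrier = sorted(barriers, key=lambda t: -t[1])
    return SurfaceRanking(
        by_contact_depth=by_depth,
        by_first_barrier=by_barrier,
        depth_ties=_tie_groups(by_depth),
        barrier_ties=_tie_groups(by_barrier),
        excluded=excluded,
    )
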