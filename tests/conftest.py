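import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hydroshape as hs

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ambient():
    return hs.ThermoConstants.ambient()


@pytest.fixture(scope="session")
def bulk_box_frame():
    """A periodic water-like packing at ambient density, no solute."""
    return hs.generate_water_box(None, 18.0, density=hs.BULK_WATER_DENSITY, seed=42)


@pytest.fixture(scope="session")
def double_well_truth():
    return hs.default_double_well()


@pytest.fixture(scope="session")
def small_umbrella_windows(double_well_truth):
    """Modest-size biased samples from the default double-well truth."""
    return hs.generate_umbrella_samples(
        double_well_truth, np.arange(3.0, 13.1, 1.0), spring_k=15.0,
        n_samples=2000, seed=7,
    )


def random_water_frame(rng: np.random.Generator, n: int, box: float | None = None):
    """Random frame with plausible O–H geometry for oracle comparisons."""
    span = box if box is not None else 12.0
    oxy = rng.uniform(0, span, size=(n, 3))
    u1 = rng.standard_normal((n, 3))
    u1 /= np.linalg.norm(u1, axis=1, keepdims=True)
    helper = np.where(np.abs(u1[:, :1]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    e1 = np.cross(u1, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(u1, e1)
    phi = rng.uniform(0, 2 * np.pi, n)[:, None]
    theta = np.radians(104.5)
    u2 = np.cos(theta) * u1 + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
    hyd = oxy[:, None, :] + 0.96 * np.stack([u1, u2], axis=1)
    return hs.WaterFrame(
        frame_index=0, oxygen_positions=oxy, hydrogen_positions=hyd,
        box=np.full(3, box) if box is not None else None,
    )


def brute_force_hbond_edges(frame, criterion=None):
    """All-pairs reference implementation of the geometric H-bond criterion.

    Independent of the KD-tree path: exhaustive loops, with the same
    nearest-acceptor resolution per donated hydrogen.
    """
    criterion = criterion or hs.HBondCriterion()
    cos_max = np.cos(np.radians(criterion.angle_ooh_max_deg))
    n = frame.n_waters
    candidates: dict[tuple[int, int], list[tuple[float, int]]] = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            doo = frame.minimum_image(frame.oxygen_positions[j] - frame.oxygen_positions[i])
            d = float(np.linalg.norm(doo))
            if d >= criterion.r_oo_max:
                continue
            for h in range(2):
                oh = frame.minimum_image(
                    frame.hydrogen_positions[i, h] - frame.oxygen_positions[i]
                )
                cosang = float(doo @ oh / (d * np.linalg.norm(oh)))
                if cosang > cos_max:
                    candidates.setdefault((i, h), []).append((d, j))
    edges = set()
    for (i, h), lst in candidates.items():
        lst.sort()
        edges.add((i, h, lst[0][1]))
    return edges
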