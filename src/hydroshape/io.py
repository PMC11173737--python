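"""Readers and writers for the package's on-disk formats.

Frames travel as XYZ (atom order O, H, H per molecule; generator metadata as
a JSON comment line) or PDB (residue-grouped waters, read via MDAnalysis).
Umbrella windows, free-energy profiles, layer labels and hydrogen-bond edge
lists are tab-separated tables; PMF features and association schedules are
JSON.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FrameValidationError
from .frames import WaterFrame
from .hbonds import HBondGraph
from .layers import LayerLabels
from .pmf import PMFFeatures, PMFProfile, UmbrellaWindow
from .synth import AssociationSchedule

__all__ = [
    "write_xyz",
    "read_xyz",
    "read_pdb",
    "write_windows_tsv",
    "read_windows",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_features_json",
    "write_schedule_json",
    "write_hbond_edges_tsv",
    "write_labels_tsv",
    "atomic_write_text",
]

_WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL", "H2O", "TIP"}


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` atomically (temp file + rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_xyz(frames: Sequence[WaterFrame], path: str | Path, metadata: dict | None = None) -> None:
    """Write frames as multi-frame XYZ with O,H,H atom order per molecule.

    The per-frame comment line carries a JSON object with the frame index,
    any frame metadata, and the optional file-level ``metadata``.
    """
    lines: list[str] = []
    for frame in frames:
        n = frame.n_waters
        comment = {"frame": frame.frame_index, **frame.metadata, **(metadata or {})}
        if frame.box is not None:
            comment["box"] = list(map(float, frame.box))
        lines.append(str(3 * n))
        lines.append(json.dumps(comment))
        for i in range(n):
            ox, oy, oz = frame.oxygen_positions[i]
            lines.append(f"O {ox:.6f} {oy:.6f} {oz:.6f}")
            for h in range(2):
                hx, hy, hz = frame.hydrogen_positions[i, h]
                lines.append(f"H {hx:.6f} {hy:.6f} {hz:.6f}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def _frames_from_universe(universe, comments: list[dict] | None = None) -> list[WaterFrame]:
    names = [n.upper() for n in universe.atoms.names]
    frames = []
    for k, _ts in enumerate(universe.trajectory):
        pos = universe.atoms.positions.astype(float)
        if len(names) % 3 != 0:
            raise FrameValidationError("atom count is not a multiple of 3 (O,H,H per water)")
        oxy, hyd = [], []
        for i in range(0, len(names), 3):
            if not (names[i].startswith("O") and names[i + 1].startswith("H")
                    and names[i + 2].startswith("H")):
                raise FrameValidationError(
                    f"expected O,H,H atom order at atom {i}, got "
                    f"{names[i:i + 3]}"
                )
            oxy.append(pos[i])
            hyd.append([pos[i + 1], pos[i + 2]])
        comment = comments[k] if comments else {}
        box = np.asarray(comment["box"], dtype=float) if "box" in comment else None
        frames.append(
            WaterFrame(
                frame_index=int(comment.get("frame", k)),
                oxygen_positions=np.array(oxy).reshape(-1, 3),
                hydrogen_positions=np.array(hyd).reshape(-1, 2, 3),
                box=box,
                metadata={k2: v for k2, v in comment.items() if k2 not in ("frame", "box")},
            )
        )
    return frames


def _xyz_comments(path: Path) -> list[dict]:
    comments = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment_line = fh.readline().strip()
            try:
                comments.append(json.loads(comment_line))
            except json.JSONDecodeError:
                comments.append({})
            for _ in range(n):
                fh.readline()
    return comments


def read_xyz(path: str | Path) -> list[WaterFrame]:
    """Read a multi-frame XYZ water file (O,H,H per molecule)."""
    import MDAnalysis as mda

    path = Path(path)
    universe = mda.Universe(str(path), format="XYZ")
    return _frames_from_universe(universe, _xyz_comments(path))


def read_pdb(path: str | Path) -> list[WaterFrame]:
    """Read waters from a PDB file, grouped by residue.

    Residues with standard water residue names are used; each must contain
    one oxygen and two hydrogens.
    """
    import MDAnalysis as mda

    universe = mda.Universe(str(path))
    waters = universe.select_atoms(
        "resname " + " ".join(sorted(_WATER_RESNAMES))
    )
    if len(waters) == 0:
        raise FrameValidationError("no water residues found in PDB")
    dims = universe.dimensions
    box = None
    if dims is not None and np.all(dims[:3] > 0):
        box = np.asarray(dims[:3], dtype=float)
    frames = []
    for k, _ts in enumerate(universe.trajectory):
        oxy, hyd = [], []
        for res in waters.residues:
            o_atoms = res.atoms.select_atoms("name O* OW")
            h_atoms = res.atoms.select_atoms("name H* HW*")
            if len(o_atoms) != 1 or len(h_atoms) != 2:
                raise FrameValidationError(
                    f"residue {res.resid} has {len(o_atoms)} O and {len(h_atoms)} H atoms; "
                    "expected 1 and 2"
                )
            oxy.append(o_atoms.positions[0].astype(float))
            hyd.append(h_atoms.positions.astype(float))
        frames.append(
            WaterFrame(
                frame_index=k,
                oxygen_positions=np.array(oxy).reshape(-1, 3),
                hydrogen_positions=np.array(hyd).reshape(-1, 2, 3),
                box=box,
            )
        )
    return frames


_WINDOW_COLUMNS = ["window_id", "center_A", "spring_k_kJ_mol_A2", "sample_A", "temperature_K"]


def write_windows_tsv(windows: Sequence[UmbrellaWindow], path: str | Path) -> None:
    """Write umbrella windows as one long-format TSV."""
    parts = []
    for i, w in enumerate(windows):
        parts.append(
            pd.DataFrame(
                {
                    "window_id": i,
                    "center_A": w.center,
                    "spring_k_kJ_mol_A2": w.spring_k,
                    "sample_A": w.samples,
                    "temperature_K": w.temperature,
                }
            )
        )
    df = pd.concat(parts, ignore_index=True)
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def _windows_from_df(df: pd.DataFrame) -> list[UmbrellaWindow]:
    required = {"center_A", "spring_k_kJ_mol_A2", "sample_A"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"window table is missing columns {sorted(missing)}")
    if "window_id" not in df.columns:
        df = df.assign(window_id=0)
    windows = []
    for _wid, group in df.groupby("window_id", sort=True):
        centers = group["center_A"].unique()
        springs = group["spring_k_kJ_mol_A2"].unique()
        if len(centers) != 1 or len(springs) != 1:
            raise DomainError("center/spring_k must be constant within a window_id")
        temp = (
            float(group["temperature_K"].iloc[0])
            if "temperature_K" in group.columns
            else 300.0
        )
        windows.append(
            UmbrellaWindow(
                center=float(centers[0]),
                spring_k=float(springs[0]),
                samples=group["sample_A"].to_numpy(dtype=float),
                temperature=temp,
            )
        )
    return windows


def read_windows(path: str | Path) -> list[UmbrellaWindow]:
    """Read umbrella windows from a TSV file, or a directory of one-file-per-window TSVs."""
    path = Path(path)
    if path.is_dir():
        windows = []
        for f in sorted(path.glob("*.tsv")):
            windows.extend(_windows_from_df(pd.read_csv(f, sep="\t", comment="#")))
        if not windows:
            raise DomainError(f"no .tsv window files found in {path}")
        return windows
    return _windows_from_df(pd.read_csv(path, sep="\t", comment="#"))


def write_profile_tsv(profile: PMFProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        {"r_A": profile.grid, "dG_kJ_mol": profile.values, "provenance": profile.provenance}
    )
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def read_profile_tsv(path: str | Path) -> PMFProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    provenance = str(df["provenance"].iloc[0]) if "provenance" in df.columns else "total"
    return PMFProfile(
        grid=df["r_A"].to_numpy(dtype=float),
        values=df["dG_kJ_mol"].to_numpy(dtype=float),
        provenance=provenance,
    )


def write_features_json(features: PMFFeatures, path: str | Path) -> None:
    payload = {
        "minima": [
            {"position_A": m.position, "depth_kJ_mol": m.depth, "rank": m.rank}
            for m in features.minima
        ],
        "barriers": [
            {"position_A": b.position, "height_kJ_mol": b.height} for b in features.barriers
        ],
    }
    atomic_write_text(path, json.dumps(payload, indent=2) + "\n")


def write_schedule_json(schedule: AssociationSchedule, path: str | Path) -> None:
    payload = {
        "separations_A": schedule.separations.tolist(),
        "cumulative_transitions": schedule.cumulative_transitions.tolist(),
        "gap_region_counts": schedule.gap_region_counts.tolist(),
        "sphere_centers_A": schedule.sphere_centers.tolist(),
        "layer_cutoff_A": schedule.layer_cutoff,
        "planted_interfacial_counts": [int(m.sum()) for m in schedule.planted_labels],
        "metadata": schedule.metadata,
    }
    atomic_write_text(path, json.dumps(payload, indent=2) + "\n")


def write_hbond_edges_tsv(graph: HBondGraph, path: str | Path) -> None:
    df = pd.DataFrame(graph.edges, columns=["donor", "hydrogen", "acceptor"])
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def write_labels_tsv(labels: LayerLabels, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "molecule": np.arange(labels.n_molecules),
            "layer": np.where(labels.is_interfacial, "interfacial", "bulk"),
        }
    )
    atomic_write_text(path, df.to_csv(sep="\t", index=False))
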