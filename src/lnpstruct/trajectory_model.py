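"""Trajectory and topology containers, readers/writers, leaflet logic.

Conventions
-----------
* z is the membrane normal; analyses recenter the membrane center of
  mass to z = 0 per frame.
* Coordinates are in Angstrom, times in ns, masses in amu.
* Atom and lipid ids are 1-based in files, 0-based arrays internally
  (array position == atom order in the topology table).

Two trajectory formats are supported: multi-model PDB (MODEL/ENDMDL
with a CRYST1 box record, read via MDAnalysis) and a documented plain
text format (see :func:`write_plain_frames`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "Trajectory",
    "FormatError",
    "TopologyError",
    "load_trajectory",
    "write_trajectory",
    "load_topology",
    "write_topology",
    "load_pressure_profile",
    "assign_leaflets",
    "select_analysis_frames",
]

ROLES = ("head", "tail", "linker", "other")
CHARGE_STATES = ("neutral", "protonated")
REFERENCE_KINDS = ("phosphate_P", "hydroxyl_O", "head_N", "none")
LIPID_TYPES = ("ionizable", "helper", "cholesterol", "peg", "other")

TOPOLOGY_COLUMNS = (
    "atom_id", "lipid_id", "lipid_type", "charge_state", "role",
    "is_terminal_tail", "reference_kind", "mass",
)


class FormatError(ValueError):
    """Malformed trajectory or profile file."""


class TopologyError(ValueError):
    """Topology table violates an invariant."""


@dataclass
class Topology:
    """Per-atom metadata table mapping atoms to lipids and roles."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TOPOLOGY_COLUMNS if c not in self.table.columns]
        if missing:
            raise TopologyError(f"topology missing columns: {missing}")
        t = self.table
        for col, allowed in (
            ("role", ROLES),
            ("charge_state", CHARGE_STATES),
            ("reference_kind", REFERENCE_KINDS),
            ("lipid_type", LIPID_TYPES),
        ):
            bad = set(t[col].unique()) - set(allowed)
            if bad:
                raise TopologyError(f"invalid {col} value(s): {sorted(bad)}")
        if (t["mass"] <= 0).any():
            raise TopologyError("masses must be positive")
        # Ionizable lipids analyzed for CPP need a head group and a
        # defined tail end; auto-flag the last tail atom of a lipid
        # whose tails carry no terminal flag (chain-end convention).
        for lid, grp in t.groupby("lipid_id"):
            if len(grp) == 0:
                raise TopologyError(f"lipid {lid} has no atoms")
            if grp["lipid_type"].iloc[0] == "ionizable":
                if not (grp["role"] == "head").any():
                    raise TopologyError(f"ionizable lipid {lid} has no head atoms")
                tails = grp[grp["role"] == "tail"]
                if len(tails) and not tails["is_terminal_tail"].any():
                    warnings.warn(
                        f"lipid {lid}: no terminal-tail flag; "
                        "auto-flagging last tail atom",
                        stacklevel=2,
                    )
                    self.table.loc[tails.index[-1], "is_terminal_tail"] = True

    @property
    def n_atoms(self) -> int:
        return len(self.table)

    @property
    def masses(self) -> np.ndarray:
        return self.table["mass"].to_numpy(dtype=float)

    @property
    def lipid_ids(self) -> np.ndarray:
        return np.sort(self.table["lipid_id"].unique())

    def atoms_of(self, lipid_id: int, role: str | None = None,
                 terminal_only: bool = False) -> np.ndarray:
        """0-based array indices of a lipid's atoms, optionally filtered."""
        t = self.table
        mask = t["lipid_id"] == lipid_id
        if role is not None:
            mask &= t["role"] == role
        if terminal_only:
            mask &= t["is_terminal_tail"]
        return np.flatnonzero(mask.to_numpy())

    def reference_atoms(self, kind: str | None = None) -> np.ndarray:
        mask = self.table["reference_kind"] != "none"
        if kind is not None:
            mask = self.table["reference_kind"] == kind
        return np.flatnonzero(mask.to_numpy())

    def ionizable_lipids(self, charge_state: str | None = None) -> np.ndarray:
        t = self.table
        mask = t["lipid_type"] == "ionizable"
        if charge_state is not None:
            mask &= t["charge_state"] == charge_state
        return np.sort(t.loc[mask, "lipid_id"].unique())


@dataclass
class Trajectory:
    """Frames of per-atom coordinates with box dimensions.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; ``times``
    is in ns (strictly increasing); ``box`` is (n_frames, 3) with
    (Lx, Ly, Lz) per frame.
    """

    times: np.ndarray
    coords: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.coords) or len(self.box) != len(self.coords):
            raise FormatError("times/coords/box frame counts disagree")
        if np.any(np.diff(self.times) <= 0):
            raise FormatError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def frame_spacing(self) -> float:
        if self.n_frames < 2:
            return 1.0
        return float(self.times[1] - self.times[0])


# ---------------------------------------------------------------------------
# Trajectory I/O


def write_trajectory(
    path: str | Path,
    traj: Trajectory,
    fmt: Literal["pdb_multimodel", "plain_frames"] = "pdb_multimodel",
) -> None:
    if fmt == "plain_frames":
        write_plain_frames(path, traj)
        return
    if fmt != "pdb_multimodel":
        raise ValueError(f"unknown trajectory format: {fmt!r}")
    import MDAnalysis as mda

    n = traj.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, trajectory=True)
        u.add_TopologyAttr("names", ["C"] * n)
        u.add_TopologyAttr("elements", ["C"] * n)
        u.add_TopologyAttr("resids", [1])
        u.add_TopologyAttr("resnames", ["LIP"])
        with mda.Writer(str(path), n, multiframe=True) as writer:
            for f in range(traj.n_frames):
                u.dimensions = [*traj.box[f], 90.0, 90.0, 90.0]
                u.atoms.positions = traj.coords[f]
                writer.write(u.atoms)


def _read_pdb_multimodel(path: str | Path, dt: float) -> Trajectory:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        frames = []
        boxes = []
        for ts in u.trajectory:
            frames.append(u.atoms.positions.copy())
            boxes.append(None if ts.dimensions is None else ts.dimensions[:3].copy())
    if any(b is None for b in boxes):
        # MDAnalysis only attaches CRYST1 records embedded inside a
        # MODEL block; a single header CRYST1 (constant-volume runs)
        # applies to every frame.
        global_box = _scan_global_cryst1(path)
        boxes = [global_box if b is None else b for b in boxes]
    coords = np.stack(frames)
    times = np.arange(coords.shape[0], dtype=float) * dt
    return Trajectory(times=times, coords=coords, box=np.stack(boxes))


def _scan_global_cryst1(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                return np.array(
                    [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                )
    raise FormatError(f"no CRYST1 record in {path}")


PLAIN_HEADER = "# lnpstruct plain_frames v1"


def write_plain_frames(path: str | Path, traj: Trajectory) -> None:
    """Plain text trajectory: header, then per frame a line
    ``frame <t_ns> <Lx> <Ly> <Lz>`` followed by one ``x y z`` line per
    atom (Angstrom, full float precision)."""
    with open(path, "w") as fh:
        fh.write(f"{PLAIN_HEADER}\n")
        fh.write(f"natoms {traj.n_atoms}\n")
        for f in range(traj.n_frames):
            bx = traj.box[f]
            fh.write(f"frame {traj.times[f]:.6f} {bx[0]:.6f} {bx[1]:.6f} {bx[2]:.6f}\n")
            for xyz in traj.coords[f]:
                fh.write(f"{xyz[0]:.10g} {xyz[1]:.10g} {xyz[2]:.10g}\n")


def _read_plain_frames(path: str | Path) -> Trajectory:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise FormatError("missing plain_frames header")
    if not lines[1].startswith("natoms"):
        raise FormatError("missing natoms line")
    n_atoms = int(lines[1].split()[1])
    times, boxes, frames = [], [], []
    i = 2
    frame_no = 0
    while i < len(lines):
        parts = lines[i].split()
        if parts[0] != "frame":
            raise FormatError(f"expected 'frame' line at line {i + 1}")
        times.append(float(parts[1]))
        boxes.append([float(p) for p in parts[2:5]])
        block = lines[i + 1 : i + 1 + n_atoms]
        if len(block) < n_atoms or any(b.split()[0] == "frame" for b in block):
            raise FormatError(f"frame {frame_no}: expected {n_atoms} atom lines")
        frames.append([[float(v) for v in b.split()] for b in block])
        i += 1 + n_atoms
        frame_no += 1
    return Trajectory(
        times=np.array(times), coords=np.array(frames), box=np.array(boxes)
    )


def load_trajectory(
    path: str | Path,
    fmt: Literal["pdb_multimodel", "plain_frames"] = "pdb_multimodel",
    dt: float = 1.0,
) -> Trajectory:
    """Load a trajectory; ``dt`` (ns) assigns times to PDB models,
    which carry no time stamps."""
    if fmt == "pdb_multimodel":
        return _read_pdb_multimodel(path, dt)
    if fmt == "plain_frames":
        return _read_plain_frames(path)
    raise ValueError(f"unknown trajectory format: {fmt!r}")


# ---------------------------------------------------------------------------
# Topology and pressure-profile I/O


def load_topology(path: str | Path) -> Topology:
    df = pd.read_csv(path)
    if "is_terminal_tail" in df.columns:
        df["is_terminal_tail"] = df["is_terminal_tail"].astype(bool)
    return Topology(df)


def write_topology(path: str | Path, topo: Topology) -> None:
    topo.table.to_csv(path, index=False)


def load_pressure_profile(path: str | Path):
    """Read a pressure-profile CSV (z, p_xx, p_yy, p_zz) into a
    :class:`~lnpstruct.membrane_features.PressureProfile`."""
    from .membrane_features import PressureProfile

    df = pd.read_csv(path)
    required = {"z", "p_xx", "p_yy", "p_zz"}
    if not required <= set(df.columns):
        raise FormatError(f"pressure profile needs columns {sorted(required)}")
    return PressureProfile(
        z=df["z"].to_numpy(dtype=float),
        p_xx=df["p_xx"].to_numpy(dtype=float),
        p_yy=df["p_yy"].to_numpy(dtype=float),
        p_zz=df["p_zz"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Geometry helpers


def membrane_midplane_z(traj: Trajectory, topo: Topology, frame: int) -> float:
    """Mass-weighted z of the membrane center of mass in one frame."""
    m = topo.masses
    return float(np.average(traj.coords[frame, :, 2], weights=m))


def assign_leaflets(
    traj: Trajectory, topo: Topology, frame: int
) -> dict[int, str]:
    """Map lipid_id -> 'upper'/'lower' by reference-atom z (fallback:
    lipid center of mass) relative to the membrane midplane."""
    mid = membrane_midplane_z(traj, topo, frame)
    z = traj.coords[frame, :, 2]
    masses = topo.masses
    out: dict[int, str] = {}
    ref_mask = (topo.table["reference_kind"] != "none").to_numpy()
    lipid_col = topo.table["lipid_id"].to_numpy()
    for lid in topo.lipid_ids:
        lipid_mask = lipid_col == lid
        ref = lipid_mask & ref_mask
        sel = ref if ref.any() else lipid_mask
        zref = np.average(z[sel], weights=masses[sel])
        out[int(lid)] = "upper" if zref > mid else "lower"
    return out


def select_analysis_frames(
    traj: Trajectory, window_ns: float, stride_ns: float
) -> np.ndarray:
    """Frame indices covering the final ``window_ns`` of the run at
    ``stride_ns`` spacing, counted backward so the last frame is
    always included."""
    t = traj.times
    span = t[-1] - t[0]
    if window_ns > span + traj.frame_spacing:
        raise ValueError(
            f"analysis window {window_ns} ns exceeds trajectory span {span} ns"
        )
    in_window = np.flatnonzero(t > t[-1] - window_ns)
    step = max(1, int(round(stride_ns / traj.frame_spacing)))
    picked = in_window[::-1][::step][::-1]
    return picked
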