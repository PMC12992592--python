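"""Trajectory-derived bilayer estimators.

Critical packing parameter (CPP) by two routes:

* ``cpp_v`` models each ionizable lipid as a truncated cone,
  CPP_V = V / (a0 * l_c) with a0 = pi r_head^2 and
  V = (pi l_c / 3)(r_head^2 + r_head r_tail + r_tail^2), where r_head
  (r_tail) is half the maximum pairwise in-plane distance among head
  (terminal tail) atoms and l_c is the mean distance from the
  head-group centroid to each terminal tail atom.  Note l_c cancels,
  so CPP_V depends only on the radii.
* ``cpp_rg`` aligns each lipid's head-to-tail axis to the membrane
  normal and takes the ratio of mass-weighted planar radii of gyration
  of tail and head atom subsets.

CPP < 1 indicates a cone (positive curvature), CPP close to 1 a
cylinder, CPP > 1 an inverted cone (negative curvature, associated
with the inverse hexagonal phase and membrane fusion).

Also provided: component density profiles along the membrane normal,
bilayer thickness from leaflet reference-atom planes, monolayer torque
density from the first moment of the lateral pressure profile, area
compressibility from projected-area fluctuations, and the
escaped-lipid stability screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .synthetic_data import BOLTZMANN_J_PER_K
from .trajectory_model import (
    Topology,
    TopologyError,
    Trajectory,
    membrane_midplane_z,
)

__all__ = [
    "LipidGeometry",
    "CPPResult",
    "PressureProfile",
    "TorqueResult",
    "CompressibilityResult",
    "StabilityReport",
    "Shape",
    "compute_lipid_geometry",
    "compute_cpp_v",
    "compute_cpp_rg",
    "classify_shape",
    "compute_density_profile",
    "compute_thickness",
    "compute_torque_density",
    "compute_area_compressibility",
    "classify_stability",
]


class Shape(Enum):
    CONE = "cone"
    CYLINDER = "cylinder"
    INVERTED_CONE = "inverted_cone"


@dataclass(frozen=True)
class LipidGeometry:
    """Truncated-cone descriptors of one lipid in one frame."""

    lipid_id: int
    frame: int
    r_head: float
    r_tail: float
    l_c: float
    a_0: float
    V: float
    degenerate: bool


@dataclass
class CPPResult:
    method: str  # "cpp_v" | "cpp_rg"
    per_lipid_means: dict[int, float]
    pooled_mean: float
    dispersion: float  # SEM across lipid means (cpp_v), SD of values (cpp_rg)
    dispersion_kind: str  # "sem" | "sd"
    variance_across_lipids: float
    frame_variance: float  # variance of the pooled lipid-frame values
    n_lipids: int
    n_frames: int
    excluded_lipids: int


@dataclass(frozen=True)
class PressureProfile:
    """Lateral pressure table on uniform z bins (bar, Angstrom)."""

    z: np.ndarray
    p_xx: np.ndarray
    p_yy: np.ndarray
    p_zz: np.ndarray

    def __post_init__(self) -> None:
        widths = np.diff(self.z)
        if len(widths) == 0 or not np.allclose(widths, widths[0], rtol=1e-6):
            raise ValueError("pressure profile bins must be uniform")

    @property
    def bin_width(self) -> float:
        return float(self.z[1] - self.z[0])

    @property
    def Lz(self) -> float:
        return float(self.z[-1] - self.z[0] + self.bin_width)


@dataclass
class TorqueResult:
    tau_upper: float
    tau_lower: float
    tau_mean_literal: float  # (tau_up + tau_low)/2; 0 for symmetric profiles
    tau_mean_leaflet: float  # (tau_up - tau_low)/2; leaflet-oriented average
    p_lateral: np.ndarray = field(repr=False)
    z: np.ndarray = field(repr=False)


@dataclass
class CompressibilityResult:
    K_A: float  # mN/m
    mean_area: float  # Angstrom^2
    area_variance: float  # Angstrom^4
    temperature: float  # K


@dataclass
class StabilityReport:
    escaped_lipids: list[tuple[int, int]]  # (lipid_id, first escape frame)
    stable: bool
    escape_margin: float
    persistence: int


# ---------------------------------------------------------------------------
# Per-lipid geometry and CPP_V


def _half_max_pairwise(xy: np.ndarray) -> float:
    if len(xy) < 2:
        return 0.0
    return 0.5 * float(pdist(xy).max())


def compute_lipid_geometry(
    traj: Trajectory,
    topo: Topology,
    frames: Sequence[int] | np.ndarray | None = None,
    lipids: Sequence[int] | None = None,
) -> list[LipidGeometry]:
    """Truncated-cone geometry per ionizable lipid per frame.

    In-plane means xy after recentering the membrane center of mass to
    z = 0 (recentring does not move xy, so radii are unaffected; it
    matters for the z-referenced quantities downstream).
    """
    if frames is None:
        frames = np.arange(traj.n_frames)
    frames = np.asarray(frames, dtype=int)
    if frames.size == 0:
        raise ValueError("empty frame selection")
    if lipids is None:
        lipids = topo.ionizable_lipids()

    per_lipid = {
        int(lid): (
            topo.atoms_of(lid, role="head"),
            topo.atoms_of(lid, role="tail", terminal_only=True),
        )
        for lid in lipids
    }
    out: list[LipidGeometry] = []
    for f in frames:
        coords = traj.coords[f]
        for lid, (head_idx, term_idx) in per_lipid.items():
            head = coords[head_idx]
            term = coords[term_idx]
            r_head = _half_max_pairwise(head[:, :2])
            r_tail = _half_max_pairwise(term[:, :2])
            centroid = head.mean(axis=0)
            l_c = (
                float(np.linalg.norm(term - centroid, axis=1).mean())
                if len(term)
                else 0.0
            )
            a_0 = np.pi * r_head**2
            V = (np.pi * l_c / 3.0) * (r_head**2 + r_head * r_tail + r_tail**2)
            out.append(
                LipidGeometry(
                    lipid_id=lid, frame=int(f), r_head=r_head, r_tail=r_tail,
                    l_c=l_c, a_0=a_0, V=V,
                    degenerate=(r_head == 0.0 or l_c == 0.0),
                )
            )
    return out


def _aggregate(method: str, values_by_lipid: dict[int, np.ndarray],
               n_frames: int, excluded: int, dispersion_kind: str) -> CPPResult:
    per_lipid_means = {lid: float(v.mean()) for lid, v in values_by_lipid.items()}
    means = np.array(list(per_lipid_means.values()))
    pooled = np.concatenate(list(values_by_lipid.values()))
    n = len(means)
    var_lipids = float(means.var(ddof=1)) if n > 1 else 0.0
    if dispersion_kind == "sem":
        dispersion = float(np.sqrt(var_lipids / n)) if n > 1 else 0.0
    else:
        dispersion = float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0
    return CPPResult(
        method=method,
        per_lipid_means=per_lipid_means,
        pooled_mean=float(means.mean()),
        dispersion=dispersion,
        dispersion_kind=dispersion_kind,
        variance_across_lipids=var_lipids,
        frame_variance=float(pooled.var(ddof=1)) if len(pooled) > 1 else 0.0,
        n_lipids=n,
        n_frames=n_frames,
        excluded_lipids=excluded,
    )


def compute_cpp_v(geometries: Sequence[LipidGeometry]) -> CPPResult:
    """CPP_V = V / (a0 l_c) per lipid-frame; lipids averaged over
    frames first, then pooled.  Dispersion is the SEM across lipid
    means (CPP_V fluctuates strongly between frames, so the SEM of the
    central tendency is the conventional error bar)."""
    by_lipid: dict[int, list[float]] = {}
    excluded: set[int] = set()
    for g in geometries:
        if g.degenerate:
            excluded.add(g.lipid_id)
            continue
        by_lipid.setdefault(g.lipid_id, []).append(g.V / (g.a_0 * g.l_c))
    if not by_lipid:
        raise ValueError("all lipids degenerate; no CPP_V values")
    frames = {g.frame for g in geometries}
    return _aggregate(
        "cpp_v",
        {lid: np.array(v) for lid, v in by_lipid.items()},
        n_frames=len(frames),
        excluded=len(excluded - set(by_lipid)),
        dispersion_kind="sem",
    )


# ---------------------------------------------------------------------------
# CPP_Rg


def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit(v) onto +z (Rodrigues)."""
    v = v / np.linalg.norm(v)
    zhat = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, zhat)
    s = np.linalg.norm(axis)
    c = float(v @ zhat)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _planar_rg(xy: np.ndarray, masses: np.ndarray) -> float:
    return float(np.sqrt(np.sum(masses * (xy**2).sum(axis=1)) / masses.sum()))


def compute_cpp_rg(
    traj: Trajectory,
    topo: Topology,
    frames: Sequence[int] | np.ndarray | None = None,
    lipids: Sequence[int] | None = None,
    axis_tolerance: float = 1e-8,
) -> CPPResult:
    """CPP_Rg = Rg_tail / Rg_head from mass-weighted planar radii of
    gyration after aligning each lipid's head-to-tail axis with z.

    Per lipid the frame-averaged Rg values are ratioed; the dispersion
    reported is the SD of the per-lipid-frame ratio distribution.
    Lipids whose head and tail centers of mass coincide (no defined
    axis) are excluded with a warning.
    """
    if frames is None:
        frames = np.arange(traj.n_frames)
    frames = np.asarray(frames, dtype=int)
    if frames.size == 0:
        raise ValueError("empty frame selection")
    if lipids is None:
        lipids = topo.ionizable_lipids()

    masses = topo.masses
    sel = {
        int(lid): (topo.atoms_of(lid, role="head"), topo.atoms_of(lid, role="tail"))
        for lid in lipids
    }
    rg_head: dict[int, list[float]] = {}
    rg_tail: dict[int, list[float]] = {}
    ratios: dict[int, list[float]] = {}
    excluded: set[int] = set()
    for f in frames:
        coords = traj.coords[f]
        for lid, (head_idx, tail_idx) in sel.items():
            mh, mt = masses[head_idx], masses[tail_idx]
            com_head = np.average(coords[head_idx], axis=0, weights=mh)
            com_tail = np.average(coords[tail_idx], axis=0, weights=mt)
            v = com_head - com_tail
            if np.linalg.norm(v) < axis_tolerance:
                excluded.add(lid)
                continue
            mid = 0.5 * (com_head + com_tail)
            R = _rotation_to_z(v)
            head_xy = (coords[head_idx] - mid) @ R.T
            tail_xy = (coords[tail_idx] - mid) @ R.T
            h = _planar_rg(head_xy[:, :2], mh)
            t = _planar_rg(tail_xy[:, :2], mt)
            if h == 0.0:
                excluded.add(lid)
                continue
            rg_head.setdefault(lid, []).append(h)
            rg_tail.setdefault(lid, []).append(t)
            ratios.setdefault(lid, []).append(t / h)
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} lipid(s) with degenerate axis or "
            "zero head radius of gyration",
            stacklevel=2,
        )
    if not rg_head:
        raise ValueError("no lipids with a defined head-tail axis")

    per_lipid_means = {
        lid: float(np.mean(rg_tail[lid]) / np.mean(rg_head[lid])) for lid in rg_head
    }
    means = np.array(list(per_lipid_means.values()))
    pooled = np.concatenate([np.array(v) for v in ratios.values()])
    n = len(means)
    return CPPResult(
        method="cpp_rg",
        per_lipid_means=per_lipid_means,
        pooled_mean=float(means.mean()),
        dispersion=float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0,
        dispersion_kind="sd",
        variance_across_lipids=float(means.var(ddof=1)) if n > 1 else 0.0,
        frame_variance=float(pooled.var(ddof=1)) if len(pooled) > 1 else 0.0,
        n_lipids=n,
        n_frames=len(frames),
        excluded_lipids=len(excluded - set(rg_head)),
    )


def classify_shape(cpp: float, cylinder_band: float = 0.05) -> Shape:
    """Cone (< 1), cylinder (within ``cylinder_band`` of 1), or
    inverted cone (> 1)."""
    if cpp < 0:
        raise ValueError("CPP must be nonnegative")
    if abs(cpp - 1.0) <= cylinder_band:
        return Shape.CYLINDER
    return Shape.CONE if cpp < 1.0 else Shape.INVERTED_CONE


# ---------------------------------------------------------------------------
# Density profiles and thickness


def compute_density_profile(
    traj: Trajectory,
    topo: Topology,
    frames: Sequence[int] | np.ndarray | None = None,
    bin_width: float = 1.0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Representative-atom number density vs z per lipid type.

    One representative atom tracks each lipid (hydroxyl O for
    cholesterol, P for helper lipids, head N for ionizable lipids).
    Frames are recentered to put the membrane center of mass at z = 0,
    counts averaged over frames and divided by bin width, so the
    integral of each profile recovers that component's lipid count.
    Returns {lipid_type: (bin_centers, density)}.
    """
    if frames is None:
        frames = np.arange(traj.n_frames)
    frames = np.asarray(frames, dtype=int)

    t = topo.table
    ref_mask = (t["reference_kind"] != "none").to_numpy()
    types_present = t["lipid_type"].unique()
    by_type: dict[str, np.ndarray] = {}
    for lt in types_present:
        idx = np.flatnonzero((t["lipid_type"] == lt).to_numpy() & ref_mask)
        if idx.size == 0:
            raise TopologyError(
                f"component {lt!r} present but has no representative atoms"
            )
        by_type[lt] = idx

    half = traj.box[:, 2].max() / 2
    edges = np.arange(-half, half + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for lt, idx in by_type.items():
        acc = np.zeros(len(centers))
        for f in frames:
            mid = membrane_midplane_z(traj, topo, f)
            z = traj.coords[f, idx, 2] - mid
            hist, _ = np.histogram(z, bins=edges)
            acc += hist
        out[lt] = (centers, acc / len(frames) / bin_width)
    return out


def compute_thickness(
    traj: Trajectory,
    topo: Topology,
    frames: Sequence[int] | np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Bilayer thickness d_B(t) = <z_ref,upper> - <z_ref,lower> per
    frame, plus the window mean.

    Reference atoms are the phosphate-like per-lipid markers
    (``reference_kind != 'none'``); leaflet membership follows the
    sign of each reference atom's z relative to the membrane midplane.
    """
    if frames is None:
        frames = np.arange(traj.n_frames)
    frames = np.asarray(frames, dtype=int)
    ref_idx = topo.reference_atoms()
    if ref_idx.size == 0:
        raise ValueError("no reference atoms in topology")
    series = np.empty(len(frames))
    for k, f in enumerate(frames):
        mid = membrane_midplane_z(traj, topo, f)
        z = traj.coords[f, ref_idx, 2] - mid
        upper, lower = z[z > 0], z[z <= 0]
        if upper.size == 0 or lower.size == 0:
            raise ValueError(f"frame {f}: a leaflet has no reference atoms")
        series[k] = upper.mean() - lower.mean()
    return series, float(series.mean())


# ---------------------------------------------------------------------------
# Torque density and compressibility


def compute_torque_density(
    profile: PressureProfile,
    normal_component: str = "p_zz",
) -> TorqueResult:
    """Leaflet torques from the first moment of p(z) = p_T(z) - p_N(z).

    p_T = (p_xx + p_yy)/2 and, by default, p_N = p_zz (the component
    along the membrane normal).  ``normal_component='p_xx'`` is
    available for cross-checking alternative conventions, though it
    makes p vanish under isotropic lateral stress.  Quadrature is the
    per-bin midpoint rule (exact for bin-aligned piecewise-constant
    profiles); torques are in bar * Angstrom.
    """
    p_T = 0.5 * (profile.p_xx + profile.p_yy)
    if normal_component == "p_zz":
        p_N = profile.p_zz
    elif normal_component == "p_xx":
        p_N = profile.p_xx
    else:
        raise ValueError("normal_component must be 'p_zz' or 'p_xx'")
    p = p_T - p_N
    z = profile.z
    w = profile.bin_width
    moment = z * p * w
    tau_upper = float(moment[z > 0].sum())
    tau_lower = float(moment[z < 0].sum())
    return TorqueResult(
        tau_upper=tau_upper,
        tau_lower=tau_lower,
        tau_mean_literal=0.5 * (tau_upper + tau_lower),
        tau_mean_leaflet=0.5 * (tau_upper - tau_lower),
        p_lateral=p,
        z=z,
    )


def compute_area_compressibility(
    area_series: np.ndarray, temperature: float = 310.0
) -> CompressibilityResult:
    """K_A = k_B T <A> / var(A) from projected bilayer area
    fluctuations, converted from Angstrom units to mN/m."""
    a = np.asarray(area_series, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 area samples")
    mean = float(a.mean())
    var = float(a.var(ddof=1))
    if var == 0.0:
        raise ValueError("degenerate area series: zero fluctuation variance")
    ka_mn_per_m = BOLTZMANN_J_PER_K * temperature * mean / var * 1e23
    return CompressibilityResult(
        K_A=ka_mn_per_m, mean_area=mean, area_variance=var, temperature=temperature
    )


# ---------------------------------------------------------------------------
# Stability screen


def classify_stability(
    traj: Trajectory,
    topo: Topology,
    escape_margin: float = 10.0,
    persistence: int = 5,
    frames: Sequence[int] | np.ndarray | None = None,
) -> StabilityReport:
    """Flag ionizable lipids that leave the membrane slab.

    A lipid is escaped once its center of mass satisfies
    |z - midplane| > d_B/2 + escape_margin for at least ``persistence``
    consecutive analysis frames; any escape marks the bilayer
    unstable.  d_B is the window-mean thickness.
    """
    if frames is None:
        frames = np.arange(traj.n_frames)
    frames = np.asarray(frames, dtype=int)
    _, d_b = compute_thickness(traj, topo, frames)
    threshold = d_b / 2.0 + escape_margin

    masses = topo.masses
    lipid_col = topo.table["lipid_id"].to_numpy()
    escaped: list[tuple[int, int]] = []
    for lid in topo.ionizable_lipids():
        idx = np.flatnonzero(lipid_col == lid)
        run = 0
        first: int | None = None
        found = None
        for f in frames:
            mid = membrane_midplane_z(traj, topo, f)
            zcom = np.average(traj.coords[f, idx, 2], weights=masses[idx])
            if abs(zcom - mid) > threshold:
                if run == 0:
                    first = int(f)
                run += 1
                if run >= persistence:
                    found = first
                    break
            else:
                run = 0
        if found is not None:
            escaped.append((int(lid), found))
    return StabilityReport(
        escaped_lipids=escaped,
        stable=not escaped,
        escape_margin=escape_margin,
        persistence=persistence,
    )
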