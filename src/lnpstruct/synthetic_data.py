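"""Synthetic inputs with analytic ground truth.

Real bilayer trajectories come from microsecond all-atom MD runs; the
generators here emulate their geometry at the level the downstream
estimators consume: pseudo-atom lipids with prescribed cone geometry
(head/tail disc radii, length), mirrored leaflets, Gaussian positional
noise, and optional membrane-escape events.  Every generator is a pure
function of its spec including the seed, and each records the analytic
value every downstream estimator should recover, so tests never need
to re-derive geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectory_model import Topology, Trajectory

__all__ = [
    "SyntheticBilayerSpec",
    "BilayerGroundTruth",
    "EscapeEvent",
    "DeliverySimSpec",
    "GeometryError",
    "make_bilayer_trajectory",
    "make_area_series",
    "analytic_area_compressibility",
    "make_pressure_profile",
    "make_delivery_dataset",
    "fixture_smiles",
]

BOLTZMANN_J_PER_K = 1.380649e-23


class GeometryError(ValueError):
    """Lipids do not fit in the requested box."""


@dataclass(frozen=True)
class EscapeEvent:
    """A lipid displaced out of the membrane slab from ``start_frame``
    onward (persistent z offset, signed away from the midplane)."""

    lipid_id: int
    start_frame: int
    z_offset: float


@dataclass(frozen=True)
class SyntheticBilayerSpec:
    """Construction parameters of a synthetic bilayer trajectory.

    Each lipid is a rigid truncated-cone scaffold: ``atoms_per_head``
    pseudo-atoms on a circle of radius ``head_radius`` at the
    head-group plane and ``atoms_per_tail`` pseudo-atoms (all flagged
    terminal) on a circle of radius ``tail_radius`` at depth
    ``lipid_length`` below it, leaflets mirrored about z = 0.
    Per-atom per-frame Gaussian noise of sd ``positional_noise_sd``
    emulates thermal disorder.  Defaults give a moderately
    inverted-cone lipid (tail/head radius ratio 1.5) of roughly
    phospholipid dimensions.
    """

    n_lipids_per_leaflet: int = 25
    head_radius: float = 4.0
    tail_radius: float = 6.0
    lipid_length: float = 15.0
    atoms_per_head: int = 6
    atoms_per_tail: int = 6
    positional_noise_sd: float = 0.1
    n_frames: int = 100
    frame_spacing: float = 1.0
    box: tuple[float, float, float] | None = None
    protonated_fraction: float = 0.0
    escape_events: tuple[EscapeEvent, ...] = ()
    masses: str = "unit"  # "unit" or "alternating" (unequal-mass fixture)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head_radius <= 0 or self.tail_radius < 0 or self.lipid_length <= 0:
            raise ValueError("radii/length must be positive (tail radius may be 0)")
        if not 0.0 <= self.protonated_fraction <= 1.0:
            raise ValueError("protonated_fraction must be in [0, 1]")


@dataclass(frozen=True)
class BilayerGroundTruth:
    """Analytic values the estimators should recover."""

    head_radius: float
    tail_radius: float
    lipid_length: float
    l_c: float
    expected_cpp_v: float
    expected_cpp_rg: float
    expected_thickness: float
    escape_events: tuple[EscapeEvent, ...]
    n_lipids: int


#: z offset of the terminal-tail plane from the midplane; keeps the two
#: leaflets' tail ends from coinciding exactly at z = 0.
_TAIL_PLANE_OFFSET = 1.0


def _cone_cpp_v(r_h: float, r_t: float) -> float:
    return (r_h**2 + r_h * r_t + r_t**2) / (3.0 * r_h**2)


def make_bilayer_trajectory(
    spec: SyntheticBilayerSpec,
) -> tuple[Trajectory, Topology, BilayerGroundTruth]:
    """Build a mirrored two-leaflet trajectory with known geometry.

    Ground truth: CPP by truncated-cone volume reduces to
    (r_h^2 + r_h r_t + r_t^2) / (3 r_h^2) (the length cancels); CPP by
    planar radii of gyration is r_t / r_h for equal-mass circle
    scaffolds; thickness is the separation of the head reference
    planes.
    """
    n = spec.n_lipids_per_leaflet
    rng = np.random.default_rng(spec.seed)
    r_max = max(spec.head_radius, spec.tail_radius)
    pitch = 2.0 * r_max + 2.0

    ncols = math.ceil(math.sqrt(n))
    nrows = math.ceil(n / ncols)
    if spec.box is None:
        box = (ncols * pitch, nrows * pitch, 2 * (spec.lipid_length + _TAIL_PLANE_OFFSET) + 40.0)
    else:
        box = spec.box
        if box[0] < ncols * pitch or box[1] < nrows * pitch:
            raise GeometryError(
                f"box {box[:2]} too small for {n} lipids of radius {r_max}"
            )
        if box[2] < 2 * (spec.lipid_length + _TAIL_PLANE_OFFSET):
            raise GeometryError("box z-dimension shorter than the bilayer")

    z_tail = _TAIL_PLANE_OFFSET
    z_head = _TAIL_PLANE_OFFSET + spec.lipid_length

    head_angles = 2 * np.pi * np.arange(spec.atoms_per_head) / spec.atoms_per_head
    tail_angles = 2 * np.pi * np.arange(spec.atoms_per_tail) / spec.atoms_per_tail
    head_disc = spec.head_radius * np.stack(
        [np.cos(head_angles), np.sin(head_angles)], axis=1
    )
    tail_disc = spec.tail_radius * np.stack(
        [np.cos(tail_angles), np.sin(tail_angles)], axis=1
    )

    per_lipid = spec.atoms_per_head + spec.atoms_per_tail
    n_total = 2 * n
    base = np.empty((n_total * per_lipid, 3))
    rows = []
    n_protonated = int(round(spec.protonated_fraction * n_total))
    atom = 0
    for lipid in range(n_total):
        leaflet_sign = 1.0 if lipid < n else -1.0
        cell = lipid % n
        cx = (cell % ncols + 0.5) * box[0] / ncols - box[0] / 2
        cy = (cell // ncols + 0.5) * box[1] / nrows - box[1] / 2
        charge = "protonated" if lipid < n_protonated else "neutral"
        for k in range(spec.atoms_per_head):
            base[atom] = (cx + head_disc[k, 0], cy + head_disc[k, 1], leaflet_sign * z_head)
            rows.append(
                dict(atom_id=atom + 1, lipid_id=lipid + 1, lipid_type="ionizable",
                     charge_state=charge, role="head", is_terminal_tail=False,
                     reference_kind="head_N" if k == 0 else "none", mass=1.0)
            )
            atom += 1
        for k in range(spec.atoms_per_tail):
            base[atom] = (cx + tail_disc[k, 0], cy + tail_disc[k, 1], leaflet_sign * z_tail)
            rows.append(
                dict(atom_id=atom + 1, lipid_id=lipid + 1, lipid_type="ionizable",
                     charge_state=charge, role="tail", is_terminal_tail=True,
                     reference_kind="none", mass=1.0)
            )
            atom += 1

    table = pd.DataFrame(rows)
    if spec.masses == "alternating":
        # Unequal-mass fixture: masses alternate 1/2 within each disc
        # symmetrically, which keeps disc centroids (and hence ground
        # truth) unchanged for even atom counts.
        table["mass"] = np.where(np.arange(len(table)) % 2 == 0, 1.0, 2.0)
    topo = Topology(table)

    coords = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    if spec.positional_noise_sd > 0:
        coords = coords + rng.normal(
            0.0, spec.positional_noise_sd, size=coords.shape
        )
    lipid_col = table["lipid_id"].to_numpy()
    for ev in spec.escape_events:
        sel = lipid_col == ev.lipid_id
        sign = 1.0 if ev.lipid_id <= n else -1.0
        coords[ev.start_frame :, sel, 2] += sign * ev.z_offset

    times = np.arange(spec.n_frames, dtype=float) * spec.frame_spacing
    box_arr = np.tile(np.asarray(box, dtype=float), (spec.n_frames, 1))
    traj = Trajectory(times=times, coords=coords, box=box_arr)

    truth = BilayerGroundTruth(
        head_radius=spec.head_radius,
        tail_radius=spec.tail_radius,
        lipid_length=spec.lipid_length,
        l_c=math.hypot(spec.tail_radius, spec.lipid_length),
        expected_cpp_v=_cone_cpp_v(spec.head_radius, spec.tail_radius),
        expected_cpp_rg=spec.tail_radius / spec.head_radius,
        expected_thickness=2.0 * z_head,
        escape_events=spec.escape_events,
        n_lipids=n_total,
    )
    return traj, topo, truth


def make_area_series(
    mean_area: float, sd_area: float, n: int, seed: int = 0
) -> np.ndarray:
    """I.i.d. Gaussian projected-area series A(t) in Angstrom^2."""
    if mean_area <= 0 or sd_area < 0 or n < 2:
        raise ValueError("need mean_area > 0, sd_area >= 0, n >= 2")
    rng = np.random.default_rng(seed)
    return mean_area + sd_area * rng.standard_normal(n)


def analytic_area_compressibility(
    mean_area: float, area_variance: float, temperature: float
) -> float:
    """Closed-form K_A = k_B T <A> / var(A) in mN/m for Angstrom inputs."""
    ka_n_per_m = BOLTZMANN_J_PER_K * temperature * mean_area / area_variance * 1e20
    return ka_n_per_m * 1e3


@dataclass(frozen=True)
class PressureProfileTruth:
    tau_upper: float
    tau_lower: float


def make_pressure_profile(
    shape: str,
    params: dict,
    bin_width: float = 0.2,
    Lz: float = 80.0,
):
    """Piecewise-analytic lateral pressure profile with known torques.

    Shapes
    ------
    ``piecewise_constant``
        params: ``p`` (bar), ``z_lo``, ``z_hi``; lateral pressure p on
        [z_lo, z_hi], zero elsewhere.  tau over a leaflet is
        p (z_hi^2 - z_lo^2)/2 clipped to that leaflet.
    ``symmetric_gaussian``
        params: ``amplitude``, ``sigma``; p(z) = A exp(-z^2/2 sigma^2).
        tau_upper = A sigma^2 (up to box truncation), tau_lower the
        negative.
    ``antisymmetric``
        params: ``amplitude``, ``sigma``; p(z) = A z exp(-z^2/2 sigma^2)
        gives equal leaflet torques A sigma^3 sqrt(pi/2).

    Returns (profile, truth) where profile is a
    :class:`~lnpstruct.membrane_features.PressureProfile` with the
    lateral load placed in p_xx = p_yy and p_zz = 0.
    """
    from .membrane_features import PressureProfile

    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    nbins = int(round(Lz / bin_width))
    edges = -Lz / 2 + bin_width * np.arange(nbins + 1)
    z = 0.5 * (edges[:-1] + edges[1:])

    if shape == "piecewise_constant":
        p, z_lo, z_hi = params["p"], params["z_lo"], params["z_hi"]
        lateral = np.where((z >= z_lo) & (z < z_hi), p, 0.0)

        def seg(a: float, b: float) -> float:
            lo, hi = max(a, z_lo), min(b, z_hi)
            return 0.5 * p * (hi**2 - lo**2) if hi > lo else 0.0

        truth = PressureProfileTruth(tau_upper=seg(0, Lz / 2), tau_lower=seg(-Lz / 2, 0))
    elif shape == "symmetric_gaussian":
        amp, sigma = params["amplitude"], params["sigma"]
        lateral = amp * np.exp(-0.5 * (z / sigma) ** 2)
        half = amp * sigma**2 * (1.0 - math.exp(-0.5 * (Lz / 2 / sigma) ** 2))
        truth = PressureProfileTruth(tau_upper=half, tau_lower=-half)
    elif shape == "antisymmetric":
        amp, sigma = params["amplitude"], params["sigma"]
        lateral = amp * z * np.exp(-0.5 * (z / sigma) ** 2)
        # int_0^L z * (A z e^{-z^2/2s^2}) dz -> A s^3 sqrt(pi/2) erf-corrected
        L = Lz / 2
        half = amp * (
            sigma**2
            * (math.sqrt(math.pi / 2) * sigma * math.erf(L / (math.sqrt(2) * sigma))
               - L * math.exp(-0.5 * (L / sigma) ** 2))
        )
        truth = PressureProfileTruth(tau_upper=half, tau_lower=half)
    else:
        raise ValueError(f"unknown profile shape: {shape!r}")

    profile = PressureProfile(
        z=z, p_xx=lateral.copy(), p_yy=lateral.copy(), p_zz=np.zeros_like(z)
    )
    return profile, truth


@dataclass(frozen=True)
class DeliverySimSpec:
    """Bivariate-normal (feature, delivery) pairs with population
    correlation ``rho``; optional stratum labels assigned round-robin."""

    n: int
    rho: float
    strata: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("|rho| must be <= 1")
        if self.n < 2:
            raise ValueError("need n >= 2")


def make_delivery_dataset(spec: DeliverySimSpec) -> pd.DataFrame:
    """Columns: feature, delivery, stratum (empty string if none)."""
    rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal(spec.n)
    if abs(spec.rho) == 1.0:
        y = math.copysign(1.0, spec.rho) * x
    else:
        y = spec.rho * x + math.sqrt(1 - spec.rho**2) * rng.standard_normal(spec.n)
    strata = (
        [spec.strata[i % len(spec.strata)] for i in range(spec.n)]
        if spec.strata
        else [""] * spec.n
    )
    return pd.DataFrame({"feature": x, "delivery": y, "stratum": strata})


def fixture_smiles() -> list[tuple[str, str | None]]:
    """Hand-annotated (SMILES, expected protonated SMILES or None)
    pairs covering the decision tree under the default periphery rule.

    Expected outputs were written by hand from the rules and are
    compared after canonicalization.
    """
    return [
        # single nitrogen -> protonate it, whatever its class
        ("CCN", "CC[NH3+]"),
        ("CCO", None),  # no nitrogen at all
        # substitution hierarchy
        ("CCN(CC)CC", "CC[NH+](CC)CC"),  # lone tertiary amine
        ("CNCCN(C)C", "CNCC[NH+](C)C"),  # tertiary beats secondary
        ("NCCN(C)C", "NCC[NH+](C)C"),  # tertiary beats primary
        # exclusions
        ("CNC(C)=O", None),  # amide
        ("CS(=O)(=O)NC", None),  # sulfonamide
        ("C[N+](C)(C)C", None),  # quaternary
        ("NCCNC(C)=O", "[NH3+]CCNC(C)=O"),  # amide excluded, primary wins
        # ring systems
        ("c1ccncc1", "c1cc[nH+]cc1"),  # pyridine
        ("c1c[nH]cn1", "c1c[nH]c[nH+]1"),  # imidazole pyridine-type N
        ("CN(C)CCc1ccncc1", "C[NH+](C)CCc1ccncc1"),  # amine beats pyridine
        # aromatic amines
        ("CNc1ccccc1", "C[NH2+]c1ccccc1"),  # secondary aromatic amine
        ("Nc1ccccc1", "[NH3+]c1ccccc1"),  # single N, aniline
        # periphery tie-break: the N(C)(C) end has eccentricity 5, the
        # ethylated end 4 (hand-counted shortest paths)
        ("CN(C)CCN(C)CC", "C[NH+](C)CCN(C)CC"),
        # symmetric tie: both tertiary ends equivalent, canonical-rank
        # tie-break must still pick a site deterministically
        ("CN(C)CCN(C)C", "C[NH+](C)CCN(C)C"),
    ]
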