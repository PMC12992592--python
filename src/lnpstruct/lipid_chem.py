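"""Molecular-graph analysis of ionizable lipids.

Ionizable lipids often carry several nitrogens with plausible
protonation sites.  A single representative +1e protonated state is
assigned per lipid by a rule-based decision tree:

1. A lone nitrogen is protonated.
2. Otherwise the highest-priority amine class wins, in the order
   tertiary amine > secondary amine > primary amine > imidazole >
   pyridine > tertiary aromatic amine > secondary aromatic amine >
   primary aromatic amine.  Amide, sulfonamide, and quaternary
   nitrogens are never protonated.
3. Ties within a class go to the nitrogen nearest the molecular
   periphery (greatest graph eccentricity on the heavy-atom graph).
   An opt-in variant for tail-amine lipid libraries instead picks the
   most central candidate (lowest mean squared graph distance to all
   other atoms).
4. Any remaining tie is broken by lowest canonical atom rank, so the
   chosen site is independent of SMILES atom ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

__all__ = [
    "SiteClass",
    "NitrogenSite",
    "ProtonationResult",
    "ParseError",
    "InvalidSiteError",
    "classify_nitrogen_sites",
    "select_protonation_site",
    "protonate",
    "protonate_smiles",
    "protonation_fraction",
    "lipid_summary_stats",
]


class ParseError(ValueError):
    """SMILES failed to parse into a molecule."""


class InvalidSiteError(ValueError):
    """Requested protonation site is not a protonatable nitrogen."""


class SiteClass(Enum):
    TERTIARY_AMINE = "tertiary_amine"
    SECONDARY_AMINE = "secondary_amine"
    PRIMARY_AMINE = "primary_amine"
    IMIDAZOLE = "imidazole"
    PYRIDINE = "pyridine"
    TERTIARY_AROMATIC_AMINE = "tertiary_aromatic_amine"
    SECONDARY_AROMATIC_AMINE = "secondary_aromatic_amine"
    PRIMARY_AROMATIC_AMINE = "primary_aromatic_amine"
    EXCLUDED = "excluded"


#: Protonation priority, highest first.
PRIORITY: tuple[SiteClass, ...] = (
    SiteClass.TERTIARY_AMINE,
    SiteClass.SECONDARY_AMINE,
    SiteClass.PRIMARY_AMINE,
    SiteClass.IMIDAZOLE,
    SiteClass.PYRIDINE,
    SiteClass.TERTIARY_AROMATIC_AMINE,
    SiteClass.SECONDARY_AROMATIC_AMINE,
    SiteClass.PRIMARY_AROMATIC_AMINE,
)

# Nitrogens adjacent to a carbonyl carbon (amides, ureas, carbamates)
# or to S(=O) (sulfonamides) are not basic enough to protonate.
_AMIDE = Chem.MolFromSmarts("[#7][CX3]=[OX1]")
_SULFONAMIDE = Chem.MolFromSmarts("[#7][#16]=[OX1]")


@dataclass(frozen=True)
class NitrogenSite:
    atom_index: int
    site_class: SiteClass
    eccentricity: int
    mean_sq_graph_distance: float
    canonical_rank: int


@dataclass
class ProtonationResult:
    selected_index: int | None
    protonated_smiles: str | None
    rule_trace: list[str]


def _as_mol(mol: str | Chem.Mol) -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    parsed = Chem.MolFromSmiles(mol)
    if parsed is None:
        raise ParseError(f"unparseable SMILES: {mol!r}")
    return parsed


def _classify_atom(mol: Chem.Mol, atom: Chem.Atom, excluded_idx: set[int]) -> SiteClass:
    idx = atom.GetIdx()
    if atom.GetFormalCharge() != 0:
        return SiteClass.EXCLUDED
    if atom.GetTotalDegree() >= 4:  # quaternary
        return SiteClass.EXCLUDED
    if idx in excluded_idx:  # amide / sulfonamide
        return SiteClass.EXCLUDED
    if atom.GetIsAromatic() and atom.IsInRing():
        # Protonatable ring nitrogens are the pyridine-type ([nX2],
        # lone pair in plane).  Pyrrole-type [nH] donates its lone pair
        # to the ring and is excluded.
        if atom.GetTotalNumHs() > 0 or atom.GetDegree() == 3:
            return SiteClass.EXCLUDED
        ring_info = mol.GetRingInfo()
        for ring in ring_info.AtomRings():
            if idx in ring and len(ring) == 5:
                n_in_ring = sum(
                    1 for a in ring if mol.GetAtomWithIdx(a).GetAtomicNum() == 7
                )
                if n_in_ring >= 2:
                    return SiteClass.IMIDAZOLE
        return SiteClass.PYRIDINE
    # Non-aromatic nitrogen: require a saturated amine (all single
    # bonds); imines, nitriles, nitro nitrogens fall through to
    # excluded since the priority list does not cover them.
    if any(b.GetBondType() != Chem.BondType.SINGLE for b in atom.GetBonds()):
        return SiteClass.EXCLUDED
    heavy_neighbors = atom.GetDegree()
    aromatic_neighbor = any(n.GetIsAromatic() for n in atom.GetNeighbors())
    table = {
        3: (SiteClass.TERTIARY_AROMATIC_AMINE, SiteClass.TERTIARY_AMINE),
        2: (SiteClass.SECONDARY_AROMATIC_AMINE, SiteClass.SECONDARY_AMINE),
    }
    aromatic, plain = table.get(
        heavy_neighbors, (SiteClass.PRIMARY_AROMATIC_AMINE, SiteClass.PRIMARY_AMINE)
    )
    return aromatic if aromatic_neighbor else plain


def classify_nitrogen_sites(mol: str | Chem.Mol) -> list[NitrogenSite]:
    """Classify every nitrogen in the molecule.

    Eccentricity is the longest shortest-path distance (unit bond
    lengths, heavy-atom graph) from the nitrogen to any other atom;
    ``mean_sq_graph_distance`` is the average squared shortest-path
    distance to all other heavy atoms.
    """
    m = _as_mol(mol)
    excluded_idx: set[int] = set()
    for patt in (_AMIDE, _SULFONAMIDE):
        for match in m.GetSubstructMatches(patt):
            excluded_idx.add(match[0])

    dmat = Chem.GetDistanceMatrix(m)
    ranks = list(Chem.CanonicalRankAtoms(m, breakTies=True))
    n_atoms = m.GetNumAtoms()
    sites: list[NitrogenSite] = []
    for atom in m.GetAtoms():
        if atom.GetAtomicNum() != 7:
            continue
        idx = atom.GetIdx()
        d = dmat[idx]
        ecc = int(d.max()) if n_atoms > 1 else 0
        msq = float((d**2).sum() / (n_atoms - 1)) if n_atoms > 1 else 0.0
        sites.append(
            NitrogenSite(
                atom_index=idx,
                site_class=_classify_atom(m, atom, excluded_idx),
                eccentricity=ecc,
                mean_sq_graph_distance=msq,
                canonical_rank=ranks[idx],
            )
        )
    return sites


def select_protonation_site(
    sites: Sequence[NitrogenSite],
    dataset_rule: str = "default",
    trace: list[str] | None = None,
) -> int | None:
    """Pick the nitrogen to protonate, or None if no candidate exists.

    ``dataset_rule='tail_amine_central'`` switches the within-class
    tie-break from greatest eccentricity to lowest mean squared graph
    distance (used for tail-amine combinatorial libraries).
    """
    if dataset_rule not in ("default", "tail_amine_central"):
        raise ValueError(f"unknown dataset_rule: {dataset_rule!r}")
    log = trace if trace is not None else []
    if not sites:
        log.append("no nitrogens present -> none")
        return None
    candidates = [s for s in sites if s.site_class is not SiteClass.EXCLUDED]
    if not candidates:
        log.append("all nitrogens excluded (amide/sulfonamide/quaternary) -> none")
        return None
    if len(sites) == 1:
        log.append("single nitrogen -> protonate it")
        return sites[0].atom_index
    for cls in PRIORITY:
        tier = [s for s in candidates if s.site_class is cls]
        if not tier:
            continue
        log.append(f"highest-priority class present: {cls.value} ({len(tier)} candidate(s))")
        if len(tier) == 1:
            return tier[0].atom_index
        if dataset_rule == "tail_amine_central":
            best = min(s.mean_sq_graph_distance for s in tier)
            tier = [s for s in tier if s.mean_sq_graph_distance == best]
            log.append(f"central-candidate rule: min mean sq distance {best:.4f}")
        else:
            best = max(s.eccentricity for s in tier)
            tier = [s for s in tier if s.eccentricity == best]
            log.append(f"periphery rule: max eccentricity {best}")
        if len(tier) > 1:
            log.append("residual tie -> lowest canonical atom rank")
        return min(tier, key=lambda s: s.canonical_rank).atom_index
    log.append("no protonatable class matched -> none")  # pragma: no cover
    return None


def protonate(mol: str | Chem.Mol, site: int) -> ProtonationResult:
    """Assign +1 formal charge and one extra hydrogen at ``site``.

    Raises :class:`InvalidSiteError` if the site is not a neutral,
    protonatable (non-excluded) nitrogen.
    """
    m = Chem.RWMol(_as_mol(mol))
    if site < 0 or site >= m.GetNumAtoms():
        raise InvalidSiteError(f"atom index {site} out of range")
    sites = {s.atom_index: s for s in classify_nitrogen_sites(m)}
    if site not in sites:
        raise InvalidSiteError(f"atom {site} is not a nitrogen")
    if sites[site].site_class is SiteClass.EXCLUDED:
        raise InvalidSiteError(
            f"atom {site} is excluded (amide/sulfonamide/quaternary or already charged)"
        )
    atom = m.GetAtomWithIdx(site)
    atom.SetFormalCharge(1)
    atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
    atom.SetNoImplicit(True)
    Chem.SanitizeMol(m)
    smiles = Chem.MolToSmiles(m)
    return ProtonationResult(
        selected_index=site,
        protonated_smiles=smiles,
        rule_trace=[f"protonated atom {site}: +1 charge, +1 H"],
    )


def protonate_smiles(
    smiles: str, dataset_rule: str = "default"
) -> ProtonationResult:
    """End-to-end decision tree: classify, select, protonate."""
    trace: list[str] = []
    sites = classify_nitrogen_sites(smiles)
    chosen = select_protonation_site(sites, dataset_rule=dataset_rule, trace=trace)
    if chosen is None:
        return ProtonationResult(None, None, trace)
    result = protonate(smiles, chosen)
    result.rule_trace = trace + result.rule_trace
    return result


def protonation_fraction(pH: float, pKa: float) -> float:
    """Henderson-Hasselbalch protonated fraction of a basic site.

    f = 1 / (1 + 10^(pH - pKa)); equals 1/2 at pH = pKa.
    """
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def _substitution_label(sites: Sequence[NitrogenSite]) -> str:
    if not sites:
        return "no amine"
    present = sorted(
        {s.site_class.value for s in sites if s.site_class is not SiteClass.EXCLUDED},
        key=lambda v: [c.value for c in PRIORITY].index(v),
    )
    if not present:
        return "excluded only"
    return "+".join(present)


def lipid_summary_stats(smiles_list: Iterable[str]) -> tuple[pd.DataFrame, dict]:
    """Per-lipid molecular weight, nitrogen count, and substitution class.

    Returns a table (one row per input; parse failures flagged in the
    ``error`` column) plus aggregate mean/sd/range of the parseable
    entries.
    """
    rows = []
    for smi in smiles_list:
        try:
            m = _as_mol(smi)
        except ParseError as exc:
            rows.append(
                {"smiles": smi, "mol_weight": np.nan, "n_nitrogens": np.nan,
                 "substitution_class": None, "error": str(exc)}
            )
            continue
        sites = classify_nitrogen_sites(m)
        rows.append(
            {
                "smiles": smi,
                "mol_weight": Descriptors.MolWt(m),
                "n_nitrogens": len(sites),
                "substitution_class": _substitution_label(sites),
                "error": None,
            }
        )
    df = pd.DataFrame(rows)
    ok = df[df["error"].isna()]
    agg = {
        "n_parsed": int(len(ok)),
        "n_failed": int(len(df) - len(ok)),
        "mol_weight_mean": float(ok["mol_weight"].mean()) if len(ok) else np.nan,
        "mol_weight_sd": float(ok["mol_weight"].std(ddof=1)) if len(ok) > 1 else 0.0,
        "mol_weight_range": (
            [float(ok["mol_weight"].min()), float(ok["mol_weight"].max())]
            if len(ok)
            else [np.nan, np.nan]
        ),
        "n_nitrogens_mean": float(ok["n_nitrogens"].mean()) if len(ok) else np.nan,
    }
    return df, agg
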