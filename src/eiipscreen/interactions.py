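"""Geometric detection of receptor–ligand interactions in 3D poses.

Classifies contacts between a receptor and a docked ligand with explicit
distance/angle criteria:

* hydrogen bond   — donor···acceptor <= 3.4 Å, D-H-A angle in [90°, 180°]
* salt bridge     — opposite formal charges <= 4 Å apart
* π–π stacked     — ring centroids <= 6 Å, θ <= 50°, γ <= 35°
* π–π T-shaped    — centroids <= 6 Å, θ within 30° of perpendicular, γ <= 55°
* π–cation        — cation to centroid <= 4 Å, off-normal angle <= 40°
* π–alkyl         — alkyl carbon to centroid <= 4 Å, off-normal angle <= 45°

θ is the angle between ring normals, γ the angle between a ring normal and
the centroid–centroid vector; both are folded to [0°, 90°] because ring
normals are sign-ambiguous.  All distance cutoffs are closed balls.  The
per-residue union of detected contact types forms an interaction
fingerprint, the representation used to check that a pose reproduces the
anchoring contacts of aminergic GPCRs (e.g. the conserved D3.32 aspartate
salt bridge / hydrogen bond).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "AtomRecord",
    "RingSystem",
    "ComplexStructure",
    "GeometryThresholds",
    "InteractionRecord",
    "select_binding_site",
    "perceive_rings",
    "detect_hbonds",
    "detect_salt_bridges",
    "detect_pi_pi",
    "detect_pi_cation",
    "detect_pi_alkyl",
    "detect_all",
    "interaction_fingerprint",
    "assign_roles",
    "DEFAULT_SITE_CENTER",
]

#: Grid-box center used for the 5HT6 binding site (carbon of the D3.32
#: carboxyl group in the homology model's frame).
DEFAULT_SITE_CENTER = (-25.9, 5.82, 18.04)

# Covalent radii (Å) for distance-based bond inference.
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
_BOND_TOLERANCE = 0.45  # Å added to the radius sum


@dataclass
class AtomRecord:
    """One typed atom of a receptor–ligand complex."""

    element: str
    coords: tuple[float, float, float]
    residue_number: int = 0
    residue_name: str = "UNK"
    chain: str = "A"
    atom_name: str = ""
    is_ligand: bool = False
    hbond_donor: bool = False  # heavy atom carrying a donatable H
    hbond_acceptor: bool = False
    cation: bool = False
    anion: bool = False
    hydrophobic_carbon: bool = False  # sp3 C with only C/H neighbours
    aromatic: bool = False
    formal_charge: int = 0

    def __post_init__(self) -> None:
        if self.cation and self.anion:
            raise ValueError("an atom cannot be flagged both cation and anion")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError("atom coordinates must be finite")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class RingSystem:
    """A perceived 5–7 membered ring: members, centroid, unit normal."""

    members: tuple[int, ...]
    centroid: np.ndarray
    normal: np.ndarray
    planarity_rms: float
    aromatic: bool
    is_ligand: bool
    residue_number: int = 0

    def __post_init__(self) -> None:
        if len(self.members) < 5:
            raise ValueError("ring systems must have >= 5 members")
        n = np.linalg.norm(self.normal)
        if not math.isclose(n, 1.0, rel_tol=1e-6):
            raise ValueError("ring normal must be a unit vector")


@dataclass
class ComplexStructure:
    """Typed 3D atoms + optional bonds of one receptor–ligand pose."""

    atoms: list[AtomRecord]
    bonds: Optional[list[tuple[int, int]]] = None

    @property
    def receptor_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_ligand]

    @property
    def ligand_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.is_ligand]

    def residues(self) -> list[tuple[str, int, str]]:
        """Distinct (chain, residue_number, residue_name) in file order."""
        seen, out = set(), []
        for a in self.atoms:
            key = (a.chain, a.residue_number, a.residue_name)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def infer_bonds(self) -> list[tuple[int, int]]:
        """Distance-based covalent bond inference (radius sum + 0.45 Å)."""
        coords = np.array([a.xyz for a in self.atoms])
        radii = np.array([_COVALENT_RADII.get(a.element, 0.77) for a in self.atoms])
        bonds = []
        n = len(self.atoms)
        for i in range(n):
            d = np.linalg.norm(coords[i + 1 :] - coords[i], axis=1)
            cut = radii[i] + radii[i + 1 :] + _BOND_TOLERANCE
            for off in np.nonzero((d <= cut) & (d > 0.4))[0]:
                bonds.append((i, i + 1 + int(off)))
        return bonds

    def get_bonds(self) -> list[tuple[int, int]]:
        return self.bonds if self.bonds is not None else self.infer_bonds()


@dataclass(frozen=True)
class GeometryThresholds:
    """Distance (Å) and angle (deg) cutoffs for every interaction type."""

    hbond_dist_max: float = 3.4
    hbond_angle_min: float = 90.0
    hbond_angle_max: float = 180.0
    hbond_distance_mode: str = "D-A"  # or "H-A"
    salt_bridge_max: float = 4.0
    pi_alkyl_dist: float = 4.0
    pi_alkyl_angle: float = 45.0
    pi_pi_dist: float = 6.0
    pi_pi_stacked_theta: float = 50.0
    pi_pi_stacked_gamma: float = 35.0
    pi_pi_tshaped_theta: float = 30.0  # allowed deviation from 90°
    pi_pi_tshaped_gamma: float = 55.0
    pi_cation_dist: float = 4.0
    pi_cation_angle: float = 40.0

    def __post_init__(self) -> None:
        for name in ("hbond_dist_max", "salt_bridge_max", "pi_alkyl_dist",
                     "pi_pi_dist", "pi_cation_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.hbond_distance_mode not in ("D-A", "H-A"):
            raise ValueError("hbond_distance_mode must be 'D-A' or 'H-A'")


@dataclass
class InteractionRecord:
    """One classified receptor–ligand contact with its measured geometry."""

    type: str  # hbond | salt_bridge | pi_pi_stacked | pi_pi_tshaped | pi_cation | pi_alkyl
    receptor_residue: int
    receptor_part: str  # atom name/index or ring description
    ligand_part: str
    distance: float
    angles: dict[str, float] = field(default_factory=dict)


def _fold90(angle_deg: float) -> float:
    """Fold an angle to [0°, 90°] (normals are sign-ambiguous)."""
    a = angle_deg % 180.0
    return min(a, 180.0 - a)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def select_binding_site(
    c: ComplexStructure,
    center: Sequence[float] = DEFAULT_SITE_CENTER,
    radius: float = 15.0,
) -> ComplexStructure:
    """Restrict the receptor to a sphere around the site center.

    Receptor atoms within ``radius`` (closed ball) of ``center`` are kept;
    ligand atoms are always kept.  Bonds are re-indexed onto the subset.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    ctr = np.asarray(center, dtype=float)
    keep = [
        i
        for i, a in enumerate(c.atoms)
        if a.is_ligand or np.linalg.norm(a.xyz - ctr) <= radius
    ]
    if not any(not c.atoms[i].is_ligand for i in keep):
        import warnings

        warnings.warn("binding-site selection retains no receptor atoms", stacklevel=2)
    remap = {old: new for new, old in enumerate(keep)}
    bonds = None
    if c.bonds is not None:
        bonds = [(remap[i], remap[j]) for i, j in c.bonds if i in remap and j in remap]
    return ComplexStructure(atoms=[replace(c.atoms[i]) for i in keep], bonds=bonds)


def perceive_rings(c: ComplexStructure) -> list[RingSystem]:
    """Find 5–7 membered rings and fit centroid/normal/planarity.

    Uses the minimum cycle basis of the bond graph (bonds supplied or
    inferred from covalent radii).  A ring is aromatic if every member atom
    carries the aromatic flag, or — when no flags are set anywhere — if its
    planarity RMS is <= 0.1 Å.  The normal is the least-variance direction
    of the member coordinates, sign-canonicalized to positive z (ties:
    positive x, then y).  Rings mixing receptor and ligand atoms are
    discarded.
    """
    if not c.atoms:
        return []
    bonds = c.get_bonds()
    g = nx.Graph()
    g.add_nodes_from(range(len(c.atoms)))
    g.add_edges_from(bonds)
    any_aromatic_flag = any(a.aromatic for a in c.atoms)
    rings: list[RingSystem] = []
    for cycle in nx.minimum_cycle_basis(g):
        if not 5 <= len(cycle) <= 7:
            continue
        members = tuple(sorted(cycle))
        part = {c.atoms[i].is_ligand for i in members}
        if len(part) != 1:
            continue
        coords = np.array([c.atoms[i].xyz for i in members])
        centroid = coords.mean(axis=0)
        centered = coords - centroid
        # least-squares plane: normal = eigenvector of smallest eigenvalue
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        normal = vt[-1]
        rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
        # canonical sign
        for comp in (2, 0, 1):
            if abs(normal[comp]) > 1e-9:
                if normal[comp] < 0:
                    normal = -normal
                break
        if any_aromatic_flag:
            aromatic = all(c.atoms[i].aromatic for i in members)
        else:
            aromatic = rms <= 0.1
        rings.append(
            RingSystem(
                members=members,
                centroid=centroid,
                normal=normal / np.linalg.norm(normal),
                planarity_rms=rms,
                aromatic=aromatic,
                is_ligand=part.pop(),
                residue_number=c.atoms[members[0]].residue_number,
            )
        )
    rings.sort(key=lambda r: r.members)
    return rings


def _donor_hydrogens(c: ComplexStructure) -> dict[int, list[int]]:
    """Map donor heavy-atom index -> indices of bonded hydrogens."""
    out: dict[int, list[int]] = {}
    for i, j in c.get_bonds():
        for d, h in ((i, j), (j, i)):
            if c.atoms[h].element == "H" and c.atoms[d].hbond_donor:
                out.setdefault(d, []).append(h)
    return out


def _cross(pairs_a: Iterable[int], pairs_b: Iterable[int]):
    for a in pairs_a:
        for b in pairs_b:
            yield a, b


def detect_hbonds(
    c: ComplexStructure, thresholds: GeometryThresholds | None = None
) -> list[InteractionRecord]:
    """Hydrogen bonds between receptor and ligand.

    One record per (donor, H, acceptor) triad whose distance (donor–acceptor
    by default, hydrogen–acceptor in 'H-A' mode) is within the cutoff and
    whose D-H-A angle lies in the accepted window.
    """
    t = thresholds or GeometryThresholds()
    donors = _donor_hydrogens(c)
    acceptors = [i for i, a in enumerate(c.atoms) if a.hbond_acceptor]
    records = []
    for d, hs in sorted(donors.items()):
        for acc in acceptors:
            if c.atoms[d].is_ligand == c.atoms[acc].is_ligand:
                continue
            for h in hs:
                ref = c.atoms[d].xyz if t.hbond_distance_mode == "D-A" else c.atoms[h].xyz
                dist = float(np.linalg.norm(ref - c.atoms[acc].xyz))
                if dist > t.hbond_dist_max:
                    continue
                angle = _angle_deg(
                    c.atoms[d].xyz - c.atoms[h].xyz, c.atoms[acc].xyz - c.atoms[h].xyz
                )
                if not (t.hbond_angle_min <= angle <= t.hbond_angle_max):
                    continue
                rec_idx, lig_idx = (d, acc) if not c.atoms[d].is_ligand else (acc, d)
                records.append(
                    InteractionRecord(
                        type="hbond",
                        receptor_residue=c.atoms[rec_idx].residue_number,
                        receptor_part=c.atoms[rec_idx].atom_name or f"atom{rec_idx}",
                        ligand_part=c.atoms[lig_idx].atom_name or f"atom{lig_idx}",
                        distance=dist,
                        angles={"DHA": angle},
                    )
                )
    return records


def detect_salt_bridges(
    c: ComplexStructure, thresholds: GeometryThresholds | None = None
) -> list[InteractionRecord]:
    """Opposite formal charges across the partition within the cutoff."""
    t = thresholds or GeometryThresholds()
    cations = [i for i, a in enumerate(c.atoms) if a.cation]
    anions = [i for i, a in enumerate(c.atoms) if a.anion]
    records = []
    for i, j in _cross(cations, anions):
        if c.atoms[i].is_ligand == c.atoms[j].is_ligand:
            continue
        dist = float(np.linalg.norm(c.atoms[i].xyz - c.atoms[j].xyz))
        if dist > t.salt_bridge_max:
            continue
        rec_idx, lig_idx = (i, j) if not c.atoms[i].is_ligand else (j, i)
        records.append(
            InteractionRecord(
                type="salt_bridge",
                receptor_residue=c.atoms[rec_idx].residue_number,
                receptor_part=c.atoms[rec_idx].atom_name or f"atom{rec_idx}",
                ligand_part=c.atoms[lig_idx].atom_name or f"atom{lig_idx}",
                distance=dist,
            )
        )
    return records


def _ring_pair_geometry(r1: RingSystem, r2: RingSystem) -> tuple[float, float, float]:
    """(centroid distance, θ, γ); γ is the smaller of the two normal choices."""
    v = r2.centroid - r1.centroid
    dist = float(np.linalg.norm(v))
    theta = _fold90(_angle_deg(r1.normal, r2.normal))
    if dist < 1e-9:
        return dist, theta, 0.0
    gamma = min(_fold90(_angle_deg(r1.normal, v)), _fold90(_angle_deg(r2.normal, v)))
    return dist, theta, gamma


def detect_pi_pi(
    c: ComplexStructure,
    thresholds: GeometryThresholds | None = None,
    rings: Optional[list[RingSystem]] = None,
) -> list[InteractionRecord]:
    """π–π contacts between receptor and ligand aromatic rings.

    A qualifying pair is classified stacked first; one record per pair.
    """
    t = thresholds or GeometryThresholds()
    rings = perceive_rings(c) if rings is None else rings
    rec_rings = [r for r in rings if r.aromatic and not r.is_ligand]
    lig_rings = [r for r in rings if r.aromatic and r.is_ligand]
    records = []
    for rr in rec_rings:
        for lr in lig_rings:
            dist, theta, gamma = _ring_pair_geometry(rr, lr)
            if dist > t.pi_pi_dist:
                continue
            if theta <= t.pi_pi_stacked_theta and gamma <= t.pi_pi_stacked_gamma:
                kind = "pi_pi_stacked"
            elif abs(theta - 90.0) <= t.pi_pi_tshaped_theta and gamma <= t.pi_pi_tshaped_gamma:
                kind = "pi_pi_tshaped"
            else:
                continue
            records.append(
                InteractionRecord(
                    type=kind,
                    receptor_residue=rr.residue_number,
                    receptor_part=f"ring{rr.members}",
                    ligand_part=f"ring{lr.members}",
                    distance=dist,
                    angles={"theta": theta, "gamma": gamma},
                )
            )
    return records


def _ring_point_contacts(
    c: ComplexStructure,
    rings: list[RingSystem],
    point_indices: list[int],
    dist_max: float,
    angle_max: float,
    kind: str,
) -> list[InteractionRecord]:
    records = []
    for ring in rings:
        if not ring.aromatic:
            continue
        for p in point_indices:
            if c.atoms[p].is_ligand == ring.is_ligand:
                continue
            v = c.atoms[p].xyz - ring.centroid
            dist = float(np.linalg.norm(v))
            if dist > dist_max or dist < 1e-9:
                continue
            angle = _fold90(_angle_deg(ring.normal, v))
            if angle > angle_max:
                continue
            if ring.is_ligand:
                res, rec_part, lig_part = (
                    c.atoms[p].residue_number,
                    c.atoms[p].atom_name or f"atom{p}",
                    f"ring{ring.members}",
                )
            else:
                res, rec_part, lig_part = (
                    ring.residue_number,
                    f"ring{ring.members}",
                    c.atoms[p].atom_name or f"atom{p}",
                )
            records.append(
                InteractionRecord(
                    type=kind,
                    receptor_residue=res,
                    receptor_part=rec_part,
                    ligand_part=lig_part,
                    distance=dist,
                    angles={"off_normal": angle},
                )
            )
    return records


def detect_pi_cation(
    c: ComplexStructure,
    thresholds: GeometryThresholds | None = None,
    rings: Optional[list[RingSystem]] = None,
) -> list[InteractionRecord]:
    """Cation within the cutoff of an aromatic centroid, near the normal."""
    t = thresholds or GeometryThresholds()
    rings = perceive_rings(c) if rings is None else rings
    cations = [i for i, a in enumerate(c.atoms) if a.cation]
    return _ring_point_contacts(
        c, rings, cations, t.pi_cation_dist, t.pi_cation_angle, "pi_cation"
    )


def detect_pi_alkyl(
    c: ComplexStructure,
    thresholds: GeometryThresholds | None = None,
    rings: Optional[list[RingSystem]] = None,
) -> list[InteractionRecord]:
    """Alkyl (sp3, C/H-only neighbours) carbon over an aromatic ring."""
    t = thresholds or GeometryThresholds()
    rings = perceive_rings(c) if rings is None else rings
    alkyls = [i for i, a in enumerate(c.atoms) if a.hydrophobic_carbon]
    return _ring_point_contacts(
        c, rings, alkyls, t.pi_alkyl_dist, t.pi_alkyl_angle, "pi_alkyl"
    )


def detect_all(
    c: ComplexStructure, thresholds: GeometryThresholds | None = None
) -> list[InteractionRecord]:
    """Run every detector; rings are perceived once and shared."""
    t = thresholds or GeometryThresholds()
    rings = perceive_rings(c)
    out: list[InteractionRecord] = []
    out += detect_hbonds(c, t)
    out += detect_salt_bridges(c, t)
    out += detect_pi_pi(c, t, rings)
    out += detect_pi_cation(c, t, rings)
    out += detect_pi_alkyl(c, t, rings)
    return out


def interaction_fingerprint(
    c: ComplexStructure,
    thresholds: GeometryThresholds | None = None,
    bw_map: Optional[dict[int, str]] = None,
) -> dict:
    """Residue-level fingerprint: receptor residue -> set of contact types.

    Keys are residue numbers ordered ascending; with ``bw_map`` supplied the
    keys become Ballesteros–Weinstein labels (e.g. 106 -> 'D3.32').
    """
    records = detect_all(c, thresholds)
    fp: dict[int, set[str]] = {}
    for r in records:
        fp.setdefault(r.receptor_residue, set()).add(r.type)
    ordered = {k: fp[k] for k in sorted(fp)}
    if bw_map:
        return {bw_map.get(k, k): v for k, v in ordered.items()}
    return ordered


def assign_roles(c: ComplexStructure) -> ComplexStructure:
    """Heuristic donor/acceptor/charge/alkyl typing for untyped structures.

    Used for structures read from plain PDB files, which carry no explicit
    typing.  Rules (logged as the documented fallback):

    * N or O bonded to an H       -> hydrogen-bond donor
    * any N or O                  -> hydrogen-bond acceptor
    * N with four bonds or formal charge > 0 -> cation
    * terminal O on a carbon that bears two terminal O (carboxylate), or
      formal charge < 0           -> anion
    * C bonded only to C/H, not in any ring of size 5-7 perceived as
      aromatic                    -> hydrophobic (alkyl) carbon
    """
    bonds = c.get_bonds()
    nbrs: dict[int, list[int]] = {i: [] for i in range(len(c.atoms))}
    for i, j in bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    atoms = [replace(a) for a in c.atoms]

    def is_terminal_o(idx: int) -> bool:
        return atoms[idx].element == "O" and len(nbrs[idx]) == 1

    aromatic_members: set[int] = set()
    for ring in perceive_rings(ComplexStructure(atoms=list(atoms), bonds=bonds)):
        if ring.aromatic:
            aromatic_members.update(ring.members)
    for i, a in enumerate(atoms):
        if a.element in ("N", "O"):
            a.hbond_acceptor = True
            if any(atoms[j].element == "H" for j in nbrs[i]):
                a.hbond_donor = True
        if a.element == "N" and (len(nbrs[i]) >= 4 or a.formal_charge > 0):
            a.cation = True
        if a.formal_charge < 0:
            a.anion = True
        elif is_terminal_o(i):
            carbon = nbrs[i][0]
            if atoms[carbon].element == "C":
                n_term_o = sum(1 for j in nbrs[carbon] if is_terminal_o(j))
                if n_term_o >= 2:
                    a.anion = True
        if (
            a.element == "C"
            and i not in aromatic_members
            and all(atoms[j].element in ("C", "H") for j in nbrs[i])
        ):
            a.hydrophobic_carbon = True
        if i in aromatic_members:
            a.aromatic = True
    return ComplexStructure(atoms=atoms, bonds=bonds)
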