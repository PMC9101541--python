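"""Deterministic synthetic fixtures with recorded ground truth.

Every generator takes a seed and returns (fixture, manifest); the manifest
records the parameters and the planted ground truth, so tests can check the
pipeline's output against what was actually put in:

* compositions spanning a chosen AQVN window (in/out membership known),
* clustered descriptor matrices from a low-rank factor model with
  candidates planted at controlled distances from the learning centroid,
* idealized 3D receptor–ligand complexes with one interaction of each
  requested type planted at a known fraction of its detection threshold,
* Gaussian FEP energy-difference samples whose exact free energy is known
  in closed form (ΔA = μ − σ²/2kT per window).

Planted geometries default to 90% of each threshold (a clear pass); a
factor above 1 plants a deliberate miss.  These fixtures exercise the
detection and estimation logic, not chemistry: fragments are idealized
(regular 1.39 Å hexagons, collinear donor–H–acceptor triads), not
force-field-relaxed conformers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

from .chem_io import MoleculeRecord
from .eiip import (
    DomainWindow,
    MolecularComposition,
    ValenceTable,
    compute_aqvn,
    compute_eiip,
)
from .energetics import FEPSeries, PhysicalConstants
from .interactions import AtomRecord, ComplexStructure, GeometryThresholds
from .pca_screen import DescriptorMatrix

__all__ = [
    "FixtureManifest",
    "gen_compositions",
    "gen_descriptor_matrix",
    "gen_complex_fixture",
    "gen_fep_gaussian",
    "SEROTONIN_COMPOSITION",
]

#: The serotonin anchor formula, AQVN exactly 68/25 = 2.72.
SEROTONIN_COMPOSITION = MolecularComposition({"C": 10, "H": 12, "N": 2, "O": 1})


@dataclass
class FixtureManifest:
    """What a generator produced: seed, parameters, and ground truth."""

    seed: int
    generator: str
    parameters: dict[str, Any] = field(default_factory=dict)
    ground_truth: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# compositions


def _random_composition(rng: np.random.Generator) -> MolecularComposition:
    counts = {
        "C": int(rng.integers(1, 25)),
        "H": int(rng.integers(1, 35)),
    }
    if rng.random() < 0.7:
        counts["N"] = int(rng.integers(1, 5))
    if rng.random() < 0.7:
        counts["O"] = int(rng.integers(1, 6))
    if rng.random() < 0.15:
        counts["S"] = 1
    return MolecularComposition(counts)


def _composition_in_window(
    window: DomainWindow,
    rng: np.random.Generator,
    table: ValenceTable,
    max_tries: int = 5000,
) -> Optional[MolecularComposition]:
    """Integer search for a CxHyNzOw composition with AQVN inside the window.

    For a total atom count N the valence-electron sum s must be an integer
    in [aqvn_lo·N, aqvn_hi·N]; solving h + c + n + o = N and
    h + 4c + 5n + 6o = s for c gives c = (s − N − 4n − 5o) / 3.  Narrow
    windows admit integer solutions only for some N, so N and s are
    sampled until one works.
    """
    for _ in range(max_tries):
        n_atoms = int(rng.integers(12, 90))
        s_lo = math.ceil(window.aqvn_lo * n_atoms - 1e-9)
        s_hi = math.floor(window.aqvn_hi * n_atoms + 1e-9)
        if s_lo > s_hi:
            continue
        s = int(rng.integers(s_lo, s_hi + 1))
        n = int(rng.integers(0, 5))
        o = int(rng.integers(0, 5))
        c3 = s - n_atoms - 4 * n - 5 * o
        if c3 < 3 or c3 % 3 != 0:
            continue
        c = c3 // 3
        h = n_atoms - n - o - c
        if h < 1:
            continue
        counts = {"C": c, "H": h}
        if n:
            counts["N"] = n
        if o:
            counts["O"] = o
        comp = MolecularComposition(counts)
        if window.contains(compute_eiip(compute_aqvn(comp, table))):
            return comp
    return None


def gen_compositions(
    n: int,
    window: DomainWindow,
    fraction_inside: float = 0.3,
    seed: int = 0,
    table: ValenceTable | None = None,
    max_tries: int = 200_000,
) -> tuple[list[MoleculeRecord], FixtureManifest]:
    """Random CxHyNzOw(S) compositions with exact in-window membership.

    Exactly ``round(n * fraction_inside)`` records fall inside the AQVN
    window; the serotonin sentinel (C10H12N2O) is always the first record
    and counts toward whichever side of the window it lands on.  Rejection
    sampling over integer compositions; an infeasible window raises.
    """
    if not 0 <= fraction_inside <= 1:
        raise ValueError("fraction_inside must be in [0, 1]")
    table = table or ValenceTable()
    rng = np.random.default_rng(seed)
    n_inside_target = round(n * fraction_inside)

    records: list[MoleculeRecord] = []
    truth: list[dict[str, Any]] = []
    sent_desc = compute_eiip(compute_aqvn(SEROTONIN_COMPOSITION, table))
    sentinel_inside = window.contains(sent_desc)
    if n >= 1:
        records.append(
            MoleculeRecord(id="sentinel_serotonin", composition=SEROTONIN_COMPOSITION)
        )
        truth.append(
            {"id": "sentinel_serotonin", "aqvn": sent_desc.aqvn, "inside": sentinel_inside}
        )
    need_inside = n_inside_target - (1 if sentinel_inside and n >= 1 else 0)
    need_outside = (n - len(records)) - need_inside
    if need_inside < 0 or need_outside < 0:
        raise ValueError("fraction_inside incompatible with the sentinel record")

    idx = 0

    def emit(comp: MolecularComposition, inside: bool) -> None:
        nonlocal idx
        desc = compute_eiip(compute_aqvn(comp, table))
        rid = f"syn{idx:04d}"
        idx += 1
        records.append(MoleculeRecord(id=rid, composition=comp))
        truth.append({"id": rid, "aqvn": desc.aqvn, "inside": inside})

    # in-window members by constructive integer search
    for _ in range(need_inside):
        comp = _composition_in_window(window, rng, table)
        if comp is None:
            raise ValueError(
                f"window {window.label!r} infeasible for the element pool "
                f"(no CxHyNzOw composition found)"
            )
        emit(comp, True)
    # out-of-window members by rejection sampling
    tries = 0
    placed_outside = 0
    while placed_outside < need_outside and tries < max_tries:
        tries += 1
        comp = _random_composition(rng)
        if window.contains(compute_eiip(compute_aqvn(comp, table))):
            continue
        emit(comp, False)
        placed_outside += 1
    if placed_outside < need_outside:
        raise ValueError(
            f"window {window.label!r} infeasible for the element pool "
            f"(still need {need_outside - placed_outside} outside)"
        )
    manifest = FixtureManifest(
        seed=seed,
        generator="gen_compositions",
        parameters={
            "n": n,
            "window": window.label,
            "aqvn_center": window.aqvn_center,
            "aqvn_halfwidth": window.aqvn_halfwidth,
            "fraction_inside": fraction_inside,
        },
        ground_truth={
            "records": truth,
            "inside_ids": [t["id"] for t in truth if t["inside"]],
        },
    )
    return records, manifest


# ---------------------------------------------------------------------------
# descriptor matrices


def gen_descriptor_matrix(
    n_learning: int = 100,
    n_candidates: int = 30,
    k_factors: int = 5,
    n_descriptors: int = 10,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[DescriptorMatrix, DescriptorMatrix, FixtureManifest]:
    """Learning + candidate matrices from a k-factor linear model.

    Learning rows are ``mu + T L + noise`` with orthonormal factor loadings
    L (k × p) and factor scores of decreasing variance.  Candidates are
    placed along a fixed in-subspace direction at increasing multiples of a
    step, so their true distance ordering from the learning centroid is
    known and survives any linear re-description of the space.  Candidate 0
    sits exactly at the centroid.
    """
    if k_factors >= n_descriptors:
        raise ValueError("k_factors must be smaller than the descriptor count")
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, 2.0, size=n_descriptors)
    # orthonormal k×p loadings via QR of a random Gaussian matrix
    q, _ = np.linalg.qr(rng.normal(size=(n_descriptors, k_factors)))
    loadings = q.T  # k × p
    factor_sd = np.linspace(3.0, 1.0, k_factors)
    scores = rng.normal(size=(n_learning, k_factors)) * factor_sd
    X_learning = mu + scores @ loadings + rng.normal(0.0, noise_sd, (n_learning, n_descriptors))

    direction = loadings[0]  # unit vector inside the factor subspace
    steps = np.arange(n_candidates, dtype=float)  # 0, 1, 2, ...
    X_candidates = mu + steps[:, None] * direction[None, :]

    names = [f"d{j}" for j in range(n_descriptors)]
    learning = DescriptorMatrix(
        ids=[f"L{i:03d}" for i in range(n_learning)], X=X_learning, descriptor_names=names
    )
    candidates = DescriptorMatrix(
        ids=[f"C{i:03d}" for i in range(n_candidates)], X=X_candidates, descriptor_names=names
    )
    manifest = FixtureManifest(
        seed=seed,
        generator="gen_descriptor_matrix",
        parameters={
            "n_learning": n_learning,
            "n_candidates": n_candidates,
            "k_factors": k_factors,
            "n_descriptors": n_descriptors,
            "noise_sd": noise_sd,
        },
        ground_truth={
            "loadings": loadings,
            "mu": mu,
            "candidate_order": list(candidates.ids),  # ascending true distance
            "candidate_steps": steps.tolist(),
        },
    )
    return learning, candidates, manifest


# ---------------------------------------------------------------------------
# 3D complexes


def _benzene(center: np.ndarray, normal: np.ndarray, residue: int, name: str,
             is_ligand: bool, start_index: int) -> tuple[list[AtomRecord], list[tuple[int, int]]]:
    """Regular C6 hexagon (1.39 Å) in the plane orthogonal to ``normal``."""
    normal = normal / np.linalg.norm(normal)
    # build an orthonormal basis of the ring plane
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    atoms = []
    for i in range(6):
        ang = i * math.pi / 3.0
        pos = center + 1.39 * (math.cos(ang) * u + math.sin(ang) * v)
        atoms.append(
            AtomRecord(
                element="C",
                coords=tuple(pos),
                residue_number=residue,
                residue_name=name,
                is_ligand=is_ligand,
                aromatic=True,
                atom_name=f"C{i + 1}",
            )
        )
    bonds = [(start_index + i, start_index + (i + 1) % 6) for i in range(6)]
    return atoms, bonds


_PLANT_TYPES = ("hbond", "salt_bridge", "pi_pi_stacked", "pi_pi_tshaped",
                "pi_cation", "pi_alkyl")

_LIGAND_RESIDUE = 900


def gen_complex_fixture(
    plants: Sequence[tuple[str, int] | tuple[str, int, float]],
    seed: int = 0,
    thresholds: GeometryThresholds | None = None,
) -> tuple[ComplexStructure, FixtureManifest]:
    """Build an idealized complex with one planted contact per entry.

    Each plant is ``(type, receptor_residue)`` or
    ``(type, receptor_residue, distance_factor)``; the contact is placed at
    ``distance_factor`` × its distance threshold (default 0.9, a clear
    pass; above 1.0 plants a deliberate miss) with ideal angles.  Plants
    are spaced 50 Å apart so they cannot interfere; decoy atoms without
    role flags are scattered far outside every cutoff.  Ground truth lists
    which plants are expected to be detected.
    """
    t = thresholds or GeometryThresholds()
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    expected: list[dict[str, Any]] = []

    for p_idx, plant in enumerate(plants):
        ptype, residue = plant[0], int(plant[1])
        factor = float(plant[2]) if len(plant) > 2 else 0.9
        if ptype not in _PLANT_TYPES:
            raise ValueError(f"unknown interaction type {ptype!r}")
        if factor <= 0:
            raise ValueError("distance_factor must be > 0")
        origin = np.array([50.0 * p_idx, 0.0, 0.0])
        i0 = len(atoms)
        if ptype == "hbond":
            d = factor * t.hbond_dist_max
            atoms.append(AtomRecord("N", tuple(origin), residue, "ASN",
                                    hbond_donor=True, atom_name="ND"))
            atoms.append(AtomRecord("H", tuple(origin + [1.0, 0, 0]), residue, "ASN",
                                    atom_name="HD"))
            atoms.append(AtomRecord("O", tuple(origin + [d, 0, 0]), _LIGAND_RESIDUE,
                                    "LIG", is_ligand=True, hbond_acceptor=True,
                                    atom_name="O1"))
            bonds.append((i0, i0 + 1))
            detected = d <= t.hbond_dist_max  # angle is ideal (180°)
        elif ptype == "salt_bridge":
            d = factor * t.salt_bridge_max
            atoms.append(AtomRecord("O", tuple(origin), residue, "ASP",
                                    anion=True, formal_charge=-1, atom_name="OD1"))
            atoms.append(AtomRecord("N", tuple(origin + [d, 0, 0]), _LIGAND_RESIDUE,
                                    "LIG", is_ligand=True, cation=True,
                                    formal_charge=1, atom_name="N1"))
            detected = d <= t.salt_bridge_max
        elif ptype in ("pi_pi_stacked", "pi_pi_tshaped"):
            d = factor * t.pi_pi_dist
            ring_a, bonds_a = _benzene(origin, np.array([0.0, 0.0, 1.0]),
                                       residue, "PHE", False, i0)
            atoms.extend(ring_a)
            bonds.extend(bonds_a)
            i1 = len(atoms)
            if ptype == "pi_pi_stacked":
                ring_b, bonds_b = _benzene(origin + [0, 0, d], np.array([0.0, 0.0, 1.0]),
                                           _LIGAND_RESIDUE, "LIG", True, i1)
            else:
                ring_b, bonds_b = _benzene(origin + [0, 0, d], np.array([1.0, 0.0, 0.0]),
                                           _LIGAND_RESIDUE, "LIG", True, i1)
            atoms.extend(ring_b)
            bonds.extend(bonds_b)
            detected = d <= t.pi_pi_dist
        elif ptype == "pi_cation":
            d = factor * t.pi_cation_dist
            ring_a, bonds_a = _benzene(origin, np.array([0.0, 0.0, 1.0]),
                                       residue, "TRP", False, i0)
            atoms.extend(ring_a)
            bonds.extend(bonds_a)
            atoms.append(AtomRecord("N", tuple(origin + [0, 0, d]), _LIGAND_RESIDUE,
                                    "LIG", is_ligand=True, cation=True,
                                    formal_charge=1, atom_name="N1"))
            detected = d <= t.pi_cation_dist
        else:  # pi_alkyl
            d = factor * t.pi_alkyl_dist
            ring_a, bonds_a = _benzene(origin, np.array([0.0, 0.0, 1.0]),
                                       residue, "PHE", False, i0)
            atoms.extend(ring_a)
            bonds.extend(bonds_a)
            atoms.append(AtomRecord("C", tuple(origin + [0, 0, d]), _LIGAND_RESIDUE,
                                    "LIG", is_ligand=True, hydrophobic_carbon=True,
                                    atom_name="CM"))
            detected = d <= t.pi_alkyl_dist
        expected.append(
            {"type": ptype, "residue": residue, "distance_factor": factor,
             "detected": bool(detected)}
        )

    # decoys: plain untyped atoms far outside every cutoff
    n_decoys = 5
    base = np.array([0.0, 500.0, 0.0])
    for i in range(n_decoys):
        pos = base + rng.normal(0, 5.0, 3) + [30.0 * i, 0, 0]
        atoms.append(AtomRecord("C", tuple(pos), 800 + i, "ALA",
                                atom_name="CB"))

    manifest = FixtureManifest(
        seed=seed,
        generator="gen_complex_fixture",
        parameters={"plants": [tuple(p) for p in plants]},
        ground_truth={
            "plants": expected,
            "fingerprint": {
                e["residue"]: {e["type"]} for e in expected if e["detected"]
            },
        },
    )
    return ComplexStructure(atoms=atoms, bonds=bonds), manifest


# ---------------------------------------------------------------------------
# FEP samples


def gen_fep_gaussian(
    mu: float = 0.5,
    sigma: float = 0.3,
    n_windows: int = 50,
    n_samples: int = 10_000,
    T: float = 298.0,
    seed: int = 0,
) -> tuple[FEPSeries, FEPSeries, FixtureManifest]:
    """Gaussian per-window ΔU samples with a known analytic free energy.

    Forward samples are N(μ, σ²); consistent backward samples (measured in
    the end state, reporting the reverse perturbation) are
    N(−μ + σ²/kT, σ²).  The exact per-window free energy is
    ΔA = μ − σ²/(2kT); the manifest records it and the exact total.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_samples < 2:
        raise ValueError("need at least 2 samples per window")
    rng = np.random.default_rng(seed)
    kT = PhysicalConstants(T=T).kT_kcal
    lambdas = np.linspace(0.0, 1.0, n_windows, endpoint=False)
    fwd_samples = [rng.normal(mu, sigma, n_samples) for _ in range(n_windows)]
    mu_b = -mu + sigma**2 / kT
    bwd_samples = [rng.normal(mu_b, sigma, n_samples) for _ in range(n_windows)]
    fwd = FEPSeries(lambdas=lambdas, samples=fwd_samples, direction="forward")
    bwd = FEPSeries(lambdas=lambdas, samples=bwd_samples, direction="backward")
    per_window = mu - sigma**2 / (2.0 * kT)
    manifest = FixtureManifest(
        seed=seed,
        generator="gen_fep_gaussian",
        parameters={"mu": mu, "sigma": sigma, "n_windows": n_windows,
                    "n_samples": n_samples, "T": T},
        ground_truth={
            "per_window_dA": per_window,
            "total_dA": per_window * n_windows,
        },
    )
    return fwd, bwd, manifest
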