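# Methods

## EIIP/AQVN descriptors

The average quasi-valence number is Z* = Σ nᵢZᵢ/N with neutral-atom
valence-electron counts (H 1, C 4, N 5/P 5, O 6/S 6, halogens 7). Formal
charges do not change Zᵢ: the definition is per element, and the
calibration anchor — serotonin C10H12N2O giving exactly 68/25 = 2.72 —
holds only with neutral-atom counts. Compositions always include
hydrogens; structures arriving without explicit hydrogens (SMILES, some
SDF) get valence-based completion through RDKit before counting.

EIIP = 0.25·Z*·sin(1.04·π·Z*)/(2π), in Rydberg. Two conventions needed
fixing:

* the division by 2π applies to the **whole product** — verified
  numerically against the tabulated pairs (2.72, 0.055), (2.55, 0.090),
  (2.909, 0.009), (3.08, 0.073);
* published tables print the **magnitude**. The signed value is negative
  at 2.909 and 3.08 (the sine is past its node at Z* = 3/1.04 ≈ 2.8846);
  both fields are kept, `eiip` being the magnitude.

Screening windows default to ±0.005 around each printed center, since the
campaign's candidate tables list AQVN exactly at 2.55/2.72/2.99; the
halfwidth is configuration. The "2.99" subdomain is shipped as printed
even though EIIP(2.99) ≈ 0.040 rather than the quoted 0.009 — the quoted
pair matches intepirdine's AQVN 2.909, so a "2.909" preset is shipped
alongside without guessing which was intended. Similarly, the clinical
compounds cerlapirdine (2.88 → printed EIIP 0.000, recomputed 0.002) and
the 2.99-window candidates inherit small print/recompute discrepancies;
the analysis driver reports the agreement count rather than forcing it.

## PCA centroid-distance screening

The descriptor source is pluggable: any molecules × descriptors numeric
table is accepted. The campaign's GRID/MIF probe descriptors (DRY, O, N1,
TIP with AMANDA discretization and MACC2 encoding) are proprietary to an
external package and are not re-implemented, so the printed 64.84%
explained variance is not reproducible here; what this module owns is the
screening procedure — centering (always) and autoscaling (default, since
descriptor columns mix units), a k = 5 component model, and ranking by
the Euclidean norm of the candidate's score vector. The learning-set
centroid is the origin of component space, so "shortest centroid
distance" is just that norm; a nearest-neighbor variant (distance to the
closest learning-set member) is available behind a separate function for
the alternative reading of the phrase. Component signs are canonicalized
(largest-magnitude loading positive) to make fits deterministic; ties in
ranking keep input order. Top-k defaults to ten per window, mirroring the
3 × 10 candidate design.

## Interaction geometry

Detection runs on typed atoms: donor (N/O bearing an H), acceptor (N/O),
cation, anion, hydrophobic (sp3, C/H-only neighbours) carbon, aromatic
ring member. Structures built programmatically carry flags directly; PDB
input gets a documented heuristic typing pass (charges from columns
79–80 when present; N with four bonds → cation; carboxylate-pattern
terminal O → anion).

Numerical choices:

* all "maximum distance" thresholds are closed balls (≤);
* the H-bond distance is donor-to-acceptor (D···A ≤ 3.4 Å) by default —
  3.4 Å is the conventional heavy-atom cutoff, and the alternative
  hydrogen–acceptor reading is switchable (`hbond_distance_mode="H-A"`);
* ring normals come from the least-variance singular vector of the
  centered ring coordinates; because normals are sign-ambiguous, every
  angle against a normal (θ, γ, off-normal angles) is folded to
  [0°, 90°] before thresholding, and the stored normal is
  sign-canonicalized (positive z, then x, then y) for reproducibility;
* γ is taken as the smaller of the two choices of reference ring — the
  criterion does not say which ring's normal defines it;
* the T-shaped window is read as "within 30° of perpendicular"
  (|θ − 90°| ≤ 30°) with γ ≤ 55°; a pair satisfying both classifications
  is recorded as stacked, one record per ring pair;
* rings are the 5–7-membered cycles of the minimum cycle basis of the
  bond graph (bonds supplied, or inferred from covalent radii + 0.45 Å);
  a ring is aromatic if its atoms are flagged so, or — with no flags
  anywhere — if its planarity RMS is ≤ 0.1 Å.

The binding site is a 15 Å closed sphere around the docking grid center
(−25.9, 5.82, 18.04), the carboxyl carbon of the conserved D3.32
aspartate in the receptor model's frame; ligand atoms are always
retained. Fingerprints are the per-residue union of detected contact
types, optionally relabelled with Ballesteros–Weinstein positions via a
user-supplied map.

## ADMET rules

Inequality strictness follows the published footnote verbatim: MW
strictly below 500, logP strictly below 5, DHB/AHB up to and including
5/10, PSA strictly positive; logS strictly above −5.7, PCaco strictly
above 22 nm/s, PM strictly below 7. The PSA condition counts as the
fifth Lipinski rule (no published row exercises it, so this is testable
only on synthetic rows). Fractional donor/acceptor counts (a QikProp
convention, e.g. AHB 4.45) are compared as reals. The set-level summary
is max over compounds of max(VRF, VRT) — the statistic behind "no more
than one violation". CNS MPO uses the published Wager desirability
transforms (clogP 3→5, clogD 2→4, MW 360→500, HBD 0.5→3.5, pKa 8→10
monotone; TPSA hump 20/40–90/120); the bundled tables' CNS MPO columns
are carried as data, not recomputed, because they depend on external
pKa/logD predictors.

## Free-energy bookkeeping

Double annihilation: ΔΔG = ΔG_unbound − ΔG_bound, binding
ΔG = −ΔΔG, reproducing the published 45.06 − 29.79 = 15.27 kcal/mol
endpoint arithmetic. The SOS estimator per λ window is
ΔA = −kT·ln(⟨e^(−ΔU_f/2kT)⟩_fwd / ⟨e^(−ΔU_b/2kT)⟩_bwd), summed over
windows, computed with log-sum-exp so extreme ΔU cannot overflow; the
campaign names the estimator without defining it, so the formula is the
standard one from the overlap-sampling literature. Constants are pinned
(R = 8.314 J mol⁻¹ K⁻¹, T = 298 K default, 4184 J/kcal) so the Kd
conversion Kd = exp(ΔG·4184/RT) is exactly testable; the sign convention
makes a negative binding ΔG give Kd < 1 M, consistent with the
(sub)nanomolar affinity implied by the docking estimate (−13.13 kcal/mol
→ Kd ≈ 2.3 × 10⁻¹⁰ M). Hysteresis is |ΔA_fwd + ΔA_bwd| over independent
forward and backward estimates.

## Synthetic data

The generators produce the study's test conditions with known ground
truth:

* **compositions** — C/H/N/O(+S) integer compositions; in-window members
  are found by constructive integer search (a narrow AQVN window admits
  an integer valence-electron sum only for some total atom counts, so
  rejection sampling alone stalls), out-of-window members by rejection.
  The serotonin sentinel is always the first record. Default library
  draws use a few percent in-window, echoing the sparse hit rate of a
  descriptor filter over a large library.
* **descriptor matrices** — a 100-molecule learning set from a 5-factor
  linear model over 10 descriptors with Gaussian noise (σ = 0.1), the
  factor count matching the 5-component screening model and the learning
  size matching the 100-compound active set; candidates lie along a
  fixed in-subspace direction at increasing steps, so their distance
  order survives any linear re-description of the space.
* **complexes** — idealized fragments (regular 1.39 Å benzene hexagons,
  collinear donor–H–acceptor triads, charged pairs) planted at 90% of
  each threshold by default (a clear pass; factors above 1 plant
  deliberate misses), 50 Å apart so plants cannot interact, with
  far-away decoy atoms.
* **FEP samples** — forward ΔU ~ N(μ, σ²) per window and consistent
  backward samples N(−μ + σ²/kT, σ²), for which the exact free energy is
  ΔA = μ − σ²/2kT per window. Defaults (50 windows, matching the λ step
  0.02; 10⁴ samples) make the SOS standard error small enough for a
  3-SE recovery test.

All generators are deterministic given (seed, parameters), and manifests
record the full ground truth.

What these fixtures do **not** emulate: real conformational ensembles,
force-field geometries, correlated FEP time series, or the descriptor
distributions of actual MIF probes. Green tests therefore demonstrate
that the screening *logic* is correct — filters, rankings, detectors and
estimators do exactly what their definitions say — not that the
descriptors themselves are predictive for real 5HT6 ligands.

## Known limitations

* Docking, MD and descriptor-field generation are out of scope; the
  pipeline ingests their outputs.
* PDB atom typing is heuristic and intended for poses with explicit
  charges or standard residue chemistry; unusual ligand chemotypes may
  need pre-typed structures.
* Ring perception covers 5–7-membered rings (the sizes the π criteria
  address), not macrocycles.
* The published explained-variance figure and docking scores cannot be
  recomputed without the proprietary external tools; they are carried as
  reference data only.
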