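"""Seeded generators for structures, variant sets and docking ensembles with
known ground truth.

Real interface/variant data requires structure databases; these generators
instead build inputs whose correct answer is known by construction, so every
pipeline stage can be tested end to end:

* :func:`make_toy_complex` — two compact poly-alanine-like "lattice globule"
  chains in geometric contact, with ground-truth region labels derived from
  the construction geometry.  A triplet of facing residues carries opposite
  partial charges so the bound orientation is energetically favorable.
* :func:`plant_variants` — Bernoulli variant placement with per-region rates,
  i.e. a planted odds-ratio structure.
* :func:`make_pose_ensemble` — a docking ensemble of near-native poses (small
  perturbations of the true orientation, favorable scores) plus random
  decoys (unfavorable scores), emulating a rescored rigid-body search at
  reduced scale.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .docking_nip import Pose
from .structure_model import Atom, ChainStructure, Residue
from .variant_atlas import AA1, VariantRecord

LATTICE_SPACING = 3.5      # A between residue centers
UNIFORM_RADIUS = 1.9       # A, single-sphere residue model
PROBE = 1.4
#: two expanded spheres stop occluding each other beyond this separation
OCCLUSION_DISTANCE = 2.0 * (UNIFORM_RADIUS + PROBE)


@dataclass
class SyntheticComplexSpec:
    n_residues: int = 120
    fold_style: str = "lattice-globule"   # or "extended-helix"
    contact_offset: float = 4.0           # A gap between the chain surfaces
    seed: int = 0
    jitter: float = 0.15                  # A positional noise on lattice points

    def __post_init__(self) -> None:
        if self.contact_offset <= 0:
            raise ValueError("contact_offset must be positive")
        if self.n_residues < 10:
            raise ValueError("need at least 10 residues per chain")
        if self.fold_style not in ("lattice-globule", "extended-helix"):
            raise ValueError(f"unknown fold_style {self.fold_style!r}")


@dataclass
class PlantedEnrichmentSpec:
    """Per-region Bernoulli variant rates; the implied odds ratios are the
    planted ground truth."""
    disease_rates: dict = field(default_factory=lambda: {
        "buried": 0.30, "surface": 0.18, "rim": 0.17, "core": 0.30})
    neutral_rates: dict = field(default_factory=lambda: {
        "buried": 0.09, "surface": 0.25, "rim": 0.19, "core": 0.07})
    seed: int = 0

    def __post_init__(self) -> None:
        for rates in (self.disease_rates, self.neutral_rates):
            for region, r in rates.items():
                if not (0.0 <= r <= 1.0):
                    raise ValueError(f"rate for {region} outside [0, 1]")

    def implied_odds_ratio(self, category: str, region_i: str, region_j: str) -> float:
        rates = self.disease_rates if category == "disease" else self.neutral_rates
        pi, pj = rates[region_i], rates[region_j]
        return (pi / (1 - pi)) / (pj / (1 - pj))


@dataclass
class ToyComplex:
    receptor: ChainStructure
    ligand: ChainStructure
    labels_receptor: dict          # position -> buried/surface/rim/core (ground truth)
    labels_ligand: dict
    true_interface_receptor: frozenset
    true_interface_ligand: frozenset
    spec: SyntheticComplexSpec


def _truncated_ball(n: int) -> np.ndarray:
    """The n cubic-lattice points nearest the origin within the half-space
    x <= 0: a compact globule with a flat face at x = 0 that serves as the
    designed binding surface.  Deterministic tie-breaking by coordinates."""
    reach = int(np.ceil((n * 6 / (4 * np.pi)) ** (1 / 3))) + 3
    grid = np.arange(-reach, reach + 1)
    pts = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T * LATTICE_SPACING
    pts = pts[pts[:, 0] <= 0]
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0],
                        np.round(np.linalg.norm(pts, axis=1), 6)))
    return pts[order[:n]]


def _helix_pair(n: int, rng: np.random.Generator, jitter: float) -> np.ndarray:
    """Extended-helix fold: residues on a coarse helix along x."""
    t = np.arange(n) * 1.5
    coords = np.column_stack([t, 4.5 * np.cos(t / 2.5), 4.5 * np.sin(t / 2.5)])
    return coords + rng.normal(0.0, jitter, coords.shape)


def _as_chain(coords: np.ndarray, chain_id: str) -> ChainStructure:
    residues = [Residue(author_number=i + 1, amino_acid="A",
                        atoms=[Atom(element="C", coord=c,
                                    vdw_radius=UNIFORM_RADIUS, name="CA")])
                for i, c in enumerate(coords)]
    return ChainStructure(chain_id=chain_id, residues=residues,
                          source_label="synthetic")


def _ground_truth(coords_a: np.ndarray, coords_b: np.ndarray,
                  contact_offset: float) -> tuple[dict, frozenset]:
    """Region labels from construction geometry: interior residues are
    buried; exposed residues occluded by the partner are interface (core if
    on the closest contact layer, rim otherwise); the rest are surface."""
    n = len(coords_a)
    d_self = cdist(coords_a, coords_a)
    neighbor_count = ((d_self < 1.3 * LATTICE_SPACING).sum(axis=1)) - 1
    d_cross = cdist(coords_a, coords_b).min(axis=1)
    labels = {}
    for i in range(n):
        pos = i + 1
        if neighbor_count[i] >= 6:
            labels[pos] = "buried"
        elif d_cross[i] < OCCLUSION_DISTANCE:
            # occluded by the partner; closest contact layer is the core
            if d_cross[i] < contact_offset + 0.5 * LATTICE_SPACING:
                labels[pos] = "core"
            else:
                labels[pos] = "rim"
        else:
            labels[pos] = "surface"
    interface = frozenset(p for p, lab in labels.items() if lab in ("core", "rim"))
    return labels, interface


def make_toy_complex(spec: SyntheticComplexSpec) -> ToyComplex:
    """Build two chains in geometric contact with ground-truth labels.

    Chain B is a copy of chain A's fold translated along +x so that the gap
    between the facing surfaces is ``contact_offset``.  The three closest
    cross-chain residue pairs get opposite unit charges (+1 on the receptor,
    -1 on the ligand): a planted hot-spot triplet that makes the bound
    orientation electrostatically favorable.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.fold_style == "lattice-globule":
        base = _truncated_ball(spec.n_residues)
        coords_a = base + rng.normal(0.0, spec.jitter, base.shape)
        # mirror the fold so its flat face points toward the receptor
        coords_b_local = base * np.array([-1.0, 1.0, 1.0]) \
            + rng.normal(0.0, spec.jitter, base.shape)
    else:
        coords_a = _helix_pair(spec.n_residues, rng, spec.jitter)
        coords_b_local = _helix_pair(spec.n_residues, rng, spec.jitter)
    shift = coords_a[:, 0].max() - coords_b_local[:, 0].min() + spec.contact_offset
    coords_b = coords_b_local + np.array([shift, 0.0, 0.0])
    # stable residue ordering along x, then y, z
    coords_a = coords_a[np.lexsort((coords_a[:, 2], coords_a[:, 1], coords_a[:, 0]))]
    coords_b = coords_b[np.lexsort((coords_b[:, 2], coords_b[:, 1], coords_b[:, 0]))]
    receptor = _as_chain(coords_a, "A")
    ligand = _as_chain(coords_b, "B")
    labels_a, iface_a = _ground_truth(coords_a, coords_b, spec.contact_offset)
    labels_b, iface_b = _ground_truth(coords_b, coords_a, spec.contact_offset)
    # planted hot-spot triplet: three closest cross-chain pairs
    d = cdist(coords_a, coords_b)
    flat = np.argsort(d, axis=None, kind="stable")
    chosen_a: list[int] = []
    chosen_b: list[int] = []
    for idx in flat:
        i, j = divmod(idx, len(coords_b))
        if i not in chosen_a and j not in chosen_b:
            chosen_a.append(i)
            chosen_b.append(j)
        if len(chosen_a) == 3:
            break
    for i in chosen_a:
        receptor.residues[i].atoms[0].charge = 1.0
    for j in chosen_b:
        ligand.residues[j].atoms[0].charge = -1.0
    return ToyComplex(receptor=receptor, ligand=ligand,
                      labels_receptor=labels_a, labels_ligand=labels_b,
                      true_interface_receptor=iface_a,
                      true_interface_ligand=iface_b, spec=spec)


def make_region_labels(counts: dict[str, int]) -> dict[int, str]:
    """Positional label map with the requested number of residues per region
    (positions 1..N, regions in the given order).  Used for purely
    statistical fixtures where geometry is irrelevant."""
    labels = {}
    pos = 1
    for region, n in counts.items():
        for _ in range(n):
            labels[pos] = region
            pos += 1
    return labels


_ALT_FOR = {a: ("V" if a != "V" else "L") for a in AA1}


def plant_variants(labels: dict, spec: PlantedEnrichmentSpec,
                   amino_acids: dict | None = None
                   ) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Independently mutate each residue with its region's per-category rate.

    Returns (disease, neutral) record lists; the realized counts are whatever
    the Bernoulli draws produced.
    """
    for rates in (spec.disease_rates, spec.neutral_rates):
        missing = set(labels.values()) - set(rates)
        if missing:
            raise ValueError(f"no rate specified for regions {sorted(missing)}")
    rng = np.random.default_rng(spec.seed)
    disease: list[VariantRecord] = []
    neutral: list[VariantRecord] = []
    positions = sorted(labels)
    draws_d = rng.random(len(positions))
    draws_n = rng.random(len(positions))
    for k, pos in enumerate(positions):
        region = labels[pos]
        ref = (amino_acids or {}).get(pos, "A")
        alt = _ALT_FOR[ref]
        if draws_d[k] < spec.disease_rates[region]:
            disease.append(VariantRecord("SYN", pos, ref, alt, "disease", "planted"))
        if draws_n[k] < spec.neutral_rates[region]:
            neutral.append(VariantRecord("SYN", pos, ref, alt, "neutral", "planted"))
    return disease, neutral


def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q).as_matrix()


def _small_rotations(n: int, rng: np.random.Generator, sigma_deg: float) -> np.ndarray:
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = rng.normal(0.0, np.deg2rad(sigma_deg), size=(n, 1))
    return Rotation.from_rotvec(axes * angles).as_matrix()


def make_pose_ensemble(complex_: ToyComplex, n_near: int = 100,
                       n_decoy: int = 900, seed: int = 0,
                       score_gap: float = 15.0,
                       near_score: float = -20.0,
                       near_rot_sigma_deg: float = 3.0,
                       near_trans_sigma: float = 0.5) -> list[Pose]:
    """A rescored docking ensemble at reduced scale.

    Near-native poses perturb the true (as-built) ligand placement slightly
    and score around ``near_score``; decoys are random orientations docked
    against a random patch of the receptor and score ``score_gap`` higher
    (less favorable) on average.  Deterministic per seed.
    """
    if n_near + n_decoy < 200:
        raise ValueError("ensemble must contain at least 200 poses")
    rng = np.random.default_rng(seed)
    lig_coords = np.vstack([r.atoms[0].coord for r in complex_.ligand.residues])
    rec_coords = np.vstack([r.atoms[0].coord for r in complex_.receptor.residues])
    c_lig = lig_coords.mean(axis=0)
    c_rec = rec_coords.mean(axis=0)
    r_rec = np.linalg.norm(rec_coords - c_rec, axis=1).max() + UNIFORM_RADIUS
    r_lig = np.linalg.norm(lig_coords - c_lig, axis=1).max() + UNIFORM_RADIUS
    poses: list[Pose] = []
    rots = _small_rotations(n_near, rng, near_rot_sigma_deg)
    jit = rng.normal(0.0, near_trans_sigma, size=(n_near, 3))
    scores = near_score + rng.normal(0.0, 2.0, size=n_near)
    for k in range(n_near):
        t = c_lig - rots[k] @ c_lig + jit[k]
        poses.append(Pose(rotation=rots[k], translation=t,
                          score=float(scores[k]), pose_id=k))
    d_rots = _random_rotations(n_decoy, rng)
    dirs = rng.normal(size=(n_decoy, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    d_scores = near_score + score_gap + rng.normal(0.0, 3.0, size=n_decoy)
    gap = complex_.spec.contact_offset
    for k in range(n_decoy):
        target = c_rec + dirs[k] * (r_rec + r_lig + gap - 2.0 * UNIFORM_RADIUS)
        t = target - d_rots[k] @ c_lig
        poses.append(Pose(rotation=d_rots[k], translation=t,
                          score=float(d_scores[k]), pose_id=n_near + k))
    return poses
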