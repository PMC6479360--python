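"""Docking-ensemble scoring and Normalized Interface Propensity (NIP).

When no complex structure exists, the interface is predicted from a
rigid-body docking ensemble.  Poses are rescored with a simplified binding
energy of the same term structure as pyDock: distance-dependent-dielectric
Coulomb electrostatics (truncated per atom pair), a down-weighted 6-12 van
der Waals term, and an atomic-solvation-parameter desolvation term on the
surface area buried by binding.  For each receptor residue the NIP over the
``n_top`` lowest-energy poses is

    NIP_i = (f_i - f_rand) / (1 - f_rand)

where f_i is the fraction of those poses whose interface contains residue i
and f_rand the average interface coverage per surface residue (the random
expectation).  NIP = 1 means the residue is at the interface of every
low-energy pose, 0 means it appears as often as expected by chance, and
negative values mean depletion.  Residues with NIP above a cutoff (default
0.1) form the predicted core; surface residues within 10 A of a core residue
form the predicted rim.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .enrichment_stats import RegionTally
from .sasa_regions import compute_asa
from .structure_model import ChainStructure

logger = logging.getLogger(__name__)

COULOMB_CONSTANT = 332.0637   # kcal mol^-1 A e^-2
DEFAULT_CONTACT_CUTOFF = 5.0  # A, heavy-atom pose-interface criterion
DEFAULT_RIM_DISTANCE = 10.0   # A, predicted rim around predicted core
DEFAULT_NIP_CUTOFF = 0.1
DEFAULT_LOW_ENERGY = -2.0     # a.u., "energetically relevant" threshold
DEFAULT_N_TOP = 100


@dataclass
class Pose:
    """Rigid-body pose: the ligand is mapped by x -> rotation @ x + translation."""
    rotation: np.ndarray
    translation: np.ndarray
    score: float
    pose_id: int = 0
    interface_residues: frozenset | None = None

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        # tolerance admits matrices round-tripped through 8-decimal text
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError(f"pose {self.pose_id}: rotation is not orthonormal")

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class EnergyModelParams:
    """Parameters of the simplified binding-energy model (arbitrary units,
    calibrated loosely to a kcal/mol-like scale)."""
    coulomb_weight: float = 1.0
    vdw_weight: float = 0.1             # "limited" van der Waals contribution
    vdw_eps: float = 0.2                # well depth, a.u.
    elec_cap: float = 1.0               # per-pair truncation, a.u.
    vdw_cap: float = 1.0                # per-pair repulsion cap before weighting
    distance_cutoff: float = 12.0       # A, pairwise interaction cutoff
    desolvation_asp: dict[str, float] = field(default_factory=lambda: {
        "C": -0.015, "N": 0.005, "O": 0.005, "S": -0.010})  # a.u. / A^2
    low_energy_threshold: float = DEFAULT_LOW_ENERGY
    asa_n_points: int = 240             # sampling density for desolvation ASA
    probe_radius: float = 1.4

    def __post_init__(self) -> None:
        if not (0.0 < self.vdw_weight <= 1.0):
            raise ValueError("vdw_weight must be in (0, 1]")
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be positive")


@dataclass
class NIPProfile:
    f_i: dict                 # residue -> fraction of top poses at interface
    nip: dict                 # residue -> normalized propensity
    f_rand: float
    n_top: int


def pose_interface(receptor: ChainStructure, ligand: ChainStructure, pose: Pose,
                   contact_cutoff: float = DEFAULT_CONTACT_CUTOFF) -> frozenset:
    """Receptor residues with any heavy atom within ``contact_cutoff`` of any
    transformed ligand heavy atom."""
    r_coords, _, _, r_owner = receptor.atom_arrays()
    l_coords, _, _, _ = ligand.atom_arrays()
    d = cdist(r_coords, pose.transform(l_coords))
    close = (d < contact_cutoff).any(axis=1)
    owner = np.asarray(r_owner)
    hit = {receptor.residues[i].author_number
           for i in np.unique(owner[close])}
    return frozenset(hit)


def annotate_interfaces(poses: list[Pose], receptor: ChainStructure,
                        ligand: ChainStructure,
                        contact_cutoff: float = DEFAULT_CONTACT_CUTOFF) -> list[Pose]:
    """Fill in each pose's interface residue set (in place); returns the list."""
    for p in poses:
        p.interface_residues = pose_interface(receptor, ligand, p, contact_cutoff)
    return poses


def _pairwise_terms(receptor: ChainStructure, ligand: ChainStructure, pose: Pose,
                    params: EnergyModelParams):
    """Per-atom-pair electrostatic and van der Waals energies (capped),
    zero beyond the distance cutoff."""
    r_coords, r_radii, r_q, r_owner = receptor.atom_arrays()
    l_coords, l_radii, l_q, _ = ligand.atom_arrays()
    lt = pose.transform(l_coords)
    d = cdist(r_coords, lt)
    np.clip(d, 1e-6, None, out=d)
    within = d < params.distance_cutoff
    # Coulomb with distance-dependent dielectric eps = 4r
    elec = COULOMB_CONSTANT * np.outer(r_q, l_q) / (4.0 * d * d)
    np.clip(elec, -params.elec_cap, params.elec_cap, out=elec)
    elec *= within * params.coulomb_weight
    # 6-12 Lennard-Jones with rmin = sum of vdW radii, repulsion capped
    rmin = r_radii[:, None] + l_radii[None, :]
    s6 = (rmin / d) ** 6
    vdw = params.vdw_eps * (s6 * s6 - 2.0 * s6)
    np.clip(vdw, None, params.vdw_cap, out=vdw)
    vdw *= within * params.vdw_weight
    return elec, vdw, d, np.asarray(r_owner)


def _desolvation(receptor: ChainStructure, ligand: ChainStructure, pose: Pose,
                 params: EnergyModelParams):
    """Per-atom desolvation energy: asp coefficient times the ASA buried on
    binding, for receptor and transformed ligand atoms."""
    r_coords, r_radii, _, _ = receptor.atom_arrays()
    l_coords, l_radii, _, _ = ligand.atom_arrays()
    lt = pose.transform(l_coords)
    nr = len(r_coords)
    asa_free_r = compute_asa(r_coords, r_radii, params.probe_radius, params.asa_n_points)
    asa_free_l = compute_asa(lt, l_radii, params.probe_radius, params.asa_n_points)
    asa_cplx = compute_asa(np.vstack([r_coords, lt]),
                           np.concatenate([r_radii, l_radii]),
                           params.probe_radius, params.asa_n_points)
    d_r = asa_free_r - asa_cplx[:nr]
    d_l = asa_free_l - asa_cplx[nr:]
    asp_r = np.array([params.desolvation_asp.get(a.element, 0.0)
                      for res in receptor.residues for a in res.atoms])
    asp_l = np.array([params.desolvation_asp.get(a.element, 0.0)
                      for res in ligand.residues for a in res.atoms])
    return asp_r * d_r, asp_l * d_l


def residue_binding_energy(receptor: ChainStructure, ligand: ChainStructure,
                           pose: Pose, params: EnergyModelParams | None = None,
                           include_desolvation: bool = True) -> dict:
    """Per-receptor-residue contributions to the pose binding energy.

    Pairwise terms are attributed to the receptor residue of each pair;
    receptor-atom desolvation to its own residue; ligand-atom desolvation to
    the receptor residue with the nearest atom (deterministic argmin).  The
    contributions partition the total: their sum equals
    :func:`score_pose` exactly.
    """
    params = params or EnergyModelParams()
    elec, vdw, d, owner = _pairwise_terms(receptor, ligand, pose, params)
    per_atom = (elec + vdw).sum(axis=1)
    n_res = len(receptor.residues)
    energies = np.zeros(n_res)
    np.add.at(energies, owner, per_atom)
    if include_desolvation:
        desolv_r, desolv_l = _desolvation(receptor, ligand, pose, params)
        np.add.at(energies, owner, desolv_r)
        nearest_atom = d.argmin(axis=0)          # receptor atom closest to each ligand atom
        np.add.at(energies, owner[nearest_atom], desolv_l)
    return {receptor.residues[i].author_number: float(energies[i])
            for i in range(n_res)}


def score_pose(receptor: ChainStructure, ligand: ChainStructure, pose: Pose,
               params: EnergyModelParams | None = None,
               include_desolvation: bool = True) -> float:
    """Total binding energy of a pose (a.u.); the sum of the per-residue
    decomposition."""
    return float(sum(residue_binding_energy(
        receptor, ligand, pose, params, include_desolvation).values()))


def flag_low_energy(per_residue_energies: dict,
                    threshold: float = DEFAULT_LOW_ENERGY) -> frozenset:
    """Residues strictly below the energy threshold: the energetically
    relevant (hot-spot-like) set."""
    return frozenset(r for r, e in per_residue_energies.items() if e < threshold)


def compute_nip(poses: list[Pose], n_top: int = DEFAULT_N_TOP,
                surface_residues: set | frozenset = frozenset()) -> NIPProfile:
    """Normalized interface propensity over the lowest-energy poses.

    Poses are ranked by score (ties broken by pose index).  Every pose must
    carry its interface residue set (see :func:`annotate_interfaces`).
    """
    if len(poses) < n_top:
        raise ValueError(f"need at least {n_top} poses, got {len(poses)}")
    surface = set(surface_residues)
    if not surface:
        raise ValueError("surface_residues must be non-empty")
    for p in poses:
        if p.interface_residues is None:
            raise ValueError(f"pose {p.pose_id} has no interface set; "
                             "run annotate_interfaces first")
    ranked = sorted(poses, key=lambda p: (p.score, p.pose_id))[:n_top]
    counts = {r: 0 for r in surface}
    total_cover = 0
    for p in ranked:
        iface = set(p.interface_residues) & surface
        total_cover += len(iface)
        for r in iface:
            counts[r] += 1
    f_rand = total_cover / (n_top * len(surface))
    if f_rand >= 1.0:
        raise ValueError("degenerate ensemble: every pose covers every surface residue")
    f_i = {r: c / n_top for r, c in counts.items()}
    nip = {r: (f - f_rand) / (1.0 - f_rand) for r, f in f_i.items()}
    return NIPProfile(f_i=f_i, nip=nip, f_rand=f_rand, n_top=n_top)


def predicted_core(profile: NIPProfile, cutoff: float = DEFAULT_NIP_CUTOFF) -> frozenset:
    """Residues with NIP >= cutoff (inclusive): the predicted interface core
    (docking hot-spots)."""
    core = frozenset(r for r, v in profile.nip.items() if v >= cutoff)
    if not core:
        warnings.warn("no confident interface: all NIP values below cutoff")
    return core


def predicted_rim(core: frozenset, receptor: ChainStructure,
                  surface_residues: set | frozenset,
                  rim_distance: float = DEFAULT_RIM_DISTANCE) -> frozenset:
    """Surface residues (outside the core) with any heavy atom within
    ``rim_distance`` of any heavy atom of a core residue."""
    if not core:
        return frozenset()
    by_number = {res.author_number: res for res in receptor.residues}
    core_coords = np.vstack([by_number[r].coords for r in core])
    rim = set()
    for r in set(surface_residues) - set(core):
        if r not in by_number:
            continue
        if (cdist(by_number[r].coords, core_coords) < rim_distance).any():
            rim.add(r)
    return frozenset(rim)


def low_energy_enrichment(region_labels: dict, flagged_residues: frozenset
                          ) -> list[dict]:
    """Distribution of energetically relevant residues across the interface
    regions (core/rim), with expected counts under proportional allocation.

    ``region_labels`` maps interface residues to 'core' or 'rim'.
    """
    missing = [r for r in flagged_residues if r not in region_labels]
    if missing:
        raise ValueError(f"flagged residues without region labels: {missing[:5]}")
    regions = ("rim", "core")
    totals = {g: sum(1 for v in region_labels.values() if v == g) for g in regions}
    observed = {g: sum(1 for r in flagged_residues if region_labels[r] == g)
                for g in regions}
    total_N = sum(totals.values())
    total_obs = sum(observed.values())
    rows = []
    for g in regions:
        if total_obs == 0 or total_N == 0:
            exp, oe = None, None
        else:
            exp = total_obs * totals[g] / total_N
            oe = observed[g] / exp if exp > 0 else None
        rows.append({"region": g, "all_residues": totals[g],
                     "observed": observed[g], "expected": exp, "o_over_e": oe,
                     "tally": RegionTally(g, totals[g], observed[g])})
    return rows


# ---------------------------------------------------------------------------
# Pose ensemble file format: TSV with pose_id, row-major rotation (r11..r33),
# translation (t1..t3, A) and score.

_POSE_COLUMNS = ["pose_id", "r11", "r12", "r13", "r21", "r22", "r23",
                 "r31", "r32", "r33", "t1", "t2", "t3", "score"]


def write_pose_ensemble(poses: list[Pose]) -> str:
    rows = []
    for p in poses:
        rows.append([p.pose_id, *p.rotation.ravel(), *p.translation, p.score])
    df = pd.DataFrame(rows, columns=_POSE_COLUMNS)
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.8f")
    return buf.getvalue()


def read_pose_ensemble(text: str) -> list[Pose]:
    df = pd.read_csv(io.StringIO(text), sep="\t")
    poses = []
    for row in df.itertuples(index=False):
        poses.append(Pose(
            rotation=np.array(row[1:10], dtype=float).reshape(3, 3),
            translation=np.array(row[10:13], dtype=float),
            score=float(row.score), pose_id=int(row.pose_id)))
    return poses
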