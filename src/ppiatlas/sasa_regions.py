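"""Solvent accessibility and interface region classification.

Every residue of a chain is assigned to exactly one of four regions by
comparing its relative accessible surface area in the free monomer (rASA_u)
against the two-chain complex (rASA_c):

* buried    — rASA_u < 0.1
* surface   — exposed, accessibility unchanged by the partner
* rim       — interface residue that stays exposed in the complex (rASA_c >= 0.1)
* core      — interface residue that becomes buried in the complex (rASA_c < 0.1)

rASA is the residue ASA divided by the ASA of the same residue type X in an
extended Gly-X-Gly tripeptide.  ASA itself is computed by deterministic
sphere-point sampling (a Shrake-Rupley-style scheme with a golden-spiral
point set), so results are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .structure_model import ChainStructure

logger = logging.getLogger(__name__)

#: ASA (Angstrom^2) of residue type X in an extended Gly-X-Gly peptide.
#: Shipped as a replaceable constant table.
GXG_REFERENCE_ASA = {
    "A": 110.1, "R": 247.3, "N": 146.0, "D": 144.1, "C": 140.2,
    "Q": 178.6, "E": 174.0, "G": 78.7,  "H": 181.2, "I": 183.1,
    "L": 181.9, "K": 204.1, "M": 200.1, "F": 200.7, "P": 141.9,
    "S": 117.2, "T": 138.7, "W": 266.3, "Y": 228.2, "V": 153.7,
}

RASA_THRESHOLD = 0.1       # buried / exposed boundary on rASA
DELTA_INTERFACE = 1e-6     # minimal rASA drop that counts as interface contact
DEFAULT_PROBE = 1.4        # water probe radius, Angstrom
DEFAULT_N_POINTS = 960

REGION_PRECEDENCE = {"core": 3, "rim": 2, "surface": 1, "buried": 0}


class RasaInconsistencyError(ValueError):
    """rASA in the complex exceeds rASA in the free form beyond tolerance."""


@dataclass
class ResidueSurfaceProfile:
    canonical_position: int | str
    amino_acid: str
    asa_u: float
    asa_c: float
    rasa_u: float
    rasa_c: float
    region: str
    partner_id: str = ""


@lru_cache(maxsize=8)
def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i          # golden angle increments
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts.setflags(write=False)
    return pts


def compute_asa(centers: np.ndarray, radii: np.ndarray,
                probe_radius: float = DEFAULT_PROBE,
                n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom accessible surface area of a set of spheres.

    Each atom's solvent-expanded sphere (radius + probe) is sampled at
    ``n_points`` deterministic points; the exposed fraction times the sphere
    area gives the ASA.  Exact duplicates (same center and radius) are
    discarded with a warning and contribute zero area.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).ravel()
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable sampling density")
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    n = len(centers)
    asa = np.zeros(n)
    # drop exact duplicates (identical center and radius)
    active = np.ones(n, dtype=bool)
    seen: dict[tuple, int] = {}
    for i in range(n):
        key = (round(centers[i, 0], 6), round(centers[i, 1], 6),
               round(centers[i, 2], 6), round(radii[i], 6))
        if key in seen:
            logger.warning("duplicate atom at %s discarded for ASA", key)
            active[i] = False
        else:
            seen[key] = i
    pts = _sphere_points(n_points)
    expanded = radii + probe_radius
    idx = np.flatnonzero(active)
    ctr = centers[idx]
    exp = expanded[idx]
    # pairwise distances between active atoms for neighbor pruning
    diff = ctr[:, None, :] - ctr[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    for k, i in enumerate(idx):
        nbr = np.flatnonzero((dist[k] < exp[k] + exp) & (np.arange(len(idx)) != k))
        if nbr.size == 0:
            asa[i] = 4.0 * np.pi * exp[k] ** 2
            continue
        sample = ctr[k] + exp[k] * pts                       # (n_points, 3)
        d2 = ((sample[:, None, :] - ctr[nbr][None, :, :]) ** 2).sum(-1)
        buried = (d2 < (exp[nbr] ** 2)[None, :]).any(axis=1)
        frac = 1.0 - buried.sum() / n_points
        asa[i] = frac * 4.0 * np.pi * exp[k] ** 2
    return asa


def residue_rasa(residue_asa: float, residue_type: str,
                 table: dict[str, float] = GXG_REFERENCE_ASA) -> float:
    """Relative ASA: residue ASA over the Gly-X-Gly reference for its type.

    Not clamped at 1; terminal residues may exceed the extended-tripeptide
    reference.
    """
    if residue_type not in table:
        raise ValueError(f"unknown residue type {residue_type!r} (no reference ASA)")
    return residue_asa / table[residue_type]


def classify_region(rasa_u: float, rasa_c: float,
                    threshold: float = RASA_THRESHOLD,
                    delta: float = DELTA_INTERFACE,
                    tol: float = 1e-9) -> str:
    """Assign one of buried / surface / rim / core from the free and
    complexed relative accessibilities."""
    if rasa_c > rasa_u + tol:
        raise RasaInconsistencyError(
            f"rasa_c {rasa_c} exceeds rasa_u {rasa_u}: complexation cannot "
            "increase accessibility")
    rasa_c = min(rasa_c, rasa_u)
    if rasa_u < threshold:
        return "buried"
    if rasa_u - rasa_c > delta:
        return "core" if rasa_c < threshold else "rim"
    return "surface"


def interface_partition(receptor: ChainStructure, partner: ChainStructure | None,
                        probe_radius: float = DEFAULT_PROBE,
                        n_points: int = DEFAULT_N_POINTS,
                        table: dict[str, float] = GXG_REFERENCE_ASA,
                        partner_id: str = "") -> list[ResidueSurfaceProfile]:
    """Classify every receptor residue against one partner chain.

    asa_u is computed on the receptor alone, asa_c on the two-chain assembly;
    both use the identical point set so asa_c <= asa_u holds exactly.
    """
    r_coords, r_radii, _, r_owner = receptor.atom_arrays()
    asa_u_atoms = compute_asa(r_coords, r_radii, probe_radius, n_points)
    if partner is not None:
        p_coords, p_radii, _, _ = partner.atom_arrays()
        all_coords = np.vstack([r_coords, p_coords])
        all_radii = np.concatenate([r_radii, p_radii])
        asa_c_atoms = compute_asa(all_coords, all_radii, probe_radius,
                                  n_points)[: len(r_coords)]
        pid = partner_id or partner.chain_id
    else:
        asa_c_atoms = asa_u_atoms
        pid = partner_id
    profiles = []
    owner = np.asarray(r_owner)
    for i, res in enumerate(receptor.residues):
        sel = owner == i
        asa_u = float(asa_u_atoms[sel].sum())
        asa_c = float(asa_c_atoms[sel].sum())
        ru = residue_rasa(asa_u, res.amino_acid, table)
        rc = residue_rasa(asa_c, res.amino_acid, table)
        profiles.append(ResidueSurfaceProfile(
            canonical_position=res.author_number,
            amino_acid=res.amino_acid,
            asa_u=asa_u, asa_c=asa_c, rasa_u=ru, rasa_c=rc,
            region=classify_region(ru, rc), partner_id=pid))
    return profiles


@dataclass
class ConsolidatedLabels:
    """Per-residue label sets across partners plus one headline label."""
    label_sets: dict          # position -> set of labels
    headline: dict            # position -> single label
    amino_acids: dict         # position -> 1-letter code

    def region_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {"buried": 0, "surface": 0, "rim": 0, "core": 0}
        for lab in self.headline.values():
            counts[lab] += 1
        return counts


def aggregate_labels(profiles_per_partner: list[list[ResidueSurfaceProfile]]
                     ) -> ConsolidatedLabels:
    """Consolidate per-partner labels into one headline label per residue.

    A residue counts as interface core if it is core in at least one complex;
    precedence is core > rim > surface, and a residue buried in every complex
    stays buried.
    """
    if not profiles_per_partner:
        raise ValueError("need at least one profile list")
    positions = [p.canonical_position for p in profiles_per_partner[0]]
    posset = set(positions)
    label_sets: dict = {p: set() for p in positions}
    aas: dict = {}
    for plist in profiles_per_partner:
        if {p.canonical_position for p in plist} != posset:
            raise ValueError("profile lists cover different canonical positions")
        for p in plist:
            label_sets[p.canonical_position].add(p.region)
            aas[p.canonical_position] = p.amino_acid
    headline = {}
    for pos, labels in label_sets.items():
        if labels == {"buried"}:
            headline[pos] = "buried"
        else:
            headline[pos] = max(labels - {"buried"} or {"buried"},
                                key=REGION_PRECEDENCE.__getitem__)
    return ConsolidatedLabels(label_sets=label_sets, headline=headline,
                              amino_acids=aas)
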