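"""Read protein chains from PDB text, reconcile structure numbering with the
canonical (UniProt-style) sequence, and assess structural coverage.

The classification pipeline needs a per-residue coordinate model plus a
reliable mapping between the author numbering found in a structure file and
the 1-based positions of the canonical protein sequence, because variant
positions are always reported on the canonical sequence.  Coverage of the
canonical sequence by resolved residues decides whether a protein (or a
protein pair) is usable for rigid-body docking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio import Align

logger = logging.getLogger(__name__)

#: Heavy-atom van der Waals radii (Angstrom) used throughout the package.
#: Hydrogens are ignored; unknown heavy elements fall back to carbon.
VDW_RADII = {"C": 1.76, "N": 1.65, "O": 1.40, "S": 1.85}
DEFAULT_VDW_RADIUS = 1.76

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

COVERAGE_THRESHOLD = 0.8   # "greater than 80% in a single PDB file"
MIN_MAPPING_IDENTITY = 0.30


class EmptyChainError(ValueError):
    """No ATOM records found for the requested chain."""


class UnreliableMappingError(ValueError):
    """Structure-to-canonical alignment identity below the usable floor."""


@dataclass
class Atom:
    element: str
    coord: np.ndarray          # (3,) Angstrom
    vdw_radius: float          # Angstrom
    charge: float = 0.0        # partial charge, e units (0 unless assigned)
    name: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name or self.element}: vdw_radius must be > 0")


@dataclass
class Residue:
    author_number: int | str   # author seqid, with insertion code appended when present
    amino_acid: str            # 1-letter code
    atoms: list[Atom] = field(default_factory=list)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class ChainStructure:
    chain_id: str
    residues: list[Residue]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptyChainError(f"empty chain: no residues for chain {self.chain_id!r}")
        numbers = [r.author_number for r in self.residues]
        if len(numbers) != len(set(numbers)):
            raise ValueError(f"duplicate author numbers in chain {self.chain_id!r}")

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def atom_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
        """Flatten to (coords, radii, charges, residue_index_per_atom)."""
        coords, radii, charges, owner = [], [], [], []
        for i, res in enumerate(self.residues):
            for a in res.atoms:
                coords.append(a.coord)
                radii.append(a.vdw_radius)
                charges.append(a.charge)
                owner.append(i)
        return (np.asarray(coords, dtype=float), np.asarray(radii, dtype=float),
                np.asarray(charges, dtype=float), owner)


@dataclass
class ResidueNumberMap:
    """One-to-one, strictly increasing map from structure sequence positions
    (1-based along the chain) to canonical sequence positions (1-based)."""
    pairs: list[tuple[int, int]]
    unmapped_structure_positions: list[int]
    unmapped_canonical_positions: list[int]
    sequence_identity: float = 1.0

    def __post_init__(self) -> None:
        s = [p[0] for p in self.pairs]
        c = [p[1] for p in self.pairs]
        if sorted(set(s)) != s or sorted(set(c)) != c:
            raise ValueError("mapping must be one-to-one and strictly increasing")

    def to_canonical(self) -> dict[int, int]:
        return dict(self.pairs)


@dataclass
class CoverageReport:
    sequence_identity: float
    structural_coverage: float
    tier: str                  # single-file-global | domain-only | insufficient

    def __post_init__(self) -> None:
        if not (0.0 <= self.structural_coverage <= 1.0):
            raise ValueError("coverage must be in [0, 1]")


def read_structure(pdb_text: str, chain_selector: str) -> ChainStructure:
    """Parse one chain from PDB-format text.

    HETATM records and waters are excluded, hydrogens dropped, and alternate
    locations resolved to the highest-occupancy conformer (ties broken by
    altloc identifier).  Unknown residue types are skipped with a warning.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise EmptyChainError(f"empty chain: no model in PDB text")
    model = st[0]
    residues: list[Residue] = []
    for chain in model:
        if chain.name != chain_selector:
            continue
        for res in chain:
            if res.het_flag != "A":      # ATOM records only: no HETATM, no water
                continue
            aa = THREE_TO_ONE.get(res.name.strip().upper())
            if aa is None:
                logger.warning("skipping unknown residue type %s %s in chain %s",
                               res.name, res.seqid.num, chain.name)
                continue
            # resolve altlocs: per atom name keep highest occupancy
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ or (
                        atom.occ == prev.occ and atom.altloc < prev.altloc):
                    best[atom.name] = atom
            atoms = []
            for name in sorted(best):
                a = best[name]
                elem = a.element.name.upper()
                atoms.append(Atom(
                    element=elem,
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    vdw_radius=VDW_RADII.get(elem, DEFAULT_VDW_RADIUS),
                    name=name,
                ))
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            residues.append(Residue(
                author_number=f"{res.seqid.num}{icode}" if icode else res.seqid.num,
                amino_acid=aa,
                atoms=atoms,
            ))
    if not residues:
        raise EmptyChainError(f"empty chain: no ATOM records for chain {chain_selector!r}")
    return ChainStructure(chain_id=chain_selector, residues=residues,
                          source_label="pdb")


def write_pdb(*chains: ChainStructure) -> str:
    """Serialize chains back to minimal PDB-format text (ATOM records only)."""
    lines = []
    serial = 0
    for ch in chains:
        for res in ch.residues:
            num = str(res.author_number)
            icode = " "
            if num and num[-1].isalpha():
                num, icode = num[:-1], num[-1]
            for atom in res.atoms:
                serial += 1
                name = atom.name or atom.element
                pad = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {pad:<4s} {ONE_TO_THREE[res.amino_acid]:<3s} "
                    f"{ch.chain_id:1s}{int(num):4d}{icode}   "
                    f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:5d}      {ONE_TO_THREE[ch.residues[-1].amino_acid]:<3s} "
                     f"{ch.chain_id:1s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_to_canonical(structure_sequence: str, canonical_sequence: str) -> ResidueNumberMap:
    """Globally align the structure-derived sequence to the canonical one and
    return the column-wise residue number map.

    Raises :class:`UnreliableMappingError` when identity over aligned columns
    falls below 30%, which would make renumbering untrustworthy.
    """
    if not structure_sequence or not canonical_sequence:
        raise ValueError("both sequences must be non-empty")
    aln = _make_aligner().align(structure_sequence, canonical_sequence)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (s_start, s_end), (c_start, c_end) in zip(*aln.aligned):
        for k in range(s_end - s_start):
            si, ci = s_start + k, c_start + k
            pairs.append((si + 1, ci + 1))
            if structure_sequence[si] == canonical_sequence[ci]:
                matches += 1
    if not pairs:
        raise UnreliableMappingError("unreliable mapping: no aligned columns")
    identity = matches / len(pairs)
    if identity < MIN_MAPPING_IDENTITY:
        raise UnreliableMappingError(
            f"unreliable mapping: aligned identity {identity:.2f} < {MIN_MAPPING_IDENTITY}")
    mapped_s = {p[0] for p in pairs}
    mapped_c = {p[1] for p in pairs}
    return ResidueNumberMap(
        pairs=pairs,
        unmapped_structure_positions=[i + 1 for i in range(len(structure_sequence))
                                      if i + 1 not in mapped_s],
        unmapped_canonical_positions=[i + 1 for i in range(len(canonical_sequence))
                                      if i + 1 not in mapped_c],
        sequence_identity=identity,
    )


def compute_coverage(nmap: ResidueNumberMap, canonical_length: int,
                     in_single_file: bool,
                     resolved_structure_positions: set[int] | None = None,
                     domain_coverage: float | None = None) -> CoverageReport:
    """Fraction of the canonical sequence with resolved structure.

    Missing loops (structure positions without coordinates) are excluded by
    passing ``resolved_structure_positions``; by default every mapped position
    counts as resolved.  The tier follows the three-way rule: global coverage
    > 0.8 in a single file, else a qualifying domain (> 0.8), else
    insufficient.
    """
    if canonical_length <= 0:
        raise ValueError("canonical_length must be positive")
    if resolved_structure_positions is None:
        mapped = len(nmap.pairs)
    else:
        mapped = sum(1 for s, _ in nmap.pairs if s in resolved_structure_positions)
    coverage = mapped / canonical_length
    if coverage > COVERAGE_THRESHOLD and in_single_file:
        tier = "single-file-global"
    elif domain_coverage is not None and domain_coverage > COVERAGE_THRESHOLD:
        tier = "domain-only"
    else:
        tier = "insufficient"
    return CoverageReport(sequence_identity=nmap.sequence_identity,
                          structural_coverage=coverage, tier=tier)


def classify_ppi_dockability(report_a: CoverageReport, report_b: CoverageReport) -> bool:
    """A protein pair is dockable only when both partners have > 80% global
    coverage in a single structure file."""
    return (report_a.tier == "single-file-global"
            and report_b.tier == "single-file-global")
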