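"""Variant parsing, homology-derived neutral variants, and region mapping.

Disease variants come from a humsavar-style table (accession, substitution,
label).  Neutral variants are derived from a multiple sequence alignment:
every mismatch between the human sequence and a close homolog (pairwise
identity above 95%, gaps excluded) is taken as a substitution tolerated by
evolution.  Variants are then mapped onto consolidated residue region labels
to build the per-region contingency tallies, counting residues (a residue
with several variants of one category counts once).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from .enrichment_stats import RegionTally, n_minus_one_chi_square
from .sasa_regions import ConsolidatedLabels
from .structure_model import THREE_TO_ONE

logger = logging.getLogger(__name__)

STOP = "*"
AA1 = set("ACDEFGHIKLMNPQRSTVWY")

_SHORT_RE = re.compile(r"^([A-Z])(\d+)([A-Z]|\*)$")
_LONG_RE = re.compile(r"^(?:p\.)?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|Ter|\*)$")

_LABEL_MAP = {"disease": "disease", "neutral": "neutral"}
_DROP_LABELS = {"polymorphism", "unclassified"}


class ReferenceMismatchError(ValueError):
    """Variant reference residues disagree with the canonical sequence."""


@dataclass(frozen=True)
class VariantRecord:
    accession: str
    position: int
    ref_aa: str
    alt: str                  # 1-letter code or "*" for a stop codon
    category: str             # disease | neutral
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.ref_aa == self.alt:
            raise ValueError("reference and alternate residues must differ")
        if self.alt == STOP and self.category != "disease":
            raise ValueError("stop-codon (nonsense) variants are disease-only")


def parse_substitution(text: str) -> tuple[str, int, str]:
    """Parse 'Q358K', 'R399*', 'p.Gln358Lys' or 'p.Arg399Ter' into
    (ref, position, alt) with 1-letter codes and '*' for stop."""
    text = text.strip()
    m = _SHORT_RE.match(text)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if ref not in AA1 or (alt not in AA1 and alt != STOP):
            raise ValueError(f"unknown amino acid code in {text!r}")
        return ref, pos, alt
    m = _LONG_RE.match(text)
    if m:
        three_to_one = {k.capitalize(): v for k, v in THREE_TO_ONE.items()}
        ref = three_to_one.get(m.group(1))
        alt_tok = m.group(3)
        alt = STOP if alt_tok in ("Ter", "*") else three_to_one.get(alt_tok)
        if ref is None or alt is None:
            raise ValueError(f"unknown amino acid code in {text!r}")
        return ref, int(m.group(2)), alt
    raise ValueError(f"unparsable substitution {text!r}")


def parse_variants(rows, canonical_sequences: dict[str, str] | None = None,
                   ) -> tuple[list[VariantRecord], list[tuple[str, str]]]:
    """Parse humsavar-like rows into variant records.

    ``rows`` may be a DataFrame with columns accession/variant/label or an
    iterable of (accession, variant, label) tuples.  Rows labelled
    Polymorphism or Unclassified are dropped; rows that cannot be parsed are
    rejected with a logged reason and returned in the second element.  If
    canonical sequences are supplied, variants whose reference residue
    disagrees with the sequence raise :class:`ReferenceMismatchError`.
    """
    if isinstance(rows, pd.DataFrame):
        it = rows[["accession", "variant", "label"]].itertuples(index=False)
    else:
        it = rows
    records: list[VariantRecord] = []
    rejected: list[tuple[str, str]] = []
    mismatches: list[str] = []
    for acc, var, label in it:
        lab = str(label).strip().lower()
        if lab in _DROP_LABELS:
            continue
        category = _LABEL_MAP.get(lab)
        if category is None:
            rejected.append((var, f"unknown label {label!r}"))
            logger.warning("rejected %s: unknown label %r", var, label)
            continue
        try:
            ref, pos, alt = parse_substitution(str(var))
            if ref == alt:
                raise ValueError("reference equals alternate")
            rec = VariantRecord(accession=str(acc), position=pos, ref_aa=ref,
                                alt=alt, category=category, source_tag="table")
        except ValueError as exc:
            rejected.append((str(var), str(exc)))
            logger.warning("rejected %s: %s", var, exc)
            continue
        if canonical_sequences is not None and rec.accession in canonical_sequences:
            seq = canonical_sequences[rec.accession]
            if rec.position > len(seq) or seq[rec.position - 1] != rec.ref_aa:
                mismatches.append(f"{rec.accession}:{var} at position {rec.position}")
                continue
        records.append(rec)
    if mismatches:
        raise ReferenceMismatchError(
            "reference mismatch against canonical sequence: " + ", ".join(mismatches))
    return records, rejected


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Identity over aligned columns where neither sequence has a gap."""
    matches = total = 0
    for a, b in zip(seq_a, seq_b):
        if a == "-" or b == "-":
            continue
        total += 1
        if a == b:
            matches += 1
    return matches / total if total else 0.0


def derive_neutral_variants(msa: dict[str, str], human_id: str,
                            identity_threshold: float = 0.95
                            ) -> list[VariantRecord]:
    """Neutral variants from close homologs in an aligned FASTA.

    For each homolog with pairwise identity to the human sequence strictly
    above the threshold (gap columns excluded from both numerator and
    denominator), every aligned mismatch becomes one neutral record at the
    human sequence position; duplicates across homologs are collapsed.
    Output order is independent of homolog order in the alignment.
    """
    if human_id not in msa:
        raise ValueError(f"human sequence {human_id!r} absent from alignment")
    human = msa[human_id]
    seen: set[tuple[int, str, str]] = set()
    for hid, hom in msa.items():
        if hid == human_id:
            continue
        if len(hom) != len(human):
            raise ValueError(f"{hid!r}: aligned length differs from human")
        if pairwise_identity(human, hom) <= identity_threshold:
            continue
        pos = 0
        for a, b in zip(human, hom):
            if a != "-":
                pos += 1
            if a == "-" or b == "-":
                continue
            if a != b and b in AA1:
                seen.add((pos, a, b))
    return [VariantRecord(accession=human_id, position=p, ref_aa=r, alt=alt,
                          category="neutral", source_tag="homology")
            for p, r, alt in sorted(seen)]


REGION_ORDER = ["buried", "surface", "rim", "core"]


def map_variants_to_regions(variants: list[VariantRecord],
                            labels: ConsolidatedLabels | dict,
                            ) -> tuple[dict[str, list[RegionTally]], list[VariantRecord]]:
    """Tabulate variant-bearing residues per region and category.

    The counting unit is the residue: a residue with one or more variants of
    a category contributes one to that category's tally in its headline
    region; a residue mutated in both categories counts in both.  Variants at
    positions without a label (no structural coverage) are returned in the
    side list.
    """
    headline = labels.headline if isinstance(labels, ConsolidatedLabels) else labels
    unmapped: list[VariantRecord] = []
    hit: dict[str, set] = {"disease": set(), "neutral": set()}
    for v in variants:
        if v.position not in headline:
            unmapped.append(v)
        else:
            hit[v.category].add(v.position)
    totals: dict[str, int] = {r: 0 for r in REGION_ORDER}
    for lab in headline.values():
        totals[lab] += 1
    tallies = {}
    for category in ("disease", "neutral"):
        observed = {r: 0 for r in REGION_ORDER}
        for pos in hit[category]:
            observed[headline[pos]] += 1
        tallies[category] = [RegionTally(r, totals[r], observed[r])
                             for r in REGION_ORDER]
    return tallies, unmapped


def substitution_susceptibility(interface_variants: list[VariantRecord],
                                interface_composition: dict[str, int],
                                amino_acids: dict | None = None) -> pd.DataFrame:
    """Per amino-acid type susceptibility to mutation within interfaces.

    For each residue type: the fraction of interface residues of that type
    carrying at least one disease (resp. neutral) variant, and the "N-1"
    chi-squared p-value comparing the two proportions.  Types absent from the
    interface are omitted.  ``amino_acids`` optionally maps positions to
    types for validation; variant ref_aa is used otherwise.
    """
    rows = []
    mutated: dict[str, dict[str, set]] = {
        "disease": {}, "neutral": {}}
    for v in interface_variants:
        aa = amino_acids.get(v.position, v.ref_aa) if amino_acids else v.ref_aa
        mutated[v.category].setdefault(aa, set()).add(v.position)
    for aa in sorted(interface_composition):
        n_type = interface_composition[aa]
        if n_type == 0:
            continue
        d = len(mutated["disease"].get(aa, set()))
        u = len(mutated["neutral"].get(aa, set()))
        p = n_minus_one_chi_square(d, n_type - d, u, n_type - u)
        rows.append({"amino_acid": aa, "interface_residues": n_type,
                     "disease_mutated": d, "neutral_mutated": u,
                     "disease_fraction": d / n_type,
                     "neutral_fraction": u / n_type,
                     "p_value": p})
    return pd.DataFrame(rows)
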