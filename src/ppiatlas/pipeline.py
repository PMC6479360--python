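"""End-to-end orchestration: structures + variants -> region/enrichment
reports, and pose ensembles -> NIP-based interface predictions.

The report shapes mirror the study design: a region table (region, residue
total, observed variant-bearing residues, expected under proportional
allocation, O/E) and an enrichment table with seven region-pair odds ratios
per variant category (buried vs surface, core vs buried, core vs rim, core
vs surface, rim vs surface, rim vs buried, interface vs surface), each with
a Woolf 95% CI, a two-tailed Fisher exact p and its Bonferroni adjustment.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import docking_nip as dn
from . import enrichment_stats as es
from . import sasa_regions as sr
from . import structure_model as sm
from . import variant_atlas as va

logger = logging.getLogger(__name__)

#: The seven region comparisons reported per category; "interface" pools
#: rim and core.
REGION_PAIRS = [
    ("buried", "surface"),
    ("core", "buried"),
    ("core", "rim"),
    ("core", "surface"),
    ("rim", "surface"),
    ("rim", "buried"),
    ("interface", "surface"),
]


@dataclass
class Thresholds:
    rasa: float = 0.1
    nip: float = 0.1
    rim_distance: float = 10.0
    low_energy: float = -2.0
    coverage: float = 0.8
    identity: float = 0.95
    contact_cutoff: float = 5.0
    n_top: int = 100


@dataclass
class PipelineConfig:
    structures: list = field(default_factory=list)   # {pdb, receptor_chain, partner_chain}
    variants: str | None = None                      # TSV path
    receptor_pdb: str | None = None
    ensembles: list = field(default_factory=list)    # {partner_id, ligand_pdb, poses}
    thresholds: Thresholds = field(default_factory=Thresholds)
    bonferroni_m: int = len(REGION_PAIRS)
    seed: int = 0
    outdir: str = "."

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        thr = Thresholds(**d.pop("thresholds", {}))
        return cls(thresholds=thr, **d)


def _with_interface(tallies: list[es.RegionTally]) -> dict[str, es.RegionTally]:
    by_name = {t.region_name: t for t in tallies}
    rim, core = by_name["rim"], by_name["core"]
    by_name["interface"] = es.RegionTally("interface", rim.N_i + core.N_i,
                                          rim.n_i + core.n_i)
    return by_name


def region_table(tallies_by_category: dict[str, list[es.RegionTally]]) -> pd.DataFrame:
    """The Region / All Residues / Observed / Expected / O-E table, one block
    per variant category."""
    rows = []
    for category, tallies in tallies_by_category.items():
        expected = es.expected_counts(tallies)
        for t, (_, exp, oe) in zip(tallies, expected):
            rows.append({"category": category, "region": t.region_name,
                         "all_residues": t.N_i, "observed": t.n_i,
                         "expected": round(exp, 2),
                         "o_over_e": round(oe, 2) if oe is not None else None})
    return pd.DataFrame(rows)


def enrichment_report(tallies_by_category: dict[str, list[es.RegionTally]],
                      m: int | None = None) -> pd.DataFrame:
    """Seven odds-ratio rows per category, Bonferroni-adjusted within each
    category (m defaults to the number of comparisons)."""
    rows = []
    for category, tallies in tallies_by_category.items():
        by_name = _with_interface(tallies)
        results = []
        for ri, rj in REGION_PAIRS:
            ti, tj = by_name[ri], by_name[rj]
            if ti.N_i == 0 or tj.N_i == 0 or (ti.n_i == 0 and tj.n_i == 0):
                results.append(None)
                continue
            results.append(es.odds_ratio(ti, tj))
        mm = m if m is not None else len(REGION_PAIRS)
        adjusted = es.bonferroni([r.p_value for r in results if r is not None], mm)
        ai = iter(adjusted)
        for (ri, rj), r in zip(REGION_PAIRS, results):
            if r is None:
                rows.append({"category": category,
                             "comparison": f"{ri.capitalize()} versus {rj.capitalize()}",
                             "odds_ratio": None, "ci_low": None, "ci_high": None,
                             "p_value": None, "p_adjusted": None,
                             "flags": "undefined"})
                continue
            r.p_adjusted = next(ai)
            rows.append({"category": category,
                         "comparison": f"{ri.capitalize()} versus {rj.capitalize()}",
                         "odds_ratio": round(r.odds_ratio, 2),
                         "ci_low": round(r.ci_low, 2),
                         "ci_high": round(r.ci_high, 2),
                         "p_value": es.format_p(r.p_value),
                         "p_adjusted": es.format_p(r.p_adjusted),
                         "flags": ";".join(r.flags)})
    return pd.DataFrame(rows)


def structural_atlas_report(labels: sr.ConsolidatedLabels,
                            variants: list[va.VariantRecord],
                            m: int | None = None) -> dict[str, pd.DataFrame]:
    """Region tallies, enrichment statistics and substitution susceptibility
    from consolidated labels and a variant list."""
    tallies, unmapped = va.map_variants_to_regions(variants, labels)
    for v in unmapped:
        logger.info("variant %s%d%s outside structural coverage (dropped)",
                    v.ref_aa, v.position, v.alt)
    interface_positions = {p for p, lab in labels.headline.items()
                           if lab in ("rim", "core")}
    composition: dict[str, int] = {}
    for p in interface_positions:
        aa = labels.amino_acids.get(p, "A")
        composition[aa] = composition.get(aa, 0) + 1
    iface_variants = [v for v in variants if v.position in interface_positions]
    return {
        "regions": region_table(tallies),
        "enrichment": enrichment_report(tallies, m),
        "susceptibility": va.substitution_susceptibility(
            iface_variants, composition, labels.amino_acids),
        "unmapped": pd.DataFrame(
            [{"accession": v.accession, "position": v.position,
              "variant": f"{v.ref_aa}{v.position}{v.alt}",
              "category": v.category} for v in unmapped]),
    }


def read_variants_tsv(path: str | Path) -> list[va.VariantRecord]:
    df = pd.read_csv(path, sep="\t")
    records, rejected = va.parse_variants(df)
    for var, reason in rejected:
        logger.warning("dropped variant row %s: %s", var, reason)
    return records


def run_structural_atlas(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """File-driven Table-1-style analysis: classify every structure entry's
    receptor chain against its partner, consolidate labels, map variants,
    and write the reports to the output directory."""
    if not config.structures or config.variants is None:
        raise FileNotFoundError("config must name structure entries and a variant file")
    profile_lists = []
    for entry in config.structures:
        pdb_path = Path(entry["pdb"])
        if not pdb_path.exists():
            raise FileNotFoundError(f"structure file not found: {pdb_path}")
        text = pdb_path.read_text()
        receptor = sm.read_structure(text, entry["receptor_chain"])
        partner = sm.read_structure(text, entry["partner_chain"])
        profile_lists.append(sr.interface_partition(
            receptor, partner, partner_id=entry.get("partner_id",
                                                    entry["partner_chain"])))
    labels = sr.aggregate_labels(profile_lists)
    variants = read_variants_tsv(config.variants)
    reports = structural_atlas_report(labels, variants, config.bonferroni_m)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in reports.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.6g")
    return reports


def _fmt_variants(variants: list[va.VariantRecord], residues: frozenset) -> str:
    hits = sorted({(v.position, v.ref_aa, v.alt) for v in variants
                   if v.position in residues})
    return ", ".join(f"{r}{p}{a}" for p, r, a in hits) if hits else "-"


def docking_prediction_report(receptor: sm.ChainStructure,
                              partner_ensembles: dict[str, list[dn.Pose]],
                              ligands: dict[str, sm.ChainStructure],
                              variants: list[va.VariantRecord],
                              thresholds: Thresholds | None = None
                              ) -> pd.DataFrame:
    """Per-partner predicted core/rim and the variants falling in each, in
    the four-column layout (neutral core/rim, pathogenic core/rim); empty
    cells print as '-'."""
    thr = thresholds or Thresholds()
    free_profiles = sr.interface_partition(receptor, None)
    surface = frozenset(p.canonical_position for p in free_profiles
                        if p.rasa_u >= thr.rasa)
    neutral = [v for v in variants if v.category == "neutral"]
    disease = [v for v in variants if v.category == "disease"]
    rows = []
    for partner_id in sorted(partner_ensembles):
        poses = partner_ensembles[partner_id]
        if len(poses) < thr.n_top:
            raise ValueError(f"ensemble for {partner_id} smaller than "
                             f"n_top={thr.n_top}")
        dn.annotate_interfaces(poses, receptor, ligands[partner_id],
                               thr.contact_cutoff)
        profile = dn.compute_nip(poses, thr.n_top, surface)
        core = dn.predicted_core(profile, thr.nip)
        rim = dn.predicted_rim(core, receptor, surface, thr.rim_distance)
        rows.append({
            "partner": partner_id,
            "neutral_core": _fmt_variants(neutral, core),
            "neutral_rim": _fmt_variants(neutral, rim),
            "pathogenic_core": _fmt_variants(disease, core),
            "pathogenic_rim": _fmt_variants(disease, rim),
            "n_core": len(core), "n_rim": len(rim),
        })
    return pd.DataFrame(rows)


def run_docking_prediction(config: PipelineConfig) -> pd.DataFrame:
    """File-driven Table-3-style analysis from a receptor PDB, per-partner
    ligand PDBs + pose ensembles, and a variant TSV."""
    if config.receptor_pdb is None or not config.ensembles:
        raise FileNotFoundError("config must name a receptor PDB and pose ensembles")
    receptor = sm.read_structure(Path(config.receptor_pdb).read_text(), "A")
    ensembles, ligands = {}, {}
    for entry in config.ensembles:
        pid = entry["partner_id"]
        ensembles[pid] = dn.read_pose_ensemble(Path(entry["poses"]).read_text())
        ligands[pid] = sm.read_structure(Path(entry["ligand_pdb"]).read_text(), "B")
    variants = read_variants_tsv(config.variants) if config.variants else []
    report = docking_prediction_report(receptor, ensembles, ligands, variants,
                                       config.thresholds)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_csv(outdir / "docking_prediction.tsv", sep="\t", index=False)
    return report
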