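"""Variant enrichment across protein regions from published residue tallies.

Feeds the published per-region counts (residues with pathogenic or neutral
single amino acid variants, out of all residues per region) through the
odds-ratio report.

Run:  python examples/02_variant_enrichment.py
"""

from ppiatlas import enrichment_stats as es
from ppiatlas import pipeline as pl

tallies = {
    "disease": [es.RegionTally("buried", 6019, 1842),
                es.RegionTally("surface", 3118, 552),
                es.RegionTally("rim", 916, 151),
                es.RegionTally("core", 1146, 337)],
    "neutral": [es.RegionTally("buried", 6019, 524),
                es.RegionTally("surface", 3118, 767),
                es.RegionTally("rim", 916, 178),
                es.RegionTally("core", 1146, 83)],
}

print("Observed versus expected counts per region:")
print(pl.region_table(tallies).to_string(index=False))

print("\nOdds ratios (Woolf 95% CI, Fisher exact p, Bonferroni m=7):")
print(pl.enrichment_report(tallies).to_string(index=False))
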