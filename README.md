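# ppiatlas

Tools for studying where disease-related missense variants sit on protein
structures, with a focus on protein–protein interfaces.

Pathogenic single amino acid variants (SAVs) are not spread uniformly over a
protein: they concentrate in the hydrophobic interior and, on the surface, in
the patches where the protein binds its partners. `ppiatlas` implements the
full analysis chain needed to quantify that picture:

1. **Region classification** (`sasa_regions`): every residue is assigned to
   one of four structural regions from its relative accessible surface area
   (rASA) computed alone (`rasa_u`) and in the complex (`rasa_c`):
   *buried* (rASA&lt;0.1 alone), *surface*, *interface rim* (loses area on
   binding, stays partly exposed) and *interface core* (exposed alone,
   buried in the complex).
2. **Variant mapping** (`variant_atlas`): parses pathogenic variant lists
   (`Q358K`, `p.Gln358Lys`, nonsense forms), derives putatively neutral
   variants from close homologs (≥ 95% identity), and tallies, per region,
   how many residues carry a variant.
3. **Enrichment statistics** (`enrichment_stats`): odds ratios between
   regions with Woolf 95% confidence intervals, Fisher exact tests,
   Bonferroni correction, expected counts under proportional allocation and
   chi-square goodness of fit.
4. **Docking-based interface prediction** (`docking_nip`): when no complex
   structure exists, rigid-body docking pose ensembles are scored with a
   simplified electrostatics + van der Waals + desolvation model; the
   normalized interface propensity (NIP) of a residue over the 100
   lowest-energy poses predicts the interface core (NIP ≥ 0.1), and
   per-residue energies below −2 a.u. flag hot-spot candidates.
5. **Synthetic ground truth** (`synthetic_data`): seeded generators for toy
   two-chain complexes with a known contact face, planted variant
   enrichments with a known odds ratio, and docking ensembles with known
   near-native poses — the test bed for every statistical claim above.
6. **Pipeline and CLI** (`pipeline`, `ppiatlas` command): file-driven runs
   producing deterministic TSV reports.

## Worked example

Feed per-region tallies (residues carrying a variant, out of all residues in
the region) through the enrichment report:

```python
from ppiatlas import enrichment_stats as es
from ppiatlas import pipeline as pl

tallies = {
    "disease": [es.RegionTally("buried", 6019, 1842),
                es.RegionTally("surface", 3118, 552),
                es.RegionTally("rim", 916, 151),
                es.RegionTally("core", 1146, 337)],
}
print(pl.enrichment_report(tallies).to_string(index=False))
```

```
category               comparison  odds_ratio  ci_low  ci_high     p_value  p_adjusted flags
 disease    Buried versus Surface        2.05    1.84     2.28      <1e-12      <1e-12
 disease       Core versus Buried        0.94    0.82     1.08    0.440919           1
 disease          Core versus Rim        2.11    1.70     2.62 4.71609e-12 3.30127e-11
 disease      Core versus Surface        1.94    1.66     2.27      <1e-12      <1e-12
 disease       Rim versus Surface        0.92    0.75     1.12     0.42799           1
 disease        Rim versus Buried        0.45    0.37     0.54      <1e-12      <1e-12
 disease Interface versus Surface        1.44    1.26     1.65 1.86081e-07 1.30257e-06
```

Disease variants are about twice as likely at the interface core as at the
rim (OR 2.11) or the non-interacting surface (OR 1.94), while the rim
behaves like ordinary surface (OR 0.92).

The scripts in `examples/` walk through the other stages:

- `examples/01_interface_regions.py` — build a synthetic complex and
  classify its residues by rASA; the SASA-based call agrees with the
  generator's planted interface at Jaccard ≈ 0.90.
- `examples/02_variant_enrichment.py` — the full observed/expected table and
  both variant categories.
- `examples/03_docking_nip.py` — a 1000-pose docking ensemble, NIP-based
  core prediction (precision 0.95 against the planted interface) and a
  per-partner report placing variants on the predicted core/rim.

The same stages are available from the command line:

```bash
ppiatlas synth --seed 3 --out fixtures/          # complex.pdb, variants.tsv, poses.tsv
ppiatlas stats --tallies tallies.tsv --out enrichment.tsv
ppiatlas atlas --config config.yaml --out out/   # structures + variants -> reports
ppiatlas nip   --config config.yaml --out out/   # pose ensembles -> interface report
```

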