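# Methods

This note records the models, parameter choices and numerical conventions
used throughout `ppiatlas`, and what the synthetic generators do and do not
emulate.

## Structure model

PDB text is parsed with gemmi. Only ATOM records of standard amino acids
are kept: HETATM records, waters, hydrogens and unknown residue types are
dropped (unknowns with a logged warning). Alternate locations are resolved
per atom name to the highest-occupancy conformer, ties broken by altloc
letter. Residues carry their author numbering; an insertion code makes the
number a string.

Structure positions are reconciled with canonical (e.g. UniProt) numbering
by global pairwise alignment (match +1, mismatch −1, gap open −5, extend
−1, via Biopython's PairwiseAligner). Mappings below 30% sequence identity
are refused as unreliable. A structure "covers" a protein when ≥ 80% of the
canonical sequence is resolved; an interaction is considered dockable when
both partners meet that bar in a single file.

## Solvent accessibility and regions

Accessible surface area (ASA) uses a deterministic Shrake–Rupley-style
scheme: each atom's solvent-expanded sphere (van der Waals radius + 1.4 Å
probe) is sampled at 960 golden-spiral points; the exposed fraction times
the sphere area is the atom ASA. Van der Waals radii: C 1.76, N 1.65,
O 1.40, S 1.85 Å. The fixed point set makes results exactly reproducible
and guarantees that a residue's ASA in the complex never exceeds its ASA
alone (the same points are occluded by a superset of spheres).

Relative ASA (rASA) divides the residue ASA by the residue type's reference
ASA in an extended Gly-X-Gly peptide. Regions:

- **buried**: rASA (unbound) < 0.1;
- **interface**: rASA_u − rASA_c > δ (δ = 1e-6), i.e. any area lost to the
  partner; **core** if rASA_c < 0.1, **rim** otherwise;
- **surface**: the rest.

When a protein appears in several complexes, labels are consolidated:
buried only if buried everywhere, otherwise core > rim > surface by
precedence.

## Variants

Pathogenic and neutral single amino acid variants are parsed from one-letter
(`Q358K`, `R399*`) or three-letter (`p.Gln358Lys`, `p.Arg399Ter`) forms.
Synonymous records are rejected; nonsense variants are accepted for the
disease category only. Putatively neutral variants are derived from
homologs aligned at > 95% identity (gap columns excluded from the identity
computation): every column where a close homolog differs from the human
sequence yields one neutral substitution. The counting unit everywhere is
the residue — a residue carrying two distinct variants counts once per
category.

## Enrichment statistics

For region *i* with N_i residues of which n_i carry a variant,
x_i = n_i/N_i, and the odds ratio between regions is
OR_ij = [x_i/(1−x_i)] / [x_j/(1−x_j)]. Confidence intervals are Woolf
(normal approximation on the log odds ratio); zero cells get the Haldane
0.5 correction and a flag; p-values are two-tailed Fisher exact tests,
Bonferroni-corrected with m = 7 (the seven region pairs reported per
category; configurable). Expected counts under proportional allocation are
expected_i = (Σn)·N_i/(ΣN). Substitution-type contrasts between categories
use the "N−1" chi-square (Pearson statistic scaled by (N−1)/N, df 1),
which behaves better than Pearson at small counts.

## Docking and NIP

Poses are rigid-body transforms of the ligand chain. The scoring function
is a simplified pyDock-style sum of:

- Coulomb electrostatics with distance-dependent dielectric ε = 4r,
  truncated to ±1 a.u. per atom pair;
- 6-12 Lennard-Jones (rmin = sum of vdW radii, well depth 0.2, repulsion
  capped at +1) weighted by 0.1;
- desolvation as atomic solvation parameter × buried ASA (C −0.015,
  N/O +0.005, S −0.010).

The total decomposes exactly into per-receptor-residue contributions
(ligand-atom desolvation is attributed to the nearest receptor residue), so
per-residue energies sum to the pose score to machine precision. Residues
below −2 a.u. are hot-spot candidates.

NIP for residue *i* over the 100 lowest-energy poses with interface
appearance frequency f_i is (f_i − f_rand)/(1 − f_rand), where f_rand is
the mean interface coverage over those poses. Predicted core: NIP ≥ 0.1
(inclusive). Predicted rim: surface residues with any heavy atom within
10 Å of a core residue. Pose interfaces use a 5 Å heavy-atom contact
cutoff.

## Synthetic generators

The toy complex is two compact cubic-lattice globules (3.5 Å spacing,
single 1.9 Å sphere per residue, 0.15 Å coordinate jitter) with flat faces
meeting across a 4 Å gap; the three closest cross-chain residue pairs get
±1 charges so the true pose is energetically favorable. Ground-truth
regions come from construction geometry (interior coordination number,
distance to the partner against the 6.6 Å sphere-occlusion distance), and
agree with the SASA-based classification at Jaccard ≈ 0.9. Pose ensembles
mix near-native poses (small rotations/translations, scores ~N(−20, 2))
with random decoys (scores ~N(−5, 3)).

These fixtures emulate the *shape* of the real analyses — a contact patch,
planted per-region variant rates with a known implied odds ratio, an
ensemble whose top poses concentrate at the true interface. They do not
emulate real protein chemistry: no backbone, side chains, secondary
structure, realistic energetics or real variant databases. Problem sizes
(120 residues per chain, 1000-pose ensembles, 2000-residue statistical
fixtures) were chosen so the full suite runs in well under a minute of CPU
per property while keeping sampling noise far below the tested tolerances.

## Numerical conventions

- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator takes an explicit seed and is byte-reproducible.
- Pose ensemble TSVs store rotations/translations/scores at 8 decimals and
  round-trip byte-identically; rotation orthonormality is checked at a
  tolerance admitting that text round trip (1e-6).
- Reported tables round odds ratios, CIs and expected counts to 2 decimals;
  p-values floor at 1e-12 and print as `<1e-12` below that.

## Limitations

- The SASA sampler is exact only in the sampling limit; with 960 points it
  is within ~2% of converged values, which bounds how sharp the 0.1 rASA
  boundary can be in edge cases.
- The energy model is a caricature: adequate for ranking planted poses and
  exercising the statistics, not for real affinity prediction.
- Neutral variants derived from homologs inherit the usual caveat that
  fixation in another species does not guarantee neutrality in human.
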