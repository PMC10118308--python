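# quatfun

Does a homodimer's quaternary structure contribute to its biochemical
function?  `quatfun` implements the full decision pipeline as a tested,
reusable Python package:

1. **structure_annotation** — parse biounit PDB files; annotate every
   residue as *interface* (inter-chain contact under a probe-augmented van
   der Waals criterion, probe 0.25 Å), *ligand-binding* (SASA change upon
   ligand removal, Shrake–Rupley at probe 0.21 Å) or *solvent-accessible
   surface* (RSA > 0.2 against a Gly-X-Gly reference); classify binding
   sites as multichain (MBS) or single-chain (SBS); compute interface size
   and mean ligand–interface distance.
2. **coevolution** — load pairwise evolutionary-coupling scores (`i,j,cn`
   CSV) and compute three standardized statistics, each
   `(mean_focus − mean_reference) / SD_reference` with a two-sided
   Mann–Whitney p-value: cross-interface Z (optionally Yeo–Johnson
   transformed, λ fitted per protein on the reference distribution),
   ligand–interface Z, and LBR–LBR Z; Neff/L ≥ 1 quality filter; best
   ligand selection (MBS ligands only in MBS complexes).
3. **conservation** — interface-conservation delta
   (mean surface − mean interface score, ConSurf convention) with rank-sum
   significance.
4. **dynamics** — Cα anisotropic elastic network model (15 Å cutoff,
   uniform springs), dynamic cross-correlation matrix over all non-rigid
   modes, and the coupling–dynamics R²: per interface residue, mean
   coupling to the ligand-binding residues vs mean motional correlation
   with them.  *Divergence from the original protocol:* the all-atom
   rotation–translation-block NMA is replaced by the Cα network model;
   cutoff and spring constant are configurable, and validation is
   property-based (mode counts, analytic limits, synthetic recovery).
5. **classification** — per-complex scorecards; non-functionality flags
   per method (negative or non-significant statistic after
   Benjamini–Hochberg, gated on significant LBR–LBR coevolution;
   complexes with < 40 interface residues excluded; strata at 100);
   Venn overlaps with simulated random expectations; type-III ANCOVA with
   backwards elimination; test of proportions.
6. **variants** — amino-acid composition of regions vs missense-variant
   alternate alleles, slope-vs-one F test, enrichment ratios (cysteine
   excess).
7. **fva** — flux variability analysis on small JSON metabolic models with
   GPR-based gene knockouts; a reaction is *affected* when its maximum
   absolute flux drops by > 50 %, *blocked* below 1e-6.
8. **synthetic_data** — generators for all inputs with planted,
   parameterized ground truth: toy dimers (planted interface, MBS/SBS
   ligands), coupling tables with effect sizes in baseline-SD units,
   conservation shifts, variant spectra, toy metabolic networks, and full
   cohorts with functional/gratuitous truth labels.
9. **pipeline** — orchestration over a directory of complex bundles with
   per-complex failure isolation and reproducibility metadata.

## CLI

```bash
# generate a synthetic cohort with planted ground truth
quatfun synth cohort --n-mbs 10 --n-sbs 10 --effects strong --seed 42 --out cohort/

# run the full pipeline (scorecards, flags, overlap report)
quatfun run --in cohort/ --out report/

# individual stages
quatfun annotate --pdb cohort/sbs_000/structure.pdb \
    --rsa-reference cohort/sbs_000/rsa_reference.json --out ann.tsv
quatfun coevo --bundle cohort/sbs_000 --statistic ligand
quatfun dccm --pdb cohort/sbs_000/structure.pdb --cutoff 15 --out dccm.csv
quatfun classify --scorecards report/scorecards.tsv --stratum lt100 \
    --complex-class SBS --reps 1000 --seed 7
```

A complex bundle directory contains `structure.pdb`, `couplings.csv`
(columns `i,j,cn`, 1-based positions), `alignment_stats.json`
(`{"neff": ..., "L": ...}`), `conservation.tsv` (`chain`, `resnum`,
`score`), optional `variants.tsv` (`position`, `ref`, `alt`) and optional
`rsa_reference.json` (per-amino-acid reference SASA; the shipped
Gly-X-Gly table is used otherwise).

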