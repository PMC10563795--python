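# precevo

Multi-region precancer evolution toolkit: an integrative analysis pipeline for
microdissected precursor-lesion cohorts, plus a synthetic cohort simulator
with full ground truth.

The pipeline harmonizes per-region somatic calls from three variant callers
(two-or-more consensus with a union fallback, targeted rescue at driver
hotspots and patient-shared sites, population-AF and indel-depth filters),
calls copy-number events by overlaying allelic-imbalance and log-ratio
segmentations (focal < 3 Mb, arm-level aneuploidy score at the 75%-of-arm
rule, 1q-amplification flags, gene annotation), infers per-patient clonal
trajectories from both SNVs (CCF clustering + containment trees) and CNAs
(exhaustive unit-cost small parsimony over arm states), classifies each
patient as linear / branched / unclassifiable, assigns transcriptomic
subtypes to expression replicates by nearest-template prediction with
permutation FDR, and tests subtype × 1q association with an exact 2×2 test.

Because the real cohort is controlled-access, the `synthetic` module
generates desk-scale cohorts (2–5 regions per patient, ~400× depth, truncal
KRAS/GNAS-style hotspots, subclonal SNVs, arm-scale and focal CNAs, three
emulated callers with distinct sensitivity/false-positive profiles, and
template-derived expression replicates) together with ground truth, so every
stage is testable end to end.

## Command line

```sh
# simulate a 4-patient cohort (use --noiseless for the exact-recovery regime)
precevo simulate --out cohort/ --seed 1 --patients 4

# run the full pipeline: variants -> CNA -> trees -> subtype -> stats
precevo run-all --cohort cohort/ --out report/ --seed 1

# individual stages
precevo variants --vcf-dir cohort/patients/P01/P01_LG
precevo cna --ai ai.tsv --seg logr.seg
precevo stats --table 18,16,3,15
```

`run-all` writes `report/report.json` (per-region burden, aneuploidy score,
1q flag, subtype; per-patient topology labels; cohort tables and tests) and
`report/regions.tsv`.

## Cohort directory layout

```
cohort/
  manifest.json             patients, regions, grades, purities, file map
  truth.json                simulated ground truth (clone trees, labels)
  arms.tsv  genes.tsv       coordinate resources (toy genome by default)
  templates/*.tsv           subtype template sets (gene, class, weight)
  expression/counts.tsv     gene x replicate counts
  patients/<P>/<R>/         M2.vcf SC.vcf MU.vcf ai.tsv logr.seg
```

VCFs are uncompressed VCF v4.2 with INFO keys `VT`, `POPAF`, `PRED7`
(7-predictor bitmask), `CLNSIG`, `FUNC`, `GENE`.

## Notable conventions

- Coordinates are 1-based inclusive throughout.
- CNA calls are gated on allelic imbalance; balanced amplifications are
  invisible by construction.
- The aneuploidy score counts arms whose union of CNA bases (any direction)
  covers ≥ 75% of the arm.
- Mutation burden counts exonic/splicing variants per captured Mb; rescued
  variants are excluded by default (auditable via a flag).
- The packaged toy genome (4 chromosomes, 400 Mb) keeps tests fast; an
  hg19-like arm table ships alongside (`ArmTable.hg19()`).
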