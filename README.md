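# polq-scars

Two bespoke analyses of DNA double-strand-break repair outcomes in one tested
package:

1. **Junction arm** — an amplicon-sequencing pipeline for end-joining scars:
   read merging, affine-gap alignment with indel left-alignment, four-way read
   classification (deletion-only / insertion-only / deletion-and-insertion /
   soft-clipped), event grouping with supporting-read counts, Poisson
   background filtering, deletion-microhomology measurement with a
   TMEJ-signature flag (3–6 bp MH by default), and templated-insertion origin
   classification (distant / nearby / snapback / direct-repeat / random for
   5–15 bp; template / snapback / undetermined for shorter ones) with
   MH-initiated / MH-ended calls.
2. **Cohort arm** — mutational-signature enrichment testing: SBS96 / ID83
   channel catalogs, per-sample catalogs from variant tables, stratification
   of samples by gene mutation status (frameshift / nonsense calls) and
   expression tertile, two-sided rank-sum contrasts of signature exposures
   between strata with Bonferroni adjustment, and Pearson signature
   correlations.

Both arms ship first-class simulators (`polq_scars.readsim`,
`polq_scars.cohort_sim`) that emit data with known planted truth; every
planted event is self-verified against the classifiers before emission, so the
whole pipeline is testable offline with no external downloads.

## Stand-in reference constructs

The original assay reference sequences are not redistributable, so
`polq_scars.constructs` builds deterministic synthetic stand-ins that honor
every published coordinate of the assay design:

* a 9406 bp distal-EJ reporter with I-SceI motifs (first at position 1758),
  whose simple join deletes 1769 bp and yields 597 bp first-round and 429 bp
  nested in-silico PCR products with the published primer sequences (the
  reconstituted site spans amplicon positions 253–270, cut at 262:261);
* a 546 bp proximal-EJ amplicon with a staggered nuclease cut at 273|274.

## CLI

```bash
polq-scars channels --kind id                # list the 83 indel channels
polq-scars cells --mass-ng 54                # genomic DNA mass -> cells (7930)

# junction arm: simulate, then analyze
polq-scars simulate-reads --assay distal --depth 2000 --seed 1 --out-dir sim/
polq-scars junction --reads sim/reads.fastq --ref sim/amplicon.fa \
    --construct sim/construct.fa --amplicon-offset 1505 \
    --assay distal --ci 0.99 --out-dir junction_out/

# cohort arm: simulate, then analyze
polq-scars simulate-cohort --n 400 --fold 2 --seed 1 --out-dir cohort_sim/
polq-scars cohort --exposures cohort_sim/exposures.tsv \
    --expression cohort_sim/expression.tsv --gene POLQ --out-dir cohort_out/
```

All outputs are TSV tables with `#` header comments recording the version and
parameters, plus a machine-readable `summary.json`. Re-running with the same
config and seed reproduces identical outputs.

## Layout

| module | role |
| --- | --- |
| `channels` | SBS96 / ID83 channel catalogs and per-sample mutation catalogs |
| `cohort` | stratification, rank tests, Bonferroni, enrichment reports |
| `cohort_sim` | Dirichlet-exposure cohort simulator with planted enrichment |
| `constructs` | coordinates, motif search, in-silico PCR, I-SceI cleavage/ligation |
| `pipeline` | read merging, alignment, soft-clip realignment, event extraction/grouping |
| `scars` | microhomology, TMEJ calls, Poisson noise filter, insertion origins |
| `readsim` | junction read simulator with self-verified planted outcomes |
| `analysis` | end-to-end junction orchestration |
| `cli`, `io` | command-line surface and format plumbing |
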