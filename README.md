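# rohscan

Runs of homozygosity (ROH), genomic inbreeding and linkage-disequilibrium
decay from SNP-array genotypes, for population geneticists working with
livestock (or any diploid species genotyped on a medium-density chip).

A ROH is a contiguous stretch of homozygous genotypes in one individual,
the footprint of the two haplotypes descending from a common ancestor.
`rohscan` implements the standard array workflow end to end:

- **QC** of PLINK PED/MAP or BED/BIM/FAM genotypes (autosomes, call rate
  of SNPs and individuals, minor allele frequency).
- **ROH detection** with the sliding-window scan: a window of 50
  consecutive SNPs (≤ 1 heterozygote, ≤ 5 missing calls) slides one SNP at
  a time; each SNP is scored by the fraction of overlapping windows judged
  homozygous, and runs of flagged SNPs become segments subject to minimum
  length (1 Mb), SNP count (50), density (1 SNP / 100 kb) and gap (1 Mb)
  constraints. Segments are classed 1–5, 5–10 and > 10 Mb.
- **Inbreeding coefficients**: per individual,

  F_ROH = Σ L_ROH / L_auto,  F_HOM = (O − E) / (L − E),

  where L_auto is the autosomal length spanned by the retained markers, O
  and E the observed and expected homozygous genotype counts and L the
  individual's genotyped SNP count — with F_ROH split by length class and
  Pearson correlations between all five coefficients.
- **ROH islands**: per-SNP ROH incidence across individuals, the top-1%
  incidence threshold, merging of adjacent qualifying SNPs into island
  regions, and optional annotation against a user BED/GFF3 of genes.
- **LD decay**: within-chromosome pairwise r² (squared dosage
  correlation), 100-kb distance bins, the distance at which mean r² falls
  to a reference level, and the SNP-panel size that spacing implies.
- A **seeded simulator** that generates array-like maps, Hardy–Weinberg
  backgrounds, planted autozygous tracts of known location (and, if asked,
  a shared tract that becomes a ROH island), so every stage can be
  validated against ground truth.

## Worked example

```python
import numpy as np
from rohscan import (SimConfig, simulate_population, detect_roh,
                     inbreeding_table, pearson_correlations)

cfg = SimConfig(n_chromosomes=8, snps_per_chromosome=1_200,
                n_individuals=80, target_f=0.08, seed=7)
gm, truth = simulate_population(cfg)
table = inbreeding_table(gm, detect_roh(gm))
print(table[["f_roh_total", "f_hom"]].mean().round(4))
print(round(np.corrcoef(table["f_roh_total"], truth.true_f)[0, 1], 3))
```

prints

```
f_roh_total    0.082
f_hom          0.0816
0.996
```

The population was simulated with a planted mean autozygosity of 0.08
(realised 0.0829 under this seed): the ROH-based coefficient recovers it
to within 0.001 and correlates 0.996 with the per-individual truth, while
the homozygosity-excess coefficient lands at the same level with more
noise — the qualitative relationship expected between the two estimators.
More walkthroughs live in `examples/` (one script per capability:
detection, inbreeding, islands, LD decay, full pipeline).

## Command line

Every stage is also a subcommand of the `rohscan` executable:

```sh
rohscan simulate --config sim.yaml --out data
rohscan qc   --geno data --out clean
rohscan roh  --geno clean --out roh
rohscan inbreed --geno clean --segments roh.roh_segments.tsv --out inb
rohscan islands --segments roh.roh_segments.tsv --map clean.map \
                --n-individuals 60 --out isl
rohscan ld   --geno clean --out ld
rohscan run  --geno data --out results/full   # the whole pipeline + manifest
```

`run` writes every stage table (QC report, segments, length-class summary,
per-chromosome counts, inbreeding coefficients and correlations, SNP
incidence, islands, LD bins) plus a JSON manifest of parameters, input
hashes and the package version, so a run is reproducible from its outputs.

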