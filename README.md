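# caml

Case/control discovery of cancer-associated microsatellite loci (CAMLs)
from exome alignments, and signature-based sample classification.

The package implements a complete, testable pipeline:

1. **Catalog** (`caml.catalog`) — detect maximal perfect tandem repeats
   (unit size 1–6) in a reference sequence and filter them: minimum tract
   length 12 nt (10 nt inside exons), unique 10 nt flank context on both
   strands, and exclusion of repeat pairs separated by fewer than 5
   non-repeat bases.
2. **Genotyper** (`caml.genotyper`) — call per-sample allele-length-pair
   genotypes from SAM/BAM reads. A read counts only when it spans the
   tract plus ≥ 5 bases on each side and both 5 nt flank windows match
   the reference exactly (configurable to 1 mismatch). Alleles supported
   by ≥ 20% of validated depth are retained; loci with more than two
   supported alleles are excluded, and calls require ≥ 15× depth.
3. **Association** (`caml.association`) — per-sample (≥ 15,000 called
   loci) and per-locus (≥ 10 callable samples per cohort) inclusion
   filters; control-side predominant genotype; two-sided Fisher exact
   test per non-predominant genotype (hypergeometric enumeration);
   Benjamini–Hochberg step-up at q\* = 1/X (X = hypotheses with p < 1);
   relative risk; signature assembly at p ≤ 0.01.
4. **Classifier** (`caml.classifier`) — per-sample detection fraction
   over callable signature loci, ROC cutoff by Youden's J, sensitivity /
   specificity, grade-vs-grade comparisons, and tumor/germline
   concordance reporting.
5. **Annotation** (`caml.annotation`) — nearest CpG-island (≤ 10 kb) and
   TFBS (≤ 40 b) gap distances, methylation contrasts, and the driver
   mutation × detection-fraction cross-tabulation.
6. **Simulator** (`caml.simulate`) — fully seeded synthetic references,
   cohort genotype tables with planted case-enriched genotypes at
   configurable relative risk, and per-sample SAM reads with Poisson
   depth, PCR stutter and base errors, so every stage is testable
   without external data.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests
(detector vs brute-force scan, Fisher vs exact rational enumeration, BH
vs textbook step-up, ROC vs exhaustive threshold search) and
`tests/test_acceptance.py` with one test per acceptance criterion.

## CLI

```sh
caml simulate --seed 3 -o fixtures/                      # synthetic inputs
caml catalog build --fasta ref.fa --exons exons.bed -o catalog.tsv
caml genotype --catalog catalog.tsv --manifest manifest.tsv -o genotypes.tsv
caml assoc --genotypes genotypes.tsv --case GBM --control NORMAL \
     --catalog catalog.tsv -o signature.json
caml classify --genotypes genotypes.tsv --signature signature.json \
     --positive GBM --negative NORMAL -o roc.json
caml annotate --catalog catalog.tsv --cpg cpg.bed --tfbs tfbs.bed -o annot.tsv
```

Manifests are TSVs with columns `sample_id`, `cohort`, `path` (paths are
resolved relative to the manifest's directory).

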