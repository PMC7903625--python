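# varbench

A benchmarking toolkit for germline small-variant calling assays, built
for clinical genomics laboratories validating laboratory-developed tests
(LDTs). Given a query VCF, a gold-standard truth set (truth VCF plus
high-confidence regions, e.g. from Genome in a Bottle), and one or more
regions of interest (ROIs), `varbench`:

* classifies every call as **TP / FP / FN / UNK** with
  haplotype-equivalence matching that is robust to representation
  differences (MNP vs. component SNPs, shifted InDels, padded alleles);
* computes per-stratum **precision**, **recall**, **TN** and **NPA**
  (negative percent agreement, the specificity surrogate recommended for
  clinical assay validation) from the ROI base count:

      precision = TP / (TP + FP)
      recall    = TP / (TP + FN)
      TN        = ROI bases − (TP + FP + FN)
      NPA       = TN / (TN + FP)

* stratifies InDels by size (default bins 1–10, 11–20, 21–50, >50 bp,
  mergeable into coarser report bins) and emits size-spectrum tables and
  histograms;
* verifies the presence/absence of named clinically relevant variants
  (e.g. GeT-RM reference-material pathogenic calls) in a query VCF;
* orchestrates multi-sample × multi-ROI runs from one YAML config into a
  single deterministic validation report with input checksums.

A deterministic synthetic-fixture generator (`varbench simulate`) plants
known TP/FP/FN structure and representation perturbations, providing an
exact oracle for the whole pipeline at desk scale.

## Worked example

Generate a fixture (50 concordant SNPs, 15 concordant InDels across the
four size bins, 5 query-only and 3 truth-only SNPs planted), then compare
query against truth:

```
$ varbench simulate --seed 42 --out fixture
$ varbench compare --query fixture/query.vcf --truth fixture/truth.vcf \
    --ref fixture/ref.fa --confident-bed fixture/confident.bed \
    --roi-bed fixture/roi.bed --out comparison.vcf --metrics-out metrics.tsv
classified 140 records in 73 clusters -> comparison.vcf
```

`metrics.tsv` (columns abridged):

```
variant_type  size_bin  total_bases  truth_total  TP  FP  FN  TN     NPA  precision  recall
SNP                     23800        53           50  5   3   23742  100  90.91      94.34
INDEL         All       23800        15           15  0   0   23785  100  100.00     100.00
INDEL         1-10      23800        8            8   0   0   23792  100  100.00     100.00
INDEL         11-20     23800        4            4   0   0   23796  100  100.00     100.00
INDEL         21-50     23800        2            2   0   0   23798  100  100.00     100.00
INDEL         >50       23800        1            1   0   0   23799  100  100.00     100.00
```

Reading the SNP row: of 53 truth SNPs inside the 23,800-base evaluation
region the query recovered 50 (recall 50/53 = 94.34%) and made 5 spurious
calls (precision 50/55 = 90.91%); TN = 23,800 − 58 reference-concordant
bases, giving NPA ≈ 100. The planted counts are recovered exactly.
`comparison.vcf` carries the per-call decisions in hap.py-style TRUTH and
QUERY columns (`BD` = decision, `BVT` = variant type):

```
chr1  1131  .  A  T  .  PASS  .  GT:BD:BVT  0/1:FN:SNP  ./.:.:.
chr1  1255  .  C  A  .  PASS  .  GT:BD:BVT  0/1:TP:SNP  0/1:TP:SNP
```

Verify named truth variants:

```
$ varbench verify --assertions fixture/assertions.tsv \
    --query fixture/query.vcf --ref fixture/ref.fa --out verdicts.tsv
3/3 detected -> verdicts.tsv
```

Full multi-sample runs go through `varbench run --config run.yaml`; see
`docs/methods.md` for the model, the matching algorithm, parameter
defaults, and the configuration schema's fields.

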