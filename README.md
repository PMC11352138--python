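# rhdtype

In-silico implementation of a two-stage molecular **RHD** blood-group
typing scheme, with a synthetic-data module that makes every stage
testable end to end without any external downloads.

## The problem

Serology is the first-line test for the Rhesus D antigen, but samples
with weakened or ambiguous D expression need DNA-based phenotype
prediction: carriers of *weak D* types 1–3 can safely be managed as
D-positive, while *partial D* and *DEL* carriers can form anti-D and
must not be. In Central European populations a handful of variant
alleles dominates, so an efficient typing scheme is:

1. **Allele-specific real-time PCR (PCR-SSP) with melting-curve
   genotyping** for the four regionally predominant variants —
   `RHD*01W.1` (c.809T>G), `RHD*01W.2` (c.1154G>C), `RHD*01W.3`
   (c.8C>G) and `RHD*07.01` (c.329T>C). A primer whose 3′-terminal base
   sits on the variant nucleotide amplifies only the variant haplotype;
   a co-amplified ß-globin fragment excludes false negatives, and
   products are identified by matching −dF/dT melt peaks against
   predefined temperature standards.
2. **Exon-amplification triage and Sanger sequence-based typing (SBT)**
   for target-negative samples: all ten *RHD* exons are amplified with
   M13-tailed primers. No amplification at all suggests the whole-gene
   deletion `RHD*01N.01`; a missing exon 6–9 block suggests the hybrid
   allele `RHD*04.03`; otherwise each exon is sequenced in a single
   direction, base calls with Phred quality QV ≥ 20 (error probability
   ≤ 10^(−QV/10) = 0.01) are validated automatically, substitutions are
   called against the coding reference `NM_016124.6`, and the variant
   set is matched to an ISBT allele name with a predicted phenotype.

The package simulates both stages faithfully — binary 3′-mismatch
discrimination, Gaussian melt-peak synthesis and classification,
per-exon traces with IUPAC mixed calls at heterozygous positions — and
ships the 24-sample external quality assessment (EQA) panel whose
published determinations the pipeline reproduces exactly.

## Worked example

```python
from rhdtype import (
    Assay, build_synthetic_reference, load_allele_db,
    load_exon_assays, load_ssp_assays, make_eqa_panel, run_panel,
)

db = load_allele_db()                      # 12 ISBT alleles, editable TSV
model = build_synthetic_reference(seed=1)  # 10-exon gene, CDS length 1254
panel = make_eqa_panel(model, db)          # 24 proficiency samples
assays = [Assay.from_def(d) for d in load_ssp_assays()]
reports, summary = run_panel(panel, model, db, assays, load_exon_assays(),
                             mode="study", seed=1)
print(summary.route_counts, summary.n_chromatograms)
for r in reports[:4]:
    print(r.sample_id, r.route.value, r.genotype, r.phenotype)
```

prints

```
{'SEQUENCE': 18, 'SUSPECT_HYBRID': 1, 'SUSPECT_DELETION': 5} 180
2019-31 SEQUENCE RHD*01 normal D antigen
2019-32 SEQUENCE RHD*01 normal D antigen
2019-33 SUSPECT_HYBRID RHD*04.03 DIV type 3
2019-34 SEQUENCE RHD*01W.5 weak D type 5
```

In *study* mode every amplifiable sample is sequenced regardless of the
SSP outcome (18 samples × 10 exons = 180 chromatograms), so concordance
between the two stages can be verified; *routine* mode reports
SSP-positive samples directly and sequences only the remainder. Five
samples with no exon amplification are routed to a suspected deletion
and one with an absent exon 6–9 block to the suspected hybrid — both
provisional pending confirmatory exon-specific PCR. The heterozygous
DNB sample is reported as `RHD*25/RHD*01` with the summary
`NM_016124.6:c.[1063G>A];[1063=]`.

The same run is available from the shell:

```bash
rhdtype simulate-panel --seed 1 --out panel/
rhdtype type --panel panel/ --out results/ --mode study --seed 1
rhdtype report --results results/
```

All outputs (haplotype FASTA, trace FASTQ, plate-order CSV, report CSV)
are plain text and byte-identical across reruns with the same seed.

## Layout

| module | responsibility |
|---|---|
| `rhdtype.alleles` | ISBT allele database, HGVS c. parsing/formatting, variant-set matching |
| `rhdtype.genemodel` | 10-exon gene model, CDS↔genomic coordinates, synthetic reference builder |
| `rhdtype.primers` | published primer/assay tables (packaged TSV) |
| `rhdtype.simulate` | diploid sample construction, EQA panel, trace simulation |
| `rhdtype.ssp` | in-silico PCR, melt-curve synthesis and classification, exon screen |
| `rhdtype.sbt` | QV filtering, anchored variant calling, HGVS summaries |
| `rhdtype.pipeline` | triage, per-sample typing, panel runs |
| `rhdtype.cli` / `rhdtype.io` | command-line surface and text formats |

See `docs/methods.md` for the model, its assumptions and limitations.
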