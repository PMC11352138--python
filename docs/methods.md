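# Methods

This note documents the models behind `rhdtype`, the choices made where
the design was genuinely open, and what the synthetic fixtures do and do
not establish about real laboratory data.

## Scope of the simulation

The package models the *information flow* of a two-stage RHD typing
scheme, not its chemistry. Amplification is a deterministic predicate
over primer/template sequence; melt peaks are synthetic curves placed at
configured temperatures; traces are base + quality sequences, not
electropherogram waveforms. Reagent chemistry, thermocycling kinetics,
amplification efficiency (Cq), capillary electrophoresis and instrument
file formats are all out of scope, as is any network transport of
orders or results.

## Allele database (`alleles`)

Alleles are rows of an editable tab-separated table: name, defining CDS
substitutions in HGVS c. notation, structural class (`FULL_GENE`,
`GENE_ABSENT`, `EXON_DROPOUT`), category, phenotype label, optional rs
identifiers and exon assignments. The packaged default holds the twelve
alleles the typing scheme distinguishes. Matching is exact-set
equality:

* empty variant set → `RHD*01`, second haplotype unresolved
  (sequencing cannot distinguish homozygous from hemizygous);
* a lone heterozygous variant defining allele *A* → (*A*, `RHD*01`):
  a single-direction Sanger read cannot phase, but a mixed call with a
  reference component implies the trans haplotype is reference at that
  site;
* anything else that is not an exact database hit → `novel_candidate`
  carrying the observed variants verbatim, never an exception. Sets
  with more than one heterozygous variant are additionally marked
  phase-unknown; no multi-site phasing is attempted.

`RHD*01EL.01` is defined by the synonymous substitution c.1227G>A; its
DEL phenotype is stored purely as annotation — the package does no
protein-level reasoning anywhere.

The exon housing each defining variant is configuration, not
computation. The defaults are consistent with the packaged gene model's
exon grid; pipeline correctness does not depend on them.

## Gene model (`genemodel`)

Internally all genomic coordinates are 0-based half-open; HGVS CDS
coordinates are 1-based. The conversion lives in one place
(`GeneModel.cds_to_genomic` / `genomic_to_cds`).

The synthetic reference is a deterministic function of a seed. Exon CDS
lengths default to `(148, 187, 151, 148, 167, 138, 134, 80, 74, 27)`
(sum 1254). These are pinned by the junction-spanning SSP primers, whose
lowercase/uppercase structure marks the intron/exon boundary: the weak D
type 2 forward primer has a single exonic base at c.1154, fixing the
exon 9 start; the DVII reverse primer's seven exonic bases end at c.335,
fixing the exon 2 end; the weak D type 1 forward primer's eight exonic
bases end at c.809. Intron and flank sizes (roughly 230–350 nt) are
arbitrary documented scaffolding; they are *not* claimed to be the
biological intron lengths.

Construction embeds every published primer verbatim at exactly one
registered site: exon-amplification primers in the flanking introns,
consensus SSP primers inside their exons, junction primers straddling
their boundary. The reference base at each allele-defining position is
the database's reference base, so each allele-specific primer's full
core (3′ base on the variant) is absent from the reference and appears
only after the variant is applied. A post-build scan verifies site
uniqueness and re-rolls the random background on collision (expected
essentially never at these primer lengths).

The ß-globin internal control is modelled as a separate control locus
present in every non-NTC sample, carrying the 107 bp and 268 bp control
amplicons implied by the published primer coordinates. Only control
*presence* matters to the logic, so no attempt is made at human genome
fidelity.

A user-supplied real reference can be loaded through the same
`GeneModel` container (FASTA + exon/primer annotation table); nothing is
downloaded.

## Sample and trace simulation (`simulate`)

A sample is two haplotypes plus the control locus. Deletion haplotypes
carry no RHD sequence at all; hybrid (`EXON_DROPOUT`) haplotypes have
the genomic block from the first dropped exon's forward primer site to
the last dropped exon's reverse primer site replaced by random sequence
screened to contain no primer match, so every assay internal to the
block fails while the neighbouring exons' assays survive.

The packaged panel is 24 proficiency samples (four per year, 2019–2024)
with fixed truth alleles. Published panel interpretations state only the
allele; zygosity is fixed in the fixture as homozygous/hemizygous-
equivalent for all samples except the DNB sample 2023-33, which is built
heterozygous (`RHD*25` in trans to `RHD*01`) to match its reported
single heterozygous substitution. The packaged panel seed is
`20240806`; every stochastic operation takes an explicit seed and
per-trace seeds are derived stably from (run seed, sample id, exon).

Traces cover one exon amplicon each, in the direction of the M13-tailed
primer (reverse orientation for exon 8, whose reverse primer carries the
tail). Positions where the contributing haplotypes disagree are emitted
as IUPAC two-base codes. Quality values are uniform draws in
`[floor, ceiling]`:

* **clean** profile (default): floor 25 — every call is above the
  QV 20 validation threshold and no miscalls occur, reproducing the
  panel's all-above-QV-20 behaviour;
* **degraded** profile: floor 5 — exercises the review path. Miscalls
  are injected *only* at positions with QV < 20 (rate 0.25), so the
  quality filter alone guarantees correctness of accepted calls. This
  is a deliberate idealisation: real traces can contain high-confidence
  errors; passing tests therefore demonstrate the logic, not basecaller
  accuracy.

## SSP engine (`ssp`)

`find_amplicon` is exact string matching: a product exists iff both
primers find convergently oriented sites whose 3′-terminal base matches
exactly, with at most `mismatch_budget` (default 0) mismatches
elsewhere, product length ≤ 1500 nt; the shortest (then leftmost)
product wins. 3′ discrimination is binary — no partial-efficiency or
late-amplification modelling. The default zero budget reflects that
fixture primers are embedded verbatim; a nonzero budget is available for
user-supplied references.

Melt curves are sums of Gaussian peaks (σ = 0.8 °C, target amplitude
1.0, control amplitude 0.6) on a 70–95 °C grid at 0.1 °C steps; the
amplitudes and width are arbitrary documented constants — only peak
*positions* carry information. Classification matches called peaks
(height ≥ 0.1) to the nearest standard within a tolerance of 1.0 °C.
The instrument software's numeric tolerance is not published; 1.0 °C is
this package's choice, small enough to resolve the tightest published
pair (83.0 °C target vs 80.7 °C control). Standards closer than twice
the tolerance are rejected at configuration time, not at run time.

Classification uses the *published empirical* Tm standards, never
thermodynamic estimates: the instrument values depend on buffer and dye
conditions that no calculation reproduces. `estimate_tm` (biopython's
nearest-neighbor model with salt correction) is exposed as a diagnostic
only.

An exon counts as present iff a product forms on at least one haplotype
*and* its melt peak matches that exon's standard. The no-template
control contains no template of any kind; any peak in an NTC reaction
invalidates the whole run.

## SBT engine (`sbt`)

Quality filtering is inclusive at the threshold (QV 20 counts as
validated, error probability 10^(−20/10) = 0.01). Pure sub-threshold
calls are flagged `low_quality`; IUPAC calls are flagged `mixed_base`
whatever their quality. Filtering is idempotent and monotone in the
threshold.

"Alignment" is anchored placement at the amplicon's known coordinates —
simulated traces are indel-free, so a general aligner would add failure
modes without adding information. An indel in an input trace raises an
explicit unsupported-event error. Only substitutions are callable.

Heterozygote resolution replaces manual chromatogram editing with a
deterministic rule: a validated mixed call decomposing to {reference,
one alternate} becomes a heterozygous call; any other mixed call stays
flagged and its position counts as uncovered. Summaries follow the
reporting convention: `c.1_1254=` for reference-identical samples, the
bracket style `c.[1063G>A];[1063=]` for a lone heterozygous
substitution, and an explicit `(incomplete)` qualifier whenever CDS
coverage is partial.

## Orchestration (`pipeline`)

Triage order: (routine mode only) any SSP positive → report from SSP;
all exons absent → suspect deletion; absent set exactly equal to a
database allele's dropped exons → suspect that hybrid; any other
dropout pattern → sequence with an `unexplained_dropout` flag;
otherwise sequence. Both structural suspicions carry
`confirmation_required`, since the confirmatory exon-specific PCR is
not simulated. In study mode SSP positives are still sequenced and the
two stages are cross-checked; a disagreement raises a `discordant`
flag rather than an error, because a diagnostic tool must not crash on
real discordance. The hybrid-suspect sample is *not* sequenced in
study mode even though six of its exons amplify — sequencing a sample
already explained by its amplification pattern adds nothing, which is
why the panel yields 18 sequenced samples and 180 chromatograms.

A negative SSP result never grounds a genotype claim by itself:
deletion and hybrid calls cite the exon profile, and the test suite
asserts this.

## Problem sizes and determinism

The packaged workload — one ~4.2 kb reference, 24 samples, 96 SSP
reactions, 240 exon reactions, 180 traces of ~300–400 nt — runs in
seconds; property suites (100-template PCR oracle comparison, 50-sample
variant-injection round trip) stay well under a minute. All randomness
flows from explicit seeds; panel files and reports are byte-identical
across reruns.

## Known limitations

* No chromatogram waveform synthesis or basecalling; quality values are
  assigned, not estimated from signal.
* No amplification-efficiency, contamination-carryover or primer-dimer
  modelling; the NTC model is categorical.
* Phasing beyond the single-heterozygote trans case is not attempted.
* The allele table covers the twelve panel alleles by default; regional
  extension is expected and supported, but untested alleles are
  reported as novel candidates rather than named.
* The synthetic reference shares only its constrained positions with
  the real locus; results on it validate the pipeline's logic, not
  primer performance on genomic DNA.
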