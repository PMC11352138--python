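"""Fixture generation: diploid RHD samples, the packaged 24-sample EQA
panel, and simulated single-direction Sanger traces with Phred quality
values.

A sample is a pair of haplotypes.  Each haplotype is either the full
synthetic gene with its allele's substitutions applied, absent entirely
(whole-gene deletion), or exon-masked (hybrid allele: the genomic block
spanning the dropped exons, including every primer site internal to it,
replaced by non-matching sequence).  The autosomal control locus used by
the internal-control PCR is present in every sample regardless of RHD
status.

Traces are base + quality-value records, not chromatogram waveforms.
Positions where the two haplotypes disagree are emitted as IUPAC
two-base codes; in the default "clean" profile every quality value is
at or above the automatic-validation threshold of 20, so the published
panel behaviour (all calls above QV 20) is reproduced.  A "degraded"
profile lowers the quality floor to exercise manual-review flagging.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .alleles import AlleleDatabase, StructuralClass
from .genemodel import GeneModel
from .primers import load_exon_assays, load_ssp_assays, revcomp

PANEL_SEED = 20240806  # seed of the packaged panel fixtures

_IUPAC_TWO = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
}
IUPAC_DECODE = {code: pair for pair, code in _IUPAC_TWO.items()}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Haplotype:
    """One chromosome's RHD status: full sequence, absent, or exon-masked."""

    allele_name: str
    sequence: str | None  # None for a whole-gene deletion
    masked_exons: frozenset[int] = frozenset()

    @property
    def absent(self) -> bool:
        return self.sequence is None

    def carries_exon(self, exon: int) -> bool:
        return self.sequence is not None and exon not in self.masked_exons


@dataclass(frozen=True)
class SampleGenotype:
    sample_id: str
    haplotypes: tuple[Haplotype, Haplotype]
    truth_allele_pair: tuple[str, str]
    control_sequence: str | None = None  # None only for a no-template control

    def __post_init__(self) -> None:
        names = tuple(h.allele_name for h in self.haplotypes)
        if names != self.truth_allele_pair:
            raise ValueError(f"{self.sample_id}: truth {self.truth_allele_pair} != haplotypes {names}")


@dataclass(frozen=True)
class TraceRead:
    """Single-direction sequencing read: IUPAC base calls plus Phred QVs.

    ``strand`` is the direction of the M13-tailed primer ('+' when the
    forward amplification primer carries the tail); ``genomic_start`` is
    the plus-strand coordinate of the read's leftmost template base.
    """

    sample_id: str
    exon: int
    bases: str
    qvs: tuple[int, ...]
    genomic_start: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qvs):
            raise ValueError("bases and qvs must have equal length")
        if any(q < 0 for q in self.qvs):
            raise ValueError("quality values must be non-negative")

    def plus_strand(self) -> tuple[str, tuple[int, ...]]:
        """Base calls and QVs re-oriented to the plus strand."""
        if self.strand == "+":
            return self.bases, self.qvs
        return revcomp(self.bases), self.qvs[::-1]


@dataclass(frozen=True)
class QVProfile:
    """Quality-value model for simulated traces.

    ``floor``/``ceiling`` bound the uniform QV draw.  Miscalls are
    introduced only at positions whose QV falls below
    ``miscall_below``, so a QV filter at that threshold is sufficient to
    guarantee base-call correctness.
    """

    floor: int = 25
    ceiling: int = 60
    miscall_below: int = 20
    miscall_rate: float = 0.25


CLEAN_PROFILE = QVProfile()
DEGRADED_PROFILE = QVProfile(floor=5)


def make_sample(
    allele_a: str,
    allele_b: str,
    model: GeneModel,
    db: AlleleDatabase,
    sample_id: str = "sample",
    mask_seed: int = 0,
) -> SampleGenotype:
    """Build a diploid sample from two allele names."""
    haps = tuple(
        _make_haplotype(db[name], model, mask_seed + i) for i, name in enumerate((allele_a, allele_b))
    )
    return SampleGenotype(
        sample_id=sample_id,
        haplotypes=haps,
        truth_allele_pair=(allele_a, allele_b),
        control_sequence=model.control_sequence,
    )


def _make_haplotype(allele, model: GeneModel, mask_seed: int) -> Haplotype:
    if allele.structural_class is StructuralClass.GENE_ABSENT:
        return Haplotype(allele.name, None)
    seq = list(model.genomic_sequence)
    for v in allele.defining_variants:
        g = model.cds_to_genomic(v.cds_pos)
        if seq[g] != v.ref_base:
            raise ValueError(
                f"reference base {seq[g]} at c.{v.cds_pos} does not match {v.ref_base}"
            )
        seq[g] = v.alt_base
    masked: frozenset[int] = frozenset()
    if allele.structural_class is StructuralClass.EXON_DROPOUT:
        masked = allele.dropped_exons
        start, end = model.dropout_mask_interval(masked)
        seq[start:end] = _nonmatching_filler(end - start, model, mask_seed)
    return Haplotype(allele.name, "".join(seq), masked)


def _nonmatching_filler(n: int, model: GeneModel, seed: int) -> list[str]:
    """Random replacement block guaranteed to contain no primer site."""
    cores = [p.core for a in load_ssp_assays() for p in (a.fwd, a.rev, a.ctrl_fwd, a.ctrl_rev)]
    cores += [p.core for e in load_exon_assays() for p in (e.fwd, e.rev)]
    rng = np.random.default_rng((seed + 7919) % 2**31)
    for _ in range(50):
        block = "".join(_BASES[rng.integers(0, 4, n)])
        if not any(c in block or revcomp(c) in block for c in cores):
            return list(block)
    raise RuntimeError("could not generate a primer-free masked block")


# ---------------------------------------------------------------------------
# The packaged EQA panel: 24 proficiency samples, four per year 2019-2024.
# Zygosity is homozygous/hemizygous-equivalent for every sample except the
# DNB sample 2023-33, which carries its variant in trans to the reference
# allele.
PANEL_TRUTH: tuple[tuple[str, str, str], ...] = (
    ("2019-31", "RHD*01", "RHD*01"),
    ("2019-32", "RHD*01", "RHD*01"),
    ("2019-33", "RHD*04.03", "RHD*04.03"),
    ("2019-34", "RHD*01W.5", "RHD*01W.5"),
    ("2020-31", "RHD*01N.01", "RHD*01N.01"),
    ("2020-32", "RHD*01N.01", "RHD*01N.01"),
    ("2020-33", "RHD*01W.1", "RHD*01W.1"),
    ("2020-34", "RHD*07.01", "RHD*07.01"),
    ("2021-31", "RHD*01N.01", "RHD*01N.01"),
    ("2021-32", "RHD*01EL.01", "RHD*01EL.01"),
    ("2021-33", "RHD*01", "RHD*01"),
    ("2021-34", "RHD*01", "RHD*01"),
    ("2022-31", "RHD*19", "RHD*19"),
    ("2022-32", "RHD*01W.1", "RHD*01W.1"),
    ("2022-33", "RHD*01N.01", "RHD*01N.01"),
    ("2022-34", "RHD*01", "RHD*01"),
    ("2023-31", "RHD*01", "RHD*01"),
    ("2023-32", "RHD*01N.01", "RHD*01N.01"),
    ("2023-33", "RHD*25", "RHD*01"),
    ("2023-34", "RHD*01W.2", "RHD*01W.2"),
    ("2024-31", "RHD*01", "RHD*01"),
    ("2024-32", "RHD*01", "RHD*01"),
    ("2024-33", "RHD*01W.3", "RHD*01W.3"),
    ("2024-34", "RHD*11", "RHD*11"),
)


def make_eqa_panel(model: GeneModel, db: AlleleDatabase) -> list[SampleGenotype]:
    """The 24-sample external quality assessment panel."""
    return [
        make_sample(a, b, model, db, sample_id=sid, mask_seed=PANEL_SEED + 2 * i)
        for i, (sid, a, b) in enumerate(PANEL_TRUTH)
    ]


def trace_seed(base_seed: int, sample_id: str, exon: int) -> int:
    """Stable per-trace seed derived from a run seed."""
    return (base_seed * 131 + exon * 17 + zlib.crc32(sample_id.encode())) % 2**31


def simulate_trace(
    sample: SampleGenotype,
    exon: int,
    model: GeneModel,
    qv_profile: QVProfile = CLEAN_PROFILE,
    seed: int = PANEL_SEED,
) -> TraceRead:
    """Simulate the single sequencing read covering one exon's amplicon.

    Heterozygous positions yield the IUPAC two-base code.  The read is
    reported in the direction of the exon's M13-tailed primer (reverse
    complement for exon 8, whose reverse primer carries the tail).
    """
    carriers = [h for h in sample.haplotypes if h.carries_exon(exon)]
    if not carriers:
        raise ValueError(f"{sample.sample_id}: no haplotype amplifies exon {exon}")
    start, end = model.amplicon_interval(exon)
    segments = [h.sequence[start:end] for h in carriers]
    rng = np.random.default_rng(seed)
    n = end - start
    qvs = rng.integers(qv_profile.floor, qv_profile.ceiling + 1, n)
    bases = []
    for i in range(n):
        calls = {s[i] for s in segments}
        base = calls.pop() if len(calls) == 1 else _IUPAC_TWO[frozenset(calls)]
        if qvs[i] < qv_profile.miscall_below and rng.random() < qv_profile.miscall_rate:
            base = str(rng.choice(_BASES[_BASES != base])) if base in "ACGT" else base
        bases.append(base)
    read = "".join(bases)
    qv_tuple = tuple(int(q) for q in qvs)
    exon_assay = {e.exon: e for e in load_exon_assays()}[exon]
    if exon_assay.tailed_primer == "rev":
        return TraceRead(sample.sample_id, exon, revcomp(read), qv_tuple[::-1], start, "-")
    return TraceRead(sample.sample_id, exon, read, qv_tuple, start, "+")
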