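"""Sequence-based typing: quality filtering of traces, anchored placement
on the reference, variant calling with zygosity, and HGVS summaries.

Reads are placed by their amplicon's known genomic coordinates rather
than aligned freely: simulated traces are indel-free and the amplicon
boundaries are fixed by the registered primer sites.  Base calls at or
above the quality threshold are validated automatically; mixed (IUPAC)
calls whose two bases are reference plus one alternate are resolved to a
heterozygous variant, replacing the manual chromatogram-editing step
with a deterministic, conservative rule.  Anything else stays flagged
for review and counts as uncovered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .alleles import CDS_LENGTH, REFERENCE_ID, Variant, Zygosity
from .genemodel import GeneModel
from .simulate import IUPAC_DECODE, TraceRead

QV_THRESHOLD = 20  # automatic-validation boundary, inclusive

LOW_QUALITY = "low_quality"
MIXED_BASE = "mixed_base"


@dataclass(frozen=True)
class FilteredRead:
    """Partition of a trace into auto-validated calls and review flags.

    ``accepted`` maps read position -> (base, QV) for pure calls at or
    above the threshold; ``review`` maps every remaining position to
    (base, QV, tags).  Together they cover the read; mixed calls are
    never silently dropped.
    """

    read: TraceRead
    qv_threshold: int
    accepted: dict[int, tuple[str, int]]
    review: dict[int, tuple[str, int, frozenset[str]]]


@dataclass(frozen=True)
class VariantCallEvidence:
    exon: int
    read_pos: int
    qv: int


@dataclass(frozen=True)
class VariantCall:
    variant: Variant
    zygosity: Zygosity
    evidence: VariantCallEvidence


@dataclass(frozen=True)
class CoverageReport:
    """CDS positions resolved by accepted or auto-resolved calls."""

    covered: frozenset[int]
    review_positions: tuple[tuple[int, frozenset[str]], ...] = ()

    @property
    def complete(self) -> bool:
        return len(self.covered) == CDS_LENGTH

    @property
    def missing(self) -> tuple[int, ...]:
        return tuple(sorted(set(range(1, CDS_LENGTH + 1)) - self.covered))


def filter_read(read: TraceRead | FilteredRead, qv_threshold: int = QV_THRESHOLD) -> FilteredRead:
    """Partition a trace's base calls by quality and purity.

    Idempotent: filtering an already-filtered read returns it unchanged.
    """
    if qv_threshold < 0:
        raise ValueError("qv_threshold must be >= 0")
    if isinstance(read, FilteredRead):
        return read
    accepted: dict[int, tuple[str, int]] = {}
    review: dict[int, tuple[str, int, frozenset[str]]] = {}
    for i, (base, qv) in enumerate(zip(read.bases, read.qvs)):
        tags = set()
        if base not in "ACGT":
            tags.add(MIXED_BASE)
        if qv < qv_threshold:
            tags.add(LOW_QUALITY)
        if tags:
            review[i] = (base, qv, frozenset(tags))
        else:
            accepted[i] = (base, qv)
    return FilteredRead(read=read, qv_threshold=qv_threshold, accepted=accepted, review=review)


class ReadPlacementError(ValueError):
    pass


def _check_placement(read: TraceRead, model: GeneModel) -> None:
    start, end = model.amplicon_interval(read.exon)
    if read.genomic_start != start or read.genomic_start + len(read.bases) > len(
        model.genomic_sequence
    ):
        raise ReadPlacementError(
            f"read for exon {read.exon} cannot be placed at its amplicon coordinates"
        )


def call_variants(
    reads: Iterable[TraceRead | FilteredRead],
    model: GeneModel,
    qv_threshold: int = QV_THRESHOLD,
) -> tuple[list[VariantCall], CoverageReport]:
    """Call CDS substitutions from per-exon reads against the reference.

    Accepted pure calls differing from the reference become
    homozygous-or-hemizygous calls; high-quality mixed calls decomposing
    to {reference, alternate} become heterozygous calls.  The coverage
    report lists CDS positions left without an accepted or resolvable
    call.
    """
    calls: dict[Variant, VariantCall] = {}
    covered: set[int] = set()
    review_positions: list[tuple[int, frozenset[str]]] = []
    for item in reads:
        fr = filter_read(item, qv_threshold)
        read = fr.read
        _check_placement(read, model)
        plus_bases, plus_qvs = read.plus_strand()
        n = len(plus_bases)
        # review/accepted dicts are keyed by read orientation; re-key to plus
        flip = read.strand == "-"
        for i in range(n):
            g = read.genomic_start + i
            if not model.is_coding(g):
                continue
            cds_pos = model.genomic_to_cds(g)
            ref = model.genomic_sequence[g]
            base, qv = plus_bases[i], plus_qvs[i]
            read_pos = n - 1 - i if flip else i
            if read_pos in fr.accepted:
                covered.add(cds_pos)
                if base != ref:
                    v = Variant(cds_pos, ref, base)
                    calls.setdefault(
                        v,
                        VariantCall(v, Zygosity.HOM, VariantCallEvidence(read.exon, read_pos, qv)),
                    )
                continue
            _b, _q, tags = fr.review[read_pos]
            if MIXED_BASE in tags and LOW_QUALITY not in tags and base in IUPAC_DECODE:
                pair = IUPAC_DECODE[base]
                if ref in pair:
                    alt = next(iter(pair - {ref}))
                    v = Variant(cds_pos, ref, alt)
                    calls.setdefault(
                        v,
                        VariantCall(v, Zygosity.HET, VariantCallEvidence(read.exon, read_pos, qv)),
                    )
                    covered.add(cds_pos)
                    continue
            review_positions.append((cds_pos, tags))
    report = CoverageReport(frozenset(covered), tuple(review_positions))
    ordered = sorted(calls.values(), key=lambda c: c.variant.cds_pos)
    return ordered, report


def summarize_cds(
    calls: Sequence[VariantCall],
    coverage: CoverageReport,
    reference_id: str = REFERENCE_ID,
) -> str:
    """HGVS-style summary of a sample's coding sequence.

    No calls over a fully covered CDS formats as ``c.1_1254=``; a single
    heterozygous substitution uses the two-haplotype bracket style
    (``c.[1063G>A];[1063=]``).
    """
    qualifier = "" if coverage.complete else " (incomplete)"
    if not calls:
        return f"{reference_id}:c.1_{CDS_LENGTH}={qualifier}"
    if len(calls) == 1:
        c = calls[0]
        v = c.variant
        if c.zygosity is Zygosity.HET:
            return (
                f"{reference_id}:c.[{v.cds_pos}{v.ref_base}>{v.alt_base}];"
                f"[{v.cds_pos}=]{qualifier}"
            )
        return f"{reference_id}:c.{v.cds_pos}{v.ref_base}>{v.alt_base}{qualifier}"
    parts = []
    for c in calls:
        v = c.variant
        token = f"{v.cds_pos}{v.ref_base}>{v.alt_base}"
        if c.zygosity is Zygosity.HET:
            token += "(het)"
        parts.append(token)
    return f"{reference_id}:c.[{';'.join(parts)}]{qualifier}"
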