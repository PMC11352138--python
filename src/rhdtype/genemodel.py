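"""Ten-exon RHD gene model: CDS/genomic coordinate mapping and synthetic
reference construction with registered primer binding sites.

The synthetic reference is not a copy of the human locus.  It is a
deterministic sequence in which (a) the coding sequence has length 1254
with the true reference base at every allele-defining position, (b) every
published primer binds at exactly one registered site, and (c) primers
whose case structure spans an intron/exon junction are placed so their
lowercase run falls in the intron and their uppercase run in the exon.
That is everything the amplification, melt-classification, and
sequence-typing logic depends on.  A user-supplied real reference with an
exon annotation can be substituted through the same :class:`GeneModel`
container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alleles import CDS_LENGTH
from .primers import (
    ExonAssayDef,
    SspAssayDef,
    load_exon_assays,
    load_ssp_assays,
    revcomp,
)

# CDS span of each exon, chosen so every defining variant falls in the
# exon its published junction-spanning primer implies (e.g. the weak D
# type 2 primer's single exonic base is c.1154, fixing the exon 9 start).
EXON_CDS_LENGTHS = (148, 187, 151, 148, 167, 138, 134, 80, 74, 27)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Site:
    """A registered primer binding site on one contig."""

    contig: str  # "RHD" or "control"
    start: int  # 0-based, half-open
    end: int
    strand: str  # '+' or '-'

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


class NotCodingError(ValueError):
    """Genomic position falls in an intron or flank."""


@dataclass
class GeneModel:
    """Genomic template plus coordinate map and primer-site registry."""

    genomic_sequence: str
    control_sequence: str
    exon_intervals: tuple[tuple[int, int], ...]  # genomic, 0-based half-open
    primer_sites: Mapping[str, Site]
    exon_primer_ids: Mapping[int, tuple[str, str]]  # exon -> (fwd_id, rev_id)
    seed: int | None = None
    _cds_to_g: np.ndarray = field(init=False, repr=False)
    _g_to_cds: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lengths = [e - s for s, e in self.exon_intervals]
        if sum(lengths) != CDS_LENGTH:
            raise ValueError(f"exon lengths sum to {sum(lengths)}, expected {CDS_LENGTH}")
        starts = [s for s, _ in self.exon_intervals]
        if starts != sorted(starts):
            raise ValueError("exons must be ordered and non-overlapping")
        positions = np.concatenate(
            [np.arange(s, e) for s, e in self.exon_intervals]
        )
        self._cds_to_g = positions
        self._g_to_cds = {int(g): i + 1 for i, g in enumerate(positions)}

    # -- coordinates ---------------------------------------------------

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Map a 1-based CDS position to a 0-based genomic position."""
        if not 1 <= cds_pos <= CDS_LENGTH:
            raise ValueError(f"cds_pos {cds_pos} outside 1..{CDS_LENGTH}")
        return int(self._cds_to_g[cds_pos - 1])

    def genomic_to_cds(self, genomic_pos: int) -> int:
        """Inverse mapping; raises :class:`NotCodingError` in introns."""
        try:
            return self._g_to_cds[genomic_pos]
        except KeyError:
            raise NotCodingError(f"genomic position {genomic_pos} is not coding") from None

    def is_coding(self, genomic_pos: int) -> bool:
        return genomic_pos in self._g_to_cds

    @property
    def cds_sequence(self) -> str:
        return "".join(self.genomic_sequence[s:e] for s, e in self.exon_intervals)

    def exon_of_cds(self, cds_pos: int) -> int:
        """1-based exon index housing a CDS position."""
        g = self.cds_to_genomic(cds_pos)
        for i, (s, e) in enumerate(self.exon_intervals, start=1):
            if s <= g < e:
                return i
        raise AssertionError("unreachable")

    def exon_cds_span(self, exon: int) -> tuple[int, int]:
        """Inclusive 1-based CDS span of an exon."""
        lengths = [e - s for s, e in self.exon_intervals]
        start = sum(lengths[: exon - 1]) + 1
        return start, start + lengths[exon - 1] - 1

    # -- amplicons -----------------------------------------------------

    def amplicon_interval(self, exon: int) -> tuple[int, int]:
        """Genomic interval covered by an exon's amplification product."""
        fwd_id, rev_id = self.exon_primer_ids[exon]
        return (self.primer_sites[fwd_id].start, self.primer_sites[rev_id].end)

    def dropout_mask_interval(self, dropped_exons: frozenset[int]) -> tuple[int, int]:
        """Genomic block whose replacement removes all primer sites of the
        dropped exons while preserving the neighbouring exons' sites."""
        starts = [self.primer_sites[self.exon_primer_ids[e][0]].start for e in dropped_exons]
        ends = [self.primer_sites[self.exon_primer_ids[e][1]].end for e in dropped_exons]
        return (min(starts), max(ends))


class _Assembler:
    def __init__(self, rng: np.random.Generator, contig: str):
        self.rng = rng
        self.contig = contig
        self.parts: list[str] = []
        self.pos = 0
        self.sites: dict[str, Site] = {}

    def rand(self, n: int) -> None:
        self.add("".join(_BASES[self.rng.integers(0, 4, n)]))

    def add(self, seq: str) -> None:
        self.parts.append(seq)
        self.pos += len(seq)

    def site(self, primer_id: str, seq: str, strand: str) -> None:
        self.register(primer_id, self.pos, self.pos + len(seq), strand)
        self.add(seq)

    def register(self, primer_id: str, start: int, end: int, strand: str) -> None:
        self.sites[primer_id] = Site(self.contig, start, end, strand)

    @property
    def sequence(self) -> str:
        return "".join(self.parts)


def _random_cds(rng: np.random.Generator, ssp: Mapping[str, SspAssayDef]) -> str:
    """Coding sequence: random background with the constrained stretches
    implied by the in-exon primer sites and the allele-defining reference
    bases written over it."""
    cds = list("".join(_BASES[rng.integers(0, 4, CDS_LENGTH)]))
    w1, w2, w3, dvii = (ssp[k] for k in ("RHD*01W.1", "RHD*01W.2", "RHD*01W.3", "RHD*07.01"))

    def put(cds_pos: int, seq: str) -> None:
        cds[cds_pos - 1 : cds_pos - 1 + len(seq)] = list(seq)

    put(1, w3.fwd.exonic_part[:-1])              # ATGAGAT, start codon onward
    put(8, "C")                                  # ref at the weak D type 3 site
    put(100, revcomp(w3.rev.core))               # WD3-r site
    put(201, dvii.fwd.core)                      # RHD-E2-201-f site
    put(329, "T" + revcomp(dvii.rev.core)[1:7])  # ref T, then exon tail of the DVII site
    put(446, "C")                                # weak D type 5 ref
    put(802, w1.fwd.exonic_part[:-1])            # ACTTATG
    put(809, "T")                                # weak D type 1 ref
    put(848, "C")                                # DHMi ref
    put(885, "G")                                # weak partial type 11 ref
    put(900, revcomp(w1.rev.core))               # WD1-r site
    put(1063, "G")                               # DNB ref
    put(1154, "G")                               # weak D type 2 ref (primer 3' base)
    put(1207, revcomp(w2.rev.exonic_part))       # exon 9 tail of the WD2-r site, ends c.1227 = G
    return "".join(cds)


def _exon_chunks(cds: str, lengths: Sequence[int]) -> list[str]:
    out, i = [], 0
    for n in lengths:
        out.append(cds[i : i + n])
        i += n
    return out


def _count_hits(needle: str, haystacks: Sequence[str]) -> int:
    total = 0
    for hay in haystacks:
        for probe in (needle, revcomp(needle)):
            start = 0
            while (idx := hay.find(probe, start)) != -1:
                total += 1
                start = idx + 1
    return total


def _validate_uniqueness(
    model: GeneModel,
    ssp: Sequence[SspAssayDef],
    exon_assays: Sequence[ExonAssayDef],
) -> bool:
    contigs = (model.genomic_sequence, model.control_sequence)
    seen: set[str] = set()
    for a in ssp:
        disc, other = (a.fwd, a.rev) if a.discriminating_end == "fwd" else (a.rev, a.fwd)
        # allele-specific core must be absent from the reference; the
        # reference version of its site (3'-terminal base reverted) unique
        ref_site = disc.core[:-1] + _ref_3prime_base(a)
        if _count_hits(disc.core, contigs) != 0 or _count_hits(ref_site, contigs) != 1:
            return False
        for p in (other, a.ctrl_fwd, a.ctrl_rev):
            if p.primer_id not in seen:
                seen.add(p.primer_id)
                if _count_hits(p.core, contigs) != 1:
                    return False
    for e in exon_assays:
        for p in (e.fwd, e.rev):
            if _count_hits(p.core, contigs) != 1:
                return False
    return True


def _ref_3prime_base(assay: SspAssayDef) -> str:
    # the discriminating 3' base targets the variant allele; the reference
    # carries the complement-strand-appropriate reference base instead
    refs = {"RHD*01W.1": "T", "RHD*01W.2": "G", "RHD*01W.3": "C", "RHD*07.01": "T"}
    ref = refs[assay.target_allele]
    return ref if assay.discriminating_end == "fwd" else revcomp(ref)


def build_synthetic_reference(
    seed: int = 1,
    exon_lengths: Sequence[int] | None = None,
    max_attempts: int = 20,
) -> GeneModel:
    """Construct a deterministic synthetic reference for a given seed.

    The builder embeds the published primer sequences at their registered
    sites (junction primers straddling the intron/exon boundary their
    lowercase/uppercase structure dictates) and re-rolls the random
    background in the rare event an accidental second primer match
    appears.
    """
    lengths = tuple(exon_lengths) if exon_lengths is not None else EXON_CDS_LENGTHS
    if len(lengths) != 10 or sum(lengths) != CDS_LENGTH:
        raise ValueError(f"exon lengths must be 10 values summing to {CDS_LENGTH}")
    rng = np.random.default_rng(seed)
    ssp_list = load_ssp_assays()
    exon_list = load_exon_assays()
    ssp = {a.assay_name: a for a in ssp_list}
    ex = {e.exon: e for e in exon_list}

    for _ in range(max_attempts):
        model = _build_once(rng, lengths, ssp, ex, seed)
        if _validate_uniqueness(model, ssp_list, exon_list):
            return model
    raise RuntimeError("could not build a collision-free reference")


def _build_once(
    rng: np.random.Generator,
    lengths: Sequence[int],
    ssp: Mapping[str, SspAssayDef],
    ex: Mapping[int, ExonAssayDef],
    seed: int,
) -> GeneModel:
    w1, w2, w3, dvii = (ssp[k] for k in ("RHD*01W.1", "RHD*01W.2", "RHD*01W.3", "RHD*07.01"))
    cds = _random_cds(rng, ssp)
    exon_seq = _exon_chunks(cds, lengths)
    A = _Assembler(rng, "RHD")
    exon_intervals: list[tuple[int, int]] = []

    def add_exon(i: int) -> int:
        start = A.pos
        A.add(exon_seq[i - 1])
        exon_intervals.append((start, A.pos))
        return start

    def fwd_site(exon: int) -> None:
        A.site(ex[exon].fwd.primer_id, ex[exon].fwd.core, "+")

    def rev_site(exon: int) -> None:
        A.site(ex[exon].rev.primer_id, revcomp(ex[exon].rev.core), "-")

    def junction_fwd(assay: SspAssayDef) -> None:
        # lowercase run in the intron tail, uppercase run opens the exon
        start = A.pos
        A.add(assay.fwd.intronic_part)
        A.register(assay.fwd.primer_id, start, start + len(assay.fwd.core), "+")

    # 5' flank
    A.rand(80)
    fwd_site(1)
    A.rand(120)
    junction_fwd(w3)
    e1 = add_exon(1)
    A.register(w3.rev.primer_id, e1 + 99, e1 + 99 + len(w3.rev.core), "-")  # c.100
    A.rand(70); rev_site(1); A.rand(90); fwd_site(2); A.rand(70)
    e2 = add_exon(2)
    A.register(dvii.fwd.primer_id, e2 + 52, e2 + 52 + len(dvii.fwd.core), "+")  # c.201
    A.register(dvii.rev.primer_id, e2 + 180, e2 + 180 + len(dvii.rev.core), "-")  # c.329
    A.add(revcomp(dvii.rev.intronic_part))  # intron 2 opens with the site's intronic run
    A.rand(46); rev_site(2)  # reverse site 61 nt into intron 2
    A.rand(90); fwd_site(3); A.rand(70)
    add_exon(3)
    A.rand(70); rev_site(3); A.rand(90); fwd_site(4); A.rand(70)
    add_exon(4)
    A.rand(70); rev_site(4); A.rand(90); fwd_site(5); A.rand(70)
    add_exon(5)
    A.rand(70); rev_site(5); A.rand(90); fwd_site(6); A.rand(100)
    junction_fwd(w1)
    e6 = add_exon(6)
    A.register(w1.rev.primer_id, e6 + 98, e6 + 98 + len(w1.rev.core), "-")  # c.900
    A.rand(70); rev_site(6); A.rand(90); fwd_site(7); A.rand(70)
    add_exon(7)
    A.rand(70); rev_site(7); A.rand(90); fwd_site(8); A.rand(70)
    add_exon(8)
    A.rand(70); rev_site(8); A.rand(90); fwd_site(9); A.rand(80)
    junction_fwd(w2)
    e9 = add_exon(9)
    A.register(w2.rev.primer_id, e9 + 53, e9 + 53 + len(w2.rev.core), "-")  # c.1207..intron 9
    A.add(revcomp(w2.rev.intronic_part))
    A.rand(60); rev_site(9); A.rand(90); fwd_site(10); A.rand(70)
    add_exon(10)
    A.rand(70); rev_site(10); A.rand(120)

    # separate control locus carrying the two internal-control amplicons
    B = _Assembler(rng, "control")
    B.rand(50)
    B.site(w1.ctrl_fwd.primer_id, w1.ctrl_fwd.core, "+")
    B.rand(107 - len(w1.ctrl_fwd.core) - len(w1.ctrl_rev.core))  # 107 bp product
    B.site(w1.ctrl_rev.primer_id, revcomp(w1.ctrl_rev.core), "-")
    B.rand(60)
    B.site(w2.ctrl_fwd.primer_id, w2.ctrl_fwd.core, "+")
    B.rand(268 - len(w2.ctrl_fwd.core) - len(w2.ctrl_rev.core))  # 268 bp product
    B.site(w2.ctrl_rev.primer_id, revcomp(w2.ctrl_rev.core), "-")
    B.rand(50)

    return GeneModel(
        genomic_sequence=A.sequence,
        control_sequence=B.sequence,
        exon_intervals=tuple(exon_intervals),
        primer_sites={**A.sites, **B.sites},
        exon_primer_ids={e.exon: (e.fwd.primer_id, e.rev.primer_id) for e in ex.values()},
        seed=seed,
    )
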