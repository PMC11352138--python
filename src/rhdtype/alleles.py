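"""RHD allele knowledge base: ISBT allele definitions, HGVS c. substitution
handling, and matching of observed variant sets to allele names.

The packaged default database covers the twelve alleles handled by the
two-stage typing scheme: the reference allele *RHD*01*, the whole-gene
deletion *RHD*01N.01*, the exon 6-9 dropout hybrid *RHD*04.03*, and nine
SNP-defined weak D / partial D / DEL alleles.  The table is an editable
flat file so laboratories can extend it to their regional allele spectrum.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

CDS_LENGTH = 1254
REFERENCE_ID = "NM_016124.6"

_NUCLEOTIDES = frozenset("ACGT")


class StructuralClass(Enum):
    FULL_GENE = "FULL_GENE"
    GENE_ABSENT = "GENE_ABSENT"
    EXON_DROPOUT = "EXON_DROPOUT"


class Category(Enum):
    NORMAL = "normal"
    WEAK_D = "weak D"
    PARTIAL_D = "partial D"
    WEAK_PARTIAL_D = "weak partial D"
    DEL = "DEL"
    D_NEGATIVE = "D-negative"


class Zygosity(Enum):
    HOM = "homozygous_or_hemizygous"
    HET = "heterozygous"


class Confidence(Enum):
    EXACT_MATCH = "exact_match"
    HET_PHASE_ASSUMED = "heterozygous_phase_assumed"
    NOVEL_CANDIDATE = "novel_candidate"
    CONFIRMATION_REQUIRED = "confirmation_required"


@dataclass(frozen=True, order=True)
class Variant:
    """A single-nucleotide substitution in the coding sequence (1-based)."""

    cds_pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if not 1 <= self.cds_pos <= CDS_LENGTH:
            raise ValueError(
                f"cds_pos {self.cds_pos} outside CDS 1..{CDS_LENGTH}"
            )
        if self.ref_base not in _NUCLEOTIDES or self.alt_base not in _NUCLEOTIDES:
            raise ValueError(f"bases must be A/C/G/T, got {self.ref_base}>{self.alt_base}")
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref and alt identical at c.{self.cds_pos}")


# HGVS coding-DNA substitution grammar: <ref_id>:c.<pos><ref>><alt>
_HGVS_SUB = re.compile(r"^(?:(?P<ref>[A-Za-z0-9_.]+):)?c\.(?P<pos>\d+)(?P<from>[ACGT])>(?P<to>[ACGT])$")
_HGVS_UNSUPPORTED = re.compile(r"(del|dup|ins|inv)", re.IGNORECASE)


class HgvsSyntaxError(ValueError):
    """Raised for HGVS expressions outside the substitution grammar."""


def hgvs_format(v: Variant, reference_id: str = REFERENCE_ID) -> str:
    """Format a substitution as ``NM_016124.6:c.809T>G``."""
    return f"{reference_id}:c.{v.cds_pos}{v.ref_base}>{v.alt_base}"


def hgvs_parse(s: str) -> Variant:
    """Parse an HGVS c. substitution string into a :class:`Variant`.

    Only simple substitutions are supported; indels, duplications and
    other events raise :class:`HgvsSyntaxError`.
    """
    m = _HGVS_SUB.match(s.strip())
    if m is None:
        if _HGVS_UNSUPPORTED.search(s):
            raise HgvsSyntaxError(f"unsupported HGVS event (only substitutions handled): {s!r}")
        raise HgvsSyntaxError(f"not a valid HGVS c. substitution: {s!r}")
    return Variant(int(m.group("pos")), m.group("from"), m.group("to"))


@dataclass(frozen=True)
class AlleleDefinition:
    """An ISBT RHD allele with its defining CDS variants and phenotype."""

    name: str
    defining_variants: frozenset[Variant]
    structural_class: StructuralClass
    dropped_exons: frozenset[int]
    category: Category
    phenotype_label: str
    defining_exon: Mapping[Variant, int] = field(default_factory=dict)
    rs_ids: Mapping[Variant, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.structural_class is StructuralClass.GENE_ABSENT and self.defining_variants:
            raise ValueError(f"{self.name}: GENE_ABSENT alleles carry no defining variants")
        if self.structural_class is StructuralClass.EXON_DROPOUT:
            if not self.dropped_exons:
                raise ValueError(f"{self.name}: EXON_DROPOUT requires dropped exons")
            exons = sorted(self.dropped_exons)
            if exons != list(range(exons[0], exons[-1] + 1)):
                raise ValueError(f"{self.name}: dropped exons must be contiguous, got {exons}")
        elif self.dropped_exons:
            raise ValueError(f"{self.name}: dropped_exons only valid for EXON_DROPOUT")


REFERENCE_ALLELE = "RHD*01"
DELETION_ALLELE = "RHD*01N.01"
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class AlleleCall:
    """Result of matching an observed variant set against the database.

    ``allele_pair`` is ordered; the second entry is ``"unresolved"`` when
    hemizygosity cannot be excluded from sequence data alone.  For
    ``novel_candidate`` calls the unmatched variants are carried verbatim.
    """

    allele_pair: tuple[str, str]
    confidence_note: Confidence
    unmatched: tuple[tuple[Variant, Zygosity], ...] = ()
    phase_unknown: bool = False


class AlleleDatabaseError(ValueError):
    pass


class AlleleDatabase:
    """Lookup container for :class:`AlleleDefinition` records."""

    def __init__(self, alleles: Iterable[AlleleDefinition]):
        self._by_name: dict[str, AlleleDefinition] = {}
        for a in alleles:
            if a.name in self._by_name:
                raise AlleleDatabaseError(f"duplicate allele name {a.name!r}")
            self._by_name[a.name] = a

    def __getitem__(self, name: str) -> AlleleDefinition:
        try:
            return self._by_name[name]
        except KeyError:
            raise AlleleDatabaseError(f"unknown allele {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    @property
    def names(self) -> list[str]:
        return list(self._by_name)

    def variant_alleles(self) -> list[AlleleDefinition]:
        """Alleles defined by at least one CDS substitution."""
        return [a for a in self if a.defining_variants]

    def dropout_alleles(self) -> list[AlleleDefinition]:
        return [a for a in self if a.structural_class is StructuralClass.EXON_DROPOUT]

    def find_by_variant_set(self, variants: frozenset[Variant]) -> AlleleDefinition | None:
        for a in self:
            if a.defining_variants == variants and a.structural_class is StructuralClass.FULL_GENE:
                return a
        return None

    def find_by_dropout(self, absent_exons: frozenset[int]) -> AlleleDefinition | None:
        for a in self.dropout_alleles():
            if a.dropped_exons == absent_exons:
                return a
        return None

    def reference_base(self, cds_pos: int) -> str | None:
        """The reference base implied by the database at a CDS position."""
        for a in self:
            for v in a.defining_variants:
                if v.cds_pos == cds_pos:
                    return v.ref_base
        return None


def _parse_record(row: Mapping[str, str], index: int) -> AlleleDefinition:
    name = (row.get("allele_name") or "").strip()
    if not name:
        raise AlleleDatabaseError(f"record {index}: missing allele_name")
    try:
        variants = tuple(
            hgvs_parse(tok) for tok in (row.get("variants") or "").split(";") if tok.strip()
        )
        structural = StructuralClass((row.get("structural_class") or "FULL_GENE").strip())
        dropped = frozenset(
            int(tok) for tok in (row.get("dropped_exons") or "").split(",") if tok.strip()
        )
        category = Category((row.get("category") or "").strip())
        exon_toks = [tok for tok in (row.get("defining_exons") or "").split(",") if tok.strip()]
        rs_toks = [tok for tok in (row.get("rs_ids") or "").split(";") if tok.strip()]
        defining_exon = {v: int(e) for v, e in zip(variants, exon_toks)}
        rs_ids = {v: r.strip() for v, r in zip(variants, rs_toks)}
        return AlleleDefinition(
            name=name,
            defining_variants=frozenset(variants),
            structural_class=structural,
            dropped_exons=dropped,
            category=category,
            phenotype_label=(row.get("phenotype_label") or "").strip(),
            defining_exon=defining_exon,
            rs_ids=rs_ids,
        )
    except (ValueError, HgvsSyntaxError) as exc:
        raise AlleleDatabaseError(f"record {index} ({name!r}): {exc}") from exc


def load_allele_db(source: str | Path | Iterable[Mapping[str, str]] | None = None) -> AlleleDatabase:
    """Load an allele database from a delimited table.

    ``source`` may be a path to a tab-delimited file or an iterable of
    dict records; ``None`` loads the packaged default table.
    """
    if source is None:
        with resources.files("rhdtype.data").joinpath("alleles.tsv").open() as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    elif isinstance(source, (str, Path)):
        with open(source, newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    else:
        rows = list(source)
    return AlleleDatabase(_parse_record(row, i) for i, row in enumerate(rows))


def match_variants(
    observed: Iterable[tuple[Variant, Zygosity]],
    db: AlleleDatabase,
) -> AlleleCall:
    """Assign an allele pair to an observed set of CDS substitutions.

    The rule is exact-match against the database: an allele matches when
    its defining variant set equals the portion of the observed set
    attributable to one haplotype.  A lone heterozygous variant is placed
    in trans to the unaltered reference allele; an empty observed set is
    the reference allele in a homozygous-or-hemizygous state (the second
    haplotype left unresolved).  Combinations absent from the database are
    reported as novel candidates, never raised.
    """
    obs = sorted(set(observed))
    if not obs:
        return AlleleCall((REFERENCE_ALLELE, UNRESOLVED), Confidence.EXACT_MATCH)

    hom = frozenset(v for v, z in obs if z is Zygosity.HOM)
    het = frozenset(v for v, z in obs if z is Zygosity.HET)

    if not het:
        allele = db.find_by_variant_set(hom)
        if allele is not None:
            return AlleleCall((allele.name, UNRESOLVED), Confidence.EXACT_MATCH)
        return AlleleCall(
            ("novel", UNRESOLVED), Confidence.NOVEL_CANDIDATE, unmatched=tuple(obs)
        )

    if not hom and len(het) == 1:
        allele = db.find_by_variant_set(het)
        if allele is not None:
            # single-direction Sanger cannot phase, but a lone het variant
            # implies the alternate haplotype is reference at that site
            return AlleleCall(
                (allele.name, REFERENCE_ALLELE), Confidence.HET_PHASE_ASSUMED
            )

    # multi-het or mixed hom/het combinations are not phased
    return AlleleCall(
        ("novel", UNRESOLVED),
        Confidence.NOVEL_CANDIDATE,
        unmatched=tuple(obs),
        phase_unknown=len(het) > 0,
    )
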