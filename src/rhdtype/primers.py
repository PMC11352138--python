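"""Oligonucleotide definitions for the SSP genotyping assays and the
exon 1-10 amplification reactions.

Primer sequences preserve the published case convention: lowercase
characters sit in introns, uppercase characters in exons.  Sequencing
primers are M13-tailed; the tail is recognised by its fixed prefix and is
excluded from template matching but appended to amplification products.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from importlib import resources

M13_TAIL = "CAGGAAACAGCTATGAC"  # M13 forward (-21) universal primer

_COMPLEMENT = str.maketrans("ACGTRYKMSWN", "TGCAYRMKSWN")


def revcomp(seq: str) -> str:
    """Reverse complement, tolerating IUPAC two-base codes."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


class PrimerRole(Enum):
    ALLELE_SPECIFIC = "allele_specific"
    CONSENSUS = "consensus"
    CONTROL = "control"
    EXON_AMPLIFICATION = "exon_amplification"


@dataclass(frozen=True)
class Primer:
    """A PCR primer with case-preserved sequence and optional M13 tail."""

    primer_id: str
    sequence: str  # 5'->3', case as published
    concentration: float  # µM, annotation only
    role: PrimerRole
    tail: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 15:
            raise ValueError(f"{self.primer_id}: primer shorter than 15 nt")
        if not set(self.sequence.upper()) <= set("ACGTRYKMSWN"):
            raise ValueError(f"{self.primer_id}: non-IUPAC characters")

    @property
    def core(self) -> str:
        """Template-matching portion (tail stripped), uppercase."""
        return self.sequence.upper()[len(self.tail):]

    @property
    def exonic_part(self) -> str:
        """Uppercase (exonic) run of the core, empty if none."""
        body = self.sequence[len(self.tail):]
        return "".join(c for c in body if c.isupper())

    @property
    def intronic_part(self) -> str:
        body = self.sequence[len(self.tail):]
        return "".join(c.upper() for c in body if c.islower())


def _mk(primer_id: str, seq: str, conc: str, role: PrimerRole) -> Primer:
    tail = M13_TAIL if seq.upper().startswith(M13_TAIL) and primer_id.endswith("_M13") else ""
    return Primer(primer_id, seq, float(conc), role, tail=tail)


@dataclass(frozen=True)
class SspAssayDef:
    """One allele-specific PCR assay with its co-amplified control pair."""

    assay_name: str
    target_allele: str
    rs_id: str
    fwd: Primer
    rev: Primer
    target_tm: float
    ctrl_fwd: Primer
    ctrl_rev: Primer
    control_tm: float
    discriminating_end: str  # "fwd" or "rev"


@dataclass(frozen=True)
class ExonAssayDef:
    """Primer pair amplifying one exon with its melt standard."""

    exon: int
    fwd: Primer
    rev: Primer
    tm: float

    @property
    def tailed_primer(self) -> str:
        """Which primer carries the sequencing tail ('fwd' or 'rev')."""
        return "fwd" if self.fwd.tail else "rev"


def load_ssp_assays() -> list[SspAssayDef]:
    with resources.files("rhdtype.data").joinpath("ssp_assays.tsv").open() as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    assays = []
    for r in rows:
        disc = r["discriminating_end"]
        fwd_role = PrimerRole.ALLELE_SPECIFIC if disc == "fwd" else PrimerRole.CONSENSUS
        rev_role = PrimerRole.ALLELE_SPECIFIC if disc == "rev" else PrimerRole.CONSENSUS
        assays.append(
            SspAssayDef(
                assay_name=r["assay_name"],
                target_allele=r["target_allele"],
                rs_id=r["rs_id"],
                fwd=_mk(r["fwd_id"], r["fwd_seq"], r["fwd_conc_um"], fwd_role),
                rev=_mk(r["rev_id"], r["rev_seq"], r["rev_conc_um"], rev_role),
                target_tm=float(r["target_tm_c"]),
                ctrl_fwd=_mk(r["ctrl_fwd_id"], r["ctrl_fwd_seq"], r["ctrl_conc_um"], PrimerRole.CONTROL),
                ctrl_rev=_mk(r["ctrl_rev_id"], r["ctrl_rev_seq"], r["ctrl_conc_um"], PrimerRole.CONTROL),
                control_tm=float(r["ctrl_tm_c"]),
                discriminating_end=disc,
            )
        )
    return assays


def load_exon_assays() -> list[ExonAssayDef]:
    with resources.files("rhdtype.data").joinpath("exon_assays.tsv").open() as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return [
        ExonAssayDef(
            exon=int(r["exon"]),
            fwd=_mk(r["fwd_id"], r["fwd_seq"], r["fwd_conc_um"], PrimerRole.EXON_AMPLIFICATION),
            rev=_mk(r["rev_id"], r["rev_seq"], r["rev_conc_um"], PrimerRole.EXON_AMPLIFICATION),
            tm=float(r["tm_c"]),
        )
        for r in rows
    ]
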