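"""In-silico allele-specific PCR and melting-curve genotyping.

Sequence-specific priming is modelled categorically: a primer pair yields
a product if and only if both primers find a convergently oriented site
whose 3'-terminal base matches exactly, total mismatches elsewhere stay
within the configured budget (default 0), and the product is no longer
than ``max_len``.  Melt curves are synthesised as sums of Gaussian peaks
in -dF/dT placed at each product's assigned melting temperature;
classification matches called peaks to configured genotyping standards.
The printed instrument Tm standards are authoritative for classification;
the nearest-neighbor thermodynamic estimate is a diagnostic only, since
the empirical values depend on buffer and dye conditions that no
calculation reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp
from scipy.signal import find_peaks

from .primers import ExonAssayDef, Primer, SspAssayDef, revcomp

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import SampleGenotype

MAX_AMPLICON_LEN = 1500
MELT_GRID = (70.0, 95.0)  # instrument melting window, °C
MELT_STEP = 0.1
PEAK_SIGMA = 0.8  # °C, synthetic peak width
TARGET_AMPLITUDE = 1.0
CONTROL_AMPLITUDE = 0.6
PEAK_HEIGHT_THRESHOLD = 0.1
DEFAULT_TOLERANCE = 1.0  # °C, melt-standard matching window

UNCLASSIFIED = "unclassified_peak"


class AssayConfigError(ValueError):
    """Raised when melt standards cannot be discriminated at the tolerance."""


@dataclass(frozen=True)
class Assay:
    """A configured SSP genotyping assay (target pair + control pair)."""

    assay_name: str
    target_allele: str
    target_pair: tuple[Primer, Primer]
    control_pair: tuple[Primer, Primer]
    target_tm: float
    control_tm: float
    discriminating_end: str
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if abs(self.target_tm - self.control_tm) <= 2 * self.tolerance:
            raise AssayConfigError(
                f"{self.assay_name}: target Tm {self.target_tm} and control Tm "
                f"{self.control_tm} not separated by > 2 x {self.tolerance} °C"
            )

    @property
    def standards(self) -> dict[str, float]:
        return {self.target_allele: self.target_tm, "control": self.control_tm}

    @classmethod
    def from_def(cls, d: SspAssayDef, tolerance: float = DEFAULT_TOLERANCE) -> "Assay":
        return cls(
            assay_name=d.assay_name,
            target_allele=d.target_allele,
            target_pair=(d.fwd, d.rev),
            control_pair=(d.ctrl_fwd, d.ctrl_rev),
            target_tm=d.target_tm,
            control_tm=d.control_tm,
            discriminating_end=d.discriminating_end,
            tolerance=tolerance,
        )


@dataclass(frozen=True)
class MeltCurve:
    """-dF/dT profile over the melting window with called peaks."""

    temperatures: np.ndarray
    signal: np.ndarray
    peaks: tuple[tuple[float, float], ...]  # (peak Tm °C, height)

    @property
    def peak_tms(self) -> tuple[float, ...]:
        return tuple(tm for tm, _ in self.peaks)


@dataclass(frozen=True)
class SSPResult:
    assay_name: str
    call: str  # POSITIVE / NEGATIVE / INVALID
    observed_tms: tuple[float, ...]
    genotype_label: str
    curve: MeltCurve


@dataclass(frozen=True)
class ExonAmplificationProfile:
    """Presence/absence of the ten exon amplicons for one sample."""

    sample_id: str
    present: frozenset[int]
    observed_tms: dict[int, float]

    @property
    def absent(self) -> frozenset[int]:
        return frozenset(range(1, 11)) - self.present

    @property
    def all_present(self) -> bool:
        return len(self.present) == 10

    @property
    def all_absent(self) -> bool:
        return not self.present


# ---------------------------------------------------------------------------
# amplification


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _plus_sites(template: str, core: str, budget: int) -> list[int]:
    """Start positions where the primer anneals to the minus strand and
    extends rightward along the plus strand (site read equals the primer);
    the 3'-terminal base (last position) must match exactly."""
    n, L = len(template), len(core)
    out = []
    if budget == 0:
        start = 0
        while (i := template.find(core, start)) != -1:
            out.append(i)
            start = i + 1
        return out
    for i in range(n - L + 1):
        window = template[i : i + L]
        if window[-1] == core[-1] and _mismatches(window[:-1], core[:-1]) <= budget:
            out.append(i)
    return out


def _minus_sites(template: str, core: str, budget: int) -> list[int]:
    """Start positions of plus-strand windows equal to revcomp(core); the
    primer's 3' end maps to the window's first base."""
    rc = revcomp(core)
    n, L = len(template), len(core)
    out = []
    if budget == 0:
        start = 0
        while (i := template.find(rc, start)) != -1:
            out.append(i)
            start = i + 1
        return out
    for i in range(n - L + 1):
        window = template[i : i + L]
        if window[0] == rc[0] and _mismatches(window[1:], rc[1:]) <= budget:
            out.append(i)
    return out


def find_amplicon(
    template: str | None,
    fwd: Primer,
    rev: Primer,
    max_len: int = MAX_AMPLICON_LEN,
    mismatch_budget: int = 0,
) -> str | None:
    """Return the PCR product of a primer pair on a template, or ``None``.

    Both convergent orientations are searched (forward primer on either
    strand).  When several products are possible the shortest one wins,
    ties broken leftmost; M13 tails are excluded from matching but
    appended to the product.
    """
    if not template:
        return None
    template = template.upper()
    candidates: list[tuple[int, int, str]] = []  # (length, start, product)

    def collect(left: Primer, right: Primer, flip: bool) -> None:
        for a in _plus_sites(template, left.core, mismatch_budget):
            for b in _minus_sites(template, right.core, mismatch_budget):
                end = b + len(right.core)
                if a <= b and end - a <= max_len and end - a >= max(len(left.core), len(right.core)):
                    segment = template[a:end]
                    if flip:
                        product = right.tail + revcomp(segment) + revcomp(left.tail)
                    else:
                        product = left.tail + segment + revcomp(right.tail)
                    candidates.append((end - a, a, product))

    collect(fwd, rev, flip=False)
    collect(rev, fwd, flip=True)
    if not candidates:
        return None
    candidates.sort(key=lambda t: (t[0], t[1]))
    return candidates[0][2]


# ---------------------------------------------------------------------------
# melt curves


def synthesize_melt_curve(
    products: Sequence[tuple[str, float, float]],
) -> MeltCurve:
    """Sum of Gaussian -dF/dT peaks, one per (sequence, Tm, amplitude)."""
    temps = np.arange(MELT_GRID[0], MELT_GRID[1] + MELT_STEP / 2, MELT_STEP)
    signal = np.zeros_like(temps)
    for _seq, tm, amplitude in products:
        signal += amplitude * np.exp(-0.5 * ((temps - tm) / PEAK_SIGMA) ** 2)
    idx, props = find_peaks(signal, height=PEAK_HEIGHT_THRESHOLD)
    peaks = tuple(
        (float(temps[i]), float(h)) for i, h in zip(idx, props["peak_heights"])
    )
    return MeltCurve(temperatures=temps, signal=signal, peaks=peaks)


def validate_standards(standards: dict[str, float], tolerance: float) -> None:
    labels = sorted(standards, key=standards.get)
    for a, b in zip(labels, labels[1:]):
        if abs(standards[a] - standards[b]) <= 2 * tolerance:
            raise AssayConfigError(
                f"standards {a!r} ({standards[a]}) and {b!r} ({standards[b]}) "
                f"are not separated by > 2 x {tolerance} °C"
            )


def classify_melt(
    curve: MeltCurve,
    standards: dict[str, float],
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[str]:
    """Match each called peak to the nearest standard within tolerance.

    Peaks outside every standard's window are labelled
    ``unclassified_peak``.  Ambiguous standard sets are a configuration
    error, raised before any sample is classified.
    """
    validate_standards(standards, tolerance)
    labels = []
    for tm in curve.peak_tms:
        best = min(standards, key=lambda lab: abs(standards[lab] - tm), default=None)
        if best is not None and abs(standards[best] - tm) <= tolerance:
            labels.append(best)
        else:
            labels.append(UNCLASSIFIED)
    return labels


# ---------------------------------------------------------------------------
# assays


def run_ssp_assay(
    sample: "SampleGenotype",
    assay: Assay,
    mismatch_budget: int = 0,
) -> SSPResult:
    """Run one allele-specific assay on a diploid sample.

    The target peak appears if either haplotype amplifies; the internal
    control amplifies from the sample's control locus, so a template-
    bearing sample can never be INVALID.
    """
    products: list[tuple[str, float, float]] = []
    for hap in sample.haplotypes:
        amp = find_amplicon(hap.sequence, *assay.target_pair, mismatch_budget=mismatch_budget)
        if amp is not None:
            products.append((amp, assay.target_tm, TARGET_AMPLITUDE))
            break
    ctrl = find_amplicon(sample.control_sequence, *assay.control_pair, mismatch_budget=mismatch_budget)
    if ctrl is not None:
        products.append((ctrl, assay.control_tm, CONTROL_AMPLITUDE))
    curve = synthesize_melt_curve(products)
    labels = classify_melt(curve, assay.standards, assay.tolerance)
    target_seen = assay.target_allele in labels
    control_seen = "control" in labels
    if target_seen:
        call, label = "POSITIVE", assay.target_allele
    elif control_seen:
        call, label = "NEGATIVE", f"non-{assay.target_allele}"
    else:
        call, label = "INVALID", "invalid"
    return SSPResult(
        assay_name=assay.assay_name,
        call=call,
        observed_tms=curve.peak_tms,
        genotype_label=label,
        curve=curve,
    )


def amplify_exons(
    sample: "SampleGenotype",
    exon_assays: Iterable[ExonAssayDef],
    tolerance: float = DEFAULT_TOLERANCE,
    mismatch_budget: int = 0,
) -> ExonAmplificationProfile:
    """Run the ten exon amplification reactions and score presence.

    An exon is present iff at least one haplotype yields a product and
    the product's melt peak matches the exon's Tm standard.
    """
    present: set[int] = set()
    tms: dict[int, float] = {}
    for ea in exon_assays:
        amp = None
        for hap in sample.haplotypes:
            amp = find_amplicon(hap.sequence, ea.fwd, ea.rev, mismatch_budget=mismatch_budget)
            if amp is not None:
                break
        if amp is None:
            continue
        curve = synthesize_melt_curve([(amp, ea.tm, TARGET_AMPLITUDE)])
        labels = classify_melt(curve, {f"exon{ea.exon}": ea.tm}, tolerance)
        if f"exon{ea.exon}" in labels:
            present.add(ea.exon)
            tms[ea.exon] = curve.peak_tms[0]
    return ExonAmplificationProfile(sample.sample_id, frozenset(present), tms)


def estimate_tm(amplicon: str, Na: float = 50.0) -> float:
    """Nearest-neighbor melting-temperature estimate with salt correction.

    Diagnostic only: genotype classification always uses the configured
    empirical standards.
    """
    if not amplicon:
        raise ValueError("empty sequence")
    if not set(amplicon.upper()) <= set("ACGT"):
        raise ValueError("sequence contains non-ACGT symbols")
    return float(MeltingTemp.Tm_NN(amplicon.upper(), Na=Na))
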