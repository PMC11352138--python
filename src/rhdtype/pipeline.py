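"""Two-stage typing orchestration: SSP screening, exon-profile triage,
sequence-based typing of the remainder, and final allele/phenotype
assignment with per-well reporting.

Two run modes mirror laboratory practice versus evaluation design:

* ``routine`` — a sample positive in any SSP assay is reported directly
  from that assay and undergoes no further characterisation.
* ``study`` — every amplifiable sample is sequenced regardless of the
  SSP outcome, allowing concordance between the two stages to be
  checked; a discordance raises a flag, never an exception.

Triage from the exon profile: no amplification of any exon suggests the
whole-gene deletion; a contiguous absent block matching a known hybrid
allele's dropped exons suggests that allele.  Both structural suspicions
require confirmatory exon-specific PCR that this pipeline does not
simulate, so they carry a confirmation-required flag.  A negative SSP
result never contributes to a genotype claim on its own: deletion and
hybrid calls cite the exon profile as evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .alleles import (
    AlleleCall,
    AlleleDatabase,
    Confidence,
    DELETION_ALLELE,
    REFERENCE_ALLELE,
    UNRESOLVED,
)
from .genemodel import GeneModel
from .sbt import VariantCall, call_variants, summarize_cds
from .simulate import (
    CLEAN_PROFILE,
    QVProfile,
    SampleGenotype,
    TraceRead,
    simulate_trace,
    trace_seed,
)
from .ssp import (
    Assay,
    ExonAmplificationProfile,
    SSPResult,
    amplify_exons,
    run_ssp_assay,
    synthesize_melt_curve,
)
from .primers import ExonAssayDef

FLAG_CONFIRMATION_REQUIRED = "confirmation_required"
FLAG_DISCORDANT = "discordant"
FLAG_UNEXPLAINED_DROPOUT = "unexplained_dropout"
FLAG_INCOMPLETE_COVERAGE = "incomplete_coverage"


class Route(Enum):
    REPORT_FROM_SSP = "REPORT_FROM_SSP"
    SUSPECT_DELETION = "SUSPECT_DELETION"
    SUSPECT_HYBRID = "SUSPECT_HYBRID"
    SEQUENCE = "SEQUENCE"


@dataclass(frozen=True)
class TriageDecision:
    route: Route
    allele_name: str | None = None  # for REPORT_FROM_SSP / SUSPECT_* routes
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class TypingReport:
    """Per-sample end-to-end result; every field traces to an upstream
    stage output."""

    sample_id: str
    route: Route
    ssp_calls: Mapping[str, str]  # assay name -> POSITIVE/NEGATIVE
    ssp_labels: Mapping[str, str]
    observed_tms: Mapping[str, tuple[float, ...]]
    exon_profile: ExonAmplificationProfile | None
    hgvs_summary: str | None
    variant_calls: tuple[VariantCall, ...]
    allele_pair: tuple[str, str]
    genotype: str
    phenotype: str
    flags: tuple[str, ...]
    well_position: str | None = None


@dataclass
class RunSummary:
    n_samples: int
    route_counts: dict[str, int]
    genotype_counts: dict[str, int]
    n_chromatograms: int
    ntc_clean: bool
    mode: str

    @property
    def run_valid(self) -> bool:
        return self.ntc_clean


class RunInvalidError(RuntimeError):
    """No-template control showed amplification; whole run is invalid."""


def triage(
    ssp_results: Sequence[SSPResult],
    profile: ExonAmplificationProfile,
    db: AlleleDatabase,
    mode: str = "routine",
) -> TriageDecision:
    """Route a sample after the SSP stage and the exon screen."""
    if mode not in ("routine", "study"):
        raise ValueError(f"unknown mode {mode!r}")
    if any(r.call == "INVALID" for r in ssp_results):
        raise RunInvalidError("INVALID SSP result in a clean run")
    positives = [r for r in ssp_results if r.call == "POSITIVE"]
    if mode == "routine" and positives:
        return TriageDecision(Route.REPORT_FROM_SSP, allele_name=positives[0].genotype_label)
    if profile.all_absent:
        return TriageDecision(
            Route.SUSPECT_DELETION,
            allele_name=DELETION_ALLELE,
            flags=(FLAG_CONFIRMATION_REQUIRED,),
        )
    if not profile.all_present:
        hybrid = db.find_by_dropout(profile.absent)
        if hybrid is not None:
            return TriageDecision(
                Route.SUSPECT_HYBRID,
                allele_name=hybrid.name,
                flags=(FLAG_CONFIRMATION_REQUIRED,),
            )
        return TriageDecision(Route.SEQUENCE, flags=(FLAG_UNEXPLAINED_DROPOUT,))
    return TriageDecision(Route.SEQUENCE)


def _genotype_string(pair: tuple[str, str]) -> str:
    a, b = pair
    if b in (UNRESOLVED, a) or b == "":
        return a
    return f"{a}/{b}"


def _phenotype(pair: tuple[str, str], db: AlleleDatabase) -> str:
    a, b = pair
    if a not in db:
        return "unknown"
    label = db[a].phenotype_label
    if b == REFERENCE_ALLELE and a != REFERENCE_ALLELE:
        return f"{label} het."
    return label


def type_sample(
    sample: SampleGenotype,
    ssp_results: Sequence[SSPResult],
    profile: ExonAmplificationProfile | None,
    decision: TriageDecision,
    db: AlleleDatabase,
    model: GeneModel,
    traces: Sequence[TraceRead] | None = None,
    qv_threshold: int = 20,
    well_position: str | None = None,
) -> TypingReport:
    """Assemble the final per-sample report from all stage outputs."""
    flags = list(decision.flags)
    hgvs = None
    vcalls: tuple[VariantCall, ...] = ()
    if decision.route is Route.SEQUENCE:
        if traces is None:
            raise ValueError(f"{sample.sample_id}: SEQUENCE route requires traces")
        calls, coverage = call_variants(traces, model, qv_threshold)
        vcalls = tuple(calls)
        hgvs = summarize_cds(calls, coverage)
        if not coverage.complete:
            flags.append(FLAG_INCOMPLETE_COVERAGE)
        observed = [(c.variant, c.zygosity) for c in calls]
        allele_call: AlleleCall = _match(observed, db)
        pair = allele_call.allele_pair
        if allele_call.confidence_note is Confidence.NOVEL_CANDIDATE:
            flags.append("novel_candidate")
        # concordance between stages: a positive assay's allele must appear
        # in the sequencing-derived pair
        for r in ssp_results:
            if r.call == "POSITIVE" and r.genotype_label not in pair:
                flags.append(FLAG_DISCORDANT)
                break
    elif decision.route is Route.REPORT_FROM_SSP:
        pair = (decision.allele_name, UNRESOLVED)
    else:  # structural suspicion routes
        pair = (decision.allele_name, decision.allele_name)
        # a positive SSP alongside a structural suspicion is contradictory
        if any(r.call == "POSITIVE" for r in ssp_results):
            flags.append(FLAG_DISCORDANT)
    return TypingReport(
        sample_id=sample.sample_id,
        route=decision.route,
        ssp_calls={r.assay_name: r.call for r in ssp_results},
        ssp_labels={r.assay_name: r.genotype_label for r in ssp_results},
        observed_tms={r.assay_name: r.observed_tms for r in ssp_results},
        exon_profile=profile,
        hgvs_summary=hgvs,
        variant_calls=vcalls,
        allele_pair=pair,
        genotype=_genotype_string(pair),
        phenotype=_phenotype(pair, db),
        flags=tuple(flags),
        well_position=well_position,
    )


def _match(observed, db: AlleleDatabase) -> AlleleCall:
    from .alleles import match_variants

    return match_variants(observed, db)


def run_ntc(assays: Sequence[Assay]) -> bool:
    """Run the no-template control through every assay; True iff clean.

    The NTC well carries the control primers but no template of any
    kind, so a clean run shows zero melt peaks in every reaction.
    """
    clean = True
    for _assay in assays:
        curve = synthesize_melt_curve([])
        if curve.peaks:
            clean = False
    return clean


def run_panel(
    panel: Sequence[SampleGenotype],
    model: GeneModel,
    db: AlleleDatabase,
    ssp_assays: Sequence[Assay],
    exon_assays: Sequence[ExonAssayDef],
    mode: str = "study",
    seed: int = 0,
    qv_profile: QVProfile = CLEAN_PROFILE,
    qv_threshold: int = 20,
    traces_by_sample: Mapping[str, Sequence[TraceRead]] | None = None,
) -> tuple[list[TypingReport], RunSummary]:
    """Type every sample of a panel and tally the run.

    Traces for sequencing-routed samples are simulated from ``seed``
    unless pre-generated traces are supplied.  The chromatogram count is
    the number of reads actually evaluated by the sequencing stage.
    """
    ntc_clean = run_ntc(ssp_assays)
    if not ntc_clean:
        raise RunInvalidError("no-template control shows amplification")
    reports: list[TypingReport] = []
    n_chromatograms = 0
    for sample in panel:
        ssp_results = [run_ssp_assay(sample, a) for a in ssp_assays]
        positives = [r for r in ssp_results if r.call == "POSITIVE"]
        if mode == "routine" and positives:
            profile = None
            decision = triage(ssp_results, _EMPTY_PROFILE_SENTINEL, db, mode="routine")
        else:
            profile = amplify_exons(sample, exon_assays)
            decision = triage(ssp_results, profile, db, mode=mode)
        traces = None
        if decision.route is Route.SEQUENCE:
            if traces_by_sample is not None and sample.sample_id in traces_by_sample:
                traces = list(traces_by_sample[sample.sample_id])
            else:
                traces = [
                    simulate_trace(
                        sample,
                        exon,
                        model,
                        qv_profile,
                        seed=trace_seed(seed, sample.sample_id, exon),
                    )
                    for exon in sorted(profile.present)
                ]
            n_chromatograms += len(traces)
        reports.append(
            type_sample(
                sample,
                ssp_results,
                profile,
                decision,
                db,
                model,
                traces=traces,
                qv_threshold=qv_threshold,
            )
        )
    route_counts: dict[str, int] = {}
    genotype_counts: dict[str, int] = {}
    for r in reports:
        route_counts[r.route.value] = route_counts.get(r.route.value, 0) + 1
        genotype_counts[r.genotype] = genotype_counts.get(r.genotype, 0) + 1
    summary = RunSummary(
        n_samples=len(reports),
        route_counts=route_counts,
        genotype_counts=genotype_counts,
        n_chromatograms=n_chromatograms,
        ntc_clean=ntc_clean,
        mode=mode,
    )
    return reports, summary


# routine-mode SSP positives skip the exon screen entirely; triage still
# wants a profile argument, so hand it an all-present placeholder that the
# positive branch returns before inspecting
_EMPTY_PROFILE_SENTINEL = ExonAmplificationProfile(
    "_ssp_positive", frozenset(range(1, 11)), {}
)
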