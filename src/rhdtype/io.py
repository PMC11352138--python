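"""File formats tying the pipeline stages into reproducible runs.

Everything is plain text: FASTA for reference and haplotypes, FASTQ for
simulated traces (IUPAC codes permitted in the base line), tab/comma
delimited tables for annotations, truth, plate orders and reports.  All
writers are deterministic for a fixed configuration so reruns are
byte-identical.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alleles import AlleleDatabase
from .genemodel import GeneModel, Site
from .pipeline import TypingReport
from .simulate import SampleGenotype, Haplotype, TraceRead

PLATE_COLUMNS = ["well_position", "sample_id", "assay_name", "run_profile_name", "sample_role"]
PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = 12


# -- reference ---------------------------------------------------------


def export_reference(model: GeneModel, fasta_path: Path, annot_path: Path) -> None:
    records = [
        SeqRecord(Seq(model.genomic_sequence), id="RHD_synthetic", description="synthetic RHD locus"),
        SeqRecord(Seq(model.control_sequence), id="control_locus", description="synthetic internal-control locus"),
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    with open(annot_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow([f"#seed={model.seed}"])
        for i, (s, e) in enumerate(model.exon_intervals, start=1):
            w.writerow(["exon", i, s, e, "+", ""])
        for pid, site in model.primer_sites.items():
            w.writerow(["primer", pid, site.start, site.end, site.strand, site.contig])


def load_reference(fasta_path: Path, annot_path: Path) -> GeneModel:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    exon_intervals: list[tuple[int, int]] = []
    primer_sites: dict[str, Site] = {}
    seed = None
    with open(annot_path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row:
                continue
            if row[0].startswith("#seed="):
                seed = int(row[0].split("=", 1)[1])
                continue
            kind = row[0]
            if kind == "exon":
                exon_intervals.append((int(row[2]), int(row[3])))
            elif kind == "primer":
                primer_sites[row[1]] = Site(row[5], int(row[2]), int(row[3]), row[4])
    from .primers import load_exon_assays

    exon_primer_ids = {e.exon: (e.fwd.primer_id, e.rev.primer_id) for e in load_exon_assays()}
    return GeneModel(
        genomic_sequence=seqs["RHD_synthetic"],
        control_sequence=seqs["control_locus"],
        exon_intervals=tuple(exon_intervals),
        primer_sites=primer_sites,
        exon_primer_ids=exon_primer_ids,
        seed=seed,
    )


# -- panel -------------------------------------------------------------


def export_panel(panel: Sequence[SampleGenotype], fasta_path: Path, truth_path: Path, seed: int) -> None:
    records = []
    for s in panel:
        for i, hap in enumerate(s.haplotypes, start=1):
            if hap.absent:
                continue
            records.append(
                SeqRecord(
                    Seq(hap.sequence),
                    id=f"{s.sample_id}|hap{i}|{hap.allele_name}",
                    description="",
                )
            )
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    with open(truth_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow([f"#seed={seed}"])
        w.writerow(["sample_id", "allele_a", "allele_b"])
        for s in panel:
            w.writerow([s.sample_id, *s.truth_allele_pair])


def load_panel(
    fasta_path: Path, truth_path: Path, db: AlleleDatabase, model: GeneModel
) -> list[SampleGenotype]:
    seqs: dict[tuple[str, int], tuple[str, str]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sid, hap, allele = rec.id.split("|")
        seqs[(sid, int(hap[3:]))] = (allele, str(rec.seq))
    samples = []
    with open(truth_path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    for sid, a, b in rows[1:]:
        haps = []
        for i, name in enumerate((a, b), start=1):
            allele = db[name]
            if (sid, i) in seqs:
                _, seq = seqs[(sid, i)]
                haps.append(Haplotype(name, seq, allele.dropped_exons))
            else:
                haps.append(Haplotype(name, None))
        samples.append(
            SampleGenotype(sid, (haps[0], haps[1]), (a, b), control_sequence=model.control_sequence)
        )
    return samples


# -- traces ------------------------------------------------------------


def export_traces(traces: Iterable[TraceRead], path: Path) -> None:
    records = []
    for t in traces:
        rec = SeqRecord(
            Seq(t.bases),
            id=f"{t.sample_id}|exon{t.exon}|{t.strand}|start={t.genomic_start}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = list(t.qvs)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def load_traces(path: Path) -> dict[str, list[TraceRead]]:
    out: dict[str, list[TraceRead]] = {}
    index = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            index += 1
            sid, exon_tok, strand, start_tok = rec.id.split("|")
            read = TraceRead(
                sample_id=sid,
                exon=int(exon_tok[4:]),
                bases=str(rec.seq),
                qvs=tuple(rec.letter_annotations["phred_quality"]),
                genomic_start=int(start_tok.split("=")[1]),
                strand=strand,
            )
            out.setdefault(sid, []).append(read)
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ near record {index + 1} in {path}: {exc}") from exc
    return out


# -- plate order -------------------------------------------------------


def well_labels() -> list[str]:
    return [f"{r}{c}" for r in PLATE_ROWS for c in range(1, PLATE_COLS + 1)]


def build_plate_order(
    sample_ids: Sequence[str],
    assay_names: Sequence[str],
    run_profile_name: str = "RHD_SSP_meltcurve",
    ntc_well: str = "H12",
) -> pd.DataFrame:
    """Assign sample x assay reactions to 96-well plates.

    Each plate carries a no-template control at ``ntc_well``; reactions
    overflow onto additional plates as needed (well labels gain a plate
    prefix from the second plate on).
    """
    labels = well_labels()
    if ntc_well not in labels:
        raise ValueError(f"NTC well {ntc_well!r} is not a 96-well label")
    reactions = [(sid, a) for sid in sample_ids for a in assay_names]
    rows = []
    plate, free = 1, [w for w in labels if w != ntc_well]
    slot = 0
    for sid, assay in reactions:
        if slot == len(free):
            rows.append(_plate_row(plate, ntc_well, "NTC", "NTC", run_profile_name))
            plate += 1
            slot = 0
        rows.append(_plate_row(plate, free[slot], sid, assay, run_profile_name, role="SAMPLE"))
        slot += 1
    rows.append(_plate_row(plate, ntc_well, "NTC", "NTC", run_profile_name))
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def _plate_row(plate: int, well: str, sid: str, assay: str, profile: str, role: str = "NTC") -> dict:
    label = well if plate == 1 else f"P{plate}-{well}"
    return {
        "well_position": label,
        "sample_id": sid,
        "assay_name": assay,
        "run_profile_name": profile,
        "sample_role": role,
    }


def write_plate_order(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"#seed={seed}\n")
        df.to_csv(fh, index=False)


def read_plate_order(path: Path) -> pd.DataFrame:
    with open(path, newline="") as fh:
        lines = fh.readlines()
    body = [ln for ln in lines if not ln.startswith("#")]
    reader = csv.DictReader(body)
    rows = []
    for i, row in enumerate(reader, start=2):
        if row.get("well_position") is None or any(row.get(c) in (None, "") for c in PLATE_COLUMNS):
            raise ValueError(f"malformed plate order line {i} in {path}")
        rows.append(row)
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


# -- reports -----------------------------------------------------------


def reports_to_frame(reports: Sequence[TypingReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        tms = {
            f"tm_{name}": ";".join(f"{t:.1f}" for t in tms)
            for name, tms in r.observed_tms.items()
        }
        rows.append(
            {
                "sample_id": r.sample_id,
                "well_position": r.well_position or "",
                "route": r.route.value,
                **{f"ssp_{k}": v for k, v in r.ssp_calls.items()},
                **tms,
                "exons_present": (
                    ";".join(map(str, sorted(r.exon_profile.present)))
                    if r.exon_profile is not None
                    else ""
                ),
                "hgvs_summary": r.hgvs_summary or "",
                "genotype": r.genotype,
                "phenotype": r.phenotype,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)


def write_report_csv(reports: Sequence[TypingReport], path: Path, seed: int) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"#seed={seed}\n")
        reports_to_frame(reports).to_csv(fh, index=False)


def write_run_summary(summary, path: Path, seed: int) -> None:
    payload = {
        "seed": seed,
        "mode": summary.mode,
        "n_samples": summary.n_samples,
        "route_counts": summary.route_counts,
        "genotype_counts": summary.genotype_counts,
        "n_chromatograms": summary.n_chromatograms,
        "ntc_clean": summary.ntc_clean,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
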