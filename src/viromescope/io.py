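"""Plain-text readers/writers for the pipeline's external formats.

FASTA goes through Biopython; tabular artifacts are TSV with fixed,
documented column orders so that two identical runs produce byte-identical
files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .triage import EVIDENCE_COLUMNS, ContigRecord, TriageDecision, ViralEvidence


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_evidence_tsv(evidence: list[ViralEvidence], path: str | Path) -> None:
    rows = [
        (
            ev.contig_id,
            ev.viral_gene_count,
            ev.microbial_gene_count,
            f"{ev.dvf_score:.6g}",
            f"{ev.dvf_pvalue:.6g}",
            int(ev.vibrant_viral),
            ev.checkv_quality,
            ev.busco_hits,
            ev.total_genes,
        )
        for ev in evidence
    ]
    pd.DataFrame(rows, columns=list(EVIDENCE_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_evidence_tsv(path: str | Path) -> dict[str, ViralEvidence]:
    table = pd.read_csv(path, sep="\t", dtype={"checkv_quality": str})
    missing = set(EVIDENCE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    out: dict[str, ViralEvidence] = {}
    for row in table.itertuples(index=False):
        ev = ViralEvidence(
            contig_id=str(row.contig_id),
            viral_gene_count=int(row.viral_genes),
            microbial_gene_count=int(row.microbial_genes),
            dvf_score=float(row.dvf_score),
            dvf_pvalue=float(row.dvf_pvalue),
            vibrant_viral=bool(int(row.vibrant)),
            checkv_quality=str(row.checkv_quality),
            busco_hits=int(row.busco_hits),
            total_genes=int(row.total_genes),
        )
        out[ev.contig_id] = ev
    return out


def write_decisions_tsv(decisions: list[TriageDecision], path: str | Path) -> None:
    pd.DataFrame(
        [(d.contig_id, d.verdict, ",".join(d.reasons)) for d in decisions],
        columns=["contig_id", "verdict", "reasons"],
    ).to_csv(path, sep="\t", index=False)


def write_design_tsv(design, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(design.sample_ids), "group": list(design.labels)}
    ).to_csv(path, sep="\t", index=False)


def read_design_tsv(path: str | Path):
    from .synthetic import StudyDesign

    table = pd.read_csv(path, sep="\t")
    labels = sorted(table["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"design must have exactly two groups, got {labels}")
    # the lexicographically later label is treated as control only if the
    # canonical pair is present; otherwise first = case by convention
    if set(labels) == {"SLE", "Control"}:
        case, control = "SLE", "Control"
    else:
        case, control = labels[0], labels[1]
    return StudyDesign(
        tuple(table["sample"].astype(str)),
        tuple(table["group"].astype(str)),
        case_label=case,
        control_label=control,
    )


def contigs_from_fasta(path: str | Path, sample_id: str, mode: str) -> list[ContigRecord]:
    return [
        ContigRecord(id=name, sample_id=sample_id, mode=mode, length=len(seq),
                     sequence=seq)
        for name, seq in read_fasta(path).items()
    ]
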