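"""Readers and writers for the formats the pipeline touches.

GFF3 (1-based closed on disk) is converted to the package's 0-based
half-open convention on read and back on write; PSL is natively 0-based
half-open and is preserved as-is. GFF3 parsing goes through gffutils,
FASTA through Bio.SeqIO; PSL has no parser in the standard libraries and
is decoded here.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import DomainTable, GeneLocus, GenePrediction, GenomicInterval, TranscriptAlignment


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} map."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3


def _validate_gff3_columns(path: str | os.PathLike) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ncol = len(line.split("\t"))
            if ncol != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, found {ncol}")


def read_gff3(path: str | os.PathLike) -> list[GenePrediction]:
    """Read gene models from GFF3 (gene -> mRNA -> exon/CDS hierarchy).

    Coordinates are converted from GFF3's 1-based closed convention to
    0-based half-open. ``coding_length_nt`` is the summed CDS length when
    CDS features are present, otherwise the summed exon length.
    """
    _validate_gff3_columns(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    predictions = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = gene.id
        exons = []
        for exon in db.children(gene, featuretype="exon", order_by="start"):
            iv = GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand or ".")
            if iv.start < gene.start - 1 or iv.end > gene.end:
                raise ParseError(
                    f"gene {gene_id}: exon [{iv.start},{iv.end}) outside gene span "
                    f"[{gene.start - 1},{gene.end})"
                )
            exons.append(iv)
        if not exons:
            raise ParseError(f"gene {gene_id} has no exon features")
        cds_len = sum(c.end - (c.start - 1) for c in db.children(gene, featuretype="CDS"))
        predictions.append(
            GenePrediction(
                gene_id=gene_id,
                exons=exons,
                coding_length_nt=cds_len if cds_len > 0 else -1,
            )
        )
    return predictions


def write_gff3(predictions: list[GenePrediction], path: str | os.PathLike) -> None:
    """Write gene models as gene -> mRNA -> exon (+ CDS) GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in predictions:
            s = p.span
            strand = p.strand if p.strand in "+-" else "."
            fh.write(
                f"{s.scaffold_id}\tlocusfuse\tgene\t{s.start + 1}\t{s.end}\t.\t{strand}\t.\t"
                f"ID={p.gene_id}\n"
            )
            mrna_id = f"{p.gene_id}.t1"
            fh.write(
                f"{s.scaffold_id}\tlocusfuse\tmRNA\t{s.start + 1}\t{s.end}\t.\t{strand}\t.\t"
                f"ID={mrna_id};Parent={p.gene_id}\n"
            )
            for i, e in enumerate(p.exons, start=1):
                fh.write(
                    f"{e.scaffold_id}\tlocusfuse\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            # exons double as CDS in this dialect: coding length = exon sum
            for i, e in enumerate(p.exons, start=1):
                fh.write(
                    f"{e.scaffold_id}\tlocusfuse\tCDS\t{e.start + 1}\t{e.end}\t.\t{strand}\t0\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# PSL (BLAT's 21-column tab format, 0-based half-open)

_PSL_NCOL = 21


def _psl_int_list(field: str, name: str, lineno: int) -> list[int]:
    try:
        return [int(x) for x in field.rstrip(",").split(",") if x != ""]
    except ValueError as exc:
        raise ParseError(f"PSL line {lineno}: bad {name} field {field!r}") from exc


def read_psl(
    path: str | os.PathLike, best_alignment_only: bool = True
) -> list[TranscriptAlignment]:
    """Read 21-column PSL spliced alignments.

    Header banners ("psLayout", column-name and dash lines) are skipped.
    When ``best_alignment_only`` is set (the default) only the row with the
    most matching bases is kept for each transcript, so each reference
    transcript maps to the genome once; ties break deterministically on
    (target name, target start).
    """
    alignments: list[TranscriptAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or not line[0].isdigit():
                continue  # banner, column names, separator dashes
            fields = line.split("\t")
            if len(fields) != _PSL_NCOL:
                raise ParseError(
                    f"PSL line {lineno}: expected {_PSL_NCOL} columns, found {len(fields)}"
                )
            matches = int(fields[0])
            strand = fields[8]
            q_name = fields[9]
            q_size = int(fields[10])
            t_name = fields[13]
            block_count = int(fields[17])
            block_sizes = _psl_int_list(fields[18], "blockSizes", lineno)
            t_starts = _psl_int_list(fields[20], "tStarts", lineno)
            if len(block_sizes) != block_count or len(t_starts) != block_count:
                raise ParseError(
                    f"PSL line {lineno}: blockCount={block_count} but "
                    f"{len(block_sizes)} blockSizes / {len(t_starts)} tStarts"
                )
            strand_char = strand[-1] if strand and strand[-1] in "+-" else "+"
            blocks = [
                GenomicInterval(t_name, ts, ts + bs, strand_char)
                for ts, bs in zip(t_starts, block_sizes)
            ]
            alignments.append(
                TranscriptAlignment(
                    transcript_id=q_name,
                    scaffold_id=t_name,
                    blocks=blocks,
                    query_length=q_size,
                    matches=matches,
                    strand=strand_char,
                )
            )
    if best_alignment_only:
        best: dict[str, TranscriptAlignment] = {}
        for aln in alignments:
            cur = best.get(aln.transcript_id)
            if cur is None or (-aln.matches, aln.scaffold_id, aln.span.start) < (
                -cur.matches,
                cur.scaffold_id,
                cur.span.start,
            ):
                best[aln.transcript_id] = aln
        alignments = [a for a in alignments if best[a.transcript_id] is a]
    return alignments


def write_psl(alignments: list[TranscriptAlignment], path: str | os.PathLike) -> None:
    """Write 21-column PSL. Query-side coordinates assume the transcript
    aligns end-to-end minus mismatches (the synthetic generator's model)."""
    with open(path, "w") as fh:
        for a in alignments:
            aligned = sum(b.length for b in a.blocks)
            mismatches = aligned - a.matches
            block_sizes = ",".join(str(b.length) for b in a.blocks) + ","
            q_starts = []
            q = 0
            for b in a.blocks:
                q_starts.append(q)
                q += b.length
            q_starts_s = ",".join(str(x) for x in q_starts) + ","
            t_starts_s = ",".join(str(b.start) for b in a.blocks) + ","
            t_num_insert = len(a.blocks) - 1
            t_base_insert = sum(
                cur.start - prev.end for prev, cur in zip(a.blocks, a.blocks[1:])
            )
            row = [
                a.matches, mismatches, 0, 0,  # matches misMatches repMatches nCount
                0, 0, t_num_insert, t_base_insert,
                a.strand, a.transcript_id, a.query_length, 0, aligned,
                a.scaffold_id, a.blocks[-1].end, a.blocks[0].start, a.blocks[-1].end,
                len(a.blocks), block_sizes, q_starts_s, t_starts_s,
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Domain tables and locus reports


def read_domain_table(path: str | os.PathLike, genome_id: str) -> DomainTable:
    """Read a per-genome TSV of (gene_id, domain_id) hits; duplicate rows
    are retained as multiset entries."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "domain_id"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    hits = list(zip(df["gene_id"].tolist(), df["domain_id"].tolist()))
    return DomainTable(genome_id=genome_id, hits=hits)


def write_domain_table(table: DomainTable, path: str | os.PathLike) -> None:
    pd.DataFrame(table.hits, columns=["gene_id", "domain_id"]).to_csv(
        path, sep="\t", index=False
    )


LOCUS_TABLE_COLUMNS = [
    "locus_id",
    "scaffold",
    "start",
    "end",
    "n_predictions",
    "n_transcripts",
    "supported",
    "max_coding_length_aa",
    "prediction_ids",
    "transcript_ids",
]


def write_locus_table(loci: list[GeneLocus], path: str | os.PathLike) -> None:
    """Write the locus report TSV, rows ordered by (scaffold, start, locus_id)."""
    rows = [
        {
            "locus_id": lo.locus_id,
            "scaffold": lo.scaffold_id,
            "start": lo.span.start,
            "end": lo.span.end,
            "n_predictions": len(lo.prediction_ids),
            "n_transcripts": len(lo.transcript_ids),
            "supported": int(lo.supported),
            "max_coding_length_aa": lo.max_coding_length_aa,
            "prediction_ids": ",".join(lo.prediction_ids),
            "transcript_ids": ",".join(lo.transcript_ids),
        }
        for lo in sorted(loci, key=lambda lo: (lo.scaffold_id, lo.span.start, lo.locus_id))
    ]
    pd.DataFrame(rows, columns=LOCUS_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_locus_table(path: str | os.PathLike) -> list[GeneLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"prediction_ids": str, "transcript_ids": str})
    loci = []
    for row in df.itertuples(index=False):
        pred_ids = [] if pd.isna(row.prediction_ids) else str(row.prediction_ids).split(",")
        tx_ids = [] if pd.isna(row.transcript_ids) else str(row.transcript_ids).split(",")
        loci.append(
            GeneLocus(
                locus_id=row.locus_id,
                scaffold_id=row.scaffold,
                span=GenomicInterval(row.scaffold, int(row.start), int(row.end)),
                prediction_ids=[p for p in pred_ids if p],
                transcript_ids=[t for t in tx_ids if t],
                max_coding_length_aa=int(row.max_coding_length_aa),
            )
        )
    return loci


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
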