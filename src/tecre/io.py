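"""Readers and writers for the standard formats the pipeline consumes.

BED and narrowPeak are read as 0-based half-open; RepeatMasker ``.out`` and
GTF are 1-based inclusive on disk and converted on read (and back on write).
All readers are gzip-transparent; all writers emit tab-separated,
newline-terminated records.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Union

import gffutils
import pandas as pd
from Bio import SeqIO

from .intervals import (
    GeneModel,
    GenomicInterval,
    Peak,
    TEInstance,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _open_text(path: PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _norm_strand(s: str) -> str:
    # RepeatMasker marks the minus strand with 'C' (complement)
    return {"C": "-", "+": "+", "-": "-"}.get(s, ".")


def read_fasta(path: PathLike, alphabet: str = "nucleotide") -> dict[str, str]:
    """Read FASTA into ``{id: sequence}``, upper-cased; U->T in nucleotide mode.

    Duplicate ids raise, matching the assumption that ids key the mapping.
    """
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            seq = str(rec.seq).upper()
            if alphabet == "nucleotide":
                seq = seq.replace("U", "T")
            out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_bed_line(fields: list[str], lineno: int, path) -> tuple:
    if len(fields) < 3:
        raise ValueError(f"{path}: malformed BED line {lineno}: fewer than 3 fields")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed BED line {lineno}: {exc}") from exc
    name = fields[3] if len(fields) > 3 else ""
    strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
    score = fields[4] if len(fields) > 4 else "0"
    return fields[0], start, end, name, score, strand


def read_intervals(path: PathLike, format: str = "BED") -> list:
    """Read intervals from BED / narrowPeak / RepeatMasker .out / TSV.

    Returns TEInstances for BED (name column = family) and repeatmasker_out,
    Peaks for narrowPeak (signalValue column), and bare GenomicIntervals for
    TSV (columns chrom, start, end[, strand]). Input order is preserved; an
    empty file yields an empty list with a logged warning.
    """
    fmt = format.lower()
    if fmt not in {"bed", "narrowpeak", "repeatmasker_out", "tsv"}:
        raise ValueError(f"unknown format {format!r}")
    records: list = []
    with _open_text(path) as fh:
        lines = fh.readlines()
    if fmt == "repeatmasker_out":
        # Skip the 3-line header block if present (starts with 'SW' / 'score')
        body = [
            (i + 1, ln)
            for i, ln in enumerate(lines)
            if ln.strip() and not ln.lstrip().startswith(("SW", "score"))
        ]
        for lineno, ln in body:
            fields = ln.split()
            if len(fields) < 11:
                raise ValueError(
                    f"{path}: malformed RepeatMasker line {lineno}: "
                    f"{len(fields)} fields"
                )
            try:
                div = float(fields[1])
                begin, end = int(fields[5]), int(fields[6])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed RepeatMasker line {lineno}: {exc}"
                ) from exc
            records.append(
                TEInstance(
                    # 1-based inclusive -> 0-based half-open
                    interval=GenomicInterval(
                        fields[4], begin - 1, end, _norm_strand(fields[8])
                    ),
                    family=fields[9],
                    divergence=div,
                    id=f"{fields[9]}_{len(records)}",
                )
            )
    else:
        for lineno, ln in enumerate(lines, 1):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            fields = ln.split("\t")
            chrom, start, end, name, score, strand = _parse_bed_line(
                fields, lineno, path
            )
            iv = GenomicInterval(chrom, start, end, strand)
            if fmt == "narrowpeak":
                if len(fields) < 7:
                    raise ValueError(
                        f"{path}: malformed narrowPeak line {lineno}: "
                        "needs >= 7 fields"
                    )
                records.append(Peak(interval=iv, signal=float(fields[6]), dataset=""))
            elif fmt == "bed":
                records.append(
                    TEInstance(
                        interval=iv,
                        family=name or "NA",
                        id=name + f"_{lineno}" if name else f"rec_{lineno}",
                    )
                )
            else:  # tsv
                records.append(iv)
    if not records:
        logger.warning("no records read from %s", path)
    return records


def write_bed(records, path: PathLike) -> None:
    """Write TEInstances / Peaks / GenomicIntervals as BED6."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, TEInstance):
                iv, name, score = rec.interval, rec.family, 0
            elif isinstance(rec, Peak):
                iv, name, score = rec.interval, rec.dataset or ".", rec.signal
            else:
                iv, name, score = rec, ".", 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_genes(path: PathLike) -> list[GeneModel]:
    """Read gene models from GTF (1-based inclusive -> 0-based half-open).

    The strand-aware 3' terminus is exposed as ``GeneModel.end3``. A
    transcript without exons and an exon outside its gene's declared span
    both raise.
    """
    with _open_text(path) as fh:
        data = fh.read()
    db = gffutils.create_db(
        data,
        ":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gene = GeneModel(gene_id=g.id, strand=g.strand or ".")
        for t in db.children(g, featuretype="transcript"):
            exons = [
                GenomicInterval(e.seqid, e.start - 1, e.end, e.strand or ".")
                for e in db.children(t, featuretype="exon", order_by="start")
            ]
            if not exons:
                raise ValueError(f"transcript {t.id} has no exons")
            for e in exons:
                if e.start < g.start - 1 or e.end > g.end:
                    raise ValueError(
                        f"exon [{e.start}, {e.end}) of transcript {t.id} lies "
                        f"outside gene {g.id} span [{g.start - 1}, {g.end})"
                    )
            tm = TranscriptModel(transcript_id=t.id, exons=exons)
            # polyA site = the 3' boundary of the terminal exon
            tm.polya_site = (
                tm.exons[-1].end if (g.strand or ".") != "-" else tm.exons[0].start
            )
            gene.transcripts.append(tm)
        if not gene.transcripts:
            logger.warning("gene %s has no transcripts; skipped", g.id)
            continue
        genes.append(gene)
    return genes


def read_table(path: PathLike) -> pd.DataFrame:
    """Read a headered TSV (e.g. a CNV/SV table or expression matrix)."""
    return pd.read_csv(path, sep="\t")
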