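"""Readers and writers for the standard formats the pipeline touches.

BED3/BED6, ENCODE narrowPeak, FASTA, RepeatMasker ``.out``, a minimal
MEME-style motif text, 4-column fragment TSVs, 12-column blast-style
tabular alignments, and plain TSVs for emitted tables. All intervals are
0-based half-open on the way in and out.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import PWM, AlignmentHit, Gene, GenomicInterval, Peak, RepeatInstance

logger = logging.getLogger(__name__)

BED_DIALECTS = ("bed3", "bed6", "narrowPeak")


class ParseError(ValueError):
    """A malformed line in a tabular input, carrying the line number."""


def _parse_coords(chrom: str, start_s: str, end_s: str, lineno: int) -> tuple[int, int]:
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer coordinates") from exc
    if start < 0 or end <= start:
        raise ParseError(f"line {lineno}: invalid interval [{start}, {end})")
    return start, end


def read_bed(path: str | Path, dialect: str = "bed6") -> list[GenomicInterval] | list[Peak]:
    """Read BED3/BED6/narrowPeak intervals (0-based half-open).

    bed3 returns bare :class:`GenomicInterval`; bed6 and narrowPeak return
    :class:`Peak` objects (narrowPeak signal/p/q/summit columns retained in
    ``metadata``).
    """
    if dialect not in BED_DIALECTS:
        raise ValueError(f"dialect must be one of {BED_DIALECTS}")
    min_cols = {"bed3": 3, "bed6": 6, "narrowPeak": 10}[dialect]
    out: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ParseError(
                    f"line {lineno}: expected >= {min_cols} columns for {dialect}, "
                    f"got {len(fields)}"
                )
            start, end = _parse_coords(fields[0], fields[1], fields[2], lineno)
            if dialect == "bed3":
                out.append(GenomicInterval(fields[0], start, end))
                continue
            strand = fields[5] if fields[5] in ("+", "-") else "."
            interval = GenomicInterval(fields[0], start, end, strand)
            meta: dict = {"score": fields[4]}
            if dialect == "narrowPeak":
                meta.update(
                    signalValue=float(fields[6]),
                    pValue=float(fields[7]),
                    qValue=float(fields[8]),
                    summit=int(fields[9]),
                )
            out.append(Peak(interval=interval, id=fields[3], metadata=meta))
    if not out:
        logger.warning("no intervals read from %s", path)
    return out


def write_bed(records: Iterable, path: str | Path) -> None:
    """Write intervals or peaks as BED (bed3 for intervals, bed6 for peaks)."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomicInterval):
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\n")
            else:
                iv = rec.interval
                score = rec.metadata.get("score", "0") if rec.metadata else "0"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.id}\t{score}\t{iv.strand}\n")


_RM_HEADER_LINES = 3


def read_repeatmasker_out(path: str | Path) -> list[RepeatInstance]:
    """Read a standard RepeatMasker ``.out`` annotation.

    Genomic coordinates (1-based inclusive in the file) are converted to
    0-based half-open; orientation ``C`` maps to ``-``; the family is the
    second component of the class/family column (``SINE/Alu`` -> ``Alu``,
    bare classes kept whole). ``consensus_length`` is reconstructed from
    the repeat-consensus coordinates and the parenthesized remainder.
    """
    out: list[RepeatInstance] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if lineno <= _RM_HEADER_LINES or not raw.strip():
                continue
            fields = raw.split()
            if len(fields) < 14:
                raise ParseError(f"line {lineno}: expected >= 14 columns, got {len(fields)}")
            chrom, qbegin, qend = fields[4], fields[5], fields[6]
            orient, subfamily, cls = fields[8], fields[9], fields[10]
            start = int(qbegin) - 1
            end = int(qend)
            if end <= start:
                raise ParseError(f"line {lineno}: invalid interval [{start}, {end})")
            strand = "-" if orient == "C" else "+"
            family = cls.split("/", 1)[1] if "/" in cls else cls
            # consensus coords: '+' rows are begin end (left); 'C' rows (left) end begin
            def _paren(v: str) -> int:
                return int(v.strip("()"))
            if orient == "C":
                left, r_end = _paren(fields[11]), int(fields[12])
                consensus_length = r_end + left
            else:
                r_end, left = int(fields[12]), _paren(fields[13])
                consensus_length = r_end + left
            out.append(
                RepeatInstance(
                    interval=GenomicInterval(chrom, start, end, strand),
                    family=family,
                    subfamily=subfamily,
                    consensus_length=consensus_length,
                )
            )
    return out


def write_repeatmasker_out(repeats: Sequence[RepeatInstance], path: str | Path) -> None:
    """Write repeats in RepeatMasker ``.out`` layout (for fixtures and round trips)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW   perc perc perc  query     position in query    matching repeat"
            "       position in repeat\n"
            "score   div. del. ins.  sequence  begin end   (left)   repeat class/family"
            "  begin end (left)  ID\n\n"
        )
        for i, rep in enumerate(repeats, start=1):
            iv = rep.interval
            length = len(iv)
            cl = rep.consensus_length
            cls = f"SINE/{rep.family}" if rep.family == "Alu" else rep.family
            if "/" not in cls and rep.family in ("L1", "CR1"):
                cls = f"LINE/{rep.family}"
            if iv.strand == "-":
                fields = [f"({max(cl - length, 0)})", str(length), "1"]
                orient = "C"
            else:
                fields = ["1", str(length), f"({max(cl - length, 0)})"]
                orient = "+"
            fh.write(
                f"  500   10.0  0.0  0.0  {iv.chrom}  {iv.start + 1} {iv.end} (0)  "
                f"{orient}  {rep.subfamily or rep.family}  {cls}  "
                f"{fields[0]} {fields[1]} {fields[2]}  {i}\n"
            )


_MEME_MOTIF_RE = re.compile(r"^MOTIF\s+(\S+)")
_MEME_MATRIX_RE = re.compile(r"letter-probability matrix:.*w=\s*(\d+)")
_MEME_BG_RE = re.compile(r"^Background letter frequencies")


def read_pwm(path: str | Path, pseudocount: float = 1e-3) -> list[PWM]:
    """Read PWMs from a minimal MEME-style motif file (one file, many motifs).

    Rows must sum to 1 within 1e-3; the stated background is used if
    present, otherwise uniform. The pseudocount is folded in at
    construction.
    """
    motifs: list[PWM] = []
    background = np.full(4, 0.25)
    name: str | None = None
    rows: list[list[float]] = []
    expect_rows = 0
    reading_bg = False

    def _flush() -> None:
        nonlocal name, rows
        if name is not None and rows:
            motifs.append(
                PWM(name, np.array(rows), background.copy(), pseudocount=pseudocount)
            )
        name, rows = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if reading_bg and line:
                toks = line.split()
                try:
                    background = np.array([float(toks[i]) for i in (1, 3, 5, 7)])
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"line {lineno}: malformed background line") from exc
                reading_bg = False
                continue
            if _MEME_BG_RE.match(line):
                reading_bg = True
                continue
            m = _MEME_MOTIF_RE.match(line)
            if m:
                _flush()
                name = m.group(1)
                continue
            m = _MEME_MATRIX_RE.search(line)
            if m:
                expect_rows = int(m.group(1))
                continue
            if name is not None and line and line[0] in "-0123456789.":
                vals = [float(v) for v in line.split()]
                if len(vals) != 4:
                    raise ParseError(f"line {lineno}: expected 4 probabilities")
                if any(v < 0 for v in vals):
                    raise ParseError(f"line {lineno}: negative probability")
                if abs(sum(vals) - 1.0) > 1e-3:
                    raise ParseError(
                        f"line {lineno}: probabilities sum to {sum(vals):.4f}, not 1"
                    )
                rows.append(vals)
    _flush()
    if expect_rows and motifs and len(motifs[-1]) != expect_rows:
        logger.warning("motif %s row count differs from declared w=", motifs[-1].name)
    return motifs


def write_pwm(motifs: Sequence[PWM], path: str | Path) -> None:
    """Write PWMs as minimal MEME motif text."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for pwm in motifs:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(pwm)}\n")
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a name -> uppercase-sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read a 4-column fragment TSV: chrom, start, end, sample."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "sample"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "sample": str},
    )
    if (df["end"] <= df["start"]).any():
        bad = int((df["end"] <= df["start"]).idxmax()) + 1
        raise ParseError(f"line {bad}: fragment end <= start")
    return df


def write_fragments(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "sample"]].to_csv(path, sep="\t", header=False, index=False)


def read_alignment_hits(path: str | Path) -> list[AlignmentHit]:
    """Read 12-column blast-style tabular output (outfmt 6).

    Columns: query, subject, %identity, length, mismatches, gap opens,
    qstart, qend, sstart, send, evalue, bitscore. A reversed subject span
    encodes a minus-strand hit.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            f = raw.split("\t")
            if len(f) < 12:
                raise ParseError(f"line {lineno}: expected 12 columns, got {len(f)}")
            hits.append(
                AlignmentHit(
                    query_id=f[0],
                    subject=f[1],
                    identity_pct=float(f[2]),
                    aligned_length=int(f[3]),
                    query_span=(int(f[6]), int(f[7])),
                    subject_span=(int(f[8]), int(f[9])),
                    evalue=float(f[10]),
                    bitscore=float(f[11]),
                )
            )
    return hits


def write_alignment_hits(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            mismatches = round(h.aligned_length * (1 - h.identity_pct / 100.0))
            fh.write(
                f"{h.query_id}\t{h.subject}\t{h.identity_pct:.2f}\t{h.aligned_length}\t"
                f"{mismatches}\t0\t{h.query_span[0]}\t{h.query_span[1]}\t"
                f"{h.subject_span[0]}\t{h.subject_span[1]}\t{h.evalue:.2g}\t{h.bitscore:.1f}\n"
            )


def read_tss_bed(path: str | Path) -> list[Gene]:
    """Read gene TSSs from a bed6 file (width-1 intervals, name = gene id)."""
    genes = []
    for peak in read_bed(path, dialect="bed6"):
        genes.append(Gene(id=peak.id, tss=peak.interval))
    return genes


def write_tss_bed(genes: Sequence[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            t = g.tss
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{g.id}\t0\t{t.strand}\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression TSV with columns gene_id, log2fc[, ...]."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "log2fc" not in df.columns:
        raise ParseError("expression table must have gene_id and log2fc columns")
    return df
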