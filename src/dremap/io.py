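"""Readers and writers for every external format the pipeline touches.

Dialects handled: ENCODE narrowPeak and BED6 peak lists, GFF3 gene models,
bedGraph and WIG (fixedStep/variableStep) coverage, TSV expression matrices,
JASPAR-style PFM text, FASTA genomes and two-column scaffold-length tables.

Everything is validated on the way in; in-memory records use 0-based
half-open coordinates exclusively (GFF3 and WIG are converted from their
1-based conventions at this boundary and back on write).
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio import motifs as bio_motifs

from .model import BASES, CoverageTrack, ExpressionTable, GeneModel, GenomicInterval, PWM, Peak


class FormatError(ValueError):
    """A malformed input file; the message names file and line."""


def _err(path, lineno, msg) -> FormatError:
    return FormatError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# peaks: narrowPeak / BED6
# ---------------------------------------------------------------------------

def read_peaks(path: str | os.PathLike, dialect: str = "narrowPeak") -> list[Peak]:
    """Read a peak list.

    ``narrowPeak`` expects the 10-column ENCODE layout; column 10 (0-based
    offset of the summit from the peak start) becomes ``summit_offset``,
    with ``-1`` meaning "not reported". ``bed6`` expects plain 6-column BED
    with the score column used as the signal.
    """
    if dialect not in ("narrowPeak", "bed6"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    ncols = 10 if dialect == "narrowPeak" else 6
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != ncols:
                raise _err(path, lineno, f"expected {ncols} columns, got {len(fields)}")
            try:
                scaffold = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5] if fields[5] in ("+", "-") else "."
            except ValueError as e:
                raise _err(path, lineno, f"bad coordinate field: {e}") from None
            if start >= end:
                raise _err(path, lineno, f"start {start} >= end {end}")
            if dialect == "narrowPeak":
                try:
                    signal = float(fields[6])
                    summit_raw = int(fields[9])
                except ValueError as e:
                    raise _err(path, lineno, f"bad numeric field: {e}") from None
                summit = None if summit_raw == -1 else summit_raw
            else:
                try:
                    signal = float(fields[4])
                except ValueError as e:
                    raise _err(path, lineno, f"bad score field: {e}") from None
                summit = None
            try:
                peaks.append(
                    Peak(GenomicInterval(scaffold, start, end, strand), name, signal, summit)
                )
            except ValueError as e:
                raise _err(path, lineno, str(e)) from None
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | os.PathLike,
                dialect: str = "narrowPeak") -> None:
    if dialect not in ("narrowPeak", "bed6"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            if dialect == "narrowPeak":
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write(
                    f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}"
                    f"\t{p.signal:g}\t-1\t-1\t{summit}\n"
                )
            else:
                fh.write(
                    f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{p.name}\t{p.signal:g}\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# gene models: GFF3
# ---------------------------------------------------------------------------

def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene and exon features from a GFF3 file.

    GFF3 coordinates are 1-based inclusive; they come back 0-based
    half-open. Exons must name a parent gene; genes must be stranded.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneModel] = {}
    exons_by_parent: dict[str, list[GenomicInterval]] = {}
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise FormatError(
                f"{path}: gene {feat.id} has strand {feat.strand!r}; genes must be stranded"
            )
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        genes[feat.id] = GeneModel(feat.id, iv, [])
    for feat in db.features_of_type("exon"):
        parents = feat.attributes.get("Parent")
        if not parents:
            raise FormatError(f"{path}: exon at {feat.seqid}:{feat.start} has no Parent")
        parent = parents[0]
        if parent not in genes:
            raise FormatError(
                f"{path}: exon at {feat.seqid}:{feat.start} names unknown parent {parent!r}"
            )
        exons_by_parent.setdefault(parent, []).append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
    out = []
    for gid, gene in genes.items():
        exons = sorted(exons_by_parent.get(gid, []), key=lambda e: e.start)
        out.append(GeneModel(gid, gene.interval, exons))
    out.sort(key=lambda g: (g.interval.scaffold, g.interval.start, g.gene_id))
    return out


def write_gene_models(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.scaffold}\tdremap\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, ex in enumerate(g.exons, start=1):
                fh.write(
                    f"{ex.scaffold}\tdremap\texon\t{ex.start + 1}\t{ex.end}\t.\t{iv.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# scaffold lengths
# ---------------------------------------------------------------------------

def read_scaffold_lengths(path: str | os.PathLike) -> dict[str, int]:
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise _err(path, lineno, f"expected 2 columns, got {len(fields)}")
            name, length = fields[0], int(fields[1])
            if length <= 0:
                raise _err(path, lineno, f"non-positive scaffold length {length}")
            if name in lengths:
                raise _err(path, lineno, f"duplicate scaffold {name}")
            lengths[name] = length
    return lengths


def write_scaffold_lengths(lengths: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in lengths.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# coverage: bedGraph / WIG
# ---------------------------------------------------------------------------

def read_coverage(path: str | os.PathLike, scaffold_lengths: dict[str, int],
                  dialect: str = "bedGraph",
                  library_size: float | None = None) -> CoverageTrack:
    """Read a coverage track into dense per-base vectors.

    Uncovered bases are zero. Overlapping bedGraph intervals and negative
    values are rejected. The library size is taken, in order of precedence,
    from the ``library_size`` argument, from a ``library_size=`` attribute
    on the file's ``track`` line (written by :func:`write_coverage`), or
    from the track's own total signal summed over all bases.
    """
    vectors = {name: np.zeros(length, dtype=np.float64)
               for name, length in scaffold_lengths.items()}
    covered = {name: np.zeros(length, dtype=bool)
               for name, length in scaffold_lengths.items()}
    header_library_size: float | None = None

    def fill(scaffold, start, end, value, lineno):
        if scaffold not in vectors:
            raise _err(path, lineno, f"unknown scaffold {scaffold!r}")
        if value < 0:
            raise _err(path, lineno, f"negative coverage value {value}")
        n = len(vectors[scaffold])
        if start < 0 or end > n or start >= end:
            raise _err(path, lineno,
                       f"interval [{start},{end}) outside scaffold of length {n}")
        if covered[scaffold][start:end].any():
            raise _err(path, lineno, "overlapping coverage intervals")
        vectors[scaffold][start:end] = value
        covered[scaffold][start:end] = True

    def parse_track_line(line: str, lineno: int) -> None:
        nonlocal header_library_size
        for token in line.split()[1:]:
            if token.startswith("library_size="):
                try:
                    header_library_size = float(token.split("=", 1)[1])
                except ValueError:
                    raise _err(path, lineno, f"bad track attribute {token!r}") from None

    if dialect == "bedGraph":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if line.startswith("track"):
                    parse_track_line(line, lineno)
                    continue
                if not line or line.startswith(("#", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise _err(path, lineno, f"expected 4 columns, got {len(fields)}")
                try:
                    start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
                except ValueError as e:
                    raise _err(path, lineno, f"bad field: {e}") from None
                fill(fields[0], start, end, value, lineno)
    elif dialect == "wig":
        mode = None      # ("fixed", scaffold, next_start0, step, span) or ("variable", scaffold, span)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if line.startswith("track"):
                    parse_track_line(line, lineno)
                    continue
                if not line or line.startswith(("#", "browser")):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(f.split("=") for f in line.split()[1:])
                    try:
                        # WIG is 1-based: declared start N covers base N-1 first
                        mode = ["fixed", kv["chrom"], int(kv["start"]) - 1,
                                int(kv.get("step", 1)), int(kv.get("span", 1))]
                    except (KeyError, ValueError) as e:
                        raise _err(path, lineno, f"bad fixedStep header: {e}") from None
                elif line.startswith("variableStep"):
                    kv = dict(f.split("=") for f in line.split()[1:])
                    try:
                        mode = ["variable", kv["chrom"], int(kv.get("span", 1))]
                    except (KeyError, ValueError) as e:
                        raise _err(path, lineno, f"bad variableStep header: {e}") from None
                else:
                    if mode is None:
                        raise _err(path, lineno, "data line before any WIG header")
                    fields = line.split()
                    if mode[0] == "fixed":
                        _, scaffold, nxt, step, span = mode
                        try:
                            value = float(fields[0])
                        except ValueError as e:
                            raise _err(path, lineno, f"bad value: {e}") from None
                        fill(scaffold, nxt, nxt + span, value, lineno)
                        mode[2] = nxt + step
                    else:
                        _, scaffold, span = mode
                        if len(fields) != 2:
                            raise _err(path, lineno, "variableStep lines need pos and value")
                        try:
                            pos, value = int(fields[0]) - 1, float(fields[1])
                        except ValueError as e:
                            raise _err(path, lineno, f"bad field: {e}") from None
                        fill(scaffold, pos, pos + span, value, lineno)
    else:
        raise ValueError(f"unknown coverage dialect {dialect!r}")

    if library_size is None:
        library_size = header_library_size
    if library_size is None:
        total = float(sum(v.sum() for v in vectors.values()))
        library_size = total if total > 0 else 1.0
    return CoverageTrack(vectors, library_size=library_size, step=1)


def write_coverage(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Write a track as run-length-encoded bedGraph (zero runs omitted).

    The track line records the library size so that a round trip preserves
    the scaling denominator."""
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph library_size={track.library_size:.10g}\n")
        for scaffold in track.values:
            vec = track.values[scaffold]
            if track.step != 1:
                vec = np.repeat(vec, track.step)
            # run-length encode
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{scaffold}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# expression table
# ---------------------------------------------------------------------------

def read_expression(path: str | os.PathLike) -> ExpressionTable:
    """Read a TSV with header ``gene_id<TAB><condition>...``."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: no condition columns")
    df = df.set_index("gene_id")
    return ExpressionTable(df.astype(float))


def write_expression(table: ExpressionTable, path: str | os.PathLike) -> None:
    table.rpkm.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# PWM: JASPAR text
# ---------------------------------------------------------------------------

def read_pwms(path: str | os.PathLike, pseudocount: float = 0.01) -> list[PWM]:
    """Read JASPAR-format matrices (``>ID name`` header, four base rows).

    Counts are normalized to column probabilities after adding
    ``pseudocount`` to every cell.
    """
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in BASES], dtype=float)
        widths = {len(rec.counts[b]) for b in BASES}
        if len(widths) != 1:
            raise FormatError(f"{path}: motif {rec.matrix_id}: rows of unequal width")
        raw = PWM(rec.matrix_id or rec.name or "motif", counts)
        out.append(raw.normalized(pseudocount))
    if not out:
        raise FormatError(f"{path}: no motifs found")
    return out


def write_pwm(pwm: PWM, path: str | os.PathLike, counts_scale: float = 1.0) -> None:
    """Write a matrix in JASPAR text format (rows ``A [ ... ]`` etc.)."""
    with open(path, "w") as fh:
        fh.write(f">{pwm.motif_id} {pwm.motif_id}\n")
        for i, b in enumerate(BASES):
            row = " ".join(f"{v * counts_scale:.4f}" for v in pwm.matrix[i])
            fh.write(f"{b} [ {row} ]\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a genome FASTA into plain upper-case strings keyed by scaffold."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise FormatError(f"{path}: no sequences")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
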