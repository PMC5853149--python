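"""Readers and writers for every external format the pipeline touches.

All coordinates are normalised to 0-based half-open at this boundary:
GTF (1-based closed) and the MAF-style mutation table (1-based positions)
are converted on read and back-converted on write; BED/BEDPE pass through
unchanged. Rejected rows are counted on the returned objects and logged —
readers never silently drop data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    BASE_ORDER,
    Interval,
    Loop,
    MutationRecord,
    Pwm,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

VALID_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """A malformed input file."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a genome FASTA into {chrom: uppercase sequence}."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"duplicate chromosome name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {rec.id!r}")
        bad = set(seq) - VALID_ALPHABET
        if bad:
            raise FormatError(f"invalid characters {sorted(bad)} in {rec.id!r}")
        genome[rec.id] = seq
    return genome


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


@dataclass
class GtfResult:
    """Transcripts parsed from a GTF plus bookkeeping on rejected records."""

    transcripts: list[TranscriptModel]
    n_rejected: int = 0

    def __iter__(self):
        return iter(self.transcripts)

    def __len__(self):
        return len(self.transcripts)


def read_gtf(path, feature_types: tuple[str, ...] = ("exon", "CDS")) -> GtfResult:
    """Parse a GTF into :class:`TranscriptModel` records.

    Only `feature_types` rows are consumed (the annotation's other feature
    rows are redundant with exon structure). Coordinates are converted from
    1-based closed to 0-based half-open. Records with an unknown strand
    symbol are rejected and counted; malformed lines raise
    :class:`FormatError` with the line number.
    """
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, dict] = {}
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 columns, "
                                  f"got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in feature_types:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise FormatError(f"line {lineno}: end < start")
            if strand not in ("+", "-"):
                logger.warning("line %d: rejected record with strand %r",
                               lineno, strand)
                n_rejected += 1
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id")
            if not tid or not gid:
                raise FormatError(
                    f"line {lineno}: missing transcript_id/gene_id")
            iv = Interval(chrom, start1 - 1, end1, strand)
            target = exons if feature == "exon" else cds
            target.setdefault(tid, []).append(iv)
            meta.setdefault(tid, {
                "gene_id": gid,
                "gene_symbol": attr.get("gene_name"),
                "chrom": chrom,
                "strand": strand,
                "source": attr.get("source_tag", "annotation"),
            })
    transcripts = []
    for tid, ex in exons.items():
        m = meta[tid]
        transcripts.append(TranscriptModel(
            transcript_id=tid, gene_id=m["gene_id"], chrom=m["chrom"],
            strand=m["strand"], exons=ex, cds=cds.get(tid, []),
            gene_symbol=m["gene_symbol"], source=m["source"],
        ))
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return GtfResult(transcripts, n_rejected)


def write_gtf(transcripts, path) -> None:
    """Write transcripts as GTF exon/CDS rows (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for tx in sorted(transcripts, key=lambda t: (t.chrom, t.start,
                                                     t.transcript_id)):
            sym = f' gene_name "{tx.gene_symbol}";' if tx.gene_symbol else ""
            attrs = (f'gene_id "{tx.gene_id}"; transcript_id '
                     f'"{tx.transcript_id}";{sym} '
                     f'source_tag "{tx.source}";')
            for feature, ivs in (("exon", tx.exons), ("CDS", tx.cds)):
                for iv in ivs:
                    fh.write("\t".join([
                        tx.chrom, "taprna", feature,
                        str(iv.start + 1), str(iv.end), ".", tx.strand, ".",
                        attrs,
                    ]) + "\n")


# ---------------------------------------------------------------------------
# BED / BEDPE

def read_bed(path) -> list[Interval]:
    """Read a BED3/BED6 file of intervals (scores optional)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"line {lineno}: BED needs >= 3 columns")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 else "."
            out.append(Interval(f[0], int(f[1]), int(f[2]), strand,
                                name=name, score=score))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
            fh.write("\t".join([
                iv.chrom, str(iv.start), str(iv.end),
                iv.name or ".",
                "." if iv.score is None else f"{iv.score:g}",
                iv.strand,
            ]) + "\n")


@dataclass
class LoopSet:
    """Paired-anchor chromatin loops with rejected-row bookkeeping."""

    loops: list[Loop] = field(default_factory=list)
    n_rejected: int = 0

    def __iter__(self):
        return iter(self.loops)

    def __len__(self):
        return len(self.loops)

    def anchors(self):
        for loop in self.loops:
            yield loop.anchor_a
            yield loop.anchor_b


def read_bedpe_loops(path) -> LoopSet:
    """Read chromatin loops from 6+ column BEDPE.

    Anchors are canonicalised so anchor_a precedes anchor_b. Rows with
    inter-chromosomal or mutually overlapping anchors are rejected and
    counted.
    """
    loops, n_rejected = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"line {lineno}: BEDPE needs >= 6 columns")
            a = Interval(f[0], int(f[1]), int(f[2]))
            b = Interval(f[3], int(f[4]), int(f[5]))
            if a.chrom != b.chrom:
                logger.warning("line %d: rejected inter-chromosomal loop", lineno)
                n_rejected += 1
                continue
            if a.start > b.start:
                a, b = b, a
            name = f[6] if len(f) > 6 and f[6] != "." else None
            score = float(f[7]) if len(f) > 7 and f[7] != "." else None
            if a.end > b.start:
                logger.warning("line %d: rejected loop with overlapping anchors",
                               lineno)
                n_rejected += 1
                continue
            loops.append(Loop(a, b, score=score, loop_id=name))
    return LoopSet(loops, n_rejected)


def write_bedpe(loops, path) -> None:
    with open(path, "w") as fh:
        for i, loop in enumerate(sorted(
                loops, key=lambda l: (l.chrom, l.anchor_a.start))):
            fh.write("\t".join([
                loop.chrom, str(loop.anchor_a.start), str(loop.anchor_a.end),
                loop.chrom, str(loop.anchor_b.start), str(loop.anchor_b.end),
                loop.loop_id or f"loop_{i}",
                "." if loop.score is None else f"{loop.score:g}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# JASPAR PFM

def read_pfm(path, pseudocount: float = 0.5) -> list[Pwm]:
    """Read JASPAR-style PFM text into probability PWMs.

    Counts get an additive pseudocount per cell before normalising, so no
    log-odds score is ever -inf.
    """
    pwms = []
    with open(path) as fh:
        block: list[list[float]] = []
        motif_id = None

        def flush():
            if motif_id is None:
                return
            if len(block) != 4:
                raise FormatError(f"motif {motif_id!r}: expected 4 count rows")
            lens = {len(row) for row in block}
            if len(lens) != 1:
                raise FormatError(f"motif {motif_id!r}: rows of unequal length")
            counts = np.array(block, dtype=float)
            if (counts < 0).any():
                raise FormatError(f"motif {motif_id!r}: negative counts")
            probs = counts + pseudocount
            pwms.append(Pwm(motif_id, probs / probs.sum(axis=0)))

        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                block = []
            else:
                row = re.sub(r"^[ACGTacgt]\s*", "", line)
                row = row.strip("[]")
                block.append([float(x) for x in row.replace("]", "").split()])
        flush()
    return pwms


def write_pfm(pwms, path, scale: float = 100.0) -> None:
    """Write PWMs as JASPAR PFM text (probabilities scaled to pseudo-counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for base, row in zip(BASE_ORDER, pwm.matrix):
                vals = " ".join(f"{v * scale:.6f}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Expression matrices

@dataclass
class ExpressionMatrix:
    """Non-negative feature x sample matrix with tissue/species metadata."""

    values: pd.DataFrame           # features x samples
    samples: pd.DataFrame          # index: sample id; columns: tissue, species

    def __post_init__(self):
        missing = [s for s in self.values.columns
                   if s not in self.samples.index]
        if missing:
            raise FormatError(f"samples missing from metadata: {missing}")
        if (self.values.to_numpy() < 0).any():
            raise FormatError("expression values must be non-negative")

    def tissues(self) -> pd.Series:
        return self.samples.loc[self.values.columns, "tissue"]


def read_expression_matrix(path, meta_path) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, meta)


def write_expression_matrix(expr: ExpressionMatrix, path, meta_path) -> None:
    expr.values.to_csv(path, sep="\t", float_format="%.10g")
    expr.samples.to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# Mutation table (MAF-style TSV, 1-based positions in the file)

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "cancer_type", "sample_id"]


def read_mutations(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"mutation table missing columns: {sorted(missing)}")
    return [
        MutationRecord(row.chrom, int(row.pos) - 1, row.ref, row.alt,
                       row.cancer_type, row.sample_id)
        for row in df.itertuples()
    ]


def write_mutations(mutations, path) -> None:
    rows = [
        (m.chrom, m.pos + 1, m.ref, m.alt, m.cancer_type, m.sample_id)
        for m in sorted(mutations, key=lambda m: (m.chrom, m.pos, m.sample_id))
    ]
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ortholog table

def read_orthologs(path) -> dict[str, str]:
    """Read a human->mouse ortholog TSV (human_gene_id, mouse_gene_id, symbol).

    Returns a bidirectional-consistent human->mouse map; an inconsistent
    chain (A->B recorded alongside B used as a human id) raises.
    """
    df = pd.read_csv(path, sep="\t")
    mapping = dict(zip(df["human_gene_id"], df["mouse_gene_id"]))
    if set(mapping) & set(mapping.values()):
        raise FormatError("ortholog map is not a bipartite human->mouse map")
    if len(set(mapping.values())) != len(mapping):
        raise FormatError("ortholog map is not one-to-one")
    return mapping


def write_orthologs(pairs, path) -> None:
    """pairs: iterable of (human_gene_id, mouse_gene_id, symbol)."""
    pd.DataFrame(pairs, columns=["human_gene_id", "mouse_gene_id",
                                 "symbol"]).to_csv(path, sep="\t", index=False)
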