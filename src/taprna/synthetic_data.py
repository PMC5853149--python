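"""Synthetic human-like/mouse-like genome pair with planted ground truth.

The generator emits a fully cross-referenced toy dataset for every pipeline
stage: orthologous coding genes laid out in disjoint loci, lncRNAs planted
in each of the seven orientation categories with promoters copied across
genomes (then point-mutated at a configurable rate), non-conserved decoy
lncRNAs, conserved transcript domains carrying a planted 8-mer, chromatin
loops anchored at planted tapRNA promoters, TADs, CTCF-like peaks,
chromatin-state tracks, tissue expression with a planted pair correlation
(Gaussian copula on the Spearman scale), and somatic mutations enriched at
motif sites inside tapRNA loci.

Everything is deterministic under the config seed: each stage draws from
``default_rng([seed, stage_index])`` so stages are independent of call
order, and all writers emit sorted, fixed-format text.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats
from .catalogue import coding_potential, promoter_of
from .config import PipelineConfig, SimulationConfig
from .models import Interval, Loop, MutationRecord, Pwm, TranscriptModel, revcomp

GENE_LEN = 3000
GENE_OFFSET = 6400          # gene start within its locus
LOCUS_STRIDE = 17_000
LOCUS_MARGIN = 1000
STD_EXONS = ((0, 500), (900, 1400), (1800, 2400))

#: lncRNA placement per category, in the gene's 5'->3' frame:
#: (span_start, span_end, relative strand, exon offsets within the span).
PLACEMENTS = {
    "BT": (-2500, -300, "A", ((0, 500), (800, 1300), (1600, 2200))),
    "US-S": (-5200, -2800, "S", STD_EXONS),
    "US-AS": (-5200, -2800, "A", STD_EXONS),
    "AS": (500, 2900, "A", STD_EXONS),
    "OLAP": (400, 2100, "S", ((0, 300), (600, 900), (1400, 1700))),
    "DS-S": (GENE_LEN + 2000, GENE_LEN + 4400, "S", STD_EXONS),
    "DS-AS": (GENE_LEN + 2000, GENE_LEN + 4400, "A", STD_EXONS),
}

#: Gene exon/CDS structure in the gene frame.
GENE_EXONS = ((0, 300), (1200, 1700), (2400, 3000))
GENE_CDS = ((1300, 1700), (2400, 2800))

CTCF_CONSENSUS = "CCACCAGGTGGC"
ZNF263_CONSENSUS = "GAGGAGGAGGAG"

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


def ctcf_like_pwm(p: float = 0.85) -> Pwm:
    return _consensus_pwm("CTCF_SYNTH", CTCF_CONSENSUS, p)


def znf263_like_pwm(p: float = 0.85) -> Pwm:
    return _consensus_pwm("ZNF263_SYNTH", ZNF263_CONSENSUS, p)


def _consensus_pwm(motif_id: str, consensus: str, p: float) -> Pwm:
    mat = np.full((4, len(consensus)), (1 - p) / 3)
    for j, base in enumerate(consensus):
        mat["ACGT".index(base), j] = p
    return Pwm(motif_id, mat)


@dataclass
class PlantedPcRNA:
    """Ground truth for one planted positionally conserved lncRNA."""

    pcrna_id: str               # human lncRNA transcript id
    mouse_id: str
    category: str
    human_gene: str
    mouse_gene: str
    symbol: str
    chrom: str
    promoter: tuple[int, int, str]       # start, end, strand
    is_taprna: bool
    is_novel: bool
    domain_tx: tuple[int, int]           # conserved patch, transcript space
    tss: int


@dataclass
class GroundTruth:
    pcrnas: list[PlantedPcRNA] = field(default_factory=list)
    decoy_ids: list[str] = field(default_factory=list)
    planted_kmer: str = ""
    pair_rho: float = 0.0
    site_mutation_rate_test: float = 0.0
    site_mutation_rate_background: float = 0.0

    @property
    def taprna_ids(self) -> set[str]:
        return {p.pcrna_id for p in self.pcrnas if p.is_taprna}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["pcrnas"] = [
            PlantedPcRNA(**{**p,
                            "promoter": tuple(p["promoter"]),
                            "domain_tx": tuple(p["domain_tx"])})
            for p in data["pcrnas"]
        ]
        return cls(**data)


@dataclass
class SyntheticDataset:
    """In-memory bundle of every generated file's content."""

    config: SimulationConfig
    genome_h: dict[str, str]
    genome_m: dict[str, str]
    transcripts_h: list[TranscriptModel]
    transcripts_m: list[TranscriptModel]
    ortholog_pairs: list[tuple[str, str, str]]
    truth: GroundTruth
    loops: list[Loop] = field(default_factory=list)
    tads: list[Interval] = field(default_factory=list)
    ctcf_peaks: list[Interval] = field(default_factory=list)
    states: list[Interval] = field(default_factory=list)
    expr_h: io_formats.ExpressionMatrix | None = None
    expr_m: io_formats.ExpressionMatrix | None = None
    mutations: list[MutationRecord] = field(default_factory=list)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_fasta(self.genome_h, out / "genome_human.fa")
        io_formats.write_fasta(self.genome_m, out / "genome_mouse.fa")
        io_formats.write_gtf(self.transcripts_h, out / "human.gtf")
        io_formats.write_gtf(self.transcripts_m, out / "mouse.gtf")
        io_formats.write_orthologs(self.ortholog_pairs,
                                   out / "orthologs.tsv")
        io_formats.write_bedpe(self.loops, out / "loops.bedpe")
        io_formats.write_bed(self.tads, out / "tads.bed")
        io_formats.write_bed(self.ctcf_peaks, out / "ctcf_peaks.bed")
        io_formats.write_bed(self.states, out / "chromhmm.bed")
        if self.expr_h is not None:
            io_formats.write_expression_matrix(
                self.expr_h, out / "expr_human.tsv",
                out / "samples_human.tsv")
            io_formats.write_expression_matrix(
                self.expr_m, out / "expr_mouse.tsv",
                out / "samples_mouse.tsv")
        if self.mutations:
            io_formats.write_mutations(self.mutations, out / "mutations.tsv")
        self.truth.to_json(out / "ground_truth.json")


# ---------------------------------------------------------------------------
# genome pair


def _frame_to_genome(a: int, b: int, gene_start: int,
                     gene_strand: str) -> tuple[int, int]:
    if gene_strand == "+":
        return gene_start + a, gene_start + b
    return gene_start + GENE_LEN - b, gene_start + GENE_LEN - a


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_genome(rng: np.random.Generator, n_chrom: int,
                   length: int) -> dict[str, bytearray]:
    return {
        f"chr{i + 1}": bytearray(
            _BASE_BYTES[rng.integers(0, 4, size=length)].tobytes())
        for i in range(n_chrom)
    }


def _write_seq(genome: dict[str, bytearray], chrom: str, start: int,
               seq: str) -> None:
    genome[chrom][start:start + len(seq)] = seq.encode()


def _read_seq(genome: dict[str, bytearray], chrom: str, start: int,
              end: int) -> str:
    return genome[chrom][start:end].decode()


def _make_gene(gene_id: str, symbol: str, chrom: str, start: int,
               strand: str) -> TranscriptModel:
    exons = [Interval(chrom, *_frame_to_genome(a, b, start, strand),
                      strand=strand) for a, b in GENE_EXONS]
    cds = [Interval(chrom, *_frame_to_genome(a, b, start, strand),
                    strand=strand) for a, b in GENE_CDS]
    return TranscriptModel(
        transcript_id=f"{gene_id}.t1", gene_id=gene_id, chrom=chrom,
        strand=strand, exons=exons, cds=cds, gene_symbol=symbol)


def _make_lnc(tx_id: str, gene_id: str, symbol: str | None, chrom: str,
              strand: str, exon_intervals, source: str) -> TranscriptModel:
    exons = [Interval(chrom, a, b, strand=strand) for a, b in exon_intervals]
    return TranscriptModel(
        transcript_id=tx_id, gene_id=gene_id, chrom=chrom, strand=strand,
        exons=exons, gene_symbol=symbol, source=source)


def _domain_exon(tx: TranscriptModel) -> Interval:
    """The middle exon hosts the planted conserved domain."""
    return tx.exons[1]


def _tx_interval_of_exon(tx: TranscriptModel, exon: Interval,
                         ) -> tuple[int, int]:
    """Spliced-transcript coordinates of a genomic exon."""
    offset = 0
    order = tx.exons if tx.strand == "+" else list(reversed(tx.exons))
    for e in order:
        if e.start == exon.start and e.end == exon.end:
            return offset, offset + e.length
        offset += e.length
    raise ValueError("exon not in transcript")


def _spliced_from_bytes(genome: dict[str, bytearray],
                        tx: TranscriptModel) -> str:
    seq = "".join(_read_seq(genome, tx.chrom, e.start, e.end)
                  for e in tx.exons)
    return revcomp(seq) if tx.strand == "-" else seq


def _break_orfs(genome: dict[str, bytearray], tx: TranscriptModel,
                hard: list[tuple[int, int]],
                soft: list[tuple[int, int]] | None = None,
                max_orf_codons: int = 100) -> None:
    """Plant stop codons until no spliced ORF reaches ``max_orf_codons``.

    Breaks never touch ``hard`` intervals (planted k-mers) and avoid
    ``soft`` intervals (copied promoters/domains) whenever a free codon
    exists elsewhere in the offending frame.
    """
    soft = soft or []

    def clash(gpos: list[int], regions) -> bool:
        return any(lo <= g < hi for g in gpos for lo, hi in regions)

    for _ in range(40):
        seq = _spliced_from_bytes(genome, tx)
        span = _longest_orf_span(seq)
        if span is None or (span[1] - span[0]) // 3 < max_orf_codons:
            return
        codon_starts = list(range(span[0] + 3, span[1] - 3, 3))
        chosen = None
        for regions in (hard + soft, hard):
            for cpos in codon_starts:
                gpos = [tx.transcript_to_genome(cpos + k) for k in range(3)]
                if not clash(gpos, regions):
                    chosen = cpos
                    break
            if chosen is not None:
                break
        if chosen is None:
            return
        stop = "TAA"
        for k in range(3):
            gpos = tx.transcript_to_genome(chosen + k)
            base = stop[k] if tx.strand == "+" else revcomp(stop[k])
            _write_seq(genome, tx.chrom, gpos, base)


def _longest_orf_span(seq: str) -> tuple[int, int] | None:
    """(start, end) of the longest ATG-initiated ORF (codons only)."""
    best = None
    n = len(seq)
    for frame in range(3):
        pos = frame
        while pos + 3 <= n:
            if seq[pos:pos + 3] == "ATG":
                q = pos
                while q + 3 <= n and seq[q:q + 3] not in {"TAA", "TAG", "TGA"}:
                    q += 3
                if best is None or q - pos > best[1] - best[0]:
                    best = (pos, q)
                pos = q + 3
            else:
                pos += 3
    return best


def generate_genome_pair(config: SimulationConfig,
                         pipeline_config: PipelineConfig | None = None,
                         ) -> SyntheticDataset:
    """Build the annotated two-genome pair and its ground truth."""
    pconf = pipeline_config or PipelineConfig()
    rng = np.random.default_rng([config.seed, 1])
    genome_h = _random_genome(rng, config.n_chromosomes, config.chrom_length)
    genome_m = _random_genome(rng, config.n_chromosomes, config.chrom_length)
    chroms = sorted(genome_h)

    # locus roster: planted pcRNAs, decoys, then spare ortholog genes
    roster: list[tuple[str, str]] = []
    for cat in sorted(config.n_pcrnas):
        roster.extend(("pcrna:" + cat, cat)
                      for _ in range(config.n_pcrnas[cat]))
    roster.extend(("decoy", "") for _ in range(config.n_decoys))
    n_spare = max(0, config.n_ortholog_genes
                  - sum(config.n_pcrnas.values()))
    roster.extend(("spare", "") for _ in range(n_spare))
    per_chrom = (len(genome_h[chroms[0]]) - 2 * LOCUS_MARGIN) // LOCUS_STRIDE
    if len(roster) > per_chrom * len(chroms):
        raise ValueError("chromosomes too short for the requested loci")
    order = rng.permutation(len(roster))

    truth = GroundTruth(
        planted_kmer=config.planted_kmer, pair_rho=config.pair_rho,
        site_mutation_rate_test=config.site_mutation_rate_test,
        site_mutation_rate_background=config.site_mutation_rate_background)
    txs_h: list[TranscriptModel] = []
    txs_m: list[TranscriptModel] = []
    ortholog_pairs: list[tuple[str, str, str]] = []

    n_tap_wanted = round(config.fraction_taprna
                         * sum(config.n_pcrnas.values()))
    pcrna_counter = 0
    lnc_records: list[tuple[TranscriptModel, TranscriptModel | None,
                            PlantedPcRNA | None]] = []

    for slot, idx in enumerate(order):
        kind, cat = roster[idx]
        chrom = chroms[slot % len(chroms)]
        locus = LOCUS_MARGIN + (slot // len(chroms)) * LOCUS_STRIDE
        gene_start = locus + GENE_OFFSET
        gene_strand = "+" if rng.random() < 0.5 else "-"
        if kind == "decoy":
            d_id = f"DECOY{len(truth.decoy_ids) + 1:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            exon_ivs = [(gene_start + a, gene_start + b) for a, b in STD_EXONS]
            lnc_h = _make_lnc(f"{d_id}.h", d_id, None, chrom,
                              strand, exon_ivs, "annotation")
            txs_h.append(lnc_h)
            truth.decoy_ids.append(lnc_h.transcript_id)
            lnc_records.append((lnc_h, None, None))
            continue
        num = len(ortholog_pairs) + 1
        symbol = f"SYM{num:03d}"
        hg, mg = f"HG{num:03d}", f"MG{num:03d}"
        txs_h.append(_make_gene(hg, symbol, chrom, gene_start, gene_strand))
        txs_m.append(_make_gene(mg, symbol, chrom, gene_start, gene_strand))
        ortholog_pairs.append((hg, mg, symbol))
        if kind == "spare":
            continue
        pcrna_counter += 1
        span_a, span_b, rel, exon_spec = PLACEMENTS[cat]
        strand = gene_strand if rel == "S" else ("-" if gene_strand == "+"
                                                 else "+")
        # exons laid out in the gene frame, then mirrored with the frame
        exon_ivs = sorted(
            _frame_to_genome(span_a + a, span_a + b, gene_start, gene_strand)
            for a, b in exon_spec)
        is_novel = rng.random() < 0.2
        source = "assembled" if is_novel else "annotation"
        lnc_h = _make_lnc(f"PC{pcrna_counter:03d}.h", f"LNC_H{pcrna_counter:03d}",
                          symbol, chrom, strand, exon_ivs, source)
        lnc_m = _make_lnc(f"PC{pcrna_counter:03d}.m", f"LNC_M{pcrna_counter:03d}",
                          symbol, chrom, strand, exon_ivs, source)
        txs_h.append(lnc_h)
        txs_m.append(lnc_m)
        dom = _domain_exon(lnc_h)
        promoter = promoter_of(lnc_h, pconf.promoter_upstream,
                               pconf.promoter_downstream,
                               chrom_length=config.chrom_length)
        planted = PlantedPcRNA(
            pcrna_id=lnc_h.transcript_id, mouse_id=lnc_m.transcript_id,
            category=cat, human_gene=hg, mouse_gene=mg, symbol=symbol,
            chrom=chrom, promoter=(promoter.start, promoter.end, strand),
            is_taprna=len(truth.pcrnas) < n_tap_wanted,
            is_novel=is_novel,
            domain_tx=_tx_interval_of_exon(lnc_h, dom), tss=lnc_h.tss)
        truth.pcrnas.append(planted)
        lnc_records.append((lnc_h, lnc_m, planted))

    # plant the enriched 8-mer inside each conserved-domain exon
    kmer = config.planted_kmer
    protected_h: list[tuple[int, int]] = []
    for lnc_h, lnc_m, planted in lnc_records:
        if planted is None:
            continue
        dom = _domain_exon(lnc_h)
        offsets = sorted({50, dom.length // 2, dom.length - 60})
        for off in offsets:
            s = kmer if lnc_h.strand == "+" else revcomp(kmer)
            _write_seq(genome_h, lnc_h.chrom, dom.start + off, s)
            protected_h.append((dom.start + off, dom.start + off + 8))

    # plant motif instances in every lncRNA's introns (before the
    # cross-species promoter copy, so a motif falling inside a promoter
    # window is shared by both genomes)
    for lnc_h, _lnc_m, _p in lnc_records:
        i1 = lnc_h.exons[0].end + 20
        i2 = lnc_h.exons[1].end + 20
        _write_seq(genome_h, lnc_h.chrom, i1, CTCF_CONSENSUS)
        _write_seq(genome_h, lnc_h.chrom, i2, ZNF263_CONSENSUS)

    # suppress spurious coding potential in the human lncRNAs
    for lnc_h, _lnc_m, _p in lnc_records:
        _break_orfs(genome_h, lnc_h, hard=protected_h,
                    max_orf_codons=pconf.max_orf_codons)

    # copy promoters + conserved domains to the mouse genome, then diverge
    # the promoter copies at the configured point-mutation rate
    protected_m: list[tuple[int, int]] = []
    for lnc_h, lnc_m, planted in lnc_records:
        if planted is None:
            continue
        prom_start, prom_end, _ = planted.promoter
        _write_seq(genome_m, lnc_m.chrom, prom_start,
                   _read_seq(genome_h, lnc_h.chrom, prom_start, prom_end))
        dom = _domain_exon(lnc_h)
        _write_seq(genome_m, lnc_m.chrom, dom.start,
                   _read_seq(genome_h, lnc_h.chrom, dom.start, dom.end))
        protected_m.append((prom_start, prom_end))
        protected_m.append((dom.start, dom.end))
        if config.promoter_mutation_rate > 0:
            for pos in range(prom_start, prom_end):
                if rng.random() < config.promoter_mutation_rate:
                    current = chr(genome_m[lnc_m.chrom][pos])
                    alt = rng.choice([b for b in "ACGT" if b != current])
                    _write_seq(genome_m, lnc_m.chrom, pos, str(alt))
    for _lnc_h, lnc_m, planted in lnc_records:
        if planted is None:
            continue
        _break_orfs(genome_m, lnc_m, hard=protected_h, soft=protected_m,
                    max_orf_codons=pconf.max_orf_codons)

    dataset = SyntheticDataset(
        config=config,
        genome_h={c: s.decode() for c, s in genome_h.items()},
        genome_m={c: s.decode() for c, s in genome_m.items()},
        transcripts_h=sorted(txs_h, key=lambda t: (t.chrom, t.start,
                                                   t.transcript_id)),
        transcripts_m=sorted(txs_m, key=lambda t: (t.chrom, t.start,
                                                   t.transcript_id)),
        ortholog_pairs=ortholog_pairs, truth=truth)
    return dataset


# ---------------------------------------------------------------------------
# topology files


def generate_topology_files(config: SimulationConfig,
                            dataset: SyntheticDataset) -> None:
    """Attach loops, TADs, CTCF-like peaks and chromatin states.

    Every planted tapRNA gets one loop whose proximal anchor overlaps its
    promoter and whose distal anchor is enhancer-annotated for the
    configured fraction of its length; background loops and peaks avoid all
    lncRNA promoters.
    """
    rng = np.random.default_rng([config.seed, 2])
    truth = dataset.truth
    chrom_len = config.chrom_length
    w = config.anchor_width
    promoters = [(p.chrom, p.promoter[0], p.promoter[1])
                 for p in truth.pcrnas]
    promoters += [(tx.chrom, tx.start - 2000, tx.end + 2000)
                  for tx in dataset.transcripts_h
                  if tx.transcript_id in set(truth.decoy_ids)]

    def clashes(chrom: str, start: int, end: int) -> bool:
        return any(c == chrom and start < e + 2000 and s - 2000 < end
                   for c, s, e in promoters)

    loops, states, peaks = [], [], []
    for p in truth.pcrnas:
        if not p.is_taprna:
            continue
        mid = (p.promoter[0] + p.promoter[1]) // 2
        prox = Interval(p.chrom, max(0, mid - w // 2), mid + w // 2)
        for _ in range(200):
            offset = int(rng.integers(30_000, 80_000))
            sign = 1 if prox.end + offset + w < chrom_len - 1000 else -1
            start = prox.end + offset if sign > 0 else prox.start - offset - w
            if start < 0:
                continue
            if not clashes(p.chrom, start, start + w):
                break
        distal = Interval(p.chrom, start, start + w)
        a, b = (prox, distal) if prox.start <= distal.start else (distal, prox)
        loops.append(Loop(a, b, loop_id=f"loop_{p.pcrna_id}"))
        enh_len = int(config.enhancer_fraction * distal.length)
        if enh_len > 0:
            states.append(Interval(p.chrom, distal.start,
                                   distal.start + enh_len,
                                   name="Strong_Enhancer"))
        if enh_len < distal.length:
            states.append(Interval(p.chrom, distal.start + enh_len,
                                   distal.end, name="Txn_Elongation"))
    for i in range(config.n_loops):
        chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
        for _ in range(200):
            s1 = int(rng.integers(1000, chrom_len - 100_000))
            s2 = s1 + w + int(rng.integers(30_000, 80_000))
            if not clashes(chrom, s1, s1 + w) and not clashes(chrom, s2,
                                                              s2 + w):
                break
        loops.append(Loop(Interval(chrom, s1, s1 + w),
                          Interval(chrom, s2, s2 + w),
                          loop_id=f"bg_loop_{i}"))

    for loop in loops:
        for anchor in (loop.anchor_a, loop.anchor_b):
            mid = int(anchor.midpoint)
            peaks.append(Interval(anchor.chrom, max(0, mid - 150), mid + 150,
                                  name="CTCF"))
    for i in range(50):
        chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
        s = int(rng.integers(0, chrom_len - 300))
        peaks.append(Interval(chrom, s, s + 300, name="CTCF"))

    tads = []
    tap_tss: dict[str, list[int]] = {}
    for p in truth.pcrnas:
        if p.is_taprna:
            tap_tss.setdefault(p.chrom, []).append(p.tss)
    for i in range(config.n_chromosomes):
        chrom = f"chr{i + 1}"
        bounds = set(sorted(tap_tss.get(chrom, []))[::2])
        fillers = np.linspace(0, chrom_len, config.tad_count + 1).astype(int)
        bounds.update(int(b) for b in fillers)
        ordered = sorted(bounds)
        tads.extend(Interval(chrom, a, b, name=f"tad_{chrom}_{j}")
                    for j, (a, b) in enumerate(zip(ordered, ordered[1:]))
                    if b > a)

    dataset.loops = loops
    dataset.tads = tads
    dataset.ctcf_peaks = sorted(peaks, key=lambda p: (p.chrom, p.start))
    dataset.states = sorted(states, key=lambda s: (s.chrom, s.start))


# ---------------------------------------------------------------------------
# expression


def spearman_to_latent(rho_s: float) -> float:
    """Latent Gaussian-copula correlation yielding Spearman ``rho_s``."""
    return float(2 * np.sin(np.pi * rho_s / 6))


def _sparsify_to_tau(x: np.ndarray, target: float) -> np.ndarray:
    from .expression_stats import tissue_specificity_tau
    x = x.copy()
    order = np.argsort(x)
    for idx in order[:-1]:
        if tissue_specificity_tau(x) >= target:
            break
        x[idx] = 0.0
    return x


def generate_expression(config: SimulationConfig,
                        dataset: SyntheticDataset,
                        shared_tissue_weight: float = 0.7) -> None:
    """Tissue expression for both species with the planted pair
    correlation.

    Gene/lncRNA latents share a bivariate normal with correlation
    ``2 sin(pi rho/6)`` so the planted target is on the Spearman scale;
    species share per-pair tissue effects, giving positive cross-species
    correlation for the same feature.
    """
    import pandas as pd

    rng = np.random.default_rng([config.seed, 3])
    truth = dataset.truth
    T = config.n_tissues
    tissues = [f"tissue_{i + 1:02d}" for i in range(T)]
    rho_lat = spearman_to_latent(config.pair_rho)
    a = shared_tissue_weight

    rows_h: dict[str, np.ndarray] = {}
    rows_m: dict[str, np.ndarray] = {}

    def lnc_from_gene(z_gene: np.ndarray) -> np.ndarray:
        noise = rng.standard_normal(T)
        if abs(rho_lat) >= 1:
            return z_gene.copy()
        return rho_lat * z_gene + np.sqrt(1 - rho_lat ** 2) * noise

    for p in truth.pcrnas:
        t_eff = rng.standard_normal(T)
        z_gh = a * t_eff + np.sqrt(1 - a ** 2) * rng.standard_normal(T)
        z_gm = a * t_eff + np.sqrt(1 - a ** 2) * rng.standard_normal(T)
        rows_h[p.human_gene] = np.exp(2.0 + z_gh)
        rows_m[p.mouse_gene] = np.exp(2.0 + z_gm)
        lnc_h = np.exp(0.5 + lnc_from_gene(z_gh))
        lnc_m = np.exp(0.5 + lnc_from_gene(z_gm))
        if config.tissue_specificity_target > 0:
            lnc_h = _sparsify_to_tau(lnc_h,
                                     config.tissue_specificity_target)
            lnc_m = _sparsify_to_tau(lnc_m,
                                     config.tissue_specificity_target)
        rows_h[p.pcrna_id] = lnc_h
        rows_m[p.mouse_id] = lnc_m
    for d in truth.decoy_ids:
        rows_h[d] = np.exp(0.5 + rng.standard_normal(T))

    def build(rows: dict, species: str) -> io_formats.ExpressionMatrix:
        samples = [f"{species}_{t}" for t in tissues]
        values = pd.DataFrame.from_dict(rows, orient="index",
                                        columns=samples)
        meta = pd.DataFrame({"tissue": tissues, "species": species},
                            index=pd.Index(samples, name="sample"))
        return io_formats.ExpressionMatrix(values, meta)

    dataset.expr_h = build(rows_h, "human")
    dataset.expr_m = build(rows_m, "mouse")


# ---------------------------------------------------------------------------
# mutations


def generate_mutations(config: SimulationConfig,
                       dataset: SyntheticDataset,
                       motif_hits,
                       ) -> None:
    """Somatic mutations hitting motif sites at the planted rates.

    Sites inside tapRNA loci (promoter union transcript span) mutate at
    ``site_mutation_rate_test``; sites inside background lncRNA loci
    (non-tapRNA pcRNAs and decoys) at ``site_mutation_rate_background``.
    """
    rng = np.random.default_rng([config.seed, 4])
    truth = dataset.truth
    tx_by_id = {t.transcript_id: t for t in dataset.transcripts_h}

    def locus_of(tx_id: str, promoter: tuple | None) -> list[Interval]:
        tx = tx_by_id[tx_id]
        lo, hi = tx.start, tx.end
        if promoter is not None:
            lo, hi = min(lo, promoter[0]), max(hi, promoter[1])
        return [Interval(tx.chrom, lo, hi)]

    tap_loci, bg_loci = [], []
    for p in truth.pcrnas:
        target = tap_loci if p.is_taprna else bg_loci
        target.extend(locus_of(p.pcrna_id, p.promoter))
    for d in truth.decoy_ids:
        bg_loci.extend(locus_of(d, None))

    def in_loci(iv: Interval, loci) -> bool:
        return any(iv.overlaps(l) for l in loci)

    mutations = []
    counter = 0
    for hit in motif_hits:
        iv = hit.interval
        if in_loci(iv, tap_loci):
            rate = config.site_mutation_rate_test
        elif in_loci(iv, bg_loci):
            rate = config.site_mutation_rate_background
        else:
            continue
        if rng.random() >= rate:
            continue
        pos = int(rng.integers(iv.start, iv.end))
        ref = dataset.genome_h[iv.chrom][pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        counter += 1
        mutations.append(MutationRecord(
            chrom=iv.chrom, pos=pos, ref=ref, alt=alt,
            cancer_type=str(rng.choice(list(config.cancer_types))),
            sample_id=f"S{counter:04d}"))
    dataset.mutations = mutations


# ---------------------------------------------------------------------------
# orchestration / validation


def generate_dataset(config: SimulationConfig | None = None,
                     with_expression: bool = True,
                     with_mutations: bool = True) -> SyntheticDataset:
    """Full deterministic dataset: genomes, topology, expression,
    mutations."""
    from .motifs import pwm_scan

    config = config or SimulationConfig()
    dataset = generate_genome_pair(config)
    generate_topology_files(config, dataset)
    if with_expression:
        generate_expression(config, dataset)
    if with_mutations:
        hits = pwm_scan(dataset.genome_h, ctcf_like_pwm(), 0.8)
        hits += pwm_scan(dataset.genome_h, znf263_like_pwm(), 0.8)
        generate_mutations(config, dataset, hits)
    validate(dataset)
    return dataset


def validate(dataset: SyntheticDataset) -> None:
    """Internal-consistency pass: every planted id resolves, coordinates
    stay within chromosome bounds, and annotated transcripts pass the
    catalogue's own filters."""
    ids_h = {t.transcript_id for t in dataset.transcripts_h}
    ids_m = {t.transcript_id for t in dataset.transcripts_m}
    genes_h = {t.gene_id for t in dataset.transcripts_h}
    genes_m = {t.gene_id for t in dataset.transcripts_m}
    for p in dataset.truth.pcrnas:
        assert p.pcrna_id in ids_h and p.mouse_id in ids_m
        assert p.human_gene in genes_h and p.mouse_gene in genes_m
    for d in dataset.truth.decoy_ids:
        assert d in ids_h
    for tx in dataset.transcripts_h:
        assert tx.end <= len(dataset.genome_h[tx.chrom])
    for tx in dataset.transcripts_m:
        assert tx.end <= len(dataset.genome_m[tx.chrom])
    for h, m, _s in dataset.ortholog_pairs:
        assert h in genes_h and m in genes_m
    for tx in dataset.transcripts_h:
        if not tx.is_coding:
            assert coding_potential(
                tx.spliced_sequence(dataset.genome_h)) < 100, tx.transcript_id
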