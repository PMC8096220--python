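"""Synthetic genomes, annotations, occupancy tracks, reads and resources.

Everything the pipeline consumes can be generated here with planted ground
truth, so every stage — peak calling, artifact filtering, classification,
feature construction, the classifier — is testable without downloads.

What the generator emulates: sparse per-base background reads placed
uniformly within transcribed spans (exactly the resampling null of the
pause caller), single-nucleotide pauses planted as fold-amplified counts
over the local occupied-position mean, reads carrying 10-nt UMIs with
configurable PCR duplication and RT mispriming (UMI replaced by the
downstream genomic 10-mer, then corrupted per base at ``umi_error_rate``
to create "escaped" events), and feature resources (pentamer shape tables,
PWM sets with a planted consensus, block-structured methylation).

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .annotation import Gene, GenomeAnnotation
from .artifacts import revcomp
from .occupancy import OccupancyTrack, ReadRecord, TrackSet

BASES = ("A", "C", "G", "T")

# IUPAC codes used for planted motifs (Y = pyrimidine etc.)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "Y": "CT", "R": "AG", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "N": "ACGT",
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic fixtures.

    Defaults are chosen to resemble a sparse nascent-transcription data set:
    a 1-Mb genome with 50 multi-exon genes, uniform background of 0.1
    reads/nt over transcribed spans, and ~20-fold single-nucleotide pauses
    at 0.5 per kb of transcribed sequence (~200 genome-wide).
    """

    seed: int
    genome_length: int = 1_000_000
    gc_content: float = 0.5
    contig: str = "chr1"
    n_genes: int = 50
    gene_length: Tuple[int, int] = (4_000, 12_000)
    n_exons: Tuple[int, int] = (2, 5)
    intergenic_gap: Tuple[int, int] = (2_000, 8_000)
    antisense_overlap: bool = False
    n_enhancers: int = 10
    background_rate: float = 0.1       # reads per transcribed nt
    pause_rate_per_kb: float = 0.5     # planted pauses per transcribed kb
    pause_fold: float = 20.0           # amplification over local occupied mean
    planted_motif: Optional[Mapping[int, str]] = None  # rel pos -> IUPAC base
    misprime_rate: float = 0.0         # fraction of reads converted to artifacts
    duplication_rate: float = 0.0      # fraction of reads PCR-duplicated
    umi_error_rate: float = 0.0        # per-base UMI corruption of misprimed reads
    n_misprime_loci: int = 20

    def __post_init__(self) -> None:
        if self.pause_fold <= 1:
            raise ValueError("pause_fold must be > 1")
        for rate in (self.background_rate, self.pause_rate_per_kb,
                     self.misprime_rate, self.duplication_rate,
                     self.umi_error_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> Dict[str, str]:
    """I.i.d. bases at the configured GC content; seeded and reproducible."""
    rng = np.random.default_rng([config.seed, 1])
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(list(BASES), size=config.genome_length, p=probs)
    return {config.contig: "".join(seq)}


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig) -> GenomeAnnotation:
    """Genes laid along the contig with multi-exon structure.

    Strands alternate pseudo-randomly; with ``antisense_overlap`` every
    seventh gene is placed overlapping its predecessor on the opposite
    strand, so gene-body/antisense conflict loci exist. Enhancers are
    dropped into intergenic gaps.
    """
    rng = np.random.default_rng([config.seed, 2])
    genes: Dict[str, Gene] = {}
    enhancers: List[Tuple[int, int]] = []
    cursor = 2_000
    prev: Optional[Tuple[int, int, str]] = None  # start, end, strand
    for i in range(config.n_genes):
        length = int(rng.integers(*config.gene_length))
        overlap_prev = (config.antisense_overlap and prev is not None
                        and i % 7 == 3)
        if overlap_prev:
            start = max(prev[0] + 500, prev[1] - length // 2)
            strand = "-" if prev[2] == "+" else "+"
        else:
            start = cursor
            strand = "+" if rng.integers(2) else "-"
        end = start + length
        if end + 2_000 > config.genome_length:
            raise ValueError(
                f"genes do not fit in genome_length={config.genome_length}; "
                "reduce n_genes or gene_length")
        n_ex = int(rng.integers(config.n_exons[0], config.n_exons[1] + 1))
        cuts = np.sort(rng.choice(
            np.arange(200, length - 200, 100), size=2 * (n_ex - 1),
            replace=False)) if n_ex > 1 else np.array([], dtype=int)
        bounds = [0, *cuts.tolist(), length]
        exons = [(start + bounds[2 * k], start + bounds[2 * k + 1])
                 for k in range(n_ex)]
        tss = start if strand == "+" else end - 1
        pa = end - 1 if strand == "+" else start
        gid = f"gene{i + 1:03d}"
        genes[gid] = Gene(gid, config.contig, strand, [tss], [pa], exons)
        prev = (start, end, strand)
        gap = int(rng.integers(*config.intergenic_gap))
        if not overlap_prev and config.n_enhancers and gap > 4_800 and \
                len(enhancers) < config.n_enhancers:
            es = end + 4_000
            enhancers.append((es, es + 400))
        cursor = max(cursor, end) + gap
    return GenomeAnnotation(genes, {config.contig: config.genome_length},
                            {config.contig: enhancers})


def write_gtf(annotation: GenomeAnnotation, path: str) -> None:
    """Write genes as GTF (1-based inclusive) with gene/transcript/exon rows."""
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            g = annotation.genes[gid]
            lo, hi = g.span()  # hi is the exclusive exon-end bound
            attrs = f'gene_id "{gid}";'
            fh.write(f"{g.contig}\tsim\tgene\t{lo + 1}\t{hi}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            tid = f"{gid}.t1"
            tattrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            fh.write(f"{g.contig}\tsim\ttranscript\t{lo + 1}\t{hi}\t.\t"
                     f"{g.strand}\t.\t{tattrs}\n")
            for s, e in g.exons:
                fh.write(f"{g.contig}\tsim\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\t{tattrs}\n")


def write_bed(intervals: Mapping[str, Sequence[Tuple[int, int]]], path: str
              ) -> None:
    with open(path, "w") as fh:
        for contig in sorted(intervals):
            for s, e in sorted(intervals[contig]):
                fh.write(f"{contig}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Occupancy with planted pauses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPause:
    contig: str
    strand: str
    position: int
    count: int


def _motif_matches(genome: Mapping[str, str], contig: str, strand: str,
                   positions: np.ndarray,
                   motif: Mapping[int, str]) -> np.ndarray:
    """Filter candidate pause positions to those whose coding-strand context
    matches the planted IUPAC motif (relative convention: pause base = -1)."""
    seq = genome[contig]
    keep = []
    for pos in positions:
        ok = True
        for rel, code in motif.items():
            offset = rel + 1 if rel < 0 else rel
            gpos = pos + offset if strand == "+" else pos - offset
            if not 0 <= gpos < len(seq):
                ok = False
                break
            base = seq[gpos] if strand == "+" else revcomp(seq[gpos])
            if base not in IUPAC[code]:
                ok = False
                break
        if ok:
            keep.append(pos)
    return np.array(keep, dtype=int)


def simulate_occupancy(config: SimConfig, annotation: GenomeAnnotation,
                       genome: Optional[Mapping[str, str]] = None
                       ) -> Tuple[TrackSet, List[PlantedPause]]:
    """Background reads uniform over transcribed spans, plus planted pauses.

    Planted pause counts are ``pause_fold`` times the mean count of occupied
    positions in the surrounding 200-nt window (at least 2). With a
    ``planted_motif``, pause positions are restricted to motif matches
    (``genome`` required). Planted positions keep >= 10 nt spacing so each
    remains a strict local maximum.
    """
    if config.planted_motif is not None and genome is None:
        raise ValueError("planted_motif requires the genome")
    rng = np.random.default_rng([config.seed, 3])
    tracks = TrackSet.empty(annotation.contig_lengths)
    truth: List[PlantedPause] = []
    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        lo = min(gene.upstream_most_tss, gene.downstream_most_pa)
        hi = max(gene.upstream_most_tss, gene.downstream_most_pa) + 1
        span = hi - lo
        counts = tracks[(gene.contig, gene.strand)].counts
        n_bg = rng.poisson(config.background_rate * span)
        for pos in rng.integers(lo, hi, size=n_bg):
            pos = int(pos)
            counts[pos] = counts.get(pos, 0) + 1
        n_pauses = rng.poisson(config.pause_rate_per_kb * span / 1000.0)
        if n_pauses == 0:
            continue
        candidates = np.arange(lo + 30, hi - 30)
        if config.planted_motif is not None:
            candidates = _motif_matches(genome, gene.contig, gene.strand,
                                        candidates, config.planted_motif)
        rng.shuffle(candidates)
        chosen: List[int] = []
        for pos in candidates:
            if len(chosen) == n_pauses:
                break
            if all(abs(pos - c) >= 10 for c in chosen):
                chosen.append(int(pos))
        for pos in chosen:
            local = [c for p, c in counts.items()
                     if abs(p - pos) <= 100 and p != pos]
            local_mean = float(np.mean(local)) if local else 1.0
            planted = max(2, int(round(config.pause_fold * local_mean)))
            counts[pos] = counts.get(pos, 0) + planted
            truth.append(PlantedPause(gene.contig, gene.strand, pos,
                                      counts[pos]))
    return tracks, truth


# ---------------------------------------------------------------------------
# Reads with artifacts
# ---------------------------------------------------------------------------

@dataclass
class ReadTruth:
    duplicate_ids: Set[str] = field(default_factory=set)
    misprimed_ids: Set[str] = field(default_factory=set)
    escaped_ids: Set[str] = field(default_factory=set)  # misprimed, UMI corrupted
    misprime_loci: List[Tuple[str, str, int]] = field(default_factory=list)


def _random_umi(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=10))


def simulate_reads(config: SimConfig, tracks: TrackSet,
                   genome: Mapping[str, str]
                   ) -> Tuple[List[ReadRecord], ReadTruth]:
    """Expand a track into reads with UMIs, then plant artifacts.

    One read per track count with a random UMI; ``misprime_rate`` of reads
    are relocated to one of ``n_misprime_loci`` adapter-like loci with the
    UMI replaced by the genomic 10-mer downstream of the locus, each base
    then corrupted with probability ``umi_error_rate`` (a corrupted UMI is
    an "escaped" event); ``duplication_rate`` of reads are PCR-duplicated
    preserving the UMI. Truth records every artifact read id.
    """
    rng = np.random.default_rng([config.seed, 4])
    truth = ReadTruth()
    reads: List[ReadRecord] = []
    serial = 0

    # adapter-like loci: arbitrary genomic positions (the filter keys on
    # UMI/genome identity, not on adapter content)
    loci: List[Tuple[str, str, int]] = []
    keys = sorted(tracks)
    for _ in range(config.n_misprime_loci):
        contig, strand = keys[int(rng.integers(len(keys)))]
        length = len(genome[contig])
        pos = int(rng.integers(20, length - 20))
        loci.append((contig, strand, pos))
    truth.misprime_loci = loci

    def downstream(contig: str, strand: str, pos: int) -> str:
        if strand == "+":
            mer = genome[contig][pos + 1:pos + 11]
        else:
            mer = revcomp(genome[contig][pos - 10:pos])
        return mer

    for (contig, strand), track in sorted(tracks.items()):
        for pos in track.positions():
            for _ in range(track.counts[pos]):
                serial += 1
                rid = f"r{serial:07d}"
                if config.misprime_rate and rng.random() < config.misprime_rate:
                    lcontig, lstrand, lpos = loci[int(rng.integers(len(loci)))]
                    umi = list(downstream(lcontig, lstrand, lpos))
                    escaped = False
                    for k in range(10):
                        if config.umi_error_rate and \
                                rng.random() < config.umi_error_rate:
                            alternatives = [b for b in BASES if b != umi[k]]
                            umi[k] = alternatives[int(rng.integers(3))]
                            escaped = True
                    reads.append(ReadRecord(lcontig, lstrand, lpos,
                                            "".join(umi), rid))
                    truth.misprimed_ids.add(rid)
                    if escaped:
                        truth.escaped_ids.add(rid)
                else:
                    reads.append(ReadRecord(contig, strand, pos,
                                            _random_umi(rng), rid))

    if config.duplication_rate:
        duplicates = []
        for r in reads:
            if rng.random() < config.duplication_rate:
                serial += 1
                rid = f"r{serial:07d}"
                duplicates.append(ReadRecord(r.contig, r.strand, r.end3,
                                             r.umi, rid))
                truth.duplicate_ids.add(rid)
        reads.extend(duplicates)
    return reads, truth


# ---------------------------------------------------------------------------
# Feature resources
# ---------------------------------------------------------------------------

def simulate_shape_table(mode: str = "random", seed: int = 0,
                         constant: float = 1.0):
    """Complete 1024-pentamer shape table: 'constant', 'g_count' (value =
    number of Gs in the pentamer, all descriptors) or 'random'."""
    from itertools import product

    from .features import ShapeTable

    rng = np.random.default_rng([seed, 5])
    values = {}
    for combo in product(BASES, repeat=5):
        pent = "".join(combo)
        if mode == "constant":
            v = (constant,) * 5
        elif mode == "g_count":
            v = (float(pent.count("G")),) * 5
        elif mode == "random":
            v = tuple(float(x) for x in rng.normal(0.0, 1.0, size=5))
        else:
            raise ValueError(f"unknown shape-table mode {mode!r}")
        values[pent] = v
    return ShapeTable(values)


def write_shape_tsv(table, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("pentamer\tMGW\tRoll\tProT\tHelT\tEP\n")
        for pent in sorted(table.values):
            vals = "\t".join(f"{v:.6g}" for v in table.values[pent])
            fh.write(f"{pent}\t{vals}\n")


def simulate_pwms(consensus: str = "TGACGTCA", n_random: int = 2,
                  seed: int = 0):
    """Small PWM set containing one near-deterministic planted consensus
    plus random background motifs."""
    from .features import Pwm, PwmSet

    rng = np.random.default_rng([seed, 6])
    pwms = []
    probs = np.full((4, len(consensus)), 0.02)
    for j, base in enumerate(consensus):
        probs[BASES.index(base), j] = 0.94
    pwms.append(Pwm("planted", probs / probs.sum(axis=0)))
    for i in range(n_random):
        raw = rng.dirichlet(np.ones(4), size=8).T
        pwms.append(Pwm(f"random{i + 1}", raw))
    return PwmSet(pwms)


def write_pfm(pwm_set, path: str, counts_scale: int = 100) -> None:
    """Write PWMs as JASPAR pfm (counts)."""
    with open(path, "w") as fh:
        for pwm in pwm_set.pwms:
            fh.write(f">{pwm.name} {pwm.name}\n")
            for i, base in enumerate(BASES):
                row = " ".join(str(int(round(p * counts_scale)))
                               for p in pwm.probs[i])
                fh.write(f"{base} [ {row} ]\n")


def simulate_methylation(contig_lengths: Mapping[str, int], seed: int = 0,
                         block: int = 5_000, cpg_every: int = 50
                         ) -> Dict[Tuple[str, int], float]:
    """Block-structured methylation: alternating 5-kb blocks of high and low
    methylation, one covered CpG every ~50 nt."""
    rng = np.random.default_rng([seed, 7])
    meth: Dict[Tuple[str, int], float] = {}
    for contig, length in contig_lengths.items():
        pos = int(rng.integers(1, cpg_every))
        while pos < length:
            level = 0.9 if (pos // block) % 2 == 0 else 0.1
            meth[(contig, pos)] = float(np.clip(
                level + rng.normal(0, 0.03), 0.0, 1.0))
            pos += int(rng.integers(cpg_every // 2, cpg_every * 3 // 2))
    return meth


def write_methylation_tsv(meth: Mapping[Tuple[str, int], float], path: str
                          ) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tposition\tlevel\n")
        for (contig, pos) in sorted(meth):
            fh.write(f"{contig}\t{pos}\t{meth[(contig, pos)]:.4f}\n")


def read_methylation_tsv(path: str) -> Dict[Tuple[str, int], float]:
    meth: Dict[Tuple[str, int], float] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "contig")):
                continue
            contig, pos, level = line.split("\t")
            meth[(contig, int(pos))] = float(level)
    return meth


# ---------------------------------------------------------------------------
# Synthetic feature matrices (for classifier properties)
# ---------------------------------------------------------------------------

def simulate_feature_labels(n: int = 2000, p: int = 40,
                            informative: Sequence[int] = (0, 1, 2, 3, 4),
                            effect: float = 1.5, seed: int = 0):
    """Balanced labelled matrix where exactly ``informative`` features carry
    a planted mean shift (log-odds signal); everything else is N(0, 1) noise."""
    from .features import FeatureMatrix
    import pandas as pd

    rng = np.random.default_rng([seed, 8])
    informative = tuple(j for j in informative if j < p)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0.0, 1.0, size=(len(y), p))
    for j in informative:
        X[y == 1, j] += effect
    order = rng.permutation(len(y))
    X, y = X[order], y[order]
    cols = [f"f{j:02d}" for j in range(p)]
    ids = [f"site{i:05d}" for i in range(len(y))]
    data = pd.DataFrame(X, index=ids, columns=cols)
    labels = pd.Series(y, index=ids)
    return FeatureMatrix(data, labels, [], {"planted": [cols[j] for j in informative]})
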