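"""Strand-specific single-nucleotide 3'-end occupancy tracks.

NET-seq records the genomic position of the 3' end of each nascent-RNA
fragment. This module holds the sparse per-base count representation of
that signal (one track per contig and strand), reads and writes the
bedGraph exchange format, and converts deduplicated, artifact-filtered
read records into masked 3'-end tracks.

Coordinates are 0-based half-open throughout; bedGraph is native to that
convention, GTF input is converted on load (see :mod:`polpause.annotation`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Set, Tuple

STRANDS = ("+", "-")

TrackKey = Tuple[str, str]  # (contig, strand)


@dataclass
class OccupancyTrack:
    """Sparse per-base read counts on one contig and strand.

    ``counts`` maps 0-based position -> positive integer count; positions
    with zero signal are absent. This is the ``x_i`` signal the pause
    caller operates on.
    """

    contig: str
    strand: str
    counts: Dict[int, int] = field(default_factory=dict)
    contig_length: int = 0

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def validate(self) -> None:
        for pos, c in self.counts.items():
            if c < 1:
                raise ValueError(f"count at {self.contig}:{pos} is {c}, must be >= 1")
            if not (0 <= pos < self.contig_length):
                raise ValueError(
                    f"position {pos} outside [0, {self.contig_length}) on {self.contig}"
                )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def positions(self) -> List[int]:
        return sorted(self.counts)


class TrackSet(Dict[TrackKey, OccupancyTrack]):
    """Collection of tracks keyed by (contig, strand)."""

    @classmethod
    def empty(cls, contig_lengths: Mapping[str, int]) -> "TrackSet":
        ts = cls()
        for contig, length in contig_lengths.items():
            for strand in STRANDS:
                ts[(contig, strand)] = OccupancyTrack(contig, strand, {}, length)
        return ts

    @property
    def total(self) -> int:
        return sum(t.total for t in self.values())

    def nonempty(self) -> Iterator[OccupancyTrack]:
        return (t for t in self.values() if t.counts)


@dataclass(frozen=True)
class ReadRecord:
    """One deduplicable nascent-RNA 3'-end observation.

    ``end3`` is the 0-based genomic position of the nascent-RNA 3' end
    (the 5' end of the sequencing read). ``umi`` is the 10-nt random
    decamer introduced during library preparation.
    """

    contig: str
    strand: str
    end3: int
    umi: str
    read_id: str

    def __post_init__(self) -> None:
        if len(self.umi) != 10:
            raise ValueError(f"UMI must be 10 nt, got {self.umi!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class MaskSet:
    """Positions and intervals excluded from 3'-end counting.

    Masked single positions are the strand-aware 3'-most bases of annotated
    exons and introns plus pA sites (RNA-processing intermediates pile up
    there); masked intervals cover abundant RNA classes and similar
    user-supplied regions (strand-independent).
    """

    positions: Dict[TrackKey, Set[int]] = field(default_factory=dict)
    intervals: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    def add_position(self, contig: str, strand: str, pos: int) -> None:
        self.positions.setdefault((contig, strand), set()).add(pos)

    def add_interval(self, contig: str, start: int, end: int) -> None:
        self.intervals.setdefault(contig, []).append((start, end))

    def is_masked(self, contig: str, strand: str, pos: int) -> bool:
        if pos in self.positions.get((contig, strand), ()):
            return True
        for start, end in self.intervals.get(contig, ()):
            if start <= pos < end:
                return True
        return False

    def masked_positions(self, contig: str, strand: str) -> Set[int]:
        """All masked single positions on one contig/strand, intervals expanded."""
        out = set(self.positions.get((contig, strand), ()))
        for start, end in self.intervals.get(contig, ()):
            out.update(range(start, end))
        return out


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def _read_bedgraph(path: str, strand: str, contig_lengths: Mapping[str, int],
                   tracks: TrackSet) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            contig, start_s, end_s, value_s = fields
            start, end = int(start_s), int(end_s)
            value = float(value_s)
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value {value}")
            if value != int(value):
                raise ValueError(
                    f"{path}:{lineno}: non-integer count {value}; "
                    "occupancy tracks must hold read counts"
                )
            count = int(value)
            if contig not in contig_lengths:
                raise ValueError(f"{path}:{lineno}: unknown contig {contig!r}")
            if count == 0:
                continue
            track = tracks[(contig, strand)]
            for pos in range(start, end):
                if pos in track.counts:
                    raise ValueError(
                        f"{path}:{lineno}: position {contig}:{pos} covered twice"
                    )
                track.counts[pos] = count


def read_bedgraph_pair(path_plus: str, path_minus: str,
                       contig_lengths: Mapping[str, int]) -> TrackSet:
    """Load a strand-separated bedGraph pair into a :class:`TrackSet`.

    Intervals of width w expand to w single-base entries of equal count;
    zero-valued records are dropped. Overlapping intervals on one strand
    and non-integer values are errors.
    """
    tracks = TrackSet.empty(contig_lengths)
    _read_bedgraph(path_plus, "+", contig_lengths, tracks)
    _read_bedgraph(path_minus, "-", contig_lengths, tracks)
    for t in tracks.values():
        t.validate()
    return tracks


def _write_bedgraph(tracks: Iterable[OccupancyTrack], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# bedGraph: contig start end count (0-based half-open)\n")
        for track in sorted(tracks, key=lambda t: t.contig):
            positions = track.positions()
            i = 0
            while i < len(positions):
                start = positions[i]
                count = track.counts[start]
                j = i + 1
                # merge runs of adjacent equal counts into one interval
                while (j < len(positions) and positions[j] == positions[j - 1] + 1
                       and track.counts[positions[j]] == count):
                    j += 1
                fh.write(f"{track.contig}\t{start}\t{positions[j - 1] + 1}\t{count}\n")
                i = j


def write_bedgraph_pair(tracks: TrackSet, out_prefix: str) -> Tuple[str, str]:
    """Write a track set as ``<prefix>.plus.bedgraph`` / ``<prefix>.minus.bedgraph``."""
    paths = (f"{out_prefix}.plus.bedgraph", f"{out_prefix}.minus.bedgraph")
    for strand, path in zip(STRANDS, paths):
        _write_bedgraph((t for (c, s), t in tracks.items() if s == strand), path)
    return paths


# ---------------------------------------------------------------------------
# Read records (TSV exchange format)
# ---------------------------------------------------------------------------

READS_TSV_COLUMNS = ("contig", "end3", "strand", "umi", "read_id")


def read_reads_tsv(path: str) -> List[ReadRecord]:
    """Read the 5-column reads TSV (contig, end3, strand, umi, read_id)."""
    reads: List[ReadRecord] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "contig":
                continue
            contig, end3, strand, umi, read_id = row[:5]
            reads.append(ReadRecord(contig, strand, int(end3), umi, read_id))
    return reads


def write_reads_tsv(reads: Iterable[ReadRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(READS_TSV_COLUMNS) + "\n")
        for r in reads:
            fh.write(f"{r.contig}\t{r.end3}\t{r.strand}\t{r.umi}\t{r.read_id}\n")


# ---------------------------------------------------------------------------
# Masking and 3'-end track construction
# ---------------------------------------------------------------------------

def build_mask(annotation, masked_intervals: Mapping[str, List[Tuple[int, int]]]
               | None = None) -> MaskSet:
    """Build the RNA-processing-intermediate mask from a gene annotation.

    Masks, per gene strand, the 3'-most base of every annotated exon and
    intron plus every pA site (splicing and 3'-cleavage intermediates end
    exactly there), and any supplied intervals (abundant RNA classes).

    The 3'-most base is strand-aware: genomic ``end - 1`` on +, genomic
    ``start`` on -.
    """
    mask = MaskSet()
    for gene in annotation.genes.values():
        exons = sorted(gene.exons)
        introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
                   if exons[i + 1][0] > exons[i][1]]
        for start, end in exons + introns:
            pos = end - 1 if gene.strand == "+" else start
            mask.add_position(gene.contig, gene.strand, pos)
        for pa in gene.pa_sites:
            mask.add_position(gene.contig, gene.strand, pa)
    if masked_intervals:
        for contig, ivals in masked_intervals.items():
            for start, end in ivals:
                mask.add_interval(contig, start, end)
    return mask


def three_prime_track(reads: Iterable[ReadRecord], mask: MaskSet,
                      contig_lengths: Mapping[str, int]) -> TrackSet:
    """Count read 3' ends per (contig, strand, position), dropping masked ends.

    Input reads should already be deduplicated and mispriming-filtered
    (:mod:`polpause.artifacts`). Order-independent; the sum of counts equals
    the number of surviving reads.
    """
    tracks = TrackSet.empty(contig_lengths)
    for r in reads:
        if r.contig not in contig_lengths:
            raise ValueError(f"read {r.read_id}: unknown contig {r.contig!r}")
        if mask.is_masked(r.contig, r.strand, r.end3):
            continue
        counts = tracks[(r.contig, r.strand)].counts
        counts[r.end3] = counts.get(r.end3, 0) + 1
    return tracks


def read_bed_intervals(path: str) -> Dict[str, List[Tuple[int, int]]]:
    """Read BED (>=3 columns) into per-contig interval lists."""
    out: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return out
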