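"""UMI deduplication and reverse-transcription mispriming filtering.

Two library-preparation artifacts create spurious single-nucleotide pileups
in NET-seq data: PCR duplicates (identified by the 10-nt UMI) and RT
mispriming, where the RT primer anneals to an adapter-like sequence inside
the nascent RNA instead of the ligated 3' adapter. A misprimed read's "UMI"
is then not a random decamer but a copy of the genomic sequence immediately
downstream (in transcription direction) of the apparent 3' end — which is
how it is detected.

The filter (a) removes reads whose UMI matches that downstream 10-mer
exactly, (b) masks positions where more than ``prone_threshold`` of reads
were such exact matches, and (c) estimates how many mispriming events
escape exact-match detection because of base errors introduced during RT,
PCR or sequencing: among reads at prone positions, any UMI with at least
``similarity_threshold`` identity to the downstream 10-mer counts as a
mispriming event, and the escaped fraction is the share of those events
whose UMI was not an exact match.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .occupancy import OccupancyTrack, ReadRecord, TrackKey, TrackSet

logger = logging.getLogger(__name__)

UMI_LEN = 10


@dataclass
class MisprimingReport:
    """Outcome of mispriming detection on one sample."""

    prone_positions: Dict[TrackKey, Set[int]] = field(default_factory=dict)
    n_mispriming_events: int = 0
    n_exact_match_events: int = 0
    removed_read_ids: Set[str] = field(default_factory=set)
    n_untestable: int = 0  # reads too close to a contig edge for a downstream 10-mer

    @property
    def escaped_fraction(self) -> float:
        """Share of mispriming events whose UMI was not an exact genomic match."""
        if self.n_mispriming_events == 0:
            return 0.0
        return (self.n_mispriming_events - self.n_exact_match_events) / self.n_mispriming_events

    def to_json(self, path: str) -> None:
        payload = {
            "n_mispriming_events": self.n_mispriming_events,
            "n_exact_match_events": self.n_exact_match_events,
            "escaped_fraction": self.escaped_fraction,
            "n_removed_reads": len(self.removed_read_ids),
            "n_untestable": self.n_untestable,
            "n_prone_positions": sum(len(v) for v in self.prone_positions.values()),
            "prone_positions": {
                f"{contig}:{strand}": sorted(pos)
                for (contig, strand), pos in self.prone_positions.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# PCR-duplicate collapsing
# ---------------------------------------------------------------------------

def dedup_reads(reads: Iterable[ReadRecord], collapse_mode: str = "exact"
                ) -> List[ReadRecord]:
    """Collapse PCR duplicates: identical (contig, strand, end3, UMI) -> one read.

    ``hamming1`` additionally merges, within one position, UMIs at Hamming
    distance <= 1 into a higher-count UMI (greedy by descending count, ties
    broken lexicographically) — the dominant error mode for sequencing-error
    UMI variants at NET-seq UMI lengths.
    """
    if collapse_mode not in ("exact", "hamming1"):
        raise ValueError(f"unknown collapse_mode {collapse_mode!r}")
    groups: Dict[Tuple[str, str, int], Dict[str, ReadRecord]] = defaultdict(dict)
    umi_counts: Dict[Tuple[str, str, int], Counter] = defaultdict(Counter)
    for r in reads:
        key = (r.contig, r.strand, r.end3)
        groups[key].setdefault(r.umi, r)  # first read per UMI survives
        umi_counts[key][r.umi] += 1

    survivors: List[ReadRecord] = []
    for key in sorted(groups):
        by_umi = groups[key]
        if collapse_mode == "exact":
            survivors.extend(by_umi[u] for u in sorted(by_umi))
            continue
        counts = umi_counts[key]
        # greedy absorption: most-supported UMIs first, lexicographic on ties
        order = sorted(counts, key=lambda u: (-counts[u], u))
        kept: List[str] = []
        for umi in order:
            parent = next((k for k in kept if _hamming(k, umi) <= 1), None)
            if parent is None:
                kept.append(umi)
        survivors.extend(by_umi[u] for u in sorted(kept))
    return survivors


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Mispriming detection
# ---------------------------------------------------------------------------

def downstream_10mer(genome, contig: str, strand: str, end3: int) -> str | None:
    """Genomic 10-mer continuing past the 3' end in transcription direction.

    On + this is [end3+1, end3+11); on - it is the reverse complement of
    [end3-10, end3). Returns None when the window leaves the contig.
    These are the bases a correctly primed RT would have copied next.
    """
    if strand == "+":
        start, end = end3 + 1, end3 + 11
    else:
        start, end = end3 - 10, end3
    if start < 0 or end > len(genome[contig]):
        return None
    seq = str(genome[contig][start:end]).upper()
    if strand == "-":
        seq = revcomp(seq)
    return seq


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def umi_similarity(umi: str, genomic: str) -> float:
    """Positionwise identity over the 10-mer; N never matches."""
    return sum(a == b and a != "N" for a, b in zip(umi, genomic)) / UMI_LEN


def detect_mispriming(reads: Sequence[ReadRecord], genome,
                      prone_threshold: float = 0.05,
                      similarity_threshold: float = 0.5,
                      ) -> Tuple[List[ReadRecord], MisprimingReport]:
    """Remove RT-mispriming reads and quantify how many escape detection.

    Steps, applied to deduplicated reads:

    1. A read is an *exact-match event* if its UMI equals the genomic 10-mer
       immediately downstream of its 3' end; exact-match reads are removed.
    2. A position is *prone* if its fraction of exact-match reads (over all
       reads aligned there, pre-removal) is strictly greater than
       ``prone_threshold``; all reads at prone positions are removed.
    3. Among reads at prone positions, any UMI with similarity >=
       ``similarity_threshold`` to the downstream 10-mer counts as a
       *mispriming event* (exact matches included).
    4. ``escaped_fraction`` = events that were not exact matches / all events.

    Reads whose 3' end sits closer than 10 nt to a contig edge have no
    downstream 10-mer and are exempt from testing (kept, logged).
    """
    report = MisprimingReport()
    by_pos: Dict[Tuple[str, str, int], List[Tuple[ReadRecord, str | None]]] = defaultdict(list)
    for r in reads:
        mer = downstream_10mer(genome, r.contig, r.strand, r.end3)
        if mer is None:
            report.n_untestable += 1
        by_pos[(r.contig, r.strand, r.end3)].append((r, mer))
    if report.n_untestable:
        logger.info("%d reads too close to a contig edge for mispriming testing",
                    report.n_untestable)

    clean: List[ReadRecord] = []
    for (contig, strand, pos), items in by_pos.items():
        testable = [(r, mer) for r, mer in items if mer is not None]
        exact = [r for r, mer in testable if r.umi == mer]
        n_total = len(items)
        frac_exact = len(exact) / n_total if n_total else 0.0
        prone = frac_exact > prone_threshold
        if prone:
            report.prone_positions.setdefault((contig, strand), set()).add(pos)
            for r, mer in testable:
                if umi_similarity(r.umi, mer) >= similarity_threshold:
                    report.n_mispriming_events += 1
                    if r.umi == mer:
                        report.n_exact_match_events += 1
            report.removed_read_ids.update(r.read_id for r, _ in items)
        else:
            # exact matches are removed everywhere, but mispriming events are
            # only *quantified* at prone positions
            report.removed_read_ids.update(r.read_id for r in exact)
            exact_ids = {r.read_id for r in exact}
            clean.extend(r for r, _ in items if r.read_id not in exact_ids)
    return clean, report


def apply_mispriming_mask(track: OccupancyTrack, report: MisprimingReport
                          ) -> OccupancyTrack:
    """Drop all mispriming-prone positions from a track (idempotent)."""
    prone = report.prone_positions.get((track.contig, track.strand), set())
    counts = {p: c for p, c in track.counts.items() if p not in prone}
    return OccupancyTrack(track.contig, track.strand, counts, track.contig_length)


def apply_mispriming_mask_all(tracks: TrackSet, report: MisprimingReport) -> TrackSet:
    out = TrackSet()
    for key, track in tracks.items():
        out[key] = apply_mispriming_mask(track, report)
    return out
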