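"""Pause-detecting algorithm (PDA): single-nucleotide peak calling.

Pol II pausing appears in NET-seq occupancy as single-base spikes above the
local read density. PDA works in two steps:

1. *Peak detection* — every strict local maximum of the signal, i.e. a
   position i with ``x[i-1] < x[i] > x[i+1]`` (absent neighbours count 0).
2. *Peak evaluation* — a nonparametric resampling test of the null that
   reads are uniformly distributed over the occupied positions of the
   surrounding window: with M reads over l occupied positions in the
   window of length L centred on i, redistribute the M reads uniformly
   over the l positions N times, record each redistribution's maximum
   per-position count, and compare the observed count against that null
   pool. Benjamini–Hochberg correction is applied across all local maxima
   of the sample; corrected q < alpha is called significant.

The resampling null (the maximum cell count of a uniform multinomial) also
admits an exact tail probability, computed here by conditioning independent
truncated Poissons on their sum; it replaces resampling when cheap, and
serves as the independent oracle for the resampled p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, log2
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .occupancy import OccupancyTrack, TrackSet


@dataclass
class PdaParams:
    """Tunable parameters of the pause caller.

    window_length
        L, the window centred on each candidate over which local density
        is measured (default 200 nt).
    n_resamples
        N, size of the simulated null pool per (M, l) (default 10000).
    alpha
        BH-corrected significance level (default 0.05).
    exact_cutoff
        Upper bound on the convolution work ~(M+1)^2 * log2(l) below which
        the exact null tail is used instead of resampling.
    strict
        If True, reproduce the literal resampling rule p = #{max > observed}/N
        (which can return 0 on discrete ties); default uses the add-one
        permutation form p = (1 + #{max >= observed}) / (N + 1), which is
        guaranteed valid.
    """

    window_length: int = 200
    n_resamples: int = 10000
    alpha: float = 0.05
    seed: int = 0
    exact_cutoff: int = 10 ** 6
    strict: bool = False

    def __post_init__(self) -> None:
        if self.window_length < 2 or self.window_length % 2:
            raise ValueError("window_length must be even and >= 2")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class LocalDensity:
    """Local Pol II density: M reads over l occupied positions in the window."""

    M: int
    l: int

    def __post_init__(self) -> None:
        if self.M < 1 or self.l < 1:
            raise ValueError("M and l must be >= 1")


@dataclass
class PauseSite:
    """One called (or candidate) pause: a significant single-base occupancy peak."""

    contig: str
    strand: str
    position: int
    count: int
    density: LocalDensity
    p: float
    q: float = 1.0
    significant: bool = False
    method: str = "resample"  # or "exact"

    @property
    def key(self) -> Tuple[str, str, int]:
        return (self.contig, self.strand, self.position)


@dataclass
class ReproducibilityReport:
    """Replicate agreement of significant pause calls."""

    percent_shared: List[float]
    fisher_p: float
    n_common: int
    n_per_replicate: List[int]


# ---------------------------------------------------------------------------
# Step 1: peak detection
# ---------------------------------------------------------------------------

def find_local_maxima(track: OccupancyTrack) -> List[int]:
    """Positions with strictly greater count than both immediate neighbours.

    Absent neighbours count 0; equal-count plateaus are never maxima
    (strict definition, so adjacent co-maximal positions are excluded).
    """
    c = track.counts
    return sorted(p for p, x in c.items()
                  if x > c.get(p - 1, 0) and x > c.get(p + 1, 0))


def local_density(track: OccupancyTrack, i: int, L: int) -> LocalDensity:
    """M (reads) and l (occupied positions) in [i - L/2, i + L/2) on one strand,
    clipped to the contig."""
    lo = max(0, i - L // 2)
    hi = min(track.contig_length, i + L // 2)
    M = l = 0
    for p, x in track.counts.items():
        if lo <= p < hi:
            M += x
            l += 1
    return LocalDensity(M, l)


def _densities_batch(track: OccupancyTrack, candidates: Sequence[int], L: int
                     ) -> List[LocalDensity]:
    """Vectorised local_density for many candidates on one track."""
    positions = np.array(track.positions(), dtype=np.int64)
    counts = np.array([track.counts[p] for p in positions], dtype=np.int64)
    csum = np.concatenate([[0], np.cumsum(counts)])
    out = []
    for i in candidates:
        lo = max(0, i - L // 2)
        hi = min(track.contig_length, i + L // 2)
        a, b = np.searchsorted(positions, [lo, hi])
        out.append(LocalDensity(int(csum[b] - csum[a]), int(b - a)))
    return out


# ---------------------------------------------------------------------------
# Step 2: the resampling null and its exact counterpart
# ---------------------------------------------------------------------------

def exact_max_tail(M: int, l: int, k: int) -> float:
    """Exact P(max cell count >= k) when M reads fall uniformly on l cells.

    Uses the Poisson conditioning identity: with X_1..X_l iid Poisson(M/l),
    the cell counts are distributed as (X_1..X_l | sum X = M), so
    P(max <= c, sum = M) is the M-th coefficient of the l-fold convolution
    of the truncated Poisson pmf, and P(sum = M) = Poisson(M).pmf(M).
    """
    if k > M:
        return 0.0
    if k <= ceil(M / l):
        return 1.0  # pigeonhole: some cell always holds >= ceil(M/l)
    if l == 1:
        return 1.0  # max == M >= k handled above
    c = k - 1
    lam = M / l
    base = stats.poisson.pmf(np.arange(c + 1), lam)
    # l-fold self-convolution by squaring, truncated at M+1 terms
    acc = None
    power = base
    n = l
    while n:
        if n & 1:
            acc = power if acc is None else np.convolve(acc, power)[: M + 1]
        n >>= 1
        if n:
            power = np.convolve(power, power)[: M + 1]
    joint = acc[M] if len(acc) > M else 0.0
    p_max_le_c = float(joint / stats.poisson.pmf(M, lam * l))  # lam * l == M
    return float(min(1.0, max(0.0, 1.0 - p_max_le_c)))


def exact_feasible(M: int, l: int, cutoff: int) -> bool:
    """Work heuristic for preferring the exact tail over resampling."""
    if l == 1 or M <= 1:
        return True
    return (M + 1) ** 2 * max(1, ceil(log2(l)) + 1) <= cutoff


def _null_max_pool(M: int, l: int, N: int, seed: int) -> np.ndarray:
    """N simulated maxima of a uniform multinomial(M, l) redistribution."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, M, l])
    probs = np.full(l, 1.0 / l)
    # chunk to cap memory at ~8M cells
    chunk = max(1, 8_000_000 // max(l, 1))
    maxima = np.empty(N, dtype=np.int64)
    done = 0
    while done < N:
        n = min(chunk, N - done)
        maxima[done:done + n] = rng.multinomial(M, probs, size=n).max(axis=1)
        done += n
    return maxima


def resampled_pvalue(density: LocalDensity, observed: int, N: int, seed: int,
                     strict: bool = False) -> float:
    """Resampling p-value for an observed count against the uniform null.

    Default is the add-one permutation form (1 + #{max >= obs}) / (N + 1);
    ``strict`` reproduces the literal fraction #{max > obs} / N.
    """
    if observed > density.M:
        raise ValueError("observed count exceeds window total M")
    maxima = _null_max_pool(density.M, density.l, N, seed)
    if strict:
        return float((maxima > observed).sum() / N)
    return float((1 + (maxima >= observed).sum()) / (N + 1))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# The full caller
# ---------------------------------------------------------------------------

def call_pauses(tracks: TrackSet | OccupancyTrack, params: PdaParams
                ) -> List[PauseSite]:
    """Run PDA over a sample: detect local maxima, evaluate each against the
    local uniform-redistribution null, BH-correct across all candidates.

    The BH family is every local maximum of the sample (all contigs and both
    strands pooled). Null p-values are cached per (M, l); the exact tail is
    used where :func:`exact_feasible`, resampling (seeded per (M, l) from
    ``params.seed``) otherwise. Bit-reproducible for a fixed seed.
    """
    if isinstance(tracks, OccupancyTrack):
        ts = TrackSet()
        ts[(tracks.contig, tracks.strand)] = tracks
        tracks = ts

    sites: List[PauseSite] = []
    pool_cache: Dict[Tuple[int, int], np.ndarray] = {}
    for (contig, strand), track in sorted(tracks.items()):
        candidates = find_local_maxima(track)
        if not candidates:
            continue
        densities = _densities_batch(track, candidates, params.window_length)
        for pos, dens in zip(candidates, densities):
            observed = track.counts[pos]
            if exact_feasible(dens.M, dens.l, params.exact_cutoff):
                p = exact_max_tail(dens.M, dens.l, observed)
                method = "exact"
            else:
                key = (dens.M, dens.l)
                if key not in pool_cache:
                    pool_cache[key] = _null_max_pool(
                        dens.M, dens.l, params.n_resamples, params.seed)
                maxima = pool_cache[key]
                N = params.n_resamples
                if params.strict:
                    p = float((maxima > observed).sum() / N)
                else:
                    p = float((1 + (maxima >= observed).sum()) / (N + 1))
                method = "resample"
            sites.append(PauseSite(contig, strand, pos, observed, dens,
                                   p=p, method=method))
    if not sites:
        return sites
    q = bh_adjust([s.p for s in sites])
    for s, qi in zip(sites, q):
        s.q = float(qi)
        s.significant = bool(qi < params.alpha)
    return sites


# ---------------------------------------------------------------------------
# Reproducibility across replicates
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric tail sum)."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 non-negative integers")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def replicate_overlap(calls: Sequence[Sequence[PauseSite]]) -> ReproducibilityReport:
    """Replicate agreement of pause calls at exact nucleotide positions.

    Percent shared per replicate counts only peaks whose position is a local
    maximum (a candidate) in *all* replicates: it is the share of a
    replicate's significant peaks (restricted to jointly detectable ones)
    that are significant in every replicate. The two-sided Fisher test uses
    all peaks of the first two replicates regardless of joint detectability.
    """
    if len(calls) < 2:
        raise ValueError("need at least two replicates")
    cand_sets = [frozenset(s.key for s in rep) for rep in calls]
    sig_sets = [frozenset(s.key for s in rep if s.significant) for rep in calls]
    common_cand = frozenset.intersection(*cand_sets)
    sig_in_common = [s & common_cand for s in sig_sets]
    common_sig = frozenset.intersection(*sig_in_common)
    percents = [100.0 * len(common_sig) / len(s) if s else 0.0
                for s in sig_in_common]

    universe = cand_sets[0] | cand_sets[1]
    a = len(sig_sets[0] & sig_sets[1])
    b = len(sig_sets[0] - sig_sets[1])
    c = len(sig_sets[1] - sig_sets[0])
    d = len(universe) - a - b - c
    fisher_p = fisher_exact_2x2([[a, b], [c, d]])
    return ReproducibilityReport(
        percent_shared=percents,
        fisher_p=fisher_p,
        n_common=len(common_sig),
        n_per_replicate=[len(s) for s in sig_sets],
    )


# ---------------------------------------------------------------------------
# Depth sensitivity
# ---------------------------------------------------------------------------

def downsample(tracks: TrackSet | OccupancyTrack, fraction: float, seed: int
               ) -> TrackSet | OccupancyTrack:
    """Binomial thinning: keep each read independently with probability
    ``fraction`` (simulates lower sequencing depth); zero positions dropped."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)

    def thin(track: OccupancyTrack) -> OccupancyTrack:
        if fraction == 1.0:
            return OccupancyTrack(track.contig, track.strand,
                                  dict(track.counts), track.contig_length)
        counts = {}
        for pos in track.positions():
            kept = int(rng.binomial(track.counts[pos], fraction))
            if kept:
                counts[pos] = kept
        return OccupancyTrack(track.contig, track.strand, counts,
                              track.contig_length)

    if isinstance(tracks, OccupancyTrack):
        return thin(tracks)
    out = TrackSet()
    for key in sorted(tracks):
        out[key] = thin(tracks[key])
    return out


# ---------------------------------------------------------------------------
# Pause-table I/O
# ---------------------------------------------------------------------------

PAUSE_TSV_COLUMNS = ("contig", "start", "end", "strand", "count", "M", "l",
                     "p", "q", "significant", "method")


def write_pause_tsv(sites: Iterable[PauseSite], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PAUSE_TSV_COLUMNS) + "\n")
        for s in sorted(sites, key=lambda s: s.key):
            fh.write(f"{s.contig}\t{s.position}\t{s.position + 1}\t{s.strand}\t"
                     f"{s.count}\t{s.density.M}\t{s.density.l}\t"
                     f"{s.p:.10g}\t{s.q:.10g}\t{int(s.significant)}\t{s.method}\n")


def read_pause_tsv(path: str) -> List[PauseSite]:
    sites = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sites.append(PauseSite(
                contig=f[0], strand=f[3], position=int(f[1]), count=int(f[4]),
                density=LocalDensity(int(f[5]), int(f[6])),
                p=float(f[7]), q=float(f[8]),
                significant=bool(int(f[9])), method=f[10]))
    return sites
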