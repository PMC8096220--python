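"""DNA-sequence feature construction for pausing and non-pausing sites.

Relative-coordinate convention (used throughout): the called pause base is
position **-1**, the last nucleotide added to the nascent RNA; **+1** is the
next base in transcription direction, where the incoming NTP binds; there
is no position 0; negative indices extend upstream. The RNA-DNA hybrid
inside the polymerase spans -10..-1. All sequences are reported on the
coding (non-template) strand, 5'->3' in transcription direction, so for a
minus-strand site the genomic extraction is reverse-complemented.

Features built here (the species-universal set):

* nucleotide-skew differences between a 20-nt window downstream and one
  upstream of the site, for all six base pairs;
* nucleotide identity (one-hot) at +1, -1, -2, -3, -10, -11 — the active
  centre and both ends of the hybrid;
* nearest-neighbor thermodynamics (dH, dS, dG37, Tm) of the 10-bp RNA-DNA
  hybrid;
* minimum free energy of the nascent-RNA stretch -29..-11 (the hairpin-
  formation region), via a builtin stacking-energy dynamic program.

Optional resource-backed features: pentamer DNA-shape statistics, PWM-match
flags for transcription-factor and RNA-binding-protein motifs (exact
null-score thresholding), mean CpG methylation, and interval-overlap flags
(non-B DNA, G-quadruplexes, ...). Sequence enrichment logos contrast
pause against control sites.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .artifacts import revcomp

BASES = ("A", "C", "G", "T")
BASE_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"),
              ("C", "G"), ("C", "T"), ("G", "T"))
IDENTITY_POSITIONS = (1, -1, -2, -3, -10, -11)

GAS_CONSTANT = 1.987  # cal/(mol*K)


class AmbiguousBaseError(ValueError):
    """A required window contains a non-ACGT base; the site is dropped."""


class WindowError(ValueError):
    """A required window does not fit on the contig; the site is dropped."""


# ---------------------------------------------------------------------------
# Site sequences and the relative-coordinate map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteSequence:
    """Coding-strand sequence around one genomic site.

    ``offset_zero`` is the string index of the site base (relative
    position -1). Relative coordinate r maps to index
    ``offset_zero + r + 1`` for r < 0 and ``offset_zero + r`` for r > 0.
    """

    contig: str
    strand: str
    position: int
    seq: str
    offset_zero: int

    def index(self, r: int) -> int:
        if r == 0:
            raise ValueError("relative position 0 does not exist")
        return self.offset_zero + r + 1 if r < 0 else self.offset_zero + r

    def base(self, r: int) -> str:
        i = self.index(r)
        if not 0 <= i < len(self.seq):
            raise WindowError(f"relative position {r} outside extracted window")
        return self.seq[i]

    def window(self, r_lo: int, r_hi: int) -> str:
        """Inclusive relative window [r_lo, r_hi] as a string (no 0 position)."""
        i_lo, i_hi = self.index(r_lo), self.index(r_hi)
        if i_lo < 0 or i_hi >= len(self.seq):
            raise WindowError(f"window [{r_lo},{r_hi}] outside extracted span")
        return self.seq[i_lo:i_hi + 1]


def site_sequence(genome, site, upstream: int, downstream: int) -> SiteSequence:
    """Extract the coding-strand sequence ``upstream`` bases before, through
    ``downstream`` bases after, the site base (relative -1).

    Minus-strand sites are reverse-complemented so that downstream is the
    direction of transcription. Raises :class:`WindowError` when the window
    leaves the contig.
    """
    contig, strand, pos = site.contig, site.strand, site.position
    length = len(genome[contig])
    if strand == "+":
        start, end = pos - upstream, pos + downstream + 1
    else:
        start, end = pos - downstream, pos + upstream + 1
    if start < 0 or end > length:
        raise WindowError(
            f"window [{start},{end}) off contig {contig} (length {length})")
    seq = str(genome[contig][start:end]).upper()
    if strand == "-":
        seq = revcomp(seq)
    return SiteSequence(contig, strand, pos, seq, upstream)


# ---------------------------------------------------------------------------
# Skewness differences
# ---------------------------------------------------------------------------

def base_skew(window: str, x: str, y: str) -> float:
    """XY skew (|X| - |Y|) / (|X| + |Y|) of one window; 0 when neither occurs."""
    nx, ny = window.count(x), window.count(y)
    return 0.0 if nx + ny == 0 else (nx - ny) / (nx + ny)


def skew_diff_features(seq: SiteSequence) -> Dict[str, float]:
    """Downstream-minus-upstream skew difference for the six base pairs.

    Windows are the 20-nt stretches whose near edges sit 10 nt from the
    site: upstream [-29, -10] and downstream [+10, +29].
    """
    up = seq.window(-29, -10)
    down = seq.window(10, 29)
    return {f"skew_diff_{x}{y}": base_skew(down, x, y) - base_skew(up, x, y)
            for x, y in BASE_PAIRS}


# ---------------------------------------------------------------------------
# Nucleotide identity
# ---------------------------------------------------------------------------

def nucleotide_identity_features(seq: SiteSequence) -> Dict[str, float]:
    """One-hot base identity at +1, -1, -2, -3, -10, -11 (24 binary features).

    These positions cover the NTP-insertion site, the pause base and both
    ends of the RNA-DNA hybrid; an N at any of them raises
    :class:`AmbiguousBaseError`.
    """
    out: Dict[str, float] = {}
    for r in IDENTITY_POSITIONS:
        b = seq.base(r)
        if b not in BASES:
            raise AmbiguousBaseError(f"ambiguous base {b!r} at position {r:+d}")
        for base in BASES:
            out[f"nt_{r:+d}_{base}"] = 1.0 if base == b else 0.0
    return out


# ---------------------------------------------------------------------------
# RNA-DNA hybrid thermodynamics
# ---------------------------------------------------------------------------

@dataclass
class ThermoParams:
    """Nearest-neighbor parameters for the RNA/DNA hybrid duplex.

    ``dh`` (kcal/mol) and ``ds`` (cal/(mol*K)) are keyed by RNA-strand
    dinucleotide (5'->3'); initiation terms are stored separately.
    ``strand_concentration`` (M) enters the two-state melting temperature.
    """

    dh: Dict[str, float]
    ds: Dict[str, float]
    dh_init: float
    ds_init: float
    strand_concentration: float = 1e-4

    @classmethod
    def from_tsv(cls, path) -> "ThermoParams":
        dh: Dict[str, float] = {}
        ds: Dict[str, float] = {}
        dh_init = ds_init = 0.0
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("rna_"):
                    continue
                key, h, s = line.split("\t")
                if key == "INIT":
                    dh_init, ds_init = float(h), float(s)
                else:
                    dh[key], ds[key] = float(h), float(s)
        missing = {a + b for a in "ACGU" for b in "ACGU"} - set(dh)
        if missing:
            raise ValueError(f"thermo table missing dinucleotides: {sorted(missing)}")
        return cls(dh, ds, dh_init, ds_init)

    @classmethod
    def default(cls) -> "ThermoParams":
        ref = importlib_resources.files("polpause.data") / "rna_dna_nn_sugimoto1995.tsv"
        with importlib_resources.as_file(ref) as path:
            return cls.from_tsv(path)


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def hybrid_thermo_features(seq: SiteSequence,
                           params: Optional[ThermoParams] = None
                           ) -> Dict[str, float]:
    """dH, dS, dG37 and Tm of the 10-nt RNA-DNA hybrid spanning -10..-1.

    The nascent RNA -10..-1 (coding-strand sequence transcribed to RNA)
    pairs with the DNA template; totals are initiation plus the nine
    nearest-neighbor steps. dG37 = dH - 310.15 * dS / 1000 (kcal/mol);
    Tm(K) = 1000 * dH / (dS + R * ln(CT / 4)) for the two-state,
    non-self-complementary duplex.
    """
    if params is None:
        params = ThermoParams.default()
    rna = dna_to_rna(seq.window(-10, -1))
    if any(b not in "ACGU" for b in rna):
        raise AmbiguousBaseError(f"ambiguous base in hybrid window {rna!r}")
    dh = params.dh_init
    ds = params.ds_init
    for i in range(len(rna) - 1):
        step = rna[i:i + 2]
        if step not in params.dh:
            raise ValueError(f"missing nearest-neighbor entry {step!r}")
        dh += params.dh[step]
        ds += params.ds[step]
    dg37 = dh - 310.15 * ds / 1000.0
    tm = 1000.0 * dh / (ds + GAS_CONSTANT * math.log(params.strand_concentration / 4.0))
    return {"hybrid_dH": dh, "hybrid_dS": ds, "hybrid_dG37": dg37,
            "hybrid_Tm": tm}


# ---------------------------------------------------------------------------
# Nascent-RNA minimum free energy (builtin stacking-energy DP)
# ---------------------------------------------------------------------------

# Watson-Crick + wobble pairs, with per-pair stacking weights (kcal/mol):
# the energy of two adjacent base pairs is -(w(pair1) + w(pair2)); isolated
# pairs contribute nothing. A deliberately small, documented model — the
# classifier needs a monotone structure-propensity score, not Turner-grade
# absolute energies.
_PAIR_WEIGHT = {("G", "C"): 1.5, ("C", "G"): 1.5,
                ("A", "U"): 0.9, ("U", "A"): 0.9,
                ("G", "U"): 0.5, ("U", "G"): 0.5}
MIN_HAIRPIN_LOOP = 3


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIR_WEIGHT


def _stack_energy(a1: str, b1: str, a2: str, b2: str) -> float:
    return -(_PAIR_WEIGHT[(a1, b1)] + _PAIR_WEIGHT[(a2, b2)])


def rna_mfe(rna: str) -> float:
    """Minimum free energy over pseudoknot-free structures of an RNA string.

    Nearest-neighbor stacking model with minimum hairpin loop of 3,
    computed by a Nussinov-style dynamic program over (paired, unpaired)
    subproblems; exact for this energy model (verified against exhaustive
    structure enumeration in the test-suite for short sequences).
    """
    n = len(rna)
    if n < MIN_HAIRPIN_LOOP + 2:
        return 0.0
    INF = float("inf")
    V = [[INF] * n for _ in range(n)]  # best energy with (i, j) paired
    W = [[0.0] * n for _ in range(n)]  # best energy of subsequence [i, j]
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            if _can_pair(rna[i], rna[j]):
                v = W[i + 1][j - 1] if j - 1 >= i + 1 else 0.0
                if (j - 1 - (i + 1) > MIN_HAIRPIN_LOOP
                        and _can_pair(rna[i + 1], rna[j - 1])
                        and V[i + 1][j - 1] < INF):
                    v = min(v, V[i + 1][j - 1]
                            + _stack_energy(rna[i], rna[j], rna[i + 1], rna[j - 1]))
                V[i][j] = v
            best = W[i + 1][j]
            for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                if V[i][k] < INF:
                    rest = W[k + 1][j] if k + 1 <= j else 0.0
                    best = min(best, V[i][k] + rest)
            W[i][j] = best
    return W[0][n - 1]


def nascent_mfe(seq: SiteSequence, engine: str = "builtin") -> float:
    """MFE (kcal/mol) of the nascent-RNA stretch -29..-11 — the region just
    outside the polymerase where hairpins can form."""
    if engine != "builtin":
        raise ValueError(f"unknown MFE engine {engine!r}")
    rna = dna_to_rna(seq.window(-29, -11))
    if any(b not in "ACGU" for b in rna):
        raise AmbiguousBaseError("ambiguous base in nascent-RNA window")
    return rna_mfe(rna)


# ---------------------------------------------------------------------------
# Pentamer DNA-shape statistics
# ---------------------------------------------------------------------------

SHAPE_DESCRIPTORS = ("MGW", "Roll", "ProT", "HelT", "EP")
SHAPE_STATS = ("min", "max", "mean", "span", "deriv")


@dataclass
class ShapeTable:
    """Pentamer -> (MGW, Roll, ProT, HelT, EP) lookup; must be complete."""

    values: Dict[str, Tuple[float, float, float, float, float]]

    def __post_init__(self) -> None:
        if len(self.values) != 4 ** 5:
            raise ValueError(
                f"shape table has {len(self.values)} pentamers, expected 1024")

    @classmethod
    def from_tsv(cls, path) -> "ShapeTable":
        values = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("pentamer"):
                    continue
                f = line.split("\t")
                values[f[0]] = tuple(float(x) for x in f[1:6])
        return cls(values)

    def lookup(self, pentamer: str) -> Tuple[float, ...]:
        try:
            return self.values[pentamer]
        except KeyError:
            raise KeyError(f"pentamer {pentamer!r} absent from shape table")


def shape_features(seq: SiteSequence, table: ShapeTable) -> Dict[str, float]:
    """Shape-descriptor statistics over the 16 pentamer centres covering the
    10 bases upstream through 5 bases downstream of the site base.

    Per descriptor: min, max, mean, span (max - min) and the mean absolute
    successive difference ("deriv"), giving 25 features.
    """
    z = seq.offset_zero
    centres = range(z - 10, z + 6)
    if centres[0] - 2 < 0 or centres[-1] + 2 >= len(seq.seq):
        raise WindowError("shape window [-12,+7] outside extracted span")
    profiles = np.array([table.lookup(seq.seq[c - 2:c + 3]) for c in centres])
    out: Dict[str, float] = {}
    for d, name in enumerate(SHAPE_DESCRIPTORS):
        col = profiles[:, d]
        out[f"shape_{name}_min"] = float(col.min())
        out[f"shape_{name}_max"] = float(col.max())
        out[f"shape_{name}_mean"] = float(col.mean())
        out[f"shape_{name}_span"] = float(col.max() - col.min())
        out[f"shape_{name}_deriv"] = float(np.abs(np.diff(col)).mean())
    return out


# ---------------------------------------------------------------------------
# PWM scanning with exact null-score thresholds
# ---------------------------------------------------------------------------

@dataclass
class Pwm:
    """One position weight matrix: rows A, C, G, T; columns sum to 1."""

    name: str
    probs: np.ndarray  # shape (4, width)

    def __post_init__(self) -> None:
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        p = np.clip(self.probs, 1e-9, None)
        return np.log2(p / background[:, None])


@dataclass
class PwmSet:
    pwms: List[Pwm]
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    @classmethod
    def from_jaspar(cls, path) -> "PwmSet":
        """Read a JASPAR pfm file (counts), normalising with +1 pseudocount."""
        from Bio import motifs as bio_motifs

        with open(path) as fh:
            records = bio_motifs.parse(fh, "jaspar")
        pwms = []
        for m in records:
            counts = np.array([m.counts[b] for b in BASES], dtype=float) + 1.0
            pwms.append(Pwm(m.name or m.matrix_id, counts / counts.sum(axis=0)))
        return cls(pwms)


def pwm_score_threshold(pwm: Pwm, background: np.ndarray,
                        p_threshold: float) -> float:
    """Smallest score s with null tail mass P(score >= s) <= p_threshold.

    The null is a random background sequence; the per-window score is a sum
    of independent per-column contributions, so its exact distribution is
    the convolution of the 4-point column distributions (computed exactly
    as a score -> probability map, scores rounded to 1e-9 to merge ties).
    """
    lods = pwm.log_odds(background)
    dist: Dict[float, float] = {0.0: 1.0}
    for col in range(pwm.width):
        nxt: Dict[float, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = round(s + lods[b, col], 9)
                nxt[key] = nxt.get(key, 0.0) + p * background[b]
        dist = nxt
    scores = sorted(dist, reverse=True)
    tail = 0.0
    threshold = math.inf
    for s in scores:
        if tail + dist[s] > p_threshold:
            break
        tail += dist[s]
        threshold = s
    return threshold


_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def _scan_one_strand(seq: str, lods: np.ndarray, threshold: float) -> bool:
    w = lods.shape[1]
    if len(seq) < w:
        return False
    idx = np.array([_BASE_INDEX.get(b, -1) for b in seq])
    cols = np.arange(w)
    # 1e-6 guard: the threshold's score grid is rounded during convolution
    for start in range(len(seq) - w + 1):
        window = idx[start:start + w]
        if (window < 0).any():
            continue
        if lods[window, cols].sum() >= threshold - 1e-6:
            return True
    return False


def pwm_scan_presence(regions: Mapping[str, str], pwms: PwmSet,
                      p_threshold: float = 1e-4,
                      both_strands: bool = True) -> Dict[Tuple[str, str], int]:
    """Binary motif-presence flags per (PWM, region).

    A region is flagged when any window scores at least the exact-null
    threshold at ``p_threshold``. Transcription-factor scans use both
    strands; RBP scans (``both_strands=False``) use only the given strand,
    whose complement is the nascent RNA the protein can bind. Regions
    shorter than the motif get flag 0.
    """
    flags: Dict[Tuple[str, str], int] = {}
    for pwm in pwms.pwms:
        lods = pwm.log_odds(pwms.background)
        threshold = pwm_score_threshold(pwm, pwms.background, p_threshold)
        for region_name, seq in regions.items():
            hit = _scan_one_strand(seq, lods, threshold)
            if not hit and both_strands:
                hit = _scan_one_strand(revcomp(seq), lods, threshold)
            flags[(pwm.name, region_name)] = int(hit)
    return flags


FOOTPRINT_HALFWIDTH = 25
FLANK_WIDTH = 100


def scan_regions(genome, site) -> Dict[str, str]:
    """The three scan regions around a site, on the coding strand.

    'footprint' covers 25 nt either side of the site base; 'upstream' and
    'downstream' are the 100-nt flanks beyond the footprint. Regions are
    clipped at contig edges.
    """
    contig, strand, pos = site.contig, site.strand, site.position
    length = len(genome[contig])

    def fetch(start: int, end: int) -> str:
        start, end = max(0, start), min(length, end)
        if end <= start:
            return ""
        s = str(genome[contig][start:end]).upper()
        return revcomp(s) if strand == "-" else s

    f = FOOTPRINT_HALFWIDTH
    if strand == "+":
        return {
            "footprint": fetch(pos - f, pos + f + 1),
            "upstream": fetch(pos - f - FLANK_WIDTH, pos - f),
            "downstream": fetch(pos + f + 1, pos + f + 1 + FLANK_WIDTH),
        }
    return {
        "footprint": fetch(pos - f, pos + f + 1),
        "upstream": fetch(pos + f + 1, pos + f + 1 + FLANK_WIDTH),
        "downstream": fetch(pos - f - FLANK_WIDTH, pos - f),
    }


# ---------------------------------------------------------------------------
# Methylation and interval-overlap features
# ---------------------------------------------------------------------------

def methylation_feature(meth: Mapping[Tuple[str, int], float], site,
                        radius: int = 100) -> Dict[str, float]:
    """Mean methylation level over covered CpGs within +/- radius of the
    site; uncovered sites get 0 with the coverage flag unset."""
    contig, pos = site.contig, site.position
    levels = [meth[(contig, p)] for p in range(pos - radius, pos + radius + 1)
              if (contig, p) in meth]
    if not levels:
        return {"meth_mean": 0.0, "meth_covered": 0.0}
    return {"meth_mean": float(np.mean(levels)), "meth_covered": 1.0}


def interval_overlap_features(site,
                              interval_sets: Mapping[str, Mapping[str, List[Tuple[int, int]]]],
                              radius: int = 100) -> Dict[str, float]:
    """Per interval set (non-B DNA classes, G4 predictions, ...): 1 iff any
    interval intersects [site - radius, site + radius]."""
    lo, hi = site.position - radius, site.position + radius
    out = {}
    for name, per_contig in interval_sets.items():
        hit = any(s <= hi and e > lo
                  for s, e in per_contig.get(site.contig, ()))
        out[f"nonb_{name}"] = float(hit)
    return out


# ---------------------------------------------------------------------------
# Enrichment logos
# ---------------------------------------------------------------------------

def _logo_labels(halfwidth: int) -> List[int]:
    return list(range(-halfwidth - 1, 0)) + list(range(1, halfwidth + 1))


def enrichment_logo(fg_sites: Sequence, bg_sites: Sequence, genome,
                    halfwidth: int, epsilon: float = 0.01) -> pd.DataFrame:
    """Per-position log2 enrichment of foreground over background base
    frequencies around the site base.

    Rows are bases, columns relative positions -(halfwidth+1)..-1, +1..+halfwidth
    (the site base is -1). Entries are log2((f + eps) / (b + eps)). Sites
    whose window leaves the contig or contains N are skipped.
    """
    if not len(fg_sites) or not len(bg_sites):
        raise ValueError("foreground and background site sets must be non-empty")

    def freq_matrix(sites) -> np.ndarray:
        counts = np.zeros((4, 2 * halfwidth + 1))
        n = 0
        for site in sites:
            try:
                ss = site_sequence(genome, site, halfwidth, halfwidth)
            except WindowError:
                continue
            if any(b not in BASES for b in ss.seq):
                continue
            for i, b in enumerate(ss.seq):
                counts[_BASE_INDEX[b], i] += 1
            n += 1
        if n == 0:
            raise ValueError("no usable sites for logo construction")
        return counts / n

    fg = freq_matrix(fg_sites)
    bg = freq_matrix(bg_sites)
    mat = np.log2((fg + epsilon) / (bg + epsilon))
    return pd.DataFrame(mat, index=list(BASES), columns=_logo_labels(halfwidth))


# ---------------------------------------------------------------------------
# Feature-matrix assembly
# ---------------------------------------------------------------------------

UNIVERSAL_SPAN = (29, 29)  # upstream, downstream bases around the site base


@dataclass
class FeatureResources:
    """Optional resource bundle for the human-specific feature block."""

    thermo: Optional[ThermoParams] = None
    shape_table: Optional[ShapeTable] = None
    tf_pwms: Optional[PwmSet] = None
    rbp_pwms: Optional[PwmSet] = None
    methylation: Optional[Mapping[Tuple[str, int], float]] = None
    interval_sets: Optional[Mapping[str, Mapping[str, List[Tuple[int, int]]]]] = None
    pwm_p_threshold: float = 1e-4


@dataclass
class FeatureMatrix:
    """Labelled per-site feature table feeding the pause classifier."""

    data: pd.DataFrame          # index: site ids; columns: features
    labels: pd.Series           # 1 = pause, 0 = non-pause
    dropped: List[str]
    provenance: Dict[str, object]

    @property
    def n(self) -> int:
        return len(self.data)

    def to_tsv(self, path: str) -> None:
        df = self.data.copy()
        df.insert(0, "label", self.labels)
        df.to_csv(path, sep="\t", index_label="site_id")

    @classmethod
    def from_tsv(cls, path: str) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="site_id")
        labels = df.pop("label")
        return cls(df, labels, [], {"source": str(path)})


def site_id(site, label: int) -> str:
    return f"{site.contig}:{site.strand}:{site.position}:{'pause' if label else 'ctrl'}"


def site_features(site, genome, resources: FeatureResources) -> Dict[str, float]:
    """All features for one site; raises AmbiguousBaseError / WindowError
    when a required window is unusable (caller drops the site)."""
    seq = site_sequence(genome, site, *UNIVERSAL_SPAN)
    thermo = resources.thermo or ThermoParams.default()
    row: Dict[str, float] = {}
    row.update(skew_diff_features(seq))
    row.update(nucleotide_identity_features(seq))
    row.update(hybrid_thermo_features(seq, thermo))
    row["nascent_mfe"] = nascent_mfe(seq)
    if resources.shape_table is not None:
        row.update(shape_features(seq, resources.shape_table))
    if resources.tf_pwms is not None:
        regions = scan_regions(genome, site)
        flags = pwm_scan_presence(regions, resources.tf_pwms,
                                  resources.pwm_p_threshold, both_strands=True)
        for (pwm, region), v in flags.items():
            row[f"tf_{pwm}_{region}"] = float(v)
    if resources.rbp_pwms is not None:
        regions = scan_regions(genome, site)
        flags = pwm_scan_presence({"upstream": regions["upstream"]},
                                  resources.rbp_pwms,
                                  resources.pwm_p_threshold, both_strands=False)
        for (pwm, region), v in flags.items():
            row[f"rbp_{pwm}_{region}"] = float(v)
    if resources.methylation is not None:
        row.update(methylation_feature(resources.methylation, site))
    if resources.interval_sets is not None:
        row.update(interval_overlap_features(site, resources.interval_sets))
    return row


def build_feature_matrix(pause_sites: Sequence, control_sites: Sequence,
                         genome,
                         resources: Optional[FeatureResources] = None
                         ) -> FeatureMatrix:
    """Assemble the labelled feature matrix for paired pause / non-pause sites.

    The species-universal block (6 skew differences + 24 identities +
    4 hybrid-thermodynamic values + 1 nascent-RNA MFE = 35 columns) is
    always built; shape, motif, methylation and interval features are added
    exactly when their resources are supplied. Sites with any unusable
    window are dropped and recorded. Deterministic for fixed inputs.
    """
    resources = resources or FeatureResources()
    rows: Dict[str, Dict[str, float]] = {}
    labels: Dict[str, int] = {}
    dropped: List[str] = []
    for label, sites in ((1, pause_sites), (0, control_sites)):
        for site in sites:
            sid = site_id(site, label)
            try:
                rows[sid] = site_features(site, genome, resources)
            except (AmbiguousBaseError, WindowError, KeyError):
                dropped.append(sid)
                continue
            labels[sid] = label
    if not rows:
        raise ValueError("no sites survived feature construction")
    data = pd.DataFrame.from_dict(rows, orient="index")
    if data.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    provenance = {
        "universal_span": UNIVERSAL_SPAN,
        "mfe_engine": "builtin",
        "optional_blocks": sorted(
            name for name, present in (
                ("shape", resources.shape_table is not None),
                ("tf_pwms", resources.tf_pwms is not None),
                ("rbp_pwms", resources.rbp_pwms is not None),
                ("methylation", resources.methylation is not None),
                ("intervals", resources.interval_sets is not None),
            ) if present),
        "n_dropped": len(dropped),
    }
    return FeatureMatrix(data, pd.Series(labels).loc[data.index], dropped,
                         provenance)
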