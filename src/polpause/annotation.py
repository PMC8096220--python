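"""Genomic classification of pause sites and genome-wide statistics.

Called pauses are assigned to one of four major categories based on gene
annotation — promoter-proximal (within 300 nt downstream of a TSS on the
same strand), gene-body (between +301 and the 3'-most pA site), antisense
(opposite strand, from 1000 nt upstream of the most upstream TSS to the
most downstream pA) or intergenic — with subclasses (exonic/intronic,
divergent/convergent, termination-zone/enhancer/other). Overlaps between
one gene's body and another's antisense region are left undetermined, as
are antisense sites whose divergent/convergent assignment conflicts across
genes.

The module also samples distance-matched non-pausing control sites, marks
active genes (TPM > 1), and computes per-gene pausing statistics
(splice-site proximity, average pausing distance, promoter vs gene-body
intensity comparison, signal densities around sites, premature-termination
flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats as scipy_stats

from .occupancy import MaskSet, TrackSet

CATEGORIES = ("promoter-proximal", "gene-body", "antisense", "intergenic",
              "undetermined")

PROMOTER_WINDOW = 300       # nt downstream of a TSS
ANTISENSE_UPSTREAM = 1000   # nt upstream of the most upstream TSS
TERMINATION_ZONE = 3500     # nt downstream of a pA site


@dataclass
class Gene:
    gene_id: str
    contig: str
    strand: str
    tss_sites: List[int]                  # 0-based positions, one per isoform
    pa_sites: List[int]
    exons: List[Tuple[int, int]]          # 0-based half-open, merged
    active: bool = True

    @property
    def upstream_most_tss(self) -> int:
        """TSS 5'-most in transcription direction."""
        return min(self.tss_sites) if self.strand == "+" else max(self.tss_sites)

    @property
    def downstream_most_pa(self) -> int:
        """pA 3'-most in transcription direction."""
        return max(self.pa_sites) if self.strand == "+" else min(self.pa_sites)

    def span(self) -> Tuple[int, int]:
        """Genomic [min, max] over TSSs, pAs and exons."""
        coords = (self.tss_sites + self.pa_sites
                  + [c for e in self.exons for c in e])
        return min(coords), max(coords)


@dataclass
class GenomeAnnotation:
    genes: Dict[str, Gene]
    contig_lengths: Dict[str, int]
    enhancers: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    def genes_on(self, contig: str) -> List[Gene]:
        return [g for g in self.genes.values() if g.contig == contig]


@dataclass
class PauseClass:
    category: str
    subclass: str = "none"
    gene_id: Optional[str] = None


# ---------------------------------------------------------------------------
# GTF loading
# ---------------------------------------------------------------------------

def load_gtf(path: str, contig_lengths: Mapping[str, int],
             enhancers: Mapping[str, List[Tuple[int, int]]] | None = None
             ) -> GenomeAnnotation:
    """Load genes from GTF (1-based inclusive -> 0-based half-open on load).

    Each transcript contributes one TSS and one pA site; exons are unioned
    per gene.
    """
    import gffutils

    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes: Dict[str, Gene] = {}
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("gene_id", [g.id])[0]
        tss, pa, exons = [], [], []
        for t in db.children(g, featuretype="transcript"):
            start0, end0 = t.start - 1, t.end  # to 0-based half-open
            if g.strand == "+":
                tss.append(start0)
                pa.append(end0 - 1)
            else:
                tss.append(end0 - 1)
                pa.append(start0)
        for e in db.children(g, featuretype="exon"):
            exons.append((e.start - 1, e.end))
        if not tss:  # gene without transcript records
            start0, end0 = g.start - 1, g.end
            tss = [start0 if g.strand == "+" else end0 - 1]
            pa = [end0 - 1 if g.strand == "+" else start0]
        genes[gid] = Gene(gid, g.seqid, g.strand, tss, pa,
                          merge_intervals(exons))
    return GenomeAnnotation(genes, dict(contig_lengths),
                            dict(enhancers) if enhancers else {})


def merge_intervals(ivals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# Category assignment
# ---------------------------------------------------------------------------

def _in_promoter(gene: Gene, pos: int) -> bool:
    """Within [TSS, TSS + 300] downstream (transcription direction) of any TSS."""
    for tss in gene.tss_sites:
        if gene.strand == "+" and tss <= pos <= tss + PROMOTER_WINDOW:
            return True
        if gene.strand == "-" and tss - PROMOTER_WINDOW <= pos <= tss:
            return True
    return False


def _in_gene_body(gene: Gene, pos: int) -> bool:
    """Between +301 (from the most upstream TSS) and the 3'-most pA."""
    tss, pa = gene.upstream_most_tss, gene.downstream_most_pa
    if gene.strand == "+":
        return tss + PROMOTER_WINDOW < pos <= pa
    return pa <= pos < tss - PROMOTER_WINDOW


def _in_antisense(gene: Gene, pos: int) -> bool:
    """Between 1000 nt upstream of the most upstream TSS and the most
    downstream pA (gene coordinates; the site itself is on the other strand)."""
    tss, pa = gene.upstream_most_tss, gene.downstream_most_pa
    if gene.strand == "+":
        return tss - ANTISENSE_UPSTREAM <= pos <= pa
    return pa <= pos <= tss + ANTISENSE_UPSTREAM


def _antisense_subclass(gene: Gene, pos: int) -> str:
    """divergent when upstream of the TSS, convergent when over the gene body."""
    tss = gene.upstream_most_tss
    if gene.strand == "+":
        return "divergent" if pos < tss else "convergent"
    return "divergent" if pos > tss else "convergent"


def _in_termination_zone(gene: Gene, pos: int) -> bool:
    """Within 3.5 kb downstream (transcription direction) of the pA site."""
    pa = gene.downstream_most_pa
    if gene.strand == "+":
        return pa < pos <= pa + TERMINATION_ZONE
    return pa - TERMINATION_ZONE <= pos < pa


def classify_pause(site, annotation: GenomeAnnotation) -> PauseClass:
    """Assign one pause site to its genomic category and subclass.

    Precedence: promoter-proximal first (any TSS of a same-strand gene);
    a joint gene-body/antisense hit across different genes is undetermined;
    then gene-body (exonic/intronic), antisense (divergent/convergent,
    undetermined on conflict), and intergenic (termination-zone, enhancer,
    other-intergenic). Deterministic and independent of gene order.
    """
    contig, strand, pos = site.contig, site.strand, site.position
    if contig not in annotation.contig_lengths:
        raise ValueError(f"unknown contig {contig!r}")
    if not 0 <= pos < annotation.contig_lengths[contig]:
        raise ValueError(f"position {pos} outside contig {contig}")

    promoter_genes, body_genes, antisense_genes = [], [], []
    for gene in annotation.genes_on(contig):
        if gene.strand == strand:
            if _in_promoter(gene, pos):
                promoter_genes.append(gene)
            elif _in_gene_body(gene, pos):
                body_genes.append(gene)
        else:
            if _in_antisense(gene, pos):
                antisense_genes.append(gene)

    if promoter_genes:
        gene = min(promoter_genes, key=lambda g: g.gene_id)
        return PauseClass("promoter-proximal", "none", gene.gene_id)
    if body_genes and antisense_genes:
        return PauseClass("undetermined", "undetermined")
    if body_genes:
        gene = min(body_genes, key=lambda g: g.gene_id)
        exonic = any(s <= pos < e for s, e in gene.exons)
        return PauseClass("gene-body", "exonic" if exonic else "intronic",
                          gene.gene_id)
    if antisense_genes:
        subclasses = {_antisense_subclass(g, pos) for g in antisense_genes}
        gene = min(antisense_genes, key=lambda g: g.gene_id)
        if len(subclasses) > 1:
            return PauseClass("antisense", "undetermined", gene.gene_id)
        return PauseClass("antisense", subclasses.pop(), gene.gene_id)

    # intergenic subclasses
    for gene in sorted(annotation.genes_on(contig), key=lambda g: g.gene_id):
        if _in_termination_zone(gene, pos):
            return PauseClass("intergenic", "termination-zone", gene.gene_id)
    for s, e in annotation.enhancers.get(contig, ()):
        if s <= pos < e:
            return PauseClass("intergenic", "enhancer")
    return PauseClass("intergenic", "other-intergenic")


# ---------------------------------------------------------------------------
# Splice-site proximity
# ---------------------------------------------------------------------------

SPLICE_LABELS = ("first exon-intron", "exon-intron", "intron-exon",
                 "last intron-exon")


def splice_proximity(site, annotation: GenomeAnnotation, radius: int = 40,
                     gene_id: Optional[str] = None) -> List[str]:
    """Splice-junction proximity labels for a gene-body pause.

    Proximal when within ``radius`` nt of a splice junction; a site near
    several boundaries receives every matching label; otherwise
    ``['distal']``. Junction coordinates are the half-open exon boundaries;
    exon ordering (first/last) is strand-aware.
    """
    contig, strand, pos = site.contig, site.strand, site.position
    if gene_id is not None:
        genes = [annotation.genes[gene_id]]
    else:
        genes = [g for g in annotation.genes_on(contig)
                 if g.strand == strand and _in_gene_body(g, pos)]
    labels: List[str] = []
    for gene in genes:
        exons = gene.exons if gene.strand == "+" else gene.exons[::-1]
        n = len(exons)
        if n < 2:
            continue
        for i, (s, e) in enumerate(exons):  # i in transcription order
            donor = e if gene.strand == "+" else s        # exon -> intron
            acceptor = s if gene.strand == "+" else e     # intron -> exon
            if i < n - 1 and abs(pos - donor) <= radius:
                labels.append("first exon-intron" if i == 0 else "exon-intron")
            if i > 0 and abs(pos - acceptor) <= radius:
                labels.append("last intron-exon" if i == n - 1 else "intron-exon")
    return sorted(set(labels)) if labels else ["distal"]


# ---------------------------------------------------------------------------
# Non-pausing control sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ControlSite:
    contig: str
    strand: str
    position: int
    source: Tuple[str, str, int]  # the pause it was sampled for


def sample_nonpausing(classified: Sequence[Tuple[object, PauseClass]],
                      annotation: GenomeAnnotation, seed: int,
                      mask: Optional[MaskSet] = None,
                      max_attempts: int = 50) -> List[ControlSite]:
    """One distance-matched non-pausing control per pause.

    The control position is drawn uniformly from [pos + x, pos + x + 20] or
    [pos - x - 20, pos - x] (side chosen uniformly), with x = 50 for
    promoter-proximal pauses and 300 otherwise, so that local sequence
    context stays comparable. Draws that coincide with any pause position,
    a masked position, or fall off the contig are redrawn (up to
    ``max_attempts``); a pause with no valid control is dropped (logged via
    the return value simply omitting it).
    """
    rng = np.random.default_rng(seed)
    pause_positions: Set[Tuple[str, str, int]] = {
        (s.contig, s.strand, s.position) for s, _ in classified}
    controls: List[ControlSite] = []
    for site, pclass in classified:
        x = 50 if pclass.category == "promoter-proximal" else 300
        clen = annotation.contig_lengths[site.contig]
        for _ in range(max_attempts):
            offset = int(rng.integers(x, x + 21))
            side = 1 if rng.integers(2) else -1
            pos = site.position + side * offset
            if not 0 <= pos < clen:
                continue
            if (site.contig, site.strand, pos) in pause_positions:
                continue
            if mask is not None and mask.is_masked(site.contig, site.strand, pos):
                continue
            controls.append(ControlSite(site.contig, site.strand, pos,
                                        (site.contig, site.strand, site.position)))
            break
    return controls


# ---------------------------------------------------------------------------
# Genome-wide statistics
# ---------------------------------------------------------------------------

def active_genes(expr: Mapping[str, float], cutoff: float = 1.0) -> Set[str]:
    """Genes actively transcribed: steady-state TPM strictly greater than
    ``cutoff`` (default 1)."""
    return {g for g, tpm in expr.items() if tpm > cutoff}


def average_pause_distance(classified: Sequence[Tuple[object, PauseClass]],
                           annotation: GenomeAnnotation) -> Dict[str, float]:
    """Per gene: mean gap between consecutive pause positions within the span
    from the most upstream TSS to the most downstream pA. Genes with fewer
    than two spanned pauses are absent."""
    per_gene: Dict[str, List[int]] = {}
    for site, pclass in classified:
        if pclass.gene_id is None or pclass.category not in (
                "promoter-proximal", "gene-body"):
            continue
        gene = annotation.genes[pclass.gene_id]
        lo = min(gene.upstream_most_tss, gene.downstream_most_pa)
        hi = max(gene.upstream_most_tss, gene.downstream_most_pa)
        if lo <= site.position <= hi:
            per_gene.setdefault(gene.gene_id, []).append(site.position)
    out = {}
    for gid, positions in per_gene.items():
        if len(positions) >= 2:
            ps = sorted(positions)
            out[gid] = float(np.mean(np.diff(ps)))
    return out


def compare_intensities(classified: Sequence[Tuple[object, PauseClass]]
                        ) -> Tuple[Dict[str, Tuple[float, float]], float]:
    """Promoter-proximal vs gene-body pausing intensity across genes.

    Only genes with pauses in both regions are included; per gene the mean
    pause-site count in each region is taken, and a one-sided Welch
    (unequal-variance) t-test asks whether gene-body intensities exceed
    promoter-proximal ones.
    """
    pp: Dict[str, List[float]] = {}
    gb: Dict[str, List[float]] = {}
    for site, pclass in classified:
        if pclass.gene_id is None:
            continue
        if pclass.category == "promoter-proximal":
            pp.setdefault(pclass.gene_id, []).append(float(site.count))
        elif pclass.category == "gene-body":
            gb.setdefault(pclass.gene_id, []).append(float(site.count))
    genes = sorted(set(pp) & set(gb))
    if len(genes) < 2:
        raise ValueError("need >= 2 genes with pauses in both regions")
    means = {g: (float(np.mean(pp[g])), float(np.mean(gb[g]))) for g in genes}
    pp_means = [means[g][0] for g in genes]
    gb_means = [means[g][1] for g in genes]
    p = float(scipy_stats.ttest_ind(gb_means, pp_means, equal_var=False,
                                    alternative="greater").pvalue)
    return means, p


def site_signal_density(tracks: Sequence[TrackSet] | TrackSet, sites,
                        window: Tuple[str, int]) -> np.ndarray:
    """Mean signal per position around each site, averaged over replicates.

    ``window`` is ``("upstream", width)`` — the ``width`` bases 5' of the
    site in transcription direction, site excluded — or
    ``("centered", width)`` — ``width`` bases centred on the site. Windows
    are clipped at contig edges and the density divides by the clipped width.
    """
    mode, width = window
    if mode not in ("upstream", "centered"):
        raise ValueError(f"unknown window mode {mode!r}")
    replicates = [tracks] if isinstance(tracks, TrackSet) else list(tracks)
    out = np.zeros(len(sites))
    for rep in replicates:
        for i, site in enumerate(sites):
            track = rep.get((site.contig, site.strand))
            if track is None:
                continue
            pos = site.position
            if mode == "upstream":
                if site.strand == "+":
                    lo, hi = pos - width, pos
                else:
                    lo, hi = pos + 1, pos + 1 + width
            else:
                lo, hi = pos - width // 2, pos - width // 2 + width
            lo = max(0, lo)
            hi = min(track.contig_length, hi)
            if hi <= lo:
                continue
            total = sum(c for p, c in track.counts.items() if lo <= p < hi)
            out[i] += total / (hi - lo)
    return out / len(replicates)


def premature_termination_calls(site_densities: Sequence[float],
                                pa_densities: Sequence[float]) -> np.ndarray:
    """Flag sites whose nascent 3'-end density exceeds the 25th percentile
    (linear interpolation) of the density at polyadenylation sites."""
    pa = np.asarray(pa_densities, dtype=float)
    if pa.size == 0:
        raise ValueError("need at least one pA-site density")
    threshold = float(np.percentile(pa, 25))
    return np.asarray(site_densities, dtype=float) > threshold
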