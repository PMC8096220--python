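"""Sequence features: skew, identity, hybrid thermodynamics, RNA MFE,
shape statistics, PWM scanning, methylation, logos, matrix assembly.

Independent oracles: term-by-term summation for the nearest-neighbor
thermodynamics, exhaustive secondary-structure enumeration for the MFE
dynamic program, and exhaustive k-mer score enumeration for the PWM
null-score threshold.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from polpause.features import AmbiguousBaseError
from polpause import (
    FeatureResources,
    Pwm,
    PwmSet,
    ThermoParams,
    build_feature_matrix,
    enrichment_logo,
    hybrid_thermo_features,
    interval_overlap_features,
    methylation_feature,
    nascent_mfe,
    nucleotide_identity_features,
    pwm_scan_presence,
    pwm_score_threshold,
    rna_mfe,
    scan_regions,
    site_sequence,
    skew_diff_features,
    shape_features,
)
from polpause.features import (
    MIN_HAIRPIN_LOOP,
    WindowError,
    _can_pair,
    _stack_energy,
    base_skew,
)
from polpause import simulate as sim


class Site:
    def __init__(self, contig, strand, position):
        self.contig, self.strand, self.position = contig, strand, position


# ---------------------------------------------------------------------------
# Site sequences
# ---------------------------------------------------------------------------

class TestSiteSequence:
    genome = {"chr1": "AACCGGTTAACCGGTTAACC"}

    def test_plus_strand_window_and_offset(self):
        ss = site_sequence(self.genome, Site("chr1", "+", 5), 2, 1)
        assert ss.seq == self.genome["chr1"][3:7]
        assert len(ss.seq) == 4 and ss.offset_zero == 2
        assert ss.base(-1) == self.genome["chr1"][5]
        assert ss.base(1) == self.genome["chr1"][6]

    def test_minus_strand_is_reverse_complement(self):
        plus = site_sequence(self.genome, Site("chr1", "+", 10), 3, 3)
        from polpause import revcomp
        minus = site_sequence({"chr1": revcomp(self.genome["chr1"])},
                              Site("chr1", "-", 9), 3, 3)
        assert minus.seq == plus.seq  # strand symmetry of the construction

    def test_window_off_contig_errors(self):
        with pytest.raises(WindowError):
            site_sequence(self.genome, Site("chr1", "+", 1), 5, 1)


# ---------------------------------------------------------------------------
# Skew differences
# ---------------------------------------------------------------------------

class TestSkew:
    def test_direct_formula(self):
        assert base_skew("GGGGGGCC", "G", "C") == pytest.approx(0.5)
        assert base_skew("AAAA", "G", "C") == 0.0  # neither base present

    def test_antisymmetry(self):
        w = "ACGGGTTACG"
        assert base_skew(w, "G", "C") == -base_skew(w, "C", "G")

    def test_identical_windows_give_zero_differences(self, random_genome):
        ss = site_sequence({"chr1": "ACGT" * 30}, Site("chr1", "+", 60), 29, 29)
        # periodic sequence: up/down windows have identical composition
        diffs = skew_diff_features(ss)
        assert all(v == 0.0 for v in diffs.values())
        assert len(diffs) == 6


# ---------------------------------------------------------------------------
# Identity features
# ---------------------------------------------------------------------------

class TestIdentity:
    def test_one_hot_and_motif_positions(self):
        # build a sequence with G at -10, -1 and C (pyrimidine) at -2, +1
        seq = ["A"] * 60
        z = 29
        for r, b in ((-10, "G"), (-2, "C"), (-1, "G"), (1, "C"),
                     (-3, "T"), (-11, "A")):
            seq[z + r + 1 if r < 0 else z + r] = b
        genome = {"chr1": "".join(seq)}
        ss = site_sequence(genome, Site("chr1", "+", z), 29, 29)
        f = nucleotide_identity_features(ss)
        assert len(f) == 24
        assert f["nt_-10_G"] == f["nt_-1_G"] == f["nt_-2_C"] == f["nt_+1_C"] == 1
        for r in (-11, -10, -3, -2, -1, 1):
            assert sum(f[f"nt_{r:+d}_{b}"] for b in "ACGT") == 1

    def test_ambiguous_base_drops_site(self):
        genome = {"chr1": "A" * 29 + "N" + "A" * 30}
        ss = site_sequence(genome, Site("chr1", "+", 29), 29, 29)
        with pytest.raises(AmbiguousBaseError):
            nucleotide_identity_features(ss)


# ---------------------------------------------------------------------------
# Hybrid thermodynamics
# ---------------------------------------------------------------------------

def thermo_oracle(rna, params):
    """Independent term-by-term summation of the published table."""
    dh = params.dh_init + sum(params.dh[rna[i:i + 2]] for i in range(9))
    ds = params.ds_init + sum(params.ds[rna[i:i + 2]] for i in range(9))
    return dh, ds, dh - 310.15 * ds / 1000.0


class TestHybridThermo:
    params = ThermoParams.default()

    def _ss(self, hybrid_dna):
        # hybrid occupies relative -10..-1 = genomic [20, 30) for site 29
        genome = {"chr1": "A" * 20 + hybrid_dna + "A" * 30}
        return site_sequence(genome, Site("chr1", "+", 29), 29, 29)

    def test_homopolymer_additivity(self):
        f = hybrid_thermo_features(self._ss("A" * 10), self.params)
        assert f["hybrid_dH"] == pytest.approx(
            self.params.dh_init + 9 * self.params.dh["AA"])
        assert f["hybrid_dS"] == pytest.approx(
            self.params.ds_init + 9 * self.params.ds["AA"])

    def test_matches_summation_oracle_on_random_hybrids(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            dna = "".join(rng.choice(list("ACGT"), size=10))
            f = hybrid_thermo_features(self._ss(dna), self.params)
            dh, ds, dg = thermo_oracle(dna.replace("T", "U"), self.params)
            assert f["hybrid_dH"] == pytest.approx(dh)
            assert f["hybrid_dS"] == pytest.approx(ds)
            assert f["hybrid_dG37"] == pytest.approx(dg)

    def test_tm_rises_with_gc_content(self):
        tm_at = hybrid_thermo_features(self._ss("ATATATATAT"), self.params)["hybrid_Tm"]
        tm_gc = hybrid_thermo_features(self._ss("GCGCGCGCGC"), self.params)["hybrid_Tm"]
        assert tm_gc > tm_at


# ---------------------------------------------------------------------------
# Nascent-RNA MFE
# ---------------------------------------------------------------------------

def enumerate_structures(rna):
    """All pseudoknot-free pair sets with min hairpin loop; yields energies."""
    n = len(rna)
    pairs = [(i, j) for i in range(n) for j in range(i + MIN_HAIRPIN_LOOP + 1, n)
             if _can_pair(rna[i], rna[j])]

    def compatible(p, chosen):
        i, j = p
        for a, b in chosen:
            if len({i, j, a, b}) < 4:
                return False
            if (a < i < b < j) or (i < a < j < b):
                return False  # crossing
        return True

    def energy(chosen):
        e = 0.0
        s = set(chosen)
        for i, j in chosen:
            if (i + 1, j - 1) in s:
                e += _stack_energy(rna[i], rna[j], rna[i + 1], rna[j - 1])
        return e

    best = 0.0
    stack = [(0, [])]
    while stack:
        idx, chosen = stack.pop()
        best = min(best, energy(chosen))
        for k in range(idx, len(pairs)):
            if compatible(pairs[k], chosen):
                stack.append((k + 1, chosen + [pairs[k]]))
    return best


class TestNascentMfe:
    def test_unstructured_homopolymer_is_zero(self):
        assert rna_mfe("A" * 19) == 0.0

    def test_gc_hairpin_is_strictly_negative(self):
        assert rna_mfe("GGGGGGGGAAACCCCCCCC") < 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_dp_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        rna = "".join(rng.choice(list("ACGU"), size=int(rng.integers(6, 13))))
        assert rna_mfe(rna) == pytest.approx(enumerate_structures(rna))

    def test_site_window_extraction(self):
        # hairpin planted in the -29..-11 window only
        genome = {"chr1": "A" * 1 + "GGGGGGGGAAACCCCCCCC" + "A" * 40}
        ss = site_sequence(genome, Site("chr1", "+", 29), 29, 29)
        assert nascent_mfe(ss) < 0.0


# ---------------------------------------------------------------------------
# Shape features
# ---------------------------------------------------------------------------

class TestShape:
    def test_constant_table_forces_degenerate_stats(self, random_genome):
        table = sim.simulate_shape_table("constant", constant=2.5)
        ss = site_sequence(random_genome, Site("chr1", "+", 1000), 29, 29)
        f = shape_features(ss, table)
        assert len(f) == 25
        for d in ("MGW", "Roll", "ProT", "HelT", "EP"):
            assert f[f"shape_{d}_mean"] == 2.5
            assert f[f"shape_{d}_span"] == 0.0
            assert f[f"shape_{d}_deriv"] == 0.0

    def test_g_count_table_on_poly_g(self):
        table = sim.simulate_shape_table("g_count")
        genome = {"chr1": "G" * 60}
        f = shape_features(site_sequence(genome, Site("chr1", "+", 29), 29, 29),
                           table)
        assert f["shape_MGW_mean"] == 5.0 and f["shape_MGW_span"] == 0.0

    def test_linear_ramp_derivative(self):
        # table value = index of the pentamer's centre base (A=0..T=3):
        # on sequence ACGTACGT... consecutive pentamer centres step by 1 cyclic
        from polpause.features import ShapeTable
        order = {"A": 0.0, "C": 1.0, "G": 2.0, "T": 3.0}
        values = {"".join(p): (order["".join(p)[2]],) * 5
                  for p in itertools.product("ACGT", repeat=5)}
        table = ShapeTable(values)
        genome = {"chr1": "ACGT" * 20}
        f = shape_features(site_sequence(genome, Site("chr1", "+", 29), 29, 29),
                           table)
        # |diffs| over the 15 steps are 1,1,1,3 repeating: 11 ones + 4 threes
        assert f["shape_MGW_deriv"] == pytest.approx(23 / 15)


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

def threshold_oracle(pwm, background, p):
    """Exhaustive enumeration of all 4^w k-mer scores."""
    lods = pwm.log_odds(background)
    scored = []
    for kmer in itertools.product(range(4), repeat=pwm.width):
        s = sum(lods[b, i] for i, b in enumerate(kmer))
        prob = math.prod(background[b] for b in kmer)
        scored.append((s, prob))
    scored.sort(reverse=True)
    tail, threshold = 0.0, math.inf
    for s, prob in scored:
        if tail + prob > p:
            break
        tail += prob
        threshold = s
    return threshold


class TestPwmScan:
    def _pwm(self, consensus="TGACGT", strength=0.91):
        probs = np.full((4, len(consensus)), (1 - strength) / 3)
        for j, b in enumerate(consensus):
            probs["ACGT".index(b), j] = strength
        return Pwm("m", probs / probs.sum(axis=0))

    @pytest.mark.parametrize("width", [4, 6, 8])
    def test_threshold_matches_enumeration(self, width):
        rng = np.random.default_rng(width)
        probs = rng.dirichlet(np.ones(4), size=width).T
        pwm = Pwm("r", probs)
        bg = np.full(4, 0.25)
        for p in (1e-2, 1e-3, 1e-4):
            assert pwm_score_threshold(pwm, bg, p) == pytest.approx(
                threshold_oracle(pwm, bg, p), abs=1e-6)

    def test_planted_consensus_is_flagged(self):
        pwm = self._pwm("TGACGTCA", 0.94)
        seq = "A" * 40 + "TGACGTCA" + "A" * 40
        flags = pwm_scan_presence({"footprint": seq}, PwmSet([pwm]))
        assert flags[("m", "footprint")] == 1

    def test_reverse_strand_hit_found_for_tf_scan(self):
        # non-palindromic consensus so the strands are distinguishable
        from polpause import revcomp
        pwm = self._pwm("TGACGTAC", 0.94)
        seq = "C" * 40 + revcomp("TGACGTAC") + "C" * 40
        assert pwm_scan_presence({"r": seq}, PwmSet([pwm]))[("m", "r")] == 1
        assert pwm_scan_presence({"r": seq}, PwmSet([pwm]),
                                 both_strands=False)[("m", "r")] == 0

    def test_region_shorter_than_motif_flags_zero(self):
        pwm = self._pwm("TGACGTCA")
        assert pwm_scan_presence({"tiny": "ACG"}, PwmSet([pwm]))[("m", "tiny")] == 0

    def test_false_positive_rate_matches_threshold(self):
        # expected hits on random sequence ~ positions x p_threshold
        rng = np.random.default_rng(12)
        pwm = self._pwm("TGACGT", 0.9)
        pset = PwmSet([pwm])
        n, length, p = 3000, 40, 1e-3
        hits = 0
        for _ in range(n):
            seq = "".join(rng.choice(list("ACGT"), size=length))
            hits += pwm_scan_presence({"x": seq}, pset, p_threshold=p,
                                      both_strands=False)[("m", "x")]
        windows = length - pwm.width + 1
        # realized tail at the discrete threshold (from the enumeration oracle)
        thr = pwm_score_threshold(pwm, pset.background, p)
        lods = pwm.log_odds(pset.background)
        tail = sum(
            math.prod(pset.background[b] for b in kmer)
            for kmer in itertools.product(range(4), repeat=pwm.width)
            if sum(lods[b, i] for i, b in enumerate(kmer)) >= thr - 1e-6)
        assert tail <= p  # threshold construction is conservative by design
        expected = n * windows * tail  # union bound, accurate at small tails
        assert abs(hits - expected) < 5 * math.sqrt(max(expected, 1.0)) + 5

    def test_scan_regions_orientation(self, random_genome):
        regions = scan_regions(random_genome, Site("chr1", "+", 10_000))
        assert len(regions["footprint"]) == 51
        assert regions["upstream"] == str(random_genome["chr1"][9875:9975])
        minus = scan_regions(random_genome, Site("chr1", "-", 10_000))
        from polpause import revcomp
        assert minus["upstream"] == revcomp(
            str(random_genome["chr1"][10_026:10_126]))


# ---------------------------------------------------------------------------
# Methylation and interval overlap
# ---------------------------------------------------------------------------

class TestMethAndIntervals:
    def test_methylation_mean_and_coverage_flag(self):
        meth = {("chr1", 995): 1.0, ("chr1", 1005): 0.0}
        f = methylation_feature(meth, Site("chr1", "+", 1000))
        assert f == {"meth_mean": 0.5, "meth_covered": 1.0}
        f = methylation_feature({}, Site("chr1", "+", 1000))
        assert f == {"meth_mean": 0.0, "meth_covered": 0.0}

    def test_interval_overlap_edge_behaviour(self):
        sets = {"z": {"chr1": [(1101, 1150)]}}
        # radius 100 around 1000 covers [900,1100]; interval starts at 1101
        assert interval_overlap_features(Site("chr1", "+", 1000), sets)["nonb_z"] == 0.0
        sets = {"z": {"chr1": [(1100, 1150)]}}
        assert interval_overlap_features(Site("chr1", "+", 1000), sets)["nonb_z"] == 1.0
        assert interval_overlap_features(
            Site("chr1", "+", 1000), {"z": {"chr1": []}})["nonb_z"] == 0.0


# ---------------------------------------------------------------------------
# Enrichment logos
# ---------------------------------------------------------------------------

class TestLogo:
    def test_fg_equals_bg_gives_near_zero(self, random_genome):
        rng = np.random.default_rng(4)
        sites = [Site("chr1", "+", int(p))
                 for p in rng.integers(100, 40_000, size=400)]
        mat = enrichment_logo(sites, sites, random_genome, halfwidth=10)
        assert np.abs(mat.to_numpy()).max() == 0.0

    def test_fixed_base_shows_large_positive_entry(self, random_genome):
        rng = np.random.default_rng(5)
        fg = [Site("chr1", "+", int(p))
              for p in rng.integers(100, 40_000, size=2000)
              if random_genome["chr1"][int(p)] == "G"]
        bg = [Site("chr1", "+", int(p))
              for p in rng.integers(100, 40_000, size=500)]
        mat = enrichment_logo(fg, bg, random_genome, halfwidth=5)
        assert mat.loc["G", -1] > 1.0
        assert mat.loc["G", -1] == mat.to_numpy().max()

    def test_empty_set_errors(self, random_genome):
        with pytest.raises(ValueError):
            enrichment_logo([], [Site("chr1", "+", 500)], random_genome, 5)


# ---------------------------------------------------------------------------
# Feature-matrix assembly
# ---------------------------------------------------------------------------

class TestFeatureMatrix:
    def test_universal_set_has_35_columns_and_balanced_labels(self,
                                                              random_genome):
        rng = np.random.default_rng(6)
        pauses = [Site("chr1", "+", int(p))
                  for p in rng.integers(100, 40_000, size=30)]
        controls = [Site("chr1", "-", int(p))
                    for p in rng.integers(100, 40_000, size=30)]
        fm = build_feature_matrix(pauses, controls, random_genome)
        assert fm.data.shape == (60, 35)
        assert fm.labels.sum() == 30
        again = build_feature_matrix(pauses, controls, random_genome)
        pd.testing.assert_frame_equal(fm.data, again.data)

    def test_strand_symmetry_of_feature_vectors(self, random_genome):
        from polpause import revcomp
        seq = str(random_genome["chr1"])
        flipped = {"chr1": revcomp(seq)}
        n = len(seq)
        plus = build_feature_matrix([Site("chr1", "+", 5000)], [],
                                    random_genome)
        minus = build_feature_matrix([Site("chr1", "-", n - 1 - 5000)], [],
                                     flipped)
        assert np.allclose(plus.data.to_numpy(), minus.data.to_numpy())

    def test_edge_sites_dropped_and_recorded(self, random_genome):
        fm = build_feature_matrix([Site("chr1", "+", 5), Site("chr1", "+", 5000)],
                                  [], random_genome)
        assert fm.data.shape[0] == 1 and len(fm.dropped) == 1

    def test_optional_blocks_add_columns(self, random_genome):
        res = FeatureResources(
            shape_table=sim.simulate_shape_table("random", seed=1),
            methylation=sim.simulate_methylation({"chr1": 50_000}, seed=1),
        )
        fm = build_feature_matrix([Site("chr1", "+", 5000)],
                                  [Site("chr1", "+", 9000)],
                                  random_genome, res)
        assert fm.data.shape[1] == 35 + 25 + 2
        assert sorted(fm.provenance["optional_blocks"]) == ["methylation",
                                                            "shape"]
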