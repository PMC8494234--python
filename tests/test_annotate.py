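"""Interpretation statistics: specificity, gene linkage, enrichment, entropy."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from scitopic.annotate import (
    EnrichmentResult,
    GeneAnnotation,
    assign_stages_by_zscore,
    chip_overlap_enrichment,
    filter_hot_sites,
    marker_gene_cells,
    mean_peak_entropy,
    nearest_downstream_gene,
    overlap_stats,
    peak_diversity_score,
    shuffle_peaks,
    signal_enrichment_over_peaks,
    stage_enrichment,
    tissue_enrichment,
    tissue_entropy,
    top_topic_peaks,
    topic_specificity,
)
from scitopic.matrix import CellsByPeaksMatrix
from scitopic.peaks import PeakSet, SignalTrack, merge_peak_sets
from scitopic.preprocess import GenomeTable
from scitopic.synthetic import plant_peaks, simulate_chip, simulate_expression


def _matrix(dense, peak_names=None):
    dense = np.asarray(dense)
    n, p = dense.shape
    return CellsByPeaksMatrix(
        sp.csr_matrix(np.asarray(dense, dtype=np.int8)),
        pd.Index([f"c{i}" for i in range(n)]),
        pd.Index(peak_names or [f"chr1:{j * 100}-{j * 100 + 50}" for j in range(p)]),
    )


class TestTopicSpecificity:
    def test_exclusive_peak_scores_one(self):
        m = _matrix([[1], [1], [0]])
        labels = np.array([3, 3, -1])
        assert topic_specificity(m, labels, 3).iloc[0] == 1.0

    def test_half_in_cluster(self):
        m = _matrix([[1], [1]])
        assert topic_specificity(m, np.array([3, 5]), 3).iloc[0] == 0.5

    def test_unassigned_carriers_score_zero(self):
        m = _matrix([[1], [1]])
        assert topic_specificity(m, np.array([-1, -1]), 3).iloc[0] == 0.0

    def test_zero_carrier_peak_is_nan_with_warning(self):
        m = _matrix([[1, 0], [1, 0]])
        with pytest.warns(UserWarning, match="no carrying cells"):
            s = topic_specificity(m, np.array([3, 3]), 3)
        assert np.isnan(s.iloc[1])


class TestTopTopicPeaks:
    def test_all_above_floor_returned_when_more_than_n(self):
        s = pd.Series(np.linspace(0.51, 0.99, 300),
                      index=[f"chr1:{i}-{i+1}" for i in range(300)])
        assert len(top_topic_peaks(s, n=250, floor=0.5)) == 300

    def test_top_n_when_few_above_floor(self):
        vals = np.concatenate([np.full(100, 0.8), np.full(900, 0.1)])
        s = pd.Series(vals, index=[f"chr1:{i}-{i+1}" for i in range(1000)])
        out = top_topic_peaks(s, n=250, floor=0.5)
        assert len(out) == 250
        assert set(s.loc[out][:100]) == {0.8}

    def test_fewer_peaks_than_n_returns_all(self):
        s = pd.Series([0.3, 0.2], index=["chr1:0-1", "chr1:5-6"])
        assert len(top_topic_peaks(s, n=250)) == 2


class TestNearestDownstreamGene:
    def test_plus_strand_within_limit(self):
        genes = [GeneAnnotation("g", "chr1", "+", ((2000, 2100),), (2000, 2100))]
        assert nearest_downstream_gene(("chr1", 900, 1100), genes) == "g"

    def test_plus_strand_beyond_limit(self):
        genes = [GeneAnnotation("g", "chr1", "+", ((2400, 2500),), (2400, 2500))]
        assert nearest_downstream_gene(("chr1", 900, 1100), genes) is None

    def test_minus_strand_gene_downstream_is_lower_coordinate(self):
        genes = [GeneAnnotation("g", "chr1", "-", ((600, 800),), (600, 800))]
        assert nearest_downstream_gene(("chr1", 900, 1100), genes) == "g"

    def test_overlap_requires_flag(self):
        genes = [GeneAnnotation("g", "chr1", "+", ((1000, 1200),), (1000, 1200))]
        assert nearest_downstream_gene(("chr1", 900, 1100), genes) is None
        assert nearest_downstream_gene(("chr1", 900, 1100), genes,
                                       allow_overlap=True) == "g"

    def test_brute_force_over_stranded_distances(self):
        rng = np.random.default_rng(0)
        genes = []
        for i in range(30):
            s = int(rng.integers(0, 50_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneAnnotation(f"g{i}", "chr1", strand,
                                        ((s, s + 200),), (s, s + 200)))
        for _ in range(40):
            ps = int(rng.integers(0, 50_000))
            peak = ("chr1", ps, ps + 150)
            best = None
            for g in genes:
                es, ee = g.exons[0]
                if es < peak[2] and ee > peak[1]:
                    continue
                if g.strand == "+" and es >= peak[2]:
                    gap = es - peak[2]
                elif g.strand == "-" and ee <= peak[1]:
                    gap = peak[1] - ee
                else:
                    continue
                if gap <= 1200 and (best is None or (gap, g.gene_id) < best):
                    best = (gap, g.gene_id)
            got = nearest_downstream_gene(peak, genes)
            assert got == (best[1] if best else None)


class TestOverlapStats:
    GENOME = GenomeTable([("chr1", 1000)])

    def test_toy_table_and_hypergeometric_oracle(self):
        a = PeakSet.from_intervals([("chr1", 0, 100)])
        b = PeakSet.from_intervals([("chr1", 50, 150)])
        st_ = overlap_stats(a, b, self.GENOME)
        assert st_.bp_table == (50, 50, 50, 850)
        assert st_.a_in_b == 1 and st_.b_in_a == 1
        p_exact = hypergeom.sf(49, 1000, 100, 100)
        assert abs(st_.fisher_p - p_exact) < 1e-12

    def test_identical_sets(self):
        a = PeakSet.from_intervals([("chr1", 100, 300)])
        st_ = overlap_stats(a, a, self.GENOME)
        assert st_.a_fraction_overlapping == 1.0
        assert st_.fisher_p < 1e-100

    def test_disjoint_sets(self):
        a = PeakSet.from_intervals([("chr1", 0, 100)])
        b = PeakSet.from_intervals([("chr1", 500, 600)])
        st_ = overlap_stats(a, b, self.GENOME)
        assert st_.a_in_b == 0 and st_.bp_table[0] == 0

    def test_interval_exceeding_chromosome_errors(self):
        a = PeakSet.from_intervals([("chr1", 900, 1100)])
        with pytest.raises(ValueError):
            overlap_stats(a, a, self.GENOME)


@pytest.fixture(scope="module")
def table():
    return simulate_expression(seed=1)[0]


class TestTissueEnrichment:
    def test_null_self_sampling_ci_covers_zero(self, table):
        rng = np.random.default_rng(2)
        genes = rng.choice(table.index.to_numpy(), 250, replace=False)
        res = tissue_enrichment(genes, table, seed=3)
        assert ((res.ci_low <= 0) & (res.ci_high >= 0)).mean() >= 0.9

    def test_planted_markers_enriched_in_their_tissue(self, table):
        _, truth = simulate_expression(seed=1)
        res = tissue_enrichment(truth.marker_genes["tissue05"], table, seed=4)
        i = res.categories.index("tissue05")
        assert res.log2_ratio[i] > 0 and res.ci_low[i] > 0

    def test_empty_gene_set_rejected(self, table):
        with pytest.raises(ValueError):
            tissue_enrichment([], table)

    def test_doubling_draws_shrinks_ci(self, table):
        _, truth = simulate_expression(seed=1)
        genes = truth.marker_genes["tissue01"]
        w = {}
        for n in (50, 200):
            res = tissue_enrichment(genes, table, n_random=n, seed=5)
            w[n] = np.mean(res.ci_high - res.ci_low)
        assert w[200] <= w[50] * 1.15  # monotone in expectation, allow noise


CHIP_GENOME = GenomeTable([("chrT", 200_000)])


@pytest.fixture(scope="module")
def planted():
    return plant_peaks(CHIP_GENOME, 3, 15, seed=4)


class TestChipEnrichment:
    GENOME = CHIP_GENOME

    def test_hot_filter_boundary(self):
        df = pd.DataFrame({"chrom": "c", "start": [0, 10], "end": [5, 15],
                           "occupancy": [40, 41]})
        out = filter_hot_sites(df)
        assert out["occupancy"].tolist() == [40]

    def test_hot_fraction_one_empties_set(self, planted):
        chip = simulate_chip(planted, self.GENOME, hot_fraction=1.0, seed=5)
        assert len(filter_hot_sites(chip)) == 0

    def test_planted_overlaps_enrich_matching_topic(self, planted):
        chip = simulate_chip(planted, self.GENOME, fraction_covered=1.0,
                             decoy_count=0, hot_fraction=0.0, seed=6)
        tf = PeakSet.from_intervals(
            [(r.chrom, r.start, r.end) for r in
             chip[chip.tf == "TF_type0"].itertuples()]
        ).merge()
        res = chip_overlap_enrichment(
            {t: planted[t] for t in range(3)}, tf,
            {t: len(planted[t]) for t in range(3)}, seed=7,
        )
        assert res.log2_ratio[res.categories.index(0)] > 1.0
        assert res.observed[res.categories.index(1)] == 0  # pseudo-counted
        assert res.flags["zero_observed_topics"]

    def test_null_sampled_observed_covers_zero(self, planted):
        # draw the "observed" from the null itself: expect CI to straddle 0
        rng = np.random.default_rng(8)
        counts = {t: len(planted[t]) for t in range(3)}
        universe = merge_peak_sets(list(planted.values()))
        take = rng.choice(len(universe), 20, replace=False)
        tf = PeakSet(universe.df.iloc[np.sort(take)])
        res = chip_overlap_enrichment({t: planted[t] for t in range(3)}, tf,
                                      counts, seed=9)
        assert ((res.ci_low <= 0) & (res.ci_high >= 0)).mean() >= 0.66

    def test_empty_tf_set_rejected(self, planted):
        with pytest.raises(ValueError):
            chip_overlap_enrichment({0: planted[0]},
                                    PeakSet(pd.DataFrame(columns=["chrom", "start", "end"])),
                                    {0: 1})


class TestStageEnrichment:
    def test_zscore_assignment_threshold(self):
        # a one-hot row over 4 stages has max z = 1.73 >= 1.5 (population
        # std); a flat row has z = 0 everywhere and lands nowhere
        sig = pd.DataFrame(
            [[10.0, 1.0, 1.0, 1.0], [5.0, 5.0, 5.0, 5.0]],
            index=["p1", "p2"], columns=["L1", "L2", "L3", "L4"],
        )
        out = assign_stages_by_zscore(sig, z_threshold=1.5)
        assert out == {"L1": ["p1"], "L2": [], "L3": [], "L4": []}

    def test_planted_stage_enrichment(self):
        genome = GenomeTable([("chrT", 200_000)])
        planted = plant_peaks(genome, 3, 15, seed=1)
        stage_sets = {"L2": planted[0], "embryo": planted[1]}
        universe = merge_peak_sets(list(planted.values()))
        res = stage_enrichment(planted[0], stage_sets, universe, seed=2)
        i = res.categories.index("L2")
        assert res.log2_ratio[i] > 0.5 and res.ci_low[i] > 0


class TestSignalEnrichment:
    GENOME = GenomeTable([("c", 50_000)])

    def test_constant_signal_ratios_zero(self):
        t = SignalTrack(self.GENOME)
        t.arrays["c"][:] = 2.0
        peaks = PeakSet.from_intervals([("c", 100, 400), ("c", 10_000, 10_200)])
        true, shuf = signal_enrichment_over_peaks(peaks, t, genome=self.GENOME, seed=1)
        np.testing.assert_allclose(true, 0.0)
        np.testing.assert_allclose(shuf, 0.0)

    def test_doubled_signal_inside_peaks(self):
        t = SignalTrack(self.GENOME)
        t.arrays["c"][:] = 1.0
        peaks = PeakSet.from_intervals([("c", i * 5000, i * 5000 + 200)
                                        for i in range(1, 5)])
        for _, r in peaks.df.iterrows():
            t.arrays["c"][r["start"]: r["end"]] = 2.0
        true, shuf = signal_enrichment_over_peaks(peaks, t, genome=self.GENOME, seed=2)
        assert np.all(true > 0.9)
        assert np.mean(np.abs(shuf)) < 0.2

    def test_shuffle_preserves_counts_and_widths(self):
        peaks = PeakSet.from_intervals([("c", 0, 300), ("c", 400, 450)])
        shuf = shuffle_peaks(peaks, self.GENOME, seed=3)
        assert sorted(shuf.df["end"] - shuf.df["start"]) == [50, 300]
        d = shuf.df.sort_values("start")
        assert (d["start"].iloc[1:].to_numpy() >= d["end"].iloc[:-1].to_numpy()).all()


class TestEntropyAndDiversity:
    def test_point_mass_zero(self):
        assert tissue_entropy([0, 1, 0]) == 0.0

    def test_uniform_27_tissues(self):
        assert tissue_entropy(np.ones(27)) == pytest.approx(np.log2(27))

    def test_two_equal_categories_one_bit(self):
        assert tissue_entropy([0.5, 0.5]) == 1.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            tissue_entropy([0.0, 0.0])

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=27))
    def test_permutation_invariant_and_uniform_maximal(self, vals):
        v = np.array(vals)
        assert tissue_entropy(v) == pytest.approx(
            tissue_entropy(v[::-1].copy()), abs=1e-9
        )
        assert tissue_entropy(v) <= np.log2(v.size) + 1e-9

    GENE = GeneAnnotation("gX", "chr1", "+", ((5000, 5200),), (5000, 5400))
    SETS = {
        "neuron": PeakSet.from_intervals([("chr1", 4000, 4300)]),
        "intestine": PeakSet.from_intervals([("chr1", 4500, 4800)]),
        "pharynx": PeakSet.from_intervals([("chr1", 4700, 4950)]),
    }

    def test_worked_diversity_example_scores_two(self):
        assert peak_diversity_score("gX", self.SETS, [self.GENE]) == 2

    def test_single_tissue_single_peak_scores_one(self):
        sets = {"neuron": self.SETS["neuron"]}
        assert peak_diversity_score("gX", sets, [self.GENE]) == 1

    def test_identical_signatures_deduplicate(self):
        sets = {"neuron": PeakSet.from_intervals(
            [("chr1", 4000, 4300), ("chr1", 4500, 4800)]
        )}
        assert peak_diversity_score("gX", sets, [self.GENE]) == 1
        assert peak_diversity_score("gX", sets, [self.GENE],
                                    dedup_signatures=False) == 2

    def test_mean_peak_entropy(self):
        # one peak in a single tissue (entropy 0), one in two tissues (entropy 1)
        peaks = PeakSet.from_intervals([("chr1", 4000, 4300), ("chr1", 4700, 4800)])
        val = mean_peak_entropy("gX", peaks, self.SETS, [self.GENE])
        assert val == pytest.approx(0.5)

    def test_no_linked_peaks_is_undefined(self):
        peaks = PeakSet.from_intervals([("chr1", 40_000, 40_100)])
        with pytest.raises(ValueError):
            mean_peak_entropy("gX", peaks, self.SETS, [self.GENE])


class TestMarkerGeneCells:
    def test_window_and_strand_logic(self):
        genes = [
            GeneAnnotation("gp", "chr1", "+", ((5000, 5100),), (5000, 5200)),
            GeneAnnotation("gm", "chr1", "-", ((8000, 8100),), (8000, 8200)),
        ]
        peaks = ["chr1:5050-5080",    # inside gp body
                 "chr1:3600-3700",    # 1300 bp upstream of gp -> excluded
                 "chr1:9300-9350",    # 1100 bp beyond gm's high end (- strand upstream)
                 "chr1:20000-20050"]
        dense = np.array([
            [1, 0, 0, 0],
            [0, 1, 0, 0],
            [0, 0, 1, 0],
            [0, 0, 0, 1],
        ])
        m = _matrix(dense, peaks)
        assert marker_gene_cells("gp", m, genes) == {"c0"}
        assert marker_gene_cells("gm", m, genes) == {"c2"}
        with pytest.raises(KeyError):
            marker_gene_cells("nope", m, genes)


def test_enrichment_result_frame_shape():
    res = EnrichmentResult(
        categories=["a", "b"], observed=np.ones(2), null_mean=np.ones(2),
        log2_ratio=np.zeros(2), ci_low=-np.ones(2), ci_high=np.ones(2), n_random=10,
    )
    df = res.to_frame()
    assert list(df.columns) == ["observed", "null_mean", "log2_ratio", "ci_low", "ci_high"]
    assert (df["ci_low"] <= df["log2_ratio"]).all()
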