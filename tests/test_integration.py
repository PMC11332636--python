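import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from methlink.genome_features import FeatureGeometry, FeatureInterval
from methlink.integration import (
    Annotation,
    DmrGeneLink,
    assign_primary_feature,
    correlate,
    dmr_mean_methylation,
    feature_density,
    intersect_dmrs_features,
    summarize_links,
)

from conftest import make_matrix


def dmr_frame(rows):
    return pd.DataFrame(rows, columns=["dmr_id", "contig", "start", "end"])


def feature(gene, cls, contig, start, end, strand="+"):
    return FeatureInterval(gene, cls, contig, start, end, strand)


class TestIntersect:
    def test_dmr_spanning_feature_boundary_gets_both(self):
        dmrs = dmr_frame([("d1", "c", 950, 1100)])
        feats = [
            feature("gA", "P1", "c", 0, 1000),
            feature("gA", "GS", "c", 1000, 2500),
        ]
        ann = intersect_dmrs_features(dmrs, feats)
        assert {(a.gene_id, a.feature_class) for a in ann} == {("gA", "P1"), ("gA", "GS")}

    def test_overlapping_genes_give_cross_gene_annotations(self):
        dmrs = dmr_frame([("d1", "c", 500, 600)])
        feats = [
            feature("gA", "P1", "c", 400, 1400),
            feature("gB", "GB", "c", 100, 5000),
        ]
        ann = intersect_dmrs_features(dmrs, feats)
        assert {(a.gene_id, a.feature_class) for a in ann} == {("gA", "P1"), ("gB", "GB")}

    def test_touching_intervals_do_not_overlap(self):
        dmrs = dmr_frame([("d1", "c", 100, 200)])
        feats = [feature("g", "P1", "c", 200, 300), feature("g", "GS", "c", 0, 100)]
        assert intersect_dmrs_features(dmrs, feats) == []

    def test_different_contigs_never_overlap(self):
        dmrs = dmr_frame([("d1", "c1", 0, 1000)])
        feats = [feature("g", "GB", "c2", 0, 1000)]
        assert intersect_dmrs_features(dmrs, feats) == []

    @given(st.data())
    def test_sweep_matches_quadratic_oracle(self, data):
        """The event sweep reproduces an all-pairs brute-force overlap check
        on random instances."""
        n_d = data.draw(st.integers(0, 40))
        n_f = data.draw(st.integers(0, 60))
        def iv(draw):
            s = draw(st.integers(0, 500))
            e = s + draw(st.integers(1, 120))
            c = draw(st.sampled_from(["c1", "c2"]))
            return c, s, e
        dmrs = dmr_frame(
            [(f"d{i}", *iv(data.draw)) for i in range(n_d)]
        )
        feats = [
            feature(
                f"g{i % 7}",
                data.draw(st.sampled_from(["P1", "GS", "P6", "GB", "TTR"])),
                *iv(data.draw),
            )
            for i in range(n_f)
        ]
        got = {(a.dmr_id, a.gene_id, a.feature_class) for a in intersect_dmrs_features(dmrs, feats)}
        brute = set()
        for row in dmrs.itertuples(index=False):
            for f in feats:
                if row.contig == f.contig and row.start < f.end and f.start < row.end:
                    brute.add((row.dmr_id, f.gene_id, f.feature_class))
        assert got == brute


class TestAssignPrimaryFeature:
    def test_hierarchy_within_gene(self):
        ann = [Annotation("d1", "gA", "GS"), Annotation("d1", "gA", "GB")]
        assert assign_primary_feature(ann, ["d1"]) == {"d1": "GS"}

    def test_hierarchy_across_genes(self):
        ann = [Annotation("d1", "gA", "GB"), Annotation("d1", "gB", "P1")]
        assert assign_primary_feature(ann, ["d1"]) == {"d1": "P1"}

    def test_no_annotation_is_intergenic(self):
        assert assign_primary_feature([], ["d1"]) == {"d1": "Intergenic"}

    def test_partition_property(self, sim):
        """Every DMR gets exactly one class, and N_A >= N_DMRs contributions."""
        rng = np.random.default_rng(0)
        dmr_ids = [f"d{i}" for i in range(30)]
        classes = ["P1", "GS", "P6", "GB", "TTR"]
        ann = [
            Annotation(rng.choice(dmr_ids), f"g{rng.integers(5)}", rng.choice(classes))
            for _ in range(60)
        ]
        ann = list({(a.dmr_id, a.gene_id, a.feature_class) for a in ann})
        ann = [Annotation(*t) for t in ann]
        assigned = assign_primary_feature(ann, dmr_ids)
        assert set(assigned) == set(dmr_ids)
        assert len(ann) >= len({d for d in assigned if assigned[d] != "Intergenic"})


class TestFeatureDensity:
    def test_printed_table_arithmetic(self):
        """Density = N_DMRs / canonical span for the promoter, gene-start and
        terminal features at the published spans."""
        density = feature_density(
            {"P1": 109, "GS": 74, "TTR": 33, "P6": 140, "Intergenic": 278},
            FeatureGeometry(),
        )
        assert round(density["P1"], 3) == 0.109
        assert round(density["GS"], 3) == 0.049
        assert round(density["TTR"], 3) == 0.033
        assert round(density["P6"], 3) == 0.028  # 140 / (6000 - 1000)
        assert density["Intergenic"] is None

    def test_gene_body_requires_mean_length(self):
        with pytest.raises(ValueError):
            feature_density({"GB": 423}, FeatureGeometry())
        d = feature_density({"GB": 423}, FeatureGeometry(), mean_gene_body_length=30_000)
        assert round(d["GB"], 3) == 0.014

    def test_inclusive_p6_changes_denominator(self):
        d = feature_density({"P6": 140}, FeatureGeometry(p6_excludes_p1=False))
        assert d["P6"] == pytest.approx(140 / 6000)


class TestDmrMeanMethylation:
    def _matrix(self):
        return make_matrix(
            [("c", 10), ("c", 20), ("c", 500)],
            [[4, 3, 0], [0, 1, 0], [2, 0, 0]],
            [[4, 4, 0], [4, 4, 0], [2, 4, 1]],
        )

    def test_count_weighted_mean(self):
        row = pd.Series({"contig": "c", "start": 0, "end": 30})
        lv = dmr_mean_methylation(self._matrix(), row)
        assert lv[0] == pytest.approx(0.5)  # (4+0)/8
        assert lv[1] == pytest.approx(0.5)  # (3+1)/8

    def test_zero_coverage_sample_is_nan(self):
        row = pd.Series({"contig": "c", "start": 0, "end": 30})
        lv = dmr_mean_methylation(self._matrix(), row)
        assert np.isnan(lv[2])

    def test_region_without_cpgs_raises(self):
        row = pd.Series({"contig": "c", "start": 100, "end": 200})
        with pytest.raises(ValueError):
            dmr_mean_methylation(self._matrix(), row)


class TestCorrelate:
    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        r, p, n = correlate(x, -x)
        assert r == pytest.approx(-1.0)
        assert p == 0.0 and n == 5

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate(np.ones(5), np.arange(5.0))

    def test_nan_pairs_dropped(self):
        x = np.array([0.1, 0.4, np.nan, 0.8, 0.2])
        y = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        _, _, n = correlate(x, y)
        assert n == 3

    def test_significance_boundary_at_n17(self):
        """|r| needed for p < 0.05 at n = 17 equals the t-quantile value
        r* = t* / sqrt(n - 2 + t*^2); r just above flips the flag."""
        n = 17
        t_star = stats.t.ppf(0.975, n - 2)
        r_star = t_star / np.sqrt(n - 2 + t_star**2)

        def pearson_p(r_target):
            rng = np.random.default_rng(0)
            x = rng.normal(size=n)
            x = (x - x.mean()) / x.std()
            e = rng.normal(size=n)
            e -= e.mean()
            e -= x * (x @ e) / (x @ x)  # orthogonalize
            e /= np.linalg.norm(e)
            y = r_target * x / np.linalg.norm(x) + np.sqrt(1 - r_target**2) * e
            r, p, _ = correlate(x, y)
            assert r == pytest.approx(r_target, abs=1e-9)
            return p

        assert pearson_p(r_star * 1.02) < 0.05
        assert pearson_p(r_star * 0.98) > 0.05

    def test_p_matches_exhaustive_permutation_for_small_n(self):
        """The t-based p is close to the exact permutation p at n = 6."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=6)
        y = 0.9 * x + 0.3 * rng.normal(size=6)
        r_obs, p_t, _ = correlate(x, y)
        perm_rs = [
            abs(np.corrcoef(x, np.array(perm))[0, 1])
            for perm in itertools.permutations(y)
        ]
        p_perm = np.mean([pr >= abs(r_obs) - 1e-12 for pr in perm_rs])
        assert abs(p_t - p_perm) < 0.05


def links_fixture():
    """Synthetic links/annotations whose per-class counts mirror a published
    correlation summary: per class (N_A, N_DMRs, n_sig, n_neg)."""
    spec = {
        "P6": (93, 71, 2, 0),
        "P1": (38, 38, 7, 6),
        "GS": (45, 27, 4, 1),
        "GB": (249, 225, 9, 8),
        "TTR": (53, 35, 0, 0),
    }
    links, annotations = [], []
    gene_counter = itertools.count()
    for cls, (n_a, n_dmrs, n_sig, n_neg) in spec.items():
        for i in range(n_dmrs):
            dmr_id = f"{cls}_d{i}"
            gene_id = f"g{next(gene_counter)}"
            sig = i < n_sig
            neg = i < n_neg
            r = (-0.6 if neg else 0.6) if sig else 0.1
            p = 0.01 if sig else 0.5
            links.append(DmrGeneLink(dmr_id, gene_id, cls, r, p, 17))
            annotations.append(Annotation(dmr_id, gene_id, cls))
        # extra annotations beyond one per DMR: same DMRs touching further genes
        for j in range(n_a - n_dmrs):
            dmr_id = f"{cls}_d{j % n_dmrs}"
            gene_id = f"g{next(gene_counter)}"
            links.append(DmrGeneLink(dmr_id, gene_id, cls, 0.05, 0.8, 17))
            annotations.append(Annotation(dmr_id, gene_id, cls))
    return links, annotations


class TestSummarizeLinks:
    def test_published_shape_proportions(self):
        links, annotations = links_fixture()
        summary = summarize_links(links, annotations).set_index("feature_class")
        assert summary.loc["P6", "proportion_significant"] == 2.8
        assert summary.loc["P1", "proportion_significant"] == 18.4
        assert summary.loc["GS", "proportion_significant"] == 14.8
        assert summary.loc["GB", "proportion_significant"] == 4.0
        assert summary.loc["TTR", "proportion_significant"] == 0.0
        assert summary.loc["Total", "n_annotations"] == 478
        assert summary.loc["Total", "n_dmrs"] == 396
        assert summary.loc["Total", "n_significant"] == 22
        assert summary.loc["Total", "n_negative"] == 15

    def test_multi_gene_dmr_counts_once_in_n_dmrs(self):
        links = [
            DmrGeneLink("d1", "gA", "GB", 0.2, 0.5, 10),
            DmrGeneLink("d1", "gB", "GB", 0.3, 0.4, 10),
        ]
        ann = [Annotation("d1", "gA", "GB"), Annotation("d1", "gB", "GB")]
        summary = summarize_links(links, ann).set_index("feature_class")
        assert summary.loc["GB", "n_annotations"] == 2
        assert summary.loc["GB", "n_dmrs"] == 1

    def test_short_gene_annotations_split_out(self):
        links = [DmrGeneLink("d1", "gA", "GS", 0.2, 0.5, 10)]
        ann = [Annotation("d1", "gA", "GS")]
        summary = summarize_links(links, ann, gene_lengths={"gA": 900}).set_index(
            "feature_class"
        )
        assert summary.loc["GS", "n_annotations"] == 0
        assert summary.loc["GS", "n_a_short_genes"] == 1
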