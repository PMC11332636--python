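import itertools
import math

import numpy as np
import pytest

from methlink.dmr_detection import (
    VAR_EPSILON,
    DmrConfig,
    classify_direction,
    direction_summary,
    find_candidate_regions,
    per_cpg_difference,
    permutation_pvalues,
    region_statistic,
    records_to_frame,
)

from conftest import make_matrix


def level_matrix(levels, positions=None, contig="c", cov=10, size_classes=None, feeds=None):
    """Matrix whose meth/total reproduce the given per-CpG per-sample levels
    exactly (levels must be multiples of 1/cov)."""
    levels = np.asarray(levels, dtype=float)
    if positions is None:
        positions = np.arange(levels.shape[0]) * 100
    total = np.full(levels.shape, cov)
    meth = np.rint(levels * cov).astype(int)
    return make_matrix(
        [(contig, int(p)) for p in positions], meth, total, size_classes, feeds
    )


class TestPerCpgDifference:
    def test_single_stratum_difference(self):
        m = level_matrix([[0.8, 0.8, 0.6, 0.6]], size_classes=["large"] * 2 + ["small"] * 2)
        d = per_cpg_difference(m, m.metadata["size_class"], m.metadata["feed"], "large")
        assert d.d[0] == pytest.approx(0.2)

    def test_strata_combined_weighted_by_size(self):
        # stratum A: d = 0.2, stratum B: d = 0.0, equal sizes -> 0.1
        m = level_matrix(
            [[0.8, 0.6, 0.5, 0.5]],
            size_classes=["large", "small", "large", "small"],
            feeds=["F1", "F1", "F2", "F2"],
        )
        d = per_cpg_difference(m, m.metadata["size_class"], m.metadata["feed"], "large")
        assert d.d[0] == pytest.approx(0.1)

    def test_isolated_cpg_smooth_equals_raw(self):
        m = level_matrix(
            [[0.8, 0.6], [0.7, 0.5]], positions=[0, 10_000],
            size_classes=["large", "small"],
        )
        d = per_cpg_difference(m, m.metadata["size_class"], m.metadata["feed"], "large")
        assert np.allclose(d.d_smooth, d.d)

    def test_smoothing_averages_neighbours(self):
        m = level_matrix(
            [[0.8, 0.6], [0.6, 0.6], [0.8, 0.6]],
            positions=[0, 100, 200],
            size_classes=["large", "small"],
        )
        d = per_cpg_difference(
            m, m.metadata["size_class"], m.metadata["feed"], "large",
            DmrConfig(smooth_bw=250),
        )
        assert d.d_smooth[1] == pytest.approx((0.2 + 0.0 + 0.2) / 3)

    def test_single_group_stratum_excluded_with_warning(self):
        m = level_matrix(
            [[0.8, 0.6, 0.5]],
            size_classes=["large", "small", "large"],
            feeds=["F1", "F1", "F2"],
        )
        with pytest.warns(UserWarning, match="single group"):
            d = per_cpg_difference(m, m.metadata["size_class"], m.metadata["feed"], "large")
        assert d.d[0] == pytest.approx(0.2)

    def test_unfiltered_matrix_rejected(self):
        m = make_matrix([("c", 0)], [[0, 0]], [[0, 4]])
        with pytest.raises(ValueError, match="filtered"):
            per_cpg_difference(m, ["large", "small"], ["F", "F"], "large")


def diffs_from_arrays(d_smooth, positions=None, contig_breaks=(), d=None):
    from methlink.dmr_detection import CpgDifferences

    d_smooth = np.asarray(d_smooth, dtype=float)
    n = len(d_smooth)
    if positions is None:
        positions = np.arange(n) * 100
    contigs = np.array(["c1"] * n, dtype=object)
    for b in contig_breaks:
        contigs[b:] = "c2"
    return CpgDifferences(
        contigs, np.asarray(positions),
        d_smooth if d is None else np.asarray(d, float),
        d_smooth, np.full(n, 0.0),
    )


class TestFindCandidateRegions:
    def test_six_qualifying_cpgs_form_one_region(self):
        regions = find_candidate_regions(diffs_from_arrays([0.08] * 6))
        assert regions == [(0, 6)]

    def test_four_qualifying_cpgs_below_minimum(self):
        assert find_candidate_regions(diffs_from_arrays([0.08] * 4)) == []

    def test_sign_change_splits_region(self):
        regions = find_candidate_regions(
            diffs_from_arrays([0.08] * 5 + [-0.08] * 5)
        )
        assert regions == [(0, 5), (5, 10)]

    def test_gap_rule_splits_region(self):
        positions = [0, 100, 200, 300, 400, 2000, 2100, 2200, 2300, 2400]
        regions = find_candidate_regions(
            diffs_from_arrays([0.08] * 10, positions=positions)
        )
        assert regions == [(0, 5), (5, 10)]

    def test_contig_boundary_splits_region(self):
        regions = find_candidate_regions(
            diffs_from_arrays([0.08] * 10, contig_breaks=(5,))
        )
        assert regions == [(0, 5), (5, 10)]

    def test_subthreshold_cpg_breaks_run(self):
        regions = find_candidate_regions(
            diffs_from_arrays([0.08] * 5 + [0.01] + [0.08] * 5)
        )
        assert regions == [(0, 5), (6, 11)]

    def test_monotone_in_cutoff(self, sim, sim_filtered):
        md = sim.metadata
        loose = permutation_pvalues(
            sim_filtered, md["size_class"], md["feed"], "large",
            DmrConfig(cutoff=0.05, n_perm=50, seed=3),
        )
        tight = permutation_pvalues(
            sim_filtered, md["size_class"], md["feed"], "large",
            DmrConfig(cutoff=0.10, n_perm=50, seed=3),
        )
        assert len(tight) <= len(loose)


class TestRegionStatistic:
    def test_zero_differences_give_zero(self):
        diffs = diffs_from_arrays([0.08] * 5, d=[0.0] * 5)
        assert region_statistic((0, 5), diffs) == 0.0

    def test_doubling_identical_cpgs_scales_by_sqrt2(self):
        diffs5 = diffs_from_arrays([0.08] * 5)
        diffs10 = diffs_from_arrays([0.08] * 10)
        s5 = region_statistic((0, 5), diffs5)
        s10 = region_statistic((0, 10), diffs10)
        assert s10 == pytest.approx(math.sqrt(2) * s5)

    def test_matches_single_pass_oracle(self):
        """Statistic equals an independently coded plain loop over the toy
        region (3 samples per group)."""
        levels = np.array(
            [
                [0.9, 0.8, 0.85, 0.6, 0.5, 0.55],
                [0.7, 0.75, 0.8, 0.5, 0.45, 0.4],
                [0.95, 0.9, 1.0, 0.7, 0.65, 0.75],
            ]
        )
        m = level_matrix(levels, cov=20, size_classes=["large"] * 3 + ["small"] * 3)
        diffs = per_cpg_difference(m, m.metadata["size_class"], m.metadata["feed"], "large")
        got = region_statistic((0, 3), diffs)

        # oracle: recompute everything from the level table with plain python
        acc = 0.0
        for i in range(3):
            large = levels[i, :3]
            small = levels[i, 3:]
            d_i = large.mean() - small.mean()
            ss = sum((x - large.mean()) ** 2 for x in large) + sum(
                (x - small.mean()) ** 2 for x in small
            )
            s2 = ss / (6 - 2)
            acc += d_i / math.sqrt(s2 + VAR_EPSILON)
        assert got == pytest.approx(acc / math.sqrt(3))


def permutation_oracle(levels, positions, labels, config):
    """Brute-force permutation caller for a single stratum: enumerates every
    distinct reassignment of the reference labels, recomputes regions and
    statistics from scratch, pools the null, and applies the
    (1 + exceedances)/(1 + N) rule."""
    levels = np.asarray(levels, dtype=float)
    n_samples = levels.shape[1]
    n_ref = labels.count("large")

    def pipeline(ref_cols):
        ref = levels[:, list(ref_cols)]
        other = levels[:, [j for j in range(n_samples) if j not in ref_cols]]
        d = ref.mean(axis=1) - other.mean(axis=1)
        # smoothing
        d_sm = np.empty_like(d)
        for i, p in enumerate(positions):
            win = [k for k, q in enumerate(positions) if abs(q - p) <= config.smooth_bw]
            d_sm[i] = np.mean([d[k] for k in win])
        # regions
        regions = []
        run = []
        for i in range(len(d)):
            ok = abs(d_sm[i]) >= config.cutoff
            if run:
                gap_ok = positions[i] - positions[i - 1] <= config.max_gap
                same_sign = np.sign(d_sm[i]) == np.sign(d_sm[run[-1]])
                if not (ok and gap_ok and same_sign):
                    if len(run) >= config.min_cpgs:
                        regions.append(tuple(run))
                    run = []
            if ok and not run:
                run = [i]
            elif ok:
                run.append(i)
        if len(run) >= config.min_cpgs:
            regions.append(tuple(run))
        stats = []
        for reg in regions:
            acc = 0.0
            for i in reg:
                ss = ((ref[i] - ref[i].mean()) ** 2).sum() + (
                    (other[i] - other[i].mean()) ** 2
                ).sum()
                s2 = ss / (n_samples - 2)
                acc += d[i] / math.sqrt(s2 + VAR_EPSILON)
            stats.append(acc / math.sqrt(len(reg)))
        return regions, stats

    obs_cols = tuple(j for j, l in enumerate(labels) if l == "large")
    obs_regions, obs_stats = pipeline(obs_cols)
    null = []
    for cols in itertools.combinations(range(n_samples), n_ref):
        if cols == obs_cols:
            continue
        _, stats = pipeline(cols)
        null.extend(abs(s) for s in stats)
    out = []
    for stat in obs_stats:
        exceed = sum(1 for s in null if s >= abs(stat) - 1e-12)
        out.append((stat, (1 + exceed) / (1 + len(null))))
    return obs_regions, out


class TestPermutationPvalues:
    def toy(self):
        rng = np.random.default_rng(42)
        n_cpgs = 30
        levels = np.clip(rng.normal(0.7, 0.05, size=(n_cpgs, 6)), 0, 1)
        levels[10:18, :3] += 0.25  # strong planted region, large group
        levels = np.clip(levels, 0, 1)
        levels = np.rint(levels * 20) / 20
        positions = np.arange(n_cpgs) * 100
        return levels, positions

    def test_matches_exhaustive_enumeration_oracle(self):
        """3v3 single stratum: p-values equal a brute-force enumeration of
        the 20 relabelings with the whole pipeline recomputed per shuffle."""
        levels, positions = self.toy()
        labels = ["large"] * 3 + ["small"] * 3
        m = level_matrix(levels, positions=positions, cov=20, size_classes=labels)
        config = DmrConfig(n_perm=1000, seed=1)
        records = permutation_pvalues(
            m, m.metadata["size_class"], m.metadata["feed"], "large", config
        )
        oracle_regions, oracle = permutation_oracle(levels, list(positions), labels, config)
        assert len(records) == len(oracle_regions) > 0
        for rec, (stat, p) in zip(records, oracle):
            assert rec.stat == pytest.approx(stat)
            assert rec.p == pytest.approx(p)

    def test_no_region_above_cutoff_gives_empty_list(self):
        levels = np.full((20, 6), 0.7)
        m = level_matrix(levels, cov=10, size_classes=["large"] * 3 + ["small"] * 3)
        records = permutation_pvalues(
            m, m.metadata["size_class"], m.metadata["feed"], "large", DmrConfig(seed=1)
        )
        assert records == []

    def test_label_swap_negates_stats_keeps_p(self):
        levels, positions = self.toy()
        labels = ["large"] * 3 + ["small"] * 3
        m = level_matrix(levels, positions=positions, cov=20, size_classes=labels)
        config = DmrConfig(n_perm=1000, seed=1)
        a = permutation_pvalues(m, m.metadata["size_class"], m.metadata["feed"], "large", config)
        b = permutation_pvalues(m, m.metadata["size_class"], m.metadata["feed"], "small", config)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert ra.stat == pytest.approx(-rb.stat)
            assert ra.delta_beta == pytest.approx(-rb.delta_beta)
            assert ra.p == pytest.approx(rb.p)
            assert {ra.direction, rb.direction} == {"hyper", "hypo"}

    def test_deterministic_under_fixed_seed(self, sim, sim_filtered):
        md = sim.metadata
        config = DmrConfig(n_perm=100, seed=5)
        a = permutation_pvalues(sim_filtered, md["size_class"], md["feed"], "large", config)
        b = permutation_pvalues(sim_filtered, md["size_class"], md["feed"], "large", config)
        assert a == b

    def test_region_bounds_cover_cpg_dinucleotide(self):
        levels, positions = self.toy()
        labels = ["large"] * 3 + ["small"] * 3
        m = level_matrix(levels, positions=positions, cov=20, size_classes=labels)
        records = permutation_pvalues(
            m, m.metadata["size_class"], m.metadata["feed"], "large", DmrConfig(seed=1)
        )
        for r in records:
            assert (r.end - r.start) >= 2
            assert r.end % 100 == 2  # last CpG position + 2


class TestDirection:
    def test_positive_delta_is_hyper(self):
        assert classify_direction(0.12) == "hyper"

    def test_negative_delta_is_hypo(self):
        assert classify_direction(-0.07) == "hypo"

    def test_zero_delta_rejected(self):
        with pytest.raises(ValueError):
            classify_direction(0.0)

    def test_candidate_direction_percentages(self):
        """A 1,057-region fixture with 576 hypermethylated regions summarises
        to 54.5% / 45.5%."""
        directions = ["hyper"] * 576 + ["hypo"] * 481
        summary = direction_summary(directions)
        assert summary["n"] == 1057
        assert summary["pct_hyper"] == 54.5
        assert summary["pct_hypo"] == 45.5


def test_records_frame_has_volcano_columns(sim, sim_filtered):
    md = sim.metadata
    records = permutation_pvalues(
        sim_filtered, md["size_class"], md["feed"], "large", DmrConfig(n_perm=50, seed=2)
    )
    df = records_to_frame(records)
    assert {"delta_beta", "neg_log10_p", "candidate"} <= set(df.columns)
    assert (df["neg_log10_p"] >= 0).all()
    # sign consistency between statistic, delta beta and direction
    assert (np.sign(df["stat"]) == np.sign(df["delta_beta"])).all()
    assert ((df["delta_beta"] > 0) == (df["direction"] == "hyper")).all()
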