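"""Candidate DMR detection by smoothing, run construction and label permutation.

Per-CpG methylation differences between the two size classes are computed
within each feed stratum and combined, smoothed over a +/- 250 bp window, and
assembled into candidate regions: maximal runs of adjacent CpGs whose smoothed
difference clears the cutoff with a constant sign and without large positional
gaps.  Each region gets a variance-standardised signed statistic; its p-value
comes from a pooled permutation null in which group labels are shuffled within
strata and the entire region-construction pipeline is re-run.  Raw p-values
are used directly (no multiplicity adjustment); regions with p below
``candidate_alpha`` are flagged candidates.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .methylation_io import MethylationMatrix

__all__ = [
    "DmrConfig",
    "DmrRecord",
    "CpgDifferences",
    "per_cpg_difference",
    "find_candidate_regions",
    "region_statistic",
    "permutation_pvalues",
    "classify_direction",
    "direction_summary",
    "records_to_frame",
]

VAR_EPSILON = 0.01  # stabiliser added to the pooled variance in the statistic


@dataclass(frozen=True)
class DmrConfig:
    cutoff: float = 0.05
    min_cpgs: int = 5
    max_gap: int = 1000
    smooth_bw: int = 250
    n_perm: int = 1000
    seed: int = 1
    candidate_alpha: float = 0.01

    def __post_init__(self):
        if not (0 < self.cutoff < 1):
            raise ValueError("cutoff must lie in (0,1)")
        if self.min_cpgs < 2:
            raise ValueError("min_cpgs must be >= 2")


@dataclass(frozen=True)
class DmrRecord:
    """One detected region; ``end`` covers the last CpG dinucleotide."""

    contig: str
    start: int
    end: int
    n_cpgs: int
    stat: float
    p: float
    delta_beta: float
    direction: str
    candidate: bool

    def __post_init__(self):
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be 'hyper' or 'hypo'")


@dataclass
class CpgDifferences:
    """Per-CpG raw (``d``) and smoothed (``d_smooth``) group differences."""

    contigs: np.ndarray
    positions: np.ndarray
    d: np.ndarray
    d_smooth: np.ndarray
    pooled_var: np.ndarray


def _group_masks(
    group_labels: Sequence, reference: str
) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(groups)}")
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not among {list(groups)}")
    ref = labels == reference
    return ref, ~ref


def _usable_strata(
    ref_mask: np.ndarray, strata: np.ndarray, warn: bool = True
) -> list[np.ndarray]:
    """Per-stratum sample index arrays; strata missing a group are dropped."""
    out = []
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        n_ref = ref_mask[idx].sum()
        if n_ref == 0 or n_ref == len(idx):
            if warn:
                warnings.warn(f"stratum {s!r} holds a single group; excluded")
            continue
        out.append(idx)
    if not out:
        raise ValueError("no stratum contains both groups")
    return out


def _stratified_difference(
    levels: np.ndarray, ref_mask: np.ndarray, strata_idx: list[np.ndarray]
) -> np.ndarray:
    """Within-stratum reference-minus-other mean difference, combined across
    strata weighted by stratum size."""
    num = np.zeros(levels.shape[0])
    denom = 0.0
    for idx in strata_idx:
        r = idx[ref_mask[idx]]
        o = idx[~ref_mask[idx]]
        d_s = levels[:, r].mean(axis=1) - levels[:, o].mean(axis=1)
        w = len(idx)
        num += w * d_s
        denom += w
    return num / denom


def _pooled_variance(levels: np.ndarray, ref_mask: np.ndarray) -> np.ndarray:
    """Pooled between-sample variance of levels within the two groups."""
    n = levels.shape[1]
    ss = np.zeros(levels.shape[0])
    for mask in (ref_mask, ~ref_mask):
        sub = levels[:, mask]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n - 2
    return ss / df if df > 0 else np.full(levels.shape[0], np.nan)


def _smoothing_windows(
    contigs: np.ndarray, positions: np.ndarray, smooth_bw: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per CpG, the [lo, hi) index range of CpGs within +/- smooth_bw on the
    same contig.  Loci must be sorted by (contig, position)."""
    n = len(positions)
    lo = np.empty(n, dtype=np.int64)
    hi = np.empty(n, dtype=np.int64)
    boundaries = np.flatnonzero(contigs[1:] != contigs[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    for a, b in zip(starts, ends):
        pos = positions[a:b]
        lo[a:b] = a + np.searchsorted(pos, pos - smooth_bw, side="left")
        hi[a:b] = a + np.searchsorted(pos, pos + smooth_bw, side="right")
    return lo, hi


def _windowed_mean(d: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    csum = np.concatenate(([0.0], np.cumsum(d)))
    return (csum[hi] - csum[lo]) / (hi - lo)


def per_cpg_difference(
    matrix: MethylationMatrix,
    group_labels: Sequence,
    strata_labels: Sequence,
    reference: str,
    config: DmrConfig = DmrConfig(),
) -> CpgDifferences:
    """Raw and smoothed per-CpG methylation differences (reference - other).

    The matrix must be complete-coverage filtered.  Differences are computed
    within each stratum and combined weighted by stratum size; smoothing is
    the plain mean of raw differences over CpGs within ``smooth_bw`` bp.
    """
    if (matrix.total == 0).any():
        raise ValueError("matrix must be complete-coverage filtered first")
    levels = matrix.meth / matrix.total
    ref_mask, _ = _group_masks(group_labels, reference)
    strata = np.asarray(strata_labels)
    strata_idx = _usable_strata(ref_mask, strata)
    d = _stratified_difference(levels, ref_mask, strata_idx)
    contigs = matrix.loci["contig"].to_numpy()
    positions = matrix.loci["position"].to_numpy()
    lo, hi = _smoothing_windows(contigs, positions, config.smooth_bw)
    d_smooth = _windowed_mean(d, lo, hi)
    pooled = _pooled_variance(levels, ref_mask)
    return CpgDifferences(contigs, positions, d, d_smooth, pooled)


def find_candidate_regions(
    diffs: CpgDifferences, config: DmrConfig = DmrConfig()
) -> list[tuple[int, int]]:
    """Maximal runs of adjacent qualifying CpGs as [i, j) index ranges.

    A run extends while |d_smooth| >= cutoff, the sign of d_smooth is
    constant, CpGs sit on one contig, and consecutive CpGs are <= max_gap bp
    apart; runs shorter than min_cpgs CpGs are discarded.
    """
    q = np.abs(diffs.d_smooth) >= config.cutoff
    n = len(q)
    if n == 0:
        return []
    sign = np.sign(diffs.d_smooth)
    brk = np.ones(n, dtype=bool)  # brk[i]: position i starts a new run
    same_contig = diffs.contigs[1:] == diffs.contigs[:-1]
    small_gap = (diffs.positions[1:] - diffs.positions[:-1]) <= config.max_gap
    same_sign = sign[1:] == sign[:-1]
    brk[1:] = ~(same_contig & small_gap & same_sign & q[1:] & q[:-1])
    run_starts = np.flatnonzero(brk)
    run_ends = np.append(run_starts[1:], n)
    keep = q[run_starts] & ((run_ends - run_starts) >= config.min_cpgs)
    return [(int(i), int(j)) for i, j in zip(run_starts[keep], run_ends[keep])]


def region_statistic(
    region: tuple[int, int], diffs: CpgDifferences, epsilon: float = VAR_EPSILON
) -> float:
    """Signed region statistic, comparable across region sizes.

    stat = (1/sqrt(n)) * sum over CpGs of d_i / sqrt(s_i^2 + epsilon), where
    s_i^2 is the pooled between-sample variance of levels at CpG i.  The
    1/sqrt(n) scaling keeps the pooled permutation null comparable between
    short and long regions: without it, long weakly-differential regions
    arising under near-identity relabelings dominate the null tail and mask
    short genuine regions.
    """
    i, j = region
    n = j - i
    return float(
        np.sum(diffs.d[i:j] / np.sqrt(diffs.pooled_var[i:j] + epsilon)) / math.sqrt(n)
    )


def _regions_and_stats(
    levels: np.ndarray,
    contigs: np.ndarray,
    positions: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    ref_mask: np.ndarray,
    strata_idx: list[np.ndarray],
    config: DmrConfig,
) -> tuple[list[tuple[int, int]], np.ndarray, CpgDifferences]:
    d = _stratified_difference(levels, ref_mask, strata_idx)
    d_smooth = _windowed_mean(d, lo, hi)
    pooled = _pooled_variance(levels, ref_mask)
    diffs = CpgDifferences(contigs, positions, d, d_smooth, pooled)
    regions = find_candidate_regions(diffs, config)
    w = d / np.sqrt(pooled + VAR_EPSILON)
    csum = np.concatenate(([0.0], np.cumsum(w)))
    stats = np.array([(csum[j] - csum[i]) / math.sqrt(j - i) for i, j in regions])
    return regions, stats, diffs


def _within_strata_assignments(
    ref_mask: np.ndarray, strata_idx: list[np.ndarray]
) -> int:
    total = 1
    for idx in strata_idx:
        total *= math.comb(len(idx), int(ref_mask[idx].sum()))
    return total


def _enumerate_masks(
    ref_mask: np.ndarray, strata_idx: list[np.ndarray]
) -> list[np.ndarray]:
    """All distinct within-stratum reassignments of the reference label."""
    per_stratum: list[list[np.ndarray]] = []
    for idx in strata_idx:
        k = int(ref_mask[idx].sum())
        options = [np.asarray(c, dtype=np.int64) for c in itertools.combinations(idx, k)]
        per_stratum.append(options)
    masks = []
    for combo in itertools.product(*per_stratum):
        m = np.zeros_like(ref_mask)
        for arr in combo:
            m[arr] = True
        masks.append(m)
    return masks


def permutation_pvalues(
    matrix: MethylationMatrix,
    group_labels: Sequence,
    strata_labels: Sequence,
    reference: str,
    config: DmrConfig = DmrConfig(),
) -> list[DmrRecord]:
    """Detect regions and assign pooled-permutation p-values.

    Group labels are shuffled within strata; each shuffle re-runs the full
    difference/smoothing/region pipeline and its region statistics join one
    pooled null.  p = (1 + #{null |stat| >= |stat_obs|}) / (1 + N_null).
    When the distinct within-stratum relabelings number at most ``n_perm``
    they are enumerated exhaustively (the observed labeling excluded).
    """
    if (matrix.total == 0).any():
        raise ValueError("matrix must be complete-coverage filtered first")
    levels = matrix.meth / matrix.total
    ref_mask, _ = _group_masks(group_labels, reference)
    strata = np.asarray(strata_labels)
    strata_idx = _usable_strata(ref_mask, strata)
    contigs = matrix.loci["contig"].to_numpy()
    positions = matrix.loci["position"].to_numpy()
    lo, hi = _smoothing_windows(contigs, positions, config.smooth_bw)

    regions, stats, diffs = _regions_and_stats(
        levels, contigs, positions, lo, hi, ref_mask, strata_idx, config
    )
    if not regions:
        return []

    n_distinct = _within_strata_assignments(ref_mask, strata_idx)
    if n_distinct < 2:
        raise ValueError("fewer than 2 distinct relabelings possible")

    null_stats: list[np.ndarray] = []
    if n_distinct <= config.n_perm:
        for mask in _enumerate_masks(ref_mask, strata_idx):
            if np.array_equal(mask, ref_mask):
                continue
            _, s, _ = _regions_and_stats(
                levels, contigs, positions, lo, hi, mask, strata_idx, config
            )
            null_stats.append(np.abs(s))
    else:
        rng = np.random.default_rng(config.seed)
        for _ in range(config.n_perm):
            mask = np.zeros_like(ref_mask)
            for idx in strata_idx:
                k = int(ref_mask[idx].sum())
                chosen = rng.choice(idx, size=k, replace=False)
                mask[chosen] = True
            _, s, _ = _regions_and_stats(
                levels, contigs, positions, lo, hi, mask, strata_idx, config
            )
            null_stats.append(np.abs(s))
    null = np.concatenate(null_stats) if null_stats else np.empty(0)
    null.sort()
    n_null = len(null)

    records: list[DmrRecord] = []
    for (i, j), stat in zip(regions, stats):
        exceed = n_null - np.searchsorted(null, abs(stat) - 1e-12, side="left")
        p = (1 + exceed) / (1 + n_null)
        delta = float(diffs.d[i:j].mean())
        records.append(
            DmrRecord(
                contig=str(contigs[i]),
                start=int(positions[i]),
                end=int(positions[j - 1]) + 2,
                n_cpgs=j - i,
                stat=float(stat),
                p=float(p),
                delta_beta=delta,
                direction=classify_direction(delta),
                candidate=bool(p < config.candidate_alpha),
            )
        )
    return records


def classify_direction(delta_beta: float) -> str:
    """'hyper' iff the reference group is more methylated (delta_beta > 0)."""
    if delta_beta > 0:
        return "hyper"
    if delta_beta < 0:
        return "hypo"
    raise ValueError("delta_beta is exactly zero; direction undefined")


def direction_summary(directions: Sequence[str]) -> dict[str, float]:
    """Counts and percentages (1 decimal) of hyper/hypomethylated regions."""
    dirs = pd.Series(list(directions))
    n = len(dirs)
    n_hyper = int((dirs == "hyper").sum())
    n_hypo = int((dirs == "hypo").sum())
    if n_hyper + n_hypo != n:
        raise ValueError("directions must be 'hyper' or 'hypo'")
    return {
        "n": n,
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "pct_hyper": round(100.0 * n_hyper / n, 1) if n else float("nan"),
        "pct_hypo": round(100.0 * n_hypo / n, 1) if n else float("nan"),
    }


def records_to_frame(records: Sequence[DmrRecord]) -> pd.DataFrame:
    """BED-like table of DMR records (adds -log10 p for volcano plotting)."""
    df = pd.DataFrame(
        [
            (r.contig, r.start, r.end, r.n_cpgs, r.stat, r.p, r.delta_beta,
             r.direction, r.candidate)
            for r in records
        ],
        columns=[
            "contig", "start", "end", "n_cpgs", "stat", "p", "delta_beta",
            "direction", "candidate",
        ],
    )
    if len(df):
        df["neg_log10_p"] = -np.log10(df["p"])
    else:
        df["neg_log10_p"] = pd.Series(dtype=float)
    return df
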