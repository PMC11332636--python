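"""Genome-wide methylation patterns: tiling, PCA, PERMANOVA, TSS metaprofile.

The genome is cut into fixed windows (10 kb by default) whose per-sample mean
methylation forms the sample-profile matrix for ordination.  Group separation
is tested with a PERMANOVA on Euclidean distances between sample profiles.
The metaprofile pools CpG methylation into 50-bp bins of strand-aware distance
from annotated TSSs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_features import GeneModel
from .methylation_io import MethylationMatrix

__all__ = [
    "TileConfig",
    "TileMatrix",
    "PermanovaResult",
    "MetaProfile",
    "tile_methylation",
    "pca",
    "permanova",
    "tss_metaprofile",
]


@dataclass(frozen=True)
class TileConfig:
    window: int = 10_000
    min_cpgs: int = 100
    min_cov: float = 1.0
    max_cov: float = 30.0

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.min_cov > self.max_cov:
            raise ValueError("min_cov must be <= max_cov")


@dataclass
class TileMatrix:
    """Retained genomic tiles with per-sample mean methylation levels."""

    tiles: pd.DataFrame  # contig, start, end, n_cpgs, mean_cov
    samples: list[str]
    levels: np.ndarray  # tiles x samples, in [0,1] or NaN where uncovered

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    def to_frame(self) -> pd.DataFrame:
        df = self.tiles.reset_index(drop=True).copy()
        for j, s in enumerate(self.samples):
            df[f"level_{s}"] = self.levels[:, j]
        return df


@dataclass(frozen=True)
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p: float
    n_perm: int
    exhaustive: bool


@dataclass
class MetaProfile:
    """Mean methylation by binned strand-aware distance from the TSS."""

    bin_starts: np.ndarray
    mean_level: np.ndarray  # NaN where no covered CpG fell in the bin
    n_cpgs: np.ndarray
    bin: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_starts,
                "mean_level": self.mean_level,
                "n_cpgs": self.n_cpgs,
            }
        )


def tile_methylation(matrix: MethylationMatrix, config: TileConfig = TileConfig()) -> TileMatrix:
    """Aggregate CpGs into non-overlapping windows and apply retention filters.

    A tile is kept iff it holds >= ``min_cpgs`` CpG loci and its mean per-CpG
    coverage, averaged over CpGs and samples, lies in [min_cov, max_cov].
    The per-sample tile level is the count-weighted mean sum(meth)/sum(total).
    """
    contigs = matrix.loci["contig"].to_numpy()
    positions = matrix.loci["position"].to_numpy()
    tile_idx = positions // config.window

    key = pd.DataFrame({"contig": contigs, "tile": tile_idx})
    groups = key.groupby(["contig", "tile"], sort=True).indices

    rows = []
    levels = []
    for (contig, tile), idx in groups.items():
        n_cpgs = len(idx)
        if n_cpgs < config.min_cpgs:
            continue
        tot = matrix.total[idx]
        mean_cov = tot.mean()
        if not (config.min_cov <= mean_cov <= config.max_cov):
            continue
        meth_sum = matrix.meth[idx].sum(axis=0).astype(float)
        tot_sum = tot.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lv = meth_sum / tot_sum
        lv[tot_sum == 0] = np.nan
        start = int(tile) * config.window
        rows.append((contig, start, start + config.window, n_cpgs, float(mean_cov)))
        levels.append(lv)
    tiles = pd.DataFrame(rows, columns=["contig", "start", "end", "n_cpgs", "mean_cov"])
    lv_arr = (
        np.vstack(levels) if levels else np.empty((0, matrix.n_samples))
    )
    return TileMatrix(tiles, list(matrix.samples), lv_arr)


def pca(tile_matrix: TileMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of sample profiles over tiles (centered, unscaled), via SVD.

    Tiles with any undefined level are dropped.  Returns per-sample scores
    and the per-component variance fractions (NaN if total variance is zero).
    """
    X = tile_matrix.levels.T  # samples x tiles
    keep = ~np.isnan(tile_matrix.levels).any(axis=1)
    X = X[:, keep]
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 tiles")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, p)
    scores = U[:, :k] * S[:k]
    var = S[:k] ** 2
    total = var.sum()
    fractions = var / total if total > 0 else np.full(k, np.nan)
    score_df = pd.DataFrame(
        scores,
        index=tile_matrix.samples,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return score_df, fractions


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """(SS_total, SS_within, SS_between) from squared distances and labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += np.triu(sub, 1).sum() / len(idx)
    return ss_total, ss_within, ss_total - ss_within


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    g = len(np.unique(labels))
    ss_total, ss_within, ss_between = _permanova_ss(d2, labels)
    if ss_within <= 0:
        f = math.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / (g - 1)) / (ss_within / (n - g))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def _n_distinct_relabelings(labels: np.ndarray) -> int:
    n = len(labels)
    counts = pd.Series(labels).value_counts()
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(int(c))
    return total


def permanova(
    tile_matrix: TileMatrix | np.ndarray,
    labels: Sequence,
    n_perm: int = 999,
    seed: int = 1,
) -> PermanovaResult:
    """PERMANOVA on Euclidean distances between sample tile profiles.

    pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g)) from the distance
    matrix; p is the label-permutation tail probability, by exhaustive
    enumeration when the number of distinct relabelings is <= ``n_perm``
    and by (1 + exceedances)/(1 + n_perm) Monte Carlo otherwise.
    """
    if isinstance(tile_matrix, TileMatrix):
        X = tile_matrix.levels.T
        X = X[:, ~np.isnan(tile_matrix.levels).any(axis=1)]
    else:
        X = np.asarray(tile_matrix, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    if n != len(labels):
        raise ValueError("labels must match the number of samples")
    if n < 3:
        raise ValueError("PERMANOVA needs at least 3 samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts == 0).any():
        raise ValueError("need >= 2 non-empty groups")

    diff = X[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    f_obs, r2 = _pseudo_f(d2, labels)

    n_distinct = _n_distinct_relabelings(labels)
    if n_distinct <= n_perm:
        from sympy.utilities.iterables import multiset_permutations

        count_ge = 0
        total = 0
        for perm in multiset_permutations(list(labels)):
            f_perm, _ = _pseudo_f(d2, np.asarray(perm))
            total += 1
            if f_perm >= f_obs - 1e-12:
                count_ge += 1
        p = count_ge / total
        return PermanovaResult(r2, f_obs, p, total, True)

    rng = np.random.default_rng(seed)
    count_ge = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        f_perm, _ = _pseudo_f(d2, lab)
        if f_perm >= f_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return PermanovaResult(r2, f_obs, p, n_perm, False)


def tss_metaprofile(
    matrix: MethylationMatrix,
    genes: Iterable[GeneModel],
    span_up: int = 6000,
    span_down: int = 5000,
    bin: int = 50,
) -> MetaProfile:
    """Count-weighted mean methylation in bins of distance from the TSS.

    Each CpG within [-span_up, +span_down) of a gene's TSS contributes once
    per gene it is near; offsets are strand-aware (negative = upstream).  On
    the - strand the destranded CpG anchor at genomic position p corresponds
    to the - strand cytosine at p+1, so the offset is tss - p - 1.
    """
    if (span_up + span_down) % bin:
        raise ValueError("span must be a whole number of bins")
    n_bins = (span_up + span_down) // bin
    bin_starts = np.arange(-span_up, span_down, bin)
    meth_sum = np.zeros(n_bins)
    tot_sum = np.zeros(n_bins)
    n_cpgs = np.zeros(n_bins, dtype=np.int64)

    contigs = matrix.loci["contig"].to_numpy()
    positions = matrix.loci["position"].to_numpy()
    meth_tot = matrix.meth.sum(axis=1).astype(float)
    tot_tot = matrix.total.sum(axis=1).astype(float)

    by_contig: dict[str, np.ndarray] = {}
    for contig in np.unique(contigs):
        by_contig[contig] = np.flatnonzero(contigs == contig)

    for gene in genes:
        idx = by_contig.get(gene.contig)
        if idx is None:
            continue
        pos = positions[idx]
        tss = gene.tss
        if gene.strand == "+":
            lo = np.searchsorted(pos, tss - span_up)
            hi = np.searchsorted(pos, tss + span_down)
            sel = idx[lo:hi]
            offsets = positions[sel] - tss
        else:
            # offset = tss - p - 1 in [-span_up, span_down) <=> p in
            # (tss - span_down, tss + span_up - 1]
            lo = np.searchsorted(pos, tss - span_down + 1)
            hi = np.searchsorted(pos, tss + span_up)
            sel = idx[lo:hi]
            offsets = tss - positions[sel] - 1
        bins = (offsets + span_up) // bin
        ok = (bins >= 0) & (bins < n_bins)
        bins = bins[ok]
        sel = sel[ok]
        np.add.at(meth_sum, bins, meth_tot[sel])
        np.add.at(tot_sum, bins, tot_tot[sel])
        np.add.at(n_cpgs, bins, 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_level = meth_sum / tot_sum
    mean_level[tot_sum == 0] = np.nan
    return MetaProfile(bin_starts, mean_level, n_cpgs, bin)
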