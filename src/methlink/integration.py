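"""DMR annotation onto genomic features and methylation-expression linking.

Candidate DMRs are intersected with the per-gene feature intervals (1 bp
overlap suffices); every (DMR, gene, feature-class) interaction is one
annotation (N_A), while each DMR also receives exactly one feature class via
the hierarchy P1 > GS > P6 > GB > TTR > Intergenic (N_DMRs).  DMR density is
N_DMRs over the canonical feature length.  For every annotated (DMR, gene)
pair with expression data, the DMR's count-weighted mean methylation per
sample is Pearson-correlated against the gene's normalized counts; feature
summaries mirror the N_A / N_DMRs / significant-correlation bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dmr_detection import DmrRecord
from .genome_features import FeatureGeometry, FeatureInterval, GeneModel
from .methylation_io import MethylationMatrix

__all__ = [
    "HIERARCHY",
    "Annotation",
    "DmrGeneLink",
    "intersect_dmrs_features",
    "assign_primary_feature",
    "feature_density",
    "dmr_mean_methylation",
    "correlate",
    "compute_links",
    "summarize_links",
    "summarize_annotation",
    "build_links_and_summaries",
]

#: Feature-class priority, highest first; Intergenic is the fallback.
HIERARCHY = ("P1", "GS", "P6", "GB", "TTR", "Intergenic")
_RANK = {c: i for i, c in enumerate(HIERARCHY)}


@dataclass(frozen=True)
class Annotation:
    """One DMR-gene-feature overlap interaction."""

    dmr_id: str
    gene_id: str
    feature_class: str


@dataclass(frozen=True)
class DmrGeneLink:
    """One correlated DMR-gene pair with its hierarchy-assigned class."""

    dmr_id: str
    gene_id: str
    assigned_class: str
    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05

    @property
    def sign(self) -> str:
        return "positive" if self.r > 0 else "negative"


def _dmr_intervals(dmrs: Sequence[DmrRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(dmrs, pd.DataFrame):
        df = dmrs.copy()
        if "dmr_id" not in df.columns:
            df["dmr_id"] = [f"dmr{i}" for i in range(len(df))]
        return df[["dmr_id", "contig", "start", "end"]]
    return pd.DataFrame(
        {
            "dmr_id": [f"dmr{i}" for i in range(len(dmrs))],
            "contig": [d.contig for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
        }
    )


def intersect_dmrs_features(
    dmrs: Sequence[DmrRecord] | pd.DataFrame,
    features: Iterable[FeatureInterval],
) -> list[Annotation]:
    """Event-sweep overlap of DMRs with feature intervals (>= 1 bp).

    Returns one :class:`Annotation` per overlapping (DMR, gene, class)
    triple.  Half-open semantics: intervals that merely touch do not overlap.
    """
    ddf = _dmr_intervals(dmrs)
    feats = list(features)
    # events: (contig, coord, kind, payload); ends sort before starts at a
    # coordinate so touching intervals never pair (half-open intervals).
    START_D, START_F, END = 1, 2, 0
    events: list[tuple] = []
    for row in ddf.itertuples(index=False):
        events.append((row.contig, row.start, START_D, row))
        events.append((row.contig, row.end, END, ("d", row.dmr_id)))
    for k, iv in enumerate(feats):
        events.append((iv.contig, iv.start, START_F, (k, iv)))
        events.append((iv.contig, iv.end, END, ("f", k)))
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    out: set[tuple[str, str, str]] = set()
    active_d: dict[str, object] = {}
    active_f: dict[int, FeatureInterval] = {}
    current_contig = None
    for contig, _, kind, payload in events:
        if contig != current_contig:
            active_d.clear()
            active_f.clear()
            current_contig = contig
        if kind == END:
            tag, key = payload
            (active_d if tag == "d" else active_f).pop(key, None)
        elif kind == START_D:
            active_d[payload.dmr_id] = payload
            for iv in active_f.values():
                out.add((payload.dmr_id, iv.gene_id, iv.feature_class))
        else:
            k, iv = payload
            active_f[k] = iv
            for dmr_id in active_d:
                out.add((dmr_id, iv.gene_id, iv.feature_class))
    return [Annotation(*t) for t in sorted(out)]


def assign_primary_feature(
    annotations: Iterable[Annotation], dmr_ids: Iterable[str]
) -> dict[str, str]:
    """One class per DMR: the highest-ranked class among all its annotations
    across genes; DMRs with none are Intergenic."""
    assigned = {d: "Intergenic" for d in dmr_ids}
    for a in annotations:
        if a.dmr_id not in assigned:
            raise KeyError(f"annotation references unknown DMR {a.dmr_id!r}")
        if _RANK[a.feature_class] < _RANK[assigned[a.dmr_id]]:
            assigned[a.dmr_id] = a.feature_class
    return assigned


def feature_density(
    n_dmrs: Mapping[str, int],
    geometry: FeatureGeometry = FeatureGeometry(),
    mean_gene_body_length: float | None = None,
) -> dict[str, float | None]:
    """N_DMRs per bp of canonical feature length; Intergenic has none."""
    out: dict[str, float | None] = {}
    for cls, n in n_dmrs.items():
        if cls == "Intergenic":
            out[cls] = None
            continue
        length = geometry.canonical_length(cls, mean_gene_body_length)
        out[cls] = n / length
    return out


def dmr_mean_methylation(
    matrix: MethylationMatrix, dmr: DmrRecord | pd.Series
) -> np.ndarray:
    """Per-sample count-weighted mean methylation over the DMR's CpGs;
    NaN where the region has zero coverage in a sample."""
    contig = dmr.contig if hasattr(dmr, "contig") else dmr["contig"]
    start = int(dmr.start if hasattr(dmr, "start") else dmr["start"])
    end = int(dmr.end if hasattr(dmr, "end") else dmr["end"])
    in_region = (
        (matrix.loci["contig"] == contig)
        & (matrix.loci["position"] >= start)
        & (matrix.loci["position"] < end)
    ).to_numpy()
    if not in_region.any():
        raise ValueError(f"no matrix CpGs inside {contig}:{start}-{end}")
    meth = matrix.meth[in_region].sum(axis=0).astype(float)
    tot = matrix.total[in_region].sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lv = meth / tot
    lv[tot == 0] = np.nan
    return lv


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r with its two-sided t-test p over defined pairs.

    Raises on zero variance; perfectly collinear pairs get p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 paired samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1 - 1e-12:
        p = 0.0
    return float(r), float(p), n


def compute_links(
    dmrs: pd.DataFrame,
    annotations: Sequence[Annotation],
    matrix: MethylationMatrix,
    normalized: pd.DataFrame,
) -> list[DmrGeneLink]:
    """One link per annotated (DMR, gene) pair with expression data.

    Uses the samples present in both data sets; the pair's class is the
    highest-ranked of that gene's annotated classes for the DMR.  Pairs with
    undefined correlation (zero variance, too few samples) are skipped.
    """
    shared = [s for s in matrix.samples if s in normalized.columns]
    if len(shared) < 3:
        raise ValueError("need >= 3 samples with both data types")
    cols = [matrix.sample_column(s) for s in shared]
    dmr_rows = {row.dmr_id: row for row in _dmr_intervals(dmrs).itertuples(index=False)}

    pair_classes: dict[tuple[str, str], str] = {}
    for a in annotations:
        key = (a.dmr_id, a.gene_id)
        best = pair_classes.get(key)
        if best is None or _RANK[a.feature_class] < _RANK[best]:
            pair_classes[key] = a.feature_class

    links: list[DmrGeneLink] = []
    meth_cache: dict[str, np.ndarray] = {}
    for (dmr_id, gene_id), cls in sorted(pair_classes.items()):
        if gene_id not in normalized.index:
            continue
        if dmr_id not in meth_cache:
            meth_cache[dmr_id] = dmr_mean_methylation(matrix, dmr_rows[dmr_id])
        x = meth_cache[dmr_id][cols]
        y = normalized.loc[gene_id, shared].to_numpy(dtype=float)
        try:
            r, p, n = correlate(x, y)
        except ValueError:
            continue
        links.append(DmrGeneLink(dmr_id, gene_id, cls, r, p, n))
    return links


def _round1(x: float) -> float:
    return float(np.round(x, 1))


def summarize_links(
    links: Sequence[DmrGeneLink],
    annotations: Sequence[Annotation],
    gene_lengths: Mapping[str, int] | None = None,
    gs_span: int = 1500,
) -> pd.DataFrame:
    """Per-feature correlation summary over the linked pairs.

    N_A counts annotations restricted to linked pairs; ``n_a_short_genes``
    splits out annotations on genes no longer than ``gs_span``.  N_DMRs,
    significant and negative counts are per unique DMR under the cross-gene
    hierarchy.  Proportions are percentages at 1 decimal.  Ends with a Total
    row.
    """
    linked_pairs = {(l.dmr_id, l.gene_id) for l in links}
    ann = [a for a in annotations if (a.dmr_id, a.gene_id) in linked_pairs]

    dmr_class = assign_primary_feature(ann, {l.dmr_id for l in links})
    sig_links = [l for l in links if l.significant]
    sig_dmr_class: dict[str, tuple[str, float]] = {}
    for l in sig_links:
        # a DMR's significant correlation is booked under its assigned class;
        # keep the strongest link for the sign
        prev = sig_dmr_class.get(l.dmr_id)
        if prev is None or abs(l.r) > abs(prev[1]):
            sig_dmr_class[l.dmr_id] = (dmr_class[l.dmr_id], l.r)

    rows = []
    for cls in HIERARCHY[:-1]:
        if gene_lengths is None:
            n_a = sum(1 for a in ann if a.feature_class == cls)
            n_a_short = 0
        else:
            n_a = sum(
                1
                for a in ann
                if a.feature_class == cls and gene_lengths.get(a.gene_id, gs_span + 1) > gs_span
            )
            n_a_short = sum(
                1
                for a in ann
                if a.feature_class == cls and gene_lengths.get(a.gene_id, gs_span + 1) <= gs_span
            )
        n_dmrs = sum(1 for c in dmr_class.values() if c == cls)
        n_sig = sum(1 for c, _ in sig_dmr_class.values() if c == cls)
        n_neg = sum(1 for c, r in sig_dmr_class.values() if c == cls and r < 0)
        prop = _round1(100.0 * n_sig / n_dmrs) if n_dmrs else 0.0
        rows.append((cls, n_a, n_a_short, n_dmrs, n_sig, prop, n_neg))

    total_na = len(ann)
    total_dmrs = len(dmr_class)
    total_sig = len(sig_dmr_class)
    total_neg = sum(1 for _, r in sig_dmr_class.values() if r < 0)
    rows.append(
        ("Total", total_na, 0, total_dmrs, total_sig,
         _round1(100.0 * total_sig / total_dmrs) if total_dmrs else 0.0, total_neg)
    )
    df = pd.DataFrame(
        rows,
        columns=[
            "feature_class", "n_annotations", "n_a_short_genes", "n_dmrs",
            "n_significant", "proportion_significant", "n_negative",
        ],
    )
    df.attrs["n_genes_linked"] = len({l.gene_id for l in links})
    df.attrs["n_genes_significant"] = len({l.gene_id for l in sig_links})
    return df


def summarize_annotation(
    annotations: Sequence[Annotation],
    dmr_ids: Sequence[str],
    geometry: FeatureGeometry = FeatureGeometry(),
    genes: Sequence[GeneModel] | None = None,
    mean_gene_body_length: float | None = None,
) -> pd.DataFrame:
    """Annotation bookkeeping: per class N_A, N_DMRs and DMR density, with an
    Intergenic row and a Total row (densities rounded to 3 decimals)."""
    assigned = assign_primary_feature(annotations, dmr_ids)
    gene_lengths = {g.gene_id: g.length for g in genes} if genes else None
    if genes and mean_gene_body_length is None:
        long_bodies = [g.length - geometry.gs_span for g in genes if g.length > geometry.gs_span]
        mean_gene_body_length = (
            float(np.mean(long_bodies)) if long_bodies else None
        )
    n_dmrs = {cls: sum(1 for c in assigned.values() if c == cls) for cls in HIERARCHY}
    density = feature_density(
        {c: n for c, n in n_dmrs.items() if c != "Intergenic" and (c != "GB" or mean_gene_body_length)},
        geometry,
        mean_gene_body_length,
    )
    rows = []
    for cls in HIERARCHY:
        if gene_lengths is None:
            n_a = sum(1 for a in annotations if a.feature_class == cls)
            n_a_short = 0
        else:
            n_a = sum(
                1 for a in annotations
                if a.feature_class == cls and gene_lengths.get(a.gene_id, geometry.gs_span + 1) > geometry.gs_span
            )
            n_a_short = sum(
                1 for a in annotations
                if a.feature_class == cls and gene_lengths.get(a.gene_id, geometry.gs_span + 1) <= geometry.gs_span
            )
        d = density.get(cls)
        rows.append(
            (cls, n_a if cls != "Intergenic" else None, n_a_short, n_dmrs[cls],
             round(d, 3) if d is not None else None)
        )
    rows.append(("Total", len(annotations), 0, len(assigned), None))
    return pd.DataFrame(
        rows,
        columns=["feature_class", "n_annotations", "n_a_short_genes", "n_dmrs", "density"],
    )


def build_links_and_summaries(
    dmrs: pd.DataFrame,
    annotations: Sequence[Annotation],
    matrix: MethylationMatrix,
    normalized: pd.DataFrame,
    gene_lengths: Mapping[str, int] | None = None,
) -> tuple[list[DmrGeneLink], pd.DataFrame]:
    """Correlate every annotated (DMR, gene) pair and summarise per feature."""
    links = compute_links(dmrs, annotations, matrix, normalized)
    summary = summarize_links(links, annotations, gene_lengths)
    return links, summary


def links_to_frame(links: Sequence[DmrGeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (l.dmr_id, l.gene_id, l.assigned_class, l.r, l.p, l.n,
             l.significant, l.sign)
            for l in links
        ],
        columns=["dmr_id", "gene_id", "assigned_class", "r", "p", "n",
                 "significant", "sign"],
    )
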