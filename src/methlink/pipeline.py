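"""Configuration-driven orchestration of the full analysis.

Stages run in order (io -> features -> global patterns -> DMR -> expression
-> integration), each writing its tables plus a manifest of input hashes,
parameters and timings under ``outdir/<stage>/``.  A stage whose manifest
matches the current inputs and parameters is skipped on rerun, so partial
reruns resume from cached outputs.  Fixed seed + fixed inputs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import (
    DmrConfig,
    FeatureGeometry,
    TileConfig,
)
from .dmr_detection import direction_summary, permutation_pvalues, records_to_frame
from .expression import (
    differential_expression,
    filter_genes,
    ma_volcano_tables,
    normalize_counts,
    size_factors,
)
from .genome_features import build_feature_intervals, parse_gene_models, write_bed
from .global_patterns import pca, permanova, tile_methylation, tss_metaprofile
from .integration import (
    build_links_and_summaries,
    intersect_dmrs_features,
    links_to_frame,
    summarize_annotation,
)
from .methylation_io import (
    MethylationMatrix,
    assemble_matrix,
    filter_complete_coverage,
    global_methylation_summary,
    merge_strands,
    read_cytosine_report,
    read_metadata,
)

log = logging.getLogger("methlink")

STAGES = ("io", "features", "global", "dmr", "expression", "integrate")

#: parameters that are package choices rather than study-stated values
ASSUMPTION_KEYS = {
    "dmr.max_gap", "dmr.smooth_bw", "dmr.n_perm", "dmr.seed",
    "expression.min_prevalence",
}


@dataclass
class PipelineConfig:
    gff: str
    methylation_dir: str
    counts: str
    metadata: str
    outdir: str
    reference_group: str = "large"
    group_column: str = "size_class"
    strata_column: str = "feed"
    coverage_format: str = "coverage"
    tile: TileConfig = field(default_factory=TileConfig)
    geometry: FeatureGeometry = field(default_factory=FeatureGeometry)
    dmr: DmrConfig = field(default_factory=DmrConfig)
    min_total: int = 10
    min_count: int = 10
    min_prevalence: float = 0.5
    seed: int = 1
    n_perm_permanova: int = 999

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, sub in (("tile", TileConfig), ("geometry", FeatureGeometry), ("dmr", DmrConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_inputs(paths: list[str]) -> dict[str, str]:
    out = {}
    for p in sorted(paths):
        if os.path.isdir(p):
            for name in sorted(os.listdir(p)):
                out[os.path.join(p, name)] = _hash_file(os.path.join(p, name))
        else:
            out[p] = _hash_file(p)
    return out


class Pipeline:
    """Runs the stages, caching each under ``outdir/<stage>/``."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.report: dict[str, dict] = {}
        os.makedirs(config.outdir, exist_ok=True)
        for path, label in [
            (config.gff, "gff"),
            (config.methylation_dir, "methylation_dir"),
            (config.counts, "counts"),
            (config.metadata, "metadata"),
        ]:
            if not os.path.exists(path):
                raise FileNotFoundError(f"{label} path does not exist: {path}")

    # -- stage plumbing -----------------------------------------------------
    def _stage_dir(self, stage: str) -> str:
        d = os.path.join(self.config.outdir, stage)
        os.makedirs(d, exist_ok=True)
        return d

    def _params(self, stage: str) -> dict:
        cfg = self.config.to_dict()
        relevant = {
            "io": ["methylation_dir", "metadata", "coverage_format"],
            "features": ["gff", "geometry"],
            "global": ["tile", "n_perm_permanova", "seed", "group_column"],
            "dmr": ["dmr", "group_column", "strata_column", "reference_group"],
            "expression": [
                "counts", "min_total", "min_count", "min_prevalence",
                "group_column", "strata_column", "reference_group",
            ],
            "integrate": ["geometry"],
        }[stage]
        return {k: cfg[k] for k in relevant}

    def _run_stage(self, stage: str, inputs: list[str], fn: Callable[[str], None]) -> None:
        sdir = self._stage_dir(stage)
        manifest_path = os.path.join(sdir, "manifest.json")
        params = self._params(stage)
        hashes = _hash_inputs(inputs)
        if os.path.exists(manifest_path):
            with open(manifest_path) as fh:
                old = json.load(fh)
            if old.get("params") == json.loads(json.dumps(params)) and old.get("inputs") == hashes:
                log.info("[%s] cached; skipping", stage)
                self.report[stage] = {**old, "cached": True}
                return
        log.info("[%s] running", stage)
        t0 = time.time()
        try:
            fn(sdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest = {
            "stage": stage,
            "params": params,
            "inputs": hashes,
            "assumptions": sorted(
                k for k in ASSUMPTION_KEYS if k.split(".")[0] in (stage, "")
            ),
            "elapsed_s": round(time.time() - t0, 3),
            "outputs": sorted(
                f for f in os.listdir(sdir) if f != "manifest.json"
            ),
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        self.report[stage] = {**manifest, "cached": False}

    # -- stages -------------------------------------------------------------
    def run(self, until: str | None = None) -> dict:
        """Run stages in order; stop after ``until`` when given ('io',
        'features', 'global', 'dmr', 'expression' or 'integrate')."""
        if until is not None and until not in STAGES:
            raise ValueError(f"unknown stage {until!r}")
        cfg = self.config
        md = read_metadata(cfg.metadata)

        def _done(stage: str) -> bool:
            if until == stage:
                report_path = os.path.join(cfg.outdir, "run_report.json")
                with open(report_path, "w") as fh:
                    json.dump(self.report, fh, indent=2, sort_keys=True)
                return True
            return False

        # io: assemble and filter the methylation matrix
        matrix_holder: dict[str, MethylationMatrix] = {}

        def io_stage(sdir: str) -> None:
            per_sample = {}
            for name in sorted(os.listdir(cfg.methylation_dir)):
                sample = os.path.splitext(name)[0]
                calls = read_cytosine_report(
                    os.path.join(cfg.methylation_dir, name), cfg.coverage_format
                )
                per_sample[sample] = merge_strands(calls)
            matrix = assemble_matrix(per_sample, md)
            matrix.write_tsv(os.path.join(sdir, "matrix.tsv"))
            summary = global_methylation_summary(matrix)
            summary.to_csv(os.path.join(sdir, "global_methylation.tsv"), sep="\t")
            matrix_holder["full"] = matrix
            matrix_holder["filtered"] = filter_complete_coverage(matrix)
            matrix_holder["filtered"].write_tsv(os.path.join(sdir, "matrix_filtered.tsv"))

        self._run_stage("io", [cfg.methylation_dir, cfg.metadata], io_stage)
        if _done("io"):
            return self.report
        if "full" not in matrix_holder:  # cached
            sdir = self._stage_dir("io")
            matrix_holder["full"] = MethylationMatrix.read_tsv(
                os.path.join(sdir, "matrix.tsv"), md
            )
            matrix_holder["filtered"] = MethylationMatrix.read_tsv(
                os.path.join(sdir, "matrix_filtered.tsv"), md
            )
        matrix = matrix_holder["full"]
        filtered = matrix_holder["filtered"]

        # features
        genes = parse_gene_models(cfg.gff)
        contig_lengths = None  # clip at zero only; GFF sequence-regions optional

        def features_stage(sdir: str) -> None:
            ivs = build_feature_intervals(genes, cfg.geometry, contig_lengths)
            write_bed(ivs, os.path.join(sdir, "features.bed"))

        self._run_stage("features", [cfg.gff], features_stage)
        if _done("features"):
            return self.report
        features = build_feature_intervals(genes, cfg.geometry, contig_lengths)

        # global patterns
        def global_stage(sdir: str) -> None:
            tiles = tile_methylation(matrix, cfg.tile)
            tiles.to_frame().to_csv(os.path.join(sdir, "tiles.tsv"), sep="\t", index=False)
            result = {}
            if tiles.n_tiles >= 2:
                scores, fractions = pca(tiles)
                scores.to_csv(os.path.join(sdir, "pca_scores.tsv"), sep="\t")
                pd.Series(fractions, name="variance_fraction").to_csv(
                    os.path.join(sdir, "pca_variance.tsv"), sep="\t"
                )
                groups = md.loc[tiles.samples, cfg.group_column]
                pr = permanova(tiles, groups, cfg.n_perm_permanova, cfg.seed)
                result = {
                    "r_squared": pr.r_squared, "pseudo_f": pr.pseudo_f,
                    "p": pr.p, "n_perm": pr.n_perm, "exhaustive": pr.exhaustive,
                }
            with open(os.path.join(sdir, "permanova.json"), "w") as fh:
                json.dump(result, fh, indent=2)
            profile = tss_metaprofile(matrix, genes)
            profile.to_frame().to_csv(
                os.path.join(sdir, "tss_metaprofile.tsv"), sep="\t", index=False
            )

        self._run_stage(
            "global", [cfg.methylation_dir, cfg.metadata, cfg.gff], global_stage
        )
        if _done("global"):
            return self.report

        # dmr
        def dmr_stage(sdir: str) -> None:
            groups = md.loc[filtered.samples, cfg.group_column]
            strata = md.loc[filtered.samples, cfg.strata_column]
            records = permutation_pvalues(
                filtered, groups, strata, cfg.reference_group, cfg.dmr
            )
            df = records_to_frame(records)
            df.insert(0, "dmr_id", [f"dmr{i}" for i in range(len(df))])
            df.to_csv(os.path.join(sdir, "dmrs.tsv"), sep="\t", index=False)
            cand = df[df["candidate"]]
            summary = (
                direction_summary(cand["direction"]) if len(cand) else
                {"n": 0, "n_hyper": 0, "n_hypo": 0, "pct_hyper": None, "pct_hypo": None}
            )
            with open(os.path.join(sdir, "direction_summary.json"), "w") as fh:
                json.dump(summary, fh, indent=2)

        self._run_stage("dmr", [cfg.methylation_dir, cfg.metadata], dmr_stage)
        if _done("dmr"):
            return self.report
        dmrs = pd.read_csv(os.path.join(self._stage_dir("dmr"), "dmrs.tsv"), sep="\t")

        # expression
        def expression_stage(sdir: str) -> None:
            counts = pd.read_csv(cfg.counts, sep="\t", index_col=0)
            kept = filter_genes(
                counts, cfg.min_total, cfg.min_count, cfg.min_prevalence
            )
            factors = size_factors(kept, allow_pseudo_reference=True)
            factors.to_csv(os.path.join(sdir, "size_factors.tsv"), sep="\t")
            normalized = normalize_counts(kept, factors)
            normalized.to_csv(os.path.join(sdir, "normalized_counts.tsv"), sep="\t")
            groups = md.loc[kept.columns, cfg.group_column].to_numpy()
            strata = md.loc[kept.columns, cfg.strata_column].to_numpy()
            de = differential_expression(kept, factors, groups, strata, cfg.reference_group)
            de.to_csv(os.path.join(sdir, "de_results.tsv"), sep="\t")
            ma, volcano = ma_volcano_tables(de, normalized)
            ma.to_csv(os.path.join(sdir, "ma_table.tsv"), sep="\t")
            volcano.to_csv(os.path.join(sdir, "volcano_table.tsv"), sep="\t")

        self._run_stage("expression", [cfg.counts, cfg.metadata], expression_stage)
        if _done("expression"):
            return self.report

        # integrate
        def integrate_stage(sdir: str) -> None:
            cand = dmrs[dmrs["candidate"]].reset_index(drop=True)
            annotations = intersect_dmrs_features(cand, features)
            pd.DataFrame(
                [(a.dmr_id, a.gene_id, a.feature_class) for a in annotations],
                columns=["dmr_id", "gene_id", "feature_class"],
            ).to_csv(os.path.join(sdir, "annotations.tsv"), sep="\t", index=False)
            table1 = summarize_annotation(
                annotations, list(cand["dmr_id"]), cfg.geometry, genes
            )
            table1.to_csv(os.path.join(sdir, "annotation_summary.tsv"), sep="\t", index=False)
            normalized = pd.read_csv(
                os.path.join(self._stage_dir("expression"), "normalized_counts.tsv"),
                sep="\t", index_col=0,
            )
            rna = md[md["has_rna"]].index
            normalized = normalized[[c for c in normalized.columns if c in set(rna)]]
            gene_lengths = {g.gene_id: g.length for g in genes}
            links, table2 = build_links_and_summaries(
                cand, annotations, filtered, normalized, gene_lengths
            )
            links_to_frame(links).to_csv(os.path.join(sdir, "links.tsv"), sep="\t", index=False)
            table2.to_csv(os.path.join(sdir, "link_summary.tsv"), sep="\t", index=False)

        self._run_stage(
            "integrate",
            [cfg.methylation_dir, cfg.counts, cfg.metadata, cfg.gff],
            integrate_stage,
        )

        report_path = os.path.join(cfg.outdir, "run_report.json")
        with open(report_path, "w") as fh:
            json.dump(self.report, fh, indent=2, sort_keys=True)
        return self.report


def run_pipeline(config: PipelineConfig, until: str | None = None) -> dict:
    return Pipeline(config).run(until)


def _fmt(value, nd=3):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "-"
    if isinstance(value, float):
        return f"{value:.{nd}f}"
    return str(value)


def summarize_tables(outdir: str) -> str:
    """Render the annotation and correlation summaries as aligned text."""
    lines = []
    t1_path = os.path.join(outdir, "integrate", "annotation_summary.tsv")
    t2_path = os.path.join(outdir, "integrate", "link_summary.tsv")
    if not (os.path.exists(t1_path) and os.path.exists(t2_path)):
        raise FileNotFoundError("integration outputs not found; run the pipeline first")
    t1 = pd.read_csv(t1_path, sep="\t")
    lines.append("DMR annotation by genomic feature")
    lines.append(f"{'Feature':<12}{'N_A':>8}{'N_DMRs':>8}{'Density':>10}")
    for _, row in t1.iterrows():
        n_a = row["n_annotations"]
        extra = f" (+{int(row['n_a_short_genes'])})" if row.get("n_a_short_genes", 0) else ""
        lines.append(
            f"{row['feature_class']:<12}"
            f"{(_fmt(None) if pd.isna(n_a) else str(int(n_a)) + extra):>10}"
            f"{int(row['n_dmrs']):>8}{_fmt(None if pd.isna(row['density']) else row['density']):>10}"
        )
    lines.append("")
    t2 = pd.read_csv(t2_path, sep="\t")
    lines.append("DMR-gene correlation by genomic feature")
    lines.append(
        f"{'Feature':<12}{'N_A':>8}{'N_DMRs':>8}{'Signif':>8}{'Prop(%)':>9}{'Negative':>10}"
    )
    for _, row in t2.iterrows():
        lines.append(
            f"{row['feature_class']:<12}{int(row['n_annotations']):>8}"
            f"{int(row['n_dmrs']):>8}{int(row['n_significant']):>8}"
            f"{_fmt(row['proportion_significant'], 1):>9}{int(row['n_negative']):>10}"
        )
    return "\n".join(lines)
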