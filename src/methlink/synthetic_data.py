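"""Synthetic paired WGBS + RNA-seq data with planted truth.

The generator emulates the structure of a gut-epithelium methylome study:
a mostly hypermethylated CpG landscape (~78% background) with hypomethylation
dips around transcription start sites, beta-binomial sequencing counts at
~5X coverage, planted differentially methylated regions between two size
classes split over two feed pens, and negative-binomial gene counts whose
log-mean is coupled to the latent methylation of a gene feature with a
feature-dependent sign (negative near the TSS, mixed elsewhere).  Every
random draw flows from one seeded generator, so outputs are byte-identical
under a fixed seed.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genome_features import (
    FeatureGeometry,
    FeatureInterval,
    GeneModel,
    build_feature_intervals,
)
from .integration import HIERARCHY, intersect_dmrs_features
from .methylation_io import MethylationMatrix

__all__ = [
    "CouplingSpec",
    "SimConfig",
    "PlantedDmr",
    "GeneCoupling",
    "TruthTable",
    "SimGenome",
    "SimulatedDataset",
    "simulate_genome",
    "simulate_methylation",
    "simulate_expression",
    "simulate_dataset",
]


@dataclass(frozen=True)
class CouplingSpec:
    """Methylation-expression coupling for one feature class.

    ``sign`` is -1 (repressive), +1 (permissive) or 0 for mixed (each coupled
    gene draws a random sign); ``probability`` is the chance that a gene whose
    feature holds a planted DMR is coupled at all; ``strength`` is the log-mean
    shift per standard deviation of feature methylation.
    """

    sign: int
    probability: float
    strength: float


DEFAULT_COUPLING: dict[str, CouplingSpec] = {
    "P1": CouplingSpec(-1, 0.9, 1.2),
    "GS": CouplingSpec(-1, 0.9, 1.2),
    "P6": CouplingSpec(0, 0.7, 1.0),
    "GB": CouplingSpec(0, 0.7, 1.0),
    "TTR": CouplingSpec(0, 0.5, 0.8),
}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 1
    n_contigs: int = 2
    contig_length: int = 400_000
    n_genes: int = 60
    cpg_rate: float = 0.02
    background_beta: float = 0.78
    tss_dip_beta: float = 0.2
    tss_dip_halfwidth: int = 500
    coverage_mean: float = 5.0
    bb_precision: float = 30.0
    n_large: int = 10
    n_small: int = 10
    feed_split: float = 0.5
    n_rna_missing: int = 3
    n_planted_dmrs: int = 20
    planted_delta: float = 0.3
    planted_cpgs: tuple[int, int] = (8, 25)
    short_gene_fraction: float = 0.15
    coupling_table: Mapping[str, CouplingSpec] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING)
    )
    baseline_log_mean_range: tuple[float, float] = (math.log(20), math.log(2000))
    nb_dispersion: float = 0.1

    def __post_init__(self):
        for b in (self.background_beta, self.tss_dip_beta):
            if not (0 < b < 1):
                raise ValueError("beta parameters must lie in (0,1)")
        lo = self.background_beta - self.planted_delta / 2
        hi = self.background_beta + self.planted_delta / 2
        if not (0 < lo and hi < 1):
            raise ValueError("planted_delta pushes group means outside (0,1)")


@dataclass(frozen=True)
class PlantedDmr:
    contig: str
    start: int
    end: int
    n_cpgs: int
    delta: float  # large-group beta minus small-group beta
    direction: str  # hyper/hypo in the large (reference) group


@dataclass(frozen=True)
class GeneCoupling:
    gene_id: str
    feature_class: str
    sign: int  # -1 or +1 after resolving mixed classes
    strength: float


@dataclass
class TruthTable:
    planted: list[PlantedDmr]
    couplings: list[GeneCoupling]
    baseline_log_mean: dict[str, float]

    def write_jsonl(self, path: str) -> None:
        with open(path, "w") as fh:
            for d in self.planted:
                fh.write(json.dumps({"kind": "dmr", **d.__dict__}) + "\n")
            for c in self.couplings:
                fh.write(json.dumps({"kind": "coupling", **c.__dict__}) + "\n")
            for g, b in self.baseline_log_mean.items():
                fh.write(
                    json.dumps({"kind": "baseline", "gene_id": g, "log_mean": b}) + "\n"
                )


@dataclass
class SimGenome:
    genes: list[GeneModel]
    cpg_positions: dict[str, np.ndarray]
    contig_lengths: dict[str, int]
    gff_text: str


def _simulate_contig_genes(
    contig: str, length: int, n: int, config: SimConfig, rng: np.random.Generator
) -> list[tuple[int, int, str]]:
    """(start, end, strand) for n non-overlapping genes on one contig."""
    lengths = []
    for _ in range(n):
        if rng.random() < config.short_gene_fraction:
            lengths.append(int(rng.integers(600, 1400)))
        else:
            lengths.append(int(np.clip(rng.lognormal(8.3, 0.6), 1600, 25_000)))
    margin = 8000  # room for promoter/TTR windows at contig edges
    min_gap = 2000
    footprint = sum(lengths) + (n + 1) * min_gap + 2 * margin
    if footprint > length:
        raise ValueError(
            f"infeasible packing: {n} genes need {footprint} bp on a "
            f"{length} bp contig"
        )
    slack = length - footprint
    gaps = rng.dirichlet(np.ones(n + 1)) * slack
    out = []
    cursor = margin
    for i, L in enumerate(lengths):
        cursor += min_gap + int(gaps[i])
        strand = "+" if rng.random() < 0.5 else "-"
        out.append((cursor, cursor + L, strand))
        cursor += L
    return out


def _genes_to_gff(genes: list[GeneModel], contig_lengths: dict[str, int]) -> str:
    lines = ["##gff-version 3"]
    for contig, length in contig_lengths.items():
        lines.append(f"##sequence-region {contig} 1 {length}")
    for g in genes:
        lines.append(
            f"{g.contig}\tmethlink_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
            f"{g.strand}\t.\tID={g.gene_id}"
        )
    return "\n".join(lines) + "\n"


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> SimGenome:
    """Place non-overlapping genes and draw CpG positions per contig.

    CpGs follow a thinned uniform point process at ``cpg_rate`` with doubled
    density within the TSS dip window of each gene (CpG-island-like), with a
    minimum spacing of 2 bp so dinucleotides cannot overlap.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    contig_lengths = {
        f"chr{i + 1:02d}": config.contig_length for i in range(config.n_contigs)
    }
    per_contig = np.full(config.n_contigs, config.n_genes // config.n_contigs)
    per_contig[: config.n_genes % config.n_contigs] += 1

    genes: list[GeneModel] = []
    cpgs: dict[str, np.ndarray] = {}
    gi = 0
    for (contig, length), n in zip(contig_lengths.items(), per_contig):
        placed = _simulate_contig_genes(contig, length, int(n), config, rng)
        for start, end, strand in placed:
            gi += 1
            genes.append(GeneModel(f"gene{gi:04d}", contig, start, end, strand))
        n_base = rng.poisson(config.cpg_rate * length)
        pos = rng.integers(0, length - 1, size=n_base)
        extra = []
        for start, end, strand in placed:
            tss = start if strand == "+" else end - 1
            hw = config.tss_dip_halfwidth
            n_extra = rng.poisson(config.cpg_rate * 2 * hw)
            lo = max(0, tss - hw)
            hi = min(length - 1, tss + hw)
            extra.append(rng.integers(lo, hi, size=n_extra))
        pos = np.concatenate([pos] + extra)
        pos = np.unique(pos)
        keep = np.concatenate(([True], np.diff(pos) >= 2))
        cpgs[contig] = pos[keep]
    return SimGenome(genes, cpgs, contig_lengths, _genes_to_gff(genes, contig_lengths))


def _plant_dmrs(
    genome: SimGenome, config: SimConfig, rng: np.random.Generator
) -> list[PlantedDmr]:
    """Choose non-overlapping CpG runs as planted DMRs, alternating direction.

    Runs must be internally dense (no gap > 800 bp) and planted regions stay
    >= 2 kb apart so smoothing does not blur one into another.
    """
    contigs = list(genome.cpg_positions)
    planted: list[PlantedDmr] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    attempts = 0
    while len(planted) < config.n_planted_dmrs and attempts < 5000:
        attempts += 1
        contig = contigs[int(rng.integers(len(contigs)))]
        pos = genome.cpg_positions[contig]
        k = int(rng.integers(config.planted_cpgs[0], config.planted_cpgs[1] + 1))
        if len(pos) <= k:
            continue
        i = int(rng.integers(0, len(pos) - k))
        run = pos[i : i + k]
        if np.diff(run).max() > 800:
            continue
        start, end = int(run[0]), int(run[-1]) + 2
        if any(start - 2000 < e and s < end + 2000 for s, e in occupied[contig]):
            continue
        occupied[contig].append((start, end))
        direction = "hyper" if len(planted) % 2 == 0 else "hypo"
        delta = config.planted_delta if direction == "hyper" else -config.planted_delta
        planted.append(PlantedDmr(contig, start, end, k, delta, direction))
    if len(planted) < config.n_planted_dmrs:
        raise RuntimeError("could not place all planted DMRs; enlarge the genome")
    return planted


def _assign_couplings(
    genome: SimGenome,
    features: list[FeatureInterval],
    planted: list[PlantedDmr],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[GeneCoupling]:
    """Couple genes whose features hold a planted DMR, per the coupling table.

    Each gene is coupled at most once, through the highest-hierarchy feature
    class a planted DMR touches.
    """
    dmr_df = pd.DataFrame(
        {
            "dmr_id": [f"planted{i}" for i in range(len(planted))],
            "contig": [d.contig for d in planted],
            "start": [d.start for d in planted],
            "end": [d.end for d in planted],
        }
    )
    annotations = intersect_dmrs_features(dmr_df, features)
    rank = {c: i for i, c in enumerate(HIERARCHY)}
    best: dict[str, str] = {}
    for a in annotations:
        if a.gene_id not in best or rank[a.feature_class] < rank[best[a.gene_id]]:
            best[a.gene_id] = a.feature_class
    couplings = []
    for gene_id in sorted(best):
        cls = best[gene_id]
        spec = config.coupling_table.get(cls)
        if spec is None or rng.random() >= spec.probability:
            continue
        sign = spec.sign if spec.sign != 0 else (1 if rng.random() < 0.5 else -1)
        couplings.append(GeneCoupling(gene_id, cls, sign, spec.strength))
    return couplings


def _sample_metadata(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"L{i + 1:02d}" for i in range(config.n_large)] + [
        f"S{i + 1:02d}" for i in range(config.n_small)
    ]
    size_class = ["large"] * config.n_large + ["small"] * config.n_small
    feed = []
    for n in (config.n_large, config.n_small):
        n_feed1 = int(round(n * config.feed_split))
        feed += ["Feed1"] * n_feed1 + ["Feed2"] * (n - n_feed1)
    has_rna = np.ones(len(ids), dtype=bool)
    if config.n_rna_missing:
        drop = rng.choice(len(ids), size=config.n_rna_missing, replace=False)
        has_rna[drop] = False
    return pd.DataFrame(
        {"size_class": size_class, "feed": feed, "has_rna": has_rna},
        index=pd.Index(ids, name="sample_id"),
    )


def simulate_methylation(
    genome: SimGenome,
    config: SimConfig,
    truth_planted: list[PlantedDmr],
    metadata: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[MethylationMatrix, np.ndarray]:
    """Draw per-CpG per-sample counts; returns the matrix and the latent
    (read-sampling-free) methylation levels used for expression coupling.

    True beta = background, lowered to the dip level around each TSS, shifted
    by +/- planted_delta/2 per size class inside planted DMRs; the latent
    per-sample level is Beta(beta*kappa, (1-beta)*kappa) (biological
    variability), total coverage is Poisson and methylated counts binomial.
    """
    rows = []
    for contig in sorted(genome.cpg_positions):
        for p in genome.cpg_positions[contig]:
            rows.append((contig, int(p)))
    loci = pd.DataFrame(rows, columns=["contig", "position"])
    n = len(loci)
    samples = list(metadata.index)
    s = len(samples)
    large = (metadata["size_class"] == "large").to_numpy()

    base = np.full(n, config.background_beta)
    contigs = loci["contig"].to_numpy()
    positions = loci["position"].to_numpy()
    for g in genome.genes:
        in_dip = (
            (contigs == g.contig)
            & (positions >= g.tss - config.tss_dip_halfwidth)
            & (positions <= g.tss + config.tss_dip_halfwidth)
        )
        base[in_dip] = config.tss_dip_beta

    beta = np.tile(base[:, None], (1, s))
    for d in truth_planted:
        in_dmr = (
            (contigs == d.contig) & (positions >= d.start) & (positions < d.end)
        )
        beta[np.ix_(in_dmr, large)] += d.delta / 2
        beta[np.ix_(in_dmr, ~large)] -= d.delta / 2
    beta = np.clip(beta, 0.02, 0.98)

    kappa = config.bb_precision
    latent = rng.beta(beta * kappa, (1 - beta) * kappa)
    total = rng.poisson(config.coverage_mean, size=(n, s))
    meth = rng.binomial(total, latent)
    matrix = MethylationMatrix(loci, samples, meth, total, metadata)
    return matrix, latent


def simulate_expression(
    genome: SimGenome,
    features: list[FeatureInterval],
    latent: np.ndarray,
    loci: pd.DataFrame,
    config: SimConfig,
    truth: TruthTable,
    metadata: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """NB gene counts for the RNA samples, coupled to latent methylation.

    log mean = baseline + strength * sign * z(feature methylation) +
    log(sample depth factor); uncoupled genes use the baseline only.
    Couplings whose feature holds no CpG are skipped with a warning and
    removed from the truth table.
    """
    rna_samples = [s for s in metadata.index if metadata.loc[s, "has_rna"]]
    s_idx = [list(metadata.index).index(s) for s in rna_samples]
    contigs = loci["contig"].to_numpy()
    positions = loci["position"].to_numpy()

    feat_lookup = {(f.gene_id, f.feature_class): f for f in features}
    lo, hi = config.baseline_log_mean_range
    depth = rng.uniform(0.7, 1.4, size=len(rna_samples))

    coupled = {c.gene_id: c for c in truth.couplings}
    kept_couplings: list[GeneCoupling] = []
    counts = np.zeros((len(genome.genes), len(rna_samples)), dtype=np.int64)
    gene_ids = []
    for gi, gene in enumerate(genome.genes):
        gene_ids.append(gene.gene_id)
        baseline = truth.baseline_log_mean.setdefault(
            gene.gene_id, float(rng.uniform(lo, hi))
        )
        log_mean = np.full(len(rna_samples), baseline)
        c = coupled.get(gene.gene_id)
        if c is not None:
            iv = feat_lookup.get((gene.gene_id, c.feature_class))
            sel = (
                (contigs == iv.contig)
                & (positions >= iv.start)
                & (positions < iv.end)
            ) if iv is not None else np.zeros(len(loci), dtype=bool)
            if iv is None or not sel.any():
                warnings.warn(
                    f"coupled feature {gene.gene_id}/{c.feature_class} has no "
                    "CpGs; coupling skipped"
                )
            else:
                m = latent[sel][:, s_idx].mean(axis=0)
                sd = m.std()
                if sd > 0:
                    z = (m - m.mean()) / sd
                    log_mean = log_mean + c.strength * c.sign * z
                    kept_couplings.append(c)
                else:
                    warnings.warn(
                        f"feature methylation constant for {gene.gene_id}; "
                        "coupling skipped"
                    )
        mu = np.exp(log_mean) * depth
        if config.nb_dispersion > 0:
            r = 1.0 / config.nb_dispersion
            counts[gi] = rng.negative_binomial(r, r / (r + mu))
        else:
            counts[gi] = rng.poisson(mu)
    truth.couplings = kept_couplings
    return pd.DataFrame(counts, index=gene_ids, columns=rna_samples)


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: SimGenome
    features: list[FeatureInterval]
    truth: TruthTable
    metadata: pd.DataFrame
    matrix: MethylationMatrix
    latent: np.ndarray
    counts: pd.DataFrame

    def true_link_r(self, contig: str, start: int, end: int, gene_id: str) -> float:
        """Noise-free correlation between a region's methylation and a gene's
        expression driver, over the RNA samples.

        For a coupled gene the expression log-mean varies as
        sign * strength * z(coupled-feature latent methylation); the true
        link correlation is the Pearson correlation of the region's mean
        latent methylation with that driver.  Uncoupled genes return 0.
        """
        coupling = next(
            (c for c in self.truth.couplings if c.gene_id == gene_id), None
        )
        if coupling is None:
            return 0.0
        rna = [s for s in self.metadata.index if self.metadata.loc[s, "has_rna"]]
        s_idx = [list(self.metadata.index).index(s) for s in rna]
        contigs = self.matrix.loci["contig"].to_numpy()
        positions = self.matrix.loci["position"].to_numpy()
        sel = (contigs == contig) & (positions >= start) & (positions < end)
        if not sel.any():
            return float("nan")
        region_m = self.latent[sel][:, s_idx].mean(axis=0)
        iv = next(
            f for f in self.features
            if f.gene_id == gene_id and f.feature_class == coupling.feature_class
        )
        fsel = (contigs == iv.contig) & (positions >= iv.start) & (positions < iv.end)
        driver = coupling.sign * self.latent[fsel][:, s_idx].mean(axis=0)
        if region_m.std() == 0 or driver.std() == 0:
            return float("nan")
        return float(np.corrcoef(region_m, driver)[0, 1])

    def write_all(self, outdir: str) -> dict[str, str]:
        """Write GFF3, per-sample Bismark coverage, counts, metadata, truth."""
        from .methylation_io import write_coverage

        os.makedirs(outdir, exist_ok=True)
        paths = {"gff": os.path.join(outdir, "genes.gff3")}
        with open(paths["gff"], "w") as fh:
            fh.write(self.genome.gff_text)
        meth_dir = os.path.join(outdir, "methylation")
        os.makedirs(meth_dir, exist_ok=True)
        for sample in self.matrix.samples:
            write_coverage(
                self.matrix, sample, os.path.join(meth_dir, f"{sample}.cov")
            )
        paths["methylation_dir"] = meth_dir
        paths["counts"] = os.path.join(outdir, "counts.tsv")
        self.counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
        paths["metadata"] = os.path.join(outdir, "metadata.tsv")
        self.metadata.rename_axis("sample_id").to_csv(paths["metadata"], sep="\t")
        paths["truth"] = os.path.join(outdir, "truth.jsonl")
        self.truth.write_jsonl(paths["truth"])
        return paths


def simulate_dataset(
    config: SimConfig = SimConfig(), geometry: FeatureGeometry = FeatureGeometry()
) -> SimulatedDataset:
    """Full generator: genome, planted DMRs, methylomes, coupled counts."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    features = build_feature_intervals(genome.genes, geometry, genome.contig_lengths)
    planted = _plant_dmrs(genome, config, rng)
    couplings = _assign_couplings(genome, features, planted, config, rng)
    truth = TruthTable(planted, couplings, {})
    metadata = _sample_metadata(config, rng)
    matrix, latent = simulate_methylation(genome, config, planted, metadata, rng)
    counts = simulate_expression(
        genome, features, latent, matrix.loci, config, truth, metadata, rng
    )
    return SimulatedDataset(
        config, genome, features, truth, metadata, matrix, latent, counts
    )
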