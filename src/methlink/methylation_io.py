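"""Reading Bismark-style cytosine calls and assembling CpG methylation matrices.

Per-sample methylated/unmethylated counts are read from either of the two
common Bismark text dialects, destranded onto the + strand cytosine of each
CpG dinucleotide (CpG methylation is symmetric), and assembled into a
loci x samples count matrix with per-sample metadata (size class, feed pen,
RNA availability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CytosineCall",
    "MethylationMatrix",
    "read_cytosine_report",
    "merge_strands",
    "assemble_matrix",
    "filter_complete_coverage",
    "global_methylation_summary",
    "write_coverage",
    "read_metadata",
]

METADATA_COLUMNS = ("size_class", "feed")


@dataclass(frozen=True)
class CytosineCall:
    """One cytosine's methylated/unmethylated read counts (0-based position)."""

    contig: str
    position: int
    strand: str
    meth: int
    unmeth: int

    def __post_init__(self):
        if self.meth < 0 or self.unmeth < 0:
            raise ValueError(
                f"{self.contig}:{self.position}: negative count "
                f"(meth={self.meth}, unmeth={self.unmeth})"
            )

    @property
    def total(self) -> int:
        return self.meth + self.unmeth


@dataclass
class MethylationMatrix:
    """Destranded CpG loci x samples methylated/total count matrix.

    ``loci`` is a DataFrame with columns (contig, position), sorted; ``meth``
    and ``total`` are int arrays of shape (n_loci, n_samples); ``metadata``
    is indexed by sample id and carries at least size_class and feed.
    Methylation level meth/total is defined only where total > 0.
    """

    loci: pd.DataFrame
    samples: list[str]
    meth: np.ndarray
    total: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self):
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        n, s = self.meth.shape
        if self.total.shape != (n, s) or len(self.loci) != n or len(self.samples) != s:
            raise ValueError("inconsistent matrix dimensions")
        if (self.meth < 0).any() or (self.meth > self.total).any():
            raise ValueError("requires 0 <= meth <= total elementwise")
        missing = [s_ for s_ in self.samples if s_ not in self.metadata.index]
        if missing:
            raise KeyError(f"metadata missing samples: {missing}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def levels(self) -> np.ndarray:
        """meth/total with NaN where total == 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            lv = self.meth / self.total
        lv[self.total == 0] = np.nan
        return lv

    def sample_column(self, sample: str) -> int:
        return self.samples.index(sample)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: contig, position, then meth_<s>/total_<s> per sample."""
        df = self.loci.reset_index(drop=True).copy()
        for j, s in enumerate(self.samples):
            df[f"meth_{s}"] = self.meth[:, j]
            df[f"total_{s}"] = self.total[:, j]
        return df

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: pd.DataFrame) -> "MethylationMatrix":
        samples = [c[len("meth_"):] for c in df.columns if c.startswith("meth_")]
        meth = df[[f"meth_{s}" for s in samples]].to_numpy()
        total = df[[f"total_{s}" for s in samples]].to_numpy()
        return cls(df[["contig", "position"]].copy(), samples, meth, total, metadata)

    @classmethod
    def read_tsv(cls, path: str, metadata: pd.DataFrame) -> "MethylationMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t"), metadata)


def _open_lines(stream: str | IO[str] | Iterable[str]):
    if isinstance(stream, str) and "\n" not in stream and "\t" not in stream:
        fh = open(stream)
        return fh, True
    if isinstance(stream, str):
        return iter(stream.splitlines()), False
    return iter(stream), False


def read_cytosine_report(
    stream: str | IO[str] | Iterable[str], format: str = "coverage"
) -> list[CytosineCall]:
    """Read Bismark text calls; positions become 0-based.

    ``coverage``: chrom, start(1-based), end, %methylation, meth, unmeth.
    ``cytosine_report``: chrom, pos(1-based), strand, meth, unmeth, context,
    trinucleotide — only CpG-context rows are kept.
    """
    if format not in ("coverage", "cytosine_report"):
        raise ValueError(f"unknown format {format!r}")
    handle, close = _open_lines(stream)
    calls: list[CytosineCall] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if format == "coverage":
                    contig, pos1 = cols[0], int(cols[1])
                    meth, unmeth = int(cols[4]), int(cols[5])
                    strand = "+"
                else:
                    contig, pos1, strand = cols[0], int(cols[1]), cols[2]
                    meth, unmeth = int(cols[3]), int(cols[4])
                    if cols[5] != "CpG":
                        continue
            except (IndexError, ValueError) as exc:
                raise ValueError(f"line {lineno}: malformed row ({exc})") from None
            calls.append(CytosineCall(contig, pos1 - 1, strand, meth, unmeth))
    finally:
        if close:
            handle.close()
    return calls


def merge_strands(calls: Iterable[CytosineCall]) -> list[CytosineCall]:
    """Destrand CpG calls: the - strand cytosine at p+1 merges into the CpG
    anchored at the + strand position p; orphan - strand calls re-anchor to p.
    """
    merged: dict[tuple[str, int], list[int]] = {}
    for call in calls:
        anchor = call.position if call.strand == "+" else call.position - 1
        key = (call.contig, anchor)
        if key in merged:
            merged[key][0] += call.meth
            merged[key][1] += call.unmeth
        else:
            merged[key] = [call.meth, call.unmeth]
    return [
        CytosineCall(contig, pos, "+", m, u)
        for (contig, pos), (m, u) in sorted(merged.items())
    ]


def read_metadata(path: str) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, size_class, feed[, has_rna]."""
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    for col in METADATA_COLUMNS:
        if col not in md.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    if "has_rna" not in md.columns:
        md["has_rna"] = True
    md["has_rna"] = md["has_rna"].astype(bool)
    return md


def assemble_matrix(
    per_sample_calls: Mapping[str, Iterable[CytosineCall]],
    metadata: pd.DataFrame,
) -> MethylationMatrix:
    """Union destranded calls across samples into a MethylationMatrix.

    Loci absent from a sample get total = 0 there.  Duplicate positions
    within one sample are summed with a warning.
    """
    samples = list(per_sample_calls)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    missing = [s for s in samples if s not in metadata.index]
    if missing:
        raise KeyError(f"metadata missing samples: {missing}")

    per_sample: list[dict[tuple[str, int], tuple[int, int]]] = []
    loci: set[tuple[str, int]] = set()
    for s in samples:
        d: dict[tuple[str, int], tuple[int, int]] = {}
        dupes = 0
        for call in per_sample_calls[s]:
            if call.strand != "+":
                raise ValueError("assemble_matrix expects destranded (+) calls")
            key = (call.contig, call.position)
            if key in d:
                dupes += 1
                m, u = d[key]
                d[key] = (m + call.meth, u + call.unmeth)
            else:
                d[key] = (call.meth, call.unmeth)
        if dupes:
            warnings.warn(f"sample {s}: {dupes} duplicate positions summed")
        per_sample.append(d)
        loci.update(d)

    order = sorted(loci)
    meth = np.zeros((len(order), len(samples)), dtype=np.int64)
    total = np.zeros_like(meth)
    index = {key: i for i, key in enumerate(order)}
    for j, d in enumerate(per_sample):
        for key, (m, u) in d.items():
            i = index[key]
            meth[i, j] = m
            total[i, j] = m + u
    loci_df = pd.DataFrame(order, columns=["contig", "position"])
    return MethylationMatrix(loci_df, samples, meth, total, metadata)


def filter_complete_coverage(matrix: MethylationMatrix) -> MethylationMatrix:
    """Keep exactly the loci with nonzero coverage in every sample."""
    mask = (matrix.total > 0).all(axis=1)
    return MethylationMatrix(
        matrix.loci.loc[mask].reset_index(drop=True),
        list(matrix.samples),
        matrix.meth[mask],
        matrix.total[mask],
        matrix.metadata,
    )


def global_methylation_summary(matrix: MethylationMatrix) -> pd.Series:
    """Per-sample count-weighted mean methylation, sum(meth)/sum(total).

    Samples with zero total coverage get NaN rather than 0.
    """
    if matrix.n_loci == 0:
        raise ValueError("empty matrix")
    tot = matrix.total.sum(axis=0).astype(float)
    meth = matrix.meth.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        level = meth / tot
    level[tot == 0] = np.nan
    return pd.Series(level, index=matrix.samples, name="mean_methylation")


def write_coverage(matrix: MethylationMatrix, sample: str, path: str) -> None:
    """Write one sample's covered loci in Bismark coverage format (1-based)."""
    j = matrix.sample_column(sample)
    mask = matrix.total[:, j] > 0
    with open(path, "w") as fh:
        for (contig, pos), m, t in zip(
            matrix.loci.loc[mask].itertuples(index=False),
            matrix.meth[mask, j],
            matrix.total[mask, j],
        ):
            pct = 100.0 * m / t
            fh.write(f"{contig}\t{pos + 1}\t{pos + 1}\t{pct:.6g}\t{m}\t{t - m}\n")
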