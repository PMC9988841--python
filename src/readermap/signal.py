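"""Signal-level association: BPM normalization, percentile extraction over
merged peaks, input normalization with log/Z transform, Pearson matrix and
complete-linkage clustering."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import GenomicInterval, SignalTrack

logger = logging.getLogger("readermap")

STATES = ("raw95", "inputNorm", "logZ")


@dataclass
class SignalVector:
    """Per-locus summary signal of one sample over a fixed locus list."""

    sample: str
    values: np.ndarray
    state: str = "raw95"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")

    def __len__(self) -> int:
        return len(self.values)


def bpm_normalize(track: SignalTrack, chrom_lengths: dict[str, int],
                  bin_size: int = 20) -> SignalTrack:
    """Bins-per-million normalization at ``bin_size`` resolution.

    Mean per-base coverage is computed for each bin and all bins are scaled
    so their genome-wide sum is 1e6.
    """
    if track.normalization == "BPM":
        raise ValueError("track already BPM-normalized")
    bins: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    total = 0.0
    for chrom, length in sorted(chrom_lengths.items()):
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        vals = track.window_means(chrom, starts, ends)
        bins[chrom] = (starts, ends, vals)
        total += vals.sum()
    if total <= 0:
        raise ValueError("empty coverage: cannot BPM-normalize an all-zero track")
    scale = 1e6 / total
    runs = {chrom: (s, e, v * scale) for chrom, (s, e, v) in bins.items()}
    return SignalTrack(runs, normalization="BPM")


def percentile_signal(track: SignalTrack, loci: list[GenomicInterval],
                      sample: str = "", q: float = 95.0) -> SignalVector:
    """q-th percentile of per-base signal over each locus (linear interpolation).

    Loci outside covered runs score 0 (implicit-zero convention).
    """
    values = np.empty(len(loci))
    for i, iv in enumerate(loci):
        if len(iv) == 0:
            raise ValueError(f"zero-length locus {iv.chrom}:{iv.start}")
        per_base = track.per_base(iv.chrom, iv.start, iv.end)
        values[i] = np.percentile(per_base, q, method="linear")
    return SignalVector(sample, values, "raw95")


def input_normalize_log_z(signal: SignalVector, control: SignalVector,
                          pseudocount: float = 1.0) -> SignalVector:
    """log2((signal+eps)/(input+eps)), then standardized to Z-scores."""
    if len(signal) != len(control):
        raise ValueError("signal and input cover different locus lists")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = np.log2((signal.values + pseudocount) / (control.values + pseudocount))
    sd = x.std()
    if sd == 0:
        raise ValueError(f"degenerate signal (zero variance) for {signal.sample}")
    z = (x - x.mean()) / sd
    return SignalVector(signal.sample, z, "logZ")


def pearson_matrix(vectors: list[SignalVector]) -> tuple[np.ndarray, list[str]]:
    """Pairwise Pearson correlation matrix of log-Z signal vectors."""
    if len(vectors) < 2:
        raise ValueError("need at least two vectors")
    n = len(vectors[0])
    if n < 3:
        raise ValueError("need at least 3 loci")
    for v in vectors:
        if len(v) != n:
            raise ValueError(f"length mismatch for {v.sample}")
        if v.state != "logZ":
            raise ValueError(f"{v.sample} not in logZ state")
    mat = np.corrcoef(np.vstack([v.values for v in vectors]))
    return mat, [v.sample for v in vectors]


def hcluster(corr: np.ndarray, labels: list[str], method: str = "complete"
             ) -> tuple[np.ndarray, list[str], str]:
    """Hierarchical clustering on distance 1 - r.

    Returns (scipy linkage matrix, leaf order labels, Newick string).
    """
    corr = np.asarray(corr, dtype=float)
    if corr.shape[0] != corr.shape[1] or not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    condensed = squareform((dist + dist.T) / 2, checks=False)
    link = hierarchy.linkage(condensed, method=method)
    order = [labels[i] for i in hierarchy.leaves_list(link)]
    return link, order, linkage_to_newick(link, labels)


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree with merge heights."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = link[i - n]
        heights[i] = h
        la = node(int(a))
        lb = node(int(b))
        ba = h - heights[int(a)]
        bb = h - heights[int(b)]
        return f"({la}:{ba:g},{lb}:{bb:g})"

    return node(n + len(link) - 1) + ";"


def write_corr_tsv(mat: np.ndarray, labels: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, mat):
            fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
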