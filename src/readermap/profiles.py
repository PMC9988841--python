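"""Reference-point profile matrices, minimal-k homogeneity clustering and
per-row coverage calls.

A profile matrix has one row per peak, centered on the peak's reference
point (summit if available, else midpoint), with 20-bp bins spanning +/-3 kb
by default (300 columns).  Coverage calls compare the central signal of
each row against a genome-wide background level and feed the heatmap
criterion of the graded-occupancy classifier.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .core import PeakSet, SignalTrack

logger = logging.getLogger("readermap")


@dataclass
class ProfileMatrix:
    values: np.ndarray           # peaks x bins
    peak_ids: list[str]
    flank: int = 3000
    bin_size: int = 20
    truncated: np.ndarray = field(default=None)  # rows clipped at chromosome edges

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.truncated is None:
            self.truncated = np.zeros(len(self.values), dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def write_tsv_gz(self, path) -> None:
        header = {"peaks": len(self.peak_ids), "flank": self.flank,
                  "bin_size": self.bin_size}
        with gzip.open(path, "wt") as fh:
            fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
            for pid, row in zip(self.peak_ids, self.values):
                fh.write(pid + "\t" + "\t".join(f"{v:.4g}" for v in row) + "\n")


@dataclass
class CoverageCall:
    covered: np.ndarray        # per-row flags
    covered_count: int
    n_rows: int
    heatmap_overlap_detected: bool
    background: float
    fold: float
    row_fraction: float


def compute_matrix(track: SignalTrack, peaks: PeakSet,
                   chrom_lengths: dict[str, int] | None = None,
                   flank: int = 3000, bin_size: int = 20,
                   smooth_length: int | None = None) -> ProfileMatrix:
    """Mean signal in ``bin_size`` windows around each peak's reference point.

    Windows extending past chromosome bounds are zero-padded and the row is
    flagged truncated.  ``smooth_length`` (a multiple of ``bin_size``)
    applies a centered moving average over ``smooth_length/bin_size`` bins.
    """
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    offsets = np.arange(n_bins, dtype=np.int64) * bin_size - flank
    values = np.zeros((len(peaks), n_bins))
    truncated = np.zeros(len(peaks), dtype=bool)
    for i, iv in enumerate(peaks):
        c = iv.reference_point
        starts = c + offsets
        ends = starts + bin_size
        length = chrom_lengths.get(iv.chrom) if chrom_lengths else None
        lo = np.maximum(starts, 0)
        hi = np.minimum(ends, length) if length is not None else ends
        valid = lo < hi
        if not valid.all():
            truncated[i] = True
        row = np.zeros(n_bins)
        means = track.window_means(iv.chrom, lo[valid], hi[valid])
        # zero-padded edge bins keep full bin_size denominator
        row[valid] = means * (hi[valid] - lo[valid]) / bin_size
        values[i] = row
    if smooth_length:
        w = max(1, smooth_length // bin_size)
        kernel = np.ones(w) / w
        values = np.apply_along_axis(
            lambda r: np.convolve(r, kernel, mode="same"), 1, values)
    ids = [iv.name or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in peaks]
    return ProfileMatrix(values, ids, flank, bin_size, truncated)


def _mean_pairwise_cosine(rows: np.ndarray) -> float:
    """Mean cosine similarity over distinct row pairs (zero rows score 0)."""
    n = len(rows)
    if n < 2:
        return 1.0
    norms = np.linalg.norm(rows, axis=1)
    unit = np.divide(rows, norms[:, None], out=np.zeros_like(rows),
                     where=norms[:, None] > 0)
    s = unit.sum(axis=0)
    total = float(s @ s) - float((unit * unit).sum())
    return total / (n * (n - 1))


def kmeans_min_k(matrix: ProfileMatrix, ks: tuple[int, ...] = (1, 2, 3),
                 theta_h: float = 0.8, seed: int = 0
                 ) -> tuple[int, np.ndarray, dict[int, float]]:
    """Smallest k whose k-means clustering is homogeneous.

    Rows are scaled by their maximum before clustering (shape- rather than
    amplitude-driven clusters).  A clustering is homogeneous when every
    cluster's mean pairwise cosine similarity of raw profiles is >= theta_h.
    Returns (chosen k, row labels, homogeneity score per k).
    """
    rows = matrix.values
    if len(rows) < 10:
        raise ValueError("need at least 10 rows for profile clustering")
    row_max = rows.max(axis=1, keepdims=True)
    scaled = np.divide(rows, row_max, out=np.zeros_like(rows), where=row_max > 0)
    scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in sorted(ks):
        if k > len(rows):
            logger.warning("skipping k=%d: fewer rows than clusters", k)
            continue
        if k == 1:
            labels = np.zeros(len(rows), dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            labels = km.fit_predict(scaled)
        worst = min(_mean_pairwise_cosine(rows[labels == c]) for c in range(k))
        scores[k] = worst
        labelings[k] = labels
        if worst >= theta_h:   # minimal homogeneous k
            return k, labels, scores
    k = max(labelings)
    logger.warning("no homogeneous clustering found; using k=%d", k)
    return k, labelings[k], scores


def track_background(track: SignalTrack, chrom_lengths: dict[str, int],
                     bin_size: int = 20) -> float:
    """Background level: median of genome-wide per-bin mean signal.

    Falls back to the genome-wide mean when the median is 0 (very sparse
    tracks), so the coverage threshold never degenerates to 0.
    """
    vals = []
    for chrom, length in sorted(chrom_lengths.items()):
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        vals.append(track.window_means(chrom, starts, ends))
    vals = np.concatenate(vals)
    med = float(np.median(vals))
    if med > 0:
        return med
    mean = float(vals.mean())
    logger.warning("zero median background; falling back to mean %.4g", mean)
    return mean


def coverage_call(matrix: ProfileMatrix, background: float, fold: float = 2.0,
                  row_fraction: float = 0.5, core_halfwidth: int = 500) -> CoverageCall:
    """Per-row covered calls and the pair-level heatmap-overlap flag.

    A row is covered when its mean signal over the central +/-core_halfwidth
    window exceeds ``background * fold``; the pair-level flag fires when the
    covered fraction is >= ``row_fraction``.
    """
    n_core = core_halfwidth // matrix.bin_size
    center = matrix.n_bins // 2
    core = matrix.values[:, center - n_core:center + n_core]
    covered = core.mean(axis=1) > background * fold
    count = int(covered.sum())
    n = len(covered)
    flag = n > 0 and count / n >= row_fraction
    return CoverageCall(covered, count, n, flag, background, fold, row_fraction)
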