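"""ChIP-seq dataset quality statistics: FRiP, strand cross-correlation
profile, fragment-length estimate, NSC and RSC.

The cross-correlation profile correlates the + strand 5'-end occupancy
vector with the - strand vector shifted left by delta; real libraries show
a peak at the fragment length and (from mapping artifacts) a "phantom" peak
at the read length.  NSC contrasts the fragment-length peak with the
profile background; RSC contrasts it with the phantom peak.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import GenomicInterval, PeakSet, merge_intervals

logger = logging.getLogger("readermap")


@dataclass
class ReadSet:
    """Single-end reads as 5' positions per strand and chromosome."""

    positions: dict[str, dict[str, np.ndarray]]  # chrom -> {"+": pos, "-": pos}
    read_length: int

    def __post_init__(self) -> None:
        for chrom, strands in self.positions.items():
            for strand in ("+", "-"):
                strands[strand] = np.asarray(strands.get(strand, []), dtype=np.int64)

    @property
    def n_reads(self) -> int:
        return sum(len(s["+"]) + len(s["-"]) for s in self.positions.values())

    @classmethod
    def from_bed(cls, path, read_length: int) -> "ReadSet":
        """BED6 of reads; the 5' end is start for +, end-1 for - records."""
        pos: dict[str, dict[str, list[int]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                p = line.rstrip("\n").split("\t")
                chrom, start, end = p[0], int(p[1]), int(p[2])
                strand = p[5] if len(p) > 5 else "+"
                d = pos.setdefault(chrom, {"+": [], "-": []})
                d[strand].append(start if strand == "+" else end - 1)
        return cls({c: {s: np.array(v) for s, v in d.items()} for c, d in pos.items()},
                   read_length)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.positions):
                for strand in ("+", "-"):
                    for p in self.positions[chrom][strand]:
                        if strand == "+":
                            s, e = p, p + self.read_length
                        else:
                            s, e = p - self.read_length + 1, p + 1
                        fh.write(f"{chrom}\t{max(0, s)}\t{e}\t.\t0\t{strand}\n")


@dataclass
class QCReport:
    frip: float | None
    cc_profile: np.ndarray
    frag_len_estimate: int
    nsc: float
    rsc: float
    rsc_unsubtracted: float
    read_length: int

    def to_dict(self) -> dict:
        return {"frip": self.frip, "frag_len_estimate": self.frag_len_estimate,
                "nsc": self.nsc, "rsc": self.rsc,
                "rsc_unsubtracted": self.rsc_unsubtracted,
                "read_length": self.read_length}


def frip(reads: ReadSet, peaks: PeakSet) -> float:
    """Fraction of reads whose 5' position falls inside any peak."""
    n = reads.n_reads
    if n == 0:
        raise ValueError("read set is empty")
    merged = merge_intervals(list(peaks))
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, ([], []))
        by_chrom[iv.chrom][0].append(iv.start)
        by_chrom[iv.chrom][1].append(iv.end)
    inside = 0
    for chrom, strands in reads.positions.items():
        if chrom not in by_chrom:
            continue
        starts = np.array(by_chrom[chrom][0])
        ends = np.array(by_chrom[chrom][1])
        for strand in ("+", "-"):
            pos = strands[strand]
            if len(pos) == 0:
                continue
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
            inside += int(ok.sum())
    return inside / n


def cross_correlation_profile(reads: ReadSet, chrom_lengths: dict[str, int],
                              max_shift: int = 400, binarize: bool = True
                              ) -> np.ndarray:
    """Pearson correlation of strand occupancy vectors per shift 0..max_shift.

    Per chromosome the - strand vector is shifted left by delta and
    correlated with the + strand vector; chromosome profiles are averaged
    weighted by length.  With ``binarize`` each position scores 1 when >= 1
    read 5' end falls on it, else the raw count.
    """
    profiles = []
    weights = []
    for chrom, length in sorted(chrom_lengths.items()):
        strands = reads.positions.get(chrom)
        if strands is None:
            continue
        if len(strands["+"]) == 0 or len(strands["-"]) == 0:
            raise ValueError(f"{chrom}: reads on a single strand only")
        if max_shift >= length:
            raise ValueError(f"max_shift {max_shift} >= chromosome length {length}")
        x = np.bincount(strands["+"], minlength=length).astype(np.float64)
        y = np.bincount(strands["-"], minlength=length).astype(np.float64)
        if binarize:
            x = (x > 0).astype(np.float64)
            y = (y > 0).astype(np.float64)
        cum_x = np.concatenate([[0.0], np.cumsum(x)])
        cum_y = np.concatenate([[0.0], np.cumsum(y)])
        cum_x2 = np.concatenate([[0.0], np.cumsum(x * x)])
        cum_y2 = np.concatenate([[0.0], np.cumsum(y * y)])
        prof = np.empty(max_shift + 1)
        for delta in range(max_shift + 1):
            n = length - delta
            sxy = float(x[:n] @ y[delta:])
            sx, sy = cum_x[n], cum_y[length] - cum_y[delta]
            sxx = cum_x2[n]
            syy = cum_y2[length] - cum_y2[delta]
            var_x = sxx - sx * sx / n
            var_y = syy - sy * sy / n
            if var_x <= 0 or var_y <= 0:
                prof[delta] = 0.0
            else:
                prof[delta] = (sxy - sx * sy / n) / math.sqrt(var_x * var_y)
        profiles.append(prof)
        weights.append(length)
    if not profiles:
        raise ValueError("no reads on any chromosome in the manifest")
    w = np.array(weights, dtype=float)
    return np.average(np.vstack(profiles), axis=0, weights=w)


def nsc_rsc(cc_profile: np.ndarray, read_len: int, exclusion_halfwidth: int = 10
            ) -> tuple[float, float, int, float]:
    """(NSC, RSC, fragment-length estimate, background-free RSC).

    Background b = profile minimum; cc_frag = maximum outside the phantom
    exclusion zone [read_len - hw, read_len + hw]; cc_read = profile at the
    read length.  NSC = cc_frag / b; RSC = (cc_frag - b) / (cc_read - b).
    """
    prof = np.asarray(cc_profile, dtype=float)
    if len(prof) <= read_len:
        raise ValueError("profile must extend past the read length")
    b = float(prof.min())
    shifts = np.arange(len(prof))
    mask = np.abs(shifts - read_len) > exclusion_halfwidth
    frag_len = int(shifts[mask][np.argmax(prof[mask])])
    cc_frag = float(prof[frag_len])
    cc_read = float(prof[read_len])
    if b <= 0:
        logger.warning("non-positive background correlation (%.4g); NSC unstable", b)
        nsc = math.inf if cc_frag > 0 else 1.0
    else:
        nsc = cc_frag / b
    if cc_read - b <= 0:
        logger.warning("phantom peak at background level; RSC reported as +inf")
        rsc = math.inf
    else:
        rsc = (cc_frag - b) / (cc_read - b)
    rsc_plain = cc_frag / cc_read if cc_read > 0 else math.inf
    return nsc, rsc, frag_len, rsc_plain


def qc_report(reads: ReadSet, chrom_lengths: dict[str, int],
              peaks: PeakSet | None = None, max_shift: int = 400,
              binarize: bool = True, exclusion_halfwidth: int = 10) -> QCReport:
    prof = cross_correlation_profile(reads, chrom_lengths, max_shift, binarize)
    nsc, rsc, frag_len, rsc_plain = nsc_rsc(prof, reads.read_length, exclusion_halfwidth)
    f = frip(reads, peaks) if peaks is not None else None
    return QCReport(f, prof, frag_len, nsc, rsc, rsc_plain, reads.read_length)
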