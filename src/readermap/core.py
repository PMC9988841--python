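"""Genomic primitives: intervals, peak sets, signal tracks, chromosome domains.

Coordinates are 0-based half-open (BED convention) everywhere.  GFF3 input
is converted on read.  Strand is ignored for overlap computations; promoter
windows are strand-aware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("readermap")

STAGES = ("E", "L", "A")  # embryo, larva, adult sample tags


class ParseError(ValueError):
    """Malformed record in a genomic text file."""


# ---------------------------------------------------------------------------
# interval types
# ---------------------------------------------------------------------------

@dataclass
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome.

    ``summit`` is an optional absolute position (narrowPeak summit); when
    present it overrides the midpoint as the peak's reference point.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."
    summit: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def reference_point(self) -> int:
        """Summit if recorded, else the interval midpoint."""
        return self.summit if self.summit is not None else self.midpoint

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class PeakSet:
    """Peaks of one factor at one developmental stage, sorted by position."""

    sample: str
    intervals: list[GenomicInterval]
    stage: str = "A"

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def merged(self) -> "PeakSet":
        return PeakSet(self.sample, merge_intervals(self.intervals), self.stage)


@dataclass
class ChromosomeDomains:
    """Per-chromosome arm/center partition.

    Each chromosome of length L splits into leftArm [0, a), center [a, b)
    and rightArm [b, L); the three segments tile the chromosome exactly.
    """

    boundaries: dict[str, tuple[int, int, int]]  # chrom -> (a, b, L)

    def __post_init__(self) -> None:
        for chrom, (a, b, length) in self.boundaries.items():
            if not (0 < a < b < length):
                raise ValueError(f"{chrom}: need 0 < a < b < L, got a={a} b={b} L={length}")

    def chroms(self) -> list[str]:
        return sorted(self.boundaries)

    def segments(self, chrom: str) -> list[tuple[str, int, int]]:
        a, b, length = self.boundaries[chrom]
        return [("arm", 0, a), ("center", a, b), ("arm", b, length)]

    def classify(self, chrom: str, pos: int) -> str:
        """Domain class ('arm' or 'center') containing position ``pos``."""
        if chrom not in self.boundaries:
            raise KeyError(f"no domain coordinates for chromosome {chrom!r}")
        a, b, _ = self.boundaries[chrom]
        return "center" if a <= pos < b else "arm"

    def segment_containing(self, chrom: str, pos: int) -> tuple[str, int, int]:
        for cls, s, e in self.segments(chrom):
            if s <= pos < e:
                return cls, s, e
        raise ValueError(f"position {chrom}:{pos} outside chromosome bounds")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ChromosomeDomains":
        """Read a `chrom  armEnd  centerEnd  length` table (header optional)."""
        bounds = {}
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "chrom\t")):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 4:
                    raise ParseError(f"{path}:{i}: expected 4 columns")
                bounds[parts[0]] = (int(parts[1]), int(parts[2]), int(parts[3]))
        return cls(bounds)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tarmEnd\tcenterEnd\tlength\n")
            for chrom in self.chroms():
                a, b, length = self.boundaries[chrom]
                fh.write(f"{chrom}\t{a}\t{b}\t{length}\n")


@dataclass
class GeneModel:
    """Gene with TSS, exons and a derived strand-aware promoter window."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    promoter_upstream: int = 1000
    promoter_downstream: int = 100

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    @property
    def promoter(self) -> tuple[int, int]:
        """[TSS-up, TSS+down) on the gene's strand, clamped at 0."""
        if self.strand == "+":
            lo, hi = self.tss - self.promoter_upstream, self.tss + self.promoter_downstream
        else:
            lo, hi = self.tss - self.promoter_downstream + 1, self.tss + self.promoter_upstream + 1
        return max(0, lo), max(1, hi)

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.gene_id,
                               strand=self.strand)


@dataclass
class ActivityCall:
    gene_id: str
    fpkm: float
    label: str  # active | silent | unclassified


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, fmt: str = "bed", sample: str | None = None,
                   stage: str = "A") -> PeakSet:
    """Read a BED6 or ENCODE narrowPeak file into a sorted :class:`PeakSet`.

    Records with start >= end are rejected with a logged warning; otherwise
    malformed lines raise :class:`ParseError` naming the line number.
    """
    if fmt not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown format {fmt!r}")
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed record: {exc}") from exc
            if start >= end:
                logger.warning("%s:%d: rejected record with start >= end (%d >= %d)",
                               path, lineno, start, end)
                continue
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-." else "."
            summit = None
            if fmt == "narrowPeak":
                if len(parts) < 10:
                    raise ParseError(f"{path}:{lineno}: narrowPeak needs 10 columns")
                offset = int(parts[9])
                if offset >= 0:
                    summit = start + offset
            intervals.append(GenomicInterval(chrom, start, end, name, score, strand, summit))
    return PeakSet(sample or path.stem, intervals, stage)


def write_bed(peaks: PeakSet | list[GenomicInterval], path: str | Path) -> None:
    items = peaks.intervals if isinstance(peaks, PeakSet) else peaks
    with open(path, "w") as fh:
        for iv in items:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n")


def write_narrowpeak(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            summit = iv.summit - iv.start if iv.summit is not None else -1
            score = 0 if iv.score is None else iv.score
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score:g}\t"
                     f"{iv.strand}\t0\t-1\t-1\t{summit}\n")


def read_gene_models(path: str | Path, fmt: str = "bed12", **promoter_kw) -> list[GeneModel]:
    """Read gene models from BED12 or GFF3-lite (gene + exon records)."""
    path = Path(path)
    genes: list[GeneModel] = []
    if fmt == "bed12":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                p = line.rstrip("\n").split("\t")
                if len(p) < 12:
                    raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns")
                chrom, start = p[0], int(p[1])
                sizes = [int(x) for x in p[10].rstrip(",").split(",")]
                starts = [int(x) for x in p[11].rstrip(",").split(",")]
                exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
                genes.append(GeneModel(p[3], chrom, p[5], exons, **promoter_kw))
    elif fmt == "gff3":
        exons_by_gene: dict[str, list[tuple[int, int]]] = {}
        meta: dict[str, tuple[str, str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                p = line.rstrip("\n").split("\t")
                if len(p) < 9:
                    raise ParseError(f"{path}:{lineno}: GFF3 needs 9 columns")
                attrs = dict(kv.split("=", 1) for kv in p[8].split(";") if "=" in kv)
                # GFF3 is 1-based inclusive -> 0-based half-open
                start, end = int(p[3]) - 1, int(p[4])
                if p[2] == "gene":
                    meta[attrs["ID"]] = (p[0], p[6])
                elif p[2] == "exon":
                    exons_by_gene.setdefault(attrs["Parent"], []).append((start, end))
        for gid, exons in exons_by_gene.items():
            chrom, strand = meta[gid]
            genes.append(GeneModel(gid, chrom, strand, exons, **promoter_kw))
    else:
        raise ValueError(f"unknown gene model format {fmt!r}")
    return genes


def read_fpkm_table(path: str | Path) -> dict[str, float]:
    """Read a two-column `gene_id  FPKM` TSV (header optional)."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0].lower() in ("gene", "gene_id"):
                continue
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            table[parts[0]] = float(parts[1])
    return table


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

class SignalTrack:
    """Piecewise-constant per-base coverage; uncovered bases are 0.

    Runs are stored per chromosome as parallel (starts, ends, values) arrays,
    non-overlapping and sorted.  ``normalization`` is 'raw' or 'BPM'.
    """

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 normalization: str = "raw"):
        self.runs = {}
        for chrom, (s, e, v) in runs.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=np.float64)
            if np.any(e <= s):
                raise ValueError(f"{chrom}: runs must have start < end")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"{chrom}: runs overlap or are unsorted")
            if np.any(v < 0):
                raise ValueError(f"{chrom}: negative signal values")
            self.runs[chrom] = (s, e, v)
        self.normalization = normalization
        self._cum: dict[str, np.ndarray] = {}

    def chroms(self) -> list[str]:
        return sorted(self.runs)

    def total(self) -> float:
        """Integral of the track: sum of value x run length over all runs."""
        return float(sum(((e - s) * v).sum() for s, e, v in self.runs.values()))

    def _cumulative(self, chrom: str) -> np.ndarray:
        if chrom not in self._cum:
            s, e, v = self.runs[chrom]
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum((e - s) * v)])
        return self._cum[chrom]

    def integral(self, chrom: str, a: int, b: int) -> float:
        """Integral of signal over [a, b) (0 where the track is undefined)."""
        if chrom not in self.runs or b <= a:
            return 0.0
        s, e, v = self.runs[chrom]
        cum = self._cumulative(chrom)
        i = int(np.searchsorted(e, a, side="right"))
        j = int(np.searchsorted(s, b, side="left"))
        if i >= j:
            return 0.0
        full = cum[j] - cum[i]
        # trim partial overlap at the two edge runs
        left_trim = max(0, a - s[i]) * v[i]
        right_trim = max(0, e[j - 1] - b) * v[j - 1]
        return float(full - left_trim - right_trim)

    def mean(self, chrom: str, a: int, b: int) -> float:
        """Mean per-base signal over [a, b), counting uncovered bases as 0."""
        if b <= a:
            raise ValueError("empty window")
        return self.integral(chrom, a, b) / (b - a)

    def window_means(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`mean` over many windows (clipped lengths)."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out = np.zeros(len(starts))
        if chrom not in self.runs:
            return out
        s, e, v = self.runs[chrom]
        cum = self._cumulative(chrom)
        i = np.searchsorted(e, starts, side="right")
        j = np.searchsorted(s, ends, side="left")
        has = i < j
        ih, jh = i[has], j[has]
        full = cum[jh] - cum[ih]
        left = np.maximum(0, starts[has] - s[ih]) * v[ih]
        right = np.maximum(0, e[jh - 1] - ends[has]) * v[jh - 1]
        out[has] = full - left - right
        return out / np.maximum(1, ends - starts)

    def per_base(self, chrom: str, a: int, b: int) -> np.ndarray:
        """Per-base values over [a, b) with implicit zeros."""
        out = np.zeros(b - a)
        if chrom not in self.runs:
            return out
        s, e, v = self.runs[chrom]
        i = int(np.searchsorted(e, a, side="right"))
        j = int(np.searchsorted(s, b, side="left"))
        for k in range(i, j):
            lo, hi = max(s[k], a), min(e[k], b)
            out[lo - a:hi - a] = v[k]
        return out

    @classmethod
    def read_bedgraph(cls, path: str | Path, normalization: str = "raw") -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                p = line.rstrip("\n").split("\t")
                if len(p) < 4:
                    raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
                by_chrom.setdefault(p[0], []).append((int(p[1]), int(p[2]), float(p[3])))
        runs = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            arr = np.array(recs, dtype=float)
            runs[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
        return cls(runs, normalization)

    def write_bedgraph(self, path: str | Path, skip_zero: bool = True) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms():
                s, e, v = self.runs[chrom]
                for si, ei, vi in zip(s, e, v):
                    if skip_zero and vi == 0:
                        continue
                    fh.write(f"{chrom}\t{si}\t{ei}\t{vi:g}\n")


# ---------------------------------------------------------------------------
# interval algebra & annotation
# ---------------------------------------------------------------------------

def merge_intervals(*interval_lists: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of one or more interval lists as minimal disjoint sorted intervals.

    Book-ended intervals ([0,10) and [10,20)) merge.
    """
    pool = [iv for lst in interval_lists for iv in lst]
    if not pool:
        return []
    pool.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = pool[0].chrom, pool[0].start, pool[0].end
    for iv in pool[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


def partition_by_domain(peaks: PeakSet, domains: ChromosomeDomains
                        ) -> tuple[dict[str, PeakSet], dict[str, float]]:
    """Split peaks into arm/center sets by midpoint; conserves counts exactly.

    Returns ({'arm': PeakSet, 'center': PeakSet}, {'arm': frac, 'center': frac}).
    """
    buckets: dict[str, list[GenomicInterval]] = {"arm": [], "center": []}
    for iv in peaks:
        buckets[domains.classify(iv.chrom, iv.midpoint)].append(iv)
    total = len(peaks)
    sets = {cls: PeakSet(peaks.sample, lst, peaks.stage) for cls, lst in buckets.items()}
    fracs = {cls: (len(lst) / total if total else 0.0) for cls, lst in buckets.items()}
    return sets, fracs


FEATURE_PRIORITY = ("promoter", "exon", "intron", "intergenic")


def assign_feature(peaks: PeakSet, genes: list[GeneModel]
                   ) -> tuple[list[str], dict[str, float]]:
    """Label each peak's reference point promoter/exon/intron/intergenic.

    Priority promoter > exon > intron; labels partition the peak set and the
    summary fractions sum to 1.
    """
    by_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for g in genes:
        d = by_chrom.setdefault(g.chrom, {"promoter": [], "exon": [], "intron": []})
        d["promoter"].append(g.promoter)
        d["exon"].extend(g.exons)
        d["intron"].extend(g.introns)
    index: dict[str, dict[str, tuple[np.ndarray, np.ndarray, int]]] = {}
    for chrom, feats in by_chrom.items():
        index[chrom] = {}
        for feat, ivs in feats.items():
            ivs.sort()
            arr = np.array(ivs, dtype=np.int64).reshape(-1, 2)
            max_len = int((arr[:, 1] - arr[:, 0]).max()) if len(arr) else 0
            index[chrom][feat] = (arr[:, 0], arr[:, 1], max_len)

    def _hits(chrom: str, feat: str, pos: int) -> bool:
        if chrom not in index or len(index[chrom][feat][0]) == 0:
            return False
        starts, ends, max_len = index[chrom][feat]
        k = int(np.searchsorted(starts, pos, side="right"))
        # features of different genes may overlap; scan back no further than
        # the longest feature could reach
        for m in range(k - 1, -1, -1):
            if ends[m] > pos:
                return True
            if pos - starts[m] >= max_len:
                break
        return False

    labels = []
    for iv in peaks:
        pos = iv.reference_point
        for feat in ("promoter", "exon", "intron"):
            if _hits(iv.chrom, feat, pos):
                labels.append(feat)
                break
        else:
            labels.append("intergenic")
    n = len(labels)
    fracs = {feat: (labels.count(feat) / n if n else 0.0) for feat in FEATURE_PRIORITY}
    return labels, fracs


def classify_gene_activity(fpkm: dict[str, float],
                           euchromatin_occupied: dict[str, bool],
                           heterochromatin_occupied: dict[str, bool]
                           ) -> list[ActivityCall]:
    """Call genes active / silent / unclassified.

    active: FPKM >= 1 and occupied by any euchromatin mark;
    silent: FPKM < 1 and occupied by any heterochromatin mark.
    Genes absent from the FPKM table get FPKM 0 (logged).
    """
    gene_ids = sorted(set(fpkm) | set(euchromatin_occupied) | set(heterochromatin_occupied))
    calls = []
    for gid in gene_ids:
        if gid not in fpkm:
            logger.warning("gene %s missing from FPKM table; treated as 0", gid)
        value = fpkm.get(gid, 0.0)
        if value < 0:
            raise ValueError(f"negative FPKM for gene {gid}: {value}")
        eu = euchromatin_occupied.get(gid, False)
        het = heterochromatin_occupied.get(gid, False)
        if value >= 1 and eu:
            label = "active"
        elif value < 1 and het:
            label = "silent"
        else:
            label = "unclassified"
        calls.append(ActivityCall(gid, value, label))
    return calls


def repeat_family_overlap(peaks: PeakSet, repeats: list[GenomicInterval]
                          ) -> tuple[dict[str, int], float]:
    """Per-family counts of peaks overlapping >=1 repeat, and the fraction of
    peaks overlapping >=1 repeat of any family.

    Repeat family is taken from the interval name.  A peak overlapping two
    families counts once per family but once overall.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for rep in repeats:
        by_chrom.setdefault(rep.chrom, []).append(rep)
    for lst in by_chrom.values():
        lst.sort(key=lambda iv: iv.start)

    family_counts: dict[str, int] = {}
    for rep in repeats:
        family_counts.setdefault(rep.name or "unknown", 0)
    n_any = 0
    for iv in peaks:
        fams = set()
        for rep in by_chrom.get(iv.chrom, []):
            if rep.start >= iv.end:
                break
            if rep.end > iv.start:
                fams.add(rep.name or "unknown")
        if fams:
            n_any += 1
        for fam in fams:
            family_counts[fam] += 1
    frac = n_any / len(peaks) if len(peaks) else 0.0
    return family_counts, frac
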