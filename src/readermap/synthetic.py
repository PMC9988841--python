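"""Synthetic domain-structured genomes with marks, coupled readers and reads.

The generator emulates a small nematode-like genome: each chromosome is
split into two arms and a center; heterochromatin-type marks are laid down
as dispersed small domains strongly enriched on arms, euchromatin-type
marks sit at promoters or bodies of active genes (which concentrate in
centers), and each reader peak set is coupled to a chosen mark with
strength theta: every peak lands uniformly inside a random target-mark
domain with probability theta, else uniformly in the genome.  A ground
truth manifest records what was planted so pipeline stages can be tested
for recovery.

Randomness: one master seed, expanded into an independent named stream per
sub-generator (CRC32 of the stream label), so adding a reader never
perturbs mark placement.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (ChromosomeDomains, GeneModel, GenomicInterval, PeakSet,
                   SignalTrack, merge_intervals, write_narrowpeak)
from .qc import ReadSet

logger = logging.getLogger("readermap")

EU_MARKS = ("H3K4me3", "H3K36me3", "H3K79me3")
HET_MARKS = ("H3K9me2", "H3K9me3", "H3K27me3")


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent, label-keyed RNG stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class MarkSpec:
    """One histone mark.  Heterochromatin marks ('het') are placed as
    dispersed domains at ``rate_arm`` / ``rate_center`` domains per bp;
    euchromatin marks ('eu') follow active genes (promoter or body)."""

    name: str
    kind: str = "het"             # het | eu
    rate_arm: float = 2.5e-5
    rate_center: float = 2.5e-6
    length_median: float = 800.0
    length_sigma: float = 0.5
    depth: float = 20.0
    eu_placement: str = "promoter"  # promoter | body
    eu_prob: float = 0.9            # per active gene

    def __post_init__(self) -> None:
        if self.kind not in ("het", "eu"):
            raise ValueError(f"mark kind must be het or eu, got {self.kind!r}")
        if min(self.rate_arm, self.rate_center) < 0:
            raise ValueError("placement rates must be >= 0")

    def mean_length(self) -> float:
        return self.length_median * float(np.exp(self.length_sigma ** 2 / 2))


@dataclass
class ReaderSpec:
    """One chromodomain-reader peak set coupled to ``target_mark`` with
    strength theta (probability a peak is planted inside a mark domain)."""

    name: str
    target_mark: str
    theta: float
    n_peaks: int = 500
    length_median: float = 300.0
    length_sigma: float = 0.4
    depth: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must be in [0, 1], got {self.theta}")


@dataclass
class ReadSimSpec:
    """Read-level simulation.  ChIP fragments pile up at peak reference
    points; each emits a + read at its left end and/or a - read at its
    right end, each with probability 0.5 independently.  Background reads
    are single-end draws from a block-wise log-normal intensity field
    (regional coverage structure shared by both strands, as in real
    libraries); the input library is background-only at matched depth.
    ``phantom_rate`` duplicates a + read onto the - strand at read-length
    offset, modeling the mapping artifact behind the phantom peak."""

    fragment_length: int = 200
    read_length: int = 50
    reads_per_peak: int = 50
    background_rate: float = 0.3   # background reads per bp
    jitter_sd: float = 30.0
    phantom_rate: float = 0.01
    block_size: int = 20000
    block_sigma: float = 1.2

    def __post_init__(self) -> None:
        if self.fragment_length <= self.read_length:
            raise ValueError("fragment length must exceed read length")


def _default_marks() -> list[MarkSpec]:
    marks = [MarkSpec(name, kind="het") for name in HET_MARKS]
    marks.append(MarkSpec("H3K4me3", kind="eu", eu_placement="promoter"))
    marks.extend(MarkSpec(n, kind="eu", eu_placement="body") for n in ("H3K36me3", "H3K79me3"))
    return marks


@dataclass
class SyntheticConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{r}": 2_000_000 for r in ("I", "II", "III", "IV", "V")})
    arm_fraction: float = 0.25       # per side; arms cover 2x this fraction
    marks: list[MarkSpec] = field(default_factory=_default_marks)
    readers: list[ReaderSpec] = field(
        default_factory=lambda: [ReaderSpec("reader1", "H3K9me2", 0.9)])
    n_genes: int = 500
    active_fraction: float = 0.5
    center_gene_bias: float = 0.8    # probability a gene falls in the center
    repeat_families: tuple[str, ...] = ("DNA", "LTR", "LINE", "Satellite")
    repeats_per_family: int = 150
    arm_repeat_bias: float = 0.8
    noise_rate: float = 1.0          # per-base Poisson background of tracks
    track_bin: int = 20
    reads: ReadSimSpec = field(default_factory=ReadSimSpec)

    def __post_init__(self) -> None:
        if not 0 < 2 * self.arm_fraction < 1:
            raise ValueError("need 0 < 2*arm_fraction < 1")
        mark_names = {m.name for m in self.marks}
        for r in self.readers:
            if r.target_mark not in mark_names:
                raise ValueError(f"reader {r.name} targets unknown mark {r.target_mark}")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    chrom_lengths: dict[str, int]
    domains: ChromosomeDomains
    genes: list[GeneModel]
    repeats: list[GenomicInterval]
    fpkm: dict[str, float]
    active: dict[str, bool]

    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


def _choose_chrom(rng: np.random.Generator, chrom_lengths: dict[str, int]) -> str:
    names = sorted(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in names], dtype=float)
    return names[rng.choice(len(names), p=lens / lens.sum())]


def simulate_genome(config: SyntheticConfig) -> Genome:
    """Genome manifest: arm/center domains, genes (center-biased), repeats
    (arm-biased) and an FPKM table consistent with planted activity."""
    het_mean = max((m.mean_length() for m in config.marks if m.kind == "het"), default=0.0)
    for chrom, length in config.chrom_lengths.items():
        if het_mean and length < 10 * het_mean:
            raise ValueError(f"{chrom} shorter than 10x mean mark domain length")
    bounds = {}
    for chrom, length in config.chrom_lengths.items():
        a = int(round(length * config.arm_fraction))
        bounds[chrom] = (a, length - a, length)
    domains = ChromosomeDomains(bounds)

    rng = _stream(config.seed, "genome")
    genes: list[GeneModel] = []
    fpkm: dict[str, float] = {}
    active: dict[str, bool] = {}
    for i in range(config.n_genes):
        gid = f"gene{i:04d}"
        chrom = _choose_chrom(rng, config.chrom_lengths)
        a, b, length = bounds[chrom]
        in_center = rng.random() < config.center_gene_bias
        n_exons = int(rng.integers(2, 7))
        exon_lens = np.round(rng.lognormal(np.log(200), 0.5, n_exons)).astype(int) + 1
        intron_lens = np.round(rng.lognormal(np.log(300), 0.6, n_exons - 1)).astype(int) + 1
        span = int(exon_lens.sum() + intron_lens.sum())
        if in_center:
            lo, hi = a, b
        else:
            lo, hi = (0, a) if rng.random() < 0.5 else (b, length)
        if hi - lo <= span + 2:
            lo, hi = 0, length
        start = int(rng.integers(lo, hi - span))
        exons = []
        pos = start
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gid, chrom, strand, exons))
        is_active = rng.random() < config.active_fraction
        active[gid] = is_active
        if is_active:
            fpkm[gid] = float(max(1.0, rng.lognormal(np.log(10), 1.0)))
        else:
            fpkm[gid] = float(rng.uniform(0.0, 0.99))

    repeats: list[GenomicInterval] = []
    for fam in config.repeat_families:
        for j in range(config.repeats_per_family):
            chrom = _choose_chrom(rng, config.chrom_lengths)
            a, b, length = bounds[chrom]
            on_arm = rng.random() < config.arm_repeat_bias
            if on_arm:
                lo, hi = (0, a) if rng.random() < 0.5 else (b, length)
            else:
                lo, hi = a, b
            rep_len = int(rng.lognormal(np.log(150), 0.6)) + 10
            rep_len = min(rep_len, hi - lo - 1)
            start = int(rng.integers(lo, hi - rep_len))
            repeats.append(GenomicInterval(chrom, start, start + rep_len, name=fam))
    return Genome(dict(config.chrom_lengths), domains, genes, repeats, fpkm, active)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def indicator_track(genome: Genome, intervals: list[GenomicInterval],
                    depth: float, noise_rate: float, bin_size: int,
                    rng: np.random.Generator) -> SignalTrack:
    """Per-base indicator x depth over intervals, plus Poisson noise, at
    ``bin_size`` resolution (noise drawn per bin)."""
    runs = {}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(genome.chrom_lengths):
        length = genome.chrom_lengths[chrom]
        n_bins = (length + bin_size - 1) // bin_size
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, length)
        widths = (ends - starts).astype(float)
        noise = rng.poisson(noise_rate * widths) / widths
        covered = np.zeros(n_bins)
        for iv in by_chrom.get(chrom, []):
            s, e = max(0, iv.start), min(length, iv.end)
            if e <= s:
                continue
            b0, b1 = s // bin_size, (e - 1) // bin_size
            if b0 == b1:
                covered[b0] += e - s
            else:
                covered[b0] += (b0 + 1) * bin_size - s
                covered[b1] += e - b1 * bin_size
                covered[b0 + 1:b1] += bin_size
        vals = noise + depth * np.minimum(covered, widths) / widths
        runs[chrom] = (starts, ends, vals)
    return SignalTrack(runs, "raw")


# ---------------------------------------------------------------------------
# marks and readers
# ---------------------------------------------------------------------------

@dataclass
class MarkData:
    spec: MarkSpec
    peaks: PeakSet          # merged mark domains
    track: SignalTrack


def simulate_marks(genome: Genome, config: SyntheticConfig) -> dict[str, MarkData]:
    """Place every configured mark and build its signal track."""
    out: dict[str, MarkData] = {}
    active_genes = [g for g in genome.genes if genome.active[g.gene_id]]
    for spec in config.marks:
        rng = _stream(config.seed, f"mark:{spec.name}")
        intervals: list[GenomicInterval] = []
        if spec.kind == "het":
            for chrom in sorted(genome.chrom_lengths):
                for cls, seg_lo, seg_hi in genome.domains.segments(chrom):
                    rate = spec.rate_arm if cls == "arm" else spec.rate_center
                    n = rng.poisson(rate * (seg_hi - seg_lo))
                    for _ in range(n):
                        dom_len = max(50, int(rng.lognormal(np.log(spec.length_median),
                                                            spec.length_sigma)))
                        start = int(rng.integers(seg_lo, seg_hi))
                        end = min(start + dom_len, seg_hi)
                        if end > start:
                            intervals.append(GenomicInterval(chrom, start, end))
        else:
            for g in active_genes:
                if rng.random() >= spec.eu_prob:
                    continue
                if spec.eu_placement == "promoter":
                    lo, hi = g.promoter
                else:
                    lo, hi = g.start, g.end
                hi = min(hi, genome.chrom_lengths[g.chrom])
                if hi > lo:
                    intervals.append(GenomicInterval(g.chrom, lo, hi))
        merged = merge_intervals(intervals)
        track = indicator_track(genome, merged, spec.depth, config.noise_rate,
                                config.track_bin, rng)
        out[spec.name] = MarkData(spec, PeakSet(spec.name, merged), track)
    return out


@dataclass
class ReaderData:
    spec: ReaderSpec
    peaks: PeakSet
    track: SignalTrack
    realized_in_mark_fraction: float


def simulate_reader(genome: Genome, marks: dict[str, MarkData],
                    spec: ReaderSpec, config: SyntheticConfig) -> ReaderData:
    """Reader peaks coupled to the target mark with strength theta."""
    rng = _stream(config.seed, f"reader:{spec.name}")
    domains = list(marks[spec.target_mark].peaks)
    if spec.theta > 0 and not domains:
        raise ValueError(f"target mark {spec.target_mark} has no domains")
    intervals: list[GenomicInterval] = []
    in_mark = 0
    dom_index = {c: [(iv.start, iv.end) for iv in ivs]
                 for c, ivs in marks[spec.target_mark].peaks.by_chrom().items()}
    for i in range(spec.n_peaks):
        if domains and rng.random() < spec.theta:
            dom = domains[int(rng.integers(len(domains)))]
            chrom = dom.chrom
            center = int(rng.integers(dom.start, dom.end))
        else:
            chrom = _choose_chrom(rng, genome.chrom_lengths)
            center = int(rng.integers(0, genome.chrom_lengths[chrom]))
        peak_len = max(50, int(rng.lognormal(np.log(spec.length_median), spec.length_sigma)))
        start = max(0, center - peak_len // 2)
        end = min(start + peak_len, genome.chrom_lengths[chrom])
        start = max(0, min(start, end - 1))
        intervals.append(GenomicInterval(chrom, start, end, name=f"{spec.name}_p{i}",
                                         summit=min(center, end - 1)))
        if any(s <= center < e for s, e in dom_index.get(chrom, [])):
            in_mark += 1
    track = indicator_track(genome, intervals, spec.depth, config.noise_rate,
                            config.track_bin, rng)
    return ReaderData(spec, PeakSet(spec.name, intervals), track,
                      in_mark / spec.n_peaks if spec.n_peaks else 0.0)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _background_positions(rng: np.random.Generator, chrom_lengths: dict[str, int],
                          n: int, block_size: int, block_sigma: float
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Draw n genome positions from a block-wise log-normal intensity field.

    Returns (chrom index into sorted names, position).  The field is redrawn
    per library from its own stream, standing in for the regional coverage
    structure (accessibility, mappability) of real libraries.
    """
    names = sorted(chrom_lengths)
    blocks = []  # (chrom_idx, block_start, block_end)
    for ci, name in enumerate(names):
        length = chrom_lengths[name]
        for s in range(0, length, block_size):
            blocks.append((ci, s, min(s + block_size, length)))
    weights = rng.lognormal(0.0, block_sigma, len(blocks))
    weights *= np.array([b[2] - b[1] for b in blocks], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(blocks), size=n, p=weights)
    chrom_idx = np.empty(n, dtype=np.int64)
    pos = np.empty(n, dtype=np.int64)
    for k, bi in enumerate(picks):
        ci, s, e = blocks[bi]
        chrom_idx[k] = ci
        pos[k] = rng.integers(s, e)
    return chrom_idx, pos


def simulate_reads(peaks: PeakSet, genome: Genome, spec: ReadSimSpec,
                   seed: int, label: str = "reads") -> tuple[ReadSet, ReadSet]:
    """(ChIP ReadSet, matched input ReadSet) for one peak set.

    ChIP fragments pile at peak reference points with Gaussian jitter; each
    emits its + (left) and - (right) end read independently with
    probability 0.5.  Background and input reads are single-end draws from
    the block intensity field.
    """
    rng = _stream(seed, f"{label}:{peaks.sample}")
    names = sorted(genome.chrom_lengths)
    F, R = spec.fragment_length, spec.read_length
    plus: dict[str, list[int]] = {c: [] for c in names}
    minus: dict[str, list[int]] = {c: [] for c in names}

    n_frag = 0
    for iv in peaks:
        length = genome.chrom_lengths[iv.chrom]
        centers = iv.reference_point + rng.normal(0, spec.jitter_sd, spec.reads_per_peak)
        left = np.clip(np.round(centers - F / 2).astype(np.int64), 0, length - F)
        emit_p = rng.random(spec.reads_per_peak) < 0.5
        emit_m = rng.random(spec.reads_per_peak) < 0.5
        plus[iv.chrom].extend(left[emit_p].tolist())
        minus[iv.chrom].extend((left[emit_m] + F - 1).tolist())
        n_frag += spec.reads_per_peak

    n_bg = int(rng.poisson(spec.background_rate * genome.total_length()))
    def background_library(rng_lib: np.random.Generator, n: int,
                           p: dict[str, list[int]], m: dict[str, list[int]]) -> None:
        ci, pos = _background_positions(rng_lib, genome.chrom_lengths, n,
                                        spec.block_size, spec.block_sigma)
        strands = rng_lib.random(n) < 0.5
        for k in range(n):
            chrom = names[ci[k]]
            if strands[k]:
                p[chrom].append(int(pos[k]))
            else:
                m[chrom].append(int(min(pos[k] + R - 1, genome.chrom_lengths[chrom] - 1)))

    background_library(rng, n_bg, plus, minus)

    # phantom-peak artifact: a fraction of + reads re-mapped on the - strand
    for chrom in names:
        arr = np.array(plus[chrom], dtype=np.int64)
        dup = arr[rng.random(len(arr)) < spec.phantom_rate] + R
        dup = dup[dup < genome.chrom_lengths[chrom]]
        minus[chrom].extend(dup.tolist())

    chip = ReadSet({c: {"+": np.array(sorted(plus[c])), "-": np.array(sorted(minus[c]))}
                    for c in names}, R)

    rng_in = _stream(seed, f"{label}:input:{peaks.sample}")
    p_in: dict[str, list[int]] = {c: [] for c in names}
    m_in: dict[str, list[int]] = {c: [] for c in names}
    background_library(rng_in, chip.n_reads, p_in, m_in)
    for chrom in names:
        arr = np.array(p_in[chrom], dtype=np.int64)
        dup = arr[rng_in.random(len(arr)) < spec.phantom_rate] + R
        dup = dup[dup < genome.chrom_lengths[chrom]]
        m_in[chrom].extend(dup.tolist())
    inp = ReadSet({c: {"+": np.array(sorted(p_in[c])), "-": np.array(sorted(m_in[c]))}
                   for c in names}, R)
    return chip, inp


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    genome: Genome
    marks: dict[str, MarkData]
    readers: dict[str, ReaderData]
    input_track: SignalTrack
    truth: dict


def simulate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Full synthetic input set plus ground-truth manifest."""
    genome = simulate_genome(config)
    marks = simulate_marks(genome, config)
    readers = {spec.name: simulate_reader(genome, marks, spec, config)
               for spec in config.readers}
    input_track = indicator_track(genome, [], 0.0, config.noise_rate,
                                  config.track_bin, _stream(config.seed, "input"))
    genome_len = genome.total_length()
    truth = {
        "seed": config.seed,
        "marks": {name: {"n_domains": len(md.peaks),
                         "bp": sum(len(iv) for iv in md.peaks),
                         "genome_fraction": sum(len(iv) for iv in md.peaks) / genome_len}
                  for name, md in marks.items()},
        "readers": {name: {"target_mark": rd.spec.target_mark,
                           "theta": rd.spec.theta,
                           "realized_in_mark_fraction": rd.realized_in_mark_fraction}
                    for name, rd in readers.items()},
        "genes": {g.gene_id: ("active" if genome.active[g.gene_id] else "silent")
                  for g in genome.genes},
    }
    return SyntheticBundle(config, genome, marks, readers, input_track, truth)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write the bundle as plain-text standard formats plus truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.genome.domains.write_tsv(out / "domains.tsv")
    with open(out / "genes.bed12", "w") as fh:
        for g in bundle.genome.genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                     f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n")
    with open(out / "fpkm.tsv", "w") as fh:
        fh.write("gene_id\tfpkm\n")
        for gid in sorted(bundle.genome.fpkm):
            fh.write(f"{gid}\t{bundle.genome.fpkm[gid]:.4f}\n")
    with open(out / "repeats.bed", "w") as fh:
        for iv in sorted(bundle.genome.repeats, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t.\t.\n")
    with open(out / "chrom_lengths.tsv", "w") as fh:
        for c in sorted(bundle.genome.chrom_lengths):
            fh.write(f"{c}\t{bundle.genome.chrom_lengths[c]}\n")
    for name, md in bundle.marks.items():
        write_narrowpeak(md.peaks, out / f"mark_{name}.narrowPeak")
        md.track.write_bedgraph(out / f"mark_{name}.bedgraph")
    for name, rd in bundle.readers.items():
        write_narrowpeak(rd.peaks, out / f"reader_{name}.narrowPeak")
        rd.track.write_bedgraph(out / f"reader_{name}.bedgraph")
    bundle.input_track.write_bedgraph(out / "input.bedgraph")
    with open(out / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
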