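import filecmp
import json

import numpy as np
import pytest

from readermap import (ChromosomeDomains, MarkSpec, ReaderSpec, ReadSimSpec,
                       SignalTrack, SyntheticConfig, read_fpkm_table,
                       read_gene_models, read_intervals, simulate_bundle,
                       simulate_genome, simulate_marks, simulate_reader,
                       simulate_reads, write_bundle)


def tiny_config(seed=0, **kw):
    defaults = dict(
        seed=seed,
        chrom_lengths={"chrI": 300_000, "chrII": 300_000},
        readers=[ReaderSpec("r1", "H3K9me2", 0.9, 60)],
        n_genes=40,
        repeats_per_family=10,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


def test_arm_boundaries_arithmetic():
    cfg = SyntheticConfig(seed=0, chrom_lengths={"chrI": 1_000_000},
                          arm_fraction=0.25,
                          readers=[ReaderSpec("r", "H3K9me2", 0.5, 10)],
                          n_genes=20, repeats_per_family=5)
    genome = simulate_genome(cfg)
    a, b, length = genome.domains.boundaries["chrI"]
    assert (a, b, length) == (250_000, 750_000, 1_000_000)
    segs = genome.domains.segments("chrI")
    assert segs[0] == ("arm", 0, 250_000)
    assert segs[-1] == ("arm", 750_000, 1_000_000)
    # the three segments tile the chromosome exactly
    assert sum(e - s for _, s, e in segs) == length


def test_too_short_chromosome_rejected():
    with pytest.raises(ValueError, match="10x"):
        simulate_genome(tiny_config(chrom_lengths={"chrI": 5_000}))


def test_theta_one_gives_full_in_mark_fraction():
    cfg = tiny_config(readers=[ReaderSpec("r1", "H3K9me2", 1.0, 50)])
    genome = simulate_genome(cfg)
    marks = simulate_marks(genome, cfg)
    rd = simulate_reader(genome, marks, cfg.readers[0], cfg)
    assert rd.realized_in_mark_fraction == 1.0
    assert len(rd.peaks) == 50  # exactly n peaks produced


def test_theta_zero_matches_mark_genome_fraction():
    """With no coupling the in-mark rate equals the mark's genome fraction
    in expectation (checked within 3 standard errors over seeds)."""
    rates, expected = [], []
    for seed in range(20):
        cfg = tiny_config(seed=seed, readers=[ReaderSpec("r1", "H3K9me2", 0.0, 100)])
        genome = simulate_genome(cfg)
        marks = simulate_marks(genome, cfg)
        rd = simulate_reader(genome, marks, cfg.readers[0], cfg)
        rates.append(rd.realized_in_mark_fraction)
        expected.append(sum(len(iv) for iv in marks["H3K9me2"].peaks)
                        / genome.total_length())
    mean_rate, mean_exp = np.mean(rates), np.mean(expected)
    se = np.sqrt(mean_exp * (1 - mean_exp) / (20 * 100))
    assert abs(mean_rate - mean_exp) < 3 * se + 1e-9


def test_zero_center_rate_keeps_marks_on_arms():
    cfg = tiny_config(marks=[MarkSpec("H3K9me2", kind="het", rate_center=0.0)],
                      readers=[ReaderSpec("r1", "H3K9me2", 0.5, 20)])
    genome = simulate_genome(cfg)
    marks = simulate_marks(genome, cfg)
    for iv in marks["H3K9me2"].peaks:
        assert genome.domains.classify(iv.chrom, iv.midpoint) == "arm"


def test_mark_arm_fraction_matches_closed_form():
    """Expected arm share of mark bp ~ rho_arm*armBp / (rho_arm*armBp +
    rho_center*centerBp)."""
    obs = []
    for seed in range(20):
        cfg = tiny_config(seed=seed)
        genome = simulate_genome(cfg)
        marks = simulate_marks(genome, cfg)
        arm_bp = center_bp = 0
        for iv in marks["H3K9me2"].peaks:
            if genome.domains.classify(iv.chrom, iv.midpoint) == "arm":
                arm_bp += len(iv)
            else:
                center_bp += len(iv)
        obs.append(arm_bp / (arm_bp + center_bp))
    spec = tiny_config().marks[0]
    total = 600_000
    arm_frac_bp = 0.5 * total
    expected = (spec.rate_arm * arm_frac_bp) / (
        spec.rate_arm * arm_frac_bp + spec.rate_center * (total - arm_frac_bp))
    se = np.std(obs, ddof=1) / np.sqrt(len(obs))
    assert abs(np.mean(obs) - expected) < 3 * se + 0.02


def test_track_nonnegative_everywhere():
    cfg = tiny_config()
    genome = simulate_genome(cfg)
    marks = simulate_marks(genome, cfg)
    for md in marks.values():
        for _, _, v in md.track.runs.values():
            assert (v >= 0).all()


def test_same_seed_reproduces_bundle_byte_identically(tmp_path):
    for sub in ("a", "b"):
        write_bundle(simulate_bundle(tiny_config(seed=3)), tmp_path / sub)
    files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
    files_b = sorted(p.name for p in (tmp_path / "b").iterdir())
    assert files_a == files_b
    for name in files_a:
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                           shallow=False), name


def test_adding_reader_does_not_perturb_marks_or_other_readers():
    cfg1 = tiny_config(readers=[ReaderSpec("r1", "H3K9me2", 0.9, 40)])
    cfg2 = tiny_config(readers=[ReaderSpec("r1", "H3K9me2", 0.9, 40),
                                ReaderSpec("r2", "H3K4me3", 0.5, 40)])
    b1 = simulate_bundle(cfg1)
    b2 = simulate_bundle(cfg2)
    for name in b1.marks:
        assert [(iv.start, iv.end) for iv in b1.marks[name].peaks] == \
               [(iv.start, iv.end) for iv in b2.marks[name].peaks]
    assert [(iv.start, iv.end) for iv in b1.readers["r1"].peaks] == \
           [(iv.start, iv.end) for iv in b2.readers["r1"].peaks]


def test_bundle_round_trips_through_readers(tmp_path):
    bundle = simulate_bundle(tiny_config(seed=5))
    write_bundle(bundle, tmp_path)
    doms = ChromosomeDomains.read_tsv(tmp_path / "domains.tsv")
    assert doms.boundaries == bundle.genome.domains.boundaries
    peaks = read_intervals(tmp_path / "reader_r1.narrowPeak", "narrowPeak")
    orig = bundle.readers["r1"].peaks
    assert [(iv.chrom, iv.start, iv.end, iv.summit) for iv in peaks] == \
           [(iv.chrom, iv.start, iv.end, iv.summit) for iv in orig]
    track = SignalTrack.read_bedgraph(tmp_path / "mark_H3K9me2.bedgraph")
    assert track.total() == pytest.approx(bundle.marks["H3K9me2"].track.total(),
                                          rel=1e-6)
    genes = read_gene_models(tmp_path / "genes.bed12", "bed12")
    assert [(g.gene_id, g.exons) for g in genes] == \
           [(g.gene_id, g.exons) for g in bundle.genome.genes]
    fpkm = read_fpkm_table(tmp_path / "fpkm.tsv")
    for gid, value in bundle.genome.fpkm.items():
        assert fpkm[gid] == pytest.approx(value, abs=5e-5)
    truth = json.loads((tmp_path / "truth.json").read_text())
    assert truth["readers"]["r1"]["theta"] == 0.9


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def test_reads_local_to_single_peak_without_background():
    cfg = tiny_config(readers=[ReaderSpec("r1", "H3K9me2", 1.0, 1)])
    genome = simulate_genome(cfg)
    marks = simulate_marks(genome, cfg)
    rd = simulate_reader(genome, marks, cfg.readers[0], cfg)
    spec = ReadSimSpec(background_rate=0.0, phantom_rate=0.0, reads_per_peak=200)
    chip, _ = simulate_reads(rd.peaks, genome, spec, seed=1)
    (peak,) = rd.peaks
    lo = peak.reference_point - spec.fragment_length - 3 * spec.jitter_sd
    hi = peak.reference_point + spec.fragment_length + 3 * spec.jitter_sd
    for chrom, strands in chip.positions.items():
        for pos in np.concatenate([strands["+"], strands["-"]]):
            assert chrom == peak.chrom and lo <= pos <= hi


def test_strand_counts_roughly_balanced():
    fracs = []
    for seed in range(20):
        cfg = tiny_config(seed=seed, readers=[ReaderSpec("r1", "H3K9me2", 1.0, 20)])
        genome = simulate_genome(cfg)
        marks = simulate_marks(genome, cfg)
        rd = simulate_reader(genome, marks, cfg.readers[0], cfg)
        chip, _ = simulate_reads(rd.peaks, genome,
                                 ReadSimSpec(background_rate=0.0, phantom_rate=0.0),
                                 seed=seed)
        n_plus = sum(len(s["+"]) for s in chip.positions.values())
        fracs.append(n_plus / chip.n_reads)
    se = 0.5 / np.sqrt(20 * 20 * 50)
    assert abs(np.mean(fracs) - 0.5) < 3 * se + 1e-9


def test_same_seed_identical_reads():
    cfg = tiny_config()
    genome = simulate_genome(cfg)
    marks = simulate_marks(genome, cfg)
    rd = simulate_reader(genome, marks, cfg.readers[0], cfg)
    spec = ReadSimSpec(background_rate=0.01)
    c1, i1 = simulate_reads(rd.peaks, genome, spec, seed=9)
    c2, i2 = simulate_reads(rd.peaks, genome, spec, seed=9)
    for a, b in [(c1, c2), (i1, i2)]:
        for chrom in a.positions:
            for strand in "+-":
                assert np.array_equal(a.positions[chrom][strand],
                                      b.positions[chrom][strand])
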