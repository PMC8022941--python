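import numpy as np
import pytest

from gapweaver.alignments import AlignmentBlock
from gapweaver.gap_validator import (
    classify_gap_support,
    collinearity_check,
    coverage_stats,
    group_molecules,
    read_barcoded_tsv,
    classify_gap_support,
)
from gapweaver.genome_model import Assembly


def fill_block(query, target, t_start, n=5000):
    return AlignmentBlock(query, n, 0, n, "+", target, 1_000_000,
                          t_start, t_start + n, n, n)


# --- collinearity ----------------------------------------------------------

def test_collinearity_concordant_and_discordant():
    expected = {"f1": "chr1", "f2": "chr1", "f3": "chr2"}
    blocks = [fill_block("f1", "chr1", 0),
              fill_block("f2", "chr3", 0),
              fill_block("f3", "chr2", 0)]
    rep = collinearity_check(expected, blocks, min_identity=0.9, min_len=100)
    assert rep.labels == {"f1": "concordant_chrom", "f2": "discordant_chrom",
                          "f3": "concordant_chrom"}
    assert rep.n_aligned == 3 and rep.n_discordant == 1


def test_collinearity_unaligned_fill():
    rep = collinearity_check({"f1": "chr1"}, [], min_identity=0.9, min_len=100)
    assert rep.labels["f1"] == "unaligned"
    assert rep.fraction_aligned == 0.0


def test_collinearity_planted_translocation(anomaly_bundle):
    b = anomaly_bundle
    expected = {tg.gap_id: tg.chrom for tg in b.truth_gaps
                if tg.origin in ("gap", "chrun") and tg.anomaly != "nonlinear"}
    rep = collinearity_check(expected, b.fills_paf, min_identity=0.9, min_len=100)
    discordant = {k for k, v in rep.labels.items() if v == "discordant_chrom"}
    assert discordant == {gid for gid, k in b.anomalies.items() if k == "translocated"}


# --- molecule grouping -----------------------------------------------------

def rows_from(specs):
    return [(f"r{i}", bc, chrom, s, s + 150)
            for i, (bc, chrom, s) in enumerate(specs)]


def test_group_single_molecule():
    rows = rows_from([("bx1", "chr1", s) for s in range(0, 30_000, 6000)])
    mols, skipped = group_molecules(rows)
    assert len(mols) == 1 and skipped == 0
    assert len(mols[0].reads) == 5


def test_group_splits_distant_clusters():
    rows = rows_from([("bx1", "chr1", 0), ("bx1", "chr1", 10_000),
                      ("bx1", "chr1", 210_000), ("bx1", "chr1", 215_000)])
    mols, _ = group_molecules(rows, max_gap_within_molecule=50_000)
    assert len(mols) == 2
    assert [len(m.reads) for m in mols] == [2, 2]


def single_linkage_oracle(starts, max_gap, read_len=150):
    starts = sorted(starts)
    clusters = 1
    for a, b in zip(starts, starts[1:]):
        if b - (a + read_len) > max_gap:
            clusters += 1
    return clusters


def test_group_matches_single_linkage_oracle():
    rng = np.random.default_rng(2)
    starts = sorted(map(int, rng.integers(0, 2_000_000, 60)))
    rows = rows_from([("bx1", "chr1", s) for s in starts])
    mols, _ = group_molecules(rows, max_gap_within_molecule=50_000)
    assert len(mols) == single_linkage_oracle(starts, 50_000)


def test_group_empty_and_missing_barcode():
    assert group_molecules([]) == ([], 0)
    rows = [("r1", "", "chr1", 0, 150), ("r2", ".", "chr1", 0, 150),
            ("r3", "bx1", "chr1", 0, 150)]
    mols, skipped = group_molecules(rows)
    assert skipped == 2 and len(mols) == 1


def test_group_separates_chromosomes():
    rows = [("r1", "bx1", "chr1", 0, 150), ("r2", "bx1", "chr2", 0, 150)]
    mols, _ = group_molecules(rows)
    assert len(mols) == 2


# --- classify_gap_support --------------------------------------------------

def tiled_rows(chrom, lo, hi, bc="bx1", step=100, read_len=150):
    return [(f"t{s}", bc, chrom, s, s + read_len) for s in range(lo, hi, step)]


def test_supported_gap():
    rows = tiled_rows("chr1", 800, 2400)
    mols, _ = group_molecules(rows)
    call = classify_gap_support(("chr1", 1000, 2000), rows, mols)
    assert call.verdict == "supported"
    assert call.spanning_molecules >= 1


def test_unsupported_zero_depth_interior():
    rows = [r for r in tiled_rows("chr1", 800, 2400) if not (r[3] < 2000 and r[4] > 1000)]
    mols, _ = group_molecules(rows)
    call = classify_gap_support(("chr1", 1000, 2000), rows, mols)
    assert call.verdict == "unsupported"
    assert call.min_depth_in_fill == 0


def test_spanning_molecule_required():
    # depth everywhere but left/right reads carry different barcodes
    left = tiled_rows("chr1", 800, 1600, bc="bxL")
    right = tiled_rows("chr1", 1500, 2400, bc="bxR")
    mols, _ = group_molecules(left + right)
    call = classify_gap_support(("chr1", 1000, 2000), left + right, mols)
    assert call.spanning_molecules == 0
    assert call.verdict == "unsupported"


def test_monotone_in_depth_threshold():
    rows = tiled_rows("chr1", 800, 2400)
    mols, _ = group_molecules(rows)
    verdicts = [classify_gap_support(("chr1", 1000, 2000), rows, mols,
                                     depth_threshold=t).verdict
                for t in (1, 2, 5, 50)]
    # once unsupported, raising the threshold never flips back
    seen_unsupported = False
    for v in verdicts:
        if v == "unsupported":
            seen_unsupported = True
        assert not (seen_unsupported and v == "supported")


def test_degenerate_fill_interval_rejected():
    with pytest.raises(ValueError):
        classify_gap_support(("chr1", 1000, 1000), [], [])


def test_planted_uncovered_fill_caught(anomaly_bundle):
    b = anomaly_bundle
    mols, _ = group_molecules(b.linked_reads)
    unsupported = []
    for gid, interval in b.fill_new_intervals.items():
        if classify_gap_support(interval, b.linked_reads, mols).verdict == "unsupported":
            unsupported.append(gid)
    assert unsupported == [gid for gid, k in b.anomalies.items() if k == "uncovered"]


def test_all_correct_fills_supported(default_bundle):
    b = default_bundle
    mols, _ = group_molecules(b.linked_reads)
    calls = [classify_gap_support(iv, b.linked_reads, mols)
             for iv in b.fill_new_intervals.values()]
    assert all(c.verdict == "supported" for c in calls)
    assert len(calls) == len(b.fill_new_intervals)


# --- coverage stats --------------------------------------------------------

def test_alignment_rate_arithmetic():
    asm = Assembly.from_sequences({"chr1": "A" * 1000})
    rows = [(f"r{i}", "bx", "chr1", 0, 100) for i in range(844)]
    stats = coverage_stats(rows, asm, total_reads=1000)
    assert stats["alignment_rate"] == pytest.approx(0.844)


def test_no_reads():
    asm = Assembly.from_sequences({"chr1": "A" * 1000})
    stats = coverage_stats([], asm, total_reads=0)
    assert stats == {"alignment_rate": 0.0, "mean_depth": 0.0}


def test_mean_depth_matches_pileup_oracle():
    rng = np.random.default_rng(9)
    L = 10_000
    asm = Assembly.from_sequences({"chr1": "A" * L})
    rows = [(f"r{i}", "bx", "chr1", int(s), int(s) + 150)
            for i, s in enumerate(rng.integers(0, L - 150, 500))]
    depth = np.zeros(L)
    for _, _, _, s, e in rows:
        depth[s:e] += 1
    stats = coverage_stats(rows, asm)
    assert stats["mean_depth"] == pytest.approx(depth.mean())


def test_simulated_depth_near_configured(default_bundle):
    b = default_bundle
    depth_sum = 0
    span_sum = 0
    for chrom, lo, hi in b.read_windows:
        cov = np.zeros(hi - lo)
        for _, _, c, s, e in b.linked_reads:
            if c == chrom and s < hi and e > lo:
                cov[max(s, lo) - lo : min(e, hi) - lo] += 1
        depth_sum += cov.sum()
        span_sum += hi - lo
    mean_depth = depth_sum / span_sum
    assert mean_depth == pytest.approx(b.cfg.read_depth, rel=0.10)


def test_read_barcoded_sam(tmp_path):
    from gapweaver.gap_validator import read_barcoded_bam

    sam = tmp_path / "linked.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:chr1\tLN:10000\n"
        "r1\t0\tchr1\t101\t60\t150M\t*\t0\t0\t*\t*\tBX:Z:bx1\n"
        "r2\t0\tchr1\t401\t60\t150M\t*\t0\t0\t*\t*\tBX:Z:bx1\n"
        "r3\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
    )
    rows = read_barcoded_bam(sam)
    assert rows == [("r1", "bx1", "chr1", 100, 250), ("r2", "bx1", "chr1", 400, 550)]


def test_read_barcoded_tsv(tmp_path):
    p = tmp_path / "reads.tsv"
    p.write_text("r1\tbx1\tchr1\t0\t150\nr2\tbx1\tchr1\t300\t450\n")
    rows = read_barcoded_tsv(p)
    assert rows == [("r1", "bx1", "chr1", 0, 150), ("r2", "bx1", "chr1", 300, 450)]
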