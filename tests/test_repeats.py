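import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gapweaver._seq import random_seq, revcomp
from gapweaver.alignments import AlignmentBlock
from gapweaver.genome_model import Assembly, PatchLedger
from gapweaver.repeats import (
    TELOMERE_FWD,
    TELOMERE_REV,
    assign_centromere,
    assign_telomere,
    count_motif,
    find_monomers,
    hor_period,
    merge_telomere,
    monomer_array,
    select_telomeric_reads,
    TelomereCandidate,
)
from gapweaver.simulate import SimulationConfig, make_hor_array, simulate


# --- count_motif -----------------------------------------------------------

def test_count_simple_array():
    assert count_motif(TELOMERE_FWD * 60, TELOMERE_FWD) == 60


def test_count_is_case_insensitive_nonoverlapping():
    assert count_motif("ttagggTTAGGG", "TTAGGG") == 2
    assert count_motif("AAAA", "AA") == 2  # non-overlapping scan


def test_revcomp_array_counts_match():
    seq = TELOMERE_FWD * 50
    assert count_motif(revcomp(seq), TELOMERE_REV) == 50


@given(st.text(alphabet="ACGT", min_size=0, max_size=300))
@settings(max_examples=300, deadline=None)
def test_strand_symmetry_property(seq):
    assert count_motif(seq, TELOMERE_FWD) == count_motif(revcomp(seq), TELOMERE_REV)


def test_empty_motif_rejected():
    with pytest.raises(ValueError):
        count_motif("ACGT", "")


# --- selection -------------------------------------------------------------

def test_selection_strictly_above_threshold():
    reads = {"a": TELOMERE_FWD * 60, "b": TELOMERE_FWD * 50, "c": "ACGT" * 100}
    selected = select_telomeric_reads(reads, 50)
    assert [c.read for c in selected] == ["a"]


def test_selection_either_strand():
    reads = {"rev": TELOMERE_REV * 55}
    assert len(select_telomeric_reads(reads, 50)) == 1


def test_selection_empty():
    assert select_telomeric_reads({}, 50) == []


def test_all_simulated_telomeric_reads_selected(default_bundle):
    b = default_bundle
    selected = {c.read for c in select_telomeric_reads(b.telomere_reads, 50)}
    assert selected == set(b.telomere_reads)  # decoy included: it is motif-rich


# --- assignment ------------------------------------------------------------

def anchor_block(read, q_start, q_end, chrom, t_start, t_end, primary=True):
    n = q_end - q_start
    return AlignmentBlock(read, 20_000, q_start, q_end, "+", chrom, 200_000,
                          t_start, t_end, n, n, primary)


def test_assign_right_terminus():
    cand = TelomereCandidate("r1", 60, 0)
    blocks = [anchor_block("r1", 0, 12_000, "chrIV", 188_000, 200_000)]
    assign_telomere(cand, blocks, {"chrIV": 200_000})
    assert cand.assigned_end == ("chrIV", "right")
    assert cand.unique_anchor_bp == 12_000


def test_assign_below_unique_threshold():
    cand = TelomereCandidate("r1", 60, 0)
    blocks = [anchor_block("r1", 0, 9_000, "chrIV", 191_000, 200_000)]
    assign_telomere(cand, blocks, {"chrIV": 200_000})
    assert cand.assigned_end is None


def test_assign_ambiguous_two_chromosomes():
    cand = TelomereCandidate("r1", 60, 0)
    blocks = [anchor_block("r1", 0, 12_000, "chrIV", 188_000, 200_000),
              anchor_block("r1", 0, 12_000, "chrV", 188_000, 200_000)]
    assign_telomere(cand, blocks, {"chrIV": 200_000, "chrV": 200_000})
    assert cand.assigned_end is None


def test_secondary_alignments_ignored():
    cand = TelomereCandidate("r1", 60, 0)
    blocks = [anchor_block("r1", 0, 12_000, "chrIV", 188_000, 200_000, primary=False)]
    assign_telomere(cand, blocks, {"chrIV": 200_000})
    assert cand.assigned_end is None


# --- merging ---------------------------------------------------------------

def test_merge_right_end_appends_overhang(default_bundle):
    b = default_bundle
    chrom_lengths = {r.name: len(r) for r in b.v5_truth.chromosomes()}
    ledger = PatchLedger()
    for cand in select_telomeric_reads(b.telomere_reads, 50):
        assign_telomere(cand, b.telomere_paf, chrom_lengths)
        if cand.assigned_end is None:
            continue
        edit = merge_telomere(b.v5_truth, cand, b.telomere_reads[cand.read],
                              b.telomere_paf)
        ledger.add(edit)
    assert len(ledger) == 2 * b.cfg.n_chroms
    extended = ledger.apply(b.v5_truth)
    tail = TELOMERE_FWD * b.cfg.tel_read_copies
    head = TELOMERE_REV * b.cfg.tel_read_copies
    for rec in extended.chromosomes():
        old = b.v5_truth[rec.name].sequence
        assert rec.sequence.endswith(tail) and rec.sequence.startswith(head)
        # pre-existing bases untouched; growth is exactly the two overhangs
        assert rec.sequence[len(head):len(head) + len(old)] == old
        assert len(rec) == len(old) + len(tail) + len(head)


def test_merge_no_overhang_returns_none():
    asm = Assembly.from_sequences({"chr1": "A" * 20_000})
    cand = TelomereCandidate("r1", 60, 0, assigned_end=("chr1", "right"))
    blocks = [anchor_block("r1", 0, 12_000, "chr1", 8_000, 20_000)]
    read = "A" * 12_000  # aligns fully: nothing to add
    assert merge_telomere(asm, cand, read, blocks) is None


# --- monomer arrays --------------------------------------------------------

@pytest.fixture(scope="module")
def monomer():
    return random_seq(np.random.default_rng(42), 186)


def test_exact_tandem_hits(monomer):
    seq = monomer * 10
    hits = find_monomers(seq, monomer, 0.75)
    assert len(hits) == 10
    assert hits[-1].end - hits[0].start == 1_860
    assert all(h.identity == 1.0 for h in hits)


def test_low_identity_not_hit(monomer):
    rng = np.random.default_rng(1)
    diverged = "".join(
        c if rng.random() > 0.45 else "ACGT"[rng.integers(4)] for c in monomer
    )
    hits = find_monomers(diverged, monomer, 0.80)
    assert hits == []


def test_reverse_strand_detected(monomer):
    seq = revcomp(monomer * 5)
    hits = find_monomers(seq, monomer, 0.75)
    assert len(hits) == 5 and all(h.strand == "-" for h in hits)


def test_consensus_too_short_rejected():
    with pytest.raises(ValueError):
        find_monomers("ACGT" * 100, "ACGT", 0.75)


def test_fixture_centromere_recovered(default_bundle):
    b = default_bundle
    layout = b.truth.layouts["chrI"]
    cen_seq = b.truth.assembly["chrI"].sequence[layout.cen_start : layout.cen_end]
    arr = monomer_array("chrI_cen", cen_seq, b.truth.consensus, 0.75)
    expected = b.cfg.hor_period * b.cfg.hor_blocks
    assert arr.monomer_count == expected
    assert arr.span == expected * b.cfg.monomer_len


# --- centromere assignment -------------------------------------------------

@pytest.fixture(scope="module")
def cen_bundle():
    return simulate(SimulationConfig(seed=4, mask_centromeres=True))


def test_assign_centromere_sides(cen_bundle):
    b = cen_bundle
    by_query = {}
    for blk in b.cen_paf:
        by_query.setdefault(blk.query, []).append(blk)
    results = {name: assign_centromere(by_query.get(name, []), b.cen_gaps)
               for name in b.cen_contigs}
    assert results["cen_chrI_span"] == ("chrI", "spanning")
    assert results["cen_chrII_left"] == ("chrII", "left_of_gap")
    assert results["cen_chrIII_short"] is None  # 8 kb anchor below 10 kb rule


def test_assign_centromere_right_side():
    gaps = {"chr1": (50_000, 60_000)}
    blocks = [AlignmentBlock("c1", 20_000, 0, 15_000, "+", "chr1", 200_000,
                             60_000, 75_000, 15_000, 15_000)]
    assert assign_centromere(blocks, gaps) == ("chr1", "right_of_gap")


# --- self-identity matrix --------------------------------------------------

def test_identity_matrix_symmetric_unit_diagonal(monomer):
    from gapweaver.repeats import self_identity_matrix

    m = self_identity_matrix(monomer * 6, window=186)
    assert m.shape == (6, 6)
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 1.0)
    assert np.allclose(m, 1.0)  # perfect tandem: everything identical


def test_identity_matrix_tsv_roundtrip(tmp_path, monomer):
    from gapweaver.repeats import self_identity_matrix, write_identity_matrix

    m = self_identity_matrix(monomer * 4, window=186)
    p = tmp_path / "matrix.tsv"
    write_identity_matrix(m, p)
    back = np.loadtxt(p, delimiter="\t")
    assert np.allclose(back, m, atol=1e-4)


# --- higher-order repeat period -------------------------------------------

def hor_oracle(monomers, margin=0.02):
    """Brute-force score over all periods."""
    from gapweaver.repeats import _pair_identity

    n = len(monomers)
    scores = {}
    for p in range(1, n // 3 + 1):
        vals = [_pair_identity(monomers[i], monomers[i + p]) for i in range(n - p)]
        scores[p] = sum(vals) / len(vals)
    best = max(scores, key=lambda p: (scores[p], -p))
    if best > 1 and scores[best] - scores[1] > margin:
        return best
    return 1


def test_hor_period_planted_abc(default_bundle):
    b = default_bundle
    variants = b.truth.variants
    seq = make_hor_array(variants, 8)
    m = b.cfg.monomer_len
    monos = [seq[i : i + m] for i in range(0, len(seq), m)]
    res = hor_period(monos)
    assert res.period == 3 and res.confident


def test_hor_perfect_tandem_period_one(monomer):
    res = hor_period([monomer] * 12)
    assert res.period == 1 and res.confident


def test_hor_randomized_order_low_confidence(monomer):
    rng = np.random.default_rng(8)
    variants = [monomer]
    for _ in range(3):
        variants.append("".join(
            c if rng.random() > 0.15 else "ACGT"[rng.integers(4)] for c in monomer
        ))
    monos = [variants[rng.integers(4)] for _ in range(30)]
    res = hor_period(monos)
    if res.period == 1:
        assert not res.confident


def test_hor_too_few_monomers_undefined(monomer):
    assert hor_period([monomer] * 5) is None


def test_hor_matches_exhaustive_oracle(monomer):
    rng = np.random.default_rng(3)
    variants = [monomer] + [
        "".join(c if rng.random() > 0.15 else "ACGT"[rng.integers(4)] for c in monomer)
        for _ in range(3)
    ]
    for n, period in [(12, 2), (24, 4), (60, 3), (18, 1)]:
        monos = [variants[i % period] for i in range(n)]
        assert hor_period(monos).period == hor_oracle(monos)
        assert hor_period(monos).period == period if period > 1 else 1
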