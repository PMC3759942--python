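"""Profile construction and both-strand genome scanning."""

import math

import numpy as np
import pytest

from conftest import random_dna

from afebox.palindromes import (
    VariantAlignment,
    builtin_template,
    enumerate_variants,
    revcomp,
)
from afebox.profiles import (
    Hit,
    build_profile,
    calibrate_threshold,
    genome_background,
    scan_genome,
    score_window,
)


def brute_force_scan(model, genome, threshold):
    """Independent oracle: score every window on both strands one position at
    a time, collapse palindromic strand duplicates, and apply the same greedy
    descending-score non-overlap selection."""
    contigs = genome if isinstance(genome, dict) else {"contig_1": genome}
    hits = []
    for contig in sorted(contigs):
        seq = contigs[contig]
        L = model.length
        lo = model.log_odds()
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        cands = []
        for pos in range(len(seq) - L + 1):
            win = seq[pos : pos + L]
            f = sum(lo[j, idx.get(win[j], 4)] for j in range(L))
            rwin = revcomp(win)
            r = sum(lo[j, idx.get(rwin[j], 4)] for j in range(L))
            if abs(f - r) <= 1e-9:
                m = max(f, r)
                if m >= threshold:
                    cands.append((m, pos, "+"))
            else:
                if f >= threshold:
                    cands.append((f, pos, "+"))
                if r >= threshold:
                    cands.append((r, pos, "-"))
        cands.sort(key=lambda c: (-c[0], c[1], c[2]))
        taken = []
        acc = []
        for score, pos, strand in cands:
            if any(pos < e and s < pos + L for s, e in taken):
                continue
            taken.append((pos, pos + L))
            acc.append(Hit(contig, pos, pos + L, model.model_id, strand, score))
        hits.extend(sorted(acc, key=lambda h: (h.start, h.strand)))
    return hits


def test_single_sequence_pseudocount_zero_is_one_hot():
    aln = VariantAlignment(template_id="MP18", sequences=("ACGT",))
    m = build_profile(aln, pseudocount=0.0)
    assert np.allclose(m.emissions, np.eye(4))


def test_sp13_wildcard_columns_uniform():
    """Each N column of the 64-variant alignment holds 16 of each base."""
    aln = enumerate_variants(builtin_template("SP13"))
    for pc in (0.0, 1.0, 2.5):
        m = build_profile(aln, pseudocount=pc)
        assert np.allclose(m.emissions[5:8], 0.25)


def test_sp13_fixed_column_pseudocount_one():
    m = build_profile(enumerate_variants(builtin_template("SP13")), pseudocount=1.0)
    assert m.emissions[0, 3] == pytest.approx(65 / 68)  # T at position 0


def test_ragged_alignment_rejected():
    aln = VariantAlignment(template_id="SP13", sequences=("ACGT", "ACG"))
    with pytest.raises(ValueError, match="ragged"):
        build_profile(aln)


def test_one_hot_consensus_scores_two_bits_per_position():
    aln = VariantAlignment(template_id="MP18", sequences=("TGACA",))
    m = build_profile(aln, pseudocount=0.0)
    assert score_window(m, "TGACA") == pytest.approx(10.0)  # 2 bits x 5


def test_minus_strand_scores_reverse_complement(profiles):
    m = profiles["C"]
    rng = np.random.default_rng(3)
    for _ in range(5):
        w = random_dna(rng, m.length)
        assert score_window(m, w, "-") == pytest.approx(score_window(m, revcomp(w), "+"))


def test_consensus_score_matches_per_position_hand_sum():
    m = build_profile(enumerate_variants(builtin_template("SP13")), pseudocount=1.0)
    cons = m.consensus()
    expected = sum(
        math.log2(m.emissions[i, "ACGT".index(b)] / 0.25) for i, b in enumerate(cons)
    )
    assert score_window(m, cons) == pytest.approx(expected)


def test_window_length_mismatch_rejected(profiles):
    with pytest.raises(ValueError, match="length"):
        score_window(profiles["A"], "ACGT")


def test_scan_finds_planted_consensus(profiles):
    rng = np.random.default_rng(17)
    seq = random_dna(rng, 5000)
    cons = builtin_template("LP30").pattern.replace("N", "A")
    seq = seq[:1000] + cons + seq[1030:]
    hits = scan_genome(profiles["E"], seq, threshold=20.0)
    assert any(h.start == 1000 for h in hits)


def test_contig_shorter_than_model_yields_no_hits(profiles):
    assert scan_genome(profiles["E"], "ACGTACGT", threshold=-100.0) == []


def test_scan_matches_brute_force_oracle(profiles):
    rng = np.random.default_rng(5)
    for mid in "ACE":
        m = profiles[mid]
        seq = random_dna(rng, 800)
        for thr in (0.0, 5.0):
            assert scan_genome(m, seq, threshold=thr) == brute_force_scan(m, seq, thr)


def test_scan_mirror_symmetry(profiles):
    """Scanning the reverse complement mirrors hit coordinates."""
    m = profiles["C"]
    rng = np.random.default_rng(23)
    seq = random_dna(rng, 1500)
    L = len(seq)
    fwd = scan_genome(m, seq, threshold=3.0)
    mirrored = scan_genome(m, revcomp(seq), threshold=3.0)
    got = sorted((L - h.end, L - h.start, round(h.score, 9)) for h in mirrored)
    want = sorted((h.start, h.end, round(h.score, 9)) for h in fwd)
    assert got == want


def test_no_accepted_hits_overlap(profiles):
    rng = np.random.default_rng(29)
    seq = random_dna(rng, 3000)
    for m in profiles.values():
        hits = scan_genome(m, seq, threshold=0.0)
        hits = sorted(hits, key=lambda h: h.start)
        for a, b in zip(hits, hits[1:]):
            assert a.end <= b.start


def test_expected_score_signs(profiles):
    """KL non-negativity: background expectation <= 0, model expectation >= 0."""
    for m in profiles.values():
        lo = m.log_odds()[:, :4]
        under_bg = float((m.background[None, :] * lo).sum())
        under_model = float((m.emissions * lo).sum())
        assert under_bg <= 1e-9
        assert under_model >= -1e-9


def test_genome_background_strand_symmetric():
    bg = genome_background("AAAACCCGGT")
    assert bg[0] == pytest.approx(bg[3])
    assert bg[1] == pytest.approx(bg[2])
    assert bg.sum() == pytest.approx(1.0)
    assert np.allclose(genome_background("NNNN"), 0.25)


def test_ambiguous_bases_score_zero(profiles):
    m = profiles["A"]
    assert score_window(m, "N" * m.length) == pytest.approx(0.0)


def test_calibrated_threshold_bounds_hit_rate(profiles):
    m = profiles["A"]
    rng = np.random.default_rng(31)
    seq = random_dna(rng, 20_000)
    thr = calibrate_threshold(m, seq, q=1e-3, seed=0)
    hits = scan_genome(m, seq, threshold=thr)
    # ~q x 2 x 20k windows expected before the non-overlap selection
    assert len(hits) <= 200
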