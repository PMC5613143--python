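"""Motif profiling: dedup/ranking, windows, occurrence matrix, smoothing,
hypergeometric enrichment."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matdosage.motif import (
    OccurrenceMatrix,
    build_occurrence_matrix,
    dedupe_and_rank,
    enrichment_test,
    extract_anchor_window,
    motif_match_positions,
    positional_profile,
    select_sets,
)
from matdosage.records import TranscriptRecord


def _transcript(tid, seq, cds_start=0, stop_start=None):
    if stop_start is None:
        stop_start = len(seq) - 3
    return TranscriptRecord(tid, f"gene_{tid}", seq, cds_start, stop_start)


# -------------------------------------------------------- dedupe & rank

def test_highest_absolute_fold_change_isoform_retained():
    results = pd.DataFrame(
        {"transcript_id": ["t1", "t2"], "gene_id": ["g1", "g1"],
         "log2FC": [1.2, 0.3]}
    )
    seqs = {"t1": "AAAA", "t2": "CCCC"}
    ranked = dedupe_and_rank(results, seqs)
    assert list(ranked["transcript_id"]) == ["t1"]


def test_identical_sequences_keep_first_ranked_only():
    results = pd.DataFrame(
        {"transcript_id": ["t1", "t2"], "gene_id": ["g1", "g2"],
         "log2FC": [2.0, 1.0]}
    )
    seqs = {"t1": "AAAA", "t2": "AAAA"}
    ranked = dedupe_and_rank(results, seqs)
    assert list(ranked["transcript_id"]) == ["t1"]


def test_missing_sequence_error_lists_genes():
    results = pd.DataFrame(
        {"transcript_id": ["t1"], "gene_id": ["g9"], "log2FC": [1.0]}
    )
    with pytest.raises(ValueError, match="g9"):
        dedupe_and_rank(results, {})


def test_dedupe_matches_brute_force_two_pass_oracle():
    rng = np.random.default_rng(61)
    rows, seqs = [], {}
    for g in range(200):
        for i in range(rng.integers(1, 4)):
            tid = f"t{g}_{i}"
            rows.append({"transcript_id": tid, "gene_id": f"g{g}",
                         "log2FC": float(rng.normal())})
            # a small sequence pool forces cross-gene duplicates
            seqs[tid] = "".join(rng.choice(list("ACGU"), 6))
    results = pd.DataFrame(rows)
    ranked = dedupe_and_rank(results, seqs)

    # oracle pass 1: best isoform per gene
    best = {}
    for r in rows:
        g = r["gene_id"]
        cur = best.get(g)
        if (cur is None or abs(r["log2FC"]) > abs(cur["log2FC"])
                or (abs(r["log2FC"]) == abs(cur["log2FC"])
                    and r["transcript_id"] < cur["transcript_id"])):
            best[g] = r
    # oracle pass 2: signed sort, then first occurrence of each sequence
    chosen = sorted(best.values(),
                    key=lambda r: (-r["log2FC"], r["transcript_id"]))
    seen, expect = set(), []
    for r in chosen:
        if seqs[r["transcript_id"]] not in seen:
            seen.add(seqs[r["transcript_id"]])
            expect.append(r["transcript_id"])
    assert list(ranked["transcript_id"]) == expect
    assert ranked["gene_id"].is_unique
    assert (ranked["log2FC"].diff().dropna() <= 1e-12).all()


# ----------------------------------------------------------- set blocks

def _ranked(n):
    return pd.DataFrame(
        {"transcript_id": [f"t{i}" for i in range(n)],
         "gene_id": [f"g{i}" for i in range(n)],
         "log2FC": np.linspace(5, -5, n)}
    )


def test_exact_tiling_center_block():
    sets = select_sets(_ranked(3000), set_size=1000)
    assert list(sets["center"]["transcript_id"]) == [
        f"t{i}" for i in range(1000, 2000)
    ]


def test_floor_convention_for_odd_lengths():
    sets = select_sets(_ranked(3001), set_size=1000)
    assert list(sets["center"]["transcript_id"]) == [
        f"t{i}" for i in range(1000, 2000)
    ]


def test_minimal_sets_on_three_transcripts():
    sets = select_sets(_ranked(3), set_size=1)
    assert list(sets["up"]["transcript_id"]) == ["t0"]
    assert list(sets["center"]["transcript_id"]) == ["t1"]
    assert list(sets["down"]["transcript_id"]) == ["t2"]


def test_sets_are_disjoint_and_down_is_reversed():
    sets = select_sets(_ranked(3500), set_size=1000)
    ids = [set(s["transcript_id"]) for s in sets.values()]
    assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])
    assert list(sets["down"]["transcript_id"])[0] == "t3499"


def test_insufficient_list_length_rejected():
    with pytest.raises(ValueError, match="need >= 3000"):
        select_sets(_ranked(2999), set_size=1000)


# -------------------------------------------------------------- windows

def test_interior_anchor_is_a_pure_slice():
    seq = "".join(np.random.default_rng(0).choice(list("ACGU"), 1000))
    seq = seq[:500] + "UAA" + seq[503:]
    t = _transcript("t1", seq, cds_start=10, stop_start=500)
    w = extract_anchor_window(t, "stop_codon", flank_len=400)
    assert w.sequence == seq[100:900]
    assert w.n_pad_left == w.n_pad_right == 0


def test_left_padding_when_anchor_is_close_to_five_prime():
    seq = "A" * 1000
    t = _transcript("t1", seq, cds_start=10, stop_start=100)
    w = extract_anchor_window(t, "stop_codon", flank_len=400)
    assert w.n_pad_left == 300
    assert w.sequence[:300] == "N" * 300
    assert len(w.sequence) == 800


def test_right_padding_at_three_prime_end_matches_slice_oracle():
    rng = np.random.default_rng(67)
    for _ in range(20):
        n = int(rng.integers(50, 1200))
        seq = "".join(rng.choice(list("ACGU"), n))
        stop = int(rng.integers(1, n - 2))
        t = _transcript("t", seq, cds_start=0, stop_start=stop)
        for anchor, a in (("stop_codon", stop), ("start_codon", 0)):
            w = extract_anchor_window(t, anchor, flank_len=400)
            expect = ("N" * max(0, 400 - a)
                      + seq[max(0, a - 400): min(n, a + 400)]
                      + "N" * max(0, a + 400 - n))
            assert w.sequence == expect
            assert len(w.sequence) == 800


def test_terminal_stop_right_pad_is_flank_minus_three():
    seq = "A" * 500
    t = _transcript("t1", seq, cds_start=0, stop_start=497)
    w = extract_anchor_window(t, "stop_codon", flank_len=400)
    assert w.n_pad_right == 397


# -------------------------------------------------------------- matcher

@pytest.mark.parametrize(
    "window,expected",
    [
        ("GACU", [0]),
        ("GACA", [0]),
        ("GACG", []),
        ("GACUGACA", [0, 4]),
        ("GACACU", [0]),
        ("NACU", []),
        ("GACN", []),
    ],
)
def test_single_site_matches(window, expected):
    assert motif_match_positions(window) == expected


def test_overlapping_matches_all_count():
    assert motif_match_positions("GACUACU", "AC[UA]") == [1, 4]


def test_malformed_pattern_rejected():
    with pytest.raises(ValueError):
        motif_match_positions("GACU", "GAC[")


# ----------------------------------------------------- occurrence matrix

def _random_members(rng, n, length=900):
    transcripts = {}
    rows = []
    for i in range(n):
        seq = "".join(rng.choice(list("ACGU"), length))
        seq = seq[:600] + "UAA" + seq[603:]
        tid = f"t{i}"
        transcripts[tid] = _transcript(tid, seq, cds_start=30, stop_start=600)
        rows.append({"transcript_id": tid, "gene_id": f"g{i}", "log2FC": 0.0})
    return pd.DataFrame(rows), transcripts


def test_matrix_shape_is_set_size_by_twice_flank():
    rng = np.random.default_rng(71)
    members, transcripts = _random_members(rng, 40)
    occ = build_occurrence_matrix(members, transcripts, flank_len=400)
    assert occ.shape == (40, 800)


def test_absent_pattern_gives_all_zero_matrix():
    members = pd.DataFrame(
        {"transcript_id": ["t0"], "gene_id": ["g0"], "log2FC": [0.0]}
    )
    transcripts = {"t0": _transcript("t0", "A" * 400 + "UAA" + "A" * 200,
                                     cds_start=0, stop_start=400)}
    occ = build_occurrence_matrix(members, transcripts)
    assert occ.matrix.sum() == 0


def test_matrix_rows_agree_with_match_positions():
    rng = np.random.default_rng(73)
    members, transcripts = _random_members(rng, 25)
    occ = build_occurrence_matrix(members, transcripts)
    for i, tid in enumerate(occ.transcript_ids):
        w = extract_anchor_window(transcripts[tid], "stop_codon", 400)
        expected = motif_match_positions(w.sequence)
        assert list(np.flatnonzero(occ.matrix[i])) == expected


def test_matrix_is_row_permutation_equivariant():
    rng = np.random.default_rng(79)
    members, transcripts = _random_members(rng, 30)
    occ = build_occurrence_matrix(members, transcripts)
    perm = rng.permutation(30)
    occ_p = build_occurrence_matrix(members.iloc[perm], transcripts)
    np.testing.assert_array_equal(occ_p.matrix, occ.matrix[perm])


# -------------------------------------------------------------- profile

def _occ_from_matrix(mat):
    return OccurrenceMatrix(
        set_label="x", anchor="stop_codon", flank_len=mat.shape[1] // 2,
        pattern="GAC[UA]", transcript_ids=[f"t{i}" for i in range(mat.shape[0])],
        matrix=mat.astype(np.uint8),
    )


def test_constant_profile_is_reproduced_by_the_spline():
    mat = np.ones((7, 100), dtype=np.uint8)
    prof = positional_profile(_occ_from_matrix(mat))
    np.testing.assert_allclose(prof.smoothed, 7.0, atol=1e-6 * 7)


def test_spline_recovers_a_planted_bump_location():
    rng = np.random.default_rng(83)
    cols = 800
    x = np.arange(cols) - 400
    lam = 50.0 * np.exp(-0.5 * (x / 30.0) ** 2) + 5.0
    raw = rng.poisson(lam).astype(np.uint8)[None, :]
    # single-row matrix whose column sums equal the noisy bump
    prof = positional_profile(_occ_from_matrix(np.clip(raw, 0, 1) * 0 + raw))
    peak_offset = prof.offsets[np.argmax(prof.smoothed)]
    assert abs(peak_offset) <= 25


def test_infinite_smoothing_tends_to_the_least_squares_line():
    rng = np.random.default_rng(89)
    mat = rng.integers(0, 2, size=(40, 200))
    occ = _occ_from_matrix(mat)
    prof = positional_profile(occ, smooth_param=1e12)
    raw = occ.matrix.sum(axis=0).astype(float)
    x = prof.offsets.astype(float)
    slope, intercept = np.polyfit(x, raw, 1)
    line = np.clip(slope * x + intercept, 0, None)
    np.testing.assert_allclose(prof.smoothed, line, atol=1e-3 * max(1, raw.max()))


def test_loess_smoother_runs_and_preserves_length():
    rng = np.random.default_rng(97)
    mat = rng.integers(0, 2, size=(20, 300))
    prof = positional_profile(_occ_from_matrix(mat), smoother="loess")
    assert prof.smoothed.shape == (300,)
    assert (prof.smoothed >= 0).all()


def test_too_few_columns_rejected():
    with pytest.raises(ValueError, match="10"):
        positional_profile(_occ_from_matrix(np.ones((3, 8))))


# ----------------------------------------------------------- enrichment

def exact_hypergeom_upper_tail(k, N, K, n):
    """Factorial enumeration oracle, exact rational arithmetic."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i),
                          math.comb(N, n))
    return total


def _occ_with_hits(n_rows, hit_rows, col=400):
    mat = np.zeros((n_rows, 800), dtype=np.uint8)
    mat[list(hit_rows), col] = 1
    return _occ_from_matrix(mat)


def test_zero_hits_give_unit_p():
    res = enrichment_test(_occ_with_hits(10, []), _occ_with_hits(10, range(5)))
    assert res.k == 0
    assert res.p_value == 1.0


def test_exact_combinatorial_example():
    res = enrichment_test(_occ_with_hits(10, range(9)), _occ_with_hits(10, [0]))
    assert (res.N, res.n, res.K, res.k) == (20, 10, 10, 9)
    expected = float(exact_hypergeom_upper_tail(9, 20, 10, 10))
    assert res.p_value == pytest.approx(expected, rel=1e-12)


def test_hypergeometric_matches_enumeration_on_a_grid():
    rng = np.random.default_rng(101)
    for _ in range(150):
        N = int(rng.integers(2, 61))
        n = int(rng.integers(1, N))
        K = int(rng.integers(0, N + 1))
        k_max = min(K, n)
        k = int(rng.integers(0, k_max + 1))
        from scipy import stats

        p = float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))
        exact = float(exact_hypergeom_upper_tail(k, N, K, n))
        assert p == pytest.approx(exact, rel=1e-12, abs=1e-300)


def test_p_is_monotone_nonincreasing_in_k():
    last = 1.1
    for k in range(0, 11):
        res = enrichment_test(
            _occ_with_hits(10, range(k)), _occ_with_hits(10, range(5))
        )
        assert res.p_value <= last + 1e-15
        last = res.p_value


def test_hits_outside_the_region_do_not_count():
    test_occ = _occ_with_hits(10, range(10), col=780)  # beyond +-50 default band
    ref_occ = _occ_with_hits(10, [])
    res = enrichment_test(test_occ, ref_occ)
    assert res.k == 0
    res_wide = enrichment_test(test_occ, ref_occ, region=(0, 800))
    assert res_wide.k == 10


def test_empty_region_rejected():
    with pytest.raises(ValueError, match="region"):
        enrichment_test(_occ_with_hits(5, []), _occ_with_hits(5, []),
                        region=(10, 10))


def test_mismatched_widths_rejected():
    a = _occ_with_hits(5, [])
    b = OccurrenceMatrix("y", "stop_codon", 200, "GAC[UA]",
                         ["t0"], np.zeros((1, 400), dtype=np.uint8))
    with pytest.raises(ValueError, match="width"):
        enrichment_test(a, b)
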