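import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import binom_upper_tail
from skipedit import editing_quant as eq
from skipedit import synthetic_fixtures as sf


def _pair(name, s1, q1, s2=None, q2=None):
    s2 = s2 if s2 is not None else s1
    q2 = q2 if q2 is not None else q1
    return eq.ReadPair(name, s1, tuple(q1), s2, tuple(q2))


PRIMERS = {"amp1": ("ACGTACGT", "TTTTCCCC"), "amp2": ("GGGGAAAA", "CCCCTTTT")}


@pytest.mark.parametrize("n_mm,expected_bin", [(0, "amp1"), (1, "amp1"),
                                               (2, "unassigned")])
def test_demultiplex_primer_mismatch_threshold(n_mm, expected_bin):
    fwd = list("ACGTACGT")
    for i in range(n_mm):
        fwd[i] = "T" if fwd[i] != "T" else "A"
    pair = _pair("r", "".join(fwd) + "A" * 20, [30] * 28,
                 "TTTTCCCC" + "A" * 20, [30] * 28)
    bins = eq.demultiplex_by_primer([pair], PRIMERS, max_mismatches=1)
    assert [b for b, reads in bins.items() if reads] == [expected_bin]


def test_demultiplex_ambiguous_pair_is_unassigned():
    table = {"a": ("AAAA", "TTTT"), "b": ("AAAT", "TTTA")}
    pair = _pair("r", "AAAA" + "G" * 20, [30] * 24, "TTTT" + "G" * 20, [30] * 24)
    bins = eq.demultiplex_by_primer([pair], table, max_mismatches=1)
    assert len(bins["unassigned"]) == 1


def test_demultiplex_swapped_mates_still_assign():
    pair = _pair("r", "TTTTCCCC" + "A" * 20, [30] * 28,
                 "ACGTACGT" + "A" * 20, [30] * 28)
    bins = eq.demultiplex_by_primer([pair], PRIMERS, max_mismatches=0)
    assert len(bins["amp1"]) == 1


def test_identical_primers_are_a_hard_error():
    with pytest.raises(eq.QuantError, match="identical"):
        eq.demultiplex_by_primer([], {"a": ("AAAA", "TTTT"),
                                      "b": ("AAAA", "GGGG")})


def test_trim_strips_low_quality_tail():
    seq, quals = eq.trim_read("A" * 100, [30] * 90 + [10] * 10, 20)
    assert len(seq) == 90


@pytest.mark.parametrize("final_len,kept", [(50, False), (51, True)])
def test_pair_discarded_at_fifty_bp_boundary(final_len, kept):
    quals = [30] * final_len + [5] * (100 - final_len)
    pairs = eq.trim_and_filter([_pair("r", "A" * 100, quals)])
    assert bool(pairs) is kept


@given(st.lists(st.integers(min_value=0, max_value=41), min_size=1, max_size=80))
def test_trimming_is_idempotent(quals):
    seq = "A" * len(quals)
    once = eq.trim_read(seq, quals, 20)
    assert eq.trim_read(*once, 20) == once


def test_quality_string_length_mismatch_is_error():
    with pytest.raises(eq.QuantError, match="length mismatch"):
        _pair("r", "ACGT", [30] * 3)


def _window(ref, counts, start=0):
    return eq.PileupWindow(contig="c", start=start, end=start + len(ref),
                           ref=ref, counts=np.asarray(counts, dtype=np.int64))


def test_pileup_counting_and_alt_fraction():
    # 10 reads at an A position, 3 carry G
    win = _window("A", [[7, 0, 3, 0]])
    assert win.depth[0] == 10
    assert win.alt_depth[0] == 3
    assert win.alt_fraction[0] == pytest.approx(0.3)


def test_pileup_window_matches_simulator_truth(toy, tmp_path):
    spec = toy.spec
    guide = toy.guides[0]
    amp = sf.simulate_amplicon_reads(toy.genome, "chr1", guide.target_genome_pos,
                                     spec)
    paths = amp.write(str(tmp_path))
    win = eq.build_pileup_window(paths["sam"], toy.genome, "chr1",
                                 (guide.start, guide.start + 20))
    rel = slice(win.start - amp.region_start, win.end - amp.region_start)
    assert (win.counts == amp.truth_counts[rel]).all()
    assert (win.depth == spec.depth).all()


def test_low_quality_bases_excluded_from_pileup(toy, tmp_path):
    guide = toy.guides[0]
    amp = sf.simulate_amplicon_reads(toy.genome, "chr1", guide.target_genome_pos,
                                     toy.spec)
    lines = amp.sam.splitlines()
    body = [l for l in lines if not l.startswith("@")]
    fields = body[0].split("\t")
    fields[10] = "!" * len(fields[10])  # all bases Q0 on one read
    body[0] = "\t".join(fields)
    path = tmp_path / "degraded.sam"
    path.write_text("\n".join([l for l in lines if l.startswith("@")] + body) + "\n")
    win = eq.build_pileup_window(str(path), toy.genome, "chr1",
                                 (guide.start, guide.start + 20))
    assert win.depth.max() <= toy.spec.depth
    assert win.depth.min() >= toy.spec.depth - 1


def test_global_error_is_the_mean_alt_fraction():
    win = _window("AAA", [[999, 0, 1, 0], [998, 0, 2, 0], [997, 0, 3, 0]])
    assert eq.estimate_global_error(win) == pytest.approx(0.002)


def test_global_error_excludes_candidate_positions():
    win = _window("AAA", [[999, 0, 1, 0], [998, 0, 2, 0], [500, 0, 500, 0]])
    assert eq.estimate_global_error(win, exclude_positions=[2]) == pytest.approx(
        0.0015)


def test_global_error_all_reference_is_zero():
    win = _window("AA", [[100, 0, 0, 0], [100, 0, 0, 0]])
    assert eq.estimate_global_error(win) == 0.0


def test_global_error_without_coverage_is_error():
    win = _window("A", [[0, 0, 0, 0]])
    with pytest.raises(eq.QuantError):
        eq.estimate_global_error(win)


def test_positional_error_from_control():
    control = _window("A", [[998, 0, 2, 0]], start=5)
    assert eq.estimate_positional_error(control, 5) == pytest.approx(0.002)
    assert eq.estimate_positional_error(None, 5) is None
    empty = _window("A", [[0, 0, 0, 0]], start=5)
    assert eq.estimate_positional_error(empty, 5) is None
    with pytest.raises(eq.QuantError):
        eq.estimate_positional_error(control, 99)


def test_no_conversions_give_p_value_one():
    win = _window("A", [[1000, 0, 0, 0]])
    (call,) = eq.call_conversions(win, [0], global_err=0.002)
    assert call.p_value == pytest.approx(1.0)
    assert not call.significant


def test_single_conversion_p_value_is_exact_tail():
    win = _window("A", [[99, 0, 1, 0]])
    (call,) = eq.call_conversions(win, [0], global_err=0.01)
    assert call.p_value == pytest.approx(1 - 0.99 ** 100)
    assert not call.significant


def test_strong_editing_is_significant_and_matches_summation_oracle():
    win = _window("A", [[475, 0, 25, 0]])
    (call,) = eq.call_conversions(win, [0], global_err=0.002)
    assert call.p_value == pytest.approx(binom_upper_tail(25, 500, 0.002), rel=1e-9)
    assert call.p_value < 1e-5 and call.significant
    assert call.rate == pytest.approx(0.05)


def test_t_to_c_conversion_uses_the_complementary_base():
    win = _window("T", [[0, 30, 0, 970]])
    (call,) = eq.call_conversions(win, [0], global_err=0.002)
    assert call.conversion == "T>C"
    assert call.alt_depth == 30


def test_background_is_max_of_global_and_positional():
    win = _window("A", [[990, 0, 10, 0]])
    (call,) = eq.call_conversions(win, [0], global_err=0.001,
                                  positional_err={0: 0.004})
    assert call.background == pytest.approx(0.004)


def test_zero_depth_target_is_flagged_not_significant():
    win = _window("A", [[0, 0, 0, 0]])
    (call,) = eq.call_conversions(win, [0], global_err=0.002)
    assert math.isnan(call.rate) and not call.significant


def test_p_value_monotone_in_k_and_background():
    def p(k, p0):
        win = _window("A", [[1000 - k, 0, k, 0]])
        return eq.call_conversions(win, [0], global_err=p0)[0].p_value

    ps = [p(k, 0.002) for k in range(0, 20, 2)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
    ps = [p(5, p0) for p0 in (0.0005, 0.001, 0.002, 0.01)]
    assert all(a <= b for a, b in zip(ps, ps[1:]))
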