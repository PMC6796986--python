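import numpy as np
import pytest

from _oracles import brute_force_guides
from skipedit import genome_io as gio
from skipedit import guide_design as gd
from skipedit import offtarget as ot
from skipedit import synthetic_fixtures as sf


def _inner_exon(contig, strand, start, end, genome=None):
    if strand == "+":
        a, g = start - 2, start - 1
    else:
        a, g = end + 1, end
    exon = gio.InnerExon(contig=contig, strand=strand, start=start, end=end,
                         acceptor_A_pos=a, acceptor_G_pos=g)
    if genome is not None:
        exons = gio.enumerate_inner_exons  # noqa: F841 (documentation only)
    return exon


def test_single_planted_locus_yields_one_guide_at_position_five():
    # intron ...CCTTAG | exon GATCGATCGATCGA then TGG PAM inside the exon
    seq = "TTTT" + "CCTTAG" + "GATCGATCGATCGA" + "TGG" + "TTTT"
    genome = gio.Genome({"chr1": seq})
    exon = _inner_exon("chr1", "+", 10, 27)
    exon.canonical = True
    cands = gd.find_protospacers(genome, exon, "ABE", window=range(4, 10))
    assert len(cands) == 1
    (c,) = cands
    assert c.protospacer == "CCTTAGGATCGATCGATCGA"
    assert c.pam == "TGG"
    assert c.target_pos == 5
    assert c.target_genome_pos == 8
    oracle = brute_force_guides(genome, exon, "ABE", range(4, 10))
    assert {(c.start, c.guide_strand, c.target_pos, c.protospacer, c.pam)} == oracle


def test_non_canonical_acceptor_yields_nothing():
    seq = "TTTT" + "CCTTGG" + "GATCGATCGATCGA" + "TGG" + "TTTT"
    genome = gio.Genome({"chr1": seq})
    exon = _inner_exon("chr1", "+", 10, 27)
    exon.canonical = False
    assert gd.find_protospacers(genome, exon, "ABE", window=range(4, 10)) == []


def test_found_guides_match_truth_on_toy_genome(toy, toy_inner_exons):
    found = []
    for exon in toy_inner_exons:
        for mode in gd.MODES:
            found.extend(gd.find_protospacers(toy.genome, exon, mode))
    got = {(c.exon_key, c.mode, c.target_pos, c.start, c.guide_strand,
            c.protospacer, c.pam) for c in found}
    want = {(g.exon_key, g.mode, g.position, g.start, g.guide_strand,
             g.protospacer, g.pam) for g in toy.guides}
    assert got == want


def test_guides_relocate_exactly_at_reported_coordinates(toy, toy_inner_exons):
    seq = toy.genome.sequences["chr1"]
    for exon in toy_inner_exons:
        for mode in gd.MODES:
            for c in gd.find_protospacers(toy.genome, exon, mode):
                if c.guide_strand == "+":
                    assert seq[c.start:c.start + 20] == c.protospacer
                    assert seq[c.start + 20:c.start + 23] == c.pam
                else:
                    assert gio.revcomp(seq[c.start:c.start + 20]) == c.protospacer
                    assert gio.revcomp(seq[c.start - 3:c.start]) == c.pam


def test_editing_the_target_base_destroys_the_acceptor(toy, toy_inner_exons):
    abe = [g for g in toy.guides if g.mode == "ABE"]
    for g in abe:
        chars = list(toy.genome.sequences["chr1"])
        # A->G on the guide strand; on the plus strand of the genome this is
        # A->G for plus-strand guides and T->C for minus-strand guides
        chars[g.target_genome_pos] = (
            "G" if chars[g.target_genome_pos] == "A" else "C")
        edited = gio.Genome({"chr1": "".join(chars)})
        inner = gio.enumerate_inner_exons(toy.transcripts, edited)
        flags = {e.exon_key: e.canonical for e in inner}
        assert flags[g.exon_key] is False


def test_candidate_count_monotone_as_window_shrinks(toy, toy_inner_exons):
    for exon in toy_inner_exons:
        wide = gd.find_protospacers(toy.genome, exon, "ABE", window=range(4, 10))
        for lo, hi in [(4, 9), (5, 8), (6, 7)]:
            narrow = gd.find_protospacers(toy.genome, exon, "ABE",
                                          window=range(lo, hi + 1))
            assert len(narrow) <= len(wide)
            assert {c.target_pos for c in narrow} <= {c.target_pos for c in wide}


@pytest.mark.parametrize("position,expect", [(5, 50.0), (12, 0.0)])
def test_efficiency_lookup_and_window_boundary(position, expect):
    table = gd.EfficiencyTable("ABE", {4: 10.0, 5: 50.0, 6: 40.0}, 50.0)
    assert table.efficiency(position) == expect


def test_relative_efficiencies_scale_by_maximum():
    table = gd.EfficiencyTable.from_relative("ABE", {5: 0.8}, 50.0)
    assert table.efficiency(5) == pytest.approx(40.0)


def test_default_tables_cover_the_documented_windows():
    assert gd.EfficiencyTable.default("ABE").positions == (4, 5, 6, 7, 8, 9)
    assert gd.EfficiencyTable.default("BE3").positions == (4, 5, 6, 7, 8)


@pytest.fixture()
def two_guide_exon():
    """A toy gene whose single inner exon carries ABE guides at 5 and 6."""
    spec = sf.FixtureSpec(
        seed=21, n_genes=1, exons_per_gene=3, alternate_strands=False,
        guide_layout=(sf.PlantedGuide(0, 0, "ABE", 5),
                      sf.PlantedGuide(0, 0, "ABE", 6)))
    toy = sf.make_toy_genome(spec)
    inner = gio.enumerate_inner_exons(toy.transcripts, toy.genome)
    return toy, inner


def test_efficiency_threshold_is_strictly_above(two_guide_exon):
    toy, inner = two_guide_exon
    table = gd.EfficiencyTable("ABE", {5: 30.0, 6: 31.0}, 31.0)
    cands, summary = gd.design_for_exons(
        toy.genome, inner, "ABE", table=table, eff_threshold=30.0,
        attach_offtargets=False)
    passing = cands[cands.passes]
    assert list(passing.target_pos) == [6]
    assert summary.iloc[0].targetable


def test_offtarget_threshold_keeps_exactly_ten(two_guide_exon, monkeypatch):
    toy, inner = two_guide_exon
    scores = iter([10.0, 10.1])
    monkeypatch.setattr(ot, "enumerate_offtargets", lambda *a, **k: [])
    monkeypatch.setattr(ot, "aggregate_offtarget_score",
                        lambda hits, locus: next(scores))
    table = gd.EfficiencyTable("ABE", {5: 40.0, 6: 40.0}, 40.0)
    cands, _ = gd.design_for_exons(toy.genome, inner, "ABE", table=table,
                                   ot_threshold=10.0)
    passing = cands[cands.passes]
    assert list(passing.target_pos) == [5]
    assert list(cands[cands.best].target_pos) == [5]


def test_untargetable_exon_is_reported(two_guide_exon):
    toy, inner = two_guide_exon
    table = gd.EfficiencyTable("ABE", {5: 10.0, 6: 10.0}, 10.0)
    cands, summary = gd.design_for_exons(
        toy.genome, inner, "ABE", table=table, attach_offtargets=False)
    assert not cands.passes.any()
    assert not summary.targetable.any()
    assert len(summary) == len(inner)


def test_best_guide_tie_breaks_to_lower_offtarget_then_5prime(two_guide_exon,
                                                              monkeypatch):
    toy, inner = two_guide_exon
    scores = iter([5.0, 2.0])
    monkeypatch.setattr(ot, "enumerate_offtargets", lambda *a, **k: [])
    monkeypatch.setattr(ot, "aggregate_offtarget_score",
                        lambda hits, locus: next(scores))
    table = gd.EfficiencyTable("ABE", {5: 40.0, 6: 40.0}, 40.0)
    cands, _ = gd.design_for_exons(toy.genome, inner, "ABE", table=table)
    assert list(cands[cands.best].target_pos) == [6]  # equal eff, lower score


def test_design_report_is_deterministically_ordered(toy, toy_inner_exons):
    a, _ = gd.design_for_exons(toy.genome, toy_inner_exons, "ABE",
                               attach_offtargets=False)
    b, _ = gd.design_for_exons(toy.genome, toy_inner_exons[::-1], "ABE",
                               attach_offtargets=False)
    assert a.equals(b)
    keys = list(zip(a["exon_key"], a["mode"], a["target_pos"], a["guide_strand"]))
    assert keys == sorted(keys)
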