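"""Protospacer discovery and on-target efficiency prediction.

An adenine base editor (ABE) disrupts a splice acceptor by converting the
conserved intronic A of the acceptor AG to G; a cytidine editor (BE3)
disrupts the conserved G by converting the complementary C on the
antisense strand to T.  Either way the protospacer must place the target
base inside the editor's active window (1-based protospacer positions,
PAM-distal = 1, NGG PAM at positions 21-23).

ABE guides therefore lie on the transcript sense strand (where the
acceptor base reads A); BE3 guides lie on the antisense strand (where the
conserved G reads C).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import Genome, GenomeError, InnerExon, extract_sequence, format_exon_key

log = logging.getLogger(__name__)

MODES = ("ABE", "BE3")
PROTOSPACER_LEN = 20
PAM_LEN = 3

#: Default on-target efficiency filter: strictly above 30 %.
DEFAULT_EFFICIENCY_THRESHOLD = 30.0
#: Default specificity filter: guides with aggregate off-target score
#: above 10 are removed (score <= 10 kept).
DEFAULT_OFFTARGET_THRESHOLD = 10.0


@dataclass(frozen=True)
class EfficiencyTable:
    """Predicted editing efficiency (%) per protospacer window position.

    Positions absent from ``window`` have efficiency 0.  ``max_efficiency``
    records the scalar (%) used to scale relative per-position activities.
    """

    mode: str
    window: Mapping[int, float]
    max_efficiency: float

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown editor mode {self.mode!r}")
        for pos, val in self.window.items():
            if not 1 <= pos <= PROTOSPACER_LEN:
                raise ValueError(f"window position {pos} outside protospacer")
            if not 0.0 <= val <= 100.0:
                raise ValueError(f"efficiency {val} at position {pos} not in [0,100]")

    def efficiency(self, position: int) -> float:
        return float(self.window.get(position, 0.0))

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.window))

    @classmethod
    def from_relative(cls, mode: str, relative: Mapping[int, float],
                      max_efficiency: float) -> "EfficiencyTable":
        window = {int(p): float(r) * max_efficiency for p, r in relative.items()}
        return cls(mode=mode, window=window, max_efficiency=max_efficiency)

    @classmethod
    def default(cls, mode: str) -> "EfficiencyTable":
        """Built-in table (see data/efficiency_tables.json for provenance)."""
        text = resources.files("skipedit.data").joinpath(
            "efficiency_tables.json").read_text()
        return cls._from_config(mode, json.loads(text))

    @classmethod
    def from_json(cls, path, mode: str) -> "EfficiencyTable":
        with open(path) as fh:
            return cls._from_config(mode, json.load(fh))

    @classmethod
    def _from_config(cls, mode: str, cfg: dict) -> "EfficiencyTable":
        if mode not in cfg:
            raise KeyError(f"no efficiency table for mode {mode!r}")
        entry = cfg[mode]
        return cls.from_relative(mode, {int(k): v for k, v in entry["relative"].items()},
                                 float(entry["max_efficiency"]))


@dataclass
class GuideCandidate:
    """A 20-nt protospacer + NGG PAM disrupting one splice acceptor.

    ``protospacer`` is read 5'->3' on ``guide_strand``; the target base
    (A for ABE, C for BE3) sits at 1-based ``target_pos`` within it.
    ``start`` is the 0-based genome coordinate of the protospacer 20-mer.
    """

    exon_key: tuple
    mode: str
    contig: str
    guide_strand: str
    start: int
    protospacer: str
    pam: str
    target_pos: int
    target_genome_pos: int
    predicted_efficiency: float
    offtarget_score: float | None = None
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != PAM_LEN or not self.pam.endswith("GG"):
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        base = self.protospacer[self.target_pos - 1]
        need = "A" if self.mode == "ABE" else "C"
        if base != need:
            raise ValueError(
                f"target base at position {self.target_pos} is {base!r}, "
                f"expected {need!r} for {self.mode}"
            )


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def find_protospacers(genome: Genome, inner_exon: InnerExon, mode: str,
                      table: EfficiencyTable | None = None,
                      window: Iterable[int] | None = None) -> list[GuideCandidate]:
    """All guides placing the acceptor target base in the editing window.

    For each window position p a candidate exists iff the 20-mer that puts
    the target base at protospacer position p is followed by an NGG PAM
    and contains no N.  Non-canonical acceptors yield no candidates.
    Acceptors too close to a contig edge are skipped with a warning.
    """
    if mode not in MODES:
        raise ValueError(f"unknown editor mode {mode!r}")
    if table is None and window is None:
        table = EfficiencyTable.default(mode)
    if table is not None and table.mode != mode:
        raise ValueError(f"table mode {table.mode} does not match {mode}")
    positions = sorted(window) if window is not None else list(table.positions)
    if not positions:
        raise ValueError("empty editing window")
    if inner_exon.canonical is False:
        return []

    if mode == "ABE":
        guide_strand = inner_exon.strand
        target = inner_exon.acceptor_A_pos
    else:
        guide_strand = _flip(inner_exon.strand)
        target = inner_exon.acceptor_G_pos

    seq = genome.sequences[inner_exon.contig]
    length = len(seq)
    out: list[GuideCandidate] = []
    for p in positions:
        if guide_strand == "+":
            s = target - (p - 1)
            lo, hi = s, s + PROTOSPACER_LEN + PAM_LEN
        else:
            s = target + p - PROTOSPACER_LEN
            lo, hi = s - PAM_LEN, s + PROTOSPACER_LEN
        if lo < 0 or hi > length:
            log.warning(
                "acceptor at %s too close to contig edge for window position %d; skipped",
                format_exon_key(inner_exon.exon_key), p,
            )
            continue
        if guide_strand == "+":
            pam = seq[s + PROTOSPACER_LEN:s + PROTOSPACER_LEN + PAM_LEN]
            proto = seq[s:s + PROTOSPACER_LEN]
        else:
            pam = extract_sequence(genome, inner_exon.contig, s - PAM_LEN, s, "-")
            proto = extract_sequence(genome, inner_exon.contig, s, s + PROTOSPACER_LEN, "-")
        if not pam.endswith("GG"):
            continue
        if "N" in proto or "N" in pam:
            continue
        eff = table.efficiency(p) if table is not None else 0.0
        out.append(GuideCandidate(
            exon_key=inner_exon.exon_key, mode=mode, contig=inner_exon.contig,
            guide_strand=guide_strand, start=s, protospacer=proto, pam=pam,
            target_pos=p, target_genome_pos=target,
            predicted_efficiency=eff, gene_ids=inner_exon.gene_ids,
        ))
    return out


def predict_editing_efficiency(candidate: GuideCandidate,
                               table: EfficiencyTable) -> float:
    """Table lookup at the candidate's target position; 0 outside the window."""
    if candidate.mode != table.mode:
        raise ValueError(
            f"candidate mode {candidate.mode} does not match table {table.mode}"
        )
    return table.efficiency(candidate.target_pos)


_REPORT_COLUMNS = [
    "exon_key", "gene_ids", "mode", "protospacer", "pam", "guide_strand",
    "contig", "start", "target_pos", "target_genome_pos",
    "predicted_efficiency", "offtarget_score", "passes", "best",
]


def design_for_exons(genome: Genome, inner_exons: Sequence[InnerExon], mode: str,
                     table: EfficiencyTable | None = None,
                     eff_threshold: float = DEFAULT_EFFICIENCY_THRESHOLD,
                     ot_threshold: float = DEFAULT_OFFTARGET_THRESHOLD,
                     *, attach_offtargets: bool = True,
                     max_mismatches: int = 2,
                     pam_rules: Sequence[str] = ("NGG",),
                     weights=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Design and filter guides for a set of inner exons.

    Filtering: predicted efficiency must be strictly above
    ``eff_threshold``; aggregate off-target score must be <=
    ``ot_threshold`` (guides scoring above the threshold are removed).
    Per exon the surviving guide with the highest efficiency is marked
    best; ties break to the lower off-target score, then the 5'-most
    (smallest) target position.

    Returns ``(candidates, exon_summary)`` DataFrames.  Exons with no
    surviving candidate appear in ``exon_summary`` as untargetable.
    """
    from . import offtarget as ot_mod

    if table is None:
        table = EfficiencyTable.default(mode)
    rows = []
    summaries = []
    for exon in inner_exons:
        cands = find_protospacers(genome, exon, mode, table=table)
        if attach_offtargets:
            for c in cands:
                hits = ot_mod.enumerate_offtargets(
                    genome, c.protospacer, pam_rules=pam_rules,
                    max_mismatches=max_mismatches, weights=weights)
                c.offtarget_score = ot_mod.aggregate_offtarget_score(
                    hits, (c.contig, c.start, c.guide_strand))
        cands.sort(key=lambda c: (c.target_pos, c.guide_strand))
        passing = [
            c for c in cands
            if c.predicted_efficiency > eff_threshold
            and (c.offtarget_score is None or c.offtarget_score <= ot_threshold)
        ]
        best = None
        if passing:
            best = min(passing, key=lambda c: (
                -c.predicted_efficiency,
                c.offtarget_score if c.offtarget_score is not None else 0.0,
                c.target_pos,
            ))
        log.info("%s %s: %d candidates, %d pass filters", mode,
                 exon.exon_key_str, len(cands), len(passing))
        for c in cands:
            rows.append({
                "exon_key": format_exon_key(c.exon_key),
                "gene_ids": ",".join(c.gene_ids),
                "mode": c.mode, "protospacer": c.protospacer, "pam": c.pam,
                "guide_strand": c.guide_strand, "contig": c.contig,
                "start": c.start, "target_pos": c.target_pos,
                "target_genome_pos": c.target_genome_pos,
                "predicted_efficiency": c.predicted_efficiency,
                "offtarget_score": c.offtarget_score,
                "passes": c in passing, "best": c is best,
            })
        summaries.append({
            "exon_key": exon.exon_key_str,
            "gene_ids": ",".join(exon.gene_ids),
            "mode": mode,
            "n_candidates": len(cands),
            "n_passing": len(passing),
            "targetable": bool(passing),
            "best_protospacer": best.protospacer if best else "",
            "best_efficiency": best.predicted_efficiency if best else float("nan"),
            "best_offtarget_score": (
                best.offtarget_score if best and best.offtarget_score is not None
                else float("nan")),
        })
    candidates = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    candidates = candidates.sort_values(
        ["exon_key", "mode", "target_pos", "guide_strand"],
        kind="mergesort").reset_index(drop=True)
    summary = pd.DataFrame(summaries)
    return candidates, summary
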