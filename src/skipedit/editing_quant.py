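"""Quantification of base-editing outcomes from amplicon deep sequencing.

Pipeline: demultiplex paired reads by PCR primer, 3'-quality-trim at
Phred 20 and discard pairs with a mate trimmed to 50 bp or less, build a
120-bp pileup window centred on the protospacer from coordinate-sorted
SAM alignments, estimate the sequencing-error background (global mean of
alternative-allele fractions, optionally a position-dependent estimate
from an untreated control), and call significant A>G / T>C conversion
with a one-sided (upper tail) exact binomial test at p < 1e-5 using the
higher of the two error estimates as the null conversion probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from scipy import stats

from .genome_io import Genome

log = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_BASE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i

#: conversion read out at a target position, keyed by reference base
CONVERSIONS = {"A": ("G", "A>G"), "T": ("C", "T>C")}


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class QuantConfig:
    trim_quality: int = 20          # Phred floor for 3' trimming
    min_mate_length: int = 50       # pairs with a mate <= this after trimming are discarded
    window_width: int = 120         # pileup window, centred on the protospacer
    p_cutoff: float = 1e-5          # one-sided binomial significance cutoff
    demux_max_mismatches: int = 1
    min_base_quality: int = 20      # per-base floor inside pileups

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cutoff < 1.0:
            raise ValueError("p_cutoff must lie in (0,1)")
        if self.trim_quality < 0:
            raise ValueError("trim_quality must be >= 0")
        if self.window_width < 20:
            raise ValueError("window_width must cover at least a protospacer")


@dataclass
class ReadPair:
    name: str
    seq1: str
    qual1: tuple[int, ...]
    seq2: str
    qual2: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise QuantError(f"read {self.name}: sequence/quality length mismatch")


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    """Load mate-paired FASTQ (Phred+33) into ReadPair records."""
    r1 = list(SeqIO.parse(str(path1), "fastq"))
    r2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(r1) != len(r2):
        raise QuantError("mate files differ in read count")
    pairs = []
    for a, b in zip(r1, r2):
        pairs.append(ReadPair(
            name=a.id.removesuffix("/1"),
            seq1=str(a.seq), qual1=tuple(a.letter_annotations["phred_quality"]),
            seq2=str(b.seq), qual2=tuple(b.letter_annotations["phred_quality"]),
        ))
    return pairs


def load_primer_table(path) -> dict[str, tuple[str, str]]:
    """TSV ``amplicon<TAB>fwd<TAB>rev``; identical primers are a hard error."""
    table: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("amplicon\t"):
                continue
            name, fwd, rev = line.split("\t")
            table[name] = (fwd.upper(), rev.upper())
    _validate_primer_table(table)
    return table


def _validate_primer_table(table: Mapping[str, tuple[str, str]]) -> None:
    fwds = [p[0] for p in table.values()]
    revs = [p[1] for p in table.values()]
    if len(set(fwds)) != len(fwds) or len(set(revs)) != len(revs):
        raise QuantError("two amplicons share an identical primer sequence")


def _prefix_mismatches(read: str, primer: str) -> int | None:
    if len(read) < len(primer):
        return None
    return sum(a != b for a, b in zip(read, primer))


def demultiplex_by_primer(pairs: Iterable[ReadPair],
                          primer_table: Mapping[str, tuple[str, str]],
                          max_mismatches: int = 1) -> dict[str, list[ReadPair]]:
    """Assign each pair to the unique amplicon whose primers prefix-match.

    Both mate orders are tried.  Pairs matching zero or more than one
    amplicon land in the ``"unassigned"`` bin.
    """
    _validate_primer_table(primer_table)
    bins: dict[str, list[ReadPair]] = {name: [] for name in primer_table}
    bins["unassigned"] = []
    for pair in pairs:
        matches = []
        for name, (fwd, rev) in primer_table.items():
            for s1, s2 in ((pair.seq1, pair.seq2), (pair.seq2, pair.seq1)):
                m1 = _prefix_mismatches(s1, fwd)
                m2 = _prefix_mismatches(s2, rev)
                if (m1 is not None and m1 <= max_mismatches
                        and m2 is not None and m2 <= max_mismatches):
                    matches.append(name)
                    break
        if len(matches) == 1:
            bins[matches[0]].append(pair)
        else:
            bins["unassigned"].append(pair)
    counts = {k: len(v) for k, v in bins.items()}
    log.info("demultiplexed %d pairs: %s", sum(counts.values()), counts)
    return bins


def trim_read(seq: str, quals: Sequence[int], quality: int) -> tuple[str, tuple[int, ...]]:
    """Strip 3'-terminal bases with quality below the threshold."""
    i = len(quals)
    while i > 0 and quals[i - 1] < quality:
        i -= 1
    return seq[:i], tuple(quals[:i])


def trim_and_filter(pairs: Iterable[ReadPair],
                    config: QuantConfig | None = None) -> list[ReadPair]:
    """3'-quality-trim both mates; drop pairs with a short mate.

    A pair is discarded when either mate is trimmed to
    ``min_mate_length`` bp *or less* (the 50-bp boundary itself drops).
    """
    config = config or QuantConfig()
    kept = []
    n_in = 0
    for pair in pairs:
        n_in += 1
        s1, q1 = trim_read(pair.seq1, pair.qual1, config.trim_quality)
        s2, q2 = trim_read(pair.seq2, pair.qual2, config.trim_quality)
        if len(s1) <= config.min_mate_length or len(s2) <= config.min_mate_length:
            continue
        kept.append(ReadPair(pair.name, s1, q1, s2, q2))
    log.info("trimmed %d pairs, kept %d", n_in, len(kept))
    return kept


@dataclass
class PileupWindow:
    """Per-position base counts over a window of the reference."""

    contig: str
    start: int  # 0-based, inclusive
    end: int    # exclusive
    ref: str    # reference bases over [start, end)
    counts: np.ndarray  # (width, 4) int array in A,C,G,T order

    def __post_init__(self) -> None:
        width = self.end - self.start
        if len(self.ref) != width or self.counts.shape != (width, 4):
            raise QuantError("window ref/counts shape mismatch")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.end)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def alt_depth(self) -> np.ndarray:
        ref_idx = _BASE_LUT[np.frombuffer(self.ref.encode(), dtype=np.uint8)]
        depth = self.depth
        ref_count = np.where(
            ref_idx >= 0,
            self.counts[np.arange(len(self.ref)), np.clip(ref_idx, 0, 3)],
            0)
        return depth - ref_count

    @property
    def alt_fraction(self) -> np.ndarray:
        """alt_depth / depth, 0 where depth is 0 (flag via ``depth``)."""
        depth = self.depth
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(depth > 0, self.alt_depth / np.maximum(depth, 1), 0.0)
        return frac

    def index_of(self, position: int) -> int:
        if not self.start <= position < self.end:
            raise QuantError(
                f"position {position} outside window [{self.start},{self.end})")
        return position - self.start

    def base_count(self, position: int, base: str) -> int:
        return int(self.counts[self.index_of(position), _BASE_INDEX[base]])


def build_pileup_window(alignments, genome: Genome, contig: str,
                        protospacer_interval: tuple[int, int],
                        config: QuantConfig | None = None) -> PileupWindow:
    """Count aligned bases per position over a window centred on a guide.

    ``alignments`` is a SAM/BAM path or an open ``pysam.AlignmentFile``,
    coordinate-sorted.  Bases below ``min_base_quality`` are ignored;
    deletions and reference skips do not contribute to depth.  Windows
    extending past the contig are truncated with a warning.
    """
    config = config or QuantConfig()
    ps, pe = protospacer_interval
    center = (ps + pe) // 2
    start = center - config.window_width // 2
    end = start + config.window_width
    length = genome.length(contig)
    if start < 0 or end > length:
        log.warning("window [%d,%d) truncated to contig %s bounds", start, end, contig)
        start, end = max(start, 0), min(end, length)
    width = end - start
    counts = np.zeros((width, 4), dtype=np.int64)

    own = isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__")
    af = pysam.AlignmentFile(str(alignments), "r") if own else alignments
    try:
        for read in af.fetch(until_eof=True):
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.reference_name != contig):
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            if seq is None or quals is None:
                continue
            cig = read.cigartuples
            if cig is not None and len(cig) == 1 and cig[0][0] == 0:
                # fast path: fully-matched read
                rstart = read.reference_start
                lo = max(start, rstart)
                hi = min(end, rstart + len(seq))
                if lo >= hi:
                    continue
                qs, qe = lo - rstart, hi - rstart
                codes = _BASE_LUT[np.frombuffer(seq[qs:qe].encode(), dtype=np.uint8)]
                q = np.asarray(quals[qs:qe])
                mask = (q >= config.min_base_quality) & (codes >= 0)
                np.add.at(counts, (np.arange(lo, hi)[mask] - start, codes[mask]), 1)
            else:
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    if start <= rpos < end and quals[qpos] >= config.min_base_quality:
                        base = seq[qpos]
                        if base in _BASE_INDEX:
                            counts[rpos - start, _BASE_INDEX[base]] += 1
    finally:
        if own:
            af.close()

    ref = genome.sequences[contig][start:end]
    return PileupWindow(contig=contig, start=start, end=end, ref=ref, counts=counts)


def estimate_global_error(window: PileupWindow,
                          exclude_positions: Sequence[int] = ()) -> float:
    """Unweighted mean alternative-allele fraction over covered positions.

    Candidate edited positions are excluded so genuine editing signal does
    not inflate the error estimate.
    """
    depth = window.depth
    frac = window.alt_fraction
    mask = depth > 0
    for pos in exclude_positions:
        if window.start <= pos < window.end:
            mask[pos - window.start] = False
    if not mask.any():
        raise QuantError("no covered positions available for the global error estimate")
    return float(frac[mask].mean())


def estimate_positional_error(control_window: PileupWindow | None,
                              position: int) -> float | None:
    """Alt fraction at one position in an untreated control window.

    Returns None (caller falls back to the global estimate alone) when no
    control is available or the control has zero depth at the position.
    """
    if control_window is None:
        return None
    i = control_window.index_of(position)
    if control_window.depth[i] == 0:
        log.warning("control depth 0 at position %d; positional estimate unavailable",
                    position)
        return None
    return float(control_window.alt_fraction[i])


@lru_cache(maxsize=1 << 16)
def _binom_upper_tail(k: int, n: int, p0: float) -> float:
    """Exact P(X >= k) under Binomial(n, p0); cached because pileups test
    many positions at few distinct alt depths."""
    return float(stats.binom.sf(k - 1, n, p0))


@dataclass(frozen=True)
class ConversionCall:
    position: int
    conversion: str          # "A>G" or "T>C"
    depth: int
    alt_depth: int           # depth of the matching conversion base
    rate: float              # alt_depth / depth (nan when depth 0)
    background: float        # null conversion probability used
    p_value: float           # upper-tail exact binomial P(X >= k)
    significant: bool


def call_conversions(window: PileupWindow, targets: Sequence[int],
                     global_err: float,
                     positional_err: Mapping[int, float | None] | None = None,
                     config: QuantConfig | None = None) -> list[ConversionCall]:
    """One-sided exact binomial test for conversion at each target.

    For a target with depth n and conversion-base depth k the p-value is
    the exact upper tail P(X >= k) under Binomial(n, p0), with p0 the
    higher of the global and position-dependent error estimates.
    """
    config = config or QuantConfig()
    positional_err = positional_err or {}
    depth = window.depth  # computed once; windows can span many positions
    calls = []
    for pos in targets:
        i = window.index_of(pos)
        ref = window.ref[i]
        if ref not in CONVERSIONS:
            raise QuantError(
                f"target position {pos} has reference base {ref!r}; expected A or T")
        alt_base, label = CONVERSIONS[ref]
        n = int(depth[i])
        k = int(window.counts[i, _BASE_INDEX[alt_base]])
        p_err = positional_err.get(pos)
        p0 = max(global_err, p_err) if p_err is not None else global_err
        if n == 0:
            calls.append(ConversionCall(
                position=pos, conversion=label, depth=0, alt_depth=0,
                rate=float("nan"), background=p0, p_value=1.0, significant=False))
            continue
        p_value = _binom_upper_tail(k, n, p0)
        calls.append(ConversionCall(
            position=pos, conversion=label, depth=n, alt_depth=k, rate=k / n,
            background=p0, p_value=p_value,
            significant=p_value < config.p_cutoff))
    return calls
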