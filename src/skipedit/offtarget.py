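"""Genome-wide off-target enumeration and specificity scoring.

Every 20-mer adjacent to a PAM on either strand whose Hamming distance to
the protospacer is at most ``max_mismatches`` (default 2) is an off-target
hit.  Each hit receives a position-weighted mismatch score in [0, 100]
(100 = perfect match): the product of per-position penalties, a
mean-pairwise-distance term that penalises clustered mismatches, and a
1/n^2 mismatch-count term.  A guide's aggregate off-target score is the
SUM of hit scores over all hits except the on-target locus, so lower
means more specific; guides with aggregate score above 10 are removed by
the default design filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .genome_io import Genome, revcomp

log = logging.getLogger(__name__)

PROTOSPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = PROTOSPACER_LEN + PAM_LEN

#: Canonical position-specific mismatch penalty weights (position 1 =
#: PAM-distal): mismatches near the PAM are penalised most.  Shipped as
#: an editable default; see MismatchWeights.from_json.
DEFAULT_WEIGHTS = (
    0.000, 0.000, 0.014, 0.000, 0.000, 0.395, 0.317, 0.000, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583,
)

_BASE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i
_N_CODE = 4


class OffTargetError(ValueError):
    pass


@dataclass(frozen=True)
class MismatchWeights:
    """Per-position mismatch penalties plus the distance-term constants.

    The distance term for n >= 2 mismatches with mean pairwise distance d
    is ``1 / (((distance_scale - d) / distance_scale) * distance_coeff + 1)``.
    """

    w: tuple[float, ...] = DEFAULT_WEIGHTS
    distance_scale: float = 19.0
    distance_coeff: float = 4.0

    def __post_init__(self) -> None:
        if len(self.w) != PROTOSPACER_LEN:
            raise ValueError("weight vector must have exactly 20 entries")
        if any(not 0.0 <= x <= 1.0 for x in self.w):
            raise ValueError("mismatch weights must lie in [0,1]")

    @classmethod
    def from_json(cls, path) -> "MismatchWeights":
        import json
        with open(path) as fh:
            cfg = json.load(fh)
        return cls(w=tuple(cfg["w"]),
                   distance_scale=float(cfg.get("distance_scale", 19.0)),
                   distance_coeff=float(cfg.get("distance_coeff", 4.0)))


@dataclass(frozen=True)
class OffTargetHit:
    """One genomic near-match of a protospacer (20-mer + PAM)."""

    contig: str
    strand: str
    start: int  # 0-based start of the 20-nt site on the genome
    site_sequence: str  # as read 5'->3' on ``strand``
    pam: str
    mismatch_positions: tuple[int, ...]  # sorted, 1-based protospacer positions
    hit_score: float

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


def hit_score(mismatch_positions: Sequence[int],
              weights: MismatchWeights | None = None) -> float:
    """Score one hit: 100 for a perfect match, else weighted penalties."""
    if weights is None:
        weights = MismatchWeights()
    pos = sorted(mismatch_positions)
    n = len(pos)
    if n == 0:
        return 100.0
    if pos[0] < 1 or pos[-1] > PROTOSPACER_LEN:
        raise ValueError("mismatch positions must lie in 1..20")
    penalty = 1.0
    for p in pos:
        penalty *= 1.0 - weights.w[p - 1]
    if n > 1:
        d = float(np.mean([abs(a - b) for a, b in combinations(pos, 2)]))
        dist_term = 1.0 / (
            ((weights.distance_scale - d) / weights.distance_scale)
            * weights.distance_coeff + 1.0)
    else:
        dist_term = 1.0
    return 100.0 * penalty * dist_term / (n * n)


def _pam_mask(pam_codes: np.ndarray, rule: str) -> np.ndarray:
    """Boolean mask of windows whose PAM matches ``rule`` (e.g. 'NGG')."""
    if len(rule) != PAM_LEN:
        raise ValueError(f"PAM rule {rule!r} must be 3 nt")
    mask = np.ones(len(pam_codes), dtype=bool)
    for i, ch in enumerate(rule.upper()):
        if ch == "N":
            continue
        mask &= pam_codes[:, i] == _BASE_LUT[ord(ch)]
    return mask


def _encode(seq: str) -> np.ndarray:
    return _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def enumerate_offtargets(genome: Genome, protospacer: str,
                         pam_rules: Sequence[str] = ("NGG",),
                         max_mismatches: int = 2,
                         weights: MismatchWeights | None = None) -> list[OffTargetHit]:
    """Scan both strands of every contig for near-matches of a guide.

    Sites containing N are excluded; the PAM is matched by rule and never
    counted as a mismatch.  The on-target locus itself comes back as a
    0-mismatch hit.
    """
    protospacer = protospacer.upper()
    if len(protospacer) != PROTOSPACER_LEN or "N" in protospacer:
        raise OffTargetError("protospacer must be 20 nt over {A,C,G,T}")
    if weights is None:
        weights = MismatchWeights()
    proto = _encode(protospacer)
    hits: list[OffTargetHit] = []
    for contig, seq in genome.sequences.items():
        length = len(seq)
        if length < SITE_LEN:
            continue
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            arr = _encode(s)
            win = np.lib.stride_tricks.sliding_window_view(arr, SITE_LEN)
            protopart = win[:, :PROTOSPACER_LEN]
            pampart = win[:, PROTOSPACER_LEN:]
            mism = (protopart != proto).sum(axis=1)
            has_n = (win == _N_CODE).any(axis=1)
            pam_ok = np.zeros(len(win), dtype=bool)
            for rule in pam_rules:
                pam_ok |= _pam_mask(pampart, rule)
            for j in np.nonzero((mism <= max_mismatches) & pam_ok & ~has_n)[0]:
                positions = tuple(
                    int(x) + 1 for x in np.nonzero(protopart[j] != proto)[0])
                start = int(j) if strand == "+" else length - int(j) - PROTOSPACER_LEN
                hits.append(OffTargetHit(
                    contig=contig, strand=strand, start=start,
                    site_sequence=s[j:j + PROTOSPACER_LEN],
                    pam=s[j + PROTOSPACER_LEN:j + SITE_LEN],
                    mismatch_positions=positions,
                    hit_score=hit_score(positions, weights),
                ))
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def aggregate_offtarget_score(hits: Iterable[OffTargetHit],
                              on_target: tuple[str, int, str]) -> float:
    """Sum of hit scores excluding the designated on-target locus.

    ``on_target`` is (contig, start, strand) of the design locus; it must
    appear among the hits (a scan that misses its own guide indicates a
    locus mismatch).  A guide with no other hits scores 0.
    """
    contig, start, strand = on_target
    total = 0.0
    found = False
    for h in hits:
        if (not found and h.contig == contig and h.start == start
                and h.strand == strand and h.n_mismatches == 0):
            found = True
            continue
        total += h.hit_score
    if not found:
        raise OffTargetError(
            f"on-target locus {contig}:{start}({strand}) not found among hits"
        )
    return total


def score_guide(genome: Genome, protospacer: str, on_target: tuple[str, int, str],
                pam_rules: Sequence[str] = ("NGG",), max_mismatches: int = 2,
                weights: MismatchWeights | None = None) -> float:
    """Convenience: enumerate then aggregate for one guide."""
    hits = enumerate_offtargets(genome, protospacer, pam_rules=pam_rules,
                                max_mismatches=max_mismatches, weights=weights)
    return aggregate_offtarget_score(hits, on_target)
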