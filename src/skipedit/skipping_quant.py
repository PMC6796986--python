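"""Exon-skipping quantification from RNA reads and gel densitometry.

RNA reads are classified by junction probes built from transcript
sequence: a read containing the exon-skipped junction (3' end of the
upstream exon joined to the 5' start of the downstream exon) counts
toward the skipped isoform, a read containing either canonical junction
(upstream->target or target->downstream) counts toward the canonical
isoform, and everything else is excluded.  The skipping rate is
skipped / (skipped + canonical); replicate rates are averaged
unweighted.  Gel band intensities are combined as
100 * skipped / (wt + skipped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Sequence

from .genome_io import (ExonKey, Genome, TranscriptModel, extract_sequence,
                        format_exon_key, revcomp)

log = logging.getLogger(__name__)

DEFAULT_ANCHOR = 10


class JunctionError(ValueError):
    pass


@dataclass(frozen=True)
class JunctionSet:
    """Probe sequences for one target exon in one transcript context.

    Each probe is ``2 * anchor`` nt of transcript-orientation sequence
    spanning the junction.
    """

    exon_key: ExonKey
    anchor: int
    skipped: str        # upstream-exon 3' end + downstream-exon 5' start
    canonical_5p: str   # upstream-exon 3' end + target-exon 5' start
    canonical_3p: str   # target-exon 3' end + downstream-exon 5' start

    def __post_init__(self) -> None:
        want = 2 * self.anchor
        for name in ("skipped", "canonical_5p", "canonical_3p"):
            if len(getattr(self, name)) != want:
                raise JunctionError(f"{name} probe is not {want} nt")
        if self.skipped in (self.canonical_5p, self.canonical_3p):
            raise JunctionError(
                "skipped probe equals a canonical probe; increase the anchor")


@dataclass(frozen=True)
class JunctionCounts:
    skipped_reads: int
    canonical_reads: int
    excluded_reads: int

    def __post_init__(self) -> None:
        if min(self.skipped_reads, self.canonical_reads, self.excluded_reads) < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total(self) -> int:
        return self.skipped_reads + self.canonical_reads + self.excluded_reads

    @property
    def skipping_rate(self) -> float | None:
        """skipped / (skipped + canonical); None when no junction reads."""
        denom = self.skipped_reads + self.canonical_reads
        if denom == 0:
            log.warning("no junction-spanning reads; skipping rate undefined")
            return None
        return self.skipped_reads / denom


@dataclass(frozen=True)
class BandDensitometry:
    """Background-subtracted band intensities from a gel image."""

    skipped_intensity: float
    wt_intensity: float

    def __post_init__(self) -> None:
        if self.skipped_intensity < 0 or self.wt_intensity < 0:
            raise ValueError("band intensities must be non-negative")
        if self.skipped_intensity == 0 and self.wt_intensity == 0:
            raise ValueError("both band intensities are zero")


def build_junction_set(genome: Genome, transcripts: Sequence[TranscriptModel],
                       exon_key: ExonKey,
                       anchor: int = DEFAULT_ANCHOR) -> tuple[JunctionSet, ...]:
    """Junction probes for every distinct flanking-exon context of an exon.

    The exon must be inner (flanked on both sides) in at least one
    transcript.  Probes are assembled in transcript orientation, so reads
    from minus-strand genes match after reverse complement.  Duplicate
    probe sets from redundant transcripts are collapsed.
    """
    contig, start, end, strand = exon_key
    seen: dict[tuple, JunctionSet] = {}
    for t in transcripts:
        if t.contig != contig or t.strand != strand:
            continue
        for i, (s, e) in enumerate(t.exons):
            if (s, e) != (start, end) or i == 0 or i == t.n_exons - 1:
                continue
            up, tg, down = t.exons[i - 1], t.exons[i], t.exons[i + 1]
            for name, (es, ee) in (("upstream", up), ("target", tg), ("downstream", down)):
                if ee - es < anchor:
                    raise JunctionError(
                        f"{name} exon ({es},{ee}) shorter than anchor {anchor}; "
                        "use a smaller anchor")
            up_seq = extract_sequence(genome, contig, *up, strand)
            tg_seq = extract_sequence(genome, contig, *tg, strand)
            down_seq = extract_sequence(genome, contig, *down, strand)
            jset = JunctionSet(
                exon_key=exon_key, anchor=anchor,
                skipped=up_seq[-anchor:] + down_seq[:anchor],
                canonical_5p=up_seq[-anchor:] + tg_seq[:anchor],
                canonical_3p=tg_seq[-anchor:] + down_seq[:anchor],
            )
            seen.setdefault((jset.skipped, jset.canonical_5p, jset.canonical_3p), jset)
    if not seen:
        raise JunctionError(
            f"exon {format_exon_key(exon_key)} is not inner in any transcript")
    return tuple(seen.values())


def _contains(read: str, probe: str, max_mismatches: int) -> bool:
    if max_mismatches == 0:
        return probe in read
    m = len(probe)
    for i in range(len(read) - m + 1):
        mm = 0
        for a, b in zip(read[i:i + m], probe):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            return True
    return False


def _probe_hit(read: str, probe: str, max_mismatches: int) -> bool:
    return (_contains(read, probe, max_mismatches)
            or _contains(read, revcomp(probe), max_mismatches))


def classify_reads(reads: Iterable[str], junction_set: JunctionSet,
                   max_mismatches: int = 0) -> JunctionCounts:
    """Count reads per isoform by junction-probe matching.

    Each mate is treated independently as a single read; probes are
    matched in either orientation.  Reads matching both the skipped and a
    canonical probe are ambiguous and excluded, as are reads matching
    neither.
    """
    skipped = canonical = excluded = 0
    for read in reads:
        read = read.upper()
        hit_skip = _probe_hit(read, junction_set.skipped, max_mismatches)
        hit_canon = (_probe_hit(read, junction_set.canonical_5p, max_mismatches)
                     or _probe_hit(read, junction_set.canonical_3p, max_mismatches))
        if hit_skip and not hit_canon:
            skipped += 1
        elif hit_canon and not hit_skip:
            canonical += 1
        else:
            excluded += 1
    counts = JunctionCounts(skipped, canonical, excluded)
    log.info("classified %d reads: %d skipped, %d canonical, %d excluded",
             counts.total, skipped, canonical, excluded)
    return counts


def reads_from_sam(path, min_mapq: int = 0) -> list[str]:
    """Read sequences from a SAM/BAM file for probe-based classification."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r") as af:
        for read in af.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq or read.query_sequence is None:
                continue
            out.append(read.query_sequence)
    return out


def average_replicates(rates: Sequence[float | None]) -> float:
    """Unweighted mean over defined replicate rates."""
    defined = [r for r in rates if r is not None]
    if len(defined) < len(rates):
        log.warning("%d replicate(s) had undefined rates and were excluded",
                    len(rates) - len(defined))
    if not defined:
        raise ValueError("no defined replicate rates to average")
    return fmean(defined)


def percent_skipping_from_bands(band: BandDensitometry) -> float:
    """Densitometry readout: 100 * skipped / (wt + skipped)."""
    return 100.0 * band.skipped_intensity / (
        band.wt_intensity + band.skipped_intensity)
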