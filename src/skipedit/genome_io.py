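"""Genome and annotation ingestion for splice-acceptor targeting.

Reads multi-record FASTA genomes and GENCODE-style GTF transcript
annotation, enumerates *inner exons* (exons that are neither first nor
last in at least one transcript), and locates the conserved splice
acceptor AG dinucleotide immediately 5' of each inner exon in transcript
orientation.

Coordinate convention: everything in memory is 0-based, half-open.  GTF
input (1-based, inclusive) is converted at the parsing boundary and only
there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GenomeError(ValueError):
    """Raised for malformed genome sequence input."""


class AnnotationError(ValueError):
    """Raised for malformed transcript annotation input."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N} (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Genome:
    """An in-memory genome: contig name -> uppercase DNA over {A,C,G,T,N}."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise GenomeError(f"contig {name!r} has empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise GenomeError(
                    f"contig {name!r} contains non-IUPAC character "
                    f"{seq[pos]!r} at position {pos}"
                )

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    def length(self, contig: str) -> int:
        return len(self.sequences[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        return extract_sequence(self, contig, start, end, strand)


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exons as 0-based half-open genome intervals.

    ``exons`` is ordered 5'->3' in *transcript* orientation, i.e. ascending
    genome coordinate on '+', descending on '-'.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(
                f"transcript {self.transcript_id}: bad strand {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        for s, e in self.exons:
            if not s < e:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: empty exon ({s},{e})"
                )
        by_coord = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(by_coord, by_coord[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        expect = by_coord if self.strand == "+" else by_coord[::-1]
        if tuple(expect) != tuple(self.exons):
            raise AnnotationError(
                f"transcript {self.transcript_id}: exons not in 5'->3' "
                "transcript order"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)


ExonKey = tuple[str, int, int, str]


def format_exon_key(key: ExonKey) -> str:
    contig, start, end, strand = key
    return f"{contig}:{start}-{end}({strand})"


def parse_exon_key(text: str) -> ExonKey:
    """Parse ``contig:start-end(strand)`` back into an exon key tuple."""
    try:
        contig, rest = text.rsplit(":", 1)
        coords, strand = rest[:-1].split("(")
        start, end = coords.split("-")
        if rest[-1] != ")" or strand not in "+-":
            raise ValueError
        return (contig, int(start), int(end), strand)
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed exon key {text!r}") from exc


@dataclass
class InnerExon:
    """A deduplicated exon that is non-terminal in >=1 transcript.

    ``acceptor_A_pos`` / ``acceptor_G_pos`` are the genome coordinates of
    the conserved intronic A and G immediately 5' of the exon in
    transcript orientation: on '+' the G sits at start-1 and the A at
    start-2; on '-' the G sits at ``end`` and the A at ``end + 1``.
    ``canonical`` is None when no genome was supplied to check the bases.
    """

    contig: str
    strand: str
    start: int
    end: int
    acceptor_A_pos: int
    acceptor_G_pos: int
    supporting_transcripts: tuple[str, ...] = ()
    gene_ids: tuple[str, ...] = ()
    canonical: bool | None = None

    @property
    def exon_key(self) -> ExonKey:
        return (self.contig, self.start, self.end, self.strand)

    @property
    def exon_key_str(self) -> str:
        return format_exon_key(self.exon_key)


def read_fasta(path) -> Genome:
    """Load a FASTA file into a :class:`Genome`.

    Contig names are the first whitespace-delimited token of the header;
    sequence is uppercased.  Duplicate contig names and non-IUPAC
    characters are hard errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequences:
            raise GenomeError(f"duplicate contig name {name!r}")
        sequences[name] = str(record.seq).upper()
    if not sequences:
        raise GenomeError(f"no FASTA records found in {path}")
    return Genome(sequences)


_BIOTYPE_KEYS = ("transcript_type", "transcript_biotype", "gene_type", "gene_biotype")


def read_annotation(path, biotype_filter: str | None = "protein_coding") -> list[TranscriptModel]:
    """Parse a GTF into :class:`TranscriptModel` records.

    Only ``exon`` features are used.  Coordinates are converted from the
    GTF's 1-based inclusive convention to 0-based half-open.  Transcripts
    whose biotype (``transcript_type``/``gene_type`` GENCODE keys) does
    not match ``biotype_filter`` are excluded; pass ``None`` to keep all.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, dict] = {}
    for ex in db.features_of_type("exon", order_by=("seqid", "start")):
        if "transcript_id" not in ex.attributes:
            raise AnnotationError(
                f"exon at {ex.seqid}:{ex.start}-{ex.end} lacks transcript_id"
            )
        tid = ex.attributes["transcript_id"][0]
        gid = ex.attributes.get("gene_id", ["?"])[0]
        biotype = ""
        for key in _BIOTYPE_KEYS:
            if key in ex.attributes:
                biotype = ex.attributes[key][0]
                break
        entry = grouped.setdefault(
            tid, {"gene_id": gid, "contig": ex.seqid, "strand": ex.strand,
                  "biotype": biotype, "exons": []}
        )
        if entry["contig"] != ex.seqid or entry["strand"] != ex.strand:
            raise AnnotationError(
                f"transcript {tid}: exons on multiple contigs or strands"
            )
        entry["exons"].append((ex.start - 1, ex.end))

    transcripts = []
    for tid, entry in grouped.items():
        if biotype_filter is not None and entry["biotype"] != biotype_filter:
            continue
        exons = sorted(entry["exons"])
        if entry["strand"] == "-":
            exons = exons[::-1]
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=entry["gene_id"],
                contig=entry["contig"],
                strand=entry["strand"],
                exons=tuple(exons),
                biotype=entry["biotype"],
            )
        )
    return transcripts


def extract_sequence(genome: Genome, contig: str, start: int, end: int,
                     strand: str = "+") -> str:
    """Genome slice; on '-' the reverse complement of the slice."""
    if contig not in genome.sequences:
        raise GenomeError(f"unknown contig {contig!r}")
    seq = genome.sequences[contig]
    if not (0 <= start < end <= len(seq)):
        raise GenomeError(
            f"interval [{start},{end}) out of range for contig {contig!r} "
            f"of length {len(seq)}"
        )
    if strand == "+":
        return seq[start:end]
    if strand == "-":
        return revcomp(seq[start:end])
    raise GenomeError(f"bad strand {strand!r}")


def _acceptor_positions(strand: str, start: int, end: int) -> tuple[int, int]:
    if strand == "+":
        return start - 2, start - 1
    return end + 1, end


def enumerate_inner_exons(transcripts: Iterable[TranscriptModel],
                          genome: Genome | None = None) -> list[InnerExon]:
    """All exons that are non-terminal in at least one transcript.

    Per transcript with n >= 3 exons, exons 2..n-1 (transcript order) are
    inner; results are deduplicated by (contig, start, end, strand) with
    the union of supporting transcript ids.  When a genome is supplied the
    acceptor dinucleotide is checked and non-canonical (!= AG) acceptors
    are flagged via ``canonical=False`` rather than dropped.
    """
    seen: dict[ExonKey, InnerExon] = {}
    tx_sets: dict[ExonKey, list[str]] = {}
    gene_sets: dict[ExonKey, list[str]] = {}
    for t in transcripts:
        if t.n_exons < 3:
            continue
        for start, end in t.exons[1:-1]:
            key = (t.contig, start, end, t.strand)
            if key not in seen:
                a_pos, g_pos = _acceptor_positions(t.strand, start, end)
                seen[key] = InnerExon(
                    contig=t.contig, strand=t.strand, start=start, end=end,
                    acceptor_A_pos=a_pos, acceptor_G_pos=g_pos,
                )
                tx_sets[key] = []
                gene_sets[key] = []
            if t.transcript_id not in tx_sets[key]:
                tx_sets[key].append(t.transcript_id)
            if t.gene_id not in gene_sets[key]:
                gene_sets[key].append(t.gene_id)

    result = []
    for key, exon in seen.items():
        exon.supporting_transcripts = tuple(tx_sets[key])
        exon.gene_ids = tuple(gene_sets[key])
        if genome is not None:
            exon.canonical = _is_canonical(genome, exon)
            if not exon.canonical:
                log.debug("non-canonical acceptor at %s", exon.exon_key_str)
        result.append(exon)
    return result


def _is_canonical(genome: Genome, exon: InnerExon) -> bool:
    length = genome.length(exon.contig)
    lo = min(exon.acceptor_A_pos, exon.acceptor_G_pos)
    hi = max(exon.acceptor_A_pos, exon.acceptor_G_pos)
    if lo < 0 or hi >= length:
        return False
    if exon.strand == "+":
        dinuc = genome.sequences[exon.contig][exon.acceptor_A_pos:exon.acceptor_G_pos + 1]
    else:
        dinuc = revcomp(
            genome.sequences[exon.contig][exon.acceptor_G_pos:exon.acceptor_A_pos + 1]
        )
    return dinuc == "AG"


def transcripts_to_gtf(transcripts: Sequence[TranscriptModel],
                       source: str = "skipedit") -> str:
    """Serialize transcripts back to GTF text (1-based inclusive)."""
    lines = []
    for t in transcripts:
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'gene_type "{t.biotype}"; transcript_type "{t.biotype}";'
        )
        for start, end in sorted(t.exons):
            lines.append(
                "\t".join([
                    t.contig, source, "exon", str(start + 1), str(end), ".",
                    t.strand, ".", attrs,
                ])
            )
    return "\n".join(lines) + "\n"


def write_fasta(genome: Genome, path, width: int = 60) -> None:
    """Write a genome as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
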