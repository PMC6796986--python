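"""Deterministic synthetic fixtures with exact ground truth.

Generates toy genomes whose genes have canonical splice acceptors (every
intron ends in AG) and planted NGG PAMs placing the acceptor target base
at a chosen protospacer window position, plus amplicon sequencing reads
with a known per-molecule editing rate and uniform sequencing error, and
RNA reads drawn from a two-isoform (canonical / exon-skipped) mixture at
a known skip fraction.  Every planted guide, off-target site and read
event is recorded in truth tables, and a fixed seed reproduces
byte-identical FASTA/GTF/FASTQ/SAM output.

Genes are laid out in transcript orientation and reverse-complemented
onto the genome for minus-strand genes, so strand handling downstream is
exercised for real.  A sanitiser guarantees that, per acceptor, *only*
the planted window positions carry a PAM, making the expected guide set
exactly the planted set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import (Genome, TranscriptModel, extract_sequence,
                        format_exon_key, revcomp, transcripts_to_gtf,
                        write_fasta)

log = logging.getLogger(__name__)

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3

ABE_WINDOW = (4, 5, 6, 7, 8, 9)
BE3_WINDOW = (4, 5, 6, 7, 8)


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedGuide:
    """A guide to plant: which gene, which inner exon (0-based among the
    gene's inner exons), which editor, and the protospacer position at
    which the target base should sit."""

    gene_index: int
    inner_index: int
    mode: str  # ABE | BE3
    position: int


@dataclass(frozen=True)
class OffTargetPlant:
    """A near-copy of truth guide ``guide_index`` to plant intergenically,
    with substitutions at the given 1-based protospacer positions."""

    guide_index: int
    mismatch_positions: tuple[int, ...]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_genes: int = 4
    exons_per_gene: int = 3
    exon_length: tuple[int, int] = (60, 90)
    intron_length: tuple[int, int] = (80, 120)
    intergenic_length: tuple[int, int] = (150, 250)
    contig: str = "chr1"
    alternate_strands: bool = True
    guide_layout: tuple[PlantedGuide, ...] | None = None  # None -> default layout
    abe_window: tuple[int, ...] = ABE_WINDOW
    be3_window: tuple[int, ...] = BE3_WINDOW
    offtarget_plants: tuple[OffTargetPlant, ...] = ()
    # amplicon simulation
    editing_rate: float = 0.05
    sequencing_error: float = 0.002
    read_length: int = 150
    depth: int = 1000
    # RNA simulation
    skip_fraction: float = 0.25
    n_junction_reads: int = 2000
    n_background_reads: int = 500
    rna_read_length: int = 60
    rna_sequencing_error: float = 0.0
    anchor: int = 10

    def __post_init__(self) -> None:
        for name in ("editing_rate", "sequencing_error", "skip_fraction",
                     "rna_sequencing_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureError(f"{name}={v} not in [0,1]")
        if self.exons_per_gene < 3:
            raise FixtureError("need >=3 exons per gene for inner exons")
        if self.exon_length[0] < 30 or self.intron_length[0] < 30:
            raise FixtureError("exons and introns must be >=30 bp for PAM layout")
        if self.rna_read_length // 2 > self.exon_length[0]:
            raise FixtureError("rna_read_length too long for the shortest exon")


def default_guide_layout(spec: FixtureSpec) -> tuple[PlantedGuide, ...]:
    """One ABE plant per inner exon (positions cycling over the window),
    plus a BE3 plant on two of every three inner exons."""
    plants: list[PlantedGuide] = []
    count = 0
    for gene in range(spec.n_genes):
        for j in range(spec.exons_per_gene - 2):
            plants.append(PlantedGuide(
                gene, j, "ABE", spec.abe_window[count % len(spec.abe_window)]))
            if count % 3 != 2:
                plants.append(PlantedGuide(
                    gene, j, "BE3", spec.be3_window[count % len(spec.be3_window)]))
            count += 1
    return tuple(plants)


@dataclass(frozen=True)
class TruthGuide:
    gene_id: str
    exon_key: tuple
    mode: str
    position: int
    guide_strand: str
    start: int
    protospacer: str
    pam: str
    target_genome_pos: int

    @property
    def exon_key_str(self) -> str:
        return format_exon_key(self.exon_key)


@dataclass(frozen=True)
class TruthOffTarget:
    guide_index: int
    contig: str
    strand: str
    start: int
    site_sequence: str
    pam: str
    mismatch_positions: tuple[int, ...]


@dataclass
class ToyGenome:
    spec: FixtureSpec
    genome: Genome
    transcripts: tuple[TranscriptModel, ...]
    gtf: str
    guides: tuple[TruthGuide, ...]
    offtargets: tuple[TruthOffTarget, ...]

    def write(self, out_dir) -> dict[str, str]:
        """Write FASTA/GTF/truth TSVs; returns name -> path."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "genome": os.path.join(out_dir, "genome.fa"),
            "annotation": os.path.join(out_dir, "annotation.gtf"),
            "guides": os.path.join(out_dir, "guides_truth.tsv"),
            "offtargets": os.path.join(out_dir, "offtargets_truth.tsv"),
        }
        write_fasta(self.genome, paths["genome"])
        with open(paths["annotation"], "w") as fh:
            fh.write(self.gtf)
        with open(paths["guides"], "w") as fh:
            fh.write("exon_key\tgene_id\tmode\tposition\tguide_strand\tstart\t"
                     "protospacer\tpam\ttarget_genome_pos\n")
            for g in self.guides:
                fh.write(f"{g.exon_key_str}\t{g.gene_id}\t{g.mode}\t{g.position}\t"
                         f"{g.guide_strand}\t{g.start}\t{g.protospacer}\t{g.pam}\t"
                         f"{g.target_genome_pos}\n")
        with open(paths["offtargets"], "w") as fh:
            fh.write("guide_index\tcontig\tstrand\tstart\tsite_sequence\tpam\t"
                     "mismatch_positions\n")
            for h in self.offtargets:
                pos = ",".join(map(str, h.mismatch_positions))
                fh.write(f"{h.guide_index}\t{h.contig}\t{h.strand}\t{h.start}\t"
                         f"{h.site_sequence}\t{h.pam}\t{pos}\n")
        return paths


def _sanitize_gene(local: np.ndarray, exon_ivs: list[tuple[int, int]],
                   plants: Sequence[PlantedGuide], spec: FixtureSpec) -> None:
    """Remove accidental PAMs so each acceptor yields exactly its plants."""
    n_ex = len(exon_ivs)
    planted_abe = {(p.inner_index + 1, p.position) for p in plants if p.mode == "ABE"}
    planted_be3 = {(p.inner_index + 1, p.position) for p in plants if p.mode == "BE3"}
    protected: set[int] = set()
    for k in range(1, n_ex):
        s = exon_ivs[k][0]
        protected.update((s - 2, s - 1))  # the acceptor AG itself
    for k, p in planted_abe:
        t = exon_ivs[k][0] - 2
        protected.update((t + 22 - p, t + 23 - p))
    for k, p in planted_be3:
        g = exon_ivs[k][0] - 1
        protected.update((g + p - 23, g + p - 22))

    def _clear(i: int, j: int, code: int) -> bool:
        if local[i] == code and local[j] == code:
            free = [x for x in (i, j) if x not in protected]
            if not free:
                raise FixtureError(
                    "impossible layout: accidental PAM formed entirely by "
                    "planted/protected bases")
            local[free[0]] = _T if code != _T else _A
            return True
        return False

    for _ in range(100):
        changed = False
        for k in range(1, n_ex - 1):  # inner exons only
            t = exon_ivs[k][0] - 2
            g = t + 1
            for p in spec.abe_window:
                if (k, p) in planted_abe:
                    continue
                changed |= _clear(t + 22 - p, t + 23 - p, _G)
            for p in spec.be3_window:
                if (k, p) in planted_be3:
                    continue
                changed |= _clear(g + p - 23, g + p - 22, _C)
        if not changed:
            return
    raise FixtureError("PAM sanitiser failed to converge")


def _mutate_protospacer(proto: str, positions: Sequence[int]) -> str:
    cycle = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(proto)
    for p in positions:
        out[p - 1] = cycle[out[p - 1]]
    return "".join(out)


def make_toy_genome(spec: FixtureSpec) -> ToyGenome:
    """Build genome + GTF + truth tables per the fixture spec."""
    rng = np.random.default_rng(spec.seed)
    layout = spec.guide_layout if spec.guide_layout is not None else default_guide_layout(spec)
    for p in layout:
        if not 0 <= p.gene_index < spec.n_genes:
            raise FixtureError(f"plant references unknown gene {p.gene_index}")
        if not 0 <= p.inner_index < spec.exons_per_gene - 2:
            raise FixtureError(f"plant references non-inner exon index {p.inner_index}")
        window = spec.abe_window if p.mode == "ABE" else spec.be3_window
        if p.position not in window:
            raise FixtureError(f"plant position {p.position} outside {p.mode} window")

    def rand(n: int) -> np.ndarray:
        return rng.integers(0, 4, int(n), dtype=np.uint8)

    gene_blocks = []
    for gi in range(spec.n_genes):
        strand = "+" if (not spec.alternate_strands or gi % 2 == 0) else "-"
        ex_lens = rng.integers(spec.exon_length[0], spec.exon_length[1] + 1,
                               spec.exons_per_gene)
        in_lens = rng.integers(spec.intron_length[0], spec.intron_length[1] + 1,
                               spec.exons_per_gene - 1)
        parts, exon_ivs, cur = [], [], 0
        for k in range(spec.exons_per_gene):
            if k > 0:
                parts.append(rand(in_lens[k - 1]))
                cur += int(in_lens[k - 1])
            exon_ivs.append((cur, cur + int(ex_lens[k])))
            parts.append(rand(ex_lens[k]))
            cur += int(ex_lens[k])
        local = np.concatenate(parts)
        for k in range(1, spec.exons_per_gene):
            s = exon_ivs[k][0]
            local[s - 2], local[s - 1] = _A, _G  # canonical acceptor
        plants = [p for p in layout if p.gene_index == gi]
        for p in plants:
            t = exon_ivs[p.inner_index + 1][0] - 2
            if p.mode == "ABE":
                local[t + 22 - p.position] = _G
                local[t + 23 - p.position] = _G
            else:
                g = t + 1
                local[g + p.position - 23] = _C
                local[g + p.position - 22] = _C
        _sanitize_gene(local, exon_ivs, plants, spec)
        gene_blocks.append((strand, local, exon_ivs, plants))

    # assemble the contig: pads between genes plus an off-target landing pad
    segments: list[np.ndarray] = []
    cursor = 0
    transcripts: list[TranscriptModel] = []
    genome_exons: list[list[tuple[int, int]]] = []
    gene_strands: list[str] = []
    for gi, (strand, local, exon_ivs, _plants) in enumerate(gene_blocks):
        pad = int(rng.integers(*spec.intergenic_length))
        segments.append(rand(pad))
        cursor += pad
        length = len(local)
        if strand == "+":
            block = local
            ivs = [(cursor + s, cursor + e) for s, e in exon_ivs]
        else:
            block = (3 - local)[::-1].copy()
            ivs = [(cursor + length - e, cursor + length - s) for s, e in exon_ivs]
        segments.append(block)
        cursor += length
        transcripts.append(TranscriptModel(
            transcript_id=f"g{gi}.t1", gene_id=f"g{gi}", contig=spec.contig,
            strand=strand, exons=tuple(ivs), biotype="protein_coding"))
        genome_exons.append(ivs)
        gene_strands.append(strand)
    tail_pad = max(200, 33 * len(spec.offtarget_plants) + 60)
    tail_start = cursor + 30
    segments.append(rand(tail_pad))
    contig_arr = np.concatenate(segments)

    seq_chars = np.frombuffer(b"ACGT", dtype="S1")[contig_arr]
    contig_seq = b"".join(seq_chars).decode()
    prelim = Genome({spec.contig: contig_seq})

    guides: list[TruthGuide] = []
    for gi, (strand, _local, _exon_ivs, plants) in enumerate(gene_blocks):
        for p in sorted(plants, key=lambda x: (x.inner_index, x.mode, x.position)):
            s, e = genome_exons[gi][p.inner_index + 1]
            if strand == "+":
                a_pos, g_pos = s - 2, s - 1
            else:
                a_pos, g_pos = e + 1, e
            if p.mode == "ABE":
                guide_strand, target = strand, a_pos
            else:
                guide_strand = "-" if strand == "+" else "+"
                target = g_pos
            if guide_strand == "+":
                start = target - (p.position - 1)
                proto = contig_seq[start:start + 20]
                pam = contig_seq[start + 20:start + 23]
            else:
                start = target + p.position - 20
                proto = revcomp(contig_seq[start:start + 20])
                pam = revcomp(contig_seq[start - 3:start])
            if not pam.endswith("GG"):
                raise FixtureError("internal error: planted PAM missing")
            need = "A" if p.mode == "ABE" else "C"
            if proto[p.position - 1] != need:
                raise FixtureError("internal error: planted target base wrong")
            guides.append(TruthGuide(
                gene_id=f"g{gi}", exon_key=(spec.contig, s, e, strand),
                mode=p.mode, position=p.position, guide_strand=guide_strand,
                start=start, protospacer=proto, pam=pam,
                target_genome_pos=target))

    offtargets: list[TruthOffTarget] = []
    if spec.offtarget_plants:
        chars = list(contig_seq)
        for i, plant in enumerate(spec.offtarget_plants):
            guide = guides[plant.guide_index]
            site = _mutate_protospacer(guide.protospacer, plant.mismatch_positions)
            start = tail_start + 33 * i
            chars[start:start + 23] = site + "TGG"
            offtargets.append(TruthOffTarget(
                guide_index=plant.guide_index, contig=spec.contig, strand="+",
                start=start, site_sequence=site, pam="TGG",
                mismatch_positions=tuple(sorted(plant.mismatch_positions))))
        contig_seq = "".join(chars)

    genome = Genome({spec.contig: contig_seq}) if spec.offtarget_plants else prelim
    gtf = transcripts_to_gtf(transcripts)
    return ToyGenome(spec=spec, genome=genome, transcripts=tuple(transcripts),
                     gtf=gtf, guides=tuple(guides), offtargets=tuple(offtargets))


# ---------------------------------------------------------------------------
# amplicon reads


@dataclass
class AmpliconSim:
    """Paired amplicon reads + pre-aligned SAM + exact per-position truth.

    ``truth_counts`` is an (region width, 4) array of final base calls in
    A,C,G,T order, exactly matching what a Q-blind pileup of the emitted
    SAM contains.
    """

    contig: str
    region_start: int
    region_end: int
    target_pos: int
    true_rate: float
    n_edited_molecules: int
    fastq1: str
    fastq2: str
    sam: str
    truth_counts: np.ndarray

    def write(self, out_dir, prefix: str = "amplicon") -> dict[str, str]:
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "fastq1": os.path.join(out_dir, f"{prefix}_R1.fastq"),
            "fastq2": os.path.join(out_dir, f"{prefix}_R2.fastq"),
            "sam": os.path.join(out_dir, f"{prefix}.sam"),
        }
        for key in ("fastq1", "fastq2", "sam"):
            with open(paths[key], "w") as fh:
                fh.write(getattr(self, key))
        return paths


def simulate_amplicon_reads(genome: Genome, contig: str, target_pos: int,
                            spec: FixtureSpec, *, seed: int | None = None,
                            editing_rate: float | None = None) -> AmpliconSim:
    """Simulate edited amplicon read pairs around one target base.

    A fraction ``editing_rate`` of template molecules carries the
    conversion at ``target_pos`` (A->G on the plus strand, or T->C when
    the edited strand reads T on plus); every sequenced base is then
    substituted uniformly at random with probability ``sequencing_error``
    (so the expected error-driven A->G component is error/3).  The two
    mates tile the amplicon without overlap, so every position is covered
    by exactly one base call per molecule and per-position depth equals
    the molecule count.  Mates are emitted as coordinate-sorted,
    fully-matching SAM records, so no aligner is needed downstream.
    """
    e = spec.editing_rate if editing_rate is None else editing_rate
    eps = spec.sequencing_error
    L = spec.read_length
    depth = spec.depth
    region_len = 2 * L
    if L < 120:
        raise FixtureError("read_length must be >= 120 for full window coverage")
    start = target_pos - L
    end = target_pos + L
    if start < 0 or end > genome.length(contig):
        raise FixtureError("amplicon region extends past the contig")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)

    ref = genome.sequences[contig][start:end]
    ref_codes = np.frombuffer(ref.encode(), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    ref_codes = lut[ref_codes]
    if (ref_codes == 255).any():
        raise FixtureError("amplicon region contains N")
    t_rel = L
    ref_base = ref[t_rel]
    if ref_base == "A":
        edited_code = _G
    elif ref_base == "T":
        edited_code = _C
    else:
        raise FixtureError(f"target base {ref_base!r} is not editable (need A or T)")

    templates = np.tile(ref_codes, (depth, 1))
    edited = rng.random(depth) < e
    templates[edited, t_rel] = edited_code

    r1 = templates[:, :L].copy()
    r2 = templates[:, L:].copy()  # forward orientation; tiles [L, 2L)
    for mat in (r1, r2):
        err = rng.random(mat.shape) < eps
        shift = rng.integers(1, 4, mat.shape, dtype=np.uint8)
        mat[err] = (mat[err] + shift[err]) % 4

    truth = np.zeros((region_len, 4), dtype=np.int64)
    for col in range(L):
        truth[col] += np.bincount(r1[:, col], minlength=4)
    off = region_len - L
    for col in range(L):
        truth[off + col] += np.bincount(r2[:, col], minlength=4)

    decode = np.frombuffer(b"ACGT", dtype="S1")
    qual = "I" * L  # Q40
    pos1 = start + 1
    pos2 = start + off + 1

    def to_str(row: np.ndarray) -> str:
        return b"".join(decode[row]).decode()

    fq1, fq2, sam1, sam2 = [], [], [], []
    for i in range(depth):
        name = f"amp{i:05d}"
        s1 = to_str(r1[i])
        s2f = to_str(r2[i])
        fq1.append(f"@{name}/1\n{s1}\n+\n{qual}\n")
        fq2.append(f"@{name}/2\n{revcomp(s2f)}\n+\n{qual}\n")
        sam1.append(f"{name}\t99\t{contig}\t{pos1}\t60\t{L}M\t=\t{pos2}\t"
                    f"{region_len}\t{s1}\t{qual}\n")
        sam2.append(f"{name}\t147\t{contig}\t{pos2}\t60\t{L}M\t=\t{pos1}\t"
                    f"-{region_len}\t{s2f}\t{qual}\n")
    header = (f"@HD\tVN:1.6\tSO:coordinate\n"
              f"@SQ\tSN:{contig}\tLN:{genome.length(contig)}\n")
    sam = header + "".join(sam1) + "".join(sam2)
    return AmpliconSim(
        contig=contig, region_start=start, region_end=end, target_pos=target_pos,
        true_rate=e, n_edited_molecules=int(edited.sum()),
        fastq1="".join(fq1), fastq2="".join(fq2), sam=sam, truth_counts=truth)


# ---------------------------------------------------------------------------
# RNA reads


@dataclass
class RnaSim:
    exon_key: tuple
    fastq: str
    n_skipped: int
    n_canonical: int
    n_background: int
    true_skip_fraction: float

    def write(self, out_dir, prefix: str = "rna") -> dict[str, str]:
        import os

        os.makedirs(out_dir, exist_ok=True)
        path = os.path.join(out_dir, f"{prefix}.fastq")
        with open(path, "w") as fh:
            fh.write(self.fastq)
        return {"fastq": path}


def simulate_rna_reads(genome: Genome, transcripts: Sequence[TranscriptModel],
                       exon_key: tuple, spec: FixtureSpec, *,
                       seed: int | None = None,
                       skip_fraction: float | None = None) -> RnaSim:
    """Simulate junction-spanning RNA reads for one target exon.

    Each junction read comes from the exon-skipped isoform with
    probability ``skip_fraction``, otherwise from the canonical isoform
    (5' or 3' junction, equiprobable).  Background reads from the target
    exon interior span no junction and must be excluded downstream.
    Read orientation is random; truth counts are exact.
    """
    from .skipping_quant import build_junction_set

    s = spec.skip_fraction if skip_fraction is None else skip_fraction
    L = spec.rna_read_length
    half = L // 2
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)

    jset = build_junction_set(genome, transcripts, exon_key, anchor=spec.anchor)[0]
    contig, start, end, strand = exon_key
    context = None
    for t in transcripts:
        if t.contig != contig or t.strand != strand:
            continue
        for i, iv in enumerate(t.exons):
            if iv == (start, end) and 0 < i < t.n_exons - 1:
                context = (t, i)
                break
        if context:
            break
    if context is None:
        raise FixtureError("exon is not inner in any supplied transcript")
    t, i = context
    up = extract_sequence(genome, contig, *t.exons[i - 1], strand)
    tg = extract_sequence(genome, contig, *t.exons[i], strand)
    down = extract_sequence(genome, contig, *t.exons[i + 1], strand)
    if min(len(up), len(tg), len(down)) < half:
        raise FixtureError("flanking exon shorter than half the read length")

    templates = {
        "skipped": up[-half:] + down[:half],
        "canonical_5p": up[-half:] + tg[:half],
        "canonical_3p": tg[-half:] + down[:half],
        "background": tg[:L],
    }
    probes = {"skipped": jset.skipped, "canonical_5p": jset.canonical_5p,
              "canonical_3p": jset.canonical_3p}
    for name, template in templates.items():
        for pname, probe in probes.items():
            expected = name == pname
            present = probe in template or revcomp(probe) in template
            if present != expected:
                raise FixtureError(
                    f"fixture probe collision: {pname} probe "
                    f"{'missing from' if expected else 'present in'} {name} template")

    draws = rng.random(spec.n_junction_reads)
    which_canonical = rng.integers(0, 2, spec.n_junction_reads)
    flip = rng.random(spec.n_junction_reads + spec.n_background_reads) < 0.5
    eps = spec.rna_sequencing_error

    seqs: list[str] = []
    n_skip = n_canon = 0
    for j in range(spec.n_junction_reads):
        if draws[j] < s:
            seq = templates["skipped"]
            n_skip += 1
        else:
            seq = templates["canonical_5p" if which_canonical[j] == 0 else "canonical_3p"]
            n_canon += 1
        seqs.append(seq)
    for _ in range(spec.n_background_reads):
        seqs.append(templates["background"])

    if eps > 0:
        cycle = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
        noisy = []
        for seq in seqs:
            chars = list(seq)
            err = np.nonzero(rng.random(len(chars)) < eps)[0]
            picks = rng.integers(0, 3, len(err))
            for idx, pick in zip(err, picks):
                chars[idx] = cycle[chars[idx]][pick]
            noisy.append("".join(chars))
        seqs = noisy

    out = []
    for j, seq in enumerate(seqs):
        if flip[j]:
            seq = revcomp(seq)
        out.append(f"@rna{j:05d}\n{seq}\n+\n{'I' * len(seq)}\n")
    return RnaSim(exon_key=exon_key, fastq="".join(out), n_skipped=n_skip,
                  n_canonical=n_canon, n_background=spec.n_background_reads,
                  true_skip_fraction=s)
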