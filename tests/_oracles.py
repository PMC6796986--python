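"""Independent brute-force oracles for validating the fast implementations.

These deliberately share no code with the package internals beyond the
reverse-complement helper: guides are found by sliding every 20-mer and
checking the PAM and target placement directly; off-targets by computing
Hamming distance at every genomic offset on both strands.
"""

from skipedit.genome_io import revcomp


def brute_force_guides(genome, inner_exon, mode, window):
    """All (start, strand, position, protospacer, pam) placing the acceptor
    target base in the window with an NGG PAM, by exhaustive scan."""
    seq = genome.sequences[inner_exon.contig]
    if mode == "ABE":
        strand = inner_exon.strand
        target = inner_exon.acceptor_A_pos
        base = "A"
    else:
        strand = "-" if inner_exon.strand == "+" else "+"
        target = inner_exon.acceptor_G_pos
        base = "C"
    window = set(window)
    results = set()
    length = len(seq)
    if strand == "+":
        for s in range(length - 22):
            proto, pam = seq[s:s + 20], seq[s + 20:s + 23]
            if pam[1:] == "GG" and s <= target < s + 20 and "N" not in proto + pam:
                p = target - s + 1
                if p in window and proto[p - 1] == base:
                    results.add((s, "+", p, proto, pam))
    else:
        rc = revcomp(seq)
        for j in range(length - 22):
            proto, pam = rc[j:j + 20], rc[j + 20:j + 23]
            start = length - j - 20
            if pam[1:] == "GG" and start <= target < start + 20 and "N" not in proto + pam:
                p = start + 20 - target
                if p in window and proto[p - 1] == base:
                    results.add((start, "-", p, proto, pam))
    return results


def brute_force_offtargets(genome, protospacer, max_mismatches=2):
    """All NGG-adjacent 20-mers within Hamming distance of the guide, as a
    set of (contig, strand, start, site, pam, mismatch_positions)."""
    out = set()
    for contig, seq in genome.sequences.items():
        length = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            for j in range(length - 22):
                site, pam = s[j:j + 20], s[j + 20:j + 23]
                if "N" in site or "N" in pam or pam[1:] != "GG":
                    continue
                mm = tuple(i + 1 for i in range(20) if site[i] != protospacer[i])
                if len(mm) <= max_mismatches:
                    start = j if strand == "+" else length - j - 20
                    out.add((contig, strand, start, site, pam, mm))
    return out


def binom_upper_tail(k, n, p):
    """Exact P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    from math import comb

    if k <= 0:
        return 1.0
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))
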