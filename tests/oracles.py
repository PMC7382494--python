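"""Independent brute-force oracles the test suite checks the package against.

Each function re-derives an expected result by direct enumeration or naive
O(n^2) scanning, sharing no code with the implementation under test.
"""

from __future__ import annotations

import networkx as nx

STOPS = {"TAA", "TAG", "TGA"}
COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def orf_oracle(seq: str, both_strands: bool = True):
    """Enumerate every candidate start/stop pair in all frames; pick the best.

    Candidate starts are every ATG codon plus the frame's 5' edge; each start
    pairs with the first in-frame stop after it (span includes the stop) or,
    failing that, with the frame's 3' edge. Candidates spanning an internal
    stop are impossible by construction. Best = longest span, ties to the +
    strand then the 5'-most start. Returns (length, strand, start, protein)
    or None.
    """
    seq = seq.upper()
    strands = [("+", seq)]
    if both_strands:
        strands.append(("-", revcomp(seq)))
    candidates = []
    for rank, (strand, s) in enumerate(strands):
        n = len(s)
        for f in range(3):
            codons = [s[p : p + 3] for p in range(f, n - 2, 3)]
            stops = [i for i, c in enumerate(codons) if c in STOPS]
            starts = [i for i, c in enumerate(codons) if c == "ATG"]
            starts.append(0)
            for c0 in set(starts):
                later_stops = [i for i in stops if i >= c0]
                if later_stops:
                    c1 = later_stops[0]
                    if any(c0 <= i < c1 for i in stops):
                        continue
                    span = (c1 - c0 + 1) * 3
                    end = f + 3 * (c1 + 1)
                    has_stop = True
                else:
                    if any(i >= c0 for i in stops):
                        continue
                    span = (len(codons) - c0) * 3
                    end = f + 3 * len(codons)
                    has_stop = False
                if span <= (3 if has_stop else 0):
                    continue
                # a 5'-edge start is only distinct when ATG-less; an internal
                # non-ATG start is not a candidate
                if c0 != 0 and codons[c0] != "ATG":
                    continue
                start = f + 3 * c0
                candidates.append(
                    (-span, rank, start, strand, end, codons[c0] == "ATG", has_stop)
                )
    if not candidates:
        return None
    candidates.sort()
    neg_span, rank, start, strand, end, has_start, has_stop = candidates[0]
    s = strands[rank][1]
    cds = s[start:end]
    if has_stop:
        cds = cds[:-3]
    prot = "".join(translate_codon(cds[p : p + 3]) for p in range(0, len(cds), 3))
    return {
        "length": -neg_span,
        "strand": strand,
        "start": start + 1,
        "end": end,
        "has_start": has_start,
        "has_stop": has_stop,
        "protein": prot,
    }


_TABLE = {}


def translate_codon(codon: str) -> str:
    global _TABLE
    if not _TABLE:
        bases = "TCAG"
        aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        _TABLE = {
            a + b + c: aas[i * 16 + j * 4 + k]
            for i, a in enumerate(bases)
            for j, b in enumerate(bases)
            for k, c in enumerate(bases)
        }
    return _TABLE.get(codon, "X")


def duplicate_oracle(named_seqs: list[tuple[str, str, int]]) -> dict[str, str]:
    """All-pairs duplicate detection; (id, seq, cds_len) -> dropped id -> survivor."""
    dropped: dict[str, str] = {}
    order = sorted(named_seqs, key=lambda r: (-r[2], r[0]))
    for i, (tid, seq, _) in enumerate(order):
        if tid in dropped:
            continue
        for tid2, seq2, _ in order[i + 1 :]:
            if tid2 in dropped and tid2 != tid:
                pass
            if tid2 != tid and seq2 == seq and tid2 not in dropped:
                dropped[tid2] = tid
    return dropped


def fragment_oracle(
    named_seqs: list[tuple[str, str]], check_revcomp: bool = True
) -> set[str]:
    """Naive containment scan: dropped ids (substring of a surviving longer seq)."""
    order = sorted(named_seqs, key=lambda r: (-len(r[1]), r[0]))
    kept: list[tuple[str, str]] = []
    dropped: set[str] = set()
    for tid, seq in order:
        hit = False
        for _, kseq in kept:
            if seq in kseq or (check_revcomp and revcomp(seq) in kseq):
                hit = True
                break
        if hit:
            dropped.add(tid)
        else:
            kept.append((tid, seq))
    return dropped


def overlap_components_oracle(genes) -> list[frozenset]:
    """Union-find over all O(n^2) pairwise overlap tests.

    ``genes``: iterable of (gene_id, chrom, strand, start, end), 1-based
    inclusive. Returns the set of components as frozensets of gene ids.
    """
    genes = list(genes)
    g = nx.Graph()
    for gid, *_ in genes:
        g.add_node(gid)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            if a[1] == b[1] and a[2] == b[2] and a[3] <= b[4] and b[3] <= a[4]:
                g.add_edge(a[0], b[0])
    return [frozenset(c) for c in nx.connected_components(g)]


def nx_oracle(lengths: list[int], fraction: float) -> int:
    """Cumulative-sum N-metric over the stated definition, by direct scan."""
    if not lengths:
        return 0
    total = sum(lengths)
    best = 0
    for L in sorted(set(lengths), reverse=True):
        covered = sum(x for x in lengths if x >= L)
        if covered >= fraction * total:
            return L
    return min(lengths)


def semiglobal_identity_oracle(a: str, b: str) -> float:
    """matches / shorter-length identity via Biopython infix alignment."""
    from Bio import Align

    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aligner.end_gap_score = 0.0  # semi-global: overhangs are free
    aln = aligner.align(long_, short)[0]
    matches = 0
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        seg_t = long_[ts:te]
        seg_q = short[qs:qe]
        matches += sum(1 for x, y in zip(seg_t, seg_q) if x == y)
    return matches / len(short)
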