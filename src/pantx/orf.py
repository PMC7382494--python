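"""Open reading frame calling on de novo assembled transcripts.

Transcript sets pooled from many assemblers mix oriented and unoriented
sequences, truncated 5'/3' ends and UTR junk, so the ORF caller scans all six
frames, tolerates edge-truncated reading frames, and reports completeness
(start/stop presence) rather than demanding a full codon triplet structure.
The longest coding region is the redundancy-reduction currency: duplicate and
variant groups keep the member with the longest CDS.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


@dataclass(frozen=True)
class Orf:
    """A called open reading frame.

    ``start``/``end`` are 1-based inclusive coordinates *on the given strand*
    (i.e. on the reverse complement when ``strand == "-"``). The span includes
    the terminal stop codon when ``has_stop`` is true, so the span length is
    divisible by 3 in that case.
    """

    start: int = 0
    end: int = 0
    strand: str = "+"
    has_start: bool = False
    has_stop: bool = False

    @property
    def length(self) -> int:
        return 0 if self.end == 0 else self.end - self.start + 1

    @property
    def is_empty(self) -> bool:
        return self.end == 0

    @property
    def complete(self) -> bool:
        return self.has_start and self.has_stop


def translate_cds(cds: str) -> str:
    """Translate a nucleotide CDS with the standard nuclear code.

    A terminal stop codon is trimmed; incomplete trailing bases are ignored;
    ambiguous codons (any N) translate to X.
    """
    n = len(cds) // 3 * 3
    cds = cds[:n].upper()
    if cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    if not cds:
        return ""
    aa = list(str(Seq(cds).translate()))
    acgt = set("ACGT")
    for i in range(len(aa)):
        if not acgt.issuperset(cds[3 * i : 3 * i + 3]):
            aa[i] = "X"  # any ambiguity blocks silent-variant matching
    return "".join(aa)


def _frame_candidates(seq: str, strand: str):
    """Yield ORF candidates (start0, end0, has_start, has_stop) on one strand.

    Coordinates are 0-based half-open on the strand sequence. A candidate
    either begins at the first ATG of a stop-free codon run, or at the run
    start when the run is truncated at the 5' edge of its frame. Runs that end
    without a stop are only candidates when truncated at the 3' edge.
    """
    n = len(seq)
    for frame in range(3):
        ncod = (n - frame) // 3
        if ncod <= 0:
            continue
        run_start = 0  # codon index where current stop-free run begins
        i = 0
        while i <= ncod:
            at_stop = i < ncod and seq[frame + 3 * i : frame + 3 * i + 3] in STOP_CODONS
            if at_stop or i == ncod:
                run_end = i  # exclusive codon index
                if run_end > run_start or at_stop:
                    has_stop = at_stop
                    cand_end = frame + 3 * (run_end + (1 if has_stop else 0))
                    edge5 = run_start == 0
                    first_atg = None
                    for c in range(run_start, run_end):
                        if seq[frame + 3 * c : frame + 3 * c + 3] == START_CODON:
                            first_atg = c
                            break
                    if first_atg is not None:
                        yield (frame + 3 * first_atg, cand_end, True, has_stop)
                    if edge5 and first_atg != run_start and run_end > run_start:
                        yield (frame + 3 * run_start, cand_end, False, has_stop)
                run_start = i + 1
            i += 1


def find_longest_orf(seq: str, both_strands: bool = True) -> tuple[Orf, str]:
    """Find the longest ORF in ``seq`` and its translation.

    Scans 3 frames per strand (6 when ``both_strands``). Edge-truncated ORFs
    are allowed and flagged via ``has_start``/``has_stop``. Ties are broken in
    favour of the + strand, then the 5'-most start on the reported strand.

    Returns an empty :class:`Orf` and an empty protein when no candidate
    exists (e.g. the sequence is shorter than one codon).
    """
    seq = seq.upper()
    strands = [("+", seq)]
    if both_strands:
        strands.append(("-", str(Seq(seq).reverse_complement())))

    best: tuple[int, int, int] | None = None  # (-length, strand_rank, start)
    best_orf = Orf()
    best_aa = ""
    for rank, (strand, s) in enumerate(strands):
        for start0, end0, has_start, has_stop in _frame_candidates(s, strand):
            if end0 <= start0:
                continue
            key = (-(end0 - start0), rank, start0)
            if best is None or key < best:
                best = key
                best_orf = Orf(start0 + 1, end0, strand, has_start, has_stop)
                best_aa = translate_cds(s[start0:end0])
    return best_orf, best_aa
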