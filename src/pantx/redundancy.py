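"""Reduce a transcript over-assembly to main / alt / drop sets.

Pooling the output of many de novo assemblers over the same reads produces a
deliberately redundant "over-assembly". Reduction proceeds in four steps,
each recorded with a reason tag:

1. perfect duplicates — byte-identical nucleotide sequences collapse to the
   member with the longest coding region (ascending-id tie-break);
2. perfect fragments — exact substrings of a surviving longer sequence are
   dropped (reverse-complement containment counts by default, as unstranded
   protocols are common);
3. silent variants — identical protein, non-identical nucleotide sequence,
   grouped as putative alleles of one locus;
4. isoform linking — pairs sharing a high-identity exon-sized local segment
   are linked as putative splice forms.

Connected components over (3)+(4) each elect one representative ("main",
longest CDS) with the remaining members tagged "alt" pointing at it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
from Bio.Seq import Seq

from ._align import best_local_path
from .orf import Orf, find_longest_orf

DROP_REASONS = ("perfect_duplicate", "perfect_fragment")


@dataclass
class TranscriptRecord:
    """A candidate transcript from an over-assembly, with its called ORF."""

    transcript_id: str
    seq: str
    genotype: str = ""
    assembly_id: str = ""
    orf: Orf | None = None
    aa: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    @property
    def cds_len(self) -> int:
        return 0 if self.orf is None else self.orf.length

    @property
    def cds(self) -> str:
        """Nucleotide CDS on the ORF strand (terminal stop included)."""
        if self.orf is None or self.orf.is_empty:
            return ""
        s = self.seq if self.orf.strand == "+" else str(Seq(self.seq).reverse_complement())
        return s[self.orf.start - 1 : self.orf.end]


@dataclass(frozen=True)
class ClassTag:
    cls: str  # "main" | "alt" | "drop"
    rep_id: str | None = None
    reason: str = "other"

    def __post_init__(self) -> None:
        if self.cls == "main" and self.rep_id is not None:
            raise ValueError("main transcripts carry no rep_id")
        if self.cls == "alt" and self.rep_id is None:
            raise ValueError("alt transcripts must name their representative")


@dataclass(frozen=True)
class IsoformParams:
    """Exon-sized high-identity segment criterion for isoform linking."""

    min_segment_len: int = 120
    min_segment_identity: float = 0.98

    def __post_init__(self) -> None:
        if not (0 < self.min_segment_identity <= 1):
            raise ValueError("identity must be in (0, 1]")
        if self.min_segment_len < 1:
            raise ValueError("segment length must be >= 1")


def call_orfs(records: list[TranscriptRecord], both_strands: bool = True) -> None:
    """Call the longest ORF for every record in place."""
    for r in records:
        r.orf, r.aa = find_longest_orf(r.seq, both_strands=both_strands)


def _survivor_order(records: list[TranscriptRecord]) -> list[TranscriptRecord]:
    return sorted(records, key=lambda r: (-r.cds_len, r.transcript_id))


def drop_perfect_duplicates(records: list[TranscriptRecord]) -> dict[str, ClassTag]:
    """Tag all but one member of each byte-identical sequence group.

    The survivor is the member with the longest CDS; identical sequences have
    identical CDS, so the tie-break is ascending transcript id — the order the
    upstream tooling is observed to use.
    """
    groups: dict[str, list[TranscriptRecord]] = defaultdict(list)
    for r in records:
        groups[r.seq].append(r)
    tags: dict[str, ClassTag] = {}
    for members in groups.values():
        if len(members) < 2:
            continue
        ordered = _survivor_order(members)
        keeper = ordered[0]
        for other in ordered[1:]:
            tags[other.transcript_id] = ClassTag(
                "drop", rep_id=keeper.transcript_id, reason="perfect_duplicate"
            )
    return tags


def drop_perfect_fragments(
    records: list[TranscriptRecord],
    dropped: dict[str, ClassTag] | None = None,
    check_revcomp: bool = True,
) -> dict[str, ClassTag]:
    """Tag records whose sequence is an exact substring of a surviving longer one.

    Processes candidates longest-first so that no survivor is a substring of
    another survivor. With ``check_revcomp`` (default) containment on either
    strand counts, matching unstranded assembly pooling.
    """
    dropped = dict(dropped or {})
    alive = [r for r in records if r.transcript_id not in dropped]
    alive.sort(key=lambda r: (-len(r.seq), r.transcript_id))
    blob = ""
    tags: dict[str, ClassTag] = {}
    kept: list[TranscriptRecord] = []
    for r in alive:
        hit = None
        if blob:
            if r.seq in blob:
                hit = r.seq
            elif check_revcomp:
                rc = str(Seq(r.seq).reverse_complement())
                if rc in blob:
                    hit = rc
        if hit is not None:
            container = next(k for k in kept if hit in k.seq)
            tags[r.transcript_id] = ClassTag(
                "drop", rep_id=container.transcript_id, reason="perfect_fragment"
            )
        else:
            kept.append(r)
            blob = r.seq if not blob else blob + "#" + r.seq
    return tags


def group_silent_variants(
    records: list[TranscriptRecord], dropped: dict[str, ClassTag] | None = None
) -> list[list[str]]:
    """Group surviving records whose translations are identical.

    Such records differ only at silent (synonymous) sites or in their UTRs and
    are treated as one locus. Records without an ORF, or whose protein contains
    X from ambiguous codons, never group. Each group is ordered representative
    first (longest transcript, ascending-id tie-break).
    """
    dropped = dropped or {}
    by_aa: dict[str, list[TranscriptRecord]] = defaultdict(list)
    for r in records:
        if r.transcript_id in dropped:
            continue
        if not r.aa or "X" in r.aa:
            continue
        by_aa[r.aa].append(r)
    groups = []
    for members in by_aa.values():
        if len(members) < 2:
            continue
        members.sort(key=lambda r: (-len(r.seq), r.transcript_id))
        groups.append([r.transcript_id for r in members])
    groups.sort(key=lambda g: g[0])
    return groups


def _shares_exact_block(a: str, b: str, min_len: int) -> bool:
    """Cheap sufficient check: an exact common substring of >= min_len nt."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if len(short) < min_len:
        return False
    windows = {short[p : p + min_len] for p in range(len(short) - min_len + 1)}
    return any(long_[p : p + min_len] in windows for p in range(len(long_) - min_len + 1))


def _segment_in_path(a: str, b: str, params: IsoformParams) -> bool:
    """True when a local-alignment window of length >= min_segment_len reaches
    identity >= min_segment_identity (checked over the optimal local path)."""
    if _shares_exact_block(a, b, params.min_segment_len):
        return True
    _, is_match = best_local_path(a, b)
    cols = len(is_match)
    L = params.min_segment_len
    if cols < L:
        return False
    window = sum(is_match[:L])
    if window >= params.min_segment_identity * L:
        return True
    for c in range(L, cols):
        window += is_match[c] - is_match[c - L]
        if window >= params.min_segment_identity * L:
            return True
    return False


def _seed_len(params: IsoformParams) -> int:
    # pigeonhole: a qualifying segment of length L with <= floor((1-I)*L)
    # non-match columns contains an exact run of at least L/(errors+1) - 1 nt
    errors = int((1 - params.min_segment_identity) * params.min_segment_len)
    return max(12, params.min_segment_len // (errors + 1) - 1)


def link_isoforms(
    records: list[TranscriptRecord],
    params: IsoformParams = IsoformParams(),
    dropped: dict[str, ClassTag] | None = None,
) -> set[tuple[str, str]]:
    """Link pairs sharing an exon-sized high-identity local segment.

    Candidate pairs are generated from shared exact seeds (guaranteed to exist
    inside any qualifying segment), then verified by Smith-Waterman local
    alignment. Edges are symmetric and returned as sorted id pairs.
    """
    dropped = dropped or {}
    alive = [r for r in records if r.transcript_id not in dropped]
    k = _seed_len(params)
    index: dict[str, set[int]] = defaultdict(set)
    for i, r in enumerate(alive):
        seen = set()
        for p in range(0, len(r.seq) - k + 1):
            kmer = r.seq[p : p + k]
            if kmer not in seen:
                seen.add(kmer)
                index[kmer].add(i)
    candidates: set[tuple[int, int]] = set()
    for ids in index.values():
        if len(ids) < 2:
            continue
        ids = sorted(ids)
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                candidates.add((ids[x], ids[y]))
    edges: set[tuple[str, str]] = set()
    for i, j in sorted(candidates):
        a, b = alive[i], alive[j]
        if _segment_in_path(a.seq, b.seq, params):
            edges.add(tuple(sorted((a.transcript_id, b.transcript_id))))
    return edges


def assign_classes(
    records: list[TranscriptRecord],
    groups: list[list[str]],
    edges: set[tuple[str, str]],
    dropped: dict[str, ClassTag] | None = None,
) -> dict[str, ClassTag]:
    """Elect one main per connected component; everything else is alt or drop.

    Components are taken over the union of silent-variant groups and isoform
    edges among surviving records. The main is the member with the longest CDS
    (ascending-id tie-break); other members become alt pointing at it.
    """
    dropped = dict(dropped or {})
    by_id = {r.transcript_id: r for r in records}
    g = nx.Graph()
    for r in records:
        if r.transcript_id not in dropped:
            g.add_node(r.transcript_id)
    for grp in groups:
        for other in grp[1:]:
            g.add_edge(grp[0], other)
    for a, b in edges:
        g.add_edge(a, b)
    tags: dict[str, ClassTag] = dict(dropped)
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda t: (-by_id[t].cds_len, t))
        main = members[0]
        tags[main] = ClassTag("main", reason="representative")
        for other in members[1:]:
            r = by_id[other]
            reason = (
                "silent_variant"
                if any(other in grp and main in grp for grp in groups)
                else "high_identity_isoform"
            )
            tags[other] = ClassTag("alt", rep_id=main, reason=reason)
    return tags


@dataclass
class ReductionResult:
    """Outcome of the four-step reduction, one :class:`ClassTag` per input."""

    records: list[TranscriptRecord]
    tags: dict[str, ClassTag]
    groups: list[list[str]] = field(default_factory=list)
    edges: set[tuple[str, str]] = field(default_factory=set)

    def ids(self, cls: str) -> list[str]:
        return sorted(t for t, tag in self.tags.items() if tag.cls == cls)

    @property
    def main_ids(self) -> list[str]:
        return self.ids("main")

    @property
    def alt_ids(self) -> list[str]:
        return self.ids("alt")

    @property
    def drop_ids(self) -> list[str]:
        return self.ids("drop")

    def subset(self, cls: str) -> list[TranscriptRecord]:
        by_id = {r.transcript_id: r for r in self.records}
        return [by_id[t] for t in self.ids(cls)]


def reduce_overassembly(
    records: list[TranscriptRecord],
    params: IsoformParams = IsoformParams(),
    both_strands: bool = True,
    check_revcomp: bool = True,
) -> ReductionResult:
    """Run the full four-step reduction and classify every record."""
    if any(r.orf is None for r in records):
        call_orfs(records, both_strands=both_strands)
    dropped = drop_perfect_duplicates(records)
    dropped.update(drop_perfect_fragments(records, dropped, check_revcomp=check_revcomp))
    groups = group_silent_variants(records, dropped)
    edges = link_isoforms(records, params, dropped)
    tags = assign_classes(records, groups, edges, dropped)
    return ReductionResult(records=records, tags=tags, groups=groups, edges=edges)
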