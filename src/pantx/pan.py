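"""Pan-transcriptome construction by two-stage greedy CDS clustering.

Per-genotype representative coding sequences are pooled with the merged
reference gene-model CDS and clustered into paralogue groups in two stages,
mirroring the cd-hit-est / cd-hit-2d pair of passes commonly used for this:

* stage 1 — greedy incremental clustering at 90% *global* identity
  (matching columns / shorter-sequence length) with the aligned span
  covering >= 75% of the shorter sequence;
* stage 2 — the stage-1 leftovers, split into tetraploid and reference
  sets, are joined across sets at 90% *local* identity (matching columns /
  alignment length) with >= 45% shorter-sequence coverage.

Clusters are classified by their member genotype set: "core" clusters carry
all genotypes including the reference, clusters restricted to a single
genotype are "genotype_specific", and the two mixed patterns are kept apart
(reference plus a subset of tetraploids vs tetraploid-only sharing).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
from Bio import SeqIO

from ._align import best_local_path

REF_GENOTYPE = "REF"
CATEGORIES = ("core", "ref_plus_some", "tuberosum_shared", "genotype_specific")
STOPS = ("TAA", "TAG", "TGA")


class PanError(ValueError):
    pass


@dataclass
class CdsEntry:
    cds_id: str
    genotype: str
    seq: str
    complete: bool = True

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise PanError(f"{self.cds_id}: empty sequence")


@dataclass(frozen=True)
class StageParams:
    identity: float
    min_short_cov: float
    band: int
    word: int

    def __post_init__(self) -> None:
        if not (0 < self.identity <= 1) or not (0 < self.min_short_cov <= 1):
            raise PanError("identity and coverage must be in (0, 1]")
        if self.word < 1:
            raise PanError("word length must be >= 1")


@dataclass(frozen=True)
class ClusterParams:
    """Two-stage clustering parameters.

    Band and word sizes are recorded for provenance and used as alignment
    search hints; the clustering contract is the identity/coverage criterion.
    """

    stage1: StageParams = StageParams(identity=0.90, min_short_cov=0.75, band=51, word=9)
    stage2: StageParams = StageParams(identity=0.90, min_short_cov=0.45, band=45, word=5)


@dataclass
class PanCluster:
    pan_id: str
    rep_id: str
    members: list[tuple[str, str]]  # (cds_id, genotype)
    category: str | None = None
    partial_fraction: float = 0.0


def seq_is_complete(seq: str) -> bool:
    """A CDS is complete when it begins with ATG and ends in a stop codon."""
    seq = seq.upper()
    return len(seq) % 3 == 0 and seq.startswith("ATG") and seq[-3:] in STOPS


def pool_cds(
    sets: dict[str, str | Path | list[tuple[str, str]]],
    prefix_ids: bool = True,
) -> tuple[list[CdsEntry], dict[str, int]]:
    """Pool per-genotype CDS FASTA files (or in-memory lists) into one list.

    Ids are prefixed with their genotype label (``G1|id``) unless already so
    prefixed; a duplicate id after prefixing is an error. Returns the pooled
    entries and per-genotype counts.
    """
    entries: list[CdsEntry] = []
    counts: dict[str, int] = {}
    seen: set[str] = set()
    for genotype in sets:
        source = sets[genotype]
        if isinstance(source, (str, Path)):
            pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(source), "fasta")]
        else:
            pairs = list(source)
        counts[genotype] = len(pairs)
        for cds_id, seq in pairs:
            if prefix_ids and not cds_id.startswith(genotype + "|"):
                cds_id = f"{genotype}|{cds_id}"
            if cds_id in seen:
                raise PanError(f"duplicate CDS id after genotype prefixing: {cds_id}")
            seen.add(cds_id)
            entries.append(
                CdsEntry(cds_id=cds_id, genotype=genotype, seq=seq, complete=seq_is_complete(seq))
            )
    return entries, counts


def global_identity(a: str, b: str) -> tuple[float, float]:
    """(identity, shorter-sequence coverage) under the global convention.

    The shorter sequence is aligned end-to-end inside the longer (infix
    alignment), so identity = matching columns / shorter length and the
    aligned span covers the whole shorter sequence.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(short, long_, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return 0.0, 0.0
    matches = sum(int(n) for n, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]) if op == "=")
    return matches / len(short), 1.0


def local_segment(a: str, b: str) -> tuple[float, float]:
    """(identity, shorter-sequence coverage) of the best local alignment.

    Identity follows the local convention: matching columns / alignment
    length. Coverage is the aligned span on the shorter sequence over its
    length.
    """
    path, flags = best_local_path(a, b)
    if path is None:
        return 0.0, 0.0
    (a0, a1), (b0, b1) = path.ranges
    short_len = min(len(a), len(b))
    span = (a1 - a0) if len(a) <= len(b) else (b1 - b0)
    return sum(flags) / len(flags), span / short_len


def _greedy_order(entries: list[CdsEntry]) -> list[CdsEntry]:
    return sorted(entries, key=lambda e: (-len(e.seq), e.cds_id))


def greedy_cluster_stage1(
    entries: list[CdsEntry], params: StageParams | None = None
) -> tuple[list[list[CdsEntry]], list[CdsEntry]]:
    """Deterministic greedy incremental clustering (cd-hit-est style).

    Entries are processed longest-first (ascending-id tie-break); each joins
    the first existing cluster whose *representative* it matches at
    >= ``identity`` (global convention) with >= ``min_short_cov`` coverage of
    the shorter sequence, else founds a new cluster. Returns the clusters in
    founding order and the entries whose clusters stayed singletons.
    """
    params = params or ClusterParams().stage1
    clusters: list[list[CdsEntry]] = []
    for e in _greedy_order(entries):
        placed = False
        for cluster in clusters:
            rep = cluster[0]
            short_len = min(len(e.seq), len(rep.seq))
            long_len = max(len(e.seq), len(rep.seq))
            # matches >= t*|short| forces edit distance <= |long| - (2t-1)*|short|
            # (substitutions + query gaps <= (1-t)|short|, target gaps <= |long| - t|short|);
            # capping the edlib search there skips hopeless pairs fast
            cap = long_len - int((2 * params.identity - 1) * short_len) + 1
            chk = edlib.align(
                *((e.seq, rep.seq) if len(e.seq) <= len(rep.seq) else (rep.seq, e.seq)),
                mode="HW",
                k=max(1, cap),
            )
            if chk["editDistance"] < 0:
                continue
            ident, cov = global_identity(e.seq, rep.seq)
            if ident >= params.identity and cov >= params.min_short_cov:
                cluster.append(e)
                placed = True
                break
        if not placed:
            clusters.append([e])
    singletons = [c[0] for c in clusters if len(c) == 1]
    multi = [c for c in clusters if len(c) > 1]
    return multi, singletons


def two_set_cluster_stage2(
    unclustered_tetraploid: list[CdsEntry],
    unclustered_ref: list[CdsEntry],
    params: StageParams | None = None,
) -> tuple[list[list[CdsEntry]], list[CdsEntry]]:
    """Join stage-1 leftovers across the tetraploid/reference split.

    Each reference leftover seeds a cluster (longest-first); each tetraploid
    leftover joins the first reference cluster it matches at >= ``identity``
    (local convention) with >= ``min_short_cov`` coverage of the shorter
    sequence, else stays a singleton. Returns clusters with >= 2 members and
    the remaining singletons (unjoined from both sets).
    """
    params = params or ClusterParams().stage2
    seeds = _greedy_order(unclustered_ref)
    clusters: list[list[CdsEntry]] = [[s] for s in seeds]
    leftovers: list[CdsEntry] = []
    for e in _greedy_order(unclustered_tetraploid):
        placed = False
        for cluster in clusters:
            rep = cluster[0]
            ident, cov = local_segment(e.seq, rep.seq)
            if ident >= params.identity and cov >= params.min_short_cov:
                cluster.append(e)
                placed = True
                break
        if not placed:
            leftovers.append(e)
    multi = [c for c in clusters if len(c) > 1]
    singles = [c[0] for c in clusters if len(c) == 1] + leftovers
    return multi, singles


def classify_membership(
    genotypes: set[str],
    all_genotypes: set[str],
    ref_genotype: str = REF_GENOTYPE,
) -> str:
    """Assign the pan category from a cluster's member genotype set."""
    if not genotypes:
        raise PanError("empty cluster")
    if genotypes == all_genotypes:
        return "core"
    if len(genotypes) == 1:
        return "genotype_specific"
    if ref_genotype in genotypes:
        return "ref_plus_some"
    return "tuberosum_shared"


@dataclass
class PanResult:
    clusters: list[PanCluster]
    entries: list[CdsEntry]
    params: ClusterParams

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for cl in self.clusters:
            counts[cl.category] += 1
        return counts

    def membership(self) -> dict[str, str]:
        """cds_id -> pan_id over every pooled entry."""
        return {cid: cl.pan_id for cl in self.clusters for cid, _ in cl.members}


def build_pan(
    entries: list[CdsEntry],
    params: ClusterParams | None = None,
    ref_genotype: str = REF_GENOTYPE,
) -> PanResult:
    """Run both clustering stages and classify every cluster.

    Every pooled entry ends up in exactly one cluster; pan ids are assigned in
    cluster-founding order (stage-1 clusters, stage-2 clusters, then the
    remaining singletons) as ``stPanTr_`` + a zero-padded 6-digit index.
    """
    params = params or ClusterParams()
    all_genotypes = {e.genotype for e in entries}
    stage1, leftovers = greedy_cluster_stage1(entries, params.stage1)
    tetra = [e for e in leftovers if e.genotype != ref_genotype]
    ref = [e for e in leftovers if e.genotype == ref_genotype]
    stage2, singles = two_set_cluster_stage2(tetra, ref, params.stage2)
    ordered: list[list[CdsEntry]] = stage1 + stage2 + [[s] for s in singles]
    by_id = {e.cds_id: e for e in entries}
    clusters: list[PanCluster] = []
    for i, members in enumerate(ordered, 1):
        rep = sorted(members, key=lambda e: (-len(e.seq), e.cds_id))[0]
        genos = {e.genotype for e in members}
        partial = sum(1 for e in members if not e.complete) / len(members)
        clusters.append(
            PanCluster(
                pan_id=f"stPanTr_{i:06d}",
                rep_id=rep.cds_id,
                members=[(e.cds_id, e.genotype) for e in members],
                category=classify_membership(genos, all_genotypes, ref_genotype),
                partial_fraction=partial,
            )
        )
    assert sum(len(c.members) for c in clusters) == len(by_id)
    return PanResult(clusters=clusters, entries=entries, params=params)


def export_pan(
    result: PanResult,
    rep_fasta: str | Path,
    alt_fasta: str | Path,
    membership_tsv: str | Path,
    counts_tsv: str | Path | None = None,
) -> None:
    """Write representative/alternative FASTA, membership TSV and counts."""
    by_id = {e.cds_id: e for e in result.entries}
    with open(rep_fasta, "w") as rf, open(alt_fasta, "w") as af:
        for cl in result.clusters:
            rf.write(f">{cl.pan_id} rep={cl.rep_id} category={cl.category}\n")
            rf.write(by_id[cl.rep_id].seq + "\n")
            for cid, _ in cl.members:
                if cid != cl.rep_id:
                    af.write(f">{cid} pan={cl.pan_id}\n{by_id[cid].seq}\n")
    with open(membership_tsv, "w") as mf:
        mf.write("pan_id\tcategory\trep_id\tn_members\tpartial_fraction\tgenotypes\tmembers\n")
        for cl in result.clusters:
            genos = ",".join(sorted({g for _, g in cl.members}))
            members = ",".join(cid for cid, _ in cl.members)
            mf.write(
                f"{cl.pan_id}\t{cl.category}\t{cl.rep_id}\t{len(cl.members)}"
                f"\t{cl.partial_fraction:.4f}\t{genos}\t{members}\n"
            )
    if counts_tsv is not None:
        with open(counts_tsv, "w") as cf:
            cf.write("category\tn_clusters\n")
            for cat, n in result.category_counts().items():
                cf.write(f"{cat}\t{n}\n")
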