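"""Merge two gene-model annotations over one genome into a union gene set.

Two independent annotation projects over the same reference genome (labelled
source A and source B; for potato, the PGSC and ITAG gene models) predict
overlapping but non-identical gene sets. Merging proceeds in three steps:

1. genes from both sources are clustered into connected components of the
   same-chromosome, same-strand, >=1 bp span-overlap graph;
2. each component is classified by a decision tree on its (A, B) topology:
   singletons are kept as-is; 1:1 components keep the policy-preferred
   source; 1:2 / 2:1 components keep the spanning gene when its CDS covers
   enough of each covered gene's CDS, otherwise the split genes; everything
   larger or more tangled goes to a manual-curation queue;
3. retained genes are written to a merged GFF3 together with a curation
   report and a full per-gene accounting table.

Curation is file-driven: a reviewed override table maps cluster ids to the
gene ids to retain, and is applied on a re-run — never interactively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

from .coords import gff_to_internal, internal_to_gff, overlap_len, union_length

OUTCOMES = (
    "keep_singleton",
    "keep_A",
    "keep_B",
    "keep_spanning",
    "keep_split",
    "manual_curation",
)


class MergeError(ValueError):
    pass


@dataclass
class GeneModelRecord:
    """One annotated gene span with its mRNA/CDS structure.

    ``start``/``end`` are 1-based inclusive genomic coordinates, as in GFF3.
    ``transcripts`` maps each mRNA id to its CDS segments (1-based inclusive).
    """

    gene_id: str
    source_set: str  # "A" | "B"
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[tuple[str, list[tuple[int, int]]]] = field(default_factory=list)
    gff_lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.source_set not in ("A", "B"):
            raise MergeError(f"source_set must be A or B, got {self.source_set!r}")
        if self.strand not in ("+", "-"):
            raise MergeError(f"{self.gene_id}: strand must be + or -")
        if self.start > self.end or self.start < 1:
            raise MergeError(f"{self.gene_id}: invalid span [{self.start}, {self.end}]")
        for mrna, segs in self.transcripts:
            for s, e in segs:
                if s < self.start or e > self.end or s > e:
                    raise MergeError(
                        f"{self.gene_id}: CDS segment [{s}, {e}] of {mrna} "
                        f"outside gene span [{self.start}, {self.end}]"
                    )

    @property
    def span0(self) -> tuple[int, int]:
        return gff_to_internal(self.start, self.end)

    def cds_intervals0(self) -> list[tuple[int, int]]:
        return [gff_to_internal(s, e) for _, segs in self.transcripts for s, e in segs]

    def cds_length(self) -> int:
        """Union length of all CDS segments across the gene's transcripts."""
        return union_length(self.cds_intervals0())


@dataclass
class OverlapCluster:
    cluster_id: str
    members: list[GeneModelRecord]
    outcome: str | None = None
    retained: list[GeneModelRecord] = field(default_factory=list)

    @property
    def n_A(self) -> int:
        return sum(1 for m in self.members if m.source_set == "A")

    @property
    def n_B(self) -> int:
        return sum(1 for m in self.members if m.source_set == "B")

    @property
    def topology(self) -> tuple[int, int]:
        return (self.n_A, self.n_B)


@dataclass(frozen=True)
class MergePolicy:
    """Programmatic resolution rules for the non-trivial merge outcomes.

    ``preferred_source`` settles 1:1 ties (default B, the second annotation);
    ``spanning_rule`` is the minimum fraction of each covered gene's CDS that
    the spanning gene's CDS must contain before the spanning gene replaces
    the split genes. Curation decisions come from ``curation_overrides``,
    a reviewed cluster_id -> retained-gene-ids map.
    """

    preferred_source: str = "B"
    spanning_rule: float = 0.5
    curation_overrides: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.preferred_source not in ("A", "B"):
            raise MergeError("preferred_source must be A or B")
        if not (0 <= self.spanning_rule <= 1):
            raise MergeError("spanning_rule must be in [0, 1]")


def _validate_gff_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise MergeError(
                    f"{path}: malformed GFF3 at line {lineno}: "
                    f"expected 9 tab-separated columns, found {len(cols)}"
                )
            try:
                s, e = int(cols[3]), int(cols[4])
            except ValueError:
                raise MergeError(
                    f"{path}: malformed GFF3 at line {lineno}: non-numeric coordinates"
                ) from None
            if s < 1 or e < s:
                raise MergeError(f"{path}: malformed GFF3 at line {lineno}: bad interval {s}..{e}")


def read_gene_models(path: str | Path, source_label: str) -> list[GeneModelRecord]:
    """Read gene records (with attached mRNA/CDS children) from a GFF3 file.

    Child features are attached through their Parent attributes; CDS features
    that cannot be traced to a gene raise an error listing the orphan ids.
    """
    _validate_gff_lines(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    records: list[GeneModelRecord] = []
    claimed_cds: set[str] = set()
    for gene in db.features_of_type("gene"):
        transcripts: list[tuple[str, list[tuple[int, int]]]] = []
        direct_cds = [f for f in db.children(gene, level=1, featuretype="CDS")]
        if direct_cds:
            segs = sorted((f.start, f.end) for f in direct_cds)
            transcripts.append((gene.id, segs))
            claimed_cds.update(str(f) for f in direct_cds)
        for mrna in db.children(gene, level=1, featuretype="mRNA"):
            cds = [f for f in db.children(mrna, level=1, featuretype="CDS")]
            segs = sorted((f.start, f.end) for f in cds)
            transcripts.append((mrna.id, segs))
            claimed_cds.update(str(f) for f in cds)
        lines = [str(gene)] + [str(f) for f in db.children(gene, order_by="start")]
        records.append(
            GeneModelRecord(
                gene_id=gene.id,
                source_set=source_label,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                transcripts=transcripts,
                gff_lines=lines,
            )
        )
    orphans = [str(f.attributes.get("ID", ["?"])[0]) for f in db.features_of_type("CDS") if str(f) not in claimed_cds]
    if orphans:
        raise MergeError(f"{path}: CDS features without a resolvable parent gene: {sorted(set(orphans))}")
    return records


def build_overlap_clusters(
    models_A: list[GeneModelRecord], models_B: list[GeneModelRecord]
) -> list[OverlapCluster]:
    """Connected components of the same-chrom, same-strand, >=1 bp overlap graph.

    A plane-sweep over genes sorted by start yields the same components as an
    explicit pairwise-overlap graph: within one (chrom, strand) track, a gene
    joins the open component when it starts at or before the component's
    running maximum end.
    """
    by_track: dict[tuple[str, str], list[GeneModelRecord]] = {}
    for m in list(models_A) + list(models_B):
        by_track.setdefault((m.chrom, m.strand), []).append(m)
    clusters: list[OverlapCluster] = []
    raw: list[list[GeneModelRecord]] = []
    for track in sorted(by_track):
        genes = sorted(by_track[track], key=lambda g: (g.start, g.end, g.source_set, g.gene_id))
        current: list[GeneModelRecord] = []
        max_end = -1
        for g in genes:
            if current and g.start <= max_end:
                current.append(g)
            else:
                if current:
                    raw.append(current)
                current = [g]
            max_end = max(max_end, g.end)
        if current:
            raw.append(current)
    raw.sort(key=lambda ms: (ms[0].chrom, ms[0].start, ms[0].strand, ms[0].gene_id))
    for i, members in enumerate(raw, 1):
        clusters.append(OverlapCluster(cluster_id=f"OC{i:06d}", members=members))
    return clusters


def _cds_coverage_of(spanner: GeneModelRecord, covered: GeneModelRecord) -> float:
    """Fraction of `covered`'s CDS union contained in `spanner`'s CDS union."""
    cov_len = covered.cds_length()
    if cov_len == 0:
        return 0.0
    from .coords import interval_union

    sp = interval_union(spanner.cds_intervals0())
    cv = interval_union(covered.cds_intervals0())
    shared = sum(overlap_len(a, b) for a in sp for b in cv)
    return shared / cov_len


def classify_and_resolve(cluster: OverlapCluster, policy: MergePolicy) -> OverlapCluster:
    """Fill the decision-tree outcome and the retained member set of a cluster."""
    mem = cluster.members
    n_A, n_B = cluster.topology
    total = n_A + n_B
    if total == 1:
        cluster.outcome = "keep_singleton"
        cluster.retained = list(mem)
    elif (n_A, n_B) == (1, 1):
        cluster.outcome = "keep_A" if policy.preferred_source == "A" else "keep_B"
        cluster.retained = [m for m in mem if m.source_set == policy.preferred_source]
    elif (n_A, n_B) in ((1, 2), (2, 1)):
        single_src = "A" if n_A == 1 else "B"
        single = next(m for m in mem if m.source_set == single_src)
        covered = [m for m in mem if m.source_set != single_src]
        if all(_cds_coverage_of(single, c) >= policy.spanning_rule for c in covered):
            cluster.outcome = "keep_spanning"
            cluster.retained = [single]
        else:
            cluster.outcome = "keep_split"
            cluster.retained = sorted(covered, key=lambda m: (m.start, m.gene_id))
    else:
        cluster.outcome = "manual_curation"
        override = policy.curation_overrides.get(cluster.cluster_id)
        if override is not None:
            ids = {m.gene_id: m for m in mem}
            unknown = [g for g in override if g not in ids]
            if unknown:
                raise MergeError(
                    f"{cluster.cluster_id}: override names gene ids not in cluster: {unknown}"
                )
            cluster.retained = [ids[g] for g in override]
        else:
            cluster.retained = []
    return cluster


def _gene_gff_lines(g: GeneModelRecord) -> list[str]:
    if g.gff_lines:
        lines = list(g.gff_lines)
        lines[0] = lines[0] + f";merge_source={g.source_set}"
        return lines
    lines = [
        "\t".join(
            [g.chrom, "pantx", "gene", str(g.start), str(g.end), ".", g.strand, ".",
             f"ID={g.gene_id};merge_source={g.source_set}"]
        )
    ]
    for mrna, segs in g.transcripts:
        mstart = min(s for s, _ in segs) if segs else g.start
        mend = max(e for _, e in segs) if segs else g.end
        lines.append(
            "\t".join([g.chrom, "pantx", "mRNA", str(mstart), str(mend), ".", g.strand, ".",
                       f"ID={mrna};Parent={g.gene_id}"])
        )
        for i, (s, e) in enumerate(segs, 1):
            lines.append(
                "\t".join([g.chrom, "pantx", "CDS", str(s), str(e), ".", g.strand, "0",
                           f"ID={mrna}.cds{i};Parent={mrna}"])
            )
    return lines


def write_merged_gff(
    clusters: list[OverlapCluster],
    out_path: str | Path,
    report_path: str | Path | None = None,
    accounting_path: str | Path | None = None,
    strict: bool = False,
) -> dict[str, str]:
    """Write the merged GFF3 plus curation report; return per-gene accounting.

    Every input gene maps to exactly one of ``retained``,
    ``superseded_by:<gene_id>`` or ``curation:<cluster_id>``.
    """
    unresolved = [
        c.cluster_id for c in clusters if c.outcome == "manual_curation" and not c.retained
    ]
    if strict and unresolved:
        raise MergeError(f"unresolved manual-curation clusters: {unresolved}")
    accounting: dict[str, str] = {}
    retained_genes: list[GeneModelRecord] = []
    for c in clusters:
        if c.outcome is None:
            raise MergeError(f"{c.cluster_id}: cluster not classified")
        retained_ids = {m.gene_id for m in c.retained}
        retained_genes.extend(c.retained)
        for m in c.members:
            if m.gene_id in retained_ids:
                accounting[m.gene_id] = "retained"
            elif c.outcome == "manual_curation":
                accounting[m.gene_id] = f"curation:{c.cluster_id}"
            else:
                accounting[m.gene_id] = f"superseded_by:{c.retained[0].gene_id}"
    retained_genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    with open(out_path, "w") as out:
        out.write("##gff-version 3\n")
        for g in retained_genes:
            for line in _gene_gff_lines(g):
                out.write(line + "\n")
    if report_path is not None:
        with open(report_path, "w") as rep:
            rep.write("cluster_id\tn_A\tn_B\tmember_gene_ids\tmember_coordinates\taction\n")
            for c in clusters:
                if c.outcome != "manual_curation":
                    continue
                coords = ";".join(f"{m.chrom}:{m.start}-{m.end}({m.strand})" for m in c.members)
                ids = ";".join(m.gene_id for m in c.members)
                action = (
                    "retain:" + ";".join(m.gene_id for m in c.retained)
                    if c.retained
                    else "pending"
                )
                rep.write(f"{c.cluster_id}\t{c.n_A}\t{c.n_B}\t{ids}\t{coords}\t{action}\n")
    if accounting_path is not None:
        with open(accounting_path, "w") as acc:
            acc.write("gene_id\tfate\n")
            for gid in sorted(accounting):
                acc.write(f"{gid}\t{accounting[gid]}\n")
    if unresolved:
        warnings.warn(
            f"{len(unresolved)} manual-curation clusters remain unresolved", stacklevel=2
        )
    return accounting


def read_overrides(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a curation override TSV (cluster_id <tab> semicolon-joined gene ids)."""
    overrides: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("cluster_id"):
                continue
            cols = line.split("\t")
            genes = tuple(g for g in cols[1].split(";") if g) if len(cols) > 1 else ()
            overrides[cols[0]] = genes
    return overrides


def merge_annotations(
    models_A: list[GeneModelRecord],
    models_B: list[GeneModelRecord],
    policy: MergePolicy = MergePolicy(),
) -> list[OverlapCluster]:
    """Cluster, classify and resolve both gene sets in one call."""
    clusters = build_overlap_clusters(models_A, models_B)
    return [classify_and_resolve(c, policy) for c in clusters]
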