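"""Gene-model merging: GFF3 IO, overlap components, decision tree, output."""

from __future__ import annotations

import itertools

import pytest

from pantx.annotation import (
    GeneModelRecord,
    MergeError,
    MergePolicy,
    build_overlap_clusters,
    classify_and_resolve,
    merge_annotations,
    read_gene_models,
    write_merged_gff,
)

from .oracles import overlap_components_oracle


def gene(gid, source, chrom="chr01", strand="+", start=1, end=900, cds=None):
    segs = cds or [(start, end)]
    return GeneModelRecord(
        gene_id=gid, source_set=source, chrom=chrom, strand=strand,
        start=start, end=end, transcripts=[(f"{gid}.m1", segs)],
    )


def write_gff(path, genes):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsrc\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for mrna, segs in g.transcripts:
                ms, me = min(s for s, _ in segs), max(e for _, e in segs)
                fh.write(
                    f"{g.chrom}\tsrc\tmRNA\t{ms}\t{me}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(segs, 1):
                    fh.write(
                        f"{g.chrom}\tsrc\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\tID={mrna}.c{i};Parent={mrna}\n"
                    )


class TestReadGeneModels:
    def test_reads_synthetic_fixture_spans(self, tmp_path):
        genes = [
            gene("g1", "A", start=100, end=500),
            gene("g2", "A", start=700, end=1200, cds=[(700, 900), (1000, 1200)]),
            gene("g3", "A", chrom="chr02", start=50, end=200),
        ]
        path = tmp_path / "a.gff3"
        write_gff(path, genes)
        # independent line-oriented scan of the fixture
        spans = {}
        for line in open(path):
            cols = line.rstrip("\n").split("\t")
            if len(cols) == 9 and cols[2] == "gene":
                spans[cols[8].split("=")[1]] = (cols[0], int(cols[3]), int(cols[4]))
        records = read_gene_models(path, "A")
        assert len(records) == 3
        assert {r.gene_id: (r.chrom, r.start, r.end) for r in records} == spans
        g2 = next(r for r in records if r.gene_id == "g2")
        assert g2.transcripts == [("g2.m1", [(700, 900), (1000, 1200)])]

    def test_pragma_only_file_is_empty_set(self, tmp_path):
        path = tmp_path / "empty.gff3"
        path.write_text("##gff-version 3\n")
        assert read_gene_models(path, "B") == []

    def test_malformed_line_error_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("##gff-version 3\nchr01\tsrc\tgene\toops\t10\t.\t+\t.\tID=g\n")
        with pytest.raises(MergeError, match="line 2"):
            read_gene_models(path, "A")

    def test_orphan_cds_error_lists_ids(self, tmp_path):
        path = tmp_path / "orphan.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr01\tsrc\tgene\t1\t90\t.\t+\t.\tID=g1\n"
            "chr01\tsrc\tCDS\t1\t90\t.\t+\t0\tID=lost;Parent=nowhere\n"
        )
        with pytest.raises(MergeError, match="lost"):
            read_gene_models(path, "A")


class TestOverlapClusters:
    def test_opposite_strands_stay_apart(self):
        a = gene("a", "A", strand="+", start=100, end=500)
        b = gene("b", "B", strand="-", start=100, end=500)
        clusters = build_overlap_clusters([a], [b])
        assert sorted(len(c.members) for c in clusters) == [1, 1]

    def test_spanning_gene_joins_three_covered_genes(self):
        # one source-B gene spanning three source-A coding sequences
        b = gene("Sotub12g014200", "B", start=1000, end=9000)
        a_genes = [
            gene("PGSC5728", "A", start=1200, end=2400),
            gene("PGSC5745", "A", start=3000, end=4800),
            gene("PGSC5726", "A", start=6000, end=8500),
        ]
        clusters = build_overlap_clusters(a_genes, [b])
        assert len(clusters) == 1
        assert len(clusters[0].members) == 4

    def test_component_assignment_matches_union_find(self, rng):
        genes_a, genes_b = [], []
        for i in range(60):
            chrom = f"chr{int(rng.integers(1, 3)):02d}"
            strand = "+-"[int(rng.integers(0, 2))]
            start = int(rng.integers(1, 5000))
            end = start + int(rng.integers(50, 800))
            g = gene(f"g{i:03d}", "AB"[i % 2], chrom=chrom, strand=strand, start=start, end=end)
            (genes_a if i % 2 == 0 else genes_b).append(g)
        clusters = build_overlap_clusters(genes_a, genes_b)
        got = {frozenset(m.gene_id for m in c.members) for c in clusters}
        expected = set(
            overlap_components_oracle(
                (g.gene_id, g.chrom, g.strand, g.start, g.end)
                for g in genes_a + genes_b
            )
        )
        assert got == expected

    def test_every_gene_in_exactly_one_cluster(self, rng):
        genes_a = [
            gene(f"a{i}", "A", start=int(rng.integers(1, 2000)), end=int(rng.integers(2000, 3000)))
            for i in range(20)
        ]
        clusters = build_overlap_clusters(genes_a, [])
        ids = [m.gene_id for c in clusters for m in c.members]
        assert sorted(ids) == sorted(g.gene_id for g in genes_a)


def make_cluster(n_a, n_b, spanning_covers=True):
    """Build a 1D chain cluster with the requested source topology.

    For 1:2 / 2:1 shapes, the single gene spans both others; its CDS either
    covers them fully or only marginally, driving the spanning decision.
    """
    members = []
    if (n_a, n_b) in ((1, 2), (2, 1)):
        single_src = "A" if n_a == 1 else "B"
        other_src = "B" if single_src == "A" else "A"
        if spanning_covers:
            cds = [(100, 2900)]
        else:
            cds = [(100, 250)]
        members.append(gene("single", single_src, start=100, end=2900, cds=cds))
        members.append(gene("o1", other_src, start=200, end=1000))
        members.append(gene("o2", other_src, start=1900, end=2800))
    else:
        pos = 100
        for i in range(n_a):
            members.append(gene(f"a{i}", "A", start=pos, end=pos + 500))
            pos += 300
        for i in range(n_b):
            members.append(gene(f"b{i}", "B", start=pos, end=pos + 500))
            pos += 300
    from pantx.annotation import OverlapCluster

    return OverlapCluster(cluster_id="c1", members=members)


class TestDecisionTree:
    def test_singleton_kept_as_is(self):
        c = classify_and_resolve(make_cluster(1, 0), MergePolicy())
        assert c.outcome == "keep_singleton"
        assert [m.gene_id for m in c.retained] == ["a0"]

    def test_one_to_one_prefers_policy_source(self):
        c = classify_and_resolve(make_cluster(1, 1), MergePolicy(preferred_source="B"))
        assert c.outcome == "keep_B"
        assert [m.source_set for m in c.retained] == ["B"]
        c2 = classify_and_resolve(make_cluster(1, 1), MergePolicy(preferred_source="A"))
        assert c2.outcome == "keep_A"

    def test_one_plus_three_goes_to_curation(self):
        c = classify_and_resolve(make_cluster(3, 1), MergePolicy())
        assert c.outcome == "manual_curation"
        assert c.retained == []

    def test_spanning_rule_drives_1_2_resolution(self):
        c = classify_and_resolve(make_cluster(1, 2, spanning_covers=True), MergePolicy())
        assert c.outcome == "keep_spanning"
        assert [m.gene_id for m in c.retained] == ["single"]
        c2 = classify_and_resolve(make_cluster(1, 2, spanning_covers=False), MergePolicy())
        assert c2.outcome == "keep_split"
        assert sorted(m.gene_id for m in c2.retained) == ["o1", "o2"]

    def test_exhaustive_truth_table_up_to_four_members(self):
        def expected(n_a, n_b):
            if n_a + n_b == 1:
                return "keep_singleton"
            if (n_a, n_b) == (1, 1):
                return "keep_B"
            if (n_a, n_b) in ((1, 2), (2, 1)):
                return "keep_spanning"  # built with covering CDS
            return "manual_curation"

        for n_a, n_b in itertools.product(range(5), range(5)):
            if not (1 <= n_a + n_b <= 4):
                continue
            c = classify_and_resolve(make_cluster(n_a, n_b), MergePolicy())
            assert c.outcome == expected(n_a, n_b), (n_a, n_b)

    def test_override_with_unknown_gene_errors(self):
        policy = MergePolicy(curation_overrides={"c1": ("ghost",)})
        with pytest.raises(MergeError, match="ghost"):
            classify_and_resolve(make_cluster(2, 2), policy)

    def test_override_fills_retained(self):
        policy = MergePolicy(curation_overrides={"c1": ("a0", "b1")})
        c = classify_and_resolve(make_cluster(2, 2), policy)
        assert c.outcome == "manual_curation"
        assert sorted(m.gene_id for m in c.retained) == ["a0", "b1"]


class TestWriteMergedGff:
    def _merge(self, tmp_path, policy=MergePolicy()):
        genes_a = [
            gene("a1", "A", start=100, end=900),
            gene("a2", "A", start=5000, end=5900),
        ]
        genes_b = [gene("b1", "B", start=400, end=1300)]
        clusters = merge_annotations(genes_a, genes_b, policy)
        out = tmp_path / "merged.gff3"
        acc = write_merged_gff(clusters, out, tmp_path / "report.tsv", tmp_path / "acc.tsv")
        return clusters, out, acc

    def test_round_trip_preserves_retained_genes(self, tmp_path):
        clusters, out, acc = self._merge(tmp_path)
        back = read_gene_models(out, "A")
        retained = {m.gene_id for c in clusters for m in c.retained}
        assert {r.gene_id for r in back} == retained == {"a2", "b1"}
        spans = {m.gene_id: (m.start, m.end) for c in clusters for m in c.retained}
        assert {r.gene_id: (r.start, r.end) for r in back} == spans

    def test_accounting_partitions_every_input_gene(self, tmp_path):
        _, _, acc = self._merge(tmp_path)
        assert acc == {
            "a1": "superseded_by:b1",
            "b1": "retained",
            "a2": "retained",
        }

    def test_zero_clusters_writes_pragma_only(self, tmp_path):
        out = tmp_path / "empty.gff3"
        write_merged_gff([], out)
        assert out.read_text() == "##gff-version 3\n"

    def test_strict_mode_rejects_unresolved_curation(self, tmp_path):
        cluster = classify_and_resolve(make_cluster(2, 2), MergePolicy())
        with pytest.raises(MergeError, match="c1"):
            write_merged_gff([cluster], tmp_path / "x.gff3", strict=True)

    def test_outputs_are_deterministic(self, tmp_path):
        _, out1, _ = self._merge(tmp_path / "r1" if (tmp_path / "r1").mkdir() is None else tmp_path)
        (tmp_path / "r2").mkdir()
        _, out2, _ = self._merge(tmp_path / "r2")
        assert out1.read_bytes() == out2.read_bytes()

    def test_retained_genes_disjoint_on_strand(self, rng, tmp_path):
        genes_a = []
        genes_b = []
        for i in range(40):
            start = int(rng.integers(1, 20000))
            g = gene(f"g{i:02d}", "AB"[i % 2], start=start, end=start + int(rng.integers(100, 900)))
            (genes_a if i % 2 == 0 else genes_b).append(g)
        clusters = merge_annotations(genes_a, genes_b)
        retained = [
            m
            for c in clusters
            for m in c.retained
            if c.outcome not in ("keep_split", "manual_curation")
        ]
        for x in retained:
            for y in retained:
                if x.gene_id < y.gene_id and x.chrom == y.chrom and x.strand == y.strand:
                    assert x.end < y.start or y.end < x.start


def test_partition_invariant_on_merge(rng):
    genes_a = [
        gene(f"a{i}", "A", start=int(rng.integers(1, 9000)), end=int(rng.integers(9000, 9900)))
        for i in range(15)
    ]
    genes_b = [
        gene(f"b{i}", "B", start=int(rng.integers(1, 9000)), end=int(rng.integers(9000, 9900)))
        for i in range(15)
    ]
    clusters = merge_annotations(genes_a, genes_b)
    fates = {"retained": 0, "superseded": 0, "curation": 0}
    for c in clusters:
        retained_ids = {m.gene_id for m in c.retained}
        for m in c.members:
            if m.gene_id in retained_ids:
                fates["retained"] += 1
            elif c.outcome == "manual_curation":
                fates["curation"] += 1
            else:
                fates["superseded"] += 1
    assert sum(fates.values()) == 30
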