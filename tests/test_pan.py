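"""Two-stage CDS clustering, membership classification and export."""

from __future__ import annotations

import itertools

import pytest

from pantx.pan import (
    CdsEntry,
    ClusterParams,
    PanError,
    StageParams,
    build_pan,
    classify_membership,
    export_pan,
    global_identity,
    greedy_cluster_stage1,
    local_segment,
    pool_cds,
    two_set_cluster_stage2,
)

from .conftest import random_cds, random_seq
from .oracles import semiglobal_identity_oracle

GENOS = ("G1", "G2", "G3", "REF")


def entry(cid, genotype, seq):
    return CdsEntry(cds_id=cid, genotype=genotype, seq=seq)


class TestPoolCds:
    def test_pooled_list_equals_concatenation(self, tmp_path, rng):
        sets = {}
        expected = []
        for g in GENOS:
            pairs = [(f"c{i}", random_cds(rng, 40)) for i in range(3)]
            fasta = tmp_path / f"{g}.fasta"
            with open(fasta, "w") as fh:
                for cid, seq in pairs:
                    fh.write(f">{cid}\n{seq}\n")
            sets[g] = fasta
            expected.extend((f"{g}|{cid}", seq) for cid, seq in pairs)
        entries, counts = pool_cds(sets)
        assert [(e.cds_id, e.seq) for e in entries] == expected
        assert counts == {g: 3 for g in GENOS}

    def test_empty_fasta_counts_zero(self, tmp_path, rng):
        empty = tmp_path / "e.fasta"
        empty.write_text("")
        other = tmp_path / "o.fasta"
        other.write_text(f">x\n{random_cds(rng, 40)}\n")
        entries, counts = pool_cds({"G1": empty, "G2": other})
        assert counts == {"G1": 0, "G2": 1} and len(entries) == 1

    def test_duplicate_id_after_prefixing_errors(self, rng):
        seq = random_cds(rng, 40)
        with pytest.raises(PanError, match="duplicate"):
            pool_cds({"G1": [("x", seq), ("x", seq)]})

    def test_completeness_flag_from_sequence(self):
        entries, _ = pool_cds({"G1": [("full", "ATGAAATAA"), ("part", "ATGAAA")]})
        flags = {e.cds_id: e.complete for e in entries}
        assert flags == {"G1|full": True, "G1|part": False}


class TestStage1:
    def test_identical_cds_from_four_genotypes_cluster(self, rng):
        seq = random_cds(rng, 100)
        entries = [entry(f"{g}|x", g, seq) for g in GENOS]
        clusters, singles = greedy_cluster_stage1(entries)
        assert len(clusters) == 1 and len(clusters[0]) == 4 and singles == []

    def test_85_percent_identity_stays_apart(self, rng):
        a = random_cds(rng, 134)  # 402 nt
        pos = list(rng.choice(range(3, 399), size=60, replace=False))
        b = list(a)
        for p in pos:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        b = "".join(b)
        ident, _ = global_identity(a, b)
        assert ident < 0.90  # below threshold by construction
        clusters, singles = greedy_cluster_stage1([entry("a", "G1", a), entry("b", "G2", b)])
        assert clusters == [] and len(singles) == 2

    def test_memberships_match_allpairs_alignment_oracle(self, rng):
        entries = []
        for fam in range(12):
            base = random_cds(rng, int(rng.integers(60, 120)))
            n = int(rng.integers(1, 6))
            for i in range(n):
                seq = list(base)
                for p in rng.choice(range(3, len(base) - 3), size=max(1, len(base) // 200), replace=False):
                    seq[int(p)] = "ACGT"[int(rng.integers(0, 4))]
                entries.append(entry(f"f{fam:02d}_{i}", GENOS[i % 4], "".join(seq)))
        entries = entries[:50]
        clusters, singles = greedy_cluster_stage1(entries)
        got = {frozenset(e.cds_id for e in c) for c in clusters}
        got |= {frozenset([e.cds_id]) for e in singles}

        # independent greedy replay with a Biopython-based identity oracle
        params = ClusterParams().stage1
        order = sorted(entries, key=lambda e: (-len(e.seq), e.cds_id))
        oracle_clusters: list[list] = []
        for e in order:
            for c in oracle_clusters:
                rep = c[0]
                if semiglobal_identity_oracle(e.seq, rep.seq) >= params.identity:
                    c.append(e)
                    break
            else:
                oracle_clusters.append([e])
        expected = {frozenset(x.cds_id for x in c) for c in oracle_clusters}
        assert got == expected

    def test_representatives_pairwise_fail_join_criterion(self, rng):
        entries = [
            entry(f"e{i}", GENOS[i % 4], random_cds(rng, int(rng.integers(50, 90))))
            for i in range(30)
        ]
        params = ClusterParams().stage1
        clusters, singles = greedy_cluster_stage1(entries, params)
        reps = [c[0] for c in clusters] + singles
        for a, b in itertools.combinations(reps, 2):
            ident, cov = global_identity(a.seq, b.seq)
            assert not (ident >= params.identity and cov >= params.min_short_cov)


class TestStage2:
    def test_half_length_exact_substring_joins(self, rng):
        ref_seq = random_cds(rng, 120)
        tet_seq = ref_seq[: len(ref_seq) // 2]
        clusters, singles = two_set_cluster_stage2(
            [entry("G1|t", "G1", tet_seq)], [entry("REF|r", "REF", ref_seq)]
        )
        assert len(clusters) == 1
        assert {e.cds_id for e in clusters[0]} == {"REF|r", "G1|t"}

    def test_no_match_stays_singleton(self, rng):
        clusters, singles = two_set_cluster_stage2(
            [entry("G1|t", "G1", random_cds(rng, 80))],
            [entry("REF|r", "REF", random_cds(rng, 80))],
        )
        assert clusters == [] and len(singles) == 2

    def test_planted_truncations_match_local_alignment_oracle(self, rng):
        refs = [entry(f"REF|r{i}", "REF", random_cds(rng, int(rng.integers(80, 140)))) for i in range(6)]
        tets = []
        for i, r in enumerate(refs):
            cut = len(r.seq) // 2
            tets.append(entry(f"G1|t{i}", "G1", r.seq[:cut]))
        tets.append(entry("G1|noise", "G1", random_cds(rng, 100)))
        clusters, singles = two_set_cluster_stage2(tets, refs)
        params = ClusterParams().stage2
        joined = {e.cds_id: c[0].cds_id for c in clusters for e in c[1:]}
        for t in tets:
            best = None
            for r in sorted(refs, key=lambda e: (-len(e.seq), e.cds_id)):
                ident, cov = local_segment(t.seq, r.seq)
                if ident >= params.identity and cov >= params.min_short_cov:
                    best = r.cds_id
                    break
            assert joined.get(t.cds_id) == best


class TestClassifyMembership:
    def test_all_genotypes_is_core(self):
        assert classify_membership(set(GENOS), set(GENOS)) == "core"

    def test_single_genotype_is_specific(self):
        assert classify_membership({"G3"}, set(GENOS)) == "genotype_specific"

    def test_empty_cluster_errors(self):
        with pytest.raises(PanError):
            classify_membership(set(), set(GENOS))

    def test_all_15_subsets_match_truth_table(self):
        for r in range(1, 5):
            for subset in itertools.combinations(GENOS, r):
                s = set(subset)
                if s == set(GENOS):
                    expected = "core"
                elif len(s) == 1:
                    expected = "genotype_specific"
                elif "REF" in s:
                    expected = "ref_plus_some"
                else:
                    expected = "tuberosum_shared"
                assert classify_membership(s, set(GENOS)) == expected, subset


class TestExport:
    def _result(self, rng):
        seqs = {g: random_cds(rng, 100) for g in ("G1", "G2")}
        shared = random_cds(rng, 120)
        sets = {
            "G1": [("a", shared), ("solo", seqs["G1"])],
            "G2": [("b", shared), ("c", shared[:-3] + "TGA")],
            "REF": [("r", shared)],
        }
        entries, _ = pool_cds(sets)
        return build_pan(entries)

    def test_pan_ids_sequential_zero_padded(self, rng):
        result = self._result(rng)
        assert [c.pan_id for c in result.clusters] == [
            f"stPanTr_{i:06d}" for i in range(1, len(result.clusters) + 1)
        ]

    def test_partial_fraction_arithmetic(self):
        entries, _ = pool_cds(
            {
                "G1": [("a", "ATGAAATAA"), ("b", "ATGAAATAA")],
                "G2": [("c", "ATGAAATAA")],
                "REF": [("d", "ATGAAA")],  # no stop: partial
            }
        )
        result = build_pan(entries)
        assert len(result.clusters) == 1
        assert result.clusters[0].partial_fraction == pytest.approx(0.25)

    def test_export_files_consistent(self, rng, tmp_path):
        result = self._result(rng)
        rep, alt, mem, cnt = (tmp_path / n for n in ("r.fa", "a.fa", "m.tsv", "c.tsv"))
        export_pan(result, rep, alt, mem, cnt)
        mem_rows = [l.split("\t") for l in mem.read_text().splitlines()[1:]]
        assert sum(int(r[3]) for r in mem_rows) == len(result.entries)
        assert rep.read_text().count(">") == len(result.clusters)
        assert alt.read_text().count(">") == len(result.entries) - len(result.clusters)

    def test_every_entry_in_exactly_one_cluster(self, rng):
        result = self._result(rng)
        members = [cid for c in result.clusters for cid, _ in c.members]
        assert sorted(members) == sorted(e.cds_id for e in result.entries)

    def test_determinism(self, rng, tmp_path):
        import numpy as np

        r1 = self._result(np.random.default_rng(5))
        r2 = self._result(np.random.default_rng(5))
        assert [(c.pan_id, c.rep_id, c.members, c.category) for c in r1.clusters] == [
            (c.pan_id, c.rep_id, c.members, c.category) for c in r2.clusters
        ]
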