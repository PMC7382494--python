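"""End-to-end synthetic pipeline: simulate, reduce, filter, cluster, score.

This is the integration surface the recovery checks run against: generate a
seeded synthetic study, push each genotype's over-assembly through redundancy
reduction and evidence filtering, pool the final representative CDS with the
reference CDS, build the pan-transcriptome, and score everything against the
planted truth ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .evidence import FilterThresholds, apply_evidence_filter, load_evidence, reassign_classes
from .pan import PanResult, build_pan, export_pan, pool_cds
from .qc import ContigMetrics, contig_metrics
from .redundancy import ReductionResult, TranscriptRecord, reduce_overassembly
from .simulate import SimParams, SimTruth, corrupt_to_overassembly, simulate_evidence, simulate_transcript_truth


@dataclass
class GenotypeOutcome:
    reduction: ReductionResult
    kept_ids: list[str]
    final_tags: dict
    main_records: list[TranscriptRecord]


@dataclass
class PipelineOutcome:
    params: SimParams
    truth: SimTruth
    overassembly: dict[str, list[tuple[str, str]]]
    genotypes: dict[str, GenotypeOutcome]
    pan: PanResult
    metrics: dict[str, float] = field(default_factory=dict)


def run_synthetic_pipeline(
    params: SimParams,
    seed: int,
    workdir: str | Path,
    thresholds: FilterThresholds = FilterThresholds(),
) -> PipelineOutcome:
    """Run the full pipeline on one seeded synthetic study."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    transcripts, truth = simulate_transcript_truth(params, seed)
    over = corrupt_to_overassembly(truth, transcripts, params, seed + 1)
    evidence_paths = simulate_evidence(truth, over, seed + 2, workdir / "evidence",
                                       vector_fraction=params.vector_fraction)
    genotypes: dict[str, GenotypeOutcome] = {}
    pool_sets: dict[str, list[tuple[str, str]]] = {}
    for g in sorted(over):
        records = [TranscriptRecord(tid, seq, genotype=g) for tid, seq in over[g]]
        red = reduce_overassembly(records)
        ep = evidence_paths[g]
        seq_lengths = {tid: len(seq) for tid, seq in over[g]}
        target_lengths = {}
        for line in open(ep.target_lengths_path):
            tid, ln = line.split("\t")
            target_lengths[tid] = int(ln)
        bundles = load_evidence(
            map_path=ep.map_path,
            protein_hits_path=ep.protein_hits_path,
            domain_path=ep.domain_path,
            vector_path=ep.vector_path,
            seq_lengths=seq_lengths,
            target_lengths=target_lengths,
        )
        okay = red.subset("main") + red.subset("alt")
        kept, _dropped = apply_evidence_filter(okay, bundles, thresholds)
        final = reassign_classes(kept, red.tags, records, extra_edges=red.edges)
        by_id = {r.transcript_id: r for r in records}
        mains = [by_id[t] for t, tag in sorted(final.items()) if tag.cls == "main"]
        genotypes[g] = GenotypeOutcome(
            reduction=red, kept_ids=kept, final_tags=final, main_records=mains
        )
        pool_sets[g] = [(r.transcript_id, r.cds) for r in mains]
    pool_sets[params.ref_genotype] = [(rid, seq) for rid, seq, _ in truth.ref_cds]
    entries, _counts = pool_cds(pool_sets)
    pan = build_pan(entries, ref_genotype=params.ref_genotype)
    outcome = PipelineOutcome(
        params=params, truth=truth, overassembly=over, genotypes=genotypes, pan=pan
    )
    outcome.metrics = score_against_truth(outcome)
    return outcome


def score_against_truth(outcome: PipelineOutcome) -> dict[str, float]:
    """Recovery metrics of a pipeline run against its planted truth."""
    truth = outcome.truth
    params = outcome.params
    metrics: dict[str, float] = {}

    pairs = 0
    recovered = 0
    for locus in truth.loci.values():
        planted = locus.all_cds()
        for g in locus.genotypes:
            if g == params.ref_genotype:
                continue
            pairs += 1
            mains = outcome.genotypes[g].main_records
            if any(r.cds in planted for r in mains):
                recovered += 1
    metrics["locus_genotype_pairs"] = pairs
    metrics["main_recovery_pct"] = 100.0 * recovered / pairs if pairs else 0.0

    for kind, reason in (("duplicate", "perfect_duplicate"), ("fragment", "perfect_fragment")):
        planted_n = tagged = 0
        for g, outc in outcome.genotypes.items():
            ledger = truth.ledger[g]
            for tid, entry in ledger.items():
                if entry["kind"] != kind:
                    continue
                planted_n += 1
                tag = outc.reduction.tags.get(tid)
                if tag is not None and tag.cls == "drop" and tag.reason == reason:
                    tagged += 1
        metrics[f"{kind}_tag_pct"] = 100.0 * tagged / planted_n if planted_n else 100.0

    contaminants = removed = 0
    for g, outc in outcome.genotypes.items():
        final_ids = set(outc.final_tags)
        for tid, entry in truth.ledger[g].items():
            if entry["kind"] == "contaminant":
                contaminants += 1
                if tid not in final_ids:
                    removed += 1
    metrics["contaminant_removal_pct"] = (
        100.0 * removed / contaminants if contaminants else 100.0
    )

    # pan category recovery: the locus's entries must sit alone in one cluster
    # whose category matches the planted one
    entry_locus: dict[str, str | None] = {}
    for e in outcome.pan.entries:
        genotype, _, tid = e.cds_id.partition("|")
        entry_locus[e.cds_id] = _locus_of(truth, genotype, tid, params)
    cluster_of: dict[str, int] = {}
    for i, cl in enumerate(outcome.pan.clusters):
        for cid, _ in cl.members:
            cluster_of[cid] = i
    correct = 0
    for locus in truth.loci.values():
        cids = [cid for cid, loc in entry_locus.items() if loc == locus.locus_id]
        if not cids:
            continue
        clusters = {cluster_of[c] for c in cids}
        if len(clusters) != 1:
            continue
        cl = outcome.pan.clusters[clusters.pop()]
        pure = all(entry_locus[c] == locus.locus_id for c, _ in cl.members)
        if pure and cl.category == locus.category:
            correct += 1
    metrics["pan_category_recovery_pct"] = 100.0 * correct / len(truth.loci)
    metrics["n_pan_clusters"] = len(outcome.pan.clusters)
    for cat, n in outcome.pan.category_counts().items():
        metrics[f"pan_{cat}"] = n
    return metrics


def _locus_of(truth: SimTruth, genotype: str, tid: str, params: SimParams) -> str | None:
    if genotype == params.ref_genotype:
        for rid, _seq, locus in truth.ref_cds:
            if rid == tid:
                return locus
        return None
    entry = truth.ledger.get(genotype, {}).get(tid)
    if entry is None or entry["locus"] is None:
        return None
    return entry["locus"].split("+")[0]


def export_outcome(outcome: PipelineOutcome, out_dir: str | Path) -> dict[str, Path]:
    """Write the pan-transcriptome artefacts; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rep_fasta": out_dir / "pan_representatives.fasta",
        "alt_fasta": out_dir / "pan_alternatives.fasta",
        "membership": out_dir / "pan_membership.tsv",
        "counts": out_dir / "pan_category_counts.tsv",
    }
    export_pan(outcome.pan, paths["rep_fasta"], paths["alt_fasta"],
               paths["membership"], paths["counts"])
    return paths


def main_set_metrics(outcome: PipelineOutcome) -> dict[str, ContigMetrics]:
    """Contig metrics of each genotype's final representative set."""
    return {
        g: contig_metrics([r.seq for r in outc.main_records])
        for g, outc in outcome.genotypes.items()
    }
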