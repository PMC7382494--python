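"""External-evidence filtering of reduced transcript sets.

Redundancy reduction uses only internal evidence (the sequences themselves),
so surviving transcripts are validated against three independent external
sources: alignment to the reference genome, protein-database search hits at
significance/coverage thresholds, and protein-domain annotation. A transcript
with none of the three is eliminated. Vector-screen results are annotated and
summarised but do not remove sequences unless explicitly requested, since
meta-transcripts and borderline calls are worth keeping for inspection.

After filtering, representative/alternative classes are re-assigned: if a
component's representative was eliminated, the surviving member with the
longest CDS is promoted and the remaining survivors re-pointed at it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .redundancy import ClassTag, TranscriptRecord

VECTOR_STRENGTHS = ("strong", "moderate", "weak")


class EvidenceError(ValueError):
    pass


@dataclass
class EvidenceBundle:
    """All external evidence known for one transcript."""

    genome_hits: list[tuple[str, int, int, str, float]] = field(default_factory=list)
    protein_hits: list[tuple[str, float, float, float]] = field(default_factory=list)
    domain_hits: list[str] = field(default_factory=list)
    vector_hits: list[tuple[str, float]] = field(default_factory=list)


@dataclass(frozen=True)
class FilterThresholds:
    """Significance/coverage thresholds a protein hit must meet to count."""

    max_e_value: float = 1e-5
    min_query_cov: float = 0.5
    min_target_cov: float = 0.5

    def __post_init__(self) -> None:
        if self.max_e_value <= 0:
            raise EvidenceError("max_e_value must be positive")
        for c in (self.min_query_cov, self.min_target_cov):
            if not (0 <= c <= 1):
                raise EvidenceError("coverage thresholds must be in [0, 1]")


def _parse_error(path, lineno, msg):
    raise EvidenceError(f"{path}: line {lineno}: {msg}")


def _iter_rows(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _load_genome_hits(path, bundles, seq_lengths):
    """Genome-mapping results: GFF3-like, BED, or PAF rows, auto-detected."""
    for lineno, cols in _iter_rows(path):
        try:
            if len(cols) >= 12 and cols[4] in "+-" and cols[1].isdigit():
                # PAF: qname qlen qstart qend strand tname tstart tend ...
                qname, qlen = cols[0], int(cols[1])
                qstart, qend = int(cols[2]), int(cols[3])
                cov = (qend - qstart) / qlen if qlen else 0.0
                bundles.setdefault(qname, EvidenceBundle()).genome_hits.append(
                    (cols[5], int(cols[6]) + 1, int(cols[7]), cols[4], cov)
                )
            elif len(cols) == 9 and "=" in cols[8]:
                # GFF3: transcript id in ID= or Target=
                attrs = dict(
                    kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
                )
                tid = attrs.get("ID") or attrs.get("Target", "").split(" ")[0]
                if not tid:
                    _parse_error(path, lineno, "no ID/Target attribute")
                start, end = int(cols[3]), int(cols[4])
                alen = end - start + 1
                qlen = (seq_lengths or {}).get(tid)
                cov = min(1.0, alen / qlen) if qlen else 1.0
                bundles.setdefault(tid, EvidenceBundle()).genome_hits.append(
                    (cols[0], start, end, cols[6], cov)
                )
            elif len(cols) >= 6:
                # BED6: chrom start end name score strand
                chrom, start, end, tid, _, strand = cols[:6]
                start, end = int(start), int(end)
                alen = end - start
                qlen = (seq_lengths or {}).get(tid)
                cov = min(1.0, alen / qlen) if qlen else 1.0
                bundles.setdefault(tid, EvidenceBundle()).genome_hits.append(
                    (chrom, start + 1, end, strand, cov)
                )
            else:
                _parse_error(path, lineno, f"unrecognised mapping row ({len(cols)} columns)")
        except (ValueError, IndexError) as exc:
            if isinstance(exc, EvidenceError):
                raise
            _parse_error(path, lineno, f"unparseable mapping row: {exc}")


def _load_protein_hits(path, bundles, seq_lengths, target_lengths):
    """12-column tabular search hits (qid sid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore); coverages are computed from the
    aligned spans and the supplied sequence lengths when available."""
    for lineno, cols in _iter_rows(path):
        if len(cols) < 12:
            _parse_error(path, lineno, f"expected >=12 columns, found {len(cols)}")
        try:
            qid, sid = cols[0], cols[1]
            qstart, qend = int(cols[6]), int(cols[7])
            sstart, send = int(cols[8]), int(cols[9])
            evalue = float(cols[10])
        except ValueError as exc:
            _parse_error(path, lineno, f"unparseable hit row: {exc}")
        qlen = (seq_lengths or {}).get(qid)
        slen = (target_lengths or {}).get(sid)
        qcov = min(1.0, (abs(qend - qstart) + 1) / qlen) if qlen else 1.0
        scov = min(1.0, (abs(send - sstart) + 1) / slen) if slen else 1.0
        bundles.setdefault(qid, EvidenceBundle()).protein_hits.append((sid, evalue, qcov, scov))


def _load_domain_hits(path, bundles):
    """Domain annotation TSV: simple (id, accession) or a 13+ column scanner
    TSV where the accession sits in column 12."""
    for lineno, cols in _iter_rows(path):
        if len(cols) < 2:
            _parse_error(path, lineno, "expected at least 2 columns")
        acc = cols[11] if len(cols) >= 12 else cols[1]
        if acc and acc != "-":
            bundles.setdefault(cols[0], EvidenceBundle()).domain_hits.append(acc)


def _load_vector_hits(path, bundles):
    """Vector-screen table: id, strength keyword, span fraction."""
    for lineno, cols in _iter_rows(path):
        if len(cols) < 2 or cols[0] == "transcript_id":
            continue
        strength = cols[1].strip().lower()
        if strength not in VECTOR_STRENGTHS:
            _parse_error(path, lineno, f"unknown vector-hit strength {cols[1]!r}")
        span = float(cols[2]) if len(cols) > 2 else 0.0
        bundles.setdefault(cols[0], EvidenceBundle()).vector_hits.append((strength, span))


def load_evidence(
    map_path: str | Path | None = None,
    protein_hits_path: str | Path | None = None,
    domain_path: str | Path | None = None,
    vector_path: str | Path | None = None,
    seq_lengths: dict[str, int] | None = None,
    target_lengths: dict[str, int] | None = None,
) -> dict[str, EvidenceBundle]:
    """Load per-transcript evidence; absent files mean no evidence of that kind."""
    bundles: dict[str, EvidenceBundle] = {}
    if map_path is not None:
        _load_genome_hits(map_path, bundles, seq_lengths)
    if protein_hits_path is not None:
        _load_protein_hits(protein_hits_path, bundles, seq_lengths, target_lengths)
    if domain_path is not None:
        _load_domain_hits(domain_path, bundles)
    if vector_path is not None:
        _load_vector_hits(vector_path, bundles)
    return bundles


def has_evidence(bundle: EvidenceBundle, thresholds: FilterThresholds) -> bool:
    if bundle.genome_hits or bundle.domain_hits:
        return True
    return any(
        e <= thresholds.max_e_value
        and qcov >= thresholds.min_query_cov
        and scov >= thresholds.min_target_cov
        for _, e, qcov, scov in bundle.protein_hits
    )


def apply_evidence_filter(
    records: list[TranscriptRecord],
    bundles: dict[str, EvidenceBundle],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[str], dict[str, str]]:
    """Partition records into kept ids and dropped ids (reason "no_evidence").

    A transcript is eliminated only when it has no genome mapping, no domain
    hit, and no protein hit meeting all three thresholds.
    """
    kept: list[str] = []
    dropped: dict[str, str] = {}
    empty = EvidenceBundle()
    for r in records:
        if has_evidence(bundles.get(r.transcript_id, empty), thresholds):
            kept.append(r.transcript_id)
        else:
            dropped[r.transcript_id] = "no_evidence"
    return kept, dropped


def reassign_classes(
    surviving_ids: list[str],
    prior_tags: dict[str, ClassTag],
    records: list[TranscriptRecord],
    extra_edges: set[tuple[str, str]] | None = None,
) -> dict[str, ClassTag]:
    """Re-elect one representative per surviving component after filtering.

    Components are rebuilt from the prior alt->main edges (plus any extra
    isoform edges) restricted to survivors. A surviving prior main keeps its
    class; if the main was eliminated, the surviving member with the longest
    CDS (ascending-id tie-break) is promoted and the others re-pointed to it.
    """
    alive = set(surviving_ids)
    by_id = {r.transcript_id: r for r in records}
    g = nx.Graph()
    for tid, tag in prior_tags.items():
        if tag.cls in ("main", "alt"):
            g.add_node(tid)
        if tag.cls == "alt":
            g.add_edge(tid, tag.rep_id)
    for a, b in extra_edges or set():
        if a in g and b in g:
            g.add_edge(a, b)
    new_tags: dict[str, ClassTag] = {}
    for comp in nx.connected_components(g):
        survivors = sorted(
            (t for t in comp if t in alive),
            key=lambda t: (-(by_id[t].cds_len if t in by_id else 0), t),
        )
        if not survivors:
            continue
        main = survivors[0]
        new_tags[main] = ClassTag("main", reason="representative")
        for other in survivors[1:]:
            prior = prior_tags.get(other)
            reason = prior.reason if prior and prior.cls == "alt" else "other"
            new_tags[other] = ClassTag("alt", rep_id=main, reason=reason)
    return new_tags


def annotate_vector_contamination(
    records: list[TranscriptRecord],
    bundles: dict[str, EvidenceBundle],
) -> tuple[dict[str, tuple[str, float]], dict[str, int]]:
    """Annotate each hit transcript with its strongest vector evidence.

    Returns (per-transcript (max strength, max span fraction), per-strength
    summary counts). Nothing is removed here; removal is the caller's choice.
    """
    rank = {s: i for i, s in enumerate(VECTOR_STRENGTHS)}
    annotations: dict[str, tuple[str, float]] = {}
    counts = {s: 0 for s in VECTOR_STRENGTHS}
    ids = {r.transcript_id for r in records}
    for tid, bundle in bundles.items():
        if tid not in ids or not bundle.vector_hits:
            continue
        strongest = min((s for s, _ in bundle.vector_hits), key=lambda s: rank[s])
        span = max(f for _, f in bundle.vector_hits)
        annotations[tid] = (strongest, span)
        counts[strongest] += 1
    return annotations, counts
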