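"""Assembly QC: contig metrics and reciprocal-best-hit reference coverage.

N50/N90 follow the "largest contig size at which at least 50%/90% of bases
are contained in contigs at least this length" definition. Reference
coverage bins count how many reference sequences have >=50% / >=95% of their
bases covered by alignments from their reciprocal-best-hit partner, a
simplified stand-in for conditional reciprocal-best-hit schemes: "best" is
the highest bit-score (ties: lowest e-value, then subject id).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .coords import union_length

HIT_COLUMNS = [
    "qid", "sid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class QcError(ValueError):
    pass


@dataclass(frozen=True)
class ContigMetrics:
    n_sequences: int
    mean_length: float
    n_under_200: int
    n_over_1000: int
    n_over_10000: int
    n50: int
    n90: int
    gc_percent: float
    ambiguous_percent: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class CoverageBins:
    n_query_with_hit: int
    n_query_reciprocal: int
    n_reference_with_hit: int
    coverage50: int
    coverage95: int
    reference_coverage: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def nx_metric(lengths: list[int], fraction: float) -> int:
    """Largest length L such that contigs of length >= L hold >= fraction of bases."""
    if not lengths:
        return 0
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc >= fraction * total:
            return L
    return min(lengths)


def _read_seqs(fasta) -> list[str]:
    if isinstance(fasta, (str, Path)):
        return [str(r.seq).upper() for r in SeqIO.parse(str(fasta), "fasta")]
    return [s.upper() for s in fasta]


def contig_metrics(fasta) -> ContigMetrics:
    """Compute contig metrics from a FASTA path or an iterable of sequences."""
    seqs = _read_seqs(fasta)
    if not seqs:
        warnings.warn("no sequences: all contig metrics are zero", stacklevel=2)
        return ContigMetrics(0, 0.0, 0, 0, 0, 0, 0, 0.0, 0.0)
    lengths = [len(s) for s in seqs]
    total = sum(lengths)
    gc = sum(s.count("G") + s.count("C") for s in seqs)
    acgt = sum(s.count(b) for b in "ACGT" for s in seqs)
    return ContigMetrics(
        n_sequences=len(seqs),
        mean_length=total / len(seqs),
        n_under_200=sum(1 for L in lengths if L < 200),
        n_over_1000=sum(1 for L in lengths if L > 1000),
        n_over_10000=sum(1 for L in lengths if L > 10000),
        n50=nx_metric(lengths, 0.5),
        n90=nx_metric(lengths, 0.9),
        gc_percent=100.0 * gc / total,
        ambiguous_percent=100.0 * (total - acgt) / total,
    )


def read_hits(path_or_df) -> pd.DataFrame:
    """Read a 12-column tabular search hit table."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
        df.columns = HIT_COLUMNS[: len(df.columns)]
        return df
    return pd.read_csv(path_or_df, sep="\t", names=HIT_COLUMNS, comment="#")


def _best_partner(df: pd.DataFrame) -> dict[str, str]:
    """qid -> sid of its best hit (bitscore desc, evalue asc, sid asc)."""
    best: dict[str, str] = {}
    ordered = df.sort_values(
        ["qid", "bitscore", "evalue", "sid"], ascending=[True, False, True, True]
    )
    for qid, group in ordered.groupby("qid", sort=False):
        best[qid] = group.iloc[0]["sid"]
    return best


def reciprocal_coverage(
    hits_query_vs_ref,
    hits_ref_vs_query,
    ref_lengths: dict[str, int],
) -> CoverageBins:
    """Reciprocal-best-hit coverage bins of a reference set.

    A (query, reference) pair is reciprocal when each is the other's best
    hit. Covered reference bases are the union of that pair's aligned
    reference intervals; references with >=50% / >=95% of their bases covered
    are binned, and ``reference_coverage`` is the fraction of references in
    any reciprocal pair.
    """
    q2r = read_hits(hits_query_vs_ref)
    r2q = read_hits(hits_ref_vs_query)
    unknown = set(q2r["sid"]) - set(ref_lengths)
    unknown |= set(r2q["qid"]) - set(ref_lengths)
    if unknown:
        raise QcError(f"hits reference unknown reference ids: {sorted(unknown)[:5]}")
    best_q = _best_partner(q2r)
    best_r = _best_partner(r2q)
    pairs = {(q, r) for q, r in best_q.items() if best_r.get(r) == q}
    ref_intervals: dict[str, list[tuple[int, int]]] = {}
    pair_set = pairs
    for row in q2r.itertuples(index=False):
        if (row.qid, row.sid) in pair_set:
            lo, hi = sorted((int(row.sstart), int(row.send)))
            ref_intervals.setdefault(row.sid, []).append((lo - 1, hi))
    cov50 = cov95 = 0
    for rid, ivs in ref_intervals.items():
        frac = union_length(ivs) / ref_lengths[rid]
        if frac >= 0.5:
            cov50 += 1
        if frac >= 0.95:
            cov95 += 1
    n_ref_hit = len({r for _, r in pairs})
    return CoverageBins(
        n_query_with_hit=q2r["qid"].nunique(),
        n_query_reciprocal=len({q for q, _ in pairs}),
        n_reference_with_hit=n_ref_hit,
        coverage50=cov50,
        coverage95=cov95,
        reference_coverage=n_ref_hit / len(ref_lengths) if ref_lengths else 0.0,
    )
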