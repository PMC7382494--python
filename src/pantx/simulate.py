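"""Seeded synthetic data with planted ground truth for the whole pipeline.

The generator emulates a tetraploid crop transcriptome study: loci with up to
four allelic haplotypes, splice variants, core vs genotype-specific locus
sharing across three tetraploid genotypes plus a reference clone, and the
artifact classes a multi-assembler over-assembly produces (byte-perfect
duplicates, perfect fragments, UTR variants, frameshifted misassemblies,
two-locus chimeras, contaminants), together with evidence tables consistent
with the planted truth. Everything derives from a single integer seed through
one numpy generator, so outputs are byte-identical across runs.

Design constraints baked into the generator:

* loci are drawn independently, giving >= 15% inter-locus divergence, so the
  90%-identity clustering stage is unambiguous and recovery tests are sharp;
* each transcript's planted CDS is its unique longest ORF: UTRs abut the CDS
  through a stop-in-all-six-frames boundary motif (``TTAATTAATTAA``, its own
  reverse complement, and G-free so it cannot spawn an upstream ATG), and
  candidate CDS are rejected while any non-coding frame carries a stop-free
  run long enough to rival the coding frame;
* artifact ids sort after truth ids, so the ascending-name duplicate
  tie-break retains the original of a planted byte-identical copy;
* chimeras fuse the first half of one transcript with the second half of
  another — concatenating whole transcripts would turn a parent into a
  perfect fragment of its own chimera;
* contaminants are dinucleotide-resampled versions of real transcripts, so
  they defeat naive composition filters but carry no planted evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .orf import STOP_CODONS, find_longest_orf

MOTIF = "TTAATTAATTAA"
BASES = np.array(list("ACGT"))
NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
ARTIFACT_KINDS = ("duplicate", "fragment", "utr_variant", "frameshift", "chimera", "contaminant")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Study-condition knobs for the synthetic generator."""

    n_loci: int = 200
    genotypes: tuple[str, ...] = ("G1", "G2", "G3")
    ref_genotype: str = "REF"
    haplotypes_per_locus: int = 4
    snp_rate: float = 0.01
    splice_variant_prob: float = 0.2
    core_fraction: float = 0.5
    specific_fraction: float = 0.3
    cds_codon_range: tuple[int, int] = (110, 300)
    utr_len_range: tuple[int, int] = (30, 120)
    min_fragment_len: int = 100
    artifact_counts: dict[str, int] = field(
        default_factory=lambda: {
            "duplicate": 20,
            "fragment": 20,
            "utr_variant": 20,
            "frameshift": 10,
            "chimera": 5,
            "contaminant": 20,
        }
    )
    vector_fraction: float = 0.02
    topology_counts: dict[str, int] = field(
        default_factory=lambda: {
            "singleton": 10,
            "one_to_one": 5,
            "one_to_two": 3,
            "curation": 2,
        }
    )

    def __post_init__(self) -> None:
        for f in (self.snp_rate, self.splice_variant_prob, self.core_fraction,
                  self.specific_fraction, self.vector_fraction):
            if not (0 <= f <= 1):
                raise SimulationError("fractions must be in [0, 1]")
        if not (1 <= self.haplotypes_per_locus <= 4):
            raise SimulationError("haplotypes_per_locus must be 1..4")
        if any(v < 0 for v in self.artifact_counts.values()):
            raise SimulationError("artifact counts must be >= 0")
        unknown = set(self.artifact_counts) - set(ARTIFACT_KINDS)
        if unknown:
            raise SimulationError(f"unknown artifact kinds: {sorted(unknown)}")


@dataclass
class LocusTruth:
    locus_id: str
    category: str
    genotypes: tuple[str, ...]  # genotypes carrying the locus (REF included)
    cds: dict[str, list[str]]  # genotype -> haplotype CDS sequences
    variants: dict[str, list[str]]  # genotype -> splice-variant CDS sequences

    def all_cds(self) -> set[str]:
        out: set[str] = set()
        for seqs in self.cds.values():
            out.update(seqs)
        for seqs in self.variants.values():
            out.update(seqs)
        return out


@dataclass
class SimTruth:
    """Machine-readable ground truth: planted loci plus the artifact ledger."""

    loci: dict[str, LocusTruth] = field(default_factory=dict)
    transcripts: dict[str, dict[str, dict]] = field(default_factory=dict)
    ref_cds: list[tuple[str, str, str]] = field(default_factory=list)  # (id, seq, locus)
    ledger: dict[str, dict[str, dict]] = field(default_factory=dict)
    evidence_pass: dict[str, set[str]] = field(default_factory=dict)


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _max_stopfree_run(seq: str, frame: int) -> int:
    best = run = 0
    for p in range(frame, len(seq) - 2, 3):
        if seq[p : p + 3] in STOP_CODONS:
            best = max(best, run)
            run = 0
        else:
            run += 1
    return max(best, run)


def _noncoding_frames_ok(cds: str) -> bool:
    """No non-coding frame may hold a stop-free run rivalling the CDS."""
    from Bio.Seq import Seq

    limit = (len(cds) - 36) // 3
    rc = str(Seq(cds).reverse_complement())
    runs = [_max_stopfree_run(cds, f) for f in (1, 2)]
    runs += [_max_stopfree_run(rc, f) for f in (0, 1, 2)]
    return max(runs) <= limit


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    while True:
        interior = rng.integers(0, len(NONSTOP_CODONS), size=n_codons - 2)
        stop = sorted(STOP_CODONS)[rng.integers(0, 3)]
        cds = "ATG" + "".join(NONSTOP_CODONS[i] for i in interior) + stop
        if _noncoding_frames_ok(cds):
            return cds


def _mutate_cds(rng: np.random.Generator, cds: str, snp_rate: float) -> str:
    for _ in range(10):
        seq = list(cds)
        n_mut = rng.binomial(len(cds) - 6, snp_rate)
        if n_mut == 0:
            return cds
        positions = rng.choice(np.arange(3, len(cds) - 3), size=n_mut, replace=False)
        for pos in sorted(int(p) for p in positions):
            old = seq[pos]
            for base in rng.permutation(BASES):
                if base == old:
                    continue
                seq[pos] = base
                cstart = pos - pos % 3
                if "".join(seq[cstart : cstart + 3]) not in STOP_CODONS:
                    break
                seq[pos] = old
        out = "".join(seq)
        if _noncoding_frames_ok(out):
            return out
    return cds


def _splice_variant(rng: np.random.Generator, cds: str) -> str | None:
    """In-frame internal deletion leaving >= 150 nt shared on each flank."""
    ncod = len(cds) // 3
    dcod = 30
    if ncod < 2 * 50 + dcod + 10:
        return None
    start = int(rng.integers(50, ncod - 50 - dcod))
    variant = cds[: 3 * start] + cds[3 * (start + dcod) :]
    return variant if _noncoding_frames_ok(variant) else None


def _assemble_transcript(rng: np.random.Generator, cds: str, utr_range) -> str:
    lo, hi = utr_range
    utr5 = _random_seq(rng, int(rng.integers(lo, hi + 1))) + MOTIF
    utr3 = MOTIF + _random_seq(rng, int(rng.integers(lo, hi + 1)))
    return utr5 + cds + utr3


def _locus_categories(params: SimParams, rng: np.random.Generator) -> list[tuple[str, tuple[str, ...]]]:
    tetra = list(params.genotypes)
    ref = params.ref_genotype
    everyone = tuple(tetra + [ref])
    n_core = round(params.core_fraction * params.n_loci)
    n_spec = round(params.specific_fraction * params.n_loci)
    out: list[tuple[str, tuple[str, ...]]] = []
    all_labels = tetra + [ref]
    for i in range(params.n_loci):
        if i < n_core:
            out.append(("core", everyone))
        elif i < n_core + n_spec:
            g = all_labels[i % len(all_labels)]
            out.append(("genotype_specific", (g,)))
        else:
            if rng.random() < 0.5:
                k = int(rng.integers(1, len(tetra)))
                subset = sorted(rng.choice(tetra, size=k, replace=False))
                out.append(("ref_plus_some", tuple(subset + [ref])))
            else:
                k = int(rng.integers(2, len(tetra) + 1))
                subset = tuple(sorted(rng.choice(tetra, size=k, replace=False)))
                out.append(("tuberosum_shared", subset))
    return out


def simulate_transcript_truth(
    params: SimParams, seed: int
) -> tuple[dict[str, list[tuple[str, str]]], SimTruth]:
    """Generate per-genotype true transcripts and the locus truth table.

    Tetraploid transcripts carry UTRs around the planted CDS; the reference
    genotype contributes bare CDS (its sequences stand for merged gene-model
    coding sequences, which have no UTRs).
    """
    rng = np.random.default_rng(seed)
    truth = SimTruth()
    transcripts: dict[str, list[tuple[str, str]]] = {g: [] for g in params.genotypes}
    for g in params.genotypes:
        truth.transcripts[g] = {}
    categories = _locus_categories(params, rng)
    lo, hi = params.cds_codon_range
    for i, (category, genos) in enumerate(categories):
        locus_id = f"L{i:04d}"
        base = _random_cds(rng, int(rng.integers(lo, hi + 1)))
        cds_map: dict[str, list[str]] = {}
        var_map: dict[str, list[str]] = {}
        for g in genos:
            if g == params.ref_genotype:
                cds_map[g] = [base]
                truth.ref_cds.append((f"ref{i:04d}", base, locus_id))
                continue
            n_hap = int(rng.integers(1, params.haplotypes_per_locus + 1))
            haps = [base]
            for _ in range(1, n_hap):
                haps.append(_mutate_cds(rng, base, params.snp_rate))
            cds_map[g] = haps
            var_map[g] = []
            if rng.random() < params.splice_variant_prob:
                sv = _splice_variant(rng, haps[0])
                if sv is not None:
                    var_map[g].append(sv)
            for h, hcds in enumerate(haps):
                tid = f"tx{i:04d}_h{h}"
                seq = _assemble_transcript(rng, hcds, params.utr_len_range)
                transcripts[g].append((tid, seq))
                truth.transcripts[g][tid] = {
                    "kind": "hap", "locus": locus_id, "cds": hcds, "hap": h,
                }
            for v, vcds in enumerate(var_map[g]):
                tid = f"tx{i:04d}_h0sv{v}"
                seq = _assemble_transcript(rng, vcds, params.utr_len_range)
                transcripts[g].append((tid, seq))
                truth.transcripts[g][tid] = {
                    "kind": "splice", "locus": locus_id, "cds": vcds, "hap": 0,
                }
        truth.loci[locus_id] = LocusTruth(
            locus_id=locus_id, category=category, genotypes=genos,
            cds=cds_map, variants=var_map,
        )
    return transcripts, truth


def _dinuc_resample(rng: np.random.Generator, seq: str) -> str:
    """Generate a same-length sequence from the source's dinucleotide chain."""
    idx = {b: i for i, b in enumerate("ACGT")}
    counts = np.ones((4, 4))
    for a, b in zip(seq, seq[1:]):
        counts[idx[a], idx[b]] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    state = int(rng.integers(0, 4))
    out = ["ACGT"[state]]
    for _ in range(len(seq) - 1):
        state = int(rng.choice(4, p=probs[state]))
        out.append("ACGT"[state])
    return "".join(out)


def corrupt_to_overassembly(
    truth: SimTruth,
    transcripts: dict[str, list[tuple[str, str]]],
    params: SimParams,
    seed: int,
) -> dict[str, list[tuple[str, str]]]:
    """Plant artifacts into the study's transcript sets, in exact total counts.

    ``params.artifact_counts`` are study-wide totals, dealt round-robin across
    genotypes (artifact ids carry a study-wide index, so each planted sequence
    is traceable). Fills ``truth.ledger`` (one entry per emitted sequence id,
    artifact or true) and ``truth.evidence_pass`` (ids that must survive the
    evidence filter — everything but contaminants).
    """
    genotypes = sorted(transcripts)
    rngs = dict(zip(genotypes, _rng_children(seed, len(genotypes))))
    quota: dict[str, dict[str, list[int]]] = {g: {k: [] for k in ARTIFACT_KINDS} for g in genotypes}
    for kind in ARTIFACT_KINDS:
        for i in range(params.artifact_counts.get(kind, 0)):
            quota[genotypes[i % len(genotypes)]][kind].append(i)
    over: dict[str, list[tuple[str, str]]] = {}
    for g in genotypes:
        rng = rngs[g]
        base = list(transcripts[g])
        ledger: dict[str, dict] = {
            tid: dict(truth.transcripts[g][tid]) for tid, _ in base
        }
        by_id = dict(base)
        ids = sorted(by_id)
        out = list(base)
        seen_seqs = {seq for _, seq in base}

        def pick(rng=rng, ids=ids):
            return ids[int(rng.integers(0, len(ids)))]

        counts = {k: v for k, v in quota[g].items()}
        for i in counts.get("duplicate", []):
            src = pick()
            tid = f"zdup{i:03d}"
            out.append((tid, by_id[src]))
            ledger[tid] = {"kind": "duplicate", "source": src,
                           "locus": ledger[src]["locus"]}
        eligible = [t for t in ids if len(by_id[t]) >= 2 * params.min_fragment_len]
        if counts.get("fragment", []) and not eligible:
            raise SimulationError(
                "no transcript is at least twice the minimum fragment length"
            )
        for i in counts.get("fragment", []):
            for _ in range(50):
                src = eligible[int(rng.integers(0, len(eligible)))]
                seq = by_id[src]
                flen = int(rng.integers(params.min_fragment_len, len(seq) - 10))
                start = int(rng.integers(1, len(seq) - flen))
                frag = seq[start : start + flen]
                if frag not in seen_seqs:
                    break
            tid = f"zfrag{i:03d}"
            seen_seqs.add(frag)
            out.append((tid, frag))
            ledger[tid] = {"kind": "fragment", "source": src,
                           "locus": ledger[src]["locus"]}
        for i in counts.get("utr_variant", []):
            for _ in range(50):
                src = pick()
                cds = ledger[src]["cds"]
                seq = _assemble_transcript(rng, cds, params.utr_len_range)
                if seq not in seen_seqs:
                    break
            tid = f"zutr{i:03d}"
            seen_seqs.add(seq)
            out.append((tid, seq))
            ledger[tid] = {"kind": "utr_variant", "source": src,
                           "locus": ledger[src]["locus"]}
        for i in counts.get("frameshift", []):
            placed = False
            for _ in range(50):
                src = pick()
                seq = by_id[src]
                cds = ledger[src]["cds"]
                cds_start = seq.find(cds)
                third = len(cds) // 3
                pos = cds_start + third + int(rng.integers(0, third))
                mutant = seq[:pos] + seq[pos + 1 :]
                orf, _aa = find_longest_orf(mutant)
                if orf.length < len(cds) and mutant not in seen_seqs:
                    placed = True
                    break
            if not placed:
                raise SimulationError("could not place a frameshift artifact")
            tid = f"zfs{i:03d}"
            seen_seqs.add(mutant)
            out.append((tid, mutant))
            ledger[tid] = {"kind": "frameshift", "source": src,
                           "locus": ledger[src]["locus"]}
        for i in counts.get("chimera", []):
            for _ in range(50):
                a, b = pick(), pick()
                if ledger[a]["locus"] != ledger[b]["locus"]:
                    break
            sa, sb = by_id[a], by_id[b]
            seq = sa[: len(sa) // 2] + sb[len(sb) // 2 :]
            tid = f"zchi{i:03d}"
            seen_seqs.add(seq)
            out.append((tid, seq))
            ledger[tid] = {"kind": "chimera", "source": f"{a}+{b}",
                           "locus": f"{ledger[a]['locus']}+{ledger[b]['locus']}"}
        for i in counts.get("contaminant", []):
            src = pick()
            seq = _dinuc_resample(rng, by_id[src])
            tid = f"zcon{i:03d}"
            seen_seqs.add(seq)
            out.append((tid, seq))
            ledger[tid] = {"kind": "contaminant", "source": src, "locus": None}
        over[g] = out
        truth.ledger[g] = ledger
        truth.evidence_pass[g] = {
            tid for tid in ledger if ledger[tid]["kind"] != "contaminant"
        }
    return over


@dataclass(frozen=True)
class EvidencePaths:
    map_path: Path
    protein_hits_path: Path
    domain_path: Path
    vector_path: Path
    target_lengths_path: Path


def simulate_evidence(
    truth: SimTruth,
    over: dict[str, list[tuple[str, str]]],
    seed: int,
    out_dir: str | Path,
    vector_fraction: float = 0.02,
) -> dict[str, EvidencePaths]:
    """Write per-genotype evidence tables consistent with the planted truth.

    True-locus-derived sequences (including duplicates, fragments, UTR
    variants, frameshifts and chimeras) receive genome-mapping rows and
    protein hits comfortably inside the default thresholds; contaminants
    receive nothing. A ``vector_fraction`` of non-contaminant ids receives
    vector-screen rows, mostly weak.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genotypes = sorted(over)
    rngs = dict(zip(genotypes, _rng_children(seed + 1, len(genotypes))))
    paths: dict[str, EvidencePaths] = {}
    for g in genotypes:
        rng = rngs[g]
        ledger = truth.ledger[g]
        rows = sorted(over[g])
        ep = EvidencePaths(
            map_path=out_dir / f"{g}_map.bed",
            protein_hits_path=out_dir / f"{g}_protein_hits.tsv",
            domain_path=out_dir / f"{g}_domains.tsv",
            vector_path=out_dir / f"{g}_vector.tsv",
            target_lengths_path=out_dir / f"{g}_target_lengths.tsv",
        )
        target_lens: dict[str, int] = {}
        with open(ep.map_path, "w") as bed, open(ep.protein_hits_path, "w") as hits, open(
            ep.domain_path, "w"
        ) as dom:
            for tid, seq in rows:
                entry = ledger[tid]
                if entry["kind"] == "contaminant":
                    continue
                locus = entry["locus"].split("+")[0]
                locus_idx = int(locus[1:])
                gstart = 100_000 + locus_idx * 10_000
                bed.write(
                    f"chr01\t{gstart}\t{gstart + len(seq)}\t{tid}\t0\t+\n"
                )
                prot = f"PROT{locus_idx:04d}"
                plen = len(truth.loci[locus].cds[
                    sorted(truth.loci[locus].cds)[0]
                ][0]) // 3
                target_lens[prot] = plen
                qend = max(30, int(0.9 * len(seq)))
                send = max(10, int(0.9 * plen))
                hits.write(
                    f"{tid}\t{prot}\t99.0\t{qend}\t1\t0\t1\t{qend}\t1\t{send}"
                    f"\t1e-50\t500.0\n"
                )
                if locus_idx % 2 == 0:
                    dom.write(f"{tid}\tPF{locus_idx:05d}\n")
        with open(ep.target_lengths_path, "w") as tl:
            for prot in sorted(target_lens):
                tl.write(f"{prot}\t{target_lens[prot]}\n")
        non_contam = [tid for tid, _ in rows if ledger[tid]["kind"] != "contaminant"]
        n_vec = int(round(vector_fraction * len(non_contam)))
        with open(ep.vector_path, "w") as vec:
            if non_contam:
                chosen = sorted(
                    rng.choice(non_contam, size=min(n_vec, len(non_contam)), replace=False)
                )
                for tid in chosen:
                    strength = ["strong", "moderate", "weak"][
                        int(rng.choice(3, p=[0.02, 0.08, 0.90]))
                    ]
                    span = float(rng.uniform(0.005, 0.3))
                    vec.write(f"{tid}\t{strength}\t{span:.4f}\n")
        paths[g] = ep
    return paths


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write (id, seq) pairs as FASTA, wrapped and in the given order."""
    with open(path, "w") as fh:
        for tid, seq in records:
            fh.write(f">{tid}\n")
            for p in range(0, len(seq), width):
                fh.write(seq[p : p + width] + "\n")


@dataclass
class AnnotationTruth:
    """Planted overlap clusters: (intended outcome under default policy, member ids)."""

    clusters: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    def outcome_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for outcome, _ in self.clusters:
            counts[outcome] = counts.get(outcome, 0) + 1
        return counts


def _gff_gene(out, chrom, gid, start, end, cds_segments):
    out.append(f"{chrom}\tpantx_sim\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}")
    mid = f"{gid}.m1"
    out.append(f"{chrom}\tpantx_sim\tmRNA\t{start}\t{end}\t.\t+\t.\tID={mid};Parent={gid}")
    for i, (s, e) in enumerate(cds_segments, 1):
        out.append(f"{chrom}\tpantx_sim\tCDS\t{s}\t{e}\t.\t+\t0\tID={mid}.cds{i};Parent={mid}")


def simulate_annotation_pair(
    params: SimParams,
    seed: int,
    out_dir: str | Path,
    genome_length: int | None = None,
) -> tuple[Path, Path, Path, AnnotationTruth]:
    """Plant gene pairs realising the requested overlap topologies.

    Writes a genome FASTA and two GFF3 files (source A and source B) to
    ``out_dir`` and returns their paths with the planted truth. Topologies:
    ``singleton`` (alternating source), ``one_to_one`` (overlapping pair,
    resolved to the preferred source), ``one_to_two`` (one B gene whose CDS
    fully covers two A genes — resolved to the spanning gene), ``curation``
    (a four-gene chain sent to manual curation). With ``genome_length``
    given, a layout that does not fit raises an error.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chrom = "chr01"
    cur = 1000
    gap = 1000
    a_lines: list[str] = []
    b_lines: list[str] = []
    truth = AnnotationTruth()
    na = nb = 0

    def next_a():
        nonlocal na
        na += 1
        return f"A{na:05d}"

    def next_b():
        nonlocal nb
        nb += 1
        return f"B{nb:05d}"

    counts = params.topology_counts
    for i in range(counts.get("singleton", 0)):
        gid = next_a() if i % 2 == 0 else next_b()
        lines = a_lines if i % 2 == 0 else b_lines
        s, e = cur, cur + 899
        _gff_gene(lines, chrom, gid, s, e, [(s, s + 399), (s + 500, e)])
        truth.clusters.append(("keep_singleton", (gid,)))
        cur = e + gap
    for _ in range(counts.get("one_to_one", 0)):
        ga, gb = next_a(), next_b()
        s = cur
        _gff_gene(a_lines, chrom, ga, s, s + 899, [(s, s + 899)])
        _gff_gene(b_lines, chrom, gb, s + 300, s + 1199, [(s + 300, s + 1199)])
        truth.clusters.append(("keep_B", (ga, gb)))
        cur = s + 1200 + gap
    for _ in range(counts.get("one_to_two", 0)):
        gb, ga1, ga2 = next_b(), next_a(), next_a()
        s = cur
        _gff_gene(
            b_lines, chrom, gb, s, s + 2099, [(s + 60, s + 839), (s + 1260, s + 2039)]
        )
        _gff_gene(a_lines, chrom, ga1, s + 60, s + 839, [(s + 60, s + 839)])
        _gff_gene(a_lines, chrom, ga2, s + 1260, s + 2039, [(s + 1260, s + 2039)])
        truth.clusters.append(("keep_spanning", (gb, ga1, ga2)))
        cur = s + 2100 + gap
    for _ in range(counts.get("curation", 0)):
        ga1, gb1, ga2, gb2 = next_a(), next_b(), next_a(), next_b()
        s = cur
        _gff_gene(a_lines, chrom, ga1, s, s + 599, [(s, s + 599)])
        _gff_gene(b_lines, chrom, gb1, s + 300, s + 899, [(s + 300, s + 899)])
        _gff_gene(a_lines, chrom, ga2, s + 700, s + 1299, [(s + 700, s + 1299)])
        _gff_gene(b_lines, chrom, gb2, s + 1000, s + 1599, [(s + 1000, s + 1599)])
        truth.clusters.append(("manual_curation", (ga1, gb1, ga2, gb2)))
        cur = s + 1600 + gap
    total_len = cur + 1000
    if genome_length is not None and total_len > genome_length:
        raise SimulationError(
            f"planted topologies need {total_len} bp but the genome is {genome_length} bp"
        )
    genome_path = out_dir / "genome.fasta"
    gff_a = out_dir / "models_A.gff3"
    gff_b = out_dir / "models_B.gff3"
    write_fasta([(chrom, _random_seq(rng, genome_length or total_len))], genome_path)
    for path, lines in ((gff_a, a_lines), (gff_b, b_lines)):
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for line in lines:
                fh.write(line + "\n")
    return genome_path, gff_a, gff_b, truth
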