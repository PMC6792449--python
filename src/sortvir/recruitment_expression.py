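"""Competitive recruitment of transcriptome reads to viral proteomes.

Stage 1 recruits reads by translated (six-frame, BLOSUM62) search against the
viral protein set at a bit-score floor; stage 2 re-searches survivors against
the viral set plus a large labeled decoy database and retains a read only
when its single best overall hit is viral, with ties broken by a seeded
uniform choice. Per-gene counts become RPKM; per-read amino-acid identities
become the recruitment-identity histogram that distinguishes endemic-like
(low high-identity mass) from resident populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .protein_profiles import protein_align, _kmer_set, _sanitize
from .sequence_io import NucSequence, six_frame_translate

__all__ = [
    "RecruitmentTable",
    "competitive_recruit",
    "expression_summary",
    "identity_profile",
]


@dataclass
class RecruitmentTable:
    gene_counts: dict[str, int]                 # gene -> retained reads
    gene_lengths: dict[str, int]                # gene -> aa length
    gene_genome: dict[str, str]                 # gene -> viral genome label
    assignments: list[dict]                     # per retained read
    n_input: int
    n_stage1: int
    seed: int

    @property
    def n_retained(self) -> int:
        return len(self.assignments)

    def rpkm(self) -> dict[str, float]:
        total_millions = self.n_retained / 1e6
        out = {}
        for gene, count in self.gene_counts.items():
            kb = 3 * self.gene_lengths[gene] / 1000.0
            out[gene] = count / (kb * total_millions) if count and total_millions else 0.0
        return out


def _read_best_hits(
    read: NucSequence | str,
    db: Sequence[tuple[str, str, set[str]]],
    min_bits: float,
) -> list[tuple[float, float, str]]:
    """All qualifying (bits, pct_identity, target_id) for one read against a
    protein db [(target_id, seq, 4-mer set)]; exact 4-aa seed gates each
    alignment."""
    seq = read.residues if isinstance(read, NucSequence) else str(read)
    hits: dict[str, tuple[float, float]] = {}
    for pep in six_frame_translate(seq):
        for seg in pep.split("*"):
            if len(seg) < 4:
                continue
            seg_k = _kmer_set(_sanitize(seg))
            for tid, tseq, tk in db:
                if not (seg_k & tk):
                    continue
                res = protein_align(seg, tseq)
                if res is None or res["bits"] < min_bits:
                    continue
                prev = hits.get(tid)
                if prev is None or res["bits"] > prev[0]:
                    hits[tid] = (res["bits"], res["pct_identity"])
    return sorted(
        ((b, pid, tid) for tid, (b, pid) in hits.items()),
        key=lambda h: (-h[0], h[2]),
    )


def competitive_recruit(
    reads: Sequence[NucSequence],
    viral_proteomes: dict[str, list[tuple[str, str]]],
    decoy_db: Sequence[tuple[str, str]],
    bit_min: float = 50.0,
    seed: int = 0,
) -> RecruitmentTable:
    """Two-stage competitive translated recruitment.

    ``viral_proteomes`` maps genome label -> [(gene_id, protein)], the decoy
    is a labeled non-viral protein set standing in for a comprehensive
    database. A read survives stage 1 with any viral hit at >= ``bit_min``
    bits and is retained after stage 2 only if its single best hit across
    viral and decoy proteins is viral (ties resolved by a seeded uniform
    draw over the tied references).
    """
    import warnings

    if not decoy_db:
        warnings.warn("empty decoy database: stage 2 is degenerate", stacklevel=2)
    rng = np.random.default_rng(seed)

    viral_db = []
    gene_lengths: dict[str, int] = {}
    gene_genome: dict[str, str] = {}
    for genome in sorted(viral_proteomes):
        for gid, seq in viral_proteomes[genome]:
            viral_db.append((gid, seq, _kmer_set(_sanitize(seq))))
            gene_lengths[gid] = len(seq)
            gene_genome[gid] = genome
    decoy = [(did, seq, _kmer_set(_sanitize(seq))) for did, seq in decoy_db]
    full_db = viral_db + decoy
    viral_ids = set(gene_lengths)

    gene_counts = {gid: 0 for gid in gene_lengths}
    assignments: list[dict] = []
    n_stage1 = 0
    for read in reads:
        stage1 = _read_best_hits(read, viral_db, bit_min)
        if not stage1:
            continue
        n_stage1 += 1
        stage2 = _read_best_hits(read, full_db, 0.0)
        if not stage2:
            continue
        best_bits = stage2[0][0]
        tied = [h for h in stage2 if h[0] >= best_bits - 1e-9]
        pick = tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]
        bits, pid, tid = pick
        if tid not in viral_ids:
            continue
        gene_counts[tid] += 1
        rid = read.id if isinstance(read, NucSequence) else "read"
        assignments.append({
            "read_id": rid,
            "gene": tid,
            "genome": gene_genome[tid],
            "bits": bits,
            "pct_identity": pid,
        })
    return RecruitmentTable(
        gene_counts, gene_lengths, gene_genome, assignments,
        n_input=len(reads), n_stage1=n_stage1, seed=seed,
    )


def expression_summary(
    table: RecruitmentTable,
    other: Optional[RecruitmentTable] = None,
    min_reads: int = 1,
) -> dict:
    """Fraction of genes expressed (>= ``min_reads`` retained reads), the
    ranked gene table, and — when a second sample is given — the Pearson
    correlation of log10(RPKM + 1) over genes expressed in either sample."""
    rpkm = table.rpkm()
    expressed = [g for g, c in table.gene_counts.items() if c >= min_reads]
    n_genes = len(table.gene_counts)
    ranked = sorted(
        ((g, table.gene_counts[g], rpkm[g]) for g in table.gene_counts),
        key=lambda t: (-t[2], t[0]),
    )
    out = {
        "n_genes": n_genes,
        "n_expressed": len(expressed),
        "fraction_expressed": len(expressed) / n_genes if n_genes else 0.0,
        "ranked": ranked,
    }
    if other is not None:
        rpkm_b = other.rpkm()
        union = sorted(
            {g for g, c in table.gene_counts.items() if c >= min_reads}
            | {g for g, c in other.gene_counts.items() if c >= min_reads}
        )
        if len(union) >= 2:
            a = np.log10(np.array([rpkm.get(g, 0.0) for g in union]) + 1.0)
            b = np.log10(np.array([rpkm_b.get(g, 0.0) for g in union]) + 1.0)
            if a.std() > 0 and b.std() > 0:
                out["log_rpkm_correlation"] = float(np.corrcoef(a, b)[0, 1])
            else:
                out["log_rpkm_correlation"] = None
        else:
            out["log_rpkm_correlation"] = None
    return out


def identity_profile(
    table: RecruitmentTable,
    bin_width: float = 1.0,
    endemic_high_identity: float = 90.0,
    endemic_max_fraction: float = 0.1,
) -> dict[str, dict]:
    """Per-genome amino-acid identity histogram of retained reads.

    Reports the histogram (``bin_width``% bins over 0-100), mean identity,
    the fraction of reads above ``endemic_high_identity``%, and an
    endemic-like flag when that high-identity mass stays below
    ``endemic_max_fraction`` — the signature of recruiting only distant
    relatives of the reference."""
    per_genome: dict[str, list[float]] = {}
    for a in table.assignments:
        per_genome.setdefault(a["genome"], []).append(a["pct_identity"])
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    out: dict[str, dict] = {}
    for genome, idents in sorted(per_genome.items()):
        arr = np.asarray(idents)
        hist, _ = np.histogram(np.clip(arr, 0, 100 - 1e-9), bins=edges)
        high = float((arr > endemic_high_identity).mean())
        out[genome] = {
            "histogram": hist,
            "bin_edges": edges,
            "mean_identity": float(arr.mean()),
            "n_reads": len(arr),
            "high_identity_fraction": high,
            "endemic_like": high < endemic_max_fraction,
        }
    return out
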