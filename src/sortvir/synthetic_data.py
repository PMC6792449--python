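"""Synthetic sorted-cell metagenome communities with known ground truth.

Emulates the statistical structure a flow-sorted single-cell/multi-cell
metagenome presents to the downstream pipeline: a low-GC giant virus, a
higher-GC eukaryote host (optionally a bacterial contaminant and phage),
distinct tetranucleotide signatures per organism, planted ancestral-marker
ORFs and rRNA operons, MDA-style highly uneven coverage, and paired-end
reads with linearly decaying qualities.

Genomes are drawn from an order-m Markov chain whose emissions interpolate
between a GC-matched order-0 model and a random per-entity order-3 signature,
so GC content and 4-mer composition — the two binning axes — are controlled
independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .sequence_io import (
    NucSequence,
    ReadPair,
    reverse_complement,
    serialize_fastx,
)

__all__ = [
    "EntitySpec",
    "CommunityConfig",
    "TruthTable",
    "PlantedFeature",
    "simulate_genomes",
    "make_contigs",
    "simulate_reads",
    "simulate_community",
    "synthetic_marker_alignments",
    "synthetic_rrna_references",
    "write_community",
]

_BASES = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"

# codons per amino acid, ordered so GC-rich synonyms can be preferred
_CODONS: dict[str, list[str]] = {}
_STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
for codon, aa in _STANDARD_TABLE.items():
    _CODONS.setdefault(aa, []).append(codon)


@dataclass
class EntitySpec:
    """One organism in the sorted community."""

    name: str
    role: str  # {giant_virus, host_eukaryote, bacterium, phage}
    genome_len: int
    gc_target: float
    markov_order: int = 3
    n_markers_planted: int = 0
    has_rrna: bool = False
    abundance: float = 1.0
    n_genes: int = 0  # planted protein-coding genes beyond markers
    rrna_divergence: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be a fraction in (0,1)")
        if self.n_markers_planted > 47:
            raise ValueError("at most 47 markers can be planted")
        if self.markov_order not in (0, 1, 2, 3):
            raise ValueError("markov_order must be 0-3")


@dataclass
class CommunityConfig:
    """Study conditions for one simulated sort.

    Defaults mirror a coastal single-cell sort: one ~1 Mb eukaryote host at
    45% GC carrying an 18S rRNA operon, plus one 300 kb giant virus at 28%
    GC carrying 30 ancestral-marker genes, amplified with strong MDA coverage
    bias and sequenced as 150 bp pairs with mild quality decay.
    """

    seed: int = 0
    entities: list[EntitySpec] = field(default_factory=lambda: [
        EntitySpec("host", "host_eukaryote", 1_000_000, 0.45,
                   has_rrna=True, abundance=0.6, n_genes=20),
        EntitySpec("virus", "giant_virus", 300_000, 0.28,
                   n_markers_planted=30, abundance=0.4, n_genes=20),
    ])
    contig_len_mu: float = 10.3   # lognormal(mu, sigma) of contig length, bp
    contig_len_sigma: float = 0.9
    min_contig_len: int = 1000
    emit_sub1kb: int = 0          # extra sub-1 kb fragments per entity
    planted_overlaps: int = 0     # contig pairs sharing an exact >100 bp end overlap
    overlap_len: int = 150
    read_len: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 40.0
    n_pairs: int = 10_000
    error_rate: float = 0.002
    qual_start: int = 37
    qual_end: int = 28
    mda_sigma: float = 1.5        # lognormal scale of per-window coverage bias
    mda_window: int = 2000
    marker_divergence: float = 0.30
    signature_strength: float = 0.6

    def __post_init__(self) -> None:
        for p in (self.error_rate,):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        virus_gc = [e.gc_target for e in self.entities if e.role == "giant_virus"]
        host_gc = [e.gc_target for e in self.entities if e.role == "host_eukaryote"]
        if virus_gc and host_gc and min(host_gc) - max(virus_gc) < 0.08:
            raise ValueError("host GC must exceed virus GC by >= 0.08")


@dataclass
class PlantedFeature:
    entity: str
    name: str
    kind: str  # {marker, gene, rrna}
    start: int
    end: int
    strand: str
    protein: Optional[str] = None


@dataclass
class TruthTable:
    """Ground truth for everything the simulator emitted."""

    contig_origin: dict[str, str] = field(default_factory=dict)
    contig_class: dict[str, str] = field(default_factory=dict)  # assembly|sub1kb
    features: list[PlantedFeature] = field(default_factory=list)
    gene_weights: dict[str, float] = field(default_factory=dict)
    read_origin: dict[str, str] = field(default_factory=dict)
    overlap_pairs: list[tuple[str, str]] = field(default_factory=list)

    def markers(self, entity: Optional[str] = None) -> list[PlantedFeature]:
        return [f for f in self.features
                if f.kind == "marker" and (entity is None or f.entity == entity)]

    def rrna(self, entity: Optional[str] = None) -> list[PlantedFeature]:
        return [f for f in self.features
                if f.kind == "rrna" and (entity is None or f.entity == entity)]


# ---------------------------------------------------------------------------
# Reference sets (synthetic stand-ins, generated — never shipped as data)
# ---------------------------------------------------------------------------

def synthetic_marker_alignments(
    n_markers: int = 47,
    n_seqs: int = 8,
    length_range: tuple[int, int] = (140, 260),
    within_divergence: float = 0.20,
    seed: int = 947,
) -> dict[str, list[tuple[str, str]]]:
    """Synthetic stand-in for the 47 ancestral giant-virus protein families.

    Each family is a random consensus protein plus ``n_seqs`` aligned members
    diverged from it by per-column substitution at ``within_divergence``.
    Alignments are gap-free except for a terminal ragged region, exercising
    the >50%-gap column filter downstream. Returns {marker_name: [(id, row)]}.
    """
    rng = np.random.default_rng(seed)
    families: dict[str, list[tuple[str, str]]] = {}
    aa = np.array(list(_AA))
    for m in range(n_markers):
        name = f"NCVOG{m + 1:04d}"
        L = int(rng.integers(*length_range))
        consensus = aa[rng.integers(0, 20, L)]
        rows = []
        for s in range(n_seqs):
            seq = consensus.copy()
            mut = rng.random(L) < within_divergence
            seq[mut] = aa[rng.integers(0, 20, int(mut.sum()))]
            row = "".join(seq)
            # ragged C-terminus on a minority of members
            if s >= n_seqs - 2:
                cut = int(rng.integers(3, 10))
                row = row[:-cut] + "-" * cut
            rows.append((f"{name}_m{s}", row))
        families[name] = rows
    return families


_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


def synthetic_rrna_references(
    n_genera: int = 6,
    seqs_per_genus: int = 3,
    gene_len: int = 1500,
    within_divergence: float = 0.02,
    between_divergence: float = 0.25,
    seed: int = 553,
) -> list[tuple[str, str, str]]:
    """Synthetic ranked-lineage SSU rRNA reference set.

    Genera descend from a shared root sequence (so references look homologous,
    as real 16S/18S do) with ``between_divergence`` separating genera and
    ``within_divergence`` separating members. Returns (id, lineage, sequence)
    with SILVA-style semicolon lineages; even genera are "Bacteria" (16S-like),
    odd are "Eukaryota" (18S-like).
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list(_BASES))
    root = bases[rng.integers(0, 4, gene_len)]
    refs = []
    for g in range(n_genera):
        genus_seq = root.copy()
        mut = rng.random(gene_len) < between_divergence
        genus_seq[mut] = bases[rng.integers(0, 4, int(mut.sum()))]
        domain = "Bacteria" if g % 2 == 0 else "Eukaryota"
        lineage = ";".join(
            [domain] + [f"{r.capitalize()}{g}" for r in _RANKS[1:]]
        )
        for s in range(seqs_per_genus):
            seq = genus_seq.copy()
            mut = rng.random(gene_len) < within_divergence
            seq[mut] = bases[rng.integers(0, 4, int(mut.sum()))]
            refs.append((f"ref_g{g}_s{s}", lineage, "".join(seq)))
    return refs


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def _emission_table(
    gc: float, order: int, strength: float, rng: np.random.Generator
) -> np.ndarray:
    """(4^order, 4) emission probabilities: GC-matched order-0 perturbed by a
    random per-context signature of the given strength."""
    p0 = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    n_ctx = 4 ** order
    z = rng.normal(0.0, strength, size=(n_ctx, 4))
    table = p0[None, :] * np.exp(z)
    table /= table.sum(axis=1, keepdims=True)
    # rescale within AT and GC pairs so realized GC stays on target
    at = table[:, [0, 3]].sum(axis=1)
    gc_mass = table[:, [1, 2]].sum(axis=1)
    table[:, [0, 3]] *= ((1 - gc) / at)[:, None]
    table[:, [1, 2]] *= (gc / gc_mass)[:, None]
    return table


def _draw_markov(length: int, table: np.ndarray, order: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Sequential draw from the order-m chain; returns int8 codes 0-3."""
    cum = np.cumsum(table, axis=1)
    n_ctx = table.shape[0]
    out = np.empty(length, dtype=np.int8)
    r = rng.random(length)
    ctx = 0
    mask = n_ctx - 1
    for i in range(length):
        row = cum[ctx]
        x = r[i]
        b = 0
        while row[b] < x and b < 3:
            b += 1
        out[i] = b
        ctx = ((ctx << 2) | b) & mask
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return codes.tobytes().translate(bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT")).decode()


def _reverse_translate(protein: str, gc: float, rng: np.random.Generator) -> str:
    """Pick synonymous codons with probability tilted toward the target GC."""
    out = []
    for aa in protein:
        codons = _CODONS.get(aa)
        if codons is None:  # X or unknown: filler alanine
            codons = _CODONS["A"]
        # codon weight = product of per-base probabilities under the target
        # GC composition, the strongest synonymous tilt the code allows
        w = np.array([
            math.prod((gc / 2 if c in "GC" else (1 - gc) / 2) for c in cod)
            for cod in codons
        ])
        out.append(codons[rng.choice(len(codons), p=w / w.sum())])
    return "".join(out)


def _mutate_protein(protein: str, divergence: float,
                    rng: np.random.Generator) -> str:
    arr = np.array(list(protein))
    mut = rng.random(len(arr)) < divergence
    arr[mut] = np.array(list(_AA))[rng.integers(0, 20, int(mut.sum()))]
    return "".join(arr)


def simulate_genomes(
    config: CommunityConfig,
    marker_alignments: Optional[dict[str, list[tuple[str, str]]]] = None,
    rrna_refs: Optional[list[tuple[str, str, str]]] = None,
) -> tuple[dict[str, str], TruthTable]:
    """Draw one genome per entity and plant markers, genes and rRNA operons.

    Marker genes are sampled from the marker alignments (consensus mutated at
    ``config.marker_divergence`` amino-acid distance), reverse-translated
    with GC-matched codon choice and inserted flanked by in-frame stop codons
    so coding coordinates are exact in the truth table.
    """
    rng = np.random.default_rng(config.seed)
    if marker_alignments is None:
        marker_alignments = synthetic_marker_alignments()
    if rrna_refs is None:
        rrna_refs = synthetic_rrna_references()
    truth = TruthTable()
    genomes: dict[str, str] = {}

    for ent in config.entities:
        inserts: list[tuple[str, str, str, Optional[str]]] = []  # (name, kind, cds, protein)
        marker_names = sorted(marker_alignments)
        if ent.n_markers_planted:
            chosen = rng.choice(
                len(marker_names), size=ent.n_markers_planted, replace=False
            )
            for idx in sorted(chosen):
                mname = marker_names[idx]
                rows = [r.replace("-", "") for _, r in marker_alignments[mname]]
                protein = _mutate_protein(
                    rows[0], config.marker_divergence, rng
                )
                cds = _reverse_translate(protein, ent.gc_target, rng)
                inserts.append((mname, "marker", cds, protein))
        for g in range(ent.n_genes):
            plen = int(rng.integers(120, 400))
            protein = "".join(
                np.array(list(_AA))[rng.integers(0, 20, plen)]
            )
            gname = f"{ent.name}_gene{g:03d}"
            cds = _reverse_translate(protein, ent.gc_target, rng)
            inserts.append((gname, "gene", cds, protein))
        if ent.has_rrna:
            # eukaryote hosts get an 18S-like operon, bacteria a 16S-like one
            want = "Eukaryota" if ent.role == "host_eukaryote" else "Bacteria"
            candidates = [r for r in rrna_refs if r[1].startswith(want)] or rrna_refs
            rid, _, rseq = candidates[int(rng.integers(len(candidates)))]
            arr = np.array(list(rseq))
            mut = rng.random(len(arr)) < ent.rrna_divergence
            arr[mut] = np.array(list(_BASES))[rng.integers(0, 4, int(mut.sum()))]
            inserts.append((f"{ent.name}_rrna_{rid}", "rrna", "".join(arr), None))

        total_insert = sum(len(c) + 6 for _, _, c, _ in inserts)
        if total_insert >= ent.genome_len:
            raise ValueError(
                f"{ent.name}: genome of {ent.genome_len} bp cannot host "
                f"{total_insert} bp of planted features"
            )

        # codon choice cannot push a CDS all the way to an extreme GC target,
        # so the backbone compensates for the realized GC of the inserts
        insert_gc = sum(c.count("G") + c.count("C") for _, _, c, _ in inserts)
        backbone_len = ent.genome_len
        backbone_gc = (
            ent.gc_target * (backbone_len + total_insert) - insert_gc
        ) / backbone_len
        backbone_gc = min(max(backbone_gc, 0.05), 0.95)
        table = _emission_table(
            backbone_gc, ent.markov_order, config.signature_strength, rng
        )
        backbone = _codes_to_str(
            _draw_markov(backbone_len, table, ent.markov_order, rng)
        )

        # place features at non-overlapping random positions
        positions = np.sort(rng.choice(
            ent.genome_len - total_insert, size=len(inserts), replace=False
        ))
        genome_parts = []
        cursor = 0
        offset = 0
        for (name, kind, payload, protein), pos in zip(inserts, positions):
            genome_parts.append(backbone[cursor:pos])
            offset += pos - cursor
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == "rrna":
                block = payload if strand == "+" else reverse_complement(payload)
                start, end = offset, offset + len(block)
            else:
                cds = payload if strand == "+" else reverse_complement(payload)
                stop5, stop3 = ("TAA", "TAA") if strand == "+" else ("TTA", "TTA")
                block = stop5 + cds + stop3
                start, end = offset + 3, offset + 3 + len(cds)
            genome_parts.append(block)
            offset += len(block)
            cursor = pos
            truth.features.append(PlantedFeature(
                ent.name, name, kind, start, end, strand, protein
            ))
        genome_parts.append(backbone[cursor:])
        genomes[ent.name] = "".join(genome_parts)

    return genomes, truth


# ---------------------------------------------------------------------------
# Contig fragmentation
# ---------------------------------------------------------------------------

def make_contigs(
    genomes: dict[str, str], config: CommunityConfig, truth: TruthTable
) -> list[NucSequence]:
    """Fragment each genome into contigs drawn from the configured lognormal
    length distribution (truncated at 1 kb). Optionally emits sub-1 kb
    fragments (to exercise the size filter) and pairs of contigs sharing an
    exact terminal overlap (to exercise secondary assembly)."""
    rng = np.random.default_rng(config.seed + 1)
    contigs: list[NucSequence] = []
    overlap_budget = config.planted_overlaps
    for ent_name, genome in genomes.items():
        pos = 0
        n = 0
        while pos < len(genome):
            length = int(np.exp(rng.normal(config.contig_len_mu,
                                           config.contig_len_sigma)))
            length = max(length, config.min_contig_len)
            frag = genome[pos : pos + length]
            if len(frag) < config.min_contig_len and contigs and n:
                # absorb the tail into the previous contig of this entity
                prev = contigs[-1]
                contigs[-1] = NucSequence(prev.id, prev.residues + frag)
                break
            cid = f"{ent_name}_c{n:04d}"
            if overlap_budget > 0 and len(frag) >= 4 * config.overlap_len:
                # emit as two pieces sharing an exact terminal overlap
                mid = len(frag) // 2
                a = frag[:mid]
                b = frag[mid - config.overlap_len :]
                # guard against a second accidental occurrence of the junction
                for piece, tag in ((a, "a"), (b, "b")):
                    pid = f"{cid}{tag}"
                    contigs.append(NucSequence(pid, piece))
                    truth.contig_origin[pid] = ent_name
                    truth.contig_class[pid] = "assembly"
                truth.overlap_pairs.append((f"{cid}a", f"{cid}b"))
                overlap_budget -= 1
            else:
                contigs.append(NucSequence(cid, frag))
                truth.contig_origin[cid] = ent_name
                truth.contig_class[cid] = "assembly"
            pos += length
            n += 1
        for j in range(config.emit_sub1kb):
            length = int(rng.integers(200, config.min_contig_len))
            start = int(rng.integers(0, len(genome) - length))
            cid = f"{ent_name}_s{j:04d}"
            contigs.append(NucSequence(cid, genome[start : start + length]))
            truth.contig_origin[cid] = ent_name
            truth.contig_class[cid] = "sub1kb"
    return contigs


# ---------------------------------------------------------------------------
# Read simulation (MDA-biased paired-end)
# ---------------------------------------------------------------------------

def _apply_errors(mat: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return mat
    mask = rng.random(mat.shape) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()))
    out = mat.copy()
    out[mask] = (out[mask] + shift) % 4
    return out


def simulate_reads(
    genomes: dict[str, str], config: CommunityConfig, truth: TruthTable
) -> list[ReadPair]:
    """Paired-end reads with MDA-style coverage skew.

    Fragment starts are drawn with per-window lognormal(0, ``mda_sigma``)
    weights; substitutions occur at ``error_rate``; per-base qualities decay
    linearly from ``qual_start`` to ``qual_end``; mate 2 is the reverse
    complement of the fragment's far end.
    """
    if config.n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(config.seed + 2)
    names = [e.name for e in config.entities]
    weights = np.array([e.abundance for e in config.entities], dtype=float)
    weights /= weights.sum()
    n_per = rng.multinomial(config.n_pairs, weights)

    trans = bytes.maketrans(b"ACGT", b"\x00\x01\x02\x03")
    back = bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT")
    L = config.read_len
    ramp = np.linspace(config.qual_start, config.qual_end, L)
    pairs: list[ReadPair] = []
    serial = 0
    for ent_name, n_reads in zip(names, n_per):
        if n_reads == 0:
            continue
        g = np.frombuffer(
            genomes[ent_name].encode().translate(trans), dtype=np.uint8
        ).astype(np.int8)
        glen = len(g)
        n_win = max(1, glen // config.mda_window)
        if config.mda_sigma > 0:
            wts = np.exp(rng.normal(0.0, config.mda_sigma, n_win))
        else:
            wts = np.ones(n_win)
        wts /= wts.sum()
        win = rng.choice(n_win, size=n_reads, p=wts)
        inserts = np.maximum(
            rng.normal(config.insert_mean, config.insert_sd, n_reads), L
        ).astype(int)
        starts = win * config.mda_window + rng.integers(
            0, config.mda_window, n_reads
        )
        starts = np.minimum(starts, glen - inserts)
        starts = np.maximum(starts, 0)
        inserts = np.minimum(inserts, glen - starts)

        idx1 = starts[:, None] + np.arange(L)[None, :]
        ends = starts + inserts
        idx2 = ends[:, None] - 1 - np.arange(L)[None, :]
        fwd = _apply_errors(g[idx1], config.error_rate, rng)
        rev_src = g[np.maximum(idx2, 0)]
        rev = _apply_errors(3 - rev_src, config.error_rate, rng)

        jitter1 = rng.integers(-2, 3, size=(n_reads, L))
        jitter2 = rng.integers(-2, 3, size=(n_reads, L))
        q1 = np.clip(np.round(ramp[None, :] + jitter1), 2, 41).astype(int)
        q2 = np.clip(np.round(ramp[None, :] + jitter2), 2, 41).astype(int)

        for i in range(n_reads):
            pid = f"p{serial:07d}"
            serial += 1
            f_seq = fwd[i].astype(np.uint8).tobytes().translate(back).decode()
            r_seq = rev[i].astype(np.uint8).tobytes().translate(back).decode()
            pairs.append(ReadPair(
                NucSequence(f"{pid}/1", f_seq, tuple(q1[i])),
                NucSequence(f"{pid}/2", r_seq, tuple(q2[i])),
                pid,
            ))
            truth.read_origin[pid] = ent_name
    # interleave deterministically by shuffling with the same generator
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


def simulate_rrna_pairs(
    rrna_refs: list[tuple[str, str, str]],
    genus_weights: dict[str, float],
    n_pairs: int,
    read_len: int = 150,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    divergence: float = 0.02,
    error_rate: float = 0.002,
    seed: int = 0,
) -> tuple[list[ReadPair], dict[str, str]]:
    """Paired reads drawn from rRNA genes of chosen genera.

    Each pair comes from a reference of its genus mutated at ``divergence``
    (a novel environmental strain) with sequencing errors on top. Returns
    (pairs, truth genus per pair id).
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list(_BASES))
    by_genus: dict[str, list[str]] = {}
    for _, lineage, seq in rrna_refs:
        genus = lineage.split(";")[-1]
        by_genus.setdefault(genus, []).append(seq)
    genera = sorted(genus_weights)
    w = np.array([genus_weights[g] for g in genera], dtype=float)
    w /= w.sum()
    truth: dict[str, str] = {}
    pairs: list[ReadPair] = []

    def mutate(s: str, rate: float) -> str:
        arr = np.array(list(s))
        m = rng.random(len(arr)) < rate
        arr[m] = bases[rng.integers(0, 4, int(m.sum()))]
        return "".join(arr)

    quals = tuple([35] * read_len)
    for i in range(n_pairs):
        genus = genera[int(rng.choice(len(genera), p=w))]
        ref = by_genus[genus][int(rng.integers(len(by_genus[genus])))]
        strain = mutate(ref, divergence)
        insert = int(max(rng.normal(insert_mean, insert_sd), read_len))
        insert = min(insert, len(strain))
        start = int(rng.integers(0, len(strain) - insert + 1))
        frag = strain[start : start + insert]
        fwd = mutate(frag[:read_len], error_rate)
        rev = mutate(reverse_complement(frag)[:read_len], error_rate)
        pid = f"rp{i:06d}"
        pairs.append(ReadPair(
            NucSequence(f"{pid}/1", fwd, quals),
            NucSequence(f"{pid}/2", rev, quals),
            pid,
        ))
        truth[pid] = genus
    return pairs, truth


# ---------------------------------------------------------------------------
# Convenience drivers
# ---------------------------------------------------------------------------

def simulate_community(
    config: CommunityConfig,
    marker_alignments=None,
    rrna_refs=None,
    with_reads: bool = True,
):
    """Genomes -> contigs -> reads in one call. Returns
    (genomes, contigs, pairs, truth)."""
    genomes, truth = simulate_genomes(config, marker_alignments, rrna_refs)
    contigs = make_contigs(genomes, config, truth)
    pairs = simulate_reads(genomes, config, truth) if with_reads else []
    return genomes, contigs, pairs, truth


def write_community(outdir: str | Path, contigs, pairs, truth: TruthTable) -> None:
    """contigs.fasta, reads_R1/R2.fastq, truth.tsv, features.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    serialize_fastx(contigs, outdir / "contigs.fasta", "fasta")
    serialize_fastx((p.fwd for p in pairs), outdir / "reads_R1.fastq", "fastq")
    serialize_fastx((p.rev for p in pairs), outdir / "reads_R2.fastq", "fastq")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("contig_id\tentity\tclass\n")
        for cid, ent in truth.contig_origin.items():
            fh.write(f"{cid}\t{ent}\t{truth.contig_class[cid]}\n")
    with open(outdir / "features.tsv", "w") as fh:
        fh.write("entity\tname\tkind\tstart\tend\tstrand\n")
        for f in truth.features:
            fh.write(f"{f.entity}\t{f.name}\t{f.kind}\t{f.start}\t{f.end}\t{f.strand}\n")
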