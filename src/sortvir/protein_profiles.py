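"""Comparative protein-content analysis across virus genomes.

Orthogroups are inferred as connected components of an all-vs-all similarity
graph (bit score >= 50 over >= 50% of the shorter protein), the
genome-by-orthogroup presence/absence matrix is clustered by average linkage
on Jaccard distance with bootstrap (BP) and approximately unbiased (AU)
support from a multiscale bootstrap, protein taxonomy is affiliated from the
top ten reference hits, rhodopsin queries are typed by their three-residue
functional motif and spectral-tuning site, and a neighbor-joining tree over
concatenated marker alignments provides the phylogenetic counterpart that
presence/absence clustering is compared against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import norm
from skbio import DistanceMatrix
from skbio.tree import nj

from .sequence_io import KA_BLOSUM62

__all__ = [
    "OrthoMatrix",
    "SupportedDendrogram",
    "protein_align",
    "infer_orthogroups",
    "cluster_presence_absence",
    "taxonomy_affiliation",
    "rhodopsin_motif",
    "marker_concat_tree",
]


@dataclass
class OrthoMatrix:
    genomes: list[str]
    orthogroups: list[str]
    presence: np.ndarray                  # (n_genomes, n_orthogroups) in {0,1}
    members: dict[str, list[tuple[str, str]]]   # og -> [(genome, protein_id)]
    private_counts: dict[str, int]        # genome -> proteins shared with no other genome

    def genome_counts(self) -> np.ndarray:
        return self.presence.sum(axis=0)


@dataclass
class ClusterNode:
    leaves: frozenset
    height: float
    bp: Optional[float] = None
    au: Optional[float] = None


@dataclass
class SupportedDendrogram:
    labels: list[str]
    linkage_matrix: np.ndarray
    nodes: list[ClusterNode]

    def support_for(self, leaves: set) -> Optional[ClusterNode]:
        target = frozenset(leaves)
        for node in self.nodes:
            if node.leaves == target:
                return node
        return None

    def to_newick(self, support: str = "bp") -> str:
        n = len(self.labels)
        children: dict[int, tuple[int, int]] = {}
        for i, (a, b, _, _) in enumerate(self.linkage_matrix):
            children[n + i] = (int(a), int(b))
        heights = {i: 0.0 for i in range(n)}
        for i, row in enumerate(self.linkage_matrix):
            heights[n + i] = row[2]
        by_leaves = {node.leaves: node for node in self.nodes}

        def leaves_of(idx: int) -> frozenset:
            if idx < n:
                return frozenset([self.labels[idx]])
            a, b = children[idx]
            return leaves_of(a) | leaves_of(b)

        def render(idx: int, parent_h: float) -> str:
            bl = max(parent_h - heights[idx], 0.0)
            if idx < n:
                return f"{self.labels[idx]}:{bl:.6f}"
            a, b = children[idx]
            h = heights[idx]
            inner = f"({render(a, h)},{render(b, h)})"
            node = by_leaves.get(leaves_of(idx))
            label = ""
            if node is not None:
                val = getattr(node, support)
                if val is not None:
                    label = f"{val:.3f}"
            return f"{inner}{label}:{bl:.6f}"

        root = n + len(self.linkage_matrix) - 1
        return render(root, heights[root]) + ";"


# ---------------------------------------------------------------------------
# Protein-protein alignment (blastp stand-in)
# ---------------------------------------------------------------------------

_PROT_ALIGNER: Optional[PairwiseAligner] = None


def _get_prot_aligner() -> PairwiseAligner:
    global _PROT_ALIGNER
    if _PROT_ALIGNER is None:
        aln = PairwiseAligner()
        aln.mode = "local"
        aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aln.open_gap_score = -11.0
        aln.extend_gap_score = -1.0
        _PROT_ALIGNER = aln
    return _PROT_ALIGNER


_SAFE = set("ACDEFGHIKLMNPQRSTVWYBZX*")


def _sanitize(seq: str) -> str:
    return "".join(c if c in _SAFE else "X" for c in seq.upper()).replace("*", "X")


def protein_align(query: str, target: str) -> Optional[dict]:
    """Best local BLOSUM62 alignment; returns bits, identity, coverage of the
    shorter sequence, or None when nothing aligns."""
    q, t = _sanitize(query), _sanitize(target)
    if not q or not t:
        return None
    aligner = _get_prot_aligner()
    alns = aligner.align(q, t)
    if not len(alns) or alns.score <= 0:
        return None
    aln = alns[0]
    counts = aln.counts()
    aligned_len = counts.identities + counts.mismatches + counts.gaps
    lam, k = KA_BLOSUM62
    bits = (lam * aln.score - math.log(k)) / math.log(2)
    shorter = min(len(q), len(t))
    q_span = int(aln.aligned[0][-1][1]) - int(aln.aligned[0][0][0])
    t_span = int(aln.aligned[1][-1][1]) - int(aln.aligned[1][0][0])
    cov = min(q_span, t_span) / shorter if shorter else 0.0
    return {
        "bits": bits,
        "raw": float(aln.score),
        "identities": int(counts.identities),
        "aligned_len": int(aligned_len),
        "pct_identity": 100.0 * counts.identities / aligned_len if aligned_len else 0.0,
        "coverage_shorter": cov,
        "evalue": len(q) * len(t) * 2.0 ** (-bits),
    }


def _kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


# ---------------------------------------------------------------------------
# Orthogroup inference
# ---------------------------------------------------------------------------

def infer_orthogroups(
    proteomes: dict[str, list[tuple[str, str]]],
    min_bits: float = 50.0,
    min_cov: float = 0.5,
) -> OrthoMatrix:
    """Connected-component orthogroups from an all-vs-all similarity graph.

    ``proteomes`` maps genome -> [(protein_id, sequence)]. Edges require bit
    score >= ``min_bits`` and >= ``min_cov`` coverage of the shorter protein;
    an exact 4-aa shared word gates the alignment. Proteins in no cross-genome
    orthogroup count toward their genome's private total.
    """
    if len(proteomes) < 2:
        raise ValueError("need >= 2 proteomes")
    import warnings

    nodes: list[tuple[str, str, str]] = []   # (genome, protein_id, seq)
    for genome in sorted(proteomes):
        prots = proteomes[genome]
        if not prots:
            warnings.warn(f"empty proteome for {genome}", stacklevel=2)
        for pid, seq in prots:
            nodes.append((genome, pid, seq))

    kmers = [_kmer_set(_sanitize(s)) for _, _, s in nodes]
    G = nx.Graph()
    G.add_nodes_from(range(len(nodes)))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if nodes[i][0] == nodes[j][0] and nodes[i][1] == nodes[j][1]:
                continue
            if not (kmers[i] & kmers[j]):
                continue
            res = protein_align(nodes[i][2], nodes[j][2])
            if res and res["bits"] >= min_bits and res["coverage_shorter"] >= min_cov:
                G.add_edge(i, j)

    genomes = sorted(proteomes)
    gi = {g: k for k, g in enumerate(genomes)}
    components = sorted(
        (sorted(c) for c in nx.connected_components(G)), key=lambda c: c[0]
    )
    og_ids: list[str] = []
    members: dict[str, list[tuple[str, str]]] = {}
    rows = []
    private = {g: 0 for g in genomes}
    serial = 0
    for comp in components:
        comp_genomes = {nodes[i][0] for i in comp}
        if len(comp_genomes) == 1:
            # not shared with any other virus analysed: genome-private
            for i in comp:
                private[nodes[i][0]] += 1
        og = f"OG{serial:05d}"
        serial += 1
        og_ids.append(og)
        members[og] = [(nodes[i][0], nodes[i][1]) for i in comp]
        row = np.zeros(len(genomes), dtype=np.int8)
        for g in comp_genomes:
            row[gi[g]] = 1
        rows.append(row)

    presence = np.vstack(rows).T if rows else np.zeros((len(genomes), 0), dtype=np.int8)
    return OrthoMatrix(genomes, og_ids, presence, members, private)


# ---------------------------------------------------------------------------
# Presence/absence clustering with BP and AU support
# ---------------------------------------------------------------------------

def _tree_clades(Z: np.ndarray, n: int) -> list[frozenset]:
    clades: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for i, (a, b, _, _) in enumerate(Z):
        clades[n + i] = clades[int(a)] | clades[int(b)]
        out.append(clades[n + i])
    return out


_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5 .. 1.4


def cluster_presence_absence(
    matrix: OrthoMatrix | np.ndarray,
    labels: Optional[Sequence[str]] = None,
    n_boot: int = 500,
    seed: int = 0,
) -> SupportedDendrogram:
    """Average-linkage clustering of genomes on Jaccard distance over the
    binary orthogroup matrix, with node support from a multiscale bootstrap.

    BP is the fraction of column-resampled trees (at the original number of
    columns) containing each node's leaf set. AU comes from the multiscale
    fit: z_r = Phi^-1(1 - BP_r) is regressed on v*sqrt(r) + c/sqrt(r) over
    scales r in 0.5..1.4 and AU = 1 - Phi(v - c). Deterministic under seed.
    """
    if isinstance(matrix, OrthoMatrix):
        X = matrix.presence.astype(bool)
        labels = list(matrix.genomes)
    else:
        X = np.asarray(matrix).astype(bool)
        labels = list(labels) if labels is not None else [
            f"g{i}" for i in range(X.shape[0])
        ]
    n, p = X.shape
    if n < 3:
        raise ValueError("need >= 3 genomes to cluster")
    degenerate = bool((X == X[0]).all())
    if degenerate:
        import warnings
        warnings.warn("constant presence/absence matrix: degenerate tree",
                      stacklevel=2)

    def build(Xb: np.ndarray) -> np.ndarray:
        D = pdist(Xb, metric="jaccard")
        D = np.nan_to_num(D, nan=0.0)
        return linkage(D, method="average")

    Z = build(X)
    clades = _tree_clades(Z, n)
    nontrivial = [c for c in clades if 1 < len(c) < n]

    rng = np.random.default_rng(seed)
    counts: dict[float, dict[frozenset, int]] = {
        r: {c: 0 for c in nontrivial} for r in _SCALES
    }
    for r in _SCALES:
        pr = max(1, int(round(r * p)))
        for _ in range(n_boot):
            cols = rng.integers(0, p, pr)
            Zb = build(X[:, cols])
            for c in _tree_clades(Zb, n):
                if c in counts[r]:
                    counts[r][c] += 1

    eps = 1.0 / (2 * n_boot)
    nodes: list[ClusterNode] = []
    for i, (a, b, h, _) in enumerate(Z):
        leaves = clades[i]
        named = frozenset(labels[j] for j in leaves)
        node = ClusterNode(named, float(h))
        if leaves in counts[1.0]:
            node.bp = counts[1.0][leaves] / n_boot
            scale_counts = [counts[r][leaves] for r in _SCALES]
            if min(scale_counts) == n_boot:
                node.au = 1.0     # saturated at every scale: fully supported
            elif max(scale_counts) == 0:
                node.au = 0.0
            else:
                zs, xs = [], []
                for r, cnt in zip(_SCALES, scale_counts):
                    bp_r = min(max(cnt / n_boot, eps), 1 - eps)
                    zs.append(norm.ppf(1.0 - bp_r))
                    xs.append(r)
                A = np.column_stack([np.sqrt(xs), 1.0 / np.sqrt(xs)])
                coef, *_ = np.linalg.lstsq(A, np.array(zs), rcond=None)
                v, c = coef
                node.au = float(1.0 - norm.cdf(v - c))
        else:
            node.bp = 1.0 if len(leaves) in (1, n) else None
            node.au = node.bp
        if len(leaves) == n:
            node.bp = node.au = 1.0
        nodes.append(node)
    return SupportedDendrogram(labels, Z, nodes)


# ---------------------------------------------------------------------------
# Taxonomy affiliation (top-ten-hit rule)
# ---------------------------------------------------------------------------

def taxonomy_affiliation(
    proteins: Sequence[tuple[str, str]],
    labeled_reference: Sequence[tuple[str, str, str]],
    evalue_max: float = 1e-5,
    top_n: int = 10,
) -> dict:
    """Affiliate each protein by the lineages among its top ``top_n``
    reference hits below ``evalue_max``.

    ``labeled_reference`` holds (ref_id, lineage, sequence) with lineage in
    {Eukaryote, Prokaryote, NCLDV, ...} (archaea and bacteria pooled as
    Prokaryote upstream). The category is the sorted set of lineages among
    the retained hits, 'no-hit' when nothing qualifies.
    """
    per_protein: dict[str, dict] = {}
    tally: dict[str, int] = {}
    ref_kmers = [(_sanitize(s), _kmer_set(_sanitize(s))) for _, _, s in labeled_reference]
    for pid, seq in proteins:
        qk = _kmer_set(_sanitize(seq))
        hits = []
        for (rid, lineage, rseq), (rs, rk) in zip(labeled_reference, ref_kmers):
            if not (qk & rk):
                continue
            res = protein_align(seq, rseq)
            if res and res["evalue"] < evalue_max:
                hits.append((res["bits"], rid, lineage))
        hits.sort(key=lambda h: (-h[0], h[1]))
        top = hits[:top_n]
        if not top:
            category = "no-hit"
        else:
            category = "+".join(sorted({lineage for _, _, lineage in top}))
        per_protein[pid] = {
            "category": category,
            "hits": [(rid, bits) for bits, rid, _ in top],
        }
        tally[category] = tally.get(category, 0) + 1
    total = len(per_protein)
    return {
        "per_protein": per_protein,
        "fractions": {c: n / total for c, n in sorted(tally.items())} if total else {},
    }


# ---------------------------------------------------------------------------
# Rhodopsin motif typing
# ---------------------------------------------------------------------------

def rhodopsin_motif(
    protein: str,
    reference_alignment: Sequence[tuple[str, str]],
    motif_columns: tuple[int, int, int],
    tuning_column: int,
    min_bits: float = 40.0,
) -> Optional[dict]:
    """Type a rhodopsin by the residues at the aligned motif and tuning
    columns (0-based columns of ``reference_alignment``).

    The query is aligned to the ungapped first reference sequence; reference
    alignment columns map through that sequence onto the query. Tuning is
    called 'green' only for methionine at the tuning site; any other residue
    is reported without a spectral claim. Returns ``None`` (no-call) when the
    query does not align above ``min_bits``.
    """
    anchor_id, anchor_row = reference_alignment[0]
    col_to_res: dict[int, int] = {}
    ri = 0
    for col, ch in enumerate(anchor_row):
        if ch not in "-.":
            col_to_res[col] = ri
            ri += 1
    try:
        anchor_positions = [col_to_res[c] for c in (*motif_columns, tuning_column)]
    except KeyError as exc:
        raise ValueError(f"anchor sequence is gapped at column {exc}") from exc

    anchor_seq = anchor_row.replace("-", "").replace(".", "")
    res = protein_align(protein, anchor_seq)
    if res is None or res["bits"] < min_bits:
        return None
    # map anchor residue index -> query residue via the alignment blocks
    aligner = _get_prot_aligner()
    aln = aligner.align(_sanitize(protein), _sanitize(anchor_seq))[0]
    q_blocks, t_blocks = aln.aligned
    t_to_q: dict[int, int] = {}
    for (q0, q1), (t0, t1) in zip(q_blocks, t_blocks):
        for k in range(t1 - t0):
            t_to_q[t0 + k] = q0 + k
    residues = []
    for pos in anchor_positions:
        qpos = t_to_q.get(pos)
        residues.append(protein[qpos] if qpos is not None else "?")
    motif = "".join(residues[:3])
    tuning_res = residues[3]
    return {
        "motif": motif,
        "tuning_residue": tuning_res,
        "tuning_call": "green" if tuning_res == "M" else "unknown",
        "bits": res["bits"],
    }


# ---------------------------------------------------------------------------
# Concatenated-marker neighbor-joining tree
# ---------------------------------------------------------------------------

def marker_concat_tree(
    marker_alignments: dict[str, dict[str, str]],
):
    """Neighbor-joining tree on p-distances over concatenated marker
    alignments.

    ``marker_alignments`` maps marker -> {genome: aligned sequence}; a genome
    missing a marker contributes gaps there (pairwise deletion: only columns
    where both genomes carry residues enter each p-distance). Returns a
    scikit-bio ``TreeNode``.
    """
    genomes = sorted({g for aln in marker_alignments.values() for g in aln})
    if len(genomes) < 4:
        raise ValueError("need >= 4 genomes for a meaningful NJ tree")
    concat: dict[str, list[str]] = {g: [] for g in genomes}
    for marker in sorted(marker_alignments):
        aln = marker_alignments[marker]
        width = len(next(iter(aln.values())))
        if any(len(s) != width for s in aln.values()):
            raise ValueError(f"ragged alignment for {marker}")
        for g in genomes:
            concat[g].append(aln.get(g, "-" * width))
    seqs = {g: "".join(parts) for g, parts in concat.items()}

    n = len(genomes)
    D = np.zeros((n, n))
    arrs = {g: np.frombuffer(seqs[g].encode(), dtype="S1") for g in genomes}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[genomes[i]], arrs[genomes[j]]
            ok = (a != b"-") & (b != b"-") & (a != b".") & (b != b".")
            m = int(ok.sum())
            d = float((a[ok] != b[ok]).sum()) / m if m else 0.0
            D[i, j] = D[j, i] = d
    dm = DistanceMatrix(D, ids=genomes)
    return nj(dm)
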