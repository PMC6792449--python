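"""Sort composition from unassembled read pairs.

Pairs where BOTH mates align to an SSU rRNA reference set are kept, mates are
joined with a single N, and the joined fragment is classified with an
RDP-style bootstrap naive-Bayes classifier: per-genus 8-mer presence
probabilities with add-half smoothing, scored over the query's distinct
words (words containing the joining N carry no signal), with confidence from
100 resamples of one-eighth of the words. The per-rank summary is the
text/JSON stand-in for a Krona chart.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .sequence_io import (
    NucSequence,
    ReadPair,
    local_align,
    reverse_complement,
)

__all__ = [
    "RankedLineage",
    "GenusModel",
    "RANKS",
    "extract_rrna_pairs",
    "join_pair_with_N",
    "train_genus_model",
    "rdp_classify",
    "summarize_composition",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
WORD_SIZE = 8


@dataclass(frozen=True)
class RankedLineage:
    """Ordered taxonomy path, domain -> genus; may be truncated when deeper
    ranks fall below the confidence cutoff."""

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ranks:
            raise ValueError("lineage must carry at least one rank")

    @property
    def leaf(self) -> str:
        return self.ranks[-1]

    @classmethod
    def from_string(cls, s: str) -> "RankedLineage":
        return cls(tuple(p.strip() for p in s.split(";") if p.strip()))


@dataclass
class GenusModel:
    """Naive-Bayes word model: P(word | genus) with add-half smoothing over
    the number of training sequences per genus; uniform genus priors."""

    genera: list[str]
    lineages: dict[str, RankedLineage]
    word_index: dict[str, int]
    log_probs: np.ndarray          # (n_genera, n_words)
    log_missing: np.ndarray        # (n_genera,) score for unseen words
    word_size: int = WORD_SIZE


# ---------------------------------------------------------------------------
# Pair extraction (both-mates rule) and joining
# ---------------------------------------------------------------------------

_SEED_K = 14


def _build_ref_index(refs: Sequence[NucSequence]) -> dict[str, set[int]]:
    """k-mer -> indices of references containing it (either strand)."""
    index: dict[str, set[int]] = {}
    for ri, ref in enumerate(refs):
        for s in (ref.residues, reverse_complement(ref.residues)):
            for i in range(len(s) - _SEED_K + 1):
                index.setdefault(s[i : i + _SEED_K], set()).add(ri)
    return index


def _mate_is_rrna(
    read: NucSequence,
    refs: Sequence[NucSequence],
    index: dict[str, set[int]],
    min_bits: float,
) -> bool:
    """One mate qualifies when it aligns to any reference above ``min_bits``;
    an exact k-mer seed gates the Smith-Waterman confirmation."""
    candidates: set[int] = set()
    probe = read.residues
    for i in range(0, len(probe) - _SEED_K + 1, 5):
        candidates |= index.get(probe[i : i + _SEED_K], set())
    for ri in sorted(candidates):
        res = local_align(read, refs[ri], mode="nucleotide")
        if res is not None and res.bit_score >= min_bits:
            return True
    return False


def extract_rrna_pairs(
    pairs: Sequence[ReadPair],
    rrna_refs: Sequence[NucSequence],
    min_bits: float = 80.0,
) -> list[ReadPair]:
    """Keep only pairs where both mates independently align to the rRNA
    reference set above ``min_bits`` (the strict two-mate confirmation)."""
    index = _build_ref_index(rrna_refs)
    kept = []
    for pair in pairs:
        if _mate_is_rrna(pair.fwd, rrna_refs, index, min_bits) and _mate_is_rrna(
            pair.rev, rrna_refs, index, min_bits
        ):
            kept.append(pair)
    return kept


def join_pair_with_N(pair: ReadPair) -> NucSequence:
    """fwd + 'N' + revcomp(rev), so both mates read the same strand."""
    return NucSequence(
        pair.pair_id,
        pair.fwd.residues + "N" + reverse_complement(pair.rev.residues),
    )


# ---------------------------------------------------------------------------
# RDP-style naive Bayes
# ---------------------------------------------------------------------------

def _distinct_words(seq: str, k: int) -> list[str]:
    words = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" not in w:
            words.add(w)
    return sorted(words)


def train_genus_model(
    references: Sequence[tuple[str, str, str]],
    word_size: int = WORD_SIZE,
) -> GenusModel:
    """Train on (id, lineage-string, sequence) references; the genus is the
    last rank of each lineage. P(w|g) = (m_g(w) + 0.5) / (M_g + 1) with m =
    sequences in g containing w and M = sequences in g."""
    by_genus: dict[str, list[str]] = {}
    lineages: dict[str, RankedLineage] = {}
    for _, lineage_str, seq in references:
        lin = RankedLineage.from_string(lineage_str)
        by_genus.setdefault(lin.leaf, []).append(seq.upper())
        lineages[lin.leaf] = lin

    vocab: dict[str, int] = {}
    genus_word_counts: list[Counter] = []
    genera = sorted(by_genus)
    for g in genera:
        counts: Counter = Counter()
        for seq in by_genus[g]:
            counts.update(_distinct_words(seq, word_size))
        genus_word_counts.append(counts)
        for w in counts:
            if w not in vocab:
                vocab[w] = len(vocab)

    n_g, n_w = len(genera), len(vocab)
    log_probs = np.empty((n_g, n_w))
    log_missing = np.empty(n_g)
    for gi, (g, counts) in enumerate(zip(genera, genus_word_counts)):
        M = len(by_genus[g])
        log_missing[gi] = math.log(0.5 / (M + 1))
        row = np.full(n_w, log_missing[gi])
        for w, m in counts.items():
            row[vocab[w]] = math.log((m + 0.5) / (M + 1))
        log_probs[gi] = row
    return GenusModel(genera, lineages, vocab, log_probs, log_missing, word_size)


def _genus_scores(model: GenusModel, word_ids: np.ndarray, missing: int) -> np.ndarray:
    if word_ids.size:
        s = model.log_probs[:, word_ids].sum(axis=1)
    else:
        s = np.zeros(len(model.genera))
    return s + missing * model.log_missing


def rdp_classify(
    joined: NucSequence | str,
    model: GenusModel,
    n_boot: int = 100,
    conf_cutoff: float = 0.8,
    seed: int = 0,
) -> Optional[tuple[RankedLineage, dict[str, float]]]:
    """Classify a joined pair; returns (lineage truncated at the deepest rank
    with confidence >= ``conf_cutoff``, per-rank confidences), or ``None``
    when the query has fewer than one informative word."""
    seq = joined.residues if isinstance(joined, NucSequence) else joined.upper()
    words = _distinct_words(seq, model.word_size)
    if not words:
        return None
    known = np.array(
        [model.word_index[w] for w in words if w in model.word_index],
        dtype=np.int64,
    )
    n_missing = len(words) - known.size

    full = _genus_scores(model, known, n_missing)
    best_genus = model.genera[int(np.argmax(full))]

    rng = np.random.default_rng(seed)
    W = len(words)
    subset = max(1, math.ceil(W / model.word_size))
    all_ids = np.array(
        [model.word_index.get(w, -1) for w in words], dtype=np.int64
    )
    votes: Counter = Counter()
    for _ in range(n_boot):
        pick = all_ids[rng.integers(0, W, subset)]
        ids = pick[pick >= 0]
        s = _genus_scores(model, ids, int((pick < 0).sum()))
        votes[model.genera[int(np.argmax(s))]] += 1

    conf: dict[str, float] = {}
    best_lineage = model.lineages[best_genus]
    for depth, rank_name in enumerate(best_lineage.ranks):
        agree = sum(
            v for g, v in votes.items()
            if len(model.lineages[g].ranks) > depth
            and model.lineages[g].ranks[depth] == rank_name
        )
        conf[rank_name] = agree / n_boot

    keep = 0
    for rank_name in best_lineage.ranks:
        if conf[rank_name] >= conf_cutoff:
            keep += 1
        else:
            break
    if keep == 0:
        return None
    return RankedLineage(best_lineage.ranks[:keep]), conf


# ---------------------------------------------------------------------------
# Composition summary
# ---------------------------------------------------------------------------

def summarize_composition(lineages: Sequence[RankedLineage]) -> dict:
    """Nested per-rank counts and percentages (each level sums to 100 within
    rounding). Empty input yields an explicit zero-total summary."""
    total = len(lineages)
    root: dict = {"name": "root", "count": total, "pct": 100.0 if total else 0.0,
                  "children": {}}
    for lin in lineages:
        node = root
        for rank in lin.ranks:
            node = node["children"].setdefault(
                rank, {"name": rank, "count": 0, "pct": 0.0, "children": {}}
            )
            node["count"] += 1
    def fill_pct(node: dict) -> None:
        for child in node["children"].values():
            child["pct"] = 100.0 * child["count"] / total if total else 0.0
            fill_pct(child)
    fill_pct(root)
    return root


def composition_table(summary: dict) -> list[tuple[int, str, int, float]]:
    """Flatten a nested summary to (depth, taxon, count, pct) rows."""
    rows: list[tuple[int, str, int, float]] = []
    def walk(node: dict, depth: int) -> None:
        for name in sorted(node["children"]):
            child = node["children"][name]
            rows.append((depth, name, child["count"], child["pct"]))
            walk(child, depth + 1)
    walk(summary, 0)
    return rows
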