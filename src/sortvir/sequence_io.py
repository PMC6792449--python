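"""Sequence primitives shared by every pipeline stage.

Readers/writers for FASTA/FASTQ (Sanger phred+33), sliding-window quality
trimming, six-frame translation, strand-canonical k-mer composition vectors,
GC content, and Smith-Waterman local alignment in nucleotide and translated
(six-frame vs. protein) modes with BLAST-style bit scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "NucSequence",
    "ReadPair",
    "AlignmentResult",
    "FastxParseError",
    "parse_fastx",
    "serialize_fastx",
    "reverse_complement",
    "quality_trim",
    "six_frame_translate",
    "canonical_kmers",
    "canonical_kmer_counts",
    "gc_content",
    "moving_gc",
    "local_align",
    "alignment_to_tsv",
]

_NUC_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Karlin-Altschul parameters per scoring scheme, fixed library constants.
# Nucleotide: match +1 / mismatch -2 (ungapped blastn values); protein:
# BLOSUM62 with gap open 11 / extend 1 (standard gapped blastp values).
KA_NUCLEOTIDE = (1.28, 0.46)
KA_BLOSUM62 = (0.267, 0.041)


@dataclass(frozen=True)
class NucSequence:
    """A nucleotide record: reads and contigs alike.

    ``residues`` is uppercase over {A,C,G,T,N}; ``quals`` are Sanger phred
    scores (0-41) of equal length, or ``None`` for FASTA-origin records.
    """

    id: str
    residues: str
    quals: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        res = self.residues.upper()
        if set(res) - _NUC_ALPHABET:
            bad = sorted(set(res) - _NUC_ALPHABET)
            raise ValueError(f"record {self.id!r}: non-ACGTN residues {bad}")
        object.__setattr__(self, "residues", res)
        if self.quals is not None:
            q = tuple(int(v) for v in self.quals)
            if len(q) != len(res):
                raise ValueError(
                    f"record {self.id!r}: {len(q)} quality values for "
                    f"{len(res)} residues"
                )
            if q and (min(q) < 0 or max(q) > 41):
                raise ValueError(f"record {self.id!r}: phred scores outside 0-41")
            object.__setattr__(self, "quals", q)

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucSequence":
        quals = self.quals[::-1] if self.quals is not None else None
        return NucSequence(self.id, reverse_complement(self.residues), quals)


@dataclass(frozen=True)
class ReadPair:
    fwd: NucSequence
    rev: NucSequence
    pair_id: str

    def __post_init__(self) -> None:
        if self.pair_id not in self.fwd.id or self.pair_id not in self.rev.id:
            raise ValueError(
                f"mate ids {self.fwd.id!r}/{self.rev.id!r} do not share "
                f"pair id {self.pair_id!r}"
            )


@dataclass
class AlignmentResult:
    """A local alignment hit. Intervals are 0-based half-open on the forward
    coordinate system of each sequence; ``strand``/``frame`` record where the
    query matched for translated searches."""

    query_id: str
    target_id: str
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    strand: str = "+"
    frame: Optional[int] = None
    matches: int = 0
    aligned_len: int = 0
    raw_score: float = 0.0
    bit_score: float = 0.0
    evalue: float = math.inf

    @property
    def pct_identity(self) -> float:
        if self.aligned_len == 0:
            return 0.0
        return 100.0 * self.matches / self.aligned_len


class FastxParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O
# ---------------------------------------------------------------------------

def parse_fastx(path: str | Path, format: str) -> Iterator[NucSequence]:
    """Stream records from a FASTA or FASTQ file (Sanger phred+33 only)."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    record_no = 0
    try:
        for rec in SeqIO.parse(str(path), format):
            record_no += 1
            quals = None
            if format == "fastq":
                quals = tuple(rec.letter_annotations["phred_quality"])
            yield NucSequence(rec.id, str(rec.seq), quals)
    except ValueError as exc:
        # Biopython reports the failure; add file position context. The
        # offending line is derived from the record index (4 lines/record for
        # FASTQ, best-effort for multi-line FASTA).
        line_hint = record_no * 4 + 1 if format == "fastq" else record_no + 1
        raise FastxParseError(
            f"{path}: malformed {format} at/after record {record_no + 1} "
            f"(near line {line_hint}): {exc}"
        ) from exc


def serialize_fastx(
    records: Iterable[NucSequence], path: str | Path, format: str
) -> None:
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    with open(path, "w") as fh:
        for rec in records:
            if format == "fasta":
                fh.write(f">{rec.id}\n{rec.residues}\n")
            else:
                if rec.quals is None:
                    raise ValueError(f"record {rec.id!r} has no qualities")
                qual = "".join(chr(q + 33) for q in rec.quals)
                fh.write(f"@{rec.id}\n{rec.residues}\n+\n{qual}\n")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Quality trimming (Trimmomatic-style LEADING/TRAILING/SLIDINGWINDOW/MINLEN)
# ---------------------------------------------------------------------------

def quality_trim(
    read: NucSequence,
    leading_q: int = 3,
    trailing_q: int = 3,
    window: int = 25,
    window_q: float = 30.0,
    min_len: int = 50,
) -> Optional[NucSequence]:
    """Trim a read: drop leading/trailing bases below ``leading_q``/
    ``trailing_q``, then truncate at the start of the first ``window``-base
    window whose mean quality is below ``window_q``. Returns ``None`` when the
    survivor is shorter than ``min_len``.
    """
    if read.quals is None:
        raise ValueError(f"read {read.id!r} has no qualities to trim")
    q = np.asarray(read.quals, dtype=float)
    start, end = 0, len(q)
    while start < end and q[start] < leading_q:
        start += 1
    while end > start and q[end - 1] < trailing_q:
        end -= 1
    if end - start >= window:
        qs = q[start:end]
        means = np.convolve(qs, np.ones(window) / window, mode="valid")
        bad = np.flatnonzero(means < window_q)
        if bad.size:
            end = start + int(bad[0])
    if end - start < min_len:
        return None
    return NucSequence(
        read.id, read.residues[start:end], read.quals[start:end]
    )


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def six_frame_translate(seq: NucSequence | str) -> list[str]:
    """Translate all six frames (0-2 forward, 3-5 on the reverse complement).
    Stops are '*', ambiguous codons 'X'; trailing partial codons dropped."""
    s = seq.residues if isinstance(seq, NucSequence) else seq.upper()
    rc = reverse_complement(s)
    frames = []
    for template in (s, rc):
        for off in range(3):
            sub = template[off : off + 3 * ((len(template) - off) // 3)]
            frames.append(str(Seq(sub).translate()))
    return frames


# ---------------------------------------------------------------------------
# Canonical k-mer composition
# ---------------------------------------------------------------------------

def canonical_kmers(k: int = 4) -> list[str]:
    """Lexicographically smaller representative of each k-mer/revcomp pair."""
    bases = "ACGT"
    seen: set[str] = set()
    out: list[str] = []
    def gen(prefix: str) -> None:
        if len(prefix) == k:
            canon = min(prefix, reverse_complement(prefix))
            if canon not in seen:
                seen.add(canon)
                out.append(canon)
            return
        for b in bases:
            gen(prefix + b)
    gen("")
    return sorted(out)


_KMER_INDEX_CACHE: dict[int, dict[str, int]] = {}


def _kmer_index(k: int) -> dict[str, int]:
    if k not in _KMER_INDEX_CACHE:
        _KMER_INDEX_CACHE[k] = {km: i for i, km in enumerate(canonical_kmers(k))}
    return _KMER_INDEX_CACHE[k]


def canonical_kmer_counts(
    seq: NucSequence | str, k: int = 4, normalize: bool = True
) -> tuple[np.ndarray, bool]:
    """Strand-canonical k-mer frequency vector.

    Returns ``(vector, empty)`` where ``empty`` flags a sequence too short
    (or too N-rich) to contribute any k-mer. k-mers containing N are skipped;
    the vector is simplex-normalized when anything was counted.
    """
    s = seq.residues if isinstance(seq, NucSequence) else seq.upper()
    index = _kmer_index(k)
    vec = np.zeros(len(index))
    total = 0
    for i in range(len(s) - k + 1):
        km = s[i : i + k]
        if "N" in km:
            continue
        vec[index[min(km, reverse_complement(km))]] += 1
        total += 1
    if total == 0:
        return vec, True
    if normalize:
        vec /= total
    return vec, False


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def gc_content(seq: NucSequence | str) -> Optional[float]:
    """GC fraction over unambiguous bases; ``None`` for an all-N sequence."""
    s = seq.residues if isinstance(seq, NucSequence) else seq.upper()
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    if denom == 0:
        return None
    return gc / denom


def moving_gc(
    seq: NucSequence | str, window: int = 1000, step: Optional[int] = None
) -> list[tuple[int, Optional[float]]]:
    """Moving-window GC: (window start, GC fraction) at step = window/2."""
    s = seq.residues if isinstance(seq, NucSequence) else seq.upper()
    if step is None:
        step = max(1, window // 2)
    out = []
    for start in range(0, max(1, len(s) - window + 1), step):
        out.append((start, gc_content(s[start : start + window])))
    return out


# ---------------------------------------------------------------------------
# Local alignment (Smith-Waterman; blastn / blastx stand-in)
# ---------------------------------------------------------------------------

def _nuc_aligner(match: float, mismatch: float, open_: float, extend: float) -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.match_score = match
    aln.mismatch_score = mismatch
    aln.open_gap_score = open_
    aln.extend_gap_score = extend
    return aln


def _prot_aligner(open_: float, extend: float) -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = open_
    aln.extend_gap_score = extend
    return aln


def _bit_score(raw: float, lam: float, k: float) -> float:
    return (lam * raw - math.log(k)) / math.log(2)


def _result_from_alignment(
    aln, query_id: str, target_id: str, m: int, n: int, lam: float, k: float,
    strand: str = "+", frame: Optional[int] = None,
) -> AlignmentResult:
    counts = aln.counts()
    matches = counts.identities
    aligned_len = counts.identities + counts.mismatches + counts.gaps
    bit = _bit_score(aln.score, lam, k)
    q0, q1 = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
    t0, t1 = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])
    return AlignmentResult(
        query_id=query_id,
        target_id=target_id,
        query_interval=(q0, q1),
        target_interval=(t0, t1),
        strand=strand,
        frame=frame,
        matches=int(matches),
        aligned_len=int(aligned_len),
        raw_score=float(aln.score),
        bit_score=bit,
        evalue=m * n * 2.0 ** (-bit),
    )


def local_align(
    query: NucSequence | str,
    target,
    mode: str = "nucleotide",
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> Optional[AlignmentResult]:
    """Best local alignment of ``query`` against ``target``.

    ``nucleotide``: Smith-Waterman on the given strands (both orientations of
    the query are tried; the better is reported with its strand flag).
    ``translated``: blastx-style — all six query frames against a protein
    target under BLOSUM62 with affine gaps (-11/-1); the best frame wins.
    Query intervals for translated hits are in amino acids within the frame.
    """
    qid = query.id if isinstance(query, NucSequence) else "query"
    qseq = query.residues if isinstance(query, NucSequence) else str(query).upper()
    tid = getattr(target, "id", "target")
    tseq = target.residues if isinstance(target, NucSequence) else str(target).upper()
    if not qseq or not tseq:
        return None

    if mode == "nucleotide":
        lam, k = KA_NUCLEOTIDE
        aligner = _nuc_aligner(match, mismatch, gap_open, gap_extend)
        best: Optional[AlignmentResult] = None
        for strand, qs in (("+", qseq), ("-", reverse_complement(qseq))):
            alns = aligner.align(qs, tseq)
            if not len(alns) or alns.score <= 0:
                continue
            res = _result_from_alignment(
                alns[0], qid, tid, len(qseq), len(tseq), lam, k, strand=strand
            )
            if strand == "-":
                a, b = res.query_interval
                res.query_interval = (len(qseq) - b, len(qseq) - a)
            if best is None or res.raw_score > best.raw_score:
                best = res
        return best

    if mode == "translated":
        lam, k = KA_BLOSUM62
        aligner = _prot_aligner(-11.0, -1.0)
        best = None
        for frame, pep in enumerate(six_frame_translate(qseq)):
            if len(pep) < 1:
                continue
            # stop codons break candidate peptides; align each stop-free run
            offset = 0
            for seg in pep.split("*"):
                if len(seg) >= 4:
                    alns = aligner.align(seg, tseq)
                    if len(alns) and alns.score > 0:
                        res = _result_from_alignment(
                            alns[0], qid, tid, len(seg), len(tseq), lam, k,
                            strand="+" if frame < 3 else "-", frame=frame,
                        )
                        a, b = res.query_interval
                        res.query_interval = (a + offset, b + offset)
                        if best is None or res.raw_score > best.raw_score:
                            best = res
                offset += len(seg) + 1
        return best

    raise ValueError(f"unknown mode {mode!r}")


def alignment_to_tsv(results: Sequence[AlignmentResult]) -> str:
    """BLAST outfmt-6-style TSV (qseqid sseqid pident length ... bitscore evalue)."""
    lines = []
    for r in results:
        mismatches = r.aligned_len - r.matches
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    r.query_id, r.target_id, f"{r.pct_identity:.2f}",
                    r.aligned_len, mismatches, 0,
                    r.query_interval[0] + 1, r.query_interval[1],
                    r.target_interval[0] + 1, r.target_interval[1],
                    f"{r.evalue:.2g}", f"{r.bit_score:.1f}",
                )
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
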