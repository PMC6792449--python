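"""Sequence primitives: I/O round trips, trimming vs an exhaustive-window
oracle, translation vs an independent codon table, canonical k-mer
properties, GC, and local alignment vs a full dynamic-programming oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sortvir.sequence_io import (
    NucSequence,
    canonical_kmer_counts,
    canonical_kmers,
    gc_content,
    local_align,
    moving_gc,
    parse_fastx,
    quality_trim,
    reverse_complement,
    serialize_fastx,
    six_frame_translate,
)

# independent codon lookup for the translation oracle
_CODON = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


def _random_records(rng, n, with_quals):
    bases = np.array(list("ACGT"))
    recs = []
    for i in range(n):
        L = int(rng.integers(1, 120))
        seq = "".join(bases[rng.integers(0, 4, L)])
        quals = tuple(int(q) for q in rng.integers(0, 42, L)) if with_quals else None
        recs.append(NucSequence(f"rec{i}", seq, quals))
    return recs


class TestFastxIO:
    @pytest.mark.parametrize("fmt", ["fasta", "fastq"])
    def test_roundtrip_100_random_records(self, tmp_path, rng, fmt):
        recs = _random_records(rng, 100, with_quals=(fmt == "fastq"))
        path = tmp_path / f"x.{fmt}"
        serialize_fastx(recs, path, fmt)
        assert list(parse_fastx(path, fmt)) == recs

    def test_minimal_fasta_record(self, tmp_path):
        path = tmp_path / "m.fasta"
        path.write_text(">s1\nACGT\n")
        (rec,) = parse_fastx(path, "fasta")
        assert rec.id == "s1" and rec.residues == "ACGT" and rec.quals is None

    def test_multiline_fasta_accepted(self, tmp_path):
        path = tmp_path / "m.fasta"
        path.write_text(">s1\nACGT\nGGCC\n")
        (rec,) = parse_fastx(path, "fasta")
        assert rec.residues == "ACGTGGCC"

    def test_fastq_phred33(self, tmp_path):
        path = tmp_path / "m.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\n")
        (rec,) = parse_fastx(path, "fastq")
        assert rec.quals == (40, 40, 40, 40)

    def test_malformed_fastq_names_position(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nIII\n")
        with pytest.raises(ValueError, match="line"):
            list(parse_fastx(path, "fastq"))

    def test_quality_length_enforced(self):
        with pytest.raises(ValueError, match="quality"):
            NucSequence("x", "ACGT", (40, 40))


class TestQualityTrim:
    @staticmethod
    def _oracle(quals, leading=3, trailing=3, window=25, wq=30.0, min_len=50):
        """Exhaustive reimplementation: scan every window by brute force."""
        q = list(quals)
        start, end = 0, len(q)
        while start < end and q[start] < leading:
            start += 1
        while end > start and q[end - 1] < trailing:
            end -= 1
        for i in range(start, end - window + 1):
            if sum(q[i : i + window]) / window < wq:
                end = i
                break
        if end - start < min_len:
            return None
        return start, end

    def test_clean_read_unchanged(self):
        read = NucSequence("r", "A" * 100, tuple([40] * 100))
        assert quality_trim(read) == read

    def test_hopeless_read_dropped(self):
        read = NucSequence("r", "A" * 100, tuple([2] * 100))
        assert quality_trim(read) is None

    def test_missing_qualities_error(self):
        with pytest.raises(ValueError):
            quality_trim(NucSequence("r", "ACGT"))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(60):
            L = int(rng.integers(10, 200))
            quals = tuple(int(v) for v in rng.integers(0, 42, L))
            read = NucSequence("r", "A" * L, quals)
            got = quality_trim(read)
            expect = self._oracle(quals)
            if expect is None:
                assert got is None
            else:
                s, e = expect
                assert got is not None
                assert got.residues == read.residues[s:e]
                assert got.quals == quals[s:e]

    def test_output_is_contiguous_substring(self, rng):
        for _ in range(50):
            L = int(rng.integers(50, 150))
            quals = tuple(int(v) for v in rng.integers(0, 42, L))
            read = NucSequence("r", "A" * L, quals)
            out = quality_trim(read)
            if out is not None:
                assert out.residues in read.residues


class TestTranslation:
    def test_simple_codons(self):
        assert six_frame_translate(NucSequence("s", "ATGAAA"))[0] == "MK"

    def test_reverse_frames_equal_forward_of_revcomp(self, rng):
        bases = np.array(list("ACGT"))
        s = "".join(bases[rng.integers(0, 4, 99)])
        assert (
            six_frame_translate(s)[3]
            == six_frame_translate(reverse_complement(s))[0]
        )

    def test_all_frames_match_codon_table_oracle(self, rng):
        bases = np.array(list("ACGT"))
        s = "".join(bases[rng.integers(0, 4, 300)])
        frames = six_frame_translate(s)
        for f in range(6):
            template = s if f < 3 else reverse_complement(s)
            off = f % 3
            expected = "".join(
                _CODON[template[i : i + 3]]
                for i in range(off, len(template) - 2, 3)
            )
            assert frames[f] == expected

    def test_n_codons_become_x(self):
        assert six_frame_translate("ATGANA")[0] == "MX"


class TestCanonicalKmers:
    def test_136_canonical_tetramer_classes_brute_force(self):
        bases = "ACGT"
        all_kmers = {
            a + b + c + d for a in bases for b in bases for c in bases for d in bases
        }
        pooled = {min(k, reverse_complement(k)) for k in all_kmers}
        assert len(pooled) == 136
        assert sorted(pooled) == canonical_kmers(4)

    def test_homopolymer_mass_on_one_class(self):
        vec, empty = canonical_kmer_counts("A" * 20, k=4)
        assert not empty
        assert vec.sum() == pytest.approx(1.0)
        assert (vec > 0).sum() == 1

    @settings(max_examples=40, deadline=None)
    @given(dna.filter(lambda s: len(s) >= 4))
    def test_strand_invariance(self, s):
        v1, e1 = canonical_kmer_counts(s)
        v2, e2 = canonical_kmer_counts(reverse_complement(s))
        assert e1 == e2
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    def test_short_sequence_flagged_empty(self):
        vec, empty = canonical_kmer_counts("ACG", k=4)
        assert empty and vec.sum() == 0

    def test_n_kmers_skipped(self):
        vec, empty = canonical_kmer_counts("AAAANAAAA", k=4)
        assert not empty
        assert vec.sum() == pytest.approx(1.0)


class TestGC:
    @pytest.mark.parametrize("seq,expect", [("ATGC", 0.5), ("AAAA", 0.0), ("GGCC", 1.0)])
    def test_known_values(self, seq, expect):
        assert gc_content(seq) == pytest.approx(expect)

    def test_all_n_undefined(self):
        assert gc_content("NNNN") is None

    def test_n_excluded_from_denominator(self):
        assert gc_content("ATNN") == pytest.approx(0.0)
        assert gc_content("GCNN") == pytest.approx(1.0)

    def test_moving_gc_windows(self):
        s = "G" * 1000 + "A" * 1000
        vals = moving_gc(s, window=1000)
        assert vals[0] == (0, 1.0)
        starts = [v[0] for v in vals]
        assert starts == [0, 500, 1000]
        assert vals[-1][1] == 0.0


def _sw_oracle(a, b, match=1.0, mismatch=-2.0, gap_open=-5.0, gap_extend=-2.0):
    """Full Gotoh local-alignment DP (affine gaps), best score only."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestLocalAlign:
    def test_identical_50mers(self, rng):
        bases = np.array(list("ACGT"))
        s = "".join(bases[rng.integers(0, 4, 50)])
        res = local_align(NucSequence("q", s), NucSequence("t", s))
        assert res.pct_identity == pytest.approx(100.0)
        assert res.aligned_len == 50
        assert res.matches == 50

    def test_seven_substitutions_in_1kb_gives_99_3(self, rng):
        bases = np.array(list("ACGT"))
        s = "".join(bases[rng.integers(0, 4, 1000)])
        arr = np.array(list(s))
        # substitutions in the interior so local trimming cannot clip them
        pos = rng.choice(np.arange(20, 980), 7, replace=False)
        for p in pos:
            arr[p] = "ACGT"["ACGT".index(arr[p]) - 1]
        res = local_align(NucSequence("q", s), NucSequence("t", "".join(arr)))
        assert res.pct_identity == pytest.approx(99.3, abs=0.05)

    @pytest.mark.parametrize("seed", range(8))
    def test_score_matches_full_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        a = "".join(bases[rng.integers(0, 4, int(rng.integers(5, 21)))])
        b = "".join(bases[rng.integers(0, 4, int(rng.integers(5, 21)))])
        res = local_align(NucSequence("q", a), NucSequence("t", b))
        expect = max(
            _sw_oracle(a, b), _sw_oracle(reverse_complement(a), b)
        )
        got = 0.0 if res is None else res.raw_score
        assert got == pytest.approx(expect)

    def test_score_symmetric_under_swap(self, rng):
        bases = np.array(list("ACGT"))
        a = "".join(bases[rng.integers(0, 4, 40)])
        b = "".join(bases[rng.integers(0, 4, 40)])
        r1 = local_align(NucSequence("q", a), NucSequence("t", b))
        r2 = local_align(NucSequence("q", b), NucSequence("t", a))
        s1 = 0.0 if r1 is None else r1.raw_score
        s2 = 0.0 if r2 is None else r2.raw_score
        assert s1 == pytest.approx(s2)

    def test_empty_input_no_alignment(self):
        assert local_align(NucSequence("q", ""), NucSequence("t", "ACGT")) is None

    def test_translated_mode_finds_protein(self, rng):
        from sortvir.synthetic_data import _reverse_translate

        prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        cds = _reverse_translate(prot, 0.4, rng)
        res = local_align(NucSequence("q", cds), prot, mode="translated")
        assert res is not None
        assert res.frame == 0
        assert res.pct_identity == pytest.approx(100.0)
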