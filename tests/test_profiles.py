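from collections import Counter

import numpy as np
import pytest

from spacedwords import (
    FrequencyProfile,
    SequenceRecord,
    count_spaced_words,
    detect_alphabet,
    parse_pattern,
    profile_sequences,
    relative_frequencies,
    sample_pattern_set,
    spaced_key,
    table_size_bits,
)

from conftest import random_dna, random_protein


def naive_counts(seq: str, mask: str, alphabet: str):
    """Independent oracle: count match-position substrings by string keys."""
    match_pos = [i for i, c in enumerate(mask) if c == "1"]
    counts = Counter()
    n_windows = 0
    for i in range(len(seq) - len(mask) + 1):
        word = "".join(seq[i + j] for j in match_pos)
        if all(c in alphabet for c in word):
            counts[word] += 1
            n_windows += 1
    return counts, n_windows


class TestCountSpacedWords:
    def test_worked_example(self, rtab):
        rec = SequenceRecord("s", "ACACACA", "dna")
        p = parse_pattern("101")
        prof = count_spaced_words(rec, p, rtab)
        assert prof.n_windows == 5
        counts = prof.count_dict()
        assert counts[spaced_key("AxA".replace("x", "C"), p, rtab)] == 3
        assert counts[spaced_key("CxC".replace("x", "A"), p, rtab)] == 2

    def test_homopolymer(self, rtab):
        prof = count_spaced_words(SequenceRecord("s", "AAAA"), parse_pattern("11"), rtab)
        assert prof.counts.tolist() == [3]
        assert prof.n_windows == 3

    def test_ambiguity_on_dont_care_tolerated(self, rtab):
        prof = count_spaced_words(SequenceRecord("s", "ANA"), parse_pattern("101"), rtab)
        assert prof.n_windows == 1
        assert prof.counts.tolist() == [1]

    def test_ambiguity_on_match_discards(self, rtab):
        prof = count_spaced_words(SequenceRecord("s", "ANA"), parse_pattern("111"), rtab)
        assert prof.n_windows == 0

    def test_strict_mode_discards_any_ambiguity(self, rtab):
        prof = count_spaced_words(
            SequenceRecord("s", "ANA"), parse_pattern("101"), rtab, strict=True
        )
        assert prof.n_windows == 0

    def test_short_sequence_yields_empty_profile(self, rtab):
        prof = count_spaced_words(SequenceRecord("s", "ACG"), parse_pattern("10101"), rtab)
        assert prof.n_windows == 0
        assert prof.keys.size == 0

    @pytest.mark.parametrize(
        "alphabet,maker,masks",
        [
            ("dna", random_dna, ("11", "11111111", "101", "1001010011", "100000001")),
            ("protein", random_protein, ("111", "1101", "101001")),
        ],
    )
    def test_counts_match_naive_oracle(self, rtab, rng, alphabet, maker, masks):
        letters = "ACGT" if alphabet == "dna" else "ACDEFGHIKLMNPQRSTVWY"
        seq = maker(rng, 1000)
        # sprinkle ambiguity characters
        chars = list(seq)
        for i in rng.choice(len(chars), size=10, replace=False):
            chars[i] = "N" if alphabet == "dna" else "X"
        seq = "".join(chars)
        rec = SequenceRecord("s", seq, alphabet)
        for mask in masks:
            p = parse_pattern(mask)
            prof = count_spaced_words(rec, p, rtab)
            expected, n_windows = naive_counts(seq, mask, letters)
            assert prof.n_windows == n_windows
            got = prof.count_dict()
            assert len(got) == len(expected)
            for word, count in expected.items():
                # embed the word in a window to recompute its key
                window = list(mask)
                it = iter(word)
                for j, c in enumerate(mask):
                    window[j] = next(it) if c == "1" else "A"
                assert got[spaced_key("".join(window), p, rtab)] == count

    def test_distinct_keys_bounded(self, rtab, rng):
        rec = SequenceRecord("s", random_dna(rng, 500), "dna")
        for mask in ("11", "111"):
            prof = count_spaced_words(rec, parse_pattern(mask), rtab)
            assert prof.keys.size <= min(4 ** mask.count("1"), 500 - len(mask) + 1)


class TestCanonicalStrand:
    def test_profiles_strand_symmetric(self, rtab, rng):
        comp = str.maketrans("ACGT", "TGCA")
        seq = random_dna(rng, 400)
        rc = seq.translate(comp)[::-1]
        for mask in ("11111", "1101", "100101"):
            p = parse_pattern(mask)
            a = count_spaced_words(SequenceRecord("f", seq), p, rtab, canonical=True)
            b = count_spaced_words(SequenceRecord("r", rc), p, rtab, canonical=True)
            assert (a.keys == b.keys).all()
            assert (a.counts == b.counts).all()

    def test_rejected_for_protein(self, rtab):
        rec = SequenceRecord("p", "MKVLWWRNDEK", "protein")
        with pytest.raises(ValueError, match="DNA"):
            count_spaced_words(rec, parse_pattern("11"), rtab, canonical=True)


class TestRelativeFrequencies:
    def test_normalizes(self):
        assert relative_frequencies({1: 3, 2: 2}, 5) == {1: 0.6, 2: 0.4}

    def test_single_word(self):
        assert relative_frequencies({9: 4}, 4) == {9: 1.0}

    def test_zero_windows(self):
        assert relative_frequencies({}, 0) == {}

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            relative_frequencies({1: -1}, 1)
        with pytest.raises(ValueError):
            relative_frequencies({1: 1}, -1)

    def test_profile_frequencies_sum_to_one(self, rtab, rng):
        rec = SequenceRecord("s", random_dna(rng, 400), "dna")
        prof = count_spaced_words(rec, parse_pattern("10011"), rtab)
        assert prof.frequencies.sum() == pytest.approx(1.0, abs=1e-9)


class TestProfileSequences:
    def test_workers_do_not_change_result(self, rtab, rng):
        seqs = [SequenceRecord(f"s{i}", random_dna(rng, 300)) for i in range(4)]
        pats = sample_pattern_set(5, (6, 12), 6, seed=0)
        serial = profile_sequences(seqs, pats, rtab, workers=1)
        parallel = profile_sequences(seqs, pats, rtab, workers=8)
        for row_a, row_b in zip(serial, parallel):
            for a, b in zip(row_a, row_b):
                assert (a.keys == b.keys).all()
                assert (a.counts == b.counts).all()
                assert a.n_windows == b.n_windows

    def test_mixed_alphabets_rejected(self, rtab):
        seqs = [SequenceRecord("a", "ACGT", "dna"), SequenceRecord("b", "MKV", "protein")]
        with pytest.raises(ValueError, match="alphabet"):
            profile_sequences(seqs, [parse_pattern("11")], rtab)

    def test_case_folded_on_ingest(self, rtab):
        low = SequenceRecord("a", "acgtacgt")
        up = SequenceRecord("a", "ACGTACGT")
        pa = count_spaced_words(low, parse_pattern("101"), rtab)
        pb = count_spaced_words(up, parse_pattern("101"), rtab)
        assert (pa.keys == pb.keys).all() and (pa.counts == pb.counts).all()


class TestTableSizing:
    @pytest.mark.parametrize(
        "n,l,k,a,expected",
        [
            (16000, 8, 8, 4, 14),   # n-l+1 = 15993 -> 2^14
            (100, 3, 2, 4, 4),      # alphabet bound 16 < 98 windows
            (10, 5, 3, 4, 3),       # 6 windows -> 2^3
            (2, 2, 2, 4, 0),        # single window
        ],
    )
    def test_smallest_power_of_two(self, n, l, k, a, expected):
        b = table_size_bits(n, l, k, a)
        bound = min(a**k, n - l + 1)
        assert b == expected
        assert 2**b >= bound and (b == 0 or 2 ** (b - 1) < bound)

    def test_invalid(self):
        with pytest.raises(ValueError):
            table_size_bits(0, 2, 2, 4)


def test_detect_alphabet():
    assert detect_alphabet("ACGTACGTNNAC") == "dna"
    assert detect_alphabet("MKVLITAGPTREPLD") == "protein"


def test_profile_tsv_export(tmp_path, rtab):
    prof = count_spaced_words(SequenceRecord("s", "ACACACA"), parse_pattern("101"), rtab)
    path = tmp_path / "prof.tsv"
    prof.to_tsv(path)
    lines = path.read_text().splitlines()
    assert lines[0] == "key\tcount\tfrequency"
    assert len(lines) == 3
    counts = {int(f[0], 16): int(f[1]) for f in (l.split("\t") for l in lines[1:])}
    assert counts == prof.count_dict()
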