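"""Window extraction, labeling, identity screening, benchmark assembly."""

import pytest
from hypothesis import given, settings, strategies as st

from carbonsite.alphabet import AA20
from carbonsite.errors import DataValidationError
from carbonsite.seq_io import ProteinRecord, SiteAnnotation
from carbonsite.windows import (
    PeptideWindow,
    SampleSet,
    WindowConfig,
    build_benchmark,
    extract_windows,
    label_windows,
    pairwise_identity,
    redundancy_filter,
)
from conftest import make_benchmark


def window(residues, center="K", pid="p", pos=1, label="unlabeled"):
    return PeptideWindow(residues=residues, center_type=center,
                         protein_id=pid, center_position=pos, label=label)


K_CONFIG = WindowConfig(xi=7, center_type="K")


class TestExtractWindows:
    def test_exact_fit_no_padding(self):
        protein = ProteinRecord("p1", "AAAAAAAKAAAAAAA")
        (w,) = extract_windows(protein, K_CONFIG)
        assert w.residues == protein.sequence
        assert w.center_position == 8
        assert "X" not in w.residues

    def test_terminal_center_padded_both_sides(self):
        (w,) = extract_windows(ProteinRecord("p1", "KAA"), K_CONFIG)
        assert w.residues == "XXXXXXXKAAXXXXX"
        assert w.center_position == 1

    def test_one_window_per_center_occurrence(self):
        protein = ProteinRecord("p1", "KAKAK")
        windows = extract_windows(protein, K_CONFIG)
        assert [w.center_position for w in windows] == [1, 3, 5]

    def test_no_center_residue_yields_empty(self):
        assert extract_windows(ProteinRecord("p1", "AAAA"), K_CONFIG) == []

    def test_all_windows_have_center_and_length(self, small_benchmark):
        xi = small_benchmark.xi
        for w in small_benchmark.positives + small_benchmark.negatives:
            assert len(w.residues) == 2 * xi + 1 == 15
            assert w.residues[xi] == small_benchmark.center_type


@settings(max_examples=60, derandomize=True)
@given(st.text(alphabet=AA20, min_size=1, max_size=40), st.integers(1, 10))
def test_padding_count_matches_terminal_deficit(sequence, xi):
    """The number of X's in a window equals the combined shortfall of the
    two flanks against the sequence termini."""
    protein = ProteinRecord("p", sequence)
    config = WindowConfig(xi=xi, center_type="K")
    L = protein.length
    for w in extract_windows(protein, config):
        pos = w.center_position
        expected = max(0, xi - (pos - 1)) + max(0, xi - (L - pos))
        assert w.residues.count("X") == expected


class TestLabelWindows:
    def test_positive_annotation_marks_matching_center(self):
        protein = ProteinRecord("p1", "AK" + "A" * 5 + "K" + "A" * 5 + "KA")
        windows = extract_windows(protein, K_CONFIG)
        assert [w.center_position for w in windows] == [2, 8, 14]
        labeled = label_windows(
            windows, [SiteAnnotation("p1", 8, "K", "positive")]
        )
        assert [w.label for w in labeled] == ["negative", "positive",
                                              "negative"]

    def test_no_annotations_all_negative(self):
        windows = extract_windows(ProteinRecord("p1", "KAK"), K_CONFIG)
        assert all(w.label == "negative" for w in label_windows(windows, []))

    def test_orphan_positive_annotation_is_error(self):
        windows = extract_windows(ProteinRecord("p1", "KAK"), K_CONFIG)
        with pytest.raises(DataValidationError, match="no matching"):
            label_windows(windows, [SiteAnnotation("p1", 2, "K", "positive")])


class TestPairwiseIdentity:
    A = window("AAAAAAAKAAAAAAA")
    B = window("CCCCAAAKAAACCCC")

    def test_identity_of_identical_windows(self):
        assert pairwise_identity(self.A, self.A) == 1.0

    def test_only_center_shared(self):
        other = window("CCCCCCCKCCCCCCC")
        assert pairwise_identity(self.A, other) == pytest.approx(1 / 15)

    def test_partial_match(self):
        # matching columns: 3 upstream A's, the K center, 3 downstream A's
        assert pairwise_identity(self.A, self.B) == pytest.approx(7 / 15)

    def test_x_matches_only_x(self):
        padded = window("XXXXXXXKAAXXXXX")
        assert pairwise_identity(padded, padded) == 1.0
        assert pairwise_identity(padded, self.A) == pytest.approx(3 / 15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            pairwise_identity(self.A, window("AKA", pos=2))


class TestRedundancyFilter:
    def test_exact_duplicate_dropped(self):
        a, b = window("AAAAAAAKAAAAAAA"), window("AAAAAAAKAAAAAAA", pos=2)
        assert redundancy_filter([a, b], 0.30) == [a]

    def test_threshold_one_keeps_all_distinct(self):
        a = window("AAAAAAAKAAAAAAA")
        b = window("CAAAAAAKAAAAAAA")
        assert redundancy_filter([a, b], 1.0) == [a, b]

    def test_greedy_keep_first(self):
        a = window("AAAAAAAKAAAAAAA")
        b = window("CCCCAAAKAAACCCC")  # identity with a: 7/15 >= 0.30
        c = window("CCCCCCCKCCCCCCC")  # identity with a: 1/15 < 0.30
        assert redundancy_filter([a, b, c], 0.30) == [a, c]

    def test_output_is_a_fixed_point(self, small_benchmark):
        kept = redundancy_filter(small_benchmark.negatives, 0.30)
        assert redundancy_filter(kept, 0.30) == kept

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            redundancy_filter([], 0.0)


class TestBuildBenchmark:
    def test_single_positive(self):
        protein = ProteinRecord("p1", "AKAAAKA")
        anns = [SiteAnnotation("p1", 2, "K", "positive")]
        config = WindowConfig(filter_enabled=False)
        bench = build_benchmark([protein], anns, config)
        assert bench.n_positive == 1 and bench.n_negative == 1

    def test_generator_bookkeeping(self, small_benchmark):
        """With the filter disabled, positives equal the generator's
        planted-site count exactly."""
        from carbonsite import GeneratorSpec, effect_preset, generate_corpus

        spec = GeneratorSpec(n_proteins=30, site_rate=0.4,
                             effect=effect_preset("strong"), seed=7)
        _, annotations, _ = generate_corpus(spec)
        planted = sum(a.label == "positive" for a in annotations)
        assert small_benchmark.n_positive == planted

    def test_filter_never_grows_subsets(self):
        unfiltered = make_benchmark(20, 0.4, "strong", seed=3)
        from carbonsite import GeneratorSpec, effect_preset, generate_corpus

        spec = GeneratorSpec(n_proteins=20, site_rate=0.4,
                             effect=effect_preset("strong"), seed=3)
        proteins, annotations, _ = generate_corpus(spec)
        filtered = build_benchmark(
            proteins, annotations,
            WindowConfig(identity_threshold=0.30, filter_enabled=True),
        )
        assert filtered.n_positive <= unfiltered.n_positive
        assert filtered.n_negative <= unfiltered.n_negative

    def test_empty_positive_subset_is_error(self):
        protein = ProteinRecord("p1", "AKAAAKA")
        with pytest.raises(DataValidationError, match="no positive"):
            build_benchmark([protein], [], WindowConfig(filter_enabled=False))


class TestSampleSetIO:
    def test_tsv_round_trip(self, tmp_path, small_benchmark):
        path = tmp_path / "bench.tsv"
        small_benchmark.write_tsv(path)
        loaded = SampleSet.read_tsv(path)
        assert loaded.center_type == small_benchmark.center_type
        assert loaded.positives == small_benchmark.positives
        assert loaded.negatives == small_benchmark.negatives

    def test_subsets_disjoint_by_site(self, small_benchmark):
        pos = {w.key for w in small_benchmark.positives}
        neg = {w.key for w in small_benchmark.negatives}
        assert not pos & neg
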