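"""Sequence-coupled conditional-probability tables and window encoding."""

from collections import Counter, defaultdict

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carbonsite.alphabet import ALPHABET, index_of
from carbonsite.coupling import (
    CouplingModel,
    encode,
    encode_many,
    fit_coupling_model,
    fit_profile,
    flank_positions,
)
from carbonsite.errors import SelfConsistencyError
from carbonsite.windows import PeptideWindow, SampleSet


def window(residues, center="K", pid="p", pos=1, label="positive"):
    return PeptideWindow(residues=residues, center_type=center,
                         protein_id=pid, center_position=pos, label=label)


def make_set(pos_seqs, neg_seqs):
    return SampleSet(
        center_type="K", xi=len(pos_seqs[0]) // 2,
        positives=[window(s, pid=f"pp{i}", pos=i + 1, label="positive")
                   for i, s in enumerate(pos_seqs)],
        negatives=[window(s, pid=f"nn{i}", pos=i + 1, label="negative")
                   for i, s in enumerate(neg_seqs)],
    )


class TestFitProfile:
    def test_hand_counted_pair_frequencies(self):
        profile = fit_profile([window("AAAAAAAKAAAAAAA"),
                               window("CAAAAAAKAAAAAAA", pos=2)])
        # position -7 is A once and C once, both with neighbor A at -6
        assert profile.probability(-7, "A", "A") == pytest.approx(0.5)
        assert profile.probability(-7, "C", "A") == pytest.approx(0.5)
        assert profile.probability(-6, "A", "A") == pytest.approx(1.0)
        assert profile.probability(-1, "A", None) == pytest.approx(1.0)

    def test_single_sample_degenerate_mle(self):
        profile = fit_profile([window("AAAAAAAKAAAAAAA")])
        for pos in profile.positions:
            if pos in (-1, 1):
                assert profile.marginal[pos][index_of("A")] == 1.0
            else:
                assert profile.conditional[pos][index_of("A"),
                                                index_of("A")] == 1.0

    def test_smoothing_makes_rows_positive_and_stochastic(self):
        profile = fit_profile([window("AAAAAAAKAAAAAAA")], alpha=0.5)
        for pos in profile.positions:
            if pos in (-1, 1):
                assert np.all(profile.marginal[pos] > 0)
                assert profile.marginal[pos].sum() == pytest.approx(1.0)
            else:
                table = profile.conditional[pos]
                assert np.all(table > 0)
                assert np.allclose(table.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_profile([])

    def test_rows_with_support_are_stochastic(self, small_benchmark):
        profile = fit_profile(small_benchmark.negatives)
        for pos in profile.positions:
            if pos in (-1, 1):
                assert profile.marginal[pos].sum() == pytest.approx(1.0)
                continue
            table = profile.conditional[pos]
            supported = profile.support[pos]
            assert np.allclose(table[supported].sum(axis=1), 1.0, atol=1e-9)
            assert np.all(table[~supported] == 0.0)


def _oracle_profile(windows_, xi):
    """Brute-force dictionary counting of the same probabilities."""
    pair_counts = defaultdict(Counter)   # (pos, b) -> Counter of a
    marg_counts = defaultdict(Counter)   # pos -> Counter of a
    for w in windows_:
        for pos in flank_positions(xi):
            a = w.residues[pos + xi]
            marg_counts[pos][a] += 1
            if pos in (-1, 1):
                continue
            nb = pos + 1 if pos < 0 else pos - 1
            pair_counts[(pos, w.residues[nb + xi])][a] += 1

    def conditional(pos, a, b):
        counter = pair_counts[(pos, b)]
        total = sum(counter.values())
        return counter[a] / total if total else None

    def marginal(pos, a):
        return marg_counts[pos][a] / len(windows_)

    return conditional, marginal


@settings(max_examples=100, derandomize=True)
@given(st.data())
def test_profile_matches_counting_oracle(data):
    """Vectorized estimation equals naive dictionary counting on random
    small sample sets."""
    xi = data.draw(st.integers(2, 4))
    flank = st.text(alphabet=ALPHABET, min_size=xi, max_size=xi)
    n = data.draw(st.integers(1, 8))
    windows_ = [
        window(data.draw(flank) + "K" + data.draw(flank), pos=i + 1)
        for i in range(n)
    ]
    profile = fit_profile(windows_)
    cond_oracle, marg_oracle = _oracle_profile(windows_, xi)
    for pos in flank_positions(xi):
        for a in ALPHABET:
            assert profile.marginal[pos][index_of(a)] == pytest.approx(
                marg_oracle(pos, a), abs=1e-12)
            if pos in (-1, 1):
                continue
            for b in ALPHABET:
                expected = cond_oracle(pos, a, b)
                if expected is None:
                    assert not profile.support[pos][index_of(b)]
                else:
                    got = profile.conditional[pos][index_of(b), index_of(a)]
                    assert got == pytest.approx(expected, abs=1e-12)


class TestEncode:
    def test_fourteen_components_for_default_flank(self, small_benchmark):
        model = fit_coupling_model(small_benchmark)
        vec = encode(small_benchmark.positives[0], model)
        assert vec.shape == (14,)
        assert np.all(vec >= -1.0) and np.all(vec <= 1.0)

    def test_antisymmetry_under_class_swap(self, small_benchmark):
        model = fit_coupling_model(small_benchmark)
        swapped = CouplingModel(
            positive_profile=model.negative_profile,
            negative_profile=model.positive_profile,
            center_type=model.center_type, xi=model.xi,
        )
        for w in small_benchmark.positives[:5] + small_benchmark.negatives[:5]:
            assert np.array_equal(encode(w, swapped), -encode(w, model))

    def test_identical_subsets_encode_to_zero(self):
        seqs = ["AAAAAAAKAAAAAAA", "CADEFGHKACDEFGH"]
        model = fit_coupling_model(make_set(seqs, seqs))
        probe = window("CADEFGHKACDEFGH")
        assert np.allclose(encode(probe, model), 0.0)

    def test_unseen_everything_with_zero_fallback(self):
        model = fit_coupling_model(
            make_set(["AAAAAAAKAAAAAAA"], ["AAAAAAAKAAAAAAA"]),
            fallback_policy="zero",
        )
        probe = window("CCCCCCCKCCCCCCC")
        assert np.array_equal(encode(probe, model), np.zeros(14))

    def test_encode_is_deterministic(self, small_benchmark):
        model = fit_coupling_model(small_benchmark)
        w = small_benchmark.negatives[0]
        assert np.array_equal(encode(w, model), encode(w, model))

    def test_center_type_mismatch_rejected(self, small_benchmark):
        model = fit_coupling_model(small_benchmark)
        probe = window("AAAAAAAPAAAAAAA", center="P")
        with pytest.raises(SelfConsistencyError):
            encode(probe, model)

    def test_marginal_fallback_uses_positional_marginal(self):
        # conditioning residue W never observed at position -1
        model = fit_coupling_model(
            make_set(["AAAAAAAKAAAAAAA"], ["CCCCCCCKCCCCCCC"])
        )
        # W at position -1; the lookup at -2 conditions on that W
        probe = window("AAAAAAWK" + "AAAAAAA")
        vec_marginal = encode(probe, model, fallback_policy="marginal")
        vec_zero = encode(probe, model, fallback_policy="zero")
        pos_index = 5  # position -2 in the -7..-1,+1..+7 ordering
        assert vec_zero[pos_index] == 0.0
        # marginal fallback: p(-2 = A) is 1 in positives, 0 in negatives
        assert vec_marginal[pos_index] == pytest.approx(1.0)


class TestSeparation:
    def test_planted_signal_separates_class_means(self, strong_benchmark):
        """Windows of the positive class score higher under the fitted
        model than negative windows, summed over components."""
        model = fit_coupling_model(strong_benchmark)
        pos_sum = encode_many(strong_benchmark.positives, model).sum(axis=1)
        neg_sum = encode_many(strong_benchmark.negatives, model).sum(axis=1)
        assert pos_sum.mean() > neg_sum.mean()

    def test_enrichment_grows_with_effect_size(self):
        """The positive/negative probability gap at a boosted position
        grows with the generator's boost."""
        from conftest import make_benchmark

        gaps = []
        for strength in ("none", "weak", "strong"):
            bench = make_benchmark(40, 0.4, strength, seed=5)
            model = fit_coupling_model(bench)
            # motif residue E at position -1 (unconditional)
            gap = (model.positive_profile.marginal[-1][index_of("E")]
                   - model.negative_profile.marginal[-1][index_of("E")])
            gaps.append(gap)
        assert gaps[0] < gaps[1] < gaps[2]


class TestSerialization:
    def test_json_round_trip_preserves_encoding(self, tmp_path,
                                                small_benchmark):
        model = fit_coupling_model(small_benchmark, alpha=0.1)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = CouplingModel.from_json(path)
        assert loaded.alpha == model.alpha
        assert loaded.fallback_policy == model.fallback_policy
        for w in small_benchmark.positives[:3]:
            assert np.array_equal(encode(w, loaded), encode(w, model))

    def test_version_mismatch_refused(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"format_version": 99}')
        with pytest.raises(ValueError, match="format version"):
            CouplingModel.from_json(path)
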