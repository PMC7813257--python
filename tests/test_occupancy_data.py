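"""Occupancy ingestion, segmentation, state encoding and empirical statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinocc import (
    MomentSet,
    OccupancySignal,
    TrialWindow,
    decode_state,
    empirical_distribution,
    empirical_moments,
    encode_states,
    pair_indices,
    read_occupancy,
    segment_trials,
    stationary_slice,
    write_occupancy,
)


class TestReadOccupancy:
    def test_per_node_files(self, tmp_path):
        for i, col in enumerate([[0, 1, 1], [1, 0, 1]]):
            (tmp_path / f"node{i}.txt").write_text("\n".join(map(str, col)))
        sig = read_occupancy([tmp_path / "node0.txt", tmp_path / "node1.txt"])
        assert sig.n_frames == 3 and sig.n_nodes == 2
        np.testing.assert_array_equal(sig.values, [[0, 1], [1, 0], [1, 1]])
        assert sig.provenance["layout"] == "per-node-files"

    def test_matrix_file(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 0\n1 0\n")
        sig = read_occupancy([p], layout="matrix-file")
        assert sig.n_frames == 2 and sig.n_nodes == 2
        np.testing.assert_array_equal(sig.values, [[0, 0], [1, 0]])

    def test_matrix_file_with_header_and_commas(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("a,b\n0,1\n1,1\n")
        sig = read_occupancy([p], layout="matrix-file")
        assert sig.node_labels == ["a", "b"]
        np.testing.assert_array_equal(sig.values, [[0, 1], [1, 1]])

    @pytest.mark.parametrize(
        "contents, match",
        [("2\n", "non-binary"), ("", "empty"), ("0 x 1", "non-")],
    )
    def test_bad_tokens(self, tmp_path, contents, match):
        p = tmp_path / "bad.txt"
        p.write_text(contents)
        with pytest.raises(ValueError, match=match):
            read_occupancy([p])

    def test_mismatched_lengths(self, tmp_path):
        (tmp_path / "a.txt").write_text("0 1 0")
        (tmp_path / "b.txt").write_text("0 1")
        with pytest.raises(ValueError, match="mismatched"):
            read_occupancy([tmp_path / "a.txt", tmp_path / "b.txt"])

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_occupancy([tmp_path / "nope.txt"])

    def test_write_read_round_trip(self, tmp_path, rng):
        sig = OccupancySignal(rng.integers(0, 2, size=(30, 3)))
        for layout in ("per-node-files", "matrix-file"):
            files = write_occupancy(sig, tmp_path / layout, layout=layout)
            back = read_occupancy(files, layout=layout)
            np.testing.assert_array_equal(back.values, sig.values)


class TestSegmentation:
    def test_study_geometry(self):
        sig = OccupancySignal(np.zeros((135_000, 2)))
        wins = segment_trials(sig, trial_length=5400, regime_split_day=13)
        assert len(wins) == 25
        assert sum(w.regime == "A" for w in wins) == 13
        assert sum(w.regime == "B" for w in wins) == 12

    def test_two_trials(self):
        sig = OccupancySignal(np.zeros((10, 1)))
        assert len(segment_trials(sig, trial_length=5)) == 2

    def test_non_divisible_reports_remainder(self):
        sig = OccupancySignal(np.zeros((11, 1)))
        with pytest.raises(ValueError, match="remainder 1"):
            segment_trials(sig, trial_length=5)

    def test_stationary_slice(self):
        w = TrialWindow(0, 0, 5400, "A")
        s = stationary_slice(w, 2700, 5400, frame_period=1.0)
        assert (s.start, s.end) == (2700, 5400)
        assert s.regime == "A"

    def test_stationary_slice_identity_and_errors(self):
        w = TrialWindow(0, 0, 100)
        s = stationary_slice(w, 0, 100)
        assert (s.start, s.end) == (0, 100)
        with pytest.raises(ValueError):
            stationary_slice(w, 5400, 2700)
        with pytest.raises(ValueError, match="beyond"):
            stationary_slice(w, 0, 200)


class TestStateEncoding:
    def test_all_empty_is_zero(self):
        assert encode_states(np.zeros((1, 8), dtype=int))[0] == 0

    def test_node_one_is_lsb(self):
        occ = np.zeros((1, 8), dtype=int)
        occ[0, 0] = 1
        assert encode_states(occ)[0] == 1

    def test_codes_in_range_n8(self, rng):
        codes = encode_states(rng.integers(0, 2, size=(1000, 8)))
        assert codes.min() >= 0 and codes.max() < 256

    @settings(deadline=None, derandomize=True)
    @given(n=st.integers(1, 12))
    def test_encode_decode_round_trip_all_codes(self, n):
        codes = np.arange(2**n)
        assert np.array_equal(encode_states(decode_state(codes, n)), codes)


class TestEmpiricalStatistics:
    def test_single_node_distribution(self):
        dist = empirical_distribution(np.array([0, 0, 1, 1]), n_nodes=1)
        np.testing.assert_allclose(dist.probs, [0.5, 0.5])

    def test_point_mass(self):
        dist = empirical_distribution(np.full(10, 5), n_nodes=3)
        assert dist.probs[5] == 1.0 and dist.probs.sum() == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            empirical_distribution(np.array([], dtype=int), n_nodes=2)

    def test_uniform_draw_within_multinomial_error(self, rng):
        n_frames = 1_000_000
        codes = rng.integers(0, 8, size=n_frames)
        dist = empirical_distribution(codes, n_nodes=3)
        sigma = np.sqrt((1 / 8) * (7 / 8) / n_frames)
        assert np.abs(dist.probs - 1 / 8).max() < 3 * sigma

    def test_constant_occupied_moments(self):
        sig = OccupancySignal(np.ones((5, 3)))
        m = empirical_moments(sig)
        np.testing.assert_allclose(m.occ_means, 1.0)
        np.testing.assert_allclose(m.occ_pairs, 1.0)
        np.testing.assert_allclose(m.spin_means, 1.0)
        np.testing.assert_allclose(m.spin_pairs, 1.0)

    def test_anti_synchronized_pair(self):
        sig = OccupancySignal(np.array([[0, 1], [1, 0]] * 5))
        m = empirical_moments(sig)
        assert m.occ_pairs[0] == 0.0
        assert m.spin_pairs[0] == pytest.approx(-1.0)

    def test_toy_matrix_hand_computation(self):
        # frames: (1,0), (1,1), (0,1), (1,1)
        sig = OccupancySignal(np.array([[1, 0], [1, 1], [0, 1], [1, 1]]))
        m = empirical_moments(sig)
        np.testing.assert_allclose(m.occ_means, [3 / 4, 3 / 4])
        np.testing.assert_allclose(m.occ_pairs, [2 / 4])
        np.testing.assert_allclose(m.spin_means, [1 / 2, 1 / 2])
        # spins: (+,-),(+,+),(-,+),(+,+) -> products -1,1,-1,1
        np.testing.assert_allclose(m.spin_pairs, [0.0])

    def test_marginals_match_moments(self, rng):
        sig = OccupancySignal(rng.integers(0, 2, size=(500, 4)))
        dist = empirical_distribution(encode_states(sig.values), 4)
        m = empirical_moments(sig)
        np.testing.assert_allclose(dist.occupancy_marginals(), m.occ_means,
                                   atol=1e-12)

    def test_relabeling_equivariance(self, rng):
        values = rng.integers(0, 2, size=(200, 4))
        perm = np.array([2, 0, 3, 1])
        m = empirical_moments(OccupancySignal(values))
        mp = empirical_moments(OccupancySignal(values[:, perm]))
        np.testing.assert_allclose(mp.occ_means, m.occ_means[perm])
        pairs = pair_indices(4)
        orig_lookup = {pair: k for k, pair in enumerate(pairs)}
        for k, (i, j) in enumerate(pairs):
            # permuted column i holds original node perm[i]
            orig_k = orig_lookup[tuple(sorted((perm[i], perm[j])))]
            assert mp.occ_pairs[k] == pytest.approx(m.occ_pairs[orig_k])


class TestMomentSetConsistency:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_affine_map_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        occ = rng.integers(0, 2, size=(50, 3))
        m = MomentSet.from_occupancy_frames(occ)
        m2 = MomentSet.from_spin(m.spin_means, m.spin_pairs)
        np.testing.assert_allclose(m2.occ_means, m.occ_means, atol=1e-12)
        np.testing.assert_allclose(m2.occ_pairs, m.occ_pairs, atol=1e-12)

    def test_inconsistent_bases_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            MomentSet(spin_means=np.array([0.5]), spin_pairs=np.empty(0),
                      occ_means=np.array([0.5]), occ_pairs=np.empty(0))
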