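import numpy as np
import pytest

from gaitid.cycles import GaitCycle, extract_cycles
from gaitid.siamese import (
    LAMBDA_JOINTS,
    LambdaSequence,
    build_lambda,
    identify,
    make_pairs,
    similarity,
    train_malstm,
    verification_accuracy,
)
from gaitid.skeleton import H36M_JOINTS, JointSequence3D, h36m_column


def _static_cycle(n_frames=60):
    pos = np.zeros((n_frames, len(H36M_JOINTS), 3))
    for c in range(len(H36M_JOINTS)):
        pos[:, c, :] = [c * 0.1, -c * 0.05, c * 0.02]
    seq = JointSequence3D(positions=pos, fps=125.0, subject_id="S")
    pt = dict(zip(("ta", "tb", "tc", "td", "te", "tf", "tg", "th"),
                  np.linspace(0, n_frames - 1, 8)))
    return GaitCycle(source=seq, phase_times=pt, cycle_index=0)


def _random_sequences(rng, n_subjects=4, n_cycles=4, length=50, spread=1.0):
    out = []
    for s in range(n_subjects):
        center = rng.normal(0.0, spread, 18)
        for c in range(n_cycles):
            steps = center + rng.normal(0.0, 0.05, (length, 18))
            out.append(LambdaSequence(steps=steps, subject_id=f"S{s}", cycle_index=c))
    return out


class TestBuildLambda:
    def test_component_order_matches_joint_list(self, default_walk):
        seq, _ = default_walk
        cycle = extract_cycles(seq)[0]
        lam = build_lambda(cycle, length=None)
        frame = int(np.ceil(cycle.ta))
        root = seq.positions  # interpolated source inside the cycle
        src = cycle.source
        expected = []
        r = src.positions[frame, h36m_column(0)]
        for j in LAMBDA_JOINTS:
            expected.extend(src.positions[frame, h36m_column(j)] - r)
        assert np.allclose(lam.steps[0], expected, atol=1e-12)

    def test_native_length_cycle_is_identity_resample(self, default_walk):
        seq, _ = default_walk
        cycle = extract_cycles(seq)[0]
        native = build_lambda(cycle, length=None)
        resampled = build_lambda(cycle, length=len(native))
        assert np.allclose(native.steps, resampled.steps, atol=1e-12)

    def test_stationary_pose_gives_identical_steps(self):
        lam = build_lambda(_static_cycle(), length=50)
        assert np.allclose(lam.steps, lam.steps[0])

    def test_mirror_symmetry(self, default_walk):
        # x-mirror with left/right joints swapped reproduces the original
        # with block order swapped and x components negated
        seq, _ = default_walk
        swap = {1: 6, 2: 7, 3: 8, 6: 1, 7: 2, 8: 3,
                17: 25, 18: 26, 19: 27, 25: 17, 26: 18, 27: 19}
        mirrored = seq.positions.copy()
        for a, b in swap.items():
            mirrored[:, h36m_column(a), :] = seq.positions[:, h36m_column(b), :]
        mirrored[:, :, 0] *= -1.0
        mseq = seq.with_positions(mirrored)

        cycle = extract_cycles(seq)[0]
        mcycles = extract_cycles(mseq)
        lam = build_lambda(cycle)
        mlam = build_lambda(mcycles[0])
        # joints (8,7,6,3,2,1) <-> swapped is (3,2,1,8,7,6): swap the two 9-blocks
        swapped = np.concatenate([lam.steps[:, 9:], lam.steps[:, :9]], axis=1)
        swapped[:, 0::3] *= -1.0
        assert np.allclose(mlam.steps, swapped, atol=1e-9)


class TestMakePairs:
    def test_balance_and_no_self_pairs(self, rng):
        seqs = _random_sequences(rng, n_subjects=2, n_cycles=2)
        ps = make_pairs(seqs, n_pairs=4, seed=0)
        assert int(ps.labels.sum()) == 2
        for l, r, y in zip(ps.left, ps.right, ps.labels):
            assert not (l.subject_id == r.subject_id and l.cycle_index == r.cycle_index)
            if y == 1.0:
                assert l.subject_id == r.subject_id

    def test_deterministic_given_seed(self, rng):
        seqs = _random_sequences(rng)
        a = make_pairs(seqs, n_pairs=20, seed=5)
        b = make_pairs(seqs, n_pairs=20, seed=5)
        assert np.array_equal(a.labels, b.labels)
        for x, y in zip(a.left, b.left):
            assert x.subject_id == y.subject_id and x.cycle_index == y.cycle_index

    def test_single_subject_rejected(self, rng):
        seqs = _random_sequences(rng, n_subjects=1)
        with pytest.raises(ValueError, match="2 subjects"):
            make_pairs(seqs, n_pairs=4, seed=0)


@pytest.fixture(scope="module")
def trained_toy_model():
    rng = np.random.default_rng(0)
    seqs = _random_sequences(rng, n_subjects=4, n_cycles=6, spread=1.0)
    pairs = make_pairs(seqs, n_pairs=400, seed=1)
    model = train_malstm(pairs, config={"batch_size": 64, "epochs": 10}, seed=1)
    return model, seqs, pairs


class TestTrainMalstm:
    def test_identical_twins_have_similarity_one(self, trained_toy_model):
        model, seqs, _ = trained_toy_model
        assert similarity(model, seqs[0], seqs[0]) == 1.0

    def test_similarity_symmetric_and_in_range(self, trained_toy_model, rng):
        model, seqs, _ = trained_toy_model
        for _ in range(5):
            i, j = rng.integers(len(seqs), size=2)
            s_ij = similarity(model, seqs[i], seqs[j])
            s_ji = similarity(model, seqs[j], seqs[i])
            assert s_ij == s_ji
            assert 0.0 < s_ij <= 1.0

    def test_loss_decreases_over_training(self, trained_toy_model):
        model, _, _ = trained_toy_model
        losses = model.history["loss"].to_numpy()
        assert losses[-1] < losses[0]

    def test_same_pairs_score_above_different_pairs(self, trained_toy_model):
        model, seqs, pairs = trained_toy_model
        sims = np.array([similarity(model, l, r) for l, r in zip(pairs.left, pairs.right)])
        same = np.median(sims[pairs.labels == 1.0])
        diff = np.median(sims[pairs.labels == 0.0])
        assert same > diff

    def test_trained_verification_beats_chance(self, trained_toy_model):
        model, seqs, pairs = trained_toy_model
        assert verification_accuracy(model, pairs) > 0.8

    def test_untrained_model_is_at_chance_on_random_pairs(self, rng):
        from gaitid.siamese import _LSTM, SimilarityModel

        enc = _LSTM(input_size=18, hidden_size=18, rng=np.random.default_rng(3))
        model = SimilarityModel(encoder=enc, config={}, seed=3, threshold=0.5)
        seqs = _random_sequences(rng, n_subjects=6, n_cycles=4, spread=0.0)
        # identical subjects: labels carry no signal at all
        pairs = make_pairs(seqs, n_pairs=300, seed=2)
        acc = verification_accuracy(model, pairs)
        se = np.sqrt(0.25 / 300)
        assert abs(acc - 0.5) < 4 * se

    def test_training_deterministic_given_seed(self, rng):
        seqs = _random_sequences(rng, n_subjects=3, n_cycles=3)
        pairs = make_pairs(seqs, n_pairs=60, seed=4)
        m1 = train_malstm(pairs, config={"batch_size": 32, "epochs": 2}, seed=9)
        m2 = train_malstm(pairs, config={"batch_size": 32, "epochs": 2}, seed=9)
        for k in m1.encoder.params:
            assert np.array_equal(m1.encoder.params[k], m2.encoder.params[k])
        assert m1.threshold == m2.threshold

    def test_empty_pairs_rejected(self):
        from gaitid.siamese import PairSet

        with pytest.raises(ValueError, match="empty"):
            train_malstm(PairSet(left=[], right=[], labels=np.array([])))


class TestIdentify:
    def test_probe_identical_to_gallery_cycle_wins(self, trained_toy_model):
        model, seqs, _ = trained_toy_model
        probe = seqs[7]
        assert identify(model, seqs, probe) == probe.subject_id

    def test_single_subject_gallery_always_wins(self, trained_toy_model, rng):
        model, seqs, _ = trained_toy_model
        gallery = [s for s in seqs if s.subject_id == "S2"]
        probe = seqs[0]  # belongs to S0
        assert identify(model, gallery, probe) == "S2"

    def test_empty_gallery_rejected(self, trained_toy_model):
        model, seqs, _ = trained_toy_model
        with pytest.raises(ValueError, match="gallery"):
            identify(model, [], seqs[0])
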