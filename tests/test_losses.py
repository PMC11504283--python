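"""Projection, contrastive pair construction and the MERCL loss terms."""

import numpy as np
import pytest

from mercl._tensor import Parameter, Tensor
from mercl.losses import (ContrastiveSet, LiteralDomainError, MerclWeights,
                          amcl_loss, build_pairs, emcl_loss, mercl_loss,
                          project, smcl_loss)
from mercl.nn import Adam
from oracles import ratio_loss_oracle, smcl_oracle


def make_set(anchor, positives, negatives, scheme="amcl"):
    return ContrastiveSet(np.asarray(anchor, dtype=float),
                          np.atleast_2d(np.asarray(positives, dtype=float)),
                          (np.atleast_2d(np.asarray(negatives, dtype=float))
                           if len(negatives) else np.empty((0, len(anchor)))),
                          scheme, "video", 0)


def random_embeddings(rng, n=6, p=8):
    z = {}
    for m in ("video", "audio", "eeg"):
        v = rng.normal(size=(n, p))
        z[m] = v / np.linalg.norm(v, axis=1, keepdims=True)
    return z


class TestProjection:
    def test_identity_projection_single_step_returns_row(self, rng):
        h = rng.normal(size=(3, 1, 4))
        z = project(h, np.eye(4), normalize=False)
        assert np.allclose(z.data, h[:, 0, :])

    def test_normalized_rows_have_unit_norm(self, rng):
        z = project(rng.normal(size=(5, 7, 4)), rng.normal(size=(6, 4)))
        assert np.allclose(np.linalg.norm(z.data, axis=1), 1.0, atol=1e-6)

    def test_mean_pooling_of_constant_sequence_equals_slice(self, rng):
        row = rng.normal(size=(1, 1, 4))
        h = np.repeat(row, 5, axis=1)
        W = rng.normal(size=(3, 4))
        z_seq = project(h, W, normalize=False).data
        z_one = project(row, W, normalize=False).data
        assert np.allclose(z_seq, z_one)

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="width"):
            project(rng.normal(size=(2, 3, 4)), np.eye(5))


class TestBuildPairs:
    def test_amcl_same_label_others_are_positives(self, rng):
        z = random_embeddings(rng, n=3)
        cs = build_pairs(z, [0, 0, 1], 0, "video", "amcl")
        assert cs.positive_tags == [("video", 1)]
        assert cs.negative_tags == [("video", 2)]

    def test_emcl_draws_from_both_other_modalities(self, rng):
        z = random_embeddings(rng, n=3)
        cs = build_pairs(z, [0, 0, 1], 0, "video", "emcl")
        # 2N positives with N=2 (samples 0 and 1 in audio and eeg)
        assert sorted(cs.positive_tags) == [("audio", 0), ("audio", 1),
                                            ("eeg", 0), ("eeg", 1)]
        assert sorted(cs.negative_tags) == [("audio", 2), ("eeg", 2)]

    def test_smcl_silent_audio_leaves_single_positive(self, rng):
        from mercl.preprocess import AudioEnergyFlag
        z = random_embeddings(rng, n=2)
        flags = [AudioEnergyFlag(0.0, False, 1.0), AudioEnergyFlag(5.0, True, 1.0)]
        cs = build_pairs(z, [0, 1], 0, "video", "smcl", flags)
        assert cs.positive_tags == [("eeg", 0)]
        assert np.allclose(cs.positives[0], z["eeg"][0])

    def test_no_positive_returns_skip_signal(self, rng):
        z = random_embeddings(rng, n=2)
        assert build_pairs(z, [0, 1], 0, "video", "amcl") is None

    def test_silent_audio_anchor_skipped(self, rng):
        from mercl.preprocess import AudioEnergyFlag
        z = random_embeddings(rng, n=2)
        flags = [AudioEnergyFlag(0.0, False, 1.0)] * 2
        assert build_pairs(z, [0, 0], 0, "audio", "amcl", flags) is None


class TestRatioLosses:
    def test_perfect_separation_literal_loss_is_zero(self):
        anchor = np.array([1.0, 0.0])
        cs = make_set(anchor, [[1.0, 0.0]], [[0.0, 1.0]])
        w = MerclWeights(literal_mode=True)
        assert amcl_loss(cs, w) == pytest.approx(0.0)

    def test_softened_matches_scalar_oracle_on_random_sets(self, rng):
        w = MerclWeights(temperature=0.1)
        for _ in range(120):
            p = rng.integers(1, 6)
            m = rng.integers(0, 6)
            dim = 4
            anchor = rng.normal(size=dim)
            anchor /= np.linalg.norm(anchor)
            pos = rng.normal(size=(p, dim))
            neg = rng.normal(size=(m, dim)) if m else []
            cs = make_set(anchor, pos, neg)
            expected = ratio_loss_oracle([r @ anchor for r in np.atleast_2d(pos)],
                                         [r @ anchor for r in np.atleast_2d(neg)]
                                         if m else [], temperature=0.1)
            assert amcl_loss(cs, w) == pytest.approx(expected, rel=1e-9)

    def test_raising_a_negative_similarity_raises_loss(self, rng):
        anchor = np.array([1.0, 0.0, 0.0])
        pos = [[0.9, 0.1, 0.0]]
        base = amcl_loss(make_set(anchor, pos, [[0.1, 0.9, 0.0]]))
        bumped = amcl_loss(make_set(anchor, pos, [[0.3, 0.9, 0.0]]))
        assert bumped > base

    def test_literal_mode_raises_on_nonpositive_ratio(self):
        cs = make_set([1.0, 0.0], [[-1.0, 0.0]], [[0.5, 0.0]])
        with pytest.raises(LiteralDomainError, match="softened"):
            amcl_loss(cs, MerclWeights(literal_mode=True))

    def test_emcl_equals_amcl_on_identical_sets(self, rng):
        anchor = rng.normal(size=4)
        cs = make_set(anchor, rng.normal(size=(3, 4)), rng.normal(size=(2, 4)),
                      scheme="emcl")
        assert emcl_loss(cs) == pytest.approx(amcl_loss(cs))


class TestSmcl:
    def test_exact_margin_gives_zero_loss(self):
        assert smcl_loss(None, np.array([0.8, 0.8]), alpha=0.8) == 0.0

    def test_hand_computed_value(self):
        assert smcl_loss(None, np.array([1.0, 0.5]),
                         alpha=0.8) == pytest.approx(0.065)

    def test_single_surviving_positive(self):
        s = 0.3
        assert smcl_loss(None, np.array([s]), alpha=0.8) == pytest.approx(
            0.5 * (s - 0.8) ** 2)

    def test_embedding_rows_equal_similarity_oracle(self, rng):
        anchor = rng.normal(size=5)
        pos = rng.normal(size=(2, 5))
        sims = pos @ anchor
        assert smcl_loss(anchor, pos, 0.8) == pytest.approx(
            smcl_oracle(sims, 0.8))

    def test_empty_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            smcl_loss(None, np.array([]), 0.8)


class TestMerclCombined:
    def test_weight_masking_recovers_single_term(self, rng):
        z = random_embeddings(rng)
        labels = [0, 0, 1, 1, 2, 2]
        w = MerclWeights(lambda_amcl=1.0, lambda_emcl=0.0, lambda_smcl=0.0)
        res = mercl_loss(z, labels, weights=w)
        assert res.total.item() == pytest.approx(res.amcl)

    def test_weighted_sum_arithmetic(self, rng):
        z = random_embeddings(rng)
        labels = [0, 0, 1, 1, 2, 2]
        w = MerclWeights(0.5, 0.25, 0.25)
        res = mercl_loss(z, labels, weights=w)
        assert res.total.item() == pytest.approx(
            0.5 * res.amcl + 0.25 * res.emcl + 0.25 * res.smcl)

    def test_batch_order_invariance(self, rng):
        z = random_embeddings(rng)
        labels = np.array([0, 0, 1, 1, 2, 2])
        perm = rng.permutation(6)
        res = mercl_loss(z, labels)
        res_p = mercl_loss({m: v[perm] for m, v in z.items()}, labels[perm])
        assert res.total.item() == pytest.approx(res_p.total.item())
        assert res.amcl == pytest.approx(res_p.amcl)

    def test_batched_terms_equal_mean_of_per_anchor_losses(self, rng):
        z = random_embeddings(rng)
        labels = [0, 0, 1, 1, 2, 2]
        w = MerclWeights()
        res = mercl_loss(z, labels, weights=w)
        for scheme, batched in (("amcl", res.amcl), ("emcl", res.emcl)):
            per_mod = []
            for m in ("video", "audio", "eeg"):
                vals = [amcl_loss(cs, w) for i in range(6)
                        if (cs := build_pairs(z, labels, i, m, scheme))]
                per_mod.append(np.mean(vals))
            assert batched == pytest.approx(np.mean(per_mod), rel=1e-9)
        per_mod = []
        for m in ("video", "audio", "eeg"):
            vals = [smcl_loss(cs.anchor, cs.positives, w.alpha) for i in range(6)
                    if (cs := build_pairs(z, labels, i, m, "smcl"))]
            per_mod.append(np.mean(vals))
        assert res.smcl == pytest.approx(np.mean(per_mod), rel=1e-9)

    def test_silent_audio_counted_as_skipped(self, rng):
        from mercl.preprocess import AudioEnergyFlag
        z = random_embeddings(rng, n=4)
        flags = [AudioEnergyFlag(1.0, True, 0.5), AudioEnergyFlag(0.0, False, 0.5),
                 AudioEnergyFlag(1.0, True, 0.5), AudioEnergyFlag(1.0, True, 0.5)]
        res = mercl_loss(z, [0, 0, 1, 1], energy_flags=flags)
        assert res.skipped["smcl"] >= 1

    def test_one_gradient_step_decreases_loss(self, rng):
        n, p, d = 8, 6, 5
        labels = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        h = {m: rng.normal(size=(n, d)) for m in ("video", "audio", "eeg")}
        W = {m: Parameter(rng.normal(size=(d, p))) for m in h}

        def forward():
            z = {m: (Tensor(h[m]) @ W[m]).l2_normalize() for m in h}
            return mercl_loss(z, labels)

        base = forward()
        base.total.backward()
        grads = {m: W[m].grad.copy() for m in W}
        for step in (1e-3, 1e-4, 1e-5):
            for m in W:
                W[m].data -= step * grads[m]
            new = forward().total.item()
            for m in W:
                W[m].data += step * grads[m]
            if new < base.total.item():
                break
        else:
            pytest.fail("no step size decreased the loss")

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            MerclWeights(0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            MerclWeights(temperature=-1.0)
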