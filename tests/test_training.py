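"""Two-phase schedule: accumulation, determinism, Siamese pass, freezing."""

import numpy as np
import pytest

from camloc import nn
from camloc.backbone import assemble_multires_model
from camloc.nn import Tensor
from camloc.nn import autograd as ag
from camloc.pcm import attach_pcm
from camloc.training import (Phase1Config, Phase2Config, rotate_batch,
                             siamese_forward, train_phase1, train_phase2_pcm)


def _toy_data(n=24, side=64, n_classes=3, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3, side, side)) * 0.1
    y = np.zeros((n, n_classes))
    for i in range(n):
        c = i % n_classes
        y[i, c] = 1
        x[i, 0, 8 * c:8 * c + 8, 8 * c:8 * c + 8] += 3.0    # class-specific patch
    return x, y


@pytest.fixture(scope="module")
def trained_tiny():
    model = assemble_multires_model("tiny", 3, finest_level=3, seed=1)
    x, y = _toy_data()
    hist = train_phase1((x, y), None, model,
                        Phase1Config(lr=3e-3, epochs=3, micro_batch=8,
                                     accumulation_steps=1), seed=2)
    return model, (x, y), hist


def test_phase1_loss_decreases(trained_tiny):
    _, _, hist = trained_tiny
    assert hist["train"][-1] < hist["train"][0]


def test_phase1_deterministic_given_seed():
    runs = []
    for _ in range(2):
        model = assemble_multires_model("tiny", 2, finest_level=4, seed=5)
        x, y = _toy_data(n=12, n_classes=2, seed=3)
        hist = train_phase1((x, y), None, model,
                            Phase1Config(lr=1e-3, epochs=2, micro_batch=6,
                                         accumulation_steps=1), seed=7)
        runs.append(hist["train"])
    assert runs[0] == runs[1]


def test_empty_training_set_rejected():
    model = assemble_multires_model("tiny", 2, finest_level=4, seed=0)
    with pytest.raises(ValueError, match="empty"):
        train_phase1((np.zeros((0, 3, 64, 64)), np.zeros((0, 2))), None, model)


def test_accumulation_equivalent_to_large_batch_on_linear_model():
    """3 accumulation steps over micro-batches == one step on the union,
    checked on a bias-free linear least-squares model (loss is an average,
    so accumulation with 1/3 scaling reproduces the big-batch gradient)."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 4))
    w_true = rng.normal(size=4)
    yv = X @ w_true

    def run(accum):
        w = nn.Parameter(np.zeros(4))
        opt = nn.Adam([w], lr=0.1)
        batches = np.split(np.arange(12), 3) if accum else [np.arange(12)]
        for idx in batches:
            pred = Tensor(X[idx]) @ w.reshape(4, 1)
            loss = ((pred.reshape(len(idx)) - Tensor(yv[idx])) ** 2).mean()
            scale = 1.0 / 3 if accum else 1.0
            (loss * scale).backward()
        opt.step()
        return w.data.copy()

    # identical per-element losses appear in both variants with equal weight
    assert np.allclose(run(accum=True), run(accum=False), atol=1e-12)


@pytest.fixture(scope="module")
def siamese_model():
    m = assemble_multires_model("tiny", 3, finest_level=3, seed=4)
    attach_pcm(m, embed_channels=8, seed=5)
    m.eval()
    return m


class TestSiamese:

    def test_identity_transform_branches_agree(self, siamese_model):
        x = np.random.default_rng(6).normal(size=(2, 3, 64, 64))
        with nn.no_grad():
            out = siamese_forward(x, siamese_model, angles=[0.0, 0.0])
        assert np.allclose(out.yhat_o.array, out.yhat_t.array)
        assert np.allclose(out.y_o.array, out.y_t.array)

    def test_rotation_near_inverse_on_cams(self):
        # CAMs are smooth, so bilinear round-trip must return interior pixels
        yy, xx = np.meshgrid(np.linspace(0, 1, 16), np.linspace(0, 1, 16),
                             indexing="ij")
        smooth = np.stack([np.sin(2 * np.pi * yy) * np.cos(np.pi * xx),
                           yy * (1 - xx)])
        cam = Tensor(smooth[None])
        back = rotate_batch(rotate_batch(cam, [14.0]), [-14.0]).data
        inner = np.s_[:, :, 4:-4, 4:-4]
        assert np.abs(back[inner] - cam.data[inner]).max() < 0.08

    def test_pointwise_model_is_exactly_equivariant_to_90_degrees(self):
        """A single 1x1 conv commutes with any spatial permutation, and a 90
        degree rotation is one, so both branches agree exactly."""
        conv = nn.Conv2d(2, 3, 1, rng=np.random.default_rng(8))
        x = Tensor(np.random.default_rng(9).normal(size=(1, 2, 8, 8)))
        with nn.no_grad():
            t_then_f = conv(ag.rotate(x, 90.0)).data
            f_then_t = ag.rotate(conv(x), 90.0).data
        assert np.allclose(t_then_f, f_then_t, atol=1e-10)

    def test_requires_attached_pcm(self):
        bare = assemble_multires_model("tiny", 2, finest_level=4, seed=0)
        with pytest.raises(ValueError, match="PCM"):
            siamese_forward(np.zeros((1, 3, 64, 64)), bare, [5.0])


class TestPhase2:
    def test_only_pcm_parameters_move_and_scores_unchanged(self, trained_tiny):
        model, (x, y), _ = trained_tiny
        attach_pcm(model, embed_channels=8, seed=9)
        non_pcm_before = {k: v.data.copy() for k, v in model.named_parameters()
                          if not k.startswith("pcm")}
        buffers_before = {k: np.copy(v) for k, v in model.named_buffers()}
        model.eval()
        with nn.no_grad():
            z_before, _, _ = model(Tensor(x[:6]))
        theta_before = model.pcm.theta.weight.data.copy()
        train_phase2_pcm((x, y), model,
                         Phase2Config(lr=1e-2, epochs=1, micro_batch=8),
                         seed=10)
        for k, v in model.named_parameters():
            if k.startswith("pcm"):
                assert not np.array_equal(v.data, theta_before)
            else:
                assert np.array_equal(v.data, non_pcm_before[k]), k
        for k, v in model.named_buffers():
            assert np.array_equal(v, buffers_before[k]), k
        model.eval()
        with nn.no_grad():
            z_after, _, _ = model(Tensor(x[:6]))
        assert np.array_equal(z_before.z.data, z_after.z.data)

    def test_sampled_transforms_are_rotations_within_range_no_flips(self,
                                                                    trained_tiny):
        model, (x, y), _ = trained_tiny
        attach_pcm(model, embed_channels=8, seed=11)
        seen = []
        import camloc.training as tr
        orig = tr.siamese_forward
        def spy(images, m, angles):
            seen.extend(np.asarray(angles).tolist())
            return orig(images, m, angles)
        tr.siamese_forward = spy
        try:
            train_phase2_pcm((x[:8], y[:8]), model,
                             Phase2Config(lr=1e-3, epochs=1, micro_batch=4),
                             seed=12)
        finally:
            tr.siamese_forward = orig
        assert seen and all(-30.0 <= a <= 30.0 for a in seen)

    def test_pcm_required(self, trained_tiny):
        model = assemble_multires_model("tiny", 3, finest_level=3, seed=0)
        with pytest.raises(ValueError, match="PCM"):
            train_phase2_pcm((np.zeros((2, 3, 64, 64)), np.zeros((2, 3))),
                             model)


def test_ecr_decreases_over_phase2_training():
    model = assemble_multires_model("tiny", 3, finest_level=3, seed=13)
    x, y = _toy_data(n=24, seed=14)
    train_phase1((x, y), None, model,
                 Phase1Config(lr=3e-3, epochs=3, micro_batch=8,
                              accumulation_steps=1), seed=15)
    attach_pcm(model, embed_channels=8, seed=16)
    hist = train_phase2_pcm((x, y), model,
                            Phase2Config(lr=3e-2, epochs=3, micro_batch=8),
                            seed=17)
    assert hist["ecr"][-1] < hist["ecr"][0]
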