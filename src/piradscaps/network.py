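"""The multi-task capsule segmentation network.

One 2-D model processes a case slice by slice:

* a lightweight 4-stage encoder of depthwise-separable convolutions maps
  each ``3×100×100`` slice (T2, ADC, zonal mask) to ``256×6×6`` features;
* a primary capsule layer reshapes those features into a ``6×6`` grid of
  32 capsule types × 8 dimensions (squashed);
* a convolutional GRU carries the capsule feature stack across adjacent
  slices, base to apex, so through-plane context informs every slice;
* a second capsule layer with dynamic routing terminates in two class
  capsules whose lengths score low grade (PI-RADS 1/2/3) versus high
  grade (PI-RADS 4/5);
* three fully connected layers reconstruct the encoder features from the
  winning class capsule; passed through a sigmoid they gate the encoder
  features, focusing the decoder on grade-relevant structure;
* the decoder upsamples back to ``100×100`` and emits 5 sigmoid channels:
  4 ordinal PI-RADS channels plus one benign-nodule (BPH) channel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from piradscaps.autodiff import Tensor, concat, stack
from piradscaps import nn

N_SEG_CHANNELS = 5  # 4 ordinal PI-RADS channels + 1 BPH channel
N_GRADE_CAPS = 2  # low grade (PI-RADS 1/2/3) vs high grade (PI-RADS 4/5)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    The default profile realizes every published shape of the reference
    design (``6×6×256`` encoder features, ``32×8`` primary capsules); the
    :meth:`desk` profile narrows the widths so that training-time tests
    run on one CPU while keeping the architecture identical.
    """

    in_channels: int = 3
    crop_size: int = 100
    encoder_widths: tuple[int, int, int, int] = (32, 64, 128, 256)
    caps_types: int = 32
    caps_dim: int = 8
    class_caps_dim: int = 16
    routing_iters: int = 3
    recon_hidden: tuple[int, int] = (512, 1024)
    gru_enabled: bool = True
    gru_kernel: int = 3
    seed: int = 0

    @property
    def caps_channels(self) -> int:
        return self.caps_types * self.caps_dim

    @classmethod
    def desk(cls, **overrides) -> "NetworkConfig":
        """CPU-scale profile used by the training tests and examples."""
        cfg = cls(encoder_widths=(8, 16, 32, 64), caps_types=8, caps_dim=4,
                  class_caps_dim=8, recon_hidden=(64, 128))
        return replace(cfg, **overrides)


def squash(v: Tensor, axis: int = -1, eps: float = 1e-8) -> Tensor:
    """Capsule nonlinearity ``(‖v‖²/(1+‖v‖²))·v/‖v‖``.

    Scales the norm into ``[0, 1)`` while preserving direction; the zero
    vector maps to itself.
    """
    n2 = (v * v).sum(axis=axis, keepdims=True)
    scale = n2 / (1.0 + n2) / (n2 + eps).sqrt()
    return v * scale


def capsule_lengths(v: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    return ((v * v).sum(axis=axis) + eps).sqrt()


def dynamic_routing(u_hat: Tensor, iterations: int = 3,
                    record: list | None = None) -> Tensor:
    """Routing-by-agreement between capsule layers.

    Parameters
    ----------
    u_hat
        Prediction vectors, shape ``(N, n_in, n_out, dim)``.
    iterations
        Number of routing iterations (≥ 1).
    record
        Optional list; when given, the coupling-coefficient array of every
        iteration (shape ``(N, n_in, n_out, 1)``) is appended for
        inspection.

    Returns
    -------
    Tensor
        Squashed output capsules, shape ``(N, n_out, dim)``.
    """
    if iterations < 1:
        raise ValueError(f"routing iterations must be >= 1, got {iterations}")
    n, n_in, n_out, _ = u_hat.shape
    logits = Tensor(np.zeros((n, n_in, n_out, 1), np.float32))
    v: Tensor | None = None
    for it in range(iterations):
        coupling = logits.softmax(axis=2)
        if record is not None:
            record.append(coupling.data.copy())
        s = (coupling * u_hat).sum(axis=1)  # (N, n_out, dim)
        v = squash(s, axis=-1)
        if it + 1 < iterations:
            agreement = (u_hat * v.reshape(n, 1, n_out, -1)).sum(axis=-1, keepdims=True)
            logits = logits + agreement
    return v


def attention_fuse(enc: Tensor, rec: Tensor) -> Tensor:
    """Gate encoder features by the sigmoid of the reconstruction."""
    if enc.shape != rec.shape:
        raise ValueError(f"attention shapes differ: {enc.shape} vs {rec.shape}")
    return enc * rec.sigmoid()


class _EncoderStage(nn.Module):
    """Stride-2 separable downsampling followed by a refining block."""

    def __init__(self, c_in: int, c_out: int, rng):
        self.down = nn.SeparableConv2d(c_in, c_out, kernel=4, stride=2, padding=1, rng=rng)
        self.refine = nn.SeparableConv2d(c_out, c_out, kernel=3, padding=1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.refine(self.down(x).relu()).relu()


class _DecoderStage(nn.Module):
    def __init__(self, c_in: int, c_skip: int, c_out: int, rng):
        self.block = nn.SeparableConv2d(c_in + c_skip, c_out, kernel=3, padding=1, rng=rng)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        x = x.resize_nearest(skip.shape[-2:])
        return self.block(concat([x, skip], axis=1)).relu()


class CapsOrdinalSegNet(nn.Module):
    """Joint ordinal lesion segmentation and binary PI-RADS grading."""

    def __init__(self, config: NetworkConfig | None = None):
        self.config = cfg = config or NetworkConfig()
        rng = np.random.default_rng(cfg.seed)
        w0, w1, w2, w3 = cfg.encoder_widths
        w4 = w3  # deepest stage keeps the widest channel count

        self.stem = nn.Conv2d(cfg.in_channels, w0, 3, padding=1, rng=rng)
        self.stages = [
            _EncoderStage(w0, w1, rng),
            _EncoderStage(w1, w2, rng),
            _EncoderStage(w2, w3, rng),
            _EncoderStage(w3, w4, rng),
        ]

        cc = cfg.caps_channels
        self.primary_conv = nn.Conv2d(w4, cc, 3, padding=1, rng=rng)
        self.gru = nn.ConvGRUCell(cc, kernel=cfg.gru_kernel, rng=rng)

        # one prediction weight per (input capsule location*type, class capsule)
        feat_hw = self._feature_hw()
        n_in_caps = cfg.caps_types * feat_hw * feat_hw
        self.caps_weight = Tensor(
            np.random.default_rng(cfg.seed + 1).normal(
                0.0, 0.1, (n_in_caps, N_GRADE_CAPS, cfg.caps_dim, cfg.class_caps_dim)
            ).astype(np.float32),
            requires_grad=True,
        )

        h1, h2 = cfg.recon_hidden
        n_feat = w4 * feat_hw * feat_hw
        self.recon_fc1 = nn.Linear(N_GRADE_CAPS * cfg.class_caps_dim, h1, rng=rng)
        self.recon_fc2 = nn.Linear(h1, h2, rng=rng)
        self.recon_fc3 = nn.Linear(h2, n_feat, rng=rng)

        self.decoder = [
            _DecoderStage(w4, w3, w2, rng),
            _DecoderStage(w2, w2, w1, rng),
            _DecoderStage(w1, w1, w0, rng),
            _DecoderStage(w0, w0, w0, rng),
        ]
        self.head = nn.Conv2d(w0, N_SEG_CHANNELS, 1, rng=rng)

    # -- pieces ---------------------------------------------------------
    def _feature_hw(self) -> int:
        n = self.config.crop_size
        for _ in range(4):
            n = (n + 2 - 4) // 2 + 1  # kernel 4, pad 1, stride 2
        return n

    def encoder_forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """``(N,3,100,100) -> (N,256,6,6)`` features plus skip maps."""
        if x.ndim != 4 or x.shape[1] != self.config.in_channels \
                or x.shape[2] != self.config.crop_size or x.shape[3] != self.config.crop_size:
            raise ValueError(
                f"expected (N,{self.config.in_channels},{self.config.crop_size},"
                f"{self.config.crop_size}) input, got {x.shape}")
        skips = [self.stem(x).relu()]
        h = skips[0]
        for stage in self.stages[:-1]:
            h = stage(h)
            skips.append(h)
        features = self.stages[-1](h)
        return features, skips

    def primary_caps(self, features: Tensor) -> Tensor:
        """Features to a squashed capsule grid ``(N, types, dim, h, w)``."""
        cfg = self.config
        n = features.shape[0]
        hw = features.shape[-1]
        raw = self.primary_conv(features)
        grid = raw.reshape(n, cfg.caps_types, cfg.caps_dim, hw, hw)
        return squash(grid, axis=2)

    def caps_to_stack(self, grid: Tensor) -> Tensor:
        """Capsule grid to a plain feature stack ``(N, types*dim, h, w)``."""
        n, t, d, h, w = grid.shape
        return grid.reshape(n, t * d, h, w)

    def caps_gru(self, e_seq: Tensor) -> Tensor:
        """Recurrence ``h_s = Φ(h_{s-1}, e_s)`` over the slice axis.

        ``e_seq`` is the capsule feature stack of one ordered case,
        shape ``(S, C, h, w)``; output has the identical shape.
        """
        if e_seq.ndim != 4:
            raise ValueError(f"expected (S,C,h,w) sequence, got {e_seq.shape}")
        s_total = e_seq.shape[0]
        h = self.gru.init_state(e_seq[0:1])
        states = []
        for s in range(s_total):
            h = self.gru(h, e_seq[s:s + 1])
            states.append(h)
        return concat(states, axis=0)

    def class_caps(self, stack_or_grid: Tensor, record: list | None = None) -> Tensor:
        """Terminal capsule layer: dynamic routing into 2 grade capsules."""
        cfg = self.config
        x = stack_or_grid
        if x.ndim == 4:  # feature stack (N, types*dim, h, w)
            n, c, h, w = x.shape
            x = x.reshape(n, cfg.caps_types, cfg.caps_dim, h, w)
        n, t, d, h, w = x.shape
        u = x.transpose(0, 1, 3, 4, 2).reshape(n, t * h * w, d)
        u_hat = u.caps_transform(self.caps_weight)
        return dynamic_routing(u_hat, iterations=cfg.routing_iters, record=record)

    def reconstruct(self, class_vectors: Tensor,
                    target_class: np.ndarray | None = None) -> Tensor:
        """Masked 3-FC reconstruction of the encoder features.

        The capsule of ``target_class`` (ground truth during training, the
        longest capsule at inference) is kept, the other zeroed, before
        the fully connected stack maps to a ``(N, C, h, w)`` feature map.
        """
        n = class_vectors.shape[0]
        lengths = capsule_lengths(class_vectors).data
        if target_class is None:
            chosen = lengths.argmax(axis=1)
        else:
            chosen = np.asarray(target_class, dtype=int)
            if chosen.shape != (n,) or chosen.min() < 0 or chosen.max() >= N_GRADE_CAPS:
                raise ValueError("target_class must be per-item labels in {0,1}")
        mask = np.zeros((n, N_GRADE_CAPS, 1), np.float32)
        mask[np.arange(n), chosen] = 1.0
        masked = class_vectors * Tensor(mask)
        flat = masked.reshape(n, -1)
        h = self.recon_fc1(flat).relu()
        h = self.recon_fc2(h).relu()
        out = self.recon_fc3(h)
        hw = self._feature_hw()
        return out.reshape(n, -1, hw, hw)

    def decoder_forward(self, fused: Tensor, skips: list[Tensor]) -> Tensor:
        """Fused features back to ``(N, 5, 100, 100)`` sigmoid maps."""
        h = fused
        for stage, skip in zip(self.decoder, reversed(skips)):
            h = stage(h, skip)
        return self.head(h).sigmoid()

    # -- full model -------------------------------------------------------
    def forward(self, case_slices: Tensor,
                target_grade: np.ndarray | None = None) -> dict[str, Tensor]:
        """Run one ordered case through both branches.

        Parameters
        ----------
        case_slices
            ``(S, 3, 100, 100)`` tensor of the case's slices, base to apex.
        target_grade
            Optional per-slice grade labels (0 low / 1 high) used to mask
            the reconstruction during training.

        Returns
        -------
        dict
            ``ordinal`` (S,4,H,W), ``bph`` (S,1,H,W), ``grade_vectors``
            (S,2,dim), ``grade_lengths`` (S,2), ``reconstruction`` and
            ``features`` (S,C,h,w).
        """
        if case_slices.ndim != 4 or case_slices.shape[0] < 1:
            raise ValueError("model_forward needs a non-empty (S,3,H,W) slice sequence")
        features, skips = self.encoder_forward(case_slices)
        grid = self.primary_caps(features)
        e_stack = self.caps_to_stack(grid)
        h_stack = self.caps_gru(e_stack) if self.config.gru_enabled else e_stack
        grade_vectors = self.class_caps(h_stack)
        recon = self.reconstruct(grade_vectors, target_class=target_grade)
        fused = attention_fuse(features, recon)
        seg = self.decoder_forward(fused, skips)
        s = seg.shape[0]
        return {
            "ordinal": seg[:, 0:4],
            "bph": seg[:, 4:5],
            "grade_vectors": grade_vectors,
            "grade_lengths": capsule_lengths(grade_vectors),
            "reconstruction": recon,
            "features": features,
        }

    __call__ = forward
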