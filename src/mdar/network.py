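"""The dual-branch heart-rate network (MDAR).

Two parallel convolutional branches process each video chunk:

* the **static branch** (5 stages, r1-r5) sees chunk-standardized frames and
  extracts time-independent appearance features.  Since the target features
  are by definition stable over the chunk, the branch runs on the chunk's
  temporal-mean frame and its output gates every frame of the chunk.
* the **dynamic branch** (6 stages, d1-d6) sees diff-normalized frames; an
  alternating time-shift (ATSM) precedes the convolution of stages 1-4,
  widening the temporal receptive field to +/-2 frames per shifted stage.

Average pooling (2x2) follows stages 2 and 4 of both branches.  DSFFM fuses
the branches after stages 2 and 5 (the gated product feeds the dynamic
branch's next stage).  Multiscale fusion concatenates downsampled d2 and d5
with d6; a spatial average, dropout and a dense layer map the fused features
to one blood-volume-pulse value per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _engine as eng
from ._engine import Tensor
from .fusion import FusionConfig
from .shift import ShiftConfig

__all__ = ["MDARConfig", "MDARNetwork", "build_mdar", "count_parameters"]


@dataclass(frozen=True)
class MDARConfig:
    """Architecture hyperparameters.

    ``stage_widths`` are the channel counts of stages 1-6 (the static branch
    uses the first five).  ``image_size`` must be divisible by 4 (two 2x2
    average-pooling steps) and ``chunk_len`` is the number of frames per
    processed chunk.
    """

    in_channels: int = 3
    stage_widths: tuple[int, ...] = (32, 32, 64, 64, 64, 64)
    kernel_size: int = 3
    pool_size: int = 2
    dropout_rates: tuple[float, float] = (0.25, 0.5)
    activation: str = "tanh"
    shift: ShiftConfig = field(default_factory=ShiftConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    chunk_len: int = 180
    image_size: int = 72

    def __post_init__(self) -> None:
        if len(self.stage_widths) != 6:
            raise ValueError("stage_widths must list six stage channel counts")
        if min(self.stage_widths) < 4:
            raise ValueError("stage widths must be >= 4")
        if self.shift.alpha2 > 0 and min(self.stage_widths) < 1.0 / self.shift.alpha2:
            raise ValueError(
                "stage widths are incompatible with the shift fractions: "
                f"floor(alpha2*C) would be empty (need widths >= {1.0/self.shift.alpha2:.0f})"
            )
        if self.kernel_size != 3 or self.pool_size != 2:
            raise ValueError("only 3x3 kernels with 2x2 pooling are implemented")
        if self.image_size % 4 != 0 or self.image_size <= 0:
            raise ValueError("image_size must be a positive multiple of 4")
        if self.chunk_len < 4:
            raise ValueError("chunk_len must be >= 4")
        if self.activation != "tanh":
            raise ValueError("branch activation must be 'tanh'")
        if not all(0 <= p < 1 for p in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")


def desk_tiny_config() -> MDARConfig:
    """Half-width, 36x36, 120-frame configuration for CPU-scale runs."""
    return MDARConfig(stage_widths=(16, 16, 32, 32, 32, 32), chunk_len=120, image_size=36)


def config_to_dict(config: MDARConfig) -> dict:
    return {
        "in_channels": config.in_channels,
        "stage_widths": list(config.stage_widths),
        "kernel_size": config.kernel_size,
        "pool_size": config.pool_size,
        "dropout_rates": list(config.dropout_rates),
        "activation": config.activation,
        "shift": {
            "alpha1": config.shift.alpha1,
            "alpha2": config.shift.alpha2,
            "fill_value": config.shift.fill_value,
        },
        "fusion": {
            "beta": config.fusion.beta,
            "epsilon": config.fusion.epsilon,
            "conv_kernel": config.fusion.conv_kernel,
        },
        "chunk_len": config.chunk_len,
        "image_size": config.image_size,
    }


def config_from_dict(d: dict) -> MDARConfig:
    d = dict(d)
    shift = ShiftConfig(**d.pop("shift", {}))
    fusion = FusionConfig(**d.pop("fusion", {}))
    d["stage_widths"] = tuple(d.get("stage_widths", (32, 32, 64, 64, 64, 64)))
    d["dropout_rates"] = tuple(d.get("dropout_rates", (0.25, 0.5)))
    return MDARConfig(shift=shift, fusion=fusion, **d)


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, shape).astype(np.float32)


class MDARNetwork:
    """Parameterized forward graph; see the module docstring for the layout."""

    def __init__(self, config: MDARConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(seed))

    def _init_params(self, rng: np.random.Generator) -> None:
        w = self.config.stage_widths
        cin = self.config.in_channels
        static_io = list(zip([cin, w[0], w[1], w[2], w[3]], w[:5]))
        dyn_io = list(zip([cin, w[0], w[1], w[2], w[3], w[4]], w[:6]))
        for prefix, ios in (("static", static_io), ("dyn", dyn_io)):
            for i, (ci, co) in enumerate(ios, start=1):
                self.params[f"{prefix}{i}.w"] = Tensor(
                    _glorot(rng, (co, ci, 3, 3), ci * 9, co * 9)
                )
                self.params[f"{prefix}{i}.b"] = Tensor(np.zeros(co, np.float32))
        for stage, c in (("gate2", w[1]), ("gate5", w[4])):
            self.params[f"{stage}.w"] = Tensor(_glorot(rng, (c, c), c, c))
            self.params[f"{stage}.b"] = Tensor(np.zeros(c, np.float32))
        c_cat = w[1] + w[4] + w[5]
        self.params["head.w"] = Tensor(_glorot(rng, (c_cat,), c_cat, 1))
        self.params["head.b"] = Tensor(np.zeros((), np.float32))

    # ------------------------------------------------------------------ #

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def count_parameters(self) -> int:
        """Exact number of trainable scalars."""
        return int(sum(p.data.size for p in self.params.values()))

    def _stage(self, x: Tensor, name: str) -> Tensor:
        return eng.tanh(eng.conv3x3(x, self.params[f"{name}.w"], self.params[f"{name}.b"]))

    def _gate(self, r: Tensor, name: str) -> Tensor:
        g = eng.silu(eng.conv1x1(r, self.params[f"{name}.w"], self.params[f"{name}.b"]))
        return eng.sample_norm(g, self.config.fusion.epsilon)

    def forward(
        self,
        static_input: np.ndarray,
        dynamic_input: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Run batched chunks through the graph.

        Inputs are ``(N, T, H, W, 3)`` arrays (a single chunk may omit the
        batch axis); returns the predicted waveform as a ``(N*T,)`` tensor.
        Deterministic when ``training`` is False (dropout disabled).
        """
        static_input = np.asarray(static_input, np.float32)
        dynamic_input = np.asarray(dynamic_input, np.float32)
        if static_input.ndim == 4:
            static_input = static_input[None]
            dynamic_input = dynamic_input[None]
        if static_input.shape != dynamic_input.shape or static_input.ndim != 5:
            raise ValueError("static/dynamic inputs must share a (N,T,H,W,3) shape")
        if not (np.all(np.isfinite(static_input)) and np.all(np.isfinite(dynamic_input))):
            raise ValueError("non-finite values in network input")
        n, t, h, w_img, _ = static_input.shape
        if h != self.config.image_size or w_img != self.config.image_size:
            raise ValueError(
                f"input spatial size {h}x{w_img} does not match config "
                f"image_size {self.config.image_size}"
            )
        if training and rng is None:
            rng = np.random.default_rng()
        a1, a2 = self.config.shift.alpha1, self.config.shift.alpha2
        beta = self.config.fusion.beta
        p0, p1 = self.config.dropout_rates

        # static branch on the chunk-mean frame: (3, N, H, W)
        s = Tensor(
            np.ascontiguousarray(static_input.mean(axis=1).transpose(3, 0, 1, 2)),
            requires_grad=False,
        )
        r = self._stage(s, "static1")
        r2 = self._stage(r, "static2")
        r = eng.avgpool2(r2)
        r = self._stage(r, "static3")
        r = self._stage(r, "static4")
        r = eng.avgpool2(r)
        r5 = self._stage(r, "static5")

        # dynamic branch: (3, N*T, H, W)
        d = Tensor(
            np.ascontiguousarray(
                dynamic_input.transpose(4, 0, 1, 2, 3).reshape(3, n * t, h, w_img)
            ),
            requires_grad=False,
        )
        d = self._stage(eng.temporal_shift(d, n, t, a1, a2), "dyn1")
        d2 = self._stage(eng.temporal_shift(d, n, t, a1, a2), "dyn2")
        d = eng.gate_mul(d2, self._gate(r2, "gate2"), n, t, beta)
        d = eng.avgpool2(d)
        d = self._stage(eng.temporal_shift(d, n, t, a1, a2), "dyn3")
        d = self._stage(eng.temporal_shift(d, n, t, a1, a2), "dyn4")
        d = eng.avgpool2(d)
        d5 = self._stage(d, "dyn5")
        d = eng.gate_mul(d5, self._gate(r5, "gate5"), n, t, beta)
        d6 = self._stage(d, "dyn6")

        # multiscale fusion at d6's spatial scale
        s6 = d6.data.shape[2]
        mh = eng.bilinear_matrix(d2.data.shape[2], 2 * s6)
        mw = eng.bilinear_matrix(d2.data.shape[3], 2 * s6)
        d2_down = eng.avgpool2(eng.resize_hw(d2, mh, mw))
        mh5 = eng.bilinear_matrix(d5.data.shape[2], 2 * s6)
        mw5 = eng.bilinear_matrix(d5.data.shape[3], 2 * s6)
        d5_down = eng.avgpool2(eng.resize_hw(d5, mh5, mw5))
        fused = eng.concat_channels([d2_down, d5_down, d6])

        fused = eng.dropout(fused, p0, rng, training)
        pooled = eng.spatial_mean(fused)
        pooled = eng.dropout(pooled, p1, rng, training)
        return eng.dense_scalar(pooled, self.params["head.w"], self.params["head.b"])

    def predict(self, static_input: np.ndarray, dynamic_input: np.ndarray) -> np.ndarray:
        """Evaluation-mode waveform, reshaped to (N, T) (or (T,) for one chunk)."""
        single = np.asarray(static_input).ndim == 4
        out = self.forward(static_input, dynamic_input, training=False)
        if single:
            return out.data.copy()
        n = np.asarray(static_input).shape[0]
        return out.data.reshape(n, -1).copy()

    # ------------------------------------------------------------------ #

    def save(self, path) -> None:
        """Single-archive checkpoint: parameters + YAML-serialized config."""
        arrays = {k: v.data for k, v in self.params.items()}
        arrays["config_yaml"] = np.array(yaml.safe_dump(config_to_dict(self.config)))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MDARNetwork":
        with np.load(path, allow_pickle=False) as z:
            config = config_from_dict(yaml.safe_load(str(z["config_yaml"][()])))
            net = cls(config, seed=0)
            for k in net.params:
                net.params[k] = Tensor(z[k].astype(np.float32))
        return net

    def export_config_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(config_to_dict(self.config), fh)


def build_mdar(config: MDARConfig, seed: int = 0) -> MDARNetwork:
    """Construct a parameterized network from a validated config."""
    return MDARNetwork(config, seed=seed)


def count_parameters(model: MDARNetwork) -> int:
    return model.count_parameters()
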