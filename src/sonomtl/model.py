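"""Shared backbone plus independent per-task sigmoid heads.

The model maps a batch of grayscale lesion images to one probability
per configured task: ``bm`` (malignancy), ``alnm`` (nodal metastasis)
and optional nodal-burden thresholds ``burden_ge2/3/4``.  Each head is
a fully connected layer on the globally pooled backbone features with a
sigmoid activation, so scores live in [0, 1] and heads are independent
given the shared features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from sonomtl._nn import DTYPE, Adam, Linear, SmallResNet
from sonomtl.errors import ConfigurationError

VALID_TASKS = ("bm", "alnm", "burden_ge2", "burden_ge3", "burden_ge4")

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class BackboneSpec:
    """Feature-extractor configuration.

    ``small_resnet`` is a four-stage residual CNN (stem plus three
    down-sampling residual blocks, global average pooling); its channel
    widths are configurable.  No pretrained weights are distributed.
    """

    name: str = "small_resnet"
    widths: tuple[int, ...] = (8, 16, 32, 64)
    input_size: int = 48
    pretrained: bool = False

    @property
    def feature_dim(self) -> int:
        return self.widths[-1]

    def validate(self) -> "BackboneSpec":
        if self.name != "small_resnet":
            raise ConfigurationError(
                f"unknown backbone {self.name!r}; this package builds 'small_resnet' "
                "(channel widths configurable via BackboneSpec.widths)"
            )
        if self.pretrained:
            raise ConfigurationError("no pretrained weights are available for small_resnet")
        if len(self.widths) < 2 or any(w < 1 for w in self.widths):
            raise ConfigurationError(f"invalid widths {self.widths}")
        if self.input_size < 8:
            raise ConfigurationError(f"input_size too small: {self.input_size}")
        return self


@dataclass
class MultiTaskScores:
    """Per-sample sigmoid outputs; ``y1`` malignancy, ``y2`` nodal metastasis."""

    y1: float | None = None
    y2: float | None = None
    burden: dict[str, float] = field(default_factory=dict)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MultiTaskModel:
    """Shared ``SmallResNet`` backbone with one sigmoid head per task."""

    def __init__(self, spec: BackboneSpec, tasks: tuple[str, ...],
                 rng: np.random.Generator | None = None):
        spec.validate()
        bad = [t for t in tasks if t not in VALID_TASKS]
        if bad:
            raise ConfigurationError(f"unknown task name(s) {bad}; valid: {VALID_TASKS}")
        if not tasks:
            raise ConfigurationError("tasks must be a nonempty subset of " + str(VALID_TASKS))
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        self.tasks = tuple(tasks)
        self.backbone = SmallResNet(spec.widths, rng=rng)
        self.heads = {t: Linear(spec.feature_dim, 1, rng=rng) for t in self.tasks}
        self._last_probs: dict[str, np.ndarray] = {}

    # -- forward -----------------------------------------------------------
    def _to_batch(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=DTYPE)
        if x.ndim == 2:
            x = x[None]
        n = self.spec.input_size
        if x.ndim != 3 or x.shape[1:] != (n, n):
            raise ValueError(
                f"expected a batch of {n}x{n} grayscale images, got array of shape {x.shape}"
            )
        return (x / 255.0 - 0.5)[:, None, :, :]  # (N, 1, H, W)

    def forward_arrays(self, images: np.ndarray, train: bool = False) -> dict[str, np.ndarray]:
        """Scores per task for a (N, S, S) batch of [0,255] images."""
        feats = self.backbone.forward(self._to_batch(images), train=train)
        self._last_feats = feats
        probs = {}
        for t in self.tasks:
            z = self.heads[t].forward(feats)[:, 0]
            probs[t] = sigmoid(z)
        self._last_probs = probs
        return probs

    def forward(self, images: np.ndarray, train: bool = False) -> list[MultiTaskScores]:
        """Per-sample :class:`MultiTaskScores`, batch order preserved."""
        probs = self.forward_arrays(images, train=train)
        n = len(next(iter(probs.values())))
        out = []
        for i in range(n):
            s = MultiTaskScores()
            if "bm" in probs:
                s.y1 = float(probs["bm"][i])
            if "alnm" in probs:
                s.y2 = float(probs["alnm"][i])
            s.burden = {t: float(probs[t][i]) for t in probs if t.startswith("burden")}
            out.append(s)
        return out

    # -- backward ----------------------------------------------------------
    def backward_from_probs(self, dprobs: dict[str, np.ndarray]) -> None:
        """Backprop given dL/d(probability) per task; accumulates parameter grads."""
        dfeat = np.zeros_like(self._last_feats)
        for t, dp in dprobs.items():
            p = self._last_probs[t]
            dz = (np.asarray(dp) * p * (1.0 - p)).astype(DTYPE)[:, None]
            dfeat += self.heads[t].backward(dz)
        self.backbone.backward(dfeat)

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        out = [(f"backbone.{n}", v, g) for n, v, g in self.backbone.params()]
        for t in self.tasks:
            out += [(f"head_{t}.{n}", v, g) for n, v, g in self.heads[t].params()]
        return out

    def zero_grad(self) -> None:
        for _, _, g in self.params():
            g[...] = 0.0

    def make_optimizer(self) -> Adam:
        return Adam(self.params())

    # -- checkpointing -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {n: v for n, v, _ in self.params()}
        for i, blk in enumerate(self.backbone.blocks):
            for bn_name, bn in [("bn1", blk.bn1), ("bn2", blk.bn2), ("bn_s", blk.bn_s)]:
                state[f"backbone.block{i}.{bn_name}.running_mean"] = bn.running_mean
                state[f"backbone.block{i}.{bn_name}.running_var"] = bn.running_var
        state["backbone.stem_bn.running_mean"] = self.backbone.stem_bn.running_mean
        state["backbone.stem_bn.running_var"] = self.backbone.stem_bn.running_var
        return state

    def save(self, path: str | Path, seed: int | None = None) -> None:
        """Write a versioned checkpoint (npz weights + JSON sidecar config)."""
        path = Path(path)
        np.savez(path, **self.state_arrays())
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "backbone": {"name": self.spec.name, "widths": list(self.spec.widths),
                         "input_size": self.spec.input_size},
            "tasks": list(self.tasks),
            "seed": seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "MultiTaskModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ConfigurationError(f"unsupported checkpoint version {meta['format_version']}")
        spec = BackboneSpec(name=meta["backbone"]["name"],
                            widths=tuple(meta["backbone"]["widths"]),
                            input_size=meta["backbone"]["input_size"])
        model = cls(spec, tuple(meta["tasks"]))
        npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
        with np.load(npz_path) as data:
            state = model.state_arrays()
            for name, arr in state.items():
                arr[...] = data[name]
        return model


def build_model(backbone: BackboneSpec, tasks, seed: int = 0) -> MultiTaskModel:
    """Construct a model with seeded initialization."""
    return MultiTaskModel(backbone, tuple(tasks), rng=np.random.default_rng(seed))
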