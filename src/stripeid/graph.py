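"""Declarative layer graph: specification, shape inference, counting, forward.

A :class:`ModelGraph` is an ordered set of named layer specs.  The spec is
pure data, so parameter counts and output shapes come from closed-form
arithmetic without ever instantiating weights; ``forward`` interprets the
same specs with the autodiff ops, so the counted model and the executed
model cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ops

__all__ = ["LayerSpec", "ModelGraph", "GraphError"]


class GraphError(ValueError):
    """Raised for inconsistent graph structure or shape mismatches."""


@dataclass
class LayerSpec:
    name: str
    kind: str
    inputs: tuple
    attrs: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.attrs[key]

    def get(self, key, default=None):
        return self.attrs.get(key, default)


def _conv_out(side, k, stride, padding):
    if padding == "same":
        return side
    out = (side - k) // stride + 1
    if out < 1:
        raise GraphError(
            f"{side}px side collapses under {k}x{k}/s{stride} valid convolution "
            f"(minimum side is {k})")
    return out


class ModelGraph:
    """Ordered, named layer specifications with named output taps."""

    def __init__(self):
        self.specs: dict[str, LayerSpec] = {}
        self.taps: dict[str, str] = {}
        self.output: str | None = None

    # -- construction -----------------------------------------------------

    def add(self, name: str, kind: str, inputs=(), **attrs) -> str:
        if name in self.specs:
            raise GraphError(f"duplicate layer name {name!r}")
        if isinstance(inputs, str):
            inputs = (inputs,)
        for i in inputs:
            if i not in self.specs:
                raise GraphError(f"layer {name!r} references unknown input {i!r}")
        self.specs[name] = LayerSpec(name, kind, tuple(inputs), attrs)
        self.output = name
        return name

    def tap(self, alias: str, name: str | None = None):
        self.taps[alias] = name or self.output

    def extend(self, other: "ModelGraph", input_name: str):
        """Append ``other``'s layers, rewiring its input node to ``input_name``."""
        remap = {}
        for spec in other.specs.values():
            if spec.kind == "input":
                remap[spec.name] = input_name
                continue
            inputs = tuple(remap.get(i, i) for i in spec.inputs)
            self.add(spec.name, spec.kind, inputs, **dict(spec.attrs))
            remap[spec.name] = spec.name
        for alias, name in other.taps.items():
            self.taps[alias] = remap.get(name, name)

    # -- parameters -------------------------------------------------------

    def param_specs(self) -> dict[str, tuple]:
        """Mapping of parameter key -> array shape (shared keys deduplicated)."""
        out: dict[str, tuple] = {}
        for s in self.specs.values():
            key = s.get("param_key", s.name)
            if s.kind == "conv":
                kh, kw = s["kernel"]
                out[f"{key}.w"] = (kh, kw, s["in_channels"], s["out_channels"])
                if s.get("use_bias", False):
                    out[f"{key}.b"] = (s["out_channels"],)
            elif s.kind == "bn":
                out[f"{key}.beta"] = (s["channels"],)
            elif s.kind == "dense":
                out[f"{key}.w"] = (s["in_features"], s["out_features"])
                if s.get("use_bias", True):
                    out[f"{key}.b"] = (s["out_features"],)
            elif s.kind == "conv1d":
                out[f"{key}.w"] = (s["kernel"],)
        return out

    def param_count(self) -> int:
        """Learnable weights and biases plus batch-norm statistics.

        Batch norm is scale-free: each normalized channel carries a shift
        plus running mean and variance — 3 numbers per channel.
        """
        total = sum(int(np.prod(shape)) for shape in self.param_specs().values())
        seen = set()
        for s in self.specs.values():
            key = s.get("param_key", s.name)
            if s.kind == "bn" and key not in seen:
                seen.add(key)
                total += 2 * s["channels"]
        return total

    def init_params(self, seed: int = 0) -> dict[str, np.ndarray]:
        """He-scaled truncated-normal weights, zero shifts and biases."""
        rng = np.random.default_rng(seed)
        params = {}
        for key, shape in sorted(self.param_specs().items()):
            if key.endswith(".b") or key.endswith(".beta"):
                params[key] = np.zeros(shape, dtype=np.float32)
            elif len(shape) == 4:
                fan_in = shape[0] * shape[1] * shape[2]
                params[key] = _truncated_normal(rng, shape, np.sqrt(2.0 / fan_in))
            elif len(shape) == 2:
                params[key] = _truncated_normal(rng, shape, np.sqrt(2.0 / shape[0]))
            else:
                params[key] = _truncated_normal(rng, shape, 0.1)
        return params

    def init_state(self) -> dict[str, np.ndarray]:
        """Batch-norm running means and variances."""
        state = {}
        for s in self.specs.values():
            key = s.get("param_key", s.name)
            if s.kind == "bn" and f"{key}.mean" not in state:
                state[f"{key}.mean"] = np.zeros(s["channels"], dtype=np.float32)
                state[f"{key}.var"] = np.ones(s["channels"], dtype=np.float32)
        return state

    # -- shapes -----------------------------------------------------------

    def infer_shapes(self, input_shape) -> dict[str, tuple]:
        """Propagate (H, W, C) / (C,) shapes through every layer."""
        shapes: dict[str, tuple] = {}
        for s in self.specs.values():
            try:
                shapes[s.name] = self._shape_of(s, [shapes[i] for i in s.inputs],
                                                tuple(input_shape))
            except GraphError as e:
                raise GraphError(f"layer {s.name!r}: {e}") from None
        return shapes

    @staticmethod
    def _shape_of(s: LayerSpec, ins, input_shape):
        if s.kind == "input":
            return input_shape
        x = ins[0]
        if s.kind == "conv":
            h, w, c = x
            if c != s["in_channels"]:
                raise GraphError(f"expects {s['in_channels']} channels, got {c}")
            kh, kw = s["kernel"]
            st, pad = s.get("stride", 1), s.get("padding", "valid")
            return (_conv_out(h, kh, st, pad), _conv_out(w, kw, st, pad),
                    s["out_channels"])
        if s.kind in ("bn", "relu", "sigmoid", "softmax", "dropout"):
            return x
        if s.kind == "maxpool":
            h, w, c = x
            k, st = s.get("kernel", 3), s.get("stride", 2)
            return (_conv_out(h, k, st, "valid"), _conv_out(w, k, st, "valid"), c)
        if s.kind == "avgpool_same":
            return x
        if s.kind == "concat":
            h, w = x[0], x[1]
            for o in ins[1:]:
                if o[:2] != (h, w):
                    raise GraphError(f"concat spatial mismatch {ins}")
            return (h, w, sum(o[2] for o in ins))
        if s.kind == "resadd":
            if ins[0] != ins[1]:
                raise GraphError(f"residual add shape mismatch {ins[0]} vs {ins[1]}")
            return x
        if s.kind in ("add", "mul"):
            return ins[0] if len(ins[0]) >= len(ins[1]) else ins[1]
        if s.kind in ("gap", "gmp"):
            return (x[2],)
        if s.kind in ("chan_mean", "chan_max"):
            return (x[0], x[1], 1)
        if s.kind == "dense":
            if x[-1] != s["in_features"]:
                raise GraphError(f"expects {s['in_features']} features, got {x[-1]}")
            return (s["out_features"],)
        if s.kind == "conv1d":
            return x
        raise GraphError(f"unknown layer kind {s.kind!r}")

    # -- execution --------------------------------------------------------

    def forward(self, x, params, state, training: bool = False,
                rng: np.random.Generator | None = None,
                wanted: tuple = (), bn_momentum: float = 0.9) -> dict[str, ops.Tensor]:
        """Run the graph; returns the output node plus any ``wanted`` taps."""
        if training and rng is None:
            rng = np.random.default_rng(0)
        values: dict[str, ops.Tensor] = {}
        tensors = {k: ops.Tensor(v, requires_grad=training) for k, v in params.items()}
        for s in self.specs.values():
            ins = [values[i] for i in s.inputs]
            key = s.get("param_key", s.name)
            if s.kind == "input":
                values[s.name] = x if isinstance(x, ops.Tensor) else ops.Tensor(x)
            elif s.kind == "conv":
                values[s.name] = ops.conv2d(
                    ins[0], tensors[f"{key}.w"],
                    tensors.get(f"{key}.b") if s.get("use_bias", False) else None,
                    stride=s.get("stride", 1), padding=s.get("padding", "valid"))
            elif s.kind == "bn":
                values[s.name] = ops.batchnorm(
                    ins[0], tensors[f"{key}.beta"], state[f"{key}.mean"],
                    state[f"{key}.var"], training, momentum=bn_momentum,
                    eps=s.get("eps", 1e-3))
            elif s.kind == "relu":
                values[s.name] = ops.relu(ins[0])
            elif s.kind == "sigmoid":
                values[s.name] = ops.sigmoid(ins[0])
            elif s.kind == "maxpool":
                values[s.name] = ops.maxpool2d(ins[0], s.get("kernel", 3),
                                               s.get("stride", 2))
            elif s.kind == "avgpool_same":
                values[s.name] = ops.avgpool2d_same(ins[0], s.get("kernel", 3))
            elif s.kind == "concat":
                values[s.name] = ops.concat(ins)
            elif s.kind == "resadd":
                values[s.name] = ops.scale_add(ins[0], ins[1], s["scale"])
            elif s.kind == "add":
                values[s.name] = ops.add(ins[0], ins[1])
            elif s.kind == "mul":
                a, b = ins
                # broadcast a channel gate (n, C) or spatial gate (n,H,W,1)
                if b.data.ndim == 2 and a.data.ndim == 4:
                    b = _reshape(b, (b.data.shape[0], 1, 1, b.data.shape[1]))
                values[s.name] = ops.mul(a, b)
            elif s.kind == "gap":
                values[s.name] = ops.global_avg_pool(ins[0])
            elif s.kind == "gmp":
                values[s.name] = ops.global_max_pool(ins[0])
            elif s.kind == "chan_mean":
                values[s.name] = ops.channel_mean(ins[0])
            elif s.kind == "chan_max":
                values[s.name] = ops.channel_max(ins[0])
            elif s.kind == "dense":
                values[s.name] = ops.dense(
                    ins[0], tensors[f"{key}.w"],
                    tensors.get(f"{key}.b") if s.get("use_bias", True) else None)
            elif s.kind == "conv1d":
                values[s.name] = ops.conv1d_channels(ins[0], tensors[f"{key}.w"])
            elif s.kind == "dropout":
                values[s.name] = ops.dropout(ins[0], s["rate"], rng, training)
            elif s.kind == "softmax":
                values[s.name] = ops.softmax(ins[0])
            else:
                raise GraphError(f"unknown layer kind {s.kind!r}")
        result = {"output": values[self.output], "_params": tensors}
        for alias in wanted:
            result[alias] = values[self.taps.get(alias, alias)]
        return result

    # -- reporting --------------------------------------------------------

    def layer_table(self, input_shape) -> list[tuple[str, str, int]]:
        """(layer, output shape, parameter count) rows for every layer."""
        shapes = self.infer_shapes(input_shape)
        pspecs = self.param_specs()
        seen_keys: set[str] = set()
        rows = []
        for s in self.specs.values():
            key = s.get("param_key", s.name)
            count = 0
            if key not in seen_keys:
                for suffix in (".w", ".b", ".beta"):
                    if f"{key}{suffix}" in pspecs:
                        count += int(np.prod(pspecs[f"{key}{suffix}"]))
                if s.kind == "bn":
                    count += 2 * s["channels"]
                seen_keys.add(key)
            shape = shapes[s.name]
            shape_str = "(None, " + ", ".join(str(d) for d in shape) + ")"
            rows.append((f"{s.name} ({s.kind})", shape_str, count))
        return rows


def _reshape(t: ops.Tensor, shape):
    out_data = t.data.reshape(shape)

    def backward():
        if t.grad is None:
            t.grad = np.zeros_like(t.data)
        t.grad += out.grad.reshape(t.data.shape)

    out = ops.Tensor(out_data, requires_grad=t.requires_grad)
    if t.requires_grad:
        out._parents = (t,)
        out._backward = backward
    return out


def _truncated_normal(rng, shape, std):
    """Normal samples re-drawn outside two standard deviations."""
    x = rng.standard_normal(shape)
    bad = np.abs(x) > 2.0
    while bad.any():
        x[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(x) > 2.0
    return (std * x).astype(np.float32)
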