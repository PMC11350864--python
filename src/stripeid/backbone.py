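"""InceptionResNetV2-style feature extractor as a declarative layer graph.

Two dialects are supported:

* ``reference`` — the widely distributed implementation (10 A blocks, 20 B
  blocks, 10 C blocks, residual scales 0.17/0.10/0.20, final 1x1
  convolution to 1536 channels).  At width multiplier 1 this counts exactly
  54,336,736 parameters (convolution weights, residual-projection biases,
  and scale-free batch-norm shift + running statistics).
* ``original`` — the 5/10/5 repetition schema of the original publication
  narrative, sharing the same layer inventory but without the final
  1536-channel projection.

Every convolution is followed by scale-free batch normalization and ReLU
except the residual-merge projections, which carry a bias and stay linear
until the post-merge ReLU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import GraphError, ModelGraph

__all__ = ["ArchConfig", "build_stem", "build_block_a", "build_block_b",
           "build_block_c", "build_reduction_a", "build_reduction_b",
           "build_backbone", "count_parameters", "MIN_INPUT_SIZE"]

#: Smallest input side for which the full backbone (stem plus both
#: reductions) still yields a nonempty feature map.
MIN_INPUT_SIZE = 75

_DIALECTS = {
    "reference": {"repeats": (10, 20, 10), "scales": (0.17, 0.10, 0.20),
                  "final_conv": True},
    "original": {"repeats": (5, 10, 5), "scales": (0.17, 0.10, 0.20),
                 "final_conv": False},
}

@dataclass
class ArchConfig:
    """All architecture knobs for the identification network.

    ``width_multiplier`` scales every channel count (rounded, minimum 1) so
    that desk-scale variants of the full topology can be built and trained;
    ``attention`` selects the gate inserted after the last C block.
    """

    n_classes: int = 107
    input_size: int = 299
    dialect: str = "reference"
    repeats_a: int | None = None
    repeats_b: int | None = None
    repeats_c: int | None = None
    width_multiplier: float = 1.0
    residual_scales: tuple[float, float, float] | None = None
    attention: str = "cbam"
    dropout_rate: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.dialect not in _DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        d = _DIALECTS[self.dialect]
        if self.repeats_a is None:
            self.repeats_a = d["repeats"][0]
        if self.repeats_b is None:
            self.repeats_b = d["repeats"][1]
        if self.repeats_c is None:
            self.repeats_c = d["repeats"][2]
        if self.residual_scales is None:
            self.residual_scales = d["scales"]
        if self.input_size < MIN_INPUT_SIZE:
            raise ValueError(
                f"input_size {self.input_size} is too small: the stem and two "
                f"reductions collapse the map below 1x1 (minimum input_size is "
                f"{MIN_INPUT_SIZE})")
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if min(self.repeats_a, self.repeats_b, self.repeats_c) < 1:
            raise ValueError("block repeat counts must be positive")
        if self.attention not in ("none", "se", "eca", "cbam"):
            raise ValueError(f"unknown attention kind {self.attention!r}")
        for s in self.residual_scales:
            if not 0.0 < s <= 1.0:
                raise ValueError("residual scales must lie in (0, 1]")

    def width(self, channels: int) -> int:
        """Apply the width multiplier, keeping every branch nonempty."""
        return max(1, round(self.width_multiplier * channels))

    @classmethod
    def tiny(cls, n_classes: int, input_size: int = 96, **kw) -> "ArchConfig":
        """A desk-scale variant: 1/8 width, one block of each type."""
        kw.setdefault("width_multiplier", 0.125)
        kw.setdefault("repeats_a", 1)
        kw.setdefault("repeats_b", 1)
        kw.setdefault("repeats_c", 1)
        return cls(n_classes=n_classes, input_size=input_size, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model config keys: {sorted(unknown)}")
        if "residual_scales" in d and d["residual_scales"] is not None:
            d = dict(d, residual_scales=tuple(d["residual_scales"]))
        return cls(**d)


# ---------------------------------------------------------------------------
# builder helpers


def _conv_bn(g: ModelGraph, name: str, src: str, cin: int, cout: int,
             kernel=(3, 3), stride=1, padding="valid") -> str:
    g.add(f"{name}_conv", "conv", src, kernel=tuple(kernel), stride=stride,
          padding=padding, in_channels=cin, out_channels=cout, use_bias=False)
    g.add(f"{name}_bn", "bn", f"{name}_conv", channels=cout)
    g.add(f"{name}_relu", "relu", f"{name}_bn")
    return f"{name}_relu"


def _new_graph() -> ModelGraph:
    g = ModelGraph()
    g.add("input", "input")
    return g


def build_stem(cfg: ArchConfig) -> ModelGraph:
    """conv/s2, conv, conv(same), maxpool, 1x1 conv, conv, maxpool."""
    g = _new_graph()
    w = cfg.width
    t = _conv_bn(g, "stem1", "input", 3, w(32), stride=2)
    t = _conv_bn(g, "stem2", t, w(32), w(32))
    t = _conv_bn(g, "stem3", t, w(32), w(64), padding="same")
    g.add("stem_pool1", "maxpool", t)
    t = _conv_bn(g, "stem4", "stem_pool1", w(64), w(80), kernel=(1, 1))
    t = _conv_bn(g, "stem5", t, w(80), w(192))
    g.add("stem_pool2", "maxpool", t)
    g.tap("stem")
    return g


def _append_base(g: ModelGraph, src: str, cfg: ArchConfig) -> tuple[str, int]:
    """Multi-branch base stage widening the stem output (192 -> 320 ch)."""
    w = cfg.width
    cin = w(192)
    b0 = _conv_bn(g, "base_b0", src, cin, w(96), kernel=(1, 1))
    t = _conv_bn(g, "base_b1a", src, cin, w(48), kernel=(1, 1))
    b1 = _conv_bn(g, "base_b1b", t, w(48), w(64), kernel=(5, 5), padding="same")
    t = _conv_bn(g, "base_b2a", src, cin, w(64), kernel=(1, 1))
    t = _conv_bn(g, "base_b2b", t, w(64), w(96), padding="same")
    b2 = _conv_bn(g, "base_b2c", t, w(96), w(96), padding="same")
    g.add("base_pool", "avgpool_same", src)
    b3 = _conv_bn(g, "base_b3", "base_pool", cin, w(64), kernel=(1, 1))
    g.add("base_concat", "concat", (b0, b1, b2, b3))
    return "base_concat", w(96) + w(64) + w(96) + w(64)


_BLOCK_WIDTHS = {
    # branch channel widths and nominal input width per block type
    "a": {"cin": 320, "branches": [[(32, (1, 1))],
                                   [(32, (1, 1)), (32, (3, 3))],
                                   [(32, (1, 1)), (48, (3, 3)), (64, (3, 3))]]},
    "b": {"cin": 1088, "branches": [[(192, (1, 1))],
                                    [(128, (1, 1)), (160, (1, 7)), (192, (7, 1))]]},
    "c": {"cin": 2080, "branches": [[(192, (1, 1))],
                                    [(192, (1, 1)), (224, (1, 3)), (256, (3, 1))]]},
}


def _append_block(g: ModelGraph, src: str, cfg: ArchConfig, block_type: str,
                  name: str, in_channels: int, scale: float) -> str:
    """Residual multi-branch block: branches, concat, 1x1 projection,
    scaled add to the input, ReLU."""
    w = cfg.width
    spec = _BLOCK_WIDTHS[block_type]
    ends, widths = [], []
    for bi, branch in enumerate(spec["branches"]):
        t, c = src, in_channels
        for li, (cout, kernel) in enumerate(branch):
            pad = "valid" if kernel == (1, 1) else "same"
            t = _conv_bn(g, f"{name}_b{bi}l{li}", t, c, w(cout), kernel=kernel,
                         padding=pad)
            c = w(cout)
        ends.append(t)
        widths.append(c)
    g.add(f"{name}_concat", "concat", tuple(ends))
    g.add(f"{name}_up", "conv", f"{name}_concat", kernel=(1, 1),
          in_channels=sum(widths), out_channels=in_channels, use_bias=True)
    g.add(f"{name}_res", "resadd", (src, f"{name}_up"), scale=scale)
    g.add(f"{name}_relu", "relu", f"{name}_res")
    return f"{name}_relu"


def _standalone_block(cfg: ArchConfig, block_type: str, in_channels=None):
    spec = _BLOCK_WIDTHS[block_type]
    cin = in_channels if in_channels is not None else cfg.width(spec["cin"])
    g = _new_graph()
    scale = cfg.residual_scales["abc".index(block_type)]
    _append_block(g, "input", cfg, block_type, f"block_{block_type}", cin, scale)
    g.tap(f"block_{block_type}")
    return g


def build_block_a(cfg: ArchConfig, in_channels: int | None = None) -> ModelGraph:
    """Shape-preserving residual block operating on the 35x35 stage."""
    return _standalone_block(cfg, "a", in_channels)


def build_block_b(cfg: ArchConfig, in_channels: int | None = None) -> ModelGraph:
    return _standalone_block(cfg, "b", in_channels)


def build_block_c(cfg: ArchConfig, in_channels: int | None = None) -> ModelGraph:
    return _standalone_block(cfg, "c", in_channels)


def _append_reduction_a(g: ModelGraph, src: str, cfg: ArchConfig,
                        in_channels: int) -> tuple[str, int]:
    w = cfg.width
    b0 = _conv_bn(g, "reda_b0", src, in_channels, w(384), stride=2)
    t = _conv_bn(g, "reda_b1a", src, in_channels, w(256), kernel=(1, 1))
    t = _conv_bn(g, "reda_b1b", t, w(256), w(256), padding="same")
    b1 = _conv_bn(g, "reda_b1c", t, w(256), w(384), stride=2)
    g.add("reda_pool", "maxpool", src)
    g.add("reda_concat", "concat", (b0, b1, "reda_pool"))
    return "reda_concat", w(384) + w(384) + in_channels


def _append_reduction_b(g: ModelGraph, src: str, cfg: ArchConfig,
                        in_channels: int) -> tuple[str, int]:
    w = cfg.width
    t = _conv_bn(g, "redb_b0a", src, in_channels, w(256), kernel=(1, 1))
    b0 = _conv_bn(g, "redb_b0b", t, w(256), w(384), stride=2)
    t = _conv_bn(g, "redb_b1a", src, in_channels, w(256), kernel=(1, 1))
    b1 = _conv_bn(g, "redb_b1b", t, w(256), w(288), stride=2)
    t = _conv_bn(g, "redb_b2a", src, in_channels, w(256), kernel=(1, 1))
    t = _conv_bn(g, "redb_b2b", t, w(256), w(288), padding="same")
    b2 = _conv_bn(g, "redb_b2c", t, w(288), w(320), stride=2)
    g.add("redb_pool", "maxpool", src)
    g.add("redb_concat", "concat", (b0, b1, b2, "redb_pool"))
    return "redb_concat", w(384) + w(288) + w(320) + in_channels


def build_reduction_a(cfg: ArchConfig, in_channels: int | None = None) -> ModelGraph:
    """Strided three-branch stage halving the spatial side (35 -> 17)."""
    g = _new_graph()
    cin = in_channels if in_channels is not None else cfg.width(320)
    _append_reduction_a(g, "input", cfg, cin)
    g.tap("reduction_a")
    return g


def build_reduction_b(cfg: ArchConfig, in_channels: int | None = None) -> ModelGraph:
    g = _new_graph()
    cin = in_channels if in_channels is not None else cfg.width(1088)
    _append_reduction_b(g, "input", cfg, cin)
    g.tap("reduction_b")
    return g


def build_backbone(cfg: ArchConfig) -> ModelGraph:
    """stem -> base stage -> A blocks -> Reduction-A -> B blocks ->
    Reduction-B -> C blocks (-> 1x1 conv to 1536 in the reference dialect)."""
    g = build_stem(cfg)
    src = "stem_pool2"
    src, c = _append_base(g, src, cfg)
    sa, sb, sc = cfg.residual_scales
    for i in range(cfg.repeats_a):
        src = _append_block(g, src, cfg, "a", f"a{i + 1}", c, sa)
    src, c = _append_reduction_a(g, src, cfg, c)
    g.tap("reduction_a", src)
    for i in range(cfg.repeats_b):
        src = _append_block(g, src, cfg, "b", f"b{i + 1}", c, sb)
    src, c = _append_reduction_b(g, src, cfg, c)
    g.tap("reduction_b", src)
    for i in range(cfg.repeats_c):
        src = _append_block(g, src, cfg, "c", f"c{i + 1}", c, sc)
    if _DIALECTS[cfg.dialect]["final_conv"]:
        src = _conv_bn(g, "final", src, c, cfg.width(1536), kernel=(1, 1))
    g.tap("backbone", src)
    g.output = src
    return g


def backbone_channels(cfg: ArchConfig) -> int:
    """Channel count of the backbone output feature map."""
    if _DIALECTS[cfg.dialect]["final_conv"]:
        return cfg.width(1536)
    w = cfg.width
    base = w(96) + w(64) + w(96) + w(64)
    after_a = w(384) + w(384) + base
    return w(384) + w(288) + w(320) + after_a


def count_parameters(g: ModelGraph) -> int:
    """Learnable weights/biases plus batch-norm running statistics."""
    return g.param_count()


def stem_output_size(input_size: int) -> int:
    """Closed-form spatial side of the stem output."""
    s = input_size
    s = (s - 3) // 2 + 1      # 3x3/s2 valid
    s = s - 2                 # 3x3 valid
    s = (s - 3) // 2 + 1      # maxpool3/s2
    s = s - 2                 # 3x3 valid
    s = (s - 3) // 2 + 1      # maxpool3/s2
    if s < 1:
        raise GraphError(f"input {input_size} collapses in the stem")
    return s
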