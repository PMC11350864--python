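"""Channel and spatial attention gates: SE, ECA, and CBAM.

CBAM refines a feature map sequentially: a channel gate computed from
average- and max-pooled descriptors through a shared bias-free bottleneck
MLP, then a spatial gate computed by a bias-free k x k convolution over the
stacked channel-mean and channel-max maps.  SE is the channel gate alone
(average pool only); ECA replaces the MLP with a local 1-D convolution
across channels.

Two surfaces are provided: plain-numpy functions operating on a single
H x W x C feature map (`channel_attention`, `spatial_attention`,
`apply_cbam`, ...) and graph builders (`append_attention`) that insert the
same computation into a trainable :class:`~stripeid.graph.ModelGraph`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import ModelGraph

__all__ = ["AttentionConfig", "init_attention_params", "channel_attention",
           "spatial_attention", "apply_cbam", "apply_se", "apply_eca",
           "attention_param_count", "append_attention"]


@dataclass
class AttentionConfig:
    kind: str  # se | eca | cbam
    channels: int
    reduction_ratio: int = 8
    spatial_kernel: int = 7
    eca_kernel: int = 3
    use_bias: bool = False

    def __post_init__(self):
        if self.kind not in ("se", "eca", "cbam"):
            raise ValueError(f"unknown attention kind {self.kind!r}")
        if self.channels < 1:
            raise ValueError("channels must be positive")
        if self.kind in ("se", "cbam") and self.channels % self.reduction_ratio:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by the "
                f"reduction ratio ({self.reduction_ratio})")
        if self.spatial_kernel % 2 == 0 or self.eca_kernel % 2 == 0:
            raise ValueError("attention kernels must be odd")

    @property
    def hidden(self) -> int:
        return self.channels // self.reduction_ratio


def init_attention_params(cfg: AttentionConfig, seed: int = 0) -> dict:
    """Random weights for the functional surface (standard normal * 0.1)."""
    rng = np.random.default_rng(seed)
    c, h = cfg.channels, cfg.hidden if cfg.kind != "eca" else 0
    p: dict[str, np.ndarray] = {}
    if cfg.kind in ("se", "cbam"):
        p["mlp_w1"] = 0.1 * rng.standard_normal((c, h)).astype(np.float32)
        p["mlp_w2"] = 0.1 * rng.standard_normal((h, c)).astype(np.float32)
        if cfg.use_bias:
            p["mlp_b1"] = np.zeros(h, dtype=np.float32)
            p["mlp_b2"] = np.zeros(c, dtype=np.float32)
    if cfg.kind == "cbam":
        k = cfg.spatial_kernel
        p["spatial_w"] = 0.1 * rng.standard_normal((k, k, 2, 1)).astype(np.float32)
    if cfg.kind == "eca":
        p["eca_w"] = 0.1 * rng.standard_normal(cfg.eca_kernel).astype(np.float32)
    return p


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _mlp(v, params, cfg):
    h = v @ params["mlp_w1"]
    if cfg.use_bias:
        h = h + params["mlp_b1"]
    h = np.maximum(h, 0.0)
    out = h @ params["mlp_w2"]
    if cfg.use_bias:
        out = out + params["mlp_b2"]
    return out


def channel_attention(F, params, cfg: AttentionConfig):
    """Channel gate in (0,1)^C: sigmoid(MLP(avgpool F) + MLP(maxpool F))."""
    F = np.asarray(F, dtype=np.float32)
    if F.shape[-1] != cfg.channels:
        raise ValueError(f"feature map has {F.shape[-1]} channels, "
                         f"config expects {cfg.channels}")
    avg = F.mean(axis=(0, 1))
    mx = F.max(axis=(0, 1))
    if cfg.kind == "eca":
        k, w = cfg.eca_kernel, params["eca_w"]
        p = (k - 1) // 2
        vp = np.pad(avg, (p, p))
        z = np.zeros_like(avg)
        for i in range(k):
            z += w[i] * vp[i:i + cfg.channels]
        return _sigmoid(z)
    z = _mlp(avg, params, cfg)
    if cfg.kind == "cbam":
        z = z + _mlp(mx, params, cfg)
    return _sigmoid(z)


def spatial_attention(F, params, cfg: AttentionConfig):
    """Spatial gate in (0,1)^{H x W} from the [mean; max] channel stack."""
    F = np.asarray(F, dtype=np.float32)
    stack = np.stack([F.mean(axis=-1), F.max(axis=-1)], axis=-1)  # H, W, 2
    k = cfg.spatial_kernel
    p = (k - 1) // 2
    sp = np.pad(stack, ((p, p), (p, p), (0, 0)))
    h, w = F.shape[:2]
    z = np.zeros((h, w), dtype=np.float32)
    W = params["spatial_w"]
    for a in range(k):
        for b in range(k):
            z += sp[a:a + h, b:b + w, :] @ W[a, b, :, 0]
    return _sigmoid(z)


def apply_cbam(F, params, cfg: AttentionConfig):
    """Sequential gating: F' = Mc(F) * F, then F'' = Ms(F') * F'."""
    F = np.asarray(F, dtype=np.float32)
    mc = channel_attention(F, params, cfg)
    F1 = F * mc[None, None, :]
    ms = spatial_attention(F1, params, cfg)
    return F1 * ms[:, :, None]


def apply_se(F, params, cfg: AttentionConfig):
    """Channel-only gate from the average-pooled descriptor."""
    F = np.asarray(F, dtype=np.float32)
    z = _mlp(F.mean(axis=(0, 1)), params, cfg)
    return F * _sigmoid(z)[None, None, :]


def apply_eca(F, params, cfg: AttentionConfig):
    F = np.asarray(F, dtype=np.float32)
    return F * channel_attention(F, params, cfg)[None, None, :]


def attention_param_count(cfg: AttentionConfig) -> int:
    """Closed-form parameter count for an attention gate.

    cbam: 2 * C * (C/r) shared-MLP weights + k*k*2 spatial-conv weights;
    se:   2 * C * (C/r) (+ C/r + C biases if enabled);
    eca:  the 1-D kernel alone.
    """
    if cfg.kind == "eca":
        return cfg.eca_kernel
    count = 2 * cfg.channels * cfg.hidden
    if cfg.use_bias:
        count += cfg.hidden + cfg.channels
    if cfg.kind == "cbam":
        count += cfg.spatial_kernel ** 2 * 2
    return count


# ---------------------------------------------------------------------------
# graph builders


def append_attention(g: ModelGraph, src: str, cfg: AttentionConfig,
                     prefix: str = "att") -> str:
    """Insert the configured attention gate after node ``src``."""
    if cfg.kind in ("se", "cbam"):
        src = _append_channel_gate(g, src, cfg, prefix)
    if cfg.kind == "eca":
        g.add(f"{prefix}_gap", "gap", src)
        g.add(f"{prefix}_conv1d", "conv1d", f"{prefix}_gap", kernel=cfg.eca_kernel)
        g.add(f"{prefix}_sig", "sigmoid", f"{prefix}_conv1d")
        g.add(f"{prefix}_gate", "mul", (src, f"{prefix}_sig"))
        src = f"{prefix}_gate"
    if cfg.kind == "cbam":
        src = _append_spatial_gate(g, src, cfg, prefix)
    return src


def _append_channel_gate(g, src, cfg, prefix):
    c, h = cfg.channels, cfg.hidden
    g.add(f"{prefix}_gap", "gap", src)
    g.add(f"{prefix}_fc1a", "dense", f"{prefix}_gap", in_features=c,
          out_features=h, use_bias=cfg.use_bias, param_key=f"{prefix}_fc1")
    g.add(f"{prefix}_relu_a", "relu", f"{prefix}_fc1a")
    g.add(f"{prefix}_fc2a", "dense", f"{prefix}_relu_a", in_features=h,
          out_features=c, use_bias=cfg.use_bias, param_key=f"{prefix}_fc2")
    branch = f"{prefix}_fc2a"
    if cfg.kind == "cbam":  # max-pooled path through the shared MLP
        g.add(f"{prefix}_gmp", "gmp", src)
        g.add(f"{prefix}_fc1m", "dense", f"{prefix}_gmp", in_features=c,
              out_features=h, use_bias=cfg.use_bias, param_key=f"{prefix}_fc1")
        g.add(f"{prefix}_relu_m", "relu", f"{prefix}_fc1m")
        g.add(f"{prefix}_fc2m", "dense", f"{prefix}_relu_m", in_features=h,
              out_features=c, use_bias=cfg.use_bias, param_key=f"{prefix}_fc2")
        g.add(f"{prefix}_sum", "add", (branch, f"{prefix}_fc2m"))
        branch = f"{prefix}_sum"
    g.add(f"{prefix}_csig", "sigmoid", branch)
    g.add(f"{prefix}_cgate", "mul", (src, f"{prefix}_csig"))
    return f"{prefix}_cgate"


def _append_spatial_gate(g, src, cfg, prefix):
    g.add(f"{prefix}_mean", "chan_mean", src)
    g.add(f"{prefix}_max", "chan_max", src)
    g.add(f"{prefix}_stack", "concat", (f"{prefix}_mean", f"{prefix}_max"))
    g.add(f"{prefix}_sconv", "conv", f"{prefix}_stack",
          kernel=(cfg.spatial_kernel, cfg.spatial_kernel), padding="same",
          in_channels=2, out_channels=1, use_bias=False)
    g.add(f"{prefix}_ssig", "sigmoid", f"{prefix}_sconv")
    g.add(f"{prefix}_sgate", "mul", (src, f"{prefix}_ssig"))
    return f"{prefix}_sgate"
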