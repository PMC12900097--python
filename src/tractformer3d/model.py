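"""The 3D TractFormer network.

A symmetric 4-level U-shaped encoder-decoder in which convolutions and
channel-wise transformer blocks are interleaved. Each transformer block is
multi-head convolution-based channel-wise attention (MCCA) followed by a
context-enhanced feed-forward network (CFFN):

  MCCA:  Q = pool_r(dsQ(F)), K = pool_r(dsK(F)), V = dsV(F)
         F' = refine(Softmax(Q' K'^T * alpha) V') + F
  CFFN:  F'' = project(dsA(F') * GELU(dsB(F'))) + F'

where ds* are depthwise-separable convolutions (3^3 depthwise + 1^3
pointwise), pool_r is max pooling with factor r, and the attention map is
channel-by-channel (C' x C' per head), so its cost is linear in voxel count
and reduced by r^3 through the pooling of Q and K. alpha is a learnable
positive per-head scalar multiplying the attention logits.

Default architectural choices that the configuration record exposes as flags
(feed-forward expansion, separable stride-2 resampling, additive skip
fusion, encoder-only transformer blocks, pre-norm) were fixed by calibrating
the analytic parameter count against the published complexity figures; see
docs/methods.md and scripts/calibrate_complexity.py.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .io_volumes import PeakVolume, TractLabelVolume
from .nn import functional as F

# Feed-forward expansion calibrated so the published configuration counts
# 8.84 M trainable parameters (see scripts/calibrate_complexity.py).
CALIBRATED_FFN_EXPANSION = 2.2625

__all__ = ["NetworkConfig", "CALIBRATED_FFN_EXPANSION", "MCCA", "CFFN",
           "TransformerBlock", "TractFormerNet", "build_network",
           "threshold_probabilities", "save_network", "load_network",
           "published_config", "tiny_config"]


@dataclass(frozen=True)
class NetworkConfig:
    """Complete architectural hyperparameter record."""

    in_channels: int = 9
    out_channels: int = 72
    level_channels: tuple[int, ...] = (36, 72, 144, 288)
    blocks_per_level: tuple[int, ...] = (1, 2, 4, 8)
    heads_per_level: tuple[int, ...] = (1, 2, 4, 8)
    pool_factor: int = 2
    conv_kernel: int = 3
    resample_kernel: int = 4
    resample_stride: int = 2
    ffn_expansion: float = CALIBRATED_FFN_EXPANSION
    use_norm: bool = True
    qk_l2_normalize: bool = False
    resample_mode: str = "separable"      # "separable" | "dense"
    skip_fusion: str = "add"              # "add" | "concat1" | "concat3"
    decoder_blocks_mirrored: bool = False
    head_bias: bool = True
    threshold: float = 0.5
    nominal_patch: int = 64               # sets the alpha initialization scale

    def __post_init__(self):
        L = len(self.level_channels)
        if not (len(self.blocks_per_level) == len(self.heads_per_level) == L):
            raise ValueError("level_channels, blocks_per_level and "
                             "heads_per_level must have equal length")
        for c, h in zip(self.level_channels, self.heads_per_level):
            if c % h:
                raise ValueError(f"channels {c} not divisible by heads {h}")
        if self.pool_factor < 1:
            raise ValueError("pool_factor must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.ffn_expansion <= 0:
            raise ValueError("ffn_expansion must be positive")
        if self.resample_mode not in ("separable", "dense"):
            raise ValueError(f"unknown resample_mode {self.resample_mode!r}")
        if self.skip_fusion not in ("add", "concat1", "concat3"):
            raise ValueError(f"unknown skip_fusion {self.skip_fusion!r}")

    @property
    def n_levels(self) -> int:
        return len(self.level_channels)

    def ffn_hidden(self, c: int) -> int:
        return max(1, int(round(self.ffn_expansion * c)))

    @property
    def divisibility(self) -> int:
        """Input spatial dims must be divisible by this for an exact pass."""
        return 2 ** (self.n_levels - 1) * self.pool_factor

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for k in ("level_channels", "blocks_per_level", "heads_per_level"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def published_config(**overrides) -> NetworkConfig:
    """The published 4-level configuration (72 tracts, 9 peak channels)."""
    return NetworkConfig(**overrides)


def tiny_config(**overrides) -> NetworkConfig:
    """A desk-scale configuration for tests and demos."""
    kw = dict(
        out_channels=6,
        level_channels=(8, 16, 32, 64),
        blocks_per_level=(1, 1, 2, 2),
        heads_per_level=(1, 2, 4, 8),
        ffn_expansion=2.0,
        nominal_patch=32,
    )
    kw.update(overrides)
    return NetworkConfig(**kw)


class MCCA(nn.Module):
    """Multi-head convolution-based channel-wise attention."""

    def __init__(self, c: int, heads: int, cfg: NetworkConfig,
                 rng: np.random.Generator, level: int):
        self.c, self.heads, self.r = c, heads, cfg.pool_factor
        self.qk_l2_normalize = cfg.qk_l2_normalize
        k = cfg.conv_kernel
        self.norm = nn.ChannelLayerNorm(c) if cfg.use_norm else None
        self.ds_q = nn.SeparableConv3d(c, c, k, rng)
        self.ds_k = nn.SeparableConv3d(c, c, k, rng)
        self.ds_v = nn.SeparableConv3d(c, c, k, rng)
        self.refine = nn.Conv3d(c, c, 1, rng, bias=False, init="zero")
        tokens = max((cfg.nominal_patch // 2 ** level) ** 3 // self.r ** 3, 1)
        self.alpha = nn.parameter(np.full((heads, 1, 1), tokens ** -0.5))

    def _heads(self, x: nn.Tensor, n: int) -> nn.Tensor:
        # (B,H,W,D,C) -> (B,h,C/h,N)
        B = x.shape[0]
        return (x.reshape(B, n, self.c).transpose(0, 2, 1)
                .reshape(B, self.heads, self.c // self.heads, n))

    def forward(self, x: nn.Tensor, return_attention: bool = False):
        B, H, W, D, C = x.shape
        if H % self.r or W % self.r or D % self.r:
            raise ValueError(f"spatial dims {(H, W, D)} not divisible by "
                             f"pool factor {self.r}")
        y = self.norm(x) if self.norm is not None else x
        q = F.max_pool3d(self.ds_q(y), self.r)
        k = F.max_pool3d(self.ds_k(y), self.r)
        v = self.ds_v(y)
        n, np_ = H * W * D, (H // self.r) * (W // self.r) * (D // self.r)
        qp = self._heads(q, np_)
        kp = self._heads(k, np_)
        vp = self._heads(v, n)
        if self.qk_l2_normalize:
            qp = qp * nn.Tensor(1.0 / (np.linalg.norm(qp.data, axis=-1,
                                                      keepdims=True) + 1e-8))
            kp = kp * nn.Tensor(1.0 / (np.linalg.norm(kp.data, axis=-1,
                                                      keepdims=True) + 1e-8))
        logits = qp.matmul(kp.transpose(0, 1, 3, 2)) * self.alpha
        attn = F.softmax(logits, axis=-1)
        out = attn.matmul(vp)                      # (B,h,C/h,N)
        out = (out.reshape(B, C, n).transpose(0, 2, 1)
               .reshape(B, H, W, D, C))
        result = self.refine(out) + x
        if return_attention:
            return result, attn.data
        return result


class CFFN(nn.Module):
    """Context-enhanced feed-forward network with a GELU gate."""

    def __init__(self, c: int, cfg: NetworkConfig, rng: np.random.Generator):
        hidden = cfg.ffn_hidden(c)
        k = cfg.conv_kernel
        self.norm = nn.ChannelLayerNorm(c) if cfg.use_norm else None
        self.ds_a = nn.SeparableConv3d(c, hidden, k, rng)
        self.ds_b = nn.SeparableConv3d(c, hidden, k, rng)
        self.project = nn.Conv3d(hidden, c, 1, rng, bias=False, init="zero")

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        y = self.norm(x) if self.norm is not None else x
        gated = self.ds_a(y) * F.gelu(self.ds_b(y))
        return self.project(gated) + x


class TransformerBlock(nn.Module):
    """One channel-wise transformer block: MCCA then CFFN (pre-norm)."""

    def __init__(self, c: int, heads: int, cfg: NetworkConfig,
                 rng: np.random.Generator, level: int):
        self.mcca = MCCA(c, heads, cfg, rng, level)
        self.cffn = CFFN(c, cfg, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.cffn(self.mcca(x))


class _Fusion(nn.Module):
    """Skip fusion at a decoder level: addition or concat + conv."""

    def __init__(self, c: int, cfg: NetworkConfig, rng: np.random.Generator):
        self.mode = cfg.skip_fusion
        if self.mode == "concat1":
            self.conv = nn.Conv3d(2 * c, c, 1, rng, bias=True)
        elif self.mode == "concat3":
            self.conv = nn.Conv3d(2 * c, c, cfg.conv_kernel, rng,
                                  padding=cfg.conv_kernel // 2, bias=True)

    def forward(self, up: nn.Tensor, skip: nn.Tensor) -> nn.Tensor:
        if self.mode == "add":
            return up + skip
        return self.conv(F.concat_channels(up, skip))


class TractFormerNet(nn.Module):
    """Encoder-decoder network; see the module docstring for the layout."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        L = cfg.n_levels
        k, rk, rs = cfg.conv_kernel, cfg.resample_kernel, cfg.resample_stride
        ch = cfg.level_channels
        self.conv_in = nn.Conv3d(cfg.in_channels, ch[0], k, rng,
                                 padding=k // 2, bias=False)
        self.encoder_blocks = [
            [TransformerBlock(ch[l], cfg.heads_per_level[l], cfg, rng, l)
             for _ in range(cfg.blocks_per_level[l])]
            for l in range(L)
        ]
        down_cls = (nn.SeparableConv3d if cfg.resample_mode == "separable"
                    else nn.Conv3d)
        self.downs = [
            down_cls(ch[l], ch[l + 1], rk, rng, stride=rs, padding=(rk - rs) // 2,
                     bias=False)
            for l in range(L - 1)
        ]
        up_cls = (nn.SeparableConvTranspose3d if cfg.resample_mode == "separable"
                  else nn.ConvTranspose3d)
        self.ups = [
            up_cls(ch[l + 1], ch[l], rk, rng, stride=rs, padding=(rk - rs) // 2,
                   bias=False)
            for l in reversed(range(L - 1))
        ]
        self.fusions = [_Fusion(ch[l], cfg, rng) for l in reversed(range(L - 1))]
        if cfg.decoder_blocks_mirrored:
            self.decoder_blocks = [
                [TransformerBlock(ch[l], cfg.heads_per_level[l], cfg, rng, l)
                 for _ in range(cfg.blocks_per_level[l])]
                for l in reversed(range(L - 1))
            ]
        else:
            self.decoder_blocks = [[] for _ in range(L - 1)]
        self.head = nn.Conv3d(ch[0], cfg.out_channels, k, rng,
                              padding=k // 2, bias=cfg.head_bias, init="small")

    # -- core passes ----------------------------------------------------------
    def logits(self, x: nn.Tensor) -> nn.Tensor:
        """Batched logits for spatial dims already divisible by the factor."""
        cfg = self.cfg
        L = cfg.n_levels
        y = self.conv_in(x)
        skips = []
        for l in range(L):
            for blk in self.encoder_blocks[l]:
                y = blk(y)
            if l < L - 1:
                skips.append(y)
                y = self.downs[l](y)
        for i, l in enumerate(reversed(range(L - 1))):
            y = self.ups[i](y)
            y = self.fusions[i](y, skips[l])
            for blk in self.decoder_blocks[i]:
                y = blk(y)
        return self.head(y)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return F.sigmoid(self.logits(x))

    # -- whole-volume inference ----------------------------------------------
    def predict_proba(self, peaks: PeakVolume | np.ndarray) -> np.ndarray:
        """Whole-volume inference; arbitrary spatial dims (internal symmetric
        zero-pad to the divisibility factor, output cropped back)."""
        arr = peaks.data if isinstance(peaks, PeakVolume) else np.asarray(peaks)
        if arr.ndim != 4 or arr.shape[3] != self.cfg.in_channels:
            raise ValueError(
                f"expected H x W x D x {self.cfg.in_channels} input, "
                f"got shape {arr.shape}")
        d = self.cfg.divisibility
        pads = []
        for n in arr.shape[:3]:
            total = (-n) % d
            pads.append((total // 2, total - total // 2))
        with nn.no_grad():
            x = nn.Tensor(arr[None])
            if any(lo or hi for lo, hi in pads):
                x = F.pad_spatial(x, tuple(pads))
            prob = self.forward(x).data[0]
        sl = tuple(slice(lo, lo + n) for (lo, _), n in zip(pads, arr.shape[:3]))
        return prob[sl]

    def predict(self, peaks: PeakVolume | np.ndarray) -> TractLabelVolume:
        prob = self.predict_proba(peaks)
        affine = peaks.affine if isinstance(peaks, PeakVolume) else np.eye(4)
        spacing = peaks.spacing if isinstance(peaks, PeakVolume) else (1.0,) * 3
        lab = threshold_probabilities(prob, self.cfg.threshold)
        return TractLabelVolume(lab, spacing, affine)


def build_network(cfg: NetworkConfig, rng: np.random.Generator | int = 0
                  ) -> TractFormerNet:
    """Construct a network with deterministic weight initialization."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return TractFormerNet(cfg, rng)


def threshold_probabilities(prob: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Binarize probabilities: a voxel-channel is set iff prob > tau (strict)."""
    if not 0.0 < tau < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    prob = np.asarray(prob)
    if prob.min() < 0.0 or prob.max() > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    return (prob > tau).astype(np.uint8)


def save_network(net: TractFormerNet, path: str | Path) -> None:
    """Serialize weights (npz) with a JSON config sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **net.state_dict())
    path.with_suffix(".json").write_text(
        json.dumps(net.cfg.to_dict(), indent=2))


def load_network(path: str | Path) -> TractFormerNet:
    path = Path(path)
    cfg = NetworkConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
    net = build_network(cfg, 0)
    with np.load(path.with_suffix(".npz")) as st:
        net.load_state_dict(dict(st))
    return net
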