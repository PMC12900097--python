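"""Analytic parameter / MAC / FLOP accounting.

Counts are derived from the architectural configuration alone (nothing is
executed). Conventions:

* one MAC = one multiply + one accumulate; only convolutions and the two
  attention matrix products contribute MACs. Depthwise and pointwise parts
  of separable convolutions are counted separately, each at the actual
  feature resolution where it runs. Transposed convolutions are counted as
  Cin * Cout * k^3 multiplies per *input* voxel (the true multiply count of
  the scatter form).
* FLOPs = 2 x MACs plus itemized elementwise work: bias and residual
  additions, gating multiplies, GELU (4 FLOPs/element), sigmoid
  (4 FLOPs/element), softmax exp/sum/divide, max-pool comparisons, and
  layer-norm arithmetic (5 FLOPs/element/pass).

The walk below enumerates exactly the layers the network builder creates,
and the test suite asserts that the analytic parameter total equals the
constructed network's trainable-scalar count.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .model import NetworkConfig

__all__ = ["Component", "ComplexityReport", "count_parameters",
           "count_macs", "count_flops", "complexity_report"]

GELU_FLOPS_PER_ELEMENT = 4
SIGMOID_FLOPS_PER_ELEMENT = 4
NORM_FLOPS_PER_ELEMENT = 5


@dataclass(frozen=True)
class Component:
    name: str
    params: int
    macs: int
    eflops: int  # elementwise FLOPs beyond 2*macs

    @property
    def flops(self) -> int:
        return 2 * self.macs + self.eflops


@dataclass
class ComplexityReport:
    total_params: int
    total_macs: int
    total_flops: int
    breakdown: list[Component] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "total_params": self.total_params,
            "total_macs": self.total_macs,
            "total_flops": self.total_flops,
            "params_millions": round(self.total_params / 1e6, 2),
            "tmacs": round(self.total_macs / 1e12, 3),
            "tflops": round(self.total_flops / 1e12, 3),
            "breakdown": [
                {"name": c.name, "params": c.params, "macs": c.macs,
                 "flops": c.flops}
                for c in self.breakdown
            ],
        }


def _padded_dims(cfg: NetworkConfig, input_dims) -> tuple[int, int, int]:
    d = cfg.divisibility
    return tuple(n + ((-n) % d) for n in input_dims)


def _sep_conv(name: str, cin: int, cout: int, k: int, n: int,
              bias: bool = False) -> Component:
    p = k ** 3 * cin + cin * cout + (cout if bias else 0)
    m = (k ** 3 * cin + cin * cout) * n
    return Component(name, p, m, (cout * n if bias else 0))


def _dense_conv(name: str, cin: int, cout: int, k: int, n: int,
                bias: bool) -> Component:
    p = k ** 3 * cin * cout + (cout if bias else 0)
    m = k ** 3 * cin * cout * n
    return Component(name, p, m, (cout * n if bias else 0))


def _block_components(cfg: NetworkConfig, level: int, n: int
                      ) -> Iterator[Component]:
    c = cfg.level_channels[level]
    h = cfg.heads_per_level[level]
    k = cfg.conv_kernel
    r = cfg.pool_factor
    hid = cfg.ffn_hidden(c)
    np_ = n // r ** 3
    tag = f"L{level + 1}"
    if cfg.use_norm:
        yield Component(f"{tag}.norm", 4 * c,
                        0, 2 * NORM_FLOPS_PER_ELEMENT * c * n)
    for nm in ("ds_q", "ds_k", "ds_v"):
        yield _sep_conv(f"{tag}.mcca.{nm}", c, c, k, n)
    # max pooling of Q and K: comparisons only
    yield Component(f"{tag}.mcca.pool", 0, 0, 2 * c * (n - np_))
    softmax_ops = 3 * (c * c // h) + (c * c // h)  # exp+sum+div and alpha scale
    yield Component(f"{tag}.mcca.attention_qk", h,
                    h * ((c // h) ** 2) * np_, softmax_ops)
    yield Component(f"{tag}.mcca.attention_av", 0, h * ((c // h) ** 2) * n, 0)
    yield _dense_conv(f"{tag}.mcca.refine", c, c, 1, n, bias=False)
    yield Component(f"{tag}.mcca.residual", 0, 0, c * n)
    for nm in ("ds_a", "ds_b"):
        yield _sep_conv(f"{tag}.cffn.{nm}", c, hid, k, n)
    yield Component(f"{tag}.cffn.gate", 0, 0,
                    (GELU_FLOPS_PER_ELEMENT + 1) * hid * n)
    yield _dense_conv(f"{tag}.cffn.project", hid, c, 1, n, bias=False)
    yield Component(f"{tag}.cffn.residual", 0, 0, c * n)


def _components(cfg: NetworkConfig, input_dims=None) -> Iterator[Component]:
    L = cfg.n_levels
    k, rk = cfg.conv_kernel, cfg.resample_kernel
    ch = cfg.level_channels
    if input_dims is None:
        ns = [0] * L
    else:
        dims = _padded_dims(cfg, input_dims)
        ns = [dims[0] * dims[1] * dims[2] // 8 ** l for l in range(L)]
    yield _dense_conv("conv_in", cfg.in_channels, ch[0], k, ns[0], bias=False)
    for l in range(L):
        for b in range(cfg.blocks_per_level[l]):
            yield from _block_components(cfg, l, ns[l])
        if l < L - 1:
            if cfg.resample_mode == "separable":
                yield _sep_conv(f"down{l + 1}", ch[l], ch[l + 1], rk, ns[l + 1])
            else:
                yield _dense_conv(f"down{l + 1}", ch[l], ch[l + 1], rk,
                                  ns[l + 1], bias=False)
    for l in reversed(range(L - 1)):
        n_in, n_out = ns[l + 1], ns[l]
        cin, cout = ch[l + 1], ch[l]
        if cfg.resample_mode == "separable":
            # depthwise transposed resampling at input resolution, then
            # pointwise channel mapping at output resolution
            p = rk ** 3 * cin + cin * cout
            m = rk ** 3 * cin * n_in + cin * cout * n_out
            yield Component(f"up{l + 1}", p, m, 0)
        else:
            p = rk ** 3 * cin * cout
            m = rk ** 3 * cin * cout * n_in
            yield Component(f"up{l + 1}", p, m, 0)
        if cfg.skip_fusion == "add":
            yield Component(f"fuse{l + 1}", 0, 0, cout * n_out)
        elif cfg.skip_fusion == "concat1":
            yield _dense_conv(f"fuse{l + 1}", 2 * cout, cout, 1, n_out, bias=True)
        else:
            yield _dense_conv(f"fuse{l + 1}", 2 * cout, cout, k, n_out, bias=True)
        if cfg.decoder_blocks_mirrored:
            for b in range(cfg.blocks_per_level[l]):
                yield from _block_components(cfg, l, ns[l])
    yield _dense_conv("head", ch[0], cfg.out_channels, k, ns[0],
                      bias=cfg.head_bias)
    yield Component("sigmoid", 0, 0,
                    SIGMOID_FLOPS_PER_ELEMENT * cfg.out_channels * ns[0])


def count_parameters(cfg: NetworkConfig) -> int:
    """Exact trainable-scalar count of the configured network."""
    return sum(c.params for c in _components(cfg))


def count_macs(cfg: NetworkConfig, input_dims: tuple[int, int, int]) -> int:
    """Multiply-accumulates of one whole-volume inference pass."""
    return sum(c.macs for c in _components(cfg, input_dims))


def count_flops(cfg: NetworkConfig, input_dims: tuple[int, int, int]) -> int:
    """FLOPs = 2 x MACs + itemized elementwise contributions."""
    return sum(c.flops for c in _components(cfg, input_dims))


def complexity_report(cfg: NetworkConfig,
                      input_dims: tuple[int, int, int] | None = None
                      ) -> ComplexityReport:
    comps = list(_components(cfg, input_dims))
    return ComplexityReport(
        total_params=sum(c.params for c in comps),
        total_macs=sum(c.macs for c in comps),
        total_flops=sum(c.flops for c in comps),
        breakdown=comps,
    )
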