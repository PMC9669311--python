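"""Untrained AlexNet-style convolutional hierarchy.

Five strided/padded group-convolution layers with ReLU and interleaved
3x3/stride-2 max pooling, randomly initialized from zero-mean Gaussians
with He-style standard deviation sqrt(2 / fan_in) and zero biases.  The
forward pass is implemented with im2col (``sliding_window_view`` + BLAS
matmul); no deep-learning framework is involved, which keeps the network
transparent to the brute-force convolution oracles used in the tests and
to the inverse-convolution connectivity lookup (`receptive_sources`).

Activations are recorded post-ReLU, pre-pool at each requested layer; with
zero biases and ReLU the whole network is positively homogeneous, so rank
statistics downstream are insensitive to input scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .stimgen import StimulusImage, StimulusSet


@dataclass(frozen=True)
class LayerSpec:
    name: str
    in_channels: int
    out_channels: int
    kernel: int
    stride: int = 1
    padding: int = 0
    groups: int = 1
    pool: tuple[int, int] | None = None   # (size, stride) max-pool after ReLU

    @property
    def fan_in(self) -> int:
        return (self.in_channels // self.groups) * self.kernel * self.kernel


ALEXNET_SPECS: tuple[LayerSpec, ...] = (
    LayerSpec("conv1", 3, 96, 11, stride=4, padding=0, groups=1, pool=(3, 2)),
    LayerSpec("conv2", 96, 256, 5, stride=1, padding=2, groups=2, pool=(3, 2)),
    LayerSpec("conv3", 256, 384, 3, stride=1, padding=1, groups=1),
    LayerSpec("conv4", 384, 384, 3, stride=1, padding=1, groups=2),
    LayerSpec("conv5", 384, 256, 3, stride=1, padding=1, groups=2, pool=(3, 2)),
)

INPUT_SIZE = 227


@dataclass(frozen=True)
class UnitID:
    layer: str
    channel: int
    y: int
    x: int


@dataclass
class Network:
    """Layer specs plus per-layer random kernels (biases all zero)."""

    specs: tuple[LayerSpec, ...]
    weights: dict[str, np.ndarray]        # name -> (out, in/groups, k, k)
    init_seed: int
    init_sd_rule: dict[str, float] = field(default_factory=dict)

    # -- geometry ----------------------------------------------------------
    def layer_shapes(self, input_size: int = INPUT_SIZE) -> dict[str, dict]:
        """Pre-pool and post-pool (C, H, W) per layer for a square input."""
        shapes = {}
        size = input_size
        for sp in self.specs:
            size = (size + 2 * sp.padding - sp.kernel) // sp.stride + 1
            pre = (sp.out_channels, size, size)
            if sp.pool is not None:
                size = (size - sp.pool[0]) // sp.pool[1] + 1
            shapes[sp.name] = {"pre_pool": pre, "post_pool": (sp.out_channels, size, size)}
        return shapes

    def spec(self, name: str) -> LayerSpec:
        for sp in self.specs:
            if sp.name == name:
                return sp
        raise KeyError(name)

    def layer_index(self, name: str) -> int:
        return [sp.name for sp in self.specs].index(name)


def init_untrained(seed: int, specs: tuple[LayerSpec, ...] = ALEXNET_SPECS) -> Network:
    """He-initialized random network: w ~ N(0, 2/fan_in), biases zero."""
    rng = np.random.default_rng(seed)
    weights, rule = {}, {}
    for sp in specs:
        sd = float(np.sqrt(2.0 / sp.fan_in))
        shape = (sp.out_channels, sp.in_channels // sp.groups, sp.kernel, sp.kernel)
        weights[sp.name] = rng.normal(0.0, sd, shape).astype(np.float32)
        rule[sp.name] = sd
    return Network(tuple(specs), weights, int(seed), rule)


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def _conv2d_group(x: np.ndarray, w: np.ndarray, stride: int, padding: int,
                  groups: int) -> np.ndarray:
    """Strided group convolution of (B, C, H, W) with (O, C/g, k, k)."""
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    k = w.shape[-1]
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (B, C, Ho, Wo, k, k)
    b, c, ho, wo = win.shape[:4]
    cg = c // groups
    og = w.shape[0] // groups
    out = np.empty((b, w.shape[0], ho, wo), dtype=np.float32)
    for g in range(groups):
        cols = win[:, g * cg:(g + 1) * cg].transpose(0, 2, 3, 1, 4, 5)
        cols = np.ascontiguousarray(cols).reshape(b * ho * wo, cg * k * k)
        wg = w[g * og:(g + 1) * og].reshape(og, cg * k * k)
        res = cols @ wg.T
        out[:, g * og:(g + 1) * og] = res.reshape(b, ho, wo, og).transpose(0, 3, 1, 2)
    return out


def _maxpool(x: np.ndarray, size: int, stride: int) -> np.ndarray:
    win = sliding_window_view(x, (size, size), axis=(2, 3))[:, :, ::stride, ::stride]
    return win.max(axis=(4, 5))


def preprocess(image: StimulusImage | np.ndarray) -> np.ndarray:
    """Calibrated [0,255] grayscale -> (3, H, W) float32 in [0, 1]."""
    px = image.pixels if isinstance(image, StimulusImage) else np.asarray(image)
    return np.repeat(px[None].astype(np.float32) / 255.0, 3, axis=0)


def forward(net: Network, images: np.ndarray,
            record_layers: tuple[str, ...] = ("conv5",),
            input_size: int | None = None) -> dict[str, np.ndarray]:
    """Run a batch of preprocessed images; record post-ReLU, pre-pool maps.

    Parameters
    ----------
    images : (B, C, H, W) or (C, H, W) float array in [0, 1].
    record_layers : layer names whose activation maps are returned,
        each as (B, C, H, W), values >= 0.
    """
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if input_size is None:
        input_size = INPUT_SIZE if net.specs == ALEXNET_SPECS else x.shape[-1]
    if x.shape[1] != net.specs[0].in_channels or x.shape[-1] != input_size:
        raise ValueError(
            f"expected input (B, {net.specs[0].in_channels}, {input_size}, "
            f"{input_size}), got {x.shape}")
    known = {sp.name for sp in net.specs}
    missing = set(record_layers) - known
    if missing:
        raise KeyError(f"unknown record layers: {sorted(missing)}")
    recorded: dict[str, np.ndarray] = {}
    for sp in net.specs:
        x = _conv2d_group(x, net.weights[sp.name], sp.stride, sp.padding, sp.groups)
        np.maximum(x, 0.0, out=x)
        if sp.name in record_layers:
            recorded[sp.name] = x.copy()
            if len(recorded) == len(set(record_layers)):
                break               # recordings are pre-pool; nothing left to do
        if sp.pool is not None:
            x = _maxpool(x, *sp.pool)
    return recorded


def forward_stimulus_set(net: Network, stim: StimulusSet | np.ndarray,
                         record_layers: tuple[str, ...] = ("conv5",),
                         batch_size: int = 16) -> dict[str, np.ndarray]:
    """Forward a whole stimulus set in batches.

    Returns, per recorded layer, a (n_units, n_images) float32 matrix with
    units flattened in C-order over (channel, y, x).
    """
    pixels = stim.pixel_stack() if isinstance(stim, StimulusSet) else np.asarray(stim)
    n = pixels.shape[0]
    out: dict[str, list[np.ndarray]] = {l: [] for l in record_layers}
    for lo in range(0, n, batch_size):
        batch = np.stack([preprocess(p) for p in pixels[lo:lo + batch_size]])
        rec = forward(net, batch, record_layers)
        for l in record_layers:
            b = rec[l]
            out[l].append(b.reshape(b.shape[0], -1).T.astype(np.float32))
    return {l: np.concatenate(v, axis=1) for l, v in out.items()}


# ---------------------------------------------------------------------------
# unit indexing and connectivity backtracking
# ---------------------------------------------------------------------------

def unit_index(shape: tuple[int, int, int], unit: UnitID) -> int:
    """Flat index of a unit in a (C, H, W) activation map (C-order)."""
    c, h, w = shape
    if not (0 <= unit.channel < c and 0 <= unit.y < h and 0 <= unit.x < w):
        raise ValueError(f"unit {unit} outside map {shape}")
    return (unit.channel * h + unit.y) * w + unit.x


def unit_from_index(shape: tuple[int, int, int], layer: str, idx: int) -> UnitID:
    c, y, x = np.unravel_index(idx, shape)
    return UnitID(layer, int(c), int(y), int(x))


def receptive_field_footprint(net: Network, unit: UnitID,
                              input_size: int = INPUT_SIZE
                              ) -> tuple[slice, slice]:
    """Theoretical input-pixel footprint of a unit (row slice, col slice).

    Walks the unit's map position back through every conv (stride, padding,
    kernel) and pooling stage below its layer, clipping to the image.
    """
    li = net.layer_index(unit.layer)
    ylo = yhi = unit.y
    xlo = xhi = unit.x
    for j in range(li, -1, -1):
        sp = net.specs[j]
        ylo = ylo * sp.stride - sp.padding
        yhi = yhi * sp.stride - sp.padding + sp.kernel - 1
        xlo = xlo * sp.stride - sp.padding
        xhi = xhi * sp.stride - sp.padding + sp.kernel - 1
        if j > 0 and net.specs[j - 1].pool is not None:
            psize, pstride = net.specs[j - 1].pool
            ylo, yhi = ylo * pstride, yhi * pstride + psize - 1
            xlo, xhi = xlo * pstride, xhi * pstride + psize - 1
    return (slice(max(ylo, 0), min(yhi, input_size - 1) + 1),
            slice(max(xlo, 0), min(xhi, input_size - 1) + 1))


def receptive_sources(net: Network, target: UnitID,
                      input_size: int = INPUT_SIZE) -> list[tuple[UnitID, float]]:
    """Enumerate source-layer units feeding a target unit, with their weights.

    Inverts the group convolution: returns every unit of the previous conv
    layer's post-ReLU (pre-pool) map lying inside the target's kernel
    window, respecting stride, padding and group membership.  Where a max
    pool sits between the layers, connectivity is structural: every member
    of a pooled window is listed, carrying the kernel weight of its pooled
    position (the winning unit is stimulus-dependent).
    """
    li = net.layer_index(target.layer)
    if li == 0:
        raise ValueError("conv1 has no convolutional source layer")
    sp = net.spec(target.layer)
    src_sp = net.specs[li - 1]
    shapes = net.layer_shapes(input_size)
    pre_c, pre_h, pre_w = shapes[src_sp.name]["pre_pool"]
    post_c, post_h, post_w = shapes[src_sp.name]["post_pool"]
    tgt_c, tgt_h, tgt_w = shapes[target.layer]["pre_pool"]
    if not (0 <= target.channel < tgt_c and 0 <= target.y < tgt_h
            and 0 <= target.x < tgt_w):
        raise ValueError(f"target {target} outside layer map {shapes[target.layer]}")

    w = net.weights[target.layer]
    og = sp.out_channels // sp.groups
    cg = sp.in_channels // sp.groups
    group = target.channel // og
    sources: list[tuple[UnitID, float]] = []
    for ky in range(sp.kernel):
        iy = target.y * sp.stride - sp.padding + ky
        if not 0 <= iy < post_h:
            continue
        for kx in range(sp.kernel):
            ix = target.x * sp.stride - sp.padding + kx
            if not 0 <= ix < post_w:
                continue
            for ic in range(cg):
                ch = group * cg + ic
                wt = float(w[target.channel, ic, ky, kx])
                if src_sp.pool is None:
                    sources.append((UnitID(src_sp.name, ch, iy, ix), wt))
                else:
                    psize, pstride = src_sp.pool
                    for dy in range(psize):
                        sy = iy * pstride + dy
                        if sy >= pre_h:
                            continue
                        for dx in range(psize):
                            sx = ix * pstride + dx
                            if sx >= pre_w:
                                continue
                            sources.append((UnitID(src_sp.name, ch, sy, sx), wt))
    return sources
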