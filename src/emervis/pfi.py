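"""Preferred feature images by reverse correlation, and the linear
combination analysis relating invariant-unit PFIs to specific-unit PFIs.

The estimator is classical spike-triggered averaging over an ensemble of
random dot stimuli (bright or dark Gaussian blobs on a mid-gray field):
each iteration presents fresh dot fields superimposed on the previous
estimate, computes the response-weighted sum of the (ensemble-centered)
stimuli with ensemble-centered responses, and accumulates the normalized
per-iteration estimate with equal weight.  Dot amplitude is annealed
(halved every 25 iterations) so early iterations explore and later ones
refine.  The returned PFI is normalized to zero mean, unit variance, which
makes it exactly invariant to positive rescaling of the unit's responses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

BACKGROUND_LEVEL = 127.5


@dataclass(frozen=True)
class DotStimulusConfig:
    n_stimuli: int = 2500
    dots_per_stimulus: int = 10
    amplitude: float = 60.0          # intensity around the mid-gray level
    gaussian_sd: float = 8.0         # pixels
    image_size: int = 227
    anneal_every: int = 25           # halve the dot amplitude this often
    pfi_gain: float = 30.0           # display scale of the running PFI
    seed: int = 0

    def __post_init__(self):
        if self.n_stimuli < 100:
            raise ValueError("need at least 100 stimuli per iteration")
        if self.gaussian_sd <= 0:
            raise ValueError("gaussian sd must be positive")


@dataclass
class PFI:
    unit: object
    array: np.ndarray
    iterations: int
    config: DotStimulusConfig
    defined: bool = True


@dataclass
class CombinationFit:
    weights: np.ndarray              # convex weights, sum 1
    best_correlation: float
    surface: list[tuple[tuple[float, ...], float]] = field(repr=False,
                                                           default_factory=list)


def _dot_kernel(sd: float) -> np.ndarray:
    r = int(np.ceil(3 * sd))
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    return np.exp(-(x * x + y * y) / (2 * sd * sd))


def make_dot_fields(rng: np.random.Generator, config: DotStimulusConfig,
                    n: int, amplitude: float | None = None) -> np.ndarray:
    """(n, size, size) zero-baseline dot fields: +-amplitude Gaussian blobs."""
    size = config.image_size
    amp = config.amplitude if amplitude is None else amplitude
    kern = _dot_kernel(config.gaussian_sd)
    r = kern.shape[0] // 2
    fields = np.zeros((n, size + 2 * r, size + 2 * r))
    ys = rng.integers(0, size, (n, config.dots_per_stimulus))
    xs = rng.integers(0, size, (n, config.dots_per_stimulus))
    pol = rng.choice([-1.0, 1.0], (n, config.dots_per_stimulus))
    for i in range(n):
        for d in range(config.dots_per_stimulus):
            fields[i, ys[i, d]:ys[i, d] + kern.shape[0],
                   xs[i, d]:xs[i, d] + kern.shape[0]] += pol[i, d] * amp * kern
    return fields[:, r:r + size, r:r + size]


def _normalize(a: np.ndarray) -> np.ndarray:
    a = a - a.mean()
    sd = a.std()
    return a / sd if sd > 0 else a


def reverse_correlation(respond: Callable[[np.ndarray], np.ndarray],
                        config: DotStimulusConfig,
                        iterations: int = 100) -> PFI:
    """Estimate a unit's preferred feature image.

    ``respond`` maps a stimulus batch (n, size, size), intensities in
    [0, 255], to an (n,) response vector.  A unit whose responses carry no
    variance at the first iteration is flagged undefined.
    """
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    pfi = np.zeros((size, size))
    acc = np.zeros((size, size))
    for t in range(iterations):
        amp = config.amplitude * 0.5 ** (t // config.anneal_every)
        fields = make_dot_fields(rng, config, config.n_stimuli, amplitude=amp)
        stimuli = np.clip(BACKGROUND_LEVEL + config.pfi_gain * pfi + fields,
                          0.0, 255.0)
        r = np.asarray(respond(stimuli), dtype=np.float64)
        w = r - r.mean()
        if not np.any(w):
            if t == 0:
                return PFI(None, np.zeros((size, size)), 0, config, defined=False)
            continue
        sta = np.tensordot(w, stimuli - stimuli.mean(axis=0), axes=(0, 0))
        acc += _normalize(sta)
        pfi = _normalize(acc)
    return PFI(None, pfi, iterations, config)


def unit_response_fn(net, unit, input_size: int | None = None) -> Callable:
    """Adapter: a network unit as a stimulus->response function."""
    from . import network as nw

    shape = net.layer_shapes(input_size or nw.INPUT_SIZE)[unit.layer]["pre_pool"]
    idx = nw.unit_index(shape, unit)

    def respond(stimuli: np.ndarray) -> np.ndarray:
        rec = nw.forward_stimulus_set(net, np.asarray(stimuli),
                                      record_layers=(unit.layer,))
        return rec[unit.layer][idx]

    return respond


def pfi_viewpoint_correlation(pfi: PFI | np.ndarray,
                              images_by_viewpoint: dict[float, np.ndarray],
                              footprint: tuple[slice, slice] | None = None
                              ) -> dict[float, float]:
    """Pearson correlation between a PFI and the per-viewpoint mean stimulus.

    ``footprint`` restricts the comparison to the unit's receptive-field
    window (row slice, column slice) when the PFI does not span the image.
    """
    arr = pfi.array if isinstance(pfi, PFI) else np.asarray(pfi)
    out = {}
    for v, imgs in images_by_viewpoint.items():
        avg = np.asarray(imgs).mean(axis=0)
        if footprint is not None:
            avg = avg[footprint]
            a = arr[footprint] if arr.shape == np.asarray(imgs).shape[1:] else arr
        else:
            a = arr
        af, bf = a.ravel() - a.mean(), avg.ravel() - avg.mean()
        denom = np.linalg.norm(af) * np.linalg.norm(bf)
        out[float(v)] = float(af @ bf / denom) if denom > 0 else 0.0
    return out


def _simplex_grid(k: int, step: float):
    """All convex weight vectors of length k on a grid of spacing step."""
    m = int(round(1.0 / step))
    for combo in itertools.product(range(m + 1), repeat=k - 1):
        if sum(combo) <= m:
            yield tuple(c / m for c in combo) + ((m - sum(combo)) / m,)


def fit_combination(invariant_pfi: PFI | np.ndarray,
                    specific_pfis: list, grid_step: float = 0.05) -> CombinationFit:
    """Best convex combination of specific-unit PFIs matching an invariant PFI.

    Exhaustive search over the simplex grid; the objective is the pixel-wise
    Pearson correlation, which is invariant to common affine transforms of
    the PFIs.
    """
    if len(specific_pfis) < 2:
        raise ValueError("need at least 2 specific PFIs")
    target = (invariant_pfi.array if isinstance(invariant_pfi, PFI)
              else np.asarray(invariant_pfi)).ravel().astype(float)
    target = target - target.mean()
    tn = np.linalg.norm(target)
    comps = np.stack([
        (p.array if isinstance(p, PFI) else np.asarray(p)).ravel().astype(float)
        for p in specific_pfis
    ])
    comps = comps - comps.mean(axis=1, keepdims=True)
    best_w, best_c, surface = None, -np.inf, []
    for wts in _simplex_grid(len(specific_pfis), grid_step):
        mix = np.asarray(wts) @ comps
        denom = np.linalg.norm(mix) * tn
        c = float(mix @ target / denom) if denom > 0 else 0.0
        surface.append((wts, c))
        if c > best_c:
            best_c, best_w = c, np.asarray(wts)
    assert abs(best_w.sum() - 1.0) < 1e-9
    return CombinationFit(best_w, best_c, surface)
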