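"""Shared fixtures: small render configs, toy networks, planted tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from emervis import network as nw
from emervis import selectivity as sl
from emervis import stimgen as sg


@pytest.fixture(scope="session")
def uniform_cfg() -> sg.RenderConfig:
    return sg.RenderConfig(background_kind="uniform")


@pytest.fixture(scope="session")
def rigid_chair() -> sg.ObjectSpec:
    """Mirror-symmetric object with jitter disabled."""
    return sg.ObjectSpec("chair", sg.BUILTIN_CLASSES["chair"],
                         sg.JitterParams(0.0, 0.0), 0)


def toy_specs(in_channels=2, out_channels=4, kernel=3, stride=1, padding=0,
              groups=2, pool=None, n_layers=1):
    """A stack of identical small conv layers for oracle tests."""
    specs = []
    c_in = in_channels
    for i in range(n_layers):
        specs.append(nw.LayerSpec(f"conv{i + 1}", c_in, out_channels, kernel,
                                  stride, padding, groups, pool))
        c_in = out_channels
    return tuple(specs)


@pytest.fixture
def toy_net() -> nw.Network:
    return nw.init_untrained(0, toy_specs())


def conv_oracle(x, w, stride, padding, groups):
    """Nested-loop strided group convolution; the independent reference."""
    b, c, h, wdt = x.shape
    o, cg, k, _ = w.shape
    if padding:
        xp = np.zeros((b, c, h + 2 * padding, wdt + 2 * padding), x.dtype)
        xp[:, :, padding:padding + h, padding:padding + wdt] = x
        x = xp
        h, wdt = h + 2 * padding, wdt + 2 * padding
    ho = (h - k) // stride + 1
    wo = (wdt - k) // stride + 1
    og = o // groups
    out = np.zeros((b, o, ho, wo))
    for bi in range(b):
        for oc in range(o):
            g = oc // og
            for yy in range(ho):
                for xx in range(wo):
                    acc = 0.0
                    for ic in range(cg):
                        for ky in range(k):
                            for kx in range(k):
                                acc += (w[oc, ic, ky, kx]
                                        * x[bi, g * cg + ic,
                                            yy * stride + ky, xx * stride + kx])
                    out[bi, oc, yy, xx] = acc
    return out


def pool_oracle(x, size, stride):
    b, c, h, w = x.shape
    ho = (h - size) // stride + 1
    wo = (w - size) // stride + 1
    out = np.zeros((b, c, ho, wo))
    for yy in range(ho):
        for xx in range(wo):
            out[:, :, yy, xx] = x[:, :, yy * stride:yy * stride + size,
                                  xx * stride:xx * stride + size].max(axis=(2, 3))
    return out


def planted_table(n_units=50, n_planted=10, shift=2.0, noise_sd=1.0,
                  n_per_class=200, classes=("a", "b", "c", "d", "e",
                                            "f", "g", "h", "i"),
                  target="a", seed=0, scrambled=True) -> sl.ResponseTable:
    """Response table with the first `n_planted` units shifted on the target.

    Responses are |N(baseline, noise_sd)| so they stay non-negative; planted
    units get +shift on target-class images.
    """
    rng = np.random.default_rng(seed)
    labels = []
    for c in classes:
        labels += [c] * n_per_class
    if scrambled:
        labels += [sl.SCRAMBLED_LABEL] * n_per_class
    labels = np.array(labels)
    base = 5.0
    resp = np.abs(rng.normal(base, noise_sd, (n_units, len(labels))))
    resp[:n_planted, labels == target] += shift
    meta = pd.DataFrame({"class": labels})
    return sl.ResponseTable(resp, meta)


def viewpoint_table(curve_fn, n_units=1, n_per_vp=50, noise_sd=1.0,
                    grid=(-60.0, -30.0, 0.0, 30.0, 60.0), target="toilet",
                    seed=0, subset="heldout") -> sl.ResponseTable:
    """Table whose unit means follow curve_fn(unit, viewpoint)."""
    rng = np.random.default_rng(seed)
    rows, cols = [], []
    for v in grid:
        for _ in range(n_per_vp):
            rows.append({"class": target, "viewpoint_deg": v, "subset": subset})
    meta = pd.DataFrame(rows)
    resp = np.zeros((n_units, len(meta)))
    vps = meta["viewpoint_deg"].to_numpy()
    for u in range(n_units):
        mean = np.array([curve_fn(u, v) for v in vps])
        resp[u] = np.abs(mean + rng.normal(0, noise_sd, len(vps)))
    return sl.ResponseTable(resp, meta)
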