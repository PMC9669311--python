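"""Viewpoint tuning: effective range, specific/invariant classification,
invariance index, and the raw-image-correlation control.

The *effective range* of a unit (or population) is the angular span over
which its target response stays significantly above the pooled non-target
response (one-sided rank-sum, default alpha 0.05).  Significance must be
contiguous around the frontal view; the span runs between the outermost
contiguous significant viewpoints plus one half grid step on each side, so
significance at -45..+45 on a 15 degree grid gives 90 + 15 = 105 degrees.

*Viewpoint-invariant* units show no significant response difference across
viewpoint classes (one-way ANOVA, p > alpha); *viewpoint-specific* units
are significant with a single peak, a peak being a per-viewpoint mean
exceeding the grand mean plus one sd of the per-viewpoint means.  The
*invariance index* is the inverse of the (population) sd of per-viewpoint
mean responses, capped for near-flat curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .selectivity import ResponseTable

DEFAULT_INDEX_CAP = 1e6


@dataclass
class ViewpointTuningCurve:
    unit: int
    grid: np.ndarray            # viewpoint angles, degrees, symmetric about 0
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.grid, float)
        if not np.allclose(np.sort(g) + np.sort(g)[::-1], 0, atol=1e-9):
            raise ValueError("viewpoint grid must be symmetric about 0")
        if np.any(np.asarray(self.n) < 2):
            raise ValueError("need n >= 2 images per viewpoint")


@dataclass
class EffectiveRange:
    unit: int | str
    significant: list[float]
    range_deg: float
    flagged: bool = False       # frontal view itself not significant
    pvalues: dict[float, float] = field(default_factory=dict)


@dataclass
class InvarianceLabel:
    unit: int
    label: str                  # specific | invariant | unclassified
    preferred_angle: float | None
    anova_p: float


@dataclass
class InvarianceIndex:
    unit: int
    index: float
    capped: bool


def _viewpoint_groups(table: ResponseTable, unit: int, target_class: str,
                      subset: str | None, grid=None):
    meta = table.meta
    mask = (meta["class"] == target_class).to_numpy()
    if subset is not None and "subset" in meta:
        mask &= (meta["subset"] == subset).to_numpy()
    vps = np.asarray(sorted(meta.loc[mask, "viewpoint_deg"].unique()))
    if grid is not None:
        vps = np.asarray([v for v in vps if np.any(np.isclose(v, grid))])
    resp = table.responses[unit]
    vp_col = meta["viewpoint_deg"].to_numpy()
    return vps, [resp[mask & np.isclose(vp_col, v)] for v in vps]


def tuning_curve(table: ResponseTable, unit: int, target_class: str,
                 subset: str | None = "analysis") -> ViewpointTuningCurve:
    """Per-viewpoint mean and sem of one unit over the analysis identities."""
    if "viewpoint_deg" not in table.meta:
        raise ValueError("response table has no viewpoint metadata")
    vps, groups = _viewpoint_groups(table, unit, target_class, subset)
    if len(vps) == 0:
        raise ValueError(f"no images of class {target_class!r} in table")
    mean = np.array([g.mean() for g in groups])
    sem = np.array([g.std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else 0.0
                    for g in groups])
    n = np.array([len(g) for g in groups])
    return ViewpointTuningCurve(unit, vps, mean, sem, n)


def effective_range(target_by_viewpoint: dict[float, np.ndarray],
                    nontarget: np.ndarray, alpha: float = 0.05,
                    unit: int | str = "population") -> EffectiveRange:
    """Span of viewpoints with target response significantly above non-target.

    One-sided rank-sum per grid point; only the contiguous block of
    significant viewpoints around 0 deg counts (isolated significant
    outliers beyond a gap are excluded).  Span = outermost contiguous
    significant angles plus half a grid step each side.  If 0 deg itself is
    not significant the range is 0 and the result is flagged.
    """
    vps = np.asarray(sorted(target_by_viewpoint))
    if len(vps) < 2:
        raise ValueError("need at least 2 viewpoints")
    if not np.any(np.isclose(vps, 0.0)):
        raise ValueError("0 deg must be on the viewpoint grid")
    step = float(np.diff(vps).min())
    pvals = {}
    sig = {}
    for v in vps:
        p = stats.ranksums(target_by_viewpoint[v], nontarget,
                           alternative="greater").pvalue
        pvals[float(v)] = float(p)
        sig[float(v)] = p < alpha
    i0 = int(np.argmin(np.abs(vps)))
    if not sig[float(vps[i0])]:
        return EffectiveRange(unit, [], 0.0, flagged=True, pvalues=pvals)
    lo = i0
    while lo - 1 >= 0 and sig[float(vps[lo - 1])]:
        lo -= 1
    hi = i0
    while hi + 1 < len(vps) and sig[float(vps[hi + 1])]:
        hi += 1
    significant = [float(v) for v in vps[lo:hi + 1]]
    range_deg = float(vps[hi] - vps[lo]) + step
    return EffectiveRange(unit, significant, range_deg, pvalues=pvals)


def unit_effective_range(table: ResponseTable, unit: int, target_class: str,
                         nontarget: np.ndarray, alpha: float = 0.05,
                         subset: str | None = "analysis") -> EffectiveRange:
    """Effective range of a single unit from a viewpoint response table."""
    vps, groups = _viewpoint_groups(table, unit, target_class, subset)
    return effective_range({float(v): g for v, g in zip(vps, groups)},
                           nontarget, alpha, unit=unit)


def _pearson_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between two (N, ...) image stacks."""
    af = a.reshape(len(a), -1).astype(float)
    bf = b.reshape(len(b), -1).astype(float)
    af = af - af.mean(axis=1, keepdims=True)
    bf = bf - bf.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(af, axis=1) * np.linalg.norm(bf, axis=1)
    return np.divide((af * bf).sum(axis=1), denom,
                     out=np.zeros(len(af)), where=denom > 0)


def raw_image_correlation_range(images_by_viewpoint: dict[float, np.ndarray],
                                nontarget_images: np.ndarray,
                                alpha: float = 0.05) -> EffectiveRange:
    """Effective range of pixel-wise image similarity under rotation.

    Per viewpoint, correlates each rotated image with the front view of the
    same identity; the null pool is the correlation of front views with
    non-target images.  The significance rule and span convention are the
    same as for response effective ranges.
    """
    vzero = min(images_by_viewpoint, key=lambda v: abs(v))
    front = np.asarray(images_by_viewpoint[vzero])
    corr_by_vp = {
        float(v): _pearson_pairs(np.asarray(imgs), front)
        for v, imgs in images_by_viewpoint.items()
    }
    nt = np.asarray(nontarget_images)
    null = _pearson_pairs(nt, front[np.arange(len(nt)) % len(front)])
    return effective_range(corr_by_vp, null, alpha, unit="raw_image")


def classify_units(table: ResponseTable, units, target_class: str,
                   alpha: float = 0.05, grid=None,
                   subset: str | None = "heldout") -> list[InvarianceLabel]:
    """Label units as viewpoint-specific / -invariant / unclassified.

    Uses held-out identities (those not used to find selective units).
    Invariant: one-way ANOVA across viewpoint classes, p > alpha.
    Specific: p < alpha AND exactly one per-viewpoint mean above the grand
    mean plus one sd of the per-viewpoint means (single-peak rule); the
    preferred angle is that viewpoint.  Otherwise unclassified.
    """
    if grid is None:
        grid = np.array([-60.0, -30.0, 0.0, 30.0, 60.0])
    labels = []
    for u in units:
        vps, groups = _viewpoint_groups(table, u, target_class, subset, grid=grid)
        if len(vps) < 2:
            raise ValueError("need at least 2 viewpoint classes")
        if min(len(g) for g in groups) < 2:
            raise ValueError("need at least 2 images per viewpoint class")
        means = np.array([g.mean() for g in groups])
        if all(np.ptp(g) == 0 for g in groups) and np.ptp(means) == 0:
            labels.append(InvarianceLabel(int(u), "unclassified", None, np.nan))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = stats.f_oneway(*groups).pvalue
        if not np.isfinite(p) or p > alpha:
            labels.append(InvarianceLabel(int(u), "invariant", None, float(p)))
            continue
        thr = means.mean() + means.std(ddof=0)
        peaks = np.nonzero(means > thr)[0]
        if len(peaks) == 1:
            labels.append(InvarianceLabel(int(u), "specific",
                                          float(vps[peaks[0]]), float(p)))
        else:
            labels.append(InvarianceLabel(int(u), "unclassified", None, float(p)))
    return labels


def percentile_split(ranges: dict[int, float] | pd.Series,
                     fraction: float = 0.30) -> tuple[list[int], list[int]]:
    """Top / bottom fraction of units by effective range.

    Returns (tentative invariant ids, tentative specific ids); ties are
    broken by unit id for determinism, and an all-equal input emits a
    warning.
    """
    s = pd.Series(ranges)
    if len(s) < 10:
        raise ValueError("need at least 10 units to split")
    if s.nunique() == 1:
        warnings.warn("all effective ranges equal; split is id-ordered",
                      stacklevel=2)
    k = int(np.floor(fraction * len(s)))
    order_desc = sorted(s.index, key=lambda u: (-s[u], u))
    order_asc = sorted(s.index, key=lambda u: (s[u], u))
    return [int(u) for u in order_desc[:k]], [int(u) for u in order_asc[:k]]


def invariance_index(per_viewpoint_means: np.ndarray, unit: int = -1,
                     cap: float = DEFAULT_INDEX_CAP) -> InvarianceIndex:
    """1 / population sd of per-viewpoint mean responses, capped for flat
    curves (larger = flatter = more invariant)."""
    means = np.asarray(per_viewpoint_means, float)
    if means.size < 2:
        raise ValueError("need at least 2 viewpoint classes")
    sd = float(means.std(ddof=0))
    if sd <= 1.0 / cap:
        return InvarianceIndex(int(unit), float(cap), True)
    return InvarianceIndex(int(unit), 1.0 / sd, False)


def unit_invariance_index(table: ResponseTable, unit: int, target_class: str,
                          subset: str | None = "analysis",
                          cap: float = DEFAULT_INDEX_CAP) -> InvarianceIndex:
    _, groups = _viewpoint_groups(table, unit, target_class, subset)
    means = np.array([g.mean() for g in groups])
    return invariance_index(means, unit=unit, cap=cap)


def invariance_index_matrix(table: ResponseTable, target_class: str,
                            subset: str | None = "analysis",
                            cap: float = DEFAULT_INDEX_CAP) -> np.ndarray:
    """Invariance index of every unit at once (vectorized over units).

    Equivalent to calling :func:`unit_invariance_index` per unit; used when
    whole selective populations are summarized so layer medians are not
    subject to subsampling noise.
    """
    meta = table.meta
    mask = (meta["class"] == target_class).to_numpy()
    if subset is not None and "subset" in meta:
        mask &= (meta["subset"] == subset).to_numpy()
    vp_col = meta["viewpoint_deg"].to_numpy()
    vps = np.unique(vp_col[mask])
    if vps.size < 2:
        raise ValueError("need at least 2 viewpoint classes")
    means = np.stack([table.responses[:, mask & np.isclose(vp_col, v)]
                      .mean(axis=1) for v in vps], axis=1)
    sd = means.std(axis=1)
    with np.errstate(divide="ignore"):
        return np.minimum(np.where(sd > 0, 1.0 / sd, cap), cap)
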