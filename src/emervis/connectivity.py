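"""Feedforward connectivity: backtracked projection profiles and the
homogeneous index of inputs to viewpoint-specific vs -invariant units.

For a target unit in layer L, every connected source unit of layer L-1
(enumerated by ``network.receptive_sources``) is assigned to one of four
disjoint categories from the source layer's tuning labels: same-object
viewpoint-specific (grouped by preferred angle), same-object viewpoint-
invariant, other-object selective, and non-selective.  Signed kernel
weights are averaged per category; signed averages are what makes the
homogeneity of per-angle inputs meaningful.

The *homogeneous index* of a target is the inverse of the population sd of
its per-angle average weights; it is cohort-normalized so the mean index
over viewpoint-specific targets equals one, making "above one" read as
"more homogeneously wired than a typical specific unit".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .network import Network, UnitID, receptive_sources

INDEX_CAP = 1e6

SPECIFIC = "specific"
INVARIANT = "invariant"
OTHER_SELECTIVE = "other_selective"
NON_SELECTIVE = "non_selective"


@dataclass
class SourceLabels:
    """Category of every source-layer unit, keyed by flat unit index.

    ``specific`` maps unit -> preferred angle (deg); ``invariant`` and
    ``other_selective`` are sets of unit indices; everything else connected
    is non-selective.
    """

    specific: dict[int, float] = field(default_factory=dict)
    invariant: set[int] = field(default_factory=set)
    other_selective: set[int] = field(default_factory=set)

    def category(self, idx: int) -> tuple[str, float | None]:
        if idx in self.specific:
            return SPECIFIC, self.specific[idx]
        if idx in self.invariant:
            return INVARIANT, None
        if idx in self.other_selective:
            return OTHER_SELECTIVE, None
        return NON_SELECTIVE, None


@dataclass
class ProjectionProfile:
    target: UnitID
    angle_avg: dict[float, float]      # per preferred-angle average signed weight
    angle_count: dict[float, int]
    category_avg: dict[str, float]     # invariant / other_selective / non_selective
    category_count: dict[str, int]

    @property
    def same_object_avg(self) -> float:
        """Average weight over all same-object selective sources."""
        tot, n = 0.0, 0
        for a, cnt in self.angle_count.items():
            tot += self.angle_avg[a] * cnt
            n += cnt
        if INVARIANT in self.category_count:
            tot += self.category_avg[INVARIANT] * self.category_count[INVARIANT]
            n += self.category_count[INVARIANT]
        return tot / n if n else np.nan


@dataclass
class HomogeneousIndexRecord:
    target: UnitID
    raw_index: float
    normalized_index: float
    capped: bool = False


def _flat_index(map_shape: tuple[int, int, int], unit: UnitID) -> int:
    c, h, w = map_shape
    return (unit.channel * h + unit.y) * w + unit.x


def build_projection_profiles(net: Network, targets: list[UnitID],
                              source_labels: SourceLabels,
                              input_size: int = 227) -> list[ProjectionProfile]:
    """Backtrack each target's inputs and average signed weights by category."""
    profiles = []
    shapes = net.layer_shapes(input_size)
    for tgt in targets:
        src_layer = net.specs[net.layer_index(tgt.layer) - 1].name
        src_shape = shapes[src_layer]["pre_pool"]
        sums: dict[object, float] = {}
        counts: dict[object, int] = {}
        for src, wt in receptive_sources(net, tgt, input_size):
            idx = _flat_index(src_shape, src)
            cat, angle = source_labels.category(idx)
            key = ("angle", angle) if cat == SPECIFIC else cat
            sums[key] = sums.get(key, 0.0) + wt
            counts[key] = counts.get(key, 0) + 1
        angle_avg = {k[1]: sums[k] / counts[k] for k in sums
                     if isinstance(k, tuple)}
        angle_count = {k[1]: counts[k] for k in counts if isinstance(k, tuple)}
        cat_avg = {k: sums[k] / counts[k] for k in sums if isinstance(k, str)}
        cat_count = {k: counts[k] for k in counts if isinstance(k, str)}
        profiles.append(ProjectionProfile(tgt, angle_avg, angle_count,
                                          cat_avg, cat_count))
    return profiles


def raw_homogeneous_index(per_angle_averages, cap: float = INDEX_CAP
                          ) -> tuple[float, bool]:
    """1 / population sd of the per-angle average weights, capped at sd -> 0."""
    vals = np.asarray(list(per_angle_averages), float)
    if vals.size < 2:
        raise ValueError("need >= 2 non-empty preferred-angle categories")
    sd = float(vals.std(ddof=0))
    if sd <= 1.0 / cap:
        return float(cap), True
    return 1.0 / sd, False


def homogeneous_index(profiles: list[ProjectionProfile],
                      specific_cohort: list[ProjectionProfile],
                      cap: float = INDEX_CAP) -> list[HomogeneousIndexRecord]:
    """Cohort-normalized homogeneous index for each target profile.

    Raw indices are divided by the mean raw index over the viewpoint-
    specific target cohort, so that cohort's mean normalized index is
    exactly one.  Targets with fewer than two non-empty angle categories
    are skipped (undefined).
    """
    def raw(p: ProjectionProfile) -> float | None:
        if len(p.angle_avg) < 2:
            return None
        return raw_homogeneous_index(p.angle_avg.values(), cap)[0]

    cohort_raws = [r for r in (raw(p) for p in specific_cohort) if r is not None]
    if not cohort_raws:
        raise ValueError("specific cohort has no defined raw indices")
    norm = float(np.mean(cohort_raws))
    out = []
    for p in profiles:
        r = raw(p)
        if r is None:
            continue
        out.append(HomogeneousIndexRecord(p.target, r, r / norm, capped=r >= cap))
    return out


def bias_tests(profiles: list[ProjectionProfile],
               labels: dict[UnitID, str],
               preferred_angle: dict[UnitID, float] | None = None) -> dict:
    """Wiring-bias statistics across target units.

    (i) Two-sided rank-sum of same-object vs other-object average input
    weights across all targets; (ii) one-way ANOVA of per-angle average
    weights across source-angle groups.  For viewpoint-specific targets the
    bias is tied to each target's own preferred angle, so the ANOVA is run
    within the largest cohort of targets sharing a preferred angle
    (expected significant under biased wiring); for viewpoint-invariant
    targets all profiles enter (expected non-significant under homogeneous
    wiring).  Raw p values only.
    """
    same = [p.same_object_avg for p in profiles
            if np.isfinite(p.same_object_avg)]
    other = [p.category_avg[OTHER_SELECTIVE] for p in profiles
             if OTHER_SELECTIVE in p.category_avg]
    report: dict = {}
    if len(same) >= 2 and len(other) >= 2:
        stat = stats.ranksums(same, other)
        report["same_vs_other"] = {"statistic": float(stat.statistic),
                                   "p": float(stat.pvalue)}

    def anova(sub: list[ProjectionProfile]) -> tuple[float, float] | None:
        angles = sorted({a for p in sub for a in p.angle_avg})
        groups = [[p.angle_avg[a] for p in sub if a in p.angle_avg]
                  for a in angles]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            return None
        f = stats.f_oneway(*groups)
        return float(f.statistic), float(f.pvalue)

    spec = [p for p in profiles if labels.get(p.target) == SPECIFIC]
    if preferred_angle and spec:
        by_pref: dict[float, list[ProjectionProfile]] = {}
        for p in spec:
            ang = preferred_angle.get(p.target)
            if ang is not None:
                by_pref.setdefault(ang, []).append(p)
        if by_pref:
            spec = max(by_pref.values(), key=len)
    if len(spec) >= 2 and (res := anova(spec)) is not None:
        report["anova_specific"] = {"F": res[0], "p": res[1]}
    inv = [p for p in profiles if labels.get(p.target) == INVARIANT]
    if len(inv) >= 2 and (res := anova(inv)) is not None:
        report["anova_invariant"] = {"F": res[0], "p": res[1]}
    return report
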