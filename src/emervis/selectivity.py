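"""Object-selectivity statistics for network unit populations.

A unit is *object-selective* for a target class when (i) its mean response
to target images exceeds its mean response to every other object class and
to the scrambled control set, and (ii) a two-sided Wilcoxon rank-sum test
of target vs pooled non-target responses is significant (default alpha
0.001, no multiple-testing correction).

Two tuning indices are computed per unit:

* the z-scored response, (R_target - R_secondmax) / sd(all object-class
  responses), positive iff the target class has strictly the highest mean;
* the OSI, a d'-style contrast (R_target - R_nontarget) /
  sqrt((var_target + var_nontarget) / 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SCRAMBLED_LABEL = "scrambled"


@dataclass
class ResponseTable:
    """Unit x image response matrix with per-image metadata.

    ``responses`` is (n_units, n_images), all entries finite and >= 0;
    ``meta`` carries one row per image (class, identity, viewpoint_deg, ...).
    ``layer`` and ``map_shape`` identify where the units came from.
    """

    responses: np.ndarray
    meta: pd.DataFrame
    layer: str = "conv5"
    map_shape: tuple[int, int, int] | None = None

    def __post_init__(self):
        self.responses = np.asarray(self.responses)
        if self.responses.shape[1] != len(self.meta):
            raise ValueError("metadata rows must match response columns")
        if not np.isfinite(self.responses).all():
            raise ValueError("responses contain missing/non-finite entries")
        if (self.responses < 0).any():
            raise ValueError("responses must be non-negative (post-ReLU)")

    @property
    def n_units(self) -> int:
        return self.responses.shape[0]

    def subset_images(self, mask: np.ndarray) -> "ResponseTable":
        return ResponseTable(self.responses[:, mask],
                             self.meta.loc[mask].reset_index(drop=True),
                             self.layer, self.map_shape)


def zscored_response(r_target, r_secondmax, sigma_allobject):
    """(R_target - R_secondmax) / sigma over all object-class responses."""
    sigma = np.asarray(sigma_allobject, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma_allobject must be positive")
    return (np.asarray(r_target, float) - np.asarray(r_secondmax, float)) / sigma


def osi(r_target, r_nontarget, var_target, var_nontarget):
    """Object selectivity index: d'-style target vs non-target contrast."""
    pooled = (np.asarray(var_target, float) + np.asarray(var_nontarget, float)) / 2.0
    if np.any(pooled <= 0):
        raise ValueError("pooled variance must be positive")
    return (np.asarray(r_target, float) - np.asarray(r_nontarget, float)) / np.sqrt(pooled)


def find_selective_units(table: ResponseTable, target_class: str,
                         alpha: float = 0.001) -> pd.DataFrame:
    """Per-unit tuning statistics and the selectivity decision.

    Returns a DataFrame with one row per unit: class means, R_secondmax,
    sigma over all object images, zscore, OSI, rank-sum p (NaN for units
    failing the mean-ordering precondition), `selected` and `degenerate`
    flags.  Degenerate (constant-response) units are never selected.
    """
    classes = [c for c in table.meta["class"].unique() if c != SCRAMBLED_LABEL]
    if target_class not in classes:
        raise ValueError(f"target class {target_class!r} not in table")
    if len(classes) < 2:
        raise ValueError("need at least 2 object classes")
    labels = table.meta["class"].to_numpy()
    resp = table.responses
    t_mask = labels == target_class
    nt_mask = (labels != target_class) & (labels != SCRAMBLED_LABEL)
    scr_mask = labels == SCRAMBLED_LABEL
    obj_mask = t_mask | nt_mask
    if t_mask.sum() < 2 or nt_mask.sum() < 2:
        raise ValueError("need at least 2 images per class")

    class_means = {c: resp[:, labels == c].mean(axis=1) for c in classes}
    cm = np.column_stack([class_means[c] for c in classes])
    ti = classes.index(target_class)
    other = np.delete(cm, ti, axis=1)
    r_target = cm[:, ti]
    # highest non-target class mean; equals the second-highest overall mean
    # whenever the unit prefers the target, and makes the z-score negative
    # when some other class responds more
    r_secondmax = other.max(axis=1)

    r_nontarget = resp[:, nt_mask].mean(axis=1)
    r_scrambled = resp[:, scr_mask].mean(axis=1) if scr_mask.any() else \
        np.full(table.n_units, -np.inf)
    sigma_all = resp[:, obj_mask].std(axis=1)
    var_t = resp[:, t_mask].var(axis=1)
    var_nt = resp[:, nt_mask].var(axis=1)

    degenerate = resp[:, obj_mask].std(axis=1) == 0
    mean_order = (r_target > other.max(axis=1)) & (r_target > r_scrambled)
    candidates = np.nonzero(mean_order & ~degenerate)[0]

    pvals = np.full(table.n_units, np.nan)
    t_resp = resp[:, t_mask]
    nt_resp = resp[:, nt_mask]
    for u in candidates:
        pvals[u] = stats.ranksums(t_resp[u], nt_resp[u]).pvalue
    selected = mean_order & ~degenerate & (pvals < alpha)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma_all > 0, (r_target - r_secondmax) / sigma_all, np.nan)
        pooled = (var_t + var_nt) / 2
        osi_vals = np.where(pooled > 0, (r_target - r_nontarget) / np.sqrt(pooled),
                            np.nan)

    out = pd.DataFrame({
        "unit": np.arange(table.n_units),
        "r_target": r_target,
        "r_secondmax": r_secondmax,
        "r_nontarget": r_nontarget,
        "r_scrambled": (resp[:, scr_mask].mean(axis=1) if scr_mask.any()
                        else np.full(table.n_units, np.nan)),
        "sigma_allobject": sigma_all,
        "zscore": z,
        "osi": osi_vals,
        "p_selectivity": pvals,
        "selected": selected,
        "degenerate": degenerate,
    })
    for c in classes:
        out[f"mean_{c}"] = class_means[c]
    out.attrs["target_class"] = target_class
    out.attrs["alpha"] = alpha
    return out


def count_selective_by_layer(
        stats_by_layer: dict[str, dict[str, pd.DataFrame]]) -> pd.DataFrame:
    """Selective-unit counts and mean OSI per (layer, class).

    ``stats_by_layer`` maps layer name -> {class -> find_selective_units
    output}.  Empty tables yield zero counts.  Counts are invariant to unit
    ordering by construction.
    """
    rows = []
    for layer, by_class in stats_by_layer.items():
        for cl, df in by_class.items():
            sel = df[df["selected"]] if len(df) else df
            rows.append({
                "layer": layer, "class": cl,
                "n_selective": int(sel["selected"].sum()) if len(df) else 0,
                "mean_osi": float(sel["osi"].mean()) if len(sel) else np.nan,
            })
    return pd.DataFrame(rows)


@dataclass
class ClusterAudit:
    embedding: np.ndarray                 # (n_images, 2)
    silhouette_by_class: pd.Series
    pearson_r: float
    pearson_p: float


def cluster_audit(table: ResponseTable, counts_per_class: dict[str, int],
                  seed: int = 0, perplexity: float | None = None) -> ClusterAudit:
    """t-SNE embedding of image responses + per-class silhouette, and the
    correlation between class silhouette and selective-unit count."""
    from sklearn.manifold import TSNE
    from sklearn.metrics import silhouette_samples

    labels = table.meta["class"].to_numpy()
    classes = [c for c in pd.unique(labels) if c != SCRAMBLED_LABEL]
    if len(classes) < 3:
        raise ValueError("need at least 3 classes for the cluster audit")
    mask = labels != SCRAMBLED_LABEL
    X = table.responses[:, mask].T.astype(np.float64)
    y = labels[mask]
    if perplexity is None:
        perplexity = min(30.0, max(5.0, (len(y) - 1) / 4))
    emb = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
               init="pca").fit_transform(X)
    sil = silhouette_samples(emb, y)
    by_class = pd.Series({c: float(sil[y == c].mean()) for c in classes})
    common = [c for c in classes if c in counts_per_class]
    if len(common) >= 3:
        r, p = stats.pearsonr(by_class[common].to_numpy(),
                              np.array([counts_per_class[c] for c in common], float))
    else:
        r, p = np.nan, np.nan
    return ClusterAudit(emb, by_class, float(r), float(p))


def silhouette_count_correlation(silhouettes: np.ndarray,
                                 counts: np.ndarray) -> tuple[float, float]:
    """Pearson r (and p) between class silhouette and selective-unit count."""
    r, p = stats.pearsonr(np.asarray(silhouettes, float), np.asarray(counts, float))
    return float(r), float(p)
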