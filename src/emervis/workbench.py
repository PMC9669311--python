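"""End-to-end driver: stimuli -> untrained networks -> responses ->
selectivity -> invariance -> connectivity -> detection -> report.

Every random stage derives its seed deterministically from the master seed
plus the stage name, so re-running an identical configuration reproduces
identical outputs; the run manifest records a config hash, per-stage output
checksums and wall-clock times, and completed stages are skipped on resume.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as cn
from . import detection as dt
from . import invariance as iv
from . import network as nw
from . import selectivity as sl
from . import stimgen as sg


@dataclass
class RunConfig:
    master_seed: int = 0
    n_networks: int = 20
    classes: tuple[str, ...] = sg.DEFAULT_CLASSES
    target_class: str | None = None        # None: pick class with most units
    viewpoint_classes: tuple[str, ...] = ("toilet", "sofa", "monitor")
    n_per_class: int = 200
    vp_steps: int = 13
    vp_span: float = 90.0
    vp_identities: int = 250
    vp_heldout: int = 50
    svm_identities: int = 60
    svm_ranges: tuple[float, ...] = tuple(float(v) for v in range(10, 181, 10))
    layers: tuple[str, ...] = ("conv3", "conv4", "conv5")
    alpha_selectivity: float = 0.001
    alpha_viewpoint: float = 0.05
    max_units_per_layer: int = 200    # cap on per-unit viewpoint analyses
    n_connectivity_targets: int = 30
    detection_repeats: int = 10
    batch_size: int = 16

    @classmethod
    def smoke(cls, master_seed: int = 0) -> "RunConfig":
        """Desk-scale profile: one network, few classes, few images."""
        return cls(
            master_seed=master_seed, n_networks=1,
            classes=("toilet", "sofa", "monitor", "chair"),
            viewpoint_classes=("toilet",),
            n_per_class=12, vp_steps=13, vp_identities=10, vp_heldout=4,
            svm_identities=12, svm_ranges=(60.0, 180.0),
            detection_repeats=5,
        )

    def stage_seed(self, stage: str) -> int:
        return (int(self.master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % 2**31

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
            .encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    stages: dict[str, dict] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config_hash": self.config_hash, "stages": self.stages}, indent=2))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        d = json.loads(path.read_text())
        return cls(d["config_hash"], d["stages"])


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _save_set(outdir: Path, name: str, stim: sg.StimulusSet) -> list[Path]:
    px = outdir / f"{name}_pixels.npy"
    mf = outdir / f"{name}_manifest.csv"
    np.save(px, stim.pixel_stack())
    stim.manifest.to_csv(mf, index=False)
    return [px, mf]


def _load_set(outdir: Path, name: str) -> tuple[np.ndarray, pd.DataFrame]:
    return (np.load(outdir / f"{name}_pixels.npy"),
            pd.read_csv(outdir / f"{name}_manifest.csv"))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_stimuli(cfg: RunConfig, outdir: Path) -> list[Path]:
    seed = cfg.stage_seed("stimuli")
    target = cfg.target_class or cfg.viewpoint_classes[0]
    obj = sg.build_object_dataset(cfg.n_per_class, seed, cfg.classes, target)
    vp = sg.build_viewpoint_dataset(cfg.vp_steps, (-cfg.vp_span, cfg.vp_span),
                                    cfg.vp_identities, cfg.vp_heldout,
                                    seed + 1, cfg.viewpoint_classes)
    svm = sg.build_svm_dataset(cfg.svm_identities, len(cfg.svm_ranges), seed + 2,
                               cfg.classes)
    files = []
    for name, st in (("object", obj), ("viewpoint", vp), ("svm", svm)):
        files += _save_set(outdir, name, st)
    return files


def stage_networks(cfg: RunConfig, outdir: Path) -> list[Path]:
    files = []
    for k in range(cfg.n_networks):
        net = nw.init_untrained(cfg.stage_seed("networks") + k)
        p = outdir / f"net{k:03d}_weights.npz"
        np.savez(p, **net.weights)
        files.append(p)
    meta = outdir / "networks.json"
    meta.write_text(json.dumps({
        "n_networks": cfg.n_networks,
        "seeds": [cfg.stage_seed("networks") + k for k in range(cfg.n_networks)],
        "sd_rule": nw.init_untrained(0).init_sd_rule,
    }, indent=2))
    files.append(meta)
    return files


def _load_net(cfg: RunConfig, outdir: Path, k: int) -> nw.Network:
    data = np.load(outdir / f"net{k:03d}_weights.npz")
    return nw.Network(nw.ALEXNET_SPECS, {n: data[n] for n in data.files},
                      cfg.stage_seed("networks") + k)


def stage_responses(cfg: RunConfig, outdir: Path) -> list[Path]:
    files = []
    for k in range(cfg.n_networks):
        net = _load_net(cfg, outdir, k)
        for name in ("object", "viewpoint", "svm"):
            px, _ = _load_set(outdir, name)
            layers = cfg.layers if name != "svm" else ("conv5",)
            rec = nw.forward_stimulus_set(net, px, layers, cfg.batch_size)
            p = outdir / f"net{k:03d}_{name}_responses.npz"
            np.savez(p, **rec)
            files.append(p)
    return files


def _table(outdir: Path, k: int, name: str, layer: str) -> sl.ResponseTable:
    rec = np.load(outdir / f"net{k:03d}_{name}_responses.npz")
    _, meta = _load_set(outdir, name)
    shape = nw.init_untrained(0).layer_shapes()[layer]["pre_pool"]
    return sl.ResponseTable(rec[layer], meta, layer, shape)


def stage_selectivity(cfg: RunConfig, outdir: Path) -> list[Path]:
    rows = []
    files = []
    for k in range(cfg.n_networks):
        for layer in cfg.layers:
            table = _table(outdir, k, "object", layer)
            for cl in cfg.classes:
                stats = sl.find_selective_units(table, cl, cfg.alpha_selectivity)
                sel = stats[stats["selected"]]
                rows.append({"net": k, "layer": layer, "class": cl,
                             "n_selective": len(sel),
                             "mean_osi": float(sel["osi"].mean())
                             if len(sel) else np.nan})
                if layer == "conv5" or cl in cfg.viewpoint_classes:
                    p = outdir / f"net{k:03d}_{layer}_{cl}_tuning.csv"
                    stats[stats["selected"]].to_csv(p, index=False)
                    files.append(p)
    p = outdir / "selective_counts.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    return files + [p]


def _target_class(cfg: RunConfig, outdir: Path, k: int) -> str:
    if cfg.target_class:
        return cfg.target_class
    counts = pd.read_csv(outdir / "selective_counts.csv")
    sub = counts[(counts["net"] == k) & (counts["layer"] == "conv5")
                 & counts["class"].isin(cfg.viewpoint_classes)]
    return str(sub.sort_values("n_selective", ascending=False)["class"].iloc[0])


def _selected_units(outdir: Path, k: int, layer: str, cl: str) -> np.ndarray:
    p = outdir / f"net{k:03d}_{layer}_{cl}_tuning.csv"
    if not p.exists():
        return np.array([], int)
    df = pd.read_csv(p)
    return df["unit"].to_numpy(int)


def stage_invariance(cfg: RunConfig, outdir: Path) -> list[Path]:
    rows, idx_rows = [], []
    for k in range(cfg.n_networks):
        target = _target_class(cfg, outdir, k)
        obj5 = _table(outdir, k, "object", "conv5")
        nt_mask = (~obj5.meta["class"].isin([target, sl.SCRAMBLED_LABEL])).to_numpy()
        rng = np.random.default_rng(cfg.stage_seed("invariance") + k)
        for layer in cfg.layers:
            units = _selected_units(outdir, k, layer, target)
            if len(units) == 0:
                continue
            if len(units) > cfg.max_units_per_layer:
                units = np.sort(rng.choice(units, cfg.max_units_per_layer,
                                           replace=False))
            vp = _table(outdir, k, "viewpoint", layer)
            objL = _table(outdir, k, "object", layer)
            nontarget = objL.responses[:, nt_mask]
            labels = iv.classify_units(vp, units, target, cfg.alpha_viewpoint)
            for u, lab in zip(units, labels):
                er = iv.unit_effective_range(vp, int(u), target, nontarget[int(u)],
                                             cfg.alpha_viewpoint)
                ii = iv.unit_invariance_index(vp, int(u), target)
                rows.append({"net": k, "layer": layer, "class": target,
                             "unit": int(u), "label": lab.label,
                             "preferred_angle": lab.preferred_angle,
                             "anova_p": lab.anova_p,
                             "effective_range": er.range_deg,
                             "range_flagged": er.flagged,
                             "invariance_index": ii.index,
                             "index_capped": ii.capped})
            med = float(np.median([r["invariance_index"] for r in rows
                                   if r["net"] == k and r["layer"] == layer]))
            idx_rows.append({"net": k, "layer": layer,
                             "median_invariance_index": med})
    p1 = outdir / "invariance_units.csv"
    pd.DataFrame(rows).to_csv(p1, index=False)
    p2 = outdir / "invariance_by_layer.csv"
    pd.DataFrame(idx_rows).to_csv(p2, index=False)
    return [p1, p2]


def _labels_df(outdir: Path, k: int, layer: str) -> pd.DataFrame:
    df = pd.read_csv(outdir / "invariance_units.csv")
    return df[(df["net"] == k) & (df["layer"] == layer)]


def stage_connectivity(cfg: RunConfig, outdir: Path) -> list[Path]:
    rows = []
    shapes = nw.init_untrained(0).layer_shapes()
    for k in range(cfg.n_networks):
        if not {"conv4", "conv5"} <= set(cfg.layers):
            break
        net = _load_net(cfg, outdir, k)
        target = _target_class(cfg, outdir, k)
        src_df = _labels_df(outdir, k, "conv4")
        tgt_df = _labels_df(outdir, k, "conv5")
        if len(src_df) == 0 or len(tgt_df) == 0:
            continue
        shape4 = shapes["conv4"]["pre_pool"]
        shape5 = shapes["conv5"]["pre_pool"]
        other = np.concatenate([
            _selected_units(outdir, k, "conv4", cl)
            for cl in cfg.classes if cl != target]) if len(cfg.classes) > 1 \
            else np.array([], int)
        labels = cn.SourceLabels(
            specific={int(r.unit): float(r.preferred_angle)
                      for r in src_df.itertuples() if r.label == "specific"},
            invariant={int(r.unit) for r in src_df.itertuples()
                       if r.label == "invariant"},
            other_selective=set(int(u) for u in other),
        )
        rng = np.random.default_rng(cfg.stage_seed("connectivity") + k)
        recs = {}
        for lbl in ("specific", "invariant"):
            sub = tgt_df[tgt_df["label"] == lbl]["unit"].to_numpy(int)
            if len(sub) > cfg.n_connectivity_targets:
                sub = rng.choice(sub, cfg.n_connectivity_targets, replace=False)
            recs[lbl] = [nw.unit_from_index(shape5, "conv5", int(u)) for u in sub]
        profiles = {lbl: cn.build_projection_profiles(net, tgts, labels)
                    for lbl, tgts in recs.items()}
        defined = [p for p in profiles["specific"] if len(p.angle_avg) >= 2]
        if defined:      # needs >=2 source preferred-angle groups to exist
            for lbl in ("specific", "invariant"):
                for rec in cn.homogeneous_index(profiles[lbl], defined):
                    rows.append({"net": k, "label": lbl,
                                 "raw_index": rec.raw_index,
                                 "normalized_index": rec.normalized_index})
    p = outdir / "homogeneous_index.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    return [p]


def stage_detection(cfg: RunConfig, outdir: Path) -> list[Path]:
    rows = []
    for k in range(cfg.n_networks):
        target = _target_class(cfg, outdir, k)
        svm5 = _table(outdir, k, "svm", "conv5")
        labdf = _labels_df(outdir, k, "conv5")
        units_all = np.arange(svm5.n_units)
        sel = _selected_units(outdir, k, "conv5", target)
        spec = labdf[labdf["label"] == "specific"]["unit"].to_numpy(int)
        inv = labdf[labdf["label"] == "invariant"]["unit"].to_numpy(int)
        center = labdf[(labdf["label"] == "specific")
                       & (np.isclose(labdf["preferred_angle"].fillna(99), 0.0))
                       ]["unit"].to_numpy(int)
        rng = np.random.default_rng(cfg.stage_seed("detection") + k)
        nonsel = rng.choice(np.setdiff1d(units_all, sel),
                            size=max(len(inv), len(spec), 1), replace=False)
        subsets = {"invariant": inv, "specific_all": spec,
                   "specific_center": center if len(center) else spec,
                   "non_selective": nonsel}
        subsets = {n: v for n, v in subsets.items() if len(v) > 0}
        if "invariant" not in subsets or len(subsets) < 2:
            continue
        meta = svm5.meta
        tmask = (meta["class"] == target).to_numpy()
        train_resp, test_by_range, labels_vec = _detection_pools(
            cfg, svm5, tmask, target, rng)
        base = dt.TaskConfig(n_target=cfg.svm_identities,
                             n_nontarget=cfg.svm_identities,
                             n_train=(4 * cfg.svm_identities) // 3,
                             n_test=(2 * cfg.svm_identities) // 3,
                             n_repeats=cfg.detection_repeats,
                             seed=cfg.stage_seed("detection") + k)
        res = dt.sweep_variation_range(train_resp, test_by_range, labels_vec,
                                       subsets, base)
        for name, by_range in res.items():
            for V, r in by_range.items():
                rows.append({"net": k, "subset": name, "range": V,
                             "mean_accuracy": r.mean, "sd_accuracy": r.sd,
                             "subset_size": r.subset_size})
    p = outdir / "detection.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    return [p]


def _detection_pools(cfg: RunConfig, svm5: sl.ResponseTable, tmask: np.ndarray,
                     target: str, rng: np.random.Generator):
    """Assemble aligned train/test response pools for the detection task.

    Columns are identity-aligned: target identities first, then the same
    number of non-target identities drawn uniformly from the other classes.
    Train pool = front-view (V=0) responses; test pools = responses within
    each variation range.
    """
    meta = svm5.meta
    idents = sorted(meta.loc[tmask, "identity"].unique())
    others = [c for c in meta["class"].unique() if c != target]
    non_pairs = [(rng.choice(others), i) for i in idents]

    def cols(V: float) -> np.ndarray:
        sel = []
        for cl, ident in ([(target, i) for i in idents] + non_pairs):
            m = ((meta["class"] == cl) & (meta["identity"] == ident)
                 & np.isclose(meta["variation_range"], V))
            sel.append(int(np.nonzero(m.to_numpy())[0][0]))
        return np.asarray(sel)

    labels_vec = np.array([True] * len(idents) + [False] * len(non_pairs))
    train_resp = svm5.responses[:, cols(0.0)]
    test_by_range = {float(V): svm5.responses[:, cols(float(V))]
                     for V in cfg.svm_ranges}
    return train_resp, test_by_range, labels_vec


def stage_report(cfg: RunConfig, outdir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files = []
    counts = pd.read_csv(outdir / "selective_counts.csv")
    fig, ax = plt.subplots(figsize=(7, 4))
    sub = counts[counts["layer"] == "conv5"]
    ax.boxplot([sub[sub["class"] == c]["n_selective"] for c in cfg.classes],
               tick_labels=cfg.classes)
    ax.set_ylabel("selective units (conv5)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    p = outdir / "panel_selective_counts.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    files.append(p)

    inv = pd.read_csv(outdir / "invariance_by_layer.csv")
    if len(inv):
        fig, ax = plt.subplots(figsize=(5, 4))
        for k, g in inv.groupby("net"):
            g = g.set_index("layer").reindex(list(cfg.layers))
            ax.plot(list(cfg.layers), g["median_invariance_index"], "o-", alpha=0.6)
        ax.set_ylabel("median invariance index")
        fig.tight_layout()
        p = outdir / "panel_invariance_by_layer.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        files.append(p)

    det_path = outdir / "detection.csv"
    if det_path.exists():
        det = pd.read_csv(det_path)
        if len(det):
            fig, ax = plt.subplots(figsize=(5, 4))
            for name, g in det.groupby("subset"):
                g2 = g.groupby("range")["mean_accuracy"].mean()
                ax.plot(g2.index, g2.values, "o-", label=name)
            ax.axhline(0.5, ls="--", c="gray")
            ax.set_xlabel("test viewpoint variation range (deg)")
            ax.set_ylabel("detection accuracy")
            ax.legend(fontsize=7)
            fig.tight_layout()
            p = outdir / "panel_detection.png"
            fig.savefig(p, dpi=100)
            plt.close(fig)
            files.append(p)

    summary = counts.copy()
    p = outdir / "summary.csv"
    summary.to_csv(p, index=False)
    files.append(p)
    return files


# ---------------------------------------------------------------------------
# in-memory end-to-end study (no file IO); the qualitative-replication runner
# ---------------------------------------------------------------------------

def run_study(master_seed: int = 0, n_networks: int = 5,
              classes: tuple[str, ...] = sg.DEFAULT_CLASSES,
              target_class: str = "toilet",
              n_per_class: int = 16,
              vp_identities: int = 25, vp_heldout: int = 10,
              svm_identities: int = 12, test_range: float = 180.0,
              max_units_per_layer: int = 150,
              detection_repeats: int = 20, batch_size: int = 16) -> dict:
    """Stimuli -> several untrained networks -> headline statistics.

    A desk-scale version of the full study: one shared synthetic stimulus
    set, ``n_networks`` independently initialized networks, and per network
    (i) selective-unit counts per class in conv5, (ii) median invariance
    index of target-class selective units in conv3/4/5, and (iii) the
    front-view-trained detection accuracy of invariant, front-preferring
    specific, and non-selective unit subsets at the given test range.
    When the one-way-ANOVA labels leave fewer than three units in either
    viewpoint class, the tentative top/bottom-30%-by-effective-range split
    stands in for them.
    """
    seed = (int(master_seed) * 1_000_003 + zlib.crc32(b"study")) % 2**31
    layers = ("conv3", "conv4", "conv5")
    obj = sg.build_object_dataset(n_per_class, seed, classes, target_class)
    vp = sg.build_viewpoint_dataset(13, (-90.0, 90.0), vp_identities,
                                    vp_heldout, seed + 1, (target_class,))
    svm = sg.build_svm_dataset(svm_identities, 1, seed + 2, classes)
    obj_px, vp_px, svm_px = (s.pixel_stack() for s in (obj, vp, svm))

    per_seed = []
    for k in range(n_networks):
        net = nw.init_untrained(seed + 10 + k)
        rec_obj = nw.forward_stimulus_set(net, obj_px, layers, batch_size)
        rec_vp = nw.forward_stimulus_set(net, vp_px, layers, batch_size)
        rec_svm = nw.forward_stimulus_set(net, svm_px, ("conv5",), batch_size)
        obj_tables = {l: sl.ResponseTable(rec_obj[l], obj.manifest, l)
                      for l in layers}
        vp_tables = {l: sl.ResponseTable(rec_vp[l], vp.manifest, l)
                     for l in layers}
        svm_table = sl.ResponseTable(rec_svm["conv5"], svm.manifest, "conv5")
        rng = np.random.default_rng(seed + 500 + k)

        counts = {}
        sel_units = {}
        any_selective = np.zeros(obj_tables["conv5"].n_units, bool)
        for cl in classes:
            stats5 = sl.find_selective_units(obj_tables["conv5"], cl)
            counts[cl] = int(stats5["selected"].sum())
            any_selective |= stats5["selected"].to_numpy()
            if cl == target_class:
                sel_units["conv5"] = stats5.index[stats5["selected"]].to_numpy()
        for l in ("conv3", "conv4"):
            st = sl.find_selective_units(obj_tables[l], target_class)
            sel_units[l] = st.index[st["selected"]].to_numpy()

        medians = {}
        for l in layers:
            units = sel_units[l]
            if len(units) == 0:
                medians[l] = np.nan
                continue
            idx = iv.invariance_index_matrix(vp_tables[l], target_class)
            medians[l] = float(np.median(idx[units]))

        result = {"net_seed": seed + 10 + k, "counts": counts,
                  "invariance_medians": medians,
                  "n_selective_target": {l: int(len(sel_units[l]))
                                         for l in layers}}

        units5 = sel_units["conv5"]
        if len(units5) > max_units_per_layer:
            units5 = np.sort(rng.choice(units5, max_units_per_layer,
                                        replace=False))
        if len(units5) >= 10:
            labels5 = iv.classify_units(vp_tables["conv5"], units5, target_class)
            inv_ids = [l.unit for l in labels5 if l.label == "invariant"]
            spec = [l for l in labels5 if l.label == "specific"]
            center_ids = [l.unit for l in spec
                          if l.preferred_angle is not None
                          and abs(l.preferred_angle) <= 1e-9]
            if min(len(inv_ids), len(spec)) < 3:
                nt_mask = (~obj.manifest["class"].isin(
                    [target_class, sl.SCRAMBLED_LABEL])).to_numpy()
                nontgt = obj_tables["conv5"].responses[:, nt_mask]
                ranges = {int(u): iv.unit_effective_range(
                    vp_tables["conv5"], int(u), target_class,
                    nontgt[int(u)]).range_deg for u in units5}
                inv_ids, spec_ids = iv.percentile_split(ranges)
                center_ids = spec_ids
            elif not center_ids:
                center_ids = [l.unit for l in spec]
            # non-selective: units selective for no object class at all
            non_sel = rng.choice(np.nonzero(~any_selective)[0],
                                 size=max(len(inv_ids), len(center_ids)),
                                 replace=False)
            subsets = {"invariant": np.asarray(inv_ids, int),
                       "specific_center": np.asarray(center_ids, int),
                       "non_selective": non_sel}
            tmask = (svm.manifest["class"] == target_class).to_numpy()
            cfg0 = RunConfig(master_seed=master_seed,
                             svm_ranges=(float(test_range),),
                             svm_identities=svm_identities)
            train_resp, test_by_range, labels_vec = _detection_pools(
                cfg0, svm_table, tmask, target_class, rng)
            base = dt.TaskConfig(
                n_target=svm_identities, n_nontarget=svm_identities,
                n_train=(4 * svm_identities) // 3,
                n_test=2 * svm_identities - (4 * svm_identities) // 3,
                n_repeats=detection_repeats, seed=seed + 900 + k)
            sweep = dt.sweep_variation_range(train_resp, test_by_range,
                                             labels_vec, subsets, base)
            result["detection"] = {name: by_r[float(test_range)].mean
                                   for name, by_r in sweep.items()}
            result["subset_sizes"] = {name: int(len(v))
                                      for name, v in subsets.items()}
        per_seed.append(result)

    ms = [r["invariance_medians"] for r in per_seed]
    summary = {
        "per_seed": per_seed,
        "n_seeds_with_selective_units": sum(
            1 for r in per_seed if max(r["counts"].values()) > 0),
        "n_seeds_monotone_invariance": sum(
            1 for m in ms
            if np.isfinite([m[l] for l in layers]).all()
            and m["conv3"] <= m["conv4"] <= m["conv5"]),
        "n_seeds_detection_ordered": sum(
            1 for r in per_seed if "detection" in r
            and r["detection"]["invariant"] > r["detection"]["specific_center"]
            and abs(r["detection"]["non_selective"] - 0.5) < 0.15),
        "n_networks": n_networks,
    }
    return summary


STAGES = (
    ("stimuli", stage_stimuli),
    ("networks", stage_networks),
    ("responses", stage_responses),
    ("selectivity", stage_selectivity),
    ("invariance", stage_invariance),
    ("connectivity", stage_connectivity),
    ("detection", stage_detection),
    ("report", stage_report),
)


def run_pipeline(cfg: RunConfig, outdir: str | Path,
                 stages: tuple[str, ...] | None = None) -> RunManifest:
    """Execute the pipeline stage by stage; completed stages are skipped.

    A stage is considered complete when the manifest lists it under the
    current config hash and all of its output files still exist.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    man_path = outdir / "manifest.json"
    chash = cfg.config_hash()
    manifest = (RunManifest.load(man_path)
                if man_path.exists() else RunManifest(chash))
    if manifest.config_hash != chash:
        manifest = RunManifest(chash)
    wanted = stages or tuple(n for n, _ in STAGES)
    for name, fn in STAGES:
        if name not in wanted:
            continue
        done = manifest.stages.get(name)
        if done and all(Path(f).exists() for f in done["files"]):
            continue
        t0 = time.time()
        try:
            files = fn(cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.stages[name] = {
            "files": [str(f) for f in files],
            "checksums": {Path(f).name: _checksum(Path(f)) for f in files},
            "seconds": round(time.time() - t0, 2),
        }
        manifest.save(man_path)
    return manifest
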