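"""Viewpoint tuning curves, effective ranges, unit classification and the
invariance index."""

import numpy as np
import pandas as pd
import pytest

from emervis import invariance as iv
from emervis import selectivity as sl

from conftest import viewpoint_table

GRID15 = tuple(float(v) for v in range(-90, 91, 15))


class TestTuningCurve:
    def _table(self, curve_fn, **kw):
        kw.setdefault("grid", GRID15)
        kw.setdefault("subset", "analysis")
        return viewpoint_table(curve_fn, **kw)

    def test_constant_responses_flat_zero_sem(self):
        rows = []
        for v in (-30.0, 0.0, 30.0):
            rows += [{"class": "toilet", "viewpoint_deg": v,
                      "subset": "analysis"}] * 5
        meta = pd.DataFrame(rows)
        table = sl.ResponseTable(np.full((1, len(meta)), 2.0), meta)
        c = iv.tuning_curve(table, 0, "toilet")
        assert np.allclose(c.mean, 2.0) and np.allclose(c.sem, 0.0)

    def test_planted_cosine_recovered(self):
        amp, base = 2.0, 5.0
        table = self._table(lambda u, v: base + amp * np.cos(np.deg2rad(v)),
                            n_per_vp=200, noise_sd=0.5, seed=1)
        c = iv.tuning_curve(table, 0, "toilet")
        planted = base + amp * np.cos(np.deg2rad(c.grid))
        assert np.all(np.abs(c.mean - planted) < 3 * np.maximum(c.sem, 1e-9) + 0.05)

    def test_means_match_independent_average(self):
        table = self._table(lambda u, v: 3 + 0.01 * v, n_per_vp=10, seed=2)
        c = iv.tuning_curve(table, 0, "toilet")
        for i, v in enumerate(c.grid):
            mask = ((table.meta["viewpoint_deg"] == v)
                    & (table.meta["class"] == "toilet")).to_numpy()
            assert np.isclose(c.mean[i], table.responses[0, mask].mean())

    def test_missing_viewpoint_metadata_rejected(self):
        table = sl.ResponseTable(np.ones((1, 4)),
                                 pd.DataFrame({"class": ["toilet"] * 4}))
        with pytest.raises(ValueError):
            iv.tuning_curve(table, 0, "toilet")


def _range_fixture(sig_until, grid=GRID15, n=200, seed=0):
    """Target responses hugely above non-target for |v| <= sig_until."""
    rng = np.random.default_rng(seed)
    # non-significant viewpoints sit well below the null pool so the
    # one-sided test cannot flip them in by chance
    target = {v: (np.abs(rng.normal(10.0, 0.5, n)) if abs(v) <= sig_until
                  else np.abs(rng.normal(0.3, 0.1, n))) for v in grid}
    nontarget = np.abs(rng.normal(1.0, 0.5, 5 * n))
    return target, nontarget


class TestEffectiveRange:
    def test_contiguous_45_yields_105(self):
        """Significance at -45..+45 on a 15-degree grid spans 105 degrees."""
        target, nontarget = _range_fixture(45)
        er = iv.effective_range(target, nontarget)
        assert er.range_deg == 105.0
        assert er.significant == [-45.0, -30.0, -15.0, 0.0, 15.0, 30.0, 45.0]

    def test_significant_everywhere_yields_195(self):
        target, nontarget = _range_fixture(90)
        er = iv.effective_range(target, nontarget)
        assert er.range_deg == 195.0

    def test_frontal_view_not_significant_flags_zero(self):
        rng = np.random.default_rng(1)
        target = {v: np.abs(rng.normal(1.0, 0.5, 100)) for v in GRID15}
        nontarget = np.abs(rng.normal(1.0, 0.5, 500))
        er = iv.effective_range(target, nontarget)
        assert er.range_deg == 0.0 and er.flagged

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_separation_recovered(self, seed):
        cut = [15, 30, 45, 60][seed % 4]
        target, nontarget = _range_fixture(cut, seed=seed)
        er = iv.effective_range(target, nontarget)
        assert er.range_deg == 2 * cut + 15

    def test_monotone_under_added_adjacent_significance(self):
        """Raising an adjacent viewpoint into significance never shrinks
        the effective range."""
        t1, nt = _range_fixture(30, seed=3)
        base = iv.effective_range(t1, nt).range_deg
        t2 = dict(t1)
        t2[45.0] = np.abs(np.random.default_rng(4).normal(10.0, 0.5, 200))
        t2[-45.0] = np.abs(np.random.default_rng(5).normal(10.0, 0.5, 200))
        assert iv.effective_range(t2, nt).range_deg >= base

    def test_isolated_outlier_beyond_gap_excluded(self):
        t, nt = _range_fixture(15, seed=6)
        t[90.0] = np.abs(np.random.default_rng(7).normal(10.0, 0.5, 200))
        er = iv.effective_range(t, nt)
        assert er.range_deg == 45.0 and 90.0 not in er.significant


class TestRawImageCorrelation:
    def test_front_view_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        imgs = rng.uniform(0, 255, (5, 32, 32))
        prof = iv._pearson_pairs(imgs, imgs)
        assert np.allclose(prof, 1.0)

    def test_white_noise_pairs_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (200, 32, 32))
        b = rng.normal(0, 1, (200, 32, 32))
        assert abs(iv._pearson_pairs(a, b).mean()) < 0.02

    def test_rendered_objects_decorrelate_with_rotation(self):
        """Average front-to-rotated correlation falls as |viewpoint| grows."""
        from emervis import stimgen as sg
        cfg = sg.RenderConfig(background_kind="uniform")
        by_vp = {}
        for v in (0.0, 30.0, 60.0, 90.0):
            by_vp[v] = np.stack([
                sg.render_dataset_image("toilet", i, v, 0, cfg, "t").pixels
                for i in range(4)])
        front = by_vp[0.0]
        means = [iv._pearson_pairs(by_vp[v], front).mean()
                 for v in (0.0, 30.0, 60.0, 90.0)]
        assert all(a > b for a, b in zip(means[:-1], means[1:]))

    def test_effective_range_of_correlations(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, (20, 16, 16))
        by_vp = {}
        for v in GRID15:
            noise = rng.normal(0, 1, (20, 16, 16))
            w = 0.9 if abs(v) <= 30 else 0.0
            by_vp[v] = w * base + np.sqrt(1 - w ** 2) * noise
        nt = rng.normal(0, 1, (100, 16, 16))
        er = iv.raw_image_correlation_range(by_vp, nt)
        assert er.range_deg == 75.0


class TestClassifyUnits:
    def test_planted_flat_units_labelled_invariant(self):
        """Flat planted units: at alpha 0.05 at least 90% come out
        invariant (the ANOVA type-I error is the only loss)."""
        table = viewpoint_table(lambda u, v: 5.0, n_units=200, n_per_vp=50,
                                noise_sd=1.0, seed=0)
        labels = iv.classify_units(table, range(200), "toilet")
        frac = np.mean([l.label == "invariant" for l in labels])
        assert frac >= 0.90

    def test_planted_unimodal_units_labelled_specific(self):
        """One viewpoint raised by 3 noise-sd: at least 95% specific with
        the correct preferred angle."""
        prefs = {u: [-60, -30, 0, 30, 60][u % 5] for u in range(100)}
        table = viewpoint_table(
            lambda u, v: 5.0 + (3.0 if v == prefs[u] else 0.0),
            n_units=100, n_per_vp=50, noise_sd=1.0, seed=1)
        labels = iv.classify_units(table, range(100), "toilet")
        good = np.mean([l.label == "specific"
                        and l.preferred_angle == prefs[l.unit]
                        for l in labels])
        assert good >= 0.95

    def test_bimodal_unit_unclassified(self):
        table = viewpoint_table(
            lambda u, v: 5.0 + (4.0 if abs(v) == 60 else 0.0),
            n_units=1, n_per_vp=100, noise_sd=0.5, seed=2)
        (label,) = iv.classify_units(table, [0], "toilet")
        assert label.label == "unclassified"

    def test_type_one_rate_bounded(self):
        """Exchangeable flat units: fraction labelled specific stays near
        or below alpha."""
        table = viewpoint_table(lambda u, v: 3.0, n_units=400, n_per_vp=30,
                                noise_sd=1.0, seed=3)
        labels = iv.classify_units(table, range(400), "toilet", alpha=0.05)
        frac = np.mean([l.label == "specific" for l in labels])
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 400)


class TestPercentileSplit:
    def test_ten_distinct_units_split_three_three(self):
        ranges = {u: float(u * 10) for u in range(10)}
        inv, spec = iv.percentile_split(ranges)
        assert inv == [9, 8, 7] and spec == [0, 1, 2]

    def test_all_equal_warns_and_uses_id_order(self):
        ranges = {u: 30.0 for u in range(10)}
        with pytest.warns(UserWarning, match="equal"):
            inv, spec = iv.percentile_split(ranges)
        assert inv == [0, 1, 2] and spec == [0, 1, 2]

    def test_matches_sort_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(10, 40))
            vals = rng.choice(np.arange(0, 200, 15.0), n)
            ranges = dict(enumerate(vals))
            inv, spec = iv.percentile_split(ranges)
            k = int(np.floor(0.3 * n))
            order = sorted(range(n), key=lambda u: (-vals[u], u))
            assert inv == order[:k]
            order = sorted(range(n), key=lambda u: (vals[u], u))
            assert spec == order[:k]

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            iv.percentile_split({0: 1.0, 1: 2.0})


class TestInvarianceIndex:
    def test_worked_value(self):
        rec = iv.invariance_index([1.0, 2.0, 3.0])
        assert np.isclose(rec.index, 1.0 / np.sqrt(2.0 / 3.0))
        assert np.isclose(rec.index, 1.2247, atol=1e-4)

    def test_flat_curve_capped_and_flagged(self):
        rec = iv.invariance_index([2.0, 2.0, 2.0])
        assert rec.index == iv.DEFAULT_INDEX_CAP and rec.capped

    def test_monotone_decreasing_in_tuning_amplitude(self):
        amps = np.linspace(0.1, 2.0, 8)
        vals = []
        for a in amps:
            means = 5.0 + a * np.cos(np.deg2rad(np.array(GRID15)))
            vals.append(iv.invariance_index(means).index)
        assert all(x > y for x, y in zip(vals[:-1], vals[1:]))

    def test_scale_covariance(self):
        means = np.array([1.0, 3.0, 2.0])
        base = iv.invariance_index(means).index
        assert np.isclose(iv.invariance_index(5.0 * means).index, base / 5.0)


class TestInvarianceIndexMatrix:
    def test_matches_per_unit_computation(self):
        table = viewpoint_table(
            lambda u, v: 4.0 + 0.3 * u + 0.02 * abs(v), n_units=6,
            n_per_vp=10, noise_sd=0.5, seed=9, subset="analysis")
        mat = iv.invariance_index_matrix(table, "toilet")
        for u in range(6):
            per = iv.unit_invariance_index(table, u, "toilet").index
            assert np.isclose(mat[u], per, atol=1e-9)
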