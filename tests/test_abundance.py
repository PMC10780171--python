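import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ramanabund as ra
from ramanabund.peakfit import SQRT_PI_OVER_2


def eq2_band(ax, mu, area, sigma):
    return area / (sigma * SQRT_PI_OVER_2) * np.exp(-2 * (ax - mu) ** 2 / sigma**2)


def planted_set(n_cells=6, area=4.0, center=1000.0, sigma=8.0, noise=0.0, seed=0):
    ax = np.arange(400.0, 2000.0, 2.0)
    rng = np.random.default_rng(seed)
    rows = [eq2_band(ax, center, area, sigma) + rng.normal(0, noise, ax.size)
            for _ in range(n_cells)]
    phases = (["lag", "log", "stationary"] * n_cells)[:n_cells]
    labels = pd.DataFrame({"cell_id": [f"c{i}" for i in range(n_cells)],
                           "culture_time_h": [1.0] * n_cells,
                           "phase": phases})
    return ra.SpectrumSet(ax, np.vstack(rows), labels)


class TestQuantify:
    def test_isolated_peak_tpa_within_5pct(self):
        sset = planted_set(area=4.0)
        table = ra.quantify(sset, [(1000.0, "protein")], mode="tpa", rescale=False)
        got = table.areas["1000"].to_numpy()
        assert np.all(np.abs(got - 4.0) / 4.0 < 0.05)
        assert set(table.methods["1000"]) == {"tpa"}

    def test_shoulder_pair_takes_gaussian_path(self):
        ax, spectra, truth = ra.simulate_shoulder_spectra(n_spectra=20, snr=5.0,
                                                          seed=13)
        labels = pd.DataFrame({"cell_id": [f"c{i}" for i in range(20)],
                               "culture_time_h": [5.0] * 20,
                               "phase": ["log"] * 20})
        sset = ra.SpectrumSet(ax, spectra, labels)
        cfg = ra.PipelineConfig(tpa_half_width=15.0, fit_window_half_width=15.0)
        table = ra.quantify(sset, [(1096.8, "nucleic_acid")], mode="auto",
                            config=cfg, rescale=False)
        methods = table.methods["1096.8"].to_numpy()
        assert (methods == "gauss").mean() > 0.5
        areas = table.areas["1096.8"].to_numpy()
        rel = np.abs(areas - truth["areas"][0]) / truth["areas"][0]
        assert np.median(rel[np.isfinite(rel)]) < 0.10

    def test_out_of_range_peak_skipped_with_warning(self):
        sset = planted_set()
        with pytest.warns(UserWarning, match="outside"):
            table = ra.quantify(sset, [(1000.0, "protein"), (2100.0, "protein")],
                                mode="tpa", rescale=False)
        assert list(table.areas.columns) == ["1000"]


class TestAnovaByPhase:
    def _table(self, values_by_phase, peak="726"):
        rows, phases = [], []
        for ph, vals in values_by_phase.items():
            rows.extend(vals)
            phases.extend([ph] * len(vals))
        areas = pd.DataFrame({peak: rows})
        labels = pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(rows))],
                               "phase": phases})
        return ra.AbundanceTable(areas=areas, methods=areas.astype(str),
                                 labels=labels)

    def test_identical_means_not_significant(self):
        rng = np.random.default_rng(0)
        table = self._table({ph: list(5 + rng.normal(0, 1, 15))
                             for ph in ("lag", "log", "stationary")})
        out = ra.anova_by_phase(table).table.iloc[0]
        assert out["p"] > 0.05 and out["stars"] == "ns"

    def test_strong_effect_three_stars_and_closed_form_F(self):
        rng = np.random.default_rng(1)
        groups = {"lag": 1 + 0.1 * rng.normal(size=20),
                  "log": 2 + 0.1 * rng.normal(size=20),
                  "stationary": 3 + 0.1 * rng.normal(size=20)}
        out = ra.anova_by_phase(self._table(groups)).table.iloc[0]
        assert out["p"] < 0.001 and out["stars"] == "***"
        # closed-form one-way F oracle
        g = [np.asarray(v) for v in groups.values()]
        grand = np.concatenate(g).mean()
        ss_b = sum(len(x) * (x.mean() - grand) ** 2 for x in g)
        ss_w = sum(((x - x.mean()) ** 2).sum() for x in g)
        F = (ss_b / 2) / (ss_w / (60 - 3))
        assert out["F"] == pytest.approx(F, rel=1e-10)

    def test_under_two_cells_per_phase_flagged(self):
        table = self._table({"lag": [1.0], "log": [1.0, 2.0],
                             "stationary": [1.0, 2.0]})
        out = ra.anova_by_phase(table).table.iloc[0]
        assert out["stars"] == "untestable"

    def test_bonferroni_option_scales_p(self):
        rng = np.random.default_rng(2)
        groups = {ph: list(5 + rng.normal(0, 1, 10))
                  for ph in ("lag", "log", "stationary")}
        areas = pd.DataFrame({"a": np.concatenate([groups[p] for p in groups]),
                              "b": np.concatenate([groups[p] for p in groups])})
        labels = pd.DataFrame({"cell_id": [f"c{i}" for i in range(30)],
                               "phase": sum(([p] * 10 for p in groups), [])})
        t = ra.AbundanceTable(areas=areas, methods=areas.astype(str), labels=labels)
        raw = ra.anova_by_phase(t, bonferroni=False).table["p"]
        adj = ra.anova_by_phase(t, bonferroni=True).table["p"]
        assert np.allclose(np.minimum(raw * 2, 1.0), adj)

    def test_failed_fits_excluded_pairwise(self):
        groups = {"lag": [1.0, 1.1, np.nan], "log": [2.0, 2.1, 2.2],
                  "stationary": [3.0, 3.1, 2.9]}
        out = ra.anova_by_phase(self._table(groups)).table.iloc[0]
        assert out["n_lag"] == 2 and out["n_log"] == 3
        assert np.isfinite(out["F"])


class TestHeatmapMatrix:
    def _table(self, phase_means, n=4, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows, phases = [], []
        for ph, m in phase_means.items():
            rows.extend(m + sd * rng.normal(size=n))
            phases.extend([ph] * n)
        areas = pd.DataFrame({"p1": rows})
        labels = pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(rows))],
                               "phase": phases})
        return ra.AbundanceTable(areas=areas, methods=areas.astype(str),
                                 labels=labels)

    def test_row_minmax_arithmetic(self):
        hm = ra.heatmap_matrix(self._table({"lag": 1.0, "log": 2.0,
                                            "stationary": 4.0}))
        assert np.allclose(hm.loc["p1", ["lag", "log", "stationary"]],
                           [0.0, 1 / 3, 1.0])

    def test_rows_span_unit_interval(self):
        hm = ra.heatmap_matrix(self._table({"lag": 2.0, "log": 7.0,
                                            "stationary": 4.0}, sd=0.1))
        vals = hm.loc["p1", ["lag", "log", "stationary"]].to_numpy(float)
        assert vals.min() == pytest.approx(0.0) and vals.max() == pytest.approx(1.0)

    def test_constant_row_flagged_at_half(self):
        hm = ra.heatmap_matrix(self._table({"lag": 3.0, "log": 3.0,
                                            "stationary": 3.0}))
        assert bool(hm.loc["p1", "constant"])
        assert np.allclose(hm.loc["p1", ["lag", "log", "stationary"]], 0.5)

    def test_empty_table_raises(self):
        t = ra.AbundanceTable(areas=pd.DataFrame(), methods=pd.DataFrame(),
                              labels=pd.DataFrame())
        with pytest.raises(ValueError):
            ra.heatmap_matrix(t)


class TestStars:
    @pytest.mark.parametrize("p,expected", [
        (0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0009, "***")])
    def test_threshold_map(self, p, expected):
        assert ra.significance_stars(p) == expected
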