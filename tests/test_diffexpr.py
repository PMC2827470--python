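import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from sigtome import diffexpr, synthetic_data as sd
from sigtome.errors import DataError, StatError


# ---------------------------------------------------------------------------
# Independent Welch oracle: hand-rolled statistic + t CDF by quadrature
# ---------------------------------------------------------------------------

def welch_p_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))

    def pdf(u):
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        return c * (1 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(pdf, abs(t), np.inf)
    return 2 * tail


def make_study(matrix_log2, r=3):
    n = matrix_log2.shape[0]
    probes = [f"p{i}" for i in range(n)]
    samples = [f"ctrl_{i}" for i in range(r)] + [f"trt_{i}" for i in range(r)]
    return sd.ExpressionStudy(
        intensities=pd.DataFrame(np.exp2(matrix_log2),
                                 index=pd.Index(probes, name="probe_id"),
                                 columns=samples),
        group_labels=pd.Series(["control"] * r + ["treated"] * r,
                               index=samples, name="group"),
        probe_gene_map={p: p for p in probes},
    )


class TestNormalize:
    def test_none_is_identity(self, small_study):
        out = diffexpr.normalize(small_study, method="none")
        assert out.intensities.equals(small_study.intensities)
        assert out.intensities is not small_study.intensities

    def test_median_equalizes_offset_samples(self):
        rng = np.random.default_rng(0)
        base = rng.normal(8, 1, size=(200, 6))
        base[:, 3:] += 1.7  # constant log2 offset on treated samples
        study = make_study(base)
        out = diffexpr.normalize(study, method="median")
        medians = np.median(np.log2(out.intensities.to_numpy()), axis=0)
        np.testing.assert_allclose(medians, medians[0], atol=1e-9)
        assert study.intensities.iloc[0, 0] == pytest.approx(2.0 ** base[0, 0])

    def test_quantile_equalizes_sorted_columns(self):
        rng = np.random.default_rng(1)
        study = make_study(rng.normal(8, 2, size=(100, 6)))
        out = diffexpr.normalize(study, method="quantile")
        log2 = np.log2(out.intensities.to_numpy())
        sorted_cols = np.sort(log2, axis=0)
        for j in range(1, 6):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0],
                                       atol=1e-9)

    def test_non_positive_intensity_names_probe_and_sample(self, small_study):
        broken = small_study.intensities.copy()
        broken.iloc[2, 1] = 0.0
        study = sd.ExpressionStudy(
            intensities=broken, group_labels=small_study.group_labels,
            probe_gene_map=small_study.probe_gene_map,
        )
        with pytest.raises(DataError) as err:
            diffexpr.normalize(study, method="median")
        assert broken.index[2] in str(err.value)


class TestProbeStatistics:
    def test_identical_groups_give_zero_fc_and_p_one(self):
        m = np.tile(np.array([[5.0], [7.0]]), (1, 6))
        stats = diffexpr.probe_statistics(make_study(m))
        np.testing.assert_allclose(stats["log2fc"], 0.0)
        np.testing.assert_allclose(stats["p_value"], 1.0)

    def test_fourfold_change_on_linear_scale(self):
        m = np.log2(np.array([[4.0, 4, 4, 16, 16, 16]]))
        stats = diffexpr.probe_statistics(make_study(m))
        assert stats["log2fc"].iloc[0] == pytest.approx(2.0)
        assert stats["p_value"].iloc[0] < 1e-200  # zero-variance, unequal means

    def test_agrees_with_quadrature_welch_oracle(self):
        rng = np.random.default_rng(42)
        m = rng.normal(8, 1, size=(1000, 6)) + rng.normal(0, 0.5, size=(1000, 1))
        stats = diffexpr.probe_statistics(make_study(m))
        for i in range(1000):
            expected = welch_p_oracle(m[i, 3:], m[i, :3])
            assert stats["p_value"].iloc[i] == pytest.approx(expected, abs=1e-9)

    def test_requires_two_replicates(self):
        samples = ["c1", "c2", "t1"]
        study = sd.ExpressionStudy(
            intensities=pd.DataFrame(np.ones((3, 3)) * 8,
                                     index=["p1", "p2", "p3"], columns=samples),
            group_labels=pd.Series(["control", "control", "treated"],
                                   index=samples),
            probe_gene_map={"p1": "g1", "p2": "g2", "p3": "g3"},
        )
        with pytest.raises(StatError, match="replicates"):
            diffexpr.probe_statistics(study)


class TestBuildSignature:
    def _stats(self, p_values, log2fc=None):
        n = len(p_values)
        return pd.DataFrame({
            "log2fc": log2fc if log2fc is not None else np.ones(n),
            "p_value": p_values,
        }, index=pd.Index([f"p{i}" for i in range(n)], name="probe_id"))

    def test_all_null_gives_empty_signature(self):
        sig = diffexpr.build_signature(self._stats([1.0, 1.0, 1.0]))
        assert len(sig) == 0

    def test_keeps_exactly_sub_alpha_probes(self):
        sig = diffexpr.build_signature(self._stats([0.01, 0.049, 0.05, 0.2]))
        assert {e.probe_id for e in sig.entries} == {"p0", "p1"}

    def test_sorted_by_p_then_magnitude_then_id(self):
        stats = self._stats([0.01, 0.01, 0.001],
                            log2fc=[1.0, 2.0, 0.5])
        sig = diffexpr.build_signature(stats)
        assert [e.probe_id for e in sig.entries] == ["p2", "p1", "p0"]

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(3)
        stats = self._stats(rng.uniform(0, 1, 200),
                            log2fc=rng.normal(0, 1, 200))
        loose = {e.probe_id for e in diffexpr.build_signature(stats, alpha=0.1).entries}
        tight = {e.probe_id for e in diffexpr.build_signature(stats, alpha=0.02).entries}
        assert tight <= loose

    def test_bh_correction_is_more_conservative(self):
        rng = np.random.default_rng(4)
        stats = self._stats(rng.uniform(0, 1, 500),
                            log2fc=rng.normal(0, 1, 500))
        raw = diffexpr.build_signature(stats, alpha=0.05)
        bh = diffexpr.build_signature(stats, alpha=0.05, correction="bh")
        assert len(bh) <= len(raw)


class TestCollapseAndDirection:
    def test_single_probe_per_gene_is_identity(self):
        entries = (
            diffexpr.SignatureEntry("p1", "g1", 2.0, 0.01),
            diffexpr.SignatureEntry("p2", "g2", -1.0, 0.02),
        )
        sig = diffexpr.Signature(entries=entries, background_size=100, alpha=0.05)
        assert diffexpr.collapse_to_genes(sig).entries == entries

    def test_keeps_smallest_p_probe_per_gene(self):
        entries = (
            diffexpr.SignatureEntry("p1", "g1", 1.0, 0.01),
            diffexpr.SignatureEntry("p2", "g1", 3.0, 0.04),
        )
        sig = diffexpr.Signature(entries=entries, background_size=100, alpha=0.05)
        collapsed = diffexpr.collapse_to_genes(sig)
        assert len(collapsed) == 1
        assert collapsed.entries[0].probe_id == "p1"

    def test_collapse_idempotent(self, small_study):
        stats = diffexpr.probe_statistics(small_study)
        sig = diffexpr.build_signature(stats, probe_gene_map=small_study.probe_gene_map)
        once = diffexpr.collapse_to_genes(sig)
        twice = diffexpr.collapse_to_genes(once)
        assert once.entries == twice.entries
        assert len(once) <= len(sig)

    @pytest.mark.parametrize("n_up,n_down,pct_up,pct_down", [
        (9, 1, 90.0, 10.0),
        (10, 0, 100.0, 0.0),
    ])
    def test_direction_percentages(self, n_up, n_down, pct_up, pct_down):
        entries = tuple(
            diffexpr.SignatureEntry(f"p{i}", f"g{i}",
                                    1.0 if i < n_up else -1.0, 0.01)
            for i in range(n_up + n_down)
        )
        sig = diffexpr.Signature(entries=entries, background_size=100, alpha=0.05)
        summary = diffexpr.summarize_direction(sig)
        assert (summary.pct_up, summary.pct_down) == (pct_up, pct_down)

    def test_empty_signature_direction_undefined(self):
        sig = diffexpr.Signature(entries=(), background_size=10, alpha=0.05)
        with pytest.raises(StatError):
            diffexpr.summarize_direction(sig)


class TestRecoveryProperties:
    def test_type_one_error_controlled_under_pure_null(self):
        """Null studies (no planted effects): fraction of probes at p < 0.05
        stays near the nominal level (Welch on triplicates runs a little
        conservative), averaged over 20 seeds."""
        fracs = []
        for seed in range(20):
            cfg = sd.SimulationConfig(n_probes=5000, signature_size=0, seed=seed)
            stats = diffexpr.probe_statistics(sd.generate_study(cfg))
            fracs.append((stats["p_value"] < 0.05).mean())
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_planted_signature_sensitivity_and_false_positive_band(self):
        """At default effect sizes (2 +- 0.5 log2, noise 0.25, triplicates)
        >=95% of planted probes reach p < 0.05 while null probes are called
        near the nominal 5% level, 20-seed average. Overlap with the planted
        set is reported via sensitivity/FP rather than Jaccard: at a 9:1
        null:signal ratio a nominal-level filter necessarily admits enough
        nulls to cap Jaccard near sens/(1 + 9*fp) ~ 0.75."""
        sens, fps = [], []
        for seed in range(20):
            cfg = sd.SimulationConfig(n_probes=5000, signature_size=500, seed=seed)
            study = sd.generate_study(cfg)
            stats = diffexpr.probe_statistics(study)
            raw = diffexpr.build_signature(stats, alpha=0.05,
                                           probe_gene_map=study.probe_gene_map)
            planted = study.truth.signature_probes
            rec = {e.probe_id for e in raw.entries}
            sens.append(len(rec & planted) / len(planted))
            fps.append(len(rec - planted) / (cfg.n_probes - len(planted)))
        assert np.mean(sens) >= 0.95
        assert 0.03 <= np.mean(fps) <= 0.07
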