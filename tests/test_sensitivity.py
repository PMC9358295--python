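"""eFAST estimator validation on analytic benchmarks and design properties."""
import numpy as np
import pytest

from aquahumor.sensitivity import (
    SensitivityConfig,
    _efast_unit_design,
    efast_design,
    efast_frequencies,
    efast_total_index,
)

A_ISH, B_ISH = 7.0, 0.1


def ishigami(x):
    return (
        np.sin(x[:, 0])
        + A_ISH * np.sin(x[:, 1]) ** 2
        + B_ISH * x[:, 2] ** 4 * np.sin(x[:, 0])
    )


def ishigami_total_indices():
    """Closed-form total-order indices of the Ishigami function."""
    v1 = 0.5 * (1 + B_ISH * np.pi**4 / 5) ** 2
    v2 = A_ISH**2 / 8
    v13 = B_ISH**2 * np.pi**8 * 8 / 225
    v = v1 + v2 + v13
    return np.array([(v1 + v13) / v, v2 / v, v13 / v])


def _ishigami_design(ns, nr, seed=3, extra_dummy=False):
    names = ("x1", "x2", "x3", "dummy") if extra_dummy else ("x1", "x2", "x3")
    cfg = SensitivityConfig(
        parameters=names, samples_per_curve=ns, resamples=nr, outputs=("y",), seed=seed
    )
    unit = _efast_unit_design(cfg, len(names))
    return cfg, -np.pi + 2 * np.pi * unit


class TestDesign:
    def test_rows_and_range(self, params):
        cfg = SensitivityConfig(samples_per_curve=257, resamples=1, seed=0)
        values, base = efast_design(cfg, params)
        assert values.shape == (10 * 257, 10)
        assert np.all(values >= base * 0.5 - 1e-15)
        assert np.all(values <= base * 1.5 + 1e-15)

    def test_study_scale_row_count(self, params):
        """At the full study scale (1991 samples x 3 resamples, ten parameters)
        the design totals 59,730 model runs."""
        cfg = SensitivityConfig(samples_per_curve=1991, resamples=3)
        assert cfg.runs_per_parameter == 5973
        values, _ = efast_design(cfg, params)
        assert values.shape[0] == 59730

    def test_reproducible_under_seed(self, params):
        cfg = SensitivityConfig(samples_per_curve=257, resamples=2, seed=42)
        v1, _ = efast_design(cfg, params)
        v2, _ = efast_design(cfg, params)
        assert np.array_equal(v1, v2)

    def test_nyquist_bound_enforced(self):
        with pytest.raises(ValueError, match="Nyquist"):
            SensitivityConfig(samples_per_curve=33, interference=4)

    def test_frequency_interference(self):
        """Complementary harmonics up to order M stay below half the driving
        frequency, so the total-index band is interference-free."""
        for ns in (257, 513, 1991):
            omega, comp = efast_frequencies(10, ns, 4)
            assert np.all(comp * 4 <= omega // 2)


class TestEstimator:
    def test_ishigami_benchmark(self):
        """Total-order indices match the analytic variance decomposition."""
        cfg, x = _ishigami_design(ns=513, nr=8)
        res = efast_total_index(ishigami(x)[:, None], cfg, design=x, output_names=("y",))
        est = res.total_index["y"].values
        assert np.all(np.abs(est - ishigami_total_indices()) < 0.06)
        assert np.all((est >= 0) & (est <= 1))

    def test_dummy_parameter_null(self):
        """A parameter without any model effect gets a total index < 0.05."""
        cfg, x = _ishigami_design(ns=257, nr=2, extra_dummy=True)
        res = efast_total_index(ishigami(x)[:, None], cfg, design=x, output_names=("y",))
        assert res.total_index.loc["dummy", "y"] < 0.05

    def test_indices_invariant_under_doubling(self):
        """Doubling the samples per curve moves the indices by < 0.02."""
        estimates = []
        for ns in (257, 513):
            cfg, x = _ishigami_design(ns=ns, nr=8)
            res = efast_total_index(ishigami(x)[:, None], cfg, design=x, output_names=("y",))
            estimates.append(res.total_index["y"].values)
        assert np.all(np.abs(estimates[1] - estimates[0]) < 0.02)

    def test_directions_from_monotone_function(self):
        cfg = SensitivityConfig(
            parameters=("a", "b"), samples_per_curve=257, resamples=2, outputs=("y",), seed=1
        )
        x = _efast_unit_design(cfg, 2)
        y = 2.0 * x[:, 0] - 3.0 * x[:, 1]
        res = efast_total_index(y[:, None], cfg, design=x, output_names=("y",))
        assert res.direction.loc["a", "y"] == "+"
        assert res.direction.loc["b", "y"] == "-"

    def test_failed_run_handling(self):
        cfg, x = _ishigami_design(ns=257, nr=1)
        y = ishigami(x)
        mask = np.zeros(len(y), bool)
        mask[::40] = True  # ~2.5% failures: imputed silently
        res = efast_total_index(y[:, None], cfg, design=x, output_names=("y",), failed_mask=mask)
        assert res.failed_runs == mask.sum()
        mask2 = np.zeros(len(y), bool)
        mask2[: len(y) // 3] = True  # >25%: unusable
        with pytest.raises(RuntimeError):
            efast_total_index(y[:, None], cfg, design=x, output_names=("y",), failed_mask=mask2)
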