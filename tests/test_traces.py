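"""Replicate averaging and monoexponential k_obs extraction."""

import numpy as np
import pytest

from vesikin import (
    BindingConditions,
    DataError,
    DegenerateTraceError,
    FluorescenceTrace,
    KineticParams,
    KobsPoint,
    NoiseSpec,
    average_replicates,
    extract_kobs_table,
    fit_monoexponential,
    generate_replicates,
    kobs_closed_form,
)
from vesikin.traces import AVERAGED_ID


def monoexp_trace(k=1.57, plateau=10.0, amplitude=2.0, n=200, span=4.0, lipid=45.5):
    t = np.linspace(0.0, span, n)
    return FluorescenceTrace(
        time=t, signal=plateau - amplitude * np.exp(-k * t), lipid_total=lipid
    )


class TestTraceValidation:
    def test_non_monotone_time_rejected(self):
        t = np.linspace(0, 1, 10)
        t[5] = t[4]
        with pytest.raises(DataError, match="strictly increasing"):
            FluorescenceTrace(time=t, signal=np.ones(10), lipid_total=1.0)

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            FluorescenceTrace(time=np.arange(5.0), signal=np.ones(5), lipid_total=1.0)

    def test_point_invariants(self):
        with pytest.raises(DataError):
            KobsPoint(lipid_accessible=-1.0, k_obs=1.0)
        with pytest.raises(DataError):
            KobsPoint(lipid_accessible=1.0, k_obs=0.0)
        with pytest.raises(DataError):
            KobsPoint(lipid_accessible=1.0, k_obs=1.0, se=-0.1)


class TestAverageReplicates:
    def test_mean_of_identical_traces_is_identity(self):
        tr = monoexp_trace()
        avg = average_replicates([tr, tr])
        assert np.allclose(avg.signal, tr.signal)
        assert avg.replicate_id == AVERAGED_ID

    def test_pointwise_mean(self):
        t = np.linspace(0, 1, 8)
        a = FluorescenceTrace(time=t, signal=np.tile([0.0, 2.0], 4), lipid_total=1.0)
        b = FluorescenceTrace(time=t, signal=np.tile([2.0, 0.0], 4), lipid_total=1.0)
        avg = average_replicates([a, b])
        assert np.allclose(avg.signal, 1.0)

    def test_noise_reduced_by_sqrt_n(self, study_params):
        cond = BindingConditions(protein_conc=0.78, lipid_total=136.5)
        sigma = 0.05
        reps = generate_replicates(
            study_params, cond, 5, noise=NoiseSpec(sigma=sigma, seed=11)
        )
        clean = generate_replicates(study_params, cond, 1)[0]
        avg = average_replicates(reps)
        resid_sd = np.std(avg.signal - clean.signal)
        assert resid_sd == pytest.approx(sigma / np.sqrt(5), rel=0.25)

    def test_mismatched_lipid_rejected(self):
        with pytest.raises(DataError, match="lipid_total"):
            average_replicates([monoexp_trace(lipid=1.0), monoexp_trace(lipid=2.0)])

    def test_mismatched_grid_rejected(self):
        a = monoexp_trace(n=200)
        b = monoexp_trace(n=201)
        with pytest.raises(DataError, match="time grid"):
            average_replicates([a, b])

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            average_replicates([])


class TestMonoexponentialFit:
    def test_exact_model_recovered(self):
        fit = fit_monoexponential(monoexp_trace())
        assert fit.k_obs == pytest.approx(1.57, rel=1e-6)
        assert fit.plateau == pytest.approx(10.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(2.0, rel=1e-6)

    def test_noisy_trace_within_two_percent(self):
        tr = monoexp_trace()
        rng = np.random.default_rng(7)
        noisy = FluorescenceTrace(
            time=tr.time,
            signal=tr.signal + rng.normal(0, 0.02, tr.signal.shape),
            lipid_total=tr.lipid_total,
        )
        fit = fit_monoexponential(noisy)
        assert fit.k_obs == pytest.approx(1.57, rel=0.02)
        assert fit.se_kobs > 0

    def test_agrees_with_grid_search_oracle(self):
        # brute-force oracle: profile the linear parameters exactly for
        # each rate on a log grid, take the argmin
        tr = monoexp_trace(k=0.83, plateau=3.0, amplitude=1.2)
        rng = np.random.default_rng(3)
        y = tr.signal + rng.normal(0, 0.01, tr.signal.shape)
        noisy = FluorescenceTrace(time=tr.time, signal=y, lipid_total=tr.lipid_total)
        grid = np.geomspace(0.01, 10.0, 400)
        costs = []
        for k in grid:
            design = np.column_stack([np.ones_like(tr.time), -np.exp(-k * tr.time)])
            _, rss, *_ = np.linalg.lstsq(design, y, rcond=None)
            costs.append(rss[0] if len(rss) else 0.0)
        k_oracle = grid[int(np.argmin(costs))]
        step = grid[1] / grid[0]
        fit = fit_monoexponential(noisy)
        assert k_oracle / step <= fit.k_obs <= k_oracle * step

    def test_invariant_to_affine_signal_rescaling(self):
        tr = monoexp_trace()
        k0 = fit_monoexponential(tr).k_obs
        scaled = FluorescenceTrace(
            time=tr.time, signal=3.7 * tr.signal + 11.0, lipid_total=tr.lipid_total
        )
        assert fit_monoexponential(scaled).k_obs == pytest.approx(k0, rel=1e-8)

    def test_time_unit_rescaling_scales_rate(self):
        tr = monoexp_trace()
        k0 = fit_monoexponential(tr).k_obs
        ms = FluorescenceTrace(
            time=tr.time * 1000.0, signal=tr.signal, lipid_total=tr.lipid_total
        )
        assert fit_monoexponential(ms).k_obs == pytest.approx(k0 / 1000.0, rel=1e-6)

    def test_flat_trace_is_degenerate(self):
        t = np.linspace(0, 1, 50)
        tr = FluorescenceTrace(time=t, signal=np.full(50, 2.0), lipid_total=1.0)
        with pytest.raises(DegenerateTraceError):
            fit_monoexponential(tr)

    def test_window_with_too_few_points_rejected(self):
        with pytest.raises(DataError, match=">= 4"):
            fit_monoexponential(monoexp_trace(), fit_window=(3.99, 4.0))

    def test_settle_window_removes_second_order_bias(self, study_params):
        # second-order transient biases the full-window rate upward; the
        # settle window recovers the relaxation rate within 2%
        cond = BindingConditions(protein_conc=0.78, lipid_total=91.0)
        tr = generate_replicates(study_params, cond, 1)[0]
        s0 = study_params.c1 * 0.5 * 91.0
        expected = kobs_closed_form(study_params, 0.78, s0)
        biased = fit_monoexponential(tr).k_obs
        settled = fit_monoexponential(tr, settle_decades=3.0).k_obs
        assert abs(settled / expected - 1) < 0.02
        assert abs(settled / expected - 1) < abs(biased / expected - 1)


class TestExtractKobsTable:
    def test_six_group_roundtrip(self, study_params, study_lipid_totals):
        traces = []
        for lt in study_lipid_totals:
            cond = BindingConditions(protein_conc=0.78, lipid_total=lt)
            traces.extend(generate_replicates(study_params, cond, 3))
        cond = BindingConditions(protein_conc=0.78, leaflet_factor=0.5)
        out = extract_kobs_table(traces, cond, settle_decades=3.0)
        assert not out.failures
        assert [p.lipid_accessible for p in out.points] == [
            lt * 0.5 for lt in study_lipid_totals
        ]
        for p in out.points:
            expected = kobs_closed_form(
                study_params, 0.78, study_params.c1 * p.lipid_accessible
            )
            assert p.k_obs == pytest.approx(expected, rel=0.02)

    def test_empty_input_gives_empty_table(self):
        cond = BindingConditions(protein_conc=0.78)
        out = extract_kobs_table([], cond)
        assert out.points == [] and out.failures == {}

    def test_one_failing_group_recorded_not_fatal(self, study_params):
        traces = []
        for lt in (45.5, 91.0, 136.5, 182.0, 227.5):
            cond = BindingConditions(protein_conc=0.78, lipid_total=lt)
            traces.extend(generate_replicates(study_params, cond, 2))
        t = np.linspace(0, 4, 50)
        traces.append(
            FluorescenceTrace(time=t, signal=np.full(50, 1.0), lipid_total=273.0)
        )
        cond = BindingConditions(protein_conc=0.78)
        out = extract_kobs_table(traces, cond, settle_decades=3.0)
        assert len(out.points) == 5
        assert list(out.failures) == [273.0]
        assert "Degenerate" in out.failures[273.0]
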