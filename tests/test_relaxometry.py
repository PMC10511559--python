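"""Inverse problem: forward-inverse identities, oracles, truncation."""

import numpy as np
import pandas as pd
import pytest

from ferrofat.relaxometry import (
    DecayModel,
    InputError,
    fit_fat_water,
    fit_monoexponential,
    fit_truncated,
)
from ferrofat.signal_model import (
    AcquisitionProtocol,
    EchoTrain,
    TissueState,
    add_magnitude_noise,
    evaluate_signal,
)


def make_train(spectrum, protocol, s0=300.0, t2s=15.0, ff=0.0, noise_sd=0.0, seed=None):
    train = evaluate_signal(TissueState(s0=s0, t2star_ms=t2s, ff=ff), protocol, spectrum)
    if noise_sd:
        train = add_magnitude_noise(train, noise_sd, seed=seed)
    return train


class TestMonoexponential:
    def test_forward_inverse_identity(self, spectrum, pancreas_protocol):
        train = make_train(spectrum, pancreas_protocol, s0=500.0, t2s=20.0)
        fit = fit_monoexponential(train)
        assert fit.t2star_ms == pytest.approx(20.0, abs=1e-5)
        assert fit.s0 == pytest.approx(500.0, rel=1e-6)
        assert fit.converged

    def test_matches_loglinear_oracle_on_noiseless_input(self, spectrum, pancreas_protocol):
        """On noiseless monoexponential data the nonlinear estimate equals
        the log-linear regression of ln(signal) on TE."""
        train = make_train(spectrum, pancreas_protocol, s0=120.0, t2s=8.5)
        slope, _ = np.polyfit(train.echo_times_ms, np.log(train.signals), 1)
        t2s_loglinear = -1.0 / slope
        fit = fit_monoexponential(train)
        assert fit.t2star_ms == pytest.approx(t2s_loglinear, rel=1e-6)

    def test_constant_signal_pins_t2s_at_upper_bound(self):
        train = EchoTrain(echo_times_ms=np.arange(1.0, 13.0), signals=np.full(12, 80.0))
        fit = fit_monoexponential(train)
        assert fit.at_bound
        assert fit.t2star_ms == pytest.approx(1000.0, rel=1e-3)

    def test_too_few_echoes_rejected(self):
        train = EchoTrain(echo_times_ms=np.array([1.0, 2.0, 3.0]), signals=np.ones(3))
        with pytest.raises(InputError):
            fit_monoexponential(train)

    def test_offset_recovered(self, spectrum, pancreas_protocol):
        base = make_train(spectrum, pancreas_protocol, s0=400.0, t2s=6.0)
        train = EchoTrain(
            echo_times_ms=base.echo_times_ms, signals=base.signals + 12.0
        )
        fit = fit_monoexponential(train, with_offset=True)
        assert fit.offset == pytest.approx(12.0, rel=1e-4)
        assert fit.t2star_ms == pytest.approx(6.0, rel=1e-4)


class TestFatWater:
    @pytest.mark.parametrize("t2s", [2.0, 10.0, 40.0])
    @pytest.mark.parametrize("ff", [0.1, 0.3, 0.5])
    def test_forward_inverse_identity(self, spectrum, pancreas_protocol, t2s, ff):
        train = make_train(spectrum, pancreas_protocol, s0=300.0, t2s=t2s, ff=ff)
        fit = fit_fat_water(train, spectrum)
        assert fit.converged
        assert fit.t2star_ms == pytest.approx(t2s, rel=1e-4)
        assert fit.ff == pytest.approx(ff, abs=1e-4)
        assert fit.s0 == pytest.approx(300.0, rel=1e-4)

    def test_nests_monoexponential_at_zero_ff(self, spectrum, pancreas_protocol):
        train = make_train(spectrum, pancreas_protocol, s0=200.0, t2s=18.0, ff=0.0)
        fw = fit_fat_water(train, spectrum)
        mono = fit_monoexponential(train)
        assert fw.ff < 1e-6
        assert fw.t2star_ms == pytest.approx(mono.t2star_ms, rel=1e-6)

    def test_scale_equivariance(self, spectrum, pancreas_protocol):
        train = make_train(spectrum, pancreas_protocol, s0=100.0, t2s=12.0, ff=0.35)
        scaled = EchoTrain(
            echo_times_ms=train.echo_times_ms, signals=train.signals * 7.5
        )
        a = fit_fat_water(train, spectrum)
        b = fit_fat_water(scaled, spectrum)
        assert b.s0 == pytest.approx(7.5 * a.s0, rel=1e-6)
        assert b.t2star_ms == pytest.approx(a.t2star_ms, rel=1e-6)
        assert b.ff == pytest.approx(a.ff, abs=1e-6)

    def test_row_order_invariance(self, spectrum, pancreas_protocol, rng):
        train = make_train(
            spectrum, pancreas_protocol, s0=300.0, t2s=9.0, ff=0.25, noise_sd=3.0, seed=5
        )
        perm = rng.permutation(len(train))
        shuffled = EchoTrain(
            echo_times_ms=train.echo_times_ms[perm], signals=train.signals[perm]
        )
        a = fit_fat_water(train, spectrum)
        b = fit_fat_water(shuffled, spectrum)
        assert b.t2star_ms == pytest.approx(a.t2star_ms, rel=1e-8)
        assert b.ff == pytest.approx(a.ff, abs=1e-8)

    def test_too_few_echoes_rejected(self, spectrum):
        train = EchoTrain(echo_times_ms=np.arange(1.0, 6.0), signals=np.ones(5))
        with pytest.raises(InputError):
            fit_fat_water(train, spectrum)

    def test_grid_search_oracle_brackets_optimum(self, spectrum, pancreas_protocol):
        """A coarse exhaustive SSE grid (T2* x FF, with S0 profiled out
        analytically) must bracket the solver's optimum on noisy data."""
        te = np.asarray(pancreas_protocol.echo_times_ms)
        phasor = spectrum.phasor(te)
        t2s_grid = np.arange(1.0, 50.01, 0.5)
        ff_grid = np.arange(0.0, 1.0001, 0.01)
        mod = np.abs(
            (1.0 - ff_grid[:, None, None])
            + ff_grid[:, None, None] * phasor[None, None, :]
        )  # (ff, 1, te)
        decay = np.exp(-te[None, None, :] / t2s_grid[None, :, None])  # (1, t2s, te)
        g = mod * decay  # (ff, t2s, te)

        rng = np.random.default_rng(99)
        for _ in range(8):
            t2s_true = rng.uniform(5.0, 30.0)
            ff_true = rng.uniform(0.05, 0.6)
            train = make_train(
                spectrum, pancreas_protocol, s0=500.0, t2s=t2s_true, ff=ff_true,
                noise_sd=10.0, seed=int(rng.integers(1 << 31)),
            )
            y = train.signals
            s0_opt = (g * y).sum(axis=2) / (g * g).sum(axis=2)
            sse = ((s0_opt[:, :, None] * g - y) ** 2).sum(axis=2)
            i, j = np.unravel_index(np.argmin(sse), sse.shape)

            fit = fit_fat_water(train, spectrum)
            assert fit.rss <= sse[i, j] + 1e-9
            assert abs(fit.t2star_ms - t2s_grid[j]) <= 0.5 + 1e-9
            assert abs(fit.ff - ff_grid[i]) <= 0.01 + 1e-9


class TestTruncated:
    def test_high_snr_keeps_all_echoes_and_matches_mono(self, spectrum, pancreas_protocol):
        train = make_train(
            spectrum, pancreas_protocol, s0=1000.0, t2s=25.0, noise_sd=1.0, seed=3
        )
        trunc = fit_truncated(train)
        mono = fit_monoexponential(train)
        assert trunc.n_echoes_used == len(train)
        assert trunc.t2star_ms == pytest.approx(mono.t2star_ms, rel=1e-6)

    def test_short_t2s_with_noise_floor_truncates(self, spectrum, pancreas_protocol):
        train = make_train(
            spectrum, pancreas_protocol, s0=1000.0, t2s=1.5, noise_sd=50.0, seed=7
        )
        trunc = fit_truncated(train)
        assert trunc.n_echoes_used < len(train)
        assert trunc.n_echoes_used >= 4

    def test_truncation_reduces_mean_error_at_short_t2s(self, spectrum, pancreas_protocol):
        """Dropping echoes below the noise floor must not worsen the
        average T2* error (simulation oracle at reduced scale)."""
        t2s_true, errs_trunc, errs_full = 1.5, [], []
        for seed in range(60):
            train = make_train(
                spectrum, pancreas_protocol, s0=1000.0, t2s=t2s_true,
                noise_sd=50.0, seed=seed,
            )
            errs_trunc.append(abs(fit_truncated(train).t2star_ms - t2s_true))
            errs_full.append(abs(fit_monoexponential(train).t2star_ms - t2s_true))
        assert np.mean(errs_trunc) <= np.mean(errs_full)

    def test_requires_five_echoes(self):
        train = EchoTrain(echo_times_ms=np.arange(1.0, 5.0), signals=np.ones(4))
        with pytest.raises(InputError):
            fit_truncated(train)


class TestDecayModelResults:
    def test_fit_and_summary(self, spectrum, pancreas_protocol):
        train = make_train(spectrum, pancreas_protocol, s0=300.0, t2s=15.0, ff=0.25)
        model = DecayModel.from_echo_train(train, spectrum=spectrum)
        res = model.fit("fat_water")
        assert res.params["t2star_ms"] == pytest.approx(15.0, rel=1e-4)
        text = res.summary()
        assert "fat_water" in text and "t2star_ms" in text
        assert set(res.bse) == {"s0", "t2star_ms", "ff"}
        np.testing.assert_allclose(res.predict(), train.signals, rtol=1e-6)

    def test_from_dataframe(self, spectrum, pancreas_protocol):
        train = make_train(spectrum, pancreas_protocol, s0=100.0, t2s=30.0)
        df = pd.DataFrame({"te_ms": train.echo_times_ms, "signal": train.signals})
        res = DecayModel.from_dataframe(df).fit("mono")
        assert res.params["t2star_ms"] == pytest.approx(30.0, rel=1e-5)

    def test_unknown_variant_rejected(self, spectrum, pancreas_protocol):
        train = make_train(spectrum, pancreas_protocol)
        with pytest.raises(ValueError):
            DecayModel.from_echo_train(train).fit("biexponential")
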