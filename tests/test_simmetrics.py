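import numpy as np
import pandas as pd
import pytest

from drybench import simmetrics
from drybench.ioformats import ValidationError
from drybench.simmetrics import (
    SpectralParams,
    UndefinedMetricError,
    band_correlation,
    grand_average,
    msc,
    rms_amplitude,
    split_half_stability,
    welch_psd,
)

from conftest import make_epochset


# --- independent direct-DFT oracle (brute force, no FFT machinery) ---------


def _hamming(m):  # periodic window, the Welch convention
    n = np.arange(m)
    return 0.54 - 0.46 * np.cos(2 * np.pi * n / m)


def _oracle_segments(x, nperseg, noverlap):
    win = _hamming(nperseg)
    step = nperseg - noverlap
    out = []
    for s in range(1 + (len(x) - nperseg) // step):
        seg = x[s * step : s * step + nperseg]
        seg = (seg - seg.mean()) * win
        k = np.arange(nperseg // 2 + 1)
        out.append(
            np.array(
                [np.sum(seg * np.exp(-2j * np.pi * kk * np.arange(nperseg) / nperseg)) for kk in k]
            )
        )
    return np.array(out), 1.0 / np.sum(win**2)


def oracle_welch(x, fs, nperseg, noverlap):
    spec, scale = _oracle_segments(x, nperseg, noverlap)
    p = (np.abs(spec) ** 2).mean(axis=0) * scale / fs
    p[1:-1] *= 2
    return p


def oracle_msc(x, y, fs, nperseg, noverlap):
    sx, scale = _oracle_segments(x, nperseg, noverlap)
    sy, _ = _oracle_segments(y, nperseg, noverlap)
    pxy = (sx * np.conj(sy)).mean(axis=0)
    pxx = (np.abs(sx) ** 2).mean(axis=0)
    pyy = (np.abs(sy) ** 2).mean(axis=0)
    return np.abs(pxy) ** 2 / (pxx * pyy)


# ---------------------------------------------------------------------------


class TestRms:
    def test_constant(self):
        ep = make_epochset(np.full((4, 1, 100), 3.0), 50.0, ["a"])
        per, mean = rms_amplitude(ep, "a")
        assert np.allclose(per, 3.0) and mean == pytest.approx(3.0)

    def test_sine_amplitude(self):
        t = np.arange(1000) / 1000.0
        x = 5.0 * np.sin(2 * np.pi * 10 * t)  # whole cycles
        ep = make_epochset(x[None, None, :], 1000.0, ["a"])
        _, mean = rms_amplitude(ep, "a")
        assert mean == pytest.approx(5.0 / np.sqrt(2), rel=1e-6)

    def test_zero_and_empty(self):
        ep = make_epochset(np.zeros((2, 1, 10)), 10.0, ["a"])
        assert rms_amplitude(ep, "a")[1] == 0.0
        empty = make_epochset(np.empty((0, 1, 10)), 10.0, ["a"])
        with pytest.raises(UndefinedMetricError):
            rms_amplitude(empty, "a")


class TestBandCorrelation:
    def test_identity_and_monotone_invariance(self):
        x = np.random.default_rng(0).normal(size=500)
        assert band_correlation(x, x) == pytest.approx(1.0)
        assert band_correlation(x, np.exp(x)) == pytest.approx(1.0)

    def test_constant_is_missing(self):
        x = np.random.default_rng(0).normal(size=500)
        assert np.isnan(band_correlation(x, np.full(500, 2.0)))

    def test_null_width(self):
        # independent pairs at n = 1e4: |rho| < 0.05 in >= 95% of seeds
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rho = band_correlation(rng.normal(size=10_000), rng.normal(size=10_000))
            hits += abs(rho) < 0.05
        assert hits / n_seeds >= 0.95

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError, match="100"):
            band_correlation(np.arange(50.0), np.arange(50.0))


class TestWelchPsd:
    def test_agrees_with_direct_dft_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        ep = make_epochset(x[None, None, :], 4.0, ["a"])
        params = SpectralParams(f_range=(0.0, 2.0), resolution_hz=1.0)
        _, per, _ = welch_psd(ep, "a", params)
        expected = oracle_welch(x, 4.0, 4, 2)
        assert np.max(np.abs(10 ** (per[0] / 10) - expected)) < 1e-10

    def test_white_noise_flat(self):
        rng = np.random.default_rng(2)
        ep = make_epochset(rng.normal(size=(250, 1, 400)), 200.0, ["a"])
        _, _, db = welch_psd(ep, "a")
        assert db.max() - db.min() < 2.0  # flat within ±1 dB

    def test_sine_peak_bin_and_plus_6db(self):
        t = np.arange(400) / 200.0
        base = np.sin(2 * np.pi * 10 * t)
        f, _, db1 = welch_psd(make_epochset(base[None, None, :], 200.0, ["a"]), "a")
        _, _, db2 = welch_psd(make_epochset(2 * base[None, None, :], 200.0, ["a"]), "a")
        peak = np.argmax(db1)
        assert f[peak] == 10.0
        assert db2[peak] - db1[peak] == pytest.approx(20 * np.log10(2), abs=1e-6)

    def test_range_outside_nyquist(self):
        ep = make_epochset(np.zeros((1, 1, 400)), 60.0, ["a"])
        with pytest.raises(ValidationError, match="Nyquist"):
            welch_psd(ep, "a", SpectralParams(f_range=(2.0, 35.0)))


class TestMsc:
    def test_agrees_with_direct_dft_oracle(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=8)
        ep = make_epochset(np.stack([x, y])[None], 4.0, ["a", "b"])
        params = SpectralParams(f_range=(0.0, 2.0), resolution_hz=1.0)
        _, coh = msc(ep, ("a", "b"), params)
        assert np.max(np.abs(coh - oracle_msc(x, y, 4.0, 4, 2))) < 1e-10

    def test_identical_and_rescaled_channels(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 400))
        ep = make_epochset(np.stack([x, x], axis=1), 200.0, ["a", "b"])
        _, coh = msc(ep, ("a", "b"))
        assert np.allclose(coh, 1.0, atol=1e-9)
        ep2 = make_epochset(np.stack([x, -2.0 * x], axis=1), 200.0, ["a", "b"])
        _, coh2 = msc(ep2, ("a", "b"))
        assert np.allclose(coh2, 1.0, atol=1e-9)

    def test_symmetric_in_channel_order(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(10, 2, 400))
        ep = make_epochset(data, 200.0, ["a", "b"])
        assert np.allclose(msc(ep, ("a", "b"))[1], msc(ep, ("b", "a"))[1])

    def test_common_signal_closed_form(self):
        # x = s + n1, y = s + n2 with source/noise PSD ratio r -> r^2/(1+r)^2
        rng = np.random.default_rng(6)
        n_ep, n_t = 400, 400
        s = rng.normal(size=(n_ep, n_t))
        x = s + rng.normal(size=(n_ep, n_t))
        y = s + rng.normal(size=(n_ep, n_t))
        ep = make_epochset(np.stack([x, y], axis=1), 200.0, ["a", "b"])
        _, coh = msc(ep, ("a", "b"), mode="pooled")
        assert coh.mean() == pytest.approx(0.25, abs=0.03)

    def test_independent_epoch_mode_bias_floor(self):
        # 3 segments/epoch: small-sample bias keeps epoch-mode MSC well above 0
        rng = np.random.default_rng(7)
        ep = make_epochset(rng.normal(size=(300, 2, 400)), 200.0, ["a", "b"])
        _, coh_epoch = msc(ep, ("a", "b"), mode="epoch")
        _, coh_pooled = msc(ep, ("a", "b"), mode="pooled")
        assert 0.2 < coh_epoch.mean() < 0.5  # bias floor, does not vanish
        assert coh_pooled.mean() < 0.02  # consistent estimator does

    def test_single_segment_epochs_rejected(self):
        ep = make_epochset(np.zeros((3, 2, 200)), 200.0, ["a", "b"])
        with pytest.raises(ValidationError, match="identically 1"):
            msc(ep, ("a", "b"), SpectralParams(resolution_hz=1.0))

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(8)
        ep = make_epochset(rng.normal(size=(5, 2, 400)), 200.0, ["a", "b"])
        for mode in ("epoch", "pooled"):
            _, coh = msc(ep, ("a", "b"), mode=mode)
            assert np.all((coh >= 0) & (coh <= 1))


class TestSplitHalf:
    def test_stationary_signal_high_stability(self):
        t = np.arange(400) / 200.0
        x = np.sin(2 * np.pi * 10 * t) + 0.5 * np.sin(2 * np.pi * 5 * t)
        data = np.tile(x, (20, 2, 1))
        ep = make_epochset(data, 200.0, ["a", "b"])
        assert split_half_stability(ep, ("a", "b"), metric="psd") == pytest.approx(1.0)

    def test_symmetric_in_half_order(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(20, 2, 400))
        ep = make_epochset(data, 200.0, ["a", "b"])
        swapped = make_epochset(
            np.concatenate([data[10:], data[:10]]), 200.0, ["a", "b"]
        )
        a = split_half_stability(ep, ("a", "b"))
        b = split_half_stability(swapped, ("a", "b"))
        assert a == pytest.approx(b)

    def test_too_few_epochs_missing(self):
        ep = make_epochset(np.zeros((3, 2, 400)), 200.0, ["a", "b"])
        assert np.isnan(split_half_stability(ep, ("a", "b")))


class TestAggregation:
    def test_grand_mean_equals_mean_of_participants(self):
        frame = pd.DataFrame(
            {
                "participant": ["p0", "p1", "p2"] * 2,
                "pair": ["A:B"] * 3 + ["A:C"] * 3,
                "band": ["Alpha"] * 6,
                "value": [0.8, 0.9, 1.0, 0.1, 0.2, 0.3],
            }
        )
        grand = grand_average(frame)
        ab = grand[grand["pair"] == "A:B"]["value"].iloc[0]
        assert ab == pytest.approx(0.9)
        assert (grand["level"] == "grand").all()
        assert grand[grand["pair"] == "A:C"]["variance"].iloc[0] == pytest.approx(0.01)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            grand_average(pd.DataFrame({"value": [1.0]}))
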