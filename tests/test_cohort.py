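"""Synthetic cohort generator: calibration constants, PSD repair, moment fidelity."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ohlra.cohort import (
    ITEM_GRIDS,
    VARIABLE_NAMES,
    default_moments,
    generate_cohort,
    generate_raw_records,
    nearest_correlation,
)
from ohlra.io import score_cohort


class TestDefaultMoments:
    def test_packaged_constants(self, moments):
        idx = dict(zip(moments.names, range(10)))
        assert moments.means[idx["hearing_loss"]] == pytest.approx(31.46)
        assert moments.sds[idx["hearing_loss"]] == pytest.approx(17.95)
        assert moments.corr[idx["ON"], idx["hearing_loss"]] == pytest.approx(0.791)
        assert moments.corr[idx["A"], idx["WE"]] == pytest.approx(0.778)

    def test_symmetric_unit_diagonal_psd(self, moments):
        assert np.allclose(moments.corr, moments.corr.T)
        assert np.allclose(np.diag(moments.corr), 1.0)
        # the published (rounded) matrix happens to be PSD as printed
        assert moments.is_psd


class TestNearestCorrelation:
    def test_identity_and_psd_pass_through(self, moments):
        out, dist = nearest_correlation(np.eye(4))
        assert np.array_equal(out, np.eye(4)) and dist == 0.0
        out, dist = nearest_correlation(moments.corr)
        assert dist == 0.0

    def test_repairs_indefinite_matrix(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(bad).min() < -0.01
        fixed, dist = nearest_correlation(bad)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-10
        assert np.allclose(np.diag(fixed), 1.0)
        assert dist > 0

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            nearest_correlation(np.array([[1.0, 0.2], [0.4, 1.0]]))


class TestContinuousMode:
    def test_moment_fidelity_large_n(self, moments):
        """All 45 pairwise correlations within +-0.02 and hearing-loss moments
        within +-0.2 of their clamped-Gaussian values at n=100k.

        The >=0 dB clamp shifts the target mean/SD slightly (closed form for
        E[max(X,0)] under X ~ N(31.46, 17.95^2)): the comparison uses those,
        not the raw latent moments.
        """
        from scipy.stats import norm

        mu, sd = 31.46, 17.95
        a = mu / sd
        clamped_mean = mu * norm.cdf(a) + sd * norm.pdf(a)
        clamped_sd = np.sqrt((mu**2 + sd**2) * norm.cdf(a) + mu * sd * norm.pdf(a) - clamped_mean**2)
        df = generate_cohort(moments, n=100_000, seed=7, mode="continuous")
        assert abs(df["hearing_loss"].mean() - clamped_mean) < 0.2
        assert abs(df["hearing_loss"].std() - clamped_sd) < 0.2
        sample = df[list(moments.names)].corr().to_numpy()
        err = np.abs(sample - moments.corr)[np.triu_indices(10, 1)]
        assert err.max() < 0.02
        assert abs(sample[4, 9] - 0.791) < 0.01  # occupational noise vs hearing loss

    def test_hearing_loss_clamped_at_zero(self, moments):
        df = generate_cohort(moments, n=5000, seed=3)
        assert (df["hearing_loss"] >= 0).all()

    def test_optional_range_clamp(self, moments):
        df = generate_cohort(moments, n=5000, seed=3, clamp_hearing_loss_range=True)
        assert df["hearing_loss"].between(10.0, 67.26).all()

    def test_determinism_byte_identical(self, moments):
        a = generate_cohort(moments, n=500, seed=42).to_csv()
        b = generate_cohort(moments, n=500, seed=42).to_csv()
        assert a == b
        c = generate_cohort(moments, n=500, seed=43).to_csv()
        assert a != c


class TestDiscreteMode:
    def test_grid_and_mean_fidelity(self, moments):
        """Each item lands on its rubric grid with mean within +-0.05 of target."""
        df = generate_cohort(moments, n=100_000, seed=7, mode="discrete")
        for j, name in enumerate(VARIABLE_NAMES[:-1]):
            values = set(np.unique(df[name]))
            assert values <= set(ITEM_GRIDS[name]), name
            assert abs(df[name].mean() - moments.means[j]) < 0.05, name

    def test_rank_correlations_attenuate_mildly(self, moments):
        df = generate_cohort(moments, n=100_000, seed=7, mode="discrete")
        rho = df[list(VARIABLE_NAMES)].corr(method="spearman").to_numpy()
        latent = moments.corr
        # Spearman of the discretized draws tracks the latent correlation
        err = np.abs(rho - latent)[np.triu_indices(10, 1)]
        assert np.median(err) < 0.06

    def test_rejects_bad_inputs(self, moments):
        with pytest.raises(ValueError):
            generate_cohort(moments, n=5, seed=1)
        with pytest.raises(ValueError):
            generate_cohort(moments, n=100, seed=1, mode="ordinal")


class TestRawRecords:
    def test_round_trip_exact(self, moments):
        """Scoring a generated raw record reproduces its item scores, exhaustively."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = generate_raw_records(400, seed=9)
            raw.attrs["dialect"] = "raw"
            rescored = score_cohort(raw)
        target = generate_cohort(moments, n=400, seed=9, mode="discrete")
        for col in ("A", "WE", "S", "D", "ON", "LN", "UPPE", "NRR", "APPE"):
            assert np.allclose(rescored[col].to_numpy(), target[col].to_numpy()), col

    def test_every_bin_appears_and_inverts(self):
        """400 records cover most rubric bins; spot-check the bin inversion."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = generate_raw_records(400, seed=9)
        target = generate_cohort(n=400, seed=9, mode="discrete")
        age5 = raw.loc[target["A"].to_numpy() == 5, "age_years"]
        assert (age5 >= 50).all() and len(age5) > 0
        d2 = raw.loc[target["D"].to_numpy() == 2, "diseases"]
        assert all(len(s.split(";")) == 2 for s in d2)
        nonuse = raw.loc[target["NRR"].to_numpy() == 5, "ppe_nrr_dB"]
        assert (nonuse == "non-use").all() and len(nonuse) > 0

    def test_determinism(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = generate_raw_records(50, seed=4).to_csv()
            b = generate_raw_records(50, seed=4).to_csv()
        assert a == b
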