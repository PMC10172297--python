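import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.special import logit

from sirrank.synthetic import (
    CohortGenerator,
    CovariateSpec,
    GeneratorConfig,
    default_correlation,
    default_covariates,
    extended_covariates,
    resample_within_hospital,
)


def _latent_icc(latent, gidx, min_volume=0, volumes=None):
    """One-way ANOVA ICC of a latent column."""
    m = gidx.max() + 1
    if volumes is not None and min_volume:
        keep_h = np.nonzero(volumes >= min_volume)[0]
        mask = np.isin(gidx, keep_h)
        latent, gidx = latent[mask], gidx[mask]
        _, gidx = np.unique(gidx, return_inverse=True)
        m = gidx.max() + 1
    n_i = np.bincount(gidx)
    mean_i = np.bincount(gidx, weights=latent) / n_i
    grand = latent.mean()
    n0 = (len(latent) - np.sum(n_i**2) / len(latent)) / (m - 1)
    msb = np.sum(n_i * (mean_i - grand) ** 2) / (m - 1)
    msw = np.sum((latent - mean_i[gidx]) ** 2) / (len(latent) - m)
    s2b = (msb - msw) / n0
    return s2b / (s2b + msw)


class TestVolumes:
    def test_constant_spec(self):
        cfg = GeneratorConfig(m=10, volume_min=100, volume_max=100, anchor_volumes=())
        vols = CohortGenerator(cfg).generate_volumes(np.random.default_rng(0))
        assert (vols == 100).all()

    def test_bounds_hold_across_seeds(self, default_generator):
        for seed in range(50):
            vols = default_generator.generate_volumes(np.random.default_rng(seed))
            assert vols.min() >= 2 and vols.max() <= 903
            assert len(vols) == 149

    def test_mean_volume_calibrated(self, default_generator):
        means = [
            default_generator.generate_volumes(np.random.default_rng(s)).mean()
            for s in range(20)
        ]
        assert np.mean(means) == pytest.approx(265, rel=0.10)

    def test_anchor_volumes_present(self, default_generator):
        vols = default_generator.generate_volumes(np.random.default_rng(3))
        assert 78 in vols and 303 in vols


class TestCovariates:
    def test_latent_icc_hits_targets(self, default_generator, default_pool):
        gen = default_generator
        gidx = gen.last_group_index_
        volumes = np.bincount(gidx)
        for j, spec in enumerate(gen.config.covariates):
            icc = _latent_icc(gen.last_latent_[:, j], gidx, min_volume=30, volumes=volumes)
            assert icc == pytest.approx(spec.icc, abs=0.03), spec.name

    def test_latent_correlations_near_spec(self, default_generator, default_pool):
        gen = default_generator
        R_hat = np.corrcoef(gen.last_latent_.T)
        R = default_correlation(6)
        assert np.max(np.abs(R_hat - R)) < 0.05

    def test_observed_correlations_within_published_range(self, default_pool):
        R_hat = np.corrcoef(default_pool.cohort.covariates.T)
        off = R_hat[~np.eye(6, dtype=bool)]
        assert off.min() >= -0.2722 and off.max() <= 0.6515

    def test_zero_icc_leaves_only_sampling_noise(self):
        cfg = GeneratorConfig(
            m=60,
            volume_min=100,
            volume_max=100,
            anchor_volumes=(),
            covariates=tuple(replace(c, icc=0.0) for c in default_covariates()),
        )
        gen = CohortGenerator(cfg)
        gen.generate_covariates(np.full(60, 100), np.random.default_rng(5))
        for j in range(6):
            icc = _latent_icc(gen.last_latent_[:, j], gen.last_group_index_)
            assert abs(icc) < 0.02

    def test_binary_observed_icc_attenuated_but_bounded(self):
        spec = CovariateSpec("b", "binary", 0.0, 0.12, prevalence=0.5)
        cfg = GeneratorConfig(
            m=100, volume_min=100, volume_max=100, anchor_volumes=(),
            covariates=(spec,), correlation=np.eye(1),
        )
        gen = CohortGenerator(cfg)
        iccs = []
        for seed in range(5):
            covs = gen.generate_covariates(np.full(100, 100), np.random.default_rng(seed))
            iccs.append(_latent_icc(covs.covariates[:, 0], covs.group_index))
        assert 0.06 <= np.mean(iccs) <= 0.18

    def test_extended_set_is_superset(self):
        base = [c.name for c in default_covariates()]
        ext = [c.name for c in extended_covariates()]
        assert ext[: len(base)] == base
        assert len(ext) == 13
        assert np.min(np.linalg.eigvalsh(default_correlation(13))) > 0


class TestCalibration:
    def test_null_model_half_rate(self, default_generator):
        cfg = GeneratorConfig(
            m=5, volume_min=50, volume_max=50, anchor_volumes=(),
            covariates=tuple(replace(c, coefficient=0.0) for c in default_covariates()),
            sigma_alpha=0.0,
        )
        gen = CohortGenerator(cfg)
        covs = gen.generate_covariates(np.full(5, 50), np.random.default_rng(0))
        assert gen.calibrate_intercept(covs, 0.5, sigma_alpha=0.0) == pytest.approx(0.0, abs=1e-6)
        assert gen.calibrate_intercept(covs, 0.03, sigma_alpha=0.0) == pytest.approx(
            logit(0.03), abs=1e-6
        )

    def test_default_pool_rate_near_target(self, default_pool):
        assert default_pool.cohort.outcomes.mean() == pytest.approx(0.031, abs=0.005)

    def test_unbracketable_rate_rejected(self, default_generator, default_pool):
        covs = default_pool.cohort.drop_outcomes()
        with pytest.raises(ValueError):
            default_generator.calibrate_intercept(covs, 1.5)


class TestGenerateCohort:
    def test_seed_determinism(self, default_generator):
        a = default_generator.generate_cohort(seed=42)
        b = default_generator.generate_cohort(seed=42)
        pd.testing.assert_frame_equal(a.cohort.frame, b.cohort.frame)
        assert a.params.alpha == b.params.alpha

    def test_truth_parameters_recorded(self, default_pool):
        assert default_pool.params.sigma_alpha == 0.5
        assert len(default_pool.hospital_effects) == 149
        np.testing.assert_array_equal(
            default_pool.params.beta, [c.coefficient for c in default_covariates()]
        )


class TestResampleWithinHospital:
    def test_volumes_preserved_and_rows_are_members(self, tiny_cohort):
        rng = np.random.default_rng(9)
        out = resample_within_hospital(tiny_cohort, rng)
        np.testing.assert_array_equal(out.volumes, tiny_cohort.volumes)
        assert out.schema.outcome_col is None
        for hosp in tiny_cohort.hospital_ids:
            src = set(
                tiny_cohort.frame.loc[
                    tiny_cohort.frame["hospital_id"] == hosp, "x1"
                ]
            )
            got = set(out.frame.loc[out.frame["hospital_id"] == hosp, "x1"])
            assert got <= src

    def test_single_row_hospital_repeats_its_row(self):
        frame = pd.DataFrame(
            {"hospital_id": ["A", "B", "B"], "outcome": [1, 0, 1], "x1": [3.0, 1.0, 2.0]}
        )
        from sirrank.cohort import CohortSchema, CohortTable

        c = CohortTable(frame, CohortSchema("hospital_id", "outcome", ("x1",)))
        out = resample_within_hospital(c, np.random.default_rng(0))
        assert out.frame.loc[out.frame["hospital_id"] == "A", "x1"].tolist() == [3.0]
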