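import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import zebraldt as z
from zebraldt.catalog import BIN_SECONDS, ConfigurationError, PARAMETERS
from zebraldt.synthetic import latent_drivers, mean_profile


def _row(record, name):
    return record.param(name)


class TestRecordInvariants:
    def test_conservation_every_minute(self, default_cohort):
        """Durations sum to 60 s and class distances sum to dist, per minute."""
        for rec in default_cohort:
            rec.validate(atol=1e-6)
            total_dur = _row(rec, "inadur") + _row(rec, "smldur") + _row(rec, "lardur")
            assert np.allclose(total_dur, BIN_SECONDS, atol=1e-9)
            assert np.allclose(
                _row(rec, "dist"),
                _row(rec, "inadist") + _row(rec, "smldist") + _row(rec, "lardist"),
            )

    def test_burst_aggregates_bounded(self, default_cohort):
        for rec in default_cohort:
            assert np.all(_row(rec, "distb") <= _row(rec, "dist") + 1e-9)
            assert np.all(_row(rec, "durb") <= _row(rec, "dur") + 1e-9)

    @given(
        cv=st.floats(0, 0.5), noise=st.floats(0, 0.5), mult=st.floats(0.3, 3.0),
        seed=st.integers(0, 10_000),
    )
    def test_invariants_hold_across_configs(self, cv, noise, mult, seed):
        cfg = z.GeneratorConfig(
            n_control=2, n_exposed=2, seed=seed,
            between_larva_cv=cv, within_larva_noise_sd=noise,
            effect=z.EffectSpec(multiplier=mult),
        )
        for rec in z.generate_cohort(cfg):
            rec.validate(atol=1e-6)


class TestGeneratorBehavior:
    def test_phase_contrast_on_means(self, quiet_config):
        """Control larvae are quiet in light, hyperactive in dark."""
        rec = z.generate_record(
            quiet_config, "control", np.random.default_rng(0), "c1"
        )
        phases = quiet_config.schedule.phases()
        for p in ("dur", "dist"):
            assert _row(rec, p)[phases == "dark"].mean() > _row(rec, p)[phases == "light"].mean()

    def test_transition_spike_and_habituation(self, quiet_config):
        """Activity peaks at the first dark minute and decays within the phase."""
        profile = mean_profile(quiet_config, "control")
        dur = profile[list(PARAMETERS).index("dur")]
        dark1 = dur[10:20]  # first dark phase, minutes 11..20
        assert dark1[0] == dark1.max()
        assert np.all(np.diff(dark1) <= 0)

    def test_zero_noise_records_identical(self, quiet_config):
        a = z.generate_record(quiet_config, "control", np.random.default_rng(1), "a")
        b = z.generate_record(quiet_config, "control", np.random.default_rng(2), "b")
        assert np.array_equal(a.values, b.values)

    def test_no_effect_means_identical_across_groups(self, null_config):
        assert np.array_equal(
            mean_profile(null_config, "control"), mean_profile(null_config, "exposed")
        )

    def test_effect_scales_duration_driver(self):
        cfg = z.GeneratorConfig(
            effect=z.EffectSpec(affected_params=("dur",), affected_phase="dark",
                                multiplier=1.5)
        )
        ctrl = latent_drivers(cfg, "control")
        expo = latent_drivers(cfg, "exposed")
        dark = cfg.schedule.phases() == "dark"
        expect = np.clip(ctrl["active_s"][dark] * 1.5, 0, BIN_SECONDS)
        assert np.allclose(expo["active_s"][dark], expect)
        assert np.allclose(expo["active_s"][~dark], ctrl["active_s"][~dark])

    def test_effect_scales_speed_driver_keeps_durations(self):
        cfg = z.GeneratorConfig(
            effect=z.EffectSpec(affected_params=("dist",), affected_phase="dark",
                                multiplier=2.0)
        )
        ctrl = mean_profile(cfg, "control")
        expo = mean_profile(cfg, "exposed")
        idx = {p: i for i, p in enumerate(PARAMETERS)}
        dark = cfg.schedule.phases() == "dark"
        assert np.allclose(expo[idx["dur"]], ctrl[idx["dur"]])
        assert np.allclose(expo[idx["dist"], dark], 2.0 * ctrl[idx["dist"], dark])
        assert np.allclose(expo[idx["dist"], ~dark], ctrl[idx["dist"], ~dark])

    def test_effect_onset_minute(self):
        cfg = z.GeneratorConfig(
            effect=z.EffectSpec(affected_params=("dur",), affected_phase="both",
                                multiplier=2.0, onset_min=30)
        )
        ctrl = latent_drivers(cfg, "control")["active_s"]
        expo = latent_drivers(cfg, "exposed")["active_s"]
        assert np.allclose(expo[:30], ctrl[:30])
        assert np.all(expo[30:] >= ctrl[30:])


class TestCohort:
    def test_size_and_unique_ids(self, default_cohort):
        assert len(default_cohort) == 72
        ids = [r.larva_id for r in default_cohort]
        assert len(set(ids)) == 72
        groups = [r.group for r in default_cohort]
        assert groups.count("control") == 36 and groups.count("exposed") == 36

    def test_seed_determinism(self):
        cfg = z.GeneratorConfig(n_control=3, n_exposed=3, seed=42)
        a = z.generate_cohort(cfg)
        b = z.generate_cohort(cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.values, rb.values)

    def test_different_seeds_differ(self):
        a = z.generate_cohort(z.GeneratorConfig(n_control=2, n_exposed=2, seed=1))
        b = z.generate_cohort(z.GeneratorConfig(n_control=2, n_exposed=2, seed=2))
        assert any(not np.array_equal(ra.values, rb.values) for ra, rb in zip(a, b))

    @pytest.mark.parametrize(
        "make_kwargs",
        [
            lambda: {"n_control": 1},
            lambda: {"between_larva_cv": -0.1},
            lambda: {"habituation_rate": 1.0},
            lambda: {"effect": z.EffectSpec(multiplier=-1)},
            lambda: {"effect": z.EffectSpec(affected_params=("bogus",))},
            lambda: {"effect": z.EffectSpec(onset_min=99)},
        ],
    )
    def test_invalid_config_names_violation(self, make_kwargs):
        with pytest.raises(ConfigurationError):
            cfg = z.GeneratorConfig(**make_kwargs())
            z.generate_cohort(cfg)


class TestNullMatrix:
    def test_shape_range_and_balance(self):
        m = z.generate_null_matrix(36, 780, seed=5)
        assert m.features.shape == (72, 780)
        assert np.all((m.features >= 0) & (m.features < 1))
        assert list(m.labels).count("control") == 36

    def test_minimal_shape(self):
        assert z.generate_null_matrix(2, 1, seed=0).features.shape == (4, 1)

    def test_uniform_mean(self):
        m = z.generate_null_matrix(1000, 10, seed=9)
        assert abs(m.features.mean() - 0.5) < 0.01

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ConfigurationError):
            z.generate_null_matrix(1, 10, seed=0)
        with pytest.raises(ConfigurationError):
            z.generate_null_matrix(5, 0, seed=0)
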