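"""Generative backends: losses, diffusion mechanics, training smoke, oracle."""


import numpy as np
import pytest

from bmelseg._nn import Adam
from bmelseg.anomaly import anomaly_map_for_study
from bmelseg.backends import (
    CGANBackend,
    CGANConfig,
    DiffusionBackend,
    DiffusionConfig,
    DiffusionState,
    OracleBackend,
    cgan_discriminator_loss,
    cgan_generator_loss,
    diffusion_forward,
    diffusion_reverse_step,
    diffusion_sample,
    diffusion_train_step,
    init_diffusion_state,
    oracle_synthesize,
    quadratic_schedule,
)
from bmelseg.phantom import PhantomConfig, generate_dataset
from bmelseg.preprocess import preprocess_study
from bmelseg.tasks import TaskKind, build_pair, build_training_set


@pytest.fixture(scope="module")
def tiny_pairs(small_config):
    studies = [preprocess_study(s) for s in generate_dataset(small_config, 2, 0, seed=5)]
    return build_training_set(studies, TaskKind.SEQUENCE_TRANSLATION)


class TestCGANLosses:
    def test_l1_term_vanishes_for_perfect_reconstruction(self):
        x = np.array([1.0, 2.0])
        base = cgan_generator_loss(np.array([0.5]), x, x, lambda_l1=100.0)
        assert base == pytest.approx(cgan_generator_loss(np.array([0.5]), x, x, 0.0))

    def test_hand_computed_l1_term(self):
        x = np.array([1.0, 2.0])
        x_hat = np.array([0.0, 4.0])
        with_l1 = cgan_generator_loss(np.array([0.5]), x, x_hat, lambda_l1=1.0)
        without = cgan_generator_loss(np.array([0.5]), x, x_hat, lambda_l1=0.0)
        assert with_l1 - without == pytest.approx(1.5)

    def test_perfect_discrimination_drives_loss_to_zero(self):
        loss = cgan_discriminator_loss(np.array([1.0 - 1e-9]), np.array([1e-9]))
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_maximally_confused_discriminator_scores_two_ln_two(self):
        loss = cgan_discriminator_loss(np.array([0.5]), np.array([0.5]))
        assert loss == pytest.approx(2 * np.log(2))

    def test_symmetric_under_label_swap_with_complemented_outputs(self):
        rng = np.random.default_rng(0)
        pr, pf = rng.uniform(0.05, 0.95, size=(2, 10))
        assert cgan_discriminator_loss(pr, pf) == pytest.approx(
            cgan_discriminator_loss(1.0 - pf, 1.0 - pr)
        )


class TestSchedule:
    def test_alpha_bar_strictly_decreasing_and_endpoints_match(self):
        sch = quadratic_schedule(100, beta_start=1e-4, beta_end=2e-2)
        assert sch.betas[0] == pytest.approx(1e-4)
        assert sch.betas[-1] == pytest.approx(2e-2)
        assert np.all(np.diff(sch.alpha_bars) < 0)

    def test_single_step_schedule_valid(self):
        sch = quadratic_schedule(1, beta_start=1e-4)
        assert sch.T == 1 and sch.alpha_bars[0] == pytest.approx(1 - 1e-4)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            quadratic_schedule(10, beta_start=0.5, beta_end=1.5)


class TestDiffusionForward:
    def test_matches_closed_form(self):
        sch = quadratic_schedule(10)
        x0 = np.array([0.3]); noise = np.array([-1.1])
        for t in (1, 5, 10):
            ab = sch.alpha_bars[t - 1]
            expected = np.sqrt(ab) * x0 + np.sqrt(1 - ab) * noise
            assert diffusion_forward(x0, t, noise, sch) == pytest.approx(expected)

    def test_early_step_barely_perturbs_and_late_step_is_mostly_noise(self):
        sch = quadratic_schedule(1000)
        x0 = np.array([1.0]); noise = np.array([-1.0])
        assert diffusion_forward(x0, 1, noise, sch)[0] == pytest.approx(1.0, abs=0.05)
        ab_T = sch.alpha_bars[-1]
        assert ab_T < 0.02  # terminal signal nearly destroyed

    def test_out_of_range_timestep_rejected(self):
        sch = quadratic_schedule(10)
        with pytest.raises(ValueError):
            diffusion_forward(np.zeros(1), 11, np.zeros(1), sch)

    def test_unit_variance_at_terminal_time_monte_carlo(self):
        """Var(x_T) = abar + (1-abar) = 1 for standard-normal x0 and noise."""
        sch = quadratic_schedule(100)
        rng = np.random.default_rng(0)
        n = 10_000
        x_t = diffusion_forward(rng.standard_normal(n), 100, rng.standard_normal(n), sch)
        se = np.sqrt(2.0 / n)  # SE of a unit-normal sample variance
        assert abs(x_t.var() - 1.0) < 3 * se


class TestDiffusionReverse:
    def test_exact_noise_prediction_recovers_x0(self):
        sch = quadratic_schedule(50)
        x0 = np.array([[0.37]])
        eps = np.array([[1.3]])
        x1 = diffusion_forward(x0, 1, eps, sch)
        assert np.max(np.abs(diffusion_reverse_step(x1, eps, 1, sch) - x0)) < 1e-5

    def test_stubbed_noise_model_yields_zero_training_loss(self, tiny_pairs):
        cfg = DiffusionConfig(timesteps=20)
        rng_seed = 123
        # replicate the step's internal draws to hand the stub the exact noise
        state_rng = np.random.default_rng(rng_seed)
        batch = tiny_pairs[:3]
        n = len(batch)
        shape = (n, 1) + batch[0].target.shape
        _t = state_rng.integers(1, 21, size=n)
        known_noise = state_rng.standard_normal(shape)

        class StubNoiseModel:
            def forward(self, inp, t):
                return known_noise

            def backward(self, dout):
                return dout

        state = DiffusionState(
            model=StubNoiseModel(), optimizer=Adam([]),
            schedule=quadratic_schedule(20), rng=np.random.default_rng(rng_seed),
        )
        loss = diffusion_train_step(batch, state, cfg)
        assert loss == 0.0

    def test_training_loss_decreases_on_toy_set(self, tiny_pairs):
        cfg = DiffusionConfig(timesteps=50)
        state = init_diffusion_state(cfg, seed=0)
        rng = np.random.default_rng(1)
        pool = tiny_pairs[:16]
        losses = []
        for _ in range(200):
            idx = rng.integers(0, len(pool), size=cfg.batch_size)
            losses.append(diffusion_train_step([pool[i] for i in idx], state, cfg))
        assert all(np.isfinite(losses)) and all(l >= 0 for l in losses)
        assert np.mean(losses[-20:]) < np.mean(losses[:20])

    def test_sampling_deterministic_and_shaped(self, tiny_pairs):
        cfg = DiffusionConfig(timesteps=10)
        state = init_diffusion_state(cfg, seed=0)
        diffusion_train_step(tiny_pairs[:2], state, cfg)
        c = tiny_pairs[0].conditioning
        a = diffusion_sample(c, state, cfg, sampling_seed=7)
        b = diffusion_sample(c, state, cfg, sampling_seed=7)
        assert np.array_equal(a, b)
        assert a.shape == c.shape
        assert a.min() >= -1.0 and a.max() <= 1.0

    def test_untrained_state_rejected_for_sampling(self, tiny_pairs):
        cfg = DiffusionConfig(timesteps=10)
        state = init_diffusion_state(cfg, seed=0)
        with pytest.raises(RuntimeError, match="untrained"):
            diffusion_sample(tiny_pairs[0].conditioning, state, cfg, 0)


class TestOracle:
    def test_healthy_study_gives_identically_zero_anomaly(self, small_config):
        study = preprocess_study(generate_dataset(small_config, 1, 0, seed=8)[0])
        backend = OracleBackend.from_studies([study], TaskKind.SEQUENCE_TRANSLATION)
        amap = anomaly_map_for_study(study, backend, TaskKind.SEQUENCE_TRANSLATION)
        assert not amap.values.any()

    def test_lesioned_study_differs_only_inside_lesion_support(self, small_config):
        study = preprocess_study(generate_dataset(small_config, 0, 1, seed=9)[0])
        backend = OracleBackend.from_studies([study], TaskKind.SEQUENCE_TRANSLATION)
        amap = anomaly_map_for_study(study, backend, TaskKind.SEQUENCE_TRANSLATION,
                                     mask_bone=False)
        outside = study.lesion_field.data == 0
        assert not amap.values[outside].any()
        assert amap.values[study.lesion_truth.data > 0].max() > 0

    def test_lookup_miss_raises(self, small_config):
        study = preprocess_study(generate_dataset(small_config, 1, 0, seed=8)[0])
        backend = OracleBackend.from_studies([study], TaskKind.SEQUENCE_TRANSLATION)
        pair = build_pair(study, 0, TaskKind.BONE_INPAINTING)
        with pytest.raises(KeyError):
            backend.synthesize(pair)


class TestBackendContract:
    """All backends plug into the anomaly pipeline interchangeably."""

    @pytest.mark.parametrize("name", ["oracle", "cgan", "diffusion"])
    def test_synthesize_respects_shape_and_range(self, name, small_config, tiny_pairs):
        studies = [preprocess_study(s) for s in generate_dataset(small_config, 0, 1, seed=30)]
        task = TaskKind.SEQUENCE_TRANSLATION
        if name == "oracle":
            backend = OracleBackend.from_studies(studies, task)
        elif name == "cgan":
            backend = CGANBackend(CGANConfig(steps=5, base_channels=8))
            backend.train(tiny_pairs, seed=0)
        else:
            backend = DiffusionBackend(DiffusionConfig(steps=5, timesteps=10, base_channels=8))
            backend.train(tiny_pairs, seed=0)
        amap = anomaly_map_for_study(studies[0], backend, task)
        assert amap.values.shape == studies[0].target.shape
        assert np.all(amap.values >= 0)

    def test_untrained_trainable_backends_refuse_to_synthesize(self, tiny_pairs):
        for backend in (CGANBackend(), DiffusionBackend()):
            with pytest.raises(RuntimeError, match="untrained"):
                backend.synthesize(tiny_pairs[0])


def test_cgan_short_training_improves_heldout_reconstruction(small_config):
    """Desk-scale smoke: a brief training run beats the initialised net."""
    studies = [preprocess_study(s) for s in generate_dataset(small_config, 3, 0, seed=17)]
    train = build_training_set(studies[:2], TaskKind.SEQUENCE_TRANSLATION)
    held = build_training_set(studies[2:], TaskKind.SEQUENCE_TRANSLATION)
    backend = CGANBackend(CGANConfig(steps=60, base_channels=8))
    backend._build(seed=0)
    before = backend.held_out_l1(held)
    backend.train(train, seed=0)
    assert backend.held_out_l1(held) < before
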