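import numpy as np
import pytest

from flla import (
    SimulationConfig,
    accuracy_landmark_table,
    generate_accuracy_dataset,
    generate_reliability_dataset,
    generate_subject,
    hka_angle,
    icc2k,
    pka_angle,
    render_annotations,
)
from flla.geometry import LimbAnnotation
from flla.simulate import _substream


def noise_free(**overrides) -> SimulationConfig:
    base = dict(
        true_hka_sd=0.0,
        fma_fta_sd=0.0,
        ankle_center_offset_sd=0.0,
        landmark_noise_sd_mm=0.0,
        rater_bias_sd_mm=0.0,
        session_sd_deg=0.0,
        seed=0,
    )
    return SimulationConfig.orthopedic(**{**base, **overrides})


class TestGenerateSubject:
    def test_straight_limb_when_all_parameters_zero(self):
        cfg = noise_free(true_hka_mean=180.0, fma_fta_mean=0.0, ankle_center_offset_mean=0.0)
        limb = generate_subject(cfg, _substream(cfg.seed, "subject", 0, "right"))
        photo = render_annotations(limb, "photograph", "R1", 1, cfg, np.random.default_rng(0))
        radio = render_annotations(limb, "radiograph", "R1", 1, cfg, np.random.default_rng(0))
        assert pka_angle(photo).value == pytest.approx(180.0, abs=1e-9)
        assert hka_angle(radio).value == pytest.approx(180.0, abs=1e-9)

    def test_additive_construction_of_pka(self):
        """Noise-free PKA = HKA + FMA–FTA + ankle offset: 178.8 + 3.1 + 0.8 = 182.7."""
        cfg = noise_free()
        limb = generate_subject(cfg, _substream(cfg.seed, "subject", 0, "right"))
        photo = render_annotations(limb, "photograph", "R1", 1, cfg, np.random.default_rng(0))
        assert limb.true_pka == pytest.approx(182.7, abs=1e-12)
        assert pka_angle(photo).value == pytest.approx(182.7, abs=1e-9)

    def test_noise_free_roundtrip_through_geometry(self):
        """Measured angles on zero-noise renderings equal the configured truths."""
        cfg = noise_free(n_subjects=6)
        df = generate_accuracy_dataset(cfg)
        assert np.allclose(df["pka_deg"], df["true_pka"], atol=1e-9)
        assert np.allclose(df["hka_deg"], df["true_hka"], atol=1e-9)

    def test_population_moments_recovered(self):
        """Sample mean/SD of true HKA over 10,000 draws match (178.8, 5.2)."""
        cfg = SimulationConfig.orthopedic(seed=0)
        draws = np.array(
            [
                generate_subject(cfg, _substream(cfg.seed, "subject", i, "right")).true_hka
                for i in range(10_000)
            ]
        )
        se_mean = 5.2 / np.sqrt(10_000)
        se_sd = 5.2 / np.sqrt(2 * 10_000)
        assert abs(draws.mean() - 178.8) < 2 * se_mean
        assert abs(draws.std(ddof=1) - 5.2) < 2 * se_sd

    def test_fma_fta_never_negative(self):
        cfg = SimulationConfig.orthopedic(fma_fta_mean=0.2, fma_fta_sd=1.0, seed=3)
        for i in range(200):
            limb = generate_subject(cfg, _substream(cfg.seed, "subject", i, "right"))
            assert limb.true_fma_fta >= 0.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="true_hka_sd"):
            SimulationConfig.orthopedic(true_hka_sd=-1.0)
        with pytest.raises(ValueError, match="subjects"):
            SimulationConfig.orthopedic(n_subjects=2)


class TestRenderAnnotations:
    def test_marking_noise_is_unbiased(self):
        """Mean PKA over 500 noisy renderings ≈ true PKA, with nonzero spread."""
        cfg = noise_free(landmark_noise_sd_mm=1.5)
        limb = generate_subject(cfg, _substream(cfg.seed, "subject", 0, "right"))
        rng = np.random.default_rng(42)
        vals = np.array(
            [
                pka_angle(render_annotations(limb, "photograph", "R1", 1, cfg, rng)).value
                for _ in range(500)
            ]
        )
        assert vals.std(ddof=1) > 0.05
        assert abs(vals.mean() - limb.true_pka) < 4 * vals.std(ddof=1) / np.sqrt(500)

    def test_session_perturbation_dominates_between_session_variance(self):
        """Repositioning noise separates photographs more than re-marking does."""
        cfg = noise_free(landmark_noise_sd_mm=0.3, session_sd_deg=1.0)
        limb = generate_subject(cfg, _substream(cfg.seed, "subject", 0, "right"))
        per_session = []
        for session in range(1, 41):
            readings = [
                pka_angle(
                    render_annotations(
                        limb, "photograph", "R1", session, cfg,
                        _substream(cfg.seed, "mark", 0, "right", session, reading),
                    )
                ).value
                for reading in range(2)
            ]
            per_session.append(readings)
        arr = np.array(per_session)
        between = arr.mean(axis=1).var(ddof=1)
        within = arr.var(axis=1, ddof=1).mean()
        assert between > within

    def test_rater_bias_is_systematic(self):
        """A rater's offset is identical across renderings of the same limb."""
        cfg = noise_free(rater_bias_sd_mm=2.0)
        limb = generate_subject(cfg, _substream(cfg.seed, "subject", 0, "right"))
        a = render_annotations(limb, "photograph", "R2", 1, cfg, np.random.default_rng(0))
        b = render_annotations(limb, "photograph", "R2", 1, cfg, np.random.default_rng(1))
        assert pka_angle(a).value == pytest.approx(pka_angle(b).value, abs=1e-12)
        c = render_annotations(limb, "photograph", "R3", 1, cfg, np.random.default_rng(0))
        assert pka_angle(c).value != pytest.approx(pka_angle(a).value, abs=1e-6)

    def test_unknown_modality_rejected(self):
        cfg = noise_free()
        limb = generate_subject(cfg, _substream(cfg.seed, "subject", 0, "right"))
        with pytest.raises(ValueError, match="modality"):
            render_annotations(limb, "mri", "R1", 1, cfg, np.random.default_rng(0))


class TestAccuracyDataset:
    def test_default_limb_count_and_schema(self):
        df = generate_accuracy_dataset(SimulationConfig.orthopedic(seed=1))
        assert len(df) == 33
        assert {"subject_id", "limb_side", "pka_deg", "hka_deg", "fma_fta_deg"} <= set(df.columns)

    def test_determinism(self):
        cfg = SimulationConfig.orthopedic(seed=9)
        assert generate_accuracy_dataset(cfg).equals(generate_accuracy_dataset(cfg))
        lm1, tr1 = accuracy_landmark_table(cfg)
        lm2, tr2 = accuracy_landmark_table(cfg)
        assert lm1.equals(lm2) and tr1.equals(tr2)

    def test_seed_changes_data(self):
        a = generate_accuracy_dataset(SimulationConfig.orthopedic(seed=1))
        b = generate_accuracy_dataset(SimulationConfig.orthopedic(seed=2))
        assert not np.allclose(a["pka_deg"], b["pka_deg"])

    def test_zero_noise_gives_perfect_correlation_of_truths(self):
        cfg = noise_free(true_hka_sd=3.0, n_subjects=10)
        df = generate_accuracy_dataset(cfg)
        # offsets are constant, so PKA is an exact shift of HKA
        assert np.allclose(df["pka_deg"] - df["hka_deg"], 3.9, atol=1e-9)

    def test_mean_offset_matches_configured_bias(self):
        """E[PKA − HKA] = fma_fta_mean + ankle_center_offset_mean = 3.9°."""
        cfg = SimulationConfig.orthopedic(n_subjects=1500, rater_bias_sd_mm=0.0, seed=5)
        df = generate_accuracy_dataset(cfg, n_limbs=3000)
        diff = df["pka_deg"] - df["hka_deg"]
        assert diff.mean() == pytest.approx(3.9, abs=4 * diff.std() / np.sqrt(len(diff)))

    def test_correlation_near_generating_model_value(self):
        """Mean Pearson r over replicates ≈ σ_HKA/√(σ_HKA² + σ_offset²)."""
        cfg0 = SimulationConfig.orthopedic()
        var_offsets = cfg0.fma_fta_sd**2 + cfg0.ankle_center_offset_sd**2
        expected = cfg0.true_hka_sd / np.sqrt(cfg0.true_hka_sd**2 + var_offsets)
        rs = []
        for rep in range(60):
            df = generate_accuracy_dataset(SimulationConfig.orthopedic(seed=100 + rep))
            rs.append(np.corrcoef(df["pka_deg"], df["hka_deg"])[0, 1])
        assert np.mean(rs) == pytest.approx(expected, abs=0.02)

    def test_limb_count_bounds(self):
        with pytest.raises(ValueError, match="n_limbs"):
            generate_accuracy_dataset(SimulationConfig.orthopedic(), n_limbs=35)


class TestReliabilityDataset:
    def test_structure_matches_three_designs(self):
        data = generate_reliability_dataset(SimulationConfig.healthy(n_subjects=8, seed=4))
        assert set(data.intrarater) == {"R1", "R2", "R3"}
        for m in data.intrarater.values():
            assert m.values.shape == (8, 2)
        assert data.interrater.values.shape == (8, 3)
        assert data.test_retest.values.shape == (8, 2)
        assert len(data.long) == 8 * 2 * 3 * 2

    def test_zero_measurement_noise_gives_perfect_iccs(self):
        cfg = SimulationConfig.healthy(
            n_subjects=10,
            landmark_noise_sd_mm=0.0,
            rater_bias_sd_mm=0.0,
            session_sd_deg=0.0,
            seed=6,
        )
        data = generate_reliability_dataset(cfg)
        for m in list(data.intrarater.values()) + [data.interrater, data.test_retest]:
            assert icc2k(m).estimate == pytest.approx(1.0, abs=1e-9)

    def test_determinism(self):
        cfg = SimulationConfig.healthy(n_subjects=6, seed=12)
        a = generate_reliability_dataset(cfg)
        b = generate_reliability_dataset(cfg)
        assert a.long.equals(b.long)

    def test_variance_components_order_the_three_reliability_designs(self):
        """With reading noise ≪ rater bias ≪ session noise, mean ICCs order
        intrarater > interrater > test–retest."""
        intra, inter, retest = [], [], []
        for rep in range(25):
            cfg = SimulationConfig.healthy(
                n_subjects=30,
                landmark_noise_sd_mm=0.5,
                rater_bias_sd_mm=3.0,
                session_sd_deg=1.2,
                seed=300 + rep,
            )
            data = generate_reliability_dataset(cfg)
            intra.append(np.mean([icc2k(m).estimate for m in data.intrarater.values()]))
            inter.append(icc2k(data.interrater).estimate)
            retest.append(icc2k(data.test_retest).estimate)
        assert np.mean(intra) > np.mean(inter) > np.mean(retest)

    def test_healthy_defaults_give_excellent_interrater_reliability(self):
        """The calibrated defaults land interrater ICC(2,3) in the >0.9 band."""
        estimates = [
            icc2k(
                generate_reliability_dataset(SimulationConfig.healthy(seed=700 + rep)).interrater
            ).estimate
            for rep in range(5)
        ]
        assert np.median(estimates) > 0.9


class TestHealthyGroupTargets:
    def test_healthy_pka_moments(self):
        """Healthy config targets PKA 182.6° ± 2.5° via the additive construction."""
        cfg = SimulationConfig.healthy(n_subjects=4000, seed=8)
        pka = np.array(
            [
                generate_subject(cfg, _substream(cfg.seed, "subject", i, "right")).true_pka
                for i in range(cfg.n_subjects)
            ]
        )
        assert pka.mean() == pytest.approx(182.6, abs=3 * 2.5 / np.sqrt(4000))
        assert pka.std(ddof=1) == pytest.approx(2.5, abs=0.1)
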