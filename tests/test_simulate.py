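"""Synthetic cohort generator: determinism, ground truth, model contracts."""

import numpy as np
import pytest

from cytocin.aberrations import call_clonality
from cytocin.diversity import diversity_of
from cytocin.fish import cin_individual
from cytocin.simulate import (
    CloneSpec,
    CohortConfig,
    KaryotypeRateModel,
    NoiseModel,
    default_karyotype_model,
    load_config,
    nested_clones,
    simulate_cohort,
    simulate_fish_individual,
    simulate_karyotypes,
)


class TestCloneAndNoiseSpecs:
    def test_clone_validation(self):
        with pytest.raises(ValueError):
            CloneSpec((2, 2, 2), 0.5)  # wrong arity
        with pytest.raises(ValueError):
            CloneSpec((2, 2, 2, 2, 2, 7), 0.5)  # count out of range
        with pytest.raises(ValueError):
            CloneSpec((2,) * 6, 0.0)

    def test_noise_validation(self):
        with pytest.raises(ValueError):
            NoiseModel(p_dropout=0.7)
        assert NoiseModel(0.0, 0.0).diploid_deviation_rate == 0.0

    def test_nested_clones_have_exact_marginals(self, rng):
        for _ in range(20):
            f = rng.uniform(0, 0.6, size=6)
            clones = nested_clones(f, rng)
            freqs = np.array([c.frequency for c in clones])
            assert freqs.sum() == pytest.approx(1.0, abs=1e-12)
            sigs = np.array([c.signature for c in clones])
            marginal = ((sigs != 2) * freqs[:, None]).sum(axis=0)
            assert marginal == pytest.approx(f, abs=1e-9)


class TestSimulateFishIndividual:
    def test_single_diploid_clone_zero_noise(self, no_noise):
        m = simulate_fish_individual([CloneSpec((2,) * 6, 1.0)], no_noise, 100, seed=1)
        assert cin_individual(m).mean_cin == 0.0
        assert diversity_of(m).td == pytest.approx(1.0)

    def test_two_clone_mixture_recovers_entropy(self, no_noise):
        clones = [CloneSpec((2,) * 6, 0.7), CloneSpec((3, 2, 2, 2, 2, 2), 0.3)]
        cins, tds = [], []
        rng = np.random.default_rng(4)
        for _ in range(200):
            m = simulate_fish_individual(clones, no_noise, 100, rng)
            prof = cin_individual(m)
            cins.append(prof.per_chromosome_cin[0])
            tds.append(diversity_of(m).td)
        assert np.mean(cins) == pytest.approx(30.0, abs=1.0)
        assert np.mean(tds) == pytest.approx(np.exp(0.6109), abs=0.05)

    def test_same_seed_is_bit_identical(self):
        clones = [CloneSpec((2,) * 6, 0.8), CloneSpec((1, 2, 3, 2, 2, 2), 0.2)]
        noise = NoiseModel()
        a = simulate_fish_individual(clones, noise, 150, seed=42)
        b = simulate_fish_individual(clones, noise, 150, seed=42)
        assert np.array_equal(a.counts, b.counts)

    def test_invalid_frequencies_error(self, no_noise):
        with pytest.raises(ValueError):
            simulate_fish_individual(
                [CloneSpec((2,) * 6, 0.6), CloneSpec((3,) * 6, 0.6)], no_noise, 10, 0
            )


class TestSimulateCohort:
    def test_deterministic_and_complete(self):
        a = simulate_cohort(CohortConfig(n_per_group=4, n_nuclei=50), seed=9)
        b = simulate_cohort(CohortConfig(n_per_group=4, n_nuclei=50), seed=9)
        assert set(a.fish) == {f"E{i}" for i in range(1, 5)} | {f"UE{i}" for i in range(1, 5)}
        for k in a.fish:
            assert np.array_equal(a.fish[k].counts, b.fish[k].counts)
        assert a.metadata.equals(b.metadata)
        assert a.truth.equals(b.truth)

    def test_minimal_cohort_runs(self):
        bundle = simulate_cohort(CohortConfig(n_per_group=2, n_nuclei=30), seed=0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profiles = [cin_individual(m) for m in bundle.fish.values()]
        assert all(0 <= p.mean_cin <= 100 for p in profiles)
        with pytest.raises(ValueError):
            simulate_cohort(CohortConfig(n_per_group=1), seed=0)

    def test_group_means_track_configured_targets(self):
        """Exposed-group mean CIN stays within 3 points of its configured
        target when averaged over independent cohorts."""
        means_e, means_u = [], []
        for seed in range(20):
            bundle = simulate_cohort(CohortConfig(n_per_group=8), seed=seed)
            cins = {k: cin_individual(m).mean_cin for k, m in bundle.fish.items()}
            means_e.append(np.mean([v for k, v in cins.items() if k.startswith("E")]))
            means_u.append(np.mean([v for k, v in cins.items() if not k.startswith("E")]))
        cfg = CohortConfig()
        assert abs(np.mean(means_e) - cfg.exposed.mean_cin) < 3.0
        assert abs(np.mean(means_u) - cfg.unexposed.mean_cin) < 3.0


class TestSimulateKaryotypes:
    def test_zero_rates_give_normal_records(self):
        model = KaryotypeRateModel(rates={}, metaphases_range=(19, 25))
        sim = simulate_karyotypes(model, 3, seed=1)
        assert all(r.is_normal for r in sim.records)

    def test_poisson_concentration_of_event_totals(self):
        model = KaryotypeRateModel(rates={"scas": 0.1}, metaphases_range=(50, 50))
        total = 0
        n_meta = 0
        for seed in range(20):
            sim = simulate_karyotypes(model, 1, seed=seed)
            n_meta += len(sim.records)
            total += sum(len(r.events) for r in sim.records)
        lam = 0.1 * n_meta
        assert abs(total - lam) < 3 * np.sqrt(lam)

    def test_injected_structural_aberration_called_cca(self):
        model = KaryotypeRateModel(
            rates={}, clonal_injections=(("del(6)(q25)", 2),),
            metaphases_range=(19, 25),
        )
        sim = simulate_karyotypes(model, 1, seed=3)
        calls = {c.key: c for c in call_clonality(list(sim.records))}
        assert calls["del(6)(q25)"].call == "CCA"
        assert sim.injections[0][1:] == ("del(6)(q25)", 2)

    def test_injection_count_bounded_by_min_metaphases(self):
        with pytest.raises(ValueError):
            KaryotypeRateModel(rates={}, clonal_injections=(("del(6)(q25)", 30),),
                               metaphases_range=(19, 25))

    def test_constitutional_sexes_respected(self):
        model = default_karyotype_model("unexposed")
        sim = simulate_karyotypes(model, 3, seed=2,
                                  constitutional_sexes=["XX", "XY", "XX"])
        assert sim.constitutional_sex == {"S1": "XX", "S2": "XY", "S3": "XX"}
        for r in sim.records:
            base = sim.constitutional_sex[r.individual_id]
            assert r.sex_complement in (base, "X")

    def test_default_models_reflect_group_burdens(self):
        e = default_karyotype_model("exposed")
        u = default_karyotype_model("unexposed")
        assert sum(e.rates.values()) > 3 * sum(u.rates.values())
        with pytest.raises(ValueError):
            default_karyotype_model("other")


def test_yaml_config_round_trip(tmp_path):
    cfg_text = """
n_per_group: 5
n_nuclei: 60
exposed:
  mean_cin: 30.0
  sd_cin: 5.0
  noise: {p_dropout: 0.02, p_split: 0.005}
"""
    path = tmp_path / "cohort.yaml"
    path.write_text(cfg_text)
    cfg = load_config(path)
    assert cfg.n_per_group == 5 and cfg.n_nuclei == 60
    assert cfg.exposed.mean_cin == 30.0
    assert cfg.exposed.noise.p_dropout == 0.02
    assert cfg.unexposed.mean_cin == CohortConfig().unexposed.mean_cin
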