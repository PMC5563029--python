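import numpy as np
import pandas as pd
import pytest

from offtype.simulate import (
    CultivarSpec,
    DEFAULT_DEPTH_MEANS,
    SimConfig,
    default_cluster_assignment,
    default_config,
    simulate_flow,
    simulate_genotypes,
    simulate_morphology,
    write_simulation,
)


def zero_noise_config(seed=0, n_loci=50):
    return SimConfig(
        seed=seed,
        n_loci=n_loci,
        cultivars=[
            CultivarSpec("A", 3, 4, "standard"),
            CultivarSpec("B", 3, 4, "standard"),
        ],
        within_family_divergence=0.0,
        contaminant_divergence=0.0,
        somatic_mutation_rate=0.0,
        sequencing_error=0.0,
        depth_mean={3: 30.0},
    )


def test_same_seed_same_outputs():
    cfg = default_config(seed=11, n_loci=200)
    t1, truth1 = simulate_genotypes(cfg)
    t2, truth2 = simulate_genotypes(cfg)
    assert t1 == t2
    assert truth1.contaminants == truth2.contaminants
    assert truth1.founder_dosage == truth2.founder_dosage


def test_different_seeds_differ():
    t1, _ = simulate_genotypes(default_config(seed=1, n_loci=200))
    t2, _ = simulate_genotypes(default_config(seed=2, n_loci=200))
    assert t1 != t2


def test_zero_noise_clones_are_identical():
    table, truth = simulate_genotypes(zero_noise_config())
    assert truth.contaminants == []
    # with no divergence and no somatic mutations every triploid sample
    # carries the consensus genotype vector
    consensus = np.array(truth.consensus_dosage[3], dtype=np.int16)
    for j in range(table.n_samples):
        called = table.dosage[:, j] >= 0
        assert np.array_equal(table.dosage[called, j], consensus[called])


def test_invalid_configs_rejected():
    cfg = zero_noise_config()
    cfg.depth_mean = {3: 0.0}
    with pytest.raises(ValueError, match="depth_mean"):
        simulate_genotypes(cfg)
    cfg = zero_noise_config()
    cfg.within_family_divergence = 1.5
    with pytest.raises(ValueError, match="probability"):
        cfg.validate()
    with pytest.raises(ValueError):
        CultivarSpec("A", 3, 2, "standard", n_contaminants=3)


def test_divergent_founder_loci_count_matches_binomial_oracle():
    """Two cultivars at divergence r differ per locus with probability
    1 - [(1-r)^2 + 2r(1-r)/(p+1) + r^2/(p+1)] (independent uniform redraws);
    the observed mean count over 20 seeds must sit within 3 pooled SDs."""
    r, L, p = 0.01, 1000, 3
    p_diff = 1 - ((1 - r) ** 2 + 2 * r * (1 - r) / (p + 1) + r**2 / (p + 1))
    counts = []
    for seed in range(20):
        cfg = SimConfig(
            seed=seed,
            n_loci=L,
            cultivars=[CultivarSpec("A", p, 1, "standard"), CultivarSpec("B", p, 1, "standard")],
            within_family_divergence=r,
            somatic_mutation_rate=0.0,
            sequencing_error=0.0,
        )
        _, truth = simulate_genotypes(cfg)
        fa = np.array(truth.founder_dosage[f"A|{p}"])
        fb = np.array(truth.founder_dosage[f"B|{p}"])
        counts.append(int((fa != fb).sum()))
    expected = L * p_diff
    se_mean = np.sqrt(L * p_diff * (1 - p_diff) / len(counts))
    assert abs(np.mean(counts) - expected) < 3 * se_mean


def test_morphology_zero_sd_yields_exact_cluster_means():
    cfg = zero_noise_config()
    cfg.morph_cluster_params = {
        1: {
            "internode_mm": (34.6, 0.0),
            "stolon_diam_mm": (0.8, 0.0),
            "leaf_len_mm": (14.9, 0.0),
            "leaf_wid_mm": (2.2, 0.0),
        }
    }
    records = simulate_morphology(cfg, {"S1": 1, "S2": 1})
    assert len(records) == 48  # 2 samples x 4 pots x 3 stolons x 2 dates
    assert (records["internode_mm"] == 34.6).all()
    assert (records["leaf_len_mm"] == 14.9).all()


def test_morphology_defaults_carry_three_cluster_structure():
    cfg = SimConfig()
    assert cfg.morph_cluster_params[1]["internode_mm"][0] == 34.6
    assert cfg.morph_cluster_params[2]["internode_mm"][0] == 21.9
    assert cfg.morph_cluster_params[3]["internode_mm"][0] == 24.7
    assert cfg.morph_cluster_params[1]["leaf_len_mm"][0] == 14.9
    assert cfg.morph_cluster_params[2]["leaf_len_mm"][0] == 9.9
    assert cfg.morph_cluster_params[3]["leaf_len_mm"][0] == 29.8


def test_morphology_unknown_cluster_is_error():
    with pytest.raises(ValueError, match="cluster"):
        simulate_morphology(zero_noise_config(), {"S1": 99})


def test_morphology_sample_means_recover_cluster_means():
    """Per-sample aggregates over 24 records are unbiased for the cluster
    mean: across 50 seeds the grand mean sits within 3 standard errors."""
    mean, sd = 21.9, 4.0
    vals = []
    for seed in range(50):
        cfg = zero_noise_config(seed=seed)
        rec = simulate_morphology(cfg, {"S1": 2})
        vals.append(rec["internode_mm"].mean())
    se = sd / np.sqrt(50 * 24)
    assert abs(np.mean(vals) - mean) < 3 * se


def test_flow_ratios():
    cfg = zero_noise_config()
    cfg.flow_cv = 0.0
    cfg.genome_sizes = {3: 1.67}
    table, _ = simulate_genotypes(cfg)
    flow = simulate_flow(cfg, table.samples)
    assert np.allclose(flow["fl2a_sample"], flow["fl2a_standard"])
    cfg.genome_sizes = {3: 3.34}
    flow = simulate_flow(cfg, table.samples)
    assert np.allclose(flow["fl2a_sample"] / flow["fl2a_standard"], 2.0)


def test_flow_missing_genome_size_is_error():
    cfg = zero_noise_config()
    cfg.genome_sizes = {2: 1.0}
    table, _ = simulate_genotypes(cfg)
    with pytest.raises(ValueError, match="ploidy"):
        simulate_flow(cfg, table.samples)


def test_flow_monte_carlo_recovery():
    """With CV noise the genome-size estimate stays within 3 x CV of truth
    per sample; the mean over 50 seeds is far tighter."""
    from offtype.genome_size import FlowMeasure, estimate_genome_size

    cv, pg = 0.02, 1.61
    ests = []
    for seed in range(50):
        cfg = zero_noise_config(seed=seed)
        cfg.flow_cv = cv
        cfg.genome_sizes = {3: pg}
        table, _ = simulate_genotypes(cfg)
        flow = simulate_flow(cfg, table.samples[:1])
        m = FlowMeasure("x", flow.fl2a_sample[0], flow.fl2a_standard[0])
        ests.append(estimate_genome_size(m))
    assert abs(np.mean(ests) - pg) < 3 * cv * pg / np.sqrt(50)


def test_default_depth_means_by_ploidy():
    assert DEFAULT_DEPTH_MEANS == {2: 9.5, 3: 4.9, 4: 7.4}
    cfg = default_config()
    lo, hi = cfg.raw_read_count_range
    assert (lo, hi) == (1.3e6, 13.9e6)


def test_default_roster_structure():
    cfg = default_config()
    table, truth = simulate_genotypes(cfg)
    roles = pd.Series([s.role for s in table.samples]).value_counts()
    assert roles["standard"] == 36
    assert roles["progenitor"] == 12
    assert roles["desirable"] + roles["off_type"] == 47
    assert len(truth.contaminants) == 5
    reads = np.array([s.raw_read_count for s in table.samples])
    assert reads.min() >= 1.3e6 and reads.max() <= 13.9e6


def test_write_simulation_is_deterministic(tmp_path):
    cfg = default_config(seed=5, n_loci=60)
    p1 = write_simulation(cfg, tmp_path / "a")
    p2 = write_simulation(cfg, tmp_path / "b")
    for key in p1:
        with open(p1[key], "rb") as f1, open(p2[key], "rb") as f2:
            assert f1.read() == f2.read(), key


def test_default_cluster_assignment_proportions():
    ids = [f"S{i}" for i in range(52)]
    a = default_cluster_assignment(ids, seed=0)
    sizes = pd.Series(list(a.values())).value_counts().sort_index()
    assert sizes.sum() == 52
    assert set(sizes.index) == {1, 2, 3}
    assert sizes[2] == max(sizes)
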