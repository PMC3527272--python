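"""Generator contracts: determinism, planted structure, ground-truth recovery."""

import numpy as np
import pandas as pd
import pytest

from topotx.normalization import compute_slr, fit_spikein_scale
from topotx.synthetic import (
    ConfigurationError,
    Kinetics,
    MutantSpec,
    SimulationConfig,
    occupancy_template,
    simulate_arrays,
    simulate_compendium,
    simulate_genome,
    simulate_qpcr,
)


def test_identical_seed_gives_identical_outputs(small_config):
    g1 = simulate_genome(small_config)
    g2 = simulate_genome(small_config)
    pd.testing.assert_frame_equal(g1.annotation, g2.annotation)
    for chrom in g1.track.values:
        np.testing.assert_array_equal(g1.track.values[chrom], g2.track.values[chrom])
    a1 = simulate_arrays(small_config, g1.annotation)
    a2 = simulate_arrays(small_config, g2.annotation)
    pd.testing.assert_frame_equal(a1.matrix.intensities, a2.matrix.intensities)
    c1 = simulate_compendium(small_config, g1.annotation)
    c2 = simulate_compendium(small_config, g2.annotation)
    pd.testing.assert_frame_equal(c1, c2)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_genes=0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(global_scale=0.0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(global_scale=1.5)
    with pytest.raises(ConfigurationError):
        SimulationConfig(frac_affected=1.2)
    with pytest.raises(ConfigurationError):
        SimulationConfig(noise_sd=-0.1)
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_conditions=1)


def test_class_balance_is_exact_and_degenerate_case_uniform():
    cfg = SimulationConfig(seed=0, n_genes=500, frac_affected=0.2)
    ann = simulate_genome(cfg).annotation
    affected = (ann["dependency_class"] != "unaffected").sum()
    assert affected == round(0.2 * 500)

    cfg0 = SimulationConfig(seed=0, n_genes=300, frac_affected=0.0)
    g0 = simulate_genome(cfg0)
    assert (g0.annotation["dependency_class"] == "unaffected").all()


def test_nfr_depth_set_by_dependency_class():
    # frac_affected=0: all NFR levels identical across genes (before noise);
    # with planted classes the template means differ by exactly the
    # configured depth difference.
    offsets = np.arange(-200, 0, 10)
    mean_aff = occupancy_template(offsets, 0.5).mean()
    mean_unaff = occupancy_template(offsets, 0.2).mean()
    assert mean_aff - mean_unaff == pytest.approx(0.3, abs=1e-12)
    assert np.allclose(occupancy_template(offsets, 0.2), 0.2)


def test_null_simulation_mutant_equals_wildtype():
    cfg = SimulationConfig(
        seed=2, n_genes=80, n_spikeins=8, noise_sd=0.0, activity_effect=0.0,
        frac_affected=0.0, bio_sd=0.0,
        mutants={"mut": MutantSpec(global_scale=1.0, effect_scale=1.0)},
    )
    sim = simulate_arrays(cfg, simulate_genome(cfg).annotation)
    wt = sim.matrix.intensities[["wt_1", "wt_2", "wt_3"]].to_numpy()
    mut = sim.matrix.intensities[["mut_1", "mut_2", "mut_3"]].to_numpy()
    np.testing.assert_array_equal(wt, mut)


def test_half_scale_halves_genes_and_leaves_spikeins():
    cfg = SimulationConfig(
        seed=2, n_genes=80, n_spikeins=8, noise_sd=0.0, activity_effect=0.0,
        frac_affected=0.0, bio_sd=0.0,
        mutants={"mut": MutantSpec(global_scale=0.5, effect_scale=1.0)},
    )
    sim = simulate_arrays(cfg, simulate_genome(cfg).annotation)
    genes = ~sim.matrix.spikein
    wt = sim.matrix.intensities.loc[genes, "wt_1"]
    mut = sim.matrix.intensities.loc[genes, "mut_1"]
    np.testing.assert_allclose(mut.to_numpy(), 0.5 * wt.to_numpy(), rtol=1e-12)
    spikes = sim.matrix.intensities.loc[sim.matrix.spikein]
    np.testing.assert_allclose(
        spikes["mut_1"].to_numpy(), spikes["wt_1"].to_numpy(), rtol=1e-12
    )


def test_spikein_neutrality_across_strains_at_zero_noise(small_config):
    cfg = SimulationConfig(
        seed=small_config.seed, n_genes=100, n_spikeins=16, noise_sd=0.0,
    )
    sim = simulate_arrays(cfg, simulate_genome(cfg).annotation)
    spikes = sim.matrix.intensities.loc[sim.matrix.spikein]
    # identical expected intensity on every array
    assert (spikes.nunique(axis=1) == 1).all()


def test_stored_slr_matches_computed_slr_after_exact_normalization():
    cfg = SimulationConfig(
        seed=5, n_genes=200, n_spikeins=16, noise_sd=0.0,
        mutants={"mut": MutantSpec(global_scale=0.7, effect_scale=1.0)},
    )
    sim = simulate_arrays(cfg, simulate_genome(cfg).annotation)
    result = fit_spikein_scale(sim.matrix)
    table = compute_slr(result, "mut", "wt", floor=1e-12)
    np.testing.assert_allclose(
        table["slr"].to_numpy(), sim.truth["slr_mut"].to_numpy(), atol=1e-9
    )


def test_ground_truth_slr_correlates_with_activity_as_recomputed():
    # the stored ground truth must reproduce its own planted correlation
    cfg = SimulationConfig(seed=11, n_genes=1000)
    ann = simulate_genome(cfg).annotation
    sim = simulate_arrays(cfg, ann)
    activity = ann["abundance_wt"] / ann["half_life"]
    rank = activity.rank(method="first").to_numpy()
    slr = sim.truth["slr_top1dtop2ts"].to_numpy()
    r = np.corrcoef(rank, slr)[0, 1]
    assert r < -0.05  # negative by construction at default effect


def test_compendium_class_spread_variance_identity():
    cfg = SimulationConfig(
        seed=4, n_genes=300, n_conditions=173,
        plasticity_sd_high=1.0, plasticity_sd_low=0.2,
    )
    ann = simulate_genome(cfg).annotation
    comp = simulate_compendium(cfg, ann)
    msq = (comp ** 2).mean(axis=1)
    affected = ann["dependency_class"] != "unaffected"
    assert msq[affected].mean() == pytest.approx(1.0, rel=0.15)
    assert msq[~affected].mean() == pytest.approx(0.04, rel=0.15)


def test_compendium_null_when_spreads_equal():
    cfg = SimulationConfig(
        seed=4, n_genes=400, n_conditions=60,
        plasticity_sd_high=0.5, plasticity_sd_low=0.5,
    )
    ann = simulate_genome(cfg).annotation
    comp = simulate_compendium(cfg, ann)
    msq = (comp ** 2).mean(axis=1)
    affected = ann["dependency_class"] != "unaffected"
    diff = msq[affected].mean() - msq[~affected].mean()
    se = np.sqrt(msq[affected].var() / affected.sum() + msq[~affected].var() / (~affected).sum())
    assert abs(diff) < 4 * se


def test_responsiveness_ranking_recovers_planted_class_with_bruteforce_auroc():
    from topotx.features import responsiveness

    cfg = SimulationConfig(seed=9, n_genes=500, n_conditions=100)
    ann = simulate_genome(cfg).annotation
    comp = simulate_compendium(cfg, ann)
    z = responsiveness(comp)
    labels = (ann["dependency_class"] != "unaffected").astype(int)
    # brute-force AUROC from the generated matrix itself
    pos = z[labels == 1].to_numpy()
    neg = z[labels == 0].to_numpy()
    auroc = np.mean(pos[:, None] > neg[None, :]) + 0.5 * np.mean(pos[:, None] == neg[None, :])
    assert auroc > 0.95


def test_qpcr_ct_log2_identity_and_truth_recovery():
    kin = {"locus": {"wt": Kinetics(timepoints=(0, 60), fold=(1.0, 0.5))}}
    cfg = SimulationConfig(seed=1, ct_noise_sd=0.0, expression_kinetics=kin)
    sim = simulate_qpcr(cfg)
    sub = sim.expression[sim.expression["locus"] == "locus"]
    ct0 = sub[sub["timepoint_min"] == 0][["ct_1", "ct_2", "ct_3"]].mean(axis=1).iloc[0]
    ct60 = sub[sub["timepoint_min"] == 60][["ct_1", "ct_2", "ct_3"]].mean(axis=1).iloc[0]
    assert ct60 - ct0 == pytest.approx(1.0, abs=1e-9)  # halving = +1 cycle


def test_qpcr_rejects_non_positive_quantities():
    kin = {"locus": {"wt": Kinetics(timepoints=(0,), fold=(0.0,))}}
    cfg = SimulationConfig(seed=1, expression_kinetics=kin)
    with pytest.raises(ConfigurationError):
        simulate_qpcr(cfg)


def test_planted_array_scales_are_applied_to_all_rows():
    cfg = SimulationConfig(
        seed=2, n_genes=50, n_spikeins=8, n_replicates=1, noise_sd=0.0,
        activity_effect=0.0, frac_affected=0.0, bio_sd=0.0,
        mutants={"mut": MutantSpec(1.0, 0.0)},
        array_scales={"mut_1": 2.0},
    )
    sim = simulate_arrays(cfg, simulate_genome(cfg).annotation)
    np.testing.assert_allclose(
        sim.matrix.intensities["mut_1"].to_numpy(),
        2.0 * sim.matrix.intensities["wt_1"].to_numpy(),
        rtol=1e-12,
    )
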