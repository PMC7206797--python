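import numpy as np
import pandas as pd
import pytest

from coresort.simulate import (
    SimulationConfig,
    generate_profiles,
    mix_samples,
    simulate_experiment,
)


def small_config(**kw):
    defaults = dict(
        n_proteins=120,
        celltype_fractions={
            "microglia": 0.1, "neuron": 0.1, "astrocyte": 0.1,
            "oligodendrocyte": 0.1, "endothelial": 0.05,
        },
        seed=7,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_config_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        SimulationConfig(group_compositions={"A": {"microglia": 0.5}, "B": {"microglia": 1.0}})
    with pytest.raises(ValueError, match="celltype_fractions"):
        SimulationConfig(celltype_fractions={"microglia": 0.7, "neuron": 0.7})
    with pytest.raises(ValueError, match="n_replicates"):
        SimulationConfig(n_replicates=1)
    with pytest.raises(ValueError, match="noise_sigma"):
        SimulationConfig(noise_sigma=-0.1)


def test_profiles_deterministic_given_seed():
    config = small_config()
    p1, t1 = generate_profiles(config)
    p2, t2 = generate_profiles(config)
    assert p1.equals(p2) and t1.equals(t2)


def test_zero_enrichment_gives_identical_celltype_profiles():
    profiles, _ = generate_profiles(small_config(marker_log2_enrichment=0.0))
    assert np.allclose(profiles.to_numpy().std(axis=1), 0.0)


def test_marker_rows_differ_by_exactly_the_enrichment():
    config = small_config(marker_log2_enrichment=2.5)
    profiles, truth = generate_profiles(config)
    for acc, cell_type in truth.items():
        row = profiles.loc[acc]
        if cell_type == "shared":
            assert row.nunique() == 1
        else:
            others = row.drop(cell_type)
            assert others.nunique() == 1
            assert row[cell_type] - others.iloc[0] == pytest.approx(2.5)


def test_pure_noise_free_samples_equal_profiles():
    compositions = {
        "MACS": {"microglia": 1.0},
        "FACS": {"microglia": 1.0},
    }
    config = small_config(
        group_compositions=compositions, noise_sigma=0.0, dropout_slope=0.0
    )
    profiles, truth = generate_profiles(config)
    table, truth_frame = mix_samples(profiles, truth, config)
    expected = np.power(2.0, profiles["microglia"].to_numpy())
    for sample in table.samples:
        assert np.allclose(table.data[sample].to_numpy(), expected)
    assert np.allclose(truth_frame["expected_log2fc"], 0.0)


def test_half_half_mixture_of_equal_profiles_is_convex():
    compositions = {
        "MACS": {"microglia": 0.5, "neuron": 0.5},
        "FACS": {"microglia": 1.0},
    }
    config = small_config(
        group_compositions=compositions,
        noise_sigma=0.0,
        dropout_slope=0.0,
        marker_log2_enrichment=0.0,  # all profiles identical
    )
    profiles, truth = generate_profiles(config)
    table, truth_frame = mix_samples(profiles, truth, config)
    expected = np.power(2.0, profiles["microglia"].to_numpy())
    assert np.allclose(table.data[table.samples[0]].to_numpy(), expected)
    assert np.allclose(truth_frame["expected_log2fc"], 0.0)


def test_empirical_log2fc_matches_closed_form():
    """Many replicates, no dropout: mean estimated log2fc within 3 SE of truth."""
    n_rep = 200
    config = small_config(n_proteins=40, n_replicates=n_rep, dropout_slope=0.0,
                          seed=20240519)
    table, design, _, truth = simulate_experiment(config)
    log2 = np.log2(table.data.to_numpy())
    ref_cols = [i for i, s in enumerate(table.samples) if s.startswith("MACS")]
    comp_cols = [i for i, s in enumerate(table.samples) if s.startswith("FACS")]
    estimate = log2[:, comp_cols].mean(axis=1) - log2[:, ref_cols].mean(axis=1)
    se = config.noise_sigma * np.sqrt(2.0 / n_rep)
    within = np.abs(estimate - truth["expected_log2fc"].to_numpy()) <= 3 * se
    assert within.mean() >= 0.95


def test_experiment_shape_and_truth_bookkeeping():
    table, design, reference, truth = simulate_experiment(seed=3)
    assert table.shape == (1791, 10)
    assert len(design.samples("MACS")) == 5 and len(design.samples("FACS")) == 5
    assert design.reference == "MACS"
    # marker reference contains exactly the simulated marker proteins
    markers = set(truth.index[truth["is_marker"]])
    assert set(reference.mapping) == markers
    for acc in list(markers)[:20]:
        assert reference.label(acc) == truth.loc[acc, "cell_type"]
    # same seed reproduces the table exactly
    table2, _, _, _ = simulate_experiment(seed=3)
    assert table.data.equals(table2.data)


def test_purified_markers_have_positive_expected_fc():
    _, _, _, truth = simulate_experiment(small_config())
    microglia = truth[truth["cell_type"] == "microglia"]
    assert (microglia["expected_log2fc"] > 0).all()
    neurons = truth[truth["cell_type"] == "neuron"]
    assert (neurons["expected_log2fc"] < 0).all()
    shared = truth[truth["cell_type"] == "shared"]
    assert np.allclose(shared["expected_log2fc"], 0.0, atol=0.2)


def test_null_config_zeroes_expected_effects():
    _, _, _, truth = simulate_experiment(small_config().null())
    assert np.allclose(truth["expected_log2fc"], 0.0)


def test_dropout_is_monotone_in_abundance():
    config = SimulationConfig(
        n_proteins=4000,
        celltype_fractions={},
        baseline_mean=6.0,
        baseline_sd=2.5,
        dropout_midpoint=5.0,
        dropout_slope=1.0,
        seed=11,
    )
    profiles, truth = generate_profiles(config)
    table, _ = mix_samples(profiles, truth, config)
    values = table.data.to_numpy()
    baseline = profiles.iloc[:, 0].to_numpy()
    bins = pd.cut(baseline, bins=[-np.inf, 3, 5, 7, 9, np.inf], labels=False)
    missing_rate = pd.Series((values == 0).mean(axis=1)).groupby(bins).mean()
    rates = missing_rate.to_numpy()
    assert (np.diff(rates) <= 1e-9).all()
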