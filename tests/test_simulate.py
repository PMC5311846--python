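"""Generator: effect encoding, standardization, variance structure, bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import blastopower as bp
from blastopower.design import TREATMENTS
from blastopower.simulate import ParameterError


@pytest.mark.parametrize(
    "spacing,expected",
    [(0, (0, 0, 0, 0)), (2, (0, 2, 4, 6)), (10, (0, 10, 20, 30))],
)
def test_effect_vector_equally_spaced(spacing, expected):
    assert bp.effect_vector(spacing).tolist() == list(expected)


def test_effect_vector_rejects_negative():
    with pytest.raises(ParameterError):
        bp.effect_vector(-1)


@pytest.mark.parametrize("spacing,sd,d", [(1, 10, 0.1), (10, 10, 1.0), (0, 10, 0.0)])
def test_standardize_effect(spacing, sd, d):
    assert bp.standardize_effect(spacing, sd) == pytest.approx(d)


def test_standardize_effect_rejects_nonpositive_sd():
    with pytest.raises(ParameterError):
        bp.standardize_effect(1, 0)


def test_params_validation():
    with pytest.raises(ParameterError):
        bp.SimulationParams(error_sd=-1)
    with pytest.raises(ParameterError):
        bp.SimulationParams(blastocyst_sd=-0.5)


def test_no_variance_limit_returns_baseline(design8, rng):
    params = bp.SimulationParams(
        treatment_spacing=0, celltype_spacing=0, error_sd=1e-12, blastocyst_sd=0, baseline_mean=7.5
    )
    y = bp.simulate_gene(design8, params, rng)
    assert np.allclose(y, 7.5, atol=1e-9)


def test_simulate_gene_rejects_bad_level_order(design8, rng):
    params = bp.SimulationParams()
    with pytest.raises(ParameterError):
        bp.simulate_gene(design8, params, rng, treatment_level_order=["control"] * 4)


def _component_estimates(design, params, n_genes, rng):
    """Moment-based oracle: pooled within-blastocyst variance and variance
    of blastocyst means, averaged over independent null genes."""
    sim = bp.GeneSimulator(design)
    b = pd.Categorical(design["blastocyst_id"]).codes
    within, between = [], []
    for _ in range(n_genes):
        y = sim.draw(params, rng)
        df = pd.DataFrame({"y": y, "b": b})
        groups = df.groupby("b")["y"]
        within.append(groups.var(ddof=1).mean())
        between.append(groups.mean().var(ddof=1))
    return float(np.mean(within)), float(np.mean(between))


def test_blastocyst_variance_recovered_in_zero_error_limit(design8):
    # sd_B = 5, error -> 0: no within-blastocyst spread, blastocyst means vary with variance 25
    params = bp.SimulationParams(
        treatment_spacing=0, celltype_spacing=0, error_sd=1e-9, blastocyst_sd=5
    )
    rng = np.random.default_rng(101)
    within, between = _component_estimates(design8, params, 10_000, rng)
    assert within == pytest.approx(0.0, abs=1e-12)
    assert between == pytest.approx(25.0, rel=0.05)


def test_error_variance_recovered_pooled_over_genes(design8):
    # spacings 0, sd_B = 0: pooled sample variance approaches error_sd^2 = 100
    params = bp.SimulationParams(treatment_spacing=0, celltype_spacing=0, error_sd=10, blastocyst_sd=0)
    rng = np.random.default_rng(202)
    sim = bp.GeneSimulator(design8)
    pooled = np.mean([sim.draw(params, rng).var(ddof=1) for _ in range(10_000)])
    assert pooled == pytest.approx(100.0, rel=0.02)


def test_dataset_reproducible_bit_identical(design8):
    preset = bp.ScenarioPreset(n_genes=50, de_fraction=0.2, cohens_d=0.3)
    params = bp.SimulationParams()
    m1 = bp.simulate_dataset(design8, preset, params, np.random.default_rng(9))
    m2 = bp.simulate_dataset(design8, preset, params, np.random.default_rng(9))
    pd.testing.assert_frame_equal(m1.values, m2.values)
    pd.testing.assert_frame_equal(m1.gene_meta, m2.gene_meta)


@pytest.mark.parametrize(
    "n_genes,frac,expected",
    [(12_000, 0.10, 1200), (12_000, 0.01, 120), (100, 0.0, 0), (10, 0.25, 2)],
)
def test_de_gene_bookkeeping_is_exact(n_genes, frac, expected):
    preset = bp.ScenarioPreset(n_genes=n_genes, de_fraction=frac, cohens_d=0.5)
    assert preset.n_de == expected


def test_simulated_de_flags_match_preset(design8):
    preset = bp.ScenarioPreset(n_genes=200, de_fraction=0.1, cohens_d=0.5)
    m = bp.simulate_dataset(design8, preset, bp.SimulationParams(), np.random.default_rng(3))
    assert int(m.gene_meta["is_de"].sum()) == 20
    assert m.n_genes == 200


def test_nonde_genes_have_no_treatment_effect(design8):
    """Null columns must be exchangeable wrt treatment: with all noise off,
    non-DE genes are flat across treatments."""
    # DE spacing is cohens_d * error_sd, so keep it large relative to the noise
    preset = bp.ScenarioPreset(n_genes=10, de_fraction=0.5, cohens_d=1000.0)
    params = bp.SimulationParams(celltype_spacing=0, error_sd=1e-9, blastocyst_sd=0)
    m = bp.simulate_dataset(design8, preset, params, np.random.default_rng(4))
    de = m.gene_meta["is_de"].to_numpy()
    vals = m.values.to_numpy()
    assert np.allclose(vals[:, ~de], 0.0, atol=1e-7)
    assert np.all(np.ptp(vals[:, de], axis=0) > 1e-6)


def test_treatment_permutation_is_uniform_over_levels(design8):
    """Across many DE genes each treatment should carry the largest effect
    magnitude in about 1/4 of genes."""
    preset = bp.ScenarioPreset(n_genes=10_000, de_fraction=1.0, cohens_d=0.1)
    m = bp.simulate_dataset(design8, preset, bp.SimulationParams(), np.random.default_rng(5))
    top_level = m.gene_meta["treatment_permutation"].str.split("|").str[-1]
    observed = top_level.value_counts().reindex(list(TREATMENTS)).to_numpy()
    chi2, p = stats.chisquare(observed)
    assert p > 0.01


def test_dataset_csv_round_trip(tmp_path, design8):
    preset = bp.ScenarioPreset(n_genes=5, de_fraction=0.2, cohens_d=0.5)
    m = bp.simulate_dataset(design8, preset, bp.SimulationParams(), np.random.default_rng(6))
    vpath, mpath = tmp_path / "values.csv", tmp_path / "genes.csv"
    m.to_csv(vpath, mpath)
    vals = pd.read_csv(vpath, index_col="sample_id")
    meta = pd.read_csv(mpath)
    np.testing.assert_allclose(vals.to_numpy(), m.values.to_numpy())
    assert list(meta.columns) == ["gene_id", "is_de", "treatment_permutation"]
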