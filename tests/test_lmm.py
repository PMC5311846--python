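"""Mixed-model LRT: chi-square reference, nesting, degeneracy, external oracles."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import blastopower as bp
from blastopower.lmm import LmmFit, TREATMENT_DF


def _fit_stub(lrt):
    return LmmFit(
        fixed_effects={},
        blastocyst_variance=0.0,
        residual_variance=1.0,
        loglik_full_ml=0.0,
        loglik_reduced_ml=0.0,
        lrt_statistic=lrt,
        lrt_df=TREATMENT_DF,
        p_value=0.5,
        converged=True,
    )


def test_treatment_pvalue_reference_distribution():
    assert bp.treatment_pvalue(_fit_stub(0.0)) == pytest.approx(1.0)
    # 7.8147 is the 95th percentile of chi-square(3)
    assert bp.treatment_pvalue(_fit_stub(7.8147)) == pytest.approx(0.05, abs=1e-4)
    assert bp.treatment_pvalue(_fit_stub(100.0)) < 1e-15
    failed = _fit_stub(1.0)
    failed.converged = False
    assert np.isnan(bp.treatment_pvalue(failed))


def test_constant_response_flags_nonconvergence(design8):
    fit = bp.fit_lmm(np.full(32, 3.0), design8)
    assert not fit.converged
    assert np.isnan(fit.p_value)


def test_misaligned_response_raises(design8):
    with pytest.raises(ValueError):
        bp.fit_lmm(np.zeros(10), design8)


def test_single_blastocyst_flags_nonconvergence(rng):
    d = bp.build_unbalanced_design([8], ["control"])
    fit = bp.fit_lmm(rng.normal(size=8), d)
    assert not fit.converged


@pytest.mark.parametrize("spacing", [0, 2, 10])
def test_full_model_never_less_likely_than_reduced(design8, spacing):
    """ML nesting property: adding treatment cannot decrease the likelihood."""
    rng = np.random.default_rng(spacing)
    params = bp.SimulationParams(treatment_spacing=spacing)
    for _ in range(8):
        fit = bp.fit_lmm(bp.simulate_gene(design8, params, rng), design8)
        assert fit.converged
        assert fit.loglik_full_ml >= fit.loglik_reduced_ml - 1e-6
        assert fit.lrt_statistic >= 0
        assert 0 <= fit.p_value <= 1


def test_lrt_is_scale_equivariant(design8, rng):
    y = bp.simulate_gene(design8, bp.SimulationParams(treatment_spacing=3), rng)
    f1 = bp.fit_lmm(y, design8)
    f2 = bp.fit_lmm(3.7 * y, design8)
    assert f2.lrt_statistic == pytest.approx(f1.lrt_statistic, abs=1e-5)
    assert f2.p_value == pytest.approx(f1.p_value, abs=1e-6)


def test_boundary_fit_collapses_to_ols(design8):
    """With the blastocyst variance estimated at zero, the mixed-model ML
    log-likelihood must equal the OLS log-likelihood on the same data."""
    from blastopower.lmm import DesignMatrices

    m = DesignMatrices(design8)
    params = bp.SimulationParams(treatment_spacing=0, blastocyst_sd=0.0)
    rng = np.random.default_rng(77)
    checked = 0
    for _ in range(40):
        y = bp.simulate_gene(design8, params, rng)
        fit = bp.fit_lmm(y, design8)
        if not fit.converged or fit.blastocyst_variance > 1e-8:
            continue
        ols_full = sm.OLS(y, m.exog_full).fit()
        ols_reduced = sm.OLS(y, m.exog_reduced).fit()
        assert fit.loglik_full_ml == pytest.approx(ols_full.llf, abs=1e-4)
        # the reduced mixed model may keep a positive blastocyst variance
        # (it can absorb what the treatment contrasts explained), so it can
        # only beat the reduced OLS likelihood, never undercut it
        assert fit.loglik_reduced_ml >= ols_reduced.llf - 1e-6
        checked += 1
    assert checked >= 10


def test_variance_components_recovered_on_average(design8):
    """ML point estimates should track the generative components across genes."""
    params = bp.SimulationParams(treatment_spacing=0)
    rng = np.random.default_rng(55)
    fits = [bp.fit_lmm(bp.simulate_gene(design8, params, rng), design8) for _ in range(60)]
    bvar = np.mean([f.blastocyst_variance for f in fits if f.converged])
    rvar = np.mean([f.residual_variance for f in fits if f.converged])
    # ML estimates are biased low with 8 blastocysts and 7 fixed effects;
    # accept a generous band around (100, 100)
    assert 40 < bvar < 160
    assert 70 < rvar < 130


def test_pvalues_match_lme4_reference(design8, tmp_path):
    """The LRT must reproduce lme4's anova() model comparison, the reference
    implementation of this analysis, on identical data."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available; lme4 cross-validation cannot run")
    params = bp.SimulationParams(treatment_spacing=2)
    rng = np.random.default_rng(31)
    df = design8.copy()
    ours = []
    for i in range(5):
        y = bp.simulate_gene(design8, params, rng)
        df[f"y{i}"] = y
        ours.append(bp.fit_lmm(y, design8).p_value)
    csv = tmp_path / "data.csv"
    df.to_csv(csv, index=False)
    rcode = textwrap.dedent(
        f"""
        suppressMessages(library(lme4))
        df <- read.csv("{csv}")
        for (i in 0:4) {{
          y <- df[[paste0("y", i)]]
          m1 <- suppressWarnings(lmer(y ~ treatment + cell_type + (1|blastocyst_id), data=df, REML=FALSE))
          m0 <- suppressWarnings(lmer(y ~ cell_type + (1|blastocyst_id), data=df, REML=FALSE))
          cat(anova(m0, m1)$`Pr(>Chisq)`[2], "\\n")
        }}
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=300, check=True
    )
    theirs = [float(x) for x in out.stdout.split()]
    np.testing.assert_allclose(ours, theirs, atol=1e-6)


def test_fits_to_frame_schema(design8, rng):
    fits = [bp.fit_lmm(bp.simulate_gene(design8, bp.SimulationParams(), rng), design8)]
    frame = bp.fits_to_frame(fits, gene_ids=["geneA"])
    assert list(frame.columns) == [
        "gene_id", "lrt_statistic", "df", "p_value",
        "blastocyst_variance", "residual_variance", "converged",
    ]
    assert frame.loc[0, "gene_id"] == "geneA"
    assert frame.loc[0, "df"] == 3
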