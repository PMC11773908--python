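import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tspoquant import (
    bonferroni,
    fit_changepoint_lmm,
    fit_neuron_lmm,
    successive_difference_contrasts,
)
from tspoquant.synthetic import (
    LesionSimParams,
    generate_lesion_dataset,
    generate_neuron_rois,
)


class TestContrasts:
    def test_two_levels(self):
        C = successive_difference_contrasts([1, 2])
        np.testing.assert_allclose(C, [[-1.0, 1.0]])

    def test_three_levels_worked_example(self):
        # the third month is compared with the average of months one and two
        C = successive_difference_contrasts([1, 2, 3])
        np.testing.assert_allclose(C[1], [-0.5, -0.5, 1.0])

    def test_four_levels_brute_force(self, rng):
        C = successive_difference_contrasts([1, 2, 3, 4])
        np.testing.assert_allclose(C[2], [-1 / 3, -1 / 3, -1 / 3, 1.0])
        for _ in range(1000):
            x = rng.normal(size=4)
            for t in range(1, 4):
                assert C[t - 1] @ x == pytest.approx(x[t] - x[:t].mean())

    def test_rows_sum_to_zero_and_full_rank(self):
        for k in range(2, 9):
            C = successive_difference_contrasts(list(range(1, k + 1)))
            np.testing.assert_allclose(C.sum(axis=1), 0.0, atol=1e-12)
            assert np.linalg.matrix_rank(C) == k - 1

    def test_too_few_or_unordered_levels(self):
        with pytest.raises(ValueError):
            successive_difference_contrasts([3])
        with pytest.raises(ValueError):
            successive_difference_contrasts([2, 1, 3])


class TestBonferroni:
    def test_simple(self):
        np.testing.assert_allclose(bonferroni([0.005, 0.5], m=2), [0.01, 1.0])

    def test_m_one_is_identity(self):
        p = [0.01, 0.2, 0.9]
        np.testing.assert_allclose(bonferroni(p, m=1), p)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_never_decreases_and_caps_at_one(self, p):
        adj = bonferroni(p)
        assert (adj >= np.asarray(p)).all()
        assert (adj <= 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])


def zero_variance_dataset(seed=5):
    params = LesionSimParams(
        n_animals=6, lesions_per_animal=8, sigma_animal=0.0, sigma_lesion=0.0,
        n_cells=10**6,
    )
    return generate_lesion_dataset(params, seed=seed)[0]


class TestChangepointModel:
    def test_zero_variance_matches_wls_oracle(self):
        """On balanced data with no random variation the mixed fit must
        reproduce ordinary least squares on the same design exactly."""
        import statsmodels.api as sm

        from tspoquant.models import _coding_matrix

        df = zero_variance_dataset()
        fit = fit_changepoint_lmm(df)
        levels = sorted(df.month.unique())
        k = len(levels)
        D = np.zeros((len(df), k))
        for r, m in enumerate(df.month):
            D[r, levels.index(m)] = 1.0
        X = np.column_stack([D @ np.linalg.inv(_coding_matrix(k)),
                             df.treated.astype(float)])
        beta = sm.OLS(df.fraction.to_numpy(), X).fit().params
        ours = [fit.baseline_pp / 100.0]
        ours += [fit.estimates_pp[lvl] / 100.0 for lvl in levels[1:]]
        ours += [fit.treatment_pp / 100.0]
        np.testing.assert_allclose(ours, beta, rtol=1e-6)

    def test_constant_fractions_give_zero_contrasts(self):
        df = zero_variance_dataset()
        df["fraction"] = 0.5
        fit = fit_changepoint_lmm(df)
        for lvl in fit.levels[1:]:
            assert fit.estimates_pp[lvl] == pytest.approx(0.0, abs=1e-8)
        assert fit.var_animal == pytest.approx(0.0, abs=1e-10)
        assert fit.var_residual == pytest.approx(0.0, abs=1e-10)

    def test_drop_recovered_on_single_simulation(self):
        params = LesionSimParams(n_animals=20, lesions_per_animal=10, n_cells=1000)
        df, _ = generate_lesion_dataset(params, seed=17)
        fit = fit_changepoint_lmm(df)
        assert fit.estimates_pp[5] == pytest.approx(-12.8, abs=3 * fit.ses_pp[5])
        assert fit.m_comparisons == 7
        for lvl in fit.levels[1:]:
            assert fit.p_bonferroni[lvl] >= fit.p_raw[lvl]
            assert fit.p_bonferroni[lvl] <= 1.0

    def test_row_order_invariance(self):
        params = LesionSimParams()
        df, _ = generate_lesion_dataset(params, seed=23)
        fit_a = fit_changepoint_lmm(df)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit_b = fit_changepoint_lmm(shuffled)
        for lvl in fit_a.levels[1:]:
            assert fit_a.estimates_pp[lvl] == pytest.approx(
                fit_b.estimates_pp[lvl], abs=1e-8
            )

    def test_design_validation(self):
        df, _ = generate_lesion_dataset(LesionSimParams(), seed=2)
        with pytest.raises(ValueError, match=">= 2 month levels"):
            fit_changepoint_lmm(df[df.month == 1])
        with pytest.raises(ValueError, match=">= 2 animals"):
            fit_changepoint_lmm(df[df.animal_id == 1])
        with pytest.raises(ValueError, match="no observations"):
            fit_changepoint_lmm(df[df.month != 3], levels=list(range(1, 9)))

    def test_lesion_variance_component_with_replicates(self):
        params = LesionSimParams(n_animals=8, lesions_per_animal=4,
                                 month_levels=(1, 2, 3, 4))
        df, _ = generate_lesion_dataset(params, seed=31)
        dup = pd.concat([df, df], ignore_index=True)  # replicate observations
        fit = fit_changepoint_lmm(dup)
        assert fit.var_lesion is not None and fit.var_lesion >= 0.0


class TestNeuronModel:
    def _degenerate(self):
        rows = []
        for a, g, f in [(1, "control", 0.006)] + [
            (i, "EAE", 0.121) for i in range(2, 7)
        ]:
            for s in ("left", "right"):
                rows.append(
                    dict(animal_id=a, group=g, side=s, fraction=f, n_neurons=100)
                )
        return pd.DataFrame(rows)

    def test_degenerate_group_means_give_published_difference(self):
        fit = fit_neuron_lmm(self._degenerate())
        assert fit.eae_effect_pp == pytest.approx(11.5, abs=1e-6)

    def test_weight_scale_invariance(self):
        df = generate_neuron_rois(seed=3)
        fit_a = fit_neuron_lmm(df)
        doubled = df.assign(n_neurons=df.n_neurons * 2)
        fit_b = fit_neuron_lmm(doubled)
        assert fit_a.eae_effect_pp == pytest.approx(fit_b.eae_effect_pp, abs=1e-8)
        assert fit_a.eae_se_pp == pytest.approx(fit_b.eae_se_pp, abs=1e-6)

    def test_matches_lme4_reference(self, tmp_path):
        """Independent oracle: lme4::lmer with precision weights fits the
        identical model; fixed effects, SEs and the animal variance must
        agree."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; lme4 oracle cannot run")
        df = generate_neuron_rois(seed=7, sigma_animal=0.05)
        csv = tmp_path / "rois.csv"
        df.to_csv(csv, index=False)
        script = f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
d$group <- relevel(factor(d$group), ref="control")
m <- lmer(fraction ~ group + side + (1|animal_id), data=d,
          weights=n_neurons, REML=TRUE)
fe <- fixef(m); vc <- as.data.frame(VarCorr(m))
cat(sprintf("%.10f %.10f %.10f %.10f %.10f\\n",
    fe[2], fe[3], sqrt(diag(vcov(m)))[2], vc$vcov[1], sigma(m)^2))
"""
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        eae_r, side_r, se_r, va_r, ve_r = map(float, out.stdout.split())
        fit = fit_neuron_lmm(df)
        assert fit.eae_effect_pp / 100 == pytest.approx(eae_r, abs=1e-6)
        assert fit.side_effect_pp / 100 == pytest.approx(side_r, abs=1e-6)
        assert fit.eae_se_pp / 100 == pytest.approx(se_r, abs=1e-5)
        assert fit.var_animal == pytest.approx(va_r, rel=1e-3, abs=1e-8)
        assert fit.var_residual == pytest.approx(ve_r, rel=1e-3)

    def test_null_type_one_error_controlled(self):
        """With no group difference the EAE test rejects at ~nominal rate."""
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            df = generate_neuron_rois(
                n_animals_control=3, n_animals_eae=3,
                p_control=0.06, p_eae=0.06, sigma_animal=0.02,
                cells_per_roi=300, seed=5000 + rep,
            )
            fit = fit_neuron_lmm(df)
            rejections += fit.eae_p < 0.05
        assert rejections / n_rep <= 0.10  # small-sample tolerance

    def test_single_group_rejected(self):
        df = generate_neuron_rois(seed=1)
        with pytest.raises(ValueError, match="control and EAE"):
            fit_neuron_lmm(df[df.group == "EAE"])

    def test_flagged_rows_rejected(self):
        df = generate_neuron_rois(seed=1).assign(flagged=True)
        with pytest.raises(ValueError, match="flagged"):
            fit_neuron_lmm(df)
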