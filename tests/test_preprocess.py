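"""Filtering, CLR transformation and nuisance adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microtriad.preprocess import (
    CLRTransformer,
    DEFAULT_COVARIATES,
    NuisanceAdjuster,
    PipelineConfig,
    PrevalenceFilter,
    TransformedTable,
    adjust_nuisance,
    clr_transform,
    covariate_effect_report,
    prevalence_filter,
    qc_filter_samples,
    to_relative,
)
from microtriad.tables import AbundanceTable, MetadataTable, TableValidationError


def _count_table(values, modality="taxon"):
    values = np.asarray(values, dtype=float)
    return AbundanceTable(
        pd.DataFrame(
            values,
            index=[f"s{i}" for i in range(values.shape[0])],
            columns=[f"f{j}" for j in range(values.shape[1])],
        ),
        modality=modality,
    )


class TestSampleQC:
    def test_low_richness_in_one_table_removes_sample(self):
        rng = np.random.default_rng(0)
        taxa = _count_table(rng.integers(1, 10, size=(3, 60)))
        modules = _count_table(rng.integers(1, 10, size=(3, 200)), "module")
        # sample s0: only 49 nonzero genera, plenty of modules
        taxa.data.iloc[0, 49:] = 0.0
        kept = qc_filter_samples(taxa, modules, min_features=50)
        assert kept == ["s1", "s2"]

    def test_all_pass_is_identity(self):
        taxa = _count_table(np.ones((4, 5)))
        modules = _count_table(np.ones((4, 5)), "module")
        assert qc_filter_samples(taxa, modules, 5) == taxa.sample_ids

    def test_planted_low_richness_cohort(self):
        from microtriad.simulate import CohortSpec, generate_cohort

        spec = CohortSpec(
            n_samples=62, n_taxa=210, n_modules=235, n_low_richness=5, seed=3
        )
        taxa, modules, meta, _ = generate_cohort(spec)
        kept = qc_filter_samples(taxa, modules, min_features=50)
        assert len(kept) == 57

    def test_disjoint_sample_sets_error(self):
        taxa = _count_table(np.ones((2, 5)))
        modules = AbundanceTable(
            pd.DataFrame(np.ones((2, 5)), index=["x1", "x2"],
                         columns=[f"f{j}" for j in range(5)]),
            modality="module",
        )
        with pytest.raises(TableValidationError, match="share no samples"):
            qc_filter_samples(taxa, modules, 1)


class TestPrevalenceFilter:
    def test_boundary_is_at_least(self, tiny_counts):
        # f2 present in 2 samples: kept at threshold 2, dropped at 3
        assert "f2" in prevalence_filter(tiny_counts, 2).feature_ids
        assert "f2" not in prevalence_filter(tiny_counts, 3).feature_ids

    def test_exact_surviving_set_by_enumeration(self, tiny_counts):
        expected = [
            c for c in tiny_counts.feature_ids
            if (tiny_counts.data[c] > 0).sum() >= 2
        ]
        assert prevalence_filter(tiny_counts, 2).feature_ids == expected == ["f1", "f2", "f4"]

    def test_threshold_one_drops_only_all_zero(self, tiny_counts):
        table = AbundanceTable(
            tiny_counts.data.assign(f5=0.0), modality="taxon"
        )
        assert prevalence_filter(table, 1).feature_ids == tiny_counts.feature_ids

    def test_nothing_surviving_is_an_error(self, tiny_counts):
        empty = AbundanceTable(tiny_counts.data * 0.0, modality="taxon")
        with pytest.raises(TableValidationError, match="threshold"):
            prevalence_filter(empty, 1)

    def test_commutes_with_closure(self, standard_cohort):
        taxa = standard_cohort["taxa"]
        direct = prevalence_filter(taxa, 15).feature_ids
        closed = prevalence_filter(to_relative(taxa), 15).feature_ids
        assert direct == closed


class TestToRelative:
    def test_proportionality(self):
        table = _count_table([[2.0, 2.0, 4.0]])
        np.testing.assert_allclose(
            to_relative(table).data.to_numpy()[0], [0.25, 0.25, 0.5]
        )

    def test_rows_sum_to_one(self, standard_cohort):
        rel = to_relative(standard_cohort["taxa"])
        np.testing.assert_allclose(rel.data.sum(axis=1), 1.0, atol=1e-12)

    def test_relative_input_needs_flag(self, tiny_counts):
        rel = to_relative(tiny_counts)
        with pytest.raises(TableValidationError, match="already"):
            to_relative(rel)
        assert to_relative(rel, allow_relative=True) is rel

    def test_all_zero_row_names_sample(self, tiny_counts):
        data = tiny_counts.data.copy()
        data.loc["s3"] = 0.0
        with pytest.raises(TableValidationError, match="s3"):
            to_relative(AbundanceTable(data, modality="taxon"))


class TestCLR:
    def test_uniform_composition_maps_to_zero(self):
        rel = _count_table([[1, 1, 1]])
        out = clr_transform(to_relative(rel))
        np.testing.assert_allclose(out.data.to_numpy(), 0.0, atol=1e-12)

    def test_hand_evaluated_values(self):
        rel = AbundanceTable(
            pd.DataFrame([[0.5, 0.25, 0.25]], index=["s0"], columns=list("abc")),
            modality="taxon", unit="relative",
        )
        out = clr_transform(rel).data.to_numpy()[0]
        np.testing.assert_allclose(out, [0.462098, -0.231049, -0.231049], atol=1e-5)

    def test_scale_invariance(self, tiny_counts):
        a = clr_transform(to_relative(tiny_counts)).data
        doubled = AbundanceTable(tiny_counts.data * 2, modality="taxon")
        b = clr_transform(to_relative(doubled)).data
        pd.testing.assert_frame_equal(a, b)

    def test_rows_sum_to_zero_and_finite(self, standard_cohort):
        out = clr_transform(to_relative(standard_cohort["taxa"]))
        values = out.data.to_numpy()
        assert np.isfinite(values).all()
        np.testing.assert_allclose(values.sum(axis=1), 0.0, atol=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.lists(st.floats(0.01, 100.0), min_size=4, max_size=4),
                    min_size=2, max_size=6))
    def test_property_rowsum_zero_and_scale_invariance(self, rows):
        table = _count_table(rows)
        clr = clr_transform(to_relative(table)).data.to_numpy()
        assert np.abs(clr.sum(axis=1)).max() < 1e-9
        scaled = _count_table(np.asarray(rows) * 7.5)
        clr2 = clr_transform(to_relative(scaled)).data.to_numpy()
        np.testing.assert_allclose(clr, clr2, atol=1e-9)


class TestAdjustment:
    def _as_transformed(self, values, index):
        return TransformedTable(
            pd.DataFrame(values, index=index,
                         columns=[f"f{j}" for j in range(values.shape[1])]),
            stage="adjusted",
        )

    def test_matches_normal_equations(self, small_metadata):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(6, 3))
        t = self._as_transformed(Y, small_metadata.sample_ids)
        covs = ("age", "crp")
        out = adjust_nuisance(t, small_metadata, covs)
        X = np.column_stack([
            np.ones(6),
            small_metadata.frame["age"].to_numpy(float),
            small_metadata.frame["crp"].to_numpy(float),
        ])
        # independent oracle: explicit normal equations
        beta = np.linalg.solve(X.T @ X, X.T @ Y)
        np.testing.assert_allclose(out.data.to_numpy(), Y - X @ beta, atol=1e-10)

    def test_intercept_only_behaviour_is_centering(self, small_metadata):
        # a constant covariate is rank-deficient; degenerate design rejected
        Y = np.arange(12.0).reshape(6, 2)
        t = self._as_transformed(Y, small_metadata.sample_ids)
        frame = small_metadata.frame.copy()
        frame["age"] = 40.0
        with pytest.raises(TableValidationError, match="age"):
            adjust_nuisance(t, MetadataTable(frame), ("age",))

    def test_perfect_fit_gives_zero_residuals(self, small_metadata):
        age = small_metadata.frame["age"].to_numpy(float)
        Y = np.column_stack([2.0 * age + 1.0])
        t = self._as_transformed(Y, small_metadata.sample_ids)
        out = adjust_nuisance(t, small_metadata, ("age", "crp"))
        np.testing.assert_allclose(out.data.to_numpy(), 0.0, atol=1e-9)

    def test_residuals_orthogonal_to_design(self, standard_cohort):
        from microtriad.preprocess import clr_transform, to_relative

        taxa = standard_cohort["taxa"]
        meta = standard_cohort["meta"]
        clr = clr_transform(to_relative(taxa))
        out = adjust_nuisance(clr, meta, DEFAULT_COVARIATES)
        resid = out.data.to_numpy()
        design = meta.frame.loc[out.sample_ids, list(DEFAULT_COVARIATES)].to_numpy(float)
        scale = np.abs(resid).max()
        assert np.abs(resid.mean(axis=0)).max() < 1e-8 * scale
        for j in range(design.shape[1]):
            c = design[:, j] - design[:, j].mean()
            assert np.abs(c @ resid).max() / (np.abs(c).max() * len(c)) < 1e-8 * scale

    def test_missing_covariate_drops_sample(self, small_metadata):
        frame = small_metadata.frame.copy()
        frame.loc["s2", "crp"] = np.nan
        meta = MetadataTable(frame)
        Y = np.random.default_rng(0).normal(size=(6, 2))
        t = self._as_transformed(Y, meta.sample_ids)
        out = adjust_nuisance(t, meta, ("crp",))
        assert "s2" not in out.sample_ids
        assert out.provenance["dropped_samples"] == ["s2"]

    def test_insufficient_residual_df(self, small_metadata):
        Y = np.random.default_rng(0).normal(size=(6, 2))
        t = self._as_transformed(Y, small_metadata.sample_ids)
        covs = ("age", "crp", "sex", "steroid", "hads_d")  # 6 - 6 params = 0 df
        with pytest.raises(TableValidationError, match="degrees of freedom"):
            adjust_nuisance(t, small_metadata, covs)


class TestCovariateEffectReport:
    def test_t_stats_match_residual_recomputation(self, small_metadata):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(6, 2))
        t = TransformedTable(
            pd.DataFrame(Y, index=small_metadata.sample_ids, columns=["a", "b"]),
            stage="adjusted",
        )
        covs = ("age", "crp")
        report = covariate_effect_report(t, small_metadata, covs)
        X = np.column_stack([
            np.ones(6),
            small_metadata.frame["age"].to_numpy(float),
            small_metadata.frame["crp"].to_numpy(float),
        ])
        XtX_inv = np.linalg.inv(X.T @ X)
        for k, feature in enumerate(["a", "b"]):
            y = Y[:, k]
            beta = XtX_inv @ X.T @ y
            resid = y - X @ beta
            sigma2 = resid @ resid / (6 - 3)
            se = np.sqrt(np.diag(XtX_inv) * sigma2)
            np.testing.assert_allclose(
                report.loc[feature, ["t_age", "t_crp"]].to_numpy(),
                (beta / se)[1:], atol=1e-8,
            )
            assert 0.0 <= report.loc[feature, "r_squared"] <= 1.0

    def test_strong_dependence_gives_r2_near_one(self, small_metadata):
        age = small_metadata.frame["age"].to_numpy(float)
        Y = (2.0 * age + 1e-8 * np.random.default_rng(0).normal(size=6))[:, None]
        t = TransformedTable(
            pd.DataFrame(Y, index=small_metadata.sample_ids, columns=["a"]),
            stage="adjusted",
        )
        report = covariate_effect_report(t, small_metadata, ("age", "crp"))
        assert report.loc["a", "r_squared"] > 1 - 1e-9

    def test_independent_feature_has_small_t_and_r2(self):
        rng = np.random.default_rng(1)
        n = 200
        frame = pd.DataFrame(
            {
                "age": rng.normal(45, 12, n).round(1).clip(18),
                "sex": rng.integers(0, 2, n),
                "diagnosis": rng.choice(["CD", "UC"], n),
                "crp": rng.lognormal(2.5, 0.9, n).round(1),
                "fcal": rng.lognormal(5.6, 0.7, n).round(0),
                "steroid": rng.integers(0, 2, n),
                "mesalamine": rng.integers(0, 2, n),
                "immunosuppressant": rng.integers(0, 2, n),
                "contraceptive": rng.integers(0, 2, n),
                "antidepressant": rng.integers(0, 2, n),
                "ppi": rng.integers(0, 2, n),
                "hads_d": rng.integers(0, 22, n),
                "weimus": rng.integers(0, 69, n),
            },
            index=pd.Index([f"s{i}" for i in range(n)], name="sample"),
        )
        meta = MetadataTable(frame)
        Y = rng.normal(size=(n, 1))
        t = TransformedTable(
            pd.DataFrame(Y, index=meta.sample_ids, columns=["a"]), stage="adjusted"
        )
        report = covariate_effect_report(t, meta, DEFAULT_COVARIATES)
        assert report.loc["a", "r_squared"] < 0.12
        tcols = [c for c in report.columns if c.startswith("t_")]
        assert report.loc["a", tcols].abs().max() < 4.0


class TestConfigAndTransformers:
    def test_config_requires_ten_covariates(self):
        with pytest.raises(ValueError, match="10 nuisance"):
            PipelineConfig(covariates=("age", "sex"))

    def test_config_defaults_are_study_constants(self):
        cfg = PipelineConfig()
        assert (cfg.prevalence_min, cfg.qc_min_features) == (15, 50)
        assert cfg.rscale == pytest.approx(0.354)
        assert cfg.bf_log10_threshold == 0.5

    def test_sklearn_pipeline_composition(self, standard_cohort):
        from sklearn.pipeline import Pipeline

        meta = standard_cohort["meta"]
        pipe = Pipeline([
            ("prevalence", PrevalenceFilter(min_prevalence=15)),
            ("clr", CLRTransformer()),
            ("adjust", NuisanceAdjuster(metadata=meta)),
        ])
        out = pipe.fit_transform(standard_cohort["taxa"].data)
        assert out.shape[0] == 57
        assert pipe.named_steps["prevalence"].feature_names_ == list(out.columns)
        params = pipe.get_params()
        assert params["prevalence__min_prevalence"] == 15

    def test_transformer_matches_functions(self, standard_cohort):
        taxa = standard_cohort["taxa"]
        via_fn = clr_transform(to_relative(prevalence_filter(taxa, 15))).data
        filt = PrevalenceFilter(15).fit(taxa.data)
        via_tf = CLRTransformer().fit_transform(filt.transform(taxa.data))
        pd.testing.assert_frame_equal(via_fn, via_tf)
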