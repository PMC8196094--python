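import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pestmix import catalog as cat
from pestmix.design import (
    DEFAULT_COVARIATE_SCHEMA,
    PriorConfig,
    assemble_design,
    build_chemistry_z,
    build_class_z,
    build_design_z,
    build_primary_z,
    tau_from_half_width,
)

CATALOG = cat.default_catalog()
PRENATAL = [p for p in CATALOG if p.name in cat.prenatal_pesticides()]


class TestTauRule:
    def test_default_half_width_and_mass(self):
        """±5 T-score support with 95% central mass gives tau ~ 2.551."""
        tau = tau_from_half_width(5.0, 0.95)
        assert tau == pytest.approx(5.0 / stats.norm.ppf(0.975), abs=1e-12)
        assert tau == pytest.approx(2.551, abs=1e-3)

    def test_one_sigma_identity(self):
        mass_1sd = 2 * stats.norm.cdf(1) - 1
        assert tau_from_half_width(5.0, mass_1sd) == pytest.approx(5.0, abs=1e-9)

    def test_linear_in_half_width(self):
        assert tau_from_half_width(10.0, 0.95) == pytest.approx(
            2 * tau_from_half_width(5.0, 0.95)
        )

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            tau_from_half_width(5.0, 1.0)

    def test_placed_mass_is_recovered(self):
        """A N(0, tau) variate lands in ±half_width with the stated mass."""
        tau = tau_from_half_width(3.0, 0.8)
        assert stats.norm.cdf(3.0, scale=tau) - stats.norm.cdf(-3.0, scale=tau) == pytest.approx(0.8)


class TestPrimaryZ:
    def test_prenatal_pools_six_ops(self):
        z = build_primary_z(PRENATAL)
        assert z.n_hier == 6
        op_names = [p.name for p in PRENATAL if p.chem_class == "organophosphate"]
        for n in op_names:
            assert z.hierarchical[n]
            assert z.z.loc[n, "organophosphate"] == 1.0
        singles = [n for n in z.coef_names if n not in op_names]
        assert len(singles) == 5
        assert not z.hierarchical[singles].any()

    def test_postnatal_pools_seven_ops(self):
        z = build_primary_z(CATALOG)
        assert z.n_hier == 7
        assert z.hierarchical["naled"]

    def test_all_singletons_degenerate_to_vague(self):
        singles = [p for p in CATALOG if p.chem_class != "organophosphate"]
        z = build_primary_z(singles)
        assert z.n_hier == 0


class TestClassZ:
    def test_one_column_per_class_row_sums_one(self):
        z = build_class_z(PRENATAL)
        assert z.z.shape[1] == 6  # six chemical classes
        np.testing.assert_allclose(z.z.to_numpy().sum(axis=1), 1.0)
        assert z.hierarchical.all()

    def test_same_class_rows_identical(self):
        z = build_class_z(CATALOG)
        assert (z.z.loc["chlorpyrifos"] == z.z.loc["diazinon"]).all()

    @pytest.mark.parametrize("builder", [build_primary_z, build_class_z, build_chemistry_z])
    def test_permutation_equivariance(self, builder, rng):
        perm = rng.permutation(len(PRENATAL))
        z1 = builder(PRENATAL)
        z2 = builder([PRENATAL[i] for i in perm])
        names = [PRENATAL[i].name for i in perm]
        pd.testing.assert_frame_equal(
            z1.z.loc[names, z2.z.columns], z2.z, check_like=False
        )
        assert (z1.hierarchical.loc[names] == z2.hierarchical).all()


class TestChemistryZ:
    def test_subtype_indicators(self):
        z = build_chemistry_z(CATALOG)
        assert z.z.loc["chlorpyrifos", "diethyl"] == 1.0
        assert z.z.loc["chlorpyrifos", "dimethyl"] == 0.0
        assert z.z.loc["malathion", "dimethyl"] == 1.0

    def test_potency_standardized_over_ops(self):
        z = build_chemistry_z(CATALOG)
        ops = [p.name for p in CATALOG if p.chem_class == "organophosphate"]
        pot = z.z.loc[ops, "potency"].to_numpy()
        assert pot.mean() == pytest.approx(0.0, abs=1e-12)
        assert pot.std() == pytest.approx(1.0, abs=1e-12)

    def test_non_ops_stay_vague(self):
        z = build_chemistry_z(CATALOG)
        assert not z.hierarchical["glyphosate"]

    def test_missing_bmd_rejected(self):
        broken = [
            cat.PesticideInfo("opx", "organophosphate", True, "diethyl", None, 1e4, 1e4)
        ]
        with pytest.raises(ValueError, match="benchmark dose"):
            build_chemistry_z(broken)


class TestDesignZ:
    def test_postnatal_blocks_pool_separately(self):
        names = cat.postnatal_pesticides() + [f"pre_{p}" for p in cat.prenatal_pesticides()]
        z = build_design_z(names, CATALOG, variant="primary")
        assert z.n_hier == 7 + 6
        assert z.z.loc["chlorpyrifos", "organophosphate"] == 1.0
        assert z.z.loc["pre_chlorpyrifos", "pre:organophosphate"] == 1.0
        assert z.z.loc["pre_chlorpyrifos", "organophosphate"] == 0.0

    def test_sex_interaction_makes_all_hierarchical(self):
        pests = cat.prenatal_pesticides()
        names = pests + [f"{p}:girl" for p in pests]
        z = build_design_z(names, CATALOG, variant="primary")
        assert z.hierarchical.all()

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            build_design_z(["glyphosate"], CATALOG, variant="bogus")


class TestPriorConfig:
    def test_defaults(self):
        p = PriorConfig()
        assert p.tau == pytest.approx(2.551, abs=1e-3)
        assert p.vague_variance >= 1e4

    def test_too_small_vague_variance_rejected(self):
        with pytest.raises(ValueError):
            PriorConfig(vague_variance=10.0)


class TestAssembleDesign:
    def test_dimensions_small_cohort(self, small_study):
        pests = cat.prenatal_pesticides()
        d = assemble_design(
            small_study.exposures, small_study.covariates, small_study.outcomes,
            "prenatal", "maternal", "score", pests,
        )
        assert d.X.shape[1] == 11
        assert d.n_rows == len(d.y)
        assert d.n_rows <= 2 * d.n_subjects
        # maternal models include the language-of-interview covariate
        assert "language_spanish" in d.w_names
        counts = np.bincount(d.subject)
        assert counts.max() <= 2 and counts.min() >= 1

    def test_youth_reporter_drops_language_column(self, small_study):
        d = assemble_design(
            small_study.exposures, small_study.covariates, small_study.outcomes,
            "prenatal", "youth", "score", cat.prenatal_pesticides(),
        )
        assert "language_spanish" not in d.w_names

    def test_postnatal_appends_prenatal_adjustment_columns(self):
        from pestmix.simulate import SimulationConfig, simulate_study

        post = simulate_study(SimulationConfig(
            n_subjects=60, window="postnatal",
            pesticides=CATALOG, seed=7,
        ))
        pre = simulate_study(SimulationConfig(n_subjects=60, window="prenatal", seed=7))
        exposures = pd.concat([post.exposures, pre.exposures], ignore_index=True)
        d = assemble_design(
            exposures, post.covariates, post.outcomes, "postnatal", "maternal", "score",
            cat.postnatal_pesticides(), prenatal_adjustment=cat.prenatal_pesticides(),
        )
        assert d.X.shape[1] == 12 + 11
        assert sum(n.startswith("pre_") for n in d.x_names) == 11

    def test_sex_interaction_doubles_exposure_columns(self, small_study):
        pests = cat.prenatal_pesticides()
        d = assemble_design(
            small_study.exposures, small_study.covariates, small_study.outcomes,
            "prenatal", "maternal", "score", pests, sex_interaction=True,
        )
        assert d.X.shape[1] == 22
        j = d.x_names.index("glyphosate")
        k = d.x_names.index("glyphosate:girl")
        np.testing.assert_allclose(d.X[:, k], d.X[:, j] * d.sex_girl)

    def test_single_visit_subject_contributes_one_row(self, small_study):
        outcomes = small_study.outcomes.copy()
        pid = outcomes["participant_id"].iloc[0]
        mask = (outcomes["participant_id"] == pid) & (outcomes["visit"] == 18)
        outcomes = outcomes[~mask]
        d = assemble_design(
            small_study.exposures, small_study.covariates, outcomes,
            "prenatal", "maternal", "score", cat.prenatal_pesticides(),
        )
        code = d.subject_ids.index(pid)
        assert (d.subject == code).sum() == 1

    def test_reference_coding_expands_categoricals(self, small_study):
        cov = small_study.covariates.set_index("participant_id")
        W = DEFAULT_COVARIATE_SCHEMA.expand(cov, "maternal")
        assert "years_us[gt5_foreign]" in W.columns
        assert "years_us[le5]" not in W.columns  # reference level absorbed
        assert set(np.unique(W["years_us[gt5_foreign]"])) <= {0.0, 1.0}
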