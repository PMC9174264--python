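"""Synthetic-study generator: determinism, shapes, planted structure, doses."""

import numpy as np
import pandas as pd
import pytest

import periobiome as pb
from periobiome.errors import ConfigError
from periobiome.synth import (
    EffectSpec,
    StudyDesign,
    combined_inoculum_per_ml,
    default_effects,
    equal_volume_mix,
    generate_assay_fixtures,
    generate_study,
)


class TestDesignValidation:
    def test_defaults_are_eight_groups_of_six(self):
        d = StudyDesign()
        assert len(d.groups) == 8
        assert d.n_per_group == 6
        assert len(d.sample_ids()) == 48

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_per_group": 1},
            {"groups": ("only",)},
            {"n_bacterial_taxa": 0},
            {"library_size_mean": 10},
            {"groups": ("A", "A")},
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            StudyDesign(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"recovery": {"Infection": 1.5}},
            {"disease_taxa": {"vir_s001": -2.0}},
            {"lognormal_sigma": -0.1},
        ],
    )
    def test_invalid_effects_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            EffectSpec(**kwargs)

    def test_unknown_effect_taxon_rejected_at_generation(self):
        design = StudyDesign(n_bacterial_taxa=5, n_viral_taxa=2)
        with pytest.raises(ConfigError, match="bact_s099"):
            generate_study(design, EffectSpec(disease_taxa={"bact_s099": 2.0}))


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        design = StudyDesign(n_bacterial_taxa=20, n_viral_taxa=6, seed=3)
        t1, m1, mk1, tr1 = generate_study(design)
        t2, m2, mk2, tr2 = generate_study(design)
        pd.testing.assert_frame_equal(t1.data, t2.data)
        pd.testing.assert_frame_equal(mk1, mk2)
        pd.testing.assert_frame_equal(tr1.expected_log10_rpm, tr2.expected_log10_rpm)

    def test_different_seed_differs(self):
        design = StudyDesign(n_bacterial_taxa=20, n_viral_taxa=6)
        t1, *_ = generate_study(design, seed=1)
        t2, *_ = generate_study(design, seed=2)
        assert not t1.data.equals(t2.data)

    def test_fixture_bundle_deterministic(self):
        design = StudyDesign()
        f1 = generate_assay_fixtures(design, seed=9)
        f2 = generate_assay_fixtures(design, seed=9)
        pd.testing.assert_frame_equal(f1.bone_loss, f2.bone_loss)
        pd.testing.assert_frame_equal(f1.ct, f2.ct)


class TestStudyShape:
    def test_counts_nonnegative_integers_with_expected_shape(self, default_study):
        t = default_study["counts"]
        assert t.data.shape == (120, 48)
        assert (t.data.to_numpy() >= 0).all()
        assert t.data.dtypes.eq(np.int64).all()

    def test_library_sizes_near_mean(self, default_study):
        totals = default_study["counts"].totals()
        mean = default_study["design"].library_size_mean
        assert abs(totals.mean() - mean) < 4 * np.sqrt(mean / 48)

    def test_metadata_covers_every_sample_once(self, default_study):
        t = default_study["counts"]
        assert list(t.samples.index) == t.sample_ids
        assert t.samples["group"].value_counts().eq(6).all()

    def test_markers_nonnegative_full_panel(self, default_study):
        mk = default_study["markers"]
        assert mk.shape == (48, 7)
        assert (mk.to_numpy() >= 0).all()

    def test_truth_effect_multiplier_interpolates_geometrically(self, default_study):
        tr = default_study["truth"]
        # rho=0 keeps the full fold; rho=0.9 keeps fold^0.1
        assert tr.effect_multiplier.loc["vir_s001", "Infection"] == pytest.approx(4.0)
        assert tr.effect_multiplier.loc["vir_s001", "Infection+Nisin"] == pytest.approx(
            4.0**0.1
        )
        assert tr.effect_multiplier.loc["vir_s001", "Control"] == pytest.approx(1.0)


class TestPlantedStructure:
    def test_disease_virus_has_largest_log_difference(self):
        """A 4-fold planted virus dominates the Infection-vs-Control contrast."""
        design = StudyDesign(seed=12345)
        eff = EffectSpec(
            disease_taxa={"vir_s001": 4.0},
            recovery={"Infection": 0.0},
            lognormal_sigma=0.3,
            baseline_log10={"vir_s001": 0.5},
        )
        table, meta, _, _ = generate_study(design, eff)
        ab = pb.filter_low_abundance(pb.normalize_rpm(table))
        y = np.log10(ab.data + 0.1)
        grp = meta["group"]
        diff = (
            y[grp.index[grp == "Infection"]].mean(axis=1)
            - y[grp.index[grp == "Control"]].mean(axis=1)
        ).abs()
        assert diff.idxmax() == "vir_s001"

    def test_marginal_log10_rpm_matches_truth(self):
        """Mean log10 RPM over 200 replicate samples sits within 3 SEs of truth."""
        design = StudyDesign(
            groups=("Control", "Infection"),
            n_per_group=200,
            n_bacterial_taxa=25,
            n_viral_taxa=5,
            library_size_mean=300_000,
            seed=21,
        )
        table, meta, _, truth = generate_study(design, EffectSpec(lognormal_sigma=0.3))
        ctrl = meta.index[meta["group"] == "Control"]
        rpm = table.data[ctrl] / table.data[ctrl].sum(axis=0) * 1e6
        # restrict to taxa never hitting zero counts so log10 is exact
        solid = rpm.index[(table.data[ctrl] > 0).all(axis=1)]
        logr = np.log10(rpm.loc[solid])
        mean = logr.mean(axis=1)
        se = logr.std(axis=1, ddof=1) / np.sqrt(len(ctrl))
        expected = truth.expected_log10_rpm.loc[solid, "Control"]
        z = ((mean - expected) / se).abs()
        assert (z < 3).mean() > 0.95  # allow a single 3-SE excursion among ~30 taxa

    def test_null_rejection_rate_near_alpha(self):
        """With effects off, per-taxon t-tests reject at about the nominal rate."""
        design = StudyDesign(
            groups=("Control", "Infection"),
            n_per_group=6,
            n_bacterial_taxa=700,
            n_viral_taxa=300,
            library_size_mean=1_000_000,
            seed=77,
        )
        table, *_ = generate_study(design, EffectSpec(lognormal_sigma=0.3))
        ab = pb.filter_low_abundance(pb.normalize_rpm(table))
        da = pb.differential_abundance(
            pb.log_transform(ab), "Control", levels=("species",)
        )
        rate = (da["p"] < 0.05).mean()
        m = len(da)
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m)


class TestAssayFixtures:
    def test_bone_loss_has_28_sites_per_mouse(self):
        fx = generate_assay_fixtures(StudyDesign(), seed=0)
        site_cols = [c for c in fx.bone_loss.columns if c.startswith("site_")]
        assert len(site_cols) == 28
        assert len(fx.bone_loss) == 48
        assert (fx.bone_loss[site_cols].to_numpy() >= 0).all()

    def test_defects_out_of_72_surfaces_per_group(self):
        fx = generate_assay_fixtures(StudyDesign(), seed=0)
        assert (fx.defects["total_surfaces"] == 72).all()
        assert fx.defects["defects"].between(0, 72).all()
        assert len(fx.defects) == 8

    def test_qpcr_pathogens_bounded_by_total(self):
        fx = generate_assay_fixtures(StudyDesign(), seed=1)
        from periobiome.synth import PATHOGENS

        for p in PATHOGENS:
            assert (fx.qpcr[p] <= fx.qpcr["total_16s"]).all()

    def test_infection_more_severe_than_control(self):
        fx = generate_assay_fixtures(StudyDesign(), seed=2)
        site_cols = [c for c in fx.bone_loss.columns if c.startswith("site_")]
        by_group = fx.bone_loss.groupby("group")[site_cols].mean().mean(axis=1)
        assert by_group["Infection"] > by_group["Control"]
        d = fx.defects.set_index("group")["defects"]
        assert d["Infection"] > d["Control"]

    def test_round_trip_through_tsv(self, tmp_path):
        fx = generate_assay_fixtures(StudyDesign(), seed=3)
        fx.write(tmp_path)
        back = pd.read_csv(tmp_path / "boneloss.tsv", sep="\t")
        pd.testing.assert_frame_equal(back, fx.bone_loss)


class TestDoseArithmetic:
    def test_combined_inoculum_concentration(self):
        assert combined_inoculum_per_ml() == pytest.approx(5e9)

    def test_nisin_final_concentration(self):
        assert equal_volume_mix(600.0) == pytest.approx(300.0)

    def test_probiotic_final_concentration(self):
        assert equal_volume_mix(1e10) == pytest.approx(5e9)

    def test_invalid_dose_rejected(self):
        with pytest.raises(ConfigError):
            combined_inoculum_per_ml(cells_per_pathogen=0)


def test_default_effects_reference_real_taxa():
    design = StudyDesign()
    eff = default_effects(design)
    # the coupled taxon must exist and carry a disease effect
    assert eff.cytokine_coupling["IL-6"].taxon in eff.disease_taxa
    # recovery map covers exactly the infected arms
    assert set(eff.recovery) == {
        "Infection", "Infection+Nisin", "Infection+L.lactis", "Infection+NonNisinL.lactis"
    }
    assert eff.recovery["Infection"] == 0.0
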