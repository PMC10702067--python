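"""Synthetic crossbreeding-design generator."""

import numpy as np
import pandas as pd
import pytest

from crosslay.heterosis import percent_heterosis, reciprocal_difference
from crosslay.simulate import (
    LayingProcessParams,
    MatingDesign,
    TraitGeneticParams,
    measurements_from_traits,
    simulate_breeding_values,
    simulate_laying_records,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_rack_assignment,
)

TINY = MatingDesign(
    n_sires_per_line=2,
    n_dams_per_sire_cross=2,
    offspring_per_group={"YY": 4, "WW": 4, "WY": 4, "YW": 4},
    base_generations=1,
    n_base_females_per_line=6,
)


class TestPedigreeSimulation:
    def test_tiny_design_structure(self):
        ped = simulate_pedigree(TINY, seed=0)
        tab = ped.table
        off = tab[tab.group != "base"]
        assert sorted(off.group.unique()) == ["WW", "WY", "YW", "YY"]
        # sire line of every offspring matches the group's first letter
        sire_line = off["sire"].str[0]
        assert (sire_line == off["group"].str[0]).all()
        dam_line = off["dam"].str[0]
        assert (dam_line == off["group"].str[1]).all()

    def test_sires_shared_between_pure_and_cross(self):
        ped = simulate_pedigree(TINY, seed=0)
        tab = ped.table
        pure = set(tab.loc[tab.group == "YY", "sire"])
        cross = set(tab.loc[tab.group == "YW", "sire"])
        assert pure == cross

    def test_study_scale_group_counts(self):
        ped = simulate_pedigree(MatingDesign(), seed=1)
        counts = ped.table.groupby("group").size()
        assert counts["YY"] == 315
        assert counts["WW"] == 271
        assert counts["WY"] == 315
        assert counts["YW"] == 359

    def test_deterministic_given_seed(self):
        a = simulate_pedigree(TINY, seed=3).table
        b = simulate_pedigree(TINY, seed=3).table
        assert a.equals(b)

    def test_nonpositive_counts_rejected(self):
        bad = MatingDesign(n_sires_per_line=0)
        with pytest.raises(ValueError, match="positive"):
            simulate_pedigree(bad, seed=0)


class TestBreedingValues:
    def test_zero_variance_gives_zeros(self):
        ped = simulate_pedigree(TINY, seed=0)
        params = TraitGeneticParams("T", {"W": 1, "Y": 2}, sigma_a2=0.0)
        bv = simulate_breeding_values(ped, params, seed=1)
        assert (bv == 0).all()

    def test_full_sib_covariance(self):
        """Covariance of full-sib breeding values converges to sigma_a2 / 2."""
        import pandas as pd

        from crosslay.pedigree import Pedigree

        n_fam, sa2 = 8000, 2.0
        rows = []
        for i in range(n_fam):
            rows += [
                {"animal": f"s{i}", "sire": "", "dam": ""},
                {"animal": f"d{i}", "sire": "", "dam": ""},
                {"animal": f"a{i}", "sire": f"s{i}", "dam": f"d{i}"},
                {"animal": f"b{i}", "sire": f"s{i}", "dam": f"d{i}"},
            ]
        ped = Pedigree(pd.DataFrame(rows))
        params = TraitGeneticParams("T", {"W": 0, "Y": 0}, sigma_a2=sa2)
        bv = simulate_breeding_values(ped, params, seed=9)
        x = bv[[f"a{i}" for i in range(n_fam)]].to_numpy()
        y = bv[[f"b{i}" for i in range(n_fam)]].to_numpy()
        cov = np.mean(x * y)  # means are 0 by construction
        se = np.std(x * y, ddof=1) / np.sqrt(n_fam)
        assert abs(cov - 0.5 * sa2) < 3 * se

    def test_mendelian_sampling_variance_noninbred(self):
        """Within-family deviation variance is sigma_a2 / 2 for F = 0."""
        import pandas as pd

        from crosslay.pedigree import Pedigree

        n, sa2 = 20000, 4.0
        rows = [
            {"animal": "s", "sire": "", "dam": ""},
            {"animal": "d", "sire": "", "dam": ""},
        ] + [{"animal": f"o{i}", "sire": "s", "dam": "d"} for i in range(n)]
        ped = Pedigree(pd.DataFrame(rows))
        params = TraitGeneticParams("T", {"W": 0, "Y": 0}, sigma_a2=sa2)
        bv = simulate_breeding_values(ped, params, seed=2)
        dev = bv.iloc[2:] - 0.5 * (bv["s"] + bv["d"])
        assert np.var(dev) == pytest.approx(sa2 / 2, rel=0.05)


class TestPhenotypes:
    def test_noise_free_crossbreds_equal_parental_mean(self):
        ped = simulate_pedigree(TINY, seed=0)
        racks = simulate_rack_assignment(ped, 4, seed=0)
        params = TraitGeneticParams("T", {"W": 60.0, "Y": 50.0})
        bv = simulate_breeding_values(ped, params, seed=1)
        phen = simulate_phenotypes(ped, bv, params, racks, seed=2)
        cross = phen[phen.group.isin(["WY", "YW"])]
        assert np.allclose(cross["value"], 55.0)

    def test_programmed_heterosis_closed_loop(self):
        """5% average heterosis + 2% reciprocal gap reproduce exactly."""
        ped = simulate_pedigree(TINY, seed=0)
        racks = simulate_rack_assignment(ped, 4, seed=0)
        pmean = 55.0
        params = TraitGeneticParams(
            "T",
            {"W": 60.0, "Y": 50.0},
            heterosis_shift=0.05 * pmean,
            reciprocal_shift=0.02 * pmean,
        )
        bv = simulate_breeding_values(ped, params, seed=1)
        phen = simulate_phenotypes(ped, bv, params, racks, seed=2)
        gm = phen.groupby("group")["value"].mean()
        h_wy = percent_heterosis(gm["WW"], gm["YY"], gm["WY"])
        h_yw = percent_heterosis(gm["WW"], gm["YY"], gm["YW"])
        assert 0.5 * (h_wy + h_yw) == pytest.approx(5.0, abs=1e-10)
        assert reciprocal_difference(gm["WW"], gm["YY"], gm["WY"], gm["YW"]) == (
            pytest.approx(2.0, abs=1e-10)
        )

    def test_within_group_variance_composition(self):
        """Empirical phenotypic variance matches sigma_a2+sigma_e2+rack var."""
        design = MatingDesign(
            n_sires_per_line=30,
            n_dams_per_sire_cross=5,
            offspring_per_group={"YY": 3000, "WW": 3000, "WY": 100, "YW": 100},
            base_generations=1,
        )
        ped = simulate_pedigree(design, seed=5)
        racks = simulate_rack_assignment(ped, 24, seed=5)
        params = TraitGeneticParams(
            "T", {"W": 0.0, "Y": 0.0}, sigma_a2=4.0, sigma_e2=6.0, rack_sd=1.0
        )
        bv = simulate_breeding_values(ped, params, seed=6)
        phen = simulate_phenotypes(ped, bv, params, racks, seed=7)
        v = phen.loc[phen.group == "WW", "value"].var()
        # family structure inflates the naive MC tolerance; 10% is ample
        assert v == pytest.approx(4.0 + 6.0 + 1.0, rel=0.10)

    def test_missing_rack_raises_with_animal_name(self):
        ped = simulate_pedigree(TINY, seed=0)
        racks = simulate_rack_assignment(ped, 4, seed=0).iloc[:-1]
        params = TraitGeneticParams("T", {"W": 1.0, "Y": 1.0})
        bv = simulate_breeding_values(ped, params, seed=1)
        with pytest.raises(ValueError, match="rack"):
            simulate_phenotypes(ped, bv, params, racks, seed=2)


class TestLayingProcess:
    def test_always_lay_single_clutch(self):
        ped = simulate_pedigree(TINY, seed=0)
        params = LayingProcessParams(
            p_lay_lay=(1.0, 1.0), p_pause_lay=(1.0, 1.0),
            end_day=250, nonlayer_fraction=0.0, afe_sd=0.0,
        )
        rec = simulate_laying_records(ped, params, seed=1).records
        for _, sub in rec.groupby("hen"):
            days = np.sort(sub["day"].to_numpy())
            assert np.all(np.diff(days) == 1)  # one unbroken clutch

    def test_never_relay_gives_unit_clutches(self):
        ped = simulate_pedigree(TINY, seed=0)
        params = LayingProcessParams(
            p_lay_lay=(0.0, 0.0), p_pause_lay=(0.5, 0.5),
            end_day=250, nonlayer_fraction=0.0,
        )
        rec = simulate_laying_records(ped, params, seed=1).records
        for _, sub in rec.groupby("hen"):
            days = np.sort(sub["day"].to_numpy())
            assert np.all(np.diff(days) >= 2)  # average clutch length 1

    def test_calibrated_defaults_weekly_rate(self):
        """Cohort mean eggs/week over weeks 24-43 is close to 5.8."""
        ped = simulate_pedigree(MatingDesign(), seed=2)
        rec = simulate_laying_records(ped, LayingProcessParams(), seed=3).records
        en43 = rec[rec.day <= 43 * 7].groupby("hen").size()
        en23 = rec[rec.day <= 23 * 7].groupby("hen").size()
        rate = (en43 - en23.reindex(en43.index).fillna(0)) / (43 - 23)
        assert abs(rate.mean() - 5.8) < 0.5

    def test_nonlayer_fraction(self):
        ped = simulate_pedigree(MatingDesign(), seed=2)
        lay = simulate_laying_records(
            ped, LayingProcessParams(nonlayer_fraction=0.1), seed=4
        )
        frac = 1.0 - lay.records["hen"].nunique() / len(lay.hens)
        assert frac == pytest.approx(0.1, abs=0.03)

    def test_timestamps_on_grid_inside_window(self):
        ped = simulate_pedigree(TINY, seed=0)
        rec = simulate_laying_records(ped, LayingProcessParams(), seed=5).records
        t = rec["time_h"].dropna()
        assert ((t * 2) == (t * 2).round()).all()
        assert t.min() >= 7.0 and t.max() <= 19.0


class TestMeasurements:
    def test_inversion_roundtrip(self):
        tab = pd.DataFrame(
            [
                {"hen": "h1", "group": "WW", "rack": 1, "trait": "FEWt",
                 "age": "first", "rep": 0, "value": 43.0},
                {"hen": "h1", "group": "WW", "rack": 1, "trait": "EWt40",
                 "age": "40", "rep": 0, "value": 58.0},
                {"hen": "h1", "group": "WW", "rack": 1, "trait": "ESI40",
                 "age": "40", "rep": 0, "value": 76.0},
                {"hen": "h1", "group": "WW", "rack": 1, "trait": "YR40",
                 "age": "40", "rep": 0, "value": 30.0},
            ]
        )
        meas = measurements_from_traits(tab, seed=0)
        firsts = meas[meas.age_weeks == "first"]
        assert len(firsts) == 3 and np.allclose(firsts.egg_weight, 43.0)
        aged = meas[meas.age_weeks == "40"].iloc[0]
        assert 100 * aged.width / aged.length == pytest.approx(76.0)
        assert 100 * aged.yolk_weight / aged.egg_weight == pytest.approx(30.0)
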