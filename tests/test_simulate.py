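"""Synthetic designs, stands, point clouds and generated AWP."""

import numpy as np
import pandas as pd
import pytest

from canopyfill import canopy, productivity, voxel
from canopyfill.pointcloud import clip_buffer, split_subplots
from canopyfill.simulate import (
    DEFAULT_SPECIES,
    GUILDS,
    SimulationParams,
    generate_awp,
    make_design,
    sample_point_cloud,
    simulate_csfi_table,
    simulate_stand,
)


class TestMakeDesign:
    def test_default_design_has_22_plots_88_subplots(self):
        design = make_design(seed=0)
        assert design.n_plots == 22
        assert design.n_subplots == 88
        types = pd.Series([p.plot_type for p in design.plots]).value_counts()
        assert types["mono"] == 10 and types["mix3"] == 6 and types["mix6"] == 6

    def test_no_exclusions_gives_24_plots(self):
        design = make_design(exclude=(), seed=0)
        assert design.n_plots == 24
        assert design.n_subplots == 96

    def test_mix3_draws_one_species_per_guild(self):
        design = make_design(seed=11)
        for plot in design.plots:
            if plot.plot_type == "mix3":
                guilds = sorted(DEFAULT_SPECIES[s].guild for s in plot.composition)
                assert guilds == sorted(GUILDS)

    def test_mix6_contains_all_species(self):
        design = make_design(seed=0)
        for plot in design.plots:
            if plot.plot_type == "mix6":
                assert set(plot.composition) == set(DEFAULT_SPECIES)

    def test_deterministic_given_seed(self):
        assert make_design(seed=42) == make_design(seed=42)

    def test_different_seeds_can_differ(self):
        a = make_design(seed=1)
        b = make_design(seed=2)
        mix3_a = [p.composition for p in a.plots if p.plot_type == "mix3"]
        mix3_b = [p.composition for p in b.plots if p.plot_type == "mix3"]
        assert mix3_a != mix3_b


class TestSimulateStand:
    def test_225_planting_positions_per_plot(self):
        design = make_design(1, 0, 0, exclude=(), seed=0)
        records, _ = simulate_stand(design, seed=0)
        assert (records.groupby("plot_id").size() == 225).all()

    def test_zero_mortality_keeps_all_trees(self):
        design = make_design(1, 1, 1, seed=0)
        records, crowns = simulate_stand(design, SimulationParams(mortality=0.0), seed=1)
        assert records["alive_t2"].all()
        assert len(crowns) == len(records)

    def test_zero_growth_gives_zero_awp(self):
        """Species with zero growth rates close the loop: AWP from the
        productivity module is exactly zero."""
        frozen = {code: tr.__class__(**{**tr.__dict__, "h_growth": 0.0,
                                        "h_growth_sd": 0.0, "d_growth": 0.0,
                                        "d_growth_sd": 0.0})
                  for code, tr in DEFAULT_SPECIES.items()}
        design = make_design(1, 1, 1, seed=0)
        records, _ = simulate_stand(design, SimulationParams(mortality=0.0),
                                    seed=2, species=frozen)
        table = productivity.awp_table(records)
        assert (table["awp_cm3_yr"] == 0.0).all()

    def test_inventory_passes_validation(self, tmp_path):
        design = make_design(1, 1, 1, seed=0)
        records, _ = simulate_stand(design, seed=3)
        path = tmp_path / "inv.csv"
        records.to_csv(path, index=False)
        assert len(productivity.read_inventory(path)) == len(records)

    def test_mixture_types_derived_correctly(self):
        design = make_design(1, 1, 1, seed=0)
        records, _ = simulate_stand(design, seed=4)
        table = productivity.awp_table(records)
        merged = table.merge(
            pd.DataFrame([{"plot_id": p.plot_id, "type": p.plot_type}
                          for p in design.plots]), on="plot_id")
        assert (merged.loc[merged.type == "mono", "mixture_type"] == "monoculture").all()
        assert (merged.loc[merged.type != "mono", "mixture_type"] == "mixture").all()

    def test_deterministic_given_seed(self):
        design = make_design(1, 1, 1, seed=0)
        r1, c1 = simulate_stand(design, seed=9)
        r2, c2 = simulate_stand(design, seed=9)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(c1, c2)


class TestSamplePointCloud:
    def crowns_one_tree(self, semi_h=1.5, semi_v=2.0, density=100.0, base=4.0):
        return pd.DataFrame([{
            "tree_id": "t", "plot_id": "P01", "subplot_id": "SW",
            "species": "X", "x": 20.0, "y": 20.0,
            "z_centre": base + semi_v, "semi_v": semi_v, "semi_h": semi_h,
            "crown_base": base, "height": base + 2 * semi_v,
            "density": density,
        }])

    def test_poisson_count_matches_crown_volume(self):
        crowns = self.crowns_one_tree(semi_h=1.0, semi_v=2.387324, density=100.0)
        vol = 4 / 3 * np.pi * 1.0 * 1.0 * 2.387324  # ~10 m^3
        mean = vol * 100.0
        counts = [len(sample_point_cloud(crowns, seed=s, stem_points_per_m=0)["P01"])
                  for s in range(30)]
        grand = np.mean(counts)
        assert abs(grand - mean) < 4 * np.sqrt(mean / 30)

    def test_crown_points_inside_ellipsoid(self):
        crowns = self.crowns_one_tree()
        cloud = sample_point_cloud(crowns, seed=5, stem_points_per_m=0)["P01"]
        rel = (cloud.xyz - np.array([20.0, 20.0, 6.0])) / np.array([1.5, 1.5, 2.0])
        assert np.all((rel ** 2).sum(axis=1) <= 1.0 + 1e-12)

    def test_stem_points_below_crown_base(self):
        crowns = self.crowns_one_tree(density=0.0)
        cloud = sample_point_cloud(crowns, seed=1, stem_points_per_m=10)["P01"]
        assert len(cloud) == 40
        assert cloud.xyz[:, 2].max() < 4.0
        np.testing.assert_allclose(cloud.xyz[:, :2], [[20.0, 20.0]] * 40)

    def test_crown_base_fraction_raises_detected_lgb(self):
        """Raising every species' crown-base fraction must raise the
        lowest-green-branch height the pipeline detects (end to end)."""
        design = make_design(1, 0, 0, exclude=[c for c in DEFAULT_SPECIES if c != "LUSE"],
                             seed=0)
        lgbs = []
        for frac in (0.2, 0.4, 0.6):
            species = {c: t.__class__(**{**t.__dict__, "crown_base_frac": frac})
                       for c, t in DEFAULT_SPECIES.items()}
            _, crowns = simulate_stand(design, SimulationParams(mortality=0.0),
                                       seed=7, species=species)
            cloud = sample_point_cloud(crowns, seed=8, density_scale=0.3,
                                       stem_points_per_m=0)[design.plots[0].plot_id]
            geom = design.geometry
            sub = split_subplots(clip_buffer(cloud, geom), geom)["SW"]
            x0, y0, x1, y1 = geom.subplot_bounds("SW")
            spec = voxel.spec_for_footprint(x1 - x0, y1 - y0, float(sub.xyz[:, 2].max()),
                                            origin=(x0, y0, 0.0))
            bounds = canopy.detect_bounds(voxel.voxelize(sub, spec))
            lgbs.append(bounds.lgb)
        assert lgbs[0] < lgbs[1] < lgbs[2]

    def test_deterministic_given_seed(self):
        crowns = self.crowns_one_tree()
        c1 = sample_point_cloud(crowns, seed=3)["P01"]
        c2 = sample_point_cloud(crowns, seed=3)["P01"]
        np.testing.assert_array_equal(c1.xyz, c2.xyz)


class TestGenerateAWP:
    def test_null_model_mean_matches_intercept(self):
        design = make_design(8, 24, 24, seed=0)  # many subplots
        tab = simulate_csfi_table(design, seed=1)
        params = SimulationParams(beta0=10.0, beta1=0.0, sigma_plot=0.0, shape=5.0)
        awp, _ = generate_awp(tab, params, seed=2)
        mean = awp["awp_cm3_yr"].mean()
        mu = np.exp(10.0)
        se = mu / np.sqrt(5.0 * len(awp))
        assert abs(mean - mu) < 4 * se

    def test_large_shape_shrinks_cv(self):
        design = make_design(seed=0)
        tab = simulate_csfi_table(design, seed=3)
        cvs = []
        for shape in (2.0, 200.0):
            params = SimulationParams(beta1=0.0, sigma_plot=0.0, shape=shape)
            awp, _ = generate_awp(tab, params, seed=4)
            y = awp["awp_cm3_yr"]
            cvs.append(y.std() / y.mean())
        assert cvs[1] < cvs[0] / 3

    def test_truth_records_parameters_and_intercepts(self):
        design = make_design(seed=0)
        tab = simulate_csfi_table(design, seed=5)
        params = SimulationParams(beta1=2.5, sigma_plot=0.4)
        _, truth = generate_awp(tab, params, seed=6)
        assert truth["beta1"] == 2.5
        assert set(truth["plot_intercepts"]) == {p.plot_id for p in design.plots}

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(shape=-1.0)
        with pytest.raises(ValueError):
            SimulationParams(mode="magic")


class TestEndToEndStructure:
    def test_mechanistic_csfi_ordering_through_pipeline(self):
        """Stands with crowns concentrated in the mid canopy reproduce
        the qualitative mean ordering mid >= main >= total >= top."""
        design = make_design(1, 2, 2, seed=5)
        _, crowns = simulate_stand(design, seed=6)
        clouds = sample_point_cloud(crowns, seed=7, density_scale=0.4)
        geom = design.geometry
        grids = {}
        for pid, cloud in clouds.items():
            for lab, sub in split_subplots(clip_buffer(cloud, geom), geom).items():
                x0, y0, x1, y1 = geom.subplot_bounds(lab)
                spec = voxel.spec_for_footprint(
                    x1 - x0, y1 - y0, float(sub.xyz[:, 2].max()), origin=(x0, y0, 0.0))
                grids[f"{pid}:{lab}"] = voxel.voxelize(sub, spec)
        tab = canopy.csfi_table(grids)
        means = tab[tab.valid].groupby("definition")["csfi"].mean()
        assert means["mid"] >= means["main"] >= means["total"] >= means["top"]

    def test_definitions_positively_correlated(self):
        design = make_design(1, 1, 1, seed=2)
        _, crowns = simulate_stand(design, seed=3)
        clouds = sample_point_cloud(crowns, seed=4, density_scale=0.3)
        geom = design.geometry
        grids = {}
        for pid, cloud in clouds.items():
            for lab, sub in split_subplots(clip_buffer(cloud, geom), geom).items():
                x0, y0, x1, y1 = geom.subplot_bounds(lab)
                spec = voxel.spec_for_footprint(
                    x1 - x0, y1 - y0, float(sub.xyz[:, 2].max()), origin=(x0, y0, 0.0))
                grids[f"{pid}:{lab}"] = voxel.voxelize(sub, spec)
        corr = canopy.definition_correlations(canopy.csfi_table(grids))
        assert corr is not None
        assert (corr.values > 0).all()
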