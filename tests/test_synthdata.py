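"""Generator contracts: determinism, composition, planted-effect calibration."""

import numpy as np
import pandas as pd
import pytest

from plaqueniche import (
    ImageConfig,
    PlantedEffect,
    PlantedEnrichment,
    SyntheticConfig,
    synthdata,
)


class TestConfigValidation:
    def test_layer_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticConfig(layer_fractions=(0.2,) * 7).validate()

    def test_too_many_states_rejected(self):
        states = {f"S{i}": "Exc" for i in range(30)}
        with pytest.raises(ValueError, match="states"):
            SyntheticConfig(n_genes=60, states_per_major_type=states).validate()

    def test_duplicate_planted_gene_rejected(self):
        cfg = SyntheticConfig(
            planted_de=[PlantedEffect("G0001", 1.0), PlantedEffect("G0001", 0.5)]
        )
        with pytest.raises(ValueError, match="twice"):
            cfg.validate()

    def test_unknown_enriched_state_rejected(self):
        cfg = SyntheticConfig(
            planted_state_enrichment=[PlantedEnrichment("Nope.1", 2.0)]
        )
        with pytest.raises(ValueError, match="unknown state"):
            cfg.validate()


class TestReference:
    def test_marker_blocks_elevated(self):
        states = {"A": "Ast", "B": "Mic", "C": "Oli"}
        cfg = SyntheticConfig(n_genes=60, states_per_major_type=states, seed=1)
        sig, nuclei = synthdata.generate_reference(cfg)
        assert sig.means.shape == (60, 3)
        for state in states:
            block = sig.marker_blocks[state]
            assert len(block) == 10
            others = [s for s in states if s != state]
            assert (
                sig.means.loc[block, state] > sig.means.loc[block, others].max(axis=1)
            ).all()

    def test_determinism(self):
        cfg = SyntheticConfig(seed=9)
        sig1, nuc1 = synthdata.generate_reference(cfg)
        sig2, nuc2 = synthdata.generate_reference(cfg)
        pd.testing.assert_frame_equal(sig1.means, sig2.means)
        np.testing.assert_array_equal(np.asarray(nuc1.X), np.asarray(nuc2.X))

    def test_no_markers_degrades_deconvolution(self):
        from plaqueniche import deconv

        cfg = SyntheticConfig(seed=2, n_sections=1, n_donors=1)
        flat = cfg.replace(marker_strength=0.0)

        def mean_r(config):
            data = synthdata.generate_dataset(config)
            adata = data.concatenated()
            est = deconv.estimate_abundance(adata, data.reference)
            true = pd.DataFrame(
                data.sections[0].obsm["true_composition"],
                index=adata.obs_names,
                columns=data.reference.states,
            )
            rs = []
            for m in data.reference.major_type.unique():
                cols = [s for s in data.reference.states
                        if data.reference.major_type[s] == m]
                tp = true[cols].div(true[cols].sum(1), axis=0)
                for s in cols:
                    rs.append(np.corrcoef(tp[s], est.proportions[s].fillna(0))[0, 1])
            return np.nanmean(rs)

        assert mean_r(cfg) > mean_r(flat) + 0.3

    def test_zero_marker_strength_signatures_equal(self):
        cfg = SyntheticConfig(seed=3, marker_strength=0.0)
        sig, _ = synthdata.generate_reference(cfg)
        spread = sig.means.max(axis=1) - sig.means.min(axis=1)
        assert float(spread.max()) == pytest.approx(0.0, abs=1e-12)


class TestSections:
    def test_determinism_and_distinct_sections(self):
        cfg = SyntheticConfig(seed=4, n_sections=2)
        d1 = synthdata.generate_dataset(cfg)
        d2 = synthdata.generate_dataset(cfg)
        np.testing.assert_array_equal(
            np.asarray(d1.sections[0].X), np.asarray(d2.sections[0].X)
        )
        assert not np.array_equal(
            np.asarray(d1.sections[0].X), np.asarray(d1.sections[1].X)
        )

    def test_composition_sums_to_one(self, default_dataset):
        for section in default_dataset.sections:
            comp = section.obsm["true_composition"]
            np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-9)

    def test_unbiased_plaque_process(self):
        cfg = SyntheticConfig(
            seed=5, deep_layer_plaque_bias=1.0, plaques_per_section=80.0
        )
        data = synthdata.generate_dataset(cfg)
        spots = pd.concat([s.obs for s in data.sections])
        edges = data.sections[0].uns["layer_edges_um"]
        y = data.plaques["y_um"].to_numpy()
        deep = ((y >= edges[3]) & (y < edges[6])).sum()
        upper = (y < edges[3]).sum()
        spots_deep = spots["true_layer"].isin(["L4", "L5", "L6"]).sum()
        spots_upper = spots["true_layer"].isin(["L1", "L2", "L3"]).sum()
        ratio = (deep / spots_deep) / (upper / spots_upper)
        assert ratio == pytest.approx(1.0, abs=0.25)

    def test_planted_effect_calibration(self):
        """Mean normalized expression doubles at d=0 vs far with +1 log2."""
        gene = "G0300"
        cfg = SyntheticConfig(
            seed=6,
            grid_rows=44,
            grid_cols=22,
            n_sections=4,
            plaques_per_section=14.0,
            planted_de=[PlantedEffect(gene, 1.0, decay_um=100.0)],
        )
        data = synthdata.generate_dataset(cfg)
        adata = data.concatenated()
        gi = list(adata.var_names).index(gene)
        counts = np.asarray(adata.X, dtype=float)
        sf = counts.sum(1) / counts.sum(1).mean()
        norm = counts[:, gi] / sf
        d = adata.obs["true_plaque_dist_um"].to_numpy()
        near = d <= 100.0  # multiplier between 2^0.37 and 2^1
        far = d >= 500.0  # multiplier <= 2^(0.0067)
        assert near.sum() >= 50 and far.sum() >= 200
        # expected ratio given the realized near-spot distances
        expected_near = np.exp2(np.exp(-d[near] / 100.0)).mean()
        ratio = norm[near].mean() / norm[far].mean()
        se = np.sqrt(
            norm[near].var() / near.sum() / norm[near].mean() ** 2
            + norm[far].var() / far.sum() / norm[far].mean() ** 2
        ) * ratio
        assert abs(ratio - expected_near) <= 3 * se + 0.05 * expected_near

    def test_control_sections_have_no_plaques(self):
        cfg = SyntheticConfig(seed=7, n_sections=2, n_control_sections=2)
        data = synthdata.generate_dataset(cfg)
        control_ids = {
            s.obs["section_id"].iloc[0]
            for s in data.sections
            if not s.obs["ad"].iloc[0]
        }
        assert len(control_ids) == 2
        assert not data.plaques["section_id"].isin(control_ids).any()

    def test_focal_enrichment_shifts_within_type_odds(self):
        cfg = SyntheticConfig(
            seed=8,
            planted_state_enrichment=[PlantedEnrichment("Ast.5", 1.5)],
        )
        data = synthdata.generate_dataset(cfg)
        null = synthdata.generate_dataset(cfg.replace(planted_state_enrichment=[]))
        states = data.reference.states
        k = states.index("Ast.5")
        ast = [i for i, s in enumerate(states)
               if data.reference.major_type[s] == "Ast"]
        shifts = []
        for sec_e, sec_0 in zip(data.sections, null.sections):
            near = sec_e.obs["true_plaque_dist_um"].to_numpy() <= 150.0
            for sec, mask in ((sec_e, near), (sec_0, near)):
                comp = sec.obsm["true_composition"][mask]
                q = comp[:, k] / comp[:, ast].sum(axis=1)
                shifts.append(np.log(q / (1 - q)).mean())
        planted = np.mean(shifts[::2]) - np.mean(shifts[1::2])
        assert planted == pytest.approx(np.log(1.5), abs=0.05)

    def test_empty_layer_band_rejected(self):
        cfg = SyntheticConfig(grid_rows=10, grid_cols=12,
                              layer_fractions=(0.94, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01))
        with pytest.raises(ValueError, match="no spots"):
            synthdata.generate_dataset(cfg)


class TestImages:
    def test_null_proximal_factor_equal_truth(self):
        icfg = ImageConfig(
            proximal_serpina3_factor=1.0, proximal_gfap_factor=1.0, seed=11
        )
        _, cells, _ = synthdata.generate_if_image(icfg)
        astro = cells[cells["is_astrocyte"]]
        prox = astro[astro["true_class"] == "proximal"]["true_serpina3"]
        dist = astro[astro["true_class"] == "distant"]["true_serpina3"]
        # same lognormal law in both groups: means agree within sampling error
        pooled_se = np.sqrt(prox.var() / len(prox) + dist.var() / len(dist))
        assert abs(prox.mean() - dist.mean()) <= 3 * pooled_se

    def test_planted_factor_in_truth_table(self):
        icfg = ImageConfig(noise_sd=0.0, intensity_cv=0.0,
                           proximal_serpina3_factor=1.10, seed=12)
        _, cells, _ = synthdata.generate_if_image(icfg)
        astro = cells[cells["is_astrocyte"]]
        prox = astro[astro["true_class"] == "proximal"]["true_serpina3"].mean()
        dist = astro[astro["true_class"] == "distant"]["true_serpina3"].mean()
        assert prox / dist == pytest.approx(1.10, abs=1e-9)

    def test_determinism(self):
        icfg = ImageConfig(seed=13)
        ch1, cells1, p1 = synthdata.generate_if_image(icfg)
        ch2, cells2, p2 = synthdata.generate_if_image(icfg)
        np.testing.assert_array_equal(ch1["GFAP"], ch2["GFAP"])
        pd.testing.assert_frame_equal(cells1, cells2)

    def test_small_image_rejected(self):
        with pytest.raises(ValueError, match="512"):
            synthdata.generate_if_image(ImageConfig(size_px=256))
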