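import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import dualmeth as dm
from dualmeth.preprocess import (
    average_technical_replicates,
    cluster_samples,
    filter_missingness,
    mask_by_detection_p,
    preprocess_arm,
    structure_profile,
)
from tests.conftest import make_annotation


def sheet_of(rows):
    return pd.DataFrame(rows, columns=["sample_id", "species", "assay", "beadchip", "replicate_group"])


class TestMasking:
    def setup_method(self):
        self.betas = pd.DataFrame(
            {"s1": [0.5, 0.5, 0.5], "s2": [0.2, 0.3, 0.4]},
            index=["a", "b", "c"],
        )

    def test_above_threshold_masked_at_threshold_kept(self):
        detp = pd.DataFrame(
            {"s1": [0.02, 0.01, 0.0], "s2": [0.0, 0.0, 0.0]}, index=["a", "b", "c"]
        )
        out = mask_by_detection_p(self.betas, detp)
        assert np.isnan(out.loc["a", "s1"])  # 0.02 exceeds 0.01
        assert out.loc["b", "s1"] == 0.5  # exactly 0.01 is retained
        assert out.loc["c", "s1"] == 0.5

    def test_zero_detp_identity(self):
        detp = self.betas * 0.0
        pd.testing.assert_frame_equal(mask_by_detection_p(self.betas, detp), self.betas)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            mask_by_detection_p(self.betas, self.betas.iloc[:2])

    def test_stricter_threshold_masks_monotonically_more(self):
        rng = np.random.default_rng(0)
        betas = pd.DataFrame(rng.uniform(0, 1, (50, 4)))
        detp = pd.DataFrame(rng.uniform(0, 0.1, (50, 4)))
        survivors = [
            filter_missingness(mask_by_detection_p(betas, detp, threshold=t)).shape[0]
            for t in (0.1, 0.05, 0.01, 0.001)
        ]
        assert all(a >= b for a, b in zip(survivors, survivors[1:]))


class TestReplicateAveraging:
    def setup_method(self):
        self.sheet = sheet_of(
            [
                ["r1a", "human", "TAB", "c1", "r1"],
                ["r1b", "human", "TAB", "c1", "r1"],
                ["r2a", "monkey", "TAB", "c1", "r2"],
                ["r2b", "monkey", "TAB", "c1", "r2"],
                ["solo", "monkey", "TAB", "c2", "solo"],
            ]
        )

    def test_pair_mean_and_missing_member(self):
        betas = pd.DataFrame(
            {
                "r1a": [0.4, 0.3],
                "r1b": [0.6, np.nan],
                "r2a": [0.1, np.nan],
                "r2b": [0.2, np.nan],
                "solo": [0.9, 0.8],
            },
            index=["p1", "p2"],
        )
        out, new_sheet = average_technical_replicates(betas, self.sheet)
        assert out.loc["p1", "r1"] == pytest.approx(0.5)
        assert out.loc["p2", "r1"] == pytest.approx(0.3)  # available member used
        assert np.isnan(out.loc["p2", "r2"])  # all-missing stays missing
        assert out.loc["p1", "solo"] == 0.9  # singleton unchanged
        assert list(new_sheet["sample_id"]) == ["r1", "r2", "solo"]

    def test_commutes_with_probe_subsetting(self):
        rng = np.random.default_rng(1)
        betas = pd.DataFrame(
            rng.uniform(0, 1, (20, 5)),
            index=[f"p{i}" for i in range(20)],
            columns=self.sheet["sample_id"],
        )
        keep = [f"p{i}" for i in range(0, 20, 3)]
        a, _ = average_technical_replicates(betas.loc[keep], self.sheet)
        b, _ = average_technical_replicates(betas, self.sheet)
        pd.testing.assert_frame_equal(a, b.loc[keep])


class TestMissingness:
    @pytest.mark.parametrize("n_missing,kept", [(0, True), (1, True), (2, False)])
    def test_at_most_one_missing_kept(self, n_missing, kept):
        row = np.full(10, 0.5)
        row[:n_missing] = np.nan
        betas = pd.DataFrame([row], index=["p"])
        assert ("p" in filter_missingness(betas).index) == kept


class TestStructureProfile:
    def _sheet(self):
        return sheet_of(
            [
                ["h1", "human", "BS", "c1", "h1"],
                ["h2", "human", "BS", "c1", "h2"],
                ["m1", "monkey", "BS", "c1", "m1"],
            ]
        )

    def test_constant_beta_gives_constant_means(self):
        ann = make_annotation(
            [
                ("a", "chr1", 1, (("g", "Body"),), "Island"),
                ("b", "chr1", 2, (), "OpenSea"),
            ]
        )
        betas = pd.DataFrame(0.5, index=["a", "b"], columns=["h1", "h2", "m1"])
        prof = structure_profile(betas, ann, self._sheet())
        assert (prof["mean_beta"] == 0.5).all()

    def test_two_body_probes_average(self):
        ann = make_annotation(
            [
                ("a", "chr1", 1, (("g", "Body"),), "OpenSea"),
                ("b", "chr1", 2, (("g", "Body"),), "OpenSea"),
            ]
        )
        betas = pd.DataFrame(
            {"h1": [0.2, 0.4], "h2": [0.2, 0.4], "m1": [0.9, 0.9]}, index=["a", "b"]
        )
        prof = structure_profile(betas, ann, self._sheet())
        human_body = prof[
            (prof.species == "human") & (prof.label == "Body")
        ]["mean_beta"].item()
        assert human_body == pytest.approx(0.3)

    def test_multi_group_probe_contributes_to_each_label(self):
        ann = make_annotation(
            [("a", "chr1", 1, (("g1", "Body"), ("g2", "TSS200")), "OpenSea")]
        )
        betas = pd.DataFrame({"h1": [0.8], "h2": [0.8], "m1": [0.1]}, index=["a"])
        prof = structure_profile(betas, ann, self._sheet())
        human = prof[prof.species == "human"].set_index("label")
        assert human.loc["Body", "mean_beta"] == pytest.approx(0.8)
        assert human.loc["TSS200", "mean_beta"] == pytest.approx(0.8)

    def test_island_ladder_on_simulated_data(self, small_dataset):
        b, sh = preprocess_arm(
            small_dataset.bs_betas,
            small_dataset.bs_detp,
            small_dataset.sheet[small_dataset.sheet.assay == "BS"],
        )
        prof = structure_profile(b, small_dataset.annotation, sh)
        human = prof[
            (prof.species == "human") & (prof.label_type == "island")
        ].set_index("label")["mean_beta"]
        shore = (human["N_Shore"] + human["S_Shore"]) / 2
        shelf = (human["N_Shelf"] + human["S_Shelf"]) / 2
        assert human["Island"] < shore < shelf < human["OpenSea"]


class TestClustering:
    def test_duplicate_profiles_merge_first(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 50)
        betas = pd.DataFrame({"a": x, "b": x, "c": 1 - x})
        Z, _ = cluster_samples(betas)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == 0.0

    def test_species_separation_on_strong_signal(self):
        cfg = dm.SimulationConfig(
            n_probes=2000,
            effect_size=4.0,
            frac_hmc_driven=0.0,
            noise_sd=0.2,
            n_latent=0,
            confounder_sd=0.0,
            seed=9,
        )
        d = dm.simulate_dataset(cfg)
        b, sh = preprocess_arm(d.bs_betas, d.bs_detp, d.sheet[d.sheet.assay == "BS"])
        _, labels = cluster_samples(b)
        species = sh.set_index("sample_id").loc[labels.index, "species"]
        assert adjusted_rand_score(species, labels) == 1.0

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        betas = pd.DataFrame(
            rng.uniform(0, 1, (100, 5)), columns=list("abcde")
        )
        _, l1 = cluster_samples(betas)
        _, l2 = cluster_samples(betas[["d", "b", "a", "e", "c"]])
        merged = pd.concat([l1.rename("x"), l2.rename("y")], axis=1)
        assert adjusted_rand_score(merged["x"], merged["y"]) == 1.0

    def test_fewer_than_three_samples_rejected(self):
        betas = pd.DataFrame({"a": [0.1], "b": [0.2]})
        with pytest.raises(ValueError, match="3 samples"):
            cluster_samples(betas)
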