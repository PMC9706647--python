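import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chickscan import pcasel, qc, simdata
from chickscan.dataio import GenotypeDataset, TraitTable


def dataset_from_matrix(X):
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(m)],
            "chromosome": ["1"] * m,
            "position_bp": (np.arange(m) + 1) * 1000,
            "allele_a": ["A"] * m,
            "allele_b": ["C"] * m,
            "minor_allele": ["C"] * m,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "breed": ["b"] * n,
            "type": ["T"] * n,
            "sex": ["male"] * n,
        }
    )
    return GenotypeDataset(X, markers, samples)


@pytest.fixture(scope="module")
def random_model():
    rng = np.random.default_rng(21)
    X = rng.integers(0, 3, size=(12, 8)).astype(float)
    while (X.var(axis=0) == 0).any():
        X = rng.integers(0, 3, size=(12, 8)).astype(float)
    ds = dataset_from_matrix(X)
    return ds, pcasel.run_pca(ds)


class TestRunPca:
    def test_two_samples_single_component(self):
        ds = dataset_from_matrix([[0, 0, 1], [2, 2, 2]])
        model = pcasel.run_pca(ds)
        d = np.sqrt(((ds.dosage[0] - ds.dosage[1]) ** 2).sum())
        coords = model.scores[:, 0]
        assert np.abs(coords) == pytest.approx([d / 2, d / 2])
        assert model.sdev[1:] == pytest.approx(0, abs=1e-9)

    def test_rank_one_hand_matrix(self):
        ds = dataset_from_matrix([[1, 1], [0, 0], [2, 2], [0, 0]])
        model = pcasel.run_pca(ds)
        assert np.abs(model.rotation[:, 0]) == pytest.approx([1 / np.sqrt(2)] * 2)
        assert model.sdev[1] == pytest.approx(0.0, abs=1e-12)

    def test_total_variance_preserved(self, random_model):
        ds, model = random_model
        assert (model.sdev**2).sum() == pytest.approx(ds.dosage.var(axis=0, ddof=1).sum())

    def test_reconstructs_centered_matrix(self, random_model):
        ds, model = random_model
        Xc = ds.dosage - ds.dosage.mean(axis=0)
        np.testing.assert_allclose(model.scores @ model.rotation.T, Xc, atol=1e-8)

    def test_missing_and_constant_rejected(self):
        X = np.array([[0.0, 1.0], [np.nan, 2.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="complete"):
            pcasel.run_pca(dataset_from_matrix(X))
        with pytest.raises(ValueError, match="constant"):
            pcasel.run_pca(dataset_from_matrix([[0, 1], [0, 2], [0, 0]]))


class TestContributions:
    def test_sum_to_hundred(self, random_model):
        _, model = random_model
        contrib = pcasel.contributions(model, component=1)
        assert contrib["contribution"].sum() == pytest.approx(100.0, abs=1e-6)
        assert contrib["cos2"].to_numpy() == pytest.approx(contrib["varcor"].to_numpy() ** 2)

    def test_equal_loadings_split_evenly(self):
        ds = dataset_from_matrix([[1, 1], [0, 0], [2, 2], [0, 0]])
        contrib = pcasel.contributions(pcasel.run_pca(ds), component=1)
        assert contrib["contribution"].to_numpy() == pytest.approx([50.0, 50.0])

    def test_sdev_cancels_in_contribution(self, random_model):
        """Contribution reduces to 100 * loading^2 (unit-norm rotation columns)."""
        _, model = random_model
        contrib = pcasel.contributions(model, component=2)
        rot2 = model.rotation[:, 1] ** 2
        np.testing.assert_allclose(contrib["contribution"], 100 * rot2 / rot2.sum(), atol=1e-9)


class TestPcadobsSignificance:
    def make(self, pcadobs_target):
        """Build a model + records with a prescribed pcaDObs vector."""
        m = len(pcadobs_target)
        model = pcasel.PcaModel(
            sample_ids=["s"],
            marker_ids=[f"m{i}" for i in range(m)],
            scores=np.zeros((1, 1)),
            rotation=np.sign(np.asarray(pcadobs_target, dtype=float)).reshape(-1, 1),
            sdev=np.array([1.0]),
            explained=np.array([1.0]),
        )
        records = pd.DataFrame(
            {
                "marker_id": model.marker_ids,
                "contribution": np.abs(np.asarray(pcadobs_target, dtype=float)),
            }
        )
        return records, model

    def test_value_at_mean_capped_to_one(self):
        records, model = self.make([1.0, 1.0, 1.0, 3.0])
        out = pcasel.pcadobs_significance(records, model)
        # entries at |pcaDObs| <= mean have upper tail >= 0.5, doubled -> capped at 1
        assert (out.loc[:2, "p_value"] == 1.0).all()

    def test_normal_quantile_value(self):
        vals = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        records, model = self.make(list(vals))
        out = pcasel.pcadobs_significance(records, model)
        mu, sd = vals.mean(), vals.std(ddof=1)
        target = mu + 1.959964 * sd
        p_at = 2 * stats.norm.sf(target, loc=mu, scale=sd)
        assert p_at == pytest.approx(0.05, abs=1e-6)

    def test_symmetric_toy_shares_p(self):
        c = 2.0
        records, model = self.make([-c, -c, c, c])
        out = pcasel.pcadobs_significance(records, model)
        assert out["pcadobs"].mean() == pytest.approx(0.0)
        assert out["p_value"].nunique() == 1

    def test_orientation_invariance(self, random_model):
        """Flipping a component's sign flips pcaDObs but not p-values or selection."""
        _, model = random_model
        contrib = pcasel.contributions(model, component=1)
        base = pcasel.pcadobs_significance(contrib, model, component=1)
        flipped_model = pcasel.PcaModel(
            sample_ids=model.sample_ids,
            marker_ids=model.marker_ids,
            scores=model.scores * np.where(np.arange(model.n_components) == 0, -1, 1),
            rotation=model.rotation * np.where(np.arange(model.n_components) == 0, -1, 1),
            sdev=model.sdev,
            explained=model.explained,
        )
        contrib_f = pcasel.contributions(flipped_model, component=1)
        flip = pcasel.pcadobs_significance(contrib_f, flipped_model, component=1)
        np.testing.assert_allclose(flip["pcadobs"], -base["pcadobs"], atol=1e-12)
        np.testing.assert_allclose(flip["p_value"], base["p_value"], atol=1e-12)
        assert (flip["selected"] == base["selected"]).all()

    def test_degenerate_spread_rejected(self):
        records, model = self.make([1.0, 1.0])
        with pytest.raises(ValueError, match="degenerate"):
            pcasel.pcadobs_significance(records, model)


class TestMergeDistanceRegions:
    def frame(self, positions, chrom="1", pvals=None):
        m = len(positions)
        return pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(m)],
                "chromosome": [chrom] * m,
                "position_bp": positions,
                "p_value": pvals if pvals is not None else np.linspace(1e-8, 1e-6, m),
                "pcadobs": np.ones(m),
                "p_bonf": np.full(m, 0.01),
                "contribution": np.ones(m),
            }
        )

    def test_gap_within_two_mb_joins(self):
        regions = pcasel.merge_distance_regions(self.frame([1_000_000, 2_500_000]))
        assert len(regions) == 1
        assert (regions[0].start_bp, regions[0].end_bp) == (1_000_000, 2_500_000)

    def test_gap_beyond_two_mb_splits(self):
        regions = pcasel.merge_distance_regions(self.frame([1_000_000, 3_500_000]))
        assert len(regions) == 2

    def test_chaining_extends_past_window(self):
        """1, 2.8, 4.6 Mb: adjacent gaps 1.8 Mb chain into one 3.6 Mb region."""
        regions = pcasel.merge_distance_regions(self.frame([1_000_000, 2_800_000, 4_600_000]))
        assert len(regions) == 1
        assert (regions[0].start_bp, regions[0].end_bp) == (1_000_000, 4_600_000)

    def test_marker_order_invariance(self):
        f = self.frame([5_000_000, 1_000_000, 2_500_000])
        a = pcasel.merge_distance_regions(f)
        b = pcasel.merge_distance_regions(f.iloc[::-1].reset_index(drop=True))
        assert [(r.start_bp, r.end_bp) for r in a] == [(r.start_bp, r.end_bp) for r in b]


class TestPcTraitCorrelation:
    def model_with_scores(self, scores):
        n = len(scores)
        return pcasel.PcaModel(
            sample_ids=[f"s{i}" for i in range(n)],
            marker_ids=["m0", "m1"],
            scores=np.column_stack([scores, np.zeros(n)]),
            rotation=np.eye(2),
            sdev=np.array([1.0, 0.5]),
            explained=np.array([0.6, 0.4]),
        )

    def traits(self, values, n):
        return TraitTable(
            raw=pd.DataFrame({"body_weight_kg": values},
                             index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
        )

    def test_monotone_transform_gives_rho_one(self):
        scores = np.linspace(-2, 2, 20)
        tt = self.traits(list(np.exp(scores)), 20)
        out = pcasel.pc_trait_correlation(self.model_with_scores(scores), 1, tt)
        assert out.loc[0, "spearman_rho"] == pytest.approx(1.0)

    def test_orientation_antisymmetry(self):
        rng = np.random.default_rng(31)
        scores = rng.normal(size=30)
        tt = self.traits(list(rng.normal(size=30) + scores), 30)
        a = pcasel.pc_trait_correlation(self.model_with_scores(scores), 1, tt)
        b = pcasel.pc_trait_correlation(self.model_with_scores(-scores), 1, tt)
        assert b.loc[0, "spearman_rho"] == pytest.approx(-a.loc[0, "spearman_rho"])

    def test_independent_trait_low_rho(self):
        """Null traits at n=201: |rho| < 0.2 in >= 95% of 500 replicates."""
        rng = np.random.default_rng(32)
        scores = rng.normal(size=201)
        model = self.model_with_scores(scores)
        small = 0
        for _ in range(500):
            tt = self.traits(list(rng.normal(size=201)), 201)
            out = pcasel.pc_trait_correlation(model, 1, tt)
            small += abs(out.loc[0, "spearman_rho"]) < 0.2
        assert small >= 475

    def test_constant_trait_reported_missing(self):
        tt = self.traits([1.0] * 10, 10)
        out = pcasel.pc_trait_correlation(self.model_with_scores(np.arange(10.0)), 1, tt)
        assert np.isnan(out.loc[0, "spearman_rho"])


class TestTypeSeparationAndSelection:
    def test_pc1_separates_types_and_selects_planted_loci(self):
        """Differentiated loci (0.9 vs 0.1) drive PC1: types separate and planted
        loci are recovered by selected regions with few null selections."""
        sens_list, null_rates = [], []
        for seed in range(3):
            cfg = simdata.default_panel_config(seed, n_markers=1500)
            cfg.missing_rate = 0.0
            ds, _, _ = simdata.simulate(cfg)
            filtered, _ = qc.filter_markers(ds)
            masked, _ = qc.mask_small_genotype_classes(filtered)
            complete, _ = qc.complete_case_markers(masked)
            model = pcasel.run_pca(complete)
            game = (complete.samples["type"] == "Game").to_numpy()
            s = model.scores[:, 0]
            assert max(s[game].min(), s[~game].min()) > min(s[game].max(), s[~game].max()) or \
                (s[game].max() < s[~game].min() or s[~game].max() < s[game].min())
            contrib = pcasel.pcadobs_significance(pcasel.contributions(model), model)
            contrib["chromosome"] = complete.markers["chromosome"].to_numpy()
            contrib["position_bp"] = complete.markers["position_bp"].to_numpy()
            regions = pcasel.merge_distance_regions(contrib[contrib["selected"]])
            planted = ds.markers.loc[[d.marker_index for d in cfg.differentiated_loci]]
            hits = sum(
                any(r.chromosome == row.chromosome and r.start_bp <= row.position_bp <= r.end_bp
                    for r in regions)
                for row in planted.itertuples()
            )
            sens_list.append(hits / len(planted))
            planted_ids = set(planted["marker_id"])
            nulls = contrib[~contrib["marker_id"].isin(planted_ids)]
            null_rates.append(nulls["selected"].mean())
        assert np.mean(sens_list) >= 0.8
        assert max(null_rates) <= 0.05
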