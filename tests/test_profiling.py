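"""Z'-gated feature selection, PCA phenotype space, classification."""

import numpy as np
import pandas as pd
import pytest

import cystscreen as cs
from cystscreen.profiling import PC_NAMES, ProfilingParams


def control_table(features: dict, roles):
    n = len(roles)
    df = pd.DataFrame({"well_id": [f"W{i:03d}" for i in range(n)],
                       "plate": "P1", "treatment": "ctrl",
                       "concentration_um": 0.0, "role": roles,
                       "stimulated": True})
    for name, vals in features.items():
        df[name] = vals
    return df


class TestFeatureGate:
    def _two_group_table(self, rng, n=8, informative=3, noise=5, delta=6.0):
        roles = ["stimulated"] * n + ["reference_inhibitor"] * n
        feats = {}
        for i in range(informative):
            feats[f"inf_{i}"] = np.concatenate([
                rng.normal(delta, 1.0, n), rng.normal(0.0, 1.0, n)])
        for i in range(noise):
            feats[f"noise_{i}"] = rng.normal(0.0, 1.0, 2 * n)
        return control_table(feats, roles)

    def test_identical_feature_excluded(self):
        rng = np.random.default_rng(0)
        df = self._two_group_table(rng)
        df["flat"] = 1.0
        selected, ranking = cs.rank_features_by_zprime(df)
        assert "flat" not in selected
        assert "flat" not in set(ranking["feature"])

    def test_perfect_separator_ranked_first(self):
        rng = np.random.default_rng(1)
        df = self._two_group_table(rng)
        df["perfect"] = np.where(df["role"] == "stimulated", 100.0, 0.0) \
            + rng.normal(0, 1e-6, len(df))
        selected, _ = cs.rank_features_by_zprime(df)
        assert selected[0] == "perfect"

    def test_informative_features_selected(self):
        rng = np.random.default_rng(2)
        selected, _ = cs.rank_features_by_zprime(self._two_group_table(rng))
        assert {"inf_0", "inf_1", "inf_2"} <= set(selected)

    def test_raising_cutoff_never_adds_features(self):
        rng = np.random.default_rng(3)
        df = self._two_group_table(rng)
        prev = None
        for cutoff in (-2.0, -1.0, 0.0, 0.5):
            sel, _ = cs.rank_features_by_zprime(
                df, ProfilingParams(zprime_cutoff=cutoff))
            if prev is not None:
                assert set(sel) <= prev
            prev = set(sel)


class TestPhenotypeSpace:
    @staticmethod
    def _iso_table(n=2000, k=3, seed=0):
        rng = np.random.default_rng(seed)
        feats = {f"f{i}": rng.normal(size=n) for i in range(k)}
        roles = ["unstimulated"] * (n // 2) + ["stimulated"] * (n - n // 2)
        return control_table(feats, roles)

    def test_rank_deficient_data_explained_by_two_components(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=50), rng.normal(size=50)
        df = control_table({"f0": a, "f1": b, "f2": 2 * a - 3 * b + 1},
                           ["unstimulated"] * 25 + ["stimulated"] * 25)
        space = cs.fit_phenotype_space(df, ["f0", "f1", "f2"])
        ev = space.explained_variance_fraction
        assert ev[0] + ev[1] == pytest.approx(1.0, abs=1e-9)
        assert ev[2] == pytest.approx(0.0, abs=1e-9)

    def test_duplication_invariance(self):
        df = self._iso_table(n=100)
        space1 = cs.fit_phenotype_space(df, ["f0", "f1", "f2"])
        space2 = cs.fit_phenotype_space(pd.concat([df, df], ignore_index=True),
                                        ["f0", "f1", "f2"])
        np.testing.assert_allclose(space1.loadings, space2.loadings, atol=1e-9)
        np.testing.assert_allclose(space1.explained_variance_fraction,
                                   space2.explained_variance_fraction,
                                   atol=1e-9)

    def test_isotropic_data_splits_variance_evenly(self):
        space = cs.fit_phenotype_space(self._iso_table(), ["f0", "f1", "f2"])
        np.testing.assert_allclose(space.explained_variance_fraction,
                                   [1 / 3] * 3, atol=0.05)

    def test_explained_fractions_non_increasing_and_bounded(self):
        space = cs.fit_phenotype_space(self._iso_table(n=200, seed=5),
                                       ["f0", "f1", "f2"])
        ev = space.explained_variance_fraction
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() <= 1.0 + 1e-9

    def test_too_few_features_raises(self):
        with pytest.raises(ValueError):
            cs.fit_phenotype_space(self._iso_table(n=20), ["f0", "f1"])


class TestProjection:
    def test_mean_well_projects_to_origin(self):
        df = TestPhenotypeSpace._iso_table(n=60, seed=6)
        space = cs.fit_phenotype_space(df, ["f0", "f1", "f2"])
        mean_well = df.iloc[[0]].copy()
        for f in ("f0", "f1", "f2"):
            mean_well[f] = df[f].mean()
        scores = cs.project(space, mean_well)
        np.testing.assert_allclose(scores[list(PC_NAMES)].to_numpy(), 0.0,
                                   atol=1e-9)

    def test_score_variance_matches_explained_fractions(self):
        df = TestPhenotypeSpace._iso_table(n=150, seed=7)
        space = cs.fit_phenotype_space(df, ["f0", "f1", "f2"])
        scores = cs.project(space, df)[list(PC_NAMES)].to_numpy()
        var = scores.var(axis=0, ddof=0)
        np.testing.assert_allclose(var / var.sum() * space
                                   .explained_variance_fraction.sum(),
                                   space.explained_variance_fraction,
                                   atol=1e-9)

    def test_affine_rescaled_features_give_identical_scores(self):
        df = TestPhenotypeSpace._iso_table(n=80, seed=8)
        space1 = cs.fit_phenotype_space(df, ["f0", "f1", "f2"])
        df2 = df.copy()
        df2["f0"] = 10.0 * df2["f0"] - 4.0
        df2["f2"] = 0.5 * df2["f2"] + 100.0
        space2 = cs.fit_phenotype_space(df2, ["f0", "f1", "f2"])
        s1 = cs.project(space1, df)[list(PC_NAMES)].to_numpy()
        s2 = cs.project(space2, df2)[list(PC_NAMES)].to_numpy()
        np.testing.assert_allclose(s1, s2, atol=1e-8)

    def test_missing_feature_flags_well(self):
        df = TestPhenotypeSpace._iso_table(n=40, seed=9)
        space = cs.fit_phenotype_space(df, ["f0", "f1", "f2"])
        df.loc[0, "f1"] = np.nan
        scores = cs.project(space, df)
        assert not scores.loc[0, "projected"]
        assert scores.loc[0, "PC0"] != scores.loc[0, "PC0"]  # NaN
        assert scores["projected"].iloc[1:].all()

    def test_control_wells_project_near_their_centroids(self, mini_analysis):
        # on the simulated screen, stimulated controls sit nearer the
        # stimulated centroid than the unstimulated one
        labels = mini_analysis.labels
        inert = labels[(labels["treatment"] == "inert")]
        assert (inert["dist_stimulated"] < inert["dist_unstimulated"]).all()


class TestClassification:
    def test_fixture_truth_recovered(self, mini_analysis):
        labels = mini_analysis.labels.set_index(["treatment",
                                                 "concentration_um"])
        assert labels.loc[("active", 1.0), "label"] == "restored"
        assert labels.loc[("inert", 1.0), "label"] == "unchanged"
        assert labels.loc[("toxicant", 1.0), "label"] == "novel"

    def test_low_nuclei_forces_novel_label(self, mini_analysis):
        labels = mini_analysis.labels
        tox = labels[labels["treatment"] == "toxicant"].iloc[-1]
        feats = mini_analysis.features
        unstim_nuc = feats[feats["role"] == "unstimulated"]["nuclei_count"] \
            .median()
        assert tox["mean_nuclei_count"] < 0.5 * unstim_nuc
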