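from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from barfit.cofitness import (
    COMPARISONS,
    binom_test_two_sided,
    build_profiles,
    comparison_covariates,
    enrichment,
    glm_select,
    pam_cluster,
    split_by_direction,
)
from barfit.errors import ParameterError, ValidationError


def profile_frame(data, n=None):
    arr = np.asarray(data, dtype=float)
    idx = [f"S{i:04d}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, columns=list(COMPARISONS), index=idx)


def brute_force_pam_cost(X, k):
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    return min(D[:, list(p)].min(axis=1).sum()
               for p in combinations(range(X.shape[0]), k))


class TestBuildProfiles:
    def contrast(self, strains, values):
        return pd.DataFrame({"log2fc": values}, index=strains)

    def test_complete_strain_kept_partial_dropped(self):
        contrasts = {c: self.contrast(["s1", "s2"], [0.1, 0.2]) for c in COMPARISONS}
        contrasts["LE_Nlim36"] = self.contrast(["s1"], [0.1])  # s2 present in 7/8
        profiles, dropped = build_profiles(contrasts)
        assert list(profiles.index) == ["s1"]
        assert dropped == 1

    def test_column_order_canonical_regardless_of_input_order(self):
        contrasts = {c: self.contrast(["s1"], [i * 0.1]) for i, c in enumerate(COMPARISONS)}
        shuffled = dict(reversed(list(contrasts.items())))
        p1, _ = build_profiles(contrasts)
        p2, _ = build_profiles(shuffled)
        assert list(p1.columns) == list(COMPARISONS)
        pd.testing.assert_frame_equal(p1, p2)

    def test_missing_comparison_rejected(self):
        contrasts = {c: self.contrast(["s1"], [0.0]) for c in COMPARISONS[:-1]}
        with pytest.raises(ValidationError, match="missing"):
            build_profiles(contrasts)


class TestGlmSelect:
    def test_covariate_coding(self):
        cov = comparison_covariates(COMPARISONS)
        assert cov.loc["BP_Clim30"].tolist() == [0, 0, 0]
        assert cov.loc["LE_Nlim36"].tolist() == [1, 1, 1]

    def test_zero_profile_not_retained(self):
        sel = glm_select(profile_frame(np.zeros((1, 8))))
        assert not sel["retained"].iloc[0]

    def test_exact_temperature_contrast(self):
        temp = comparison_covariates(COMPARISONS)["temperature"].to_numpy()
        profiles = profile_frame((2.0 * temp - 1.0)[None, :])  # +1 at 36°, −1 at 30°
        sel = glm_select(profiles)
        assert sel["coef_temperature"].iloc[0] == pytest.approx(2.0)
        assert sel["retained"].iloc[0]

    def test_selection_rates_with_planted_effect(self):
        r = np.random.default_rng(1)
        temp = comparison_covariates(COMPARISONS)["temperature"].to_numpy()
        signal = r.normal(0, 0.3, (200, 8)) + 1.0 * temp
        noise = r.normal(0, 0.3, (200, 8))
        sel = glm_select(profile_frame(np.vstack([signal, noise])))
        assert sel["retained"][:200].mean() >= 0.90
        assert sel["retained"][200:].mean() <= 0.15

    def test_retained_set_invariant_to_column_order(self):
        r = np.random.default_rng(3)
        profiles = profile_frame(r.normal(0, 0.5, (50, 8)))
        sel1 = glm_select(profiles)
        shuffled = profiles[list(reversed(profiles.columns))]
        sel2 = glm_select(shuffled)
        pd.testing.assert_series_equal(sel1["retained"], sel2["retained"])


class TestPam:
    def test_two_blobs_recovered(self):
        r = np.random.default_rng(0)
        X = np.vstack([r.normal(0, 0.1, (10, 8)), r.normal(3, 0.1, (12, 8))])
        profiles = profile_frame(X)
        sol = pam_cluster(profiles, k=2)
        labels = sol.assignment.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_small_fixtures_match_brute_force(self):
        """Structured seeded fixtures ≤8 points: SWAP reaches the optimum."""
        r = np.random.default_rng(0)
        for _ in range(15):
            n = int(r.integers(4, 9))
            centers = r.normal(0, 2.5, (2, 8))
            X = centers[r.integers(0, 2, n)] + r.normal(0, 0.3, (n, 8))
            sol = pam_cluster(profile_frame(X), k=2)
            assert sol.cost == pytest.approx(brute_force_pam_cost(X, 2), abs=1e-9)

    def test_duplicating_points_preserves_cost_per_point(self):
        r = np.random.default_rng(5)
        X = np.vstack([r.normal(0, 0.2, (4, 8)), r.normal(2, 0.2, (4, 8))])
        sol1 = pam_cluster(profile_frame(X), k=2)
        sol2 = pam_cluster(profile_frame(np.vstack([X, X])), k=2)
        assert sol2.cost / 16 == pytest.approx(sol1.cost / 8, abs=1e-9)

    def test_auto_k_picks_two_for_two_planted_clusters(self):
        r = np.random.default_rng(2)
        X = np.vstack([r.normal(0, 0.1, (15, 8)), r.normal(4, 0.1, (15, 8))])
        sol = pam_cluster(profile_frame(X))
        assert sol.k == 2
        assert -1.0 <= sol.silhouette <= 1.0

    def test_medoids_are_members_and_cost_reconciles(self):
        r = np.random.default_rng(9)
        profiles = profile_frame(r.normal(0, 1, (30, 8)))
        sol = pam_cluster(profiles, k=3)
        assert set(sol.medoids) <= set(profiles.index)
        X = profiles.to_numpy()
        med_idx = [profiles.index.get_loc(m) for m in sol.medoids]
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
        assert sol.cost == pytest.approx(D[:, med_idx].min(axis=1).sum())
        # every medoid belongs to its own cluster
        for m, mi in zip(sol.medoids, med_idx):
            assert sol.assignment[m] == sol.assignment.iloc[mi]

    def test_invalid_k_rejected(self):
        profiles = profile_frame(np.eye(4, 8))
        with pytest.raises(ParameterError):
            pam_cluster(profiles, k=1)
        with pytest.raises(ParameterError):
            pam_cluster(profiles, k=5)

    def test_direction_split(self):
        X = np.vstack([np.full((3, 8), 0.5), np.full((2, 8), -0.5)])
        profiles = profile_frame(X)
        sol = pam_cluster(profiles, k=2)
        sub = split_by_direction(profiles, sol)
        assert sub.tolist() == [1, 1, 1, 2, 2]


class TestEnrichment:
    def make_solution(self, labels):
        idx = [f"S{i:04d}" for i in range(len(labels))]
        assignment = pd.Series(labels, index=idx, name="cluster")
        from barfit.cofitness import ClusterSolution
        return ClusterSolution(k=len(set(labels)), assignment=assignment,
                               medoids=[], cost=0.0, silhouette=0.0)

    def test_exact_binomial_tail_doubling(self):
        assert binom_test_two_sided(8, 10, 0.5) == pytest.approx(0.109375, abs=1e-12)

    def test_observed_equal_expected_gives_one(self):
        assert binom_test_two_sided(5, 10, 0.5) == 1.0

    def test_single_row_q_equals_p(self):
        sol = self.make_solution([1] * 10)
        classes = {f"S{i:04d}": ("SUT" if i < 8 else "tRNA") for i in range(10)}
        rows = enrichment(sol, classes, tested_classes=("SUT",))
        assert len(rows) == 1
        assert rows["q"].iloc[0] == rows["p_binomial"].iloc[0]

    def test_uniform_labels_rarely_enriched(self):
        hits = 0
        runs = 40
        for seed in range(runs):
            r = np.random.default_rng(seed)
            n = 120
            labels = r.integers(1, 5, n)  # 4 random clusters
            classes = {f"S{i:04d}": ("SUT" if r.random() < 0.3 else
                                     "CUT" if r.random() < 0.3 else "tRNA")
                       for i in range(n)}
            sol = self.make_solution(labels)
            rows = enrichment(sol, classes)
            if len(rows) and (rows["q"] < 0.05).any():
                hits += 1
        assert hits <= 0.05 * runs + 1

    def test_missing_class_label_rejected(self):
        sol = self.make_solution([1, 1, 2, 2])
        with pytest.raises(ValidationError, match="class"):
            enrichment(sol, {"S0000": "SUT"})
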