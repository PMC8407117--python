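"""Occupancy computation, competitor classes, PCA and PERMANOVA."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rhizokmer.phenotype import (MissingCellError, OccupancyMatrix,
                                 classify_competitor, mean_occupancy,
                                 normalize_for_gwas, pca_strains, permanova,
                                 plant_occupancy)


def counts_table(rows):
    return pd.DataFrame(rows, columns=["competition_id", "strain_id",
                                       "plant_id", "n_green", "n_red",
                                       "n_mixed"])


class TestPlantOccupancy:
    def test_direct_ratio(self):
        t = plant_occupancy(counts_table([("c", "s", "p1", 6, 3, 1)]))
        row = t.iloc[0]
        assert (row["f_green"], row["f_red"], row["f_mixed"]) == \
            (0.6, 0.3, 0.1)

    def test_boundary_all_green(self):
        t = plant_occupancy(counts_table([("c", "s", "p1", 10, 0, 0)]))
        assert t.iloc[0]["f_green"] == 1.0

    def test_zero_nodule_plant_excluded_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            t = plant_occupancy(counts_table(
                [("c", "s", "p1", 0, 0, 0), ("c", "s", "p2", 2, 2, 0)]))
        assert len(t) == 1
        assert "no nodules" in caplog.text

    def test_conservation(self, rng):
        rows = [("c", "s", f"p{i}", *rng.integers(0, 20, 3))
                for i in range(50)]
        t = plant_occupancy(counts_table(
            [r for r in rows if sum(r[3:]) > 0]))
        total = t["f_green"] + t["f_red"] + t["f_mixed"]
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            plant_occupancy(counts_table([("c", "s", "p1", -1, 2, 0)]))


class TestMeanOccupancy:
    TWO_PLANTS = [("c", "s", "p1", 6, 3, 1), ("c", "s", "p2", 4, 5, 1)]

    def test_single_mode_hand_value(self):
        occ = mean_occupancy(counts_table(self.TWO_PLANTS), "single")
        assert occ.values.loc["s", "c"] == pytest.approx(0.5)
        assert occ.n_plants.loc["s", "c"] == 2

    def test_single_plus_mixed_hand_value(self):
        occ = mean_occupancy(counts_table(self.TWO_PLANTS),
                             "single_plus_mixed")
        assert occ.values.loc["s", "c"] == pytest.approx(0.6)

    def test_single_replicate(self):
        occ = mean_occupancy(counts_table([("c", "s", "p1", 6, 3, 1)]))
        assert occ.values.loc["s", "c"] == pytest.approx(0.6)
        assert occ.n_plants.loc["s", "c"] == 1

    def test_all_plants_excluded_raises(self):
        with pytest.raises(MissingCellError):
            mean_occupancy(counts_table(
                [("c", "s", "p1", 0, 0, 0),
                 ("c", "t", "p1", 3, 1, 0)]))

    def test_mixed_mode_dominates_single(self, default_study):
        single = mean_occupancy(default_study["counts"], "single")
        both = mean_occupancy(default_study["counts"], "single_plus_mixed")
        assert (both.values.to_numpy() >=
                single.values.to_numpy() - 1e-12).all()


class TestNormalize:
    def test_percent_scale_table(self):
        df = pd.DataFrame({"vs_Rm1021": [93.4, 1.7]}, index=["GR4", "Rm41"])
        v = normalize_for_gwas(df, "vs_Rm1021")
        assert v["GR4"] == pytest.approx(0.934)
        assert v["Rm41"] == pytest.approx(0.017)

    def test_fraction_identity(self):
        df = pd.DataFrame({"c": [0.5, 0.25]}, index=["a", "b"])
        assert normalize_for_gwas(df, "c")["a"] == 0.5

    def test_above_100_rejected(self):
        df = pd.DataFrame({"c": [101.0]}, index=["a"])
        with pytest.raises(ValueError):
            normalize_for_gwas(df, "c")

    def test_missing_competition(self):
        df = pd.DataFrame({"c": [0.5]}, index=["a"])
        with pytest.raises(KeyError):
            normalize_for_gwas(df, "nope")


class TestClassifyCompetitor:
    @pytest.mark.parametrize("value,label", [
        (0.639, "good"),       # top competitor occupancy
        (0.60, "medium"),      # boundary belongs to medium
        (0.20, "medium"),
        (0.017, "weak"),
        (0.199999, "weak"),
        (1.0, "good"),
        (0.0, "weak"),
    ])
    def test_examples(self, value, label):
        assert classify_competitor(value) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_competitor(1.2)

    @given(st.floats(min_value=0.0, max_value=1.0,
                     allow_nan=False))
    def test_total_cover(self, v):
        assert classify_competitor(v) in {"good", "medium", "weak"}


def occupancy_matrix(values: np.ndarray) -> OccupancyMatrix:
    df = pd.DataFrame(values,
                      index=[f"S{i}" for i in range(values.shape[0])],
                      columns=[f"c{j}" for j in range(values.shape[1])])
    return OccupancyMatrix(values=df, mode="single", n_plants=df * 0 + 6)


class TestPca:
    def test_matches_direct_eigendecomposition(self, rng):
        x = rng.random((4, 3))
        occ = occupancy_matrix(x)
        scores, loadings, ev = pca_strains(occ)
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc
        eigval = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(np.sort(ev)[::-1],
                           eigval / eigval.sum(), atol=1e-10)
        # reconstruct data from scores and loadings
        assert np.allclose(scores.to_numpy() @ loadings.to_numpy().T,
                           xc, atol=1e-10)

    def test_identical_rows_degenerate(self):
        occ = occupancy_matrix(np.tile([0.2, 0.4, 0.6], (4, 1)))
        scores, _, ev = pca_strains(occ)
        assert np.allclose(scores, 0.0, atol=1e-12)
        assert np.allclose(ev, 0.0)

    def test_two_strains_single_component(self):
        occ = occupancy_matrix(np.array([[0.1, 0.4], [0.5, 0.2]]))
        _, _, ev = pca_strains(occ)
        assert ev[0] == pytest.approx(1.0)

    def test_missing_cells_rejected(self):
        values = np.array([[0.1, np.nan], [0.5, 0.2]])
        df = pd.DataFrame(values, index=["a", "b"], columns=["c0", "c1"])
        occ = OccupancyMatrix(values=df, mode="single", n_plants=df * 0)
        with pytest.raises(ValueError, match="missing"):
            pca_strains(occ)


class TestPermanova:
    def test_planted_separation_min_p(self, rng):
        # 8 + 8 strains: the chance that a label permutation reproduces
        # the planted split (and ties the observed F) is ~2/12870
        x = np.clip(np.vstack([rng.normal(0.05, 0.005, (8, 3)),
                               rng.normal(0.95, 0.005, (8, 3))]), 0, 1)
        occ = occupancy_matrix(x)
        groups = {f"S{i}": ("a" if i < 8 else "b") for i in range(16)}
        res = permanova(occ, groups, n_perm=199, seed=1)
        assert res["p"] == pytest.approx(1 / 200)

    def test_zero_permutations_p_one(self, rng):
        occ = occupancy_matrix(rng.random((6, 3)))
        groups = {f"S{i}": ("a" if i < 3 else "b") for i in range(6)}
        res = permanova(occ, groups, n_perm=0, seed=1)
        assert res["p"] == 1.0

    def test_seeded_reproducible_and_order_invariant_f(self, rng):
        x = rng.random((8, 3))
        occ = occupancy_matrix(x)
        groups = {f"S{i}": ("a" if i % 2 else "b") for i in range(8)}
        r1 = permanova(occ, groups, n_perm=99, seed=7)
        r2 = permanova(occ, groups, n_perm=99, seed=7)
        assert r1 == r2
        perm = rng.permutation(8)
        shuffled = OccupancyMatrix(values=occ.values.iloc[perm],
                                   mode="single",
                                   n_plants=occ.n_plants.iloc[perm])
        r3 = permanova(shuffled, groups, n_perm=99, seed=7)
        assert r3["F"] == pytest.approx(r1["F"])

    def test_f_matches_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova
        x = rng.random((9, 4))
        occ = occupancy_matrix(x)
        labels = ["a"] * 4 + ["b"] * 5
        groups = {f"S{i}": labels[i] for i in range(9)}
        res = permanova(occ, groups, n_perm=49, seed=0)
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        sk = sk_permanova(DistanceMatrix(d, ids=list(occ.values.index)),
                          grouping=labels, permutations=49)
        assert res["F"] == pytest.approx(sk["test statistic"], abs=1e-10)

    def test_small_group_rejected(self, rng):
        occ = occupancy_matrix(rng.random((4, 3)))
        groups = {"S0": "a", "S1": "b", "S2": "b", "S3": "b"}
        with pytest.raises(ValueError, match="groups"):
            permanova(occ, groups)

    def test_pairwise_bonferroni_present_for_three_groups(self, rng):
        occ = occupancy_matrix(rng.random((9, 3)))
        groups = {f"S{i}": "abc"[i // 3] for i in range(9)}
        res = permanova(occ, groups, n_perm=49, seed=3)
        assert len(res["pairwise"]) == 3
        for pair in res["pairwise"]:
            assert pair["p_bonferroni"] >= pair["p"]
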