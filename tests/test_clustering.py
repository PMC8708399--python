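"""ward.D linkage, gap-statistic k selection, semantic labelling,
pattern features and the repeatability audit."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from phagedyn.clustering import (
    ClusterAssignment,
    assign_groups,
    cut_tree,
    repeatability,
    select_k,
    subcluster_group3,
    ward_linkage,
)
from phagedyn.curves import CombinationKey, TimeGrid
from phagedyn.features import extract_pattern_features
from phagedyn.ordination import DistanceMatrix

from conftest import make_curve, logistic_od


def dm(points):
    return DistanceMatrix(n=len(points), d=pdist(points))


def brute_ward_d(d_square):
    """Independent ward.D agglomeration: dict-based clusters, Lance-Williams
    recomputed from scratch each step, lowest-pair-index tie break."""
    n = d_square.shape[0]
    clusters = {i: {"members": [i], "size": 1} for i in range(n)}
    dist = {(i, j): d_square[i, j] for i in range(n) for j in range(i + 1, n)}
    ids = {i: i for i in range(n)}
    merges = []
    next_id = n
    for step in range(n - 1):
        keys = sorted(dist)
        best = min(keys, key=lambda k: (dist[k], k))
        i, j = best
        h = dist[best]
        ni, nj = clusters[i]["size"], clusters[j]["size"]
        for k in list(clusters):
            if k in (i, j):
                continue
            nk = clusters[k]["size"]
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * h) / (ni + nj + nk)
            dist[(min(i, k), max(i, k))] = new
        for k in list(dist):
            if j in k:
                del dist[k]
        merges.append((sorted((ids[i], ids[j])), h, ni + nj))
        clusters[i] = {"members": clusters[i]["members"] + clusters[j]["members"],
                       "size": ni + nj}
        del clusters[j]
        ids[i] = next_id
        next_id += 1
    return merges


class TestWardLinkage:
    def test_two_tight_pairs_merge_first(self):
        pts = np.array([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0]])
        Z = ward_linkage(dm(pts))
        first_two = {tuple(sorted((int(Z[t, 0]), int(Z[t, 1])))) for t in (0, 1)}
        assert first_two == {(0, 1), (2, 3)}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_6_point(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((6, 3))
        d = dm(pts)
        Z = ward_linkage(d)
        oracle = brute_ward_d(d.square())
        for t, (pair, h, size) in enumerate(oracle):
            assert [int(Z[t, 0]), int(Z[t, 1])] == pair
            assert Z[t, 2] == pytest.approx(h, abs=1e-10)
            assert Z[t, 3] == size

    def test_n2_single_merge_at_pair_distance(self):
        d = DistanceMatrix(n=2, d=np.array([3.7]))
        Z = ward_linkage(d)
        assert Z.shape == (1, 4)
        assert (Z[0, 0], Z[0, 1], Z[0, 2], Z[0, 3]) == (0, 1, 3.7, 2)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(42)
        Z = ward_linkage(dm(rng.standard_normal((20, 4))))
        assert np.all(np.diff(Z[:, 2]) >= -1e-9)

    def test_cut_tree_partitions(self):
        pts = np.array([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0], [20, 0]])
        Z = ward_linkage(dm(pts))
        labels = cut_tree(Z, 3)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert len(set(labels)) == 3


class TestSelectK:
    def test_three_blobs_select_three(self):
        rng = np.random.default_rng(0)
        centres = np.array([[0, 0], [10, 0], [0, 10]])
        pts = np.vstack([c + 0.1 * rng.standard_normal((30, 2)) for c in centres])
        assert select_k(dm(pts), k_max=8, B=100, seed=0) == 3

    def test_single_blob_selects_one(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((60, 2))
        assert select_k(dm(pts), k_max=8, B=100, seed=0) == 1


class TestPatternFeatures:
    def test_logistic_closed_form(self, grid):
        od = logistic_od(grid, k_od=0.7, r=0.85, n0_frac=0.05)
        f = extract_pattern_features(make_curve(od, grid))
        assert f.final_od == pytest.approx(0.70, abs=0.005)
        # closed-form inversion: OD = 0.95*final at t = ln(19*0.95/0.05)/r
        final = f.final_od
        frac = 0.95 * final / 0.7
        t_true = np.log(19 * frac / (1 - frac)) / 0.85
        assert abs(f.t_stationary_h - t_true) <= 0.5

    def test_all_zero_curve(self, grid):
        f = extract_pattern_features(make_curve(0.0, grid))
        assert f.lag_h == 22.0 and f.regrowth is False

    def test_rise_fall_rise_is_regrowth(self, grid):
        t = grid.times
        od = np.interp(t, [0, 2, 5, 12, 22], [0.0, 0.3, 0.02, 0.45, 0.45])
        f = extract_pattern_features(make_curve(od, grid))
        assert f.regrowth is True

    def test_steady_slow_growth_is_not_regrowth(self, grid):
        # crosses 0.1 only after 2 h, but is steadily growing: not regrowth
        od = logistic_od(grid, k_od=0.45, r=0.45, n0_frac=0.078)
        f = extract_pattern_features(make_curve(od, grid))
        assert f.regrowth is False


class TestAssignGroups:
    def _curves(self, pattern_counts, seed=0):
        from phagedyn.simulate import NoiseModel, generate_archetype_curve
        curves, truth = [], []
        i = 0
        for pid, count in pattern_counts.items():
            for _ in range(count):
                i += 1
                c = generate_archetype_curve(pid, noise=NoiseModel(seed=1000 + i))
                curves.append(make_curve(c.od, c.grid, phage=f"P{1 + i % 6}",
                                         bact="B1", moi=1.0, rep=i))
                truth.append(pid)
        return curves, truth

    def test_pure_g1_g2_fully_recovered_at_k2(self):
        curves, truth = self._curves({"G1": 15, "G2": 15})
        assigns = assign_groups(curves, k=2)
        for a, t in zip(assigns, truth):
            assert a.group == (1 if t == "G1" else 2)

    def test_single_cluster_high_growth_is_group1(self):
        curves, _ = self._curves({"G1": 10})
        assert all(a.group == 1 for a in assign_groups(curves, k=1))

    def test_single_cluster_low_growth_errors(self):
        curves, _ = self._curves({"G2": 10})
        with pytest.raises(ValueError):
            assign_groups(curves, k=1)

    def test_labelling_invariant_to_input_order(self):
        curves, truth = self._curves({"G1": 10, "G2": 10, "G3.2": 10})
        assigns = assign_groups(curves, k=3)
        rev = assign_groups(curves[::-1], k=3)[::-1]
        assert [a.group for a in assigns] == [a.group for a in rev]


class TestSubcluster:
    def test_five_archetype_mixture_recovered(self):
        from phagedyn.simulate import NoiseModel, generate_archetype_curve
        curves, truth = [], []
        i = 0
        for pid in ("G3.1", "G3.2", "G3.3", "G3.4", "G3.5"):
            for _ in range(30):
                i += 1
                c = generate_archetype_curve(pid, noise=NoiseModel(seed=2000 + i))
                curves.append(c)
                truth.append(pid[1:])    # "3.1" ...
        labels = subcluster_group3(curves, k_sub=5, seed=3)
        acc = np.mean([l == t for l, t in zip(labels, truth)])
        assert acc >= 0.90

    def test_impaired_only_split_by_final_od(self):
        from phagedyn.simulate import NoiseModel, generate_archetype_curve
        curves, truth = [], []
        i = 0
        for pid in ("G3.4", "G3.5"):
            for _ in range(10):
                i += 1
                curves.append(generate_archetype_curve(
                    pid, noise=NoiseModel(seed=3000 + i)))
                truth.append(pid[1:])
        labels = subcluster_group3(curves, k_sub=2, seed=0)
        assert labels == truth

    def test_empty_group3_is_noop_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="phagedyn.clustering"):
            assert subcluster_group3([]) == []
        assert "no group-3" in caplog.text


class TestRepeatability:
    def _assign(self, phage, bact, moi, rep, group, sub="none"):
        return ClusterAssignment(
            CombinationKey(phage, bact, moi, rep, "treatment"), group, sub
        )

    def test_identical_replicates_no_discrepancy(self):
        assigns = [self._assign("P1", "B1", 1.0, r, 2) for r in (1, 2, 3)]
        rep = repeatability(assigns)
        assert rep.n_discrepant == 0

    def test_split_replicates_flagged(self):
        assigns = [
            self._assign("P1", "B1", 1.0, 1, 2),
            self._assign("P1", "B1", 1.0, 2, 3, "3.1"),
            self._assign("P2", "B1", 1.0, 1, 1),
            self._assign("P2", "B1", 1.0, 2, 1),
        ]
        rep = repeatability(assigns)
        flagged = rep.per_combination[rep.per_combination["discrepancy"]]
        assert len(flagged) == 1
        assert flagged.iloc[0]["phage_id"] == "P1"

    def test_matches_naive_groupby_oracle(self):
        rng = np.random.default_rng(6)
        assigns = []
        for i in range(50):
            phage = f"P{rng.integers(1, 4)}"
            bact = f"B{rng.integers(1, 3)}"
            moi = float(rng.choice([10.0, 1.0]))
            group = int(rng.integers(1, 4))
            sub = "none" if group != 3 else str(rng.choice(["3.1", "3.4"]))
            assigns.append(self._assign(phage, bact, moi, i + 1, group, sub))
        rep = repeatability(assigns)
        df = pd.DataFrame(
            {
                "c": [(a.key.phage_id, a.key.bacterium_id, a.key.moi) for a in assigns],
                "g": [a.group for a in assigns],
                "s": [a.subgroup for a in assigns],
            }
        )
        naive = df.groupby("c").agg(g=("g", "nunique"), s=("s", "nunique"))
        want = int(((naive["g"] > 1) | (naive["s"] > 1)).sum())
        assert rep.n_discrepant == want
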