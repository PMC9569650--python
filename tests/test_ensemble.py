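"""Pairwise RMSD, Kelley clustering, shift prediction, CS-RMSD selection, Q factor."""

import numpy as np
import pandas as pd
import pytest

from pepshift.ensemble import (
    ConformerEnsemble,
    ToyShiftPredictor,
    global_cs_rmsd,
    kelley_cluster,
    load_basins,
    pairwise_rmsd,
    predict_shifts,
    q_factor,
    select_ensemble,
)
from pepshift.shifts import RandomCoilModel, secondary_shifts
from pepshift.synthetic import build_backbone, make_recovery_instance

from conftest import make_shift_table


def _ensemble_from_models(models, names=None):
    models = np.asarray(models)
    n = models.shape[1]
    names = names or ["ALA"] * n
    return ConformerEnsemble.from_coords("t", np.arange(1, n + 1), names, models)


def _rotation(axis, deg):
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(np.deg2rad(deg) * np.asarray(axis)).as_matrix()


class TestPairwiseRmsd:
    def test_identical_models_give_zero_matrix(self):
        c = build_backbone(np.array([0.0, -63.0, -75.0]), np.array([-42.0, 150.0, 0.0]))
        d = pairwise_rmsd(_ensemble_from_models([c, c, c]))
        assert np.allclose(d, 0.0)

    def test_rigid_rotation_is_superposed_away(self):
        c = build_backbone(np.array([0.0, -63.0, -75.0]), np.array([-42.0, 150.0, 0.0]))
        rot = _rotation([0, 0, 1], 73.0)
        c2 = c @ rot.T + np.array([5.0, -3.0, 2.0])
        d = pairwise_rmsd(_ensemble_from_models([c, c2]))
        assert d[0, 1] == pytest.approx(0.0, abs=1e-8)
        assert d[0, 1] == d[1, 0] and d[0, 0] == 0.0

    def test_toy_pair_matches_rotation_grid_oracle(self):
        """Brute-force search over rotations cannot beat the Kabsch optimum."""
        rng = np.random.default_rng(3)
        a = rng.normal(size=(3, 3))
        b = rng.normal(size=(3, 3))
        # coords must be (M, 1, 4, 3): pad the 3-atom toys with their centroid
        a4 = np.vstack([a, a.mean(axis=0)])
        b4 = np.vstack([b, b.mean(axis=0)])
        ens = ConformerEnsemble(
            "t", np.array([1]), ["ALA"], np.stack([a4[None], b4[None]]),
            phi=np.full((2, 1), np.nan), psi=np.full((2, 1), np.nan),
        )
        d = pairwise_rmsd(ens, atom_selection=("N", "CA", "C", "O"))
        ac = a4 - a4.mean(axis=0)
        bc = b4 - b4.mean(axis=0)
        best = np.inf
        for ax in np.linspace(0, np.pi, 14):
            for az in np.linspace(0, 2 * np.pi, 27):
                for th in np.linspace(0, 2 * np.pi, 27):
                    axis = np.array(
                        [np.sin(ax) * np.cos(az), np.sin(ax) * np.sin(az), np.cos(ax)]
                    )
                    rot = _rotation(axis, np.rad2deg(th))
                    r = np.sqrt(np.mean(np.sum((ac @ rot.T - bc) ** 2, axis=1)))
                    best = min(best, r)
        assert d[0, 1] <= best + 1e-6
        assert d[0, 1] == pytest.approx(best, abs=0.05)


def _two_group_matrix(n1=6, n2=6, within=0.5, between=10.0, seed=0):
    rng = np.random.default_rng(seed)
    m = n1 + n2
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            same = (i < n1) == (j < n1)
            base = within if same else between
            d[i, j] = d[j, i] = base + rng.uniform(0, 0.05)
    return d


def _kelley_oracle(d, labels_per_k):
    """Independent exhaustive evaluation of the penalty at every cut level."""
    m = d.shape[0]
    spreads = {}
    for k, labels in labels_per_k.items():
        vals = []
        for cid in np.unique(labels):
            members = np.flatnonzero(labels == cid)
            if len(members) < 2:
                continue
            sub = d[np.ix_(members, members)]
            vals.append(sub[np.triu_indices(len(members), 1)].mean())
        if vals:
            spreads[k] = float(np.mean(vals))
    ks = sorted(spreads)
    arr = np.array([spreads[k] for k in ks])
    norm = (arr - arr.min()) / (arr.max() - arr.min()) * (m - 2) + 1 if arr.max() > arr.min() else np.ones_like(arr)
    pen = {k: float(nv) + k for k, nv in zip(ks, norm)}
    return min(pen, key=lambda k: (pen[k], k))


class TestKelleyCluster:
    def test_two_separated_groups_found_with_exhaustive_check(self):
        d = _two_group_matrix()
        res = kelley_cluster(d)
        assert res.n_clusters == 2
        labels = res.labels
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[-1]
        # oracle: recompute the penalty over every cut level from the tree
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        z = linkage(squareform(d, checks=False), method="average")
        labels_per_k = {k: fcluster(z, t=k, criterion="maxclust") for k in range(1, 12)}
        assert _kelley_oracle(d, labels_per_k) == 2

    def test_identical_points_collapse_to_one_cluster(self):
        d = np.zeros((6, 6))
        assert kelley_cluster(d).n_clusters == 1

    def test_permutation_leaves_membership_invariant(self):
        d = _two_group_matrix()
        rng = np.random.default_rng(5)
        perm = rng.permutation(d.shape[0])
        dp = d[np.ix_(perm, perm)]
        res_p = kelley_cluster(dp)
        res = kelley_cluster(d)
        # same partition up to label names
        orig = [frozenset(np.flatnonzero(res.labels == c)) for c in np.unique(res.labels)]
        permuted = [
            frozenset(perm[i] for i in np.flatnonzero(res_p.labels == c))
            for c in np.unique(res_p.labels)
        ]
        assert set(orig) == set(permuted)

    def test_fewer_than_three_models_trivial_cluster(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        res = kelley_cluster(d)
        assert res.n_clusters == 1
        assert res.representatives[1] in (0, 1)

    def test_medoid_belongs_to_its_cluster(self):
        d = _two_group_matrix()
        res = kelley_cluster(d)
        for cid, rep in res.representatives.items():
            assert res.labels[rep] == cid


class TestToyPredictor:
    def test_coil_basin_conformer_equals_random_coil(self, coil_conformer, toy_predictor, rc):
        table = predict_shifts(coil_conformer, 0, toy_predictor)
        for _, row in table.data.iterrows():
            # termini (undefined phi/psi) are treated as coil too
            assert row.shift_ppm == pytest.approx(rc.lookup(row.residue_name, row.atom_name))

    def test_determinism(self, coil_conformer, toy_predictor):
        t1 = predict_shifts(coil_conformer, 0, toy_predictor)
        t2 = predict_shifts(coil_conformer, 0, toy_predictor)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_helix_basin_offsets_match_documented_table(self, toy_predictor, rc):
        basins = load_basins()
        ctr = basins["helix"]["center"]
        n = 5
        coords = build_backbone(np.full(n, ctr[0]), np.full(n, ctr[1]))
        names = ["MET", "ASP", "ARG", "ASN", "HIS"]
        ens = ConformerEnsemble.from_coords("h", np.arange(1, n + 1), names, coords[None])
        table = predict_shifts(ens, 0, toy_predictor)
        offsets = basins["helix"]["offsets"]
        # interior residues carry the full helix offset; termini fall back to coil
        for res_idx in (2, 3, 4):
            name = names[res_idx - 1]
            for atom in ("CA", "CB", "HA", "H", "N"):
                ref = rc.lookup(name, atom)
                if ref is None:
                    continue
                assert table.get(res_idx, atom) == pytest.approx(ref + offsets[atom])
        assert table.get(1, "CA") == pytest.approx(rc.lookup("MET", "CA"))


class TestGlobalCsRmsd:
    def test_identity_is_zero(self):
        t = make_shift_table("p", [(1, "ALA", "CA", 52.5), (1, "ALA", "H", 8.24)])
        out = global_cs_rmsd(t, t)
        assert out["global_ppm"] == 0.0
        assert all(v == 0.0 for v in out["per_class"].values())

    def test_single_cell_reduction(self):
        a = make_shift_table("p", [(1, "ALA", "CA", 52.5)])
        b = make_shift_table("p", [(1, "ALA", "CA", 53.0)])
        out = global_cs_rmsd(a, b)
        assert out["global_ppm"] == pytest.approx(0.5)
        assert "CB" in out["skipped_classes"]

    def test_two_class_toy_matches_hand_sum(self):
        a = make_shift_table(
            "p", [(1, "ALA", "CA", 52.0), (2, "GLY", "CA", 45.0), (1, "ALA", "H", 8.0)]
        )
        b = make_shift_table(
            "p", [(1, "ALA", "CA", 52.6), (2, "GLY", "CA", 45.8), (1, "ALA", "H", 8.2)]
        )
        out = global_cs_rmsd(a, b)
        exp_ca = np.sqrt((0.6**2 + 0.8**2) / 2)
        exp_hn = 0.2
        assert out["per_class"]["CA"] == pytest.approx(exp_ca)
        assert out["per_class"]["HN"] == pytest.approx(exp_hn)
        assert out["global_ppm"] == pytest.approx(exp_ca + exp_hn)

    def test_no_shared_cells_fails(self):
        a = make_shift_table("p", [(1, "ALA", "CA", 52.0)])
        b = make_shift_table("p", [(2, "GLY", "CA", 45.0)])
        with pytest.raises(ValueError):
            global_cs_rmsd(a, b)

    def test_invariant_under_residue_reordering(self):
        rows_a = [(1, "ALA", "CA", 52.0), (2, "GLY", "CA", 45.0), (3, "MET", "CB", 33.0)]
        rows_b = [(1, "ALA", "CA", 52.5), (2, "GLY", "CA", 45.5), (3, "MET", "CB", 32.0)]
        a1 = make_shift_table("p", rows_a)
        b1 = make_shift_table("p", rows_b)
        a2 = make_shift_table("p", rows_a[::-1])
        b2 = make_shift_table("p", rows_b[::-1])
        assert global_cs_rmsd(a1, b1)["global_ppm"] == pytest.approx(
            global_cs_rmsd(a2, b2)["global_ppm"]
        )


@pytest.fixture(scope="module")
def recovery():
    ens, truth, obs = make_recovery_instance(n_total=120, n_true=30, sigma_ppm=0.05, seed=17)
    predictor = ToyShiftPredictor()
    predicted = {i: predict_shifts(ens, i, predictor) for i in range(ens.n_models)}
    return ens, truth, obs, predicted


class TestSelection:
    def test_all_modes_agree_when_selecting_everything(self, recovery):
        _, _, obs, predicted = recovery
        n = len(predicted)
        ids = {
            mode: set(select_ensemble(obs, predicted, n=n, mode=mode, seed=1).selected_ids)
            for mode in ("lowest", "highest", "random")
        }
        assert ids["lowest"] == ids["highest"] == ids["random"]

    def test_lowest_mode_sorted_and_sized(self, recovery):
        _, _, obs, predicted = recovery
        sel = select_ensemble(obs, predicted, n=30, mode="lowest")
        assert len(sel.selected_ids) == 30
        scores = sel.ranking["global_cs_rmsd"].to_numpy()
        assert (np.diff(scores) >= 0).all()

    def test_oversized_request_selects_all_with_warning(self, recovery):
        _, _, obs, predicted = recovery
        small = {i: predicted[i] for i in range(5)}
        sel = select_ensemble(obs, small, n=50)
        assert len(sel.selected_ids) == 5
        assert sel.warning is not None

    def test_deterministic_tie_break_on_conformer_id(self):
        t = make_shift_table("p", [(1, "ALA", "CA", 52.5)])
        pred = {i: make_shift_table("p", [(1, "ALA", "CA", 53.0)]) for i in range(6)}
        sel = select_ensemble(t, pred, n=3, mode="lowest")
        assert sel.selected_ids == [0, 1, 2]

    def test_recovery_of_hidden_sub_ensemble(self, recovery):
        """Lowest-N selection recovers >= 80% of the designated true set."""
        _, truth, obs, predicted = recovery
        sel = select_ensemble(obs, predicted, n=len(truth.true_ids), mode="lowest")
        overlap = len(set(sel.selected_ids) & set(truth.true_ids)) / len(truth.true_ids)
        assert overlap >= 0.8

    def test_mode_ordering_on_recovery_instance(self, recovery):
        """Ensemble CS-RMSD: lowest < random < highest."""
        _, truth, obs, predicted = recovery
        n = len(truth.true_ids)
        low = select_ensemble(obs, predicted, n=n, mode="lowest")
        rnd = select_ensemble(obs, predicted, n=n, mode="random", seed=23)
        high = select_ensemble(obs, predicted, n=n, mode="highest")
        assert low.ensemble_cs_rmsd < rnd.ensemble_cs_rmsd < high.ensemble_cs_rmsd

    def test_ensemble_average_beats_best_single_conformer(self, recovery):
        """The population-averaged ensemble describes obs better than any
        single conformer (obs was generated as an ensemble average)."""
        _, truth, obs, predicted = recovery
        low = select_ensemble(obs, predicted, n=len(truth.true_ids), mode="lowest")
        best_single = low.ranking["global_cs_rmsd"].iloc[0]
        assert low.ensemble_cs_rmsd <= best_single


class TestQFactor:
    def _sec(self, rows):
        rc = RandomCoilModel.from_packaged()
        return secondary_shifts(make_shift_table("p", rows), rc)

    def test_identity_gives_zero(self):
        rows = [(1, "ALA", "CA", 54.0), (2, "GLY", "HA", 4.2)]
        rep = q_factor(self._sec(rows), self._sec(rows))
        assert rep.q_pooled == 0.0

    def test_zero_prediction_gives_one(self):
        rows_obs = [(1, "ALA", "CA", 54.0), (2, "GLY", "HA", 4.2)]
        rows_pred = [(1, "ALA", "CA", 52.5), (2, "GLY", "HA", 3.96)]  # == random coil
        rep = q_factor(self._sec(rows_obs), self._sec(rows_pred))
        assert rep.q_pooled == pytest.approx(1.0)

    def test_four_value_toy_matches_hand_computation(self):
        rows_obs = [
            (1, "ALA", "CA", 53.0), (2, "ALA", "CA", 52.0),
            (3, "ALA", "CA", 54.0), (4, "ALA", "CA", 52.5),
        ]
        rows_pred = [
            (1, "ALA", "CA", 52.9), (2, "ALA", "CA", 52.6),
            (3, "ALA", "CA", 53.0), (4, "ALA", "CA", 52.1),
        ]
        d_obs = np.array([0.5, -0.5, 1.5, 0.0])
        d_pred = np.array([0.4, 0.1, 0.5, -0.4])
        expected = np.sqrt(np.mean((d_obs - d_pred) ** 2)) / np.sqrt(np.mean(d_obs**2))
        rep = q_factor(self._sec(rows_obs), self._sec(rows_pred))
        assert rep.q_pooled == pytest.approx(expected, abs=1e-12)

    def test_undefined_when_obs_rms_zero(self):
        rows_obs = [(1, "ALA", "CA", 52.5), (2, "GLY", "HA", 3.96)]  # all at coil
        rows_pred = [(1, "ALA", "CA", 53.0), (2, "GLY", "HA", 4.2)]
        with pytest.raises(ValueError):
            q_factor(self._sec(rows_obs), self._sec(rows_pred))

    def test_invariant_under_residue_reordering(self):
        rows_obs = [(1, "ALA", "CA", 53.0), (2, "GLY", "HA", 4.2), (3, "MET", "CB", 33.5)]
        rows_pred = [(1, "ALA", "CA", 52.8), (2, "GLY", "HA", 4.1), (3, "MET", "CB", 33.0)]
        q1 = q_factor(self._sec(rows_obs), self._sec(rows_pred)).q_pooled
        q2 = q_factor(self._sec(rows_obs[::-1]), self._sec(rows_pred[::-1])).q_pooled
        assert q1 == pytest.approx(q2)
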