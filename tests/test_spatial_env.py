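import numpy as np
import pandas as pd
import pytest

from ecoassembly.diversity import bray_curtis
from ecoassembly.spatial_env import (
    EARTH_RADIUS_KM,
    cca,
    distance_decay,
    forward_select,
    haversine_matrix,
    hellinger,
    mantel,
    pcnm,
    variation_partition,
)
from ecoassembly.synthetic_communities import (
    SimulationScenario,
    simulate_metacommunity,
    simulate_niche_samples,
)
from ecoassembly.tables_io import CountTable, DistanceMatrix, SampleFrame


def _frame(lats, lons):
    n = len(lats)
    return SampleFrame(
        pd.DataFrame(
            {"group": ["g"] * n, "lat": lats, "lon": lons},
            index=[f"s{i}" for i in range(n)],
        )
    )


@pytest.fixture(scope="module")
def niche_data():
    pool = simulate_metacommunity(200, log_sd=1.2, seed=7)
    scn = SimulationScenario(
        regime="niche", n_samples=15, J=5000, breadth=0.3, seed=7
    )
    return simulate_niche_samples(pool, scn)


class TestHaversine:
    def test_identical_points(self):
        dm = haversine_matrix(_frame([10.0, 10.0], [20.0, 20.0]))
        assert dm.values[0, 1] == 0.0

    def test_one_degree_latitude(self):
        dm = haversine_matrix(_frame([0.0, 1.0], [0.0, 0.0]))
        expected = 2 * np.pi * EARTH_RADIUS_KM / 360
        assert dm.values[0, 1] == pytest.approx(expected, abs=0.01)

    def test_antipodal(self):
        dm = haversine_matrix(_frame([0.0, 0.0], [0.0, 180.0]))
        assert dm.values[0, 1] == pytest.approx(np.pi * EARTH_RADIUS_KM, abs=1.0)

    def test_missing_coordinates_error(self):
        f = _frame([0.0, np.nan], [0.0, 1.0])
        with pytest.raises(ValueError, match="missing"):
            haversine_matrix(f)


class TestMantel:
    def _random_dm(self, rng, n=12):
        from scipy.spatial.distance import pdist, squareform

        return DistanceMatrix(
            [str(i) for i in range(n)], squareform(pdist(rng.normal(size=(n, 3))))
        )

    def test_self_mantel(self):
        rng = np.random.default_rng(0)
        dm = self._random_dm(rng)
        res = mantel(dm, dm, n_perm=199, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_statistic_matches_brute_force(self):
        rng = np.random.default_rng(1)
        a, b = self._random_dm(rng), self._random_dm(rng)
        res = mantel(a, b, method="pearson", n_perm=99, seed=0)
        iu = np.triu_indices(12, 1)
        brute = np.corrcoef(a.values[iu], b.values[iu])[0, 1]
        assert res.statistic == pytest.approx(brute)

    def test_spearman_matches_ranks(self):
        rng = np.random.default_rng(2)
        a, b = self._random_dm(rng), self._random_dm(rng)
        from scipy import stats

        res = mantel(a, b, method="spearman", n_perm=99, seed=0)
        iu = np.triu_indices(12, 1)
        brute, _ = stats.spearmanr(a.values[iu], b.values[iu])
        assert res.statistic == pytest.approx(brute)

    def test_label_mismatch_error(self):
        rng = np.random.default_rng(3)
        a = self._random_dm(rng)
        b = DistanceMatrix([f"x{i}" for i in range(12)], a.values, "d")
        with pytest.raises(ValueError, match="labels"):
            mantel(a, b)


class TestDistanceDecay:
    def test_perfect_monotone_decay(self):
        n = 8
        pos = np.arange(n, dtype=float)
        d = np.abs(pos[:, None] - pos[None, :])
        sim = np.exp(-d)
        np.fill_diagonal(sim, 0)
        labels = [str(i) for i in range(n)]
        out = distance_decay(
            DistanceMatrix(labels, d), DistanceMatrix(labels, sim), n_perm=99, seed=0
        )
        assert out["rho"] == pytest.approx(-1.0)
        assert out["n"] == n * (n - 1) // 2

    def test_niche_transect_shows_decay(self, niche_data):
        table, frame = niche_data
        geo = haversine_matrix(frame)
        bc = bray_curtis(table)
        sim = DistanceMatrix(
            bc.labels, np.where(np.eye(bc.n, dtype=bool), 0, 1 - bc.values), "sim"
        )
        out = distance_decay(geo, sim, n_perm=199, seed=0)
        assert out["rho"] < 0
        assert out["p"] <= 0.05


class TestPcnm:
    def _transect_geo(self, n=20):
        lats = np.linspace(0, 1, n)
        return haversine_matrix(_frame(lats, np.zeros(n)))

    def test_first_eigenfunction_halfwave(self):
        eig = pcnm(self._transect_geo())
        v1 = eig.vectors.iloc[:, 0].to_numpy()
        sign_changes = int((np.diff(np.sign(v1)) != 0).sum())
        assert sign_changes == 1

    def test_orthogonal_and_centered(self):
        eig = pcnm(self._transect_geo())
        V = eig.vectors.to_numpy()
        gram = V.T @ V
        assert np.all(np.abs(gram - np.diag(np.diag(gram))) < 1e-8)
        assert np.all(np.abs(V.mean(axis=0)) < 1e-10)

    def test_truncation_is_mst_max_edge(self):
        geo = self._transect_geo(10)
        eig = pcnm(geo)
        # brute-force MST via Prim's algorithm
        n = geo.n
        in_tree = {0}
        edges = []
        while len(in_tree) < n:
            best = min(
                (
                    (geo.values[i, j], i, j)
                    for i in in_tree
                    for j in range(n)
                    if j not in in_tree
                ),
            )
            edges.append(best[0])
            in_tree.add(best[2])
        assert eig.truncation_km == pytest.approx(max(edges))

    def test_all_duplicate_coordinates_error(self):
        # t = 0 only when the MST degenerates (all points coincide)
        geo = haversine_matrix(_frame([0.0] * 4, [0.0] * 4))
        with pytest.raises(ValueError, match="duplicate"):
            pcnm(geo)


class TestForwardSelect:
    def test_generating_gradient_selected(self, niche_data):
        table, frame = niche_data
        hel = hellinger(table)
        cand = frame.env()[["gradient", "WT"]]
        out = forward_select(hel, cand, n_perm=99, seed=0)
        assert "gradient" in list(out["variable"])
        assert (out[out.variable == "gradient"]["p"] <= 0.05).all()

    def test_no_candidates_pass_empty(self):
        rng = np.random.default_rng(0)
        Y = pd.DataFrame(rng.normal(size=(20, 5)))
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        out = forward_select(Y, X, n_perm=99, seed=1)
        assert isinstance(out, pd.DataFrame)  # empty frame, not an error

    def test_constant_candidate_skipped(self):
        rng = np.random.default_rng(0)
        Y = pd.DataFrame(rng.normal(size=(15, 4)))
        X = pd.DataFrame({"c": np.ones(15), "x": rng.normal(size=15)})
        with pytest.warns(UserWarning, match="constant"):
            forward_select(Y, X, n_perm=99, seed=0)


class TestCca:
    def test_constant_predictor_zero_inertia(self, niche_data):
        table, frame = niche_data
        pred = pd.DataFrame({"c": np.ones(table.n_samples)}, index=table.sample_ids)
        res = cca(table, pred, n_perm=99, seed=0)
        assert res.constrained_inertia == pytest.approx(0.0, abs=1e-9)

    def test_gradient_significant(self, niche_data):
        table, frame = niche_data
        pred = frame.env()[["gradient"]]
        res = cca(table, pred, n_perm=999, seed=0)
        assert res.anova_p <= 0.005

    def test_inertia_decomposition(self, niche_data):
        table, frame = niche_data
        pred = frame.env()[["gradient", "WT"]]
        res = cca(table, pred, n_perm=99, seed=0)
        assert res.constrained_inertia + res.unconstrained_inertia == pytest.approx(
            res.total_inertia, abs=1e-9
        )
        assert np.all(res.eigenvalues <= 1 + 1e-9)


class TestVariationPartition:
    def test_fractions_sum_to_one(self, niche_data):
        table, frame = niche_data
        geo = haversine_matrix(frame)
        eig = pcnm(geo)
        vp = variation_partition(table, frame.env()[["gradient"]], eig)
        s = vp.as_series()
        assert s.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_predictors_all_shared(self, niche_data):
        table, frame = niche_data
        X = frame.env()[["gradient"]]
        vp = variation_partition(table, X, X.rename(columns={"gradient": "g2"}))
        assert abs(vp.a) < 1e-9
        assert abs(vp.c) < 1e-9

    def test_orthogonal_design_no_shared(self):
        rng = np.random.default_rng(0)
        n = 50
        env = rng.normal(size=n)
        space = rng.normal(size=n)
        # response driven by both, independently
        mat = np.maximum(
            0,
            np.round(
                20
                + 5 * env[:, None] * rng.normal(size=(1, 10))
                + 5 * space[:, None] * rng.normal(size=(1, 10))
                + rng.normal(size=(n, 10))
            ),
        ).astype(int)
        mat[mat.sum(axis=1) == 0, 0] = 1
        table = CountTable(
            pd.DataFrame(
                mat, index=[f"s{i}" for i in range(n)], columns=[f"t{j}" for j in range(10)]
            )
        )
        vp = variation_partition(
            table,
            pd.DataFrame({"e": env}, index=table.sample_ids),
            pd.DataFrame({"s": space}, index=table.sample_ids),
        )
        assert abs(vp.b) < 0.02

    def test_predictor_order_invariance(self, niche_data):
        table, frame = niche_data
        geo = haversine_matrix(frame)
        eig = pcnm(geo)
        env = frame.env()[["gradient", "WT", "pH"]]
        vp1 = variation_partition(table, env, eig)
        vp2 = variation_partition(table, env[["pH", "gradient", "WT"]], eig)
        assert vp1.as_series().round(12).equals(vp2.as_series().round(12))

    def test_shared_fraction_dominates_on_spatially_structured_gradient(self, niche_data):
        table, frame = niche_data
        geo = haversine_matrix(frame)
        eig = pcnm(geo)
        vp = variation_partition(
            table, frame.env()[["gradient"]], eig, linear_trend=frame.coords()
        )
        assert vp.b > vp.a

    def test_too_many_predictors_error(self, niche_data):
        table, frame = niche_data
        rng = np.random.default_rng(0)
        wide = pd.DataFrame(
            rng.normal(size=(15, 14)),
            index=table.sample_ids,
            columns=[f"v{i}" for i in range(14)],
        )
        with pytest.raises(ValueError, match="predictors"):
            variation_partition(table, wide, wide.iloc[:, :2])
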