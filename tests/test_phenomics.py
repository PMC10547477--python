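import numpy as np
import pandas as pd
import pytest

from phenofun import fixtures
from phenofun.phenomics import (
    PhenomicsError,
    call_benign,
    call_stress,
    correlation_distance,
    discretize,
    filter_matrix,
    pam,
    pam_cluster,
    silhouette,
    stress_scores,
)


def fitness_frame(rows):
    return pd.DataFrame(rows, columns=["strain", "condition", "repeat", "fitness"])


def make_benign_table(strain_mult, n_rep=10, sd=0.02, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for strain, mult in {**strain_mult, "wildtype": 1.0}.items():
        for r in range(n_rep):
            rows.append((strain, "benign0", r, mult * float(rng.lognormal(0, sd))))
    return fitness_frame(rows)


class TestCallBenign:
    def test_hit_needs_both_thresholds(self):
        table = make_benign_table({"slow": 0.90, "small": 0.97, "null": 1.0})
        out = call_benign(table).set_index("strain")
        assert out.loc["slow", "call"] == "slow"
        assert out.loc["small", "call"] == "none"  # significant but <5% effect
        assert out.loc["null", "call"] == "none"

    def test_direction_fast(self):
        out = call_benign(make_benign_table({"fast": 1.15})).set_index("strain")
        assert out.loc["fast", "call"] == "fast"

    def test_untestable_single_repeat(self):
        table = make_benign_table({"ok": 0.9})
        table = pd.concat(
            [table, fitness_frame([("lonely", "benign0", 0, 0.5)])], ignore_index=True
        )
        out = call_benign(table).set_index("strain")
        assert out.loc["lonely", "call"] == "untestable"

    def test_bh_monotone_within_condition(self):
        rng = np.random.default_rng(3)
        table = make_benign_table({f"s{i}": float(rng.uniform(0.85, 1.1)) for i in range(20)})
        out = call_benign(table)
        o = out.sort_values("p")
        assert o["adj_p"].is_monotonic_increasing or np.allclose(
            o["adj_p"], np.maximum.accumulate(o["adj_p"].to_numpy() - 1e-12), atol=1e-9
        )

    def test_nonpositive_fitness_rejected(self):
        with pytest.raises(PhenomicsError):
            call_benign(fitness_frame([("s", "c", 0, -1.0), ("wildtype", "c", 0, 1.0)]))


class TestCallStress:
    @pytest.fixture()
    def cmap(self):
        return pd.DataFrame(
            {"condition": ["benign0", "stressA"], "control": ["benign0", "benign0"],
             "is_benign": [True, False]}
        )

    def _table(self, stress_mult, control_mult=1.0):
        rows = []
        for strain in ["m", "wildtype"]:
            sm = stress_mult if strain == "m" else 1.0
            cm = control_mult if strain == "m" else 1.0
            for r in range(4):
                rows.append((strain, "stressA", r, sm))
                rows.append((strain, "benign0", r, cm))
        return fitness_frame(rows)

    @pytest.mark.parametrize(
        "mult,expected", [(0.89, "sensitive"), (1.12, "resistant"), (1.05, "none"), (0.90, "sensitive")]
    )
    def test_effect_band(self, cmap, mult, expected):
        out = call_stress(self._table(mult), cmap).set_index("strain")
        assert out.loc["m", "call"] == expected

    def test_control_normalization(self, cmap):
        # constitutively slow strain: same defect in stress and control = no call
        out = call_stress(self._table(0.8, control_mult=0.8), cmap).set_index("strain")
        assert out.loc["m", "call"] == "none"

    def test_missing_control_missing_call(self, cmap):
        table = self._table(0.8)
        table = table.loc[~((table.strain == "m") & (table.condition == "benign0"))]
        out = call_stress(table, cmap).set_index("strain")
        assert out.loc["m", "call"] == "missing"


class TestDiscretize:
    def test_bands_boundary_inclusive(self):
        scores = pd.DataFrame(
            {"strain": ["s"] * 3, "condition": ["c1", "c2", "c3"], "score": [0.90, 1.099, 1.10]}
        )
        m = discretize(scores)
        assert m.loc["s", "c1"] == -1
        assert m.loc["s", "c2"] == 0
        assert m.loc["s", "c3"] == 1

    def test_benign_needs_significance(self):
        scores = pd.DataFrame(columns=["strain", "condition", "score"])
        benign = pd.DataFrame(
            {"strain": ["s", "t"], "condition": ["benign0"] * 2,
             "median": [0.88, 0.88], "p": [0.2, 1e-4], "adj_p": [0.2, 1e-3],
             "call": ["none", "slow"]}
        )
        m = discretize(scores, benign)
        assert m.loc["s", "benign0"] == 0  # 12% effect but adj p = 0.2
        assert m.loc["t", "benign0"] == -1

    def test_missing_stays_missing(self):
        scores = pd.DataFrame({"strain": ["s"], "condition": ["c"], "score": [np.nan]})
        assert np.isnan(discretize(scores).loc["s", "c"])


class TestFilterMatrix:
    def _matrix(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(
            rng.choice([-1.0, 0.0, 1.0], p=[0.25, 0.5, 0.25], size=(20, 10)),
            index=[f"s{i}" for i in range(20)],
            columns=[f"c{j}" for j in range(10)],
        )
        return m

    def test_missing_strain_dropped_both_modes(self):
        m = self._matrix()
        m.iloc[0, :6] = np.nan  # 60% missing
        for mode in ("methods", "fig3"):
            assert "s0" not in filter_matrix(m, mode).index

    def test_zero_condition_dropped_methods(self):
        m = self._matrix()
        m["c0"] = 0.0
        m.loc["s1", "c0"] = 1.0  # 95% zeros
        assert "c0" not in filter_matrix(m, "methods").columns

    def test_sparse_mutant_dropped_fig3(self):
        m = self._matrix()
        m.loc["s2"] = 0.0
        m.loc["s2", ["c1", "c2", "c3"]] = 1.0  # 3 phenotypes < 4
        assert "s2" not in filter_matrix(m, "fig3").index

    def test_all_removed_is_error(self):
        m = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("xyz"))
        m[:] = np.nan
        with pytest.raises(PhenomicsError):
            filter_matrix(m, "methods")


class TestPam:
    def test_k_equals_n_zero_cost(self):
        rng = np.random.default_rng(1)
        x = rng.random((6, 6))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        labels, medoids, cost = pam(d, k=6)
        assert cost == 0.0
        assert sorted(medoids) == list(range(6))

    def test_row_permutation_invariance(self):
        mat, truth = fixtures.make_ternary_archetypes(n_strains=30, seed=2)
        out1 = pam_cluster(mat, k=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(mat))
        out2 = pam_cluster(mat.iloc[perm], k=3)
        m1 = out1.set_index("strain")["cluster"]
        m2 = out2.set_index("strain")["cluster"]
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(m1[m2.index], m2) == 1.0

    def test_archetype_recovery(self):
        mat, truth = fixtures.make_ternary_archetypes(seed=1)
        out = pam_cluster(mat, k_range=range(2, 9))
        from sklearn.metrics import adjusted_rand_score

        assert out["k"].iloc[0] == 3
        assert adjusted_rand_score(truth["archetype"], out["cluster"]) >= 0.9

    def test_zero_variance_row_max_distance(self):
        m = pd.DataFrame(
            [[1.0, -1.0, 1.0, -1.0], [1.0, -1.0, 1.0, -1.0], [0.0, 0.0, 0.0, 0.0]],
            index=list("abc"),
        )
        d = correlation_distance(m, min_overlap=2)
        assert d[0, 2] == 1.0 and d[1, 2] == 1.0
        assert d[0, 1] == pytest.approx(0.0)

    def test_min_overlap_imputation(self):
        m = pd.DataFrame(
            [[1, 0, 1, 0, 1], [1, 0, 1, 0, 1], [np.nan, np.nan, np.nan, 0, 1]],
            index=list("abc"), dtype=float,
        )
        d = correlation_distance(m, min_overlap=3)
        # pair (a,c) overlaps on 2 < 3 conditions: imputed with median distance
        assert np.isfinite(d[0, 2])


def test_stress_recall_and_false_call_rate(fixture_phenotypes):
    """Planted-effect simulation: the 10% rule recovers planted stress hits."""
    fit, cmap, truth = fixture_phenotypes
    out = call_stress(fit, cmap)
    th = truth["hits"]
    th = th.loc[th["condition"].str.startswith("stress")]
    m = out.merge(th, on=["strain", "condition"])
    is_hit = m["direction"] != 0
    called = m["call"].isin(["sensitive", "resistant"])
    recall = (is_hit & called).sum() / is_hit.sum()
    false_rate = (called & ~is_hit).sum() / (~is_hit).sum()
    assert recall >= 0.95
    assert false_rate <= 0.05


def test_hit_counts_invariant_to_row_order(fixture_phenotypes):
    fit, cmap, _ = fixture_phenotypes
    a = call_stress(fit, cmap)
    b = call_stress(fit.sample(frac=1.0, random_state=0), cmap)
    merged = a.merge(b, on=["strain", "condition"], suffixes=("_a", "_b"))
    assert (merged["call_a"] == merged["call_b"]).all()
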