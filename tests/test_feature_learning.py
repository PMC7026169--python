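"""Feature construction, decision trees, MDI and shuffle correction."""

import math

import numpy as np
import pandas as pd
import pytest

from edura.control_strength import differential_calls
from edura.feature_learning import (
    FEATURES,
    FeatureError,
    _impurity,
    binding_site_density,
    compute_feature_table,
    corrected_importance,
    fit_tree,
    importance_ctc_correlation,
    mdi_importance,
    pos_oric,
    pos_oric_signed,
    predict,
)
from edura.genome_networks import build_gpn

from conftest import digraph, point_genome


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def test_binding_site_density_window():
    g = 1_000_000
    sites = [10_000, 49_000, 51_000, 950_000]     # last is 50k behind 0
    assert binding_site_density(sites, 0, g) == 3  # 10k, 49k and wrap 950k
    assert binding_site_density([50_000], 0, g) == 1   # boundary inclusive
    assert binding_site_density([], 0, g) == 0


@pytest.mark.parametrize(
    "center, ori, g, expected",
    [(42, 42, 1000, 0), (500, 0, 1000, 500), (75, 0, 100, 25)],
)
def test_pos_oric(center, ori, g, expected):
    assert pos_oric(center, ori, g) == expected


def test_pos_oric_signed_arms():
    assert pos_oric_signed(25, 0, 100) == 25
    assert pos_oric_signed(75, 0, 100) == -25


def test_compute_feature_table():
    genome = point_genome([0, 10, 20, 30, 40], 1000)
    trn = digraph([("g0", "g1"), ("g0", "g2"), ("g3", "g1")],
                  nodes=genome.gene_ids)
    gpn = build_gpn(genome, 15)
    call = differential_calls(
        pd.Series({"g0": 3.0, "g2": -3.0, "g1": 0.0, "g3": 0.0, "g4": 0.0}),
        2.5, "absdge", "t")
    sites = {"crp": np.array([5.0]), "hns": np.empty(0), "fis": np.empty(0)}
    x, y = compute_feature_table(genome, trn, gpn, sites, call, ori=0,
                                 factor_genes={"hns": "g0", "fis": "g3",
                                               "crp": "g9"})
    assert list(x.columns) == list(FEATURES)
    assert y.tolist() == [1, 0, 1, 0, 0]
    # g1 at 10: GPN neighbours g0(0), g2(20) both called -> gpn_cont 2
    assert x.loc["g1", "gpn_cont"] == 2
    # g1 regulators g0 (called), g3 (not) -> trn_cont 1
    assert x.loc["g1", "trn_cont"] == 1
    # hns mapped to g0: targets g1, g2 flagged
    assert x["hns_dig_cont"].tolist() == [0, 1, 1, 0, 0]
    # crp factor gene absent from TRN -> all zero
    assert (x["crp_dig_cont"] == 0).all()
    assert x.loc["g4", ["gpn_cont", "trn_cont"]].tolist() == [0, 0]
    assert (x["crp_density"] > 0).all()     # one site within 50 kbp of all


def test_feature_table_ancestors_mode():
    genome = point_genome([0, 100, 200], 1000)
    trn = digraph([("g0", "g1"), ("g1", "g2")], nodes=genome.gene_ids)
    gpn = build_gpn(genome, 10)
    call = differential_calls(pd.Series({"g0": 3.0, "g1": 3.0, "g2": 0.0}),
                              2.5, "absdge")
    sites = {k: np.empty(0) for k in ("crp", "hns", "fis")}
    x_direct, _ = compute_feature_table(genome, trn, gpn, sites, call, 0)
    x_anc, _ = compute_feature_table(genome, trn, gpn, sites, call, 0,
                                     ancestors=True)
    assert x_direct.loc["g2", "trn_cont"] == 1    # only g1 direct
    assert x_anc.loc["g2", "trn_cont"] == 2       # g0 and g1 transitively


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def test_impurity_formulas():
    assert _impurity(np.array([0.5]), "entropy")[0] == pytest.approx(math.log(2))
    assert _impurity(np.array([0.5]), "gini")[0] == pytest.approx(0.5)
    for crit in ("entropy", "gini"):
        assert _impurity(np.array([0.0, 1.0]), crit) == pytest.approx([0, 0])
    # both maximised at p1 = 0.5
    grid = np.linspace(0.01, 0.99, 99)
    for crit in ("entropy", "gini"):
        vals = _impurity(grid, crit)
        assert grid[np.argmax(vals)] == pytest.approx(0.5, abs=0.011)


def test_pure_node_is_leaf():
    tree = fit_tree(np.arange(6.0).reshape(-1, 1), np.zeros(6, int))
    assert tree.is_leaf and tree.impurity == 0.0


def test_separable_data_classified_perfectly():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(40, 3))
    y = (x[:, 1] > 0.2).astype(int)
    for crit in ("entropy", "gini"):
        tree = fit_tree(x, y, crit)
        assert (predict(tree, x) == y).all()


def test_tree_deterministic():
    rng = np.random.default_rng(5)
    x = rng.integers(0, 4, size=(60, 4)).astype(float)
    y = rng.integers(0, 2, size=60)
    t1, t2 = fit_tree(x, y), fit_tree(x, y)

    def flat(node, acc):
        acc.append((node.feature, node.threshold, node.n))
        if not node.is_leaf:
            flat(node.left, acc)
            flat(node.right, acc)
        return acc

    assert flat(t1, []) == flat(t2, [])


def test_contradictory_duplicates_impure_leaf():
    x = np.ones((4, 2))
    y = np.array([0, 1, 0, 1])
    tree = fit_tree(x, y)
    assert tree.is_leaf and tree.impurity > 0


def exhaustive_best_split(x, y, criterion):
    """Independent exhaustive-search oracle over all (feature, threshold)."""

    def imp(labels):
        n = len(labels)
        p1 = sum(labels) / n
        p0 = 1 - p1
        if criterion == "entropy":
            return -sum(p * math.log(p) for p in (p0, p1) if p > 0)
        return 2 * p1 * p0

    n, n_feat = x.shape
    s_node = imp(list(y))
    best = None
    for j in range(n_feat):
        values = sorted(set(x[:, j]))
        for lo, hi in zip(values[:-1], values[1:]):
            thr = (lo + hi) / 2
            left = [y[i] for i in range(n) if x[i, j] <= thr]
            right = [y[i] for i in range(n) if x[i, j] > thr]
            g = (len(left) * imp(left) + len(right) * imp(right)) / n
            gain = s_node - g
            if best is None or gain > best[0] + 1e-12:
                best = (gain, j, thr)
    return best


@pytest.mark.parametrize("criterion", ["entropy", "gini"])
def test_root_split_matches_exhaustive_search(criterion):
    """The chosen root split equals brute-force search on small datasets."""
    rng = np.random.default_rng(31)
    for trial in range(20):
        n = int(rng.integers(8, 51))
        x = rng.integers(0, 5, size=(n, 4)).astype(float)
        y = rng.integers(0, 2, size=n)
        if len(set(y)) < 2:
            continue
        tree = fit_tree(x, y, criterion)
        oracle = exhaustive_best_split(x, y, criterion)
        if oracle is None or oracle[0] <= 1e-12:
            assert tree.is_leaf
            continue
        gain_impl = tree.impurity - tree.child_impurity
        assert gain_impl == pytest.approx(oracle[0], abs=1e-9)
        assert (tree.feature, tree.threshold) == (oracle[1], pytest.approx(oracle[2]))


def test_split_never_increases_impurity():
    rng = np.random.default_rng(8)
    x = rng.normal(size=(80, 5))
    y = rng.integers(0, 2, size=80)
    tree = fit_tree(x, y)

    def walk(node):
        if node.is_leaf:
            return
        assert node.impurity >= node.child_impurity - 1e-12
        walk(node.left)
        walk(node.right)

    walk(tree)


def test_tree_cross_check_against_sklearn():
    """Perfectly separable tie-free data: sklearn agrees on importances."""
    from sklearn.tree import DecisionTreeClassifier

    rng = np.random.default_rng(12)
    x = rng.normal(size=(100, 3)) * np.array([1.0, 3.0, 0.5])
    y = ((x[:, 0] > 0.1) & (x[:, 1] > -0.5)).astype(int)
    mine = mdi_importance(fit_tree(x, y, "entropy"), 3)
    sk = DecisionTreeClassifier(criterion="entropy", random_state=0).fit(x, y)
    assert mine == pytest.approx(sk.feature_importances_, abs=1e-8)


# ---------------------------------------------------------------------------
# importances
# ---------------------------------------------------------------------------

def test_mdi_importance_single_split():
    x = np.zeros((10, 9))
    x[:, 3] = np.arange(10)
    y = (np.arange(10) >= 5).astype(int)
    imp = mdi_importance(fit_tree(x, y), 9)
    expected = np.zeros(9)
    expected[3] = 1.0
    assert imp == pytest.approx(expected)


def test_mdi_importance_no_split_zeros():
    imp = mdi_importance(fit_tree(np.zeros((5, 9)), np.zeros(5, int)), 9)
    assert (imp == 0).all()


def test_mdi_importance_sums_to_one():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(60, 9))
    y = rng.integers(0, 2, size=60)
    imp = mdi_importance(fit_tree(x, y), 9)
    assert (imp >= 0).all()
    assert imp.sum() == pytest.approx(1.0)


def test_corrected_importance_constant_labels_flagged():
    prof = corrected_importance(np.random.default_rng(0).normal(size=(20, 9)),
                                np.zeros(20, int), seed=0)
    assert prof.degenerate and (prof.corrected_importance == 0).all()


def test_corrected_importance_predictive_feature_tops():
    """A single perfectly predictive feature dominates after correction."""
    rng = np.random.default_rng(6)
    x = rng.normal(size=(80, 9))
    y = (x[:, 4] > 0).astype(int)
    prof = corrected_importance(x, y, n_shuffles=30, seed=1)
    assert np.argmax(prof.corrected_importance) == 4


def test_corrected_importance_independent_feature_near_zero():
    """Random labels: every feature's corrected importance centres on zero.

    The raw fit is then itself one draw from the shuffle ensemble, so the
    correction removes the overfitting bias entirely.
    """
    rng = np.random.default_rng(44)
    vals = []
    for rep in range(10):
        x = rng.normal(size=(60, 9))
        y = rng.integers(0, 2, size=60)   # independent of all features
        prof = corrected_importance(x, y, n_shuffles=50, seed=100 + rep)
        vals.append(prof.corrected_importance[5])
    assert abs(np.mean(vals)) < 0.05


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def make_profiles(matrix):
    from edura.feature_learning import ImportanceProfile

    return [
        ImportanceProfile(f"c{i}", row, row, 0)
        for i, row in enumerate(np.asarray(matrix, dtype=float))
    ]


def test_importance_ctc_correlation_signs():
    n = 6
    imp = np.zeros((n, 9))
    imp[:, 4] = np.arange(n)          # gpn_cont tracks analog CTC
    imp[:, 5] = -np.arange(n)         # trn_cont anti-tracks it
    ctc_table = pd.DataFrame(
        {"analog_ctc": np.arange(n, dtype=float),
         "digital_ctc": -np.arange(n, dtype=float)},
        index=[f"c{i}" for i in range(n)],
    )
    out = importance_ctc_correlation(make_profiles(imp), ctc_table)
    out = out.set_index("feature")
    assert out.loc["gpn_cont", "rho_analog"] == pytest.approx(1.0)
    assert out.loc["trn_cont", "rho_analog"] == pytest.approx(-1.0)
    assert out.loc["gpn_cont", "rho_digital"] == pytest.approx(-1.0)
    assert out.loc["pos_oric", "flagged_analog"]          # constant column
    assert out.loc["gpn_cont", "feature_class"] == "analog"
    assert out.loc["trn_cont", "feature_class"] == "digital"


def test_spearman_average_ranks_on_ties():
    from scipy.stats import spearmanr

    rho = spearmanr([1, 2, 2, 4], [1, 2, 3, 4]).statistic
    assert rho == pytest.approx(0.9487, abs=1e-4)


def test_importance_ctc_correlation_needs_three():
    with pytest.raises(FeatureError):
        importance_ctc_correlation(make_profiles(np.zeros((2, 9))),
                                   pd.DataFrame())
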