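"""Differential calls, effective networks, control ratio and CTC."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from edura.control_strength import (
    AnalysisConfig,
    ControlError,
    control_ratio,
    control_scan,
    ctc,
    differential_calls,
    effective_subgraph,
    extended_subgraph,
    operon_calls,
)

from conftest import digraph


@pytest.fixture
def logfc():
    return pd.Series({"a": 3.0, "b": -3.0, "c": 1.0, "d": np.nan}, name="c1")


def test_differential_calls_modes(logfc):
    assert differential_calls(logfc, 2.5, "absdge").genes == {"a", "b"}
    assert differential_calls(logfc, 2.5, "posdge").genes == {"a"}
    assert differential_calls(logfc, 2.5, "negdge").genes == {"b"}


def test_differential_calls_strict_threshold():
    s = pd.Series({"a": 2.5, "b": 2.5000001})
    assert differential_calls(s, 2.5, "absdge").genes == {"b"}


def test_differential_calls_bad_params(logfc):
    with pytest.raises(ControlError):
        differential_calls(logfc, 2.5, "weird")
    with pytest.raises(ControlError):
        differential_calls(logfc, -1.0, "absdge")


def test_effective_subgraph_cases():
    triangle = nx.Graph([("a", "b"), ("b", "c"), ("c", "a")])
    call = differential_calls(pd.Series({"a": 3.0, "b": 3.0, "c": 0.0}),
                              2.5, "absdge")
    sub = effective_subgraph(triangle, call)
    assert sub.number_of_nodes() == 2 and sub.number_of_edges() == 1
    empty = differential_calls(pd.Series({"a": 0.0}), 2.5, "absdge")
    assert effective_subgraph(triangle, empty).number_of_nodes() == 0
    full = differential_calls(pd.Series({"a": 3.0, "b": 3.0, "c": 3.0}),
                              2.5, "absdge")
    assert effective_subgraph(triangle, full).number_of_edges() == 3


def test_extended_subgraph_includes_neighbors():
    star = digraph([("hub", "a"), ("hub", "b"), ("hub", "c")])
    call = differential_calls(pd.Series({"a": 3.0}), 2.5, "absdge", "x")
    ext = extended_subgraph(star, call)
    assert set(ext.nodes) == {"a", "hub"}
    assert ext.nodes["a"]["called"] and not ext.nodes["hub"]["called"]
    hub_call = differential_calls(pd.Series({"hub": 3.0}), 2.5, "absdge")
    assert set(extended_subgraph(star, hub_call).nodes) == {"hub", "a", "b", "c"}


def test_control_ratio():
    graph = nx.Graph()
    graph.add_nodes_from("abcd")
    graph.add_edge("a", "b")
    assert control_ratio(graph) == (2, 2, 1.0)
    iso = nx.Graph()
    iso.add_nodes_from("abc")
    assert control_ratio(iso) == (0, 3, 0.0)
    k5 = nx.complete_graph(5)
    assert control_ratio(k5) == (5, 0, 5.0)   # clamped denominator
    assert control_ratio(nx.Graph()) == (0, 0, 0.0)


def test_ctc_null_calibration_small():
    """CTC of sets drawn from the null itself is ~N(0, 1)."""
    rng = np.random.default_rng(3)
    base = nx.gnm_random_graph(120, 300, seed=1)
    universe = list(base.nodes)
    cfg = AnalysisConfig(n_null=2000, seed=0)
    zs = []
    for i in range(40):
        called = rng.choice(universe, size=12, replace=False)
        res = ctc(base, called, universe, cfg, "digital", rng=rng)
        zs.append(res.z_score)
    assert abs(np.mean(zs)) < 0.4
    assert 0.6 < np.std(zs) < 1.5


def test_ctc_detects_planted_clique():
    """A called clique in a sparse graph scores far above the null."""
    base = nx.gnm_random_graph(500, 400, seed=2)
    clique = list(range(10))
    base.add_edges_from((i, j) for i in clique for j in clique if i < j)
    cfg = AnalysisConfig(n_null=2000, seed=5)
    res = ctc(base, clique, list(base.nodes), cfg, "digital")
    assert res.z_score > 3


def test_ctc_degenerate_null_flagged():
    base = nx.complete_graph(8)
    cfg = AnalysisConfig(n_null=50, seed=0)
    res = ctc(base, [0, 1, 2], list(base.nodes), cfg, "digital")
    assert res.degenerate_null and res.z_score == 0.0


def test_ctc_empty_intersection_raises():
    base = nx.complete_graph(4)
    cfg = AnalysisConfig(n_null=10, seed=0)
    with pytest.raises(ControlError, match="x1"):
        ctc(base, ["nope"], list(base.nodes), cfg, "digital", contrast_id="x1")


def test_ctc_permutation_equivariance():
    """Relabeling genes leaves the CTC distribution unchanged (same seed)."""
    base = nx.gnm_random_graph(60, 150, seed=3)
    mapping = {n: f"n{(n * 7) % 60}" for n in base.nodes}
    relabeled = nx.relabel_nodes(base, mapping)
    called = [0, 5, 10, 15, 20]
    cfg = AnalysisConfig(n_null=3000, seed=11)
    r1 = ctc(base, called, sorted(base.nodes), cfg, "digital")
    r2 = ctc(relabeled, [mapping[c] for c in called],
             [mapping[n] for n in sorted(base.nodes)], cfg, "digital")
    assert r1.ratio == r2.ratio
    assert r1.z_score == pytest.approx(r2.z_score)


def test_monotonicity_edge_addition():
    """Connecting two isolated called nodes never decreases R."""
    rng = np.random.default_rng(9)
    graph = nx.gnm_random_graph(30, 20, seed=4)
    _, _, r0 = control_ratio(graph)
    isolated = [n for n, d in graph.degree() if d == 0][:2]
    assert len(isolated) == 2
    graph.add_edge(*isolated)
    _, _, r1 = control_ratio(graph)
    assert r1 >= r0


def test_operon_calls_any_member():
    operons = {"a": "O1", "b": "O1", "c": "O2"}
    call = differential_calls(pd.Series({"a": 3.0, "b": 0.0, "c": 0.0}),
                              2.5, "absdge")
    lifted = operon_calls(call, operons)
    assert lifted.genes == {"O1"}
    with pytest.raises(ControlError):
        operon_calls(differential_calls(pd.Series({"z": 3.0}), 2.5, "absdge"),
                     operons)


def test_operon_calls_conflict_resolution(caplog):
    """Up+down members in posdge mode: warn and follow the largest |logFC|."""
    operons = {"a": "O1", "b": "O1"}
    series = pd.Series({"a": 3.0, "b": -4.0})
    up = differential_calls(series, 2.5, "posdge")
    with caplog.at_level("WARNING"):
        lifted = operon_calls(up, operons)
    assert lifted.genes == set()          # dominant member is down-regulated
    down = differential_calls(series, 2.5, "negdge")
    assert operon_calls(down, operons).genes == {"O1"}


def test_control_scan_duplicate_contrasts_identical():
    rng = np.random.default_rng(1)
    graph = nx.relabel_nodes(nx.gnm_random_graph(50, 120, seed=6),
                             {i: f"g{i}" for i in range(50)})
    trn = nx.DiGraph(graph.edges())
    trn.add_nodes_from(graph.nodes)
    vals = np.where(rng.random(50) < 0.3, 4.0, 0.0)
    contrasts = pd.DataFrame({"c1": vals, "c2": vals},
                             index=[f"g{i}" for i in range(50)])
    cfg = AnalysisConfig(n_null=500, seed=2)
    table, rho = control_scan(contrasts, trn, graph, cfg)
    assert table.loc[0, "digital_ctc"] != 0
    pair = table.set_index("contrast_id")
    assert pair.loc["c1", "n_called"] == pair.loc["c2", "n_called"]


def test_operon_contrasts_dominant_member():
    """Operon logFC = largest-|logFC| member, so threshold calls agree with
    the any-member rule."""
    from edura.control_strength import operon_contrasts

    contrasts = pd.DataFrame({"c1": [3.0, 0.5, -4.0, 1.0]},
                             index=["a", "b", "c", "d"])
    ops = {"a": "O1", "b": "O1", "c": "O2", "d": "O2"}
    out = operon_contrasts(contrasts, ops)
    assert out.loc["O1", "c1"] == 3.0
    assert out.loc["O2", "c1"] == -4.0
    gene_call = differential_calls(contrasts["c1"], 2.5, "absdge")
    lifted = operon_calls(gene_call, ops)
    matrix_call = differential_calls(out["c1"], 2.5, "absdge")
    assert matrix_call.genes == lifted.genes


def test_control_scan_needs_two_contrasts():
    with pytest.raises(ControlError):
        control_scan(pd.DataFrame({"c1": [3.0]}, index=["a"]),
                     nx.DiGraph(), nx.Graph(), AnalysisConfig(n_null=10))
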