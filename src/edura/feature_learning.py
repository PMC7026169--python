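"""Per-gene features, decision trees, and shuffle-corrected importances.

Each gene is described by nine features chosen to separate the two control
modes: its unsigned distance to Ori (``pos_oric``, a dual feature), the
CRP/H-NS/FIS binding-site counts within +/-50 kbp (analog), the number of
differentially expressed GPN neighbours (``gpn_cont``, analog), the number
of differentially expressed direct TRN regulators (``trn_cont``, digital),
and three binary flags for being a direct target of hns/fis/crp (digital).

Per contrast, a binary decision tree (entropy or Gini impurity, grown to
purity, no train/test split — the object of interest is which features the
tree uses, not generalisation) yields mean-decrease-impurity importances.
Because MDI is biased, the class labels are shuffled ``n_shuffles`` times,
the tree refit, and the mean shuffled importance subtracted: the corrected
importance of a label-independent feature fluctuates around zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .control_strength import DifferentialCall
from .genome_networks import CircularGenome, circular_distance

logger = logging.getLogger(__name__)

FEATURES = (
    "pos_oric",
    "crp_density",
    "hns_density",
    "fis_density",
    "gpn_cont",
    "trn_cont",
    "hns_dig_cont",
    "fis_dig_cont",
    "crp_dig_cont",
)

#: Feature classes mirroring the analog / digital / dual split.
FEATURE_CLASS = {
    "pos_oric": "dual",
    "crp_density": "analog",
    "hns_density": "analog",
    "fis_density": "analog",
    "gpn_cont": "analog",
    "trn_cont": "digital",
    "hns_dig_cont": "digital",
    "fis_dig_cont": "digital",
    "crp_dig_cont": "digital",
}

_GAIN_TOL = 1e-12


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def binding_site_density(
    sites, center: float, g: float, half_window: float = 50_000
) -> int:
    """Number of sites within a circular +/-half_window of a gene centre."""
    sites = np.asarray(sites, dtype=float)
    if len(sites) == 0:
        return 0
    d = np.abs(sites - center)
    return int(np.sum(np.minimum(d, g - d) <= half_window))


def _density_many(sites, centers, g, half_window):
    """Vectorised window counts via a doubled sorted site array."""
    sites = np.sort(np.asarray(sites, dtype=float))
    centers = np.asarray(centers, dtype=float)
    if len(sites) == 0:
        return np.zeros(len(centers), dtype=np.int64)
    if 2 * half_window >= g:
        return np.full(len(centers), len(sites), dtype=np.int64)
    s2 = np.concatenate([sites, sites + g])
    c = np.where(centers - half_window < 0, centers + g, centers)
    hi = np.searchsorted(s2, c + half_window, side="right")
    lo = np.searchsorted(s2, c - half_window, side="left")
    return (hi - lo).astype(np.int64)


def pos_oric(center: float, ori: float, g: float) -> float:
    """Unsigned circular distance from a gene centre to Ori, in [0, g/2]."""
    return circular_distance(center, ori, g)


def pos_oric_signed(center: float, ori: float, g: float) -> float:
    """Signed variant: positive on the right arm, negative on the left."""
    d = (center - ori) % g
    return d if d <= g / 2 else d - g


def compute_feature_table(
    genome: CircularGenome,
    trn: nx.DiGraph,
    gpn: nx.Graph,
    sites: dict[str, np.ndarray],
    call: DifferentialCall,
    ori: float,
    factor_genes: dict[str, str] | None = None,
    ancestors: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Nine-feature matrix over all genome genes, plus the call labels.

    ``sites`` maps factor name ('crp', 'hns', 'fis') to site positions;
    ``factor_genes`` maps factor name to its gene_id in the TRN (defaults to
    the factor name itself).  ``ancestors=True`` counts all transitive TRN
    ancestors for ``trn_cont`` instead of direct regulators.  Genes absent
    from the TRN or GPN get zero network features.
    """
    factor_genes = factor_genes or {f: f for f in ("hns", "fis", "crp")}
    gene_ids = genome.gene_ids
    centers = np.array([r.center_bp for r in genome.genes], dtype=float)
    g = genome.length_bp
    called = call.genes

    x = pd.DataFrame(0.0, index=pd.Index(gene_ids, name="gene_id"),
                     columns=list(FEATURES))
    d = np.abs(centers - ori)
    x["pos_oric"] = np.minimum(d, g - d)
    for factor in ("crp", "hns", "fis"):
        x[f"{factor}_density"] = _density_many(
            sites.get(factor, np.empty(0)), centers, g, 50_000
        )

    trn_nodes = set(trn.nodes)
    gpn_nodes = set(gpn.nodes)
    target_sets: dict[str, set] = {}
    for factor in ("hns", "fis", "crp"):
        fg = factor_genes.get(factor)
        if fg in trn_nodes:
            target_sets[factor] = set(trn.successors(fg))
        else:
            target_sets[factor] = set()
            logger.warning(
                "factor gene %r for %s absent from TRN; dig_cont feature all 0",
                fg, factor,
            )
    for i, gid in enumerate(gene_ids):
        if gid in gpn_nodes:
            x.iat[i, 4] = sum(1 for nb in gpn.neighbors(gid) if nb in called)
        if gid in trn_nodes:
            if ancestors:
                regs = nx.ancestors(trn, gid)
            else:
                regs = set(trn.predecessors(gid))
            x.iat[i, 5] = sum(1 for r in regs if r in called)
        x.iat[i, 6] = float(gid in target_sets["hns"])
        x.iat[i, 7] = float(gid in target_sets["fis"])
        x.iat[i, 8] = float(gid in target_sets["crp"])
    y = pd.Series([int(gid in called) for gid in gene_ids],
                  index=x.index, name="called")
    return x, y


# ---------------------------------------------------------------------------
# decision tree
# ---------------------------------------------------------------------------

def _impurity(p1: np.ndarray, criterion: str) -> np.ndarray:
    """Binary-class impurity: entropy S = -(p1 ln p1 + p0 ln p0) or Gini."""
    p1 = np.asarray(p1, dtype=float)
    p0 = 1.0 - p1
    if criterion == "entropy":
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(p1 > 0, p1 * np.log(p1), 0.0)
            t0 = np.where(p0 > 0, p0 * np.log(p0), 0.0)
        return -(t1 + t0)
    if criterion == "gini":
        return p1 * p0 * 2.0
    raise FeatureError(f"unknown criterion {criterion!r}")


@dataclass
class TreeNode:
    n: int
    p1: float
    impurity: float
    feature: int | None = None      # split feature index; None for leaves
    threshold: float | None = None  # x[feature] <= threshold goes left
    child_impurity: float | None = None   # G, sample-weighted
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _best_split(x: np.ndarray, y: np.ndarray, criterion: str):
    """Exhaustive best (feature, threshold) by impurity gain S - G.

    Thresholds are midpoints of consecutive distinct sorted values.
    Tie-break: lowest feature index, then lowest threshold (enforced by
    strict-improvement scanning in ascending order).
    """
    n, n_feat = x.shape
    total1 = int(y.sum())
    s_node = float(_impurity(np.array([total1 / n]), criterion)[0])
    best = None  # (gain, feature, threshold, g_children)
    for j in range(n_feat):
        order = np.argsort(x[:, j], kind="stable")
        xs = x[order, j]
        ys = y[order]
        c1 = np.cumsum(ys)
        i = np.arange(1, n)
        valid = xs[1:] > xs[:-1]
        if not valid.any():
            continue
        i = i[valid]
        nl = i.astype(float)
        nr = n - nl
        p1l = c1[i - 1] / nl
        p1r = (total1 - c1[i - 1]) / nr
        g_split = (nl * _impurity(p1l, criterion)
                   + nr * _impurity(p1r, criterion)) / n
        gains = s_node - g_split
        k = int(np.argmax(gains))      # first max = lowest threshold
        gain = float(gains[k])
        if best is None or gain > best[0] + _GAIN_TOL:
            thr = float((xs[i[k] - 1] + xs[i[k]]) / 2.0)
            best = (gain, j, thr, float(g_split[k]))
    if best is None or best[0] <= _GAIN_TOL:
        return None
    return best


def fit_tree(x, y, criterion: str = "entropy") -> TreeNode:
    """Grow a binary classification tree to purity (or until unsplittable).

    Deterministic: identical (x, y, criterion) always yield the same tree.
    Nodes whose samples are contradictory duplicates (identical feature
    vectors, mixed labels) become impure leaves.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if x.ndim != 2 or len(x) != len(y):
        raise FeatureError("x must be 2-D and aligned with y")
    if len(y) == 0:
        raise FeatureError("need at least one sample")

    def grow(idx: np.ndarray) -> TreeNode:
        sub_y = y[idx]
        n = len(idx)
        p1 = float(sub_y.mean())
        imp = float(_impurity(np.array([p1]), criterion)[0])
        node = TreeNode(n=n, p1=p1, impurity=imp)
        if imp == 0.0:
            return node
        split = _best_split(x[idx], sub_y, criterion)
        if split is None:
            logger.debug("impure leaf with %d contradictory sample(s)", n)
            return node
        _, j, thr, g_children = split
        node.feature = j
        node.threshold = thr
        node.child_impurity = g_children
        mask = x[idx, j] <= thr
        node.left = grow(idx[mask])
        node.right = grow(idx[~mask])
        return node

    return grow(np.arange(len(y)))


def predict(tree: TreeNode, x) -> np.ndarray:
    """Majority-class prediction (ties to class 1)."""
    x = np.asarray(x, dtype=float)
    out = np.empty(len(x), dtype=int)
    for i, row in enumerate(x):
        node = tree
        while not node.is_leaf:
            node = node.left if row[node.feature] <= node.threshold else node.right
        out[i] = int(node.p1 >= 0.5)
    return out


def mdi_importance(tree: TreeNode, n_features: int = 9) -> np.ndarray:
    """Mean-decrease-impurity importances, normalised to sum to 1.

    Each internal node splitting on feature i contributes n * (S - G): the
    node's impurity reduction weighted by the samples routed to it.  A tree
    with no split returns all zeros.
    """
    acc = np.zeros(n_features)

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        acc[node.feature] += node.n * (node.impurity - node.child_impurity)
        walk(node.left)
        walk(node.right)

    walk(tree)
    total = acc.sum()
    return acc / total if total > 0 else acc


@dataclass
class ImportanceProfile:
    contrast_id: str
    raw_importance: np.ndarray
    corrected_importance: np.ndarray
    n_shuffles: int
    degenerate: bool = False     # constant labels; importances all zero


def corrected_importance(
    x,
    y,
    criterion: str = "entropy",
    n_shuffles: int = 100,
    seed: int | None = None,
    contrast_id: str = "",
) -> ImportanceProfile:
    """Shuffle-corrected MDI: raw importance minus the mean over label
    permutations (class counts preserved)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    n_feat = x.shape[1]
    if len(np.unique(y)) < 2:
        logger.warning("%s: constant labels; corrected importance all zero",
                       contrast_id)
        z = np.zeros(n_feat)
        return ImportanceProfile(contrast_id, z, z.copy(), n_shuffles, True)
    raw = mdi_importance(fit_tree(x, y, criterion), n_feat)
    rng = np.random.default_rng(seed)
    acc = np.zeros(n_feat)
    for _ in range(n_shuffles):
        y_perm = rng.permutation(y)
        acc += mdi_importance(fit_tree(x, y_perm, criterion), n_feat)
    corrected = raw - acc / max(n_shuffles, 1)
    return ImportanceProfile(contrast_id, raw, corrected, n_shuffles)


def importance_ctc_correlation(
    profiles: list[ImportanceProfile], ctc_table: pd.DataFrame
) -> pd.DataFrame:
    """Spearman of each corrected-importance column with analog/digital CTC.

    ``ctc_table`` must be indexed by contrast_id with columns
    ``analog_ctc`` and ``digital_ctc``.  Constant columns yield 0 with the
    flagged column set.
    """
    if len(profiles) < 3:
        raise FeatureError("need >= 3 contrasts for the correlation")
    imp = pd.DataFrame(
        [p.corrected_importance for p in profiles],
        index=[p.contrast_id for p in profiles],
        columns=list(FEATURES),
    )
    common = imp.index.intersection(ctc_table.index)
    if len(common) < 3:
        raise FeatureError("fewer than 3 contrasts shared with the CTC table")
    imp = imp.loc[common]
    rows = []
    for feat in FEATURES:
        col = imp[feat].to_numpy()
        row = {"feature": feat, "feature_class": FEATURE_CLASS[feat]}
        for which in ("analog", "digital"):
            target = ctc_table.loc[common, f"{which}_ctc"].to_numpy()
            if np.all(col == col[0]) or np.all(target == target[0]):
                row[f"rho_{which}"] = 0.0
                row[f"flagged_{which}"] = True
            else:
                row[f"rho_{which}"] = float(spearmanr(col, target).statistic)
                row[f"flagged_{which}"] = False
        rows.append(row)
    return pd.DataFrame(rows)
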