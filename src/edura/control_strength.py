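"""Digital and analog control strengths of differential-expression contrasts.

For one expression contrast, genes passing the logFC threshold form an
*effective network*: the induced subgraph of the TRN (digital control) or of
the GPN (analog control) on the called genes.  Its control ratio is

    R = N_connected / N_isolated,

the number of subgraph nodes with at least one neighbour among the called
genes over the number without any (denominator clamped at 1).  The control
type confidence (CTC, the control strength) is the z-score of R against a
null model of equally sized random gene sets: digital null = random sets on
the TRN node set, analog null = random sets of genome gene positions.  A
high digital CTC means the differentially expressed genes agree with the
regulatory network far more than chance; a high analog CTC means they
cluster in chromosomal neighbourhoods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import spearmanr

from .genome_networks import circular_distance_array

logger = logging.getLogger(__name__)

MODES = ("absdge", "posdge", "negdge")


class ControlError(ValueError):
    pass


@dataclass(frozen=True)
class AnalysisConfig:
    t_fc: float = 2.5            # logFC call threshold (strict inequality)
    t_gpn: int = 20_000          # GPN distance threshold, bp
    n_null: int = 10_000         # null-model ensemble size
    seed: int | None = None
    statistic: str = "ratio"     # "ratio" (R) or "connected" (N_connected)
    analog_null: str = "genes"   # "genes" resamples gene positions; "uniform"
                                 # draws fresh uniform circle positions

    def __post_init__(self) -> None:
        if self.t_fc <= 0 or self.t_gpn <= 0:
            raise ControlError("thresholds must be positive")
        if self.n_null < 1:
            raise ControlError("n_null must be >= 1")
        if self.statistic not in ("ratio", "connected"):
            raise ControlError(f"unknown statistic {self.statistic!r}")


@dataclass
class DifferentialCall:
    contrast_id: str
    mode: str
    threshold: float
    genes: set[str]
    logfc: dict[str, float] = field(default_factory=dict)


def differential_calls(
    logfc: pd.Series, t_fc: float, mode: str, contrast_id: str = ""
) -> DifferentialCall:
    """Call differentially expressed genes from one logFC column.

    absdge: |logFC| > T_FC; posdge: logFC > T_FC; negdge: logFC < -T_FC
    (all strict).  Missing values are never called.
    """
    if t_fc <= 0:
        raise ControlError("t_fc must be positive")
    if mode not in MODES:
        raise ControlError(f"unknown mode {mode!r}; expected one of {MODES}")
    vals = logfc.dropna()
    if mode == "absdge":
        called = vals[vals.abs() > t_fc]
    elif mode == "posdge":
        called = vals[vals > t_fc]
    else:
        called = vals[vals < -t_fc]
    return DifferentialCall(
        contrast_id=contrast_id or str(logfc.name),
        mode=mode,
        threshold=t_fc,
        genes=set(called.index.astype(str)),
        logfc={str(k): float(v) for k, v in vals.items()},
    )


def effective_subgraph(base: nx.Graph, call: DifferentialCall) -> nx.Graph:
    """Induced subgraph of the base network on the called genes."""
    present = call.genes & set(base.nodes)
    absent = len(call.genes) - len(present)
    if absent:
        logger.debug("%s: %d called gene(s) absent from base graph",
                     call.contrast_id, absent)
    return base.subgraph(present).copy()


def extended_subgraph(trn: nx.DiGraph, call: DifferentialCall) -> nx.DiGraph:
    """Called genes plus all their TRN neighbours (either direction).

    Node attribute ``called`` marks membership in the original call.
    """
    present = call.genes & set(trn.nodes)
    nodes = set(present)
    for gene in present:
        nodes.update(trn.predecessors(gene))
        nodes.update(trn.successors(gene))
    sub = trn.subgraph(nodes).copy()
    nx.set_node_attributes(sub, {n: (n in call.genes) for n in sub.nodes}, "called")
    return sub


def control_ratio(effnet: nx.Graph) -> tuple[int, int, float]:
    """(N_connected, N_isolated, R) of an effective network.

    N_connected = nodes with non-zero degree in the subgraph; R clamps the
    denominator at 1 so fully connected subgraphs stay finite.
    """
    n = effnet.number_of_nodes()
    if n == 0:
        return 0, 0, 0.0
    n_connected = sum(1 for _, d in effnet.degree() if d > 0)
    n_isolated = n - n_connected
    return n_connected, n_isolated, n_connected / max(n_isolated, 1)


@dataclass
class ControlResult:
    contrast_id: str
    base: str                    # "TRN" or "GPN"
    n_called: int
    n_connected: int
    n_isolated: int
    ratio: float
    z_score: float
    null_mean: float
    null_sd: float
    n_null: int
    degenerate_null: bool = False


def _symmetric_adjacency(base: nx.Graph, universe: list) -> sp.csr_matrix:
    """Boolean symmetric adjacency of base restricted to the universe.

    Self-loops keep a diagonal entry (a self-looped node is never isolated).
    """
    index = {n: i for i, n in enumerate(universe)}
    rows, cols = [], []
    for u, v in base.edges():
        iu, iv = index.get(u), index.get(v)
        if iu is None or iv is None:
            continue
        rows.append(iu)
        cols.append(iv)
        if iu != iv:
            rows.append(iv)
            cols.append(iu)
    n = len(universe)
    a = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    a.data[:] = 1
    return a


def _null_statistics(
    adj: sp.csr_matrix,
    k: int,
    n_null: int,
    rng: np.random.Generator,
    statistic: str,
    chunk: int = 2000,
) -> tuple[float, float]:
    """Mean and SD of the control statistic over random k-subsets."""
    n_universe = adj.shape[0]
    vals = np.empty(n_null)
    done = 0
    while done < n_null:
        d = min(chunk, n_null - done)
        draws = np.empty((d, k), dtype=np.int64)
        for i in range(d):
            draws[i] = rng.choice(n_universe, size=k, replace=False)
        m = sp.csr_matrix(
            (np.ones(d * k, dtype=np.int8),
             (np.repeat(np.arange(d), k), draws.ravel())),
            shape=(d, n_universe),
        )
        q = (m @ adj).multiply(m)
        q.eliminate_zeros()
        connected = np.diff(q.tocsr().indptr)
        if statistic == "connected":
            vals[done:done + d] = connected
        else:
            isolated = np.maximum(k - connected, 1)
            vals[done:done + d] = connected / isolated
        done += d
    return float(vals.mean()), float(vals.std())


def _null_statistics_uniform_positions(
    k: int, n_null: int, g: int, t_gpn: int, rng: np.random.Generator,
    statistic: str, chunk: int = 500,
) -> tuple[float, float]:
    """Analog null variant: k fresh uniform circle positions per draw."""
    vals = np.empty(n_null)
    done = 0
    while done < n_null:
        d = min(chunk, n_null - done)
        pos = rng.uniform(0, g, size=(d, k))
        dist = circular_distance_array(pos[:, :, None], pos[:, None, :], g)
        near = dist <= t_gpn
        np.einsum("ijj->ij", near)[:] = False
        connected = near.any(axis=2).sum(axis=1)
        if statistic == "connected":
            vals[done:done + d] = connected
        else:
            vals[done:done + d] = connected / np.maximum(k - connected, 1)
        done += d
    return float(vals.mean()), float(vals.std())


def ctc(
    base: nx.Graph,
    called_genes,
    universe,
    config: AnalysisConfig,
    null_type: str,
    contrast_id: str = "",
    genome_length: int | None = None,
    rng: np.random.Generator | None = None,
) -> ControlResult:
    """Control type confidence: z-score of R against the null ensemble.

    ``null_type`` is "digital" (random sets on the TRN) or "analog" (random
    gene sets on the chromosome).  A zero-variance null yields CTC 0 with
    the degenerate flag set.
    """
    if null_type not in ("digital", "analog"):
        raise ControlError(f"unknown null_type {null_type!r}")
    universe = list(universe)
    called = set(called_genes) & set(universe)
    if not called:
        raise ControlError(
            f"contrast {contrast_id!r}: no called genes in the {null_type} universe"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sub = base.subgraph(called & set(base.nodes))
    n_connected, n_isolated, ratio = control_ratio(sub)
    observed = float(n_connected) if config.statistic == "connected" else ratio
    k = len(called)
    if null_type == "analog" and config.analog_null == "uniform":
        if genome_length is None:
            raise ControlError("uniform analog null needs genome_length")
        null_mean, null_sd = _null_statistics_uniform_positions(
            k, config.n_null, genome_length, config.t_gpn, rng, config.statistic
        )
    else:
        adj = _symmetric_adjacency(base, universe)
        null_mean, null_sd = _null_statistics(
            adj, k, config.n_null, rng, config.statistic
        )
    degenerate = null_sd == 0
    if degenerate:
        logger.warning("%s: degenerate null (zero variance); CTC set to 0",
                       contrast_id)
        z = 0.0
    else:
        z = (observed - null_mean) / null_sd
    return ControlResult(
        contrast_id=contrast_id,
        base="TRN" if null_type == "digital" else "GPN",
        n_called=k,
        n_connected=n_connected,
        n_isolated=n_isolated,
        ratio=ratio,
        z_score=z,
        null_mean=null_mean,
        null_sd=null_sd,
        n_null=config.n_null,
        degenerate_null=degenerate,
    )


def operon_calls(call: DifferentialCall, operons) -> DifferentialCall:
    """Lift a gene-level call to operon level.

    An operon is called iff any member gene is called.  In posdge/negdge
    mode an operon with both up- and down-called members (a conflict that
    should not arise in curated data) is assigned by its largest-|logFC|
    member, with a warning.
    """
    unmapped = [gene for gene in call.genes if gene not in operons]
    if unmapped:
        raise ControlError(f"called genes missing from operon map: {sorted(unmapped)[:10]}")
    members: dict[str, list[str]] = {}
    for gene, op in operons.items():
        members.setdefault(op, []).append(gene)
    called_ops: set[str] = set()
    op_logfc: dict[str, float] = {}
    for op, genes in members.items():
        hit = [gene for gene in genes if gene in call.genes]
        if not hit:
            continue
        if call.mode in ("posdge", "negdge"):
            fcs = [call.logfc.get(gene, 0.0) for gene in genes
                   if gene in call.logfc
                   and abs(call.logfc.get(gene, 0.0)) > call.threshold]
            has_up = any(v > call.threshold for v in fcs)
            has_down = any(v < -call.threshold for v in fcs)
            if has_up and has_down:
                logger.warning(
                    "operon %s mixes up- and down-regulated members; "
                    "assigned by largest |logFC|", op,
                )
                best = max(fcs, key=abs)
                wanted_up = call.mode == "posdge"
                if (best > 0) != wanted_up:
                    continue
        called_ops.add(op)
        op_logfc[op] = max(
            (call.logfc.get(gene, 0.0) for gene in hit), key=abs, default=0.0
        )
    return DifferentialCall(
        contrast_id=call.contrast_id,
        mode=call.mode,
        threshold=call.threshold,
        genes=called_ops,
        logfc=op_logfc,
    )


def operon_contrasts(contrasts: pd.DataFrame, operons) -> pd.DataFrame:
    """Lift a gene-level logFC matrix to operon level.

    Each operon takes its largest-|logFC| member per contrast, so an operon
    passes a threshold iff some member does — the matrix analogue of
    :func:`operon_calls` (and of its conflict rule in one-sided modes).
    """
    ops = pd.Series({g: operons[g] for g in contrasts.index if g in operons},
                    name="operon_id")
    missing = len(contrasts.index) - len(ops)
    if missing:
        logger.warning("operon_contrasts: %d gene(s) not in operon map dropped",
                       missing)
    sub = contrasts.loc[ops.index]

    def dominant(col):
        order = col.abs().fillna(-1.0).groupby(ops).idxmax()
        return pd.Series(col.loc[order].to_numpy(), index=order.index)

    out = sub.apply(dominant)
    out.index.name = "gene_id"
    return out


def control_scan(
    contrasts: pd.DataFrame,
    trn: nx.DiGraph,
    gpn: nx.Graph,
    config: AnalysisConfig,
    mode: str = "absdge",
) -> tuple[pd.DataFrame, float]:
    """Digital and analog CTC per contrast, plus their Spearman correlation.

    ``contrasts`` is a genes x contrasts logFC table.  Contrasts with no
    called genes in either universe are skipped and logged.  Returns the
    per-contrast result table and Spearman(digital CTC, analog CTC) with
    average ranks on ties.
    """
    if contrasts.shape[1] < 2:
        raise ControlError("need at least 2 contrasts for the correlation")
    rng = np.random.default_rng(config.seed)
    trn_universe = list(trn.nodes)
    gpn_universe = list(gpn.nodes)
    rows = []
    for cid in contrasts.columns:
        call = differential_calls(contrasts[cid], config.t_fc, mode, str(cid))
        try:
            dig = ctc(trn, call.genes, trn_universe, config, "digital",
                      contrast_id=str(cid), rng=rng)
            ana = ctc(gpn, call.genes, gpn_universe, config, "analog",
                      contrast_id=str(cid), rng=rng)
        except ControlError as exc:
            logger.info("skipping contrast %s: %s", cid, exc)
            continue
        rows.append(
            {
                "contrast_id": str(cid),
                "mode": mode,
                "n_called": len(call.genes),
                "digital_ctc": dig.z_score,
                "analog_ctc": ana.z_score,
                "digital_ratio": dig.ratio,
                "analog_ratio": ana.ratio,
                "digital_null_mean": dig.null_mean,
                "digital_null_sd": dig.null_sd,
                "analog_null_mean": ana.null_mean,
                "analog_null_sd": ana.null_sd,
            }
        )
    if not rows:
        raise ControlError("all contrasts had empty calls")
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        rho = float(spearmanr(table["digital_ctc"], table["analog_ctc"]).statistic)
    else:
        rho = float("nan")
    return table, rho
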