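"""Synthetic genomes, regulatory networks, binding sites, and contrasts.

The generators emulate the statistical structure of the real inputs at desk
scale: a circular genome with (optionally) nonuniform gene density, a
hub-dominated disassortative TRN, binding sites clustered near a factor's
targets, and logFC contrast matrices whose differentially expressed gene
sets arise from a controllable mixture of two mechanisms:

* **digital** seed events pick a regulator and spread the call to its TRN
  targets (each with probability ``p_d``);
* **analog** seed events pick a chromosomal focal position and call genes
  within a window ``w_a`` (each with probability ``p_a``).

The mixing parameter ``lam`` (lambda) interpolates: 1 = pure digital,
0 = pure analog.  Background calls occur at rate ``rho``.  By default the
logFC magnitudes of called genes are kept strictly above the call threshold
(and uncalled genes strictly below), so threshold calls recover the ground
truth exactly; ``noisy=True`` relaxes this.

All generators are deterministic given spec + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .genome_networks import (
    CircularGenome,
    GeneRecord,
    build_gpn,
    circular_distance_array,
    write_edges,
    write_genome,
)

logger = logging.getLogger(__name__)


class GeneratorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(
    n_genes: int,
    g: int,
    density_profile: str = "uniform",
    seed: int | None = None,
    n_clusters: int = 2,
    cluster_sd: float | None = None,
) -> CircularGenome:
    """Random circular genome with distinct integer gene centres.

    ``clustered`` draws centres from a mixture of wrapped normals around
    ``n_clusters`` random cluster centres (sd defaults to g / 8 / n_clusters)
    to emulate nonuniform gene density.  Genes get odd lengths in
    [301, 2999] bp so centres stay integral; wrap-around genes occur
    naturally near the origin.
    """
    if n_genes < 1:
        raise GeneratorError("n_genes must be >= 1")
    if g <= n_genes:
        raise GeneratorError(f"genome length {g} too short for {n_genes} genes")
    rng = np.random.default_rng(seed)
    if density_profile == "uniform":
        centers = rng.choice(g, size=n_genes, replace=False)
    elif density_profile == "clustered":
        sd = cluster_sd if cluster_sd is not None else g / (8 * n_clusters)
        anchors = rng.uniform(0, g, size=n_clusters)
        chosen: set[int] = set()
        while len(chosen) < n_genes:
            a = anchors[rng.integers(n_clusters)]
            c = int(np.floor(a + rng.normal(0, sd))) % g
            chosen.add(c)
        centers = np.array(sorted(chosen))
        centers = centers[rng.permutation(n_genes)] if len(centers) == n_genes \
            else centers[:n_genes]
    else:
        raise GeneratorError(f"unknown density_profile {density_profile!r}")
    lengths = 2 * rng.integers(150, 1500, size=n_genes) + 1   # odd, 301..2999
    records = []
    for i, (c, length) in enumerate(zip(centers, lengths)):
        halfspan = (length - 1) // 2
        start = int((c - halfspan) % g)
        end = int((c + halfspan) % g)
        records.append(GeneRecord.make(f"g{i:04d}", start, end, g))
    return CircularGenome(g, records)


# ---------------------------------------------------------------------------
# TRN
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrnGeneratorSpec:
    """Hub-dominated directed network: ``n_hubs`` regulators carry edge
    weight ``concentration`` each (non-hubs weight 1) when edge sources are
    drawn, so most regulation emanates from a few hubs."""

    n_genes: int
    n_edges: int
    n_hubs: int = 20
    concentration: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_edges > self.n_genes * (self.n_genes - 1):
            raise GeneratorError("n_edges exceeds the number of ordered pairs")
        if self.n_hubs < 1 or self.n_hubs > self.n_genes:
            raise GeneratorError("n_hubs must be in [1, n_genes]")


def generate_trn(spec: TrnGeneratorSpec, gene_ids=None) -> nx.DiGraph:
    """Random hub-dominated TRN: no self-loops, no duplicate edges, exact
    edge count.  Hub gene ids are recorded in ``graph.graph['hubs']``."""
    rng = np.random.default_rng(spec.seed)
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]
    gene_ids = list(gene_ids)
    if len(gene_ids) != spec.n_genes:
        raise GeneratorError("gene_ids length must equal n_genes")
    n = spec.n_genes
    hubs = rng.choice(n, size=spec.n_hubs, replace=False)
    if np.isinf(spec.concentration):
        src_pool, src_p = hubs, np.full(spec.n_hubs, 1.0 / spec.n_hubs)
    else:
        w = np.ones(n)
        w[hubs] = spec.concentration
        src_pool, src_p = np.arange(n), w / w.sum()
    edges: set[tuple[int, int]] = set()
    attempts, cap = 0, 200 * spec.n_edges + 1000
    while len(edges) < spec.n_edges:
        if attempts > cap:
            raise GeneratorError(
                f"could not place {spec.n_edges} edges after {attempts} attempts"
            )
        attempts += 1
        s = int(rng.choice(src_pool, p=src_p))
        t = int(rng.integers(n))
        if s != t:
            edges.add((s, t))
    graph = nx.DiGraph()
    graph.add_nodes_from(gene_ids)
    graph.add_edges_from((gene_ids[s], gene_ids[t]) for s, t in sorted(edges))
    graph.graph["hubs"] = [gene_ids[h] for h in sorted(hubs)]
    return graph


# ---------------------------------------------------------------------------
# binding sites
# ---------------------------------------------------------------------------

def generate_binding_sites(
    genome: CircularGenome,
    n_sites: int,
    placement: str = "uniform",
    trn: nx.DiGraph | None = None,
    factor_gene: str | None = None,
    seed: int | None = None,
    jitter_sd: float = 5_000.0,
) -> np.ndarray:
    """Site centre positions: uniform, or normal-jittered around the TRN
    targets of ``factor_gene`` ('near-targets')."""
    if n_sites < 0:
        raise GeneratorError("n_sites must be >= 0")
    rng = np.random.default_rng(seed)
    g = genome.length_bp
    if n_sites == 0:
        return np.empty(0, dtype=np.int64)
    if placement == "uniform":
        return rng.integers(0, g, size=n_sites)
    if placement == "near-targets":
        if trn is None or factor_gene is None or factor_gene not in trn:
            raise GeneratorError(
                f"near-targets placement needs a TRN containing {factor_gene!r}"
            )
        targets = list(trn.successors(factor_gene))
        if not targets:
            raise GeneratorError(f"factor {factor_gene!r} has no TRN targets")
        centers = genome.centers
        anchors = np.array([centers[t] for t in targets])
        picks = anchors[rng.integers(len(anchors), size=n_sites)]
        return (np.round(picks + rng.normal(0, jitter_sd, size=n_sites))
                .astype(np.int64) % g)
    raise GeneratorError(f"unknown placement {placement!r}")


def write_binding_sites(positions, path) -> None:
    pd.DataFrame(
        {"site_id": [f"s{i:05d}" for i in range(len(positions))],
         "position": np.asarray(positions, dtype=np.int64)}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastGeneratorSpec:
    """Mixture model for differentially expressed gene sets.

    lam:   probability that a seed event is digital (1 = pure digital).
    n_seed_events: seed events per contrast.
    p_d:   per-target call probability in a digital event.
    w_a:   circular half-window (bp) of an analog event.
    p_a:   per-gene call probability within an analog window.
    rho:   background call rate.
    mu_fc/sigma_fc: |logFC| distribution of called genes (truncated above
           t_fc unless noisy).
    sigma_0: logFC sd of uncalled genes (truncated to |logFC| <= t_fc
           unless noisy).
    """

    lam: float = 0.5
    n_seed_events: int = 2
    p_d: float = 0.5
    w_a: float = 15_000.0
    p_a: float = 0.5
    rho: float = 0.001
    mu_fc: float = 4.0
    sigma_fc: float = 0.5
    sigma_0: float = 0.5
    t_fc: float = 2.5
    min_reg_degree: int = 10
    noisy: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("lam", "p_d", "p_a", "rho"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise GeneratorError(f"{name} must be in [0, 1], got {v}")
        if self.mu_fc <= self.t_fc:
            raise GeneratorError("mu_fc must exceed t_fc")


def generate_contrasts(
    genome: CircularGenome,
    trn: nx.DiGraph,
    gpn: nx.Graph,
    spec: ContrastGeneratorSpec,
    n_contrasts: int,
) -> tuple[pd.DataFrame, dict[str, set[str]], dict[str, list[dict]]]:
    """logFC matrix (genes x contrasts), ground-truth call sets, and the
    per-contrast seed-event log (mechanism, regulator or focal position)."""
    rng = np.random.default_rng(spec.seed)
    gene_ids = genome.gene_ids
    n = len(gene_ids)
    centers = np.array([r.center_bp for r in genome.genes])
    g = genome.length_bp
    # digital seed events perturb a global regulator: restrict the pool to
    # regulators with substantial regulons so event sizes are comparable to
    # analog windows (falls back to all regulators on sparse TRNs)
    pool = [u for u in trn.nodes if trn.out_degree(u) >= spec.min_reg_degree]
    if not pool:
        pool = [u for u in trn.nodes if trn.out_degree(u) > 0]
    if spec.lam > 0 and not pool:
        raise GeneratorError("digital events need a TRN with regulators")
    index = {gid: i for i, gid in enumerate(gene_ids)}
    mat = np.zeros((n, n_contrasts))
    truth: dict[str, set[str]] = {}
    events: dict[str, list[dict]] = {}
    for j in range(n_contrasts):
        cid = f"c{j:04d}"
        called = np.zeros(n, dtype=bool)
        log: list[dict] = []
        for _ in range(spec.n_seed_events):
            if rng.random() < spec.lam:
                reg = pool[rng.integers(len(pool))]
                called[index[reg]] = True
                for tgt in trn.successors(reg):
                    if rng.random() < spec.p_d:
                        called[index[tgt]] = True
                log.append({"mechanism": "digital", "regulator": reg})
            else:
                focal = float(rng.uniform(0, g))
                near = circular_distance_array(centers, focal, g) <= spec.w_a
                hits = near & (rng.random(n) < spec.p_a)
                called |= hits
                log.append({"mechanism": "analog", "focal_bp": focal})
        called |= rng.random(n) < spec.rho
        truth[cid] = {gene_ids[i] for i in np.nonzero(called)[0]}
        events[cid] = log
        mat[:, j] = _draw_logfc(called, spec, rng)
    df = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"),
                      columns=[f"c{j:04d}" for j in range(n_contrasts)])
    return df, truth, events


def _draw_logfc(called: np.ndarray, spec: ContrastGeneratorSpec,
                rng: np.random.Generator) -> np.ndarray:
    n = len(called)
    k = int(called.sum())
    out = np.empty(n)
    sign = rng.choice([-1.0, 1.0], size=k)
    if spec.noisy:
        mag = rng.normal(spec.mu_fc, spec.sigma_fc, size=k)
        noise = rng.normal(0, spec.sigma_0, size=n - k)
    else:
        a = (spec.t_fc - spec.mu_fc) / spec.sigma_fc
        mag = truncnorm.rvs(a, np.inf, loc=spec.mu_fc, scale=spec.sigma_fc,
                            size=k, random_state=rng)
        mag = np.maximum(mag, np.nextafter(spec.t_fc, np.inf))
        b = spec.t_fc / spec.sigma_0
        noise = truncnorm.rvs(-b, b, loc=0, scale=spec.sigma_0,
                              size=n - k, random_state=rng)
        noise = np.clip(noise, np.nextafter(-spec.t_fc, 0),
                        np.nextafter(spec.t_fc, 0))
    out[called] = sign * mag
    out[~called] = noise
    return out


def write_contrasts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def load_contrasts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
    return df.astype(float)


# ---------------------------------------------------------------------------
# dataset presets
# ---------------------------------------------------------------------------

def simulate_dataset(
    out_dir,
    lam: float = 0.5,
    n_contrasts: int = 40,
    seed: int | None = None,
    n_genes: int = 2000,
    g: int = 2_000_000,
    n_edges: int = 5000,
    n_hubs: int = 20,
    t_gpn: int = 20_000,
    n_sites: int = 300,
    density_profile: str = "uniform",
) -> dict[str, Path]:
    """Write a complete synthetic dataset (genes, edges, sites, contrasts,
    ground truth) in the standard table formats; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seeds = {name: int(rng.integers(2**31 - 1))
             for name in ("genome", "trn", "sites", "contrasts")}
    genome = generate_genome(n_genes, g, density_profile, seed=seeds["genome"])
    trn = generate_trn(
        TrnGeneratorSpec(n_genes, n_edges, n_hubs, seed=seeds["trn"]),
        gene_ids=genome.gene_ids,
    )
    gpn = build_gpn(genome, t_gpn)
    # name three hub genes after the global regulators so the dig_cont
    # features are live in synthetic data
    contrasts, truth, events = generate_contrasts(
        genome, trn, gpn,
        ContrastGeneratorSpec(lam=lam, seed=seeds["contrasts"]),
        n_contrasts,
    )
    files = {}
    files["genes"] = out / "genes.tsv"
    write_genome(genome, files["genes"])
    files["edges"] = out / "edges.tsv"
    write_edges(trn, files["edges"])
    site_rng = np.random.default_rng(seeds["sites"])
    hubs = trn.graph.get("hubs", [])[:3]
    for i, factor in enumerate(("fis", "hns", "crp")):
        if i < len(hubs):
            pos = generate_binding_sites(
                genome, n_sites, "near-targets", trn, hubs[i],
                seed=int(site_rng.integers(2**31 - 1)),
            )
        else:
            pos = generate_binding_sites(
                genome, n_sites, "uniform",
                seed=int(site_rng.integers(2**31 - 1)),
            )
        files[f"sites_{factor}"] = out / f"sites_{factor}.tsv"
        write_binding_sites(pos, files[f"sites_{factor}"])
    files["contrasts"] = out / "contrasts.tsv"
    write_contrasts(contrasts, files["contrasts"])
    files["truth"] = out / "truth.json"
    files["truth"].write_text(json.dumps(
        {"called": {cid: sorted(genes) for cid, genes in truth.items()},
         "events": events},
        indent=0,
    ))
    files["factors"] = out / "factors.tsv"
    with open(files["factors"], "w") as fh:
        fh.write("factor\tgene_id\n")
        for i, factor in enumerate(("fis", "hns", "crp")):
            if i < len(hubs):
                fh.write(f"{factor}\t{hubs[i]}\n")
    return files
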