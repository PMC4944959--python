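"""Synthetic benchmark instances with planted guilt-by-association structure.

Real evaluations of phenotype networks rest on an empirical regularity:
genes associated with phenotypically similar diseases tend to encode
proteins that are close in the PPI network.  The generator plants exactly
that structure so every pipeline stage can be exercised end to end without
external downloads:

* a connected, simple, scale-free-like PPI graph (preferential attachment);
* disease modules, each anchored at a PPI node whose breadth-first
  neighborhood forms the module's gene pool;
* diseases drawing their causal genes from their module's pool;
* a phenotype similarity matrix whose within-module similarities are drawn
  with a higher mean than between-module ones (truncated normal, clipped to
  [0, 1]), with the diagonal set to each row's off-diagonal maximum so that
  self-similarity dominates and Lin/Sqrt/Tanimoto stay within [0, 1];
* optional additive noise that breaks symmetry, emulating asymmetric
  pairwise exports.

A label-permutation control (:func:`permute_labels`) destroys the
disease-to-gene alignment while preserving the value distribution, giving
the null against which planted-structure recovery is measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .evaluation import DiseaseGeneMap
from .exceptions import DegenerateInputError
from .propagation import GeneNet
from .similarity import PhenotypeNet


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; output is deterministic given ``seed``.

    Defaults describe a mid-sized instance: 500 genes in a
    preferential-attachment PPI (3 edges per new node), 100 diseases in 10
    modules, within-module similarity around 0.6 versus 0.1 between
    modules, 1-3 causal genes per disease, and an exactly symmetric
    phenotype matrix (``asym_noise=0``).
    """

    n_genes: int = 500
    n_diseases: int = 100
    n_modules: int = 10
    edges_per_node: int = 3
    within_sim: tuple[float, float] = (0.6, 0.1)
    between_sim: tuple[float, float] = (0.1, 0.05)
    genes_per_disease: tuple[int, int] = (1, 3)
    module_pool_size: int = 15
    asym_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules > self.n_diseases:
            raise ValueError("n_modules must not exceed n_diseases")
        for name, (mean, _sd) in (
            ("within_sim", self.within_sim),
            ("between_sim", self.between_sim),
        ):
            if not 0.0 < mean < 1.0:
                raise ValueError(f"{name} mean must lie in (0, 1)")
        lo, hi = self.genes_per_disease
        if not 1 <= lo <= hi:
            raise ValueError("genes_per_disease must be a nondecreasing range >= 1")
        if self.asym_noise < 0:
            raise ValueError("asym_noise must be >= 0")


def gen_ppi(cfg: SynthConfig) -> GeneNet:
    """Connected simple PPI graph grown by preferential attachment."""
    if not 1 <= cfg.edges_per_node < cfg.n_genes:
        raise DegenerateInputError(
            f"edges_per_node={cfg.edges_per_node} infeasible for "
            f"{cfg.n_genes} genes"
        )
    G = nx.barabasi_albert_graph(cfg.n_genes, cfg.edges_per_node, seed=cfg.seed)
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    rows, cols = zip(*G.edges())
    data = np.ones(len(rows))
    A = sp.coo_matrix(
        (np.r_[data, data], (np.r_[rows, cols], np.r_[cols, rows])),
        shape=(cfg.n_genes, cfg.n_genes),
    ).tocsr()
    return GeneNet(gene_ids, A)


def _module_pools(cfg: SynthConfig, ppi: GeneNet, rng: np.random.Generator) -> list[list[int]]:
    G = nx.from_scipy_sparse_array(ppi.adjacency)
    if not nx.is_connected(G):
        raise DegenerateInputError("PPI graph must be connected")
    pool_size = min(cfg.module_pool_size, cfg.n_genes)
    anchors = rng.choice(cfg.n_genes, size=cfg.n_modules, replace=False)
    pools = []
    for a in anchors:
        # BFS order from the anchor gives a PPI-proximal gene neighborhood
        order = [int(a)] + [int(v) for _u, v in nx.bfs_edges(G, int(a))]
        pools.append(order[:pool_size])
    return pools


def gen_disease_model(
    cfg: SynthConfig, ppi: GeneNet
) -> tuple[PhenotypeNet, DiseaseGeneMap]:
    """Phenotype network plus disease-gene map aligned with PPI modules.

    Disease i belongs to module ``i % n_modules``; its genes are a sample
    (without replacement) from the module's BFS gene pool.  Pairwise
    similarities are drawn from truncated normals with within- or
    between-module parameters; the diagonal is set to each row's
    off-diagonal maximum.
    """
    rng = np.random.default_rng((cfg.seed, 211))
    pools = _module_pools(cfg, ppi, rng)
    gmin, gmax = cfg.genes_per_disease
    if any(len(p) < gmax for p in pools):
        raise DegenerateInputError(
            "module gene pool smaller than genes_per_disease maximum"
        )
    disease_ids = [f"D{i:04d}" for i in range(cfg.n_diseases)]
    modules = np.arange(cfg.n_diseases) % cfg.n_modules

    pairs = []
    for i, d in enumerate(disease_ids):
        k = int(rng.integers(gmin, gmax + 1))
        chosen = rng.choice(pools[modules[i]], size=k, replace=False)
        pairs.extend((d, ppi.gene_ids[int(g)]) for g in chosen)

    n = cfg.n_diseases
    same = modules[:, None] == modules[None, :]
    iu = np.triu_indices(n, k=1)
    means = np.where(same[iu], cfg.within_sim[0], cfg.between_sim[0])
    sds = np.where(same[iu], cfg.within_sim[1], cfg.between_sim[1])
    vals = np.clip(rng.normal(means, sds), 0.0, 1.0)
    S = np.zeros((n, n))
    S[iu] = vals
    S = S + S.T
    symmetric = cfg.asym_noise == 0.0
    if not symmetric:
        noise = rng.normal(0.0, cfg.asym_noise, size=(n, n))
        np.fill_diagonal(noise, 0.0)
        S = np.clip(S + noise, 0.0, 1.0)
    off = S.copy()
    np.fill_diagonal(off, -np.inf)
    np.fill_diagonal(S, off.max(axis=1))
    return PhenotypeNet(disease_ids, S, symmetric=symmetric), DiseaseGeneMap(pairs)


def generate(cfg: SynthConfig) -> tuple[GeneNet, PhenotypeNet, DiseaseGeneMap]:
    """Convenience wrapper: PPI, phenotype network and association map."""
    ppi = gen_ppi(cfg)
    phenonet, dgmap = gen_disease_model(cfg, ppi)
    return ppi, phenonet, dgmap


def permute_labels(
    net: PhenotypeNet, seed: int | None = None, perm: np.ndarray | None = None
) -> PhenotypeNet:
    """Null control: permute disease labels jointly over rows and columns.

    The similarity value multiset (and each row-sum multiset) is preserved,
    but the alignment between disease labels and similarity structure is
    destroyed, so any prioritization signal attributable to phenotype
    similarity should vanish.  Either a ``seed`` (random permutation) or an
    explicit ``perm`` index array may be given.
    """
    if perm is None:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(net.n)
    else:
        perm = np.asarray(perm, dtype=int)
        if sorted(perm.tolist()) != list(range(net.n)):
            raise ValueError("perm is not a permutation of the disease indices")
    scores = net.scores[np.ix_(perm, perm)]
    return PhenotypeNet(list(net.disease_ids), scores, symmetric=net.symmetric)
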