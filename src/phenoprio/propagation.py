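"""PRINCE label propagation over a protein-protein interaction network.

Gene prioritization by guilt-by-association: a phenotype-informed prior Y
over the genes of a PPI network is smoothed by the iteration

    F(t) = alpha * W_norm @ F(t-1) + (1 - alpha) * Y,      F(1) = Y,

where ``W_norm = D^(-1/2) A D^(-1/2)`` is the symmetric degree-normalized
adjacency (spectral radius <= 1, so the iteration contracts for alpha < 1
and its fixed point is ``(1 - alpha) (I - alpha W_norm)^(-1) Y``).  The prior
assigns 1 to known (seed) genes of the query disease and, to every other
gene, the calibrated similarity between the query and the most similar
disease that gene is associated with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .exceptions import DegenerateInputError, NumericError
from .similarity import Form, PhenotypeNet, query_similarities

if TYPE_CHECKING:  # pragma: no cover
    from .evaluation import DiseaseGeneMap

logger = logging.getLogger(__name__)


@dataclass
class GeneNet:
    """Undirected weighted gene-gene interaction network.

    ``adjacency`` is a sparse symmetric nonnegative matrix with empty
    diagonal (no self-interactions); the degree-normalized form is computed
    lazily and cached.
    """

    gene_ids: list[str]
    adjacency: sp.spmatrix
    _index: dict[str, int] = field(init=False, repr=False, compare=False)
    _w_norm: sp.csr_matrix | None = field(
        default=None, init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        n = len(self.gene_ids)
        A = sp.csr_matrix(self.adjacency, dtype=float)
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} != ({n}, {n})")
        if A.diagonal().any():
            raise ValueError("adjacency must have no self-loops")
        if A.nnz and A.min() < 0:
            raise ValueError("adjacency weights must be nonnegative")
        asym = abs(A - A.T)
        if asym.nnz and asym.max() > 1e-12:
            raise ValueError("adjacency must be symmetric")
        self.adjacency = A
        self._index = {g: i for i, g in enumerate(self.gene_ids)}
        if len(self._index) != n:
            raise ValueError("gene_ids contains duplicates")

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in network") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degree of every gene."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def normalized_adjacency(self) -> sp.csr_matrix:
        """Symmetric degree normalization D^(-1/2) A D^(-1/2), cached.

        Isolated genes keep zero rows/columns.
        """
        if self._w_norm is None:
            deg = self.degrees
            with np.errstate(divide="ignore"):
                inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
            D = sp.diags(inv_sqrt)
            self._w_norm = sp.csr_matrix(D @ self.adjacency @ D)
        return self._w_norm


def normalize_adjacency(net: GeneNet) -> sp.csr_matrix:
    """Functional alias for :meth:`GeneNet.normalized_adjacency`."""
    return net.normalized_adjacency()


@dataclass
class ScoreVector:
    """Per-gene scores aligned to a :class:`GeneNet` node order."""

    values: np.ndarray
    kind: str = "prior"  # "prior" or "propagated"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind == "prior" and self.values.size:
            lo, hi = self.values.min(), self.values.max()
            if lo < 0 or hi > 1:
                raise ValueError(f"prior values must lie in [0, 1], got [{lo}, {hi}]")


@dataclass(frozen=True)
class PropagationParams:
    """Propagation controls: restart weight, convergence tolerance, cap.

    ``alpha`` weights network smoothing against the prior (0.9 default —
    propagation is insensitive to alpha above 0.5); iteration stops when the
    L1 difference of successive iterates falls below ``tol`` or after
    ``max_iter`` updates.
    """

    alpha: float = 0.9
    tol: float = 1e-9
    max_iter: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be positive and max_iter >= 1")


@dataclass
class PropagationResult:
    scores: ScoreVector
    n_iter: int
    converged: bool


def propagate(
    net: GeneNet, prior: ScoreVector, params: PropagationParams | None = None
) -> PropagationResult:
    """Iterate F(t) = alpha*W_norm@F(t-1) + (1-alpha)*Y from F(1) = Y.

    Stops when the L1 norm of F(t) - F(t-1) drops below ``params.tol`` or
    ``params.max_iter`` updates have been applied, whichever comes first.
    """
    params = params or PropagationParams()
    y = np.asarray(prior.values, dtype=float)
    if y.shape != (net.n,):
        raise ValueError(f"prior length {y.shape} does not match network size {net.n}")
    W = net.normalized_adjacency()
    restart = (1.0 - params.alpha) * y
    F = y.copy()
    converged = False
    n_iter = 0
    for t in range(params.max_iter):
        F_next = params.alpha * (W @ F) + restart
        diff = float(np.abs(F_next - F).sum())
        if not np.isfinite(diff):
            raise NumericError(
                "propagation diverged (non-finite values); is W normalized?"
            )
        F = F_next
        n_iter = t + 1
        if diff < params.tol:
            converged = True
            break
    return PropagationResult(ScoreVector(F, kind="propagated"), n_iter, converged)


def closed_form_propagate(
    net: GeneNet, prior: ScoreVector, alpha: float
) -> ScoreVector:
    """Fixed point of the propagation: solve (I - alpha*W_norm) F = (1-alpha) Y.

    Valid whenever the spectral radius of ``alpha * W_norm`` is below 1,
    which holds for alpha < 1 since the normalized adjacency has spectral
    radius at most 1.  Serves as the exact reference for the iterative
    solver.
    """
    y = np.asarray(prior.values, dtype=float)
    if y.shape != (net.n,):
        raise ValueError(f"prior length {y.shape} does not match network size {net.n}")
    if alpha == 0.0:
        return ScoreVector(y.copy(), kind="propagated")
    W = net.normalized_adjacency()
    A = sp.eye(net.n, format="csc") - alpha * sp.csc_matrix(W)
    F = spla.spsolve(A, (1.0 - alpha) * y)
    if not np.all(np.isfinite(F)):
        raise DegenerateInputError("propagation system is singular")
    return ScoreVector(np.asarray(F, dtype=float), kind="propagated")


# ---------------------------------------------------------------------------
# Phenotype-informed prior and ranking
# ---------------------------------------------------------------------------


def build_prior(
    query: str,
    dgmap: "DiseaseGeneMap",
    phenonet: PhenotypeNet,
    form: Form,
    genes: GeneNet,
    seed_value: float = 1.0,
) -> ScoreVector:
    """Prior Y over PPI genes for a query disease.

    Seed genes — genes associated with the query in ``dgmap`` — get
    ``seed_value`` (1 by default: a direct association is certain evidence).
    Every other gene gets the maximum calibrated similarity between the
    query and any other disease the gene is associated with (the
    most-similar-disease rule keeps Y <= 1); genes with no disease
    association get 0.  Association genes absent from the PPI are dropped
    with a logged warning.  ``phenonet`` is expected post-calibration.
    """
    if query not in phenonet:
        raise KeyError(f"query disease {query!r} not in phenotype network")
    sim = query_similarities(phenonet, query, form)
    y = np.zeros(genes.n)
    n_dropped = 0
    for disease, gene in dgmap.associations:
        if gene not in genes:
            n_dropped += 1
            continue
        if disease == query or disease not in phenonet:
            continue
        gi = genes.index(gene)
        s = sim[phenonet.index(disease)]
        if s > y[gi]:
            y[gi] = s
    y = np.clip(y, 0.0, 1.0)
    for gene in dgmap.genes_of(query):
        if gene in genes:
            y[genes.index(gene)] = seed_value
    if n_dropped:
        logger.warning(
            "build_prior: dropped %d association(s) with genes absent from the PPI",
            n_dropped,
        )
    return ScoreVector(y, kind="prior")


def competition_rank(scores: np.ndarray, target_idx: int) -> int:
    """Pessimistic competition rank of one entry among ``scores``.

    The target is placed after every competitor with a strictly greater or
    equal score, i.e. rank = #{s > s_target} + #{s == s_target} (the target
    itself included).  A unique maximum gets rank 1; tied entries all get
    the shared worst rank, which keeps the evaluation conservative and
    reproducible.
    """
    s = scores[target_idx]
    return int(np.count_nonzero(scores > s) + np.count_nonzero(scores == s))


def prioritize(
    query: str,
    dgmap: "DiseaseGeneMap",
    phenonet: PhenotypeNet,
    form: Form,
    genes: GeneNet,
    candidates: Iterable[str] | None = None,
    params: PropagationParams | None = None,
    seed_value: float = 1.0,
) -> list[tuple[str, float]]:
    """Rank candidate genes for a query disease, best first.

    Seeds (known genes of the query) drive the prior but are excluded from
    the ranked output.  ``candidates`` defaults to every PPI gene that is
    not a seed; an explicit candidate list (e.g. the genes of a linkage
    interval) is restricted the same way.  Ties are ordered by gene
    identifier for determinism; note that rank-based evaluation uses the
    pessimistic :func:`competition_rank` instead of list positions.
    """
    seeds = {g for g in dgmap.genes_of(query) if g in genes}
    if candidates is None:
        cand = [g for g in genes.gene_ids if g not in seeds]
    else:
        cand = [g for g in candidates if g not in seeds]
        missing = [g for g in cand if g not in genes]
        if missing:
            raise KeyError(f"candidate gene(s) not in PPI network: {missing[:5]}")
    if not cand:
        raise DegenerateInputError("empty candidate set")
    prior = build_prior(query, dgmap, phenonet, form, genes, seed_value=seed_value)
    result = propagate(genes, prior, params)
    F = result.scores.values
    scored = [(g, float(F[genes.index(g)])) for g in cand]
    scored.sort(key=lambda gs: (-gs[1], gs[0]))
    return scored
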