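"""Disease phenotype similarity networks.

A disease phenotype network (DPN) is a weighted network whose nodes are
diseases (e.g. OMIM entries) and whose edge weights are phenotype-similarity
scores.  Two input dialects exist in practice: dense symmetric matrices with
values already in [0, 1] (mimMiner-style) and possibly asymmetric,
unbounded pairwise-score exports (resnikHPO-style).  This module provides the
container plus every matrix-level transformation the evaluation pipeline
needs:

* symmetrization (arithmetic mean of the two directed scores),
* range normalization (Lin, Sqrt, Maxmin, Tanimoto),
* logistic calibration ``L(x) = 1 / (1 + exp(c*x + d))`` with ``d = ln 9999``,
* convex combination of two aligned networks,
* restriction of two networks to their common disease set,
* the relative-network-mean diagnostic (mean per-disease row-sum ratio
  against a reference network).

Normalization is computed once on the stored matrix.  The row/column ("-R" /
"-C") reading of an asymmetric network is a read-direction choice made when a
per-disease similarity vector is extracted (see :func:`query_similarities`),
not a separate normalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
import numpy as np

from .exceptions import AlignmentError, DegenerateInputError

logger = logging.getLogger(__name__)

#: offset of the logistic calibration; forces L(0) = 1/(1 + 9999) = 1e-4
LOGISTIC_D = math.log(9999.0)

NORMALIZATION_METHODS = ("lin", "sqrt", "maxmin", "tanimoto")


class Form(str, Enum):
    """How per-disease similarities are read from a (possibly asymmetric) DPN.

    ``ROW`` reads Sim(query -> other) along the query's row, ``COL`` reads
    Sim(other -> query) down the query's column; on a symmetric network the
    two coincide and ``SYMMETRIC`` is the only valid choice.
    """

    ROW = "row"
    COL = "col"
    SYMMETRIC = "symmetric"


@dataclass
class PhenotypeNet:
    """Square labeled matrix of disease-disease similarity scores.

    Parameters
    ----------
    disease_ids
        Ordered unique disease identifiers (opaque strings, typically
        6-digit OMIM numbers).
    scores
        Square real matrix, entry (i, j) the similarity of disease i toward
        disease j.
    symmetric
        Whether ``scores`` is exactly symmetric.  Symmetrization averages
        stored values, so the flag promises exact equality, not a tolerance.
    """

    disease_ids: list[str]
    scores: np.ndarray
    symmetric: bool = False
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.disease_ids = [str(d) for d in self.disease_ids]
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.disease_ids)
        if self.scores.shape != (n, n):
            raise ValueError(
                f"scores has shape {self.scores.shape}, expected ({n}, {n})"
            )
        self._index = {d: i for i, d in enumerate(self.disease_ids)}
        if len(self._index) != n:
            raise ValueError("disease_ids contains duplicates")

    @property
    def n(self) -> int:
        return len(self.disease_ids)

    @property
    def value_range(self) -> tuple[float, float]:
        """(min, max) actually observed in the matrix."""
        return float(self.scores.min()), float(self.scores.max())

    def index(self, disease: str) -> int:
        try:
            return self._index[disease]
        except KeyError:
            raise KeyError(f"disease {disease!r} not in network") from None

    def __contains__(self, disease: str) -> bool:
        return disease in self._index


def _check_form(net: PhenotypeNet, form: Form) -> None:
    form = Form(form)
    if form is Form.SYMMETRIC and not net.symmetric:
        raise ValueError("form 'symmetric' requires a symmetric network")
    if form in (Form.ROW, Form.COL) and net.symmetric:
        raise ValueError(f"form {form.value!r} applies to an asymmetric network")


def query_similarities(net: PhenotypeNet, query: str, form: Form) -> np.ndarray:
    """Similarity of ``query`` with every disease, read per ``form``."""
    _check_form(net, form)
    i = net.index(query)
    if Form(form) is Form.COL:
        return net.scores[:, i].copy()
    return net.scores[i, :].copy()


# ---------------------------------------------------------------------------
# Symmetrization and normalization
# ---------------------------------------------------------------------------


def symmetrize(net: PhenotypeNet) -> PhenotypeNet:
    """Arithmetic-mean symmetrization: out[i,j] = (S[i,j] + S[j,i]) / 2."""
    out = (net.scores + net.scores.T) / 2.0
    return PhenotypeNet(list(net.disease_ids), out, symmetric=True)


def normalize(net: PhenotypeNet, method: str) -> PhenotypeNet:
    """Map a similarity matrix into [0, 1].

    ``lin``      2*S(A,B) / (S(A,A) + S(B,B))
    ``sqrt``     S(A,B) / sqrt(S(A,A) * S(B,B))
    ``maxmin``   (S(A,B) - S_min) / (S_max - S_min), extremes taken over the
                 whole matrix including the diagonal
    ``tanimoto`` S(A,B) / (S(A,A) + S(B,B) - S(A,B))

    Entries whose denominator is not strictly positive (e.g. a disease with
    zero self-similarity, which carries no phenotype evidence) are defined as
    0.  Values outside [0, 1] — possible for lin/sqrt/tanimoto when a
    cross-similarity exceeds a self-similarity in noisy input — are clipped
    with a warning, since downstream logistic calibration assumes [0, 1].
    """
    method = method.lower()
    if method not in NORMALIZATION_METHODS:
        raise ValueError(
            f"unknown method {method!r}; expected one of {NORMALIZATION_METHODS}"
        )
    S = net.scores
    if method == "maxmin":
        smin, smax = S.min(), S.max()
        if smax <= smin:
            raise DegenerateInputError(
                "maxmin normalization needs a non-constant matrix "
                f"(min == max == {smin})"
            )
        out = (S - smin) / (smax - smin)
    else:
        d = np.diag(S)
        if method == "lin":
            num = 2.0 * S
            den = d[:, None] + d[None, :]
        elif method == "sqrt":
            num = S
            with np.errstate(invalid="ignore"):
                den = np.sqrt(np.outer(d, d))
        else:  # tanimoto
            num = S
            den = d[:, None] + d[None, :] - S
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        n_out = int(np.count_nonzero((out < 0) | (out > 1)))
        if n_out:
            logger.warning(
                "%s normalization produced %d value(s) outside [0, 1]; clipped",
                method,
                n_out,
            )
            out = np.clip(out, 0.0, 1.0)
    return PhenotypeNet(list(net.disease_ids), out, symmetric=net.symmetric)


def logistic_transform(net: PhenotypeNet, c: float) -> PhenotypeNet:
    """Logistic calibration L(x) = 1 / (1 + exp(c*x + d)), d = ln(9999).

    With ``c < 0`` (the useful regime) the map is strictly increasing and
    sends 0 to 1e-4, sharpening the contrast between strong and weak
    similarities before they enter the propagation prior.
    """
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(c * net.scores + LOGISTIC_D))
    return PhenotypeNet(list(net.disease_ids), out, symmetric=net.symmetric)


def logistic(x, c: float):
    """Scalar/array form of the calibration used by :func:`logistic_transform`."""
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(c * np.asarray(x, dtype=float) + LOGISTIC_D))


# ---------------------------------------------------------------------------
# Combination, intersection and diagnostics
# ---------------------------------------------------------------------------


def _check_aligned(netA: PhenotypeNet, netB: PhenotypeNet) -> None:
    if netA.disease_ids != netB.disease_ids:
        raise AlignmentError(
            "networks carry different disease sets or orderings; "
            "use intersect_networks first"
        )


def combine(netA: PhenotypeNet, netB: PhenotypeNet, p: float) -> PhenotypeNet:
    """Entrywise convex combination p*A + (1-p)*B of two aligned networks.

    Both networks are expected on the [0, 1] scale; the combination is
    applied before logistic calibration so that a single C parameter is
    fitted to the combined network.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion p must be in [0, 1], got {p}")
    _check_aligned(netA, netB)
    if p == 1.0:
        out = netA.scores.copy()
    elif p == 0.0:
        out = netB.scores.copy()
    else:
        out = p * netA.scores + (1.0 - p) * netB.scores
    return PhenotypeNet(
        list(netA.disease_ids), out, symmetric=netA.symmetric and netB.symmetric
    )


def intersect_networks(
    netA: PhenotypeNet, netB: PhenotypeNet
) -> tuple[PhenotypeNet, PhenotypeNet]:
    """Restrict both networks to their common diseases, in sorted order."""
    common = sorted(set(netA.disease_ids) & set(netB.disease_ids))
    if not common:
        raise AlignmentError("networks share no disease identifiers")

    def _restrict(net: PhenotypeNet) -> PhenotypeNet:
        idx = np.array([net.index(d) for d in common])
        sub = net.scores[np.ix_(idx, idx)].copy()
        return PhenotypeNet(list(common), sub, symmetric=net.symmetric)

    return _restrict(netA), _restrict(netB)


def relative_network_mean(net: PhenotypeNet, reference: PhenotypeNet) -> float:
    """Mean over diseases of rowsum(net) / rowsum(reference).

    The total similarity of a disease is the sum of its row; the statistic
    averages, over diseases, the ratio of that total in ``net`` to the same
    total in ``reference``.  It equals 1 when ``net`` is the reference and
    tracks how concentrated the similarity mass of a network is relative to
    the reference.
    """
    _check_aligned(net, reference)
    rs_net = net.scores.sum(axis=1)
    rs_ref = reference.scores.sum(axis=1)
    bad = np.where(rs_ref <= 0)[0]
    if bad.size:
        raise DegenerateInputError(
            f"reference row sum not positive for disease "
            f"{reference.disease_ids[bad[0]]!r}"
        )
    return float(np.mean(rs_net / rs_ref))
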