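"""Readers and writers for the plain-text dialects the pipeline consumes.

Three kinds of input exist: disease phenotype networks (a dense labeled
matrix dialect and a sparse pairwise-score dialect), a PPI gene-gene edge
list, and a two-column disease-gene association table.  All files are
UTF-8 TSV with "." decimals; identifiers are treated as opaque strings
(OMIM numbers are not validated numerically, so Orphanet/DECIPHER-style
identifiers pass through unchanged).
"""

from __future__ import annotations

import logging
from pathlib import Path
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .evaluation import DiseaseGeneMap
from .exceptions import FormatError
from .propagation import GeneNet
from .similarity import PhenotypeNet

logger = logging.getLogger(__name__)

#: tolerance above which a dialect declared symmetric is rejected
SYMMETRY_TOL = 1e-9


# ---------------------------------------------------------------------------
# Phenotype networks
# ---------------------------------------------------------------------------


def read_dense_matrix(path: str | Path, symmetric: bool = True) -> PhenotypeNet:
    """Dense labeled matrix: first row and first column are disease IDs.

    With ``symmetric=True`` (the mimMiner-style contract) any asymmetry
    above 1e-9 raises :class:`FormatError`; sub-tolerance residuals are
    averaged away so the returned network is exactly symmetric.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip"
    )
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if len(set(row_ids)) != len(row_ids):
        raise FormatError(f"{path}: duplicate disease identifiers")
    if row_ids != col_ids:
        raise FormatError(f"{path}: row and column identifiers differ")
    try:
        scores = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    if symmetric:
        asym = np.abs(scores - scores.T).max() if scores.size else 0.0
        if asym > SYMMETRY_TOL:
            raise FormatError(
                f"{path}: declared symmetric but max asymmetry is {asym:g}"
            )
        scores = (scores + scores.T) / 2.0
    return PhenotypeNet(row_ids, scores, symmetric=symmetric)


def write_dense_matrix(net: PhenotypeNet, path: str | Path) -> None:
    df = pd.DataFrame(net.scores, index=net.disease_ids, columns=net.disease_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_pair_scores(path: str | Path) -> PhenotypeNet:
    """Pairwise-score dialect: disease-ID, disease-ID, score per line.

    Lines beginning with "#" are headers and skipped.  Pairs may be listed
    in one direction only and the matrix may be asymmetric and unbounded;
    unlisted pairs (including unlisted diagonal self-similarities) default
    to 0, which downstream normalization treats as absent evidence.  A pair
    listed twice with conflicting scores is an error.  The symmetric flag
    of the result reflects the actually assembled matrix.
    """
    seen: dict[tuple[str, str], float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 'disease disease score', got {line!r}"
                )
            a, b, raw = parts[0], parts[1], parts[2]
            try:
                score = float(raw)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric score {raw!r}"
                ) from None
            key = (a, b)
            if key in seen and seen[key] != score:
                raise FormatError(
                    f"{path}:{lineno}: pair {a}-{b} listed twice with "
                    f"different scores ({seen[key]} vs {score})"
                )
            seen[key] = score
    if not seen:
        raise FormatError(f"{path}: no score lines found")
    ids = sorted({d for pair in seen for d in pair})
    index = {d: i for i, d in enumerate(ids)}
    scores = np.zeros((len(ids), len(ids)))
    for (a, b), v in seen.items():
        scores[index[a], index[b]] = v
    return PhenotypeNet(ids, scores, symmetric=bool(np.array_equal(scores, scores.T)))


def write_pair_scores(net: PhenotypeNet, path: str | Path) -> None:
    """Write every nonzero entry (including the diagonal) as a score line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# disease_a\tdisease_b\tscore\n")
        for i, a in enumerate(net.disease_ids):
            for j, b in enumerate(net.disease_ids):
                v = net.scores[i, j]
                if v != 0.0:
                    fh.write(f"{a}\t{b}\t{v:.17g}\n")


# ---------------------------------------------------------------------------
# PPI network and associations
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path) -> GeneNet:
    """Undirected gene-gene edge list: two symbol columns, optional weight.

    Unweighted edges get weight 1; duplicate edges (either direction)
    collapse to the maximum weight; self-loops are dropped with a warning.
    """
    weights: dict[tuple[str, str], float] = {}
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'gene gene [weight]', got {line!r}"
                )
            a, b = parts[0], parts[1]
            if a == b:
                n_self += 1
                continue
            try:
                w = float(parts[2]) if len(parts) >= 3 else 1.0
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                ) from None
            key = (a, b) if a < b else (b, a)
            weights[key] = max(weights.get(key, 0.0), w)
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    if not weights:
        raise FormatError(f"{path}: no edges found")
    ids = sorted({g for pair in weights for g in pair})
    index = {g: i for i, g in enumerate(ids)}
    rows, cols, data = [], [], []
    for (a, b), w in weights.items():
        rows += [index[a], index[b]]
        cols += [index[b], index[a]]
        data += [w, w]
    A = sp.coo_matrix((data, (rows, cols)), shape=(len(ids), len(ids))).tocsr()
    return GeneNet(ids, A)


def write_edge_list(net: GeneNet, path: str | Path) -> None:
    A = sp.triu(net.adjacency).tocoo()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gene_a\tgene_b\tweight\n")
        for i, j, w in zip(A.row, A.col, A.data):
            fh.write(f"{net.gene_ids[i]}\t{net.gene_ids[j]}\t{w:.17g}\n")


def read_associations(path: str | Path) -> DiseaseGeneMap:
    """Two-column disease-gene table; duplicates are collapsed."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'disease gene', got {line!r}"
                )
            pairs.append((parts[0], parts[1]))
    if not pairs:
        raise FormatError(f"{path}: no associations found")
    return DiseaseGeneMap(pairs)


def write_associations(dgmap: DiseaseGeneMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# disease\tgene\n")
        for d, g in dgmap.associations:
            fh.write(f"{d}\t{g}\n")
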