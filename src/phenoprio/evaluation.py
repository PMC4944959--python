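"""Leave-one-out cross-validation of phenotype networks for gene ranking.

Every known disease-gene association is removed in turn; the held-out
(target) gene is then re-predicted from the remaining genes of the same
disease (the seed set — empty for monogenic diseases) plus the calibrated
phenotype similarities, by PRINCE propagation over the PPI network.  The
per-association ranks feed the summary statistics used to compare networks:

* MRR (mean rank ratio): average of 100 * rank / n_candidates, lower better;
* number of top-ranking genes: targets recovered at rank 1;
* TPR@k: fraction of targets ranked within the top k, for k in {5, 10, 30}.

The module also provides the C-parameter sweep of the logistic calibration
(best C = the one maximizing the top-ranking count) and the 2x2 concordance
table comparing which targets two networks each recover at rank 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import DegenerateInputError
from .propagation import (
    GeneNet,
    PropagationParams,
    build_prior,
    competition_rank,
    propagate,
)
from .similarity import Form, PhenotypeNet, logistic_transform

logger = logging.getLogger(__name__)

DEFAULT_C_GRID: tuple[float, ...] = tuple(range(-25, -7))  # integers -25..-8
TPR_KS: tuple[int, ...] = (5, 10, 30)


@dataclass(frozen=True)
class DiseaseGeneMap:
    """Many-to-many disease-gene associations (deduplicated, sorted)."""

    associations: tuple[tuple[str, str], ...]
    _by_disease: dict[str, tuple[str, ...]] = field(
        init=False, repr=False, compare=False, hash=False
    )
    _by_gene: dict[str, tuple[str, ...]] = field(
        init=False, repr=False, compare=False, hash=False
    )

    def __init__(self, associations: Iterable[tuple[str, str]]):
        pairs = sorted({(str(d), str(g)) for d, g in associations})
        object.__setattr__(self, "associations", tuple(pairs))
        by_d: dict[str, list[str]] = {}
        by_g: dict[str, list[str]] = {}
        for d, g in pairs:
            by_d.setdefault(d, []).append(g)
            by_g.setdefault(g, []).append(d)
        object.__setattr__(self, "_by_disease", {d: tuple(v) for d, v in by_d.items()})
        object.__setattr__(self, "_by_gene", {g: tuple(v) for g, v in by_g.items()})

    def __len__(self) -> int:
        return len(self.associations)

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(self._by_disease)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self._by_gene)

    def genes_of(self, disease: str) -> tuple[str, ...]:
        return self._by_disease.get(disease, ())

    def diseases_of(self, gene: str) -> tuple[str, ...]:
        return self._by_gene.get(gene, ())

    def monogenic_diseases(self) -> tuple[str, ...]:
        """Diseases with exactly one associated gene."""
        return tuple(d for d, gs in self._by_disease.items() if len(gs) == 1)

    def polygenic_diseases(self) -> tuple[str, ...]:
        """Diseases with two or more associated genes."""
        return tuple(d for d, gs in self._by_disease.items() if len(gs) >= 2)

    def without(self, pair: tuple[str, str]) -> "DiseaseGeneMap":
        return DiseaseGeneMap(p for p in self.associations if p != pair)

    def restrict(
        self,
        diseases: Iterable[str] | None = None,
        genes: Iterable[str] | None = None,
    ) -> "DiseaseGeneMap":
        ds = set(diseases) if diseases is not None else None
        gs = set(genes) if genes is not None else None
        return DiseaseGeneMap(
            (d, g)
            for d, g in self.associations
            if (ds is None or d in ds) and (gs is None or g in gs)
        )


@dataclass(frozen=True)
class RankRecord:
    """Outcome of one held-out prediction."""

    disease: str
    target_gene: str
    rank: int
    n_candidates: int

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= self.n_candidates:
            raise ValueError(
                f"rank {self.rank} outside [1, {self.n_candidates}]"
            )


@dataclass(frozen=True)
class EvalReport:
    """LOOCV summary for one network / one C value."""

    mrr_percent: float
    top_count: int
    tpr_at: Mapping[int, float]
    n_targets: int
    c_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "mrr_percent": self.mrr_percent,
            "top_count": self.top_count,
            "tpr_at": {str(k): v for k, v in self.tpr_at.items()},
            "n_targets": self.n_targets,
            "c_value": self.c_value,
        }


def compute_report(
    records: Sequence[RankRecord],
    ks: Sequence[int] = TPR_KS,
    c_value: float | None = None,
) -> EvalReport:
    """Summarize per-association ranks into MRR, top count and TPR@k."""
    if not records:
        raise DegenerateInputError("no rank records to summarize")
    ranks = np.array([r.rank for r in records], dtype=float)
    ncand = np.array([r.n_candidates for r in records], dtype=float)
    n = len(records)
    return EvalReport(
        mrr_percent=float(np.mean(100.0 * ranks / ncand)),
        top_count=int(np.count_nonzero(ranks == 1)),
        tpr_at={int(k): float(100.0 * np.count_nonzero(ranks <= k) / n) for k in ks},
        n_targets=n,
        c_value=c_value,
    )


def _associations_in_scope(
    dgmap: DiseaseGeneMap,
    phenonet: PhenotypeNet,
    ppi: GeneNet,
    mode: str,
) -> tuple[DiseaseGeneMap, tuple[tuple[str, str], ...]]:
    """Restrict the map to usable associations and select the mode's slice.

    Associations whose gene is absent from the PPI or whose disease is
    absent from the phenotype network cannot be evaluated and are dropped
    with a logged count.  Mono/polygenic status is determined on the
    restricted map.
    """
    usable = dgmap.restrict(
        diseases=(d for d in dgmap.diseases if d in phenonet),
        genes=(g for g in dgmap.genes if g in ppi),
    )
    n_dropped = len(dgmap) - len(usable)
    if n_dropped:
        logger.warning(
            "loocv: dropped %d association(s) outside the phenotype/PPI networks",
            n_dropped,
        )
    if mode == "monogenic":
        scope = set(usable.monogenic_diseases())
    elif mode == "polygenic":
        scope = set(usable.polygenic_diseases())
    elif mode == "all":
        scope = set(usable.diseases)
    else:
        raise ValueError(f"mode must be monogenic/polygenic/all, got {mode!r}")
    pairs = tuple(p for p in usable.associations if p[0] in scope)
    return usable, pairs


def loocv(
    dgmap: DiseaseGeneMap,
    phenonet: PhenotypeNet,
    form: Form,
    ppi: GeneNet,
    mode: str = "all",
    params: PropagationParams | None = None,
    seed_value: float = 1.0,
) -> list[RankRecord]:
    """Leave-one-out cross-validation over disease-gene associations.

    For each association in scope the link is removed, the remaining genes
    of the disease form the seed set, candidates are all PPI genes minus
    the seeds (the target included), and the target's pessimistic
    competition rank among the candidates is recorded.  ``phenonet`` must
    already be calibrated (post-logistic) if calibration is wanted.
    """
    params = params or PropagationParams()
    usable, pairs = _associations_in_scope(dgmap, phenonet, ppi, mode)
    records: list[RankRecord] = []
    all_idx = np.arange(ppi.n)
    for disease, gene in pairs:
        held_out = usable.without((disease, gene))
        prior = build_prior(
            disease, held_out, phenonet, form, ppi, seed_value=seed_value
        )
        F = propagate(ppi, prior, params).scores.values
        seeds = held_out.genes_of(disease)
        seed_idx = {ppi.index(s) for s in seeds}
        cand_idx = np.array([i for i in all_idx if i not in seed_idx])
        cand_scores = F[cand_idx]
        target_pos = int(np.where(cand_idx == ppi.index(gene))[0][0])
        rank = competition_rank(cand_scores, target_pos)
        records.append(RankRecord(disease, gene, rank, len(cand_idx)))
    return records


def sweep_c(
    c_grid: Sequence[float],
    dgmap: DiseaseGeneMap,
    prenet: PhenotypeNet,
    form: Form,
    ppi: GeneNet,
    mode: str = "all",
    params: PropagationParams | None = None,
) -> tuple[float, dict[float, EvalReport]]:
    """Run the full LOOCV for every C in ``c_grid`` and pick the best.

    ``prenet`` is the normalized (and, if applicable, combined) network
    before logistic calibration; each grid point applies
    ``logistic_transform`` with that C and re-runs the validation.  The
    best C maximizes the top-ranking count; ties go to the C of smallest
    magnitude (least aggressive calibration), then to the larger C, for
    determinism.
    """
    if not c_grid:
        raise ValueError("c_grid must be nonempty")
    reports: dict[float, EvalReport] = {}
    for c in c_grid:
        net_c = logistic_transform(prenet, c)
        records = loocv(dgmap, net_c, form, ppi, mode=mode, params=params)
        reports[c] = compute_report(records, c_value=c)
    best_c = min(reports, key=lambda c: (-reports[c].top_count, abs(c), -c))
    return best_c, reports


def compare_networks(
    records_a: Sequence[RankRecord], records_b: Sequence[RankRecord]
) -> dict[str, int]:
    """2x2 concordance of top-ranked (rank 1) targets between two runs.

    Both record lists must cover the same associations.  Returns counts of
    targets recovered by neither network, by both, only by the first and
    only by the second; the four counts partition the targets.
    """
    key_a = {(r.disease, r.target_gene): r for r in records_a}
    key_b = {(r.disease, r.target_gene): r for r in records_b}
    if set(key_a) != set(key_b) or len(key_a) != len(records_a) or len(key_b) != len(
        records_b
    ):
        raise ValueError("record sets cover different association lists")
    counts = {"neither": 0, "both": 0, "only_a": 0, "only_b": 0}
    for pair, ra in key_a.items():
        hit_a = ra.rank == 1
        hit_b = key_b[pair].rank == 1
        if hit_a and hit_b:
            counts["both"] += 1
        elif hit_a:
            counts["only_a"] += 1
        elif hit_b:
            counts["only_b"] += 1
        else:
            counts["neither"] += 1
    return counts
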