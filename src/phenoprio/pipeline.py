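"""End-to-end evaluation pipeline: load, align, calibrate, validate, report.

The four stages mirror how phenotype networks are benchmarked in practice:

1. data extraction — load the phenotype network(s), PPI and associations,
   and restrict two phenotype networks to their common disease set;
2. normalization and regression — symmetrize if requested, apply one of
   the four range normalizations, optionally blend with a reference
   network, then calibrate with the logistic function;
3. validation — leave-one-out cross-validation with PRINCE propagation,
   either at a fixed C or sweeping a C grid;
4. reporting — TSV table (one row per C) and a JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import io as pio
from .evaluation import (
    DEFAULT_C_GRID,
    EvalReport,
    compute_report,
    loocv,
    sweep_c,
)
from .propagation import PropagationParams
from .similarity import (
    Form,
    PhenotypeNet,
    combine,
    intersect_networks,
    logistic_transform,
    normalize,
    relative_network_mean,
    symmetrize,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative description of one evaluation run.

    ``network`` is the phenotype network under evaluation;
    ``reference_network`` (dense, symmetric, already in [0, 1]) is optional
    and enables blending (``proportion`` = weight of the primary network)
    plus the relative-network-mean diagnostic.  Exactly one of ``c`` /
    ``c_grid`` selects fixed-C versus sweep mode; both absent means no
    logistic calibration (raw similarities).
    """

    network: str
    ppi: str
    associations: str
    network_dialect: str = "dense"  # "dense" or "pairs"
    network_symmetric: bool = True  # symmetry contract of the dense dialect
    reference_network: str | None = None
    method: str | None = None  # lin / sqrt / maxmin / tanimoto / None
    form: str = "symmetric"
    proportion: float | None = None
    c: float | None = None
    c_grid: list[float] | None = None
    mode: str = "all"
    alpha: float = 0.9
    tol: float = 1e-9
    max_iter: int = 100
    out_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    reports: dict[float | None, EvalReport]
    best_c: float | None
    relative_network_mean: float | None
    n_diseases: int
    n_genes: int
    n_associations: int

    @property
    def best_report(self) -> EvalReport:
        return self.reports[self.best_c]


def _load_phenonet(cfg: PipelineConfig) -> PhenotypeNet:
    if cfg.network_dialect == "dense":
        return pio.read_dense_matrix(cfg.network, symmetric=cfg.network_symmetric)
    if cfg.network_dialect == "pairs":
        return pio.read_pair_scores(cfg.network)
    raise ValueError(f"network_dialect must be 'dense' or 'pairs', got {cfg.network_dialect!r}")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the configured evaluation and (optionally) write reports."""
    for label, p in (
        ("network", cfg.network),
        ("reference_network", cfg.reference_network),
        ("ppi", cfg.ppi),
        ("associations", cfg.associations),
    ):
        if p is not None and not Path(p).is_file():
            raise FileNotFoundError(f"{label} file not found: {p}")
    if cfg.c is not None and cfg.c_grid:
        raise ValueError("give either c or c_grid, not both")

    # Stage 1: extraction and alignment
    net = _load_phenonet(cfg)
    ppi = pio.read_edge_list(cfg.ppi)
    dgmap = pio.read_associations(cfg.associations)
    reference = None
    if cfg.reference_network is not None:
        reference = pio.read_dense_matrix(cfg.reference_network, symmetric=True)
        net, reference = intersect_networks(net, reference)

    # Stage 2: normalization, combination, calibration
    form = Form(cfg.form)
    if form is Form.SYMMETRIC and not net.symmetric:
        net = symmetrize(net)
    if cfg.method is not None:
        net = normalize(net, cfg.method)
    rnm = None
    if reference is not None:
        rnm = relative_network_mean(net, reference)
        if cfg.proportion is not None:
            net = combine(net, reference, cfg.proportion)

    # Stage 3: validation
    params = PropagationParams(alpha=cfg.alpha, tol=cfg.tol, max_iter=cfg.max_iter)
    reports: dict[float | None, EvalReport]
    if cfg.c_grid:
        best_c, sweep_reports = sweep_c(
            list(cfg.c_grid), dgmap, net, form, ppi, mode=cfg.mode, params=params
        )
        reports = dict(sweep_reports)
    else:
        best_c = cfg.c
        calibrated = net if cfg.c is None else logistic_transform(net, cfg.c)
        records = loocv(dgmap, calibrated, form, ppi, mode=cfg.mode, params=params)
        reports = {cfg.c: compute_report(records, c_value=cfg.c)}

    result = PipelineResult(
        reports=reports,
        best_c=best_c,
        relative_network_mean=rnm,
        n_diseases=net.n,
        n_genes=ppi.n,
        n_associations=len(dgmap),
    )

    # Stage 4: reporting
    if cfg.out_dir is not None:
        _write_reports(cfg, result)
    return result


def _write_reports(cfg: PipelineConfig, result: PipelineResult) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["c\tmrr_percent\ttop_count\ttpr_at_5\ttpr_at_10\ttpr_at_30\tn_targets"]
    for c, rep in sorted(
        result.reports.items(), key=lambda kv: (kv[0] is None, kv[0] or 0)
    ):
        rows.append(
            f"{c}\t{rep.mrr_percent:.4f}\t{rep.top_count}\t"
            f"{rep.tpr_at[5]:.4f}\t{rep.tpr_at[10]:.4f}\t{rep.tpr_at[30]:.4f}\t"
            f"{rep.n_targets}"
        )
    (out / "loocv_report.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    summary = {
        "config": dataclasses.asdict(cfg),
        "best_c": result.best_c,
        "relative_network_mean": result.relative_network_mean,
        "n_diseases": result.n_diseases,
        "n_genes": result.n_genes,
        "n_associations": result.n_associations,
        "reports": {str(c): rep.to_dict() for c, rep in result.reports.items()},
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
    )
    logger.info("wrote %s and %s", out / "loocv_report.tsv", out / "summary.json")
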