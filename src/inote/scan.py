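"""Scan many gene sets against one subject-level dataset.

This is the application workflow: read outcome + covariates, molecular
matrices and a GMT file; align subjects across all inputs; fit the null
model once; then test every gene set with the requested iTEGS models and
omnibus procedures. Per-set perturbation normals are seeded from
``(global seed, set index)`` so a set's p-value does not change when the
GMT file is subsetted or reordered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import pooled_stats, prepare_genes
from .core_data import (
    Cohort,
    DiseaseModel,
    assemble_blocks,
    read_feature_matrix,
    read_gmt,
    read_locus_map,
    read_outcome_table,
)
from .inote import inote_test
from .null_dist import PerturbationEngine, davies_p, empirical_p, satterthwaite_p
from .null_model import fit_null

logger = logging.getLogger(__name__)

__all__ = ["ScanConfig", "run_scan"]


@dataclass
class ScanConfig:
    """File paths and options for a gene-set scan."""

    outcome_path: str
    gmt_path: str
    methylation_path: str | None = None
    expression_path: str | None = None
    locus_map_path: str | None = None
    covariate_path: str | None = None
    outcome_col: str = "y"
    models: tuple[str, ...] = ("M", "MG", "MGC")
    methods: tuple[str, ...] = ("davies", "perturbation")
    omnibus: tuple[str, ...] = ("chi", "uni")
    b: int = 1000
    seed: int = 0
    alpha: float = 0.05
    bonferroni: bool = True

    def __post_init__(self) -> None:
        if not self.models and not self.omnibus:
            raise ValueError("request at least one model or omnibus test")
        if not self.methods:
            raise ValueError("request at least one p-value method")


def _md5(path) -> str:
    import hashlib

    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _fmt_p(p: float | None, b: int) -> str:
    if p is None:
        return ""
    if p <= 1.0 / (b + 1):
        return f"<{1.0 / (b + 1):.0E}"
    return f"{p:.3E}"


def run_scan(config: ScanConfig) -> pd.DataFrame:
    """Execute the scan; returns one row per gene set.

    Untestable sets (no gene with usable data) are reported with a flag,
    not raised. Deterministic given ``config.seed``.
    """
    for attr in ("outcome_path", "gmt_path", "methylation_path",
                 "expression_path", "locus_map_path", "covariate_path"):
        path = getattr(config, attr)
        if path:
            logger.info("input %s: %s (md5 %s)", attr, path, _md5(path))
    outcome = read_outcome_table(config.outcome_path, config.outcome_col)
    meth = read_feature_matrix(config.methylation_path) \
        if config.methylation_path else None
    expr = read_feature_matrix(config.expression_path) \
        if config.expression_path else None
    lmap = read_locus_map(config.locus_map_path) if config.locus_map_path else None
    sets = read_gmt(config.gmt_path)

    ids = [str(i) for i in outcome.index]
    for df in (meth, expr):
        if df is not None:
            ids = [i for i in ids if i in set(df.columns)]
    if not ids:
        raise ValueError("no subjects shared by outcome and molecular data")
    logger.info("scan: %d aligned subjects, %d gene sets", len(ids), len(sets))

    y = outcome.loc[ids, config.outcome_col].to_numpy(dtype=float)
    if config.covariate_path:
        cov = read_outcome_table(config.covariate_path).loc[ids]
        x = np.column_stack([np.ones(len(ids)), cov.to_numpy(dtype=float)])
    else:
        x = np.ones((len(ids), 1))
    cohort = Cohort(y=y, x=x, subject_ids=ids)
    null = fit_null(cohort)

    models = tuple(DiseaseModel(m) for m in config.models)
    need_pert = "perturbation" in config.methods or bool(config.omnibus)
    need_eig = "davies" in config.methods or "satterthwaite" in config.methods
    n_sets = len(sets)
    bonf_threshold = config.alpha / n_sets if config.bonferroni else config.alpha

    rows = []
    for set_idx, gene_set in enumerate(sets):
        row: dict = {"set_id": gene_set.set_id, "n0": len(gene_set)}
        try:
            blocks, report = assemble_blocks(cohort, meth, lmap, expr, gene_set)
        except ValueError as exc:
            logger.warning("set %s: %s", gene_set.set_id, exc)
            row.update(n_t=0, untestable=True, note=str(exc))
            rows.append(row)
            continue
        row["n_t"] = report.n_genes_testable
        row["untestable"] = report.untestable
        if report.untestable:
            rows.append(row)
            continue

        engine = None
        if need_pert:
            engine = PerturbationEngine.create(
                cohort.n, b=config.b,
                seed=(config.seed * 100_003 + set_idx) % (2**31 - 1),
            )
        genes = prepare_genes(blocks, null, engine=engine, perturb=need_pert)
        min_p = np.inf
        for model in models:
            pooled = pooled_stats(genes, null, model, need_eig=need_eig,
                                  need_pert=need_pert)
            if pooled is None:
                row[f"q_{model.value}"] = np.nan
                continue
            row[f"q_{model.value}"] = pooled.q_net_obs
            if "satterthwaite" in config.methods:
                p = satterthwaite_p(pooled.q_net_obs, pooled.lambda_net)
                row[f"p_satt_{model.value}"] = _fmt_p(p, config.b)
                min_p = min(min_p, p)
            if "davies" in config.methods:
                p = davies_p(pooled.q_net_obs, pooled.lambda_net)
                row[f"p_davies_{model.value}"] = _fmt_p(p, config.b)
                min_p = min(min_p, p)
            if "perturbation" in config.methods:
                p = empirical_p(pooled.q_net_obs, pooled.q_net_null)
                row[f"p_perm_{model.value}"] = _fmt_p(p, config.b)
                min_p = min(min_p, p)
        if config.omnibus:
            res = inote_test(blocks, null, engine, which=config.omnibus,
                             genes=genes)
            if "chi" in config.omnibus:
                row["p_inote_chi"] = _fmt_p(res.p_inote_chi, config.b)
                min_p = min(min_p, res.p_inote_chi or np.inf)
            if "uni" in config.omnibus:
                row["p_inote_uni"] = _fmt_p(res.p_inote_uni, config.b)
                row["selected_model"] = (
                    res.selected_model.value if res.selected_model else ""
                )
                min_p = min(min_p, res.p_inote_uni or np.inf)
        row["significant"] = bool(min_p <= bonf_threshold)
        row["b"] = config.b
        rows.append(row)

    table = pd.DataFrame(rows)
    table.attrs["seed"] = config.seed
    table.attrs["bonferroni_threshold"] = bonf_threshold
    return table
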