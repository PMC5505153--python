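"""Synthetic cohort generator for size and power experiments.

The generator emulates the structure of array methylation + RNA expression
studies of a disease outcome:

* per gene, a block of correlated CpG beta-values: an exchangeable-
  correlation latent Gaussian (within-gene correlation ``rho_within``,
  default 0.8 — high-correlation CpG blocks) mapped to (0, 1) through the
  logistic function; the first locus of each block is the designated
  causal CpG;
* expression driven by the causal CpG, ``G_j = delta0 + delta M_causal_j
  + eps``, with subject-level residuals drawn MVN across genes with unit
  variance and between-gene covariance ``rho_between_expr`` (default 0.7);
* a dichotomous outcome from a logistic model whose linear predictor sums
  model-specific terms over the causal genes — ``kappa*beta_m*M_causal``
  for an M gene, adding ``kappa*beta_g*G`` for MG and further
  ``kappa*beta_c*M_causal*G`` for MGC — with the intercept solved
  numerically so the cohort prevalence matches ``base_prevalence``;
* a case-control sample (default 100 + 100) drawn without replacement
  from the simulated cohort (default 681 subjects).

``kappa`` is the common effect multiplier scanned in power studies;
``kappa = 0`` is the exact global null. ``signal_density`` is the fraction
of genes randomly selected to be causal, and ``model_mix`` assigns disease
models to the causal genes (the seven standard settings: single models,
50:50 pairs, and the one-third mixture of M, MG and MGC).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._engine import prepare_genes, pooled_stats
from .core_data import Cohort, DiseaseModel, GeneBlock
from .inote import inote_test
from .null_dist import PerturbationEngine, davies_p, empirical_p, satterthwaite_p
from .null_model import fit_null

__all__ = [
    "SimScenario",
    "simulate_methylation",
    "simulate_expression",
    "simulate_outcome",
    "simulate_dataset",
    "run_size_power_study",
    "MODEL_MIXES",
]

#: the seven disease-model mixture settings for causal genes
MODEL_MIXES: dict[int, tuple[str, ...]] = {
    1: ("M",),
    2: ("MG",),
    3: ("MGC",),
    4: ("M", "MG"),
    5: ("M", "MGC"),
    6: ("MG", "MGC"),
    7: ("M", "MG", "MGC"),
}


@dataclass
class SimScenario:
    """Full parameterisation of one simulation setting."""

    j_genes: int = 50
    p_per_gene: int = 11
    rho_within: float = 0.8
    rho_between_meth: float = 0.3
    rho_between_expr: float = 0.7
    cohort_n: int = 681
    n_cases: int = 100
    n_controls: int = 100
    signal_density: float = 0.2
    model_mix: int | tuple[str, ...] = 3
    kappa: float = 0.0
    beta_m: float = 0.5
    beta_g: float = 0.5
    beta_c: float = 0.5
    delta0: float = 0.0
    delta: float = 1.0
    base_prevalence: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.signal_density <= 1.0):
            raise ValueError("signal_density must lie in (0, 1]")
        if self.n_cases + self.n_controls > self.cohort_n:
            raise ValueError("case-control sample exceeds cohort size")
        for rho in (self.rho_within, self.rho_between_meth, self.rho_between_expr):
            if not (0.0 <= rho < 1.0):
                raise ValueError("correlation parameters must lie in [0, 1)")
        if self.rho_between_meth > self.rho_within:
            raise ValueError("rho_between_meth cannot exceed rho_within")
        if not (0.0 < self.base_prevalence < 1.0):
            raise ValueError("base_prevalence must lie in (0, 1)")

    def mix_models(self) -> tuple[DiseaseModel, ...]:
        mix = MODEL_MIXES[self.model_mix] if isinstance(self.model_mix, int) \
            else tuple(self.model_mix)
        return tuple(DiseaseModel(m) for m in mix)

    @classmethod
    def from_file(cls, path) -> "SimScenario":
        """Load a scenario from a flat key/value YAML file."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        if isinstance(data.get("model_mix"), list):
            data["model_mix"] = tuple(data["model_mix"])
        return cls(**data)


def _rep_seed(seed: int, rep: int, salt: int = 0) -> int:
    """Deterministic sub-stream seed, kept below 2**31."""
    return (seed * 1_000_003 + rep * 7_919 + salt) % (2**31 - 1)


def simulate_methylation(scn: SimScenario, rng: np.random.Generator) -> list[np.ndarray]:
    """Per-gene CpG beta-value matrices (cohort_n x p_per_gene each).

    Latent-Gaussian factor construction mapped to (0, 1) through the
    logistic function: loci of the same gene correlate at ``rho_within``
    (high-correlation CpG blocks) and loci of different genes at
    ``rho_between_meth``, the genome-wide co-methylation induced by
    subject-level factors (cell composition, global methylation gradients)
    that array blocks drawn from the same subjects inevitably share.
    Column 0 of each block is the designated causal locus.
    """
    n, p = scn.cohort_n, scn.p_per_gene
    a2 = scn.rho_between_meth              # global-factor share
    b2 = scn.rho_within - a2               # gene-factor share
    c2 = 1.0 - scn.rho_within              # locus noise share
    global_factor = rng.standard_normal((n, 1))
    out = []
    for _ in range(scn.j_genes):
        gene_factor = rng.standard_normal((n, 1))
        latent = (
            np.sqrt(a2) * global_factor
            + np.sqrt(b2) * gene_factor
            + np.sqrt(c2) * rng.standard_normal((n, p))
        )
        out.append(expit(latent))
    return out


def simulate_expression(
    meth: list[np.ndarray], scn: SimScenario, rng: np.random.Generator
) -> np.ndarray:
    """Expression matrix (cohort_n x J) driven by each gene's causal CpG.

    Residuals are MVN across genes with unit variance and equal between-gene
    covariance ``rho_between_expr`` (shared-factor construction).
    """
    n, j, rho = scn.cohort_n, scn.j_genes, scn.rho_between_expr
    m_causal = np.column_stack([m[:, 0] for m in meth])
    shared = rng.standard_normal((n, 1))
    eps = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal((n, j))
    return scn.delta0 + scn.delta * m_causal + eps


def _assign_causal(scn: SimScenario, rng: np.random.Generator) -> dict[int, DiseaseModel]:
    """Pick causal genes and assign disease models as evenly as possible.

    ``round(J * signal_density)`` genes are selected at random; the mixture
    models are assigned in the fixed order of the setting with any remainder
    going to the earlier models (e.g. 10 causal genes under the one-third
    mixture give a 4/3/3 split).
    """
    n_causal = int(round(scn.j_genes * scn.signal_density))
    n_causal = max(n_causal, 1)
    genes = rng.choice(scn.j_genes, size=n_causal, replace=False)
    models = scn.mix_models()
    k = len(models)
    counts = [n_causal // k + (1 if i < n_causal % k else 0) for i in range(k)]
    assignment: dict[int, DiseaseModel] = {}
    pos = 0
    for model, cnt in zip(models, counts):
        for g in genes[pos:pos + cnt]:
            assignment[int(g)] = model
        pos += cnt
    return assignment


def simulate_outcome(
    meth: list[np.ndarray],
    expr: np.ndarray,
    scn: SimScenario,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict[int, DiseaseModel]]:
    """Cohort outcomes plus the case-control row selection.

    Returns ``(y_cohort, sample_idx, causal_assignment)``. The logistic
    intercept is solved so the expected cohort prevalence equals
    ``base_prevalence`` given the realised linear predictor.
    """
    n = scn.cohort_n
    eta = np.zeros(n)
    assignment: dict[int, DiseaseModel] = {}
    if scn.kappa != 0.0:
        assignment = _assign_causal(scn, rng)
        for gi, model in assignment.items():
            mc = meth[gi][:, 0]
            eta += scn.kappa * scn.beta_m * mc
            if model in (DiseaseModel.MG, DiseaseModel.MGC):
                eta += scn.kappa * scn.beta_g * expr[:, gi]
            if model is DiseaseModel.MGC:
                eta += scn.kappa * scn.beta_c * mc * expr[:, gi]

    def prev_gap(b0: float) -> float:
        return float(expit(b0 + eta).mean() - scn.base_prevalence)

    # bracket wide enough that every subject's logit is pushed past +-30
    lo = -30.0 - max(0.0, float(eta.max()))
    hi = 30.0 - min(0.0, float(eta.min()))
    beta0 = brentq(prev_gap, lo, hi, xtol=1e-10)
    y = (rng.random(n) < expit(beta0 + eta)).astype(float)

    cases = np.flatnonzero(y == 1.0)
    controls = np.flatnonzero(y == 0.0)
    if cases.size < scn.n_cases or controls.size < scn.n_controls:
        raise RuntimeError(
            f"cohort yielded {cases.size} cases / {controls.size} controls; "
            f"need {scn.n_cases}+{scn.n_controls}. Increase base_prevalence "
            "or reduce effect sizes."
        )
    sample = np.concatenate([
        rng.choice(cases, size=scn.n_cases, replace=False),
        rng.choice(controls, size=scn.n_controls, replace=False),
    ])
    return y, sample, assignment


def simulate_dataset(
    scn: SimScenario, seed: int | None = None
) -> tuple[Cohort, list[GeneBlock], dict[int, DiseaseModel]]:
    """One complete case-control dataset ready for testing.

    Returns the sampled cohort (intercept-only covariates), per-gene blocks
    restricted to the sampled subjects, and the causal-model assignment
    (empty under the null).
    """
    rng = np.random.default_rng(scn.seed if seed is None else seed)
    meth = simulate_methylation(scn, rng)
    expr = simulate_expression(meth, scn, rng)
    y, sample, assignment = simulate_outcome(meth, expr, scn, rng)
    n_s = sample.size
    cohort = Cohort(
        y=y[sample],
        x=np.ones((n_s, 1)),
        subject_ids=[f"S{i}" for i in sample],
    )
    blocks = [
        GeneBlock(f"gene{j}", m=meth[j][sample], g=expr[sample, j])
        for j in range(scn.j_genes)
    ]
    return cohort, blocks, assignment


def dataset_to_frames(
    scn: SimScenario, seed: int | None = None
) -> dict[str, pd.DataFrame]:
    """Simulate and package a dataset as text-ready tables (for the CLI)."""
    cohort, blocks, _ = simulate_dataset(scn, seed)
    ids = list(cohort.subject_ids)
    meth_rows, map_rows = [], []
    expr_rows = {}
    for b in blocks:
        for l in range(b.p):
            locus = f"{b.gene_id}_cg{l}"
            meth_rows.append(pd.Series(b.m[:, l], index=ids, name=locus))
            map_rows.append((locus, b.gene_id))
        expr_rows[b.gene_id] = pd.Series(b.g, index=ids)
    return {
        "outcome": pd.DataFrame({"subject_id": ids, "y": cohort.y.astype(int)}),
        "methylation": pd.DataFrame(meth_rows),
        "expression": pd.DataFrame(expr_rows).T,
        "locus_map": pd.DataFrame(map_rows, columns=["locus", "gene"]),
    }


# ---------------------------------------------------------------------------
# size / power studies

_ITEGS_MODELS = (DiseaseModel.M, DiseaseModel.MG, DiseaseModel.MGC)


def run_size_power_study(
    scn: SimScenario,
    n_reps: int = 1000,
    alpha: float = 0.05,
    tests: tuple[str, ...] = ("itegs-M", "itegs-MG", "itegs-MGC"),
    methods: tuple[str, ...] = ("davies",),
    b: int = 500,
    seed: int = 0,
    collect_pvalues: bool = False,
) -> pd.DataFrame:
    """Empirical rejection rates of the requested tests over replicates.

    Parameters
    ----------
    scn : SimScenario
        Study conditions; ``kappa = 0`` measures size, otherwise power.
    n_reps : int
        Number of simulation replicates.
    alpha : float
        Significance threshold.
    tests : tuple of str
        Any of ``itegs-M``, ``itegs-G``, ``itegs-MG``, ``itegs-MGC``,
        ``inote-chi``, ``inote-uni``.
    methods : tuple of str
        P-value routes for the iTEGS entries (the omnibus tests are always
        perturbation-based).
    b : int
        Perturbations per replicate where perturbation is involved.
    seed : int
        Master seed; replicate streams are derived deterministically.
    collect_pvalues : bool
        Also return the raw per-replicate p-values (for uniformity
        diagnostics) in a ``pvalues`` DataFrame attribute.

    Returns
    -------
    DataFrame
        One row per (test, method) with rejection counts, rates and
        binomial standard errors.
    """
    itegs_models = [DiseaseModel(t.split("-", 1)[1]) for t in tests
                    if t.startswith("itegs-")]
    want_chi = "inote-chi" in tests
    want_uni = "inote-uni" in tests
    need_pert = want_chi or want_uni or ("perturbation" in methods)
    need_eig = bool(itegs_models) and (
        "davies" in methods or "satterthwaite" in methods
    )

    keys: list[tuple[str, str]] = []
    for m in itegs_models:
        keys.extend((f"itegs-{m.value}", meth) for meth in methods)
    if want_chi:
        keys.append(("inote-chi", "perturbation"))
    if want_uni:
        keys.append(("inote-uni", "perturbation"))
    rejections = {k: 0 for k in keys}
    pvals: dict[tuple[str, str], list[float]] = {k: [] for k in keys}

    for rep in range(n_reps):
        cohort, blocks, _ = simulate_dataset(scn, seed=_rep_seed(seed, rep, 1))
        null = fit_null(cohort)
        engine = None
        if need_pert:
            engine = PerturbationEngine.create(cohort.n, b=b,
                                               seed=_rep_seed(seed, rep, 2))
        genes = prepare_genes(blocks, null, engine=engine, perturb=need_pert)

        for model in itegs_models:
            pooled = pooled_stats(genes, null, model, need_eig=need_eig,
                                  need_pert="perturbation" in methods)
            for meth_name in methods:
                if meth_name == "davies":
                    p = davies_p(pooled.q_net_obs, pooled.lambda_net)
                elif meth_name == "satterthwaite":
                    p = satterthwaite_p(pooled.q_net_obs, pooled.lambda_net)
                else:
                    p = empirical_p(pooled.q_net_obs, pooled.q_net_null)
                key = (f"itegs-{model.value}", meth_name)
                rejections[key] += p <= alpha
                pvals[key].append(p)
        if want_chi or want_uni:
            which = tuple(w for w, ok in (("chi", want_chi), ("uni", want_uni)) if ok)
            res = inote_test(blocks, null, engine, which=which, genes=genes)
            if want_chi:
                rejections[("inote-chi", "perturbation")] += res.p_inote_chi <= alpha
                pvals[("inote-chi", "perturbation")].append(res.p_inote_chi)
            if want_uni:
                rejections[("inote-uni", "perturbation")] += res.p_inote_uni <= alpha
                pvals[("inote-uni", "perturbation")].append(res.p_inote_uni)

    rows = []
    for (test, meth_name), cnt in rejections.items():
        rate = cnt / n_reps
        rows.append({
            "test": test, "method": meth_name, "kappa": scn.kappa,
            "rejections": cnt, "n_reps": n_reps, "rate": rate,
            "se": np.sqrt(rate * (1 - rate) / n_reps), "alpha": alpha,
        })
    table = pd.DataFrame(rows)
    if collect_pvalues:
        table.attrs["pvalues"] = pd.DataFrame(
            {f"{t}:{m}": v for (t, m), v in pvals.items()}
        )
    return table


def power_curve(
    scn: SimScenario,
    kappas: tuple[float, ...],
    **kwargs,
) -> pd.DataFrame:
    """Rejection rates over a kappa grid (concatenated study tables)."""
    parts = []
    for kappa in kappas:
        parts.append(run_size_power_study(replace(scn, kappa=kappa), **kwargs))
    return pd.concat(parts, ignore_index=True)
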