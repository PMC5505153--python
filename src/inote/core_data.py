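"""Domain types and I/O for subject-level omics matrices and gene sets.

The testing machinery operates on three aligned pieces of subject-level
data: a dichotomous outcome with covariates (:class:`Cohort`), per-gene
molecular data (:class:`GeneBlock` holding a CpG methylation matrix, an
expression vector and their within-gene cross products), and gene-set
membership (:class:`GeneSet`, read from GMT files in the MSigDB dialect).

Molecular matrices are exchanged as delimited text with features on rows
and a header row of subject IDs; covariate tables carry one row per
subject. :func:`assemble_blocks` inner-joins everything on subject ID and
reports which genes of a set are actually testable on which platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "GeneBlock",
    "GeneSet",
    "DiseaseModel",
    "AssemblyReport",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "assemble_blocks",
    "read_outcome_table",
    "read_feature_matrix",
    "read_locus_map",
]


class GmtParseError(ValueError):
    """Raised when a GMT line cannot be parsed."""


class DiseaseModel(str, Enum):
    """Disease-risk model specification for a gene's total-effect test.

    ``M``: CpG methylation main effects only; ``G``: expression main effect
    only; ``MG``: both main effects; ``MGC``: both main effects plus the
    within-gene methylation-by-expression cross products.
    """

    M = "M"
    G = "G"
    MG = "MG"
    MGC = "MGC"

    @property
    def needs_m(self) -> bool:
        return self in (DiseaseModel.M, DiseaseModel.MG, DiseaseModel.MGC)

    @property
    def needs_g(self) -> bool:
        return self in (DiseaseModel.G, DiseaseModel.MG, DiseaseModel.MGC)

    def compatible_with(self, block: "GeneBlock") -> bool:
        """Whether ``block`` carries the data this model requires."""
        if self.needs_m and block.m is None:
            return False
        if self.needs_g and block.g is None:
            return False
        return True


#: Fixed evaluation / tie-break order of the candidate disease models.
MODEL_ORDER = (DiseaseModel.M, DiseaseModel.G, DiseaseModel.MG, DiseaseModel.MGC)


@dataclass
class Cohort:
    """Outcome and covariates for ``n`` aligned subjects.

    Parameters
    ----------
    y : array of shape (n,)
        Dichotomous outcome, coded 0/1. Both classes must be present.
    x : array of shape (n, r)
        Covariate design including the intercept as its first column.
    subject_ids : sequence of str
        Subject labels, in row order of ``y`` and ``x``.
    """

    y: np.ndarray
    x: np.ndarray
    subject_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        n, r = self.x.shape
        if self.y.shape[0] != n:
            raise ValueError(f"outcome length {self.y.shape[0]} != design rows {n}")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("outcome must be coded 0/1")
        if self.y.min() == self.y.max():
            raise ValueError("outcome contains a single class; both 0 and 1 required")
        if not np.allclose(self.x[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept (all ones)")
        if n < r + 2:
            raise ValueError(f"need n >= r + 2 subjects (n={n}, r={r})")
        if np.linalg.matrix_rank(self.x) < r:
            raise ValueError("covariate matrix is rank deficient")
        if not self.subject_ids:
            self.subject_ids = [f"S{i}" for i in range(n)]
        elif len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match n")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def r(self) -> int:
        return self.x.shape[1]


@dataclass
class GeneBlock:
    """One gene's molecular data for ``n`` subjects.

    ``m`` is the n x p_j methylation matrix (CpG loci on columns), ``g`` the
    expression vector, and ``c`` the derived n x p_j interaction matrix with
    ``c[i, l] = g[i] * m[i, l]``; ``c`` exists only when both platforms do.
    """

    gene_id: str
    m: np.ndarray | None = None
    g: np.ndarray | None = None
    c: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.m is None and self.g is None:
            raise ValueError(f"gene {self.gene_id}: no molecular data at all")
        if self.m is not None:
            self.m = np.atleast_2d(np.asarray(self.m, dtype=float))
            if self.m.shape[1] < 1:
                raise ValueError(f"gene {self.gene_id}: empty methylation matrix")
            if np.isnan(self.m).any():
                raise ValueError(f"gene {self.gene_id}: missing methylation values")
        if self.g is not None:
            self.g = np.asarray(self.g, dtype=float).ravel()
            if np.isnan(self.g).any():
                raise ValueError(f"gene {self.gene_id}: missing expression values")
            if self.m is not None and self.g.shape[0] != self.m.shape[0]:
                raise ValueError(f"gene {self.gene_id}: m and g row counts differ")
        if self.m is not None and self.g is not None:
            self.c = self.m * self.g[:, None]
        else:
            self.c = None

    @property
    def n(self) -> int:
        return self.m.shape[0] if self.m is not None else self.g.shape[0]

    @property
    def p(self) -> int:
        """Number of CpG loci (0 if methylation absent)."""
        return 0 if self.m is None else self.m.shape[1]

    def supported_models(self) -> list[DiseaseModel]:
        return [mdl for mdl in MODEL_ORDER if mdl.compatible_with(self)]


@dataclass
class GeneSet:
    """A named, ordered collection of gene labels."""

    set_id: str
    gene_ids: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"gene set {self.set_id} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"gene set {self.set_id} has duplicate gene ids")

    def __len__(self) -> int:
        return len(self.gene_ids)


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (tab-separated MSigDB dialect).

    Each line is ``set_name<TAB>description<TAB>gene1<TAB>gene2...``.
    Duplicate gene symbols within a line are dropped (first occurrence kept)
    with a logged warning.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            genes: list[str] = []
            seen = set()
            dups = 0
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    dups += 1
                    continue
                seen.add(g)
                genes.append(g)
            if dups:
                logger.warning(
                    "GMT set %s (line %d): dropped %d duplicate gene symbol(s)",
                    name, lineno, dups,
                )
            if not genes:
                raise GmtParseError(f"{path}: line {lineno}: set {name} has no genes")
            sets.append(GeneSet(name, genes, provenance=desc))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    """Write gene sets back to GMT, preserving set names and gene order."""
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.provenance or "na", *gs.gene_ids]) + "\n")


@dataclass
class AssemblyReport:
    """Bookkeeping from :func:`assemble_blocks`.

    ``n_genes_total`` mirrors N0 (genes named by the set), ``n_genes_testable``
    mirrors N_T (genes with at least one usable platform).
    """

    set_id: str
    n_genes_total: int
    n_genes_testable: int
    excluded: dict[str, str] = field(default_factory=dict)
    n_subjects: int = 0
    untestable: bool = False


def assemble_blocks(
    cohort: Cohort,
    methylation: pd.DataFrame | None,
    locus_map: pd.DataFrame | None,
    expression: pd.DataFrame | None,
    gene_set: GeneSet,
    standardize: bool = False,
) -> tuple[list[GeneBlock], AssemblyReport]:
    """Build per-gene data blocks for one gene set, aligned to a cohort.

    Parameters
    ----------
    cohort : Cohort
        Outcome/covariates; its ``subject_ids`` define the target ordering.
    methylation : DataFrame or None
        CpG loci on the index, subject IDs on columns.
    locus_map : DataFrame or None
        Two columns ``locus`` and ``gene`` mapping CpG loci to gene symbols.
        Required when ``methylation`` is given.
    expression : DataFrame or None
        Gene symbols on the index, subject IDs on columns.
    gene_set : GeneSet
        Genes to assemble.
    standardize : bool
        Scale each methylation column and the expression vector to mean 0
        and unit variance (off by default; the component weights already
        equalise scales across the score components).

    Returns
    -------
    (blocks, report)
        One :class:`GeneBlock` per gene with at least one platform; genes
        lacking both platforms are excluded and listed in the report. A set
        whose every gene lacks both platforms is flagged ``untestable``.
    """
    ids = list(cohort.subject_ids)
    avail = set(ids)
    if methylation is not None:
        avail &= set(map(str, methylation.columns))
    if expression is not None:
        avail &= set(map(str, expression.columns))
    keep = [s for s in ids if s in avail]
    if not keep:
        raise ValueError(f"gene set {gene_set.set_id}: no overlapping subjects")
    dropped = len(ids) - len(keep)
    if dropped:
        logger.info(
            "gene set %s: %d subject(s) missing from molecular data, inner join keeps %d",
            gene_set.set_id, dropped, len(keep),
        )

    gene_to_loci: dict[str, list[str]] = {}
    if methylation is not None:
        if locus_map is None:
            raise ValueError("locus_map is required when methylation data is given")
        lm = locus_map[["locus", "gene"]].astype(str)
        present = set(map(str, methylation.index))
        for locus, gene in lm.itertuples(index=False):
            if locus in present:
                gene_to_loci.setdefault(gene, []).append(locus)

    blocks: list[GeneBlock] = []
    excluded: dict[str, str] = {}
    for gene in gene_set.gene_ids:
        m = None
        g = None
        loci = gene_to_loci.get(gene)
        if methylation is not None and loci:
            m = methylation.loc[loci, keep].to_numpy(dtype=float).T
        if expression is not None and gene in expression.index:
            g = expression.loc[gene, keep].to_numpy(dtype=float).ravel()
        if m is None and g is None:
            excluded[gene] = "no methylation probes and no expression row"
            continue
        if standardize:
            if m is not None:
                m = (m - m.mean(axis=0)) / m.std(axis=0)
            if g is not None:
                g = (g - g.mean()) / g.std()
        blocks.append(GeneBlock(gene, m=m, g=g))

    report = AssemblyReport(
        set_id=gene_set.set_id,
        n_genes_total=len(gene_set),
        n_genes_testable=len(blocks),
        excluded=excluded,
        n_subjects=len(keep),
        untestable=not blocks,
    )
    if report.untestable:
        logger.warning("gene set %s: no testable genes", gene_set.set_id)
    if dropped and not report.untestable:
        # callers needing a subset cohort can rebuild it from `keep`
        report.excluded.setdefault("_subjects_dropped", str(dropped))
    return blocks, report


# ---------------------------------------------------------------------------
# Text readers for the CLI (TSV/CSV, delimiter sniffed by pandas)


def read_outcome_table(path, outcome_col: str | None = None) -> pd.DataFrame:
    """Read a subject table whose first column is the subject ID."""
    df = pd.read_csv(path, sep=None, engine="python")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    if outcome_col is not None and outcome_col not in df.columns:
        raise ValueError(f"{path}: missing outcome column {outcome_col!r}")
    return df


def read_feature_matrix(path) -> pd.DataFrame:
    """Read a features-by-subjects matrix (header row = subject IDs)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_locus_map(path) -> pd.DataFrame:
    """Read the two-column (locus, gene) CpG-to-gene mapping."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c.lower() for c in df.columns]
    if "locus" in cols and "gene" in cols:
        df.columns = cols
    else:
        df = df.iloc[:, :2]
        df.columns = ["locus", "gene"]
    return df[["locus", "gene"]].astype(str)
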