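"""Cell-composition-adjusted epigenome-wide association analysis.

Per CpG, methylation is regressed on the phenotype (an ordinal variable
treated as numeric, e.g. smoking status 0/1/2) plus optional technical
covariates and, when supplied, estimated cell-type fractions. Differential
CpGs are called at a Benjamini-Hochberg FDR threshold and scored for
sensitivity, specificity and empirical FDR against curated gold-standard
true-positive and true-negative CpG lists.

Because estimated fractions sum to (approximately) one and the design
includes an intercept, one cell-type covariate must be dropped to keep the
design full rank; by default the cell type with the smallest mean fraction
is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .core import BetaMatrix, CellFractions
from .refbuild import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class GoldStandard:
    """Disjoint curated sets of known-positive and known-negative CpGs."""

    true_positives: frozenset[str]
    true_negatives: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.true_positives & self.true_negatives
        if overlap:
            raise ValueError(
                f"gold-standard TP and TN sets overlap ({len(overlap)} CpGs)"
            )


@dataclass
class PerformanceSummary:
    """Sensitivity/specificity/empirical-FDR of a call set against a gold standard."""

    n_calls: int
    tp_found: int
    fp_found: int
    sensitivity: float
    specificity: float
    empirical_fdr: float


def _design_matrix(
    pheno: pd.DataFrame,
    phenotype: str,
    covariates: Sequence[str],
    fractions: CellFractions | None,
    drop_celltypes: Sequence[str] | str | None,
    samples: list[str],
) -> tuple[np.ndarray, list[str]]:
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(samples))}
    cols[phenotype] = pheno.loc[samples, phenotype].to_numpy(dtype=float)
    for cov in covariates:
        series = pheno.loc[samples, cov]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(series, prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols[name] = dummies[name].to_numpy(dtype=float)
        else:
            cols[cov] = series.to_numpy(dtype=float)
    if fractions is not None:
        frac = fractions.data.loc[samples]
        if drop_celltypes == "auto":
            dropped = [frac.mean(axis=0).idxmin()]
        elif drop_celltypes is None:
            dropped = []
        else:
            dropped = list(drop_celltypes)
        for cell_type in frac.columns:
            if cell_type not in dropped:
                cols[cell_type] = frac[cell_type].to_numpy(dtype=float)
        if dropped:
            logger.info("dropped cell-type covariates: %s", dropped)
    names = list(cols)
    X = np.column_stack([cols[n] for n in names])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank-deficient (cell fractions summing to 1 "
            "alongside an intercept?); drop one cell-type covariate"
        )
    return X, names


def fit_ewas(
    beta: BetaMatrix,
    pheno: pd.DataFrame,
    phenotype: str = "smoking",
    covariates: Sequence[str] = (),
    fractions: CellFractions | None = None,
    drop_celltypes: Sequence[str] | str | None = "auto",
) -> pd.DataFrame:
    """Per-CpG linear association of methylation with the phenotype.

    Returns a table indexed by CpG with the phenotype coefficient (beta
    units per phenotype unit), its standard error, t statistic, two-sided
    p-value and BH q-value across all tested CpGs. All CpGs share the same
    design, so the fit is a single multi-response least-squares solve.
    """
    samples = beta.sample_ids
    missing = set(samples) - set(pheno.index)
    if missing:
        raise ValueError(f"samples without phenotype entries: {sorted(missing)[:5]}")
    if len(samples) < 10:
        raise ValueError("need at least 10 samples for an association analysis")
    X, names = _design_matrix(
        pheno, phenotype, covariates, fractions, drop_celltypes, samples
    )
    j = names.index(phenotype)
    Y = beta.values.T  # samples x CpGs
    n, p = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    coef = XtX_inv @ (X.T @ Y)
    resid = Y - X @ coef
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef[j] / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * t_dist.sf(np.abs(t), dof)
    return pd.DataFrame(
        {
            "coef": coef[j],
            "se": se,
            "t": t,
            "p": pvals,
            "q": bh_fdr(pvals),
        },
        index=beta.cpg_ids,
    )


def call_dmcs(result: pd.DataFrame, fdr_threshold: float = 0.05) -> set[str]:
    """CpGs significant at ``q < fdr_threshold``."""
    return set(result.index[result["q"] < fdr_threshold])


def score_calls(calls: Iterable[str], gold: GoldStandard) -> PerformanceSummary:
    """Score a call set against the gold standard.

    Sensitivity is the fraction of true positives recovered; specificity is
    one minus the fraction of true negatives called; empirical FDR is the
    fraction of calls that are known true negatives (0 when nothing is
    called).
    """
    if not gold.true_positives or not gold.true_negatives:
        raise ValueError("gold-standard TP and TN sets must both be non-empty")
    calls = set(calls)
    tp_found = len(calls & gold.true_positives)
    fp_found = len(calls & gold.true_negatives)
    n_calls = len(calls)
    return PerformanceSummary(
        n_calls=n_calls,
        tp_found=tp_found,
        fp_found=fp_found,
        sensitivity=tp_found / len(gold.true_positives),
        specificity=1.0 - fp_found / len(gold.true_negatives),
        empirical_fdr=fp_found / n_calls if n_calls else 0.0,
    )
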