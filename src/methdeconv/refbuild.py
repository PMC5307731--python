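"""Reference DNAm database construction from purified-cell data.

Two marker-selection recipes are supported, mirroring the two data regimes a
reference builder faces:

* **fdr mode** (replicated purified samples): per cell type, a one-vs-rest
  moderated-t test with empirical-Bayes variance shrinkage selects
  differentially methylated CpGs (DMCs) at a Benjamini-Hochberg FDR
  threshold; the DMCs are optionally restricted to DNase-hypersensitive
  sites (DHS) of the profiled cell types and the top-k by absolute mean
  beta difference are kept per cell type.
* **pairwise mode** (a single representative profile per cell type): CpGs
  whose beta values differ by more than a large threshold (default 0.9)
  between some pair of cell types are selected; no test statistic is
  involved.

The reference centroid matrix is the per-cell-type mean beta over the union
of selected CpGs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import norm, t as t_dist
from statsmodels.stats.multitest import multipletests

from .core import BetaMatrix, ReferenceMatrix

logger = logging.getLogger(__name__)

DMC_COLUMNS = ["cell_type", "mean_target", "mean_rest", "delta", "t", "p", "q", "in_dhs"]


@dataclass
class PurifiedDataset:
    """A beta matrix of purified-cell samples plus their cell-type labels."""

    beta: BetaMatrix
    cell_type_of_sample: dict[str, str]

    def __post_init__(self) -> None:
        unlabelled = set(self.beta.sample_ids) - set(self.cell_type_of_sample)
        if unlabelled:
            raise ValueError(f"samples without a cell-type label: {sorted(unlabelled)}")

    @property
    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.beta.sample_ids:
            seen.setdefault(self.cell_type_of_sample[s], None)
        return list(seen)

    def samples_of(self, cell_type: str) -> list[str]:
        return [
            s for s in self.beta.sample_ids if self.cell_type_of_sample[s] == cell_type
        ]

    def mean_profiles(self) -> ReferenceMatrix:
        """Per-cell-type mean beta profile over all CpGs."""
        cols = {
            ct: self.beta.data[self.samples_of(ct)].mean(axis=1)
            for ct in self.cell_types
        }
        return ReferenceMatrix(pd.DataFrame(cols))


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(x: float) -> float:
    # Newton iteration for y with trigamma(y) = x (monotone decreasing).
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate the scaled-inverse-chi-square prior (d0, s0^2) on residual variances.

    Uses moment matching on ``log s^2`` across CpGs: under the hierarchical
    model the excess variance of ``log s^2`` over the sampling trigamma term
    identifies the prior degrees of freedom d0, and the mean identifies the
    prior variance s0^2. Returns ``d0 = inf`` when the observed variances are
    less dispersed than pure sampling noise (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        raise ValueError("cannot fit a variance prior: fewer than 2 positive variances")
    z = np.log(pos)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def moderated_t_one_vs_rest(
    data: PurifiedDataset, target: str, prior_df: float | None = None
) -> pd.DataFrame:
    """Per-CpG moderated-t comparison of ``target`` samples vs all the rest.

    The pooled two-group residual variance ``s^2`` (d degrees of freedom) is
    shrunk towards the prior: ``s~^2 = (d0 s0^2 + d s^2) / (d0 + d)``, with
    (d0, s0^2) estimated across CpGs by :func:`fit_variance_prior` unless
    ``prior_df`` forces d0. The moderated statistic
    ``t~ = delta / (s~ sqrt(1/n1 + 1/n2))`` is referred to a t distribution
    with ``d0 + d`` degrees of freedom; ``delta`` is the beta-scale mean
    difference (target minus rest).
    """
    if target not in data.cell_types:
        raise KeyError(f"unknown cell type {target!r}")
    target_samples = data.samples_of(target)
    rest_samples = [s for s in data.beta.sample_ids if s not in set(target_samples)]
    n1, n2 = len(target_samples), len(rest_samples)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {n1} target and {n2} rest"
        )
    x1 = data.beta.data[target_samples].to_numpy(dtype=float)
    x2 = data.beta.data[rest_samples].to_numpy(dtype=float)
    mean1 = x1.mean(axis=1)
    mean2 = x2.mean(axis=1)
    delta = mean1 - mean2
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d

    if prior_df is not None:
        d0 = float(prior_df)
        try:
            _, s02 = fit_variance_prior(s2, d)
        except ValueError:
            s02 = 0.0
    else:
        try:
            d0, s02 = fit_variance_prior(s2, d)
        except ValueError:
            warnings.warn(
                "variance prior estimation failed (degenerate variances); "
                "falling back to the ordinary pooled t-test",
                RuntimeWarning,
                stacklevel=2,
            )
            d0, s02 = 0.0, 0.0

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.where(se > 0, se, np.nan)
        t = np.where(se > 0, t, np.sign(delta) * np.inf)
        t = np.where((se == 0) & (delta == 0), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * norm.sf(np.abs(t))
    else:
        p = 2.0 * t_dist.sf(np.abs(t), df_total)

    return pd.DataFrame(
        {
            "cell_type": target,
            "mean_target": mean1,
            "mean_rest": mean2,
            "delta": delta,
            "t": t,
            "p": p,
            "q": np.nan,
            "in_dhs": False,
        },
        index=data.beta.data.index,
    )


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def select_dmcs_one_vs_rest(
    data: PurifiedDataset,
    fdr_threshold: float = 0.05,
    prior_df: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Significant one-vs-rest DMC tables per cell type (q < ``fdr_threshold``)."""
    if len(data.cell_types) < 2:
        raise ValueError("DMC selection needs at least 2 cell types")
    out: dict[str, pd.DataFrame] = {}
    for cell_type in data.cell_types:
        table = moderated_t_one_vs_rest(data, cell_type, prior_df=prior_df)
        table["q"] = bh_fdr(table["p"].to_numpy())
        out[cell_type] = table.loc[table["q"] < fdr_threshold].copy()
    return out


def select_dmcs_pairwise(
    profiles: ReferenceMatrix, delta_threshold: float = 0.9
) -> tuple[dict[tuple[str, str], set[str]], set[str]]:
    """CpGs with |beta difference| > threshold for each cell-type pair, plus the union."""
    per_pair: dict[tuple[str, str], set[str]] = {}
    union: set[str] = set()
    for a, b in combinations(profiles.cell_types, 2):
        diff = (profiles.data[a] - profiles.data[b]).abs()
        cpgs = set(profiles.data.index[diff > delta_threshold])
        per_pair[(a, b)] = cpgs
        union |= cpgs
    return per_pair, union


def filter_to_dhs(dmcs: pd.DataFrame, dhs_cpgs: Iterable[str]) -> pd.DataFrame:
    """Restrict a DMC table to CpGs in ``dhs_cpgs`` and set the ``in_dhs`` flag."""
    dhs_cpgs = set(dhs_cpgs)
    out = dmcs.loc[[c in dhs_cpgs for c in dmcs.index]].copy()
    out["in_dhs"] = True
    return out


def top_k_by_delta(dmcs: pd.DataFrame, k: int = 50) -> list[str]:
    """Top ``k`` CpGs by |mean beta difference|, ties broken by CpG id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(
        dmcs.index, key=lambda cpg: (-abs(dmcs.at[cpg, "delta"]), cpg)
    )
    return order[: min(k, len(order))]


def build_reference(
    data: PurifiedDataset, selected_cpgs: Iterable[str]
) -> ReferenceMatrix:
    """Centroid reference: per-cell-type mean beta over the selected CpG union."""
    selected = sorted(set(selected_cpgs))
    missing = [c for c in selected if c not in data.beta.data.index]
    if missing:
        raise KeyError(f"selected CpGs absent from the purified data: {missing[:5]}")
    sub = data.beta.data.loc[selected]
    cols = {
        ct: sub[data.samples_of(ct)].mean(axis=1) for ct in data.cell_types
    }
    return ReferenceMatrix(pd.DataFrame(cols))


def build_reference_pipeline(
    data: PurifiedDataset,
    mode: str = "fdr",
    fdr_threshold: float = 0.05,
    delta_threshold: float = 0.9,
    top_k: int = 50,
    dhs_cpgs: Iterable[str] | None = None,
    prior_df: float | None = None,
) -> tuple[ReferenceMatrix, dict[str, list[str]]]:
    """Full reference construction: select markers, filter, rank, average.

    With ``dhs_cpgs=None`` the DHS filter is skipped (the "non-DHS" recipe is
    the same code path with an absent filter). Returns the reference and the
    per-cell-type marker picks (``mode='pairwise'`` keys picks by the pair
    label "A|B").
    """
    picks: dict[str, list[str]] = {}
    if mode == "fdr":
        dmcs = select_dmcs_one_vs_rest(data, fdr_threshold, prior_df=prior_df)
        for cell_type, table in dmcs.items():
            if dhs_cpgs is not None:
                table = filter_to_dhs(table, dhs_cpgs)
            picks[cell_type] = top_k_by_delta(table, top_k)
    elif mode == "pairwise":
        profiles = data.mean_profiles()
        if dhs_cpgs is not None:
            keep = [c for c in profiles.cpg_ids if c in set(dhs_cpgs)]
            profiles = ReferenceMatrix(profiles.data.loc[keep])
        per_pair, _ = select_dmcs_pairwise(profiles, delta_threshold)
        for (a, b), cpgs in per_pair.items():
            picks[f"{a}|{b}"] = sorted(cpgs)
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'fdr' or 'pairwise')")
    union: set[str] = set()
    for cpgs in picks.values():
        union |= set(cpgs)
    if not union:
        raise ValueError("no marker CpGs selected; reference would be empty")
    logger.info("reference built over %d unique marker CpGs", len(union))
    return build_reference(data, union), picks
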