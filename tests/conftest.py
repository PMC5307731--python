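"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import pytest

import methdeconv as md


@pytest.fixture(scope="session")
def blood_sim():
    """Blood-like synthetic purified study: 7 cell types x 6 replicates."""
    return md.synth_purified_dataset(md.SynthConfig(seed=11))


@pytest.fixture(scope="session")
def blood_reference(blood_sim):
    """DHS-filtered reference built from the train study."""
    dhs_cpgs = md.cpgs_in_dhs(blood_sim.cpg_map, blood_sim.dhs, blood_sim.dhs.cell_types)
    ref, _ = md.build_reference_pipeline(blood_sim.train, dhs_cpgs=dhs_cpgs)
    return ref


@pytest.fixture(scope="session")
def full_benchmark(blood_sim, blood_reference):
    """Full Monte-Carlo benchmark: 4 methods x SD 0-6 x 25 runs x 100 mixtures."""
    profiles = blood_sim.test.mean_profiles()
    return md.run_benchmark(blood_reference, profiles, master_seed=1)


def make_beta(values, cpgs=None, samples=None) -> md.BetaMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    cpgs = cpgs or [f"cg{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return md.BetaMatrix(pd.DataFrame(values, index=cpgs, columns=samples))


def make_reference(values, cpgs=None, cell_types=None) -> md.ReferenceMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    cpgs = cpgs or [f"cg{i}" for i in range(values.shape[0])]
    cell_types = cell_types or [f"CT{j}" for j in range(values.shape[1])]
    return md.ReferenceMatrix(pd.DataFrame(values, index=cpgs, columns=cell_types))


# ---------------------------------------------------------------------------
# independent oracles (never share code with the implementation they check)


def bh_stepup_brute(p: np.ndarray) -> np.ndarray:
    """BH q-values straight from the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    q = np.empty(m)
    for i in range(m):
        # q_i = min over p_(j) >= p_i of m * p_(j) / rank(p_(j))
        candidates = []
        order = np.argsort(p, kind="stable")
        for rank, j in enumerate(order, start=1):
            if p[j] >= p[i]:
                candidates.append(m * p[j] / rank)
        q[i] = min(1.0, min(candidates))
    return q


def wilcoxon_exact_enum(diffs: np.ndarray, alternative: str = "greater") -> float:
    """Exact signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    absd = np.abs(d)
    order = np.argsort(absd)
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    # midranks for ties
    for v in np.unique(absd):
        mask = absd == v
        ranks[mask] = ranks[mask].mean()
    w_obs = ranks[d > 0].sum()
    stats = []
    for signs in product([0, 1], repeat=n):
        stats.append(sum(r for s, r in zip(signs, ranks) if s))
    stats = np.asarray(stats)
    if alternative == "greater":
        return float(np.mean(stats >= w_obs))
    return float(np.mean(stats <= w_obs))


def cp_grid_search(y: np.ndarray, B: np.ndarray, step: float = 0.01) -> np.ndarray:
    """Brute-force least squares over the gridded truncated simplex (sum <= 1)."""
    C = B.shape[1]
    ticks = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    grids = np.meshgrid(*([ticks] * C), indexing="ij")
    W = np.stack([g.ravel() for g in grids])
    W = W[:, W.sum(axis=0) <= 1.0 + 1e-12]
    resid = B @ W - y[:, None]
    sse = (resid**2).sum(axis=0)
    return W[:, np.argmin(sse)]


def dhs_hits_brute(cpg_map: md.CpGMap, catalog: md.DHSCatalog, cell_types) -> set[str]:
    """Per-interval linear scan over every CpG (no tree structure)."""
    hits = set()
    for cpg, row in cpg_map.data.iterrows():
        p0 = int(row["pos"]) - 1
        for ct in cell_types:
            for chrom, start, end in catalog.intervals[ct]:
                if chrom == row["chrom"] and start <= p0 < end:
                    hits.add(cpg)
    return hits
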