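"""Scoring of estimated against true fractions and the mixture benchmark.

Performance of an estimator on a set of in-silico mixtures is summarised
per cell type by the root-mean-square error between estimated and true
weights across mixtures, and by the squared Pearson correlation (R^2). The
benchmark harness repeats the whole exercise over Monte-Carlo runs (fresh
simplex weights each run), a grid of M-space noise levels, and all methods
on identical noisy data; method pairs are compared by a one-tailed paired
Wilcoxon signed-rank test on the run-level averages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .core import ReferenceMatrix
from .deconv import DeconvConfig, deconvolve
from .simulate import MixtureTruth, add_mspace_noise, make_mixtures, sample_simplex_weights

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Per-cell-type RMSE and R^2 for one method on one mixture set."""

    per_celltype: pd.DataFrame  # index: cell type; columns: rmse, r2
    avg_rmse: float
    avg_r2: float
    metadata: dict = field(default_factory=dict)


@dataclass
class BenchmarkReport:
    """Long-format grid of evaluation scores over methods x noise SDs x runs."""

    table: pd.DataFrame  # columns: method, sd, run, cell_type, rmse, r2, failed
    master_seed: int

    def run_averages(self, method: str, sd: float, metric: str = "rmse") -> np.ndarray:
        """The per-run cell-type-averaged scores for one method at one noise level."""
        sel = self.table[
            (self.table["method"] == method)
            & (self.table["sd"] == sd)
            & (self.table["cell_type"] == "avg")
        ].sort_values("run")
        return sel[metric].to_numpy()

    def compare(
        self,
        method_a: str,
        method_b: str,
        sd: float,
        metric: str = "rmse",
        alternative: str = "less",
    ) -> float:
        """Paired one-tailed Wilcoxon p-value on run-level averages (a vs b)."""
        a = self.run_averages(method_a, sd, metric)
        b = self.run_averages(method_b, sd, metric)
        return paired_wilcoxon_one_tailed(a, b, alternative=alternative)


def score_fractions(est, truth: MixtureTruth) -> EvalReport:
    """Score estimated fractions against the truth, per cell type and averaged.

    RMSE is over samples; R^2 is the squared Pearson correlation across
    samples, defined as 0 when either vector is constant and as missing
    (NaN) when there are fewer than 2 samples.
    """
    est_df = est.data if hasattr(est, "data") else pd.DataFrame(est)
    if list(est_df.index) != list(truth.sample_ids) or list(est_df.columns) != list(
        truth.cell_types
    ):
        try:
            est_df = est_df.loc[truth.sample_ids, truth.cell_types]
        except KeyError as exc:
            raise ValueError(f"samples/cell types do not match the truth: {exc}")
    e = est_df.to_numpy(dtype=float)
    t = truth.values
    rows = {}
    for j, cell_type in enumerate(truth.cell_types):
        err = e[:, j] - t[:, j]
        rmse = float(np.sqrt(np.mean(err**2)))
        if e.shape[0] < 2:
            r2 = np.nan
        elif np.std(e[:, j]) == 0 or np.std(t[:, j]) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(e[:, j], t[:, j])[0, 1] ** 2)
        rows[cell_type] = {"rmse": rmse, "r2": r2}
    per_ct = pd.DataFrame(rows).T
    return EvalReport(
        per_celltype=per_ct,
        avg_rmse=float(per_ct["rmse"].mean()),
        avg_r2=float(per_ct["r2"].mean()),
    )


def run_benchmark(
    reference: ReferenceMatrix,
    mix_profiles: ReferenceMatrix,
    methods: Sequence[str] = ("lr", "rpc", "svr", "cp"),
    n_mixtures: int = 100,
    n_runs: int = 25,
    noise_sds: Sequence[float] = (0, 1, 2, 3, 4, 5, 6),
    master_seed: int = 0,
    config: DeconvConfig | None = None,
) -> BenchmarkReport:
    """The full Monte-Carlo x noise-grid x method benchmark.

    Per run, fresh simplex weights generate mixtures from ``mix_profiles``;
    per noise level, M-space Gaussian noise is added once and every method
    is applied to the identical noisy matrix. Seeds are derived
    deterministically from ``master_seed``; per-method failures are recorded
    as flagged rows, not raised.
    """
    base = config or DeconvConfig()
    records = []
    root = np.random.SeedSequence(master_seed)
    run_seeds = root.spawn(n_runs)
    for run, run_seed in enumerate(run_seeds):
        weight_ss, *noise_ss = run_seed.spawn(1 + len(noise_sds))
        truth = sample_simplex_weights(
            n_mixtures, mix_profiles.cell_types, np.random.default_rng(weight_ss)
        )
        clean = make_mixtures(mix_profiles, truth)
        for k, sd in enumerate(noise_sds):
            noisy = (
                add_mspace_noise(clean, sd, np.random.default_rng(noise_ss[k]))
                if sd > 0
                else clean
            )
            for method in methods:
                cfg = DeconvConfig(
                    method=method,
                    huber_c=base.huber_c,
                    rpc_max_iter=base.rpc_max_iter,
                    rpc_tol=base.rpc_tol,
                    svr_nu_grid=base.svr_nu_grid,
                )
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        est = deconvolve(noisy, reference, cfg)
                    report = score_fractions(est, truth)
                    failed = False
                except Exception as exc:
                    logger.warning(
                        "method %s failed at sd=%s run=%d: %s", method, sd, run, exc
                    )
                    report = None
                    failed = True
                if report is not None:
                    for cell_type, row in report.per_celltype.iterrows():
                        records.append(
                            dict(
                                method=method,
                                sd=sd,
                                run=run,
                                cell_type=cell_type,
                                rmse=row["rmse"],
                                r2=row["r2"],
                                failed=False,
                            )
                        )
                    records.append(
                        dict(
                            method=method,
                            sd=sd,
                            run=run,
                            cell_type="avg",
                            rmse=report.avg_rmse,
                            r2=report.avg_r2,
                            failed=False,
                        )
                    )
                else:
                    records.append(
                        dict(
                            method=method,
                            sd=sd,
                            run=run,
                            cell_type="avg",
                            rmse=np.nan,
                            r2=np.nan,
                            failed=True,
                        )
                    )
    return BenchmarkReport(table=pd.DataFrame.from_records(records), master_seed=master_seed)


def paired_wilcoxon_one_tailed(
    a: Sequence[float], b: Sequence[float], alternative: str = "greater"
) -> float:
    """One-tailed paired Wilcoxon signed-rank p-value for a vs b.

    ``alternative='greater'`` tests whether ``a`` tends to exceed ``b``.
    Zero differences are dropped; the exact null distribution is used for
    small samples without ties, the tie-corrected normal approximation
    otherwise. All-zero differences return p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-d arrays of equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if np.all(a == b):
        warnings.warn(
            "all paired differences are zero; p-value defined as 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    res = wilcoxon(a, b, alternative=alternative, zero_method="wilcox")
    return float(res.pvalue)
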