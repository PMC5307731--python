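"""Cell-type fraction estimation from a reference centroid matrix.

Each sample's methylation profile ``y`` over the reference CpGs is modelled
as a non-negative combination of the cell-type centroid profiles ``b_c``:

    y = sum_c w_c * b_c + noise,   w_c >= 0,  sum_c w_c <= 1

Four estimators are provided; they differ in how the simplex constraint is
handled:

* ``lr``  — ordinary least squares, constraints applied a posteriori;
* ``rpc`` — robust (Huber M-estimator) regression fitted by iteratively
  reweighted least squares, constraints a posteriori;
* ``svr`` — linear-kernel nu-support-vector regression (CIBERSORT-style,
  best-of-a-nu-grid by RMSE), constraints a posteriori;
* ``cp``  — constrained projection: quadratic programming with the
  non-negativity and sum<=1 constraints imposed during the fit.

The a-posteriori rule zeroes negative coefficients and rescales the
positive remainder to sum to one. None of the regressions includes an
intercept: the mixing model has none.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.optimize import minimize
from sklearn.svm import NuSVR

from .core import BetaMatrix, CellFractions, ReferenceMatrix

logger = logging.getLogger(__name__)

METHODS = ("lr", "rpc", "svr", "cp")


@dataclass
class DeconvConfig:
    """Tuning knobs for the four estimators.

    ``huber_c`` is the Huber threshold in units of the robust residual scale
    (1.345 gives 95% efficiency under Gaussian noise); ``svr_nu_grid`` is the
    candidate nu set for support-vector regression, each in (0, 1).
    """

    method: str = "rpc"
    huber_c: float = 1.345
    rpc_max_iter: int = 50
    rpc_tol: float = 1e-6
    svr_nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if not all(0.0 < nu < 1.0 for nu in self.svr_nu_grid):
            raise ValueError("svr_nu_grid values must lie in (0, 1)")


def _check_design(B: np.ndarray, columns: list[str] | None = None) -> None:
    B = np.asarray(B, dtype=float)
    if B.shape[0] < B.shape[1]:
        raise ValueError("reference needs at least as many CpGs as cell types")
    rank = np.linalg.matrix_rank(B)
    if rank < B.shape[1]:
        # pivoted QR: the trailing pivots index the (near-)dependent columns
        _, _, piv = qr(B, mode="economic", pivoting=True)
        bad = piv[rank:]
        names = [columns[i] if columns else str(i) for i in sorted(bad)]
        raise ValueError(f"reference matrix is rank-deficient; collinear columns: {names}")


def estimate_lr(y: np.ndarray, B: np.ndarray, columns: list[str] | None = None) -> np.ndarray:
    """Ordinary least-squares coefficients of ``y ~ B w`` (no intercept)."""
    B = np.asarray(B, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_design(B, columns)
    w, *_ = np.linalg.lstsq(B, y, rcond=None)
    return w


def estimate_rpc(
    y: np.ndarray, B: np.ndarray, config: DeconvConfig | None = None
) -> np.ndarray:
    """Huber M-estimator coefficients via iteratively reweighted least squares.

    The residual scale is the median absolute deviation divided by 0.6745
    (consistent for the Gaussian SD), re-estimated at every iteration.
    Residuals within ``huber_c`` scales get weight 1, larger ones are
    downweighted proportionally. Starts from the OLS fit and stops when the
    largest coefficient change drops below ``rpc_tol``.
    """
    config = config or DeconvConfig(method="rpc")
    B = np.asarray(B, dtype=float)
    y = np.asarray(y, dtype=float)
    w = estimate_lr(y, B)
    c = config.huber_c
    for _ in range(config.rpc_max_iter):
        r = y - B @ w
        mad = np.median(np.abs(r - np.median(r)))
        scale = mad / 0.6745
        if scale <= 0:
            warnings.warn(
                "all residuals identical (zero MAD); returning current iterate",
                RuntimeWarning,
                stacklevel=2,
            )
            return w
        absr = np.abs(r)
        huber_w = np.where(absr <= c * scale, 1.0, c * scale / np.where(absr > 0, absr, 1.0))
        sw = np.sqrt(huber_w)
        w_new, *_ = np.linalg.lstsq(B * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(w_new - w)) < config.rpc_tol:
            return w_new
        w = w_new
    return w


def estimate_svr(
    y: np.ndarray,
    B: np.ndarray,
    config: DeconvConfig | None = None,
    return_details: bool = False,
):
    """Linear nu-SVR coefficients, best nu in the grid by fitted-vs-observed RMSE.

    One model is fitted per nu; the candidate with the smallest RMSE between
    its fitted values and ``y`` wins and its coefficient vector (intercept
    excluded) is returned. Features and response are used on the raw beta
    scale so coefficients remain interpretable as mixing weights.
    """
    config = config or DeconvConfig(method="svr")
    B = np.asarray(B, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_design(B)
    fits: list[tuple[float, float, np.ndarray]] = []  # (rmse, nu, coefs)
    for nu in config.svr_nu_grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = NuSVR(kernel="linear", nu=nu, C=1.0)
                model.fit(B, y)
            pred = model.predict(B)
            rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
            fits.append((rmse, nu, model.coef_.ravel().copy()))
        except Exception as exc:  # solver failure at this nu
            warnings.warn(
                f"nu-SVR failed at nu={nu}: {exc}", RuntimeWarning, stacklevel=2
            )
    if not fits:
        raise RuntimeError("nu-SVR failed at every nu in the grid")
    fits.sort(key=lambda item: item[0])
    best_rmse, best_nu, coefs = fits[0]
    if return_details:
        return coefs, {"rmse_by_nu": {nu: r for r, nu, _ in fits}, "best_nu": best_nu}
    return coefs


def estimate_cp(y: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Constrained projection: least squares with w >= 0 and sum(w) <= 1 built in.

    Solves the quadratic program ``min ||y - B w||^2`` over the truncated
    simplex via SLSQP with the analytic gradient; the origin is always
    feasible so the program cannot be infeasible.
    """
    B = np.asarray(B, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_design(B)
    C = B.shape[1]
    BtB = B.T @ B
    Bty = B.T @ y

    def objective(w: np.ndarray) -> float:
        r = B @ w - y
        return 0.5 * float(r @ r)

    def grad(w: np.ndarray) -> np.ndarray:
        return BtB @ w - Bty

    x0 = np.full(C, 1.0 / (2 * C))
    res = minimize(
        objective,
        x0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, None)] * C,
        constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum(), "jac": lambda w: -np.ones(C)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    if not res.success and res.status != 8:  # 8: positive directional derivative dust
        raise RuntimeError(f"constrained projection failed: {res.message}")
    w = np.clip(res.x, 0.0, None)
    total = w.sum()
    if total > 1.0:
        w = w / total  # shave constraint dust
    return w


def apply_aposteriori_constraints(w: np.ndarray) -> tuple[np.ndarray, bool]:
    """Zero negatives, rescale positives to sum to 1.

    Returns ``(fractions, degenerate)``; ``degenerate`` is True when every
    coefficient was non-positive and an all-zero row is returned.
    """
    w = np.asarray(w, dtype=float).copy()
    w[w < 0] = 0.0
    total = w.sum()
    if total <= 0:
        warnings.warn(
            "all weight estimates non-positive; returning an all-zero row",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros_like(w), True
    return w / total, False


def deconvolve(
    mix: BetaMatrix, ref: ReferenceMatrix, config: DeconvConfig | None = None
) -> CellFractions:
    """Estimate cell-type fractions for every sample in ``mix``.

    The mixture matrix is restricted to the CpGs shared with the reference
    (in reference order); estimation is per-sample with the configured
    method. LR/RPC/SVR coefficients pass through the a-posteriori simplex
    constraints; CP output already satisfies them.
    """
    config = config or DeconvConfig()
    shared = [c for c in ref.cpg_ids if c in set(mix.cpg_ids)]
    C = len(ref.cell_types)
    if len(shared) < C:
        raise ValueError(
            f"only {len(shared)} CpGs shared between mixture and reference; "
            f"need at least {C}"
        )
    logger.info("deconvolving over %d shared CpGs (%s)", len(shared), config.method)
    B = ref.data.loc[shared].to_numpy(dtype=float)
    Y = mix.data.loc[shared].to_numpy(dtype=float)
    columns = ref.cell_types
    rows = []
    degenerate: list[str] = []
    for j, sample in enumerate(mix.sample_ids):
        y = Y[:, j]
        if config.method == "lr":
            raw = estimate_lr(y, B, columns)
        elif config.method == "rpc":
            raw = estimate_rpc(y, B, config)
        elif config.method == "svr":
            raw = estimate_svr(y, B, config)
        else:
            raw = estimate_cp(y, B)
        if config.method == "cp":
            w = raw
        else:
            w, degen = apply_aposteriori_constraints(raw)
            if degen:
                degenerate.append(sample)
        rows.append(w)
    frame = pd.DataFrame(np.vstack(rows), index=mix.sample_ids, columns=columns)
    return CellFractions(frame, degenerate=tuple(degenerate))
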