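"""Restricted maximum likelihood estimation of SNP heritability.

The model is y = X b + g + e with Var(g) = sigma_g2 * A (A the GRM) and
Var(e) = sigma_e2 * I, so h2 = sigma_g2 / (sigma_g2 + sigma_e2). Components
are estimated by average-information (AI) REML after a few EM warm-up
iterations, with step-halving when a step lowers the restricted likelihood
and both components floored at ``floor_fraction * Var(y)``.

The restricted log-likelihood convention is
    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ]
with no additive constant, so likelihood-ratio statistics are
convention-free. Significance of sigma_g2 uses the one-sided boundary null
0.5*chi2_0 + 0.5*chi2_1, i.e. p = 0.5 * Pr(chi2_1 >= LRT).

Internally all fits run in the eigenbasis of A, where V is diagonal; a
dense-algebra evaluation of the same likelihood is exposed for
cross-checking and small problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .grm import GRM, CovariateMatrix

__all__ = [
    "RemlOptions",
    "HeritabilityResult",
    "restricted_loglik",
    "fit_reml",
    "fit_reml_batch",
    "write_hsq_table",
]

_P_FLOOR = 1e-300  # keep p strictly positive


@dataclass(frozen=True)
class RemlOptions:
    max_iter: int = 100
    tol: float = 1e-8
    floor_fraction: float = 1e-6
    em_warmup_iters: int = 3

    def __post_init__(self) -> None:
        if self.floor_fraction <= 0 or self.tol <= 0:
            raise ValueError("floor_fraction and tol must be positive")


@dataclass
class HeritabilityResult:
    trait_id: str
    sigma_g2: float
    sigma_e2: float
    h2: float
    h2_se: float
    loglik_full: float
    loglik_null: float
    lrt: float
    p_value: float
    n_iter: int
    converged: bool
    constrained: bool
    status: str = "ok"  # "ok" or a failure reason; failed fits carry NaNs


def _as_xy(x) -> np.ndarray:
    return x.values if isinstance(x, CovariateMatrix) else np.asarray(x, dtype=float)


def restricted_loglik(y, x, a, sigma_g2: float, sigma_e2: float) -> float:
    """Dense-algebra REML log-likelihood at fixed variance components.

    ``a`` may be a GRM or a plain symmetric matrix. sigma_g2 may be 0 as
    long as V = sigma_g2*A + sigma_e2*I stays positive definite.
    """
    y = np.asarray(y, dtype=float)
    xm = _as_xy(x)
    am = a.values if isinstance(a, GRM) else np.asarray(a, dtype=float)
    n = y.shape[0]
    v = sigma_g2 * am + sigma_e2 * np.eye(n)
    try:
        l_chol = np.linalg.cholesky(v)
    except np.linalg.LinAlgError as exc:
        raise ValueError("V is not positive definite") from exc
    logdet_v = 2.0 * np.log(np.diag(l_chol)).sum()
    vinv_x = np.linalg.solve(v, xm)
    vinv_y = np.linalg.solve(v, y)
    xtvx = xm.T @ vinv_x
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        raise ValueError("X' V^-1 X singular; X must have full column rank")
    beta = np.linalg.solve(xtvx, xm.T @ vinv_y)
    ypy = y @ vinv_y - (xm.T @ vinv_y) @ beta
    return float(-0.5 * (logdet_v + logdet_xtvx + ypy))


# ---------------------------------------------------------------------------
# Eigenbasis machinery
# ---------------------------------------------------------------------------

class _EigenDesign:
    """A rotated by its eigenbasis: V becomes diag(sg*d + se)."""

    def __init__(self, a, x) -> None:
        am = a.values if isinstance(a, GRM) else np.asarray(a, dtype=float)
        self.d, self.u = np.linalg.eigh(am)
        self.xt = self.u.T @ _as_xy(x)
        self.n, self.c = self.xt.shape

    def rotate(self, y: np.ndarray) -> np.ndarray:
        return self.u.T @ np.asarray(y, dtype=float)


def _eigen_quantities(eig: _EigenDesign, yt: np.ndarray, sg: float, se: float):
    """Return (loglik, Py, v) in the eigenbasis; Py is P @ yt."""
    v = sg * eig.d + se
    if (v <= 0).any():
        raise ValueError("V is not positive definite")
    vinv_y = yt / v
    vinv_x = eig.xt / v[:, None]
    xtvx = eig.xt.T @ vinv_x
    xtvy = eig.xt.T @ vinv_y
    chol = np.linalg.cholesky(xtvx)
    beta = np.linalg.solve(xtvx, xtvy)
    py = vinv_y - vinv_x @ beta
    logdet_v = np.log(v).sum()
    logdet_xtvx = 2.0 * np.log(np.diag(chol)).sum()
    ll = -0.5 * (logdet_v + logdet_xtvx + yt @ py)
    return float(ll), py, v


def _trace_pa(eig: _EigenDesign, v: np.ndarray, weights: np.ndarray) -> float:
    """tr(P diag-weighted A-part): weights = d for A, ones for I."""
    vinv_x = eig.xt / v[:, None]
    xtvx = eig.xt.T @ vinv_x
    # tr(P W) = tr(V^-1 W) - tr((X'V^-1X)^-1 X'V^-1 W V^-1 X), W = diag(weights)
    t1 = (weights / v).sum()
    m = vinv_x.T @ (vinv_x * weights[:, None])
    t2 = np.trace(np.linalg.solve(xtvx, m))
    return float(t1 - t2)


def _null_fit(eig: _EigenDesign, yt: np.ndarray) -> tuple[float, float]:
    """REML under sigma_g2 = 0: closed-form residual variance."""
    n, c = eig.n, eig.c
    xtx = eig.xt.T @ eig.xt
    beta = np.linalg.solve(xtx, eig.xt.T @ yt)
    rss = float(yt @ yt - (eig.xt.T @ yt) @ beta)
    se = rss / (n - c)
    ll, _, _ = _eigen_quantities(eig, yt, 0.0, se)
    return se, ll


def _fit_one(
    yt: np.ndarray,
    eig: _EigenDesign,
    opts: RemlOptions,
    var_y: float,
    trait_id: str,
) -> HeritabilityResult:
    n = eig.n
    floor = opts.floor_fraction * var_y
    d = eig.d
    ones = np.ones_like(d)

    sg = se = max(0.5 * var_y, floor)
    ll, py, v = _eigen_quantities(eig, yt, sg, se)
    n_iter = 0
    converged = False

    def derivs(py, v):
        apy = d * py  # A Py in eigenbasis
        tr_pa = _trace_pa(eig, v, d)
        tr_pi = _trace_pa(eig, v, ones)
        # dl/d(sigma) = -1/2 [tr(P A_i) - y'P A_i P y]
        grad = np.array([-0.5 * (tr_pa - py @ apy), -0.5 * (tr_pi - py @ py)])
        return grad, apy

    for it in range(opts.max_iter):
        n_iter = it + 1
        grad, apy = derivs(py, v)
        if it < opts.em_warmup_iters:
            # EM update: sigma_i <- sigma_i + sigma_i^2 * 2*grad_i / n
            step = np.array([sg, se]) ** 2 * 2.0 * grad / n
        else:
            # average-information matrix
            p_apy = _project(eig, v, apy)
            p_py = _project(eig, v, py)
            ai = 0.5 * np.array(
                [
                    [py @ (d * p_apy), py @ p_apy],
                    [py @ (d * p_py), py @ p_py],
                ]
            )
            ai = (ai + ai.T) / 2.0
            try:
                step = np.linalg.solve(ai + 1e-12 * np.eye(2), grad)
            except np.linalg.LinAlgError:
                step = np.array([sg, se]) ** 2 * 2.0 * grad / n
        new = np.maximum(np.array([sg, se]) + step, floor)
        ll_new, py_new, v_new = _eigen_quantities(eig, yt, new[0], new[1])
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new = np.maximum(np.array([sg, se]) + step, floor)
            ll_new, py_new, v_new = _eigen_quantities(eig, yt, new[0], new[1])
            halvings += 1
        delta = ll_new - ll
        sg, se = float(new[0]), float(new[1])
        ll, py, v = ll_new, py_new, v_new
        if it >= opts.em_warmup_iters and abs(delta) < opts.tol:
            converged = True
            break

    constrained = bool(np.isclose(sg, floor) or np.isclose(se, floor))
    h2 = sg / (sg + se)

    # delta-method SE from the inverse AI matrix at the optimum
    apy = d * py
    p_apy = _project(eig, v, apy)
    p_py = _project(eig, v, py)
    ai = 0.5 * np.array(
        [[py @ (d * p_apy), py @ p_apy], [py @ (d * p_py), py @ p_py]]
    )
    ai = (ai + ai.T) / 2.0
    try:
        cov = np.linalg.inv(ai)
        grad_h = np.array([se, -sg]) / (sg + se) ** 2
        h2_var = float(grad_h @ cov @ grad_h)
        h2_se = float(np.sqrt(h2_var)) if h2_var > 0 else float("nan")
    except np.linalg.LinAlgError:
        h2_se = float("nan")

    _, ll_null = _null_fit(eig, yt)
    lrt = max(0.0, 2.0 * (ll - ll_null))
    p_value = float(min(1.0, max(_P_FLOOR, 0.5 * chi2.sf(lrt, df=1))))

    return HeritabilityResult(
        trait_id=trait_id,
        sigma_g2=sg,
        sigma_e2=se,
        h2=float(h2),
        h2_se=h2_se,
        loglik_full=float(ll),
        loglik_null=float(ll_null),
        lrt=float(lrt),
        p_value=p_value,
        n_iter=n_iter,
        converged=converged,
        constrained=constrained,
    )


def _project(eig: _EigenDesign, v: np.ndarray, z: np.ndarray) -> np.ndarray:
    """P @ z in the eigenbasis."""
    vinv_z = z / v
    vinv_x = eig.xt / v[:, None]
    xtvx = eig.xt.T @ vinv_x
    return vinv_z - vinv_x @ np.linalg.solve(xtvx, eig.xt.T @ vinv_z)


def fit_reml(
    y,
    x,
    a,
    opts: RemlOptions = RemlOptions(),
    trait_id: str = "trait",
) -> HeritabilityResult:
    """Fit the two-component model for one trait.

    Raises on a constant phenotype or on axis mismatches; non-convergence
    within ``opts.max_iter`` returns a result with ``converged = False``.
    """
    y = np.asarray(y, dtype=float)
    xm = _as_xy(x)
    n = y.shape[0]
    if xm.shape[0] != n:
        raise ValueError("covariate rows do not match phenotype length")
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains non-finite values")
    var_y = float(np.var(y, ddof=1))
    if var_y == 0.0:
        raise ValueError("constant phenotype: variance components unidentifiable")
    if n < xm.shape[1] + 2:
        raise ValueError("need N >= C + 2 samples")
    eig = _EigenDesign(a, x)
    return _fit_one(eig.rotate(y), eig, opts, var_y, trait_id)


def fit_reml_batch(
    pheno,
    x,
    a,
    opts: RemlOptions = RemlOptions(),
) -> list[HeritabilityResult]:
    """Fit every column of a phenotype matrix, sharing one eigendecomposition.

    ``pheno`` is a VoxelQTMatrix (sample IDs checked against the GRM) or a
    plain N x V array. Degenerate (constant or non-finite) columns are
    recorded with ``status`` set to the failure reason and skipped.
    """
    from .voxelmap import VoxelQTMatrix

    if isinstance(pheno, VoxelQTMatrix):
        if isinstance(a, GRM) and pheno.samples != a.samples:
            missing = sorted(set(pheno.samples) ^ set(a.samples))
            raise ValueError(
                "phenotype and GRM sample IDs differ "
                f"(symmetric difference: {missing[:10]}{'...' if len(missing) > 10 else ''})"
            )
        values = pheno.values
        ids = [f"voxel_{i}_{j}_{k}" for i, j, k in pheno.index.coords]
    else:
        values = np.asarray(pheno, dtype=float)
        ids = [f"trait{j}" for j in range(values.shape[1])]

    eig = _EigenDesign(a, x)
    yt_all = eig.u.T @ values
    results: list[HeritabilityResult] = []
    nan = float("nan")
    for j in range(values.shape[1]):
        col = values[:, j]
        var_y = float(np.var(col, ddof=1))
        if not np.isfinite(col).all() or var_y == 0.0:
            reason = "non_finite_phenotype" if not np.isfinite(col).all() else "constant_phenotype"
            results.append(
                HeritabilityResult(
                    trait_id=ids[j], sigma_g2=nan, sigma_e2=nan, h2=nan,
                    h2_se=nan, loglik_full=nan, loglik_null=nan, lrt=nan,
                    p_value=nan, n_iter=0, converged=False, constrained=False,
                    status=reason,
                )
            )
            continue
        results.append(_fit_one(yt_all[:, j], eig, opts, var_y, ids[j]))
    return results


def write_hsq_table(results: list[HeritabilityResult], path) -> None:
    """TSV mirroring GCTA .hsq content, one row per trait."""
    rows = [
        {
            "id": r.trait_id,
            "sigma_g2": r.sigma_g2,
            "sigma_e2": r.sigma_e2,
            "h2": r.h2,
            "se": r.h2_se,
            "lrt": r.lrt,
            "p": r.p_value,
            "n_iter": r.n_iter,
            "converged": r.converged,
            "constrained": r.constrained,
            "status": r.status,
        }
        for r in results
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")
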