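"""Penalized-spline binomial additive model engine.

Fits logit(P(y=1)) = X beta where the design mixes unpenalized linear
columns, low-rank penalized spline bases (cubic P-splines with a
second-order difference penalty for one-dimensional smooths, optionally
cyclic; a knot-based thin-plate radial basis for the two-dimensional
spatial smooth), and ridge-penalized group dummies for random intercepts.
Coefficients are estimated by penalized IRLS; smoothing and variance
parameters by maximizing a Laplace-approximate restricted marginal
likelihood (the criterion mgcv calls REML for a GAM), so a random-intercept
block with penalty lambda * I corresponds to a Gaussian random effect with
standard deviation 1/sqrt(lambda).

This module is deliberately free of any domain vocabulary: it sees only a
response vector and design blocks.  The severity module translates a model
specification and a collision table into blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from .errors import ConvergenceError, InvalidArgumentError

MAX_ABS_COEF = 15.0  # |log-odds| beyond this is treated as separation drift


# ---------------------------------------------------------------------------
# Basis construction
# ---------------------------------------------------------------------------

def bspline_basis(x: np.ndarray, k: int = 10, degree: int = 3,
                  xrange: tuple[float, float] | None = None
                  ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Cubic B-spline design matrix with k basis functions and its
    second-order difference penalty (P-spline).

    Returns (X, S, meta) where meta lets the same basis be evaluated on a
    prediction grid.
    """
    x = np.asarray(x, dtype=float)
    if k < degree + 2:
        raise InvalidArgumentError(f"k must be >= {degree + 2}")
    if xrange is None:
        lo, hi = float(x.min()), float(x.max())
    else:
        lo, hi = xrange
    if hi <= lo:
        raise InvalidArgumentError("degenerate covariate range")
    # uniform extended knots (Eilers-Marx): the difference-penalty null
    # space then maps to curves exactly linear in x
    pad = 1e-9 * (hi - lo)
    h = (hi - lo + 2 * pad) / (k - degree)
    t = (lo - pad) + h * np.arange(-degree, k + 1)
    xc = np.clip(x, lo, hi)
    X = BSpline.design_matrix(xc, t, degree).toarray()
    D = np.diff(np.eye(k), n=2, axis=0)
    S = D.T @ D
    meta = {"kind": "bspline", "t": t, "degree": degree, "k": k,
            "range": (lo, hi)}
    return X, S, meta


def cyclic_bspline_basis(x: np.ndarray, k: int = 10, period: float = 24.0,
                         degree: int = 3
                         ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Cyclic cubic B-spline basis on [0, period) with a circular
    second-order difference penalty; column j of the extended basis folds
    onto j mod k, so the fitted curve and its derivatives wrap."""
    if k < degree + 1:
        raise InvalidArgumentError(f"k must be >= {degree + 1}")
    x = np.mod(np.asarray(x, dtype=float), period)
    h = period / k
    t = np.arange(-degree, k + degree + 1) * h
    Xe = BSpline.design_matrix(x, t, degree).toarray()
    X = np.zeros((len(x), k))
    for j in range(Xe.shape[1]):
        X[:, j % k] += Xe[:, j]
    D = np.zeros((k, k))
    for i in range(k):
        D[i, i] = 1.0
        D[i, (i + 1) % k] = -2.0
        D[i, (i + 2) % k] = 1.0
    S = D.T @ D
    meta = {"kind": "cyclic", "t": t, "degree": degree, "k": k,
            "period": period}
    return X, S, meta


def thinplate_2d_basis(xy: np.ndarray, k: int = 30
                       ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Low-rank thin-plate-type radial basis on a knot grid.

    Columns are [x, y, eta(||u - knot_j||)] with eta(r) = r^2 log r (r
    scaled by the knot spacing for conditioning); the penalty is the radial
    kernel matrix evaluated at the knots, eigenvalue-clipped to positive
    semidefinite, with the linear null space (x, y) unpenalized.
    """
    xy = np.asarray(xy, dtype=float)
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    m = max(2, int(round(np.sqrt(k))))
    gx = np.linspace(lo[0], hi[0], m)
    gy = np.linspace(lo[1], hi[1], m)
    knots = np.array([(a, b) for b in gy for a in gx])
    scale = float(np.mean(span) / m)

    def eta(r):
        with np.errstate(divide="ignore", invalid="ignore"):
            v = (r / scale) ** 2 * np.log(r / scale)
        return np.where(r > 0, v, 0.0)

    r_obs = np.sqrt(((xy[:, None, :] - knots[None, :, :]) ** 2).sum(axis=2))
    Xr = eta(r_obs)
    Xn = (xy - lo) / span  # null-space columns, scaled to [0, 1]
    X = np.column_stack([Xn, Xr])
    r_kk = np.sqrt(((knots[:, None, :] - knots[None, :, :]) ** 2).sum(axis=2))
    E = eta(r_kk)
    w, v = np.linalg.eigh((E + E.T) / 2)
    E_psd = (v * np.maximum(w, 0.0)) @ v.T
    S = np.zeros((X.shape[1], X.shape[1]))
    S[2:, 2:] = E_psd
    meta = {"kind": "thinplate2d", "knots": knots, "scale": scale,
            "lo": lo, "span": span}
    return X, S, meta


def evaluate_basis(meta: dict, x: np.ndarray) -> np.ndarray:
    """Evaluate a stored basis on new covariate values."""
    if meta["kind"] == "bspline":
        lo, hi = meta["range"]
        xc = np.clip(np.asarray(x, dtype=float), lo, hi)
        return BSpline.design_matrix(xc, meta["t"], meta["degree"]).toarray()
    if meta["kind"] == "cyclic":
        xm = np.mod(np.asarray(x, dtype=float), meta["period"])
        Xe = BSpline.design_matrix(xm, meta["t"], meta["degree"]).toarray()
        k = meta["k"]
        X = np.zeros((len(xm), k))
        for j in range(Xe.shape[1]):
            X[:, j % k] += Xe[:, j]
        return X
    if meta["kind"] == "thinplate2d":
        xy = np.asarray(x, dtype=float)
        knots = meta["knots"]
        scale = meta["scale"]

        def eta(r):
            with np.errstate(divide="ignore", invalid="ignore"):
                v = (r / scale) ** 2 * np.log(r / scale)
            return np.where(r > 0, v, 0.0)

        r = np.sqrt(((xy[:, None, :] - knots[None, :, :]) ** 2).sum(axis=2))
        Xn = (xy - meta["lo"]) / meta["span"]
        return np.column_stack([Xn, eta(r)])
    raise InvalidArgumentError(f"unknown basis kind {meta['kind']!r}")


def center_constraint(X: np.ndarray, S: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the sum-to-zero identifiability constraint to a smooth block.

    Reparameterizes to a basis orthogonal to the column-mean vector so the
    smooth carries no intercept; returns (XZ, Z'SZ, Z).
    """
    c = X.mean(axis=0)
    q, _ = np.linalg.qr(np.column_stack([c, np.eye(len(c))]))
    Z = q[:, 1:len(c)]
    return X @ Z, Z.T @ S @ Z, Z


# ---------------------------------------------------------------------------
# Model blocks and fitting
# ---------------------------------------------------------------------------

@dataclass
class Block:
    """One design block: columns of X with an optional single penalty."""

    name: str
    X: np.ndarray
    S: np.ndarray | None = None       # block-local penalty (None = linear)
    kind: str = "linear"              # linear | smooth | random
    meta: dict = field(default_factory=dict)
    Z: np.ndarray | None = None       # centering reparameterization


@dataclass
class GamFit:
    beta: np.ndarray
    cov: np.ndarray                   # Bayesian posterior covariance
    lambdas: np.ndarray               # per penalized block
    blocks: list[Block]
    slices: list[slice]
    edf: float
    deviance: float
    loglik: float
    n_obs: int
    converged: bool
    iterations: int
    separation_flags: np.ndarray      # per-coefficient bool

    def block_slice(self, name: str) -> slice:
        for blk, sl in zip(self.blocks, self.slices):
            if blk.name == name:
                return sl
        raise KeyError(name)

    def block(self, name: str) -> Block:
        for blk in self.blocks:
            if blk.name == name:
                return blk
        raise KeyError(name)

    def random_sd(self) -> dict[str, float]:
        """Random-effect standard deviations implied by the ridge penalties
        (binomial scale parameter is 1)."""
        out = {}
        j = 0
        for blk in self.blocks:
            if blk.S is not None:
                if blk.kind == "random":
                    out[blk.name] = float(1.0 / np.sqrt(self.lambdas[j]))
                j += 1
        return out


def _binomial_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    sat = 0.0  # saturated loglik is 0 for 0/1 responses
    return -2.0 * (_binomial_loglik(y, mu) - sat)


def _pirls(y: np.ndarray, X: np.ndarray, S_full: np.ndarray,
           beta0: np.ndarray | None = None, tol: float = 1e-8,
           max_iter: int = 200) -> dict:
    """Penalized IRLS for a binomial GLM with fixed total penalty S_full."""
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    eta = X @ beta
    mu = 1 / (1 + np.exp(-eta))
    pen_dev = _binomial_deviance(y, mu) + float(beta @ S_full @ beta)
    trace = [pen_dev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        A = X.T @ Xw + S_full
        b = Xw.T @ z
        ridge = 0.0
        for _ in range(6):
            try:
                c, low = cho_factor(A + ridge * np.eye(p), lower=True)
                beta_new = cho_solve((c, low), b)
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10, 1e-8)
        else:  # pragma: no cover
            raise ConvergenceError("normal equations not factorizable",
                                   trace)
        # step halving if the penalized deviance does not improve
        step = 1.0
        for _ in range(30):
            cand = beta + step * (beta_new - beta)
            eta_c = X @ cand
            mu_c = 1 / (1 + np.exp(-eta_c))
            pd_c = _binomial_deviance(y, mu_c) + float(cand @ S_full @ cand)
            if pd_c <= pen_dev + 1e-12 or step < 1e-6:
                break
            step *= 0.5
        beta, eta, mu = cand, eta_c, mu_c
        delta = abs(pen_dev - pd_c)
        pen_dev = pd_c
        trace.append(pen_dev)
        if delta < tol * (abs(pen_dev) + 1.0):
            converged = True
            break
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = X.T @ (X * w[:, None])
    return {"beta": beta, "mu": mu, "H": H, "pen_dev": pen_dev,
            "deviance": _binomial_deviance(y, mu),
            "loglik": _binomial_loglik(y, mu),
            "converged": converged, "iterations": it, "trace": trace}


def _logdet_psd(A: np.ndarray) -> float:
    w = np.linalg.eigvalsh((A + A.T) / 2)
    w = w[w > 1e-12 * max(w.max(), 1.0)]
    return float(np.log(w).sum())


def fit_penalized_glm(y: np.ndarray, blocks: list[Block],
                      lambdas: np.ndarray | None = None,
                      optimize_lambda: bool = True,
                      tol: float = 1e-8,
                      rho_bounds: tuple[float, float] = (-12.0, 18.0)
                      ) -> GamFit:
    """Fit the binomial penalized model, selecting smoothing parameters by
    Laplace-approximate restricted marginal likelihood unless fixed
    ``lambdas`` are given."""
    y = np.asarray(y, dtype=float)
    Xs, slices, j0 = [], [], 0
    for blk in blocks:
        Xs.append(blk.X)
        slices.append(slice(j0, j0 + blk.X.shape[1]))
        j0 += blk.X.shape[1]
    X = np.hstack(Xs)
    n, p = X.shape
    pen_idx = [i for i, blk in enumerate(blocks) if blk.S is not None]
    # positive eigenvalues of each block penalty: rank and log-pseudodet
    pen_eigs = []
    for i in pen_idx:
        w = np.linalg.eigvalsh(blocks[i].S)
        wpos = w[w > 1e-10 * max(w.max(), 1.0)]
        pen_eigs.append(wpos)

    def total_penalty(lam: np.ndarray) -> np.ndarray:
        S = np.zeros((p, p))
        for lam_k, i in zip(lam, pen_idx):
            sl = slices[i]
            S[sl, sl] += lam_k * blocks[i].S
        return S

    warm = {"beta": None}

    def neg_laml(rho: np.ndarray) -> float:
        rho = np.clip(rho, *rho_bounds)
        lam = np.exp(rho)
        S = total_penalty(lam)
        res = _pirls(y, X, S, beta0=warm["beta"], tol=tol)
        warm["beta"] = res["beta"]
        beta = res["beta"]
        l_pen = res["loglik"] - 0.5 * float(beta @ S @ beta)
        log_s = sum(len(e) * r + float(np.log(e).sum())
                    for e, r in zip(pen_eigs, rho))
        log_h = _logdet_psd(res["H"] + S)
        return -(l_pen + 0.5 * log_s - 0.5 * log_h)

    if pen_idx and lambdas is None and optimize_lambda:
        rho0 = np.zeros(len(pen_idx))
        if len(pen_idx) == 1:
            r = optimize.minimize_scalar(
                lambda r: neg_laml(np.array([r])),
                bounds=rho_bounds, method="bounded",
                options={"xatol": 1e-3})
            rho_hat = np.array([r.x])
        else:
            r = optimize.minimize(neg_laml, rho0, method="Nelder-Mead",
                                  options={"xatol": 1e-2, "fatol": 1e-4,
                                           "maxiter": 200 * len(pen_idx)})
            rho_hat = np.clip(r.x, *rho_bounds)
        lam = np.exp(rho_hat)
    elif pen_idx:
        lam = np.ones(len(pen_idx)) if lambdas is None \
            else np.asarray(lambdas, dtype=float)
    else:
        lam = np.array([])

    S = total_penalty(lam) if pen_idx else np.zeros((p, p))
    res = _pirls(y, X, S, beta0=warm["beta"], tol=tol, max_iter=400)
    if not res["converged"]:
        sep = np.abs(res["beta"]) > MAX_ABS_COEF
        if not sep.any():
            raise ConvergenceError("penalized IRLS did not converge",
                                   res["trace"])
    H = res["H"]
    A = H + S
    ridge = 0.0
    for _ in range(8):
        try:
            c, low = cho_factor(A + ridge * np.eye(p), lower=True)
            cov = cho_solve((c, low), np.eye(p))
            break
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10, 1e-8)
    edf = float(np.trace(cov @ H))
    sep_flags = np.abs(res["beta"]) > MAX_ABS_COEF
    return GamFit(beta=res["beta"], cov=cov, lambdas=lam, blocks=blocks,
                  slices=slices, edf=edf, deviance=res["deviance"],
                  loglik=res["loglik"], n_obs=n,
                  converged=res["converged"], iterations=res["iterations"],
                  separation_flags=sep_flags)
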