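"""Phylogenetic count regression by generalized estimating equations.

The model keeps the GLM mean structure (Poisson or NB2, log or canonical
link) but replaces the independence assumption with a working covariance

    W = S^{1/2} C S^{1/2},

where C is the tree's shared-branch-length matrix and S = diag(V(mu_i)) the
family variances.  The regression coefficients solve the quasi-score system

    U(beta) = D' W^{-1} (Y - mu) = 0,    D = diag(dmu/deta) X,

which reduces exactly to the GLM score X'(Y - mu) when C is (a multiple of)
the identity — the star-tree case.  beta is found by damped Fisher scoring
with step-halving; a singular working covariance falls back to an SVD
pseudo-inverse with a relative singular-value cutoff.

Uniform rescaling of the tree multiplies W by a constant and therefore
cancels in the root: estimates do not depend on the tree's time units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .data import CountRegData
from .families import NB2, DomainError, Family, Poisson
from .glm import CountGLM
from .tree import PhyloCovariance

__all__ = ["gee_score", "fitted_values", "PhyloGEE", "PhyloGEEResults"]


def _working_parts(beta, data: CountRegData, fam: Family, working_variance: str):
    eta = data.X @ beta
    fam.check_domain(eta, labels=data.labels)
    mu = fam.mean(eta)
    if working_variance == "model":
        V = fam.variance(mu)
    elif working_variance == "mean":
        V = np.asarray(mu, dtype=float).copy()
    else:
        raise ValueError(f"unknown working_variance {working_variance!r}")
    D = fam.dmu_deta(eta)[:, None] * data.X
    return mu, V, D


class _WorkingCov:
    """Solver for W = S^{1/2} C S^{1/2}: Cholesky, else SVD pseudo-inverse."""

    def __init__(self, C: np.ndarray, V: np.ndarray, rcond: float = 1e-10):
        s = np.sqrt(np.maximum(V, 0.0))
        with np.errstate(invalid="ignore", over="ignore"):
            self.W = s[:, None] * C * s[None, :]
        if not np.all(np.isfinite(self.W)):
            raise FloatingPointError("non-finite working covariance")
        self.rcond = rcond
        self.used_pinv = False
        try:
            self._cho = linalg.cho_factor(self.W, lower=True)
            self._pinv = None
        except linalg.LinAlgError:
            self._cho = None
            self._pinv = linalg.pinvh(self.W, rtol=rcond)
            self.used_pinv = True

    def solve(self, b: np.ndarray) -> np.ndarray:
        if self._cho is not None:
            return linalg.cho_solve(self._cho, b)
        return self._pinv @ b

    def cond(self) -> float:
        return float(np.linalg.cond(self.W))


def gee_score(
    beta,
    data: CountRegData,
    C: PhyloCovariance,
    fam: Family,
    working_variance: str = "model",
    rcond: float = 1e-10,
) -> np.ndarray:
    """Evaluate the estimating function U(beta) = D' W^{-1} (Y - mu).

    ``working_variance="model"`` uses the family variance in S (for NB2 the
    full mu + mu^2/r); ``"mean"`` uses S = diag(mu), the literal reading of
    the NB2 working matrix, kept as an option for comparison.
    """
    beta = np.asarray(beta, dtype=float)
    Cm = _as_matrix(C, data)
    mu, V, D = _working_parts(beta, data, fam, working_variance)
    wc = _WorkingCov(Cm, V, rcond=rcond)
    return D.T @ wc.solve(data.y - mu)


def _as_matrix(C, data: CountRegData) -> np.ndarray:
    if isinstance(C, PhyloCovariance):
        if C.labels != data.labels:
            C = C.reorder(data.labels)
        Cm = C.matrix
    else:
        Cm = np.asarray(C, dtype=float)
    if Cm.shape != (data.n, data.n):
        raise ValueError(f"C has shape {Cm.shape}, expected ({data.n}, {data.n})")
    w = np.linalg.eigvalsh(Cm)
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise ValueError("C is not positive semi-definite")
    return Cm


def fitted_values(fit: "PhyloGEEResults", X: np.ndarray | None = None) -> np.ndarray:
    """Fitted means mu-hat at the estimated coefficients.

    Poisson / log-link NB2: exp(X beta); canonical-link NB2:
    r exp(X beta) / (1 - exp(X beta)).
    """
    if X is None:
        return fit.fittedvalues
    X = np.atleast_2d(np.asarray(X, dtype=float))
    eta = X @ fit.params
    fit.family.check_domain(eta)
    return fit.family.mean(eta)


@dataclass
class PhyloGEEResults:
    """Solution of the phylogenetic estimating equations."""

    params: np.ndarray
    colnames: list[str]
    family: Family
    converged: bool
    iterations: int
    score_norm: float
    scaled_score_norm: float
    fittedvalues: np.ndarray
    working_cov_conditioning: float
    used_pinv: bool
    model: "PhyloGEE" = field(repr=False, default=None)

    @property
    def r(self) -> float | None:
        return getattr(self.family, "r", None)

    def predict(self, X=None) -> np.ndarray:
        return fitted_values(self, X)

    def bootstrap(self, B: int = 1000, seed: int | None = None, level: float = 0.95):
        from .bootstrap import parametric_bootstrap

        return parametric_bootstrap(self, B=B, seed=seed, level=level)

    def summary(self) -> str:
        fam = self.family
        head = f"Phylogenetic {fam.name.upper()} regression via GEE ({fam.link} link)"
        lines = [head]
        if self.r is not None:
            lines.append(f"dispersion r (fixed) = {self.r:.4g}")
        lines.append(
            f"converged = {self.converged} ({self.iterations} iterations), "
            f"max |score| = {self.score_norm:.3e} "
            f"(scaled {self.scaled_score_norm:.3e})"
        )
        lines.append(
            f"working covariance condition number = "
            f"{self.working_cov_conditioning:.3e}"
            + ("  [pseudo-inverse used]" if self.used_pinv else "")
        )
        lines.append(f"{'term':>12} {'estimate':>12}")
        for name, b in zip(self.colnames, self.params):
            lines.append(f"{name:>12} {b:>12.6g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "family": self.family.name,
            "link": self.family.link,
            "r": None if self.r is None else float(self.r),
            "params": dict(zip(self.colnames, map(float, self.params))),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "score_norm": float(self.score_norm),
            "scaled_score_norm": float(self.scaled_score_norm),
            "working_cov_conditioning": float(self.working_cov_conditioning),
            "pseudo_inverse": bool(self.used_pinv),
        }


class PhyloGEE:
    """Phylogenetic Poisson/NB2 regression model.

    Parameters
    ----------
    data:
        aligned counts and design matrix.
    C:
        tree covariance (``PhyloCovariance`` or plain PSD array aligned to
        ``data.labels``).  Used as a covariance, not a correlation: any
        uniform rescaling cancels in the estimating-equation root.
    family:
        a :class:`~phylocount.families.Family`; for NB2 the dispersion r is
        fixed inside the family object (it is not estimated by the GEE).
    working_variance:
        ``"model"`` (default, S = family variance) or ``"mean"``
        (S = diag(mu), the literal NB2 working matrix variant).
    """

    def __init__(
        self,
        data: CountRegData,
        C,
        family: Family | None = None,
        working_variance: str = "model",
        rcond: float = 1e-10,
    ):
        self.data = data
        self.family = family if family is not None else Poisson()
        self.working_variance = working_variance
        self.rcond = rcond
        self.C = _as_matrix(C, data)

    @classmethod
    def from_dataframe(cls, df, response, covariates, tree, family=None, **kw):
        from .data import align_data

        data, C = align_data(tree, df, response, covariates)
        return cls(data, C, family=family, **kw)

    def score(self, beta) -> np.ndarray:
        mu, V, D = _working_parts(beta, self.data, self.family, self.working_variance)
        wc = _WorkingCov(self.C, V, rcond=self.rcond)
        return D.T @ wc.solve(self.data.y - mu)

    def _start_params(self) -> np.ndarray:
        """Initial beta from the corresponding independent GLM fit.

        For saturated problems (n <= p+1, where the GLM refuses to fit) a
        least-squares fit on the link scale of the shifted counts is used.
        """
        fam = self.family
        if self.data.n <= self.data.p + 1:
            eta0 = fam.link_of_mean(np.maximum(self.data.y, 0.5))
            beta0, *_ = np.linalg.lstsq(self.data.X, eta0, rcond=None)
            return beta0
        if isinstance(fam, Poisson):
            return CountGLM(self.data, "poisson").fit().params
        glm = CountGLM(self.data, "nb2").fit(r=fam.r)
        if fam.link == "log":
            return glm.params
        # map the log-link fit onto the canonical-link scale through the means
        mu = np.maximum(glm.fittedvalues, 1e-8)
        eta_c = np.log(mu / (mu + fam.r))
        beta0, *_ = np.linalg.lstsq(self.data.X, eta_c, rcond=None)
        return beta0

    def fit(
        self,
        start_params=None,
        maxiter: int = 100,
        tol: float = 1e-8,
        beta_rtol: float = 1e-10,
        max_halvings: int = 30,
    ) -> PhyloGEEResults:
        """Solve U(beta) = 0 by damped Fisher scoring.

        The Newton direction uses the quasi-information J = D' W^{-1} D;
        steps are halved until the sup-norm of the score decreases (and, for
        the canonical NB2 link, until the predictor stays in-domain).

        Convergence is declared when the score, standardized componentwise
        by max(1, sqrt(J_jj)), falls below ``tol`` in sup-norm.  The
        standardization makes the test invariant to the scale of the counts
        (an absolute test is unattainable in double precision once fitted
        means reach ~1e7, where the score's floating-point floor exceeds any
        fixed small tolerance).  A fit that exhausts ``maxiter`` or stalls
        is returned with ``converged=False``.
        """
        data, fam = self.data, self.family
        beta = (
            np.asarray(start_params, dtype=float)
            if start_params is not None
            else self._start_params()
        )
        fam.check_domain(data.X @ beta, labels=data.labels)

        def evaluate(b):
            mu, V, D = _working_parts(b, data, fam, self.working_variance)
            wc = _WorkingCov(self.C, V, rcond=self.rcond)
            U = D.T @ wc.solve(data.y - mu)
            J = D.T @ wc.solve(D)
            scale = np.maximum(1.0, np.sqrt(np.abs(np.diag(J))))
            snorm = float(np.max(np.abs(U) / scale))
            return mu, D, wc, U, J, snorm

        used_pinv = False
        last_wc = None
        norm = np.inf
        snorm = np.inf
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            mu, D, wc, U, J, snorm = evaluate(beta)
            last_wc = wc
            used_pinv = used_pinv or wc.used_pinv
            norm = float(np.max(np.abs(U)))
            if snorm < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(J, U)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(J, U, rcond=self.rcond)[0]
            # damped update: require in-domain predictor and score decrease
            accepted = False
            for h in range(max_halvings + 1):
                cand = beta + step / (2.0**h)
                if not fam.in_domain(data.X @ cand):
                    continue
                try:
                    _, _, _, U_c, _, snorm_c = evaluate(cand)
                except (DomainError, FloatingPointError):
                    continue
                if np.all(np.isfinite(U_c)) and snorm_c < snorm:
                    accepted = True
                    break
            if not accepted:
                break
            small_move = np.max(np.abs(cand - beta)) <= beta_rtol * max(
                1.0, float(np.max(np.abs(beta)))
            )
            beta = cand
            if small_move:
                mu, D, wc, U, J, snorm = evaluate(beta)
                last_wc = wc
                norm = float(np.max(np.abs(U)))
                converged = snorm < tol
                break

        if not converged:
            warnings.warn(
                f"phylogenetic GEE did not converge (max |scaled score| = "
                f"{snorm:.3e} after {it} iterations)",
                RuntimeWarning,
                stacklevel=2,
            )
        eta = data.X @ beta
        return PhyloGEEResults(
            params=beta,
            colnames=data.colnames,
            family=fam,
            converged=converged,
            iterations=it,
            score_norm=norm,
            scaled_score_norm=snorm,
            fittedvalues=fam.mean(eta),
            working_cov_conditioning=last_wc.cond() if last_wc is not None else np.nan,
            used_pinv=used_pinv,
            model=self,
        )
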