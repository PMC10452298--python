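"""Brute-force root enumeration for the 2-parameter GEE score.

Independent of the package's damped Fisher-scoring solver: the estimating
function D' W^{-1} (Y - mu) is re-implemented here from its definition, its
sup-norm is scanned on a dense 2-D grid over a (beta0, beta1) box, and each
local minimum of the scanned surface is polished with MINPACK's hybrid
(modified Powell) root finder.  Small-n problems can have several genuine
roots; all distinct ones found in the box are returned.
"""

import numpy as np
from scipy import optimize

from phylocount.tree import PhyloCovariance


def make_score(data, C, fam):
    """Direct evaluation of U(beta) = D' W^{-1} (Y - mu) for p = 1."""
    Cm = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, float)
    X, y = data.X, data.y.astype(float)

    def score(beta):
        eta = X @ beta
        try:
            fam.check_domain(eta)
            mu = fam.mean(eta)
        except ValueError:
            return np.array([np.inf, np.inf])
        V = fam.variance(mu)
        s = np.sqrt(V)
        W = s[:, None] * Cm * s[None, :]
        D = fam.dmu_deta(eta)[:, None] * X
        try:
            sol = np.linalg.solve(W, y - mu)
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(W) @ (y - mu)
        return D.T @ sol

    return score


def brute_force_roots(data, C, fam, b0_range=(-8.0, 10.0),
                      b1_range=(-10.0, 12.0), n_grid=100):
    """All distinct roots of the estimating equations inside the search box."""
    score = make_score(data, C, fam)

    def norm(b0, b1):
        u = score(np.array([b0, b1]))
        return float(np.max(np.abs(u))) if np.all(np.isfinite(u)) else np.inf

    g0 = np.linspace(*b0_range, n_grid)
    g1 = np.linspace(*b1_range, n_grid)
    vals = np.array([[norm(a, b) for b in g1] for a in g0])
    pad = np.pad(vals, 1, constant_values=np.inf)
    local_min = (
        (vals <= pad[:-2, 1:-1]) & (vals <= pad[2:, 1:-1])
        & (vals <= pad[1:-1, :-2]) & (vals <= pad[1:-1, 2:])
        & np.isfinite(vals)
    )
    candidates = sorted(zip(vals[local_min], zip(*np.nonzero(local_min))))[:10]
    scale = float(np.median(vals[np.isfinite(vals)])) + 1.0
    roots = []
    for _, (i, j) in candidates:
        x0 = np.array([g0[i], g1[j]])
        if any(np.max(np.abs(x0 - r)) < 0.2 for r in roots):
            continue
        sol = optimize.root(score, x0, method="hybr", tol=1e-13)
        if not np.all(np.isfinite(sol.x)):
            continue
        if norm(*sol.x) < 1e-8 * scale:
            if not any(np.max(np.abs(sol.x - r)) < 1e-3 for r in roots):
                roots.append(sol.x)
    return roots
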