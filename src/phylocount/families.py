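"""Mean/variance/link specifications for the count regression families.

Each family maps the linear predictor ``eta = X beta`` to the conditional
mean ``mu``, the conditional variance ``V``, and the derivative
``dmu/deta`` needed by the estimating equations.

* Poisson with log link: ``mu = V = dmu/deta = exp(eta)``.
* NB2 with log link: ``mu = exp(eta)``, ``V = mu + mu^2/r``, ``dmu/deta = mu``.
* NB2 with its canonical link ``theta = log(mu/(mu+r))``:
  ``mu = r e^eta/(1-e^eta)``, ``V = dmu/deta = r e^eta/(1-e^eta)^2``,
  defined only for ``eta < 0``.

The NB2 dispersion ``r`` (variance ``mu + mu^2/r``; Poisson recovered as
r -> infinity) is a fixed attribute of the family object, not estimated by
the GEE.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Family", "Poisson", "NB2", "family_from_name"]


class DomainError(ValueError):
    """Linear predictor outside the family's domain."""


class Family:
    """Abstract link/mean/variance triple."""

    name: str
    link: str

    def mean(self, eta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def variance(self, mu: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def dmu_deta(self, eta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def check_domain(self, eta: np.ndarray, labels=None) -> None:
        """Raise :class:`DomainError` if eta is outside the link's domain."""
        return None

    def in_domain(self, eta: np.ndarray) -> bool:
        try:
            self.check_domain(eta)
        except DomainError:
            return False
        return True

    def link_of_mean(self, mu: np.ndarray) -> np.ndarray:
        """Inverse direction: eta as a function of mu (used for starting values)."""
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{type(self).__name__} link={self.link}>"


class Poisson(Family):
    """Poisson family, log link."""

    name = "poisson"
    link = "log"

    def mean(self, eta):
        with np.errstate(over="ignore"):
            return np.exp(np.asarray(eta, dtype=float))

    def variance(self, mu):
        return np.asarray(mu, dtype=float)

    def dmu_deta(self, eta):
        with np.errstate(over="ignore"):
            return np.exp(np.asarray(eta, dtype=float))

    def link_of_mean(self, mu):
        return np.log(np.asarray(mu, dtype=float))


class NB2(Family):
    """Negative binomial (NB2) family with fixed dispersion r.

    Variance is ``mu + mu^2/r``.  ``link="log"`` is the convention used for
    fitting empirical data; ``link="canonical"`` (theta = log(mu/(mu+r)),
    valid only for eta < 0) matches the parameterization used in the
    simulation study.
    """

    name = "nb2"

    def __init__(self, r: float, link: str = "log"):
        if not np.isfinite(r) or r <= 0:
            raise ValueError(f"dispersion r must be positive, got {r}")
        if link not in ("log", "canonical"):
            raise ValueError(f"unknown NB2 link {link!r}")
        self.r = float(r)
        self.link = link

    def check_domain(self, eta, labels=None):
        if self.link == "canonical":
            eta = np.asarray(eta, dtype=float)
            bad = np.nonzero(eta >= 0)[0]
            if bad.size:
                where = (
                    [labels[i] for i in bad] if labels is not None else bad.tolist()
                )
                raise DomainError(
                    "canonical NB2 link requires eta < 0; violated at "
                    f"{where}"
                )

    def mean(self, eta):
        eta = np.asarray(eta, dtype=float)
        if self.link == "log":
            with np.errstate(over="ignore"):
                return np.exp(eta)
        self.check_domain(eta)
        q = np.exp(eta)
        return self.r * q / (1.0 - q)

    def variance(self, mu):
        mu = np.asarray(mu, dtype=float)
        return mu + mu**2 / self.r

    def dmu_deta(self, eta):
        eta = np.asarray(eta, dtype=float)
        if self.link == "log":
            with np.errstate(over="ignore"):
                return np.exp(eta)
        self.check_domain(eta)
        q = np.exp(eta)
        return self.r * q / (1.0 - q) ** 2

    def link_of_mean(self, mu):
        mu = np.asarray(mu, dtype=float)
        if self.link == "log":
            return np.log(mu)
        return np.log(mu / (mu + self.r))

    def success_prob(self, mu):
        """NB success probability p = r/(r+mu) (scipy.stats.nbinom convention)."""
        mu = np.asarray(mu, dtype=float)
        return self.r / (self.r + mu)


def family_from_name(name: str, r: float | None = None, link: str | None = None) -> Family:
    name = name.lower()
    if name == "poisson":
        return Poisson()
    if name == "nb2":
        if r is None:
            raise ValueError("NB2 family requires a dispersion r")
        return NB2(r, link=link or "log")
    raise ValueError(f"unknown family {name!r}")
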