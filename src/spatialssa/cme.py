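"""Exact stationary solution of the reversible-binding master equation.

A single compartment holding ``D_T`` binding sites and ``P_T`` proteins,
with only binding and unbinding active, is a finite birth-death chain in the
number of bound complexes ``n in {0, ..., min(D_T, P_T)}``:

* birth (binding):   ``(kf/omega) (D_T - n)(P_T - n)``
* death (unbinding): ``kb * n``

Its stationary law follows from detailed balance and is evaluated in
log-space.  This module is the brute-force oracle against which the QSSA
expressions are validated, and it generates the relative-error landscape of
the total-QSSA over small copy-number grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "BindingChain",
    "StationaryDistribution",
    "stationary_distribution",
    "mean_free_sites_exact",
    "error_map",
]

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class BindingChain:
    """Reversible-binding birth-death chain over the bound-complex count."""

    D_T: int
    P_T: int
    kf_per_omega: float
    kb: float

    def __post_init__(self) -> None:
        if self.D_T < 0 or self.P_T < 0:
            raise ValueError("totals must be nonnegative")
        if self.kf_per_omega <= 0 or self.kb <= 0:
            raise ValueError("rates must be > 0")

    @classmethod
    def from_kd(cls, D_T: int, P_T: int, Kd: float) -> "BindingChain":
        """Chain with unit unbinding rate and the given dissociation constant."""
        return cls(D_T, P_T, kf_per_omega=1.0 / Kd, kb=1.0)

    @property
    def n_states(self) -> int:
        return min(self.D_T, self.P_T) + 1

    def birth_rate(self, n: int) -> float:
        return self.kf_per_omega * (self.D_T - n) * (self.P_T - n)

    def death_rate(self, n: int) -> float:
        return self.kb * n


@dataclass(frozen=True)
class StationaryDistribution:
    """Stationary probabilities over the bound count with its two means."""

    probabilities: np.ndarray  # index n = number of bound complexes
    mean_free_sites: float
    mean_free_proteins: float

    def __post_init__(self) -> None:
        p = self.probabilities
        if np.any(p < 0) or abs(p.sum() - 1.0) > _NORM_TOL:
            raise ValueError("stationary probabilities must be a distribution")


def stationary_distribution(chain: BindingChain) -> StationaryDistribution:
    """Detailed-balance solution ``pi(n) ~ prod_k birth(k-1)/death(k)``.

    Log-space cumulative products keep the evaluation overflow-safe for any
    copy numbers.
    """
    n_max = chain.n_states - 1
    logpi = np.zeros(chain.n_states)
    for n in range(1, n_max + 1):
        logpi[n] = logpi[n - 1] + np.log(chain.birth_rate(n - 1)) - np.log(
            chain.death_rate(n)
        )
    logpi -= logsumexp(logpi)
    pi = np.exp(logpi)
    pi /= pi.sum()  # remove residual rounding
    n = np.arange(chain.n_states)
    return StationaryDistribution(
        probabilities=pi,
        mean_free_sites=float(np.dot(chain.D_T - n, pi)),
        mean_free_proteins=float(np.dot(chain.P_T - n, pi)),
    )


def mean_free_sites_exact(chain: BindingChain) -> float:
    """Exact stationary mean of the free-site count, ``sum (D_T - n) pi(n)``."""
    return stationary_distribution(chain).mean_free_sites


def error_map(
    method,
    D_T_range: Iterable[int],
    P_T_range: Iterable[int],
    K_d: float,
    eps: float = 1e-12,
) -> pd.DataFrame:
    """Relative error of a reduction against the exact stationary mean.

    Returns a tidy frame with columns ``D_T, P_T, K_d, method, exact,
    approx, rel_error`` where
    ``rel_error = |D_q - <D>_exact| / max(<D>_exact, eps)``.
    """
    from . import qssa

    tag = method.tag if hasattr(method, "tag") else str(method)
    rows = []
    for dt in D_T_range:
        for pt in P_T_range:
            chain = BindingChain.from_kd(int(dt), int(pt), K_d)
            exact = mean_free_sites_exact(chain)
            approx = qssa.expected_free_sites(tag, int(dt), int(pt), K_d)
            rows.append(
                {
                    "D_T": int(dt),
                    "P_T": int(pt),
                    "K_d": K_d,
                    "method": tag,
                    "exact": exact,
                    "approx": approx,
                    "rel_error": abs(approx - exact) / max(exact, eps),
                }
            )
    return pd.DataFrame(rows)
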