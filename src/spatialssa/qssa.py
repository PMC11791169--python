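"""Quasi-steady-state reductions of the reversible DNA-repressor binding step.

When binding/unbinding is much faster than transcription, degradation and
diffusion, the free-site count ``D`` inside a compartment equilibrates
conditionally on the slow totals ``D_T = D + D:P`` and ``P_T = P + D:P``.
Two reductions replace ``D`` by an expectation:

* **slQSSA** (stochastic low-state QSSA): the exact stationary mean of the
  binding/unbinding birth-death chain,

  ``<D> = sum_l l * w_l / sum_l w_l``,
  ``w_l = K_d^l / (l! (D_T - l)! (P_T - D_T + l)!)``,

  summed over the admissible number of free sites
  ``l = max(0, D_T - P_T), ..., D_T``.

* **stQSSA** (stochastic total QSSA): the nonnegative root of the
  deterministic total-QSSA quadratic
  ``x^2 - (D_T - P_T - K_d) x - K_d D_T = 0``, i.e.
  ``x = [(D_T - P_T - K_d) + sqrt((D_T - P_T - K_d)^2 + 4 K_d D_T)] / 2``.

The stQSSA is accurate for weak binding or strongly unbalanced totals, but
inflates the expected free-site count when binding is tight
(``K_d << 1``) and ``D_T ~ P_T`` — the regime spatial compartments enter
locally even when the domain-wide totals are unbalanced.

Free-protein bookkeeping: bound proteins cannot diffuse, so reduced models
diffuse (and degrade, in the oscillator) the expected *free* protein count
``P_q = P_T - (D_T - D_q)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ReactionChannel, ReactionSystem

__all__ = [
    "QssaMethod",
    "slqssa_free_sites",
    "slqssa_low_state_closed_form",
    "stqssa_free_sites",
    "expected_free_sites",
    "free_protein",
    "compile_reduced_spatial_system",
    "REDUCED_SPECIES",
]

REDUCED_SPECIES = ("DT", "PT", "M")


@dataclass(frozen=True)
class QssaMethod:
    """A reduction tag plus the per-compartment dissociation constant."""

    tag: str  # "slqssa" or "stqssa"
    Kd: float

    def __post_init__(self) -> None:
        if self.tag not in ("slqssa", "stqssa"):
            raise ValueError(f"unknown reduction {self.tag!r}")
        if self.Kd <= 0:
            raise ValueError("Kd must be > 0")

    def free_sites(self, D_T: int, P_T: int) -> float:
        return expected_free_sites(self.tag, D_T, P_T, self.Kd)


def _check_inputs(D_T, P_T, K_d) -> None:
    if D_T < 0 or P_T < 0:
        raise ValueError("totals must be nonnegative")
    if D_T != int(D_T) or P_T != int(P_T):
        raise ValueError("totals must be integers")
    if K_d <= 0:
        raise ValueError("K_d must be > 0")


def slqssa_free_sites(D_T: int, P_T: int, K_d: float) -> float:
    """Exact stationary mean number of free sites (the slQSSA).

    Evaluated by the stable term-ratio recursion
    ``w_{l+1} = w_l * K_d (D_T - l) / ((l + 1)(P_T - D_T + l + 1))``
    starting from the smallest admissible ``l``; no factorials are formed.
    """
    _check_inputs(D_T, P_T, K_d)
    D_T, P_T = int(D_T), int(P_T)
    if D_T == 0:
        return 0.0
    if P_T == 0:
        return float(D_T)
    l = max(0, D_T - P_T)
    w = 1.0
    den = w
    num = l * w
    while l < D_T:
        w *= K_d * (D_T - l) / ((l + 1.0) * (P_T - D_T + l + 1.0))
        l += 1
        den += w
        num += l * w
    return num / den


def slqssa_low_state_closed_form(D_T: int, P_T: int, K_d: float) -> float:
    """Closed-form slQSSA for at most three binding sites.

    Explicit polynomial specializations of the stationary mean for
    ``D_T in {0, 1, 2, 3}``, obtained by clearing the factorial weights of
    the general ratio case by case; algebraically identical to
    :func:`slqssa_free_sites` on this domain.
    """
    _check_inputs(D_T, P_T, K_d)
    D_T, P_T, K = int(D_T), int(P_T), float(K_d)
    if D_T > 3:
        raise ValueError("closed form only covers D_T <= 3")
    if D_T == 0 or P_T == 0:
        return 0.0 if D_T == 0 else float(D_T)
    if D_T == 1:
        return K / (P_T + K)
    if D_T == 2:
        if P_T >= 2:
            return (2 * K * P_T + 2 * K * K) / (
                P_T * (P_T - 1) + 2 * K * P_T + K * K
            )
        return (2 + 2 * K) / (2 + K)  # P_T == 1
    # D_T == 3
    if P_T >= 3:
        num = 3 * K * P_T * (P_T - 1) + 6 * K * K * P_T + 3 * K ** 3
        den = (
            P_T * (P_T - 1) * (P_T - 2)
            + 3 * K * P_T * (P_T - 1)
            + 3 * K * K * P_T
            + K ** 3
        )
        return num / den
    if P_T == 2:
        return (1 + 2 * K + K * K / 2) / (1 + K + K * K / 6)
    return (6 + 3 * K) / (3 + K)  # P_T == 1


def stqssa_free_sites(D_T: int, P_T: int, K_d: float) -> float:
    """Total-QSSA expected free sites: the nonnegative quadratic root.

    Monotone nondecreasing in ``K_d``, with limits ``max(0, D_T - P_T)`` as
    ``K_d -> 0`` and ``D_T`` as ``K_d -> inf``; always in ``[0, D_T]``.
    """
    _check_inputs(D_T, P_T, K_d)
    a = D_T - P_T - K_d
    x = 0.5 * (a + np.sqrt(a * a + 4.0 * K_d * D_T))
    return float(min(max(x, 0.0), D_T))


def expected_free_sites(method: str, D_T: int, P_T: int, K_d: float) -> float:
    if method == "slqssa":
        return slqssa_free_sites(D_T, P_T, K_d)
    if method == "stqssa":
        return stqssa_free_sites(D_T, P_T, K_d)
    raise ValueError(f"unknown reduction {method!r}")


def free_protein(D_T: int, P_T: int, K_d: float, method) -> float:
    """Expected free proteins ``P_T - (D_T - D_q)`` under a reduction.

    Bound proteins are immobile, so this is the count that diffuses.
    """
    tag = method.tag if isinstance(method, QssaMethod) else str(method)
    dq = expected_free_sites(tag, D_T, P_T, K_d)
    pq = P_T - (D_T - dq)
    return float(min(max(pq, 0.0), P_T))


def compile_reduced_spatial_system(
    lattice,
    params,
    method,
    site_totals,
    label: str = "",
) -> ReactionSystem:
    """Reduced (QSSA) spatial model over totals ``(D_T, P_T, M)``.

    Binding/unbinding channels are eliminated.  Per compartment ``i``:
    transcription at ``kp * D_q,i``, mRNA decay at ``kd * M_i``, and protein
    diffusion at ``d * P_q,i`` per lattice direction, where ``D_q`` / ``P_q``
    are the reduction's expected free-site / free-protein counts given the
    integer totals.  Each diffusion event moves one unit of total protein.
    ``site_totals`` maps 1-based compartment index to its fixed ``D_T``.

    ``D_T`` is carried as a constant species so that reduced trajectories
    share the sampling machinery of the full model.
    """
    if isinstance(method, str):
        method = QssaMethod(method, params.Kd)
    n = lattice.n_compartments
    dtot = np.zeros(n, dtype=np.int64)
    for comp, v in dict(site_totals).items():
        if not (1 <= comp <= n):
            raise ValueError(f"site total at compartment {comp} outside lattice")
        dtot[comp - 1] = v
    if "P" not in lattice.diffusing:
        raise ValueError("reduced models expect P to be the diffusing species")

    d_rate = lattice.diffusion_rate(params.delta)
    channels = []
    for i in range(n):
        dt_i = int(dtot[i])
        if dt_i > 0:
            channels.append(
                ReactionChannel(
                    label=f"transcribe@{i + 1}",
                    rate=params.kp,
                    reactants=((i, "PT"),),
                    changes=((i, "M", +1),),
                    kind="qssa_sites",
                    qssa_method=method.tag,
                    qssa_dtotal=dt_i,
                    qssa_kd=method.Kd,
                )
            )
        channels.append(
            ReactionChannel(
                label=f"decay@{i + 1}",
                rate=params.kd,
                reactants=((i, "M"),),
                changes=((i, "M", -1),),
            )
        )
    for i, j in lattice.neighbor_pairs():
        for a, b in ((i, j), (j, i)):
            dt_a = int(dtot[a])
            if dt_a > 0:
                channels.append(
                    ReactionChannel(
                        label=f"P-diff@{a + 1}->{b + 1}",
                        rate=d_rate,
                        reactants=((a, "PT"),),
                        changes=((a, "PT", -1), (b, "PT", +1)),
                        kind="qssa_protein",
                        qssa_method=method.tag,
                        qssa_dtotal=dt_a,
                        qssa_kd=method.Kd,
                    )
                )
            else:
                channels.append(
                    ReactionChannel(
                        label=f"P-diff@{a + 1}->{b + 1}",
                        rate=d_rate,
                        reactants=((a, "PT"),),
                        changes=((a, "PT", -1), (b, "PT", +1)),
                    )
                )
    return ReactionSystem(
        species=REDUCED_SPECIES,
        channels=tuple(channels),
        n_compartments=n,
        label=label or f"reduced-{method.tag}",
    )
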