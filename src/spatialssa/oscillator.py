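"""Spatial negative-feedback oscillator: repressor self-repression with
peripheral protein delivery.

The domain is a whole cell (default 30 um, K = 30 compartments of 1 um) with
the nucleus as the central 10 um (compartments 11-20) and DNA carrying two
binding sites fixed at compartment 15.  Free sites produce repressor protein
``P``; each newly made protein appears at the cell periphery (compartment 1
or K, chosen with probability 1/2 each, realised as two half-rate channels)
and must diffuse back to the nucleus to bind the DNA and shut its own
production off.  Free protein degrades first-order everywhere; bound protein
is protected.  Delayed negative feedback through diffusion yields sustained
stochastic oscillations of the total protein count.

Reduced variants replace the binding/unbinding pair by a QSSA: production
fires at ``kp * D_q,15`` and protein hops/degradation act on the expected
free-protein count, exactly as in :mod:`spatialssa.qssa`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .lattice import Ensemble, LatticeGeometry, build_lattice, run_ensemble
from .network import ReactionChannel, ReactionSystem, SystemState
from .params import RateParameters
from .qssa import QssaMethod, REDUCED_SPECIES

__all__ = ["OscillatorScenario", "build_oscillator_system", "run_oscillator"]

_FULL_SPECIES = ("D", "D:P", "P")


@dataclass(frozen=True)
class OscillatorScenario:
    """Parameterization of the negative-feedback oscillator.

    Defaults: cell length 30 um split into K = 30 compartments (h = 1 um),
    nucleus at compartments 11-20, DNA with two binding sites at
    compartment 15, kf/omega = 1e4 /s, kb = 100 /s (per-compartment
    Kd = 0.01), kp = 10 /s per free site, kd = 0.01 /s, delta such that
    d = delta/h^2 = 1.8 /s, horizon 5000 s.  ``reduction`` is ``None`` for
    the full model or ``"slqssa"`` / ``"stqssa"``.
    """

    cell_length: float = 30.0
    K: int = 30
    nucleus: Tuple[int, int] = (11, 20)
    dna_compartment: int = 15
    n_sites: int = 2
    kf_per_omega: float = 1.0e4
    kb: float = 100.0
    kp: float = 10.0
    kd: float = 0.01
    delta: float = 1.8  # with h = 1 um this gives d = 1.8 /s
    t_max: float = 5000.0
    grid_dt: float = 1.0
    reduction: Optional[str] = None
    Kd_override: Optional[float] = None

    def __post_init__(self) -> None:
        lo, hi = self.nucleus
        if not (1 <= lo <= hi <= self.K) or (lo == 1 and hi == self.K):
            raise ValueError("nucleus must lie strictly inside the cell")
        if not (lo <= self.dna_compartment <= hi):
            raise ValueError("DNA compartment must lie inside the nucleus")
        if self.reduction not in (None, "slqssa", "stqssa"):
            raise ValueError(f"unknown reduction {self.reduction!r}")

    @property
    def params(self) -> RateParameters:
        return RateParameters(
            kf=self.kf_per_omega, kb=self.kb, kp=self.kp, kd=self.kd,
            delta=self.delta, omega=1.0,
        )

    @property
    def Kd(self) -> float:
        return self.Kd_override if self.Kd_override is not None else (
            self.kb / self.kf_per_omega
        )

    @property
    def lattice(self) -> LatticeGeometry:
        mobile = ("P",) if self.reduction is None else ("PT",)
        imm = ("D", "D:P") if self.reduction is None else ("DT", "M")
        return build_lattice(
            self.cell_length, self.K, dims=1,
            diffusing=mobile, immobile=imm,
            nucleus=(self.nucleus,),
        )

    @property
    def sample_grid(self) -> np.ndarray:
        n = int(round(self.t_max / self.grid_dt))
        return np.linspace(0.0, self.t_max, n + 1)


def build_oscillator_system(scenario: OscillatorScenario) -> ReactionSystem:
    """Compile the oscillator's channel list (full or QSSA-reduced)."""
    K = scenario.K
    dna = scenario.dna_compartment - 1  # 0-based
    lattice = scenario.lattice
    d_rate = lattice.diffusion_rate(scenario.delta)

    if scenario.reduction is None:
        channels = [
            ReactionChannel(
                label="bind",
                rate=scenario.kf_per_omega,
                reactants=((dna, "D"), (dna, "P")),
                changes=((dna, "D", -1), (dna, "P", -1), (dna, "D:P", +1)),
            ),
            ReactionChannel(
                label="unbind",
                rate=scenario.kb,
                reactants=((dna, "D:P"),),
                changes=((dna, "D", +1), (dna, "P", +1), (dna, "D:P", -1)),
            ),
        ]
        # production from free sites; the new protein lands at either end
        for end, side in ((0, "left"), (K - 1, "right")):
            channels.append(
                ReactionChannel(
                    label=f"produce-{side}",
                    rate=scenario.kp / 2.0,
                    reactants=((dna, "D"),),
                    changes=((end, "P", +1),),
                )
            )
        for i in range(K):
            channels.append(
                ReactionChannel(
                    label=f"degrade@{i + 1}",
                    rate=scenario.kd,
                    reactants=((i, "P"),),
                    changes=((i, "P", -1),),
                )
            )
        for i, j in lattice.neighbor_pairs():
            for a, b in ((i, j), (j, i)):
                channels.append(
                    ReactionChannel(
                        label=f"P-diff@{a + 1}->{b + 1}",
                        rate=d_rate,
                        reactants=((a, "P"),),
                        changes=((a, "P", -1), (b, "P", +1)),
                    )
                )
        return ReactionSystem(
            species=_FULL_SPECIES,
            channels=tuple(channels),
            n_compartments=K,
            label="oscillator-full",
        )

    method = QssaMethod(scenario.reduction, scenario.Kd)
    dt_dna = scenario.n_sites
    channels = []
    for end, side in ((0, "left"), (K - 1, "right")):
        channels.append(
            ReactionChannel(
                label=f"produce-{side}",
                rate=scenario.kp / 2.0,
                reactants=((dna, "PT"),),
                changes=((end, "PT", +1),),
                kind="qssa_sites",
                qssa_method=method.tag,
                qssa_dtotal=dt_dna,
                qssa_kd=method.Kd,
            )
        )
    for i in range(K):
        if i == dna:
            channels.append(
                ReactionChannel(
                    label=f"degrade@{i + 1}",
                    rate=scenario.kd,
                    reactants=((i, "PT"),),
                    changes=((i, "PT", -1),),
                    kind="qssa_protein",
                    qssa_method=method.tag,
                    qssa_dtotal=dt_dna,
                    qssa_kd=method.Kd,
                )
            )
        else:
            channels.append(
                ReactionChannel(
                    label=f"degrade@{i + 1}",
                    rate=scenario.kd,
                    reactants=((i, "PT"),),
                    changes=((i, "PT", -1),),
                )
            )
    for i, j in scenario.lattice.neighbor_pairs():
        for a, b in ((i, j), (j, i)):
            if a == dna:
                channels.append(
                    ReactionChannel(
                        label=f"P-diff@{a + 1}->{b + 1}",
                        rate=d_rate,
                        reactants=((a, "PT"),),
                        changes=((a, "PT", -1), (b, "PT", +1)),
                        kind="qssa_protein",
                        qssa_method=method.tag,
                        qssa_dtotal=dt_dna,
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
        n_compartments=K,
        label=f"oscillator-{scenario.reduction}",
    )


def initial_oscillator_state(scenario: OscillatorScenario) -> SystemState:
    """Two free sites at the DNA compartment, one protein per compartment."""
    K = scenario.K
    if scenario.reduction is None:
        counts = np.zeros((K, len(_FULL_SPECIES)), dtype=np.int64)
        counts[:, _FULL_SPECIES.index("P")] = 1
        counts[scenario.dna_compartment - 1, _FULL_SPECIES.index("D")] = (
            scenario.n_sites
        )
    else:
        counts = np.zeros((K, len(REDUCED_SPECIES)), dtype=np.int64)
        counts[:, REDUCED_SPECIES.index("PT")] = 1
        counts[scenario.dna_compartment - 1, REDUCED_SPECIES.index("DT")] = (
            scenario.n_sites
        )
    return SystemState(0.0, counts)


def total_protein(ensemble: Ensemble) -> np.ndarray:
    """(n_runs, n_times) total protein, counting bound copies.

    Full-model trajectories sum ``P + D:P``; reduced trajectories already
    track the bound-inclusive total ``PT``.
    """
    species = ensemble.trajectories[0].species
    if "PT" in species:
        return ensemble.totals("PT")
    out = ensemble.totals("P")
    if "D:P" in species:
        out = out + ensemble.totals("D:P")
    return out


def run_oscillator(
    scenario: OscillatorScenario, n_runs: int, base_seed: int
) -> Ensemble:
    """Ensemble of total-protein trajectories on the scenario's 1 s grid."""
    system = build_oscillator_system(scenario)
    init = initial_oscillator_state(scenario)
    return run_ensemble(
        system, init, scenario.t_max, n_runs, base_seed,
        scenario.sample_grid,
        label=system.label,
    )
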