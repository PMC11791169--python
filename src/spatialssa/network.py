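"""Reaction networks for transcription-factor mediated gene regulation.

The model family: DNA binding sites (``D``) reversibly bind a repressor
protein (``P``) forming a transcriptionally inactive complex (``D:P``);
mRNA (``M``) is transcribed from each free site and degrades first-order.
Three structural variants are provided:

* one binding site (``build_one_site_network``),
* an explicit two-site model that tracks every DNA occupancy status
  ``D00, D01, D10, D11`` (``build_two_site_explicit``),
* the lumped model that tracks only the number of free sites, equivalent in
  distribution to the explicit model (``build_lumped_network``), and
* an activating variant where transcription proceeds from the bound complex
  instead of the free site (``build_activating_variant``).

Channels are declarative (rate constant, reactant species, integer state
change); the simulation kernel compiles them to arrays.  Every channel is
mass-action unless tagged as a QSSA (expected-count) propensity, in which
case its rate multiplies the conditional steady-state expectation of free
sites or free proteins given the compartment totals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ReactionChannel",
    "ReactionSystem",
    "SystemState",
    "Trajectory",
    "build_one_site_network",
    "build_two_site_explicit",
    "build_lumped_network",
    "build_activating_variant",
    "lump_state",
    "make_state",
]

# species tuples used by the lumped / one-site family
LUMPED_SPECIES: Tuple[str, ...] = ("D", "D:P", "P", "M")
EXPLICIT_SPECIES: Tuple[str, ...] = ("D00", "D01", "D10", "D11", "P", "M")


@dataclass(frozen=True)
class ReactionChannel:
    """One reaction channel: a propensity rule plus an integer state change.

    ``reactants`` lists ``(compartment, species)`` pairs whose counts multiply
    ``rate`` (mass action, stoichiometry one each).  ``changes`` lists
    ``(compartment, species, delta)`` triples applied when the channel fires.
    QSSA channels (``kind != "mass_action"``) instead evaluate
    ``rate * f(D_T, P_T, K_d)`` where ``P_T`` is the single listed reactant,
    ``D_T`` is the fixed site total ``qssa_dtotal`` and ``f`` is the expected
    free-site or free-protein count of the tagged reduction.
    """

    label: str
    rate: float
    reactants: Tuple[Tuple[int, str], ...]
    changes: Tuple[Tuple[int, str, int], ...]
    kind: str = "mass_action"  # mass_action | qssa_sites | qssa_protein
    qssa_method: Optional[str] = None  # slqssa | stqssa
    qssa_dtotal: int = 0
    qssa_kd: float = 0.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"channel {self.label!r}: negative rate")
        if self.kind == "mass_action":
            if len(self.reactants) > 2:
                raise ValueError(
                    f"channel {self.label!r}: at most bimolecular mass action"
                )
        elif self.kind in ("qssa_sites", "qssa_protein"):
            if len(self.reactants) != 1:
                raise ValueError(
                    f"channel {self.label!r}: QSSA channel needs one reactant (P_T)"
                )
            if self.qssa_method not in ("slqssa", "stqssa"):
                raise ValueError(f"channel {self.label!r}: bad qssa_method")
            if self.qssa_kd <= 0:
                raise ValueError(f"channel {self.label!r}: qssa_kd must be > 0")
        else:
            raise ValueError(f"channel {self.label!r}: unknown kind {self.kind!r}")

    def propensity(self, state: "SystemState", system: "ReactionSystem") -> float:
        """Evaluate the propensity on an integer state (reference path)."""
        counts = state.counts
        if self.kind == "mass_action":
            a = self.rate
            for comp, sp in self.reactants:
                a *= counts[comp, system.species_index(sp)]
            return float(a)
        from . import qssa  # local import to avoid a cycle

        comp, sp = self.reactants[0]
        pt = int(counts[comp, system.species_index(sp)])
        dq = qssa.expected_free_sites(
            self.qssa_method, self.qssa_dtotal, pt, self.qssa_kd
        )
        if self.kind == "qssa_sites":
            return float(self.rate * dq)
        pq = pt - (self.qssa_dtotal - dq)
        return float(self.rate * max(pq, 0.0))


@dataclass(frozen=True)
class ReactionSystem:
    """A compiled set of reaction channels over per-compartment species."""

    species: Tuple[str, ...]
    channels: Tuple[ReactionChannel, ...]
    n_compartments: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique")
        if not self.channels:
            raise ValueError("reaction system has no channels")
        if self.n_compartments < 1:
            raise ValueError("n_compartments must be >= 1")
        known = set(self.species)
        for ch in self.channels:
            for comp, sp in ch.reactants:
                if sp not in known or not (0 <= comp < self.n_compartments):
                    raise ValueError(
                        f"channel {ch.label!r} references unknown ({comp}, {sp})"
                    )
            for comp, sp, _ in ch.changes:
                if sp not in known or not (0 <= comp < self.n_compartments):
                    raise ValueError(
                        f"channel {ch.label!r} changes unknown ({comp}, {sp})"
                    )

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def propensities(self, state: "SystemState") -> np.ndarray:
        return np.array([ch.propensity(state, self) for ch in self.channels])


@dataclass
class SystemState:
    """Integer copy numbers per (compartment, species) at one time point."""

    time: float
    counts: np.ndarray  # shape (n_compartments, n_species), integer

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("state counts must be integers")
            arr = arr.astype(np.int64)
        if arr.ndim == 1:
            arr = arr[None, :]
        if np.any(arr < 0):
            raise ValueError("state counts must be nonnegative")
        self.counts = arr.astype(np.int64)

    def copy(self) -> "SystemState":
        return SystemState(self.time, self.counts.copy())


@dataclass
class Trajectory:
    """Time-sampled counts: ``counts[t, compartment, species]``."""

    times: np.ndarray
    counts: np.ndarray
    species: Tuple[str, ...]
    label: str = ""

    def totals(self, species: str) -> np.ndarray:
        """Domain-wide total of one species at every sample time."""
        j = self.species.index(species)
        return self.counts[:, :, j].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns time, compartment, species, count.

        Compartments are reported 1-based, matching the lattice convention.
        """
        nt, nc, ns = self.counts.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, nc * ns),
                "compartment": np.tile(np.repeat(np.arange(1, nc + 1), ns), nt),
                "species": np.tile(np.array(self.species), nt * nc),
                "count": self.counts.reshape(-1),
            }
        )


def make_state(
    system: ReactionSystem,
    counts: Mapping,
    time: float = 0.0,
) -> SystemState:
    """Build a state from a sparse mapping.

    Keys are species names (compartment 1 implied for single-compartment
    systems) or ``(compartment, species)`` pairs with 1-based compartments.
    """
    arr = np.zeros((system.n_compartments, len(system.species)), dtype=np.int64)
    for key, value in counts.items():
        if isinstance(key, tuple):
            comp, sp = key
            arr[comp - 1, system.species_index(sp)] = value
        else:
            arr[0, system.species_index(key)] = value
    return SystemState(time, arr)


# ---------------------------------------------------------------------------
# network builders (single compartment; compartment index 0)
# ---------------------------------------------------------------------------

def _c(label, rate, reactants, changes, **kw):
    return ReactionChannel(
        label=label,
        rate=rate,
        reactants=tuple((0, sp) for sp in reactants),
        changes=tuple((0, sp, d) for sp, d in changes),
        **kw,
    )


def build_one_site_network(params) -> ReactionSystem:
    """Repression of DNA with a single binding site.

    Channels: binding ``kf/omega * D * P``, unbinding ``kb * D:P``,
    transcription ``kp * D`` and mRNA decay ``kd * M``.
    """
    return build_lumped_network(params, n_sites=1)


def build_lumped_network(params, n_sites: int) -> ReactionSystem:
    """Multi-site regulation tracked by the number of free sites only.

    Statistically equivalent to the explicit occupancy-status model because
    transcription depends only on how many sites are free, not on which.
    The natural initial condition sets ``D = n_sites``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    channels = (
        _c("bind", params.kf_per_omega, ["D", "P"],
           [("D", -1), ("P", -1), ("D:P", +1)]),
        _c("unbind", params.kb, ["D:P"],
           [("D", +1), ("P", +1), ("D:P", -1)]),
        _c("transcribe", params.kp, ["D"], [("M", +1)]),
        _c("decay", params.kd, ["M"], [("M", -1)]),
    )
    return ReactionSystem(
        species=LUMPED_SPECIES,
        channels=channels,
        label=f"lumped-{n_sites}site",
    )


def build_two_site_explicit(params) -> ReactionSystem:
    """Two-site repression resolving all four DNA occupancy statuses.

    ``D00`` binds P at either site (two channels, ``kf/omega`` each) forming
    ``D01``/``D10``; these bind again forming ``D11``.  Each bound site
    unbinds at ``kb`` (so ``D11`` loses a protein at total rate ``2 kb``).
    Transcription runs at ``2 kp`` from ``D00``, ``kp`` from each singly
    occupied status, and is fully repressed in ``D11``.
    """
    kfo, kb, kp, kd = params.kf_per_omega, params.kb, params.kp, params.kd
    channels = (
        _c("bind-00-01", kfo, ["D00", "P"], [("D00", -1), ("P", -1), ("D01", +1)]),
        _c("bind-00-10", kfo, ["D00", "P"], [("D00", -1), ("P", -1), ("D10", +1)]),
        _c("bind-01-11", kfo, ["D01", "P"], [("D01", -1), ("P", -1), ("D11", +1)]),
        _c("bind-10-11", kfo, ["D10", "P"], [("D10", -1), ("P", -1), ("D11", +1)]),
        _c("unbind-01-00", kb, ["D01"], [("D01", -1), ("P", +1), ("D00", +1)]),
        _c("unbind-10-00", kb, ["D10"], [("D10", -1), ("P", +1), ("D00", +1)]),
        _c("unbind-11-01", kb, ["D11"], [("D11", -1), ("P", +1), ("D01", +1)]),
        _c("unbind-11-10", kb, ["D11"], [("D11", -1), ("P", +1), ("D10", +1)]),
        _c("transcribe-00", 2.0 * kp, ["D00"], [("M", +1)]),
        _c("transcribe-01", kp, ["D01"], [("M", +1)]),
        _c("transcribe-10", kp, ["D10"], [("M", +1)]),
        _c("decay", kd, ["M"], [("M", -1)]),
    )
    return ReactionSystem(
        species=EXPLICIT_SPECIES, channels=channels, label="two-site-explicit"
    )


def lump_state(explicit_state: SystemState) -> SystemState:
    """Map an explicit two-site state onto free-site coordinates.

    ``D = 2 D00 + D01 + D10`` (free sites), ``D:P = D01 + D10 + 2 D11``
    (occupied sites); ``P`` and ``M`` are unchanged.
    """
    idx = {sp: i for i, sp in enumerate(EXPLICIT_SPECIES)}
    c = explicit_state.counts
    out = np.zeros((c.shape[0], len(LUMPED_SPECIES)), dtype=np.int64)
    d00, d01, d10, d11 = (c[:, idx[s]] for s in ("D00", "D01", "D10", "D11"))
    out[:, 0] = 2 * d00 + d01 + d10
    out[:, 1] = d01 + d10 + 2 * d11
    out[:, 2] = c[:, idx["P"]]
    out[:, 3] = c[:, idx["M"]]
    return SystemState(explicit_state.time, out)


def build_activating_variant(base: ReactionSystem) -> ReactionSystem:
    """Swap repression for activation: transcription from ``D:P``, not ``D``.

    Every transcription channel whose reactant is a free-site species is
    rewired to read the bound complex at the same rate.
    """
    new_channels = []
    found = False
    for ch in base.channels:
        if (
            ch.label.startswith("transcribe")
            and ch.kind == "mass_action"
            and any(sp == "D" for _, sp in ch.reactants)
        ):
            found = True
            reactants = tuple(
                (comp, "D:P" if sp == "D" else sp) for comp, sp in ch.reactants
            )
            ch = replace(ch, reactants=reactants)
        new_channels.append(ch)
    if not found:
        raise ValueError("base system has no transcription channel to rewire")
    return replace(
        base, channels=tuple(new_channels), label=base.label + "-activating"
    )
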