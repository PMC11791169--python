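"""Compartment lattices and spatial compilation of reaction networks.

The reaction-diffusion master equation is realised by partitioning a 1-D
domain of length ``L`` into ``K`` compartments of size ``h = L / K`` (or a
2-D rectangle into ``K1 x K2`` cells) and treating diffusion of each mobile
species as first-order hop reactions between lattice neighbours at rate
``d = delta / h^2`` per direction.  Boundaries are reflecting: edge
compartments simply lack the outward hop channel.  Reactions run
independently inside every compartment with system size ``omega = 1`` per
compartment, so a K-compartment lattice matched against a well-mixed run
corresponds to ``omega = K`` there.

Compartments are indexed 1-based in all user-facing I/O (``P@15``); 2-D
cells are addressed ``(row, column)``, flattened row-major internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np

from .kernel import ssa_run
from .network import ReactionChannel, ReactionSystem, SystemState

__all__ = [
    "LatticeGeometry",
    "Ensemble",
    "diffusion_rate",
    "build_lattice",
    "compile_spatial_system",
    "run_ensemble",
]

_H_TOL = 1e-9


def diffusion_rate(delta: float, h: float) -> float:
    """Hop rate ``d = delta / h**2`` between neighbouring compartments (1/s)."""
    if h <= 0:
        raise ValueError("compartment size h must be > 0")
    if delta < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    return delta / (h * h)


@dataclass(frozen=True)
class LatticeGeometry:
    """A 1-D or 2-D compartment lattice with reflecting boundaries."""

    dims: int
    lengths: Tuple[float, ...]  # domain length per axis (um)
    counts: Tuple[int, ...]  # compartments per axis
    diffusing: Tuple[str, ...]
    immobile: Tuple[str, ...]
    nucleus: Optional[Tuple[Tuple[int, int], ...]] = None  # 1-based ranges

    def __post_init__(self) -> None:
        if self.dims not in (1, 2):
            raise ValueError("only 1-D and 2-D lattices are supported")
        if len(self.lengths) != self.dims or len(self.counts) != self.dims:
            raise ValueError("lengths/counts must have one entry per axis")
        for L, K in zip(self.lengths, self.counts):
            if L <= 0 or K < 1:
                raise ValueError("domain length must be > 0 and K >= 1")
            h = L / K
            if abs(h * K - L) > _H_TOL * L:
                raise ValueError("h * K must equal L")
        hs = {round(L / K, 15) for L, K in zip(self.lengths, self.counts)}
        if len(hs) != 1:
            raise ValueError("compartment size must match across axes")
        if set(self.diffusing) & set(self.immobile):
            raise ValueError("a species cannot be both diffusing and immobile")
        if self.nucleus is not None:
            for (lo, hi), K in zip(self.nucleus, self.counts):
                if not (1 <= lo <= hi <= K):
                    raise ValueError("nucleus range outside the lattice")

    @property
    def h(self) -> float:
        """Compartment size (um), identical on every axis."""
        return self.lengths[0] / self.counts[0]

    @property
    def n_compartments(self) -> int:
        return int(np.prod(self.counts))

    def diffusion_rate(self, delta: float) -> float:
        return diffusion_rate(delta, self.h)

    def flat_index(self, *index: int) -> int:
        """Flatten a 1-based compartment index (or ``(i, j)`` pair)."""
        if len(index) != self.dims:
            raise ValueError("index arity must match dims")
        if self.dims == 1:
            (i,) = index
            if not 1 <= i <= self.counts[0]:
                raise ValueError("index outside lattice")
            return i - 1
        i, j = index
        K1, K2 = self.counts
        if not (1 <= i <= K1 and 1 <= j <= K2):
            raise ValueError("index outside lattice")
        return (i - 1) * K2 + (j - 1)

    def neighbor_pairs(self) -> Iterator[Tuple[int, int]]:
        """Unordered neighbour pairs (flat 0-based), 2 per interior bond."""
        if self.dims == 1:
            K = self.counts[0]
            for i in range(K - 1):
                yield (i, i + 1)
        else:
            K1, K2 = self.counts
            for i in range(K1):
                for j in range(K2):
                    if j + 1 < K2:
                        yield (i * K2 + j, i * K2 + j + 1)
                    if i + 1 < K1:
                        yield (i * K2 + j, (i + 1) * K2 + j)

    def center(self) -> int:
        """Flat index of the conventional centre compartment.

        For the conventional even ``K = 30`` axis the centre is compartment 15
        (1-based), i.e. ``K // 2`` on each axis.
        """
        idx = tuple(K // 2 for K in self.counts)  # 1-based K//2
        return self.flat_index(*idx)


def build_lattice(
    L,
    K,
    dims: int = 1,
    diffusing: Sequence[str] = ("P",),
    immobile: Sequence[str] = ("D", "D:P", "M"),
    nucleus=None,
) -> LatticeGeometry:
    """Construct a lattice; scalars are broadcast across axes for 2-D."""
    lengths = tuple(float(x) for x in (L if np.iterable(L) else [L] * dims))
    counts = tuple(int(x) for x in (K if np.iterable(K) else [K] * dims))
    if nucleus is not None:
        nucleus = tuple(tuple(int(v) for v in rng) for rng in nucleus)
    return LatticeGeometry(
        dims=dims,
        lengths=lengths,
        counts=counts,
        diffusing=tuple(diffusing),
        immobile=tuple(immobile),
        nucleus=nucleus,
    )


def compile_spatial_system(
    network: ReactionSystem,
    lattice: LatticeGeometry,
    params,
) -> ReactionSystem:
    """Replicate a one-compartment network over a lattice and add diffusion.

    Every reaction channel is instantiated in each compartment (system size
    ``omega = 1`` per compartment); each diffusing species gets one hop
    channel per lattice direction at rate ``d * count`` with reflecting
    boundaries.  Immobile species never receive hop channels.
    """
    if network.n_compartments != 1:
        raise ValueError("expected a single-compartment reaction network")
    declared = set(lattice.diffusing) | set(lattice.immobile)
    if declared != set(network.species):
        missing = set(network.species) ^ declared
        raise ValueError(
            f"diffusing/immobile must partition the species set (mismatch: {missing})"
        )
    n = lattice.n_compartments
    channels = []
    for comp in range(n):
        for ch in network.channels:
            channels.append(
                replace(
                    ch,
                    label=f"{ch.label}@{comp + 1}",
                    reactants=tuple((comp, sp) for _, sp in ch.reactants),
                    changes=tuple((comp, sp, d) for _, sp, d in ch.changes),
                )
            )
    d_rate = lattice.diffusion_rate(params.delta)
    for i, j in lattice.neighbor_pairs():
        for a, b in ((i, j), (j, i)):
            for sp in lattice.diffusing:
                channels.append(
                    ReactionChannel(
                        label=f"{sp}-diff@{a + 1}->{b + 1}",
                        rate=d_rate,
                        reactants=((a, sp),),
                        changes=((a, sp, -1), (b, sp, +1)),
                    )
                )
    return ReactionSystem(
        species=network.species,
        channels=tuple(channels),
        n_compartments=n,
        label=(network.label + "-spatial") if network.label else "spatial",
    )


@dataclass
class Ensemble:
    """Independent trajectories sharing one sample grid and species set."""

    trajectories: list
    base_seed: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("empty ensemble")
        t0 = self.trajectories[0]
        for tr in self.trajectories[1:]:
            if tr.species != t0.species or not np.array_equal(tr.times, t0.times):
                raise ValueError("trajectories must share grid and species")

    @property
    def n_runs(self) -> int:
        return len(self.trajectories)

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times

    def totals(self, species: str) -> np.ndarray:
        """(n_runs, n_times) array of domain-wide totals of one species."""
        return np.stack([tr.totals(species) for tr in self.trajectories])


def run_ensemble(
    system: ReactionSystem,
    init: SystemState,
    t_max: float,
    n_runs: int,
    base_seed: int,
    grid,
    label: str = "",
) -> Ensemble:
    """``n_runs`` independent SSA runs seeded ``base_seed ... base_seed+n-1``."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    trajectories = [
        ssa_run(system, init, t_max, base_seed + r, grid) for r in range(n_runs)
    ]
    return Ensemble(
        trajectories=trajectories,
        base_seed=base_seed,
        label=label or system.label,
    )
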