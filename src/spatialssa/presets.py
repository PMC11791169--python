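"""Scenario presets: the simulation conditions behind each comparison.

Each preset fixes rate constants, lattice geometry, initial condition and
run controls for one published comparison:

====================  =====================================================
``fig2a``             one site, uniform P (1 per compartment), fast
                      diffusion delta = 20 um^2/s
``fig2c``             as ``fig2a`` with slow diffusion delta = 0.2 um^2/s
``fig2e``/``fig3c``   one site, non-uniform P (1 in the central ten
                      compartments, 5 elsewhere; total 110), slow diffusion
``fig2g``/``fig3d``   two binding sites, uniform P (total 30), slow diffusion
``s2-activating``     activating regulation (transcription from D:P),
                      kf/omega = 700 /s, kb = 900 /s
``s4-2d``             one site on a 30 x 30 grid over 10 um x 10 um
``s5-convergence``    ``fig2a`` rerun at K = 60 with matched totals and the
                      volume-rescaled binding rate (kf/omega ~ 1/h)
``fig4``              the negative-feedback oscillator (see
                      :mod:`spatialssa.oscillator`)
====================  =====================================================

Shared kinetics for the gene-expression scenarios: kf/omega = 5000 /s,
kb = 100 /s (per-compartment Kd = 0.02), kp = 50 /s, kd = 0.001 /s,
horizon 50 s.  The matched well-mixed (homogeneous) run uses the same rate
constants with omega equal to the total compartment count and the summed
initial condition.

Initial conditions use a sparse 1-based syntax: ``D@15=1`` (single
compartment), ``P@11-20=1`` (range), ``P@*=5`` (everywhere), ``D@15,15=1``
(2-D cell).  Explicit entries override the wildcard.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .lattice import LatticeGeometry, build_lattice, compile_spatial_system
from .network import (
    ReactionSystem,
    SystemState,
    build_activating_variant,
    build_lumped_network,
)
from .params import RateParameters
from .qssa import REDUCED_SPECIES, compile_reduced_spatial_system

__all__ = [
    "ScenarioPreset",
    "PresetRun",
    "PRESETS",
    "build_preset",
    "homogeneous_counterpart",
    "reduced_counterpart",
    "apply_init_spec",
]

_GENE_PARAMS = dict(kf=5000.0, kb=100.0, kp=50.0, kd=0.001, omega=1.0)


@dataclass(frozen=True)
class ScenarioPreset:
    """Full parameterization of one spatial gene-expression scenario."""

    label: str
    description: str
    params: RateParameters
    dims: int = 1
    L: Tuple[float, ...] = (10.0,)
    K: Tuple[int, ...] = (30,)
    n_sites: int = 1
    activating: bool = False
    init: Tuple[str, ...] = ()
    t_max: float = 50.0
    grid_dt: float = 0.1
    observable: str = "M"
    n_runs_published: int = 1000

    @property
    def lattice(self) -> LatticeGeometry:
        return build_lattice(
            self.L if self.dims > 1 else self.L[0],
            self.K if self.dims > 1 else self.K[0],
            dims=self.dims,
            diffusing=("P",),
            immobile=("D", "D:P", "M"),
        )

    @property
    def sample_grid(self) -> np.ndarray:
        n = int(round(self.t_max / self.grid_dt))
        return np.linspace(0.0, self.t_max, n + 1)

    @property
    def site_compartment(self) -> Tuple[int, ...]:
        """1-based index of the DNA compartment, parsed from the init spec."""
        for token in self.init:
            sp, idx, _ = _parse_token(token)
            if sp == "D" and idx != "*":
                return idx if isinstance(idx, tuple) else (idx,)
        raise ValueError(f"preset {self.label!r} places no DNA")


@dataclass
class PresetRun:
    """A ready-to-run (system, initial state, controls) bundle."""

    preset: ScenarioPreset
    system: ReactionSystem
    init: SystemState
    t_max: float
    grid: np.ndarray


_TOKEN_RE = re.compile(r"^([A-Za-z:\d]+)@([\d,\-\*]+)=(\d+)$")


def _parse_token(token: str):
    m = _TOKEN_RE.match(token.replace(" ", ""))
    if not m:
        raise ValueError(f"bad init token {token!r}")
    sp, where, value = m.group(1), m.group(2), int(m.group(3))
    if where == "*":
        return sp, "*", value
    if "," in where:
        i, j = where.split(",")
        return sp, (int(i), int(j)), value
    if "-" in where:
        lo, hi = where.split("-")
        return sp, range(int(lo), int(hi) + 1), value
    return sp, int(where), value


def apply_init_spec(
    tokens: Sequence[str],
    lattice: LatticeGeometry,
    species: Sequence[str],
) -> np.ndarray:
    """Expand sparse init tokens into a dense (compartment, species) array.

    Wildcards are applied first so that explicit singles and ranges
    override them.
    """
    counts = np.zeros((lattice.n_compartments, len(species)), dtype=np.int64)
    sidx = {sp: j for j, sp in enumerate(species)}
    parsed = [_parse_token(t) for t in tokens]
    for pass_wildcard in (True, False):
        for sp, where, value in parsed:
            if sp not in sidx:
                raise ValueError(f"init species {sp!r} not in model")
            if (where == "*") != pass_wildcard:
                continue
            if where == "*":
                counts[:, sidx[sp]] = value
            elif isinstance(where, tuple):
                counts[lattice.flat_index(*where), sidx[sp]] = value
            elif isinstance(where, range):
                for i in where:
                    counts[lattice.flat_index(i), sidx[sp]] = value
            else:
                counts[lattice.flat_index(where), sidx[sp]] = value
    return counts


def _gene_preset(label, description, delta, **over) -> ScenarioPreset:
    p = dict(_GENE_PARAMS)
    p.update(over.pop("rates", {}))
    return ScenarioPreset(
        label=label,
        description=description,
        params=RateParameters(delta=delta, **p),
        **over,
    )


PRESETS: Dict[str, ScenarioPreset] = {
    pr.label: pr
    for pr in [
        _gene_preset(
            "fig2a", "one site, uniform P, fast diffusion", 20.0,
            init=("D@15=1", "P@*=1"),
        ),
        _gene_preset(
            "fig2c", "one site, uniform P, slow diffusion", 0.2,
            init=("D@15=1", "P@*=1"),
        ),
        _gene_preset(
            "fig2e", "one site, peripheral P accumulation, slow diffusion",
            0.2, init=("D@15=1", "P@*=5", "P@11-20=1"),
        ),
        _gene_preset(
            "fig2g", "two binding sites, uniform P, slow diffusion", 0.2,
            n_sites=2, init=("D@15=2", "P@*=1"),
        ),
        _gene_preset(
            "fig3c", "reduction benchmark: peripheral P accumulation", 0.2,
            init=("D@15=1", "P@*=5", "P@11-20=1"),
        ),
        _gene_preset(
            "fig3d", "reduction benchmark: two binding sites", 0.2,
            n_sites=2, init=("D@15=2", "P@*=1"),
        ),
        _gene_preset(
            "s2-activating", "activating regulation, slow diffusion", 0.2,
            rates=dict(kf=700.0, kb=900.0), activating=True,
            init=("D@15=1", "P@*=1"),
        ),
        _gene_preset(
            "s4-2d", "one site on a 30x30 grid, slow diffusion", 0.2,
            dims=2, L=(10.0, 10.0), K=(30, 30),
            init=("D@15,15=1", "P@*=1"),
        ),
        _gene_preset(
            "s5-convergence",
            "fig2a at doubled lattice resolution, matched totals", 20.0,
            K=(60,),
            # bimolecular propensity rescales with compartment volume
            # (kf/omega ~ 1/h), keeping the homogenised Kd fixed
            rates=dict(kf=10000.0),
            # total P stays 30: one protein in every other compartment
            init=("D@30=1",)
            + tuple(f"P@{i}=1" for i in range(1, 61, 2)),
        ),
    ]
}


def build_preset(label: str) -> PresetRun:
    """Compile a preset into a runnable spatial system and initial state.

    The oscillator preset ``fig4`` lives in :mod:`spatialssa.oscillator`;
    requesting it here returns its full-model bundle for convenience.
    """
    if label == "fig4":
        from .oscillator import (
            OscillatorScenario,
            build_oscillator_system,
            initial_oscillator_state,
        )

        sc = OscillatorScenario()
        sys_ = build_oscillator_system(sc)
        return PresetRun(
            preset=None, system=sys_, init=initial_oscillator_state(sc),
            t_max=sc.t_max, grid=sc.sample_grid,
        )
    try:
        preset = PRESETS[label]
    except KeyError:
        raise KeyError(
            f"unknown scenario {label!r}; known: {sorted(PRESETS) + ['fig4']}"
        ) from None
    network = build_lumped_network(preset.params, preset.n_sites)
    if preset.activating:
        network = build_activating_variant(network)
    lattice = preset.lattice
    system = compile_spatial_system(network, lattice, preset.params)
    counts = apply_init_spec(preset.init, lattice, system.species)
    return PresetRun(
        preset=preset,
        system=system,
        init=SystemState(0.0, counts),
        t_max=preset.t_max,
        grid=preset.sample_grid,
    )


def homogeneous_counterpart(run: PresetRun) -> PresetRun:
    """The matched well-mixed model: omega = K, totals summed over space."""
    preset = run.preset
    if preset is None:
        raise ValueError("no homogeneous counterpart for the oscillator")
    n_comp = run.system.n_compartments
    params = preset.params.with_omega(float(n_comp))
    network = build_lumped_network(params, preset.n_sites)
    if preset.activating:
        network = build_activating_variant(network)
    totals = run.init.counts.sum(axis=0)[None, :]
    return PresetRun(
        preset=preset,
        system=network,
        init=SystemState(0.0, totals),
        t_max=preset.t_max,
        grid=preset.sample_grid,
    )


def reduced_counterpart(run: PresetRun, method: str) -> PresetRun:
    """The QSSA-reduced spatial model matching a full-model preset run.

    State collapses to per-compartment totals: ``DT`` fixed at the preset's
    site placement, ``PT`` starting from the initial free protein (no
    complexes at t = 0), ``M`` as before.
    """
    preset = run.preset
    if preset is None:
        raise ValueError("use OscillatorScenario(reduction=...) for fig4")
    if preset.activating:
        raise ValueError("reductions are defined for the repressive model")
    lattice = preset.lattice
    sidx = {sp: j for j, sp in enumerate(run.system.species)}
    d_init = run.init.counts[:, sidx["D"]]
    site_totals = {
        int(i) + 1: int(d_init[i]) for i in np.nonzero(d_init)[0]
    }
    system = compile_reduced_spatial_system(
        lattice, preset.params, method, site_totals,
        label=f"{preset.label}-{method}",
    )
    counts = np.zeros(
        (lattice.n_compartments, len(REDUCED_SPECIES)), dtype=np.int64
    )
    counts[:, REDUCED_SPECIES.index("DT")] = d_init
    counts[:, REDUCED_SPECIES.index("PT")] = (
        run.init.counts[:, sidx["P"]] + run.init.counts[:, sidx["D:P"]]
    )
    counts[:, REDUCED_SPECIES.index("M")] = run.init.counts[:, sidx["M"]]
    return PresetRun(
        preset=preset,
        system=system,
        init=SystemState(0.0, counts),
        t_max=preset.t_max,
        grid=preset.sample_grid,
    )
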