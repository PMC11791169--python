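"""Tabular output and the flat key-value scenario config format.

Trajectories and summaries are written as plain CSV so downstream tools
(pandas, R) read them directly.  Scenario configs are flat ``key = value``
text files mirroring the CLI flags; presets round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from . import qssa
from .params import RateParameters
from .presets import ScenarioPreset

__all__ = [
    "write_trajectory",
    "write_ensemble_summary",
    "write_compartment_summary",
    "preset_to_config",
    "config_to_preset",
    "read_config",
    "write_config",
    "write_manifest",
]


def write_trajectory(trajectory, path) -> None:
    """CSV with columns time, compartment, species, count.

    Reduced-model trajectories (species ``DT, PT, M``) additionally get the
    derived expected free-site/free-protein columns when the system metadata
    is attached by the caller via ``derived``.
    """
    trajectory.to_frame().to_csv(path, index=False)


def write_reduced_trajectory(trajectory, path, method: str, Kd: float) -> None:
    """Reduced trajectory CSV including derived ``D_q`` and ``P_q`` columns."""
    frame = trajectory.to_frame()
    wide = frame.pivot_table(
        index=["time", "compartment"], columns="species", values="count"
    ).reset_index()
    dq = np.array(
        [
            qssa.expected_free_sites(method, int(d), int(p), Kd)
            for d, p in zip(wide["DT"], wide["PT"])
        ]
    )
    wide["D_q"] = dq
    wide["P_q"] = np.maximum(wide["PT"] - (wide["DT"] - dq), 0.0)
    wide.to_csv(path, index=False)


def write_ensemble_summary(summary, path) -> None:
    """CSV with columns time, species, mean, sd, n_runs."""
    t = summary.table.copy()
    t.insert(1, "species", summary.observable)
    t.to_csv(path, index=False)


def write_compartment_summary(ensemble, species: str, path) -> None:
    """Per-compartment mean/SD of one species over the ensemble (final grid)."""
    stack = np.stack(
        [tr.counts[:, :, tr.species.index(species)] for tr in ensemble.trajectories]
    )  # (runs, times, compartments)
    times = ensemble.times
    nt, nc = stack.shape[1], stack.shape[2]
    pd.DataFrame(
        {
            "time": np.repeat(times, nc),
            "compartment": np.tile(np.arange(1, nc + 1), nt),
            "species": species,
            "mean": stack.mean(axis=0).reshape(-1),
            "sd": stack.std(axis=0, ddof=1).reshape(-1),
            "n_runs": stack.shape[0],
        }
    ).to_csv(path, index=False)


# -- flat key = value config -------------------------------------------------

def preset_to_config(preset: ScenarioPreset) -> Dict[str, str]:
    return {
        "label": preset.label,
        "description": preset.description,
        "kf": repr(preset.params.kf),
        "kb": repr(preset.params.kb),
        "kp": repr(preset.params.kp),
        "kd": repr(preset.params.kd),
        "delta": repr(preset.params.delta),
        "omega": repr(preset.params.omega),
        "dims": str(preset.dims),
        "L": ",".join(repr(x) for x in preset.L),
        "K": ",".join(str(x) for x in preset.K),
        "n_sites": str(preset.n_sites),
        "activating": str(preset.activating).lower(),
        "init": ";".join(preset.init),
        "t_max": repr(preset.t_max),
        "grid_dt": repr(preset.grid_dt),
        "observable": preset.observable,
        "n_runs_published": str(preset.n_runs_published),
    }


def config_to_preset(config: Dict[str, str]) -> ScenarioPreset:
    return ScenarioPreset(
        label=config["label"],
        description=config.get("description", ""),
        params=RateParameters(
            kf=float(config["kf"]),
            kb=float(config["kb"]),
            kp=float(config["kp"]),
            kd=float(config["kd"]),
            delta=float(config["delta"]),
            omega=float(config.get("omega", "1.0")),
        ),
        dims=int(config.get("dims", "1")),
        L=tuple(float(x) for x in config["L"].split(",")),
        K=tuple(int(x) for x in config["K"].split(",")),
        n_sites=int(config.get("n_sites", "1")),
        activating=config.get("activating", "false") == "true",
        init=tuple(t for t in config["init"].split(";") if t),
        t_max=float(config["t_max"]),
        grid_dt=float(config["grid_dt"]),
        observable=config.get("observable", "M"),
        n_runs_published=int(config.get("n_runs_published", "1000")),
    )


def write_config(config: Dict[str, str], path) -> None:
    lines = [f"{k} = {v}" for k, v in config.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"bad config line {raw!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def write_manifest(path, **fields) -> None:
    """Run manifest: every parameter and seed of a run, as JSON text."""
    from . import __version__

    payload = {"spatialssa_version": __version__}
    payload.update(fields)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
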