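"""Serialization and reproducible experiment runs.

Networks round-trip losslessly through a flat JSON schema::

    {"N": int, "K": int, "s": int, "topology_type": "er|ss|sf", "seed": int,
     "inputs": [[int x K] x N], "functions": [[int x s**K] x N],
     "state": [int x N]}

`run_experiment` ties the modules into a self-contained artifact directory:
the exact config (with all seeds) is written next to the outputs, so a run
is reproducible from its directory alone, and reruns with the same config
are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .annealed import AnnealedParams, derrida_step
from .damage import DEFAULT_THRESHOLD_FRAC, CrocodileResult, crocodile, damage_distribution
from .dynamics import Trajectory
from .evolution import EvolutionConfig, evolve
from .network import KauffmanSystem, NetworkSpec, make_point_attractor, random_system

__all__ = [
    "save_network",
    "load_network",
    "RunConfig",
    "run_experiment",
    "save_trajectory_tsv",
]


def save_network(system: KauffmanSystem, path: str | Path) -> None:
    """Write a system to the JSON schema (lossless)."""
    doc = {
        "N": system.spec.N,
        "K": system.spec.K,
        "s": system.spec.s,
        "topology_type": system.spec.topology_type,
        "seed": system.spec.seed,
        "inputs": system.inputs.tolist(),
        "functions": system.functions.tolist(),
        "state": system.state.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def _require(doc: dict, key: str, kind: type) -> Any:
    if key not in doc:
        raise ValueError(f"network JSON: missing field {key!r}")
    val = doc[key]
    if kind is int and (not isinstance(val, int) or isinstance(val, bool)):
        raise ValueError(f"network JSON: field {key!r} must be an integer, got {val!r}")
    if kind is str and not isinstance(val, str):
        raise ValueError(f"network JSON: field {key!r} must be a string, got {val!r}")
    if kind is list and not isinstance(val, list):
        raise ValueError(f"network JSON: field {key!r} must be a list")
    return val


def load_network(path: str | Path) -> KauffmanSystem:
    """Load and validate a network JSON; errors name the offending field."""
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError("network JSON: top level must be an object")
    N = _require(doc, "N", int)
    K = _require(doc, "K", int)
    s = _require(doc, "s", int)
    topology_type = _require(doc, "topology_type", str)
    seed = _require(doc, "seed", int)
    spec = NetworkSpec(N=N, K=K, s=s, topology_type=topology_type, seed=seed)

    def as_array(key: str) -> np.ndarray:
        try:
            return np.asarray(_require(doc, key, list), dtype=np.int64)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"network JSON: field {key!r} is not a rectangular int array") from exc

    inputs = as_array("inputs")
    functions = as_array("functions")
    state = as_array("state")
    if inputs.shape != (N, K):
        raise ValueError(f"network JSON: field 'inputs' must be {N} lists of {K} ints")
    if functions.shape != (N, s**K):
        raise ValueError(f"network JSON: field 'functions' must be {N} lists of {s**K} ints")
    if state.shape != (N,):
        raise ValueError(f"network JSON: field 'state' must hold {N} ints")
    if (functions < 0).any() or (functions >= s).any():
        raise ValueError("network JSON: field 'functions' has entries outside [0, s-1]")
    if (state < 0).any() or (state >= s).any():
        raise ValueError("network JSON: field 'state' has values outside [0, s-1]")
    if (inputs < 0).any() or (inputs >= N).any():
        raise ValueError("network JSON: field 'inputs' has node indices outside [0, N-1]")
    return KauffmanSystem(spec=spec, inputs=inputs, functions=functions, state=state)


def save_trajectory_tsv(traj: Trajectory, path: str | Path) -> None:
    """Trajectory export: columns t, node_0 ... node_{N-1}."""
    N = traj.states.shape[1]
    with open(path, "w") as fh:
        fh.write("t\t" + "\t".join(f"node_{i}" for i in range(N)) + "\n")
        for t in range(traj.states.shape[0]):
            fh.write(str(t) + "\t" + "\t".join(map(str, traj.states[t])) + "\n")


def _save_crocodile_tsv(result: CrocodileResult, path: Path, stride: int = 1) -> None:
    ts = list(range(0, result.tmx + 1, stride))
    with open(path, "w") as fh:
        fh.write(
            "process_id\tnode\tinput_index\tnew_output\t"
            + "\t".join(f"A_t{t}" for t in ts)
            + "\n"
        )
        for i, s in enumerate(result.series):
            a = s.A
            row = [str(int(a[t])) if t < len(a) else "" for t in ts]
            d = s.disturbance
            fh.write(f"{i}\t{d.node}\t{d.input_index}\t{d.new_output}\t" + "\t".join(row) + "\n")


def _save_q_tsv(result: CrocodileResult, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("t\tq\n")
        for t, qt in enumerate(result.q):
            fh.write(f"{t}\t{qt:.6f}\n")


@dataclass(frozen=True)
class RunConfig:
    """Reproducible experiment description.

    kind: "generate" (write the network), "crocodile" (damage ensemble +
    q + P(d)), "evolve" (PAS-seeded evolution), "derrida" (annealed curve).
    Exactly one of `spec` / `network_path` provides the network (except
    "derrida", which only needs s and K from `spec`).
    """

    kind: str
    spec: NetworkSpec | None = None
    network_path: str | None = None
    pas: bool = False
    tmx: int = 1000
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC
    stride: int = 1
    evolution: EvolutionConfig | None = None
    out_dir: str = "run"

    def to_json(self) -> dict:
        doc = dataclasses.asdict(self)
        return doc


def _get_system(config: RunConfig) -> KauffmanSystem:
    if config.network_path is not None:
        system = load_network(config.network_path)
    elif config.spec is not None:
        system = random_system(config.spec)
    else:
        raise ValueError("RunConfig needs either spec or network_path")
    if config.pas:
        system = make_point_attractor(system)
    return system


def run_experiment(config: RunConfig) -> Path:
    """Execute one experiment and write its artifact directory.

    Always writes config.json; experiment outputs depend on `kind`. Returns
    the output directory path.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_json(), indent=2))

    if config.kind == "generate":
        system = _get_system(config)
        save_network(system, out / "network.json")
    elif config.kind == "crocodile":
        system = _get_system(config)
        save_network(system, out / "network.json")
        result = crocodile(system, tmx=config.tmx, threshold_frac=config.threshold_frac)
        _save_crocodile_tsv(result, out / "crocodile.tsv", stride=config.stride)
        _save_q_tsv(result, out / "q.tsv")
        dist = damage_distribution(result)
        (out / "distribution.json").write_text(
            json.dumps(
                {
                    "left_mass": dist.left_mass,
                    "right_mass": dist.right_mass,
                    "left_mode": dist.left_mode,
                    "right_mode": dist.right_mode,
                    "gap_lo": None if np.isnan(dist.gap_lo) else dist.gap_lo,
                    "gap_hi": None if np.isnan(dist.gap_hi) else dist.gap_hi,
                }
            )
        )
    elif config.kind == "evolve":
        system = _get_system(config)
        evo = config.evolution if config.evolution is not None else EvolutionConfig()
        evolved, log = evolve(system, evo)
        save_network(evolved, out / "evolved.json")
        with open(out / "log.tsv", "w") as fh:
            fh.write("trial\tnode\tinput_index\tnew_output\td_final\tperiod\taccepted\treason\n")
            for rec in log.trials:
                d = rec.disturbance
                period = "" if rec.period is None else str(rec.period)
                fh.write(
                    f"{rec.trial}\t{d.node}\t{d.input_index}\t{d.new_output}\t"
                    f"{rec.d_final:.6f}\t{period}\t{int(rec.accepted)}\t{rec.reason}\n"
                )
    elif config.kind == "derrida":
        if config.spec is None:
            raise ValueError("derrida experiment needs a spec for s and K")
        params = AnnealedParams.from_sk(config.spec.s, config.spec.K)
        (out / "annealed.json").write_text(
            json.dumps({"s": params.s, "K": params.K, "w": params.w, "d_star": params.d_star})
        )
        with open(out / "curve.tsv", "w") as fh:
            fh.write("d\td_next\n")
            for d in np.linspace(0, 1, 101):
                fh.write(f"{d:.4f}\t{derrida_step(d, params.s, params.K):.6f}\n")
    else:
        raise ValueError(f"unknown experiment kind {config.kind!r}")
    return out
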