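"""Experiment orchestration: presets, parameter sweeps, fixtures, config I/O.

The "paper" presets hold the full-scale reference conditions (N = 125 cells
in an L = 20 box, T = 400–800, for 60–80 replicate ensembles); the
"reduced" preset keeps the same area density (N·π/L² ≈ 0.99) and time step
at desk scale (N = 50, L = 12.6, T = 200) so ensemble sweeps finish in
minutes.  Replicate k of a sweep always runs with seed = base_seed + k, so
sweep summaries are bit-for-bit reproducible from the base seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import Frame, ModelParams, Population, Trajectory, simulate
from .geometry import EllipseSpec
from .observables import equilibrated_alignment

_ALIASES = {"N": "n_cells", "L": "box", "T": "t_end", "lambda": "lam"}
_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


def reduced_preset(**overrides) -> ModelParams:
    """Desk-scale base parameters: N=50, L=12.6 (area density N·π/L² ≈ 0.99,
    matching the full-scale 125·π/400), T=200, dt=0.01, r=2."""
    base = dict(n_cells=50, box=12.6, t_end=200.0, dt=0.01, r_init=2.0,
                nu=0.5, rbar=2.0)
    base.update(overrides)
    return ModelParams(**base)


def paper_preset(experiment: str, **overrides) -> ModelParams:
    """Full-scale reference experiments (N=125 cells in an L=20 box).

    ``base``: slow self-propulsion base model run to T=800;
    ``base_sweep``: the ν=0.5 base configuration used by the aspect-ratio
    and ν ensembles; ``deformable``: dynamic aspect ratio with γ=0.1;
    ``junction_actin``: front/back junctions with actin torques
    (κ=1, λ=0.2, μ=5, T=400).
    """
    sets = {
        "base": dict(nu=0.2, n_cells=125, box=20.0, r_init=2.0, t_end=800.0),
        "base_sweep": dict(nu=0.5, n_cells=125, box=20.0, r_init=2.0,
                           t_end=800.0),
        "deformable": dict(nu=0.5, gamma=0.1, rbar=2.0, shape_on=True,
                           n_cells=125, box=20.0, t_end=400.0),
        "junction_actin": dict(nu=0.5, kappa=1.0, lam=0.2, mu=5.0,
                               junctions_on=True, n_cells=125, box=20.0,
                               r_init=2.0, t_end=400.0),
    }
    if experiment not in sets:
        raise ValueError(
            f"unknown preset {experiment!r}; choose from {sorted(sets)}")
    cfg = sets[experiment]
    cfg.update(overrides)
    return ModelParams(**cfg)


@dataclass
class SweepSpec:
    """One-parameter ensemble sweep."""

    parameter: str
    grid: list[float]
    replicates: int
    base: ModelParams
    scale: str = "reduced"      # paper | reduced (bookkeeping tag)

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError("sweep grid must be non-empty")
        if self.parameter not in _FIELDS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class RunSummary:
    """Memoised per-replicate result (final frame only, to keep sweeps light)."""

    equil_alignment: float
    final_frame: Frame
    events: dict
    params: ModelParams

    @property
    def final(self) -> Population:
        return self.final_frame.population(self.params.box)


def _cache_key(params: ModelParams):
    d = dataclasses.asdict(params)
    return tuple(sorted(d.items()))


def run_replicate(params: ModelParams,
                  cache: dict | None = None) -> RunSummary:
    """Simulate one replicate, memoised on the full parameter set."""
    key = _cache_key(params) if cache is not None else None
    if cache is not None and key in cache:
        return cache[key]
    traj = simulate(params)
    summary = RunSummary(
        equil_alignment=equilibrated_alignment(traj),
        final_frame=traj.frames[-1], events=traj.events, params=params)
    if cache is not None:
        cache[key] = summary
    return summary


def run_sweep(spec: SweepSpec, out_dir: str | Path | None = None,
              cache: dict | None = None) -> pd.DataFrame:
    """Ensemble sweep: mean and standard deviation of equilibrated alignment
    per grid value, over ``replicates`` runs seeded base_seed + k.

    Returns a tidy table (one row per grid value); also written as CSV when
    ``out_dir`` is given.  A failed replicate aborts with its seed recorded.
    """
    rows = []
    for value in spec.grid:
        vals = []
        for k in range(spec.replicates):
            params = dataclasses.replace(
                spec.base, **{spec.parameter: value},
                seed=spec.base.seed + k)
            try:
                vals.append(run_replicate(params, cache).equil_alignment)
            except Exception as exc:
                raise RuntimeError(
                    f"replicate seed={params.seed} at "
                    f"{spec.parameter}={value} failed: {exc}") from exc
        rows.append((value, float(np.mean(vals)), float(np.std(vals)),
                     len(vals)))
    table = pd.DataFrame(rows, columns=[spec.parameter, "alignment_mean",
                                        "alignment_sd", "n_replicates"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / f"sweep_{spec.parameter}.csv", index=False)
    return table


def two_cell_fixture(name: str):
    """Deterministic two-cell scenarios for analytic tests.

    ``overlapping_circles``, ``symmetric_ellipses``, ``fb_junction_pair`` and
    ``ff_junction_pair`` return a :class:`Population` (L = 20 box);
    ``containment`` returns a pair of :class:`EllipseSpec` (strict
    containment needs unequal areas, which population cells — fixed at area
    π — cannot represent).
    """
    L = 20.0
    sr2 = np.sqrt(2.0)
    if name == "overlapping_circles":
        return Population(np.array([[5.0, 5.0], [6.0, 5.0]]),
                          np.array([0.0, 0.0]), np.array([1.0, 1.0]), L)
    if name == "symmetric_ellipses":
        # mirror-symmetric r=2 pair, long axes parallel, centres one unit apart
        return Population(np.array([[5.0, 5.0], [6.0, 5.0]]),
                          np.array([np.pi / 2, np.pi / 2]),
                          np.array([2.0, 2.0]), L)
    if name == "fb_junction_pair":
        # collinear r=2 cells: front of cell 0 to back of cell 1, gap 0.1
        return Population(np.array([[5.0, 5.0], [5.0 + 2 * sr2 + 0.1, 5.0]]),
                          np.array([0.0, 0.0]), np.array([2.0, 2.0]), L)
    if name == "ff_junction_pair":
        # facing r=2 cells: front of cell 0 to front of cell 1, gap 0.1
        return Population(np.array([[5.0, 5.0], [5.0 + 2 * sr2 + 0.1, 5.0]]),
                          np.array([0.0, np.pi]), np.array([2.0, 2.0]), L)
    if name == "containment":
        return (EllipseSpec(np.array([5.0, 5.0]), 0.0, 3.0, 2.0),
                EllipseSpec(np.array([5.5, 5.0]), 0.3, 1.0, 0.5))
    raise ValueError(f"unknown fixture {name!r}")


class ConfigError(ValueError):
    """A configuration file violated the schema; names the offending field."""


def _params_from_dict(cfg: dict) -> ModelParams:
    cfg = {_ALIASES.get(k, k): v for k, v in cfg.items()}
    unknown = set(cfg) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    if "n_cells" not in cfg:
        raise ConfigError("missing required field 'n_cells' (alias 'N')")
    try:
        return ModelParams(**cfg)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path):
    """Read a run or sweep configuration (YAML or JSON by extension).

    A plain mapping of parameter fields yields a :class:`ModelParams`
    (``N``/``L``/``T``/``lambda`` accepted as aliases); a mapping with a
    ``sweep`` key holding ``parameter``, ``grid``, ``replicates`` and
    ``base`` yields a :class:`SweepSpec`.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    if "sweep" in cfg:
        sw = dict(cfg["sweep"])
        for k in ("parameter", "grid", "base"):
            if k not in sw:
                raise ConfigError(f"sweep config missing field {k!r}")
        base = _params_from_dict(sw.pop("base"))
        return SweepSpec(parameter=_ALIASES.get(sw["parameter"], sw["parameter"]),
                         grid=list(sw["grid"]),
                         replicates=int(sw.get("replicates", 10)),
                         base=base, scale=sw.get("scale", "reduced"))
    return _params_from_dict(cfg)


def save_config(obj, path: str | Path) -> None:
    path = Path(path)
    if isinstance(obj, SweepSpec):
        cfg = {"sweep": {"parameter": obj.parameter, "grid": list(obj.grid),
                         "replicates": obj.replicates, "scale": obj.scale,
                         "base": dataclasses.asdict(obj.base)}}
    else:
        cfg = dataclasses.asdict(obj)
    text = json.dumps(cfg, indent=1) if path.suffix == ".json" \
        else yaml.safe_dump(cfg, sort_keys=False)
    path.write_text(text)


def write_outputs(trajectory: Trajectory, out_dir: str | Path,
                  with_observables: bool = True) -> None:
    """Write frames CSV, junctions CSV, run metadata JSON and (optionally)
    an observables JSON for one trajectory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trajectory.to_frames_dataframe().to_csv(out_dir / "frames.csv", index=False)
    if trajectory.params.junctions_on:
        trajectory.to_junctions_dataframe().to_csv(
            out_dir / "junctions.csv", index=False)
    meta = {"params": dataclasses.asdict(trajectory.params),
            "events": trajectory.events}
    (out_dir / "run.json").write_text(json.dumps(meta, indent=1))
    if with_observables:
        from .observables import report
        (out_dir / "observables.json").write_text(
            json.dumps(report(trajectory).to_dict(), indent=1))
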