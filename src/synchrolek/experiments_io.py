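"""Configuration, fixtures, result serialization, and experiment runners.

Everything here is reproducibility plumbing around the model modules:
strictly validated YAML run configurations (unknown keys are rejected
with their key path), seeded fixture generators for initial lag and
phase sets, tidy CSV/TSV/JSON outputs, and a manifest that echoes the
full configuration, seed and content digests so any experiment can be
replayed from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .binary_evolution import (
    BinaryPopulation,
    SelectionParams,
    SweepConfig,
    critical_fraction_sweep,
    integrate_reduced_gap,
    mean_field_sync,
    replicator_flow,
)
from .generational_evolution import (
    EvolutionConfig,
    MutationParams,
    classify_outcome,
    lag_bin_edges,
    run_evolution,
)
from .phase_dynamics import (
    OscillatorEnsemble,
    cluster_gap,
    integrate_fast,
    wrap_phase,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "RunManifest",
    "load_config",
    "parse_config",
    "render_config",
    "make_fixture",
    "write_results",
    "run_experiment",
]


class ConfigError(ValueError):
    """A run configuration failed validation."""


class _Settings(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class MutationSettings(_Settings):
    mutate_fraction: float = 0.1
    mutate_scale: float = 0.05


class ExtinctionSettings(_Settings):
    r_threshold: float = 0.2
    patience: int = 20


class SweepSettings(_Settings):
    lag_start: float = float(np.pi / 2)
    lag_stop: float = float(np.pi)
    lag_count: int = 21
    fraction_step: float = 0.02
    fraction_max: float = 1.0
    population_size: int = 200
    horizon: float = 400.0
    incoherence_threshold: float = 0.1
    noise_sd: float = 0.05


class BinaryRunSettings(_Settings):
    alpha_cheater: float = float(np.pi / 2)
    alpha_cooperator: float = 0.0
    initial_cheater_fraction: float = 0.2
    selection_rate: float = 1.0
    horizon: float = 200.0


class EvolveSettings(_Settings):
    strategy_kind: str = "symmetric_policing"
    strategy_amplitude: float = 1.0
    population_size: int = 200
    generations: int = 300
    fast_horizon: float = 100.0
    payoff_window: float = 0.1
    initial_lag_mean: float = 0.0
    initial_lag_sd: float = 0.1
    cost_weight: float = 1.0
    phase_noise_sd: float = 0.1
    mutation: MutationSettings = MutationSettings()
    extinction: ExtinctionSettings = ExtinctionSettings()


class ReduceCompareSettings(_Settings):
    alpha_cheater: float = float(np.pi / 2)
    cheater_fraction: float = 0.2
    initial_gap: float = 0.3
    population_size: int = 200
    horizon: float = 50.0


class RunConfig(_Settings):
    """A fully specified, serializable experiment configuration.

    Defaults are the canonical study conditions: K = 1, omega = 0,
    T_final = 100, beta = 1, n_mutate = 0.1, sigma_mutate = 0.05.
    """

    experiment: Literal["sweep_boundary", "binary_run", "evolve", "reduce_compare"]
    seed: int = 0
    output_dir: str = "results"
    coupling: float = 1.0
    natural_frequency: float = 0.0
    sweep: SweepSettings = SweepSettings()
    binary_run: BinaryRunSettings = BinaryRunSettings()
    evolve: EvolveSettings = EvolveSettings()
    reduce_compare: ReduceCompareSettings = ReduceCompareSettings()


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{path}: {err['msg']}")
    return "; ".join(lines)


def parse_config(raw: dict) -> RunConfig:
    """Validate a plain mapping into a :class:`RunConfig`."""
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return parse_config(raw)


def render_config(config: RunConfig) -> str:
    """Serialize a config to YAML; ``parse(render(c)) == c`` round-trips."""
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)


# ---------------------------------------------------------------------------
# Fixture generation

_FIXTURE_PARAMS = {
    "normal_lags": ({"mean", "sd", "size"}, set()),
    "binary_lags": (
        {"cheater_fraction", "lag_cheaters", "size"},
        {"lag_cooperators"},
    ),
    "clustered_phases": ({"cheater_fraction", "gap", "size"}, {"noise_sd"}),
    "uniform_phases": ({"size"}, set()),
}


def make_fixture(kind: str, params: dict, seed: int) -> np.ndarray:
    """Seeded initial lag or phase sets.

    Kinds: ``normal_lags`` (N(mu, sigma^2) draws, wrapped),
    ``binary_lags`` (exactly ``round(f*N)`` cheater entries, cooperators
    first), ``clustered_phases`` (cooperators at 0, cheaters at ``gap``,
    optional Gaussian noise) and ``uniform_phases``.
    """
    if kind not in _FIXTURE_PARAMS:
        raise ValueError(f"unknown fixture kind: {kind!r}")
    required, optional = _FIXTURE_PARAMS[kind]
    given = set(params)
    if not required <= given:
        raise ValueError(f"{kind}: missing parameters {sorted(required - given)}")
    if given - required - optional:
        raise ValueError(
            f"{kind}: unknown parameters {sorted(given - required - optional)}"
        )
    size = int(params["size"])
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(seed)

    if kind == "normal_lags":
        return wrap_phase(rng.normal(params["mean"], params["sd"], size))
    if kind == "uniform_phases":
        return wrap_phase(rng.uniform(-np.pi, np.pi, size))

    frac = float(params["cheater_fraction"])
    if not 0.0 <= frac <= 1.0:
        raise ValueError("cheater_fraction must lie in [0, 1]")
    num_cheaters = int(round(frac * size))
    if kind == "binary_lags":
        out = np.full(size, float(params.get("lag_cooperators", 0.0)))
        out[size - num_cheaters:] = float(params["lag_cheaters"])
        return out
    # clustered_phases
    out = np.zeros(size)
    out[size - num_cheaters:] = float(params["gap"])
    noise_sd = float(params.get("noise_sd", 0.0))
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size)
    return wrap_phase(out)


# ---------------------------------------------------------------------------
# Result serialization

@dataclasses.dataclass
class RunManifest:
    """Replay record: config echo, version, seed, timing, file digests."""

    config: dict
    version: str
    seed: int
    started: str
    finished: str
    files: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def verify(self, base_dir) -> None:
        """Check that every listed output exists and matches its digest."""
        base = Path(base_dir)
        for name, entry in self.files.items():
            path = base / entry["path"]
            if not path.exists():
                raise FileNotFoundError(f"manifest entry {name!r}: missing {path}")
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            if digest != entry["sha256"]:
                raise ValueError(f"manifest entry {name!r}: digest mismatch for {path}")


def _write_one(path: Path, payload) -> None:
    if isinstance(payload, pd.DataFrame):
        payload.to_csv(path, index=False)
    elif isinstance(payload, np.ndarray):
        fmt = "%d" if np.issubdtype(payload.dtype, np.integer) else "%.10g"
        np.savetxt(path, np.atleast_2d(payload), fmt=fmt, delimiter="\t")
    elif isinstance(payload, dict):
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    else:
        raise TypeError(f"unsupported output payload type: {type(payload)!r}")


def write_results(outputs: dict, out_dir, *, config: RunConfig, started: str) -> RunManifest:
    """Write tidy outputs plus a digest-bearing JSON manifest.

    ``outputs`` maps a short name to a DataFrame (written as CSV), a
    numeric matrix (tab-delimited text) or a mapping (JSON).  The
    manifest is verified immediately after writing.
    """
    base = Path(out_dir)
    base.mkdir(parents=True, exist_ok=True)
    suffix = {pd.DataFrame: ".csv", np.ndarray: ".tsv", dict: ".json"}
    files = {}
    for name, payload in outputs.items():
        ext = next(
            (s for cls, s in suffix.items() if isinstance(payload, cls)), None
        )
        if ext is None:
            raise TypeError(f"unsupported output payload for {name!r}")
        path = base / f"{name}{ext}"
        try:
            _write_one(path, payload)
        except OSError as exc:
            raise OSError(f"cannot write result {name!r} to {path}: {exc}") from exc
        files[name] = {
            "path": path.name,
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
    manifest = RunManifest(
        config=config.model_dump(mode="json"),
        version=__version__,
        seed=config.seed,
        started=started,
        finished=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        files=files,
    )
    (base / "manifest.json").write_text(manifest.to_json())
    manifest.verify(base)
    return manifest


# ---------------------------------------------------------------------------
# Experiment runners

def _run_sweep(config: RunConfig) -> dict:
    s = config.sweep
    lag_grid = np.linspace(s.lag_start, s.lag_stop, s.lag_count)
    fractions = np.arange(s.fraction_step, s.fraction_max + 1e-9, s.fraction_step)
    cfg = SweepConfig(
        population_size=s.population_size,
        horizon=s.horizon,
        coupling=config.coupling,
        natural_frequency=config.natural_frequency,
        incoherence_threshold=s.incoherence_threshold,
        noise_sd=s.noise_sd,
        seed=config.seed,
    )
    df = critical_fraction_sweep(lag_grid, fractions, cfg)
    meta = {"incoherence_threshold": s.incoherence_threshold, "horizon": s.horizon}
    return {"boundary": df, "sweep_meta": meta}


def _run_binary(config: RunConfig) -> dict:
    s = config.binary_run
    pop = BinaryPopulation(
        1.0 - s.initial_cheater_fraction,
        s.initial_cheater_fraction,
        s.alpha_cooperator,
        s.alpha_cheater,
    )
    traj = replicator_flow(
        pop, SelectionParams(selection_strength=s.selection_rate), s.horizon
    )
    df = pd.DataFrame(
        {
            "time": traj.times,
            "n_co": traj.frac_cooperators,
            "n_ch": traj.frac_cheaters,
            "R": traj.sync_history(),
        }
    )
    return {"membership": df}


def _run_evolve(config: RunConfig) -> dict:
    s = config.evolve
    evo = EvolutionConfig(
        population_size=s.population_size,
        generations=s.generations,
        fast_horizon=s.fast_horizon,
        payoff_window=s.payoff_window,
        coupling=config.coupling,
        natural_frequency=config.natural_frequency,
        initial_lag_mean=s.initial_lag_mean,
        initial_lag_sd=s.initial_lag_sd,
        strategy_kind=s.strategy_kind,
        strategy_params={"amplitude": s.strategy_amplitude},
        cost_weight=s.cost_weight,
        mutation=MutationParams(s.mutation.mutate_fraction, s.mutation.mutate_scale),
        seed=config.seed,
        extinction_R_threshold=s.extinction.r_threshold,
        extinction_patience=s.extinction.patience,
        phase_noise_sd=s.phase_noise_sd,
    )
    summaries = run_evolution(evo)
    df = pd.DataFrame(
        {
            "generation": [s_.generation_index for s_ in summaries],
            "mean_R": [s_.mean_R for s_ in summaries],
            "lag_mean": [s_.lag_mean for s_ in summaries],
            "lag_sd": [s_.lag_sd for s_ in summaries],
            "outcome": [s_.outcome_flag for s_ in summaries],
        }
    )
    histogram = np.vstack([s_.lag_histogram for s_ in summaries])
    meta = {
        "classification": classify_outcome(summaries, evo),
        "bin_edges": lag_bin_edges(evo.lag_bin_width).tolist(),
        "generations_run": len(summaries),
    }
    return {"generations": df, "lag_histograms": histogram, "evolve_meta": meta}


def _run_reduce_compare(config: RunConfig) -> dict:
    s = config.reduce_compare
    n = s.population_size
    num_cheaters = int(round(s.cheater_fraction * n))
    lags = np.zeros(n)
    lags[n - num_cheaters:] = s.alpha_cheater
    phases0 = np.zeros(n)
    phases0[n - num_cheaters:] = s.initial_gap
    ensemble = OscillatorEnsemble(
        phases0, lags, config.natural_frequency, config.coupling
    )
    traj = integrate_fast(ensemble, s.horizon)
    mask = lags != 0
    gap_full = np.array([cluster_gap(row, mask) for row in traj.phase_history])
    pop = BinaryPopulation(1.0 - num_cheaters / n, num_cheaters / n, 0.0, s.alpha_cheater)
    _, gap_reduced = integrate_reduced_gap(
        s.initial_gap, pop, s.horizon, coupling=config.coupling
    )
    df = pd.DataFrame(
        {
            "time": traj.times,
            "gap_full": gap_full,
            "gap_reduced": gap_reduced,
            "abs_diff": np.abs(gap_full - gap_reduced),
        }
    )
    return {"gap_comparison": df}


_RUNNERS = {
    "sweep_boundary": _run_sweep,
    "binary_run": _run_binary,
    "evolve": _run_evolve,
    "reduce_compare": _run_reduce_compare,
}


def run_experiment(config: RunConfig, out_dir=None) -> RunManifest:
    """Execute the configured experiment and write results + manifest."""
    started = _dt.datetime.now(_dt.timezone.utc).isoformat()
    outputs = _RUNNERS[config.experiment](config)
    return write_results(
        outputs, out_dir or config.output_dir, config=config, started=started
    )
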