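"""Configuration files, output tables, run manifests, and fixtures.

Configs are YAML mappings; every key has a CLI flag mirror. Outputs are
tab-separated text tables plus a JSON manifest/summary — no binary formats.
Numeric columns are written with a fixed ``%.10g`` format so identical
config+seed reruns reproduce byte-identical tables (timestamps live only in
the manifest).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compartments import (
    BiasConfig,
    make_competitive_pair,
    make_cooperative_pair,
    majority_monomer,
)
from .observables import SteadyStateSummary, provenance_histogram
from .sequence import MotifSpec, complement
from .simulate import (
    ExperimentConfig,
    PopulationState,
    TrajectoryRecord,
    derive_trial_seeds,
)

__all__ = [
    "ConfigError",
    "parse_config",
    "expand_sweep",
    "config_to_dict",
    "write_outputs",
    "make_fixture",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_DEFAULTS = {
    "N": 100,
    "M": 100,
    "L": 7,
    "r": 0.05,
    "rounds": 7000,
    "burn_in": 1000,
    "sample_end": 7000,
    "trials": 50,
    "seed": 0,
    "mode": "single",
    "bias": 0.5,
    "relationship": None,
    "motif": None,
    "favored": None,
    "track": (),
}

_SWEEP_KEYS = ("bias", "motif", "r")


def _check_pattern_key(value, key: str) -> str:
    if not isinstance(value, str) or not value or set(value) - {"0", "1"}:
        raise ConfigError(f"{key}: motif patterns must be non-empty 0/1 strings, got {value!r}")
    return value


def _build_bias(raw: dict) -> BiasConfig:
    mode = raw["mode"]
    if mode == "neutral":
        return BiasConfig.neutral()
    motif = raw.get("motif")
    if motif is None:
        raise ConfigError(f"motif: required for mode {mode!r}")
    _check_pattern_key(motif, "motif")
    b = raw["bias"]
    if not isinstance(b, (int, float)) or not 0.0 <= float(b) <= 1.0:
        raise ConfigError(f"bias: must be a number in [0, 1], got {b!r}")
    if mode == "single":
        favored = raw.get("favored")
        if favored is None:
            try:
                favored = majority_monomer(motif)
            except ValueError as exc:
                raise ConfigError(f"favored: {exc}") from exc
        if favored not in (0, 1):
            raise ConfigError(f"favored: must be 0 or 1, got {favored!r}")
        return BiasConfig.single(MotifSpec(motif, favored_monomer=favored, bias=float(b)))
    if mode == "paired":
        relationship = raw.get("relationship")
        if relationship == "cooperative":
            return make_cooperative_pair(motif, float(b))
        if relationship == "competitive":
            return make_competitive_pair(motif, float(b))
        raise ConfigError(
            f"relationship: paired mode needs 'cooperative' or 'competitive', got {relationship!r}"
        )
    raise ConfigError(f"mode: must be neutral, single or paired, got {mode!r}")


def parse_config(source) -> ExperimentConfig:
    """Validate a config mapping (or YAML file path) into an ExperimentConfig.

    Missing keys take the standard defaults (N=100, M=100, L=7, r=0.05,
    burn_in=1000, sample_end=7000, trials=50); unknown keys and out-of-range
    values are rejected with messages naming the offending field.
    """
    raw = _load_raw(source)
    for key in _SWEEP_KEYS:
        if isinstance(raw.get(key), (list, tuple)):
            raise ConfigError(
                f"{key}: is a sweep list; expand it with expand_sweep() first"
            )
    return _single_config(raw)


def _load_raw(source) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of keys to values")
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = dict(_DEFAULTS)
    merged.update(raw)
    return merged


def _single_config(raw: dict) -> ExperimentConfig:
    bias = _build_bias(raw)
    track = raw["track"] or ()
    if isinstance(track, str):
        track = (track,)
    track = tuple(_check_pattern_key(p, "track") for p in track)
    for key in ("N", "M", "L", "rounds", "burn_in", "sample_end", "trials", "seed"):
        if not isinstance(raw[key], (int, np.integer)) or isinstance(raw[key], bool):
            raise ConfigError(f"{key}: must be an integer, got {raw[key]!r}")
    if not isinstance(raw["r"], (int, float)) or not 0.0 < float(raw["r"]) <= 1.0:
        raise ConfigError(f"r: must be in (0, 1], got {raw['r']!r}")
    try:
        return ExperimentConfig(
            bias=bias,
            N=int(raw["N"]),
            M=int(raw["M"]),
            L=int(raw["L"]),
            r=float(raw["r"]),
            rounds=int(raw["rounds"]),
            burn_in=int(raw["burn_in"]),
            sample_end=int(raw["sample_end"]),
            trials=int(raw["trials"]),
            seed=int(raw["seed"]),
            track_patterns=track,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def expand_sweep(source) -> list[ExperimentConfig]:
    """Expand list-valued keys (bias, motif, r) into independent experiments.

    Each grid point gets a seed derived deterministically from the base seed
    and its position, so sweep members are independent and reproducible.
    """
    raw = _load_raw(source)
    grids = {k: raw[k] for k in _SWEEP_KEYS if isinstance(raw.get(k), (list, tuple))}
    if not grids:
        return [_single_config(raw)]
    combos = [dict()]
    for key, values in grids.items():
        combos = [{**c, key: v} for c in combos for v in values]
    base_seed = raw["seed"]
    configs = []
    for i, combo in enumerate(combos):
        point = dict(raw)
        point.update(combo)
        point["seed"] = int(np.random.SeedSequence([int(base_seed), i]).generate_state(1)[0] >> 1)
        configs.append(_single_config(point))
    return configs


def config_to_dict(config: ExperimentConfig) -> dict:
    """Round-trippable plain mapping: parse_config(config_to_dict(c)) == c."""
    bias = config.bias
    out = {
        "N": config.N,
        "M": config.M,
        "L": config.L,
        "r": config.r,
        "rounds": config.rounds,
        "burn_in": config.burn_in,
        "sample_end": config.sample_end,
        "trials": config.trials,
        "seed": config.seed,
        "mode": bias.mode,
        "track": list(config.track_patterns),
    }
    if bias.mode == "single":
        out["motif"] = bias.motif_a.pattern
        out["favored"] = bias.motif_a.favored_monomer
        out["bias"] = bias.motif_a.bias
    elif bias.mode == "paired":
        out["motif"] = bias.motif_a.pattern
        out["bias"] = bias.motif_a.bias
        out["relationship"] = bias.relationship
    return out


# ---------------------------------------------------------------------------
# output writing

_FLOAT_FMT = "%.10g"


def _rounds_table(records: list[TrajectoryRecord]) -> pd.DataFrame:
    rows = []
    for trial, rec in enumerate(records):
        n_rounds, n_pat = rec.motif_freq.shape
        for k, pat in enumerate(rec.patterns):
            rows.append(
                pd.DataFrame(
                    {
                        "trial": trial,
                        "round": np.arange(1, n_rounds + 1),
                        "motif": pat,
                        "motif_frequency": rec.motif_freq[:, k],
                        "compartment_frequency": rec.comp_freq[:, k],
                    }
                )
            )
    cols = ["trial", "round", "motif", "motif_frequency", "compartment_frequency"]
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=cols)


def _events_table(records: list[TrajectoryRecord]) -> pd.DataFrame:
    rows = []
    for trial, rec in enumerate(records):
        if rec.event_rounds.size:
            rows.append(
                pd.DataFrame(
                    {
                        "trial": trial,
                        "round": rec.event_rounds,
                        "compartment": rec.event_comp_ids,
                        "motif": [rec.patterns[k] for k in rec.event_pattern_idx],
                    }
                )
            )
    cols = ["trial", "round", "compartment", "motif"]
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=cols)


def _provenance_table(records: list[TrajectoryRecord]) -> pd.DataFrame:
    rows = []
    for trial, rec in enumerate(records):
        for pat in rec.patterns:
            hist = provenance_histogram([rec], pattern=pat, min_frequency=0.0)
            for label_pattern, frac in sorted(hist.items()):
                rows.append(
                    {
                        "trial": trial,
                        "motif": pat,
                        "pattern": label_pattern,
                        "fraction": frac,
                    }
                )
    cols = ["trial", "motif", "pattern", "fraction"]
    return pd.DataFrame(rows, columns=cols)


def _summary_table(summaries: list[SteadyStateSummary], config: ExperimentConfig) -> pd.DataFrame:
    b = config.bias.motif_a.bias if config.bias.mode != "neutral" else 0.5
    rows = [
        {
            "motif": s.pattern,
            "b": b,
            "mean": s.mean,
            "ci_low": s.ci_low,
            "ci_high": s.ci_high,
            "trials": s.per_trial.size,
        }
        for s in summaries
    ]
    cols = ["motif", "b", "mean", "ci_low", "ci_high", "trials"]
    return pd.DataFrame(rows, columns=cols)


def write_outputs(
    records: list[TrajectoryRecord],
    summaries: list[SteadyStateSummary],
    config: ExperimentConfig,
    out_dir,
) -> dict:
    """Write the tidy tables, config echo, and JSON manifest for one run.

    Returns the manifest mapping (also written to ``manifest.json``), whose
    file inventory carries a sha256 checksum per output file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    tables = {
        "rounds.tsv": _rounds_table(records),
        "events.tsv": _events_table(records),
        "provenance.tsv": _provenance_table(records),
        "summary.tsv": _summary_table(summaries, config),
    }
    for name, frame in tables.items():
        frame.to_csv(out / name, sep="\t", index=False, float_format=_FLOAT_FMT)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
    summary_doc = {
        "patterns": list(records[0].patterns) if records else [],
        "steady_state": [
            {
                "motif": s.pattern,
                "mean": s.mean,
                "ci_half_width": s.ci_half_width,
                "window": [s.burn_in, s.sample_end],
            }
            for s in summaries
        ],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary_doc, fh, indent=2, sort_keys=True)

    inventory = {}
    for name in sorted([*tables, "config.yaml", "summary.json"]):
        digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
        inventory[name] = digest
    manifest = {
        "package_version": __version__,
        "config": config_to_dict(config),
        "base_seed": config.seed,
        "trial_seeds": derive_trial_seeds(config.seed, len(records) or config.trials),
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "files": inventory,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# deterministic fixtures


def make_fixture(name: str) -> tuple[ExperimentConfig, PopulationState]:
    """Small deterministic populations for tests and worked examples.

    ``"fig1"``: two compartments of four slots, cap 7, single motif 100 — a
    fresh (round 0) population of empty strands. ``"fig3c"``: one
    compartment holding all four length-2 primers {00, 01, 10, 11} with
    motif 1000 in the deterministic limiting regime b = 1, r = 1.
    """
    if name == "fig1":
        config = ExperimentConfig(
            bias=BiasConfig.single(MotifSpec("100", favored_monomer=0, bias=0.9)),
            N=2,
            M=4,
            L=7,
            r=0.05,
            rounds=100,
            burn_in=10,
            sample_end=100,
            trials=1,
            seed=0,
        )
        return config, PopulationState.empty(2, 4)
    if name == "fig3c":
        config = ExperimentConfig(
            bias=BiasConfig.single(MotifSpec("1000", favored_monomer=0, bias=1.0)),
            N=1,
            M=4,
            L=7,
            r=1.0,
            rounds=5,
            burn_in=1,
            sample_end=5,
            trials=1,
            seed=0,
        )
        return config, PopulationState.from_bits([["00", "01", "10", "11"]], M=4)
    raise ValueError(f"unknown fixture {name!r}; known: 'fig1', 'fig3c'")
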