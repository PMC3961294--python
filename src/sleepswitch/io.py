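"""Configuration files, artifact I/O, run manifests, fixture scenarios.

The config format is a flat ``key = value`` text file with one
documented, unit-suffixed key per model symbol (see
``docs/config_schema.md``).  Artifact writers use a write-then-rename
contract so partial writes never leave truncated files behind, and every
output directory carries a machine-readable manifest sufficient to
reproduce each stochastic run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .experiments import ScenarioSpec, run_scenario
from .hypnogram import Hypnogram, SleepStats
from .integrate import Trajectory
from .params import (SECONDS_PER_HOUR, ModelParameters, NOISE_CONVENTIONS,
                     ParameterError)

__all__ = [
    "load_config", "save_config", "write_trajectory_csv",
    "read_trajectory_csv", "write_hypnogram_tsv", "read_hypnogram_tsv",
    "write_stats_csv", "write_outputs", "RunManifest",
    "rerun_from_manifest", "FixtureScenario", "make_fixtures",
]

logger = logging.getLogger(__name__)

# key -> (group attr, field, scale internal = value * scale)
CONFIG_SCHEMA: dict[str, tuple[str, str, float]] = {
    "q_max_per_s": ("sigmoid", "q_max", 1.0),
    "theta_mV": ("sigmoid", "theta", 1.0),
    "sigma_prime_mV": ("sigmoid", "sigma_prime", 1.0),
    "nu_vm_mVs": ("coupling", "nu_vm", 1.0),
    "nu_mv_mVs": ("coupling", "nu_mv", 1.0),
    "nu_ov_mVs": ("coupling", "nu_ov", 1.0),
    "nu_mo_mVs": ("coupling", "nu_mo", 1.0),
    "nu_om_mVs": ("coupling", "nu_om", 1.0),
    "nu_vc_mV": ("drives", "nu_vc", 1.0),
    "nu_vh_mV": ("drives", "nu_vh", 1.0),
    "nu_oc_mV": ("drives", "nu_oc", 1.0),
    "nu_oh_mV": ("drives", "nu_oh", 1.0),
    "a_v_mV": ("drives", "a_v", 1.0),
    "a_m_mV": ("drives", "a_m", 1.0),
    "a_o_mV": ("drives", "a_o", 1.0),
    "phase_ref_h": ("drives", "phase_ref", SECONDS_PER_HOUR),
    "chi_h": ("homeostat", "chi", SECONDS_PER_HOUR),
    "mu_H": ("homeostat", "mu", 1.0),
    "q_sat_per_s": ("homeostat", "q_sat", 1.0),
    "tau_v_s": ("tau", "tau_v", 1.0),
    "tau_m_s": ("tau", "tau_m", 1.0),
    "tau_o_s": ("tau", "tau_o", 1.0),
    "sigma_v_mV": ("noise", "sigma_v", 1.0),
    "sigma_m_mV": ("noise", "sigma_m", 1.0),
}

SCENARIO_KEYS = ("duration_days", "equilibration_days", "seed", "dt_s",
                 "noise", "init", "record_dt_s")

_KNOWN_SYMBOL_KEYS = {key.rsplit("_", 1)[0]: key for key in CONFIG_SCHEMA}


def _parse_kv(text: str) -> dict[str, str]:
    out = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        out[key] = value
    return out


def load_config(path: str | Path) -> tuple[ModelParameters, ScenarioSpec]:
    """Load a flat key-value config into parameters + scenario spec.

    Unknown keys are rejected by name; a known symbol carrying the wrong
    unit suffix is a hard error naming the offending key; keys that are
    absent fall back to the nominal values with a logged notice.
    """
    raw = _parse_kv(Path(path).read_text())
    params = ModelParameters.nominal()
    scenario: dict = {}
    for key, value in raw.items():
        if key in CONFIG_SCHEMA:
            group, fieldname, scale = CONFIG_SCHEMA[key]
            setattr(getattr(params, group), fieldname, float(value) * scale)
        elif key == "noise_convention":
            params.noise.scaling_convention = value
        elif key in SCENARIO_KEYS:
            scenario[key] = value
        else:
            stem = key.rsplit("_", 1)[0]
            if stem in _KNOWN_SYMBOL_KEYS:
                raise ValueError(
                    f"config key {key!r} has the wrong unit suffix; "
                    f"expected {_KNOWN_SYMBOL_KEYS[stem]!r}")
            raise ValueError(f"unknown config key {key!r}")
    missing = [k for k in CONFIG_SCHEMA if k not in raw]
    if missing:
        logger.info("config %s: %d keys missing, filled from nominal values",
                    path, len(missing))
    try:
        params.validate()
    except ParameterError as err:
        raise ValueError(f"invalid config {path}: {err}") from err
    spec = ScenarioSpec(
        duration_days=float(scenario.get("duration_days", 25.0)),
        equilibration_days=float(scenario.get("equilibration_days", 3.0)),
        seed=int(scenario.get("seed", 0)),
        noise=scenario.get("noise", "1").lower() not in ("0", "false", "no"),
        init=scenario.get("init", "awake"),
        dt=float(scenario.get("dt_s", 0.1)),
        record_dt=float(scenario.get("record_dt_s", 1.0)),
    )
    return params, spec


def _format_config(params: ModelParameters, spec: ScenarioSpec | None) -> str:
    lines = ["# sleepswitch configuration (flat key = value)"]
    for key, (group, fieldname, scale) in CONFIG_SCHEMA.items():
        val = getattr(getattr(params, group), fieldname) / scale
        lines.append(f"{key} = {val!r}")
    lines.append(f"noise_convention = {params.noise.scaling_convention}")
    if spec is not None:
        lines += [
            f"duration_days = {spec.duration_days!r}",
            f"equilibration_days = {spec.equilibration_days!r}",
            f"seed = {spec.seed}",
            f"dt_s = {spec.dt!r}",
            f"noise = {int(spec.noise)}",
            f"init = {spec.init}",
            f"record_dt_s = {spec.record_dt!r}",
        ]
    return "\n".join(lines) + "\n"


def save_config(params: ModelParameters, path: str | Path,
                spec: ScenarioSpec | None = None) -> None:
    _atomic_write(Path(path), _format_config(params, spec))


# -- artifact writers ------------------------------------------------------

def _atomic_write(path: Path, content: str | bytes) -> None:
    """Write-then-rename so failures never leave truncated files."""
    path.parent.mkdir(parents=True, exist_ok=True)
    mode = "w" if isinstance(content, str) else "wb"
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            fh.write(content)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Trajectory (states + derived columns) as CSV with metadata header.

    Full float precision; `read_trajectory_csv` round-trips exactly.
    """
    buf = _io.StringIO()
    buf.write(f"# fingerprint={traj.fingerprint()}\n")
    buf.write(f"# seed={traj.seed} dt={traj.dt!r} kind={traj.kind}\n")
    buf.write("# params=" + json.dumps(traj.params.symbols()) + "\n")
    frame = traj.to_frame()
    frame.to_csv(buf, index=False, float_format="%.17g")
    _atomic_write(Path(path), buf.getvalue())


def read_trajectory_csv(path: str | Path) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    meta = {}
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        if line.startswith("# params="):
            meta["params"] = json.loads(line[len("# params="):])
        elif line.startswith("# seed="):
            parts = dict(tok.split("=", 1) for tok in line[2:].split())
            meta.update(parts)
    frame = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])),
                        float_precision="round_trip")
    symbols = dict(meta["params"])
    convention = symbols.pop("scaling_convention")
    params = ModelParameters.nominal().with_overrides(symbols)
    params.noise.scaling_convention = convention
    seed = None if meta.get("seed") == "None" else int(meta["seed"])
    dt = None if meta.get("dt") == "None" else float(meta["dt"])
    states = frame[["Vv_mV", "Vm_mV", "Vo_mV", "H"]].to_numpy(dtype=float)
    return Trajectory(times=frame["t_s"].to_numpy(dtype=float), states=states,
                      params=params, seed=seed, dt=dt,
                      kind=meta.get("kind", "stochastic"))


def write_hypnogram_tsv(hyp: Hypnogram, path: str | Path) -> None:
    buf = _io.StringIO()
    buf.write(f"# debounce_s={hyp.debounce_s!r} source={hyp.source}\n")
    hyp.to_frame().to_csv(buf, sep="\t", index=False, float_format="%.17g")
    _atomic_write(Path(path), buf.getvalue())


def read_hypnogram_tsv(path: str | Path) -> Hypnogram:
    lines = Path(path).read_text().splitlines()
    debounce, source = 60.0, ""
    body = lines
    if lines and lines[0].startswith("#"):
        head = lines[0][2:]
        debounce = float(head.split("debounce_s=")[1].split()[0])
        source = head.split("source=", 1)[1] if "source=" in head else ""
        body = lines[1:]
    frame = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t",
                        float_precision="round_trip")
    intervals = [(float(a), float(b), str(s))
                 for a, b, s in frame.itertuples(index=False)]
    return Hypnogram(intervals=intervals, debounce_s=debounce, source=source)


def write_stats_csv(stats: SleepStats, path: str | Path) -> None:
    rows = "".join(f"{k},{v!r}\n" for k, v in stats.to_dict().items())
    _atomic_write(Path(path), "key,value\n" + rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Everything needed to bit-reproduce a stochastic run."""

    params: dict
    spec: dict
    version: str
    files: dict[str, str]      # name -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def write_outputs(result, out_dir: str | Path,
                  portrait=None) -> RunManifest:
    """Write a scenario result's artifacts plus a manifest.

    Writes trajectory CSV, hypnogram TSV, stats CSV, optional portrait
    JSON, and ``manifest.json`` with checksums of all files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trajectory_csv(result.trajectory, out / "trajectory.csv")
    write_hypnogram_tsv(result.hypnogram, out / "hypnogram.tsv")
    write_stats_csv(result.stats, out / "stats.csv")
    names = ["trajectory.csv", "hypnogram.tsv", "stats.csv"]
    if portrait is not None:
        _atomic_write(out / "portrait.json", portrait.to_json())
        names.append("portrait.json")
    manifest = RunManifest(
        params=result.params.symbols(),
        spec=dataclasses.asdict(result.spec),
        version=__version__,
        files={name: _sha256(out / name) for name in names},
    )
    _atomic_write(out / "manifest.json", manifest.to_json())
    return manifest


def rerun_from_manifest(manifest_path: str | Path):
    """Re-execute the scenario recorded in a manifest.

    Returns the fresh ScenarioResult; with the same package version the
    trajectory reproduces bit-for-bit (checksummable against the
    manifest's file inventory).
    """
    manifest = RunManifest.from_json(Path(manifest_path).read_text())
    symbols = dict(manifest.params)
    convention = symbols.pop("scaling_convention")
    params = ModelParameters.nominal().with_overrides(symbols)
    params.noise.scaling_convention = convention
    spec = ScenarioSpec(**manifest.spec)
    return run_scenario(spec, base_params=params)


# -- fixture scenarios -----------------------------------------------------

@dataclass
class FixtureScenario:
    """Named, seeded scenario with an expected qualitative outcome tag."""

    name: str
    spec: ScenarioSpec | None
    expected: str                       # qualitative outcome tag
    frozen_drives: tuple[float, float] | None = None  # (D_v, D_m) panels


def make_fixtures(seed: int = 0) -> list[FixtureScenario]:
    """Deterministic fixture set spanning the model's regimes.

    Time-series fixtures run in well under a minute each at the reduced
    durations used here; the frozen-drive entries mark (D_v, D_m) points
    of the bistable wedge for phase-plane demonstrations (deep bistable,
    sleep-biased, and fragmented low-drive regimes).
    """
    from .experiments import derive_seed
    return [
        FixtureScenario(
            name="nominal_noise_free",
            spec=ScenarioSpec(duration_days=5, noise=False,
                              seed=derive_seed(seed, 0)),
            expected="periodic_noise_free"),
        FixtureScenario(
            name="nominal_noisy",
            spec=ScenarioSpec(duration_days=5, seed=derive_seed(seed, 1)),
            expected="consolidated"),
        FixtureScenario(
            name="orexin_knockout",
            spec=ScenarioSpec(overrides={"nu_mo": 0.0}, duration_days=2,
                              seed=derive_seed(seed, 2)),
            expected="fragmented"),
        FixtureScenario(
            name="bistable_deep", spec=None, expected="pinned",
            frozen_drives=(2.3, 2.0)),
        FixtureScenario(
            name="bistable_sleep_biased", spec=None, expected="sleep_biased",
            frozen_drives=(2.6, 1.5)),
        FixtureScenario(
            name="bistable_low_drives", spec=None, expected="fragmented",
            frozen_drives=(1.0, 0.52)),
    ]
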