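"""Dataset/config readers and writers, run manifests and test fixtures.

Cohort files are plain CSV with a mandatory header and columns
``time,event,exposure[,stratum]`` (comma-separated, period decimal, UTF-8).
Scenario files are YAML with the keys ``model, gamma, beta, q, n, reps, seed,
tau, lambda0, admin_censor_time``; omitted keys take the scenario defaults.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import ARCurve, CohortSample, ValidationError
from .simulate import ScenarioConfig, generate, replicate_rng, theoretical_ar

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "write_ar_csv",
    "read_scenario_config",
    "RunManifest",
    "make_fixture",
]

_REQUIRED = ("time", "event", "exposure")
_SCENARIO_KEYS = {
    "model", "gamma", "beta", "q", "n", "reps", "seed", "tau", "lambda0",
    "admin_censor_time", "theta",
}


def read_cohort_csv(path) -> CohortSample:
    """Read and validate a subject-level cohort CSV.

    Validation failures name the first offending data row (1-based, header
    excluded) so problems in large files can be located directly.
    """
    frame = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    if frame.empty:
        raise ValidationError(f"{path}: no data rows")

    def first_bad(mask: pd.Series, what: str):
        if mask.any():
            row = int(mask.idxmax()) + 1
            raise ValidationError(f"{path}: {what} on data row {row}")

    time = pd.to_numeric(frame["time"], errors="coerce")
    first_bad(time.isna(), "non-numeric or missing time")
    first_bad(time < 0, "negative follow-up time")
    for col in ("event", "exposure"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        first_bad(~vals.isin([0, 1]), f"{col} not coded 0/1")
    stratum = None
    if "stratum" in frame.columns:
        s = pd.to_numeric(frame["stratum"], errors="coerce")
        first_bad(s.isna() | (s != s.round()), "non-integer stratum")
        stratum = s.to_numpy(dtype=np.int64)
    return CohortSample(
        time.to_numpy(float),
        frame["event"].to_numpy(np.int8),
        frame["exposure"].to_numpy(np.int8),
        stratum,
    )


def write_cohort_csv(sample: CohortSample, path) -> None:
    frame = pd.DataFrame(
        {
            "time": sample.time,
            "event": sample.event,
            "exposure": sample.exposure,
            "stratum": sample.stratum,
        }
    )
    frame.to_csv(path, index=False)


def write_ar_csv(curves: list[ARCurve] | ARCurve, path) -> None:
    if isinstance(curves, ARCurve):
        curves = [curves]
    pd.concat([c.to_frame() for c in curves]).to_csv(path, index=False)


def read_scenario_config(path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: scenario file must be a YAML mapping")
    unknown = set(raw) - _SCENARIO_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown scenario key(s) {sorted(unknown)}")
    return ScenarioConfig(**raw)


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    subcommand: str
    config: dict
    seed: int | None
    version: str
    started: str
    finished: str = ""
    outputs: list[str] = field(default_factory=list)

    @classmethod
    def start(cls, subcommand: str, config: dict, seed: int | None) -> "RunManifest":
        from . import __version__

        return cls(
            subcommand=subcommand,
            config=config,
            seed=seed,
            version=__version__,
            started=datetime.now(timezone.utc).isoformat(),
        )

    def finish(self, path) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()
        for out in self.outputs:
            if not Path(out).exists():
                raise RuntimeError(f"manifest references missing output {out}")
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


# --- deterministic fixtures for tests and documentation ---------------------

# Ten hand-checkable subjects.  Unexposed group: events at 1, 3, 4 and
# censorings at 2, 5, giving KM steps 4/5, 8/15, 4/15.
_TOY_ROWS = [
    (1.0, 1, 0), (2.0, 0, 0), (3.0, 1, 0), (4.0, 1, 0), (5.0, 0, 0),
    (2.0, 1, 1), (4.0, 1, 1), (5.0, 1, 1), (6.0, 0, 1), (8.0, 1, 1),
]
_TOY_KM_UNEXPOSED = [(1.0, 4 / 5), (3.0, 8 / 15), (4.0, 4 / 15)]


def make_fixture(kind: str, seed: int, out_dir) -> list[Path]:
    """Write a small deterministic dataset (plus truth/expected values).

    ``toy`` — ten hand-checkable subjects with the unexposed Kaplan-Meier
    values stored alongside; ``table1`` — one PH replicate (γ=1, β=ln 2,
    q=0.5, n=1,000) with its closed-form A(t); ``nph`` — one replicate of the
    nonproportional-hazards mechanism with its truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "toy":
        data = out_dir / "toy.csv"
        pd.DataFrame(_TOY_ROWS, columns=["time", "event", "exposure"]).to_csv(
            data, index=False
        )
        expected = out_dir / "toy_expected_km_unexposed.csv"
        pd.DataFrame(_TOY_KM_UNEXPOSED, columns=["time", "survival"]).to_csv(
            expected, index=False
        )
        written += [data, expected]
    elif kind in ("table1", "nph"):
        config = ScenarioConfig(
            model="PH" if kind == "table1" else "NPH",
            beta=math.log(2.0),
            q=0.5,
            n=1000,
            reps=1,
            seed=seed,
        )
        sample = generate(config, replicate_rng(seed, 0))
        data = out_dir / f"{kind}.csv"
        write_cohort_csv(sample, data)
        times = config.tau * np.array([0.25, 0.5, 0.75, 1.0])
        truth = out_dir / f"{kind}_truth.csv"
        pd.DataFrame(
            {"time": times, "true_ar": np.atleast_1d(theoretical_ar(config, times))}
        ).to_csv(truth, index=False)
        written += [data, truth]
    else:
        raise ValueError("fixture kind must be 'toy', 'table1' or 'nph'")
    return written
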