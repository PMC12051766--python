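"""CSV schemas and provenance-stamped output files.

All tables are plain UTF-8 CSV with a header row and decimal points.  Output
files written by the pipeline carry a leading comment line with the package
version, the run seed and a hash of the run configuration, so any result
file can be traced to the exact run that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Iterable

import pandas as pd

from . import __version__
from .kinetics import TimeActivityCurve
from .stp import StpMeasurement

FLOAT_FORMAT = "%.10g"


def version_string() -> str:
    return f"istpdose-{__version__}"


def config_hash(obj: Any) -> str:
    """Short stable hash of a configuration object.

    Output-location fields are excluded so the hash identifies the
    scientific configuration: two runs differing only in where they write
    are the same run.
    """
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        obj = {k: v for k, v in obj.items() if k != "out_dir"}
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance_line(seed: int, cfg_hash: str) -> str:
    return f"# {version_string()} seed={seed} config_hash={cfg_hash}"


def write_csv(
    df: pd.DataFrame, path: str | Path, *, seed: int, cfg_hash: str
) -> None:
    """Write a provenance-stamped CSV with fixed float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_line(seed, cfg_hash) + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: Any, path: str | Path, *, seed: int, cfg_hash: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "provenance": {
            "version": version_string(),
            "seed": seed,
            "config_hash": cfg_hash,
        },
        **obj,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def curves_to_frame(curves: Iterable[TimeActivityCurve]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": c.patient_id,
            "cycle": c.cycle,
            "organ": c.organ,
            "t_hours": t,
            "activity_MBq": a,
        }
        for c in curves
        for t, a in zip(c.times_hours, c.activities_MBq)
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "cycle", "organ", "t_hours", "activity_MBq"]
    )


def frame_to_curves(df: pd.DataFrame) -> list[TimeActivityCurve]:
    """Assemble curves from the long cohort CSV schema."""
    required = {"patient_id", "cycle", "organ", "t_hours", "activity_MBq"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    curves = []
    for (pid, cycle, organ), grp in df.groupby(
        ["patient_id", "cycle", "organ"], sort=True
    ):
        grp = grp.sort_values("t_hours")
        curves.append(
            TimeActivityCurve(
                patient_id=str(pid),
                cycle=int(cycle),
                organ=str(organ),
                times_hours=tuple(grp["t_hours"].astype(float)),
                activities_MBq=tuple(grp["activity_MBq"].astype(float)),
            )
        )
    return curves


def read_curves(path: str | Path) -> list[TimeActivityCurve]:
    return frame_to_curves(read_csv(path))


def read_measurements(path: str | Path) -> list[StpMeasurement]:
    """Read single-time-point measurements (patient_id, cycle, organ, t_sc_hours, activity_MBq)."""
    df = read_csv(path)
    required = {"patient_id", "cycle", "organ", "t_sc_hours", "activity_MBq"}
    if not required.issubset(df.columns):
        raise ValueError(f"measurement table must have columns {sorted(required)}")
    return [
        StpMeasurement(
            patient_id=str(r.patient_id),
            cycle=int(r.cycle),
            organ=str(r.organ),
            t_sc_hours=float(r.t_sc_hours),
            activity_MBq=float(r.activity_MBq),
        )
        for r in df.itertuples()
    ]
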