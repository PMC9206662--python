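"""Result serialization: run CSVs with JSON metadata sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunManifest
from .simulator import RunResult


def sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json")


def write_run(result: RunResult, path: str | Path, seed: int | None = None) -> Path:
    """Write a scenario run as CSV plus a JSON metadata sidecar.

    The CSV holds one row per output time with a commented header
    documenting the columns; the sidecar records the full parameter
    set, scenario, seed, spin-up diagnostics, conservation residuals
    and the output digest. Reading the pair back reproduces the arrays
    to full precision.
    """
    path = Path(path)
    df = result.to_dataframe()
    header = (
        "# siclimate scenario run\n"
        "# time_yr: model time; concentrations mol m^-3; fluxes Tmol yr^-1;\n"
        "# temp_anomaly degC relative to the spin-up state; d13c permil VPDB\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.12g")
    meta = {
        "params": result.params.to_dict(),
        "scenario": dataclasses.asdict(result.scenario),
        "dynamic_rw": result.dynamic_rw,
        "seed": seed,
        "spinup_pco2": result.spinup_pco2,
        "accepted_spinup": bool(result.accepted_spinup),
        "conservation": {
            "carbon": result.conservation_c,
            "silicon": result.conservation_si,
            "carbon13": result.conservation_c13,
        },
    }
    manifest = RunManifest(config=meta, seed=seed)
    manifest.add_output(path)
    manifest.write(sidecar_path(path))
    return path


def read_run(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a run CSV and its sidecar back."""
    df = pd.read_csv(path, comment="#")
    meta_file = sidecar_path(path)
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    return df, meta


def write_table(df: pd.DataFrame, path: str | Path, description: str = "") -> Path:
    """Write a tidy analysis table with an optional commented header."""
    path = Path(path)
    with open(path, "w") as fh:
        if description:
            for line in description.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.10g")
    return path


def write_ensemble_outputs(
    summary: dict, out_dir: str | Path, trace: pd.DataFrame | None = None,
    seed: int | None = None, extra_meta: dict | None = None,
) -> Path:
    """Write envelope CSVs, the acceptance log and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for var, env in summary["envelopes"].items():
        f = out / f"envelope_{var}.csv"
        env.to_csv(f, index=False, float_format="%.10g")
        written.append(f)
    if "success_by_duration" in summary:
        f = out / "success_by_duration.csv"
        summary["success_by_duration"].to_csv(f, index=False)
        written.append(f)
    if trace is not None:
        f = out / "acceptance_log.csv"
        trace.to_csv(f, index=False)
        written.append(f)
    manifest = RunManifest(config=extra_meta or {}, seed=seed)
    for f in written:
        manifest.add_output(f)
    manifest.write(out / "manifest.json")
    return out


def ensure_finite(df: pd.DataFrame, columns: list[str]) -> None:
    for col in columns:
        if not np.all(np.isfinite(df[col].to_numpy())):
            raise ValueError(f"non-finite values in column {col!r}")
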