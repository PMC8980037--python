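"""CSV/JSON serialization of experiment records, results and datasets.

All on-disk formats are plain text: one CSV per trace or curve with the
experimental condition carried in columns (conc_uM, nacl_mM, adenosine_mM,
temperature_C), plus a JSON manifest tying a multi-modality dataset
together.  Numeric values round-trip at full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibrium import BindingIsotherm, DialysisMeasurement
from .errors import DataError
from .global_fit import Dataset, UnwindingRateRecord
from .model_core import ExperimentalCondition, ModelParameters
from .transients import KobsCurve, StoppedFlowTrace
from .tweezers import ContourTrace, Pause, TweezersTrace
from .unwinding import UnwindingTrace

__all__ = [
    "condition_columns",
    "save_isotherm",
    "load_isotherm",
    "save_transients",
    "load_transients",
    "save_kobs_curve",
    "load_kobs_curve",
    "save_unwinding_traces",
    "load_unwinding_traces",
    "save_tweezers_trace",
    "load_tweezers_trace",
    "save_contour_trace",
    "save_pauses",
    "write_dataset",
    "load_dataset",
    "save_params",
    "load_params",
]

_COND_COLS = ("nacl_mM", "adenosine_mM", "temperature_C")


def condition_columns(cond: ExperimentalCondition) -> dict:
    return {
        "nacl_mM": cond.nacl,
        "adenosine_mM": cond.adenosine,
        "temperature_C": cond.temperature,
    }


def _condition_from_row(row, ligand: float = 0.0) -> ExperimentalCondition:
    return ExperimentalCondition(
        ligand_conc=float(ligand),
        nacl=float(row["nacl_mM"]),
        adenosine=float(row["adenosine_mM"]),
        temperature=float(row["temperature_C"]),
    )


def save_isotherm(iso: BindingIsotherm, path) -> None:
    df = pd.DataFrame({"conc_uM": iso.conc, "signal": iso.signal})
    if iso.sem is not None:
        df["sem"] = iso.sem
    for k, v in condition_columns(iso.condition).items():
        df[k] = v
    df.to_csv(path, index=False)


def load_isotherm(path) -> BindingIsotherm:
    df = pd.read_csv(path)
    for col in ("conc_uM", "signal"):
        if col not in df:
            raise DataError(f"isotherm file {path} lacks column {col!r}")
    sem = df["sem"].to_numpy() if "sem" in df else None
    cond = _condition_from_row(df.iloc[0]) if set(_COND_COLS) <= set(df) else ExperimentalCondition()
    return BindingIsotherm(df["conc_uM"].to_numpy(), df["signal"].to_numpy(), sem, cond)


def save_transients(traces: list[StoppedFlowTrace], path) -> None:
    """Long format: trace_id, time_s, signal, conc_uM, dead_time_s + condition."""
    frames = []
    for i, tr in enumerate(traces):
        df = pd.DataFrame({"trace_id": i, "time_s": tr.time, "signal": tr.signal})
        df["conc_uM"] = tr.conc
        df["dead_time_s"] = tr.dead_time
        for k, v in condition_columns(tr.condition).items():
            df[k] = v
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_transients(path) -> list[StoppedFlowTrace]:
    df = pd.read_csv(path)
    traces = []
    for _, grp in df.groupby("trace_id", sort=True):
        row = grp.iloc[0]
        traces.append(
            StoppedFlowTrace(
                grp["time_s"].to_numpy(),
                grp["signal"].to_numpy(),
                float(row["conc_uM"]),
                float(row.get("dead_time_s", 0.001)),
                _condition_from_row(row, ligand=row["conc_uM"])
                if set(_COND_COLS) <= set(df)
                else ExperimentalCondition(ligand_conc=float(row["conc_uM"])),
            )
        )
    return traces


def save_kobs_curve(curve: KobsCurve, path) -> None:
    df = pd.DataFrame({"conc_uM": curve.conc, "k_obs_per_s": curve.k_obs})
    if curve.stderr is not None:
        df["stderr"] = curve.stderr
    df["phase"] = curve.phase
    for k, v in condition_columns(curve.condition).items():
        df[k] = v
    df.to_csv(path, index=False)


def load_kobs_curve(path) -> KobsCurve:
    df = pd.read_csv(path)
    row = df.iloc[0]
    return KobsCurve(
        df["conc_uM"].to_numpy(),
        df["k_obs_per_s"].to_numpy(),
        df["stderr"].to_numpy() if "stderr" in df else None,
        _condition_from_row(row) if set(_COND_COLS) <= set(df) else ExperimentalCondition(),
        str(row.get("phase", "fast")),
    )


def save_unwinding_traces(traces: list[UnwindingTrace], path) -> None:
    frames = []
    for i, tr in enumerate(traces):
        df = pd.DataFrame({"trace_id": i, "time_s": tr.time, "signal": tr.signal})
        df["length_bp"] = tr.length_bp
        df["modality"] = tr.modality
        df["conc_uM"] = tr.condition.ligand_conc
        for k, v in condition_columns(tr.condition).items():
            df[k] = v
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_unwinding_traces(path) -> list[UnwindingTrace]:
    df = pd.read_csv(path)
    out = []
    for _, grp in df.groupby("trace_id", sort=True):
        row = grp.iloc[0]
        cond = (
            _condition_from_row(row, ligand=row.get("conc_uM", 0.0))
            if set(_COND_COLS) <= set(df)
            else ExperimentalCondition()
        )
        out.append(
            UnwindingTrace(
                grp["time_s"].to_numpy(),
                grp["signal"].to_numpy(),
                float(row["length_bp"]),
                cond,
                str(row.get("modality", "FA")),
            )
        )
    return out


def save_tweezers_trace(trace: TweezersTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "extension_nm": trace.extension, "force_pN": trace.force}
    ).to_csv(path, index=False)


def load_tweezers_trace(path) -> TweezersTrace:
    df = pd.read_csv(path)
    return TweezersTrace(
        df["time_s"].to_numpy(), df["extension_nm"].to_numpy(), df["force_pN"].to_numpy()
    )


def save_contour_trace(trace: ContourTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "contour_bp": trace.contour, "force_pN": trace.force}
    ).to_csv(path, index=False)


def save_pauses(pauses: list[Pause], path) -> None:
    pd.DataFrame(
        {
            "start_s": [p.start for p in pauses],
            "end_s": [p.end for p in pauses],
            "position_bp": [p.position for p in pauses],
        }
    ).to_csv(path, index=False)


def save_params(params: ModelParameters, path) -> None:
    Path(path).write_text(params.to_json())


def load_params(path) -> ModelParameters:
    return ModelParameters.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Dataset manifest
# ---------------------------------------------------------------------------

def write_dataset(dataset: Dataset, directory) -> Path:
    """Write one CSV per record plus a manifest.json; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"isotherms": [], "dialysis": [], "kobs_curves": [], "unwinding": []}
    for i, (iso, weights) in enumerate(dataset.isotherms):
        name = f"isotherm_{i:02d}.csv"
        save_isotherm(iso, directory / name)
        manifest["isotherms"].append({"file": name, "signal_weights": list(weights)})
    for m, stderr in dataset.dialysis:
        manifest["dialysis"].append(
            {
                "ligand_initial_uM": m.ligand_initial,
                "ligand_final_uM": m.ligand_final,
                "protein_uM": m.protein,
                "stderr": stderr,
            }
        )
    for i, curve in enumerate(dataset.kobs_curves):
        name = f"kobs_{i:02d}.csv"
        save_kobs_curve(curve, directory / name)
        manifest["kobs_curves"].append({"file": name})
    for rec in dataset.unwinding:
        manifest["unwinding"].append(
            {
                "rate_bp_s": rec.rate,
                "stderr": rec.stderr,
                "conc_uM": rec.condition.ligand_conc,
                **condition_columns(rec.condition),
            }
        )
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_dataset(directory) -> Dataset:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    ds = Dataset()
    for entry in manifest["isotherms"]:
        iso = load_isotherm(directory / entry["file"])
        ds.isotherms.append((iso, tuple(entry["signal_weights"])))
    for entry in manifest["dialysis"]:
        ds.dialysis.append(
            (
                DialysisMeasurement(
                    entry["ligand_initial_uM"], entry["ligand_final_uM"], entry["protein_uM"]
                ),
                entry["stderr"],
            )
        )
    for entry in manifest["kobs_curves"]:
        ds.kobs_curves.append(load_kobs_curve(directory / entry["file"]))
    for entry in manifest["unwinding"]:
        ds.unwinding.append(
            UnwindingRateRecord(
                entry["rate_bp_s"],
                entry["stderr"],
                ExperimentalCondition(
                    ligand_conc=entry["conc_uM"],
                    nacl=entry["nacl_mM"],
                    adenosine=entry["adenosine_mM"],
                    temperature=entry["temperature_C"],
                ),
            )
        )
    return ds
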