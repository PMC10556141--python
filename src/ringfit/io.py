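"""Readers and writers for the package's plain-text file schemas.

All on-disk formats are CSV (data) and JSON (truth sidecars, fit
reports). Column names are fixed per schema:

titration        step, x_nt_per_decamer, F_raw, V_mL, f_photobleach
mp events        mass_kDa   (single column; or ``contrast`` before calibration)
mp standards     name, mass_kDa, contrast
hdx uptake       peptide_id, start, end, sequence, state, timepoint_h, uptake_Da, sem
hdx bimodal      centroid_Da, intensity
fret trace       I_D, I_A   (one file per trace)
fret manifest    trace_id, path, frame_time_s

Writers pair each synthetic dataset with a ``<stem>.truth.json``
sidecar holding the generator's ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import TitrationSeries
from .corrections import CorrectionLedger, correct_fluorescence, normalized_quenching
from .hdx import UPTAKE_COLUMNS
from .smfret import FretTrace
from .stoichiometry import MassEventSet
from .synthgen import HdxBimodalDataset, TitrationDataset

TITRATION_COLUMNS = ["step", "x_nt_per_decamer", "F_raw", "V_mL", "f_photobleach"]


class SchemaError(ValueError):
    """A file does not match its documented column schema."""


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing columns {missing}; expected header {list(columns)}"
        )


# -- titrations -------------------------------------------------------------

def load_titration_csv(path, protein_nM: float = 50.0) -> TitrationSeries:
    """Read a raw titration table, apply the correction algebra, return a series.

    The raw fluorescence is corrected for dilution and photobleaching
    from the per-step ledger columns, converted to normalized quenching
    against the zero-ligand point, and validated (strictly increasing
    ligand axis). The raw table is kept on ``series.meta['raw']``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require(df, TITRATION_COLUMNS, path)
    x = df["x_nt_per_decamer"].to_numpy(dtype=float)
    if np.any(np.diff(x) <= 0):
        raise SchemaError(f"{path}: x_nt_per_decamer must be strictly increasing")
    ledger = CorrectionLedger(
        F_raw=df["F_raw"].to_numpy(dtype=float),
        V=df["V_mL"].to_numpy(dtype=float),
        f=df["f_photobleach"].to_numpy(dtype=float),
    )
    F_corr = correct_fluorescence(ledger)
    signal = normalized_quenching(F_corr[0], F_corr)
    sem = df["sem"].to_numpy(dtype=float) if "sem" in df.columns else None
    return TitrationSeries(
        x=x, signal=signal, sem=sem, protein_nM=protein_nM,
        meta={"path": str(path), "raw": df},
    )


def write_titration_csv(dataset: TitrationDataset, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "step": np.arange(len(dataset.series)),
        "x_nt_per_decamer": dataset.series.x,
        "F_raw": dataset.raw,
        "V_mL": dataset.ledger.V,
        "f_photobleach": dataset.ledger.f,
    })
    df.to_csv(path, index=False)
    _write_truth(path, dataset.truth_dict())
    return path


# -- mass photometry --------------------------------------------------------

def load_mp_events_csv(path) -> MassEventSet:
    path = Path(path)
    df = pd.read_csv(path)
    if "mass_kDa" in df.columns:
        return MassEventSet(df["mass_kDa"].to_numpy(dtype=float), calibration_applied=True)
    if "contrast" in df.columns:
        return MassEventSet(df["contrast"].to_numpy(dtype=float), calibration_applied=False)
    raise SchemaError(f"{path}: expected a 'mass_kDa' or 'contrast' column")


def write_mp_events_csv(events: MassEventSet, path, truth: dict | None = None) -> Path:
    path = Path(path)
    col = "mass_kDa" if events.calibration_applied else "contrast"
    pd.DataFrame({col: events.events}).to_csv(path, index=False)
    if truth is not None:
        _write_truth(path, truth)
    return path


def load_mp_standards_csv(path):
    path = Path(path)
    df = pd.read_csv(path)
    _require(df, ["name", "mass_kDa", "contrast"], path)
    return list(df[["name", "mass_kDa", "contrast"]].itertuples(index=False, name=None))


# -- HDX --------------------------------------------------------------------

def load_hdx_uptake_csv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require(df, UPTAKE_COLUMNS, path)
    return df


def write_hdx_uptake_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, columns=UPTAKE_COLUMNS)
    return path


def load_hdx_bimodal_csv(path):
    path = Path(path)
    df = pd.read_csv(path)
    _require(df, ["centroid_Da", "intensity"], path)
    return df["centroid_Da"].to_numpy(dtype=float), df["intensity"].to_numpy(dtype=float)


def write_hdx_bimodal_csv(dataset: HdxBimodalDataset, path) -> Path:
    path = Path(path)
    pd.DataFrame({"centroid_Da": dataset.centers, "intensity": dataset.intensity}
                 ).to_csv(path, index=False)
    _write_truth(path, dataset.truth)
    return path


# -- smFRET -----------------------------------------------------------------

def write_fret_traces(traces, directory, stem: str = "trace") -> Path:
    """Write one two-column CSV per trace plus a manifest CSV.

    Returns the manifest path. Latent state paths, when present, go to
    the truth sidecar of each trace file.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, t in enumerate(traces):
        p = directory / f"{stem}_{i:04d}.csv"
        pd.DataFrame({"I_D": t.i_d, "I_A": t.i_a}).to_csv(p, index=False)
        if t.latent_states is not None:
            _write_truth(p, {"latent_states": t.latent_states.tolist(), **t.meta})
        rows.append({"trace_id": i, "path": p.name, "frame_time_s": t.frame_time})
    manifest = directory / f"{stem}_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_fret_traces(manifest_path, crosstalk: float = 0.0,
                     cross_excitation: float = 0.0) -> list[FretTrace]:
    manifest_path = Path(manifest_path)
    mf = pd.read_csv(manifest_path)
    _require(mf, ["trace_id", "path", "frame_time_s"], manifest_path)
    traces = []
    for _, row in mf.iterrows():
        p = manifest_path.parent / row["path"]
        df = pd.read_csv(p)
        _require(df, ["I_D", "I_A"], p)
        traces.append(FretTrace(
            i_d=df["I_D"].to_numpy(dtype=float),
            i_a=df["I_A"].to_numpy(dtype=float),
            frame_time=float(row["frame_time_s"]),
            crosstalk=crosstalk, cross_excitation=cross_excitation,
        ))
    return traces


# -- sidecars / JSON --------------------------------------------------------

def _write_truth(data_path: Path, truth: dict) -> Path:
    sidecar = data_path.with_suffix(".truth.json")
    sidecar.write_text(json.dumps(truth, indent=2, default=_jsonable))
    return sidecar


def load_truth(data_path) -> dict:
    return json.loads(Path(data_path).with_suffix(".truth.json").read_text())


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_jsonable))
    return path
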