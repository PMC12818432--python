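"""CSV/TOML/JSON interchange between the generators, fits and CLI.

All tabular data crosses the pipeline as plain CSV with fixed column sets;
validation errors name the offending file and column so CLI messages stay
actionable.  Configuration files are TOML; manifests are JSON.
"""

from __future__ import annotations

import json
import tomllib

import numpy as np
import pandas as pd

from .fitting import CestProfile, CpmgDispersion, ResidueDataset
from .populations_affinity import PeakVolumePair, TitrationSeries
from .relaxation_basic import DecaySeries

CEST_COLUMNS = ["residue_id", "offset_hz", "intensity", "intensity_ref",
                "sigma"]
CPMG_COLUMNS = ["residue_id", "ncyc", "intensity", "sigma"]
TITRATION_COLUMNS = ["point_index", "protein_total_M", "ligand_total_M",
                     "residue_id", "dH_ppm", "dN_ppm", "sigma"]
VOLUME_COLUMNS = ["residue_id", "v_open", "v_closed", "sigma_open",
                  "sigma_closed"]
DECAY_COLUMNS = ["residue_id", "delay_s", "intensity", "sigma"]


def _read_checked(path, columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (OSError, ValueError, pd.errors.ParserError) as err:
        raise ValueError(f"{path}: cannot parse CSV: {err}") from err
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {', '.join(missing)}")
    for col in columns:
        if col in ("residue_id",):
            continue
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header + 1-based
            raise ValueError(
                f"{path}: non-numeric value in column '{col}' at line {line}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cest_table(path) -> list:
    """CSV -> list of ResidueDataset with CEST profiles."""
    df = _read_checked(path, CEST_COLUMNS)
    out = []
    for rid, sub in df.groupby("residue_id", sort=False):
        sub = sub.sort_values("offset_hz")
        out.append(ResidueDataset(str(rid), cest=CestProfile(
            sub["offset_hz"].to_numpy(float),
            sub["intensity"].to_numpy(float),
            sub["intensity_ref"].to_numpy(float),
            sub["sigma"].to_numpy(float))))
    return out


def read_cpmg_table(path) -> list:
    """CSV -> list of ResidueDataset with CPMG dispersions."""
    df = _read_checked(path, CPMG_COLUMNS)
    out = []
    for rid, sub in df.groupby("residue_id", sort=False):
        out.append(ResidueDataset(str(rid), cpmg=CpmgDispersion(
            sub["ncyc"].to_numpy(int),
            sub["intensity"].to_numpy(float),
            sub["sigma"].to_numpy(float))))
    return out


def read_titration_table(path) -> TitrationSeries:
    """CSV -> TitrationSeries (shared schedule, per-residue shifts)."""
    df = _read_checked(path, TITRATION_COLUMNS)
    df = df.sort_values("point_index")
    first = None
    shifts = {}
    sigma = float(df["sigma"].iloc[0])
    for rid, sub in df.groupby("residue_id", sort=False):
        sched = (sub["protein_total_M"].to_numpy(float),
                 sub["ligand_total_M"].to_numpy(float))
        if first is None:
            first = sched
        elif not (np.allclose(first[0], sched[0])
                  and np.allclose(first[1], sched[1])):
            raise ValueError(
                f"{path}: residue {rid} has a different concentration "
                "schedule (columns protein_total_M/ligand_total_M)")
        shifts[str(rid)] = (sub["dH_ppm"].to_numpy(float),
                            sub["dN_ppm"].to_numpy(float))
    return TitrationSeries(protein_total=first[0], ligand_total=first[1],
                           shifts=shifts, sigma=sigma)


def read_volume_table(path) -> list:
    """CSV -> list of PeakVolumePair."""
    df = _read_checked(path, VOLUME_COLUMNS)
    return [PeakVolumePair(str(r.residue_id), float(r.v_open),
                           float(r.v_closed), float(r.sigma_open),
                           float(r.sigma_closed))
            for r in df.itertuples()]


def read_decay_table(path) -> list:
    """CSV -> list of DecaySeries."""
    df = _read_checked(path, DECAY_COLUMNS)
    return [DecaySeries(str(rid), sub["delay_s"].to_numpy(float),
                        sub["intensity"].to_numpy(float),
                        sub["sigma"].to_numpy(float))
            for rid, sub in df.groupby("residue_id", sort=False)]


def read_config(path) -> dict:
    """TOML config file -> dict."""
    try:
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    except tomllib.TOMLDecodeError as err:
        raise ValueError(f"{path}: invalid TOML: {err}") from err


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_manifest(data: dict, path) -> None:
    """Write a JSON manifest (seed, truth, parameters) deterministically."""
    with open(path, "w") as fh:
        json.dump(_jsonable(data), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
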