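"""CSV/JSON/YAML input-output and run manifests.

Two documented CSV schemas are accepted for measured series:

* raw CT:        ``time_hr, tumor_hu, aorta_hu, volume_mm3``
  (a calibration factor in HU per mgI cm^-3 is required to interpret it)
* pre-converted: ``time_hr, tumor_mgI, blood_mgI`` (optional ``volume_mm3``)

Single curves use ``time_hr, conc_mgI_per_cm3``.  All writers use a
fixed float format so identical inputs reproduce identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import AccumulationCurve
from .imaging import DEFAULT_HEMATOCRIT, ImagingSeries
from .pressure import PressureField

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "read_imaging_csv",
    "write_pressure_csv",
    "write_field_csv",
    "write_json",
    "write_run_manifest",
    "SchemaError",
]

logger = logging.getLogger(__name__)

_HU_COLUMNS = {"time_hr", "tumor_hu", "aorta_hu", "volume_mm3"}
_MGI_COLUMNS = {"time_hr", "tumor_mgI", "blood_mgI"}
_CURVE_COLUMNS = {"time_hr", "conc_mgI_per_cm3"}


class SchemaError(ValueError):
    """A CSV file does not match any documented schema."""


def _load_sorted(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "time_hr" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'time_hr'")
    if not df["time_hr"].is_monotonic_increasing:
        logger.warning("%s: rows not time-ordered; sorting", path)
        df = df.sort_values("time_hr", kind="stable").reset_index(drop=True)
    if df["time_hr"].duplicated().any():
        raise SchemaError(f"{path}: duplicate time points")
    return df


def read_imaging_csv(
    path,
    calibration: float | None = None,
    hematocrit: float = DEFAULT_HEMATOCRIT,
    species_label: str = "",
) -> ImagingSeries:
    """Read an imaging series in either documented schema.

    HU files need ``calibration`` (HU per mgI cm^-3); files already in
    mgI cm^-3 do not.  Rows are sorted by time with a warning if they
    arrive shuffled.
    """
    df = _load_sorted(path)
    cols = set(df.columns)
    if _HU_COLUMNS <= cols:
        if calibration is None:
            raise SchemaError(
                f"{path}: HU schema requires a calibration factor "
                "(HU per mgI cm^-3)"
            )
        return ImagingSeries(
            times=df["time_hr"].to_numpy(),
            tumor=df["tumor_hu"].to_numpy(),
            blood=df["aorta_hu"].to_numpy(),
            volume_mm3=df["volume_mm3"].to_numpy(),
            units="HU",
            calibration=calibration,
            hematocrit=hematocrit,
            species_label=species_label,
        )
    if _MGI_COLUMNS <= cols:
        vol = df["volume_mm3"].to_numpy() if "volume_mm3" in cols else None
        return ImagingSeries(
            times=df["time_hr"].to_numpy(),
            tumor=df["tumor_mgI"].to_numpy(),
            blood=df["blood_mgI"].to_numpy(),
            volume_mm3=vol,
            units="mgI",
            hematocrit=hematocrit,
            species_label=species_label,
        )
    missing_hu = sorted(_HU_COLUMNS - cols)
    missing_mgi = sorted(_MGI_COLUMNS - cols)
    raise SchemaError(
        f"{path}: columns {sorted(cols)} match no schema "
        f"(HU schema missing {missing_hu}; mgI schema missing {missing_mgi})"
    )


def read_curve_csv(path, basis: str = "interstitial") -> AccumulationCurve:
    """Read a single concentration curve: ``time_hr, conc_mgI_per_cm3``."""
    df = _load_sorted(path)
    missing = sorted(_CURVE_COLUMNS - set(df.columns))
    if missing:
        raise SchemaError(f"{path}: curve schema missing column(s) {missing}")
    return AccumulationCurve(
        times=df["time_hr"].to_numpy(),
        conc=df["conc_mgI_per_cm3"].to_numpy(),
        basis=basis,
    )


def write_curve_csv(curve: AccumulationCurve, path) -> None:
    curve.to_dataframe().to_csv(path, index=False, float_format="%.12g")


def write_pressure_csv(field: PressureField, path) -> None:
    """Columns: r_cm, p_mmHg, u_cm_per_s."""
    field.to_dataframe().to_csv(path, index=False, float_format="%.12g")


def write_field_csv(field, path) -> None:
    """Long-format concentration snapshots: time_hr, r_cm, c_mgI_per_cm3."""
    field.to_dataframe().to_csv(path, index=False, float_format="%.12g")


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def read_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def config_hash(config: dict) -> str:
    """Stable hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=_jsonify)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_run_manifest(out_path, command: str, config: dict, seed, inputs) -> Path:
    """Write a reproducibility manifest next to an output artifact."""
    out_path = Path(out_path)
    manifest = {
        "command": command,
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "inputs": [str(p) for p in inputs],
        "versions": {
            "ittm": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_path.with_name(out_path.name + ".manifest.json")
    write_json(manifest, path)
    return path
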