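"""Reader/writer for the tabular trial-dataset dialect and config files.

Datasets are plain CSV in a NONMEM-like event/observation layout: one row per
dose event, circuit event or observation.  ``DVID`` codes the specimen (1-5:
pre-filter plasma, post-filter plasma, effluent, cumulated-effluent
concentration, cumulated-effluent volume); circuit settings travel as
covariate columns so a dataset is self-contained for estimation.  Units are
fixed at mg, L, h (flow columns in L/h); a leading ``# flow_units=...``
comment line declares mL/min or mL/h inputs, which are converted on read.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .core import RRTSettings

__all__ = [
    "COLUMNS",
    "REQUIRED_COLUMNS",
    "FLOW_COLUMNS",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "settings_from_row",
    "load_config",
    "save_config",
]

COLUMNS = [
    "ID", "TIME", "EVID", "MDV", "AMT", "RATE", "DVID", "DV", "BLQ", "OCC",
    "QB", "QD", "QRFPRE", "QRFPOST", "QFRR", "HCT", "RBCR",
    "FILTCHG", "BAGCHG", "RRTON",
]
REQUIRED_COLUMNS = ["ID", "TIME", "EVID", "MDV", "AMT", "DV", "DVID"]
FLOW_COLUMNS = ["QB", "QD", "QRFPRE", "QRFPOST", "QFRR"]

_FLOW_FACTORS = {"L/h": 1.0, "mL/h": 1e-3, "mL/min": 0.06}


class DatasetError(ValueError):
    """Malformed or inconsistent dataset content."""


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a dataset table.

    Checks required columns, numeric content, non-negative times, DV sign
    (negative observations only allowed when flagged BLQ) and returns a copy
    sorted by subject and time with BLQ rows marked missing (``MDV=1``) so
    they are excluded from likelihoods by default.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"dataset is missing required column(s): {', '.join(missing)}")
    out = df.copy()
    for col in ("TIME", "EVID", "MDV", "AMT", "DV", "DVID"):
        try:
            out[col] = pd.to_numeric(out[col])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(out[col], errors="coerce")
            row = int(bad[bad.isna() & out[col].notna()].index[0])
            raise DatasetError(f"malformed numeric cell in column {col}, row {row}") from exc
    if (out["TIME"] < 0).any():
        raise DatasetError("negative TIME values")
    if "BLQ" not in out.columns:
        out["BLQ"] = 0
    obs = out["EVID"] == 0
    neg = obs & (out["DV"] < 0) & (out["BLQ"] != 1)
    if neg.any():
        raise DatasetError(
            f"negative DV without BLQ flag at row(s) {list(out.index[neg])[:5]}"
        )
    if "OCC" not in out.columns:
        # occasion counter disambiguates repeated (ID, TIME, DVID) observations
        out["OCC"] = out.groupby(["ID", "TIME", "DVID", "EVID"]).cumcount() + 1
    out.loc[out["BLQ"] == 1, "MDV"] = 1
    out = out.sort_values(["ID", "TIME"], kind="stable").reset_index(drop=True)
    return out


def read_dataset(path: Union[str, Path]) -> pd.DataFrame:
    """Read a dataset CSV, applying any declared flow-unit conversion.

    Unknown columns are preserved as covariates.
    """
    path = Path(path)
    flow_factor = 1.0
    with open(path, "r") as fh:
        first = fh.readline()
        if first.startswith("#"):
            text = fh.read()
            for token in first.lstrip("#").strip().split():
                if token.startswith("flow_units="):
                    unit = token.split("=", 1)[1]
                    if unit not in _FLOW_FACTORS:
                        raise DatasetError(f"unknown flow unit {unit!r} in header")
                    flow_factor = _FLOW_FACTORS[unit]
        else:
            text = first + fh.read()
    df = pd.read_csv(_io.StringIO(text))
    if flow_factor != 1.0:
        for col in FLOW_COLUMNS:
            if col in df.columns:
                df[col] = df[col] * flow_factor
    return validate_dataset(df)


def write_dataset(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a dataset with deterministic column order and formatting."""
    path = Path(path)
    cols = [c for c in COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    with open(path, "w") as fh:
        fh.write("# flow_units=L/h\n")
        df[cols].to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")


def settings_from_row(row) -> RRTSettings:
    """Reconstruct circuit settings from a dataset row's covariate columns."""

    def get(col: str, default: float = 0.0) -> float:
        val = row.get(col, default) if hasattr(row, "get") else getattr(row, col, default)
        return float(val) if pd.notna(val) else default

    return RRTSettings(
        Q_blood=get("QB"),
        Hct=get("HCT"),
        Q_dial=get("QD"),
        Q_RF_pre=get("QRFPRE"),
        Q_RF_post=get("QRFPOST"),
        Q_FRR=get("QFRR"),
        c_rbc_ratio=get("RBCR"),
        postfilter_sampled_before_RF=bool(get("POSTPRERF", 0.0)),
    )


def load_config(path: Union[str, Path]) -> dict:
    with open(path, "r") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DatasetError("config file must contain a mapping")
    return cfg


def save_config(cfg: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
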