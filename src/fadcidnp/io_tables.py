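"""Tabular text I/O and parameter files.

All interchange files are tab-separated text with '#'-prefixed metadata
header lines ("# key: value"), fields stored in tesla.  Parameter files are
flat "key = value" text mirroring the published model-parameter table.
"""

from __future__ import annotations

import io
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .nmrd_fit import NMRDCurve
from .shuttle_deconv import TransferProfile
from .spin_sim import (
    BiradicalModel,
    BiradicalSpinParams,
    CIDNPCurve,
    ExchangeModel,
    KineticsRelaxationParams,
)

__all__ = [
    "read_table",
    "write_table",
    "read_cidnp_curve",
    "write_cidnp_curve",
    "read_nmrd_curves",
    "write_nmrd_curves",
    "read_transfer_profile",
    "write_transfer_profile",
    "parse_params",
    "format_params",
    "read_params",
    "write_params",
]


class SchemaError(ValueError):
    pass


def write_table(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    """Write a DataFrame as TSV with '#' metadata header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_table(path, required: list[str] | None = None) -> tuple[pd.DataFrame, dict]:
    """Read a '#'-headed TSV; returns (DataFrame, metadata dict).

    Numeric columns are validated cell by cell: a malformed value raises a
    SchemaError naming the file line.  Decimal parsing is locale independent
    (dot only).  Missing required columns raise a SchemaError naming them.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    body_start: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    k, _, v = stripped.partition(":")
                    meta[k.strip()] = v.strip()
                continue
            if line.strip() == "":
                continue
            body_lines.append(line)
            body_start.append(lineno)
    if not body_lines:
        raise SchemaError(f"{path}: no table body")
    df = pd.read_csv(io.StringIO("".join(body_lines)), sep="\t", dtype=str)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}; have {list(df.columns)}")
    # convert columns that look numeric; report the offending line on failure
    for col in df.columns:
        vals = df[col]
        try:
            df[col] = vals.astype(float)
        except (TypeError, ValueError):
            conv = pd.to_numeric(vals, errors="coerce")
            n_bad = conv.isna() & vals.notna()
            if n_bad.any() and (~n_bad).sum() > 0 and conv.notna().sum() > 0:
                row = int(np.flatnonzero(n_bad)[0])
                raise SchemaError(
                    f"{path}, line {body_start[row + 1]}: malformed numeric value "
                    f"{vals.iloc[row]!r} in column {col!r}"
                ) from None
            # genuinely non-numeric column (labels): keep as str
    return df, meta


# -- domain-object round trips ------------------------------------------------


def write_cidnp_curve(path, curve: CIDNPCurve) -> None:
    df = pd.DataFrame({"field_T": curve.field_T, "polarization": curve.amplitude})
    if curve.uncertainty is not None:
        df["uncertainty"] = curve.uncertainty
    df["nucleus"] = curve.nucleus
    write_table(path, df, meta=curve.meta)


def read_cidnp_curve(path) -> CIDNPCurve:
    df, meta = read_table(path, required=["field_T", "polarization"])
    unc = df["uncertainty"].to_numpy() if "uncertainty" in df.columns else None
    nucleus = str(df["nucleus"].iloc[0]) if "nucleus" in df.columns else "A8"
    return CIDNPCurve(
        df["field_T"].to_numpy(), df["polarization"].to_numpy(), uncertainty=unc,
        nucleus=nucleus, meta=meta,
    )


def write_nmrd_curves(path, curves: list[NMRDCurve], meta: dict | None = None) -> None:
    rows = []
    for c in curves:
        for k in range(len(c.B)):
            rows.append(
                {
                    "proton": c.proton,
                    "B_T": c.B[k],
                    "T1_s": c.T1[k],
                    "T1_err_s": c.T1_err[k] if c.T1_err is not None else np.nan,
                }
            )
    write_table(path, pd.DataFrame(rows), meta=meta)


def read_nmrd_curves(path) -> list[NMRDCurve]:
    df, _ = read_table(path, required=["proton", "B_T", "T1_s"])
    out = []
    for proton, sub in df.groupby("proton", sort=False):
        sub = sub.sort_values("B_T")
        err = sub["T1_err_s"].to_numpy() if "T1_err_s" in sub.columns else None
        if err is not None and np.all(np.isnan(err)):
            err = None
        out.append(
            NMRDCurve(str(proton), sub["B_T"].to_numpy(), sub["T1_s"].to_numpy(), T1_err=err)
        )
    return out


def write_transfer_profile(path, profile: TransferProfile, meta: dict | None = None) -> None:
    write_table(path, pd.DataFrame({"t_s": profile.t, "B_T": profile.B}), meta=meta)


def read_transfer_profile(path) -> TransferProfile:
    df, _ = read_table(path, required=["t_s", "B_T"])
    return TransferProfile(df["t_s"].to_numpy(), df["B_T"].to_numpy())


# -- parameter files ----------------------------------------------------------

_SPIN_KEYS = {"ga", "gb", "A", "A_add", "n_add"}
_EXCH_KEYS = {"J0", "alpha", "convention", "r_contact"}
_KIN_KEYS = {"D", "G", "tau_u", "tau_rot", "kp", "ks"}


def parse_params(text: str) -> BiradicalModel:
    """Parse a flat 'key = value' parameter file into a BiradicalModel."""
    values: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, sep, val = line.partition("=")
        if not sep:
            raise SchemaError(f"line {lineno}: expected 'key = value', got {raw!r}")
        values[key.strip()] = val.strip()
    unknown = set(values) - _SPIN_KEYS - _EXCH_KEYS - _KIN_KEYS
    if unknown:
        raise SchemaError(f"unknown parameter keys {sorted(unknown)}")

    def build(cls, keys, casts):
        kwargs = {}
        for k in keys:
            if k in values:
                kwargs[k] = casts.get(k, float)(values[k])
        return cls(**kwargs)

    spins = build(BiradicalSpinParams, _SPIN_KEYS, {"n_add": int})
    exch = build(ExchangeModel, _EXCH_KEYS, {"convention": str})
    kin = build(KineticsRelaxationParams, _KIN_KEYS, {})
    return BiradicalModel(spins=spins, exchange=exch, kinetics=kin)


def format_params(model: BiradicalModel) -> str:
    lines = ["# biradical model parameters"]
    for block in (model.spins, model.exchange, model.kinetics):
        for k, v in asdict(block).items():
            lines.append(f"{k} = {v}")
    return "\n".join(lines) + "\n"


def read_params(path) -> BiradicalModel:
    return parse_params(Path(path).read_text())


def write_params(path, model: BiradicalModel) -> None:
    Path(path).write_text(format_params(model))
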