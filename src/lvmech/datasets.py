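"""Packaged reference tables: patient geometries and material parameters.

The geometry table holds best-fit 6-parameter shapes for 45 subjects in four
clinical groups (N normal, HYP hypertrophic, HF-NI / HF-I heart failure
without / with infarct) at two diastolic phases (BoD beginning of diastole,
EoD end of diastole).  The unloaded table holds stretch-conditioned unloaded
shapes for the same subjects at midwall fiber-stretch targets of 1.10
("lff10") and 1.15 ("lff15").  Angles are stored in degrees in the CSV files
and converted to radians when geometries are constructed.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .geometry import PARAM_NAMES, LVGeometry

__all__ = [
    "load_geometry_table",
    "load_unloaded_table",
    "load_group_stats",
    "geometry_from_row",
    "get_geometry",
    "population_stats",
    "GROUPS",
    "PHASES",
]

GROUPS = ("N", "HYP", "HF-NI", "HF-I")
PHASES = ("BoD", "EoD")


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("lvmech.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_geometry_table() -> pd.DataFrame:
    """Per-patient best-fit geometry parameters (45 subjects x 2 phases)."""
    df = _read_csv("geometry_table.csv")
    expected = {"id", "group", "phase", "R_b", "L", "Z", "H", "e", "psi0_deg"}
    if set(df.columns) != expected or df["id"].nunique() != 45:
        raise ValueError("packaged geometry table is corrupted")
    return df


def load_unloaded_table() -> pd.DataFrame:
    """Stretch-conditioned unloaded geometries (45 subjects x 2 targets)."""
    df = _read_csv("unloaded_table.csv")
    if df["id"].nunique() != 45 or set(df["target"]) != {"lff10", "lff15"}:
        raise ValueError("packaged unloaded table is corrupted")
    return df


def load_group_stats() -> pd.DataFrame:
    """Group-average geometry parameters (mean, sd) per phase."""
    return _read_csv("geometry_group_stats.csv")


def geometry_from_row(row) -> LVGeometry:
    """Build an :class:`LVGeometry` from a table row (psi0 in degrees)."""
    return LVGeometry(
        R_b=float(row["R_b"]),
        Z=float(row["Z"]),
        L=float(row["L"]),
        H=float(row["H"]),
        e=min(float(row["e"]), 1.0),
        psi0=float(np.deg2rad(row["psi0_deg"])),
    )


def get_geometry(patient_id: str, phase: str = "EoD") -> LVGeometry:
    """Look up one patient/phase geometry, e.g. ``get_geometry('HF-I-02')``."""
    df = load_geometry_table()
    sel = df[(df["id"] == patient_id) & (df["phase"] == phase)]
    if sel.empty:
        raise KeyError(f"no entry for id={patient_id!r}, phase={phase!r}")
    return geometry_from_row(sel.iloc[0])


def population_stats(group: str | None = None, phase: str = "BoD"):
    """Per-parameter (mean, sd) tuple of arrays in canonical order.

    ``group=None`` pools all 45 subjects of the requested phase (sd computed
    across patients); a named group returns the packaged group-average row.
    Angles are returned in radians.
    """
    if group is None:
        df = load_geometry_table()
        df = df[df["phase"] == phase].copy()
        df["psi0"] = np.deg2rad(df["psi0_deg"])
        cols = ["R_b", "Z", "L", "H", "e", "psi0"]
        return df[cols].mean().to_numpy(), df[cols].std(ddof=1).to_numpy()
    stats = load_group_stats()
    row = stats[(stats["group"] == group) & (stats["phase"] == phase)]
    if row.empty:
        raise KeyError(f"no stats for group={group!r}, phase={phase!r}")
    row = row.iloc[0]
    mean = np.array(
        [row[f"{p}_mean"] if p != "psi0" else np.deg2rad(row["psi0_deg_mean"])
         for p in PARAM_NAMES]
    )
    sd = np.array(
        [row[f"{p}_sd"] if p != "psi0" else np.deg2rad(row["psi0_deg_sd"])
         for p in PARAM_NAMES]
    )
    return mean, sd
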