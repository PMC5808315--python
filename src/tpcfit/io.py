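"""CSV readers and writers for curves, fit tables and synthetic truth.

All user-facing files carry temperatures in degrees Celsius (columns and
flags suffixed ``_C``); kelvin never appears at the file boundary.  Dialect:
comma-separated, '.' decimal, UTF-8, mandatory header, no index column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fit import SWEEP_COLUMNS, TPCurve
from .simulate import BetaCurveSpec

__all__ = [
    "SchemaError",
    "read_curves_csv",
    "write_curves_csv",
    "write_fit_table",
    "write_truth_csv",
    "write_instances_csv",
    "read_instances_csv",
]

REQUIRED_COLUMNS = ("curve_id", "temperature_C", "rate")


class SchemaError(ValueError):
    """The file does not match the documented CSV schema."""


def read_curves_csv(path) -> list[TPCurve]:
    """Read long-format curves: curve_id, temperature_C, rate[, species, trait].

    Malformed numeric rows are reported with their line numbers (header is
    line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    bad_lines = []
    for col in ("temperature_C", "rate"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_lines += [int(i) + 2 for i in df.index[vals.isna() & df[col].notna()]]
        df[col] = vals
    na_rows = df.index[df[["curve_id", "temperature_C", "rate"]].isna().any(axis=1)]
    bad_lines += [int(i) + 2 for i in na_rows]
    if bad_lines:
        raise SchemaError(f"{path}: malformed row(s) at line(s) "
                          f"{sorted(set(bad_lines))}")
    curves = []
    for cid, grp in df.groupby("curve_id", sort=False):
        meta = {}
        for opt in ("species", "trait"):
            if opt in grp.columns and grp[opt].notna().any():
                meta[opt] = str(grp[opt].dropna().iloc[0])
        curves.append(TPCurve.from_celsius(str(cid),
                                           grp["temperature_C"].to_numpy(),
                                           grp["rate"].to_numpy(), **meta))
    return curves


def write_curves_csv(curves: Sequence[TPCurve], path) -> None:
    """Write curves in the long-format input schema."""
    rows = []
    for c in curves:
        for t_k, r in zip(c.temperatures, c.rates):
            row = {"curve_id": c.curve_id,
                   "temperature_C": t_k - 273.15, "rate": r}
            if c.species is not None:
                row["species"] = c.species
            if c.trait is not None:
                row["trait"] = c.trait
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fit_table(table: pd.DataFrame, path) -> None:
    """Write a fit/sweep table with the documented column order."""
    extra = [c for c in table.columns if c not in SWEEP_COLUMNS]
    table[SWEEP_COLUMNS + extra].to_csv(path, index=False)


def write_truth_csv(specs: Sequence[BetaCurveSpec], curve_ids: Sequence[str],
                    seed: int, path) -> None:
    """Write the generator truth for a synthetic population."""
    rows = [
        {
            "curve_id": cid,
            "alpha": s.alpha,
            "beta": s.beta_,
            "j": s.width_mult,
            "k_sim": s.height_offset,
            "true_T_pk_C": s.true_t_pk_c,
            "value_at_7C": s.value_at_7c,
            "seed": seed,
        }
        for cid, s in zip(curve_ids, specs)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_instances_csv(instances, path) -> None:
    """Write tree instances: curve_id, d_pk_h, d_pk_ref, d_h_ref, label."""
    rows = [
        {"curve_id": i.curve_id or "", "d_pk_h": i.d_pk_h,
         "d_pk_ref": i.d_pk_ref, "d_h_ref": i.d_h_ref,
         "label": int(i.label)}
        for i in instances
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_instances_csv(path):
    """Read tree instances written by :func:`write_instances_csv`."""
    from .ctree import TreeInstance

    df = pd.read_csv(path)
    needed = ("d_pk_h", "d_pk_ref", "d_h_ref", "label")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return [
        TreeInstance(d_pk_h=float(r.d_pk_h), d_pk_ref=float(r.d_pk_ref),
                     d_h_ref=float(r.d_h_ref), label=bool(r.label),
                     curve_id=str(getattr(r, "curve_id", "")) or None)
        for r in df.itertuples(index=False)
    ]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
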