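"""Reading and writing NONMEM-convention event tables.

One row per event: dose rows (EVID=1) carry AMT (mg) and RATE (mg/h), so
infusion duration is AMT/RATE; observation rows (EVID=0) carry DV (mg/L),
MDV (1 when the DV is missing or BQL-excluded) and the BQL flag.
Covariates repeat on every row of a subject and must be constant within
subject.  TIME is hours since the subject's first dose.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import LLOQ_MG_L, CovariateRecord
from .dataset import Observation, StudyDataset, Subject
from .pkmodel import DoseEvent

COLUMNS = [
    "ID", "TIME", "EVID", "AMT", "RATE", "DV", "MDV", "BQL",
    "CW", "BW", "GA", "PNA", "PMA", "CREA", "BUN", "ALB",
]

_COV_MAP = {
    "CW": "cw_g", "BW": "bw_g", "GA": "ga_weeks", "PNA": "pna_days",
    "PMA": "pma_weeks", "CREA": "crea_umol_L", "BUN": "bun_mmol_L",
    "ALB": "alb_g_L",
}


class SchemaError(ValueError):
    """The file does not have the expected event-table layout."""


class ValidationError(ValueError):
    """The file parsed but violates a dataset invariant."""


@dataclass(frozen=True)
class Dialect:
    delimiter: str = ","
    missing: str = "."


def write_dataset(
    dataset: StudyDataset, path: str, dialect: Dialect | None = None
) -> None:
    """Write a dataset as a delimited event table (stable across runs)."""
    dialect = dialect or Dialect()
    rows = []
    for s in dataset.subjects:
        cov = {k: getattr(s.covariates, v) for k, v in _COV_MAP.items()}
        events: list[tuple[float, int, dict]] = []
        for d in s.doses:
            events.append(
                (d.start_h, 1, {"AMT": d.amount_mg, "RATE": d.rate_mg_h})
            )
        for o in s.observations:
            events.append(
                (o.time_h, 0, {"DV": o.dv_mg_L, "MDV": int(o.bql), "BQL": int(o.bql)})
            )
        # stable order: time, then doses before observations at ties
        events.sort(key=lambda e: (e[0], -e[1]))
        for t, evid, extra in events:
            row = {"ID": s.id, "TIME": t, "EVID": evid, **cov}
            row.update(extra)
            rows.append(row)
    df = pd.DataFrame(rows, columns=COLUMNS)
    df["MDV"] = df["MDV"].fillna(1).astype(int)
    df["BQL"] = df["BQL"].fillna(0).astype(int)
    df.to_csv(
        path, sep=dialect.delimiter, index=False,
        na_rep=dialect.missing, float_format="%.10g",
    )


def read_dataset(path: str, dialect: Dialect | None = None) -> StudyDataset:
    """Read and validate an event table into a :class:`StudyDataset`.

    Invariant violations are reported with the offending row number
    (1-based, header excluded).  DV values below the 0.2 mg/L LLOQ whose
    BQL flag is 0 are auto-flagged with a warning.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep=dialect.delimiter, na_values=[dialect.missing])
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing_cols)}")
    df = df[COLUMNS]
    df["_row"] = np.arange(1, len(df) + 1)

    subjects = []
    for sid, g in df.groupby("ID", sort=False):
        for col, fld in _COV_MAP.items():
            if g[col].nunique(dropna=False) != 1:
                raise ValidationError(
                    f"subject {sid}: covariate {col} varies within subject "
                    f"(rows {', '.join(map(str, g['_row'].tolist()))})"
                )
        first = g.iloc[0]
        cov_vals = {fld: float(first[col]) for col, fld in _COV_MAP.items()}
        # PMA is the construction identity GA + PNA/7; the stored column is
        # checked against it loosely (formatting round-off) and recomputed
        pma_expected = cov_vals["ga_weeks"] + cov_vals["pna_days"] / 7.0
        if abs(cov_vals["pma_weeks"] - pma_expected) > 0.01:
            raise ValidationError(
                f"subject {sid}: PMA {cov_vals['pma_weeks']} inconsistent "
                f"with GA + PNA/7 = {pma_expected:.3f}"
            )
        cov_vals["pma_weeks"] = pma_expected
        cov = CovariateRecord(**cov_vals)
        if not (g["TIME"].diff().dropna() >= 0).all():
            bad = int(g.loc[g["TIME"].diff() < 0, "_row"].iloc[0])
            raise ValidationError(
                f"subject {sid}: TIME decreases at row {bad}"
            )
        doses, observations = [], []
        for _, r in g.iterrows():
            if int(r["EVID"]) == 1:
                if not (r["AMT"] > 0 and r["RATE"] > 0):
                    raise ValidationError(
                        f"row {int(r['_row'])}: dose rows need AMT > 0 and RATE > 0"
                    )
                doses.append(
                    DoseEvent(
                        amount_mg=float(r["AMT"]),
                        start_h=float(r["TIME"]),
                        duration_h=float(r["AMT"] / r["RATE"]),
                    )
                )
            else:
                bql = bool(int(r["BQL"])) if not np.isnan(r["BQL"]) else False
                dv = float(r["DV"]) if not np.isnan(r["DV"]) else np.nan
                if not bql and not np.isnan(dv) and dv < LLOQ_MG_L:
                    warnings.warn(
                        f"row {int(r['_row'])}: DV {dv} below LLOQ "
                        f"{LLOQ_MG_L} mg/L not flagged BQL; auto-flagging",
                        stacklevel=2,
                    )
                    bql = True
                if np.isnan(dv):
                    raise ValidationError(
                        f"row {int(r['_row'])}: observation row without DV"
                    )
                if not bql and dv <= 0:
                    raise ValidationError(
                        f"row {int(r['_row'])}: non-BQL DV must be positive"
                    )
                observations.append(Observation(float(r["TIME"]), dv, bql=bql))
        if not doses:
            raise ValidationError(f"subject {sid}: no dose events")
        subjects.append(Subject(str(sid), cov, doses, observations))
    ds = StudyDataset(subjects=subjects)
    ds.validate()
    return ds
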