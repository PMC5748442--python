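"""Reading and writing datasets in a NONMEM-style rectangular CSV dialect.

One row per event: dosing rows carry ``EVID=1`` with the infused amount
(``AMT``, mg) and zero-order ``RATE`` (mg/h); observation rows carry
``EVID=0`` with the measured concentration ``DV`` (mg/L) and a ``BLQ``
flag.  ``TIME`` is hours after infusion start; bodyweight ``BW`` (kg) and
``BSA`` (m2) ride along on every row.  Simulation provenance (true etas,
true parameters, true AUC, the g/m2 dose level) is written as optional
columns so a simulated dataset round-trips exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ConcentrationRecord, Dataset, DoseRegimen, Subject
from .pkmodel import PKParameters, RandomEffects

__all__ = ["write_dataset", "read_dataset"]

_REQUIRED = ["ID", "TIME", "AMT", "RATE", "DV", "EVID", "BW"]
_PROV_COLS = [
    "ETA_CL", "ETA_V1", "ETA_Q",
    "TRUE_CL", "TRUE_V1", "TRUE_Q", "TRUE_V2", "TRUE_AUC",
]


def write_dataset(dataset: Dataset, path) -> None:
    rows = []
    for s in dataset.subjects:
        base = {"ID": s.id, "BW": s.bodyweight, "BSA": s.bsa, "DPB": s.regimen.dose_per_bsa}
        dose_row = dict(
            base,
            TIME=0.0,
            AMT=s.regimen.total_dose,
            RATE=s.regimen.total_dose / s.regimen.t_inf,
            DUR=s.regimen.t_inf,
            DV=np.nan,
            EVID=1,
            MDV=1,
            BLQ=0,
        )
        if s.eta is not None:
            dose_row.update(ETA_CL=s.eta.eta_cl, ETA_V1=s.eta.eta_v1, ETA_Q=s.eta.eta_q)
        if s.true_params is not None:
            p = s.true_params
            dose_row.update(TRUE_CL=p.cl, TRUE_V1=p.v1, TRUE_Q=p.q, TRUE_V2=p.v2)
        if s.true_auc is not None:
            dose_row["TRUE_AUC"] = s.true_auc
        rows.append(dose_row)
        for r in s.records:
            rows.append(dict(base, TIME=r.time, AMT=np.nan, RATE=np.nan, DV=r.conc,
                             EVID=0, MDV=0, BLQ=int(r.blq)))
    df = pd.DataFrame(rows)
    # %.17g round-trips IEEE doubles exactly through text
    df.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> Dataset:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    obs = df[df["EVID"] == 0]
    if (obs["DV"] < 0).any():
        raise ValueError("negative DV encountered")
    subjects = []
    for sid, g in df.groupby("ID", sort=False):
        dose_rows = g[g["EVID"] == 1]
        if len(dose_rows) != 1:
            raise ValueError(f"subject {sid}: expected exactly one dosing row")
        d = dose_rows.iloc[0]
        bw = float(d["BW"])
        bsa = float(d["BSA"]) if "BSA" in g.columns else None
        total = float(d["AMT"])
        if "DUR" in g.columns and not pd.isna(d.get("DUR", np.nan)):
            t_inf = float(d["DUR"])
        else:
            t_inf = total / float(d["RATE"])
        if "DPB" in g.columns and not pd.isna(d.get("DPB", np.nan)):
            dpb = float(d["DPB"])
        else:
            dpb = min((10.0, 12.0, 14.0), key=lambda v: abs(v - total / (1000.0 * (bsa or 1.0))))
        if bsa is None:
            from .cohort import bsa_from_weight

            bsa = bsa_from_weight(bw)
        og = g[g["EVID"] == 0]
        times = og["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"subject {sid}: observation times must be strictly increasing")
        records = [
            ConcentrationRecord(time=float(r["TIME"]), conc=float(r["DV"]), blq=bool(r.get("BLQ", 0)))
            for _, r in og.iterrows()
        ]
        eta = None
        if all(c in g.columns for c in ("ETA_CL", "ETA_V1", "ETA_Q")) and not pd.isna(d["ETA_CL"]):
            eta = RandomEffects(float(d["ETA_CL"]), float(d["ETA_V1"]), float(d["ETA_Q"]))
        true_params = None
        if all(c in g.columns for c in ("TRUE_CL", "TRUE_V1", "TRUE_Q", "TRUE_V2")) and not pd.isna(d["TRUE_CL"]):
            true_params = PKParameters(float(d["TRUE_CL"]), float(d["TRUE_V1"]),
                                       float(d["TRUE_Q"]), float(d["TRUE_V2"]))
        true_auc = None
        if "TRUE_AUC" in g.columns and not pd.isna(d.get("TRUE_AUC", np.nan)):
            true_auc = float(d["TRUE_AUC"])
        subjects.append(
            Subject(
                id=str(sid),
                bodyweight=bw,
                bsa=float(bsa),
                regimen=DoseRegimen(dose_per_bsa=dpb, t_inf=t_inf, total_dose=total),
                records=records,
                eta=eta,
                true_params=true_params,
                true_auc=true_auc,
            )
        )
    return Dataset(subjects, {"source": str(path)})
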