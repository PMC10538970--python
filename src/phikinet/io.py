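"""Trace CSV and report JSON input/output.

Trace files use the header ``t_s,C_<name>,...,A_tot`` with times in
seconds, concentrations in M and values written at 17 significant digits,
so a write/read round trip is lossless.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .phiorder import CoupledFit, PhiOrderModel, model_initial_rate
from .simulate import KineticTrace
from .solver import SolveReport

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "fit_report_dict",
    "solve_report_dict",
    "write_json",
]


def write_trace_csv(tr: KineticTrace, path) -> None:
    data = {"t_s": tr.times}
    for j, name in enumerate(tr.species):
        data[f"C_{name}"] = tr.conc[:, j]
    if tr.atot is not None:
        data["A_tot"] = tr.atot
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_trace_csv(path) -> KineticTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    if "t_s" not in df.columns:
        raise ValueError("trace CSV must have a 't_s' column")
    species = tuple(c[2:] for c in df.columns if c.startswith("C_"))
    conc = df[[f"C_{n}" for n in species]].to_numpy(dtype=float)
    atot = df["A_tot"].to_numpy(dtype=float) if "A_tot" in df.columns else None
    return KineticTrace(times=df["t_s"].to_numpy(dtype=float), conc=conc, species=species, atot=atot)


def _model_dict(pm: PhiOrderModel) -> dict:
    return {
        "c_inf": pm.c_inf,
        "cc": pm.cc,
        "terms": [{"omega": w, "k": k} for w, k in pm.terms],
        "initial_rate": model_initial_rate(pm),
    }


def fit_report_dict(cf: CoupledFit) -> dict:
    out = {
        "seed": cf.seed,
        "n_starts": cf.n_starts,
        "cc": cf.cc,
        "k_values": list(cf.k_values),
        "species": {},
        "warnings": list(cf.warnings),
    }
    for name in cf.species:
        q = cf.quality[name]
        out["species"][name] = _model_dict(cf.models[name]) | {
            "r2": q.r2, "sse": q.sse, "rmse": q.rmse,
        }
    if cf.atot_model is not None:
        q = cf.atot_quality
        out["atot"] = _model_dict(cf.atot_model) | {"r2": q.r2, "sse": q.sse, "rmse": q.rmse}
    return out


def solve_report_dict(rep: SolveReport) -> dict:
    out = {
        "epsilons_M_cm": rep.epsilons,
        "phis": rep.phis,
        "timepoints_s": list(rep.timepoints),
        "cond_epsilons": rep.cond_epsilons,
        "cond_phis": rep.cond_phis,
        "fit": None if rep.fit is None else fit_report_dict(rep.fit),
    }
    if rep.pct_err_epsilons is not None:
        out["pct_err_epsilons"] = rep.pct_err_epsilons
        out["pct_err_phis"] = rep.pct_err_phis
    return out


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
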