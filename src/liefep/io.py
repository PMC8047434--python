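"""Delimiter-separated file formats for energy samples, gaps and affinities.

All on-disk formats are plain text with a header row, readable by any
spreadsheet or ``pandas.read_csv``:

* energy samples: ``compound_id,state,replicate,u_vdw,u_el`` — one row per
  sample of a LIE trajectory;
* FEP gap samples: ``transformation,environment,replicate,stage,
  window_index,lambda,gap_fwd,gap_rev`` — ``gap_rev``/``gap_fwd`` may be
  empty at path ends;
* affinity tables: ``compound_id,ki_uM,censored,dg_exp,dg_calc,
  dg_calc_sem`` — a ``>`` prefix on ki_uM is parsed as censoring;
* cycle definitions: JSON with ``nodes`` and directed ``edges``.
"""

from __future__ import annotations

import json
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fep import FEPLeg, FEPWindow, Subperturbation, TransformationResult
from .lie import EnergySeries
from .thermo import AffinityRecord, InvalidInputError


def write_energy_series(series: list[EnergySeries], path) -> None:
    rows = []
    for s in series:
        for v, e in zip(s.u_vdw, s.u_el):
            rows.append((s.compound_id, s.state, s.replicate_id, v, e))
    pd.DataFrame(rows, columns=["compound_id", "state", "replicate", "u_vdw", "u_el"]).to_csv(
        path, index=False
    )


def read_energy_series(path) -> list[EnergySeries]:
    """Read per-sample LIE energies; rows are grouped into replicate series."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    required = {"compound_id", "state", "replicate", "u_vdw", "u_el"}
    if missing := required - set(df.columns):
        raise InvalidInputError(f"energy file {path} missing columns: {sorted(missing)}")
    out = []
    for (cid, state, rep), grp in df.groupby(["compound_id", "state", "replicate"], sort=False):
        out.append(
            EnergySeries(
                compound_id=str(cid),
                state=str(state),
                replicate_id=int(rep),
                u_vdw=grp["u_vdw"].to_numpy(),
                u_el=grp["u_el"].to_numpy(),
            )
        )
    return out


def _parse_ki(raw) -> tuple[float | None, bool]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None, False
    s = str(raw).strip()
    if not s:
        return None, False
    if s.startswith(">"):
        return float(s[1:]), True
    return float(s), False


def read_affinity_table(path) -> list[AffinityRecord]:
    """Read an affinity table; '>' prefixed Ki values mark censored records."""
    df = pd.read_csv(path, dtype={"compound_id": str, "ki_uM": str})
    if "compound_id" not in df.columns or "ki_uM" not in df.columns:
        raise InvalidInputError(f"affinity file {path} needs compound_id and ki_uM columns")
    records = []
    for _, row in df.iterrows():
        ki, censored = _parse_ki(row["ki_uM"])
        if "censored" in df.columns and not pd.isna(row.get("censored")):
            censored = censored or bool(row["censored"])

        def _opt(col):
            v = row.get(col)
            return None if v is None or pd.isna(v) else float(v)

        records.append(
            AffinityRecord(
                compound_id=str(row["compound_id"]),
                ki=ki,
                censored=censored,
                dg_exp=_opt("dg_exp"),
                dg_calc=_opt("dg_calc"),
                dg_calc_sem=_opt("dg_calc_sem"),
            )
        )
    return records


def write_affinity_table(records: list[AffinityRecord], path) -> None:
    rows = []
    for r in records:
        ki = "" if r.ki is None else (f">{r.ki:g}" if r.censored else f"{r.ki:g}")
        rows.append((r.compound_id, ki, r.censored, r.dg_exp, r.dg_calc, r.dg_calc_sem))
    pd.DataFrame(
        rows, columns=["compound_id", "ki_uM", "censored", "dg_exp", "dg_calc", "dg_calc_sem"]
    ).to_csv(path, index=False)


def write_fep_samples(legs: list[FEPLeg], path) -> None:
    rows = []
    for leg in legs:
        for stage in leg.subperturbations:
            for i, w in enumerate(stage.windows):
                n = max(
                    w.gaps_forward.size if w.gaps_forward is not None else 0,
                    w.gaps_reverse.size if w.gaps_reverse is not None else 0,
                )
                for j in range(n):
                    gf = w.gaps_forward[j] if w.gaps_forward is not None and j < w.gaps_forward.size else ""
                    gr = w.gaps_reverse[j] if w.gaps_reverse is not None and j < w.gaps_reverse.size else ""
                    rows.append((leg.transformation_id, leg.environment, leg.replicate_id,
                                 stage.label, i, w.lambda_m, gf, gr))
    pd.DataFrame(rows, columns=["transformation", "environment", "replicate", "stage",
                                "window_index", "lambda", "gap_fwd", "gap_rev"]).to_csv(
        path, index=False
    )


def read_fep_samples(path) -> list[FEPLeg]:
    """Read FEP gap samples into legs keyed by (transformation, environment, replicate)."""
    df = pd.read_csv(path)
    required = {"transformation", "environment", "replicate", "stage",
                "window_index", "lambda", "gap_fwd", "gap_rev"}
    if missing := required - set(df.columns):
        raise InvalidInputError(f"FEP file {path} missing columns: {sorted(missing)}")
    legs = []
    for (tid, env, rep), leg_df in df.groupby(["transformation", "environment", "replicate"],
                                              sort=False):
        stage_map: dict[str, list[FEPWindow]] = defaultdict(list)
        for (stage, _idx), w_df in leg_df.groupby(["stage", "window_index"], sort=True):
            gf = w_df["gap_fwd"].dropna().to_numpy(dtype=float)
            gr = w_df["gap_rev"].dropna().to_numpy(dtype=float)
            stage_map[str(stage)].append(
                FEPWindow(
                    lambda_m=float(w_df["lambda"].iloc[0]),
                    gaps_forward=gf if gf.size else None,
                    gaps_reverse=gr if gr.size else None,
                )
            )
        subs = [Subperturbation(label=lbl, windows=wins) for lbl, wins in stage_map.items()]
        legs.append(FEPLeg(transformation_id=str(tid), environment=str(env),
                           replicate_id=int(rep), subperturbations=subs))
    return legs


def read_cycle_definition(path) -> tuple[list[str], list[tuple[str, str]]]:
    """Read a JSON cycle definition: {"nodes": [...], "edges": [[a, b], ...]}."""
    data = json.loads(Path(path).read_text())
    if "edges" not in data:
        raise InvalidInputError(f"cycle file {path} has no 'edges' key")
    edges = [(str(a), str(b)) for a, b in data["edges"]]
    nodes = [str(n) for n in data.get("nodes", [])] or sorted({n for e in edges for n in e})
    return nodes, edges


def write_transformation_table(results: list[TransformationResult], path) -> None:
    rows = [(r.a_label, r.b_label, r.ddg, r.ddg_sem, r.hysteresis_total) for r in results]
    pd.DataFrame(rows, columns=["a_label", "b_label", "ddg", "ddg_sem", "hysteresis_total"]).to_csv(
        path, index=False
    )
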