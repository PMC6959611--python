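"""Functional-circuit developmental completion and degree comparisons.

Functional circuits (F1-F9: mechanosensation, egg laying, thermotaxis,
chemosensation, feeding, exploration, tap withdrawal, O2 and CO2 sensation)
are behaviorally defined neuron groups.  This module asks when each circuit
acquires its full complement over the Embryo/L1/L2/L3 stages, and whether
circuit neurons differ from the rest in their synaptic in/out and
gap-junction degree distributions (two-sample Kolmogorov-Smirnov tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CIRCUITS, Connectome, NeuronTable, TestResult

__all__ = ["CircuitSummary", "circuit_completion", "degree_group_compare",
           "stage_degree_dispersion"]

STAGES = ("Embryo", "L1", "L2", "L3")


@dataclass
class CircuitSummary:
    """Stage-wise completion and composition of the functional circuits."""

    members: dict[str, list[str]]
    completion: pd.DataFrame       # circuit x stage cumulative fractions
    fully_embryonic: list[str]     # complete before hatching
    late_completing: list[str]
    composition: pd.DataFrame | None  # circuit x proc class fractions


def circuit_completion(table: NeuronTable,
                       circuits: tuple[str, ...] = CIRCUITS) -> CircuitSummary:
    """Cumulative differentiated fraction of each circuit per stage.

    Circuits whose entire complement differentiates in the embryonic stage
    are classified fully-embryonic; empty circuits are omitted.  When
    process classes are available a per-circuit S/M/L composition table is
    included (fractions summing to 1 over classified members).
    """
    table.require("circuits", "circuit completion")
    table.require("birth_stage", "circuit completion")
    stage = table.column("birth_stage")
    members = {}
    for c in circuits:
        m = table.circuit_members(c)
        if m:
            members[c] = m
    if not members:
        raise ValueError("no circuit memberships found")
    order = {s: k for k, s in enumerate(STAGES)}
    rows = {}
    for c, m in members.items():
        ranks = stage.reindex(m).dropna().map(order)
        rows[c] = [float((ranks <= k).mean()) for k in range(len(STAGES))]
    completion = pd.DataFrame(rows, index=list(STAGES)).T
    fully = sorted(completion.index[completion["Embryo"] >= 1.0])
    late = sorted(completion.index[completion["Embryo"] < 1.0])

    composition = None
    if table.has("proc_cat"):
        cat = table.column("proc_cat")
        comp = {}
        for c, m in members.items():
            cc = cat.reindex(m).dropna()
            if len(cc):
                comp[c] = cc.value_counts(normalize=True).reindex(
                    ["S", "M", "L"], fill_value=0.0)
        composition = pd.DataFrame(comp).T
    return CircuitSummary(members=members, completion=completion,
                          fully_embryonic=fully, late_completing=late,
                          composition=composition)


def _degrees(conn: Connectome, names: list[str]) -> dict[str, np.ndarray]:
    idx = [conn.index[n] for n in names if n in conn.index]
    return {
        "k_in": conn.k_in[idx].astype(float),
        "k_out": conn.k_out[idx].astype(float),
        "k_gap": conn.k_gap[idx].astype(float),
    }


def degree_group_compare(conn: Connectome, group: list[str],
                         other: list[str], alpha: float = 0.05
                         ) -> dict[str, TestResult]:
    """Two-sample KS tests on k_in, k_out and k_gap between neuron groups.

    Returns one :class:`TestResult` per degree type; ``h`` is the
    rejection indicator at the supplied significance level.
    """
    if len(group) < 2 or len(other) < 2:
        raise ValueError("each group needs at least 2 neurons")
    da, db = _degrees(conn, group), _degrees(conn, other)
    out = {}
    for key in ("k_in", "k_out", "k_gap"):
        res = stats.ks_2samp(da[key], db[key])
        out[key] = TestResult(statistic=float(res.statistic),
                              p_value=float(res.pvalue), alpha=alpha)
    return out


def _box_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo) & (values <= hi)]
    outliers = values[(values < lo) | (values > hi)]
    return {
        "n": len(values), "q1": q1, "median": med, "q3": q3,
        "whisker_low": float(inside.min()) if len(inside) else np.nan,
        "whisker_high": float(inside.max()) if len(inside) else np.nan,
        "outliers": sorted(outliers.tolist()),
    }


def stage_degree_dispersion(conn: Connectome, table: NeuronTable,
                            groups: dict[str, list[str]]) -> pd.DataFrame:
    """Box-plot tables of each degree type per stage per neuron group.

    Whiskers extend to the most extreme values within 1.5 IQR of the
    quartiles; values beyond are listed as outliers.
    """
    table.require("birth_stage", "stage degree dispersion")
    stage = table.column("birth_stage")
    rows = []
    for gname, names in groups.items():
        present = [n for n in names if n in conn.index]
        st = stage.reindex(present)
        for s in STAGES:
            sel = [n for n, sv in zip(present, st) if sv == s]
            if not sel:
                continue
            degs = _degrees(conn, sel)
            for key, vals in degs.items():
                rows.append({"group": gname, "stage": s, "degree": key,
                             **_box_stats(vals)})
    return pd.DataFrame(rows)
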