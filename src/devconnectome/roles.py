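"""Network cartography: within-module degree z-scores, participation, roles.

Given a module partition of the network (here the six previously published
topological modules, supplied as input), each neuron is placed in the
(z, P) plane:

* z — within-module degree z-score: its intra-module degree standardized
  against the module members (population standard deviation); z >= 0.7
  marks hubs.
* P — participation coefficient: P_i = 1 - sum_c (kappa_ci / k_i)^2 over
  the m modules, 0 when all links stay inside the neuron's own module and
  at most 1 - 1/m (links spread evenly over all modules).

Role classes R1-R7 follow the standard cartographic thresholds: non-hubs
are ultra-peripheral (R1: P <= 0.05), peripheral (R2: P <= 0.62), satellite
connectors (R3: P <= 0.8) or kinless (R4: P > 0.8); hubs are provincial
(R5: P <= 0.3), connector (R6: P <= 0.75) or global (R7: P > 0.75).

Degrees default to the undirected combined network (synapses in either
direction plus gap junctions, binarized), the convention under which the
module partition was originally derived; 'syn' or 'gap' are selectable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import Connectome, NeuronTable

__all__ = ["HUB_Z_THRESHOLD", "degree_matrix", "within_module_zscore",
           "participation_coefficient", "classify_roles", "role_table",
           "role_birth_summary"]

HUB_Z_THRESHOLD = 0.7

_NONHUB_BOUNDS = (("R1", 0.05), ("R2", 0.62), ("R3", 0.8), ("R4", np.inf))
_HUB_BOUNDS = (("R5", 0.3), ("R6", 0.75), ("R7", np.inf))


def degree_matrix(conn: Connectome, graph: str = "combined") -> np.ndarray:
    """Symmetric adjacency whose row sums are the degrees used for roles."""
    if graph == "combined":
        return conn.combined_undirected()
    if graph == "syn":
        a = ((conn.syn + conn.syn.T) > 0).astype(np.int8)
        np.fill_diagonal(a, 0)
        return a
    if graph == "gap":
        return conn.gap
    raise ValueError("graph must be 'combined', 'syn' or 'gap'")


def _module_vector(conn: Connectome, modules) -> np.ndarray:
    if isinstance(modules, pd.Series):
        return modules.reindex(conn.neurons).to_numpy(dtype=object)
    if isinstance(modules, dict):
        return np.array([modules.get(n) for n in conn.neurons], dtype=object)
    arr = np.asarray(modules, dtype=object)
    if len(arr) != len(conn.neurons):
        raise ValueError("module vector length does not match connectome")
    return arr


def within_module_zscore(conn: Connectome, modules,
                         graph: str = "combined") -> pd.Series:
    """Within-module degree z per neuron (population sd over the module).

    NaN for members of single-member modules or modules whose internal
    degrees have zero variance.
    """
    a = degree_matrix(conn, graph)
    mod = _module_vector(conn, modules)
    z = pd.Series(np.nan, index=conn.neurons, dtype=float)
    for m in pd.unique(mod[~pd.isna(mod)]):
        members = np.flatnonzero(mod == m)
        if len(members) < 2:
            continue
        kappa = a[np.ix_(members, members)].sum(axis=1).astype(float)
        sd = kappa.std()
        if sd == 0:
            continue
        z.iloc[members] = (kappa - kappa.mean()) / sd
    return z


def participation_coefficient(conn: Connectome, modules,
                              graph: str = "combined") -> pd.Series:
    """P_i = 1 - sum_c (kappa_ci / k_i)^2; NaN for isolated neurons."""
    a = degree_matrix(conn, graph)
    mod = _module_vector(conn, modules)
    labels = pd.unique(mod[~pd.isna(mod)])
    k = a.sum(axis=1).astype(float)
    p = np.full(len(k), np.nan)
    nz = k > 0
    acc = np.zeros(len(k))
    for m in labels:
        members = mod == m
        kappa = a[:, members].sum(axis=1).astype(float)
        acc[nz] += (kappa[nz] / k[nz]) ** 2
    p[nz] = 1.0 - acc[nz]
    return pd.Series(p, index=conn.neurons)


def classify_roles(z, p) -> pd.Series | str:
    """Map (z, P) to role classes R1-R7; NaN inputs are 'unclassified'.

    The hub threshold z >= 0.7 is inclusive and the P thresholds are
    upper-inclusive, so the classification is a total function on the
    defined domain (no gaps, no overlaps).
    """
    scalar = np.isscalar(z)
    zs = pd.Series([z]) if scalar else pd.Series(z)
    ps = pd.Series([p]) if scalar else pd.Series(p)
    out = []
    for zv, pv in zip(zs, ps):
        if pd.isna(zv) or pd.isna(pv):
            out.append("unclassified")
            continue
        bounds = _HUB_BOUNDS if zv >= HUB_Z_THRESHOLD else _NONHUB_BOUNDS
        for role, upper in bounds:
            if pv <= upper:
                out.append(role)
                break
    if scalar:
        return out[0]
    return pd.Series(out, index=zs.index)


def role_table(conn: Connectome, modules, graph: str = "combined"
               ) -> pd.DataFrame:
    """Per-neuron (z, P, role) table on the chosen degree convention."""
    z = within_module_zscore(conn, modules, graph)
    p = participation_coefficient(conn, modules, graph)
    roles = classify_roles(z, p)
    mod = _module_vector(conn, modules)
    return pd.DataFrame({"neuron": conn.neurons, "module": mod,
                         "z": z.values, "P": p.values,
                         "role": roles.values}).set_index("neuron")


def role_birth_summary(roles: pd.DataFrame, table: NeuronTable,
                       stages: tuple[str, ...] = ("Embryo", "L1", "L2", "L3")
                       ) -> pd.DataFrame:
    """Cumulative fraction of each role class differentiated by stage end.

    Rows are role classes (empty classes omitted), columns developmental
    stages; entries are non-decreasing and reach 1 in the final stage for
    neurons with known stages.
    """
    table.require("birth_stage", "role birth summary")
    stage = table.column("birth_stage")
    rows = {}
    for role, grp in roles.groupby("role"):
        if role == "unclassified":
            continue
        st = stage.reindex(grp.index).dropna()
        if len(st) == 0:
            continue
        order = {s: k for k, s in enumerate(stages)}
        ranks = st.map(order)
        rows[role] = [float((ranks <= k).mean()) for k in range(len(stages))]
    return pd.DataFrame(rows, index=list(stages)).T
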