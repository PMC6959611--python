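"""Attribute homophily on the connectome via modularity and null ensembles.

Homophily — the preference of neurons sharing an attribute (process-length
class, birth cohort, ...) to connect to each other — is quantified by the
modularity of the partition induced by the attribute:

    Q = (1/L) * sum_ij [A_ij - k_in(i) * k_out(j) / L] * delta(c_i, c_j)

with A[i, j] = 1 iff i receives a connection from j, and L the total number
of adjacency entries (for the symmetric gap-junction matrix each undirected
junction is counted twice, so k_in = k_out = k and Q values remain
comparable with the directed case).  Class-pair modularities Q_XY decompose
Q over ordered label pairs; the diagonal sums back to Q exactly.

Two surrogate ensembles give the statistics their significance scale:

* attribute shuffling — the label vector is randomly permuted, preserving
  class sizes exactly and leaving the network untouched;
* constrained degree-preserving rewiring — double-edge swaps keep every
  in- and out-degree fixed while a physical reach constraint (cell-body
  separation must not exceed the sum of the two neurons' drawn process
  lengths) disallows un-physical connections.

z-scores use the population standard deviation of the ensemble samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .io import Connectome, NeuronTable

logger = logging.getLogger(__name__)

__all__ = [
    "modularity", "class_pair_modularity", "shuffle_attribute_surrogate",
    "constrained_rewire_surrogate", "draw_process_lengths",
    "homophily_zscore", "homophily_report", "birth_cohort_analysis",
]


def _align_labels(conn: Connectome, labels) -> np.ndarray:
    """Label per node in connectome order; NaN/None marks unlabeled."""
    if isinstance(labels, pd.Series):
        lab = labels.reindex(conn.neurons)
        return lab.to_numpy(dtype=object)
    if isinstance(labels, dict):
        return np.array([labels.get(n) for n in conn.neurons], dtype=object)
    arr = np.asarray(labels, dtype=object)
    if len(arr) != len(conn.neurons):
        raise ValueError("label vector length does not match connectome")
    return arr


def _labeled_subnetwork(conn: Connectome, labels, graph: str):
    lab = _align_labels(conn, labels)
    keep = np.array([l is not None and not (isinstance(l, float) and np.isnan(l))
                     for l in lab])
    a = conn.matrix(graph)[np.ix_(keep, keep)]
    return a.astype(float), lab[keep]


def modularity(conn: Connectome, labels, graph: str = "syn") -> float:
    """Modularity Q of the partition defined by ``labels``.

    Unlabeled neurons are excluded (the induced subnetwork is used); the
    effective n is logged.  Raises on an empty graph.
    """
    a, lab = _labeled_subnetwork(conn, labels, graph)
    L = a.sum()
    if L == 0:
        raise ValueError("no links in the selected graph")
    logger.debug("modularity over %d labeled neurons, L=%d", len(lab), int(L))
    k_in = a.sum(axis=1)
    k_out = a.sum(axis=0)
    same = lab[:, None] == lab[None, :]
    return float(((a - np.outer(k_in, k_out) / L) * same).sum() / L)


def class_pair_modularity(conn: Connectome, labels, graph: str = "syn"
                          ) -> pd.DataFrame:
    """Matrix of class-pair modularities Q_XY.

    Entry ``.loc[X, Y]`` restricts the modularity sum to receiving neurons
    of class Y and sending neurons of class X; ``sum_X Q_XX == Q``.
    """
    a, lab = _labeled_subnetwork(conn, labels, graph)
    L = a.sum()
    if L == 0:
        raise ValueError("no links in the selected graph")
    k_in = a.sum(axis=1)
    k_out = a.sum(axis=0)
    b = a - np.outer(k_in, k_out) / L
    classes = sorted(set(lab))
    out = pd.DataFrame(0.0, index=classes, columns=classes)
    for x in classes:
        col = lab == x  # sender class (index j)
        for y in classes:
            row = lab == y  # receiver class (index i)
            out.loc[x, y] = b[np.ix_(row, col)].sum() / L
    return out


def shuffle_attribute_surrogate(labels, n_real: int, seed: int = 0
                                ) -> Iterator[np.ndarray]:
    """Yield uniformly permuted copies of the label vector.

    Class sizes are preserved exactly in every realization; only the
    assignment of labels to neurons is randomized.
    """
    if n_real < 2:
        raise ValueError("need at least 2 realizations")
    lab = labels.to_numpy(dtype=object) if isinstance(labels, pd.Series) \
        else np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    for _ in range(n_real):
        yield rng.permutation(lab)


def draw_process_lengths(table: NeuronTable, rng: np.random.Generator,
                         body_length: float | None = None) -> pd.Series:
    """One numeric neurite length per neuron, uniform within its S/M/L band.

    Bands are [0, L/3], [L/3, 2L/3] and [2L/3, L] of the body length.
    """
    table.require("proc_cat", "process-length draw")
    L = table.body_length if body_length is None else body_length
    lo = {"S": 0.0, "M": L / 3, "L": 2 * L / 3}
    out = {}
    for name, cat in zip(table.df["name"], table.df["proc_cat"]):
        if pd.isna(cat):
            out[name] = np.nan
        else:
            out[name] = rng.uniform(lo[cat], lo[cat] + L / 3)
    return pd.Series(out)


def _swap_directed(edges: np.ndarray, adj: np.ndarray, feasible: np.ndarray,
                   n_swaps: int, rng: np.random.Generator) -> int:
    """In-place double-edge swaps on a directed edge array; returns accepts."""
    m = len(edges)
    if m < 2:
        return 0
    accepted = 0
    picks = rng.integers(0, m, size=(n_swaps, 2))
    for e1, e2 in picks:
        if e1 == e2:
            continue
        p, q = edges[e1]
        u, v = edges[e2]
        if p == v or u == q or q == v or p == u:
            continue
        if adj[p, v] or adj[u, q]:
            continue
        if not (feasible[p, v] and feasible[u, q]):
            continue
        adj[p, q] = adj[u, v] = 0
        adj[p, v] = adj[u, q] = 1
        edges[e1, 1] = v
        edges[e2, 1] = q
        accepted += 1
    return accepted


def _swap_undirected(edges: np.ndarray, adj: np.ndarray, feasible: np.ndarray,
                     n_swaps: int, rng: np.random.Generator) -> int:
    m = len(edges)
    if m < 2:
        return 0
    accepted = 0
    picks = rng.integers(0, m, size=(n_swaps, 2))
    flips = rng.random(n_swaps) < 0.5
    for (e1, e2), flip in zip(picks, flips):
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        # propose {a, d}, {c, b}
        if len({a, b, c, d}) < 4:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        if not (feasible[a, d] and feasible[c, b]):
            continue
        adj[a, b] = adj[b, a] = adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = adj[c, b] = adj[b, c] = 1
        edges[e1] = (a, d)
        edges[e2] = (c, b)
        accepted += 1
    return accepted


def constrained_rewire_surrogate(conn: Connectome, table: NeuronTable,
                                 n_swaps: int = 500_000, n_real: int = 100,
                                 seed: int = 0,
                                 body_length: float | None = None
                                 ) -> Iterator[Connectome]:
    """Yield degree-preserving rewired connectomes under the reach constraint.

    Per realization one numeric process length is drawn per neuron
    (uniform within its category band, redrawn once per realization, not
    per swap) and ``n_swaps`` double-edge-swap *attempts* are made on each
    graph; swaps creating self-loops, multi-edges or connections whose
    cell-body separation exceeds the summed reach are rejected.  The
    acceptance count is logged; a warning is emitted when fewer than 10% of
    attempts succeed.
    """
    table.require("proc_cat", "constrained rewiring")
    pos = table.positions()
    order = [table.names.index(n) for n in conn.neurons]
    pos = pos[order]
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    rng = np.random.default_rng(seed)
    for r in range(n_real):
        lengths = draw_process_lengths(table, rng, body_length=body_length)
        reach = lengths.reindex(conn.neurons).to_numpy(dtype=float)
        feasible = dist <= (reach[:, None] + reach[None, :])
        # missing lengths impose no constraint
        feasible |= np.isnan(reach)[:, None] | np.isnan(reach)[None, :]

        syn = conn.syn.copy()
        post, pre = np.nonzero(syn)  # A[i, j]: j -> i
        syn_edges = np.column_stack([pre, post])  # directed (pre, post)
        adj_dir = np.zeros_like(syn)
        adj_dir[syn_edges[:, 0], syn_edges[:, 1]] = 1
        acc_s = _swap_directed(syn_edges, adj_dir, feasible, n_swaps, rng)

        gap = conn.gap.copy()
        gi, gj = np.nonzero(np.triu(gap))
        gap_edges = np.column_stack([gi, gj])
        acc_g = _swap_undirected(gap_edges, gap, feasible, n_swaps, rng)

        if min(acc_s, acc_g) < 0.1 * n_swaps:
            logger.warning("realization %d: low swap acceptance (syn=%d, gap=%d "
                           "of %d attempts)", r, acc_s, acc_g, n_swaps)
        else:
            logger.debug("realization %d: accepted syn=%d gap=%d", r, acc_s, acc_g)
        yield Connectome(list(conn.neurons), adj_dir.T, gap)


def homophily_zscore(x_emp: float, ensemble_samples) -> float:
    """z = (x_emp - mean) / population-sd of the surrogate samples.

    NaN when the ensemble variance is zero (reported as undefined).
    """
    s = np.asarray(list(ensemble_samples), dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 ensemble samples")
    sd = s.std()
    if sd == 0:
        return float("nan")
    return float((x_emp - s.mean()) / sd)


@dataclass
class HomophilyResult:
    """Empirical modularity with its surrogate calibration."""

    Q: float
    Q_pairs: pd.DataFrame
    surrogate_mean: float
    surrogate_sd: float
    z: float
    ensemble: str
    n_real: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "statistic": "Q", "value": self.Q,
            "surrogate_mean": self.surrogate_mean,
            "surrogate_sd": self.surrogate_sd, "z": self.z,
            "ensemble": self.ensemble, "n_real": self.n_real,
            "seed": self.seed,
        }])


def homophily_report(conn: Connectome, labels, graph: str = "syn",
                     n_real: int = 100, seed: int = 0) -> HomophilyResult:
    """Modularity of an attribute partition against the label-shuffle null."""
    q = modularity(conn, labels, graph)
    qp = class_pair_modularity(conn, labels, graph)
    lab = _align_labels(conn, labels)
    keep = np.array([l is not None and not (isinstance(l, float) and np.isnan(l))
                     for l in lab])
    sub = Connectome(
        [n for n, k in zip(conn.neurons, keep) if k],
        conn.syn[np.ix_(keep, keep)], conn.gap[np.ix_(keep, keep)])
    samples = [modularity(sub, perm, graph)
               for perm in shuffle_attribute_surrogate(lab[keep], n_real, seed)]
    mu, sd = float(np.mean(samples)), float(np.std(samples))
    return HomophilyResult(
        Q=q, Q_pairs=qp, surrogate_mean=mu, surrogate_sd=sd,
        z=homophily_zscore(q, samples), ensemble="attribute_shuffle",
        n_real=n_real, seed=seed,
    )


@dataclass
class CohortStratumResult:
    """Birth-cohort connection counts in one cell-body-distance stratum."""

    stratum: str
    n_pairs: int
    counts: pd.Series            # connected-pair counts by epoch combination
    surrogate_mean: pd.Series
    surrogate_sd: pd.Series
    z: pd.Series
    homophily_flag: bool         # same-cohort counts exceed the null envelope
    distances: dict[str, np.ndarray]  # connected-pair d per epoch combination


def _epoch_counts(a: np.ndarray, cohort: np.ndarray, mask: np.ndarray
                  ) -> tuple[pd.Series, dict[str, np.ndarray]]:
    conn_pairs = (a + a.T) > 0
    labels = ("early-early", "early-late", "late-late")
    counts = dict.fromkeys(labels, 0)
    where = {k: [] for k in labels}
    ii, jj = np.nonzero(np.triu(conn_pairs & mask, k=1))
    for i, j in zip(ii, jj):
        if cohort[i] not in ("early", "late") or cohort[j] not in ("early", "late"):
            continue
        both = {cohort[i], cohort[j]}
        key = ("early-early" if both == {"early"} else
               "late-late" if both == {"late"} else "early-late")
        counts[key] += 1
        where[key].append((i, j))
    return pd.Series(counts), where


def birth_cohort_analysis(conn: Connectome, table: NeuronTable,
                          graph: str = "syn", n_real: int = 20,
                          n_swaps: int = 20_000, seed: int = 0,
                          body_length: float | None = None
                          ) -> list[CohortStratumResult]:
    """Cohort mixing of connected pairs, stratified by cell-body distance.

    Pairs are stratified into d < L/3, L/3 <= d < 2L/3 and d >= 2L/3 of the
    body length.  In each stratum the counts of connected pairs that are
    early-early / early-late / late-late are compared with the
    degree-preserving reach-constrained rewiring ensemble; a stratum is
    flagged when an empirical same-cohort count exceeds the surrogate mean
    by more than two surrogate standard deviations.  Connected-pair
    distance samples split by epoch combination are also returned.
    """
    table.require("cohort", "birth-cohort analysis")
    pos = table.positions()
    order = [table.names.index(n) for n in conn.neurons]
    pos = pos[order]
    cohort = table.column("cohort").reindex(conn.neurons).to_numpy(dtype=object)
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    L = table.body_length if body_length is None else body_length
    strata = {
        "short (d < L/3)": dist < L / 3,
        "medium (L/3 <= d < 2L/3)": (dist >= L / 3) & (dist < 2 * L / 3),
        "long (d >= 2L/3)": dist >= 2 * L / 3,
    }
    a_emp = conn.matrix(graph)
    sur_counts = {k: [] for k in strata}
    for sur in constrained_rewire_surrogate(conn, table, n_swaps=n_swaps,
                                            n_real=n_real, seed=seed,
                                            body_length=body_length):
        a = sur.matrix(graph)
        for sname, mask in strata.items():
            counts, _ = _epoch_counts(a, cohort, mask)
            sur_counts[sname].append(counts)

    results = []
    for sname, mask in strata.items():
        counts, where = _epoch_counts(a_emp, cohort, mask)
        sur = pd.DataFrame(sur_counts[sname])
        mu, sd = sur.mean(), sur.std(ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (counts - mu) / sd
        same = counts[["early-early", "late-late"]]
        flag = bool(((same - mu[same.index]) > 2 * sd[same.index]).any())
        distances = {k: np.array([dist[i, j] for i, j in v]) for k, v in where.items()}
        results.append(CohortStratumResult(
            stratum=sname, n_pairs=int(counts.sum()), counts=counts,
            surrogate_mean=mu, surrogate_sd=sd, z=z,
            homophily_flag=flag, distances=distances,
        ))
    return results
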