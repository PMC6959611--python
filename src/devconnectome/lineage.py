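"""Cell-lineage tree metrics from Sulston-style lineage names.

A lineage name encodes the full division path of a cell: a founder
blastomere token (``AB``, ``MS``, ``C`` ...) followed by lowercase letters
from ``{a, p, l, r, d, v}``, one per division (e.g. ``ABprpapaap``).  The
*rung* of a cell is its number of divisions from the zygote P0; for AB
descendants this is 1 (AB itself) plus the number of trailing letters.
The *lineage distance* l between two cells is the number of divisions
leading to each from their last common progenitor, summed — computable
directly from the longest common prefix of the two division paths, so no
external lineage database is required.

Almost all somatic neurons descend from AB; the handful from other founders
(MS, C, ...) are handled through a built-in table of founder depths taken
from standard nematode embryology (P0 -> AB + P1; P1 -> EMS + P2;
EMS -> MS + E; P2 -> C + P3; P3 -> D + P4), overridable per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "rung_of", "lineage_distance", "max_lineage_distance", "division_path",
    "LineageTree", "build_lineage_tree", "ganglion_lineage_stats",
    "GanglionLineageStats", "chrono_dendrogram_export",
]

DIVISION_LETTERS = frozenset("aplrdv")

#: division path from the zygote P0 to each founder blastomere
FOUNDER_PATHS: dict[str, tuple[str, ...]] = {
    "P0": (),
    "AB": ("AB",),
    "P1": ("P1",),
    "EMS": ("P1", "EMS"),
    "P2": ("P1", "P2"),
    "MS": ("P1", "EMS", "MS"),
    "E": ("P1", "EMS", "E"),
    "C": ("P1", "P2", "C"),
    "P3": ("P1", "P2", "P3"),
    "D": ("P1", "P2", "P3", "D"),
    "P4": ("P1", "P2", "P3", "P4"),
    "Z2": ("P1", "P2", "P3", "P4", "Z2"),
    "Z3": ("P1", "P2", "P3", "P4", "Z3"),
}


class LineageNameError(ValueError):
    """Raised for a lineage name that cannot be parsed."""


def _split(name: str) -> tuple[str, str]:
    """Split a lineage name into (founder token, division letters)."""
    if not name:
        raise LineageNameError("empty lineage name")
    i = 0
    while i < len(name) and not name[i].islower():
        i += 1
    founder, letters = name[:i], name[i:]
    if founder not in FOUNDER_PATHS:
        raise LineageNameError(f"unknown founder token {founder!r} in {name!r}")
    bad = set(letters) - DIVISION_LETTERS
    if bad:
        raise LineageNameError(
            f"invalid division letter(s) {sorted(bad)} in {name!r}")
    return founder, letters


def division_path(name: str,
                  founder_paths: dict[str, tuple[str, ...]] | None = None
                  ) -> tuple[str, ...]:
    """Full division path from P0; its length equals the cell's rung."""
    paths = FOUNDER_PATHS if founder_paths is None else founder_paths
    i = 0
    while i < len(name) and not name[i].islower():
        i += 1
    founder, letters = name[:i], name[i:]
    if founder not in paths:
        raise LineageNameError(f"unknown founder token {founder!r} in {name!r}")
    bad = set(letters) - DIVISION_LETTERS
    if bad:
        raise LineageNameError(
            f"invalid division letter(s) {sorted(bad)} in {name!r}")
    return tuple(paths[founder]) + tuple(letters)


def rung_of(name: str) -> int:
    """Number of cell divisions from the zygote (AB counts as one letter)."""
    return len(division_path(name))


def lineage_distance(a: str, b: str) -> int:
    """Cell divisions separating two cells via their last common progenitor.

    Counts the dividing progenitors on the tree path between the cells.
    The division of the common progenitor itself is shared by both
    lineages and counted once, so for cells at rungs R_a, R_b with the
    progenitor at rung k the distance is (R_a - k) + (R_b - k) - 1.  Two
    distinct cells on the same rung therefore always have an odd distance,
    and the distance between an ancestor and its descendant is their rung
    difference.  Zero iff the names are identical; symmetric; a metric on
    leaf names.
    """
    pa, pb = division_path(a), division_path(b)
    k = 0
    for x, y in zip(pa, pb):
        if x != y:
            break
        k += 1
    da, db = len(pa) - k, len(pb) - k
    if da == 0 and db == 0:
        return 0
    if da == 0 or db == 0:  # ancestor-descendant
        return da + db
    return da + db - 1


def max_lineage_distance(r1: int, r2: int) -> int | None:
    """Largest lineage distance between two AB-sublineage cells at given rungs.

    Within the AB sublineage the last common progenitor of two distinct
    cells lies at rung >= 1, hence l_max = (R1 - 1) + (R2 - 1) - 1.  For the
    degenerate case R1 = R2 = 1 (AB itself twice) the formula is negative
    and ``None`` is returned ("same cell / undefined").
    """
    if r1 < 1 or r2 < 1:
        raise ValueError("rungs must be >= 1")
    val = (r1 - 1) + (r2 - 1) - 1
    return None if val < 0 else val


# ---------------------------------------------------------------------------
# tree construction


@dataclass
class TreeNode:
    name: str
    rung: int
    parent: str | None
    time: float | None = None
    time_imputed: bool = False
    children: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


def _path_name(path: tuple[str, ...]) -> str:
    """Canonical name of the cell at a division path."""
    if not path:
        return "P0"
    # last founder token followed by division letters
    k = len(path)
    while k > 0 and path[k - 1].islower():
        k -= 1
    return path[k - 1] + "".join(path[k:])


class LineageTree:
    """Rooted tree of cell divisions materialized from leaf lineage names."""

    def __init__(self, nodes: dict[str, TreeNode], root: str = "P0"):
        self.nodes = nodes
        self.root = root

    @property
    def leaves(self) -> list[str]:
        return [n for n, node in self.nodes.items() if node.is_leaf]

    def rung(self, name: str) -> int:
        return self.nodes[name].rung

    def distance_matrix(self, names: list[str] | None = None
                        ) -> tuple[np.ndarray, list[str]]:
        """Pairwise lineage distances between the given cells (default: leaves)."""
        names = self.leaves if names is None else names
        paths = [division_path(n) for n in names]
        m = len(names)
        d = np.zeros((m, m), dtype=int)
        for i in range(m):
            for j in range(i + 1, m):
                pa, pb = paths[i], paths[j]
                k = 0
                for x, y in zip(pa, pb):
                    if x != y:
                        break
                    k += 1
                da, db = len(pa) - k, len(pb) - k
                if da and db:
                    d[i, j] = d[j, i] = da + db - 1
                else:
                    d[i, j] = d[j, i] = da + db
        return d, names

    def pairwise_distance_histogram(self) -> pd.Series:
        d, _ = self.distance_matrix()
        vals = d[np.triu_indices_from(d, k=1)]
        return pd.Series(vals).value_counts().sort_index()

    def to_newick(self) -> str:
        """Newick string; branch lengths are inter-division times when known."""
        def render(name: str) -> str:
            node = self.nodes[name]
            label = name
            if node.parent is not None:
                pt, ct = self.nodes[node.parent].time, node.time
                if pt is not None and ct is not None:
                    label += f":{max(ct - pt, 0.0):g}"
            if node.is_leaf:
                return label
            inner = ",".join(render(c) for c in sorted(node.children))
            return f"({inner}){label}"
        return render(self.root) + ";"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"name": n.name, "rung": n.rung, "parent": n.parent,
             "time": n.time, "time_imputed": n.time_imputed,
             "is_leaf": n.is_leaf}
            for n in self.nodes.values()
        ]
        return pd.DataFrame(rows).sort_values(["rung", "name"]).reset_index(drop=True)


def build_lineage_tree(table, division_times: dict[str, float] | None = None
                       ) -> LineageTree:
    """Materialize the division tree implied by a neuron table's lineage names.

    Leaf times come from ``birth_time``.  Internal-node times come from
    ``division_times`` when supplied; otherwise they are linearly
    interpolated between the zygote (t = 0) and the earliest descendant
    leaf, and flagged ``time_imputed`` (used only for chrono-dendrogram
    rendering, never for statistics).
    """
    df = table.df
    if df["lineage_name"].isna().any():
        missing = list(df.loc[df["lineage_name"].isna(), "name"])
        raise ValueError(f"lineage_name missing for {missing}")
    dup = df["lineage_name"][df["lineage_name"].duplicated()]
    if len(dup):
        raise ValueError(f"two neurons share lineage name(s): {sorted(set(dup))}")

    division_times = division_times or {}
    nodes: dict[str, TreeNode] = {"P0": TreeNode("P0", 0, None, time=0.0)}
    leaf_time: dict[str, float] = {}
    for lname, btime in zip(df["lineage_name"], df["birth_time"]):
        path = division_path(lname)
        for r in range(1, len(path) + 1):
            name = _path_name(path[:r])
            if name not in nodes:
                parent = _path_name(path[:r - 1])
                nodes[name] = TreeNode(name, r, parent)
                nodes[parent].children.append(name)
        leaf = _path_name(path)
        if not pd.isna(btime):
            leaf_time[leaf] = float(btime)

    tree = LineageTree(nodes)
    assign_node_times(tree, leaf_time, division_times)
    return tree


def assign_node_times(tree: LineageTree, leaf_time: dict[str, float],
                      division_times: dict[str, float] | None = None) -> None:
    """Set node times in place: leaves from ``leaf_time``, internal nodes
    from ``division_times`` when given, else linearly interpolated between
    the zygote (t = 0) and the earliest descendant leaf and flagged
    imputed."""
    division_times = division_times or {}
    nodes = tree.nodes

    def earliest_leaf_below(name: str) -> tuple[float, int] | None:
        node = nodes[name]
        if node.is_leaf:
            t = leaf_time.get(name)
            return None if t is None else (t, node.rung)
        best = None
        for c in node.children:
            sub = earliest_leaf_below(c)
            if sub is not None and (best is None or sub[0] < best[0]):
                best = sub
        return best

    for name, node in nodes.items():
        if node.is_leaf:
            node.time = leaf_time.get(name)
        elif name in division_times:
            node.time = float(division_times[name])
        elif name == tree.root:
            node.time = 0.0
        else:
            anchor = earliest_leaf_below(name)
            if anchor is not None:
                t_leaf, r_leaf = anchor
                node.time = t_leaf * node.rung / r_leaf
                node.time_imputed = True


# ---------------------------------------------------------------------------
# ganglion-level statistics with a leaf-permutation null


@dataclass
class GanglionLineageStats:
    """Per ganglion-pair lineage-distance statistics and null z-scores.

    Each frame is symmetric and indexed by ganglion label; the diagonal
    holds intra-ganglionic values.  ``z_mean``/``z_cv`` compare the
    empirical mean and coefficient of variation with an ensemble of trees
    whose leaf labels were randomly swapped (preserving the multiset of
    pairwise distances exactly).
    """

    mean_l: pd.DataFrame
    cv_l: pd.DataFrame
    z_mean: pd.DataFrame
    z_cv: pd.DataFrame
    n_real: int
    seed: int


def _group_stats(dmat: np.ndarray, idx: dict[str, np.ndarray],
                 ganglia: list[str]) -> tuple[np.ndarray, np.ndarray]:
    g = len(ganglia)
    mean = np.full((g, g), np.nan)
    cv = np.full((g, g), np.nan)
    for a in range(g):
        for b in range(a, g):
            ia, ib = idx[ganglia[a]], idx[ganglia[b]]
            if a == b:
                if len(ia) < 2:
                    continue  # intra stats undefined
                sub = dmat[np.ix_(ia, ia)]
                vals = sub[np.triu_indices(len(ia), k=1)]
            else:
                vals = dmat[np.ix_(ia, ib)].ravel()
            if len(vals) == 0:
                continue
            m = vals.mean()
            mean[a, b] = mean[b, a] = m
            if m > 0:
                cv[a, b] = cv[b, a] = vals.std() / m
    return mean, cv


def ganglion_lineage_stats(tree: LineageTree, table, n_real: int = 1000,
                           n_swaps: int = 10_000, seed: int = 0
                           ) -> GanglionLineageStats:
    """Intra/inter-ganglion lineage-distance means and CVs with null z-scores.

    The null exchanges leaf positions on the tree: each realization applies
    ``n_swaps`` random pairwise swaps of the neuron -> leaf assignment,
    decoupling ganglion membership from tree position while keeping the
    global multiset of pairwise distances invariant.
    """
    table.require("ganglion", "ganglion lineage statistics")
    df = table.df.dropna(subset=["ganglion", "lineage_name"])
    names = list(df["lineage_name"])
    dmat, _ = tree.distance_matrix(names)
    ganglia = sorted(df["ganglion"].unique())
    positions = np.arange(len(names))
    idx = {g: np.flatnonzero((df["ganglion"] == g).to_numpy()) for g in ganglia}

    emp_mean, emp_cv = _group_stats(dmat, idx, ganglia)

    rng = np.random.default_rng(seed)
    n = len(names)
    means = np.empty((n_real,) + emp_mean.shape)
    cvs = np.empty_like(means)
    for r in range(n_real):
        perm = positions.copy()
        ii = rng.integers(0, n, size=n_swaps)
        jj = rng.integers(0, n, size=n_swaps)
        for i, j in zip(ii, jj):
            perm[i], perm[j] = perm[j], perm[i]
        pmat = dmat[np.ix_(perm, perm)]
        means[r], cvs[r] = _group_stats(pmat, idx, ganglia)

    def zscore(emp, samples):
        mu = samples.mean(axis=0)
        sd = samples.std(axis=0)  # population convention
        with np.errstate(invalid="ignore", divide="ignore"):
            return (emp - mu) / sd

    wrap = lambda a: pd.DataFrame(a, index=ganglia, columns=ganglia)
    return GanglionLineageStats(
        mean_l=wrap(emp_mean), cv_l=wrap(emp_cv),
        z_mean=wrap(zscore(emp_mean, means)), z_cv=wrap(zscore(emp_cv, cvs)),
        n_real=n_real, seed=seed,
    )


def chrono_dendrogram_export(tree: LineageTree,
                             highlight: set[str] | list[str] = ()
                             ) -> pd.DataFrame:
    """Per-node table (name, rung, time, parent, highlighted) for plotting.

    A chrono-dendrogram lays the tree out cylindrically with division time
    on the vertical axis and rung on the radial axis; this table is the
    complete data behind such a rendering.
    """
    highlight = set(highlight)
    out = tree.to_frame()
    out["highlighted"] = out["name"].isin(highlight)
    return out
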