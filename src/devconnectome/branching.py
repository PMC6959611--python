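"""Asymmetric stochastic branching model of the cell-lineage tree.

Each cell division produces at most two daughters, the two branches
occurring independently with probabilities P1 and P2 (P1 >= P2).  A node
that spawns neither branch is a terminal leaf (a differentiated neuron; the
model does not distinguish apoptosis or non-neural fates from absent
branches).  Proliferation drops sharply after an early near-binary phase:
the default profile uses P1 = 1, P2 = 0.85 up to a cutoff rung and
P1 = 0.25, P2 = 0.2 afterwards, values estimated from the empirical
*C. elegans* lineage tree.  The cutoff is configurable (default 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lineage import LineageTree, TreeNode

__all__ = ["BranchProfile", "simulate_tree", "estimate_branch_probs",
           "tree_summary_stats", "TreeSummary"]


@dataclass(frozen=True)
class BranchProfile:
    """Per-rung branch probabilities, piecewise-constant around a cutoff.

    ``p1(r)``/``p2(r)`` give the probability that the first/second branch
    occurs at a division out of rung ``r``.  Probabilities before the
    cutoff rung (exclusive) are (p1_early, p2_early); from the cutoff on
    they are (p1_late, p2_late).
    """

    p1_early: float = 1.0
    p2_early: float = 0.85
    p1_late: float = 0.25
    p2_late: float = 0.2
    cutoff: int = 10

    def __post_init__(self):
        for a, b in ((self.p1_early, self.p2_early), (self.p1_late, self.p2_late)):
            if not (0.0 <= b <= a <= 1.0):
                raise ValueError("need 0 <= P2 <= P1 <= 1 in each regime")

    def p1(self, rung: int) -> float:
        return self.p1_early if rung < self.cutoff else self.p1_late

    def p2(self, rung: int) -> float:
        return self.p2_early if rung < self.cutoff else self.p2_late


def simulate_tree(profile: BranchProfile, max_rung: int = 16,
                  seed: int | np.random.Generator = 0) -> LineageTree:
    """Grow one realization of the branching process into a lineage tree.

    Starting from a single root, every frontier node at rung r spawns
    branch 1 with probability ``p1(r)`` and, independently, branch 2 with
    probability ``p2(r)``.  ``max_rung`` guards against non-termination
    under pathological profiles (the empirical tree reaches rung 14).
    Node names follow the lineage-string convention with daughters labelled
    'a' and 'p', so simulated trees serialize exactly like parsed ones.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes: dict[str, TreeNode] = {"P0": TreeNode("P0", 0, None)}
    frontier = ["P0"]
    while frontier:
        nxt = []
        for name in frontier:
            rung = nodes[name].rung
            if rung >= max_rung:
                continue
            u1, u2 = rng.random(2)
            branches = []
            if u1 < profile.p1(rung):
                branches.append("a")
            if u2 < profile.p2(rung):
                branches.append("p")
            base = "" if name == "P0" else name
            for letter in branches:
                child = ("AB" if name == "P0" and letter == "a" else
                         "P1" if name == "P0" else base + letter)
                nodes[child] = TreeNode(child, rung + 1, name)
                nodes[name].children.append(child)
                nxt.append(child)
        frontier = nxt
    return LineageTree(nodes)


def estimate_branch_probs(tree: LineageTree) -> pd.DataFrame:
    """Per-rung branch-probability estimates from an observed tree.

    At each rung the observable quantities are ``p_any``, the fraction of
    nodes with at least one child (= P1 + P2 - P1*P2 under independent
    branches), and ``p_both``, the fraction with two children (= P1*P2).
    Inverting those two moments gives the estimates: P1-hat and P2-hat are
    the roots of x^2 - (p_any + p_both) x + p_both, with P1-hat >= P2-hat
    by construction.  In the near-binary regime (P1 = 1) this reduces to
    reading P1-hat = p_any and P2-hat = p_both directly.  Rungs with no
    nodes are absent from the result.
    """
    counts: dict[int, list[int]] = {}
    for node in tree.nodes.values():
        n_nodes, n_any, n_both = counts.setdefault(node.rung, [0, 0, 0])
        counts[node.rung] = [
            n_nodes + 1,
            n_any + (len(node.children) >= 1),
            n_both + (len(node.children) == 2),
        ]
    rows = []
    for r, (n, k_any, k_both) in sorted(counts.items()):
        f_any, f_both = k_any / n, k_both / n
        s = f_any + f_both                     # estimates P1 + P2
        disc = max(s * s - 4 * f_both, 0.0)    # sampling noise can dip below 0
        root = np.sqrt(disc)
        rows.append({"rung": r, "n_nodes": n, "p_any": f_any,
                     "p_both": f_both,
                     "p1_hat": min((s + root) / 2, 1.0),
                     "p2_hat": max((s - root) / 2, 0.0)})
    return pd.DataFrame(rows)


@dataclass
class TreeSummary:
    """Leaf count, per-rung occupancy and pairwise-distance histogram."""

    n_leaves: int
    rung_counts: pd.Series
    l_histogram: pd.Series
    expected_rung_counts: pd.Series | None = None


def tree_summary_stats(tree: LineageTree,
                       profile: BranchProfile | None = None) -> TreeSummary:
    """Summaries used to compare simulated and observed trees.

    When a profile is given, the expected number of nodes at rung r under
    the branching process, prod_{s<r} (P1(s) + P2(s)), is included for
    comparison with the realized occupancy.
    """
    rungs = pd.Series([n.rung for n in tree.nodes.values()])
    rung_counts = rungs.value_counts().sort_index()
    leaves = tree.leaves
    if len(leaves) >= 2:
        l_hist = tree.pairwise_distance_histogram()
    else:
        l_hist = pd.Series(dtype=int)
    expected = None
    if profile is not None:
        max_r = int(rung_counts.index.max())
        vals, running = [], 1.0
        for r in range(max_r + 1):
            vals.append(running)
            running *= profile.p1(r) + profile.p2(r)
        expected = pd.Series(vals, index=range(max_r + 1))
    return TreeSummary(
        n_leaves=len(leaves),
        rung_counts=rung_counts,
        l_histogram=l_hist,
        expected_rung_counts=expected,
    )
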