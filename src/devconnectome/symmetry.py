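"""Bilateral-pair connectivity, lineage parity and neighborhood overlap.

Roughly two thirds of somatic neurons come in left/right mirror pairs.
This module measures how exceptional those pairs are: the probability that
partners share a synapse (either direction), a reciprocal synapse, or a gap
junction, against the same probabilities over all unordered pairs; the
parity of the lineage distance between partners (same-rung mirror cells
have odd distances by construction, so even values are exceptions worth
listing); and the Jaccard overlap of the partners' synaptic/gap
neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Connectome, NeuronTable
from .lineage import lineage_distance

__all__ = ["PairStats", "pair_connection_stats", "neighborhood_jaccard",
           "jaccard_ccdf_populations", "pair_lineage_parity", "ParitySummary"]


@dataclass
class PairStats:
    """Connection probabilities among bilateral pairs vs all pairs."""

    n_pairs: int
    p_syn_pair: float
    p_syn_recip: float
    p_gap_pair: float
    p_syn_all: float
    p_syn_recip_all: float
    p_gap_all: float
    by_origin: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"population": "bilateral pairs", "n": self.n_pairs,
             "p_syn": self.p_syn_pair, "p_recip": self.p_syn_recip,
             "p_gap": self.p_gap_pair},
            {"population": "all pairs", "n": None,
             "p_syn": self.p_syn_all, "p_recip": self.p_syn_recip_all,
             "p_gap": self.p_gap_all},
        ])


def pair_connection_stats(conn: Connectome, table: NeuronTable) -> PairStats:
    """Synapse / reciprocal-synapse / gap-junction rates for bilateral pairs.

    "Connected by synapse" counts either direction; reciprocity requires
    both.  Baselines are computed over all unordered neuron pairs.  When a
    ``sym_origin`` column is present the pair rates are also broken down by
    symmetric- vs nonsymmetric-blastomere origin.
    """
    pairs = table.bilateral_pairs()
    if not pairs:
        raise ValueError("no bilateral pairs in the table")
    a, g = conn.syn, conn.gap
    either = (a + a.T) > 0
    recip = (a * a.T) > 0

    def rate(mat, idx_pairs):
        return float(np.mean([mat[i, j] for i, j in idx_pairs]))

    idx_pairs = [(conn.index[x], conn.index[y]) for x, y in pairs
                 if x in conn.index and y in conn.index]
    n = len(conn.neurons)
    iu = np.triu_indices(n, k=1)
    stats = PairStats(
        n_pairs=len(idx_pairs),
        p_syn_pair=rate(either, idx_pairs),
        p_syn_recip=rate(recip, idx_pairs),
        p_gap_pair=rate(g > 0, idx_pairs),
        p_syn_all=float(either[iu].mean()),
        p_syn_recip_all=float(recip[iu].mean()),
        p_gap_all=float((g > 0)[iu].mean()),
    )
    if table.has("sym_origin"):
        origin = table.column("sym_origin")
        rows = []
        for cls in ("symmetric_blastomere", "nonsymmetric_blastomere"):
            sel = [(i, j) for (x, y), (i, j) in zip(pairs, idx_pairs)
                   if origin.get(x) == cls]
            if not sel:
                continue
            rows.append({"sym_origin": cls, "n": len(sel),
                         "p_syn": rate(either, sel),
                         "p_recip": rate(recip, sel),
                         "p_gap": rate(g > 0, sel)})
        stats.by_origin = pd.DataFrame(rows)
    return stats


def _neighbor_sets(conn: Connectome, mode: str) -> list[set[int]]:
    if mode == "pre":
        mat = conn.syn        # row i lists the pre-synaptic partners of i
    elif mode == "post":
        mat = conn.syn.T      # row i lists the neurons i projects to
    elif mode == "gap":
        mat = conn.gap
    else:
        raise ValueError("mode must be 'pre', 'post' or 'gap'")
    return [set(np.flatnonzero(row)) for row in mat]


def neighborhood_jaccard(conn: Connectome, mode: str = "pre") -> pd.DataFrame:
    """Jaccard overlap J(i, j) = |N(i) & N(j)| / |N(i) | N(j)| per mode.

    ``mode`` selects the neighborhood: incoming synaptic partners
    ('pre'), outgoing targets ('post'), or gap-junction partners ('gap').
    J is NaN where both neighborhoods are empty, 1 on the diagonal for
    nonempty neighborhoods.
    """
    sets = _neighbor_sets(conn, mode)
    n = len(sets)
    j = np.full((n, n), np.nan)
    for i in range(n):
        for k in range(i, n):
            union = sets[i] | sets[k]
            if union:
                j[i, k] = j[k, i] = len(sets[i] & sets[k]) / len(union)
    return pd.DataFrame(j, index=conn.neurons, columns=conn.neurons)


def jaccard_ccdf_populations(conn: Connectome, table: NeuronTable,
                             mode: str = "pre",
                             proximity_mm: float = 0.05) -> dict[str, np.ndarray]:
    """Jaccard samples for three pair populations: bilateral, all, proximate.

    Proximate pairs are those whose cell bodies lie within ``proximity_mm``
    of each other.  The returned samples (NaN entries dropped) are the data
    behind complementary-cumulative-distribution comparisons.
    """
    j = neighborhood_jaccard(conn, mode).to_numpy()
    n = len(conn.neurons)
    iu = np.triu_indices(n, k=1)
    allv = j[iu]
    pos = table.positions()
    order = [table.names.index(nm) for nm in conn.neurons]
    pos = pos[order]
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    prox = j[iu][dist[iu] < proximity_mm]
    pair_idx = [(conn.index[x], conn.index[y]) for x, y in table.bilateral_pairs()
                if x in conn.index and y in conn.index]
    pairs = np.array([j[i, k] for i, k in pair_idx])
    clean = lambda v: v[~np.isnan(v)]
    return {"pairs": clean(pairs), "all": clean(allv), "proximate": clean(prox)}


@dataclass
class ParitySummary:
    """Lineage-distance parity between bilateral partners."""

    distances: pd.Series          # partner pair label -> lineage distance
    fraction_odd: float
    even_exceptions: list[str]


def pair_lineage_parity(table: NeuronTable) -> ParitySummary:
    """Distribution of lineage distance between partners, and its parity.

    Mirror-symmetric partners sit on the same rung of the lineage tree, so
    their distance is odd whenever they are distinct cells; even values
    signal pairs with non-symmetric lineage histories and are listed.
    """
    table.require("lineage_name", "pair lineage parity")
    lin = table.column("lineage_name")
    dists = {}
    for x, y in table.bilateral_pairs():
        lx, ly = lin.get(x), lin.get(y)
        if pd.isna(lx) or pd.isna(ly):
            continue
        dists[f"{x}/{y}"] = lineage_distance(lx, ly)
    s = pd.Series(dists, dtype=int)
    odd = s % 2 == 1
    return ParitySummary(
        distances=s,
        fraction_odd=float(odd.mean()) if len(s) else float("nan"),
        even_exceptions=sorted(s.index[~odd]),
    )
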