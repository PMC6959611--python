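"""Synthetic worm generator: lineage tree, attributes and connectome.

Produces complete datasets with the statistical structure the analysis
modules assume, so the whole pipeline runs and can be calibrated without
any external download.  A generated worm consists of:

1. a lineage tree from the asymmetric branching model (near-binary early
   proliferation, sharply reduced after the cutoff rung), sized to roughly
   the somatic neuron count;
2. bilateral partners: a configurable fraction of leaves matched into
   pairs within the same rung and birth cohort — same-rung distinct leaves
   automatically have odd lineage distances, with a configurable number of
   planted cross-rung (even-distance) exceptions;
3. bimodal birth times: leaves under a few "stalled" mid-rung progenitors
   differentiate late (larval stages L1-L3), the rest early (embryonic),
   reproducing the early/late burst structure;
4. positions: bimodal anterior-posterior mixtures for short- and
   long-process neurons (head and tail clusters), near-uniform for medium;
   small dorsal-ventral jitter with partners mirrored across the midline;
5. a connectome drawn dyad-by-dyad from the logistic connection model at
   planted coefficients (same process class, same cohort, partnership,
   lineage distance), optionally filtered by the physical reach constraint
   and overlaid with block-model module structure.

Everything planted is returned in a truth record for parameter-recovery
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .branching import BranchProfile, simulate_tree
from .io import Connectome, NeuronTable
from .lineage import LineageTree

__all__ = ["SyntheticConfig", "generate_worm", "simulate_dyads",
           "recovery_report"]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic worm.

    Planted coefficient vectors are ``(b0, b_p, b_b, b_s, b_l)`` on the
    log-odds scale; the defaults place the four homophily effects at the
    magnitudes reported for the real somatic nervous system, with
    intercepts chosen to give realistic connection densities (a few
    percent).  ``fraction_paired`` is the fraction of neurons living in
    bilateral pairs and ``fraction_early`` the fraction differentiating
    before hatching.
    """

    seed: int = 0
    profile: BranchProfile = field(
        default_factory=lambda: BranchProfile(cutoff=9))
    max_rung: int = 16
    fraction_paired: float = 0.66
    fraction_early: float = 0.72
    n_even_exceptions: int = 1
    t_hatch: float = 800.0
    t_max: float = 3400.0
    stage_bounds: tuple[float, float, float] = (1700.0, 2600.0, 3400.0)
    body_length: float = 1.1           # mm, anterior-posterior span
    dv_halfwidth: float = 0.03         # mm, dorsal-ventral jitter scale
    proc_class_probs: tuple[float, float, float] = (0.6, 0.2, 0.2)  # S, M, L
    beta_syn: tuple[float, ...] = (-3.0, 0.35, 0.71, 1.78, -0.06)
    beta_gap: tuple[float, ...] = (-3.5, 0.22, 0.16, 3.22, -0.08)
    apply_reach_constraint: bool = True
    n_modules: int | None = 6
    module_odds: float = 3.0
    early_hub_odds: float = 1.0        # >1 plants early high-degree neurons
    early_hub_fraction: float = 0.1
    n_ganglia: int = 10

    def validate(self) -> None:
        for name in ("fraction_paired", "fraction_early", "early_hub_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(sum(self.proc_class_probs) - 1.0) > 1e-9:
            raise ValueError("proc_class_probs must sum to 1")
        for b in (*self.beta_syn, *self.beta_gap):
            if not np.isfinite(b):
                raise ValueError("planted coefficients must be finite")
        if self.module_odds <= 0 or self.early_hub_odds <= 0:
            raise ValueError("odds multipliers must be positive")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _late_subtree_leaves(tree: LineageTree, rng, target_fraction: float
                         ) -> set[str]:
    """Pick mid-rung progenitors to stall until the leaf share is reached."""
    leaves = tree.leaves
    target = target_fraction * len(leaves)
    below: dict[str, list[str]] = {}

    def collect(name: str) -> list[str]:
        node = tree.nodes[name]
        if node.is_leaf:
            below[name] = [name]
        else:
            below[name] = [l for c in node.children for l in collect(c)]
        return below[name]

    collect(tree.root)
    candidates = [n for n, node in tree.nodes.items()
                  if not node.is_leaf and 6 <= node.rung <= 9]
    rng.shuffle(candidates)
    late: set[str] = set()
    for cand in candidates:
        if len(late) >= target:
            break
        sub = set(below[cand])
        if sub & late:
            continue
        if len(late) + len(sub) <= target * 1.15:
            late |= sub
    return late


def _pair_leaves(leaf_df: pd.DataFrame, cfg: SyntheticConfig, rng):
    """Match leaves into bilateral pairs within rung and cohort groups."""
    n_target = int(cfg.fraction_paired * len(leaf_df) / 2)
    partner = {name: None for name in leaf_df["lineage_name"]}
    pairs: list[tuple[str, str]] = []
    groups = leaf_df.groupby(["rung", "cohort"])["lineage_name"].apply(list)
    order = sorted(groups.index, key=lambda k: -len(groups[k]))
    for key in order:
        members = list(groups[key])
        rng.shuffle(members)
        while len(members) >= 2 and len(pairs) < n_target:
            a, b = members.pop(), members.pop()
            pairs.append((a, b))
        if len(pairs) >= n_target:
            break
    # planted even-distance exceptions: re-pair across adjacent rungs
    exceptions = []
    for _ in range(cfg.n_even_exceptions):
        if len(pairs) < 2:
            break
        (a1, b1), (a2, b2) = pairs.pop(), pairs.pop()
        r1 = leaf_df.set_index("lineage_name").loc[a1, "rung"]
        r2 = leaf_df.set_index("lineage_name").loc[a2, "rung"]
        if r1 != r2:
            pairs.append((a1, a2))
            pairs.append((b1, b2))
            exceptions.append((a1, a2))
            exceptions.append((b1, b2))
        else:  # same rung: keep original odd pairs
            pairs.extend([(a1, b1), (a2, b2)])
    for a, b in pairs:
        partner[a], partner[b] = b, a
    return partner, pairs, exceptions


def generate_worm(config: SyntheticConfig | None = None
                  ) -> tuple[NeuronTable, Connectome, LineageTree, dict]:
    """Generate one synthetic worm; returns (table, connectome, tree, truth)."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    tree = simulate_tree(cfg.profile, max_rung=cfg.max_rung, seed=rng)
    leaves = tree.leaves
    n = len(leaves)
    if n < 20:
        raise ValueError("degenerate branching realization: too few leaves; "
                         "choose a less extreme profile or another seed")

    late_leaves = _late_subtree_leaves(tree, rng, 1.0 - cfg.fraction_early)
    rungs = np.array([tree.rung(l) for l in leaves])
    cohort = np.array(["late" if l in late_leaves else "early" for l in leaves])

    # birth times: early branch linear in rung, late branch dispersed L1-L3
    t = np.empty(n)
    early = cohort == "early"
    slope = (cfg.t_hatch * 0.9) / max(rungs.max(), 1)
    t[early] = np.clip(slope * rungs[early]
                       + rng.normal(0, 0.04 * cfg.t_hatch, early.sum()),
                       1.0, cfg.t_hatch - 1)
    t[~early] = rng.uniform(cfg.t_hatch, cfg.t_max, (~early).sum())
    b1, b2, b3 = cfg.stage_bounds
    stage = np.where(t < cfg.t_hatch, "Embryo",
                     np.where(t < b1, "L1", np.where(t < b2, "L2", "L3")))

    leaf_df = pd.DataFrame({"lineage_name": leaves, "rung": rungs,
                            "cohort": cohort, "birth_time": t,
                            "birth_stage": stage})
    partner_lin, pairs, exceptions = _pair_leaves(leaf_df, cfg, rng)

    # process classes: identical within a pair
    cats = rng.choice(["S", "M", "L"], size=n, p=cfg.proc_class_probs)
    lin_index = {l: i for i, l in enumerate(leaves)}
    for a, b in pairs:
        cats[lin_index[b]] = cats[lin_index[a]]

    # positions: bimodal AP for S/L, uniform for M; partners mirrored in DV
    Lb = cfg.body_length
    x = np.empty(n)
    for i in range(n):
        if cats[i] == "M":
            x[i] = rng.uniform(0, Lb)
        else:
            if rng.random() < 0.75:
                x[i] = rng.normal(0.1 * Lb, 0.05 * Lb)
            else:
                x[i] = rng.normal(0.9 * Lb, 0.05 * Lb)
    x = np.clip(x, 0, Lb)
    y = rng.normal(0, cfg.dv_halfwidth, n) + cfg.dv_halfwidth
    for a, b in pairs:
        ia, ib = lin_index[a], lin_index[b]
        x[ib] = np.clip(x[ia] + rng.normal(0, 0.005 * Lb), 0, Lb)
        y[ib] = -y[ia]
    # pin the AP extremes so the realized span equals the body length
    x[np.argmin(x)] = 0.0
    x[np.argmax(x)] = Lb

    # functional types: motor neurons dominate the late burst
    def draw_types(mask, probs):
        return rng.choice(["sensory", "inter", "motor", "polymodal"],
                          size=mask.sum(), p=probs)
    func = np.empty(n, dtype=object)
    func[early] = draw_types(early, (0.35, 0.38, 0.22, 0.05))
    func[~early] = draw_types(~early, (0.10, 0.12, 0.75, 0.03))

    # ganglia: leaves inherit their rung-4 ancestor's clade, clades are
    # distributed round-robin over the ganglia (several 'families' each)
    clade_of = {}
    for l in leaves:
        node = l
        while tree.nodes[node].rung > 4 and tree.nodes[node].parent:
            node = tree.nodes[node].parent
        clade_of[l] = node
    clades = sorted(set(clade_of.values()))
    gmap = {c: f"G{(i % cfg.n_ganglia) + 1}" for i, c in enumerate(clades)}
    ganglion = np.array([gmap[clade_of[l]] for l in leaves])

    # module labels for the mesoscopic-role analyses
    if cfg.n_modules:
        modules = rng.integers(1, cfg.n_modules + 1, size=n)
        for a, b in pairs:
            modules[lin_index[b]] = modules[lin_index[a]]
    else:
        modules = np.full(n, np.nan)

    # circuit memberships at pair level; F4-F6 complete before hatching
    circuits = [[] for _ in range(n)]
    units = [(lin_index[a], lin_index[b]) for a, b in pairs]
    units += [(i,) for i, l in enumerate(leaves) if partner_lin[l] is None]
    early_units = [u for u in units if all(cohort[i] == "early" for i in u)]
    for k in range(1, 10):
        pool = early_units if k in (4, 5, 6) else units
        size = min(rng.integers(5, 13), len(pool))
        chosen = rng.choice(len(pool), size=size, replace=False)
        for ui in chosen:
            for i in pool[ui]:
                circuits[i].append(f"F{k}")

    names = [f"SYN{i:03d}" for i in range(n)]
    partner_names = [
        names[lin_index[partner_lin[l]]] if partner_lin[l] else pd.NA
        for l in leaves]
    lcp_rung = {(a, b): _lcp_depth(a, b) for a, b in pairs}
    sym_origin = []
    for i, l in enumerate(leaves):
        p = partner_lin[l]
        if p is None:
            sym_origin.append("unpaired")
        else:
            key = (l, p) if (l, p) in lcp_rung else (p, l)
            sym_origin.append("symmetric_blastomere" if lcp_rung[key] <= 3
                              else "nonsymmetric_blastomere")

    table = NeuronTable(pd.DataFrame({
        "name": names,
        "x_ap": x, "y_dv": y,
        "proc_cat": cats,
        "birth_time": t, "birth_stage": stage, "cohort": cohort,
        "lineage_name": leaves,
        "ganglion": ganglion,
        "func_type": func,
        "partner": partner_names,
        "sym_origin": sym_origin,
        "circuits": ["|".join(c) if c else pd.NA for c in circuits],
        "module_id": modules,
    }), t_hatch=cfg.t_hatch)

    from .lineage import assign_node_times
    assign_node_times(tree, dict(zip(leaves, t)))

    conn, reach_truth = _draw_connectome(table, tree, cfg, rng)

    truth = {
        "config": {**asdict(cfg), "profile": asdict(cfg.profile)},
        "n_neurons": n,
        "pairs": [(names[lin_index[a]], names[lin_index[b]]) for a, b in pairs],
        "even_exceptions": [(names[lin_index[a]], names[lin_index[b]])
                            for a, b in exceptions],
        "beta_syn": list(cfg.beta_syn),
        "beta_gap": list(cfg.beta_gap),
        **reach_truth,
    }
    return table, conn, tree, truth


def _lcp_depth(a: str, b: str) -> int:
    from .lineage import division_path
    pa, pb = division_path(a), division_path(b)
    k = 0
    for xx, yy in zip(pa, pb):
        if xx != yy:
            break
        k += 1
    return k


def _draw_connectome(table: NeuronTable, tree: LineageTree,
                     cfg: SyntheticConfig, rng) -> tuple[Connectome, dict]:
    df = table.df
    n = len(df)
    names = list(df["name"])
    cats = df["proc_cat"].to_numpy(dtype=object)
    coh = df["cohort"].to_numpy(dtype=object)
    partner = df["partner"].to_numpy(dtype=object)
    modules = df["module_id"].to_numpy()

    ldist, _ = tree.distance_matrix(list(df["lineage_name"]))
    xp = (cats[:, None] == cats[None, :]).astype(float)
    xb = (coh[:, None] == coh[None, :]).astype(float)
    xs = np.zeros((n, n))
    for i in range(n):
        if not pd.isna(partner[i]):
            j = names.index(partner[i])
            xs[i, j] = xs[j, i] = 1.0

    extra = np.zeros((n, n))
    if cfg.n_modules and cfg.module_odds != 1.0:
        same_mod = modules[:, None] == modules[None, :]
        extra += np.log(cfg.module_odds) * same_mod
    hub_flags = np.zeros(n, dtype=bool)
    if cfg.early_hub_odds != 1.0:
        early_idx = np.flatnonzero(coh == "early")
        k = max(1, int(cfg.early_hub_fraction * len(early_idx)))
        hubs = rng.choice(early_idx, size=k, replace=False)
        hub_flags[hubs] = True
        touched = hub_flags[:, None] | hub_flags[None, :]
        extra += np.log(cfg.early_hub_odds) * touched

    def logits(beta):
        b0, bp, bb, bs, bl = beta
        return b0 + bp * xp + bb * xb + bs * xs + bl * ldist + extra

    p_syn = _sigmoid(logits(cfg.beta_syn))
    p_gap = _sigmoid(logits(cfg.beta_gap))
    syn = (rng.random((n, n)) < p_syn).astype(np.int8)   # independent per direction
    gup = np.triu(rng.random((n, n)) < p_gap, k=1)
    gap = (gup | gup.T).astype(np.int8)
    np.fill_diagonal(syn, 0)
    np.fill_diagonal(gap, 0)

    reach_truth = {"process_lengths": None, "hub_neurons":
                   [names[i] for i in np.flatnonzero(hub_flags)]}
    if cfg.apply_reach_constraint:
        Lb = cfg.body_length
        lo = {"S": 0.0, "M": Lb / 3, "L": 2 * Lb / 3}
        lengths = np.array([rng.uniform(lo[c], lo[c] + Lb / 3) for c in cats])
        pos = df[["x_ap", "y_dv"]].to_numpy(dtype=float)
        dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        feasible = dist <= lengths[:, None] + lengths[None, :]
        syn = (syn.astype(bool) & feasible).astype(np.int8)
        gap = (gap.astype(bool) & feasible).astype(np.int8)
        reach_truth["process_lengths"] = dict(zip(names, lengths.tolist()))
    return Connectome(names, syn, gap), reach_truth


def simulate_dyads(beta: tuple[float, ...], n_dyads: int, seed: int = 0,
                   max_l: int = 25) -> pd.DataFrame:
    """Draw dyads straight from the logistic connection model.

    The pure parameter-recovery harness: predictors are sampled with
    realistic marginals (binary indicators, integer lineage distances in
    1..``max_l``) and the outcome follows the model exactly, with no reach
    filtering or network structure.
    """
    rng = np.random.default_rng(seed)
    xp = rng.random(n_dyads) < 0.45
    xb = rng.random(n_dyads) < 0.55
    xs = rng.random(n_dyads) < 0.01
    xl = rng.integers(1, max_l + 1, size=n_dyads)
    b0, bp, bb, bs, bl = beta
    p = _sigmoid(b0 + bp * xp + bb * xb + bs * xs + bl * xl)
    y = rng.random(n_dyads) < p
    return pd.DataFrame({"x_p": xp.astype(int), "x_b": xb.astype(int),
                         "x_s": xs.astype(int), "x_l": xl.astype(int),
                         "y": y.astype(int)})


def recovery_report(truth_beta: tuple[float, ...], fits: list,
                    level: float = 0.95) -> pd.DataFrame:
    """Planted-vs-estimated table with CI coverage over replicate fits.

    ``fits`` are :class:`~devconnectome.regression.LogisticFit` objects from
    replicate synthetic datasets; coverage is the fraction of replicates
    whose Wald interval at the given level contains the planted value.
    """
    from scipy import stats as sps
    zcrit = sps.norm.ppf(0.5 + level / 2)
    terms = ["const", "x_p", "x_b", "x_s", "x_l"]
    rows = []
    for term, planted in zip(terms, truth_beta):
        ests, covered = [], 0
        for f in fits:
            if term not in f.coefficients.index:
                continue
            est = f.coefficients.loc[term, "estimate"]
            se = f.coefficients.loc[term, "std_err"]
            ests.append(est)
            if abs(est - planted) <= zcrit * se:
                covered += 1
        rows.append({"term": term, "planted": planted,
                     "mean_estimate": float(np.mean(ests)) if ests else np.nan,
                     "bias": float(np.mean(ests) - planted) if ests else np.nan,
                     "coverage": covered / len(ests) if ests else np.nan,
                     "n_replicates": len(ests)})
    return pd.DataFrame(rows)
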