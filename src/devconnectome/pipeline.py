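"""One-command orchestration of all analysis stages with a run manifest.

``run_all`` executes the stages in dependency order — lineage, branching,
homophily, spatial, symmetry, regression, roles, circuits — on either a
loaded dataset or a generated synthetic worm, writing tidy CSV outputs and
a YAML manifest (config snapshot, per-stage seeds and effective sample
sizes, output hashes).  A single global seed fans out to independent
per-stage streams keyed by stage name, so adding a stage never perturbs
the randomness of the others.  Stages whose required columns are missing
are skipped with an explicit notice in the manifest.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, branching, circuits, homophily, roles, spatial, symmetry
from .io import Connectome, DataValidationError, NeuronTable, load_connectome, load_neuron_table
from .lineage import build_lineage_tree, chrono_dendrogram_export, ganglion_lineage_stats
from .regression import belsley_condition_indices, build_design, fit_logistic
from .synthetic import SyntheticConfig, generate_worm

logger = logging.getLogger(__name__)

__all__ = ["stage_seed", "run_all", "load_inputs"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31)


def load_inputs(config: dict) -> tuple[NeuronTable, Connectome]:
    table = load_neuron_table(config["neurons"],
                              t_hatch=config.get("t_hatch", 800.0))
    conn = load_connectome(config["synapses"], config["gap_junctions"], table)
    return table, conn


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(out_dir, seed: int = 0, config: dict | None = None,
            synthetic: bool = False, n_real: int = 50,
            rewire_swaps: int = 20_000, alpha: float = 0.05) -> Path:
    """Run every stage and write results plus a manifest under ``out_dir``.

    ``n_real`` and ``rewire_swaps`` size the surrogate ensembles for this
    run (the module defaults correspond to full-scale analyses).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or {}
    manifest: dict = {"version": __version__, "seed": seed,
                      "synthetic": synthetic, "stages": {}, "skipped": {}}

    if synthetic:
        opts = dict(config.get("synthetic", {}))
        opts.pop("seed", None)  # the global seed fan-out owns the stream
        scfg = SyntheticConfig(seed=stage_seed(seed, "generate"), **opts)
        table, conn, tree, truth = generate_worm(scfg)
        table.to_csv(out / "neurons.csv")
        conn.to_csv(out / "synapses.csv", out / "gap_junctions.csv")
        with open(out / "truth.yaml", "w") as fh:
            yaml.safe_dump({k: v for k, v in truth.items()
                            if k != "process_lengths"}, fh)
    else:
        table, conn = load_inputs(config)
        tree = None

    def record(stage, frame: pd.DataFrame, filename: str, **meta):
        path = out / filename
        frame.to_csv(path)
        manifest["stages"][stage] = {"output": filename, "sha256": _sha256(path),
                                     "seed": meta.pop("seed", None), **meta}

    # --- lineage -------------------------------------------------------
    try:
        table.require("lineage_name", "lineage stage")
        if tree is None:
            tree = build_lineage_tree(table)
        record("lineage_chrono", chrono_dendrogram_export(tree),
               "chrono_dendrogram.csv", n=len(tree.leaves))
        (out / "lineage_tree.nwk").write_text(tree.to_newick())
        if table.has("ganglion"):
            s = stage_seed(seed, "lineage_null")
            gstats = ganglion_lineage_stats(tree, table, n_real=max(n_real, 20),
                                            n_swaps=2000, seed=s)
            record("lineage_ganglia", gstats.z_mean, "ganglion_z_mean.csv", seed=s)
            gstats.z_cv.to_csv(out / "ganglion_z_cv.csv")
    except DataValidationError as exc:
        manifest["skipped"]["lineage"] = str(exc)

    # --- branching -----------------------------------------------------
    if tree is not None:
        est = branching.estimate_branch_probs(tree)
        record("branching_estimates", est.set_index("rung"),
               "branch_probs.csv", n=len(tree.nodes))

    # --- homophily -----------------------------------------------------
    for attr in ("proc_cat", "cohort"):
        if not table.has(attr):
            manifest["skipped"][f"homophily_{attr}"] = f"missing column {attr}"
            continue
        frames = []
        for graph in ("syn", "gap"):
            s = stage_seed(seed, f"homophily_{attr}_{graph}")
            res = homophily.homophily_report(conn, table.column(attr),
                                             graph=graph, n_real=n_real, seed=s)
            frame = res.to_frame()
            frame.insert(0, "graph", graph)
            frames.append(frame)
        record(f"homophily_{attr}", pd.concat(frames, ignore_index=True),
               f"homophily_{attr}.csv")

    if table.has("cohort") and table.has("proc_cat"):
        s = stage_seed(seed, "cohort_strata")
        strata = homophily.birth_cohort_analysis(
            conn, table, n_real=max(4, n_real // 5), n_swaps=rewire_swaps,
            seed=s)
        frame = pd.DataFrame([
            {"stratum": r.stratum, "flag": r.homophily_flag,
             **{f"n_{k}": v for k, v in r.counts.items()},
             **{f"z_{k}": v for k, v in r.z.items()}}
            for r in strata]).set_index("stratum")
        record("cohort_strata", frame, "cohort_strata.csv", seed=s)

    # --- spatial -------------------------------------------------------
    if table.has("proc_cat"):
        dmat = spatial.pairwise_distance(table)
        frames = []
        for graph in ("syn", "gap"):
            s = stage_seed(seed, f"spatial_{graph}")
            st = spatial.connected_distance_stats(conn, dmat, table,
                                                  graph=graph,
                                                  n_real=n_real, seed=s)
            frame = st.stats
            frame.insert(0, "graph", graph)
            frames.append(frame)
        record("spatial", pd.concat(frames, ignore_index=True),
               "connected_distance_stats.csv")
        if tree is not None:
            lmat, _ = tree.distance_matrix(list(table.df["lineage_name"]))
            lframe = pd.DataFrame(lmat, index=table.names, columns=table.names)
            prof = spatial.connection_prob_profile(conn, lframe, graph="syn",
                                                   kind="lineage")
            record("lineage_profile", prof, "connection_prob_vs_lineage.csv",
                   pearson_r=prof.attrs["pearson_r"])
    else:
        manifest["skipped"]["spatial"] = "missing column proc_cat"

    # --- symmetry ------------------------------------------------------
    if table.has("partner"):
        stats = symmetry.pair_connection_stats(conn, table)
        record("symmetry", stats.to_frame(), "pair_stats.csv", n=stats.n_pairs)
        parity = symmetry.pair_lineage_parity(table)
        parity.distances.rename("lineage_distance").to_csv(out / "pair_lineage.csv")
    else:
        manifest["skipped"]["symmetry"] = "missing column partner"

    # --- regression ----------------------------------------------------
    try:
        frames = []
        for graph in ("syn", "gap"):
            design = build_design(conn, table, graph=graph)
            fit = fit_logistic(design)
            frame = fit.coefficients.copy()
            frame.insert(0, "graph", graph)
            frame["n_dyads"] = fit.n_dyads
            frame["ordered"] = design.attrs["ordered"]
            frames.append(frame)
            belsley_condition_indices(design).to_csv(
                out / f"condition_indices_{graph}.csv")
        record("regression", pd.concat(frames), "logistic_coefficients.csv")
    except (DataValidationError, ValueError) as exc:
        manifest["skipped"]["regression"] = str(exc)

    # --- roles ---------------------------------------------------------
    if table.has("module_id"):
        rt = roles.role_table(conn, table.column("module_id"))
        record("roles", rt, "roles.csv", n=int(rt["role"].ne("unclassified").sum()))
        if table.has("birth_stage"):
            roles.role_birth_summary(rt, table).to_csv(out / "role_birth.csv")
    else:
        manifest["skipped"]["roles"] = "missing column module_id"

    # --- circuits ------------------------------------------------------
    if table.has("circuits"):
        summary = circuits.circuit_completion(table)
        record("circuits", summary.completion, "circuit_completion.csv")
        members = sorted({m for ms in summary.members.values() for m in ms})
        rest = [nm for nm in conn.neurons if nm not in members]
        if len(members) >= 2 and len(rest) >= 2:
            ks = circuits.degree_group_compare(conn, members, rest, alpha=alpha)
            pd.DataFrame({k: {"statistic": v.statistic, "p_value": v.p_value,
                              "h": v.h, "alpha": v.alpha}
                          for k, v in ks.items()}).T.to_csv(out / "circuit_ks.csv")
        disp = circuits.stage_degree_dispersion(
            conn, table, {"circuit": members, "other": rest})
        disp.to_csv(out / "stage_degree_dispersion.csv", index=False)
        manifest["stages"]["circuits"]["alpha"] = alpha
    else:
        manifest["skipped"]["circuits"] = "missing column circuits"

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out
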