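"""Shared data model: neuron metadata tables and binary connectomes.

The package analyses the 279-neuron somatic nervous system of *C. elegans*
(or synthetic stand-ins of it) through two objects:

``NeuronTable``
    one row per neuron carrying its developmental / spatial / functional
    attributes (2D cell-body position, process-length class, birth time and
    larval stage, lineage-name string, ganglion, functional type, bilateral
    partner, circuit memberships, topological module label).

``Connectome``
    two binary adjacency matrices over a fixed neuron ordering: a directed
    chemical-synapse matrix and a symmetric gap-junction matrix.

Adjacency orientation: ``syn[i, j] == 1`` means neuron *i* receives a
connection from neuron *j* (*j* is pre-synaptic).  Edge-list files are rows
of ``(pre, post)`` and are transposed on load so that the modularity formula
can be applied literally with in-degree ``k_in(i) = sum_j A[i, j]``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns every neuron table must provide
REQUIRED_COLUMNS = (
    "name", "x_ap", "y_dv", "proc_cat", "birth_time", "birth_stage",
    "lineage_name",
)
#: recognised optional columns
OPTIONAL_COLUMNS = (
    "ganglion", "func_type", "partner", "sym_origin", "circuits",
    "module_id", "proc_len", "cohort",
)

PROC_CATS = ("S", "M", "L")
BIRTH_STAGES = ("Embryo", "L1", "L2", "L3")
FUNC_TYPES = ("sensory", "inter", "motor", "polymodal")
SYM_ORIGINS = ("symmetric_blastomere", "nonsymmetric_blastomere", "unpaired")
GANGLIA = tuple(f"G{i}" for i in range(1, 11))
CIRCUITS = tuple(f"F{i}" for i in range(1, 10))

#: default hatching time (minutes post-fertilization), used only as a
#: fallback when birth_stage is absent
DEFAULT_T_HATCH = 800.0


class DataValidationError(ValueError):
    """Raised when an input table or edge list violates the data contract."""


@dataclass
class TestResult:
    """Outcome of a two-sample hypothesis test.

    ``h`` is the rejection indicator: 1 iff ``p_value < alpha``.
    """

    statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def h(self) -> int:
        return int(self.p_value < self.alpha)


def categorize_process_length(length: float, body_length: float) -> str:
    """Classify a neurite length into S/M/L thirds of the body length.

    Short: ``length <= body_length / 3`` (closed boundary); medium up to
    ``2 * body_length / 3``; long beyond.
    """
    if body_length <= 0:
        raise ValueError("body_length must be positive")
    if length < 0:
        raise ValueError("process length cannot be negative")
    if length <= body_length / 3:
        return "S"
    if length <= 2 * body_length / 3:
        return "M"
    return "L"


class NeuronTable:
    """Validated per-neuron attribute table.

    Parameters
    ----------
    df : DataFrame with at least :data:`REQUIRED_COLUMNS`.
    t_hatch : hatching time in minutes, used to derive the early/late cohort
        only when ``birth_stage`` is missing for a record.
    """

    def __init__(self, df: pd.DataFrame, t_hatch: float = DEFAULT_T_HATCH):
        self.df = df.reset_index(drop=True).copy()
        self.t_hatch = float(t_hatch)
        self._validate()
        self._derive_cohort()

    # -- validation -----------------------------------------------------

    def _validate(self) -> None:
        df = self.df
        if len(df) == 0:
            raise DataValidationError("no records")
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DataValidationError(f"missing required columns: {missing}")
        dup = df["name"][df["name"].duplicated()]
        if len(dup):
            raise DataValidationError(f"duplicate neuron names: {sorted(set(dup))}")
        self._check_tokens("proc_cat", PROC_CATS)
        self._check_tokens("birth_stage", BIRTH_STAGES)
        self._check_tokens("func_type", FUNC_TYPES)
        self._check_tokens("sym_origin", SYM_ORIGINS)
        self._check_tokens("ganglion", GANGLIA)
        if "partner" in df.columns:
            self._check_partner_involution()

    def _check_tokens(self, col: str, allowed: tuple[str, ...]) -> None:
        if col not in self.df.columns:
            return
        vals = self.df[col]
        bad = self.df.index[~(vals.isna() | vals.isin(allowed))]
        if len(bad):
            i = int(bad[0])
            raise DataValidationError(
                f"unknown {col} token {self.df[col].iloc[i]!r} in row {i} "
                f"(neuron {self.df['name'].iloc[i]!r}); allowed: {allowed}"
            )

    def _check_partner_involution(self) -> None:
        partner = dict(zip(self.df["name"], self.df["partner"]))
        for name, p in partner.items():
            if pd.isna(p) or p == "":
                continue
            if p not in partner:
                raise DataValidationError(
                    f"partner {p!r} of {name!r} is not in the table")
            back = partner[p]
            if pd.isna(back) or back != name:
                raise DataValidationError(
                    f"partner relation not an involution: {name} -> {p} -> {back}")

    def _derive_cohort(self) -> None:
        df = self.df
        if "cohort" not in df.columns:
            df["cohort"] = pd.NA
        by_stage = df["birth_stage"].map(
            lambda s: pd.NA if pd.isna(s) else ("early" if s == "Embryo" else "late"))
        by_time = df["birth_time"].map(
            lambda t: pd.NA if pd.isna(t) else ("early" if t < self.t_hatch else "late"))
        derived = by_stage.where(~by_stage.isna(), by_time)
        given = df["cohort"]
        clash = (~given.isna()) & (~derived.isna()) & (given != derived)
        if clash.any():
            names = list(df.loc[clash, "name"])
            raise DataValidationError(f"cohort inconsistent with birth_stage for {names}")
        df["cohort"] = given.where(~given.isna(), derived)

    # -- convenience ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def names(self) -> list[str]:
        return list(self.df["name"])

    def has(self, column: str) -> bool:
        """True if the column exists and has at least one non-missing value."""
        return column in self.df.columns and self.df[column].notna().any()

    def require(self, column: str, analysis: str) -> None:
        if not self.has(column):
            raise DataValidationError(
                f"{analysis} requires the {column!r} column, which is missing "
                "from the neuron table")

    def column(self, name: str) -> pd.Series:
        return self.df.set_index("name")[name]

    @property
    def body_length(self) -> float:
        """Anterior-posterior span of the loaded positions (mm)."""
        x = self.df["x_ap"].astype(float)
        return float(x.max() - x.min())

    def positions(self) -> np.ndarray:
        return self.df[["x_ap", "y_dv"]].to_numpy(dtype=float)

    def circuit_members(self, circuit: str) -> list[str]:
        """Neurons whose ``circuits`` field contains the given label."""
        self.require("circuits", "circuit membership lookup")
        out = []
        for name, c in zip(self.df["name"], self.df["circuits"]):
            if not pd.isna(c) and circuit in str(c).split("|"):
                out.append(name)
        return out

    def bilateral_pairs(self) -> list[tuple[str, str]]:
        """Unordered (left, right) partner pairs, each reported once."""
        self.require("partner", "bilateral pair analysis")
        seen, pairs = set(), []
        for name, p in zip(self.df["name"], self.df["partner"]):
            if pd.isna(p) or p == "" or name in seen:
                continue
            pairs.append((name, p))
            seen.update((name, p))
        return pairs

    # -- I/O -------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, NeuronTable):
            return NotImplemented
        a = self.df.fillna("").astype(str)
        b = other.df[a.columns].fillna("").astype(str) if set(a.columns) <= set(other.df.columns) else None
        return b is not None and a.equals(b)


def load_neuron_table(path, t_hatch: float = DEFAULT_T_HATCH,
                      sep: str | None = None) -> NeuronTable:
    """Read a delimited neuron-attribute file into a validated table.

    The delimiter is sniffed (comma or tab) unless given.  Numeric columns
    are coerced; unknown category tokens and duplicate names raise
    :class:`DataValidationError` naming the offending row.
    """
    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error):
        raise DataValidationError("no records") from None
    if len(df) == 0:
        raise DataValidationError("no records")
    for col in ("x_ap", "y_dv", "birth_time", "proc_len"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    absent = [c for c in OPTIONAL_COLUMNS if c not in df.columns]
    if absent:
        logger.info("optional columns absent from %s: %s", path, absent)
    return NeuronTable(df, t_hatch=t_hatch)


@dataclass
class Connectome:
    """Binary synapse and gap-junction adjacencies over a fixed node order.

    ``syn[i, j] == 1`` iff neuron ``i`` receives a chemical synapse from
    neuron ``j``; ``gap`` is symmetric with zero diagonal.
    """

    neurons: list[str]
    syn: np.ndarray
    gap: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        n = len(self.neurons)
        self.syn = np.asarray(self.syn, dtype=np.int8)
        self.gap = np.asarray(self.gap, dtype=np.int8)
        if self.syn.shape != (n, n) or self.gap.shape != (n, n):
            raise DataValidationError("adjacency shape does not match neuron list")
        for name, a in (("syn", self.syn), ("gap", self.gap)):
            if np.diag(a).any():
                raise DataValidationError(f"{name} matrix has self-loops")
            if not np.isin(a, (0, 1)).all():
                raise DataValidationError(f"{name} matrix is not binary")
        if not np.array_equal(self.gap, self.gap.T):
            raise DataValidationError("gap matrix is not symmetric")
        self.index = {name: i for i, name in enumerate(self.neurons)}

    # degree vectors ----------------------------------------------------

    @property
    def k_in(self) -> np.ndarray:
        return self.syn.sum(axis=1)

    @property
    def k_out(self) -> np.ndarray:
        return self.syn.sum(axis=0)

    @property
    def k_gap(self) -> np.ndarray:
        return self.gap.sum(axis=1)

    def matrix(self, graph: str) -> np.ndarray:
        """Adjacency for ``graph`` in {'syn', 'gap'}."""
        if graph == "syn":
            return self.syn
        if graph == "gap":
            return self.gap
        raise ValueError(f"unknown graph {graph!r}; expected 'syn' or 'gap'")

    def n_links(self, graph: str) -> int:
        """Total link count L = sum of adjacency entries.

        For the symmetric gap matrix each undirected junction contributes 2.
        """
        return int(self.matrix(graph).sum())

    def combined_undirected(self) -> np.ndarray:
        """Binarized union of synapses (either direction) and gap junctions."""
        a = ((self.syn + self.syn.T + self.gap) > 0).astype(np.int8)
        np.fill_diagonal(a, 0)
        return a

    # I/O ----------------------------------------------------------------

    def edge_lists(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(pre, post) synapse rows and canonical unordered gap rows."""
        pre, post = np.nonzero(self.syn.T)
        syn = pd.DataFrame({
            "source": [self.neurons[i] for i in pre],
            "target": [self.neurons[j] for j in post],
        })
        gi, gj = np.nonzero(np.triu(self.gap))
        gap = pd.DataFrame({
            "source": [self.neurons[i] for i in gi],
            "target": [self.neurons[j] for j in gj],
        })
        return syn, gap

    def to_csv(self, syn_path, gap_path) -> None:
        syn, gap = self.edge_lists()
        syn.to_csv(syn_path, index=False)
        gap.to_csv(gap_path, index=False)


def _read_edges(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["source", "target"])
    cols = list(df.columns[:2])
    df = df.rename(columns={cols[0]: "source", cols[1]: "target"})
    if df.shape[1] >= 3:
        w = pd.to_numeric(df[df.columns[2]], errors="coerce").fillna(1.0)
        df = df[w > 0]
    return df[["source", "target"]]


def load_connectome(syn_path, gap_path, neurons: NeuronTable) -> Connectome:
    """Assemble a :class:`Connectome` from two edge-list files.

    Synapse rows are ``(pre, post)`` and stored transposed; weights collapse
    to existence; gap edges are symmetrized; self-loops are dropped with a
    logged count.  Unknown neuron names raise.
    """
    names = neurons.names
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    syn = np.zeros((n, n), dtype=np.int8)
    gap = np.zeros((n, n), dtype=np.int8)
    dropped = 0
    for path, mat, symmetric in ((syn_path, syn, False), (gap_path, gap, True)):
        for src, tgt in _read_edges(path).itertuples(index=False):
            for nm in (src, tgt):
                if nm not in idx:
                    raise DataValidationError(
                        f"edge list {path} names unknown neuron {nm!r}")
            if src == tgt:
                dropped += 1
                continue
            i, j = idx[src], idx[tgt]
            if symmetric:
                mat[i, j] = mat[j, i] = 1
            else:
                mat[j, i] = 1  # post receives from pre
    if dropped:
        logger.info("dropped %d self-loop edge(s)", dropped)
    return Connectome(names, syn, gap)
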