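"""Dyadic logistic regression of connection probability on homophily terms.

Every neuron pair (dyad) contributes a row with four predictors — same
process-length class (X_p), same birth cohort (X_b), bilateral partnership
(X_s), and lineage distance (X_l, an integer in 1..25) — and the binary
outcome Y of a connection.  The model

    P(Y = 1) = 1 / (1 + exp(-(b0 + bp*X_p + bb*X_b + bs*X_s + bl*X_l)))

is fit by plain maximum likelihood (no regularization); coefficient
magnitudes rank the relative influence of the four attributes.  Synapse
designs default to ordered dyads (each unordered pair contributes both
directions, since the synapse matrix is directed while all predictors are
symmetric); gap-junction designs use unordered dyads.  Belsley condition
indices on the scaled design screen for collinearity among predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import Connectome, NeuronTable
from .lineage import lineage_distance

logger = logging.getLogger(__name__)

__all__ = ["build_design", "fit_logistic", "LogisticFit",
           "belsley_condition_indices"]

PREDICTORS = ("x_p", "x_b", "x_s", "x_l")


def build_design(conn: Connectome, table: NeuronTable, graph: str = "syn",
                 ordered: bool | None = None) -> pd.DataFrame:
    """One row per dyad with homophily predictors and connection outcome.

    ``ordered`` defaults to True for synapses (both directions of each
    pair) and False for gap junctions.  Dyads with any missing attribute
    are dropped; the dropped count is logged and stored in
    ``.attrs['n_dropped']``.
    """
    if ordered is None:
        ordered = graph == "syn"
    for col in ("proc_cat", "cohort", "partner", "lineage_name"):
        table.require(col, "dyadic design")
    df = table.df.set_index("name").reindex(conn.neurons)
    cats = df["proc_cat"].to_numpy(dtype=object)
    coh = df["cohort"].to_numpy(dtype=object)
    partner = df["partner"].to_numpy(dtype=object)
    lin = df["lineage_name"].to_numpy(dtype=object)
    a = conn.matrix(graph)
    n = len(conn.neurons)

    # pairwise lineage distances, computed once
    ldist = np.full((n, n), np.nan)
    ok = [i for i in range(n) if not pd.isna(lin[i])]
    for ii, i in enumerate(ok):
        for j in ok[ii + 1:]:
            ldist[i, j] = ldist[j, i] = lineage_distance(lin[i], lin[j])

    rows, dropped = [], 0
    names = conn.neurons
    for i in range(n):
        j_range = range(n) if ordered else range(i + 1, n)
        for j in j_range:
            if i == j:
                continue
            if (pd.isna(cats[i]) or pd.isna(cats[j]) or pd.isna(coh[i])
                    or pd.isna(coh[j]) or np.isnan(ldist[i, j])):
                dropped += 1
                continue
            rows.append({
                "i": names[i], "j": names[j],
                "x_p": int(cats[i] == cats[j]),
                "x_b": int(coh[i] == coh[j]),
                "x_s": int(not pd.isna(partner[i]) and partner[i] == names[j]),
                "x_l": int(ldist[i, j]),
                "y": int(a[i, j] if ordered else (a[i, j] or a[j, i])),
            })
    if dropped:
        logger.info("dropped %d dyad(s) with missing attributes", dropped)
    out = pd.DataFrame(rows)
    if out.empty or out[list(PREDICTORS)].isna().all().any():
        raise ValueError("no usable dyads: an attribute is entirely missing")
    out.attrs["n_dropped"] = dropped
    out.attrs["graph"] = graph
    out.attrs["ordered"] = ordered
    return out


@dataclass
class LogisticFit:
    """Maximum-likelihood fit of the dyadic connection model."""

    coefficients: pd.DataFrame   # estimate, std_err, p_value per term
    n_dyads: int
    converged: bool
    log_likelihood: float

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])


def fit_logistic(design: pd.DataFrame) -> LogisticFit:
    """Fit the connection-probability model by maximum likelihood.

    Predictor columns that are constant (e.g. all zero) are excluded from
    the fit, leaving an intercept-only model in the degenerate case where
    all predictors are constant.  Perfect separation or non-convergence is
    reported through ``converged`` rather than raised.
    """
    y = design["y"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    cols = [c for c in PREDICTORS if c in design.columns
            and design[c].nunique() > 1]
    x = sm.add_constant(design[cols].astype(float), has_constant="add")
    model = sm.Logit(y, x)
    try:
        res = model.fit(disp=False, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as exc:  # separation etc. — report diagnostically
        logger.warning("logistic fit failed: %s", exc)
        raise
    coefs = pd.DataFrame({
        "estimate": res.params,
        "std_err": res.bse,
        "p_value": res.pvalues,
    })
    return LogisticFit(coefficients=coefs, n_dyads=len(design),
                       converged=converged,
                       log_likelihood=float(res.llf))


def belsley_condition_indices(design: pd.DataFrame,
                              include_intercept: bool = False) -> pd.Series:
    """Belsley condition indices of the unit-length-scaled design matrix.

    Columns are scaled to unit Euclidean norm; the indices are
    sigma_1 / sigma_j over the singular values of the scaled matrix.  A
    rank-deficient design yields an infinite top index; indices below ~5
    indicate negligible collinearity.  By default the diagnostic runs on
    the predictor columns only: an uncentered count predictor such as the
    lineage distance is always strongly aligned with a constant column,
    and including the intercept would flag that structural alignment
    rather than dependence among the predictors.
    """
    cols = [c for c in PREDICTORS if c in design.columns]
    x = design[cols].to_numpy(dtype=float)
    if include_intercept:
        x = np.column_stack([np.ones(len(x)), x])
        cols = ["const"] + cols
    if x.shape[1] < 2:
        raise ValueError("need at least 2 columns including the intercept")
    norms = np.linalg.norm(x, axis=0)
    norms[norms == 0] = 1.0
    s = np.linalg.svd(x / norms, compute_uv=False)
    with np.errstate(divide="ignore"):
        idx = np.where(s > 0, s[0] / s, np.inf)
    return pd.Series(idx, index=[f"sv{i+1}" for i in range(len(idx))],
                     name="condition_index")
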