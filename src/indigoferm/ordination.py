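"""Redundancy analysis (RDA) of the community matrix on environmental drivers.

RDA ordinates a (samples x taxa) response matrix Y in the subspace spanned by
a (samples x variables) environmental matrix X: Y is column-centred, fitted by
least squares, and the fitted part Yhat = X (X'X)^-1 X'Y is diagonalised.
Constrained eigenvalues partition the variance explained by the environment;
the residual Y - Yhat yields the unconstrained axes.  Community proportions
are Hellinger-transformed (sqrt p) by default before ordination, the standard
pre-transform that makes Euclidean RDA well behaved for relative abundances.

Environmental encoding treats wheat-bran additions as an exponentially
decaying pulse covariate (the bran is consumed over roughly a month), so a
sample's bran level is the sum of e^{-(t - t_event)/tau} over past additions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["EnvMatrix", "RDAResult", "encode_environment", "transform_community", "fit_rda", "bran_level"]


@dataclass
class EnvMatrix:
    """Standardised samples-by-variables environmental matrix."""

    values: pd.DataFrame  # samples x variables
    standardized: bool = True

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("environmental matrix contains missing values")


@dataclass
class RDAResult:
    """Eigenvalues, scores and variance decomposition of a fitted RDA."""

    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    site_scores: pd.DataFrame       # samples x constrained axes
    species_scores: pd.DataFrame    # taxa x constrained axes
    biplot_scores: pd.DataFrame     # variables x constrained axes
    axis_explained: np.ndarray      # % of total variance per constrained axis
    total_variance: float

    @property
    def constrained_proportion(self) -> float:
        return float(self.constrained_eigenvalues.sum() / self.total_variance)


def bran_level(day: float, bran_days, amount: float = 1.0, tau: float = 30.0) -> float:
    """Decayed wheat-bran pool at ``day``: sum over past pulses of
    amount * e^{-(day - t_event)/tau}."""
    level = 0.0
    for t_event in bran_days:
        if day >= t_event:
            level += amount * np.exp(-(day - t_event) / tau)
    return float(level)


def encode_environment(
    env_series,
    samples: pd.DataFrame,
    bran_days=(5, 19, 51, 85, 194),
    bran_amount: float = 1.0,
    bran_decay_days: float = 30.0,
    extra_vars=(),
    standardize: bool = True,
) -> EnvMatrix:
    """Build the environmental matrix for a set of samples.

    ``samples`` is a DataFrame indexed by sample id with ``batch_id`` and
    ``day`` columns; pH and ORP are looked up in ``env_series`` (a mapping
    batch_id -> day-indexed DataFrame with ``ph``/``orp`` columns) unless the
    samples frame already carries them.  Wheat bran enters as the decayed
    pulse level.  Variables are standardised to zero mean, unit variance.
    """
    rows = {}
    for sample_id, meta in samples.iterrows():
        day = float(meta["day"])
        if env_series is not None:
            batch = meta["batch_id"]
            if batch not in env_series:
                raise ValueError(f"sample {sample_id!r}: batch {batch!r} not in environment series")
            series = env_series[batch]
            if day not in series.index:
                raise ValueError(f"sample {sample_id!r}: day {day} not in environment series for {batch!r}")
            rec = series.loc[day]
            ph, orp = float(rec["ph"]), float(rec["orp"])
        else:
            ph, orp = float(meta["ph"]), float(meta["orp"])
        row = {"ph": ph, "orp": orp,
               "bran": bran_level(day, bran_days, bran_amount, bran_decay_days)}
        for var in extra_vars:
            row[var] = float(meta[var])
        rows[sample_id] = row
    values = pd.DataFrame.from_dict(rows, orient="index").loc[list(samples.index)]
    if standardize:
        sd = values.std(axis=0, ddof=1)
        const = sd.index[sd == 0].tolist()
        if const:
            logger.warning("dropping constant environmental variable(s): %s", const)
            values = values.drop(columns=const)
            sd = sd.drop(index=const)
        values = (values - values.mean(axis=0)) / sd
    return EnvMatrix(values=values, standardized=standardize)


def transform_community(rel: pd.DataFrame, method: str = "hellinger") -> pd.DataFrame:
    """Pre-transform a taxa-by-sample proportion table into a samples-by-taxa
    response matrix Y (column-centred downstream by fit_rda).

    ``hellinger`` takes sqrt of each proportion; ``none`` uses raw values.
    """
    if method == "hellinger":
        y = np.sqrt(rel.T)
    elif method == "none":
        y = rel.T.astype(float)
    else:
        raise ValueError(f"unknown transform {method!r}")
    return y


def _drop_collinear(X: np.ndarray, cols, tol: float = 1e-10):
    """Greedily drop columns that are linear combinations of earlier ones."""
    keep = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol) == len(keep) + 1:
            keep.append(j)
        else:
            logger.warning("dropping collinear environmental variable %r", cols[j])
    return X[:, keep], [cols[j] for j in keep]


def fit_rda(Y: pd.DataFrame, X: EnvMatrix) -> RDAResult:
    """Redundancy analysis of response Y (samples x taxa) on constraints X.

    Both matrices are column-centred; Yhat is the least-squares projection of
    Y onto the column space of X.  Constrained axes are the eigenvectors of
    Yhat'Yhat/(n-1), residual axes those of (Y-Yhat)'(Y-Yhat)/(n-1).  Scores
    follow the scaling-2 (species-focused) convention; each axis's sign is
    fixed so its largest-magnitude species loading is positive.
    """
    if list(Y.index) != list(X.values.index):
        raise ValueError("sample order of Y and X must match")
    n, p = Y.shape
    q = X.values.shape[1]
    if n <= q:
        raise ValueError(f"need more samples ({n}) than environmental variables ({q})")

    Yc = Y.to_numpy(dtype=float)
    Yc = Yc - Yc.mean(axis=0)
    Xc = X.values.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    Xc, kept_vars = _drop_collinear(Xc, list(X.values.columns))
    if Xc.shape[1] == 0:
        raise ValueError("no usable environmental variables after collinearity pruning")

    # least-squares projection of Y onto span(X)
    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Yhat = Xc @ B
    Yres = Yc - Yhat

    total_var = float((Yc**2).sum()) / (n - 1)

    def _eig(M: np.ndarray, rank_cap: int):
        C = M.T @ M / (n - 1)
        vals, vecs = np.linalg.eigh(C)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        vals = np.where(vals < 0, np.maximum(vals, -1e-10), vals)
        k = min(rank_cap, (vals > 1e-12 * max(vals.max(), 1.0)).sum())
        return vals, vecs, int(k)

    cons_vals, cons_vecs, k = _eig(Yhat, min(Xc.shape[1], p, n - 1))
    res_vals, _, _ = _eig(Yres, min(p, n - 1))

    axes = [f"RDA{i + 1}" for i in range(k)]
    U = cons_vecs[:, :k]                      # species eigenvectors
    lam = cons_vals[:k]
    # deterministic sign: largest-magnitude species loading positive
    for j in range(k):
        i_max = np.argmax(np.abs(U[:, j]))
        if U[i_max, j] < 0:
            U[:, j] = -U[:, j]

    # scaling 2: species scaled by sqrt(eigenvalue), sites are fitted-site
    # positions in eigenvector space scaled by 1/sqrt(eigenvalue)
    sqrt_lam = np.sqrt(np.maximum(lam, 0.0))
    species_scores = U * sqrt_lam
    site_raw = Yhat @ U                        # sample coordinates on axes
    with np.errstate(divide="ignore", invalid="ignore"):
        site_scores = np.where(sqrt_lam > 0, site_raw / sqrt_lam, 0.0)
    # biplot arrows: correlations of constraints with the site axes
    biplot = np.zeros((Xc.shape[1], k))
    for j in range(k):
        axis = site_raw[:, j]
        sd = axis.std(ddof=1)
        if sd > 0:
            for v in range(Xc.shape[1]):
                sv = Xc[:, v].std(ddof=1)
                if sv > 0:
                    biplot[v, j] = float(np.corrcoef(Xc[:, v], axis)[0, 1])

    explained = 100.0 * lam / total_var if total_var > 0 else np.zeros(k)
    return RDAResult(
        constrained_eigenvalues=lam,
        unconstrained_eigenvalues=res_vals[res_vals > 1e-12 * max(total_var, 1.0)],
        site_scores=pd.DataFrame(site_scores, index=Y.index, columns=axes),
        species_scores=pd.DataFrame(species_scores, index=Y.columns, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=kept_vars, columns=axes),
        axis_explained=explained,
        total_variance=total_var,
    )
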