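"""Constrained ordination: how much community variation do the
physicochemical factors explain?

RDA (redundancy analysis) fits each (column-centered) genus profile by
least squares on the standardized environmental factors and
eigen-decomposes the fitted values: the constrained fraction is
trace(fitted covariance) / trace(total covariance), i.e. the share of
community variance lying in the environmental subspace. Linear
species-environment responses are assumed.

CCA (canonical correspondence analysis) works in the chi-square metric
of correspondence analysis: the abundance table is converted to the
standardized residual matrix Q = (P - r c^T) / sqrt(r c^T) (P the
relative table, r row masses, c column masses), environmental factors
are standardized under row-mass weights, and Q is projected onto the
weighted environmental subspace. Total inertia equals the table's
chi-square statistic divided by its grand total; unimodal responses
are the usual motivation for preferring CCA on long gradients.

The source study pairs RDA with the early stage and CCA with the late
stage without stating a reason; both methods are exposed for either
stage here, with that pairing kept as the default in the pipeline. Its
printed fractions (73.39% early RDA, 46.3% late CCA) depend on
sequencing data not consumed here and are documented reference values
only (:mod:`sufucore.reference`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import spearman_matrix
from .tables import AbundanceTable, PhysicoTable, ValidationError

__all__ = ["OrdinationResult", "rda", "cca", "factor_heatmap"]


@dataclass
class OrdinationResult:
    method: str  # "rda" | "cca"
    constrained_fraction: float
    eigenvalues: np.ndarray  # constrained axes, non-increasing
    total_inertia: float
    site_scores: pd.DataFrame
    factor_scores: pd.DataFrame
    dropped_factors: list[str]


def _env_matrix(env: PhysicoTable, weights: np.ndarray | None = None):
    """Standardize factors ((weighted) z-scores), dropping constants and
    collinear columns with a warning."""
    X = env.values.to_numpy(dtype=float)
    names = list(env.values.columns)
    n = X.shape[0]
    w = np.full(n, 1.0 / n) if weights is None else weights / weights.sum()
    mean = w @ X
    Xc = X - mean
    var = w @ (Xc**2)
    keep = var > 1e-12 * max(1.0, np.abs(X).max() ** 2)
    dropped = [names[j] for j in range(len(names)) if not keep[j]]
    Xs = Xc[:, keep] / np.sqrt(var[keep])
    kept_names = [n_ for n_, k in zip(names, keep) if k]
    # drop collinear columns (greedy, in input order)
    sw = np.sqrt(w)[:, None]
    cols: list[int] = []
    for j in range(Xs.shape[1]):
        trial = sw * Xs[:, cols + [j]]
        if np.linalg.matrix_rank(trial, tol=1e-9) == len(cols) + 1:
            cols.append(j)
        else:
            dropped.append(kept_names[j])
    if dropped:
        warnings.warn(
            f"dropped constant/collinear environmental factors: {dropped}",
            UserWarning,
            stacklevel=3,
        )
    return Xs[:, cols], [kept_names[j] for j in cols], dropped, w


def _check_match(species_index, env: PhysicoTable) -> None:
    if list(species_index) != list(env.values.index):
        raise ValidationError("species and environmental tables must share samples")


def rda(species: pd.DataFrame | AbundanceTable, env: PhysicoTable) -> OrdinationResult:
    """Redundancy analysis of a samples x genera matrix on the factors.

    The species matrix is column-centered (no transform by default;
    apply a Hellinger transform upstream if desired); environmental
    factors are standardized. Requires more samples than (retained)
    factors.
    """
    Y = species.values if isinstance(species, AbundanceTable) else species
    _check_match(Y.index, env)
    Yn = Y.to_numpy(dtype=float)
    n = Yn.shape[0]
    if n <= env.values.shape[1]:
        raise ValidationError(
            f"need more samples ({n}) than environmental factors "
            f"({env.values.shape[1]})"
        )
    X, kept, dropped, _ = _env_matrix(env)
    if X.shape[1] == 0:
        raise ValidationError("no usable environmental factors remain")
    Yc = Yn - Yn.mean(axis=0)
    B, *_ = np.linalg.lstsq(X, Yc, rcond=None)
    fitted = X @ B
    total = float((Yc**2).sum())
    constrained = float((fitted**2).sum())
    if total <= 0:
        raise ValidationError("species matrix has no variation")
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    k = min(X.shape[1], Yn.shape[1])
    eig = (s[:k] ** 2) / (n - 1)
    site = pd.DataFrame(
        (U[:, :k] * s[:k]), index=Y.index, columns=[f"RDA{i+1}" for i in range(k)]
    )
    factor = pd.DataFrame(
        X.T @ U[:, :k], index=kept, columns=site.columns
    )
    return OrdinationResult(
        method="rda",
        constrained_fraction=constrained / total,
        eigenvalues=eig,
        total_inertia=total / (n - 1),
        site_scores=site,
        factor_scores=factor,
        dropped_factors=dropped,
    )


def cca(species: pd.DataFrame | AbundanceTable, env: PhysicoTable) -> OrdinationResult:
    """Canonical correspondence analysis (chi-square metric).

    ``species`` must be non-negative with positive row and column sums.
    """
    Y = species.values if isinstance(species, AbundanceTable) else species
    _check_match(Y.index, env)
    Yn = Y.to_numpy(dtype=float)
    if (Yn < 0).any():
        raise ValidationError("CCA requires a non-negative species matrix")
    rs = Yn.sum(axis=1)
    cs = Yn.sum(axis=0)
    if (rs <= 0).any():
        bad = Y.index[rs <= 0][0]
        raise ValidationError(f"zero row sum for sample {bad!r}")
    keep_cols = cs > 0
    if not keep_cols.all():
        Yn = Yn[:, keep_cols]
        cs = cs[keep_cols]
    grand = Yn.sum()
    P = Yn / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)
    total = float((Q**2).sum())
    X, kept, dropped, w = _env_matrix(env, weights=r)
    if X.shape[1] == 0:
        # all factors constant/collinear: nothing can be explained
        empty = pd.DataFrame(index=Y.index)
        return OrdinationResult(
            method="cca",
            constrained_fraction=0.0,
            eigenvalues=np.zeros(0),
            total_inertia=total,
            site_scores=empty,
            factor_scores=pd.DataFrame(),
            dropped_factors=dropped,
        )
    Z = np.sqrt(r)[:, None] * X  # row-mass weighted regressors
    B, *_ = np.linalg.lstsq(Z, Q, rcond=None)
    fitted = Z @ B
    constrained = float((fitted**2).sum())
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    k = min(X.shape[1], Q.shape[1])
    eig = s[:k] ** 2
    site = pd.DataFrame(
        U[:, :k] * s[:k], index=Y.index, columns=[f"CCA{i+1}" for i in range(k)]
    )
    factor = pd.DataFrame(Z.T @ U[:, :k], index=kept, columns=site.columns)
    return OrdinationResult(
        method="cca",
        constrained_fraction=constrained / total if total > 0 else 0.0,
        eigenvalues=eig,
        total_inertia=total,
        site_scores=site,
        factor_scores=factor,
        dropped_factors=dropped,
    )


def factor_heatmap(
    core: list[str],
    at: AbundanceTable,
    physico: PhysicoTable,
    method: str = "spearman",
):
    """Core-genus x factor correlation matrix with p-values.

    Returns ``(rho, p)`` DataFrames of shape |core| x n_factors, using
    the same Spearman machinery as the association screens. A constant
    factor column makes its correlations undefined and raises.
    """
    if method != "spearman":
        raise ValidationError("only spearman correlations are supported")
    unknown = [g for g in core if g not in at.genera]
    if unknown:
        raise ValidationError(f"unknown genera: {unknown}")
    if list(at.values.index) != list(physico.values.index):
        raise ValidationError("abundance and physicochemical samples must match")
    env = physico.values
    const = [f for f in env.columns if env[f].nunique() <= 1]
    if const:
        raise ValidationError(f"correlation undefined for constant factors: {const}")
    rho, p = spearman_matrix(at.values[core], env)
    return rho, p
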