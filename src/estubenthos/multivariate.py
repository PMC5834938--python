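"""Community dissimilarity and multivariate procedures.

Bray-Curtis dissimilarity on square-root transformed abundances, nested
PERMANOVA sharing the univariate EMS denominator logic, non-metric MDS
(SMACOF majorization with monotone regression, Kruskal stress-1), SIMPER
decomposition of between-group dissimilarity, and canonical
correspondence analysis (CCA) of plot-level densities on sediment
covariates.

The PERMANOVA partitions the Gower-centred inner-product matrix
``G = (I - 11'/n) (-D^2/2) (I - 11'/n)`` with the same orthogonal effect
projectors used by the univariate engine, so ``SS_term = tr(P_term G)``
and, with Euclidean distances, every pseudo-F equals the classical
ANOVA F exactly.  Significance uses permutation of residuals under a
reduced model (Freedman-Lane): the tested term's effect is removed
along with all other modelled effects, the residual matrix is permuted
whole, and the pseudo-F recomputed; p = (b + 1) / (m + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .univariate import RESIDUAL, ModelSpec, effect_projectors, ems_denominators


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(matrix: pd.DataFrame, transform: str = "sqrt") -> pd.DataFrame:
    """Bray-Curtis dissimilarity between the rows of a samples x taxa matrix.

    ``transform`` is ``"sqrt"`` (the convention for abundance data) or
    ``"none"``.  Rows that are entirely zero have no defined Bray-Curtis
    dissimilarity and are excluded with a warning; the excluded labels
    are recorded in ``result.attrs["dropped_rows"]``.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("community matrix entries must be non-negative")
    if transform == "sqrt":
        X = np.sqrt(matrix.to_numpy(dtype=float))
    elif transform == "none":
        X = matrix.to_numpy(dtype=float)
    else:
        raise ValueError("transform must be 'sqrt' or 'none'")
    keep = X.sum(axis=1) > 0
    dropped = [matrix.index[i] for i in np.flatnonzero(~keep)]
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} all-zero row(s) from Bray-Curtis: {dropped}"
        )
        X = X[keep]
    index = matrix.index[keep]
    D = squareform(pdist(X, metric="braycurtis")) if len(X) > 1 else np.zeros((len(X), len(X)))
    out = pd.DataFrame(D, index=index, columns=index)
    out.attrs["transform"] = transform
    out.attrs["dropped_rows"] = dropped
    return out


def gower_center(dissim: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix of a distance matrix."""
    A = -0.5 * np.asarray(dissim, dtype=float) ** 2
    n = A.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return J @ A @ J


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    table: pd.DataFrame
    n_perm: int
    seed: int
    spec: ModelSpec


def permanova(
    dissim: pd.DataFrame,
    data: pd.DataFrame,
    spec: ModelSpec,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """Nested multi-factor PERMANOVA on a dissimilarity matrix.

    ``data`` holds the factor columns, row-aligned with ``dissim``.
    Denominators come from the univariate EMS map (partial SS; the
    balanced designs used here make sequential and partial SS identical).
    ``seed`` is required whenever ``n_perm > 0``.
    """
    if n_perm > 0 and seed is None:
        raise ValueError("a seed is required for the permutation test")
    if len(data) != len(dissim):
        raise ValueError("factor table and dissimilarity matrix differ in length")
    G = gower_center(dissim.to_numpy())
    projectors = effect_projectors(data, spec)
    denominators = ems_denominators(spec)

    ss = {name: float(np.sum(P * G)) for name, (P, _) in projectors.items()}
    df = {name: d for name, (_, d) in projectors.items()}
    ms = {name: ss[name] / df[name] if df[name] > 0 else np.nan for name in ss}

    rng = np.random.default_rng(seed)
    n = len(G)
    rows = []
    for t in spec.terms():
        d_name = denominators[t.name]
        F = ms[t.name] / ms[d_name] if ms[d_name] > 0 else np.nan
        p = np.nan
        if n_perm > 0 and np.isfinite(F):
            # Freedman-Lane: strip all modelled effects, permute the
            # residual structure whole, recompute both mean squares.
            H_red = np.full((n, n), 1.0 / n)
            for u_name, (P_u, _) in projectors.items():
                if u_name not in (t.name, RESIDUAL):
                    H_red = H_red + P_u
            R = np.eye(n) - H_red
            G_res = R @ G @ R
            P_t, P_d = projectors[t.name][0], projectors[d_name][0]
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                Gp = G_res[np.ix_(perm, perm)]
                ms_t = np.sum(P_t * Gp) / df[t.name]
                ms_d = np.sum(P_d * Gp) / df[d_name]
                f_star = ms_t / ms_d if ms_d > 0 else np.inf
                if f_star >= F:
                    exceed += 1
            p = (exceed + 1) / (n_perm + 1)
        rows.append((t.name, df[t.name], ss[t.name], ms[t.name], d_name, F, p))
    rows.append((RESIDUAL, df[RESIDUAL], ss[RESIDUAL], ms[RESIDUAL], "", np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "SS", "MS", "denominator", "pseudo_F", "p_perm"]
    )
    return PermanovaResult(table=table, n_perm=n_perm, seed=seed if seed is not None else -1,
                           spec=spec)


# ---------------------------------------------------------------------------
# nMDS
# ---------------------------------------------------------------------------

@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float
    converged: bool
    n_starts: int
    stress_history: list[float] = field(default_factory=list)


def _kruskal_stress(d: np.ndarray, d_hat: np.ndarray) -> float:
    denom = float(np.sum(d ** 2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - d_hat) ** 2) / denom))


def _smacof_nonmetric(
    delta: np.ndarray, X: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool, list[float]]:
    """Iterative majorization with monotone (isotonic) regression."""
    n = X.shape[0]
    iso = IsotonicRegression(increasing=True)
    history: list[float] = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        d = pdist(X)
        if np.all(d < 1e-12):
            # collapsed configuration: a perfect fit only if the input
            # dissimilarities are themselves all zero, else degenerate
            degenerate = bool(np.any(delta > 1e-12))
            history.append(np.inf if degenerate else 0.0)
            converged = not degenerate
            break
        d_hat = iso.fit(delta, d).predict(delta)
        # scale disparities to the configuration's size
        s = np.sum(d_hat ** 2)
        if s > 0:
            d_hat = d_hat * np.sqrt(np.sum(d ** 2) / s)
        stress = _kruskal_stress(d, d_hat)
        history.append(stress)
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, d_hat / d, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = B @ X / n
    return X - X.mean(axis=0), history[-1] if history else 0.0, converged, history


def nmds(
    dissim: pd.DataFrame,
    k: int = 2,
    n_starts: int = 50,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NmdsResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Best configuration over ``n_starts`` random starts plus one metric
    (classical scaling) start; coordinates are centred.  Non-convergence
    of the best run is reported through ``converged``, never raised.
    """
    if n_starts > 0 and seed is None:
        raise ValueError("a seed is required for the random starts")
    D = dissim.to_numpy(dtype=float)
    n = D.shape[0]
    delta = squareform(D, checks=False)
    rng = np.random.default_rng(seed)

    # metric start: classical scaling on the Gower matrix
    G = gower_center(D)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1][:k]
    metric_start = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))

    starts = [metric_start] + [rng.normal(size=(n, k)) for _ in range(n_starts)]
    best: tuple[np.ndarray, float, bool, list[float]] | None = None
    for X0 in starts:
        res = _smacof_nonmetric(delta, np.asarray(X0, dtype=float), max_iter, tol)
        if best is None or res[1] < best[1]:
            best = res
    X, stress, converged, history = best
    coords = pd.DataFrame(
        X, index=dissim.index, columns=[f"MDS{i + 1}" for i in range(k)]
    )
    return NmdsResult(coordinates=coords, stress=stress, converged=converged,
                      n_starts=len(starts), stress_history=history)


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

def simper(
    matrix: pd.DataFrame,
    grouping: Sequence,
    transform: str = "sqrt",
) -> pd.DataFrame:
    """Per-taxon contributions to average between-group Bray-Curtis
    dissimilarity, for every pair of groups.

    For each cross-group sample pair the Bray-Curtis dissimilarity is
    split additively over taxa, ``|x_ik - x_jk| / sum_k (x_ik + x_jk)``,
    and contributions are averaged over pairs.  Taxa are ranked by
    contribution; ``cum_pct`` accumulates their percentage share of the
    average dissimilarity.
    """
    groups = pd.Series(list(grouping), index=matrix.index)
    X = np.sqrt(matrix.to_numpy(dtype=float)) if transform == "sqrt" else matrix.to_numpy(dtype=float)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("SIMPER needs at least two groups")
    out = []
    for ia in range(len(levels)):
        for ib in range(ia + 1, len(levels)):
            a, b = levels[ia], levels[ib]
            Xa, Xb = X[(groups == a).to_numpy()], X[(groups == b).to_numpy()]
            if len(Xa) == 0 or len(Xb) == 0:
                raise ValueError(f"no samples in group {a!r} or {b!r}")
            # all cross pairs at once: |xa - xb| summed per taxon
            diff = np.abs(Xa[:, None, :] - Xb[None, :, :])
            tot = (Xa[:, None, :] + Xb[None, :, :]).sum(axis=2)
            if np.any(tot == 0):
                raise ValueError(
                    f"a cross-group pair between {a!r} and {b!r} is entirely zero; "
                    "Bray-Curtis undefined"
                )
            contrib = (diff / tot[:, :, None]).mean(axis=(0, 1))
            avg_d = contrib.sum()
            tab = pd.DataFrame({
                "group_a": a, "group_b": b,
                "taxon": matrix.columns,
                "contribution": contrib,
                "contribution_pct": 100 * contrib / avg_d if avg_d > 0 else np.nan,
                "average_dissimilarity": avg_d,
            }).sort_values("contribution", ascending=False, kind="stable")
            tab["cum_pct"] = tab["contribution_pct"].cumsum()
            out.append(tab)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------

@dataclass
class CcaResult:
    """Constrained correspondence analysis of a community matrix.

    ``proportion_total`` is eigenvalue / total inertia;
    ``proportion_constrained`` is eigenvalue / constrained inertia —
    both conventions for "variation explained" are reported.
    """

    eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    proportion_total: np.ndarray
    proportion_constrained: np.ndarray
    site_scores: pd.DataFrame          # weighted-average scores
    site_scores_lc: pd.DataFrame       # linear-combination scores
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    dropped_covariates: list[str] = field(default_factory=list)
    dropped_rows: list = field(default_factory=list)


def cca(matrix: pd.DataFrame, covariates: pd.DataFrame) -> CcaResult:
    """CCA: chi-square standardized community matrix regressed on
    covariates with row-mass weights, then eigen-decomposed.

    Rows (typically plots) must align between ``matrix`` and
    ``covariates``.  All-zero community rows are removed with a warning;
    collinear covariates are dropped with a warning.  Total inertia is
    the chi-square statistic of the table divided by its grand total and
    equals constrained + unconstrained inertia.
    """
    if not matrix.index.equals(covariates.index):
        raise ValueError("community matrix and covariates must share row labels")
    Y = matrix.to_numpy(dtype=float)
    if (Y < 0).any():
        raise ValueError("community matrix entries must be non-negative")
    keep = Y.sum(axis=1) > 0
    dropped_rows = [matrix.index[i] for i in np.flatnonzero(~keep)]
    if dropped_rows:
        warnings.warn(f"removing {len(dropped_rows)} all-zero community row(s)")
        Y = Y[keep]
    keep_taxa = Y.sum(axis=0) > 0
    Y = Y[:, keep_taxa]
    taxa = matrix.columns[keep_taxa]
    index = matrix.index[keep]
    Z = covariates.loc[index].to_numpy(dtype=float)

    gt = Y.sum()
    P = Y / gt
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    total_inertia = float(np.sum(Q ** 2))

    # weighted standardization of covariates; drop collinear columns
    mean_w = r @ Z
    Zc = Z - mean_w
    sd_w = np.sqrt(r @ Zc ** 2)
    keep_cov, dropped_cov = [], []
    for j, name in enumerate(covariates.columns):
        if sd_w[j] <= 0:
            dropped_cov.append(name)
            continue
        cand = keep_cov + [j]
        Xw = (np.sqrt(r)[:, None] * (Zc[:, cand] / sd_w[cand]))
        if np.linalg.matrix_rank(Xw) < len(cand):
            dropped_cov.append(name)
        else:
            keep_cov.append(j)
    if dropped_cov:
        warnings.warn(f"dropping collinear/constant covariate(s): {dropped_cov}")
    if not keep_cov:
        raise ValueError("no usable covariates remain")
    cov_names = [covariates.columns[j] for j in keep_cov]
    Xw = np.sqrt(r)[:, None] * (Zc[:, keep_cov] / sd_w[keep_cov])

    B, *_ = np.linalg.lstsq(Xw, Q, rcond=None)
    Qhat = Xw @ B
    U, S, Vt = np.linalg.svd(Qhat, full_matrices=False)
    rank = int(np.sum(S > 1e-10))
    U, S, V = U[:, :rank], S[:rank], Vt[:rank].T
    eig = S ** 2
    constrained = float(eig.sum())
    axes = [f"CCA{i + 1}" for i in range(rank)]

    with np.errstate(divide="ignore", invalid="ignore"):
        species = V * S / np.sqrt(c)[:, None]
        site_lc = U * S / np.sqrt(r)[:, None]
        site_wa = (Q @ V) / np.sqrt(r)[:, None]
    biplot = Xw.T @ U  # weighted correlations of covariates with axes

    return CcaResult(
        eigenvalues=eig,
        total_inertia=total_inertia,
        constrained_inertia=constrained,
        proportion_total=eig / total_inertia,
        proportion_constrained=eig / constrained,
        site_scores=pd.DataFrame(site_wa, index=index, columns=axes),
        site_scores_lc=pd.DataFrame(site_lc, index=index, columns=axes),
        species_scores=pd.DataFrame(species, index=taxa, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=cov_names, columns=axes),
        dropped_covariates=dropped_cov,
        dropped_rows=dropped_rows,
    )


def top_taxa(matrix: pd.DataFrame, n: int = 5) -> list[str]:
    """The n taxa with the greatest summed abundance; ties broken
    lexicographically (and logged)."""
    totals = matrix.sum(axis=0)
    ranked = totals.sort_index().sort_values(ascending=False, kind="stable")
    chosen = list(ranked.index[:n])
    if len(ranked) > n and ranked.iloc[n - 1] == ranked.iloc[n]:
        warnings.warn(f"tie at rank {n} broken lexicographically: kept {chosen[-1]!r}")
    return chosen
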