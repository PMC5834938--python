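"""Balanced mixed-model nested ANOVA with EMS-derived F ratios.

Hierarchical field surveys mix fixed factors (habitat) with random,
nested spatial factors (estuary > site > plot).  In such mixed models the
correct F denominator for each term is not the residual mean square but
the mean square whose *expectation* (EMS) equals the numerator's
expectation under the null.  This module derives those denominators
symbolically from the design using the Cornfield-Tukey algorithm under
the restricted mixed-model convention (the convention used by the
ecological ANOVA literature and the GAD package), and computes exact
sums of squares for balanced designs by orthogonal projection.

Also provides Cochran's C pre-test of variance homogeneity, the
customary companion of these designs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

RESIDUAL = "Residual"

#: named response transforms offered when Cochran's test rejects
TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "none": lambda x: np.asarray(x, dtype=float),
    "sqrt": lambda x: np.sqrt(np.asarray(x, dtype=float)),
    "log1p": lambda x: np.log1p(np.asarray(x, dtype=float)),
}


class UnbalancedDesignError(ValueError):
    """The data are not balanced; the exact EMS engine does not apply."""


class QuasiFError(ValueError):
    """No single mean square matches a term's null EMS (quasi-F needed)."""


@dataclass(frozen=True)
class Factor:
    """One classification factor of the model.

    ``nested_in`` lists ancestor factor names from the immediate parent
    outward (e.g. plot: ``("site", "estuary")``).  ``label`` is the short
    symbol used in report tables (H, E, S, P ...).
    """

    name: str
    n_levels: int
    random: bool
    nested_in: tuple[str, ...] = ()
    label: str | None = None

    @property
    def symbol(self) -> str:
        return self.label if self.label is not None else self.name


@dataclass(frozen=True)
class Term:
    """A testable model term: a set of essential factors plus, implicitly,
    all their nesting ancestors (the term's subscript set)."""

    essential: tuple[Factor, ...]
    subs: frozenset[str]
    random: bool
    name: str


@dataclass(frozen=True)
class ModelSpec:
    """A balanced mixed model: factors, their nesting tree, and the
    replicate count of the residual stratum."""

    factors: tuple[Factor, ...]
    n_replicates: int
    response: str = "y"

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor names")
        for f in self.factors:
            for anc in f.nested_in:
                if anc not in names:
                    raise ValueError(f"{f.name} nested in unknown factor {anc}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def _term_name(self, essential: Sequence[Factor]) -> str:
        parts = []
        for f in essential:
            label = f.symbol
            for anc in f.nested_in:  # immediate parent outward
                label = f"{label}({self.factor(anc).symbol}"
            label += ")" * len(f.nested_in)
            parts.append(label)
        return " × ".join(parts)

    def terms(self) -> list[Term]:
        """All model terms, ordered by increasing subscript-set size.

        A valid essential set contains no factor together with one of its
        ancestors; nesting ancestors enter through the subscript set.
        """
        out: list[Term] = []
        for r in range(1, len(self.factors) + 1):
            for combo in itertools.combinations(self.factors, r):
                names = {f.name for f in combo}
                if any(set(f.nested_in) & names for f in combo):
                    continue
                subs = set(names)
                for f in combo:
                    subs.update(f.nested_in)
                random = any(self.factor(n).random for n in subs)
                out.append(
                    Term(tuple(combo), frozenset(subs), random, self._term_name(combo))
                )
        out.sort(key=lambda t: (len(t.subs), t.name))
        return out

    @property
    def n_obs(self) -> int:
        n = self.n_replicates
        for f in self.factors:
            n *= f.n_levels
        return n


def expected_mean_squares(spec: ModelSpec) -> dict[str, dict[str, int]]:
    """Symbolic EMS for every term, as ``{term: {component: coefficient}}``.

    Cornfield-Tukey rules, restricted mixed-model convention: the
    component of term U enters EMS(T) iff U's subscripts contain T's and
    every *essential* factor of U outside T's subscripts is random
    (bracketed nesting subscripts always pass).  The coefficient is the
    product of the level counts of all subscripts absent from U,
    including the replicate subscript.
    """
    terms = spec.terms()
    all_names = {f.name for f in spec.factors}
    ems: dict[str, dict[str, int]] = {}

    def coefficient(subs: frozenset[str], has_rep: bool) -> int:
        coef = 1 if has_rep else spec.n_replicates
        for f in spec.factors:
            if f.name not in subs:
                coef *= f.n_levels
        return coef

    rows = [(t.name, t.subs, t.essential, False) for t in terms]
    rows.append((RESIDUAL, frozenset(all_names), (), True))
    for t_name, t_subs, _, t_rep in rows:
        comp: dict[str, int] = {}
        for u_name, u_subs, u_ess, u_rep in rows:
            if not (t_subs <= u_subs and (u_rep or not t_rep)):
                continue
            extra_essential = [f for f in u_ess if f.name not in t_subs]
            if any(not f.random for f in extra_essential):
                continue
            comp[u_name] = coefficient(u_subs, u_rep)
        ems[t_name] = comp
    return ems


def ems_denominators(spec: ModelSpec) -> dict[str, str]:
    """Map every testable term to its F-ratio denominator term.

    The denominator of T is the unique term whose EMS equals EMS(T)
    stripped of T's own component.  Raises :class:`QuasiFError`, naming
    the term, when no single mean square matches.
    """
    ems = expected_mean_squares(spec)
    denom: dict[str, str] = {}
    for term, comp in ems.items():
        if term == RESIDUAL:
            continue
        target = {k: v for k, v in comp.items() if k != term}
        matches = [u for u, c in ems.items() if u != term and c == target]
        if len(matches) != 1:
            raise QuasiFError(
                f"term {term!r} has no single denominator mean square "
                f"(linear combination / quasi-F required)"
            )
        denom[term] = matches[0]
    return denom


# ---------------------------------------------------------------------------
# Sums of squares by orthogonal projection (balanced designs only)
# ---------------------------------------------------------------------------

def _cell_averaging_matrix(data: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    """n x n projection onto cell means of the given factor columns."""
    n = len(data)
    if not columns:
        return np.full((n, n), 1.0 / n)
    codes = pd.MultiIndex.from_frame(data[list(columns)]).codes
    cell = np.ravel_multi_index(codes, [max(c) + 1 for c in codes])
    H = np.zeros((n, n))
    for c in np.unique(cell):
        idx = np.flatnonzero(cell == c)
        H[np.ix_(idx, idx)] = 1.0 / len(idx)
    return H


def check_balance(data: pd.DataFrame, spec: ModelSpec) -> None:
    """Raise :class:`UnbalancedDesignError` unless every full-design cell
    holds exactly ``n_replicates`` observations and every factor shows its
    declared number of levels."""
    for f in spec.factors:
        group = list(f.nested_in) + [f.name]
        n_lev = data.groupby(group, observed=True).ngroups // max(
            1, data.groupby(list(f.nested_in), observed=True).ngroups if f.nested_in else 1
        )
        if n_lev != f.n_levels:
            raise UnbalancedDesignError(
                f"factor {f.name!r}: found {n_lev} levels per parent cell, "
                f"declared {f.n_levels}; run validate_design on the input"
            )
    counts = data.groupby([f.name for f in spec.factors], observed=True).size()
    if counts.nunique() != 1 or counts.iloc[0] != spec.n_replicates:
        raise UnbalancedDesignError(
            "unequal replication across cells; the exact EMS engine requires a "
            "balanced design — run validate_design on the input"
        )


def effect_projectors(
    data: pd.DataFrame, spec: ModelSpec
) -> dict[str, tuple[np.ndarray, int]]:
    """Orthogonal effect projector and df for every term plus the residual.

    For balanced designs the cell-mean averaging operators form a lattice
    and Moebius inversion over subscript-set inclusion yields mutually
    orthogonal idempotent projectors; ``SS_term = y' P_term y`` and the
    same projectors partition a Gower-centred distance matrix for the
    multivariate analysis.
    """
    check_balance(data, spec)
    terms = spec.terms()
    n = len(data)
    grand = np.full((n, n), 1.0 / n)
    projectors: dict[str, tuple[np.ndarray, int]] = {}
    by_subs: list[tuple[frozenset[str], np.ndarray]] = []
    for t in terms:
        H = _cell_averaging_matrix(data, [f for f in (fa.name for fa in spec.factors) if f in t.subs])
        P = H - grand
        for subs_u, P_u in by_subs:
            if subs_u < t.subs:
                P = P - P_u
        by_subs.append((t.subs, P))
        projectors[t.name] = (P, int(round(np.trace(P))))
    P_res = np.eye(n) - grand - sum(P for _, P in by_subs)
    projectors[RESIDUAL] = (P_res, int(round(np.trace(P_res))))
    return projectors


@dataclass
class AnovaResult:
    """ANOVA table plus the symbolic EMS used to pick denominators."""

    table: pd.DataFrame
    spec: ModelSpec
    ems: dict[str, dict[str, int]]
    transform: str = "none"
    warnings: list[str] = field(default_factory=list)


def nested_anova(
    data: pd.DataFrame,
    spec: ModelSpec,
    transform: str | None = None,
) -> AnovaResult:
    """Exact balanced mixed-model ANOVA of one scalar response per core.

    ``data`` must contain one column per factor plus the response column.
    ``transform`` ('sqrt', 'log1p') is applied before analysis and never
    silently.  F ratios use the EMS denominator map; a zero denominator
    mean square (e.g. constant response) yields NaN F and p.
    """
    transform = transform or "none"
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; options: {sorted(TRANSFORMS)}")
    y = TRANSFORMS[transform](data[spec.response].to_numpy())
    projectors = effect_projectors(data, spec)
    denominators = ems_denominators(spec)

    ss = {name: float(y @ P @ y) for name, (P, _) in projectors.items()}
    df = {name: d for name, (_, d) in projectors.items()}
    ms = {name: (ss[name] / df[name] if df[name] > 0 else np.nan) for name in ss}

    rows = []
    for t in spec.terms():
        d_name = denominators[t.name]
        if ms[d_name] and ms[d_name] > 0 and np.isfinite(ms[d_name]):
            F = ms[t.name] / ms[d_name]
            p = float(stats.f.sf(F, df[t.name], df[d_name]))
        else:
            F, p = np.nan, np.nan
        rows.append((t.name, df[t.name], ss[t.name], ms[t.name], d_name, F, p))
    rows.append((RESIDUAL, df[RESIDUAL], ss[RESIDUAL], ms[RESIDUAL], "", np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "SS", "MS", "denominator", "F", "p"]
    )
    return AnovaResult(table=table, spec=spec, ems=expected_mean_squares(spec),
                       transform=transform)


def f_ratios_from_mean_squares(
    mean_squares: Mapping[str, float], spec: ModelSpec
) -> pd.DataFrame:
    """Form every term's F ratio from externally supplied mean squares.

    This is the desk check used against published ANOVA tables: given the
    printed MS column, the EMS denominator map alone determines every F.
    """
    denominators = ems_denominators(spec)
    rows = []
    for term, d_name in denominators.items():
        if term not in mean_squares:
            continue
        F = mean_squares[term] / mean_squares[d_name]
        rows.append((term, mean_squares[term], d_name, F))
    return pd.DataFrame(rows, columns=["term", "MS", "denominator", "F"])


def variance_components(result: AnovaResult) -> pd.DataFrame:
    """Method-of-moments variance components from the EMS equations.

    Solves the linear system ``MS = C sigma^2`` over the random terms and
    the residual.  Both the raw solution and the zero-truncated version
    customarily reported are returned.
    """
    spec = result.spec
    random_terms = [t.name for t in spec.terms() if t.random] + [RESIDUAL]
    ms = dict(zip(result.table["term"], result.table["MS"]))
    C = np.zeros((len(random_terms), len(random_terms)))
    b = np.zeros(len(random_terms))
    for i, t in enumerate(random_terms):
        b[i] = ms[t]
        for j, u in enumerate(random_terms):
            C[i, j] = result.ems[t].get(u, 0)
    raw = np.linalg.solve(C, b)
    return pd.DataFrame(
        {"term": random_terms, "component": raw, "component_truncated": np.clip(raw, 0, None)}
    )


# ---------------------------------------------------------------------------
# Cochran's C
# ---------------------------------------------------------------------------

@dataclass
class CochranResult:
    C: float
    k: int
    n_per_group: int
    p_value: float
    heterogeneous: bool
    alpha: float


def cochran_c(groups: Sequence[Sequence[float]] | np.ndarray, alpha: float = 0.05) -> CochranResult:
    """Cochran's C test of variance homogeneity across balanced groups.

    ``C = max(s_i^2) / sum(s_i^2)`` over k groups of equal size n.  The
    upper-tail p-value uses the union bound on the Beta distribution of a
    single variance ratio, ``p = min(1, k * P(Beta(v/2, (k-1)v/2) > C))``
    with ``v = n - 1`` — exact whenever the critical value exceeds 1/2
    (only one ratio can then be extreme), which holds at conventional
    alpha for the group counts met in these surveys.
    """
    arr = [np.asarray(g, dtype=float) for g in groups]
    k = len(arr)
    if k < 2:
        raise ValueError("Cochran's C needs at least two groups")
    sizes = {len(g) for g in arr}
    if len(sizes) != 1:
        raise ValueError("Cochran's C assumes balanced groups (equal replicate counts)")
    n = sizes.pop()
    if n < 2:
        raise ValueError("each group needs at least two replicates")
    variances = np.array([g.var(ddof=1) for g in arr])
    total = variances.sum()
    if total == 0:
        # no variance anywhere: perfectly homogeneous
        return CochranResult(C=1.0 / k, k=k, n_per_group=n, p_value=1.0,
                             heterogeneous=False, alpha=alpha)
    C = float(variances.max() / total)
    nu = n - 1
    p = float(min(1.0, k * stats.beta.sf(C, nu / 2.0, (k - 1) * nu / 2.0)))
    return CochranResult(C=C, k=k, n_per_group=n, p_value=p,
                         heterogeneous=p < alpha, alpha=alpha)


# ---------------------------------------------------------------------------
# Ready-made specs for the two survey designs
# ---------------------------------------------------------------------------

def core_model_spec(design, response: str = "y") -> ModelSpec:
    """Habitat (fixed) crossed with estuary/site/plot (random, nested);
    replicate cores form the residual stratum."""
    return ModelSpec(
        factors=(
            Factor("habitat", len(design.habitats), random=False, label="H"),
            Factor("estuary", len(design.estuaries), random=True, label="E"),
            Factor("site", design.sites_per_estuary, random=True,
                   nested_in=("estuary",), label="S"),
            Factor("plot", design.plots_per_site_habitat, random=True,
                   nested_in=("site", "estuary"), label="P"),
        ),
        n_replicates=design.replicates_per_plot,
        response=response,
    )


def plot_model_spec(design, response: str = "y") -> ModelSpec:
    """Plot-level responses (sediment variables): habitat crossed with
    estuary/site; the plots within each site x habitat are the residual."""
    return ModelSpec(
        factors=(
            Factor("habitat", len(design.habitats), random=False, label="H"),
            Factor("estuary", len(design.estuaries), random=True, label="E"),
            Factor("site", design.sites_per_estuary, random=True,
                   nested_in=("estuary",), label="S"),
        ),
        n_replicates=design.plots_per_site_habitat,
        response=response,
    )
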