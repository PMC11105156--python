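"""Exact partition of genetic variance across reference-free model terms.

Because every recentered coefficient is a deviation from its lower-order
expectation, the variance of the genetic score over all complexes decomposes
exactly into per-coefficient contributions: a term of magnitude ``theta`` at
epistatic order ``O`` explains ``theta**2 / A**O`` of the variance (``A`` =
alphabet size; the RE main effect sigma0 has ``O = 0``).  ``FVar`` is that
contribution as a fraction of the total.  This module computes the partition,
its roll-ups by order/site/effect type, the minimal "99% set" of terms, the
classification of interaction terms into sign / reciprocal-sign /
diminishing-returns / diminishing-costs epistasis, and the per-variant
fraction of genetic score attributable to epistasis or specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .model import (
    Complex,
    CoefficientTable,
    TermKey,
    build_indicator_row,
    score_landscape,
)
from .sequence_space import InputError

EPISTASIS_TYPES = (
    "sign",
    "reciprocal_sign",
    "diminishing_returns",
    "diminishing_costs",
)


class NotRecenteredError(ValueError):
    """The variance decomposition is only valid for recentered tables."""


def _require_recentered(coeffs: CoefficientTable) -> None:
    if not coeffs.is_recentered:
        raise NotRecenteredError(
            "variance partition requires a recentered table; call recenter()"
        )


def total_variance(
    coeffs: CoefficientTable | None = None,
    scores: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Total genetic variance Var(y(G)).

    From a recentered table it is the sum of squared coefficients weighted by
    ``A**-O`` (excluding the global intercept beta0); from complete scores it
    is the population variance of the score over all complexes.  The two
    routes agree to numerical precision.
    """
    if scores is not None:
        y = np.concatenate(scores)
        return float(np.mean((y - y.mean()) ** 2))
    if coeffs is None:
        raise InputError("provide a coefficient table or complete scores")
    _require_recentered(coeffs)
    A = coeffs.n_states
    var = 0.0
    for (etype, sites), arr in coeffs.tables.items():
        if etype == "beta" and not sites:
            continue  # the global average carries no variance
        var += float(np.sum(np.asarray(arr) ** 2)) / A ** len(sites)
    return var


def fvar(term: TermKey, coeffs: CoefficientTable) -> float:
    """Fraction of total genetic variance explained by one coefficient."""
    _require_recentered(coeffs)
    var = total_variance(coeffs)
    if var == 0:
        raise InputError("total genetic variance is zero")
    value = coeffs.get(term)
    return value**2 / (coeffs.n_states**term.order * var)


@dataclass
class VariancePartition:
    """Per-term FVar values with roll-ups by order, sites and effect type."""

    total: float
    per_term: pd.DataFrame  # effect_type, order, sites, states, value, fvar

    def by_order(self) -> pd.DataFrame:
        return (
            self.per_term.groupby(["effect_type", "order"])["fvar"]
            .sum()
            .reset_index()
        )

    def by_sites(self) -> pd.DataFrame:
        return (
            self.per_term.groupby(["effect_type", "order", "sites"])["fvar"]
            .sum()
            .reset_index()
        )


def variance_partition(coeffs: CoefficientTable) -> VariancePartition:
    """FVar of every model term (beta0 excluded: it carries no variance)."""
    _require_recentered(coeffs)
    var = total_variance(coeffs)
    if var == 0:
        raise InputError("total genetic variance is zero")
    A = coeffs.n_states
    rows = []
    for key, value in coeffs.items():
        if key.effect_type == "beta" and key.order == 0:
            continue
        rows.append(
            (
                key.effect_type,
                key.order,
                "".join(map(str, key.sites)),
                "".join(key.states),
                value,
                value**2 / (A**key.order * var),
            )
        )
    per_term = pd.DataFrame(
        rows,
        columns=["effect_type", "order", "sites", "states", "value", "fvar"],
    )
    return VariancePartition(var, per_term)


def cumulative_term_set(
    coeffs: CoefficientTable, threshold: float = 0.99
) -> pd.DataFrame:
    """Minimal prefix of FVar-ranked terms whose summed FVar reaches
    ``threshold`` (the paper-style "99% set" at the default)."""
    if not 0 < threshold <= 1:
        raise InputError("threshold must be in (0, 1]")
    part = variance_partition(coeffs)
    ranked = part.per_term.sort_values(
        "fvar", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    csum = ranked["fvar"].cumsum()
    # smallest prefix with cumulative fvar >= threshold * total explained
    target = min(threshold, float(csum.iloc[-1]))
    n_keep = int(np.searchsorted(csum.values, target - 1e-12) + 1)
    kept = ranked.iloc[:n_keep].copy()
    kept["cumulative_fvar"] = csum.iloc[:n_keep].values
    if threshold == 1.0:
        kept = kept[kept["fvar"] > 0]
    return kept


# ---------------------------------------------------------------------------
# epistasis-type classification
# ---------------------------------------------------------------------------


def _classify_pair(main_i: float, main_j: float, inter: float) -> str:
    """Sign rule for one interaction against its two constituent effects.

    A flip of ``sign(main + inter)`` vs ``sign(main)`` for one state is sign
    epistasis; for both, reciprocal sign.  Interactions that leave both
    directions intact are magnitude epistasis: negative interactions diminish
    returns (or amplify costs), positive ones diminish costs (or amplify
    returns).  A net effect of exactly zero does not count as a flip.
    """
    flips = 0
    for main in (main_i, main_j):
        before = np.sign(main)
        after = np.sign(main + inter)
        if before != 0 and after != 0 and before != after:
            flips += 1
    if flips == 2:
        return "reciprocal_sign"
    if flips == 1:
        return "sign"
    return "diminishing_returns" if inter < 0 else "diminishing_costs"


@dataclass
class EpistasisTypeSummary:
    """FVar of pairwise + third-order terms split across the four categories,
    separately for binding (beta) and specificity (sigma) terms."""

    fractions: pd.DataFrame  # effect_type x category -> fvar

    def total(self) -> float:
        return float(self.fractions["fvar"].sum())


def classify_epistasis(coeffs: CoefficientTable) -> EpistasisTypeSummary:
    """Assign the FVar of every interaction term to an epistasis category.

    Pairwise terms are compared against the main effects of their two states.
    Third-order terms are handled by fixing each of the three states in turn
    — which conditions the two remaining main effects and their interaction
    on the fixed state — and adding one third of the term's FVar per fixing.
    """
    _require_recentered(coeffs)
    if coeffs.max_order < 2:
        raise InputError("epistasis classification needs max_order >= 2")
    var = total_variance(coeffs)
    if var == 0:
        raise InputError("total genetic variance is zero")
    A = coeffs.n_states
    totals: dict[tuple[str, str], float] = {
        (etype, cat): 0.0
        for etype in ("beta", "sigma")
        for cat in EPISTASIS_TYPES
    }
    for etype in ("beta", "sigma"):
        mains = {
            s[0]: arr
            for (et, s), arr in coeffs.tables.items()
            if et == etype and len(s) == 1
        }
        pairs = {
            s: arr
            for (et, s), arr in coeffs.tables.items()
            if et == etype and len(s) == 2
        }
        for (i, j), arr in pairs.items():
            f = arr**2 / (A**2 * var)
            for qi in range(A):
                for qj in range(A):
                    inter = float(arr[qi, qj])
                    if inter == 0:
                        continue
                    cat = _classify_pair(
                        float(mains[i][qi]), float(mains[j][qj]), inter
                    )
                    totals[(etype, cat)] += float(f[qi, qj])
        triples = {
            s: arr
            for (et, s), arr in coeffs.tables.items()
            if et == etype and len(s) == 3
        }
        for sites, arr in triples.items():
            f = arr**2 / (A**3 * var)
            for fixed_pos in range(3):
                k = sites[fixed_pos]
                (pi, i), (pj, j) = [
                    (p, s)
                    for p, s in enumerate(sites)
                    if p != fixed_pos
                ]
                pair_ik = _pair_array(coeffs, etype, i, k)
                pair_jk = _pair_array(coeffs, etype, j, k)
                pair_ij = _pair_array(coeffs, etype, i, j)
                it = np.nditer(arr, flags=["multi_index"])
                for t in it:
                    inter3 = float(t)
                    if inter3 == 0:
                        continue
                    idx = it.multi_index
                    qk = idx[fixed_pos]
                    qi, qj = idx[pi], idx[pj]
                    main_i = float(mains[i][qi]) + pair_ik[qi, qk]
                    main_j = float(mains[j][qj]) + pair_jk[qj, qk]
                    inter = pair_ij[qi, qj] + inter3
                    cat = _classify_pair(main_i, main_j, inter)
                    totals[(etype, cat)] += float(f[idx]) / 3.0
    fractions = pd.DataFrame(
        [
            {"effect_type": et, "category": cat, "fvar": v}
            for (et, cat), v in totals.items()
        ]
    )
    return EpistasisTypeSummary(fractions)


def _pair_array(
    coeffs: CoefficientTable, etype: str, i: int, j: int
) -> np.ndarray:
    """Pair table for (i, j) oriented as [state_i, state_j]."""
    a, b = sorted((i, j))
    arr = coeffs.tables[(etype, (a, b))]
    return arr if (a, b) == (i, j) else arr.T


# ---------------------------------------------------------------------------
# per-variant score fractions
# ---------------------------------------------------------------------------


def epistatic_score_fraction(c: Complex, coeffs: CoefficientTable) -> float:
    """|pairwise + third-order| terms over |all| terms of one variant's score."""
    return _score_fraction(c, coeffs, lambda key: key.order >= 2)


def specificity_score_fraction(c: Complex, coeffs: CoefficientTable) -> float:
    """|specificity| terms over |all| terms of one variant's score."""
    return _score_fraction(c, coeffs, lambda key: key.effect_type == "sigma")


def _score_fraction(c: Complex, coeffs: CoefficientTable, select) -> float:
    row = build_indicator_row(c, coeffs.max_order)
    num = den = 0.0
    for key, _ in row.entries:
        mag = abs(coeffs.get(key))
        den += mag
        if select(key):
            num += mag
    if den == 0:
        return 0.0
    return num / den


def variance_conservation_error(coeffs: CoefficientTable) -> float:
    """|sum of FVar - 1| plus the coefficient-vs-score route discrepancy.

    Both quantities are ~0 for scores generated exactly by the table; exposed
    as a single diagnostic used by the acceptance checks.
    """
    part = variance_partition(coeffs)
    fvar_gap = abs(float(part.per_term["fvar"].sum()) - 1.0)
    direct = total_variance(scores=score_landscape(coeffs))
    route_gap = abs(direct - part.total) / max(part.total, 1e-300)
    return max(fvar_gap, route_gap)
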