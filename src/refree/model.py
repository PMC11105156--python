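"""Reference-free ordinal regression of multi-phenotype landscapes.

The model assigns every protein/response-element (RE) complex a latent
*genetic score* — the sum of reference-free effects of the amino-acid states
and combinations the variant contains — and maps that score onto ordered
activation classes (Null < Weak < Strong) through a cumulative (proportional
odds) logistic link::

    P(class >= Weak)   = logistic((y - theta_NW) / link_scale)
    P(class == Strong) = logistic((y - theta_WS) / link_scale)

Every state/combination carries two coefficients: a *binding* effect (beta,
its contribution averaged over the two REs) and a *specificity* effect
(sigma, added on ERE and subtracted on SRE).  All coefficients are defined as
deviations from the global average rather than from a wild-type reference,
which makes each set and marginal subset of same-order coefficients sum to
zero once recentered, and makes the exact genetic-variance partition of
:mod:`refree.variance` possible.

Fitting maximizes the L2-penalized likelihood of the cumulative model via its
two-binary recoding (Null=00, Weak=10, Strong=11 against the two thresholds)
with shared coefficients, using an analytic-gradient L-BFGS on a sparse
design.  The thresholds and the two order-0 terms are never penalized.  The
regularization strength is selected by cost-weighted, repeated k-fold
cross-validation where misclassification into an adjacent class counts one
error and Null<->Strong counts two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations, product
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
from scipy.special import expit
from scipy.stats import linregress

from .sequence_space import (
    AMINO_ACIDS,
    Genotype,
    GenotypeSpace,
    InputError,
    site_subsets,
)

CLASSES: tuple[str, ...] = ("Null", "Weak", "Strong")
CLASS_CODE: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}


class ConfigurationError(ValueError):
    """Raised when a coefficient table and a query are incompatible."""


class ConvergenceError(RuntimeError):
    """Raised when the penalized likelihood optimizer fails to converge."""


# ---------------------------------------------------------------------------
# response elements and complexes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseElement:
    """One of the two DNA response elements; sign +1 for ERE, -1 for SRE."""

    label: str
    sign: int


ERE = ResponseElement("ERE", +1)
SRE = ResponseElement("SRE", -1)
RESPONSE_ELEMENTS: dict[str, ResponseElement] = {"ERE": ERE, "SRE": SRE}


@dataclass(frozen=True)
class Complex:
    """A protein variant bound to a response element."""

    genotype: Genotype
    re: ResponseElement


# ---------------------------------------------------------------------------
# term keys and coefficient tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermKey:
    """Identifies one model coefficient.

    ``effect_type`` is ``"beta"`` (binding) or ``"sigma"`` (specificity);
    ``sites`` is a sorted tuple of 1-based site indices (empty for the two
    order-0 terms beta0 and sigma0); ``states`` the matching amino acids.
    """

    effect_type: str
    sites: tuple[int, ...]
    states: tuple[str, ...]

    def __post_init__(self):
        if self.effect_type not in ("beta", "sigma"):
            raise InputError(f"unknown effect type {self.effect_type!r}")
        if len(self.sites) != len(self.states):
            raise InputError("sites and states must have equal length")
        if tuple(sorted(self.sites)) != tuple(self.sites):
            raise InputError("sites must be sorted")

    @property
    def order(self) -> int:
        return len(self.sites)


@dataclass
class CoefficientTable:
    """All coefficients of one fitted (or constructed) model.

    Coefficients are stored per effect type and site subset as dense numpy
    arrays of shape ``(A,) * order`` (scalars for the order-0 terms), which
    keeps the zero-sum recentering and variance partition simple array
    algebra.  ``link_scale`` divides the score-threshold differences inside
    the logistic link so that the affine score rescaling of
    :func:`rescale_scores` leaves every class probability unchanged.
    """

    alphabet: tuple[str, ...]
    n_sites: int
    max_order: int
    tables: dict[tuple[str, tuple[int, ...]], np.ndarray]
    theta_nw: float
    theta_ws: float
    link_scale: float = 1.0
    is_recentered: bool = False
    lam: float | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.alphabet = tuple(self.alphabet)
        if self.max_order not in (1, 2, 3):
            raise InputError("max_order must be 1, 2, or 3")
        if not self.theta_nw <= self.theta_ws:
            raise InputError(
                "thresholds must satisfy theta_NW <= theta_WS for "
                "Null < Weak < Strong"
            )
        self._index = {s: i for i, s in enumerate(self.alphabet)}

    # -- construction -------------------------------------------------------

    @classmethod
    def zeros(
        cls,
        alphabet: Sequence[str] = AMINO_ACIDS,
        n_sites: int = 4,
        max_order: int = 3,
        theta_nw: float = 0.0,
        theta_ws: float = 0.0,
    ) -> "CoefficientTable":
        A = len(alphabet)
        tables: dict[tuple[str, tuple[int, ...]], np.ndarray] = {}
        for etype in ("beta", "sigma"):
            tables[(etype, ())] = np.zeros(())
            for order in range(1, max_order + 1):
                for sites in site_subsets(n_sites, order):
                    tables[(etype, sites)] = np.zeros((A,) * order)
        return cls(
            tuple(alphabet), n_sites, max_order, tables, theta_nw, theta_ws
        )

    def copy(self) -> "CoefficientTable":
        return replace(
            self, tables={k: v.copy() for k, v in self.tables.items()}
        )

    @property
    def space(self) -> GenotypeSpace:
        return GenotypeSpace(self.alphabet, self.n_sites)

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    @property
    def n_terms(self) -> int:
        """Total number of model coefficients, including beta0 and sigma0.

        68,962 for the default 20-state, 4-site, third-order model.
        """
        return sum(int(np.asarray(v).size) for v in self.tables.values())

    def n_terms_at_order(self, order: int, effect_type: str = "beta") -> int:
        return sum(
            int(np.asarray(v).size)
            for (et, sites), v in self.tables.items()
            if et == effect_type and len(sites) == order
        )

    # -- element access ------------------------------------------------------

    def _state_codes(self, states: Sequence[str]) -> tuple[int, ...]:
        try:
            return tuple(self._index[s] for s in states)
        except KeyError as err:
            raise ConfigurationError(
                f"state {err.args[0]!r} not in table alphabet"
            ) from None

    def get(self, key: TermKey) -> float:
        sites0 = tuple(s - 1 for s in key.sites)
        try:
            arr = self.tables[(key.effect_type, sites0)]
        except KeyError:
            raise ConfigurationError(
                f"no {key.effect_type} terms for sites {key.sites} "
                f"(max_order={self.max_order})"
            ) from None
        return float(arr[self._state_codes(key.states)])

    def set(self, key: TermKey, value: float) -> None:
        sites0 = tuple(s - 1 for s in key.sites)
        self.tables[(key.effect_type, sites0)][
            self._state_codes(key.states)
        ] = value

    def items(self) -> Iterator[tuple[TermKey, float]]:
        """Iterate over every coefficient in a fixed deterministic order."""
        for etype in ("beta", "sigma"):
            for order in range(0, self.max_order + 1):
                for sites0 in site_subsets(self.n_sites, order):
                    if (etype, sites0) not in self.tables:
                        continue
                    arr = self.tables[(etype, sites0)]
                    sites1 = tuple(s + 1 for s in sites0)
                    if order == 0:
                        yield TermKey(etype, (), ()), float(arr)
                        continue
                    for codes in product(
                        range(self.n_states), repeat=order
                    ):
                        states = tuple(self.alphabet[c] for c in codes)
                        yield TermKey(etype, sites1, states), float(arr[codes])


# ---------------------------------------------------------------------------
# indicator encoding and scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndicatorRow:
    """The sparse design row of one complex: (TermKey, indicator) pairs.

    In the full third-order model each row has exactly 30 non-zeros: the
    intercept, the RE term, and a binding plus a specificity indicator for
    each of the 4 states, 6 pairs, and 4 triplets the variant contains.
    Binding indicators are 1; specificity indicators carry the RE sign.
    """

    entries: tuple[tuple[TermKey, int], ...]

    def __len__(self) -> int:
        return len(self.entries)


def build_indicator_row(c: Complex, max_order: int = 3) -> IndicatorRow:
    """Sparse +-1/0 encoding of a complex up to ``max_order`` interactions."""
    if max_order not in (1, 2, 3):
        raise InputError("max_order must be 1, 2, or 3")
    n_sites = len(c.genotype)
    entries: list[tuple[TermKey, int]] = [
        (TermKey("beta", (), ()), 1),
        (TermKey("sigma", (), ()), c.re.sign),
    ]
    for order in range(1, max_order + 1):
        for sites0 in combinations(range(n_sites), order):
            sites1 = tuple(s + 1 for s in sites0)
            states = tuple(c.genotype.states[s] for s in sites0)
            entries.append((TermKey("beta", sites1, states), 1))
            entries.append((TermKey("sigma", sites1, states), c.re.sign))
    return IndicatorRow(tuple(entries))


def genetic_score(c: Complex, coeffs: CoefficientTable) -> float:
    """Genetic score of one complex: the signed sparse dot product of its
    indicator row with the coefficient table."""
    row = build_indicator_row(c, coeffs.max_order)
    return float(
        sum(coeffs.get(key) * value for key, value in row.entries)
    )


def _component_scores(
    coeffs: CoefficientTable, effect_type: str, codes: np.ndarray
) -> np.ndarray:
    """Sum of all terms of one effect type for every genotype in ``codes``."""
    total = np.zeros(len(codes))
    for (etype, sites0), arr in coeffs.tables.items():
        if etype != effect_type:
            continue
        if len(sites0) == 0:
            total += float(arr)
        else:
            total += arr[tuple(codes[:, s] for s in sites0)]
    return total


def score_landscape(
    coeffs: CoefficientTable, space: GenotypeSpace | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Genetic scores of every complex.

    Returns ``(y_ere, y_sre)`` in the space's enumeration order:
    ``y_ere = beta_part + sigma_part`` and ``y_sre = beta_part - sigma_part``.
    """
    space = space or coeffs.space
    codes = space.codes()
    b = _component_scores(coeffs, "beta", codes)
    s = _component_scores(coeffs, "sigma", codes)
    return b + s, b - s


def class_probabilities(
    score, theta_nw: float, theta_ws: float, link_scale: float = 1.0
):
    """(pNull, pWeak, pStrong) for a score under the cumulative logistic link.

    Larger scores give higher classes; at ``score == theta_WS`` the
    probability of being at most Weak equals 0.5.
    """
    if theta_nw > theta_ws:
        raise InputError("theta_NW must not exceed theta_WS")
    score = np.asarray(score, dtype=float)
    p_ge_weak = expit((score - theta_nw) / link_scale)
    p_strong = expit((score - theta_ws) / link_scale)
    return 1.0 - p_ge_weak, p_ge_weak - p_strong, p_strong


def predict_class_from_scores(
    scores, coeffs: CoefficientTable
) -> np.ndarray:
    """Highest-probability class code (0/1/2) per score; ties break low."""
    p = np.stack(
        class_probabilities(
            scores, coeffs.theta_nw, coeffs.theta_ws, coeffs.link_scale
        )
    )
    return np.argmax(p, axis=0)


def predict_class(c: Complex, coeffs: CoefficientTable) -> str:
    """Highest-probability activation class of one complex."""
    code = int(predict_class_from_scores(genetic_score(c, coeffs), coeffs))
    return CLASSES[code]


def predict_landscape_classes(
    coeffs: CoefficientTable, space: GenotypeSpace | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class codes on ERE and SRE for the whole space."""
    y_ere, y_sre = score_landscape(coeffs, space)
    return (
        predict_class_from_scores(y_ere, coeffs),
        predict_class_from_scores(y_sre, coeffs),
    )


# ---------------------------------------------------------------------------
# reference-free averaging (the brute-force oracle) and recentering
# ---------------------------------------------------------------------------


def _projection_from_tensor(
    tensor: np.ndarray, max_order: int
) -> dict[tuple[int, ...], np.ndarray]:
    """ANOVA components of a full score tensor up to ``max_order``.

    The component for site subset V is the inclusion-exclusion sum of subset
    means ``sum_{W subseteq V} (-1)^{|V|-|W|} mean_{sites not in W}``, i.e.
    exactly the reference-free definitions: main effects are subset-mean
    deviations from the global mean, higher orders are deviations from the
    sum of their lower-order expectations.
    """
    n_sites = tensor.ndim
    all_axes = set(range(n_sites))
    out: dict[tuple[int, ...], np.ndarray] = {
        (): np.asarray(tensor.mean())
    }
    for order in range(1, max_order + 1):
        for sites in site_subsets(n_sites, order):
            comp = np.zeros(tuple(tensor.shape[s] for s in sites))
            for k in range(order + 1):
                for w in combinations(sites, k):
                    m = tensor.mean(axis=tuple(sorted(all_axes - set(w))))
                    # expand the W-shaped mean to V shape
                    shape = [1] * order
                    for pos, s in enumerate(sites):
                        if s in w:
                            shape[pos] = tensor.shape[s]
                    m = m.reshape(shape)
                    comp = comp + ((-1) ** (order - k)) * m
            out[sites] = comp
    return out


def reffree_coefficients_from_scores(
    y_ere: np.ndarray,
    y_sre: np.ndarray,
    space: GenotypeSpace,
    max_order: int = 3,
    theta_nw: float = 0.0,
    theta_ws: float = 0.0,
) -> CoefficientTable:
    """Reference-free coefficients computed directly from complete scores.

    Implements the averaging definitions verbatim: beta0 is the global mean
    over all complexes, sigma0 is half the difference between the ERE and SRE
    means, main effects are subset-mean deviations, and higher orders are
    deviations from lower-order sums.  Serves as the brute-force oracle for
    the regression fit and for recentering; reconstruction is exact whenever
    the generating scores contain no interaction above ``max_order``.
    """
    y_ere = np.asarray(y_ere, dtype=float)
    y_sre = np.asarray(y_sre, dtype=float)
    if y_ere.shape != (space.size,) or y_sre.shape != (space.size,):
        raise InputError(
            "scores must cover the complete space on both REs "
            f"(expected length {space.size})"
        )
    A, S = space.n_states, space.n_sites
    shape = (A,) * S
    b_tensor = ((y_ere + y_sre) / 2.0).reshape(shape)
    s_tensor = ((y_ere - y_sre) / 2.0).reshape(shape)
    tables: dict[tuple[str, tuple[int, ...]], np.ndarray] = {}
    for etype, tensor in (("beta", b_tensor), ("sigma", s_tensor)):
        for sites, comp in _projection_from_tensor(tensor, max_order).items():
            tables[(etype, sites)] = comp
    return CoefficientTable(
        space.alphabet,
        S,
        max_order,
        tables,
        theta_nw,
        theta_ws,
        is_recentered=True,
    )


def recenter(coeffs: CoefficientTable) -> CoefficientTable:
    """Impose the zero-sum constraint by subtracting marginal averages.

    Works directly on the coefficients: the recentered coefficient for site
    subset V collects, from every stored subset U containing V, the
    inclusion-exclusion combination of marginal averages of the unconstrained
    U-coefficients; the intercepts absorb all the grand means.  Each set and
    marginal subset of same-order coefficients then averages to zero, and no
    complex's genetic score changes.
    """
    A = coeffs.n_states
    new_tables: dict[tuple[str, tuple[int, ...]], np.ndarray] = {}
    for etype in ("beta", "sigma"):
        subsets = [
            sites for (et, sites) in coeffs.tables if et == etype
        ]
        # intercept absorbs the grand mean of every set
        intercept = sum(
            float(np.mean(coeffs.tables[(etype, u)])) for u in subsets
        )
        new_tables[(etype, ())] = np.asarray(intercept)
        for v in subsets:
            if not v:
                continue
            order = len(v)
            comp = np.zeros((A,) * order)
            for u in subsets:
                if not set(v) <= set(u):
                    continue
                arr = coeffs.tables[(etype, u)]
                for k in range(order + 1):
                    for w in combinations(v, k):
                        keep = set(w)
                        axes = tuple(
                            i for i, s in enumerate(u) if s not in keep
                        )
                        m = arr.mean(axis=axes) if axes else arr
                        shape = [1] * order
                        for pos, s in enumerate(v):
                            if s in keep:
                                shape[pos] = A
                        comp = comp + ((-1) ** (order - k)) * m.reshape(
                            shape
                        )
            new_tables[(etype, v)] = comp
    return replace(coeffs, tables=new_tables, is_recentered=True)


def check_zero_sum(coeffs: CoefficientTable, tol: float = 1e-9) -> float:
    """Largest absolute set or marginal-subset mean; 0 for a centered table."""
    worst = 0.0
    for (etype, sites), arr in coeffs.tables.items():
        if not sites:
            continue
        for k in range(len(sites)):
            for keep in combinations(range(len(sites)), k):
                axes = tuple(
                    i for i in range(len(sites)) if i not in keep
                )
                worst = max(worst, float(np.abs(arr.mean(axis=axes)).max()))
    return worst


def rescale_scores(coeffs: CoefficientTable) -> CoefficientTable:
    """Affinely rescale so the global mean score is 0 and theta_WS is 1.

    The same affine map is applied to every coefficient and both thresholds,
    and the link scale is multiplied accordingly, so every class probability
    (and hence every predicted class) is unchanged.
    """
    mean_score = sum(
        float(np.mean(arr))
        for (etype, sites), arr in coeffs.tables.items()
        if etype == "beta"
    )
    denom = coeffs.theta_ws - mean_score
    if denom == 0:
        raise InputError(
            "theta_WS equals the global mean score; rescaling undefined"
        )
    a = 1.0 / denom
    new_tables: dict[tuple[str, tuple[int, ...]], np.ndarray] = {}
    for (etype, sites), arr in coeffs.tables.items():
        if etype == "beta" and not sites:
            new_tables[(etype, sites)] = np.asarray(
                (float(arr) - mean_score) * a
            )
        else:
            new_tables[(etype, sites)] = arr * a
    return replace(
        coeffs,
        tables=new_tables,
        theta_nw=(coeffs.theta_nw - mean_score) * a,
        theta_ws=1.0,
        link_scale=coeffs.link_scale * a,
    )


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


def dataset_arrays(
    dataset: pd.DataFrame, space: GenotypeSpace
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert a variant-class table into (genotype codes, RE signs, class codes).

    The table needs columns ``genotype`` (contiguous one-letter string),
    ``re`` (ERE/SRE), and ``cls`` (Null/Weak/Strong).
    """
    required = {"genotype", "re", "cls"}
    missing = required - set(dataset.columns)
    if missing:
        raise InputError(f"dataset missing columns {sorted(missing)}")
    index = {s: i for i, s in enumerate(space.alphabet)}
    try:
        codes = np.array(
            [[index[ch] for ch in g] for g in dataset["genotype"]],
            dtype=np.int64,
        )
    except KeyError as err:
        raise InputError(
            f"unknown amino-acid symbol {err.args[0]!r} in dataset"
        ) from None
    if codes.shape[1] != space.n_sites:
        raise InputError(
            f"genotypes must have {space.n_sites} sites, "
            f"got {codes.shape[1]}"
        )
    try:
        signs = np.array(
            [RESPONSE_ELEMENTS[r].sign for r in dataset["re"]],
            dtype=np.int64,
        )
    except KeyError as err:
        raise InputError(f"unknown RE label {err.args[0]!r}") from None
    try:
        y = np.array([CLASS_CODE[c] for c in dataset["cls"]], dtype=np.int64)
    except KeyError as err:
        raise InputError(f"unknown class label {err.args[0]!r}") from None
    return codes, signs, y


# ---------------------------------------------------------------------------
# sparse design and penalized proportional-odds fitting
# ---------------------------------------------------------------------------


def _column_layout(
    A: int, n_sites: int, max_order: int
) -> tuple[dict[tuple[str, tuple[int, ...]], int], int, np.ndarray]:
    """Column offsets for the fitted design (sigma0 first; beta0 omitted).

    Returns the offset of every (effect_type, site subset) block, the total
    column count, and the penalty mask (sigma0 unpenalized).
    """
    offsets: dict[tuple[str, tuple[int, ...]], int] = {("sigma", ()): 0}
    pos = 1
    for etype in ("beta", "sigma"):
        for order in range(1, max_order + 1):
            for sites in site_subsets(n_sites, order):
                offsets[(etype, sites)] = pos
                pos += A**order
    mask = np.ones(pos)
    mask[0] = 0.0
    return offsets, pos, mask


def _design_rows(
    codes: np.ndarray, signs: np.ndarray, A: int, max_order: int
) -> sp.csr_matrix:
    """Sparse design matrix for arbitrary complexes (one row each)."""
    n = len(codes)
    n_sites = codes.shape[1]
    offsets, P, _ = _column_layout(A, n_sites, max_order)
    nnz_per_row = len(offsets)
    cols = np.empty((n, nnz_per_row), dtype=np.int32)
    data = np.empty((n, nnz_per_row), dtype=np.float64)
    cols[:, 0] = 0
    data[:, 0] = signs
    for j, ((etype, sites), off) in enumerate(
        (item for item in offsets.items() if item[0][1]), start=1
    ):
        flat = np.zeros(n, dtype=np.int64)
        for s in sites:
            flat = flat * A + codes[:, s]
        cols[:, j] = off + flat
        data[:, j] = 1.0 if etype == "beta" else signs
    indptr = np.arange(0, (n + 1) * nnz_per_row, nnz_per_row, dtype=np.int64)
    return sp.csr_matrix(
        (data.ravel(), cols.ravel(), indptr), shape=(n, P)
    )


def _table_from_solution(
    w: np.ndarray,
    theta: np.ndarray,
    alphabet: Sequence[str],
    n_sites: int,
    max_order: int,
    lam: float,
) -> CoefficientTable:
    A = len(alphabet)
    offsets, _, _ = _column_layout(A, n_sites, max_order)
    tables: dict[tuple[str, tuple[int, ...]], np.ndarray] = {
        ("beta", ()): np.asarray(0.0),
        ("sigma", ()): np.asarray(float(w[0])),
    }
    for (etype, sites), off in offsets.items():
        if not sites:
            continue
        size = A ** len(sites)
        tables[(etype, sites)] = (
            w[off : off + size].reshape((A,) * len(sites)).copy()
        )
    return CoefficientTable(
        tuple(alphabet),
        n_sites,
        max_order,
        tables,
        float(theta[0]),
        float(theta[1]),
        lam=lam,
    )


def _fit_binary_stack(
    X: sp.csr_matrix,
    targets: np.ndarray,
    lam: float,
    pen_mask: np.ndarray,
    x0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximize the shared-coefficient stacked-binary logistic likelihood.

    ``targets`` has one column per threshold (here: class >= Weak and
    class >= Strong); each threshold gets its own unpenalized intercept while
    the coefficient vector is shared, which is exactly the proportional-odds
    model.  Returns (thresholds, coefficients, converged).
    """
    n, P = X.shape
    K = targets.shape[1]
    b = targets.astype(np.float64)

    def objective(p):
        theta, w = p[:K], p[K:]
        s = X @ w
        eta = s[:, None] - theta[None, :]
        nll = np.logaddexp(0.0, eta) - b * eta
        r = expit(eta) - b
        value = nll.sum() / n + 0.5 * lam * np.dot(pen_mask * w, w)
        grad_w = (X.T @ r.sum(axis=1)) / n + lam * pen_mask * w
        grad_theta = -r.sum(axis=0) / n
        return value, np.concatenate([grad_theta, grad_w])

    if x0 is None:
        x0 = np.zeros(K + P)
        x0[:K] = np.linspace(-0.1, 0.1, K)
    res = scipy.optimize.minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6},
    )
    theta, w = res.x[:K], res.x[K:]
    return theta, w, bool(res.success)


@dataclass
class FitConfig:
    """Regularization path, cross-validation layout, and optimizer knobs.

    The default lambda grid spans 1e-1 down to 1e-8 on a log10 scale (900
    values) with 10x repeated 10-fold cross-validation; ``reduced`` gives a
    desk-scale configuration (20 lambdas, 3 folds, 1 repeat).
    """

    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-1, -8, 900)
    )
    folds: int = 10
    repeats: int = 10
    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self):
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if np.any(np.diff(self.lambda_grid) >= 0):
            raise InputError("lambda grid must be strictly decreasing")
        if self.folds < 2:
            raise InputError("need at least 2 folds")

    @classmethod
    def reduced(cls, seed: int = 0, n_lambda: int = 20) -> "FitConfig":
        return cls(
            lambda_grid=np.logspace(-1, -8, n_lambda),
            folds=3,
            repeats=1,
            seed=seed,
        )


@dataclass
class FitResult:
    """Fitted coefficients plus the cross-validation curve that chose lambda."""

    coefficients: CoefficientTable
    cv_curve: pd.DataFrame  # columns: lam, mean_misclassification, se
    chosen_lambda: float


def weighted_misclassification(
    predicted: np.ndarray, observed: np.ndarray
) -> float:
    """Mean per-complex error cost: adjacent-class errors count 1,
    Null<->Strong counts 2."""
    return float(np.abs(predicted - observed).mean())


def _cv_folds(
    n: int, folds: int, y: np.ndarray, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random equal fold assignment; redrawn until every training set
    contains all three classes."""
    for _ in range(100):
        assign = rng.permutation(n) % folds
        ok = all(
            len(np.unique(y[assign != f])) == len(CLASSES)
            for f in range(folds)
        )
        if ok:
            return [np.flatnonzero(assign == f) for f in range(folds)]
    raise InputError(
        "could not draw cross-validation folds whose training sets "
        "contain all classes"
    )


def fit(
    dataset: pd.DataFrame,
    config: FitConfig | None = None,
    max_order: int = 3,
    space: GenotypeSpace | None = None,
) -> FitResult:
    """Fit the L2-penalized proportional-odds model to a variant-class table.

    Lambda is selected by repeated k-fold cross-validation minimizing the
    mean cost-weighted misclassification rate; the final model is refit on
    all data at the chosen lambda.  The returned table is *not* recentered;
    apply :func:`recenter` to obtain reference-free coefficients.
    """
    config = config or FitConfig()
    if space is None:
        n_sites = len(str(dataset["genotype"].iloc[0]))
        space = GenotypeSpace(AMINO_ACIDS, n_sites)
    codes, signs, y = dataset_arrays(dataset, space)
    n = len(y)
    if len(np.unique(y)) < len(CLASSES):
        raise InputError(
            "training data must contain all three activation classes"
        )
    key = codes @ (space.n_states ** np.arange(space.n_sites)[::-1]) * 2 + (
        signs < 0
    )
    if len(np.unique(key)) != n:
        raise InputError("duplicate complexes in dataset")
    A = space.n_states
    X = _design_rows(codes, signs, A, max_order)
    _, P, pen_mask = _column_layout(A, space.n_sites, max_order)
    targets = np.stack([y >= 1, y >= 2], axis=1)
    lambdas = config.lambda_grid
    rng = np.random.default_rng(config.seed)

    rates = np.zeros((config.repeats, len(lambdas)))
    for rep in range(config.repeats):
        folds = _cv_folds(n, config.folds, y, rng)
        fold_rates = np.zeros((config.folds, len(lambdas)))
        for fi, test_idx in enumerate(folds):
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            Xtr = X[train_mask]
            btr = targets[train_mask]
            Xte = X[test_idx]
            yte = y[test_idx]
            x0 = None
            for li, lam in enumerate(lambdas):
                theta, w, _ = _fit_binary_stack(
                    Xtr,
                    btr,
                    lam,
                    pen_mask,
                    x0=x0,
                    tol=config.tol,
                    max_iter=config.max_iter,
                )
                x0 = np.concatenate([theta, w])
                s_te = Xte @ w
                p = np.stack(
                    class_probabilities(s_te, theta[0], theta[1])
                )
                pred = np.argmax(p, axis=0)
                fold_rates[fi, li] = weighted_misclassification(pred, yte)
        rates[rep] = fold_rates.mean(axis=0)

    mean_rates = rates.mean(axis=0)
    se = (
        rates.std(axis=0, ddof=1) / np.sqrt(config.repeats)
        if config.repeats > 1
        else np.zeros_like(mean_rates)
    )
    best = int(np.argmin(mean_rates))  # ties -> larger lambda
    chosen = float(lambdas[best])

    # final fit on all data, warm-started along the path down to chosen
    x0 = None
    theta = w = None
    for lam in lambdas[: best + 1]:
        theta, w, converged = _fit_binary_stack(
            X,
            targets,
            lam,
            pen_mask,
            x0=x0,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        x0 = np.concatenate([theta, w])
    if not converged:
        raise ConvergenceError(
            f"final fit at lambda={chosen:g} did not converge "
            f"(max_iter={config.max_iter}, tol={config.tol:g})"
        )
    coeffs = _table_from_solution(
        w, theta, space.alphabet, space.n_sites, max_order, chosen
    )
    curve = pd.DataFrame(
        {"lam": lambdas, "mean_misclassification": mean_rates, "se": se}
    )
    return FitResult(coeffs, curve, chosen)


# ---------------------------------------------------------------------------
# diagnostics and calibration
# ---------------------------------------------------------------------------


def check_proportional_odds(
    dataset: pd.DataFrame,
    max_order: int = 1,
    lam: float = 1e-4,
    space: GenotypeSpace | None = None,
) -> tuple[pd.DataFrame, float]:
    """Compare coefficients across the two binary collapses of the classes.

    Fits two plain ridge-logistic regressions — Null vs. Weak-or-Strong and
    Null-or-Weak vs. Strong — with the same design, and returns the paired
    coefficient estimates with their Pearson correlation.  Under proportional
    odds the two estimates should be nearly identical (the small ridge also
    keeps perfectly separated collapses finite).  Diagnostic only.
    """
    if lam <= 0:
        raise InputError("lam must be positive (guards perfect separation)")
    if space is None:
        n_sites = len(str(dataset["genotype"].iloc[0]))
        space = GenotypeSpace(AMINO_ACIDS, n_sites)
    codes, signs, y = dataset_arrays(dataset, space)
    X = _design_rows(codes, signs, space.n_states, max_order)
    _, P, pen_mask = _column_layout(space.n_states, space.n_sites, max_order)
    estimates = []
    for cut in (1, 2):
        b = (y >= cut).astype(float)[:, None]
        if b.min() == b.max():
            raise InputError(
                f"degenerate collapse at cut {cut}: only one class present"
            )
        _, w, _ = _fit_binary_stack(X, b, lam, pen_mask)
        estimates.append(w)
    pairs = pd.DataFrame(
        {"null_vs_rest": estimates[0], "strong_vs_rest": estimates[1]}
    )
    corr = float(
        np.corrcoef(estimates[0][1:], estimates[1][1:])[0, 1]
    )  # skip sigma0: intercept-like
    return pairs, corr


def calibrate_ddg(scores, dg_measurements) -> tuple[float, float, float]:
    """Least-squares line relating genetic score to measured binding ΔG.

    Both quantities accrue additively over states, so a linear relationship
    is expected.  Returns (slope, intercept, R^2).
    """
    scores = np.asarray(scores, dtype=float)
    dg = np.asarray(dg_measurements, dtype=float)
    if len(scores) < 3:
        raise InputError("need at least 3 paired observations")
    if np.allclose(scores, scores[0]):
        raise InputError("scores have zero variance; calibration undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = linregress(scores, dg)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def predict_ddg(
    coeffs: CoefficientTable, slope: float, intercept: float
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a score->ΔG calibration line to every complex."""
    y_ere, y_sre = score_landscape(coeffs)
    return slope * y_ere + intercept, slope * y_sre + intercept
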