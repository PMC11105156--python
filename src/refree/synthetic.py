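"""Synthetic combinatorial landscapes with known ground-truth architecture.

The generator draws reference-free coefficients per epistatic order — with
magnitudes that decay with order, mimicking landscapes where main and
pairwise effects dominate and higher-order epistasis is tiny — recenters them
exactly, and emits complete ordinal class labels for every protein/RE complex.
Every pipeline stage (fitting, variance partitioning, mutation catalogs,
networks, simulations) is therefore testable against known truth without any
experimental download.

The defaults emulate the statistical shape of a 20-state x 4-site combinatorial
DMS: dense small-magnitude main and pairwise effects for binding and
specificity, tiny third-order terms, and thresholds placed so that strong
activators are a small minority of the library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .model import (
    CLASSES,
    CoefficientTable,
    class_probabilities,
    predict_class_from_scores,
    recenter,
    score_landscape,
)
from .sequence_space import AMINO_ACIDS, GenotypeSpace, InputError, site_subsets


@dataclass
class SyntheticSpec:
    """Ground-truth landscape parameters.

    ``beta_sd`` / ``sigma_sd`` give the coefficient standard deviation per
    order 1..max_order (before recentering); ``sparsity`` the fraction of
    coefficients zeroed per order.  ``label_noise`` is the probability that a
    complex's class is sampled from its ordinal class probabilities instead
    of taken as the argmax.  Thresholds are in raw score units; with the
    default score scale (total SD around 2.4) they make strong activators a
    clear minority, as in real activation landscapes.
    """

    alphabet: tuple[str, ...] = AMINO_ACIDS
    n_sites: int = 4
    max_order: int = 3
    beta_sd: tuple[float, ...] = (1.0, 0.5, 0.1)
    sigma_sd: tuple[float, ...] = (0.5, 0.3, 0.05)
    sparsity: tuple[float, ...] = (0.0, 0.0, 0.0)
    beta0: float = 0.0
    sigma0: float = 0.25
    theta_nw: float = 3.0
    theta_ws: float = 6.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.beta_sd) < self.max_order or len(self.sigma_sd) < self.max_order:
            raise InputError("need a coefficient SD per order")
        if any(s < 0 for s in self.beta_sd + self.sigma_sd):
            raise InputError("coefficient SDs must be >= 0")
        if any(not 0 <= f <= 1 for f in self.sparsity):
            raise InputError("sparsity fractions must lie in [0, 1]")
        if not 0 <= self.label_noise <= 1:
            raise InputError("label_noise must lie in [0, 1]")

    @property
    def space(self) -> GenotypeSpace:
        return GenotypeSpace(self.alphabet, self.n_sites)


def generate_coefficients(spec: SyntheticSpec) -> CoefficientTable:
    """Draw a ground-truth coefficient table satisfying all zero-sum
    constraints exactly.

    Coefficients are drawn i.i.d. normal per order, a sparsity-chosen subset
    is zeroed, and the table is recentered so every set and marginal subset
    averages to zero (recentering keeps scores identical, so the stored
    table *is* the ground truth for recovery tests).
    """
    rng = np.random.default_rng(spec.seed)
    A = len(spec.alphabet)
    tables: dict[tuple[str, tuple[int, ...]], np.ndarray] = {
        ("beta", ()): np.asarray(float(spec.beta0)),
        ("sigma", ()): np.asarray(float(spec.sigma0)),
    }
    for etype, sds in (("beta", spec.beta_sd), ("sigma", spec.sigma_sd)):
        for order in range(1, spec.max_order + 1):
            sd = sds[order - 1]
            sparsity = (
                spec.sparsity[order - 1]
                if order - 1 < len(spec.sparsity)
                else 0.0
            )
            for sites in site_subsets(spec.n_sites, order):
                arr = rng.normal(0.0, sd, size=(A,) * order) if sd > 0 else (
                    np.zeros((A,) * order)
                )
                if sparsity > 0:
                    mask = rng.random(arr.shape) < sparsity
                    arr[mask] = 0.0
                tables[(etype, sites)] = arr
    raw = CoefficientTable(
        spec.alphabet,
        spec.n_sites,
        spec.max_order,
        tables,
        spec.theta_nw,
        spec.theta_ws,
    )
    return recenter(raw)


def sample_classes(
    coeffs: CoefficientTable, spec: SyntheticSpec
) -> pd.DataFrame:
    """Variant-class table for the complete space on both REs.

    In deterministic mode (``label_noise = 0``) labels are the
    highest-probability class; with noise ``p`` each complex's label is,
    with probability ``p``, drawn from its ordinal class probabilities.
    """
    rng = np.random.default_rng(spec.seed + 1)
    space = coeffs.space
    y_ere, y_sre = score_landscape(coeffs, space)
    genotypes = [str(space.decode(i)) for i in range(space.size)]
    frames = []
    for re_label, y in (("ERE", y_ere), ("SRE", y_sre)):
        labels = predict_class_from_scores(y, coeffs)
        if spec.label_noise > 0:
            probs = np.stack(
                class_probabilities(
                    y, coeffs.theta_nw, coeffs.theta_ws, coeffs.link_scale
                ),
                axis=1,
            )
            u = rng.random(space.size)
            noisy = rng.random(space.size) < spec.label_noise
            cum = probs.cumsum(axis=1)
            sampled = (u[:, None] > cum).sum(axis=1)
            labels = np.where(noisy, sampled, labels)
        frames.append(
            pd.DataFrame(
                {
                    "genotype": genotypes,
                    "re": re_label,
                    "cls": [CLASSES[c] for c in labels],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# deterministic fixtures shared across the test-suite and examples
# ---------------------------------------------------------------------------


def _labeled_graph(edges, labels) -> nx.Graph:
    g = nx.Graph()
    for node, label in labels.items():
        g.add_node(node, phenotype=label)
    g.add_edges_from(edges)
    return g


@dataclass(frozen=True)
class FixtureLandscapes:
    """Named small instances with hand-verifiable answers."""

    chain: nx.Graph = field(default_factory=lambda: _labeled_graph(
        [("a", "x"), ("x", "b")],
        {"a": "ERE-specific", "x": "promiscuous", "b": "SRE-specific"},
    ))
    diamond: nx.Graph = field(default_factory=lambda: _labeled_graph(
        [("a", "x"), ("a", "y"), ("x", "b"), ("y", "b")],
        {
            "a": "ERE-specific",
            "x": "promiscuous",
            "y": "promiscuous",
            "b": "SRE-specific",
        },
    ))
    cube: nx.Graph = field(default_factory=lambda: _labeled_graph(
        [
            (u, v)
            for u in ["000", "001", "010", "011", "100", "101", "110", "111"]
            for v in ["000", "001", "010", "011", "100", "101", "110", "111"]
            if sum(a != b for a, b in zip(u, v)) == 1 and u < v
        ],
        {
            "000": "ERE-specific",
            "111": "SRE-specific",
            **{
                n: "promiscuous"
                for n in ["001", "010", "011", "100", "101", "110"]
            },
        },
    ))


def fixture_landscapes() -> FixtureLandscapes:
    """Chain, diamond and 3-cube networks used throughout the tests:
    1, 2, and 6 shortest paths between their opposite ends."""
    return FixtureLandscapes()


def single_term_table(
    alphabet=("A", "C"), n_sites: int = 2, value: float = 1.0
) -> CoefficientTable:
    """A centered table whose variance comes from one main-effect contrast."""
    table = CoefficientTable.zeros(alphabet, n_sites, max_order=2)
    arr = table.tables[("beta", (0,))]
    arr[0] = value
    arr[1:] = -value / (len(alphabet) - 1)
    table.is_recentered = True
    return table
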