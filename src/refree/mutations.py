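"""Context-specific mutation effects and their epistatic decomposition.

A mutation exchanges the state at one site and thereby replaces one main
effect, three pairwise interactions, and three third-order interactions (for
both binding and specificity), so its effect on the genetic score is the sum
of 14 coefficient differences.  This module computes those decompositions,
the direction profile of each of the 1520 mutation types across its 8000
genetic backgrounds, catalogs of context-specific mutations that promote a
variant's activation class or switch its RE specificity, and the calls of
whether epistasis is necessary and/or sufficient for each transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    CLASSES,
    Complex,
    CoefficientTable,
    ResponseElement,
    RESPONSE_ELEMENTS,
    TermKey,
    build_indicator_row,
    genetic_score,
    predict_class,
    predict_landscape_classes,
    score_landscape,
)
from .sequence_space import AdjacencyRule, Genotype, InputError


@dataclass(frozen=True)
class MutationType:
    """A single-residue exchange: site (1-based), from-state, to-state."""

    site: int
    from_state: str
    to_state: str

    def __post_init__(self):
        if self.from_state == self.to_state:
            raise InputError("from-state and to-state must differ")


def n_mutation_types(coeffs: CoefficientTable) -> int:
    """Number of distinct mutation types (1520 in the default space)."""
    A = coeffs.n_states
    return coeffs.n_sites * A * (A - 1)


@dataclass
class MutationEffectRecord:
    """One mutation in one background on one RE, fully decomposed.

    ``components`` maps (sites, effect_type) -> signed score change, with one
    main entry, three pairwise and three third-order entries per effect type
    in the full model; their sum equals ``delta_score``.
    """

    background: tuple[str, ...]
    mutation: MutationType
    re: ResponseElement
    score_before: float
    delta_score: float
    components: dict[tuple[tuple[int, ...], str], float]
    class_before: str
    class_after: str

    @property
    def delta_main(self) -> float:
        return sum(
            v for (sites, _), v in self.components.items() if len(sites) == 1
        )

    @property
    def delta_pairwise(self) -> float:
        return sum(
            v for (sites, _), v in self.components.items() if len(sites) == 2
        )

    @property
    def delta_third(self) -> float:
        return sum(
            v for (sites, _), v in self.components.items() if len(sites) == 3
        )

    @property
    def delta_epistatic(self) -> float:
        return self.delta_pairwise + self.delta_third


def mutation_effect(
    g: Genotype | str,
    site: int,
    to_state: str,
    re: ResponseElement | str,
    coeffs: CoefficientTable,
) -> MutationEffectRecord:
    """Effect of mutating ``site`` (1-based) of ``g`` to ``to_state`` on ``re``.

    The score change is decomposed into the coefficient differences of the
    one main effect and every interaction involving the mutated site, split
    into binding and specificity parts (specificity parts carry the RE sign).
    """
    if isinstance(g, str):
        g = Genotype.from_string(g)
    if isinstance(re, str):
        re = RESPONSE_ELEMENTS[re]
    site0 = site - 1
    old_state = g.states[site0]
    if to_state == old_state:
        raise InputError("mutation must change the state")
    new_states = list(g.states)
    new_states[site0] = to_state
    g_new = Genotype(tuple(new_states))

    components: dict[tuple[tuple[int, ...], str], float] = {}
    row_old = {k: v for k, v in build_indicator_row(
        Complex(g, re), coeffs.max_order).entries}
    row_new = {k: v for k, v in build_indicator_row(
        Complex(g_new, re), coeffs.max_order).entries}
    for key, ind in row_new.items():
        if key.order == 0 or site not in key.sites:
            continue
        delta = coeffs.get(key) * ind
        old_key = TermKey(
            key.effect_type,
            key.sites,
            tuple(
                old_state if s == site else st
                for s, st in zip(key.sites, key.states)
            ),
        )
        delta -= coeffs.get(old_key) * row_old[old_key]
        components[(key.sites, key.effect_type)] = components.get(
            (key.sites, key.effect_type), 0.0
        ) + delta

    score_before = genetic_score(Complex(g, re), coeffs)
    score_after = genetic_score(Complex(g_new, re), coeffs)
    return MutationEffectRecord(
        background=tuple(
            s for i, s in enumerate(g.states) if i != site0
        ),
        mutation=MutationType(site, old_state, to_state),
        re=re,
        score_before=score_before,
        delta_score=score_after - score_before,
        components=components,
        class_before=predict_class(Complex(g, re), coeffs),
        class_after=predict_class(Complex(g_new, re), coeffs),
    )


def _score_tensor(
    coeffs: CoefficientTable, re: ResponseElement
) -> np.ndarray:
    y_ere, y_sre = score_landscape(coeffs)
    y = y_ere if re.sign > 0 else y_sre
    A, S = coeffs.n_states, coeffs.n_sites
    return y.reshape((A,) * S)


def direction_profile(
    mt: MutationType,
    re: ResponseElement | str,
    coeffs: CoefficientTable,
    min_effect: float = 0.05,
) -> tuple[float, float]:
    """Fractions of backgrounds where a mutation type increases / decreases
    the genetic score by more than ``min_effect``.

    Intended for rescaled score units (global mean 0, strong threshold 1), so
    the default 0.05 is 5% of the mean-to-strong-threshold gap.  Changes of
    magnitude at most ``min_effect`` count toward neither fraction.
    """
    if isinstance(re, str):
        re = RESPONSE_ELEMENTS[re]
    index = {s: i for i, s in enumerate(coeffs.alphabet)}
    y = _score_tensor(coeffs, re)
    axis = mt.site - 1
    delta = np.take(y, index[mt.to_state], axis=axis) - np.take(
        y, index[mt.from_state], axis=axis
    )
    delta = delta.ravel()
    frac_up = float(np.mean(delta > min_effect))
    frac_down = float(np.mean(delta < -min_effect))
    return frac_up, frac_down


def direction_profile_table(
    coeffs: CoefficientTable,
    re: ResponseElement | str,
    min_effect: float = 0.05,
) -> pd.DataFrame:
    """Direction profile of every mutation type on one RE."""
    if isinstance(re, str):
        re = RESPONSE_ELEMENTS[re]
    rows = []
    for site in range(1, coeffs.n_sites + 1):
        for a in coeffs.alphabet:
            for b in coeffs.alphabet:
                if a == b:
                    continue
                up, down = direction_profile(
                    MutationType(site, a, b), re, coeffs, min_effect
                )
                rows.append((site, a, b, up, down))
    return pd.DataFrame(
        rows,
        columns=["site", "from", "to", "frac_increase", "frac_decrease"],
    )


def class_transitions(coeffs: CoefficientTable) -> pd.DataFrame:
    """Catalog of context-specific mutations that raise the activation class.

    One row per (RE, background, mutation) whose predicted class increases;
    use :func:`aggregate_transitions` to collapse the catalog to mutation
    types (a type counts once no matter how many backgrounds it promotes).
    """
    A, S = coeffs.n_states, coeffs.n_sites
    classes = predict_landscape_classes(coeffs)
    alphabet = coeffs.alphabet
    rows = []
    bg_codes = None
    for re_label, cls in zip(("ERE", "SRE"), classes):
        tensor = cls.reshape((A,) * S)
        for site0 in range(S):
            order = [site0] + [i for i in range(S) if i != site0]
            moved = np.transpose(tensor, order)  # site of interest first
            flat = moved.reshape(A, -1)
            if bg_codes is None or bg_codes.shape[0] != flat.shape[1]:
                grids = np.meshgrid(
                    *[np.arange(A)] * (S - 1), indexing="ij"
                )
                bg_codes = np.stack([x.ravel() for x in grids], axis=1)
            for a in range(A):
                for b in range(A):
                    if a == b:
                        continue
                    promoted = np.flatnonzero(flat[b] > flat[a])
                    for idx in promoted:
                        bg = "".join(
                            alphabet[c] for c in bg_codes[idx]
                        )
                        rows.append(
                            (
                                re_label,
                                site0 + 1,
                                alphabet[a],
                                alphabet[b],
                                bg,
                                CLASSES[flat[a][idx]],
                                CLASSES[flat[b][idx]],
                            )
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "re",
            "site",
            "from",
            "to",
            "background",
            "class_before",
            "class_after",
        ],
    )


def aggregate_transitions(catalog: pd.DataFrame) -> pd.DataFrame:
    """Count backgrounds per mutation type and transition (type counted once
    per transition regardless of background multiplicity)."""
    if catalog.empty:
        return pd.DataFrame(
            columns=[
                "re",
                "site",
                "from",
                "to",
                "class_before",
                "class_after",
                "n_backgrounds",
            ]
        )
    return (
        catalog.groupby(
            ["re", "site", "from", "to", "class_before", "class_after"]
        )
        .size()
        .rename("n_backgrounds")
        .reset_index()
    )


@dataclass
class NecessitySufficiency:
    """Whether epistatic score changes are needed and/or enough for a
    class promotion, plus the analogous third-order-vs-lower calls."""

    epistasis_necessary: bool
    epistasis_sufficient: bool
    third_order_necessary: bool
    third_order_sufficient: bool


def necessity_sufficiency(
    rec: MutationEffectRecord, coeffs: CoefficientTable
) -> NecessitySufficiency:
    """Threshold arithmetic for one class-promoting mutation record.

    Epistasis is *necessary* if the main-effect change alone fails to carry
    the score across the threshold of the new class, and *sufficient* if the
    pairwise + third-order changes alone cross it.  The third-order calls
    compare third-order changes against main + pairwise in the same way.
    """
    if not rec.components:
        raise InputError("record lacks a decomposition")
    before = CLASSES.index(rec.class_before)
    after = CLASSES.index(rec.class_after)
    if after <= before:
        raise InputError(
            "necessity/sufficiency is defined for class promotions"
        )
    threshold = coeffs.theta_ws if after == 2 else coeffs.theta_nw
    s0 = rec.score_before
    epi = rec.delta_pairwise + rec.delta_third
    return NecessitySufficiency(
        epistasis_necessary=(s0 + rec.delta_main) < threshold,
        epistasis_sufficient=(s0 + epi) >= threshold,
        third_order_necessary=(s0 + rec.delta_main + rec.delta_pairwise)
        < threshold,
        third_order_sufficient=(s0 + rec.delta_third) >= threshold,
    )


def specificity_switches(
    coeffs: CoefficientTable,
    rule: AdjacencyRule | None = None,
) -> pd.DataFrame:
    """Single-step mutations that turn an ERE-specific variant SRE-specific.

    Labels use the Strong class (ERE-specific = strong on ERE only).  For
    every adjacent pair under ``rule`` (hamming by default; a genetic-code
    rule restricts which amino-acid exchanges are possible — serine-split
    rules are collapsed to the union of the two groups' adjacencies for this
    catalog), the necessity and sufficiency of epistasis for losing ERE,
    gaining SRE, and both are reported via the strong-threshold arithmetic.
    """
    rule = rule or AdjacencyRule("hamming")
    A, S = coeffs.n_states, coeffs.n_sites
    index = {s: i for i, s in enumerate(coeffs.alphabet)}
    y_ere, y_sre = score_landscape(coeffs)
    cls_e, cls_s = predict_landscape_classes(coeffs)
    strong_e = (cls_e == 2).reshape((A,) * S)
    strong_s = (cls_s == 2).reshape((A,) * S)
    ye = y_ere.reshape((A,) * S)
    ys = y_sre.reshape((A,) * S)
    ere_specific = strong_e & ~strong_s
    sre_specific = strong_s & ~strong_e

    adj = rule.state_adjacency()
    if adj is not None and "Z" in adj:
        # collapse the serine split: S adjacency = union of both groups
        collapsed: dict[str, set[str]] = {}
        for a, nbrs in adj.items():
            key = "S" if a == "Z" else a
            vals = {"S" if b == "Z" else b for b in nbrs}
            collapsed.setdefault(key, set()).update(vals)
            collapsed[key].discard(key)
        adj = collapsed

    theta = coeffs.theta_ws
    space = coeffs.space
    rows = []
    for flat_idx in np.flatnonzero(ere_specific.ravel()):
        g = space.decode(int(flat_idx))
        idx = tuple(index[s] for s in g.states)
        for site0 in range(S):
            a = g.states[site0]
            for b in coeffs.alphabet:
                if b == a:
                    continue
                if adj is not None and b not in adj.get(a, ()):
                    continue
                jdx = idx[:site0] + (index[b],) + idx[site0 + 1 :]
                if not sre_specific[jdx]:
                    continue
                rec_e = mutation_effect(g, site0 + 1, b, "ERE", coeffs)
                rec_s = mutation_effect(g, site0 + 1, b, "SRE", coeffs)
                # main-effect-only and epistasis-only hypothetical scores
                mo_e = ye[idx] + rec_e.delta_main
                mo_s = ys[idx] + rec_s.delta_main
                eo_e = ye[idx] + rec_e.delta_epistatic
                eo_s = ys[idx] + rec_s.delta_epistatic
                nec_lose = not (mo_e < theta)
                nec_gain = not (mo_s >= theta)
                suf_lose = eo_e < theta
                suf_gain = eo_s >= theta
                rows.append(
                    (
                        str(g),
                        site0 + 1,
                        a,
                        b,
                        nec_lose,
                        nec_gain,
                        nec_lose and nec_gain,
                        suf_lose,
                        suf_gain,
                        suf_lose and suf_gain,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "genotype",
            "site",
            "from",
            "to",
            "epi_necessary_lose_ere",
            "epi_necessary_gain_sre",
            "epi_necessary_both",
            "epi_sufficient_lose_ere",
            "epi_sufficient_gain_sre",
            "epi_sufficient_both",
        ],
    )
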