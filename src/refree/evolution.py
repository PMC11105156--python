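"""Origin-fixation evolutionary walks on functional genotype networks.

Two scenarios are simulated from ERE-specific starting nodes until an
SRE-specific node is reached:

* **neutral** — purifying selection plus drift: every functional neighbor is
  an equally likely next step.
* **selection** — positive selection for SRE specificity: each neighbor's
  selection coefficient is proportional to its gain in specificity
  (``y(g|SRE) - y(g|ERE)``) over the current node, and step probabilities are
  the relative Kimura fixation probabilities
  ``pi(s, N) = (1 - exp(-2 s)) / (1 - exp(-4 N s))``.

The scaling constant converts one rescaled score unit of specificity gain
(the non-binder to strong-binder gap) into ``s = 0.01``, so ``N s = 1`` at
``N = 100``.  Selection walks that exceed a step cap (default 20) — e.g.
trapped cycling between two near-optimal genotypes — are censored and
excluded from path-length summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .model import CoefficientTable, score_landscape
from .sequence_space import InputError

#: selection per unit of rescaled specificity gain: Ns = 1 at N = 100
DEFAULT_SELECTION_SCALE = 0.01


@dataclass
class WalkConfig:
    """Simulation layout for evolutionary walks."""

    mode: str = "neutral"  # or "selection"
    replicates: int = 100
    population_size: int = 100
    selection_scale: float = DEFAULT_SELECTION_SCALE
    max_steps: int = 20  # censor cap for selection walks
    hard_cap: int = 10_000  # guards non-absorbing toy networks
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("neutral", "selection"):
            raise InputError(f"unknown walk mode {self.mode!r}")
        if self.replicates < 1 or self.population_size < 1:
            raise InputError("replicates and population size must be >= 1")


@dataclass
class WalkResult:
    """One simulated trajectory."""

    start: str
    steps: list[str] = field(default_factory=list)
    censored: bool = False

    @property
    def endpoint(self) -> str:
        return self.steps[-1] if self.steps else self.start

    @property
    def n_steps(self) -> int:
        return len(self.steps)


def fixation_probability(s, N: int):
    """Kimura fixation probability of a new mutant, diploid form.

    ``pi = (1 - exp(-2 s)) / (1 - exp(-4 N s))`` with initial frequency
    ``1/(2N)``; the neutral limit ``s -> 0`` gives ``1/(2N)`` exactly.
    """
    if N < 1:
        raise InputError("population size must be >= 1")
    s = np.asarray(s, dtype=float)
    out = np.empty_like(s)
    tiny = np.abs(s) < 1e-12
    out[tiny] = 1.0 / (2 * N)
    with np.errstate(over="ignore"):
        num = -np.expm1(-2.0 * s[~tiny])
        den = -np.expm1(-4.0 * N * s[~tiny])
    out[~tiny] = num / den
    return out if out.ndim else float(out)


def _specificity_map(coeffs: CoefficientTable) -> dict[str, float]:
    """SRE-minus-ERE genetic score per 20-letter sequence."""
    y_ere, y_sre = score_landscape(coeffs)
    space = coeffs.space
    return {
        str(space.decode(i)): float(y_sre[i] - y_ere[i])
        for i in range(space.size)
    }


def _walk(
    net: nx.Graph,
    start: str,
    rng: np.random.Generator,
    cfg: WalkConfig,
    specificity: dict[str, float] | None,
) -> WalkResult:
    if start not in net:
        raise InputError(f"start node {start!r} not in network")
    if net.degree(start) == 0:
        raise InputError(f"start node {start!r} is isolated")
    result = WalkResult(start=start)
    current = start
    cap = cfg.max_steps if cfg.mode == "selection" else cfg.hard_cap
    while True:
        nbrs = list(net[current])
        if cfg.mode == "neutral" or cfg.selection_scale == 0:
            nxt = nbrs[rng.integers(len(nbrs))]
        else:
            seq = net.nodes[current].get("sequence", current)
            s_cur = specificity[seq]
            s_arr = np.array(
                [
                    cfg.selection_scale
                    * (
                        specificity[net.nodes[v].get("sequence", v)]
                        - s_cur
                    )
                    for v in nbrs
                ]
            )
            pi = np.atleast_1d(
                fixation_probability(s_arr, cfg.population_size)
            )
            total = pi.sum()
            if total <= 0:
                nxt = nbrs[rng.integers(len(nbrs))]
            else:
                nxt = nbrs[rng.choice(len(nbrs), p=pi / total)]
        result.steps.append(nxt)
        current = nxt
        if net.nodes[current].get("phenotype") == "SRE-specific":
            return result
        if len(result.steps) >= cap:
            result.censored = True
            return result


def neutral_walk(
    net: nx.Graph, start: str, rng: np.random.Generator
) -> WalkResult:
    """One purifying-selection-plus-drift walk: uniform steps over functional
    neighbors, absorbed at the first SRE-specific node."""
    return _walk(net, str(start), rng, WalkConfig(mode="neutral"), None)


def selection_walk(
    net: nx.Graph,
    start: str,
    coeffs: CoefficientTable,
    cfg: WalkConfig,
    rng: np.random.Generator,
    _specificity: dict[str, float] | None = None,
) -> WalkResult:
    """One walk under positive selection for SRE specificity."""
    spec = _specificity if _specificity is not None else _specificity_map(
        coeffs
    )
    return _walk(net, str(start), rng, cfg, spec)


def simulate_walks(
    net: nx.Graph,
    coeffs: CoefficientTable | None,
    cfg: WalkConfig,
    starts: list[str] | None = None,
) -> list[WalkResult]:
    """``cfg.replicates`` walks from every ERE-specific start (or ``starts``)."""
    rng = np.random.default_rng(cfg.seed)
    if starts is None:
        starts = [
            n
            for n, d in net.nodes(data=True)
            if d.get("phenotype") == "ERE-specific" and net.degree(n) > 0
        ]
    spec = None
    if cfg.mode == "selection":
        if coeffs is None:
            raise InputError("selection walks need a coefficient table")
        spec = _specificity_map(coeffs)
    results = []
    for start in starts:
        for _ in range(cfg.replicates):
            results.append(_walk(net, start, rng, cfg, spec))
    return results


@dataclass
class WalkSummary:
    mean_steps: float
    ci_low: float
    ci_high: float
    n_walks: int
    censor_fraction: float
    empty: bool = False


def censor_and_summarize(
    results: list[WalkResult], max_steps: int = 20
) -> WalkSummary:
    """Mean steps with a normal-approximation 95% CI over uncensored walks.

    Walks flagged censored or longer than ``max_steps`` are excluded from the
    mean; their fraction is reported.  An all-censored input yields an empty
    summary.
    """
    kept = [
        r.n_steps
        for r in results
        if not r.censored and r.n_steps <= max_steps
    ]
    frac = 1.0 - len(kept) / len(results) if results else 0.0
    if not kept:
        return WalkSummary(np.nan, np.nan, np.nan, 0, frac, empty=True)
    arr = np.asarray(kept, dtype=float)
    mean = float(arr.mean())
    half = (
        1.96 * float(arr.std(ddof=1)) / np.sqrt(len(arr))
        if len(arr) > 1
        else 0.0
    )
    return WalkSummary(mean, mean - half, mean + half, len(arr), frac)


def summarize_by_start(
    results: list[WalkResult], max_steps: int = 20
) -> pd.DataFrame:
    """Per-start summary table (mean steps, CI, censor fraction)."""
    rows = []
    by_start: dict[str, list[WalkResult]] = {}
    for r in results:
        by_start.setdefault(r.start, []).append(r)
    for start, rs in by_start.items():
        s = censor_and_summarize(rs, max_steps)
        rows.append(
            (
                start,
                s.mean_steps,
                s.ci_low,
                s.ci_high,
                s.n_walks,
                s.censor_fraction,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "start",
            "mean_steps",
            "ci_low",
            "ci_high",
            "n_walks",
            "censor_fraction",
        ],
    )


def mean_absorption_steps(net: nx.Graph, start: str) -> float:
    """Exact expected neutral-walk absorption time via the linear system
    ``(I - Q) t = 1`` of the absorbing Markov chain (oracle-grade reference
    for small networks)."""
    nodes = [
        n
        for n, d in net.nodes(data=True)
        if d.get("phenotype") != "SRE-specific"
    ]
    index = {n: i for i, n in enumerate(nodes)}
    if start not in index:
        return 0.0
    n = len(nodes)
    Q = np.zeros((n, n))
    for u in nodes:
        deg = net.degree(u)
        for v in net[u]:
            if v in index:
                Q[index[u], index[v]] = 1.0 / deg
    t = np.linalg.solve(np.eye(n) - Q, np.ones(n))
    return float(t[index[start]])
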