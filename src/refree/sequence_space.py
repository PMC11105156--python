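"""Combinatorial protein sequence spaces and mutational adjacency.

This module provides the bookkeeping shared by the rest of the package: the
enumeration of all ``|alphabet|^n_sites`` protein variants (by default all
160,000 combinations of the 20 amino acids at four sites), and the rules that
decide which variants are a single mutational step apart.

Two adjacency rules are supported:

``hamming``
    Variants are neighbors if they differ at exactly one site.
``genetic_code``
    The single amino-acid difference must additionally be achievable by a
    single nucleotide change: two states are adjacent iff some codon of one
    and some codon of the other differ at exactly one nucleotide position.
    Stop codons are excluded, so paths through a stop intermediate are not
    allowed.

Serine is the only amino acid whose codon set is internally disconnected at
the single-nucleotide level (TCN vs. AGY). With ``serine_split`` the two codon
groups are treated as distinct, non-interchangeable symbols ``S`` (TCN) and
``Z`` (AGY); a sequence with *n* serines then corresponds to ``2**n`` split
genotypes with the same phenotype but different connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np

AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
"""The 20 one-letter amino-acid codes in fixed alphabetical order."""

SERINE_SPLIT_ALPHABET: tuple[str, ...] = AMINO_ACIDS + ("Z",)
"""Amino acids plus ``Z`` (the AGY serine group), appended last so that
coefficient tables serialized over the base alphabet stay byte-stable."""

_NT = "ACGT"


class InputError(ValueError):
    """Raised for invalid user-supplied inputs (alphabets, files, tables)."""


def load_code_table(path=None) -> dict[str, str]:
    """Read a codon -> amino-acid table from a two-column text file.

    Lines starting with ``#`` are ignored.  The packaged default is the
    standard nuclear code restricted to the 61 sense codons.
    """
    if path is None:
        text = (
            resources.files("refree.data")
            .joinpath("standard_code.txt")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2 or len(fields[0]) != 3:
            raise InputError(f"malformed code-table line: {raw!r}")
        table[fields[0].upper()] = fields[1].upper()
    return table


def split_serine_codons(code_table: dict[str, str]) -> dict[str, str]:
    """Relabel the AGY serine codons as ``Z``, leaving TCN codons as ``S``."""
    out = {}
    for codon, aa in code_table.items():
        if aa == "S" and codon.startswith("AG"):
            out[codon] = "Z"
        else:
            out[codon] = aa
    return out


def _codon_neighbors(codon: str) -> Iterator[str]:
    for pos in range(3):
        for nt in _NT:
            if nt != codon[pos]:
                yield codon[:pos] + nt + codon[pos + 1 :]


def amino_acid_adjacency(code_table: dict[str, str]) -> dict[str, set[str]]:
    """Single-nucleotide adjacency between amino acids.

    Two amino acids are adjacent iff some codon of one can be turned into a
    codon of the other by a single nucleotide substitution.  Mutations through
    codons absent from the table (e.g. stops) are not counted, and the
    relation is irreflexive.
    """
    adj: dict[str, set[str]] = {aa: set() for aa in set(code_table.values())}
    for codon, aa in code_table.items():
        for mutant in _codon_neighbors(codon):
            other = code_table.get(mutant)
            if other is not None and other != aa:
                adj[aa].add(other)
    return adj


@dataclass(frozen=True)
class Genotype:
    """A protein variant: an ordered tuple of amino-acid symbols, one per site."""

    states: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))

    def __str__(self) -> str:
        return "".join(self.states)

    def __len__(self) -> int:
        return len(self.states)

    @classmethod
    def from_string(cls, seq: str) -> "Genotype":
        return cls(tuple(seq))


@dataclass(frozen=True)
class GenotypeSpace:
    """The complete enumeration of genotypes over an alphabet.

    Genotypes are enumerated lexicographically in the declared alphabet order
    with the first site varying slowest, so the enumeration (and everything
    serialized from it) is deterministic.

    Attributes
    ----------
    alphabet : tuple of str
        Allowed symbols, in a fixed order.
    n_sites : int
        Number of variable sites.
    """

    alphabet: tuple[str, ...]
    n_sites: int
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        if len(set(self.alphabet)) != len(self.alphabet):
            raise InputError("alphabet contains duplicate symbols")
        if not self.alphabet:
            raise InputError("alphabet is empty")
        if self.n_sites < 1:
            raise InputError("n_sites must be >= 1")
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.alphabet)}
        )

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    @property
    def size(self) -> int:
        return self.n_states**self.n_sites

    def codes(self) -> np.ndarray:
        """Integer state codes for every genotype, shape ``(size, n_sites)``."""
        A, S = self.n_states, self.n_sites
        grids = np.meshgrid(*[np.arange(A)] * S, indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def encode(self, g: Genotype | str) -> int:
        """Index of ``g`` in the enumeration order."""
        states = g.states if isinstance(g, Genotype) else tuple(g)
        if len(states) != self.n_sites:
            raise InputError(
                f"genotype {''.join(states)!r} has {len(states)} sites, "
                f"expected {self.n_sites}"
            )
        idx = 0
        for s in states:
            try:
                idx = idx * self.n_states + self._index[s]
            except KeyError:
                raise InputError(f"symbol {s!r} not in alphabet") from None
        return idx

    def decode(self, idx: int) -> Genotype:
        states = []
        for _ in range(self.n_sites):
            idx, r = divmod(idx, self.n_states)
            states.append(self.alphabet[r])
        return Genotype(tuple(reversed(states)))

    def genotypes(self) -> Iterator[Genotype]:
        for idx in range(self.size):
            yield self.decode(idx)

    def __contains__(self, g: Genotype | str) -> bool:
        states = g.states if isinstance(g, Genotype) else tuple(g)
        return len(states) == self.n_sites and all(
            s in self._index for s in states
        )


def enumerate_genotypes(
    alphabet: Sequence[str] = AMINO_ACIDS, n_sites: int = 4
) -> GenotypeSpace:
    """Enumerate all ``|alphabet|**n_sites`` genotypes.

    With the defaults this is the full library of 160,000 combinations of 20
    amino acids at four sites.
    """
    return GenotypeSpace(tuple(alphabet), n_sites)


@dataclass(frozen=True)
class AdjacencyRule:
    """How two genotypes can be a single mutational step apart.

    Parameters
    ----------
    mode : {"hamming", "genetic_code"}
        ``hamming`` connects genotypes differing at exactly one site;
        ``genetic_code`` additionally requires the amino-acid exchange to be
        achievable by one nucleotide substitution.
    code_table : dict, optional
        codon -> amino acid map used in ``genetic_code`` mode.  Defaults to
        the packaged standard nuclear code (sense codons only).
    serine_split : bool
        Treat TCN (``S``) and AGY (``Z``) serine codon groups as distinct,
        mutually non-adjacent symbols.
    """

    mode: str = "hamming"
    code_table: dict[str, str] | None = None
    serine_split: bool = False

    def __post_init__(self):
        if self.mode not in ("hamming", "genetic_code"):
            raise InputError(f"unknown adjacency mode {self.mode!r}")

    def state_adjacency(self) -> dict[str, set[str]] | None:
        """Amino-acid level adjacency sets, or None in hamming mode."""
        if self.mode == "hamming":
            return None
        table = self.code_table or load_code_table()
        if self.serine_split:
            table = split_serine_codons(table)
        return amino_acid_adjacency(table)

    def alphabet(self) -> tuple[str, ...]:
        """The alphabet this rule operates over."""
        if self.serine_split:
            return SERINE_SPLIT_ALPHABET
        return AMINO_ACIDS


def neighbors(
    g: Genotype | str,
    rule: AdjacencyRule,
    space: GenotypeSpace,
) -> set[Genotype]:
    """All genotypes one mutational step from ``g`` under ``rule``.

    In hamming mode every genotype in the default space has exactly
    ``4 * 19 = 76`` neighbors; genetic-code neighbors are always a subset of
    hamming neighbors.
    """
    if isinstance(g, str):
        g = Genotype.from_string(g)
    if g not in space:
        raise InputError(f"genotype {g} not in space")
    adj = rule.state_adjacency()
    out: set[Genotype] = set()
    for site, current in enumerate(g.states):
        if adj is None:
            reachable = [s for s in space.alphabet if s != current]
        else:
            allowed = adj.get(current, set())
            reachable = [s for s in space.alphabet if s in allowed]
        for s in reachable:
            states = list(g.states)
            states[site] = s
            out.add(Genotype(tuple(states)))
    return out


def serine_expand(g: Genotype | str) -> list[Genotype]:
    """Expand a 20-letter genotype into its serine-split versions.

    Every ``S`` may independently be the TCN group (``S``) or the AGY group
    (``Z``), so a sequence with *n* serines yields ``2**n`` split genotypes,
    all mapping back to the same amino-acid sequence.
    """
    if isinstance(g, str):
        g = Genotype.from_string(g)
    variants: list[tuple[str, ...]] = [()]
    for s in g.states:
        if s == "S":
            variants = [v + (c,) for v in variants for c in ("S", "Z")]
        else:
            variants = [v + (s,) for v in variants]
    return [Genotype(v) for v in variants]


def serine_collapse(g: Genotype | str) -> Genotype:
    """Map a split genotype back to the plain 20-letter alphabet (Z -> S)."""
    if isinstance(g, str):
        g = Genotype.from_string(g)
    return Genotype(tuple("S" if s == "Z" else s for s in g.states))


def site_subsets(n_sites: int, order: int) -> list[tuple[int, ...]]:
    """All site subsets of a given order, 0-based, lexicographic."""
    return list(combinations(range(n_sites), order))
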