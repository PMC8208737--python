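"""Pairwise SNV co-occurrence matrix.

The central data structure for metagenomic individual haplotyping: instead of
Lancia-style rows-of-reads, evidence is aggregated per ordered pair of variant
sites.  ``H[alpha, beta, i, j]`` counts the reads that carried symbol ``alpha``
at site ``i`` and symbol ``beta`` at site ``j > i``.  The structure is strictly
upper-triangular in ``(i, j)`` and carries one extra virtual column ``n + 1``
so that a read's final variant can be linked to an internal terminal sentinel;
that bookkeeping is what makes "number of reads spanning site j" computable
from the adjacent column ``(j, j + 1)`` alone.

Symbols come from the six-letter alphabet ``A C G T N -`` where ``-`` is a
deletion observed in a read; insertions are not modelled.  The terminal
sentinel never appears in user-facing output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

#: User-facing symbol alphabet, in deterministic tie-break order.
ALPHABET: tuple[str, ...] = ("A", "C", "G", "T", "N", "-")

#: Internal sentinel linked after the last variant covered by a read.
TERMINAL: str = "$"

SYMBOLS: tuple[str, ...] = ALPHABET + (TERMINAL,)
_SYM_INDEX: dict[str, int] = {s: k for k, s in enumerate(SYMBOLS)}
_TERM = _SYM_INDEX[TERMINAL]
_N_SYM = len(SYMBOLS)

#: Counts at or below this are treated as absent when enumerating edges and
#: observed symbols; multiplicative reweighting can leave float dust behind.
EDGE_EPSILON: float = 1e-9


class MatrixError(Exception):
    """Base class for co-occurrence matrix contract violations."""


class OrderingError(MatrixError):
    """Raised when a site pair is not strictly upper-triangular (j <= i)."""


class InvalidSymbolError(MatrixError):
    """Raised when a symbol outside the allowed alphabet is supplied."""


class PanelMismatchError(Exception):
    """Raised when indices or coordinates disagree with the variant panel."""


class NoEvidenceError(Exception):
    """No read spans the queried site: the traversal-level 'hole' signal."""

    def __init__(self, site: int, message: str | None = None):
        self.site = site
        super().__init__(message or f"no read evidence spans site {site}")


@dataclass(frozen=True)
class VariantPanel:
    """Ordered SNV positions on a contig region.

    Positions are 1-based genomic coordinates (VCF convention), strictly
    increasing and contained in ``[region_start, region_end]``.  Matrix site
    indices ``1..n`` map onto these positions in order.
    """

    contig: str
    region_start: int
    region_end: int
    positions: tuple[int, ...]

    def __post_init__(self):
        pos = tuple(int(p) for p in self.positions)
        object.__setattr__(self, "positions", pos)
        if self.region_start < 1 or self.region_end < self.region_start:
            raise ValueError("invalid region bounds")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("panel positions must be strictly increasing")
        if pos and (pos[0] < self.region_start or pos[-1] > self.region_end):
            raise ValueError("panel positions outside region bounds")

    @property
    def n(self) -> int:
        return len(self.positions)

    def position(self, index: int) -> int:
        """Genomic position of 1-based site ``index``."""
        if not 1 <= index <= self.n:
            raise PanelMismatchError(f"site index {index} outside 1..{self.n}")
        return self.positions[index - 1]

    def index_of(self, position: int) -> int:
        """1-based site index of a genomic ``position``."""
        try:
            return self.positions.index(position) + 1
        except ValueError:
            raise PanelMismatchError(f"position {position} not in panel") from None

    @classmethod
    def from_vcf(cls, path: str, contig: str, start: int, end: int) -> "VariantPanel":
        """Build a panel from the ALT-bearing records of a VCF on ``contig``
        within ``[start, end]`` (1-based inclusive)."""
        import pysam

        positions: list[int] = []
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                if rec.chrom != contig or not (start <= rec.pos <= end):
                    continue
                if rec.alts and rec.pos not in positions:
                    positions.append(rec.pos)
        return cls(contig, start, end, tuple(sorted(positions)))


class SymbolAtSite(NamedTuple):
    """A graph node: a symbol paired with a 1-based site index."""

    symbol: str
    index: int

    def __str__(self) -> str:  # node label used in graph exports
        return f"{self.symbol}@{self.index}"


class CooccurrenceMatrix:
    """Rank-4 tensor of fractional co-occurrence counts over site pairs.

    Stored densely as ``(|Σ|+1, |Σ|+1, n+2, n+2)`` floats; site indices are
    1-based and only strictly upper-triangular pairs are addressable.  Memory
    is O(|Σ|² n²), fine for the gene-scale regions local haplotyping targets.
    Counts are reals from the outset so multiplicative reweighting needs no
    special casing; before any reweighting they are non-negative integers.
    """

    def __init__(self, n: int):
        if n < 1:
            raise ValueError("panel must contain at least one site")
        self.n = int(n)
        self._counts = np.zeros((_N_SYM, _N_SYM, n + 2, n + 2), dtype=float)
        self.n_observations = 0

    # -- index guards ------------------------------------------------------

    def _check(self, alpha: str, beta: str, i: int, j: int) -> tuple[int, int]:
        if alpha not in _SYM_INDEX or beta not in _SYM_INDEX:
            raise InvalidSymbolError(f"unknown symbol in pair ({alpha}, {beta})")
        if alpha == TERMINAL:
            raise InvalidSymbolError("terminal sentinel cannot occupy the first slot")
        if not 1 <= i <= self.n:
            raise PanelMismatchError(f"site index {i} outside 1..{self.n}")
        if j <= i:
            raise OrderingError(f"site pair ({i}, {j}) is not upper-triangular")
        if j > self.n + 1:
            raise PanelMismatchError(f"site index {j} beyond terminal column {self.n + 1}")
        if beta == TERMINAL and j != i + 1:
            raise InvalidSymbolError("terminal links are only recorded at (j, j+1)")
        if beta != TERMINAL and j == self.n + 1:
            raise PanelMismatchError("column n+1 is reserved for terminal links")
        return _SYM_INDEX[alpha], _SYM_INDEX[beta]

    # -- accessors ---------------------------------------------------------

    def get(self, alpha: str, beta: str, i: int, j: int) -> float:
        a, b = self._check(alpha, beta, i, j)
        return float(self._counts[a, b, i, j])

    def increment(self, alpha: str, beta: str, i: int, j: int, amount: float = 1.0) -> None:
        a, b = self._check(alpha, beta, i, j)
        self._counts[a, b, i, j] += amount

    def scale(self, alpha: str, beta: str, i: int, j: int, factor: float) -> None:
        """Multiply one entry by ``factor``, clamping at zero."""
        a, b = self._check(alpha, beta, i, j)
        self._counts[a, b, i, j] = max(0.0, self._counts[a, b, i, j] * factor)

    def copy(self) -> "CooccurrenceMatrix":
        dup = CooccurrenceMatrix(self.n)
        dup._counts = self._counts.copy()
        dup.n_observations = self.n_observations
        return dup

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CooccurrenceMatrix)
            and self.n == other.n
            and np.array_equal(self._counts, other._counts)
        )

    # -- ingestion ---------------------------------------------------------

    def observe_read(self, obs) -> "CooccurrenceMatrix":
        """Fold one read observation into the matrix.

        For every ordered pair of covered sites the corresponding count is
        incremented, and the read's last covered site is linked to the
        terminal sentinel in the adjacent column so spanning depth stays
        countable even at the last site a read touches.
        """
        symbols = list(obs.symbols)
        for s in symbols:
            if s == TERMINAL:
                raise InvalidSymbolError("terminal sentinel cannot appear in a read")
            if s not in _SYM_INDEX:
                raise InvalidSymbolError(f"symbol {s!r} outside alphabet")
        first, last = int(obs.first_index), int(obs.last_index)
        if not (1 <= first <= last <= self.n):
            raise PanelMismatchError(
                f"observation span {first}..{last} outside panel 1..{self.n}"
            )
        if len(symbols) != last - first + 1:
            raise PanelMismatchError("observation length disagrees with its span")
        for x in range(first, last + 1):
            for y in range(x + 1, last + 1):
                self.increment(symbols[x - first], symbols[y - first], x, y)
        self.increment(symbols[-1], TERMINAL, last, last + 1)
        self.n_observations += 1
        return self

    # -- probability estimators -------------------------------------------

    def spanning_depth(self, j: int) -> float:
        """Total evidence in the adjacent column (j, j+1): the number of
        reads spanning site ``j`` (before reweighting)."""
        if not 1 <= j <= self.n:
            raise PanelMismatchError(f"site index {j} outside 1..{self.n}")
        return float(self._counts[:, :, j, j + 1].sum())

    def marginal(self, beta: str, j: int) -> float:
        """Estimated probability of symbol ``beta`` at site ``j``: reads
        carrying ``beta`` at ``j`` over reads spanning ``j``."""
        if beta not in _SYM_INDEX:
            raise InvalidSymbolError(f"unknown symbol {beta!r}")
        depth = self.spanning_depth(j)
        if depth <= 0.0:
            raise NoEvidenceError(j)
        return float(self._counts[_SYM_INDEX[beta], :, j, j + 1].sum()) / depth

    def variants_at(self, i: int, epsilon: float = EDGE_EPSILON) -> set[str]:
        """Distinct non-terminal symbols with evidence at site ``i``."""
        if not 1 <= i <= self.n:
            raise PanelMismatchError(f"site index {i} outside 1..{self.n}")
        sums = self._counts[:, :, i, i + 1].sum(axis=1)
        return {SYMBOLS[k] for k in range(_N_SYM - 1) if sums[k] > epsilon}

    def conditional(self, alpha: str, i: int, beta: str, j: int) -> float:
        """Laplace-smoothed probability of ``alpha`` at ``i`` given ``beta``
        observed at the later site ``j``.

        Smoothing adds one dummy read per possible symbol at ``i``, so the
        estimate is strictly positive even for never-co-covered pairs; the
        smoothing mass is the number of distinct symbols observed at ``i``.
        """
        if beta == TERMINAL:
            raise InvalidSymbolError("cannot condition on the terminal sentinel")
        a, b = self._check(alpha, beta, i, j)
        v_i = len(self.variants_at(i))
        if v_i == 0:
            raise NoEvidenceError(i)
        joint = float(self._counts[a, b, i, j])
        spanning_with_beta = float(self._counts[:, b, i, j].sum())
        return (1.0 + joint) / (v_i + spanning_with_beta)

    # -- graph view --------------------------------------------------------

    def available_edges(
        self, i: int, epsilon: float = EDGE_EPSILON
    ) -> set[SymbolAtSite]:
        """Traversable next nodes at site ``i + 1``.

        For ``i = 0`` (path start) these are the symbols observed at site 1;
        otherwise the non-terminal symbols at ``i + 1`` whose adjacent
        co-occurrence evidence from site ``i`` exceeds ``epsilon``.  An empty
        set is a legal return and signals a hole.
        """
        if i == 0:
            return {SymbolAtSite(s, 1) for s in self.variants_at(1, epsilon)}
        if not 1 <= i <= self.n - 1:
            raise PanelMismatchError(f"edge origin {i} outside 0..{self.n - 1}")
        sums = self._counts[:, :, i, i + 1].sum(axis=0)
        return {
            SymbolAtSite(SYMBOLS[k], i + 1)
            for k in range(_N_SYM - 1)
            if sums[k] > epsilon
        }

    def iter_edges(
        self, epsilon: float = EDGE_EPSILON
    ) -> Iterator[tuple[SymbolAtSite, SymbolAtSite, float]]:
        """All adjacent-site transitions with raw co-occurrence weight."""
        for i in range(1, self.n):
            block = self._counts[:, :, i, i + 1]
            for a in range(_N_SYM - 1):
                for b in range(_N_SYM - 1):
                    w = float(block[a, b])
                    if w > epsilon:
                        yield (
                            SymbolAtSite(SYMBOLS[a], i),
                            SymbolAtSite(SYMBOLS[b], i + 1),
                            w,
                        )

    def total_adjacent_evidence(self) -> float:
        """Sum of all real-symbol adjacent-pair counts (terminal links
        excluded); strictly decreases under reweighting with positive λ."""
        total = 0.0
        for i in range(1, self.n):
            total += float(self._counts[: _N_SYM - 1, : _N_SYM - 1, i, i + 1].sum())
        return total

    def edge_table(self, epsilon: float = EDGE_EPSILON) -> pd.DataFrame:
        rows = [
            {"source": str(u), "target": str(v), "weight": w}
            for u, v, w in self.iter_edges(epsilon)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])

    def to_dot(self, epsilon: float = EDGE_EPSILON) -> str:
        lines = ["digraph snv_graph {", "  rankdir=LR;"]
        for u, v, w in self.iter_edges(epsilon):
            lines.append(f'  "{u}" -> "{v}" [label="{w:g}"];')
        lines.append("}")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Nonzero entries as a tidy table (alpha, beta, i, j, count)."""
        a, b, i, j = np.nonzero(self._counts)
        return pd.DataFrame(
            {
                "alpha": [SYMBOLS[k] for k in a],
                "beta": [SYMBOLS[k] for k in b],
                "i": i,
                "j": j,
                "count": self._counts[a, b, i, j],
            }
        )

    def dump_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load_tsv(cls, path: str, n: int) -> "CooccurrenceMatrix":
        frame = pd.read_csv(path, sep="\t", dtype={"alpha": str, "beta": str})
        H = cls(n)
        for row in frame.itertuples(index=False):
            H.increment(str(row.alpha), str(row.beta), int(row.i), int(row.j), float(row.count))
        return H
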