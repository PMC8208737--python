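"""Greedy probabilistic graph traversal over the co-occurrence matrix.

A haplotype is a path of (symbol, site) nodes through the transition graph
implied by the adjacent columns of H.  Each step scores the candidate next
node by its marginal probability times the Laplace-smoothed conditionals of
the last L path nodes given the candidate (the "lookback"), in log10 space.
After a complete traversal the evidence directly supporting the recovered
path is depleted by the path's minimum per-site marginal λ, steering the next
traversal toward alternative haplotypes; paths are scored and ranked against
the marginals of the matrix as it stood before any reweighting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .matrix import (
    ALPHABET,
    EDGE_EPSILON,
    CooccurrenceMatrix,
    NoEvidenceError,
    SymbolAtSite,
)

log = logging.getLogger(__name__)

_SYMBOL_ORDER = {s: k for k, s in enumerate(ALPHABET)}


@dataclass(frozen=True)
class TraversalConfig:
    """Tunable knobs of the greedy search.

    lookback
        Number of trailing path nodes conditioned on when scoring the next
        edge.  Should be of the order of the number of variant sites a
        typical read spans; evidence beyond read length is pure smoothing.
    max_iterations
        Cap on traverse/reweight rounds when evidence never exhausts.
    edge_epsilon
        Counts at or below this are treated as absent when deciding whether
        an edge is traversable (reweighting leaves float dust).
    tie_break
        Identifier of the deterministic rule applied among equal-score
        candidates; only "symbol-order" (A < C < G < T < N < -) is defined.
    """

    lookback: int = 5
    max_iterations: int = 100
    edge_epsilon: float = EDGE_EPSILON
    tie_break: str = "symbol-order"

    def __post_init__(self):
        if self.lookback < 1:
            raise ValueError("lookback must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tie_break != "symbol-order":
            raise ValueError(f"unknown tie-break rule {self.tie_break!r}")


@dataclass
class HaplotypePath:
    """An ordered node sequence with its provenance and score."""

    nodes: tuple[SymbolAtSite, ...]
    complete: bool
    hole_index: int | None = None  # site that could not be reached
    log10_likelihood: float | None = None
    lambda_used: float | None = None
    iteration: int | None = None

    @property
    def symbols(self) -> str:
        return "".join(node.symbol for node in self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class TraversalResult:
    """Ranked unique haplotypes plus per-iteration diagnostics."""

    haplotypes: list[HaplotypePath]
    termination_reason: str  # evidence_exhausted | max_iterations | hole_at_start
    iterations: int
    diagnostics: list[dict] = field(default_factory=list)


class MarginalSnapshot:
    """Per-site marginal vectors of a matrix, frozen before reweighting.

    Equivalent to keeping a full copy of H for scoring purposes (scores only
    ever read per-site marginals) at a fraction of the memory.
    """

    def __init__(self, marginals: dict[int, dict[str, float]]):
        self._marginals = marginals

    @classmethod
    def from_matrix(cls, H: CooccurrenceMatrix) -> "MarginalSnapshot":
        marginals: dict[int, dict[str, float]] = {}
        for j in range(1, H.n + 1):
            try:
                marginals[j] = {s: H.marginal(s, j) for s in ALPHABET}
            except NoEvidenceError:
                marginals[j] = {}
        return cls(marginals)

    def marginal(self, symbol: str, j: int) -> float:
        return self._marginals.get(j, {}).get(symbol, 0.0)


def edge_log_score(
    H: CooccurrenceMatrix,
    path: list[SymbolAtSite],
    candidate: SymbolAtSite,
    lookback: int,
) -> float:
    """log10 probability of appending ``candidate`` given the current path.

    The full conditional on the path is approximated by the candidate's
    marginal times pairwise conditionals of the last ``min(lookback, i)``
    path nodes given the candidate; early in the path only the available
    predecessors contribute.
    """
    i = len(path)
    score = math.log10(H.marginal(candidate.symbol, candidate.index))
    for back in range(min(lookback, i)):
        prev = path[i - 1 - back]
        score += math.log10(
            H.conditional(prev.symbol, prev.index, candidate.symbol, candidate.index)
        )
    return score


def _argmax(candidates: list[SymbolAtSite], scores: list[float]) -> SymbolAtSite:
    """Highest-scoring candidate; ties broken by fixed symbol order."""
    best = max(scores)
    tied = [c for c, s in zip(candidates, scores) if s == best]
    if len(tied) > 1:
        log.debug("tie among %s at site %d; symbol-order rule applied",
                  [str(c) for c in tied], tied[0].index)
    return min(tied, key=lambda c: _SYMBOL_ORDER[c.symbol])


def traverse(H: CooccurrenceMatrix, config: TraversalConfig | None = None) -> HaplotypePath:
    """One greedy walk from site 1 to site n.

    Starts at the highest-marginal symbol of site 1, then repeatedly appends
    the available next-site node with the best lookback-conditioned score.
    If no edge is traversable the partial path is returned flagged aborted,
    with the unreachable site recorded.  Deterministic given H and config.
    """
    config = config or TraversalConfig()
    start_candidates = sorted(
        H.available_edges(0, config.edge_epsilon),
        key=lambda c: _SYMBOL_ORDER[c.symbol],
    )
    if not start_candidates:
        return HaplotypePath(nodes=(), complete=False, hole_index=1)
    start_scores = [H.marginal(c.symbol, 1) for c in start_candidates]
    path = [_argmax(start_candidates, start_scores)]
    log.debug("start node %s (marginals %s)", path[0],
              dict(zip(map(str, start_candidates), start_scores)))

    while len(path) < H.n:
        i = len(path)
        candidates = sorted(
            H.available_edges(i, config.edge_epsilon),
            key=lambda c: _SYMBOL_ORDER[c.symbol],
        )
        if not candidates:
            log.debug("hole: no traversable edge from site %d", i)
            return HaplotypePath(nodes=tuple(path), complete=False, hole_index=i + 1)
        try:
            scores = [edge_log_score(H, path, c, config.lookback) for c in candidates]
        except NoEvidenceError as exc:
            log.debug("hole while scoring edges out of site %d: %s", i, exc)
            return HaplotypePath(nodes=tuple(path), complete=False, hole_index=i + 1)
        chosen = _argmax(candidates, scores)
        log.debug("site %d -> %s (scores %s)", i, chosen,
                  dict(zip(map(str, candidates), (f"{s:.4f}" for s in scores))))
        path.append(chosen)
    return HaplotypePath(nodes=tuple(path), complete=True)


def compute_lambda(path: HaplotypePath, H: CooccurrenceMatrix) -> float:
    """Reweight ratio λ: the minimum per-site marginal along the path,
    evaluated on the current (possibly already reweighted) matrix — an
    estimate of the fraction of total evidence this haplotype explains."""
    if not path.complete:
        raise ValueError("lambda is only defined for complete paths")
    return min(H.marginal(node.symbol, node.index) for node in path.nodes)


def reweight(path: HaplotypePath, lam: float, H: CooccurrenceMatrix) -> CooccurrenceMatrix:
    """Deplete the adjacent evidence directly supporting ``path`` in place:
    each (path[i], path[i+1], i, i+1) entry is scaled by (1 − λ).  Only
    strictly adjacent entries are touched; counts never go negative."""
    if not path.complete:
        raise ValueError("only complete paths are reweighted")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    for u, v in zip(path.nodes, path.nodes[1:]):
        H.scale(u.symbol, v.symbol, u.index, v.index, 1.0 - lam)
    return H


def score_path(path: HaplotypePath, original) -> float:
    """log10 likelihood of a complete path: the sum of per-site log10
    marginals under ``original`` — the matrix (or its MarginalSnapshot) as it
    stood before any reweighting.  A zero marginal yields −inf; such a path
    remains rankable but sinks to the bottom."""
    if not path.complete:
        raise ValueError("only complete paths are scored")
    total = 0.0
    for node in path.nodes:
        try:
            m = original.marginal(node.symbol, node.index)
        except NoEvidenceError:
            m = 0.0
        total += math.log10(m) if m > 0.0 else -math.inf
    return total


def recover_all(
    H: CooccurrenceMatrix, config: TraversalConfig | None = None
) -> TraversalResult:
    """Full recovery loop: traverse, score, deplete, repeat.

    Operates on an internal copy of ``H`` (the caller's matrix is left
    intact).  Scores are computed against the pre-reweighting marginals; λ is
    computed against the current matrix inside each iteration.  Stops when a
    traversal aborts (evidence exhausted, or a hole at the very start) or
    after ``max_iterations``.  Duplicate paths re-found on later iterations
    are kept once, with the first iteration index retained.
    """
    config = config or TraversalConfig()
    work = H.copy()
    snapshot = MarginalSnapshot.from_matrix(H)
    recovered: dict[str, HaplotypePath] = {}
    diagnostics: list[dict] = []
    termination = "max_iterations"
    iteration = 0

    for iteration in range(1, config.max_iterations + 1):
        path = traverse(work, config)
        entry = {
            "iteration": iteration,
            "path": path.symbols,
            "complete": path.complete,
            "hole_index": path.hole_index,
            "total_adjacent_evidence": work.total_adjacent_evidence(),
        }
        if not path.complete:
            if iteration == 1 and len(path) == 0:
                termination = "hole_at_start"
            else:
                termination = "evidence_exhausted"
            diagnostics.append(entry)
            break
        lam = compute_lambda(path, work)
        score = score_path(path, snapshot)
        entry.update({"lambda": lam, "log10_likelihood": score})
        diagnostics.append(entry)
        key = path.symbols
        if key not in recovered:
            recovered[key] = HaplotypePath(
                nodes=path.nodes,
                complete=True,
                log10_likelihood=score,
                lambda_used=lam,
                iteration=iteration,
            )
        reweight(path, lam, work)
        log.info(
            "iteration %d: %s lambda=%.4f log10L=%.4f", iteration, key, lam, score
        )

    ranked = sorted(
        recovered.values(),
        key=lambda p: (-(p.log10_likelihood if p.log10_likelihood is not None else -math.inf),
                       p.iteration),
    )
    return TraversalResult(
        haplotypes=ranked,
        termination_reason=termination,
        iterations=iteration,
        diagnostics=diagnostics,
    )
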