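"""Greedy traversal: edge scoring, λ-reweighting, ranking, termination.

The toy expectations (AAAC first, AACC second, …) were frozen from a
brute-force enumeration applying the probability model directly to the three
toy reads, independently of the library code.
"""

import math

import numpy as np
import pytest

from mihap import (
    ALPHABET,
    CommunitySpec,
    CooccurrenceMatrix,
    MarginalSnapshot,
    NoEvidenceError,
    ReadObservation,
    SymbolAtSite,
    TERMINAL,
    TraversalConfig,
    build_matrix,
    compute_lambda,
    edge_log_score,
    evenly_spaced_positions,
    recover_all,
    reweight,
    score_path,
    traverse,
)
from mihap.traversal import HaplotypePath

from conftest import TOY_CHIMERAS, community_matrix, random_matrix

L2 = TraversalConfig(lookback=2)


def _path(symbols: str, start: int = 1) -> HaplotypePath:
    return HaplotypePath(
        nodes=tuple(
            SymbolAtSite(s, start + k) for k, s in enumerate(symbols)
        ),
        complete=True,
    )


class TestEdgeScore:
    def test_toy_site3_scores(self, toy_matrix):
        prefix = [SymbolAtSite("A", 1), SymbolAtSite("A", 2)]
        assert edge_log_score(
            toy_matrix, prefix, SymbolAtSite("A", 3), 2
        ) == pytest.approx(math.log10(1 / 3))
        assert edge_log_score(
            toy_matrix, prefix, SymbolAtSite("C", 3), 2
        ) == pytest.approx(math.log10(2 / 9))

    def test_toy_site4_scores(self, toy_matrix):
        prefix = [SymbolAtSite("A", k) for k in (1, 2, 3)]
        assert edge_log_score(
            toy_matrix, prefix, SymbolAtSite("C", 4), 2
        ) == pytest.approx(math.log10(1 / 4))
        assert edge_log_score(
            toy_matrix, prefix, SymbolAtSite("A", 4), 2
        ) == pytest.approx(math.log10(2 / 27))

    def test_empty_path_reduces_to_marginal(self, toy_matrix):
        assert edge_log_score(
            toy_matrix, [], SymbolAtSite("A", 1), 5
        ) == pytest.approx(math.log10(1.0))


class TestTraverse:
    def test_toy_first_traversal_is_a_supported_read(self, toy_matrix):
        path = traverse(toy_matrix, L2)
        assert path.complete
        assert path.symbols == "AAAC"  # the 0001 input read

    def test_single_haplotype_is_the_only_walk(self):
        H = CooccurrenceMatrix(4)
        for k in range(3):
            H.observe_read(ReadObservation(f"r{k}", 1, 4, tuple("ACGT")))
        assert traverse(H).symbols == "ACGT"

    def test_hole_aborts_at_unreachable_site(self):
        # evidence links 1-2 and 3-4 but nothing bridges 2 -> 3
        H = CooccurrenceMatrix(4)
        H.observe_read(ReadObservation("left", 1, 2, tuple("AC")))
        H.observe_read(ReadObservation("right", 3, 4, tuple("GT")))
        path = traverse(H)
        assert not path.complete
        assert len(path) == 2
        assert path.hole_index == 3

    def test_empty_matrix_aborts_immediately(self):
        path = traverse(CooccurrenceMatrix(3))
        assert not path.complete and len(path) == 0 and path.hole_index == 1

    def test_deterministic(self, toy_matrix):
        a = traverse(toy_matrix, L2)
        b = traverse(toy_matrix.copy(), L2)
        assert a.symbols == b.symbols


class TestGreedyAgainstBruteForce:
    """Every chosen step must match an exhaustive re-evaluation of the
    lookback score, recomputed here from raw counts without the library's
    estimator code."""

    @staticmethod
    def _deltas(H, j):
        # second symbols storable in column (j, j+1): the sentinel always,
        # real symbols only while j+1 is a genuine site
        return (ALPHABET + (TERMINAL,)) if j < H.n else (TERMINAL,)

    @classmethod
    def _brute_marginal(cls, H, beta, j):
        den = sum(
            H.get(g, d, j, j + 1) for g in ALPHABET for d in cls._deltas(H, j)
        )
        num = sum(H.get(beta, d, j, j + 1) for d in cls._deltas(H, j))
        return num / den

    @classmethod
    def _brute_conditional(cls, H, alpha, i, beta, j):
        v_i = len(
            {
                g
                for g in ALPHABET
                for d in cls._deltas(H, i)
                if H.get(g, d, i, i + 1) > 1e-9
            }
        )
        num = 1 + H.get(alpha, beta, i, j)
        den = v_i + sum(H.get(g, beta, i, j) for g in ALPHABET)
        return num / den

    @classmethod
    def _brute_step_scores(cls, H, path, lookback):
        i = len(path)
        sums = {
            b: sum(H.get(a, b, i, i + 1) for a in ALPHABET) for b in ALPHABET
        }
        out = {}
        for b, s in sums.items():
            if s <= 1e-9:
                continue
            score = math.log10(cls._brute_marginal(H, b, i + 1))
            for back in range(min(lookback, i)):
                prev = path[i - 1 - back]
                score += math.log10(
                    cls._brute_conditional(H, prev.symbol, prev.index, b, i + 1)
                )
            out[b] = score
        return out

    @pytest.mark.parametrize("seed", range(25))
    def test_each_step_maximizes_lookback_score(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        H = random_matrix(rng, n=n, n_reads=int(rng.integers(2, 20)))
        config = TraversalConfig(lookback=int(rng.integers(1, 5)))
        path = traverse(H, config)
        for step in range(1, len(path)):
            prefix = list(path.nodes[:step])
            scores = self._brute_step_scores(H, prefix, config.lookback)
            chosen = path.nodes[step].symbol
            assert scores, "library traversed where brute force sees no edge"
            best = max(scores.values())
            # chosen edge attains the maximum (ties broken by symbol order)
            assert scores[chosen] == pytest.approx(best, abs=1e-12)


class TestLambdaAndReweight:
    def test_toy_lambda_of_0011_path(self, toy_matrix):
        assert compute_lambda(_path("AACC"), toy_matrix) == pytest.approx(1 / 3)

    def test_single_haplotype_lambda_is_one(self):
        H = CooccurrenceMatrix(3)
        H.observe_read(ReadObservation("r", 1, 3, tuple("ACG")))
        assert compute_lambda(_path("ACG"), H) == 1.0

    def test_toy_reweight_arithmetic(self, toy_matrix):
        reweight(_path("AACC"), 1 / 3, toy_matrix)
        assert toy_matrix.get("A", "A", 1, 2) == pytest.approx(4 / 3)
        assert toy_matrix.get("A", "C", 2, 3) == pytest.approx(2 / 3)
        assert toy_matrix.get("C", "C", 3, 4) == pytest.approx(2 / 3)
        # untouched: non-adjacent and off-path entries
        assert toy_matrix.get("A", "C", 1, 3) == 1
        assert toy_matrix.get("A", "C", 1, 2) == 1

    def test_lambda_one_erases_path(self, toy_matrix):
        reweight(_path("AACC"), 1.0, toy_matrix)
        assert toy_matrix.get("A", "A", 1, 2) == 0.0
        assert toy_matrix.get("C", "C", 3, 4) == 0.0

    def test_lambda_zero_is_identity(self, toy_matrix):
        before = toy_matrix.copy()
        reweight(_path("AACC"), 0.0, toy_matrix)
        assert toy_matrix == before


class TestScorePath:
    def test_toy_0011_score(self, toy_matrix):
        assert score_path(_path("AACC"), toy_matrix) == pytest.approx(
            math.log10(4 / 27)
        )

    def test_snapshot_equals_full_matrix(self, toy_matrix):
        snap = MarginalSnapshot.from_matrix(toy_matrix)
        for symbols in ("AACC", "AAAC", "ACAA", "AAAA"):
            assert score_path(_path(symbols), snap) == pytest.approx(
                score_path(_path(symbols), toy_matrix)
            )

    def test_zero_marginal_scores_minus_infinity(self, toy_matrix):
        assert score_path(_path("GGGG"), toy_matrix) == -math.inf

    def test_pointwise_dominance_orders_scores(self, toy_matrix):
        # AAAC dominates AACC at site 3 (2/3 vs 1/3) and ties elsewhere
        assert score_path(_path("AAAC"), toy_matrix) >= score_path(
            _path("AACC"), toy_matrix
        )


class TestRecoverAll:
    def test_toy_recovery_trace(self, toy_matrix):
        result = recover_all(toy_matrix, L2)
        by_iter = {p.iteration: p for p in result.haplotypes}
        assert by_iter[1].symbols == "AAAC"
        assert by_iter[1].lambda_used == pytest.approx(2 / 3)
        assert by_iter[1].log10_likelihood == pytest.approx(math.log10(8 / 27))
        assert by_iter[2].symbols == "AACC"
        assert by_iter[2].lambda_used == pytest.approx(3 / 7)
        assert by_iter[2].log10_likelihood == pytest.approx(math.log10(4 / 27))
        assert by_iter[3].symbols == "ACAA"
        # ranking is by pre-reweighting likelihood, descending
        scores = [p.log10_likelihood for p in result.haplotypes]
        assert scores == sorted(scores, reverse=True)
        assert result.haplotypes[0].symbols == "AAAC"

    def test_toy_chimeras_never_recovered(self, toy_matrix):
        result = recover_all(toy_matrix, L2)
        recovered = {p.symbols for p in result.haplotypes}
        assert not recovered & set(TOY_CHIMERAS)

    def test_input_matrix_left_intact(self, toy_matrix):
        before = toy_matrix.copy()
        recover_all(toy_matrix, L2)
        assert toy_matrix == before

    def test_single_haplotype_exhausts_on_second_iteration(self):
        H = CooccurrenceMatrix(4)
        for k in range(5):
            H.observe_read(ReadObservation(f"r{k}", 1, 4, tuple("ACGT")))
        result = recover_all(H)
        assert [p.symbols for p in result.haplotypes] == ["ACGT"]
        assert result.haplotypes[0].lambda_used == 1.0
        assert result.haplotypes[0].log10_likelihood == 0.0
        assert result.termination_reason == "evidence_exhausted"
        assert result.iterations == 2

    def test_iteration_cap_of_one(self, toy_matrix):
        result = recover_all(toy_matrix, TraversalConfig(lookback=2, max_iterations=1))
        assert len(result.haplotypes) == 1
        assert result.termination_reason == "max_iterations"

    def test_hole_at_start(self):
        result = recover_all(CooccurrenceMatrix(3))
        assert result.haplotypes == []
        assert result.termination_reason == "hole_at_start"

    def test_evidence_monotone_and_halts(self, toy_matrix):
        result = recover_all(toy_matrix, L2)
        totals = [d["total_adjacent_evidence"] for d in result.diagnostics]
        lams = [d.get("lambda") for d in result.diagnostics]
        for before, after, lam in zip(totals, totals[1:], lams):
            assert after <= before + 1e-12
            if lam and lam > 0:
                assert after < before
        assert result.iterations <= TraversalConfig().max_iterations

    def test_counts_never_increase_across_reweighting(self, toy_matrix):
        work = toy_matrix.copy()
        for _ in range(5):
            path = traverse(work, L2)
            if not path.complete:
                break
            before = work.copy()
            reweight(path, compute_lambda(path, work), work)
            assert np.all(work._counts <= before._counts + 1e-12)

    def test_two_balanced_haplotypes_recovered_first(self, tmp_path):
        spec = CommunitySpec(
            region_length=400,
            n_haplotypes=2,
            snv_positions=evenly_spaced_positions(400, 6),
            read_length=150,
            coverage=20.0,
            error_rate=0.0,
            seed=3,
        )
        community, H, _, _ = community_matrix(spec, tmp_path)
        result = recover_all(H)
        early = {p.symbols for p in result.haplotypes if p.iteration <= 5}
        assert set(community.alleles) <= early


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [{"lookback": 0}, {"max_iterations": 0},
                                    {"tie_break": "coin-flip"}])
    def test_bad_config_rejected(self, kw):
        with pytest.raises(ValueError):
            TraversalConfig(**kw)
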