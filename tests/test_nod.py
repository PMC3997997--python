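"""NOD computation, signed-rank significance, and distribution comparison."""

import itertools

import numpy as np
import pytest
from scipy import stats

from mirnod.expression import DEResult
from mirnod.interactions import InteractionRecord, build_union_db
from mirnod.nod import (
    NODResult,
    compare_nod_distributions,
    compute_nod,
    nod_significance,
    rank_candidates_by_nod,
    signed_rank_p_greater,
)
from tests.conftest import make_records


def db_from_pairs(pairs):
    return build_union_db([make_records(pairs, "v", "validated")], [])


def brute_force_nod(pairs):
    """Independent recount: per-gene regulator tally, then per-miRNA totals."""
    regulators = {}
    for m, g in pairs:
        regulators.setdefault(g, set()).add(m)
    nod = {m: 0 for m, _ in pairs}
    for g, regs in regulators.items():
        if len(regs) == 1:
            nod[next(iter(regs))] += 1
    return nod


class TestComputeNOD:
    def test_shared_target_excluded(self):
        db = db_from_pairs([("m1", "G1"), ("m1", "G2"), ("m2", "G2"), ("m2", "G3")])
        res = compute_nod(db)
        assert res["m1"].nod == 1 and res["m1"].exclusive_targets == {"G1"}
        assert res["m2"].nod == 1 and res["m2"].exclusive_targets == {"G3"}

    def test_single_mirna_owns_all_targets(self):
        db = db_from_pairs([("m1", "G1"), ("m1", "G2"), ("m1", "G3")])
        assert compute_nod(db)["m1"].nod == 3

    def test_matches_brute_force_on_random_graphs(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mask = rng.random((50, 300)) < 0.02
            pairs = [
                (f"m{i}", f"G{j}") for i, j in zip(*np.nonzero(mask))
            ]
            if not pairs:
                continue
            res = compute_nod(db_from_pairs(pairs))
            expected = brute_force_nod(pairs)
            assert {m: r.nod for m, r in res.items()} == expected

    def test_conservation_and_disjointness(self, toy_db):
        res = compute_nod(toy_db)
        single_reg = sum(1 for regs in toy_db.gene_index.values() if len(regs) == 1)
        assert sum(r.nod for r in res.values()) == single_reg
        seen = set()
        for r in res.values():
            assert not (r.exclusive_targets & seen)
            seen |= r.exclusive_targets

    def test_adding_edge_steals_exclusivity(self):
        pairs = [("m1", "G1"), ("m1", "G2"), ("m2", "G3")]
        before = compute_nod(db_from_pairs(pairs))
        after = compute_nod(db_from_pairs(pairs + [("m2", "G1")]))
        assert after["m1"].nod == before["m1"].nod - 1
        assert after["m2"].nod <= before["m2"].nod  # never increases others


def enumerate_signed_rank_p(diffs):
    """Exact one-sided P by brute force over all 2^n sign assignments."""
    d = np.array([x for x in diffs if x != 0], dtype=float)
    n = d.size
    if n == 0:
        return 0.5
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w >= w_obs - 1e-9:
            count += 1
    return count / 2**n


class TestSignedRank:
    def test_matches_enumeration_at_small_n(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(1, 13))
            d = rng.integers(-5, 6, size=n)  # integer diffs → plenty of ties
            assert signed_rank_p_greater(d) == pytest.approx(
                enumerate_signed_rank_p(d), abs=1e-12
            )

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            d = rng.normal(size=10)  # continuous → no ties, no zeros
            ref = stats.wilcoxon(d, alternative="greater", method="exact").pvalue
            assert signed_rank_p_greater(d) == pytest.approx(ref, abs=1e-12)

    def test_focal_dominating_everyone(self):
        # 50 distinct positive differences: minimal attainable one-sided P
        p = signed_rank_p_greater(np.arange(1, 51))
        assert p < 1e-9

    def test_all_zero_differences(self):
        assert signed_rank_p_greater([0, 0, 0]) == 0.5

    def test_focal_at_symmetric_median_near_half(self):
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(50):
            pop = rng.normal(10, 3, size=101)
            focal = float(np.median(pop))
            ps.append(signed_rank_p_greater(focal - np.delete(pop, np.argsort(pop)[50])))
        assert 0.35 < np.mean(ps) < 0.65

    def test_one_sidedness_smallest_focal(self):
        nods = {"a": 0, "b": 5, "c": 9}
        assert nod_significance(nods, "a") >= 0.5

    def test_monotone_in_focal_nod(self):
        others = {f"m{i}": v for i, v in enumerate([1, 2, 2, 3, 5, 8, 9])}
        prev = 1.0
        for focal_nod in range(0, 12):
            p = signed_rank_p_greater([focal_nod - v for v in others.values()])
            assert p <= prev + 1e-12
            prev = p

    def test_focal_absent_raises(self):
        with pytest.raises(KeyError):
            nod_significance({"a": 1, "b": 2, "c": 3}, "z")


class TestDistributionComparison:
    def test_identical_vectors(self):
        cmpres = compare_nod_distributions([1, 2, 3], [1, 2, 3])
        assert cmpres.ks_stat == 0.0 and cmpres.ks_p == 1.0

    def test_disjoint_supports(self):
        assert compare_nod_distributions([10, 10, 10], [0, 0, 0]).ks_stat == 1.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            compare_nod_distributions([], [1])

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(100):
            pop = rng.poisson(2, size=600)
            group = rng.poisson(2, size=10) + 5
            ps.append(compare_nod_distributions(group, pop).ks_p)
        assert np.median(ps) < 0.05


def _de(mid, p):
    return DEResult(mid, 0.0, p, 3.0, 1.5, True)


class TestRanking:
    def test_sorted_by_nod_descending(self):
        nods = [53, 35, 33, 20, 15, 11, 11, 11, 10, 8]
        pop = {f"bg{i}": n for i, n in enumerate([0, 1, 1, 2, 0, 3, 1, 0, 2, 1] * 10)}
        nod_results = dict(pop)
        cands = []
        for i, n in enumerate(nods):
            mid = f"cand{i}"
            nod_results[mid] = n
            cands.append(_de(mid, 0.01 + i * 0.001))
        table = {m: NODResult(m, frozenset(), n) for m, n in nod_results.items()}
        ranked = rank_candidates_by_nod(cands, table)
        assert [r.nod for r in ranked] == sorted(nods, reverse=True)
        assert all(r.significant for r in ranked)  # big NODs vs small population

    def test_tie_break_is_deterministic(self):
        table = {m: NODResult(m, frozenset(), n)
                 for m, n in {"a": 5, "b": 5, "c": 1, "d": 0, "e": 0}.items()}
        ranked = rank_candidates_by_nod([_de("b", 0.02), _de("a", 0.02)], table,
                                        alpha_nod=1.0)
        assert [r.de.mirna_id for r in ranked] == ["a", "b"]  # id tie-break

    def test_alpha_one_retains_all(self):
        table = {m: NODResult(m, frozenset(), n)
                 for m, n in {"a": 0, "b": 1, "c": 2}.items()}
        ranked = rank_candidates_by_nod([_de("a", 0.01)], table, alpha_nod=1.0)
        assert ranked[0].significant

    def test_missing_nod_flagged_as_zero(self):
        table = {m: NODResult(m, frozenset(), n) for m, n in
                 {"a": 3, "b": 1, "c": 2}.items()}
        ranked = rank_candidates_by_nod([_de("zz", 0.01)], table, alpha_nod=1.0)
        assert ranked[0].missing_nod and ranked[0].nod == 0

    def test_candidate_reference_population(self):
        table = {m: NODResult(m, frozenset(), n)
                 for m, n in {"a": 9, "b": 1, "c": 1, "d": 1}.items()}
        cands = [_de(m, 0.01) for m in "abcd"]
        ranked = rank_candidates_by_nod(cands, table, alpha_nod=1.0,
                                        reference="candidates")
        by_id = {r.de.mirna_id: r for r in ranked}
        assert by_id["a"].nod_p < by_id["b"].nod_p
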