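"""Class partition and contrast statistics against enumeration oracles."""

import math

import numpy as np
import pytest

from pgnet import (AssociationRecord, ClassContrast, ContingencyTable2x2,
                   TargetTable, build_bipartite, essential_ratio,
                   fisher_exact, partition_by_degree,
                   permutation_class_test, target_coverage)
from pgnet.contrast import ContrastError, chi2_test


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the two-sided p-value."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    observed = point(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(point(x) for x in range(lo, hi + 1)
               if point(x) <= observed * (1 + 1e-12))


def net_with_degrees(degrees, flags=None):
    """Bipartite net where node i has the given degree (distinct diseases)."""
    from pgnet.io import DiseaseCatalog
    labels = DiseaseCatalog.default().labels
    records = []
    for i, k in enumerate(degrees):
        flag = bool(flags[i]) if flags is not None else False
        for d in range(k):
            records.append(AssociationRecord(
                ncrna_id=f"m{i}", ncrna_class="miRNA",
                disease=labels[d], biomarker=flag))
    return build_bipartite(records)


class TestPartition:
    def test_threshold_at_two(self):
        part = partition_by_degree(net_with_degrees([1, 1, 2, 3]))
        assert part.n_specific == 2 and part.n_universal == 2
        assert part.universal == {"m2", "m3"}

    def test_hub_is_universal(self):
        part = partition_by_degree(net_with_degrees([12, 1]))
        assert "m0" in part.universal and "m1" in part.specific

    def test_partition_covers_all_nodes(self, synthetic_default):
        net = build_bipartite(synthetic_default.associations)
        part = partition_by_degree(net)
        assert part.n_universal + part.n_specific == len(net.genotype_nodes)
        assert min((part.degree_map[n] for n in part.universal), default=2) >= 2
        assert all(part.degree_map[n] == 1 for n in part.specific)


class TestFisherExact:
    def test_diagonal_table_exact_value(self):
        p, _ = fisher_exact(ContingencyTable2x2(5, 0, 0, 5))
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_flat_table(self):
        p, odds = fisher_exact(ContingencyTable2x2(1, 1, 1, 1))
        assert p == 1.0 and odds == 1.0

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, size=4)
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            if not t.margins_positive:
                continue
            p, _ = fisher_exact(t)
            assert p == pytest.approx(
                fisher_two_sided_oracle(int(a), int(b), int(c), int(d)),
                abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ContrastError):
            fisher_exact(ContingencyTable2x2(0, 0, 3, 4))

    def test_haldane_anscombe_odds(self):
        _, odds = fisher_exact(ContingencyTable2x2(5, 0, 2, 5))
        assert odds == pytest.approx(5.5 * 5.5 / (0.5 * 2.5))

    def test_chi2_agrees_in_order_of_magnitude(self):
        t = ContingencyTable2x2(158, 17, 149, 102)
        p_f, _ = fisher_exact(t)
        p_c = chi2_test(t)
        assert p_f < 1e-6 and p_c < 1e-6


class TestPermutationTest:
    def test_extreme_separation_small_p(self):
        flags = {f"m{i}": i < 12 for i in range(24)}
        part = partition_by_degree(
            net_with_degrees([2] * 12 + [1] * 12,
                             flags=[flags[f"m{i}"] for i in range(24)]))
        p = permutation_class_test(flags, part, n_perm=999, seed=0)
        assert p <= 0.01

    def test_determinism(self):
        rng = np.random.default_rng(1)
        flags = {f"m{i}": bool(rng.random() < 0.5) for i in range(40)}
        part = partition_by_degree(net_with_degrees(
            [2] * 20 + [1] * 20, flags=[flags[f"m{i}"] for i in range(40)]))
        p1 = permutation_class_test(flags, part, n_perm=499, seed=9)
        p2 = permutation_class_test(flags, part, n_perm=499, seed=9)
        assert p1 == p2

    def test_zero_perm_rejected(self):
        flags = {"m0": True, "m1": False}
        part = partition_by_degree(net_with_degrees([2, 1],
                                                    flags=[True, False]))
        with pytest.raises(ContrastError):
            permutation_class_test(flags, part, n_perm=0)

    def test_empty_class_rejected(self):
        part = partition_by_degree(net_with_degrees([2, 2]))
        with pytest.raises(ContrastError):
            permutation_class_test({"m0": True, "m1": False}, part,
                                   n_perm=99)


class TestTargetCoverage:
    def test_set_arithmetic_example(self):
        targets = TargetTable({("m1", "G1"), ("m1", "G2"), ("m2", "G1")})
        part = partition_by_degree(net_with_degrees([1, 2, 3]))
        cov = target_coverage(part, targets)
        assert cov["universal"] == (2, 3)
        assert cov["specific"] == (0, 0)

    def test_matches_brute_force_recount(self, synthetic_default):
        net = build_bipartite(synthetic_default.associations)
        part = partition_by_degree(net)
        cov = target_coverage(part, synthetic_default.targets)
        for name, members in (("universal", part.universal),
                              ("specific", part.specific)):
            pairs = {(m, g) for m, g in
                     synthetic_default.targets.interactions if m in members}
            assert cov[name] == (len({g for _, g in pairs}), len(pairs))

    def test_monotone_in_pairs(self):
        part = partition_by_degree(net_with_degrees([2, 1]))
        small = TargetTable({("m0", "G1")})
        big = TargetTable({("m0", "G1"), ("m0", "G2")})
        assert target_coverage(part, small)["universal"] <= \
            target_coverage(part, big)["universal"]


class TestEssentialRatio:
    def test_published_counts_reproduce_ratio(self):
        genes = {f"G{i}" for i in range(5445)}
        essential = {f"G{i}" for i in range(3146)}
        assert round(essential_ratio(genes, essential), 3) == 0.578

    def test_disjoint_and_subset(self):
        assert essential_ratio({"A"}, {"B"}) == 0
        assert essential_ratio({"A", "B"}, {"A", "B", "C"}) == 1

    def test_empty_rejected(self):
        with pytest.raises(ContrastError):
            essential_ratio(set(), {"A"})


class TestClassContrastModel:
    def test_full_report(self, synthetic_default):
        net = build_bipartite(synthetic_default.associations)
        model = ClassContrast(net, targets=synthetic_default.targets,
                              essential=synthetic_default.essential)
        res = model.fit(n_perm=499, seed=3)
        assert 0 <= res.p_fisher <= 1
        assert 0 <= res.p_chi2 <= 1
        assert 0 <= res.p_perm <= 1
        assert res.biomarker_rate["universal"] > res.biomarker_rate["specific"]
        d = res.to_dict()
        assert {"p_fisher", "p_chi2", "p_perm"} <= d.keys()
        assert "biomarker rate" in res.summary()
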