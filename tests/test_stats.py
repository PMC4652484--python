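"""Statistics: entropy, KS, stratifications, bootstrap, union, methylation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h
from scipy import stats as sps

import hairpinbs as h
from hairpinbs import stats as st
from hairpinbs.mapper import Location, MappingResult


def _result(read_id, category, n_best=None):
    n_best = {h.UNIQUE: 1, h.AMBIGUOUS: 2, h.UNMAPPED: 0}[category] if n_best is None else n_best
    locs = (
        tuple(Location("c", i, "watson", "CT") for i in range(n_best)) if n_best else ()
    )
    return MappingResult(read_id, category, 0 if n_best else None, locs, n_best)


class TestEntropy:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("TTTTTTTT", 0.0),  # homopolymer
            ("ACGTACGT", 2.0),  # uniform base mix
            ("AATT", 1.0),  # two bases at 1/2
            ("AAAT", 0.8112781244591328),  # -(3/4 log2 3/4 + 1/4 log2 1/4)
        ],
    )
    def test_closed_forms(self, seq, expected):
        assert st.entropy(seq) == pytest.approx(expected, abs=1e-9)

    def test_n_bases_excluded(self):
        assert st.entropy("AANNTT") == pytest.approx(1.0)

    def test_empty_and_all_n_rejected(self):
        with pytest.raises(ValueError):
            st.entropy("")
        with pytest.raises(ValueError):
            st.entropy("NNN")

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st_h.text(alphabet="ACGT", min_size=1, max_size=50))
    def test_bounds_and_permutation_invariance(self, seq):
        e = st.entropy(seq)
        assert 0.0 <= e <= 2.0
        assert st.entropy(seq[::-1]) == pytest.approx(e)
        assert st.entropy("".join(sorted(seq))) == pytest.approx(e)

    def test_matches_scipy_on_counts(self):
        # independent oracle: scipy entropy on the composition vector
        for seq in ("AAAACGTT", "ACGGGGGT", "AACCGGTT", "AAAAAAAT"):
            counts = [seq.count(b) for b in "ACGT"]
            assert st.entropy(seq) == pytest.approx(sps.entropy(counts, base=2))

    def test_degrading_toward_homopolymer_strictly_decreases(self):
        # every length-8 composition: moving one base from a strict-minority
        # to a strict-majority base lowers entropy (scipy as oracle)
        for counts in itertools.product(range(9), repeat=4):
            if sum(counts) != 8:
                continue
            for i, j in itertools.permutations(range(4), 2):
                if 0 < counts[i] < counts[j]:
                    moved = list(counts)
                    moved[i] -= 1
                    moved[j] += 1
                    assert sps.entropy(moved, base=2) < sps.entropy(counts, base=2) - 1e-12
                    seq = "".join(b * c for b, c in zip("ACGT", moved))
                    assert st.entropy(seq) == pytest.approx(sps.entropy(moved, base=2))

    def test_conversion_never_increases_mean_entropy(self):
        # aggregate over >= 1e3 reads: C->T depletion skews compositions
        ref = h.generate_reference(50_000, seed=80)
        meth = h.generate_methylome(ref, seed=81)
        pairs = h.simulate_hairpin_pairs(ref, meth, h.SimConfig(n_pairs=1500, rng_seed=82))
        orig = np.mean(
            [st.entropy(ref.records[p.truth.name][p.truth.start : p.truth.end]) for p in pairs]
        )
        conv = np.mean([st.entropy(p.t_read) for p in pairs])
        assert conv <= orig


class TestEntropyBuckets:
    @pytest.mark.parametrize(
        "value,bucket",
        [(0.0, 0), (0.05, 1), (0.1, 1), (0.1001, 2), (1.45, 15), (2.0, 20)],
    )
    def test_bucket_convention(self, value, bucket):
        assert st.entropy_bucket(value) == bucket

    def test_point_mass_distribution(self):
        reads = {f"r{i}": "ACGTACGT" for i in range(5)}
        results = [_result(f"r{i}", h.UNIQUE) for i in range(5)]
        dist = st.entropy_by_category(reads, results)
        ce = dist.categories[h.UNIQUE]
        assert ce.n == 5
        assert ce.mean == pytest.approx(2.0)
        assert ce.buckets[20] == pytest.approx(1.0)

    def test_proportions_sum_to_one(self, study_mapped_t):
        dist = st.entropy_by_category(study_mapped_t["t_reads"], study_mapped_t["results"])
        for ce in dist.categories.values():
            if ce.n:
                assert sum(ce.buckets) == pytest.approx(1.0)

    def test_unknown_read_id_rejected(self):
        with pytest.raises(KeyError):
            st.entropy_by_category({"a": "ACGT"}, [_result("b", h.UNIQUE)])


def _brute_ks_d(a, b):
    pts = sorted(set(a) | set(b))
    return max(
        abs(sum(x <= p for x in a) / len(a) - sum(x <= p for x in b) / len(b)) for p in pts
    )


class TestKS:
    def test_identical_samples_give_zero(self):
        d, _ = st.ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_disjoint_supports_give_one(self):
        d, p = st.ks_two_sample([0.1, 0.2], [5.0, 6.0, 7.0])
        assert d == 1.0
        assert p < 0.2

    def test_matches_brute_force_cdf_scan(self):
        rng = np.random.default_rng(83)
        for _ in range(50):
            a = list(rng.normal(size=rng.integers(2, 11)))
            b = list(rng.normal(loc=rng.uniform(-1, 1), size=rng.integers(2, 11)))
            d, _ = st.ks_two_sample(a, b)
            assert d == pytest.approx(_brute_ks_d(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            st.ks_two_sample([], [1.0])

    def test_max_category_differences_consistency(self, study_mapped_t):
        dist = st.entropy_by_category(study_mapped_t["t_reads"], study_mapped_t["results"])
        diffs = st.max_category_differences(dist)
        assert set(diffs) == {"unmapped-ambiguous", "unmapped-unique", "unique-ambiguous"}
        d_direct, _ = st.ks_two_sample(dist.samples[h.UNIQUE], dist.samples[h.AMBIGUOUS])
        assert diffs["unique-ambiguous"] == pytest.approx(d_direct)
        # symmetric in pair order
        d_swapped, _ = st.ks_two_sample(dist.samples[h.AMBIGUOUS], dist.samples[h.UNIQUE])
        assert d_direct == pytest.approx(d_swapped)


class TestCategoriesByLength:
    def test_single_length_sums_to_100(self):
        reads = {"a": "ACGT" * 25, "b": "TTTT" * 25}
        results = [_result("a", h.UNIQUE), _result("b", h.AMBIGUOUS)]
        df = st.categories_by_length(reads, results)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["length"] == 100
        assert row["unique_pct"] + row["ambiguous_pct"] + row["unmapped_pct"] == pytest.approx(100)
        assert bool(row["low_support"])

    def test_recounts_from_per_read_records(self, study_mapped_t):
        df = st.categories_by_length(study_mapped_t["t_reads"], study_mapped_t["results"])
        by_len = {}
        for r in study_mapped_t["results"]:
            by_len.setdefault(len(study_mapped_t["t_reads"][r.read_id]), []).append(r.category)
        for _, row in df.iterrows():
            cats = by_len[row["length"]]
            assert row["n"] == len(cats)
            assert row["unique_pct"] == pytest.approx(100.0 * cats.count(h.UNIQUE) / len(cats))


class TestBootstrap:
    def test_null_configuration_gives_zero_improvement(self):
        # an A/T-only genome is untouched by bisulfite conversion, so the
        # recovered read equals the converted read and improvement vanishes
        ref = h.generate_reference(5000, gc_fraction=0.0, seed=84)
        meth = h.generate_methylome(ref, seed=85)
        pairs = h.simulate_hairpin_pairs(ref, meth, h.SimConfig(n_pairs=100, rng_seed=86))
        summary = st.bootstrap_improvement(pairs, ref, B=10, seed=87)
        assert summary.improvements == (0.0,) * 10
        assert summary.p_value == 1.0

    def test_single_replicate_variance_zero(self):
        ref = h.generate_reference(5000, seed=88)
        meth = h.generate_methylome(ref, seed=89)
        pairs = h.simulate_hairpin_pairs(ref, meth, h.SimConfig(n_pairs=50, rng_seed=90))
        summary = st.bootstrap_improvement(pairs, ref, B=1, seed=91)
        assert summary.B == 1
        assert summary.variance == 0.0

    def test_deterministic_under_seed(self, study_data):
        pairs = study_data["pairs"][:300]
        a = st.bootstrap_improvement(pairs, study_data["ref"], B=5, seed=92)
        b = st.bootstrap_improvement(pairs, study_data["ref"], B=5, seed=92)
        assert a == b


class TestRescueAndUnion:
    def test_identical_categories_no_rescue(self):
        res = [_result(f"r{i}", h.UNIQUE) for i in range(4)]
        out = st.cross_strand_rescue(res, res)
        assert out.t_unique_partner_not_pct == 0.0
        assert out.a_unique_partner_not_pct == 0.0
        assert out.combined_unique_pct == 100.0

    def test_full_rescue_of_unmapped_mate(self):
        res_t = [_result(f"r{i}", h.UNIQUE) for i in range(4)]
        res_a = [_result(f"r{i}", h.UNMAPPED) for i in range(4)]
        out = st.cross_strand_rescue(res_t, res_a)
        assert out.t_unique_partner_not_pct == 100.0
        assert out.combined_unique_pct == 100.0

    def test_combined_at_least_each_side(self, study_data):
        ref = study_data["ref"]
        pairs = study_data["pairs"][:300]
        bis = h.build_index(ref, mode="bisulfite")
        res_t, s_t = h.map_batch(bis, [(p.pair_id, p.t_read) for p in pairs])
        res_a, s_a = h.map_batch(bis, [(p.pair_id, p.a_read) for p in pairs])
        out = st.cross_strand_rescue(res_t, res_a)
        assert out.combined_unique_pct >= max(s_t["unique_pct"], s_a["unique_pct"])

    def test_union_identical_results_zero_increment(self):
        res = [_result(f"r{i}", h.UNIQUE) for i in range(4)]
        out = st.mapper_union(res, res)
        assert out.increment_over_1 == 0.0 and out.increment_over_2 == 0.0

    def test_union_of_disjoint_unique_sets(self):
        res_1 = [_result("a", h.UNIQUE), _result("b", h.UNMAPPED), _result("c", h.UNMAPPED)]
        res_2 = [_result("a", h.UNMAPPED), _result("b", h.UNIQUE), _result("c", h.UNMAPPED)]
        out = st.mapper_union(res_1, res_2)
        assert out.union_unique_pct == pytest.approx(100.0 * 2 / 3)
        assert out.union_unique_pct >= out.unique_pct_1
        assert out.union_unique_pct >= out.unique_pct_2

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError):
            st.mapper_union([_result("a", h.UNIQUE)], [_result("b", h.UNIQUE)])


class TestEstimateMethylation:
    def test_all_methylated_cpg(self):
        reads = [
            h.RecoveredRead("p", "ACGT", (), (h.MethCall(1, h.WATSON, True),)),
            h.RecoveredRead("q", "CCGG", (), (h.MethCall(1, h.WATSON, True),)),
        ]
        est = st.estimate_methylation(reads)
        assert est.cpg_rate == 1.0
        assert est.n_cpg == 2

    def test_estimate_equals_direct_recount(self, study_data):
        pairs = h.simulate_hairpin_pairs(
            study_data["ref"], study_data["meth"], h.SimConfig(n_pairs=200, rng_seed=93)
        )
        recovered = [h.recover(p) for p in pairs]
        est = st.estimate_methylation(recovered)
        meth_cpg = tot_cpg = 0
        for r in recovered:
            for c in r.meth_calls:
                j = c.offset + (1 if c.strand == h.WATSON else -1)
                if 0 <= j < len(r.sequence):
                    ctx_base = r.sequence[j]
                    if (c.strand == h.WATSON and ctx_base == "G") or (
                        c.strand == h.CRICK and ctx_base == "C"
                    ):
                        tot_cpg += 1
                        meth_cpg += c.methylated
        assert est.n_cpg == tot_cpg
        assert est.cpg_rate == pytest.approx(meth_cpg / tot_cpg)

    def test_no_calls_rejected(self):
        with pytest.raises(ValueError):
            st.estimate_methylation([h.RecoveredRead("p", "ATAT", (), ())])
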