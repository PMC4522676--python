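"""Grade-association screening: correlations, corrections, filters, signature."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icgsig import discovery
from icgsig.containers import Signature
from icgsig.discovery import (
    ConstantInputError,
    bh_adjust,
    build_signature,
    collapse_probes_to_genes,
    compare_rho_distributions,
    correlate_with_grade,
    enrichment_test,
    filter_by_presence,
    filter_sex_chromosomes,
    spearman_rho,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

class TestSpearman:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [10, 20, 30, 40], 1.0),
            ([1, 2, 3, 4], [4, 3, 2, 1], -1.0),
            # rank-difference formula by hand: d^2 = 4, rho = 1 - 24/120
            ([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], 0.8),
        ],
    )
    def test_rho_values(self, x, y, expected):
        rho, p = spearman_rho(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)
        assert 0 < p <= 1

    def test_exact_p_for_perfect_monotone_n4(self):
        # among the 24 rank pairings of n=4, only identity and reversal reach |rho|=1
        _, p = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert p == pytest.approx(2 / 24)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3, 4], [1, 2, 3])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [3, 2, 1])

    def test_constant_vector_flagged(self):
        with pytest.raises(ConstantInputError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(-50, 50), min_size=5, max_size=8, unique=True),
        st.permutations(range(8)),
    )
    def test_invariant_under_monotone_transforms(self, x, perm):
        y = [float(p) for p in perm[: len(x)]]
        rho, _ = spearman_rho([float(v) for v in x], y)
        # strictly increasing maps of either argument preserve all ranks
        rho2, _ = spearman_rho([v**3 + 2 * v for v in x], [v**3 + 2 * v for v in y])
        assert rho2 == pytest.approx(rho, abs=1e-12)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_stepup_reference(p):
    """Literal step-up definition: adj(i) = min_{j>=i} p(j)*m/j on sorted p."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj_sorted, None, 1.0)
    return out


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_known_values(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_stepup_on_all_permutations(self):
        base = [0.001, 0.02, 0.04, 0.2, 0.5, 0.9]
        for perm in itertools.permutations(base):
            p = np.array(perm)
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_reference(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_order_preserving(self, rng):
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# enrichment and rho-distribution comparison
# ---------------------------------------------------------------------------

def hypergeom_upper_tail_reference(k, n, K, N):
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
        if n - j <= N - K
    ) / total


class TestEnrichment:
    def test_small_table(self):
        assert enrichment_test(2, 2, 2, 4) == pytest.approx(1 / 6)

    def test_lower_extreme_is_one(self):
        assert enrichment_test(0, 5, 3, 20) == pytest.approx(1.0)

    def test_upper_extreme_closed_form(self):
        # drawing all K marked items in K draws has probability 1/C(N, K)
        assert enrichment_test(4, 4, 4, 10) == pytest.approx(1 / math.comb(10, 4))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(3, 2, 5, 10)

    def test_matches_enumeration_for_all_small_tables(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        assert enrichment_test(k, n, K, N) == pytest.approx(
                            hypergeom_upper_tail_reference(k, n, K, N), rel=1e-10
                        )


class TestCompareRho:
    def test_identical_samples(self):
        t, p = compare_rho_distributions([0.1, -0.2, 0.3], [0.1, -0.2, 0.3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_negative_shift_detected(self, rng):
        b = rng.normal(0.0, 0.2, size=100)
        a = b - 0.3
        t, p = compare_rho_distributions(a, b)
        # hand Welch statistic
        se = math.sqrt(a.var(ddof=1) / 100 + b.var(ddof=1) / 100)
        assert t == pytest.approx((a.mean() - b.mean()) / se)
        assert t < 0
        assert p < 1e-6

    def test_single_element_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_rho_distributions([0.1], [0.2])

    def test_degenerate_constant_groups_rejected(self):
        with pytest.raises(ConstantInputError):
            compare_rho_distributions([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


# ---------------------------------------------------------------------------
# filters and probe collapse
# ---------------------------------------------------------------------------

class TestPresenceFilter:
    def test_two_thirds_boundary(self):
        calls = pd.DataFrame(
            [[True, True, False], [True, False, False], [True, True, True]],
            index=["f1", "f2", "f3"], columns=["a", "b", "c"],
        )
        kept = filter_by_presence(calls, 2 / 3)
        assert list(kept) == ["f1", "f3"]

    def test_full_presence_required(self):
        calls = pd.DataFrame([[True, False]], index=["f1"], columns=["a", "b"])
        assert len(filter_by_presence(calls, 1.0)) == 0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            filter_by_presence(pd.DataFrame(), 0.5)

    def test_bad_fraction_rejected(self):
        calls = pd.DataFrame([[True]], index=["f"], columns=["a"])
        with pytest.raises(ValueError):
            filter_by_presence(calls, 0.0)


class TestSexChromosomeFilter:
    def test_x_removed_autosome_retained(self):
        m = make_matrix(
            [[1, 2], [3, 4], [5, 6]], ["fx", "f7", "fy"], ["a", "b"],
            gene_symbol=["GX", "G7", "GY"], chromosome=["chrX", "chr7", "Y"],
        )
        out = filter_sex_chromosomes(m)
        assert list(out.feature_ids) == ["f7"]

    def test_empty_matrix_identity(self):
        m = make_matrix(np.empty((0, 2)), [], ["a", "b"])
        out = filter_sex_chromosomes(m)
        assert out.n_features == 0

    def test_missing_annotation_retained_with_warning(self, caplog):
        m = make_matrix(
            [[1, 2], [3, 4]], ["f1", "f2"], ["a", "b"],
            gene_symbol=["G1", "G2"], chromosome=["", "X"],
        )
        with caplog.at_level("WARNING"):
            out = filter_sex_chromosomes(m)
        assert list(out.feature_ids) == ["f1"]
        assert any("lack chromosome" in r.message for r in caplog.records)


class TestCollapseProbes:
    def test_geometric_mean_on_linear_scale(self):
        # log2 values 2 and 4 are linear 4 and 16; geometric mean 8 is log2 3
        m = make_matrix(
            [[2.0], [4.0]], ["p1", "p2"], ["a"], gene_symbol=["G", "G"],
            chromosome=["1", "1"],
        )
        out = collapse_probes_to_genes(m)
        assert out.values.loc["G", "a"] == pytest.approx(3.0)

    def test_three_probe_mean_and_singleton_identity(self):
        m = make_matrix(
            [[1.0], [2.0], [3.0], [7.5]], ["p1", "p2", "p3", "p4"], ["a"],
            gene_symbol=["G", "G", "G", "H"], chromosome=["1"] * 4,
        )
        out = collapse_probes_to_genes(m)
        assert out.values.loc["G", "a"] == pytest.approx(2.0)
        assert out.values.loc["H", "a"] == pytest.approx(7.5)

    def test_unmapped_probe_rejected(self):
        m = make_matrix([[1.0]], ["p1"], ["a"])
        with pytest.raises(ValueError):
            collapse_probes_to_genes(m, mapping=pd.Series({"other": "G"}))


# ---------------------------------------------------------------------------
# grade correlation and signature construction
# ---------------------------------------------------------------------------

def _planted_cohort(rng, n=40, effect=0.5, sd=0.2, n_null=30):
    grades = rng.choice([1, 2, 3, 4], size=n)
    planted = 8 + effect * (grades - 1) + rng.normal(0, sd, n)
    nulls = rng.normal(8, sd, size=(n_null, n))
    values = np.vstack([planted, nulls])
    ids = ["PLANTED"] + [f"N{i}" for i in range(n_null)]
    m = make_matrix(values, ids, [f"s{i}" for i in range(n)],
                    gene_symbol=ids, chromosome=["1"] * len(ids))
    return m, pd.Series(grades, index=m.sample_ids)


class TestCorrelateWithGrade:
    def test_planted_monotone_feature_detected(self, rng):
        m, grades = _planted_cohort(rng)
        assoc = correlate_with_grade(m, grades)
        assert assoc.loc["PLANTED", "p_adj"] < 0.05
        assert assoc.loc["PLANTED", "direction"] == 1

    def test_constant_feature_excluded_and_flagged(self, rng):
        m, grades = _planted_cohort(rng, n_null=5)
        m.values.loc["N0"] = 5.0
        assoc = correlate_with_grade(m, grades)
        assert "N0" not in assoc.index
        assert assoc.attrs["excluded_features"] == ["N0"]

    def test_misaligned_samples_rejected(self, rng):
        m, grades = _planted_cohort(rng)
        with pytest.raises(ValueError):
            correlate_with_grade(m, grades.iloc[:-3])

    def test_fdr_controlled_under_global_null(self):
        # all features noise: mean fraction passing BH 0.05 must stay <= 0.05
        rng = np.random.default_rng(11)
        fracs = []
        for _ in range(100):
            grades = rng.choice([1, 2, 3, 4], size=30, p=[0.1, 0.1, 0.2, 0.6])
            values = rng.normal(8, 1, size=(200, 30))
            m = make_matrix(values, [f"g{i}" for i in range(200)],
                            [f"s{i}" for i in range(30)])
            assoc = correlate_with_grade(m, pd.Series(grades, index=m.sample_ids))
            fracs.append((assoc["p_adj"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05


def _assoc_frame(rows):
    df = pd.DataFrame(rows, columns=["feature_id", "gene_symbol", "rho", "p_adj"])
    df = df.set_index("feature_id")
    df["p_raw"] = df["p_adj"] / 2
    df["direction"] = np.sign(df["rho"]).astype(int)
    return df


class TestBuildSignature:
    def test_two_up_sixteen_down(self):
        rows = [(f"u{i}", f"UP{i}", 0.6, 0.01) for i in range(2)]
        rows += [(f"d{i}", f"DN{i}", -0.6, 0.01) for i in range(16)]
        rows += [("x0", "NS", -0.2, 0.8)]
        sig = build_signature(_assoc_frame(rows),
                              {f"UP{i}" for i in range(2)} | {f"DN{i}" for i in range(16)} | {"NS"})
        assert len(sig) == 18
        assert len(sig.subset(1)) == 2
        assert len(sig.subset(-1)) == 16

    def test_alpha_zero_gives_empty_signature(self):
        assoc = _assoc_frame([("f", "G", 0.9, 1e-12)])
        assert len(build_signature(assoc, {"G"}, alpha=0.0)) == 0

    def test_conflicting_probe_signs_exclude_gene(self, caplog):
        assoc = _assoc_frame([("f1", "G", 0.9, 0.001), ("f2", "G", -0.9, 0.001),
                              ("f3", "H", 0.8, 0.001)])
        with caplog.at_level("WARNING"):
            sig = build_signature(assoc, {"G", "H"})
        assert sig.genes == ["H"]
        assert any("conflicting" in r.message for r in caplog.records)

    def test_multiprobe_gene_enters_once(self):
        assoc = _assoc_frame([("f1", "G", 0.9, 0.001), ("f2", "G", 0.7, 0.01)])
        sig = build_signature(assoc, {"G"})
        assert sig.genes == ["G"]
        assert sig.weights["G"] == 1

    def test_planted_cohort_recovery_has_no_sign_flips(self):
        # directional fidelity: every recovered gene keeps its planted sign
        from icgsig.synthetic import CohortSpec, generate_discovery_cohort

        for seed in range(50):
            spec = CohortSpec(seed=seed, n_background_genes=100)
            m, grades, _ = generate_discovery_cohort(spec)
            assoc = correlate_with_grade(m, grades)
            sig = build_signature(assoc, m.ion_channel_genes())
            for gene, weight in sig:
                assert weight == spec.planted.weights[gene], f"sign flip at {gene}, seed {seed}"
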