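"""Concordance classification, accuracy metrics, tiers and indicators."""

import itertools
import math

import numpy as np
import pytest

import oracles
import panelkit as pk
from panelkit.imputation_eval import round_pct
from panelkit.vcf_io import MISSING


def _sites(positions, chrom="1", ref="A", alt="G"):
    return [pk.VariantSite(chrom=chrom, pos=p, id=f"v{p}", ref=ref,
                           alts=(alt,)) for p in positions]


def _matrix(codes, dosage=None):
    codes = np.asarray(codes, dtype=np.int8)
    return pk.GenotypeMatrix(
        codes=codes, samples=[f"S{i}" for i in range(codes.shape[0])],
        dosage=None if dosage is None else np.asarray(dosage,
                                                      dtype=np.float32))


class TestMatchSites:
    def test_identical_lists_fully_matched(self):
        a = _sites([10, 20, 30])
        m = pk.match_sites(a, a)
        assert m.pairs == [(0, 0), (1, 1), (2, 2)]
        assert m.unmatched_truth == [] and m.unmatched_imputed == []

    def test_swapped_ref_alt_stays_unmatched(self):
        truth = _sites([10], ref="A", alt="G")
        imputed = _sites([10], ref="G", alt="A")
        m = pk.match_sites(truth, imputed)
        assert m.pairs == []
        assert m.unmatched_truth == [0] and m.unmatched_imputed == [0]

    def test_unsorted_input_rejected(self):
        a = _sites([20, 10])
        with pytest.raises(ValueError, match="sorted"):
            pk.match_sites(a, a)

    def test_interleaved_lists_match_set_intersection(self, rng):
        pos_a = np.sort(rng.choice(np.arange(1, 500), size=80, replace=False))
        pos_b = np.sort(rng.choice(np.arange(1, 500), size=80, replace=False))
        truth, imputed = _sites(pos_a), _sites(pos_b)
        m = pk.match_sites(truth, imputed)
        shared = set(pos_a) & set(pos_b)
        assert {truth[i].pos for i, _ in m.pairs} == shared
        assert all(truth[i].pos == imputed[j].pos for i, j in m.pairs)


class TestClassifyPair:
    def test_full_truth_table(self):
        for (t, c), want in oracles.ALLELE_DOSE_TABLE.items():
            assert pk.classify_pair(t, c) == want

    def test_alternative_policies_for_het_hom_discordance(self):
        assert pk.classify_pair(1, 2, policy="mismatch-to-FP") == "FP"
        assert pk.classify_pair(2, 1, policy="mismatch-to-FP") == "FP"
        assert pk.classify_pair(1, 2, policy="mismatch-to-FN") == "FN"
        assert pk.classify_pair(2, 1, policy="mismatch-to-FN") == "FN"

    def test_missing_code_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            pk.classify_pair(MISSING, 0)


class TestConfusion:
    def test_identity_with_drop_flag_gives_tn_zero(self, small_cohort):
        sites, truth, _, _ = small_cohort
        m = pk.match_sites(sites, sites)
        counts = pk.confusion(truth, truth, m.pairs)
        assert counts.fp == counts.fn == counts.tn == 0
        assert counts.tp == int(np.sum(truth.codes > 0))

    def test_keep_homref_counts_tn(self, small_cohort):
        sites, truth, _, _ = small_cohort
        m = pk.match_sites(sites, sites)
        counts = pk.confusion(truth, truth, m.pairs,
                              drop_concordant_homref=False)
        assert counts.tn == int(np.sum(truth.codes == 0))
        assert counts.total == truth.codes.size

    def test_random_pairs_match_enumeration_oracle(self, rng):
        n, s = 50, 200
        t = rng.integers(0, 3, size=(n, s)).astype(np.int8)
        c = rng.integers(0, 3, size=(n, s)).astype(np.int8)
        t[rng.random((n, s)) < 0.05] = MISSING
        c[rng.random((n, s)) < 0.05] = MISSING
        pairs = [(j, j) for j in range(s)]
        for drop in (True, False):
            got = pk.confusion(_matrix(t), _matrix(c), pairs,
                               drop_concordant_homref=drop)
            want = oracles.tally(t.ravel(), c.ravel(),
                                 drop_concordant_homref=drop)
            assert (got.tp, got.fp, got.fn, got.tn) == (
                want["TP"], want["FP"], want["FN"], want["TN"])

    def test_pair_conservation(self, small_cohort):
        sites, truth, imp_sites, imputed = small_cohort
        m = pk.match_sites(sites, imp_sites)
        counts = pk.confusion(truth, imputed, m.pairs,
                              drop_concordant_homref=False)
        evaluated = int(np.sum((truth.codes != MISSING)
                               & (imputed.codes != MISSING)))
        assert counts.total == evaluated


class TestRatiosPrecisionSensitivity:
    def test_pure_tp(self):
        assert pk.ratios(pk.ConfusionCounts(tp=1)) == (1.0, 0.0, 0.0, 0.0)

    def test_direct_arithmetic(self):
        counts = pk.ConfusionCounts(tp=9371, fp=193, fn=435, tn=0)
        tp_r, fp_r, fn_r, tn_r = pk.ratios(counts)
        total = 9371 + 193 + 435
        assert tp_r == pytest.approx(9371 / total)
        assert tp_r + fp_r + fn_r + tn_r == pytest.approx(1.0)

    def test_ratios_sum_to_one_randomized(self, rng):
        for _ in range(20):
            c = pk.ConfusionCounts(*(int(x) for x in rng.integers(0, 500, 4)))
            if c.total == 0:
                continue
            assert sum(pk.ratios(c)) == pytest.approx(1.0)

    def test_precision_from_printed_ratio_pairs(self):
        # ratio metrics are scale-free: feed the percent values as counts
        assert round_pct(100 * pk.precision(
            pk.ConfusionCounts(tp=9371, fp=193))) == 97.98
        assert round_pct(100 * pk.precision(
            pk.ConfusionCounts(tp=9218, fp=257))) == 97.29

    def test_sensitivity_from_printed_ratio_pair(self):
        assert round_pct(100 * pk.sensitivity(
            pk.ConfusionCounts(tp=9221, fn=543))) == 94.44

    def test_perfect_calls(self):
        c = pk.ConfusionCounts(tp=10)
        assert pk.precision(c) == 1.0 and pk.sensitivity(c) == 1.0

    def test_zero_denominators_flagged_nan(self):
        with pytest.warns(UserWarning):
            assert math.isnan(pk.precision(pk.ConfusionCounts(fn=3)))
        with pytest.warns(UserWarning):
            assert math.isnan(pk.sensitivity(pk.ConfusionCounts(fp=3)))
        with pytest.raises(ValueError):
            pk.ratios(pk.ConfusionCounts())


class TestNrc:
    def test_perfect_calls_score_one(self, small_cohort):
        sites, truth, _, _ = small_cohort
        pairs = [(j, j) for j in range(truth.n_sites)]
        assert pk.nrc(truth, truth, pairs) == 1.0

    def test_half_of_hets_missed_scores_half(self):
        t = _matrix([[1] * 10])
        c = _matrix([[1] * 5 + [0] * 5])
        assert pk.nrc(t, c, [(j, j) for j in range(10)]) == 0.5

    def test_matches_counting_oracle(self, rng):
        t = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        c = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        got = pk.nrc(_matrix(t), _matrix(c), [(j, j) for j in range(50)])
        nonref = t > 0
        want = float(np.sum((t == c) & nonref)) / float(np.sum(nonref))
        assert got == pytest.approx(want)

    def test_no_nonref_truth_flagged(self):
        t, c = _matrix([[0, 0]]), _matrix([[0, 1]])
        with pytest.warns(UserWarning):
            assert math.isnan(pk.nrc(t, c, [(0, 0), (1, 1)]))


class TestSampleDosageR2:
    def test_exact_dosages_score_one(self, small_cohort):
        sites, truth, _, _ = small_cohort
        imp = _matrix(truth.codes, dosage=truth.codes.astype(float))
        pairs = [(j, j) for j in range(truth.n_sites)]
        r2, mean = pk.sample_dosage_r2(truth, imp, pairs)
        assert np.allclose(r2, 1.0)
        assert mean == pytest.approx(1.0)

    def test_independent_dosages_score_near_zero(self, rng):
        n_sites = 2000
        t = rng.integers(0, 3, size=(5, n_sites)).astype(np.int8)
        d = rng.uniform(0, 2, size=(5, n_sites))
        r2, mean = pk.sample_dosage_r2(_matrix(t), _matrix(t, dosage=d),
                                       [(j, j) for j in range(n_sites)])
        assert mean < 20 / n_sites  # E[R^2] ~ 1/(n-1) under independence

    def test_anticorrelated_dosages_square_away_the_sign(self):
        t = _matrix([[0, 1, 2, 0, 2]])
        d = 2.0 - np.array([[0, 1, 2, 0, 2]], dtype=float)
        r2, mean = pk.sample_dosage_r2(t, _matrix(t.codes, dosage=d),
                                       [(j, j) for j in range(5)])
        assert mean == pytest.approx(1.0)

    def test_constant_sample_flagged_and_excluded(self):
        t = _matrix([[1, 1, 1], [0, 1, 2]])
        d = np.array([[0.3, 0.9, 1.5], [0.1, 1.0, 1.9]])
        with pytest.warns(UserWarning):
            r2, mean = pk.sample_dosage_r2(
                t, _matrix(t.codes, dosage=d), [(j, j) for j in range(3)])
        assert math.isnan(r2[0]) and r2[1] == pytest.approx(1.0, abs=1e-2)


class TestTiers:
    @pytest.mark.parametrize("score, tier", [
        (0.9, "high"), (0.81, "high"),
        (0.8, "medium"), (0.4, "medium"), (0.5, "medium"),
        (0.39, "low"), (0.0, "low"),
    ])
    def test_boundaries(self, score, tier):
        assert pk.tier_classify(score) == tier

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pk.tier_classify(1.2)

    def test_bin_sums_reproduce_all_column(self):
        # printed per-bin counts in units of 10^4 variants
        summary = pk.TierSummary(medium=(71, 69, 27), high=(106, 210, 604))
        assert summary.medium_all == 167
        assert summary.total_well_imputed == 167 + 920

        high_row = pk.TierSummary(medium=(0, 0, 0), high=(38, 153, 595))
        assert high_row.high_all == 786

    def test_tier_summary_counts_from_arrays(self, rng):
        afs = np.array([0.005, 0.002, 0.03, 0.2, 0.5, 0.04, 0.009])
        infos = np.array([0.9, 0.5, 0.85, 0.3, 0.95, 0.6, 0.2])
        s = pk.tier_summary(afs=afs, info_scores=infos)
        assert s.high == (1, 1, 1)      # 0.9@rare, 0.85@low, 0.95@common
        assert s.medium == (1, 1, 0)    # 0.5@rare, 0.6@low
        assert s.low == (1, 0, 1)
        rates = s.high_rate()
        assert rates[0] == pytest.approx(0.5)
        assert s.total_well_imputed == 5

    def test_af_bin_edges_inclusive_on_the_right(self):
        s = pk.tier_summary(afs=np.array([0.01, 0.05, 0.0500001]),
                            info_scores=np.array([0.9, 0.9, 0.9]))
        assert s.high == (1, 1, 1)

    def test_empty_input_zero_counts_nan_rates(self):
        s = pk.tier_summary(afs=np.array([]), info_scores=np.array([]))
        assert s.medium == s.high == (0, 0, 0)
        assert all(math.isnan(r) for r in s.high_rate())


class TestTiTv:
    def test_two_transitions_one_transversion(self):
        sites = [
            pk.VariantSite(chrom="1", pos=1, id="a", ref="A", alts=("G",)),
            pk.VariantSite(chrom="1", pos=2, id="b", ref="C", alts=("T",)),
            pk.VariantSite(chrom="1", pos=3, id="c", ref="A", alts=("C",)),
        ]
        assert pk.titv(sites) == 2.0

    def test_all_transitions_flagged(self):
        sites = [pk.VariantSite(chrom="1", pos=1, id="a", ref="A",
                                alts=("G",))]
        with pytest.warns(UserWarning):
            assert math.isnan(pk.titv(sites))

    def test_matches_lookup_table_oracle(self, rng):
        bases = "ACGT"
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        sites, ti, tv = [], 0, 0
        for p in range(1, 300):
            ref, alt = rng.choice(list(bases), size=2, replace=False)
            sites.append(pk.VariantSite(chrom="1", pos=p, id=f"v{p}",
                                        ref=str(ref), alts=(str(alt),)))
            if (str(ref), str(alt)) in transitions:
                ti += 1
            else:
                tv += 1
        # indels must be ignored
        sites.append(pk.VariantSite(chrom="1", pos=999, id="indel", ref="A",
                                    alts=("AT",)))
        assert pk.titv(sites) == pytest.approx(ti / tv)


class TestHetHom:
    def test_direct_counts(self):
        geno = _matrix([[1, 1, 2]])
        per_sample, median = pk.het_hom_ratio(geno)
        assert per_sample[0] == 2.0 and median == 2.0

    def test_all_het_flagged(self):
        with pytest.warns(UserWarning):
            per_sample, median = pk.het_hom_ratio(_matrix([[1, 1, 1]]))
        assert math.isnan(per_sample[0]) and math.isnan(median)

    def test_hwe_closed_form_at_half(self):
        # het:hom = 2(1-p)/p = 2 at p = 0.5
        spec = pk.CohortSpec(n_samples=200, n_sites=2000,
                             af_model=pk.AFModel("fixed", (0.5,)), seed=21)
        _, geno = pk.simulate_truth_cohort(spec)
        _, median = pk.het_hom_ratio(geno)
        assert median == pytest.approx(2.0, rel=0.05)


class TestParameterRecoveryAndMonotonicity:
    def test_error_rate_recovered_from_ratios(self):
        e = 0.02
        spec = pk.CohortSpec(n_samples=100, n_sites=1500, seed=31,
                             af_model=pk.AFModel("uniform", (0.05, 0.5)))
        sites, truth = pk.simulate_truth_cohort(spec)
        err = pk.ErrorModel(e_rr=e, e_ra=e, e_aa=e)
        imp_sites, imp = pk.simulate_imputed(truth, sites, err, seed=32)
        m = pk.match_sites(sites, imp_sites)
        counts = pk.confusion(truth, imp, m.pairs,
                              drop_concordant_homref=False)
        total = counts.total
        assert total >= 1e5
        fpfn = (counts.fp + counts.fn) / total
        se = math.sqrt(e * (1 - e) / total)
        assert abs(fpfn - e) < 4 * se

    def test_metrics_never_improve_with_error(self):
        spec = pk.CohortSpec(n_samples=150, n_sites=700, seed=33,
                             af_model=pk.AFModel("uniform", (0.1, 0.5)))
        sites, truth = pk.simulate_truth_cohort(spec)
        rows = []
        for e in (0.0, 0.05, 0.1, 0.2):
            err = pk.ErrorModel(e_rr=e, e_ra=e, e_aa=e, dosage_sd=2 * e)
            imp_sites, imp = pk.simulate_imputed(truth, sites, err, seed=34)
            summary = pk.evaluate(sites, truth, imp_sites, imp,
                                  drop_concordant_homref=False)
            rows.append((summary.precision, summary.sensitivity, summary.nrc,
                         summary.mean_r2))
        for col in range(4):
            vals = [r[col] for r in rows]
            assert all(a >= b for a, b in zip(vals, vals[1:])), (col, vals)
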