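"""Peak-table parsing, clonality classification, perturbation scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thymospec import spectratype as sp
from thymospec.exceptions import UndetectedSubgroupError, ValidationError
from thymospec.synthetic import generate_peak_table, generate_spectratype_profile
from thymospec.trbv import TRBV_SUBGROUPS, ladder_sizes


def _dist(rel, trbv="TRBV2", start=120.0):
    rel = np.asarray(rel, dtype=float)
    lengths = tuple(start + 3 * k for k in range(rel.size))
    return sp.TRBVDistribution(trbv, lengths, rel, detected=True)


def _records(areas, trbv="TRBV2", sample="s1"):
    return [
        sp.PeakRecord(sample, trbv, 120.0 + 3 * i, a / 2.5, a) for i, a in enumerate(areas)
    ]


class TestParsePeakTable:
    def test_full_cohort_table_has_23_subgroups_per_sample(self, small_study):
        recs = sp.parse_peak_table(small_study.peak_table)
        assert len(recs) == len(small_study.subjects)
        for sid, peaks in recs.items():
            assert len({p.trbv for p in peaks}) == 23

    def test_empty_table_yields_empty_map(self):
        df = pd.DataFrame(columns=list(sp.PEAK_TABLE_COLUMNS))
        assert sp.parse_peak_table(df) == {}

    def test_unknown_subgroup_rejected_with_vocabulary(self):
        df = pd.DataFrame(
            [{"sample_id": "s", "trbv": "TRBV99", "fragment_size": 120, "height": 1, "area": 10}]
        )
        with pytest.raises(ValidationError, match="TRBV99"):
            sp.parse_peak_table(df)

    def test_missing_column_named(self):
        df = pd.DataFrame([{"sample_id": "s", "trbv": "TRBV2", "fragment_size": 120, "height": 1}])
        with pytest.raises(ValidationError, match="area"):
            sp.parse_peak_table(df)

    def test_tsv_file_roundtrip(self, tmp_path, small_study):
        path = tmp_path / "peaks.tsv"
        small_study.peak_table.to_csv(path, sep="\t", index=False)
        recs = sp.parse_peak_table(path)
        assert len(recs) == len(small_study.subjects)


class TestNormalize:
    def test_plain_normalization(self):
        d = sp.normalize_distribution(_records([10, 10, 20]))
        assert d.rel_area == pytest.approx([0.25, 0.25, 0.5])

    def test_small_peak_zeroed_below_detectability_floor(self):
        # 1/101 < 2% -> zeroed, remainder renormalized
        d = sp.normalize_distribution(_records([100, 1]), min_peak_frac=0.02)
        assert d.rel_area == pytest.approx([1.0, 0.0])

    def test_zero_area_subgroup_is_undetected(self):
        d = sp.normalize_distribution(_records([0, 0, 0]))
        assert not d.detected
        with pytest.raises(UndetectedSubgroupError):
            sp.count_peaks(d)
        with pytest.raises(UndetectedSubgroupError):
            sp.classify_profile(d)

    def test_mixed_subgroups_rejected(self):
        recs = _records([10.0], trbv="TRBV2") + _records([10.0], trbv="TRBV3")
        with pytest.raises(ValidationError):
            sp.normalize_distribution(recs)


class TestCountPeaks:
    @pytest.mark.parametrize(
        "rel, expected",
        [([0.125] * 8, 8), ([0.5, 0, 0.5, 0, 0], 2), ([1.0], 1)],
    )
    def test_counts_positive_positions(self, rel, expected):
        assert sp.count_peaks(_dist(rel)) == expected

    def test_generated_normal_profile_has_at_least_7_peaks(self, rng):
        for _ in range(50):
            peaks = generate_spectratype_profile("normal", seed=rng)
            d = sp.normalize_distribution(_records([a for _, a in peaks]))
            assert sp.count_peaks(d) >= 7


class TestClassify:
    def test_symmetric_bell_is_normal_with_high_fit(self):
        # binomial(7, 0.5) weights: an 8-peak discrete bell
        from math import comb

        w = np.array([comb(7, k) for k in range(8)], dtype=float) / 2**7
        pc = sp.classify_profile(_dist(w))
        assert pc.label == "normal"
        assert pc.gaussian_fit_score > 0.99

    def test_single_dominant_peak_is_mono_oligoclonal(self):
        pc = sp.classify_profile(_dist([1.0]))
        assert pc.label == "mono_oligoclonal" and pc.top1_share == 1.0

    def test_five_equal_peaks_is_restricted(self):
        pc = sp.classify_profile(_dist([0.2] * 5))
        assert pc.label == "restricted" and pc.peak_count == 5

    def test_dominance_precedes_peak_count(self):
        # 7 peaks but one towering: oligoclonal, not normal/shifted
        rel = np.array([0.55, 0.1, 0.08, 0.08, 0.07, 0.06, 0.06])
        assert sp.classify_profile(_dist(rel)).label == "mono_oligoclonal"

    def test_bimodal_eight_peaks_is_shifted(self):
        rel = np.array([0.05, 0.2, 0.1, 0.04, 0.04, 0.1, 0.22, 0.25])
        rel = rel / rel.sum()
        pc = sp.classify_profile(_dist(rel))
        assert pc.label == "shifted"
        assert pc.gaussian_fit_score < 0.90

    def test_peak_record_order_never_changes_output(self, rng):
        peaks = generate_spectratype_profile("normal", seed=rng)
        recs = _records([a for _, a in peaks])
        shuffled = list(recs)
        rng.shuffle(shuffled)
        a = sp.classify_profile(sp.normalize_distribution(recs))
        b = sp.classify_profile(sp.normalize_distribution(shuffled))
        assert a == b


def _brute_tv(p, r):
    """Independent oracle: total variation = half the L1 distance, percent."""
    return 50.0 * float(np.abs(np.asarray(p) - np.asarray(r)).sum())


class TestPerturbation:
    def test_identity_is_zero(self):
        d = _dist([0.3, 0.3, 0.4])
        assert sp.perturbation_score(d, d) == 0.0

    def test_disjoint_supports_score_100(self):
        p = _dist([1.0, 0.0])
        r = _dist([0.0, 1.0])
        assert sp.perturbation_score(p, r) == pytest.approx(100.0)

    def test_hand_example(self):
        p = _dist([0.5, 0.5, 0.0])
        r = _dist([0.25, 0.25, 0.5])
        assert sp.perturbation_score(p, r) == pytest.approx(50.0)

    def test_union_ladder_alignment(self):
        # different ladders: absent positions count as zero
        p = sp.TRBVDistribution("TRBV2", (120.0, 123.0), np.array([0.5, 0.5]))
        r = sp.TRBVDistribution("TRBV2", (123.0, 126.0), np.array([0.5, 0.5]))
        assert sp.perturbation_score(p, r) == pytest.approx(50.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_metric_properties_against_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 10))
        p = rng.dirichlet(np.ones(n))
        q = rng.dirichlet(np.ones(n))
        r = rng.dirichlet(np.ones(n))
        dp, dq, dr = _dist(p), _dist(q), _dist(r)
        d_pq = sp.perturbation_score(dp, dq)
        assert d_pq == pytest.approx(_brute_tv(p, q), abs=1e-9)
        assert d_pq == pytest.approx(sp.perturbation_score(dq, dp), abs=1e-12)  # symmetry
        assert 0.0 <= d_pq <= 100.0
        # triangle inequality
        assert d_pq <= sp.perturbation_score(dp, dr) + sp.perturbation_score(dr, dq) + 1e-9


class TestReference:
    def test_identical_controls_give_zero_sd(self):
        d = {"TRBV2": _dist([0.25, 0.25, 0.5])}
        hc = {f"HC-{i:03d}": d for i in range(12)}
        ref = sp.build_reference(hc, n_ref=12, seed=0)
        assert ref.perturbation_sd["TRBV2"] == 0.0
        assert ref.perturbation_mean["TRBV2"] == 0.0
        assert ref.mean_distributions["TRBV2"].rel_area == pytest.approx([0.25, 0.25, 0.5])

    def test_two_control_toy_mean_and_scores(self):
        hc = {
            "HC-001": {"TRBV2": _dist([1.0, 0.0])},
            "HC-002": {"TRBV2": _dist([0.0, 1.0])},
        }
        ref = sp.build_reference(hc, n_ref=2, seed=1)
        assert ref.mean_distributions["TRBV2"].rel_area == pytest.approx([0.5, 0.5])
        for sid in hc:
            assert sp.perturbation_score(hc[sid]["TRBV2"], ref.mean_distributions["TRBV2"]) == (
                pytest.approx(50.0)
            )

    def test_reference_is_deterministic_for_fixed_seed(self, small_study):
        from thymospec.spectratype import parse_peak_table, profiles_from_peaks

        profiles = profiles_from_peaks(parse_peak_table(small_study.peak_table))
        hc = {sid: p for sid, p in profiles.items() if sid.startswith("HC")}
        r1 = sp.build_reference(hc, n_ref=12, seed=42)
        r2 = sp.build_reference(hc, n_ref=12, seed=42)
        assert r1.reference_ids == r2.reference_ids
        for t in r1.mean_distributions:
            assert np.array_equal(
                r1.mean_distributions[t].rel_area, r2.mean_distributions[t].rel_area
            )

    def test_too_few_controls_raise(self):
        with pytest.raises(ValidationError):
            sp.build_reference({"HC-001": {}}, n_ref=12)


class TestFlagging:
    REF = sp.ReferenceRepertoire(
        mean_distributions={"TRBV2": _dist([0.5, 0.5])},
        perturbation_mean={"TRBV2": 10.0},
        perturbation_sd={"TRBV2": 2.0},
        reference_ids=("HC-001",),
    )

    @pytest.mark.parametrize(
        "d, expected",
        [
            (14.0, "none"),  # exactly mean+2SD: strict inequality
            (15.0, "over2sd"),  # mean+2.5SD
            (16.0, "over2sd"),  # exactly mean+3SD: not over3sd (strict), still over2sd
            (18.0, "over3sd"),
        ],
    )
    def test_flag_boundaries_are_strict(self, d, expected):
        res = sp.flag_overperturbed("p1", {"TRBV2": d}, self.REF)
        assert res.flags["TRBV2"] == expected

    def test_saturation_counts_all_subgroups(self):
        ref = sp.ReferenceRepertoire(
            mean_distributions={t: _dist([0.5, 0.5], trbv=t) for t in TRBV_SUBGROUPS},
            perturbation_mean={t: 10.0 for t in TRBV_SUBGROUPS},
            perturbation_sd={t: 2.0 for t in TRBV_SUBGROUPS},
            reference_ids=("HC-001",),
        )
        res = sp.flag_overperturbed("p1", {t: 18.0 for t in TRBV_SUBGROUPS}, ref)
        assert res.n_overperturbed == 23

    def test_over3sd_implies_over2sd_bound(self):
        res = sp.flag_overperturbed("p1", {"TRBV2": 99.0}, self.REF)
        m, s = self.REF.perturbation_mean["TRBV2"], self.REF.perturbation_sd["TRBV2"]
        assert res.flags["TRBV2"] == "over3sd" and 99.0 > m + 2 * s

    def test_missing_reference_entry_is_error(self):
        with pytest.raises(ValidationError):
            sp.flag_overperturbed("p1", {"TRBV3": 5.0}, self.REF)


class TestSummaries:
    def test_all_normal_subject_is_100pct_normal(self):
        pc = sp.ProfileClass("normal", 8, 0.99, 0.2, 0.4)
        classifications = {"s1": {t: pc for t in TRBV_SUBGROUPS}}
        pert = {"s1": sp.PerturbationResult("s1", {}, 5.0, {}, 0, 23)}
        summ = sp.summarize_categories(classifications, pert, {"s1": "HC"})
        assert summ.pooled_proportions["HC"]["normal"] == 1.0
        assert summ.per_subject_fraction_nonnormal["s1"] == 0.0

    def test_group_median_of_global_perturbation(self):
        pc = sp.ProfileClass("normal", 8, 0.99, 0.2, 0.4)
        classifications = {s: {"TRBV2": pc} for s in ("a", "b")}
        pert = {
            "a": sp.PerturbationResult("a", {"TRBV2": 10.0}, 10.0, {}, 0, 1),
            "b": sp.PerturbationResult("b", {"TRBV2": 20.0}, 20.0, {}, 0, 1),
        }
        summ = sp.summarize_categories(classifications, pert, {"a": "HC", "b": "HC"})
        med, q1, q3 = summ.group_perturbation_median_iqr["HC"]
        assert med == pytest.approx(15.0)

    def test_trbv_usage_shares(self):
        areas = {"s1": {"TRBV2": 2.0, "TRBV3": 1.0, "TRBV4": 1.0}}
        tidy = sp.trbv_usage(areas)
        shares = dict(zip(tidy["trbv"], tidy["share"]))
        assert shares == pytest.approx({"TRBV2": 0.5, "TRBV3": 0.25, "TRBV4": 0.25})

    def test_trbv_usage_from_peak_table_sums_to_one(self, small_study):
        tidy = sp.trbv_usage(small_study.peak_table)
        per_sample = tidy.groupby("sample_id")["share"].sum()
        assert np.allclose(per_sample, 1.0)

    def test_flag_matrix_shape(self, small_study):
        from thymospec.pipeline import analyze_study

        res = analyze_study(small_study)
        fm = sp.flag_matrix(res.perturbations)
        assert fm.shape == (len(small_study.subjects) + 1, 24)
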