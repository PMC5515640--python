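"""Core allocation algorithm: similarity, probability averaging, modes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from qstratify import (
    NotComputableError,
    Phenotype,
    Protocol,
    QSTParameter,
    QSTProfile,
    allocate_cohort,
    allocate_deterministic,
    allocate_probabilistic,
    phenotype_probability,
    probability_vector,
    similarity,
)
from qstratify.allocator import (
    SIMPLIFIED_PARAMETERS,
    InvalidCentroidError,
    protocol_parameters,
)
from qstratify.profiles import PARAMETERS

from .conftest import make_table, profile_at

finite = st.floats(-5, 5, allow_nan=False)
positive = st.floats(0.1, 5, allow_nan=False)


class TestSimilarity:
    def test_is_100_at_the_centroid_mean(self):
        for mu, sigma in [(0.0, 1.0), (-1.3, 0.4), (2.7, 2.2)]:
            assert similarity(mu, mu, sigma) == 100.0

    def test_closed_form_at_one_and_two_sd(self):
        assert similarity(1.0, 0.0, 1.0) == pytest.approx(100 * math.exp(-0.5))
        assert similarity(2.0, 0.0, 1.0) == pytest.approx(100 * math.exp(-2.0))

    @given(z=finite, mu=finite, sigma=positive)
    @settings(derandomize=True, max_examples=200)
    def test_matches_normalized_density_definition(self, z, mu, sigma):
        """The exponential form equals density(z) / density(mu), as a percent."""
        oracle = 100.0 * norm.pdf(z, mu, sigma) / norm.pdf(mu, mu, sigma)
        got = similarity(z, mu, sigma)
        assert got == pytest.approx(oracle, rel=1e-12)

    @given(z=finite, mu=finite, sigma=positive)
    @settings(derandomize=True)
    def test_range_and_monotone_decay(self, z, mu, sigma):
        s = similarity(z, mu, sigma)
        assert 0 <= s <= 100
        # strict positivity holds up to float64 underflow of the exponential
        if (z - mu) ** 2 / (2 * sigma**2) < 700:
            assert s > 0
            farther = similarity(mu + abs(z - mu) + 0.5, mu, sigma)
            assert farther < s or (z == mu and farther < 100)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(InvalidCentroidError):
            similarity(0.0, 0.0, 0.0)
        with pytest.raises(InvalidCentroidError):
            similarity(0.0, 0.0, -1.0)


class TestPhenotypeProbability:
    def test_profile_at_centroid_scores_100(self, centroids):
        prof = profile_at(centroids, Phenotype.SL)
        p, n_used = phenotype_probability(prof, Phenotype.SL, centroids)
        assert p == pytest.approx(100.0)
        assert n_used == 13

    def test_missing_value_left_out_of_average(self, centroids):
        prof = profile_at(centroids, Phenotype.SL, skip=(QSTParameter.VDT,))
        p, n_used = phenotype_probability(prof, Phenotype.SL, centroids, min_params=1)
        assert p == pytest.approx(100.0)
        assert n_used == 12

    def test_uniform_one_sd_deviation_averages_to_one_term(self, centroids):
        prof = profile_at(centroids, Phenotype.TH, offset_sd=1.0)
        p, _ = phenotype_probability(prof, Phenotype.TH, centroids)
        assert p == pytest.approx(100 * math.exp(-0.5))

    def test_zero_profile_is_100_percent_healthy(self, centroids):
        prof = QSTProfile("s", {p: 0.0 for p in PARAMETERS if not p.is_coded})
        p, _ = phenotype_probability(prof, Phenotype.HEALTHY, centroids, min_params=1)
        assert p == pytest.approx(100.0)

    def test_too_few_parameters_not_computable(self, centroids):
        prof = QSTProfile("s", {QSTParameter.CDT: 0.0})
        with pytest.raises(NotComputableError):
            phenotype_probability(prof, Phenotype.SL, centroids)

    def test_simplified_requires_both_parameters(self, centroids):
        prof = QSTProfile("s", {QSTParameter.WDT: 0.0})
        with pytest.raises(NotComputableError):
            phenotype_probability(prof, Phenotype.SL, centroids, Protocol.SIMPLIFIED)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=30)
    def test_permutation_invariance(self, seed, centroids):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=13)
        order = rng.permutation(13)
        prof_a = QSTProfile("a", dict(zip(PARAMETERS, z)), validate=False)
        prof_b = QSTProfile(
            "b", {PARAMETERS[i]: z[i] for i in order}, validate=False
        )
        for pheno in Phenotype:
            pa, _ = phenotype_probability(prof_a, pheno, centroids)
            pb, _ = phenotype_probability(prof_b, pheno, centroids)
            assert pa == pb

    def test_removing_a_mean_similarity_parameter_is_neutral(self, centroids):
        """Dropping a parameter whose similarity equals the current mean
        leaves the averaged probability unchanged."""
        prof = profile_at(centroids, Phenotype.MH, offset_sd=1.0)
        p_full, _ = phenotype_probability(prof, Phenotype.MH, centroids)
        reduced = profile_at(
            centroids, Phenotype.MH, offset_sd=1.0, skip=(QSTParameter.PPT,)
        )
        p_red, _ = phenotype_probability(reduced, Phenotype.MH, centroids)
        assert p_red == pytest.approx(p_full)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=30)
    def test_simplified_equals_full_with_11_missing(self, seed, centroids):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=13)
        full_prof = QSTProfile("a", dict(zip(PARAMETERS, z)), validate=False)
        reduced_prof = QSTProfile(
            "a", {p: full_prof.z(p) for p in SIMPLIFIED_PARAMETERS}
        )
        for pheno in Phenotype:
            p_simpl, n_simpl = phenotype_probability(
                full_prof, pheno, centroids, Protocol.SIMPLIFIED
            )
            p_full, n_full = phenotype_probability(
                reduced_prof, pheno, centroids, Protocol.FULL, min_params=2
            )
            assert p_simpl == pytest.approx(p_full, rel=1e-15)
            assert n_simpl == n_full == 2


class TestDeterministicAllocation:
    def test_argmax_label(self, flat_table):
        prof = QSTProfile("s", {p: -2.0 for p in PARAMETERS}, validate=False)
        alloc = allocate_deterministic(prof, flat_table, include_healthy=False)
        assert alloc.label is Phenotype.SL
        assert not alloc.excluded and not alloc.tie_flag

    def test_tie_broken_toward_sl_and_flagged(self):
        # SL and TH centroids identical -> exact tie at any profile
        table = make_table({"SL": 1.0, "TH": 1.0, "MH": 8.0})
        prof = QSTProfile("s", {p: 1.0 for p in PARAMETERS}, validate=False)
        alloc = allocate_deterministic(prof, table, include_healthy=False)
        assert alloc.label is Phenotype.SL
        assert alloc.tie_flag

    def test_zero_profile_goes_healthy_when_included(self, centroids):
        prof = QSTProfile("s", {p: 0.0 for p in PARAMETERS if not p.is_coded})
        alloc = allocate_deterministic(prof, centroids, min_params=1)
        assert alloc.label is Phenotype.HEALTHY
        # no phenotype centroid is the zero vector, so healthy wins strictly
        pv = alloc.probabilities
        assert pv.p[Phenotype.HEALTHY] == pytest.approx(100.0)
        assert all(pv.p[m] < 100.0 for m in (Phenotype.SL, Phenotype.TH, Phenotype.MH))


class TestProbabilisticAllocation:
    def test_single_exceedance(self, flat_table):
        prof = QSTProfile("s", {p: -2.0 for p in PARAMETERS}, validate=False)
        alloc = allocate_probabilistic(prof, flat_table, cutoff=64.0)
        assert alloc.label_set == {Phenotype.SL}
        assert not alloc.excluded

    def test_healthy_only_exceedance_is_excluded(self):
        table = make_table({"SL": 6.0, "TH": -6.0, "MH": 8.0})
        prof = QSTProfile("s", {p: 0.0 for p in PARAMETERS}, validate=False)
        alloc = allocate_probabilistic(prof, table, cutoff=64.0)
        assert alloc.excluded
        assert alloc.healthy_flag
        assert alloc.label_set == frozenset()

    def test_no_exceedance_is_excluded(self):
        table = make_table({"SL": 6.0, "TH": -6.0, "MH": 8.0})
        prof = QSTProfile("s", {p: 3.0 for p in PARAMETERS}, validate=False)
        alloc = allocate_probabilistic(prof, table, cutoff=64.0)
        assert alloc.excluded and not alloc.healthy_flag

    def test_multi_membership_with_healthy_flag(self):
        # all centroids near the profile: everything exceeds the cutoff
        table = make_table({"SL": 0.1, "TH": -0.1, "MH": 0.2})
        prof = QSTProfile("s", {p: 0.0 for p in PARAMETERS}, validate=False)
        alloc = allocate_probabilistic(prof, table, cutoff=64.0)
        assert alloc.label_set == {Phenotype.SL, Phenotype.TH, Phenotype.MH}
        assert alloc.healthy_flag and not alloc.excluded

    def test_cutoff_is_strict(self):
        table = make_table({"SL": 0.0, "TH": -6.0, "MH": 8.0})
        prof = QSTProfile("s", {p: 0.0 for p in PARAMETERS}, validate=False)
        # P(SL) is exactly 100 > any cutoff; shrink: pick cutoff exactly at P(TH)?
        pv = probability_vector(prof, table)
        alloc = allocate_probabilistic(prof, table, cutoff=pv.p[Phenotype.SL] - 1e-9)
        assert Phenotype.SL in alloc.label_set
        alloc_eq = allocate_probabilistic(prof, table, cutoff=64.0)
        assert pv.p[Phenotype.MH] <= 64.0
        assert Phenotype.MH not in alloc_eq.label_set

    def test_rejects_degenerate_cutoff(self, centroids):
        prof = QSTProfile("s", {p: 0.0 for p in PARAMETERS if not p.is_coded})
        for cutoff in (0.0, 100.0, -3.0):
            with pytest.raises(ValueError):
                allocate_probabilistic(prof, centroids, cutoff=cutoff, min_params=1)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=50)
    def test_coherent_with_deterministic_argmax(self, seed, centroids):
        """If the deterministic winner clears the cutoff, the probabilistic
        label set contains it."""
        rng = np.random.default_rng(seed)
        prof = QSTProfile("s", dict(zip(PARAMETERS, rng.normal(0, 2, 13))),
                          validate=False)
        det = allocate_deterministic(prof, centroids, include_healthy=False)
        prob = allocate_probabilistic(prof, centroids, cutoff=64.0)
        if det.probabilities.p[det.label] > 64.0:
            assert det.label in prob.label_set


class TestCohortAllocation:
    def test_centroid_profiles_all_recovered(self, centroids):
        profiles = [
            profile_at(centroids, Phenotype.SL, subject_id=f"s{i}") for i in range(10)
        ]
        result = allocate_cohort(profiles, centroids)
        assert len(result.allocations) == 10
        assert all(a.label is Phenotype.SL for a in result.allocations)

    def test_empty_cohort_rejected(self, centroids):
        with pytest.raises(ValueError):
            allocate_cohort([], centroids)

    def test_invalid_subjects_reported_not_dropped(self, centroids):
        good = profile_at(centroids, Phenotype.TH, subject_id="good")
        bad = QSTProfile("bad", {QSTParameter.CDT: 0.0})
        result = allocate_cohort([good, bad], centroids)
        assert [a.subject_id for a in result.allocations] == ["good"]
        assert result.errors and result.errors[0][0] == "bad"

    def test_output_frame_has_contracted_columns(self, centroids):
        profiles = [profile_at(centroids, Phenotype.MH, subject_id="m0")]
        df = allocate_cohort(profiles, centroids, mode="probabilistic").frame()
        for col in ("subject_id", "p_SL", "p_TH", "p_MH", "p_healthy", "n_used",
                    "mode", "protocol", "cutoff", "label_set", "healthy_flag",
                    "excluded", "tie_flag"):
            assert col in df.columns

    def test_protocol_parameter_sets(self):
        assert protocol_parameters(Protocol.FULL) == PARAMETERS
        assert protocol_parameters(Protocol.SIMPLIFIED) == SIMPLIFIED_PARAMETERS
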