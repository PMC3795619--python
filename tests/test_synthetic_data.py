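"""Synthetic size-at-age and reader-matrix generators."""

import itertools

import numpy as np
import pytest

from raygrowth import (
    SPECIES_PRESETS,
    GrowthParams,
    SpeciesTemplate,
    data_poor_subsample,
    generate_full_design,
    generate_reader_matrix,
    generate_sample,
    iape,
    predict_size,
)


def _records_equal(a, b):
    return [(r.age, r.disc_width) for r in a] == [(r.age, r.disc_width) for r in b]


class TestGenerateSample:
    def test_same_seed_identical(self):
        tpl = SPECIES_PRESETS["H_uarnak"]
        assert _records_equal(generate_sample(tpl, seed=3), generate_sample(tpl, seed=3))

    def test_different_seed_differs(self):
        tpl = SPECIES_PRESETS["H_uarnak"]
        assert not _records_equal(generate_sample(tpl, seed=3), generate_sample(tpl, seed=4))

    def test_mean_size_matches_curve_at_large_n(self):
        tpl = SpeciesTemplate(
            "sim", w_inf=100, k=0.2, w0=20, age_min=1, age_max=20, n=10_000, noise_sd=3
        )
        recs = generate_sample(tpl, seed=12)
        near_10 = [r.disc_width for r in recs if abs(r.age - 10) <= 0.25]
        assert len(near_10) > 100
        expected = predict_size(GrowthParams("vbgf2", w_inf=100, k=0.2, w0=20), 10.0)
        assert abs(np.mean(near_10) - expected) < 1.0

    def test_count_support_and_grid(self):
        recs = generate_sample(SPECIES_PRESETS["H_uarnak"], seed=0)
        assert len(recs) == 19
        assert all(0 < r.disc_width < 200 for r in recs)
        assert all(1.0 <= r.age <= 25.0 for r in recs)
        # half-year age grid
        assert all(float(2 * r.age).is_integer() for r in recs)

    def test_proportional_noise_mode(self):
        tpl = SpeciesTemplate(
            "sim", w_inf=100, k=0.2, w0=20, age_min=1, age_max=20, n=5000, noise_cv=0.05
        )
        recs = generate_sample(tpl, seed=1)
        assert all(r.disc_width > 0 for r in recs)


class TestFullDesign:
    def test_flat_age_histogram(self):
        tpl = SPECIES_PRESETS["H_uarnak"]
        recs = generate_full_design(20, 10, tpl, seed=5)
        assert len(recs) == 200
        ages, counts = np.unique([r.age for r in recs], return_counts=True)
        assert list(ages) == [float(a) for a in range(1, 21)]
        assert all(c == 10 for c in counts)

    def test_minimal_design(self):
        recs = generate_full_design(2, 1, SPECIES_PRESETS["T_lymma"], seed=5)
        assert len(recs) == 2

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            generate_full_design(1, 10, SPECIES_PRESETS["T_lymma"], seed=5)


class TestDataPoorSubsample:
    @pytest.fixture
    def full(self):
        return generate_full_design(20, 10, SPECIES_PRESETS["H_uarnak"], seed=8)

    def test_full_random_sample_is_whole_set(self, full):
        sub = data_poor_subsample(full, "random_n", len(full), seed=1)
        assert sorted((r.age, r.disc_width) for r in sub) == sorted(
            (r.age, r.disc_width) for r in full
        )

    def test_truncate_old_removes_oldest_third(self, full):
        sub = data_poor_subsample(full, "truncate_old", 30, seed=1)
        assert len(sub) == 30
        assert max(r.age for r in sub) <= 13

    def test_truncate_young_removes_youngest_third(self, full):
        sub = data_poor_subsample(full, "truncate_young", 30, seed=1)
        assert min(r.age for r in sub) >= 8

    def test_seeded_reproducibility(self, full):
        a = data_poor_subsample(full, "random_n", 15, seed=2)
        b = data_poor_subsample(full, "random_n", 15, seed=2)
        assert _records_equal(a, b)

    def test_oversized_request_rejected(self, full):
        with pytest.raises(ValueError):
            data_poor_subsample(full, "random_n", 201, seed=0)


class TestReaderMatrixGenerator:
    def test_zero_error_reads_equal_truth(self):
        truth = [2.0, 5.0, 9.0, 14.0]
        m = generate_reader_matrix(truth, epsilon=0.0, seed=0)
        assert np.array_equal(m.reads, np.array(truth)[:, None] * np.ones((1, 3)))
        assert iape(m) == 0.0

    def test_iape_matches_enumeration_oracle(self):
        """Observed IAPE at epsilon=0.2 agrees with the closed-form
        expectation obtained by enumerating all 27 reader-outcome patterns
        per animal (each reader: -1, 0, +1 with probs eps/2, 1-eps, eps/2)."""
        eps = 0.2
        rng = np.random.default_rng(77)
        truth = rng.integers(2, 21, size=10_000).astype(float)

        probs = {-1.0: eps / 2, 0.0: 1 - eps, 1.0: eps / 2}
        expected_by_age = {}
        for t in np.unique(truth):
            e = 0.0
            for deltas in itertools.product((-1.0, 0.0, 1.0), repeat=3):
                p = np.prod([probs[d] for d in deltas])
                reads = np.maximum(t + np.array(deltas), 0.0)
                mean = reads.mean()
                e += p * (100.0 / 3) * np.sum(np.abs(reads - mean)) / mean
            expected_by_age[t] = e
        expected = np.mean([expected_by_age[t] for t in truth])

        m = generate_reader_matrix(truth, epsilon=eps, seed=99)
        assert iape(m) == pytest.approx(expected, rel=0.05)

    def test_readability_proportions(self):
        m = generate_reader_matrix(np.full(10_000, 5.0), epsilon=0.1, seed=3)
        share = np.array([(m.readability == s).mean() for s in (1, 2, 3)])
        target = np.array([50, 75, 45]) / 170
        assert np.all(np.abs(share - target) < 0.02)

    def test_invalid_epsilon(self):
        with pytest.raises(ValueError):
            generate_reader_matrix([5.0], epsilon=1.0)


def test_template_validation():
    with pytest.raises(ValueError):
        SpeciesTemplate("x", w_inf=100, k=0.2, w0=20, age_min=5, age_max=4, n=10)
    with pytest.raises(ValueError):
        SpeciesTemplate("x", w_inf=100, k=0.2, w0=20, age_min=1, age_max=10, n=0)
    with pytest.raises(ValueError):
        SpeciesTemplate("x", w_inf=100, k=0.2, w0=20, age_min=1, age_max=10, n=5, noise_sd=-1)
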