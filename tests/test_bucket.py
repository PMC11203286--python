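"""Bucket geometry, positive-part integration, and 0-100 normalization."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from floranmr import (
    BucketSpec,
    MetaboliteSignature,
    Resonance,
    Spectrum,
    build_table,
    bucket_spectrum,
    make_buckets,
    normalize_buckets,
    render_spectrum,
)


def enumerate_retained_buckets(spec: BucketSpec) -> int:
    """Brute-force oracle: count buckets by exact rational interval overlap."""
    lo = Fraction(spec.range_low).limit_denominator(10**6)
    w = Fraction(spec.width).limit_denominator(10**6)
    n = int((Fraction(spec.range_high).limit_denominator(10**6) - lo) / w)
    exclusions = [
        (Fraction(a).limit_denominator(10**6), Fraction(b).limit_denominator(10**6))
        for a, b in spec.exclusions
    ]
    kept = 0
    for i in range(n):
        b_lo, b_hi = lo + i * w, lo + (i + 1) * w
        if not any(b_lo < e_hi and b_hi > e_lo for e_lo, e_hi in exclusions):
            kept += 1
    return kept


class TestMakeBuckets:
    def test_default_spec_retains_1040_buckets(self):
        spec = BucketSpec()
        buckets = make_buckets(spec)
        assert len(buckets) == enumerate_retained_buckets(spec) == 1040

    def test_no_exclusions_simple_arithmetic(self):
        buckets = make_buckets(BucketSpec(range_low=1.0, range_high=2.0, exclusions=()))
        assert len(buckets) == 100
        assert buckets[0][0] == pytest.approx(1.0)
        assert buckets[-1][1] == pytest.approx(2.0)

    def test_exclusion_covering_everything_drops_all(self):
        spec = BucketSpec(range_low=1.0, range_high=2.0, exclusions=((0.0, 3.0),))
        assert make_buckets(spec) == []

    def test_edges_contiguous_and_ascending_outside_exclusions(self):
        buckets = make_buckets(BucketSpec())
        los = [b[0] for b in buckets]
        assert los == sorted(los)
        for (_, hi), (lo, _) in zip(buckets, buckets[1:]):
            assert lo >= hi - 1e-9  # never overlapping

    def test_no_retained_bucket_touches_an_exclusion(self):
        spec = BucketSpec()
        for lo, hi in make_buckets(spec):
            for a, b in spec.exclusions:
                assert hi <= a + 1e-9 or lo >= b - 1e-9

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            BucketSpec(range_low=2.0, range_high=1.0)
        with pytest.raises(ValueError):
            BucketSpec(width=-0.01)
        with pytest.raises(ValueError, match="integer"):
            BucketSpec(range_low=1.0, range_high=1.005, width=0.01)


class TestBucketSpectrum:
    def test_all_negative_spectrum_gives_zero_vector(self):
        ppm = np.linspace(12.5, -0.5, 8192)
        s = Spectrum(ppm=ppm, intensity=-np.ones(8192))
        assert np.all(bucket_spectrum(s, BucketSpec()) == 0.0)

    def test_unit_area_lorentzian_lands_in_one_bucket(self):
        # area-1 Lorentzian: height 1/(pi*gamma), narrow vs 0.01 ppm bucket
        ppm = np.linspace(12.5, -0.5, 2**18)
        gamma = 2e-4
        center = 5.555  # mid-bucket
        y = (gamma / np.pi) / ((ppm - center) ** 2 + gamma**2)
        s = Spectrum(ppm=ppm, intensity=y)
        vec = bucket_spectrum(s, BucketSpec())
        buckets = make_buckets(BucketSpec())
        target = next(i for i, (lo, hi) in enumerate(buckets) if lo <= center < hi)
        assert vec[target] == pytest.approx(1.0, abs=0.05)
        others = np.delete(vec, target)
        assert others.max() < 0.01

    def test_matches_per_point_linear_search_oracle(self):
        rng = np.random.default_rng(0)
        ppm = np.linspace(12.5, -0.5, 4096)
        y = rng.normal(0.0, 1.0, size=4096)
        s = Spectrum(ppm=ppm, intensity=y)
        spec = BucketSpec()
        vec = bucket_spectrum(s, spec)
        buckets = make_buckets(spec)
        asc_ppm, asc_y = s.ascending()
        step = np.abs(np.gradient(asc_ppm))
        oracle = np.zeros(len(buckets))
        for p, v, st_ in zip(asc_ppm, asc_y, step):
            for k, (lo, hi) in enumerate(buckets):  # linear search per point
                if lo <= p < hi:
                    oracle[k] += max(v, 0.0) * st_
                    break
        assert np.allclose(vec, oracle, atol=1e-12)

    def test_intensity_doubling_doubles_buckets(self, library, clean_params):
        s = render_spectrum(library, {"Sucrose": 1.0}, clean_params, seed=0)
        doubled = Spectrum(ppm=s.ppm, intensity=2 * s.intensity, meta=dict(s.meta))
        v1 = bucket_spectrum(s, BucketSpec())
        v2 = bucket_spectrum(doubled, BucketSpec())
        assert np.allclose(v2, 2 * v1, rtol=1e-12)

    def test_axis_not_covering_range_raises(self):
        ppm = np.linspace(8.0, 2.0, 1024)
        s = Spectrum(ppm=ppm, intensity=np.zeros(1024))
        with pytest.raises(ValueError, match="cover"):
            bucket_spectrum(s, BucketSpec())


class TestNormalizeBuckets:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0, 0, 0, 10], [0, 0, 0, 100]),  # single above-mean value
            ([5, 5, 5, 5], [0, 0, 0, 0]),  # equal to mean is "below"
            ([0, 0, 0, 0], [0, 0, 0, 0]),  # all-zero passthrough
        ],
    )
    def test_worked_examples(self, raw, expected):
        assert normalize_buckets(np.array(raw, dtype=float)).tolist() == expected

    def test_linear_binning_between_min_and_max_above_mean(self):
        raw = np.array([0.0, 0.0, 10.0, 55.0, 100.0])
        out = normalize_buckets(raw)
        # above-mean values 55 and 100 -> 1 and 100
        assert out.tolist() == [0, 0, 0, 1, 100]

    @given(
        st.lists(st.floats(0.0, 1e6, allow_nan=False), min_size=2, max_size=50).filter(
            lambda v: max(v) > sum(v) / len(v)
        )
    )
    def test_max_is_exactly_100_whenever_anything_is_above_mean(self, vals):
        out = normalize_buckets(np.array(vals))
        assert out.max() == 100
        assert out.min() >= 0

    @given(
        st.lists(st.floats(0.0, 1e3), min_size=2, max_size=30),
        st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, vals, c):
        raw = np.array(vals)
        assert np.array_equal(normalize_buckets(raw), normalize_buckets(c * raw))

    def test_below_mean_entries_always_zero(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            raw = rng.gamma(0.5, 2.0, size=40)
            out = normalize_buckets(raw)
            assert np.all(out[raw <= raw.mean()] == 0)
            assert np.all(out[raw > raw.mean()] >= 1)

    def test_negative_and_non_finite_rejected(self):
        with pytest.raises(ValueError):
            normalize_buckets(np.array([1.0, -0.1]))
        with pytest.raises(ValueError):
            normalize_buckets(np.array([1.0, np.inf]))


class TestBuildTable:
    def test_fixture_cohort_shape_is_33_by_1040(self, design, library):
        from floranmr import SpectrumParams, generate_cohort

        spectra = generate_cohort(design, library, SpectrumParams(), seed=42)
        table = build_table(spectra, BucketSpec(), normalize=True)
        assert table.values.shape == (33, 1040)
        assert table.values.min() >= 0 and table.values.max() <= 100
        assert table.values.dtype == np.int64

    def test_empty_input_gives_empty_table_with_edges(self):
        table = build_table([], BucketSpec(), normalize=True)
        assert table.values.shape == (0, 1040)
        assert len(table.bucket_edges) == 1040

    def test_permuting_spectra_permutes_rows(self, library, clean_params):
        spectra = [
            render_spectrum(library, {"Sucrose": c}, clean_params, seed=0, meta={"sample_id": f"s{c}"})
            for c in (1.0, 2.0, 3.0)
        ]
        spec = BucketSpec()
        fwd = build_table(spectra, spec)
        rev = build_table(spectra[::-1], spec)
        assert rev.sample_ids == fwd.sample_ids[::-1]
        assert np.array_equal(rev.values, fwd.values[::-1])

    def test_errors_carry_sample_context(self):
        ppm = np.linspace(8.0, 2.0, 256)
        bad = Spectrum(ppm=ppm, intensity=np.zeros(256), meta={"sample_id": "broken-one"})
        with pytest.raises(ValueError, match="broken-one"):
            build_table([bad], BucketSpec())
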