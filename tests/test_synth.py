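"""Spectral simulation: multiplet expansion, rendering, cohort generation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.signal import argrelmax

from floranmr import (
    CohortDesign,
    CohortEntry,
    MetaboliteSignature,
    Resonance,
    SpectrumParams,
    VariantEdit,
    generate_cohort,
    multiplet_pattern,
    render_spectrum,
    sample_seeds,
)


class TestMultipletPattern:
    @pytest.mark.parametrize(
        "mult,j,expected",
        [
            # singlet by definition
            ("s", [], [(0.0, 1.0)]),
            # alanine doublet: separation J/field = 7.2/400 = 0.018 ppm
            ("d", [7.2], [(-0.009, 0.5), (0.009, 0.5)]),
            # isoleucine triplet: lines spaced 2.3/400 = 0.00575 ppm, 1:2:1
            ("t", [2.3], [(-0.00575, 0.25), (0.0, 0.5), (0.00575, 0.25)]),
            # kaempferol dd: lines at (+-2.0 +- 2.1)/800 ppm, equal weights
            (
                "dd",
                [2.0, 2.1],
                [(-0.005125, 0.25), (-0.000125, 0.25), (0.000125, 0.25), (0.005125, 0.25)],
            ),
        ],
    )
    def test_patterns_match_coupling_arithmetic(self, mult, j, expected):
        lines = multiplet_pattern(mult, j, 400.0)
        assert len(lines) == len(expected)
        for (off, w), (eoff, ew) in zip(lines, expected):
            assert off == pytest.approx(eoff, abs=1e-12)
            assert w == pytest.approx(ew, abs=1e-12)

    def test_unresolved_multiplet_is_a_flat_centered_cluster(self):
        lines = multiplet_pattern("m", [], 400.0)
        offs = [o for o, _ in lines]
        assert len(lines) == 5
        assert offs == sorted(offs)
        assert max(offs) == -min(offs) == 0.015

    @given(
        mult=st.sampled_from(["s", "d", "dd", "t", "m"]),
        j=st.lists(st.floats(0.5, 15.0), min_size=2, max_size=2),
        field=st.floats(200.0, 900.0),
    )
    def test_weights_sum_to_one_and_offsets_symmetric(self, mult, j, field):
        need = {"s": 0, "d": 1, "dd": 2, "t": 1, "m": 0}[mult]
        lines = multiplet_pattern(mult, j[:need], field)
        assert sum(w for _, w in lines) == pytest.approx(1.0, abs=1e-12)
        offs = np.array([o for o, _ in lines])
        assert np.allclose(offs, -offs[::-1], atol=1e-12)

    @pytest.mark.parametrize("mult,j", [("d", []), ("s", [1.0]), ("dd", [2.0]), ("t", [1.0, 2.0])])
    def test_inconsistent_j_count_raises(self, mult, j):
        with pytest.raises(ValueError, match="J value"):
            multiplet_pattern(mult, j, 400.0)

    def test_resonance_validation_names_the_problem(self):
        with pytest.raises(ValueError, match="requires 1 J value"):
            Resonance(center=1.0, multiplicity="d", j_values=())
        with pytest.raises(ValueError, match="outside"):
            Resonance(center=20.0, multiplicity="s")


class TestRenderSpectrum:
    def test_no_metabolites_no_noise_is_flat_zero(self, library, clean_params):
        s = render_spectrum(library, {}, clean_params, seed=0)
        assert np.all(s.intensity == 0.0)

    def test_identical_seed_gives_bit_identical_output(self, library):
        params = SpectrumParams()
        conc = {"Sucrose": 1.0, "Alanine": 0.5}
        a = render_spectrum(library, conc, params, seed=7)
        b = render_spectrum(library, conc, params, seed=7)
        assert np.array_equal(a.intensity, b.intensity)
        assert np.array_equal(a.ppm, b.ppm)

    def test_sucrose_doublet_gives_two_maxima_near_5_41(self, library, clean_params):
        s = render_spectrum(library, {"Sucrose": 1.0}, clean_params, seed=0)
        ppm, y = s.ascending()
        sel = (ppm >= 5.3) & (ppm <= 5.5)
        (maxima,) = argrelmax(y[sel])
        assert len(maxima) == 2

    def test_unknown_metabolite_is_reported_by_name(self, library, clean_params):
        with pytest.raises(ValueError, match="Nectarine"):
            render_spectrum(library, {"Nectarine": 1.0}, clean_params, seed=0)

    def test_doubling_concentration_doubles_signal(self, library, clean_params):
        conc = {m.name: 0.7 for m in library}
        one = render_spectrum(library, conc, clean_params, seed=0)
        two = render_spectrum(library, {k: 2 * v for k, v in conc.items()}, clean_params, seed=0)
        assert np.allclose(two.intensity, 2 * one.intensity, rtol=1e-12, atol=1e-14)

    @pytest.mark.parametrize("j", [3.6, 7.2, 12.0])
    def test_doublet_midpoint_recovers_center_within_one_step(self, j, clean_params):
        lib = [MetaboliteSignature("X", (Resonance(4.0, "d", (j,)),))]
        s = render_spectrum(lib, {"X": 1.0}, clean_params, seed=0)
        ppm, y = s.ascending()
        (maxima,) = argrelmax(y)
        top2 = maxima[np.argsort(y[maxima])[-2:]]
        step = ppm[1] - ppm[0]
        assert np.mean(ppm[top2]) == pytest.approx(4.0, abs=step)

    def test_axis_is_stored_decreasing(self, library, clean_params):
        s = render_spectrum(library, {}, clean_params, seed=0)
        assert np.all(np.diff(s.ppm) < 0)


class TestGenerateCohort:
    def test_fixture_cohort_has_matching_roster_metadata(self, design, library):
        spectra = generate_cohort(design, library, SpectrumParams(), seed=42)
        assert len(spectra) == 33
        assert [s.meta["sample_id"] for s in spectra] == [
            e.sample_id for e in design.entries
        ]
        species = {s.meta["species_label"] for s in spectra}
        assert len(species) == 23

    def test_zero_cv_zero_noise_same_profile_identical(self, library, clean_params):
        profile = {"Sucrose": 1.0, "Alanine": 2.0}
        entries = [
            CohortEntry("a", "Rosa", concentration_profile=profile),
            CohortEntry("b", "Rosa", concentration_profile=profile),
        ]
        design = CohortDesign(entries=tuple(entries), cv=0.0)
        sa, sb = generate_cohort(design, library, clean_params, seed=5)
        assert np.array_equal(sa.intensity, sb.intensity)

    def test_per_sample_seeds_are_stable_and_order_free(self, library):
        # regenerating a single sample reproduces its spectrum exactly
        profile = {"Sucrose": 1.0}
        e1 = CohortEntry("s1", "A", concentration_profile=profile)
        e2 = CohortEntry("s2", "B", concentration_profile=profile)
        both = generate_cohort(
            CohortDesign(entries=(e1, e2), cv=0.2), library, SpectrumParams(), seed=9
        )
        alone = generate_cohort(
            CohortDesign(entries=(e2,), cv=0.2), library, SpectrumParams(), seed=9
        )
        assert np.array_equal(both[1].intensity, alone[0].intensity)
        assert sample_seeds(9, "s1") != sample_seeds(9, "s2")

    def test_deleting_a_resonance_changes_only_its_footprint(self, library, clean_params):
        profile = {m.name: 1.0 for m in library}
        base = CohortEntry("plain", "Sp", variant_label="", concentration_profile=profile)
        edited = CohortEntry("edited", "Sp", variant_label="cut", concentration_profile=profile)
        design = CohortDesign(
            entries=(base, edited),
            cv=0.0,
            variant_edits={
                ("Sp", "cut"): (VariantEdit(action="delete", metabolite="Kaempferol", center=6.44),)
            },
        )
        sa, sb = generate_cohort(design, library, clean_params, seed=0)
        diff = np.abs(sa.intensity - sb.intensity)
        ppm = sa.ppm
        inside = np.abs(ppm - 6.44) < 0.05
        assert diff[inside].max() > 0.1
        # outside the deleted multiplet only Lorentzian tails remain
        assert diff[~inside].max() < 5e-3

    def test_duplicate_sample_ids_rejected(self, library):
        with pytest.raises(ValueError, match="duplicate"):
            CohortDesign(
                entries=(
                    CohortEntry("x", "A", concentration_profile={}),
                    CohortEntry("x", "B", concentration_profile={}),
                )
            )

    def test_profile_naming_unknown_metabolite_rejected(self, library):
        design = CohortDesign(
            entries=(CohortEntry("x", "A", concentration_profile={"Unobtainium": 1.0}),)
        )
        with pytest.raises(ValueError, match="Unobtainium"):
            design.validate_against(library)
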