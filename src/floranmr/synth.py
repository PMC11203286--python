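"""Synthetic 1H-NMR spectrum and cohort generation.

Spectra are built directly in the frequency domain: each metabolite
resonance is expanded into its multiplet lines from the scalar coupling
constants (line spacing J / field in ppm), every line is rendered as a
Lorentzian of fixed linewidth, and the weighted sum over the signature
library plus residual solvent peaks and i.i.d. Gaussian noise gives the
spectrum.  No free-induction decay, Fourier transform or phase error is
modelled: generated spectra are absorption-mode by construction.

Cohorts emulate a multi-species flower survey: each species carries a
concentration profile over the signature library, within-species
replicates jitter those concentrations lognormally (coefficient of
variation ``cv``), and flower color variants are expressed as explicit
edits (delete / scale / add a resonance) applied before rendering.

Randomness is fully seeded.  A cohort uses a splittable scheme: the
master seed and the CRC-32 of the sample id feed a ``numpy``
``SeedSequence``, which yields one stream for concentration jitter and
one for spectral noise, so any single sample can be regenerated without
rendering the rest of the cohort.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Resonance",
    "MetaboliteSignature",
    "SpectrumParams",
    "CohortEntry",
    "VariantEdit",
    "CohortDesign",
    "Spectrum",
    "multiplet_pattern",
    "render_spectrum",
    "generate_cohort",
    "sample_seeds",
]

#: multiplicity code -> required number of coupling constants
MULTIPLICITY_J_COUNT = {"s": 0, "d": 1, "dd": 2, "t": 1, "m": 0}

# Unresolved multiplets ('m', no J reported) render as a flat cluster of
# equally weighted lines spanning this many ppm, centred on delta.
M_SPAN_PPM = 0.03
M_LINES = 5


@dataclass(frozen=True)
class Resonance:
    """A single resonance of a metabolite: position, splitting, weight."""

    center: float
    multiplicity: str
    j_values: tuple[float, ...] = ()
    rel_intensity: float = 1.0
    assignment: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "j_values", tuple(float(j) for j in self.j_values))
        if self.multiplicity not in MULTIPLICITY_J_COUNT:
            raise ValueError(
                f"unknown multiplicity {self.multiplicity!r} at {self.center} ppm "
                f"(expected one of {sorted(MULTIPLICITY_J_COUNT)})"
            )
        want = MULTIPLICITY_J_COUNT[self.multiplicity]
        if len(self.j_values) != want:
            raise ValueError(
                f"resonance at {self.center} ppm: multiplicity "
                f"{self.multiplicity!r} requires {want} J value(s), "
                f"got {len(self.j_values)}"
            )
        if not -1.0 <= self.center <= 13.0:
            raise ValueError(f"resonance center {self.center} ppm outside [-1, 13]")
        if not self.rel_intensity > 0:
            raise ValueError(f"rel_intensity must be > 0, got {self.rel_intensity}")


@dataclass(frozen=True)
class MetaboliteSignature:
    """A named metabolite with its set of library resonances."""

    name: str
    resonances: tuple[Resonance, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "resonances", tuple(self.resonances))
        if not self.resonances:
            raise ValueError(f"signature {self.name!r} has no resonances")
        centers = sorted(r.center for r in self.resonances)
        for a, b in zip(centers, centers[1:]):
            if b - a < 0.001:
                raise ValueError(
                    f"signature {self.name!r}: resonance centers {a} and {b} "
                    "coincide within 0.001 ppm"
                )


@dataclass(frozen=True)
class SpectrumParams:
    """Acquisition-like parameters of the simulated spectrometer.

    ``noise_sigma`` is expressed relative to the peak height of a
    unit-amount singlet (the Lorentzian lineshape is normalised to unit
    apex height).  ``solvent_peaks`` are (ppm, amplitude) residuals; the
    defaults place water (4.87) and methanol (3.31) inside the solvent
    exclusion windows and the TMS/TSP reference singlet at 0.0 ppm.
    """

    field_mhz: float = 400.0
    n_points: int = 32768
    ppm_min: float = -0.5
    ppm_max: float = 12.5
    linewidth_hz: float = 1.5
    noise_sigma: float = 0.002
    solvent_peaks: tuple[tuple[float, float], ...] = (
        (4.87, 5.0),
        (3.31, 5.0),
        (0.0, 2.0),
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "solvent_peaks",
            tuple((float(p), float(a)) for p, a in self.solvent_peaks),
        )
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not self.ppm_min < self.ppm_max:
            raise ValueError("ppm_min must be < ppm_max")
        if not self.linewidth_hz > 0:
            raise ValueError("linewidth_hz must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.field_mhz <= 0:
            raise ValueError("field_mhz must be > 0")


@dataclass(frozen=True)
class CohortEntry:
    """One planned sample: identity labels plus its mean concentrations."""

    sample_id: str
    species_label: str
    variant_label: str = ""
    extraction: str = "methanol"
    concentration_profile: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class VariantEdit:
    """A color-variant spectral edit applied before rendering.

    action 'delete': remove the resonance of ``metabolite`` nearest
    ``center`` (presence/absence differences between variants).
    action 'scale': multiply the metabolite's concentration by ``factor``
    (whole signature, ``center`` is None) or scale one resonance's weight.
    action 'add': render ``resonance`` as an extra variant-specific signal
    with amount ``factor``.
    """

    action: str
    metabolite: str = ""
    center: float | None = None
    factor: float = 1.0
    resonance: Resonance | None = None

    def __post_init__(self) -> None:
        if self.action not in ("delete", "scale", "add"):
            raise ValueError(f"unknown variant edit action {self.action!r}")
        if self.action == "add" and self.resonance is None:
            raise ValueError("'add' edit requires a resonance")
        if self.action == "delete" and self.center is None:
            raise ValueError("'delete' edit requires a resonance center")


@dataclass(frozen=True)
class CohortDesign:
    """Sampling plan: roster entries, replicate jitter, variant edits."""

    entries: tuple[CohortEntry, ...]
    cv: float = 0.1
    variant_edits: Mapping[tuple[str, str], tuple[VariantEdit, ...]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        ids = [e.sample_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")

    def validate_against(self, library: Sequence[MetaboliteSignature]) -> None:
        names = {s.name for s in library}
        for e in self.entries:
            unknown = sorted(set(e.concentration_profile) - names)
            if unknown:
                raise ValueError(
                    f"sample {e.sample_id!r}: profile names metabolites not in "
                    f"the library: {unknown}"
                )


@dataclass
class Spectrum:
    """A 1H-NMR spectrum: ppm axis (stored decreasing), intensities, metadata."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        d = np.diff(self.ppm)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if len(d) and d[0] > 0:  # normalise to NMR display convention
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        fm = self.meta.get("field_mhz")
        if fm is not None and not float(fm) > 0:
            raise ValueError("field_mhz must be > 0")

    def ascending(self) -> tuple[np.ndarray, np.ndarray]:
        """(ppm, intensity) views in ascending-ppm order."""
        return self.ppm[::-1], self.intensity[::-1]


def multiplet_pattern(
    multiplicity: str,
    j_values: Sequence[float],
    field_mhz: float,
    name: str = "",
) -> list[tuple[float, float]]:
    """Expand a multiplicity code into (ppm offset, weight) lines.

    Offsets are symmetric about zero and weights sum to one: a doublet is
    two half-weight lines J/field apart, a triplet three lines spaced
    J/field with 1:2:1 weights, a doublet of doublets four quarter-weight
    lines at (+-J1 +- J2)/(2 field), and an unresolved multiplet an
    evenly weighted cluster spanning ``M_SPAN_PPM``.
    """
    j_values = tuple(float(j) for j in j_values)
    want = MULTIPLICITY_J_COUNT.get(multiplicity)
    if want is None:
        raise ValueError(f"unknown multiplicity {multiplicity!r}" + (f" ({name})" if name else ""))
    if len(j_values) != want:
        raise ValueError(
            f"multiplicity {multiplicity!r} requires {want} J value(s), got "
            f"{len(j_values)}" + (f" ({name})" if name else "")
        )
    if multiplicity == "s":
        return [(0.0, 1.0)]
    if multiplicity == "d":
        half = j_values[0] / field_mhz / 2.0
        return [(-half, 0.5), (half, 0.5)]
    if multiplicity == "t":
        step = j_values[0] / field_mhz
        return [(-step, 0.25), (0.0, 0.5), (step, 0.25)]
    if multiplicity == "dd":
        j1, j2 = j_values
        offs = sorted(
            (s1 * j1 + s2 * j2) / (2.0 * field_mhz) for s1 in (-1, 1) for s2 in (-1, 1)
        )
        return [(o, 0.25) for o in offs]
    # 'm': unresolved envelope
    offs = np.linspace(-M_SPAN_PPM / 2.0, M_SPAN_PPM / 2.0, M_LINES)
    return [(float(o), 1.0 / M_LINES) for o in offs]


def _lorentzian(ppm: np.ndarray, center: float, gamma: float) -> np.ndarray:
    """Unit-apex-height Lorentzian with half width at half maximum ``gamma``."""
    return gamma * gamma / ((ppm - center) ** 2 + gamma * gamma)


def render_spectrum(
    library: Sequence[MetaboliteSignature],
    concentrations: Mapping[str, float],
    params: SpectrumParams,
    seed: int,
    meta: Mapping[str, object] | None = None,
) -> Spectrum:
    """Render one spectrum from library signatures at given amounts.

    Intensity is the sum over metabolites, resonances and multiplet lines
    of ``amount * rel_intensity * weight`` unit-height Lorentzians, plus
    solvent residuals and Gaussian noise.  Identical arguments give
    bit-identical output.
    """
    names = {s.name for s in library}
    unknown = sorted(set(concentrations) - names)
    if unknown:
        raise ValueError(f"concentrations name unknown metabolites: {unknown}")

    ppm = np.linspace(params.ppm_max, params.ppm_min, params.n_points)
    y = np.zeros_like(ppm)
    gamma = params.linewidth_hz / params.field_mhz / 2.0  # HWHM in ppm

    for sig in library:
        amount = float(concentrations.get(sig.name, 0.0))
        if amount == 0.0:
            continue
        for res in sig.resonances:
            lines = multiplet_pattern(
                res.multiplicity, res.j_values, params.field_mhz, name=sig.name
            )
            for off, w in lines:
                y += (amount * res.rel_intensity * w) * _lorentzian(
                    ppm, res.center + off, gamma
                )

    for center, amp in params.solvent_peaks:
        y += amp * _lorentzian(ppm, center, gamma)

    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, params.noise_sigma, size=y.shape)

    full_meta = {"field_mhz": params.field_mhz}
    if meta:
        full_meta.update(meta)
    return Spectrum(ppm=ppm, intensity=y, meta=full_meta)


def sample_seeds(master_seed: int, sample_id: str) -> tuple[int, int]:
    """Deterministic (jitter_seed, noise_seed) for one cohort sample.

    Splittable scheme: ``SeedSequence([master_seed, crc32(sample_id)])``
    expanded to two 31-bit integers, so a sample's randomness depends
    only on the master seed and its own id.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(sample_id.encode("utf-8"))])
    a, b = (int(s) & 0x7FFFFFFF for s in ss.generate_state(2))
    return a, b


def _apply_edits(
    library: Sequence[MetaboliteSignature],
    concentrations: dict[str, float],
    edits: Sequence[VariantEdit],
) -> tuple[list[MetaboliteSignature], dict[str, float]]:
    sigs = {s.name: s for s in library}
    conc = dict(concentrations)
    extras: list[tuple[MetaboliteSignature, float]] = []
    for k, edit in enumerate(edits):
        if edit.action == "add":
            name = f"__variant_extra_{k}"
            extras.append(
                (MetaboliteSignature(name=name, resonances=(edit.resonance,)), edit.factor)
            )
            continue
        if edit.metabolite not in sigs:
            raise ValueError(f"variant edit names unknown metabolite {edit.metabolite!r}")
        sig = sigs[edit.metabolite]
        if edit.action == "delete":
            nearest = min(sig.resonances, key=lambda r: abs(r.center - edit.center))
            if abs(nearest.center - edit.center) > 0.005:
                raise ValueError(
                    f"no resonance of {edit.metabolite!r} near {edit.center} ppm to delete"
                )
            remaining = tuple(r for r in sig.resonances if r is not nearest)
            if remaining:
                sigs[edit.metabolite] = replace(sig, resonances=remaining)
            else:
                conc[edit.metabolite] = 0.0
        elif edit.action == "scale":
            if edit.center is None:
                conc[edit.metabolite] = conc.get(edit.metabolite, 0.0) * edit.factor
            else:
                nearest = min(sig.resonances, key=lambda r: abs(r.center - edit.center))
                if abs(nearest.center - edit.center) > 0.005:
                    raise ValueError(
                        f"no resonance of {edit.metabolite!r} near {edit.center} ppm to scale"
                    )
                new = tuple(
                    replace(r, rel_intensity=r.rel_intensity * edit.factor)
                    if r is nearest
                    else r
                    for r in sig.resonances
                )
                sigs[edit.metabolite] = replace(sig, resonances=new)

    out_lib = list(sigs.values())
    for sig, amount in extras:
        out_lib.append(sig)
        conc[sig.name] = amount
    return out_lib, conc


def generate_cohort(
    design: CohortDesign,
    library: Sequence[MetaboliteSignature],
    params: SpectrumParams,
    seed: int,
) -> list[Spectrum]:
    """Render one spectrum per design entry.

    Within-species concentrations are drawn lognormally around the
    species profile with coefficient of variation ``design.cv`` (the
    lognormal is mean-preserving, and cv = 0 reproduces the profile
    exactly); variant edits are applied before rendering; per-sample
    seeds come from :func:`sample_seeds`.
    """
    design.validate_against(library)
    if design.cv > 0:
        sigma = float(np.sqrt(np.log1p(design.cv**2)))
        mu = -0.5 * sigma * sigma  # E[exp(N(mu, sigma))] == 1
    spectra: list[Spectrum] = []
    for entry in design.entries:
        jitter_seed, noise_seed = sample_seeds(seed, entry.sample_id)
        if design.cv > 0:
            rng = np.random.default_rng(jitter_seed)
            conc = {
                m: entry.concentration_profile[m] * float(np.exp(rng.normal(mu, sigma)))
                for m in sorted(entry.concentration_profile)
            }
        else:
            conc = {m: float(v) for m, v in sorted(entry.concentration_profile.items())}
        edits = design.variant_edits.get((entry.species_label, entry.variant_label), ())
        eff_lib, eff_conc = _apply_edits(library, conc, edits)
        spectra.append(
            render_spectrum(
                eff_lib,
                eff_conc,
                params,
                noise_seed,
                meta={
                    "sample_id": entry.sample_id,
                    "species_label": entry.species_label,
                    "variant_label": entry.variant_label,
                    "extraction": entry.extraction,
                },
            )
        )
    return spectra
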