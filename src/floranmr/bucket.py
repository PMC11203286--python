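"""Spectral bucketing and per-spectrum normalization.

A spectrum is reduced to a fixed-length fingerprint by integrating its
positive part over simple rectangular buckets of 0.01 ppm between 1 and
12 ppm, dropping every bucket that touches a residual-solvent exclusion
window (water 4.75-5.06, methanol 3.16-3.45, reference -0.05-0.05 ppm),
then quantizing per spectrum: bucket values at or below the spectrum's
mean become 0 and values above the mean are binned linearly onto the
integers 1..100.

Conventions fixed for reproducibility: buckets are half-open [low, high)
intervals with edges computed by index arithmetic; a bucket overlapping
an exclusion window at all is dropped; the normalization mean is taken
over retained buckets only; quantization rounds half up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synth import Spectrum

__all__ = [
    "BucketSpec",
    "BucketTable",
    "make_buckets",
    "bucket_spectrum",
    "normalize_buckets",
    "build_table",
]

DEFAULT_EXCLUSIONS = ((4.75, 5.06), (3.16, 3.45), (-0.05, 0.05))


@dataclass(frozen=True)
class BucketSpec:
    """Bucketing geometry: range, width and solvent exclusion windows."""

    range_low: float = 1.0
    range_high: float = 12.0
    width: float = 0.01
    exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "exclusions",
            tuple((float(a), float(b)) for a, b in self.exclusions),
        )
        if not self.range_low < self.range_high:
            raise ValueError("range_low must be < range_high")
        if not self.width > 0:
            raise ValueError("width must be > 0")
        ratio = (self.range_high - self.range_low) / self.width
        if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
            raise ValueError(
                f"range span {self.range_high - self.range_low} is not an integer "
                f"multiple of width {self.width}"
            )
        for a, b in self.exclusions:
            if not a < b:
                raise ValueError(f"malformed exclusion interval ({a}, {b})")

    @property
    def n_total(self) -> int:
        return int(round((self.range_high - self.range_low) / self.width))


@dataclass
class BucketTable:
    """Samples x retained-buckets matrix with its geometry bookkeeping."""

    values: np.ndarray
    bucket_edges: tuple[tuple[float, float], ...]
    sample_ids: tuple[str, ...]
    normalized: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x buckets)")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample_ids")
        if self.values.shape[1] != len(self.bucket_edges):
            raise ValueError("column count does not match bucket_edges")
        if self.normalized and self.values.size:
            if self.values.min() < 0 or self.values.max() > 100:
                raise ValueError("normalized table entries must lie in [0, 100]")

    @property
    def bucket_centers(self) -> np.ndarray:
        return np.array([(a + b) / 2.0 for a, b in self.bucket_edges])


def make_buckets(spec: BucketSpec) -> list[tuple[float, float]]:
    """Retained half-open bucket intervals, ascending.

    Edges come from index arithmetic (``low + i * width``), not repeated
    addition; a bucket is dropped when it overlaps any exclusion window
    by more than a float-safety epsilon.
    """
    eps = spec.width * 1e-6
    out = []
    for i in range(spec.n_total):
        lo = spec.range_low + i * spec.width
        hi = spec.range_low + (i + 1) * spec.width
        excluded = any(lo < b - eps and hi > a + eps for a, b in spec.exclusions)
        if not excluded:
            out.append((lo, hi))
    return out


def bucket_spectrum(spectrum: Spectrum, spec: BucketSpec) -> np.ndarray:
    """Integrate the positive part of a spectrum over retained buckets.

    Each axis point contributes ``max(intensity, 0) * |axis step|`` to
    the bucket its ppm value falls in ("positive intensities without
    scaling": no division by bucket width or point count).
    """
    ppm, y = spectrum.ascending()
    if ppm[0] > spec.range_low or ppm[-1] < spec.range_high:
        raise ValueError(
            f"axis [{ppm[0]:g}, {ppm[-1]:g}] does not cover the bucketing range "
            f"[{spec.range_low:g}, {spec.range_high:g}] ppm"
        )
    step = np.abs(np.gradient(ppm))
    contrib = np.maximum(y, 0.0) * step
    # classify points against the exact float edge values used by
    # make_buckets, so edge membership follows [low, high) bit-for-bit
    lows = spec.range_low + np.arange(spec.n_total) * spec.width
    last_high = spec.range_low + spec.n_total * spec.width
    idx = np.searchsorted(lows, ppm, side="right") - 1
    in_range = (idx >= 0) & (ppm < last_high)
    totals = np.bincount(idx[in_range], weights=contrib[in_range], minlength=spec.n_total)
    retained = [
        int(round((lo - spec.range_low) / spec.width)) for lo, _ in make_buckets(spec)
    ]
    return totals[retained]


def normalize_buckets(raw: np.ndarray) -> np.ndarray:
    """Quantize one bucket vector onto integers 0..100.

    Values at or below the vector mean map to 0; strictly-above-mean
    values map linearly onto 1..100 (their minimum to 1, their maximum
    to 100, round half up).  If all above-mean values coincide they all
    map to 100; an all-zero vector stays all zero.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("bucket vector contains non-finite values")
    if raw.size and raw.min() < 0:
        raise ValueError("bucket vector contains negative values")
    out = np.zeros(raw.shape, dtype=np.int64)
    if raw.size == 0:
        return out
    mean = raw.mean()
    above = raw > mean
    if not above.any():
        return out
    vals = raw[above]
    a, b = vals.min(), vals.max()
    if b == a:
        out[above] = 100
    else:
        scaled = 1.0 + 99.0 * (vals - a) / (b - a)
        out[above] = np.floor(scaled + 0.5).astype(np.int64)  # round half up
    return out


def build_table(
    spectra: Sequence[Spectrum], spec: BucketSpec, normalize: bool = True
) -> BucketTable:
    """Bucket a list of spectra into one table, rows in input order."""
    edges = tuple(make_buckets(spec))
    ids = []
    rows = []
    for i, spectrum in enumerate(spectra):
        sample_id = str(spectrum.meta.get("sample_id", f"S{i:02d}"))
        try:
            vec = bucket_spectrum(spectrum, spec)
            rows.append(normalize_buckets(vec) if normalize else vec)
        except ValueError as err:
            raise ValueError(f"sample {sample_id!r}: {err}") from err
        ids.append(sample_id)
    if rows:
        values = np.vstack(rows)
    else:
        values = np.zeros((0, len(edges)), dtype=np.int64 if normalize else float)
    return BucketTable(
        values=values, bucket_edges=edges, sample_ids=tuple(ids), normalized=normalize
    )
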