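"""Readers and writers for spectra, tables and reports.

The native spectrum format is a plain two-column TSV (ppm, intensity)
with ``# key: value`` metadata header lines — portable and diff-able.
JCAMP-DX is supported for interchange via the ``XYDATA=(X++(Y..Y))``
AFFN subset.  Bucket tables go to CSV with a sidecar JSON recording the
bucket geometry; distance matrices to square CSV; dendrograms to Newick.
All text output is UTF-8 with LF line endings and '.' decimals so byte
output is reproducible across platforms.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .bucket import BucketSpec, BucketTable, make_buckets
from .cluster import DistanceMatrix
from .synth import Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "write_bucket_table",
    "read_bucket_table",
    "write_distance_matrix",
]

_META_KEYS = ("sample_id", "species_label", "variant_label", "extraction", "field_mhz")


def _infer_format(path: Path) -> str:
    if path.suffix.lower() in (".dx", ".jdx", ".jcamp"):
        return "jcamp"
    return "tsv"


def read_spectrum(path, format: str | None = None) -> Spectrum:
    """Read a spectrum from TSV or JCAMP-DX.

    The axis is normalised to decreasing ppm order regardless of the
    order on disk.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "jcamp":
        return _read_jcamp(path)
    raise ValueError(f"unknown spectrum format {fmt!r}")


def write_spectrum(spectrum: Spectrum, path, format: str | None = None) -> Path:
    """Write a spectrum; inverse of :func:`read_spectrum`."""
    path = Path(path)
    if spectrum.intensity.size == 0:
        raise ValueError("refusing to write an empty spectrum")
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        _write_tsv(spectrum, path)
    elif fmt == "jcamp":
        _write_jcamp(spectrum, path)
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")
    return path


def _read_tsv(path: Path) -> Spectrum:
    meta: dict = {}
    ppm, intensity = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                ppm.append(float(parts[0]))
                intensity.append(float(parts[1]))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric value: {line!r}") from err
    if "field_mhz" in meta:
        meta["field_mhz"] = float(meta["field_mhz"])
    return Spectrum(ppm=np.array(ppm), intensity=np.array(intensity), meta=meta)


def _write_tsv(spectrum: Spectrum, path: Path) -> None:
    lines = []
    for key in _META_KEYS:
        if key in spectrum.meta:
            lines.append(f"# {key}: {spectrum.meta[key]}")
    for key in sorted(spectrum.meta):
        if key not in _META_KEYS:
            lines.append(f"# {key}: {spectrum.meta[key]}")
    for p, y in zip(spectrum.ppm, spectrum.intensity):
        lines.append(f"{p:.12g}\t{y:.12g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def _write_jcamp(spectrum: Spectrum, path: Path) -> None:
    ppm, y = spectrum.ppm, spectrum.intensity
    meta = spectrum.meta
    lines = [
        f"##TITLE={meta.get('sample_id', 'spectrum')}",
        "##JCAMP-DX=5.00",
        "##DATA TYPE=NMR SPECTRUM",
        "##DATA CLASS=XYDATA",
        "##ORIGIN=floranmr",
        "##OWNER=",
        f"##.OBSERVE FREQUENCY={float(meta.get('field_mhz', 0.0)):.6g}",
    ]
    for key in ("sample_id", "species_label", "variant_label", "extraction"):
        if key in meta:
            lines.append(f"##${key.upper()}={meta[key]}")
    lines += [
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={ppm[0]:.12g}",
        f"##LASTX={ppm[-1]:.12g}",
        f"##NPOINTS={len(ppm)}",
        f"##FIRSTY={y[0]:.12g}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, len(y), per_line):
        chunk = y[i : i + per_line]
        vals = " ".join(f"{v:.12g}" for v in chunk)
        lines.append(f"{ppm[i]:.12g} {vals}")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def _read_jcamp(path: Path) -> Spectrum:
    labels: dict[str, str] = {}
    y: list[float] = []
    in_data = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper()
                if key == "END":
                    break
                in_data = key == "XYDATA"
                labels[key] = val.strip()
                continue
            if in_data:
                parts = line.split()
                try:
                    vals = [float(p) for p in parts]
                except ValueError as err:
                    raise ValueError(f"{path}:{lineno}: non-numeric value in XYDATA") from err
                y.extend(vals[1:])  # first token is the X checkpoint
    try:
        npoints = int(labels["NPOINTS"])
        firstx = float(labels["FIRSTX"])
        lastx = float(labels["LASTX"])
    except KeyError as err:
        raise ValueError(f"{path}: missing required JCAMP label {err}") from err
    if len(y) != npoints:
        raise ValueError(f"{path}: NPOINTS={npoints} but {len(y)} Y values read")
    yfactor = float(labels.get("YFACTOR", 1.0))
    intensity = np.array(y) * yfactor
    ppm = np.linspace(firstx, lastx, npoints) * float(labels.get("XFACTOR", 1.0))
    meta: dict = {}
    for key in ("SAMPLE_ID", "SPECIES_LABEL", "VARIANT_LABEL", "EXTRACTION"):
        if f"${key}" in labels:
            meta[key.lower()] = labels[f"${key}"]
    freq = labels.get(".OBSERVE FREQUENCY")
    if freq:
        meta["field_mhz"] = float(freq)
    return Spectrum(ppm=ppm, intensity=intensity, meta=meta)


def write_bucket_table(
    table: BucketTable,
    path,
    spec: BucketSpec | None = None,
    stamp: dict | None = None,
) -> Path:
    """Bucket table to CSV plus a sidecar ``<path>.json`` with geometry.

    First column is the sample id; remaining columns are labelled by
    bucket center ppm to three decimals.
    """
    path = Path(path)
    centers = table.bucket_centers
    header = "sample_id," + ",".join(f"{c:.3f}" for c in centers)
    lines = []
    if stamp:
        lines.append("# " + ", ".join(f"{k}={v}" for k, v in sorted(stamp.items())))
    lines.append(header)
    is_int = table.normalized
    for sid, row in zip(table.sample_ids, table.values):
        vals = ",".join(str(int(v)) if is_int else f"{v:.12g}" for v in row)
        lines.append(f"{sid},{vals}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    sidecar = {
        "normalized": table.normalized,
        "bucket_edges": [[a, b] for a, b in table.bucket_edges],
    }
    if spec is not None:
        sidecar["bucket_spec"] = {
            "range_low": spec.range_low,
            "range_high": spec.range_high,
            "width": spec.width,
            "exclusions": [list(e) for e in spec.exclusions],
        }
    if stamp:
        sidecar.update(stamp)
    Path(str(path) + ".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return path


def read_bucket_table(path) -> BucketTable:
    """Read a bucket table CSV written by :func:`write_bucket_table`."""
    path = Path(path)
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text(encoding="utf-8")) if sidecar.exists() else {}
    ids, rows = [], []
    header = None
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line or line.startswith("#"):
            continue
        if header is None:
            header = line.split(",")
            continue
        parts = line.split(",")
        ids.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    normalized = bool(meta.get("normalized", False))
    values = np.array(rows, dtype=np.int64 if normalized else float)
    if "bucket_edges" in meta:
        edges = tuple((a, b) for a, b in meta["bucket_edges"])
    else:
        centers = [float(c) for c in header[1:]]
        w = centers[1] - centers[0] if len(centers) > 1 else 0.01
        edges = tuple((c - w / 2, c + w / 2) for c in centers)
    return BucketTable(
        values=values, bucket_edges=edges, sample_ids=tuple(ids), normalized=normalized
    )


def write_distance_matrix(dist: DistanceMatrix, path, stamp: dict | None = None) -> Path:
    """Square distance matrix to CSV (labelled rows and columns)."""
    path = Path(path)
    lines = []
    if stamp:
        lines.append("# " + ", ".join(f"{k}={v}" for k, v in sorted(stamp.items())))
    lines.append("sample_id," + ",".join(dist.labels))
    for label, row in zip(dist.labels, dist.values):
        lines.append(label + "," + ",".join(f"{v:.12g}" for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path
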