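"""End-to-end pipeline orchestration.

Stages run in the fixed order simulate/ingest -> preprocess (calibrate,
baseline) -> bucket -> normalize -> cluster -> assign.  Every run writes
a bucket table CSV, a distance matrix CSV, a Newick dendrogram, an
assignment/purity report JSON and a parameter log into the output
directory, each stamped with the configuration hash and master seed;
identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as fio
from .assign import group_multiplets, match_library, pick_peaks
from .bucket import BucketSpec, build_table
from .cluster import cut_tree, euclidean_distances, species_recovery, to_newick, ward_linkage
from .cohort import default_design, load_design
from .library import default_library, library_from_yaml
from .preprocess import baseline_correct, calibrate
from .synth import SpectrumParams, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    out_dir: str = "floranmr_out"
    design_path: str | None = None  # None -> packaged fixture cohort
    spectra_dir: str | None = None  # read spectra instead of simulating
    library_path: str | None = None  # None -> packaged signature library
    params: SpectrumParams = field(default_factory=SpectrumParams)
    bucket_spec: BucketSpec = field(default_factory=BucketSpec)
    normalize: bool = True
    do_calibrate: bool = True
    do_baseline: bool = True
    k: int | None = None  # None -> number of distinct species labels
    delta_tol: float = 0.03
    j_tol: float = 1.0
    snr_threshold: float = 5.0
    seed: int = 42
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")

    def config_hash(self) -> str:
        doc = asdict(self)
        doc.pop("out_dir")  # where outputs land does not change what they contain
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode("utf-8")
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Read a pipeline configuration from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs = dict(doc)
    if "params" in kwargs:
        p = dict(kwargs["params"])
        if "solvent_peaks" in p:
            p["solvent_peaks"] = tuple(tuple(x) for x in p["solvent_peaks"])
        kwargs["params"] = SpectrumParams(**p)
    if "bucket_spec" in kwargs:
        b = dict(kwargs["bucket_spec"])
        if "exclusions" in b:
            b["exclusions"] = tuple(tuple(x) for x in b["exclusions"])
        kwargs["bucket_spec"] = BucketSpec(**b)
    return PipelineConfig(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and return the paths of the five outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    log_lines = [f"config_hash={stamp['config_hash']} seed={config.seed}"]

    def log(msg: str) -> None:
        log_lines.append(msg)

    library = (
        library_from_yaml(config.library_path)
        if config.library_path
        else default_library()
    )
    log(f"library: {len(library)} signatures")

    stage = "ingest"
    try:
        if config.spectra_dir:
            paths = sorted(Path(config.spectra_dir).glob("*"))
            spectra = [
                fio.read_spectrum(p) for p in paths if p.suffix in (".tsv", ".dx", ".jdx")
            ]
            log(f"ingest: read {len(spectra)} spectra from {config.spectra_dir}")
        else:
            stage = "simulate"
            design = (
                load_design(config.design_path, library)
                if config.design_path
                else default_design(library)
            )
            spectra = generate_cohort(design, library, config.params, config.seed)
            log(
                f"simulate: {len(spectra)} spectra, cv={design.cv}, "
                f"noise_sigma={config.params.noise_sigma}, "
                f"field={config.params.field_mhz} MHz, n_points={config.params.n_points}"
            )
        if not spectra:
            raise ValueError("no spectra to process")

        stage = "preprocess"
        processed = []
        for s in spectra:
            if config.do_calibrate:
                s, cal = calibrate(s)
                log(
                    f"calibrate {s.meta.get('sample_id', '?')}: shift={cal.shift_applied:.6g} "
                    f"found={cal.reference_found}"
                )
            if config.do_baseline:
                s = baseline_correct(s)
            processed.append(s)

        stage = "bucket"
        spec = config.bucket_spec
        table = build_table(processed, spec, normalize=config.normalize)
        log(
            f"bucket: range {spec.range_low}-{spec.range_high} ppm width {spec.width}, "
            f"exclusions {list(spec.exclusions)}, {table.values.shape[1]} retained buckets, "
            f"normalized={config.normalize}"
        )

        stage = "cluster"
        dist = euclidean_distances(table)
        dend = ward_linkage(dist)
        truth = {
            str(s.meta["sample_id"]): str(s.meta.get("species_label", "")) for s in processed
        }
        k = config.k or len(set(truth.values()))
        assignment = cut_tree(dend, k)
        recovered, purity = species_recovery(assignment, truth)
        log(
            f"cluster: euclidean metric, ward linkage, cut at k={k}: "
            f"{recovered}/{len(set(truth.values()))} species pure, purity={purity:.3f}"
        )

        stage = "assign"
        per_sample = {}
        for s in processed:
            peaks = pick_peaks(s, snr_threshold=config.snr_threshold)
            obs = group_multiplets(peaks, field_mhz=float(s.meta.get("field_mhz", 400.0)))
            report = match_library(
                obs, library, delta_tol=config.delta_tol, j_tol=config.j_tol
            )
            per_sample[str(s.meta["sample_id"])] = {
                "n_peaks": len(peaks),
                "n_multiplets": len(obs),
                "identified": report.identified_names,
                "region_summary": report.region_summary,
            }
        log(
            f"assign: delta_tol={config.delta_tol} ppm, j_tol={config.j_tol} Hz, "
            f"snr_threshold={config.snr_threshold}"
        )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    buckets_csv = fio.write_bucket_table(table, out / "buckets.csv", spec=spec, stamp=stamp)
    dist_csv = fio.write_distance_matrix(dist, out / "distances.csv", stamp=stamp)
    newick = out / "dendrogram.nwk"
    newick.write_text(to_newick(dend) + "\n", encoding="utf-8", newline="\n")
    report_json = out / "assignments.json"
    report_json.write_text(
        json.dumps(
            {
                **stamp,
                "k": k,
                "species_recovered": recovered,
                "n_species": len(set(truth.values())),
                "purity": purity,
                "clusters": assignment,
                "samples": per_sample,
            },
            indent=1,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )
    log_path = out / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8", newline="\n")
    return {
        "buckets": buckets_csv,
        "distances": dist_csv,
        "newick": newick,
        "report": report_json,
        "log": log_path,
    }
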