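"""Cohort design loading and the packaged default fixture.

A design YAML lists the sample roster (id, species, optional color
variant), the within-species coefficient of variation, variant edits,
and either explicit per-species concentration profiles or an ``auto``
profile block.  Auto profiles draw one mean concentration per (species,
metabolite) from a lognormal exp(N(0, sigma)) seeded by the profile seed
and the species name, so every species gets a distinct but reproducible
metabolite fingerprint and the profile of one species never depends on
which other species are in the roster.
"""

from __future__ import annotations

import zlib
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .library import default_library
from .synth import CohortDesign, CohortEntry, MetaboliteSignature, Resonance, VariantEdit

__all__ = ["default_design", "load_design", "species_profile"]

_FIXTURE = "default_cohort.yaml"


def species_profile(
    species: str,
    library: Sequence[MetaboliteSignature],
    seed: int = 101,
    sigma: float = 1.0,
) -> dict[str, float]:
    """Deterministic lognormal concentration profile for one species."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(species.encode("utf-8"))])
    rng = np.random.default_rng(ss)
    return {
        sig.name: float(np.exp(rng.normal(0.0, sigma))) for sig in library
    }


def _parse_edit(doc: Mapping) -> VariantEdit:
    res = doc.get("resonance")
    resonance = None
    if res is not None:
        resonance = Resonance(
            center=float(res["center"]),
            multiplicity=res["multiplicity"],
            j_values=tuple(res.get("j_values", ())),
            rel_intensity=float(res.get("rel_intensity", 1.0)),
            assignment=res.get("assignment", ""),
        )
    return VariantEdit(
        action=doc["action"],
        metabolite=doc.get("metabolite", ""),
        center=float(doc["center"]) if doc.get("center") is not None else None,
        factor=float(doc.get("factor", 1.0)),
        resonance=resonance,
    )


def _design_from_doc(
    doc: Mapping, library: Sequence[MetaboliteSignature]
) -> CohortDesign:
    profiles_cfg = doc.get("profiles", {"mode": "auto", "seed": 101, "sigma": 1.0})
    mode = profiles_cfg.get("mode", "auto")
    if mode == "auto":
        seed = int(profiles_cfg.get("seed", 101))
        sigma = float(profiles_cfg.get("sigma", 1.0))
        species = sorted({s["species"] for s in doc["samples"]})
        profile_by_species = {
            sp: species_profile(sp, library, seed=seed, sigma=sigma) for sp in species
        }
    elif mode == "explicit":
        profile_by_species = {
            sp: {m: float(v) for m, v in prof.items()}
            for sp, prof in profiles_cfg["values"].items()
        }
    else:
        raise ValueError(f"unknown profiles mode {mode!r}")

    default_extraction = doc.get("extraction", "methanol")
    entries = []
    for s in doc["samples"]:
        sp = s["species"]
        if sp not in profile_by_species:
            raise ValueError(f"no concentration profile for species {sp!r}")
        entries.append(
            CohortEntry(
                sample_id=s["id"],
                species_label=sp,
                variant_label=s.get("variant", ""),
                extraction=s.get("extraction", default_extraction),
                concentration_profile=profile_by_species[sp],
            )
        )

    edits = {}
    for key, edit_docs in (doc.get("variant_edits") or {}).items():
        species_label, _, variant_label = key.partition("::")
        edits[(species_label, variant_label)] = tuple(_parse_edit(e) for e in edit_docs)

    design = CohortDesign(
        entries=tuple(entries), cv=float(doc.get("cv", 0.1)), variant_edits=edits
    )
    design.validate_against(library)
    return design


def load_design(path, library: Sequence[MetaboliteSignature] | None = None) -> CohortDesign:
    """Read a cohort design from a YAML file."""
    if library is None:
        library = default_library()
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _design_from_doc(doc, library)


def default_design(library: Sequence[MetaboliteSignature] | None = None) -> CohortDesign:
    """The packaged 33-sample / 23-species fixture cohort."""
    if library is None:
        library = default_library()
    text = resources.files("floranmr.data").joinpath(_FIXTURE).read_text(encoding="utf-8")
    return _design_from_doc(yaml.safe_load(text), library)
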