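"""The default metabolite chemical-shift signature library.

Twenty flower-extract metabolites observed in methanol-extract 1H-NMR,
each as one or more resonances (chemical shift delta in ppm, multiplicity,
scalar couplings J in Hz).  ``rel_intensity`` encodes the contributing
proton count of each signal, so rendered peak areas stay roughly
proportional to proton number; it is not used during matching.

A YAML loader is provided for user-supplied libraries with the same
schema.
"""

from __future__ import annotations

from typing import Sequence

import yaml

from .synth import MetaboliteSignature, Resonance

__all__ = ["default_library", "library_from_yaml", "validate_library"]


def _sig(name: str, *resonances: tuple) -> MetaboliteSignature:
    return MetaboliteSignature(
        name=name,
        resonances=tuple(
            Resonance(
                center=c,
                multiplicity=m,
                j_values=tuple(j),
                rel_intensity=ri,
                assignment=a,
            )
            for (c, m, j, ri, a) in resonances
        ),
    )


def default_library() -> list[MetaboliteSignature]:
    """The 20-compound flower-extract signature library."""
    return [
        _sig(
            "Kaempferol",
            (8.07, "d", (8.9,), 2.0, "aromatic 2',6'-CH"),
            (6.96, "d", (3.4,), 2.0, "aromatic 3',5'-CH"),
            (6.44, "dd", (2.0, 2.1), 1.0, "aromatic CH"),
        ),
        _sig("Sucrose", (5.41, "d", (3.8,), 1.0, "furanose CH")),
        _sig("alpha-Glucose", (5.15, "d", (3.6,), 1.0, "alpha-anomeric CH")),
        _sig("beta-Glucose", (4.53, "d", (7.8,), 1.0, "beta-anomeric CH")),
        _sig("Fructose", (4.22, "d", (7.8,), 1.0, "furanose CH")),
        _sig(
            "Glucose and Fructose",
            (3.69, "m", (), 6.0, "ring CH, CH2 envelope (3.89-3.49)"),
        ),
        _sig("Aspartate", (2.99, "dd", (3.4, 3.5), 2.0, "beta-CH2")),
        _sig("Citrate", (2.79, "dd", (5.6, 7.5), 2.0, "alpha-CH2")),
        _sig("Methionine", (2.77, "m", (), 2.0, "CH2")),
        _sig("Malate", (2.73, "m", (), 2.0, "alpha-CH2")),
        _sig("Succinic acid", (2.56, "s", (), 4.0, "CH2")),
        _sig(
            "Glutamate",
            (2.37, "m", (), 2.0, "alpha-CH2"),
            (2.02, "m", (), 2.0, "beta-CH2"),
        ),
        _sig("Glutamine", (2.32, "m", (), 2.0, "CH2")),
        _sig("Acetic acid", (2.18, "s", (), 3.0, "CH3")),
        _sig("Proline", (1.91, "m", (), 2.0, "beta-CH2")),
        _sig("Lysine", (1.61, "m", (), 2.0, "CH2")),
        _sig("Alanine", (1.49, "d", (7.2,), 3.0, "beta-CH3")),
        _sig(
            "Isoleucine",
            (3.66, "m", (), 1.0, "alpha-CH"),
            (1.96, "m", (), 1.0, "beta-CH"),
            (1.47, "m", (), 1.0, "gamma-CH2"),
            (1.26, "m", (), 1.0, "gamma-CH2"),
            (1.01, "d", (2.0,), 3.0, "CH3"),
            (0.96, "t", (2.3,), 3.0, "delta-CH3"),
        ),
        _sig(
            "Leucine",
            (3.72, "m", (), 1.0, "alpha-CH"),
            (1.67, "m", (), 2.0, "beta-CH2"),
            (0.95, "m", (), 6.0, "CH3"),
        ),
        _sig(
            "Valine",
            (2.26, "m", (), 1.0, "alpha-CH"),
            (1.06, "d", (7.0,), 3.0, "beta-CH3"),
            (0.91, "d", (3.6,), 3.0, "beta-CH3"),
        ),
    ]


def validate_library(library: Sequence[MetaboliteSignature]) -> None:
    """Check cross-signature invariants (names unique)."""
    names = [s.name for s in library]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate metabolite names in library: {dupes}")


def library_from_yaml(path) -> list[MetaboliteSignature]:
    """Load a signature library from YAML.

    Schema: a top-level ``metabolites`` list of
    ``{name, resonances: [{center, multiplicity, j_values, rel_intensity,
    assignment}]}`` mappings.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    out = []
    for m in doc["metabolites"]:
        out.append(
            MetaboliteSignature(
                name=m["name"],
                resonances=tuple(
                    Resonance(
                        center=float(r["center"]),
                        multiplicity=r["multiplicity"],
                        j_values=tuple(r.get("j_values", ())),
                        rel_intensity=float(r.get("rel_intensity", 1.0)),
                        assignment=r.get("assignment", ""),
                    )
                    for r in m["resonances"]
                ),
            )
        )
    validate_library(out)
    return out
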