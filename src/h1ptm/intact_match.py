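"""Assignment of deconvoluted intact protein masses to sequence variants.

Linear-mode MALDI-TOF measures intact proteins at low resolution, so these
comparisons run on the **average** mass scale with a relative tolerance
(default 0.2%), in contrast to the monoisotopic arithmetic used everywhere
else in the pipeline.  Satellite peaks a few tens to hundreds of Da above a
variant's main peak are screened as combinations of registered
modifications.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .chem_core import (
    WATER_AVG,
    ElementCounts,
    ModificationRegistry,
    composition_mass,
    _RESIDUE_AVG,
)
from .digestion import ProteinRecord
from .ptm_discovery import suggest_mod_combinations

_ACETYL_AVG = composition_mass(ElementCounts.from_formula("C2H2O"), "average")


@dataclass(frozen=True)
class IntactObservation:
    """One deconvoluted intact mass (average-mass scale)."""

    observed_mass: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.observed_mass <= 0:
            raise ValueError("non-positive observed mass")


@dataclass(frozen=True)
class VariantMatch:
    protein: ProteinRecord
    theoretical_average_mass: float
    delta: float  # observed - theoretical
    rank: int


def protein_average_mass(protein: ProteinRecord,
                         nterm_acetyl: bool = False) -> float:
    """Average (isotope-abundance-weighted) mass of the mature chain."""
    if not protein.sequence:
        raise ValueError("empty protein sequence")
    mass = WATER_AVG + sum(_RESIDUE_AVG[ch] for ch in protein.sequence)
    if nterm_acetyl:
        mass += _ACETYL_AVG
    return mass


def match_intact(obs: IntactObservation,
                 candidates: Sequence[ProteinRecord],
                 tol_fraction: float = 0.002,
                 nterm_acetyl: bool = False) -> list[VariantMatch]:
    """Candidate variants within relative tolerance, ranked by |delta|.

    Ties on |delta| are broken by protein id; the list is empty when no
    candidate falls inside the window.
    """
    if tol_fraction <= 0:
        raise ValueError("tol_fraction must be positive")
    hits = []
    for protein in candidates:
        theo = protein_average_mass(protein, nterm_acetyl=nterm_acetyl)
        delta = obs.observed_mass - theo
        if abs(delta) <= tol_fraction * theo:
            hits.append((protein, theo, delta))
    hits.sort(key=lambda ptd: (abs(ptd[2]), ptd[0].id))
    return [VariantMatch(protein=p, theoretical_average_mass=t, delta=d,
                         rank=i + 1)
            for i, (p, t, d) in enumerate(hits)]


def explain_satellite(delta: float, registry: ModificationRegistry,
                      max_mods: int = 3, tol: float = 0.5):
    """Modification multisets accounting for a satellite-peak mass offset.

    Monoisotopic deltas are summed; at the tolerances meaningful for
    linear-mode data (a few tenths of a Da and beyond) the monoisotopic vs
    average distinction for small modifications is immaterial.
    """
    return suggest_mod_combinations(delta, registry, max_mods=max_mods, tol=tol)


def read_mass_table(path: str | Path) -> list[IntactObservation]:
    """Plain TSV of observed masses: columns ``label`` and ``mass_da``."""
    obs = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        label, mass = line.split("\t")[:2]
        obs.append(IntactObservation(observed_mass=float(mass), label=label))
    return obs


def match_table(matches: Iterable[VariantMatch]):
    import pandas as pd

    return pd.DataFrame(
        [{"protein_id": m.protein.id, "rank": m.rank,
          "theoretical_average_mass": m.theoretical_average_mass,
          "delta": m.delta} for m in matches])
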