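"""Theoretical HCD fragment ions for modified peptides.

Beam-type collisional dissociation produces b and y ions plus, for longer
peptides, internal fragments from double backbone cleavage; a/c/z series are
not generated (they are not part of the observed ion repertoire this
pipeline models).  Singly charged b/y pairs obey the conservation identity

    b_i + y_(n-i) = neutral peptide mass + 2 * proton

which the matching and localization stages rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .chem_core import (
    PROTON_MASS,
    WATER_MONO,
    Modification,
    composition_mass,
    ElementCounts,
    residue_mono_mass,
)
from .digestion import PeptideSpan

_ACETYL_MONO = composition_mass(ElementCounts.from_formula("C2H2O"), "mono")

#: Small-molecule neutral losses recognised by :func:`neutral_loss_candidates`.
NEUTRAL_LOSSES: dict[str, float] = {
    "H2O": 18.0105646863,
    "NH3": 17.0265491015,
    "H3PO4": 97.9768950447,
    "HPO3": 79.9663304276,
    "SO2": 63.9618540392,
    "CO": 27.9949146196,
    "CH2O": 30.0105646863,
}

#: Neutral losses attached to fragments carrying the named modification
#: class.  The 63.96 Da loss accompanying the phosphoglycerol-mass shift is
#: chemically unassigned (its mass matches SO2); it is annotated, not
#: interpreted.
CLASS_LOSSES: dict[str, tuple[tuple[str, float], ...]] = {
    "phospho": (("H3PO4", NEUTRAL_LOSSES["H3PO4"]),),
    "phosphoglycerol": (("unassigned (mass matches SO2)",
                         NEUTRAL_LOSSES["SO2"]),),
}


@dataclass(frozen=True)
class ModifiedPeptide:
    """A digest peptide with site-placed modifications.

    ``placements`` holds ``(peptide-local 1-based position, Modification)``
    pairs; at most one modification of a given class per position.
    """

    span: PeptideSpan
    placements: tuple[tuple[int, Modification], ...] = ()
    nterm_acetyl: bool = False

    def __post_init__(self) -> None:
        n = len(self.span.sequence)
        seen = set()
        for pos, mod in self.placements:
            if not (1 <= pos <= n):
                raise ValueError(f"placement at {pos} outside peptide of length {n}")
            key = (pos, mod.mod_class)
            if key in seen:
                raise ValueError(
                    f"two {mod.mod_class!r} placements at position {pos}")
            seen.add(key)

    @property
    def sequence(self) -> str:
        return self.span.sequence

    def residue_masses(self) -> list[float]:
        """Per-residue monoisotopic masses with modification deltas applied.

        The N-terminal acetyl, being a terminus modification, is folded into
        the first residue (it travels with every b ion and with the full-length
        y ion only).
        """
        masses = [residue_mono_mass(ch) for ch in self.sequence]
        for pos, mod in self.placements:
            masses[pos - 1] += mod.mono_delta
        if self.nterm_acetyl:
            masses[0] += _ACETYL_MONO
        return masses

    def neutral_mass(self) -> float:
        return sum(self.residue_masses()) + WATER_MONO

    def classes_at(self, index: int) -> set[str]:
        """Modification classes placed on 1-based position ``index``."""
        return {mod.mod_class for pos, mod in self.placements if pos == index}


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical fragment m/z.

    ``pos`` is the ladder index for b/y ions or the 1-based inclusive
    ``(i, j)`` residue window for internal ions.  ``shift`` records a
    precursor-delta offset applied during open-search annotation (0 for
    plain ladders).
    """

    series: str  # 'b' | 'y' | 'internal'
    pos: int | tuple[int, int]
    charge: int
    mz: float
    neutral_loss: tuple[str, float] | None = None
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("non-positive fragment m/z")

    @property
    def label(self) -> str:
        if self.series == "internal":
            i, j = self.pos  # type: ignore[misc]
            base = f"by({i}:{j})"
        else:
            base = f"{self.series}{self.pos}"
        if self.charge != 1:
            base += f"({self.charge}+)"
        if self.neutral_loss is not None:
            base += f"-{self.neutral_loss[0]}"
        if self.shift:
            base += f"+Δ{self.shift:.4f}"
        return base

    def with_shift(self, delta: float) -> "FragmentIon":
        """The same ion displaced by a neutral-mass delta (open search)."""
        return replace(self, mz=self.mz + delta / self.charge, shift=delta)


def theoretical_fragments(
    pep: ModifiedPeptide,
    charges: Sequence[int] = (1, 2),
    include_internal: bool = False,
    include_losses: bool = True,
    internal_min_len: int = 5,
    internal_max_span: int = 12,
) -> list[FragmentIon]:
    """b/y (and optionally internal) ions for a modified peptide.

    Internal ions are generated only for peptides of at least
    ``internal_min_len`` residues and for windows of at most
    ``internal_max_span`` residues (double-cleavage combinatorics grow
    quadratically).  Neutral losses are attached only to fragments carrying
    a phospho- or phosphoglycerol-class modification.

    Ions are returned in deterministic order: series (b, y, internal), then
    index, then charge.
    """
    seq = pep.sequence
    n = len(seq)
    if n < 2:
        raise ValueError("peptide too short to fragment (length < 2)")
    masses = pep.residue_masses()
    prefix = [0.0] * (n + 1)
    for i, m in enumerate(masses, start=1):
        prefix[i] = prefix[i - 1] + m
    charges = sorted(set(charges))

    def losses_for(window_classes: set[str]) -> list[tuple[str, float]]:
        if not include_losses:
            return []
        out: list[tuple[str, float]] = []
        for cls in window_classes:
            out.extend(CLASS_LOSSES.get(cls, ()))
        return out

    window_class_cache: dict[tuple[int, int], set[str]] = {}

    def window_classes(i: int, j: int) -> set[str]:
        key = (i, j)
        if key not in window_class_cache:
            classes: set[str] = set()
            for pos, mod in pep.placements:
                if i <= pos <= j:
                    classes.add(mod.mod_class)
            window_class_cache[key] = classes
        return window_class_cache[key]

    ions: list[FragmentIon] = []
    # b series, including the full-chain b_n acylium ion (the dehydrated
    # protonated molecule), so every modification is covered by the series
    for i in range(1, n + 1):
        neutral = prefix[i]
        wc = window_classes(1, i)
        for z in charges:
            ions.append(FragmentIon("b", i, z, (neutral + z * PROTON_MASS) / z))
            for name, loss in losses_for(wc):
                ions.append(FragmentIon("b", i, z,
                                        (neutral - loss + z * PROTON_MASS) / z,
                                        neutral_loss=(name, loss)))
    # y series
    for k in range(1, n):
        neutral = prefix[n] - prefix[n - k] + WATER_MONO
        wc = window_classes(n - k + 1, n)
        for z in charges:
            ions.append(FragmentIon("y", k, z, (neutral + z * PROTON_MASS) / z))
            for name, loss in losses_for(wc):
                ions.append(FragmentIon("y", k, z,
                                        (neutral - loss + z * PROTON_MASS) / z,
                                        neutral_loss=(name, loss)))
    # internal ions (b-type: residue sum + proton), singly charged.
    # Windows of >= 2 residues only: a single-residue internal would sit at
    # an immonium-unlike, b1-like mass that is not part of the observed HCD
    # repertoire and is isobaric with b1 ions of other peptides.
    if include_internal and n >= internal_min_len:
        for i in range(2, n):
            for j in range(i + 1, min(n - 1, i + internal_max_span - 1) + 1):
                neutral = prefix[j] - prefix[i - 1]
                ions.append(FragmentIon("internal", (i, j), 1,
                                        neutral + PROTON_MASS))
    order = {"b": 0, "y": 1, "internal": 2}
    ions.sort(key=lambda f: (order[f.series],
                             f.pos if isinstance(f.pos, tuple) else (f.pos,),
                             f.charge, f.mz))
    return ions


def neutral_loss_candidates(delta: float, tol: float) -> list[tuple[str, float]]:
    """Known small-molecule losses within ``tol`` of ``delta``, nearest first."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    hits = [(name, mass) for name, mass in NEUTRAL_LOSSES.items()
            if abs(mass - delta) <= tol]
    hits.sort(key=lambda nm: (abs(nm[1] - delta), nm[0]))
    return hits
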