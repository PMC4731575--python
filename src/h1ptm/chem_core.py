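"""Exact mass arithmetic and the modification registry.

Everything downstream — digestion, fragment ladders, delta-mass inference,
intact-protein assignment — funnels through the element and residue mass
tables defined here.  Two mass scales are maintained side by side:

* **monoisotopic** masses (most abundant isotope of each element), used for
  all high-resolution peptide and fragment work;
* **average** masses (abundance-weighted standard atomic weights), used for
  intact-protein comparisons against linear-mode MALDI measurements.

Compositions are restricted to CHNOPS, which covers every amino-acid residue
and every modification handled by the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import yaml

# Monoisotopic isotope masses (Da). C-12 is exactly 12 by definition; the
# remaining values carry >=7 decimals so that six-decimal agreement on small
# modification masses is meaningful.
MONOISOTOPIC_ELEMENT_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

# Standard atomic weights (Da) for average-mass work.
AVERAGE_ELEMENT_MASS: dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
    "S": 32.06,
}

#: Mass of a proton (Da), used to convert neutral masses to m/z.
PROTON_MASS = 1.00727646688

_HILL_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementCounts:
    """Integer CHNOPS composition of a molecule or of a mass delta."""

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    p: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "p", "s"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative atom count for {name.upper()}")

    def __add__(self, other: "ElementCounts") -> "ElementCounts":
        return ElementCounts(
            self.c + other.c, self.h + other.h, self.n + other.n,
            self.o + other.o, self.p + other.p, self.s + other.s,
        )

    def __mul__(self, k: int) -> "ElementCounts":
        return ElementCounts(self.c * k, self.h * k, self.n * k,
                             self.o * k, self.p * k, self.s * k)

    __rmul__ = __mul__

    def items(self) -> Iterator[tuple[str, int]]:
        yield from (("C", self.c), ("H", self.h), ("N", self.n),
                    ("O", self.o), ("P", self.p), ("S", self.s))

    @property
    def heteroatoms(self) -> int:
        """Atom count outside C and H."""
        return self.n + self.o + self.p + self.s

    def hill_formula(self) -> str:
        """Hill-notation formula, e.g. ``C6H7NO`` (count 1 is implicit)."""
        parts = []
        for sym, count in (("C", self.c), ("H", self.h), ("N", self.n),
                           ("O", self.o), ("P", self.p), ("S", self.s)):
            if count == 0:
                continue
            parts.append(sym if count == 1 else f"{sym}{count}")
        return "".join(parts)

    @classmethod
    def from_formula(cls, formula: str) -> "ElementCounts":
        """Parse a Hill-notation CHNOPS formula such as ``C2H2O``."""
        counts = {"C": 0, "H": 0, "N": 0, "O": 0, "P": 0, "S": 0}
        pos = 0
        for m in _HILL_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            sym, num = m.group(1), m.group(2)
            if sym not in counts:
                raise ValueError(f"unsupported element {sym!r} in {formula!r}")
            counts[sym] += int(num) if num else 1
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(c=counts["C"], h=counts["H"], n=counts["N"],
                   o=counts["O"], p=counts["P"], s=counts["S"])


WATER = ElementCounts(h=2, o=1)


def composition_mass(comp: ElementCounts, kind: str = "mono") -> float:
    """Exact mass of a composition on the monoisotopic or average scale.

    Parameters
    ----------
    comp:
        The CHNOPS composition.
    kind:
        ``"mono"`` for monoisotopic, ``"average"`` for standard atomic
        weights.

    The result is additive: ``composition_mass(a + b) ==
    composition_mass(a) + composition_mass(b)`` to floating-point precision.
    An empty composition weighs exactly 0.
    """
    if kind == "mono":
        table = MONOISOTOPIC_ELEMENT_MASS
    elif kind == "average":
        table = AVERAGE_ELEMENT_MASS
    else:
        raise ValueError(f"unknown mass kind {kind!r}")
    return sum(table[sym] * count for sym, count in comp.items())


def rdbe(comp: ElementCounts) -> float:
    """Ring-and-double-bond equivalents: ``C - H/2 + N/2 + 1``.

    Phosphorus and sulfur are ignored (both are commonly divalent/pentavalent
    in biomolecules and the simple formula does not capture them; the CHNO
    convention is what the composition filters rely on).  A half-integer
    result marks an odd-electron (radical) composition.
    """
    return comp.c - comp.h / 2.0 + comp.n / 2.0 + 1.0


def is_radical(comp: ElementCounts) -> bool:
    """True when the RDBE is half-integer (odd-electron composition)."""
    return abs(rdbe(comp) * 2 % 2) == 1


# ---------------------------------------------------------------------------
# Residues
# ---------------------------------------------------------------------------

#: Elemental composition of each canonical amino-acid *residue* (the amino
#: acid minus one water, i.e. the in-chain form).
RESIDUE_COMPOSITION: dict[str, ElementCounts] = {
    "G": ElementCounts.from_formula("C2H3NO"),
    "A": ElementCounts.from_formula("C3H5NO"),
    "S": ElementCounts.from_formula("C3H5NO2"),
    "P": ElementCounts.from_formula("C5H7NO"),
    "V": ElementCounts.from_formula("C5H9NO"),
    "T": ElementCounts.from_formula("C4H7NO2"),
    "C": ElementCounts.from_formula("C3H5NOS"),
    "L": ElementCounts.from_formula("C6H11NO"),
    "I": ElementCounts.from_formula("C6H11NO"),
    "N": ElementCounts.from_formula("C4H6N2O2"),
    "D": ElementCounts.from_formula("C4H5NO3"),
    "Q": ElementCounts.from_formula("C5H8N2O2"),
    "K": ElementCounts.from_formula("C6H12N2O"),
    "E": ElementCounts.from_formula("C5H7NO3"),
    "M": ElementCounts.from_formula("C5H9NOS"),
    "H": ElementCounts.from_formula("C6H7N3O"),
    "F": ElementCounts.from_formula("C9H9NO"),
    "R": ElementCounts.from_formula("C6H12N4O"),
    "Y": ElementCounts.from_formula("C9H9NO2"),
    "W": ElementCounts.from_formula("C11H10N2O"),
}

CANONICAL_RESIDUES = frozenset(RESIDUE_COMPOSITION)


def residue_mass_table() -> dict[str, tuple[float, float]]:
    """Immutable-by-convention table residue -> (monoisotopic, average) Da."""
    return {
        aa: (composition_mass(comp, "mono"), composition_mass(comp, "average"))
        for aa, comp in RESIDUE_COMPOSITION.items()
    }


_RESIDUE_MONO = {aa: composition_mass(c, "mono")
                 for aa, c in RESIDUE_COMPOSITION.items()}
_RESIDUE_AVG = {aa: composition_mass(c, "average")
                for aa, c in RESIDUE_COMPOSITION.items()}
WATER_MONO = composition_mass(WATER, "mono")
WATER_AVG = composition_mass(WATER, "average")


def residue_mono_mass(residue: str) -> float:
    try:
        return _RESIDUE_MONO[residue]
    except KeyError:
        raise ValueError(f"unknown residue {residue!r}") from None


# ---------------------------------------------------------------------------
# Modifications
# ---------------------------------------------------------------------------

#: Terminus target flags accepted alongside one-letter residue codes.
TERMINUS_TARGETS = frozenset({"protein_nterm", "peptide_nterm", "peptide_cterm"})


@dataclass(frozen=True)
class Modification:
    """A named modification: a mass delta and the residues it can sit on.

    ``delta`` is the elemental composition of the mass shift when the
    chemistry is known; ``mass`` is a bare monoisotopic delta for
    modifications whose composition is unresolved.  Exactly one of the two
    is required.  Lysine / lysine-valine / lysine-histidine adducts are
    modelled as isopeptide residue additions: the delta is the sum of the
    *residue* compositions (no terminal water), matching attachment through
    the lysine side-chain amine.
    """

    name: str
    targets: frozenset[str]
    mod_class: str
    delta: ElementCounts | None = None
    mass: float | None = None

    def __post_init__(self) -> None:
        if (self.delta is None) == (self.mass is None):
            raise ValueError(
                f"modification {self.name!r}: exactly one of composition or "
                "bare mass must be given")
        bad = self.targets - CANONICAL_RESIDUES - TERMINUS_TARGETS
        if bad:
            raise ValueError(f"modification {self.name!r}: bad targets {bad}")
        if not (-200.0 < self.mono_delta < 1000.0):
            raise ValueError(
                f"modification {self.name!r}: delta {self.mono_delta:.4f} Da "
                "outside (-200, 1000)")

    @property
    def mono_delta(self) -> float:
        if self.delta is not None:
            return composition_mass(self.delta, "mono")
        return float(self.mass)  # type: ignore[arg-type]

    @property
    def average_delta(self) -> float | None:
        """Average-mass delta; None for bare-mass (unknown) modifications."""
        if self.delta is None:
            return None
        return composition_mass(self.delta, "average")

    def applies_to(self, residue: str) -> bool:
        return residue in self.targets


class ModificationRegistry:
    """Name-unique collection of :class:`Modification` entries."""

    def __init__(self, mods: Iterable[Modification] = ()) -> None:
        self._mods: dict[str, Modification] = {}
        for mod in mods:
            self.add(mod)

    def add(self, mod: Modification) -> None:
        if mod.name in self._mods:
            raise ValueError(f"duplicate modification name {mod.name!r}")
        self._mods[mod.name] = mod

    def __getitem__(self, name: str) -> Modification:
        return self._mods[name]

    def __contains__(self, name: str) -> bool:
        return name in self._mods

    def __iter__(self) -> Iterator[Modification]:
        return iter(self._mods.values())

    def __len__(self) -> int:
        return len(self._mods)

    def names(self) -> list[str]:
        return list(self._mods)

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the registry as TSV: name, formula-or-mass, targets, class."""
        lines = ["name\tformula_or_mass\ttargets\tclass"]
        for mod in self:
            spec = (mod.delta.hill_formula() if mod.delta is not None
                    else f"{mod.mass:.6f}")
            lines.append(
                f"{mod.name}\t{spec}\t{','.join(sorted(mod.targets))}\t{mod.mod_class}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ModificationRegistry":
        reg = cls()
        lines = Path(path).read_text().splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            name, spec, targets, mod_class = line.split("\t")
            tgt = frozenset(t for t in targets.split(",") if t)
            try:
                mass = float(spec)
                reg.add(Modification(name=name, targets=tgt,
                                     mod_class=mod_class, mass=mass))
            except ValueError:
                reg.add(Modification(name=name, targets=tgt, mod_class=mod_class,
                                     delta=ElementCounts.from_formula(spec)))
        return reg

    def to_yaml(self, path: str | Path) -> None:
        entries = []
        for mod in self:
            e: dict = {"name": mod.name, "targets": sorted(mod.targets),
                       "class": mod.mod_class}
            if mod.delta is not None:
                e["formula"] = mod.delta.hill_formula()
            else:
                e["mass"] = round(float(mod.mass), 6)
            entries.append(e)
        Path(path).write_text(yaml.safe_dump(entries, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModificationRegistry":
        reg = cls()
        for e in yaml.safe_load(Path(path).read_text()):
            kwargs: dict = {"name": e["name"],
                            "targets": frozenset(e["targets"]),
                            "mod_class": e["class"]}
            if "formula" in e:
                kwargs["delta"] = ElementCounts.from_formula(e["formula"])
            else:
                kwargs["mass"] = float(e["mass"])
            reg.add(Modification(**kwargs))
        return reg


def _mod(name, formula, targets, mod_class=None):
    return Modification(name=name, delta=ElementCounts.from_formula(formula),
                        targets=frozenset(targets),
                        mod_class=mod_class or name)


def registry_default() -> ModificationRegistry:
    """The default linker-histone PTM set.

    Composition-backed entries cover the classical histone marks
    (phosphorylation, acetylation, mono-/di-methylation, formylation,
    crotonylation, propionylation), the unusual ones observed on plant H1
    (methylpyrroline, phosphoglycerol) and the K / KV / KH isopeptide
    amino-acid adducts.  Two recurrent but chemically unresolved shifts are
    carried as bare masses.
    """
    k_res = RESIDUE_COMPOSITION["K"]
    v_res = RESIDUE_COMPOSITION["V"]
    h_res = RESIDUE_COMPOSITION["H"]
    reg = ModificationRegistry([
        _mod("phospho", "HPO3", {"S", "T"}),
        _mod("acetyl", "C2H2O", {"K", "protein_nterm"}),
        _mod("methyl", "CH2", {"K", "N"}),
        _mod("dimethyl", "C2H4", {"K"}),
        _mod("formyl", "CO", {"K"}),
        _mod("crotonyl", "C4H4O", {"K"}),
        _mod("propionyl", "C3H4O", {"K"}),
        _mod("methylpyrroline", "C6H7NO", {"K", "T"}),
        # Assumed glycerophosphate composition; measured values 154.009 and
        # 154.002 Da bracket the theoretical 154.0031.
        _mod("phosphoglycerol", "C3H7O5P", {"S", "T"}),
        Modification(name="K adduct", delta=k_res,
                     targets=frozenset({"K"}), mod_class="aa-adduct"),
        Modification(name="KV adduct", delta=k_res + v_res,
                     targets=frozenset({"K"}), mod_class="aa-adduct"),
        Modification(name="KH adduct", delta=k_res + h_res,
                     targets=frozenset({"K"}), mod_class="aa-adduct"),
        # Unresolved shifts observed on H1: composition unknown.
        Modification(name="unknown-84.020", mass=84.020,
                     targets=frozenset({"K"}), mod_class="unknown"),
        Modification(name="unknown-156.102", mass=156.1016,
                     targets=frozenset({"E", "I"}), mod_class="unknown"),
    ])
    return reg


def peptide_monoisotopic_mass(
    sequence: str,
    mods: Iterable[tuple[int, Modification]] = (),
    nterm_acetyl: bool = False,
) -> float:
    """Neutral monoisotopic mass of a (possibly modified) peptide.

    ``mods`` is an iterable of ``(position, Modification)`` with 1-based
    peptide-local positions.  N-terminal acetylation is passed separately
    because it is a terminus, not a residue, modification.
    """
    if not sequence:
        raise ValueError("empty peptide")
    mass = WATER_MONO
    for ch in sequence:
        try:
            mass += _RESIDUE_MONO[ch]
        except KeyError:
            raise ValueError(f"unknown residue {ch!r}") from None
    for pos, mod in mods:
        if not (1 <= pos <= len(sequence)):
            raise ValueError(f"modification position {pos} outside peptide")
        mass += mod.mono_delta
    if nterm_acetyl:
        mass += composition_mass(ElementCounts.from_formula("C2H2O"), "mono")
    return mass
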