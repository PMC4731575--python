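"""Open delta-mass PTM discovery: localization, refinement, identification.

The inference chain, per spectrum, is:

1. **precursor delta** — observed neutral precursor mass minus the
   theoretical unmodified peptide mass; a non-zero delta (beyond tolerance)
   marks a modified peptide and its total modification mass.
2. **site localization** — the modified residue is bracketed by the fragment
   ladder: b ions below the site fly unshifted, b ions at/after it carry the
   full delta, and symmetrically for y ions; internal ions can shrink the
   bracket further.  A site is accepted only when the bracket closes to a
   single residue.
3. **mass refinement** — the modification mass is re-estimated as the mean
   per-ion shift over matched shifted fragments, preferring low-m/z ions
   where Orbitrap-type analyzers resolve best.
4. **identification** — the refined delta is compared against the
   registered modification set (residue-aware); unknown deltas are handed
   to a bounded elemental-composition search with plausibility filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .chem_core import (
    MONOISOTOPIC_ELEMENT_MASS,
    PROTON_MASS,
    ElementCounts,
    Modification,
    ModificationRegistry,
    composition_mass,
    is_radical,
    peptide_monoisotopic_mass,
    rdbe,
)
from .digestion import PeptideSpan, ProteinRecord
from .fragmentation import FragmentIon, ModifiedPeptide, theoretical_fragments
from .spectra_match import PeakMatch, Spectrum, match_peaks


# ---------------------------------------------------------------------------
# Precursor delta
# ---------------------------------------------------------------------------


def observed_neutral_mass(spectrum: Spectrum) -> float:
    """Neutral (uncharged) precursor mass from m/z and charge."""
    z = spectrum.precursor_charge
    if z < 1:
        raise ValueError("precursor charge must be >= 1")
    return (spectrum.precursor_mz - PROTON_MASS) * z


def precursor_delta(spectrum: Spectrum, peptide: PeptideSpan) -> float:
    """Observed neutral mass minus theoretical unmodified peptide mass."""
    return observed_neutral_mass(spectrum) - peptide_monoisotopic_mass(
        peptide.sequence)


# ---------------------------------------------------------------------------
# Site localization from fragment-shift brackets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalizationResult:
    """Bracketing interval for the modified residue (peptide-local, 1-based).

    ``site_specific`` is true only when the interval closes to one residue
    with shifted/unshifted evidence on each flank (or a terminal bracket).
    ``contradicted`` counts ladder positions observed both shifted and
    unshifted; such positions are excluded from the bracket.  ``ambiguous``
    flags a ladder whose contradictions leave no consistent interpretation
    (contradictions with no clean shifted evidence, or an empty bracket).
    """

    interval: tuple[int, int]
    site_specific: bool
    supporting_b: int = 0
    supporting_y: int = 0
    supporting_internal: int = 0
    ambiguous: bool = False
    contradicted: int = 0

    def __post_init__(self) -> None:
        i, j = self.interval
        if not (1 <= i <= j):
            raise ValueError(f"bad localization interval {self.interval}")


def localize_shift(delta: float, matches: Sequence[PeakMatch],
                   peptide: PeptideSpan | int) -> LocalizationResult:
    """Bracket the modification site from shifted/unshifted fragment matches.

    ``matches`` must come from annotation against a combined plain + shifted
    ladder (:attr:`FragmentIon.shift` distinguishes the two).  Returns the
    smallest interval consistent with the clean part of the ladder: a
    position observed both shifted and unshifted (typically a mass
    coincidence involving a noise or neutral-loss peak) contributes no
    constraint.  The result is flagged ambiguous — never an exception —
    when the contradictions leave no clean shifted evidence at all, or when
    the constraints produce an empty bracket.
    """
    n = peptide if isinstance(peptide, int) else len(peptide.sequence)
    shifted: dict[str, set] = {"b": set(), "y": set(), "internal": set()}
    unshifted: dict[str, set] = {"b": set(), "y": set(), "internal": set()}
    counts = {"b": 0, "y": 0, "internal": 0}
    for m in matches:
        frag = m.fragment
        bucket = shifted if frag.shift else unshifted
        bucket[frag.series].add(frag.pos)
        if frag.shift:
            counts[frag.series] += 1

    n_contradicted = 0
    for series in shifted:
        both = shifted[series] & unshifted[series]
        n_contradicted += len(both)
        shifted[series] -= both
        unshifted[series] -= both
    n_clean_shifted = sum(len(shifted[s]) for s in shifted)
    ambiguous = n_contradicted > 0 and n_clean_shifted == 0

    i_lo, j_hi = 1, n
    lo_evidence = False
    hi_evidence = False
    if unshifted["b"]:
        i_lo = max(i_lo, max(unshifted["b"]) + 1)
        lo_evidence = True
    if shifted["y"]:
        # each shifted y_k places the site in the last k residues; the
        # smallest shifted k gives the tightest lower bound
        i_lo = max(i_lo, n - min(shifted["y"]) + 1)
        lo_evidence = True
    if shifted["b"]:
        j_hi = min(j_hi, min(shifted["b"]))
        hi_evidence = True
    if unshifted["y"]:
        j_hi = min(j_hi, n - max(unshifted["y"]))
        hi_evidence = True
    # internal windows: a shifted internal contains the site, an unshifted
    # one excludes its window (usable only when it trims an end).
    for (a, b) in sorted(shifted["internal"]):
        i_lo = max(i_lo, a)
        j_hi = min(j_hi, b)
        lo_evidence = hi_evidence = True
    for (a, b) in sorted(unshifted["internal"]):
        if a <= i_lo <= b and b < j_hi:
            i_lo = b + 1
            lo_evidence = True
        elif a <= j_hi <= b and a > i_lo:
            j_hi = a - 1
            hi_evidence = True

    if i_lo > j_hi:
        ambiguous = True
        i_lo, j_hi = 1, n

    site_specific = (
        i_lo == j_hi
        and not ambiguous
        and (lo_evidence or i_lo == 1)
        and (hi_evidence or j_hi == n)
    )
    return LocalizationResult(
        interval=(i_lo, j_hi),
        site_specific=site_specific,
        supporting_b=counts["b"],
        supporting_y=counts["y"],
        supporting_internal=counts["internal"],
        ambiguous=ambiguous,
        contradicted=n_contradicted,
    )


# ---------------------------------------------------------------------------
# Modification-mass refinement
# ---------------------------------------------------------------------------


@dataclass
class DeltaObservation:
    """A modified-peptide observation: precursor delta plus per-ion shifts.

    ``ion_shifts`` holds ``(fragment m/z, inferred modification mass)``
    pairs, one per matched shifted fragment (the per-ion mass is the
    observed-minus-theoretical m/z difference scaled by charge).
    """

    peptide: PeptideSpan
    spectrum_title: str
    precursor_delta: float
    ion_shifts: list[tuple[float, float]] = field(default_factory=list)


def ion_shifts_from_matches(matches: Iterable[PeakMatch]) -> list[tuple[float, float]]:
    """Per-ion modification masses from matches against a shifted ladder."""
    shifts = []
    for m in matches:
        frag = m.fragment
        if not frag.shift:
            continue
        plain_mz = frag.mz - frag.shift / frag.charge
        shifts.append((m.observed_mz, (m.observed_mz - plain_mz) * frag.charge))
    return shifts


def estimate_mod_mass(obs: DeltaObservation, mz_cutoff: float = 800.0
                      ) -> tuple[float, int]:
    """Refined modification mass: mean per-ion shift, preferring low m/z.

    Only ions with fragment m/z at or below ``mz_cutoff`` enter the mean
    (resolution of Orbitrap-type analyzers improves toward low m/z); when no
    ion qualifies the mean falls back to all ions.  Returns ``(mass, count
    of ions used)``.
    """
    if not obs.ion_shifts:
        raise ValueError("no ion shifts to average")
    qualifying = [shift for mz, shift in obs.ion_shifts if mz <= mz_cutoff]
    if not qualifying:
        qualifying = [shift for _, shift in obs.ion_shifts]
    return sum(qualifying) / len(qualifying), len(qualifying)


# ---------------------------------------------------------------------------
# Known-PTM matching
# ---------------------------------------------------------------------------


def match_known_ptms(delta: float, registry: ModificationRegistry,
                     residue_context: str, tol: float = 0.01
                     ) -> list[tuple[Modification, float]]:
    """Registry entries within ``tol`` of ``delta`` that target the residue.

    Sorted by absolute mass difference, then name.  All hits are returned —
    near-isobaric alternatives (e.g. dimethyl vs formyl, 0.036 Da apart) are
    the caller's to report, not to silently collapse.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    hits = [(mod, abs(mod.mono_delta - delta)) for mod in registry
            if mod.applies_to(residue_context)
            and abs(mod.mono_delta - delta) <= tol]
    hits.sort(key=lambda md: (md[1], md[0].name))
    return hits


# ---------------------------------------------------------------------------
# Elemental-composition enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterConfig:
    """Plausibility filters for composition enumeration.

    * RDBE must be a non-negative integer unless ``allow_radical`` (a
      half-integer RDBE means an odd-electron species);
    * hydrogen count capped at ``2C + 2 + N`` (saturated-valence bound);
    * element ratios ``O/C`` and ``N/C`` capped (discarding compositions
      with many heteroatoms but few hydrogens/carbons);
    * at most ``n_max`` nitrogens (combinations with four or more N are
      treated as unrealistic for small adducts).

    Carbon-free compositions are only admitted when they carry no N or O
    (the ratio rules are undefined without carbon).
    """

    n_max: int = 3
    allow_radical: bool = False
    max_o_c: float = 1.2
    max_n_c: float = 1.3

    def passes(self, comp: ElementCounts) -> bool:
        r = rdbe(comp)
        if r < 0:
            return False
        if is_radical(comp) and not self.allow_radical:
            return False
        if comp.h > 2 * comp.c + 2 + comp.n:
            return False
        if comp.n > self.n_max:
            return False
        if comp.c == 0:
            return comp.n == 0 and comp.o == 0
        if comp.o / comp.c > self.max_o_c:
            return False
        if comp.n / comp.c > self.max_n_c:
            return False
        return True

    def flags(self, comp: ElementCounts) -> frozenset[str]:
        """Which individual rules the composition satisfies."""
        out = set()
        if rdbe(comp) >= 0 and not is_radical(comp):
            out.add("rdbe")
        if comp.h <= 2 * comp.c + 2 + comp.n:
            out.add("valence")
        if comp.n <= self.n_max:
            out.add("n_count")
        if comp.c > 0 and comp.o / comp.c <= self.max_o_c \
                and comp.n / comp.c <= self.max_n_c:
            out.add("ratios")
        return frozenset(out)


@dataclass(frozen=True)
class CompositionCandidate:
    comp: ElementCounts
    theoretical_mass: float
    abs_diff: float
    rdbe: float
    radical: bool
    filter_flags: frozenset[str]


_H = MONOISOTOPIC_ELEMENT_MASS["H"]


def enumerate_compositions(
    delta: float,
    tol: float,
    elements: str = "CHNO",
    filters: FilterConfig | None = None,
) -> list[CompositionCandidate]:
    """All plausible compositions with monoisotopic mass within ``tol``.

    The search is exhaustive over the requested element set (``CHNO`` by
    default; add ``P``/``S`` for phosphorus- or sulfur-bearing deltas) with
    hydrogen counts solved from the residual mass.  Candidates are sorted by
    absolute mass difference, ties broken toward fewer heteroatoms.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if delta <= 0:
        raise ValueError("delta must be positive")
    filters = filters or FilterConfig()
    elements = set(elements.upper())
    unknown = elements - {"C", "H", "N", "O", "P", "S"}
    if unknown:
        raise ValueError(f"unsupported elements {sorted(unknown)}")

    hi = delta + tol
    masses = MONOISOTOPIC_ELEMENT_MASS
    max_c = int(hi // masses["C"]) if "C" in elements else 0
    max_n = min(filters.n_max, int(hi // masses["N"])) if "N" in elements else 0
    max_o = int(hi // masses["O"]) if "O" in elements else 0
    max_p = int(hi // masses["P"]) if "P" in elements else 0
    max_s = int(hi // masses["S"]) if "S" in elements else 0
    use_h = "H" in elements

    out: list[CompositionCandidate] = []
    for c in range(max_c + 1):
        mc = c * masses["C"]
        if mc > hi:
            break
        for n in range(max_n + 1):
            mn = mc + n * masses["N"]
            if mn > hi:
                break
            for o in range(max_o + 1):
                mo = mn + o * masses["O"]
                if mo > hi:
                    break
                for p in range(max_p + 1):
                    mp = mo + p * masses["P"]
                    if mp > hi:
                        break
                    for s in range(max_s + 1):
                        ms = mp + s * masses["S"]
                        if ms > hi:
                            break
                        residual = delta - ms
                        if use_h:
                            h_center = int(round(residual / _H))
                            h_range = range(max(0, h_center - 1), h_center + 2)
                        else:
                            h_range = range(0, 1)
                        for h in h_range:
                            mass = ms + h * _H
                            diff = abs(mass - delta)
                            if diff > tol:
                                continue
                            comp = ElementCounts(c=c, h=h, n=n, o=o, p=p, s=s)
                            if not filters.passes(comp):
                                continue
                            out.append(CompositionCandidate(
                                comp=comp, theoretical_mass=mass,
                                abs_diff=diff, rdbe=rdbe(comp),
                                radical=is_radical(comp),
                                filter_flags=filters.flags(comp)))
    out.sort(key=lambda cand: (cand.abs_diff, cand.comp.heteroatoms,
                               cand.comp.hill_formula()))
    return out


# ---------------------------------------------------------------------------
# Modification combinations for composite deltas
# ---------------------------------------------------------------------------


def suggest_mod_combinations(
    delta: float,
    registry: ModificationRegistry,
    max_mods: int = 3,
    tol: float = 0.5,
) -> list[tuple[tuple[Modification, ...], float]]:
    """Multisets of up to ``max_mods`` registry entries summing near ``delta``.

    Used to rationalize composite mass shifts such as intact-protein
    satellite peaks.  Returns ``(modifications, |sum - delta|)`` sorted by
    absolute difference; the empty multiset is a legal answer for deltas
    near zero.
    """
    if max_mods < 1:
        raise ValueError("max_mods must be >= 1")
    from itertools import combinations_with_replacement

    mods = sorted(registry, key=lambda m: m.name)
    out = []
    for size in range(0, max_mods + 1):
        for combo in combinations_with_replacement(mods, size):
            total = sum(m.mono_delta for m in combo)
            diff = abs(total - delta)
            if diff <= tol:
                out.append((combo, diff))
    out.sort(key=lambda cd: (cd[1], len(cd[0]), tuple(m.name for m in cd[0])))
    return out


# ---------------------------------------------------------------------------
# Site classification in protein coordinates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifiedSite:
    """A localized modification lifted to Met-inclusive protein coordinates."""

    protein_id: str
    position: int
    residue: str
    mod_class: str
    domain: str | None = None
    evidence: int = 1


def classify_site(result: LocalizationResult, peptide: PeptideSpan,
                  protein: ProteinRecord,
                  mod_class: str = "unknown") -> ClassifiedSite:
    """Convert a site-specific localization to protein coordinates.

    Raises on non-site-specific input: only single-residue assignments make
    it onto the modification map.
    """
    if not result.site_specific:
        raise ValueError("interval not site-specific")
    local = result.interval[0]
    position = peptide.start + local - 1
    residue = peptide.sequence[local - 1]
    return ClassifiedSite(
        protein_id=peptide.protein_id,
        position=position,
        residue=residue,
        mod_class=mod_class,
        domain=protein.domain_of(position),
    )


# ---------------------------------------------------------------------------
# Open-search driver
# ---------------------------------------------------------------------------


def _informative_subset(
    ions: list[FragmentIon],
    tol_ppm: float,
    tol_da: float | None,
) -> list[FragmentIon]:
    """Drop theoretical ions that are isobaric with a different interpretation.

    Two ions of one candidate ladder whose m/z coincide within the matching
    tolerance but which carry different (series, position, shift-state)
    interpretations — e.g. a shifted y_k coinciding with the plain y_(k+1)
    when the delta equals a residue mass, or a plain b_i coinciding with a
    plain internal ion over an anagram of the same residues — are
    indistinguishable to the annotator, so a peak at that m/z carries no
    localization information.  Keeping them would turn such mass
    coincidences into arbitrary assignments and spurious ladder
    contradictions; both members of every colliding pair are removed.
    """
    order = sorted(range(len(ions)), key=lambda i: ions[i].mz)
    drop: set[int] = set()
    for a in range(len(order) - 1):
        i = order[a]
        window = ions[i].mz * tol_ppm * 1e-6
        if tol_da is not None:
            window = min(window, tol_da)
        key_i = (ions[i].series, ions[i].pos, bool(ions[i].shift))
        for b in range(a + 1, len(order)):
            j = order[b]
            if ions[j].mz - ions[i].mz > window:
                break
            if key_i != (ions[j].series, ions[j].pos, bool(ions[j].shift)):
                drop.add(i)
                drop.add(j)
    return [ion for k, ion in enumerate(ions) if k not in drop]


@dataclass
class DiscoveryResult:
    """Everything inferred from one spectrum."""

    spectrum_title: str
    peptide: PeptideSpan
    precursor_delta: float
    n_matched: int
    modified: bool
    localization: LocalizationResult | None = None
    refined_mass: float | None = None
    n_ions_used: int = 0
    site: ClassifiedSite | None = None
    candidates: list[tuple[Modification, float]] = field(default_factory=list)
    compositions: list[CompositionCandidate] = field(default_factory=list)

    @property
    def top_candidate(self) -> Modification | None:
        return self.candidates[0][0] if self.candidates else None


def open_search(
    spectrum: Spectrum,
    peptides: Sequence[PeptideSpan],
    registry: ModificationRegistry,
    proteins: Mapping[str, ProteinRecord],
    *,
    tol_ppm: float = 10.0,
    tol_da: float = 0.01,
    delta_tol: float = 0.01,
    delta_window: tuple[float, float] = (-0.5, 500.0),
    charges: Sequence[int] = (1,),
    include_internal: bool = True,
    mz_cutoff: float = 800.0,
    enumerate_unknown: bool = False,
) -> DiscoveryResult | None:
    """Open (delta-mass-tolerant) search of one spectrum against a digest.

    Each candidate is annotated with its full theoretical ladder (b/y and,
    when ``include_internal``, internal ions; plain + delta-shifted) after
    removing ions isobaric with a different (series, position, shift-state)
    interpretation — e.g. a shifted y_k coinciding with the plain y_(k+1)
    when the delta equals a residue mass, or a b ion coinciding with an
    internal ion over an anagram of the same residues; peaks at such masses
    carry no localization information.

    Candidates are ranked by (1) the fraction of observed peaks their
    ladder explains — the true peptide accounts for essentially the whole
    spectrum, while a sub- or super-peptide of it explains only the shared
    part; this coverage is computed against the unfiltered ladder, since
    the isobar filter removes ions whose interpretation is ambiguous, not
    peaks that are unexplained — then (2) the fraction of b/y ladder
    positions matched against the filtered ladder,
    discounted heavily for positions observed in both shift states (a
    candidate explaining the spectrum only through contradictory
    assignments must not outrank a consistent interpretation), then more
    matched b/y ions, fewer missed cleavages, smaller |delta|.

    For a modified winner the site is localized from the matched ladder
    (with a b/y-only fallback when dense internal evidence leaves the
    bracket open), the modification mass is refined from low-m/z ion
    shifts, and the refined delta is matched against the registry at the
    localized residue.  Returns None when no candidate peptide annotates at
    least two b/y ions.
    """
    neutral = observed_neutral_mass(spectrum)
    lo, hi = delta_window
    n_peaks = max(1, len(spectrum.peaks))
    best: tuple[tuple, PeptideSpan, list[PeakMatch], float] | None = None
    for pep in peptides:
        base_mass = peptide_monoisotopic_mass(pep.sequence)
        delta = neutral - base_mass
        if not (lo <= delta <= hi):
            continue
        mp = ModifiedPeptide(span=pep)
        frags = theoretical_fragments(mp, charges=charges,
                                      include_internal=include_internal,
                                      include_losses=False)
        if abs(delta) > delta_tol:
            frags = frags + [f.with_shift(delta) for f in frags]
        explained = len(match_peaks(spectrum, frags, tol_ppm=tol_ppm,
                                    tol_da=tol_da)) / n_peaks
        frags = _informative_subset(frags, tol_ppm, tol_da)
        matches = match_peaks(spectrum, frags, tol_ppm=tol_ppm, tol_da=tol_da)
        by_states: dict[tuple[str, int | tuple[int, int]], set[bool]] = {}
        for m in matches:
            if m.fragment.series in ("b", "y"):
                by_states.setdefault(
                    (m.fragment.series, m.fragment.pos), set()
                ).add(bool(m.fragment.shift))
        n_by = sum(len(states) for states in by_states.values())
        n_contradicted = sum(1 for states in by_states.values()
                             if len(states) > 1)
        # ladder positions: b_1..b_n plus y_1..y_(n-1)
        by_frac = (n_by - 4 * n_contradicted) / (2 * len(pep.sequence) - 1)
        key = (explained, by_frac, n_by, -pep.missed_cleavages, -abs(delta))
        if n_by - 4 * n_contradicted >= 2 and (best is None or key > best[0]):
            best = (key, pep, matches, delta)
    if best is None:
        return None
    key, pep, matches, delta = best
    n_matched = key[2]  # matched b/y ladder positions

    if abs(delta) <= delta_tol:
        return DiscoveryResult(spectrum_title=spectrum.title, peptide=pep,
                               precursor_delta=delta, n_matched=n_matched,
                               modified=False)

    loc = localize_shift(delta, matches, pep)
    if not loc.site_specific:
        by_only = [m for m in matches if m.fragment.series in ("b", "y")]
        loc_by = localize_shift(delta, by_only, pep)
        if loc_by.site_specific:
            loc = loc_by
    obs = DeltaObservation(peptide=pep, spectrum_title=spectrum.title,
                           precursor_delta=delta,
                           ion_shifts=ion_shifts_from_matches(matches))
    refined, n_used = (None, 0)
    if obs.ion_shifts:
        refined, n_used = estimate_mod_mass(obs, mz_cutoff=mz_cutoff)
    query_mass = refined if refined is not None else delta

    site = None
    candidates: list[tuple[Modification, float]] = []
    if loc.site_specific:
        residue = pep.sequence[loc.interval[0] - 1]
        candidates = match_known_ptms(query_mass, registry, residue,
                                      tol=delta_tol)
        mod_class = candidates[0][0].mod_class if candidates else "unknown"
        site = classify_site(loc, pep, proteins[pep.protein_id],
                             mod_class=mod_class)
    compositions: list[CompositionCandidate] = []
    if enumerate_unknown and not candidates and query_mass > 0:
        compositions = enumerate_compositions(query_mass, tol=delta_tol)

    return DiscoveryResult(
        spectrum_title=spectrum.title, peptide=pep, precursor_delta=delta,
        n_matched=n_matched, modified=True, localization=loc,
        refined_mass=refined, n_ions_used=n_used, site=site,
        candidates=candidates, compositions=compositions)


def results_table(results: Iterable[DiscoveryResult]):
    """Discovery results as a tidy table (TSV/JSON-ready)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "title": r.spectrum_title,
            "protein_id": r.peptide.protein_id,
            "peptide": r.peptide.sequence,
            "start": r.peptide.start,
            "end": r.peptide.end,
            "precursor_delta": r.precursor_delta,
            "modified": r.modified,
            "refined_mass": r.refined_mass,
            "n_ions_used": r.n_ions_used,
            "interval": (f"{r.localization.interval[0]}-{r.localization.interval[1]}"
                         if r.localization else ""),
            "site_specific": bool(r.localization and r.localization.site_specific),
            "protein_position": r.site.position if r.site else None,
            "residue": r.site.residue if r.site else "",
            "domain": (r.site.domain or "") if r.site else "",
            "top_hits": ";".join(f"{m.name}:{d:.4f}" for m, d in r.candidates),
            "compositions": ";".join(
                f"{c.comp.hill_formula()}:{c.abs_diff:.4f}"
                for c in r.compositions[:3]),
            "n_matched": r.n_matched,
        })
    return pd.DataFrame(rows)
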