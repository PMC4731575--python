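"""Ground-truthed synthetic inputs: proteins, planted PTMs, noisy spectra.

The generator emulates the statistical structure of a linker-histone
bottom-up experiment so that every pipeline stage can be exercised without
any external data:

* **proteins** with H1-like architecture — an acidic N-terminal segment, a
  globular-domain-like core, and a lysine-rich C-terminal tail;
* **planted modifications** drawn from the registered PTM set, placed only
  on residues each modification targets;
* **spectra** built from theoretical HCD ladders of the digest peptides,
  perturbed by Gaussian relative (ppm) mass error, thinned by random peak
  dropout, and contaminated with uniform noise peaks.

Intensities follow a rank-based exponential decay with no physical meaning;
no inference step reads them.  Identical config + seed gives byte-identical
output files.

The module also provides :func:`reference_variants`: three **synthetic
stand-in** sequences for the H1.2 / H1.1 / H1.2-splice variants, built with
the right domain architecture and lengths and mass-tuned by construction to
the reported intact average masses (28.45, 28.92 and 21.56 kDa).  They are
fixtures for the intact-mass stage, not real TAIR sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem_core import (
    PROTON_MASS,
    Modification,
    ModificationRegistry,
    registry_default,
    _RESIDUE_AVG,
)
from .digestion import PeptideSpan, ProteinRecord, digest
from .fragmentation import ModifiedPeptide, theoretical_fragments
from .ptm_discovery import open_search
from .spectra_match import Spectrum

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions.

    ``ppm_sigma`` (Gaussian relative mass error, default 3 ppm) and
    ``dropout_prob`` (fraction of fragment peaks deleted, default 0.1)
    define the noise regime; ``mod_density`` is the expected number of
    planted modifications per 100 residues.
    """

    seed: int = 0
    n_proteins: int = 3
    length_range: tuple[int, int] = (200, 260)
    lysine_enrichment: float = 0.3
    mod_density: float = 2.0
    registry_subset: tuple[str, ...] | None = None
    ppm_sigma: float = 3.0
    dropout_prob: float = 0.1
    noise_peaks_per_spectrum: int = 10
    fragment_charges: tuple[int, ...] = (1,)
    precursor_charges: tuple[tuple[int, float], ...] = ((2, 0.6), (3, 0.4))
    protease: str = "trypsin"
    max_missed: int = 2
    min_len: int = 6
    max_len: int = 30
    include_internal: bool = True
    n_unmodified_per_protein: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")
        if not (0.0 <= self.lysine_enrichment <= 1.0):
            raise ValueError("lysine_enrichment must be in [0, 1]")
        if self.ppm_sigma < 0:
            raise ValueError("ppm_sigma must be >= 0")
        lo, hi = self.length_range
        if not (10 <= lo <= hi):
            raise ValueError("invalid length_range")
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")


@dataclass(frozen=True)
class PlantedSite:
    """One planted modification in Met-inclusive protein coordinates."""

    protein_id: str
    position: int
    residue: str
    mod_name: str
    mod_class: str


@dataclass(frozen=True)
class SpectrumRecord:
    """Provenance of one emitted spectrum."""

    title: str
    protein_id: str
    start: int
    end: int
    sequence: str
    mod_name: str | None  # None for unmodified spectra
    mod_class: str | None
    local_position: int | None
    planted_delta: float
    protein_position: int | None


@dataclass
class GroundTruth:
    sites: list[PlantedSite] = field(default_factory=list)
    spectra: list[SpectrumRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Proteome generation
# ---------------------------------------------------------------------------

_ACIDIC_POOL = list("EEDDAASTPV")
_CORE_POOL = list("AAVLIFSTGEKKRNQY")
_TAIL_FILLER = list("AAPPTTSVG")


def _sample(rng: np.random.Generator, pool: Sequence[str], k: int) -> list[str]:
    return [pool[i] for i in rng.integers(0, len(pool), size=k)]


def generate_proteome(cfg: SimulationConfig) -> list[ProteinRecord]:
    """Random H1-like proteins, deterministic under the config seed.

    Each protein is an acidic N-segment (~20% of the length), a core with
    globular-domain-like composition (~35%) and a K-rich C-tail where each
    position is lysine with probability ``lysine_enrichment``.
    """
    rng = np.random.default_rng(cfg.seed)
    proteins = []
    for idx in range(cfg.n_proteins):
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        n_acid = max(4, int(0.2 * length))
        n_core = max(4, int(0.35 * length))
        n_tail = length - n_acid - n_core - 1  # -1 for the initial serine
        seq = ["S"]
        seq += _sample(rng, _ACIDIC_POOL, n_acid)
        seq += _sample(rng, _CORE_POOL, n_core)
        for _ in range(n_tail):
            if rng.random() < cfg.lysine_enrichment:
                seq.append("K")
            else:
                seq.append(_TAIL_FILLER[int(rng.integers(0, len(_TAIL_FILLER)))])
        sequence = "".join(seq)
        # Met-inclusive numbering: mature chain starts at 2.
        ntd_end = 1 + n_acid + 1
        gh1_end = ntd_end + n_core
        proteins.append(ProteinRecord(
            id=f"SYN{idx + 1:03d}",
            sequence=sequence,
            description="synthetic H1-like protein",
            met_removed=True,
            domain_annotations=(("NTD", 2, ntd_end),
                                ("GH1", ntd_end + 1, gh1_end),
                                ("CTD", gh1_end + 1, 1 + len(sequence))),
        ))
    return proteins


# ---------------------------------------------------------------------------
# Modification planting
# ---------------------------------------------------------------------------


def _assignable(protein: ProteinRecord, position: int, mod: Modification,
                tol: float = 0.02) -> bool:
    """Whether a modification at this position is assignable in principle.

    A mass shift equal (within fragment tolerance) to the mass of one
    residue, or of a pair of contiguous residues, immediately adjacent to
    the site is indistinguishable from a sequence extension or branch of
    the linear chain — e.g. a lysine isopeptide adduct on a lysine that
    neighbours another lysine, or an arginine-mass shift next to an
    arginine.  Such sites cannot be localized from spectra by any method
    and are not planted (the pipeline's recovery metric covers assignable
    modifications, mirroring the restriction of PTM discovery to sites that
    MS/MS evidence can pin down).
    """
    from .chem_core import _RESIDUE_MONO

    offset = protein.numbering_offset
    idx = position - offset  # 0-based in mature sequence
    seq = protein.sequence
    delta = mod.mono_delta
    windows = [(idx - 1, idx), (idx + 1, idx + 2),
               (idx - 2, idx), (idx + 1, idx + 3)]
    for a, b in windows:
        if 0 <= a and b <= len(seq) and a < b:
            if abs(delta - sum(_RESIDUE_MONO[ch] for ch in seq[a:b])) <= tol:
                return False
    return True


def plant_modifications(
    proteins: Sequence[ProteinRecord],
    cfg: SimulationConfig,
    registry: ModificationRegistry | None = None,
) -> GroundTruth:
    """Plant sites respecting each modification's residue targets.

    The number of planted sites per protein is ``mod_density`` per 100
    residues in expectation.  Only assignable sites are planted (see
    :func:`_assignable`).  A registry entry with no valid target residue in
    a protein is skipped with a log entry.
    """
    registry = registry or registry_default()
    if cfg.registry_subset is not None:
        mods = [registry[name] for name in cfg.registry_subset]
    else:
        mods = list(registry)
    if not mods:
        raise ValueError("empty registry subset")
    rng = np.random.default_rng(cfg.seed + 1)
    truth = GroundTruth()
    for protein in proteins:
        n_sites = int(rng.poisson(cfg.mod_density / 100.0 * len(protein.sequence)))
        occupied: set[int] = set()
        for _ in range(n_sites):
            mod = mods[int(rng.integers(0, len(mods)))]
            eligible = [
                pos for pos in range(protein.numbering_offset,
                                     protein.numbering_offset + len(protein.sequence))
                if protein.residue_at(pos) in mod.targets and pos not in occupied
                and _assignable(protein, pos, mod)
            ]
            if not eligible:
                logger.info("no eligible residue for %s in %s; skipped",
                            mod.name, protein.id)
                continue
            pos = int(eligible[int(rng.integers(0, len(eligible)))])
            occupied.add(pos)
            truth.sites.append(PlantedSite(
                protein_id=protein.id, position=pos,
                residue=protein.residue_at(pos),
                mod_name=mod.name, mod_class=mod.mod_class))
    truth.sites.sort(key=lambda s: (s.protein_id, s.position))
    return truth


# ---------------------------------------------------------------------------
# Spectrum simulation
# ---------------------------------------------------------------------------


def _pick_span(spans: Sequence[PeptideSpan], position: int
               ) -> PeptideSpan | None:
    """Smallest digest span containing a Met-inclusive position."""
    covering = [s for s in spans if s.start <= position <= s.end]
    if not covering:
        return None
    covering.sort(key=lambda s: (s.missed_cleavages, s.end - s.start, s.start))
    return covering[0]


def _emit_spectrum(
    rng: np.random.Generator,
    title: str,
    mp: ModifiedPeptide,
    cfg: SimulationConfig,
    registry: ModificationRegistry,
) -> Spectrum:
    ions = theoretical_fragments(
        mp, charges=cfg.fragment_charges,
        include_internal=cfg.include_internal, include_losses=True)
    mzs = np.array([ion.mz for ion in ions])
    # Gaussian relative mass error
    mzs = mzs * (1.0 + rng.normal(0.0, cfg.ppm_sigma * 1e-6, size=mzs.size))
    # rank-based exponential intensity decay (no physical meaning)
    ranks = rng.permutation(mzs.size)
    intensities = 1e4 * np.exp(-ranks / 30.0)
    # dropout
    keep = rng.random(mzs.size) >= cfg.dropout_prob
    mzs, intensities = mzs[keep], intensities[keep]
    peaks = list(zip(mzs.tolist(), intensities.tolist()))
    # noise peaks, uniform over the observed m/z range, at the 10th
    # percentile of signal intensity
    if cfg.noise_peaks_per_spectrum and len(peaks):
        lo, hi = 100.0, float(max(mz for mz, _ in peaks)) + 50.0
        floor = float(np.percentile(intensities, 10)) if len(intensities) else 1.0
        for _ in range(cfg.noise_peaks_per_spectrum):
            peaks.append((float(rng.uniform(lo, hi)), floor))
    # precursor
    charges, probs = zip(*cfg.precursor_charges)
    z = int(rng.choice(charges, p=np.array(probs) / sum(probs)))
    neutral = mp.neutral_mass()
    premz = (neutral + z * PROTON_MASS) / z
    premz *= 1.0 + rng.normal(0.0, cfg.ppm_sigma * 1e-6)
    return Spectrum(title=title, precursor_mz=premz, precursor_charge=z,
                    peaks=peaks)


def simulate_digest_spectra(
    proteins: Sequence[ProteinRecord],
    truth: GroundTruth,
    cfg: SimulationConfig,
    registry: ModificationRegistry | None = None,
) -> tuple[list[Spectrum], GroundTruth]:
    """Noisy HCD spectra for planted-modification and unmodified peptides.

    One spectrum is emitted per planted site (the smallest digest peptide
    covering it, carrying only that modification — emulating molecule
    subpopulations each bearing a single mark), plus a few unmodified
    peptides per protein.  Deterministic under the config seed; the
    returned :class:`GroundTruth` gains per-spectrum provenance records.
    """
    registry = registry or registry_default()
    rng = np.random.default_rng(cfg.seed + 2)
    spectra: list[Spectrum] = []
    records: list[SpectrumRecord] = []
    by_protein = {p.id: p for p in proteins}
    spans_cache: dict[str, list[PeptideSpan]] = {
        p.id: digest(p, cfg.protease, cfg.max_missed, cfg.min_len, cfg.max_len)
        for p in proteins
    }
    counter = 0
    for site in truth.sites:
        span = _pick_span(spans_cache[site.protein_id], site.position)
        if span is None:
            logger.info("no digest peptide covers %s:%d; site not observable",
                        site.protein_id, site.position)
            continue
        local = site.position - span.start + 1
        mod = registry[site.mod_name]
        mp = ModifiedPeptide(span=span, placements=((local, mod),))
        title = f"synspec_{counter:04d}"
        counter += 1
        spectra.append(_emit_spectrum(rng, title, mp, cfg, registry))
        records.append(SpectrumRecord(
            title=title, protein_id=span.protein_id, start=span.start,
            end=span.end, sequence=span.sequence, mod_name=mod.name,
            mod_class=mod.mod_class, local_position=local,
            planted_delta=mod.mono_delta, protein_position=site.position))
    for protein in proteins:
        spans = spans_cache[protein.id]
        if not spans:
            continue
        planted_positions = {s.position for s in truth.sites
                             if s.protein_id == protein.id}
        clean = [s for s in spans
                 if not any(s.start <= pos <= s.end for pos in planted_positions)]
        pool = clean or spans
        for _ in range(cfg.n_unmodified_per_protein):
            span = pool[int(rng.integers(0, len(pool)))]
            mp = ModifiedPeptide(span=span)
            title = f"synspec_{counter:04d}"
            counter += 1
            spectra.append(_emit_spectrum(rng, title, mp, cfg, registry))
            records.append(SpectrumRecord(
                title=title, protein_id=span.protein_id, start=span.start,
                end=span.end, sequence=span.sequence, mod_name=None,
                mod_class=None, local_position=None, planted_delta=0.0,
                protein_position=None))
    out = GroundTruth(sites=list(truth.sites), spectra=records)
    return spectra, out


def truth_table(truth: GroundTruth):
    """Per-spectrum ground truth as a tidy table (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame([{
        "title": r.title, "protein_id": r.protein_id, "start": r.start,
        "end": r.end, "sequence": r.sequence,
        "mod_name": r.mod_name or "", "mod_class": r.mod_class or "",
        "local_position": r.local_position,
        "protein_position": r.protein_position,
        "planted_delta": r.planted_delta} for r in truth.spectra])


# ---------------------------------------------------------------------------
# End-to-end recovery
# ---------------------------------------------------------------------------


def recovery_rate(
    spectra: Sequence[Spectrum],
    truth: GroundTruth,
    proteins: Sequence[ProteinRecord],
    registry: ModificationRegistry | None = None,
    cfg: SimulationConfig | None = None,
    **search_kwargs,
) -> tuple[float, int, int]:
    """Fraction of planted single-site modifications fully recovered.

    A planted modification counts as recovered when the open search picks a
    peptide covering the true protein position, localizes the shift
    site-specifically at that position, and ranks the planted modification
    as the top registry hit.  Returns ``(rate, n_recovered, n_planted)``.
    """
    registry = registry or registry_default()
    cfg = cfg or SimulationConfig()
    peptides: list[PeptideSpan] = []
    for p in proteins:
        peptides.extend(digest(p, cfg.protease, cfg.max_missed,
                               cfg.min_len, cfg.max_len))
    by_protein = {p.id: p for p in proteins}
    by_title = {r.title: r for r in truth.spectra}
    n_planted = 0
    n_recovered = 0
    for spectrum in spectra:
        rec = by_title[spectrum.title]
        if rec.mod_name is None:
            continue
        n_planted += 1
        result = open_search(spectrum, peptides, registry, by_protein,
                             include_internal=cfg.include_internal,
                             charges=cfg.fragment_charges, **search_kwargs)
        if result is None or not result.modified or result.site is None:
            continue
        top = result.top_candidate
        if (result.site.position == rec.protein_position
                and top is not None and top.name == rec.mod_name):
            n_recovered += 1
    rate = n_recovered / n_planted if n_planted else 0.0
    return rate, n_recovered, n_planted


# ---------------------------------------------------------------------------
# Synthetic reference variants (mass-matched stand-ins)
# ---------------------------------------------------------------------------

# Residue pool for mass tuning. Substitution granularity spans ~0.04 Da
# (K<->Q) through ~1 Da (D<->N, E<->Q) to tens of Da (A<->V, A<->K), so a
# greedy tuner converges to well under 0.1 Da.
_TUNE_POOL = "GASTVKPQEND"


def _fit_segment(seq: list[str], positions: Sequence[int], target: float,
                 tol: float = 0.05, max_steps: int = 400) -> None:
    """Greedily substitute residues at ``positions`` until the summed
    average residue mass of the whole ``seq`` list hits ``target``."""
    current = sum(_RESIDUE_AVG[ch] for ch in seq)
    for _ in range(max_steps):
        diff = target - current
        if abs(diff) <= tol:
            return
        best: tuple[float, int, str] | None = None
        for pos in positions:
            old_mass = _RESIDUE_AVG[seq[pos]]
            for new in _TUNE_POOL:
                gain = _RESIDUE_AVG[new] - old_mass
                resid = abs(diff - gain)
                if best is None or resid < best[0] - 1e-12:
                    best = (resid, pos, new)
        if best is None or best[0] >= abs(diff) - 1e-12:
            return
        _, pos, new = best
        current += _RESIDUE_AVG[new] - _RESIDUE_AVG[seq[pos]]
        seq[pos] = new


def _pad(segment: str, length: int) -> str:
    return (segment + "A" * length)[:length]


def reference_variants() -> list[ProteinRecord]:
    """Three synthetic stand-ins for the H1.2 / H1.1 / H1.2-splice variants.

    The sequences are **not** the real TAIR entries (which are not bundled);
    they reproduce the variants' architecture — Met start (removed in the
    mature chain), acidic N-segment, globular core, S/TPxK-bearing K-rich
    tail — at lengths 273, 276 and 203 (Met-inclusive), and are tuned by
    construction so the mature average masses match the reported intact
    masses: 28 450, 28 920 and 21 560 Da.  The splice stand-in is the H1.2
    stand-in with a 70-residue block of the C-terminal domain removed.
    """
    # --- H1.2-like, 273 aa Met-inclusive -------------------------------
    nterm = "MS"
    acidic = _pad("EETAPAEEAVDSPAAEEKSPTEA", 23)           # pos 3-25
    basic = _pad("KKAPAKRSPAKAKAVKPKAAKPKATKSPAKKARKA", 35)  # pos 26-60
    gh1 = _pad("AELVKNAIAELKERSGSSPQAIKKYIAANYKVDAEKLAPFIK"
               "KYLKSAVASGKLVQTKGTGASGSFKL", 70)             # pos 61-130
    ctd_a = _pad("KATPVKAKSPAKAKAVAKPKSPAKAAKPKTPVKAK", 35)  # pos 131-165
    block = _pad("KAAKPKAAKAKSPAKKAATPKKAAVKPKAAKPKTAAKPKA"
                 "VAKPQKAAKPKAAVKKPAAKSPAKAKAVKA", 70)       # pos 166-235
    ctd_b = _pad("KSPAKAKATPKKAAKPKAAKAKSPTKAKAAQKPEKAAK", 38)  # pos 236-273

    full = list(nterm + acidic + basic + gh1 + ctd_a + block + ctd_b)
    assert len(full) == 273

    def _tunable(lo: int, hi: int) -> list[int]:
        """0-based indices in [lo, hi) currently holding pool residues and
        not part of an S/TPxK motif window."""
        joined = "".join(full)
        protected = set()
        for i in range(len(joined) - 3):
            if joined[i] in "ST" and joined[i + 1] == "P" and joined[i + 3] == "K":
                protected.update(range(i, i + 4))
        return [i for i in range(lo, hi)
                if i not in protected and full[i] in _TUNE_POOL]

    mature_target = 28450.0 - 18.015  # summed residue masses of the mature chain
    block_target = 28450.0 - 21560.0  # removing the block leaves the splice mass
    block_lo, block_hi = 165, 235     # 0-based slice of the deletion block
    _fit_segment(full, [i for i in _tunable(block_lo, block_hi)],
                 target=sum(_RESIDUE_AVG[ch] for ch in full)
                 - sum(_RESIDUE_AVG[ch] for ch in full[block_lo:block_hi])
                 + block_target)
    # now fix the total using positions outside the block (and outside Met)
    outside = [i for i in _tunable(2, block_lo) + _tunable(block_hi, 273)]
    _fit_segment(full, outside,
                 target=mature_target + _RESIDUE_AVG["M"])  # seq still holds Met
    h12_full = "".join(full)
    h12 = ProteinRecord(
        id="H1.2-syn", sequence=h12_full[1:],
        description="synthetic stand-in mass-matched to 28.45 kDa",
        met_removed=True,
        domain_annotations=(("NTD", 2, 60), ("GH1", 61, 130), ("CTD", 131, 273)))

    splice_seq = h12_full[1:block_lo] + h12_full[block_hi:]
    splice = ProteinRecord(
        id="H1.2s-syn", sequence=splice_seq,
        description="synthetic stand-in splice variant mass-matched to 21.56 kDa",
        met_removed=True,
        domain_annotations=(("NTD", 2, 60), ("GH1", 61, 130), ("CTD", 131, 203)))

    # --- H1.1-like, 276 aa Met-inclusive -------------------------------
    acidic1 = _pad("EEVTTPAEEAKDSPAEEAKVSPTEAAEE", 28)       # pos 3-30
    basic1 = _pad("KKPAAKRSPAKAKAVKPKAAKPKTAKSPAKKAR", 33)   # pos 31-63
    gh11 = _pad("AELVKNAIAELKERSGSSPQAIKKYIAANYKVDAEKLAPFIK"
                "KYLESAVAKGKLVQTKGTGASGSFKL", 70)            # pos 64-133
    ctd1 = _pad("KATPVKAKSPAKAKAVAKPKSPAKAAKPKTPVKAKKAAKPKAAKAKSP"
                "AKKAATPKKAAVKPKAAKPKTAAKPKAVAKPQKAAKPKAAVKKPAAKSPAKAKAV"
                "KAKSPAKAKATPKKAAKPKAAKAKSPTKAKAAQKPE", 143)  # pos 134-276
    full1 = list("MS" + acidic1 + basic1 + gh11 + ctd1)
    assert len(full1) == 276
    full = full1  # reuse _tunable closure over `full`
    _fit_segment(full1, _tunable(2, 276),
                 target=28920.0 - 18.015 + _RESIDUE_AVG["M"])
    h11 = ProteinRecord(
        id="H1.1-syn", sequence="".join(full1)[1:],
        description="synthetic stand-in mass-matched to 28.92 kDa",
        met_removed=True,
        domain_annotations=(("NTD", 2, 63), ("GH1", 64, 133), ("CTD", 134, 276)))

    return [h12, h11, splice]
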