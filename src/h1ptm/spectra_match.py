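"""MGF spectrum I/O and tolerance-based peak annotation.

Mascot Generic Format (MGF) is the single spectrum format of the pipeline:
centroided peak lists in ``BEGIN IONS``/``END IONS`` blocks with ``PEPMASS``
and ``CHARGE`` headers.  Parsing is delegated to :mod:`pyteomics.mgf`; a
light structural pre-scan runs first so that malformed files fail with the
offending line number rather than deep inside the parser.

Peak-to-fragment assignment is greedy nearest-match under a dual tolerance:
a ppm window capped by an absolute window in Da (whichever is tighter at a
given m/z), reflecting instrument behaviour where relative accuracy rules at
low m/z and the absolute floor at high m/z.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _pyteomics_mgf

from .fragmentation import FragmentIon


class MGFFormatError(ValueError):
    """Structural problem in an MGF file, reported with a line number."""


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum.

    ``peaks`` is a list of ``(mz, intensity)`` kept sorted by m/z; ``params``
    preserves any MGF headers beyond the canonical ones so that round-trips
    are lossless.
    """

    title: str
    precursor_mz: float
    precursor_charge: int
    peaks: list[tuple[float, float]] = field(default_factory=list)
    params: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("non-positive precursor m/z")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        if any(inten < 0 for _, inten in self.peaks):
            raise ValueError("negative peak intensity")
        self.peaks = sorted(self.peaks)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([mz for mz, _ in self.peaks])


@dataclass(frozen=True)
class PeakMatch:
    """An observed peak assigned to one theoretical fragment."""

    fragment: FragmentIon
    observed_mz: float
    error_ppm: float
    intensity: float


# ---------------------------------------------------------------------------
# MGF I/O
# ---------------------------------------------------------------------------

_CANONICAL_KEYS = {"title", "pepmass", "charge"}


def _prescan_mgf(path: Path) -> None:
    """Validate block structure; raise MGFFormatError with a line number."""
    in_block = False
    block_start = 0
    has_pepmass = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line == "BEGIN IONS":
            if in_block:
                raise MGFFormatError(
                    f"line {lineno}: nested BEGIN IONS (block opened at "
                    f"line {block_start} not closed)")
            in_block, block_start, has_pepmass = True, lineno, False
        elif line == "END IONS":
            if not in_block:
                raise MGFFormatError(f"line {lineno}: END IONS without BEGIN IONS")
            if not has_pepmass:
                raise MGFFormatError(
                    f"line {lineno}: block starting at line {block_start} "
                    "has no PEPMASS")
            in_block = False
        elif in_block and line.startswith("PEPMASS"):
            has_pepmass = True
    if in_block:
        raise MGFFormatError(
            f"block starting at line {block_start} never closed (missing END IONS)")


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read all spectra from an MGF file.

    CHARGE values in the ``2+`` dialect are parsed as +2.  Headers beyond
    TITLE/PEPMASS/CHARGE are preserved in :attr:`Spectrum.params`.
    """
    path = Path(path)
    _prescan_mgf(path)
    spectra = []
    with _pyteomics_mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = dict(entry["params"])
            title = str(params.pop("title", ""))
            pepmass = params.pop("pepmass")
            precursor_mz = float(pepmass[0] if isinstance(pepmass, tuple) else pepmass)
            charge_field = params.pop("charge", [1])
            charge = abs(int(charge_field[0]))
            extra = {str(k): str(v) for k, v in params.items()}
            peaks = list(zip(entry["m/z array"].tolist(),
                             entry["intensity array"].tolist()))
            spectra.append(Spectrum(title=title, precursor_mz=precursor_mz,
                                    precursor_charge=charge, peaks=peaks,
                                    params=extra))
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with 6-decimal m/z (lossless at read precision)."""
    lines: list[str] = []
    for sp in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={sp.title}")
        lines.append(f"PEPMASS={sp.precursor_mz:.6f}")
        lines.append(f"CHARGE={sp.precursor_charge}+")
        for key, value in sp.params.items():
            lines.append(f"{key.upper()}={value}")
        for mz, inten in sp.peaks:
            lines.append(f"{mz:.6f} {inten:.6f}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Peak matching
# ---------------------------------------------------------------------------


def match_peaks(
    spectrum: Spectrum,
    theoretical: Sequence[FragmentIon],
    tol_ppm: float = 10.0,
    tol_da: float | None = 0.01,
) -> list[PeakMatch]:
    """Greedy nearest assignment of observed peaks to theoretical fragments.

    The effective window at fragment m/z *m* is ``min(m * tol_ppm * 1e-6,
    tol_da)``.  Candidate pairs are consumed in order of increasing absolute
    error (ties toward lower observed m/z), and each observed peak and each
    fragment is used at most once.  The result is independent of the input
    peak order because peaks are kept canonically sorted.
    """
    if tol_ppm <= 0 or (tol_da is not None and tol_da <= 0):
        raise ValueError("tolerances must be positive")
    if not spectrum.peaks or not theoretical:
        return []
    mzs = [mz for mz, _ in spectrum.peaks]
    candidates: list[tuple[float, float, int, int]] = []
    for fi, frag in enumerate(theoretical):
        window = frag.mz * tol_ppm * 1e-6
        if tol_da is not None:
            window = min(window, tol_da)
        lo = bisect.bisect_left(mzs, frag.mz - window)
        hi = bisect.bisect_right(mzs, frag.mz + window)
        for pi in range(lo, hi):
            err = abs(mzs[pi] - frag.mz)
            candidates.append((err, mzs[pi], fi, pi))
    candidates.sort()
    used_peaks: set[int] = set()
    used_frags: set[int] = set()
    matches: list[PeakMatch] = []
    for err, omz, fi, pi in candidates:
        if pi in used_peaks or fi in used_frags:
            continue
        used_peaks.add(pi)
        used_frags.add(fi)
        frag = theoretical[fi]
        matches.append(PeakMatch(
            fragment=frag,
            observed_mz=omz,
            error_ppm=(omz - frag.mz) / frag.mz * 1e6,
            intensity=spectrum.peaks[pi][1],
        ))
    matches.sort(key=lambda m: m.observed_mz)
    return matches


def annotation_table(spectrum: Spectrum, matches: Iterable[PeakMatch]):
    """Annotation result as a tidy table (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [{"title": spectrum.title, "ion": m.fragment.label,
          "theoretical_mz": m.fragment.mz, "observed_mz": m.observed_mz,
          "error_ppm": m.error_ppm, "intensity": m.intensity}
         for m in matches])
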