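"""In-silico protease digestion and sequence-coverage accounting.

Four endoproteases are modelled, matching the experimental workflow the
pipeline reproduces:

======== ======================================================
trypsin   cleaves C-terminal to K or R, suppressed before P
argc      cleaves C-terminal to R, suppressed before P
thermolysin  cleaves N-terminal to L, I, A, F, V or M
pepsin    cleaves C-terminal to F or L
======== ======================================================

Cleavage is strict (every rule site is cut, up to the missed-cleavage
budget).  Pepsin in particular only cleaves "preferentially" in vitro; the
strict rule is a documented, reproducible simplification and both the
"not before proline" suppression and the rule sets are configurable.

Coordinates are 1-based, inclusive, and **Met-inclusive**: position 1 is the
initiator methionine even when the mature protein lacks it, so that site
labels (K70, T59, ...) agree with the standard numbering of mature histones.
A mature chain with the Met removed therefore starts at position 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem_core import CANONICAL_RESIDUES


@dataclass(frozen=True)
class ProteinRecord:
    """A mature protein chain with Met-inclusive numbering metadata.

    ``sequence`` is the mature chain (initiator Met absent when
    ``met_removed``); ``domain_annotations`` are ``(label, start, end)``
    intervals in Met-inclusive coordinates.
    """

    id: str
    sequence: str
    description: str = ""
    met_removed: bool = False
    domain_annotations: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty protein sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"non-canonical residues {sorted(bad)} in {self.id}")
        last = self.numbering_offset + len(self.sequence) - 1
        for label, start, end in self.domain_annotations:
            if not (1 <= start <= end <= last):
                raise ValueError(
                    f"domain {label!r} interval ({start},{end}) outside [1,{last}]")

    @property
    def numbering_offset(self) -> int:
        """Met-inclusive position of the first mature residue (2 if Met removed)."""
        return 2 if self.met_removed else 1

    def residue_at(self, position: int) -> str:
        """Residue at a Met-inclusive position."""
        idx = position - self.numbering_offset
        if not (0 <= idx < len(self.sequence)):
            raise ValueError(f"position {position} outside {self.id}")
        return self.sequence[idx]

    def domain_of(self, position: int) -> str | None:
        for label, start, end in self.domain_annotations:
            if start <= position <= end:
                return label
        return None


@dataclass(frozen=True)
class PeptideSpan:
    """A digest product located on its parent protein.

    ``start``/``end`` are Met-inclusive 1-based inclusive coordinates.
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    protease: str
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("reversed peptide span")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("span length disagrees with sequence")


#: protease -> (residue set, side) where side is "C" (cleave after the
#: residue) or "N" (cleave before it).
PROTEASE_RULES: dict[str, tuple[frozenset[str], str]] = {
    "trypsin": (frozenset("KR"), "C"),
    "argc": (frozenset("R"), "C"),
    "thermolysin": (frozenset("LIAFVM"), "N"),
    "pepsin": (frozenset("FL"), "C"),
}

#: proteases whose C-side cleavage is suppressed when the next residue is P.
_PROLINE_SUPPRESSED = frozenset({"trypsin", "argc"})


def cleavage_sites(sequence: str, protease: str,
                   proline_rule: bool = True) -> list[int]:
    """0-based cut points: a site ``i`` cuts between ``seq[i-1]`` and ``seq[i]``.

    Terminal cut points (0 and len) are not included.
    """
    try:
        residues, side = PROTEASE_RULES[protease]
    except KeyError:
        raise ValueError(f"unknown protease {protease!r}") from None
    sites = []
    for i in range(1, len(sequence)):
        if side == "C":
            if sequence[i - 1] in residues:
                if (proline_rule and protease in _PROLINE_SUPPRESSED
                        and sequence[i] == "P"):
                    continue
                sites.append(i)
        else:  # N-side
            if sequence[i] in residues:
                sites.append(i)
    return sites


def digest(protein: ProteinRecord, protease: str, max_missed: int = 2,
           min_len: int = 5, max_len: int = 40,
           proline_rule: bool = True) -> list[PeptideSpan]:
    """All digest peptides with up to ``max_missed`` internal cleavage sites.

    Spans are returned in deterministic order (by start, then end).  Length
    bounds are applied after enumeration; pass ``min_len=1`` and a large
    ``max_len`` to recover the full partition at ``max_missed=0``.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not (1 <= min_len <= max_len):
        raise ValueError("need 1 <= min_len <= max_len")
    seq = protein.sequence
    cuts = [0] + cleavage_sites(seq, protease, proline_rule) + [len(seq)]
    offset = protein.numbering_offset
    spans = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
            a, b = cuts[i], cuts[j]
            if not (min_len <= b - a <= max_len):
                continue
            spans.append(PeptideSpan(
                protein_id=protein.id,
                start=offset + a,
                end=offset + b - 1,
                sequence=seq[a:b],
                protease=protease,
                missed_cleavages=j - i - 1,
            ))
    spans.sort(key=lambda s: (s.start, s.end))
    return spans


def coverage(spans: Iterable[PeptideSpan], protein: ProteinRecord) -> float:
    """Fraction of mature-sequence residues covered by at least one span."""
    offset = protein.numbering_offset
    n = len(protein.sequence)
    covered = [False] * n
    for span in spans:
        if span.protein_id != protein.id:
            raise ValueError(
                f"span from {span.protein_id!r} does not belong to {protein.id!r}")
        for pos in range(span.start - offset, span.end - offset + 1):
            covered[pos] = True
    return sum(covered) / n


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------
# The description line carries record metadata as key=value tokens, e.g.
#   >H1_2 met_removed=true domains=NTD:2-60,GH1:61-130,CTD:131-273 synthetic stand-in


def _format_description(rec: ProteinRecord) -> str:
    tokens = [f"met_removed={'true' if rec.met_removed else 'false'}"]
    if rec.domain_annotations:
        doms = ",".join(f"{lbl}:{a}-{b}" for lbl, a, b in rec.domain_annotations)
        tokens.append(f"domains={doms}")
    if rec.description:
        tokens.append(rec.description)
    return " ".join(tokens)


def _parse_description(desc: str) -> tuple[bool, tuple, str]:
    met_removed = False
    domains: list[tuple[str, int, int]] = []
    rest = []
    for token in desc.split():
        if token.startswith("met_removed="):
            met_removed = token.split("=", 1)[1].lower() == "true"
        elif token.startswith("domains="):
            for item in token.split("=", 1)[1].split(","):
                label, interval = item.split(":")
                a, b = interval.split("-")
                domains.append((label, int(a), int(b)))
        else:
            rest.append(token)
    return met_removed, tuple(domains), " ".join(rest)


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description=_format_description(rec))
        for rec in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    for sr in SeqIO.parse(str(path), "fasta"):
        desc = sr.description
        if desc.startswith(sr.id):
            desc = desc[len(sr.id):].strip()
        met_removed, domains, rest = _parse_description(desc)
        records.append(ProteinRecord(
            id=sr.id, sequence=str(sr.seq), description=rest,
            met_removed=met_removed, domain_annotations=domains))
    return records


def peptide_table(spans: Iterable[PeptideSpan]) -> "pandas.DataFrame":
    """Digest products as a tidy table (for TSV export)."""
    import pandas as pd

    return pd.DataFrame(
        [{"protein_id": s.protein_id, "start": s.start, "end": s.end,
          "sequence": s.sequence, "protease": s.protease,
          "missed_cleavages": s.missed_cleavages} for s in spans])
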