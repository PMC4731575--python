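"""Per-residue modification maps, hot spots, and CDK-motif annotation.

The modification map is the end artifact of the pipeline: one row per
modified residue (Met-inclusive numbering), carrying the set of
modification classes seen there, per-class spectrum evidence counts, and
the domain label.  Hot spots are residues carrying several distinct
modification classes; S/TPxK motifs (cyclin-dependent-kinase substrate
sites in linker-histone tails) are located so that modifications falling
inside them can be flagged.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .digestion import ProteinRecord
from .ptm_discovery import ClassifiedSite

_STPXK = re.compile(r"(?=([ST]P.K))")


@dataclass
class MapRow:
    residue: str
    classes: dict[str, int] = field(default_factory=dict)  # class -> evidence
    domain: str | None = None
    in_cdk_motif: bool = False


@dataclass
class ModificationMap:
    """protein_id plus position -> :class:`MapRow` (Met-inclusive)."""

    protein_id: str
    rows: dict[int, MapRow] = field(default_factory=dict)

    def positions(self) -> list[int]:
        return sorted(self.rows)

    def to_json(self) -> str:
        payload = {
            "protein_id": self.protein_id,
            "rows": {
                str(pos): {"residue": row.residue, "classes": row.classes,
                           "domain": row.domain,
                           "in_cdk_motif": row.in_cdk_motif}
                for pos, row in sorted(self.rows.items())
            },
        }
        return json.dumps(payload, indent=2)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([
            {"protein_id": self.protein_id, "position": pos,
             "residue": row.residue,
             "classes": ",".join(sorted(row.classes)),
             "evidence": ",".join(f"{c}:{n}" for c, n in sorted(row.classes.items())),
             "domain": row.domain or "",
             "in_cdk_motif": row.in_cdk_motif}
            for pos, row in sorted(self.rows.items())])

    def text_track(self, protein: ProteinRecord, width: int = 60) -> str:
        """Plain-text per-residue track: modified residues in brackets."""
        offset = protein.numbering_offset
        chars = []
        for i, ch in enumerate(protein.sequence):
            pos = offset + i
            chars.append(f"[{ch}]" if pos in self.rows else ch)
        track = "".join(chars)
        lines = [track[i:i + width] for i in range(0, len(track), width)]
        return "\n".join(lines)


@dataclass(frozen=True)
class HotSpot:
    position: int
    residue: str
    distinct_mod_count: int


def build_map(sites: Iterable[ClassifiedSite],
              protein: ProteinRecord | None = None) -> ModificationMap:
    """Aggregate site-specific results into one row per modified position.

    Classes are deduplicated; evidence counts are summed per class.
    Idempotent on already-aggregated input.  When ``protein`` is supplied,
    rows are annotated with S/TPxK-motif membership.
    """
    sites = list(sites)
    if not sites:
        return ModificationMap(protein_id=protein.id if protein else "")
    pids = {s.protein_id for s in sites}
    if len(pids) > 1:
        raise ValueError(f"sites from several proteins: {sorted(pids)}")
    mmap = ModificationMap(protein_id=sites[0].protein_id)
    for site in sites:
        row = mmap.rows.setdefault(site.position,
                                   MapRow(residue=site.residue,
                                          domain=site.domain))
        if row.residue != site.residue:
            raise ValueError(
                f"conflicting residues at position {site.position}")
        row.classes[site.mod_class] = row.classes.get(site.mod_class, 0) \
            + site.evidence
    if protein is not None:
        motif_positions: set[int] = set()
        for start, motif in find_stpxk_motifs(protein):
            motif_positions.update(range(start, start + 4))
        for pos, row in mmap.rows.items():
            row.in_cdk_motif = pos in motif_positions
    return mmap


def find_hot_spots(mmap: ModificationMap, k: int = 3) -> list[HotSpot]:
    """Rows carrying at least ``k`` distinct modification classes.

    Sorted by class count descending, then position.
    """
    if k < 2:
        raise ValueError("hot-spot threshold must be >= 2")
    spots = [HotSpot(position=pos, residue=row.residue,
                     distinct_mod_count=len(row.classes))
             for pos, row in mmap.rows.items() if len(row.classes) >= k]
    spots.sort(key=lambda h: (-h.distinct_mod_count, h.position))
    return spots


def find_stpxk_motifs(protein: ProteinRecord) -> list[tuple[int, str]]:
    """All (possibly overlapping) S/TPxK motifs, Met-inclusive start positions."""
    offset = protein.numbering_offset
    return [(m.start() + offset, m.group(1))
            for m in _STPXK.finditer(protein.sequence)]


def write_report(mmap: ModificationMap, path: str | Path,
                 protein: ProteinRecord | None = None) -> None:
    """TSV report plus, when the protein is given, a text track footer."""
    frame = mmap.to_frame()
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    if protein is not None:
        with path.open("a") as fh:
            fh.write("\n# per-residue track ([x] = modified)\n")
            for line in mmap.text_track(protein).splitlines():
                fh.write(f"# {line}\n")
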