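"""Areas of endemism from presence/absence matrices.

An area of endemism is a geographic unit — or a clade of units on a
consensus area cladogram — whose identity is supported by at least a
threshold number of taxa found nowhere else (exclusive distributions).
"""
from __future__ import annotations

from dataclasses import dataclass

from .consensus import ConsensusTree
from .matrix import MatrixError, PresenceMatrix

__all__ = ["EndemismEntry", "EndemismReport", "exclusive_taxa", "detect_endemism"]


@dataclass
class EndemismEntry:
    areas: frozenset[str]
    taxa: list[str]

    @property
    def support(self) -> int:
        return len(self.taxa)


@dataclass
class EndemismReport:
    entries: list[EndemismEntry]
    threshold: int

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def area_sets(self) -> list[frozenset[str]]:
        return [e.areas for e in self.entries]

    def to_records(self) -> list[dict]:
        return [
            {
                "areas": sorted(e.areas),
                "n_supporting": e.support,
                "taxa": list(e.taxa),
            }
            for e in self.entries
        ]

    def pretty(self) -> str:
        lines = [f"Areas of endemism (>= {self.threshold} exclusive taxa)"]
        if not self.entries:
            lines.append("  none detected")
        for e in self.entries:
            lines.append(
                f"  {' + '.join(sorted(e.areas))}: {e.support} taxa "
                f"({', '.join(e.taxa)})"
            )
        return "\n".join(lines)


def exclusive_taxa(matrix: PresenceMatrix, area_set: set[str] | frozenset[str]) -> list[str]:
    """Characters whose full distribution equals ``area_set`` exactly."""
    area_set = frozenset(area_set)
    if not area_set:
        raise MatrixError("empty area set")
    unknown = area_set.difference(matrix.ingroup_areas)
    if unknown:
        raise MatrixError(f"unknown area ids: {sorted(unknown)}")
    df = matrix.data
    out = []
    for char in matrix.characters:
        present = frozenset(df.index[df[char] == 1])
        if present == area_set:
            out.append(char)
    return out


def detect_endemism(
    matrix: PresenceMatrix,
    consensus: ConsensusTree | None = None,
    threshold: int = 2,
) -> EndemismReport:
    """Scan candidate area sets for endemic support.

    Candidates are every single ingroup area and, when a consensus area
    cladogram is supplied, every consensus clade's leaf set.  An entry is
    emitted when at least ``threshold`` taxa are exclusively restricted to
    the candidate set; entries are sorted by support, descending.
    """
    if threshold < 2:
        raise ValueError("threshold must be >= 2 (a single taxon is not evidence)")
    candidates: list[frozenset[str]] = [frozenset([a]) for a in matrix.ingroup_areas]
    if consensus is not None:
        for clade in consensus.clades():
            if clade not in candidates:
                candidates.append(frozenset(clade))
    seen = set()
    entries = []
    for cand in candidates:
        if cand in seen:
            continue
        seen.add(cand)
        taxa = exclusive_taxa(matrix, cand)
        if len(taxa) >= threshold:
            entries.append(EndemismEntry(areas=cand, taxa=taxa))
    entries.sort(key=lambda e: (-e.support, sorted(e.areas)))
    return EndemismReport(entries=entries, threshold=threshold)
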