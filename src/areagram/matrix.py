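"""Binary area x character presence/absence matrices.

The central container of the package: rows are operational geographic
units (grid quadrats or named provinces) plus one distinguished all-zero
"outgroup" area that roots every analysis; columns are binary characters
(species presences, and after additive binary coding also hypothetical
ancestors).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PresenceMatrix", "MatrixError"]


class MatrixError(ValueError):
    """Raised when a matrix violates the presence-matrix contract."""


@dataclass
class PresenceMatrix:
    """Binary presence/absence matrix over geographic areas.

    Parameters
    ----------
    data :
        DataFrame with area ids as index, character labels as columns and
        values in {0, 1}.
    outgroup :
        Index label of the hypothetical all-absent outgroup area. The row
        must be all zeros.
    """

    data: pd.DataFrame
    outgroup: str = "Outgroup"

    def __post_init__(self) -> None:
        self.data = self.data.astype(np.int8)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].tolist()
            raise MatrixError(f"duplicate area ids: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].tolist()
            raise MatrixError(f"duplicate character labels: {dup}")
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = np.argwhere(~np.isin(vals, (0, 1)))[0]
            raise MatrixError(
                f"non-binary cell at area {df.index[bad[0]]!r}, "
                f"character {df.columns[bad[1]]!r}"
            )
        if self.outgroup not in df.index:
            raise MatrixError(f"outgroup row {self.outgroup!r} missing")
        if df.loc[self.outgroup].any():
            raise MatrixError(f"outgroup row {self.outgroup!r} is not all zeros")

    # -- views ------------------------------------------------------------
    @property
    def areas(self) -> list[str]:
        return list(self.data.index)

    @property
    def ingroup_areas(self) -> list[str]:
        return [a for a in self.data.index if a != self.outgroup]

    @property
    def characters(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def drop_empty_areas(self) -> "PresenceMatrix":
        """Drop ingroup areas with no presences (the outgroup stays)."""
        keep = (self.data.sum(axis=1) > 0) | (self.data.index == self.outgroup)
        return PresenceMatrix(self.data.loc[keep], outgroup=self.outgroup)

    def subset_characters(self, labels: list[str]) -> "PresenceMatrix":
        missing = [c for c in labels if c not in self.data.columns]
        if missing:
            raise MatrixError(f"unknown characters: {missing}")
        return PresenceMatrix(self.data[labels], outgroup=self.outgroup)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceMatrix):
            return NotImplemented
        return self.outgroup == other.outgroup and self.data.equals(other.data)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        areas: list[str],
        characters: list[str],
        cells: np.ndarray,
        outgroup: str = "Outgroup",
    ) -> "PresenceMatrix":
        df = pd.DataFrame(np.asarray(cells), index=areas, columns=characters)
        return cls(df, outgroup=outgroup)
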