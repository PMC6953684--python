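"""Binary species x leaflet presence/absence matrices.

The sampling unit is the galled leaflet: a leaflet of the host plant
bearing at least one gall morphospecies. Each site contributes one binary
matrix in which rows are gall morphospecies and columns are individual
leaflets; ``values[i, j] == 1`` means morphospecies *i* occurs on leaflet
*j*. All co-occurrence statistics downstream operate on row pairs, so
rows-as-species is the canonical internal orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MatrixFormatError",
    "PresenceAbsenceMatrix",
    "load_matrix",
    "write_matrix",
    "filter_galled_leaflets",
    "drop_empty_species",
    "subsample_leaflets",
]


class MatrixFormatError(ValueError):
    """Raised when a file or table cannot be read as a binary 0/1 matrix."""


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """A validated binary occurrence matrix for one site.

    Attributes
    ----------
    site_id
        Opaque site label (e.g. a habitat name).
    species_ids
        Row labels, one per gall morphospecies.
    leaflet_ids
        Column labels, one per leaflet.
    values
        ``(n_species, n_leaflets)`` int8 array of 0/1 entries. The array is
        made read-only; derive modified matrices through the module
        functions so invariants are re-checked.
    """

    site_id: str
    species_ids: tuple[str, ...]
    leaflet_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise MatrixFormatError(f"matrix must be 2-D, got shape {arr.shape}")
        if arr.shape != (len(self.species_ids), len(self.leaflet_ids)):
            raise MatrixFormatError(
                f"shape {arr.shape} does not match {len(self.species_ids)} species "
                f"x {len(self.leaflet_ids)} leaflet labels"
            )
        bad = (arr != 0) & (arr != 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixFormatError(
                f"non-binary value {arr[i, j]!r} at species "
                f"{self.species_ids[i]!r}, leaflet {self.leaflet_ids[j]!r}"
            )
        for name, labels in (("species", self.species_ids), ("leaflet", self.leaflet_ids)):
            if len(set(labels)) != len(labels):
                dup = next(x for x in labels if list(labels).count(x) > 1)
                raise MatrixFormatError(f"duplicated {name} label {dup!r}")
        arr = np.ascontiguousarray(arr, dtype=np.int8)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "species_ids", tuple(str(s) for s in self.species_ids))
        object.__setattr__(self, "leaflet_ids", tuple(str(s) for s in self.leaflet_ids))

    # -- derived quantities -------------------------------------------------

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def n_leaflets(self) -> int:
        return self.values.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        """Occurrence count r_i of each species (number of leaflets occupied)."""
        return self.values.sum(axis=1, dtype=np.int64)

    @property
    def col_totals(self) -> np.ndarray:
        """Species count c_j on each leaflet."""
        return self.values.sum(axis=0, dtype=np.int64)

    @property
    def grand_total(self) -> int:
        return int(self.values.sum(dtype=np.int64))

    # -- conversions --------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=pd.Index(self.species_ids, name="species"),
            columns=list(self.leaflet_ids),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, site_id: str = "site") -> "PresenceAbsenceMatrix":
        values = frame.to_numpy()
        if not np.issubdtype(np.asarray(values).dtype, np.number):
            raise MatrixFormatError("matrix table contains non-numeric cells")
        return cls(
            site_id=site_id,
            species_ids=tuple(str(i) for i in frame.index),
            leaflet_ids=tuple(str(c) for c in frame.columns),
            values=values,
        )

    def with_site_id(self, site_id: str) -> "PresenceAbsenceMatrix":
        return replace(self, site_id=site_id)


def load_matrix(
    path: str | Path,
    orientation: str = "species_rows",
    site_id: str | None = None,
) -> PresenceAbsenceMatrix:
    """Read a delimited 0/1 matrix (header = column ids, first column = row ids).

    The delimiter is auto-detected among comma, tab and semicolon. With
    ``orientation="species_cols"`` the table is transposed on load so that
    species always end up on rows internally.
    """
    path = Path(path)
    if orientation not in ("species_rows", "species_cols"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
    if orientation == "species_cols":
        frame = frame.T
    frame = frame.apply(pd.to_numeric, errors="coerce")
    if frame.isna().any().any():
        j = frame.isna().any(axis=0).idxmax()
        i = frame[j].isna().idxmax()
        raise MatrixFormatError(f"{path}: non-numeric cell at row {i!r}, column {j!r}")
    return PresenceAbsenceMatrix.from_frame(frame, site_id=site_id or path.stem)


def write_matrix(m: PresenceAbsenceMatrix, path: str | Path, sep: str = ",") -> None:
    """Write the matrix in the dialect :func:`load_matrix` reads back."""
    m.to_frame().to_csv(Path(path), sep=sep)


def filter_galled_leaflets(m: PresenceAbsenceMatrix) -> PresenceAbsenceMatrix:
    """Drop leaflets hosting no gall at all (all-zero columns).

    The sampling design admits only galled leaflets, so empty columns can
    only arise from data-entry artefacts or from subsampling; after
    filtering, every column total is >= 1. Species rows are retained even
    if they are singletons. Idempotent.
    """
    keep = m.col_totals >= 1
    if not keep.any():
        raise MatrixFormatError(f"site {m.site_id!r}: no galled leaflets remain")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("site %s: removed %d ungalled leaflet(s)", m.site_id, n_removed)
    return PresenceAbsenceMatrix(
        site_id=m.site_id,
        species_ids=m.species_ids,
        leaflet_ids=tuple(l for l, k in zip(m.leaflet_ids, keep) if k),
        values=m.values[:, keep],
    )


def drop_empty_species(m: PresenceAbsenceMatrix) -> PresenceAbsenceMatrix:
    """Drop species absent from every leaflet (all-zero rows).

    A species with r_i = 0 contributes only degenerate pairs (CU = 0) and
    would dilute the C-score mean, so it is removed before co-occurrence
    analysis.
    """
    keep = m.row_totals >= 1
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("site %s: dropped %d absent species", m.site_id, n_removed)
    return PresenceAbsenceMatrix(
        site_id=m.site_id,
        species_ids=tuple(s for s, k in zip(m.species_ids, keep) if k),
        leaflet_ids=m.leaflet_ids,
        values=m.values[keep, :],
    )


def subsample_leaflets(
    m: PresenceAbsenceMatrix,
    n: int = 137,
    seed: int | np.random.Generator = 0,
) -> PresenceAbsenceMatrix:
    """Standardize sampling effort to ``n`` leaflets drawn without replacement.

    Columns are drawn uniformly and the retained columns keep their original
    order, so downstream seeded analyses are deterministic. Species rows are
    left intact even if they become all-zero; callers decide whether to
    apply :func:`drop_empty_species` afterwards.
    """
    if n > m.n_leaflets:
        raise ValueError(
            f"cannot subsample {n} leaflets from matrix with {m.n_leaflets}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chosen = np.sort(rng.choice(m.n_leaflets, size=n, replace=False))
    return PresenceAbsenceMatrix(
        site_id=m.site_id,
        species_ids=m.species_ids,
        leaflet_ids=tuple(m.leaflet_ids[j] for j in chosen),
        values=m.values[:, chosen],
    )
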