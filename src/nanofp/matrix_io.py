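"""Read, validate and write adsorption free-energy matrices.

The central container is :class:`FreeEnergyMatrix`: a complete table of
adsorption (binding) free energies in kJ/mol, rows indexed by biomolecule
ids (e.g. ``PRO``, ``ASP``) and columns by nanomaterial ids (e.g. ``GR``,
``CNT-OH-low``).  The row vector of one molecule is its adsorption profile
across materials; the column vector of one material is its "biological
fingerprint".  Optional elementwise lower/upper bounds carry the statistical
uncertainty of the underlying free-energy estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FreeEnergyMatrix", "MatrixValidationError", "read_matrix", "write_matrix"]


class MatrixValidationError(ValueError):
    """A free-energy matrix violated a structural invariant."""


@dataclass
class FreeEnergyMatrix:
    """Molecules x materials table of adsorption free energies (kJ/mol).

    Parameters
    ----------
    molecule_ids, material_ids
        Ordered, unique axis labels.
    values
        Real matrix, shape ``(n_molecules, n_materials)``.
    lower_bound, upper_bound
        Optional same-shape matrices with ``lower <= value <= upper``.
    """

    molecule_ids: list[str]
    material_ids: list[str]
    values: np.ndarray
    lower_bound: np.ndarray | None = None
    upper_bound: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.molecule_ids = [str(m) for m in self.molecule_ids]
        self.material_ids = [str(m) for m in self.material_ids]
        self.values = np.asarray(self.values, dtype=float)
        for name, ids in (("molecule", self.molecule_ids), ("material", self.material_ids)):
            dupes = {x for x in ids if ids.count(x) > 1}
            if dupes:
                raise MatrixValidationError(f"duplicate {name} id(s): {sorted(dupes)}")
        if self.values.shape != (len(self.molecule_ids), len(self.material_ids)):
            raise MatrixValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.molecule_ids)} molecules x {len(self.material_ids)} materials"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixValidationError(
                f"non-finite value at molecule {self.molecule_ids[i]!r}, "
                f"material {self.material_ids[j]!r}"
            )
        for name in ("lower_bound", "upper_bound"):
            b = getattr(self, name)
            if b is not None:
                b = np.asarray(b, dtype=float)
                setattr(self, name, b)
                if b.shape != self.values.shape:
                    raise MatrixValidationError(f"{name} shape {b.shape} != values shape")
                if not np.all(np.isfinite(b)):
                    raise MatrixValidationError(f"non-finite entry in {name}")
        if self.lower_bound is not None and np.any(self.lower_bound > self.values + 1e-12):
            raise MatrixValidationError("lower_bound exceeds value")
        if self.upper_bound is not None and np.any(self.upper_bound < self.values - 1e-12):
            raise MatrixValidationError("upper_bound below value")

    # -- convenience -------------------------------------------------------
    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    @property
    def n_materials(self) -> int:
        return len(self.material_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.molecule_ids, columns=self.material_ids)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        lower: pd.DataFrame | None = None,
        upper: pd.DataFrame | None = None,
    ) -> "FreeEnergyMatrix":
        return cls(
            molecule_ids=list(df.index),
            material_ids=list(df.columns),
            values=df.to_numpy(dtype=float),
            lower_bound=None if lower is None else lower.to_numpy(dtype=float),
            upper_bound=None if upper is None else upper.to_numpy(dtype=float),
        )

    def transpose(self) -> "FreeEnergyMatrix":
        """Swap the molecule and material axes (fingerprint view)."""
        return FreeEnergyMatrix(
            molecule_ids=self.material_ids,
            material_ids=self.molecule_ids,
            values=self.values.T,
            lower_bound=None if self.lower_bound is None else self.lower_bound.T,
            upper_bound=None if self.upper_bound is None else self.upper_bound.T,
        )

    def select_molecules(self, ids: list[str]) -> np.ndarray:
        """Rows for the named molecules, in the given order."""
        idx = [self._mol_index(m) for m in ids]
        return self.values[idx, :]

    def _mol_index(self, mol: str) -> int:
        try:
            return self.molecule_ids.index(mol)
        except ValueError:
            raise KeyError(f"unknown molecule id {mol!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FreeEnergyMatrix):
            return NotImplemented
        same_bounds = all(
            (a is None) == (b is None) and (a is None or np.array_equal(a, b))
            for a, b in (
                (self.lower_bound, other.lower_bound),
                (self.upper_bound, other.upper_bound),
            )
        )
        return (
            self.molecule_ids == other.molecule_ids
            and self.material_ids == other.material_ids
            and np.array_equal(self.values, other.values)
            and same_bounds
        )


def _delimiter(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
        return "\t" if dialect == "tsv" else ","
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    # check header duplicates on the raw line: pandas silently mangles them
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise MatrixValidationError(f"duplicate column label(s) in {path.name}: {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise MatrixValidationError(f"duplicate row label(s) in {path.name}: {dupes}")
    values = np.empty(df.shape, dtype=float)
    for i, row in enumerate(df.index):
        for j, col in enumerate(df.columns):
            cell = df.iat[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                raise MatrixValidationError(
                    f"missing value at row {row!r}, column {col!r} (complete matrix required)"
                )
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise MatrixValidationError(
                    f"non-numeric value {cell!r} at row {row!r}, column {col!r}"
                ) from None
    return pd.DataFrame(values, index=df.index, columns=df.columns)


def _bound_path(path: Path, suffix: str) -> Path:
    return path.with_name(path.stem + suffix + path.suffix)


def read_matrix(
    path: str | Path,
    dialect: str | None = None,
    orientation: str = "molecules-as-rows",
    read_bounds: bool = True,
) -> FreeEnergyMatrix:
    """Read a delimited free-energy table into a validated matrix.

    The first row holds column labels and the first column row labels.
    ``orientation='materials-as-rows'`` transposes on read so the in-memory
    object is always molecules-as-rows.  Companion files named
    ``<stem>_min<ext>`` / ``<stem>_max<ext>``, if present, supply elementwise
    bounds.
    """
    path = Path(path)
    if orientation not in ("molecules-as-rows", "materials-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _delimiter(path, dialect)
    df = _read_table(path, sep)
    lower = upper = None
    if read_bounds:
        lo_path, hi_path = _bound_path(path, "_min"), _bound_path(path, "_max")
        if lo_path.exists() and hi_path.exists():
            lower = _read_table(lo_path, sep)
            upper = _read_table(hi_path, sep)
            for b, p in ((lower, lo_path), (upper, hi_path)):
                if list(b.index) != list(df.index) or list(b.columns) != list(df.columns):
                    raise MatrixValidationError(f"bound file {p.name} labels differ from main table")
    if orientation == "materials-as-rows":
        df = df.T
        lower = None if lower is None else lower.T
        upper = None if upper is None else upper.T
    return FreeEnergyMatrix.from_frame(df, lower, upper)


def write_matrix(
    m: FreeEnergyMatrix,
    path: str | Path,
    dialect: str | None = None,
    float_format: str = "%.17g",
) -> Path:
    """Write a matrix (and its bounds, if any) as delimited text.

    ``read_matrix(write_matrix(m)) == m``: the default ``%.17g`` format
    round-trips IEEE doubles exactly.
    """
    path = Path(path)
    sep = _delimiter(path, dialect)
    m.to_frame().to_csv(path, sep=sep, float_format=float_format)
    if m.lower_bound is not None and m.upper_bound is not None:
        lo = pd.DataFrame(m.lower_bound, index=m.molecule_ids, columns=m.material_ids)
        hi = pd.DataFrame(m.upper_bound, index=m.molecule_ids, columns=m.material_ids)
        lo.to_csv(_bound_path(path, "_min"), sep=sep, float_format=float_format)
        hi.to_csv(_bound_path(path, "_max"), sep=sep, float_format=float_format)
    return path
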