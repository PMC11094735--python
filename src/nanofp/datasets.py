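"""Access to the deposited reference free-energy matrix.

The study's measured dataset — 32 biomolecules x 33 nanomaterials of
metadynamics adsorption free energies — is distributed through the Zenodo
archive "Adsorption free energies and potentials of mean-force for
interactions between amino acids, lipid fragments, and nanoparticles"
(record 8297848, v2.0).  The archive is not redistributed with this
package; to run the reference analyses, export the free-energy table to
delimited text (molecules as rows, materials as columns, first row and
column as labels) and place it at ``data/reference/metad_free_energies.csv``
under the repository root, or pass an explicit path.
"""

from __future__ import annotations

from pathlib import Path

from .matrix_io import FreeEnergyMatrix, read_matrix

__all__ = ["DEFAULT_REFERENCE_PATH", "reference_matrix_path", "load_reference_matrix"]

DEFAULT_REFERENCE_PATH = Path("data") / "reference" / "metad_free_energies.csv"

#: Expected shape of the deposited matrix.
N_MOLECULES, N_MATERIALS = 32, 33


def reference_matrix_path(root: str | Path = ".") -> Path:
    return Path(root) / DEFAULT_REFERENCE_PATH


class ReferenceDataMissing(FileNotFoundError):
    pass


def load_reference_matrix(path: str | Path | None = None) -> FreeEnergyMatrix:
    """Load the deposited 32 x 33 matrix from a user-supplied CSV/TSV export.

    Raises :class:`ReferenceDataMissing` with download instructions when
    the file is absent, and validates the expected shape when present.
    """
    path = Path(path) if path is not None else reference_matrix_path()
    if not path.exists():
        raise ReferenceDataMissing(
            f"reference matrix not found at {path}. Download the archive from "
            "https://zenodo.org/record/8297848 (v2.0), export the adsorption "
            "free-energy table as delimited text (molecules as rows) and save "
            f"it to {path}."
        )
    m = read_matrix(path)
    if (m.n_molecules, m.n_materials) != (N_MOLECULES, N_MATERIALS):
        raise ValueError(
            f"expected {N_MOLECULES} molecules x {N_MATERIALS} materials, "
            f"got {m.n_molecules} x {m.n_materials}"
        )
    return m
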