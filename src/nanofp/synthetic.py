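"""Synthetic adsorption data with planted, recoverable structure.

The generator emulates the empirical block structure of biomolecule /
nanomaterial adsorption free-energy tables: a group of aromatic or cyclic
molecules that bind strongly to hydrophobic carbon surfaces, a small group
of anionic molecules that bind selectively to charged or polar surfaces,
and a broad remainder group — crossed with three material groups — on top
of additive per-molecule and per-material offsets and ~0.5 kJ/mol Gaussian
noise (the typical statistical uncertainty of metadynamics free energies).

Each cell is

    G[i, j] = mu + a_i + b_j + gamma[g(i), h(j)] + eps_ij

with ``a ~ N(0, molecule_offsets_sd)``, ``b ~ N(0, material_offsets_sd)``,
``eps ~ N(0, noise_sd)`` and ``gamma`` a group x group matrix of mean
shifts.  The planted group labels are returned alongside the matrix so
clustering and prediction stages can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import FreeEnergyMatrix
from .pmf import PMFProfile

__all__ = ["SyntheticConfig", "PlantedLabels", "generate_matrix", "generate_pmf"]

# Default group-interaction shifts (kJ/mol).  Row = molecule group
# (strong-aromatic, remainder, small-anionic), column = material group
# (hydrophobic carbon, mixed/polar remainder, charged surfaces).  The -25
# and -20 blocks give between-group contrasts well above 15 kJ/mol, i.e.
# far above the 0.5 kJ/mol noise floor.
_DEFAULT_GAMMA = (
    (-25.0, 0.0, 0.0),
    (0.0, 0.0, 0.0),
    (0.0, 0.0, -20.0),
)


@dataclass
class SyntheticConfig:
    """Parameters of the planted-block generator (all energies in kJ/mol)."""

    n_molecules: int = 32
    n_materials: int = 33
    molecule_group_sizes: tuple[int, ...] = (7, 22, 3)
    material_group_sizes: tuple[int, ...] = (6, 19, 8)
    mu: float = -10.0
    molecule_offsets_sd: float = 2.0
    material_offsets_sd: float = 2.0
    interaction_effects: tuple[tuple[float, ...], ...] = _DEFAULT_GAMMA
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.molecule_group_sizes) != self.n_molecules:
            raise ValueError(
                f"molecule group sizes {self.molecule_group_sizes} do not sum "
                f"to n_molecules={self.n_molecules}"
            )
        if sum(self.material_group_sizes) != self.n_materials:
            raise ValueError(
                f"material group sizes {self.material_group_sizes} do not sum "
                f"to n_materials={self.n_materials}"
            )
        if any(s <= 0 for s in self.molecule_group_sizes + self.material_group_sizes):
            raise ValueError("group sizes must be positive")
        if self.noise_sd < 0 or self.molecule_offsets_sd < 0 or self.material_offsets_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        gamma = np.asarray(self.interaction_effects, dtype=float)
        if gamma.shape != (len(self.molecule_group_sizes), len(self.material_group_sizes)):
            raise ValueError(
                f"interaction_effects shape {gamma.shape} does not match group counts"
            )
        if not np.all(np.isfinite(gamma)):
            raise ValueError("interaction_effects must be finite")

    @property
    def gamma(self) -> np.ndarray:
        return np.asarray(self.interaction_effects, dtype=float)


@dataclass
class PlantedLabels:
    """Ground-truth group index per molecule and per material."""

    molecule_group: np.ndarray
    material_group: np.ndarray


def _labels(sizes: tuple[int, ...]) -> np.ndarray:
    return np.concatenate([np.full(sz, g, dtype=int) for g, sz in enumerate(sizes)])


def generate_matrix(cfg: SyntheticConfig) -> tuple[FreeEnergyMatrix, PlantedLabels]:
    """Draw one synthetic free-energy matrix plus its planted labels.

    Deterministic for a fixed ``cfg.seed``.  Bounds are set to
    ``value -/+ noise_sd``, mimicking reported uncertainty bands.
    """
    rng = np.random.default_rng(cfg.seed)
    g = _labels(cfg.molecule_group_sizes)
    h = _labels(cfg.material_group_sizes)
    a = rng.normal(0.0, cfg.molecule_offsets_sd, cfg.n_molecules)
    b = rng.normal(0.0, cfg.material_offsets_sd, cfg.n_materials)
    eps = rng.normal(0.0, cfg.noise_sd, (cfg.n_molecules, cfg.n_materials))
    values = cfg.mu + a[:, None] + b[None, :] + cfg.gamma[np.ix_(g, h)] + eps
    mol_ids = [f"MOL{i + 1:02d}" for i in range(cfg.n_molecules)]
    mat_ids = [f"MAT{j + 1:02d}" for j in range(cfg.n_materials)]
    m = FreeEnergyMatrix(
        molecule_ids=mol_ids,
        material_ids=mat_ids,
        values=values,
        lower_bound=values - cfg.noise_sd,
        upper_bound=values + cfg.noise_sd,
    )
    return m, PlantedLabels(molecule_group=g, material_group=h)


def generate_pmf(
    depth: float = 20.0,
    width: float = 0.1,
    center: float = 0.4,
    grid: tuple[float, float, int] = (0.0, 2.0, 401),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PMFProfile:
    """A Gaussian-well toy PMF: W(s) = -depth * exp(-(s-center)^2 / 2 width^2) + noise.

    The far end of the grid serves as the reference distance s0 and the
    profile is pinned to W(s0) = 0 there.  The grid must leave a flat tail
    of at least 3 widths beyond the well center.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    lo, hi, n = grid
    if n < 2 or hi <= lo:
        raise ValueError("invalid grid spec")
    if hi < center + 3 * width:
        raise ValueError("grid too short for a flat tail beyond the well")
    s = np.linspace(lo, hi, int(n))
    rng = np.random.default_rng(seed)
    w = -depth * np.exp(-((s - center) ** 2) / (2.0 * width**2))
    if noise_sd > 0:
        w = w + rng.normal(0.0, noise_sd, s.shape)
    w = w - w[-1]  # pin tail to zero at s0
    return PMFProfile(s=s, W=w, s0=float(s[-1]), zero_tol=1e-9)
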