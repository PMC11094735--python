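"""Potential-of-mean-force post-processing.

Converts averaged mean-force or PMF profiles along the surface separation
distance (SSD) into adsorption free energies.

The PMF is obtained by integrating the negative average force from a far
reference distance ``s0`` where the force has decayed:

    W(s) = - \\int_{s0}^{s} <F(s')> ds'        (so W(s0) = 0)

and the adsorption free energy is the Boltzmann-weighted average of the PMF
over an adsorption layer of thickness ``delta`` (default 0.8 nm):

    dG_ads = -kB*T * ln[ (1/delta) \\int_layer exp(-W(s)/kB*T) ds ]

A flat PMF gives dG = 0 exactly; a deeper well gives a more negative dG.
Uncertainty is propagated by evaluating dG on the mean PMF and on the
mean +/- 1 sd envelopes built pointwise from simulation-window PMFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "KB_KJ_PER_MOL_K",
    "MeanForceProfile",
    "PMFProfile",
    "FreeEnergyParams",
    "read_profile",
    "write_profile",
    "pmf_from_mean_force",
    "default_layer_start",
    "adsorption_free_energy",
    "windowed_bounds",
]

#: Boltzmann constant in kJ/mol/K (CODATA).
KB_KJ_PER_MOL_K = 0.008314462618


def _check_grid(s: np.ndarray, y: np.ndarray, name: str) -> None:
    if s.ndim != 1 or y.ndim != 1 or s.shape != y.shape:
        raise ValueError(f"{name}: s and values must be 1-D arrays of equal length")
    if s.size < 2:
        raise ValueError(f"{name}: need at least 2 grid points, got {s.size}")
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(y))):
        raise ValueError(f"{name}: non-finite entries")
    if np.any(np.diff(s) <= 0):
        raise ValueError(f"{name}: s must be strictly increasing")


@dataclass
class MeanForceProfile:
    """Average force <F(s)> (kJ/mol/nm) on the adsorbate along the SSD grid s (nm)."""

    s: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        _check_grid(self.s, self.F, "MeanForceProfile")


@dataclass
class PMFProfile:
    """Potential of mean force W(s) (kJ/mol) with W(s0) = 0 at the far reference s0 (nm)."""

    s: np.ndarray
    W: np.ndarray
    s0: float
    #: tolerance (kJ/mol) for the W(s0)=0 convention check
    zero_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        _check_grid(self.s, self.W, "PMFProfile")
        if not (self.s[0] <= self.s0 <= self.s[-1]):
            raise ValueError(f"s0={self.s0} outside grid [{self.s[0]}, {self.s[-1]}]")
        w0 = float(np.interp(self.s0, self.s, self.W))
        if abs(w0) > self.zero_tol:
            raise ValueError(f"W(s0) = {w0:.3g} violates the zero-reference convention")


@dataclass
class FreeEnergyParams:
    """Adsorption-layer thickness delta (nm) and temperature (K)."""

    delta: float = 0.8
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kBT(self) -> float:
        """Thermal energy kB*T in kJ/mol (~2.494 at 300 K)."""
        return KB_KJ_PER_MOL_K * self.temperature


def read_profile(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column whitespace profile (s [nm], value); '#' comments ignored."""
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two whitespace-separated columns")
    return data[:, 0], data[:, 1]


def write_profile(path: str | Path, s: np.ndarray, y: np.ndarray, header: str = "") -> Path:
    path = Path(path)
    np.savetxt(path, np.column_stack([s, y]), fmt="%.10g", header=header)
    return path


def pmf_from_mean_force(
    f: MeanForceProfile, s0: float, force_tol: float | None = None
) -> PMFProfile:
    """Integrate the negative mean force from s0 to obtain the PMF.

    Trapezoidal quadrature on the supplied grid; W(s0) = 0 exactly by
    construction.  ``force_tol`` (kJ/mol/nm), if given, asserts that the
    force near s0 has decayed below the threshold.
    """
    if not (f.s[0] <= s0 <= f.s[-1]):
        raise ValueError(f"s0={s0} outside grid [{f.s[0]}, {f.s[-1]}]")
    if force_tol is not None:
        f_at_s0 = float(np.interp(s0, f.s, f.F))
        if abs(f_at_s0) > force_tol:
            raise ValueError(
                f"|<F>({s0})| = {abs(f_at_s0):.3g} exceeds force_tol={force_tol}"
            )
    # cumulative trapezoid of -F from the left edge, then re-zero at s0
    from scipy.integrate import cumulative_trapezoid

    w = -cumulative_trapezoid(f.F, f.s, initial=0.0)
    w0 = float(np.interp(s0, f.s, w))
    w = w - w0
    # snap the grid point at s0 (if any) to exactly zero
    at = np.isclose(f.s, s0)
    w[at] = 0.0
    return PMFProfile(s=f.s.copy(), W=w, s0=s0, zero_tol=1e-9)


def default_layer_start(pmf: PMFProfile, delta: float) -> float:
    """Start of the adsorption layer: the minimum of W minus delta/2, clipped to the grid."""
    s_min = float(pmf.s[np.argmin(pmf.W)])
    lo, hi = float(pmf.s[0]), float(pmf.s[-1])
    return float(np.clip(s_min - delta / 2.0, lo, max(lo, hi - delta)))


def adsorption_free_energy(
    pmf: PMFProfile,
    params: FreeEnergyParams | None = None,
    layer_start: float | None = None,
    n_sub: int = 1,
) -> float:
    """Adsorption free energy (kJ/mol) from a PMF.

    Boltzmann-averages exp(-W/kBT) over [layer_start, layer_start+delta] by
    trapezoidal quadrature on the restriction of the grid to the layer (the
    layer endpoints are added by linear interpolation of W).  ``n_sub`` > 1
    linearly up-samples W inside the layer, for convergence checks.
    """
    params = params or FreeEnergyParams()
    if layer_start is None:
        layer_start = default_layer_start(pmf, params.delta)
    a, b = float(layer_start), float(layer_start) + params.delta
    if a < pmf.s[0] - 1e-12 or b > pmf.s[-1] + 1e-12:
        raise ValueError(
            f"adsorption layer [{a:.4g}, {b:.4g}] exceeds grid "
            f"[{pmf.s[0]:.4g}, {pmf.s[-1]:.4g}]"
        )
    inside = (pmf.s > a) & (pmf.s < b)
    s_layer = np.concatenate([[a], pmf.s[inside], [b]])
    if n_sub > 1:
        fine = [
            np.linspace(s_layer[i], s_layer[i + 1], n_sub, endpoint=False)
            for i in range(len(s_layer) - 1)
        ]
        s_layer = np.concatenate(fine + [[b]])
    w_layer = np.interp(s_layer, pmf.s, pmf.W)
    if not np.all(np.isfinite(w_layer)):
        raise ValueError("non-finite PMF values inside the adsorption layer")
    kBT = params.kBT
    # factor exp(w_min) out of the integral for numerical safety on deep wells
    w_min = float(np.min(w_layer))
    boltz = np.exp(-(w_layer - w_min) / kBT)
    integral = np.trapezoid(boltz, s_layer)
    return float(-kBT * (np.log(integral / params.delta)) + w_min)


def windowed_bounds(
    window_pmfs: list[PMFProfile],
    params: FreeEnergyParams | None = None,
    layer_start: float | None = None,
    n_sd: float = 1.0,
) -> tuple[float, float, float]:
    """Free energy with window-based uncertainty: (dg, dg_min, dg_max).

    The PMF mean and standard deviation over simulation windows are taken
    pointwise; mean -/+ ``n_sd`` sd define the lower/upper PMF envelopes.
    dG is evaluated on all three profiles and the three results are sorted,
    since the Boltzmann average does not preserve pointwise PMF order of
    evaluation labels.
    """
    if len(window_pmfs) < 2:
        raise ValueError("need at least 2 windows")
    s = window_pmfs[0].s
    for p in window_pmfs[1:]:
        if not np.array_equal(p.s, s):
            raise ValueError("window PMFs must share a common grid")
    params = params or FreeEnergyParams()
    W = np.vstack([p.W for p in window_pmfs])
    mean, sd = W.mean(axis=0), W.std(axis=0, ddof=0)
    s0 = window_pmfs[0].s0

    def _dg(w: np.ndarray) -> float:
        w = w - float(np.interp(s0, s, w))  # re-apply the W(s0)=0 convention
        prof = PMFProfile(s=s, W=w, s0=s0, zero_tol=np.inf)
        return adsorption_free_energy(prof, params, layer_start)

    dg = _dg(mean)
    envelope = [dg, _dg(mean - n_sd * sd), _dg(mean + n_sd * sd)]
    return dg, min(envelope), max(envelope)
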