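"""Equilibrium-binding titration analysis.

A type-I substrate titration of a heme protein produces, at each wavelength
w, a difference absorbance that follows the single-site hyperbola

    dAU_obs(w, L) = dAU_max(w) * [L] / (K_D + [L])

with one dissociation constant K_D shared across wavelengths and one signed
amplitude per wavelength (the Soret band decreases near 419 nm and grows
near 388 nm). This module fits the hyperbola per wavelength and globally
(shared K_D, separable linear amplitudes solved by variable projection),
converts K_D to a binding free energy dG = R T ln(K_D / 1 M), decomposes a
spectrum into high-/low-spin reference fractions, and computes ionic
strength I = 1/2 sum c_i z_i^2.

The free-ligand concentration is approximated by the total (analytical)
ligand concentration; no tight-binding quadratic correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "R_KCAL",
    "TitrationDataset",
    "BindingFitResult",
    "SpinDecomposition",
    "SaltComposition",
    "hyperbolic_model",
    "fit_single_wavelength",
    "fit_global",
    "delta_g",
    "delta_g_standard_error",
    "decompose_spin",
    "spin_fraction",
    "ionic_strength",
]

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 1.987e-3

#: default temperature (K) for free-energy conversion
T_DEFAULT = 298.0

#: stoichiometry (ion -> count, charge) of common 1:1 and 1:2 salts
_SALT_TABLE: dict[str, dict[str, tuple[int, int]]] = {
    "NaCl": {"Na": (1, 1), "Cl": (1, -1)},
    "LiCl": {"Li": (1, 1), "Cl": (1, -1)},
    "KCl": {"K": (1, 1), "Cl": (1, -1)},
    "NH4Cl": {"NH4": (1, 1), "Cl": (1, -1)},
    "MgCl2": {"Mg": (1, 2), "Cl": (2, -1)},
    "CaCl2": {"Ca": (1, 2), "Cl": (2, -1)},
    "SrCl2": {"Sr": (1, 2), "Cl": (2, -1)},
}


@dataclass
class TitrationDataset:
    """Absorbance table: rows = wavelengths, columns = ligand concentrations."""

    ligand_concentrations: np.ndarray  # M, strictly increasing
    wavelengths: np.ndarray  # nm
    absorbance: np.ndarray  # AU, shape (n_wavelengths, n_concentrations)
    blank_subtracted: bool = True

    def __post_init__(self) -> None:
        self.ligand_concentrations = np.asarray(self.ligand_concentrations, float)
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.absorbance = np.asarray(self.absorbance, float)
        L = self.ligand_concentrations
        if np.any(L < 0) or np.any(np.diff(L) <= 0):
            raise ValueError("concentrations must be non-negative and strictly increasing")
        if self.absorbance.shape != (self.wavelengths.size, L.size):
            raise ValueError(
                f"absorbance table shape {self.absorbance.shape} does not match "
                f"({self.wavelengths.size} wavelengths, {L.size} concentrations)"
            )
        if np.any(~np.isfinite(self.absorbance)):
            raise ValueError("absorbance table must be complete (no NaN/inf)")


@dataclass
class BindingFitResult:
    KD: float  # M
    KD_se: float
    wavelengths: np.ndarray
    amplitudes: np.ndarray  # dAU_max per wavelength, AU
    amplitude_se: np.ndarray
    rss: float
    n_obs: int
    T: float = T_DEFAULT
    R_const: float = R_KCAL
    delta_g: float = field(init=False)
    delta_g_se: float = field(init=False)

    def __post_init__(self) -> None:
        self.delta_g = delta_g(self.KD, self.T, self.R_const)
        self.delta_g_se = delta_g_standard_error(self.KD, self.KD_se, self.T, self.R_const)


@dataclass
class SpinDecomposition:
    high_spin_reference: np.ndarray  # AU per wavelength
    low_spin_reference: np.ndarray
    fraction_high_spin: float
    fraction_low_spin: float
    residual: float  # RSS of the constrained linear fit


@dataclass
class SaltComposition:
    """Ion species -> (concentration M, integer charge)."""

    species: dict[str, tuple[float, int]]

    def __post_init__(self) -> None:
        for ion, (c, z) in self.species.items():
            if c < 0:
                raise ValueError(f"negative concentration for {ion}")
            if int(z) != z or z == 0:
                raise ValueError(f"charge of {ion} must be a nonzero integer")

    @classmethod
    def from_salt(cls, salt: str, concentration: float) -> "SaltComposition":
        """Fully dissociated composition of a named simple salt."""
        if salt not in _SALT_TABLE:
            raise KeyError(f"unknown salt {salt!r}; known: {sorted(_SALT_TABLE)}")
        return cls(
            {
                ion: (concentration * count, charge)
                for ion, (count, charge) in _SALT_TABLE[salt].items()
            }
        )


# ---------------------------------------------------------------------------


def hyperbolic_model(L, KD: float, Amax):
    """Single-site binding hyperbola: Amax * L / (KD + L)."""
    if KD <= 0:
        raise ValueError("KD must be positive")
    L = np.asarray(L, float)
    if np.any(L < 0):
        raise ValueError("ligand concentrations must be >= 0")
    return Amax * L / (KD + L)


def _vp_linear(f: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-wavelength baseline and amplitude for fixed KD (f = L/(KD+L)).

    Solves min ||y_w - b_w - a_w f||^2 for every wavelength row at once. The
    baseline b_w absorbs any zero-ligand offset, so the noise of the first
    titration point is treated like every other point's (no column
    subtraction, residuals stay independent).
    """
    n = f.size
    fbar = f.mean()
    sxx = float(((f - fbar) ** 2).sum())
    ybar = y.mean(axis=1)
    a = ((y - ybar[:, None]) @ (f - fbar)) / sxx
    b = ybar - a * fbar
    return b, a


def _sse(kd: float, L: np.ndarray, y: np.ndarray) -> float:
    f = L / (kd + L)
    b, a = _vp_linear(f, y)
    r = y - b[:, None] - a[:, None] * f[None, :]
    return float(np.sum(r * r))


def fit_global(
    data: TitrationDataset,
    wavelengths: np.ndarray | None = None,
    T: float = T_DEFAULT,
) -> BindingFitResult:
    """Joint fit of all (selected) wavelengths with one shared KD.

    Per wavelength the model is b_w + dAU_max(w) * L / (KD + L): the baseline
    b_w and amplitude enter linearly, so for each trial KD they are profiled
    out exactly (variable projection) and only the scalar KD is optimised.
    Standard errors come from the Gauss-Newton curvature of the full
    unweighted least-squares objective at the optimum.
    """
    if wavelengths is None:
        rows = np.arange(data.wavelengths.size)
    else:
        rows = np.asarray(
            [int(np.argmin(np.abs(data.wavelengths - w))) for w in np.atleast_1d(wavelengths)]
        )
    if rows.size < 1:
        raise ValueError("at least one wavelength required")
    L = data.ligand_concentrations
    y = data.absorbance[rows]
    Lpos = L[L > 0]
    if Lpos.size < 3:
        raise ValueError("need at least 3 nonzero ligand concentrations")
    if np.max(np.ptp(y, axis=1)) == 0:
        raise ValueError("all-zero response: KD is unidentifiable")

    # coarse log-grid bracket, then bounded scalar refinement
    grid = np.geomspace(Lpos.min() * 1e-3, Lpos.max() * 1e3, 121)
    sse_grid = np.array([_sse(k, L, y) for k in grid])
    i = int(np.argmin(sse_grid))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda lnk: _sse(np.exp(lnk), L, y),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise RuntimeError(f"KD optimisation failed: {res.message}")
    kd = float(np.exp(res.x))

    f = L / (kd + L)
    b, a = _vp_linear(f, y)
    resid = y - b[:, None] - a[:, None] * f[None, :]
    rss = float(np.sum(resid * resid))

    # Jacobian of residuals wrt (KD, b_1, A_1, ..., b_W, A_W); block structure
    W, n = y.shape
    dfdk = -L / (kd + L) ** 2
    J = np.zeros((W * n, 2 * W + 1))
    J[:, 0] = (a[:, None] * dfdk[None, :]).ravel()
    for w in range(W):
        J[w * n : (w + 1) * n, 1 + 2 * w] = 1.0
        J[w * n : (w + 1) * n, 2 + 2 * w] = f
    dof = max(W * n - (2 * W + 1), 1)
    s2 = rss / dof
    cov = s2 * np.linalg.inv(J.T @ J)
    kd_se = float(np.sqrt(cov[0, 0]))
    amp_se = np.sqrt(np.diag(cov)[2::2])

    if kd > L.max():
        warnings.warn(
            f"saturation not approached: fitted KD {kd:.3g} M exceeds the top "
            f"ligand concentration {L.max():.3g} M",
            stacklevel=2,
        )
    return BindingFitResult(
        KD=kd,
        KD_se=kd_se,
        wavelengths=data.wavelengths[rows],
        amplitudes=a,
        amplitude_se=amp_se,
        rss=rss,
        n_obs=W * n,
        T=T,
    )


def fit_single_wavelength(
    L, dAU, T: float = T_DEFAULT
) -> tuple[float, float, tuple[float, float]]:
    """Fit one wavelength's difference-absorbance curve.

    Returns (KD, Amax, (SE_KD, SE_Amax)). Equivalent to a one-row global fit.
    """
    L = np.asarray(L, float)
    dAU = np.asarray(dAU, float)
    if L.size < 4:
        raise ValueError("need at least 4 titration points")
    data = TitrationDataset(
        ligand_concentrations=L,
        wavelengths=np.array([0.0]),
        absorbance=dAU[None, :],
    )
    fit = fit_global(data, T=T)
    return fit.KD, float(fit.amplitudes[0]), (fit.KD_se, float(fit.amplitude_se[0]))


def delta_g(KD: float, T: float = T_DEFAULT, R_const: float = R_KCAL) -> float:
    """Binding free energy dG = R T ln(KD / 1 M), kcal/mol (negative for KD < 1 M)."""
    if KD <= 0:
        raise ValueError("KD must be positive")
    return R_const * T * float(np.log(KD))


def delta_g_standard_error(
    KD: float, KD_se: float, T: float = T_DEFAULT, R_const: float = R_KCAL
) -> float:
    """First-order propagated SE: R T * SE(KD) / KD."""
    if KD <= 0:
        raise ValueError("KD must be positive")
    return R_const * T * KD_se / KD


def decompose_spin(
    spectrum: np.ndarray, high_spin_ref: np.ndarray, low_spin_ref: np.ndarray
) -> SpinDecomposition:
    """Constrained two-reference decomposition of an absorbance spectrum.

    Solves min_a || spectrum - (a*HS + (1-a)*LS) ||^2 subject to a in [0, 1];
    with the sum-to-one constraint this is a 1-D problem with a closed form.
    """
    s = np.asarray(spectrum, float)
    hs = np.asarray(high_spin_ref, float)
    ls = np.asarray(low_spin_ref, float)
    if not (s.shape == hs.shape == ls.shape):
        raise ValueError("spectrum and references must share one wavelength grid")
    d = hs - ls
    nrm = float(d @ d)
    if nrm < 1e-20 * max(float(hs @ hs), 1e-30):
        raise ValueError("degenerate references: high- and low-spin spectra coincide")
    alpha = float(np.clip((s - ls) @ d / nrm, 0.0, 1.0))
    resid = s - (alpha * hs + (1 - alpha) * ls)
    return SpinDecomposition(
        high_spin_reference=hs,
        low_spin_reference=ls,
        fraction_high_spin=alpha,
        fraction_low_spin=1.0 - alpha,
        residual=float(resid @ resid),
    )


def spin_fraction(
    spectrum: np.ndarray, high_spin_ref: np.ndarray, low_spin_ref: np.ndarray
) -> float:
    """Fraction of the high-spin reference in a spectrum (in [0, 1])."""
    return decompose_spin(spectrum, high_spin_ref, low_spin_ref).fraction_high_spin


def ionic_strength(comp: SaltComposition) -> float:
    """I = 1/2 sum_i c_i z_i^2 over all ion species, in M."""
    return 0.5 * sum(c * z * z for c, z in comp.species.values())
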