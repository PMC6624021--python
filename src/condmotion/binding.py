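"""Binding-model math: Hill fits with bootstrap CIs, the co-sedimentation
fractional-binding inversion, and the Bonferroni helper.

The Hill equation I = I_max·c^n / (K_D^n + c^n) describes cooperative
recruitment of actin to membrane condensates as a function of the titrated
component's concentration c; K_D is the half-saturation concentration and n
the Hill coefficient (n > 1: cooperative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["BindingFit", "fit_hill", "hill", "cosed_kd", "bonferroni"]


def hill(c: np.ndarray, I_max: float, K_D: float, n: float) -> np.ndarray:
    c = np.asarray(c, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = I_max * c**n / (K_D**n + c**n)
    return np.where(c == 0, 0.0, out)


@dataclass
class BindingFit:
    """Hill-fit results: point estimates, bootstrap 95% CIs, residual norm."""

    K_D: float
    hill_n: float
    I_max: float
    K_D_ci: tuple[float, float]
    hill_n_ci: tuple[float, float]
    residual_norm: float
    n_boot: int
    seed: int

    def summary(self) -> str:
        lines = [
            "Hill fit: I = I_max * c^n / (K_D^n + c^n)",
            f"  K_D   = {self.K_D:.4g}  95% CI [{self.K_D_ci[0]:.4g}, {self.K_D_ci[1]:.4g}]",
            f"  n     = {self.hill_n:.3g}  95% CI [{self.hill_n_ci[0]:.3g}, {self.hill_n_ci[1]:.3g}]",
            f"  I_max = {self.I_max:.4g}",
            f"  residual norm = {self.residual_norm:.4g}  "
            f"(bootstrap: {self.n_boot} residual resamples, seed {self.seed})",
        ]
        return "\n".join(lines)


def _fit_once(conc: np.ndarray, intensity: np.ndarray,
              p0: tuple[float, float, float]) -> np.ndarray:
    popt, _ = curve_fit(
        hill, conc, intensity, p0=p0,
        bounds=([0.0, 1e-12, 1e-3], [np.inf, np.inf, 50.0]), maxfev=5000)
    return popt


def fit_hill(conc, intensity, n_boot: int = 1000, seed: int = 0) -> BindingFit:
    """Least-squares Hill fit with seeded residual-resampling bootstrap CIs.

    Initialization: I_max₀ = max intensity, K_D₀ = concentration at
    half-maximum by linear interpolation, n₀ = 2. CIs are percentile
    (2.5–97.5) over ``n_boot`` refits of data with resampled residuals.
    """
    conc = np.asarray(conc, float)
    intensity = np.asarray(intensity, float)
    if len(conc) < 5:
        raise ValueError("need at least 5 concentration points")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")

    imax0 = float(intensity.max())
    order = np.argsort(conc)
    cs, is_ = conc[order], intensity[order]
    half = imax0 / 2.0
    kd0 = float(np.interp(half, is_, cs)) if np.any(is_ >= half) else float(np.median(cs))
    kd0 = max(kd0, 1e-9)
    p0 = (imax0, kd0, 2.0)

    try:
        popt = _fit_once(conc, intensity, p0)
    except RuntimeError as exc:
        raise ValueError(
            f"Hill fit failed to converge (data may not be sigmoidal): {exc}; "
            f"init I_max={imax0:.3g}, K_D={kd0:.3g}, n=2") from exc
    fitted = hill(conc, *popt)
    resid = intensity - fitted
    rnorm = float(np.linalg.norm(resid))

    rng = np.random.default_rng(seed)
    # residuals from a p-parameter fit underestimate the noise scale;
    # inflate by sqrt(n / (n - p)) so the bootstrap CIs are near-nominal
    inflate = math.sqrt(len(conc) / max(len(conc) - 3, 1))
    resampled = (resid - resid.mean()) * inflate
    kds, ns = [], []
    for _ in range(n_boot):
        boot = fitted + rng.choice(resampled, size=len(resid), replace=True)
        try:
            b = _fit_once(conc, boot, popt)
        except RuntimeError:
            continue
        kds.append(b[1])
        ns.append(b[2])
    if kds:
        kd_ci = tuple(np.percentile(kds, [2.5, 97.5]))
        n_ci = tuple(np.percentile(ns, [2.5, 97.5]))
    else:
        kd_ci = (popt[1], popt[1])
        n_ci = (popt[2], popt[2])
    # a degenerate bootstrap (zero residuals) must still bracket the estimate
    kd_ci = (min(kd_ci[0], popt[1]), max(kd_ci[1], popt[1]))
    n_ci = (min(n_ci[0], popt[2]), max(n_ci[1], popt[2]))

    return BindingFit(K_D=float(popt[1]), hill_n=float(popt[2]),
                      I_max=float(popt[0]), K_D_ci=kd_ci, hill_n_ci=n_ci,
                      residual_norm=rnorm, n_boot=n_boot, seed=seed)


def cosed_kd(fraction_bound: float, accessible_factin: float) -> float:
    """Dissociation constant from a co-sedimentation fraction bound.

    The fractional-binding relation f = K_A·A / (1 + K_A·A) (A = accessible
    F-actin concentration) inverts to K_A = f / ((1 − f)·A); the reported
    K_D is its reciprocal, A·(1 − f)/f, in the units of A.
    """
    f = float(fraction_bound)
    A = float(accessible_factin)
    if not 0 < f < 1:
        raise ValueError("fraction_bound must be strictly between 0 and 1")
    if A <= 0:
        raise ValueError("accessible_factin must be > 0")
    return A * (1.0 - f) / f


def bonferroni(alpha_total: float = 0.05, m: int = 1) -> float:
    """Per-comparison threshold alpha_total / m for m comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha_total < 1:
        raise ValueError("alpha_total must be in (0, 1)")
    return alpha_total / m


def bonferroni_display(alpha_total: float = 0.05, m: int = 1) -> float:
    """The threshold rounded to three decimals for display (0.05/8 → 0.006)."""
    return round(bonferroni(alpha_total, m), 3)
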