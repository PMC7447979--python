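"""Decompose the RPA binding shape into DMC1 and RAD51 components.

ChIP signal amplitudes are not comparable across assays, but the *shapes*
of the deconvolved profiles are.  If RPA on the DSB-initiating homolog is
displaced by DMC1 near the break and RAD51 distally, its unit-area profile
P should be a linear combination of the unit-area DMC1 (D) and RAD51 (R)
profiles:

    P = alpha + beta * D + gamma * R

fitted by ordinary least squares; beta/(beta+gamma) is the relative DMC1
share of the filament.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["MixtureFit", "normalize_area", "fit_mixture", "fixed_mixture_fit"]


@dataclass
class MixtureFit:
    alpha: float
    beta: float
    gamma: float
    residual_sse: float

    @property
    def prop_dmc1(self) -> float:
        s = self.beta + self.gamma
        return self.beta / s if s > 0 else float("nan")

    @property
    def prop_rad51(self) -> float:
        s = self.beta + self.gamma
        return self.gamma / s if s > 0 else float("nan")


def normalize_area(b) -> np.ndarray:
    """Scale a nonnegative profile to unit area (sum 1 over bins)."""
    b = np.asarray(b, dtype=float)
    total = b.sum()
    if total <= 0:
        raise ValueError("cannot normalize a zero-mass profile")
    return b / total


def fit_mixture(P, D, R) -> MixtureFit:
    """OLS of P on (1, D, R) for unit-area profiles on a common grid.

    Near-collinear D and R trigger a warning but the fit is still returned;
    negative fitted coefficients are reported as-is (with a warning), in
    which case the proportions are undefined.
    """
    P, D, R = (np.asarray(a, dtype=float) for a in (P, D, R))
    if not (P.shape == D.shape == R.shape):
        raise ValueError("P, D, R must share binning")
    X = np.column_stack([np.ones_like(D), D, R])
    coef, _, _, _ = np.linalg.lstsq(X, P, rcond=None)
    dr = np.column_stack([D - D.mean(), R - R.mean()])
    sv = np.linalg.svd(dr, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        warnings.warn("DMC1 and RAD51 profiles are nearly collinear; "
                      "coefficients are poorly identified", stacklevel=2)
    resid = P - X @ coef
    fit = MixtureFit(float(coef[0]), float(coef[1]), float(coef[2]),
                     float(resid @ resid))
    if fit.beta < 0 or fit.gamma < 0:
        warnings.warn("negative mixture coefficient: proportions undefined",
                      stacklevel=2)
    return fit


def fixed_mixture_fit(P, D, R, weights) -> dict:
    """Residual of the best fit with the DMC1:RAD51 ratio held fixed.

    Fits ``P = alpha + s * (w_d*D + w_r*R)`` with only the intercept and a
    common scale free, for comparison of imposed proportions (e.g. 50:50)
    against the free fit.
    """
    w_d, w_r = weights
    if w_d < 0 or w_r < 0 or not np.isclose(w_d + w_r, 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    P, D, R = (np.asarray(a, dtype=float) for a in (P, D, R))
    M = w_d * D + w_r * R
    X = np.column_stack([np.ones_like(M), M])
    coef, _, _, _ = np.linalg.lstsq(X, P, rcond=None)
    pred = X @ coef
    resid = P - pred
    return {
        "alpha": float(coef[0]),
        "scale": float(coef[1]),
        "predicted": pred,
        "residual_sse": float(resid @ resid),
    }
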