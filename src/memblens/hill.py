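"""Cooperative (Hill) binding-isotherm fitting.

Model: y(c) = B_max * c^n / (K^n + c^n) — saturation response B_max,
half-saturation concentration K, Hill coefficient n.  n > 1 indicates
positive cooperativity (sigmoidal isotherm), n = 1 reduces to the Langmuir
isotherm.  Fitting is unweighted nonlinear least squares (per-point standard
deviations switch on weighting); parameter standard errors come from the
Jacobian-based asymptotic covariance and R² = 1 − SS_res / SS_tot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "Isotherm",
    "HillFit",
    "fit_hill",
    "hill_predict",
    "hill_response",
    "simulate_isotherm",
    "read_isotherm",
]


def hill_response(c: np.ndarray, b_max: float, k_half: float, n: float) -> np.ndarray:
    c = np.asarray(c, dtype=np.float64)
    cn = np.power(c, n)
    return b_max * cn / (np.power(k_half, n) + cn)


@dataclass(frozen=True)
class Isotherm:
    """Equilibrium binding responses vs ligand concentration."""

    concentrations: np.ndarray
    responses: np.ndarray
    sd: np.ndarray | None = None  # optional per-point standard deviations
    units: str = "uM"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=np.float64)
        y = np.asarray(self.responses, dtype=np.float64)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", y)
        if self.sd is not None:
            object.__setattr__(self, "sd", np.asarray(self.sd, dtype=np.float64))
        if len(c) != len(y):
            raise ValueError("concentrations and responses differ in length")
        if len(c) < 4:
            raise ValueError("need >= 4 points for a 3-parameter fit")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.sd is not None and (len(self.sd) != len(c) or np.any(self.sd <= 0)):
            raise ValueError("per-point sd must be positive and match length")


@dataclass(frozen=True)
class HillFit:
    n_hill: float
    k_half: float
    b_max: float
    se_n: float
    se_k: float
    se_b: float
    r_squared: float
    converged: bool
    message: str = ""

    @property
    def cooperative(self) -> bool:
        return self.n_hill > 1.0

    def summary(self) -> str:
        coop = (
            "positive cooperativity (n > 1)"
            if self.cooperative
            else "no positive cooperativity (n <= 1)"
        )
        return (
            f"n_Hill = {self.n_hill:.2f} ± {self.se_n:.2f}, "
            f"K = {self.k_half:.3g} ± {self.se_k:.2g}, "
            f"B_max = {self.b_max:.3g} ± {self.se_b:.2g}, "
            f"R² = {self.r_squared:.3f} — {coop}"
        )


def _initial_guess(c: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    b0 = float(np.max(y))
    half = b0 / 2.0
    k0 = float(np.interp(half, y, c)) if np.any(y >= half) else float(np.median(c))
    if k0 <= 0:
        k0 = float(np.median(c))
    return b0, k0, 1.0


def fit_hill(data: Isotherm, max_iterations: int = 10000) -> HillFit:
    """Least-squares Hill fit; non-convergence is reported, not raised.

    The problem is solved in normalized coordinates (concentrations divided by
    their geometric mean, responses by their maximum) so the result is
    equivariant under rescaling of either axis to solver precision.
    """
    c, y = data.concentrations, data.responses
    span = float(np.ptp(y))
    if span > 0 and float(np.min(np.diff(y))) < -0.1 * span:
        import warnings

        warnings.warn(
            "responses are grossly non-monotone in concentration", stacklevel=2
        )
    c_scale = float(np.exp(np.mean(np.log(c))))
    y_scale = float(np.max(np.abs(y))) or 1.0
    cs, ys = c / c_scale, y / y_scale
    sd = data.sd / y_scale if data.sd is not None else None
    b0, k0, n0 = _initial_guess(cs, ys)

    try:
        popt, pcov = curve_fit(
            hill_response,
            cs,
            ys,
            p0=[b0 if b0 > 0 else 1.0, k0, n0],
            sigma=sd,
            absolute_sigma=sd is not None,
            bounds=([0.0, 1e-300, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=max_iterations,
            ftol=1e-14,
            xtol=1e-14,
            gtol=1e-14,
        )
    except RuntimeError as err:
        return HillFit(
            n_hill=float("nan"),
            k_half=float("nan"),
            b_max=float("nan"),
            se_n=float("nan"),
            se_k=float("nan"),
            se_b=float("nan"),
            r_squared=float("nan"),
            converged=False,
            message=str(err),
        )
    b, k, n = popt
    b *= y_scale
    k *= c_scale
    scale = np.array([y_scale, c_scale, 1.0])
    pcov = pcov * np.outer(scale, scale)
    resid = y - hill_response(c, b, k, n)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return HillFit(
        n_hill=float(n),
        k_half=float(k),
        b_max=float(b),
        se_n=float(se[2]),
        se_k=float(se[1]),
        se_b=float(se[0]),
        r_squared=r2,
        converged=True,
    )


def hill_predict(fit: HillFit, concentrations: np.ndarray) -> np.ndarray:
    """Evaluate the fitted isotherm (monotone non-decreasing in c)."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    c = np.asarray(concentrations, dtype=np.float64)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return hill_response(c, fit.b_max, fit.k_half, fit.n_hill)


def simulate_isotherm(
    n_hill: float,
    k_half: float,
    b_max: float,
    concentrations: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Isotherm:
    """Synthetic isotherm from known parameters plus Gaussian response noise.

    Default design: 8 log-spaced concentrations from K/10 to 10 K.
    """
    if concentrations is None:
        concentrations = np.geomspace(k_half / 10.0, 10.0 * k_half, 8)
    c = np.asarray(concentrations, dtype=np.float64)
    y = hill_response(c, b_max, k_half, n_hill)
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        y = y + rng.normal(0.0, noise_sd, size=len(c))
    return Isotherm(concentrations=c, responses=y)


def matched_noise_sd(
    n_hill: float,
    k_half: float,
    b_max: float,
    concentrations: np.ndarray | None = None,
    target_r2: float = 0.98,
) -> float:
    """Noise level whose expected R² on the clean design equals ``target_r2``.

    E[SS_res] ≈ (m − 3) σ² and E[SS_tot] ≈ SS_tot(clean) + (m − 1) σ² for m
    points and 3 fitted parameters; solving 1 − E[SS_res]/E[SS_tot] =
    target_r2 for σ gives the calibration.
    """
    if concentrations is None:
        concentrations = np.geomspace(k_half / 10.0, 10.0 * k_half, 8)
    c = np.asarray(concentrations, dtype=np.float64)
    y = hill_response(c, b_max, k_half, n_hill)
    m = len(c)
    ss_clean = float(((y - y.mean()) ** 2).sum())
    q = 1.0 - target_r2
    # sigma^2 * [(m - 3) - q (m - 1)] = q * ss_clean
    denom = (m - 3) - q * (m - 1)
    if denom <= 0:
        raise ValueError("design too small for the requested R²")
    return math.sqrt(q * ss_clean / denom)


def read_isotherm(path: str | Path, units: str = "uM") -> Isotherm:
    """Read a CSV/TSV with columns concentration, response[, sd]."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        conc = df[cols["concentration"]].to_numpy()
        resp = df[cols["response"]].to_numpy()
    except KeyError as err:
        raise ValueError(f"{path}: missing column {err}") from None
    sd = df[cols["sd"]].to_numpy() if "sd" in cols else None
    return Isotherm(concentrations=conc, responses=resp, sd=sd, units=units)
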