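"""Hill-equation dose-response modeling and nonlinear least-squares fitting.

The binding isotherm is

    ΔF/F0(c) = (ΔF/F0)max * c**n / (K_d**n + c**n)

with dissociation constant K_d (µM, half-saturation point), cooperativity n
and maximal response (ΔF/F0)max.  ``HillCurveFit`` is a scikit-learn style
estimator: ``fit(conc, response)`` recovers the three parameters by bounded
nonlinear least squares and exposes them as ``Kd_``, ``n_`` and
``dff0_max_``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

#: Protocol serotonin concentrations (µM) used for dose-response curves.
PROTOCOL_CONCENTRATIONS_UM = (0.1, 1.0, 5.0, 10.0, 30.0, 70.0, 100.0)

#: Dissociation constants (µM) reported for the serotonin-sensor lineage
#: (original sensor and the per-round sensitivity winners).
REPORTED_KD_UM = {"original": 11.6, "N1-12": 12.9, "N2-1": 10.7, "N3-5": 6.6}


def hill_model(
    conc_um,
    kd_um: float,
    n: float,
    dff0_max: float,
    variant: str = "standard",
):
    """Evaluate the Hill isotherm at one or more concentrations.

    ``variant="standard"`` uses the dimensionally consistent denominator
    ``Kd**n + c**n``; ``variant="literal"`` uses ``Kd + c**n`` (an alternate
    typeset form sometimes seen in print).  The two coincide at n = 1.
    """
    if kd_um <= 0:
        raise ValueError("K_d must be positive")
    if n <= 0:
        raise ValueError("cooperativity n must be positive")
    c = np.asarray(conc_um, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    cn = c**n
    denom = kd_um**n + cn if variant == "standard" else kd_um + cn
    out = dff0_max * cn / denom
    return float(out) if np.isscalar(conc_um) else out


class HillCurveFit(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares Hill fit of a dose-response curve.

    Parameters
    ----------
    variant : {"standard", "literal"}
        Denominator form of the isotherm (see :func:`hill_model`).
    log_kd : bool
        Optimise in log-K_d space.  On well-conditioned data this returns
        the same optimum as the linear parameterisation; it is exposed to
        let tests verify that invariance.
    kd_bounds_um, n_bounds : (low, high)
        Box constraints on K_d (µM) and cooperativity.
    init : (kd0, n0, max0) or None
        Optional explicit start; by default K_d starts at the concentration
        whose response is nearest half-max, n at 1, and the maximum at the
        largest observed response.
    xtol : float
        Optimiser tolerance.

    Attributes
    ----------
    Kd_ : float
        Fitted dissociation constant, µM.
    n_ : float
        Fitted cooperativity.
    dff0_max_ : float
        Fitted maximal response.
    sse_ : float
        Residual sum of squares at the optimum.
    converged_ : bool
        Whether the optimiser reported success.
    """

    def __init__(
        self,
        variant: str = "standard",
        log_kd: bool = False,
        kd_bounds_um: tuple[float, float] = (1e-6, 1e4),
        n_bounds: tuple[float, float] = (1e-3, 10.0),
        init: tuple[float, float, float] | None = None,
        xtol: float = 1e-12,
    ):
        self.variant = variant
        self.log_kd = log_kd
        self.kd_bounds_um = kd_bounds_um
        self.n_bounds = n_bounds
        self.init = init
        self.xtol = xtol

    def fit(self, X, y):
        """Fit the isotherm to concentrations ``X`` (µM) and responses ``y``.

        ``X`` may be a 1-D array or an (n, 1) column; at least three distinct
        concentrations are required.  The fit is invariant to the ordering
        of the points.
        """
        conc = np.asarray(X, dtype=float).reshape(-1)
        resp = np.asarray(y, dtype=float).reshape(-1)
        if conc.shape != resp.shape:
            raise ValueError("concentration and response lengths differ")
        if len(np.unique(conc)) < 3:
            raise ValueError("need at least 3 distinct concentrations")
        if np.any(conc < 0) or not np.all(np.isfinite(resp)):
            raise ValueError("concentrations must be >= 0 and responses finite")

        if self.init is not None:
            kd0, n0, max0 = self.init
        else:
            max0 = float(resp.max())
            if max0 <= 0:
                raise ValueError("maximum response must be positive to fit")
            half_idx = int(np.abs(resp - max0 / 2.0).argmin())
            kd0 = float(conc[half_idx]) if conc[half_idx] > 0 else float(np.median(conc[conc > 0]))
            n0 = 1.0
        kd_lo, kd_hi = self.kd_bounds_um
        kd0 = float(np.clip(kd0, kd_lo, kd_hi))
        n0 = float(np.clip(n0, *self.n_bounds))

        def unpack(theta):
            kd = np.exp(theta[0]) if self.log_kd else theta[0]
            return kd, theta[1], theta[2]

        def residuals(theta):
            kd, n, mx = unpack(theta)
            return hill_model(conc, kd, n, mx, variant=self.variant) - resp

        theta0 = [np.log(kd0) if self.log_kd else kd0, n0, max0]
        lower = [np.log(kd_lo) if self.log_kd else kd_lo, self.n_bounds[0], 0.0]
        upper = [np.log(kd_hi) if self.log_kd else kd_hi, self.n_bounds[1], np.inf]
        result = least_squares(
            residuals, theta0, bounds=(lower, upper), xtol=self.xtol, ftol=self.xtol,
            gtol=self.xtol, method="trf",
        )
        self.Kd_, self.n_, self.dff0_max_ = map(float, unpack(result.x))
        self.sse_ = float(np.sum(result.fun**2))
        self.converged_ = bool(result.success)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Model response at concentrations ``X`` (µM)."""
        check_is_fitted(self, "Kd_")
        conc = np.asarray(X, dtype=float).reshape(-1)
        return hill_model(conc, self.Kd_, self.n_, self.dff0_max_, variant=self.variant)


def fit_hill(
    concentrations_um,
    responses,
    init: tuple[float, float, float] | None = None,
    variant: str = "standard",
) -> HillCurveFit:
    """Convenience wrapper: fit and return the estimator."""
    return HillCurveFit(variant=variant, init=init).fit(concentrations_um, responses)


def normalize_curve(responses) -> np.ndarray:
    """Divide by the maximum observed response so values lie in [0, 1].

    Normalisation rescales only (ΔF/F0)max; K_d and n of a subsequent fit
    are unchanged.
    """
    resp = np.asarray(responses, dtype=float)
    peak = resp.max()
    if peak <= 0:
        raise ValueError("cannot normalise a curve with no positive response")
    return resp / peak
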