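"""Four-parameter sigmoid decay model of foveolar cone density.

The central object of the package: cone density as a function of
eccentricity ``E`` (µm from the cone density centroid, CDC) is modelled as

    D(E) = D0 / (1 + (E/a)^b)^c

with ``D0`` the density at the CDC (cones/mm²), ``a`` a horizontal scale
(µm) setting where the drop-off begins, ``b`` the sharpness of the drop
and ``c`` the flatness of the tail.  Fitting is constrained, robust
(bisquare-reweighted) nonlinear least squares on raw density with
``a ∈ [0.1, 150]``, ``b ∈ [1, 3]`` and ``c ∈ [0, 1]``.

The module follows the statsmodels convention: build a
:class:`SigmoidDecayModel` from data, call :meth:`~SigmoidDecayModel.fit`,
and read estimates and diagnostics off the returned
:class:`SigmoidFitResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np
from scipy.optimize import least_squares

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .profiles import DensityProfile

__all__ = [
    "SigmoidParams",
    "SigmoidDecayModel",
    "SigmoidFitResults",
    "fit_profile",
    "fit_error",
    "NORMATIVE_HORIZONTAL",
    "NORMATIVE_VERTICAL",
    "NORMATIVE_RADIAL",
    "A_BOUNDS",
    "B_BOUNDS",
    "C_BOUNDS",
    "BISQUARE_TUNING",
]

A_BOUNDS = (0.1, 150.0)
B_BOUNDS = (1.0, 3.0)
C_BOUNDS = (0.0, 1.0)

#: Conventional bisquare (Tukey biweight) tuning constant, 95% Gaussian efficiency.
BISQUARE_TUNING = 4.685


@dataclass(frozen=True)
class SigmoidParams:
    """Parameter set {D0, a, b, c} of the sigmoid decay model.

    Attributes
    ----------
    d0 : float
        Cone density at the CDC, cones/mm².  Strictly positive.
    a : float
        Eccentricity scale, µm, constrained to [0.1, 150].
    b : float
        Drop sharpness, unitless, constrained to [1, 3].
    c : float
        Tail flatness, unitless, constrained to [0, 1].
    """

    d0: float
    a: float
    b: float
    c: float

    def validate(self) -> "SigmoidParams":
        if not np.isfinite([self.d0, self.a, self.b, self.c]).all():
            raise ValueError("sigmoid parameters must be finite")
        if self.d0 <= 0:
            raise ValueError(f"D0 must be > 0, got {self.d0}")
        # small numerical slack so optimiser output at a bound validates
        eps = 1e-9
        for name, value, (lo, hi) in (
            ("a", self.a, A_BOUNDS),
            ("b", self.b, B_BOUNDS),
            ("c", self.c, C_BOUNDS),
        ):
            if not (lo - eps <= value <= hi + eps):
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
        return self

    # -- model math ------------------------------------------------------

    def __call__(self, ecc):
        return self.evaluate(ecc)

    def evaluate(self, ecc):
        """Model density (cones/mm²) at eccentricity ``ecc`` (µm, ≥ 0)."""
        ecc = np.asarray(ecc, dtype=float)
        if np.any(ecc < 0):
            raise ValueError("eccentricity must be >= 0")
        value = self.d0 / (1.0 + (ecc / self.a) ** self.b) ** self.c
        return float(value) if value.ndim == 0 else value

    def fraction_crossing(self, fraction: float) -> float:
        """Eccentricity (µm) where density falls to ``fraction`` of D0.

        Closed form: ``E = a * ((1/fraction)^(1/c) - 1)^(1/b)``.
        """
        if not 0.0 < fraction < 1.0:
            raise ValueError("fraction must lie strictly in (0, 1)")
        if self.c == 0:
            raise ValueError("flat model (c = 0) has no fractional crossing")
        return self.a * ((1.0 / fraction) ** (1.0 / self.c) - 1.0) ** (1.0 / self.b)

    def slope_metrics(self, max_ecc: float = 400.0, step: float = 0.01):
        """Most negative density slope and its eccentricity.

        Numerical differentiation of the model on a dense grid
        (default 0.01 µm step).  Returns ``(max_slope, inflection_ecc)``
        with the slope in (cones/mm²)/µm (negative).
        """
        ecc = np.arange(0.0, max_ecc + step / 2, step)
        slope = np.gradient(self.evaluate(ecc), ecc)
        i = int(np.argmin(slope))
        return float(slope[i]), float(ecc[i])

    def as_dict(self) -> dict:
        return {"d0": self.d0, "a": self.a, "b": self.b, "c": self.c}

    @classmethod
    def from_dict(cls, d: dict) -> "SigmoidParams":
        return cls(float(d["d0"]), float(d["a"]), float(d["b"]), float(d["c"]))


#: Normative cohort-average fits (adult foveola, left eyes), horizontal /
#: vertical meridians and radial average.  Shared D0 is the cohort-average
#: central density of the fitted group profile.
NORMATIVE_HORIZONTAL = SigmoidParams(175_500.0, 61.95, 2.469, 0.2680)
NORMATIVE_VERTICAL = SigmoidParams(175_500.0, 59.11, 2.012, 0.3568)
NORMATIVE_RADIAL = SigmoidParams(175_500.0, 55.50, 2.453, 0.2726)


def _bisquare_weights(resid: np.ndarray, tuning: float = BISQUARE_TUNING) -> np.ndarray:
    """Tukey biweight robustness weights from raw residuals.

    Scale is the MAD-based robust sigma; an (essentially) zero scale means
    a perfect fit, in which case all weights are one.
    """
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = mad / 0.6745
    if scale <= 1e-12 * max(1.0, np.max(np.abs(resid), initial=0.0)) or scale == 0.0:
        return np.ones_like(resid)
    u = resid / (tuning * scale)
    w = np.zeros_like(resid)
    inside = np.abs(u) < 1
    w[inside] = (1 - u[inside] ** 2) ** 2
    if not np.any(w > 0):  # pathological: keep plain least squares
        return np.ones_like(resid)
    return w


class SigmoidDecayModel:
    """Sigmoid decay model of a density-vs-eccentricity profile.

    Parameters
    ----------
    eccentricity : array-like
        Eccentricities (µm, ≥ 0).
    density : array-like
        Cone densities (cones/mm²), same length.
    d0 : float, optional
        Density at the CDC.  When given (the default analysis mode), D0 is
        held fixed and only {a, b, c} are estimated, mirroring the model's
        semantics of D0 as a measured quantity.  When None, D0 is a fourth
        free parameter.

    Examples
    --------
    >>> params = NORMATIVE_RADIAL
    >>> ecc = np.arange(0, 301.0)
    >>> model = SigmoidDecayModel(ecc, params.evaluate(ecc), d0=params.d0)
    >>> res = model.fit()
    >>> round(res.params.a, 2)
    55.5
    """

    def __init__(self, eccentricity, density, d0: Optional[float] = None):
        ecc = np.asarray(eccentricity, dtype=float)
        den = np.asarray(density, dtype=float)
        if ecc.shape != den.shape or ecc.ndim != 1:
            raise ValueError("eccentricity and density must be equal-length 1-D")
        keep = np.isfinite(ecc) & np.isfinite(den)
        ecc, den = ecc[keep], den[keep]
        if np.any(ecc < 0):
            raise ValueError("eccentricity must be >= 0")
        if np.unique(ecc).size < 10:
            raise ValueError("need >= 10 distinct eccentricity bins to fit")
        rel_span = np.ptp(den) / max(np.max(np.abs(den)), 1e-300)
        if rel_span < 1e-6:
            raise ValueError("degenerate (constant) profile cannot be fitted")
        if d0 is not None and d0 <= 0:
            raise ValueError("fixed D0 must be > 0")
        order = np.argsort(ecc)
        self.ecc = ecc[order]
        self.den = den[order]
        self.fixed_d0 = d0

    @classmethod
    def from_profile(
        cls, profile: "DensityProfile", d0: Optional[float] = None
    ) -> "SigmoidDecayModel":
        """Build from a :class:`~conetopo.profiles.DensityProfile`.

        Normalized profiles are rescaled back to density by their ``d0_ref``.
        """
        den = np.asarray(profile.density, dtype=float)
        if profile.normalized:
            if profile.d0_ref is None or profile.d0_ref <= 0:
                raise ValueError("normalized profile lacks a usable d0_ref")
            den = den * profile.d0_ref
            if d0 is None:
                d0 = profile.d0_ref
        return cls(np.abs(np.asarray(profile.eccentricity, float)), den, d0=d0)

    # -- fitting ---------------------------------------------------------

    def _predict(self, theta: np.ndarray) -> np.ndarray:
        if self.fixed_d0 is None:
            d0, a, b, c = theta
        else:
            d0 = self.fixed_d0
            a, b, c = theta
        return d0 / (1.0 + (self.ecc / a) ** b) ** c

    def fit(
        self,
        start_params: Optional[SigmoidParams] = None,
        robust: bool = True,
        max_iter: int = 400,
        xtol: float = 1e-8,
    ) -> "SigmoidFitResults":
        """Constrained (bisquare-)robust least squares fit.

        ``start_params`` defaults to the normative radial triplet, the same
        seeding used for every cohort fit.  Robust fitting iterates plain
        bounded least squares with Tukey biweight reweighting until the
        relative parameter change drops below ``xtol`` or ``max_iter``
        iterations elapse.
        """
        seed = start_params if start_params is not None else NORMATIVE_RADIAL
        if self.fixed_d0 is None:
            x0 = np.array([max(seed.d0, 1.0), seed.a, seed.b, seed.c])
            lo = np.array([1e-6, A_BOUNDS[0], B_BOUNDS[0], C_BOUNDS[0]])
            hi = np.array([np.inf, A_BOUNDS[1], B_BOUNDS[1], C_BOUNDS[1]])
        else:
            x0 = np.array([seed.a, seed.b, seed.c])
            lo = np.array([A_BOUNDS[0], B_BOUNDS[0], C_BOUNDS[0]])
            hi = np.array([A_BOUNDS[1], B_BOUNDS[1], C_BOUNDS[1]])
        x0 = np.clip(x0, lo, np.minimum(hi, np.finfo(float).max))

        weights = np.ones_like(self.den)
        x = x0
        converged = False
        n_iter = 0
        while n_iter < max_iter:
            sw = np.sqrt(weights)

            def residual(theta, _sw=sw):
                return _sw * (self._predict(theta) - self.den)

            sol = least_squares(
                residual, x, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            n_iter += 1
            change = np.max(np.abs(sol.x - x) / np.maximum(np.abs(x), 1e-12))
            x = sol.x
            if not robust:
                converged = sol.status > 0
                break
            weights = _bisquare_weights(self._predict(x) - self.den)
            # IRLS fixed point: stable parameters imply stable weights; require
            # one reweighted pass so the bisquare scheme actually engages
            if n_iter >= 2 and change < xtol:
                converged = True
                break

        if self.fixed_d0 is None:
            params = SigmoidParams(x[0], x[1], x[2], x[3]).validate()
        else:
            params = SigmoidParams(self.fixed_d0, x[0], x[1], x[2]).validate()
        return SigmoidFitResults(
            model=self,
            params=params,
            seed_params=seed,
            converged=converged,
            n_iter=n_iter,
            weights=weights,
        )


@dataclass
class SigmoidFitResults:
    """Results of a :class:`SigmoidDecayModel` fit.

    Carries the parameter estimates, the robustness weights of the final
    iteration, convergence information and residual diagnostics.
    """

    model: SigmoidDecayModel
    params: SigmoidParams
    seed_params: SigmoidParams
    converged: bool
    n_iter: int
    weights: np.ndarray

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.params.evaluate(self.model.ecc)

    @property
    def residuals(self) -> np.ndarray:
        """Raw residuals, data − model (cones/mm²)."""
        return self.model.den - self.fittedvalues

    @property
    def relative_errors(self) -> np.ndarray:
        """|data − model| / model, per eccentricity bin."""
        return np.abs(self.residuals) / self.fittedvalues

    @property
    def mean_abs_rel_error(self) -> float:
        return float(np.mean(self.relative_errors))

    def predict(self, ecc):
        return self.params.evaluate(ecc)

    def fraction_crossing(self, fraction: float) -> float:
        return self.params.fraction_crossing(fraction)

    def slope_metrics(self, max_ecc: float = 400.0, step: float = 0.01):
        return self.params.slope_metrics(max_ecc=max_ecc, step=step)

    def as_dict(self) -> dict:
        return {
            "params": self.params.as_dict(),
            "seed_params": self.seed_params.as_dict(),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "mean_abs_rel_error": self.mean_abs_rel_error,
        }

    def summary(self) -> str:
        p = self.params
        slope, infl = p.slope_metrics()
        lines = [
            "Sigmoid decay model fit",
            "=" * 47,
            f"{'n obs':<28}{self.model.ecc.size:>19d}",
            f"{'D0 (cones/mm^2)':<28}{p.d0:>19,.1f}"
            + ("  (fixed)" if self.model.fixed_d0 is not None else ""),
            f"{'a (um)':<28}{p.a:>19.4g}",
            f"{'b':<28}{p.b:>19.4g}",
            f"{'c':<28}{p.c:>19.4g}",
            f"{'mean |rel. error|':<28}{self.mean_abs_rel_error:>18.2%}",
            f"{'50% crossing (um)':<28}{p.fraction_crossing(0.5):>19.1f}",
            f"{'max slope ((c/mm^2)/um)':<28}{slope:>19.1f}",
            f"{'inflection (um)':<28}{infl:>19.1f}",
            f"{'converged':<28}{str(self.converged):>19}",
            f"{'iterations':<28}{self.n_iter:>19d}",
        ]
        return "\n".join(lines)


def fit_profile(
    profile: "DensityProfile",
    seed: Optional[SigmoidParams] = None,
    fix_d0: Optional[float] = None,
) -> SigmoidFitResults:
    """Fit the sigmoid model to a density profile.

    ``fix_d0`` holds D0 fixed (the standard analysis mode, D0 measured at
    the CDC); otherwise D0 is taken from the profile's normalization
    reference if available, else fitted freely.
    """
    model = SigmoidDecayModel.from_profile(profile, d0=fix_d0)
    return model.fit(start_params=seed)


def fit_error(profile: "DensityProfile", params: SigmoidParams):
    """Per-eccentricity relative fit error and its mean.

    Error is ``|D_data − D_fit| / D_fit`` evaluated wherever the profile is
    defined.  Returns ``(mean_abs_rel_error, per_ecc_error)``.
    """
    ecc = np.abs(np.asarray(profile.eccentricity, dtype=float))
    den = np.asarray(profile.density, dtype=float)
    if profile.normalized:
        if profile.d0_ref is None:
            raise ValueError("normalized profile lacks d0_ref")
        den = den * profile.d0_ref
    keep = np.isfinite(den)
    if not np.any(keep):
        raise ValueError("profile and model domains do not overlap")
    fitted = params.evaluate(ecc[keep])
    err = np.abs(den[keep] - fitted) / fitted
    return float(np.mean(err)), err
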