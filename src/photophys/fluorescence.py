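"""PAM chlorophyll-fluorescence parameters and rapid-light-curve fitting.

Implements the standard Genty / Stern-Volmer definitions

* ``Fv/Fm = (Fm - F0) / Fm`` -- maximum PSII quantum yield (dark-adapted),
* ``Phi_PSII = (Fm' - F') / Fm'`` -- effective yield under actinic light,
* ``NPQ = Fm / Fm' - 1`` -- non-photochemical quenching,

relative electron transport ``rETR = Phi_PSII * E`` (no absorptance or
PSII-fraction factor; any constant cancels in Ek and in between-line
comparisons), and a Webb saturating-exponential fit of rETR versus
irradiance yielding alpha, rETRmax and the light saturation index
``Ek = rETRmax / alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import lmfit

from .simulate import NPQTrace, webb_retr

__all__ = [
    "PAMParameters",
    "pam_parameters",
    "NPQTimecourse",
    "npq_timecourse",
    "relative_etr",
    "LightCurveModel",
    "LightCurveFit",
    "fit_light_curve",
]


@dataclass
class PAMParameters:
    fv_fm: float
    phi_psii: float
    npq: float
    valid: bool = True


def pam_parameters(
    F0: float, Fm: float, F_prime: float, Fm_prime: float
) -> PAMParameters:
    """Compute Fv/Fm, Phi_PSII and NPQ from the four fluorescence levels.

    Non-positive denominators raise; physically inconsistent inputs
    (``F0 > Fm`` or ``F' > Fm'``) return a result flagged invalid with NaN
    fields rather than silently clamping.
    """
    if Fm <= 0 or Fm_prime <= 0:
        raise ValueError("Fm and Fm_prime must be positive")
    if F0 > Fm or F_prime > Fm_prime:
        return PAMParameters(np.nan, np.nan, np.nan, valid=False)
    return PAMParameters(
        fv_fm=(Fm - F0) / Fm,
        phi_psii=(Fm_prime - F_prime) / Fm_prime,
        npq=Fm / Fm_prime - 1.0,
    )


@dataclass
class NPQTimecourse:
    """Per-pulse NPQ series with the figure's two comparison points."""

    series: pd.DataFrame          # time_s, phase, npq
    npq_end_induction: float      # last pulse of the induction phase
    npq_end_relaxation: float     # last pulse of the relaxation phase


def npq_timecourse(trace: NPQTrace) -> NPQTimecourse:
    """NPQ per saturating pulse, referenced to the dark-adapted Fm.

    Requires at least one dark-phase reference pulse.  The summary exposes
    NPQ at the end of induction (6 min) and the end of relaxation (12 min),
    the two points compared between lines.
    """
    pulses = trace.pulses
    if not (pulses["phase"] == "dark").any():
        raise ValueError("trace has no dark-phase reference pulse")
    if trace.Fm <= 0:
        raise ValueError("dark-adapted Fm must be positive")
    npq = trace.Fm / pulses["Fm_prime"].to_numpy() - 1.0
    series = pd.DataFrame({
        "time_s": pulses["time_s"].to_numpy(),
        "phase": pulses["phase"].to_numpy(),
        "npq": npq,
    })
    def _last(phase: str) -> float:
        sub = series[series["phase"] == phase]
        return float(sub["npq"].iloc[-1]) if len(sub) else np.nan
    return NPQTimecourse(series, _last("induction"), _last("relaxation"))


def relative_etr(phi_psii, e):
    """Relative electron transport rate, ``Phi_PSII * E``."""
    phi = np.asarray(phi_psii, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("irradiance must be >= 0")
    if np.any((phi < 0) | (phi > 1)):
        raise ValueError("phi_psii must lie in [0, 1]")
    out = phi * e
    return float(out) if out.ndim == 0 else out


@dataclass
class LightCurveFit:
    """Result of a Webb photosynthesis-irradiance fit.

    ``ek`` is stored as the quotient rETRmax/alpha, so the identity
    ``ek * alpha == retr_max`` holds exactly.
    """

    alpha: float
    retr_max: float
    residual_rms: float
    n_points: int
    converged: bool
    unsaturated: bool = False
    raw_retr_max: float = np.nan   # highest observed rETR, for reference

    @property
    def ek(self) -> float:
        return self.retr_max / self.alpha


class LightCurveModel:
    """Webb saturating-exponential model of rETR versus irradiance.

    Built from (E, Phi_PSII) points; ``fit()`` performs unweighted least
    squares of ``rETR(E) = rETRmax (1 - exp(-alpha E / rETRmax))`` on the
    internally computed rETR values and returns a :class:`LightCurveFit`.
    """

    def __init__(self, points: pd.DataFrame | np.ndarray):
        if isinstance(points, pd.DataFrame):
            e = points["e_umol_m2_s"].to_numpy(dtype=float)
            phi = points["phi_psii"].to_numpy(dtype=float)
        else:
            arr = np.asarray(points, dtype=float)
            e, phi = arr[:, 0], arr[:, 1]
        if np.any(e <= 0):
            raise ValueError("irradiance steps must be positive")
        order = np.argsort(e, kind="stable")
        self.e = e[order]
        self.phi = phi[order]
        self.retr = relative_etr(np.clip(self.phi, 0.0, 1.0), self.e)

    def fit(self) -> LightCurveFit:
        e, retr = self.e, self.retr
        if len(np.unique(e)) < 5:
            raise ValueError("need at least 5 points with distinct irradiance")
        # init: alpha from the 3 lowest-E points, rETRmax from the raw maximum
        alpha0 = float(np.mean(retr[:3] / e[:3]))
        rmax0 = float(np.max(retr))
        params = lmfit.Parameters()
        params.add("alpha", value=max(alpha0, 1e-6), min=1e-9)
        params.add("retr_max", value=max(rmax0, 1e-6), min=1e-9)
        def _resid(pars):
            return webb_retr(e, pars["alpha"].value, pars["retr_max"].value) - retr
        res = lmfit.minimize(_resid, params, method="leastsq")
        alpha = float(res.params["alpha"].value)
        retr_max = float(res.params["retr_max"].value)
        rms = float(np.sqrt(np.mean(res.residual**2)))
        unsaturated = bool(np.max(e) < retr_max / alpha)
        return LightCurveFit(
            alpha=alpha, retr_max=retr_max, residual_rms=rms,
            n_points=len(e), converged=bool(res.success),
            unsaturated=unsaturated, raw_retr_max=rmax0,
        )


def fit_light_curve(points) -> LightCurveFit:
    """Convenience wrapper: ``LightCurveModel(points).fit()``."""
    return LightCurveModel(points).fit()
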