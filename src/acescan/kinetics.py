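"""Calibration-normalized fluorescence losses, dissociation rates, and the
Michaelis–Menten induced-fit dose–response fit.

Surface duplexed aptamers (DAs) lose fluorescent aptamer molecules between
imaging rounds for three reasons: handling/photobleaching (measured on the
unincubated Calibration sub-array), spontaneous duplex dissociation
(``k_off``, BufferOnly), and ligand-induced dissociation (``k*_off``,
Ligand sub-arrays).  Because dissociated aptamer is overwhelmingly diluted,
dissociation is irreversible and first-order over the incubation interval::

    S = F_post / (F_hyb * (1 - phi)),      k_total = -ln(S) / delta_t

where ``phi`` is the per-DA fractional handling loss taken from the matched
spot on the Calibration sub-array (layouts are identical across sub-arrays).
The ligand-induced component is additive, ``k*_off,[L] = k_total - k_off``,
and saturates with concentration following a Michaelis–Menten approximation
to the Briggs–Haldane kinetics of the ternary ACE–aptamer–ligand system::

    k*_off,[L] = k*_off,max * [L] / (K_Fit + [L])

``K_Fit`` (molar) is the half-saturation ligand concentration of the
induced-fit pathway; ``k*_off,max`` (1/h) its ceiling rate.

Two normalizations are emitted side by side: the *relative loss* in percent
(Calibration == 100 % by construction; the quantity the heat maps print)
and the model-based first-order rate in 1/h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


class KineticsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# calibration + rates (scalar or ndarray inputs; NaN marks uncalibratable)


def relative_loss(f_hyb_cond, f_post_cond, f_hyb_cal, f_post_cal):
    """Fluorescence loss as a percentage of the Calibration loss.

    ``100 * (F_hyb_cond - F_post_cond) / (F_hyb_cal - F_post_cal)``.
    The Calibration condition itself yields exactly 100.  A non-positive
    calibration loss (signal gain between rounds) is uncalibratable -> NaN.
    """
    cond_loss = np.asarray(f_hyb_cond, float) - np.asarray(f_post_cond, float)
    cal_loss = np.asarray(f_hyb_cal, float) - np.asarray(f_post_cal, float)
    out = np.where(cal_loss > 0, 100.0 * cond_loss / np.where(cal_loss > 0, cal_loss, 1.0), np.nan)
    return out.item() if out.ndim == 0 else out


def calibration_loss_fraction(f_hyb_cal, f_post_cal):
    """phi = (F_hyb - F_post) / F_hyb on the Calibration sub-array."""
    f_hyb_cal = np.asarray(f_hyb_cal, float)
    out = (f_hyb_cal - np.asarray(f_post_cal, float)) / f_hyb_cal
    return out.item() if out.ndim == 0 else out


def corrected_survival(
    f_hyb_cond, f_post_cond, calibration_loss_fraction, *, return_flags=False
):
    """Handling-corrected duplex survival fraction in (0, 1].

    ``S = F_post / (F_hyb * (1 - phi))``.  Values above 1 (condition lost
    less than the Calibration did; noise) are clipped to 1 and flagged;
    ``phi >= 1`` is uncalibratable -> NaN.
    """
    phi = np.asarray(calibration_loss_fraction, float)
    f_hyb = np.asarray(f_hyb_cond, float)
    f_post = np.asarray(f_post_cond, float)
    denom = f_hyb * (1.0 - phi)
    uncal = (phi >= 1.0) | (denom <= 0)
    raw = np.where(uncal, np.nan, f_post / np.where(uncal, 1.0, denom))
    clipped = raw > 1.0
    s = np.where(clipped, 1.0, raw)
    if return_flags:
        return s, clipped, uncal
    return s.item() if s.ndim == 0 else s


def rate_from_survival(s, delta_t):
    """First-order dissociation rate ``k = -ln(S) / delta_t`` in 1/h."""
    s = np.asarray(s, float)
    if np.any(s <= 0):
        raise KineticsError("survival <= 0 implies an infinite rate")
    if delta_t <= 0:
        raise KineticsError("delta_t must be > 0")
    out = -np.log(s) / delta_t
    return out.item() if out.ndim == 0 else out


def induced_fit_rate(k_total_ligand, k_off_buffer):
    """Ligand-attributable rate ``k* = k_total - k_off`` (raw, signed)."""
    out = np.asarray(k_total_ligand, float) - np.asarray(k_off_buffer, float)
    return out.item() if out.ndim == 0 else out


def floor_rate(k):
    """Display flooring at 0 for landscapes; fits use the raw values."""
    out = np.maximum(np.asarray(k, float), 0.0)
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# dose-response model


@dataclass
class DoseResponseResults:
    """Estimates and diagnostics of a Michaelis–Menten dose–response fit."""

    k_star_max: float
    K_fit: float
    se_k_star_max: float
    se_K_fit: float
    rss: float
    nobs: int
    converged: bool
    flags: tuple[str, ...] = ()
    model: "DoseResponseModel | None" = None

    @property
    def params(self) -> np.ndarray:
        return np.array([self.k_star_max, self.K_fit])

    @property
    def bse(self) -> np.ndarray:
        return np.array([self.se_k_star_max, self.se_K_fit])

    def predict(self, concentrations=None) -> np.ndarray:
        if concentrations is None:
            concentrations = self.model.concentrations
        c = np.asarray(concentrations, float)
        return self.k_star_max * c / (self.K_fit + c)

    def summary(self) -> str:
        lines = [
            "Induced-fit dose-response fit (k* = k*_max [L] / (K_Fit + [L]))",
            "-" * 62,
            f"{'n observations':<22}{self.nobs}",
            f"{'converged':<22}{self.converged}",
            f"{'k*_off,max (1/h)':<22}{self.k_star_max:#.6g}  "
            f"(se {self.se_k_star_max:#.3g})",
            f"{'K_Fit (M)':<22}{self.K_fit:#.6g}  (se {self.se_K_fit:#.3g})",
            f"{'residual SS':<22}{self.rss:#.6g}",
        ]
        if self.flags:
            lines.append(f"{'flags':<22}{', '.join(self.flags)}")
        return "\n".join(lines)


class DoseResponseModel:
    """Two-parameter Michaelis–Menten fit of k*_off against [Ligand].

    Unweighted nonlinear least squares with positivity bounds.  Starting
    values: ``k*_max0 = max(k*)``, ``K0 = geometric mean of [L]``; bounds
    ``k*_max in [0, 10 k*_max0]``, ``K_Fit in [1e-3 min[L], 1e3 max[L]]``.
    Both scale with the data, so the fit is covariant under concentration
    unit changes.
    """

    def __init__(self, concentrations, k_star):
        c = np.asarray(concentrations, float)
        k = np.asarray(k_star, float)
        keep = np.isfinite(c) & np.isfinite(k)
        c, k = c[keep], k[keep]
        if len(np.unique(c[c > 0])) < 3:
            raise KineticsError(
                "dose-response fit requires >= 3 distinct positive "
                f"concentrations, got {len(np.unique(c[c > 0]))}"
            )
        if np.any(c <= 0):
            raise KineticsError("concentrations must be positive")
        self.concentrations = c
        self.k_star = k

    @classmethod
    def from_dataframe(cls, df, conc_col="concentration", rate_col="k_star"):
        return cls(df[conc_col].to_numpy(), df[rate_col].to_numpy())

    def predict(self, params, concentrations=None) -> np.ndarray:
        kmax, K = params
        c = self.concentrations if concentrations is None else np.asarray(concentrations, float)
        return kmax * c / (K + c)

    def fit(self) -> DoseResponseResults:
        c, k = self.concentrations, self.k_star
        n = len(c)
        kmax0 = float(np.max(k))
        flags: list[str] = []
        if kmax0 <= 0:
            # no induced fit anywhere on the curve: the ceiling rate is 0
            # and the half-saturation concentration is unidentifiable
            rss = float(np.sum(k**2))
            return DoseResponseResults(
                k_star_max=0.0,
                K_fit=np.nan,
                se_k_star_max=float(np.sqrt(rss / max(n - 1, 1) / n)),
                se_K_fit=np.nan,
                rss=rss,
                nobs=n,
                converged=True,
                flags=("kfit_undefined",),
                model=self,
            )
        K0 = float(np.exp(np.mean(np.log(c))))
        lo = np.array([0.0, 1e-3 * c.min()])
        hi = np.array([10.0 * kmax0, 1e3 * c.max()])
        x0 = np.clip(np.array([kmax0, K0]), lo, hi)

        def resid(p):
            return p[0] * c / (p[1] + c) - k

        sol = optimize.least_squares(
            resid, x0, bounds=(lo, hi), xtol=1e-10, ftol=1e-12, gtol=1e-12
        )
        converged = bool(sol.success)
        if not converged:
            flags.append("non_convergence")
        rss = float(np.sum(sol.fun**2))
        # standard errors from the Jacobian at the solution
        se = np.full(2, np.nan)
        dof = n - 2
        if dof > 0:
            jtj = sol.jac.T @ sol.jac
            try:
                cov = np.linalg.inv(jtj) * rss / dof
                se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
            except np.linalg.LinAlgError:
                flags.append("singular_jacobian")
        at_bound = np.any(np.isclose(sol.x, lo)) or np.any(np.isclose(sol.x, hi))
        if at_bound:
            flags.append("at_bound")
        return DoseResponseResults(
            k_star_max=float(sol.x[0]),
            K_fit=float(sol.x[1]),
            se_k_star_max=float(se[0]),
            se_K_fit=float(se[1]),
            rss=rss,
            nobs=n,
            converged=converged,
            flags=tuple(flags),
            model=self,
        )


def fit_dose_response(concentrations, k_star_values) -> DoseResponseResults:
    """Convenience wrapper: build the model and fit in one call."""
    return DoseResponseModel(concentrations, k_star_values).fit()
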