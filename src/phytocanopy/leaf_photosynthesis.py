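"""Ye's photosynthetic light-response model and its least-squares fit.

Net leaf photosynthesis as a function of incident light Q (PPFD):

    A(Q) = alpha * (1 - beta*Q) / (1 + gamma*Q) * Q - Rd

where ``alpha`` is the initial slope of the A-Q curve
((umol CO2)(umol photons)-1), ``beta`` and ``gamma`` are dimensionless
photoinhibition and light-saturation coefficients, and ``Rd`` is the dark
respiration rate (umol m-2 s-1).  For beta > 0 the curve has an interior
maximum; its closed form is

    Amax = alpha * ((sqrt(beta+gamma) - sqrt(beta)) / gamma)^2 - Rd

Fitting follows the usual nonlinear least-squares idiom: build a
:class:`LightResponseModel` from the A-Q observations, call :meth:`fit`,
and read estimates, standard errors, R2 and a summary table off the
returned :class:`LightResponseResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "LightResponseParams",
    "AQMeasurement",
    "net_photosynthesis",
    "amax",
    "saturating_ppfd",
    "solve_beta_gamma",
    "LightResponseModel",
    "LightResponseResults",
    "fit_light_response",
    "AQ_PPFD_LEVELS",
    "assign_layer",
    "LAYERS",
]

#: PPFD levels of the standard A-Q measurement protocol (umol m-2 s-1)
AQ_PPFD_LEVELS = (2000.0, 1800.0, 1500.0, 1200.0, 1000.0, 750.0, 500.0,
                  250.0, 150.0, 100.0, 50.0, 0.0)

LAYERS = ("upper", "ear", "lower")

#: default fit bounds: physiologically plausible maize ranges
FIT_BOUNDS = {
    "alpha": (1e-6, 0.15),
    "beta": (0.0, 1e-2),
    "gamma": (1e-5, 0.1),
    "Rd": (0.0, 10.0),
}


@dataclass
class LightResponseParams:
    """Fitted light-response parameters for one canopy layer of one cultivar."""

    alpha: float
    beta: float
    gamma: float
    Rd: float
    layer: str = ""
    cultivar: str = ""

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.Rd < 0:
            raise ValueError("Rd must be >= 0")

    @property
    def amax(self) -> float:
        return amax(self)


@dataclass
class AQMeasurement:
    ppfd: float
    A: float

    def __post_init__(self):
        if self.ppfd < 0:
            raise ValueError("PPFD must be >= 0")


def net_photosynthesis(params: LightResponseParams, ppfd) -> np.ndarray | float:
    """Net photosynthesis A (umol m-2 s-1) at PPFD (scalar or array)."""
    q = np.asarray(ppfd, dtype=float)
    if np.any(q < 0):
        raise ValueError("PPFD must be >= 0")
    a = params.alpha * (1.0 - params.beta * q) / (1.0 + params.gamma * q) * q - params.Rd
    return float(a) if np.isscalar(ppfd) else a


def saturating_ppfd(params: LightResponseParams) -> float:
    """PPFD at which A(Q) peaks (umol m-2 s-1); infinite when beta = 0."""
    if params.gamma <= 0:
        raise ValueError("gamma must be > 0")
    if params.beta <= 0:
        return math.inf
    return (math.sqrt((params.beta + params.gamma) / params.beta) - 1.0) / params.gamma


def amax(params: LightResponseParams) -> float:
    """Light-saturated maximum net photosynthesis rate (umol m-2 s-1)."""
    if params.gamma <= 0:
        raise ValueError("gamma = 0: no saturation, the linear model is unbounded")
    b, g = params.beta, params.gamma
    return params.alpha * ((math.sqrt(b + g) - math.sqrt(b)) / g) ** 2 - params.Rd


def solve_beta_gamma(alpha: float, amax_target: float, Rd: float,
                     beta: float = 1e-4) -> tuple[float, float]:
    """Invert the Amax closed form for gamma at a fixed (small) beta.

    Used to reconstruct a full parameter set from published (alpha, Amax,
    Rd) triples, which do not report beta and gamma.
    """
    if amax_target + Rd <= 0:
        raise ValueError("Amax + Rd must be > 0")
    target = (amax_target + Rd) / alpha

    def f(g):
        return ((math.sqrt(beta + g) - math.sqrt(beta)) / g) ** 2 - target

    lo, hi = 1e-8, 1.0
    if f(lo) < 0:
        raise ValueError("Amax too high for this alpha/beta")
    gamma = brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)
    return beta, gamma


def assign_layer(rank: int, ear_rank: int) -> str:
    """Canopy layer of a phytomer rank: the ear leaf and its immediate
    neighbours form the middle ('ear') layer; ranks above are 'upper',
    below are 'lower'."""
    if rank > ear_rank + 1:
        return "upper"
    if rank < ear_rank - 1:
        return "lower"
    return "ear"


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class LightResponseModel:
    """Nonlinear least-squares model for one A-Q curve.

    Parameters
    ----------
    ppfd, a : array-like
        Observed PPFD levels and net photosynthesis rates.  At least five
        distinct PPFD levels including 0 are required.
    """

    def __init__(self, ppfd, a, cultivar: str = "", layer: str = ""):
        self.ppfd = np.asarray(ppfd, float)
        self.a = np.asarray(a, float)
        self.cultivar = cultivar
        self.layer = layer
        if self.ppfd.shape != self.a.shape:
            raise ValueError("ppfd and a must have the same shape")
        if np.any(self.ppfd < 0):
            raise ValueError("PPFD must be >= 0")
        if len(np.unique(self.ppfd)) < 5:
            raise ValueError("need >= 5 distinct PPFD levels")
        if not np.any(self.ppfd == 0):
            raise ValueError("an A(0) observation is required to anchor Rd")
        if np.ptp(self.a) < 1e-9:
            raise ValueError("degenerate data: constant A")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, ppfd_col: str = "PPFD_umol_m2_s",
                       a_col: str = "A_umol_m2_s", **kw) -> "LightResponseModel":
        return cls(df[ppfd_col].to_numpy(), df[a_col].to_numpy(), **kw)

    @classmethod
    def from_measurements(cls, data: list[AQMeasurement], **kw) -> "LightResponseModel":
        return cls([m.ppfd for m in data], [m.A for m in data], **kw)

    # -- internals ---------------------------------------------------------
    def _residuals(self, theta):
        alpha, beta, gamma, rd = theta
        p = LightResponseParams(alpha=max(alpha, 1e-12), beta=max(beta, 0.0),
                                gamma=max(gamma, 1e-12), Rd=rd)
        return net_photosynthesis(p, self.ppfd) - self.a

    def _starts(self, n_starts):
        # slope from the low-light points, Rd from A(0)
        rd0 = float(np.clip(-self.a[self.ppfd == 0].mean(), 0.0, 10.0))
        low = (self.ppfd > 0) & (self.ppfd <= 300)
        if low.any():
            a0 = float(np.clip(np.median((self.a[low] + rd0) / self.ppfd[low]), 1e-3, 0.14))
        else:
            a0 = 0.05
        amax_obs = self.a.max() + rd0
        g0 = float(np.clip(a0 / max(amax_obs, 1e-6), 2e-5, 0.09))
        starts = [(a0, 1e-5, g0, rd0)]
        grid = [(a0 * fa, b, g0 * fg, rd0)
                for fa in (0.7, 1.3) for b in (1e-6, 1e-4, 5e-4) for fg in (0.5, 2.0)]
        starts.extend(grid)
        return starts[:max(n_starts, 1)]

    def _solve(self, n_starts, fix_beta=None):
        lb = [FIT_BOUNDS[k][0] for k in ("alpha", "beta", "gamma", "Rd")]
        ub = [FIT_BOUNDS[k][1] for k in ("alpha", "beta", "gamma", "Rd")]
        if fix_beta is not None:
            lb[1] = fix_beta
            ub[1] = fix_beta + 1e-15
        best = None
        for x0 in self._starts(n_starts):
            if fix_beta is not None:
                x0 = (x0[0], fix_beta, x0[2], x0[3])
            x0 = np.clip(x0, lb, ub)
            try:
                sol = least_squares(self._residuals, x0, bounds=(lb, ub),
                                    method="trf", xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        return best

    def fit(self, n_starts: int = 8, select: str = "aic") -> "LightResponseResults":
        """Multistart trust-region least squares; returns the best fit.

        The photoinhibition coefficient beta is weakly identified at
        chamber PPFD <= 2000 and inflates the variance of the other
        estimates when it is not supported by the data.  With
        ``select="aic"`` (default) the full model and the beta = 0
        restriction are both fitted and the lower-AICc one is returned
        (small-sample corrected AIC; k counts the error variance);
        ``select="full"`` always keeps beta free.
        """
        full = self._solve(n_starts)
        if full is None:
            raise RuntimeError("light-response fit failed from every start")
        best, k = full, 4
        if select == "aic":
            reduced = self._solve(n_starts, fix_beta=0.0)
            if reduced is not None:
                n = len(self.a)
                def aicc(sol, kk):
                    ssr = max(2.0 * sol.cost, 1e-300)
                    a = n * math.log(ssr / n) + 2 * kk
                    return a + 2 * kk * (kk + 1) / max(n - kk - 1, 1)
                if aicc(reduced, 4) < aicc(full, 5):
                    best, k = reduced, 3
        elif select != "full":
            raise ValueError(f"unknown model selection rule {select!r}")
        params = LightResponseParams(*best.x, layer=self.layer, cultivar=self.cultivar)
        return LightResponseResults(self, params, best, k_params=k)


class LightResponseResults:
    """Estimates, uncertainties and diagnostics of a fitted A-Q curve."""

    def __init__(self, model: LightResponseModel, params: LightResponseParams, sol,
                 k_params: int = 4):
        self.model = model
        self.params = params
        self.resid = sol.fun
        n, k = len(model.a), k_params
        ss_res = float(self.resid @ self.resid)
        ss_tot = float(((model.a - model.a.mean()) ** 2).sum())
        self.rsquared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        # Gauss-Newton covariance from the final Jacobian
        dof = max(n - k, 1)
        s2 = ss_res / dof
        J = sol.jac
        try:
            cov = s2 * np.linalg.pinv(J.T @ J)
            self.bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            self.bse = np.full(k, np.nan)

    @property
    def amax(self) -> float:
        return amax(self.params)

    def predict(self, ppfd) -> np.ndarray | float:
        return net_photosynthesis(self.params, ppfd)

    def summary(self) -> str:
        p = self.params
        names = ["alpha", "beta", "gamma", "Rd"]
        vals = [p.alpha, p.beta, p.gamma, p.Rd]
        lines = ["Light-response fit (Ye model)"]
        if p.cultivar or p.layer:
            lines.append(f"  cultivar: {p.cultivar or '-'}   layer: {p.layer or '-'}")
        lines.append(f"  n obs: {len(self.model.a)}    R2: {self.rsquared:.4f}")
        lines.append(f"  Amax: {self.amax:.2f} umol m-2 s-1")
        lines.append(f"  {'param':>8} {'estimate':>12} {'std err':>12}")
        for nm, v, se in zip(names, vals, self.bse):
            lines.append(f"  {nm:>8} {v:>12.6g} {se:>12.3g}")
        return "\n".join(lines)


def fit_light_response(data: list[AQMeasurement] | pd.DataFrame,
                       n_starts: int = 8, **kw) -> LightResponseResults:
    """Fit Ye's model to A-Q measurements (functional convenience wrapper)."""
    if isinstance(data, pd.DataFrame):
        model = LightResponseModel.from_dataframe(data, **kw)
    else:
        model = LightResponseModel.from_measurements(data, **kw)
    return model.fit(n_starts=n_starts)
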