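"""Boltzmann-sigmoid fitting and derived quantities.

The sigmoid ``y = Top / (1 + exp((v50 - x)/k))`` (bottom pinned at zero)
quantifies both EPSP-spike coupling (x = fEPSP slope, y = population-spike
amplitude) and paired-pulse inhibition (x = interpulse interval, y =
second spike as % of the first).  Fits with R^2 <= 0.8 are excluded from
group analyses; level crossings (the x at which y reaches 50/75/100% of
the first response) come from the closed-form inversion of the fit, and
nested models are compared with the extra sum-of-squares F test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .model import ValidationError

R2_INCLUSION_GATE = 0.8
PPI_FIT_RANGE_MAX_MS = 100.0  # fit "until a 100 ms interpulse interval", inclusive


def boltzmann(x, top, v50, k):
    x = np.asarray(x, dtype=float)
    arg = np.clip((v50 - x) / k, -700.0, 700.0)  # overflow guard for the optimizer
    return top / (1.0 + np.exp(arg))


@dataclass
class BoltzmannFit:
    top: float
    v50: float
    k: float
    bottom: float = 0.0       # pinned
    r_squared: float = float("nan")
    residual_ss: float = float("nan")
    n_points: int = 0
    converged: bool = False
    x: Optional[np.ndarray] = field(default=None, repr=False)
    y: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def included(self) -> bool:
        """Inclusion gate for group analyses: converged and R^2 > 0.8."""
        return self.converged and self.r_squared > R2_INCLUSION_GATE

    def predict(self, x):
        return boltzmann(x, self.top, self.v50, self.k)


def _initial_guess(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    top0 = float(np.max(y))
    span = float(np.ptp(x)) or 1.0
    half = top0 / 2.0
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    cross = np.nonzero((ys[1:] >= half) != (ys[:-1] >= half))[0]
    if cross.size:
        j = int(cross[0])
        frac = (half - ys[j]) / (ys[j + 1] - ys[j]) if ys[j + 1] != ys[j] else 0.5
        v500 = float(xs[j] + frac * (xs[j + 1] - xs[j]))
    else:
        v500 = float(np.median(x))
    return top0, v500, span / 10.0


def fit_boltzmann(x: Sequence[float], y: Sequence[float],
                  fit_range_max_x: Optional[float] = None) -> BoltzmannFit:
    """Bounded nonlinear least squares with deterministic initialisation.

    Initialisation: Top = max y, v50 = x at the half-maximum crossing,
    k = x-range/10.  Bounds: Top in (0, 2 max y], k in (0, x-range],
    v50 within one span of the x range.  On non-convergence three
    deterministically perturbed restarts are tried before the fit is
    marked ``converged=False`` (and hence excluded).  R^2 is computed on
    the fitted range only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if fit_range_max_x is not None:
        keep = x <= fit_range_max_x
        x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValidationError("need at least 4 points within the fit range")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValidationError("constant y: sigmoid parameters are unidentifiable")
    span = float(np.ptp(x)) or 1.0
    top0, v500, k0 = _initial_guess(x, y)
    eps = 1e-9
    bounds = ([eps, x.min() - span, eps],
              [2.0 * max(top0, eps), x.max() + span, span])

    def resid(p):
        return boltzmann(x, *p) - y

    starts = [(top0, v500, k0)]
    for f in (0.5, 1.5, 0.25):
        starts.append((min(top0 * (1 + f / 2), bounds[1][0]),
                       v500, min(max(k0 * f, eps), span)))
    best = None
    for p0 in starts:
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            sol = optimize.least_squares(resid, p0, bounds=bounds, method="trf",
                                         xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost < 1e-20:
            break
    if best is None:
        return BoltzmannFit(top=float("nan"), v50=float("nan"), k=float("nan"),
                            n_points=x.size, converged=False, x=x, y=y)
    top, v50, k = best.x
    ss_res = float(2 * best.cost)
    r2 = 1.0 - ss_res / ss_tot
    return BoltzmannFit(top=float(top), v50=float(v50), k=float(k),
                        r_squared=r2, residual_ss=ss_res, n_points=x.size,
                        converged=bool(best.success), x=x, y=y)


def fit_ppi(ipi_ms: Sequence[float], percent_of_first: Sequence[float],
            fit_range_max_ms: float = PPI_FIT_RANGE_MAX_MS) -> BoltzmannFit:
    """Fit the paired-pulse inhibition curve over the early portion
    (interpulse intervals up to and including 100 ms)."""
    return fit_boltzmann(ipi_ms, percent_of_first,
                         fit_range_max_x=fit_range_max_ms)


def fit_epsp_spike(fepsp_slopes_Vps: Sequence[float],
                   spike_amplitudes_mV: Sequence[float]) -> BoltzmannFit:
    """Fit EPSP-spike coupling: population-spike amplitude against fEPSP
    slope.  The v50 (slope at half-maximal spike) is the group-comparison
    statistic."""
    return fit_boltzmann(fepsp_slopes_Vps, spike_amplitudes_mV)


@dataclass
class LevelCrossings:
    """Interpolated x at stated percent-of-first-response levels (ms for
    PPI fits).  A level at or above the fitted Top is unattainable and
    reported as missing."""

    ipi_at_50: Optional[float]
    ipi_at_75: Optional[float]
    ipi_at_100: Optional[float]


def invert_boltzmann(fit: BoltzmannFit, y_level: float) -> Optional[float]:
    """Closed-form inversion x = v50 - k*ln(Top/y - 1); None if y >= Top."""
    if not y_level < fit.top:
        return None
    return float(fit.v50 - fit.k * math.log(fit.top / y_level - 1.0))


def interpolate_levels(fit: BoltzmannFit,
                       levels: Sequence[float] = (50.0, 75.0, 100.0),
                       ) -> LevelCrossings:
    """Level crossings of the fitted sigmoid at the stated y levels."""
    vals = [invert_boltzmann(fit, lv) for lv in levels]
    by = dict(zip(levels, vals))
    return LevelCrossings(ipi_at_50=by.get(50.0), ipi_at_75=by.get(75.0),
                          ipi_at_100=by.get(100.0))


@dataclass
class CurveComparison:
    """Extra sum-of-squares F test of shared vs separate Boltzmann fits."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    shared_fit: BoltzmannFit
    separate_fits: Tuple[BoltzmannFit, BoltzmannFit]


def compare_curves_extra_ss(x1, y1, x2, y2,
                            fit_range_max_x: Optional[float] = None,
                            ) -> CurveComparison:
    """Do two datasets share one sigmoid, or need separate curves?

    Fits the pooled data with a single curve (3 parameters) and each
    dataset with its own curve (6 parameters); the nested models are
    compared with F = ((SS_shared - SS_sep)/(df_shared - df_sep)) /
    (SS_sep/df_sep).
    """
    f1 = fit_boltzmann(x1, y1, fit_range_max_x)
    f2 = fit_boltzmann(x2, y2, fit_range_max_x)
    shared = fit_boltzmann(np.concatenate([f1.x, f2.x]),
                           np.concatenate([f1.y, f2.y]))
    if not (f1.converged and f2.converged and shared.converged):
        raise ValidationError("one of the curve fits failed to converge")
    n = f1.n_points + f2.n_points
    ss_sep = f1.residual_ss + f2.residual_ss
    ss_shared = shared.residual_ss
    df_shared, df_sep = n - 3, n - 6
    if df_sep <= 0:
        raise ValidationError("too few points for the separate-fits model")
    num = max(ss_shared - ss_sep, 0.0) / (df_shared - df_sep)
    den = ss_sep / df_sep
    F = num / den if den > 0 else (0.0 if num == 0 else float("inf"))
    p = float(stats.f.sf(F, df_shared - df_sep, df_sep))
    return CurveComparison(f_statistic=float(F), df_num=df_shared - df_sep,
                           df_den=df_sep, p_value=p, shared_fit=shared,
                           separate_fits=(f1, f2))
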