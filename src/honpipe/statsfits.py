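"""Hill-equation dose-response fits and histology count summaries.

Two modified Hill forms are supported as first-class options and the
caller chooses which applies to a dataset:

* increasing: ``S = S_max * F^h / (EC50^h + F^h)`` (e.g. spike output
  vs light-pulse frequency),
* decreasing: ``P = P_max - P_max * F^h / (IC50^h + F^h)`` (e.g. a
  response probability falling with frequency).

Standard paired/unpaired comparisons are delegated to scipy routines;
only thin reporting helpers live here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .core import ParameterError


@dataclass
class HillParams:
    """Fitted sigmoid parameters.

    ``top`` is S_max or P_max, ``x50`` the half-maximal dose (EC50 for
    the increasing form, IC50 for the decreasing one), ``h`` the Hill
    coefficient.
    """

    top: float
    h: float
    x50: float
    form: str
    residual_norm: float = np.nan

    def __post_init__(self) -> None:
        if self.top <= 0 or self.h <= 0 or self.x50 <= 0:
            raise ParameterError("Hill parameters must be positive")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _hill(np.asarray(x, float), self.top, self.h, self.x50, self.form)


def _hill(x, top, h, x50, form):
    frac = x**h / (x50**h + x**h)
    return top * frac if form == "increasing" else top - top * frac


def hill_fit(x, y, form: str = "increasing") -> HillParams:
    """Least-squares Hill fit with multi-start initialisation.

    Starts are taken on a grid of Hill coefficients {0.5, 1, 2, 4}
    crossed with x50 at the data quantiles; the best converged start by
    residual norm wins. Raises with diagnostics if no start converges.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if form not in ("increasing", "decreasing"):
        raise ParameterError(f"unknown form {form!r}")
    if x.size < 4:
        raise ParameterError("need at least 4 points to fit a Hill curve")
    if np.any(x <= 0):
        raise ParameterError("doses must be positive")

    top0 = max(float(np.max(y)), 1e-12)
    best = None
    failures = []
    for h0 in (0.5, 1.0, 2.0, 4.0):
        for q in (0.25, 0.5, 0.75):
            x50_0 = float(np.quantile(x, q))
            try:
                popt, _ = curve_fit(
                    lambda xx, top, h, x50: _hill(xx, top, h, x50, form),
                    x, y, p0=(top0, h0, x50_0),
                    bounds=([1e-12, 1e-3, 1e-12], [np.inf, 100.0, np.inf]),
                    maxfev=20000,
                )
                rnorm = float(np.linalg.norm(y - _hill(x, *popt, form)))
                if best is None or rnorm < best[1]:
                    best = (popt, rnorm)
            except (RuntimeError, ValueError) as exc:  # non-convergence of this start
                failures.append(f"h0={h0}, x50_0={x50_0:.3g}: {exc}")
    if best is None:
        raise ParameterError("Hill fit failed for every start:\n" + "\n".join(failures))
    (top, h, x50), rnorm = best
    return HillParams(top=float(top), h=float(h), x50=float(x50), form=form, residual_norm=rnorm)


@dataclass
class HistologyCounts:
    """Cell counts from immunohistochemistry sections.

    ``orexin_pos``: cells positive for the neuropeptide marker;
    ``double_pos``: co-labelled with the expressed reporter;
    ``marker_only``: reporter without the neuropeptide marker.
    """

    orexin_pos: int
    double_pos: int = 0
    marker_only: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        for name in ("orexin_pos", "double_pos", "marker_only"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ParameterError(f"{name} must be a non-negative integer, got {v}")


def histology_summary(counts: HistologyCounts, reference: HistologyCounts | None = None) -> dict:
    """Expression specificity/penetrance and percent of cells remaining.

    specificity = 100 * double / (double + marker_only);
    penetrance = 100 * double / orexin_pos;
    percent_remaining = 100 * counts.orexin_pos / reference.orexin_pos
    (e.g. an ablated cohort against its unablated control).
    """
    out = {"condition": counts.condition}
    lab = counts.double_pos + counts.marker_only
    out["specificity"] = 100.0 * counts.double_pos / lab if lab > 0 else 0.0
    if counts.orexin_pos <= 0:
        raise ParameterError("orexin_pos must be positive to compute penetrance")
    out["penetrance"] = 100.0 * counts.double_pos / counts.orexin_pos
    if reference is not None:
        if reference.orexin_pos <= 0:
            raise ParameterError("reference orexin_pos must be positive")
        out["percent_remaining"] = 100.0 * counts.orexin_pos / reference.orexin_pos
    return out


def paired_report(x, y, test: str = "ttest") -> dict:
    """Thin wrapper over standard paired comparisons for reporting."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if test == "ttest":
        t, p = stats.ttest_rel(x, y)
    elif test == "wilcoxon":
        t, p = stats.ranksums(x, y)
    else:
        raise ParameterError(f"unknown test {test!r}")
    return {"statistic": float(t), "p": float(p), "n": int(x.size), "test": test}
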