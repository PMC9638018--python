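"""ELISA/multiplex standard-curve fitting and cell-number correction.

Immunoassay optical densities are calibrated with a four-parameter logistic
(4PL) standard curve

    OD = d + (a - d) / (1 + (conc / c)^b)

fit to a dilution series of recombinant standard, then inverted analytically
to interpolate unknown concentrations.  Because secreted-cytokine readouts
scale with the number of live secreting cells, concentrations are finally
corrected to a common reference cell input using the known plated cell number
and the measured viability fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "StandardCurve",
    "CytokineMeasurement",
    "four_pl",
    "fit_4pl",
    "interpolate_conc",
    "correct_for_cells",
    "DEFAULT_REFERENCE_COUNT",
]

#: Reference live-cell input to which corrected concentrations are scaled
#: (0.2e6 cells, the standard supernatant-harvest input).
DEFAULT_REFERENCE_COUNT = 200_000


def four_pl(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    """4PL response: ``d + (a - d) / (1 + (x / c)**b)``.

    ``a`` is the response at zero concentration, ``d`` the response at
    infinite concentration, ``c`` the inflection (EC50) concentration and
    ``b`` the Hill slope.
    """
    x = np.asarray(x, dtype=float)
    return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass
class StandardCurve:
    """Fitted 4PL calibration with residual diagnostics."""

    a: float
    b: float
    c: float
    d: float
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("inflection concentration c must be positive")
        if self.b == 0:
            raise ValueError("slope b must be nonzero")

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return four_pl(conc, self.a, self.b, self.c, self.d)

    def summary(self) -> str:
        return (
            "4PL standard curve\n"
            f"  a (zero-conc response)  {self.a:.6g}\n"
            f"  d (saturating response) {self.d:.6g}\n"
            f"  c (inflection conc)     {self.c:.6g}\n"
            f"  b (Hill slope)          {self.b:.6g}\n"
            f"  residual sum of squares {self.rss:.6g} (n={len(self.residuals)})"
        )


def fit_4pl(
    standards: list[tuple[float, float]],
    max_restarts: int = 5,
    seed: int = 0,
) -> StandardCurve:
    """Least-squares 4PL fit to (concentration, OD) standards.

    Initial guesses come from data quantiles (asymptotes from the extreme
    ODs, ``c`` from the geometric mid-concentration); on non-convergence the
    initial guess is jittered with a fixed-seed generator and the fit retried.
    """
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need >= 5 (concentration, OD) standards spanning the curve")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x < 0):
        raise ValueError("standard concentrations must be non-negative")
    order = np.argsort(x)
    a0 = float(y[order[0]])
    d0 = float(y[order[-1]])
    pos = x[x > 0]
    c0 = float(np.exp(np.mean(np.log(pos)))) if len(pos) else 1.0
    b0 = 1.0  # with the (a, d) quantile init, the canonical branch has b > 0
    rng = np.random.default_rng(seed)
    p0 = np.array([a0, b0, c0, d0])
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        try:
            popt, _ = curve_fit(
                four_pl, x, y, p0=p0, maxfev=20000,
                bounds=([-np.inf, -np.inf, 1e-12, -np.inf], np.inf),
            )
            a, b, c, d = popt
            if c <= 0 or b == 0:
                raise RuntimeError("degenerate 4PL parameters")
            if b < 0:
                # (a, b, c, d) and (d, -b, c, a) define the same curve;
                # canonicalize so that a is the zero-concentration response
                a, b, d = d, -b, a
            residuals = y - four_pl(x, a, b, c, d)
            return StandardCurve(float(a), float(b), float(c), float(d), residuals)
        except (RuntimeError, ValueError) as err:
            last_err = err
            jitter = rng.normal(1.0, 0.2, size=4)
            p0 = np.array([a0, b0, c0, d0]) * jitter
    residuals = y - four_pl(x, a0, b0, c0, d0)
    raise RuntimeError(
        f"4PL fit did not converge after {max_restarts + 1} attempts "
        f"(last error: {last_err}; initial-guess RSS {np.sum(residuals**2):.4g})"
    )


def interpolate_conc(od: float, curve: StandardCurve) -> float:
    """Analytic 4PL inverse: ``c * ((a - d)/(od - d) - 1)**(1/b)``.

    Only defined strictly between the asymptotes ``a`` and ``d``.
    """
    lo, hi = sorted((curve.a, curve.d))
    if not (lo < od < hi):
        raise ValueError(
            f"OD {od} outside the curve's dynamic range ({lo:.4g}, {hi:.4g})"
        )
    ratio = (curve.a - curve.d) / (od - curve.d) - 1.0
    return float(curve.c * ratio ** (1.0 / curve.b))


@dataclass
class CytokineMeasurement:
    """One interpolated cytokine concentration with its well's cell context."""

    sample_id: str
    cytokine: str
    concentration: float  # pg/mL, uncorrected
    input_cell_count: float
    viability_fraction: float

    def __post_init__(self) -> None:
        if self.input_cell_count <= 0:
            raise ValueError("input cell count must be positive")
        if not (0.0 < self.viability_fraction <= 1.0):
            raise ValueError("viability fraction must be in (0, 1]")


def correct_for_cells(
    measurement: CytokineMeasurement,
    reference_count: float = DEFAULT_REFERENCE_COUNT,
) -> float:
    """Scale a concentration to a common reference number of live cells.

    corrected = raw * reference_count / (input_cell_count * viability_fraction)

    The denominator is the estimated number of live (secreting) cells in the
    well; wells with fewer live cells are scaled up proportionally.
    """
    live = measurement.input_cell_count * measurement.viability_fraction
    if live <= 0:
        raise ValueError("live cell number must be positive")
    if reference_count <= 0:
        raise ValueError("reference count must be positive")
    return measurement.concentration * reference_count / live
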