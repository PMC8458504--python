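"""Closed-form assay computations and binding-isotherm fitting.

Covers the quantitative readouts around the screen: 1:1 equilibrium binding
(thermophoresis-style titration over a serial dilution, hyperbolic isotherm
Kd fit with multistart nonlinear least squares), FRET efficiency, gelatin
degradation percentage, caliper tumor volume, TD50 from a linear viability
trend, and plasma protein binding percentage.

The default isotherm is the ligand-excess hyperbola
``s(c) = s_unbound + (s_bound - s_unbound) * c / (c + Kd)``; the
ligand-depletion quadratic form is available via ``model="quadratic"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


class FitError(RuntimeError):
    """Raised when a titration cannot be fitted (non-convergence, flat curve)."""


@dataclass
class TitrationCurve:
    """Concentration series (molar) and normalized signals of one titration."""

    concentrations: np.ndarray
    signals: np.ndarray
    replicate: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if c.shape != s.shape:
            raise ValueError("concentrations and signals differ in length")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        dc = np.diff(c)
        if not (np.all(dc > 0) or np.all(dc < 0)):
            raise ValueError("concentrations must be strictly monotonic")
        self.concentrations = c
        self.signals = s

    @classmethod
    def from_csv(cls, source, replicate: str = "") -> "TitrationCurve":
        data = np.loadtxt(source, delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1], replicate)

    def to_csv(self, dest) -> None:
        own = not hasattr(dest, "write")
        fh = open(dest, "w") if own else dest
        try:
            fh.write("concentration_M,signal\n")
            for c, s in zip(self.concentrations, self.signals):
                fh.write(f"{c:.10g},{s:.10g}\n")
        finally:
            if own:
                fh.close()


@dataclass
class BindingFit:
    """Result of a 1:1 isotherm fit: estimates, uncertainty, diagnostics."""

    kd: float
    signal_unbound: float
    signal_bound: float
    rss: float
    kd_stderr: float
    n_points: int
    model: str = "hyperbolic"

    def summary(self) -> str:
        lines = [
            "1:1 binding isotherm fit",
            f"  model          : {self.model}",
            f"  n points       : {self.n_points}",
            f"  Kd             : {self.kd:.4g} M ({self.kd * 1e9:.1f} nM)",
            f"  Kd std. error  : {self.kd_stderr:.4g} M",
            f"  signal unbound : {self.signal_unbound:.4g}",
            f"  signal bound   : {self.signal_bound:.4g}",
            f"  RSS            : {self.rss:.4g}",
        ]
        return "\n".join(lines)


def serial_dilution(top: float, factor: float = 2.0, n_points: int = 18) -> np.ndarray:
    """Geometric series c_i = top / factor**i, i = 0..n_points-1.

    The default 18-point 2-fold series from 200 uM ends at 1.526 nM,
    matching the 200 uM - 1.5 nM titration design.
    """
    if top <= 0:
        raise ValueError("top concentration must be positive")
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if n_points < 2:
        raise ValueError("need at least 2 points")
    return top / factor ** np.arange(n_points, dtype=float)


def _hyperbolic(c, kd, s_unbound, s_bound):
    return s_unbound + (s_bound - s_unbound) * c / (c + kd)


def _quadratic(c, kd, s_unbound, s_bound, target_conc):
    # ligand-depletion closed form: bound fraction of the fixed target
    b = c + target_conc + kd
    frac = (b - np.sqrt(b * b - 4.0 * c * target_conc)) / (2.0 * target_conc)
    return s_unbound + (s_bound - s_unbound) * frac


def simulate_titration(kd: float, s_unbound: float, s_bound: float,
                       concentrations, noise_sigma: float = 0.0,
                       seed: int = 0, replicate: str = "") -> TitrationCurve:
    """Noisy 1:1 hyperbolic titration (seeded Gaussian noise)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    c = np.asarray(concentrations, dtype=float)
    signal = _hyperbolic(c, kd, s_unbound, s_bound)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sigma, size=signal.shape)
    return TitrationCurve(c, signal, replicate)


def fit_kd(curve: TitrationCurve, model: str = "hyperbolic",
           target_conc: float | None = None) -> BindingFit:
    """Multistart nonlinear least squares on the 1:1 isotherm.

    Initial Kd guesses are log-spaced across the measured concentration
    range; the best converged fit (lowest RSS) wins.  The Kd standard error
    comes from the linearized covariance (J^T J)^-1 * RSS / (n - p).
    """
    c = curve.concentrations
    s = curve.signals
    if len(c) < 4:
        raise FitError("need at least 4 titration points")
    span = s.max() - s.min()
    if span < 1e-12 or span < 0.05 * max(abs(s.max()), abs(s.min()), 1e-12):
        raise FitError("flat titration curve: Kd is unidentifiable")

    # fit log10(Kd): the isotherm is far better conditioned in log space
    if model == "hyperbolic":
        fun = lambda cc, logkd, su, sb: _hyperbolic(cc, 10.0 ** logkd, su, sb)
    elif model == "quadratic":
        if target_conc is None or target_conc <= 0:
            raise ValueError("quadratic model requires a positive target_conc")
        fun = lambda cc, logkd, su, sb: _quadratic(cc, 10.0 ** logkd, su, sb,
                                                   target_conc)
    else:
        raise ValueError(f"unknown model {model!r}")

    s_sorted = s[np.argsort(c)]
    s_lo, s_hi = float(s_sorted[0]), float(s_sorted[-1])
    best = None
    for kd0 in np.geomspace(c.min() / 4, c.max(), 12):
        try:
            popt, pcov = curve_fit(
                fun, c, s, p0=[np.log10(kd0), s_lo, s_hi],
                bounds=([-15.0, -np.inf, -np.inf], [0.0, np.inf, np.inf]),
                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = fun(c, *popt) - s
        rss = float(resid @ resid)
        if best is None or rss < best[1]:
            best = (popt, rss, pcov)
    if best is None:
        raise FitError("no Kd start converged; data may not span the transition")
    popt, rss, pcov = best
    kd = float(10.0 ** popt[0])
    # delta method: se(Kd) = Kd * ln(10) * se(log10 Kd)
    kd_stderr = kd * np.log(10.0) * float(np.sqrt(max(0.0, pcov[0, 0])))
    return BindingFit(kd=kd, signal_unbound=float(popt[1]),
                      signal_bound=float(popt[2]), rss=rss,
                      kd_stderr=kd_stderr, n_points=len(c), model=model)


# ---------------------------------------------------------------------------
# Scalar assay formulas
# ---------------------------------------------------------------------------

def fret_efficiency(fret_corr: float, cfp: float) -> float:
    """FRETeff = FRETcorr / (FRETcorr + CFP) x 100 (percent)."""
    fret_corr = np.asarray(fret_corr, dtype=float)
    cfp = np.asarray(cfp, dtype=float)
    if np.any(fret_corr < 0) or np.any(cfp < 0):
        raise ValueError("signals must be non-negative")
    total = fret_corr + cfp
    if np.any(total == 0):
        raise ValueError("FRET efficiency undefined when both signals are zero")
    out = fret_corr / total * 100.0
    return float(out) if out.ndim == 0 else out


def percent_degradation(degraded_area: float, cell_area: float) -> float:
    """%Degradation = degraded gelatin area / cell area x 100."""
    if cell_area <= 0:
        raise ValueError("cell area must be positive")
    if degraded_area < 0:
        raise ValueError("degraded area must be non-negative")
    return degraded_area / cell_area * 100.0


def tumor_volume(major_mm: float, minor_mm: float) -> float:
    """Caliper volume = 0.5 x major x minor^2 (mm^3)."""
    if major_mm <= 0 or minor_mm <= 0:
        raise ValueError("axes must be positive")
    if minor_mm > major_mm:
        import warnings
        warnings.warn("minor axis exceeds major axis; check the measurement")
    return 0.5 * major_mm * minor_mm ** 2


def td50_linear(doses, viability_percent) -> float:
    """Median toxic dose from an OLS linear trend of viability vs dose.

    Returns the dose where the fitted line crosses 50% viability; the
    crossing must lie within the measured dose range.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viability_percent, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 dose points")
    slope, intercept = np.polyfit(d, v, 1)
    if abs(slope) < 1e-12:
        raise FitError("flat viability trend: TD50 undefined")
    td50 = (50.0 - intercept) / slope
    if not (d.min() <= td50 <= d.max()):
        raise FitError(
            f"fitted line crosses 50% at {td50:.3g}, outside the dose range")
    return float(td50)


def ppb_percent(total_signal: float, unbound_signal: float) -> float:
    """Plasma protein binding: (1 - unbound/total) x 100."""
    if total_signal <= 0:
        raise ValueError("total signal must be positive")
    if unbound_signal < 0 or unbound_signal > total_signal:
        raise ValueError("unbound signal must lie in [0, total]")
    return (1.0 - unbound_signal / total_signal) * 100.0
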