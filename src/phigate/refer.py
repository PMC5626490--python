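"""Bronsted plots and Phi estimation.

Each construct contributes one point (x, y) = (ln K_eq, ln k_CO); the Phi
value is the ordinary-least-squares slope of y on x across the perturbation
series, with the usual OLS slope standard error
``se = sqrt(SSR/(n-2) / sum((x - xbar)^2))``.  Standard errors of the
coordinates are propagated from the dwell-time SEMs by the delta method
(``se_ln k = SEM(tau)/tau``) and reported with each point; the default fit
is unweighted (a weighted fit is available for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .bursts import MutantGating
from .errors import ConfigError, DataError


@dataclass
class BronstedPoint:
    """One construct on the Bronsted plot."""

    label: str
    x: float          # ln K_eq
    y: float          # ln k_CO
    se_x: float
    se_y: float
    is_background: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise DataError(f"non-finite Bronsted point for {self.label!r}")


@dataclass
class PhiEstimate:
    """Bronsted regression result."""

    phi: float
    se_phi: float
    intercept: float
    r2: float
    n: int
    residuals: np.ndarray

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=np.float64)
        if self.n < 3:
            raise DataError("Phi regression needs at least 3 points")
        if self.se_phi < 0:
            raise DataError("se_phi must be >= 0")


def bronsted_points(series: list[MutantGating],
                    background_label: str | None = None
                    ) -> list[BronstedPoint]:
    """Map per-construct kinetics to Bronsted coordinates.

    ``y = ln k_CO`` carries the interburst uncertainty
    (``se_y = SEM(tau_ib)/tau_ib``); ``x = ln K_eq`` combines both dwell
    uncertainties in quadrature.  The background construct (named, or the
    first in the series) is flagged but enters the fit as an ordinary point.
    """
    labels = [m.label for m in series]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"duplicate construct labels: {labels}")
    if background_label is None:
        background_label = labels[0] if labels else None
    if background_label not in labels:
        raise ConfigError(f"background construct {background_label!r} "
                          "not in series")
    points = []
    for m in series:
        se_y = m.sem_ib / m.tau_ib
        se_x = float(np.hypot(se_y, m.sem_b / m.tau_b))
        points.append(BronstedPoint(
            label=m.label, x=float(np.log(m.K_eq)), y=float(np.log(m.k_CO)),
            se_x=se_x, se_y=se_y,
            is_background=(m.label == background_label)))
    return points


def fit_phi(points: list[BronstedPoint], weighted: bool = False) -> PhiEstimate:
    """Fit the Bronsted slope (Phi) by linear regression of y on x.

    Default: unweighted OLS.  With ``weighted=True`` a weighted
    least-squares fit with weights ``1/se_y^2`` is used instead (sensitivity
    analysis; not the default convention).
    """
    if len(points) < 3:
        raise DataError(f"need >= 3 Bronsted points, have {len(points)}")
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    if np.ptp(x) == 0:
        raise DataError("no K_eq spread; Phi undefined")
    if weighted:
        import statsmodels.api as sm
        se = np.array([p.se_y for p in points])
        if np.any(se <= 0):
            raise DataError("weighted fit requires positive se_y for every "
                            "point")
        model = sm.WLS(y, sm.add_constant(x), weights=1.0 / se ** 2).fit()
        intercept, slope = model.params
        se_phi = float(model.bse[1])
        resid = y - (intercept + slope * x)
        r2 = float(model.rsquared)
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        se_phi = float(res.stderr)
        resid = y - (intercept + slope * x)
        r2 = float(res.rvalue ** 2)
    return PhiEstimate(phi=float(slope), se_phi=se_phi,
                       intercept=float(intercept), r2=r2, n=len(points),
                       residuals=resid)


def make_report(series: list[MutantGating], phi: PhiEstimate,
                outdir: str | Path, points: list[BronstedPoint] | None = None,
                phi_true: float | None = None, plot: bool = False,
                prefix: str = "bronsted") -> dict[str, Path]:
    """Write the Bronsted points TSV, a key-value summary and optional plot.

    When a ground-truth phi is supplied (synthetic series) a recovery block
    is appended: the estimation error and whether the +/-2 se interval
    covers the truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if points is None:
        points = bronsted_points(series)
    paths: dict[str, Path] = {}

    pts_path = outdir / f"{prefix}_points.tsv"
    with open(pts_path, "w") as fh:
        fh.write("# phigate Bronsted points\n")
        fh.write("construct\tlnKeq\tlnkCO\tse_x\tse_y\tis_background\n")
        for p in points:
            fh.write(f"{p.label}\t{p.x:.9g}\t{p.y:.9g}\t{p.se_x:.9g}\t"
                     f"{p.se_y:.9g}\t{int(p.is_background)}\n")
    paths["points"] = pts_path

    summary_path = outdir / f"{prefix}_summary.txt"
    with open(summary_path, "w") as fh:
        fh.write(f"phi = {phi.phi:.9g}\n")
        fh.write(f"se_phi = {phi.se_phi:.9g}\n")
        fh.write(f"intercept = {phi.intercept:.9g}\n")
        fh.write(f"r2 = {phi.r2:.9g}\n")
        fh.write(f"n = {phi.n}\n")
        if phi_true is not None:
            err = phi.phi - phi_true
            covered = abs(err) <= 2.0 * phi.se_phi
            fh.write(f"phi_true = {phi_true:.9g}\n")
            fh.write(f"phi_error = {err:.9g}\n")
            fh.write(f"ci2se_covers_truth = {int(covered)}\n")
    paths["summary"] = summary_path

    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(4.2, 3.4))
        for p in points:
            color = "crimson" if p.is_background else "black"
            ax.errorbar(p.x, p.y, xerr=p.se_x, yerr=p.se_y, fmt="o",
                        color=color, capsize=2)
            ax.annotate(p.label, (p.x, p.y), textcoords="offset points",
                        xytext=(4, 4), fontsize=7)
        xs = np.linspace(min(p.x for p in points), max(p.x for p in points), 2)
        ax.plot(xs, phi.intercept + phi.phi * xs, "-", color="steelblue",
                label=f"$\\Phi$ = {phi.phi:.2f} $\\pm$ {phi.se_phi:.2f}")
        ax.set_xlabel(r"ln $K_{eq}$")
        ax.set_ylabel(r"ln $k_{CO}$")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        plot_path = outdir / f"{prefix}_plot.svg"
        fig.savefig(plot_path)
        plt.close(fig)
        paths["plot"] = plot_path
    return paths
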