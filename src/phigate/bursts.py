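"""Dwell-time mixture fitting, critical-time burst delimitation, and
per-construct kinetic summaries.

Closed dwell times after idealization are a mixture of a fast (flicker) and
a slow (interburst) exponential component.  The critical time t_crit is the
closed-duration cutoff that minimizes the expected number of misclassified
events, i.e. the time at which the two component densities are equal:

    (a_f/tau_f) exp(-t/tau_f) = (a_s/tau_s) exp(-t/tau_s)
    t_crit = tau_f*tau_s/(tau_s - tau_f) * ln(a_f*tau_s / (a_s*tau_f))

Closures shorter than t_crit are treated as intra-burst flickers; closures
at or above it delimit bursts.  Opening and closing rates are the inverses
of the mean interburst and burst durations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .idealize import EventList
from .traces import Trace


@dataclass
class DwellSample:
    """Dwell durations of one class, left-truncated at the dead time."""

    kind: str                 # "open" or "closed"
    durations: np.ndarray     # seconds
    t_min: float = 0.0        # left-truncation bound (= dead time)

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=np.float64)
        if self.kind not in ("open", "closed"):
            raise ConfigError("kind must be 'open' or 'closed'")
        if self.t_min < 0:
            raise ConfigError("t_min must be >= 0")
        if self.durations.size and self.durations.min() < self.t_min - 1e-12:
            raise DataError("durations below the truncation bound t_min")


@dataclass
class ExpMixture:
    """Left-truncated exponential mixture (components sorted by tau)."""

    fractions: np.ndarray
    taus: np.ndarray
    log_likelihood: float
    n: int
    t_min: float = 0.0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        self.taus = np.asarray(self.taus, dtype=np.float64)
        if self.fractions.size != self.taus.size:
            raise DataError("fractions and taus must have equal length")
        if np.any(self.fractions <= 0) or abs(self.fractions.sum() - 1) > 1e-8:
            raise DataError("fractions must be positive and sum to 1")
        if np.any(self.taus <= 0):
            raise DataError("taus must be positive")
        order = np.argsort(self.taus)
        self.taus = self.taus[order]
        self.fractions = self.fractions[order]

    @property
    def k(self) -> int:
        return self.taus.size

    def pdf(self, t: np.ndarray) -> np.ndarray:
        """Density on [t_min, inf), each component renormalized there."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, tau in zip(self.fractions, self.taus):
            out = out + (a / tau) * np.exp(-(t - self.t_min) / tau)
        return np.where(t >= self.t_min, out, 0.0)


def _em_exp_mixture(y: np.ndarray, a0: np.ndarray, tau0: np.ndarray,
                    max_iter: int = 2000, tol: float = 1e-12
                    ) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """EM for an exponential mixture on shifted data y >= 0."""
    a = a0.copy()
    tau = tau0.copy()
    n = y.size
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        log_f = np.log(np.maximum(a, 1e-300))[None, :] \
            - np.log(tau)[None, :] - y[:, None] / tau[None, :]
        m = log_f.max(axis=1, keepdims=True)
        p = np.exp(log_f - m)
        tot = p.sum(axis=1, keepdims=True)
        ll = float(np.sum(np.log(tot) + m))
        resp = p / tot
        w = resp.sum(axis=0)
        a = w / n
        tau = np.maximum((resp * y[:, None]).sum(axis=0) / np.maximum(w, 1e-300),
                         1e-12)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            converged = True
            break
        ll_old = ll
    return a, tau, ll, converged


def fit_exp_mixture(dwells: DwellSample, k: int) -> ExpMixture:
    """Maximum-likelihood left-truncated exponential mixture.

    For the truncated model each component density is
    ``(1/tau_j) exp(-(t - t_min)/tau_j)`` on ``[t_min, inf)``; fitting the
    shifted durations ``t - t_min`` with an ordinary exponential mixture is
    therefore exact.  ``k = 1`` has the closed-form MLE
    ``tau = mean(t) - t_min``.  For ``k >= 2`` EM is run from a fixed
    quantile-based multi-start grid; the best likelihood wins
    (deterministic given the data).
    """
    if k < 1:
        raise ConfigError(f"component count must be >= 1, got {k}")
    t = dwells.durations
    if t.size < 10 * k:
        raise DataError(
            f"need at least {10 * k} dwells to fit {k} components, "
            f"have {t.size}")
    y = np.maximum(t - dwells.t_min, 0.0)
    n = y.size
    if k == 1:
        tau = float(y.mean())
        if tau <= 0:
            raise DataError("all dwells at the truncation bound; tau undefined")
        ll = float(-n * np.log(tau) - y.sum() / tau)
        return ExpMixture(fractions=np.array([1.0]), taus=np.array([tau]),
                          log_likelihood=ll, n=n, t_min=dwells.t_min)

    qs = [np.linspace(0.15, 0.85, k), np.linspace(0.05, 0.95, k),
          np.linspace(0.3, 0.995, k)]
    starts = []
    for q in qs:
        tau0 = np.maximum(np.quantile(y, q), y.mean() * 1e-4 + 1e-12)
        starts.append((np.full(k, 1.0 / k), tau0))
    gm = y.mean()
    starts.append((np.full(k, 1.0 / k),
                   gm * np.logspace(-1.5, 0.5, k)))
    best = None
    for a0, tau0 in starts:
        a, tau, ll, conv = _em_exp_mixture(y, a0, np.asarray(tau0, float))
        if not conv:
            continue
        if best is None or ll > best[2]:
            best = (a, tau, ll)
    if best is None:
        raise DataError(
            f"exponential-mixture fit failed to converge (k={k}, n={n}, "
            f"mean={gm:.4g}); try fewer components")
    a, tau, ll = best
    return ExpMixture(fractions=a, taus=tau, log_likelihood=ll, n=n,
                      t_min=dwells.t_min)


def mixture_lrt_components(dwells: DwellSample, k_max: int = 3,
                           alpha: float = 0.05) -> ExpMixture:
    """Fit 2 components; admit a third by likelihood-ratio test.

    Adds one component at a time while ``2*dLL`` exceeds the chi-square
    critical value with 2 df at ``alpha``; warns when the two-component
    description is rejected.
    """
    from scipy.stats import chi2
    mix = fit_exp_mixture(dwells, 2)
    k = 2
    while k < k_max:
        try:
            cand = fit_exp_mixture(dwells, k + 1)
        except DataError:
            break
        if 2.0 * (cand.log_likelihood - mix.log_likelihood) \
                > chi2.ppf(1.0 - alpha, df=2):
            warnings.warn(
                f"closed dwell-time distribution prefers {k + 1} exponential "
                "components; the two-step gating description is questionable",
                stacklevel=2)
            mix = cand
            k += 1
        else:
            break
    return mix


def log_binned_histogram(durations: np.ndarray, mix: ExpMixture | None = None,
                         bins_per_decade: int = 10) -> pd.DataFrame:
    """Log-binned dwell histogram with square-root ordinate.

    Returns columns ``bin_center_s``, ``sqrt_count`` and ``fitted_density``
    (square root of the expected count per bin under ``mix``), the standard
    display for multi-exponential dwell distributions.
    """
    t = np.asarray(durations, float)
    t = t[t > 0]
    if t.size == 0:
        raise DataError("no dwells to histogram")
    lo = np.floor(np.log10(t.min()) * bins_per_decade) / bins_per_decade
    hi = np.ceil(np.log10(t.max()) * bins_per_decade) / bins_per_decade
    edges = 10 ** np.arange(lo, hi + 1.0 / bins_per_decade,
                            1.0 / bins_per_decade)
    counts, _ = np.histogram(t, bins=edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    fitted = np.full(centers.size, np.nan)
    if mix is not None:
        def cdf(x):
            x = np.maximum(np.asarray(x, float) - mix.t_min, 0.0)
            out = np.zeros_like(x)
            for a, tau in zip(mix.fractions, mix.taus):
                out = out + a * (1.0 - np.exp(-x / tau))
            return out
        expected = t.size * (cdf(edges[1:]) - cdf(edges[:-1]))
        fitted = np.sqrt(np.maximum(expected, 0.0))
    return pd.DataFrame({"bin_center_s": centers,
                         "sqrt_count": np.sqrt(counts),
                         "fitted_density": fitted})


def critical_time(mix: ExpMixture) -> float:
    """Closed-duration cutoff minimizing expected misclassifications.

    Solves equality of the fast and slow component densities; this minimizes
    ``N(t) = a_f exp(-t/tau_f) + a_s (1 - exp(-t/tau_s))``, the expected
    number (per closure) of flickers longer than t plus interbursts shorter
    than t.
    """
    if mix.k != 2:
        raise ConfigError(f"critical_time needs exactly 2 components, "
                          f"got {mix.k}")
    (a_f, a_s), (tau_f, tau_s) = mix.fractions, mix.taus
    if tau_f == tau_s:
        raise DataError("components indistinguishable (tau_f == tau_s)")
    t_c = tau_f * tau_s / (tau_s - tau_f) * np.log(a_f * tau_s / (a_s * tau_f))
    if not np.isfinite(t_c) or t_c <= 0:
        raise DataError(
            f"no positive critical time for fractions {a_f:.3g}/{a_s:.3g}, "
            f"taus {tau_f:.3g}/{tau_s:.3g} s: the slow component dominates "
            "at all durations; check the fit or supply a global t_crit")
    return float(t_c)


def misclassified_fraction(mix: ExpMixture, t: float) -> float:
    """Expected misclassifications per closure when cutting at ``t``."""
    (a_f, a_s), (tau_f, tau_s) = mix.fractions, mix.taus
    return float(a_f * np.exp(-t / tau_f) + a_s * (1.0 - np.exp(-t / tau_s)))


@dataclass
class BurstRecord:
    """Flicker-suppressed burst and interburst durations for one construct."""

    burst_durations: np.ndarray
    interburst_durations: np.ndarray
    t_crit: float
    total_open_time: float = 0.0
    total_time: float = 0.0
    n_segments: int = 1

    def __post_init__(self) -> None:
        self.burst_durations = np.asarray(self.burst_durations, float)
        self.interburst_durations = np.asarray(self.interburst_durations, float)
        if np.any(self.burst_durations <= 0) \
                or np.any(self.interburst_durations <= 0):
            raise DataError("burst/interburst durations must be positive")
        if self.interburst_durations.size and \
                self.interburst_durations.min() < self.t_crit - 1e-12:
            raise DataError("interburst shorter than t_crit")

    @property
    def n_bursts(self) -> int:
        return self.burst_durations.size

    @property
    def n_interbursts(self) -> int:
        return self.interburst_durations.size

    @staticmethod
    def merge(records: list["BurstRecord"]) -> "BurstRecord":
        if not records:
            raise DataError("no burst records to merge")
        return BurstRecord(
            burst_durations=np.concatenate(
                [r.burst_durations for r in records]),
            interburst_durations=np.concatenate(
                [r.interburst_durations for r in records]),
            t_crit=records[0].t_crit,
            total_open_time=sum(r.total_open_time for r in records),
            total_time=sum(r.total_time for r in records),
            n_segments=sum(r.n_segments for r in records),
        )


def reconstruct_bursts(events: EventList, t_crit: float) -> BurstRecord:
    """Suppress flickers and delimit bursts with the critical time.

    Closed events shorter than ``t_crit`` are flickers: the burst continues
    and the flicker time counts inside it.  Closed events at or above
    ``t_crit`` are interbursts.  A burst spans from its first opening to the
    end of its last opening.  Bursts and interbursts abutting the segment
    edges are censored and discarded.
    """
    if events.n == 0:
        raise DataError("empty event list")
    if np.any(events.levels > 1):
        raise DataError("burst reconstruction requires single-channel "
                        "segments (level <= 1)")
    if t_crit <= events.dead_time:
        raise ConfigError(
            f"t_crit ({t_crit:.4g} s) must exceed the dead time "
            f"({events.dead_time:.4g} s)")
    lv = events.levels
    du = events.durations
    is_divider = (lv == 0) & (du >= t_crit)
    div_idx = np.nonzero(is_divider)[0]
    if div_idx.size == 0:
        warnings.warn("no closures >= t_crit; no interbursts delimited",
                      stacklevel=2)
    # interbursts: divider events not at the record edges
    inter = du[div_idx[(div_idx > 0) & (div_idx < events.n - 1)]] \
        if div_idx.size else np.empty(0)
    # bursts between consecutive dividers (interior only: the stretch before
    # the first divider and after the last are censored)
    bursts: list[float] = []
    for a, b in zip(div_idx[:-1], div_idx[1:]):
        span_lv = lv[a + 1:b]
        span_du = du[a + 1:b]
        opens = np.nonzero(span_lv >= 1)[0]
        if opens.size == 0:
            continue  # dividers separated only by sub-t_crit closures
        bursts.append(float(span_du[opens[0]:opens[-1] + 1].sum()))
    return BurstRecord(
        burst_durations=np.array(bursts),
        interburst_durations=np.asarray(inter, float),
        t_crit=t_crit,
        total_open_time=float(du[lv >= 1].sum()),
        total_time=float(du.sum()),
        n_segments=1,
    )


@dataclass
class MutantGating:
    """Per-construct kinetic summary (mean +/- SEM convention)."""

    label: str
    tau_b: float
    sem_b: float
    tau_ib: float
    sem_ib: float
    k_CO: float
    k_OC: float
    K_eq: float
    P_o: float
    P_o_burst: float
    n_bursts: int
    n_interbursts: int
    n_segments: int = 1
    t_crit: float = float("nan")


def summarize_gating(record: BurstRecord, label: str) -> MutantGating:
    """Means, SEMs and rates from a burst record.

    ``k_CO = 1/mean(tau_ib)``, ``k_OC = 1/mean(tau_b)``,
    ``K_eq = k_CO/k_OC``; ``P_o`` is time-based (open time over total time)
    and ``P_o_burst`` burst-based (sum of bursts over bursts+interbursts).
    """
    if record.n_bursts < 2 or record.n_interbursts < 2:
        raise DataError(
            f"construct {label!r}: need >= 2 bursts and >= 2 interbursts "
            f"(have {record.n_bursts}/{record.n_interbursts})")
    b = record.burst_durations
    ib = record.interburst_durations
    tau_b = float(b.mean())
    tau_ib = float(ib.mean())
    sem_b = float(b.std(ddof=1) / np.sqrt(b.size))
    sem_ib = float(ib.std(ddof=1) / np.sqrt(ib.size))
    k_co = 1.0 / tau_ib
    k_oc = 1.0 / tau_b
    denom = b.sum() + ib.sum()
    p_o = (record.total_open_time / record.total_time
           if record.total_time > 0 else float("nan"))
    return MutantGating(
        label=label, tau_b=tau_b, sem_b=sem_b, tau_ib=tau_ib, sem_ib=sem_ib,
        k_CO=k_co, k_OC=k_oc, K_eq=k_co / k_oc, P_o=p_o,
        P_o_burst=float(b.sum() / denom) if denom > 0 else float("nan"),
        n_bursts=record.n_bursts, n_interbursts=record.n_interbursts,
        n_segments=record.n_segments, t_crit=record.t_crit,
    )


@dataclass
class ChannelCount:
    """Active-channel count from a high-P_o counting segment."""

    n: int
    p_underestimate: float = float("nan")


def count_channels(events: EventList, p_open: float | None = None,
                   k_co: float | None = None) -> ChannelCount:
    """Channel count = maximum simultaneous conductance level observed.

    If a per-channel open probability is supplied (or estimable from the
    time-averaged level), the analytic probability that one additional
    channel would have escaped detection in a segment of this length is
    reported: entries into the all-open level form an approximately Poisson
    stream with rate ``pi_{N-1} * k_CO`` (binomial occupancy), so
    ``P(miss) ~ exp(-rate * T)``.
    """
    if events.n == 0:
        raise DataError("empty counting segment")
    n = int(events.levels.max())
    if n == 0:
        raise DataError("counting segment shows no openings")
    n = max(n, 1)
    T = events.total_duration
    mean_level = float((events.levels * events.durations).sum() / T)
    p = p_open if p_open is not None else mean_level / n
    p = min(max(p, 0.0), 1.0)
    p_under = float("nan")
    if k_co is not None and 0 < p < 1:
        # rate of entries into the fully open level for n channels
        pi_top_minus_1 = n * p ** (n - 1) * (1.0 - p)
        rate = pi_top_minus_1 * k_co
        p_under = float(np.exp(-rate * T))
    return ChannelCount(n=n, p_underestimate=p_under)


def saturation_ratio(trace_3mM: Trace, trace_10mM: Trace,
                     threshold: float = 0.9,
                     baseline: tuple[float, float] | None = None,
                     min_current: float = 0.05) -> tuple[float, bool]:
    """Mean-current ratio between paired low/saturating ATP segments.

    Baselines default to the mode of each trace's smoothed all-points
    histogram (the closed peak).  Returns ``(ratio, is_saturating)`` with
    ``is_saturating = ratio >= threshold``.
    """
    from scipy import ndimage

    def mode_baseline(trace: Trace) -> float:
        counts, edges = np.histogram(trace.samples, bins=256)
        smooth = ndimage.gaussian_filter1d(counts.astype(float), 2.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        i = int(np.argmax(smooth))
        if 0 < i < smooth.size - 1:
            # parabolic sub-bin refinement of the closed-peak position
            y0, y1, y2 = smooth[i - 1:i + 2]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                i_frac = 0.5 * (y0 - y2) / denom
                return float(centers[i] + i_frac * (edges[1] - edges[0]))
        return float(centers[i])

    if baseline is None:
        b3, b10 = mode_baseline(trace_3mM), mode_baseline(trace_10mM)
    else:
        b3, b10 = baseline
    m3 = float(trace_3mM.samples.mean() - b3)
    m10 = float(trace_10mM.samples.mean() - b10)
    if abs(m10) < min_current:
        raise DataError(
            f"near-zero mean current at 10 mM ATP ({m10:.4g} pA); "
            "saturation ratio undefined")
    ratio = m3 / m10
    return ratio, bool(ratio >= threshold)
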