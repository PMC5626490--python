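"""Trace idealization: Gaussian filtering, level estimation, half-amplitude
threshold crossing, dead-time imposition, single-channel segmentation.

The filter has a Gaussian magnitude response ``|H(f)| = exp(-(ln2/2)(f/fc)^2)``
so that ``|H(fc)|^2 = 1/2`` (``fc`` is the -3 dB point) and unit DC gain; it
is applied zero-phase in the frequency domain on reflection-padded data.

Idealization assigns each sample its nearest conductance class (thresholds
midway between adjacent classes, i.e. half-amplitude crossing), places event
boundaries at the linear-interpolation crossing time between samples, and
then imposes a dead time retrospectively: events shorter than the dead time
are deleted shortest-first, concatenating flanking same-class events, until
none remain.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, signal

from .errors import ConfigError, DataError
from .traces import Trace

#: Shortest event reliably passed by a Gaussian filter with cutoff fc; the
#: standard resolution bound used as the floor for the dead time.
DEAD_TIME_FACTOR = 0.179


def gaussian_lowpass(trace: Trace, fc: float) -> Trace:
    """Zero-phase Gaussian low-pass filter with -3 dB cutoff ``fc`` (Hz)."""
    fs = trace.fs
    if not (0 < fc < fs / 2):
        raise ConfigError(f"cutoff above Nyquist or non-positive: fc={fc}, fs={fs}")
    x = trace.samples
    if x.size == 0:
        raise DataError("empty trace")
    # reflection padding long enough to swallow the filter's impulse
    # response; the right pad is extended to a fast FFT length
    from scipy.fft import irfft, next_fast_len, rfft, rfftfreq
    pad = min(x.size, max(16, int(np.ceil(4.0 * fs / fc))))
    m = next_fast_len(x.size + 2 * pad)
    xp = np.pad(x, pad, mode="reflect")
    # extra zero tail to reach the fast length; it sits one full pad away
    # from the data, beyond the filter support
    xp = np.concatenate((xp, np.full(m - xp.size, xp[-1])))
    freqs = rfftfreq(xp.size, d=1.0 / fs)
    H = gaussian_response(freqs, fc)
    y = irfft(rfft(xp) * H, n=xp.size)[pad:pad + x.size]
    return trace.with_samples(y, fc=fc)


def gaussian_response(freqs: np.ndarray, fc: float) -> np.ndarray:
    """Magnitude response of the Gaussian filter (|H(fc)|^2 = 1/2)."""
    return np.exp(-(np.log(2.0) / 2.0) * (np.asarray(freqs) / fc) ** 2)


def noise_bandwidth_factor(fs: float, fc: float) -> float:
    """Variance reduction factor of the filter for white noise sampled at fs.

    ``var_out = factor * var_in`` where ``factor = mean(|H(f)|^2)`` over the
    sampled band, evaluated in closed form via the Gaussian integral.
    """
    from scipy.special import erf
    s = np.sqrt(np.log(2.0))
    return float(np.sqrt(np.pi / np.log(2.0)) * (fc / fs)
                 * erf(s * fs / (2.0 * fc)))


@dataclass
class LevelEstimate:
    """Baseline/unitary-amplitude estimate from the all-points histogram."""

    baseline: float            # closed-peak current (pA)
    unitary_amplitude: float   # signed spacing between adjacent levels (pA)
    sd: float                  # common per-level SD (pA)
    n_levels_detected: int     # levels with non-negligible occupancy
    weights: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if abs(self.unitary_amplitude) <= 0:
            raise DataError("unitary amplitude must be non-zero")
        if self.sd < 0:
            raise DataError("level SD must be >= 0")


@dataclass
class EventList:
    """Idealized alternating dwell sequence.

    ``levels`` are integer conductance classes (0 = all closed); ``durations``
    are in seconds.  The first and last events abut the record edges and are
    therefore duration-censored.
    """

    levels: np.ndarray
    durations: np.ndarray
    fs: float
    dead_time: float = 0.0
    fc: float | None = None
    censored_first: bool = True
    censored_last: bool = True

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.durations = np.asarray(self.durations, dtype=np.float64)
        if self.levels.size != self.durations.size:
            raise DataError("levels and durations must have equal length")
        if np.any(self.durations < 0):
            raise DataError("negative event duration")
        if self.levels.size > 1 and np.any(np.diff(self.levels) == 0):
            raise DataError("adjacent events must differ in level")

    @property
    def n(self) -> int:
        return self.levels.size

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    def dwell_durations(self, open_state: bool, include_censored: bool = False
                        ) -> np.ndarray:
        """Durations of open (level>=1) or closed (level==0) events.

        Censored edge events are excluded by default: their durations are
        lower bounds, not samples from the dwell distribution.
        """
        mask = (self.levels >= 1) if open_state else (self.levels == 0)
        if not include_censored and self.n:
            if self.censored_first:
                mask = mask.copy()
                mask[0] = False
            if self.censored_last:
                mask = mask.copy()
                mask[-1] = False
        return self.durations[mask]

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# phigate events v1\n")
            fh.write(f"# fs = {self.fs}\n")
            fh.write(f"# fc = {'none' if self.fc is None else self.fc}\n")
            fh.write(f"# dead_time = {self.dead_time!r}\n")
            fh.write(f"# censored_first = {int(self.censored_first)}\n")
            fh.write(f"# censored_last = {int(self.censored_last)}\n")
            fh.write("index\tlevel\tduration_s\tcensored_flag\n")
            for i, (lv, du) in enumerate(zip(self.levels, self.durations)):
                cens = int((i == 0 and self.censored_first)
                           or (i == self.n - 1 and self.censored_last))
                fh.write(f"{i}\t{lv}\t{du:.9g}\t{cens}\n")
        return path

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EventList":
        path = Path(path)
        header: dict[str, str] = {}
        levels, durations, flags = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line[1:].strip()
                    if "=" in body:
                        k, _, v = body.partition("=")
                        header[k.strip()] = v.strip()
                    continue
                if line.startswith("index"):
                    continue
                cols = line.split("\t")
                levels.append(int(cols[1]))
                durations.append(float(cols[2]))
                flags.append(int(cols[3]))
        if not levels:
            raise DataError(f"event file {path} contains no events")
        fc = header.get("fc", "none")
        return cls(
            levels=np.array(levels),
            durations=np.array(durations),
            fs=float(header.get("fs", 0) or 0) or 1.0,
            dead_time=float(header.get("dead_time", 0.0)),
            fc=None if fc == "none" else float(fc),
            censored_first=bool(flags[0]),
            censored_last=bool(flags[-1]),
        )


def estimate_levels(
    trace: Trace,
    n_channels: int | None = None,
    amplitude_sign: int = -1,
    max_points: int = 20_000,
    max_iter: int = 150,
    fixed_baseline: float | None = None,
) -> LevelEstimate:
    """Fit the all-points histogram with equally spaced Gaussian peaks.

    The amplitude histogram is modelled as a mixture of ``n_channels + 1``
    Gaussians with means ``baseline + k * amplitude`` (k = 0..n_channels),
    common SD and free weights; the constrained EM M-step solves for
    (baseline, amplitude) by weighted least squares.  Candidate starts come
    from peaks of the smoothed histogram; the best-likelihood solution with
    the expected amplitude sign wins.

    With ``fixed_baseline`` the closed level is pinned (e.g. calibrated on a
    low-P_o stretch of the same patch) and only the spacing is fitted —
    needed for high-P_o counting segments where the all-closed level is
    essentially unvisited.
    """
    x = trace.samples
    if x.size < 100:
        raise DataError("trace too short for level estimation")
    if n_channels is None:
        n_channels = trace.meta.n_channels
    stride = max(1, x.size // max_points)
    x = x[::stride]
    n = x.size

    # candidate peaks of the smoothed all-points histogram
    counts, edges = np.histogram(x, bins=256)
    smooth = ndimage.gaussian_filter1d(counts.astype(float), sigma=2.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    padded = np.concatenate(([0.0], smooth, [0.0]))
    peaks, _ = signal.find_peaks(padded, prominence=0.02 * smooth.max())
    peaks -= 1
    if peaks.size < (1 if fixed_baseline is not None else 2):
        raise DataError("no openings detected (amplitude indeterminate)")
    peak_pos = centers[peaks]
    peak_height = smooth[peaks]
    order = np.argsort(peak_height)[::-1]
    peak_pos = peak_pos[order][:4]  # at most 4 candidate peaks

    k_idx = np.arange(n_channels + 1, dtype=float)
    span_lo, span_hi = float(x.min()), float(x.max())
    log_unif = -np.log(max(span_hi - span_lo, 1e-12))

    def em(b0: float, a0: float) -> tuple[float, float, float, float, np.ndarray]:
        # Gaussian peaks at b + k*a (common SD) plus a uniform background
        # that absorbs filter-transition samples bridging the levels, which
        # otherwise drag the fitted spacing inward.
        b, a = b0, a0
        s = max(np.std(x) / 4.0, 1e-6)
        w = np.full(n_channels + 1, (1.0 - 0.05) / (n_channels + 1))
        w_u = 0.05
        ll_old = -np.inf
        for _ in range(max_iter):
            mu = b + k_idx * a
            log_pdf = (-0.5 * ((x[:, None] - mu[None, :]) / s) ** 2
                       - np.log(s) - 0.5 * np.log(2 * np.pi)
                       + np.log(np.maximum(w, 1e-300))[None, :])
            log_bg = np.full((n, 1), log_unif + np.log(max(w_u, 1e-300)))
            log_all = np.concatenate((log_pdf, log_bg), axis=1)
            m = log_all.max(axis=1, keepdims=True)
            p = np.exp(log_all - m)
            tot = p.sum(axis=1, keepdims=True)
            ll = float(np.sum(np.log(tot) + m))
            resp = p / tot
            w = resp[:, :-1].mean(axis=0)
            w_u = float(resp[:, -1].mean())
            # weighted LS for (b, a): minimize sum_ik r_ik (x_i - b - k a)^2
            G = resp[:, :-1].sum(axis=1)
            K = resp[:, :-1] @ k_idx
            KK = resp[:, :-1] @ k_idx ** 2
            sum_g = float(G.sum())
            sum_k = float(K.sum())
            sum_kk = float(KK.sum())
            sum_gx = float(np.dot(G, x))
            sum_kx = float(np.dot(K, x))
            if fixed_baseline is not None:
                if sum_kk > 0:
                    a = (sum_kx - b * sum_k) / sum_kk
            else:
                det = sum_g * sum_kk - sum_k ** 2
                if det > 1e-12 * max(sum_g * sum_kk, 1.0):
                    b = (sum_kk * sum_gx - sum_k * sum_kx) / det
                    a = (sum_g * sum_kx - sum_k * sum_gx) / det
            mu = b + k_idx * a
            var = float(np.sum(resp[:, :-1] * (x[:, None] - mu[None, :]) ** 2)
                        / max(sum_g, 1e-12))
            s = max(np.sqrt(var), 1e-9)
            if abs(ll - ll_old) < 1e-7 * (1 + abs(ll)):
                break
            ll_old = ll
        return ll, b, a, s, w / max(w.sum(), 1e-300)

    best = None
    span = float(np.ptp(x))
    if fixed_baseline is not None:
        baselines = [float(fixed_baseline)]
    else:
        baselines = list(peak_pos)
    for b0 in baselines:
        others = peak_pos[np.abs(peak_pos - b0) > 0.05 * span]
        if fixed_baseline is not None:
            cands = [(p - b0) / m for p in others
                     for m in range(1, n_channels + 1)]
        else:
            cands = [p - b0 for p in others]
        for a0 in cands:
            if np.sign(a0) != np.sign(amplitude_sign):
                continue
            ll, b, a, s, w = em(b0, a0)
            if np.sign(a) != np.sign(amplitude_sign) or abs(a) < 1e-9:
                continue
            if best is None or ll > best[0]:
                best = (ll, b, a, s, w)
    if best is None:
        raise DataError("no openings detected (amplitude indeterminate)")
    _, b, a, s, w = best
    n_occupied = int(np.sum(w > 1e-3))
    if n_occupied < 2:
        raise DataError("no openings detected (amplitude indeterminate)")
    return LevelEstimate(baseline=b, unitary_amplitude=a, sd=s,
                         n_levels_detected=n_occupied, weights=w)


def idealize(
    trace: Trace,
    levels: LevelEstimate,
    dead_time: float,
    max_level: int | None = None,
) -> EventList:
    """Half-amplitude threshold idealization with retrospective dead time.

    Thresholds sit midway between adjacent conductance classes.  Event
    boundaries are placed at the linear-interpolation crossing time between
    the two bracketing samples; the first event starts at t=0 and the last
    ends at the record duration, so durations sum exactly to the record
    length.
    """
    if trace.n == 0:
        raise DataError("empty trace")
    if dead_time < 1.0 / trace.fs:
        raise ConfigError(
            f"dead_time must be >= one sample ({1.0 / trace.fs:.6g} s), "
            f"got {dead_time}")
    fs = trace.fs
    u = (trace.samples - levels.baseline) / levels.unitary_amplitude
    lv = np.floor(u + 0.5).astype(np.int64)
    np.clip(lv, 0, None, out=lv)
    if max_level is not None:
        np.clip(lv, 0, max_level, out=lv)

    change = np.nonzero(np.diff(lv))[0]          # boundary between i and i+1
    # linear-interpolation crossing times (sample timestamps = bin centers)
    if change.size:
        u0 = u[change]
        u1 = u[change + 1]
        thr = 0.5 * (lv[change] + lv[change + 1])
        frac = np.clip((thr - u0) / (u1 - u0), 0.0, 1.0)
        t_cross = (change + 0.5 + frac) / fs
    else:
        t_cross = np.empty(0)
    bounds = np.concatenate(([0.0], t_cross, [trace.n / fs]))
    durations = np.diff(bounds)
    run_levels = lv[np.concatenate((change, [trace.n - 1]))]
    # collapse any zero-duration artifacts (clamped crossings)
    keep = durations > 0
    run_levels, durations = _merge_equal(run_levels[keep], durations[keep])

    run_levels, durations = impose_dead_time(run_levels, durations, dead_time)
    return EventList(levels=run_levels, durations=durations, fs=fs,
                     dead_time=dead_time, fc=trace.meta.fc)


def _merge_equal(levels: np.ndarray, durations: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent events with equal level (summing durations)."""
    if levels.size == 0:
        return levels, durations
    new_run = np.concatenate(([True], np.diff(levels) != 0))
    idx = np.cumsum(new_run) - 1
    out_lv = levels[new_run]
    out_du = np.zeros(out_lv.size)
    np.add.at(out_du, idx, durations)
    return out_lv, out_du


def impose_dead_time(levels: np.ndarray, durations: np.ndarray,
                     dead_time: float) -> tuple[np.ndarray, np.ndarray]:
    """Delete events shorter than ``dead_time``, shortest first.

    A deleted event flanked by two same-class events is merged into them
    (their durations and its own are concatenated into one event).  If the
    flanking classes differ (possible with >2 conductance classes) the
    deleted event's time is split equally between them.  A short edge event
    is absorbed into its single neighbour.  The procedure conserves total
    time exactly and is idempotent.
    """
    lv = np.asarray(levels, dtype=np.int64).copy()
    du = np.asarray(durations, dtype=np.float64).copy()
    n = lv.size
    if n <= 1:
        return lv, du
    prev = np.arange(-1, n - 1)
    nxt = np.arange(1, n + 1)
    nxt[-1] = -1
    alive = np.ones(n, dtype=bool)
    heap = [(du[i], i) for i in range(n) if du[i] < dead_time]
    heapq.heapify(heap)
    while heap:
        d, i = heapq.heappop(heap)
        if not alive[i] or du[i] != d or du[i] >= dead_time:
            continue
        p, q = prev[i], nxt[i]
        if p == -1 and q == -1:
            break  # single surviving event: nothing to merge into
        if p == -1:
            du[q] += du[i]
            alive[i] = False
            prev[q] = -1
            if du[q] < dead_time:
                heapq.heappush(heap, (du[q], q))
        elif q == -1:
            du[p] += du[i]
            alive[i] = False
            nxt[p] = -1
            if du[p] < dead_time:
                heapq.heappush(heap, (du[p], p))
        elif lv[p] == lv[q]:
            du[p] += du[i] + du[q]
            alive[i] = False
            alive[q] = False
            r = nxt[q]
            nxt[p] = r
            if r != -1:
                prev[r] = p
            if du[p] < dead_time:
                heapq.heappush(heap, (du[p], p))
        else:
            half = du[i] / 2.0
            du[p] += half
            du[q] += half
            alive[i] = False
            nxt[p] = q
            prev[q] = p
            if du[p] < dead_time:
                heapq.heappush(heap, (du[p], p))
            if du[q] < dead_time:
                heapq.heappush(heap, (du[q], q))
    return _merge_equal(lv[alive], du[alive])


def auto_dead_time(levels: LevelEstimate, fs: float, fc: float | None,
                   false_event_rate: float = 0.02) -> float:
    """Noise-aware dead time.

    The floor is the filter resolution bound ``0.179/fc``.  On top of that,
    the dead time is raised until the predicted rate of noise-induced events
    surviving it drops below ``false_event_rate`` (Hz).  The prediction uses
    the Rice upcrossing rate of the half-amplitude threshold by Gaussian
    noise of the estimated SD band-limited by the Gaussian filter, with a
    Rayleigh model for excursion durations.
    """
    if fc is None:
        return 1.0 / fs
    floor = DEAD_TIME_FACTOR / fc
    sd = levels.sd
    amp = abs(levels.unitary_amplitude)
    if sd <= 0:
        return floor
    z = amp / (2.0 * sd)  # threshold in SD units
    nu0 = fc / np.sqrt(2.0 * np.log(2.0))          # zero-upcrossing rate
    nu = nu0 * np.exp(-0.5 * z * z)                # threshold upcrossings /s
    if nu <= false_event_rate:
        return floor
    from scipy.stats import norm
    mean_exc = norm.sf(z) / nu                     # mean excursion length
    # Rayleigh survival: P(dur > T) = exp(-(pi/4)(T/mean)^2)
    T = mean_exc * np.sqrt((4.0 / np.pi) * np.log(nu / false_event_rate))
    return float(max(floor, T))


def segment_single_channel(events: EventList, min_duration: float = 0.0
                           ) -> list[EventList]:
    """Maximal contiguous stretches with at most one channel open.

    Stretches are delimited by events with superimposed openings
    (level >= 2); their first and last events are duration-censored (by the
    record edge or by the delimiting multi-channel stretch) and flagged so.
    Segments shorter than ``min_duration`` seconds are dropped.  If the
    record never exceeds level 1 it is returned unchanged (one segment).
    """
    if events.n == 0:
        return []
    if np.all(events.levels <= 1):
        return [events] if events.total_duration >= min_duration else []
    out: list[EventList] = []
    idx = np.nonzero(events.levels <= 1)[0]
    if idx.size == 0:
        return []
    splits = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate(([0], splits + 1))
    ends = np.concatenate((splits, [idx.size - 1]))
    for s, e in zip(starts, ends):
        lo, hi = idx[s], idx[e]
        seg = EventList(
            levels=events.levels[lo:hi + 1].copy(),
            durations=events.durations[lo:hi + 1].copy(),
            fs=events.fs, dead_time=events.dead_time, fc=events.fc,
            censored_first=True, censored_last=True,
        )
        if seg.total_duration >= min_duration:
            out.append(seg)
    return out
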