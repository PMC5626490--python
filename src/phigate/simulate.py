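"""Synthetic single-channel data: gating trajectories and rendered traces.

The generator draws continuous-time Markov trajectories over the
C <-> O <-> C_f scheme, renders them as sampled current traces (bin-averaged
occupancy times the unitary amplitude, plus Gaussian noise, then the
Gaussian low-pass), and writes whole mutant series plus a manifest that
records the ground truth for parameter-recovery checks.

Noise is specified as the post-filter SD (the experimenter-visible number);
white noise is injected before the filter with its SD inflated by the
filter's known variance reduction so the filtered trace hits the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, DataError
from .idealize import gaussian_lowpass, noise_bandwidth_factor
from .kinetics import (AtpDependence, PhiDesign, RateSet, design_phi_series,
                       scale_by_atp)
from .traces import Trace, TraceMeta, write_trace

# state codes
C, O, F = 0, 1, 2
STATE_NAMES = {C: "C", O: "O", F: "C_f"}


@dataclass
class Trajectory:
    """Latent gating trajectory: alternating (state, duration) dwells."""

    states: np.ndarray      # int8 codes: 0=C, 1=O, 2=C_f
    durations: np.ndarray   # seconds
    duration: float         # total requested duration (last dwell truncated)
    channel: int = 0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.durations = np.asarray(self.durations, dtype=np.float64)
        if self.states.size != self.durations.size:
            raise DataError("states and durations must have equal length")
        if np.any(self.durations <= 0):
            raise DataError("trajectory dwells must be positive")
        if self.states.size > 1:
            a, b = self.states[:-1], self.states[1:]
            if np.any(a == b):
                raise DataError("consecutive states must differ")
            # allowed edges: C<->O, O<->C_f
            bad = (a != O) & (b != O)
            if np.any(bad):
                raise DataError("transition outside the C<->O<->C_f scheme")

    @property
    def open_mask(self) -> np.ndarray:
        return self.states == O

    def open_fraction(self) -> float:
        tot = self.durations.sum()
        return float(self.durations[self.open_mask].sum() / tot) if tot else 0.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_trajectory(rates: RateSet, duration: float, seed,
                        start_state: int | None = None) -> Trajectory:
    """Event-driven simulation of the 3-state gating chain.

    Dwell times are exponential with rate equal to the sum of exit rates of
    the current state; the successor is chosen by rate ratios.  The initial
    state is drawn from the stationary distribution unless ``start_state``
    is given.  The final dwell is truncated at ``duration``.
    """
    if duration < 0:
        raise ConfigError(f"duration must be >= 0, got {duration}")
    rng = _as_rng(seed)
    if duration == 0:
        return Trajectory(states=np.empty(0, np.int8),
                          durations=np.empty(0), duration=0.0)
    if not rates.is_gating:
        raise DataError("non-gating rate set")
    flicker_load = rates.k_OF / rates.k_FO if rates.k_OF > 0 else 0.0
    if start_state is None:
        # stationary distribution over (C, O, C_f)
        pi = np.array([rates.k_OC / rates.k_CO, 1.0, flicker_load])
        pi /= pi.sum()
        state = int(rng.choice(3, p=pi))
    else:
        state = int(start_state)
    exit_rate = {C: rates.k_CO, O: rates.k_OC + rates.k_OF, F: rates.k_FO}
    p_open_to_c = rates.k_OC / (rates.k_OC + rates.k_OF)

    states: list[int] = []
    durs: list[float] = []
    t = 0.0
    while t < duration:
        r = exit_rate[state]
        dwell = rng.exponential(1.0 / r)
        if t + dwell >= duration:
            dwell = duration - t
            states.append(state)
            durs.append(dwell)
            break
        states.append(state)
        durs.append(dwell)
        t += dwell
        if state == C:
            state = O
        elif state == F:
            state = O
        else:
            state = C if rng.random() < p_open_to_c else F
    return Trajectory(states=np.array(states, np.int8),
                      durations=np.array(durs), duration=duration)


def render_trace(trajectories: list[Trajectory] | Trajectory,
                 meta: TraceMeta, seed=None) -> Trace:
    """Render trajectories as a sampled, noisy, filtered current trace.

    The noiseless signal in sample bin i is the time-weighted average of
    ``baseline + unitary_amplitude * n_open(t)`` over the bin, so dwells
    shorter than one sample contribute fractionally.  Gaussian white noise
    (SD inflated to hit ``meta.noise_sd`` post-filter) is added before the
    Gaussian low-pass at ``meta.fc``; with ``fc=None`` no filter is applied
    and the injected SD equals ``meta.noise_sd``.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise DataError("no trajectories to render")
    T = trajectories[0].duration
    for tr in trajectories:
        if abs(tr.duration - T) > 1e-9:
            raise DataError("mismatched trajectory durations")
    fs = meta.fs
    n = int(round(T * fs))
    if n == 0:
        raise DataError("trace would contain zero samples")
    edges = np.arange(n + 1) / fs
    open_time = np.zeros(n)
    for tr in trajectories:
        bounds = np.concatenate(([0.0], np.cumsum(tr.durations)))
        bounds[-1] = T  # guard rounding
        # cumulative open time as piecewise-linear function of t
        open_durs = np.where(tr.open_mask, tr.durations, 0.0)
        cum_open = np.concatenate(([0.0], np.cumsum(open_durs)))
        open_time += np.diff(np.interp(edges, bounds, cum_open))
    x = meta.baseline + meta.unitary_amplitude * open_time * fs
    if meta.noise_sd > 0:
        rng = _as_rng(meta.seed if seed is None else seed)
        if meta.fc is not None:
            inflate = 1.0 / np.sqrt(noise_bandwidth_factor(fs, meta.fc))
        else:
            inflate = 1.0
        x = x + rng.normal(0.0, meta.noise_sd * inflate, size=n)
    trace = Trace(samples=x, fs=fs, meta=replace(meta, fc=None))
    if meta.fc is not None:
        trace = gaussian_lowpass(trace, meta.fc)
    return trace


@dataclass
class ConstructEntry:
    label: str
    rates: RateSet
    delta: float
    traces: dict[str, str] = field(default_factory=dict)  # segment -> path


@dataclass
class SeriesManifest:
    """Ground truth and file map for a generated mutant series."""

    constructs: list[ConstructEntry]
    meta: TraceMeta
    phi_true: float | None = None
    seed: int | None = None
    atp: AtpDependence | None = None
    root: Path | None = None

    def trace_path(self, label: str, segment: str = "main") -> Path:
        for c in self.constructs:
            if c.label == label:
                rel = c.traces[segment]
                return (self.root / rel) if self.root else Path(rel)
        raise DataError(f"construct {label!r} not in manifest")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {
            "phi_true": self.phi_true,
            "seed": self.seed,
            "meta": self.meta.to_dict(),
            "atp": (None if self.atp is None
                    else {"k_CO_max": self.atp.k_CO_max, "K_m": self.atp.K_m}),
            "constructs": [
                {"label": c.label, "delta": c.delta,
                 "rates": c.rates.to_dict(), "traces": dict(c.traces)}
                for c in self.constructs
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SeriesManifest":
        path = Path(path)
        try:
            with open(path) as fh:
                doc = yaml.safe_load(fh)
        except OSError as exc:
            raise DataError(f"cannot read manifest {path}: {exc}") from exc
        constructs = [
            ConstructEntry(label=c["label"], delta=float(c.get("delta", 0.0)),
                           rates=RateSet.from_dict(c["rates"]),
                           traces=dict(c.get("traces", {})))
            for c in doc.get("constructs", [])
        ]
        atp = doc.get("atp")
        return cls(
            constructs=constructs,
            meta=TraceMeta.from_dict(doc.get("meta", {})),
            phi_true=doc.get("phi_true"),
            seed=doc.get("seed"),
            atp=None if atp is None else AtpDependence(**atp),
            root=path.parent,
        )


def generate_series(
    base: RateSet,
    design: PhiDesign,
    meta: TraceMeta,
    duration: float,
    outdir: str | Path,
    seed: int = 0,
    atp: AtpDependence | None = None,
    include_atp_pair: bool = False,
    include_counting: bool = False,
    counting_channels: int = 3,
    counting_stimulation: float = 50.0,
    counting_duration: float = 60.0,
    fmt: str = "bin",
) -> SeriesManifest:
    """Simulate and write a whole mutant series; return its manifest.

    For each construct a ``main`` single-channel segment is written
    (saturating-ATP rates as designed).  Optionally a paired low-ATP segment
    (``atp_3mM``, rates scaled by the hyperbola) and a ``counting`` segment
    (opening rate multiplied by a stimulation factor, several channels) are
    added.  All ground truth goes into ``manifest.yaml`` beside the traces.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".txt" if fmt == "txt" else ".dat"
    series = design_phi_series(base, design)
    deltas = [0.0] + list(design.deltas)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(series))
    constructs: list[ConstructEntry] = []
    for (label, rates), delta, child in zip(series, deltas, children):
        sub = child.spawn(6)
        entry = ConstructEntry(label=label, rates=rates, delta=delta)
        segments: list[tuple[str, RateSet, float, TraceMeta]] = []
        meta_main = replace(meta, segment_label="main", n_channels=1)
        segments.append(("main", rates, duration, meta_main))
        if include_atp_pair:
            if atp is None:
                raise ConfigError("include_atp_pair requires an AtpDependence")
            atp_c = AtpDependence(k_CO_max=rates.k_CO, K_m=atp.K_m)
            r3 = scale_by_atp(atp_c, 3.0, rates)
            r10 = scale_by_atp(atp_c, 10.0, rates)
            atp_dur = min(duration, 120.0)
            segments.append(("atp_3mM", r3, atp_dur,
                             replace(meta, segment_label="atp_3mM", n_channels=1)))
            segments.append(("atp_10mM", r10, atp_dur,
                             replace(meta, segment_label="atp_10mM", n_channels=1)))
        if include_counting:
            r_stim = replace(rates, k_CO=rates.k_CO * counting_stimulation)
            segments.append(("counting", r_stim, counting_duration,
                             replace(meta, segment_label="counting",
                                     n_channels=counting_channels)))
        for (seg_label, seg_rates, seg_dur, seg_meta), seg_seed in \
                zip(segments, sub):
            rng = np.random.default_rng(seg_seed)
            trajs = [simulate_trajectory(seg_rates, seg_dur, rng)
                     for _ in range(seg_meta.n_channels)]
            trace = render_trace(trajs, seg_meta, seed=rng)
            fname = f"{label}_{seg_label}{ext}"
            try:
                write_trace(trace, outdir / fname)
            except OSError as exc:
                raise DataError(
                    f"failed writing trace {outdir / fname}: {exc}") from exc
            entry.traces[seg_label] = fname
        constructs.append(entry)
    manifest = SeriesManifest(constructs=constructs, meta=meta,
                              phi_true=design.phi_true, seed=seed, atp=atp,
                              root=outdir)
    manifest.to_yaml(outdir / "manifest.yaml")
    return manifest
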