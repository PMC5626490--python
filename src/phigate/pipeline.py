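"""End-to-end orchestration: simulate -> idealize -> burst -> refer.

The pipeline can run stage-wise over on-disk artifacts (traces, event
lists, summary tables; all text with ``#`` metadata headers) or in one
shot.  All randomness flows from a single master seed, so a rerun with the
same configuration reproduces identical outputs.

``analyze_trace`` / ``analyze_construct`` / ``analyze_series`` are the
library entry points the stages (and tests) share.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bursts import (BurstRecord, DwellSample, MutantGating, critical_time,
                     fit_exp_mixture, log_binned_histogram, reconstruct_bursts,
                     saturation_ratio, summarize_gating)
from .errors import ConfigError, DataError
from .idealize import (EventList, auto_dead_time, estimate_levels,
                       gaussian_lowpass, idealize, segment_single_channel)
from .kinetics import AtpDependence, PhiDesign, RateSet
from .refer import PhiEstimate, bronsted_points, fit_phi, make_report
from .simulate import SeriesManifest, generate_series
from .traces import Trace, TraceMeta, read_trace

STAGES = ("simulate", "idealize", "burst", "refer")


@dataclass
class AnalysisOptions:
    """Analysis-stage knobs (acquisition + burst + regression)."""

    fc: float = 50.0                    # target filter cutoff (Hz)
    dead_time: float | None = None      # seconds; None = noise-aware default
    t_crit: float | None = None         # global override (s); None = per construct
    n_components: int = 2               # closed dwell mixture size
    min_segment_duration: float = 0.0   # s, for single-channel segmentation
    saturation_threshold: float = 0.9
    weighted: bool = False              # weighted Bronsted regression
    amplitude_sign: int = -1
    counting_fc: float = 10.0           # heavier filter for channel counting


@dataclass
class ConstructResult:
    """Everything the burst stage produces for one construct."""

    gating: MutantGating
    record: BurstRecord
    events: list[EventList]
    dead_time: float
    closed_mix = None


def analyze_trace(trace: Trace, opts: AnalysisOptions,
                  return_levels: bool = False):
    """Filter (if needed), estimate levels, idealize, segment.

    The filter is applied only when the trace is not already filtered at
    the target cutoff (rendered traces record their filter in metadata).
    """
    if trace.meta.fc is None and opts.fc is not None:
        trace = gaussian_lowpass(trace, opts.fc)
    levels = estimate_levels(trace, amplitude_sign=opts.amplitude_sign)
    dead = opts.dead_time
    if dead is None:
        dead = auto_dead_time(levels, trace.fs, trace.meta.fc)
    dead = max(dead, 1.0 / trace.fs)
    events = idealize(trace, levels, dead_time=dead)
    segments = segment_single_channel(events, opts.min_segment_duration)
    return (segments, levels) if return_levels else segments


def analyze_counting(trace: Trace, levels, opts: AnalysisOptions,
                     k_co: float | None = None):
    """Count active channels on a high-P_o counting segment.

    Only the maximum simultaneous level matters, so the segment is filtered
    much more heavily (``opts.counting_fc``) before thresholding: at the
    analysis bandwidth the top-level thresholds sit only ~2 noise SD above
    the (slightly attenuated) top plateau and sustained noise excursions
    fake an extra level.  Levels come from a calibration estimate on the
    low-P_o main segment of the same patch, where the closed level is
    actually visited.
    """
    from .bursts import count_channels
    from .idealize import DEAD_TIME_FACTOR
    fc = opts.counting_fc
    slow = gaussian_lowpass(trace, fc)
    dead = max(DEAD_TIME_FACTOR / fc,
               auto_dead_time(levels, trace.fs, fc))
    ev = idealize(slow, levels, dead_time=dead)
    return count_channels(ev, k_co=k_co)


def analyze_construct(segments: list[EventList], label: str,
                      opts: AnalysisOptions) -> ConstructResult:
    """Closed-dwell mixture, critical time, burst reconstruction, summary."""
    if not segments:
        raise DataError(f"construct {label!r}: no single-channel segments")
    dead = max(s.dead_time for s in segments)
    t_crit = opts.t_crit
    mix = None
    if t_crit is None:
        closed = np.concatenate([s.dwell_durations(open_state=False)
                                 for s in segments])
        mix = fit_exp_mixture(
            DwellSample(kind="closed", durations=closed, t_min=dead),
            k=opts.n_components)
        t_crit = critical_time(mix)
    records = [reconstruct_bursts(s, t_crit) for s in segments]
    record = BurstRecord.merge(records)
    gating = summarize_gating(record, label)
    res = ConstructResult(gating=gating, record=record, events=segments,
                          dead_time=dead)
    res.closed_mix = mix
    return res


def simulate_and_analyze_series(base: RateSet, design: PhiDesign,
                                meta: TraceMeta, duration: float, seed: int,
                                opts: AnalysisOptions | None = None
                                ) -> tuple[list[MutantGating], PhiEstimate]:
    """One-shot in-memory parameter-recovery run.

    Simulates one single-channel segment of ``duration`` seconds per
    construct of the designed series, renders it with ``meta``, runs the
    idealize/burst stages and fits the Bronsted slope.  All randomness
    derives from ``seed``.
    """
    from .kinetics import design_phi_series
    from .simulate import render_trace, simulate_trajectory
    if opts is None:
        opts = AnalysisOptions()
    series = design_phi_series(base, design)
    ss = np.random.SeedSequence(seed)
    summaries: list[MutantGating] = []
    for (label, rates), child in zip(series, ss.spawn(len(series))):
        rng = np.random.default_rng(child)
        traj = simulate_trajectory(rates, duration, rng)
        trace = render_trace(traj, meta, seed=rng)
        segments = analyze_trace(trace, opts)
        summaries.append(analyze_construct(segments, label, opts).gating)
    phi = fit_phi(bronsted_points(summaries), weighted=opts.weighted)
    return summaries, phi


def analyze_series(manifest: SeriesManifest, opts: AnalysisOptions,
                   traces: dict[str, Trace] | None = None
                   ) -> tuple[list[MutantGating], PhiEstimate]:
    """Run idealize+burst+refer over a series; traces may be preloaded."""
    summaries = []
    for entry in manifest.constructs:
        if traces is not None:
            trace = traces[entry.label]
        else:
            trace = read_trace(manifest.trace_path(entry.label, "main"))
        segments = analyze_trace(trace, opts)
        summaries.append(analyze_construct(segments, entry.label, opts).gating)
    phi = fit_phi(bronsted_points(summaries), weighted=opts.weighted)
    return summaries, phi


# ---------------------------------------------------------------------------
# configuration

_DEFAULT_DELTAS = (-2.0, -1.0, 0.5, 1.0, 2.0)


@dataclass
class PipelineConfig:
    """Validated configuration for a pipeline run."""

    output_dir: Path = Path("phigate_out")
    # acquisition / analysis
    fs: float = 1000.0
    fc: float = 50.0
    dead_time: float | None = None
    t_crit: float | None = None
    n_components: int = 2
    saturation_threshold: float = 0.9
    weighted: bool = False
    min_segment_duration: float = 0.0
    # simulation
    rates: RateSet = field(default_factory=lambda: RateSet(1.0, 2.0, 10.0, 100.0))
    design: PhiDesign = field(default_factory=lambda: PhiDesign(0.5, _DEFAULT_DELTAS))
    meta: TraceMeta = field(default_factory=TraceMeta)
    duration: float = 300.0
    seed: int = 1
    atp: AtpDependence | None = None
    include_atp_pair: bool = False
    include_counting: bool = False
    trace_format: str = "bin"

    def validate(self) -> None:
        problems = []
        if not self.fs > 0:
            problems.append(f"fs must be > 0 (got {self.fs})")
        if not (0 < self.fc < self.fs / 2):
            problems.append(
                f"fc must satisfy 0 < fc < fs/2 (got fc={self.fc}, fs={self.fs})")
        if self.dead_time is not None and self.dead_time < 1.0 / self.fs:
            problems.append(
                f"dead_time must be >= 1/fs = {1.0 / self.fs} s "
                f"(got {self.dead_time})")
        if self.t_crit is not None and self.t_crit <= 0:
            problems.append(f"t_crit must be > 0 (got {self.t_crit})")
        if self.n_components < 1:
            problems.append("n_components must be >= 1")
        if not (0 < self.saturation_threshold <= 1):
            problems.append("saturation_threshold must be in (0, 1]")
        if self.duration <= 0:
            problems.append(f"duration must be > 0 (got {self.duration})")
        if self.trace_format not in ("bin", "txt"):
            problems.append("trace_format must be 'bin' or 'txt'")
        if problems:
            raise ConfigError("invalid configuration:\n  - "
                              + "\n  - ".join(problems))

    @property
    def analysis_options(self) -> AnalysisOptions:
        return AnalysisOptions(
            fc=self.fc, dead_time=self.dead_time, t_crit=self.t_crit,
            n_components=self.n_components,
            min_segment_duration=self.min_segment_duration,
            saturation_threshold=self.saturation_threshold,
            weighted=self.weighted,
            amplitude_sign=int(np.sign(self.meta.unitary_amplitude) or -1),
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        path = Path(path)
        try:
            with open(path) as fh:
                doc = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(doc, **overrides)

    @classmethod
    def from_dict(cls, doc: dict, **overrides) -> "PipelineConfig":
        acq = doc.get("acquisition", {})
        ana = doc.get("analysis", {})
        sim = doc.get("simulation", {})
        kwargs: dict = {}
        if "output_dir" in doc:
            kwargs["output_dir"] = Path(doc["output_dir"])
        for key, src in (("fs", acq), ("fc", acq), ("dead_time", acq),
                         ("t_crit", ana), ("n_components", ana),
                         ("saturation_threshold", ana), ("weighted", ana),
                         ("min_segment_duration", ana)):
            if key in src:
                kwargs[key] = src[key]
        if "rates" in sim:
            kwargs["rates"] = RateSet.from_dict(sim["rates"])
        if "design" in sim:
            kwargs["design"] = PhiDesign(
                phi_true=float(sim["design"].get("phi_true", 0.5)),
                deltas=tuple(sim["design"].get("deltas", _DEFAULT_DELTAS)))
        if "meta" in sim:
            try:
                kwargs["meta"] = TraceMeta.from_dict(sim["meta"])
            except ConfigError as exc:
                raise ConfigError(f"invalid simulation.meta: {exc}") from exc
        for key in ("duration", "seed", "include_atp_pair",
                    "include_counting", "trace_format"):
            if key in sim:
                kwargs[key] = sim[key]
        if "atp" in sim and sim["atp"] is not None:
            kwargs["atp"] = AtpDependence(**sim["atp"])
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**kwargs)
        cfg.validate()
        # keep trace metadata consistent with acquisition settings
        cfg.meta = replace(cfg.meta, fs=cfg.fs, fc=cfg.fc, seed=cfg.seed)
        return cfg

    def digest(self) -> str:
        """Hash of the scientific settings (paths excluded)."""
        fields = {k: v for k, v in self.__dict__.items()
                  if k != "output_dir"}
        return hashlib.sha256(repr(sorted(
            (k, repr(v)) for k, v in fields.items())).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage runner

def _log(outdir: Path, lines: list[str]) -> None:
    with open(outdir / "run.log", "a") as fh:
        for line in lines:
            fh.write(line + "\n")


def run(config: PipelineConfig, stages=("simulate", "idealize", "burst",
                                        "refer")) -> dict:
    """Run the requested stages; each reads its predecessor's artifacts.

    Layout under ``config.output_dir``:
    ``traces/`` (+ manifest.yaml), ``events/``, ``burst/summary.tsv`` and
    histogram tables, ``refer/`` report files, ``run.log``.
    Returns a dict of headline results for the stages that ran.
    """
    config.validate()
    for st in stages:
        if st not in STAGES:
            raise ConfigError(f"unknown stage {st!r}; choose from {STAGES}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _log(outdir, [f"config_hash={config.digest()} seed={config.seed} "
                  f"stages={','.join(stages)}"])
    results: dict = {}
    opts = config.analysis_options

    if "simulate" in stages:
        manifest = generate_series(
            config.rates, config.design, config.meta, config.duration,
            outdir / "traces", seed=config.seed, atp=config.atp,
            include_atp_pair=config.include_atp_pair,
            include_counting=config.include_counting,
            fmt=config.trace_format)
        _log(outdir, [f"simulate construct={c.label} "
                      f"segments={sorted(c.traces)}"
                      for c in manifest.constructs])
        results["manifest"] = manifest

    manifest_path = outdir / "traces" / "manifest.yaml"
    if any(st in stages for st in ("idealize", "burst", "refer")):
        if not manifest_path.exists():
            raise DataError(
                f"stage 'idealize' needs {manifest_path}; run 'simulate' "
                "first or point output_dir at existing traces")
        manifest = SeriesManifest.from_yaml(manifest_path)

    events_dir = outdir / "events"
    if "idealize" in stages:
        events_dir.mkdir(exist_ok=True)
        for entry in manifest.constructs:
            trace = read_trace(manifest.trace_path(entry.label, "main"))
            segments, levels = analyze_trace(trace, opts, return_levels=True)
            for j, seg in enumerate(segments):
                seg.write_tsv(events_dir / f"{entry.label}_main_{j}.tsv")
            with open(events_dir / f"{entry.label}_levels.txt", "w") as fh:
                fh.write(f"baseline = {levels.baseline!r}\n")
                fh.write(f"unitary_amplitude = {levels.unitary_amplitude!r}\n")
                fh.write(f"sd = {levels.sd!r}\n")
            _log(outdir, [f"idealize construct={entry.label} "
                          f"segments={len(segments)} "
                          f"dead_time={segments[0].dead_time if segments else 'na'}"])

    burst_dir = outdir / "burst"
    if "burst" in stages:
        if not events_dir.exists():
            raise DataError(f"stage 'burst' needs event lists in {events_dir}")
        burst_dir.mkdir(exist_ok=True)
        rows = []
        for entry in manifest.constructs:
            files = sorted(events_dir.glob(f"{entry.label}_main_*.tsv"))
            if not files:
                raise DataError(f"stage 'burst': no event files for "
                                f"construct {entry.label!r} in {events_dir}")
            segments = [EventList.read_tsv(f) for f in files]
            res = analyze_construct(segments, entry.label, opts)
            g = res.gating
            rows.append({
                "construct": g.label, "n_bursts": g.n_bursts,
                "n_interbursts": g.n_interbursts, "tau_b": g.tau_b,
                "sem_b": g.sem_b, "tau_ib": g.tau_ib, "sem_ib": g.sem_ib,
                "k_CO": g.k_CO, "k_OC": g.k_OC, "K_eq": g.K_eq,
                "P_o": g.P_o, "P_o_burst": g.P_o_burst, "t_crit": g.t_crit,
            })
            closed = np.concatenate([s.dwell_durations(open_state=False)
                                     for s in segments])
            hist = log_binned_histogram(closed, res.closed_mix)
            hist.to_csv(burst_dir / f"{entry.label}_closed_hist.tsv",
                        sep="\t", index=False, float_format="%.9g")
            _log(outdir, [f"burst construct={entry.label} "
                          f"t_crit={g.t_crit:.9g} n_bursts={g.n_bursts}"])
            # channel counting when a stimulated segment exists
            if "counting" in entry.traces:
                lev_file = events_dir / f"{entry.label}_levels.txt"
                pairs = {}
                with open(lev_file) as fh:
                    for line in fh:
                        key, _, val = line.partition("=")
                        pairs[key.strip()] = float(val)
                from .idealize import LevelEstimate
                levels = LevelEstimate(
                    baseline=pairs["baseline"],
                    unitary_amplitude=pairs["unitary_amplitude"],
                    sd=pairs["sd"], n_levels_detected=2)
                tc = read_trace(manifest.trace_path(entry.label, "counting"))
                cc = analyze_counting(tc, levels, opts, k_co=g.k_CO)
                rows[-1]["n_channels"] = cc.n
                _log(outdir, [f"count construct={entry.label} n={cc.n} "
                              f"p_under={cc.p_underestimate:.3g}"])
            # ATP saturation check when the paired segments exist
            if "atp_3mM" in entry.traces and "atp_10mM" in entry.traces:
                t3 = read_trace(manifest.trace_path(entry.label, "atp_3mM"))
                t10 = read_trace(manifest.trace_path(entry.label, "atp_10mM"))
                ratio, ok = saturation_ratio(
                    t3, t10, threshold=opts.saturation_threshold)
                rows[-1]["atp_ratio"] = ratio
                rows[-1]["is_saturating"] = int(ok)
                if not ok:
                    warnings.warn(
                        f"construct {entry.label!r}: 10 mM ATP not "
                        f"saturating (3/10 mM ratio {ratio:.3f})",
                        stacklevel=2)
        df = pd.DataFrame(rows)
        with open(burst_dir / "summary.tsv", "w") as fh:
            fh.write(f"# phigate gating summary (config {config.digest()})\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.9g")
        results["summary"] = df

    if "refer" in stages:
        summary_path = burst_dir / "summary.tsv"
        if not summary_path.exists():
            raise DataError(f"stage 'refer' needs {summary_path}")
        df = pd.read_csv(summary_path, sep="\t", comment="#")
        summaries = [
            MutantGating(
                label=row["construct"], tau_b=row["tau_b"],
                sem_b=row["sem_b"], tau_ib=row["tau_ib"],
                sem_ib=row["sem_ib"], k_CO=row["k_CO"], k_OC=row["k_OC"],
                K_eq=row["K_eq"], P_o=row["P_o"], P_o_burst=row["P_o_burst"],
                n_bursts=int(row["n_bursts"]),
                n_interbursts=int(row["n_interbursts"]),
                t_crit=row["t_crit"])
            for _, row in df.iterrows()
        ]
        points = bronsted_points(summaries)
        phi = fit_phi(points, weighted=opts.weighted)
        make_report(summaries, phi, outdir / "refer", points=points,
                    phi_true=manifest.phi_true)
        _log(outdir, [f"refer phi={phi.phi:.9g} se={phi.se_phi:.9g} "
                      f"n={phi.n}"])
        results["phi"] = phi
    return results
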