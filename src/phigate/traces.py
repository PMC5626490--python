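"""Sampled current traces and their on-disk dialects.

A :class:`Trace` is a uniformly sampled current record in pA together with
acquisition metadata (:class:`TraceMeta`).  Two plain-text-friendly dialects
are supported:

* text: two columns ``time_s``/``current_pA`` with ``#``-prefixed header
  lines carrying the metadata;
* binary: raw little-endian float32 samples plus a key-value sidecar file
  (``<name>.meta``) carrying the same metadata.

The binary dialect round-trips bit-exactly (samples are stored as float32);
the text dialect round-trips to the printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError

SEGMENT_LABELS = ("main", "counting", "atp_3mM", "atp_10mM")


@dataclass
class TraceMeta:
    """Acquisition metadata for a current trace.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    fc : float or None
        -3 dB cutoff of the Gaussian low-pass filter already applied to the
        samples; ``None`` for an unfiltered record.
    baseline : float
        Closed-channel (zero-current) level in pA.
    unitary_amplitude : float
        Single-channel current step in pA; negative for inward current at
        negative holding potential.
    noise_sd : float
        Target post-filter baseline noise SD in pA.
    n_channels : int
        Number of active channels in the patch.
    seed : int or None
        Seed used to generate the trace, if synthetic.
    segment_label : str
        One of ``main``, ``counting``, ``atp_3mM``, ``atp_10mM``.
    """

    fs: float = 1000.0
    fc: float | None = 50.0
    baseline: float = 0.0
    unitary_amplitude: float = -0.8
    noise_sd: float = 0.15
    n_channels: int = 1
    seed: int | None = None
    segment_label: str = "main"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        if self.fc is not None and not (0 < self.fc < self.fs / 2):
            raise ConfigError(
                f"filter cutoff must satisfy 0 < fc < fs/2 (cutoff above "
                f"Nyquist?): fc={self.fc}, fs={self.fs}"
            )
        if self.n_channels < 1:
            raise ConfigError("n_channels must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.segment_label not in SEGMENT_LABELS:
            raise ConfigError(
                f"segment_label must be one of {SEGMENT_LABELS}, "
                f"got {self.segment_label!r}"
            )

    def to_dict(self) -> dict:
        return {
            "fs": self.fs,
            "fc": self.fc,
            "baseline": self.baseline,
            "unitary_amplitude": self.unitary_amplitude,
            "noise_sd": self.noise_sd,
            "n_channels": self.n_channels,
            "seed": self.seed,
            "segment_label": self.segment_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TraceMeta":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)


@dataclass
class Trace:
    """A sampled current record (pA)."""

    samples: np.ndarray
    fs: float
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise DataError("trace samples must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise DataError("trace contains non-finite samples")
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps (bin centers) in seconds."""
        return (np.arange(self.n) + 0.5) / self.fs

    def with_samples(self, samples: np.ndarray, fc: float | None = None) -> "Trace":
        meta = self.meta if fc is None else replace(self.meta, fc=fc)
        return Trace(samples=samples, fs=self.fs, meta=meta)


def _meta_lines(meta: TraceMeta) -> list[str]:
    lines = []
    for key, val in meta.to_dict().items():
        lines.append(f"{key} = {'none' if val is None else val}")
    return lines


def _parse_meta(pairs: dict[str, str]) -> TraceMeta:
    out: dict = {}
    casts = {
        "fs": float, "fc": float, "baseline": float,
        "unitary_amplitude": float, "noise_sd": float,
        "n_channels": int, "seed": int, "segment_label": str,
    }
    for key, cast in casts.items():
        if key in pairs:
            raw = pairs[key].strip()
            out[key] = None if raw.lower() in ("none", "") else cast(raw)
    return TraceMeta.from_dict(out)


def write_trace_text(trace: Trace, path: str | Path) -> Path:
    """Write a trace as two-column text (time_s, current_pA) with # header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# phigate trace v1 (text)\n")
        for line in _meta_lines(trace.meta):
            fh.write(f"# {line}\n")
        fh.write("# time_s\tcurrent_pA\n")
        times = trace.times
        for t, x in zip(times, trace.samples):
            fh.write(f"{t:.9g}\t{x:.9g}\n")
    return path


def read_trace_text(path: str | Path) -> Trace:
    path = Path(path)
    pairs: dict[str, str] = {}
    samples = []
    try:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line[1:].strip()
                    if "=" in body:
                        key, _, val = body.partition("=")
                        pairs[key.strip()] = val.strip()
                    continue
                cols = line.split()
                samples.append(float(cols[1]))
    except OSError as exc:
        raise DataError(f"cannot read trace file {path}: {exc}") from exc
    if not samples:
        raise DataError(f"trace file {path} contains no samples")
    meta = _parse_meta(pairs)
    return Trace(samples=np.array(samples), fs=meta.fs, meta=meta)


def write_trace_binary(trace: Trace, path: str | Path) -> Path:
    """Write raw little-endian float32 samples plus a key-value sidecar."""
    path = Path(path)
    np.asarray(trace.samples, dtype="<f4").tofile(path)
    sidecar = path.with_suffix(path.suffix + ".meta")
    with open(sidecar, "w") as fh:
        fh.write("format = phigate-trace-f32le\n")
        fh.write(f"n_samples = {trace.n}\n")
        for line in _meta_lines(trace.meta):
            fh.write(line + "\n")
    return path


def read_trace_binary(path: str | Path) -> Trace:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta")
    if not sidecar.exists():
        raise DataError(f"missing sidecar metadata file {sidecar}")
    pairs: dict[str, str] = {}
    with open(sidecar) as fh:
        for line in fh:
            if "=" in line:
                key, _, val = line.partition("=")
                pairs[key.strip()] = val.strip()
    try:
        samples = np.fromfile(path, dtype="<f4")
    except OSError as exc:
        raise DataError(f"cannot read trace file {path}: {exc}") from exc
    if "n_samples" in pairs and int(pairs["n_samples"]) != samples.size:
        raise DataError(
            f"trace file {path}: expected {pairs['n_samples']} samples, "
            f"found {samples.size}"
        )
    meta = _parse_meta(pairs)
    return Trace(samples=samples, fs=meta.fs, meta=meta)


def read_trace(path: str | Path) -> Trace:
    """Dispatch on dialect: ``.txt``/``.tsv`` text, anything else binary."""
    path = Path(path)
    if path.suffix in (".txt", ".tsv"):
        return read_trace_text(path)
    return read_trace_binary(path)


def write_trace(trace: Trace, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix in (".txt", ".tsv"):
        return write_trace_text(trace, path)
    return write_trace_binary(trace, path)
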