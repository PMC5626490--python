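"""Gating scheme, rate algebra and closed-form expectations.

The channel is modelled as a three-state continuous-time Markov chain

    C  <--k_CO/k_OC-->  O  <--k_OF/k_FO-->  C_f

where ``C`` is the long-lived interburst closed state, ``O`` the open
(conducting) state and ``C_f`` a brief "flickery" closed state visited only
from within a burst.  A burst is a sojourn in ``{O, C_f}`` between two
visits to ``C``; the interburst is a single sojourn in ``C``.  In the
non-hydrolytic (equilibrium) gating regime the opening rate is
``k_CO = 1/tau_ib`` and the closing rate ``k_OC = 1/tau_b``, with
``K_eq = k_CO / k_OC``.

``design_phi_series`` builds a perturbation series with a prescribed
ground-truth Phi: each construct shifts ``ln K_eq`` by a designed delta,
splitting the shift between opening and closing rates as
``ln k_CO`` += phi*delta and ``ln k_OC`` -= (1-phi)*delta.  The slope of
the Bronsted plot (ln k_CO vs ln K_eq) over such a series is exactly phi.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError, DataError


@dataclass(frozen=True)
class RateSet:
    """Microscopic rate constants (s^-1) of the C<->O<->C_f scheme.

    ``k_CO``: interburst-closed -> open; ``k_OC``: open -> interburst-closed;
    ``k_OF``: open -> flicker-closed; ``k_FO``: flicker-closed -> open.
    """

    k_CO: float
    k_OC: float
    k_OF: float = 0.0
    k_FO: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_CO", "k_OC", "k_OF", "k_FO"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ConfigError(f"rate {name} must be finite and >= 0, got {val}")
        if self.k_OF > 0 and self.k_FO == 0:
            raise ConfigError("absorbing flicker state (k_OF > 0 with k_FO = 0)")

    @property
    def is_gating(self) -> bool:
        return self.k_CO > 0 and self.k_OC > 0

    def to_dict(self) -> dict:
        return {"k_CO": self.k_CO, "k_OC": self.k_OC,
                "k_OF": self.k_OF, "k_FO": self.k_FO}

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class AtpDependence:
    """Single-site hyperbolic ATP dependence of the opening rate.

    ``k_CO(c) = k_CO_max * c / (c + K_m)`` with ``K_m`` in mM.
    """

    k_CO_max: float
    K_m: float

    def __post_init__(self) -> None:
        if self.k_CO_max <= 0:
            raise ConfigError("k_CO_max must be > 0")
        if self.K_m <= 0:
            raise ConfigError("K_m must be > 0")


@dataclass(frozen=True)
class GatingSummary:
    """Closed-form burst-level expectations for a rate set."""

    tau_b: float      # mean burst duration (s)
    tau_ib: float     # mean interburst duration (s)
    P_o: float        # stationary open probability (fraction of time in O)
    P_o_burst: float  # tau_b / (tau_b + tau_ib)
    K_eq: float       # k_CO / k_OC


@dataclass(frozen=True)
class PhiDesign:
    """A designed perturbation series: ground-truth phi and ln-K_eq shifts."""

    phi_true: float
    deltas: tuple

    def __post_init__(self) -> None:
        deltas = tuple(float(d) for d in self.deltas)
        object.__setattr__(self, "deltas", deltas)
        if any(not math.isfinite(d) for d in deltas):
            raise ConfigError("deltas must be finite")
        if len(set(deltas)) < 3:
            raise ConfigError("need at least 3 distinct deltas for a regression")
        if not math.isfinite(self.phi_true):
            raise ConfigError("phi_true must be finite")
        if not 0.0 <= self.phi_true <= 1.0:
            warnings.warn(
                f"phi_true={self.phi_true} outside [0, 1]; allowed for testing "
                "but not physical for a two-state opening step",
                stacklevel=2,
            )


def expected_burst_metrics(rates: RateSet) -> GatingSummary:
    """Closed-form burst/interburst expectations for the 3-state scheme.

    tau_ib = 1/k_CO (single exponential sojourn in C).  A burst visits O
    on average ``1 + k_OF/k_OC`` ... more precisely each O sojourn (mean
    ``1/(k_OC+k_OF)``) ends in C with probability ``k_OC/(k_OC+k_OF)``, so
    the burst contains a geometric number of O sojourns and equally many
    minus one flicker sojourns (mean ``1/k_FO``), giving

        tau_b = 1/k_OC + k_OF/(k_OC*k_FO).

    P_o is the stationary occupancy of O:
    ``1 / (1 + k_OC/k_CO + k_OF/k_FO)``.
    """
    if not rates.is_gating:
        raise DataError("non-gating rate set (k_CO and k_OC must both be > 0)")
    tau_ib = 1.0 / rates.k_CO
    flicker_load = rates.k_OF / rates.k_FO if rates.k_OF > 0 else 0.0
    tau_b = (1.0 + flicker_load) / rates.k_OC
    P_o = 1.0 / (1.0 + rates.k_OC / rates.k_CO + flicker_load)
    return GatingSummary(
        tau_b=tau_b,
        tau_ib=tau_ib,
        P_o=P_o,
        P_o_burst=tau_b / (tau_b + tau_ib),
        K_eq=rates.k_CO / rates.k_OC,
    )


def scale_by_atp(atp: AtpDependence, conc: float, base: RateSet) -> RateSet:
    """Return ``base`` with k_CO replaced by the hyperbolic value at ``conc`` mM."""
    if conc < 0:
        raise ConfigError(f"ATP concentration must be >= 0, got {conc}")
    k_co = atp.k_CO_max * conc / (conc + atp.K_m)
    return replace(base, k_CO=k_co)


def design_phi_series(
    base: RateSet,
    design: PhiDesign,
    labels: Sequence[str] | None = None,
) -> list[tuple[str, RateSet]]:
    """Build (label, RateSet) pairs for a series with ground-truth phi.

    The base (background) construct comes first with delta = 0.  For each
    delta the opening and closing rates are shifted on the log scale so that
    ``ln K_eq`` shifts by exactly delta while the Bronsted slope is
    ``phi_true``.  Flicker rates are copied unchanged.
    """
    if not base.is_gating:
        raise DataError("non-gating base rate set")
    series = [("bg", base)]
    for i, delta in enumerate(design.deltas):
        k_co = base.k_CO * math.exp(design.phi_true * delta)
        k_oc = base.k_OC * math.exp(-(1.0 - design.phi_true) * delta)
        label = labels[i] if labels is not None else f"m{i + 1}"
        series.append((label, replace(base, k_CO=k_co, k_OC=k_oc)))
    if labels is not None and len(labels) != len(design.deltas):
        raise ConfigError("labels must match the number of deltas")
    seen = [lab for lab, _ in series]
    if len(set(seen)) != len(seen):
        raise ConfigError(f"duplicate construct labels in {seen}")
    return series
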