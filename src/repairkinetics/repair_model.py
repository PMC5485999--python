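"""Delayed two-pathway kinetics of radiation-induced DNA damage.

The model tracks five damage compartments, all expressed in %DNA-in-tail
units of the alkaline comet assay:

* ``n0`` — primary breaks (SSB and DSB), induced in proportion to the
  dose rate R while the beam is on,
* ``n1_fast`` / ``n1_slow`` — breaks detected by the fast or slow repair
  pathway (first-order detection, rates ``k0``),
* ``n2_fast`` / ``n2_slow`` — processed breaks awaiting final rejoining.

Detection is first order; processing is first order but *delayed* by a
pathway-specific lag ``tr`` (the delay stands in for the chain of
intermediate repair steps); final rejoining of two free fragment ends is
second order (rate ``k2``).  Every compartment is electrophoretically
mobile, so the observable comet signal is the compartment sum plus a
baseline ``bn`` that is co-estimated during fitting.

Working units: rates ``k0``/``k1`` in min^-1, ``k2`` in (%DNA min)^-1
(second-order), ``kcleav`` in %DNA/Gy, delays in min, dose in Gy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "PathwayRates",
    "ModelParameters",
    "IrradiationProtocol",
    "DamageState",
    "dose_rate_at",
    "induction_rate",
    "state_derivative",
    "observable_signal",
]


@dataclass(frozen=True)
class PathwayRates:
    """Kinetic constants of one repair pathway.

    Parameters
    ----------
    k0 : float
        Detection rate (min^-1): first-order transfer n0 -> n1.
    k1 : float
        Processing rate (min^-1): delayed first-order transfer n1 -> n2.
    k2 : float
        Final-repair rate ((%DNA min)^-1): second-order loss of n2.
    tr : float
        Processing delay (min) applied to the n1 -> n2 transfer.
    """

    k0: float
    k1: float
    k2: float
    tr: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k0", "k1", "k2", "tr"):
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ValueError(f"{name} must be >= 0, got {v!r}")
        if not (self.tr < float("inf")):
            raise ValueError("tr must be finite")

    @property
    def is_off(self) -> bool:
        """True when all reaction rates are forced to zero."""
        return self.k0 == 0.0 and self.k1 == 0.0 and self.k2 == 0.0


#: flat serialization key order (the conventional parameter-table names)
PARAM_KEYS = (
    "kcleav",
    "k0_fast",
    "k1_fast",
    "k2_fast",
    "tr_fast",
    "k0_slow",
    "k1_slow",
    "k2_slow",
    "tr_slow",
    "bn",
)


@dataclass(frozen=True)
class ModelParameters:
    """Full kinetic parameter set of the two-pathway model."""

    kcleav: float
    fast: PathwayRates
    slow: PathwayRates = field(default_factory=lambda: PathwayRates(0.0, 0.0, 0.0, 0.0))
    bn: float = 0.0
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not (self.kcleav >= 0.0):
            raise ValueError("kcleav must be >= 0")
        if not (self.bn >= 0.0):
            raise ValueError("bn must be >= 0")
        if not (self.epsilon >= 0.0):
            raise ValueError("epsilon must be >= 0")

    @property
    def is_one_pathway(self) -> bool:
        """True when the slow pathway is switched off (all slow rates zero)."""
        return self.slow.is_off

    # -- flat serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "kcleav": self.kcleav,
            "k0_fast": self.fast.k0,
            "k1_fast": self.fast.k1,
            "k2_fast": self.fast.k2,
            "tr_fast": self.fast.tr,
            "k0_slow": self.slow.k0,
            "k1_slow": self.slow.k1,
            "k2_slow": self.slow.k2,
            "tr_slow": self.slow.tr,
            "bn": self.bn,
        }
        if self.epsilon != 0.0:
            d["epsilon"] = self.epsilon
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        missing = [k for k in ("kcleav", "k0_fast", "k1_fast", "k2_fast", "bn") if k not in d]
        if missing:
            raise KeyError(f"missing parameter key(s): {', '.join(missing)}")
        return cls(
            kcleav=float(d["kcleav"]),
            fast=PathwayRates(
                k0=float(d["k0_fast"]),
                k1=float(d["k1_fast"]),
                k2=float(d["k2_fast"]),
                tr=float(d.get("tr_fast", 0.0)),
            ),
            slow=PathwayRates(
                k0=float(d.get("k0_slow", 0.0)),
                k1=float(d.get("k1_slow", 0.0)),
                k2=float(d.get("k2_slow", 0.0)),
                tr=float(d.get("tr_slow", 0.0)),
            ),
            bn=float(d["bn"]),
            epsilon=float(d.get("epsilon", 0.0)),
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ModelParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=False))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def swap_pathways(self) -> "ModelParameters":
        """Exchange the fast and slow parameter blocks (model symmetry)."""
        return replace(self, fast=self.slow, slow=self.fast)


@dataclass(frozen=True)
class IrradiationProtocol:
    """One radiotherapy fraction delivered as a rectangular dose-rate pulse.

    ``t = 0`` is the pulse start; observation times quoted relative to
    treatment completion correspond to model times offset by
    ``pulse_end``.  Default 2 min beam-on time is the order of magnitude
    of a clinical 6 Gy linac delivery.
    """

    dose: float
    pulse_start: float = 0.0
    pulse_duration: float = 2.0

    def __post_init__(self) -> None:
        if not (self.dose >= 0.0):
            raise ValueError("dose must be >= 0")
        if not (self.pulse_duration > 0.0):
            raise ValueError("pulse_duration must be > 0")

    @property
    def dose_rate(self) -> float:
        """Constant dose rate R = dose / pulse_duration (Gy/min)."""
        return self.dose / self.pulse_duration

    @property
    def pulse_end(self) -> float:
        return self.pulse_start + self.pulse_duration

    def cumulative_dose(self, t: float) -> float:
        """Dose delivered up to model time ``t`` (Gy)."""
        if t <= self.pulse_start:
            return 0.0
        return self.dose_rate * (min(t, self.pulse_end) - self.pulse_start)

    def to_dict(self) -> dict:
        return {
            "dose": self.dose,
            "pulse_start": self.pulse_start,
            "pulse_duration": self.pulse_duration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IrradiationProtocol":
        if "dose" not in d:
            raise KeyError("missing parameter key(s): dose")
        return cls(
            dose=float(d["dose"]),
            pulse_start=float(d.get("pulse_start", 0.0)),
            pulse_duration=float(d.get("pulse_duration", 2.0)),
        )


@dataclass(frozen=True)
class DamageState:
    """The five damage compartments, each in %DNA-in-tail units."""

    n0: float = 0.0
    n1_fast: float = 0.0
    n1_slow: float = 0.0
    n2_fast: float = 0.0
    n2_slow: float = 0.0

    def as_tuple(self) -> tuple:
        return (self.n0, self.n1_fast, self.n1_slow, self.n2_fast, self.n2_slow)

    @property
    def total(self) -> float:
        return sum(self.as_tuple())


def dose_rate_at(protocol: IrradiationProtocol, t: float) -> float:
    """Dose rate (Gy/min) at model time ``t`` for a rectangular pulse.

    Returns R = dose/pulse_duration inside ``[pulse_start, pulse_end)``
    and 0 outside.
    """
    if protocol.pulse_start <= t < protocol.pulse_end:
        return protocol.dose_rate
    return 0.0


def induction_rate(params: ModelParameters, R: float, D: float = 0.0,
                   mode: str = "simple") -> float:
    """Primary-break induction rate dn0/dt (%DNA/min).

    ``simple`` mode: kcleav * R (no saturation of target sites).
    ``extended`` mode: kcleav * R * (epsilon + D) — a two-hit fragment
    liberation picture where ``D`` is the cumulative dose and ``epsilon``
    a dose-equivalent of pre-existing breaks.
    """
    if R < 0.0 or D < 0.0:
        raise ValueError("dose rate and cumulative dose must be >= 0")
    if mode == "simple":
        return params.kcleav * R
    if mode == "extended":
        return params.kcleav * R * (params.epsilon + D)
    raise ValueError(f"unknown induction mode: {mode!r}")


def state_derivative(t: float, s: DamageState, delayed_n1_fast: float,
                     delayed_n1_slow: float, params: ModelParameters,
                     protocol: IrradiationProtocol,
                     mode: str = "simple") -> DamageState:
    """Right-hand side of the delayed compartment system.

    ``delayed_n1_fast``/``delayed_n1_slow`` must be the n1 compartment
    values at ``t - tr`` for the respective pathway (0 before simulation
    start).  The delayed term ``k1 * n1(t - tr)`` appears both as the
    outflow of n1 and the inflow of n2, so mass is conserved exactly
    when ``k2 = 0``.
    """
    if min(s.as_tuple()) < 0.0:
        raise ValueError("negative compartment in input state")
    R = dose_rate_at(protocol, t)
    D = protocol.cumulative_dose(t)
    ind = induction_rate(params, R, D, mode=mode)
    f, sl = params.fast, params.slow
    proc_f = f.k1 * delayed_n1_fast
    proc_s = sl.k1 * delayed_n1_slow
    return DamageState(
        n0=ind - (f.k0 + sl.k0) * s.n0,
        n1_fast=f.k0 * s.n0 - proc_f,
        n1_slow=sl.k0 * s.n0 - proc_s,
        n2_fast=proc_f - f.k2 * s.n2_fast * s.n2_fast,
        n2_slow=proc_s - sl.k2 * s.n2_slow * s.n2_slow,
    )


def observable_signal(s: DamageState, bn: float) -> float:
    """Comet-assay observable: total damage plus baseline, in %DNA in tail.

    All compartments migrate in the electrophoresis field, so the
    predicted tail intensity is ``n0 + n1_fast + n1_slow + n2_fast +
    n2_slow + bn``.
    """
    return s.total + bn
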