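"""Simulation configuration for the synthetic dual-instrument gait generator.

The configuration captures the conditions of an overground walking session
recorded simultaneously by a markerless motion-capture (MLMC) volume sampling
at 60 Hz and a pressure-sensitive walkway (PSW) sampling at 100 Hz: gait
timing and geometry, walkway layout, instrument rates, a contact-threshold
latency emulating the pressure threshold a walkway uses to declare foot
contact, sensor noise, and the extra person tracks (safety spotter,
bystanders) that community settings produce.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SimulationConfig", "load_config"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic walking session.

    Parameters
    ----------
    cadence : float
        Step rate in steps/min. Stride time is ``120 / cadence`` seconds.
    speed : float
        Mean walking speed in m/s. Stride length is ``speed * stride_time``.
    stride_width : float
        Lateral separation of the two feet, m.
    stance_fraction : float
        Fraction of the stride spent in stance, in (0.5, 0.8).
    double_support_fraction : float or None
        Fraction of the stride spent in *each* double-support phase. For
        symmetric periodic gait this equals ``stance_fraction - 0.5`` and is
        derived when None; an explicit inconsistent value is rejected.
    asymmetry_step_time, asymmetry_step_length : (float, float)
        Per-side (left, right) multiplicative factors on step time and step
        length. ``(1.0, 1.0)`` is symmetric gait. Factors are normalized so
        stride totals stay at the configured cadence/speed.
    walkway_length : float
        Length of the camera-covered walkway, m.
    capture_margin : float
        Distance at each walkway end where the biomechanical model is not yet
        fully identified; poses there are flagged invalid.
    psw_span : float
        Length of the instrumented (pressure-sensitive) central portion of
        the walkway, m.
    n_passes : int
        Number of walking passes, alternating +Y / -Y direction.
    mlmc_rate, psw_rate : float
        Sampling rates of the two instruments, Hz.
    contact_latency : float
        Delay (s) between true initial contact and the pressure-threshold
        onset reported by the walkway; the contact offset leads true toe off
        by the same amount.
    noise_sd_position : float
        SD (m) of additive i.i.d. Gaussian noise on segment pose translations.
    noise_sd_time_jitter : float
        SD (s) of Gaussian jitter on walkway contact on/off times.
    n_bystanders : int
        Extra person tracks loitering outside the walkway corridor.
    spotter : bool
        Add a safety-spotter track trailing the participant.
    spotter_lag, spotter_lateral : float
        Along-path lag and lateral offset of the spotter, m.
    seed : int
        Seed for the single random generator driving all stochastic draws.
    """

    cadence: float = 109.72
    speed: float = 1.23
    stride_width: float = 0.125
    stance_fraction: float = 0.65
    double_support_fraction: float | None = None
    asymmetry_step_time: tuple[float, float] = (1.0, 1.0)
    asymmetry_step_length: tuple[float, float] = (1.0, 1.0)
    walkway_length: float = 10.0
    capture_margin: float = 1.5
    psw_span: float = 3.6
    n_passes: int = 6
    mlmc_rate: float = 60.0
    psw_rate: float = 100.0
    contact_latency: float = 0.0
    noise_sd_position: float = 0.0
    noise_sd_time_jitter: float = 0.0
    n_bystanders: int = 0
    spotter: bool = False
    spotter_lag: float = 0.8
    spotter_lateral: float = 0.3
    seed: int = 0

    # -- derived quantities -------------------------------------------------

    @property
    def stride_time(self) -> float:
        return 120.0 / self.cadence

    @property
    def stride_length(self) -> float:
        return self.speed * self.stride_time

    @property
    def swing_fraction(self) -> float:
        return 1.0 - self.stance_fraction

    @property
    def ds_fraction(self) -> float:
        """Per-phase double-support fraction of the stride (symmetric gait)."""
        if self.double_support_fraction is not None:
            return self.double_support_fraction
        return self.stance_fraction - 0.5

    @property
    def step_time_weights(self) -> tuple[float, float]:
        a_l, a_r = self.asymmetry_step_time
        return a_l / (a_l + a_r), a_r / (a_l + a_r)

    @property
    def step_length_weights(self) -> tuple[float, float]:
        a_l, a_r = self.asymmetry_step_length
        return a_l / (a_l + a_r), a_r / (a_l + a_r)

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ValueError("cadence must be > 0")
        if self.speed <= 0:
            raise ValueError("speed must be > 0")
        if not 0.5 < self.stance_fraction < 0.8:
            raise ValueError("stance_fraction must lie in (0.5, 0.8)")
        if self.double_support_fraction is not None:
            derived = self.stance_fraction - 0.5
            if not 0.0 < self.double_support_fraction < 0.3:
                raise ValueError("double_support_fraction must lie in (0, 0.3)")
            if abs(self.double_support_fraction - derived) > 1e-9:
                raise ValueError(
                    "double_support_fraction is over-determined for symmetric "
                    f"periodic gait: stance_fraction {self.stance_fraction} "
                    f"implies {derived:.4f} per double-support phase"
                )
        if self.swing_fraction * self.stride_time <= 0:
            raise ValueError("derived swing duration must be > 0")
        if self.stride_length >= self.walkway_length:
            raise ValueError("stride length must be shorter than the walkway")
        if self.psw_span > self.walkway_length:
            raise ValueError("instrumented span cannot exceed the walkway")
        if self.capture_margin < 0 or 2 * self.capture_margin >= self.walkway_length:
            raise ValueError("capture_margin leaves no usable walkway")
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")
        if self.mlmc_rate <= 0 or self.psw_rate <= 0:
            raise ValueError("sampling rates must be > 0")
        for pair, name in (
            (self.asymmetry_step_time, "asymmetry_step_time"),
            (self.asymmetry_step_length, "asymmetry_step_length"),
        ):
            if min(pair) <= 0:
                raise ValueError(f"{name} factors must be > 0")
        # Canonical event ordering requires every step to finish before the
        # ipsilateral stance does.
        w_l, w_r = self.step_time_weights
        if max(w_l, w_r) >= self.stance_fraction:
            raise ValueError(
                "step-time asymmetry too extreme for the configured "
                "stance_fraction: canonical IC/TO ordering would break"
            )

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["asymmetry_step_time"] = list(self.asymmetry_step_time)
        d["asymmetry_step_length"] = list(self.asymmetry_step_length)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("asymmetry_step_time", "asymmetry_step_length"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a YAML or JSON document."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config document {path} does not contain a mapping")
    return SimulationConfig.from_dict(data)
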