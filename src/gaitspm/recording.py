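"""In-memory container for one motion-capture trial."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import ANGLE_CHANNELS, POSITION_POINTS, ChannelKey, Side


@dataclass
class Recording:
    """Multi-channel joint-angle and position streams for one trial.

    Parameters
    ----------
    trial_id : str
        Identifier for the trial.
    condition : str
        ``"WR"`` (warm-up run) or ``"TR"`` (transition run).
    sample_rate : float
        Sampling rate in Hz (240 for the inertial capture system emulated
        here).
    angles : dict
        Maps each of the 30 :class:`~gaitspm.channels.ChannelKey` channels to
        a length-``T`` vector of degrees.
    positions : dict
        Maps ``pelvis`` / ``left_foot`` / ``right_foot`` to ``T x 3`` arrays
        of metres in a gravity-aligned frame, z vertical up.
    event_flags : dict, optional
        Per-sample boolean ground-contact flags per foot side (``Side.LEFT``
        / ``Side.RIGHT``). When present, event detection trusts them over
        the kinematic heuristics.
    """

    trial_id: str
    condition: str
    sample_rate: float
    angles: dict[ChannelKey, np.ndarray]
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    event_flags: dict[Side, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.angles.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def validate(self) -> None:
        if self.condition not in ("WR", "TR"):
            raise ValueError(f"condition must be WR or TR, got {self.condition!r}")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if not self.angles:
            raise ValueError("recording has no angle channels")
        lengths = {len(v) for v in self.angles.values()}
        if len(lengths) != 1:
            raise ValueError(f"angle channels have unequal lengths: {sorted(lengths)}")
        (T,) = lengths
        if T == 0:
            raise ValueError("angle channels are empty")
        for key, v in self.angles.items():
            if np.isnan(np.asarray(v, dtype=float)).any():
                raise ValueError(f"NaN values in angle channel {key.label}")
        for name, p in self.positions.items():
            if name not in POSITION_POINTS:
                raise ValueError(f"unknown position point {name!r}")
            p = np.asarray(p, dtype=float)
            if p.shape != (T, 3):
                raise ValueError(f"position {name!r} must be {T}x3, got {p.shape}")
            if np.isnan(p).any():
                raise ValueError(f"NaN values in position {name!r}")
        if self.event_flags is not None:
            for side, f in self.event_flags.items():
                if len(f) != T:
                    raise ValueError(f"event flags for {side} have length {len(f)} != {T}")

    def require_full_channel_set(self) -> None:
        """Raise if any of the 30 canonical angle channels is absent."""
        missing = [k for k in ANGLE_CHANNELS if k not in self.angles]
        if missing:
            labels = ", ".join(k.label for k in missing)
            raise ValueError(f"recording is missing angle channels: {labels}")
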