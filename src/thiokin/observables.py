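"""Mapping from species populations to measured differential-absorption channels.

Three probe energies at the sulfur K-edge carry the kinetics: the lowest
thiyl-radical line (2466.8 eV), the perthiyl-radical line (2468.2 eV) and
the parent bleach (2472.0 eV).  Neither the optically excited parent (N1)
nor the vibrationally excited parent (N3) is observed.  The perthiyl
channel additionally picks up a fixed fraction (8 % by default) of the
thiyl lineshape because the two lines overlap spectrally.

The bleach is modelled as ``-A0 * (1 - N0)``: every species that is not
the cold ground-state parent depletes the parent absorption equally.  An
alternative convention in which the vibrationally excited parent absorbs
like the cold parent (and therefore does not bleach) is available through
the ``hot_parent_absorbs`` switch of :func:`default_channels`.

ΔA values are dimensionless, normalized to the parent K-edge jump; the
per-channel amplitudes are free scale factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .kinetics import (
    IRFModel,
    InvalidInputError,
    KineticParameters,
    PopulationTrajectory,
    solve_populations,
)

__all__ = [
    "ChannelModel",
    "TransientTrace",
    "ConfigError",
    "predict_channel",
    "predict_all",
    "default_channels",
    "THIYL_EV",
    "PERTHIYL_EV",
    "BLEACH_EV",
]

THIYL_EV = 2466.8
PERTHIYL_EV = 2468.2
BLEACH_EV = 2472.0


class ConfigError(ValueError):
    """Raised for inconsistent channel configuration."""


@dataclass(frozen=True)
class ChannelModel:
    """One probe-energy channel.

    ``species_weights`` maps population names (``"N1"`` ... ``"N0"``, plus
    the pseudo-species ``"depletion"`` = 1 - N0) to dimensionless response
    coefficients.  ``amplitude`` scales the summed response into ΔA units.
    ``contamination`` optionally adds a fraction of another channel's
    predicted signal (spectral overlap of neighbouring lines).
    """

    label: float
    species_weights: Dict[str, float]
    amplitude: float
    contamination: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude):
            raise ConfigError(f"channel {self.label}: amplitude must be finite")
        if self.contamination is not None:
            _, frac = self.contamination
            if not (0.0 <= frac <= 1.0):
                raise ConfigError(
                    f"channel {self.label}: contamination fraction {frac} outside [0, 1]"
                )
        allowed = {"N1", "N2", "N3", "N4", "N0", "depletion"}
        unknown = set(self.species_weights) - allowed
        if unknown:
            raise ConfigError(f"channel {self.label}: unknown species {sorted(unknown)}")

    def with_amplitude(self, amplitude: float) -> "ChannelModel":
        return ChannelModel(self.label, dict(self.species_weights), amplitude, self.contamination)


@dataclass
class TransientTrace:
    """One delay scan: probe energy (eV), delays (ps), ΔA and per-point
    standard deviations (parent-edge-normalized)."""

    probe_energy: float
    delays: np.ndarray
    dA: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.dA = np.asarray(self.dA, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.delays.shape == self.dA.shape == self.sigma.shape):
            raise InvalidInputError(
                f"trace at {self.probe_energy} eV: delays/dA/sigma lengths differ"
            )
        if np.any(self.sigma <= 0):
            raise InvalidInputError(
                f"trace at {self.probe_energy} eV: sigma must be strictly positive"
            )
        if self.delays.size > 1 and np.any(np.diff(self.delays) <= 0):
            raise InvalidInputError(
                f"trace at {self.probe_energy} eV: delays must be strictly increasing"
            )

    def __len__(self) -> int:
        return self.delays.size


def _species_array(trajectory: PopulationTrajectory, name: str) -> np.ndarray:
    if name == "depletion":
        # number of parent molecules missing from the ground state; equals
        # 1 - N0 after excitation but stays causal (zero before time zero)
        return trajectory.N1 + trajectory.N2 + trajectory.N3 + trajectory.N4
    return getattr(trajectory, name)


def predict_channel(
    trajectory: PopulationTrajectory,
    channel: ChannelModel,
    all_channels: Optional[Sequence[ChannelModel]] = None,
    _depth: int = 0,
) -> np.ndarray:
    """Predicted ΔA for one channel on the trajectory's time grid.

    Contamination terms recursively evaluate the source channel on the
    same trajectory, so the 8 % thiyl admixture in the perthiyl channel
    tracks the thiyl channel's own amplitude.
    """
    if _depth > 4:
        raise ConfigError("contamination chain too deep (cycle?)")
    signal = np.zeros_like(trajectory.times)
    for name, weight in channel.species_weights.items():
        signal = signal + weight * _species_array(trajectory, name)
    signal = channel.amplitude * signal
    if channel.contamination is not None:
        src_label, frac = channel.contamination
        sources = [c for c in (all_channels or []) if c.label == src_label]
        if not sources:
            raise ConfigError(
                f"channel {channel.label}: contamination source {src_label} not defined"
            )
        signal = signal + frac * predict_channel(
            trajectory, sources[0], all_channels, _depth + 1
        )
    return signal


def predict_all(
    params: KineticParameters,
    irf: Optional[IRFModel],
    channels: Sequence[ChannelModel],
    grids: Sequence[np.ndarray],
) -> List[np.ndarray]:
    """One predicted ΔA trace per channel, each on its own delay grid."""
    if len(channels) != len(grids):
        raise InvalidInputError(
            f"{len(channels)} channels but {len(grids)} delay grids"
        )
    out: List[np.ndarray] = []
    cache: Dict[int, PopulationTrajectory] = {}
    for channel, grid in zip(channels, grids):
        grid = np.asarray(grid, dtype=float)
        key = hash(grid.tobytes())
        traj = cache.get(key)
        if traj is None:
            traj = solve_populations(params, grid, irf=irf)
            cache[key] = traj
        out.append(predict_channel(traj, channel, channels))
    return out


def default_channels(
    a_thiyl: float = 0.020,
    a_perthiyl: float = 0.010,
    a_bleach: float = 0.025,
    contamination: float = 0.08,
    hot_parent_absorbs: bool = False,
) -> List[ChannelModel]:
    """The three standard probe channels.

    ``hot_parent_absorbs=True`` switches the bleach to the convention where
    the vibrationally excited parent absorbs like the cold parent and thus
    does not contribute to the depletion signal.
    """
    if hot_parent_absorbs:
        bleach_weights = {"N1": -1.0, "N2": -1.0, "N4": -1.0}
    else:
        bleach_weights = {"depletion": -1.0}
    return [
        ChannelModel(THIYL_EV, {"N2": 1.0}, a_thiyl),
        ChannelModel(PERTHIYL_EV, {"N4": 1.0}, a_perthiyl, (THIYL_EV, contamination)),
        ChannelModel(BLEACH_EV, bleach_weights, a_bleach),
    ]
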