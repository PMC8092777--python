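"""Synthetic midline tracks emulating video digitization of a swimming fish.

A station-holding fish in a circulating flume oscillates laterally about
fixed body-axis stations; digitizing landmarks from 60 fps overhead video
yields per-frame lateral positions with a small, roughly Gaussian
digitization error.  This module generates such tracks directly from the
body-wave model so that every downstream estimation and simulation stage
can be exercised without original footage.

The default station layout places the nine body-axis landmarks (snout, eye
midpoint, pectoral-fin base/end midpoints, dorsal-fin root/end, adipose
root, caudal root, caudal-fin tip) at plausible anatomical fractions of the
body length; the tail tip sits beyond 1 BL because total length exceeds
body length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from fishwake.kinematics import (
    BodyWaveParams,
    MidlineTrack,
    evaluate_displacement,
)

__all__ = ["TrackGenConfig", "generate_track", "DEFAULT_STATIONS"]

#: Body-axis positions (BL) of the nine default landmarks a, n, o, p, h, i,
#: j, k, q: snout, eyes, pectoral base, pectoral end, dorsal root, dorsal
#: end, adipose root, caudal root, caudal-fin tip.
DEFAULT_STATIONS = (0.0, 0.05, 0.15, 0.25, 0.45, 0.60, 0.75, 0.85, 1.13)


@dataclass(frozen=True)
class TrackGenConfig:
    """Configuration of the synthetic track generator.

    Attributes
    ----------
    params :
        Body-wave constants driving the lateral motion.
    stations :
        Body-axis sampling positions (BL), strictly increasing.
    fps :
        Frame rate of the emulated video (Hz); 60 matches the recordings.
    duration :
        Track length in seconds; must cover at least two tail-beat periods.
    noise_sd :
        Standard deviation of the i.i.d. Gaussian digitization error (BL).
    seed :
        Seed of the generator's private random stream.
    """

    params: BodyWaveParams
    stations: tuple[float, ...] = DEFAULT_STATIONS
    fps: float = 60.0
    duration: float = 4.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.duration * self.params.frequency < 2.0:
            raise ValueError(
                "duration must cover at least two tail-beat periods "
                f"(needs >= {2.0 / self.params.frequency:.3f} s)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrackGenConfig":
        raw = yaml.safe_load(Path(path).read_text())
        params = BodyWaveParams.from_dict(raw["params"])
        kwargs = {}
        for key in ("fps", "duration", "noise_sd", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "stations" in raw:
            kwargs["stations"] = tuple(float(s) for s in raw["stations"])
        return cls(params=params, **kwargs)


def generate_track(config: TrackGenConfig) -> MidlineTrack:
    """Sample the body-wave model on the station × frame grid, plus noise.

    Displacement at station ``x_i`` and frame time ``t_j`` is
    ``h(x_i, t_j)`` with independent ``N(0, noise_sd²)`` digitization error
    added to every sample; identical seeds give identical tracks.
    """
    stations = np.asarray(config.stations, dtype=float)
    n_frames = int(round(config.duration * config.fps)) + 1
    times = np.arange(n_frames) / config.fps
    clean = evaluate_displacement(
        stations[:, None], times[None, :], config.params
    )
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        clean = clean + rng.normal(0.0, config.noise_sd, size=clean.shape)
    return MidlineTrack(stations=stations, times=times, displacements=clean)
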