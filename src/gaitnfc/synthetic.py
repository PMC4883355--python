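"""Synthetic rider hip-height signals for the four horse gaits.

Real capture databases of mounted riders are rarely shareable, so the
pipeline is exercised on controllable surrogates: 100-sample windows of
the rider's hip vertical coordinate, one rhythmic waveform family per
gait plus Gaussian noise and a small random phase offset standing in for
imperfect stride synchronisation.

The waveform families follow the qualitative signatures of the gaits as
seen from the saddle:

* walk — near-flat, low-amplitude slow oscillation (four-beat, no
  suspension phase, little vertical displacement);
* sitting trot — a clean higher-frequency sinusoid (two-beat diagonal
  gait with a bounce per beat);
* rising trot — the trot rhythm with every second cycle attenuated (the
  rider posts, rising out of the saddle on alternate beats);
* canter — a slower three-beat, asymmetric (skewed) oscillation.

These are deliberately stylised: amplitudes, frequencies and noise are
committed defaults chosen for plausible separation with overlap, not
biomechanically validated waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .dataset import DEFAULT_CLASS_CODES, GAITS, GaitDataset

__all__ = ["GaitSpec", "default_specs", "template", "generate_sample",
           "generate_dataset"]


@dataclass(frozen=True)
class GaitSpec:
    """Waveform recipe for one gait.

    Parameters
    ----------
    gait : str
        Label.
    base_frequency : float
        Cycles per 100-sample window (the window is 1 s at 100 fps, so
        this is approximately Hz).
    amplitude : float
        Oscillation amplitude in the hip-height units of the capture.
    amplitude_alternation : float in [0, 1]
        Attenuation applied to every second cycle (posting at the rising
        trot); 0 disables.
    beat_asymmetry : float in [0, 1]
        Phase-modulation skew producing an asymmetric rise/fall (the
        canter's three-beat roll); 0 gives a pure sinusoid.
    baseline : float
        Mean hip height.
    noise_sd : float
        Additive i.i.d. Gaussian noise standard deviation.
    phase_jitter_sd : float
        Standard deviation (radians) of the per-window random phase
        offset emulating imperfect stride alignment.
    """

    gait: str
    base_frequency: float
    amplitude: float
    amplitude_alternation: float = 0.0
    beat_asymmetry: float = 0.0
    baseline: float = 1.0
    noise_sd: float = 0.0
    phase_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be >= 0")
        if not self.base_frequency > 0:
            raise ValueError("base_frequency must be > 0")
        if not 0 <= self.amplitude_alternation <= 1:
            raise ValueError("amplitude_alternation must be in [0, 1]")
        if not 0 <= self.beat_asymmetry <= 1:
            raise ValueError("beat_asymmetry must be in [0, 1]")


#: Committed default profiles.  Hip-height units are metres-scale;
#: the noise floor (1 cm) is comparable to the walk amplitude so the
#: easiest class is genuinely noisy while the trots and canter separate
#: on rhythm, not on trivia.
_DEFAULTS: dict[str, GaitSpec] = {
    "walk": GaitSpec(
        gait="walk", base_frequency=2.0, amplitude=0.012,
        noise_sd=0.01, phase_jitter_sd=0.15,
    ),
    "sitting_trot": GaitSpec(
        gait="sitting_trot", base_frequency=4.0, amplitude=0.05,
        noise_sd=0.01, phase_jitter_sd=0.15,
    ),
    "rising_trot": GaitSpec(
        gait="rising_trot", base_frequency=4.0, amplitude=0.06,
        amplitude_alternation=0.5, noise_sd=0.01, phase_jitter_sd=0.15,
    ),
    "canter": GaitSpec(
        gait="canter", base_frequency=3.0, amplitude=0.07,
        beat_asymmetry=0.6, noise_sd=0.01, phase_jitter_sd=0.15,
    ),
}


def default_specs() -> dict[str, GaitSpec]:
    """The four committed gait profiles (fresh copies)."""
    return {g: replace(s) for g, s in _DEFAULTS.items()}


def template(spec: GaitSpec, length: int, phase: float = 0.0) -> np.ndarray:
    """Noise-free waveform of one window.

    baseline + A(t) * sin(theta + k * sin(theta)), theta = 2 pi f t + phase,
    where A(t) attenuates every second cycle by (1 - alternation) and k
    is the asymmetry skew.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    t = np.arange(length) / float(length)
    theta = 2.0 * np.pi * spec.base_frequency * t + phase
    cycle = np.floor((theta / (2.0 * np.pi)) % spec.base_frequency + 1e-12)
    amp = spec.amplitude * (
        1.0 - spec.amplitude_alternation * (cycle.astype(int) % 2)
    )
    wave = amp * np.sin(theta + spec.beat_asymmetry * np.sin(theta))
    return spec.baseline + wave


def generate_sample(
    spec: GaitSpec, length: int, seed: Optional[int] = None
) -> np.ndarray:
    """One noisy window: template + phase jitter + Gaussian noise.

    Deterministic per seed; with noise_sd = phase_jitter_sd = 0 this is
    exactly the analytic template.
    """
    rng = np.random.default_rng(seed)
    phase = (
        rng.normal(0.0, spec.phase_jitter_sd) if spec.phase_jitter_sd > 0
        else 0.0
    )
    x = template(spec, length, phase=phase)
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, size=length)
    return x


def generate_dataset(
    n_per_gait: int = 40,
    length: int = 100,
    seed: Optional[int] = None,
    specs: Optional[dict[str, GaitSpec]] = None,
) -> GaitDataset:
    """Labelled dataset of ``4 * n_per_gait`` windows in gait order.

    The defaults (40 per gait, 100 samples) reproduce the 100 x 160
    study geometry: 100 dimensions, 40 columns per gait.
    """
    if n_per_gait < 1:
        raise ValueError("n_per_gait must be >= 1")
    specs = specs or default_specs()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(4 * n_per_gait)
    cols, labels = [], []
    i = 0
    for gait in GAITS:
        spec = specs[gait]
        for _ in range(n_per_gait):
            cols.append(generate_sample(spec, length, seed=children[i]))
            labels.append(gait)
            i += 1
    return GaitDataset(
        signals=np.column_stack(cols),
        labels=labels,
        class_codes=dict(DEFAULT_CLASS_CODES),
    )
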