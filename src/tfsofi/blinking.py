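"""Two-state (ON/OFF) emitter photoswitching kinetics.

Quantum-dot style blinking is modelled as a discrete-time two-state Markov
chain sampled once per camera frame: with the 1 ms exposures used here the
dwell times are long compared to a frame, so sub-frame state mixing is
neglected and each frame is entirely ON or OFF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BlinkKinetics", "simulate_blink_traces", "apply_bleaching"]


@dataclass(frozen=True)
class BlinkKinetics:
    """Per-frame switching probabilities of the ON/OFF Markov chain."""

    p_on_to_off: float = 0.5
    p_off_to_on: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_on_to_off", "p_off_to_on"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def stationary_on_fraction(self) -> float:
        """Long-run fraction of time spent ON, p_off_to_on / (p_on + p_off).

        When both probabilities are 0 the chain never moves and every state
        is stationary; 0.5 is returned as the symmetric convention.
        """
        denom = self.p_on_to_off + self.p_off_to_on
        if denom == 0.0:
            return 0.5
        return self.p_off_to_on / denom


def simulate_blink_traces(
    kinetics: BlinkKinetics,
    n_emitters: int,
    n_frames: int,
    rng: np.random.Generator | int,
    initial_state=None,
) -> np.ndarray:
    """Draw independent ON/OFF traces, one per emitter.

    Parameters
    ----------
    rng
        A ``numpy.random.Generator`` or an integer seed.
    initial_state
        Optional bool (or per-emitter bool array) forcing the frame-0 state;
        by default frame 0 is drawn from the stationary distribution so the
        whole trace is stationary.

    Returns
    -------
    ndarray of bool, shape (n_emitters, n_frames)
    """
    if n_emitters < 1 or n_frames < 1:
        raise ValueError("need at least one emitter and one frame")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    states = np.empty((n_emitters, n_frames), dtype=bool)
    if initial_state is None:
        states[:, 0] = rng.random(n_emitters) < kinetics.stationary_on_fraction
    else:
        states[:, 0] = np.broadcast_to(np.asarray(initial_state, dtype=bool), (n_emitters,))

    # One vectorised uniform draw per frame transition across all emitters.
    u = rng.random((n_emitters, max(n_frames - 1, 0)))
    for t in range(1, n_frames):
        on = states[:, t - 1]
        flip = np.where(on, u[:, t - 1] < kinetics.p_on_to_off, u[:, t - 1] < kinetics.p_off_to_on)
        states[:, t] = on ^ flip
    return states


def apply_bleaching(series: np.ndarray, decay_rate: float, time_axis: int = -1) -> np.ndarray:
    """Multiply the expectation of frame ``t`` by ``exp(-decay_rate * t)``.

    ``series`` may be a set of per-emitter brightness traces (time on the
    last axis) or a movie expectation (pass ``time_axis=0``).
    """
    if decay_rate < 0:
        raise ValueError("decay_rate must be >= 0")
    series = np.asarray(series, dtype=float)
    n = series.shape[time_axis]
    decay = np.exp(-decay_rate * np.arange(n))
    shape = [1] * series.ndim
    shape[time_axis] = n
    return series * decay.reshape(shape)
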