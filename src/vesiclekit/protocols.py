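"""Stimulus protocols: ordered action-potential times built from frequency segments.

A protocol is the experimental drive applied to a synapse: one or more
constant-frequency segments of electrical stimulation, e.g. 300 Hz for 300 ms
(90 action potentials) at the calyx of Held, or a 50 Hz conditioning train
followed by a 300 Hz frequency jump.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusProtocol", "make_protocol", "InvalidProtocolError"]


class InvalidProtocolError(ValueError):
    """Raised for non-positive frequencies or stimulus counts."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered action-potential times.

    Parameters
    ----------
    stim_times : ndarray of float
        Stimulus times in seconds, strictly increasing, non-negative.
    segments : list of (float, int)
        The (frequency_hz, n_stimuli) segments the times were built from.
    label : str
        Free-form description (e.g. ``"calyx 300Hz x 300ms"``).
    """

    stim_times: np.ndarray
    segments: list = field(default_factory=list)
    label: str = ""

    def __post_init__(self):
        times = np.asarray(self.stim_times, dtype=float)
        object.__setattr__(self, "stim_times", times)
        if times.size and times[0] < 0:
            raise InvalidProtocolError("stimulus times must be non-negative")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise InvalidProtocolError("stimulus times must be strictly increasing")
        if self.segments:
            n = sum(int(c) for _, c in self.segments)
            if n != times.size:
                raise InvalidProtocolError(
                    f"segment counts sum to {n} but {times.size} stimulus times given"
                )

    @property
    def n_stimuli(self) -> int:
        return int(self.stim_times.size)

    @property
    def intervals(self) -> np.ndarray:
        """Inter-stimulus intervals in seconds (length n_stimuli - 1)."""
        return np.diff(self.stim_times)

    def shifted(self, dt: float) -> "StimulusProtocol":
        """Return a copy with all stimulus times offset by `dt` seconds."""
        return StimulusProtocol(self.stim_times + dt, list(self.segments), self.label)


def make_protocol(segments, start_time: float = 0.0, label: str = "") -> StimulusProtocol:
    """Build a protocol from constant-frequency segments.

    Within a segment the spacing is 1/frequency; a new segment starts one
    inter-stimulus interval of the *new* frequency after the last stimulus of
    the previous segment.

    Parameters
    ----------
    segments : sequence of (frequency_hz, n_stimuli)
    start_time : float
        Time of the first stimulus in seconds.

    Examples
    --------
    >>> make_protocol([(300.0, 90)]).stim_times[1]
    0.0033333333333333335
    """
    times = []
    t = float(start_time)
    for freq, count in segments:
        freq = float(freq)
        count = int(count)
        if freq <= 0:
            raise InvalidProtocolError(f"frequency must be positive, got {freq}")
        if count < 1:
            raise InvalidProtocolError(f"segment count must be >= 1, got {count}")
        isi = 1.0 / freq
        if times:
            t = times[-1] + isi
        for i in range(count):
            times.append(t + i * isi)
    return StimulusProtocol(np.array(times), [(float(f), int(c)) for f, c in segments], label)
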