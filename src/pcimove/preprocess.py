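"""Track preprocessing: recursive pairwise coarse-graining and smoothing.

Raw centroid tracks are sampled at 10 fps, which produces fictive
micro-movements at the camera's resolution limit.  Coarse-graining replaces
every two successive samples of ``time``, ``x`` and ``y`` by their average,
recursively, halving the series per level: levels 1..5 of a 0.1 s track give
effective intervals 0.2, 0.4, 0.8, 1.6 and 3.2 s.  The downstream analyses
operate on the level-4 (1.6 s) series by default.  Tracks recorded on sand,
where the centroid estimate is noisy at the scale of the movement itself,
are additionally smoothed with a centred running average.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .io import Track


def coarse_grain(track: Track, levels: int) -> Track:
    """Apply ``levels`` rounds of pairwise averaging to a track.

    Each round replaces consecutive sample pairs (time, x, y) by their
    means, halving the length; a trailing unpaired sample is dropped.
    ``coarse_grain(t, a+b) == coarse_grain(coarse_grain(t, a), b)`` and the
    effective sampling interval is ``dt * 2**levels``.
    """
    if levels < 0:
        raise ValueError("levels must be non-negative")
    if track.n_samples < 2 ** levels:
        raise ValueError(f"track of length {track.n_samples} too short for "
                         f"{levels} coarse-graining levels")
    times, xy = track.times, track.xy
    for _ in range(levels):
        n = times.shape[0] - times.shape[0] % 2
        if n < 2:
            raise ValueError("track became too short during coarse-graining")
        times = 0.5 * (times[0:n:2] + times[1:n:2])
        xy = 0.5 * (xy[0:n:2] + xy[1:n:2])
    return replace(track, times=times, xy=xy)


def smooth_track(track: Track, window: int) -> Track:
    """Centred running average of x and y with an odd window.

    Near the edges the window shrinks symmetrically (the first and last
    samples are untouched), so the track length and timestamps are
    preserved.  ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window == 1:
        return replace(track)
    half = window // 2
    n = track.n_samples
    xy = np.empty_like(track.xy)
    # cumulative sum with a leading zero row: window mean in O(1) per sample
    cs = np.vstack([np.zeros((1, 2)), np.cumsum(track.xy, axis=0)])
    for i in range(n):
        h = min(half, i, n - 1 - i)
        xy[i] = (cs[i + h + 1] - cs[i - h]) / (2 * h + 1)
    return replace(track, times=track.times.copy(), xy=xy)
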