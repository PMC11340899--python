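"""Segmentation of coarse-grained tracks into immobility/movement bouts.

A frame is *moving* when its step displacement from the previous frame
exceeds a threshold (by default an automatic per-track noise floor).  A
movement bout terminates only after at least ``still_gap`` seconds of
consecutive non-moving frames — short pauses are absorbed into the bout,
operationalising "no movement for more than a couple of seconds"; the
terminal gap frames belong to the following immobility bout.  The bout list
always starts with the immobility bout containing the first timestamp (the
post-contact immobility).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BoutSequence, Track, logger

#: default stillness gap ending a movement bout: two frames at the 1.6 s level
DEFAULT_STILL_GAP_S = 3.2

#: wall-arrival margin, about one body length
DEFAULT_WALL_MARGIN_MM = 5.0


@dataclass(frozen=True)
class BoutEvent:
    """One maximal interval of a single behavioural state."""

    kind: str               # "immobility" | "movement"
    start: float            # s
    end: float              # s
    sequential_number: int  # 1-based within its kind

    @property
    def duration(self) -> float:
        return self.end - self.start


def auto_move_threshold(track: Track, noise_quantile: float = 0.25,
                        alpha: float = 0.05) -> float:
    """Noise-floor movement threshold for one track.

    Intermittently locomoting animals are still for most frames, so a low
    quantile of the step-displacement distribution reflects apparent motion
    from centroid/camera noise alone.  With isotropic Gaussian centroid
    noise the still-frame step length is Rayleigh distributed, whose scale
    is recovered from the ``noise_quantile`` as
    ``q / sqrt(-2 log(1 - noise_quantile))``.  The threshold is then placed
    at the level a still frame exceeds with probability ``alpha`` over the
    *whole* track (``scale * sqrt(2 log(n_steps / alpha))``), so noise
    alone produces a spurious movement frame in at most a fraction
    ``alpha`` of tracks.  A jitter-free track yields threshold 0 (any
    positive step counts as movement).
    """
    steps = track.step_displacements()
    q = float(np.quantile(steps, noise_quantile))
    scale = q / float(np.sqrt(-2.0 * np.log1p(-noise_quantile)))
    n = len(steps)
    return scale * float(np.sqrt(2.0 * np.log(n / alpha)))


def segment_bouts(track: Track, move_threshold: float | str = "auto",
                  still_gap: float = DEFAULT_STILL_GAP_S) -> list[BoutEvent]:
    """Segment a (coarse-grained) track into alternating bouts.

    Parameters
    ----------
    track
        Track at the analysis coarse-graining level.
    move_threshold
        Step-displacement threshold in mm, or ``"auto"`` for the per-track
        noise floor from :func:`auto_move_threshold`.
    still_gap
        Seconds of consecutive stillness required to end a movement bout;
        must be at least the sampling interval.

    Returns
    -------
    list of :class:`BoutEvent`, strictly alternating, starting with
    immobility; bout durations sum exactly to the track's time span.
    """
    if track.n_samples < 2:
        raise ValueError("cannot segment an empty or single-sample track")
    dt = track.dt
    if still_gap < dt - 1e-9:
        raise ValueError(f"still_gap {still_gap} s is below the sampling "
                         f"interval {dt} s")
    if move_threshold == "auto":
        move_threshold = auto_move_threshold(track)
    thr = float(move_threshold)
    if thr < 0:
        raise ValueError("move_threshold must be non-negative")

    steps = track.step_displacements()
    # frame j >= 1 is moving iff its step from frame j-1 exceeds the
    # threshold; frame 0 belongs to the initial immobility by definition
    moving = np.concatenate([[False], steps > thr])
    n = moving.shape[0]
    gap_frames = max(1, int(np.ceil(still_gap / dt - 1e-9)))

    # state per frame after the still-gap rule: a still run shorter than
    # gap_frames that is flanked by moving frames is relabelled as movement
    state = moving.copy()
    j = 1
    while j < n:
        if not state[j] and state[j - 1]:
            run_end = j
            while run_end < n and not state[run_end]:
                run_end += 1
            if run_end < n and (run_end - j) < gap_frames:
                state[j:run_end] = True
            j = run_end
        else:
            j += 1

    events: list[BoutEvent] = []
    counts = {"immobility": 0, "movement": 0}
    t = track.times
    bout_start = t[0]
    current = "immobility"
    for j in range(1, n):
        kind = "movement" if state[j] else "immobility"
        if kind != current:
            boundary = t[j]
            counts[current] += 1
            events.append(BoutEvent(current, float(bout_start), float(boundary),
                                    counts[current]))
            bout_start = boundary
            current = kind
    counts[current] += 1
    events.append(BoutEvent(current, float(bout_start), float(t[-1]),
                            counts[current]))
    return events


def wall_arrival_time(track: Track, margin: float = DEFAULT_WALL_MARGIN_MM
                      ) -> float | None:
    """Time of the first frame within ``margin`` mm of any arena edge."""
    size = 2.0 * track.arena_half_width
    near = ((track.xy <= margin) | (track.xy >= size - margin)).any(axis=1)
    idx = np.flatnonzero(near)
    return float(track.times[idx[0]]) if idx.size else None


def extract_sequence(events: list[BoutEvent], individual_id: str = "",
                     treatment: str = "paper", max_pairs: int = 16,
                     wall_time: float | None = None,
                     weight_g: float | None = None) -> BoutSequence:
    """Collapse a bout-event list into a :class:`BoutSequence`.

    Truncates at ``max_pairs`` immobility and movement periods and, when
    ``wall_time`` is given, at the bout during which the animal first comes
    within the wall margin (that bout is clipped at the arrival time and the
    sequence ends there, mirroring the observation protocol on the hard
    substrate).
    """
    if not events:
        raise ValueError("no events to extract")
    for a, b in zip(events, events[1:]):
        if a.kind == b.kind:
            raise ValueError("events must strictly alternate")
    if events[0].kind != "immobility":
        raise ValueError("the first event must be the post-contact immobility")

    imm: list[float] = []
    mov: list[float] = []
    reached_wall = False
    for ev in events:
        end = ev.end
        if wall_time is not None and ev.start < wall_time <= ev.end:
            end = wall_time
            reached_wall = True
        d = end - ev.start
        if d <= 0:
            break
        if ev.kind == "immobility":
            if len(imm) >= max_pairs:
                break
            imm.append(d)
        else:
            if len(mov) >= max_pairs:
                break
            mov.append(d)
        if reached_wall:
            break
    if len(imm) == len(mov) - 1:  # truncation ended mid-pattern
        mov.pop()
    return BoutSequence(
        individual_id=individual_id,
        treatment=treatment,
        immobility_durations=np.array(imm),
        movement_durations=np.array(mov),
        arrival_time=float(events[0].start),
        reached_wall=reached_wall,
        weight_g=weight_g,
    )


def segment_cohort(tracks: list[Track], move_threshold: float | str = "auto",
                   still_gap: float = DEFAULT_STILL_GAP_S, max_pairs: int = 16,
                   wall_rule: bool = True,
                   wall_margin: float = DEFAULT_WALL_MARGIN_MM):
    """Segment every track and return a list of bout sequences."""
    from .io import Cohort

    sequences = []
    for tr in tracks:
        events = segment_bouts(tr, move_threshold=move_threshold,
                               still_gap=still_gap)
        wt = wall_arrival_time(tr, margin=wall_margin) if wall_rule else None
        try:
            sequences.append(extract_sequence(
                events, individual_id=tr.individual_id, treatment=tr.treatment,
                max_pairs=max_pairs, wall_time=wt))
        except ValueError as exc:
            logger.warning("skipping track %s: %s", tr.individual_id, exc)
    return Cohort(sequences=sequences, tracks=list(tracks))
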