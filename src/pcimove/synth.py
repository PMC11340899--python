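"""Synthetic intermittent-locomotion generator.

Emulates the statistical structure of the antlion release experiments so
every pipeline stage is testable without the original video data:

* per-individual alternating immobility/movement bout sequences (up to 16
  pairs in a 90-minute window) whose log10 durations trend linearly in
  log10 event index, with normal random intercepts/slopes per individual —
  the data-generating process the duration-trend mixed model assumes;
* optional i.i.d. bout-duration marginals from exponential, log-normal or
  power-law laws, for exercising the tail-fitting stage under known truth;
* 2-D centroid tracks at 10 samples/s in a 225 x 225 mm arena with the
  drop point at the centre: exact stillness plus small isotropic Gaussian
  centroid jitter during immobility, and a correlated random walk (wrapped
  normal turning angles, reflective walls) during movement, with a
  per-event multiplicative speed trend.

A single root seed drives everything through per-individual spawned
streams, so cohorts are bit-reproducible and individuals re-drawable.

The built-in scenarios (:func:`scenario`) encode the study conditions of
the three substrates: 22 individuals on paper with steeply shrinking
immobility (log-log slope -1.18), growing movement (+1.16) and rising
speeds; 8 on shallow sand with moderate trends (-1.00 / +0.38) and slowly
decaying speeds; 8 on deep sand with flat trends (-0.36 / +0.01) and
strongly decaying speeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import (ARENA_SIZE_MM, DROP_POINT_MM, MAX_PAIRS,
                 OBSERVATION_WINDOW_S, BoutSequence, Cohort, Track)


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic treatment group."""

    name: str
    treatment: str
    n_individuals: int
    # log10-duration trend: duration_k = 10**(a + b*log10 k + eps)
    imm_intercept: float = 2.3     # log10 s at event 1 (PCI ~ 200 s)
    imm_slope: float = -1.18
    mov_intercept: float = 0.2
    mov_slope: float = 1.16
    sd_intercept: float = 0.30     # random-effect SDs across individuals
    sd_slope: float = 0.35
    sd_resid: float = 0.30         # residual SD of log10 duration
    # i.i.d. marginal law overriding the trend model: (family, params)
    immobility_law: tuple[str, dict[str, float]] | None = None
    movement_law: tuple[str, dict[str, float]] | None = None
    # movement rendering
    base_speed: float = 1.5        # mm/s during movement event 1
    speed_trend: float = 1.15      # multiplicative per movement event
    turn_sd: float = 0.3           # SD (rad) of per-frame heading change
    jitter_sd: float = 0.05        # mm, centroid noise during immobility
    # duration floors at the 1 s manual-timing resolution; raise them
    # (e.g. to 6.4 s immobility / 1.6 s movement) to generate cohorts whose
    # every bout is resolvable at the 1.6 s analysis coarse-graining
    min_immobility: float = 1.0
    min_movement: float = 1.0
    fps: float = 10.0
    arena: float = ARENA_SIZE_MM
    # tracking ends when the animal first comes within this margin of a
    # wall, as in the observation protocol (0 disables the stop)
    wall_margin: float = 5.0
    drop: tuple[float, float] = DROP_POINT_MM
    window: float = OBSERVATION_WINDOW_S
    max_pairs: int = MAX_PAIRS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        for nm in ("sd_intercept", "sd_slope", "sd_resid", "jitter_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")
        if self.base_speed < 0 or self.speed_trend < 0:
            raise ValueError("speeds must be non-negative")


_SCENARIOS = {
    "paper": dict(treatment="paper", n_individuals=22,
                  imm_slope=-1.18, mov_slope=1.16, mov_intercept=0.2,
                  base_speed=1.5, speed_trend=1.15, turn_sd=0.3),
    "shallow": dict(treatment="shallow_sand", n_individuals=8,
                    imm_slope=-1.00, mov_slope=0.38, mov_intercept=0.4,
                    base_speed=0.8, speed_trend=0.95, turn_sd=0.8),
    "deep": dict(treatment="deep_sand", n_individuals=8,
                 imm_slope=-0.36, mov_slope=0.01, mov_intercept=0.3,
                 base_speed=0.6, speed_trend=0.92, turn_sd=0.8),
}


def scenario(name: str, seed: int = 0, **overrides) -> ScenarioSpec:
    """A built-in study-condition scenario: ``paper``, ``shallow``, ``deep``."""
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from "
                         f"{sorted(_SCENARIOS)}")
    kw = dict(_SCENARIOS[name])
    kw.update(overrides)
    return ScenarioSpec(name=name, seed=seed, **kw)


# ---------------------------------------------------------------------------
# duration laws

def sample_durations(law: tuple[str, dict[str, float]], n: int,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """I.i.d. draws from a duration law by inverse-CDF.

    ``law`` is ``(family, params)``: ``("exponential", {"lam": ...})``,
    ``("lognormal", {"mu": ..., "sigma": ...})`` or
    ``("powerlaw", {"alpha": ..., "xmin": ...})`` (continuous Pareto tail,
    ``alpha > 1``).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    family, p = law
    u = rng.random(n)
    if family == "exponential":
        lam = p["lam"]
        if lam <= 0:
            raise ValueError("lam must be positive")
        return -np.log1p(-u) / lam
    if family == "lognormal":
        sigma = p["sigma"]
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        from scipy.stats import norm
        return np.exp(p["mu"] + sigma * norm.ppf(u))
    if family == "powerlaw":
        alpha, xmin = p["alpha"], p["xmin"]
        if alpha <= 1 or xmin <= 0:
            raise ValueError("need alpha > 1 and xmin > 0")
        return xmin * (1.0 - u) ** (-1.0 / (alpha - 1.0))
    raise ValueError(f"unknown law {family!r}")


# ---------------------------------------------------------------------------
# bout cohorts

def _individual_rngs(spec: ScenarioSpec) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(spec.seed)
    return [np.random.default_rng(s) for s in ss.spawn(spec.n_individuals)]


def _draw_sequence(spec: ScenarioSpec, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Alternating durations for one individual, truncated to the window."""
    kmax = spec.max_pairs
    if spec.immobility_law is not None:
        imm_all = sample_durations(spec.immobility_law, kmax, rng)
    else:
        a = spec.imm_intercept + spec.sd_intercept * rng.standard_normal()
        b = spec.imm_slope + spec.sd_slope * rng.standard_normal()
        k = np.arange(1, kmax + 1)
        imm_all = 10.0 ** (a + b * np.log10(k)
                           + spec.sd_resid * rng.standard_normal(kmax))
    if spec.movement_law is not None:
        mov_all = sample_durations(spec.movement_law, kmax, rng)
    else:
        a = spec.mov_intercept + spec.sd_intercept * rng.standard_normal()
        k = np.arange(1, kmax + 1)
        mov_all = 10.0 ** (a + spec.mov_slope * np.log10(k)
                           + spec.sd_resid * rng.standard_normal(kmax))
    imm_all = np.maximum(imm_all, spec.min_immobility)
    mov_all = np.maximum(mov_all, spec.min_movement)
    imm, mov = [], []
    t = 0.0
    for k in range(kmax):
        if t + imm_all[k] > spec.window:
            break
        imm.append(float(imm_all[k]))
        t += imm_all[k]
        if t + mov_all[k] > spec.window:
            break
        mov.append(float(mov_all[k]))
        t += mov_all[k]
    if not imm:  # the PCI alone overruns the window: right-censor it
        imm = [float(spec.window)]
    return np.array(imm), np.array(mov)


def gen_bout_cohort(spec: ScenarioSpec) -> Cohort:
    """Generate a cohort of bout sequences under the scenario's trend model."""
    return gen_cohort(spec, with_tracks=False)


# ---------------------------------------------------------------------------
# tracks

def gen_track(bouts: BoutSequence, spec: ScenarioSpec,
              rng: np.random.Generator | int = 0) -> Track:
    """Render a bout sequence as a 2-D centroid track.

    Immobility is a fixed hold position plus isotropic Gaussian jitter;
    movement bout *k* is a correlated random walk at speed
    ``base_speed * speed_trend**(k-1)`` with wrapped-normal turning angles,
    reflected at the arena walls.
    """
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    dt = 1.0 / spec.fps
    segments: list[tuple[str, int, float]] = []  # (kind, frames, speed)
    for k in range(bouts.n_immobility):
        frames = max(1, int(round(bouts.immobility_durations[k] / dt)))
        segments.append(("immobility", frames, 0.0))
        if k < bouts.n_movement:
            frames = max(1, int(round(bouts.movement_durations[k] / dt)))
            speed = spec.base_speed * spec.speed_trend ** k
            segments.append(("movement", frames, speed))
    n = sum(f for _, f, _ in segments) + 1
    xy = np.empty((n, 2))
    pos = np.array(spec.drop, float)
    xy[0] = pos
    heading = rng.uniform(0.0, 2.0 * math.pi)
    i = 1
    margin = spec.wall_margin
    at_wall = False
    for kind, frames, speed in segments:
        if at_wall:
            break
        if kind == "immobility":
            hold = pos.copy()
            jit = (spec.jitter_sd * rng.standard_normal((frames, 2))
                   if spec.jitter_sd > 0 else np.zeros((frames, 2)))
            xy[i:i + frames] = hold + jit
            i += frames
        else:
            for _ in range(frames):
                heading += spec.turn_sd * rng.standard_normal()
                step = speed * dt * np.array([math.cos(heading),
                                              math.sin(heading)])
                pos = pos + step
                # reflective walls
                for ax in (0, 1):
                    if pos[ax] < 0:
                        pos[ax] = -pos[ax]
                        heading = math.pi - heading if ax == 0 else -heading
                    elif pos[ax] > spec.arena:
                        pos[ax] = 2 * spec.arena - pos[ax]
                        heading = math.pi - heading if ax == 0 else -heading
                xy[i] = pos
                i += 1
                if margin > 0 and (np.min(pos) <= margin
                                   or np.max(pos) >= spec.arena - margin):
                    at_wall = True  # tracking stops at wall arrival
                    break
            pos = xy[i - 1].copy()
    xy = xy[:i]
    times = bouts.arrival_time + dt * np.arange(i)
    return Track(individual_id=bouts.individual_id, treatment=bouts.treatment,
                 times=times, xy=xy)


def gen_cohort(spec: ScenarioSpec, with_tracks: bool = True) -> Cohort:
    """Generate bout sequences and (optionally) matching raw tracks.

    When a rendered track reaches the arena wall, the stored bout sequence
    is truncated at the arrival time (``reached_wall=True``), exactly as
    the observation protocol truncates the bout record.
    """
    from .bouts import BoutEvent, extract_sequence, wall_arrival_time

    sequences, tracks = [], []
    for i, rng in enumerate(_individual_rngs(spec), start=1):
        imm, mov = _draw_sequence(spec, rng)
        weight = float(np.round(10 ** rng.normal(np.log10(0.036), 0.3), 4))
        seq = BoutSequence(
            individual_id=f"{spec.name}{i:02d}",
            treatment=spec.treatment,
            immobility_durations=imm,
            movement_durations=mov,
            arrival_time=0.0,
            weight_g=weight,
        )
        if with_tracks:
            track = gen_track(seq, spec, rng)
            wall_t = (wall_arrival_time(track, margin=spec.wall_margin)
                      if spec.wall_margin > 0 else None)
            if wall_t is not None:
                events, t = [], seq.arrival_time
                for k in range(seq.n_immobility):
                    events.append(BoutEvent("immobility", t,
                                            t + imm[k], k + 1))
                    t += imm[k]
                    if k < seq.n_movement:
                        events.append(BoutEvent("movement", t,
                                                t + mov[k], k + 1))
                        t += mov[k]
                seq = extract_sequence(events, seq.individual_id,
                                       seq.treatment,
                                       max_pairs=spec.max_pairs,
                                       wall_time=wall_t, weight_g=weight)
            tracks.append(track)
        sequences.append(seq)
    return Cohort(sequences=sequences, tracks=tracks)
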