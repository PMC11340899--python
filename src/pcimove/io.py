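"""Data model and file I/O.

Domain containers (:class:`Track`, :class:`BoutSequence`, :class:`Cohort`)
plus readers/writers for the two external formats the pipeline consumes:

* a *bout table* — one row per individual with arrival time, movement-period
  start/end times and immobility/movement durations for up to 16 periods
  (columns ``ALid, Weight_g, Treat, ArrT_s, StTM1_s, EnTM1_s, I1dur_s,
  M1dur_s, ...``), as CSV or xlsx;
* a *track file* — plain CSV with columns ``time,x,y`` holding the centroid
  position (mm) of one individual at a fixed sampling interval.

Times are seconds throughout.  Manually timed bout data carry 1 s precision,
so duration-consistency checks use a ±1 s tolerance.  The arena is a
225 × 225 mm square with the drop point at its centre (112.5, 112.5); the
half-diagonal, 159 mm, is the maximum possible start-to-finish displacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("pcimove")
if not logger.handlers:
    _h = logging.StreamHandler()  # stderr
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)

ARENA_SIZE_MM = 225.0
ARENA_HALF_WIDTH_MM = 112.5
ARENA_HALF_DIAGONAL_MM = 159.0
DROP_POINT_MM = (112.5, 112.5)
OBSERVATION_WINDOW_S = 5400.0
MAX_PAIRS = 16

TREATMENTS = ("paper", "shallow_sand", "deep_sand")

_TREATMENT_ALIASES = {
    "paper": "paper",
    "2.3sand": "shallow_sand",
    "4.6sand": "deep_sand",
    "shallow_sand": "shallow_sand",
    "deep_sand": "deep_sand",
    "shallow sand": "shallow_sand",
    "deep sand": "deep_sand",
}

_TREATMENT_TO_RAW = {"paper": "Paper", "shallow_sand": "2.3sand", "deep_sand": "4.6sand"}


def normalize_treatment(label: str) -> str:
    """Map a raw substrate label (e.g. ``"2.3sand"``) to a canonical name."""
    key = str(label).strip().lower()
    try:
        return _TREATMENT_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown treatment label {label!r}; expected one of "
                         f"{sorted(set(_TREATMENT_ALIASES))}") from None


class SchemaError(ValueError):
    """Raised when an input file does not conform to the expected schema."""


@dataclass
class Track:
    """Time-ordered 2-D centroid positions for one individual."""

    individual_id: str
    treatment: str
    times: np.ndarray          # seconds, strictly increasing, constant spacing
    xy: np.ndarray             # shape (n, 2), mm
    arena_half_width: float = ARENA_HALF_WIDTH_MM
    arena_half_diagonal: float = ARENA_HALF_DIAGONAL_MM
    out_of_arena: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.treatment not in TREATMENTS:
            self.treatment = normalize_treatment(self.treatment)
        n = self.times.shape[0]
        if n < 2:
            raise ValueError("track needs at least two samples")
        if self.xy.shape != (n, 2):
            raise ValueError(f"xy shape {self.xy.shape} does not match {n} timestamps")
        diffs = np.diff(self.times)
        if np.any(diffs <= 0):
            raise ValueError("timestamps must be strictly increasing")
        dt = float(np.median(diffs))
        if np.any(np.abs(diffs - dt) > 1e-6 * dt):
            raise ValueError("irregular sampling: spacing deviates from the median "
                             f"interval {dt:g} s by more than 1e-6 relative")
        size = 2.0 * self.arena_half_width
        if np.any(self.xy < -1e-9) or np.any(self.xy > size + 1e-9):
            self.out_of_arena = True
            logger.warning("track %s: positions outside the %g mm arena (kept, flagged)",
                           self.individual_id, size)

    @property
    def dt(self) -> float:
        """Sampling interval in seconds (median spacing)."""
        return float(np.median(np.diff(self.times)))

    @property
    def t0(self) -> float:
        return float(self.times[0])

    @property
    def n_samples(self) -> int:
        return int(self.times.shape[0])

    def step_displacements(self) -> np.ndarray:
        """Euclidean displacement between consecutive samples (length n-1)."""
        return np.linalg.norm(np.diff(self.xy, axis=0), axis=1)


@dataclass
class BoutSequence:
    """Alternating immobility/movement durations for one individual.

    Durations are 1-based by sequential number within their kind; element 1
    of the immobility series is the post-contact immobility (PCI) itself.
    The number of movement periods is either equal to or one less than the
    number of immobility periods.
    """

    individual_id: str
    treatment: str
    immobility_durations: np.ndarray
    movement_durations: np.ndarray
    arrival_time: float = 0.0
    reached_wall: bool = False
    weight_g: float | None = None

    def __post_init__(self) -> None:
        self.immobility_durations = np.asarray(self.immobility_durations, dtype=float)
        self.movement_durations = np.asarray(self.movement_durations, dtype=float)
        if self.treatment not in TREATMENTS:
            self.treatment = normalize_treatment(self.treatment)
        kI, kM = self.n_immobility, self.n_movement
        if kI < 1:
            raise ValueError("at least one immobility period (the PCI) is required")
        if kM not in (kI - 1, kI):
            raise ValueError(f"movement count {kM} must be {kI - 1} or {kI} "
                             f"for {kI} immobility periods")
        if kI > MAX_PAIRS or kM > MAX_PAIRS:
            raise ValueError(f"at most {MAX_PAIRS} periods of each kind")
        if np.any(self.immobility_durations <= 0) or np.any(self.movement_durations <= 0):
            raise ValueError("durations must be positive")
        total = float(self.immobility_durations.sum() + self.movement_durations.sum())
        if total > OBSERVATION_WINDOW_S + 1e-6:
            raise ValueError(f"total bout time {total:.1f} s exceeds the "
                             f"{OBSERVATION_WINDOW_S:.0f} s observation window")

    @property
    def n_immobility(self) -> int:
        return int(self.immobility_durations.shape[0])

    @property
    def n_movement(self) -> int:
        return int(self.movement_durations.shape[0])

    @property
    def pci(self) -> float:
        """Duration of the post-contact immobility (first immobility bout)."""
        return float(self.immobility_durations[0])


@dataclass
class Cohort:
    """A set of individuals: bout sequences and/or tracks, with weights."""

    sequences: list[BoutSequence] = field(default_factory=list)
    tracks: list[Track] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for s in self.sequences:
            key = (s.treatment, s.individual_id)
            if key in seen:
                raise ValueError(f"duplicate individual {s.individual_id!r} "
                                 f"in treatment {s.treatment!r}")
            seen.add(key)
            if s.weight_g is not None and s.weight_g <= 0:
                raise ValueError("weight must be positive")

    def __len__(self) -> int:
        return len(self.sequences) if self.sequences else len(self.tracks)

    def subset(self, treatment: str) -> "Cohort":
        t = normalize_treatment(treatment)
        return Cohort(
            sequences=[s for s in self.sequences if s.treatment == t],
            tracks=[tr for tr in self.tracks if tr.treatment == t],
        )

    def durations(self, kind: str, treatment: str | None = None) -> np.ndarray:
        """Pooled durations of one kind, optionally restricted to a treatment."""
        if kind not in ("immobility", "movement"):
            raise ValueError("kind must be 'immobility' or 'movement'")
        seqs = self.sequences
        if treatment is not None:
            t = normalize_treatment(treatment)
            seqs = [s for s in seqs if s.treatment == t]
        attr = f"{kind}_durations"
        if not seqs:
            return np.empty(0)
        return np.concatenate([getattr(s, attr) for s in seqs])

    def long_table(self) -> pd.DataFrame:
        """Long-format bout table: one row per bout.

        Columns: individual, treatment, kind, seq (1-based sequential number
        within kind), duration_s.
        """
        rows = []
        for s in self.sequences:
            for kind in ("immobility", "movement"):
                for k, d in enumerate(getattr(s, f"{kind}_durations"), start=1):
                    rows.append((s.individual_id, s.treatment, kind, k, float(d)))
        return pd.DataFrame(rows, columns=["individual", "treatment", "kind",
                                           "seq", "duration_s"])


# ---------------------------------------------------------------------------
# bout tables

def _bout_table_columns() -> list[str]:
    cols = ["ALid", "Weight_g", "Treat", "ArrT_s"]
    for k in range(1, MAX_PAIRS + 1):
        cols += [f"I{k}dur_s", f"StTM{k}_s", f"EnTM{k}_s", f"M{k}dur_s"]
    return cols


def read_bout_table(path: str | Path, duration_tolerance_s: float = 1.0) -> Cohort:
    """Read a bout table (CSV or xlsx) into a :class:`Cohort`.

    Durations are recomputed from the movement start/end times wherever both
    are present and checked against the stored duration columns; any
    discrepancy beyond ``duration_tolerance_s`` raises :class:`SchemaError`
    naming the offending cells.  Rows with non-positive durations are
    rejected with a logged warning.  Missing later periods simply yield
    shorter sequences.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    required = ["ALid", "Weight_g", "Treat", "ArrT_s", "StTM1_s", "EnTM1_s",
                "I1dur_s", "M1dur_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"bout table {path.name} is missing column(s): "
                          + ", ".join(missing))

    discrepancies: list[str] = []
    sequences: list[BoutSequence] = []
    for idx, row in df.iterrows():
        alid = str(row["ALid"])
        arr = float(row["ArrT_s"])
        imm, mov = [], []
        prev_end = arr
        for k in range(1, MAX_PAIRS + 1):
            st = row.get(f"StTM{k}_s")
            en = row.get(f"EnTM{k}_s")
            idur = row.get(f"I{k}dur_s")
            mdur = row.get(f"M{k}dur_s")
            has_st, has_en = pd.notna(st), pd.notna(en)
            if not has_st and pd.isna(idur):
                break
            # immobility k runs from the previous movement's end (or arrival)
            # to this movement's start
            if has_st and pd.notna(idur):
                recomputed = float(st) - prev_end
                if abs(recomputed - float(idur)) > duration_tolerance_s:
                    discrepancies.append(
                        f"row {idx} ({alid}): I{k}dur_s={float(idur):g} but "
                        f"StTM{k}_s - previous end = {recomputed:g}")
            imm.append(float(idur) if pd.notna(idur) else float(st) - prev_end)
            if not has_st and not has_en and pd.isna(mdur):
                break
            if has_st and has_en and pd.notna(mdur):
                recomputed = float(en) - float(st)
                if abs(recomputed - float(mdur)) > duration_tolerance_s:
                    discrepancies.append(
                        f"row {idx} ({alid}): M{k}dur_s={float(mdur):g} but "
                        f"EnTM{k}_s - StTM{k}_s = {recomputed:g}")
            if pd.notna(mdur):
                mov.append(float(mdur))
            elif has_st and has_en:
                mov.append(float(en) - float(st))
            else:
                break
            if has_en:
                prev_end = float(en)
        if discrepancies:
            continue
        try:
            sequences.append(BoutSequence(
                individual_id=alid,
                treatment=normalize_treatment(row["Treat"]),
                immobility_durations=np.array(imm),
                movement_durations=np.array(mov),
                arrival_time=arr,
                weight_g=float(row["Weight_g"]) if pd.notna(row["Weight_g"]) else None,
            ))
        except ValueError as exc:
            logger.warning("rejecting row %d (%s): %s", idx, alid, exc)
    if discrepancies:
        raise SchemaError("duration/timestamp mismatch beyond "
                          f"{duration_tolerance_s:g} s:\n  " + "\n  ".join(discrepancies))
    return Cohort(sequences=sequences)


def write_bout_table(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort's bout sequences as a bout table (CSV or xlsx).

    Movement start/end times are reconstructed from the arrival time and the
    stored durations, so a read/write round trip preserves durations exactly.
    """
    path = Path(path)
    rows = []
    for s in cohort.sequences:
        row: dict[str, object] = {
            "ALid": s.individual_id,
            "Weight_g": s.weight_g if s.weight_g is not None else "",
            "Treat": _TREATMENT_TO_RAW[s.treatment],
            "ArrT_s": s.arrival_time,
        }
        t = s.arrival_time
        for k in range(1, s.n_immobility + 1):
            idur = float(s.immobility_durations[k - 1])
            row[f"I{k}dur_s"] = idur
            t += idur
            if k <= s.n_movement:
                mdur = float(s.movement_durations[k - 1])
                row[f"StTM{k}_s"] = t
                row[f"EnTM{k}_s"] = t + mdur
                row[f"M{k}dur_s"] = mdur
                t += mdur
        rows.append(row)
    df = pd.DataFrame(rows, columns=_bout_table_columns())
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# tracks

def read_track(path: str | Path, individual_id: str | None = None,
               treatment: str = "paper") -> Track:
    """Read a ``time,x,y`` CSV into a :class:`Track`.

    The sampling interval is inferred as the median spacing; spacing
    irregular beyond 1e-6 relative raises.  Out-of-arena coordinates are
    kept but flagged (``Track.out_of_arena``) with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("time", "x", "y") if c not in df.columns]
    if missing:
        raise SchemaError(f"track file {path.name} is missing column(s): "
                          + ", ".join(missing))
    return Track(
        individual_id=individual_id or path.stem,
        treatment=treatment,
        times=df["time"].to_numpy(float),
        xy=df[["x", "y"]].to_numpy(float),
    )


def write_track(track: Track, path: str | Path) -> None:
    """Write a track as a ``time,x,y`` CSV (full float precision)."""
    df = pd.DataFrame({"time": track.times, "x": track.xy[:, 0], "y": track.xy[:, 1]})
    df.to_csv(Path(path), index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict[str, object] = {
    "coarse_levels": 4,
    "smooth_window": 3,
    "move_threshold": "auto",
    "still_gap_s": 3.2,
    "max_pairs": MAX_PAIRS,
    "wall_margin_mm": 5.0,
    "n_bins": 14,
    "bin_t_min_s": 1.6,
    "bin_t_max_s": OBSERVATION_WINDOW_S,
    "seed": 0,
}


def load_config(path: str | Path | None = None) -> dict[str, object]:
    """Load a YAML analysis configuration, filling in defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        cfg.update(user)
    return cfg
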