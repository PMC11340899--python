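"""Log-binned dispersal analysis: MSD, MIS and segmented regression.

Dispersal from the release point is summarised by the mean squared
displacement (MSD, mm^2) and the mean instantaneous speed (MIS, mm/s) as
functions of time since the end of each individual's post-contact
immobility.  To mitigate shrinking sample sizes at late times while keeping
resolution near the start, the 90-minute observation window is divided into
14 logarithmically spaced intervals; each interval is represented by the
geometric mean of its edges.  Per interval the across-individual mean and
the upper limit of its t-based 95% confidence interval are reported.

On log-log axes the MSD of a Brownian walker is a line of slope 1
(``MSD = 4 D t`` in 2-D), so the fitted slope classifies the dispersal as
sub-diffusive (CI below 1), diffusive (CI straddling 1) or super-diffusive
(CI above 1).  A sharp change of regime is detected by comparing a
one-breakpoint segmented (broken-stick) regression against a simple line:
a Davies-type supremum score test over candidate breakpoints decides
whether a breakpoint exists, and the segmented model is estimated by
Muggeo's iterative linearisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OBSERVATION_WINDOW_S, Track

DEFAULT_N_BINS = 14
DEFAULT_T_MIN_S = 1.6  # one step at the level-4 coarse-graining


def log_time_bins(n_bins: int = DEFAULT_N_BINS, t_min: float = DEFAULT_T_MIN_S,
                  t_max: float = OBSERVATION_WINDOW_S
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Geometric bin edges and geometric-mean midpoints over the window."""
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    edges = np.geomspace(t_min, t_max, n_bins + 1)
    midpoints = np.sqrt(edges[:-1] * edges[1:])
    return edges, midpoints


@dataclass
class DispersalProfile:
    """Per-log-time-bin dispersal summary across individuals."""

    kind: str                      # "msd" (mm^2) | "mis" (mm/s)
    edges: np.ndarray
    table: pd.DataFrame            # midpoint_s, mean, upper_ci, n_individuals

    def regression_points(self, min_individuals: int = 2
                          ) -> tuple[np.ndarray, np.ndarray]:
        """Bin midpoints/means retained for regression.

        Bins with fewer than ``min_individuals`` contributors are dropped,
        as are bins whose mean is non-positive (no displacement yet, not
        representable on a log scale).
        """
        t = self.table
        ok = (t["n_individuals"] >= min_individuals) & (t["mean"] > 0)
        return t.loc[ok, "midpoint_s"].to_numpy(), t.loc[ok, "mean"].to_numpy()


def _profile(per_individual: dict[str, tuple[np.ndarray, np.ndarray]],
             kind: str, edges: np.ndarray, midpoints: np.ndarray,
             first_move_times: dict[str, float] | None) -> DispersalProfile:
    """Aggregate per-individual (tau, value) samples into a binned profile."""
    n_bins = len(midpoints)
    sums: list[list[float]] = [[] for _ in range(n_bins)]
    for ind, (tau, val) in per_individual.items():
        if tau.size == 0:
            continue
        # bins are (e_i, e_{i+1}]; a sample exactly at the first edge joins
        # bin 0; samples before the first edge or past the last are dropped
        which = np.searchsorted(edges, tau, side="left") - 1
        which[np.isclose(tau, edges[0])] = 0
        valid = (which >= 0) & (which < n_bins) & (tau >= edges[0] - 1e-12)
        for b in range(n_bins):
            if first_move_times is not None:
                fm = first_move_times.get(ind)
                if fm is None or fm > edges[b + 1]:
                    continue
            sel = valid & (which == b)
            if sel.any():
                sums[b].append(float(np.mean(val[sel])))
    rows = []
    for b in range(n_bins):
        vals = np.array(sums[b])
        n = len(vals)
        mean = float(np.mean(vals)) if n else np.nan
        if n >= 2:
            half = stats.t.ppf(0.975, n - 1) * np.std(vals, ddof=1) / np.sqrt(n)
            upper = mean + float(half)
        else:
            upper = np.nan
        rows.append((float(midpoints[b]), mean, upper, n))
    table = pd.DataFrame(rows, columns=["midpoint_s", "mean", "upper_ci",
                                        "n_individuals"])
    return DispersalProfile(kind=kind, edges=edges, table=table)


def _tau_and_ref(track: Track, pci_end: float):
    idx = int(np.searchsorted(track.times, pci_end - 1e-9))
    if idx >= track.n_samples:
        raise ValueError(f"track {track.individual_id} ends before its PCI end")
    ref = track.xy[idx]
    tau = track.times - track.times[idx]
    return tau, ref, idx


def msd_profile(tracks: list[Track], pci_ends: dict[str, float],
                n_bins: int = DEFAULT_N_BINS, t_min: float = DEFAULT_T_MIN_S,
                t_max: float = OBSERVATION_WINDOW_S,
                first_move_times: dict[str, float] | None = None
                ) -> DispersalProfile:
    """Log-binned mean squared displacement from each individual's PCI end.

    Per individual and bin: the mean over the bin's samples of the squared
    displacement from the position at PCI end (the time axis is re-zeroed
    there).  Per bin: the average over contributing individuals, with the
    upper 95% CI limit of that mean.  ``first_move_times`` (absolute
    seconds, same clock as the tracks) optionally restricts a bin's
    contributors to individuals that have moved by the bin's upper edge.
    """
    edges, midpoints = log_time_bins(n_bins, t_min, t_max)
    per_ind = {}
    fm_rel = None if first_move_times is None else {}
    for tr in tracks:
        tau, ref, idx = _tau_and_ref(tr, pci_ends[tr.individual_id])
        sq = np.sum((tr.xy - ref) ** 2, axis=1)
        per_ind[tr.individual_id] = (tau, sq)
        if fm_rel is not None and tr.individual_id in first_move_times:
            fm_rel[tr.individual_id] = (first_move_times[tr.individual_id]
                                        - tr.times[idx])
    return _profile(per_ind, "msd", edges, midpoints, fm_rel)


def mis_profile(tracks: list[Track], pci_ends: dict[str, float],
                n_bins: int = DEFAULT_N_BINS, t_min: float = DEFAULT_T_MIN_S,
                t_max: float = OBSERVATION_WINDOW_S,
                first_move_times: dict[str, float] | None = None
                ) -> DispersalProfile:
    """Log-binned mean instantaneous speed, analogous to :func:`msd_profile`.

    The instantaneous speed of a step is its displacement divided by the
    sampling interval, assigned to the step's later timestamp.
    """
    edges, midpoints = log_time_bins(n_bins, t_min, t_max)
    per_ind = {}
    fm_rel = None if first_move_times is None else {}
    for tr in tracks:
        tau, _, idx = _tau_and_ref(tr, pci_ends[tr.individual_id])
        speed = tr.step_displacements() / tr.dt
        per_ind[tr.individual_id] = (tau[1:], speed)
        if fm_rel is not None and tr.individual_id in first_move_times:
            fm_rel[tr.individual_id] = (first_move_times[tr.individual_id]
                                        - tr.times[idx])
    return _profile(per_ind, "mis", edges, midpoints, fm_rel)


# ---------------------------------------------------------------------------
# segmented regression

@dataclass
class SegmentedFit:
    """One-breakpoint piecewise-linear fit (or its simple-line fallback)."""

    is_segmented: bool
    slope1: float
    slope1_ci: tuple[float, float]
    slope2: float
    slope2_ci: tuple[float, float]
    intercept: float
    psi: float | None              # breakpoint on the x (log-time) scale
    psi_ci: tuple[float, float] | None
    breakpoint_p: float            # Davies-type test of H0: no breakpoint
    r2_adj: float
    n: int
    n_left: int = 0                # data points at or below the breakpoint
    n_right: int = 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if not self.is_segmented or self.psi is None:
            return self.intercept + self.slope1 * x
        return (self.intercept + self.slope1 * x
                + (self.slope2 - self.slope1) * np.clip(x - self.psi, 0, None))


def _ols(Xcols: list[np.ndarray], y: np.ndarray):
    X = np.column_stack(Xcols)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n, p = X.shape
    dof = n - rank
    s2 = float(resid @ resid) / dof if dof > 0 else np.nan
    XtX_inv = np.linalg.pinv(X.T @ X)
    cov = s2 * XtX_inv
    return beta, cov, resid, dof


def _r2_adj(y, resid, n_params):
    n = len(y)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def davies_test(x: np.ndarray, y: np.ndarray,
                candidates: np.ndarray | None = None) -> tuple[float, float]:
    """Supremum score test for the existence of one breakpoint.

    For every candidate breakpoint the t-statistic of the added hinge term
    ``(x - psi)+`` in the linear model is computed; the p-value for the
    supremum of |t| over candidates uses Davies' upper bound with the total
    variation of the statistic process.  Returns ``(best_candidate, p)``.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if candidates is None:
        xs = np.unique(x)
        candidates = xs[1:-1]
    zs, cands = [], []
    for psi in candidates:
        hinge = np.clip(x - psi, 0, None)
        if np.ptp(hinge) == 0:
            continue
        beta, cov, _, dof = _ols([np.ones_like(x), x, hinge], y)
        se = np.sqrt(cov[2, 2])
        if not np.isfinite(se) or se == 0 or dof < 1:
            continue
        zs.append(beta[2] / se)
        cands.append(psi)
    if not zs:
        return float(np.median(x)), 1.0
    zs = np.array(zs)
    m = float(np.max(np.abs(zs)))
    total_var = float(np.sum(np.abs(np.diff(zs))))
    p = 2.0 * (stats.norm.sf(m) + total_var * np.exp(-0.5 * m * m)
               / np.sqrt(8.0 * np.pi))
    best = float(cands[int(np.argmax(np.abs(zs)))])
    return best, float(min(1.0, p))


def segmented_fit(x: np.ndarray, y: np.ndarray, alpha: float = 0.05,
                  forced_psi: float | None = None, max_iter: int = 50,
                  tol: float = 1e-9) -> SegmentedFit:
    """Fit a one-breakpoint broken-stick model, testing whether to keep it.

    The breakpoint-existence test runs first; if its p-value is at or above
    ``alpha`` (and no ``forced_psi`` is given) the simple linear regression
    is returned with both slopes equal.  Otherwise the breakpoint is
    estimated by iterative linearisation: the model with hinge
    ``(x - psi)+`` and indicator correction term is refitted, each round
    updating ``psi`` by ``gamma / beta2``.  A ``forced_psi`` outside the
    data range degenerates to the simple regression.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 6:
        raise ValueError("need at least 6 points for a segmented fit")
    order = np.argsort(x)
    x, y = x[order], y[order]

    beta_s, cov_s, resid_s, dof_s = _ols([np.ones_like(x), x], y)
    tcrit_s = stats.t.ppf(0.975, dof_s)
    simple = SegmentedFit(
        is_segmented=False,
        slope1=float(beta_s[1]),
        slope1_ci=(float(beta_s[1] - tcrit_s * np.sqrt(cov_s[1, 1])),
                   float(beta_s[1] + tcrit_s * np.sqrt(cov_s[1, 1]))),
        slope2=float(beta_s[1]),
        slope2_ci=(float(beta_s[1] - tcrit_s * np.sqrt(cov_s[1, 1])),
                   float(beta_s[1] + tcrit_s * np.sqrt(cov_s[1, 1]))),
        intercept=float(beta_s[0]),
        psi=None, psi_ci=None, breakpoint_p=1.0,
        r2_adj=float(_r2_adj(y, resid_s, 1)), n=len(x),
        n_left=len(x), n_right=0)

    psi0, p_break = davies_test(x, y)
    simple.breakpoint_p = float(p_break)
    if forced_psi is None:
        if p_break >= alpha:
            return simple
        psi = psi0
    else:
        psi = float(forced_psi)
        if psi <= x[0] or psi >= x[-1]:
            return simple

    lo, hi = x[1], x[-2]
    psi = float(np.clip(psi, lo, hi))
    gamma_se = np.nan
    beta2 = np.nan

    def _rss(p):
        hinge = np.clip(x - p, 0, None)
        _, _, resid, _ = _ols([np.ones_like(x), x, hinge], y)
        return float(resid @ resid)

    converged = False
    best_psi, best_rss = psi, _rss(psi)
    stall = 0
    for _ in range(max_iter):
        hinge = np.clip(x - psi, 0, None)
        ind = -(x > psi).astype(float)
        beta, cov, _, dof = _ols([np.ones_like(x), x, hinge, ind], y)
        beta2, gamma = beta[2], beta[3]
        gamma_se = float(np.sqrt(cov[3, 3]))
        if abs(beta2) < 1e-12:
            raise RuntimeError(f"segmented fit degenerate at psi={psi:.4g}")
        step = gamma / beta2
        # step halving keeps the working-model update from overshooting
        rss0 = _rss(psi)
        new_psi = float(np.clip(psi + step, lo, hi))
        for _half in range(20):
            if _rss(new_psi) <= rss0 + 1e-15 or abs(new_psi - psi) < tol:
                break
            step *= 0.5
            new_psi = float(np.clip(psi + step, lo, hi))
        new_rss = _rss(new_psi)
        if new_rss < best_rss - 1e-12 * (1.0 + best_rss):
            best_psi, best_rss = new_psi, new_rss
            stall = 0
        else:
            # the update cycles around a kink of the piecewise-quadratic
            # RSS profile: the incumbent minimiser is the estimate
            stall += 1
        if abs(new_psi - psi) < tol or stall >= 3:
            converged = True
            psi = best_psi
            break
        psi = new_psi
    if not converged:
        raise RuntimeError(f"segmented fit did not converge; last psi={psi:.4g}")
    # local polish: RSS is piecewise quadratic in psi, so a bounded scalar
    # minimisation in the bracketing interval lands on the exact optimum
    from scipy.optimize import minimize_scalar
    span = (hi - lo) / max(len(x) - 3, 1)
    res = minimize_scalar(_rss, bounds=(max(lo, psi - span), min(hi, psi + span)),
                          method="bounded", options={"xatol": 1e-10})
    if res.fun <= best_rss:
        psi = float(res.x)
    # refresh the working-model pieces at the final psi for the psi SE
    hinge = np.clip(x - psi, 0, None)
    ind = -(x > psi).astype(float)
    beta_w, cov_w, _, _ = _ols([np.ones_like(x), x, hinge, ind], y)
    beta2 = beta_w[2]
    gamma_se = float(np.sqrt(cov_w[3, 3]))

    hinge = np.clip(x - psi, 0, None)
    beta, cov, resid, _ = _ols([np.ones_like(x), x, hinge], y)
    n = len(x)
    dof = n - 4  # psi counts as an estimated parameter
    tcrit = stats.t.ppf(0.975, max(dof, 1))
    s1 = float(beta[1])
    s2 = float(beta[1] + beta[2])
    se1 = float(np.sqrt(cov[1, 1]))
    se2 = float(np.sqrt(cov[1, 1] + cov[2, 2] + 2 * cov[1, 2]))
    psi_se = gamma_se / abs(beta2) if np.isfinite(gamma_se) else np.nan
    return SegmentedFit(
        is_segmented=True,
        slope1=s1, slope1_ci=(s1 - tcrit * se1, s1 + tcrit * se1),
        slope2=s2, slope2_ci=(s2 - tcrit * se2, s2 + tcrit * se2),
        intercept=float(beta[0]),
        psi=float(psi),
        psi_ci=(float(psi - tcrit * psi_se), float(psi + tcrit * psi_se)),
        breakpoint_p=float(p_break),
        r2_adj=float(_r2_adj(y, resid, 3)),
        n=n,
        n_left=int(np.sum(x <= psi)),
        n_right=int(np.sum(x > psi)))


def classify_diffusion(fit: SegmentedFit, reference: float = 1.0) -> str:
    """Diffusion regime from a log-MSD vs log-time fit.

    The designated slope is the one whose segment covers the most points
    (the whole line for a simple fit); its 95% CI against the Brownian
    reference slope 1 gives ``sub_diffusive`` (CI entirely below),
    ``diffusive`` (CI straddles) or ``super_diffusive`` (CI entirely above).
    """
    if fit.is_segmented and fit.n_right > fit.n_left:
        lo, hi = fit.slope2_ci
    else:
        lo, hi = fit.slope1_ci
    if hi < reference:
        return "sub_diffusive"
    if lo > reference:
        return "super_diffusive"
    return "diffusive"


# ---------------------------------------------------------------------------
# start-to-finish displacement

def start_finish_displacement(track_or_positions) -> float:
    """Euclidean distance between the first and last positions (mm)."""
    if isinstance(track_or_positions, Track):
        a, b = track_or_positions.xy[0], track_or_positions.xy[-1]
    else:
        a, b = np.asarray(track_or_positions[0], float), np.asarray(
            track_or_positions[1], float)
    return float(np.linalg.norm(b - a))


def displacement_table(tracks: list[Track]) -> pd.DataFrame:
    """Per-individual start-to-finish displacements, ready for modelling.

    Flags displacements at the arena's half-diagonal ceiling (the maximum
    possible from a centre drop).
    """
    rows = []
    for tr in tracks:
        d = start_finish_displacement(tr)
        rows.append((tr.individual_id, tr.treatment, d,
                     d >= tr.arena_half_diagonal - 1e-9))
    return pd.DataFrame(rows, columns=["individual", "treatment",
                                       "displacement_mm", "at_ceiling"])
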