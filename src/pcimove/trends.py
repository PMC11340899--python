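"""Duration-trend and displacement mixed models.

The central regression of the pipeline: log10 bout duration against log10
sequential event number, with a separate intercept and slope per substrate
treatment and a random individual effect to reflect the repeated design
(every sand-tested animal was also tested on paper).  On a log-log scale a
straight line corresponds to a power-law change of duration with event
number, so the fitted slope is the power-law exponent of the disruption
decay (negative for shrinking immobility bouts, positive for growing
movement bouts).

Model fitting delegates to :class:`statsmodels` ``MixedLM`` (REML).  Two
pieces of inference that statsmodels does not provide are implemented here:

* Satterthwaite denominator degrees of freedom for per-treatment slope
  t-tests, via numerical differentiation of the REML log-likelihood in the
  variance parameters;
* single-step max-|Z| multiplicity adjustment for the three pairwise slope
  contrasts (the joint-normal adjustment used by standard post-hoc
  machinery), with Bonferroni as a fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .io import Cohort, logger, normalize_treatment

_CONTRAST_ORDER = [("paper", "deep_sand"), ("shallow_sand", "deep_sand"),
                   ("paper", "shallow_sand")]


@dataclass
class SlopeContrast:
    """One pairwise difference between treatment slopes (or means)."""

    pair: tuple[str, str]
    difference: float
    se: float
    z: float
    p_adj: float

    def reversed(self) -> "SlopeContrast":
        return SlopeContrast((self.pair[1], self.pair[0]), -self.difference,
                             self.se, -self.z, self.p_adj)


@dataclass
class TrendFit:
    """Fitted log-log duration trend with per-treatment slopes."""

    response: str
    treatments: list[str]
    slopes: dict[str, float]
    intercepts: dict[str, float]
    slope_se: dict[str, float]
    slope_t: dict[str, float]
    slope_dof: dict[str, float]
    slope_p: dict[str, float]
    cov_slopes: np.ndarray            # covariance of the slope estimates
    random_structure: str             # "intercept_only" | "intercept_and_slope"
    log_likelihood: float
    n_obs: int
    individual_lines: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict)         # (treatment, individual) -> (a, b)
    converged: bool = True

    def predict(self, treatment: str, seq: np.ndarray) -> np.ndarray:
        """Fixed-effect predicted log10 duration at sequential numbers."""
        t = normalize_treatment(treatment)
        return self.intercepts[t] + self.slopes[t] * np.log10(np.asarray(seq, float))


# ---------------------------------------------------------------------------
# REML machinery for Satterthwaite degrees of freedom

class _RemlModel:
    """Grouped mixed-model pieces for profile-REML evaluation.

    Variance parameter vector: ``[scale]`` + lower-triangle of the random
    effect covariance (1 element for a random intercept, 3 for
    intercept+slope).
    """

    def __init__(self, X_groups, Z_groups, y_groups, q):
        self.Xg, self.Zg, self.yg, self.q = X_groups, Z_groups, y_groups, q

    def _unpack(self, theta):
        s2 = theta[0]
        if self.q == 1:
            G = np.array([[theta[1]]])
        else:
            G = np.array([[theta[1], theta[2]], [theta[2], theta[3]]])
        return s2, G

    def _feasible(self, theta):
        s2, G = self._unpack(theta)
        if s2 <= 0:
            return False
        try:
            np.linalg.cholesky(G + 1e-12 * np.eye(self.q))
        except np.linalg.LinAlgError:
            return False
        return True

    def _assemble(self, theta):
        s2, G = self._unpack(theta)
        p = self.Xg[0].shape[1]
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        ytViy = 0.0
        logdetV = 0.0
        for X, Z, y in zip(self.Xg, self.Zg, self.yg):
            V = s2 * np.eye(len(y)) + Z @ G @ Z.T
            L = np.linalg.cholesky(V)
            logdetV += 2.0 * np.sum(np.log(np.diag(L)))
            ViX = np.linalg.solve(V, X)
            Viy = np.linalg.solve(V, y)
            XtViX += X.T @ ViX
            XtViy += X.T @ Viy
            ytViy += y @ Viy
        return XtViX, XtViy, ytViy, logdetV

    def reml_loglik(self, theta) -> float:
        if not self._feasible(theta):
            return -np.inf
        XtViX, XtViy, ytViy, logdetV = self._assemble(theta)
        beta = np.linalg.solve(XtViX, XtViy)
        quad = ytViy - XtViy @ beta
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        return -0.5 * (logdetV + quad + logdetX)

    def beta_cov(self, theta) -> np.ndarray:
        XtViX, _, _, _ = self._assemble(theta)
        return np.linalg.inv(XtViX)

    def satterthwaite_dof(self, theta, c) -> float:
        """Satterthwaite dof for the scalar contrast ``c' beta``."""
        c = np.asarray(c, float)
        f0 = float(c @ self.beta_cov(theta) @ c)
        k = len(theta)
        h = np.maximum(1e-4 * np.abs(theta), 1e-7)
        grad = np.zeros(k)
        for i in range(k):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h[i]
            tm[i] -= h[i]
            if not self._feasible(tm):
                tm = theta.copy()  # one-sided at a boundary
            fp = float(c @ self.beta_cov(tp) @ c)
            fm = float(c @ self.beta_cov(tm) @ c)
            grad[i] = (fp - fm) / (tp[i] - tm[i])
        H = np.zeros((k, k))
        ll0 = self.reml_loglik(theta)
        for i in range(k):
            for j in range(i, k):
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                if i == j:
                    tpp[i] += h[i]
                    tmm[i] -= h[i]
                    lpp, lmm = self.reml_loglik(tpp), self.reml_loglik(tmm)
                    if not (np.isfinite(lpp) and np.isfinite(lmm)):
                        raise FloatingPointError("boundary")
                    H[i, i] = (lpp - 2 * ll0 + lmm) / h[i] ** 2
                else:
                    tpp[i] += h[i]; tpp[j] += h[j]
                    tpm[i] += h[i]; tpm[j] -= h[j]
                    tmp[i] -= h[i]; tmp[j] += h[j]
                    tmm[i] -= h[i]; tmm[j] -= h[j]
                    vals = [self.reml_loglik(t) for t in (tpp, tpm, tmp, tmm)]
                    if not all(np.isfinite(v) for v in vals):
                        raise FloatingPointError("boundary")
                    H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (
                        4 * h[i] * h[j])
        A = np.linalg.inv(-H)
        denom = float(grad @ A @ grad)
        if denom <= 0:
            raise FloatingPointError("non-positive variance of variance")
        return 2.0 * f0 ** 2 / denom


# ---------------------------------------------------------------------------

def _long_data(cohort: Cohort, response: str) -> pd.DataFrame:
    tab = cohort.long_table()
    tab = tab[tab["kind"] == response].copy()
    if tab.empty:
        raise ValueError(f"no {response} bouts in cohort")
    tab["y"] = np.log10(tab["duration_s"])
    tab["x"] = np.log10(tab["seq"].astype(float))
    return tab


def fit_duration_trend(cohort: Cohort, response: str = "immobility",
                       random_structure: str | None = None,
                       compute_dof: bool = True) -> TrendFit:
    """Fit log10 duration ~ log10 sequential number x treatment (LMM).

    ``random_structure`` defaults to ``"intercept_and_slope"`` for
    immobility and ``"intercept_only"`` for movement (the best models by
    AIC in the motivating experiments).  A singular random-slope fit falls
    back to intercept-only with a logged warning.  ``compute_dof=False``
    skips the Satterthwaite computation (t-tests then use residual dof),
    which is useful inside simulation loops.
    """
    if response not in ("immobility", "movement"):
        raise ValueError("response must be 'immobility' or 'movement'")
    if random_structure is None:
        random_structure = ("intercept_and_slope" if response == "immobility"
                            else "intercept_only")
    if random_structure not in ("intercept_only", "intercept_and_slope"):
        raise ValueError(f"unknown random structure {random_structure!r}")
    data = _long_data(cohort, response)
    treatments = [t for t in ("paper", "shallow_sand", "deep_sand")
                  if t in set(data["treatment"])]
    for t in treatments:
        if data.loc[data["treatment"] == t, "individual"].nunique() < 2:
            raise ValueError(f"need >= 2 individuals in treatment {t!r}")

    re_formula = "~x" if random_structure == "intercept_and_slope" else "~1"
    formula = "y ~ 0 + C(treatment) + C(treatment):x"

    def _fit(rf):
        md = smf.mixedlm(formula, data, groups=data["individual"], re_formula=rf)
        last_exc = None
        for method in ("lbfgs", "powell", "nm"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    return md, md.fit(reml=True, method=method, maxiter=2000)
                except (np.linalg.LinAlgError, ValueError) as exc:
                    last_exc = exc
        raise RuntimeError(f"mixed-model fit failed: {last_exc}")

    md, res = _fit(re_formula)
    fell_back = False
    if random_structure == "intercept_and_slope":
        cov_re = np.asarray(res.cov_re)
        if (not res.converged or np.any(np.diag(cov_re) <= 1e-10)
                or np.linalg.det(cov_re) <= 1e-14):
            logger.warning("singular intercept+slope fit for %s; falling back "
                           "to a random intercept", response)
            random_structure = "intercept_only"
            re_formula = "~1"
            md, res = _fit(re_formula)
            fell_back = True

    params = res.fe_params
    names = list(params.index)

    def _name(kind, treat):
        for nm in names:
            if f"[{treat}]" in nm and (":x" in nm) == (kind == "slope"):
                return nm
        raise KeyError(f"no {kind} coefficient for {treat}")

    slope_names = {t: _name("slope", t) for t in treatments}
    int_names = {t: _name("intercept", t) for t in treatments}
    cov_fe = np.asarray(res.cov_params())[:len(names), :len(names)]
    cov_fe = pd.DataFrame(cov_fe, index=names, columns=names)
    slopes = {t: float(params[slope_names[t]]) for t in treatments}
    intercepts = {t: float(params[int_names[t]]) for t in treatments}
    slope_se = {t: float(np.sqrt(cov_fe.loc[slope_names[t], slope_names[t]]))
                for t in treatments}
    idx = [slope_names[t] for t in treatments]
    cov_slopes = cov_fe.loc[idx, idx].to_numpy()

    # Satterthwaite dof via the REML surface; residual dof as fallback
    n, p = len(data), len(names)
    resid_dof = float(n - p)
    q = 2 if random_structure == "intercept_and_slope" else 1
    reml = None
    if compute_dof:
        Xg, Zg, yg = [], [], []
        X = np.asarray(md.exog)
        y = np.asarray(md.endog)
        Z = np.asarray(md.exog_re)
        for g in np.unique(md.group_labels):
            rows = np.asarray(md.groups) == g
            Xg.append(X[rows])
            Zg.append(Z[rows])
            yg.append(y[rows])
        scale = float(res.scale)
        cov_re = np.atleast_2d(np.asarray(res.cov_re)) * 1.0
        theta = np.array([scale, cov_re[0, 0]] if q == 1 else
                         [scale, cov_re[0, 0], cov_re[1, 0], cov_re[1, 1]])
        reml = _RemlModel(Xg, Zg, yg, q)

    slope_t, slope_dof, slope_p = {}, {}, {}
    for t in treatments:
        tval = slopes[t] / slope_se[t]
        dof = resid_dof
        if reml is not None:
            c = np.zeros(p)
            c[names.index(slope_names[t])] = 1.0
            try:
                dof = float(np.clip(reml.satterthwaite_dof(theta, c), 1.0,
                                    resid_dof))
            except (FloatingPointError, np.linalg.LinAlgError) as exc:
                logger.warning("Satterthwaite dof failed for %s slope (%s); "
                               "using residual dof", t, exc)
        slope_t[t] = float(tval)
        slope_dof[t] = dof
        slope_p[t] = float(2.0 * stats.t.sf(abs(tval), dof))

    # per-individual predicted lines from the random-effect BLUPs
    lines: dict[tuple[str, str], tuple[float, float]] = {}
    re = res.random_effects
    for (ind), eff in re.items():
        eff = np.asarray(eff, float)
        b_int = float(eff[0])
        b_slope = float(eff[1]) if eff.size > 1 else 0.0
        for t in treatments:
            sub = data[(data["individual"] == ind) & (data["treatment"] == t)]
            if len(sub):
                lines[(t, str(ind))] = (intercepts[t] + b_int,
                                        slopes[t] + b_slope)

    return TrendFit(
        response=response,
        treatments=treatments,
        slopes=slopes,
        intercepts=intercepts,
        slope_se=slope_se,
        slope_t=slope_t,
        slope_dof=slope_dof,
        slope_p=slope_p,
        cov_slopes=cov_slopes,
        random_structure=random_structure,
        log_likelihood=float(res.llf),
        n_obs=n,
        individual_lines=lines,
        converged=bool(res.converged) and not fell_back,
    )


# ---------------------------------------------------------------------------
# contrasts

def _single_step_p(zs: np.ndarray, R: np.ndarray, grid_n: int = 801,
                   span: float = 8.0) -> np.ndarray:
    """Single-step max-|Z| adjusted p-values under a joint normal.

    ``p_j = P(max_k |Z_k| >= |z_j|)`` with ``Z ~ N(0, R)``.  The three
    pairwise contrasts of three slopes span a rank-2 space, so the
    probability is evaluated by quadrature over the 2-D factor of ``R``
    (general rank handled by eigen-truncation; rank 1 in closed form).
    """
    zs = np.abs(np.asarray(zs, float))
    vals, vecs = np.linalg.eigh(R)
    keep = vals > 1e-10
    B = vecs[:, keep] * np.sqrt(vals[keep])       # Z = B W, W ~ N(0, I_r)
    r = int(keep.sum())
    out = np.empty_like(zs)
    if r == 1:
        b = np.abs(B[:, 0])
        for j, u in enumerate(zs):
            m = np.min(u / b[b > 0]) if np.any(b > 0) else np.inf
            out[j] = 1.0 - (stats.norm.cdf(m) - stats.norm.cdf(-m))
        return np.clip(out, 0.0, 1.0)
    if r > 2:  # full-rank case: scipy rectangle CDF
        from scipy.stats import multivariate_normal as mvn
        for j, u in enumerate(zs):
            lo, hi = -u * np.ones(len(R)), u * np.ones(len(R))
            out[j] = 1.0 - float(mvn.cdf(hi, mean=np.zeros(len(R)), cov=R,
                                         lower_limit=lo))
        return np.clip(out, 0.0, 1.0)
    w = np.linspace(-span, span, grid_n)
    dw = w[1] - w[0]
    W1, W2 = np.meshgrid(w, w, indexing="ij")
    dens = stats.norm.pdf(W1) * stats.norm.pdf(W2) * dw * dw
    Zk = np.tensordot(B, np.stack([W1, W2]), axes=(1, 0))  # (k, n, n)
    absZ = np.abs(Zk)
    for j, u in enumerate(zs):
        inside = np.all(absZ <= u, axis=0)
        out[j] = 1.0 - float(np.sum(dens[inside]))
    return np.clip(out, 0.0, 1.0)


def contrast_slopes(fit: TrendFit, adjust: str = "single-step"
                    ) -> list[SlopeContrast]:
    """All pairwise slope differences with multiplicity-adjusted p-values.

    ``adjust``: ``"single-step"`` (joint-normal max-|Z|), ``"bonferroni"``,
    or ``"none"``.  The difference for pair (A, B) is slope(A) - slope(B);
    reversing a pair flips the sign of the difference and the statistic but
    not the p-value.
    """
    treats = fit.treatments
    if len(treats) < 2:
        return []
    pairs = [(a, b) for (a, b) in _CONTRAST_ORDER if a in treats and b in treats]
    if not pairs:
        pairs = [(a, b) for i, a in enumerate(treats) for b in treats[i + 1:]]
    k = len(treats)
    L = np.zeros((len(pairs), k))
    for j, (a, b) in enumerate(pairs):
        L[j, treats.index(a)] = 1.0
        L[j, treats.index(b)] = -1.0
    slopes = np.array([fit.slopes[t] for t in treats])
    diffs = L @ slopes
    cov = L @ fit.cov_slopes @ L.T
    ses = np.sqrt(np.diag(cov))
    zs = diffs / ses
    if adjust == "single-step":
        d = np.sqrt(np.diag(cov))
        R = cov / np.outer(d, d)
        ps = _single_step_p(zs, R)
    elif adjust == "bonferroni":
        ps = np.minimum(1.0, len(pairs) * 2.0 * stats.norm.sf(np.abs(zs)))
    elif adjust == "none":
        ps = 2.0 * stats.norm.sf(np.abs(zs))
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return [SlopeContrast(pair, float(d), float(s), float(z), float(p))
            for pair, d, s, z, p in zip(pairs, diffs, ses, zs, ps)]


# ---------------------------------------------------------------------------
# start-to-finish displacement model

@dataclass
class DisplacementFit:
    """Treatment comparison of log10 start-to-finish displacement."""

    means_log10: dict[str, float]
    medians_mm: dict[str, float]
    contrasts: list[SlopeContrast]
    n: dict[str, int]
    log_likelihood: float


def fit_displacement_model(displacements: pd.DataFrame,
                           floor_mm: float = 0.1,
                           adjust: str = "single-step") -> DisplacementFit:
    """Mixed model of log10 displacement by treatment with random individual.

    ``displacements`` needs columns ``individual``, ``treatment``,
    ``displacement_mm`` (one row per individual per treatment).  Zero
    displacements are floored at the 0.1 mm measurement resolution before
    the log transform (logged).  Reports per-treatment model means and raw
    medians plus pairwise post-hoc contrasts.
    """
    df = displacements.copy()
    df["treatment"] = df["treatment"].map(normalize_treatment)
    nzero = int((df["displacement_mm"] < floor_mm).sum())
    if nzero:
        logger.warning("flooring %d displacement(s) at %.1f mm before log",
                       nzero, floor_mm)
    df["y"] = np.log10(df["displacement_mm"].clip(lower=floor_mm))
    treats = [t for t in ("paper", "shallow_sand", "deep_sand")
              if t in set(df["treatment"])]
    md = smf.mixedlm("y ~ 0 + C(treatment)", df, groups=df["individual"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = md.fit(reml=True)
    params = res.fe_params
    names = list(params.index)
    name_of = {t: next(nm for nm in names if f"[{t}]" in nm) for t in treats}
    cov_fe = pd.DataFrame(np.asarray(res.cov_params())[:len(names), :len(names)],
                          index=names, columns=names)
    means = {t: float(params[name_of[t]]) for t in treats}
    idx = [name_of[t] for t in treats]
    cov_means = cov_fe.loc[idx, idx].to_numpy()
    shim = TrendFit(
        response="displacement", treatments=treats, slopes=means,
        intercepts={t: 0.0 for t in treats},
        slope_se={t: float(np.sqrt(cov_means[i, i])) for i, t in enumerate(treats)},
        slope_t={}, slope_dof={}, slope_p={}, cov_slopes=cov_means,
        random_structure="intercept_only", log_likelihood=float(res.llf),
        n_obs=len(df))
    contrasts = contrast_slopes(shim, adjust=adjust)
    medians = {t: float(df.loc[df["treatment"] == t, "displacement_mm"].median())
               for t in treats}
    ns = {t: int((df["treatment"] == t).sum()) for t in treats}
    return DisplacementFit(means_log10=means, medians_mm=medians,
                           contrasts=contrasts, n=ns,
                           log_likelihood=float(res.llf))
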