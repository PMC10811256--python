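"""Client-level dependent variables derived from longitudinal records.

Five targets feed the stage-2 prediction models:

* ``outcome_slope`` — each client's conditional (shrunken) time slope of
  the symptom series over the six outcome timepoints; negative = improvement.
* ``alliance_between_client`` / ``alliance_between_therapist`` — per-client
  mean alliance across the four rated sessions (trait-like level).
* ``alliance_within_client`` / ``alliance_within_therapist`` — conditional
  time slopes of the alliance series (state-like change).

Slopes come from one jointly fitted growth model per series: value ~ time
with a client-specific random intercept and random slope (diagonal
covariance, time centered internally so the two decouple on balanced data),
estimated by maximum likelihood.  Conditional slopes are the fixed slope
plus each client's BLUP deviation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .study_data import (TIMEPOINTS, WAI_TIMEPOINTS, DegenerateVariableError,
                         DyadDataset, ScalingStats)

logger = logging.getLogger(__name__)

TARGET_COLUMNS = ("outcome_slope", "alliance_between_client",
                  "alliance_between_therapist", "alliance_within_client",
                  "alliance_within_therapist")


@dataclass
class TrajectorySpec:
    """Which series to model and how to code time."""

    variable: str
    timepoints: tuple[str, ...]
    time_coding: dict[str, float]

    def __post_init__(self) -> None:
        codes = [self.time_coding[tp] for tp in self.timepoints]
        if len(set(codes)) < 2:
            raise ValueError("time coding needs >= 2 distinct values")
        if any(b <= a for a, b in itertools.pairwise(codes)):
            raise ValueError("time coding must be strictly increasing in "
                             "timepoint order")


def oq_spec(week_coding: bool = False) -> TrajectorySpec:
    """Outcome series over all six timepoints (index coding by default)."""
    if week_coding:
        coding = {"pre": 0.0, "s1": 1.0, "s3": 3.0, "s5": 5.0, "s7": 7.0,
                  "post": 8.0}
    else:
        coding = {tp: float(i) for i, tp in enumerate(TIMEPOINTS)}
    return TrajectorySpec("oq_total", TIMEPOINTS, coding)


def wai_spec(rater: str, week_coding: bool = False) -> TrajectorySpec:
    if rater not in ("client", "therapist"):
        raise ValueError("rater must be 'client' or 'therapist'")
    if week_coding:
        coding = {"s1": 1.0, "s3": 3.0, "s5": 5.0, "s7": 7.0}
    else:
        coding = {tp: float(i) for i, tp in enumerate(WAI_TIMEPOINTS)}
    return TrajectorySpec(f"wai_{rater}", WAI_TIMEPOINTS, coding)


def oq_prepost_spec() -> TrajectorySpec:
    """Two-point alternative: slope from pre and post only."""
    return TrajectorySpec("oq_total", ("pre", "post"),
                          {"pre": 0.0, "post": 5.0})


# ----------------------------------------------------------------------
# growth model: value ~ time, random intercept + random slope per client
# ----------------------------------------------------------------------

@dataclass
class GrowthFit:
    beta0: float
    beta1: float
    tau_intercept: float
    tau_slope: float
    sigma2: float
    loglik: float
    converged: bool
    slopes: pd.Series          # conditional slope per client
    intercepts: pd.Series      # conditional intercept (at time 0)
    excluded: list = field(default_factory=list)


class _GrowthData:
    """Long data grouped by observed-time pattern for batched likelihood."""

    def __init__(self, long: pd.DataFrame, t_center: float):
        self.patterns = []  # (t array, tc array, Y matrix(k x m), client ids)
        self.N = 0
        for _key, sub in long.groupby("_pattern", sort=True):
            piv = sub.pivot(index="client_id", columns="time", values="value")
            piv = piv.sort_index(axis=1)
            t = piv.columns.to_numpy(dtype=float)
            Y = piv.to_numpy(dtype=float)
            self.patterns.append((t, t - t_center, Y, list(piv.index)))
            self.N += Y.size

    def nll(self, u: np.ndarray) -> float:
        return -self.profile(u)[3]

    def profile(self, u: np.ndarray):
        """Profiled likelihood at log-ratios u = (log r0, log r1).

        r0 = tau_intercept/sigma2, r1 = tau_slope/sigma2.  Returns
        (beta, A, sigma2, loglik, extras-per-pattern).
        """
        r0, r1 = np.exp(np.clip(u, -30.0, 30.0))
        A = np.zeros((2, 2))
        b = np.zeros(2)
        logdet = 0.0
        cache = []
        for t, tc, Y, _ in self.patterns:
            m = t.size
            W = np.eye(m) + r0 + r1 * np.outer(tc, tc)
            sign, ld = np.linalg.slogdet(W)
            if sign <= 0:
                return None, None, None, -np.inf, None
            Winv = np.linalg.inv(W)
            Xp = np.column_stack([np.ones(m), t])
            XtWi = Xp.T @ Winv
            k = Y.shape[0]
            A += k * (XtWi @ Xp)
            b += XtWi @ Y.sum(axis=0)
            logdet += k * ld
            cache.append((Xp, Winv, tc))
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return None, None, None, -np.inf, None
        rss_w = 0.0
        for (t, tc, Y, _), (Xp, Winv, _) in zip(self.patterns, cache):
            E = Y - Xp @ beta
            rss_w += float(np.einsum("ij,jk,ik->", E, Winv, E))
        sigma2 = max(rss_w / self.N, 1e-300)
        ll = -0.5 * (self.N * math.log(2.0 * math.pi * sigma2) + logdet + self.N)
        return beta, A, sigma2, ll, cache


def fit_growth(long: pd.DataFrame, min_points: int = 2) -> GrowthFit:
    """ML fit of the random-intercept-and-slope growth model.

    ``long`` needs columns client_id, time, value (value non-missing).
    Clients with fewer than ``min_points`` observations are excluded and
    reported in ``GrowthFit.excluded``.
    """
    long = long.dropna(subset=["value"]).copy()
    counts = long.groupby("client_id").size()
    excluded = sorted(counts.index[counts < min_points])
    if excluded:
        logger.warning("growth model: excluding %d client(s) with < %d "
                       "timepoints: %s", len(excluded), min_points, excluded)
        long = long[~long["client_id"].isin(excluded)]
    if long.empty:
        raise ValueError("no clients with enough observations")

    t_center = float(long["time"].mean())
    long["_pattern"] = long.groupby("client_id")["time"].transform(
        lambda s: ",".join(f"{v:g}" for v in sorted(s)))

    # per-client OLS (also the degenerate-noise fast path)
    ols = {}
    rss_tot = 0.0
    scale = float(np.var(long["value"])) + 1.0
    for cid, sub in long.groupby("client_id"):
        t = sub["time"].to_numpy(dtype=float)
        v = sub["value"].to_numpy(dtype=float)
        if np.ptp(t) == 0:
            ols[cid] = (float(v.mean()), 0.0, 0.0)
            continue
        sl, ic = np.polyfit(t, v, 1)
        resid = v - (ic + sl * t)
        ols[cid] = (float(ic), float(sl), float(resid @ resid))
        rss_tot += float(resid @ resid)

    if rss_tot <= 1e-12 * scale:
        # exactly linear per client: conditional = per-client OLS
        ids = sorted(ols)
        slopes = pd.Series({c: ols[c][1] for c in ids}, name="slope")
        intercepts = pd.Series({c: ols[c][0] for c in ids}, name="intercept")
        return GrowthFit(beta0=float(intercepts.mean()),
                         beta1=float(slopes.mean()),
                         tau_intercept=float(np.var(intercepts)),
                         tau_slope=float(np.var(slopes)),
                         sigma2=0.0, loglik=np.inf, converged=True,
                         slopes=slopes, intercepts=intercepts,
                         excluded=excluded)

    data = _GrowthData(long, t_center)
    starts = [np.array(s) for s in
              ((-1.0, -1.0), (0.0, -2.0), (-2.0, 0.0), (1.0, -1.0),
               (-20.0, -20.0))]
    best = None
    for s in starts:
        res = optimize.minimize(data.nll, s, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9,
                                         "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"growth model did not converge: {best}")

    beta, A, sigma2, ll, cache = data.profile(best.x)
    r0, r1 = np.exp(np.clip(best.x, -30.0, 30.0))
    # treat vanishing ratios as boundary zeros
    if r0 < 1e-8:
        r0 = 0.0
    if r1 < 1e-8:
        r1 = 0.0
    tau0, tau1 = r0 * sigma2, r1 * sigma2

    slopes = {}
    intercepts = {}
    for (t, tc, Y, ids), (Xp, Winv, _) in zip(data.patterns, cache):
        E = Y - Xp @ beta  # k x m residual block
        Zt = np.column_stack([np.ones(t.size), tc])  # random-effect design
        proj = np.diag([r0, r1]) @ Zt.T @ Winv  # 2 x m
        B = E @ proj.T  # k x 2 BLUPs
        for row, cid in zip(B, ids):
            b0, b1 = float(row[0]), float(row[1])
            slopes[cid] = beta[1] + b1
            intercepts[cid] = beta[0] + b0 - b1 * t_center
    ids = sorted(slopes)
    return GrowthFit(beta0=float(beta[0]), beta1=float(beta[1]),
                     tau_intercept=float(tau0), tau_slope=float(tau1),
                     sigma2=float(sigma2), loglik=float(ll), converged=True,
                     slopes=pd.Series({c: slopes[c] for c in ids}),
                     intercepts=pd.Series({c: intercepts[c] for c in ids}),
                     excluded=excluded)


# ----------------------------------------------------------------------
# target operations
# ----------------------------------------------------------------------

def _long_series(dataset: DyadDataset, spec: TrajectorySpec) -> pd.DataFrame:
    rows = dataset.sessions[dataset.sessions["timepoint"].isin(spec.timepoints)]
    out = pd.DataFrame({
        "client_id": rows["client_id"],
        "time": rows["timepoint"].map(spec.time_coding).astype(float),
        "value": pd.to_numeric(rows[spec.variable], errors="coerce"),
    })
    return out


def outcome_slope(dataset: DyadDataset,
                  spec: TrajectorySpec | None = None) -> tuple[pd.Series, GrowthFit]:
    """Conditional symptom-change slope per client (negative = improvement)."""
    spec = spec or oq_spec()
    fit = fit_growth(_long_series(dataset, spec))
    return fit.slopes.rename("outcome_slope"), fit


def between_alliance(dataset: DyadDataset, rater: str) -> pd.Series:
    """Per-client mean alliance over available rated sessions."""
    if rater not in ("client", "therapist"):
        raise ValueError("rater must be 'client' or 'therapist'")
    col = f"wai_{rater}"
    rows = dataset.sessions[dataset.sessions["timepoint"].isin(WAI_TIMEPOINTS)]
    means = rows.groupby("client_id")[col].mean()
    all_missing = sorted(set(dataset.clients["client_id"]) -
                         set(means.dropna().index))
    if all_missing:
        logger.warning("between_alliance(%s): excluding client(s) with no "
                       "rated session: %s", rater, all_missing)
    return means.dropna().rename(f"alliance_between_{rater}")


def within_alliance_slope(dataset: DyadDataset, rater: str,
                          spec: TrajectorySpec | None = None,
                          ) -> tuple[pd.Series, GrowthFit]:
    """Conditional alliance-change slope per client (positive = strengthening)."""
    spec = spec or wai_spec(rater)
    fit = fit_growth(_long_series(dataset, spec))
    return fit.slopes.rename(f"alliance_within_{rater}"), fit


def standardize_targets(targets: pd.DataFrame,
                        columns: tuple[str, ...] = TARGET_COLUMNS,
                        ) -> tuple[pd.DataFrame, ScalingStats]:
    """Z-score each derived DV across included clients (sample sd)."""
    out = targets.copy()
    stats = ScalingStats()
    for col in columns:
        if col not in out.columns:
            continue
        x = out[col].astype(float)
        m = float(x.mean())
        s = float(x.std(ddof=1))
        if not np.isfinite(s) or s <= 0:
            raise DegenerateVariableError(
                f"target {col!r} has zero variance; cannot standardize")
        out[col] = (x - m) / s
        stats.stats[col] = (m, s)
    return out, stats


def derive_targets(dataset: DyadDataset, standardize: bool = True,
                   week_coding: bool = False, prepost_only: bool = False,
                   ) -> tuple[pd.DataFrame, dict]:
    """Compute all five DVs; returns (one row per client, derivation log)."""
    o_spec = oq_prepost_spec() if prepost_only else oq_spec(week_coding)
    slopes, oq_fit = outcome_slope(dataset, o_spec)
    parts = [slopes,
             between_alliance(dataset, "client"),
             between_alliance(dataset, "therapist")]
    growth_log = {"outcome": oq_fit}
    for rater in ("client", "therapist"):
        s, fit = within_alliance_slope(dataset, rater, wai_spec(rater, week_coding))
        parts.append(s)
        growth_log[f"within_{rater}"] = fit
    targets = pd.concat(parts, axis=1)
    targets.index.name = "client_id"
    targets["included"] = targets[list(TARGET_COLUMNS)].notna().all(axis=1)

    log: dict = {
        "standardized": standardize,
        "week_coding": week_coding,
        "prepost_only": prepost_only,
        "growth_fits": {
            name: {"beta0": f.beta0, "beta1": f.beta1,
                   "tau_intercept": f.tau_intercept,
                   "tau_slope": f.tau_slope, "sigma2": f.sigma2,
                   "loglik": f.loglik, "converged": f.converged,
                   "excluded": [str(c) for c in f.excluded]}
            for name, f in growth_log.items()},
    }
    if standardize:
        targets, stats = standardize_targets(targets)
        log["scaling"] = {k: {"mean": v[0], "sd": v[1]}
                          for k, v in stats.stats.items()}
    return targets, log
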