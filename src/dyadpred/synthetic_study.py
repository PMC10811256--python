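"""Synthetic dyadic-study generator with known ground truth.

Emulates the default study design — 23 therapists, two clients each, seven
weekly sessions, alliance rated at sessions 1/3/5/7 by client and therapist,
symptom outcome at pre / s1 / s3 / s5 / s7 / post — while exposing every
generating quantity (true term set, coefficients, variance components,
missingness) so that each downstream stage can be tested for recovery.

All ground-truth effects are defined on standardized scales: continuous
covariates enter terms as (x − mean)/sd and binary covariates as ±0.5,
regardless of how the covariate is presented in the emitted tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .study_data import (CLIENT_PREDICTORS, THERAPIST_PREDICTORS, TIMEPOINTS,
                         WAI_TIMEPOINTS, DyadDataset)
from .terms import ModelTerm

Effect = tuple[ModelTerm, float]

#: session-index time codes used by the generator
OQ_TIME = {tp: float(i) for i, tp in enumerate(TIMEPOINTS)}
WAI_TIME = {tp: float(i) for i, tp in enumerate(WAI_TIMEPOINTS)}


class ConfigError(ValueError):
    """Invalid synthetic configuration; message lists offending fields."""


@dataclass
class CovariateSpec:
    """Distribution of one baseline covariate.

    continuous → Normal(mean, sd); binary → +0.5 with probability ``p``,
    else −0.5.  ``levels`` optionally gives the (low, high) string labels
    used in the emitted table (raw-scale presentation); without labels the
    coded ±0.5 values are written directly.
    """

    kind: str  # "continuous" | "binary"
    level: str  # "client" | "therapist"
    mean: float = 0.0
    sd: float = 1.0
    p: float = 0.5
    levels: tuple[str, str] | None = None

    def validate(self, name: str, errors: list[str]) -> None:
        if self.kind not in ("continuous", "binary"):
            errors.append(f"{name}.kind={self.kind!r}")
        if self.level not in ("client", "therapist"):
            errors.append(f"{name}.level={self.level!r}")
        if self.kind == "continuous" and self.sd < 0:
            errors.append(f"{name}.sd={self.sd}")
        if self.kind == "binary" and not 0.0 <= self.p <= 1.0:
            errors.append(f"{name}.p={self.p}")


@dataclass
class TrajectoryConfig:
    """Linear latent growth for one longitudinal series.

    Each client gets ``intercept_i`` and ``slope_i`` built from the fixed
    means, optional covariate effects (on standardized covariates), an
    optional therapist-level component, and a client-level deviation; the
    observed series is ``intercept_i + slope_i * t + noise``.
    """

    intercept_mean: float = 0.0
    slope_mean: float = 0.0
    intercept_sd: float = 1.0
    slope_sd: float = 0.5
    noise_sd: float = 0.5
    intercept_therapist_sd: float = 0.0
    slope_therapist_sd: float = 0.0
    intercept_effects: tuple[Effect, ...] = ()
    slope_effects: tuple[Effect, ...] = ()

    def validate(self, name: str, errors: list[str]) -> None:
        for f in ("intercept_sd", "slope_sd", "noise_sd",
                  "intercept_therapist_sd", "slope_therapist_sd"):
            if getattr(self, f) < 0:
                errors.append(f"{name}.{f}={getattr(self, f)}")


def default_covariates(raw_scales: bool = False) -> dict[str, CovariateSpec]:
    """Covariate specs mirroring the study's baseline battery."""
    def cont(level, mean=0.0, sd=1.0):
        return CovariateSpec("continuous", level,
                             mean=mean if raw_scales else 0.0,
                             sd=sd if raw_scales else 1.0)

    def binary(level, p, levels):
        return CovariateSpec("binary", level, p=p,
                             levels=levels if raw_scales else None)

    return {
        "client_age": cont("client", 19.2, 1.1),
        "client_gender": binary("client", 0.45, ("female", "male")),
        "client_income": cont("client", 30.0, 10.0),
        "ssi_total": cont("client", 270.0, 35.0),
        "iip_total": cont("client", 130.0, 30.0),
        "oq_total_baseline": cont("client", 75.0, 20.0),
        "oq_sub_symptom": cont("client", 45.0, 12.0),
        "oq_sub_interpersonal": cont("client", 18.0, 6.0),
        "oq_sub_social_role": cont("client", 12.0, 4.0),
        "prior_treatment": binary("client", 0.3, ("no", "yes")),
        "therapist_age": cont("therapist", 30.6, 9.3),
        "therapist_gender": binary("therapist", 0.35, ("female", "male")),
        "therapist_income": cont("therapist", 25.0, 12.0),
        "fis_level": binary("therapist", 0.5, ("low", "high")),
        "training": binary("therapist", 0.48, ("untrained", "trained")),
        "orientation": binary("therapist", 0.5, ("eclectic", "focused")),
    }


def _default_alliance() -> TrajectoryConfig:
    return TrajectoryConfig(intercept_mean=5.0, slope_mean=0.2,
                            intercept_sd=0.6, slope_sd=0.15, noise_sd=0.4,
                            intercept_therapist_sd=0.3,
                            slope_therapist_sd=0.05)


@dataclass
class SyntheticConfig:
    """Full generating model for one synthetic study."""

    n_therapists: int = 23
    clients_per_therapist: int = 2
    covariates: dict[str, CovariateSpec] = field(default_factory=default_covariates)
    true_outcome_model: tuple[Effect, ...] = ()
    outcome_intercept: float = -0.5
    therapist_intercept_sd: float = 0.3
    residual_sd: float = 0.7
    oq_trajectory: TrajectoryConfig = field(default_factory=lambda: TrajectoryConfig(
        intercept_mean=75.0, slope_mean=0.0, intercept_sd=15.0, slope_sd=0.0,
        noise_sd=4.0))
    alliance_client: TrajectoryConfig = field(default_factory=_default_alliance)
    alliance_therapist: TrajectoryConfig = field(default_factory=_default_alliance)
    missing_rate_income: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        errors: list[str] = []
        if self.n_therapists < 1:
            errors.append(f"n_therapists={self.n_therapists}")
        if self.clients_per_therapist < 1:
            errors.append(f"clients_per_therapist={self.clients_per_therapist}")
        if self.therapist_intercept_sd < 0:
            errors.append(f"therapist_intercept_sd={self.therapist_intercept_sd}")
        if self.residual_sd < 0:
            errors.append(f"residual_sd={self.residual_sd}")
        if not 0.0 <= self.missing_rate_income < 1.0:
            errors.append(f"missing_rate_income={self.missing_rate_income}")
        for name, spec in self.covariates.items():
            spec.validate(f"covariates[{name}]", errors)
        self.oq_trajectory.validate("oq_trajectory", errors)
        self.alliance_client.validate("alliance_client", errors)
        self.alliance_therapist.validate("alliance_therapist", errors)
        for effects, label in ((self.true_outcome_model, "true_outcome_model"),
                               (self.oq_trajectory.slope_effects, "oq_trajectory.slope_effects"),
                               (self.oq_trajectory.intercept_effects, "oq_trajectory.intercept_effects"),
                               (self.alliance_client.slope_effects, "alliance_client.slope_effects"),
                               (self.alliance_client.intercept_effects, "alliance_client.intercept_effects"),
                               (self.alliance_therapist.slope_effects, "alliance_therapist.slope_effects"),
                               (self.alliance_therapist.intercept_effects, "alliance_therapist.intercept_effects")):
            for term, _ in effects:
                for v in term.variables:
                    if v not in self.covariates:
                        errors.append(f"{label}: undeclared covariate {v!r}")
        if errors:
            raise ConfigError("invalid SyntheticConfig: " + "; ".join(errors))


@dataclass
class GroundTruth:
    """Realized generating quantities for one dataset."""

    outcome_coefficients: dict[str, float]
    therapist_intercepts: dict[str, float]
    oq_intercepts: dict[str, float]
    oq_slopes: dict[str, float]
    alliance_client_intercepts: dict[str, float]
    alliance_client_slopes: dict[str, float]
    alliance_therapist_intercepts: dict[str, float]
    alliance_therapist_slopes: dict[str, float]
    standardized_predictors: pd.DataFrame | None = None

    def to_jsonable(self) -> dict:
        d = {k: v for k, v in asdict(self).items()
             if k != "standardized_predictors"}
        return d


# ----------------------------------------------------------------------


def evaluate_term(term: ModelTerm, frame: pd.DataFrame) -> np.ndarray:
    """Evaluate a term columnwise on a (standardized) covariate frame."""
    cols = [np.asarray(frame[v], dtype=float) for v in term.variables]
    if term.kind == "linear":
        return cols[0]
    if term.kind == "quadratic":
        return cols[0] ** 2
    return cols[0] * cols[1]


def _linear_predictor(effects: Sequence[Effect], frame: pd.DataFrame) -> np.ndarray:
    out = np.zeros(len(frame))
    for term, coef in effects:
        out = out + coef * evaluate_term(term, frame)
    return out


def _draw_covariates(rng: np.random.Generator, specs: Mapping[str, CovariateSpec],
                     level: str, n: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (standardized frame, presentation frame) for one level."""
    std = {}
    raw = {}
    for name in sorted(specs):  # sorted: stable draw order
        spec = specs[name]
        if spec.level != level:
            continue
        if spec.kind == "continuous":
            z = rng.standard_normal(n)
            std[name] = z
            raw[name] = spec.mean + spec.sd * z
        else:
            coded = np.where(rng.random(n) < spec.p, 0.5, -0.5)
            std[name] = coded
            if spec.levels is None:
                raw[name] = coded
            else:
                lo, hi = spec.levels
                raw[name] = np.where(coded > 0, hi, lo)
    idx = pd.RangeIndex(n)  # keep row count even with no covariates at a level
    return pd.DataFrame(std, index=idx), pd.DataFrame(raw, index=idx)


def generate_study(config: SyntheticConfig) -> tuple[DyadDataset, GroundTruth]:
    """Generate one full synthetic study; reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_t = config.n_therapists
    n_c = n_t * config.clients_per_therapist

    t_ids = [f"T{i + 1:03d}" for i in range(n_t)]
    c_ids = [f"C{i + 1:03d}" for i in range(n_c)]
    c_tid = [t_ids[i // config.clients_per_therapist] for i in range(n_c)]

    t_std, t_raw = _draw_covariates(rng, config.covariates, "therapist", n_t)
    c_std, c_raw = _draw_covariates(rng, config.covariates, "client", n_c)

    # client-level standardized predictor frame (therapist rows repeated)
    rep = np.repeat(np.arange(n_t), config.clients_per_therapist)
    Xstd = pd.concat([c_std.reset_index(drop=True),
                      t_std.iloc[rep].reset_index(drop=True)], axis=1)
    Xstd.index = pd.Index(c_ids, name="client_id")

    # -- latent OQ growth: slope carries the true outcome model ---------
    u_out = rng.standard_normal(n_t) * config.therapist_intercept_sd
    oq = config.oq_trajectory
    oq_slope = (config.outcome_intercept
                + _linear_predictor(config.true_outcome_model, Xstd)
                + _linear_predictor(oq.slope_effects, Xstd)
                + u_out[rep]
                + rng.standard_normal(n_c) * config.residual_sd)
    u_oq_int = rng.standard_normal(n_t) * oq.intercept_therapist_sd
    oq_int = (oq.intercept_mean
              + _linear_predictor(oq.intercept_effects, Xstd)
              + u_oq_int[rep]
              + rng.standard_normal(n_c) * oq.intercept_sd)

    def trajectory(cfg: TrajectoryConfig) -> tuple[np.ndarray, np.ndarray]:
        u_int = rng.standard_normal(n_t) * cfg.intercept_therapist_sd
        u_slo = rng.standard_normal(n_t) * cfg.slope_therapist_sd
        inter = (cfg.intercept_mean + _linear_predictor(cfg.intercept_effects, Xstd)
                 + u_int[rep] + rng.standard_normal(n_c) * cfg.intercept_sd)
        slope = (cfg.slope_mean + _linear_predictor(cfg.slope_effects, Xstd)
                 + u_slo[rep] + rng.standard_normal(n_c) * cfg.slope_sd)
        return inter, slope

    wc_int, wc_slope = trajectory(config.alliance_client)
    wt_int, wt_slope = trajectory(config.alliance_therapist)

    # -- session rows (client-major, timepoint order per TIMEPOINTS) ----
    oq_t = np.array([OQ_TIME[tp] for tp in TIMEPOINTS])
    wai_t = np.array([WAI_TIME[tp] for tp in WAI_TIMEPOINTS])
    oq_vals = (oq_int[:, None] + np.outer(oq_slope, oq_t)
               + rng.standard_normal((n_c, len(TIMEPOINTS))) * oq.noise_sd)
    wc_vals = (wc_int[:, None] + np.outer(wc_slope, wai_t)
               + rng.standard_normal((n_c, len(WAI_TIMEPOINTS)))
               * config.alliance_client.noise_sd)
    wt_vals = (wt_int[:, None] + np.outer(wt_slope, wai_t)
               + rng.standard_normal((n_c, len(WAI_TIMEPOINTS)))
               * config.alliance_therapist.noise_sd)
    wai_pos = {tp: j for j, tp in enumerate(WAI_TIMEPOINTS)}
    wc_full = np.full((n_c, len(TIMEPOINTS)), np.nan)
    wt_full = np.full((n_c, len(TIMEPOINTS)), np.nan)
    for i_tp, tp in enumerate(TIMEPOINTS):
        if tp in wai_pos:
            wc_full[:, i_tp] = wc_vals[:, wai_pos[tp]]
            wt_full[:, i_tp] = wt_vals[:, wai_pos[tp]]
    sessions = pd.DataFrame({
        "client_id": np.repeat(c_ids, len(TIMEPOINTS)),
        "timepoint": np.tile(TIMEPOINTS, n_c),
        "wai_client": wc_full.ravel(),
        "wai_therapist": wt_full.ravel(),
        "oq_total": oq_vals.ravel(),
    })

    therapists = pd.DataFrame({"therapist_id": t_ids})
    for name in ("age", "gender", "income", "fis_level", "training", "orientation"):
        src = {"age": "therapist_age", "gender": "therapist_gender",
               "income": "therapist_income"}.get(name, name)
        therapists[name] = t_raw[src].to_numpy()

    clients = pd.DataFrame({"client_id": c_ids, "therapist_id": c_tid})
    for name in ("age", "gender", "income", "ssi_total", "iip_total",
                 "oq_total_baseline", "oq_sub_symptom", "oq_sub_interpersonal",
                 "oq_sub_social_role", "prior_treatment"):
        src = {"age": "client_age", "gender": "client_gender",
               "income": "client_income"}.get(name, name)
        clients[name] = c_raw[src].to_numpy()

    dataset = DyadDataset(therapists, clients, sessions,
                          provenance={"generator": {"seed": config.seed,
                                                    "n_therapists": n_t,
                                                    "clients_per_therapist":
                                                        config.clients_per_therapist}})
    if config.missing_rate_income > 0:
        dataset = inject_missingness(dataset, "clients.income",
                                     config.missing_rate_income,
                                     seed=int(rng.integers(2 ** 31)))
    dataset.validate()

    truth = GroundTruth(
        outcome_coefficients={"(Intercept)": config.outcome_intercept,
                              **{t.name: c for t, c in config.true_outcome_model}},
        therapist_intercepts=dict(zip(t_ids, map(float, u_out))),
        oq_intercepts=dict(zip(c_ids, map(float, oq_int))),
        oq_slopes=dict(zip(c_ids, map(float, oq_slope))),
        alliance_client_intercepts=dict(zip(c_ids, map(float, wc_int))),
        alliance_client_slopes=dict(zip(c_ids, map(float, wc_slope))),
        alliance_therapist_intercepts=dict(zip(c_ids, map(float, wt_int))),
        alliance_therapist_slopes=dict(zip(c_ids, map(float, wt_slope))),
        standardized_predictors=Xstd,
    )
    return dataset, truth


def generate_prediction_frame(true_model: Sequence[Effect],
                              intercept: float = 0.0,
                              n_therapists: int = 100,
                              clients_per_therapist: int = 2,
                              covariates: Mapping[str, CovariateSpec] | None = None,
                              therapist_intercept_sd: float = 0.0,
                              residual_sd: float = 1.0,
                              outcome: str = "y",
                              seed: int = 0,
                              ) -> tuple[pd.DataFrame, dict]:
    """Generate a client-level frame (predictors + outcome + therapist_id).

    A lightweight companion to :func:`generate_study` for testing the
    stage-2 prediction machinery directly: the outcome is drawn as
    ``intercept + Σ coef·term(X) + u_therapist + ε`` with standardized
    covariates, skipping the longitudinal layer.
    """
    if covariates is None:
        covariates = default_covariates()
    rng = np.random.default_rng(seed)
    n_c = n_therapists * clients_per_therapist
    rep = np.repeat(np.arange(n_therapists), clients_per_therapist)

    t_std, _ = _draw_covariates(rng, covariates, "therapist", n_therapists)
    c_std, _ = _draw_covariates(rng, covariates, "client", n_c)
    X = pd.concat([c_std.reset_index(drop=True),
                   t_std.iloc[rep].reset_index(drop=True)], axis=1)

    u = rng.standard_normal(n_therapists) * therapist_intercept_sd
    y = (intercept + _linear_predictor(true_model, X) + u[rep]
         + rng.standard_normal(n_c) * residual_sd)

    frame = X.copy()
    frame.insert(0, "therapist_id", [f"T{i + 1:03d}" for i in rep])
    frame.insert(0, "client_id", [f"C{i + 1:03d}" for i in range(n_c)])
    frame[outcome] = y
    truth = {"intercept": intercept,
             "coefficients": {t.name: c for t, c in true_model},
             "therapist_intercepts": u,
             "sigma": residual_sd,
             "tau00": therapist_intercept_sd ** 2}
    return frame, truth


# ----------------------------------------------------------------------

_MISSING_ELIGIBLE = {
    "clients.income": ("clients", "income", None),
    "therapists.income": ("therapists", "income", None),
    "sessions.wai_client": ("sessions", "wai_client", WAI_TIMEPOINTS),
    "sessions.wai_therapist": ("sessions", "wai_therapist", WAI_TIMEPOINTS),
}


def inject_missingness(dataset: DyadDataset, variable: str, rate: float,
                       seed: int) -> DyadDataset:
    """Set eligible cells of ``variable`` missing independently (MCAR)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must be in [0, 1); got {rate}")
    key = variable if "." in variable else f"clients.{variable}"
    if key not in _MISSING_ELIGIBLE:
        raise ValueError(f"variable {variable!r} is not eligible for missingness; "
                         f"eligible: {sorted(_MISSING_ELIGIBLE)}")
    table_name, col, tps = _MISSING_ELIGIBLE[key]
    ds = dataset.copy()
    table = getattr(ds, table_name)
    eligible = np.ones(len(table), dtype=bool)
    if tps is not None:
        eligible = table["timepoint"].isin(tps).to_numpy()
    rng = np.random.default_rng(seed)
    hit = eligible & (rng.random(len(table)) < rate)
    table.loc[hit, col] = np.nan
    ds.provenance.setdefault("missingness", []).append(
        {"variable": key, "rate": rate, "seed": seed,
         "n_masked": int(hit.sum()),
         "rows": [int(i) for i in np.flatnonzero(hit)]})
    return ds


def covariate_moments(dataset: DyadDataset) -> pd.DataFrame:
    """Per-covariate mean/sd summary (numeric columns of both tables)."""
    if len(dataset.clients) == 0:
        raise ValueError("empty dataset: no clients")
    rows = []
    for label, df, idcols in (("therapists", dataset.therapists, {"therapist_id"}),
                              ("clients", dataset.clients,
                               {"client_id", "therapist_id"})):
        for col in df.columns:
            if col in idcols:
                continue
            x = pd.to_numeric(df[col], errors="coerce")
            if x.notna().sum() == 0:
                continue
            rows.append({"table": label, "variable": col,
                         "n": int(x.notna().sum()),
                         "mean": float(x.mean()), "sd": float(x.std(ddof=1))})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# YAML round-trip for configs
# ----------------------------------------------------------------------

def _effects_to_yaml(effects: Sequence[Effect]) -> list:
    return [[term.name, float(coef)] for term, coef in effects]


def _effects_from_yaml(items) -> tuple[Effect, ...]:
    return tuple((ModelTerm.parse(name), float(coef)) for name, coef in items or [])


def config_to_yaml(config: SyntheticConfig) -> str:
    d = asdict(config)
    d["true_outcome_model"] = _effects_to_yaml(config.true_outcome_model)
    for key, traj in (("oq_trajectory", config.oq_trajectory),
                      ("alliance_client", config.alliance_client),
                      ("alliance_therapist", config.alliance_therapist)):
        d[key]["intercept_effects"] = _effects_to_yaml(traj.intercept_effects)
        d[key]["slope_effects"] = _effects_to_yaml(traj.slope_effects)
    for name, spec in d["covariates"].items():
        if spec["levels"] is not None:
            spec["levels"] = list(spec["levels"])
    return yaml.safe_dump(d, sort_keys=True)


def config_from_yaml(text: str) -> SyntheticConfig:
    d = yaml.safe_load(text) or {}
    covs = {name: CovariateSpec(
        kind=s["kind"], level=s["level"], mean=s.get("mean", 0.0),
        sd=s.get("sd", 1.0), p=s.get("p", 0.5),
        levels=tuple(s["levels"]) if s.get("levels") else None)
        for name, s in d.get("covariates", {}).items()}

    def traj(key, default):
        s = d.get(key)
        if s is None:
            return default
        return TrajectoryConfig(
            intercept_mean=s.get("intercept_mean", 0.0),
            slope_mean=s.get("slope_mean", 0.0),
            intercept_sd=s.get("intercept_sd", 1.0),
            slope_sd=s.get("slope_sd", 0.5),
            noise_sd=s.get("noise_sd", 0.5),
            intercept_therapist_sd=s.get("intercept_therapist_sd", 0.0),
            slope_therapist_sd=s.get("slope_therapist_sd", 0.0),
            intercept_effects=_effects_from_yaml(s.get("intercept_effects")),
            slope_effects=_effects_from_yaml(s.get("slope_effects")))

    cfg = SyntheticConfig(
        n_therapists=d.get("n_therapists", 23),
        clients_per_therapist=d.get("clients_per_therapist", 2),
        covariates=covs or default_covariates(),
        true_outcome_model=_effects_from_yaml(d.get("true_outcome_model")),
        outcome_intercept=d.get("outcome_intercept", -0.5),
        therapist_intercept_sd=d.get("therapist_intercept_sd", 0.3),
        residual_sd=d.get("residual_sd", 0.7),
        oq_trajectory=traj("oq_trajectory", SyntheticConfig().oq_trajectory),
        alliance_client=traj("alliance_client", _default_alliance()),
        alliance_therapist=traj("alliance_therapist", _default_alliance()),
        missing_rate_income=d.get("missing_rate_income", 0.0),
        seed=d.get("seed", 0))
    cfg.validate()
    return cfg
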