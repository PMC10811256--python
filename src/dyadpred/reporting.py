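"""Report rendering: coefficient tables, random-effects block, effect grids.

The text table mirrors the layout used to report the five prediction
models: Predictors / Estimates / CI / df / Statistic / p, a random-effects
block (sigma^2, tau00 tid, ICC) and the marginal training/CV R^2 pair.
Rounding happens only at render time; the JSON artifact keeps every value
at full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import mixed_model_engine as engine
from .terms import ModelTerm


def _fmt(v: float, nd: int = 2) -> str:
    return f"{v:.{nd}f}"


def _fmt_p(p: float) -> str:
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


@dataclass
class ReportBundle:
    """Everything needed to reproduce one model's report."""

    outcome: str
    fit: engine.FitResult
    r2_train: float
    r2_cv: float
    diagnostics: engine.DiagnosticsReport | None = None
    search_meta: dict = field(default_factory=dict)
    label_map: dict = field(default_factory=dict)
    effect_grids: dict = field(default_factory=dict)  # term name -> DataFrame

    # ------------------------------------------------------------------
    def _label(self, column: str) -> str:
        if column == "(Intercept)":
            return "(Intercept)"
        term = ModelTerm.parse(column)
        names = [self.label_map.get(v, v) for v in term.variables]
        if term.kind == "quadratic":
            return f"{names[0]}^2"
        if term.kind == "interaction":
            return f"{names[0]} × {names[1]}"
        return names[0]

    def to_text(self) -> str:
        fit = self.fit
        rows = [("Predictors", "Estimates", "CI", "df", "Statistic", "p")]
        for i, col in enumerate(fit.columns):
            rows.append((self._label(col), _fmt(fit.beta[i]),
                         f"{_fmt(fit.ci_low[i])} to {_fmt(fit.ci_high[i])}",
                         str(fit.df), _fmt(fit.tvalues[i]),
                         _fmt_p(fit.pvalues[i])))
        widths = [max(len(r[i]) for r in rows) for i in range(6)]
        lines = ["  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip()
                 for r in rows]
        lines.append("Random effects")
        lines.append(f"sigma^2     {_fmt(fit.sigma2)}")
        lines.append(f"tau00 tid   {_fmt(fit.tau00)}")
        lines.append(f"ICC         {_fmt(fit.icc)}")
        lines.append(f"N obs {fit.n_obs}  N therapists {fit.n_groups}")
        lines.append("Marginal training/CV R^2   "
                     f"{self.r2_train:.3f}/{self.r2_cv:.3f}")
        if self.diagnostics is not None:
            d = self.diagnostics
            lines.append("Residual diagnostics: "
                         f"normality p={_fmt_p(d.normality_p)} "
                         f"({'ok' if d.normality_ok else 'VIOLATED'}); "
                         f"heteroscedasticity p={_fmt_p(d.heteroscedasticity_p)} "
                         f"({'ok' if d.homoscedasticity_ok else 'VIOLATED'})")
        return "\n".join(lines) + "\n"

    def to_jsonable(self) -> dict:
        return {
            "outcome": self.outcome,
            "fit": self.fit.to_jsonable(),
            "r2_train": float(self.r2_train),
            "r2_cv": float(self.r2_cv),
            "diagnostics": (self.diagnostics.to_jsonable()
                            if self.diagnostics else None),
            "search": dict(self.search_meta),
            "labels": dict(self.label_map),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_jsonable(), indent=2, sort_keys=True)


def render_model_report(outcome: str, fit: engine.FitResult,
                        r2_train: float, r2_cv: float,
                        diagnostics: engine.DiagnosticsReport | None = None,
                        search_meta: Mapping | None = None,
                        label_map: Mapping[str, str] | None = None,
                        binary_predictors: Sequence[str] = (),
                        grid_terms: bool = True) -> ReportBundle:
    """Assemble a ReportBundle, including grids for non-linear terms."""
    bundle = ReportBundle(outcome=outcome, fit=fit, r2_train=r2_train,
                          r2_cv=r2_cv, diagnostics=diagnostics,
                          search_meta=dict(search_meta or {}),
                          label_map=dict(label_map or {}))
    if grid_terms and fit.spec is not None:
        binary = set(binary_predictors)
        for term in fit.spec.terms:
            if term.kind == "linear":
                continue
            focal = None
            moderator_binary = False
            if term.kind == "interaction":
                a, b = term.variables
                # prefer the continuous member as the swept (focal) variable
                if a in binary and b not in binary:
                    focal, moderator_binary = b, True
                elif b in binary and a not in binary:
                    focal, moderator_binary = a, True
                else:
                    focal, moderator_binary = a, b in binary
            bundle.effect_grids[term.name] = effect_grid(
                fit, term, focal=focal, moderator_binary=moderator_binary)
    return bundle


def effect_grid(fit: engine.FitResult, term: ModelTerm,
                focal: str | None = None,
                moderator_binary: bool = False,
                span: float = 2.0, n_points: int = 41,
                n_points_interaction: int = 21) -> pd.DataFrame:
    """Fixed-effects-only predictions over a grid for one model term.

    Quadratic (and linear) terms: the focal variable sweeps ±``span`` SD
    (41 points; 2 points suffice for a linear term) with all other
    covariates at 0.  Interactions: the focal variable sweeps ±``span`` SD
    at two moderator levels (±1 SD, or the ±0.5 coded levels for a binary
    moderator), giving one curve per level.
    """
    if fit.spec is None or term not in fit.spec.terms:
        raise ValueError(f"term {term.name} not present in the fitted model")
    variables = sorted({v for t in fit.spec.terms for v in t.variables})

    def rowframe(assign: dict[str, np.ndarray], n: int) -> pd.DataFrame:
        data = {v: np.zeros(n) for v in variables}
        data.update(assign)
        return pd.DataFrame(data)

    if term.kind in ("linear", "quadratic"):
        var = term.variables[0]
        npts = 2 if term.kind == "linear" else n_points
        x = np.linspace(-span, span, npts)
        frame = rowframe({var: x}, npts)
        pred = engine.predict(fit, frame, mode="fixed_only")
        return pd.DataFrame({var: x, "predicted": pred})

    if focal is None:
        focal = term.variables[0]
    moderator = (term.variables[1] if focal == term.variables[0]
                 else term.variables[0])
    levels = (-0.5, 0.5) if moderator_binary else (-1.0, 1.0)
    x = np.linspace(-span, span, n_points_interaction)
    frames = []
    for lev in levels:
        frame = rowframe({focal: x,
                          moderator: np.full_like(x, lev)},
                         len(x))
        pred = engine.predict(fit, frame, mode="fixed_only")
        frames.append(pd.DataFrame({focal: x, moderator: lev,
                                    "predicted": pred}))
    return pd.concat(frames, ignore_index=True)
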