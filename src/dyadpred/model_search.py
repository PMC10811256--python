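"""Best-subset model search with an out-of-sample overfitting guard.

The candidate universe contains every linear effect, quadratic effects of
continuous predictors, and all unordered pairwise interactions.  Candidates
of up to ``max_terms`` terms are scored by ML AIC; the best-AIC pool is then
re-scored by leave-one-client-out cross-validation, and the winner is the
lowest-AIC candidate whose training R² does not exceed its LOOCV R² by more
than the drop threshold (0.10 absolute by default).  If no candidate passes
the guard, the candidate with the best LOOCV R² is selected and the fallback
is recorded.

Exhaustively enumerating all ≤9-term subsets of a full study-sized universe
(~10^13 models) is infeasible; when the subset count exceeds the budget the
search switches to a forward beam search grown one term at a time, and the
mode used is always recorded in the result.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from . import mixed_model_engine as engine
from .terms import ModelSpec, ModelTerm, canonical_order

logger = logging.getLogger(__name__)


class CapacityError(RuntimeError):
    """Implied enumeration count exceeds the budget."""

    def __init__(self, count: int, budget: int):
        self.count = count
        self.budget = budget
        super().__init__(f"enumeration would visit {count} models, exceeding "
                         f"budget {budget}; use stepwise search")


@dataclass(frozen=True)
class Predictor:
    name: str
    kind: str  # "continuous" | "binary"
    level: str = "client"  # "client" | "therapist"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"predictor kind {self.kind!r}")
        if self.level not in ("client", "therapist"):
            raise ValueError(f"predictor level {self.level!r}")


@dataclass
class TermUniverse:
    predictors: tuple[Predictor, ...]
    terms: tuple[ModelTerm, ...]
    exclusions: tuple[ModelTerm, ...] = ()

    @property
    def size(self) -> int:
        return len(self.terms)


def build_universe(predictors: Sequence[Predictor],
                   exclusions: Iterable[ModelTerm] = ()) -> TermUniverse:
    """All admissible terms: L linear + Q quadratic + C(L,2) interactions."""
    names = [p.name for p in predictors]
    if len(set(names)) != len(names):
        raise ValueError("duplicate predictor names")
    excl = set(exclusions)
    terms: list[ModelTerm] = [ModelTerm.linear(p.name) for p in predictors]
    terms += [ModelTerm.quadratic(p.name) for p in predictors
              if p.kind == "continuous"]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            terms.append(ModelTerm.interaction(names[i], names[j]))
    kept = canonical_order(t for t in terms if t not in excl)
    return TermUniverse(tuple(predictors), kept, tuple(canonical_order(excl)))


def satisfies_heredity(terms: frozenset[ModelTerm] | Sequence[ModelTerm],
                       heredity_interactions: bool = True,
                       heredity_quadratics: bool = False) -> bool:
    tset = set(terms)
    for t in tset:
        if t.kind == "interaction" and heredity_interactions:
            if not all(p in tset for p in t.parents()):
                return False
        if t.kind == "quadratic" and heredity_quadratics:
            if t.parents()[0] not in tset:
                return False
    return True


def count_subsets(n_terms: int, max_terms: int) -> int:
    """Number of term subsets of size <= max_terms (heredity ignored)."""
    return sum(math.comb(n_terms, k) for k in range(min(max_terms, n_terms) + 1))


def enumerate_models(universe: TermUniverse, outcome: str,
                     max_terms: int = 9,
                     budget: int = 2_000_000,
                     heredity_interactions: bool = True,
                     heredity_quadratics: bool = False,
                     ) -> Iterator[ModelSpec]:
    """Yield every admissible spec of up to ``max_terms`` terms.

    Deterministic order: by size, then lexicographic in canonical term
    positions.  Includes the intercept-only model.  Raises
    :class:`CapacityError` up front when the implied subset count (before
    heredity filtering) exceeds ``budget``.
    """
    if max_terms < 0:
        raise ValueError("max_terms must be >= 0")
    import itertools

    count = count_subsets(universe.size, max_terms)
    if count > budget:
        raise CapacityError(count, budget)
    for k in range(min(max_terms, universe.size) + 1):
        for combo in itertools.combinations(universe.terms, k):
            if satisfies_heredity(combo, heredity_interactions,
                                  heredity_quadratics):
                yield ModelSpec(outcome, combo)


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------

@dataclass
class CandidateScore:
    spec: ModelSpec
    aic: float = float("inf")
    r2_train: float = float("nan")
    r2_cv: float = float("nan")
    converged: bool = False
    admissible: bool = False
    in_cv_pool: bool = False


@dataclass
class SearchResult:
    ledger: pd.DataFrame
    scores: list[CandidateScore]
    selected: ModelSpec
    selected_fit: engine.FitResult
    selection_note: str
    search_mode: str
    seed: int
    drop_threshold: float
    drop_mode: str

    def selected_score(self) -> CandidateScore:
        key = self.selected.key()
        for s in self.scores:
            if s.spec.key() == key:
                return s
        raise LookupError("selected spec missing from ledger")


class _FoldData:
    """Raw columns + fold-wise transforms for fast repeated fitting."""

    def __init__(self, frame: pd.DataFrame, spec: ModelSpec,
                 rescale_columns: Sequence[str] | None,
                 group_col: str):
        self.spec = spec
        self.y = frame[spec.outcome].to_numpy(dtype=float)
        self.glabels = frame[group_col].to_numpy()
        self.n = len(frame)
        used = sorted({v for t in spec.terms for v in t.variables})
        self.vars = {v: frame[v].to_numpy(dtype=float) for v in used}
        self.rescale = [v for v in (rescale_columns or ()) if v in self.vars]

    def design_matrix(self, cols: dict[str, np.ndarray]) -> np.ndarray:
        out = [np.ones(self.n)]
        for t in self.spec.terms:
            vs = [cols[v] for v in t.variables]
            if t.kind == "linear":
                out.append(vs[0])
            elif t.kind == "quadratic":
                out.append(vs[0] ** 2)
            else:
                out.append(vs[0] * vs[1])
        return np.column_stack(out)

    def fold(self, holdout: int) -> tuple[engine.Design, np.ndarray]:
        """Training design with row ``holdout`` removed + the held-out X row."""
        mask = np.ones(self.n, dtype=bool)
        mask[holdout] = False
        cols = {}
        for v, x in self.vars.items():
            if v in self.rescale:
                m = float(np.mean(x[mask]))
                s = float(np.std(x[mask], ddof=1))
                if s <= 0:
                    s = 1.0
                cols[v] = (x - m) / s
            else:
                cols[v] = x
        X = self.design_matrix(cols)
        labels, codes = np.unique(self.glabels[mask], return_inverse=True)
        design = engine.Design(y=self.y[mask], X=X[mask],
                               groups=codes.astype(np.intp),
                               group_labels=tuple(labels),
                               columns=("(Intercept)",) + self.spec.term_names,
                               spec=self.spec)
        return design, X[holdout]


def loocv_r2(frame: pd.DataFrame, spec: ModelSpec,
             rescale_columns: Sequence[str] | None = None,
             group_col: str = "therapist_id",
             ) -> tuple[float, np.ndarray, bool]:
    """Leave-one-client-out CV R² for one candidate.

    Each fold refits the model on the remaining clients (optionally
    re-Z-scoring the listed predictor columns on the training clients only)
    and predicts the held-out client, using the training therapist's
    conditional intercept when available.  Returns
    ``(r2_cv, per-client predictions, all_folds_converged)`` with
    ``r2_cv = 1 − PRESS / TSS`` about the full-sample outcome mean (may be
    negative).
    """
    data = _FoldData(frame, spec, rescale_columns, group_col)
    preds = np.full(data.n, np.nan)
    ok = True
    for i in range(data.n):
        design, x_row = data.fold(i)
        try:
            fit = engine.fit_lmm(design)
        except (np.linalg.LinAlgError, engine.ConvergenceError, ValueError):
            ok = False
            continue
        pred = float(x_row @ fit.beta)
        pred += fit.group_effects.get(data.glabels[i], 0.0)
        preds[i] = pred
    if not ok or np.isnan(preds).any():
        return float("nan"), preds, False
    y = data.y
    press = float(np.sum((y - preds) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss, preds, True


class _ScoreData:
    """Precomputed arrays for scoring many candidates on the same frame."""

    def __init__(self, frame: pd.DataFrame, universe: TermUniverse,
                 outcome: str, group_col: str):
        self.outcome = outcome
        self.y = frame[outcome].to_numpy(dtype=float)
        names = sorted({v for t in universe.terms for v in t.variables})
        self.vars = {v: frame[v].to_numpy(dtype=float) for v in names}
        bad = [outcome] if np.isnan(self.y).any() else []
        bad += [v for v, x in self.vars.items() if np.isnan(x).any()]
        if bad:
            raise ValueError("missing cells in search frame "
                             f"({', '.join(bad)}); impute before searching")
        labels, codes = np.unique(frame[group_col].to_numpy(),
                                  return_inverse=True)
        self.group_labels = tuple(labels)
        self.groups = codes.astype(np.intp)
        self.n = len(frame)
        self.columns = {}
        for t in universe.terms:
            vs = [self.vars[v] for v in t.variables]
            if t.kind == "linear":
                self.columns[t] = vs[0]
            elif t.kind == "quadratic":
                self.columns[t] = vs[0] ** 2
            else:
                self.columns[t] = vs[0] * vs[1]

    def design(self, spec: ModelSpec) -> engine.Design:
        X = np.column_stack([np.ones(self.n)]
                            + [self.columns[t] for t in spec.terms])
        return engine.Design(y=self.y, X=X, groups=self.groups,
                             group_labels=self.group_labels,
                             columns=("(Intercept)",) + spec.term_names,
                             spec=spec)


def _fit_candidate(data: _ScoreData,
                   spec: ModelSpec) -> tuple[engine.FitResult | None, CandidateScore]:
    score = CandidateScore(spec)
    try:
        fit = engine.fit_lmm(data.design(spec))
    except (np.linalg.LinAlgError, engine.ConvergenceError, ValueError):
        return None, score
    score.aic = fit.aic
    score.r2_train = fit.r2_marginal
    score.converged = fit.converged
    return fit, score


def choose_candidate(pool: Sequence[CandidateScore], drop_threshold: float,
                     drop_mode: str) -> tuple[CandidateScore, str]:
    """Apply the selection rule to a scored pool.

    Prefers the lowest-AIC admissible candidate (ties: fewer terms, then
    canonical order); when nothing passes the drop rule, falls back to the
    candidate with the best LOOCV R² and says so.
    """
    admissible = [s for s in pool if s.admissible]
    if admissible:
        best = min(admissible, key=lambda s: (s.aic, s.spec.n_terms,
                                              s.spec.describe()))
        note = (f"lowest-AIC candidate passing the {drop_mode} "
                f"R² drop rule (threshold {drop_threshold:g})")
        return best, note
    with_cv = [s for s in pool if np.isfinite(s.r2_cv)]
    if not with_cv:
        raise RuntimeError("no candidate completed cross-validation")
    best = max(with_cv, key=lambda s: (s.r2_cv, -s.aic))
    note = ("fallback: no candidate passed the drop rule; selected the "
            "candidate with maximal LOOCV R²")
    return best, note


def select_model(frame: pd.DataFrame, universe: TermUniverse, outcome: str,
                 max_terms: int = 9,
                 drop_threshold: float = 0.10,
                 drop_mode: str = "absolute",
                 cv_pool_size: int | None = 50,
                 budget: int = 2_000_000,
                 beam_width: int = 100,
                 heredity_interactions: bool = True,
                 heredity_quadratics: bool = False,
                 rescale_columns: Sequence[str] | None = None,
                 group_col: str = "therapist_id",
                 seed: int = 0) -> SearchResult:
    """Score candidates by AIC + LOOCV and select per the drop rule."""
    if universe.size == 0:
        raise ValueError("empty term universe")
    if drop_mode not in ("absolute", "relative"):
        raise ValueError(f"drop_mode {drop_mode!r}")

    data = _ScoreData(frame, universe, outcome, group_col)
    scored: dict[frozenset, CandidateScore] = {}
    fits: dict[frozenset, engine.FitResult] = {}

    def score_spec(spec: ModelSpec) -> CandidateScore:
        key = spec.key()
        if key not in scored:
            fit, sc = _fit_candidate(data, spec)
            scored[key] = sc
            if fit is not None:
                fits[key] = fit
        return scored[key]

    try:
        specs = list(enumerate_models(universe, outcome, max_terms, budget,
                                      heredity_interactions,
                                      heredity_quadratics))
        search_mode = "exhaustive"
        for spec in specs:
            score_spec(spec)
    except CapacityError as err:
        search_mode = "stepwise"
        logger.info("search space too large (%d models); using forward beam "
                    "search, width %d", err.count, beam_width)
        score_spec(ModelSpec(outcome))
        beam: list[ModelSpec] = [ModelSpec(outcome)]
        for _size in range(1, max_terms + 1):
            layer: dict[frozenset, ModelSpec] = {}
            for base in beam:
                have = set(base.terms)
                for term in universe.terms:
                    if term in have:
                        continue
                    cand_terms = have | {term}
                    if not satisfies_heredity(cand_terms,
                                              heredity_interactions,
                                              heredity_quadratics):
                        continue
                    cand = ModelSpec(outcome, tuple(cand_terms))
                    layer.setdefault(cand.key(), cand)
            if not layer:
                break
            ranked = sorted(layer.values(),
                            key=lambda s: (score_spec(s).aic, s.describe()))
            beam = ranked[:beam_width]

    candidates = [s for s in scored.values() if s.converged]
    if not candidates:
        raise RuntimeError("no candidate model converged")

    # LOOCV only for the best-AIC pool
    pool = sorted(candidates, key=lambda s: (s.aic, s.spec.n_terms,
                                             s.spec.describe()))
    if cv_pool_size is not None:
        pool = pool[:cv_pool_size]
    for sc in pool:
        sc.in_cv_pool = True
        sc.r2_cv, _, cv_ok = loocv_r2(frame, sc.spec, rescale_columns,
                                      group_col)
        if not cv_ok:
            sc.converged = False
            continue
        drop = sc.r2_train - sc.r2_cv
        if drop_mode == "relative":
            limit = drop_threshold * max(sc.r2_train, 1e-12)
        else:
            limit = drop_threshold
        sc.admissible = drop <= limit

    best, note = choose_candidate(pool, drop_threshold, drop_mode)

    ledger = pd.DataFrame(
        [{"model": s.spec.describe(), "n_terms": s.spec.n_terms,
          "aic": s.aic, "r2_train": s.r2_train, "r2_cv": s.r2_cv,
          "converged": s.converged, "in_cv_pool": s.in_cv_pool,
          "admissible": s.admissible}
         for s in sorted(scored.values(),
                         key=lambda s: (s.aic, s.spec.n_terms,
                                        s.spec.describe()))])
    return SearchResult(ledger=ledger, scores=list(scored.values()),
                        selected=best.spec, selected_fit=fits[best.spec.key()],
                        selection_note=note, search_mode=search_mode,
                        seed=seed, drop_threshold=drop_threshold,
                        drop_mode=drop_mode)
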