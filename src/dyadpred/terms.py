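"""Fixed-effect term and candidate-model descriptions.

A candidate model is a set of fixed-effect terms over baseline predictors —
linear effects, quadratic effects of continuous predictors, and pairwise
interactions — plus an implicit intercept and a grouping-level random
intercept.  Terms carry a canonical ordering so that enumeration, ledgers
and reports are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

KINDS = ("linear", "quadratic", "interaction")
_KIND_RANK = {k: i for i, k in enumerate(KINDS)}


@dataclass(frozen=True)
class ModelTerm:
    """One fixed-effect term: linear(x), quadratic(x) or interaction(a, b)."""

    kind: str
    variables: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}; expected one of {KINDS}")
        n = len(self.variables)
        if self.kind in ("linear", "quadratic"):
            if n != 1:
                raise ValueError(f"{self.kind} term takes exactly one variable, got {n}")
        else:
            if n != 2 or self.variables[0] == self.variables[1]:
                raise ValueError("interaction term takes two distinct variables")
            # unordered pair: store sorted
            object.__setattr__(self, "variables", tuple(sorted(self.variables)))

    # -- constructors -------------------------------------------------
    @classmethod
    def linear(cls, name: str) -> "ModelTerm":
        return cls("linear", (name,))

    @classmethod
    def quadratic(cls, name: str) -> "ModelTerm":
        return cls("quadratic", (name,))

    @classmethod
    def interaction(cls, a: str, b: str) -> "ModelTerm":
        return cls("interaction", (a, b))

    # -- naming -------------------------------------------------------
    @property
    def name(self) -> str:
        """Machine-friendly column name."""
        if self.kind == "linear":
            return self.variables[0]
        if self.kind == "quadratic":
            return f"{self.variables[0]}^2"
        return f"{self.variables[0]}:{self.variables[1]}"

    @property
    def label(self) -> str:
        """Human-friendly row label used in report tables."""
        if self.kind == "interaction":
            return f"{self.variables[0]} × {self.variables[1]}"
        return self.name

    def sort_key(self) -> tuple:
        return (_KIND_RANK[self.kind], self.variables)

    def parents(self) -> tuple["ModelTerm", ...]:
        """Linear terms implied by this term under heredity constraints."""
        if self.kind == "linear":
            return ()
        return tuple(ModelTerm.linear(v) for v in self.variables)

    @classmethod
    def parse(cls, text: str) -> "ModelTerm":
        """Inverse of :attr:`name` (``x``, ``x^2`` or ``a:b``)."""
        text = text.strip()
        if text.endswith("^2"):
            return cls.quadratic(text[:-2])
        if ":" in text:
            a, b = text.split(":", 1)
            return cls.interaction(a, b)
        return cls.linear(text)


def canonical_order(terms: Iterable[ModelTerm]) -> tuple[ModelTerm, ...]:
    """Sort terms: linear (alphabetical), quadratic, then interactions."""
    return tuple(sorted(set(terms), key=ModelTerm.sort_key))


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: outcome name + term set.

    The intercept and the therapist-level random intercept are implicit and
    always present; estimation is maximum likelihood.
    """

    outcome: str
    terms: tuple[ModelTerm, ...] = field(default=())

    def __post_init__(self) -> None:
        ordered = canonical_order(self.terms)
        if len(ordered) != len(self.terms):
            raise ValueError("duplicate terms in model specification")
        object.__setattr__(self, "terms", ordered)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    def with_term(self, term: ModelTerm) -> "ModelSpec":
        return ModelSpec(self.outcome, self.terms + (term,))

    def key(self) -> frozenset:
        return frozenset(self.terms)

    def describe(self) -> str:
        if not self.terms:
            return f"{self.outcome} ~ 1"
        return f"{self.outcome} ~ " + " + ".join(t.name for t in self.terms)
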