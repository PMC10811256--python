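"""Nested dyadic study data: schemas, CSV I/O and preprocessing.

The data model has three levels: therapists, clients nested in therapists,
and session-level longitudinal records per client.  Symptom outcome is
observed at six timepoints (pre, sessions 1/3/5/7, post); alliance is rated
by both parties at the four mid-treatment sessions only.

Preprocessing mirrors the analysis conventions: continuous predictors are
Z-scored, binary predictors are coded −0.5 / +0.5, and missing predictor
cells are filled by k-nearest-neighbour imputation (Euclidean distance over
jointly observed variables).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TIMEPOINTS = ("pre", "s1", "s3", "s5", "s7", "post")
WAI_TIMEPOINTS = ("s1", "s3", "s5", "s7")

THERAPIST_COLUMNS = ("therapist_id", "age", "gender", "income", "fis_level",
                     "training", "orientation")
CLIENT_COLUMNS = ("client_id", "therapist_id", "age", "gender", "income",
                  "ssi_total", "iip_total", "oq_total_baseline",
                  "oq_sub_symptom", "oq_sub_interpersonal",
                  "oq_sub_social_role", "prior_treatment")
SESSION_COLUMNS = ("client_id", "timepoint", "wai_client", "wai_therapist",
                   "oq_total")

#: canonical (prefixed) predictor names in the merged client-level frame
CLIENT_PREDICTORS = ("client_age", "client_gender", "client_income",
                     "ssi_total", "iip_total", "oq_total_baseline",
                     "oq_sub_symptom", "oq_sub_interpersonal",
                     "oq_sub_social_role", "prior_treatment")
THERAPIST_PREDICTORS = ("therapist_age", "therapist_gender",
                        "therapist_income", "fis_level", "training",
                        "orientation")

_NA_VALUES = ["", "NA"]


class SchemaError(ValueError):
    """A required column is absent or a header does not match the schema."""


class IntegrityError(ValueError):
    """Referential or uniqueness constraint violated."""


class VocabularyError(ValueError):
    """A categorical cell holds a level outside the closed vocabulary."""


class DegenerateVariableError(ValueError):
    """A variable has zero variance where positive variance is required."""


@dataclass
class ScalingStats:
    """Per-variable mean/sd used for (and recoverable from) Z-scoring."""

    stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return self.stats[name][0]

    def sd(self, name: str) -> float:
        return self.stats[name][1]

    def __contains__(self, name: str) -> bool:
        return name in self.stats


@dataclass
class DyadDataset:
    """Therapist / client / session tables plus provenance metadata."""

    therapists: pd.DataFrame
    clients: pd.DataFrame
    sessions: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def copy(self) -> "DyadDataset":
        return DyadDataset(self.therapists.copy(), self.clients.copy(),
                           self.sessions.copy(), dict(self.provenance))

    # ------------------------------------------------------------------
    def validate(self, require_longitudinal: bool = True) -> None:
        """Raise on any schema / vocabulary / referential violation."""
        for df, cols, label in ((self.therapists, THERAPIST_COLUMNS, "therapists"),
                                (self.clients, CLIENT_COLUMNS, "clients"),
                                (self.sessions, SESSION_COLUMNS, "sessions")):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"{label} table missing column(s): {', '.join(missing)}")

        if self.therapists["therapist_id"].duplicated().any():
            dup = self.therapists.loc[self.therapists["therapist_id"].duplicated(),
                                      "therapist_id"].iloc[0]
            raise IntegrityError(f"duplicate therapist_id {dup!r}")
        if self.clients["client_id"].duplicated().any():
            dup = self.clients.loc[self.clients["client_id"].duplicated(),
                                   "client_id"].iloc[0]
            raise IntegrityError(f"duplicate client_id {dup!r}")

        known_t = set(self.therapists["therapist_id"])
        orphans = sorted(set(self.clients["therapist_id"]) - known_t)
        if orphans:
            raise IntegrityError(
                f"client table references unknown therapist_id(s): {', '.join(map(str, orphans))}")

        known_c = set(self.clients["client_id"])
        orphan_s = sorted(set(self.sessions["client_id"]) - known_c)
        if orphan_s:
            raise IntegrityError(
                f"session table references unknown client_id(s): {', '.join(map(str, orphan_s))}")

        bad_tp = sorted(set(self.sessions["timepoint"]) - set(TIMEPOINTS))
        if bad_tp:
            raise VocabularyError(
                f"timepoint value(s) outside {TIMEPOINTS}: {', '.join(map(str, bad_tp))}")

        dup_mask = self.sessions.duplicated(subset=["client_id", "timepoint"])
        if dup_mask.any():
            row = self.sessions.loc[dup_mask].iloc[0]
            raise IntegrityError(
                f"duplicate session row for client {row['client_id']!r} "
                f"timepoint {row['timepoint']!r}")

        off = self.sessions[~self.sessions["timepoint"].isin(WAI_TIMEPOINTS)]
        for col in ("wai_client", "wai_therapist"):
            if off[col].notna().any():
                tp = off.loc[off[col].notna(), "timepoint"].iloc[0]
                raise IntegrityError(f"{col} observed at timepoint {tp!r}; "
                                     f"alliance is measured only at {WAI_TIMEPOINTS}")

        if require_longitudinal and len(self.sessions):
            oq_counts = (self.sessions.dropna(subset=["oq_total"])
                         .groupby("client_id").size())
            wai_any = (self.sessions[list(("wai_client", "wai_therapist"))]
                       .notna().any(axis=1))
            wai_counts = self.sessions.loc[wai_any].groupby("client_id").size()
            for cid in self.clients["client_id"]:
                if oq_counts.get(cid, 0) < 2:
                    raise IntegrityError(
                        f"client {cid!r} has fewer than 2 observed outcome timepoints")
                if wai_counts.get(cid, 0) < 1:
                    raise IntegrityError(
                        f"client {cid!r} has no observed alliance session")


# ----------------------------------------------------------------------
# CSV I/O
# ----------------------------------------------------------------------

def _read_csv(path, required: Sequence[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False,
                     float_precision="round_trip",
                     dtype={c: str for c in ("therapist_id", "client_id", "timepoint")
                            if c in required})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} table at {path} missing column(s): "
                          f"{', '.join(missing)}")
    return df


def read_study_tables(therapist_path, client_path, session_path) -> DyadDataset:
    """Load the three study CSVs and validate the nested structure."""
    therapists = _read_csv(therapist_path, THERAPIST_COLUMNS, "therapists")
    clients = _read_csv(client_path, CLIENT_COLUMNS, "clients")
    sessions = _read_csv(session_path, SESSION_COLUMNS, "sessions")
    ds = DyadDataset(therapists, clients, sessions,
                     provenance={"source": {"therapists": str(therapist_path),
                                            "clients": str(client_path),
                                            "sessions": str(session_path)}})
    ds.validate(require_longitudinal=False)
    return ds


def write_study_tables(dataset: DyadDataset, out_dir) -> dict[str, Path]:
    """Write therapists.csv / clients.csv / sessions.csv under ``out_dir``.

    Floats are written with Python's shortest round-trip representation, so
    a read → write → read cycle preserves every cell exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("therapists", dataset.therapists),
                     ("clients", dataset.clients),
                     ("sessions", dataset.sessions)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, na_rep="")
        paths[name] = p
    return paths


# ----------------------------------------------------------------------
# variable resolution across the three tables
# ----------------------------------------------------------------------

def _resolve(dataset: DyadDataset, name: str) -> tuple[pd.DataFrame, str]:
    """Map a variable name to (table, column).

    Qualified names (``clients.age``, ``therapists.income``) are explicit;
    unqualified names are searched in clients first, then therapists, and
    must not be ambiguous.
    """
    if "." in name:
        table_name, col = name.split(".", 1)
        table = {"therapists": dataset.therapists,
                 "clients": dataset.clients,
                 "sessions": dataset.sessions}.get(table_name)
        if table is None:
            raise KeyError(f"unknown table {table_name!r} in variable {name!r}")
        if col not in table.columns:
            raise KeyError(f"unknown variable {name!r}")
        return table, col
    in_c = name in dataset.clients.columns and name not in ("client_id", "therapist_id")
    in_t = name in dataset.therapists.columns and name != "therapist_id"
    if in_c and in_t:
        raise KeyError(f"variable {name!r} exists in both clients and therapists "
                       "tables; qualify as 'clients.{0}' or 'therapists.{0}'".format(name))
    if in_c:
        return dataset.clients, name
    if in_t:
        return dataset.therapists, name
    raise KeyError(f"unknown variable {name!r}")


# ----------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------

def zscore_continuous(dataset: DyadDataset,
                      variables: Sequence[str],
                      stats: ScalingStats | None = None,
                      ) -> tuple[DyadDataset, ScalingStats]:
    """Z-score continuous predictors in place (on a copy of the dataset).

    When ``stats`` is None, mean and sample sd (denominator n−1) are computed
    from the dataset and returned; otherwise the supplied statistics are
    applied unchanged (cross-validation reuse).
    """
    ds = dataset.copy()
    out = ScalingStats()
    for name in variables:
        table, col = _resolve(ds, name)
        x = pd.to_numeric(table[col], errors="coerce")
        if stats is not None:
            if name not in stats:
                raise KeyError(f"supplied ScalingStats does not cover {name!r}")
            m, s = stats.stats[name]
        else:
            m = float(x.mean())
            s = float(x.std(ddof=1))
            if not np.isfinite(s) or s <= 0:
                raise DegenerateVariableError(
                    f"variable {name!r} has zero sample sd; cannot Z-score")
        if s <= 0:
            raise DegenerateVariableError(f"variable {name!r}: sd must be > 0")
        table[col] = (x - m) / s
        out.stats[name] = (m, s)
    ds.provenance.setdefault("zscore", {}).update(
        {k: {"mean": v[0], "sd": v[1]} for k, v in out.stats.items()})
    return ds, out


def code_binaries(dataset: DyadDataset,
                  coding_map: Mapping[str, Mapping[str, float]],
                  ) -> DyadDataset:
    """Recode binary categorical predictors to −0.5 / +0.5.

    ``coding_map`` maps each variable to a two-level dict, e.g.
    ``{"gender": {"female": -0.5, "male": 0.5}}``.  An observed level
    outside the mapping is a vocabulary error.
    """
    ds = dataset.copy()
    for name, levels in coding_map.items():
        if len(levels) != 2 or set(levels.values()) != {-0.5, 0.5}:
            raise ValueError(f"coding for {name!r} must map exactly two levels "
                             "to -0.5 and +0.5")
        table, col = _resolve(ds, name)
        observed = set(table[col].dropna().astype(str))
        extra = observed - set(map(str, levels))
        if extra:
            raise VocabularyError(
                f"variable {name!r} contains unmapped level(s): "
                f"{', '.join(sorted(extra))}")
        table[col] = table[col].map(
            lambda v: levels[str(v)] if pd.notna(v) else np.nan)
    ds.provenance.setdefault("binary_coding", {}).update(
        {k: dict(v) for k, v in coding_map.items()})
    return ds


def knn_impute(matrix: pd.DataFrame, k: int = 5,
               reference_mask: Sequence[bool] | None = None,
               ) -> tuple[pd.DataFrame, list[dict]]:
    """k-nearest-neighbour imputation of missing cells.

    For each missing cell (row i, variable v) the candidates are the
    reference rows with v observed; the distance between two rows is the
    Euclidean distance over the variables observed in both, rescaled by the
    fraction observed (``sqrt(sum_sq * n_vars / n_shared)``).  The cell is
    filled with the unweighted mean of v over the k nearest candidates.
    Observed cells are never altered.

    Returns the imputed copy and a log with one entry per filled cell
    (row label, variable, donor row labels, imputed value).
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if reference_mask is None:
        ref_idx = np.arange(n)
    else:
        ref_idx = np.flatnonzero(np.asarray(reference_mask, dtype=bool))
    obs = ~np.isnan(X)
    out = X.copy()
    log: list[dict] = []
    miss_rows, miss_cols = np.where(~obs)
    for i, j in zip(miss_rows, miss_cols):
        cands = ref_idx[(ref_idx != i) & obs[ref_idx, j]]
        if cands.size == 0:
            raise ValueError(
                f"variable {matrix.columns[j]!r} is missing in all reference rows")
        if k > cands.size:
            raise ValueError(
                f"k={k} exceeds the {cands.size} available reference rows "
                f"for variable {matrix.columns[j]!r}")
        dists = np.empty(cands.size)
        for c_pos, c in enumerate(cands):
            shared = obs[i] & obs[c]
            n_shared = int(shared.sum())
            if n_shared == 0:
                dists[c_pos] = np.inf
                continue
            d2 = float(np.sum((X[i, shared] - X[c, shared]) ** 2))
            dists[c_pos] = np.sqrt(d2 * p / n_shared)
        order = np.argsort(dists, kind="stable")[:k]
        donors = cands[order]
        if not np.isfinite(dists[order]).all():
            raise ValueError(
                f"fewer than k={k} comparable reference rows for row "
                f"{matrix.index[i]!r}")
        value = float(np.mean(X[donors, j]))
        out[i, j] = value
        log.append({"row": matrix.index[i], "variable": matrix.columns[j],
                    "donors": [matrix.index[d] for d in donors],
                    "value": value})
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), log


# ----------------------------------------------------------------------
# merged client-level predictor frame
# ----------------------------------------------------------------------

def predictor_frame(dataset: DyadDataset) -> pd.DataFrame:
    """One row per client: ids plus all baseline predictors.

    Shared column names (age, gender, income) are disambiguated with
    ``client_`` / ``therapist_`` prefixes; therapist covariates repeat for
    every client of the same therapist.
    """
    c = dataset.clients.rename(columns={"age": "client_age",
                                        "gender": "client_gender",
                                        "income": "client_income"})
    t = dataset.therapists.rename(columns={"age": "therapist_age",
                                           "gender": "therapist_gender",
                                           "income": "therapist_income"})
    merged = c.merge(t, on="therapist_id", how="left", validate="m:1")
    cols = ["client_id", "therapist_id", *CLIENT_PREDICTORS, *THERAPIST_PREDICTORS]
    return merged[cols]
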