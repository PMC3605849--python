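"""CSV interchange for the experiment tables and results.

CSV (UTF-8, header row) is the interchange format throughout — no standard
bioinformatics container fits behavioral count data. Readers validate
schemas and report offending rows by number; writers round-trip exactly
through the readers.

Schemas
-------
egg counts      population,female,<category...>          (integer cells)
hatch records   population,female,treatment,location,hatched,total
wing models     model_id,pc1,pc2
trials          trial_id,presented_1,presented_2,presented_3,approached
distance matrix label,<label...>                          (square, symmetric)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .diapause_model import HatchTable
from .distance_analysis import DistanceMatrix
from .errors import InvalidInputError
from .morphospace import TrialTable
from .preference_model import EggCountTable

__all__ = [
    "read_egg_counts",
    "write_egg_counts",
    "read_hatch_table",
    "write_hatch_table",
    "read_model_scores",
    "write_model_scores",
    "read_trials",
    "write_trials",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_posterior_summary",
    "write_draws",
]


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    return pd.read_csv(path)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")


def read_egg_counts(path) -> dict[str, EggCountTable]:
    """One EggCountTable per population; category labels are all columns
    after ``population`` and ``female``."""
    df = _read_csv(path)
    _require_columns(df, ["population", "female"], path)
    cats = [c for c in df.columns if c not in ("population", "female")]
    if len(cats) < 2:
        raise InvalidInputError(f"{path}: need >= 2 category columns")
    for c in cats:
        bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()
                       | (pd.to_numeric(df[c], errors="coerce") % 1 != 0)].tolist()
        if bad:
            raise InvalidInputError(f"{path}: non-integer counts in column {c!r}, rows {bad}")
    out = {}
    for pop, sub in df.groupby("population", sort=False):
        out[str(pop)] = EggCountTable(
            population_id=str(pop),
            female_ids=[str(f) for f in sub["female"]],
            counts=sub[cats].to_numpy(dtype=np.int64),
            category_labels=cats,
        )
    return out


def write_egg_counts(tables: dict[str, EggCountTable] | EggCountTable, path) -> None:
    if isinstance(tables, EggCountTable):
        tables = {tables.population_id: tables}
    frames = []
    for pop, t in tables.items():
        df = pd.DataFrame(t.counts, columns=t.category_labels)
        df.insert(0, "female", t.female_ids)
        df.insert(0, "population", pop)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_hatch_table(path) -> dict[str, HatchTable]:
    df = _read_csv(path)
    cols = ["population", "female", "treatment", "location", "hatched", "total"]
    _require_columns(df, cols, path)
    bad = df.index[df["hatched"] > df["total"]].tolist()
    if bad:
        raise InvalidInputError(f"{path}: hatched > total at rows {bad}")
    out = {}
    for pop, sub in df.groupby("population", sort=False):
        out[str(pop)] = HatchTable(
            population_id=str(pop),
            female_ids=[str(f) for f in sub["female"]],
            treatments=[str(t) for t in sub["treatment"]],
            locations=[str(l) for l in sub["location"]],
            hatched=sub["hatched"].to_numpy(dtype=np.int64),
            total=sub["total"].to_numpy(dtype=np.int64),
        )
    return out


def write_hatch_table(tables: dict[str, HatchTable] | HatchTable, path) -> None:
    if isinstance(tables, HatchTable):
        tables = {tables.population_id: tables}
    frames = []
    for pop, t in tables.items():
        frames.append(pd.DataFrame({
            "population": pop, "female": t.female_ids, "treatment": t.treatments,
            "location": t.locations, "hatched": t.hatched, "total": t.total,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_model_scores(path) -> dict:
    df = _read_csv(path)
    _require_columns(df, ["model_id", "pc1", "pc2"], path)
    return {str(r.model_id): (float(r.pc1), float(r.pc2)) for r in df.itertuples()}


def write_model_scores(scores: dict, path) -> None:
    pd.DataFrame(
        [(m, xy[0], xy[1]) for m, xy in scores.items()],
        columns=["model_id", "pc1", "pc2"],
    ).to_csv(path, index=False)


def read_trials(path) -> TrialTable:
    """Trial rows: one row per approach event; rows sharing a trial_id must
    agree on the presented triple. A row with an empty ``approached`` cell
    records a trial without approaches."""
    df = _read_csv(path)
    cols = ["trial_id", "presented_1", "presented_2", "presented_3", "approached"]
    _require_columns(df, cols, path)
    trial_ids, presented, approaches = [], [], []
    seen = {}
    for idx, r in df.iterrows():
        pres = (str(r.presented_1), str(r.presented_2), str(r.presented_3))
        tid = str(r.trial_id)
        if tid in seen:
            if presented[seen[tid]] != pres:
                raise InvalidInputError(f"{path}: trial {tid} has conflicting presented sets (row {idx})")
        else:
            seen[tid] = len(trial_ids)
            trial_ids.append(tid)
            presented.append(pres)
            approaches.append([])
        if not (pd.isna(r.approached) or str(r.approached) == ""):
            approaches[seen[tid]].append(str(r.approached))
    return TrialTable(trial_ids=trial_ids, presented=presented, approaches=approaches)


def write_trials(trials: TrialTable, path) -> None:
    rows = []
    for tid, pres, app in zip(trials.trial_ids, trials.presented, trials.approaches):
        if app:
            for a in app:
                rows.append((tid, *pres, a))
        else:
            rows.append((tid, *pres, ""))
    pd.DataFrame(rows, columns=["trial_id", "presented_1", "presented_2",
                                "presented_3", "approached"]).to_csv(path, index=False)


def read_distance_matrix(path, kind: str = "generic") -> DistanceMatrix:
    df = _read_csv(path)
    labels = [str(l) for l in df.iloc[:, 0]]
    vals = df.iloc[:, 1:].to_numpy(dtype=float)
    if list(df.columns[1:]) != labels:
        raise InvalidInputError(f"{path}: row labels and column headers disagree")
    return DistanceMatrix(labels=labels, values=vals, kind=kind)


def write_distance_matrix(D: DistanceMatrix, path) -> None:
    df = pd.DataFrame(D.values, columns=D.labels)
    df.insert(0, "label", D.labels)
    df.to_csv(path, index=False)


def write_posterior_summary(summary_df: pd.DataFrame, path) -> None:
    summary_df.to_csv(path, index=False, float_format="%.6g")


def write_draws(draws: np.ndarray, names: list[str], path) -> None:
    """Raw-draw archive: one row per retained iteration (chains pooled)."""
    arr = np.asarray(draws)
    pd.DataFrame(arr.reshape(arr.shape[0], -1), columns=names).to_csv(path, index=False)
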