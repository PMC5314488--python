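"""Aesthetics index scores per audit location and neighbourhood averages.

An audit location's aesthetics index score is a weighted average of its
ordinal item responses, corrected for items that were not applicable at the
site (no outdoor furniture on an apartment block face, say).  With C items,
applicable count N_i for location i, weights w_j and responses x_ij in
{1..5}, the literal form is

    s_i. = (C / N_i) * sum over applicable j of w_j * x_ij

which rescales by the count of applicable items so a location is not
penalized for inapplicable items.  When weights are unequal, the literal
form can overflow the nominal 1-5 range once low-weight items go missing
(the C/N_i factor over-corrects); the ``renormalized`` mode instead divides
by the sum of applicable weights,

    s_i. = sum over applicable j of (w_j / W_i) * x_ij,  W_i = sum w_j,

a convex combination of the responses and therefore always inside [1, 5].
The neighbourhood average aesthetics index score Q_s is the unweighted mean
of its member locations' s_i. values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .instrument import WeightVector

__all__ = [
    "ObservationMatrix",
    "ScoreSet",
    "ScoreRangeWarning",
    "aesthetics_score",
    "score_locations",
    "combine_auditors",
    "neighbourhood_mean",
    "rank_neighbourhoods",
    "read_observations_csv",
    "write_observations_csv",
]

META_COLUMNS = ("neighbourhood_id", "auditor_id", "date")


class ScoreRangeWarning(UserWarning):
    """Literal-mode score fell outside the nominal 1-5 range."""


@dataclass
class ObservationMatrix:
    """Ordinal audit responses, wide form: locations x items, NaN = not applicable.

    ``data`` is a float DataFrame indexed by location id with one column per
    item; ``meta`` is indexed identically and carries neighbourhood_id,
    auditor_id and date.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        finite = vals[np.isfinite(vals)]
        bad = ~np.isin(finite, (1.0, 2.0, 3.0, 4.0, 5.0))
        if bad.any():
            raise ValueError(
                f"responses must be in {{1..5}} or NaN; found {finite[bad][:5]}"
            )
        if not self.meta.index.equals(self.data.index):
            raise ValueError("meta must be indexed by the same location ids")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta lacks columns {missing}")
        empty = self.data.isna().all(axis=1)
        if empty.any():
            raise ValueError(
                "locations with every item NOT_APPLICABLE: "
                f"{list(self.data.index[empty])}"
            )

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def applicable_counts(self) -> pd.Series:
        """N_i: number of applicable items per location."""
        return self.data.notna().sum(axis=1)


@dataclass
class ScoreSet:
    """Per-location scores s_i., neighbourhood averages Q_s and group sizes n."""

    location_scores: pd.Series
    neighbourhood_scores: pd.Series
    n: pd.Series
    neighbourhood_of: pd.Series = field(repr=False)


def aesthetics_score(
    values: pd.Series | np.ndarray,
    weights: WeightVector,
    mode: Literal["literal", "renormalized"] = "literal",
    n_items: int | None = None,
) -> float:
    """Score a single observation row (NaN entries = not applicable).

    ``n_items`` overrides the instrument size C used by the literal formula;
    it defaults to the length of the weight vector.
    """
    x = np.asarray(values, dtype=float)
    w = weights.weights
    if x.shape != w.shape:
        raise ValueError("row must have one value per weighted item")
    mask = np.isfinite(x)
    if not mask.any():
        raise ValueError("all items NOT_APPLICABLE for this row")
    c = n_items if n_items is not None else len(w)
    n_i = int(mask.sum())
    if mode == "literal":
        s = (c / n_i) * float(np.dot(w[mask], x[mask]))
        if s > 5.0 + 1e-12 or s < 1.0 - 1e-12:
            warnings.warn(
                f"literal-mode score {s:.4f} outside the nominal [1, 5] range "
                "(low-weight items marked not applicable); consider "
                "mode='renormalized'",
                ScoreRangeWarning,
                stacklevel=2,
            )
        return s
    if mode == "renormalized":
        wi = float(w[mask].sum())
        return float(np.dot(w[mask] / wi, x[mask]))
    raise ValueError(f"unknown mode {mode!r}")


def score_locations(
    obs: ObservationMatrix,
    weights: WeightVector,
    mode: Literal["literal", "renormalized"] = "literal",
) -> ScoreSet:
    """Score every location of an observation matrix and average by neighbourhood."""
    if tuple(obs.data.columns) != weights.item_ids:
        raise ValueError("observation items do not match the weight vector")
    scores = pd.Series(
        [
            aesthetics_score(obs.data.iloc[i].to_numpy(), weights, mode=mode)
            for i in range(len(obs.data))
        ],
        index=obs.data.index,
        name="score",
    )
    return neighbourhood_mean(scores, obs.meta["neighbourhood_id"])


def combine_auditors(
    matrices: Sequence[ObservationMatrix],
    policy: Literal["mean", "per_auditor"] = "mean",
) -> ObservationMatrix | list[ObservationMatrix]:
    """Combine two or more auditors' matrices over the same locations.

    ``mean``: per item, average the ordinal values over the auditors for whom
    the item was applicable; an item is NOT_APPLICABLE in the output only when
    every auditor marked it so.  ``per_auditor`` returns the inputs unchanged
    (for reliability analysis).  Averaged values may be non-integral; the
    result therefore skips the {1..5} integrality check but stays in [1, 5].
    """
    if len(matrices) < 2:
        raise ValueError("need at least two auditors to combine")
    base = matrices[0]
    loc = set(base.data.index)
    for m in matrices[1:]:
        if set(m.data.index) != loc:
            raise ValueError("auditors must cover identical location sets")
        if m.item_ids != base.item_ids:
            raise ValueError("auditors must share the instrument's items")
    if policy == "per_auditor":
        return list(matrices)
    if policy != "mean":
        raise ValueError(f"unknown policy {policy!r}")
    stack = np.stack(
        [m.data.loc[base.data.index].to_numpy() for m in matrices], axis=0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        combined = np.nanmean(stack, axis=0)
    meta = base.meta.copy()
    meta["auditor_id"] = "combined"
    out = ObservationMatrix.__new__(ObservationMatrix)
    out.data = pd.DataFrame(combined, index=base.data.index, columns=base.data.columns)
    out.meta = meta
    # combined values are means of {1..5} entries, so range checks suffice
    vals = out.data.to_numpy()
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 1 or finite.max() > 5):
        raise ValueError("combined responses left the [1, 5] range")
    if np.isnan(vals).all(axis=1).any():
        raise ValueError("a location is NOT_APPLICABLE on every item for all auditors")
    return out


def neighbourhood_mean(
    scores: pd.Series, neighbourhood_of: pd.Series
) -> ScoreSet:
    """Unweighted Q_s per neighbourhood, with member counts n."""
    if scores.empty:
        raise ValueError("no scores to average")
    neighbourhood_of = neighbourhood_of.reindex(scores.index)
    if neighbourhood_of.isna().any():
        raise ValueError("every scored location needs a neighbourhood id")
    grouped = scores.groupby(neighbourhood_of)
    return ScoreSet(
        location_scores=scores,
        neighbourhood_scores=grouped.mean().rename("q_s"),
        n=grouped.size().rename("n"),
        neighbourhood_of=neighbourhood_of,
    )


def rank_neighbourhoods(scoreset: ScoreSet, ascending: bool = True) -> pd.DataFrame:
    """Rank neighbourhoods by Q_s (default ascending: lowest aesthetics first).

    Stable sort; exact ties are broken lexicographically by neighbourhood id
    and flagged in the ``tied`` column.
    """
    qs = scoreset.neighbourhood_scores
    if len(qs) < 2:
        raise ValueError("need at least two neighbourhoods to rank")
    df = qs.rename("q_s").rename_axis("neighbourhood_id").reset_index()
    df = df.sort_values(
        ["q_s", "neighbourhood_id"], ascending=[ascending, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    counts = df["q_s"].map(df["q_s"].value_counts())
    df["tied"] = counts > 1
    return df


# ---------------------------------------------------------------------------
# long-format CSV interfaces

def read_observations_csv(path: str | Path, item_ids: Sequence[str] | None = None
                          ) -> ObservationMatrix:
    """Read long-format observations (location_id, neighbourhood_id, auditor_id,
    date, item_id, value); empty/NA values mean not applicable."""
    df = pd.read_csv(path, dtype={"location_id": str, "item_id": str})
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    wide = df.pivot(index="location_id", columns="item_id", values="value")
    if item_ids is not None:
        wide = wide.reindex(columns=list(item_ids))
    meta = (
        df.drop_duplicates("location_id")
        .set_index("location_id")[list(META_COLUMNS)]
        .loc[wide.index]
    )
    return ObservationMatrix(wide, meta)


def write_observations_csv(path: str | Path, obs: ObservationMatrix) -> None:
    long = (
        obs.data.rename_axis("location_id")
        .reset_index()
        .melt(id_vars="location_id", var_name="item_id", value_name="value")
    )
    long = long.merge(
        obs.meta.rename_axis("location_id").reset_index(), on="location_id"
    )
    cols = ["location_id", *META_COLUMNS, "item_id", "value"]
    long[cols].sort_values(["location_id", "item_id"]).to_csv(path, index=False)
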