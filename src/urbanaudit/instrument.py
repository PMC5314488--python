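"""Audit instrument definition and pairwise-comparison item weighting.

A systematic social observation instrument (SSOI) is an ordered checklist of
items, each rated on a five-point Likert scale by trained observers at an
audit location.  Because items differ in how much they matter to perceived
aesthetics (upkeep of homes vs. presence of outdoor furniture, say), each
auditor fills in a pairwise comparison matrix over the items and a
row-standardized weight vector is derived from it; the weights actually used
for scoring are the mean of the auditors' vectors.

Weight derivation follows the analytic-hierarchy-process family: the default
method is the normalized principal eigenvector of the (positive, reciprocal)
comparison matrix, with Saaty's consistency ratio reported against the
standard random-index table.  The geometric mean of rows is available as an
alternative; the two coincide exactly on consistent matrices.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Instrument",
    "PairwiseMatrix",
    "WeightVector",
    "ConsistencyWarning",
    "derive_weights",
    "average_auditor_weights",
    "read_pairwise_csv",
    "read_weight_table",
    "write_weight_table",
]

LIKERT_LEVELS = (1, 2, 3, 4, 5)

#: Saaty random consistency index by matrix order (order -> RI).
RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32,
    8: 1.41, 9: 1.45, 10: 1.49, 11: 1.51, 12: 1.48, 13: 1.56,
    14: 1.57, 15: 1.59,
}


class ConsistencyWarning(UserWarning):
    """Raised when a pairwise matrix has consistency ratio > 0.1."""


@dataclass(frozen=True)
class Instrument:
    """An ordered set of Likert-rated observation items.

    Parameters
    ----------
    item_ids : ordered unique identifiers, one per item.
    labels : display labels, parallel to ``item_ids`` (defaults to the ids).
    level_descriptors : optional text anchors per item for the minimum,
        middle and maximum Likert level.
    """

    item_ids: tuple[str, ...]
    labels: tuple[str, ...] = ()
    level_descriptors: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = tuple(self.item_ids)
        object.__setattr__(self, "item_ids", ids)
        if len(ids) < 2:
            raise ValueError("an instrument needs at least 2 items")
        if len(set(ids)) != len(ids):
            raise ValueError("item identifiers must be unique")
        labels = tuple(self.labels) or ids
        if len(labels) != len(ids):
            raise ValueError("labels must parallel item_ids")
        object.__setattr__(self, "labels", labels)

    @property
    def n_items(self) -> int:
        """Number of items C of the instrument."""
        return len(self.item_ids)

    @property
    def likert_levels(self) -> tuple[int, ...]:
        return LIKERT_LEVELS


@dataclass(frozen=True)
class PairwiseMatrix:
    """A positive reciprocal comparison matrix for one auditor.

    Entry ``[i, j]`` holds how much more important item ``i`` is than item
    ``j``; the diagonal is 1 and ``m[j, i] == 1/m[i, j]``.
    """

    auditor_id: str
    item_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        k = len(self.item_ids)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"comparison matrix must be square, got shape {m.shape}")
        if m.shape[0] != k:
            raise ValueError(
                f"matrix order {m.shape[0]} does not match {k} items"
            )
        bad = np.argwhere(~(m > 0))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"comparison entries must be positive; entry "
                f"[{self.item_ids[i]}, {self.item_ids[j]}] = {m[i, j]!r}"
            )
        if not np.allclose(np.diag(m), 1.0, rtol=1e-9, atol=0):
            i = int(np.argmax(np.abs(np.diag(m) - 1.0)))
            raise ValueError(
                f"diagonal must be 1; entry [{self.item_ids[i]}, "
                f"{self.item_ids[i]}] = {m[i, i]!r}"
            )
        recip = ~np.isclose(m * m.T, 1.0, rtol=1e-9, atol=0)
        if recip.any():
            i, j = np.argwhere(recip)[0]
            raise ValueError(
                f"matrix is not reciprocal: entry [{self.item_ids[i]}, "
                f"{self.item_ids[j]}] = {m[i, j]!r} but transpose entry is "
                f"{m[j, i]!r}"
            )


@dataclass(frozen=True)
class WeightVector:
    """Row-standardized item weights (sum to 1), with provenance.

    ``source`` is an auditor label or ``"mean"``; ``consistency_ratio`` is
    carried when the vector came from a pairwise matrix.
    """

    item_ids: tuple[str, ...]
    weights: np.ndarray
    source: str = "unknown"
    consistency_ratio: float | None = None
    #: slack on the sum-to-1 constraint; widen (e.g. to 5e-3) only when
    #: wrapping weights transcribed from a rounded, printed table.
    sum_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        if w.shape != (len(self.item_ids),):
            raise ValueError("weights must parallel item_ids")
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        if abs(w.sum() - 1.0) > self.sum_tolerance:
            raise ValueError(
                f"weights must sum to 1 within {self.sum_tolerance} "
                f"(got {w.sum()!r}); renormalize or use renormalize=True "
                "when averaging"
            )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.item_ids, self.weights.tolist()))


def derive_weights(
    pairwise: PairwiseMatrix,
    method: Literal["eigenvector", "geometric"] = "eigenvector",
) -> WeightVector:
    """Derive row-standardized weights from a pairwise comparison matrix.

    ``eigenvector`` (default) takes the principal right eigenvector of the
    matrix, normalized to sum 1, and reports Saaty's consistency ratio
    CR = ((lambda_max - k)/(k - 1)) / RI(k).  ``geometric`` normalizes the
    row-wise geometric means; for a consistent matrix both give the same
    vector and CR = 0.  A ``ConsistencyWarning`` is emitted when CR > 0.1.
    """
    m = pairwise.matrix
    k = m.shape[0]
    eigvals, eigvecs = np.linalg.eig(m)
    lead = int(np.argmax(eigvals.real))
    lam = float(eigvals[lead].real)
    if method == "eigenvector":
        v = np.abs(eigvecs[:, lead].real)
    elif method == "geometric":
        v = np.exp(np.log(m).mean(axis=1))
    else:
        raise ValueError(f"unknown method {method!r}")
    w = v / v.sum()

    ri = RANDOM_INDEX.get(k)
    if k <= 2:
        cr = 0.0
    elif ri:
        cr = max(0.0, (lam - k) / (k - 1)) / ri
    else:  # order beyond the tabulated range
        cr = float("nan")
    if np.isfinite(cr) and cr > 0.1:
        warnings.warn(
            f"pairwise matrix of auditor {pairwise.auditor_id!r} has "
            f"consistency ratio {cr:.3f} > 0.1; judgements are inconsistent",
            ConsistencyWarning,
            stacklevel=2,
        )
    return WeightVector(pairwise.item_ids, w, source=pairwise.auditor_id,
                        consistency_ratio=cr)


def average_auditor_weights(
    vectors: Sequence[WeightVector], renormalize: bool = True
) -> WeightVector:
    """Elementwise mean of several auditors' weight vectors.

    With ``renormalize`` (default) the mean is rescaled to sum exactly 1 so
    the row-standardization invariant survives rounded inputs.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 weight vectors to average")
    ids = vectors[0].item_ids
    for v in vectors[1:]:
        if v.item_ids != ids:
            raise ValueError(
                f"mismatched item sets: {ids} vs {v.item_ids}"
            )
    w = np.mean([v.weights for v in vectors], axis=0)
    if renormalize:
        w = w / w.sum()
        tol = 1e-9
    else:
        tol = max(v.sum_tolerance for v in vectors)
    return WeightVector(ids, w, source="mean", sum_tolerance=tol)


def mean_printed_weights(
    vectors: Sequence[Sequence[float]], item_ids: Sequence[str]
) -> np.ndarray:
    """Plain elementwise mean of printed (rounded) weight columns.

    Unlike :func:`average_auditor_weights` this performs no renormalization
    and no sum-to-1 validation, matching how a published weight table's Mean
    column is formed from its rounded per-auditor columns.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 weight columns")
    arr = np.asarray(vectors, dtype=float)
    if arr.shape[1] != len(item_ids):
        raise ValueError("weight columns must parallel item_ids")
    return arr.mean(axis=0)


# ---------------------------------------------------------------------------
# CSV interfaces

def read_pairwise_csv(path: str | Path, auditor_id: str) -> PairwiseMatrix:
    """Read a square comparison matrix CSV (item ids as header and first column)."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    header = rows[0][1:]
    ids, data = [], []
    for row in rows[1:]:
        ids.append(row[0])
        data.append([float(_maybe_fraction(c)) for c in row[1:]])
    if ids != header:
        raise ValueError("pairwise CSV row ids must match header ids")
    return PairwiseMatrix(auditor_id, tuple(ids), np.array(data))


def _maybe_fraction(cell: str) -> float:
    cell = cell.strip()
    if "/" in cell:
        num, den = cell.split("/", 1)
        return float(num) / float(den)
    return float(cell)


def read_weight_table(path: str | Path) -> dict[str, WeightVector]:
    """Read a headered weight table CSV into vectors keyed by source.

    Expected columns: ``item_id``, ``label`` (optional), then one
    ``w_<source>`` column per weight vector (e.g. ``w_auditor_1``, ``w_mean``).
    """
    import pandas as pd

    df = pd.read_csv(path)
    ids = tuple(df["item_id"].astype(str))
    out: dict[str, WeightVector] = {}
    for col in df.columns:
        if col.startswith("w_"):
            source = col[2:]
            w = df[col].to_numpy(float)
            out[source] = WeightVector(ids, w / w.sum(), source=source)
    if not out:
        raise ValueError(f"no w_* columns found in {path}")
    return out


def write_weight_table(
    path: str | Path,
    instrument: Instrument,
    vectors: Sequence[WeightVector],
) -> None:
    """Write item ids, labels and one ``w_<source>`` column per vector."""
    import pandas as pd

    data: dict[str, object] = {
        "item_id": list(instrument.item_ids),
        "label": list(instrument.labels),
    }
    for v in vectors:
        if v.item_ids != instrument.item_ids:
            raise ValueError("vector items do not match the instrument")
        data[f"w_{v.source}"] = v.weights
    pd.DataFrame(data).to_csv(path, index=False)
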