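"""Bundled reference tables from the original Ottawa field deployment.

The instrument this package implements was first fielded across 15 Ottawa
neighbourhoods over two seasons by two independent auditors.  Two small
published tables from that deployment are bundled here so the weighting and
correlation machinery can be exercised (and its headline numbers reproduced)
without any external download:

* the 10-item weight table — per-auditor pairwise-comparison weights and
  their mean, as printed (rounded to 3 decimals; each auditor column sums to
  1.001, an artefact of rounding that the weighting module's renormalization
  handles);
* the neighbourhood average aesthetics index scores (Q_s) for the 15
  neighbourhoods in both field seasons, rounded to 2 decimals, used for the
  inter-season rank-agreement analysis.

Raw observation matrices were never deposited; synthetic ones are produced
by :mod:`urbanaudit.synthetic`.
"""

from __future__ import annotations

import pandas as pd

from .instrument import Instrument, WeightVector

__all__ = [
    "ssoi_instrument",
    "item_weight_table",
    "auditor_weight_vectors",
    "mean_weight_vector",
    "neighbourhood_scores_by_season",
]

# item_id, label, auditor 1 weight, auditor 2 weight, printed mean
_ITEM_WEIGHTS = [
    ("cleanliness", "Cleanliness of streets and properties", 0.100, 0.152, 0.126),
    ("trees_presence", "Presence of trees", 0.038, 0.091, 0.064),
    ("trees_quality", "Quality of trees", 0.049, 0.050, 0.049),
    ("landscaping", "Landscaping", 0.220, 0.086, 0.153),
    ("flowers_shrubs", "Flowers and shrubs", 0.079, 0.047, 0.063),
    ("houses_spacing", "Houses well-spaced", 0.085, 0.204, 0.144),
    ("homes_upkeep", "Upkeep of homes", 0.284, 0.244, 0.264),
    ("furniture_presence", "Presence of outdoor furniture", 0.037, 0.032, 0.034),
    ("furniture_quality", "Quality of outdoor furniture", 0.051, 0.034, 0.042),
    ("pedestrian_infra", "Pedestrian infrastructure", 0.058, 0.061, 0.059),
]

# (neighbourhood, Q_s season one 2011, Q_s season two 2012); name variants
# between seasons ("New Barrhaven—New Development—Stonebridge") are unified.
_QS_BY_SEASON = [
    ("Beaverbrook", 4.23, 3.22),
    ("Billings Bridge-Alta Vista", 4.05, 3.56),
    ("Borden Farm-Stewart Farm-Parkwood Hills-Fisher Glen", 3.63, 3.38),
    ("CFB Rockcliffe-NRC", 3.81, 2.83),
    ("Carlington", 2.92, 3.02),
    ("Civic Hospital-Central Park", 3.50, 3.19),
    ("Emerald Woods-Sawmill Creek", 3.28, 3.07),
    ("Glen Cairn-Kanata South Business Park", 3.71, 2.91),
    ("Hunt Club Woods-Quintarra-Revelstoke", 3.89, 3.29),
    ("New Barrhaven-Stonebridge", 4.29, 3.37),
    ("Overbrook-McArthur", 3.10, 3.09),
    ("Playfair Park-Lynda Park-Guildwood Estates", 3.73, 3.74),
    ("Qualicum-Redwood Park", 3.61, 3.31),
    ("Rothwell Heights-Beacon Hill North", 3.85, 3.54),
    ("Vanier South", 3.02, 2.90),
]


def ssoi_instrument() -> Instrument:
    """The 10-item neighbourhood-aesthetics instrument."""
    return Instrument(
        item_ids=tuple(r[0] for r in _ITEM_WEIGHTS),
        labels=tuple(r[1] for r in _ITEM_WEIGHTS),
    )


def item_weight_table() -> pd.DataFrame:
    """Printed per-auditor and mean item weights, one row per item."""
    return pd.DataFrame(
        _ITEM_WEIGHTS,
        columns=["item_id", "label", "w_auditor_1", "w_auditor_2", "w_mean"],
    )


def auditor_weight_vectors() -> tuple[WeightVector, WeightVector]:
    """The two auditors' printed weight vectors (rounded; sum 1.001 each)."""
    ids = tuple(r[0] for r in _ITEM_WEIGHTS)
    w1 = [r[2] for r in _ITEM_WEIGHTS]
    w2 = [r[3] for r in _ITEM_WEIGHTS]
    return (
        WeightVector(ids, w1, source="auditor_1", sum_tolerance=5e-3),
        WeightVector(ids, w2, source="auditor_2", sum_tolerance=5e-3),
    )


def mean_weight_vector() -> WeightVector:
    """Printed Mean weight column (sums to 0.998), usable for literal scoring."""
    ids = tuple(r[0] for r in _ITEM_WEIGHTS)
    return WeightVector(
        ids, [r[4] for r in _ITEM_WEIGHTS], source="mean", sum_tolerance=5e-3
    )


def neighbourhood_scores_by_season() -> pd.DataFrame:
    """Q_s for the 15 neighbourhoods in both field seasons (2 dp, as printed)."""
    return pd.DataFrame(
        _QS_BY_SEASON, columns=["neighbourhood_id", "qs_2011", "qs_2012"]
    )
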