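"""Synthetic study regions and auditor responses for end-to-end testing.

No observation matrices from the original field deployment were deposited,
so every pipeline stage is exercised against a generator that emulates the
statistical structure the analysis assumes:

* neighbourhoods laid out as rectangular block grids in a projected
  pseudo-CRS (meters), partitioned into contiguous residential zoning
  strips (R1..R5, RM) according to a configurable area mix;
* a latent block aesthetics field: zone-type mean + a spatially
  autocorrelated Gaussian term (separable first-order autoregression over
  the block lattice, coefficient phi) + an optional mean shift over a
  contiguous "gentrified" western region, which reproduces the bimodal
  census histograms seen in partly gentrified neighbourhoods;
* two or more auditors rating each block on every instrument item: the
  continuous judgement is loading * latent + (1 - loading) * item-specific
  noise + auditor bias + auditor noise, discretized to the 1..5 Likert
  levels by fixed thresholds, with item-specific not-applicable rates
  (furniture items higher, as in the field data's smaller per-item n).

Defaults are chosen so the downstream reliability statistics land in the
0.6-0.9 range reported for field data of this kind; they are a plausible
emulation, not a fit to any deposited dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .datasets import ssoi_instrument
from .instrument import Instrument
from .sampling import ZoningMap
from .scoring import ObservationMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_study_region",
    "simulate_auditor_ratings",
    "simulate_census",
    "equicorrelated_matrix",
]

#: equal-probability standard-normal cut points between the 5 Likert levels
EQUAL_PROBABILITY_THRESHOLDS = (-0.8416212335729143, -0.2533471031357997,
                                0.2533471031357997, 0.8416212335729143)

DEFAULT_ZONE_MIX = {"R1": 0.35, "R2": 0.20, "R3": 0.20, "R4": 0.15, "R5": 0.10}
DEFAULT_ZONE_MU = {"R1": 0.8, "R2": 0.4, "R3": 0.0, "R4": -0.6, "R5": -0.9,
                   "RM": -0.2}


def _default_loadings() -> dict[str, float]:
    inst = ssoi_instrument()
    lam = {i: 0.5 for i in inst.item_ids}
    lam["furniture_presence"] = 0.4
    lam["furniture_quality"] = 0.4
    lam["pedestrian_infra"] = 0.25  # weak loading, mirrors its weak ITC
    return lam


def _default_na_rates() -> dict[str, float]:
    inst = ssoi_instrument()
    rates = {i: 0.01 for i in inst.item_ids}
    rates["furniture_presence"] = 0.2
    rates["furniture_quality"] = 0.2
    rates["pedestrian_infra"] = 0.03
    return rates


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic generator.

    Latent quantities live on a standard-normal-like scale and reach the
    1..5 Likert scale only through ``thresholds``.  ``zone_mix`` gives each
    zone type's share of a neighbourhood's blocks (contiguous strips);
    ``phi`` in [0, 1) is the lattice autoregression coefficient;
    ``gentrified_fraction``/``gentrified_shift`` define the contiguous
    western region receiving a latent mean shift (off by default).
    """

    n_neighbourhoods: int = 15
    blocks_x: int = 13
    blocks_y: int = 13
    block_size_m: float = 100.0
    zone_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ZONE_MIX))
    zone_mu: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ZONE_MU))
    field_sd: float = 1.0
    phi: float = 0.6
    gentrified_fraction: float = 0.0
    gentrified_shift: float = 0.0
    auditor_biases: Sequence[float] = (0.0, -0.1)
    auditor_sigmas: Sequence[float] = (0.5, 0.5)
    item_loadings: Mapping[str, float] = field(default_factory=_default_loadings)
    na_rates: Mapping[str, float] = field(default_factory=_default_na_rates)
    thresholds: Sequence[float] = EQUAL_PROBABILITY_THRESHOLDS

    def __post_init__(self) -> None:
        mix = dict(self.zone_mix)
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("zone_mix proportions must sum to 1")
        if not 0 <= self.phi < 1:
            raise ValueError("phi must be in [0, 1)")
        if any(s < 0 for s in self.auditor_sigmas):
            raise ValueError("auditor noise sd must be >= 0")
        if len(self.auditor_biases) != len(self.auditor_sigmas):
            raise ValueError("one bias and one sigma per auditor")
        th = tuple(self.thresholds)
        if len(th) != 4 or any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError(
                "thresholds must be 4 strictly increasing cut points")
        if any(lam <= 0 or lam > 1 for lam in self.item_loadings.values()):
            raise ValueError("item loadings must lie in (0, 1]")

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Latent ground truth per block, bit-reproducible from config + seed.

    ``blocks`` has one row per block: block_id, neighbourhood_id, zone_type,
    row, col, latent.  ``census_mean`` per neighbourhood is filled in by
    :func:`simulate_census` as the mean score of a full census audit (the
    estimand of the subsample design); it is NaN until then.
    """

    blocks: pd.DataFrame
    seed: int
    census_mean: pd.Series | None = None


def _strip_widths(ncols: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of grid columns to zone types."""
    types = sorted(mix)
    exact = {t: mix[t] * ncols for t in types}
    base = {t: int(np.floor(exact[t])) for t in types}
    rem = ncols - sum(base.values())
    order = sorted(types, key=lambda t: exact[t] - base[t], reverse=True)
    for t in order[:rem]:
        base[t] += 1
    zero = [t for t in types if base[t] == 0]
    if zero:
        raise ValueError(
            f"infeasible zone mix: type(s) {zero} receive zero blocks at "
            f"{ncols} columns; widen the grid or drop the type"
        )
    return base


def _ar_lattice(rng: np.random.Generator, shape: tuple[int, int], phi: float
                ) -> np.ndarray:
    """Separable first-order autoregressive Gaussian field, unit marginal sd."""
    f = rng.standard_normal(shape)
    if phi == 0:
        return f
    s = np.sqrt(1 - phi**2)
    for c in range(1, shape[1]):
        f[:, c] = phi * f[:, c - 1] + s * f[:, c]
    for r in range(1, shape[0]):
        f[r, :] = phi * f[r - 1, :] + s * f[r, :]
    return f


def generate_study_region(
    config: SyntheticConfig, seed: int = 0
) -> tuple[ZoningMap, dict[str, Polygon], SyntheticTruth]:
    """Build zoning polygons, block polygons and the latent aesthetics field.

    Neighbourhoods are laid out west to east with a gap; each is a
    blocks_x x blocks_y grid of square blocks, its columns split into
    contiguous zone-type strips per ``zone_mix``.  Geometry is emitted in a
    projected pseudo-CRS in meters (origin far from plausible lon/lat
    values so degree-like coordinates are never produced).
    """
    b = config.block_size_m
    widths = _strip_widths(config.blocks_x, config.zone_mix)
    types_sorted = sorted(widths)
    col_type: list[str] = []
    for t in types_sorted:
        col_type += [t] * widths[t]

    rng = np.random.default_rng(seed)
    origin_x, origin_y = 100_000.0, 100_000.0
    gap = 2 * b

    zones: dict[str, list[tuple[str, Polygon]]] = {}
    blocks: dict[str, Polygon] = {}
    rows = []
    for ni in range(config.n_neighbourhoods):
        nid = f"N{ni:02d}"
        x0 = origin_x + ni * (config.blocks_x * b + gap)
        y0 = origin_y
        # zone polygons: one rectangle per contiguous strip of equal type
        zones[nid] = []
        c = 0
        while c < config.blocks_x:
            t = col_type[c]
            c1 = c
            while c1 < config.blocks_x and col_type[c1] == t:
                c1 += 1
            zones[nid].append(
                (t, box(x0 + c * b, y0, x0 + c1 * b, y0 + config.blocks_y * b))
            )
            c = c1

        mu = np.array([[config.zone_mu[col_type[cc]]
                        for cc in range(config.blocks_x)]] * config.blocks_y)
        latent = mu + config.field_sd * _ar_lattice(
            rng, (config.blocks_y, config.blocks_x), config.phi)
        if config.gentrified_fraction > 0:
            west = int(round(config.gentrified_fraction * config.blocks_x))
            latent[:, :west] += config.gentrified_shift

        for r in range(config.blocks_y):
            for cc in range(config.blocks_x):
                bid = f"{nid}_B{r:02d}_{cc:02d}"
                blocks[bid] = box(
                    x0 + cc * b, y0 + r * b, x0 + (cc + 1) * b, y0 + (r + 1) * b
                )
                rows.append(
                    (bid, nid, col_type[cc], r, cc, latent[r, cc])
                )
    truth = SyntheticTruth(
        blocks=pd.DataFrame(
            rows,
            columns=["block_id", "neighbourhood_id", "zone_type", "row",
                     "col", "latent"],
        ).set_index("block_id"),
        seed=seed,
    )
    return ZoningMap(zones), blocks, truth


def simulate_auditor_ratings(
    truth: SyntheticTruth,
    instrument: Instrument | None = None,
    config: SyntheticConfig | None = None,
    seed: int = 0,
) -> list[ObservationMatrix]:
    """Simulate each auditor's ordinal responses over all blocks of ``truth``.

    The latent field is standardized over the region; auditor a's continuous
    judgement of item j at block b is

        u = lam_j * L~_b + (1 - lam_j) * e_bj + bias_a + N(0, sigma_a^2)

    with item noise e_bj shared between auditors (it belongs to the site x
    item pair), then discretized by the configured thresholds.
    Not-applicable flags are drawn per site x item (shared across auditors:
    applicability is a property of the place); a row that would lose every
    item keeps its most-applicable item.
    """
    config = config or SyntheticConfig()
    instrument = instrument or ssoi_instrument()
    items = instrument.item_ids
    lam = np.array([config.item_loadings[i] for i in items])
    na = np.array([config.na_rates.get(i, 0.0) for i in items])
    th = np.asarray(config.thresholds)

    latent = truth.blocks["latent"].to_numpy()
    lt = (latent - latent.mean()) / latent.std() if latent.std() > 0 else latent * 0.0
    n_blocks, n_items = latent.size, len(items)

    rng = np.random.default_rng(seed)
    item_noise = rng.standard_normal((n_blocks, n_items))
    na_mask = rng.random((n_blocks, n_items)) < na[None, :]
    # guard: never let a site lose all items
    all_na = na_mask.all(axis=1)
    if all_na.any():
        keep = int(np.argmin(na))
        na_mask[all_na, keep] = False

    out = []
    index = truth.blocks.index
    meta = pd.DataFrame(
        {
            "neighbourhood_id": truth.blocks["neighbourhood_id"],
            "auditor_id": "",
            "date": "synthetic",
        },
        index=index,
    )
    for ai, (bias, sigma) in enumerate(
        zip(config.auditor_biases, config.auditor_sigmas)
    ):
        u = (
            lam[None, :] * lt[:, None]
            + (1 - lam[None, :]) * item_noise
            + bias
            + sigma * rng.standard_normal((n_blocks, n_items))
        )
        x = 1.0 + np.searchsorted(th, u).reshape(u.shape)
        x = np.where(na_mask, np.nan, x)
        m = meta.copy()
        m["auditor_id"] = f"auditor_{ai + 1}"
        out.append(
            ObservationMatrix(pd.DataFrame(x, index=index, columns=items), m)
        )
    return out


def simulate_census(
    config: SyntheticConfig | None = None,
    seed: int = 0,
    weights=None,
    mode: str = "renormalized",
) -> dict:
    """Full census pipeline: region -> ratings -> combined scores per block.

    Returns a dict with the zoning map, block polygons, truth (census_mean
    filled with each neighbourhood's mean census score — the estimand of the
    subsample design), per-auditor observations, the combined matrix and the
    census :class:`~urbanaudit.scoring.ScoreSet`.
    """
    from .datasets import mean_weight_vector
    from .instrument import WeightVector
    from .scoring import combine_auditors, score_locations

    config = config or SyntheticConfig()
    zoning, blocks, truth = generate_study_region(config, seed=seed)
    obs = simulate_auditor_ratings(truth, config=config, seed=seed + 1)
    combined = combine_auditors(obs, policy="mean")
    if weights is None:
        printed = mean_weight_vector()
        w = printed.weights / printed.weights.sum()
        weights = WeightVector(printed.item_ids, w, source="mean")
    scores = score_locations(combined, weights, mode=mode)
    truth.census_mean = scores.neighbourhood_scores.copy()
    return {
        "zoning": zoning,
        "blocks": blocks,
        "truth": truth,
        "observations": obs,
        "combined": combined,
        "census_scores": scores,
        "weights": weights,
    }


def equicorrelated_matrix(
    n_units: int, n_items: int, rbar: float, seed: int = 0
) -> pd.DataFrame:
    """Continuous units x items matrix with exchangeable inter-item correlation.

    y_ij = sqrt(rbar) f_i + sqrt(1 - rbar) e_ij, so every item pair has
    population correlation ``rbar`` — the construction behind the
    Spearman-Brown limit alpha -> k rbar / (1 + (k-1) rbar).
    """
    if not 0 <= rbar < 1:
        raise ValueError("rbar must be in [0, 1)")
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((n_units, 1))
    e = rng.standard_normal((n_units, n_items))
    y = np.sqrt(rbar) * f + np.sqrt(1 - rbar) * e
    return pd.DataFrame(y, columns=[f"item_{j}" for j in range(n_items)])
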