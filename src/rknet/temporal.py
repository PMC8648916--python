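"""Temporal z-score decomposition of network dynamics.

For one facet of the design (a selection group x resource supply
combination, e.g. RK x H) the abundance x[i, j, k] of OTU k on sampling
day i in replicate microcosm j is reduced to a day mean

    x[i, ., k] = mean over replicates,

a series mean x[., ., k] over the N sampling days, a population standard
deviation sigma_k (1/N form), and the standardized score

    z[i, k] = (x[i, ., k] - x[., ., k]) / sigma_k.

Per OTU these z-scores have mean 0 and population SD 1, and the mean over
days of z[i, k] * z[i, l] equals the Pearson correlation of the two
day-mean series — so colouring an edge by the per-day product decomposes
the network's correlations across time.

When the underlying network was built from Spearman correlations the same
machinery runs on a rank basis: each OTU's trajectory is rank-transformed
across the sampling days within each microcosm before day means are taken.
With a single replicate the day-product mean is then exactly the Spearman
correlation of the two trajectories.

Styling rules (defaults): a node is black if z < -1 (below its average),
grey if -1 <= z <= 1 and orange if z > 1, with size a + b * |z|; an edge
is red if the product of its endpoints' z-scores is < -0.3 (contributing a
negative association), blue if > 0.3, grey otherwise.  OTUs with a
constant series (sigma_k = 0) are flagged and drawn grey at base size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .tables import AbundanceTable, SampleMetadata

__all__ = [
    "StyleConfig",
    "TemporalProfile",
    "day_mean",
    "zscores",
    "node_style",
    "edge_style",
    "correlation_identity_check",
    "compute_profile",
]


@dataclass(frozen=True)
class StyleConfig:
    """Node/edge styling constants (display units)."""

    a: float = 2.0  # base node size
    b: float = 2.0  # size gain per unit |z|
    node_z_cut: float = 1.0
    edge_product_cut: float = 0.3

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("size constants must be positive")


def day_mean(replicate_values) -> float:
    """Arithmetic mean over the replicates available on one day."""
    v = np.asarray(replicate_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan")
    return float(v.mean())


def zscores(day_means) -> np.ndarray:
    """Standardize a day-mean series with the population (1/N) SD.

    A constant series has sigma = 0 and yields all-NaN scores (the OTU is
    shown grey throughout).
    """
    x = np.asarray(day_means, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 sampling days")
    sigma = float(x.std())  # population form
    if sigma == 0 or not np.isfinite(sigma):
        return np.full(x.shape, np.nan)
    return (x - x.mean()) / sigma


def node_style(z: float, cfg: StyleConfig = StyleConfig()) -> tuple[str, float]:
    """Colour and size of a node given its z-score (grey at base size when
    the score is flagged missing)."""
    if not np.isfinite(z):
        return "grey", cfg.a
    if z < -cfg.node_z_cut:
        colour = "black"
    elif z > cfg.node_z_cut:
        colour = "orange"
    else:
        colour = "grey"
    return colour, cfg.a + cfg.b * abs(z)


def edge_style(z_k: float, z_l: float, cfg: StyleConfig = StyleConfig()) -> str:
    """Edge colour from the product of the endpoint z-scores (bounds
    inclusive for grey; flagged inputs give grey)."""
    if not (np.isfinite(z_k) and np.isfinite(z_l)):
        return "grey"
    product = z_k * z_l
    if product < -cfg.edge_product_cut:
        return "red"
    if product > cfg.edge_product_cut:
        return "blue"
    return "grey"


def correlation_identity_check(z_k, z_l) -> float:
    """Mean over days of z[i,k] * z[i,l]; equals the Pearson correlation of
    the two day-mean series (to numerical precision)."""
    z_k = np.asarray(z_k, dtype=float)
    z_l = np.asarray(z_l, dtype=float)
    if z_k.shape != z_l.shape:
        raise ValueError("z-score series must have the same number of days")
    if not (np.isfinite(z_k).all() and np.isfinite(z_l).all()):
        raise ValueError("z-score series contain flagged days")
    return float((z_k * z_l).mean())


@dataclass
class TemporalProfile:
    """Day means, series statistics and z-scores for one design facet."""

    facet: tuple[str, str]  # (selection_group, resource_supply)
    days: list[int]
    day_means: pd.DataFrame     # days x OTUs
    series_mean: pd.Series      # per OTU
    series_sd: pd.Series        # per OTU, population form
    z: pd.DataFrame             # days x OTUs, NaN where sigma = 0
    basis: str                  # raw | rank

    @property
    def n_days(self) -> int:
        return len(self.days)

    def node_styles(self, day: int, cfg: StyleConfig = StyleConfig()) -> pd.DataFrame:
        """Per-OTU colour and size on one sampling day."""
        zrow = self.z.loc[day]
        rows = {o: node_style(zrow[o], cfg) for o in self.z.columns}
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=["colour", "size"])

    def edge_styles(self, day: int, pairs, cfg: StyleConfig = StyleConfig()) -> pd.DataFrame:
        """Colour of each (otu_a, otu_b) edge on one sampling day."""
        zrow = self.z.loc[day]
        rows = [(a, b, edge_style(zrow.get(a, np.nan), zrow.get(b, np.nan), cfg))
                for a, b in pairs]
        return pd.DataFrame(rows, columns=["otu_a", "otu_b", "colour"])


def compute_profile(
    table: AbundanceTable,
    metadata: list[SampleMetadata],
    selection_group: str,
    resource_supply: str,
    basis: str = "raw",
) -> TemporalProfile:
    """Build the temporal profile for one facet of the design.

    With ``basis="rank"`` each OTU's abundance trajectory is replaced by
    its ranks across the facet's sampling days, computed within each
    microcosm, before replicate averaging; monotone transforms of the
    abundances then leave every output unchanged.
    """
    if basis not in ("raw", "rank"):
        raise ValueError(f"unknown basis {basis!r}")
    facet_meta = [m for m in metadata
                  if m.selection_group == selection_group
                  and m.resource_supply == resource_supply
                  and m.sample_id in table.sample_ids]
    if not facet_meta:
        raise ValueError(f"no samples for facet ({selection_group}, {resource_supply})")
    days = sorted({m.day for m in facet_meta})
    if len(days) < 2:
        raise ValueError("need at least 2 sampling days")
    microcosms = sorted({m.microcosm_id for m in facet_meta})
    day_index = {d: i for i, d in enumerate(days)}
    frame = table.to_frame()

    # values[day, microcosm, otu]; NaN marks a missing (microcosm, day)
    cube = np.full((len(days), len(microcosms), table.n_otus), np.nan)
    for m in facet_meta:
        cube[day_index[m.day], microcosms.index(m.microcosm_id)] = \
            frame.loc[m.sample_id].to_numpy()
    if basis == "rank":
        for j in range(len(microcosms)):
            present = ~np.isnan(cube[:, j, 0])
            if present.sum() >= 2:
                cube[present, j, :] = rankdata(cube[present, j, :], axis=0)

    with np.errstate(invalid="ignore"):
        dm = np.nanmean(cube, axis=1)  # days x OTUs
    day_means = pd.DataFrame(dm, index=days, columns=table.otu_ids)
    series_mean = day_means.mean(axis=0)
    series_sd = day_means.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        zmat = (day_means - series_mean) / series_sd.replace(0.0, np.nan)
    return TemporalProfile(
        facet=(selection_group, resource_supply), days=days,
        day_means=day_means, series_mean=series_mean, series_sd=series_sd,
        z=zmat, basis=basis)
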