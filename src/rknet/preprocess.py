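"""Abundance preprocessing: relative abundances, filtering and scaling.

The pipeline order is: counts -> relative abundances -> max-abundance
filtering at one of three named thresholds -> optional scaling to absolute
abundances by total cell density -> prevalence (``errthresh``) exclusion at
association time.  No correction for unequal sequencing depth is applied;
dividing by library size is the only compositional step.

The errthresh rule excludes an OTU from association testing when it is
absent (zero) in more than ``n * 10**(-4/n)`` of the ``n`` samples.  "More
than" is read strictly, so an OTU whose zero-count equals the cutoff is
kept.  Excluded OTUs are not discarded outright: their summed relative
mass per sample is recorded so permutation renormalization can preserve
the sum-to-constant constraint of compositional data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable

__all__ = [
    "FilterReport",
    "FILTER_LEVELS",
    "to_relative",
    "filter_by_max_abundance",
    "to_absolute",
    "errthresh_filter",
    "errthresh_cutoff",
]

#: Named max-abundance thresholds (as count proportions).
FILTER_LEVELS = {"high": 5e-3, "medium": 1e-3, "low": 5e-4}


@dataclass
class FilterReport:
    """Which OTUs a filter kept/dropped and the renormalization pool."""

    kept_otu_ids: list[str]
    dropped_otu_ids: list[str]
    threshold_used: float
    #: per-sample summed abundance of OTUs excluded by errthresh but kept
    #: for renormalization (same units as the filtered table; a fraction
    #: in [0, 1] for relative tables).  Empty for max-abundance filtering.
    residual_pool: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample's counts by its library size."""
    if table.kind != "counts":
        raise ValueError(f"expected a counts table, got kind={table.kind!r}")
    sums = table.values.sum(axis=1)
    if (sums == 0).any():
        bad = table.sample_ids[int(np.argmax(sums == 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    return AbundanceTable(table.values / sums[:, None], list(table.sample_ids),
                          list(table.otu_ids), "relative")


def filter_by_max_abundance(
    table: AbundanceTable, level: str | float = "low"
) -> tuple[AbundanceTable, FilterReport]:
    """Keep OTUs whose maximum relative abundance across samples reaches a
    threshold (named levels: high 5e-3, medium 1e-3, low 5e-4)."""
    if table.kind != "relative":
        raise ValueError("max-abundance filtering operates on relative abundances")
    threshold = FILTER_LEVELS[level] if isinstance(level, str) else float(level)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    maxima = table.values.max(axis=0)
    keep = maxima >= threshold
    kept = [o for o, k in zip(table.otu_ids, keep) if k]
    dropped = [o for o, k in zip(table.otu_ids, keep) if not k]
    return table.select_otus(kept), FilterReport(kept, dropped, threshold)


def to_absolute(table: AbundanceTable, densities: pd.Series) -> AbundanceTable:
    """Scale relative abundances by per-sample total cell density."""
    if table.kind != "relative":
        raise ValueError("absolute scaling starts from relative abundances")
    missing = [s for s in table.sample_ids if s not in densities.index]
    if missing:
        raise ValueError(f"no density estimate for samples: {missing[:5]}")
    d = densities.loc[table.sample_ids].to_numpy(dtype=float)
    if (d <= 0).any() or not np.isfinite(d).all():
        bad = table.sample_ids[int(np.argmax((d <= 0) | ~np.isfinite(d)))]
        raise ValueError(f"non-positive density for sample {bad!r}")
    return AbundanceTable(table.values * d[:, None], list(table.sample_ids),
                          list(table.otu_ids), "absolute")


def errthresh_cutoff(n_samples: int) -> float:
    """Maximum tolerated zero-count: ``n * 10**(-4/n)`` for n samples."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    return n_samples * 10.0 ** (-4.0 / n_samples)


def errthresh_filter(table: AbundanceTable) -> tuple[AbundanceTable, FilterReport]:
    """Exclude OTUs absent in more than ``n * 10**(-4/n)`` samples.

    Returns the table restricted to testable OTUs plus a report whose
    ``residual_pool`` holds, per sample, the summed abundance of the
    excluded OTUs (used when permutations are renormalized).
    """
    cutoff = errthresh_cutoff(table.n_samples)
    zeros = (table.values == 0).sum(axis=0)
    keep = zeros <= cutoff  # strictly more than the cutoff excludes
    kept = [o for o, k in zip(table.otu_ids, keep) if k]
    dropped = [o for o, k in zip(table.otu_ids, keep) if not k]
    residual = pd.Series(table.values[:, ~keep].sum(axis=1),
                         index=table.sample_ids, name="residual_pool")
    return table.select_otus(kept), FilterReport(kept, dropped, cutoff, residual)
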