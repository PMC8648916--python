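"""Community-level analyses: Bray-Curtis PCoA and sequential PERMANOVA.

Ordination embeds the samples by classical scaling of their Bray-Curtis
distances; the trajectory export attaches the design facets (current
selection regime x resource supply) so each microcosm's path through the
ordination can be drawn in chronological order.

The PERMANOVA follows the sequential (Type-I) adonis decomposition of
McArdle & Anderson: from the Gower-centred matrix G of the dissimilarities
the sum of squares explained by each term is tr((H_t - H_{t-1}) G), where
H_t is the hat matrix of the design including the first t factors.
Significance uses free permutation of the samples,
``p = (#{F_perm >= F_obs} + 1) / (permutations + 1)``.  In the study
design the dissimilarity is one minus the Spearman correlation between
sample profiles and the factors are the selection group followed by the
current selection regime, on the samples from just before the crossover
(day 28) and the end of the experiment (day 50).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

from .tables import AbundanceTable, SampleMetadata

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "bray_curtis",
    "pcoa",
    "spearman_dissimilarity",
    "permanova_sequential",
    "regime_permanova",
    "trajectory_table",
]


@dataclass
class OrdinationResult:
    """PCoA embedding: sample coordinates on the positive-eigenvalue axes."""

    coordinates: pd.DataFrame      # samples x axes (PC1, PC2, ...)
    eigenvalues: np.ndarray        # positive eigenvalues, descending
    proportion_explained: np.ndarray


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table (terms in model order, then residual and
    total rows) with columns df, SS, F, R2, p."""

    table: pd.DataFrame
    permutations: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis distances between samples,
    d(a, b) = sum|x_a - x_b| / sum(x_a + x_b)."""
    if (table.values.sum(axis=1) == 0).any():
        bad = table.sample_ids[int(np.argmax(table.values.sum(axis=1) == 0))]
        raise ValueError(f"sample {bad!r} is all zero")
    d = squareform(pdist(table.values, metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


def pcoa(dist: DistanceMatrix | np.ndarray, ids=None) -> OrdinationResult:
    """Classical scaling (principal coordinates analysis) of a distance
    matrix: eigendecomposition of the double-centred Gower matrix.

    Axes with negative eigenvalues (non-Euclidean input, common for
    Bray-Curtis) are dropped with a warning and excluded from the
    proportion-explained denominator.
    """
    if isinstance(dist, DistanceMatrix):
        D = dist.data
        ids = list(dist.ids)
    else:
        D = np.asarray(dist, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(D.shape[0])]
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    eig, vec = np.linalg.eigh(_gower(D))
    order = np.argsort(-eig, kind="stable")
    eig, vec = eig[order], vec[:, order]
    tol = 1e-12 * max(1.0, float(np.abs(eig).max(initial=0.0)))
    if (eig < -tol).any():
        warnings.warn("distance matrix is non-Euclidean; dropping "
                      f"{int((eig < -tol).sum())} negative-eigenvalue axes")
    keep = eig > tol
    eig_pos = eig[keep]
    coords = vec[:, keep] * np.sqrt(eig_pos)
    frame = pd.DataFrame(coords, index=ids,
                         columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    return OrdinationResult(frame, eig_pos, eig_pos / eig_pos.sum())


def spearman_dissimilarity(table: AbundanceTable) -> pd.DataFrame:
    """One minus the Spearman correlation between sample profiles,
    as a labelled samples x samples matrix (range [0, 2]; a constant
    profile gives flagged NaN entries).

    This is a dissimilarity, not a metric distance, so it is returned as a
    plain DataFrame rather than a strict distance-matrix container.
    """
    if table.n_otus < 2:
        raise ValueError("need at least 2 OTUs")
    R = np.asarray(rankdata(table.values, axis=1), dtype=float)
    Rc = R - R.mean(axis=1, keepdims=True)
    norms = np.sqrt((Rc * Rc).sum(axis=1))
    if (norms == 0).any():
        warnings.warn("constant sample profile(s); dissimilarities flagged NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Rc @ Rc.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def _hat(design: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(design)
    return q @ q.T


def permanova_sequential(
    dist: DistanceMatrix | np.ndarray,
    factors: pd.DataFrame,
    permutations: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA of a distance matrix on ordered factors.

    ``factors`` columns enter the model in order; every factor must have at
    least two levels.  Free permutation of sample identities is used.
    """
    if isinstance(dist, DistanceMatrix):
        D, ids = dist.data, list(dist.ids)
    elif isinstance(dist, pd.DataFrame):
        D, ids = dist.to_numpy(dtype=float), [str(i) for i in dist.index]
    else:
        D, ids = np.asarray(dist, dtype=float), None
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, equal_nan=True):
        raise ValueError("distance matrix must be square and symmetric")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains flagged (NaN) entries")
    if ids is not None:
        factors = factors.loc[ids]
    if len(factors) != n:
        raise ValueError("factor table does not match the distance matrix")
    terms = list(factors.columns)
    for t in terms:
        if factors[t].nunique() < 2:
            raise ValueError(f"factor {t!r} has fewer than two levels")

    G = _gower(D)
    # nested hat matrices: intercept, then cumulative factor designs
    designs = [np.ones((n, 1))]
    X = np.ones((n, 1))
    dfs = []
    for t in terms:
        dummies = pd.get_dummies(factors[t], drop_first=True).to_numpy(dtype=float)
        X = np.hstack([X, dummies])
        dfs.append(dummies.shape[1])
        designs.append(X.copy())
    hats = [_hat(X) for X in designs]
    df_res = n - designs[-1].shape[1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def stats(Gm: np.ndarray):
        ss_terms = np.array([np.sum((hats[i + 1] - hats[i]) * Gm)
                             for i in range(len(terms))])
        ss_res = np.sum((np.eye(n) - hats[-1]) * Gm)
        F = (ss_terms / np.asarray(dfs)) / (ss_res / df_res)
        return ss_terms, ss_res, F

    ss_terms, ss_res, F_obs = stats(G)
    ss_total = np.sum((np.eye(n) - hats[0]) * G)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(permutations):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        _, _, Fp = stats(Gp)
        exceed += Fp >= F_obs
    pvals = (exceed + 1.0) / (permutations + 1.0)

    rows = []
    for i, t in enumerate(terms):
        rows.append((t, dfs[i], ss_terms[i], F_obs[i], ss_terms[i] / ss_total, pvals[i]))
    rows.append(("Residual", df_res, ss_res, np.nan, ss_res / ss_total, np.nan))
    rows.append(("Total", n - 1, ss_total, np.nan, 1.0, np.nan))
    tab = pd.DataFrame(rows, columns=["term", "df", "SS", "F", "R2", "p"]).set_index("term")
    return PermanovaResult(tab, permutations)


def _gower(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def regime_permanova(
    table: AbundanceTable,
    metadata: list[SampleMetadata],
    days: tuple[int, ...] = (28, 50),
    permutations: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """Study-design PERMANOVA: 1 - Spearman dissimilarity of the samples
    from the given days (defaults: just before the crossover and the end),
    with selection group entered first and current regime second."""
    keep = [m for m in metadata if m.day in days and m.sample_id in table.sample_ids]
    if not keep:
        raise ValueError(f"no samples on days {days}")
    sub = table.select_samples([m.sample_id for m in keep])
    dist = spearman_dissimilarity(sub)
    factors = pd.DataFrame(
        {"selection_group": [m.selection_group for m in keep],
         "current_regime": [m.current_regime for m in keep]},
        index=[m.sample_id for m in keep])
    return permanova_sequential(dist, factors, permutations=permutations, seed=seed)


def trajectory_table(
    ordination: OrdinationResult, metadata: list[SampleMetadata], n_axes: int = 2
) -> pd.DataFrame:
    """Tidy per-sample table for trajectory plotting: ordination
    coordinates joined with microcosm, day, facet keys (current regime x
    resource supply), ordered chronologically within each microcosm."""
    meta = {m.sample_id: m for m in metadata}
    missing = [s for s in ordination.coordinates.index if s not in meta]
    if missing:
        raise ValueError(f"no metadata for samples: {missing[:5]}")
    axes = ordination.coordinates.iloc[:, :n_axes]
    rows = []
    for sample_id, coords in axes.iterrows():
        m = meta[sample_id]
        rows.append({"sample_id": sample_id, "microcosm_id": m.microcosm_id,
                     "day": m.day, "selection_group": m.selection_group,
                     "resource_supply": m.resource_supply,
                     "current_regime": m.current_regime,
                     **coords.to_dict()})
    return (pd.DataFrame(rows)
            .sort_values(["microcosm_id", "day"])
            .reset_index(drop=True))
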