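"""ReBoot significance testing of pairwise OTU associations.

For every unordered pair of OTUs the procedure contrasts two empirical
distributions of a similarity measure (Pearson or Spearman correlation,
optionally with Gaussian noise injected to break double-zero artefacts):

* a **bootstrap** distribution, obtained by resampling samples with
  replacement and recomputing the (noisy) similarity, and
* a **permutation** null, obtained by independently permuting each OTU's
  values across samples.  For relative abundances the permuted table can be
  renormalized — each sample is re-divided by its new total, including a
  residual pool of low-prevalence OTUs held out of testing — so the
  permuted data respect the sum-to-constant constraint of compositions.

The two distributions are compared with a two-sided Z-test and the
resulting p-values are adjusted with the Benjamini-Yekutieli step-up
procedure, which controls the FDR under dependence.

Z-statistic variants
--------------------
``z_variant="perm"`` (default) divides the mean difference by the
permutation SD alone, ``z = (boot_mean - perm_mean) / perm_sd``; under a
true null this is close to the observed correlation over its null sampling
SD and holds the nominal type-I error rate.  ``z_variant="pooled"`` uses
``sqrt(boot_sd**2 + perm_sd**2)`` and is conservative by roughly sqrt(2)
(the bootstrap and null SDs nearly coincide under the null).  Both are
exposed because published descriptions of the test do not pin the form
down; see docs/methods.md.

Injected noise has SD ``gamma = s * x_min`` where ``s`` is the magnitude
factor and ``x_min`` the smallest nonzero relative abundance in the
dataset.  Named levels: none (s=0), low (s=1), medium (s=10), high (s=100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable

__all__ = [
    "NOISE_LEVELS",
    "SimilaritySpec",
    "AssociationResult",
    "similarity",
    "noisy_similarity",
    "reboot",
    "adjust_q",
    "zscore_test",
    "results_to_frame",
]

NOISE_LEVELS = {"none": 0.0, "low": 1.0, "medium": 10.0, "high": 100.0}


@dataclass(frozen=True)
class SimilaritySpec:
    """Similarity measure plus noise-magnitude specification.

    ``gamma``, the SD of the injected Gaussian noise, is exactly
    ``magnitude_factor * x_min``; a magnitude factor of 0 means no noise
    and ``x_min`` may then be omitted.
    """

    measure: str = "spearman"  # pearson | spearman
    magnitude_factor: float = 0.0
    x_min: float | None = None

    def __post_init__(self) -> None:
        if self.measure not in ("pearson", "spearman"):
            raise ValueError(f"unknown similarity measure {self.measure!r}")
        if self.magnitude_factor < 0:
            raise ValueError("magnitude factor must be >= 0")
        if self.magnitude_factor > 0 and (self.x_min is None or self.x_min <= 0):
            raise ValueError("noisy similarity needs x_min > 0")

    @property
    def gamma(self) -> float:
        if self.magnitude_factor == 0:
            return 0.0
        return self.magnitude_factor * self.x_min

    @classmethod
    def for_table(cls, table: AbundanceTable, measure: str = "spearman",
                  noise: str | float = "none") -> "SimilaritySpec":
        """Build a spec with ``x_min`` taken from the table's smallest
        nonzero value (the smallest nonzero relative abundance when the
        table is relative).  ``noise`` is a named level or a magnitude
        factor."""
        s = NOISE_LEVELS[noise] if isinstance(noise, str) else float(noise)
        x_min = None
        if s > 0:
            nonzero = table.values[table.values > 0]
            if nonzero.size == 0:
                raise ValueError("table has no nonzero values; cannot set x_min")
            x_min = float(nonzero.min())
        return cls(measure=measure, magnitude_factor=s, x_min=x_min)


@dataclass
class AssociationResult:
    """ReBoot outcome for one unordered OTU pair."""

    otu_a: str
    otu_b: str
    similarity: float
    boot_mean: float
    boot_sd: float
    perm_mean: float
    perm_sd: float
    z: float
    p: float
    q: float

    @property
    def sign(self) -> str:
        return "+" if self.z >= 0 else "-"


def _corr_matrix(X: np.ndarray, measure: str) -> np.ndarray:
    """Correlation matrix over columns; NaN where a column is constant.

    Spearman uses average ranks for ties.
    """
    if measure == "spearman":
        X = rankdata(X, axis=0)
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc * Xc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc.T @ Xc) / np.outer(norms, norms)
    return np.clip(R, -1.0, 1.0)


def similarity(x: np.ndarray, y: np.ndarray, measure: str = "spearman") -> float:
    """Pearson or Spearman correlation; NaN for a constant input vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    return float(_corr_matrix(np.column_stack([x, y]), measure)[0, 1])


def noisy_similarity(x: np.ndarray, y: np.ndarray, spec: SimilaritySpec,
                     rng: np.random.Generator) -> float:
    """Similarity after adding fresh i.i.d. Gaussian noise (SD = gamma) to
    every component of both vectors.  With magnitude factor 0 this is
    bitwise identical to :func:`similarity`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gamma = spec.gamma
    if gamma > 0:
        x = x + rng.normal(0.0, gamma, size=x.shape)
        y = y + rng.normal(0.0, gamma, size=y.shape)
    return similarity(x, y, spec.measure)


def zscore_test(boot_mean: float, boot_sd: float, perm_mean: float,
                perm_sd: float, variant: str = "perm") -> tuple[float, float]:
    """Two-sided Z-test comparing bootstrap and permutation distributions.

    Returns ``(z, p)`` with ``p = 2 * Phi(-|z|)``; ``(nan, nan)`` when the
    denominator is zero (pair skipped downstream).  ``variant="perm"``
    divides by ``perm_sd``; ``variant="pooled"`` by
    ``sqrt(boot_sd**2 + perm_sd**2)``.
    """
    if variant == "pooled":
        denom = float(np.hypot(boot_sd, perm_sd))
    elif variant == "perm":
        denom = float(perm_sd)
    else:
        raise ValueError(f"unknown z variant {variant!r}")
    if not np.isfinite(denom) or denom <= 0:
        return float("nan"), float("nan")
    z = (boot_mean - perm_mean) / denom
    return float(z), float(2.0 * norm.sf(abs(z)))


def adjust_q(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli step-up q-values (correction factor
    ``c(m) = sum_{k=1..m} 1/k``), capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def _accumulate(acc: dict, r: np.ndarray) -> None:
    finite = np.isfinite(r)
    r0 = np.where(finite, r, 0.0)
    acc["n"] += finite
    acc["sum"] += r0
    acc["sumsq"] += r0 * r0


def _mean_sd(acc: dict) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(invalid="ignore", divide="ignore"):
        n = acc["n"].astype(float)
        mean = acc["sum"] / n
        var = (acc["sumsq"] - n * mean * mean) / (n - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    bad = acc["n"] < 2
    mean[bad] = np.nan
    sd[bad] = np.nan
    return mean, sd


def reboot(
    table: AbundanceTable,
    spec: SimilaritySpec,
    iterations: int = 1000,
    renormalize: bool = False,
    residual_pool: pd.Series | None = None,
    seed: int | np.random.Generator | None = None,
    z_variant: str = "perm",
) -> list[AssociationResult]:
    """Run ReBoot over every unordered OTU pair of ``table``.

    Bootstrap and permutation phases each use ``iterations`` independent
    draws, with fresh noise injected inside every iteration.  Pairs whose
    point similarity is undefined (constant vector) or whose Z denominator
    vanishes are excluded from the output and from the multiple-testing
    family.  Pass an integer ``seed`` (or a Generator) for reproducibility.
    """
    if iterations < 100:
        raise ValueError("need at least 100 iterations")
    if renormalize and table.kind != "relative":
        raise ValueError("permutation renormalization is only meaningful for "
                         f"relative abundances (table kind is {table.kind!r})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = table.values
    n, m = X.shape
    if m < 2:
        raise ValueError("need at least two OTUs")
    residual = np.zeros(n)
    if renormalize and residual_pool is not None:
        residual = residual_pool.reindex(table.sample_ids).fillna(0.0).to_numpy()

    iu = np.triu_indices(m, 1)
    point = _corr_matrix(X, spec.measure)[iu]
    gamma = spec.gamma

    def new_acc():
        npairs = iu[0].size
        return {"n": np.zeros(npairs, dtype=np.int64),
                "sum": np.zeros(npairs), "sumsq": np.zeros(npairs)}

    boot = new_acc()
    for _ in range(iterations):
        Xb = X[rng.integers(0, n, size=n)]
        if gamma > 0:
            Xb = Xb + rng.normal(0.0, gamma, size=Xb.shape)
        _accumulate(boot, _corr_matrix(Xb, spec.measure)[iu])

    perm = new_acc()
    for _ in range(iterations):
        order = rng.random((n, m)).argsort(axis=0)
        Xp = np.take_along_axis(X, order, axis=0)
        if renormalize:
            totals = Xp.sum(axis=1) + residual[rng.permutation(n)]
            with np.errstate(invalid="ignore", divide="ignore"):
                Xp = Xp / totals[:, None]
        if gamma > 0:
            Xp = Xp + rng.normal(0.0, gamma, size=Xp.shape)
        _accumulate(perm, _corr_matrix(Xp, spec.measure)[iu])

    boot_mean, boot_sd = _mean_sd(boot)
    perm_mean, perm_sd = _mean_sd(perm)
    if z_variant == "pooled":
        denom = np.hypot(boot_sd, perm_sd)
    elif z_variant == "perm":
        denom = perm_sd
    else:
        raise ValueError(f"unknown z variant {z_variant!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (boot_mean - perm_mean) / denom
    valid = np.isfinite(point) & np.isfinite(z) & (denom > 0)
    p = 2.0 * norm.sf(np.abs(z[valid]))
    q = adjust_q(p)

    results: list[AssociationResult] = []
    idx_a, idx_b = iu[0][valid], iu[1][valid]
    pt, bm, bs = point[valid], boot_mean[valid], boot_sd[valid]
    pm, ps, zz = perm_mean[valid], perm_sd[valid], z[valid]
    for k in range(idx_a.size):
        results.append(AssociationResult(
            otu_a=table.otu_ids[idx_a[k]], otu_b=table.otu_ids[idx_b[k]],
            similarity=float(pt[k]), boot_mean=float(bm[k]), boot_sd=float(bs[k]),
            perm_mean=float(pm[k]), perm_sd=float(ps[k]),
            z=float(zz[k]), p=float(p[k]), q=float(q[k])))
    return results


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten association results into a tidy table (one row per pair)."""
    return pd.DataFrame([{
        "otu_a": r.otu_a, "otu_b": r.otu_b, "similarity": r.similarity,
        "boot_mean": r.boot_mean, "boot_sd": r.boot_sd,
        "perm_mean": r.perm_mean, "perm_sd": r.perm_sd,
        "z": r.z, "p": r.p, "q": r.q, "sign": r.sign,
    } for r in results])
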