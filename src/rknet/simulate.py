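"""Synthetic selection-switch microcosm generator with planted guild structure.

The generator emulates the processed data of a 2 x 2 factorial crossover
microcosm experiment: 12 microcosms (selection group RK/KR x resource
supply H/L x 3 replicates) sampled at 17 days within 1..50, with the
selection regime switched between days 28 and 29.  OTUs belong to one of
three guilds: K-strategists (favoured under continuous feeding /
K-selection), r-strategists (favoured under pulse feeding / r-selection)
and neutral taxa.

For microcosm j and day i the latent log-abundance of OTU k is

    log a[i, j, k] = baseline_k + guild_effect * favoured(k, regime(i, j))
                     + e[i, j, k]

where ``favoured`` is +1 when the active regime matches the guild, -1 when
it opposes it and 0 for neutral OTUs, and ``e`` is a stationary AR(1)
process on the log scale (lag coefficient ``ar_coef``, marginal SD
``noise_sd``).  Read counts are drawn multinomially with probabilities
proportional to exp(latent) and a lognormally varying library size; the
flow-cytometry-style total density scales with the summed latent abundance.
Because the design is a crossover, swapping the RK/KR labels of every
microcosm while swapping the r/K guild labels leaves the latent mean
structure unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .tables import AbundanceTable, SampleMetadata, current_regime

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_experiment",
    "guild_recovery_score",
    "DEFAULT_DAYS",
]

#: Default sampling days: 17 points in 1..50 with the regime switch falling
#: between days 28 and 29, mirroring the crossover design's halfway point.
DEFAULT_DAYS = (1, 4, 7, 10, 13, 16, 19, 22, 25, 28, 29, 32, 36, 40, 44, 47, 50)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic crossover experiment.

    guild_effect is the log-scale abundance shift a guild experiences under
    its favoured regime (and -guild_effect under the opposing one);
    noise_sd is the marginal SD of the AR(1) temporal noise on the log
    scale; depth is the expected reads per sample; density_base the
    expected total cells per mL at average community size.
    """

    n_k_otus: int = 30
    n_r_otus: int = 30
    n_neutral_otus: int = 20
    n_microcosms: int = 12
    days: tuple[int, ...] = DEFAULT_DAYS
    depth: int = 60_000
    guild_effect: float = 2.0
    noise_sd: float = 0.6
    ar_coef: float = 0.5
    baseline_sd: float = 1.5
    depth_log_sd: float = 0.3
    density_base: float = 1e7
    disturbance_pulse: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_k_otus, self.n_r_otus, self.n_neutral_otus) < 0:
            raise ValueError("OTU counts must be >= 0")
        if self.n_k_otus + self.n_r_otus + self.n_neutral_otus == 0:
            raise ValueError("need at least one OTU")
        if self.n_microcosms <= 0 or not self.days:
            raise ValueError("need at least one microcosm and one sampling day")
        if self.n_microcosms != 12:
            raise ValueError("the 2x2 factorial design with 3 replicates needs "
                             "exactly 12 microcosms")
        if self.guild_effect < 0:
            raise ValueError("guild_effect must be >= 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if list(self.days) != sorted(set(self.days)):
            raise ValueError("days must be strictly increasing")


@dataclass
class SyntheticTruth:
    """Planted guild membership, the recovery target for module detection."""

    guilds: dict[str, str]  # otu_id -> K | r | neutral

    @property
    def expected_partition(self) -> tuple[set[str], set[str]]:
        k = {o for o, g in self.guilds.items() if g == "K"}
        r = {o for o, g in self.guilds.items() if g == "r"}
        return k, r


def _microcosm_design(n_microcosms: int) -> list[tuple[str, str, int]]:
    assert n_microcosms == 12
    return [(group, supply, rep)
            for group in ("RK", "KR")
            for supply in ("H", "L")
            for rep in (1, 2, 3)]


def generate_experiment(
    config: SimulationConfig,
) -> tuple[AbundanceTable, list[SampleMetadata], pd.Series, SyntheticTruth]:
    """Simulate one crossover experiment.

    Returns the count table (samples x OTUs), the sample metadata, the
    per-sample total-density estimates and the planted guild truth.
    Identical configs (including seed) give bitwise-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    guild_list = (["K"] * cfg.n_k_otus + ["r"] * cfg.n_r_otus
                  + ["neutral"] * cfg.n_neutral_otus)
    n_otus = len(guild_list)
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(n_otus)]
    truth = SyntheticTruth(dict(zip(otu_ids, guild_list)))
    # favoured(k, regime) as a vector per regime
    sign = {"K": 1.0, "r": -1.0, "neutral": 0.0}
    guild_sign = np.array([sign[g] for g in guild_list])  # +1 = K-leaning

    baselines = rng.normal(0.0, cfg.baseline_sd, size=n_otus)
    days = np.asarray(cfg.days)
    n_days = len(days)

    metadata: list[SampleMetadata] = []
    rows: list[np.ndarray] = []
    totals: list[float] = []
    sample_ids: list[str] = []
    for group, supply, rep in _microcosm_design(cfg.n_microcosms):
        microcosm = f"{group}-{supply}{rep}"
        # stationary AR(1) on the log scale, one trajectory per OTU
        e = np.empty((n_days, n_otus))
        e[0] = rng.normal(0.0, cfg.noise_sd, size=n_otus)
        innov_sd = cfg.noise_sd * np.sqrt(1.0 - cfg.ar_coef**2)
        for i in range(1, n_days):
            e[i] = cfg.ar_coef * e[i - 1] + rng.normal(0.0, innov_sd, size=n_otus)
        for i, day in enumerate(days):
            regime = current_regime(group, int(day))
            favoured = guild_sign if regime == "K" else -guild_sign
            latent = baselines + cfg.guild_effect * favoured + e[i]
            if cfg.disturbance_pulse and (day == days[0] or
                                          (day > 28 and days[max(i - 1, 0)] <= 28)):
                latent = latent + rng.normal(0.0, cfg.noise_sd, size=n_otus)
            weights = np.exp(latent)
            total = float(weights.sum())
            library = max(1, int(np.round(
                np.exp(rng.normal(np.log(cfg.depth), cfg.depth_log_sd)))))
            counts = rng.multinomial(library, weights / total)
            sample_id = f"{microcosm}_d{int(day)}"
            metadata.append(SampleMetadata(
                sample_id=sample_id, microcosm_id=microcosm, day=int(day),
                selection_group=group, resource_supply=supply, replicate=rep))
            sample_ids.append(sample_id)
            rows.append(counts)
            totals.append(total)

    counts = AbundanceTable(np.array(rows, dtype=float), sample_ids, otu_ids, "counts")
    totals_arr = np.asarray(totals)
    density = pd.Series(cfg.density_base * totals_arr / totals_arr.mean(),
                        index=sample_ids, name="density")
    return counts, metadata, density, truth


def guild_recovery_score(detected_modules: dict[str, object],
                         truth: SyntheticTruth) -> float:
    """Adjusted Rand index between detected modules and planted guilds.

    Only OTUs present in both partitions are scored; OTUs without a module
    assignment (``None`` label) are excluded.
    """
    common = [o for o, m in detected_modules.items()
              if m is not None and o in truth.guilds]
    if not common:
        raise ValueError("no overlap between detected modules and planted guilds")
    detected = [str(detected_modules[o]) for o in common]
    planted = [truth.guilds[o] for o in common]
    return float(adjusted_rand_score(planted, detected))
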