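"""End-to-end convenience wrapper: counts -> significant co-occurrence network.

Chains the standard stages in the study's order: relative abundances,
max-abundance filtering, optional absolute scaling, prevalence
(errthresh) exclusion, ReBoot association testing, edge selection and
walktrap module detection.  Each stage remains individually importable;
this wrapper only fixes the plumbing between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import preprocess
from .network import CooccurrenceNetwork, build_network, detect_modules, select_edges
from .reboot import AssociationResult, SimilaritySpec, reboot
from .tables import AbundanceTable, TaxonomyTable

__all__ = ["NetworkPipelineResult", "infer_network"]


@dataclass
class NetworkPipelineResult:
    network: CooccurrenceNetwork
    modules: dict[str, int | None]
    associations: list[AssociationResult]
    edges: list[AssociationResult]
    effective_q: float
    filter_report: preprocess.FilterReport
    errthresh_report: preprocess.FilterReport


def infer_network(
    counts: AbundanceTable,
    densities: pd.Series | None = None,
    filter_level: str | float = "low",
    abundance: str = "relative",
    measure: str = "spearman",
    noise: str | float = "low",
    iterations: int = 1000,
    renormalize: bool | None = None,
    edge_mode: str = "top_k",
    k: int = 500,
    q_max: float = 0.05,
    steps: int = 20,
    taxonomy: TaxonomyTable | None = None,
    seed: int | None = None,
    z_variant: str = "perm",
) -> NetworkPipelineResult:
    """Run the full network-inference pipeline on a count table.

    ``abundance`` selects whether associations are computed on relative or
    absolute abundances (the latter requires per-sample ``densities``).
    ``renormalize`` defaults to True for relative abundances and must be
    False for absolute ones.  The noise magnitude ``gamma`` is always
    derived from the *relative* table's smallest nonzero value.
    """
    if abundance not in ("relative", "absolute"):
        raise ValueError(f"unknown abundance type {abundance!r}")
    rel = preprocess.to_relative(counts)
    rel_f, filt_report = preprocess.filter_by_max_abundance(rel, filter_level)
    spec = SimilaritySpec.for_table(rel_f, measure=measure, noise=noise)
    if abundance == "absolute":
        if densities is None:
            raise ValueError("absolute abundances need per-sample densities")
        working = preprocess.to_absolute(rel_f, densities)
        if renormalize:
            raise ValueError("renormalization applies to relative abundances only")
        renormalize = False
    else:
        working = rel_f
        if renormalize is None:
            renormalize = True
    tested, err_report = preprocess.errthresh_filter(working)
    results = reboot(tested, spec, iterations=iterations, renormalize=renormalize,
                     residual_pool=err_report.residual_pool, seed=seed,
                     z_variant=z_variant)
    edges, effective_q = select_edges(results, mode=edge_mode, k=k, q_max=q_max)
    net = build_network(
        edges,
        abundance=working if abundance == "absolute" else None,
        relative=rel_f,
        taxonomy=taxonomy,
    )
    modules = detect_modules(net, steps=steps)
    return NetworkPipelineResult(net, modules, results, edges, effective_q,
                                 filt_report, err_report)
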