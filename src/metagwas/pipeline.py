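"""End-to-end composition: contexts -> per-context scans -> meta -> QTL."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .genotype import GenotypeMatrix, KinshipMatrix, compute_kinship
from .lmm import run_context_gwas
from .meta import MetaAnalysis, TCorrelation, build_t_matrix, bonferroni_threshold
from .phenotype import (
    MIN_CONTEXT_SAMPLES,
    ContextVector,
    aggregate_replicates,
    derive_ri_contexts,
)
from .qtl import QTLCluster, cluster_qtl

logger = logging.getLogger(__name__)

__all__ = ["TraitMetaResult", "gwas_all_contexts", "meta_per_trait", "run_full_analysis"]


@dataclass
class TraitMetaResult:
    """Bundle of meta-GWAS outputs for one trait."""

    trait: str
    results: pd.DataFrame                  # chi2, df, p, neglog10p, class + map
    t_correlation: TCorrelation
    contexts: list
    n_tests: int
    bonferroni_neglog10: float
    qtl: list[QTLCluster] = field(default_factory=list)


def gwas_all_contexts(
    G: GenotypeMatrix,
    contexts: Mapping[tuple, ContextVector],
    K: KinshipMatrix | None = None,
    min_samples: int = MIN_CONTEXT_SAMPLES,
) -> dict[tuple, pd.DataFrame]:
    """Run the mixed-model scan for every context with enough phenotypes."""
    if K is None:
        K = compute_kinship(G)
    out = {}
    for ctx, vec in contexts.items():
        if vec.n_valid < min_samples:
            logger.warning("context %s skipped: only %d phenotyped accessions",
                           ctx, vec.n_valid)
            continue
        out[ctx] = run_context_gwas(G, vec, K, min_samples=min_samples)
    return out


def meta_per_trait(
    assoc: Mapping[tuple, pd.DataFrame],
    alpha: float = 0.05,
    suggestive_p: float = 1e-4,
    min_pairs: int = 100,
) -> dict[str, TraitMetaResult]:
    """Group per-context scans by trait and combine each trait's t-values."""
    by_trait: dict[str, dict] = {}
    for ctx, table in assoc.items():
        trait = ctx[2] if isinstance(ctx, tuple) and len(ctx) == 3 else str(ctx)
        by_trait.setdefault(trait, {})[ctx] = table
    out = {}
    for trait, tables in by_trait.items():
        T = build_t_matrix(tables)
        analysis = MetaAnalysis(min_pairs=min_pairs, alpha=alpha,
                                suggestive_p=suggestive_p)
        n_tests = int(T.notna().any(axis=1).sum())
        results = analysis.fit(T).transform(T, n_tests=n_tests)
        some = next(iter(tables.values()))
        results = results.join(some.set_index("snp_id")[["chrom", "pos"]])
        _, thr = bonferroni_threshold(n_tests, alpha)
        out[trait] = TraitMetaResult(
            trait=trait,
            results=results,
            t_correlation=analysis.corr_,
            contexts=list(tables.keys()),
            n_tests=n_tests,
            bonferroni_neglog10=thr,
        )
    return out


def run_full_analysis(
    G: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    derive_ri: bool = False,
    window_bp: int = 1_000_000,
    alpha: float = 0.05,
    suggestive_p: float = 1e-4,
    min_samples: int = MIN_CONTEXT_SAMPLES,
    min_pairs: int = 100,
    significance_class: str = "significant",
) -> dict[str, TraitMetaResult]:
    """Phenotype aggregation through QTL clustering in one call.

    When ``derive_ri`` is set, reduction-index contexts are added for every
    treated context whose environment has a control.  QTL are clustered per
    trait from hits at ``significance_class`` or better.
    """
    contexts = aggregate_replicates(phenotypes, accession_ids=G.accession_ids)
    if derive_ri:
        contexts.update(derive_ri_contexts(contexts))
    assoc = gwas_all_contexts(G, contexts, min_samples=min_samples)
    traits = meta_per_trait(assoc, alpha=alpha, suggestive_p=suggestive_p,
                            min_pairs=min_pairs)
    keep = {"significant"} if significance_class == "significant" else {
        "significant", "suggestive"}
    for trait, res in traits.items():
        hits = res.results[res.results["class"].isin(keep)].reset_index()
        hits["trait"] = trait
        if len(hits):
            res.qtl = cluster_qtl(hits, window_bp=window_bp)
    return traits
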