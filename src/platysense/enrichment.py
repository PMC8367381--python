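"""Enrichment calling and signature set logic for sorted-vs-unsorted designs.

Differential-expression results (from any DE engine that reports an FDR)
are filtered into per-population "enriched" gene sets, which are then
partitioned into population-specific and shared (common) signatures.
A low-count pre-filter mirrors the standard CPM rule applied before DE
testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .expression import CountTable

__all__ = [
    "SignatureSets",
    "read_de_table",
    "filter_low_counts",
    "call_enriched",
    "partition_signatures",
    "expressed_specific",
]

DE_COLUMNS = ("gene", "mean_sorted", "mean_unsorted_head", "mean_unsorted_trunk", "fdr")


@dataclass(frozen=True)
class SignatureSets:
    """The enriched / common / specific partition for two cell populations."""

    ep_enriched: frozenset[str]
    tre_enriched: frozenset[str]
    common: frozenset[str]
    ep_specific: frozenset[str]
    tre_specific: frozenset[str]

    def sizes(self) -> dict[str, int]:
        return {
            "ep_enriched": len(self.ep_enriched),
            "tre_enriched": len(self.tre_enriched),
            "common": len(self.common),
            "ep_specific": len(self.ep_specific),
            "tre_specific": len(self.tre_specific),
        }

    def percentages(self, universe_size: int) -> dict[str, float]:
        """Set sizes as percentages of the gene universe."""
        if universe_size <= 0:
            raise ValueError("universe_size must be positive")
        return {k: 100.0 * v / universe_size for k, v in self.sizes().items()}


def read_de_table(path) -> pd.DataFrame:
    """Read a TSV of DE results; validates the required columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table is missing column(s): {missing}")
    return df


def filter_low_counts(
    counts: CountTable, cpm_threshold: float = 1.0, min_samples: int = 3
) -> set[str]:
    """Genes with CPM strictly above ``cpm_threshold`` in >= ``min_samples`` samples.

    CPM = C[g, s] / (N_s / 10^6) with N_s the sample's column sum.
    """
    N = counts.library_sizes.to_numpy(dtype=float)
    if (N <= 0).any():
        raise ValueError("every sample must have a positive library size")
    cpm = counts.counts.to_numpy(dtype=float) / (N[None, :] / 1e6)
    keep = (cpm > cpm_threshold).sum(axis=1) >= min_samples
    return {g for g, k in zip(counts.genes, keep) if k}


def call_enriched(results: pd.DataFrame, fdr_threshold: float = 0.05) -> set[str]:
    """Genes significantly enriched in the sorted population.

    A gene qualifies iff its FDR is <= ``fdr_threshold`` AND its mean
    expression in the sorted cells exceeds the mean in both unsorted
    backgrounds (head and trunk).
    """
    missing = [c for c in DE_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"DE results are missing column(s): {missing}")
    for col in ("mean_sorted", "mean_unsorted_head", "mean_unsorted_trunk"):
        if results[col].isna().any():
            raise ValueError(f"DE results contain missing values in {col!r}")
    hit = (
        (results["fdr"] <= fdr_threshold)
        & (results["mean_sorted"] > results["mean_unsorted_head"])
        & (results["mean_sorted"] > results["mean_unsorted_trunk"])
    )
    return set(results.loc[hit, "gene"])


def partition_signatures(ep_enriched: set[str], tre_enriched: set[str]) -> SignatureSets:
    """Split two enriched sets into specific and common signatures."""
    ep = frozenset(ep_enriched)
    tre = frozenset(tre_enriched)
    return SignatureSets(
        ep_enriched=ep,
        tre_enriched=tre,
        common=ep & tre,
        ep_specific=ep - tre,
        tre_specific=tre - ep,
    )


def expressed_specific(
    ep_expressed: set[str], tre_expressed: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """(EP-only, both, TRE-only) split of two expressed-gene sets."""
    ep, tre = set(ep_expressed), set(tre_expressed)
    return ep - tre, ep & tre, tre - ep
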