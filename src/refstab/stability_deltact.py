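"""Comparative delta-CT ranking of candidate reference genes.

For every unordered gene pair (g, k) the per-sample difference
``dCT_s = CT_g,s - CT_k,s`` removes the template-loading component shared
by both genes in a sample; its population standard deviation (STDEVP,
divisor N) measures how much the two genes' relative expression moves
across samples. A gene's stability statistic is the mean of its pair SDs
against every other candidate — the lower, the more stable.

Pairs are computed over pairwise-complete samples (wells missing in either
gene are dropped for that pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_tables import CtDataset

__all__ = ["DeltaCtResult", "deltact_stability"]


@dataclass
class DeltaCtResult:
    """Pairwise delta-CT variability and the derived stability ranking.

    Attributes
    ----------
    pair_sd : pandas.DataFrame or None
        Symmetric genes x genes matrix of population SDs of per-sample
        delta-CT (cycles); zero diagonal. ``None`` when the result was
        built from precomputed per-gene statistics.
    mean_sd : pandas.Series
        Per-gene mean of its off-diagonal pair SDs (cycles).
    ranking : list of str
        Gene ids sorted ascending by ``mean_sd`` (ties broken
        lexicographically by gene_id).
    n_samples_used : pandas.DataFrame or None
        Per-pair count of samples with both CTs observed.
    tied_ranks : list of tuple
        Gene-id pairs whose mean_sd coincide exactly (flagged, since their
        relative order is then purely lexicographic).
    """

    mean_sd: pd.Series
    ranking: list[str]
    pair_sd: pd.DataFrame | None = None
    n_samples_used: pd.DataFrame | None = None
    tied_ranks: list[tuple[str, str]] | None = None

    @classmethod
    def from_mean_sd(cls, mean_sd: Mapping[str, float]) -> "DeltaCtResult":
        """Build a result from precomputed per-gene statistics.

        Used to rank genes from an already-published stability column
        without access to the underlying per-sample CTs.
        """
        s = pd.Series(dict(mean_sd), dtype=float)
        ranking = _rank(s)
        return cls(mean_sd=s, ranking=ranking, tied_ranks=_ties(s))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (gene, mean_sd) in ranked order."""
        return pd.DataFrame(
            {"gene_id": self.ranking, "mean_sd": self.mean_sd.loc[self.ranking].to_numpy()}
        )


def _rank(mean_sd: pd.Series) -> list[str]:
    return sorted(mean_sd.index, key=lambda g: (mean_sd[g], g))


def _ties(mean_sd: pd.Series) -> list[tuple[str, str]]:
    out = []
    genes = list(mean_sd.index)
    for i, g in enumerate(genes):
        for k in genes[i + 1 :]:
            if mean_sd[g] == mean_sd[k]:
                out.append(tuple(sorted((g, k))))
    return out


def deltact_stability(ds: CtDataset, min_shared: int = 3) -> DeltaCtResult:
    """Rank genes by the mean population SD of pairwise delta-CT.

    Every unordered pair must share at least ``min_shared`` samples with
    observed CTs in both genes; otherwise a hard error names the pair.
    """
    genes = ds.gene_ids
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for delta-CT analysis")
    ct = ds.ct.to_numpy(dtype=float)
    G = len(genes)
    pair_sd = np.zeros((G, G))
    n_used = np.zeros((G, G), dtype=int)
    obs = np.isfinite(ct)
    for i in range(G):
        n_used[i, i] = int(obs[i].sum())
        for j in range(i + 1, G):
            shared = obs[i] & obs[j]
            n = int(shared.sum())
            if n < min_shared:
                raise ValueError(
                    f"gene pair ({genes[i]}, {genes[j]}) shares only {n} samples "
                    f"with observed CTs (< {min_shared})"
                )
            d = ct[i, shared] - ct[j, shared]
            sd = float(np.std(d))  # population SD, divisor N
            pair_sd[i, j] = pair_sd[j, i] = sd
            n_used[i, j] = n_used[j, i] = n
    mean_sd = pd.Series(pair_sd.sum(axis=1) / (G - 1), index=genes)
    pair_df = pd.DataFrame(pair_sd, index=genes, columns=genes)
    n_df = pd.DataFrame(n_used, index=genes, columns=genes)
    return DeltaCtResult(
        mean_sd=mean_sd,
        ranking=_rank(mean_sd),
        pair_sd=pair_df,
        n_samples_used=n_df,
        tied_ranks=_ties(mean_sd),
    )
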