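"""geNorm-style stability analysis: M values, stepwise exclusion, V ratios.

CT values are first converted to relative quantities
``Q_g,s = E_g ** (minCT_g - CT_g,s)`` (each gene anchored at its own
minimum CT, so the per-gene maximum quantity is 1). A gene's expression
stability M is the mean, over all other candidates k, of the population SD
across samples of ``log2(Q_g / Q_k)``; the least stable gene (highest M)
is excluded and M recomputed until two genes remain — those two cannot be
ranked against each other and are reported as the final pair.

Pairwise variation ``V_{n/n+1}`` compares normalization factors (geometric
means of the top-n quantities) built from n versus n+1 reference genes and
is the usual guide to how many references suffice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_tables import CtDataset

__all__ = ["QuantityMatrix", "GenormTrace", "relative_quantities", "m_values", "stepwise_ranking"]


@dataclass
class QuantityMatrix:
    """Relative quantities (genes x samples, dimensionless, per-gene max 1)."""

    q: pd.DataFrame
    efficiencies: dict[str, float]

    def __post_init__(self) -> None:
        vals = self.q.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError("relative quantities must be finite and > 0")


@dataclass
class GenormTrace:
    """Full record of a stepwise geNorm run.

    ``rounds`` lists, for each exclusion round, the genes still in play and
    their M values; ``exclusion_order`` is worst-first; ``ranking`` is
    most-stable-first (the final pair leads, in lexicographic order, since
    geNorm cannot split it). ``v_ratios[n]`` is V_{n/n+1} and ``nf[n]`` the
    per-sample normalization factors from the top n genes.
    """

    rounds: list[pd.Series]
    exclusion_order: list[str]
    final_pair: frozenset[str]
    ranking: list[str]
    v_ratios: dict[int, float] = field(default_factory=dict)
    nf: dict[int, pd.Series] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long table (round, gene_id, m) for re-plotting stability curves."""
        rows = []
        for r, ms in enumerate(self.rounds, start=1):
            for g, m in ms.items():
                rows.append({"round": r, "gene_id": g, "m": m})
        return pd.DataFrame(rows)


def relative_quantities(
    ds: CtDataset,
    efficiencies: Mapping[str, float] | None = None,
    default_e: float = 2.0,
) -> QuantityMatrix:
    """Convert CTs to efficiency-corrected relative quantities.

    ``Q = E ** (minCT - CT)`` per gene, anchored at that gene's minimum CT
    within the (sub)dataset. Requires a complete CT matrix: geNorm has no
    pairwise-complete mode, so missing wells must be dropped beforehand.
    """
    eff = ds.efficiencies(default=default_e)
    if efficiencies:
        eff.update(efficiencies)
    for g in ds.gene_ids:
        e = eff.get(g, default_e)
        if not (1.0 < e <= 2.2):
            raise ValueError(f"gene {g!r}: efficiency {e} outside (1, 2.2]")
        eff[g] = e
    ct = ds.ct.to_numpy(dtype=float)
    if not np.isfinite(ct).all():
        bad = np.argwhere(~np.isfinite(ct))[0]
        raise ValueError(
            f"missing CT for gene {ds.gene_ids[bad[0]]!r}, sample "
            f"{ds.sample_ids[bad[1]]!r}: drop incomplete samples before geNorm"
        )
    evec = np.array([eff[g] for g in ds.gene_ids])
    q = evec[:, None] ** (ct.min(axis=1, keepdims=True) - ct)
    return QuantityMatrix(
        q=pd.DataFrame(q, index=ds.gene_ids, columns=ds.sample_ids),
        efficiencies={g: eff[g] for g in ds.gene_ids},
    )


def m_values(q: QuantityMatrix | pd.DataFrame) -> pd.Series:
    """Per-gene geNorm M: mean over partners of SD of log2 expression ratios."""
    qdf = q.q if isinstance(q, QuantityMatrix) else q
    if qdf.shape[0] < 2 or qdf.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples for M values")
    a = np.log2(qdf.to_numpy(dtype=float))
    G = a.shape[0]
    # V_gk = population SD over samples of (a_g - a_k)
    v = np.zeros((G, G))
    for i in range(G):
        for j in range(i + 1, G):
            v[i, j] = v[j, i] = float(np.std(a[i] - a[j]))
    m = v.sum(axis=1) / (G - 1)
    return pd.Series(m, index=qdf.index)


def pairwise_variation_matrix(q: QuantityMatrix | pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of V_gk = population SD of log2(Q_g/Q_k) over samples."""
    qdf = q.q if isinstance(q, QuantityMatrix) else q
    a = np.log2(qdf.to_numpy(dtype=float))
    G = a.shape[0]
    v = np.zeros((G, G))
    for i in range(G):
        for j in range(i + 1, G):
            v[i, j] = v[j, i] = float(np.std(a[i] - a[j]))
    return pd.DataFrame(v, index=qdf.index, columns=qdf.index)


def stepwise_ranking(q: QuantityMatrix) -> GenormTrace:
    """Stepwise geNorm exclusion plus normalization-factor V ratios.

    Repeatedly removes the gene with the highest M (ties broken by
    excluding the lexicographically last gene) until two remain. V_{n/n+1}
    for n = 2..G-1 is the population SD over samples of
    ``log2(NF_n / NF_{n+1})`` with NF built from the top-n ranked genes.
    """
    qdf = q.q
    if qdf.shape[0] < 3:
        raise ValueError("stepwise geNorm needs at least 3 genes")
    remaining = qdf.copy()
    rounds: list[pd.Series] = []
    exclusion: list[str] = []
    while remaining.shape[0] > 2:
        m = m_values(remaining)
        rounds.append(m)
        worst_val = m.max()
        worst = max(g for g in m.index if m[g] == worst_val)
        exclusion.append(worst)
        remaining = remaining.drop(index=worst)
    final_m = m_values(remaining)
    rounds.append(final_m)
    final_pair = frozenset(remaining.index)
    ranking = sorted(final_pair) + list(reversed(exclusion))

    a = np.log2(qdf.loc[ranking].to_numpy(dtype=float))
    nf: dict[int, pd.Series] = {}
    v_ratios: dict[int, float] = {}
    G = len(ranking)
    for n in range(2, G + 1):
        # log2 NF_n = mean of top-n log quantities (geometric mean)
        nf[n] = pd.Series(2.0 ** a[:n].mean(axis=0), index=qdf.columns)
    for n in range(2, G):
        diff = a[:n].mean(axis=0) - a[: n + 1].mean(axis=0)
        v_ratios[n] = float(np.std(diff))
    return GenormTrace(
        rounds=rounds,
        exclusion_order=exclusion,
        final_pair=final_pair,
        ranking=ranking,
        v_ratios=v_ratios,
        nf=nf,
    )
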