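"""Efficiency-corrected relative quantification of target genes.

Fold changes follow the efficiency-corrected ratio model: for replicate r
of a condition,

``ratio_r = E_t ** (CT_t,cal - CT_t,r) / NF_r``

where the calibrator CT is the mean over calibrator replicates and ``NF_r``
is the geometric mean, over the chosen reference genes, of
``E_ref ** (CT_ref,cal - CT_ref,r)``. The reported fold change is the
geometric mean of the per-replicate ratios and its uncertainty the sample
SD of ``log2(ratio_r)`` divided by sqrt(n). With all efficiencies equal to
2 and a perfectly stable reference this reduces to the classic
``2**-ddCT``. Calibrator rows are 1 by construction.

``reference_consistency`` compares fold-change tables produced under
different reference schemes and flags the condition cells where the
schemes disagree about crossing a detection threshold (default 2-fold) —
the operational cost of normalising against an unstable reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import CtDataset

__all__ = ["FoldChangeTable", "fold_change", "reference_consistency"]


@dataclass
class FoldChangeTable:
    """Fold changes per (target, tissue, condition) under one reference scheme.

    ``table`` columns: target, tissue, condition, scheme, fold_change,
    se_log2, n_replicates. Calibrator rows carry fold_change exactly 1.
    """

    table: pd.DataFrame
    scheme: tuple[str, ...]
    calibrator: str

    def __post_init__(self) -> None:
        if (self.table["fold_change"] <= 0).any():
            raise ValueError("fold changes must be positive")

    def cell(self, target: str, tissue: str, condition: str) -> pd.Series:
        t = self.table
        m = (t["target"] == target) & (t["tissue"] == tissue) & (t["condition"] == condition)
        if not m.any():
            raise KeyError((target, tissue, condition))
        return t[m].iloc[0]


def _condition_label(samples: pd.DataFrame) -> pd.Series:
    """Condition label of each sample: '0 h' style calibrator vs 'treatment Nh'."""
    return samples.apply(
        lambda r: f"{r['treatment']} {r['timepoint_h']:g} h", axis=1
    )


def _replicate_cts(ds: CtDataset, gene: str, mask: pd.Series) -> np.ndarray:
    cts = ds.ct.loc[gene, mask[mask].index].to_numpy(dtype=float)
    if not np.isfinite(cts).all() or cts.size == 0:
        raise ValueError(f"missing CT for gene {gene!r} in a required condition")
    return cts


def fold_change(
    targets: CtDataset,
    refs: CtDataset,
    efficiencies: Mapping[str, float],
    calibrator: str,
    scheme: Sequence[str],
    conditions: Sequence[str] | None = None,
) -> FoldChangeTable:
    """Efficiency-corrected fold changes of every target gene vs a calibrator.

    Parameters
    ----------
    targets, refs
        Datasets holding target-gene and reference-gene CTs over the same
        samples (they may be the same object). Replicates are aligned by
        (tissue, condition, replicate).
    efficiencies
        Per-gene fold-per-cycle amplification efficiencies; genes without
        an entry default to 2.0.
    calibrator
        Condition label (see below) used as the 1x baseline, e.g.
        ``"control 0 h"``; the calibrator CT is the mean over its
        replicates, per tissue.
    scheme
        Reference gene ids; their per-replicate quantities are combined by
        geometric mean into the normalization factor.
    conditions
        Condition labels to report; default all present. A sample's label
        is ``"<treatment> <timepoint> h"``.
    """
    for g in scheme:
        if g not in refs.gene_ids:
            raise ValueError(f"reference gene {g!r} absent from the reference dataset")
    eff = dict(efficiencies)

    def log2e(g: str) -> float:
        e = eff.get(g, 2.0)
        if not 1.0 < e <= 2.2:
            raise ValueError(f"gene {g!r}: efficiency {e} outside (1, 2.2]")
        return float(np.log2(e))

    t_labels = _condition_label(targets.samples)
    r_labels = _condition_label(refs.samples)
    if conditions is None:
        conditions = list(dict.fromkeys(t_labels))
    rows = []
    for tissue in dict.fromkeys(targets.samples["tissue"]):
        cal_mask_t = (t_labels == calibrator) & (targets.samples["tissue"] == tissue)
        cal_mask_r = (r_labels == calibrator) & (refs.samples["tissue"] == tissue)
        if not cal_mask_t.any() or not cal_mask_r.any():
            raise ValueError(
                f"calibrator condition {calibrator!r} missing for tissue {tissue!r}"
            )
        for target in targets.gene_ids:
            ct_t_cal = float(np.mean(_replicate_cts(targets, target, cal_mask_t)))
            cal_ref_means = {
                g: float(np.mean(_replicate_cts(refs, g, cal_mask_r))) for g in scheme
            }
            for cond in conditions:
                m_t = (t_labels == cond) & (targets.samples["tissue"] == tissue)
                m_r = (r_labels == cond) & (refs.samples["tissue"] == tissue)
                if not m_t.any():
                    continue
                ct_t = _replicate_cts(targets, target, m_t)
                # per-replicate log2 ratio: target dCT minus mean reference dCT
                log_num = (ct_t_cal - ct_t) * log2e(target)
                log_nf = np.zeros_like(log_num)
                for g in scheme:
                    ct_r = _replicate_cts(refs, g, m_r)
                    if ct_r.shape != ct_t.shape:
                        raise ValueError(
                            f"replicate structure mismatch for {g!r} in {cond!r}"
                        )
                    log_nf += (cal_ref_means[g] - ct_r) * log2e(g)
                log_ratio = log_num - log_nf / len(scheme)
                n = log_ratio.size
                fc = 1.0 if cond == calibrator else float(2.0 ** np.mean(log_ratio))
                se = float(np.std(log_ratio, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
                rows.append(
                    {
                        "target": target,
                        "tissue": tissue,
                        "condition": cond,
                        "scheme": "+".join(scheme),
                        "fold_change": fc,
                        "se_log2": se,
                        "n_replicates": n,
                    }
                )
    if not rows:
        raise ValueError("no matching conditions to quantify")
    return FoldChangeTable(table=pd.DataFrame(rows), scheme=tuple(scheme), calibrator=calibrator)


def reference_consistency(
    tables: Iterable[FoldChangeTable | pd.DataFrame],
    detection_threshold: float = 2.0,
) -> pd.DataFrame:
    """Flag condition cells where reference schemes disagree on detection.

    A (target, tissue, condition) cell is flagged when at least one
    scheme's fold change reaches ``detection_threshold`` and another
    scheme's does not: the induction call then depends on the reference
    chosen. Input tables must cover identical cells. The output is sorted
    by target then tissue and lists each scheme's fold change.
    """
    frames = []
    for t in tables:
        df = t.table if isinstance(t, FoldChangeTable) else t
        frames.append(df[["target", "tissue", "condition", "scheme", "fold_change"]])
    if len(frames) < 2:
        raise ValueError("need at least two reference schemes to compare")
    allf = pd.concat(frames, ignore_index=True)
    wide = allf.pivot_table(
        index=["target", "tissue", "condition"],
        columns="scheme",
        values="fold_change",
        aggfunc="first",
    )
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index[0]
        raise ValueError(f"schemes do not overlap on cell {tuple(missing)}")
    detected = wide >= detection_threshold
    flagged = wide[detected.any(axis=1) & (~detected).any(axis=1)]
    out = flagged.reset_index().sort_values(["target", "tissue", "condition"])
    out.columns.name = None
    return out.reset_index(drop=True)
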