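import numpy as np
import pandas as pd
import pytest

from refstab.io_tables import CtDataset, GeneInfo


def make_dataset(ct_rows, gene_ids, sample_meta=None, efficiencies=None):
    """Small CtDataset from a list of per-gene CT rows.

    ``sample_meta`` defaults to one root/control sample per column at
    distinct timepoints.
    """
    ct = pd.DataFrame(np.asarray(ct_rows, dtype=float), index=gene_ids)
    ct.columns = (
        list(sample_meta.index)
        if sample_meta is not None
        else [f"s{i+1}" for i in range(ct.shape[1])]
    )
    n = ct.shape[1]
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {
                "tissue": ["root"] * n,
                "treatment": ["control"] * n,
                "timepoint_h": [float(i) for i in range(n)],
                "replicate": [1] * n,
            },
            index=ct.columns,
        )
        sample_meta.index.name = "sample_id"
    eff = efficiencies or {}
    genes = [GeneInfo(g, efficiency=eff.get(g)) for g in gene_ids]
    return CtDataset(ct=ct, samples=sample_meta, genes=genes)


@pytest.fixture
def mixed_design_dataset():
    """3 genes x 8 samples over 2 tissues x {control, dehydration, salt}."""
    rows = []
    sid = []
    for tissue in ("root", "shoot"):
        for trt, tp in (("control", 0.0), ("control", 2.0), ("dehydration", 2.0), ("salt", 2.0)):
            sid.append(f"{tissue}_{trt}_{tp:g}")
            rows.append((tissue, trt, tp, 1))
    meta = pd.DataFrame(
        rows, columns=["tissue", "treatment", "timepoint_h", "replicate"], index=sid
    )
    meta.index.name = "sample_id"
    rng = np.random.default_rng(42)
    ct = rng.uniform(18, 28, size=(3, 8))
    return make_dataset(ct, ["gA", "gB", "gC"], sample_meta=meta)
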