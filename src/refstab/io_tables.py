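"""Reading, writing and subsetting of CT tables with sample metadata.

The canonical on-disk layout is *long*: one row per (sample, gene) well with
columns ``sample_id, tissue, treatment, timepoint_h, replicate, gene_id, ct``.
A *wide* layout (one row per sample, one column per gene) is accepted for
convenience and is converted on read. Missing CT values are written as the
token ``NA``.

In memory a :class:`CtDataset` holds a genes x samples CT matrix plus the
sample metadata; condition subsetting (per tissue and/or treatment, with or
without the untreated controls) is the entry point for every stratified
stability analysis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TREATMENTS",
    "TISSUES",
    "MISSING_TOKEN",
    "GeneInfo",
    "CtDataset",
    "read_ct_table",
    "write_ct_table",
    "read_gene_table",
    "read_supplementary_table",
    "subset",
]

#: Treatment labels recognised in sample metadata. ``control`` covers the
#: mock-treated time-course samples kept alongside each stress series.
TREATMENTS = ("control", "dehydration", "salt", "cold", "ABA")
TISSUES = ("root", "shoot")
MISSING_TOKEN = "NA"

CT_MIN, CT_MAX = 1.0, 45.0

LONG_COLUMNS = (
    "sample_id",
    "tissue",
    "treatment",
    "timepoint_h",
    "replicate",
    "gene_id",
    "ct",
)

META_COLUMNS = ("sample_id", "tissue", "treatment", "timepoint_h", "replicate")


@dataclass(frozen=True)
class GeneInfo:
    """A candidate gene and its per-amplicon amplification efficiency.

    ``efficiency`` is the fold amplification per PCR cycle, in the
    ``(1, 2]`` convention (a perfect doubling is 2.0); ``None`` means
    unknown (downstream code then falls back to a default).
    """

    gene_id: str
    efficiency: float | None = None
    amplicon_length: int | None = None

    def __post_init__(self) -> None:
        if self.efficiency is not None and not (1.0 < self.efficiency <= 2.2):
            raise ValueError(
                f"gene {self.gene_id!r}: efficiency {self.efficiency} outside (1, 2.2]"
            )
        if self.amplicon_length is not None and self.amplicon_length <= 0:
            raise ValueError(f"gene {self.gene_id!r}: non-positive amplicon length")


@dataclass
class CtDataset:
    """Genes x samples cycle-threshold matrix with sample metadata.

    Attributes
    ----------
    ct : pandas.DataFrame
        Rows indexed by ``gene_id``, columns by ``sample_id``; NaN marks a
        missing well. Non-missing values must lie in [1, 45] cycles.
    samples : pandas.DataFrame
        Indexed by ``sample_id`` with columns ``tissue, treatment,
        timepoint_h, replicate``; column order follows the input file.
    genes : list of GeneInfo
        One entry per row of ``ct`` (same order).
    """

    ct: pd.DataFrame
    samples: pd.DataFrame
    genes: list[GeneInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ct.index.name = "gene_id"
        self.ct.columns.name = "sample_id"
        self.samples.index.name = "sample_id"
        if not self.genes:
            self.genes = [GeneInfo(g) for g in self.ct.index]
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if list(self.ct.index) != [g.gene_id for g in self.genes]:
            raise ValueError("ct matrix rows do not match the gene list")
        if list(self.ct.columns) != list(self.samples.index):
            raise ValueError("ct matrix columns do not match the sample table")
        if self.ct.index.duplicated().any():
            dup = self.ct.index[self.ct.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if self.samples.index.duplicated().any():
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        bad_t = set(self.samples["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise ValueError(
                f"unknown treatment label(s) {sorted(bad_t)}; allowed: {list(TREATMENTS)}"
            )
        bad_tis = set(self.samples["tissue"]) - set(TISSUES)
        if bad_tis:
            raise ValueError(
                f"unknown tissue label(s) {sorted(bad_tis)}; allowed: {list(TISSUES)}"
            )
        if (pd.to_numeric(self.samples["timepoint_h"]) < 0).any():
            raise ValueError("negative timepoint_h")
        if (pd.to_numeric(self.samples["replicate"]) < 1).any():
            raise ValueError("replicate must be a positive integer")
        key = self.samples[["tissue", "treatment", "timepoint_h", "replicate"]]
        if key.duplicated().any():
            row = key[key.duplicated()].iloc[0]
            raise ValueError(
                "duplicate (tissue, treatment, timepoint, replicate) tuple: "
                f"{tuple(row)}"
            )
        vals = self.ct.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < CT_MIN) | (finite > CT_MAX)).any():
            bad = finite[(finite < CT_MIN) | (finite > CT_MAX)][0]
            raise ValueError(f"CT value {bad} outside [{CT_MIN}, {CT_MAX}]")

    # -- convenience -----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def n_genes(self) -> int:
        return self.ct.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ct.shape[1]

    def efficiencies(self, default: float | None = None) -> dict[str, float]:
        """Per-gene efficiency map, substituting ``default`` where unknown."""
        out: dict[str, float] = {}
        for g in self.genes:
            if g.efficiency is not None:
                out[g.gene_id] = g.efficiency
            elif default is not None:
                out[g.gene_id] = default
            else:
                raise ValueError(f"no efficiency for gene {g.gene_id!r} and no default")
        return out

    def to_long(self) -> pd.DataFrame:
        """Long-format DataFrame with the canonical columns."""
        long = (
            self.ct.rename_axis(index="gene_id", columns="sample_id")
            .stack(future_stack=True)
            .rename("ct")
            .reset_index()
        )
        long = long.merge(self.samples.reset_index(), on="sample_id", how="left")
        # preserve sample-major ordering of the canonical layout
        order = {s: i for i, s in enumerate(self.ct.columns)}
        gorder = {g: i for i, g in enumerate(self.ct.index)}
        long = long.sort_values(
            by=["sample_id", "gene_id"],
            key=lambda col: col.map(order if col.name == "sample_id" else gorder),
            kind="stable",
        ).reset_index(drop=True)
        return long[list(LONG_COLUMNS)]


def _sep_for(path: str | os.PathLike) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _apply_mapping(df: pd.DataFrame, meta: Mapping[str, str] | None) -> pd.DataFrame:
    if meta:
        df = df.rename(columns={v: k for k, v in meta.items()})
    return df


def _build_dataset(long: pd.DataFrame, genes: Sequence[GeneInfo] | None) -> CtDataset:
    missing = set(LONG_COLUMNS) - set(long.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    dup = long.duplicated(subset=["sample_id", "gene_id"])
    if dup.any():
        row = long[dup].iloc[0]
        raise ValueError(
            f"duplicate (sample, gene) pair: ({row['sample_id']}, {row['gene_id']})"
        )
    def _parse_ct(v):
        if isinstance(v, float):
            return v
        if isinstance(v, str) and v.strip() in (MISSING_TOKEN, ""):
            return np.nan
        return float(v)  # exact, correctly-rounded conversion

    long = long.assign(ct=long["ct"].map(_parse_ct).astype(float))

    sample_order = list(dict.fromkeys(long["sample_id"]))
    gene_order = list(dict.fromkeys(long["gene_id"]))
    ct = (
        long.pivot(index="gene_id", columns="sample_id", values="ct")
        .reindex(index=gene_order, columns=sample_order)
    )
    samples = (
        long[list(META_COLUMNS)]
        .drop_duplicates(subset="sample_id")
        .set_index("sample_id")
        .reindex(sample_order)
    )
    samples["timepoint_h"] = pd.to_numeric(samples["timepoint_h"]).astype(float)
    samples["replicate"] = pd.to_numeric(samples["replicate"]).astype(int)
    if genes is not None:
        by_id = {g.gene_id: g for g in genes}
        gene_list = [by_id.get(g, GeneInfo(g)) for g in gene_order]
    else:
        gene_list = [GeneInfo(g) for g in gene_order]
    return CtDataset(ct=ct, samples=samples, genes=gene_list)


def read_ct_table(
    path: str | os.PathLike,
    layout: str = "long",
    meta: Mapping[str, str] | None = None,
    genes: Sequence[GeneInfo] | None = None,
) -> CtDataset:
    """Read a delimited CT table into a :class:`CtDataset`.

    Parameters
    ----------
    path
        ``.csv`` (comma) or ``.tsv`` (tab) file.
    layout
        ``"long"`` (canonical) or ``"wide"`` (one row per sample, one
        column per gene; metadata columns as in the long layout).
    meta
        Optional mapping from canonical column names to the file's column
        names, e.g. ``{"ct": "Cq"}``.
    genes
        Optional :class:`GeneInfo` records carrying amplification
        efficiencies to attach to the dataset.
    """
    if layout not in ("long", "wide"):
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    df = _apply_mapping(df, meta)
    if layout == "wide":
        meta_missing = set(META_COLUMNS) - set(df.columns)
        if meta_missing:
            raise ValueError(f"missing metadata column(s): {sorted(meta_missing)}")
        gene_cols = [c for c in df.columns if c not in META_COLUMNS]
        if not gene_cols:
            raise ValueError("wide table has no gene columns")
        df = df.melt(
            id_vars=list(META_COLUMNS),
            value_vars=gene_cols,
            var_name="gene_id",
            value_name="ct",
        )
        # melt is column-major; restore sample-major order
        order = {s: i for i, s in enumerate(dict.fromkeys(df["sample_id"]))}
        df = df.sort_values(
            "sample_id", key=lambda c: c.map(order), kind="stable"
        ).reset_index(drop=True)
    return _build_dataset(df, genes)


def write_ct_table(ds: CtDataset, path: str | os.PathLike) -> None:
    """Write a dataset in the canonical long layout (missing CTs as ``NA``)."""
    long = ds.to_long()
    long["ct"] = long["ct"].map(lambda v: MISSING_TOKEN if pd.isna(v) else repr(float(v)))
    long.to_csv(path, sep=_sep_for(path), index=False)


def read_gene_table(
    path: str | os.PathLike, meta: Mapping[str, str] | None = None
) -> list[GeneInfo]:
    """Read a gene/efficiency table (columns: gene_id, efficiency[, amplicon_length])."""
    df = pd.read_csv(path, sep=_sep_for(path))
    df = _apply_mapping(df, meta)
    if "gene_id" not in df.columns or "efficiency" not in df.columns:
        raise ValueError("gene table needs columns 'gene_id' and 'efficiency'")
    out = []
    for _, row in df.iterrows():
        length = row.get("amplicon_length")
        out.append(
            GeneInfo(
                gene_id=str(row["gene_id"]),
                efficiency=float(row["efficiency"]),
                amplicon_length=int(length) if pd.notna(length) else None,
            )
        )
    if len({g.gene_id for g in out}) != len(out):
        raise ValueError("duplicate gene_id in gene table")
    return out


def read_supplementary_table(
    path: str | os.PathLike,
    mapping: Mapping[str, str],
    sheet: str | int = 0,
    genes: Sequence[GeneInfo] | None = None,
) -> CtDataset:
    """Mapping-driven import of a per-sample CT spreadsheet.

    Supplementary spreadsheets rarely follow a standard layout, so the
    caller supplies ``mapping`` from the canonical long-format column names
    to the sheet's column headers (all seven canonical columns required).
    ``.xlsx`` is read via openpyxl; delimited text is also accepted. Legacy
    binary ``.xls`` is not supported — convert to ``.xlsx`` or CSV first.
    """
    p = str(path)
    if p.endswith(".xls"):
        raise ValueError(
            "legacy .xls workbooks are not supported; convert to .xlsx or csv first"
        )
    if p.endswith(".xlsx"):
        df = pd.read_excel(path, sheet_name=sheet, dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = set(LONG_COLUMNS) - set(mapping)
    if missing:
        raise ValueError(f"mapping must cover all canonical columns; missing {sorted(missing)}")
    df = df.rename(columns={v: k for k, v in mapping.items()})
    return _build_dataset(df[list(LONG_COLUMNS)], genes)


def subset(
    ds: CtDataset,
    tissue: str | None = None,
    treatments: Iterable[str] | None = None,
    include_control: bool = True,
) -> CtDataset:
    """Restrict a dataset to a tissue and/or set of treatments.

    ``include_control=True`` keeps control samples alongside the selected
    treatments (the usual framing when ranking stability within one
    stress). The gene list is unchanged. Raises on an empty selection.
    """
    mask = pd.Series(True, index=ds.samples.index)
    if tissue is not None:
        if tissue not in TISSUES:
            raise ValueError(f"unknown tissue {tissue!r}; allowed: {list(TISSUES)}")
        mask &= ds.samples["tissue"] == tissue
    if treatments is not None:
        wanted = set(treatments)
        unknown = wanted - set(TREATMENTS)
        if unknown:
            raise ValueError(
                f"unknown treatment(s) {sorted(unknown)}; allowed: {list(TREATMENTS)}"
            )
        absent = wanted - set(ds.samples["treatment"])
        if absent:
            raise ValueError(f"treatment(s) {sorted(absent)} not present in dataset")
        if include_control:
            wanted = wanted | {"control"}
        mask &= ds.samples["treatment"].isin(wanted)
    keep = ds.samples.index[mask]
    if len(keep) == 0:
        raise ValueError(
            f"empty selection (tissue={tissue!r}, treatments={treatments!r})"
        )
    return CtDataset(
        ct=ds.ct.loc[:, keep].copy(),
        samples=ds.samples.loc[keep].copy(),
        genes=list(ds.genes),
    )
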