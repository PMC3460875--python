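"""Synthetic CT matrices and amplification curves with known ground truth.

The CT generator emulates a multi-gene qPCR screen across a tissue x
treatment x timepoint x replicate design:

``CT_g,s = mu_g + shift_s + beta_g(condition of s) + eps_g,s``

where ``mu_g`` is the gene's baseline CT, ``shift_s ~ N(0, delta^2)`` is a
per-sample loading/RT shift common to all genes (exactly what delta-CT and
geNorm statistics are built to cancel), ``beta_g`` is a gene x condition
expression effect in cycles (0 for a perfectly stable reference), and
``eps ~ N(0, sigma^2)`` is replicate noise.

All random draws are snapped to a dyadic grid (multiples of 2**-16 cycles,
~1.5e-5 cycles — far below instrument resolution) so that the per-sample
shift cancels *exactly* in floating point when a delta-CT is formed; with
``beta = 0`` and ``sigma = 0`` every pairwise SD is then exactly zero.

The curve generator produces baseline + plateau-clamped exponentials with
optional multiplicative noise and carries analytic truth (baseline,
efficiency, and the exact CT for any threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import AmpCurve
from .io_tables import CtDataset, GeneInfo

__all__ = [
    "SimSpec",
    "CurveTruth",
    "study_design",
    "default_spec",
    "simulate_ct_dataset",
    "simulate_amplification",
]

_GRID = 2.0**-16  # dyadic quantum for exact shift cancellation


def _snap(x: np.ndarray | float) -> np.ndarray | float:
    return np.round(np.asarray(x, dtype=float) / _GRID) * _GRID


#: Condition cell of a design: (tissue, treatment, timepoints in hours, replicates)
DesignCell = tuple[str, str, tuple[float, ...], int]


def study_design(
    treatments: Sequence[str] = ("dehydration", "salt", "cold", "ABA"),
    timepoints: tuple[float, ...] = (2.0, 10.0),
    replicates: int = 3,
    control_timepoints: tuple[float, ...] = (0.0, 2.0, 10.0),
) -> list[DesignCell]:
    """The emulated screen: 2 tissues x (control + 4 stresses) x timepoints x 3 reps.

    Controls are mock-treated samples collected at the same durations;
    stress samples are collected after 2 and 10 h of treatment.
    """
    cells: list[DesignCell] = []
    for tissue in ("root", "shoot"):
        cells.append((tissue, "control", tuple(control_timepoints), replicates))
        for trt in treatments:
            cells.append((tissue, trt, tuple(timepoints), replicates))
    return cells


@dataclass
class SimSpec:
    """Ground-truth parameterisation of a synthetic CT screen.

    Attributes
    ----------
    n_genes : int
        Number of candidate reference genes.
    design : list of (tissue, treatment, timepoints, replicates)
        Condition cells; every timepoint x replicate combination yields one
        sample.
    mu : per-gene baseline CT (cycles).
    delta : SD of the per-sample loading shift (cycles).
    beta : mapping gene_id -> {(treatment, timepoint): effect in cycles}.
        Unlisted combinations are 0 (perfectly stable).
    sigma : replicate noise SD (cycles).
    seed : mandatory RNG seed; identical specs reproduce bit-identical data.
    efficiencies : optional per-gene amplification efficiency to attach.
    """

    n_genes: int
    design: list[DesignCell]
    mu: Sequence[float]
    delta: float
    sigma: float
    seed: int
    beta: Mapping[str, Mapping[tuple[str, float], float]] = field(default_factory=dict)
    gene_ids: Sequence[str] | None = None
    efficiencies: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.delta < 0:
            raise ValueError("sigma and delta must be non-negative")
        if len(self.mu) != self.n_genes:
            raise ValueError("mu must have one entry per gene")
        if self.gene_ids is None:
            width = len(str(self.n_genes))
            self.gene_ids = [f"g{i+1:0{width}d}" for i in range(self.n_genes)]
        if len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids must have one entry per gene")
        for _, _, _, reps in self.design:
            if reps < 1:
                raise ValueError("replicate count must be positive")


def default_spec(seed: int, n_genes: int = 13, sigma: float = 0.2, delta: float = 0.5) -> SimSpec:
    """A realistic 13-gene screen: baselines 17-26 CT, 0.5-cycle loading shifts,
    0.2-cycle replicate noise, no treatment effects (all genes stable)."""
    rng = np.random.default_rng(seed)
    mu = _snap(rng.uniform(17.0, 26.0, size=n_genes))
    return SimSpec(
        n_genes=n_genes,
        design=study_design(),
        mu=list(np.atleast_1d(mu)),
        delta=delta,
        sigma=sigma,
        seed=seed,
    )


def _beta_of(spec: SimSpec, gene: str, treatment: str, timepoint: float) -> float:
    g = spec.beta.get(gene)
    if not g:
        return 0.0
    return float(g.get((treatment, float(timepoint)), 0.0))


def analytic_instability(spec: SimSpec) -> pd.Series:
    """Per-gene instability score implied by the spec, ascending = stable.

    The score is ``sqrt(popvar_s(beta_g(s)) + sigma^2)``: the population
    variance of the gene's condition effects over the design's samples plus
    the replicate noise floor. Loading shifts do not appear (they cancel in
    every pairwise statistic).
    """
    genes = list(spec.gene_ids)
    rows = []
    for tissue, trt, tps, reps in spec.design:
        for tp in tps:
            rows.extend([(trt, tp)] * reps)
    scores = {}
    for g in genes:
        b = np.array([_beta_of(spec, g, trt, tp) for trt, tp in rows])
        scores[g] = float(np.sqrt(np.var(b) + spec.sigma**2))
    return pd.Series(scores)


def simulate_ct_dataset(spec: SimSpec) -> tuple[CtDataset, pd.Series]:
    """Draw a CT dataset from the spec; returns (dataset, truth ranking).

    The truth is :func:`analytic_instability` (per-gene score, lower =
    more stable). Identical specs (including seed) give identical data.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.gene_ids)
    mu = _snap(np.asarray(spec.mu, dtype=float))

    sample_rows = []
    for tissue, trt, tps, reps in spec.design:
        for tp in tps:
            for rep in range(1, reps + 1):
                sample_rows.append(
                    {
                        "sample_id": f"{tissue}_{trt}_{tp:g}h_r{rep}",
                        "tissue": tissue,
                        "treatment": trt,
                        "timepoint_h": float(tp),
                        "replicate": rep,
                    }
                )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    S = len(samples)
    shifts = _snap(rng.normal(0.0, spec.delta, size=S)) if spec.delta > 0 else np.zeros(S)
    eps = (
        _snap(rng.normal(0.0, spec.sigma, size=(spec.n_genes, S)))
        if spec.sigma > 0
        else np.zeros((spec.n_genes, S))
    )
    beta = np.zeros((spec.n_genes, S))
    for j, (_, row) in enumerate(samples.iterrows()):
        for i, g in enumerate(genes):
            beta[i, j] = _beta_of(spec, g, row["treatment"], row["timepoint_h"])
    beta = _snap(beta)
    ct = mu[:, None] + shifts[None, :] + beta + eps
    ct_df = pd.DataFrame(ct, index=genes, columns=samples.index)
    eff = spec.efficiencies or {}
    gene_list = [GeneInfo(g, efficiency=eff.get(g)) for g in genes]
    ds = CtDataset(ct=ct_df, samples=samples, genes=gene_list)
    return ds, analytic_instability(spec)


@dataclass(frozen=True)
class CurveTruth:
    """Analytic truth for a simulated amplification curve."""

    efficiency: float
    baseline: float
    n0: float
    plateau: float

    def ct_at(self, threshold: float) -> float:
        """Exact fractional cycle where the noiseless corrected signal would
        cross ``threshold`` (valid below the plateau)."""
        if not 0 < threshold < self.plateau:
            raise ValueError("threshold must be in (0, plateau)")
        return float(np.log(threshold / self.n0) / np.log(self.efficiency))


def simulate_amplification(
    e: float,
    n0: float,
    baseline: float,
    cycles: int,
    plateau: float,
    noise_sd: float,
    seed: int,
    well_id: str = "w1",
    amplicon_id: str = "amp1",
) -> tuple[AmpCurve, CurveTruth]:
    """Simulate one amplification curve with known truth.

    ``signal_c = baseline + min(n0 * e**c, plateau) * (1 + eta_c)`` with
    ``eta ~ N(0, noise_sd^2)`` (multiplicative reporter noise). Negative
    signals are clipped at 0 (fluorescence is non-negative).
    """
    if not 1.0 < e <= 2.2:
        raise ValueError("efficiency must be in (1, 2.2]")
    if plateau <= baseline:
        raise ValueError("plateau must exceed baseline")
    if n0 <= 0 or cycles < 1:
        raise ValueError("n0 must be positive and cycles >= 1")
    rng = np.random.default_rng(seed)
    c = np.arange(1, cycles + 1, dtype=float)
    amplified = np.minimum(n0 * e**c, plateau)
    eta = rng.normal(0.0, noise_sd, size=cycles) if noise_sd > 0 else np.zeros(cycles)
    signal = np.clip(baseline + amplified * (1.0 + eta), 0.0, None)
    curve = AmpCurve(well_id=well_id, amplicon_id=amplicon_id, cycles=c, signal=signal)
    return curve, CurveTruth(efficiency=e, baseline=baseline, n0=n0, plateau=plateau)
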