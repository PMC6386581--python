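"""Spike-in normalized transcriptome analysis.

Mixing a constant number of *Candida albicans* cells into each
*S. cerevisiae* sample before RNA extraction provides an absolute
abundance anchor: normalizing fragment counts to gene length and to
the number of spike reads yields fpkmCa (fragments per kilobase per
million *C. albicans* reads), a per-cell-proportional expression unit
that makes transcriptome *size* comparable between samples.  On this
scale one can ask whether individual mRNAs scale with cell volume.

Pipeline: compute_fpkm_ca -> filter_genes (protein-coding, expression
floor, coefficient-of-variation ceiling) -> scaling_analysis (per-gene
fold change vs volume-expected fold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "FilterReport",
    "compute_fpkm_ca",
    "filter_genes",
    "scaling_analysis",
    "total_expression",
]


@dataclass(frozen=True)
class CountMatrix:
    """Genes x samples fragment counts plus spike-in metadata.

    Attributes
    ----------
    counts : DataFrame (genes x samples), non-negative integers
    lengths : Series, bp, indexed by gene
    spike_reads : Series, total C. albicans reads per sample
    volumes : Series, optional
        Per-sample cell volume (excluding vacuole), fL.
    protein_coding : Series of bool, indexed by gene
        Defaults to all True.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    spike_reads: pd.Series
    volumes: pd.Series | None = None
    protein_coding: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.lengths.index.equals(self.counts.index):
            raise ValueError("lengths index must match count genes")
        if not self.spike_reads.index.equals(self.counts.columns):
            raise ValueError("spike_reads index must match count samples")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.spike_reads <= 0).any():
            raise ValueError("spike read totals must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.protein_coding is None:
            object.__setattr__(
                self,
                "protein_coding",
                pd.Series(True, index=self.counts.index),
            )
        elif not self.protein_coding.index.equals(self.counts.index):
            raise ValueError("protein_coding index must match count genes")
        if self.volumes is not None and not self.volumes.index.equals(
            self.counts.columns
        ):
            raise ValueError("volumes index must match count samples")


@dataclass(frozen=True)
class NormalizedMatrix:
    """fpkmCa expression values with processing provenance."""

    values: pd.DataFrame  # genes x samples, fpkmCa
    volumes: pd.Series | None = None
    provenance: dict = field(default_factory=dict)
    protein_coding: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("normalized values must be non-negative")


@dataclass(frozen=True)
class FilterReport:
    """Gene counts surviving each filtering step."""

    n_input: int
    n_protein_coding: int
    n_after_expression: int
    n_after_cv: int
    n_cv_undefined: int  # genes whose CV was undefined (mean log2 <= 0)

    def __str__(self) -> str:  # "3 -> 2 -> 1" style summary
        return (
            f"{self.n_input} genes -> {self.n_protein_coding} protein coding "
            f"-> {self.n_after_expression} expressed "
            f"-> {self.n_after_cv} after CV filter "
            f"({self.n_cv_undefined} with undefined CV excluded)"
        )


def compute_fpkm_ca(m: CountMatrix) -> NormalizedMatrix:
    """Fragments per kilobase per million spike (C. albicans) reads.

    ``value = count / (length_bp/1000) / (spike_reads/1e6)`` per
    sample.  Because the spike cell number is constant across samples,
    fpkmCa is proportional to per-cell transcript abundance.
    """
    per_kb = m.counts.div(m.lengths / 1_000.0, axis=0)
    values = per_kb.div(m.spike_reads / 1e6, axis=1)
    return NormalizedMatrix(
        values=values,
        volumes=m.volumes,
        provenance={"unit": "fpkmCa"},
        protein_coding=m.protein_coding,
    )


def filter_genes(
    nm: NormalizedMatrix,
    min_log2: float = 2.0,
    max_cv: float = 0.5,
    pseudocount: float = 1.0,
    expression_rule: str = "mean",
) -> tuple[NormalizedMatrix, FilterReport]:
    """Three-step gene filter on log2 fpkmCa.

    1. restrict to protein-coding genes;
    2. keep genes with log2(value + pseudocount) > ``min_log2``,
       aggregated across samples by ``expression_rule`` ("mean",
       "min" = every sample, or "any" = at least one sample);
    3. keep genes whose coefficient of variation (sd/mean) of log2
       values is <= ``max_cv``.  Genes with mean log2 <= 0 have an
       undefined CV and are excluded (counted in the report).

    Returns the filtered matrix and a report of gene counts after each
    step.
    """
    if nm.values.shape[1] < 2:
        raise ValueError("the CV step needs at least 2 samples")
    if expression_rule not in ("mean", "min", "any"):
        raise ValueError(f"unknown expression_rule {expression_rule!r}")
    vals = nm.values
    n_input = vals.shape[0]
    pc = (
        nm.protein_coding
        if nm.protein_coding is not None
        else pd.Series(True, index=vals.index)
    )
    vals = vals.loc[pc]
    n_pc = vals.shape[0]

    log2 = np.log2(vals + pseudocount)
    if expression_rule == "mean":
        expressed = log2.mean(axis=1) > min_log2
    elif expression_rule == "min":
        expressed = (log2 > min_log2).all(axis=1)
    else:  # any
        expressed = (log2 > min_log2).any(axis=1)
    log2 = log2.loc[expressed]
    n_expr = log2.shape[0]

    mean = log2.mean(axis=1)
    sd = log2.std(axis=1, ddof=1)
    defined = mean > 0
    cv_ok = defined & (sd / mean.where(defined) <= max_cv)
    n_undef = int((~defined).sum())
    kept = cv_ok[cv_ok].index

    report = FilterReport(
        n_input=n_input,
        n_protein_coding=n_pc,
        n_after_expression=n_expr,
        n_after_cv=kept.size,
        n_cv_undefined=n_undef,
    )
    filtered = NormalizedMatrix(
        values=nm.values.loc[kept],
        volumes=nm.volumes,
        provenance={
            **nm.provenance,
            "filter": {
                "min_log2": min_log2,
                "max_cv": max_cv,
                "pseudocount": pseudocount,
                "expression_rule": expression_rule,
            },
        },
        protein_coding=pc.loc[kept] if nm.protein_coding is not None else None,
    )
    return filtered, report


def scaling_analysis(
    nm: NormalizedMatrix,
    reference_sample: str,
    volumes: pd.Series | None = None,
    tolerance: float = 0.3,
    pseudocount: float = 1.0,
    sample: str | None = None,
) -> pd.DataFrame:
    """Per-gene volume-scaling classification against a reference sample.

    For each gene and sample: ``fold = (value + pc)/(value_ref + pc)``,
    ``expected_fold = volume/volume_ref`` (the gray-line expectation of
    expression increasing proportionally with vacuole-excluded cell
    volume), ``scaling_ratio = fold/expected_fold``, and
    ``scales = |log2 scaling_ratio| <= log2(1 + tolerance)``.

    By default the last non-reference sample is scored; pass ``sample``
    to score another.  Returns a DataFrame indexed by gene with columns
    fold, expected_fold, scaling_ratio, scales.
    """
    vols = volumes if volumes is not None else nm.volumes
    if vols is None:
        raise ValueError("per-sample volumes are required")
    if reference_sample not in nm.values.columns:
        raise ValueError(f"unknown reference sample {reference_sample!r}")
    if sample is None:
        others = [c for c in nm.values.columns if c != reference_sample]
        if not others:
            raise ValueError("need a non-reference sample to score")
        sample = others[-1]
    v_ref = nm.values[reference_sample] + pseudocount
    v_s = nm.values[sample] + pseudocount
    fold = v_s / v_ref
    expected = float(vols[sample] / vols[reference_sample])
    ratio = fold / expected
    return pd.DataFrame(
        {
            "fold": fold,
            "expected_fold": expected,
            "scaling_ratio": ratio,
            "scales": np.abs(np.log2(ratio)) <= np.log2(1.0 + tolerance),
        }
    )


def total_expression(nm: NormalizedMatrix) -> pd.Series:
    """Per-sample sum of fpkmCa — total transcriptome size per cell."""
    return nm.values.sum(axis=0)
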