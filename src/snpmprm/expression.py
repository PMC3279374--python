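"""Expression-side contracts: exon/gene ratio normalisation, expressed-gene
filtering, and expressed-miRNA determination from array detection p-values."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .tse import bh_adjust

logger = logging.getLogger(__name__)


class UndefinedRatioError(ValueError):
    """Exon/gene ratio requested with a non-positive gene intensity."""


@dataclass
class ExpressionMatrix:
    """Features x samples matrix of log2 intensities (or log2 ratios) with
    per-sample sex labels coded 1/2."""

    values: pd.DataFrame  # index = feature ids, columns = sample ids
    sex: pd.Series  # index = sample ids, values in {1, 2}

    def __post_init__(self) -> None:
        self.sex = self.sex.reindex(self.values.columns)
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, expr_path: str | Path, sex_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        sex_df = pd.read_csv(sex_path, sep="\t", index_col=0)
        return cls(values, sex_df.iloc[:, 0].astype(int))


@dataclass
class DetectionMatrix:
    """miRNAs x samples matrix of array detection p-values."""

    pvals: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.pvals.to_numpy()
        if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
            raise ValueError("detection p-values outside [0, 1]")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DetectionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def exon_ratio(probe_set_intensity: float, gene_intensity: float) -> float:
    """Probe-set intensity normalised by the intensity of its gene.

    Downstream fits consume log2 of this ratio, so the gene-level component
    of the signal cancels and the exon-specific part remains.
    """
    if gene_intensity <= 0:
        raise UndefinedRatioError(f"gene intensity must be positive, got {gene_intensity}")
    return probe_set_intensity / gene_intensity


def expressed_mirnas(det: DetectionMatrix, alpha: float = 0.05) -> set[str]:
    """miRNAs whose BH-adjusted median detection p-value is below ``alpha``.

    The median is taken per miRNA across all supplied sample columns; the BH
    correction is applied across miRNAs.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if det.pvals.empty:
        return set()
    medians = det.pvals.median(axis=1)
    adj = bh_adjust(medians.to_numpy())
    return set(medians.index[adj < alpha])


def expressed_genes(expr: ExpressionMatrix,
                    statistic: Callable[[pd.DataFrame], pd.Series] | None = None,
                    threshold: Optional[float] = None,
                    quantile: float = 0.25) -> set[str]:
    """Features called expressed under an explicit, logged rule.

    Default rule: median log2 intensity strictly above the ``quantile``-th
    quantile of all feature medians (a fixed ``threshold`` overrides the
    quantile).  The rule in force is written to the log so every run records
    how "expressed" was decided.
    """
    stat = (lambda df: df.median(axis=1)) if statistic is None else statistic
    values = stat(expr.values)
    if threshold is None:
        threshold = float(values.quantile(quantile))
        rule = f"median log2 intensity > {quantile:.0%} quantile ({threshold:.4g})"
    else:
        rule = f"statistic > fixed threshold {threshold:.4g}"
    logger.info("expressed-gene rule: %s", rule)
    return set(values.index[values > threshold])
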