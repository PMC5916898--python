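"""Calling DNA-proximal peptides from dimethyl-label forward/control ratios.

Peptides cross-linked to DNA are enriched in the forward channel of a
duplicate light/heavy dimethyl-labeling experiment.  Normalized ratios are
log2-transformed and a peptide is called enriched when its log2 ratio exceeds
the Tukey upper fence, Q3 + 1.5 * IQR (quartiles by linear interpolation), in
every replicate.  Calling is upper-tail only: depletion is not of interest
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import TableFormatError

logger = logging.getLogger(__name__)


@dataclass
class OutlierResult:
    """Called ids plus the per-replicate log2 ratios and fence thresholds."""

    called: list[str]
    thresholds: dict[str, float]
    log2_ratios: pd.DataFrame


def read_ratio_table(path, id_col: str = "id") -> pd.DataFrame:
    """TSV of id plus one positive-ratio column per replicate."""
    df = pd.read_csv(path, sep="\t", dtype={id_col: str})
    if id_col not in df.columns:
        raise TableFormatError(f"missing id column {id_col!r}")
    return df.set_index(id_col).astype(float)


def call_outliers(ratios: pd.DataFrame, iqr_mult: float = 1.5) -> OutlierResult:
    """Call upper-tail outliers jointly across replicates.

    ``ratios`` is indexed by peptide/protein id with one column per replicate.
    Ids with a missing value in any replicate are excluded (logged).  Per
    replicate the threshold is Q3 + ``iqr_mult`` * (Q3 - Q1) on the log2
    scale; an id is called iff it exceeds the threshold in every replicate.
    Because log2 turns a per-replicate scale factor into an additive shift
    that moves quartiles and data alike, the call set is invariant to
    rescaling any replicate by a constant.
    """
    if ratios.shape[1] < 2:
        raise ValueError("outlier calling needs at least two replicates")
    complete = ratios.dropna()
    dropped = len(ratios) - len(complete)
    if dropped:
        logger.warning("excluding %d ids with missing ratios", dropped)
    if (complete.to_numpy() <= 0).any():
        raise TableFormatError("ratios must be strictly positive")
    log2 = np.log2(complete)
    thresholds: dict[str, float] = {}
    above = pd.Series(True, index=log2.index)
    for col in log2.columns:
        q1, q3 = np.percentile(log2[col], [25, 75])  # linear interpolation
        thr = q3 + iqr_mult * (q3 - q1)
        thresholds[str(col)] = float(thr)
        above &= log2[col] > thr
    return OutlierResult(
        called=list(log2.index[above]), thresholds=thresholds, log2_ratios=log2
    )
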