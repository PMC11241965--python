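"""Bridge-sample ratio correction harmonising batch-2 intensities to batch 1.

A handful of identical samples (aliquots) are measured in both batches.  For
each protein the correction factor is the mean ratio of the batch-2 to the
batch-1 measurement over the bridge pairs,

    f_p = (1/n) * sum_i X'_i / X_i,

and every batch-2 measurement Y is corrected to  Z = Y / f_p.  With a purely
multiplicative batch effect g_p every bridge ratio equals g_p, so f_p recovers
g_p exactly and corrected values land on the batch-1 scale.  Correction is
applied on raw intensities, before the log10 transform, and per fluid.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import AbundanceTable

__all__ = ["BridgeBatchCorrector", "compute_bridge_ratios", "apply_correction",
           "correct_batches"]

logger = logging.getLogger(__name__)


class BridgeBatchCorrector(BaseEstimator):
    """Per-protein ratio correction estimated from bridge-sample pairs.

    Parameters
    ----------
    min_pairs
        Minimum number of usable (both-observed) bridge pairs required for a
        protein's factor to be defined; proteins below the minimum become
        missing in the corrected output.  Set to the number of bridge samples
        to require complete bridges.

    Attributes
    ----------
    ratios_ : pandas.Series
        Correction factor ``f_p`` per protein (NaN where undefined).
    n_used_ : pandas.Series
        Count of usable bridge pairs per protein.
    """

    def __init__(self, min_pairs: int = 1):
        self.min_pairs = min_pairs

    def fit(self, batch1: AbundanceTable, batch2: AbundanceTable,
            bridge_pairs: Sequence) -> "BridgeBatchCorrector":
        """Estimate per-protein factors from paired bridge measurements.

        ``bridge_pairs`` lists (sample_id_in_batch1, sample_id_in_batch2).
        Pairs with a missing member are dropped from the mean; a zero batch-1
        denominator is skipped with a warning.
        """
        if batch1.scale != "raw" or batch2.scale != "raw":
            raise ValueError("bridge correction operates on raw-scale tables")
        if not len(bridge_pairs):
            raise ValueError("at least one bridge pair is required")
        if self.min_pairs < 1:
            raise ValueError("min_pairs must be >= 1")
        common = batch1.data.index.intersection(batch2.data.index)
        ratios = []
        for id1, id2 in bridge_pairs:
            x = batch1.data.loc[common, id1]
            xp = batch2.data.loc[common, id2]
            zero = x == 0
            if np.asarray(zero).any():
                logger.warning("zero batch-1 denominator in bridge pair (%s, %s) "
                               "for %d protein(s); pair skipped there",
                               id1, id2, int(np.asarray(zero).sum()))
                x = x.where(~zero)
            ratios.append(xp / x)
        ratio_frame = pd.concat(ratios, axis=1)
        n_used = ratio_frame.notna().sum(axis=1)
        f = ratio_frame.mean(axis=1)
        f[n_used < self.min_pairs] = np.nan
        self.ratios_ = f
        self.n_used_ = n_used
        return self

    def transform(self, batch2: AbundanceTable) -> AbundanceTable:
        """Correct batch-2 measurements: ``Z = Y / f_p``.

        Proteins without a defined factor become missing in the output.
        """
        if not hasattr(self, "ratios_"):
            raise RuntimeError("corrector is not fitted")
        if batch2.scale != "raw":
            raise ValueError("bridge correction operates on raw-scale tables")
        f = self.ratios_.reindex(batch2.data.index)
        corrected = batch2.data.div(f, axis=0)
        return AbundanceTable(corrected, scale="raw")


def compute_bridge_ratios(batch1: AbundanceTable, batch2: AbundanceTable,
                          bridge_pairs: Sequence,
                          min_pairs: int = 1) -> BridgeBatchCorrector:
    """Fit a :class:`BridgeBatchCorrector` (functional wrapper)."""
    return BridgeBatchCorrector(min_pairs=min_pairs).fit(batch1, batch2, bridge_pairs)


def apply_correction(batch2: AbundanceTable,
                     corrector: BridgeBatchCorrector) -> AbundanceTable:
    """Apply a fitted correction to a batch-2 table (functional wrapper)."""
    return corrector.transform(batch2)


def correct_batches(table: AbundanceTable, info: pd.DataFrame,
                    bridge_pairs: Sequence, min_pairs: int = 1,
                    drop_bridge_duplicates: bool = True) -> AbundanceTable:
    """Correct the batch-2 columns of a merged two-batch table in place.

    Batch-1 columns pass through unchanged.  The batch-2 re-measurements of
    the bridge samples are dropped after estimation by default (the batch-1
    measurement represents the sample downstream).
    """
    ids = set(table.sample_ids)
    b1_ids = [s for s in info.loc[info["batch"] == 1, "sample_id"] if s in ids]
    b2_ids = [s for s in info.loc[info["batch"] == 2, "sample_id"] if s in ids]
    corrector = compute_bridge_ratios(
        table.subset_samples(b1_ids), table.subset_samples(b2_ids),
        bridge_pairs, min_pairs=min_pairs,
    )
    corrected_b2 = corrector.transform(table.subset_samples(b2_ids))
    merged = pd.concat([table.data[b1_ids], corrected_b2.data], axis=1)
    merged = merged[[s for s in table.sample_ids if s in set(b1_ids) | set(b2_ids)]]
    if drop_bridge_duplicates:
        dup_ids = [b2 for _, b2 in bridge_pairs]
        merged = merged.drop(columns=[c for c in dup_ids if c in merged.columns])
    return AbundanceTable(merged, scale="raw")
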