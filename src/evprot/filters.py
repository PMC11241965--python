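"""Detection-rate filters defining analysis universes.

Two rules recur in EV proteomics: keep only proteins detected in *every*
sample of a reference set (the "complete" universe used for differential
testing), and flag disease-specific proteins detected in nearly all patient
samples but almost never in controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io import AbundanceTable, detection_rate

__all__ = ["FilterSpec", "complete_proteins", "sals_specific"]


@dataclass
class FilterSpec:
    """Thresholds for the disease-specific detection filter.

    Inclusive bounds by default (case rate >= ``case_min_rate`` and control
    rate <= ``control_max_rate``); set ``strict=True`` for strict
    inequalities.
    """

    case_min_rate: float = 0.90
    control_max_rate: float = 0.10
    strict: bool = False

    def __post_init__(self) -> None:
        for r in (self.case_min_rate, self.control_max_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


def complete_proteins(table: AbundanceTable, sample_subset: Iterable) -> set:
    """Proteins detected in all samples of the subset (detection rate 1)."""
    rates = detection_rate(table, sample_subset)
    return set(rates.index[rates == 1.0])


def sals_specific(table: AbundanceTable, case_subset: Iterable,
                  control_subset: Iterable,
                  spec: FilterSpec | None = None) -> set:
    """Proteins near-ubiquitous in case samples and near-absent in controls.

    The case subset should be restricted to drug-naive patient samples.
    """
    spec = spec or FilterSpec()
    case_ids, control_ids = list(case_subset), list(control_subset)
    if not case_ids or not control_ids:
        raise ValueError("case and control subsets must be non-empty")
    if set(case_ids) & set(control_ids):
        raise ValueError("case and control subsets must be disjoint")
    case_rate = detection_rate(table, case_ids)
    control_rate = detection_rate(table, control_ids)
    if spec.strict:
        keep = (case_rate > spec.case_min_rate) & (control_rate < spec.control_max_rate)
    else:
        keep = (case_rate >= spec.case_min_rate) & (control_rate <= spec.control_max_rate)
    return set(keep.index[keep])
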