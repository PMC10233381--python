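"""Densitometry fold-change and comparative-CT relative expression.

Two small, exactly-specified calculations used to quantify validation
experiments:

* :func:`western_fold_change` — the ratio-of-ratios for co-IP western
  blots.  For one specimen, each band is divided through the chain
  ``IP_x / Input_x / loading`` and referenced to the bait
  (``IP_ref / Input_ref / loading``); the fold change is the subject's
  ratio over the control's.  The division chain is evaluated
  left-associatively, under which the loading control cancels within each
  specimen's ratio — a documented algebraic consequence of the formula's
  linearization, not an omission.
* :func:`ddct_expression` — comparative-CT qPCR: replicate CT values are
  averaged per condition, normalized against a housekeeping gene
  (dCT = CT_target - CT_housekeeping), referenced to a calibrator condition
  (ddCT), and converted to relative expression ``2**(-ddCT)`` assuming
  perfect amplification efficiency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["BandQuant", "CtCondition", "western_fold_change", "ddct_expression"]


@dataclass(frozen=True)
class BandQuant:
    """Densitometry readings for one specimen (subject or control).

    ``x`` is the protein of interest, ``ref`` the bait reference protein;
    ``loading`` is the loading-control band (e.g. GAPDH).  All values are
    positive densitometry units.
    """

    ip_x: float
    input_x: float
    ip_ref: float
    input_ref: float
    loading: float

    def __post_init__(self) -> None:
        for name in ("ip_x", "input_x", "ip_ref", "input_ref", "loading"):
            if getattr(self, name) <= 0:
                raise ValueError(f"BandQuant.{name} must be > 0")

    def ratio(self) -> float:
        """(IP_x / Input_x / loading) / (IP_ref / Input_ref / loading), left-associative."""
        num = self.ip_x / self.input_x / self.loading
        den = self.ip_ref / self.input_ref / self.loading
        return num / den


def western_fold_change(subject: BandQuant, control: BandQuant) -> float:
    """Fold change of the protein of interest in the subject relative to control."""
    return subject.ratio() / control.ratio()


@dataclass(frozen=True)
class CtCondition:
    """Replicate CT cycles for one condition: target gene and housekeeping gene."""

    ct_target: tuple
    ct_housekeeping: tuple

    def __post_init__(self) -> None:
        if not self.ct_target or not self.ct_housekeeping:
            raise ValueError("each condition needs >=1 replicate CT for both genes")
        for v in (*self.ct_target, *self.ct_housekeeping):
            if not (0.0 <= v <= 45.0):
                logger.warning("CT value %.2f outside the [0, 45] sanity band", v)

    def delta_ct(self) -> float:
        return float(np.mean(self.ct_target)) - float(np.mean(self.ct_housekeeping))


def ddct_expression(test: CtCondition, calibrator: CtCondition) -> float:
    """Relative expression ``2**(-ddCT)`` of the test condition vs the calibrator."""
    ddct = test.delta_ct() - calibrator.delta_ct()
    return 2.0 ** (-ddct)
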