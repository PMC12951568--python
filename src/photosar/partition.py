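"""Fluorescence-based octanol/PBS partition coefficient (log P).

The dye is partitioned between n-octanol and PBS, an aliquot of each
layer is diluted into DMF, and the emission spectra are recorded.
Because both aliquots are measured under identical conditions, the
ratio of integrated emission areas equals the concentration ratio:

    log P = log10(F_oct / F_PBS)

Replicates (triplicates in the standard protocol) are averaged on the
log scale — each run yields its own log P and the mean/SD of those is
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .spectra import Spectrum, integrate_emission

__all__ = ["PartitionExperiment", "log_p", "aggregate_partition"]


@dataclass(frozen=True)
class PartitionExperiment:
    """Paired octanol/PBS-layer emission spectra for one replicate."""

    octanol_emission: Spectrum
    pbs_emission: Spectrum
    integration_range_nm: Optional[Tuple[float, float]] = None
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.octanol_emission.kind != "emission" or self.pbs_emission.kind != "emission":
            raise ValueError("both spectra must be emission spectra")
        exc_o = self.octanol_emission.excitation_nm
        exc_p = self.pbs_emission.excitation_nm
        if exc_o != exc_p:
            raise ValueError(
                f"layers measured at different excitation wavelengths "
                f"({exc_o} vs {exc_p} nm)"
            )


def log_p(exp: PartitionExperiment) -> float:
    """log10 ratio of integrated octanol to PBS emission areas."""
    f_oct = integrate_emission(exp.octanol_emission, exp.integration_range_nm)
    f_pbs = integrate_emission(exp.pbs_emission, exp.integration_range_nm)
    if f_oct <= 0 or f_pbs <= 0:
        raise ValueError(
            f"layer signal below detection (F_oct={f_oct:g}, F_PBS={f_pbs:g})"
        )
    return math.log10(f_oct / f_pbs)


def aggregate_partition(replicates: Sequence[float]) -> Tuple[float, Optional[float]]:
    """Mean and sample SD of per-replicate log P values.

    With a single replicate the SD is undefined and returned as None.
    """
    if len(replicates) == 0:
        raise ValueError("no replicates to aggregate")
    mean = float(np.mean(replicates))
    sd = float(np.std(replicates, ddof=1)) if len(replicates) >= 2 else None
    return mean, sd
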