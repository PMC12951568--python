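"""Light dose, viability normalization, and 4PL EC50 fitting.

Phototoxicity plates are normalized against untreated wells (100%
viability) and wells killed with a lethal hydrogen-peroxide dose (0%):

    v% = 100 * (raw - killed) / (untreated - killed)

Normalized viabilities are fit with a four-parameter logistic on
log10 concentration,

    v(c) = bottom + (top - bottom) / (1 + (c / EC50)^h),

with a free Hill slope h.  Following the reporting convention of the
underlying assay ("mean +- SD of at least three independent
experiments"), each independent experiment is fit separately and the
mean and SD of the per-experiment EC50s are reported; a pooled fit
with the asymptotic standard error is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseTable",
    "EC50Result",
    "LightDose",
    "light_fluence",
    "normalize_viability",
    "fit_ec50",
]


@dataclass(frozen=True)
class LightDose:
    irradiance_mW_cm2: float
    duration_s: float
    fluence_J_cm2: float


@dataclass(frozen=True)
class DoseResponseTable:
    """Raw plate signals: concentrations x (experiment, replicate).

    ``viability_raw`` is laid out [n_concentrations, n_experiments,
    n_replicates]; the control anchors are per-table scalars.
    Concentration 0 (untreated wells) is never part of the fit — the
    untreated signal enters only through normalization.
    """

    concentrations_nM: np.ndarray
    viability_raw: np.ndarray
    untreated_signal: float
    killed_signal: float
    cell_line: str = ""
    experiment_id: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_nM, dtype=float)
        v = np.asarray(self.viability_raw, dtype=float)
        if v.ndim == 2:  # single experiment
            v = v[:, None, :]
        object.__setattr__(self, "concentrations_nM", c)
        object.__setattr__(self, "viability_raw", v)
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive (0 = untreated control)")
        if np.unique(c).size < 5:
            raise ValueError("need at least 5 distinct concentrations")
        if v.shape[0] != c.size:
            raise ValueError("viability matrix rows must match concentrations")
        if np.any(v < 0):
            raise ValueError("raw signals must be nonnegative")
        if self.untreated_signal <= self.killed_signal:
            raise ValueError("untreated signal must exceed killed-control signal")
        if v.shape[2] < 3:
            warnings.warn(
                f"only {v.shape[2]} replicates; the standard protocol uses >= 3",
                stacklevel=2,
            )

    @property
    def n_experiments(self) -> int:
        return self.viability_raw.shape[1]


@dataclass
class EC50Result:
    ec50_nM: float
    hill: float
    top_pct: float
    bottom_pct: float
    sd_nM: Optional[float]
    n_experiments: int
    flags: Tuple[str, ...] = field(default_factory=tuple)


def light_fluence(irradiance_mW_cm2: float, duration_s: float) -> LightDose:
    """Delivered light dose: fluence (J/cm^2) = irradiance x time / 1000.

    The fluence is rounded to 3 significant figures, the precision at
    which doses are conventionally quoted (e.g. 12.4 mW/cm^2 for
    15 min -> 11.2 J/cm^2).
    """
    if irradiance_mW_cm2 <= 0 or duration_s <= 0:
        raise ValueError("irradiance and duration must be positive")
    fluence = irradiance_mW_cm2 * duration_s / 1000.0
    fluence = float(np.format_float_positional(fluence, precision=3, fractional=False))
    return LightDose(irradiance_mW_cm2, duration_s, fluence)


def normalize_viability(table: DoseResponseTable) -> np.ndarray:
    """Percent viability anchored at the untreated (100%) and killed (0%)
    controls.  Values outside [0, 100] are kept (noise can push a well
    past an anchor) but warned about.
    """
    span = table.untreated_signal - table.killed_signal
    pct = 100.0 * (table.viability_raw - table.killed_signal) / span
    if pct.min() < -50 or pct.max() > 150:
        warnings.warn(
            "normalized viability far outside [0, 100]%; check control wells",
            stacklevel=2,
        )
    return pct


def _four_pl(logc: np.ndarray, top: float, bottom: float, log_ec50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logc - log_ec50) * hill))


def _fit_single(conc: np.ndarray, v: np.ndarray) -> Tuple[float, float, float, float, float]:
    """4PL fit of one experiment; returns (ec50, hill, top, bottom, se_log_ec50)."""
    logc = np.log10(conc)
    span = v.max() - v.min()
    if span < 10.0:  # less than 10 percentage points of effect
        raise ValueError("EC50 not identifiable: no transition in the data")
    # initialize EC50 from the 50%-crossing of the mean response
    order = np.argsort(logc)
    mid = (v.max() + v.min()) / 2.0
    crossing = np.interp(mid, v[order][::-1], logc[order][::-1])
    p0 = [v.max(), v.min(), float(crossing), 1.0]
    bounds = (
        [v.min() - 50, v.min() - 50, logc.min() - 3, 0.05],
        [v.max() + 50, v.max() + 50, logc.max() + 3, 20.0],
    )
    popt, pcov = curve_fit(_four_pl, logc, v, p0=p0, bounds=bounds, maxfev=20000)
    top, bottom, log_ec50, hill = popt
    if top <= bottom:
        raise ValueError("degenerate fit: top <= bottom")
    se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else float("nan")
    return float(10.0 ** log_ec50), float(hill), float(top), float(bottom), se


def fit_ec50(
    normalized_pct: np.ndarray,
    concentrations_nM: np.ndarray,
    per_experiment: bool = True,
) -> EC50Result:
    """Fit the 4PL model and report EC50.

    ``normalized_pct`` is [n_conc, n_experiments, n_replicates] (or
    [n_conc, n_replicates] for a single experiment).  With
    ``per_experiment=True`` (the default) each experiment is fit
    separately and the mean +- sample SD of the per-experiment EC50s
    is returned; otherwise all wells are pooled into one fit and the
    asymptotic SE of the EC50 (delta method from the log10 scale) is
    reported.
    """
    v = np.asarray(normalized_pct, dtype=float)
    conc = np.asarray(concentrations_nM, dtype=float)
    if v.ndim == 2:
        v = v[:, None, :]
    flags: list[str] = []
    if per_experiment and v.shape[1] > 1:
        fits = []
        for e in range(v.shape[1]):
            ve = v[:, e, :]
            c_rep = np.repeat(conc, ve.shape[1])
            fits.append(_fit_single(c_rep, ve.ravel()))
        ec50s = np.array([f[0] for f in fits])
        ec50 = float(ec50s.mean())
        sd = float(ec50s.std(ddof=1))
        hill = float(np.mean([f[1] for f in fits]))
        top = float(np.mean([f[2] for f in fits]))
        bottom = float(np.mean([f[3] for f in fits]))
        n_exp = v.shape[1]
    else:
        c_rep = np.repeat(conc, v.shape[1] * v.shape[2])
        ec50, hill, top, bottom, se_log = _fit_single(c_rep, v.ravel())
        sd = float(ec50 * np.log(10.0) * se_log) if np.isfinite(se_log) else None
        n_exp = v.shape[1]
        flags.append("pooled_fit_se")
    if not (conc.min() <= ec50 <= conc.max()):
        flags.append("ec50_extrapolated")
    return EC50Result(
        ec50_nM=ec50,
        hill=hill,
        top_pct=top,
        bottom_pct=bottom,
        sd_nM=sd,
        n_experiments=n_exp,
        flags=tuple(flags),
    )
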