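"""Forward models generating every input type the pipeline consumes.

Each generator emulates one laboratory measurement with known ground
truth, so every analysis stage can be exercised as a closed loop:
composing a generator with its stage at zero noise returns the truth
parameter (inverse consistency), and seeded noisy runs quantify
estimator spread.

What is emulated
----------------
* absorption spectra: Gaussian Q-band (default FWHM 18 nm) with a
  weak vibronic shoulder 60 nm to the blue, an optional second
  maximum for split bands, and an optional broad blue-shifted
  H-aggregate band whose weight trades off against the monomer band;
* emission spectra: mirror image of the Q-band displaced by the
  Stokes shift (~10 nm for monomeric phthalocyanines);
* DPBF photobleaching: first-order decay of the 415 nm trap
  absorbance, with the sample rate derived by inverting the
  comparative singlet-oxygen formula (using the same 2.3 exponent
  convention as the analysis);
* TCSPC decays: amplitude-weighted multi-exponentials with Poisson
  counting noise;
* viability plates: four-parameter-logistic response back-transformed
  through untreated/killed control anchors, Gaussian noise in
  percentage points;
* partition pairs: emission spectra whose area ratio encodes log P;
* BSA titrations: spectral series constructed to realize each
  response category with a comfortable margin over the classifier
  thresholds;
* SAR panels: log-normal EC50s with tag-dependent shifts.

Noise defaults are the study conditions: negligible spectrometer
noise, Poisson counting statistics for TCSPC, and 5 percentage points
of plate noise.  Identical configuration (including seed) reproduces
identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .bsa import CATEGORIES, TitrationSeries
from .dose_response import DoseResponseTable, EC50Result
from .lifetime import DecayTrace
from .partition import PartitionExperiment
from .photophysics import PhotobleachSeries, absorbed_light
from .sar import TAG_VOCABULARY, CompoundRecord, parse_tag_query
from .spectra import Spectrum, _uniform_grid

__all__ = [
    "GeneratorConfig",
    "gen_spectra_pair",
    "gen_dpbf_experiment",
    "gen_tcspc_decay",
    "gen_dose_response",
    "gen_partition_pair",
    "gen_bsa_titration",
    "gen_panel",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed, grid and per-channel noise levels for all generators."""

    seed: int = 0
    grid_step_nm: float = 0.5
    wavelength_range_nm: Tuple[float, float] = (300.0, 900.0)
    # band-shape constants (the tabulated data give only maxima; these
    # widths reproduce the visual appearance of monomeric Q-bands)
    qband_fwhm_nm: float = 18.0
    vibronic_offset_nm: float = 60.0
    vibronic_height_frac: float = 0.2
    aggregate_offset_nm: float = 40.0
    aggregate_fwhm_nm: float = 30.0
    aggregate_height_frac: float = 0.7
    # noise models
    spectrum_noise_frac: float = 0.0  # multiplicative Gaussian
    dpbf_noise_frac: float = 0.0  # multiplicative Gaussian on A_t
    viability_noise_pct: float = 5.0  # additive Gaussian, percentage points
    poisson_counts: bool = True  # TCSPC counting statistics
    tcspc_background_counts: float = 1.0

    def __post_init__(self) -> None:
        for name in ("spectrum_noise_frac", "dpbf_noise_frac", "viability_noise_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _gauss(wl: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def _apply_mult_noise(values: np.ndarray, frac: float, rng: np.random.Generator):
    if frac <= 0:
        return values
    return values * (1.0 + frac * rng.standard_normal(values.shape))


def gen_spectra_pair(
    lambda_A_nm: float,
    stokes_nm: float,
    epsilon_M1cm1: float,
    conc_M: float,
    aggregate_fraction: float = 0.0,
    split_second_peak: Optional[Tuple[float, float]] = None,
    cfg: GeneratorConfig = GeneratorConfig(),
    solvent: str = "DMF",
    emission_scale: float = 1.0,
) -> Tuple[Spectrum, Spectrum]:
    """Monomeric/aggregated absorption spectrum and its mirror emission.

    The monomer Q-band peaks at ``lambda_A_nm`` with absorbance
    A_max = (1 - aggregate_fraction) * epsilon * c * l; the aggregate
    band sits ``cfg.aggregate_offset_nm`` to the blue, broadened, with
    weight proportional to ``aggregate_fraction``.
    ``split_second_peak = (wavelength_nm, relative_height)`` adds a
    second Q-band maximum for low-symmetry chromophores.  Emission is
    the mirrored Q-band displaced by ``stokes_nm`` and scaled by the
    monomer fraction (aggregates are non-emissive).
    """
    if not (0.0 <= aggregate_fraction <= 1.0):
        raise ValueError("aggregate_fraction must lie in [0, 1]")
    rng = cfg.rng()
    lo, hi = cfg.wavelength_range_nm
    wl = _uniform_grid(lo, hi, cfg.grid_step_nm)

    a_mono = (1.0 - aggregate_fraction) * epsilon_M1cm1 * conc_M
    absorbance = a_mono * (
        _gauss(wl, lambda_A_nm, cfg.qband_fwhm_nm)
        + cfg.vibronic_height_frac
        * _gauss(wl, lambda_A_nm - cfg.vibronic_offset_nm, cfg.qband_fwhm_nm + 2.0)
    )
    if split_second_peak is not None:
        lam2, rel = split_second_peak
        absorbance = absorbance + a_mono * rel * _gauss(wl, lam2, cfg.qband_fwhm_nm)
    if aggregate_fraction > 0:
        a_agg = aggregate_fraction * epsilon_M1cm1 * conc_M * cfg.aggregate_height_frac
        absorbance = absorbance + a_agg * _gauss(
            wl, lambda_A_nm - cfg.aggregate_offset_nm, cfg.aggregate_fwhm_nm
        )
    absorbance = _apply_mult_noise(absorbance, cfg.spectrum_noise_frac, rng)

    lam_F = lambda_A_nm + stokes_nm
    em = (1.0 - aggregate_fraction) * emission_scale * (
        _gauss(wl, lam_F, cfg.qband_fwhm_nm)
        + cfg.vibronic_height_frac
        * _gauss(wl, lam_F + cfg.vibronic_offset_nm, cfg.qband_fwhm_nm + 2.0)
    )
    em = np.clip(_apply_mult_noise(em, cfg.spectrum_noise_frac, rng), 0.0, None)

    absorption = Spectrum(
        kind="absorption",
        wavelengths_nm=wl,
        values=absorbance,
        solvent=solvent,
        concentration_M=conc_M,
    )
    emission = Spectrum(
        kind="emission",
        wavelengths_nm=wl,
        values=em,
        solvent=solvent,
        concentration_M=conc_M,
        excitation_nm=lambda_A_nm - 70.0,
    )
    return absorption, emission


def gen_dpbf_experiment(
    true_phi_sample: float,
    phi_reference: float,
    abs_sample: Spectrum,
    abs_reference: Spectrum,
    excitation_profile: Spectrum,
    k_reference: float = 0.01,
    times_s: Sequence[float] = tuple(range(0, 121, 10)),
    A0: float = 0.9,
    cfg: GeneratorConfig = GeneratorConfig(),
) -> Tuple[PhotobleachSeries, PhotobleachSeries]:
    """DPBF photobleaching series pair with a known sample yield.

    Inverts the comparative singlet-oxygen relation: the sample bleach
    rate is k^S = k^R (phi^S/phi^R)(I_aT^S/I_aT^R), with both
    absorbed-light totals computed by the same routine the analysis
    uses, so the loop closes exactly at zero noise.
    """
    if not (0 < true_phi_sample <= 1) or not (0 < phi_reference <= 1):
        raise ValueError("quantum yields must be in (0, 1]")
    IaT_S = absorbed_light(abs_sample, excitation_profile).total_IaT
    IaT_R = absorbed_light(abs_reference, excitation_profile).total_IaT
    if IaT_S <= 0 or IaT_R <= 0:
        raise ValueError("zero absorbed light; check the spectra in 523-850 nm")
    k_sample = k_reference * (true_phi_sample / phi_reference) * (IaT_S / IaT_R)
    rng = cfg.rng()
    t = np.asarray(times_s, dtype=float)
    out = []
    for k, label in ((k_sample, "sample"), (k_reference, "reference")):
        a = A0 * np.exp(-k * t)
        a = _apply_mult_noise(a, cfg.dpbf_noise_frac, rng)
        out.append(PhotobleachSeries(times_s=t, absorbance_415=a, label=label))
    return out[0], out[1]


def gen_tcspc_decay(
    lifetimes_ns: Sequence[float],
    fractions_pct: Sequence[float],
    peak_counts: float = 1e4,
    n_bins: int = 4096,
    window_ns: float = 50.0,
    cfg: GeneratorConfig = GeneratorConfig(),
) -> DecayTrace:
    """TCSPC histogram from an amplitude-weighted multi-exponential.

    ``fractions_pct`` are relative amplitudes (summing to 100), the
    same convention the fitter reports.  Expected counts are scaled so
    the t=0 bin holds ``peak_counts``, a constant background is added,
    and Poisson noise is applied unless ``cfg.poisson_counts`` is off.
    """
    taus = np.asarray(lifetimes_ns, dtype=float)
    fracs = np.asarray(fractions_pct, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    if abs(fracs.sum() - 100.0) > 1e-6:
        raise ValueError("fractions must sum to 100")
    if window_ns < 3.0 * taus.max():
        import warnings

        warnings.warn(
            f"window {window_ns} ns shorter than 3x the longest lifetime "
            f"({taus.max()} ns); tail poorly constrained",
            stacklevel=2,
        )
    dt = window_ns / n_bins
    t = dt * np.arange(n_bins)  # first bin at t = 0 (the peak)
    amps = fracs / fracs.sum()
    model = (amps[None, :] * np.exp(-t[:, None] / taus[None, :])).sum(axis=1)
    expected = model * (peak_counts - cfg.tcspc_background_counts) / model[0]
    expected = expected + cfg.tcspc_background_counts
    if cfg.poisson_counts:
        counts = cfg.rng().poisson(expected).astype(float)
    else:
        counts = expected
    return DecayTrace(time_ns=t, counts=counts)


def gen_dose_response(
    true_ec50_nM: float,
    hill: float = 1.0,
    top_pct: float = 100.0,
    bottom_pct: float = 0.0,
    concentrations_nM: Optional[Sequence[float]] = None,
    n_experiments: int = 3,
    n_replicates: int = 3,
    noise_sd_pct: Optional[float] = None,
    cfg: GeneratorConfig = GeneratorConfig(),
    untreated_signal: float = 1.0,
    killed_signal: float = 0.05,
    cell_line: str = "HeLa",
) -> DoseResponseTable:
    """Neutral-red-style plate with a known 4PL truth.

    Default concentrations are 8 half-log points centred on the true
    EC50.  True viabilities get Gaussian noise in percentage points
    (``cfg.viability_noise_pct`` unless overridden), then are
    back-transformed through the control anchors into raw plate
    signals, so normalization recovers exactly the noisy percentages.
    """
    if concentrations_nM is None:
        log_c = math.log10(true_ec50_nM) + 0.5 * np.arange(-3.5, 4.0)
        concentrations_nM = 10.0 ** log_c
    conc = np.asarray(concentrations_nM, dtype=float)
    if not (conc.min() < true_ec50_nM < conc.max()):
        import warnings

        warnings.warn("concentrations do not bracket the true EC50", stacklevel=2)
    sd = cfg.viability_noise_pct if noise_sd_pct is None else noise_sd_pct
    v_true = bottom_pct + (top_pct - bottom_pct) / (1.0 + (conc / true_ec50_nM) ** hill)
    rng = cfg.rng()
    v = v_true[:, None, None] + sd * rng.standard_normal(
        (conc.size, n_experiments, n_replicates)
    )
    raw = killed_signal + v / 100.0 * (untreated_signal - killed_signal)
    raw = np.clip(raw, 0.0, None)
    return DoseResponseTable(
        concentrations_nM=conc,
        viability_raw=raw,
        untreated_signal=untreated_signal,
        killed_signal=killed_signal,
        cell_line=cell_line,
    )


def gen_partition_pair(
    true_logp: float,
    total_area: float = 1000.0,
    lambda_F_nm: float = 700.0,
    cfg: GeneratorConfig = GeneratorConfig(),
) -> PartitionExperiment:
    """Octanol/PBS emission pair whose area ratio encodes log P.

    Both layers share the same band shape (the aliquots are diluted
    into the same solvent before measurement), so the integrated-area
    ratio is exactly 10^log P independent of quadrature error.
    """
    ratio = 10.0 ** true_logp
    f_oct = total_area * ratio / (1.0 + ratio)
    f_pbs = total_area / (1.0 + ratio)
    rng = cfg.rng()
    lo, hi = cfg.wavelength_range_nm
    wl = _uniform_grid(lo, hi, cfg.grid_step_nm)
    shape = _gauss(wl, lambda_F_nm, cfg.qband_fwhm_nm)
    shape_area = np.trapezoid(shape, wl)

    def layer(area: float) -> Spectrum:
        vals = shape * (area / shape_area)
        vals = np.clip(_apply_mult_noise(vals, cfg.spectrum_noise_frac, rng), 0, None)
        return Spectrum(
            kind="emission",
            wavelengths_nm=wl,
            values=vals,
            solvent="DMF",
            excitation_nm=lambda_F_nm - 70.0,
        )

    return PartitionExperiment(octanol_emission=layer(f_oct), pbs_emission=layer(f_pbs))


# per-category schedules: (aggregate fractions, band shifts in nm,
# emission scale factors) across the four titration points
_BSA_SCHEDULES: Dict[str, Tuple[Sequence[float], Sequence[float], Sequence[float]]] = {
    "disaggregation_complete": ((0.8, 0.5, 0.2, 0.0), (0, 0, 0, 0), (1, 1, 1, 1)),
    "disaggregation_partial": ((0.85, 0.6, 0.4, 0.25), (0, 0, 0, 0), (1, 1, 1, 1)),
    "quenching": ((0, 0, 0, 0), (0, 0, 0, 0), (1.0, 0.7, 0.5, 0.3)),
    "bathochromic_shift": ((0, 0, 0, 0), (0, 3, 6, 8), (1.0, 0.97, 0.95, 0.95)),
    "no_change": ((0, 0, 0, 0), (0, 0, 0, 0), (1, 1, 1, 1)),
}


def gen_bsa_titration(
    mode: str,
    lambda_A_nm: float = 680.0,
    epsilon_M1cm1: float = 2.0e5,
    conc_M: float = 1e-6,
    bsa_concentrations_uM: Sequence[float] = (0.0, 17.5, 35.0, 100.0),
    cfg: GeneratorConfig = GeneratorConfig(),
) -> TitrationSeries:
    """Titration series realizing one BSA-response category.

    The schedules are chosen with a comfortable margin over the
    classifier thresholds: complete disaggregation sweeps the
    aggregate fraction 0.8 -> 0, quenching drops emission to 0.3x
    (threshold 0.75x), the bathochromic schedule shifts the band by
    8 nm (threshold 3 nm), and so on.
    """
    if mode not in CATEGORIES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {CATEGORIES}")
    af_sched, shift_sched, em_sched = _BSA_SCHEDULES[mode]
    n = len(bsa_concentrations_uM)
    if n != len(af_sched):
        # resample the 4-point schedules onto the requested grid
        x = np.linspace(0, 1, len(af_sched))
        xi = np.linspace(0, 1, n)
        af_sched = np.interp(xi, x, af_sched)
        shift_sched = np.interp(xi, x, shift_sched)
        em_sched = np.interp(xi, x, em_sched)
    abs_list, em_list = [], []
    for i in range(n):
        step_cfg = replace(cfg, seed=cfg.seed + 1000 * i + 1)
        a, e = gen_spectra_pair(
            lambda_A_nm + float(shift_sched[i]),
            stokes_nm=10.0,
            epsilon_M1cm1=epsilon_M1cm1,
            conc_M=conc_M,
            aggregate_fraction=float(af_sched[i]),
            cfg=step_cfg,
            emission_scale=float(em_sched[i]),
        )
        abs_list.append(a)
        em_list.append(e)
    mono_ref, _ = gen_spectra_pair(
        lambda_A_nm,
        stokes_nm=10.0,
        epsilon_M1cm1=epsilon_M1cm1,
        conc_M=conc_M,
        aggregate_fraction=0.0,
        cfg=replace(cfg, spectrum_noise_frac=0.0),
    )
    return TitrationSeries(
        bsa_concentrations_uM=tuple(float(c) for c in bsa_concentrations_uM),
        absorption_spectra=tuple(abs_list),
        emission_spectra=tuple(em_list),
        monomer_reference=mono_ref,
    )


def gen_panel(
    n_compounds_per_group: int,
    group_effects: Mapping[str, float],
    baseline_log10_ec50: float = 2.5,
    sigma_dex: float = 0.2,
    cell_line: str = "HeLa",
    cfg: GeneratorConfig = GeneratorConfig(),
) -> List[CompoundRecord]:
    """SAR panel with log-normal EC50s and tag-dependent shifts.

    ``group_effects`` maps tag queries (``"charge=cationic"``) to
    log10-EC50 shifts relative to the baseline; each group receives
    ``n_compounds_per_group`` compounds with that tag set and default
    values for the remaining vocabulary tags.
    """
    if not group_effects:
        raise ValueError("group_effects must name at least one group")
    if n_compounds_per_group < 1:
        raise ValueError("need at least one compound per group")
    rng = cfg.rng()
    defaults = {key: vals[0] for key, vals in TAG_VOCABULARY.items()}
    defaults["central_atom"] = "Zn"
    panel: List[CompoundRecord] = []
    for g, (query_str, shift) in enumerate(group_effects.items()):
        query = parse_tag_query(query_str)
        for i in range(n_compounds_per_group):
            log_ec50 = baseline_log10_ec50 + shift + sigma_dex * rng.standard_normal()
            ec50 = 10.0 ** log_ec50
            tags = dict(defaults)
            tags.update(query)
            panel.append(
                CompoundRecord(
                    compound_id=f"G{g + 1}-{i + 1}",
                    tags=tags,
                    endpoints={
                        cell_line: EC50Result(
                            ec50_nM=ec50,
                            hill=1.0,
                            top_pct=100.0,
                            bottom_pct=0.0,
                            sd_nM=0.1 * ec50,
                            n_experiments=3,
                        )
                    },
                )
            )
    return panel
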