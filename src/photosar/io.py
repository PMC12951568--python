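"""CSV dialects, run configuration, and the end-to-end pipeline.

All measurement files are plain UTF-8 CSV.  Spectra use two columns
``wavelength_nm,value`` with ``#``-prefixed metadata comment lines
(``# kind=absorption``, ``# solvent=DMF``, ``# concentration_M=1e-6``,
``# excitation_nm=610``, ``# pathlength_cm=1.0``).  Photobleach series
use ``time_s,absorbance_415``; TCSPC decays use ``time_ns,counts``;
viability plates use the long format
``concentration_nM,experiment,replicate,signal,control`` where control
rows are flagged ``untreated`` or ``killed``; SAR panels use one row
per compound x cell line.

``run_pipeline`` walks a YAML manifest of per-compound input files and
assembles a summary table (one row per compound: band maxima,
extinction coefficient, Stokes shift, lifetimes, quantum yields,
log P, EC50), flagging endpoints whose inputs are absent instead of
failing the whole run.  Column names carry explicit units.
"""

from __future__ import annotations

import dataclasses
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import partition as _partition
from .dose_response import DoseResponseTable, fit_ec50, normalize_viability
from .lifetime import DecayTrace, fit_decay
from .photophysics import (
    PhotobleachSeries,
    SolventInfo,
    absorbed_light,
    bleach_slope,
    fluorescence_qy,
    singlet_oxygen_qy,
)
from .spectra import Spectrum, integrate_emission, preprocess, q_band_features, stokes_shift

logger = logging.getLogger("photosar")

__all__ = [
    "RunConfig",
    "read_spectrum",
    "write_spectrum",
    "read_photobleach",
    "write_photobleach",
    "read_decay",
    "write_decay",
    "read_plate",
    "write_plate",
    "read_panel",
    "run_pipeline",
]

_SPECTRUM_META_FIELDS = {
    "kind": str,
    "solvent": str,
    "concentration_M": float,
    "pathlength_cm": float,
    "excitation_nm": float,
}


@dataclass
class RunConfig:
    """Pipeline constants, serializable to/from YAML."""

    integration_window_nm: Tuple[float, float] = (523.0, 850.0)
    grid_step_nm: float = 0.5
    phi_delta_reference: float = 0.56  # ZnPc in DMF
    phi_f_reference: float = 0.32  # ZnPc in THF
    refractive_index_sample: float = 1.4305  # DMF
    refractive_index_reference: float = 1.4050  # THF
    qband_window_nm: Tuple[float, float] = (550.0, 800.0)
    qband_prominence_frac: float = 0.2
    max_lifetime_components: int = 2
    ec50_per_experiment: bool = True
    seed: int = 0

    def to_yaml(self, path: Union[str, Path, None] = None) -> str:
        data = dataclasses.asdict(self)
        data["integration_window_nm"] = list(data["integration_window_nm"])
        data["qband_window_nm"] = list(data["qband_window_nm"])
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "RunConfig":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        for key in ("integration_window_nm", "qband_window_nm"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# readers / writers


def _read_csv_with_meta(path: Union[str, Path], required_cols: Sequence[str]):
    path = Path(path)
    meta: Dict[str, str] = {}
    rows: List[str] = []
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            rows.append(line)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    df = pd.read_csv(_io.StringIO("".join(rows)), float_precision="round_trip")
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in required_cols:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            first = df.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric value {df.loc[first, col]!r} in column "
                f"{col!r} (data row {first + 1})"
            )
        df[col] = pd.to_numeric(df[col])
    return df, meta


def read_spectrum(path: Union[str, Path]) -> Spectrum:
    """Read a two-column spectrum CSV with ``#`` metadata comments."""
    df, meta = _read_csv_with_meta(path, ["wavelength_nm", "value"])
    kwargs: Dict[str, object] = {"kind": meta.get("kind", "absorption")}
    for key, conv in _SPECTRUM_META_FIELDS.items():
        if key in meta and key != "kind":
            kwargs[key] = conv(meta[key])
    return Spectrum(
        wavelengths_nm=df["wavelength_nm"].to_numpy(),
        values=df["value"].to_numpy(),
        **kwargs,  # type: ignore[arg-type]
    )


def write_spectrum(spec: Spectrum, path: Union[str, Path]) -> None:
    lines = [f"# kind={spec.kind}"]
    if spec.solvent:
        lines.append(f"# solvent={spec.solvent}")
    if spec.concentration_M is not None:
        lines.append(f"# concentration_M={spec.concentration_M!r}")
    if spec.pathlength_cm != 1.0:
        lines.append(f"# pathlength_cm={spec.pathlength_cm!r}")
    if spec.excitation_nm is not None:
        lines.append(f"# excitation_nm={spec.excitation_nm!r}")
    lines.append("wavelength_nm,value")
    for wl, v in zip(spec.wavelengths_nm, spec.values):
        lines.append(f"{float(wl)!r},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_photobleach(path: Union[str, Path]) -> PhotobleachSeries:
    df, meta = _read_csv_with_meta(path, ["time_s", "absorbance_415"])
    return PhotobleachSeries(
        times_s=df["time_s"].to_numpy(),
        absorbance_415=df["absorbance_415"].to_numpy(),
        label=meta.get("label", "sample"),
    )


def write_photobleach(series: PhotobleachSeries, path: Union[str, Path]) -> None:
    lines = [f"# label={series.label}", "time_s,absorbance_415"]
    for t, a in zip(series.times_s, series.absorbance_415):
        lines.append(f"{float(t)!r},{float(a)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_decay(path: Union[str, Path]) -> DecayTrace:
    df, _ = _read_csv_with_meta(path, ["time_ns", "counts"])
    return DecayTrace(time_ns=df["time_ns"].to_numpy(), counts=df["counts"].to_numpy())


def write_decay(trace: DecayTrace, path: Union[str, Path]) -> None:
    lines = ["time_ns,counts"]
    for t, c in zip(trace.time_ns, trace.counts):
        lines.append(f"{float(t)!r},{float(c):g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_plate(table: DoseResponseTable, path: Union[str, Path]) -> None:
    rows = ["concentration_nM,experiment,replicate,signal,control"]
    rows.append(f"0,0,0,{table.untreated_signal!r},untreated")
    rows.append(f"0,0,0,{table.killed_signal!r},killed")
    n_c, n_e, n_r = table.viability_raw.shape
    for i in range(n_c):
        for e in range(n_e):
            for r in range(n_r):
                rows.append(
                    f"{float(table.concentrations_nM[i])!r},{e + 1},{r + 1},"
                    f"{float(table.viability_raw[i, e, r])!r},"
                )
    meta = [f"# cell_line={table.cell_line}"] if table.cell_line else []
    Path(path).write_text("\n".join(meta + rows) + "\n", encoding="utf-8")


def read_plate(path: Union[str, Path]) -> DoseResponseTable:
    df, meta = _read_csv_with_meta(path, ["concentration_nM", "signal"])
    ctrl = df.get("control")
    ctrl = ctrl.fillna("") if ctrl is not None else pd.Series([""] * len(df))
    untreated = df.loc[ctrl == "untreated", "signal"]
    killed = df.loc[ctrl == "killed", "signal"]
    if untreated.empty or killed.empty:
        raise ValueError(f"{path}: plate file must contain untreated and killed control rows")
    data = df[ctrl == ""].copy()
    conc = np.sort(data["concentration_nM"].unique())
    exps = np.sort(data["experiment"].unique())
    reps = np.sort(data["replicate"].unique())
    raw = np.full((conc.size, exps.size, reps.size), np.nan)
    ci = {c: i for i, c in enumerate(conc)}
    ei = {e: i for i, e in enumerate(exps)}
    ri = {r: i for i, r in enumerate(reps)}
    for _, row in data.iterrows():
        raw[ci[row["concentration_nM"]], ei[row["experiment"]], ri[row["replicate"]]] = row[
            "signal"
        ]
    if np.isnan(raw).any():
        raise ValueError(f"{path}: incomplete concentration x experiment x replicate grid")
    return DoseResponseTable(
        concentrations_nM=conc,
        viability_raw=raw,
        untreated_signal=float(untreated.mean()),
        killed_signal=float(killed.mean()),
        cell_line=str(meta.get("cell_line", "")),
    )


def read_panel(path: Union[str, Path]) -> pd.DataFrame:
    """Read a SAR panel CSV (one row per compound x cell line)."""
    df = pd.read_csv(path, comment="#")
    required = {"compound_id", "cell_line", "ec50_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing panel columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _load_if(entry: Optional[str], base: Path, reader):
    if entry is None:
        return None
    return reader(base / entry)


def run_pipeline(config: RunConfig, manifest_path: Union[str, Path]) -> pd.DataFrame:
    """Assemble a per-compound endpoint table from a YAML manifest.

    The manifest lists, per compound, whichever input files exist:
    ``absorption``/``baseline``/``emission`` spectra, a TCSPC
    ``decay``, a DPBF pair (``dpbf_sample``/``dpbf_reference``) with
    the reference absorption spectrum and filter ``excitation_profile``,
    ``partition`` replicate pairs, and a viability ``plate``.  Missing
    inputs flag the affected columns; they never abort the run.
    """
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text(encoding="utf-8"))
    base = manifest_path.parent
    rows = []
    for entry in manifest.get("compounds", []):
        cid = entry.get("id", "?")
        row: Dict[str, object] = {"compound_id": cid}
        flags: List[str] = []

        absorption = _load_if(entry.get("absorption"), base, read_spectrum)
        if absorption is not None and entry.get("baseline"):
            baseline = read_spectrum(base / entry["baseline"])
            absorption = preprocess(absorption, baseline, config.grid_step_nm)
        if absorption is not None:
            feats = q_band_features(
                absorption,
                window_nm=config.qband_window_nm,
                prominence_frac=config.qband_prominence_frac,
            )
            row["lambda_A_nm"] = feats.lambda_max_nm
            row["qband_split"] = feats.split
            row["epsilon_M1cm1"] = feats.epsilon_M1cm1
        else:
            flags.append("no_absorption")

        emission = _load_if(entry.get("emission"), base, read_spectrum)
        if emission is not None:
            peak = emission.wavelengths_nm[int(np.argmax(emission.values))]
            row["lambda_F_nm"] = float(peak)
            if "lambda_A_nm" in row:
                row["stokes_shift_nm"] = stokes_shift(row["lambda_A_nm"], float(peak))
        else:
            flags.append("no_emission")

        decay = _load_if(entry.get("decay"), base, read_decay)
        if decay is not None:
            fit = fit_decay(decay, max_components=config.max_lifetime_components,
                            seed=config.seed)
            for i, (tau, frac) in enumerate(zip(fit.lifetimes_ns, fit.fractions_pct), 1):
                row[f"tau_F{i}_ns"] = tau
                row[f"tau_F{i}_pct"] = frac
        else:
            flags.append("no_decay")

        if all(entry.get(k) for k in ("dpbf_sample", "dpbf_reference",
                                      "reference_absorption", "excitation_profile")) \
                and absorption is not None:
            s = read_photobleach(base / entry["dpbf_sample"])
            r = read_photobleach(base / entry["dpbf_reference"])
            ref_abs = read_spectrum(base / entry["reference_absorption"])
            profile = read_spectrum(base / entry["excitation_profile"])
            lo, hi = config.integration_window_nm
            IaT_S = absorbed_light(absorption, profile, lo, hi, config.grid_step_nm).total_IaT
            IaT_R = absorbed_light(ref_abs, profile, lo, hi, config.grid_step_nm).total_IaT
            qy = singlet_oxygen_qy(
                bleach_slope(s), bleach_slope(r), IaT_S, IaT_R, config.phi_delta_reference
            )
            row["phi_delta"] = qy.phi
        else:
            flags.append("no_dpbf")

        fl_ref = entry.get("fluorescence_reference")
        if emission is not None and fl_ref and entry.get("A_excitation"):
            qy = fluorescence_qy(
                F_S=integrate_emission(emission),
                F_R=float(fl_ref["F"]),
                A_S=float(entry["A_excitation"]),
                A_R=float(fl_ref["A"]),
                solvent_S=SolventInfo("sample", config.refractive_index_sample),
                solvent_R=SolventInfo("reference", config.refractive_index_reference),
                phi_R=config.phi_f_reference,
            )
            row["phi_F"] = qy.phi
        else:
            flags.append("no_phi_f_inputs")

        pairs = entry.get("partition") or []
        logps = []
        for pair in pairs:
            exp = _partition.PartitionExperiment(
                octanol_emission=read_spectrum(base / pair["octanol"]),
                pbs_emission=read_spectrum(base / pair["pbs"]),
            )
            logps.append(_partition.log_p(exp))
        if logps:
            mean, sd = _partition.aggregate_partition(logps)
            row["log_P"] = mean
            row["log_P_sd"] = sd
        else:
            flags.append("no_partition")

        if entry.get("plate"):
            table = read_plate(base / entry["plate"])
            result = fit_ec50(
                normalize_viability(table),
                table.concentrations_nM,
                per_experiment=config.ec50_per_experiment,
            )
            row["ec50_nM"] = result.ec50_nM
            row["ec50_sd_nM"] = result.sd_nM
            row["cell_line"] = table.cell_line
        else:
            flags.append("no_plate")

        row["flags"] = ";".join(flags)
        logger.info("compound %s: %s", cid, row)
        rows.append(row)
    return pd.DataFrame(rows)
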