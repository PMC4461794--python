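"""File formats, pipeline configuration and the end-to-end driver.

File dialects (UTF-8, comma-separated, header row, '.' decimal):

* spike trains — CSV ``unit_id,spike_time_s`` (seconds, 6 decimals);
* stimulus events — CSV ``stim_time_s,pulse_ms``;
* traces — flat little-endian float64 file plus a JSON sidecar
  ``{"fs_hz": ..., "units": ..., "t0_s": ...}``;
* intensity tables — CSV ``cell_id,egfp,neurogranin,appositions,true_pop``;
* size samples — CSV ``cell_id,size_um``.

Times are stored in seconds on disk; peri-stimulus quantities are reported
in ms by the analysis layer.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import imaging, invivo, morphometry, synth
from .core import SampledTrace, SpikeTrain, StimulusProtocol
from .intracellular import fit_ipsc


class FormatError(ValueError):
    """Malformed input file."""


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def write_spike_train(train: SpikeTrain, path) -> None:
    df = pd.DataFrame({"unit_id": train.unit_id,
                       "spike_time_s": np.round(train.times, 6)})
    df.to_csv(path, index=False, float_format="%.6f")


def read_spike_train(path, duration: float | None = None) -> SpikeTrain:
    df = pd.read_csv(path)
    if list(df.columns) != ["unit_id", "spike_time_s"]:
        raise FormatError(f"bad spike CSV header: {list(df.columns)}")
    t = df["spike_time_s"].to_numpy(dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise FormatError("spike times must be strictly increasing")
    dur = duration if duration is not None else (t[-1] + 1e-6 if t.size else 1.0)
    unit = str(df["unit_id"].iloc[0]) if len(df) else "unit0"
    return SpikeTrain(t, dur, unit)


def write_protocol(protocol: StimulusProtocol, path) -> None:
    pd.DataFrame({"stim_time_s": np.round(protocol.onsets_s, 6),
                  "pulse_ms": protocol.pulse_ms}).to_csv(
        path, index=False, float_format="%.6f")


def read_protocol(path) -> StimulusProtocol:
    df = pd.read_csv(path)
    if list(df.columns) != ["stim_time_s", "pulse_ms"]:
        raise FormatError(f"bad event CSV header: {list(df.columns)}")
    return StimulusProtocol(df["stim_time_s"].to_numpy(dtype=float),
                            df["pulse_ms"].to_numpy(dtype=float))


def write_trace(trace: SampledTrace, path) -> None:
    """Raw float64 little-endian samples at ``path`` + ``path + '.json'``."""
    path = Path(path)
    trace.data.astype("<f8").tofile(path)
    sidecar = {"fs_hz": trace.fs_hz, "units": trace.units, "t0_s": trace.t0_s,
               "n_samples": trace.n_samples}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_trace(path) -> SampledTrace:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    for key in ("fs_hz", "units", "t0_s"):
        if key not in meta:
            raise FormatError(f"trace sidecar missing '{key}'")
    data = np.fromfile(path, dtype="<f8")
    if "n_samples" in meta and meta["n_samples"] != data.size:
        warnings.warn(f"sidecar n_samples={meta['n_samples']} does not match "
                      f"file ({data.size} samples)", stacklevel=2)
    return SampledTrace(data, meta["fs_hz"], meta["units"], meta["t0_s"])


def write_intensity_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_intensity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_id", "egfp", "neurogranin", "appositions"}
    if not required.issubset(df.columns):
        raise FormatError(f"intensity CSV must contain columns {sorted(required)}")
    return df


def write_size_sample(values, path) -> None:
    pd.DataFrame({"cell_id": np.arange(len(values)),
                  "size_um": values}).to_csv(path, index=False)


def read_size_sample(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "size_um" not in df.columns:
        raise FormatError("size CSV must contain a 'size_um' column")
    return df["size_um"].to_numpy(dtype=float)


# --------------------------------------------------------------------------
# pipeline configuration & driver
# --------------------------------------------------------------------------

class InvivoScenario(BaseModel):
    model_config = ConfigDict(extra="forbid")
    baseline_rate: float = 10.9
    inhibited_rate: float = 1.58
    inhibition_onset: float = 14.5
    inhibition_duration: float = 23.4
    n_pulses: int = 400
    pulse_ms: float = 25.0
    bin_ms: float = 3.0


class MorphometryScenario(BaseModel):
    model_config = ConfigDict(extra="forbid")
    weights: list[float] = [0.5, 0.5]
    means: list[float] = [11.9, 16.2]
    sds: list[float] = [1.3, 2.0]
    n: int = 650
    bin_width: float = 1.0


class IPSCScenario(BaseModel):
    model_config = ConfigDict(extra="forbid")
    amplitude: float = 40.0
    rise_10_90: float = 2.5
    tau1: float = 8.2
    frac1: float = 0.523
    tau2: float = 34.8
    noise_sd: float = 2.0
    fs_khz: float = 50.0


class IntensityScenario(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cells: int = 317
    frac_low_egfp: float = 0.25


class PipelineConfig(BaseModel):
    """Full-run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    stages: list[str] = ["invivo_psth", "morphometry", "ipsc", "intensity"]
    out_dir: str | None = None
    invivo: InvivoScenario = InvivoScenario()
    morphometry: MorphometryScenario = MorphometryScenario()
    ipsc: IPSCScenario = IPSCScenario()
    intensity: IntensityScenario = IntensityScenario()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


# fixed per-stage seed offsets derived from the pipeline seed
_STAGE_SEED = {"invivo_psth": 11, "morphometry": 23, "ipsc": 37, "intensity": 53}


def _run_invivo(cfg: InvivoScenario, seed: int) -> dict:
    # 12 pulses per 10-s bout period at the default 4-Hz/3-s/7-s protocol
    total_s = (cfg.n_pulses // 12 + 1) * 10.0
    protocol = synth.make_stim_protocol(pulse_ms=cfg.pulse_ms, total_s=total_s)
    onsets = protocol.onsets_s[:cfg.n_pulses]
    protocol = StimulusProtocol(onsets, cfg.pulse_ms)
    duration = float(onsets[-1] + 1.0)
    profile = synth.RateProfile(cfg.baseline_rate, cfg.inhibition_onset,
                                cfg.inhibition_duration, cfg.inhibited_rate)
    train = synth.gen_poisson_train(profile, protocol, duration, seed)
    psth = invivo.build_psth(train, protocol, bin_ms=cfg.bin_ms)
    prof = invivo.detect_response(psth)
    return {"responsive": prof.responsive, "onset_latency_ms": prof.onset_latency,
            "peak_latency_ms": prof.peak_latency, "duration_ms": prof.duration,
            "baseline_rate_hz": prof.baseline_rate,
            "inhibited_rate_hz": prof.inhibited_rate}


def _run_morphometry(cfg: MorphometryScenario, seed: int) -> dict:
    spec = synth.MixtureSpec(tuple(zip(cfg.weights, cfg.means, cfg.sds)))
    values = synth.sample_soma_sizes(spec, cfg.n, seed)
    k = morphometry.model_select(values, cfg.bin_width)
    fit = morphometry.fit_gaussian_histogram(values, k, cfg.bin_width)
    return {"k": k, "means_um": fit.means_.tolist(), "sds_um": fit.sds_.tolist(),
            "r_square": fit.r_square_, "mean_ci_um": fit.mean_ci_.tolist()}


def _run_ipsc(cfg: IPSCScenario, seed: int) -> dict:
    params = synth.IPSCParams(cfg.amplitude, cfg.rise_10_90, cfg.tau1, cfg.frac1,
                              cfg.tau2, cfg.noise_sd)
    fit = fit_ipsc(synth.synth_ipsc(params, cfg.fs_khz, seed))
    return {"amplitude_pa": fit.amplitude_, "rise_10_90_ms": fit.rise_10_90_,
            "tau1_ms": fit.tau1_, "frac1": fit.frac1_, "tau2_ms": fit.tau2_,
            "fit_r2": fit.fit_r2_}


def _run_intensity(cfg: IntensityScenario, seed: int) -> dict:
    spec = synth.IntensityPopSpec(n_cells=cfg.n_cells, frac_low_egfp=cfg.frac_low_egfp)
    table = synth.gen_intensity_table(spec, seed)
    clusters = imaging.cluster_cells(table, seed)
    contacts = imaging.contact_summary(table, clusters.labels)
    return {"fractions": clusters.fractions,
            "centers": clusters.centers.tolist(),
            "contacted": contacts.contacted,
            "mean_appositions": contacts.mean_appositions,
            "apposition_fraction": contacts.apposition_fraction}


_STAGES = {"invivo_psth": (_run_invivo, "invivo"),
           "morphometry": (_run_morphometry, "morphometry"),
           "ipsc": (_run_ipsc, "ipsc"),
           "intensity": (_run_intensity, "intensity")}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages and return one aggregated JSON-ready
    report with provenance (seed, config hash)."""
    resolved = config.model_dump()
    cfg_hash = hashlib.sha256(
        json.dumps(resolved, sort_keys=True).encode()).hexdigest()[:16]
    report: dict = {"provenance": {"seed": config.seed, "config": resolved,
                                   "config_sha256": cfg_hash}}
    for stage in config.stages:
        if stage not in _STAGES:
            raise StageError(stage, ValueError("unknown stage"))
        fn, attr = _STAGES[stage]
        try:
            report[stage] = fn(getattr(config, attr), config.seed + _STAGE_SEED[stage])
        except Exception as exc:  # noqa: BLE001 - typed re-raise naming the stage
            raise StageError(stage, exc) from exc
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
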