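"""Trace file formats, result tables and the batch pipeline runner.

Traces travel as a two-column CSV (``time_s,current_pA``) with a JSON sidecar
at ``<path>.json`` holding sampling rate, holding potential, cell/construct
labels and the application protocol.  Result tables are TSV with units in
the column names; every pipeline run writes a JSON manifest recording the
package version, seeds, config hash and per-stage status so identical
configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .model_core import ApplicationProtocol, RateSet
from .traces import CurrentTrace

__all__ = ["read_trace", "write_trace", "read_atf", "run_pipeline", "PipelineResult"]

_HEADER = ("time_s", "current_pA")
_FLOAT_FMT = "%.10g"


def write_trace(trace: CurrentTrace, path) -> Path:
    """Write a trace CSV plus its metadata sidecar (``<path>.json``)."""
    path = Path(path)
    df = pd.DataFrame({_HEADER[0]: trace.t, _HEADER[1]: trace.i})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "sampling_rate": trace.sampling_rate,
        "holding_potential_mV": trace.holding_potential,
        "cell_id": trace.cell_id,
        "construct": trace.construct,
        "protocol": trace.protocol.to_dict() if trace.protocol is not None else None,
        "ground_truth": trace.ground_truth,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_trace(path) -> CurrentTrace:
    """Read a trace CSV and its sidecar; validates header, uniform sampling
    and sampling-rate consistency.  A missing sidecar yields a protocol-less
    trace with a warning."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in _HEADER:
        if col not in df.columns:
            raise ValidationError(f"trace file {path.name} lacks required column {col!r}")
    t = df[_HEADER[0]].to_numpy(float)
    i = df[_HEADER[1]].to_numpy(float)
    sidecar = Path(str(path) + ".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        warnings.warn(f"no sidecar metadata for {path.name}; trace has no protocol")
    if len(t) < 2:
        raise ValidationError("trace must have at least 2 rows")
    sampling_rate = meta.get("sampling_rate") or 1.0 / (t[1] - t[0])
    protocol = meta.get("protocol")
    return CurrentTrace(
        t=t, i=i, sampling_rate=float(sampling_rate),
        protocol=ApplicationProtocol.from_dict(protocol) if protocol else None,
        holding_potential=meta.get("holding_potential_mV"),
        cell_id=meta.get("cell_id"), construct=meta.get("construct"),
        ground_truth=meta.get("ground_truth"))


def read_atf(path) -> CurrentTrace:
    """Minimal Axon Text Format reader: first column time (s), second current
    (pA); header and comment records are skipped."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].upper().startswith("ATF"):
        raise ValidationError(f"{path.name} is not an ATF file")
    n_header = int(lines[1].split()[0])
    # line 2 .. 2+n_header are optional records; the next line holds column titles
    data_start = 2 + n_header + 1
    rows = [ln.replace(",", "\t").split() for ln in lines[data_start:] if ln.strip()]
    arr = np.array(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValidationError("ATF table needs at least two columns")
    t, i = arr[:, 0], arr[:, 1]
    return CurrentTrace(t=t, i=i, sampling_rate=1.0 / (t[1] - t[0]))


# ---------------------------------------------------------------------------
# batch pipeline


@dataclass
class PipelineResult:
    tables: dict = field(default_factory=dict)     # stage -> DataFrame
    manifest: dict = field(default_factory=dict)
    failed: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failed


def _stage_desens(cfg, out):
    from .desensitization import analyze_desensitization
    rows = []
    for p in cfg.get("traces", []):
        trace = read_trace(p)
        try:
            r = analyze_desensitization(trace)
            rows.append({"cell_id": trace.cell_id or Path(p).stem,
                         "I_P_pA": r.i_p, "I_SS_pA": r.i_ss, "D": r.d,
                         "tau_d_s": r.tau_d, "k_d_per_s": r.k_d,
                         "k_r_per_s": r.k_r, "fit_rmse_pA": r.fit_rmse,
                         "error": ""})
        except Exception as exc:
            rows.append({"cell_id": trace.cell_id or Path(p).stem, "error": str(exc)})
    return pd.DataFrame(rows)


def _stage_po(cfg, out):
    from .po_mk801 import two_step_pipeline
    rows = []
    for p in cfg.get("traces", []):
        trace = read_trace(p)
        desens, po = two_step_pipeline(
            trace, ku_free=cfg.get("ku_free", False),
            k_c=cfg.get("kc", 200.0), k_b=cfg.get("kb", 25.0),
            scale_mode=cfg.get("scale_mode", "free"))
        rows.append({"cell_id": trace.cell_id or Path(p).stem,
                     "D": desens.d, "tau_d_s": desens.tau_d,
                     "k_d_per_s": desens.k_d, "k_r_per_s": desens.k_r,
                     "k_o_per_s": po.k_o, "P_o_percent": po.p_o,
                     "k_u_per_s": po.k_u, "scale_pA": po.scale,
                     "converged": po.converged})
    return pd.DataFrame(rows)


def _stage_hill(cfg, out):
    from .dose_response import fit_hill
    rows = []
    for p in cfg.get("tables", []):
        df = pd.read_csv(p)
        fit = fit_hill(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                       mode=cfg.get("mode", "agonist"))
        rows.append({"table": Path(p).stem, "EC50_uM": fit.ec50, "h": fit.h,
                     "I_max": fit.i_max, "logEC50": fit.log_ec50,
                     "se_EC50_uM": fit.se_ec50, "se_h": fit.se_h,
                     "rmse": fit.rmse})
    return pd.DataFrame(rows)


def _stage_woodhull(cfg, out):
    from .mg_block import fit_woodhull
    iv0 = pd.read_csv(cfg["iv_no_mg"])
    iv1 = pd.read_csv(cfg["iv_mg"])
    fit = fit_woodhull(iv0, iv1, mg=cfg["mg_mM"], T=cfg.get("T_K", 298.15))
    return pd.DataFrame([{"V_rev_mV": fit.v_rev, "Kd0_mM": fit.a,
                          "delta": fit.delta, "b_per_V": fit.b,
                          "unreliable": fit.unreliable}])


def _stage_synaptic(cfg, out):
    from .synaptic_deactivation import summarize_synaptic
    rows = []
    for pair in cfg.get("pairs", []):
        ctrl = read_trace(pair["control"])
        ster = read_trace(pair["steroid"])
        s = summarize_synaptic(ctrl, ster, n_components=cfg.get("n_components", "auto"))
        rows.append({"cell_id": ctrl.cell_id or Path(pair["control"]).stem,
                     "potentiation_percent": s.potentiation,
                     "tau_control_s": s.tau_control, "tau_steroid_s": s.tau_steroid,
                     "deceleration": s.deceleration,
                     "charge_transfer": s.charge_transfer})
    return pd.DataFrame(rows)


def _stage_idealize(cfg, out):
    from .single_channel import HalfAmplitudeIdealizer, fit_amplitude_histogram, single_channel_po
    rows = []
    for p in cfg.get("traces", []):
        trace = read_trace(p)
        ideal = HalfAmplitudeIdealizer(
            baseline=cfg.get("baseline"), open_level=cfg.get("open_level"),
            dead_time=cfg.get("dead_time_us", 446.0) * 1e-6,
            fc=cfg.get("fc")).fit(trace)
        events = ideal.events_
        amp = fit_amplitude_histogram(ideal.trace_, events)
        rows.append({"cell_id": trace.cell_id or Path(p).stem,
                     "n_open": len(events.open_events),
                     "open_time_s": events.open_time,
                     "P_o_percent": single_channel_po(events),
                     "amp_mean_pA": amp.mean_amp, "amp_sd_pA": amp.sd})
        ev = pd.DataFrame([{"t_start_s": e.t_start, "duration_s": e.duration,
                            "state": e.state, "mean_amp_pA": e.mean_amp}
                           for e in events])
        if out is not None:
            ev.to_csv(out / f"events_{Path(p).stem}.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)
    return pd.DataFrame(rows)


def _stage_simulate(cfg, out):
    from .synthetic_data import (NoiseSpec, generate_whole_cell_trace)
    rows = []
    for spec in cfg.get("traces", []):
        rates = RateSet.from_dict(spec["rates"])
        protocol = ApplicationProtocol.from_dict(spec["protocol"])
        trace = generate_whole_cell_trace(
            rates, protocol, scale=spec.get("scale", 100.0),
            sampling_rate=spec.get("sampling_rate", 10000.0),
            noise=NoiseSpec(sd=spec.get("noise_sd", 0.0), seed=spec.get("seed", 0)))
        trace.cell_id = spec.get("cell_id")
        dest = Path(spec["path"]) if out is None else out / spec["path"]
        write_trace(trace, dest)
        rows.append({"cell_id": spec.get("cell_id", ""), "path": str(dest),
                     "n_samples": len(trace.t)})
    return pd.DataFrame(rows)


_STAGES = {
    "simulate": _stage_simulate,
    "desens": _stage_desens,
    "po": _stage_po,
    "hill": _stage_hill,
    "woodhull": _stage_woodhull,
    "synaptic": _stage_synaptic,
    "idealize": _stage_idealize,
}


def run_pipeline(config, out_dir=None) -> PipelineResult:
    """Run the configured stages fail-soft; one TSV per stage plus a manifest.

    ``config`` is a dict or a path to a JSON document of the form
    ``{"seed": 0, "stages": [{"stage": "desens", ...}, ...]}``.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()
    result = PipelineResult(manifest={
        "version": __version__, "config_sha256": cfg_hash,
        "seed": config.get("seed", 0), "stages": []})

    for stage_cfg in config.get("stages", []):
        name = stage_cfg.get("stage")
        entry = {"stage": name, "status": "ok"}
        try:
            if name not in _STAGES:
                raise ValidationError(f"unknown stage {name!r}")
            table = _STAGES[name](stage_cfg, out)
            result.tables[name] = table
            if out is not None:
                table.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                             float_format=_FLOAT_FMT)
        except Exception as exc:
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            result.failed.append(name)
        result.manifest["stages"].append(entry)

    if out is not None:
        (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1, sort_keys=True))
    return result
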