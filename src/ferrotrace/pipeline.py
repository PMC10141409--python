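"""Top-level study pipeline.

Composes the generator and the analysis stages into the five headline
experiments of the trapping study and writes a reproducible report bundle
(JSON summary, CSV tables, PNG figures, log):

1. step-contrast study  - paired apo/holo traces; percent excess of the
   holo dielectric-loading ratio DeltaT/T0 over apo (expected ~41%);
2. iron-loading study   - median sliding RMS just after trapping vs 22 min
   into loading (expected ~6.8 -> ~5.4 mV);
3. gating study         - on/off segmentation of a loading-phase trace and
   mean dwell times (expected in the 2-5 s range);
4. NRMS comparison      - permutation test on per-second NRMS populations
   of the two isoforms (expected p < 1e-4), plus isoform classification;
5. ferric control       - no gating and unchanged RMS (~14 / ~15 mV).

Every stage derives its RNG streams from a single master seed through
``numpy.random.SeedSequence([master, key])``, so a rerun with the same seed
is byte-identical (timestamps live only in the log).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, ValidationError

from . import gating as _gating
from . import metrics as _metrics
from . import stats as _stats
from . import synthetic as _syn
from .events import detect_trap_event
from .preprocess import gaussian_lowpass
from .trace import Trace

__all__ = ["PipelineConfig", "ConfigError", "load_config", "replicate_study",
           "run_pipeline", "contrast_study", "loading_study", "gating_study",
           "nrms_comparison_study", "control_study"]

log = logging.getLogger("ferrotrace")

# fixed per-stage stream keys (second word of the SeedSequence)
_KEY_CONTRAST = 1
_KEY_LOADING = 7
_KEY_GATING = 11
_KEY_CONTROL = 21
_KEY_NRMS = 100
_KEY_PERM = 0


class ConfigError(ValueError):
    """Invalid pipeline configuration (carries the offending field path)."""


class PipelineConfig(BaseModel):
    """Validated configuration of the full study pipeline.

    The defaults are the paper-replica conditions; the ``*_duration`` and
    count fields exist so smoke runs can be scaled down.
    """

    seed: int = 1
    fs: float = Field(default=10_000.0, gt=0)
    filter_cutoff_hz: float = Field(default=1000.0, gt=0)
    window_s: float = Field(default=0.1, gt=0)
    hop_s: float = Field(default=0.05, gt=0)
    # stage 1: step contrast
    n_contrast_pairs: int = Field(default=20, ge=1)
    contrast_duration_s: float = Field(default=60.0, gt=0)
    # stage 2: iron loading
    loading_duration_s: float = Field(default=1420.0, gt=0)
    loading_post_delay_s: float = Field(default=1320.0, gt=0)
    # stage 3: gating kinetics
    gating_duration_s: float = Field(default=130.0, gt=0)
    # stage 4: NRMS comparison
    n_nrms_segments: int = Field(default=50, ge=3)
    n_permutations: int = Field(default=100_000, ge=10)
    # stage 5: ferric control
    control_duration_s: float = Field(default=1320.0, gt=0)
    control_post_delay_s: float = Field(default=1200.0, gt=0)
    make_plots: bool = True

    model_config = {"extra": "forbid"}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML/JSON config file, apply overrides, validate."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return PipelineConfig(**data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"invalid config field '{loc}': {first['msg']}") from exc


def _ss(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master), *key])


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def contrast_study(config: PipelineConfig) -> dict:
    """Percent excess of the holo step ratio over apo, over paired seeds."""
    log.info("stage=contrast seed=%d pairs=%d", config.seed, config.n_contrast_pairs)
    apo, holo = _syn.apo_preset(), _syn.holo_preset()
    ratios_a, ratios_h = [], []
    for i in range(1, config.n_contrast_pairs + 1):
        pair = []
        for preset in (apo, holo):
            st = _syn.trapped_experiment(preset, _ss(config.seed, _KEY_CONTRAST, i),
                                         duration=config.contrast_duration_s,
                                         t_trap=5.0, fs=config.fs)
            ev = detect_trap_event(st.trace, config.filter_cutoff_hz)
            pair.append(ev.ratio)
        ratios_a.append(pair[0])
        ratios_h.append(pair[1])
    ratios_a, ratios_h = np.array(ratios_a), np.array(ratios_h)
    excess = 100.0 * (ratios_h / ratios_a - 1.0)
    return {
        "ratio_apo_mean": float(ratios_a.mean()),
        "ratio_holo_mean": float(ratios_h.mean()),
        "excess_pct_mean": float(excess.mean()),
        "excess_pct_sd": float(excess.std(ddof=1)) if len(excess) > 1 else 0.0,
        "n_pairs": int(config.n_contrast_pairs),
    }


def loading_study(config: PipelineConfig) -> dict:
    """Median sliding RMS early after trapping vs 22 min into loading."""
    log.info("stage=loading seed=%d duration=%.0fs", config.seed,
             config.loading_duration_s)
    st, kin = _syn.loading_experiment(_ss(config.seed, _KEY_LOADING),
                                      duration=config.loading_duration_s,
                                      fs=config.fs)
    filtered = gaussian_lowpass(st.trace, config.filter_cutoff_hz)
    ev = detect_trap_event(st.trace, config.filter_cutoff_hz)
    post_start = kin.loading_start + config.loading_post_delay_s
    trend = _gating.mineralization_trend(
        filtered, (ev.t_trap + 0.5, ev.t_trap + 20.5),
        (post_start, post_start + 20.0), config.window_s, config.hop_s)
    return {
        "t_trap_detected": float(ev.t_trap),
        "ratio": float(ev.ratio),
        "median_rms_pre_mv": trend.median_rms_pre,
        "median_rms_post_mv": trend.median_rms_post,
        "relative_change": trend.relative_change,
        "_trace": filtered, "_loading_start": kin.loading_start,
    }


def gating_study(config: PipelineConfig) -> dict:
    """Segment a loading-phase trace and extract dwell-time kinetics."""
    log.info("stage=gating seed=%d duration=%.0fs", config.seed,
             config.gating_duration_s)
    st, kin = _syn.gating_experiment(_ss(config.seed, _KEY_GATING),
                                     duration=config.gating_duration_s,
                                     fs=config.fs)
    filtered = gaussian_lowpass(st.trace, config.filter_cutoff_hz)
    trapped = filtered.crop(kin.loading_start, st.trace.duration)
    rms = _metrics.sliding_rms(trapped, config.window_s, config.hop_s)
    seg = _gating.segment_states(rms)
    dw = _gating.dwell_statistics(seg)
    i0 = int(kin.loading_start * st.trace.fs)
    pred = seg.labels_at(st.trace.times()[i0:])
    acc = float(np.mean((pred == "on") == (st.gating_state[i0:] == 1)))
    return {
        "mean_on_dwell_s": dw.mean_on,
        "mean_off_dwell_s": dw.mean_off,
        "n_cycles": dw.n_cycles,
        "n_on_dwells": len(dw.dwells_on),
        "n_segments": len(seg.segments),
        "label_accuracy": acc,
        "_rms": rms, "_segments": seg,
    }


def nrms_comparison_study(config: PipelineConfig) -> dict:
    """Permutation test on per-segment NRMS of the two isoforms."""
    log.info("stage=nrms seed=%d n=%d permutations=%d", config.seed,
             config.n_nrms_segments, config.n_permutations)
    groups = {}
    for name, preset in (("apo", _syn.apo_preset()), ("holo", _syn.holo_preset())):
        vals = []
        for i in range(config.n_nrms_segments):
            key = _KEY_NRMS + i + (0 if name == "apo" else config.n_nrms_segments)
            st = _syn.trapped_experiment(preset, _ss(config.seed, key),
                                         duration=4.0, t_trap=1.0, fs=config.fs)
            filtered = gaussian_lowpass(st.trace, config.filter_cutoff_hz)
            vals.append(_metrics.nrms(filtered.crop(2.0, 3.0)))
        groups[name] = np.array(vals)
    perm_seed = int(_ss(config.seed, _KEY_PERM).generate_state(1)[0] % (2 ** 31))
    res = _stats.permutation_test(groups["apo"], groups["holo"],
                                  config.n_permutations, seed=perm_seed)
    calls = {
        name: _stats.classify_isoform(
            nrms=float(np.median(groups[name])),
            ratio=_syn.DELTA_APO if name == "apo" else _syn.DELTA_HOLO).label
        for name in groups
    }
    return {
        "nrms_apo_mean": float(groups["apo"].mean()),
        "nrms_holo_mean": float(groups["holo"].mean()),
        "statistic": res.statistic,
        "p_value": res.p_value,
        "n_permutations": res.n_permutations,
        "classified": calls,
        "_groups": groups,
    }


def control_study(config: PipelineConfig) -> dict:
    """Ferric-solution control: no gating, unchanged fluctuation level."""
    log.info("stage=control seed=%d duration=%.0fs", config.seed,
             config.control_duration_s)
    st, expo = _syn.control_experiment(_ss(config.seed, _KEY_CONTROL),
                                       duration=config.control_duration_s,
                                       fs=config.fs)
    filtered = gaussian_lowpass(st.trace, config.filter_cutoff_hz)
    trapped = filtered.crop(expo + 0.5, st.trace.duration)
    rms = _metrics.sliding_rms(trapped, config.window_s, config.hop_s)
    seg = _gating.segment_states(rms)
    post_start = expo + config.control_post_delay_s
    trend = _gating.mineralization_trend(
        filtered.crop(10.5, st.trace.duration), (expo - 20.0, expo),
        (post_start, post_start + 20.0), config.window_s, config.hop_s)
    return {
        "median_rms_pre_mv": trend.median_rms_pre,
        "median_rms_post_mv": trend.median_rms_post,
        "single_state": bool(seg.single_state),
        "n_states": seg.n_states,
    }


# ---------------------------------------------------------------------------
# composition and report bundle
# ---------------------------------------------------------------------------

def replicate_study(config: PipelineConfig | None = None, **overrides) -> dict:
    """Run all five experiments; returns the nested results dict."""
    if config is None:
        config = load_config(None, **overrides)
    results = {
        "config": config.model_dump(),
        "contrast": contrast_study(config),
        "loading": loading_study(config),
        "gating": gating_study(config),
        "nrms": nrms_comparison_study(config),
        "control": control_study(config),
    }
    return results


def _strip_private(obj):
    if isinstance(obj, dict):
        return {k: _strip_private(v) for k, v in obj.items()
                if not str(k).startswith("_")}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the study and write the report bundle to ``out_dir``.

    Writes ``summary.json`` (deterministic given the seed), CSV tables of
    the loading RMS series, gating segments and NRMS populations, and PNG
    figures unless ``make_plots`` is off.  Returns the results dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("stage=start seed=%d", config.seed)
        results = replicate_study(config)
        _write_tables(results, out, config)
        if config.make_plots:
            _write_plots(results, out)
        summary = _strip_private(results)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        log.info("stage=done")
        return results
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_tables(results: dict, out: Path, config: PipelineConfig) -> None:
    import pandas as pd
    trace: Trace = results["loading"]["_trace"]
    rms = _metrics.sliding_rms(trace.crop(0.5, trace.duration),
                               config.window_s, config.hop_s)
    pd.DataFrame({"time_s": rms.times, "rms_mv": rms.rms}).to_csv(
        out / "loading_rms.csv", index=False, float_format="%.9g")
    seg = results["gating"]["_segments"]
    pd.DataFrame([{"t_start_s": s.t_start, "t_end_s": s.t_end,
                   "label": s.label} for s in seg.segments]).to_csv(
        out / "gating_segments.csv", index=False, float_format="%.9g")
    groups = results["nrms"]["_groups"]
    pd.DataFrame({"apo": groups["apo"], "holo": groups["holo"]}).to_csv(
        out / "nrms_populations.csv", index=False, float_format="%.9g")


def _write_plots(results: dict, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    trace: Trace = results["loading"]["_trace"]
    step = max(1, int(trace.fs / 50))
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(trace.times()[::step], trace.values[::step], lw=0.3, color="0.3")
    ax.axvline(results["loading"]["t_trap_detected"], color="tab:red",
               ls="--", label="detected trap step")
    ax.set(xlabel="time (s)", ylabel="transmission (V)",
           title="iron-loading recording")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "loading_trace.png", dpi=120)
    plt.close(fig)

    rms = results["gating"]["_rms"]
    seg = results["gating"]["_segments"]
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(rms.times, rms.rms, lw=0.6, color="0.2")
    for s in seg.segments:
        if s.label == "off":
            ax.axvspan(s.t_start, s.t_end, color="tab:purple", alpha=0.25)
    ax.set(xlabel="time (s)", ylabel="sliding RMS (mV)",
           title="on-off gating (off segments shaded)")
    fig.tight_layout()
    fig.savefig(out / "gating_rms.png", dpi=120)
    plt.close(fig)

    groups = results["nrms"]["_groups"]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.violinplot([groups["apo"], groups["holo"]], showmedians=True)
    ax.set_xticks([1, 2], ["apo", "holo"])
    ax.set(ylabel="NRMS", title=f"p = {results['nrms']['p_value']:.2g}")
    fig.tight_layout()
    fig.savefig(out / "nrms_violin.png", dpi=120)
    plt.close(fig)
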