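"""Stage orchestration: chain the analysis stages with on-disk hand-off.

Each stage reads the previous stage's delimited outputs from the output
directory and appends its own files to a manifest (JSON with SHA-256
digests), so a run is fully described by its config + seed and two runs
with equal seeds produce byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import decomposition as dec
from . import network_stats as ns
from . import preprocess as pp
from . import spectral as sp
from . import synthetic as syn
from .params import LIMBS, PipelineParams
from .recording import (Recording, read_events, read_recording,
                        write_events, write_recording)

logger = logging.getLogger("stepnet")

STAGES = ("simulate", "preprocess", "decompose", "ersp", "connectivity",
          "netstats")

# stage -> files that must already exist in outdir before it can run
_REQUIRES = {
    "simulate": {},
    "preprocess": {"simulate": ["recording.tsv", "events.tsv"]},
    "decompose": {"preprocess": ["cleaned.tsv"]},
    "ersp": {"decompose": ["activations.tsv"], "simulate": ["events.tsv"]},
    "connectivity": {"decompose": ["activations.tsv"],
                     "simulate": ["events.tsv"]},
    "netstats": {"connectivity": ["dtf_values.tsv", "dtf_meta.json"]},
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_matrix(path: Path, arr: np.ndarray, header: str = "") -> None:
    np.savetxt(path, np.atleast_2d(arr), fmt="%.10g", delimiter="\t",
               header=header)


def _read_matrix(path: Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


class MissingStageError(RuntimeError):
    pass


def _check_deps(stage: str, outdir: Path) -> None:
    for dep, files in _REQUIRES.get(stage, {}).items():
        for f in files:
            if not (outdir / f).exists():
                raise MissingStageError(
                    f"stage {stage!r} requires output {f!r} of stage "
                    f"{dep!r}; run {dep!r} first")


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2 ** 31))


def run_pipeline(config, out=None, seed: Optional[int] = None) -> dict:
    """Run the configured stages; returns the manifest dict.

    ``config`` is a YAML path or a dict with keys ``stages``, ``seed``,
    ``params`` (PipelineParams overrides), ``synthetic``, ``decompose``,
    ``ersp``, ``connectivity`` (per-stage options).
    """
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text()) or {}
    else:
        cfg = dict(config)
    outdir = Path(out or cfg.get("out", "stepnet_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    params = PipelineParams.from_dict(cfg.get("params", {}))
    stages = list(cfg.get("stages", STAGES))
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")

    manifest = {"seed": seed, "stages": {}, "config": _jsonable(cfg)}
    for stage in STAGES:          # canonical order regardless of listing order
        if stage not in stages:
            continue
        _check_deps(stage, outdir)
        t0 = time.monotonic()
        fn = globals()[f"_stage_{stage}"]
        files = fn(cfg, params, outdir, _subseed(seed, STAGES.index(stage)))
        logger.info("stage %s finished in %.1f s", stage,
                    time.monotonic() - t0)
        manifest["stages"][stage] = {
            "files": {f: _sha256(outdir / f) for f in sorted(files)}}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg, params, outdir, seed):
    opts = cfg.get("synthetic", {})
    duration = float(opts.get("duration_s", 60.0))
    n_channels = int(opts.get("n_channels", 32))
    spec = syn.default_network_spec(
        coupling_depth=float(opts.get("coupling_depth", 0.006)),
        cadence_per_min=params.cadence_per_min)
    rng = np.random.default_rng(seed)
    events = syn.generate_events(
        spec.cadence_per_min, duration, LIMBS,
        float(opts.get("phase_jitter_sd", 0.01)),
        seed=int(rng.integers(2 ** 31)))
    src = syn.simulate_source_network(spec, events, params.fs_raw, duration,
                                      seed=int(rng.integers(2 ** 31)))
    mixing, pos = syn.default_mixing(n_channels, src.n_sources,
                                     seed=int(rng.integers(2 ** 31)))
    rec = syn.mix_to_scalp(src, mixing=mixing, channel_positions=pos,
                           sensor_noise_sd=float(opts.get("sensor_noise_sd", 2.0)),
                           seed=int(rng.integers(2 ** 31)))
    write_recording(rec, outdir / "recording.tsv")
    write_events(events, outdir / "events.tsv")
    sources_rec = Recording(data=src.sources, fs=src.fs,
                            channel_labels=list(spec.source_names))
    write_recording(sources_rec, outdir / "sources.tsv")
    _write_matrix(outdir / "mixing.tsv", mixing,
                  header="ground-truth mixing (channels x sources)")
    gains = np.array([src.gains[k] for k in sorted(src.gains)])
    names = "\t".join(f"{a}->{b}@{l}" for a, b, l in sorted(src.gains))
    _write_matrix(outdir / "gains.tsv", gains.T,
                  header="ground-truth coupling gains per sample: " + names)
    if opts.get("edf", False):
        write_recording(rec, outdir / "recording.edf", format="edf")
        return ["recording.tsv", "recording.edf", "events.tsv", "sources.tsv",
                "mixing.tsv", "gains.tsv"]
    return ["recording.tsv", "events.tsv", "sources.tsv", "mixing.tsv",
            "gains.tsv"]


def _stage_preprocess(cfg, params, outdir, seed):
    rec = read_recording(outdir / "recording.tsv")
    rec = pp.highpass_filter(rec, params.highpass_cutoff)
    rec, log = pp.reject_artifacts(
        rec, sd_ratio=params.reject_sd_ratio, min_corr=params.reject_min_corr,
        window_z=params.reject_window_z, window_len=params.reject_window_len)
    rec = pp.rereference_common_average(rec)
    write_recording(rec, outdir / "cleaned.tsv")
    log.to_frame().to_csv(outdir / "rejection_log.tsv", sep="\t", index=False)
    return ["cleaned.tsv", "rejection_log.tsv"]


def _stage_decompose(cfg, params, outdir, seed):
    opts = cfg.get("decompose", {})
    rec = read_recording(outdir / "cleaned.tsv")
    n_comp = int(opts.get("n_components", 7))
    ica = dec.infomax_ica(rec, n_components=min(n_comp, rec.n_channels),
                          seed=seed,
                          quality_threshold=params.ica_quality_threshold,
                          max_iter=int(opts.get("max_iter", 500)))
    act = Recording(data=ica.activations, fs=rec.fs,
                    channel_labels=[f"IC{i + 1}" for i in
                                    range(ica.n_components)])
    write_recording(act, outdir / "activations.tsv")
    _write_matrix(outdir / "unmixing.tsv", ica.unmixing)
    _write_matrix(outdir / "mixing_estimate.tsv", ica.mixing)
    qual = pd.DataFrame({
        "component": act.channel_labels,
        "quality": ica.quality,
        "excluded": ica.excluded,
    })
    qual.to_csv(outdir / "component_quality.tsv", sep="\t", index=False)

    # feature blocks: topography centroids stand in for source coordinates
    retained = ica.retained()
    comps = retained if retained.size >= 2 else np.arange(ica.n_components)
    topo = ica.mixing[:, comps].T
    if rec.channel_positions is not None:
        w = np.abs(topo)
        coords = (w @ rec.channel_positions) / w.sum(axis=1, keepdims=True)
    else:
        coords = np.zeros((comps.size, 2))
    spectra = []
    for i in comps:
        f, s = sp.grand_mean_spectrum(ica.activations[i], rec.fs,
                                      resolution=0.25)
        sel = (f >= 3) & (f <= 80)
        spectra.append(s[sel])
    spectra = np.array(spectra)
    k = min(int(opts.get("k", 7)), comps.size)
    clusters = dec.cluster_components(
        {"coords": coords, "topography": topo, "spectrum": spectra},
        subject_ids=[rec.subject_id] * comps.size, k=k,
        min_subjects=int(opts.get("min_subjects",
                                  params.min_subjects_per_cluster)),
        seed=seed)
    cl = pd.DataFrame({
        "component": [act.channel_labels[i] for i in comps],
        "cluster": clusters.assignments,
        "retained_cluster": clusters.retained[clusters.assignments],
    })
    cl.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    return ["activations.tsv", "unmixing.tsv", "mixing_estimate.tsv",
            "component_quality.tsv", "clusters.tsv"]


def _load_activations(outdir):
    act = read_recording(outdir / "activations.tsv")
    events = read_events(outdir / "events.tsv")
    return act, events


def _stage_ersp(cfg, params, outdir, seed):
    opts = cfg.get("ersp", {})
    act, events = _load_activations(outdir)
    n_boot = int(opts.get("n_boot", params.n_boot_ersp))
    files = []
    rng = np.random.default_rng(seed)
    for i in range(act.n_channels):
        trials = sp.make_warped_epochs(act.data[i], act.fs, events, params)
        ersp = sp.compute_ersp(trials, alpha=params.alpha, n_boot=n_boot,
                               seed=int(rng.integers(2 ** 31)))
        _write_matrix(outdir / f"ersp_IC{i + 1}.tsv", ersp.ersp,
                      header="dB vs within-epoch baseline; rows=freqs")
        _write_matrix(outdir / f"ersp_mask_IC{i + 1}.tsv",
                      ersp.mask.astype(int))
        files += [f"ersp_IC{i + 1}.tsv", f"ersp_mask_IC{i + 1}.tsv"]
    _write_matrix(outdir / "ersp_freqs.tsv", trials.freqs)
    files.append("ersp_freqs.tsv")
    return files


def _stage_connectivity(cfg, params, outdir, seed):
    opts = cfg.get("connectivity", {})
    act, events = _load_activations(outdir)
    ds = pp.downsample(act, params.fs_mvar)
    ds = pp.piecewise_detrend(ds, params.detrend_window, params.detrend_step)
    epochs = conn.epoch_for_connectivity(ds.data, ds.fs, events, params)
    win = int(round(params.mvar_window * ds.fs))
    starts = list(range(0, epochs.shape[2] - win + 1,
                        int(round(params.mvar_step * ds.fs))))
    sel_windows = [epochs[:, :, s:s + win] for s in starts[::4]]
    from .mvar import select_model_order

    selection = select_model_order(sel_windows, params.order_candidates,
                                   alpha=params.alpha, h=params.whiteness_lags)
    n_boot = int(opts.get("n_boot", params.n_boot_connectivity))
    tensor = conn.sliding_window_dtf(epochs, ds.fs, selection.order, params,
                                     n_boot=n_boot, alpha=params.alpha,
                                     seed=seed)
    selection.table.to_csv(outdir / "order_selection.tsv", sep="\t",
                           index=False)
    # flat value dump + metadata for exact reload
    flat = tensor.values.reshape(tensor.values.shape[0] ** 2 *
                                 tensor.freqs.size, -1)
    _write_matrix(outdir / "dtf_values.tsv", flat)
    if tensor.mask is not None:
        _write_matrix(outdir / "dtf_mask.tsv",
                      tensor.mask.reshape(flat.shape).astype(int))
    meta = {
        "order": int(selection.order),
        "order_search_passed": bool(selection.passed),
        "n_channels": int(tensor.n_channels),
        "freqs": [float(f) for f in tensor.freqs],
        "times": [float(t) for t in tensor.times],
        "fs": float(ds.fs),
        "epoch_samples": int(epochs.shape[2]),
        "n_trials": int(epochs.shape[0]),
        "labels": act.channel_labels,
        "step_rate": conn.window_step_rate(ds.fs, params),
        "epoch_duration_s": float(epochs.shape[2] / ds.fs),
    }
    (outdir / "dtf_meta.json").write_text(json.dumps(meta, indent=1,
                                                     sort_keys=True))
    files = ["order_selection.tsv", "dtf_values.tsv", "dtf_meta.json"]
    if opts.get("long_table", False):
        tensor.to_frame(act.channel_labels).to_csv(
            outdir / "dtf_long.tsv", sep="\t", index=False)
        files.append("dtf_long.tsv")
    if tensor.mask is not None:
        files.append("dtf_mask.tsv")
    return files


def _stage_netstats(cfg, params, outdir, seed):
    meta = json.loads((outdir / "dtf_meta.json").read_text())
    m = meta["n_channels"]
    freqs = np.array(meta["freqs"])
    times = np.array(meta["times"])
    flat = _read_matrix(outdir / "dtf_values.tsv")
    values = flat.reshape(m, m, freqs.size, times.size)
    tensor = conn.DTFTensor(values=values, freqs=freqs, times=times,
                            fs=meta["fs"], order=meta["order"])
    cond = "synthetic"
    maxima = ns.pair_condition_maxima({cond: tensor}, labels=meta["labels"])
    report = ns.suprathreshold_pairs(maxima)
    report.table.to_csv(outdir / "suprathreshold.tsv", sep="\t", index=False)
    spec = ns.fluctuation_spectrum(tensor, step_rate=meta["step_rate"],
                                   nfft=params.fluct_nfft,
                                   fmax=params.fluct_fmax)
    peaks = ns.detect_harmonic_peaks(spec, params.movement_freq,
                                     params.harmonic_multiples)
    pd.DataFrame({"freq_hz": spec.freqs, "power": spec.power}).to_csv(
        outdir / "fluctuation_spectrum.tsv", sep="\t", index=False)
    pd.DataFrame([vars(p) for p in peaks]).to_csv(
        outdir / "harmonic_peaks.tsv", sep="\t", index=False)
    return ["suprathreshold.tsv", "fluctuation_spectrum.tsv",
            "harmonic_peaks.tsv"]
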