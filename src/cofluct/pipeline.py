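"""End-to-end orchestration from a validated config.

Stages: simulate -> physio -> cpca -> xcorr -> irf -> mcca -> events ->
multiecho. Every artifact is written with a provenance record (stage,
config hash, seed). A single global seed is expanded into independent
per-stage streams so toggling one stage does not perturb another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import coupling, events as ev, globalcomp, io, mcca, multiecho, physio, synthetic

log = logging.getLogger("cofluct")

_STAGES = ("simulate", "physio", "cpca", "xcorr", "irf", "mcca", "events",
           "multiecho")


def _from_dict(cls, d: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config key(s) for {cls.__name__}: "
                         f"{sorted(unknown)}")
    return cls(**d)


@dataclass
class StageToggles:
    simulate: bool = True
    physio: bool = True
    cpca: bool = True
    xcorr: bool = True
    irf: bool = True
    mcca: bool = True
    events: bool = True
    multiecho: bool = True


@dataclass
class PipelineConfig:
    outdir: str = "cofluct_out"
    seed: int = 0
    log_level: str = "INFO"
    n_subjects: int = 1
    stages: StageToggles = field(default_factory=StageToggles)
    synthetic: dict = field(default_factory=dict)
    mcca_n_perm: int = 199
    event_window_s: float = 29.0
    n_bins: int = 30

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = _from_dict(StageToggles, d["stages"])
        cfg = _from_dict(cls, d)
        known = {f.name for f in fields(synthetic.SyntheticConfig)}
        unknown = set(cfg.synthetic) - known
        if unknown:
            raise ValueError(
                f"unknown config key(s) for synthetic: {sorted(unknown)}")
        synthetic.SyntheticConfig(**{**cfg.synthetic, "seed": cfg.seed})
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _provenance(cfg: PipelineConfig, stage: str) -> dict:
    return {"stage": stage, "config_hash": cfg.hash(), "seed": cfg.seed}


def run(cfg: PipelineConfig) -> dict:
    """Execute the toggled stages; returns the in-memory results bundle."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    results: dict = {}
    scfg_base = dict(cfg.synthetic)
    subjects = []
    try:
        for s in range(cfg.n_subjects):
            scfg = synthetic.SyntheticConfig(**{**scfg_base, "seed": cfg.seed + 1000 * s})
            subjects.append(_run_subject(cfg, scfg, out / f"sub-{s:02d}", results, s))
        if cfg.stages.mcca and cfg.n_subjects >= 1:
            _run_mcca(cfg, subjects, out, results)
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    io.write_json(out / "provenance.json", _provenance(cfg, "run"))
    return results


def _run_subject(cfg, scfg, subdir, results, sub_idx):
    subdir.mkdir(parents=True, exist_ok=True)
    sub_res: dict = {}
    results[f"sub-{sub_idx:02d}"] = sub_res

    bundle = truth = None
    if cfg.stages.simulate:
        log.info("stage simulate (subject %d)", sub_idx)
        bundle, truth = synthetic.generate_session(scfg, with_events=True)
        coords = io.lattice_for(scfg.n_voxels)
        io.write_fmri_nifti(subdir / "bold.nii.gz", bundle["fmri"], coords,
                            tr_s=scfg.tr_s)
        io.write_mask_nifti(subdir / "mask.nii.gz", coords)
        for e, te in enumerate(bundle["echo_times_ms"]):
            io.write_fmri_nifti(subdir / f"bold_echo-{e + 1}.nii.gz",
                                bundle["multiecho"][:, e, :], coords,
                                tr_s=scfg.tr_s)
        io.write_physio(subdir / "physio", {
            m: bundle["physio"][m]["samples"] for m in bundle["physio"]},
            fs_hz=scfg.physio_fs_hz)
        io.write_events_tsv(subdir / "events.tsv", bundle["event_onsets_s"])
        io.write_json(subdir / "groundtruth.json", truth.to_dict())
        sub_res["bundle"], sub_res["truth"] = bundle, truth
    else:
        raise ValueError("pipeline currently requires the simulate stage "
                         "(no external inputs configured)")

    feats = {}
    if cfg.stages.physio:
        log.info("stage physio (subject %d)", sub_idx)
        feats = extract_features(bundle["physio"], scfg.n_frames, scfg.tr_s)
        for name, f in feats.items():
            io.write_feature_tsv(subdir / f"feat_{name}.tsv", f)
        sub_res["features"] = feats

    comp = ccomp = None
    if cfg.stages.cpca:
        log.info("stage cpca (subject %d)", sub_idx)
        coords = io.lattice_for(scfg.n_voxels)
        vts = globalcomp.VoxelTimeSeries(
            data=bundle["fmri"], tr_s=scfg.tr_s, mask_coords=coords,
            tissue_label=bundle["tissue_labels"])
        pre = globalcomp.preprocess_bold(vts, smoothing_fwhm_mm=0.0)
        comp = globalcomp.fit_pca(pre)
        ccomp = globalcomp.fit_cpca(pre)
        movie = globalcomp.reconstruct_movie(ccomp, n_bins=cfg.n_bins)
        io.write_map_nifti(subdir / "pc1_weights.nii.gz", comp.weights, coords)
        io.write_map_nifti(subdir / "cpc1_phase.nii.gz",
                           ccomp.phase_delay_map, coords)
        io.write_curve_tsv(subdir / "pc1_scores.tsv",
                           np.arange(comp.scores.size) * scfg.tr_s,
                           comp.scores, value_name="score",
                           meta={"explained_variance_ratio":
                                 comp.explained_variance_ratio})
        io.write_fmri_nifti(subdir / "cpc1_movie.nii.gz", movie, coords,
                            tr_s=scfg.tr_s)
        sub_res["pc1"], sub_res["cpc1"] = comp, ccomp

    if cfg.stages.xcorr and comp is not None and feats:
        log.info("stage xcorr (subject %d)", sub_idx)
        gs = physio.FeatureSeries(values=comp.scores, tr_s=scfg.tr_s,
                                  name="pc1")
        curves = {}
        for name, f in feats.items():
            c = coupling.cross_correlate(gs, f)
            io.write_curve_tsv(subdir / f"xcorr_{name}.tsv", c.lags_s, c.r,
                               value_name="r", meta={"pair": f"pc1~{name}"})
            curves[name] = c
        sub_res["xcorr"] = curves

    if cfg.stages.irf and comp is not None and feats:
        log.info("stage irf (subject %d)", sub_idx)
        gs = physio.FeatureSeries(values=comp.scores, tr_s=scfg.tr_s,
                                  name="pc1")
        irfs = {}
        for name, f in feats.items():
            r = coupling.estimate_irf(gs, f)
            io.write_curve_tsv(subdir / f"irf_{name}.tsv", r.lags_s, r.h,
                               value_name="h",
                               meta={"noise_variance": r.noise_variance})
            irfs[name] = r
        sub_res["irf"] = irfs

    if cfg.stages.events and comp is not None and len(bundle["event_onsets_s"]):
        log.info("stage events (subject %d)", sub_idx)
        gs = physio.FeatureSeries(values=comp.scores, tr_s=scfg.tr_s,
                                  name="pc1")
        table = ev.EventTable(onsets_s=bundle["event_onsets_s"])
        table = ev.filter_trials(table, min_gap_s=30.0)
        avg = ev.event_average([(gs, table)], window_s=cfg.event_window_s)
        io.write_curve_tsv(subdir / "event_avg_pc1.tsv", avg.time_s, avg.mean,
                           value_name="mean",
                           meta={"n_trials": avg.n_trials})
        sub_res["event_avg"] = avg

    if cfg.stages.multiecho:
        log.info("stage multiecho (subject %d)", sub_idx)
        me = multiecho.MultiEchoSeries(data=bundle["multiecho"],
                                       echo_times_ms=bundle["echo_times_ms"],
                                       tr_s=scfg.tr_s)
        decay = multiecho.fit_decay(me)
        coords = io.lattice_for(scfg.n_voxels)
        io.write_fmri_nifti(subdir / "t2s.nii.gz",
                            np.nan_to_num(decay.t2s_ms), coords, tr_s=scfg.tr_s)
        io.write_fmri_nifti(subdir / "s0.nii.gz",
                            np.nan_to_num(decay.s0), coords, tr_s=scfg.tr_s)
        sub_res["decay"] = decay
    return sub_res


def extract_features(raw_signals: dict, n_frames: int, tr_s: float) -> dict:
    """Raw recordings -> standardized frame-grid feature series."""
    feats = {}
    fs = raw_signals["ppg"]["fs_hz"]
    n_samples = raw_signals["ppg"]["samples"].size
    ppg = physio.RawPhysioSignal(**raw_signals["ppg"])
    beats = physio.detect_ppg_peaks(ppg)
    hr = physio.heart_rate(beats, fs, n_samples)
    amp = physio.ppg_amplitude(beats, fs, n_samples)
    feats["heart_rate"] = physio.standardize_feature(
        hr, fs, n_frames, tr_s, name="heart_rate", units="bpm")
    feats["ppg_amplitude"] = physio.standardize_feature(
        amp, fs, n_frames, tr_s, name="ppg_amplitude")
    resp = physio.RawPhysioSignal(**raw_signals["respiration"])
    rv = physio.respiratory_volume(resp)
    feats["respiratory_volume"] = physio.standardize_feature(
        rv, fs, n_frames, tr_s, name="respiratory_volume")
    sc = physio.RawPhysioSignal(**raw_signals["skin_conductance"])
    tonic = physio.tonic_skin_conductance(sc)
    feats["skin_conductance"] = physio.standardize_feature(
        tonic, fs, n_frames, tr_s, name="skin_conductance",
        apply_bandpass=False)
    pupil = raw_signals.get("pupil")
    if pupil is not None:
        cleaned = physio.interpolate_blinks(pupil["samples"])
        feats["pupil"] = physio.standardize_feature(
            cleaned, fs, n_frames, tr_s, name="pupil")
    eeg = raw_signals.get("eeg_channel")
    if eeg is not None:
        alpha = physio.alpha_power(physio.RawPhysioSignal(**eeg))
        feats["eeg_alpha"] = physio.standardize_feature(
            alpha, fs, n_frames, tr_s, name="eeg_alpha")
    return feats


def _run_mcca(cfg, subjects, out, results):
    log.info("stage mcca")
    per_subject = []
    for sub in subjects:
        feats = sub.get("features")
        comp = sub.get("pc1")
        if not feats or comp is None:
            return
        tr = next(iter(feats.values())).tr_s
        sets = [mcca.build_lagged_set(physio.FeatureSeries(
            values=comp.scores, tr_s=tr, name="pc1"))]
        for name in sorted(feats):
            sets.append(mcca.build_lagged_set(feats[name]))
        per_subject.append(sets)
    if len(per_subject) >= 3:
        sol = mcca.permutation_test(per_subject, n_perm=cfg.mcca_n_perm,
                                    seed=cfg.seed + 99)
    else:
        order = [np.arange(len(per_subject))] * len(per_subject[0])
        sol = mcca.fit_mcca(mcca._concat_sets(per_subject, order))
    summary = {"set_names": sol.set_names,
               "pairwise_r": sol.pairwise_r,
               "mean_pairwise_r": sol.mean_pairwise_r}
    if sol.p_value is not None:
        summary["p_value"] = sol.p_value
        summary["n_perm"] = cfg.mcca_n_perm
    io.write_json(out / "mcca_summary.json", summary)
    results["mcca"] = sol
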