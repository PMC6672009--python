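"""End-to-end orchestration: simulate -> decode -> patterns -> statistics.

``run_full`` executes the complete analysis on a simulated cohort and writes
all artifacts (maps, cluster tables, patterns, report) to an output
directory.  Scale presets trade problem size for runtime:

* ``ci``   — 32 sensors, 12 subjects, 880 stimuli/condition, 1000 permutations
* ``desk`` — 102 sensors, 20 subjects, 2000 stimuli/condition, 2000 permutations
* ``full`` — 102 sensors, 20 subjects, 4000 stimuli/condition (the
  experimental trial counts), 10000 permutations

All randomness flows from one master seed; derived sub-seeds are recorded in
the report.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .sequences import CONDITIONS, BlockDesign, _spawn_seeds
from .simulate import SimulationParams, simulate_cohort
from .decoding import (
    decode_entropy,
    drop_post_omission,
    balance_n1n,
    fit_lda,
    sound_to_omission_maps,
    sound_to_sound_maps,
    window_average,
)
from .patterns import haufe_correct
from .stats import (
    EntropyRegression,
    bonferroni_timecourse,
    paired_diff_test,
    spearman_corr_map,
)

SCALE_PRESETS = {
    "ci": dict(n_sensors=32, n_subjects=12, n_stimuli=880, n_perm=1000),
    "desk": dict(n_sensors=102, n_subjects=20, n_stimuli=2000, n_perm=2000),
    "full": dict(n_sensors=102, n_subjects=20, n_stimuli=4000, n_perm=10000),
}

_KNOWN_KEYS = {
    "scale", "seed", "n_subjects", "n_sensors", "n_stimuli", "rate_hz",
    "omission_rate", "n_perm", "inter_class_corr", "anticipation_gain",
    "omission_gain", "entropy_signature_gain", "noise_sd",
    "amplitude_jitter_sd", "w1_ms", "w2_ms", "train_window_s",
    "test_window_s", "cf_alpha", "entropy_gain_sd", "out_dir",
}


@dataclass
class RunConfig:
    """Validated configuration of one full analysis run."""

    scale: str = "ci"
    seed: int = 0
    n_subjects: int | None = None
    n_sensors: int | None = None
    n_stimuli: int | None = None
    rate_hz: float = 3.0
    omission_rate: float = 0.10
    n_perm: int | None = None
    inter_class_corr: float = 0.5
    anticipation_gain: float = 0.6
    omission_gain: float = 0.6
    entropy_signature_gain: float = 0.15
    noise_sd: float = 1.0
    amplitude_jitter_sd: float = 0.1
    w1_ms: tuple[float, float] = (75.0, 125.0)
    w2_ms: tuple[float, float] = (125.0, 333.0)
    train_window_s: tuple[float, float] | None = (-0.2, 0.4)
    test_window_s: tuple[float, float] | None = (-0.5, 0.5)
    cf_alpha: float = 0.025
    entropy_gain_sd: float = 0.05
    out_dir: str = "tonepred_run"

    def __post_init__(self) -> None:
        if self.scale not in SCALE_PRESETS:
            raise ValueError(f"scale must be one of {sorted(SCALE_PRESETS)}")
        preset = SCALE_PRESETS[self.scale]
        for key in ("n_subjects", "n_sensors", "n_stimuli", "n_perm"):
            if getattr(self, key) is None:
                setattr(self, key, preset[key])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("w1_ms", "w2_ms", "train_window_s", "test_window_s"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("w1_ms", "w2_ms", "train_window_s", "test_window_s"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    def design(self) -> BlockDesign:
        return BlockDesign(n_stimuli=self.n_stimuli, rate_hz=self.rate_hz,
                           omission_rate=self.omission_rate)

    def sim_params(self) -> SimulationParams:
        return SimulationParams(
            anticipation_gain=self.anticipation_gain,
            omission_gain=self.omission_gain,
            entropy_signature_gain=self.entropy_signature_gain,
            noise_sd=self.noise_sd,
            amplitude_jitter_sd=self.amplitude_jitter_sd,
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    """Provenance plus the per-analysis summary of a full run."""

    config: dict
    config_hash: str
    seed: int
    version: str
    sub_seeds: dict
    summaries: dict = field(default_factory=dict)
    log: list = field(default_factory=list)
    runtime_s: float | None = None  # not serialized: reports stay bit-identical

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "config_hash": self.config_hash,
             "seed": self.seed, "version": self.version,
             "sub_seeds": self.sub_seeds, "summaries": self.summaries,
             "log": self.log},
            indent=2, sort_keys=True)


def _log(report: RunReport, msg: str, verbose: bool) -> None:
    report.log.append(msg)
    if verbose:
        print(msg, flush=True)


def run_full(config: RunConfig, verbose: bool = False) -> RunReport:
    """Run the complete simulate -> decode -> stats -> patterns analysis."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_seed, dec_seed, stat_seed = _spawn_seeds(config.seed, 3)
    report = RunReport(config.to_dict(), config.config_hash(), config.seed,
                       __version__,
                       {"simulate": sim_seed, "decode": dec_seed,
                        "stats": stat_seed})
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    t0 = time.time()
    _log(report, f"[simulate] cohort: {config.n_subjects} subjects, "
         f"{config.n_sensors} sensors, {config.n_stimuli} stimuli/condition",
         verbose)
    cohort = simulate_cohort(
        n_subjects=config.n_subjects, n_sensors=config.n_sensors,
        design=config.design(), params=config.sim_params(),
        inter_class_corr=config.inter_class_corr, seed=sim_seed,
        entropy_gain_sd=config.entropy_gain_sd)

    # --- carrier-frequency decoding, sound- and omission-locked -------------
    _log(report, "[decode] time-generalization maps per subject", verbose)
    sound_maps, omission_maps = [], []
    entropy_sound, entropy_omission = [], []
    pattern_rows = []
    w1, w2 = config.w1_ms, config.w2_ms
    for s, ep in enumerate(cohort.subjects):
        smaps = sound_to_sound_maps(ep, dec_seed + s,
                                    train_window_s=config.train_window_s,
                                    test_window_s=config.test_window_s)
        omaps = sound_to_omission_maps(ep, dec_seed + s,
                                       train_window_s=config.train_window_s,
                                       test_window_s=config.test_window_s)
        sound_maps.append(np.stack([smaps[c].accuracy for c in CONDITIONS]))
        omission_maps.append(np.stack([omaps[c].accuracy for c in CONDITIONS]))
        entropy_sound.append(decode_entropy(ep, "sound", dec_seed + s))
        entropy_omission.append(decode_entropy(ep, "omission", dec_seed + s))
        pattern_rows.append(_w1w2_patterns(ep, dec_seed + s, w1, w2))
    train_times = smaps["RD"].train_times
    test_times = smaps["RD"].test_times
    times = cohort.subjects[0].times
    sound_vals = np.stack(sound_maps)  # subj x cond x train x test
    omis_vals = np.stack(omission_maps)
    ent_sound = np.stack(entropy_sound)  # subj x time
    ent_omis = np.stack(entropy_omission)

    _save_group_maps(out, sound_vals, omis_vals, train_times, test_times)
    pd.DataFrame({"time_s": times,
                  **{f"subj{s}": ent_sound[s] for s in range(len(ent_sound))}}
                 ).to_csv(out / "entropy_decoding_sound.csv", index=False)

    # --- group statistics ----------------------------------------------------
    _log(report, "[stats] entropy regression + cluster permutation", verbose)
    reg_results = {}
    for name, vals in (("sound", sound_vals), ("omission", omis_vals)):
        res = EntropyRegression(vals, train_times=train_times,
                                test_times=test_times).fit(
            n_perm=config.n_perm, cf_alpha=config.cf_alpha, seed=stat_seed)
        res.to_frame().to_csv(out / f"clusters_{name}.csv", index=False)
        sig = res.clusters.cluster_pvalues < 0.05
        reg_results[name] = {
            "n_clusters": int(res.clusters.n_clusters),
            "n_significant": int(sig.sum()),
            "min_p": float(res.clusters.cluster_pvalues.min())
            if res.clusters.n_clusters else None,
        }
    report.summaries["entropy_regression"] = reg_results

    # W1/W2 window courses per condition (sound- and omission-locked)
    courses = {}
    for name, vals in (("sound", sound_vals), ("omission", omis_vals)):
        for wname, win in (("W1", w1), ("W2", w2)):
            tmask = (train_times * 1000 >= win[0]) & (train_times * 1000 <= win[1])
            course = vals[:, :, tmask, :].mean(axis=2)  # subj x cond x test
            courses[f"{name}_{wname}"] = course
            dfc = pd.DataFrame(course.mean(axis=0).T,
                               columns=list(CONDITIONS))
            dfc.insert(0, "test_s", test_times)
            dfc.to_csv(out / f"window_course_{name}_{wname}.csv", index=False)
    pre_mask = (test_times >= -0.25) & (test_times <= 0.0)
    pre = courses["sound_W2"][:, :, pre_mask].mean(axis=(0, 2))
    report.summaries["preonset_W2_sound_accuracy_by_condition"] = {
        c: float(v) for c, v in zip(CONDITIONS, pre)}

    # Bonferroni time courses for entropy decoding; sound vs omission contrast
    mask_sound = bonferroni_timecourse(ent_sound, chance=0.25,
                                       alternative="greater")
    mask_diff = paired_diff_test(ent_sound, ent_omis)
    report.summaries["entropy_decoding"] = {
        "sound_mean_accuracy": float(ent_sound.mean()),
        "omission_mean_accuracy": float(ent_omis.mean()),
        "sound_sig_fraction": float(mask_sound.mean()),
        "sound_vs_omission_sig_fraction": float(mask_diff.mean()),
    }

    # Spearman correlation of entropy decoding (0-330 ms) with the low-entropy
    # (OR) carrier-frequency map
    _log(report, "[stats] across-subject Spearman correlation", verbose)
    win = (times >= 0.0) & (times <= 0.33)
    x = ent_sound[:, win].mean(axis=1)
    if config.n_subjects >= 5:
        corr_summary = {}
        for name, vals in (("sound", sound_vals), ("omission", omis_vals)):
            for wname, wkey in (("W1", f"{name}_W1"), ("W2", f"{name}_W2")):
                Y = courses[wkey][:, CONDITIONS.index("OR"), :]  # subj x test
                rho, cres = spearman_corr_map(
                    x, Y, n_perm=min(config.n_perm, 1000),
                    cf_alpha=config.cf_alpha, seed=stat_seed + 1)
                corr_summary[f"{name}_{wname}"] = {
                    "n_clusters": int(cres.n_clusters),
                    "min_p": float(cres.cluster_pvalues.min())
                    if cres.n_clusters else None,
                }
        report.summaries["spearman_correlation"] = corr_summary
    else:
        report.summaries["spearman_correlation"] = "skipped (needs >= 5 subjects)"

    # recovery verdict
    rho_order = _spearman_of_condition_means(pre)
    verdict = {
        "anticipation_cluster_sound": reg_results["sound"]["n_significant"] > 0,
        "anticipation_cluster_omission": reg_results["omission"]["n_significant"] > 0,
        "preonset_monotone_rho": rho_order,
    }
    report.summaries["recovery_verdict"] = verdict
    report.runtime_s = round(time.time() - t0, 2)

    _log(report, f"[done] wrote {out}", verbose)
    pd.concat(pattern_rows, ignore_index=True).to_csv(
        out / "haufe_patterns_w1w2.csv", index=False)
    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(_render_report(report))
    if verbose:
        print(f"runtime: {report.runtime_s} s", flush=True)
    return report


def preonset_positive_cluster(clusters, test_times: np.ndarray,
                              alpha: float = 0.05) -> bool:
    """True if a significant positive cluster overlaps pre-onset test times."""
    pre_cols = np.flatnonzero(test_times < 0)
    for cid in range(1, clusters.n_clusters + 1):
        if (clusters.cluster_pvalues[cid - 1] < alpha
                and clusters.cluster_masses[cid - 1] > 0
                and np.any(clusters.cluster_labels[:, pre_cols] == cid)):
            return True
    return False


def anticipation_recovery_replicate(
    seed: int,
    n_subjects: int = 8,
    n_sensors: int = 24,
    n_stimuli: int = 440,
    params: SimulationParams | None = None,
    n_perm: int = 500,
    train_window_s: tuple[float, float] = (-0.1, 0.35),
    test_window_s: tuple[float, float] = (-0.35, 0.35),
    w2_ms: tuple[float, float] = (125.0, 333.0),
) -> dict:
    """One replicate of the anticipation parameter-recovery experiment.

    Simulates a cohort, computes RD-trained time-generalization maps for
    sounds and omissions of every condition, runs the entropy regression with
    cluster permutation on both, and summarises (a) whether a significant
    positive cluster overlaps pre-onset test times and (b) the Spearman rho
    of the condition-mean pre-onset W2-averaged accuracy against entropy rank.
    """
    params = params or SimulationParams()
    design = BlockDesign(n_stimuli=n_stimuli, omission_rate=0.10)
    sim_seed, dec_seed, stat_seed = _spawn_seeds(seed, 3)
    cohort = simulate_cohort(n_subjects=n_subjects, n_sensors=n_sensors,
                             design=design, params=params, seed=sim_seed,
                             entropy_gain_sd=0.0)
    sound_maps, omis_maps = [], []
    for s, ep in enumerate(cohort.subjects):
        sm = sound_to_sound_maps(ep, dec_seed + s,
                                 train_window_s=train_window_s,
                                 test_window_s=test_window_s)
        om = sound_to_omission_maps(ep, dec_seed + s,
                                    train_window_s=train_window_s,
                                    test_window_s=test_window_s)
        sound_maps.append(np.stack([sm[c].accuracy for c in CONDITIONS]))
        omis_maps.append(np.stack([om[c].accuracy for c in CONDITIONS]))
    train_times, test_times = sm["RD"].train_times, sm["RD"].test_times
    out = {}
    for name, vals in (("sound", np.stack(sound_maps)),
                       ("omission", np.stack(omis_maps))):
        res = EntropyRegression(np.asarray(vals), train_times=train_times,
                                test_times=test_times).fit(
            n_perm=n_perm, seed=stat_seed)
        out[f"{name}_preonset_cluster"] = preonset_positive_cluster(
            res.clusters, test_times)
    # pre-onset W2-averaged accuracy: subjects x cond x train x test
    svals = np.stack(sound_maps)
    tmask = (train_times * 1000 >= w2_ms[0]) & (train_times * 1000 <= w2_ms[1])
    pre_by_cond = svals[:, :, tmask][:, :, :, test_times < 0].mean(axis=(0, 2, 3))
    out["monotone_rho"] = _spearman_of_condition_means(pre_by_cond)
    return out


def _spearman_of_condition_means(pre_by_cond: np.ndarray) -> float:
    from scipy import stats as sstats
    rho, _ = sstats.spearmanr(np.arange(4), pre_by_cond)
    return float(rho)


def _w1w2_patterns(ep, seed: int, w1, w2) -> pd.DataFrame:
    """Haufe-corrected activation patterns of the RD-sound classifier,
    averaged over the W1 and W2 training windows."""
    clean = drop_post_omission(ep)
    rd = clean.where(condition="RD", event_type="sound")
    bal = balance_n1n(rd.labels["tone_class"].to_numpy(),
                      rd.labels["prev_tone_class"].to_numpy(), seed)
    rd = rd.select(bal)
    y = rd.labels["tone_class"].to_numpy()
    frames = []
    for wname, win in (("W1", w1), ("W2", w2)):
        tmask = np.flatnonzero((rd.times * 1000 >= win[0])
                               & (rd.times * 1000 <= win[1]))
        A = np.mean([haufe_correct(fit_lda(rd.data[:, :, ti], y)).A
                     for ti in tmask], axis=0)
        s, k = np.meshgrid(np.arange(A.shape[0]), np.arange(A.shape[1]),
                           indexing="ij")
        frames.append(pd.DataFrame({
            "window": wname, "sensor": s.ravel(), "class": k.ravel(),
            "value": A.ravel(),
            "subject": int(ep.labels["subject_id"].iloc[0])}))
    return pd.concat(frames, ignore_index=True)


def _save_group_maps(out: Path, sound_vals, omis_vals, train_times, test_times):
    np.save(out / "timegen_sound.npy", sound_vals)
    np.save(out / "timegen_omission.npy", omis_vals)
    rows = []
    for name, vals in (("sound", sound_vals), ("omission", omis_vals)):
        mean = vals.mean(axis=0)  # cond x train x test
        for ci, cond in enumerate(CONDITIONS):
            tr, te = np.meshgrid(train_times, test_times, indexing="ij")
            rows.append(pd.DataFrame({
                "event_type": name, "condition": cond,
                "train_ms": np.round(tr.ravel() * 1000, 3),
                "test_ms": np.round(te.ravel() * 1000, 3),
                "accuracy": mean[ci].ravel()}))
    pd.concat(rows, ignore_index=True).to_csv(out / "timegen_group_mean.csv",
                                              index=False)


def _render_report(report: RunReport) -> str:
    lines = [
        "tonepred full-analysis report",
        "=============================",
        f"version: {report.version}   config hash: {report.config_hash}   "
        f"seed: {report.seed}",
        f"sub-seeds: {report.sub_seeds}",
        "",
    ]
    for section, content in report.summaries.items():
        lines.append(f"[{section}]")
        lines.append(json.dumps(content, indent=2, sort_keys=True))
        lines.append("")
    lines.append("[log]")
    lines.extend(f"  {m}" for m in report.log)
    return "\n".join(lines) + "\n"
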