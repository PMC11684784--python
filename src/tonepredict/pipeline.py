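"""End-to-end orchestration: simulate -> decode -> score -> stats.

A single :class:`RunConfig` (YAML on disk) plus the code version determines
every output byte; the master seed is split into per-stage seeds with numpy's
SeedSequence and every derived seed is logged in the run report.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .decoding import DecoderConfig, cross_decode, cv_decode_random
from .scores import WindowSpec, beta_slopes, diff_score, window_score
from .sequences import CONDITIONS, get_design
from .simulate import (
    DEFAULT_ALPHA_FRACTION_CONTROL,
    DEFAULT_SNR,
    ResponseKernel,
    pta4,
    simulate_cohort,
)
from .stats import (
    cluster_perm_test,
    jzs_bf_two_sample,
    logistic_tinnitus_model,
    spearman,
    tost_equivalence,
    welch_t,
)


@dataclass
class RunConfig:
    design: str = "study2"
    n_per_group: int = 10
    n_trials_per_condition: int | None = None   # None = design preset value
    snr: float = DEFAULT_SNR
    alpha_pre_tinnitus: float = 0.0
    alpha_pre_control: float = DEFAULT_ALPHA_FRACTION_CONTROL
    n_channels: int = 102
    n_folds: int = 5
    shrinkage: str | float = "auto"
    score_mode: str = "auto"                    # beta for study1, diff for study2
    train_window_s: tuple = (0.470, 0.570)
    test_window_s: tuple = (-0.400, 0.0)
    cluster_tail: str = "one_sided_pos"
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    seed: int = 0
    out_dir: str = "results/run"
    save_epochs: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("train_window_s", "test_window_s"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of problems; entries are prefixed 'error:' or 'warning:'."""
    problems = []
    try:
        design = get_design(cfg.design)
    except ValueError as exc:
        return [f"error: {exc}"]
    if cfg.n_per_group < 1:
        problems.append("error: n_per_group must be >= 1")
    if cfg.snr <= 0:
        problems.append("error: snr must be positive")
    if cfg.n_folds < 2:
        problems.append("error: n_folds must be >= 2")
    if cfg.cluster_tail not in ("two_sided", "one_sided_pos", "one_sided_neg"):
        problems.append(f"error: unknown tail {cfg.cluster_tail!r}")
    if cfg.n_perm < 1:
        problems.append("error: n_perm must be >= 1")
    elif cfg.n_per_group >= 1 and math.comb(2 * cfg.n_per_group, cfg.n_per_group) < cfg.n_perm:
        problems.append(
            f"error: only {math.comb(2 * cfg.n_per_group, cfg.n_per_group)} distinct "
            f"group relabelings exist with n_per_group={cfg.n_per_group}; "
            f"reduce n_perm below that"
        )
    tmin, tmax = design.epoch_window_s
    lo, hi = cfg.train_window_s
    if hi > tmax or lo < tmin:
        problems.append(
            f"warning: training window {cfg.train_window_s} exceeds the "
            f"{cfg.design} epoch {design.epoch_window_s}; it will be clipped"
        )
    lo, hi = cfg.test_window_s
    if hi > tmax or lo < tmin:
        problems.append(
            f"warning: testing window {cfg.test_window_s} exceeds the "
            f"{cfg.design} epoch {design.epoch_window_s}; it will be clipped"
        )
    n_trials = cfg.n_trials_per_condition or design.n_trials_per_condition
    if n_trials < cfg.n_folds * design.K:
        problems.append("error: too few trials per condition for stratified folds")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _scaled_design(cfg: RunConfig):
    design = get_design(cfg.design)
    if cfg.n_trials_per_condition and cfg.n_trials_per_condition != design.n_trials_per_condition:
        scale = cfg.n_trials_per_condition / design.n_trials_per_condition
        layout = tuple(
            tuple((cond, max(1, int(round(n * scale)))) for cond, n in segs)
            for segs in design.block_layout
        )
        n_per = sum(n for segs in layout for cond, n in segs if cond == design.conditions[0])
        from dataclasses import replace

        design = replace(design, n_trials_per_condition=n_per, block_layout=layout)
    return design


def subject_prediction_score(epochs, decoder_cfg: DecoderConfig, windows: WindowSpec,
                             mode: str, conditions):
    """One subject's windowed prediction score: timecourse + scalar summaries."""
    _, tg_random, conf = cv_decode_random(epochs, decoder_cfg)
    if mode == "beta_slope":
        mats = [tg_random]
        for cond in conditions[1:]:
            mats.append(cross_decode(epochs, epochs.sound_trials(cond), decoder_cfg))
        score = beta_slopes(mats)
    else:
        tg_ordered = cross_decode(epochs, epochs.sound_trials("ordered"), decoder_cfg)
        score = diff_score(tg_ordered, tg_random)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ws = window_score(score, windows)
    return score, ws, tg_random, conf


def prestim_group_cluster_test(
    cfg: RunConfig, seed=None
):
    """Simulate a cohort under ``cfg`` and run the pre-stimulus group contrast.

    Returns (ClusterTestResult, per-group windowed time courses, test times).
    This is the in-memory core of :func:`run_all`'s replication analysis and is
    reused by calibration studies that need many replicate cohorts.
    """
    design = _scaled_design(cfg)
    kernel = ResponseKernel(sfreq=design.sfreq)
    group_params = {
        "tinnitus": {"alpha_pre": cfg.alpha_pre_tinnitus, "snr": cfg.snr},
        "control": {"alpha_pre": cfg.alpha_pre_control, "snr": cfg.snr},
    }
    ss = np.random.SeedSequence(cfg.seed if seed is None else seed)
    sim_seed, stat_seed = ss.spawn(2)
    cohort = simulate_cohort(design, cfg.n_per_group, group_params, seed=sim_seed,
                             kernel=kernel)
    windows = WindowSpec(train_window_s=cfg.train_window_s, test_window_s=cfg.test_window_s)
    decoder_cfg = DecoderConfig(
        shrinkage=cfg.shrinkage, n_folds=cfg.n_folds, train_window_s=cfg.train_window_s
    )
    mode = cfg.score_mode
    if mode == "auto":
        mode = "beta_slope" if cfg.design == "study1" else "ordered_minus_random"
    conditions = list(get_design(cfg.design).conditions)
    curves = {"tinnitus": [], "control": []}
    test_times = None
    for spec, epochs in cohort:
        _, ws, _, _ = subject_prediction_score(epochs, decoder_cfg, windows, mode, conditions)
        mask = (ws["test_times_s"] >= cfg.test_window_s[0] - 1e-9) & (
            ws["test_times_s"] <= cfg.test_window_s[1] + 1e-9
        )
        curves[spec.group].append(ws["timecourse"][mask])
        test_times = ws["test_times_s"][mask]
    result = cluster_perm_test(
        np.array(curves["tinnitus"]),
        np.array(curves["control"]),
        tail=cfg.cluster_tail,
        n_perm=cfg.n_perm,
        cluster_alpha=cfg.cluster_alpha,
        seed=stat_seed,
    )
    return result, curves, test_times


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and return the run report (also written to disk)."""
    problems = validate_config(cfg)
    errors = [p for p in problems if p.startswith("error:")]
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(cfg), "problems": problems, "stages": {}}
    ss = np.random.SeedSequence(cfg.seed)
    stage_seeds = {name: s for name, s in zip(("simulate", "decode", "stats"), ss.spawn(3))}
    report["stage_seeds"] = {k: list(v.entropy if isinstance(v.entropy, tuple) else [v.entropy]) + list(v.spawn_key)
                             for k, v in stage_seeds.items()}

    # --- simulate -----------------------------------------------------------
    t0 = time.perf_counter()
    design = _scaled_design(cfg)
    kernel = ResponseKernel(sfreq=design.sfreq)
    group_params = {
        "tinnitus": {"alpha_pre": cfg.alpha_pre_tinnitus, "snr": cfg.snr},
        "control": {"alpha_pre": cfg.alpha_pre_control, "snr": cfg.snr},
    }
    cohort = simulate_cohort(
        design, cfg.n_per_group, group_params, seed=stage_seeds["simulate"], kernel=kernel
    )
    if cfg.save_epochs:
        paths = [tio.save_epochs(ep, out / "epochs" / spec.subject_id) for spec, ep in cohort]
    else:
        paths = ["" for _ in cohort]
    tio.save_cohort_manifest([s for s, _ in cohort], paths, out / "cohort.json")
    report["stages"]["simulate"] = {
        "n_subjects": len(cohort),
        "n_trials_per_condition": design.n_trials_per_condition,
        "duration_s": round(time.perf_counter() - t0, 3),
    }

    # --- decode + score -----------------------------------------------------
    t0 = time.perf_counter()
    mode = cfg.score_mode
    if mode == "auto":
        mode = "beta_slope" if cfg.design == "study1" else "ordered_minus_random"
    windows = WindowSpec(train_window_s=cfg.train_window_s, test_window_s=cfg.test_window_s)
    decoder_cfg = DecoderConfig(
        shrinkage=cfg.shrinkage, n_folds=cfg.n_folds, train_window_s=cfg.train_window_s
    )
    conditions = list(get_design(cfg.design).conditions)
    per_subject = []
    for spec, epochs in cohort:
        score, ws, tg_random, _ = subject_prediction_score(
            epochs, decoder_cfg, windows, mode, conditions
        )
        per_subject.append(
            {
                "subject_id": spec.subject_id,
                "group": spec.group,
                "pta4": pta4(spec.audiogram),
                "distress": spec.distress,
                "windowed_timecourse": ws["timecourse"],
                "test_times_s": ws["test_times_s"],
                "window_mean": ws["window_mean"],
                "at_time_value": ws["at_time_value"],
                "random_acc_mean": float(tg_random.acc.mean()),
            }
        )
    import pandas as pd

    summary = pd.DataFrame(
        [
            {k: v for k, v in row.items() if k not in ("windowed_timecourse", "test_times_s")}
            for row in per_subject
        ]
    )
    summary.to_csv(out / "subject_scores.tsv", sep="\t", index=False)
    report["stages"]["decode_score"] = {
        "mode": mode,
        "duration_s": round(time.perf_counter() - t0, 3),
    }

    # --- stats --------------------------------------------------------------
    t0 = time.perf_counter()
    test_times = per_subject[0]["test_times_s"]
    te_mask = (test_times >= cfg.test_window_s[0] - 1e-9) & (
        test_times <= cfg.test_window_s[1] + 1e-9
    )
    curves = {
        g: np.array(
            [row["windowed_timecourse"][te_mask] for row in per_subject if row["group"] == g]
        )
        for g in ("tinnitus", "control")
    }
    means = {
        g: np.array([row["window_mean"] for row in per_subject if row["group"] == g])
        for g in ("tinnitus", "control")
    }
    cluster = cluster_perm_test(
        curves["tinnitus"],
        curves["control"],
        tail=cfg.cluster_tail,
        n_perm=cfg.n_perm,
        cluster_alpha=cfg.cluster_alpha,
        seed=stage_seeds["stats"],
    )
    pre_times = test_times[te_mask]
    cluster_entries = [
        {
            "t_sum": c.t_sum,
            "p_perm": c.p_perm,
            "extent_s": [float(pre_times[c.indices.min()]), float(pre_times[c.indices.max()])],
        }
        for c in cluster.clusters
    ]
    bf = jzs_bf_two_sample(means["tinnitus"], means["control"])
    # control analysis: general (random-condition) processing should not differ
    random_acc = {
        g: np.array([row["random_acc_mean"] for row in per_subject if row["group"] == g])
        for g in ("tinnitus", "control")
    }
    wt = welch_t(random_acc["tinnitus"], random_acc["control"])
    tost = tost_equivalence(random_acc["tinnitus"], random_acc["control"], bounds=0.5)
    logistic = logistic_tinnitus_model(
        summary["window_mean"].to_numpy(),
        summary["group"].to_numpy(),
        pta=summary["pta4"].to_numpy(),
    )
    tin = summary[summary["group"] == "tinnitus"]
    distress_corr = spearman(tin["window_mean"], tin["distress"]) if len(tin) >= 4 else None

    report["stages"]["stats"] = {
        "clusters": cluster_entries,
        "bf10_group_difference": bf.bf10,
        "welch": wt,
        "tost": tost,
        "logistic": {
            "coefficients": logistic.coefficients,
            "odds_ratio_per_sd": logistic.odds_ratio_per_sd,
            "reversed_model": logistic.reversed_model,
        },
        "distress_spearman": distress_corr,
        "duration_s": round(time.perf_counter() - t0, 3),
    }

    # --- manifest -----------------------------------------------------------
    artifacts = {}
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "run_report.json":
            artifacts[str(f.relative_to(out))] = _sha256(f)
    report["artifacts"] = artifacts
    (out / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
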