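"""End-to-end orchestration: simulation -> GLM -> time courses -> ROI -> MVPA -> gaze.

A :class:`RunConfig` fully determines a study run: every random draw flows
from the config seed through named substreams (participant x stage), so a
rerun with the same config reproduces the report bit for bit.  Stages that
fail are recorded in the report and downstream stages with satisfied inputs
still run.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import gaze as gaze_mod
from . import glm as glm_mod
from . import mvpa as mvpa_mod
from . import roi as roi_mod
from . import timecourse as tc_mod
from .protocol import TrialSequence, localizer_design, main_experiment_sequence
from .synth import RoiTimeSeries, SimParams, simulate_bold, simulate_gaze

__all__ = ["RunConfig", "run_study", "rng_for", "UNIVARIATE_ROIS", "MVPA_ROIS"]

log = logging.getLogger("fillin")

UNIVARIATE_ROIS = ("lV1", "rV1", "lV2", "rV2", "lV3", "rV3")
MVPA_ROIS = ("V1", "V2", "V3")
_MVPA_MEMBERS = {"V1": ("lV1", "rV1"), "V2": ("lV2", "rV2"), "V3": ("lV3", "rV3")}


def rng_for(seed: int, *names: str) -> np.random.Generator:
    """Named, reproducible substream of the master seed."""
    key = tuple(zlib.crc32(n.encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class RunConfig:
    """Everything needed to reproduce one full study run.

    Statistical constants default to the study conventions: voxel selection
    at t > 5.09, univariate alpha 0.05/12 = 0.0042, MVPA alpha 0.05/3 =
    0.017 with a 5000-iteration permutation null, 10000 bootstrap iterations
    for the gaze contrasts at 0.025 per tail, 30 deg/s saccade cutoff, and
    BCEA k = 1.
    """

    seed: int = 0
    n_participants: int = 12
    n_gaze_participants: int = 6
    n_runs: int = 8
    sim: dict = field(default_factory=dict)       # SimParams overrides
    localizer_pool: int = 30                       # voxel pool per subregion
    t_crit: float = roi_mod.DEFAULT_T_CRIT
    alpha_family: float = 0.05
    n_univariate_tests: int = 12
    n_mvpa_tests: int = 3
    n_perm: int = 5000
    n_boot: int = 10000
    gaze_alpha_per_tail: float = 0.025
    vmax_deg_s: float = 30.0
    bcea_k: float = 1.0
    gaze_duration_s: float = 100.0
    svm_C: float = 1.0
    svm_tol: float = 1e-2
    out_dir: str | None = None

    def sim_params(self, **overrides) -> SimParams:
        kw = dict(self.sim)
        kw.update(overrides)
        return SimParams(**kw)

    @property
    def alpha_univariate(self) -> float:
        return self.alpha_family / self.n_univariate_tests

    @property
    def alpha_mvpa(self) -> float:
        return self.alpha_family / self.n_mvpa_tests

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# stages


def stage_roi(config: RunConfig) -> dict:
    """Demonstrate voxel selection on simulated localizer + main-run data.

    For each participant and retinotopic subregion: simulate one localizer
    run over a voxel pool, threshold its t-map at ``t_crit``, prune voxels
    preferring the Scotoma over the Center grating (from a 2-run main-
    experiment fit), and merge into the univariate and MVPA ROI schemes.
    """
    per_participant = []
    for p in range(config.n_participants):
        subregions = []
        for sub in roi_mod.SUBREGIONS:
            rng = rng_for(config.seed, "roi", f"p{p}", sub)
            params = config.sim_params(n_voxels=config.localizer_pool)
            loc_seq = TrialSequence(runs=[localizer_design()])
            loc = simulate_bold(loc_seq, params, seed=rng, roi_name=sub)
            X = glm_mod.build_design(loc.sequence)
            fit = glm_mod.fit(loc, X)
            t_map = glm_mod.contrast_t(fit, glm_mod.contrast_vector(X, {"Localizer": 1.0}))
            active = roi_mod.threshold_localizer(t_map, config.t_crit)

            main_seq = main_experiment_sequence(n_runs=2, seed=rng)
            main = simulate_bold(main_seq, params, seed=rng, roi_name=sub)
            Xm = glm_mod.build_design(main.sequence)
            fitm = glm_mod.fit(main, Xm)
            beta_c = fitm.condition_beta("Center")
            beta_s = 0.5 * (fitm.condition_beta("ScotomaFill")
                            + fitm.condition_beta("ScotomaNoFill"))
            kept = roi_mod.restrict_center_dominant(beta_c, beta_s, active)
            # subregion pools are disjoint by construction: offset voxel ids
            offset = roi_mod.SUBREGIONS.index(sub) * config.localizer_pool
            subregions.append(roi_mod.RoiDefinition(
                name=sub, voxels=kept + offset,
                metadata={"t_crit": config.t_crit, "pool": config.localizer_pool,
                          "n_thresholded": int(len(active))}))
        univariate = roi_mod.merge(subregions, "univariate")
        mvpa_rois = roi_mod.merge(subregions, "mvpa")
        per_participant.append({
            "subregions": {r.name: r.size for r in subregions},
            "univariate": {r.name: r.size for r in univariate},
            "mvpa": {r.name: r.size for r in mvpa_rois},
        })
    sizes = {name: [p["univariate"].get(name, 0) for p in per_participant]
             for name in UNIVARIATE_ROIS}
    return {"per_participant": per_participant,
            "mean_univariate_size": {k: float(np.mean(v)) for k, v in sizes.items()}}


def _simulate_cohort(config: RunConfig,
                     between_subject_sd: float = 0.2) -> dict[str, list[RoiTimeSeries]]:
    """Main-experiment data: per univariate ROI, one RoiTimeSeries per participant.

    ``between_subject_sd`` scales a per-participant multiplicative jitter on
    the suppression effect, so group-level effect sizes are finite rather
    than limited only by scan noise.
    """
    cohort: dict[str, list[RoiTimeSeries]] = {name: [] for name in UNIVARIATE_ROIS}
    base = config.sim_params()
    for p in range(config.n_participants):
        seq = main_experiment_sequence(
            n_runs=config.n_runs, seed=rng_for(config.seed, "design", f"p{p}"))
        subj_gain = 1.0 + between_subject_sd * float(
            rng_for(config.seed, "subject", f"p{p}").standard_normal())
        params = config.sim_params(suppression=base.suppression * subj_gain)
        for name in UNIVARIATE_ROIS:
            rng = rng_for(config.seed, "bold", f"p{p}", name)
            cohort[name].append(simulate_bold(seq, params, seed=rng, roi_name=name))
    return cohort


def stage_univariate(config: RunConfig, cohort: dict[str, list[RoiTimeSeries]]) -> dict:
    """GLM contrasts per ROI: FullField - Center (one-tail) and Fill - NoFill."""
    out = {}
    for name, participants in cohort.items():
        ffc, fnf = [], []
        for Y in participants:
            X = glm_mod.build_design(Y.sequence)
            fit = glm_mod.fit(Y, X)
            c1 = glm_mod.contrast_vector(X, {"FullField": 1.0, "Center": -1.0})
            c2 = glm_mod.contrast_vector(X, {"ScotomaFill": 1.0, "ScotomaNoFill": -1.0})
            ffc.append(float(np.mean(glm_mod.contrast_t(fit, c1))))
            fnf.append(float(np.mean(glm_mod.contrast_t(fit, c2))))
        g1 = glm_mod.group_test(np.array(ffc), tail="less",
                                family_alpha=config.alpha_family,
                                n_tests=config.n_univariate_tests)
        g2 = glm_mod.group_test(np.array(fnf), tail="less",
                                family_alpha=config.alpha_family,
                                n_tests=config.n_univariate_tests)
        out[name] = {
            "fullfield_minus_center": asdict(g1),
            "fill_minus_nofill": asdict(g2),
            "participant_t_ffc": ffc,
            "participant_t_fnf": fnf,
        }
    return out


def stage_timecourse(config: RunConfig, cohort: dict[str, list[RoiTimeSeries]]) -> dict:
    """Percent-change epochs and Fill vs NoFill time-to-peak per ROI."""
    out = {}
    for name, participants in cohort.items():
        curves = {"fill": [], "nofill": []}
        ttp = {"fill": [], "nofill": []}
        for Y in participants:
            epochs = tc_mod.epoch(Y)
            per_lab: dict[str, list] = {"fill": [], "nofill": []}
            per_ttp: dict[str, list] = {"fill": [], "nofill": []}
            for e in epochs:
                if e.label is None:
                    continue
                per_lab[e.label].append(tc_mod.percent_change(e))
                per_ttp[e.label].append(tc_mod.time_to_peak(e))
            for lab in ("fill", "nofill"):
                if per_lab[lab]:
                    curves[lab].append(np.mean(per_lab[lab], axis=0))
                    ttp[lab].append(float(np.mean(per_ttp[lab])))
        paired = tc_mod.compare_ttp(np.array(ttp["fill"]), np.array(ttp["nofill"]),
                                    family_alpha=config.alpha_family,
                                    n_tests=config.n_univariate_tests)
        out[name] = {
            "group_curve_fill": np.mean(curves["fill"], axis=0).tolist(),
            "group_curve_nofill": np.mean(curves["nofill"], axis=0).tolist(),
            "mean_ttp_fill": float(np.mean(ttp["fill"])),
            "mean_ttp_nofill": float(np.mean(ttp["nofill"])),
            "paired_t": paired,
        }
    return out


def stage_mvpa(config: RunConfig, cohort: dict[str, list[RoiTimeSeries]]) -> dict:
    """Fill/NoFill classification per hemisphere-merged ROI with permutation p."""
    out = {}
    for name in MVPA_ROIS:
        left, right = _MVPA_MEMBERS[name]
        per_participant_feats = []
        accs = []
        for p in range(config.n_participants):
            fl = mvpa_mod.features(cohort[left][p])
            fr = mvpa_mod.features(cohort[right][p])
            merged = [
                mvpa_mod.TrialFeature(
                    trial_id=a.trial_id, run_id=a.run_id, label=a.label,
                    vector=np.concatenate([a.vector, b.vector]))
                for a, b in zip(fl, fr)
            ]
            per_participant_feats.append(merged)
            accs.append(mvpa_mod.loro_cv(merged, C=config.svm_C,
                                         tol=config.svm_tol).mean_accuracy)
        observed = float(np.mean(accs))
        perm = mvpa_mod.permutation_test(
            per_participant_feats, n_iter=config.n_perm,
            seed=rng_for(config.seed, "perm", name),
            C=config.svm_C, tol=config.svm_tol, observed=observed)
        out[name] = {
            "mean_accuracy": observed,
            "participant_accuracies": accs,
            "permutation_p": perm.p,
            "n_iter": perm.n_iter,
            "alpha": config.alpha_mvpa,
            "significant": perm.p < config.alpha_mvpa,
        }
    return out


def stage_gaze(config: RunConfig) -> dict:
    """BCEA fixation-stability control across stimulus conditions."""
    conditions = ("Center", "FullField", "Fill", "NoFill")
    values: dict[str, list[float]] = {c: [] for c in conditions}
    results: dict[str, list[gaze_mod.BceaResult]] = {c: [] for c in conditions}
    for p in range(config.n_gaze_participants):
        base_sigma = 0.25 + 0.05 * rng_for(config.seed, "gaze_sigma", f"p{p}").random()
        for cond in conditions:
            rng = rng_for(config.seed, "gaze", f"p{p}", cond)
            rec = simulate_gaze(sigma_h=base_sigma, sigma_v=0.9 * base_sigma,
                                rho=0.1, duration_s=config.gaze_duration_s,
                                seed=rng)
            cleaned = gaze_mod.clean(rec, vmax_deg_s=config.vmax_deg_s)
            b = gaze_mod.bcea(cleaned, k=config.bcea_k)
            values[cond].append(b.bcea)
            results[cond].append(b)

    def contrast(a: str, b: str, name: str) -> dict:
        boot = gaze_mod.bootstrap_contrast(
            np.array(values[a]), np.array(values[b]), n_iter=config.n_boot,
            seed=rng_for(config.seed, "boot", name))
        anova = gaze_mod.rm_anova_2(np.array(values[a]), np.array(values[b]))
        contained = [
            gaze_mod.ellipse_contains(results[a][p], results[b][p].center)
            and gaze_mod.ellipse_contains(results[b][p], results[a][p].center)
            for p in range(config.n_gaze_participants)
        ]
        return {
            "mean_diff": boot["mean_diff"],
            "bootstrap_p": boot["p"],
            "n_boot": config.n_boot,
            "anova_F": anova["F"], "anova_p": anova["p"], "anova_df": list(anova["df"]),
            "mutual_center_containment": float(np.mean(contained)),
        }

    return {
        "bcea_by_condition": {c: values[c] for c in conditions},
        "center_vs_fullfield": contrast("Center", "FullField", "cf"),
        "fill_vs_nofill": contrast("Fill", "NoFill", "fn"),
        "k": config.bcea_k,
        "probability_area": gaze_mod.probability_area(config.bcea_k),
    }


def run_study(config: RunConfig) -> dict:
    """Execute all stages; failures are recorded and independent stages still run."""
    report: dict = {"config": asdict(config), "errors": {}}
    cohort = None
    for name, fn in [("roi", lambda: stage_roi(config)),
                     ("simulate", lambda: _simulate_cohort(config))]:
        try:
            result = fn()
            if name == "simulate":
                cohort = result
                report["simulate"] = {"n_participants": config.n_participants,
                                      "rois": list(result.keys())}
            else:
                report[name] = result
            log.info("stage %s: ok", name)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            report["errors"][name] = repr(exc)
            log.exception("stage %s failed", name)
    for name, fn in [("univariate", stage_univariate),
                     ("timecourse", stage_timecourse),
                     ("mvpa", stage_mvpa)]:
        if cohort is None:
            report["errors"][name] = "skipped: simulation unavailable"
            continue
        try:
            report[name] = fn(config, cohort)
            log.info("stage %s: ok", name)
        except Exception as exc:  # noqa: BLE001
            report["errors"][name] = repr(exc)
            log.exception("stage %s failed", name)
    try:
        report["gaze"] = stage_gaze(config)
    except Exception as exc:  # noqa: BLE001
        report["errors"]["gaze"] = repr(exc)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        config.to_yaml(out / "config.yaml")
    return report
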