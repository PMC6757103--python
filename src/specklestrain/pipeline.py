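"""End-to-end orchestration of the deformation-analysis stages.

Stage order: simulate (phantom and/or cohort) -> track -> areas ->
features -> mva / stats. Each stage writes its artifact next to a JSON
provenance block (inputs, parameters, seed, software version) so any stage
can be re-run individually and byte-identically from the same config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import SpecError
from . import synthetic, tracking, areas, features, multivariate, stats

log = logging.getLogger("specklestrain")

STAGES = ("simulate-phantom", "simulate-cohort", "track", "areas", "features", "mva", "stats")


@dataclass
class PipelineConfig:
    out_dir: Path = Path("specklestrain_run")
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    phantom: synthetic.PhantomSpec | None = None
    cohort: synthetic.CohortSpec | None = None
    tracker: tracking.TrackerParams = field(default_factory=tracking.TrackerParams)
    target_strain_pct: float = 10.0
    time_normalize: bool = True
    mvc_normalize: bool = True
    n_orthogonal: int = 1

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise SpecError(f"unknown stage(s): {unknown}")


def _provenance(path: Path, stage: str, config: PipelineConfig, extra: dict) -> None:
    block = {
        "stage": stage,
        "seed": config.seed,
        "version": __version__,
        **extra,
    }
    path.write_text(json.dumps(block, indent=1, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages in dependency order; return a run report."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    want = set(config.stages)

    phantom_path = out / "phantom.tif"
    cohort_path = out / "cohort.csv"
    strain_path = out / "strain.csv"
    agg_path = out / "areas_aggregated.csv"

    if "simulate-phantom" in want:
        spec = config.phantom or synthetic.PhantomSpec(seed=config.seed)
        profile = synthetic.generate_strain_profile(spec, config.target_strain_pct)
        frames, _ = synthetic.generate_speckle_sequence(spec, profile)
        synthetic.write_sequence(phantom_path, frames, spec, profile)
        log.info("wrote %s (%d frames)", phantom_path, len(frames))
        report["phantom_frames"] = int(frames.shape[0])

    if "simulate-cohort" in want:
        spec = config.cohort or synthetic.CohortSpec(seed=config.seed)
        table = synthetic.generate_cohort(spec)
        synthetic.write_cohort(cohort_path, table)
        _provenance(
            out / "cohort.provenance.json",
            "simulate-cohort",
            config,
            {"rows": len(table), "n_subjects": spec.n_subjects},
        )
        log.info("wrote %s (%d rows)", cohort_path, len(table))
        report["cohort_rows"] = len(table)

    if "track" in want:
        if not phantom_path.exists():
            raise SpecError("track stage needs the simulate-phantom artifact")
        frames, meta = synthetic.read_sequence(phantom_path)
        seq = tracking.ImageSequence(frames, meta["fps"], meta["mm_per_px"])
        band = meta.get("band_rows", [0, frames.shape[1]])
        centre = ((band[0] + band[1]) / 2.0, (frames.shape[2] - 1) / 2.0)
        roi = tracking.init_roi(
            frames[0], centre, 0.0, 15.0, meta["mm_per_px"],
        )
        series, prov = tracking.track_sequence(seq, roi, config.tracker)
        tracking.write_strain(strain_path, series, prov)
        truth = np.asarray(meta["true_strain_pct"])
        peak_err = float(
            abs(series.strain_pct[np.argmax(np.abs(truth))] - truth[np.argmax(np.abs(truth))])
        )
        report["tracking_peak_strain_error_pp"] = peak_err
        report["tracking_surviving_points"] = prov["surviving_points"][-1]
        log.info("tracking peak-strain error %.3f pp", peak_err)

    if "areas" in want:
        if not cohort_path.exists():
            raise SpecError("areas stage needs the simulate-cohort artifact")
        table = synthetic.read_cohort(cohort_path)
        agg = areas.aggregate_trials(table, time_normalize=config.time_normalize)
        if config.mvc_normalize:
            norm = areas.normalize_to_mvc(agg)
            norm.to_csv(out / "areas_normalized.csv", index=False)
        agg.to_csv(agg_path, index=False)
        report["aggregated_rows"] = len(agg)

    base = y = subj = None
    if want & {"features", "mva"}:
        agg = pd.read_csv(agg_path)
        if config.mvc_normalize:
            agg = areas.normalize_to_mvc(agg)
        base, y = features.base_feature_matrix(agg)
        subj = base.index.get_level_values("subject").to_numpy()

    if "features" in want:
        inter = features.interaction_terms(base)
        inter.to_csv(out / "interaction_terms.csv")
        report["n_interaction_terms"] = inter.shape[1]

    if "mva" in want:
        inter = features.interaction_terms(base)
        X, _state = features.mva_preprocess(inter)
        pca = multivariate.fit_pca(X.to_numpy(), n_components=3)
        model = multivariate.fit_opls(X.to_numpy(), y.to_numpy(), config.n_orthogonal)
        cv = multivariate.loso_cv(
            inter.to_numpy(), y.to_numpy(), subj,
            n_orthogonal=config.n_orthogonal, log_transform=True,
        )
        vip = multivariate.vip_scores(model, list(inter.columns))
        vip.vip.sort_values(ascending=False).to_csv(out / "vip.csv")
        cv.predictions.to_csv(out / "cv_predictions.csv", index=False)
        (out / "opls_model.json").write_text(
            json.dumps(
                {
                    "r2y": model.r2y,
                    "q2y": cv.q2y,
                    "rmsecv": cv.rmsecv,
                    "n_orthogonal": model.n_orthogonal,
                    "pca_explained": pca.explained_variance_ratio.tolist(),
                },
                indent=1,
            )
        )
        report.update(
            r2y=model.r2y, q2y=cv.q2y, rmsecv=cv.rmsecv,
            pca_explained=pca.explained_variance_ratio.tolist(),
        )
        log.info("OPLS R2Y %.3f Q2Y %.3f RMSECV %.2f", model.r2y, cv.q2y, cv.rmsecv)

    if "stats" in want:
        table = synthetic.read_cohort(cohort_path)
        agg_raw = areas.aggregate_trials(table, time_normalize=False)
        summed = areas.sum_muscles(agg_raw)
        fits = {}
        for subject, grp in summed.groupby("subject"):
            res = stats.fit_force_relationship(
                grp["mvc_pct"].to_numpy(), grp["total_area"].to_numpy()
            )
            fits[int(subject)] = {
                "selected": res.selected,
                "adj_r2": res.adj_r2_selected,
                "category": res.category,
            }
        trial_sums = (
            table.groupby(["subject", "mvc_pct", "trial"])["total_area"].sum().unstack("trial")
        )
        icc = stats.icc_trials(trial_sums.to_numpy())
        norm = areas.normalize_to_mvc(agg_raw, per_muscle=False)
        wide = (
            norm[norm["mvc_pct"] != 100]
            .groupby(["subject", "mvc_pct"])["total_area"].sum().unstack("mvc_pct")
        )
        anova = stats.rm_anova(wide.to_numpy())
        report["fits"] = fits
        report["icc_sum5"] = icc.icc
        report["icc_ci95"] = list(icc.ci95)
        report["icc_category"] = icc.category
        report["rm_anova_F"] = anova.f_stat
        report["rm_anova_p"] = anova.p_value
        pd.DataFrame(fits).T.to_csv(out / "subject_fits.csv")

    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
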