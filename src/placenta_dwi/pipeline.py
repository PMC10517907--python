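"""End-to-end orchestration: simulate (or load) → fit → summarise → test.

Stage order mirrors the study workflow: voxel maps, then ROI means per
subject, then group statistics, then the logistic risk model and ROC
analysis.  Every run writes a manifest (seed, config hash, package
versions) sufficient to reproduce all outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, models, roi, stats, synth

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    """Reproducible configuration for a full run.

    With ``cohort_csv`` unset, a synthetic cohort is simulated from the
    published group summaries (20 adverse / 40 non-adverse by default).
    """

    out_dir: str
    seed: int = 0
    cohort_csv: str | None = None
    n_adverse: int = 20
    n_non_adverse: int = 40
    parameter_correlation: float = 0.0   # common off-diagonal correlation
    fit_phantom: bool = True
    phantom_shape: tuple = (6, 6, 2)
    phantom_noise: str = "gaussian"
    phantom_sigma: float = 0.02
    icc_model: str = "two_way_random_absolute"
    reader_sd: float = 0.15              # kPa-scale reader noise for the demo ICC
    correlation_method: str = "spearman"
    alpha: float = 0.05

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom_shape"] = list(self.phantom_shape)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _correlation_matrix(rho: float) -> np.ndarray:
    k = len(synth.PARAM_ORDER)
    m = np.full((k, k), float(rho))
    np.fill_diagonal(m, 1.0)
    return m


def _stage_phantom(cfg: RunConfig, out: Path) -> dict:
    spec = synth.two_region_phantom_spec(
        shape=cfg.phantom_shape, noise_model=cfg.phantom_noise,
        noise_sigma=cfg.phantom_sigma, seed=cfg.seed)
    series, truth, mask = synth.simulate_phantom(spec)
    maps = models.fit_volume(series, mask, "ivim_segmented")
    rows = []
    for reg in spec.regions:
        reg_mask = io.ROIMask(reg.mask, label=reg.name)
        for pname in ("f", "D", "Dstar"):
            summ = roi.roi_summary(maps[pname], reg_mask, reg.name)
            rows.append({
                "region": reg.name, "parameter": pname,
                "fitted_mean": summ.mean, "fitted_sd": summ.sd,
                "true_value": float(reg.params[pname]),
                "n_voxels": summ.n_voxels, "n_failed": summ.n_failed,
            })
        io.write_parameter_map(maps["f"], out / f"phantom_f.nii.gz")
    df = pd.DataFrame(rows)
    df.to_csv(out / "phantom_roi_summaries.csv", index=False)
    return {"n_regions": len(spec.regions), "rows": len(df)}


def _stage_cohort(cfg: RunConfig) -> io.CohortTable:
    if cfg.cohort_csv is not None:
        path = Path(cfg.cohort_csv)
        if not path.exists():
            raise PipelineError("cohort", f"cohort file not found: {path}")
        return io.read_cohort(path)
    corr = _correlation_matrix(cfg.parameter_correlation)
    return synth.simulate_cohort(
        synth.adverse_group_spec(cfg.n_adverse, corr),
        synth.non_adverse_group_spec(cfg.n_non_adverse, corr),
        seed=cfg.seed,
    )


def _stage_stats(cfg: RunConfig, cohort: io.CohortTable, out: Path) -> dict:
    params = cohort.parameter_columns()
    continuous_covs = [c for c in ("maternal_age", "ga_mri", "ga_delivery",
                                   "birth_weight") if c in cohort.df.columns]
    categorical = [c for c in ("delivery_route", "preterm", "neonatal_sex")
                   if c in cohort.df.columns]

    comp_rows = []
    for var in params + continuous_covs + categorical:
        r = stats.compare_groups(cohort, var)
        row = {"variable": var, "test": r.test, "statistic": r.statistic,
               "p": r.p, "continuity_correction": r.continuity_correction}
        if r.test != "chi_square":
            for g, (m, s) in r.mean_sd_by_group.items():
                row[f"{g}_mean"], row[f"{g}_sd"] = m, s
        comp_rows.append(row)
    comp = pd.DataFrame(comp_rows)
    comp.to_csv(out / "group_comparison.csv", index=False)

    sig_params = comp.loc[comp["variable"].isin(params) & (comp["p"] < cfg.alpha),
                          "variable"].tolist()
    logi = None
    if len(sig_params) >= 1:
        logi = stats.backward_eliminate(cohort, sig_params, alpha=cfg.alpha)
        terms = [dataclasses.asdict(t) for t in logi.terms]
        (out / "logistic_model.json").write_text(json.dumps({
            "candidates": sig_params,
            "terms": terms,
            "converged": logi.converged,
            "separation_flag": logi.separation_flag,
        }, indent=2))

    labels = (cohort.df["group"] == "adverse").to_numpy()
    roc_rows = []
    for p in params:
        r = stats.roc_analysis(cohort.df[p].to_numpy(float), labels)
        roc_rows.append({"score": p, **dataclasses.asdict(r)})
    if logi is not None:
        final_covs = [t.name for t in logi.terms if t.name != "const"]
        X = cohort.df[final_covs].to_numpy(float)
        coefs = np.array([logi.term(c).coefficient for c in final_covs])
        const = logi.term("const").coefficient
        score = const + X @ coefs
        r = stats.roc_analysis(score, labels, direction="higher_is_positive")
        roc_rows.append({"score": "combined:" + "+".join(final_covs),
                         **dataclasses.asdict(r)})
    pd.DataFrame(roc_rows).to_csv(out / "roc_results.csv", index=False)

    ga_rows = []
    if "ga_mri" in cohort.df.columns and "mu_diff" in params:
        for gname in ("adverse", "non_adverse"):
            sub = io.CohortTable(cohort.df[cohort.df["group"] == gname])
            c = stats.ga_correlation(sub, "mu_diff", cfg.correlation_method)
            ga_rows.append({"group": gname, **dataclasses.asdict(c)})
        pd.DataFrame(ga_rows).to_csv(out / "ga_correlation.csv", index=False)

    # reader-agreement demo on the stiffness summaries
    truth = cohort.df["mu_diff"].to_numpy(float) if "mu_diff" in params else None
    icc_summary = None
    if truth is not None:
        ratings = synth.simulate_reader_pair(truth, cfg.reader_sd,
                                             seed=cfg.seed + 1)
        r = roi.icc(ratings, cfg.icc_model)
        icc_summary = {"icc": r.icc, "ci_low": r.ci_low, "ci_high": r.ci_high,
                       "model": r.model, "grade": roi.classify_icc(r.icc)}
        (out / "icc.json").write_text(json.dumps(icc_summary, indent=2))

    return {
        "n_comparisons": len(comp),
        "significant_parameters": sig_params,
        "final_model_terms": [t.name for t in (logi.terms if logi else [])],
        "n_roc": len(roc_rows),
        "icc": icc_summary,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages, writing a results bundle under ``config.out_dir``.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "versions": _versions(),
        "stages": {},
    }
    try:
        if config.fit_phantom:
            manifest["stages"]["phantom"] = _stage_phantom(config, out)
        cohort = _stage_cohort(config)
        io.write_cohort(cohort, out / "cohort.csv")
        manifest["stages"]["cohort"] = {"n": len(cohort),
                                        "groups": cohort.group_counts()}
        manifest["stages"]["stats"] = _stage_stats(config, cohort, out)
    except PipelineError:
        raise
    except Exception as exc:  # attribute failures to the running stage
        done = set(manifest["stages"])
        stage = ("phantom" if "phantom" not in done and config.fit_phantom
                 else "cohort" if "cohort" not in done else "stats")
        raise PipelineError(stage, str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _versions() -> dict:
    import nibabel
    import scipy
    import sklearn
    import statsmodels

    import placenta_dwi

    return {
        "placenta_dwi": placenta_dwi.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
        "statsmodels": statsmodels.__version__,
        "sklearn": sklearn.__version__,
    }
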