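"""ROI summaries of parameter maps and reader-agreement statistics.

Per-subject values are the means of a fitted parameter over the placental
ROI (failed voxels excluded).  Agreement between repeated reads is
quantified with intraclass correlation coefficients from the two-way
ANOVA decomposition: ICC(2,1) (two-way random effects, absolute
agreement, single measurement) for inter-reader agreement, and ICC(3,1)
(two-way mixed, consistency) for intra-reader agreement.  Consistency is
blind to a constant offset between raters; absolute agreement is not, so
absolute ≤ consistency on the same data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pingouin as pg

from .io import ParameterMap, ROIMask

__all__ = ["ROISummary", "ICCResult", "roi_summary", "icc", "classify_icc"]

# pingouin labels: ICC(A,1) = two-way random, absolute agreement, single
# measure (Shrout–Fleiss ICC(2,1)); ICC(C,1) = two-way mixed, consistency
# (ICC(3,1))
ICC_MODELS = {"two_way_random_absolute": "ICC(A,1)",
              "two_way_mixed_consistency": "ICC(C,1)"}


@dataclasses.dataclass
class ROISummary:
    subject_id: str
    parameter_name: str
    mean: float
    sd: float
    n_voxels: int
    n_failed: int


@dataclasses.dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str
    n_subjects: int
    n_raters: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.icc)


def roi_summary(pmap: ParameterMap, mask: ROIMask, subject_id: str) -> ROISummary:
    """Mean/SD of a parameter over the masked, successfully fitted voxels."""
    if pmap.values.shape != mask.mask.shape:
        raise ValueError("parameter map and mask grids differ")
    vals = pmap.values[mask.mask]
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError(
            f"all masked voxels unfit for subject {subject_id!r}, "
            f"parameter {pmap.parameter_name!r}"
        )
    good = vals[ok]
    sd = float(np.std(good, ddof=1)) if good.size > 1 else 0.0
    return ROISummary(
        subject_id=subject_id,
        parameter_name=pmap.parameter_name,
        mean=float(good.mean()),
        sd=sd,
        n_voxels=int(good.size),
        n_failed=int((~ok).sum()),
    )


def icc(ratings, model: str = "two_way_random_absolute") -> ICCResult:
    """Intraclass correlation of a subjects x raters matrix.

    Requires >=5 subjects, >=2 raters and no missing cells.  Zero
    between-subject variance leaves the ICC undefined (NaN, flagged via
    ``.defined``).
    """
    if model not in ICC_MODELS:
        raise ValueError(f"unknown ICC model {model!r}; expected {sorted(ICC_MODELS)}")
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    n_subj, n_rat = r.shape
    if n_subj < 5:
        raise ValueError("need at least 5 subjects for an ICC")
    if n_rat < 2:
        raise ValueError("need at least 2 raters for an ICC")
    if not np.all(np.isfinite(r)):
        raise ValueError("missing cells in ratings; no imputation performed")
    if np.var(r.mean(axis=1)) < 1e-30:
        return ICCResult(np.nan, np.nan, np.nan, model, n_subj, n_rat)

    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_subj), n_rat),
        "rater": np.tile(np.arange(n_rat), n_subj),
        "score": r.ravel(),
    })
    tab = pg.intraclass_corr(long, targets="subject", raters="rater",
                             ratings="score")
    row = tab.set_index("Type").loc[ICC_MODELS[model]]
    ci_col = "CI95%" if "CI95%" in tab.columns else "CI95"
    ci_low, ci_high = (float(x) for x in row[ci_col])
    return ICCResult(float(row["ICC"]), ci_low, ci_high, model, n_subj, n_rat)


def classify_icc(value: float) -> str:
    """Consistency grade: >=0.75 remarkable, [0.40, 0.75) medium, <0.40 poor."""
    if not np.isfinite(value):
        raise ValueError("ICC is not finite")
    if value >= 0.75:
        return "remarkable"
    if value >= 0.40:
        return "medium"
    return "poor"
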