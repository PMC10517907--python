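"""Run the subject-level statistics on the simulated cohort.

Group comparison of every parameter and covariate, backward-eliminated
logistic risk model, ROC analysis per parameter plus the combined
logistic score, and the gestational-age correlation — the full
statistical stage, written as a results bundle with a reproducibility
manifest.
"""

import json
from pathlib import Path

import pandas as pd

from placenta_dwi import pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort_stats"
SEED = 20260924


def main() -> None:
    cfg = pipeline.RunConfig(out_dir=str(OUT), seed=SEED, fit_phantom=False)
    manifest = pipeline.run_pipeline(cfg)
    print(f"wrote results bundle under {OUT} (config hash "
          f"{manifest['config_hash']})")

    comp = pd.read_csv(OUT / "group_comparison.csv")
    sig = comp[comp["p"] < 0.05]["variable"].tolist()
    print(f"significant at 0.05: {', '.join(sig)}")

    logi_path = OUT / "logistic_model.json"
    if logi_path.exists():
        logi = json.loads(logi_path.read_text())
        terms = [t for t in logi["terms"] if t["name"] != "const"]
        print("final logistic model:")
        for t in terms:
            print(f"  {t['name']}: OR {t['odds_ratio']:.3f} "
                  f"({t['ci_low']:.3f}-{t['ci_high']:.3f}), p={t['p']:.4f}")

    roc = pd.read_csv(OUT / "roc_results.csv")
    for _, r in roc.iterrows():
        print(f"  ROC {r['score']}: AUC {r['auc']:.3f} "
              f"({r['ci_low']:.3f}-{r['ci_high']:.3f}), "
              f"cutoff {r['cutoff']:.3f} ({r['direction']})")


if __name__ == "__main__":
    main()
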