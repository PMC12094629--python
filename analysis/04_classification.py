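"""Cross-validated IA-vs-HC classification over models, metrics and modes.

Evaluates SVM-RBF, random forest and kNN on the PLI and WPLI feature
tensors with stratified 5-fold CV, in both preprocessing modes: the
reproduction ordering (selection/z-score/PCA fitted on all subjects before
CV, optimistic) and the leak-free ordering (fitted per training fold).
Writes mean +/- sd accuracy, sensitivity and specificity per combination.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _cohort_cache import RESULTS, get_cohort  # noqa: E402

from eegsync.classify import ModelSpec, train_eval  # noqa: E402

CV_SEED = 7


def main() -> None:
    config, tensors, labels = get_cohort()
    rows = []
    for name, tensor in tensors.items():
        for kind in ("svm_rbf", "random_forest", "knn"):
            for mode in ("paper_faithful", "leak_free"):
                summary = train_eval(
                    tensor, labels, ModelSpec(kind, seed=CV_SEED),
                    mode=mode, seed=CV_SEED,
                )
                rows.append(summary.summary_row())
    df = pd.DataFrame(rows)
    out = RESULTS / "classification_results.csv"
    df.to_csv(out, index=False, float_format="%.4f")

    for mode in ("paper_faithful", "leak_free"):
        sub = df[df["mode"] == mode]
        print(f"\nmode = {mode}:")
        for _, r in sub.iterrows():
            print(f"  {r['features']:<5} {r['model']:<14} "
                  f"acc {r.accuracy_mean:.3f}±{r.accuracy_sd:.3f}  "
                  f"sens {r.sensitivity_mean:.3f}  "
                  f"spec {r.specificity_mean:.3f}")
    print(f"\nresults -> {out}")


if __name__ == "__main__":
    main()
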