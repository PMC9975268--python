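"""Discriminate rest / mental / physical load from (ΔPEP, ΔHR).

Builds one feature point per subject per state (deltas to the single rest
calibration), evaluates a k=13 k-NN under subject-wise fivefold
cross-validation with 20 seeded repeats, and exports the decision map.
"""

from pathlib import Path

from pepstress.classifier import build_features, decision_map, evaluate_knn
from pepstress.cohort import generate_cohort
from pepstress.config import ClassifierConfig, GeneratorConfig
from pepstress.io import write_json, write_table

SEED = 1
OUT = Path("results/classifier")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(GeneratorConfig(), SEED, beats="none")
    features = build_features(cohort.measurements)
    write_table(features, OUT / "features.csv")

    config = ClassifierConfig(k=13, n_folds=5, n_repeats=20)
    report = evaluate_knn(features, config, seed=SEED)
    write_json(report.to_dict(), OUT / "classifier_report.json")
    write_table(decision_map(features, config), OUT / "decision_map.csv")

    print(f"{len(features)} feature points ({features['subject_id'].nunique()} subjects)")
    print(f"k={config.k} k-NN, subject-wise {config.n_folds}-fold, "
          f"{config.n_repeats} repeats:")
    print(f"  macro PPV {report.macro_ppv:.1%}, "
          f"macro sensitivity {report.macro_sensitivity:.1%}")
    print("  confusion matrix (rows = truth):")
    print(report.confusion_matrix.to_string())


if __name__ == "__main__":
    main()
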