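"""Model 3: outcome prediction from in-silico generated immune features.

Collapses the Model-2 ridge ensemble into one linear generator (mean of
all per-repetition, per-fold coefficients), generates first-trimester
immune features for the 186 patients without immune measurements, and
reruns the multitask vs single-task comparison with those generated
features as input.  Writes the comparison under results/model3/.
"""

import sys
from pathlib import Path

import numpy as np

from stressmtl.generation import (
    average_ensemble,
    generate_features,
    predict_aporfs_from_generated,
    unmeasured_patients,
)
from stressmtl.immune import RidgeConfig, grouped_repeated_cv
from stressmtl.nn import NetworkConfig
from stressmtl.prep import FeatureMatrix
from stressmtl.synthetic import (
    CohortSpec,
    ImmunePanelSpec,
    generate_cohort,
    generate_immune_panel,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
N_REPETITIONS = int(sys.argv[2]) if len(sys.argv) > 2 else 10

TASKS = [
    ("gestational_diabetes", "binary"),
    ("severe_pree", "binary"),
    ("superimposed_pree", "binary"),
    ("diabetes", "binary"),
    ("hypertension", "binary"),
    ("ga_delivery", "numeric"),
    ("bmi", "numeric"),
]


def main() -> None:
    out = Path("results/model3")
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(CohortSpec(seed=SEED))
    fm = FeatureMatrix(values=cohort.psf_frame())
    panel = generate_immune_panel(cohort, ImmunePanelSpec(seed=SEED))

    screen = grouped_repeated_cv(
        panel, fm, RidgeConfig(n_repetitions=5, seed=SEED)
    )
    gen = average_ensemble(screen.ensemble)
    gen.write(out)

    rest = unmeasured_patients(cohort, panel.patient_ids)
    gen_features = generate_features(
        gen, FeatureMatrix(values=fm.values.loc[rest]), timepoint=1
    )
    print(f"generated {gen_features.shape[1]} immune features for "
          f"{gen_features.shape[0]} patients "
          f"(the {len(panel.patient_ids)} measured patients excluded)")

    cfg = NetworkConfig(n_features=gen_features.shape[1], task_specs=TASKS,
                        seed=SEED)
    res = predict_aporfs_from_generated(
        gen_features, cohort.data[[n for n, _ in TASKS]], cfg,
        measured_patient_ids=panel.patient_ids,
        n_repetitions=N_REPETITIONS,
    )
    table = res.comparison_table(paired=False)  # unpaired rank-sum variant
    table.to_csv(out / "comparison.csv", index=False)
    print(table.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
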