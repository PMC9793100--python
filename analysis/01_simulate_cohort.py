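"""Generate the default synthetic cohort and immune panel.

Emulates the study composition: 200 pregnant women (18 hypertension, 11
diabetes, 29 gestational diabetes, 6 superimposed and 13 severe
preeclampsia, 17 preterm; 52 with at least one adverse outcome or risk
factor), 79 questionnaire predictors in 15 correlated blocks, and a
14-patient x 4-timepoint panel of 534 immune features of which 40 are
genuinely linear in the stress factors.  Writes both tables plus the
planted truth under results/data/.
"""

import sys

from stressmtl.synthetic import (
    CohortSpec,
    ImmunePanelSpec,
    generate_cohort,
    generate_immune_panel,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = "results/data"


def main() -> None:
    cohort = generate_cohort(CohortSpec(seed=SEED))
    cohort.write(OUT)
    counts = cohort.data[cohort.outcome_binary_cols].sum()
    print(f"cohort: {cohort.n_patients} patients")
    print(counts.to_string())
    print(f"any adverse outcome / risk factor: {int(cohort.data['any_aporf'].sum())}")
    print(
        "median GA at questionnaire: "
        f"{cohort.data['ga_questionnaire'].median():.1f} weeks "
        f"({(cohort.data['ga_questionnaire'] < 21).mean():.1%} before 21 weeks)"
    )

    panel = generate_immune_panel(cohort, ImmunePanelSpec(seed=SEED))
    panel.write(OUT)
    print(
        f"immune panel: {len(panel.patient_ids)} patients x 4 timepoints, "
        f"{len(panel.feature_names)} features "
        f"({len(panel.signal_features)} with planted stress signal)"
    )


if __name__ == "__main__":
    main()
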