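"""Stressor categories and their outcome associations.

Clusters the 79 questionnaire predictors into 15 categories by K-means on
their Spearman correlation profiles, embeds them in 2-D (t-SNE on the
absolute profiles), and quantifies item- and cluster-level associations
with the 7 modelled outcomes at unadjusted p < 0.05 (the any-member rule
for clusters).  Writes assignment, association matrices and the cluster
summary under results/clusters/.
"""

import sys

from stressmtl.clusters import (
    associate,
    cluster_psfs,
    correlation_profiles,
    embed_psfs,
    write_associations,
)
from stressmtl.prep import FeatureMatrix
from stressmtl.synthetic import APO_TASKS, CohortSpec, generate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUTCOMES = ["hypertension", "diabetes", "gestational_diabetes",
            "superimposed_pree", "severe_pree", "ga_delivery", "bmi"]


def main() -> None:
    cohort = generate_cohort(CohortSpec(seed=SEED))
    fm = FeatureMatrix(values=cohort.psf_frame())
    profiles = correlation_profiles(fm)
    ca = cluster_psfs(profiles, seed=SEED)
    ca.embedding = embed_psfs(profiles, seed=SEED)
    res = associate(fm, cohort.data[OUTCOMES], ca,
                    apo_cols=[c for c in OUTCOMES if c in APO_TASKS])
    write_associations(res, ca, "results/clusters")

    sizes = ca.assignment.value_counts().sort_index()
    print(f"{ca.k} clusters, sizes: {sizes.tolist()}")
    print("\nper-cluster outcome associations (any-member rule):")
    print(res.cluster_summary.to_string())
    top = res.psf_counts.sort_values("n_assoc_total", ascending=False).head(8)
    print("\nitems associated with most outcomes:")
    print(top.to_string())


if __name__ == "__main__":
    main()
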