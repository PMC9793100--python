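"""Outcome interrelatedness network.

Computes pairwise Spearman correlations between the 7 modelled outcomes
(hypertension, diabetes, pre-pregnancy BMI, gestational diabetes,
superimposed and severe preeclampsia, gestational age at delivery) on the
default synthetic cohort and categorises each edge as weak / moderate /
strong.  On the printed-composition cohort roughly half of the edges come
out moderate or strong — the joint-modelling premise.
"""

import sys

from stressmtl.network import build_network, write_network
from stressmtl.synthetic import CohortSpec, generate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
NODES = ["hypertension", "diabetes", "gestational_diabetes",
         "superimposed_pree", "severe_pree", "ga_delivery", "bmi"]


def main() -> None:
    cohort = generate_cohort(CohortSpec(seed=SEED))
    cm, edges = build_network(cohort.data[NODES])
    write_network(cm, edges, "results/network")
    n_strong = sum(e.category == "strong" for e in edges)
    n_mod = sum(e.category == "moderate" for e in edges)
    print(cm.rho.round(2).to_string())
    print(
        f"\n{len(edges)} edges: {n_strong} strong, {n_mod} moderate "
        f"({(n_strong + n_mod) / len(edges):.0%} moderate-or-strong)"
    )


if __name__ == "__main__":
    main()
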