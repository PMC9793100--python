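"""Model 2: ridge screen linking stress factors to immune features.

Predicts each of the 534 immune features of the 14-patient panel from the
79 questionnaire predictors plus a timepoint integer, under shuffled
grouped 10-fold cross-validation with an inner per-feature alpha grid
search, repeated; per-feature Spearman rho/p are averaged over repetitions
and screened with Benjamini-Hochberg FDR (alpha 0.05).  Writes the
predictability table and the averaged generator inputs under
results/model2/.  The number of repetitions defaults to 10 here to keep
the driver quick; pass a second argument for the full 50.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from stressmtl.immune import RidgeConfig, grouped_repeated_cv
from stressmtl.prep import FeatureMatrix
from stressmtl.synthetic import (
    CohortSpec,
    ImmunePanelSpec,
    generate_cohort,
    generate_immune_panel,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
N_REPETITIONS = int(sys.argv[2]) if len(sys.argv) > 2 else 10


def main() -> None:
    out = Path("results/model2")
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(CohortSpec(seed=SEED))
    fm = FeatureMatrix(values=cohort.psf_frame())
    panel = generate_immune_panel(cohort, ImmunePanelSpec(seed=SEED))
    cfg = RidgeConfig(n_repetitions=N_REPETITIONS, seed=SEED)
    res = grouped_repeated_cv(panel, fm, cfg)

    res.table.to_csv(out / "predictability.csv", index=False)
    np.save(out / "ensemble_mean_coefs.npy",
            res.ensemble.coefs.mean(axis=0))
    sig = res.table[res.table["significant"]]
    planted = set(panel.signal_features)
    hits = sig["feature"].isin(planted).sum()
    print(f"screened {len(res.table)} immune features over "
          f"{cfg.n_repetitions} repetitions of grouped {cfg.k_outer}-fold CV")
    print(f"significant after FDR: {len(sig)} "
          f"({hits} of the {len(planted)} planted signal features)")
    print("\ntop 10 by mean rho:")
    print(res.table.nlargest(10, "mean_rho")
          .round(3).to_string(index=False))


if __name__ == "__main__":
    main()
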