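#!/usr/bin/env python
"""Generate the synthetic study system used by all downstream analyses.

No raw field data accompany the study design this pipeline implements, so a
synthetic system with known truth stands in: eight populations spanning a
preference gradient for two host plants (OP2-style two-plant design), hatch
experiments across four winter-length treatments at two lab locations, wing
-model presentation trials over a bivariate morphospace, and a distance
system in which genetic divergence is built from geography and phenotype.

Writes CSV inputs plus a truth record per dataset under results/data/.
"""

from pathlib import Path
import dataclasses
import json

import numpy as np

from lycaeides import io as lio
from lycaeides.synthetic_data import (
    gen_distance_system,
    gen_egg_counts,
    gen_hatch_data,
    gen_wing_trials,
)

SEED = 20130204
OUT = Path("results/data")

# population-level preference for plant A (A. m. hylophilus analogue) spans
# melissa-like (<0.5) to idas-like (>0.5); w sets individual variation
POPULATIONS = {
    "SIN": (0.45, 8.0), "LAN": (0.42, 12.0), "VIC": (0.35, 5.0),
    "BCR": (0.55, 10.0), "USL": (0.68, 15.0), "BTB": (0.72, 20.0),
    "HNV": (0.66, 25.0), "SYC": (0.30, 10.0),
}
N_FEMALES = 20
EGG_MEAN = 20.0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    truths = {}

    egg_tables = {}
    for pop, (pi_a, w) in POPULATIONS.items():
        table, truth = gen_egg_counts(
            np.array([pi_a, 1 - pi_a]), w, N_FEMALES, EGG_MEAN,
            seed=int(rng.integers(2**31 - 1)), population_id=pop,
            category_labels=["plant_A", "plant_B"],
        )
        egg_tables[pop] = table
        truths[f"egg_counts/{pop}"] = dataclasses.asdict(truth)
    lio.write_egg_counts(egg_tables, OUT / "egg_counts.csv")

    # hatch experiments: melissa-like populations hatch without winter
    # (high DIA alpha), idas-like ones diapause obligately (low DIA alpha)
    hatch_tables = {}
    for pop in POPULATIONS:
        idas_like = POPULATIONS[pop][0] > 0.5
        alpha = {"DIA": (-4.0 if idas_like else 1.5),
                 "DA11": 0.0, "DM11": -0.5, "DJ11": -1.0}
        table, truth = gen_hatch_data(
            alpha, {t: 0.3 for t in alpha}, {t: 4.0 for t in alpha},
            n_females_per_cell=8, eggs_per_female=10,
            seed=int(rng.integers(2**31 - 1)), population_id=pop,
        )
        hatch_tables[pop] = table
        truths[f"hatch/{pop}"] = dataclasses.asdict(truth)
    lio.write_hatch_table(hatch_tables, OUT / "hatch.csv")

    # wing-model trials: one population with a real PC1 preference, the rest null
    for pop, gamma in [("BTB", (1.2, 0.0)), ("VIC", (0.0, 0.0)), ("HNV", (0.0, 0.0))]:
        scores, trials, truth = gen_wing_trials(
            n_trials=40, model_pool_size=21, gamma=gamma,
            seed=int(rng.integers(2**31 - 1)),
        )
        lio.write_model_scores(scores, OUT / f"wing_scores_{pop}.csv")
        lio.write_trials(trials, OUT / f"wing_trials_{pop}.csv")
        truths[f"wing_trials/{pop}"] = dataclasses.asdict(truth)

    # distance system: geography and one preference-like trait drive F
    sys_ = gen_distance_system(
        n_pops=10, b0=0.02, b_geo=5e-4, b_pheno=0.12, noise_sd=0.01,
        seed=int(rng.integers(2**31 - 1)), posterior_sd=0.05,
    )
    lio.write_distance_matrix(sys_.genetic, OUT / "genetic_F.csv")
    lio.write_distance_matrix(sys_.geographic, OUT / "geographic_km.csv")
    for name, D in sys_.phenotypic.items():
        lio.write_distance_matrix(D, OUT / f"phenotypic_{name}.csv")
    import pandas as pd

    pd.DataFrame(sys_.trait_posteriors["trait_1"]).to_csv(
        OUT / "trait_posterior_draws.csv", index=False)
    truths["distance_system"] = dataclasses.asdict(sys_.truth)

    (OUT / "truth.json").write_text(json.dumps(truths, indent=2))
    print(f"wrote synthetic inputs for {len(POPULATIONS)} populations to {OUT}/")


if __name__ == "__main__":
    main()
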