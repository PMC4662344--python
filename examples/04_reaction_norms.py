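"""Individual plasticity: within-subject centring and the random-regression
ladder.

Simulates repeat-breeding females whose laying dates respond to temperature
identically within and between individuals (beta_W = beta_B = -2), while
density acts only between individuals (beta_W = 0, beta_B = -1.5) — the
pattern in which a population trend is *not* mirrored by individual
plasticity. The ladder compares random structures (year, +farm, +female,
+female-by-environment slopes) by REML likelihood-ratio tests, and the
centring decomposition separates the two effect levels.
"""

import numpy as np

from phenoplast.pipeline import random_regression_ladder
from phenoplast.simulate import simulate_female_table

rng = np.random.default_rng(8)
table = simulate_female_table(
    rng,
    n_females=300,
    mean_obs=2.6,
    beta_within_temp=-2.0,
    beta_between_temp=-2.0,
    beta_within_dens=0.0,
    beta_between_dens=-1.5,
    sd_female=3.0,
    sd_resid=5.0,
)
print(
    f"{len(table)} observations on {table.female_id.nunique()} females "
    "(each observed in >= 2 years)\n"
)

ladder = random_regression_ladder(table)
print(ladder.table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"\nselected random structure: {ladder.final_key}")

for cov, dec in ladder.decomposition.items():
    print(
        f"\n{cov}: beta_W = {dec.beta_within:+.2f} +- {dec.se_within:.2f}, "
        f"beta_B = {dec.beta_between:+.2f}"
    )
    print(
        f"  equality test beta_B - beta_W = {dec.equality_estimate:+.2f} "
        f"+- {dec.equality_se:.2f} (p = {dec.equality_p:.3f})"
    )
print(
    "\nFor temperature the equality test is usually non-significant: true "
    "individual plasticity mirrors the population trend. For density the "
    "between-female estimate sits below the (null) within-female one, but "
    "with ~300 females the formal equality test has only ~50% power, so a "
    "single replicate may or may not reject; the test suite measures these "
    "rates over many replicates."
)
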