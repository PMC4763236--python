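#!/usr/bin/env python
"""Step 1: within-category Spearman screening of the 19 covariates.

Log-transforms richness, area and the positive covariates, removes the
county-area effect by OLS residualization, then prunes pairs with
|Spearman ρ| > 0.7 inside each hypothesis category, keeping the member
with more univariate deviance explained.  Writes one screening report
per region under results/screening/.
"""

import sys
from pathlib import Path

import numpy as np

from richdet import screening, synthetic as syn

DATA = Path("results/data")
if not DATA.exists():
    sys.exit("run analysis/01_generate_landscape.py first")
OUT = Path("results/screening")
OUT.mkdir(parents=True, exist_ok=True)

counties = syn.read_county_table(DATA / "counties.tsv")
env = syn.read_env_matrix(DATA / "env.tsv")
richness = np.loadtxt(DATA / "richness.tsv", skiprows=1, usecols=1)

for region in ("all", "EMR", "NAR", "QTR"):
    mask = np.ones(len(counties), bool) if region == "all" else (
        counties["stratum"] == region
    ).to_numpy()
    env_sub = syn.EnvMatrix(env.data.iloc[np.flatnonzero(mask)], env.categories, env.transforms)
    y = screening.residualize_on_area(
        np.log10(richness[mask]), np.log10(counties["area_km2"].to_numpy()[mask])
    )
    res = screening.screen_variables(env_sub, y)
    res.to_json(OUT / f"screening_{region}.json")
    n_dropped = len(res.dropped)
    print(
        f"{region:4s}: retained {len(res.retained_names):2d}/19 variables "
        f"({n_dropped} dropped for within-category |rho| > 0.7)"
    )
    for d in res.dropped:
        print(
            f"      dropped {d['dropped']} (kept {d['kept']}, "
            f"rho={d['spearman_rho']:+.2f})"
        )
print(f"reports written to {OUT}/")
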