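#!/usr/bin/env python
"""Step 2: bootstrap significance counting and top-6 selection per region.

Refits the Gaussian GLM on 1000 case resamples, counts per-variable
significance (p < 0.05) and keeps the six most frequently significant
predictors.  Writes per-region selection reports and a combined counts
table under results/selection/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from richdet import screening, selection, synthetic as syn

DATA = Path("results/data")
SCREEN = Path("results/screening")
if not SCREEN.exists():
    sys.exit("run analysis/02_screen_variables.py first")
OUT = Path("results/selection")
OUT.mkdir(parents=True, exist_ok=True)

counties = syn.read_county_table(DATA / "counties.tsv")
env = syn.read_env_matrix(DATA / "env.tsv")
richness = np.loadtxt(DATA / "richness.tsv", skiprows=1, usecols=1)

SEED = 0
for region in ("all", "EMR", "NAR", "QTR"):
    mask = np.ones(len(counties), bool) if region == "all" else (
        counties["stratum"] == region
    ).to_numpy()
    env_sub = syn.EnvMatrix(env.data.iloc[np.flatnonzero(mask)], env.categories, env.transforms)
    y = screening.residualize_on_area(
        np.log10(richness[mask]), np.log10(counties["area_km2"].to_numpy()[mask])
    )
    retained = json.loads((SCREEN / f"screening_{region}.json").read_text())["retained"]
    names = [v for cat in sorted(retained) for v in retained[cat]]
    x_scaled, _ = screening.log_transform(env_sub)
    rep = selection.bootstrap_significance(y, x_scaled[names], reps=1000, seed=SEED)
    top = selection.select_top_k(rep, k=6)
    rep.to_json(OUT / f"selection_{region}.json")
    rep.counts_table().to_csv(OUT / f"counts_{region}.tsv", sep="\t", index=False)
    print(f"{region:4s}: top-6 by significance count:")
    for v in top:
        print(f"      {v:40s} {rep.counts[v]:4d}/1000")
print(f"reports written to {OUT}/")
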