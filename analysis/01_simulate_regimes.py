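#!/usr/bin/env python
"""Forward-simulate the four selection regimes.

Sweeps the 40-locus antagonistic architecture over selection strengths
and regimes, recording mean selected-locus diversity, and profiles
neutral-site diversity against recombination distance to the selected
loci.  Findings: constant environments purge selected-locus diversity
(nearly completely for s >= 0.05), temporal fluctuation leaves it near
the neutral level, and the spatial soft-selection regime maintains it
far above neutral; linked neutral diversity is reduced near selected
loci only in the constant regimes.
"""

import argparse
from pathlib import Path

import pandas as pd

from evoregime.simulate import SimConfig, neutral_linkage_profile, run_simulation

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    rows = []
    for s in (0.02, 0.05, 0.07):
        for regime in ("spatial", "temporal", "constant_A", "constant_B", "neutral"):
            res = run_simulation(
                SimConfig(regime=regime, s=s, n_reps=args.reps, seed=args.seed)
            )
            summ = res.summary()
            rows.append(summ)
            print(f"s={s} {regime:11s} selected_pi={summ['selected_pi']:.4f} "
                  f"+-{summ['selected_pi_se']:.4f}", flush=True)
    pd.DataFrame(rows).to_csv(RESULTS / "selected_pi.tsv", sep="\t", index=False)

    prof = neutral_linkage_profile(0.05, n_reps=max(200, args.reps // 2), seed=args.seed)
    prof.to_csv(RESULTS / "neutral_linkage.tsv", sep="\t", index=False)
    wide = prof.pivot(index="log10_r", columns="regime", values="neutral_pi")
    print("\nneutral-site pi by log10(effective r):")
    print(wide.round(4).to_string())


if __name__ == "__main__":
    main()
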