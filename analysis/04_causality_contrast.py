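#!/usr/bin/env python
"""Probe the trait-specific-region causality contrast under known truths.

Scenario "causal": trait 1 drives trait 2 (every trait-1 effect leaks
into trait 2 at scale 0.15) — the contrast should read
consistent_T1_causes_T2.  Scenario "pleiotropy": the traits share every
causal effect symmetrically at borderline GWAS power — the contrast
should stay inconclusive.  50 replicates each on a 300-block genome.
"""

from pathlib import Path

import pandas as pd

from ddgen.experiments import causality_verdicts

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = [causality_verdicts(s, seed=1) for s in ("causal", "pleiotropy")]
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "causality_verdicts.tsv", sep="\t", index=False)
    for r in rows:
        print(f"{r['scenario']}: causal-direction verdict in "
              f"{100 * r['frac_consistent_T1_causes_T2']:.0f}%, inconclusive in "
              f"{100 * r['frac_inconclusive']:.0f}%, not tested in "
              f"{100 * r['frac_not_tested']:.0f}% of {r['n_reps']} replicates")
    print(f"wrote {OUT / 'causality_verdicts.tsv'}")


if __name__ == "__main__":
    main()
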