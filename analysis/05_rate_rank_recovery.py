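#!/usr/bin/env python
"""How reliably does the end-to-end pipeline recover the ordering of
per-branch variation rates?  Replicates the full pipeline on fresh
synthetic data (SNP rates peaking on the ingroup stem, inversion/deletion
rates peaking on the terminal branches) and scores, per variant class,
whether the estimated branch-rate rank order equals the generating one.

Writes results/rank_recovery.tsv.
"""

import os

import pandas as pd

from cichlidvar.pipeline import PipelineConfig, run_pipeline

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 42
N_REP = 20


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    classes = ("SNP", "INDEL", "INVERSION", "DELETION")
    successes = {c: 0 for c in classes if c != "INDEL"}
    rows = []
    for rep in range(N_REP):
        res = run_pipeline(PipelineConfig(seed=SEED * 1000 + rep))
        rates = res.rates
        lam_all = res.config.simulation.rates
        for cls in successes:
            sub = rates[(rates.var_class == cls) & (rates.branch != "Tilapia")]
            est = list(sub.sort_values("rate_per_my").branch)
            true = sorted(lam_all[cls], key=lambda b: lam_all[cls][b])
            ok = est == true
            successes[cls] += ok
            rows.append({"replicate": rep, "var_class": cls,
                         "rank_recovered": ok})
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(OUT, "rank_recovery.tsv"), sep="\t", index=False)
    for cls, n_ok in successes.items():
        print(f"{cls}: rank order recovered in {n_ok}/{N_REP} replicates")
    print("(indel rates are uniform across branches by design, "
          "so their ordering is not scored)")


if __name__ == "__main__":
    main()
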