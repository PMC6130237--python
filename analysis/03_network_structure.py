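#!/usr/bin/env python
"""Network-level structure of the pooled and per-habitat webs.

Computes size, web asymmetry, interaction-strength asymmetry,
specialization asymmetry and interaction Shannon diversity for the pooled
web and every habitat sub-network (forest transects merged), then tests
NODF nestedness of each against 1,000 Ce null-model draws.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from flowerweb import (
    from_records,
    merge_networks,
    nestedness_test,
    network_metrics,
    read_records,
    summarize_significance,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "network"
SEED = 42
N_NULL = 1000


def main() -> None:
    webs = from_records(read_records(ROOT / "data" / "records.tsv"))
    webs["FOR"] = merge_networks([webs.pop("FOR-Y"), webs.pop("FOR-O")], "FOR")
    pooled = merge_networks(list(webs.values()), "pooled")
    ordered = [pooled] + [webs[h] for h in sorted(webs)]

    metrics = pd.DataFrame([network_metrics(M).to_row() for M in ordered])

    rng = np.random.default_rng(SEED)
    results = [
        nestedness_test(M, n_null=N_NULL, seed=int(rng.integers(2**31)))
        for M in ordered
    ]
    nest = summarize_significance(results, alpha=0.01)

    OUT.mkdir(parents=True, exist_ok=True)
    metrics.round(3).to_csv(OUT / "network_metrics.tsv", sep="\t", index=False)
    nest.round(3).to_csv(OUT / "nestedness.tsv", sep="\t", index=False)

    print("network-level metrics (pooled first):")
    print(metrics.round(3).to_string(index=False))
    print(f"\nNODF nestedness vs Ce null model ({N_NULL} draws, alpha = 0.01):")
    print(nest.round(3).to_string(index=False))
    n_sig = int(nest["nested"].sum())
    print(f"\n{n_sig} of {len(nest)} webs are significantly nested; "
          "abundance-product sampling makes nestedness the expected outcome")
    print(f"wrote tables to {OUT}/")


if __name__ == "__main__":
    main()
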