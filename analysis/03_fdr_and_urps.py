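#!/usr/bin/env python
"""FDR filtering and aggregation to unique residue pairs.

Reads the CSM table of the default run, applies the 1% CSM-level
target-decoy filter, aggregates to URPs, recomputes a residue-pair-level
q-value on best scores, and reports the counts at each stage.
"""

from pathlib import Path

import pandas as pd

from xlmsbench.validation import (
    aggregate_urps,
    compute_qvalues,
    filter_at_fdr,
    urp_level_qvalues,
)

RUN = Path(__file__).resolve().parents[1] / "results" / "run_default"


def main() -> None:
    csms = pd.read_csv(RUN / "csms_all.csv")
    csms = compute_qvalues(csms)
    for alpha in (0.05, 0.01):
        kept = filter_at_fdr(csms, alpha)
        print(f"alpha={alpha}: {len(kept)} CSMs")
    filtered = filter_at_fdr(csms, 0.01)
    urps = aggregate_urps(filtered)
    print(f"1% FDR: {len(filtered)} CSMs -> {len(urps)} URPs "
          f"({len(filtered) / len(urps):.2f} CSMs per URP)")
    # residue-pair level control uses the unfiltered table (decoys kept)
    urps_all = aggregate_urps(compute_qvalues(csms), exclude_self_links=True)
    urps_q = urp_level_qvalues(urps_all)
    n_pair_level = ((urps_q["q_value"] <= 0.01)
                    & (urps_q["td_class"] == "TT")).sum()
    print(f"residue-pair-level 1% FDR: {n_pair_level} URPs")
    urps.to_csv(RUN / "urps_recomputed.csv", index=False)


if __name__ == "__main__":
    main()
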