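#!/usr/bin/env python
"""Structural distance analysis of the reported residue pairs.

Maps the FDR-filtered residue pairs of the default run onto the Calpha
structure, reports the proportion within the 20 A linker limit per
abundance class, writes the distance histogram and the per-link export
CSV used for circle-plot tools.
"""

import json
from pathlib import Path

import pandas as pd

from xlmsbench.structure_analysis import (
    distance_histogram,
    export_links_csv,
    proportion_within,
    read_pdb,
)
from xlmsbench.validation import aggregate_urps

RUN = Path(__file__).resolve().parents[1] / "results" / "run_default"


def main() -> None:
    structure = read_pdb(str(RUN / "structure.pdb"))
    ann = pd.read_csv(RUN / "csms_annotated.csv")
    pairs = aggregate_urps(ann)
    cls = ann.groupby(["protein_a", "pos_a", "protein_b", "pos_b"])[
        "abundance_class"].first().rename("abundance_class").reset_index()
    pairs = pairs.merge(cls, on=["protein_a", "pos_a", "protein_b",
                                 "pos_b"], how="left")
    summary = proportion_within(pairs, structure, cutoff=20.0,
                                by="abundance_class")
    print(f"{len(pairs)} residue pairs on a {len(structure)}-residue "
          f"structure ({summary['n_unmappable']} unmappable)")
    print(f"proportion within 20 A: overall {summary['overall']:.3f}")
    for label in ("low", "medium", "high"):
        if label in summary and summary[label] is not None:
            print(f"  {label:>6}: {summary[label]:.3f}")
    hist = distance_histogram(pairs, structure, bin_width=5.0)
    (RUN / "distance_histogram.json").write_text(
        json.dumps({str(k * 5.0): v for k, v in sorted(hist.items())},
                   indent=2))
    export_links_csv(pairs, structure, str(RUN / "links_export.csv"))
    print(f"-> {RUN / 'links_export.csv'}")


if __name__ == "__main__":
    main()
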