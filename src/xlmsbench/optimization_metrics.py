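"""FAIMS CV-combination selection and acquisition/identification metrics.

Given per-CV sets of identified residue pairs, the exact UpSet partition
(region signature -> count) drives three selection criteria for CV
triplets: maximal crosslink yield with minimal redundancy, minimal total
overlap, and maximal common core.  The benchmark report computes the
standard run-level metrics: URP and CSM counts, CSMs per URP,
identifications per gradient minute, identified/acquired MS1 and MS2
ratios, mean cycle time, and replicate dispersion as the mean absolute
distance of replicates from their mean (the convention used for the error
bars this report emulates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SetFamily = Mapping[Hashable, set]


def upset_regions(sets: SetFamily) -> dict[tuple, int]:
    """Exact UpSet partition: every element of the union is counted once
    under the signature (sorted tuple of keys) of all sets containing it;
    counts therefore sum to the union size."""
    keys = sorted(sets, key=str)
    out: dict[tuple, int] = {}
    union = set().union(*sets.values()) if sets else set()
    for el in union:
        sig = tuple(k for k in keys if el in sets[k])
        out[sig] = out.get(sig, 0) + 1
    return out


@dataclass(frozen=True)
class CvCombination:
    keys: tuple
    union_size: int
    pairwise_overlap: int  # sum of |A∩B| over unordered pairs
    common_size: int  # k-way intersection


def _stats(sets: SetFamily, combo: tuple) -> CvCombination:
    members = [sets[k] for k in combo]
    union = set().union(*members)
    pairwise = sum(len(a & b) for a, b in combinations(members, 2))
    common = set(members[0]).intersection(*members[1:])
    return CvCombination(combo, len(union), pairwise, len(common))


def select_cv_combinations(sets: SetFamily, k: int = 3
                           ) -> dict[str, CvCombination]:
    """Best CV k-subset under each of three criteria.

    * ``max_yield_min_overlap`` — largest union, pairwise overlap as
      tie-break (ascending);
    * ``min_total_overlap`` — smallest summed pairwise intersections;
    * ``max_common`` — largest k-way intersection.

    All k-subsets are enumerated exhaustively; every returned combination
    carries all three statistics so users can re-rank.
    """
    keys = sorted(sets, key=str)
    if len(keys) < k:
        raise ValueError(f"need at least {k} sets, got {len(keys)}")
    combos = [_stats(sets, c) for c in combinations(keys, k)]
    by_yield = min(combos,
                   key=lambda c: (-c.union_size, c.pairwise_overlap, c.keys))
    by_overlap = min(combos, key=lambda c: (c.pairwise_overlap,
                                            -c.union_size, c.keys))
    by_common = min(combos, key=lambda c: (-c.common_size, c.keys))
    return {"max_yield_min_overlap": by_yield,
            "min_total_overlap": by_overlap,
            "max_common": by_common}


def _round_half_away(x: float, digits: int = 0) -> float:
    scale = 10.0 ** digits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def percent_increase(a: float, b: float) -> float:
    """(a - b) / b * 100 at one decimal (half away from zero)."""
    if b == 0:
        raise ValueError("baseline must be non-zero")
    return _round_half_away((a - b) / b * 100.0, 1)


def percent_increase_int(a: float, b: float) -> int:
    """Integer-rounded variant of :func:`percent_increase`."""
    if b == 0:
        raise ValueError("baseline must be non-zero")
    return int(_round_half_away((a - b) / b * 100.0, 0))


def venn_fractions(set_a: set, set_b: set,
                   digits: int = 0) -> tuple[float, float, float]:
    """(unique-to-A%, shared%, unique-to-B%) of the union size."""
    union = set_a | set_b
    if not union:
        raise ValueError("both sets empty")
    n = len(union)
    return tuple(_round_half_away(100.0 * x / n, digits) for x in
                 (len(set_a - set_b), len(set_a & set_b),
                  len(set_b - set_a)))


def mean_absolute_dispersion(values: Sequence[float]) -> float:
    """Replicate dispersion: mean absolute distance from the mean."""
    arr = np.asarray(values, float)
    return float(np.mean(np.abs(arr - arr.mean())))


REPORT_COLUMNS = ["run", "n_urps", "n_csms", "csms_per_urp",
                  "urps_per_minute", "csms_per_minute",
                  "n_ms1", "n_ms2", "ms1_id_ratio", "ms2_id_ratio",
                  "mean_cycle_time"]


def run_metrics(run: str, csms: pd.DataFrame, urps: pd.DataFrame,
                acquisition_log: pd.DataFrame,
                gradient_minutes: float) -> dict:
    """Per-run benchmark metrics from a filtered CSM table, its URP table
    and the acquisition log.

    The identified/acquired MS1 ratio counts survey scans during which at
    least one identified precursor was selected; the MS2 ratio counts
    fragment scans whose scan id appears in the identified CSM table.
    """
    if gradient_minutes <= 0:
        raise ValueError("gradient_minutes must be positive")
    ms1 = acquisition_log[acquisition_log["type"] == "MS1"]
    ms2 = acquisition_log[acquisition_log["type"] == "MS2"]
    id_scans = set(csms["scan_id"])
    n_ms2_id = int(ms2["scan_id"].isin(id_scans).sum())
    # MS1 scans credited with an identification: the survey scan directly
    # preceding an identified MS2 (same cycle)
    ms1_times = ms1["time"].to_numpy()
    id_times = ms2[ms2["scan_id"].isin(id_scans)]["time"].unique()
    n_ms1_id = int(pd.Series(id_times).isin(set(ms1_times)).sum())
    times = ms1_times
    cycle = float(np.mean(np.diff(np.sort(np.unique(times))))) \
        if len(times) > 1 else float("nan")
    n_urps, n_csms = len(urps), len(csms)
    return dict(
        run=run, n_urps=n_urps, n_csms=n_csms,
        csms_per_urp=n_csms / n_urps if n_urps else float("nan"),
        urps_per_minute=n_urps / gradient_minutes,
        csms_per_minute=n_csms / gradient_minutes,
        n_ms1=len(ms1), n_ms2=len(ms2),
        ms1_id_ratio=n_ms1_id / len(ms1) if len(ms1) else float("nan"),
        ms2_id_ratio=n_ms2_id / len(ms2) if len(ms2) else float("nan"),
        mean_cycle_time=cycle)


def benchmark_report(runs: Iterable[dict]) -> pd.DataFrame:
    """Tabulate per-run metrics (rows from :func:`run_metrics`) and append
    a replicate-mean row with mean-absolute-deviation dispersion columns."""
    df = pd.DataFrame(list(runs), columns=REPORT_COLUMNS)
    if len(df) > 1:
        numeric = df.select_dtypes("number")
        mean_row = {"run": "mean", **numeric.mean().to_dict()}
        disp_row = {"run": "dispersion",
                    **{c: mean_absolute_dispersion(numeric[c])
                       for c in numeric.columns}}
        df = pd.concat([df, pd.DataFrame([mean_row, disp_row])],
                       ignore_index=True)
    return df
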