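"""MS1 feature detection and feature-to-CSM matching.

A feature is a precursor trace over consecutive survey scans at one FAIMS
CV.  Features are matched to crosslink identifications under the criteria:
same compensation voltage, same charge, m/z within 0.01 (absolute, Th),
retention-time difference minimized.  Matched CSMs inherit ``rt_diff``,
``intensityApex`` and ``intensitySum`` and are binned into the abundance
classes low (<1e5), medium (1e5 to 1e7, inclusive) and high (>1e7).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_data import FEATURE_COLUMNS, MS1Scan

ABUNDANCE_BOUNDS = (1e5, 1e7)


def classify_abundance(intensity_apex: float) -> str:
    """low / medium / high precursor abundance class; the medium interval
    is closed on both ends."""
    if not intensity_apex > 0:
        raise ValueError("intensityApex must be positive")
    lo, hi = ABUNDANCE_BOUNDS
    if intensity_apex < lo:
        return "low"
    if intensity_apex <= hi:
        return "medium"
    return "high"


def detect_features(ms1_scans: list[MS1Scan], ppm_tol: float = 10.0,
                    min_scans: int = 1) -> pd.DataFrame:
    """Greedy centroid linking across consecutive same-CV survey scans.

    A centroid extends an open trace from the immediately preceding scan of
    the same CV when within ``ppm_tol`` (and, if charge is annotated, with
    equal charge); otherwise it opens a new trace.  A trace's apex is its
    maximum-intensity scan; ``intensitySum`` accumulates all member scans.
    Traces shorter than ``min_scans`` are dropped (the default keeps
    single-scan features).
    """
    rows: list[dict] = []

    def close(trace: dict) -> None:
        if trace["n"] < min_scans:
            return
        rows.append(dict(
            feature_id=f"D{len(rows):05d}",
            mz=trace["mz_sum"] / trace["n"], charge=trace["charge"],
            cv=trace["cv"], rt_apex=trace["apex_rt"],
            rt_start=trace["rt0"], rt_end=trace["rt1"],
            intensityApex=trace["apex_int"], intensitySum=trace["int_sum"],
            n_scans=trace["n"], source="detected",
            link_id=trace["truth"]))

    by_cv: dict[float, list[MS1Scan]] = {}
    for scan in ms1_scans:
        by_cv.setdefault(scan.cv, []).append(scan)
    for cv, scans in by_cv.items():
        open_traces: list[dict] = []
        for scan in sorted(scans, key=lambda s: s.time):
            rt = scan.time / 60.0
            nxt: list[dict] = []
            used = np.zeros(len(scan.mz), bool)
            order = np.argsort([t["last_mz"] for t in open_traces])
            for ti in order:
                tr = open_traces[ti]
                tol = tr["last_mz"] * ppm_tol * 1e-6
                best, best_d = -1, np.inf
                for ci in range(len(scan.mz)):
                    if used[ci]:
                        continue
                    if len(scan.charge) and scan.charge[ci] != tr["charge"]:
                        continue
                    d = abs(scan.mz[ci] - tr["last_mz"])
                    if d <= tol and d < best_d:
                        best, best_d = ci, d
                if best >= 0:
                    used[best] = True
                    inten = float(scan.intensity[best])
                    tr["n"] += 1
                    tr["mz_sum"] += float(scan.mz[best])
                    tr["last_mz"] = float(scan.mz[best])
                    tr["int_sum"] += inten
                    tr["rt1"] = rt
                    if inten > tr["apex_int"]:
                        tr["apex_int"], tr["apex_rt"] = inten, rt
                    nxt.append(tr)
                else:
                    close(tr)
            for ci in range(len(scan.mz)):
                if used[ci]:
                    continue
                truth = scan.feature_ids[ci] if ci < len(scan.feature_ids) \
                    else "noise"
                nxt.append(dict(
                    n=1, mz_sum=float(scan.mz[ci]),
                    last_mz=float(scan.mz[ci]),
                    charge=int(scan.charge[ci]) if len(scan.charge) else 0,
                    cv=cv, int_sum=float(scan.intensity[ci]),
                    apex_int=float(scan.intensity[ci]), apex_rt=rt,
                    rt0=rt, rt1=rt, truth=truth))
            open_traces = nxt
        for tr in open_traces:
            close(tr)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def match_features_to_csms(features: pd.DataFrame, csms: pd.DataFrame,
                           mz_tol: float = 0.01,
                           rt_shift: float | None = None
                           ) -> tuple[pd.DataFrame, float]:
    """Assign at most one MS1 feature to each CSM.

    Candidates must match CV and charge exactly and m/z within ``mz_tol``
    Th; among candidates the one minimizing |rt_apex - (csm.rt - shift)| is
    assigned (rt ties go to the higher apex intensity).  When ``rt_shift``
    is None a global alignment offset is estimated as the median
    (csm.rt - feature.rt_apex) over first-pass matches and applied in a
    second pass.  Returns (annotated CSMs, applied shift); unmatched CSMs
    keep NaN annotations and ``feature_matched=False``.
    """

    def run(shift: float) -> pd.DataFrame:
        out = csms.copy()
        out["feature_id"] = ""
        out["rt_diff"] = np.nan
        out["intensityApex"] = np.nan
        out["intensitySum"] = np.nan
        out["feature_matched"] = False
        if len(features) == 0 or len(out) == 0:
            return out
        fmz = features["mz"].to_numpy()
        forder = np.argsort(fmz)
        fmz_sorted = fmz[forder]
        for i in out.index:
            mz, z, cv, rt = (out.at[i, "precursor_mz"], out.at[i, "charge"],
                             out.at[i, "cv"], out.at[i, "rt"])
            lo = np.searchsorted(fmz_sorted, mz - mz_tol, side="left")
            hi = np.searchsorted(fmz_sorted, mz + mz_tol, side="right")
            best = None
            for k in forder[lo:hi]:
                frow = features.iloc[k]
                if frow["charge"] != z or frow["cv"] != cv:
                    continue
                dt = abs(frow["rt_apex"] - (rt - shift))
                rank = (dt, -frow["intensityApex"])
                if best is None or rank < best[0]:
                    best = (rank, k, dt)
            if best is not None:
                _, k, dt = best
                frow = features.iloc[k]
                out.at[i, "feature_id"] = frow["feature_id"]
                out.at[i, "rt_diff"] = dt
                out.at[i, "intensityApex"] = frow["intensityApex"]
                out.at[i, "intensitySum"] = frow["intensitySum"]
                out.at[i, "feature_matched"] = True
        return out

    if rt_shift is None:
        first = run(0.0)
        matched = first[first["feature_matched"]]
        if len(matched) >= 5:
            fid = features.set_index("feature_id")
            deltas = [row["rt"] - fid.at[row["feature_id"], "rt_apex"]
                      for _, row in matched.iterrows()]
            rt_shift = float(np.median(deltas))
        else:
            rt_shift = 0.0
    annotated = run(rt_shift)
    cls = []
    for apex in annotated["intensityApex"]:
        cls.append(classify_abundance(apex) if apex > 0 else "")
    annotated["abundance_class"] = cls
    return annotated, rt_shift
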