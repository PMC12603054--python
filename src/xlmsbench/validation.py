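"""Target-decoy FDR estimation and aggregation to unique residue pairs.

CSMs are classified TT/TD/DD by the target/decoy status of their two
constituent peptides.  A decoy peptide models a false match, so at a given
score threshold the expected number of false TT matches is estimated by
(#TD - #DD): each TD carries one decoy hit, each DD two, and DD pairs are
subtracted to avoid double-counting the decoy background.  q-values are
the usual running minimum of the estimated FDR along the score ranking.
The same estimator is reused at the residue-pair (URP) level on best
scores per pair.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def compute_qvalues(csms: pd.DataFrame, score_col: str = "score",
                    class_col: str = "td_class") -> pd.DataFrame:
    """Add a ``q_value`` column from the target-decoy score ranking.

    At each threshold (walking down the score-sorted list)
    ``FDR_est = max(0, #TD - #DD) / max(1, #TT)``; the q-value is the
    running minimum of FDR_est from the bottom of the list, so it is
    monotone non-decreasing as the score decreases.  With zero TT CSMs all
    q-values are 1.
    """
    out = csms.copy()
    if len(out) == 0:
        out["q_value"] = pd.Series(dtype=float)
        return out
    order = np.lexsort((np.arange(len(out)), -out[score_col].to_numpy()))
    cls = out[class_col].to_numpy()[order]
    n_tt = np.cumsum(cls == "TT")
    n_td = np.cumsum(cls == "TD")
    n_dd = np.cumsum(cls == "DD")
    if n_tt[-1] == 0:
        out["q_value"] = 1.0
        return out
    fdr = np.maximum(0, n_td - n_dd) / np.maximum(1, n_tt)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    qcol = np.empty(len(out))
    qcol[order] = q
    out["q_value"] = qcol
    return out


def filter_at_fdr(csms: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Reported set: TT CSMs with q <= alpha (decoys never reported)."""
    if "q_value" not in csms.columns:
        csms = compute_qvalues(csms)
    return csms[(csms["td_class"] == "TT")
                & (csms["q_value"] <= alpha)].copy()


URP_COLUMNS = ["protein_a", "pos_a", "protein_b", "pos_b", "n_csms",
               "best_score", "td_class"]


def aggregate_urps(csms: pd.DataFrame,
                   exclude_self_links: bool = True) -> pd.DataFrame:
    """Collapse CSMs to unique residue pairs in protein coordinates.

    Input rows need ``protein_a/pos_a/protein_b/pos_b`` (already canonical:
    (protein, pos) lexicographically ordered, so swapped duplicates and
    missed-cleavage variants of the same link collapse together).
    ``n_csms`` counts supporting CSMs, ``best_score`` is their maximum.
    """
    if len(csms) == 0:
        return pd.DataFrame(columns=URP_COLUMNS)
    df = csms.copy()
    # canonicalize defensively: order the two (protein, pos) keys
    a = list(zip(df["protein_a"], df["pos_a"]))
    b = list(zip(df["protein_b"], df["pos_b"]))
    swap = [ka > kb for ka, kb in zip(a, b)]
    for col_a, col_b in (("protein_a", "protein_b"), ("pos_a", "pos_b")):
        va, vb = df[col_a].to_numpy().copy(), df[col_b].to_numpy().copy()
        va[swap], vb[swap] = df[col_b].to_numpy()[swap], \
            df[col_a].to_numpy()[swap]
        df[col_a], df[col_b] = va, vb
    if exclude_self_links:
        df = df[~((df["protein_a"] == df["protein_b"])
                  & (df["pos_a"] == df["pos_b"]))]
    if len(df) == 0:
        return pd.DataFrame(columns=URP_COLUMNS)
    grouped = df.groupby(["protein_a", "pos_a", "protein_b", "pos_b"],
                         sort=True)
    out = grouped.agg(n_csms=("score", "size"),
                      best_score=("score", "max")).reset_index()
    # class of the best-scoring supporting CSM (used for URP-level FDR)
    best_cls = []
    for _, grp in grouped:
        best_cls.append(grp.loc[grp["score"].idxmax(), "td_class"]
                        if "td_class" in grp.columns else "TT")
    out["td_class"] = best_cls
    return out[URP_COLUMNS]


def entrapment_simulation(n_true: int = 500, n_false: int = 1500,
                          seed: int = 0) -> pd.DataFrame:
    """Synthetic CSM table for FDR calibration.

    ``n_true`` genuine TT matches score well above ``n_false`` chance
    matches.  A chance match pairs two peptides drawn independently from a
    1:1 target/decoy database, so its class is TT/TD/DD with probability
    1/4, 1/2, 1/4 and its score is class-independent — exactly the
    exchangeability assumption behind the (TD - DD)/TT estimator.  The
    ``is_true_hit`` column lets callers measure the realized false
    discovery proportion of any filter.
    """
    rng = np.random.default_rng(seed)
    true_scores = 60.0 + 8.0 * rng.standard_normal(n_true)
    null_scores = rng.exponential(8.0, n_false)
    null_cls = rng.choice(["TT", "TD", "DD"], n_false, p=[0.25, 0.5, 0.25])
    return pd.DataFrame(dict(
        score=np.concatenate([true_scores, null_scores]),
        td_class=np.concatenate([np.full(n_true, "TT"), null_cls]),
        is_true_hit=np.concatenate([np.ones(n_true, bool),
                                    np.zeros(n_false, bool)])))


def realized_fdp(filtered: pd.DataFrame) -> float:
    """Observed false-discovery proportion of a reported set carrying an
    ``is_true_hit`` truth column (0 for an empty set)."""
    if len(filtered) == 0:
        return 0.0
    return float((~filtered["is_true_hit"]).mean())


def urp_level_qvalues(urps: pd.DataFrame) -> pd.DataFrame:
    """Residue-pair-level FDR: the CSM estimator applied to URP best
    scores.  Call on URPs aggregated from *unfiltered* CSMs (targets and
    decoys) for a meaningful decoy background."""
    return compute_qvalues(urps, score_col="best_score")
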