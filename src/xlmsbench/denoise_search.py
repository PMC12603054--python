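"""Two-pass crosslink identification with adaptive spectrum de-noising.

The workflow mirrors the standard crosslink search cascade: precursor/
fragment recalibration from confident linear identifications, a linear
first pass that removes spectra confidently explained by a linear (or
monolinked) peptide, then a crosslink search over mass-matched peptide
pairs.  Spectra are de-noised adaptively: within every 100 Da window the
top ``m`` most intense peaks are kept, all values m = 1..10 are tried, and
the m yielding the highest match score wins.  Scoring uses a cumulative
binomial tail (bits-like, -10*log10 of the chance probability of matching
at least k of n theoretical ions); the published engines' exact score is
proprietary, so ranks — not absolute score values — carry all downstream
decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import binom

from .xl_core import (
    CrosslinkCandidate,
    CrosslinkerSpec,
    MassConfig,
    Peptide,
    enumerate_candidates,
    format_crosslink_notation,
    fragment_ions,
    linear_fragment_mzs,
    peptide_mass,
)


@dataclass
class Spectrum:
    """Centroided fragment spectrum with its FAIMS compensation voltage."""

    scan_id: int
    precursor_mz: float
    precursor_charge: int
    rt: float  # minutes
    cv: float
    mz: np.ndarray
    intensity: np.ndarray
    truth_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, float)
        self.intensity = np.asarray(self.intensity, float)
        if len(self.mz) > 1 and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def peak_count(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class DenoiseConfig:
    window_width: float = 100.0  # Da
    m_range: tuple[int, int] = (1, 10)  # inclusive
    fragment_tol_ppm: float = 10.0
    precursor_tol_ppm: float = 10.0
    fragment_charges: tuple[int, ...] = (1, 2)
    #: linear PSMs at or below this q-value are "highly confident" and
    #: their spectra are dropped before the crosslink search
    linear_q_threshold: float = 0.01
    doublet_prefilter: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.m_range
        if not (1 <= lo <= hi <= 10):
            raise ValueError("m_range must lie within [1, 10]")
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")


@dataclass
class CSM:
    """One spectrum matched to a crosslinked peptide pair."""

    scan_id: int
    candidate: CrosslinkCandidate
    score: float
    chosen_m: int
    td_class: str
    precursor_charge: int
    rt: float
    cv: float
    precursor_mz: float
    q_value: float = float("nan")
    rt_diff: float = float("nan")
    intensityApex: float = float("nan")
    intensitySum: float = float("nan")
    truth_id: str = ""


# ---------------------------------------------------------------------------
# de-noising

def pick_peaks(spectrum: Spectrum, m: int,
               window_width: float = 100.0) -> Spectrum:
    """Keep the ``m`` most intense peaks per half-open 100 Da window
    [k*w, (k+1)*w); intensity ties keep the lower m/z peak.  Peak order
    (by m/z) is preserved, so the operation is idempotent."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if spectrum.peak_count() == 0:
        return spectrum
    win = np.floor(spectrum.mz / window_width).astype(np.int64)
    keep = np.zeros(len(win), bool)
    start = 0
    n = len(win)
    while start < n:
        end = start
        while end < n and win[end] == win[start]:
            end += 1
        if end - start <= m:
            keep[start:end] = True
        else:
            sub = np.arange(start, end)
            # sort by intensity desc, then m/z asc (mz already ascending and
            # argsort is stable, so stable sort on -intensity suffices)
            order = sub[np.argsort(-spectrum.intensity[sub], kind="stable")]
            keep[order[:m]] = True
        start = end
    return replace(spectrum, mz=spectrum.mz[keep],
                   intensity=spectrum.intensity[keep])


# ---------------------------------------------------------------------------
# scoring

def match_count(peak_mz: np.ndarray, theoretical_mz: np.ndarray,
                tol_ppm: float) -> int:
    """Number of theoretical ions with at least one observed peak within
    the ppm tolerance (each ion counted once)."""
    if len(peak_mz) == 0 or len(theoretical_mz) == 0:
        return 0
    tol = theoretical_mz * tol_ppm * 1e-6
    lo = np.searchsorted(peak_mz, theoretical_mz - tol, side="left")
    hi = np.searchsorted(peak_mz, theoretical_mz + tol, side="right")
    return int(np.count_nonzero(hi > lo))


def score_csm(spectrum: Spectrum, theoretical_mz: np.ndarray,
              tol_ppm: float) -> float:
    """Binomial-tail match score in decibans.

    With n theoretical ions, k of which find a peak within tolerance, and a
    per-ion chance-match probability p = 2 * tol * n_peaks / span (capped
    at 0.5), the score is -10*log10 P(X >= k), X ~ Binomial(n, p).  Zero
    matches (or an empty spectrum) score 0; the score is monotone in k.
    """
    n = len(theoretical_mz)
    if n == 0 or spectrum.peak_count() == 0:
        return 0.0
    k = match_count(spectrum.mz, np.sort(theoretical_mz), tol_ppm)
    if k == 0:
        return 0.0
    span = float(spectrum.mz[-1] - spectrum.mz[0])
    if span <= 0:
        span = 1.0
    tol_da = float(np.mean(theoretical_mz)) * tol_ppm * 1e-6
    p = min(0.5, 2.0 * tol_da * spectrum.peak_count() / span)
    p = max(p, 1e-12)
    return _binom_tail_score(k, n, p)


def _window_ranks(spectrum: Spectrum, window_width: float) -> np.ndarray:
    """0-based intensity rank of each peak within its 100 Da window
    (ties resolved toward lower m/z); a peak survives de-noising at m iff
    its rank is < m, which reproduces :func:`pick_peaks` exactly."""
    win = np.floor(spectrum.mz / window_width).astype(np.int64)
    ranks = np.empty(len(win), np.int64)
    start, n = 0, len(win)
    while start < n:
        end = start
        while end < n and win[end] == win[start]:
            end += 1
        sub = np.arange(start, end)
        order = sub[np.argsort(-spectrum.intensity[sub], kind="stable")]
        ranks[order] = np.arange(end - start)
        start = end
    return ranks


def _binom_tail_score(k: int, n: int, p: float) -> float:
    """-10*log10 P(X >= k), X ~ Binomial(n, p), via the regularized
    incomplete beta function (falls back to scipy's logsf on underflow)."""
    if k <= 0:
        return 0.0
    from scipy.special import betainc
    sf = float(betainc(k, n - k + 1, p)) if k <= n else 0.0
    if sf > 0.0:
        return max(0.0, -10.0 * np.log10(sf))
    return float(max(0.0, -10.0 * binom.logsf(k - 1, n, p) / np.log(10.0)))


def adaptive_denoise_score(spectrum: Spectrum,
                           theoretical_mz: np.ndarray,
                           cfg: DenoiseConfig,
                           _ranks: np.ndarray | None = None
                           ) -> tuple[float, int]:
    """Best (score, m) over m in ``cfg.m_range`` of scoring the spectrum
    de-noised at m; ties go to the smaller m.

    Equivalent to looping ``score_csm(pick_peaks(spectrum, m), ...)`` but
    shares the per-window intensity ranking across the m sweep.
    """
    theoretical_mz = np.sort(np.asarray(theoretical_mz, float))
    n = len(theoretical_mz)
    best_score, best_m = 0.0, cfg.m_range[0]
    if n == 0 or spectrum.peak_count() == 0:
        return best_score, best_m
    ranks = _ranks if _ranks is not None \
        else _window_ranks(spectrum, cfg.window_width)
    tol = theoretical_mz * cfg.fragment_tol_ppm * 1e-6
    tol_da = float(np.mean(theoretical_mz)) * cfg.fragment_tol_ppm * 1e-6
    for m in range(cfg.m_range[0], cfg.m_range[1] + 1):
        mz = spectrum.mz[ranks < m]
        if len(mz) == 0:
            continue
        lo = np.searchsorted(mz, theoretical_mz - tol, side="left")
        hi = np.searchsorted(mz, theoretical_mz + tol, side="right")
        k = int(np.count_nonzero(hi > lo))
        if k == 0:
            continue
        span = float(mz[-1] - mz[0]) if mz[-1] > mz[0] else 1.0
        p = max(min(0.5, 2.0 * tol_da * len(mz) / span), 1e-12)
        s = _binom_tail_score(k, n, p)
        if s > best_score:
            best_score, best_m = s, m
    return best_score, best_m


def candidate_ion_mzs(candidate: CrosslinkCandidate,
                      linker: CrosslinkerSpec,
                      charges: tuple[int, ...],
                      mass_cfg: MassConfig) -> np.ndarray:
    return np.sort(np.array([f.mz for f in fragment_ions(
        candidate, linker, charges, mass_cfg)]))


# ---------------------------------------------------------------------------
# doublet detection (cleavable linkers)

def detect_doublets(spectrum: Spectrum, delta: float,
                    charges: tuple[int, ...] = (1, 2),
                    tol_ppm: float = 10.0) -> list[tuple[int, int, int]]:
    """Peak-index pairs (i, j, z) with mz_j - mz_i equal to delta/z within
    tolerance — the diagnostic doublet of a gas-phase-cleavable linker.
    Each (i, j) pair is reported once, with the smallest matching charge.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    mz = spectrum.mz
    out: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int]] = set()
    for z in sorted(charges):
        step = delta / z
        targets = mz + step
        tol = targets * tol_ppm * 1e-6
        lo = np.searchsorted(mz, targets - tol, side="left")
        hi = np.searchsorted(mz, targets + tol, side="right")
        for i in range(len(mz)):
            for j in range(lo[i], hi[i]):
                if j == i:
                    continue
                key = (i, j)
                if key not in seen:
                    seen.add(key)
                    out.append((i, j, z))
    return sorted(out)


# ---------------------------------------------------------------------------
# recalibration

def recalibrate(spectra: list[Spectrum],
                confident_psm_errors: list[float] | np.ndarray,
                min_calibrants: int = 5) -> tuple[list[Spectrum], float]:
    """Subtract the median ppm mass error (from confident linear PSMs) from
    every precursor and fragment m/z.  Fewer than ``min_calibrants``
    calibrants -> identity.  Returns (spectra, applied ppm shift)."""
    errors = np.asarray(confident_psm_errors, float)
    if len(errors) < min_calibrants:
        return spectra, 0.0
    med = float(np.median(errors))
    factor = 1.0 / (1.0 + med * 1e-6)
    out = [replace(s, mz=s.mz * factor,
                   precursor_mz=s.precursor_mz * factor)
           for s in spectra]
    return out, med


# ---------------------------------------------------------------------------
# linear first pass

def _neutral_mass(spectrum: Spectrum, mass_cfg: MassConfig) -> float:
    z = spectrum.precursor_charge
    return (spectrum.precursor_mz - mass_cfg.proton_mass) * z


def linear_first_pass(spectra: list[Spectrum], peptides: list[Peptide],
                      cfg: DenoiseConfig,
                      monolink_mass: float | None = None,
                      mass_cfg: MassConfig | None = None
                      ) -> tuple[pd.DataFrame, list[Spectrum]]:
    """Score every spectrum against linear (and monolinked) peptides and
    remove spectra with a highly confident linear identification.

    Confidence is a target-decoy q-value over the linear PSMs at
    ``cfg.linear_q_threshold``; pass ``float('inf')`` as the threshold via
    config to disable filtering.  Returns (linear PSM table, surviving
    spectra for the crosslink search).
    """
    from .validation import compute_qvalues  # local import, no cycle

    mass_cfg = mass_cfg or MassConfig()
    entries = []  # (mass, peptide, mod_mass)
    for p in peptides:
        m = peptide_mass(p, mass_cfg)
        entries.append((m, p, 0.0))
        if monolink_mass is not None:
            entries.append((m + monolink_mass, p, monolink_mass))
    entries.sort(key=lambda t: t[0])
    masses = np.array([e[0] for e in entries])

    rows = []
    for spec in spectra:
        target = _neutral_mass(spec, mass_cfg)
        tol = target * cfg.precursor_tol_ppm * 1e-6
        lo = np.searchsorted(masses, target - tol, side="left")
        hi = np.searchsorted(masses, target + tol, side="right")
        best = None
        ranks = _window_ranks(spec, cfg.window_width) if lo < hi else None
        for k in range(lo, hi):
            _, pep, mod = entries[k]
            ions = np.array(linear_fragment_mzs(
                pep.sequence, cfg.fragment_charges, mass_cfg, mod))
            score, m_used = adaptive_denoise_score(spec, ions, cfg, ranks)
            cand = (-score, len(ions), pep.sequence)
            if best is None or cand < best[0]:
                best = (cand, pep, mod, score, m_used)
        if best is not None:
            _, pep, mod, score, m_used = best
            rows.append(dict(scan_id=spec.scan_id, sequence=pep.sequence,
                             protein=pep.protein_id, is_monolink=mod != 0.0,
                             score=score, chosen_m=m_used,
                             td_class="DD" if pep.is_decoy else "TT",
                             truth_id=spec.truth_id))
    psms = pd.DataFrame(rows, columns=["scan_id", "sequence", "protein",
                                       "is_monolink", "score", "chosen_m",
                                       "td_class", "truth_id"])
    if len(psms):
        psms = compute_qvalues(psms)
        confident = set(psms.loc[(psms["q_value"] <= cfg.linear_q_threshold)
                                 & (psms["td_class"] == "TT"), "scan_id"])
    else:
        psms["q_value"] = pd.Series(dtype=float)
        confident = set()
    surviving = [s for s in spectra if s.scan_id not in confident]
    return psms, surviving


# ---------------------------------------------------------------------------
# crosslink search

def _doublet_peptide_masses(spectrum: Spectrum, linker: CrosslinkerSpec,
                            cfg: DenoiseConfig,
                            mass_cfg: MassConfig) -> np.ndarray:
    """Peptide masses implied by detected arm doublets: a short-arm fragment
    at m/z corresponds to a constituent peptide of neutral mass
    (mz*z - z*proton - short_arm)."""
    assert linker.arm_masses is not None
    short, _ = linker.arm_masses
    pairs = detect_doublets(spectrum, linker.doublet_delta,
                            cfg.fragment_charges, cfg.fragment_tol_ppm)
    out = []
    for i, _, z in pairs:
        neutral = spectrum.mz[i] * z - z * mass_cfg.proton_mass
        out.append(neutral - short)
    return np.array(sorted(out))


def search_crosslinks(spectra: list[Spectrum], peptides: list[Peptide],
                      linker: CrosslinkerSpec, cfg: DenoiseConfig,
                      mass_cfg: MassConfig | None = None) -> list[CSM]:
    """Best-scoring crosslink candidate per spectrum.

    ``peptides`` must contain targets and their decoys (1:1).  Candidates
    are peptide pairs whose summed mass plus the spacer matches the
    precursor within tolerance; for cleavable linkers with
    ``cfg.doublet_prefilter`` enabled, candidates are restricted to pairs
    where a constituent peptide mass is corroborated by an arm doublet.
    Ties are broken toward fewer theoretical ions, then lexicographic
    notation, so the result is deterministic.
    """
    mass_cfg = mass_cfg or MassConfig()
    ion_cache: dict[str, np.ndarray] = {}
    out: list[CSM] = []
    for spec in spectra:
        target = _neutral_mass(spec, mass_cfg)
        cands = enumerate_candidates(peptides, linker, target,
                                     cfg.precursor_tol_ppm, mass_cfg)
        if (cfg.doublet_prefilter and linker.cleavable
                and linker.arm_masses is not None and cands):
            pep_masses = _doublet_peptide_masses(spec, linker, cfg, mass_cfg)
            if len(pep_masses):
                def corroborated(c: CrosslinkCandidate) -> bool:
                    for pep in (c.peptide_a, c.peptide_b):
                        m = peptide_mass(pep, mass_cfg)
                        tol = max(m * cfg.fragment_tol_ppm * 1e-6, 0.01)
                        j = np.searchsorted(pep_masses, m)
                        for k in (j - 1, j):
                            if 0 <= k < len(pep_masses) and \
                                    abs(pep_masses[k] - m) <= tol:
                                return True
                    return False
                filtered = [c for c in cands if corroborated(c)]
                if filtered:
                    cands = filtered
        best = None
        ranks = _window_ranks(spec, cfg.window_width) if cands else None
        for cand in cands:
            key = format_crosslink_notation(cand, linker.name) + \
                f"|{cand.peptide_a.is_decoy}|{cand.peptide_b.is_decoy}"
            ions = ion_cache.get(key)
            if ions is None:
                ions = candidate_ion_mzs(cand, linker, cfg.fragment_charges,
                                         mass_cfg)
                ion_cache[key] = ions
            score, m_used = adaptive_denoise_score(spec, ions, cfg, ranks)
            # higher score, then fewer theoretical ions, then first in
            # lexicographic order of the notation key
            rank = (-score, len(ions), key)
            if best is None or rank < best[0]:
                best = (rank, cand, score, m_used)
        if best is not None:
            _, cand, score, m_used = best
            out.append(CSM(scan_id=spec.scan_id, candidate=cand, score=score,
                           chosen_m=m_used, td_class=cand.td_class,
                           precursor_charge=spec.precursor_charge,
                           rt=spec.rt, cv=spec.cv,
                           precursor_mz=spec.precursor_mz,
                           truth_id=spec.truth_id))
    return out


CSM_COLUMNS = ["scan_id", "sequence_a", "sequence_b", "protein_a",
               "protein_b", "pos_a", "pos_b", "link_pos_a", "link_pos_b",
               "score", "chosen_m", "td_class", "charge", "rt", "cv",
               "precursor_mz", "q_value", "rt_diff", "intensityApex",
               "intensitySum", "truth_id", "notation"]


def csms_to_frame(csms: list[CSM], linker_name: str = "XL") -> pd.DataFrame:
    """Flatten CSMs into the tabular form the downstream stages consume;
    ``pos_a``/``pos_b`` are linked positions in protein coordinates,
    canonically ordered."""
    rows = []
    for c in csms:
        (prot_a, pa), (prot_b, pb) = c.candidate.protein_positions()
        rows.append(dict(
            scan_id=c.scan_id,
            sequence_a=c.candidate.peptide_a.sequence,
            sequence_b=c.candidate.peptide_b.sequence,
            protein_a=prot_a, protein_b=prot_b, pos_a=pa, pos_b=pb,
            link_pos_a=c.candidate.link_pos_a,
            link_pos_b=c.candidate.link_pos_b,
            score=c.score, chosen_m=c.chosen_m, td_class=c.td_class,
            charge=c.precursor_charge, rt=c.rt, cv=c.cv,
            precursor_mz=c.precursor_mz, q_value=c.q_value,
            rt_diff=c.rt_diff, intensityApex=c.intensityApex,
            intensitySum=c.intensitySum, truth_id=c.truth_id,
            notation=format_crosslink_notation(c.candidate, linker_name)))
    return pd.DataFrame(rows, columns=CSM_COLUMNS)
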