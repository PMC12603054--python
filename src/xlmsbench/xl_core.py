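"""Domain types and in-silico chemistry for crosslinking mass spectrometry.

Covers tryptic digestion, monoisotopic peptide masses, enumeration of
crosslinked peptide-pair candidates against a precursor mass, theoretical
b/y fragment ions of crosslinked peptides (including cleavable-linker arm
fragments), pseudo-reverse decoy generation, and the bracket notation used
to name a crosslinked peptide pair, e.g.::

    DFNKVPNSIR-IVQSKSGLNMENLANHEHLLSPVR-[PhoX@4,5]

All masses are monoisotopic Daltons; all positions are 1-based.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field, replace

from pyteomics import mass as _pmass

# Monoisotopic constants (pyteomics nist values).
WATER_MASS: float = _pmass.calculate_mass(formula="H2O")
PROTON_MASS: float = _pmass.nist_mass["H+"][0][0]

#: carbamidomethylation of cysteine (iodoacetamide alkylation), the usual
#: fixed modification for in-solution digests.
CARBAMIDOMETHYL: float = 57.02146

N_TERM = 1  # link position denoting the protein/peptide N-terminus residue


class ChemistryError(ValueError):
    """Raised for invalid sequences, masses or notation."""


@dataclass(frozen=True)
class MassConfig:
    """Residue mass table plus fixed modifications.

    Parameters
    ----------
    residue_masses
        Monoisotopic residue (amino-acid minus water) masses in Da.
    fixed_mods
        Residue letter -> mass delta applied once per occurrence
        (e.g. ``{"C": 57.02146}`` for carbamidomethyl).
    """

    residue_masses: dict[str, float] = field(
        default_factory=lambda: dict(_pmass.std_aa_mass)
    )
    water_mass: float = WATER_MASS
    proton_mass: float = PROTON_MASS
    fixed_mods: dict[str, float] = field(
        default_factory=lambda: {"C": CARBAMIDOMETHYL}
    )

    def residue_mass(self, letter: str) -> float:
        try:
            base = self.residue_masses[letter]
        except KeyError:
            raise ChemistryError(f"no mass for residue {letter!r}") from None
        return base + self.fixed_mods.get(letter, 0.0)


@dataclass(frozen=True)
class CrosslinkerSpec:
    """Chemistry of a crosslinking reagent.

    ``spacer_mass`` is the net mass added to the sum of the two peptide
    masses.  For MS-cleavable linkers (DSSO-like) the gas-phase fragmentation
    splits the spacer into a short and a long arm whose masses are listed in
    ``arm_masses``; the characteristic doublet spacing is ``long - short``.
    ``max_distance`` is the theoretical Calpha-Calpha upper limit in Angstrom.
    """

    name: str
    spacer_mass: float
    site_residues: frozenset[str] = frozenset({"K"})
    link_nterm: bool = True
    cleavable: bool = False
    arm_masses: tuple[float, float] | None = None  # (short, long)
    max_distance: float = 20.0
    #: mass of the hydrolyzed (water-capped) linker for monolinked peptides
    monolink_mass: float | None = None

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ChemistryError("max_distance must be positive")
        if self.cleavable:
            if self.arm_masses is None:
                raise ChemistryError("cleavable linker needs arm_masses")
            short, long = self.arm_masses
            if not short < long:
                raise ChemistryError("arm_masses must be (short, long)")

    @property
    def doublet_delta(self) -> float:
        if not self.cleavable or self.arm_masses is None:
            raise ChemistryError(f"{self.name} is not cleavable")
        return self.arm_masses[1] - self.arm_masses[0]

    def cap_mass(self) -> float:
        """Monolink modification mass (hydrolyzed linker by default)."""
        if self.monolink_mass is not None:
            return self.monolink_mass
        return self.spacer_mass + WATER_MASS


# Shipped defaults.  The spacer/arm masses below are vendor/literature
# constants, not values computed here:
#   PhoX (tBu-protected phosphonate linker, Thermo "DSPP"): +209.97181 Da on
#     two lysines (C8H9O5P linkage), max Calpha-Calpha span ~20 A.
#   DSSO (disuccinimidyl sulfoxide, Thermo A33545): spacer +158.00376 Da
#     (C6H6O3S); gas-phase cleavage arms: alkene 54.01057, sulfenic acid
#     103.99320 (doublet delta 49.98264); span limit commonly taken ~30 A.
# Tests never rely on these numbers; they use round synthetic linkers.
PHOX = CrosslinkerSpec(name="PhoX", spacer_mass=209.97181, max_distance=20.0)
DSSO = CrosslinkerSpec(
    name="DSSO",
    spacer_mass=158.00376,
    cleavable=True,
    arm_masses=(54.01057, 103.99320),
    max_distance=30.0,
)
BUILTIN_LINKERS: dict[str, CrosslinkerSpec] = {"PhoX": PHOX, "DSSO": DSSO}


@dataclass(frozen=True)
class Peptide:
    sequence: str
    protein_id: str = ""
    start_pos: int = 1
    missed_cleavages: int = 0
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ChemistryError("empty peptide sequence")
        if self.start_pos < 1:
            raise ChemistryError("start_pos is 1-based")

    @property
    def end_pos(self) -> int:
        return self.start_pos + len(self.sequence) - 1


@dataclass(frozen=True)
class CrosslinkCandidate:
    peptide_a: Peptide
    peptide_b: Peptide
    link_pos_a: int
    link_pos_b: int
    precursor_mass: float  # neutral, Da

    @property
    def td_class(self) -> str:
        n = int(self.peptide_a.is_decoy) + int(self.peptide_b.is_decoy)
        return ("TT", "TD", "DD")[n]

    def protein_positions(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """Linked positions in protein coordinates, canonically ordered."""
        a = (self.peptide_a.protein_id, self.peptide_a.start_pos + self.link_pos_a - 1)
        b = (self.peptide_b.protein_id, self.peptide_b.start_pos + self.link_pos_b - 1)
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'b' or 'y'
    index: int
    charge: int
    mz: float
    peptide: str = "a"  # which constituent peptide: 'a' or 'b'
    carries_partner: bool = False
    arm_label: str = "none"  # none | short | long

    def __post_init__(self) -> None:
        if self.carries_partner and self.arm_label != "none":
            raise ChemistryError("carries_partner and arm_label are exclusive")


# ---------------------------------------------------------------------------
# digestion

_TRYPSIN_SITE = re.compile(r"(?<=[KR])(?!P)")


def digest(protein_sequence: str, max_missed: int = 0,
           protein_id: str = "", cfg: MassConfig | None = None) -> list[Peptide]:
    """Tryptic digest: cleave after K or R unless followed by P.

    Returns all peptides with 0..``max_missed`` internal missed cleavages,
    with 1-based start positions.  Unknown residue letters are rejected with
    the offending position.
    """
    table = (cfg or MassConfig()).residue_masses
    for i, ch in enumerate(protein_sequence):
        if ch not in table:
            raise ChemistryError(f"unknown residue {ch!r} at position {i + 1}")
    # fully cleaved fragments as (start, end) half-open intervals
    bounds = [0] + [m.start() for m in _TRYPSIN_SITE.finditer(protein_sequence)]
    if bounds[-1] != len(protein_sequence):
        bounds.append(len(protein_sequence))
    pieces = list(zip(bounds[:-1], bounds[1:]))
    out: list[Peptide] = []
    for i in range(len(pieces)):
        for mc in range(max_missed + 1):
            j = i + mc
            if j >= len(pieces):
                break
            start, end = pieces[i][0], pieces[j][1]
            out.append(Peptide(protein_sequence[start:end], protein_id,
                               start + 1, mc))
    return out


# sequence-mass memo per MassConfig instance (masses depend only on the
# sequence and the config's tables); the config is kept referenced so ids
# are never recycled across distinct configs
_MASS_MEMO: dict[int, tuple[MassConfig, dict[str, float]]] = {}


def peptide_mass(p: Peptide | str, cfg: MassConfig | None = None) -> float:
    """Neutral monoisotopic peptide mass with fixed modifications."""
    cfg = cfg or MassConfig()
    seq = p.sequence if isinstance(p, Peptide) else p
    entry = _MASS_MEMO.get(id(cfg))
    if entry is None:
        entry = (cfg, {})
        _MASS_MEMO[id(cfg)] = entry
    memo = entry[1]
    m = memo.get(seq)
    if m is None:
        m = sum(cfg.residue_mass(ch) for ch in seq) + cfg.water_mass
        memo[seq] = m
    return m


# ---------------------------------------------------------------------------
# candidate enumeration

def linkable_positions(p: Peptide, linker: CrosslinkerSpec) -> list[int]:
    """1-based positions within the peptide that the linker can react with.

    A C-terminal K/R is a cleavage product of trypsin: a residue that was
    crosslinked would not have been cleaved, so the peptide C-terminus is
    linkable only when it is also the protein C-terminus is unknowable here;
    we conservatively allow it (search-side permissiveness costs candidates,
    not correctness, since scoring decides).
    """
    pos = [i + 1 for i, ch in enumerate(p.sequence) if ch in linker.site_residues]
    if linker.link_nterm and p.start_pos == 1 and 1 not in pos:
        pos.insert(0, 1)
    return pos


def _canonical_pair(a: Peptide, b: Peptide, cfg: MassConfig
                    ) -> tuple[Peptide, Peptide, bool]:
    ma, mb = peptide_mass(a, cfg), peptide_mass(b, cfg)
    if ma < mb or (ma == mb and a.sequence <= b.sequence):
        return a, b, False
    return b, a, True


def enumerate_candidates(peptides: list[Peptide], linker: CrosslinkerSpec,
                         precursor_mass: float, tol_ppm: float,
                         cfg: MassConfig | None = None
                         ) -> list[CrosslinkCandidate]:
    """All peptide pairs whose summed mass + spacer matches the precursor.

    Pairs are reported once in canonical order (lower-mass peptide first,
    ties broken lexicographically), one candidate per pair of linkable
    sites.  Homeotypic pairs (a peptide with itself) are included.
    """
    cfg = cfg or MassConfig()
    masses = [(peptide_mass(p, cfg), p) for p in peptides]
    masses.sort(key=lambda t: t[0])
    tol = precursor_mass * tol_ppm * 1e-6
    target = precursor_mass - linker.spacer_mass
    out: list[CrosslinkCandidate] = []
    seen: set[tuple] = set()
    for lo in range(len(masses)):
        ma, pa = masses[lo]
        if not linkable_positions(pa, linker):
            continue
        left = bisect.bisect_left(masses, target - ma - tol, key=lambda t: t[0])
        right = bisect.bisect_right(masses, target - ma + tol, key=lambda t: t[0])
        for k in range(left, right):
            mb, pb = masses[k]
            if k < lo:
                continue  # counted when roles were swapped
            if not linkable_positions(pb, linker):
                continue
            a, b, _ = _canonical_pair(pa, pb, cfg)
            key = (a.sequence, a.protein_id, a.start_pos, a.is_decoy,
                   b.sequence, b.protein_id, b.start_pos, b.is_decoy)
            if key in seen:
                continue
            seen.add(key)
            pm = peptide_mass(a, cfg) + peptide_mass(b, cfg) + linker.spacer_mass
            for ia in linkable_positions(a, linker):
                for ib in linkable_positions(b, linker):
                    out.append(CrosslinkCandidate(a, b, ia, ib, pm))
    return out


# ---------------------------------------------------------------------------
# fragment ions

def _prefix_masses(seq: str, cfg: MassConfig) -> list[float]:
    acc, out = 0.0, []
    for ch in seq:
        acc += cfg.residue_mass(ch)
        out.append(acc)
    return out


def fragment_ions(c: CrosslinkCandidate, linker: CrosslinkerSpec,
                  charges: set[int] | tuple[int, ...] = (1, 2),
                  cfg: MassConfig | None = None) -> list[FragmentIon]:
    """Theoretical b/y ions of both constituent peptides.

    Fragments spanning the link position carry the full partner peptide plus
    the spacer (``carries_partner``).  For cleavable linkers, link-spanning
    fragments are additionally emitted with only the short or long arm
    remaining after gas-phase spacer cleavage (``arm_label``), which is what
    produces the diagnostic mass doublets.
    """
    cfg = cfg or MassConfig()
    out: list[FragmentIon] = []
    pair = (("a", c.peptide_a, c.link_pos_a, c.peptide_b),
            ("b", c.peptide_b, c.link_pos_b, c.peptide_a))
    for label, pep, link_pos, partner in pair:
        seq = pep.sequence
        n = len(seq)
        prefix = _prefix_masses(seq, cfg)
        total = prefix[-1] + cfg.water_mass
        partner_mass = peptide_mass(partner, cfg)
        for i in range(1, n):  # fragment index
            b_neutral = prefix[i - 1]
            y_neutral = total - prefix[n - 1 - i]
            b_spans = link_pos <= i
            y_spans = link_pos > n - i
            for series, neutral, spans in (("b", b_neutral, b_spans),
                                           ("y", y_neutral, y_spans)):
                mods: list[tuple[float, bool, str]] = []
                if not spans:
                    mods.append((0.0, False, "none"))
                else:
                    mods.append((partner_mass + linker.spacer_mass, True, "none"))
                    if linker.cleavable and linker.arm_masses is not None:
                        short, long = linker.arm_masses
                        mods.append((short, False, "short"))
                        mods.append((long, False, "long"))
                for delta, carries, arm in mods:
                    for z in sorted(charges):
                        mz = (neutral + delta + z * cfg.proton_mass) / z
                        out.append(FragmentIon(series, i, z, mz, label,
                                               carries, arm))
    return out


def linear_fragment_mzs(sequence: str,
                        charges: set[int] | tuple[int, ...] = (1, 2),
                        cfg: MassConfig | None = None,
                        mod_mass: float = 0.0) -> list[float]:
    """b/y fragment m/z values of a linear (or monolinked) peptide.

    ``mod_mass`` is a whole-peptide modification (e.g. a hydrolyzed-linker
    cap); its position is unknown so it is carried on the y series only —
    a crude convention that suffices for monolink pre-filtering.
    """
    cfg = cfg or MassConfig()
    prefix = _prefix_masses(sequence, cfg)
    total = prefix[-1] + cfg.water_mass + mod_mass
    out: list[float] = []
    n = len(sequence)
    for i in range(1, n):
        b = prefix[i - 1]
        y = total - prefix[i - 1]
        for z in charges:
            out.append((b + z * cfg.proton_mass) / z)
            out.append((y + z * cfg.proton_mass) / z)
    return sorted(out)


# ---------------------------------------------------------------------------
# decoys

def generate_decoy(p: Peptide) -> Peptide:
    """Pseudo-reverse decoy: reverse the sequence keeping the C-terminal
    residue in place, so decoys stay tryptic-like and isobaric."""
    seq = p.sequence
    if len(seq) >= 2:
        seq = seq[-2::-1] + seq[-1]
    return replace(p, sequence=seq, is_decoy=not p.is_decoy,
                   protein_id=_toggle_decoy_id(p.protein_id, p.is_decoy))


def _toggle_decoy_id(pid: str, currently_decoy: bool) -> str:
    if currently_decoy and pid.startswith("DECOY_"):
        return pid[len("DECOY_"):]
    if not currently_decoy:
        return f"DECOY_{pid}"
    return pid


# ---------------------------------------------------------------------------
# bracket notation

_NOTATION = re.compile(
    r"^(?P<a>[A-Z]+)-(?P<b>[A-Z]+)-\[(?P<linker>[^@\]]+)@(?P<pa>\d+),(?P<pb>\d+)\]$"
)


def format_crosslink_notation(c: CrosslinkCandidate, linker_name: str) -> str:
    return (f"{c.peptide_a.sequence}-{c.peptide_b.sequence}"
            f"-[{linker_name}@{c.link_pos_a},{c.link_pos_b}]")


def parse_crosslink_notation(text: str,
                             linker: CrosslinkerSpec | None = None,
                             cfg: MassConfig | None = None
                             ) -> CrosslinkCandidate:
    """Parse ``SEQA-SEQB-[linker@posA,posB]`` into a candidate skeleton.

    If ``linker`` is given its site rule is validated and the precursor mass
    is computed; otherwise the named builtin linker is looked up (falling
    back to a zero-spacer placeholder for unknown names).
    """
    m = _NOTATION.match(text.strip())
    if not m:
        raise ChemistryError(f"malformed crosslink notation: {text!r}")
    seq_a, seq_b = m["a"], m["b"]
    pa, pb = int(m["pa"]), int(m["pb"])
    name = m["linker"]
    if linker is None:
        linker = BUILTIN_LINKERS.get(
            name, CrosslinkerSpec(name=name, spacer_mass=0.0))
    for seq, pos, which in ((seq_a, pa, "A"), (seq_b, pb, "B")):
        if not 1 <= pos <= len(seq):
            raise ChemistryError(
                f"link position {pos} out of range for peptide {which}")
        if seq[pos - 1] not in linker.site_residues and not (
                linker.link_nterm and pos == N_TERM):
            raise ChemistryError(
                f"residue {seq[pos - 1]!r} at position {pos} of peptide "
                f"{which} is not linkable by {linker.name}")
    cfg = cfg or MassConfig()
    a, b = Peptide(seq_a), Peptide(seq_b)
    pm = peptide_mass(a, cfg) + peptide_mass(b, cfg) + linker.spacer_mass
    return CrosslinkCandidate(a, b, pa, pb, pm)
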