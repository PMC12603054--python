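"""Map residue pairs onto a 3D structure and analyze Calpha-Calpha distances.

Crosslinkers have a finite span, so a residue pair identified by mass
spectrometry should sit within the linker's theoretical maximum distance
(20 A for a PhoX-like reagent) in the folded structure; the fraction of
links "within cutoff" — optionally stratified by precursor abundance class —
is the standard structural sanity metric for a crosslink set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd


@dataclass
class Structure:
    """Calpha trace: chain id plus 1-based residue number -> (x, y, z) in A."""

    chain_id: str = "A"
    coords: dict[int, tuple[float, float, float]] = field(default_factory=dict)

    def __contains__(self, resnum: int) -> bool:
        return resnum in self.coords

    def __len__(self) -> int:
        return len(self.coords)

    def as_array(self) -> np.ndarray:
        """(n, 3) array in residue-number order."""
        return np.array([self.coords[i] for i in sorted(self.coords)])

    def exposure(self) -> dict[int, float]:
        """Surface-exposure proxy: distance from the centroid, min-max
        normalized to [0, 1] (hull residues score 1)."""
        nums = sorted(self.coords)
        xyz = self.as_array()
        d = np.linalg.norm(xyz - xyz.mean(axis=0), axis=1)
        lo, hi = d.min(), d.max()
        span = hi - lo if hi > lo else 1.0
        return {n: float((di - lo) / span) for n, di in zip(nums, d)}


def write_pdb(structure: Structure, path: str) -> None:
    """Write the Calpha trace as PDB ATOM records (one CA per residue)."""
    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    chain = gemmi.Chain(structure.chain_id)
    for resnum in sorted(structure.coords):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(resnum, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*structure.coords[resnum])
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(path)


def read_pdb(path: str, chain_id: str | None = None) -> Structure:
    """Read CA atoms of one chain from a PDB file."""
    st = gemmi.read_structure(path)
    model = st[0]
    chain = model[chain_id] if chain_id else model[0]
    coords: dict[int, tuple[float, float, float]] = {}
    for res in chain:
        ca = res.find_atom("CA", "*")
        if ca is not None:
            coords[res.seqid.num] = (ca.pos.x, ca.pos.y, ca.pos.z)
    return Structure(chain.name, coords)


def link_distance(structure: Structure, pos_a: int, pos_b: int) -> float:
    """Euclidean Calpha-Calpha distance in A; raises KeyError if a residue
    is absent from the structure (callers treat that as unmappable)."""
    xa = structure.coords[pos_a]
    xb = structure.coords[pos_b]
    return math.dist(xa, xb)


def annotate_distances(pairs: pd.DataFrame, structure: Structure
                       ) -> pd.DataFrame:
    """Add a ``distance`` column (NaN where a residue is unmappable)."""
    if len(pairs) == 0:
        out = pairs.copy()
        out["distance"] = pd.Series(dtype=float)
        return out
    dist = []
    for pa, pb in zip(pairs["pos_a"], pairs["pos_b"]):
        try:
            dist.append(link_distance(structure, int(pa), int(pb)))
        except KeyError:
            dist.append(np.nan)
    out = pairs.copy()
    out["distance"] = dist
    return out


def proportion_within(pairs: pd.DataFrame, structure: Structure,
                      cutoff: float = 20.0,
                      by: str | None = None) -> dict:
    """Fraction of mappable residue pairs with distance strictly below
    ``cutoff``, overall or per class in column ``by``.

    Returns ``{"overall": frac | None, "n_unmappable": int}`` plus one key
    per class when ``by`` is given; classes with zero mappable pairs report
    ``None``.
    """
    ann = annotate_distances(pairs, structure)
    unmappable = int(ann["distance"].isna().sum())
    mappable = ann.dropna(subset=["distance"])

    def frac(df: pd.DataFrame) -> float | None:
        if len(df) == 0:
            return None
        return float((df["distance"] < cutoff).mean())

    out: dict = {"overall": frac(mappable), "n_unmappable": unmappable}
    if by is not None:
        for label, grp in mappable.groupby(by, observed=True):
            out[str(label)] = frac(grp)
    return out


def distance_histogram(pairs: pd.DataFrame, structure: Structure,
                       bin_width: float = 5.0) -> dict[int, int]:
    """Counts per half-open bin [k*w, (k+1)*w); keys are bin indices k.
    Counts sum to the number of mappable pairs."""
    ann = annotate_distances(pairs, structure)
    d = ann["distance"].dropna().to_numpy()
    out: dict[int, int] = {}
    for k in np.floor(d / bin_width).astype(int):
        out[int(k)] = out.get(int(k), 0) + 1
    return out


LINKS_CSV_COLUMNS = ["protein_a", "pos_a", "protein_b", "pos_b",
                     "n_csms", "abundance_class", "distance"]


def export_links_csv(pairs: pd.DataFrame, structure: Structure,
                     path: str) -> pd.DataFrame:
    """One row per residue pair with distance and abundance class, in a
    stable column order suitable for circle-plot tools."""
    ann = annotate_distances(pairs, structure)
    for col in LINKS_CSV_COLUMNS:
        if col not in ann.columns:
            ann[col] = np.nan
    out = ann[LINKS_CSV_COLUMNS]
    out.to_csv(path, index=False)
    return out
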