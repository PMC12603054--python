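"""Readers and writers for the interchange formats of the pipeline.

MGF is the spectrum interchange format (with a FAIMS_CV header per scan);
a minimal mzML reader is provided for interoperability.  Feature tables
are tab-separated with the column names used by LC-MS feature detectors
(mz, charge, rtApex, ..., intensityApex, intensitySum, cv).  Protein
sequences travel as FASTA, structures as Calpha-only PDB, and CSM/URP
tables as CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .denoise_search import Spectrum


def write_mgf(spectra: list[Spectrum], path: str) -> None:
    entries = []
    for s in spectra:
        entries.append({
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": f"scan={s.scan_id} truth={s.truth_id or 'na'}",
                "pepmass": (s.precursor_mz,),
                "charge": s.precursor_charge,
                "rtinseconds": s.rt * 60.0,
                "scans": s.scan_id,
                "faims_cv": s.cv,
            },
        })
    _mgf.write(entries, path, file_mode="w")


def _truth_from_title(title: str) -> str:
    for tok in title.split():
        if tok.startswith("truth="):
            val = tok[len("truth="):]
            return "" if val == "na" else val
    return ""


def read_mgf(path: str) -> list[Spectrum]:
    out = []
    with _mgf.read(path) as reader:
        for entry in reader:
            p = entry["params"]
            charge = p.get("charge", [0])
            charge = int(charge[0]) if hasattr(charge, "__len__") else int(charge)
            out.append(Spectrum(
                scan_id=int(p.get("scans", len(out) + 1)),
                precursor_mz=float(p["pepmass"][0]),
                precursor_charge=charge,
                rt=float(p.get("rtinseconds", 0.0)) / 60.0,
                cv=float(p.get("faims_cv", 0.0)),
                mz=np.asarray(entry["m/z array"], float),
                intensity=np.asarray(entry["intensity array"], float),
                truth_id=_truth_from_title(str(p.get("title", "")))))
    return out


def _decode_binary_array(node, ns: str) -> np.ndarray | None:
    import base64
    import zlib

    params = {c.get("name") for c in node.iter(f"{ns}cvParam")}
    binary = node.find(f"{ns}binary")
    if binary is None or binary.text is None:
        return None
    raw = base64.b64decode(binary.text)
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    arr = np.frombuffer(raw, dtype=dtype).astype(float)
    if "m/z array" in params:
        return arr
    if "intensity array" in params:
        return arr
    return None


def read_mzml(path: str) -> list[Spectrum]:
    """Minimal mzML-subset reader (uncompressed or zlib 32/64-bit float
    arrays): MS2 spectra with precursor m/z and charge, retention time,
    and the FAIMS compensation voltage when annotated."""
    from lxml import etree

    tree = etree.parse(path)
    root = tree.getroot()
    ns = root.tag[:root.tag.index("}") + 1] if "}" in root.tag else ""
    out: list[Spectrum] = []
    for i, spec in enumerate(root.iter(f"{ns}spectrum")):
        params = {c.get("name"): c.get("value")
                  for c in spec.iter(f"{ns}cvParam")}
        if params.get("ms level") != "2":
            continue
        mz = inten = None
        for arr_node in spec.iter(f"{ns}binaryDataArray"):
            names = {c.get("name") for c in arr_node.iter(f"{ns}cvParam")}
            decoded = _decode_binary_array(arr_node, ns)
            if decoded is None:
                continue
            if "m/z array" in names:
                mz = decoded
            elif "intensity array" in names:
                inten = decoded
        if mz is None or inten is None:
            continue
        out.append(Spectrum(
            scan_id=i + 1,
            precursor_mz=float(params.get("selected ion m/z", 0.0)),
            precursor_charge=int(float(params.get("charge state", 0))),
            rt=float(params.get("scan start time", 0.0)),
            cv=float(params.get("FAIMS compensation voltage", 0.0)),
            mz=mz, intensity=inten))
    return out


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


_TSV_RENAME = {"rt_apex": "rtApex", "rt_start": "rtStart", "rt_end": "rtEnd"}
FEATURE_TSV_COLUMNS = ["mz", "charge", "rtApex", "rtStart", "rtEnd",
                       "intensityApex", "intensitySum", "cv",
                       "feature_id", "source", "link_id"]


def write_feature_tsv(features: pd.DataFrame, path: str) -> None:
    df = features.rename(columns=_TSV_RENAME)
    cols = [c for c in FEATURE_TSV_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_feature_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={v: k for k, v in _TSV_RENAME.items()})
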