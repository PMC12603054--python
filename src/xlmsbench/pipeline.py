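"""End-to-end orchestration: simulate -> acquire -> search -> validate ->
match -> structure-analyze -> report, as one reproducible, seeded run.

A run is described by a single :class:`RunConfig`; identical configs
produce identical outputs (the manifest records the config hash, the seed
and per-stage row counts so reruns can be compared byte for byte).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .denoise_search import (
    DenoiseConfig,
    csms_to_frame,
    linear_first_pass,
    recalibrate,
    search_crosslinks,
)
from .feature_match import detect_features, match_features_to_csms
from .io import write_fasta, write_feature_tsv, write_mgf
from .optimization_metrics import run_metrics
from .structure_analysis import (
    distance_histogram,
    export_links_csv,
    proportion_within,
    write_pdb,
)
from .synthetic_data import (
    AcquisitionMethod,
    SimConfig,
    SimulatedDataset,
    simulate_dataset,
)
from .validation import aggregate_urps, compute_qvalues, filter_at_fdr
from .xl_core import CrosslinkerSpec, MassConfig, digest, generate_decoy


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    method: AcquisitionMethod = field(default_factory=AcquisitionMethod)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    linker: CrosslinkerSpec = field(default_factory=lambda: CrosslinkerSpec(
        name="SimXL", spacer_mass=100.0, max_distance=20.0))
    fdr_alpha: float = 0.01
    feature_mz_tol: float = 0.01  # Th
    structure_cutoff: float = 20.0  # A
    histogram_bin_width: float = 5.0

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, seed=seed, sim=dataclasses.replace(self.sim, seed=seed))

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in
                        dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, frozenset):
                return sorted(obj)
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            return obj
        return enc(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def config_from_dict(d: dict) -> RunConfig:
    """Build a RunConfig from a (possibly partial) nested mapping, e.g.
    parsed YAML; unspecified values keep their defaults."""
    kw: dict = {}
    if "seed" in d:
        kw["seed"] = int(d["seed"])
    if "sim" in d:
        sim = dict(d["sim"])
        for tup_key in ("abundance_lognormal", "mass_error_ppm",
                        "fragment_charges"):
            if tup_key in sim:
                sim[tup_key] = tuple(sim[tup_key])
        if "cv_profiles" in sim:
            sim["cv_profiles"] = {int(k): tuple(v)
                                  for k, v in sim["cv_profiles"].items()}
        kw["sim"] = SimConfig(**sim)
    if "method" in d:
        m = dict(d["method"])
        for tup_key in ("mz_range", "charge_filter", "cv_program"):
            if tup_key in m:
                m[tup_key] = tuple(m[tup_key])
        kw["method"] = AcquisitionMethod(**m)
    if "denoise" in d:
        dn = dict(d["denoise"])
        for tup_key in ("m_range", "fragment_charges"):
            if tup_key in dn:
                dn[tup_key] = tuple(dn[tup_key])
        kw["denoise"] = DenoiseConfig(**dn)
    if "linker" in d:
        lk = dict(d["linker"])
        if "site_residues" in lk:
            lk["site_residues"] = frozenset(lk["site_residues"])
        if lk.get("arm_masses") is not None:
            lk["arm_masses"] = tuple(lk["arm_masses"])
        kw["linker"] = CrosslinkerSpec(**lk)
    for key in ("fdr_alpha", "feature_mz_tol", "structure_cutoff",
                "histogram_bin_width"):
        if key in d:
            kw[key] = float(d[key])
    cfg = RunConfig(**kw)
    if "seed" in d:
        cfg = cfg.with_seed(int(d["seed"]))
    return cfg


def load_config(path_or_default: str) -> RunConfig:
    if path_or_default == "default":
        return RunConfig()
    with open(path_or_default) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def build_search_database(protein_id: str, sequence: str,
                          max_missed: int = 2,
                          mass_cfg: MassConfig | None = None,
                          min_length: int = 4):
    """Tryptic target peptides plus their pseudo-reverse decoys (1:1).

    Decoys whose sequence collides with a target (palindromic prefixes
    make pseudo-reversal a fixed point) are dropped — a decoy
    indistinguishable from a target carries no error information and
    would only create degenerate score ties.
    """
    targets = [p for p in digest(sequence, max_missed, protein_id, mass_cfg)
               if len(p.sequence) >= min_length]
    target_seqs = {p.sequence for p in targets}
    decoys = [d for d in (generate_decoy(p) for p in targets)
              if d.sequence not in target_seqs]
    return targets + decoys


@dataclass
class RunBundle:
    config: RunConfig
    dataset: SimulatedDataset
    linear_psms: pd.DataFrame
    csms: pd.DataFrame  # all CSMs with q-values
    filtered_csms: pd.DataFrame
    urps: pd.DataFrame
    annotated_csms: pd.DataFrame
    detected_features: pd.DataFrame
    structure_summary: dict
    metrics: dict
    manifest: dict


def identify(spectra, peptides, linker, denoise_cfg,
             mass_cfg: MassConfig | None = None):
    """Two-pass identification on a spectrum list: linear first pass,
    recalibration from confident linear PSMs, crosslink search.

    Returns (linear PSM table, CSM table with q-values).
    """
    mass_cfg = mass_cfg or MassConfig()
    linear_psms, surviving = linear_first_pass(
        spectra, peptides, denoise_cfg,
        monolink_mass=None, mass_cfg=mass_cfg)
    # precursor ppm errors of confident linear PSMs drive recalibration
    errors = []
    if len(linear_psms):
        from .xl_core import peptide_mass
        spec_by_id = {s.scan_id: s for s in spectra}
        conf = linear_psms[(linear_psms["q_value"] <= 0.01)
                           & (linear_psms["td_class"] == "TT")]
        for _, row in conf.iterrows():
            s = spec_by_id[row["scan_id"]]
            theo = peptide_mass(row["sequence"], mass_cfg)
            obs = (s.precursor_mz - mass_cfg.proton_mass) * s.precursor_charge
            errors.append((obs - theo) / theo * 1e6)
    surviving, _shift = recalibrate(surviving, errors)
    csms = search_crosslinks(surviving, peptides, linker, denoise_cfg,
                             mass_cfg)
    table = csms_to_frame(csms, linker.name)
    return linear_psms, compute_qvalues(table)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None
                 ) -> RunBundle:
    """Execute every stage in order; write all artifacts when ``outdir``
    is given.  Identical configs yield identical outputs."""
    mass_cfg = MassConfig()
    dataset = simulate_dataset(config.sim, config.method, config.linker)
    peptides = build_search_database(dataset.protein_id,
                                     dataset.protein_sequence,
                                     config.sim.max_missed_cleavages,
                                     mass_cfg)
    linear_psms, csms = identify(dataset.spectra, peptides, config.linker,
                                 config.denoise, mass_cfg)
    filtered = filter_at_fdr(csms, config.fdr_alpha)
    urps = aggregate_urps(filtered)

    detected = detect_features(dataset.ms1_scans)
    annotated, rt_shift = match_features_to_csms(
        dataset.features, filtered, config.feature_mz_tol)

    pairs = aggregate_urps(annotated) if len(annotated) else urps
    # carry the abundance class of the best CSM onto each residue pair
    if len(annotated):
        cls = annotated.groupby(["protein_a", "pos_a", "protein_b",
                                 "pos_b"])["abundance_class"].first()
        pairs = pairs.merge(cls.rename("abundance_class").reset_index(),
                            on=["protein_a", "pos_a", "protein_b", "pos_b"],
                            how="left")
    else:
        pairs["abundance_class"] = ""
    structure_summary = proportion_within(
        pairs, dataset.structure, config.structure_cutoff,
        by="abundance_class" if len(pairs) else None)
    histogram = distance_histogram(pairs, dataset.structure,
                                   config.histogram_bin_width)
    metrics = run_metrics("run0", filtered, urps, dataset.acquisition_log,
                          config.method.gradient_minutes)

    manifest = dict(
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
        stages=dict(
            simulate=dict(n_links=len(dataset.links),
                          n_features=len(dataset.features),
                          n_ms1=int((dataset.acquisition_log["type"]
                                     == "MS1").sum()),
                          n_ms2=int((dataset.acquisition_log["type"]
                                     == "MS2").sum())),
            search=dict(n_linear_psms=len(linear_psms), n_csms=len(csms)),
            validate=dict(n_filtered_csms=len(filtered), n_urps=len(urps)),
            match=dict(n_detected_features=len(detected),
                       n_matched=int(annotated["feature_matched"].sum())
                       if len(annotated) else 0,
                       rt_shift=rt_shift),
            structure=structure_summary,
            report=metrics,
        ),
    )

    bundle = RunBundle(config, dataset, linear_psms, csms, filtered, urps,
                       annotated, detected, structure_summary, metrics,
                       manifest)
    if outdir is not None:
        write_bundle(bundle, Path(outdir), histogram)
    return bundle


def write_bundle(bundle: RunBundle, outdir: Path,
                 histogram: dict | None = None) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ds = bundle.dataset
    write_fasta({ds.protein_id: ds.protein_sequence},
                str(outdir / "protein.fasta"))
    write_pdb(ds.structure, str(outdir / "structure.pdb"))
    write_mgf(ds.spectra, str(outdir / "spectra.mgf"))
    write_feature_tsv(ds.features, str(outdir / "features.tsv"))
    ds.truth_table().to_csv(outdir / "ground_truth.csv", index=False)
    ds.acquisition_log.to_csv(outdir / "acquisition_log.csv", index=False)
    bundle.linear_psms.to_csv(outdir / "linear_psms.csv", index=False)
    bundle.csms.to_csv(outdir / "csms_all.csv", index=False)
    bundle.filtered_csms.to_csv(outdir / "csms_fdr.csv", index=False)
    bundle.urps.to_csv(outdir / "urps.csv", index=False)
    bundle.annotated_csms.to_csv(outdir / "csms_annotated.csv", index=False)
    bundle.detected_features.to_csv(outdir / "features_detected.csv",
                                    index=False)
    summary = dict(structure=bundle.structure_summary,
                   metrics=bundle.metrics)
    if histogram is not None:
        summary["distance_histogram"] = {str(k): v
                                         for k, v in histogram.items()}
    (outdir / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=2, sort_keys=True))
    (outdir / "manifest.json").write_text(
        json.dumps(_jsonable(bundle.manifest), indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def grade_against_truth(bundle: RunBundle) -> dict:
    """Truth-table grading of a run: sensitivity and observed FDP of the
    reported residue pairs against the generator's link list."""
    truth = {(l.pos_a, l.pos_b) for l in bundle.dataset.links}
    reported = {(int(r["pos_a"]), int(r["pos_b"]))
                for _, r in bundle.urps.iterrows()}
    tp = len(truth & reported)
    out = dict(n_true=len(truth), n_reported=len(reported),
               true_positives=tp,
               sensitivity=tp / len(truth) if truth else float("nan"),
               fdp=(len(reported) - tp) / len(reported)
               if reported else 0.0)
    ann = bundle.annotated_csms
    if len(ann):
        feat_link = bundle.dataset.features.set_index("feature_id")["link_id"]
        xl = ann[ann["truth_id"].str.startswith("XL", na=False)
                 & ann["feature_matched"]]
        if len(xl):
            correct = [feat_link.get(fid) == tid
                       for fid, tid in zip(xl["feature_id"], xl["truth_id"])]
            out["feature_assignment_accuracy"] = float(np.mean(correct))
    return out
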