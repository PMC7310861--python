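"""Pipeline orchestration: stage graph, config, manifest, report writers.

A single :class:`PipelineConfig` carries every numeric threshold used
across the stages (50-nt proximal cutoff, 1.5 fold-change call, 0.05 FDR,
mapq 60, 20 nt minimum read length, 0.0001 correlation pseudocount, 75 nt
meta-exon window, 9 + 27 nt clearance constants) plus input paths and the
seed.  Stages run in dependency order; every artifact lands in the output
directory and is recorded in a JSON manifest together with a hash of the
configuration, so a re-run with an identical config reproduces identical
non-stochastic artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import annotation3ui, class_enrichment, dge, ripseq_profile, synthetic_data

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "classify", "ripmeta", "dge", "enrich")


@dataclass
class PipelineConfig:
    # inputs (any may be produced by the simulate stage instead)
    annotation_path: Optional[str] = None
    annotation_dialect: str = "gtf"
    alignments_path: Optional[str] = None
    counts_path: Optional[str] = None
    samples_path: Optional[str] = None
    quant_path: Optional[str] = None
    ortholog_path: Optional[str] = None
    uorf_path: Optional[str] = None
    # thresholds
    proximal_cutoff: int = 50
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    min_mapq: int = 60
    min_read_len: int = 20
    pseudocount: float = 0.0001
    meta_window: int = 75
    ribosome_3prime_extension: int = 9
    ejc_5prime_boundary: int = 27
    unwanted_variation_k: int = 1
    seed: int = 0
    # simulation block
    simulation: synthetic_data.SimulationConfig = field(
        default_factory=synthetic_data.SimulationConfig
    )

    def validate(self) -> None:
        for name in (
            "proximal_cutoff",
            "fc_threshold",
            "fdr_threshold",
            "min_mapq",
            "min_read_len",
            "pseudocount",
            "meta_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        geom_raw = sim_raw.pop("deposition_geometry", None)
        sim = synthetic_data.SimulationConfig(**sim_raw)
        if geom_raw:
            sim.deposition_geometry = synthetic_data.DepositionGeometry(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in geom_raw.items()
                }
            )
        cfg = cls(simulation=sim, **raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    stages: tuple[str, ...] = STAGE_ORDER,
    out_dir: str | Path = "ejcnmd_out",
    dry_run: bool = False,
) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    config.validate()
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGE_ORDER if s in stages]
    if dry_run:
        return {"stages": ordered, "dry_run": True, "artifacts": {}}

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": ordered,
        "artifacts": {},
    }
    state: dict = {}

    for stage in ordered:
        logger.info("running stage %s", stage)
        _STAGES[stage](config, state, out_dir, manifest)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _record(manifest, name, path):
    manifest["artifacts"][name] = str(path)


def _stage_simulate(config, state, out_dir, manifest):
    sim = config.simulation
    sim.seed = config.seed
    bundle = synthetic_data.generate_annotation(sim)
    state["bundle"] = bundle
    gtf = out_dir / "annotation.gtf"
    synthetic_data.write_gtf(bundle, gtf)
    _record(manifest, "annotation_gtf", gtf)

    reads, truth = synthetic_data.simulate_rip_footprints(
        bundle,
        sim.deposition_geometry,
        sim.n_footprints,
        sim.duplication_rate,
        seed=config.seed,
    )
    sam = out_dir / "footprints.sam"
    synthetic_data.write_sam(reads, bundle.chrom_length, sam, bundle.chrom)
    truth_path = out_dir / "footprint_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    state["reads"] = reads
    _record(manifest, "footprints_sam", sam)
    _record(manifest, "footprint_truth", truth_path)

    counts, truth_expr = synthetic_data.simulate_expression(bundle, sim, "gene")
    counts_path = out_dir / "counts.tsv"
    counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    samples = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "genotype": sim.genotypes,
            "replicate_group": sim.replicate_groups or sim.genotypes,
        }
    )
    samples_path = out_dir / "samples.tsv"
    samples.to_csv(samples_path, sep="\t", index=False)
    truth_expr_path = out_dir / "expression_truth.tsv"
    truth_expr.to_csv(truth_expr_path, sep="\t")
    state["counts"] = counts
    state["samples"] = samples
    state["expression_truth"] = truth_expr
    for name, p in (
        ("counts", counts_path),
        ("samples", samples_path),
        ("expression_truth", truth_expr_path),
    ):
        _record(manifest, name, p)


def _require(config, state, key, path_attr, loader):
    if key in state:
        return state[key]
    path = getattr(config, path_attr)
    if path is None or not Path(path).exists():
        raise FileNotFoundError(
            f"stage input {key!r} unavailable: missing path {path_attr}={path}"
        )
    value = loader(path)
    state[key] = value
    return value


def _load_bundle(config):
    def loader(path):
        transcripts = annotation3ui.load_annotation(path, config.annotation_dialect)
        classes = {t.gene_id: "" for t in transcripts}
        return synthetic_data.AnnotationBundle(transcripts, classes)

    return loader


def _stage_classify(config, state, out_dir, manifest):
    bundle = _require(config, state, "bundle", "annotation_path", _load_bundle(config))
    selected = annotation3ui.select_isoforms(bundle.transcripts, "appris_any")
    # NMD-biotype isoforms carry no APPRIS label but still classify
    nmd = [t for t in bundle.transcripts if t.biotype == "nonsense_mediated_decay"]
    gene_calls = annotation3ui.classify_all(selected + nmd)
    state["gene_calls"] = gene_calls
    tsv = out_dir / "classification.tsv"
    annotation3ui.write_classification_tsv(gene_calls, tsv)
    bed = out_dir / "junctions.bed"
    annotation3ui.write_junction_bed(selected + nmd, bed)
    _record(manifest, "classification", tsv)
    _record(manifest, "junctions_bed", bed)


def _stage_ripmeta(config, state, out_dir, manifest):
    bundle = _require(config, state, "bundle", "annotation_path", _load_bundle(config))
    if "reads" in state:
        raw = [
            ripseq_profile.FootprintAlignment(
                r.chrom, r.start, r.end, r.strand, r.mapq, r.barcode, r.read_id
            )
            for r in state["reads"]
        ]
    else:
        if config.alignments_path is None or not Path(config.alignments_path).exists():
            raise FileNotFoundError(
                f"stage input 'alignments' unavailable: missing path "
                f"alignments_path={config.alignments_path}"
            )
        raw = ripseq_profile.read_sam(config.alignments_path)
    kept = ripseq_profile.filter_alignments(raw, config.min_mapq, config.min_read_len)
    unique = ripseq_profile.deduplicate_footprints(kept)
    profile = ripseq_profile.meta_exon_profile(
        unique, bundle.transcripts, window=config.meta_window
    )
    call = ripseq_profile.detect_deposition_site(profile)
    prof_path = out_dir / "meta_exon_profile.tsv"
    profile.to_frame().to_csv(prof_path, sep="\t", index=False, float_format="%.6g")
    call_path = out_dir / "deposition_call.json"
    call_path.write_text(
        json.dumps(
            {
                "mode_offset": call.mode_offset if call else None,
                "protected_interval": list(call.protected_interval) if call else None,
                "width": call.width if call else None,
                "n_reads": len(unique),
                "n_exons_used": profile.n_exons_used,
            },
            indent=2,
        )
        + "\n"
    )
    state["deposition_call"] = call
    _record(manifest, "meta_exon_profile", prof_path)
    _record(manifest, "deposition_call", call_path)


def _stage_dge(config, state, out_dir, manifest):
    if "counts" in state:
        counts, samples = state["counts"], state["samples"]
        m = dge.CountMatrix(
            counts,
            samples.set_index("sample_id")["genotype"],
            samples.set_index("sample_id")["replicate_group"],
        )
    else:
        for attr in ("counts_path", "samples_path"):
            p = getattr(config, attr)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(
                    f"stage input unavailable: missing path {attr}={p}"
                )
        m = dge.CountMatrix.from_tsv(config.counts_path, config.samples_path)
    results = dge.run_dge(
        m, config.unwanted_variation_k, config.fc_threshold, config.fdr_threshold
    )
    state["de_results"] = results
    de_path = out_dir / "de_results.tsv"
    dge.write_de_tsv(results, de_path)
    _record(manifest, "de_results", de_path)


def _stage_enrich(config, state, out_dir, manifest):
    if "de_results" not in state:
        raise FileNotFoundError("enrich stage requires the dge stage's results")
    results = state["de_results"]
    bundle = state.get("bundle")
    if bundle is not None and any(bundle.true_classes.values()):
        classes = bundle.true_classes
    elif "gene_calls" in state:
        classes = {g: c.gene_class.value for g, c in state["gene_calls"].items()}
    else:
        raise FileNotFoundError("enrich stage requires gene classes")

    fc = results["log2fc"].dropna()
    control = [g for g, c in classes.items() if c in ("INTRONLESS",)]
    shifts = []
    for label in ("PROXIMAL_3UI", "DISTAL_3UI", "NMD_BIOTYPE", "PROXIMAL", "DISTAL"):
        members = [g for g, c in classes.items() if c == label]
        if len(members) >= 3 and len(control) >= 3:
            shifts.append(
                class_enrichment.class_shift(fc, members, control, label=label)
            )
    shift_path = out_dir / "class_shift.tsv"
    class_enrichment.write_shift_tsv(shifts, shift_path)
    ecdf_path = out_dir / "class_ecdf.tsv"
    class_enrichment.write_ecdf_tsv(shifts, ecdf_path)
    state["shifts"] = shifts
    _record(manifest, "class_shift", shift_path)
    _record(manifest, "class_ecdf", ecdf_path)


_STAGES = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "ripmeta": _stage_ripmeta,
    "dge": _stage_dge,
    "enrich": _stage_enrich,
}
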