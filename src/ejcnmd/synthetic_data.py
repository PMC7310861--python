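"""Synthetic annotations, RIP-Seq footprints, and count matrices.

Everything downstream of alignment in the analysis pipeline is exercised on
data generated here with known ground truth:

* multi-exon gene structures on one synthetic chromosome, with 3'UTR-intron
  junction distances placed exactly where each requested NMD class demands;
* EJC footprint reads whose protected interval sits at a configurable
  offset upstream of exon 3' ends (default bases -29..-20, midpoint -24.5,
  matching the canonical EJC deposition site ~24 nt upstream of junctions),
  with PCR duplication tracked through 5-mer random barcodes;
* negative-binomial count matrices in which genotype effects are injected
  into designated gene classes.

All generation is driven by a single integer seed and is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotation3ui import (
    PROXIMAL_CUTOFF_NT,
    GenomicInterval,
    TranscriptClass,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

#: gene classes the generator knows how to build
GENE_CLASSES = (
    "INTRONLESS",
    "MULTIEXON_NO_3UI",
    "PROXIMAL_3UI",
    "DISTAL_3UI",
    "MULTI_3UI",
    "NMD_BIOTYPE",
    "UORF",
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DepositionGeometry:
    """Footprint geometry around exon 3' ends.

    ``protected_interval`` gives the first and last protected base as
    offsets relative to the exon 3' end (offset -1 = last exonic base), so
    the default (-29, -20) is a 10-nt region with midpoint -24.5.  Reads
    always cover the protected bases plus at least one flanking base on
    each side, so read 5' ends pile up at offsets <= -30 and 3' ends at
    offsets >= -19, leaving the protected interval depleted of read ends.
    """

    protected_interval: tuple[int, int] = (-29, -20)
    footprint_length_range: tuple[int, int] = (25, 45)
    background_fraction: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.protected_interval
        if not (lo < hi < 0):
            raise ValueError("protected interval must satisfy lo < hi < 0")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")
        if self.footprint_length_range[0] < self.width + 2:
            raise ValueError(
                "minimum footprint length must cover the protected interval "
                "plus one flanking base on each side"
            )

    @property
    def width(self) -> int:
        lo, hi = self.protected_interval
        return hi - lo + 1


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    ``class_composition`` maps gene class to gene count; ``class_effects``
    maps class to the log2 fold change injected into mutant samples.  The
    default design is the study's three-versus-three mutant/wild-type
    comparison.  ``dispersion`` is the NB dispersion alpha
    (var = mu + alpha mu^2), scalar or per-gene.
    """

    seed: int = 0
    class_composition: dict[str, int] = field(
        # 3'UI-containing and NMD-biotype genes are small minorities of a
        # vertebrate transcriptome (a few percent); the default composition
        # keeps the effect-bearing classes near 13% of genes so library-size
        # normalisation is not distorted by one-sided expression changes
        default_factory=lambda: {
            "INTRONLESS": 150,
            "MULTIEXON_NO_3UI": 600,
            "PROXIMAL_3UI": 50,
            "DISTAL_3UI": 50,
            "MULTI_3UI": 15,
            "NMD_BIOTYPE": 20,
            "UORF": 50,
        }
    )
    proximal_distances: list[int] = field(default_factory=lambda: [10, 20, 30, 40])
    distal_distances: list[int] = field(default_factory=lambda: [80, 150, 200, 400])
    deposition_geometry: DepositionGeometry = field(default_factory=DepositionGeometry)
    n_footprints: int = 100_000
    duplication_rate: float = 0.3
    genotypes: list[str] = field(
        default_factory=lambda: ["WT", "WT", "WT", "mutant", "mutant", "mutant"]
    )
    replicate_groups: Optional[list[str]] = None
    class_effects: dict[str, float] = field(
        default_factory=lambda: {"PROXIMAL_3UI": 1.0, "DISTAL_3UI": 1.5, "NMD_BIOTYPE": 1.5}
    )
    dispersion: float = 0.05
    depth: float = 1e6
    # optional technical batch structure: per-sample batch indicator plus the
    # sd of gene-specific batch log2 effects (0 disables the batch)
    batch_assignment: Optional[list[int]] = None
    batch_sd: float = 0.0

    def validate(self) -> None:
        if not self.class_composition or sum(self.class_composition.values()) <= 0:
            raise ValueError("class composition must request at least one gene")
        for cls, n in self.class_composition.items():
            if cls not in GENE_CLASSES:
                raise ValueError(f"unknown gene class {cls!r}")
            if n < 0:
                raise ValueError("gene counts must be >= 0")
        if any(not 0 <= d < PROXIMAL_CUTOFF_NT for d in self.proximal_distances):
            raise ValueError(
                f"proximal distances must lie in [0, {PROXIMAL_CUTOFF_NT})"
            )
        if any(d < PROXIMAL_CUTOFF_NT for d in self.distal_distances):
            raise ValueError(f"distal distances must be >= {PROXIMAL_CUTOFF_NT}")
        if not 0 <= self.duplication_rate < 1:
            raise ValueError("duplication_rate must be in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class AnnotationBundle:
    """Generated transcripts plus the ground-truth class per gene."""

    transcripts: list[TranscriptModel]
    true_classes: dict[str, str]  # gene_id -> requested generator class
    chrom: str = "chrSim"
    chrom_length: int = 0

    @property
    def genes(self) -> list[str]:
        return sorted(self.true_classes)

    def transcripts_of(self, gene_id: str) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.gene_id == gene_id]


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------


def generate_annotation(config: SimulationConfig) -> AnnotationBundle:
    """Build gene structures realising each requested class exactly.

    One isoform per gene on a single synthetic chromosome with inter-gene
    spacers; ~half the genes land on the minus strand.  Deterministic for a
    fixed seed: passing the result through the 50-nt classifier recovers
    every requested label.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    transcripts: list[TranscriptModel] = []
    true_classes: dict[str, str] = {}
    cursor = 1000
    chrom = "chrSim"
    idx = 0
    for cls in GENE_CLASSES:
        for _ in range(config.class_composition.get(cls, 0)):
            gid = f"G{idx:05d}"
            tid = f"T{idx:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            model, span = _build_gene(
                config, rng, cls, gid, tid, chrom, cursor, strand
            )
            transcripts.append(model)
            true_classes[gid] = cls
            cursor = span + int(rng.integers(500, 1500))
            idx += 1
    return AnnotationBundle(transcripts, true_classes, chrom, cursor + 1000)


def _build_gene(config, rng, cls, gid, tid, chrom, start, strand):
    """Lay out exon/intron structure for one gene of the requested class."""
    def exon_len():
        return int(rng.integers(160, 320))

    def intron_len():
        return int(rng.integers(80, 500))

    biotype = "protein_coding"
    appris = "principal1"

    if cls == "INTRONLESS":
        lens = [int(rng.integers(400, 1200))]
        d = None
        stop_exon = 0  # stop in the only exon
    elif cls in ("MULTIEXON_NO_3UI", "UORF"):
        n = int(rng.integers(3, 8))
        lens = [exon_len() for _ in range(n)]
        d = None
        stop_exon = n - 1  # stop in last exon -> no downstream junction
    elif cls in ("PROXIMAL_3UI", "DISTAL_3UI", "NMD_BIOTYPE"):
        n = int(rng.integers(3, 8))
        lens = [exon_len() for _ in range(n)]
        pool = (
            config.proximal_distances
            if cls == "PROXIMAL_3UI"
            else config.distal_distances
        )
        d = int(pool[int(rng.integers(len(pool)))])
        # stop sits in the penultimate exon, d nt before its 3' end
        lens[n - 2] = max(lens[n - 2], d + 80)
        stop_exon = n - 2
        if cls == "NMD_BIOTYPE":
            biotype = "nonsense_mediated_decay"
            appris = None
    elif cls == "MULTI_3UI":
        n = int(rng.integers(4, 8))
        lens = [exon_len() for _ in range(n)]
        d = int(rng.integers(5, 100))
        lens[n - 3] = max(lens[n - 3], d + 80)
        stop_exon = n - 3  # two junctions downstream of the stop
    else:  # pragma: no cover
        raise ValueError(cls)

    # `lens` and `stop_exon` are in transcription order; lay the exons out
    # genomically (ascending) and then orient by strand
    lens_genomic = lens if strand == "+" else lens[::-1]
    genomic = []
    pos = start
    for L in lens_genomic:
        genomic.append((pos, pos + L))
        pos += L + intron_len()
    span_end = genomic[-1][1]
    exons_tx = genomic if strand == "+" else genomic[::-1]
    lens_tx = [e - s for s, e in exons_tx]

    # stop placement in transcription coordinates
    if d is None:
        # stop inside the stop_exon, comfortably clear of its 3' end
        margin = int(rng.integers(30, max(31, lens_tx[stop_exon] - 60)))
        into = lens_tx[stop_exon] - margin
    else:
        into = lens_tx[stop_exon] - d
    s, e = exons_tx[stop_exon]
    stop_end = (s + into) if strand == "+" else (e - into)

    exon_ivals = [GenomicInterval(chrom, s, e, strand) for s, e in exons_tx]
    model = TranscriptModel(tid, gid, exon_ivals, stop_end, appris, biotype)
    model.validate()
    return model, span_end


def write_gtf(bundle: AnnotationBundle, path: str | Path) -> None:
    """Emit the bundle as GTF (1-based inclusive coordinates)."""
    lines = []
    for t in sorted(bundle.transcripts, key=lambda t: t.transcript_id):
        genomic = sorted(t.exons, key=lambda e: e.start)
        g_start, g_end = genomic[0].start + 1, genomic[-1].end
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'transcript_biotype "{t.biotype}";'
        )
        if t.appris_label:
            attrs += f' appris "{t.appris_label}";'
        for feat, fs, fe in (("gene", g_start, g_end), ("transcript", g_start, g_end)):
            lines.append(
                f"{t.chrom}\tejcnmd_sim\t{feat}\t{fs}\t{fe}\t.\t{t.strand}\t.\t{attrs}"
            )
        for e in genomic:
            lines.append(
                f"{t.chrom}\tejcnmd_sim\texon\t{e.start + 1}\t{e.end}\t.\t"
                f"{t.strand}\t.\t{attrs}"
            )
        if t.stop_end is not None:
            if t.strand == "+":
                sc = (t.stop_end - 3 + 1, t.stop_end)
                cds = (g_start, t.stop_end - 3)
            else:
                sc = (t.stop_end + 1, t.stop_end + 3)
                cds = (t.stop_end + 4, g_end)
            lines.append(
                f"{t.chrom}\tejcnmd_sim\tCDS\t{cds[0]}\t{cds[1]}\t.\t{t.strand}\t0\t{attrs}"
            )
            lines.append(
                f"{t.chrom}\tejcnmd_sim\tstop_codon\t{sc[0]}\t{sc[1]}\t.\t"
                f"{t.strand}\t0\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# RIP-Seq footprint simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated aligned footprint read."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    barcode: str
    molecule_id: int
    mapq: int = 60


def simulate_rip_footprints(
    annotation: AnnotationBundle,
    geometry: DepositionGeometry = DepositionGeometry(),
    n: int = 100_000,
    duplication_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Simulate n footprint molecules plus their PCR duplicates.

    Each non-background molecule spans the protected interval of a random
    junction (the 3' end of a non-terminal exon of a multi-exon gene),
    extending randomly within the footprint length range but staying inside
    the exon.  Background molecules land uniformly on exonic positions.
    PCR duplicates share coordinates and the 5-mer random barcode; the
    returned truth table maps each read to its molecule for exact dedup
    validation.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    lo, hi = geometry.protected_interval
    min_len, max_len = geometry.footprint_length_range
    if min_len < geometry.width + 2:
        raise ValueError("footprint shorter than protected interval plus flanks")

    junction_exons = []  # (exon, strand) for every non-terminal exon
    all_exons = []
    for t in annotation.transcripts:
        all_exons.extend(t.exons)
        if t.n_exons >= 2:
            junction_exons.extend(t.exons[:-1])
    if not junction_exons:
        raise ValueError("annotation contains no multi-exon gene")

    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    truth = []
    exon_lengths = np.array([len(e) for e in all_exons], dtype=float)
    exon_p = exon_lengths / exon_lengths.sum()

    n_background = rng.binomial(n, geometry.background_fraction)
    kinds = np.concatenate(
        [np.zeros(n - n_background, dtype=int), np.ones(n_background, dtype=int)]
    )
    rng.shuffle(kinds)
    # duplicates per molecule: geometric, mean 1/(1 - duplication_rate)
    copies = (
        rng.geometric(1.0 - duplication_rate, size=n)
        if duplication_rate > 0
        else np.ones(n, dtype=int)
    )
    barcodes = _random_barcodes(rng, n)

    for mol in range(n):
        if kinds[mol] == 0:
            exon = junction_exons[int(rng.integers(len(junction_exons)))]
            L = int(rng.integers(min_len, max_len + 1))
            # 5' end at offset <= lo - 1, 3' end at offset in [hi + 1, -1]
            s_hi = min(lo - 1, -L)  # keep the read inside the exon
            s_lo = max(hi + 2 - L, -len(exon))
            if s_lo > s_hi:  # exon too short for this length; clamp
                s_lo = s_hi
            s = int(rng.integers(s_lo, s_hi + 1))
            start, end = _offsets_to_genomic(exon, s, s + L - 1)
            strand = exon.strand
        else:
            exon = all_exons[int(rng.choice(len(all_exons), p=exon_p))]
            L = int(rng.integers(min_len, max_len + 1))
            L = min(L, len(exon))
            off = int(rng.integers(0, len(exon) - L + 1))
            start, end = exon.start + off, exon.start + off + L
            strand = exon.strand
        bc = barcodes[mol]
        for c in range(copies[mol]):
            rid = f"mol{mol:07d}c{c}_{bc}"
            reads.append(
                SimulatedRead(rid, annotation.chrom, start, end, strand, bc, mol)
            )
            truth.append((rid, mol, kinds[mol] == 1))

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth_df = pd.DataFrame(
        [truth[i] for i in order], columns=["read_id", "molecule_id", "background"]
    )
    return reads, truth_df


def _offsets_to_genomic(exon: GenomicInterval, s: int, e_off: int) -> tuple[int, int]:
    """Map inclusive offsets (relative to the exon 3' end, -1 = last base)."""
    if exon.strand == "+":
        return exon.end + s, exon.end + e_off + 1
    return exon.start - e_off - 1, exon.start - s


def _random_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, 4, size=(n, 5))
    return ["".join(row) for row in _BASES[idx]]


def write_sam(
    reads: list[SimulatedRead],
    chrom_length: int,
    path: str | Path,
    chrom: str = "chrSim",
) -> None:
    """Write reads as plain SAM with the barcode in RX and the read name."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": chrom, "LN": int(chrom_length)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.read_id
            a.reference_id = 0
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.cigarstring = f"{r.end - r.start}M"
            a.flag = 16 if r.strand == "-" else 0
            a.query_sequence = "N" * (r.end - r.start)
            a.set_tag("RX", r.barcode)
            fh.write(a)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(
    annotation: AnnotationBundle,
    config: SimulationConfig,
    level: str = "gene",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an NB count matrix (or transcript quantification table).

    Gene baselines are log-normal; sample j's expected count for gene i is
    ``depth_j * baseline_i * 2^(effect_i * mutant_j)`` with baselines
    normalised to sum to one per wild-type library.  Counts are
    gamma-Poisson with dispersion alpha (var = mu + alpha mu^2).

    Returns ``(counts, truth)`` at gene level, where counts is genes x
    samples and truth carries the per-gene class and injected log2FC; at
    transcript level returns a quantification table (TPM, log2FC estimate,
    q-value, PTC and 3'UI flags) plus truth.
    """
    config.validate()
    genotypes = config.genotypes
    for g in set(genotypes):
        if genotypes.count(g) < 2:
            raise ValueError("need >= 2 samples per genotype")
    for cls in config.class_effects:
        if cls not in GENE_CLASSES:
            raise ValueError(f"class_effects references unknown class {cls!r}")
    if level == "gene":
        return _simulate_gene_counts(annotation, config)
    if level == "transcript":
        return _simulate_transcript_quant(annotation, config)
    raise ValueError(f"unknown level {level!r}")


def _nb_draw(rng, mu, alpha):
    if alpha <= 0:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mu)
    return rng.poisson(lam)


def _simulate_gene_counts(annotation, config):
    rng = np.random.default_rng(config.seed + 1)
    genes = annotation.genes
    n_genes = len(genes)
    baseline = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    baseline /= baseline.sum()
    effects = np.array(
        [config.class_effects.get(annotation.true_classes[g], 0.0) for g in genes]
    )
    is_mut = np.array([g == "mutant" for g in config.genotypes], dtype=float)
    mu = (
        config.depth
        * baseline[:, None]
        * np.power(2.0, effects[:, None] * is_mut[None, :])
    )
    if config.batch_assignment is not None and config.batch_sd > 0:
        batch = np.asarray(config.batch_assignment, dtype=float)
        if batch.shape[0] != len(config.genotypes):
            raise ValueError("batch_assignment length must match samples")
        beta = rng.normal(0.0, config.batch_sd, size=n_genes)
        mu = mu * np.power(2.0, beta[:, None] * batch[None, :])
    alpha = np.broadcast_to(np.asarray(config.dispersion, dtype=float), (n_genes,))
    counts = np.empty(mu.shape, dtype=int)
    for i in range(n_genes):
        counts[i] = _nb_draw(rng, mu[i], float(alpha[i]))
    sample_ids = [
        f"{g}_{j}" for j, g in enumerate(config.genotypes)
    ]
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "class": [annotation.true_classes[g] for g in genes],
            "true_log2fc": effects,
            "baseline": baseline,
        }
    ).set_index("gene_id")
    return counts_df, truth


def _simulate_transcript_quant(annotation, config):
    """Two isoforms per 3'UI gene: the 3'UI+ isoform and a 3'UI- sibling.

    The class effect shifts only the 3'UI+ isoform; PTC flags follow the
    study's convention (distal 3'UI isoforms are PTC+, proximal are PTC-).
    """
    from .annotation3ui import call_transcript

    rng = np.random.default_rng(config.seed + 2)
    rows = []
    truth_rows = []
    noise_sd = 0.25
    for t in sorted(annotation.transcripts, key=lambda t: t.transcript_id):
        cls = annotation.true_classes[t.gene_id]
        call = call_transcript(t)
        has_3ui = call.transcript_class != TranscriptClass.NONE
        effect = config.class_effects.get(cls, 0.0)
        tpm = float(rng.lognormal(2.0, 1.0))
        fc_3ui = effect + float(rng.normal(0, noise_sd))
        fc_ctrl = float(rng.normal(0, noise_sd))
        ptc = call.transcript_class == TranscriptClass.DISTAL
        rows.append(
            dict(
                transcript_id=t.transcript_id,
                gene_id=t.gene_id,
                tpm_control=tpm,
                log2fc=fc_3ui if has_3ui else fc_ctrl,
                qvalue=float(rng.uniform(0, 1)) if not has_3ui or effect == 0 else float(rng.uniform(0, 0.05)),
                ptc_flag=ptc,
                has_3ui=has_3ui,
                utr3_class=call.transcript_class.value,
            )
        )
        truth_rows.append(
            dict(transcript_id=t.transcript_id, gene_id=t.gene_id, true_log2fc=effect if has_3ui else 0.0)
        )
        if has_3ui:
            # 3'UI-lacking sibling isoform from the same gene
            sib = f"{t.transcript_id}_ctrl"
            rows.append(
                dict(
                    transcript_id=sib,
                    gene_id=t.gene_id,
                    tpm_control=float(rng.lognormal(2.0, 1.0)),
                    log2fc=float(rng.normal(0, noise_sd)),
                    qvalue=float(rng.uniform(0, 1)),
                    ptc_flag=False,
                    has_3ui=False,
                    utr3_class=TranscriptClass.NONE.value,
                )
            )
            truth_rows.append(
                dict(transcript_id=sib, gene_id=t.gene_id, true_log2fc=0.0)
            )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_uorf_table(
    annotation: AnnotationBundle, seed: int = 0
) -> pd.DataFrame:
    """Ribosome-profiling summary rows: UORF-class genes pass the filter."""
    rng = np.random.default_rng(seed + 3)
    rows = []
    for g in annotation.genes:
        is_uorf = annotation.true_classes[g] == "UORF"
        if is_uorf:
            rows.append(
                dict(
                    gene_id=g,
                    utr5_rpf_rpkm=float(rng.uniform(5, 50)),
                    rna_rpkm=float(rng.uniform(5, 50)),
                    rpf_rpkm=float(rng.uniform(5, 50)),
                    te=float(rng.uniform(1.01, 5)),
                )
            )
        else:
            rows.append(
                dict(
                    gene_id=g,
                    utr5_rpf_rpkm=float(rng.uniform(0, 4.9)),
                    rna_rpkm=float(rng.uniform(0, 50)),
                    rpf_rpkm=float(rng.uniform(0, 50)),
                    te=float(rng.uniform(0, 2)),
                )
            )
    return pd.DataFrame(rows)
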