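"""Annotation parsing and NMD-relevant transcript/gene classification.

The central object is the :class:`TranscriptModel`: one isoform's exon
structure plus the genomic position where translation termination ends
(``stop_end``).  From it we compute spliced (exonic) distances from the stop
codon to every downstream exon-exon junction and classify transcripts by the
50-nt rule of nonsense-mediated decay (NMD):

* ``PROXIMAL`` — exactly one 3'UTR intron whose junction lies < 50 spliced nt
  downstream of the stop codon;
* ``DISTAL``  — one junction >= 50 nt away, or more than one 3'UTR intron
  irrespective of distance;
* ``NONE``    — no junction downstream of the stop.

Gene-level calls aggregate transcript calls with DISTAL taking precedence
over PROXIMAL; genes whose isoforms are all single-exon are ``INTRONLESS``.
An Ensembl ``nonsense_mediated_decay`` biotype is reported as an independent
flag, not as a value of the proximal/distal partition.

Coordinates are 0-based half-open internally.  ``stop_end`` is the genomic
coordinate of the first base after the stop codon's last base in
transcription direction: on ``+`` it equals the half-open end of the stop
codon; on ``-`` it equals the 0-based start of the stop codon (bases at
lower coordinates are downstream).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

PROXIMAL_CUTOFF_NT = 50


class TranscriptClass(str, Enum):
    NONE = "NONE"
    PROXIMAL = "PROXIMAL"
    DISTAL = "DISTAL"


class GeneClass(str, Enum):
    INTRONLESS = "INTRONLESS"
    NO_3UI = "NO_3UI"
    PROXIMAL = "PROXIMAL"
    DISTAL = "DISTAL"


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """One isoform: exons in transcription order plus stop-codon position.

    ``exons`` are ascending by genomic coordinate on ``+`` strands and
    descending on ``-``.  ``stop_end`` may be ``None`` for non-coding
    isoforms.  ``stop_split`` marks transcripts whose stop codon is
    interrupted by an intron.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    stop_end: Optional[int] = None
    appris_label: Optional[str] = None
    biotype: str = "protein_coding"
    stop_split: bool = False

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def validate(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        strand = self.exons[0].strand
        chrom = self.exons[0].chrom
        for e in self.exons:
            if e.strand != strand or e.chrom != chrom:
                raise ValueError(
                    f"{self.transcript_id}: exons on mixed chrom/strand"
                )
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        expected = genomic if strand == "+" else genomic[::-1]
        if self.exons != expected:
            raise ValueError(
                f"{self.transcript_id}: exons not in transcription order"
            )

    # -- spliced coordinate helpers ------------------------------------

    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def genomic_to_spliced(self, pos: int) -> int:
        """Map a genomic coordinate to a 0-based spliced offset.

        On ``+`` strands ``pos`` follows the half-open convention (it may
        equal an exon end, mapping to the offset just past that exon); on
        ``-`` strands ``pos`` marks the boundary the same way but in
        descending coordinates (it may equal an exon start).
        """
        offset = 0
        for e in self.exons:
            if self.strand == "+":
                if e.start <= pos <= e.end:
                    return offset + (pos - e.start)
            else:
                if e.start <= pos <= e.end:
                    return offset + (e.end - pos)
            offset += len(e)
        raise ValueError(
            f"{self.transcript_id}: position {pos} outside exon union"
        )

    def spliced_to_genomic(self, offset: int) -> int:
        """Inverse of :meth:`genomic_to_spliced` (boundary maps downstream)."""
        if not 0 <= offset <= self.spliced_length():
            raise ValueError(f"{self.transcript_id}: offset {offset} out of range")
        last = len(self.exons) - 1
        for i, e in enumerate(self.exons):
            # exact exon-end boundaries map downstream (next exon's start)
            if offset < len(e) or (offset == len(e) and i == last):
                return e.start + offset if self.strand == "+" else e.end - offset
            offset -= len(e)
        raise AssertionError("unreachable")


@dataclass
class UTRIntronCall:
    """Per-transcript 3'UTR-intron classification."""

    transcript_id: str
    gene_id: str
    junction_distances: list[int]
    transcript_class: TranscriptClass
    stop_split: bool = False


@dataclass
class GeneCall:
    gene_id: str
    gene_class: GeneClass
    nmd_biotype: bool
    transcript_calls: list[UTRIntronCall] = field(default_factory=list)


@dataclass(frozen=True)
class UORFTableRow:
    """Ribosome-profiling summary for one uORF-bearing gene.

    ``utr5_rpf_rpkm``: ribosome footprint density over the 5'UTR;
    ``rna_rpkm``/``rpf_rpkm``: RNA-Seq and footprint density over the ORF;
    ``te``: translation efficiency (RPF/RNA, dimensionless).
    """

    gene_id: str
    utr5_rpf_rpkm: float
    rna_rpkm: float
    rpf_rpkm: float
    te: float


@dataclass(frozen=True)
class TranscriptQuantRow:
    """One transcript in an external quantification table."""

    transcript_id: str
    gene_id: str
    tpm_control: float
    log2fc: float
    qvalue: Optional[float]
    ptc_flag: bool
    has_3ui: bool
    utr3_class: TranscriptClass = TranscriptClass.NONE


@dataclass(frozen=True)
class IsoformPair:
    gene_id: str
    utr3_isoform: TranscriptQuantRow
    control_isoform: TranscriptQuantRow


@dataclass(frozen=True)
class ClearanceConstants:
    """Geometry of the terminating ribosome and the EJC at a junction.

    ``ribosome_3prime_extension``: nt the ribosome footprint extends past
    the stop codon into the 3'UTR (default 9).  ``ejc_5prime_boundary``:
    nt upstream of the exon-exon junction where the EJC-protected region
    begins (default 27).
    """

    ribosome_3prime_extension: int = 9
    ejc_5prime_boundary: int = 27

    def __post_init__(self) -> None:
        if self.ribosome_3prime_extension < 0 or self.ejc_5prime_boundary < 0:
            raise ValueError("clearance constants must be non-negative")


# ---------------------------------------------------------------------------
# Annotation loading
# ---------------------------------------------------------------------------

_TSV_COLUMNS = {
    "transcript_id": "transcript_id",
    "gene_id": "gene_id",
    "chrom": "chrom",
    "strand": "strand",
    "exon_starts": "exon_starts",
    "exon_ends": "exon_ends",
    "cds_start": "cds_start",
    "cds_end": "cds_end",
    "appris": "appris",
    "biotype": "biotype",
}


def load_annotation(
    path: str | Path,
    dialect: str = "gtf",
    columns: Optional[Mapping[str, str]] = None,
) -> list[TranscriptModel]:
    """Load transcript models from a GTF file or an Ensembl-export TSV.

    GTF: 1-based inclusive coordinates; ``stop_end`` comes from the
    ``stop_codon`` feature when present, otherwise from the CDS 3' end
    advanced 3 spliced nt (flagging ``stop_split`` when that walk crosses a
    junction).  TSV: one row per transcript with comma-separated 1-based
    inclusive ``exon_starts``/``exon_ends`` and a CDS span that *includes*
    the stop codon, so ``stop_end`` converts directly from ``cds_end``
    (``cds_start`` on ``-`` strands).  Rows whose CDS falls outside the exon
    union are skipped with a warning; a missing mandatory column is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if dialect == "gtf":
        return _load_gtf(path)
    if dialect == "ensembl_tsv":
        return _load_ensembl_tsv(path, columns or _TSV_COLUMNS)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _load_gtf(path: Path) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    out: list[TranscriptModel] = []
    for tx in db.features_of_type("transcript"):
        tid = tx.attributes.get("transcript_id", [tx.id])[0]
        gid = tx.attributes.get("gene_id", ["?"])[0]
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
            for e in db.children(tx, featuretype="exon")
        ]
        if not exons:
            logger.warning("transcript %s has no exons; skipped", tid)
            continue
        strand = exons[0].strand
        exons.sort(key=lambda e: e.start, reverse=(strand == "-"))
        stops = list(db.children(tx, featuretype="stop_codon"))
        cds = list(db.children(tx, featuretype="CDS"))
        appris = tx.attributes.get("appris", [None])[0]
        biotype = tx.attributes.get(
            "transcript_biotype", tx.attributes.get("biotype", ["protein_coding"])
        )[0]
        model = TranscriptModel(tid, gid, exons, None, appris, biotype)
        try:
            model.validate()
            model.stop_end, model.stop_split = _stop_end_from_gtf(
                model, stops, cds
            )
        except ValueError as err:
            logger.warning("skipping transcript %s: %s", tid, err)
            continue
        out.append(model)
    return out


def _stop_end_from_gtf(model, stops, cds) -> tuple[Optional[int], bool]:
    strand = model.strand
    if stops:
        split = len(stops) > 1
        if strand == "+":
            return max(s.end for s in stops), split
        return min(s.start for s in stops) - 1, split
    if not cds:
        return None, False
    # CDS excludes the stop codon in GTF: advance its 3' end 3 spliced nt.
    if strand == "+":
        cds_3p = max(c.end for c in cds)  # half-open end already
    else:
        cds_3p = min(c.start for c in cds) - 1
    spliced = model.genomic_to_spliced(cds_3p)
    stop_end = model.spliced_to_genomic(spliced + 3)
    # split if the three stop bases do not sit in one exon
    split = not any(
        (e.start <= min(cds_3p, stop_end) and max(cds_3p, stop_end) <= e.end)
        for e in model.exons
    )
    return stop_end, split


def _load_ensembl_tsv(path: Path, cols: Mapping[str, str]) -> list[TranscriptModel]:
    out: list[TranscriptModel] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [
            c
            for k, c in cols.items()
            if k not in ("appris", "biotype") and c not in (reader.fieldnames or [])
        ]
        if missing:
            raise ValueError(f"missing mandatory columns: {missing}")
        for row in reader:
            tid = row[cols["transcript_id"]]
            try:
                model = _tsv_row_to_model(row, cols)
                model.validate()
            except ValueError as err:
                logger.warning("skipping row %s: %s", tid, err)
                continue
            out.append(model)
    return out


def _tsv_row_to_model(row: Mapping[str, str], cols: Mapping[str, str]) -> TranscriptModel:
    chrom = row[cols["chrom"]]
    strand = row[cols["strand"]]
    starts = [int(x) for x in row[cols["exon_starts"]].split(",") if x]
    ends = [int(x) for x in row[cols["exon_ends"]].split(",") if x]
    if len(starts) != len(ends):
        raise ValueError("exon_starts/exon_ends length mismatch")
    exons = [
        GenomicInterval(chrom, s - 1, e, strand) for s, e in zip(starts, ends)
    ]
    exons.sort(key=lambda e: e.start, reverse=(strand == "-"))
    cds_start_raw = row.get(cols["cds_start"], "")
    cds_end_raw = row.get(cols["cds_end"], "")
    stop_end: Optional[int] = None
    if cds_start_raw and cds_end_raw:
        cds_start = int(cds_start_raw) - 1  # to 0-based
        cds_end = int(cds_end_raw)  # 1-based inclusive == 0-based half-open end
        lo = min(e.start for e in exons)
        hi = max(e.end for e in exons)
        if cds_start < lo or cds_end > hi:
            raise ValueError("CDS outside exon union")
        # dialect: CDS span includes the stop codon
        stop_end = cds_end if strand == "+" else cds_start
    appris = row.get(cols.get("appris", "appris")) or None
    biotype = row.get(cols.get("biotype", "biotype")) or "protein_coding"
    return TranscriptModel(
        row[cols["transcript_id"]],
        row[cols["gene_id"]],
        exons,
        stop_end,
        appris,
        biotype,
    )


# ---------------------------------------------------------------------------
# Isoform selection
# ---------------------------------------------------------------------------


def select_isoforms(
    transcripts: Iterable[TranscriptModel], mode: str = "appris_any"
) -> list[TranscriptModel]:
    """Filter isoforms by APPRIS annotation.

    ``appris_any`` keeps every transcript carrying any APPRIS label;
    ``appris_principal`` keeps exactly one P1 ("principal1") transcript per
    gene, breaking ties by smallest transcript_id (logged).
    """
    transcripts = list(transcripts)
    if mode == "appris_any":
        return [t for t in transcripts if t.appris_label]
    if mode == "appris_principal":
        per_gene: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            if t.appris_label and t.appris_label.lower() in ("principal1", "p1"):
                per_gene.setdefault(t.gene_id, []).append(t)
        out = []
        for gid, cands in per_gene.items():
            cands.sort(key=lambda t: t.transcript_id)
            if len(cands) > 1:
                logger.warning(
                    "gene %s has %d P1 isoforms; keeping %s",
                    gid,
                    len(cands),
                    cands[0].transcript_id,
                )
            out.append(cands[0])
        return out
    raise ValueError(f"unknown isoform selection mode {mode!r}")


# ---------------------------------------------------------------------------
# 3'UTR junction distances and classification
# ---------------------------------------------------------------------------


def find_3utr_junctions(t: TranscriptModel) -> list[int]:
    """Spliced nt from the stop codon's end to each downstream junction.

    Distances exclude the stop codon itself: the first 3'UTR base is offset
    0, so a junction immediately after the stop has distance 0 (included).
    Junctions upstream of the stop are excluded; a junction interrupting the
    stop codon itself is excluded and the transcript is flagged upstream at
    load time (``stop_split``).
    """
    if t.stop_end is None:
        raise ValueError(f"{t.transcript_id}: no stop_end")
    if t.stop_split:
        logger.warning(
            "transcript %s: stop codon split across a junction", t.transcript_id
        )
    stop_spliced = t.genomic_to_spliced(t.stop_end)
    total = t.spliced_length()
    distances = []
    offset = 0
    for e in t.exons[:-1]:  # a junction follows every exon but the last
        offset += len(e)
        d = offset - stop_spliced
        if d >= 0:
            distances.append(d)
    assert all(d <= total for d in distances)
    return distances


def classify_transcript(distances: Sequence[int]) -> TranscriptClass:
    """Apply the 50-nt rule to a transcript's 3'UTR junction distances."""
    if any(d < 0 for d in distances):
        raise ValueError("negative junction distance")
    if not distances:
        return TranscriptClass.NONE
    if len(distances) == 1:
        return (
            TranscriptClass.PROXIMAL
            if distances[0] < PROXIMAL_CUTOFF_NT
            else TranscriptClass.DISTAL
        )
    return TranscriptClass.DISTAL


def call_transcript(t: TranscriptModel) -> UTRIntronCall:
    distances = find_3utr_junctions(t)
    return UTRIntronCall(
        t.transcript_id,
        t.gene_id,
        distances,
        classify_transcript(distances),
        t.stop_split,
    )


def classify_gene(
    transcripts: Sequence[TranscriptModel],
    calls: Optional[Sequence[UTRIntronCall]] = None,
) -> GeneCall:
    """Aggregate transcript calls to a gene class with DISTAL precedence.

    DISTAL if any transcript is DISTAL; else PROXIMAL if any is PROXIMAL;
    else INTRONLESS if every isoform is single-exon; else NO_3UI.  An NMD
    biotype on any isoform is reported as an independent flag.
    """
    if not transcripts:
        raise ValueError("gene has no transcripts")
    gene_id = transcripts[0].gene_id
    if calls is None:
        calls = [call_transcript(t) for t in transcripts if t.stop_end is not None]
    classes = {c.transcript_class for c in calls}
    if TranscriptClass.DISTAL in classes:
        gc = GeneClass.DISTAL
    elif TranscriptClass.PROXIMAL in classes:
        gc = GeneClass.PROXIMAL
    elif all(t.n_exons == 1 for t in transcripts):
        gc = GeneClass.INTRONLESS
    else:
        gc = GeneClass.NO_3UI
    nmd = any(t.biotype == "nonsense_mediated_decay" for t in transcripts)
    return GeneCall(gene_id, gc, nmd, list(calls))


def classify_all(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, GeneCall]:
    """Classify every gene in a transcript collection."""
    per_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        per_gene.setdefault(t.gene_id, []).append(t)
    return {gid: classify_gene(txs) for gid, txs in sorted(per_gene.items())}


# ---------------------------------------------------------------------------
# Cross-species conservation
# ---------------------------------------------------------------------------


def intersect_conserved_proximal(
    class_tables: Mapping[str, Mapping[str, GeneClass]],
    ortholog_map: Sequence[Mapping[str, str]],
    reference_species: Optional[str] = None,
) -> set[str]:
    """Genes whose PROXIMAL 3'UI status is conserved in every species.

    ``class_tables`` maps species name -> {gene_id: GeneClass};
    ``ortholog_map`` is a sequence of rows mapping species name -> gene id
    (one row per ortholog link; one-to-many mappings appear as multiple
    rows).  A gene is conserved only if every mapped ortholog in every
    species is PROXIMAL; a missing link excludes the gene (logged).  A
    species present in ``class_tables`` but absent from the map columns is a
    fatal error.
    """
    species = list(class_tables)
    if reference_species is None:
        reference_species = species[0]
    for row in ortholog_map:
        for sp in species:
            if sp not in row:
                raise ValueError(f"species {sp!r} missing from ortholog map")
        break
    else:
        return set()

    by_ref: dict[str, list[Mapping[str, str]]] = {}
    for row in ortholog_map:
        ref_id = row[reference_species]
        if ref_id:
            by_ref.setdefault(ref_id, []).append(row)

    conserved = set()
    for ref_id, rows in by_ref.items():
        ok = True
        for row in rows:
            for sp in species:
                gid = row.get(sp, "")
                if not gid or class_tables[sp].get(gid) != GeneClass.PROXIMAL:
                    if not gid:
                        logger.info(
                            "gene %s: missing %s ortholog; not conserved",
                            ref_id,
                            sp,
                        )
                    ok = False
                    break
            if not ok:
                break
        if ok:
            conserved.add(ref_id)
    return conserved


# ---------------------------------------------------------------------------
# uORF gene filter
# ---------------------------------------------------------------------------


def filter_uorf_genes(
    rows: Iterable[UORFTableRow],
    min_utr5_rpf_rpkm: float = 5.0,
    min_rna_rpkm: float = 5.0,
    min_rpf_rpkm: float = 5.0,
    min_te: float = 1.0,
) -> set[str]:
    """Genes with translated uORFs: three RPKM filters at >= and TE strictly >."""
    kept = set()
    for r in rows:
        vals = (r.utr5_rpf_rpkm, r.rna_rpkm, r.rpf_rpkm, r.te)
        if any(v < 0 for v in vals):
            raise ValueError(f"{r.gene_id}: negative value in uORF table")
        if (
            r.utr5_rpf_rpkm >= min_utr5_rpf_rpkm
            and r.rna_rpkm >= min_rna_rpkm
            and r.rpf_rpkm >= min_rpf_rpkm
            and r.te > min_te
        ):
            kept.add(r.gene_id)
    return kept


# ---------------------------------------------------------------------------
# Isoform pairing
# ---------------------------------------------------------------------------


def pair_isoforms(
    quant: Iterable[TranscriptQuantRow],
) -> tuple[list[IsoformPair], dict[str, int]]:
    """Pair each eligible 3'UI+ isoform with its gene's best 3'UI- control.

    Rows lacking a q-value are removed.  A gene is eligible when it has
    exactly one detectable 3'UI-containing isoform; proximal isoforms must
    lack a PTC and distal isoforms must carry one.  The control is the
    3'UI-lacking isoform with the highest control-sample TPM.  Returns the
    pairs plus a counter of genes skipped per reason.
    """
    rows = [r for r in quant if r.qvalue is not None]
    skipped = {"no_qvalue_gene": 0, "multi_3ui": 0, "ptc_mismatch": 0, "no_control": 0}
    per_gene: dict[str, list[TranscriptQuantRow]] = {}
    for r in rows:
        per_gene.setdefault(r.gene_id, []).append(r)

    pairs: list[IsoformPair] = []
    for gid, rs in sorted(per_gene.items()):
        utr3 = [r for r in rs if r.has_3ui]
        if len(utr3) != 1:
            if len(utr3) > 1:
                skipped["multi_3ui"] += 1
            continue
        iso = utr3[0]
        if iso.utr3_class == TranscriptClass.PROXIMAL and iso.ptc_flag:
            skipped["ptc_mismatch"] += 1
            continue
        if iso.utr3_class == TranscriptClass.DISTAL and not iso.ptc_flag:
            skipped["ptc_mismatch"] += 1
            continue
        controls = [r for r in rs if not r.has_3ui]
        if not controls:
            skipped["no_control"] += 1
            continue
        control = max(controls, key=lambda r: (r.tpm_control, r.transcript_id))
        pairs.append(IsoformPair(gid, iso, control))
    return pairs, skipped


# ---------------------------------------------------------------------------
# Ribosome/EJC clearance arithmetic
# ---------------------------------------------------------------------------


def ribosome_ejc_clearance(c: ClearanceConstants = ClearanceConstants()) -> int:
    """Smallest stop-to-junction distance with no ribosome/EJC overlap.

    The terminating ribosome's footprint extends
    ``ribosome_3prime_extension`` nt past the stop codon; the EJC-protected
    region begins ``ejc_5prime_boundary`` nt upstream of the junction.  At a
    stop-to-junction distance d the two are disjoint iff
    d >= extension + boundary, so the minimal non-overlap distance is their
    sum (36 nt with the defaults).
    """
    return c.ribosome_3prime_extension + c.ejc_5prime_boundary


def ribosome_ejc_overlap(d: int, c: ClearanceConstants = ClearanceConstants()) -> bool:
    """True when a stop-to-junction distance d leaves ribosome and EJC overlapping."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return d < ribosome_ejc_clearance(c)


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------


def write_classification_tsv(
    gene_calls: Mapping[str, GeneCall], path: str | Path
) -> None:
    """Per-gene and per-transcript classification TSV."""
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tgene_class\tnmd_biotype\ttranscript_id\t"
            "transcript_class\tjunction_distances\n"
        )
        for gid, call in sorted(gene_calls.items()):
            if not call.transcript_calls:
                fh.write(f"{gid}\t{call.gene_class.value}\t{int(call.nmd_biotype)}\t.\t.\t.\n")
            for tc in call.transcript_calls:
                dists = ",".join(map(str, tc.junction_distances)) or "."
                fh.write(
                    f"{gid}\t{call.gene_class.value}\t{int(call.nmd_biotype)}\t"
                    f"{tc.transcript_id}\t{tc.transcript_class.value}\t{dists}\n"
                )


def write_junction_bed(
    transcripts: Iterable[TranscriptModel], path: str | Path
) -> None:
    """BED (0-based half-open) of 3'UI junction first intronic bases."""
    with open(path, "w") as fh:
        for t in transcripts:
            if t.stop_end is None:
                continue
            distances = find_3utr_junctions(t)
            if not distances:
                continue
            stop_spliced = t.genomic_to_spliced(t.stop_end)
            for d in distances:
                # junction sits d exonic nt downstream of the stop
                start = _junction_intron_base(t, stop_spliced + d)
                fh.write(
                    f"{t.chrom}\t{start}\t{start + 1}\t"
                    f"{t.transcript_id}_d{d}\t0\t{t.strand}\n"
                )


def _junction_intron_base(t: TranscriptModel, spliced_offset: int) -> int:
    """0-based genomic coordinate of the first intronic base at a junction."""
    acc = 0
    for e in t.exons[:-1]:
        acc += len(e)
        if acc == spliced_offset:
            return e.end if t.strand == "+" else e.start - 1
    raise ValueError("spliced offset is not at a junction")
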