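"""Transcript models, 3'UTR junction distances, and NMD classification."""

import numpy as np
import pytest

from ejcnmd.annotation3ui import (
    ClearanceConstants,
    GeneClass,
    GenomicInterval,
    TranscriptClass,
    TranscriptQuantRow,
    UORFTableRow,
    classify_gene,
    classify_transcript,
    filter_uorf_genes,
    find_3utr_junctions,
    intersect_conserved_proximal,
    load_annotation,
    pair_isoforms,
    ribosome_ejc_clearance,
    ribosome_ejc_overlap,
    select_isoforms,
)

from conftest import make_transcript, random_transcript


# ---------------------------------------------------------------------------
# junction distances
# ---------------------------------------------------------------------------


def spliced_distance_oracle(t):
    """Brute-force oracle: explicit base-by-base spliced coordinate map.

    Lists every exonic base in transcription order, locates the stop
    boundary and each junction in that list, and counts the exonic bases
    between them.
    """
    bases = []  # genomic coordinate of each transcribed base, 5'->3'
    junction_after = []  # spliced index just past each junction
    acc = 0
    for i, e in enumerate(t.exons):
        if e.strand == "+":
            bases.extend(range(e.start, e.end))
        else:
            bases.extend(range(e.end - 1, e.start - 1, -1))
        acc += len(e)
        if i < len(t.exons) - 1:
            junction_after.append(acc)
    # stop boundary: number of bases transcribed before stop_end
    if t.strand == "+":
        stop_idx = sum(1 for b in bases if b < t.stop_end)
    else:
        stop_idx = sum(1 for b in bases if b >= t.stop_end)
    return [j - stop_idx for j in junction_after if j - stop_idx >= 0]


@pytest.mark.parametrize(
    "exons,strand,stop_end,expected",
    [
        # 20 exonic nt to junction 1, +100 through the middle exon
        ([(100, 200), (300, 400), (500, 600)], "+", 180, [20, 120]),
        # mirrored arithmetic on the minus strand
        ([(500, 600), (300, 400)], "-", 520, [20]),
        # stop codon's last base is the exon's last base: distance 0
        ([(100, 200), (300, 400)], "+", 200, [0]),
        # junction upstream of the stop is excluded
        ([(100, 200), (300, 400)], "+", 350, []),
    ],
)
def test_junction_distances_hand_cases(exons, strand, stop_end, expected):
    t = make_transcript(exons, stop_end, strand)
    assert find_3utr_junctions(t) == expected


def test_junction_distances_match_base_by_base_oracle(rng):
    """Spliced distances equal the explicit coordinate-map oracle."""
    for i in range(1000):
        t = random_transcript(rng, tid=f"T{i}")
        assert find_3utr_junctions(t) == spliced_distance_oracle(t), t


def test_strand_reflection_leaves_distances_unchanged(rng):
    """Mirroring all coordinates and flipping strand preserves distances."""
    L = 10**6
    for i in range(200):
        t = random_transcript(rng, tid=f"T{i}")
        flipped = "-" if t.strand == "+" else "+"
        exons = [(L - e.end, L - e.start) for e in t.exons]
        m = make_transcript(exons, L - t.stop_end, flipped, tid=f"T{i}m")
        assert find_3utr_junctions(m) == find_3utr_junctions(t)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "distances,expected",
    [
        ([], TranscriptClass.NONE),
        ([30], TranscriptClass.PROXIMAL),
        ([49], TranscriptClass.PROXIMAL),
        ([50], TranscriptClass.DISTAL),
        ([200], TranscriptClass.DISTAL),
        ([20, 300], TranscriptClass.DISTAL),
        ([5, 10], TranscriptClass.DISTAL),  # two introns, both close
        ([0], TranscriptClass.PROXIMAL),
    ],
)
def test_transcript_class_50nt_rule(distances, expected):
    assert classify_transcript(distances) == expected


def test_negative_distance_rejected():
    with pytest.raises(ValueError):
        classify_transcript([-1])


from hypothesis import given, settings
from hypothesis import strategies as st


@given(st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=6))
@settings(max_examples=200, deadline=None)
def test_multiple_introns_always_distal_regardless_of_order(distances):
    """Two or more 3'UTR introns force DISTAL, whatever the distances."""
    assert classify_transcript(distances) == TranscriptClass.DISTAL
    assert classify_transcript(distances[::-1]) == TranscriptClass.DISTAL


@given(st.integers(min_value=0, max_value=500))
@settings(max_examples=200, deadline=None)
def test_single_intron_class_flips_exactly_at_50(d):
    cls = classify_transcript([d])
    assert (cls == TranscriptClass.PROXIMAL) == (d < 50)
    assert (cls == TranscriptClass.DISTAL) == (d >= 50)


def test_gene_class_precedence():
    prox = make_transcript([(0, 100), (200, 300)], 70, tid="Tp")
    none3 = make_transcript([(0, 100), (200, 300)], 250, tid="Tn")
    dist = make_transcript([(0, 300), (400, 500)], 100, tid="Td")
    mono = make_transcript([(0, 500)], 300, tid="Tm")

    assert classify_gene([prox, none3]).gene_class == GeneClass.PROXIMAL
    assert classify_gene([prox, dist]).gene_class == GeneClass.DISTAL
    assert classify_gene([mono]).gene_class == GeneClass.INTRONLESS
    assert classify_gene([none3]).gene_class == GeneClass.NO_3UI


def test_gene_class_is_a_partition(rng):
    """Every random gene gets exactly one class; NMD biotype is a flag."""
    for i in range(100):
        txs = [
            random_transcript(rng, tid=f"T{i}_{j}", gid=f"G{i}")
            for j in range(int(rng.integers(1, 4)))
        ]
        call = classify_gene(txs)
        assert call.gene_class in GeneClass
        assert isinstance(call.nmd_biotype, bool)


def test_nmd_biotype_flag_is_orthogonal():
    t = make_transcript(
        [(0, 300), (400, 500)], 100, biotype="nonsense_mediated_decay"
    )
    call = classify_gene([t])
    assert call.gene_class == GeneClass.DISTAL
    assert call.nmd_biotype


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------


TSV_HEADER = (
    "transcript_id\tgene_id\tchrom\tstrand\texon_starts\texon_ends\t"
    "cds_start\tcds_end\tappris\tbiotype\n"
)


def test_tsv_dialect_conversion(tmp_path):
    """1-based inclusive TSV coordinates convert to 0-based half-open."""
    path = tmp_path / "ann.tsv"
    path.write_text(
        TSV_HEADER
        + "T1\tG1\tchr1\t+\t1\t100\t10\t60\tprincipal1\tprotein_coding\n"
    )
    (t,) = load_annotation(path, "ensembl_tsv")
    assert (t.exons[0].start, t.exons[0].end) == (0, 100)
    assert t.stop_end == 60  # CDS end includes the stop codon in this dialect


def test_tsv_minus_strand_transcription_order(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(
        TSV_HEADER
        + "T1\tG1\tchr1\t-\t301,501\t400,600\t320\t580\tprincipal1\tprotein_coding\n"
    )
    (t,) = load_annotation(path, "ensembl_tsv")
    assert [(e.start, e.end) for e in t.exons] == [(500, 600), (300, 400)]
    assert t.stop_end == 319  # cds_start - 1, boundary below the stop's last base


def test_tsv_cds_outside_exons_skipped(tmp_path, caplog):
    path = tmp_path / "ann.tsv"
    path.write_text(
        TSV_HEADER
        + "T1\tG1\tchr1\t+\t1\t100\t10\t60\tprincipal1\tprotein_coding\n"
        + "T2\tG2\tchr1\t+\t1\t100\t10\t900\tprincipal1\tprotein_coding\n"
    )
    with caplog.at_level("WARNING"):
        loaded = load_annotation(path, "ensembl_tsv")
    assert [t.transcript_id for t in loaded] == ["T1"]
    assert any("T2" in r.message for r in caplog.records)


def test_tsv_missing_column_fatal(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text("transcript_id\tgene_id\nT1\tG1\n")
    with pytest.raises(ValueError, match="missing mandatory columns"):
        load_annotation(path, "ensembl_tsv")


def test_gtf_round_trip_matches_source_models(tmp_path):
    """Models written as GTF reload with identical structure and stop_end."""
    import ejcnmd.synthetic_data as sd

    cfg = sd.SimulationConfig(
        seed=3,
        class_composition={"PROXIMAL_3UI": 3, "DISTAL_3UI": 3, "INTRONLESS": 2},
        proximal_distances=[25],
        distal_distances=[120],
    )
    bundle = sd.generate_annotation(cfg)
    gtf = tmp_path / "ann.gtf"
    sd.write_gtf(bundle, gtf)
    loaded = {t.transcript_id: t for t in load_annotation(gtf, "gtf")}
    assert len(loaded) == len(bundle.transcripts)
    for t in bundle.transcripts:
        lt = loaded[t.transcript_id]
        assert [(e.start, e.end) for e in lt.exons] == [
            (e.start, e.end) for e in t.exons
        ]
        assert lt.stop_end == t.stop_end
        assert lt.biotype == t.biotype


# ---------------------------------------------------------------------------
# isoform selection
# ---------------------------------------------------------------------------


def test_select_isoforms():
    p1 = make_transcript([(0, 100)], 50, tid="T1", appris="principal1")
    alt = make_transcript([(0, 100)], 50, tid="T2", appris="alternative2")
    none = make_transcript([(0, 100)], 50, tid="T3", appris=None)

    assert select_isoforms([p1, alt, none], "appris_any") == [p1, alt]
    assert select_isoforms([p1, alt, none], "appris_principal") == [p1]


def test_select_isoforms_p1_tie_break(caplog):
    b = make_transcript([(0, 100)], 50, tid="T_b", appris="principal1")
    a = make_transcript([(0, 100)], 50, tid="T_a", appris="principal1")
    with caplog.at_level("WARNING"):
        kept = select_isoforms([b, a], "appris_principal")
    assert [t.transcript_id for t in kept] == ["T_a"]
    assert any("P1" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# conservation, uORF filter, isoform pairing
# ---------------------------------------------------------------------------


def test_conserved_proximal_intersection():
    tables = {
        "zebrafish": {"z1": GeneClass.PROXIMAL, "z2": GeneClass.PROXIMAL},
        "mouse": {"m1": GeneClass.PROXIMAL, "m2": GeneClass.DISTAL},
        "human": {"h1": GeneClass.PROXIMAL, "h2": GeneClass.PROXIMAL},
    }
    omap = [
        {"zebrafish": "z1", "mouse": "m1", "human": "h1"},  # all proximal
        {"zebrafish": "z2", "mouse": "m2", "human": "h2"},  # mouse distal
    ]
    assert intersect_conserved_proximal(tables, omap) == {"z1"}


def test_conserved_missing_link_excluded():
    tables = {
        "zebrafish": {"z1": GeneClass.PROXIMAL},
        "mouse": {"m1": GeneClass.PROXIMAL},
    }
    omap = [{"zebrafish": "z1", "mouse": ""}]
    assert intersect_conserved_proximal(tables, omap) == set()


def test_conserved_one_to_many_requires_all_proximal():
    tables = {
        "zebrafish": {"z1": GeneClass.PROXIMAL},
        "mouse": {"m1": GeneClass.PROXIMAL, "m2": GeneClass.NO_3UI},
    }
    omap = [
        {"zebrafish": "z1", "mouse": "m1"},
        {"zebrafish": "z1", "mouse": "m2"},
    ]
    assert intersect_conserved_proximal(tables, omap) == set()


def test_conserved_missing_species_fatal():
    with pytest.raises(ValueError, match="missing from ortholog map"):
        intersect_conserved_proximal(
            {"zebrafish": {}, "mouse": {}}, [{"zebrafish": "z1"}]
        )


@pytest.mark.parametrize(
    "vals,kept",
    [
        ((5, 5, 5, 1.01), True),  # boundary RPKMs pass at >=, TE passes at >
        ((5, 5, 5, 1.0), False),  # TE threshold is strict
        ((4.9, 5, 5, 2.0), False),
        ((0, 0, 0, 0), False),
        ((100, 100, 100, 3), True),
    ],
)
def test_uorf_filter_thresholds(vals, kept):
    row = UORFTableRow("g", *vals)
    assert (filter_uorf_genes([row]) == {"g"}) is kept


def test_uorf_filter_rejects_negative():
    with pytest.raises(ValueError):
        filter_uorf_genes([UORFTableRow("g", -1, 5, 5, 2)])


def _quant(tid, gid, tpm, fc, q, ptc, has_3ui, cls=TranscriptClass.NONE):
    return TranscriptQuantRow(tid, gid, tpm, fc, q, ptc, has_3ui, cls)


def test_pair_isoforms_picks_highest_tpm_control():
    rows = [
        _quant("i1", "g1", 2.0, 1.0, 0.01, False, True, TranscriptClass.PROXIMAL),
        _quant("c1", "g1", 5.0, 0.0, 0.5, False, False),
        _quant("c2", "g1", 10.0, 0.1, 0.5, False, False),
    ]
    pairs, _ = pair_isoforms(rows)
    assert len(pairs) == 1
    assert pairs[0].control_isoform.transcript_id == "c2"


def test_pair_isoforms_exclusions():
    two_3ui = [
        _quant("i1", "g1", 2, 1, 0.01, False, True, TranscriptClass.PROXIMAL),
        _quant("i2", "g1", 2, 1, 0.01, True, True, TranscriptClass.DISTAL),
        _quant("c1", "g1", 5, 0, 0.5, False, False),
    ]
    pairs, skipped = pair_isoforms(two_3ui)
    assert pairs == [] and skipped["multi_3ui"] == 1

    no_control = [
        _quant("i1", "g2", 2, 1, 0.01, False, True, TranscriptClass.PROXIMAL)
    ]
    pairs, skipped = pair_isoforms(no_control)
    assert pairs == [] and skipped["no_control"] == 1

    # distal 3'UI isoforms must carry a PTC; proximal must not
    wrong_ptc = [
        _quant("i1", "g3", 2, 1, 0.01, False, True, TranscriptClass.DISTAL),
        _quant("c1", "g3", 5, 0, 0.5, False, False),
    ]
    pairs, skipped = pair_isoforms(wrong_ptc)
    assert pairs == [] and skipped["ptc_mismatch"] == 1

    # rows without q-values are invisible
    no_q = [
        _quant("i1", "g4", 2, 1, None, False, True, TranscriptClass.PROXIMAL),
        _quant("c1", "g4", 5, 0, 0.5, False, False),
    ]
    pairs, _ = pair_isoforms(no_q)
    assert pairs == []


# ---------------------------------------------------------------------------
# ribosome/EJC clearance
# ---------------------------------------------------------------------------


def test_clearance_arithmetic():
    assert ribosome_ejc_clearance(ClearanceConstants(9, 27)) == 36
    assert ribosome_ejc_clearance(ClearanceConstants(0, 0)) == 0
    assert ribosome_ejc_overlap(35, ClearanceConstants(9, 27))
    assert not ribosome_ejc_overlap(36, ClearanceConstants(9, 27))


def test_clearance_rejects_negative_constants():
    with pytest.raises(ValueError):
        ClearanceConstants(-1, 27)
    with pytest.raises(ValueError):
        ribosome_ejc_overlap(-5)
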