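import numpy as np
import pandas as pd
import pytest

from barcode_audit.audit import (
    AuditConfig,
    ProvisionalNameRegistry,
    SpeciesAuditSummary,
    assign_specimen,
    count_deep_clusters,
    find_diagnostic_positions,
    flag_discordant_specimens,
    flag_species,
    make_provisional_name,
    run_audit,
    species_pairwise_summary,
    summarize_library,
)
from barcode_audit.distance import DistanceMatrix, build_distance_matrix
from barcode_audit.seq_io_qc import AnchoredSequence, SpecimenRecord


def dm(ids, rows):
    d = np.asarray(rows, dtype=float)
    z = np.zeros_like(d, dtype=np.int64)
    return DistanceMatrix(list(ids), d, z + 658, z, z)


def rec(sid, species, genus=None, family="FamX", confidence="expert"):
    genus = genus or species.split()[0]
    return SpecimenRecord(sid, family, genus, species, id_confidence=confidence)


def seq(sid, bases):
    return AnchoredSequence(specimen_id=sid, bases=bases)


# ---------------------------------------------------------------------------
# Summaries and flags


def hand_matrix():
    # species X: x1,x2 (d=0.03); species Y: y1,y2 (d=0.01); min inter 0.08
    ids = ["x1", "x2", "y1", "y2"]
    rows = [
        [0.00, 0.03, 0.09, 0.10],
        [0.03, 0.00, 0.08, 0.09],
        [0.09, 0.08, 0.00, 0.01],
        [0.10, 0.09, 0.01, 0.00],
    ]
    return dm(ids, rows)


def hand_records():
    return {
        "x1": rec("x1", "Genx alpha"),
        "x2": rec("x2", "Genx alpha"),
        "y1": rec("y1", "Genx beta"),
        "y2": rec("y2", "Genx beta"),
    }


def test_species_summary_hand_distances():
    out = species_pairwise_summary(hand_matrix(), hand_records())
    by = {s.species_label: s for s in out}
    assert by["Genx alpha"].mxid == pytest.approx(0.03)
    assert by["Genx alpha"].mnid == pytest.approx(0.08)
    assert by["Genx alpha"].nearest_neighbor_species == "Genx beta"
    assert by["Genx beta"].mxid == pytest.approx(0.01)
    assert by["Genx beta"].mnid == pytest.approx(0.08)
    assert [s.species_label for s in out] == sorted(by)


def test_singleton_species_has_undefined_mxid():
    ids = ["x1", "y1", "y2"]
    rows = [[0, 0.08, 0.09], [0.08, 0, 0.01], [0.09, 0.01, 0]]
    records = {
        "x1": rec("x1", "Genx alpha"),
        "y1": rec("y1", "Genx beta"),
        "y2": rec("y2", "Genx beta"),
    }
    by = {s.species_label: s for s in species_pairwise_summary(dm(ids, rows), records)}
    assert by["Genx alpha"].mxid is None and by["Genx alpha"].mean_intra is None
    assert by["Genx alpha"].mnid == pytest.approx(0.08)


def test_lone_species_in_scope_has_undefined_mnid():
    ids = ["x1", "x2"]
    records = {"x1": rec("x1", "Genx alpha"), "x2": rec("x2", "Genx alpha")}
    by = {
        s.species_label: s
        for s in species_pairwise_summary(dm(ids, [[0, 0.01], [0.01, 0]]), records)
    }
    assert by["Genx alpha"].mnid is None
    assert by["Genx alpha"].nearest_neighbor_species is None


def test_mnid_scope_monotonicity(default_library, default_anchored):
    matrix = build_distance_matrix(default_anchored)
    records = {r.specimen_id: r for r in default_library.records}
    per_scope = {}
    for scope in ("genus", "family", "all"):
        out = species_pairwise_summary(matrix, records, AuditConfig(mnid_scope=scope))
        per_scope[scope] = {s.species_label: s.mnid for s in out}
    for species, g_mnid in per_scope["genus"].items():
        f_mnid, a_mnid = per_scope["family"][species], per_scope["all"][species]
        if f_mnid is not None and g_mnid is not None:
            assert f_mnid <= g_mnid
        if a_mnid is not None and f_mnid is not None:
            assert a_mnid <= f_mnid


def summary(mxid, mnid=None, n_clusters=1):
    return SpeciesAuditSummary(
        species_label="s", n_specimens=2, mxid=mxid, mean_intra=mxid,
        n_intra_pairs=1, mnid=mnid, nearest_neighbor_species=None,
        n_clusters_at_split=n_clusters,
    )


def test_deep_divergence_flag_is_strict():
    assert "deep_divergence" in flag_species(summary(0.028), AuditConfig()).flags
    assert "deep_divergence" not in flag_species(summary(0.022), AuditConfig()).flags


def test_gap_overlap_flag():
    s = flag_species(summary(0.037, mnid=0.003), AuditConfig())
    assert "gap_overlap" in s.flags
    s = flag_species(summary(0.01, mnid=0.08), AuditConfig())
    assert "gap_overlap" not in s.flags


def test_multi_cluster_flag():
    assert "multi_cluster" in flag_species(summary(0.06, n_clusters=2), AuditConfig()).flags


def test_count_deep_clusters_planted_groups():
    ids = ["a", "b", "c", "d"]
    rows = [
        [0, 0.01, 0.06, 0.06],
        [0.01, 0, 0.06, 0.06],
        [0.06, 0.06, 0, 0.01],
        [0.06, 0.06, 0.01, 0],
    ]
    n, clusters = count_deep_clusters(dm(ids, rows), ids, t_split=0.05)
    assert n == 2 and clusters == [["a", "b"], ["c", "d"]]
    n, _ = count_deep_clusters(dm(["a", "b"], [[0, 0.01], [0.01, 0]]), ["a", "b"], 0.05)
    assert n == 1


# ---------------------------------------------------------------------------
# Diagnostics


def test_diagnostics_planted_positions():
    a = "A" * 20
    b = "A" * 9 + "C" + "A" * 10  # species B differs at position 10
    c = "A" * 9 + "G" + "A" * 4 + "T" + "A" * 5  # species C at 10 and 15
    seqs = [seq("a1", a), seq("a2", a), seq("b1", b), seq("c1", c)]
    species_of = {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}
    chars = find_diagnostic_positions(seqs, species_of, ["A", "B", "C"])
    got = {(ch.species_label, ch.position, ch.state) for ch in chars}
    assert ("B", 10, "C") in got
    assert ("C", 10, "G") in got and ("C", 15, "T") in got
    # species A's base at 10 (A) is shared with nobody else at 10? b has C, c has G
    assert ("A", 10, "A") in got
    # invariant positions are never diagnostic
    assert not any(ch.position == 1 for ch in chars)


def test_diagnostics_identical_species_yield_nothing():
    seqs = [seq("a1", "ACGT" * 5), seq("b1", "ACGT" * 5)]
    chars = find_diagnostic_positions(seqs, {"a1": "A", "b1": "B"}, ["A", "B"])
    assert chars == []


def test_diagnostics_respect_missing_data():
    # species A members: one has N at site 2 -> remaining member fixes state
    seqs = [seq("a1", "ANGT"), seq("a2", "ACGT"), seq("b1", "AGGT")]
    chars = find_diagnostic_positions(
        seqs, {"a1": "A", "a2": "A", "b1": "B"}, ["A", "B"]
    )
    got = {(c.species_label, c.position, c.state) for c in chars}
    assert ("A", 2, "C") in got and ("B", 2, "G") in got
    # with min_coverage=2, species A has only 1 covered member at site 2
    chars2 = find_diagnostic_positions(
        seqs, {"a1": "A", "a2": "A", "b1": "B"}, ["A", "B"], min_coverage=2
    )
    assert ("A", 2, "C") not in {(c.species_label, c.position, c.state) for c in chars2}


def test_diagnostics_errors():
    with pytest.raises(ValueError, match="two species"):
        find_diagnostic_positions([seq("a1", "ACGT")], {"a1": "A"}, ["A"])
    with pytest.raises(ValueError, match="no sequences"):
        find_diagnostic_positions([seq("a1", "ACGT")], {"a1": "A"}, ["A", "B"])


def brute_force_diagnostics(seqs, species_of, species_set, min_coverage=1):
    """Independent site scan in pure python."""
    out = []
    frames = {s.specimen_id: s.frame_codes() for s in seqs}
    for sp in species_set:
        own = [frames[i] for i in frames if species_of[i] == sp]
        other = [frames[i] for i in frames if species_of[i] != sp and species_of[i] in species_set]
        for pos in range(658):
            states = {int(f[pos]) for f in own if f[pos] < 4}
            n_cov = sum(1 for f in own if f[pos] < 4)
            if len(states) != 1 or n_cov < min_coverage:
                continue
            state = states.pop()
            if any(f[pos] == state for f in other):
                continue
            out.append((sp, pos + 1, "ACGT"[state]))
    return sorted(out, key=lambda t: (species_set.index(t[0]), t[1]))


def test_diagnostics_agree_with_brute_force(clean_small_library):
    from conftest import anchor_all

    seqs = anchor_all(clean_small_library)
    species_of = {r.specimen_id: r.species_label for r in clean_small_library.records}
    species = sorted({r.species_label for r in clean_small_library.records})[:3]
    chars = find_diagnostic_positions(seqs, species_of, species)
    got = [(c.species_label, c.position, c.state) for c in chars]
    assert got == brute_force_diagnostics(seqs, species_of, species)


# ---------------------------------------------------------------------------
# Assignment and provisional names


def make_reference_set():
    base = "CTAACTAGC" * 73 + "C"

    def mutate(bases, k, offset=0):
        # k transitions at distinct codon-2 positions (never creates stops
        # we care about -- assignment only needs distances)
        out = list(bases)
        for i in range(k):
            pos = 3 * (i + offset) + 1
            out[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[out[pos]]
        return "".join(out)

    ref_a = seq("refA", base)
    ref_b = seq("refB", mutate(base, 80))  # far from A (~13%)
    query_near_a = seq("q1", mutate(base, 5))  # ~0.8% from A
    query_far = seq("q2", mutate(base, 40, offset=100))  # >2% from both
    return base, mutate, ref_a, ref_b, query_near_a, query_far


def test_assign_within_threshold():
    _, _, ref_a, ref_b, q_near, _ = make_reference_set()
    a = assign_specimen(q_near, [(ref_a, "sp A"), (ref_b, "sp B")])
    assert a.status == "assigned" and a.species_label == "sp A"
    assert a.confidence == "propagated"
    assert a.min_distance < 0.02


def test_assign_unassigned_beyond_threshold():
    _, _, ref_a, ref_b, _, q_far = make_reference_set()
    a = assign_specimen(q_far, [(ref_a, "sp A"), (ref_b, "sp B")])
    assert a.status == "unassigned" and a.species_label is None


def test_assign_ambiguous_between_close_species():
    base, mutate, ref_a, _, _, _ = make_reference_set()
    ref_c = seq("refC", mutate(base, 3, offset=150))  # ~0.5% from A
    q = seq("q3", mutate(base, 2, offset=200))  # close to both A and C
    a = assign_specimen(q, [(ref_a, "sp A"), (ref_c, "sp C")])
    assert a.status == "ambiguous"
    assert a.candidates == ("sp A", "sp C")


def test_assign_rejects_failed_qc():
    q = AnchoredSequence("q", "ACGT" * 160, qc_status="stop_codon")
    with pytest.raises(ValueError, match="failed QC"):
        assign_specimen(q, [(seq("r", "ACGT" * 160), "sp A")])


def test_provisional_names_serial():
    registry = ProvisionalNameRegistry()
    assert make_provisional_name("Heptagenia", "LJ", registry) == "Heptagenia sp.LJ1"
    assert make_provisional_name("Heptagenia", "LJ", registry) == "Heptagenia sp.LJ2"
    assert make_provisional_name("Baetis", "LJ", registry) == "Baetis sp.LJ1"


def test_provisional_names_respect_published_reservations():
    registry = ProvisionalNameRegistry(reserved=["Acerpenna sp. CHU1"])
    assert make_provisional_name("Acerpenna", "CHU", registry) == "Acerpenna sp.CHU2"


def test_provisional_registry_rejects_binomials():
    with pytest.raises(ValueError, match="not a provisional name"):
        ProvisionalNameRegistry(reserved=["Ephemera simulans"])


# ---------------------------------------------------------------------------
# Discordance


def test_discordant_specimen_flagged():
    # m1 labeled "beta" but sits inside alpha; its own species is far away
    ids = ["a1", "a2", "m1", "b1"]
    rows = [
        [0.00, 0.01, 0.012, 0.12],
        [0.01, 0.00, 0.015, 0.12],
        [0.012, 0.015, 0.00, 0.12],
        [0.12, 0.12, 0.12, 0.00],
    ]
    species = {"a1": "alpha", "a2": "alpha", "m1": "beta", "b1": "beta"}
    flags = flag_discordant_specimens(dm(ids, rows), species)
    assert [f.specimen_id for f in flags] == ["m1"]
    assert flags[0].nearest_neighbor_species == "alpha"
    assert flags[0].d_own_species == pytest.approx(0.12)


def test_discordance_singleton_is_vacuously_distant():
    ids = ["a1", "a2", "s1"]
    rows = [[0, 0.01, 0.012], [0.01, 0, 0.015], [0.012, 0.015, 0]]
    species = {"a1": "alpha", "a2": "alpha", "s1": "solo"}
    flags = flag_discordant_specimens(dm(ids, rows), species)
    assert [f.specimen_id for f in flags] == ["s1"]
    assert flags[0].d_own_species is None


def test_clean_library_has_no_discordance(clean_small_library):
    from conftest import anchor_all

    matrix = build_distance_matrix(anchor_all(clean_small_library))
    species = {r.specimen_id: r.species_label for r in clean_small_library.records}
    assert flag_discordant_specimens(matrix, species) == []


# ---------------------------------------------------------------------------
# Rollups


def toy_summaries():
    def s(label, n, mxid, mnid, flags=()):
        out = SpeciesAuditSummary(
            species_label=label, n_specimens=n, mxid=mxid, mean_intra=mxid,
            n_intra_pairs=(n * (n - 1)) // 2 if mxid is not None else 0,
            mnid=mnid, nearest_neighbor_species=None, n_clusters_at_split=1,
        )
        out.flags = set(flags)
        return out

    return [
        s("Gena one", 3, 0.03, 0.08, flags=["deep_divergence"]),
        s("Gena two", 2, 0.01, 0.08),
        s("Genb one", 1, None, 0.12),
    ]


def toy_records():
    return {
        "p1": rec("p1", "Gena one", family="Fam1"),
        "p2": rec("p2", "Gena two", family="Fam1"),
        "p3": rec("p3", "Genb one", family="Fam2"),
    }


def test_family_rollup_hand_checked():
    rollup, stats = summarize_library(toy_summaries(), toy_records(), {"Fam1": 10, "Fam2": 5})
    fam1 = rollup[rollup.family == "Fam1"].iloc[0]
    assert fam1.n_known_species == 10
    assert fam1.n_barcoded_species == 2 and fam1.n_deep_divergence == 1
    assert fam1.mean_mxid_pct == "2.0"  # mean(0.03, 0.01) = 2.0%
    assert fam1.mean_mnid_pct == "8.0"
    fam2 = rollup[rollup.family == "Fam2"].iloc[0]
    assert fam2.mean_mxid_pct == "–"  # singleton species only


def test_rollup_family_with_no_barcoded_species():
    rollup, _ = summarize_library(
        toy_summaries(), toy_records(), {"Fam1": 10, "Fam2": 5, "Fam3": 7}
    )
    fam3 = rollup[rollup.family == "Fam3"].iloc[0]
    assert fam3.n_barcoded_species == 0
    assert fam3.mean_mxid_pct == "–" and fam3.mean_mnid_pct == "–"


def test_global_stats_hand_checked():
    _, stats = summarize_library(toy_summaries(), toy_records())
    assert stats.n_species == 3 and stats.n_specimens == 6
    assert stats.mean_mnid == pytest.approx((0.08 + 0.08 + 0.12) / 3)
    assert stats.min_mnid == pytest.approx(0.08)
    assert stats.mean_mxid == pytest.approx(0.02)
    assert stats.pct_deep_divergence == pytest.approx(100 / 3)


def test_global_mean_mnid_two_values():
    subset = [s for s in toy_summaries() if s.mnid in (0.08, 0.12)][:2]
    subset[1].mnid = 0.12
    _, stats = summarize_library(subset, toy_records())
    assert stats.mean_mnid == pytest.approx(0.10)


# ---------------------------------------------------------------------------
# End-to-end


def test_run_audit_excludes_unidentified_from_summaries():
    matrix = hand_matrix()
    records = hand_records()
    records["y2"] = rec("y2", "Genx beta", confidence="unidentified")
    by = {s.species_label: s for s in species_pairwise_summary(matrix, records)}
    assert by["Genx beta"].n_specimens == 1


def test_run_audit_end_to_end_reports(default_library, default_anchored, tmp_path):
    from barcode_audit.audit import write_audit_reports

    result = run_audit(default_anchored, default_library.records, AuditConfig())
    assert result.stats.n_species == 20
    assert not result.shared_haplotypes
    paths = write_audit_reports(result, tmp_path)
    species_df = pd.read_csv(paths["species"], sep="\t")
    assert len(species_df) == 20
    fam_df = pd.read_csv(paths["families"], sep="\t")
    assert set(fam_df.family) == {"Family01", "Family02", "Family03"}
    assert any(name.startswith("tree_") for name in paths)
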