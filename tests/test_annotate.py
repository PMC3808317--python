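"""Reference mapping, ncRNA classification and known-miRNA assignment."""

from __future__ import annotations

import random

import pytest

from mirstress.annotate import (
    CLASSES,
    KnownMiRNAFamily,
    ReferenceDB,
    assign_known_mirna,
    class_distribution,
    classify_ncrna,
    family_name,
    family_table,
    map_perfect,
    mirna_distance,
    reverse_complement,
)
from mirstress.preprocess import collapse_to_tags


def _naive_scan(tag: str, records: dict) -> set:
    hits = set()
    for rid, seq in records.items():
        for query, strand in ((tag, "+"), (reverse_complement(tag), "-")):
            start = seq.find(query)
            while start != -1:
                hits.add((rid, start + 1, strand))
                start = seq.find(query, start + 1)
    return hits


class TestMapPerfect:
    def test_forward_hit_coordinates(self):
        ref = ReferenceDB({"t1": "N" * 9 + "ACGTACGTACGTACGTACGTA" + "N" * 10})
        tag = "ACGTACGTACGTACGTACGTA"
        hits = map_perfect([tag], ref)[tag]
        assert (hits[0].record_id, hits[0].start, hits[0].strand) == ("t1", 10, "+")

    def test_reverse_complement_hit(self):
        window = "GATTACAGATTACAGATTAC"
        ref = ReferenceDB({"t1": "CCCCC" + window + "CCCCC"})
        tag = reverse_complement(window)
        hits = map_perfect([tag], ref)[tag]
        assert hits and hits[0].strand == "-" and hits[0].start == 6

    def test_empty_reference_all_unmapped(self):
        assert map_perfect(["ACGTACGTACGTACG"], ReferenceDB({})) == {
            "ACGTACGTACGTACG": []
        }

    def test_planted_tags_match_naive_scan_oracle(self):
        rng = random.Random(17)
        records = {
            f"t{i}": "".join(rng.choice("ACGT") for _ in range(800)) for i in range(5)
        }
        ref = ReferenceDB(records)
        tags = []
        for _ in range(200):
            rid = rng.choice(list(records))
            start = rng.randrange(0, 800 - 21)
            window = records[rid][start : start + 21]
            tags.append(window if rng.random() < 0.5 else reverse_complement(window))
        hits = map_perfect(sorted(set(tags)), ref)
        for tag in set(tags):
            got = {(h.record_id, h.start, h.strand) for h in hits[tag]}
            assert got == _naive_scan(tag, records)
            assert got  # every planted tag maps somewhere


class TestNcRNA:
    def test_fragment_gets_record_class(self):
        db = ReferenceDB({"r1": "ACGT" * 50}, {"r1": "rRNA"})
        frag = ("ACGT" * 50)[10:31]
        assert classify_ncrna([frag], db)[frag] == "rRNA"

    def test_multiclass_resolves_by_priority(self):
        seq = "ACGTACGTACGTACGTACGTACGT"
        db = ReferenceDB(
            {"a": seq + "GGGG", "b": "TTTT" + seq},
            {"a": "tRNA", "b": "rRNA"},
        )
        tag = seq[:20]
        assert classify_ncrna([tag], db)[tag] == "rRNA"

    def test_planted_fraction_recovered_exactly(self, small_bundle, small_tags, small_annotation):
        """Simulator truth: every tag classified rRNA really is a fragment
        of an rRNA record, and no rRNA fragment is missed."""
        rrna_seqs = [
            s for r, s in small_bundle.ncrna.records.items()
            if small_bundle.ncrna.kinds[r] == "rRNA"
        ]
        for seq, res in small_annotation.items():
            in_rrna = any(seq in r or reverse_complement(seq) in r for r in rrna_seqs)
            assert (res.klass == "rRNA") == in_rrna


class TestKnownAssignment:
    FAMILIES = [
        KnownMiRNAFamily("miR156", [("ath-miR156a", "TGACAGAAGAGAGTGAGCACA")]),
        KnownMiRNAFamily(
            "miR396",
            [
                ("ath-miR396a", "TTCCACAGCTTTCTTGAACTG"),
                ("ath-miR396b", "TTCCACAGCTTTCTTGAACTT"),
            ],
        ),
    ]

    def test_exact_match_assigned_zero_mismatches(self):
        res = assign_known_mirna(["TGACAGAAGAGAGTGAGCACA"], self.FAMILIES)
        r = res["TGACAGAAGAGAGTGAGCACA"]
        assert (r.klass, r.family, r.mismatches) == ("known_miRNA", "miR156", 0)

    def test_three_mismatches_stays_unassigned(self):
        tag = "TGACAGAAGAGAGTGAGCACA"
        mutated = "AGACAGAAGAGAGTGAGCAGT"  # 3 substitutions
        assert mirna_distance(mutated, tag) == 3
        assert assign_known_mirna([mutated], self.FAMILIES)[mutated].klass == "unannotated"

    def test_tie_breaks_to_lexicographically_smallest_member(self):
        # one mismatch to both miR396a and miR396b, verified exhaustively
        tag = "TTCCACAGCTTTCTTGAACTC"
        dists = {
            mid: mirna_distance(tag, seq)
            for fam in self.FAMILIES
            for mid, seq in fam.members
        }
        best = min(dists.values())
        tied = sorted(m for m, d in dists.items() if d == best)
        assert len(tied) == 2 and best == 1
        assert assign_known_mirna([tag], self.FAMILIES)[tag].member == tied[0]

    def test_length_overhang_counts_as_mismatch(self):
        tag = "TGACAGAAGAGAGTGAGCACAGG"  # 2 extra 3' bases
        r = assign_known_mirna([tag], self.FAMILIES)[tag]
        assert r.klass == "known_miRNA" and r.mismatches == 2

    def test_negative_max_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assign_known_mirna([], self.FAMILIES, max_mismatch=-1)

    def test_family_aggregation_sums_and_ratio(self):
        tags = collapse_to_tags(
            ["TGACAGAAGAGAGTGAGCACA"] * 4 + ["TTCCACAGCTTTCTTGAACTG"] * 2, "CK"
        )
        tags_cd = collapse_to_tags(
            ["TGACAGAAGAGAGTGAGCACA"] * 1 + ["TTCCACAGCTTTCTTGAACTG"] * 8, "Cd200"
        )
        from mirstress.preprocess import merge_tag_sets

        merged = merge_tag_sets(tags, tags_cd)
        res = assign_known_mirna(sorted(merged), self.FAMILIES)
        table = family_table(res, merged).set_index("family")
        assert table.loc["miR156", "reads_CK"] == 4
        assert table.loc["miR156", "total_reads"] == 5
        assert table.loc["miR156", "ratio"] == 0.25
        assert table.loc["miR396", "ratio"] == 4.0


class TestFamilyParsing:
    @pytest.mark.parametrize(
        "member,family",
        [
            ("ath-miR156a-5p", "miR156"),
            ("rsa-miR396b", "miR396"),
            ("miR827", "miR827"),
            ("osa-miR1442", "miR1442"),
            ("cel-let-7", "let7"),
        ],
    )
    def test_species_prefix_and_suffixes_stripped(self, member, family):
        assert family_name(member) == family

    def test_unparseable_name_raises(self):
        with pytest.raises(ValueError):
            family_name("not-a-mirna")


def test_class_partition_is_exact(small_tags, small_annotation):
    """Every tag receives exactly one class and the per-class unique
    counts sum to the total unique tags (composition-table invariant)."""
    assert set(small_annotation) == set(small_tags)
    dist = class_distribution(small_annotation, small_tags, ["CK", "Cd200"])
    for lib in ("CK", "Cd200"):
        n_lib = sum(1 for t in small_tags.values() if t.counts.get(lib, 0) > 0)
        assert dist[f"unique_{lib}"].sum() == n_lib
        total_lib = sum(t.counts.get(lib, 0) for t in small_tags.values())
        assert dist[f"total_{lib}"].sum() == total_lib
    assert set(dist["class"]) == set(CLASSES)
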