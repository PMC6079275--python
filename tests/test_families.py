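"""Family identification: parsing, filtering, MW/pI, classification, naming."""

import math
import re
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hspkit import families
from hspkit.families import DomainHit, ProteinRecord

AA = st.sampled_from(list(families.AA_ALPHABET))
protein_seqs = st.text(alphabet=AA, min_size=1, max_size=60)


def make_hit(pid="p1", model="PF00012", e=1e-10, bits=100.0, start=1, end=50):
    return DomainHit(pid, model, e, bits, start, end)


class TestDomtblout:
    def test_round_trip_preserves_hits(self, tmp_path):
        hits = [
            make_hit("protA", "PF00012", 1.2e-30, 250.5, 10, 180),
            make_hit("protB", "PF00447", 3e-9, 55.1, 5, 90),
            make_hit("protA", "PF01556", 2e-7, 40.0, 200, 260),
        ]
        path = tmp_path / "hits.domtblout"
        families.write_domtblout(hits, path)
        back = families.read_domtblout(path)
        assert back == hits  # includes lossless 1.2e-30

    def test_comments_skipped_and_order_preserved(self, tmp_path):
        hits = [make_hit(f"p{i}", e=10.0 ** -(i + 7)) for i in range(3)]
        path = tmp_path / "hits.domtblout"
        families.write_domtblout(hits, path)
        assert [h.protein_id for h in families.read_domtblout(path)] == [
            "p0", "p1", "p2",
        ]

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.domtblout"
        path.write_text("# only comments\n")
        assert families.read_domtblout(path) == []

    def test_malformed_row_names_line_number(self, tmp_path):
        path = tmp_path / "bad.domtblout"
        path.write_text("# header\nonly three cols\n")
        with pytest.raises(ValueError, match="line 2"):
            families.read_domtblout(path)


class TestFilter:
    def test_strict_threshold(self):
        hits = [
            make_hit("a", e=1e-7), make_hit("b", e=1e-6), make_hit("c", e=1e-5),
        ]
        out = families.filter_and_validate(hits)
        assert [h.protein_id for h in out] == ["a"]  # strict <

    def test_empty_input(self):
        assert families.filter_and_validate([]) == []

    def test_best_model_wins_per_protein(self):
        hits = [
            make_hit("p", "PF00012", 1e-20),
            make_hit("p", "PF01556", 1e-8),
        ]
        out = families.filter_and_validate(hits)
        assert len(out) == 1 and out[0].model_name == "PF00012"

    def test_tie_broken_by_bit_score_then_model_name(self):
        hits = [
            make_hit("p", "PF00183", 1e-9, bits=50.0),
            make_hit("p", "PF00118", 1e-9, bits=80.0),
        ]
        assert families.filter_and_validate(hits)[0].model_name == "PF00118"
        hits = [
            make_hit("p", "PF00183", 1e-9, bits=50.0),
            make_hit("p", "PF00118", 1e-9, bits=50.0),
        ]
        assert families.filter_and_validate(hits)[0].model_name == "PF00118"

    @given(st.lists(
        st.tuples(
            st.sampled_from(["a", "b", "c"]),
            st.sampled_from(sorted(families.FAMILY_MODELS)),
            st.floats(1e-30, 1e-3),
        ),
        max_size=12,
    ))
    @settings(derandomize=True, max_examples=50)
    def test_idempotent(self, rows):
        hits = [make_hit(p, m, e) for p, m, e in rows]
        once = families.filter_and_validate(hits)
        assert families.filter_and_validate(once) == once

    def test_min_e_assignment_matches_enumeration(self):
        rng = np.random.default_rng(0)
        models = sorted(families.FAMILY_MODELS)
        hits = [
            make_hit(f"p{i % 4}", rng.choice(models), float(10.0 ** rng.uniform(-20, -7)))
            for i in range(20)
        ]
        out = {h.protein_id: h for h in families.filter_and_validate(hits)}
        for pid in {h.protein_id for h in hits}:
            best = min(
                (h for h in hits if h.protein_id == pid),
                key=lambda h: (h.e_value, -h.bit_score, h.model_name),
            )
            assert out[pid].model_name == best.model_name


class TestMolecularWeight:
    def test_diglycine_hand_sum(self):
        assert families.compute_mw("GG") == pytest.approx(132.119, abs=1e-3)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            families.compute_mw("")

    def test_unknown_residue_named(self):
        with pytest.raises(ValueError, match="'B'"):
            families.compute_mw("GAB")

    def test_x_contributes_mean_residue_mass(self):
        mean = sum(families.AVERAGE_RESIDUE_MASS.values()) / 20
        assert families.compute_mw("X") == pytest.approx(mean + families.WATER_MASS)

    @given(protein_seqs, protein_seqs)
    @settings(derandomize=True, max_examples=100)
    def test_additivity_one_water(self, a, b):
        lhs = families.compute_mw(a + b)
        rhs = families.compute_mw(a) + families.compute_mw(b) - families.WATER_MASS
        assert lhs == pytest.approx(rhs, rel=1e-6)


class TestIsoelectricPoint:
    def test_polyglycine_zero_charge_at_pi(self):
        pi = families.compute_pi("GGGGG")
        assert 0 < pi < 14
        assert abs(families.net_charge("GGGGG", pi)) < 1e-4

    @pytest.mark.parametrize("seq", ["GGGGG", "KKKK", "DDDD", "MKWVTFISLLFLFSSAYS"])
    def test_charge_sign_at_ph_extremes(self, seq):
        assert families.net_charge(seq, 0.0) > 0
        assert families.net_charge(seq, 14.0) < 0

    def test_basic_beats_acidic(self):
        # dense grid search confirms the sign argument
        grid = np.linspace(0.5, 13.5, 200)
        pk = min(grid, key=lambda p: abs(families.net_charge("KKKK", p)))
        pd_ = min(grid, key=lambda p: abs(families.net_charge("DDDD", p)))
        assert families.compute_pi("KKKK") > families.compute_pi("DDDD")
        assert pk > pd_

    @pytest.mark.parametrize("seq", ["KKKK", "DDDD", "MKWVTFISLLFLFSSAYS", "GGGGG"])
    def test_bracketing(self, seq):
        pi = families.compute_pi(seq)
        assert families.net_charge(seq, pi - 1) > 0 > families.net_charge(seq, pi + 1)


class TestAssignment:
    def test_reference_replay_reproduces_family_sizes(self):
        table = families.replay_reference_classification()
        counts = Counter(table["assigned_family"])
        assert counts == {
            "Hsp20": 3, "Hsp40": 6, "Hsp60": 10, "Hsp70": 8,
            "Hsp90": 3, "Hsp100": 1, "Hsf": 1,
        }
        reassigned = table[
            (table.source_model == "PF00012") & (table.assigned_family == "Hsp100")
        ]
        assert len(reassigned) == 1
        assert reassigned.mw_kd.iloc[0] == pytest.approx(100.328)

    def test_heavy_hsp70_reassigned_light_kept(self):
        assert families.classify_family("Hsp70", 100_328.0) == "Hsp100"
        assert families.classify_family("Hsp70", 71_617.0) == "Hsp70"
        assert families.classify_family("Hsp90", 120_000.0) == "Hsp90"

    def test_hsp100_count_monotone_in_threshold(self):
        table = families.load_reference_table()
        counts = []
        for thr in (50_000, 80_000, 95_000, 101_000, 200_000):
            n = sum(
                families.classify_family(
                    families.normalize_model(m), kd * 1000, thr
                ) == "Hsp100"
                for m, kd in zip(table.source_model, table.mw_kd)
            )
            counts.append(n)
        assert counts == sorted(counts, reverse=True)

    def test_naming_scheme_and_singletons(self):
        proteins = {
            "a": ProteinRecord("a", "", "M" * 600),
            "b": ProteinRecord("b", "", "M" * 650),
            "c": ProteinRecord("c", "", "M" * 400),
        }
        hits = [
            make_hit("a", "PF00012", 1e-20),
            make_hit("b", "PF00012", 1e-15),
            make_hit("c", "PF00447", 1e-12),
        ]
        records = families.assign_families(hits, proteins, species_prefix="Cr")
        names = [r.gene_name for r in records]
        assert names == ["CrHsp70-1", "CrHsp70-2", "CrHsf"]
        pattern = re.compile(
            r"^(Cs|Cr)(Hsp20|Hsp40|Hsp60|Hsp70|Hsp90|Hsp100|Hsf)(-[0-9]+)?$"
        )
        assert all(pattern.match(n) for n in names)

    def test_planted_family_recovery_is_exact(self, proteome_fixture):
        hits = families.scan_pssm(proteome_fixture.proteins, proteome_fixture.models)
        validated = families.filter_and_validate(hits, e_threshold=1e-6)
        got = {(h.protein_id, h.model_name) for h in validated}
        want = {
            (r.protein_id, r.family) for r in proteome_fixture.truth.itertuples()
        }
        assert got == want  # precision = recall = 1.0


class TestPSSM:
    def test_consensus_window_score_is_sum_of_column_maxima(self, proteome_fixture):
        model = proteome_fixture.models["Hsp40"]
        score = model.window_scores(model.consensus)[0]
        assert score == pytest.approx(model.matrix.max(axis=1).sum())
        # brute-force: no window of a random sequence beats the consensus
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list(families.AA_ALPHABET), size=300))
        assert model.window_scores(seq).max() < score

    def test_planted_member_best_hit_is_its_family(self, proteome_fixture):
        hits = families.scan_pssm(proteome_fixture.proteins, proteome_fixture.models)
        by_protein = {}
        for h in hits:
            by_protein.setdefault(h.protein_id, h)  # sorted by E: first is best
        for row in proteome_fixture.truth.itertuples():
            assert by_protein[row.protein_id].model_name == row.family
            assert by_protein[row.protein_id].e_value <= 1e-6

    def test_decoys_have_no_hits(self, proteome_fixture):
        hits = families.scan_pssm(proteome_fixture.proteins, proteome_fixture.models)
        planted = set(proteome_fixture.truth.protein_id)
        assert all(h.protein_id in planted for h in hits)

    def test_model_json_round_trip(self, proteome_fixture, tmp_path):
        model = proteome_fixture.models["Hsf"]
        model.to_json(tmp_path / "m.json")
        back = families.PSSM.from_json(tmp_path / "m.json")
        assert back.name == model.name and back.lam == pytest.approx(model.lam)
        np.testing.assert_allclose(back.matrix, model.matrix, atol=1e-6)


class TestGeneStructure:
    @pytest.mark.parametrize(
        "exons,expected",
        [
            ([(1, 100)], (1, 0)),
            ([(1, 50), (80, 120), (150, 200), (220, 260), (300, 320)], (5, 4)),
        ],
    )
    def test_intron_count_definition(self, exons, expected):
        assert families.intron_exon_summary(exons) == expected

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            families.intron_exon_summary([(1, 100), (90, 150)])

    def test_gff_summary_matches_planted_exon_counts(self, promoter_fixture):
        structures = families.gene_structures_from_gff(promoter_fixture.gff_path)
        for row in promoter_fixture.genes.itertuples():
            assert structures[row.gene_id] == (row.n_exons, row.n_exons - 1)
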