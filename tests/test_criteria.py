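"""The three self-resistance criteria and their merge."""

import numpy as np
import pytest

from psifootprint import codons
from psifootprint.catalog import FamilyAssignment, load_default_catalog
from psifootprint.criteria import (
    CriterionFlags,
    HgtParams,
    detect_bgc_colocalization,
    detect_duplication,
    detect_hgt_signal,
    flags_from_arts_rows,
    hgt_gene_stats,
    merge_criteria,
    write_criteria_table,
)
from psifootprint.genome_io import BgcRegion, GeneRecord, GenomeAnnotation, read_arts_table
from psifootprint.synth import generate_genome, null_spec, recovery_spec


def _assign(*pairs):
    return [FamilyAssignment(gene_id=g, accession=a, method="symbol") for g, a in pairs]


class TestDuplication:
    def test_single_copy_not_duplicated(self, catalog):
        out = detect_duplication(_assign(("g1", "TIGR00981")), catalog)
        assert out["TIGR00981"] == (1, False)

    def test_two_copies_duplicated(self, catalog):
        out = detect_duplication(_assign(("g1", "TIGR00485"), ("g2", "TIGR00485")), catalog)
        assert out["TIGR00485"] == (2, True)

    def test_monotone_in_copies(self, catalog):
        """Adding a gene copy never turns the flag off."""
        assigns = _assign(("g1", "TIGR00485"))
        for i in range(2, 6):
            assigns = assigns + _assign((f"g{i}", "TIGR00485"))
            n, flag = detect_duplication(assigns, catalog)["TIGR00485"]
            assert flag and n == i

    def test_synthetic_duplications_recovered(self, catalog, small_genome):
        genome, _, manifest = small_genome
        from psifootprint.catalog import assign_families

        out = detect_duplication(assign_families(genome, catalog), catalog)
        planted = set(manifest.spec.planted_duplications)
        flagged = {acc for acc, (_, f) in out.items() if f}
        assert flagged == planted


def _one_gene_genome(start, end):
    g = GenomeAnnotation("s", {"c1": "A" * 10000},
                         [GeneRecord("g1", "c1", start, end, "+")])
    return g, _assign(("g1", "ACC1"))


class TestBgcColocalization:
    def test_contained_gene_true_under_both_rules(self):
        region = BgcRegion("r1", "c1", 1, 5000)
        for rule in ("any-overlap", "fully-contained"):
            g, a = _one_gene_genome(1000, 2000)
            out = detect_bgc_colocalization(g, a, [region], rule)
            assert out["ACC1"] == (True, ["r1"])

    def test_boundary_gene_depends_on_rule(self):
        region = BgcRegion("r1", "c1", 1, 5000)
        g, a = _one_gene_genome(4500, 5500)
        assert detect_bgc_colocalization(g, a, [region], "any-overlap")["ACC1"][0]
        assert not detect_bgc_colocalization(g, a, [region], "fully-contained")["ACC1"][0]

    def test_monotone_in_regions(self):
        g, a = _one_gene_genome(1000, 2000)
        r1 = BgcRegion("r1", "c1", 1500, 5000)
        r2 = BgcRegion("r2", "c1", 8000, 9000)
        one = detect_bgc_colocalization(g, a, [r1])["ACC1"]
        both = detect_bgc_colocalization(g, a, [r1, r2])["ACC1"]
        assert one[0] and both[0] and set(one[1]) <= set(both[1])

    def test_unknown_contig_warns_and_ignores(self):
        g, a = _one_gene_genome(1000, 2000)
        with pytest.warns(UserWarning, match="absent"):
            out = detect_bgc_colocalization(g, a, [BgcRegion("r1", "cX", 1, 5000)])
        assert out["ACC1"] == (False, [])

    def test_unknown_rule(self):
        g, a = _one_gene_genome(1000, 2000)
        with pytest.raises(ValueError, match="overlap_rule"):
            detect_bgc_colocalization(g, a, [BgcRegion("r1", "c1", 1, 5000)], "sometimes")


class TestHgtSignal:
    def test_background_too_small(self):
        g = GenomeAnnotation("s", {"c1": "A" * 10000},
                             [GeneRecord("g1", "c1", 1, 90, "+", cds_sequence="ATG" * 30)])
        with pytest.raises(ValueError, match="50"):
            hgt_gene_stats(g)

    def test_planted_bias_detected_and_only_it(self, catalog):
        """Genes drawn from a GC-shifted codon model are flagged; background not."""
        spec = recovery_spec(seed=41, n_dup=0, n_bgc=0, n_hgt=3)
        genome, _, manifest = generate_genome(spec, catalog)
        from psifootprint.catalog import assign_families

        out = detect_hgt_signal(genome, assign_families(genome, catalog), HgtParams())
        flagged = {acc for acc, (f, _) in out.items() if f}
        assert flagged == {a for a, _ in spec.planted_hgt}

    def test_reencoded_gene_loses_flag(self, catalog):
        """Same protein re-encoded with background codon usage is not flagged."""
        spec = recovery_spec(seed=43, n_dup=0, n_bgc=0, n_hgt=1)
        genome, _, _ = generate_genome(spec, catalog)
        (hgt_acc,) = [a for a, _ in spec.planted_hgt]
        from psifootprint.catalog import assign_families
        from psifootprint.synth import _encode
        from Bio.Seq import Seq

        assigns = assign_families(genome, catalog)
        (gid,) = [a.gene_id for a in assigns if a.accession == hgt_acc]
        beta_bg = codons.solve_beta(spec.genome_gc)
        rng = np.random.default_rng(99)
        for g in genome.genes:
            if g.gene_id == gid:
                prot = str(Seq(g.cds_sequence[: len(g.cds_sequence) // 3 * 3]).translate(11)).rstrip("*")
                g.cds_sequence = _encode(prot, beta_bg, rng)
        out = detect_hgt_signal(genome, assigns, HgtParams())
        assert out[hgt_acc][0] is False

    def test_short_genes_marked_low_confidence(self, catalog):
        spec = null_spec(seed=47, gene_length=80)
        genome, _, _ = generate_genome(spec, catalog)
        stats = hgt_gene_stats(genome)
        assert stats["low_confidence"].all()

    def test_null_false_positive_rate_bounded(self, catalog):
        """Per-family false-positive rate <= 10% at z=2 on unplanted genomes."""
        from psifootprint.catalog import assign_families

        fp = n = 0
        for seed in range(20):
            genome, _, _ = generate_genome(null_spec(seed=500 + seed, n_core=10), catalog)
            out = detect_hgt_signal(genome, assign_families(genome, catalog), HgtParams())
            fp += sum(1 for f, _ in out.values() if f)
            n += len(out)
        assert fp / n <= 0.10

    def test_params_validation(self):
        with pytest.raises(ValueError):
            HgtParams(z_threshold=0)
        with pytest.raises(ValueError):
            HgtParams(features=("tea_leaves",))


class TestMerge:
    def test_single_criterion(self):
        flags = merge_criteria({"A": (2, True)}, {}, {})
        (f,) = flags
        assert f.duplication and not f.in_bgc and not f.phylogeny
        assert f.copy_number == 2

    def test_empty_maps(self):
        assert merge_criteria({}, {}, {}) == []

    def test_union_of_accessions_defaults_false(self):
        flags = merge_criteria({"A": (1, False)}, {"B": (True, ["r1"])}, {"C": (True, 3.0)})
        assert [f.accession for f in flags] == ["A", "B", "C"]
        assert [f.is_hit for f in flags] == [False, True, True]

    def test_idempotent_and_order_independent(self):
        dup = {"A": (2, True), "B": (1, False)}
        bgc = {"B": (True, ["r1"]), "A": (False, [])}
        hgt = {"A": (False, 0.5)}
        first = merge_criteria(dup, bgc, hgt)
        second = merge_criteria(dict(reversed(dup.items())), bgc, hgt)
        assert first == second == merge_criteria(dup, bgc, hgt)


class TestExternalTable:
    def test_roundtrip_through_tsv(self, tmp_path):
        flags = [
            CriterionFlags("TIGR00485", duplication=True, in_bgc=True,
                           bgc_labels=["6_3"], phylogeny=True, copy_number=2,
                           deviation_score=4.25),
            CriterionFlags("TIGR00981", in_bgc=True, bgc_labels=["6_3"], copy_number=1),
            CriterionFlags("TIGR00157", duplication=True, copy_number=2),
        ]
        write_criteria_table(flags, tmp_path / "crit.tsv")
        back = flags_from_arts_rows(read_arts_table(tmp_path / "crit.tsv"))
        assert back == sorted(flags, key=lambda f: f.accession)

    def test_plain_table_copy_number_heuristic(self, tmp_path):
        (tmp_path / "a.tsv").write_text(
            "accession\tduplication\tphylogeny\tbgc\nX1\t+\t-\t-\nX2\t-\t-\t+\n"
        )
        flags = flags_from_arts_rows(read_arts_table(tmp_path / "a.tsv"))
        assert flags[0].copy_number == 2
        assert flags[1].copy_number == 1
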