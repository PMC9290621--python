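"""Format round-trips and coordinate conventions."""

import pytest

from psifootprint.genome_io import (
    ArtsRow,
    BgcRegion,
    GenomeFormatError,
    GeneRecord,
    GenomeAnnotation,
    read_arts_table,
    read_bgc_regions,
    read_genome,
    read_report_json,
    write_bed,
    write_genbank,
    write_gff3,
    write_report,
)
from psifootprint.synth import generate_genome, load_fixture_table, recovery_spec


def _gene_tuples(genome):
    return {
        g.gene_id: (g.contig_id, g.start, g.end, g.strand, g.cds_sequence)
        for g in genome.genes
    }


def test_genbank_roundtrip_preserves_genes(tmp_path, small_genome):
    genome, _, _ = small_genome
    p = tmp_path / "g.gbk"
    write_genbank(genome, p)
    back = read_genome(p, "genbank", strain_id=genome.strain_id)
    assert _gene_tuples(back) == _gene_tuples(genome)
    assert back.contigs == genome.contigs


def test_genbank_gff3_coordinate_roundtrip(tmp_path, small_genome):
    """GenBank -> internal -> GFF3 -> internal preserves (start, end, strand)."""
    genome, _, _ = small_genome
    write_gff3(genome, tmp_path / "g.gff3", tmp_path / "g.fna")
    back = read_genome(tmp_path / "g.gff3", "gff3", fasta=tmp_path / "g.fna",
                       strain_id=genome.strain_id)
    assert _gene_tuples(back) == _gene_tuples(genome)


def test_gff3_minus_strand_convention(tmp_path):
    seq = "A" * 100 + "TTACATGGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTT" + "A" * 40
    (tmp_path / "c.fna").write_text(">chr1\n" + seq + "\n")
    (tmp_path / "c.gff3").write_text(
        "##gff-version 3\nchr1\tsrc\tCDS\t101\t160\t.\t-\t0\tID=g1;product=test\n"
    )
    g = read_genome(tmp_path / "c.gff3", "gff3", fasta=tmp_path / "c.fna")
    (rec,) = g.genes
    assert (rec.start, rec.end, rec.strand) == (101, 160, "-")
    # CDS is the reverse complement of the plus-strand slice
    import re

    plus = seq[100:160]
    rc = plus.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    assert rec.cds_sequence == rc


def test_synthetic_roundtrip_matches_manifest(tmp_path, catalog):
    spec = recovery_spec(seed=21)
    genome, _, manifest = generate_genome(spec, catalog, out_dir=tmp_path)
    back = read_genome(tmp_path / "genome.gbk", strain_id=genome.strain_id)
    truth_ids = {t["gene_id"] for t in manifest.gene_truth}
    read_ids = {g.gene_id for g in back.genes}
    assert truth_ids <= read_ids
    assert len(back.genes) == len(genome.genes)


def test_unknown_genome_format():
    with pytest.raises(GenomeFormatError, match="genbank"):
        read_genome("x.txt", format="fastq")


def test_gff3_requires_fasta():
    with pytest.raises(GenomeFormatError, match="FASTA"):
        read_genome("x.gff3", format="gff3")


class TestBgcRegions:
    def test_bed_zero_based_conversion(self, tmp_path):
        (tmp_path / "r.bed").write_text("chr1\t999\t2000\tr1\n")
        (region,) = read_bgc_regions(tmp_path / "r.bed", "bed")
        assert (region.start, region.end, region.region_id) == (1000, 2000, "r1")

    def test_bed_export_is_bit_stable(self, tmp_path):
        content = "chr1\t999\t2000\tr1\nchr1\t5000\t9000\tr2\nchr2\t0\t100\tr3\n"
        (tmp_path / "r.bed").write_text(content)
        regions = read_bgc_regions(tmp_path / "r.bed", "bed")
        write_bed(regions, tmp_path / "r2.bed")
        assert (tmp_path / "r2.bed").read_text() == content

    def test_gff_regions_sorted(self, tmp_path):
        (tmp_path / "r.gff").write_text(
            "##gff-version 3\n"
            "c1\tsrc\tregion\t5000\t9000\t.\t+\t.\tID=r2\n"
            "c1\tsrc\tregion\t100\t900\t.\t+\t.\tID=r1\n"
        )
        regions = read_bgc_regions(tmp_path / "r.gff", "gff3")
        assert [r.region_id for r in regions] == ["r1", "r2"]

    def test_empty_file(self, tmp_path):
        (tmp_path / "r.bed").write_text("")
        assert read_bgc_regions(tmp_path / "r.bed", "bed") == []

    def test_unknown_format(self, tmp_path):
        with pytest.raises(GenomeFormatError, match="supported"):
            read_bgc_regions(tmp_path / "r.xyz", "xyz")

    def test_antismash_json(self, tmp_path):
        (tmp_path / "r.json").write_text(
            '{"records": [{"id": "c1", "areas": ['
            '{"start": 999, "end": 2000, "products": ["thiopeptide"]},'
            '{"start": 4999, "end": 9000, "products": ["NRPS"]}]}]}'
        )
        regions = read_bgc_regions(tmp_path / "r.json", "antismash-json")
        assert len(regions) == 2
        assert regions[0].start == 1000
        assert regions[0].cluster_type == "thiopeptide"


class TestArtsTable:
    def test_region_label_means_true(self, tmp_path):
        (tmp_path / "a.tsv").write_text(
            "accession\tduplication\tphylogeny\tbgc\nTIGR00485\t+\t+\t6_3\n"
        )
        (row,) = read_arts_table(tmp_path / "a.tsv")
        assert row.duplication and row.phylogeny and row.in_bgc
        assert row.bgc_label == "6_3"

    def test_all_minus(self, tmp_path):
        (tmp_path / "a.tsv").write_text(
            "accession\tduplication\tphylogeny\tbgc\nTIGR00001\t-\t-\t-\n"
        )
        (row,) = read_arts_table(tmp_path / "a.tsv")
        assert not (row.duplication or row.phylogeny or row.in_bgc)

    def test_missing_column(self, tmp_path):
        (tmp_path / "a.tsv").write_text("accession\tduplication\tbgc\nX\t+\t-\n")
        with pytest.raises(GenomeFormatError, match="phylogeny"):
            read_arts_table(tmp_path / "a.tsv")

    def test_fixture_criterion_counts(self, tmp_path):
        """The packaged 15-row hit table: 9 duplicated, 6 deviant, 13 in a BGC."""
        df = load_fixture_table("berninamycin_producer_hits")
        df.to_csv(tmp_path / "t3.tsv", sep="\t", index=False)
        rows = read_arts_table(tmp_path / "t3.tsv")
        assert len(rows) == 15
        assert sum(r.duplication for r in rows) == 9
        assert sum(r.phylogeny for r in rows) == 6
        assert sum(r.in_bgc for r in rows) == 13


class TestReports:
    def test_tsv_layout(self, tmp_path, catalog):
        from psifootprint.footprint import FootprintResult

        r = FootprintResult(
            strain_id="Jiangella alkaliphila 45079",
            hit_genes=71,
            ri_present={s: s not in ("rplC", "rplK") for s in
                        ("rpsE", "rpsL", "rplC", "rplD", "rplK", "rplQ", "rplV")},
            ri_count=5,
            candidate=True,
        )
        write_report([r], tmp_path / "rep.tsv", "tsv")
        lines = (tmp_path / "rep.tsv").read_text().splitlines()
        assert lines[0].startswith("strain_id\thit_genes\trpsE")
        assert lines[1] == "Jiangella alkaliphila 45079\t71\t+\t+\t-\t+\t-\t+\t+\t5\ttrue"

    def test_empty_results_header_only(self, tmp_path):
        write_report([], tmp_path / "rep.tsv", "tsv")
        assert len((tmp_path / "rep.tsv").read_text().splitlines()) == 1

    def test_json_roundtrip(self, tmp_path, catalog, small_genome):
        from psifootprint import assign_families, compute_footprint, evaluate_criteria

        genome, regions, _ = small_genome
        flags = evaluate_criteria(genome, assign_families(genome, catalog), catalog, regions)
        res = compute_footprint(genome.strain_id, flags, catalog)
        write_report([res], tmp_path / "rep.json", "json")
        (back,) = read_report_json(tmp_path / "rep.json")
        assert back == res


def test_gene_record_invariants():
    with pytest.raises(ValueError):
        GeneRecord("g", "c", 0, 10, "+")
    with pytest.raises(ValueError):
        GeneRecord("g", "c", 10, 5, "+")
    with pytest.raises(ValueError):
        GeneRecord("g", "c", 1, 10, "*")
    with pytest.raises(ValueError):
        GenomeAnnotation("s", {"c": "ACGT"}, [GeneRecord("g", "missing", 1, 2, "+")])
    with pytest.raises(ValueError):
        BgcRegion("r", "c", 10, 5)
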