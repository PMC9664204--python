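import random

import pytest

from wgdkit.io_formats import parse_newick
from wgdkit.io_formats.tables import GeneRecord, GeneTable
from wgdkit.synteny_paralogon import (
    SyntenyConfig,
    compare_synteny,
    detect_paralogon,
    extract_window,
    genes_retained,
    select_candidate_families,
)
from wgdkit.synthetic_data import SimulationConfig, simulate


def make_table(species, rows):
    table = GeneTable(species)
    for gene_id, family, chrom, start, *rest in rows:
        status = rest[0] if rest else "coding"
        table.add(GeneRecord(gene_id, species, family, chrom, start, start + 1000,
                             status=status))
    return table


class TestExtractWindow:
    def test_window_arithmetic(self):
        table = make_table("sp", [("f", "fam", "chr1", 20_000_000)])
        table.add(GeneRecord("f2", "sp", "fam2", "chr1", 20_000_000, 20_010_000))
        window = extract_window(table, "f2", SyntenyConfig())
        assert (window.start, window.end) == (10_000_000, 30_010_000)

    def test_window_clipped_at_zero(self):
        table = make_table("sp", [])
        table.add(GeneRecord("f", "sp", "fam", "chr1", 2_000_000, 2_005_000))
        window = extract_window(table, "f", SyntenyConfig())
        assert (window.start, window.end) == (0, 12_005_000)

    def test_unknown_focal_gene(self):
        table = make_table("sp", [("g", "fam", "chr1", 0)])
        with pytest.raises(KeyError, match="ghost"):
            extract_window(table, "ghost", SyntenyConfig())

    @pytest.mark.parametrize("seed", range(5))
    def test_members_equal_naive_overlap_scan(self, seed):
        rng = random.Random(seed)
        table = GeneTable("sp")
        for i in range(200):
            chrom = f"chr{rng.randrange(3) + 1}"
            start = rng.randrange(50_000_000)
            table.add(GeneRecord(f"g{i}", "sp", f"fam{i % 20}", chrom,
                                 start, start + rng.randrange(1, 100_000)))
        config = SyntenyConfig(window_radius=5_000_000)
        focal_id = f"g{rng.randrange(200)}"
        window = extract_window(table, focal_id, config)
        focal = table.get(focal_id)
        lo = max(0, focal.start - config.window_radius)
        hi = focal.end + config.window_radius
        naive = {
            g.gene_id for g in table
            if g.chromosome == focal.chromosome and g.start < hi and lo < g.end
        }
        assert {g.gene_id for g in window.members} == naive


class TestSelectCandidateFamilies:
    def test_floor_and_extension_flags(self):
        rows = []
        # genome-wide family sizes 1..5; one member of each in the window
        for size in range(1, 6):
            for k in range(size):
                rows.append((f"f{size}_{k}", f"fam{size}",
                             "chr1" if k == 0 else "chr2", 1000 * (size + k)))
        table = make_table("sp", rows)
        window = extract_window(table, "f1_0", SyntenyConfig(window_radius=10**7))
        selected = select_candidate_families([window], table, SyntenyConfig())
        assert set(selected) == {"fam2", "fam3", "fam4", "fam5"}
        assert selected["fam3"] and selected["fam4"]
        assert not selected["fam2"] and not selected["fam5"]

    def test_empty_window(self):
        table = make_table("sp", [("g", "fam", "chr1", 0)])
        window = extract_window(table, "g", SyntenyConfig())
        window.members = []
        assert select_candidate_families([window], table, SyntenyConfig()) == {}

    def test_lossless_simulation_selects_every_family(self):
        tree = parse_newick("((A,B)V)R;")
        tree.wgd_tags = {"R": "1R", "V": "2R"}
        config = SimulationConfig(species_tree=tree, n_families=6,
                                  genes_per_chromosome=6, seed=0)
        result = simulate(config)
        table = result.gene_tables["A"]
        syn = SyntenyConfig(window_radius=10**9)
        windows = [extract_window(table, g.gene_id, syn) for g in table]
        selected = select_candidate_families(windows, table, syn)
        assert set(selected) == set(result.truth_log.family_of.values())


class TestDetectParalogon:
    def quartet_toy(self, n_quartets=3, n_triplets=8, n_doublets=0):
        """One gene per family per region on chromosomes c1..c4."""
        rows = []
        fams = []
        for i in range(n_quartets):
            fams.append((f"q{i}", 4))
        for i in range(n_triplets):
            fams.append((f"t{i}", 3))
        for i in range(n_doublets):
            fams.append((f"d{i}", 2))
        for fam, spread in fams:
            for r in range(spread):
                rows.append((f"{fam}_c{r + 1}", fam, f"c{r + 1}",
                             100_000 * (hash(fam) % 50 + r)))
        return make_table("toy", rows), {f for f, _ in fams}

    def test_lossless_2r_recovers_four_regions(self):
        tree = parse_newick("((A,B)V)R;")
        tree.wgd_tags = {"R": "1R", "V": "2R"}
        sim = SimulationConfig(species_tree=tree, n_families=8,
                               genes_per_chromosome=8, seed=3)
        result = simulate(sim)
        table = result.gene_tables["A"]
        report = detect_paralogon(table, ["chr1"], set(table.families()))
        assert sorted(r.chromosome for r in report.regions) == [
            "chr1", "chr1_w1", "chr1_w1_w2", "chr1_w2"
        ]
        assert report.multiplicity_histogram == {4: 8}

    def test_no_multicopy_families_keeps_seeds_only(self):
        rows = [(f"g{i}", f"fam{i}", "c1", 100_000 * i) for i in range(5)]
        rows += [(f"h{i}", f"other{i}", "c2", 100_000 * i) for i in range(5)]
        table = make_table("sp", rows)
        report = detect_paralogon(table, ["c1"], {f"fam{i}" for i in range(5)})
        assert [r.chromosome for r in report.regions] == ["c1"]
        assert all(k == 1 for k in report.multiplicity_histogram)

    def test_no_seed_regions_is_error(self):
        table = make_table("sp", [("g", "f", "c1", 0)])
        with pytest.raises(ValueError, match="seed"):
            detect_paralogon(table, [], {"f"})

    def test_toy_quartet_triplet_histogram(self):
        table, fams = self.quartet_toy(n_quartets=3, n_triplets=8)
        report = detect_paralogon(table, ["c1"], fams)
        assert len(report.regions) == 4
        assert report.multiplicity_histogram == {4: 3, 3: 8}
        assert report.multiplicity_histogram.get(2, 0) == 0

    def test_histogram_sums_to_family_count(self):
        table, fams = self.quartet_toy(n_quartets=2, n_triplets=5, n_doublets=3)
        report = detect_paralogon(table, ["c1"], fams)
        assert sum(report.multiplicity_histogram.values()) == len(
            report.family_membership
        )

    def test_chromosome_renaming_equivariance(self):
        table, fams = self.quartet_toy()
        report = detect_paralogon(table, ["c1"], fams)
        renamed = GeneTable("toy2")
        mapping = {"c1": "zz9", "c2": "aa1", "c3": "mm5", "c4": "kk2"}
        for rec in table:
            renamed.add(GeneRecord(rec.gene_id, "toy2", rec.family_id,
                                   mapping[rec.chromosome], rec.start, rec.end))
        report2 = detect_paralogon(renamed, ["zz9"], fams)
        hist1 = report.multiplicity_histogram
        assert report2.multiplicity_histogram == hist1
        got = {mapping[r.chromosome] for r in report.regions}
        assert got == {r.chromosome for r in report2.regions}


class TestGenesRetained:
    def test_full_quartet_toy(self):
        table, fams = TestDetectParalogon().quartet_toy(n_quartets=11, n_triplets=0)
        report = detect_paralogon(table, ["c1"], fams)
        assert genes_retained(report) == 44

    def test_printed_counts_toy(self):
        # 11 neighboring families totaling 35 genes across four regions:
        # 3 quartets + 7 triplets + 1 doublet = 12 + 21 + 2
        table, fams = TestDetectParalogon().quartet_toy(
            n_quartets=3, n_triplets=7, n_doublets=1
        )
        report = detect_paralogon(table, ["c1"], fams)
        assert len(report.family_membership) == 11
        assert genes_retained(report) == 35

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_brute_force_sum(self, seed):
        rng = random.Random(seed)
        rows = []
        fams = set()
        for i in range(30):
            fam = f"fam{rng.randrange(10)}"
            fams.add(fam)
            rows.append((f"g{i}", fam, f"c{rng.randrange(4) + 1}",
                         rng.randrange(100) * 10_000))
        table = make_table("sp", rows)
        report = detect_paralogon(table, ["c1"],
                                  fams, SyntenyConfig(
                                      min_shared_families_per_region_pair=1))
        brute = sum(
            count for per in report.family_membership.values()
            for count in per.values()
        )
        assert genes_retained(report) == brute


class TestCompareSynteny:
    def family_map(self):
        fams = ["FOCAL", "N1", "N2", "N3", "N4", "LEFT", "RIGHT"]
        return {f: f for f in fams}

    def test_identical_tables_all_present(self):
        rows = [("a", "N1", "c1", 0), ("b", "FOCAL", "c1", 100_000),
                ("c", "N2", "c1", 200_000)]
        tables = {"sp1": make_table("sp1", rows), "sp2": make_table("sp2", rows)}
        comparison = compare_synteny(tables, self.family_map(), "FOCAL")
        for row in comparison.rows:
            assert row.focal_status == "present"
            assert row.neighbor_status["N1"] == "present"
            assert row.flank_contiguous is None

    def test_missing_focal_with_adjacent_flanks(self):
        with_focal = [("l", "LEFT", "c1", 0), ("f", "FOCAL", "c1", 100_000),
                      ("r", "RIGHT", "c1", 200_000)]
        without = [("l", "LEFT", "c1", 0), ("r", "RIGHT", "c1", 100_000)]
        tables = {"has": make_table("has", with_focal),
                  "lacks": make_table("lacks", without)}
        comparison = compare_synteny(
            tables, self.family_map(), "FOCAL",
            expected_flanks=("LEFT", "RIGHT"),
        )
        rows = {r.species: r for r in comparison.rows}
        assert rows["has"].focal_status == "present"
        assert rows["lacks"].focal_status == "missing"
        assert rows["lacks"].flank_contiguous is True

    def test_flanks_not_adjacent_when_separated(self):
        rows = [("l", "LEFT", "c1", 0), ("x", "N1", "c1", 50_000),
                ("r", "RIGHT", "c1", 100_000)]
        tables = {"sp": make_table("sp", rows)}
        comparison = compare_synteny(
            tables, self.family_map(), "FOCAL",
            expected_flanks=("LEFT", "RIGHT"),
        )
        assert comparison.rows[0].flank_contiguous is False

    def test_duplicated_neighbors_vs_single_copy(self):
        teleost = [("f", "FOCAL", "c1", 0)]
        for i, fam in enumerate(["N1", "N2", "N3", "N4"]):
            teleost.append((f"{fam}a", fam, "c1", 100_000 * (i + 1)))
            teleost.append((f"{fam}b", fam, "c2", 100_000 * (i + 1)))
        gar = [("f", "FOCAL", "c1", 0)]
        for i, fam in enumerate(["N1", "N2", "N3", "N4"]):
            gar.append((f"{fam}a", fam, "c1", 100_000 * (i + 1)))
        tables = {"teleost": make_table("teleost", teleost),
                  "gar": make_table("gar", gar)}
        comparison = compare_synteny(tables, self.family_map(), "FOCAL")
        rows = {r.species: r for r in comparison.rows}
        for fam in ["N1", "N2", "N3", "N4"]:
            assert rows["teleost"].neighbor_status[fam] == "duplicated"
            assert rows["gar"].neighbor_status[fam] == "present"

    def test_pseudogene_focal_status(self):
        rows = [("f", "FOCAL", "c1", 0, "pseudogene"), ("n", "N1", "c1", 100_000)]
        tables = {"sp": make_table("sp", rows)}
        comparison = compare_synteny(tables, self.family_map(), "FOCAL")
        assert comparison.rows[0].focal_status == "pseudogene"

    def test_unplaceable_species(self):
        rows = [("z", "UNRELATED", "c9", 0)]
        tables = {"sp": make_table("sp", rows)}
        comparison = compare_synteny(tables, self.family_map(), "FOCAL")
        assert comparison.rows[0].focal_status == "unplaceable"
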