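"""Endpoint semantics versus the naive full-scan reference, plus the
allele-total, chromatid and privacy-guard contracts."""

import math

import numpy as np
import pytest

from popvarsum.datastore import VariantStore
from popvarsum.errors import PrivacyRefusal, UnknownAttributeError, UnknownGeneError
from popvarsum.popquery import (
    FrequencyRow,
    GroupCountCube,
    PopulationFilter,
    QueryEngine,
    RegionSpec,
    VariantSpec,
    privacy_guard,
)


def common_variant_specs(truth, n, rng, min_carriers=1):
    """Coordinate specs for planted variants, preferring carried ones."""
    counts = {}
    for row in truth.occurrence.values():
        for k in row:
            counts[k] = counts.get(k, 0) + 1
    keys = [k for k, c in sorted(counts.items()) if c >= min_carriers]
    rng.shuffle(keys)
    specs = []
    for raw in keys[:n]:
        chrom, pos, ref, alt = raw.split(":")
        if alt.startswith("<"):
            continue
        from helpers import normalize_key_oracle

        c, left, r, a = normalize_key_oracle(chrom, int(pos), ref, alt)
        specs.append(VariantSpec(chrom=c, left=left, ref=r, alt=a))
    return specs


def random_filters(cohort, n=25, seed=11):
    """A seeded stream of increasingly awkward population filters."""
    truth = cohort["truth"]
    rng = np.random.default_rng(seed)
    genes = [g["name"] for g in truth.genes]
    specs = common_variant_specs(truth, 40, rng, min_carriers=2)
    filters = [PopulationFilter()]
    for _ in range(n):
        meta = {}
        if rng.random() < 0.5:
            meta["gender"] = [rng.choice(["female", "male"])]
        if rng.random() < 0.4:
            meta["ethnicity"] = list(
                rng.choice(
                    ["white", "asian", "black or african american", "latin american"],
                    size=rng.integers(1, 3),
                    replace=False,
                )
            )
        if rng.random() < 0.3:
            meta["health_status"] = [rng.choice(["true", "false"])]
        with_v, without_v, same, diff, in_region = (), (), (), None, None
        if specs and rng.random() < 0.5:
            with_v = (specs[rng.integers(len(specs))],)
        if specs and rng.random() < 0.4:
            w = specs[rng.integers(len(specs))]
            if w not in with_v:
                without_v = (w,)
        if specs and rng.random() < 0.25:
            same = tuple(
                specs[i] for i in rng.choice(len(specs), size=2, replace=False)
            )
        if specs and rng.random() < 0.2:
            diff = tuple(
                specs[i] for i in rng.choice(len(specs), size=2, replace=False)
            )
        if rng.random() < 0.3:
            in_region = RegionSpec(gene=str(rng.choice(genes)))
        filters.append(
            PopulationFilter(
                meta=meta, with_variants=with_v, without_variants=without_v,
                on_same_chrom_copy=same, on_diff_chrom_copy=diff, in_region=in_region,
            )
        )
    return filters


class TestSelectPopulation:
    def test_empty_filter_selects_everyone(self, small_cohort):
        pop = small_cohort["engine"].select_population(PopulationFilter())
        assert len(pop) == small_cohort["config"].n_donors

    def test_matches_naive_scan(self, small_cohort):
        engine, naive = small_cohort["engine"], small_cohort["naive"]
        for flt in random_filters(small_cohort):
            assert engine.select_population(flt) == naive.select(flt), flt

    def test_variant_by_id_equivalent_to_coordinates(self, small_cohort):
        truth = small_cohort["truth"]
        v = next(
            v for v in truth.variants
            if v["type"] == "SEQ" and any(
                f"{v['chrom']}:{v['pos']}:{v['ref']}:{v['alt']}" in row
                for row in truth.occurrence.values()
            )
        )
        from helpers import normalize_key_oracle

        c, left, r, a = normalize_key_oracle(v["chrom"], v["pos"], v["ref"], v["alt"])
        engine = small_cohort["engine"]
        by_id = engine.select_population(
            PopulationFilter(with_variants=(VariantSpec(id=v["id"]),))
        )
        by_coord = engine.select_population(
            PopulationFilter(with_variants=(VariantSpec(chrom=c, left=left, ref=r, alt=a),))
        )
        assert by_id == by_coord and by_id


class TestTotalAlleles:
    def test_autosome(self, small_cohort):
        assert small_cohort["engine"].total_alleles(["female", "male", "male"], "1", 50) == 6

    def test_x_outside_par(self, small_cohort):
        engine = small_cohort["engine"]
        pos = small_cohort["assembly"].chromosomes["X"] // 2
        assert engine.total_alleles(["male", "female"], "X", pos) == 3

    def test_y_all_female(self, small_cohort):
        pos = small_cohort["assembly"].chromosomes["Y"] // 2
        assert small_cohort["engine"].total_alleles(["female"] * 5, "Y", pos) == 0

    def test_matches_per_donor_enumeration(self, small_cohort):
        """Engine totals equal the naive per-donor ploidy loop on every
        chromosome class x gender mix."""
        engine, naive = small_cohort["engine"], small_cohort["naive"]
        donors = sorted(naive.meta)
        a = small_cohort["assembly"]
        par_pos = 10  # inside the leading PAR
        non_par = a.chromosomes.get("X", 1000) // 2
        for chrom, pos in [("1", 123), ("X", par_pos), ("X", non_par),
                           ("Y", par_pos), ("Y", non_par), ("MT", 5)]:
            genders = [naive.meta_value(d, "gender") for d in donors]
            assert engine.total_alleles(genders, chrom, pos) == naive.total_alleles(
                donors, chrom, pos
            )


class TestDonorGrouping:
    def test_gender_counts(self, small_cohort):
        cube = small_cohort["engine"].donor_grouping(PopulationFilter(), ["gender"])
        naive = small_cohort["naive"].donor_grouping(PopulationFilter(), ["gender"])
        assert cube.as_dict() == naive

    def test_matches_naive_for_random_filters(self, small_cohort):
        engine, naive = small_cohort["engine"], small_cohort["naive"]
        for flt in random_filters(small_cohort, n=15, seed=23):
            got = engine.donor_grouping(flt, ["ethnicity", "gender"]).as_dict()
            assert got == naive.donor_grouping(flt, ["ethnicity", "gender"]), flt

    def test_partition_identity_with_without(self, small_cohort):
        """#(with v1, with v2) + #(with v1, without v2) == #(with v1)."""
        rng = np.random.default_rng(3)
        specs = common_variant_specs(small_cohort["truth"], 10, rng, min_carriers=3)
        engine = small_cohort["engine"]
        v1, v2 = specs[0], specs[1]
        n_both = len(engine.select_population(PopulationFilter(with_variants=(v1, v2))))
        n_only1 = len(
            engine.select_population(
                PopulationFilter(with_variants=(v1,), without_variants=(v2,))
            )
        )
        n_v1 = len(engine.select_population(PopulationFilter(with_variants=(v1,))))
        assert n_both + n_only1 == n_v1

    def test_multi_valued_attribute_rejected_for_grouping(self, small_cohort):
        with pytest.raises(UnknownAttributeError, match="multi-valued"):
            small_cohort["engine"].donor_grouping(PopulationFilter(), ["platform"])

    def test_monotonicity_under_added_constraints(self, small_cohort):
        """Adding a metadata constraint never increases a group's count."""
        engine = small_cohort["engine"]
        base = engine.donor_grouping(PopulationFilter(), ["ethnicity"]).as_dict()
        tighter = engine.donor_grouping(
            PopulationFilter(meta={"gender": ["female"]}), ["ethnicity"]
        ).as_dict()
        for key, count in tighter.items():
            assert count <= base.get(key, 0)


class TestVariantGrouping:
    def test_matches_naive(self, small_cohort):
        engine, naive = small_cohort["engine"], small_cohort["naive"]
        rng = np.random.default_rng(7)
        specs = common_variant_specs(small_cohort["truth"], 8, rng, min_carriers=2)
        for spec in specs:
            got = engine.variant_grouping(PopulationFilter(), ["gender"], spec)
            expected = naive.variant_grouping(PopulationFilter(), ["gender"], spec)
            assert len(got) == len(expected)
            for row in got:
                e = expected[row.key]
                assert row.occurrence == e["occurrence"]
                assert row.population_size == e["population_size"]
                assert row.positive_donors == e["positive_donors"]
                assert row.total_alleles == e["total_alleles"]
                if e["frequency"] is None:
                    assert row.frequency is None
                else:
                    assert math.isclose(row.frequency, e["frequency"], abs_tol=1e-12)

    def test_homozygous_single_donor(self, tmp_path):
        """One donor, homozygous autosomal variant: occurrence 2, size 1,
        frequency 1.0."""
        vcf = tmp_path / "chr1.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tDA\n"
            "1\t100\trs1\tA\tT\t.\tPASS\t.\tGT\t1|1\n"
        )
        meta = tmp_path / "donors.tsv"
        meta.write_text("donor_id\tgender\tpopulation\nDA\tfemale\tCEU\n")
        from popvarsum.variant_transform import transform_dataset

        transform_dataset([vcf], [meta], tmp_path / "g", source="s", assembly="hg19")
        store = VariantStore()
        store.load_gdm_dataset(tmp_path / "g", "s")
        engine = QueryEngine(store, "hg19")
        rows = engine.variant_grouping(
            PopulationFilter(), [], VariantSpec(chrom="1", left=99, ref="A", alt="T")
        )
        assert rows == [
            FrequencyRow(key=(), occurrence=2, population_size=1,
                         positive_donors=1, total_alleles=2, frequency=1.0)
        ]


class TestRanking:
    def test_matches_naive_sort(self, small_cohort):
        engine, naive = small_cohort["engine"], small_cohort["naive"]
        for flt in random_filters(small_cohort, n=8, seed=31):
            if not naive.select(flt):
                continue
            table = naive.variant_table(flt)
            got = engine.rank_variants(flt, order="most_common", limit=10**9)
            assert len(got) == len(table)
            for row in got:
                k = (row["chrom"], row["left"], row["right"], row["ref"], row["alt"])
                e = table[k]
                assert row["donor_count"] == e["donor_count"]
                assert row["occurrence"] == e["occurrence"]
                assert row["total_alleles"] == e["total_alleles"]
                if e["frequency"] is not None:
                    assert math.isclose(row["frequency"], e["frequency"], abs_tol=1e-12)
            freqs = [r["frequency"] or 0.0 for r in got]
            assert freqs == sorted(freqs, reverse=True)

    def test_most_common_reverses_rarest_under_distinct_frequencies(self, small_cohort):
        engine = small_cohort["engine"]
        most = engine.rank_variants(PopulationFilter(), order="most_common", limit=10**9)
        rare = engine.rank_variants(PopulationFilter(), order="rarest", limit=10**9)
        key = lambda r: (r["chrom"], r["left"], r["ref"], r["alt"])
        freqs = [r["frequency"] for r in most]
        if len(set(freqs)) == len(freqs):  # strict duality needs distinct values
            assert [key(r) for r in most] == [key(r) for r in reversed(rare)]
        assert {key(r) for r in most} == {key(r) for r in rare}

    def test_empty_population_refused(self, small_cohort):
        with pytest.raises(PrivacyRefusal):
            small_cohort["engine"].rank_variants(
                PopulationFilter(meta={"population": ["ZZZ"]}), limit=5
            )


class TestVariantsInRegion:
    def test_matches_interval_scan(self, small_cohort):
        engine, naive = small_cohort["engine"], small_cohort["naive"]
        rng = np.random.default_rng(13)
        L = small_cohort["config"].chrom_length
        for _ in range(10):
            start = int(rng.integers(0, L - 1000))
            stop = int(start + rng.integers(500, 20000))
            region = RegionSpec(chrom="1", start=start, stop=stop)
            got = engine.variants_in_region(PopulationFilter(), region)
            table = naive.variant_table(PopulationFilter(), region)
            assert {(r["chrom"], r["left"], r["right"], r["ref"], r["alt"]) for r in got} == set(table)

    def test_gene_region_equals_explicit_interval(self, small_cohort):
        engine = small_cohort["engine"]
        g = small_cohort["truth"].genes[0]
        by_gene = engine.variants_in_region(PopulationFilter(), RegionSpec(gene=g["name"]))
        by_interval = engine.variants_in_region(
            PopulationFilter(), RegionSpec(chrom=g["chrom"], start=g["start"], stop=g["stop"])
        )
        assert by_gene == by_interval

    def test_region_with_no_variants(self, small_cohort):
        got = small_cohort["engine"].variants_in_region(
            PopulationFilter(), RegionSpec(chrom="1", start=0, stop=5)
        )
        assert got == []

    def test_unknown_gene_suggests_near_matches(self, small_cohort):
        name = small_cohort["truth"].genes[0]["name"]
        with pytest.raises(UnknownGeneError, match=name):
            small_cohort["engine"].variants_in_region(
                PopulationFilter(), RegionSpec(gene=name + "X")
            )


class TestChromatidSemantics:
    def test_same_copy_subset_of_with_both(self, phased_cohort):
        """Same-chromatid population is contained in the plain with-both
        population, for random variant pairs."""
        engine = phased_cohort["engine"]
        rng = np.random.default_rng(17)
        specs = common_variant_specs(phased_cohort["truth"], 20, rng, min_carriers=5)
        checked = 0
        for i in range(0, len(specs) - 1, 2):
            v1, v2 = specs[i], specs[i + 1]
            same = set(
                engine.select_population(PopulationFilter(on_same_chrom_copy=(v1, v2)))
            )
            both = set(engine.select_population(PopulationFilter(with_variants=(v1, v2))))
            assert same <= both
            checked += 1
        assert checked >= 5

    def test_opposite_and_same_disjoint_for_single_copy_carriers(self, phased_cohort):
        engine, naive = phased_cohort["engine"], phased_cohort["naive"]
        rng = np.random.default_rng(19)
        specs = common_variant_specs(phased_cohort["truth"], 20, rng, min_carriers=5)
        for i in range(0, len(specs) - 1, 2):
            v1, v2 = specs[i], specs[i + 1]
            same = set(engine.select_population(PopulationFilter(on_same_chrom_copy=(v1, v2))))
            opposite = set(
                engine.select_population(PopulationFilter(on_diff_chrom_copy=(v1, v2)))
            )
            for d in same & opposite:
                # a donor in both must carry one of the variants on both copies
                occ1 = naive.occurrence(d, naive.resolve(v1))
                occ2 = naive.occurrence(d, naive.resolve(v2))
                assert occ1 == 2 or occ2 == 2

    def test_chromatid_queries_match_naive(self, phased_cohort):
        engine, naive = phased_cohort["engine"], phased_cohort["naive"]
        for flt in random_filters(phased_cohort, n=12, seed=29):
            assert engine.select_population(flt) == naive.select(flt)

    def test_unphased_donors_excluded_from_chromatid_queries(self, tmp_path):
        vcf = tmp_path / "chr1.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tDA\tDB\n"
            "1\t100\trs1\tA\tT\t.\tPASS\t.\tGT\t1/0\t1|0\n"
            "1\t200\trs2\tC\tG\t.\tPASS\t.\tGT\t0/1\t1|0\n"
        )
        meta = tmp_path / "donors.tsv"
        meta.write_text("donor_id\tgender\tpopulation\nDA\tfemale\tCEU\nDB\tmale\tYRI\n")
        from popvarsum.variant_transform import transform_dataset

        transform_dataset([vcf], [meta], tmp_path / "g", source="s", assembly="hg19")
        store = VariantStore()
        store.load_gdm_dataset(tmp_path / "g", "s")
        engine = QueryEngine(store, "hg19")
        v1 = VariantSpec(chrom="1", left=99, ref="A", alt="T")
        v2 = VariantSpec(chrom="1", left=199, ref="C", alt="G")
        # both carry both variants, but only DB's phase is trustworthy
        assert engine.select_population(PopulationFilter(with_variants=(v1, v2))) == ["DA", "DB"]
        assert engine.select_population(PopulationFilter(on_same_chrom_copy=(v1, v2))) == ["DB"]


class TestAnnotate:
    def test_matches_linear_scan(self, small_cohort):
        engine, naive = small_cohort["engine"], small_cohort["naive"]
        rng = np.random.default_rng(37)
        L = small_cohort["config"].chrom_length
        for _ in range(15):
            start = int(rng.integers(0, L - 100))
            stop = int(start + rng.integers(1, 30000))
            got = engine.annotate(RegionSpec(chrom="1", start=start, stop=stop))
            assert [g["gene_name"] for g in got] == naive.annotate("1", start, stop)

    def test_variant_inside_and_outside_gene(self, small_cohort):
        g = small_cohort["truth"].genes[0]
        engine = small_cohort["engine"]
        mid = (g["start"] + g["stop"]) // 2
        inside = engine.annotate(RegionSpec(chrom=g["chrom"], start=mid, stop=mid + 1))
        assert g["name"] in [x["gene_name"] for x in inside]
        assert engine.annotate(RegionSpec(chrom=g["chrom"], start=0, stop=1)) == []

    def test_insertion_point_strictly_inside(self, small_cohort):
        g = small_cohort["truth"].genes[0]
        engine = small_cohort["engine"]
        # an insertion exactly at the gene start is before the first base
        boundary = engine.annotate(
            VariantSpec(chrom=g["chrom"], left=g["start"], ref="", alt="TT")
        )
        assert g["name"] not in [x["gene_name"] for x in boundary]
        inside = engine.annotate(
            VariantSpec(chrom=g["chrom"], left=g["start"] + 1, ref="", alt="TT")
        )
        assert g["name"] in [x["gene_name"] for x in inside]

    def test_idh1_tp53_fixture(self, small_cohort, tmp_path):
        """SNVs at the classic glioma loci annotate to IDH1 and TP53 when a
        GENCODE-like fixture carrying those gene spans is loaded
        (synthetic stand-in intervals, GRCh38-style coordinates)."""
        gtf = tmp_path / "glioma_genes.gtf"
        gtf.write_text(
            '2\tsynth\tgene\t208236227\t208266074\t.\t-\t.\tgene_id "IDH1"; gene_name "IDH1";\n'
            '17\tsynth\tgene\t7668402\t7687550\t.\t-\t.\tgene_id "TP53"; gene_name "TP53";\n'
        )
        store = VariantStore()
        store.load_gdm_dataset(small_cohort["gdm"], "kg_synth")
        store.load_annotations(gtf, "glioma_fixture", assembly="grch38")
        engine = QueryEngine(store, "grch38")
        tm1 = engine.annotate(VariantSpec(chrom="2", left=208248386, ref="C", alt="T"))
        tm2 = engine.annotate(VariantSpec(chrom="17", left=7673801, ref="G", alt="A"))
        assert "IDH1" in [g["gene_name"] for g in tm1]
        assert "TP53" in [g["gene_name"] for g in tm2]


class TestPrivacyGuard:
    def test_zero_threshold_never_refuses(self):
        cube = GroupCountCube(("g",), ((("a",), 1), (("b",), 0)))
        assert privacy_guard(cube, 0) is cube
        assert privacy_guard(cube, 1) is cube

    def test_group_below_threshold_refused(self):
        cube = GroupCountCube(("g",), ((("a",), 4),))
        with pytest.raises(PrivacyRefusal):
            privacy_guard(cube, 5)

    def test_exactness_against_threshold_oracle(self):
        """The guard refuses exactly the cubes containing a positive count
        below the threshold."""
        rng = np.random.default_rng(41)
        for _ in range(200):
            counts = [int(c) for c in rng.integers(0, 8, size=rng.integers(1, 6))]
            threshold = int(rng.integers(0, 8))
            cube = GroupCountCube(("k",), tuple(((str(i),), c) for i, c in enumerate(counts)))
            should_refuse = any(0 < c < threshold for c in counts)
            if should_refuse:
                with pytest.raises(PrivacyRefusal):
                    privacy_guard(cube, threshold)
            else:
                assert privacy_guard(cube, threshold) is cube

    def test_engine_threshold_applies_to_grouping(self, small_cohort):
        store = small_cohort["store"]
        engine = QueryEngine(store, small_cohort["assembly"], min_donors=10**6)
        with pytest.raises(PrivacyRefusal):
            engine.donor_grouping(PopulationFilter(), ["gender"])


class TestExport:
    def test_export_then_reload_gives_identical_answers(self, small_cohort, tmp_path):
        engine = small_cohort["engine"]
        flt = PopulationFilter(meta={"gender": ["female"]})
        exported = engine.export_donors(flt, tmp_path / "exp")
        assert exported == engine.select_population(flt)

        store2 = VariantStore()
        store2.load_gdm_dataset(tmp_path / "exp", "reloaded")
        engine2 = QueryEngine(store2, small_cohort["assembly"])
        for group_by in (["gender"], ["ethnicity", "gender"]):
            a = engine.donor_grouping(flt, group_by).as_dict()
            b = engine2.donor_grouping(PopulationFilter(), group_by).as_dict()
            assert a == b

    def test_full_export_reproduces_loaded_content(self, small_cohort, tmp_path):
        engine = small_cohort["engine"]
        engine.export_donors(PopulationFilter(), tmp_path / "full")
        from helpers import gdm_occurrence_matrix

        assert gdm_occurrence_matrix(tmp_path / "full") == gdm_occurrence_matrix(
            small_cohort["gdm"]
        )

    def test_empty_selection_refused(self, small_cohort, tmp_path):
        with pytest.raises(PrivacyRefusal):
            small_cohort["engine"].export_donors(
                PopulationFilter(meta={"population": ["ZZZ"]}), tmp_path / "none"
            )
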