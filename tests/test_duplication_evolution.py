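"""Alignment, duplicate classification, NG86, dating, and QTL overlap."""

import itertools
import math
import random

import pandas as pd
import pytest

from mybkit.datasets import load_duplicate_pairs_reference
from mybkit.duplication_evolution import (
    GENETIC_CODE,
    STOP_CODONS,
    EvolConfig,
    QtlInterval,
    align_protein_pair,
    analyze_duplicates,
    classify_duplication,
    classify_selection,
    codon_align,
    count_substitutions,
    divergence_time,
    find_duplicate_pairs,
    ng86_ka_ks,
    omega_ratio,
    qtl_colocalize,
)
from mybkit.genome import GeneModel

SENSE = sorted(GENETIC_CODE)


class TestAlignment:
    def test_self_alignment_is_perfect(self):
        s = "MKVLDERWQSTN"
        summ = align_protein_pair(s, s)
        assert summ.identity == 1.0
        assert summ.coverage == 1.0

    def test_one_mismatch_over_three_columns(self):
        summ = align_protein_pair("MKV", "MKI")
        assert summ.identity == pytest.approx(2 / 3)
        assert summ.coverage == 1.0

    def test_unrelated_sequences_rarely_pass_coverage(self):
        rng = random.Random(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        passing = 0
        for _ in range(50):
            a = "".join(rng.choice(aas) for _ in range(200))
            b = "".join(rng.choice(aas) for _ in range(200))
            if align_protein_pair(a, b).coverage >= 0.75:
                passing += 1
        assert passing == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_protein_pair("", "MK")


class TestPairDiscovery:
    def test_single_gene_proteome_has_no_pairs(self):
        models = [GeneModel("g1", "chr1", 1, 900, "+")]
        assert find_duplicate_pairs({"g1": "MKVLW" * 20}, models) == []

    def test_missing_gene_model_is_a_linkage_error(self):
        with pytest.raises(KeyError):
            find_duplicate_pairs({"g1": "MKVLW" * 20}, [])

    def test_planted_duplicate_is_reported(self, small_package):
        pairs = find_duplicate_pairs(small_package.proteins, small_package.gene_models)
        found = {(p.query_id, p.subject_id) for p in pairs}
        for rec in small_package.truth["duplicate_truth"]:
            assert tuple(sorted((rec["gene_a"], rec["gene_b"]))) in found

    def test_identity_filter_is_strict(self):
        cfg = EvolConfig(identity_min=0.75)
        # 3 identical of 4 columns = exactly 0.75 -> excluded
        models = [GeneModel(g, "chr1", 1 + i, 900 + i, "+") for i, g in
                  enumerate(["a", "b"])]
        prots = {"a": "WWWWMKVA" * 8, "b": "WWWWMKVG" * 8}
        summ = align_protein_pair(prots["a"], prots["b"])
        hits = find_duplicate_pairs(prots, models, cfg)
        assert all(h.identity > 0.75 for h in hits)
        if summ.identity == pytest.approx(0.875):
            assert hits  # sanity that the fixture aligns end to end


class TestDuplicationMode:
    def _gene(self, gid, chrom, start, end):
        return GeneModel(gid, chrom, start, end, "+")

    def test_small_gap_is_tandem(self):
        a = self._gene("a", "chr1", 1, 1000)
        b = self._gene("b", "chr1", 51_000, 52_000)
        assert classify_duplication(a, b) == "tandem"

    def test_large_gap_is_segmental(self):
        a = self._gene("a", "chr1", 1, 1000)
        b = self._gene("b", "chr1", 151_001, 152_000)
        assert classify_duplication(a, b) == "segmental"

    def test_different_chromosomes_are_segmental(self):
        a = self._gene("a", "chr1", 1, 1000)
        b = self._gene("b", "chr2", 1, 1000)
        assert classify_duplication(a, b) == "segmental"

    def test_exactly_100kb_is_segmental(self):
        a = self._gene("a", "chr1", 1, 1000)
        b = self._gene("b", "chr1", 101_001, 102_000)  # gap exactly 100,000
        assert classify_duplication(a, b) == "segmental"


class TestCodonAlign:
    def test_ungapped_identical_proteins_zip_codons(self):
        cds = "ATGAAAGTT"
        summ = align_protein_pair("MKV", "MKV")
        pairs = codon_align(summ, cds, cds)
        assert pairs == [("ATG", "ATG"), ("AAA", "AAA"), ("GTT", "GTT")]

    def test_translation_mismatch_is_an_error(self):
        summ = align_protein_pair("MKV", "MKV")
        with pytest.raises(ValueError):
            codon_align(summ, "ATGAAAGTT", "ATGAAAAAA")

    def test_gap_column_becomes_codon_gap(self):
        from mybkit.synthetic_data import back_translate
        import numpy as np

        rng = np.random.default_rng(0)
        a = "MKVLWERTYIPASDFGHKLCMKVLWERTYI"
        b = a[:15] + a[16:]  # one internal deletion
        cds_a = back_translate(a, rng)[:-3]
        cds_b = back_translate(b, rng)[:-3]
        summ = align_protein_pair(a, b)
        pairs = codon_align(summ, cds_a, cds_b)
        assert sum(1 for x, y in pairs if x == "---" or y == "---") == 1


def _oracle_counts(pairs):
    """Maximally naive site/pathway enumeration, independent of the library."""
    S = N = Sd = Nd = 0.0
    skipped = 0
    for a, b in pairs:
        if "-" in a or "-" in b or a in STOP_CODONS or b in STOP_CODONS:
            continue

        def syn_sites(codon):
            s = 0.0
            for pos in range(3):
                hits = 0
                for nt in "ACGT":
                    if nt == codon[pos]:
                        continue
                    m = codon[:pos] + nt + codon[pos + 1 :]
                    if m not in STOP_CODONS and GENETIC_CODE[m] == GENETIC_CODE[codon]:
                        hits += 1
                s += hits / 3
            return s

        diff = [i for i in range(3) if a[i] != b[i]]
        tot_s = tot_n = 0.0
        valid = 0
        for order in itertools.permutations(diff):
            cur, s, n, ok = a, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if nxt in STOP_CODONS:
                    ok = False
                    break
                if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                    s += 1
                else:
                    n += 1
                cur = nxt
            if ok:
                tot_s, tot_n, valid = tot_s + s, tot_n + n, valid + 1
        if diff and valid == 0:
            skipped += 1
            continue
        S += (syn_sites(a) + syn_sites(b)) / 2
        N += 3 - (syn_sites(a) + syn_sites(b)) / 2
        if valid:
            Sd += tot_s / valid
            Nd += tot_n / valid
    return S, N, Sd, Nd, skipped


class TestNG86:
    def test_identical_cds_gives_zero_rates_and_na_ratio(self):
        pairs = [("ATG", "ATG"), ("AAA", "AAA")]
        ka, ks, counts = ng86_ka_ks(pairs)
        assert ka == 0 and ks == 0
        assert math.isnan(omega_ratio(ka, ks))

    def test_single_synonymous_third_position_change(self):
        # glycine codons: the third position is fully synonymous
        pairs = [("GGA", "GGG")] + [("GGC", "GGC")] * 29
        ka, ks, counts = ng86_ka_ks(pairs)
        assert ka == 0.0
        assert counts.Sd == 1.0
        ps = 1.0 / counts.S
        assert ks == pytest.approx(-0.75 * math.log(1 - 4 * ps / 3))

    def test_matches_enumeration_oracle_on_random_codon_pairs(self):
        rng = random.Random(1)
        for _ in range(150):
            n = rng.randint(1, 10)
            pairs = [(rng.choice(SENSE), rng.choice(SENSE)) for _ in range(n)]
            counts = count_substitutions(pairs)
            S, N, Sd, Nd, skipped = _oracle_counts(pairs)
            assert counts.S == pytest.approx(S, abs=1e-12)
            assert counts.N == pytest.approx(N, abs=1e-12)
            assert counts.Sd == pytest.approx(Sd, abs=1e-12)
            assert counts.Nd == pytest.approx(Nd, abs=1e-12)
            assert counts.skipped == skipped

    def test_symmetry(self):
        rng = random.Random(2)
        for _ in range(50):
            pairs = [(rng.choice(SENSE), rng.choice(SENSE)) for _ in range(12)]
            swapped = [(b, a) for a, b in pairs]
            ka1, ks1, _ = ng86_ka_ks(pairs)
            ka2, ks2, _ = ng86_ka_ks(swapped)
            assert (math.isnan(ka1) and math.isnan(ka2)) or ka1 == pytest.approx(ka2, abs=1e-12)
            assert (math.isnan(ks1) and math.isnan(ks2)) or ks1 == pytest.approx(ks2, abs=1e-12)

    def test_sites_sum_to_three_per_codon(self):
        rng = random.Random(3)
        pairs = [(rng.choice(SENSE), rng.choice(SENSE)) for _ in range(40)]
        counts = count_substitutions(pairs)
        assert counts.S + counts.N == pytest.approx(3 * counts.codons)

    def test_saturation_reports_na(self):
        # maximally different codons drive pN past the Jukes-Cantor bound
        pairs = [("AAA", "GGG"), ("TTT", "CCC"), ("ATA", "GCG")] * 10
        ka, _ks, counts = ng86_ka_ks(pairs)
        assert counts.pN >= 0.75
        assert math.isnan(ka)


class TestDating:
    def test_printed_table_examples(self):
        assert divergence_time(0.526) == pytest.approx(37.79, abs=0.01)
        assert divergence_time(4.312) == pytest.approx(309.77, abs=0.01)

    def test_zero_ks_is_zero_time(self):
        assert divergence_time(0.0) == 0.0

    def test_linearity(self):
        assert divergence_time(0.6) == pytest.approx(3 * divergence_time(0.2))

    def test_na_propagates(self):
        assert math.isnan(divergence_time(float("nan")))


class TestSelection:
    @pytest.mark.parametrize(
        "omega,expected",
        [(0.25, "purifying"), (1.027, "positive"), (1.0, "neutral"),
         (float("nan"), "NA")],
    )
    def test_bands(self, omega, expected):
        assert classify_selection(omega) == expected


@pytest.fixture(scope="module")
def table():
    df = load_duplicate_pairs_reference()
    return df[df.ka.notna()].reset_index(drop=True)


class TestPublishedTable:
    """Ratio and dating arithmetic against the bundled printed estimates."""

    def test_dating_reproduces_printed_column(self, table):
        lam = EvolConfig().lam
        for _, row in table.iterrows():
            # half-ULP interval of the printed 3-decimal Ks vs 2-decimal T
            lo = (row.ks - 5e-4) / (2 * lam) / 1e6
            hi = (row.ks + 5e-4) / (2 * lam) / 1e6
            assert lo <= row.t_mya + 5e-3 and hi >= row.t_mya - 5e-3
        strong = table[table.ks >= 0.2]
        rel = abs(strong.ks.map(divergence_time) - strong.t_mya) / strong.t_mya
        assert (rel < 0.005).all()

    def test_ratio_reproduces_printed_column(self, table):
        for _, row in table.iterrows():
            lo = max(row.ka - 5e-4, 0.0) / (row.ks + 5e-4)
            hi = (row.ka + 5e-4) / max(row.ks - 5e-4, 1e-9)
            assert lo <= row.ratio + 5e-4 and hi >= row.ratio - 5e-4
        strong = table[table.ka >= 0.05]
        rel = abs(strong.ka / strong.ks - strong.ratio) / strong.ratio
        assert (rel < 0.015).all()


class TestQtl:
    def test_contained_gene_is_reported(self):
        genes = [GeneModel("g1", "chr6", 100, 200, "+")]
        qtls = [QtlInterval("chr6", 50, 500, "capsaicin", "q1")]
        out = qtl_colocalize(genes, qtls)
        assert list(out.gene_id) == ["g1"]

    def test_straddling_gene_is_not_reported_under_containment(self):
        genes = [GeneModel("g1", "chr6", 400, 600, "+")]
        qtls = [QtlInterval("chr6", 50, 500, "capsaicin", "q1")]
        assert qtl_colocalize(genes, qtls).empty
        assert len(qtl_colocalize(genes, qtls, any_overlap=True)) == 1

    def test_unknown_chromosome_is_a_reference_error(self):
        genes = [GeneModel("g1", "chr6", 100, 200, "+")]
        qtls = [QtlInterval("chr99", 50, 500, "capsaicin", "q1")]
        with pytest.raises(KeyError):
            qtl_colocalize(genes, qtls, chromosomes={"chr6"})

    def test_synthetic_in_qtl_genes_are_exactly_recovered(self, small_package):
        genes = small_package.gene_models
        chosen = sorted(genes, key=lambda g: g.gene_id)[:3]
        qtls = [
            QtlInterval(g.chromosome, g.start - 10, g.end + 10, "trait", f"q{i}")
            for i, g in enumerate(chosen)
        ]
        out = qtl_colocalize(genes, qtls)
        assert set(out.gene_id) == {g.gene_id for g in chosen}
        assert len(out) == 3


def test_full_pipeline_recovers_planted_divergence(small_package):
    results = analyze_duplicates(
        small_package.proteins, small_package.cds, small_package.gene_models
    )
    truth = {
        tuple(sorted((r["gene_a"], r["gene_b"]))): r
        for r in small_package.truth["duplicate_truth"]
    }
    matched = 0
    for pair in results:
        key = tuple(sorted((pair.gene_a, pair.gene_b)))
        if key in truth:
            matched += 1
            rec = truth[key]
            assert pair.mode == rec["mode"]
            assert pair.ks == pytest.approx(rec["realized_ks"], rel=0.15)
    assert matched == len(truth)
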