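"""Summary-statistics IO and exposure/outcome harmonization."""

import dataclasses

import numpy as np
import pytest

from mrscreen.summstats import (
    AssociationTable,
    SummStatsError,
    VariantAssociation,
    apply_proxies,
    harmonize,
    HarmonizationLog,
    read_association_table,
    write_association_table,
)

from conftest import random_table


def _write(tmp_path, text, name="stats.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


WELL_FORMED = (
    "SNP\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
    "rs1\ta\tg\t0.3\t0.10\t0.02\t1e-9\t50000\n"
    "rs2\tC\tT\t0.5\t-0.05\t0.01\t1e-7\t50000\n"
    "rs3\tG\tT\t.\t0.20\t0.05\t0.02\t.\n"
)


class TestReadWrite:
    def test_well_formed_tsv_parses_fully(self, tmp_path):
        table = read_association_table(_write(tmp_path, WELL_FORMED))
        assert len(table) == 3
        assert table["rs1"].effect_allele == "A"  # upper-cased
        assert table["rs3"].eaf is None and table["rs3"].n is None

    def test_invalid_rows_rejected_not_fatal(self, tmp_path):
        bad = WELL_FORMED + "rs4\tA\tG\t0.2\t0.1\t0\t0.5\t100\n"  # se = 0
        table = read_association_table(_write(tmp_path, bad))
        assert len(table) == 3
        assert "rs4" not in table
        report = table.parse_report
        assert any(lbl == "rs4" for lbl, _ in report.rejected)

    def test_missing_mandatory_column_raises(self, tmp_path):
        p = _write(tmp_path, "SNP\tEA\tOA\tBETA\tSE\nrs1\tA\tG\t0.1\t0.01\n")
        with pytest.raises(SummStatsError, match="mandatory"):
            read_association_table(p)

    def test_zero_valid_rows_raises(self, tmp_path):
        p = _write(tmp_path, "SNP\tEA\tOA\tEAF\tBETA\tSE\tP\tN\nrs1\tA\tA\t0.3\t0.1\t0.01\t0.5\t10\n")
        with pytest.raises(SummStatsError, match="zero valid"):
            read_association_table(p)

    def test_column_map_remaps_names(self, tmp_path):
        p = _write(tmp_path, "rsid\tA1\tA2\tfreq\tb\tserr\tpv\tnn\nrs1\tA\tG\t0.3\t0.1\t0.01\t1e-9\t100\n")
        table = read_association_table(
            p, column_map={"SNP": "rsid", "EA": "A1", "OA": "A2", "EAF": "freq",
                           "BETA": "b", "SE": "serr", "P": "pv", "N": "nn"})
        assert table["rs1"].beta == 0.1

    def test_duplicate_snp_keeps_smallest_p(self, tmp_path):
        dup = WELL_FORMED + "rs1\tA\tG\t0.3\t0.99\t0.02\t1e-20\t50000\n"
        table = read_association_table(_write(tmp_path, dup))
        assert table["rs1"].beta == 0.99
        assert "rs1" in table.parse_report.duplicates_dropped

    def test_write_line_count_and_empty_error(self, tmp_path):
        table = read_association_table(_write(tmp_path, WELL_FORMED))
        out = write_association_table(table, tmp_path / "out.tsv")
        assert len(out.read_text().splitlines()) == 4
        with pytest.raises(SummStatsError):
            write_association_table(AssociationTable("x"), tmp_path / "e.tsv")

    def test_round_trip_identity(self, tmp_path, rng):
        for rep in range(20):
            table = random_table(rng, n=8, name=f"t{rep}")
            path = write_association_table(table, tmp_path / f"rt{rep}.tsv")
            back = read_association_table(path, trait_name=table.trait_name,
                                          sample_size_default=table.sample_size_default)
            assert set(back.records) == set(table.records)
            for sid, rec in table.records.items():
                assert back[sid] == rec


def _flip_outcome(table):
    """Relabel every outcome row to the opposite allele orientation."""
    flipped = {}
    for rec in table:
        flipped[rec.snp_id] = dataclasses.replace(
            rec, effect_allele=rec.other_allele, other_allele=rec.effect_allele,
            beta=-rec.beta, eaf=None if rec.eaf is None else 1.0 - rec.eaf)
    return AssociationTable(table.trait_name, flipped, table.trait_unit,
                            table.sample_size_default)


def _single(ea_x, oa_x, beta_x, ea_y, oa_y, beta_y, eaf_x=0.3, eaf_y=0.3):
    ex = AssociationTable("x", {"rs1": VariantAssociation(
        "rs1", ea_x, oa_x, beta_x, 0.01, 1e-9, eaf=eaf_x, n=10_000)})
    out = AssociationTable("y", {"rs1": VariantAssociation(
        "rs1", ea_y, oa_y, beta_y, 0.02, 0.5, eaf=eaf_y, n=20_000)}, trait_unit="log-odds")
    return ex, out


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_sign(self):
        ex, out = _single("A", "G", 0.10, "G", "A", 0.05)
        (inst,) = harmonize(ex, out)
        assert inst.gamma_y == -0.05 and inst.flipped

    def test_strand_mismatch_resolved_by_complement(self):
        # outcome reported on the other strand: A/G vs T/C
        ex, out = _single("A", "G", 0.10, "T", "C", 0.05)
        (inst,) = harmonize(ex, out)
        assert inst.gamma_y == 0.05 and not inst.flipped

    def test_palindromic_ambiguous_frequency_dropped(self):
        ex, out = _single("A", "T", 0.10, "A", "T", 0.05, eaf_x=0.50, eaf_y=0.50)
        log = HarmonizationLog()
        assert harmonize(ex, out, log=log) == []
        assert "ambiguous" in log.dropped[0][1]

    def test_palindromic_oriented_by_frequency(self):
        # discordant frequencies force a flip despite matching labels
        ex, out = _single("A", "T", 0.10, "A", "T", 0.05, eaf_x=0.2, eaf_y=0.8)
        (inst,) = harmonize(ex, out)
        assert inst.gamma_y == -0.05 and inst.flipped and inst.palindromic

    def test_palindromic_drop_all_policy(self):
        ex, out = _single("A", "T", 0.10, "A", "T", 0.05, eaf_x=0.2, eaf_y=0.2)
        assert harmonize(ex, out, palindrome_policy="drop") == []
        assert len(harmonize(ex, out, palindrome_policy="infer")) == 1

    def test_palindromic_missing_eaf_dropped(self):
        ex, out = _single("A", "T", 0.10, "A", "T", 0.05, eaf_x=None, eaf_y=0.2)
        assert harmonize(ex, out) == []

    def test_irreconcilable_alleles_dropped_not_fatal(self):
        ex, out = _single("A", "G", 0.10, "A", "C", 0.05)
        log = HarmonizationLog()
        assert harmonize(ex, out, log=log) == []
        assert log.dropped[0] == ("rs1", "irreconcilable alleles")

    def test_concordant_pairs_pass_through_unchanged(self, rng):
        exposure = random_table(rng, n=100)
        outcome = random_table(rng, n=100)  # same ids/alleles, different stats
        for sid in outcome.records:
            outcome.records[sid] = dataclasses.replace(
                outcome.records[sid],
                effect_allele=exposure[sid].effect_allele,
                other_allele=exposure[sid].other_allele)
        insts = harmonize(exposure, outcome)
        assert len(insts) == 100
        assert all(not i.flipped for i in insts)
        for i in insts:
            assert i.gamma_y == outcome[i.snp_id].beta

    def test_flip_invariance(self, rng):
        exposure = random_table(rng, n=50)
        outcome = random_table(rng, n=50)
        for sid in outcome.records:
            outcome.records[sid] = dataclasses.replace(
                outcome.records[sid],
                effect_allele=exposure[sid].effect_allele,
                other_allele=exposure[sid].other_allele)
        a = harmonize(exposure, outcome)
        b = harmonize(exposure, _flip_outcome(outcome))
        assert len(a) == len(b) == 50
        for x, y in zip(a, b):
            assert x.snp_id == y.snp_id
            assert x.gamma_y == pytest.approx(y.gamma_y, abs=0)
            assert x.se_y == y.se_y and x.gamma_x == y.gamma_x

    def test_idempotent_on_harmonized_pair(self, rng):
        exposure = random_table(rng, n=20)
        outcome = random_table(rng, n=20)
        for sid in outcome.records:
            outcome.records[sid] = dataclasses.replace(
                outcome.records[sid],
                effect_allele=exposure[sid].effect_allele,
                other_allele=exposure[sid].other_allele)
        first = harmonize(exposure, _flip_outcome(outcome))
        assert all(i.flipped for i in first)
        # rebuild the outcome in the harmonized orientation and re-harmonize
        out2 = AssociationTable("y", {
            i.snp_id: dataclasses.replace(
                outcome[i.snp_id],
                effect_allele=exposure[i.snp_id].effect_allele,
                other_allele=exposure[i.snp_id].other_allele,
                beta=i.gamma_y)
            for i in first}, "sd", outcome.sample_size_default)
        second = harmonize(exposure, out2)
        assert [(i.snp_id, i.gamma_y) for i in first] == \
               [(i.snp_id, i.gamma_y) for i in second]
        assert all(not i.flipped for i in second)

    def test_output_bounded_and_drops_logged(self, rng):
        exposure = random_table(rng, n=30)
        outcome = random_table(rng, n=30)
        # keep only half the SNPs in the outcome, concordant alleles
        keep = list(exposure.records)[:15]
        outcome = AssociationTable("y", {
            sid: dataclasses.replace(
                outcome[sid], effect_allele=exposure[sid].effect_allele,
                other_allele=exposure[sid].other_allele)
            for sid in keep}, "log-odds")
        log = HarmonizationLog()
        insts = harmonize(exposure, outcome, log=log)
        assert len(insts) <= min(len(exposure), len(outcome))
        assert len(insts) + len(log.dropped) == len(exposure)


class TestApplyProxies:
    def _tables(self):
        ex = AssociationTable("x", {
            "rs1": VariantAssociation("rs1", "A", "G", 0.1, 0.01, 1e-9, eaf=0.3),
            "rs2": VariantAssociation("rs2", "C", "T", 0.2, 0.01, 1e-9, eaf=0.4),
        })
        out = AssociationTable("y", {
            "rs1": VariantAssociation("rs1", "A", "G", 0.01, 0.02, 0.5, eaf=0.3),
            "rs9": VariantAssociation("rs9", "C", "T", 0.02, 0.02, 0.5, eaf=0.4),
        }, trait_unit="log-odds")
        return ex, out

    def test_strong_proxy_substituted(self):
        ex, out = self._tables()
        res = apply_proxies(ex, {"rs2": ("rs9", 0.95)}, out)
        assert "rs9" in res and "rs2" not in res
        assert res["rs9"].beta == 0.2  # exposure signal carried over

    def test_weak_proxy_removed(self):
        ex, out = self._tables()
        res = apply_proxies(ex, {"rs2": ("rs9", 0.5)}, out)
        assert set(res.records) == {"rs1"}

    def test_present_snp_untouched(self):
        ex, out = self._tables()
        res = apply_proxies(ex, {"rs1": ("rs9", 0.99)}, out)
        assert res["rs1"] == ex["rs1"]
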