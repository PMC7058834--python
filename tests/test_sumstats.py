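"""Summary-statistics IO, harmonization and instrument-strength checks."""

import numpy as np
import pytest

from cpgmr.exceptions import (
    ConfigurationError,
    DegenerateSampleError,
    EmptyInputError,
    EmptyOverlapError,
)
from cpgmr.simulate import association_scan
from cpgmr.sumstats import (
    AssociationRecord,
    LDMatrix,
    harmonize,
    instrument_strength,
    read_ld_matrix,
    read_sumstats,
    select_instruments,
    write_ld_matrix,
    write_sumstats,
)

from conftest import make_record


CANONICAL_TSV = (
    "variant_id\tchromosome\tposition\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
    "rs1\t1\t1000\tA\tG\t0.30\t0.10\t0.02\t5.7e-07\t846\n"
    "rs2\t1\t2000\tC\tA\t0.45\t-0.25\t0.05\t5.7e-07\t846\n"
    "rs3\t2\t3000\tT\tC\t0.12\t0.00\t0.01\t1.0\t846\n"
)


class TestReadSumstats:
    def test_well_formed_rows_parse_one_to_one(self, tmp_path):
        path = tmp_path / "sumstats.tsv"
        path.write_text(CANONICAL_TSV)
        records, rejects = read_sumstats(path)
        assert len(records) == 3 and rejects == []
        assert records[0].variant_id == "rs1"
        assert records[1].beta == -0.25
        assert records[2].pvalue == 1.0

    def test_unparseable_se_is_rejected_with_reason(self, tmp_path):
        path = tmp_path / "sumstats.tsv"
        path.write_text(
            CANONICAL_TSV.replace("rs2\t1\t2000\tC\tA\t0.45\t-0.25\t0.05",
                                  "rs2\t1\t2000\tC\tA\t0.45\t-0.25\tNA")
        )
        records, rejects = read_sumstats(path)
        assert len(records) == 2
        assert rejects == [("rs2", "unparseable se")]

    def test_dialect_maps_alternative_headers_to_same_records(self, tmp_path):
        canonical = tmp_path / "canonical.tsv"
        canonical.write_text(CANONICAL_TSV)
        alt = tmp_path / "alt.tsv"
        alt.write_text(
            "SNP\tCHR\tBP\tA1\tA2\tFREQ\tBETA\tSE\tP\tN\n"
            + "\n".join(line for line in CANONICAL_TSV.splitlines()[1:])
            + "\n"
        )
        dialect = {
            "variant_id": "SNP", "chromosome": "CHR", "position": "BP",
            "effect_allele": "A1", "other_allele": "A2", "eaf": "FREQ",
            "beta": "BETA", "se": "SE", "pvalue": "P", "n": "N",
        }
        assert read_sumstats(alt, dialect=dialect).records == read_sumstats(canonical).records

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("variant_id\tbeta\tse\nrs1\t0.1\t0.02\n")
        with pytest.raises(ConfigurationError, match="effect_allele"):
            read_sumstats(path)

    def test_empty_file_raises_empty_input(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(EmptyInputError):
            read_sumstats(path)

    def test_roundtrip_through_writer(self, tmp_path):
        records = [make_record(n=846, eaf=0.3), make_record("rs2", "C", "T", -0.2, 0.05)]
        path = tmp_path / "out.tsv"
        write_sumstats(records, path, header_comment="seed=1")
        back, rejects = read_sumstats(path)
        assert rejects == []
        assert [r.variant_id for r in back] == ["rs1", "rs2"]
        assert back[1].beta == pytest.approx(-0.2)


class TestAssociationRecord:
    def test_rejects_inconsistent_reported_pvalue(self):
        # z = 5 -> p ~ 5.7e-7; a reported p of 0.5 is wildly inconsistent
        with pytest.raises(ValueError, match="inconsistent"):
            make_record(beta=0.1, se=0.02, pvalue=0.5)

    def test_accepts_pvalue_rounded_to_one_significant_figure(self):
        record = make_record(beta=0.1, se=0.02, pvalue=6e-7)
        assert record.pvalue == 6e-7

    def test_computes_pvalue_from_z_when_absent(self):
        record = make_record(beta=0.1, se=0.05)
        assert record.pvalue == pytest.approx(0.0455, rel=1e-2)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"effect_allele": "G", "other_allele": "G"},
            {"se": 0.0},
            {"eaf": 1.5},
            {"n": 1},
            {"effect_allele": "N"},
        ],
    )
    def test_invariant_violations_raise(self, kwargs):
        with pytest.raises(ValueError):
            make_record(**kwargs)


class TestHarmonize:
    def test_aligned_records_pass_through(self):
        h = harmonize([make_record(beta=0.5)], [make_record(beta=0.1)])
        assert h.beta_outcome[0] == pytest.approx(0.1)
        assert h.exclusions == []

    def test_swapped_alleles_flip_outcome_sign(self):
        outcome = make_record(effect_allele="G", other_allele="A", beta=0.1, eaf=0.3)
        h = harmonize([make_record(beta=0.5, eaf=0.6)], [outcome])
        assert h.beta_outcome[0] == pytest.approx(-0.1)
        assert h.outcome_records[0].eaf == pytest.approx(0.7)

    def test_strand_complement_is_reconciled(self):
        # exposure A/G, outcome reported on the other strand as T/C
        outcome = make_record(effect_allele="T", other_allele="C", beta=0.1)
        h = harmonize([make_record(beta=0.5)], [outcome])
        assert h.beta_outcome[0] == pytest.approx(0.1)

    def test_ambiguous_palindrome_is_excluded(self):
        exposure = make_record(effect_allele="A", other_allele="T", eaf=0.50)
        outcome = make_record(effect_allele="A", other_allele="T", eaf=0.50)
        keeper = make_record("rs9", beta=0.4)
        h = harmonize([exposure, keeper], [outcome, make_record("rs9", beta=0.1)])
        assert ("rs1", "palindromic, ambiguous eaf") in h.exclusions
        assert h.snps == ["rs9"]

    def test_clear_palindrome_is_retained(self):
        exposure = make_record(effect_allele="A", other_allele="T", eaf=0.10)
        outcome = make_record(effect_allele="A", other_allele="T", beta=0.2, eaf=0.12)
        h = harmonize([exposure], [outcome])
        assert h.snps == ["rs1"] and h.exclusions == []

    def test_irreconcilable_alleles_are_excluded(self):
        outcome = make_record(effect_allele="C", other_allele="G", beta=0.1, eaf=0.2)
        keeper = make_record("rs9", beta=0.4)
        h = harmonize([make_record(), keeper], [outcome, make_record("rs9", beta=0.1)])
        assert ("rs1", "allele mismatch") in h.exclusions

    def test_zero_overlap_raises(self):
        with pytest.raises(EmptyOverlapError):
            harmonize([make_record("rs1")], [make_record("rs2")])

    @pytest.mark.parametrize("seed", [0, 7])
    def test_idempotent_on_own_output(self, seed):
        rng = np.random.default_rng(seed)
        alleles = [("A", "G"), ("C", "T"), ("A", "T"), ("G", "C"), ("T", "G")]
        exposure, outcome = [], []
        for i, (ea, oa) in enumerate(alleles):
            eaf = float(rng.uniform(0.05, 0.35))
            exposure.append(make_record(f"rs{i}", ea, oa, float(rng.normal(0.4, 0.1)), 0.05, eaf=eaf))
            swap = rng.random() < 0.5
            rec = make_record(f"rs{i}", ea, oa, float(rng.normal(0.1, 0.02)), 0.01,
                              eaf=eaf + 0.02)
            outcome.append(rec.flipped() if swap else rec)
        h1 = harmonize(exposure, outcome)
        h2 = harmonize(h1.exposure_records, h1.outcome_records)
        assert h1.snps == h2.snps
        np.testing.assert_allclose(h1.beta_outcome, h2.beta_outcome)
        np.testing.assert_allclose(h1.beta_exposure, h2.beta_exposure)

    def test_flipping_outcome_input_leaves_result_identical(self):
        exposure = [make_record("rs1", beta=0.5, eaf=0.3),
                    make_record("rs2", "C", "T", beta=0.3, eaf=0.2)]
        outcome = [make_record("rs1", beta=0.1, eaf=0.3),
                   make_record("rs2", "C", "T", beta=-0.2, eaf=0.25)]
        h_plain = harmonize(exposure, outcome)
        h_flipped = harmonize(exposure, [r.flipped() for r in outcome])
        np.testing.assert_allclose(h_plain.beta_outcome, h_flipped.beta_outcome)
        np.testing.assert_allclose(h_plain.se_outcome, h_flipped.se_outcome)


class TestSelectInstruments:
    def test_threshold_rule(self):
        # computed two-sided p-values: z=6 -> 2e-9, z=5.5 -> 3.8e-8, z=5 -> 5.7e-7
        records = [
            make_record("rs1", beta=0.60, se=0.1),
            make_record("rs2", beta=0.55, se=0.1),
            make_record("rs3", beta=0.50, se=0.1),
        ]
        kept = select_instruments(records, 1e-7)
        assert [r.variant_id for r in kept] == ["rs1", "rs2"]
        assert select_instruments(records, 1.0) == records
        assert select_instruments(records, 1e-12) == []

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            select_instruments([])


class TestInstrumentStrength:
    def test_direct_arithmetic(self):
        strength = instrument_strength(make_record(beta=0.3, se=0.1, n=846))
        assert strength.f_stat == pytest.approx(9.0)
        assert strength.r_squared == pytest.approx(9.0 / 853.0)

    def test_zero_beta_gives_zero_strength(self):
        strength = instrument_strength(make_record(beta=0.0, se=0.1, n=846, pvalue=1.0))
        assert strength.f_stat == 0.0 and strength.r_squared == 0.0

    def test_f_and_r2_identity(self):
        s = instrument_strength(make_record(beta=0.21, se=0.043, n=1234))
        assert s.f_stat == pytest.approx(
            s.r_squared * (1234 - 2) / (1 - s.r_squared), abs=1e-9
        )

    def test_r2_matches_pearson_oracle_on_simulated_data(self, rng):
        n, maf, true_r2 = 5000, 0.3, 0.1
        g = rng.binomial(2, maf, n).astype(float)
        lam = np.sqrt(true_r2 / (2 * maf * (1 - maf)))
        y = lam * (g - 2 * maf) + np.sqrt(1 - true_r2) * rng.standard_normal(n)
        record = association_scan(g[:, None], y)[0]
        estimated = instrument_strength(record).r_squared
        pearson_r2 = float(np.corrcoef(g, y)[0, 1] ** 2)
        assert estimated == pytest.approx(pearson_r2, abs=2e-3)
        mc_sd = np.sqrt(4 * true_r2 * (1 - true_r2) ** 2 / n)
        assert abs(estimated - true_r2) < 3 * mc_sd

    def test_r2_increases_with_z_and_vanishes_at_fixed_f(self):
        base = instrument_strength(make_record(beta=0.2, se=0.05, n=846))
        stronger = instrument_strength(make_record(beta=0.4, se=0.05, n=846))
        assert stronger.r_squared > base.r_squared
        # at fixed F = z^2, r^2 = F/(F + n - 2) -> 0 as n grows
        huge_n = instrument_strength(make_record(beta=0.2, se=0.05, n=10**8))
        assert huge_n.f_stat == pytest.approx(base.f_stat)
        assert huge_n.r_squared < 1e-6

    def test_small_sample_raises(self):
        with pytest.raises(DegenerateSampleError):
            instrument_strength(make_record(n=2))


class TestLDMatrix:
    def test_roundtrip(self, tmp_path):
        rho = np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 1.0]])
        ld = LDMatrix(("rs1", "rs2", "rs3"), rho)
        path = tmp_path / "ld.tsv"
        write_ld_matrix(ld, path)
        back = read_ld_matrix(path)
        assert back.snps == ld.snps
        np.testing.assert_allclose(back.rho, rho)

    def test_subset_reorders(self):
        rho = np.array([[1.0, 0.5], [0.5, 1.0]])
        ld = LDMatrix(("rs1", "rs2"), rho)
        sub = ld.subset(["rs2", "rs1"])
        np.testing.assert_allclose(sub.rho, rho)

    @pytest.mark.parametrize(
        "rho",
        [
            np.array([[1.0, 0.5], [0.4, 1.0]]),  # asymmetric
            np.array([[0.9, 0.5], [0.5, 1.0]]),  # diagonal not 1
            np.array([[1.0, 1.5], [1.5, 1.0]]),  # out of range
        ],
    )
    def test_invalid_matrices_raise(self, rho):
        with pytest.raises(ValueError):
            LDMatrix(("rs1", "rs2"), rho)
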