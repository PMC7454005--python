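import numpy as np
import pytest

from oracle_utils import exact_ranksum_p
from polq_scars.channels import VariantRecord
from polq_scars.cohort import (
    AssociationResult,
    SampleProfile,
    adjust_bonferroni,
    assign_strata,
    call_gene_status,
    correlate_exposures,
    enrichment_report,
    stratify_expression,
    test_signature_association,
)


class TestGeneStatus:
    def test_nonsense_is_mutant(self):
        v = VariantRecord("chr3", 100, "C", "T", consequence="nonsense")
        assert call_gene_status([v]) == "mutant"

    def test_missense_only_is_wildtype(self):
        v = VariantRecord("chr3", 100, "C", "T", consequence="other")
        assert call_gene_status([v]) == "wildtype"

    def test_no_variants_is_wildtype(self):
        assert call_gene_status([]) == "wildtype"

    def test_frameshift_classes(self):
        assert call_gene_status(["frameshift_deletion"]) == "mutant"
        assert call_gene_status(["frameshift_insertion"]) == "mutant"
        assert call_gene_status(["other", "nonsense"]) == "mutant"


class TestStratify:
    def test_exact_tertiles(self):
        values = {f"s{i}": float(i) for i in range(1, 10)}
        out = stratify_expression(values)
        assert {s for s, c in out.items() if c == "Low"} == {"s1", "s2", "s3"}
        assert {s for s, c in out.items() if c == "High"} == {"s7", "s8", "s9"}
        assert {s for s, c in out.items() if c == "Excluded"} == {"s4", "s5", "s6"}

    def test_uniform_counts(self):
        rng = np.random.default_rng(5)
        values = {f"s{i}": float(v) for i, v in enumerate(rng.random(100))}
        out = stratify_expression(values)
        counts = {c: sum(1 for v in out.values() if v == c) for c in ("Low", "High")}
        # 33 +/- the linear-interpolation quantile convention
        assert counts["Low"] in (33, 34)
        assert counts["High"] in (33, 34)

    def test_constant_degenerate(self):
        out = stratify_expression({"a": 1.0, "b": 1.0, "c": 1.0})
        assert set(out.values()) == {"Excluded"}

    def test_binary_mode(self):
        values = {f"s{i}": float(i) for i in range(1, 10)}
        out = stratify_expression(values, mode="binary")
        assert "Excluded" not in out.values()

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            stratify_expression({"a": 1.0, "b": 2.0})

    def test_partition_per_sample(self):
        profiles = [
            SampleProfile(f"s{i}", {"SBS3": 1.0}, {"POLQ": "wildtype"}, {"POLQ": float(i)})
            for i in range(9)
        ]
        labels = assign_strata(profiles, "POLQ")
        assert len(labels) == 9
        for lab in labels.values():
            assert lab.key in ("WT/High", "WT/Low", "WT/Excluded")


class TestRankTest:
    def test_exact_small_sample(self):
        stat, p = test_signature_association([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(exact_ranksum_p([1, 2, 3], [4, 5, 6]))

    def test_identical_groups(self):
        _, p = test_signature_association([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.99

    def test_all_constant(self):
        _, p = test_signature_association([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_empty_group(self):
        with pytest.raises(ValueError):
            test_signature_association([], [1.0])

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        b = rng.normal(size=40)
        _, p1 = test_signature_association(a, b)
        _, p2 = test_signature_association(a + 17.3, b + 17.3)
        assert p1 == pytest.approx(p2)

    def test_power_two_sd_shift(self):
        rng = np.random.default_rng(42)
        hits = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(0.0, 1.0, size=50)
            b = rng.normal(2.0, 1.0, size=50)
            _, p = test_signature_association(a, b)
            hits += p < 0.05
        assert hits / reps >= 0.95

    def test_paired_mode(self):
        a = [1.0, 2.0, 3.0, 4.0]
        _, p = test_signature_association(a, a, paired=True)
        assert p == 1.0
        with pytest.raises(ValueError):
            test_signature_association([1.0], [1.0, 2.0], paired=True)


class TestBonferroni:
    def test_multiplication(self):
        assert adjust_bonferroni([0.0005], m=82)[0] == pytest.approx(0.041)

    def test_capping(self):
        assert adjust_bonferroni([0.5], m=82) == [1.0]

    def test_zero(self):
        assert adjust_bonferroni([0.0], m=1000) == [0.0]

    def test_dominance(self):
        ps = [0.001, 0.02, 0.3, 1.0]
        adj = adjust_bonferroni(ps)
        assert all(a >= p for a, p in zip(adj, ps))
        assert all(a <= 1.0 for a in adj)

    def test_m_too_small(self):
        with pytest.raises(ValueError):
            adjust_bonferroni([0.1, 0.2], m=1)


class TestPearson:
    def test_perfect_positive(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _ = correlate_exposures(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _ = correlate_exposures(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_planted_rho(self):
        rng = np.random.default_rng(66)
        n, rho = 500, 0.66
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        r, p = correlate_exposures(x, y)
        assert abs(r - rho) < 0.06
        assert p < 1e-10

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            correlate_exposures([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _mini_cohort(rng, n=120, fold=1.0, signature="SBS3"):
    from polq_scars.cohort_sim import CohortSimSpec, simulate_cohort

    enriched = {} if fold == 1.0 else {signature: ("WT/High", fold)}
    spec = CohortSimSpec(n_samples=n, enriched=enriched)
    profiles, truth = simulate_cohort(spec, seed=int(rng.integers(1 << 30)))
    return spec, profiles, truth


class TestEnrichmentReport:
    def test_single_signature_row_sums(self):
        profiles = [
            SampleProfile(f"s{i}", {"SBS3": float(i + 1)}, {"POLQ": "wildtype"},
                          {"POLQ": float(i)})
            for i in range(9)
        ]
        report = enrichment_report(profiles, "POLQ", ["SBS3"])
        sums = report.proportions.dropna().sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_planted_enrichment_recovered(self, rng):
        spec, profiles, _ = _mini_cohort(rng, n=400, fold=3.0)
        report = enrichment_report(profiles, "POLQ", spec.signatures)
        assert "SBS3" in report.flagged

    def test_null_mostly_unflagged(self, rng):
        flags = 0
        for _ in range(5):
            spec, profiles, _ = _mini_cohort(rng, n=200, fold=1.0)
            report = enrichment_report(profiles, "POLQ", spec.signatures)
            flags += len(report.flagged)
        assert flags == 0

    def test_empty_stratum_skipped(self):
        # nobody mutant: MT contrasts must be skipped, not crash
        profiles = [
            SampleProfile(f"s{i}", {"SBS3": float(i + 1), "ID6": 1.0},
                          {"POLQ": "wildtype"}, {"POLQ": float(i)})
            for i in range(12)
        ]
        report = enrichment_report(profiles, "POLQ", ["SBS3", "ID6"])
        assert ("WT/High", "MT/High") in report.skipped_contrasts

    def test_missing_exposure_raises(self):
        profiles = [
            SampleProfile("a", {"SBS3": 1.0}, {"POLQ": "wildtype"}, {"POLQ": 1.0}),
        ]
        with pytest.raises(KeyError):
            enrichment_report(profiles, "POLQ", ["SBS99"])

    def test_association_result_invariants(self):
        with pytest.raises(ValueError):
            AssociationResult("SBS3", ("a", "b"), 0.0, 0.5, 0.4, (1.0, 1.0), (3, 3))
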