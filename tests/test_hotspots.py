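"""eQTL scan, cis/trans classification, hotspot enrichment and overlap."""

from fractions import Fraction

import numpy as np
import pytest

from mediqtl import (
    EqtlRecord,
    RunConfig,
    classify_cis_trans,
    detect_hotspots,
    eqtl_scan,
    overlap_hotspots_with_mediation,
    scan_trios,
    simple_regression,
)
from mediqtl.mediation import slope_pvalue
from mediqtl.simulate import SimulationSpec, simulate_dataset


def binom_upper_tail_oracle(k: int, n: int, p0: float, terms: int = 400) -> float:
    """Exact-rational upper-tail binomial P(K >= k) by cumulative summation.

    Terms beyond ``k + terms`` are negligible at the p0 values in play
    (each successive term shrinks by more than an order of magnitude).
    """
    from math import comb

    p = Fraction(p0).limit_denominator(10**12)
    q = 1 - p
    total = Fraction(0)
    for i in range(k, min(n, k + terms) + 1):
        total += comb(n, i) * p**i * q ** (n - i)
    return float(total)


class TestEqtlScan:
    def test_planted_signal_emitted(self, rng):
        from mediqtl import ExpressionMatrix, GenotypeMatrix

        n = 200
        x = rng.binomial(2, 0.4, n).astype(float)
        m = 0.9 * x + rng.normal(size=n) * 0.3
        g = GenotypeMatrix([f"S{i}" for i in range(n)], ["rs1"], x[:, None])
        e = ExpressionMatrix([f"S{i}" for i in range(n)], ["pr1"], m[:, None])
        recs = list(eqtl_scan(g, e, p_cutoff=1e-5))
        assert len(recs) == 1
        assert recs[0].p < 1e-5

    def test_pvalues_match_simple_regression(self, null_dataset):
        g, e, _, _ = null_dataset
        recs = list(eqtl_scan(g, e, p_cutoff=1.0, emit_all=True))
        by_pair = {(r.snp_id, r.probe_id): r for r in recs}
        rng = np.random.default_rng(3)
        for _ in range(25):
            j = rng.integers(g.n_snps)
            k = rng.integers(e.n_probes)
            x, m = g.dose[:, j], e.values[:, k]
            ok = ~(np.isnan(x) | np.isnan(m))
            fit = simple_regression(x[ok], m[ok])
            r = by_pair[(g.snp_ids[j], e.probe_ids[k])]
            assert r.beta == pytest.approx(fit.slope, rel=1e-9)
            assert r.p == pytest.approx(slope_pvalue(fit), rel=1e-9)

    def test_snp_major_equals_probe_major(self, null_dataset):
        # the significant pair set must not depend on iteration order
        g, e, _, _ = null_dataset
        cutoff = 0.01
        scanned = {(r.snp_id, r.probe_id) for r in eqtl_scan(g, e, p_cutoff=cutoff)}
        brute = set()
        for k in range(e.n_probes):          # probe-major brute force
            for j in range(g.n_snps):
                x, m = g.dose[:, j], e.values[:, k]
                ok = ~(np.isnan(x) | np.isnan(m))
                if ok.sum() < 5 or np.ptp(x[ok]) == 0:
                    continue
                if slope_pvalue(simple_regression(x[ok], m[ok])) < cutoff:
                    brute.add((g.snp_ids[j], e.probe_ids[k]))
        assert scanned == brute

    def test_misaligned_samples_error(self):
        from mediqtl import ExpressionMatrix, GenotypeMatrix

        g = GenotypeMatrix(["A", "B"], ["rs1"], np.zeros((2, 1)))
        e = ExpressionMatrix(["B", "A"], ["pr1"], np.zeros((2, 1)))
        with pytest.raises(ValueError, match="aligned"):
            next(iter(eqtl_scan(g, e)))


class TestCisTrans:
    @pytest.mark.parametrize(
        "sc, sp, pc, pp, window, expected",
        [
            ("1", 5000, "1", 5000, 10**6, True),      # distance 0
            ("1", 5000, "2", 5000, 10**6, False),     # different chromosome
            ("3", 0, "3", 10**6, 10**6, True),        # exactly at window: inclusive
            ("3", 0, "3", 10**6 + 1, 10**6, False),
        ],
    )
    def test_classification(self, sc, sp, pc, pp, window, expected):
        assert classify_cis_trans(sc, sp, pc, pp, window=window) is expected

    def test_missing_annotation_is_unknown(self):
        assert classify_cis_trans(None, 100, "1", 100) is None
        assert classify_cis_trans("1", float("nan"), "1", 100) is None


class TestDetectHotspots:
    def _records(self, counts: dict[str, int]):
        return [EqtlRecord(snp_id=s, probe_id=f"pr{i}", beta=1.0, p=1e-9)
                for s, k in counts.items() for i in range(k)]

    def test_below_min_probes_not_a_hotspot(self):
        recs = self._records({"rs1": 19, "rs2": 25})
        out = detect_hotspots(recs, min_probes=20, n_probes_total=1000,
                              p0=1e-5, n_snps_tested=100)
        assert [h.snp_id for h in out] == ["rs2"]

    def test_exact_binomial_tail_matches_oracle(self):
        recs = self._records({"rs1": 20})
        out = detect_hotspots(recs, min_probes=20, n_probes_total=30_000,
                              p0=1e-5, n_snps_tested=1)
        expected = binom_upper_tail_oracle(20, 30_000, 1e-5)
        assert out[0].enrichment_p_raw == pytest.approx(expected, rel=1e-9)
        assert out[0].enrichment_score == pytest.approx(
            -np.log10(min(1.0, expected)), rel=1e-9)

    def test_bonferroni_at_least_raw_and_capped(self):
        recs = self._records({"rs1": 2})
        out = detect_hotspots(recs, min_probes=2, n_probes_total=50,
                              p0=0.05, n_snps_tested=500)
        h = out[0]
        assert h.enrichment_p_bonferroni >= h.enrichment_p_raw
        assert h.enrichment_p_bonferroni == 1.0  # capped
        assert h.enrichment_score == pytest.approx(0.0)

    def test_count_monotone_in_min_probes(self):
        recs = self._records({"rs1": 5, "rs2": 10, "rs3": 20, "rs4": 40})
        sizes = [
            len(detect_hotspots(recs, min_probes=k, n_probes_total=1000,
                                p0=1e-5, n_snps_tested=10))
            for k in (1, 5, 10, 20, 40, 41)
        ]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 0

    def test_invalid_p0(self):
        with pytest.raises(ValueError):
            detect_hotspots([], min_probes=1, n_probes_total=10, p0=0.0,
                            n_snps_tested=1)


class TestOverlap:
    def test_no_hotspots_gives_zero_counts(self, planted_dataset):
        g, e, p, _ = planted_dataset
        trios = list(scan_trios(g, e, p.trait, RunConfig(trio_p_cutoff=1e-4)))
        res = overlap_hotspots_with_mediation([], trios)
        assert (res.n_overlap_trios, res.n_overlap_snps, res.n_overlap_probes) \
            == (0, 0, 0)

    def test_all_snps_hotspots_identity(self, planted_dataset):
        from mediqtl import Hotspot, summarize_scan

        g, e, p, _ = planted_dataset
        trios = list(scan_trios(g, e, p.trait, RunConfig(trio_p_cutoff=1e-4)))
        hs = [Hotspot(snp_id=s, n_significant_probes=20, enrichment_p_raw=1e-9,
                      enrichment_p_bonferroni=1e-7, enrichment_score=7.0)
              for s in g.snp_ids]
        res = overlap_hotspots_with_mediation(hs, trios)
        full = summarize_scan(trios, alpha=1e-4, n_tests=g.n_snps * e.n_probes)
        assert res.n_overlap_trios == full.n_significant_trios
        assert res.n_overlap_snps == full.n_significant_snps
        assert res.n_overlap_probes == full.n_significant_probes


class TestPlantedMasterRegulator:
    def test_hotspot_snp_and_mediator_recovered(self):
        # one SNP drives 25 probes; one of those probes mediates the trait
        driven = list(range(10, 35))
        spec = SimulationSpec(
            n_samples=200, n_snps=40, n_probes=120,
            maf_range=(0.2, 0.5),  # common variants: effects carry nominal power
            planted_trios=[(5, 10, 0.7, 0.8)],
            hotspot_spec=[(5, driven[1:], 0.7)],
            missing_rate=0.02, seed=31,
        )
        g, e, p, truth = simulate_dataset(spec)
        recs = list(eqtl_scan(g, e, p_cutoff=1e-5))
        hs = detect_hotspots(recs, min_probes=20, n_probes_total=e.n_probes,
                             p0=1e-5, n_snps_tested=g.n_snps)
        assert [h.snp_id for h in hs] == ["snp5"]
        assert hs[0].enrichment_p_bonferroni < 0.05
        trios = list(scan_trios(g, e, p.trait, RunConfig(trio_p_cutoff=1e-5)))
        res = overlap_hotspots_with_mediation(hs, trios)
        assert res.n_overlap_snps == 1
        assert res.n_overlap_probes >= 1
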