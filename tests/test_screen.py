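import numpy as np
import pandas as pd
import pytest

from mrscreen import gwas_data, instruments, screen, simulate
from mrscreen.estimators import MRResult
from mrscreen.screen import (
    ScreenConfig,
    bonferroni_threshold,
    eligibility_filter,
    forward_screen,
    protein_screen,
    reverse_screen,
    three_stage_verdict,
)


def meta_frame(rows):
    defaults = {
        "trait_type": "quantitative", "units": "SD", "n": 50_000,
        "n_variants": 2_000_000, "ancestry": "European",
        "n_case": np.nan, "n_control": np.nan,
        "gene_chrom": "", "gene_start": np.nan, "gene_end": np.nan,
    }
    out = []
    for i, r in enumerate(rows):
        rec = dict(defaults)
        rec["trait_id"] = f"t{i}"
        rec.update(r)
        out.append(rec)
    return pd.DataFrame(out)


class TestEligibility:
    def test_boundary_sample_size_excluded(self):
        meta = meta_frame([{"n": 3000}, {"n": 3001}])
        kept, counts = eligibility_filter(meta)
        assert kept == ["t1"]
        assert counts["sample_size"] == 1

    def test_enumerated_fixture(self):
        meta = meta_frame([
            {}, {}, {}, {}, {}, {},
            {"n": 2000},
            {"n_variants": 500_000},
            {"ancestry": "East Asian"},
            {"n": 100},
        ])
        kept, counts = eligibility_filter(meta)
        assert len(kept) == 6
        assert counts == {"ancestry": 1, "sample_size": 2, "variant_count": 1}

    def test_empty(self):
        kept, counts = eligibility_filter(meta_frame([]))
        assert kept == []


class TestBonferroni:
    def test_exposure_screen_value(self):
        assert bonferroni_threshold(5048, 0.05, 1) == 1e-5

    def test_outcome_screen_value(self):
        assert bonferroni_threshold(10308, 0.05, 1) == 5e-6

    def test_full_precision(self):
        assert bonferroni_threshold(1, 0.05, None) == 0.05
        assert bonferroni_threshold(7, 0.05, None) == pytest.approx(0.05 / 7)

    def test_errors(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)
        with pytest.raises(ValueError):
            bonferroni_threshold(10, 0.05, 0)


def _res(method, estimate=0.3, se=0.02, pval=1e-9, n_snp=10, estimable=True):
    return MRResult(method=method, estimate=estimate, se=se,
                    ci_low=estimate - 2 * se, ci_high=estimate + 2 * se,
                    pval=pval, n_snp=n_snp, estimable=estimable)


class TestThreeStageVerdict:
    def test_full_pass(self):
        results = [_res("ivw"), _res("weighted_median", pval=0.001),
                   _res("ivw_steiger", pval=1e-6)]
        v = three_stage_verdict(results, None, 1e-5, 10)
        assert v.stage1_pass and v.stage2_pass and v.stage3_pass
        assert v.final_pass

    def test_three_snps_fails_stage1(self):
        results = [_res("ivw", n_snp=3), _res("weighted_median", pval=0.001),
                   _res("ivw_steiger", pval=1e-6)]
        v = three_stage_verdict(results, None, 1e-5, 10)
        assert not v.stage1_pass
        assert "n_snp=3" in v.stage1_reason
        assert not v.final_pass

    def test_median_boundary_fails_stage2(self):
        results = [_res("ivw"), _res("weighted_median", pval=0.06),
                   _res("ivw_steiger", pval=1e-6)]
        v = three_stage_verdict(results, None, 1e-5, 10)
        assert not v.stage2_pass

    def test_discordant_sign_fails_stage2(self):
        results = [_res("ivw"), _res("weighted_median", estimate=-0.1,
                                     pval=0.001),
                   _res("ivw_steiger", pval=1e-6)]
        v = three_stage_verdict(results, None, 1e-5, 10)
        assert not v.stage2_pass
        assert "discordant" in v.stage2_reason

    def test_stage3_threshold_scales_with_passers(self):
        results = [_res("ivw"), _res("weighted_median", pval=0.001),
                   _res("ivw_steiger", pval=0.01)]
        ok = three_stage_verdict(results, None, 1e-5, 1)
        tight = three_stage_verdict(results, None, 1e-5, 50)
        assert ok.stage3_pass
        assert not tight.stage3_pass
        assert tight.stage3_threshold == pytest.approx(0.001)

    def test_missing_median_fails_with_reason(self):
        results = [_res("ivw"), _res("ivw_steiger", pval=1e-6)]
        v = three_stage_verdict(results, None, 1e-5, 10)
        assert not v.stage2_pass
        assert "not estimable" in v.stage2_reason


@pytest.fixture(scope="module")
def phenome():
    return simulate.simulate_phenome(
        n_traits=30, frac_causal=0.1, frac_protein=0.1, seed=21)


@pytest.fixture(scope="module")
def forward_output(phenome):
    cfg = ScreenConfig(seed=5, n_boot=100)
    return forward_screen(phenome.exposures, phenome.outcome, phenome.meta,
                          phenome.ld, cfg)


class TestForwardScreen:
    def test_recovers_causal_traits(self, phenome, forward_output):
        v = forward_output.verdicts
        causal = {t for t, d in phenome.truths.items() if d["causal"]}
        flagged = set(v.loc[v["final_pass"], "exposure_id"])
        assert len(flagged & causal) >= len(causal) - 1
        assert len(flagged - causal) <= 1

    def test_deterministic_rerun(self, phenome, forward_output):
        cfg = ScreenConfig(seed=5, n_boot=100)
        again = forward_screen(phenome.exposures, phenome.outcome,
                               phenome.meta, phenome.ld, cfg)
        pd.testing.assert_frame_equal(forward_output.verdicts, again.verdicts)

    def test_manifest_complete(self, forward_output):
        m = forward_output.manifest
        assert m["direction"] == "forward"
        assert m["seed"] == 5
        assert m["screen_threshold"] == bonferroni_threshold(30, 0.05, 1)
        assert "traits" in m and len(m["traits"]) > 0

    def test_verdict_invariant_final_implies_stages(self, forward_output):
        v = forward_output.verdicts
        passed = v[v["final_pass"]]
        assert passed["stage1_pass"].all()
        assert passed["stage2_pass"].all()
        assert passed["stage3_pass"].all()

    def test_proteins_routed_to_protein_arm(self, forward_output):
        v = forward_output.verdicts
        prot = v[v["exposure_id"].str.startswith("prot_")]
        assert (prot["arm"] == "protein").all()
        cmplx = v[v["exposure_id"].str.startswith("trait_")]
        assert (cmplx["arm"] == "complex").all()

    def test_causal_protein_colocalizes(self, phenome, forward_output):
        causal_prots = [t for t, d in phenome.truths.items()
                        if d["causal"] and d["trait_type"] == "protein"]
        for t in causal_prots:
            assert t in forward_output.coloc
            assert forward_output.coloc[t].pp4 > 0.9

    def test_plot_written(self, forward_output, tmp_path):
        path = tmp_path / "screen.png"
        screen.plot_screen(forward_output.verdicts,
                           forward_output.manifest["screen_threshold"], path)
        assert path.stat().st_size > 0


class TestSelfOnSelf:
    def test_exposure_identical_to_outcome_not_flagged(self):
        # same trait on both sides: Steiger cannot support exposure-first
        truth = simulate.make_truth(30, 1.0, seed=33, n_x=50_000, n_y=50_000)
        exp, _ = simulate.simulate_two_sample(truth)
        out = exp.copy()
        meta = pd.DataFrame([
            {"trait_id": "self", "trait_type": "quantitative", "units": "SD",
             "n": 50_000, "n_variants": 2_000_000, "ancestry": "European",
             "n_case": np.nan, "n_control": np.nan, "gene_chrom": "",
             "gene_start": np.nan, "gene_end": np.nan},
        ])
        cfg = ScreenConfig(seed=1, n_boot=50)
        ld = gwas_data.LDReference.identity([])
        outp = forward_screen({"self": exp}, out, meta, ld, cfg)
        row = outp.verdicts.iloc[0]
        # direction test is uninformative (r2_x == r2_y): stage 3 must fail
        assert not row.stage3_pass
        assert not row.final_pass


class TestReverseScreen:
    def test_downstream_traits_flagged(self):
        # one AF-like exposure, 20 outcomes of which 3 are downstream
        seed = 77
        truth = simulate.make_truth(40, 0.0, seed=seed, n_x=100_000)
        exp, _ = simulate.simulate_two_sample(truth, chrom="e0",
                                              id_prefix="afx_")
        outcomes = {}
        meta_rows = [{
            "trait_id": "af", "trait_type": "quantitative", "units": "SD",
            "n": 100_000, "n_variants": 2_000_000, "ancestry": "European",
            "n_case": np.nan, "n_control": np.nan, "gene_chrom": "",
            "gene_start": np.nan, "gene_end": np.nan}]
        for i in range(20):
            theta = 0.3 if i < 3 else 0.0
            t2 = simulate.SimTruth(theta, truth.gamma, truth.alpha, "none",
                                   truth.n_x, 100_000, truth.maf,
                                   seed=seed + 100 + i)
            _, out = simulate.simulate_two_sample(t2, chrom="e0",
                                                  id_prefix="afx_")
            # align decorative allele labels with the shared exposure table
            out[["effect_allele", "other_allele", "eaf"]] = exp[
                ["effect_allele", "other_allele", "eaf"]]
            outcomes[f"o{i:02d}"] = out
            meta_rows.append({
                "trait_id": f"o{i:02d}", "trait_type": "quantitative",
                "units": "SD", "n": 100_000, "n_variants": 2_000_000,
                "ancestry": "European", "n_case": np.nan, "n_control": np.nan,
                "gene_chrom": "", "gene_start": np.nan, "gene_end": np.nan})
        meta = pd.DataFrame(meta_rows)
        cfg = ScreenConfig(seed=3, n_boot=100)
        outp = reverse_screen(exp, outcomes, meta,
                              gwas_data.LDReference.identity([]), cfg,
                              exposure_id="af")
        v = outp.verdicts
        flagged = set(v.loc[v["final_pass"], "outcome_id"])
        assert flagged >= {"o00", "o01", "o02"}  # all downstream recovered
        assert len(flagged - {"o00", "o01", "o02"}) <= 1

    def test_clump_called_once(self, monkeypatch):
        calls = {"n": 0}
        real = screen.clump

        def counting(*a, **k):
            calls["n"] += 1
            return real(*a, **k)

        monkeypatch.setattr(screen, "clump", counting)
        truth = simulate.make_truth(10, 0.0, seed=5)
        exp, _ = simulate.simulate_two_sample(truth)
        outcomes = {}
        meta_rows = []
        for i in range(4):
            t2 = simulate.SimTruth(0.0, truth.gamma, truth.alpha, "none",
                                   truth.n_x, truth.n_y, truth.maf, seed=90 + i)
            _, out = simulate.simulate_two_sample(t2)
            out[["effect_allele", "other_allele", "eaf"]] = exp[
                ["effect_allele", "other_allele", "eaf"]]
            outcomes[f"o{i}"] = out
            meta_rows.append({
                "trait_id": f"o{i}", "trait_type": "quantitative",
                "units": "SD", "n": 50_000, "n_variants": 2_000_000,
                "ancestry": "European", "n_case": np.nan, "n_control": np.nan,
                "gene_chrom": "", "gene_start": np.nan, "gene_end": np.nan})
        reverse_screen(exp, outcomes, pd.DataFrame(meta_rows),
                       gwas_data.LDReference.identity([]),
                       ScreenConfig(seed=1, n_boot=20))
        assert calls["n"] == 1


class TestProteinScreen:
    def _meta(self, tid, chrom, start, end):
        return pd.DataFrame([{
            "trait_id": tid, "trait_type": "protein", "units": "SD",
            "n": 3301, "n_variants": 2_000_000, "ancestry": "European",
            "n_case": np.nan, "n_control": np.nan,
            "gene_chrom": chrom, "gene_start": start, "gene_end": end}])

    def test_shared_causal_passes_and_colocalizes(self):
        rx, ry, ld = simulate.simulate_coloc_region(
            n_snp=40, rho=0.8, shared=True, n_x=3301, n_y=100_000,
            ncp_x=16.0, ncp_y=10.0, seed=8, chrom="g1")
        centre = int(rx["pos"].iloc[10])
        meta = self._meta("p1", "g1", centre - 20_000, centre + 20_000)
        out = protein_screen({"p1": rx}, ry, meta, ld,
                             ScreenConfig(seed=2), screen_threshold=1e-3)
        row = out.verdicts.iloc[0]
        assert row.final_pass
        assert out.coloc["p1"].pp4 > 0.9
        assert row.pp4 > 0.9

    def test_distinct_causal_flagged_discordant(self):
        rx, ry, ld = simulate.simulate_coloc_region(
            n_snp=60, rho=0.9, shared=False, n_x=3301, n_y=100_000,
            ncp_x=16.0, ncp_y=12.0, seed=9, chrom="g2")
        lead = int(rx["pos"].iloc[15])
        meta = self._meta("p2", "g2", rx["pos"].min(), rx["pos"].max())
        out = protein_screen({"p2": rx}, ry, meta, ld,
                             ScreenConfig(seed=2), screen_threshold=0.9)
        row = out.verdicts.iloc[0]
        if row.final_pass:  # MR can pass through LD confounding
            cres = out.coloc["p2"]
            assert cres.pp3 > cres.pp4
            assert "discordant" in row.note

    def test_missing_locus_skipped(self):
        rx, ry, ld = simulate.simulate_coloc_region(
            n_snp=40, rho=0.8, shared=True, seed=10, chrom="g3")
        meta = self._meta("p3", "g3", np.nan, np.nan)
        out = protein_screen({"p3": rx}, ry, meta, ld, ScreenConfig())
        row = out.verdicts.iloc[0]
        assert not row.final_pass
        assert "no gene locus" in row.note

    def test_single_variant_instrument_uses_wald(self, assoc_frame_factory):
        prot = assoc_frame_factory([
            {"chrom": "g4", "pos": 50_000, "pval": 1e-30,
             "beta": 0.8, "se": 0.05, "n": 3301}])
        outc = assoc_frame_factory([
            {"chrom": "g4", "pos": 50_000, "pval": 1e-10,
             "beta": 0.08, "se": 0.01, "n": 100_000}])
        meta = self._meta("p4", "g4", 45_000, 55_000)
        ld = gwas_data.LDReference.identity(["rs0"])
        out = protein_screen({"p4": prot}, outc, meta, ld,
                             ScreenConfig(), screen_threshold=1e-3)
        row = out.verdicts.iloc[0]
        assert row.method == "wald_ratio"
        assert row.n_snp == 1
        # coloc attempted but not estimable with a single shared SNP
        assert "p4" in out.coloc
        assert not out.coloc["p4"].estimable
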