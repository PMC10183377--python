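import numpy as np
import pandas as pd
import pytest

from plaquestate.io import (GeneSet, GenotypeDataset, RegionSet, SumStats,
                            ValidationError)
from plaquestate.prs import (ClumpedPanel, competitive_p, evaluate_prs,
                             hybrid_prs, preferential_clump, qc_base,
                             qc_target, regions_from_genes, regions_from_peaks,
                             resize_peaks, score_prs, threshold_scan,
                             positions_in_regions)


def make_sumstats(vids, pos, p, beta=None, chrom="1", ea=None, oa=None):
    n = len(vids)
    return SumStats(pd.DataFrame({
        "variant_id": vids, "chrom": chrom, "pos": pos,
        "effect_allele": ea if ea is not None else ["A"] * n,
        "other_allele": oa if oa is not None else ["G"] * n,
        "beta": beta if beta is not None else [0.1] * n,
        "p": p, "info": 1.0, "eaf": 0.3,
    }))


def make_geno(vids, pos, dosages, chrom="1", phenotype=None, covariates=None,
              ea=None, oa=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "variant_id": vids, "chrom": chrom, "pos": pos,
        "effect_allele": ea if ea is not None else ["A"] * m,
        "other_allele": oa if oa is not None else ["G"] * m,
        "maf": 0.3, "info": 1.0,
        "missingness": np.isnan(dosages).mean(axis=0), "hwe_p": 0.5,
    })
    if phenotype is None:
        phenotype = np.arange(n) % 2
    return GenotypeDataset([f"s{i}" for i in range(n)], variants, dosages,
                           phenotype, covariates)


def regions(name, triples):
    return RegionSet(name, pd.DataFrame(
        [(c, s, e) for c, s, e in triples], columns=["chrom", "start", "end"]))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class TestQCBase:
    def test_hand_enumerated_fixture(self):
        ss = make_sumstats(
            ["v1", "v2", "v3", "v4", "v5", "v6"],
            [100, 200, 300, 400, 500, 600], [0.5] * 6,
            ea=["A", "A", "C", "G", "T", "C"],
            oa=["T", "G", "G", "C", "A", "T"])
        ss.table.loc[1, "info"] = 0.5   # fails INFO
        ss.table.loc[5, "info"] = 0.8   # boundary: kept
        out, report = qc_base(ss)
        # v1 (A/T), v3 (C/G), v4 (G/C), v5 (T/A) ambiguous; v2 low INFO
        assert report.removed == {"info": 1, "strand_ambiguous": 4}
        assert list(out.table["variant_id"]) == ["v6"]
        assert report.n_in - sum(report.removed.values()) == report.n_out

    def test_all_removed_is_error(self):
        ss = make_sumstats(["v1"], [100], [0.5], ea=["A"], oa=["T"])
        with pytest.raises(ValidationError):
            qc_base(ss)


class TestQCTarget:
    def _geno(self):
        rng = np.random.default_rng(0)
        dose = rng.integers(0, 3, size=(100, 6)).astype(float)
        dose[:50, 3] = np.nan  # 50% missing
        dose[:, 4] = 0.0       # monomorphic
        g = make_geno([f"v{i}" for i in range(6)],
                      [100 * i + 100 for i in range(6)], dose,
                      chrom=["1", "1", "X", "1", "1", "1"])
        freq = np.nanmean(dose, axis=0) / 2.0
        g.variants["maf"] = np.minimum(freq, 1 - freq)
        g.variants.loc[5, "hwe_p"] = 1e-30
        return g

    def test_filters_in_order_with_first_fail_attribution(self):
        g = self._geno()
        out, report = qc_target(g)
        assert report.removed["non_autosomal"] == 1
        assert report.removed["maf"] == 1          # monomorphic
        assert report.removed["hwe"] == 1
        assert report.removed["missingness"] == 1
        assert set(out.variants["variant_id"]) == {"v0", "v1"}

    def test_hwe_perfect_proportions_kept(self):
        # (AA, Aa, aa) = (25, 50, 25): chi-square 0, p = 1
        dose = np.concatenate([np.zeros(25), np.ones(50), np.full(25, 2.0)])
        from plaquestate.simulate import _hwe_p
        p = _hwe_p(dose[:, None])
        assert p[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Region construction
# ---------------------------------------------------------------------------

class TestRegionsFromGenes:
    def _annotation(self):
        return RegionSet("genes", pd.DataFrame({
            "chrom": ["1", "1"], "start": [10_000, 10_000],
            "end": [20_000, 20_000], "label": ["plusG", "minusG"],
            "strand": ["+", "-"]}))

    def test_plus_strand_flanks(self):
        out = regions_from_genes(self._annotation(), GeneSet("s", ("plusG",)))
        row = out.intervals.iloc[0]
        assert (row["start"], row["end"]) == (0, 30_000)  # clipped at 0

    def test_minus_strand_flanks(self):
        out = regions_from_genes(self._annotation(), GeneSet("s", ("minusG",)))
        row = out.intervals.iloc[0]
        assert (row["start"], row["end"]) == (0, 55_000)

    def test_zero_flanks_identity(self):
        out = regions_from_genes(self._annotation(), GeneSet("s", ("plusG",)),
                                 up=0, down=0)
        row = out.intervals.iloc[0]
        assert (row["start"], row["end"]) == (10_000, 20_000)

    def test_missing_gene_warns(self):
        with pytest.warns(UserWarning, match="missing"):
            regions_from_genes(self._annotation(), GeneSet("s", ("plusG", "nope")))


class TestRegionsFromPeaks:
    def _annotation(self):
        return RegionSet("genes", pd.DataFrame({
            "chrom": ["1"], "start": [1_000_000], "end": [1_010_000],
            "label": ["G"], "strand": ["+"]}))

    def test_distant_peak_dropped(self):
        peaks = regions("peaks", [("1", 1_600_500, 1_601_000)])
        out = regions_from_peaks(peaks, self._annotation(), GeneSet("s", ("G",)))
        assert len(out) == 0

    def test_edge_overlap_kept(self):
        # window = TSS +/- 500 kb inclusive; TSS at 1,000,000 (0-based), so
        # positions up to 1,500,000 qualify; a peak starting exactly there
        # shares one base
        peaks = regions("peaks", [("1", 1_500_000, 1_500_200)])
        out = regions_from_peaks(peaks, self._annotation(), GeneSet("s", ("G",)))
        assert len(out) == 1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        ann = RegionSet("genes", pd.DataFrame({
            "chrom": "1",
            "start": (starts := rng.integers(0, 5_000_000, 8)),
            "end": starts + 10_000,
            "label": [f"G{i}" for i in range(8)], "strand": "+"}))
        peaks = regions("peaks", [("1", int(s), int(s) + 500)
                                  for s in rng.integers(0, 5_000_000, 60)])
        window = 500_000
        out = regions_from_peaks(peaks, ann, GeneSet("s", tuple(ann.intervals["label"])),
                                 window=window)
        kept = set(map(tuple, out.intervals[["start", "end"]].to_numpy()))
        for _, pk in peaks.intervals.iterrows():
            near = any(
                pk["start"] <= tss + window and pk["end"] - 1 >= tss - window
                for tss in ann.intervals["start"])
            assert ((pk["start"], pk["end"]) in kept) == near


class TestResizePeaks:
    def test_summit_resize(self):
        peaks = RegionSet("p", pd.DataFrame({
            "chrom": ["1"], "start": [950], "end": [1400], "summit": [1000]}))
        out = resize_peaks(peaks, width=200)
        row = out.intervals.iloc[0]
        assert (row["start"], row["end"]) == (900, 1100)

    def test_zero_width_rejected(self):
        peaks = RegionSet("p", pd.DataFrame({
            "chrom": ["1"], "start": [950], "end": [1400], "summit": [1000]}))
        with pytest.raises(ValidationError):
            resize_peaks(peaks, width=0)

    def test_missing_summit_rejected(self):
        peaks = regions("p", [("1", 950, 1400)])
        with pytest.raises(ValidationError, match="summit"):
            resize_peaks(peaks, width=200)

    def test_widths_uniform(self):
        rng = np.random.default_rng(0)
        summits = rng.integers(10_000, 50_000, 10)
        peaks = RegionSet("p", pd.DataFrame({
            "chrom": "1", "start": summits - 5, "end": summits + 5,
            "summit": summits}))
        out = resize_peaks(peaks, width=301)
        assert ((out.intervals["end"] - out.intervals["start"]) == 301).all()


# ---------------------------------------------------------------------------
# Clumping
# ---------------------------------------------------------------------------

from oracles import brute_force_clump, r2_matrix as _r2_matrix


class TestPreferentialClump:
    def _three_variant_setup(self):
        rng = np.random.default_rng(0)
        v1 = rng.integers(0, 3, 200).astype(float)
        noise = rng.integers(0, 3, 200).astype(float)
        v2 = np.where(rng.random(200) < 0.75, v1, noise)  # strongly correlated
        v3 = rng.integers(0, 3, 200).astype(float)        # independent
        dose = np.column_stack([v1, v2, v3])
        r2 = _r2_matrix(dose)
        assert r2[0, 1] > 0.2 and r2[0, 2] < 0.2 and r2[1, 2] < 0.2
        vids = ["v1", "v2", "v3"]
        pos = [1000, 2000, 3000]
        ss = make_sumstats(vids, pos, [1e-8, 1e-4, 1e-3])
        geno = make_geno(vids, pos, dose)
        return ss, geno

    def test_hand_traced_sweep_no_set(self):
        ss, geno = self._three_variant_setup()
        panel = preferential_clump(ss, geno, None, window=500_000, r2_max=0.2)
        assert list(panel.retained["variant_id"]) == ["v1", "v3"]
        assert panel.clumps["v1"] == ["v2"]

    def test_in_set_variant_indexed_first(self):
        ss, geno = self._three_variant_setup()
        # v2 at pos 2000 inside the set -> becomes index, claims v1
        rs = regions("s", [("1", 1500, 2500)])
        panel = preferential_clump(ss, geno, rs, window=500_000, r2_max=0.2)
        assert list(panel.retained["variant_id"]) == ["v2", "v3"]
        assert panel.clumps["v2"] == ["v1"]
        assert panel.retained.set_index("variant_id")["in_set"].to_dict() == \
            {"v2": True, "v3": False}

    def test_r2_max_one_retains_everything(self):
        ss, geno = self._three_variant_setup()
        panel = preferential_clump(ss, geno, None, window=500_000, r2_max=1.0)
        assert len(panel) == 3

    def test_bad_parameters_rejected(self):
        ss, geno = self._three_variant_setup()
        with pytest.raises(ValidationError):
            preferential_clump(ss, geno, None, window=-1)
        with pytest.raises(ValidationError):
            preferential_clump(ss, geno, None, r2_max=1.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(20, 120))
        n = 80
        # blocky dosages to create real LD
        base = rng.integers(0, 3, size=(n, m)).astype(float)
        for j in range(1, m):
            mix = rng.random(n) < rng.random() * 0.8
            base[mix, j] = base[mix, j - 1]
        pos = np.sort(rng.choice(np.arange(1, 1_000_000), m, replace=False))
        chrom = rng.choice(["1", "2"], m)
        p = rng.uniform(1e-8, 1.0, m)
        vids = [f"v{j}" for j in range(m)]
        window = 100_000
        rs = regions("s", [("1", 0, 300_000)])
        ss = make_sumstats(vids, pos, p, chrom=list(chrom))
        geno = make_geno(vids, pos, base, chrom=list(chrom))
        panel = preferential_clump(ss, geno, rs, window=window, r2_max=0.2)
        in_set = positions_in_regions(ss.table["chrom"], ss.table["pos"], rs)
        oracle = brute_force_clump(vids, list(chrom), list(pos), list(p),
                                   list(in_set), _r2_matrix(base), window, 0.2)
        assert list(panel.retained["variant_id"]) == oracle
        # pairwise constraint among retained variants
        ret = panel.retained
        r2 = _r2_matrix(base)
        idx = {v: j for j, v in enumerate(vids)}
        for a in range(len(ret)):
            for b in range(a + 1, len(ret)):
                ra, rb = ret.iloc[a], ret.iloc[b]
                if ra["chrom"] == rb["chrom"] and abs(ra["pos"] - rb["pos"]) <= window:
                    assert r2[idx[ra["variant_id"]], idx[rb["variant_id"]]] <= 0.2


# ---------------------------------------------------------------------------
# Scoring and evaluation
# ---------------------------------------------------------------------------

def panel_from(ss, in_set=None):
    t = ss.table.copy()
    t["in_set"] = in_set if in_set is not None else False
    t["n_clumped"] = 0
    return ClumpedPanel(t[["variant_id", "chrom", "pos", "p", "beta",
                           "effect_allele", "other_allele", "in_set",
                           "n_clumped"]])


class TestScorePRS:
    def test_single_variant_closed_form(self):
        ss = make_sumstats(["v1"], [100], [0.01], beta=[0.5])
        geno = make_geno(["v1"], [100], [[2.0], [0.0], [1.0], [2.0]])
        prs = score_prs(geno, panel_from(ss), ss, p_threshold=1.0)
        np.testing.assert_allclose(prs.scores, [1.0, 0.0, 0.5, 1.0])
        assert prs.n_snps == 1

    def test_allele_flip_harmonized(self):
        # proper flip in the sumstats (swap alleles, negate beta) must leave
        # scores unchanged
        ss = make_sumstats(["v1", "v2"], [100, 200], [0.01, 0.02],
                           beta=[0.5, -0.3], ea=["A", "C"], oa=["G", "T"])
        dose = np.array([[2.0, 1.0], [0.0, 0.0], [1.0, 2.0], [2.0, 1.0]])
        geno = make_geno(["v1", "v2"], [100, 200], dose,
                         ea=["A", "C"], oa=["G", "T"])
        base = score_prs(geno, panel_from(ss), ss, 1.0)
        flipped_tab = ss.table.copy()
        flipped_tab.loc[0, ["effect_allele", "other_allele"]] = ["G", "A"]
        flipped_tab.loc[0, "beta"] = -0.5
        ss_fl = SumStats(flipped_tab)
        fl = score_prs(geno, panel_from(ss_fl), ss_fl, 1.0)
        # flip moves each sample's contribution by a constant (2*beta);
        # centred scores are identical
        np.testing.assert_allclose(fl.scores - fl.scores.mean(),
                                   base.scores - base.scores.mean(), atol=1e-12)

    def test_double_flip_restores_bit_identical(self):
        ss = make_sumstats(["v1"], [100], [0.01], beta=[0.5])
        geno = make_geno(["v1"], [100], [[2.0], [0.0], [1.0], [1.0]])
        tab = ss.table.copy()
        tab.loc[0, ["effect_allele", "other_allele"]] = \
            tab.loc[0, ["other_allele", "effect_allele"]].to_numpy()
        tab.loc[0, "beta"] *= -1
        twice = tab.copy()
        twice.loc[0, ["effect_allele", "other_allele"]] = \
            twice.loc[0, ["other_allele", "effect_allele"]].to_numpy()
        twice.loc[0, "beta"] *= -1
        s0 = score_prs(geno, panel_from(ss), ss, 1.0).scores
        s2 = score_prs(geno, panel_from(SumStats(twice)), SumStats(twice), 1.0).scores
        np.testing.assert_array_equal(s0, s2)

    def test_mismatched_alleles_dropped_with_warning(self):
        ss = make_sumstats(["v1", "v2"], [100, 200], [0.01, 0.02],
                           beta=[0.5, 1.0], ea=["A", "C"], oa=["G", "T"])
        geno = make_geno(["v1", "v2"], [100, 200],
                         [[2.0, 1.0], [0.0, 1.0], [1.0, 1.0], [1.0, 1.0]],
                         ea=["A", "G"], oa=["G", "C"])
        with pytest.warns(UserWarning, match="mismatch"):
            prs = score_prs(geno, panel_from(ss), ss, 1.0)
        assert prs.n_snps == 1

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(4)
        m, n = 30, 50
        vids = [f"v{j}" for j in range(m)]
        pos = list(range(100, 100 + m))
        beta = rng.normal(size=m)
        p = rng.uniform(1e-6, 1, m)
        dose = rng.integers(0, 3, size=(n, m)).astype(float)
        dose[rng.random((n, m)) < 0.05] = np.nan
        ss = make_sumstats(vids, pos, p, beta=list(beta))
        geno = make_geno(vids, pos, dose)
        thr = 0.5
        prs = score_prs(geno, panel_from(ss), ss, thr)
        col_means = np.nanmean(dose, axis=0)
        expected = np.zeros(n)
        for i in range(n):
            for j in range(m):
                if p[j] <= thr:
                    d = dose[i, j]
                    expected[i] += beta[j] * (col_means[j] if np.isnan(d) else d)
        np.testing.assert_allclose(prs.scores, expected, rtol=1e-12)
        assert prs.n_snps == int((p <= thr).sum())

    def test_score_linearity_in_disjoint_panels(self):
        rng = np.random.default_rng(5)
        m, n = 20, 30
        vids = [f"v{j}" for j in range(m)]
        pos = list(range(100, 100 + m))
        ss = make_sumstats(vids, pos, [0.01] * m, beta=list(rng.normal(size=m)))
        dose = rng.integers(0, 3, size=(n, m)).astype(float)
        geno = make_geno(vids, pos, dose)
        half = SumStats(ss.table.iloc[:10].reset_index(drop=True))
        other = SumStats(ss.table.iloc[10:].reset_index(drop=True))
        s_all = score_prs(geno, panel_from(ss), ss, 1.0).scores
        s_a = score_prs(geno, panel_from(half), half, 1.0).scores
        s_b = score_prs(geno, panel_from(other), other, 1.0).scores
        np.testing.assert_allclose(s_all, s_a + s_b, rtol=1e-12)

    def test_zero_included_is_error(self):
        ss = make_sumstats(["v1"], [100], [0.5])
        geno = make_geno(["v1"], [100], [[1.0], [0.0], [2.0], [1.0]])
        with pytest.raises(ValidationError, match="threshold"):
            score_prs(geno, panel_from(ss), ss, p_threshold=1e-4)


class TestEvaluatePRS:
    def _geno_with_pheno(self, rng, n=500, informative=False):
        dose = rng.integers(0, 3, size=(n, 1)).astype(float)
        logits = -1.0 + (1.0 * dose[:, 0] if informative else 0.0)
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        cov = pd.DataFrame({"age": rng.normal(60, 8, n),
                            "sex": rng.integers(0, 2, n).astype(float)})
        return make_geno(["v1"], [100], dose, phenotype=y, covariates=cov)

    def test_null_prs_r2_near_zero(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            geno = self._geno_with_pheno(rng)
            ss = make_sumstats(["v1"], [100], [0.01], beta=[0.3])
            prs = score_prs(geno, panel_from(ss), ss, 1.0)
            prs.scores = rng.normal(size=len(prs.scores))  # decouple from y
            vals.append(evaluate_prs(prs, geno).prs_r2)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 0.01

    def test_informative_prs_beats_null(self):
        rng = np.random.default_rng(1)
        geno = self._geno_with_pheno(rng, n=800, informative=True)
        ss = make_sumstats(["v1"], [100], [0.001], beta=[1.0])
        ev = evaluate_prs(score_prs(geno, panel_from(ss), ss, 1.0), geno)
        assert ev.prs_r2 > 0.05
        assert ev.full_r2 > ev.null_r2

    def test_prs_equal_to_covariate_adds_nothing(self):
        rng = np.random.default_rng(2)
        geno = self._geno_with_pheno(rng)
        ss = make_sumstats(["v1"], [100], [0.01], beta=[0.3])
        prs = score_prs(geno, panel_from(ss), ss, 1.0)
        prs.scores = geno.covariates["age"].to_numpy().copy()
        ev = evaluate_prs(prs, geno)
        assert abs(ev.prs_r2) < 1e-6

    def test_mcfadden_option(self):
        rng = np.random.default_rng(3)
        geno = self._geno_with_pheno(rng, informative=True)
        ss = make_sumstats(["v1"], [100], [0.01], beta=[1.0])
        ev = evaluate_prs(score_prs(geno, panel_from(ss), ss, 1.0), geno,
                          method="mcfadden")
        assert ev.method == "mcfadden" and np.isfinite(ev.prs_r2)


class TestCompetitiveP:
    def _setup(self, rng, n=300, m=40):
        vids = [f"v{j}" for j in range(m)]
        pos = [1000 * j + 1 for j in range(m)]
        dose = rng.integers(0, 3, size=(n, m)).astype(float)
        y = rng.integers(0, 2, n)
        y[:3] = [0, 1, 1]  # both classes guaranteed
        ss = make_sumstats(vids, pos, list(rng.uniform(0.001, 1, m)),
                           beta=list(rng.normal(0, 0.1, m)))
        geno = make_geno(vids, pos, dose, phenotype=y)
        return ss, geno

    def test_formula_with_nine_permutations(self):
        rng = np.random.default_rng(0)
        ss, geno = self._setup(rng)
        panel = panel_from(ss)
        ev = evaluate_prs(score_prs(geno, panel, ss, 1.0), geno)
        # observed forced above anything permutations can reach
        from dataclasses import replace
        ev_hi = replace(ev, prs_r2=1.0)
        out = competitive_p(ev_hi, panel, geno, n_snps=5, n_perm=9, seed=1)
        assert out.competitive_p == pytest.approx(1 / 10)

    def test_floor_at_inverse_nperm(self):
        rng = np.random.default_rng(1)
        ss, geno = self._setup(rng)
        panel = panel_from(ss)
        ev = evaluate_prs(score_prs(geno, panel, ss, 1.0), geno)
        out = competitive_p(ev, panel, geno, n_snps=5, n_perm=19, seed=2)
        assert out.competitive_p >= 1 / 20

    def test_zero_permutations_rejected(self):
        rng = np.random.default_rng(2)
        ss, geno = self._setup(rng)
        panel = panel_from(ss)
        ev = evaluate_prs(score_prs(geno, panel, ss, 1.0), geno)
        with pytest.raises(ValidationError, match="n_perm"):
            competitive_p(ev, panel, geno, n_snps=5, n_perm=0)

    def test_background_too_small_rejected(self):
        rng = np.random.default_rng(3)
        ss, geno = self._setup(rng, m=10)
        panel = panel_from(ss)
        ev = evaluate_prs(score_prs(geno, panel, ss, 1.0), geno)
        with pytest.raises(ValidationError, match="background"):
            competitive_p(ev, panel, geno, n_snps=50, n_perm=9)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        ss, geno = self._setup(rng)
        panel = panel_from(ss)
        ev = evaluate_prs(score_prs(geno, panel, ss, 1.0), geno)
        a = competitive_p(ev, panel, geno, n_snps=8, n_perm=25, seed=9)
        b = competitive_p(ev, panel, geno, n_snps=8, n_perm=25, seed=9)
        assert a.competitive_p == b.competitive_p


class TestThresholdScanAndHybrid:
    def _setup(self, rng):
        m, n = 30, 400
        vids = [f"v{j}" for j in range(m)]
        pos = [10_000 * j + 1 for j in range(m)]
        dose = rng.integers(0, 3, size=(n, m)).astype(float)
        liab = dose[:, :5].sum(axis=1) * 0.4 + rng.normal(0, 1, n)
        y = (liab > np.quantile(liab, 0.7)).astype(int)
        p = np.r_[rng.uniform(1e-8, 1e-5, 5), rng.uniform(0.2, 1.0, m - 5)]
        ss = make_sumstats(vids, pos, list(p),
                           beta=list(np.r_[np.full(5, 0.4),
                                           rng.normal(0, 0.02, m - 5)]))
        geno = make_geno(vids, pos, dose, phenotype=y)
        return ss, geno

    def test_single_threshold_consistency(self):
        rng = np.random.default_rng(0)
        ss, geno = self._setup(rng)
        panel = panel_from(ss)
        scan = threshold_scan(panel, geno, ss, [1.0])
        direct = evaluate_prs(score_prs(geno, panel, ss, 1.0), geno)
        assert scan["prs_r2"].iloc[0] == pytest.approx(direct.prs_r2)
        assert bool(scan["best"].iloc[0])

    def test_scan_deterministic(self):
        rng = np.random.default_rng(1)
        ss, geno = self._setup(rng)
        panel = panel_from(ss)
        a = threshold_scan(panel, geno, ss, [1e-4, 0.05, 1.0])
        b = threshold_scan(panel, geno, ss, [1e-4, 0.05, 1.0])
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_thresholds_rejected(self):
        rng = np.random.default_rng(2)
        ss, geno = self._setup(rng)
        with pytest.raises(ValidationError):
            threshold_scan(panel_from(ss), geno, ss, [0.0, 0.5])

    def test_hybrid_reduces_to_classical_when_thresholds_equal(self):
        rng = np.random.default_rng(3)
        ss, geno = self._setup(rng)
        panel = panel_from(ss)
        t = 1e-4
        classical = score_prs(geno, panel, ss, t)
        hybrid = hybrid_prs(panel, regions("peaks", [("2", 0, 10)]), ss, geno,
                            t_strong=t, t_weak=t)
        np.testing.assert_allclose(hybrid.scores, classical.scores)
        assert hybrid.n_snps == classical.n_snps

    def test_hybrid_reduces_to_classical_when_peaks_cover_genome(self):
        rng = np.random.default_rng(4)
        ss, geno = self._setup(rng)
        panel = panel_from(ss)
        everywhere = regions("peaks", [("1", 0, 10_000_000)])
        hybrid = hybrid_prs(panel, everywhere, ss, geno, t_strong=1e-4,
                            t_weak=1.0)
        classical = score_prs(geno, panel, ss, 1.0)
        np.testing.assert_allclose(hybrid.scores, classical.scores)

    def test_hybrid_invalid_thresholds(self):
        rng = np.random.default_rng(5)
        ss, geno = self._setup(rng)
        with pytest.raises(ValidationError):
            hybrid_prs(panel_from(ss), regions("p", [("1", 0, 10)]), ss, geno,
                       t_strong=0.5, t_weak=0.1)
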