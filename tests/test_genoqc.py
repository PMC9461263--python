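"""QC, kinship, pruning and alignment, checked against hand counts and
brute-force oracles on toy inputs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ehrgenpop import genoqc as gq
from ehrgenpop.matrix import MISSING

from conftest import toy_matrix


class TestVariantSampleQc:
    def test_strand_ambiguous_and_missingness_rules(self):
        # 100 samples so missing rates of exactly 0.05 and 0.051 are realizable
        d = np.ones((1000, 4), dtype=np.int8)
        d[:51, 1] = MISSING  # 5.1% missing -> removed (strict >)
        d[:50, 2] = MISSING  # 5.0% missing -> retained
        g = toy_matrix(d, allele1=["A", "A", "C", "A"], allele2=["T", "G", "A", "G"])
        out, report = gq.qc_variants(g, max_missing=0.05)
        assert list(out.variants["id"]) == ["v2", "v3"]
        assert report.removed == {"unmapped": 0, "missingness": 1, "strand_ambiguous": 1}
        assert report.n_retained + sum(report.removed.values()) == report.n_input

    def test_unmapped_variants_removed(self):
        g = toy_matrix(np.zeros((3, 2), dtype=np.int8), chrom=["0", "1"], bp=[100, 100])
        out, report = gq.qc_variants(g)
        assert list(out.variants["id"]) == ["v1"]
        assert report.removed["unmapped"] == 1

    def test_sample_missingness_strict_threshold(self):
        d = np.zeros((3, 100), dtype=np.int8)
        d[0, :6] = MISSING  # 6% -> removed
        g = toy_matrix(d)
        out, report = gq.qc_samples(g, max_missing=0.05)
        assert list(out.samples["id"]) == ["s1", "s2"]
        assert report.removed["missingness"] == 1

    def test_qc_filters_are_idempotent(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(30, 50)).astype(np.int8)
        d[rng.random(d.shape) < 0.03] = MISSING
        g = toy_matrix(d)
        once, _ = gq.qc_variants(g)
        twice, rep = gq.qc_variants(once)
        assert list(twice.variants["id"]) == list(once.variants["id"])
        assert sum(rep.removed.values()) == 0

    def test_maf_filter_matches_hand_count(self):
        # hand-counted allele-1 frequencies on a 5x5 toy matrix
        d = np.array(
            [
                [0, 2, 1, 0, 0],
                [0, 2, 1, 0, 0],
                [0, 2, 2, 1, 0],
                [0, 2, 2, 1, 0],
                [0, 1, 2, 2, 2],
            ],
            dtype=np.int8,
        )
        g = toy_matrix(d)
        np.testing.assert_allclose(g.allele1_freq(), [0.0, 0.9, 0.8, 0.4, 0.2])
        out = gq.maf_filter(g, min_maf=0.25)
        assert list(out.variants["id"]) == ["v3"]  # only MAF 0.4 >= 0.25

    def test_heterozygosity_outlier_flagging(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.5, size=(50, 400)).astype(np.int8)
        g = toy_matrix(d)
        assert gq.heterozygosity_outliers(g, n_sd=3) == []
        d2 = d.copy()
        d2[0] = 1  # het rate 1.0, far outside the group spread
        flagged = gq.heterozygosity_outliers(toy_matrix(d2), n_sd=3)
        assert flagged == ["s0"]
        assert gq.heterozygosity_outliers(toy_matrix(d2), n_sd=np.inf) == []

    def test_identical_het_rates_flag_nothing(self):
        g = toy_matrix(np.ones((5, 10), dtype=np.int8))  # all het, SD = 0
        assert gq.heterozygosity_outliers(g) == []


class TestHwe:
    def test_exact_equilibrium_gives_p_one(self):
        d = np.repeat([0, 1, 2], [25, 50, 25]).astype(np.int8)[:, None]
        assert gq.hwe_test(toy_matrix(d))[0] == pytest.approx(1.0)

    def test_no_het_extreme_deviation(self):
        # (50, 0, 50): chi2 = N = 100 at p=0.5; check against the chi2_1 tail
        d = np.repeat([0, 2], [50, 50]).astype(np.int8)[:, None]
        p = gq.hwe_test(toy_matrix(d))[0]
        assert p == pytest.approx(stats.chi2.sf(100, 1), rel=1e-10)
        assert p < 1e-20

    def test_monomorphic_gives_p_one(self):
        d = np.zeros((100, 1), dtype=np.int8)
        assert gq.hwe_test(toy_matrix(d))[0] == 1.0


class TestKinship:
    def test_verbatim_duplicate_has_phi_half(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, rng.uniform(0.1, 0.9, 300), size=(5, 300)).astype(np.int8)
        d[1] = d[0]
        kin = gq.estimate_kinship(toy_matrix(d))
        pair = kin[(kin["id1"] == "s0") & (kin["id2"] == "s1")]
        assert pair["phi"].iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_parent_offspring_phi_quarter(self):
        # pedigree oracle: child inherits one allele from the parent, one
        # from the population
        rng = np.random.default_rng(3)
        M = 5000
        p = rng.uniform(0.2, 0.8, M)
        parent_h = rng.binomial(1, p, size=(2, M))
        child_from_parent = parent_h[rng.integers(0, 2, M), np.arange(M)]
        child = (child_from_parent + rng.binomial(1, p)).astype(np.int8)
        parent = parent_h.sum(axis=0).astype(np.int8)
        others = rng.binomial(2, p, size=(3, M)).astype(np.int8)
        g = toy_matrix(np.vstack([parent, child, others]))
        kin = gq.estimate_kinship(g)
        po = kin[(kin["id1"] == "s0") & (kin["id2"] == "s1")]["phi"].iloc[0]
        assert 0.2 <= po <= 0.3

    def test_unrelated_pair_phi_near_zero(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 0.8, 5000)
        g = toy_matrix(rng.binomial(2, p, size=(2, 5000)).astype(np.int8))
        kin = gq.estimate_kinship(g)
        assert abs(kin["phi"].iloc[0]) < 0.05

    def test_grm_backend_agrees_on_duplicates(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 2000), size=(100, 2000)).astype(np.int8)
        d[1] = d[0]
        kin = gq.estimate_kinship(toy_matrix(d), method="grm")
        pair = kin[(kin["id1"] == "s0") & (kin["id2"] == "s1")]
        assert pair["phi"].iloc[0] == pytest.approx(0.5, abs=0.05)


class TestDuplicateRemoval:
    def _pair_with_missingness(self):
        rng = np.random.default_rng(6)
        base = rng.binomial(2, rng.uniform(0.2, 0.8, 400), size=400).astype(np.int8)
        d = np.vstack([base, base, rng.binomial(2, 0.5, 400).astype(np.int8)])
        d[0, :4] = MISSING  # s0 missing rate 1%
        d[1, :12] = MISSING  # s1 missing rate 3%
        return toy_matrix(d)

    def test_keep_cleaner_policy(self):
        g = self._pair_with_missingness()
        kin = gq.estimate_kinship(g)
        out = gq.remove_duplicates(g, kin)
        assert list(out.samples["id"]) == ["s0", "s2"]

    def test_drop_cleaner_policy_reproduces_literal_reading(self):
        g = self._pair_with_missingness()
        kin = gq.estimate_kinship(g)
        out = gq.remove_duplicates(g, kin, drop_policy="drop_cleaner")
        assert list(out.samples["id"]) == ["s1", "s2"]

    def test_no_duplicates_is_noop(self):
        rng = np.random.default_rng(7)
        g = toy_matrix(rng.binomial(2, 0.5, size=(4, 500)).astype(np.int8))
        kin = gq.estimate_kinship(g)
        assert gq.remove_duplicates(g, kin).n_samples == 4

    def test_triple_of_mutual_duplicates_keeps_one(self):
        rng = np.random.default_rng(8)
        base = rng.binomial(2, rng.uniform(0.2, 0.8, 400), size=400).astype(np.int8)
        d = np.vstack([base, base, base, rng.binomial(2, 0.5, 400).astype(np.int8)])
        g = toy_matrix(d)
        kin = gq.estimate_kinship(g)
        out = gq.remove_duplicates(g, kin)
        assert out.n_samples == 2  # one survivor of the triple + the outsider


def brute_force_max_unrelated(pairs, nodes, threshold):
    """Exhaustive maximum independent set on the relatedness graph."""
    bad = {(a, b) for a, b, phi in pairs if phi >= threshold}
    best = set()
    for r in range(len(nodes), 0, -1):
        for combo in itertools.combinations(nodes, r):
            ok = all(
                (a, b) not in bad and (b, a) not in bad
                for a, b in itertools.combinations(combo, 2)
            )
            if ok:
                return set(combo)
    return best


class TestUnrelatedSet:
    def _kin_table(self, pairs, nodes):
        rows = [
            {"id1": a, "id2": b, "phi": phi, "n_snps": 100}
            for a, b, phi in pairs
        ]
        present = {p for row in rows for p in (row["id1"], row["id2"])}
        for n in nodes:
            if n not in present:  # pad so every node appears in the table
                rows.append({"id1": n, "id2": nodes[0] if n != nodes[0] else nodes[1],
                             "phi": 0.0, "n_snps": 100})
        return pd.DataFrame(rows)

    def test_single_related_pair_keeps_one(self):
        kin = self._kin_table([("a", "b", 0.1)], ["a", "b"])
        kept = gq.unrelated_set(kin)
        assert len(kept & {"a", "b"}) == 1

    def test_all_below_threshold_keeps_all(self):
        kin = self._kin_table(
            [("a", "b", 0.01), ("b", "c", 0.05), ("a", "c", 0.08)], ["a", "b", "c"]
        )
        assert gq.unrelated_set(kin) == {"a", "b", "c"}

    def test_star_graph_matches_exhaustive_maximum(self):
        pairs = [("hub", x, 0.2) for x in ["l1", "l2", "l3", "l4"]]
        nodes = ["hub", "l1", "l2", "l3", "l4"]
        kin = self._kin_table(pairs, nodes)
        kept = gq.unrelated_set(kin)
        oracle = brute_force_max_unrelated(pairs, nodes, gq.DEGREE2_CUTOFF)
        assert kept == oracle == {"l1", "l2", "l3", "l4"}

    def test_random_graphs_reach_exhaustive_optimum_size(self):
        rng = np.random.default_rng(9)
        nodes = [f"n{i}" for i in range(8)]
        for _ in range(5):
            pairs = [
                (a, b, 0.2 if rng.random() < 0.3 else 0.0)
                for a, b in itertools.combinations(nodes, 2)
            ]
            kin = self._kin_table(pairs, nodes)
            kept = gq.unrelated_set(kin)
            oracle = brute_force_max_unrelated(pairs, nodes, gq.DEGREE2_CUTOFF)
            # greedy guarantee: no related pair retained
            bad = {(a, b) for a, b, phi in pairs if phi >= gq.DEGREE2_CUTOFF}
            assert not any(
                (a, b) in bad or (b, a) in bad
                for a, b in itertools.combinations(sorted(kept), 2)
            )
            assert len(kept) >= len(oracle) - 1  # greedy is near-optimal here


def brute_force_pairwise_prune(g, r2_max):
    """All-pairs greedy prune in position order, removing the later variant."""
    x = g.mean_imputed()
    order = np.lexsort((g.variants["bp"].to_numpy(), g.variants["chrom"].to_numpy()))
    removed = set()
    for ai in range(len(order)):
        a = order[ai]
        if a in removed:
            continue
        for bi in range(ai + 1, len(order)):
            b = order[bi]
            if b in removed:
                continue
            if g.variants["chrom"][a] != g.variants["chrom"][b]:
                continue
            r = np.corrcoef(x[:, a], x[:, b])[0, 1]
            if np.isnan(r):
                r = 0.0
            if r**2 > r2_max:
                removed.add(b)
    return [g.variants["id"][j] for j in range(g.n_variants) if j not in removed]


def brute_force_vif_prune(g, vif_max):
    x = g.mean_imputed()
    active = list(range(g.n_variants))
    while len(active) > 1:
        xa = x[:, active]
        xc = xa - xa.mean(axis=0)
        sd = xc.std(axis=0)
        xs = np.where(sd > 0, xc / sd, 0.0)
        r = (xs.T @ xs) / x.shape[0]
        r[np.diag_indices_from(r)] += 1e-8
        vifs = np.diag(np.linalg.inv(r))
        worst = int(np.flatnonzero(vifs >= vifs.max() - 1e-9)[-1])
        if vifs[worst] <= vif_max:
            break
        active.pop(worst)
    return [g.variants["id"][j] for j in active]


class TestLdPruning:
    def test_identical_pair_loses_one(self):
        rng = np.random.default_rng(10)
        v = rng.binomial(2, 0.5, size=(50, 1)).astype(np.int8)
        g = toy_matrix(np.hstack([v, v]))
        assert gq.ld_prune_pairwise(g) == ["v0"]
        assert gq.ld_prune_vif(g) == ["v0"]

    def test_independent_variants_all_retained(self):
        rng = np.random.default_rng(11)
        g = toy_matrix(rng.binomial(2, 0.5, size=(500, 10)).astype(np.int8))
        assert len(gq.ld_prune_pairwise(g, r2_max=0.1)) == 10
        assert len(gq.ld_prune_vif(g, vif_max=1.15)) == 10

    def test_pairwise_matches_brute_force_on_toy_set(self):
        rng = np.random.default_rng(12)
        base = rng.binomial(2, 0.5, size=(80, 20)).astype(np.int8)
        # plant correlated copies with a few flips
        for src, dst in [(0, 3), (5, 6), (10, 15)]:
            base[:, dst] = base[:, src]
            flip = rng.random(80) < 0.05
            base[flip, dst] = rng.integers(0, 3, flip.sum())
        g = toy_matrix(base)
        assert gq.ld_prune_pairwise(g, r2_max=0.1) == brute_force_pairwise_prune(g, 0.1)

    def test_vif_matches_brute_force_on_toy_set(self):
        rng = np.random.default_rng(13)
        base = rng.binomial(2, 0.5, size=(100, 10)).astype(np.int8)
        base[:, 4] = base[:, 1]  # exact copy -> infinite VIF
        g = toy_matrix(base)
        assert gq.ld_prune_vif(g, vif_max=1.15) == brute_force_vif_prune(g, 1.15)

    def test_retained_set_has_no_violating_pair(self):
        rng = np.random.default_rng(14)
        base = rng.binomial(2, 0.5, size=(60, 15)).astype(np.int8)
        base[:, 7] = base[:, 2]
        g = toy_matrix(base)
        kept = gq.ld_prune_pairwise(g, r2_max=0.1)
        sub = g.keep_variant_ids(kept)
        x = sub.mean_imputed()
        r2 = np.corrcoef(x.T) ** 2
        iu = np.triu_indices(len(kept), 1)
        assert (np.nan_to_num(r2[iu]) <= 0.1 + 1e-12).all()


class TestBpSpacing:
    def test_greedy_spacing_example(self):
        g = toy_matrix(np.zeros((2, 3), dtype=np.int8), bp=[1, 1500, 2500])
        assert gq.prune_bp_spacing(g, min_bp=2000) == ["v0", "v2"]

    def test_chromosomes_do_not_constrain_each_other(self):
        g = toy_matrix(
            np.zeros((2, 2), dtype=np.int8), chrom=["1", "2"], bp=[1000, 1001]
        )
        assert gq.prune_bp_spacing(g, min_bp=2000) == ["v0", "v1"]

    def test_matches_brute_force_greedy(self):
        rng = np.random.default_rng(15)
        bp = np.sort(rng.integers(1, 100_000, 40))
        bp = bp + np.arange(40)  # ensure strictly increasing
        g = toy_matrix(np.zeros((2, 40), dtype=np.int8), bp=bp)
        # oracle: simple greedy scan
        kept, last = [], None
        for j in range(40):
            if last is None or bp[j] - last >= 2000:
                kept.append(f"v{j}")
                last = bp[j]
        assert gq.prune_bp_spacing(g, min_bp=2000) == kept


class TestAlignToReference:
    def _study_and_panel(self, panel_alleles, study_alleles=("A", "G")):
        study = toy_matrix(
            np.array([[0, 1, 2]], dtype=np.int8),
            allele1=[study_alleles[0]] * 3,
            allele2=[study_alleles[1]] * 3,
            bp=[100, 200, 300],
            sample_ids=["st0"],
        )
        panel = toy_matrix(
            np.array([[1, 1, 1]], dtype=np.int8),
            allele1=[panel_alleles[0]] * 3,
            allele2=[panel_alleles[1]] * 3,
            bp=[100, 200, 300],
            sample_ids=["p0"],
        )
        return study, panel

    def test_identical_alleles_unchanged(self):
        study, panel = self._study_and_panel(("A", "G"))
        merged = gq.align_to_reference(study, panel)
        np.testing.assert_array_equal(merged.dosages[0], [0, 1, 2])

    def test_swapped_alleles_flip_dosage(self):
        study, panel = self._study_and_panel(("G", "A"))
        merged = gq.align_to_reference(study, panel)
        np.testing.assert_array_equal(merged.dosages[0], [2, 1, 0])

    def test_allele_mismatch_dropped(self):
        study, panel = self._study_and_panel(("A", "C"))
        with pytest.raises(ValueError, match="no reconcilable"):
            gq.align_to_reference(study, panel)

    def test_zero_overlap_errors(self):
        study, panel = self._study_and_panel(("A", "G"))
        panel.variants["bp"] = [900, 901, 902]
        with pytest.raises(ValueError, match="no overlapping"):
            gq.align_to_reference(study, panel)
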