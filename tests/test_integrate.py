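import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from atacmotif.formats import Region
from atacmotif.integrate import (
    annotate_links,
    classify_regulatory_role,
    foldchange_correlation,
    location_class,
    motif_target_enrichment,
    nearest_tss,
)
from atacmotif.motifscan import MotifMatchMatrix
from atacmotif.simulate import (
    generate_acs_set,
    make_tss_table,
    sample_motif_collection,
    simulate_expression,
)


def _tss(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"]
                        ).set_index("gene_id")


class TestLocationClass:
    @pytest.mark.parametrize("distance,expected", [
        (500, "TSS"), (-500, "TSS"), (1000, "TSS"),
        (-5000, "proximal"), (1001, "proximal"), (10000, "proximal"),
        (50000, "distal"), (10001, "distal"),
    ])
    def test_boundaries(self, distance, expected):
        assert location_class(distance) == expected


class TestNearestTss:
    def test_midpoint_equal_to_tss(self):
        acs = [Region("chr1", 900, 1100, "a")]
        links = nearest_tss(acs, _tss([("g1", "chr1", "+", 1000)]))
        assert links.loc["a", "signed_distance"] == 0

    def test_closest_wins(self):
        acs = [Region("chr1", 2900, 3100, "a")]  # midpoint 3000
        links = nearest_tss(acs, _tss([("g1", "chr1", "+", 1000),
                                       ("g2", "chr1", "+", 9000)]))
        assert links.loc["a", "gene_id"] == "g1"
        assert links.loc["a", "signed_distance"] == 2000

    def test_tie_breaks_to_smaller_gene_id(self):
        acs = [Region("chr1", 2900, 3100, "a")]
        links = nearest_tss(acs, _tss([("gB", "chr1", "+", 2000),
                                       ("gA", "chr1", "+", 4000)]))
        assert links.loc["a", "gene_id"] == "gA"

    def test_minus_strand_flips_sign(self):
        acs = [Region("chr1", 2900, 3100, "a")]
        links = nearest_tss(acs, _tss([("g1", "chr1", "-", 1000)]))
        assert links.loc["a", "signed_distance"] == -2000

    def test_chromosome_without_tss_unlinked(self):
        acs = [Region("chrY", 100, 300, "a")]
        links = nearest_tss(acs, _tss([("g1", "chr1", "+", 1000)]))
        assert links.loc["a", "gene_id"] is None

    def test_empty_tss_table_rejected(self):
        with pytest.raises(ValueError):
            nearest_tss([Region("chr1", 0, 10, "a")], _tss([]))


class TestRegulatoryRole:
    def test_concordant_is_enhancer(self):
        assert classify_regulatory_role("Up", 1.2, 0.8, True) == "enhancer"

    def test_anticoncordant_is_repressor(self):
        assert classify_regulatory_role("Up", 1.2, -0.8, True) == "repressor"

    def test_insignificant_gene_unlinked(self):
        assert classify_regulatory_role("Up", 1.2, 0.8, False) == "unlinked"

    def test_stable_acs_unlinked(self):
        assert classify_regulatory_role("Stable", 0.1, 0.8, True) == "unlinked"

    def test_invariant_to_global_sign_flip(self, rng):
        for _ in range(50):
            cls = rng.choice(["Up", "Down"])
            a, g = rng.normal(), rng.normal()
            flipped_cls = {"Up": "Down", "Down": "Up"}[cls]
            assert classify_regulatory_role(cls, a, g, True) == \
                classify_regulatory_role(flipped_cls, -a, -g, True)


class TestRoleRecovery:
    def _run(self, noise_sd, seed=0):
        pwms = sample_motif_collection(4, seed=seed)
        seqs, regions, truth = generate_acs_set(
            300, pwms=pwms, planting_prob=0.4,
            activities=[1.0, -1.0, 0.8, -0.8], noise_sd=0.3, seed=seed + 1)
        tss = make_tss_table(regions, seed=seed + 2)
        links_map = {r.id: f"gene_{i + 1:05d}" for i, r in enumerate(regions)}
        fc = pd.Series(truth.acs_log2fc_true, index=truth.acs_ids)
        gene_table = simulate_expression(tss, links_map, fc,
                                         role_design=(0.5, 0.5),
                                         noise_sd=noise_sd, seed=seed + 3)
        roles_true = gene_table.attrs["roles"]
        # differential table from the exact true fold-changes: every ACS
        # with a real change is called, so role recovery isolates the
        # concordance rule itself
        diff = pd.DataFrame({
            "log2fc": fc,
            "class": np.where(fc > 0.05, "Up",
                              np.where(fc < -0.05, "Down", "Stable")),
        })
        links = annotate_links(regions, tss, diff, gene_table)
        called = links["role"]
        correct = total = 0
        for acs_id, gene_id in links_map.items():
            want = roles_true[gene_id]
            # roles are only meaningful for genuinely differential ACS
            if want == "none" or abs(fc[acs_id]) < 0.5:
                continue
            want_role = {"enhancer": "enhancer", "repressor": "repressor"}[want]
            total += 1
            correct += int(called[acs_id] == want_role)
        assert total > 50
        return correct / total

    def test_zero_noise_full_recovery(self):
        assert self._run(0.0) == 1.0

    def test_moderate_noise_recovery(self):
        assert self._run(0.2) >= 0.9


class TestMotifTargetEnrichment:
    def _fixture(self):
        acs_ids = [f"a{i}" for i in range(10)]
        N = pd.DataFrame({"m1": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
                          "m0": [0] * 10},
                         index=pd.Index(acs_ids, name="acs_id"))
        mm = MotifMatchMatrix(N=N, threshold_p=1e-4)
        links = pd.DataFrame({"gene_id": [f"g{i}" for i in range(10)]},
                             index=pd.Index(acs_ids, name="acs_id"))
        universe = [f"g{i}" for i in range(10)]
        return mm, links, universe

    def test_toy_counts_and_p(self):
        mm, links, universe = self._fixture()
        de = ["g0", "g1", "g2", "g3"]  # all four DE genes are m1 targets
        out = motif_target_enrichment("m1", mm, links, de, universe)
        assert (out["k"], out["K"], out["n"], out["N"]) == (4, 5, 4, 10)
        assert out["p_value"] == pytest.approx(5 / 210)

    def test_matchless_motif_p_one(self):
        mm, links, universe = self._fixture()
        out = motif_target_enrichment("m0", mm, links, ["g0"], universe)
        assert out["k"] == 0 and out["K"] == 0
        assert out["p_value"] == pytest.approx(1.0)

    def test_de_outside_universe_rejected(self):
        mm, links, universe = self._fixture()
        with pytest.raises(ValueError):
            motif_target_enrichment("m1", mm, links, ["gX"], universe)

    def test_planted_target_enrichment_significant(self):
        # motif present only in ACS linked to DE genes -> p << 1e-6
        n = 600
        acs_ids = [f"a{i}" for i in range(n)]
        genes = [f"g{i}" for i in range(n)]
        member = np.zeros(n, dtype=int)
        member[:60] = 1
        mm = MotifMatchMatrix(
            N=pd.DataFrame({"m": member}, index=pd.Index(acs_ids, name="acs_id")),
            threshold_p=1e-4)
        links = pd.DataFrame({"gene_id": genes},
                             index=pd.Index(acs_ids, name="acs_id"))
        de = genes[:80]  # DE genes include every motif-linked gene
        out = motif_target_enrichment("m", mm, links, de, genes)
        assert out["p_value"] < 1e-6


class TestFoldchangeCorrelation:
    def test_perfect_anticorrelation(self):
        a = pd.Series([1, 2, 3], index=["g1", "g2", "g3"])
        b = pd.Series([3, 2, 1], index=["g1", "g2", "g3"])
        r, p = foldchange_correlation(a, b)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_r_and_p(self):
        a = pd.Series([1, 2, 3, 4], index=list("abcd"))
        b = pd.Series([2, 1, 4, 3], index=list("abcd"))
        r, p = foldchange_correlation(a, b)
        assert r == pytest.approx(0.6)
        t = 0.6 * np.sqrt(2) / np.sqrt(1 - 0.36)
        assert p == pytest.approx(2 * sps.t.sf(t, df=2), rel=1e-6)

    def test_too_few_shared_genes(self):
        a = pd.Series([1, 2], index=["g1", "g2"])
        with pytest.raises(ValueError, match="shared"):
            foldchange_correlation(a, a)

    def test_zero_variance_rejected(self):
        a = pd.Series([1.0, 1.0, 1.0], index=["g1", "g2", "g3"])
        b = pd.Series([1.0, 2.0, 3.0], index=["g1", "g2", "g3"])
        with pytest.raises(ValueError, match="variance"):
            foldchange_correlation(a, b)

    def test_shuffle_calibration(self, rng):
        a = pd.Series(rng.normal(size=80), index=[f"g{i}" for i in range(80)])
        pvals = []
        for _ in range(300):
            b = pd.Series(rng.permutation(a.to_numpy()), index=a.index)
            _, p = foldchange_correlation(a, b)
            pvals.append(p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
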