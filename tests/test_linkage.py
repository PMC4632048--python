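"""Linkage-map tests: QC arithmetic, EM vs an independent grid-search
oracle, grouping/ordering truth recovery, and the Kosambi map function."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from beanchip import linkage, synthetic
from beanchip.types import AA, AB, BB, MISSING


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class TestSegregation:
    def test_near_mendelian_retained(self):
        """counts (67,134,66) of 267: chi2 = sum (O-E)^2/E with
        E=(66.75,133.5,66.75) = 0.01124, p = exp(-chi2/2) ~ 0.9944."""
        t = linkage.segregation_test(67, 134, 66)
        assert t.chi2 == pytest.approx(0.0112359550, rel=1e-6)
        assert t.p_value == pytest.approx(np.exp(-t.chi2 / 2), rel=1e-12)
        assert t.p_value > 0.99

    def test_total_distortion_removed(self):
        t = linkage.segregation_test(267, 0, 0)
        assert t.p_value < 1e-100

    def test_p_value_matches_chi2_survival(self):
        # chi2(2) survival function is exp(-x/2); check at several points
        for n_aa, n_ab, n_bb in [(60, 140, 67), (80, 120, 67), (50, 150, 67),
                                 (70, 130, 67), (66, 134, 67)]:
            t = linkage.segregation_test(n_aa, n_ab, n_bb)
            assert t.p_value == pytest.approx(np.exp(-t.chi2 / 2), rel=1e-10)

    def test_missing_threshold_arithmetic(self):
        # 28/267 = 10.49% missing -> removed; 26/267 = 9.74% -> retained
        def column(n_missing):
            col = [AA] * 67 + [AB] * 134 + [BB] * (66 - n_missing) + [MISSING] * n_missing
            return col

        calls = pd.DataFrame({"m_hi": column(28), "m_lo": column(26)})
        retained, report = linkage.qc_filter(calls)
        assert list(retained.columns) == ["m_lo"]
        assert report.at["m_hi", "verdict"] == "removed_missing"

    def test_all_removed_is_error(self):
        calls = pd.DataFrame({"m1": [AA] * 50})
        with pytest.raises(ValueError):
            linkage.qc_filter(calls)


# ---------------------------------------------------------------------------
# two-point EM
# ---------------------------------------------------------------------------

def _grid_oracle(a, b, step=1e-4):
    """Independent maximizer of the two-locus F2 likelihood over an r grid.

    Tabulates the nine genotype classes explicitly and evaluates the class
    probabilities from first principles (independent gametes, coupling)."""
    ok = (a != MISSING) & (b != MISSING)
    counts = np.zeros((3, 3))
    for x, y in zip(a[ok], b[ok]):
        counts[x, y] += 1

    def class_probs(r):
        gam = {0: (1 - r) / 2, 1: r / 2}  # parental / recombinant per gamete
        # genotype at a locus from two gametes; enumerate gamete haplotypes
        probs = np.zeros((3, 3))
        for h1a, h1b in itertools.product((0, 1), repeat=2):  # gamete 1 alleles at loci a,b
            for h2a, h2b in itertools.product((0, 1), repeat=2):
                p1 = gam[0] if h1a == h1b else gam[1]
                p2 = gam[0] if h2a == h2b else gam[1]
                # allele 0 = parent A; P(haplotype) = 1/2 * P(parental/recomb)
                probs[h1a + h2a, h1b + h2b] += (2 * p1) * (2 * p2) / 4
        return probs

    grid = np.arange(step, 0.5 + step / 2, step)
    lls = []
    for r in grid:
        p = class_probs(r)
        with np.errstate(divide="ignore"):
            ll = np.where(counts > 0, counts * np.log(p), 0.0).sum()
        lls.append(ll)
    return grid[int(np.argmax(lls))]


def random_pair(rng, n=50, r=None):
    r = rng.uniform(0.02, 0.45) if r is None else r
    g1 = rng.integers(0, 2, size=(n, 2))
    rec = rng.random((n, 2)) < r
    g2 = np.where(rec, 1 - g1, g1)
    a = g1.sum(axis=1).astype(np.int8)
    b = g2.sum(axis=1).astype(np.int8)
    return a, b


class TestEstimateRf:
    def test_zero_recombinant_limit(self):
        n = 40
        a = np.array([AB] * n, dtype=np.int8)
        est = linkage.estimate_rf(a, a.copy())
        assert est.r_hat == 0.0
        assert est.lod == pytest.approx(n * np.log10(2), rel=1e-9)

    def test_em_matches_grid_search(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            a, b = random_pair(rng)
            est = linkage.estimate_rf(a, b)
            assert abs(est.r_hat - _grid_oracle(a, b)) <= 5e-4

    def test_em_loglik_monotone(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            a, b = random_pair(rng)
            trace = []
            linkage.estimate_rf(a, b, trace=trace)
            assert all(t2 >= t1 - 1e-9 for t1, t2 in zip(trace, trace[1:]))

    def test_unlinked_markers_lod_zero(self):
        est = linkage.TwoPointEstimate("a", "b", 0.5, 0.0, 100)
        assert est.lod == 0.0
        rng = np.random.default_rng(23)
        a = rng.integers(0, 3, 500).astype(np.int8)
        b = rng.integers(0, 3, 500).astype(np.int8)
        got = linkage.estimate_rf(a, b)
        assert got.r_hat > 0.4 and got.lod < 2.0

    def test_monomorphic_error(self):
        a = np.array([AA] * 20, dtype=np.int8)
        with pytest.raises(ValueError):
            linkage.estimate_rf(a, a.copy())

    def test_too_few_plants(self):
        a = np.array([AA, MISSING], dtype=np.int8)
        b = np.array([MISSING, AA], dtype=np.int8)
        with pytest.raises(ValueError):
            linkage.estimate_rf(a, b)

    def test_pairwise_matches_scalar(self):
        rng = np.random.default_rng(24)
        mats = [random_pair(rng, n=80) for _ in range(3)]
        cols = {}
        for i, (a, b) in enumerate(mats):
            cols[f"m{2*i}"] = a
            cols[f"m{2*i+1}"] = b
        calls = pd.DataFrame(cols)
        r, lod, n = linkage.pairwise_estimates(calls)
        for i in range(6):
            for j in range(i + 1, 6):
                est = linkage.estimate_rf(calls.iloc[:, i], calls.iloc[:, j])
                assert r[i, j] == pytest.approx(est.r_hat, abs=1e-7)
                assert lod[i, j] == pytest.approx(est.lod, abs=1e-6)
                assert n[i, j] == est.n_informative

    def test_calibration_against_truth(self, small_genome, small_panel):
        """true r = 0.10 via the Haldane spacing, n=267: the mean estimate
        over 50 replicates must sit within 0.01 of the truth."""
        tm = synthetic.true_map_from_genome(small_panel, small_genome)
        geno = small_panel.genotypes
        poly = [m for m in tm.index
                if {geno.at["var_01", m], geno.at["var_02", m]} == {"ref", "alt"}]
        two = tm.loc[poly[:2]].copy()
        two["chromosome"] = "Chr01"
        d = -50.0 * np.log(1 - 2 * 0.10)  # Haldane inverse of r=0.1
        two["cM"] = [0.0, d]
        ests = []
        for seed in range(50):
            pop = synthetic.simulate_f2(
                small_panel, "var_01", "var_02", two, n_plants=267,
                missing_rate=0.0, error_rate=0.0, seed=seed,
            )
            ests.append(linkage.estimate_rf(pop.calls.iloc[:, 0], pop.calls.iloc[:, 1]).r_hat)
        assert abs(np.mean(ests) - 0.10) <= 0.01


# ---------------------------------------------------------------------------
# grouping and ordering
# ---------------------------------------------------------------------------

def simulate_calls(seed, n_chrom=2, markers_per=12, n_plants=200):
    genome = synthetic.simulate_genome(
        n_chromosomes=n_chrom,
        scaffold_length_model={"n_scaffolds": 4, "mean_log_bp": np.log(40_000.0), "sigma_log": 0.3},
        seed=seed,
    )
    panel = synthetic.simulate_panel(genome, snp_density=0.004, seed=seed + 1)
    tm = synthetic.true_map_from_genome(panel, genome)
    geno = panel.genotypes
    poly = [m for m in tm.index
            if {geno.at["var_01", m], geno.at["var_02", m]} == {"ref", "alt"}]
    picked_idx = []
    for _, sub in tm.loc[poly].groupby("chromosome"):
        sub = sub.sort_values("cM")
        take = np.linspace(0, len(sub) - 1, min(markers_per, len(sub))).astype(int)
        picked_idx.extend(sub.index[take])
    pop = synthetic.simulate_f2(
        panel, "var_01", "var_02", tm.loc[picked_idx], n_plants=n_plants,
        missing_rate=0.0, error_rate=0.0, seed=seed + 2,
    )
    return pop


class TestGrouping:
    def test_two_chromosomes_two_groups(self):
        pop = simulate_calls(31)
        r, lod, _ = linkage.pairwise_estimates(pop.calls)
        groups = linkage.group_markers(list(pop.calls.columns), r, lod)
        assert len(groups) == 2
        for g in groups:
            chroms = set(pop.truth.loc[g, "chromosome"])
            assert len(chroms) == 1  # purity against truth

    def test_infinite_lod_singletons(self):
        pop = simulate_calls(32)
        r, lod, _ = linkage.pairwise_estimates(pop.calls)
        groups = linkage.group_markers(list(pop.calls.columns), r, lod, lod_min=np.inf)
        assert all(len(g) == 1 for g in groups)


def _sarf_of(order, d):
    return sum(d[a, b] for a, b in zip(order, order[1:]))


class TestOrdering:
    def test_three_marker_chain(self):
        markers = ["m1", "m2", "m3"]
        r = np.array([[0.0, 0.05, 0.10], [0.05, 0.0, 0.05], [0.10, 0.05, 0.0]])
        lod = 10 * (0.5 - r)
        got = linkage.order_group(markers, markers, r, lod)
        assert got == ["m1", "m2", "m3"]  # normalized: m1 < m3

    def test_two_opt_matches_exhaustive(self):
        """On <=8 markers the seriation's adjacent-r sum must equal the
        exhaustive-permutation minimum in >=95% of random instances."""
        rng = np.random.default_rng(33)
        hits = 0
        for _ in range(100):
            m = int(rng.integers(4, 9))
            pts = np.sort(rng.uniform(0, 0.5, size=m))
            noise = rng.normal(0, 0.01, size=(m, m))
            d = np.abs(pts[:, None] - pts[None, :]) + np.abs(noise + noise.T) / 2
            d = np.clip((d + d.T) / 2, 0.001, 0.499)
            np.fill_diagonal(d, 0.0)
            markers = [f"m{i}" for i in range(m)]
            got = linkage.order_group(markers, markers, d, 10 * (0.5 - d))
            idx = [markers.index(x) for x in got]
            best = min(
                _sarf_of(p, d) for p in itertools.permutations(range(m))
            )
            hits += _sarf_of(idx, d) <= best + 1e-9
        assert hits >= 95

    def test_truth_recovery_50_markers(self):
        pop = simulate_calls(34, n_chrom=1, markers_per=50, n_plants=267)
        r, lod, _ = linkage.pairwise_estimates(pop.calls)
        markers = list(pop.calls.columns)
        groups = linkage.group_markers(markers, r, lod)
        assert len(groups) == 1
        got = linkage.order_group(groups[0], markers, r, lod)
        true_cm = pop.truth.loc[got, "cM"].to_numpy()
        rho = sps.spearmanr(true_cm, np.arange(len(got))).statistic
        assert abs(rho) >= 0.99

    def test_single_marker_group(self):
        got = linkage.order_group(["m1"], ["m1"], np.zeros((1, 1)), np.zeros((1, 1)))
        assert got == ["m1"]


class TestKosambi:
    def test_closed_forms(self):
        assert linkage.kosambi(0.0) == 0.0
        assert linkage.kosambi(0.1) == pytest.approx(25 * np.log(1.2 / 0.8), rel=1e-12)
        assert linkage.kosambi(0.1) == pytest.approx(10.1366, abs=5e-5)
        assert linkage.kosambi(0.5) == np.inf

    def test_round_trip(self):
        for r in (0.0, 0.05, 0.1, 0.2, 0.3, 0.45, 0.499):
            assert linkage.kosambi_inverse(linkage.kosambi(r)) == pytest.approx(r, abs=1e-12)

    def test_inverse_form(self):
        assert linkage.kosambi_inverse(50.0) == pytest.approx(0.5 * np.tanh(1.0), rel=1e-12)


class TestBuildMap:
    def test_positions_cumulative_kosambi(self):
        pop = simulate_calls(35, n_chrom=1, markers_per=15, n_plants=250)
        gmap, summary = linkage.build_map(pop.calls)
        r, _, _ = linkage.pairwise_estimates(pop.calls)
        idx = {m: i for i, m in enumerate(pop.calls.columns)}
        table = gmap.group_table(gmap.groups()[0])
        order = table["marker"].tolist()
        pos = table["cM"].to_numpy()
        assert pos[0] == 0.0
        for k in range(1, len(order)):
            step = linkage.kosambi(r[idx[order[k - 1]], idx[order[k]]])
            assert pos[k] - pos[k - 1] == pytest.approx(step, abs=1e-9)
        assert (np.diff(pos) >= 0).all()

    def test_reversal_invariance(self):
        # total length is the sum of adjacent distances: reversing the order
        # of a group leaves it unchanged
        pop = simulate_calls(36, n_chrom=1, markers_per=12)
        gmap, summary = linkage.build_map(pop.calls)
        table = gmap.group_table(gmap.groups()[0])
        r, _, _ = linkage.pairwise_estimates(pop.calls)
        idx = {m: i for i, m in enumerate(pop.calls.columns)}
        order = table["marker"].tolist()
        fwd = sum(linkage.kosambi(r[idx[a], idx[b]]) for a, b in zip(order, order[1:]))
        rev = list(reversed(order))
        bwd = sum(linkage.kosambi(r[idx[a], idx[b]]) for a, b in zip(rev, rev[1:]))
        assert fwd == pytest.approx(bwd, rel=1e-12)
        assert summary[summary["group"] != "Total"]["length_cM"].iloc[0] == pytest.approx(fwd, abs=1e-9)

    def test_summary_totals(self):
        pop = simulate_calls(37, n_chrom=2, markers_per=10)
        gmap, summary = linkage.build_map(pop.calls)
        body = summary[summary["group"] != "Total"]
        total = summary[summary["group"] == "Total"].iloc[0]
        assert total["n_markers"] == body["n_markers"].sum()
        assert total["length_cM"] == pytest.approx(body["length_cM"].sum())

    def test_anchor_labels(self):
        pop = simulate_calls(38, n_chrom=2, markers_per=10)
        anchors = pop.truth["chromosome"].to_dict()
        gmap, _ = linkage.build_map(pop.calls, anchors=anchors)
        assert set(gmap.groups()) == set(pop.truth["chromosome"])

    def test_cosegregating_markers_share_bin(self):
        pop = simulate_calls(39, n_chrom=1, markers_per=12)
        gmap, _ = linkage.build_map(pop.calls)
        table = gmap.table
        for _, sub in table.groupby("bin"):
            assert sub["cM"].nunique() == 1

    def test_parameter_recovery_median_bias(self):
        """Across 40 simulated F2 sets (n=267, 20 markers), the median
        |r-hat - r_true| over adjacent pairs stays within 0.015.  True r
        comes from the Haldane transform of the simulated cM spacing."""
        devs = []
        for seed in range(40):
            pop = simulate_calls(100 + seed, n_chrom=1, markers_per=20, n_plants=267)
            r, _, _ = linkage.pairwise_estimates(pop.calls)
            order = pop.truth.sort_values("cM").index.tolist()
            idx = {m: i for i, m in enumerate(pop.calls.columns)}
            for a, b in zip(order, order[1:]):
                d = pop.truth.at[b, "cM"] - pop.truth.at[a, "cM"]
                r_true = (1 - np.exp(-2 * d / 100)) / 2
                devs.append(abs(r[idx[a], idx[b]] - r_true))
        assert np.median(devs) <= 0.015
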