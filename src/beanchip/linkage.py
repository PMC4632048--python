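"""F2 linkage-map construction.

Pipeline: marker QC (missingness and 1:2:1 segregation-distortion chi-square),
two-point recombination fractions by EM on the codominant F2 likelihood,
LOD-threshold grouping, seriation ordering within groups, Kosambi distances,
and cosegregation bins.

The two-point model: with coupling phase known from the cross, an F2
individual's two-locus genotype falls in 9 classes whose probabilities are
products of independent gamete probabilities with recombinant-gamete
probability r; the double heterozygote collapses the zero- and
two-recombinant phases into one observable class with probability
((1-r)^2 + r^2) / 2, which is the latent structure the EM resolves.

Sufficient statistics per pair (plants non-missing at both markers):
  n0 - parental double homozygotes (AA/AA, BB/BB), 0 recombinant gametes
  n1 - one homozygote + one heterozygote (4 classes), 1 recombinant gamete
  n2 - opposite double homozygotes (AA/BB, BB/AA), 2 recombinant gametes
  n5 - double heterozygotes (0 or 2 recombinant gametes, latent)
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import AA, AB, BB, MISSING, GeneticMap, TwoPointEstimate

EM_TOL = 1e-8
EM_MAX_ITER = 200
LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegregationTest:
    """1:2:1 chi-square test (2 df) of one marker's genotype counts."""

    n_aa: int
    n_ab: int
    n_bb: int
    chi2: float
    p_value: float


def segregation_test(n_aa: int, n_ab: int, n_bb: int) -> SegregationTest:
    """Chi-square goodness of fit against the Mendelian 1:2:1 F2 ratio.

    No continuity correction is applied.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no non-missing calls")
    expected = np.array([n / 4.0, n / 2.0, n / 4.0])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=2))
    return SegregationTest(n_aa, n_ab, n_bb, chi2, p)


def qc_filter(
    calls: pd.DataFrame,
    max_missing: float = 0.10,
    distortion_alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop markers with missing fraction > ``max_missing`` or significant
    segregation distortion from 1:2:1 (p < ``distortion_alpha``).

    Returns (retained calls, QC report with one row per marker).
    """
    vals = calls.to_numpy()
    rows = []
    keep = []
    for j, marker in enumerate(calls.columns):
        col = vals[:, j]
        n_miss = int((col == MISSING).sum())
        frac_miss = n_miss / len(col)
        counts = [int((col == g).sum()) for g in (AA, AB, BB)]
        if sum(counts) == 0:
            rows.append((marker, frac_miss, np.nan, np.nan, "removed_missing"))
            continue
        test = segregation_test(*counts)
        if frac_miss > max_missing:
            verdict = "removed_missing"
        elif test.p_value < distortion_alpha:
            verdict = "removed_distorted"
        else:
            verdict = "retained"
            keep.append(marker)
        rows.append((marker, frac_miss, test.chi2, test.p_value, verdict))
    report = pd.DataFrame(
        rows, columns=["marker", "missing_fraction", "chi2", "p_value", "verdict"]
    ).set_index("marker")
    if not keep:
        raise ValueError("QC removed every marker; no map can be built")
    return calls[keep], report


# ---------------------------------------------------------------------------
# two-point estimation
# ---------------------------------------------------------------------------

def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int, int]:
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    n0 = int(((a == AA) & (b == AA)).sum() + ((a == BB) & (b == BB)).sum())
    n2 = int(((a == AA) & (b == BB)).sum() + ((a == BB) & (b == AA)).sum())
    n5 = int(((a == AB) & (b == AB)).sum())
    n1 = int(a.size - n0 - n2 - n5)
    return n0, n1, n2, n5


def _em_counts(
    n0: float, n1: float, n2: float, n5: float, trace: list | None = None
) -> float:
    """EM for r on the sufficient statistics; the M step is

        r <- (n1 + 2 n2 + 2 n5 * r^2 / ((1-r)^2 + r^2)) / (2 n)
    """
    n = n0 + n1 + n2 + n5
    if n1 == 0 and n2 == 0:
        # no observed recombinant class: the likelihood is decreasing in r
        # on [0, 0.5), so the MLE is exactly 0 (cosegregation)
        if trace is not None:
            trace.append(_loglik(0.0, n0, n1, n2, n5))
        return 0.0
    # initializer capped below 0.5: r = 0.5 is a fixed point of the update
    # (unstable when the MLE is interior), so never start exactly there
    r = min(max((n1 + 2 * n2 + n5) / (2 * n), 1e-6), 0.49)
    for _ in range(EM_MAX_ITER):
        if trace is not None:
            trace.append(_loglik(r, n0, n1, n2, n5))
        frac = r * r / ((1 - r) ** 2 + r * r)
        r_new = (n1 + 2 * n2 + 2 * n5 * frac) / (2 * n)
        r_new = min(max(r_new, 0.0), 0.5)
        if abs(r_new - r) < EM_TOL:
            r = r_new
            break
        r = r_new
    return r


def _loglik(r: float, n0: float, n1: float, n2: float, n5: float) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = [
            (n0, np.log((1 - r) ** 2 / 4) if r < 1 else -np.inf),
            (n1, np.log(r * (1 - r) / 2) if 0 < r < 1 else -np.inf),
            (n2, np.log(r * r / 4) if r > 0 else -np.inf),
            (n5, np.log(((1 - r) ** 2 + r * r) / 2)),
        ]
    return float(sum(c * t for c, t in terms if c > 0))


def estimate_rf(
    a: np.ndarray | pd.Series,
    b: np.ndarray | pd.Series,
    marker_a: str = "a",
    marker_b: str = "b",
    trace: list | None = None,
) -> TwoPointEstimate:
    """Two-point recombination fraction and LOD for one F2 marker pair.

    ``trace``, if given, collects the log-likelihood at each EM iteration
    (it is non-decreasing; exposed for calibration checks).
    """
    a = np.asarray(a, dtype=np.int8)
    b = np.asarray(b, dtype=np.int8)
    n0, n1, n2, n5 = _pair_counts(a, b)
    n = n0 + n1 + n2 + n5
    if n < 2:
        raise ValueError("fewer than 2 plants non-missing at both markers")
    if n0 + n2 + n5 == n and (n0 == n or n2 == n):
        raise ValueError("monomorphic pair pattern: estimate undefined")
    r = _em_counts(n0, n1, n2, n5, trace=trace)
    lod = (_loglik(r, n0, n1, n2, n5) - _loglik(0.5, n0, n1, n2, n5)) / LN10
    return TwoPointEstimate(marker_a, marker_b, float(r), max(float(lod), 0.0), n)


def pairwise_estimates(calls: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs r-hat, LOD, and informative-plant counts, vectorized.

    ``calls`` is plants x markers (integer codes).  Returns three m x m
    arrays.  The EM runs simultaneously on every pair's sufficient
    statistics; this is what makes thousands of markers tractable.
    """
    vals = calls.to_numpy().T  # markers x plants
    A = (vals == AA).astype(np.float32)
    H = (vals == AB).astype(np.float32)
    B = (vals == BB).astype(np.float32)
    ok = (vals != MISSING).astype(np.float32)

    n0 = A @ A.T + B @ B.T
    n2 = A @ B.T + B @ A.T
    n5 = H @ H.T
    n = ok @ ok.T
    n1 = n - n0 - n2 - n5

    m = vals.shape[0]
    iu = np.triu_indices(m, 1)
    n0f, n1f, n2f, n5f, nf = (x[iu].astype(np.float64) for x in (n0, n1, n2, n5, n))

    with np.errstate(divide="ignore", invalid="ignore"):
        rf = np.where(nf > 0, (n1f + 2 * n2f + n5f) / (2 * np.maximum(nf, 1)), 0.49)
        rf = np.clip(rf, 1e-6, 0.49)  # 0.5 is an unstable EM fixed point
        # active-set EM: iterate only pairs that have not yet converged
        active = np.arange(rf.size)
        for _ in range(EM_MAX_ITER):
            ra = rf[active]
            frac = ra * ra / ((1 - ra) ** 2 + ra * ra)
            r_new = (n1f[active] + 2 * n2f[active] + 2 * n5f[active] * frac) / (
                2 * np.maximum(nf[active], 1)
            )
            r_new = np.clip(r_new, 0.0, 0.5)
            moved = np.abs(r_new - rf[active]) >= EM_TOL
            rf[active] = r_new
            active = active[moved]
            if active.size == 0:
                break
        rf[(n1f == 0) & (n2f == 0)] = 0.0  # cosegregation MLE is exactly 0

        def ll(rr: np.ndarray) -> np.ndarray:
            out = np.where(n0f > 0, n0f * np.log(np.maximum((1 - rr) ** 2 / 4, 1e-300)), 0.0)
            out = out + np.where(n1f > 0, n1f * np.log(np.maximum(rr * (1 - rr) / 2, 1e-300)), 0.0)
            out = out + np.where(n2f > 0, n2f * np.log(np.maximum(rr * rr / 4, 1e-300)), 0.0)
            out = out + np.where(n5f > 0, n5f * np.log(((1 - rr) ** 2 + rr * rr) / 2), 0.0)
            return out

        lodf = np.maximum((ll(rf) - ll(np.full_like(rf, 0.5))) / LN10, 0.0)

    r = np.zeros((m, m))
    lod = np.zeros((m, m))
    r[iu] = rf
    r.T[iu] = rf
    lod[iu] = lodf
    lod.T[iu] = lodf
    return r, lod, n.astype(np.int64)


# ---------------------------------------------------------------------------
# grouping, ordering, distances
# ---------------------------------------------------------------------------

def group_markers(
    markers: list[str],
    r: np.ndarray,
    lod: np.ndarray,
    lod_min: float = 6.0,
    rf_max: float = 0.35,
) -> list[list[str]]:
    """Linkage groups = connected components of the graph with an edge
    wherever LOD >= lod_min and r-hat <= rf_max.  Groups are returned
    largest first, members sorted by id."""
    g = nx.Graph()
    g.add_nodes_from(range(len(markers)))
    ii, jj = np.nonzero(np.triu((lod >= lod_min) & (r <= rf_max), k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = [sorted(markers[i] for i in comp) for comp in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), c[0]))


def _collapse_bins(members: list[int], r: np.ndarray) -> list[list[int]]:
    """Cosegregation bins: connected components of the r-hat == 0 relation."""
    g = nx.Graph()
    g.add_nodes_from(members)
    for ai, a in enumerate(members):
        for b in members[ai + 1 :]:
            if r[a, b] == 0.0:
                g.add_edge(a, b)
    return [sorted(c) for c in nx.connected_components(g)]


def _sarf(order: list[int], d: np.ndarray) -> float:
    return float(sum(d[a, b] for a, b in zip(order, order[1:])))


def _two_opt(order: list[int], d: np.ndarray) -> list[int]:
    """2-opt on the open path: reverse segments while the sum of adjacent
    distances (SARF) strictly decreases."""
    order = list(order)
    n = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                before = d[order[i - 1], order[i]] if i > 0 else 0.0
                after = d[order[j], order[j + 1]] if j < n - 1 else 0.0
                new_before = d[order[i - 1], order[j]] if i > 0 else 0.0
                new_after = d[order[i], order[j + 1]] if j < n - 1 else 0.0
                if new_before + new_after < before + after - 1e-12:
                    order[i : j + 1] = reversed(order[i : j + 1])
                    improved = True
    return order


def _spectral_order(d: np.ndarray) -> list[int]:
    """Initial order from classical multidimensional scaling: project the
    distance matrix onto its leading principal coordinate and sort.  Robust
    against the 'folded chain' local optima that greedy extension can hit on
    dense maps."""
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    coord = vecs[:, np.argmax(vals)]
    return sorted(range(n), key=lambda i: (coord[i], i))


def order_group(
    group: list[str], markers: list[str], r: np.ndarray, lod: np.ndarray
) -> list[str]:
    """Deterministic seriation of one linkage group.

    Zero-recombination bins are collapsed to representatives.  Two initial
    orders are built — a greedy chain (seeded at the max-LOD bin pair,
    extended at either end by the nearest unplaced bin) and a spectral
    principal-coordinate order — each is polished by 2-opt until no
    adjacent-r-sum (SARF) improvement remains, and the order with the
    smaller SARF wins (ties prefer the greedy chain).  The final order is
    normalized so the lexicographically smaller terminal marker comes first.
    """
    idx = {m: i for i, m in enumerate(markers)}
    members = [idx[m] for m in group]
    if len(members) == 1:
        return list(group)
    bins = _collapse_bins(members, r)
    reps = [b[0] for b in bins]
    if len(reps) == 1:
        ordered_bins = [bins[0]]
    else:
        # bin-level distances: mean r-hat over member pairs
        nb = len(bins)
        d = np.zeros((nb, nb))
        ld = np.zeros((nb, nb))
        for x in range(nb):
            for y in range(x + 1, nb):
                block = r[np.ix_(bins[x], bins[y])]
                lblock = lod[np.ix_(bins[x], bins[y])]
                d[x, y] = d[y, x] = float(block.mean())
                ld[x, y] = ld[y, x] = float(lblock.mean())
        start = np.unravel_index(np.argmax(np.triu(ld, k=1) - np.tril(np.inf * np.ones_like(ld))), ld.shape)
        chain = [int(start[0]), int(start[1])]
        unplaced = set(range(nb)) - set(chain)
        while unplaced:
            left, right = chain[0], chain[-1]
            best = min(
                ((d[e, u], e != left, u, e) for u in unplaced for e in (left, right)),
            )
            _, at_right, u, _ = best
            if at_right:
                chain.append(u)
            else:
                chain.insert(0, u)
            unplaced.remove(u)
        chain = _two_opt(chain, d)
        spectral = _two_opt(_spectral_order(d), d)
        if _sarf(spectral, d) < _sarf(chain, d) - 1e-12:
            chain = spectral
        ordered_bins = [bins[i] for i in chain]
    flat = [markers[i] for b in ordered_bins for i in b]
    if flat[-1] < flat[0]:
        flat = [markers[i] for b in reversed(ordered_bins) for i in reversed(b)]
    return flat


# ---------------------------------------------------------------------------
# map function and assembly
# ---------------------------------------------------------------------------

def kosambi(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in cM; r >= 0.5 -> inf."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        d = np.where(r < 0.5, 25.0 * np.log((1 + 2 * r) / np.maximum(1 - 2 * r, 0.0)), np.inf)
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d: float | np.ndarray) -> float | np.ndarray:
    """Inverse Kosambi: r = 0.5 tanh(d / 50)."""
    d = np.asarray(d, dtype=float)
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def build_map(
    calls: pd.DataFrame,
    lod_min: float = 6.0,
    rf_max: float = 0.35,
    anchors: dict[str, str] | None = None,
    qc: bool = True,
    max_missing: float = 0.10,
    distortion_alpha: float = 0.01,
) -> tuple[GeneticMap, pd.DataFrame]:
    """QC, group, order, and place markers; returns (map, per-group summary).

    cM positions accumulate Kosambi-transformed adjacent r-hat along the
    final order; markers at zero recombination share a bin and a position.
    ``anchors`` (marker -> chromosome label) optionally names groups by
    majority vote; unanchored groups get sequential ``LG`` labels.
    """
    if qc:
        calls, _ = qc_filter(calls, max_missing=max_missing, distortion_alpha=distortion_alpha)
    markers = list(calls.columns)
    r, lod, _ = pairwise_estimates(calls)
    groups = group_markers(markers, r, lod, lod_min=lod_min, rf_max=rf_max)
    idx = {m: i for i, m in enumerate(markers)}

    rows = []
    lg_counter = 0
    labels_used: set[str] = set()
    for group in groups:
        ordered = order_group(group, markers, r, lod)
        label = None
        if anchors:
            votes = pd.Series([anchors[m] for m in ordered if m in anchors])
            if len(votes):
                top = votes.value_counts()
                if top.iloc[0] > len(votes) / 2 and top.index[0] not in labels_used:
                    label = str(top.index[0])
        if label is None:
            lg_counter += 1
            label = f"LG{lg_counter:02d}"
        labels_used.add(label)
        pos = 0.0
        bin_id = 0
        prev = None
        for k, m in enumerate(ordered):
            if prev is not None:
                step = kosambi(min(r[idx[prev], idx[m]], 0.4999999))
                if step > 0:
                    bin_id += 1
                pos += step
            rows.append((label, k, m, pos, f"{label}_bin{bin_id:03d}"))
            prev = m
    table = pd.DataFrame(rows, columns=["group", "order_index", "marker", "cM", "bin"])
    gmap = GeneticMap(table=table)
    return gmap, gmap.summary()
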