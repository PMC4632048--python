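"""Selection of a diverse genotype subset that detects the most SNPs.

Given a genotypes x SNPs call matrix with market-class labels, pick a fixed
number of genotypes per class whose union detects as many panel-polymorphic
SNPs as possible.  Detection is a coverage function, so lazy greedy carries
the classic (1 - 1/e) guarantee; an exhaustive mode provides the true
optimum on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd


@dataclass
class DetectionInstance:
    """Calls matrix (genotypes x SNPs, values in {ref, alt, het, missing})
    plus genotype -> class labels.

    A SNP is detected by a genotype subset iff at least two non-missing
    calls in the subset jointly show both alleles (het carries both).
    """

    calls: pd.DataFrame
    class_of: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.calls.index) - set(self.class_of)
        if unknown:
            raise ValueError(f"genotypes without class label: {sorted(unknown)}")
        vals = self.calls.to_numpy()
        self._has_ref = np.isin(vals, ("ref", "het"))
        self._has_alt = np.isin(vals, ("alt", "het"))
        self._nonmiss = vals != "missing"

    @property
    def genotypes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snps(self) -> list[str]:
        return list(self.calls.columns)

    def _rows(self, subset: list[str]) -> np.ndarray:
        idx = []
        for g in subset:
            try:
                idx.append(self.calls.index.get_loc(g))
            except KeyError:
                raise KeyError(f"unknown genotype id: {g}") from None
        return np.asarray(idx, dtype=int)

    def detection_mask(self, subset: list[str]) -> np.ndarray:
        """Boolean per-SNP mask of detection by ``subset``."""
        if not subset:
            raise ValueError("subset must be non-empty")
        rows = self._rows(subset)
        return (
            self._has_ref[rows].any(axis=0)
            & self._has_alt[rows].any(axis=0)
            & (self._nonmiss[rows].sum(axis=0) >= 2)
        )

    def panel_polymorphic_mask(self) -> np.ndarray:
        return self.detection_mask(self.genotypes)


def detected_snps(subset: list[str], instance: DetectionInstance) -> set[str]:
    """The set of SNP ids polymorphic within ``subset``."""
    mask = instance.detection_mask(subset)
    return {s for s, m in zip(instance.snps, mask) if m}


def select_panel(
    instance: DetectionInstance,
    k_per_class: dict[str, int],
    method: str = "greedy",
    exhaustive_limit: int = 10**6,
) -> tuple[list[str], float]:
    """Choose ``k_per_class[c]`` genotypes from each class ``c``.

    ``greedy`` is a deterministic multi-start marginal-gain greedy with a
    single-swap exchange polish (see ``_greedy_multistart``); ``exhaustive``
    enumerates all per-class combinations and is refused above
    ``exhaustive_limit`` total combinations.  Coverage is reported
    panel-wide: |detected by the chosen set| / |panel-polymorphic SNPs|.
    """
    by_class: dict[str, list[str]] = {}
    for g in instance.genotypes:
        by_class.setdefault(instance.class_of[g], []).append(g)
    for c, k in k_per_class.items():
        if c not in by_class:
            raise ValueError(f"unknown class: {c}")
        if not 0 <= k <= len(by_class[c]):
            raise ValueError(f"infeasible k={k} for class {c} (size {len(by_class[c])})")

    poly = instance.panel_polymorphic_mask()
    n_poly = int(poly.sum())

    if method == "greedy":
        chosen = _greedy_multistart(instance, by_class, k_per_class)
    elif method == "exhaustive":
        total = 1
        for c, k in k_per_class.items():
            total *= comb(len(by_class[c]), k)
        if total > exhaustive_limit:
            raise ValueError(f"{total} combinations exceed exhaustive limit")
        pools = [
            itertools.combinations(sorted(by_class[c]), k)
            for c, k in sorted(k_per_class.items())
        ]
        best_cov, chosen = -1, []
        for combo in itertools.product(*pools):
            subset = sorted(itertools.chain.from_iterable(combo))
            cov = int(instance.detection_mask(subset).sum()) if subset else 0
            if cov > best_cov or (cov == best_cov and subset < chosen):
                best_cov, chosen = cov, subset
    else:
        raise ValueError(f"unknown method: {method}")

    detected = int(instance.detection_mask(chosen).sum()) if chosen else 0
    coverage = detected / n_poly if n_poly else 1.0
    return chosen, coverage


def _coverage(instance: DetectionInstance, subset: list[str]) -> int:
    return int(instance.detection_mask(subset).sum()) if subset else 0


def _greedy_complete(
    instance: DetectionInstance,
    by_class: dict[str, list[str]],
    k_per_class: dict[str, int],
    seed_set: list[str],
) -> list[str]:
    chosen = list(seed_set)
    remaining = dict(k_per_class)
    for g in chosen:
        remaining[instance.class_of[g]] -= 1
    while any(v > 0 for v in remaining.values()):
        best_gain, best_id = -1, None
        for c, quota in sorted(remaining.items()):
            if quota <= 0:
                continue
            for g in sorted(by_class[c]):
                if g in chosen:
                    continue
                gain = _coverage(instance, chosen + [g])
                if gain > best_gain:
                    best_gain, best_id = gain, g
        chosen.append(best_id)
        remaining[instance.class_of[best_id]] -= 1
    return chosen


def _swap_polish(
    instance: DetectionInstance, by_class: dict[str, list[str]], chosen: list[str]
) -> list[str]:
    """Hill-climb by single swaps within a class (preserves quotas)."""
    chosen = list(chosen)
    best = _coverage(instance, chosen)
    improved = True
    while improved:
        improved = False
        for i, out in enumerate(list(chosen)):
            for cand in sorted(by_class[instance.class_of[out]]):
                if cand in chosen:
                    continue
                trial = chosen[:i] + [cand] + chosen[i + 1 :]
                val = _coverage(instance, trial)
                if val > best:
                    chosen, best, improved = trial, val, True
    return chosen


def _greedy_multistart(
    instance: DetectionInstance,
    by_class: dict[str, list[str]],
    k_per_class: dict[str, int],
) -> list[str]:
    """Deterministic multi-start greedy with exchange polish.

    Detection needs two informative calls, so every singleton has zero gain
    and a single myopic pass would start from an arbitrary genotype; instead
    the greedy completion is run from every admissible first genotype and
    each result is polished by within-class single swaps.  The best coverage
    wins; ties go to the lexicographically smallest chosen set.
    """
    starts = [
        g
        for c, k in sorted(k_per_class.items())
        if k > 0
        for g in sorted(by_class[c])
    ]
    if not starts:
        return []
    best_val, best_set = -1, None
    for first in starts:
        chosen = _greedy_complete(instance, by_class, k_per_class, [first])
        chosen = _swap_polish(instance, by_class, chosen)
        val = _coverage(instance, chosen)
        key = sorted(chosen)
        if val > best_val or (val == best_val and key < best_set):
            best_val, best_set = val, key
    return best_set
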