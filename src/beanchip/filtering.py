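"""Infinium design-candidate filters for raw SNP lists.

The cascade removes SNPs that cannot be assayed on an Infinium BeadChip:
sites too close to another variant (the 25-nt probe arm would cover it),
A/T and G/C allele pairs (indistinguishable by single-color readout),
flanks containing N, and probe arms that are not unique in the genome.
A FilterReport chains the counts stage by stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd

from ._kmer import KmerIndex
from .types import SnpCandidate

ARM_LEN = 25
FLANK_LEN = 60

PROXIMITY = "Elimination of SNPs residing within 25 nt of another SNP"
ALLELE_TYPE = "Elimination of SNPs with A/T or G/C alleles"
FLANK_N = "Elimination of SNPs with N in the 60-nt regions flanking the SNP"
UNIQUENESS = "Elimination of SNPs whose 25-nt flanking sequences are not unique in the genome"


@dataclass
class FilterReport:
    """Ordered per-stage bookkeeping: (filter_name, n_in, n_removed, n_out)."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_removed: int) -> None:
        if self.stages and self.stages[-1][3] != n_in:
            raise ValueError("stage n_in does not chain from previous n_out")
        self.stages.append((name, n_in, n_removed, n_in - n_removed))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["filter", "n_in", "n_removed", "n_out"]
        )


def _validate_unique_positions(candidates: Sequence[SnpCandidate]) -> None:
    seen = set()
    for c in candidates:
        key = (c.scaffold_id, c.position)
        if key in seen:
            raise ValueError(f"duplicate SNP position {key}")
        seen.add(key)


def proximity_filter(
    candidates: Sequence[SnpCandidate],
    min_spacing: int = ARM_LEN,
    keep_first: bool = False,
) -> tuple[list[SnpCandidate], list[SnpCandidate]]:
    """Remove SNPs residing within ``min_spacing`` nt of another SNP.

    Distance is the absolute difference of 1-based positions on the same
    scaffold; "within" means distance <= min_spacing.  By default removal is
    symmetric (both members of a close pair go, since either probe arm would
    overlap the other variant); ``keep_first`` retains the leftmost of each
    run instead.
    """
    _validate_unique_positions(candidates)
    order = sorted(range(len(candidates)), key=lambda i: (candidates[i].scaffold_id, candidates[i].position))
    removed_idx: set[int] = set()
    if keep_first:
        last_kept: dict[str, int] = {}
        for i in order:
            c = candidates[i]
            prev = last_kept.get(c.scaffold_id)
            if prev is not None and c.position - prev <= min_spacing:
                removed_idx.add(i)
            else:
                last_kept[c.scaffold_id] = c.position
    else:
        for a, b in zip(order, order[1:]):
            ca, cb = candidates[a], candidates[b]
            if ca.scaffold_id == cb.scaffold_id and cb.position - ca.position <= min_spacing:
                removed_idx.update((a, b))
    retained = [c for i, c in enumerate(candidates) if i not in removed_idx]
    removed = [c for i, c in enumerate(candidates) if i in removed_idx]
    return retained, removed


def allele_type_filter(
    candidates: Sequence[SnpCandidate],
) -> tuple[list[SnpCandidate], list[SnpCandidate]]:
    """Remove A/T and G/C SNPs (order-insensitive allele pairs)."""
    bad = ({"A", "T"}, {"G", "C"})
    retained, removed = [], []
    for c in candidates:
        (removed if {c.ref_allele, c.alt_allele} in bad else retained).append(c)
    return retained, removed


def flank_n_filter(
    candidates: Sequence[SnpCandidate],
) -> tuple[list[SnpCandidate], list[SnpCandidate]]:
    """Remove SNPs with N in either 60-nt flank.

    A flank shorter than 60 nt cannot supply the probe context and is
    treated as containing N (removed with reason ``short_flank``).
    """
    retained, removed = [], []
    for c in candidates:
        if len(c.flank_left) < FLANK_LEN or len(c.flank_right) < FLANK_LEN:
            removed.append(c)
        elif "N" in c.flank_left.upper() or "N" in c.flank_right.upper():
            removed.append(c)
        else:
            retained.append(c)
    return retained, removed


def flank_removal_reason(candidate: SnpCandidate) -> str:
    if len(candidate.flank_left) < FLANK_LEN or len(candidate.flank_right) < FLANK_LEN:
        return "short_flank"
    return "flank_N"


def uniqueness_filter(
    candidates: Sequence[SnpCandidate],
    genome: dict[str, str],
    k: int = ARM_LEN,
    index: KmerIndex | None = None,
) -> tuple[list[SnpCandidate], list[SnpCandidate]]:
    """Retain SNPs whose two proximal 25-mers occur exactly once in the genome.

    Both probe arms (the k nt immediately left and immediately right of the
    variant) must be unique counting both strands; a k-mer and its reverse
    complement are the same occurrence.  ``genome`` maps scaffold id to
    sequence; a prebuilt ``index`` may be passed to amortize indexing.
    """
    for c in candidates:
        if c.scaffold_id not in genome:
            raise ValueError(f"{c.id}: scaffold {c.scaffold_id} absent from genome")
    if index is None:
        index = KmerIndex(genome, k)
    retained, removed = [], []
    for c in candidates:
        left = c.flank_left[-k:]
        right = c.flank_right[:k]
        if (
            len(left) == k
            and len(right) == k
            and index.count_both_strands(left) == 1
            and index.count_both_strands(right) == 1
        ):
            retained.append(c)
        else:
            removed.append(c)
    return retained, removed


def design_score_passthrough(candidates: Sequence[SnpCandidate]) -> list[float]:
    """Default stand-in for the proprietary assay design score: pass all."""
    return [1.0] * len(candidates)


def gc_homopolymer_score(candidates: Sequence[SnpCandidate]) -> list[float]:
    """Naive surrogate design score in [0, 1]: penalizes extreme GC content
    and long homopolymer runs in the probe arms.  Illustrative only; not a
    reimplementation of any vendor scoring tool."""
    scores = []
    for c in candidates:
        arms = c.flank_left[-ARM_LEN:] + c.flank_right[:ARM_LEN]
        if not arms:
            scores.append(0.0)
            continue
        gc = sum(b in "GCgc" for b in arms) / len(arms)
        run, best = 1, 1
        for a, b in zip(arms, arms[1:]):
            run = run + 1 if a == b else 1
            best = max(best, run)
        score = 1.0 - 2.0 * abs(gc - 0.5) - max(0, best - 5) * 0.1
        scores.append(max(0.0, min(1.0, score)))
    return scores


def run_cascade(
    candidates: Sequence[SnpCandidate],
    genome: dict[str, str] | None = None,
    min_spacing: int = ARM_LEN,
    k: int = ARM_LEN,
    apply_uniqueness: bool = True,
    design_scorer: Callable[[Sequence[SnpCandidate]], list[float]] | None = None,
    design_score_min: float = 0.6,
) -> tuple[list[SnpCandidate], FilterReport, dict[str, list[SnpCandidate]]]:
    """Apply the full cascade: proximity -> allele type -> flank N, then
    (optionally) genome-wide arm uniqueness and a pluggable design score.

    Returns (retained, report, removed-by-stage).
    """
    report = FilterReport()
    removed_by_stage: dict[str, list[SnpCandidate]] = {}
    current = list(candidates)

    for name, fn in (
        (PROXIMITY, lambda cs: proximity_filter(cs, min_spacing=min_spacing)),
        (ALLELE_TYPE, allele_type_filter),
        (FLANK_N, flank_n_filter),
    ):
        retained, removed = fn(current)
        report.add(name, len(current), len(removed))
        removed_by_stage[name] = removed
        current = retained

    if apply_uniqueness:
        if genome is None:
            raise ValueError("uniqueness filter requires a genome")
        retained, removed = uniqueness_filter(current, genome, k=k)
        report.add(UNIQUENESS, len(current), len(removed))
        removed_by_stage[UNIQUENESS] = removed
        current = retained

    if design_scorer is not None:
        scores = design_scorer(current)
        retained = [c for c, s in zip(current, scores) if s >= design_score_min]
        removed = [c for c, s in zip(current, scores) if s < design_score_min]
        name = f"Elimination of SNPs with design score <{design_score_min}"
        report.add(name, len(current), len(removed))
        removed_by_stage[name] = removed
        current = retained

    return current, report, removed_by_stage
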