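"""Chip-content selection: the diversity chip, the gap-filling/orienting
chip, and the thinned core set.

Three procedures over the filtered candidate list:

* ``design_chip1`` maximizes polymorphism across market classes, preferring
  long (>10 kb) and not-yet-covered scaffolds, with a minimum within-
  scaffold spacing (>5.5 kb).
* ``design_chip2`` fills anchoring gaps relative to chip 1: scaffolds the
  first chip missed or covered only with cross-monomorphic SNPs, second
  markers for single-marker scaffolds, extra markers for large scaffolds —
  preferring SNPs at the distal ends of a scaffold so recombination between
  them can orient it.
* ``select_core_set`` applies hard quality filters (MAF > 0.05, missing or
  ambiguous calls < 10%) and thins redundant markers, capping cosegregation
  bins in low-recombination (low cM/Mb) regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import SnpCandidate


@dataclass
class ChipSpec:
    """Tunables of a chip design round."""

    size: int = 6000
    min_spacing_bp: int = 5500  # within-scaffold distance must exceed this
    long_scaffold_bp: int = 10_000
    exclusion: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("chip size must be positive")
        if self.min_spacing_bp < 0:
            raise ValueError("spacing must be >= 0")


@dataclass
class CoreSetCriteria:
    """Hard filters and thinning parameters for the core set."""

    maf_min: float = 0.05  # exclusive
    max_missing: float = 0.10  # exclusive bound on missing + ambiguous
    low_recomb_ratio: float = 0.2  # windows below this fraction of the
    # genome-median cM/Mb get a per-bin cap
    low_recomb_bin_cap: int = 1


def _spacing_ok(
    candidate: SnpCandidate, chosen_positions: dict[str, list[int]], min_spacing: int
) -> bool:
    return all(
        abs(candidate.position - p) > min_spacing
        for p in chosen_positions.get(candidate.scaffold_id, ())
    )


def design_chip1(
    candidates: list[SnpCandidate],
    scaffold_lengths: dict[str, int],
    spec: ChipSpec | None = None,
) -> tuple[list[SnpCandidate], list[str]]:
    """Greedy market-class-polymorphism chip selection.

    Iteratively picks the candidate with the best key: more polymorphic
    market classes first, then scaffolds not yet covered by the chip, then
    scaffolds longer than the preference threshold, then higher MAF, then
    id.  Within-scaffold spacing is enforced strictly (> spacing).
    Returns (chosen, warnings).
    """
    spec = spec or ChipSpec()
    warnings: list[str] = []
    eligible = [c for c in candidates if c.id not in spec.exclusion]
    chosen: list[SnpCandidate] = []
    chosen_pos: dict[str, list[int]] = {}
    covered: set[str] = set()

    def key(c: SnpCandidate):
        # class polymorphism first, then coverage of a new scaffold, then
        # the long-scaffold preference, then MAF, then id
        return (
            -c.n_polymorphic_classes,
            c.scaffold_id in covered,
            -(scaffold_lengths.get(c.scaffold_id, 0) > spec.long_scaffold_bp),
            -(c.maf or 0.0),
            c.id,
        )

    pool = sorted(eligible, key=lambda c: c.id)
    while len(chosen) < spec.size and pool:
        pool.sort(key=key)
        picked = None
        for i, c in enumerate(pool):
            if _spacing_ok(c, chosen_pos, spec.min_spacing_bp):
                picked = pool.pop(i)
                break
        if picked is None:
            break
        chosen.append(picked)
        chosen_pos.setdefault(picked.scaffold_id, []).append(picked.position)
        covered.add(picked.scaffold_id)
    if len(chosen) < spec.size:
        warnings.append(
            f"only {len(chosen)} of {spec.size} requested SNPs were eligible"
        )
    return chosen, warnings


CHIP2_CATEGORIES = (
    "new_scaffold",  # scaffold without any chip-1 SNP
    "chip1_monomorphic_scaffold",  # chip-1 SNPs all monomorphic in the cross
    "second_marker",  # second marker for single-cross-polymorphic scaffolds
    "large_scaffold_extra",  # extra markers for large, marker-poor scaffolds
)


def design_chip2(
    candidates: list[SnpCandidate],
    chip1: list[SnpCandidate],
    cross_polymorphic: set[str],
    scaffold_lengths: dict[str, int],
    spec: ChipSpec | None = None,
    quotas: dict[str, int] | None = None,
    large_scaffold_bp: int = 100_000,
    few_markers: int = 2,
) -> tuple[list[SnpCandidate], pd.DataFrame, list[str]]:
    """Gap-filling chip: anchor new scaffolds and enable orientation.

    Candidates already on chip 1 or monomorphic between the mapping-cross
    parents (ids not in ``cross_polymorphic``) are removed.  Remaining
    candidates are taken category by category (see ``CHIP2_CATEGORIES``),
    preferring within each scaffold the SNPs closest to its two ends;
    optional per-category ``quotas`` cap each category.  Returns
    (chosen, per-category report, warnings).
    """
    spec = spec or ChipSpec()
    chip1_ids = {c.id for c in chip1}
    chip1_by_scaffold: dict[str, list[SnpCandidate]] = {}
    for c in chip1:
        chip1_by_scaffold.setdefault(c.scaffold_id, []).append(c)

    eligible = [
        c
        for c in candidates
        if c.id not in chip1_ids
        and c.id in cross_polymorphic
        and c.id not in spec.exclusion
    ]
    by_scaffold: dict[str, list[SnpCandidate]] = {}
    for c in eligible:
        by_scaffold.setdefault(c.scaffold_id, []).append(c)

    def category_of_scaffold(sid: str) -> str | None:
        on1 = chip1_by_scaffold.get(sid, [])
        if not on1:
            return "new_scaffold"
        poly1 = [c for c in on1 if c.id in cross_polymorphic]
        if not poly1:
            return "chip1_monomorphic_scaffold"
        if len(poly1) == 1:
            return "second_marker"
        if (
            scaffold_lengths.get(sid, 0) > large_scaffold_bp
            and len(poly1) < few_markers
        ):
            return "large_scaffold_extra"
        return None

    def distal_order(sid: str, cands: list[SnpCandidate]) -> list[SnpCandidate]:
        length = scaffold_lengths.get(sid, max(c.position for c in cands))
        return sorted(cands, key=lambda c: (min(c.position - 1, length - c.position), c.id))

    chosen: list[SnpCandidate] = []
    chosen_pos: dict[str, list[int]] = {}
    counts = {cat: 0 for cat in CHIP2_CATEGORIES}
    scaffold_counts = {cat: set() for cat in CHIP2_CATEGORIES}

    for cat in CHIP2_CATEGORIES:
        if len(chosen) >= spec.size:
            break
        quota = None if quotas is None else quotas.get(cat)
        sids = sorted(s for s in by_scaffold if category_of_scaffold(s) == cat)
        # per scaffold take up to 2 distal SNPs for the anchoring categories,
        # 1 for the second-marker / extra categories
        per_scaffold = 2 if cat in ("new_scaffold", "chip1_monomorphic_scaffold") else 1
        for sid in sids:
            if len(chosen) >= spec.size or (quota is not None and counts[cat] >= quota):
                break
            existing = [c.position for c in chip1_by_scaffold.get(sid, []) if c.id in cross_polymorphic]
            chosen_pos.setdefault(sid, []).extend(
                p for p in existing if p not in chosen_pos.get(sid, [])
            )
            taken = 0
            for c in distal_order(sid, by_scaffold[sid]):
                if taken >= per_scaffold or len(chosen) >= spec.size:
                    break
                if quota is not None and counts[cat] >= quota:
                    break
                if not _spacing_ok(c, chosen_pos, spec.min_spacing_bp):
                    continue
                chosen.append(c)
                chosen_pos.setdefault(sid, []).append(c.position)
                counts[cat] += 1
                scaffold_counts[cat].add(sid)
                taken += 1

    report = pd.DataFrame(
        [(cat, counts[cat], len(scaffold_counts[cat])) for cat in CHIP2_CATEGORIES],
        columns=["category", "n_snps", "n_scaffolds"],
    )
    warnings = []
    if len(chosen) < spec.size:
        warnings.append(f"only {len(chosen)} of {spec.size} requested SNPs were eligible")
    return chosen, report, warnings


def write_manifest(chosen: list[SnpCandidate], path: str, reason: str = "") -> None:
    """Serialize a chip content list as a manifest TSV (id, scaffold,
    position, alleles, flanks, selection-reason code)."""
    pd.DataFrame(
        [
            (c.id, c.scaffold_id, c.position, c.ref_allele, c.alt_allele,
             c.flank_left, c.flank_right, reason)
            for c in chosen
        ],
        columns=["snp", "scaffold", "position", "ref", "alt",
                 "flank_left", "flank_right", "reason"],
    ).to_csv(path, sep="\t", index=False)


def recombination_windows(
    map_positions: pd.DataFrame, median_ratio: float | None = None
) -> pd.DataFrame:
    """Per-bin cM/Mb ratios from map bins projected to physical coordinates.

    ``map_positions`` needs columns group, bin, cM, bp (one row per marker).
    Windows are consecutive map bins within a group; the ratio is the cM
    span between adjacent bin midpoints divided by the bp span.
    """
    rows = []
    for group, sub in map_positions.groupby("group"):
        bins = (
            sub.groupby("bin")
            .agg(cM=("cM", "first"), bp=("bp", "median"))
            .sort_values("cM")
        )
        cm = bins["cM"].to_numpy()
        bp = bins["bp"].to_numpy(dtype=float)
        for i, b in enumerate(bins.index):
            lo, hi = max(0, i - 1), min(len(cm) - 1, i + 1)
            dbp = abs(bp[hi] - bp[lo])
            ratio = (cm[hi] - cm[lo]) / (dbp / 1e6) if dbp > 0 else np.inf
            rows.append((group, b, float(ratio)))
    out = pd.DataFrame(rows, columns=["group", "bin", "cm_per_mb"])
    finite = out.loc[np.isfinite(out["cm_per_mb"]), "cm_per_mb"]
    out.attrs["median_ratio"] = float(median_ratio if median_ratio is not None else finite.median())
    return out


def select_core_set(
    stats: pd.DataFrame,
    criteria: CoreSetCriteria | None = None,
    size: int = 6000,
    windows: pd.DataFrame | None = None,
) -> tuple[list[str], list[str]]:
    """Pick the core set from per-SNP panel statistics.

    ``stats`` is indexed by SNP id with columns ``maf``, ``missing``
    (missing + ambiguous fraction), ``n_classes`` (market classes in which
    polymorphic), ``scaffold_id`` and optionally ``bin``.  Hard filters are
    strict: MAF > maf_min and missing < max_missing.  Greedy preference:
    polymorphic in more than one class, then new scaffold, then new map
    bin, ties by MAF then id.  Bins lying in low-recombination windows
    (cM/Mb below ``low_recomb_ratio`` x genome median, from ``windows``)
    accept at most ``low_recomb_bin_cap`` SNPs.  Returns (ids, warnings).
    """
    criteria = criteria or CoreSetCriteria()
    passing = stats[(stats["maf"] > criteria.maf_min) & (stats["missing"] < criteria.max_missing)]
    warnings: list[str] = []
    low_bins: set = set()
    if windows is not None and len(windows):
        cutoff = criteria.low_recomb_ratio * windows.attrs["median_ratio"]
        low_bins = set(windows.loc[windows["cm_per_mb"] < cutoff, "bin"])

    covered_scaffolds: set[str] = set()
    covered_bins: set = set()
    bin_counts: dict = {}
    chosen: list[str] = []

    pool = passing.sort_index()
    has_bin = "bin" in pool.columns
    records = list(pool.itertuples())
    while len(chosen) < size and records:
        def key(rec):
            b = getattr(rec, "bin", None) if has_bin else None
            return (
                -(rec.n_classes > 1),
                rec.scaffold_id in covered_scaffolds,
                (b in covered_bins) if b is not None else False,
                -rec.maf,
                rec.Index,
            )

        records.sort(key=key)
        picked = None
        for i, rec in enumerate(records):
            b = getattr(rec, "bin", None) if has_bin else None
            if b is not None and b in low_bins and bin_counts.get(b, 0) >= criteria.low_recomb_bin_cap:
                continue
            picked = records.pop(i)
            break
        if picked is None:
            break
        chosen.append(picked.Index)
        covered_scaffolds.add(picked.scaffold_id)
        b = getattr(picked, "bin", None) if has_bin else None
        if b is not None:
            covered_bins.add(b)
            bin_counts[b] = bin_counts.get(b, 0) + 1
    if len(chosen) < size:
        warnings.append(f"only {len(chosen)} of {size} SNPs passed the filters")
    return chosen, warnings
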