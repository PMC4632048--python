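"""Genetic-map-driven scaffold anchoring, orientation, and AGP emission.

Markers are re-located in the scaffold set by exact search for
left_flank + allele + right_flank on both strands; scaffolds inherit the
linkage group of the strict majority of their located markers and the
median cM of those markers; orientation comes from the concordance of
marker bp with cM.  Placements serialize to AGP v2.1 and pseudomolecule
FASTA.  All user-facing coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._kmer import KmerIndex
from .types import GeneticMap, MarkerLocation, ScaffoldPlacement, SnpCandidate, revcomp

SEED_K = 25
FLANK_LEN = 60


# ---------------------------------------------------------------------------
# marker location
# ---------------------------------------------------------------------------

def locate_markers(
    markers: list[SnpCandidate],
    scaffolds: dict[str, str],
    index: KmerIndex | None = None,
) -> tuple[list[MarkerLocation], pd.DataFrame]:
    """Exactly locate each marker construct in the scaffold set.

    For each marker, the four patterns left+ref+right, left+alt+right and
    their reverse complements are searched; a marker is located only when
    the total hit count across patterns and strands is exactly 1.  Returns
    (locations, exclusion log).
    """
    for m in markers:
        if len(m.flank_left) != FLANK_LEN or len(m.flank_right) != FLANK_LEN:
            raise ValueError(f"{m.id}: flanks must be exactly {FLANK_LEN} nt")
    if index is None:
        index = KmerIndex(scaffolds, SEED_K)
    locations: list[MarkerLocation] = []
    log_rows = []
    for m in markers:
        hits: list[tuple[str, int, str]] = []  # (scaffold, 0-based construct start, strand)
        for allele in (m.ref_allele, m.alt_allele):
            construct = m.flank_left + allele + m.flank_right
            for strand, pattern in (("+", construct), ("-", revcomp(construct))):
                seed = pattern[:SEED_K]
                for sid, off in index.positions(seed):
                    seq = scaffolds[sid]
                    if seq[off : off + len(pattern)] == pattern:
                        hits.append((sid, off, strand))
        uniq = sorted(set(hits))
        if len(uniq) == 1:
            sid, off, strand = uniq[0]
            locations.append(
                MarkerLocation(
                    marker_id=m.id,
                    scaffold_id=sid,
                    position=off + FLANK_LEN + 1,  # variant site, symmetric on both strands
                    strand=strand,
                    n_hits=1,
                )
            )
        else:
            reason = "no_hit" if not uniq else "multi_hit"
            log_rows.append((m.id, reason, len(uniq)))
    log = pd.DataFrame(log_rows, columns=["marker", "reason", "n_hits"])
    return locations, log


# ---------------------------------------------------------------------------
# assignment and orientation
# ---------------------------------------------------------------------------

def assign_scaffolds(
    gmap: GeneticMap, locations: list[MarkerLocation]
) -> list[ScaffoldPlacement]:
    """Assign each located scaffold to the linkage group holding a strict
    majority of its mapped markers; anchor at the median cM of those markers.

    A scaffold with no strict majority is flagged as a conflict and left
    unplaced; scaffolds without located mapped markers simply do not appear
    (they are unanchored).
    """
    marker_pos = gmap.table.set_index("marker")[["group", "cM"]]
    by_scaffold: dict[str, list[MarkerLocation]] = {}
    for loc in locations:
        if loc.marker_id in marker_pos.index:
            by_scaffold.setdefault(loc.scaffold_id, []).append(loc)
    placements = []
    for sid in sorted(by_scaffold):
        locs = by_scaffold[sid]
        groups = pd.Series([marker_pos.at[l.marker_id, "group"] for l in locs])
        counts = groups.value_counts()
        if counts.iloc[0] * 2 > len(locs):
            win = counts.index[0]
            cms = [
                float(marker_pos.at[l.marker_id, "cM"])
                for l, g in zip(locs, groups)
                if g == win
            ]
            placements.append(
                ScaffoldPlacement(
                    scaffold_id=sid,
                    chromosome=str(win),
                    anchor_cM=float(np.median(cms)),
                    orientation="unoriented",
                    n_markers=len(locs),
                    n_distinct_cM=len(set(cms)),
                    conflict=False,
                )
            )
        else:
            placements.append(
                ScaffoldPlacement(
                    scaffold_id=sid,
                    chromosome=None,
                    anchor_cM=None,
                    orientation="unoriented",
                    n_markers=len(locs),
                    n_distinct_cM=0,
                    conflict=True,
                )
            )
    return placements


def orient_scaffolds(
    placements: list[ScaffoldPlacement],
    locations: list[MarkerLocation],
    gmap: GeneticMap,
) -> list[ScaffoldPlacement]:
    """Orient scaffolds by the sign of the Kendall concordance between
    marker bp positions and cM positions.

    Requires >= 2 markers at >= 2 distinct cM (observed recombination on
    the scaffold); scaffolds whose markers all cosegregate stay unoriented.
    """
    marker_pos = gmap.table.set_index("marker")[["group", "cM"]]
    by_scaffold: dict[str, list[MarkerLocation]] = {}
    for loc in locations:
        if loc.marker_id in marker_pos.index:
            by_scaffold.setdefault(loc.scaffold_id, []).append(loc)
    for p in placements:
        if p.conflict or p.chromosome is None:
            continue
        pts = [
            (l.position, float(marker_pos.at[l.marker_id, "cM"]))
            for l in by_scaffold.get(p.scaffold_id, [])
            if marker_pos.at[l.marker_id, "group"] == p.chromosome
        ]
        p.n_distinct_cM = len({cm for _, cm in pts})
        if len(pts) >= 2 and p.n_distinct_cM >= 2:
            bp, cm = zip(*pts)
            tau = stats.kendalltau(bp, cm).statistic
            if tau > 0:
                p.orientation = "+"
            elif tau < 0:
                p.orientation = "-"
            else:
                p.orientation = "unoriented"
    return placements


# ---------------------------------------------------------------------------
# AGP and pseudomolecules
# ---------------------------------------------------------------------------

@dataclass
class AgpRow:
    object_id: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # 'W' or 'N'
    # W: component_id, component_beg, component_end, orientation
    # N: gap_length, gap_type, linkage, linkage_evidence
    fields: tuple = field(default_factory=tuple)

    def to_line(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.object_id,
                self.object_beg,
                self.object_end,
                self.part_number,
                self.component_type,
                *self.fields,
            )
        )


def ordered_placements(
    placements: list[ScaffoldPlacement], scaffold_lengths: dict[str, int]
) -> dict[str, list[ScaffoldPlacement]]:
    """Anchored placements per chromosome, ordered by anchor cM; ties broken
    by longer scaffold first, then lexicographic id (deterministic but
    arbitrary for cosegregating scaffolds)."""
    per_chrom: dict[str, list[ScaffoldPlacement]] = {}
    for p in placements:
        if p.chromosome is not None and not p.conflict:
            per_chrom.setdefault(p.chromosome, []).append(p)
    for chrom in per_chrom:
        per_chrom[chrom].sort(
            key=lambda p: (p.anchor_cM, -scaffold_lengths[p.scaffold_id], p.scaffold_id)
        )
    return dict(sorted(per_chrom.items()))


def emit_agp(
    placements: list[ScaffoldPlacement],
    scaffold_lengths: dict[str, int],
    gap_bp: int = 100,
) -> list[AgpRow]:
    """Serialize anchored placements as AGP v2.1 rows.

    W (component) lines alternate with N gap lines (gap type 'scaffold',
    linkage 'yes', evidence 'map').  Unoriented scaffolds are written with
    orientation '?'.
    """
    rows: list[AgpRow] = []
    for chrom, plist in ordered_placements(placements, scaffold_lengths).items():
        pos = 1
        part = 1
        for i, p in enumerate(plist):
            if i > 0:
                rows.append(
                    AgpRow(chrom, pos, pos + gap_bp - 1, part, "N",
                           (gap_bp, "scaffold", "yes", "map"))
                )
                pos += gap_bp
                part += 1
            length = scaffold_lengths[p.scaffold_id]
            orient = p.orientation if p.orientation in ("+", "-") else "?"
            rows.append(
                AgpRow(chrom, pos, pos + length - 1, part, "W",
                       (p.scaffold_id, 1, length, orient))
            )
            pos += length
            part += 1
    _check_agp(rows)
    return rows


def _check_agp(rows: list[AgpRow]) -> None:
    last_end: dict[str, int] = {}
    seen: set[str] = set()
    for row in rows:
        prev = last_end.get(row.object_id, 0)
        if row.object_beg != prev + 1:
            raise AssertionError(f"AGP coordinate discontinuity at {row.to_line()}")
        if row.object_end < row.object_beg:
            raise AssertionError(f"AGP inverted interval at {row.to_line()}")
        last_end[row.object_id] = row.object_end
        if row.component_type == "W":
            cid = row.fields[0]
            if cid in seen:
                raise AssertionError(f"scaffold {cid} appears twice in AGP")
            seen.add(cid)


def write_agp(rows: list[AgpRow], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for row in rows:
            fh.write(row.to_line() + "\n")


def read_agp(path: str) -> list[AgpRow]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            obj, beg, end, part, ctype = parts[0], int(parts[1]), int(parts[2]), int(parts[3]), parts[4]
            if ctype == "N":
                fields = (int(parts[5]), parts[6], parts[7], parts[8])
            else:
                fields = (parts[5], int(parts[6]), int(parts[7]), parts[8])
            rows.append(AgpRow(obj, beg, end, part, ctype, fields))
    return rows


def emit_pseudomolecules(
    rows: list[AgpRow], scaffolds: dict[str, str]
) -> dict[str, str]:
    """Build chromosome sequences from AGP rows and scaffold sequences.

    Gaps become runs of N; '?' orientation is treated as '+'.
    """
    chroms: dict[str, list[str]] = {}
    for row in rows:
        parts = chroms.setdefault(row.object_id, [])
        if row.component_type == "N":
            parts.append("N" * int(row.fields[0]))
        else:
            cid, cbeg, cend, orient = row.fields
            seq = scaffolds[cid][int(cbeg) - 1 : int(cend)]
            parts.append(revcomp(seq) if orient == "-" else seq)
    out = {}
    for chrom, parts in chroms.items():
        seq = "".join(parts)
        expected = max(r.object_end for r in rows if r.object_id == chrom)
        if len(seq) != expected:
            raise AssertionError(f"{chrom}: pseudomolecule length mismatch")
        out[chrom] = seq
    return out


# ---------------------------------------------------------------------------
# stats
# ---------------------------------------------------------------------------

SIZE_CLASSES = ((1_000_000, None, ">1 Mb"), (50_000, 1_000_000, "50 kb-1 Mb"))


def anchoring_stats(
    placements: list[ScaffoldPlacement], scaffold_lengths: dict[str, int]
) -> pd.DataFrame:
    """Summary of anchoring: scaffold and bp counts by status, percent of
    total scaffold bp anchored, and oriented counts by size class."""
    status = {sid: "unanchored" for sid in scaffold_lengths}
    oriented = set()
    for p in placements:
        status[p.scaffold_id] = p.status
        if p.orientation in ("+", "-"):
            oriented.add(p.scaffold_id)
    total_bp = sum(scaffold_lengths.values())
    rows = []
    for st in ("anchored", "conflict", "unanchored"):
        sids = [s for s, v in status.items() if v == st]
        bp = sum(scaffold_lengths[s] for s in sids)
        rows.append((f"scaffolds_{st}", len(sids), bp, 100.0 * bp / total_bp if total_bp else 0.0))
    rows.append(("scaffolds_total", len(scaffold_lengths), total_bp, 100.0))
    for lo, hi, label in SIZE_CLASSES:
        in_class = [
            s for s, ln in scaffold_lengths.items() if ln > lo and (hi is None or ln <= hi)
        ]
        n_orient = sum(1 for s in in_class if s in oriented)
        rows.append((f"oriented_{label}", n_orient, len(in_class),
                     100.0 * n_orient / len(in_class) if in_class else 0.0))
    return pd.DataFrame(rows, columns=["statistic", "count", "of", "percent"])
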