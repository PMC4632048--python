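"""Core domain records shared across the pipeline.

Coordinate convention: every user-facing coordinate in this package is
1-based inclusive (VCF/AGP style); half-open arithmetic is confined to
function bodies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: integer genotype codes used throughout the F2 machinery
AA, AB, BB, MISSING = 0, 1, 2, -1

#: letter coding used in F2 TSV files
CALL_TO_LETTER = {AA: "A", AB: "H", BB: "B", MISSING: "U"}
LETTER_TO_CALL = {v: k for k, v in CALL_TO_LETTER.items()}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScaffoldRecord:
    """Ground-truth placement of one scaffold on its source chromosome."""

    scaffold_id: str
    chromosome_id: str
    start: int  # 1-based inclusive on the chromosome
    end: int
    orientation: str  # '+' or '-'

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TrueGenome:
    """A simulated scaffolded genome with known scaffold provenance.

    ``chromosomes`` maps chromosome id to its full sequence; ``scaffolds``
    records, for every scaffold, which chromosome slice it is and in which
    orientation.  Scaffold sequences are derived, never stored twice.
    """

    chromosomes: dict[str, str]
    scaffolds: list[ScaffoldRecord]

    def scaffold_sequence(self, scaffold_id: str) -> str:
        rec = self.scaffold_by_id(scaffold_id)
        chrom = self.chromosomes[rec.chromosome_id]
        seq = chrom[rec.start - 1 : rec.end]
        return revcomp(seq) if rec.orientation == "-" else seq

    def scaffold_by_id(self, scaffold_id: str) -> ScaffoldRecord:
        for rec in self.scaffolds:
            if rec.scaffold_id == scaffold_id:
                return rec
        raise KeyError(scaffold_id)

    def scaffold_sequences(self) -> dict[str, str]:
        return {r.scaffold_id: self.scaffold_sequence(r.scaffold_id) for r in self.scaffolds}

    def scaffold_lengths(self) -> dict[str, int]:
        return {r.scaffold_id: r.length for r in self.scaffolds}

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.scaffold_id, r.chromosome_id, r.start, r.end, r.orientation)
                for r in self.scaffolds
            ],
            columns=["scaffold_id", "chromosome_id", "start", "end", "orientation"],
        )


@dataclass
class SnpCandidate:
    """A biallelic SNP with its flanking sequence and panel statistics.

    The unit that flows through the Infinium design filters.  Flanks are the
    60 nt on each side of the variant site; they may contain N (or be short
    near scaffold ends) before filtering.
    """

    id: str
    scaffold_id: str
    position: int  # 1-based bp on the scaffold
    ref_allele: str
    alt_allele: str
    flank_left: str = ""
    flank_right: str = ""
    calls: dict[str, str] | None = None  # variety -> {ref, alt, het, missing}
    class_polymorphism: dict[str, bool] | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.id}: ref and alt alleles identical")

    @property
    def n_polymorphic_classes(self) -> int:
        if not self.class_polymorphism:
            return 0
        return sum(bool(v) for v in self.class_polymorphism.values())


@dataclass
class PanelVariants:
    """A diversity panel: variants plus a varieties x variants call matrix."""

    variants: list[SnpCandidate]
    genotypes: pd.DataFrame  # index: variety ids, columns: variant ids
    market_class: dict[str, str]  # variety -> market class
    gene_pool: dict[str, str] = field(default_factory=dict)  # class -> gene pool
    skip_log: list[tuple[str, str]] = field(default_factory=list)

    def variant_by_id(self, variant_id: str) -> SnpCandidate:
        for v in self.variants:
            if v.id == variant_id:
                return v
        raise KeyError(variant_id)


@dataclass
class F2Population:
    """An F2 mapping population with ground truth per marker.

    ``calls`` is plants x markers with integer codes (AA/AB/BB/MISSING);
    ``truth`` is indexed by marker id with columns ``chromosome``, ``cM``,
    ``scaffold_id`` and ``position``.
    """

    parent_a_id: str
    parent_b_id: str
    calls: pd.DataFrame
    truth: pd.DataFrame
    missing_rate: float
    error_rate: float
    seed: int

    @property
    def n_plants(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]


@dataclass(frozen=True)
class TwoPointEstimate:
    """Recombination fraction and LOD for one marker pair."""

    marker_a: str
    marker_b: str
    r_hat: float
    lod: float
    n_informative: int


@dataclass
class GeneticMap:
    """Ordered markers with Kosambi cM positions, grouped in linkage groups.

    ``table`` columns: group, order_index, marker, cM, bin.  Map function is
    always Kosambi.
    """

    table: pd.DataFrame
    map_function: str = "kosambi"

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def group_table(self, group: str) -> pd.DataFrame:
        return self.table[self.table["group"] == group].reset_index(drop=True)

    def summary(self) -> pd.DataFrame:
        """Per-group marker counts and map lengths, with a totals row."""
        rows = []
        for g in self.groups():
            sub = self.group_table(g)
            rows.append((g, len(sub), float(sub["cM"].max())))
        df = pd.DataFrame(rows, columns=["group", "n_markers", "length_cM"])
        total = pd.DataFrame(
            [("Total", int(df["n_markers"].sum()), float(df["length_cM"].sum()))],
            columns=df.columns,
        )
        return pd.concat([df, total], ignore_index=True)


@dataclass(frozen=True)
class MarkerLocation:
    """A marker's unique physical hit within a scaffold set."""

    marker_id: str
    scaffold_id: str
    position: int  # 1-based bp of the variant site on the scaffold
    strand: str  # '+' or '-'
    n_hits: int = 1


@dataclass
class ScaffoldPlacement:
    """Assignment of a scaffold to a chromosome position via its markers."""

    scaffold_id: str
    chromosome: str | None
    anchor_cM: float | None
    orientation: str  # '+', '-', or 'unoriented'
    n_markers: int
    n_distinct_cM: int
    conflict: bool = False

    @property
    def status(self) -> str:
        if self.conflict:
            return "conflict"
        return "anchored" if self.chromosome is not None else "unanchored"
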