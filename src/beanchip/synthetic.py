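"""Simulators for a scaffolded genome, a structured variety panel, and F2 crosses.

The stated world is a scaled-down common-bean-like genome: 11 chromosomes
split into a few hundred scaffolds, ~3 SNPs per kilobase, a diversity panel
organized in market classes, and a 267-plant F2 population from two inbred
parents.  Every simulator returns ground truth alongside the data so that
downstream stages (filtering, mapping, anchoring) can be scored against it.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    F2Population,
    PanelVariants,
    ScaffoldRecord,
    SnpCandidate,
    TrueGenome,
)

FLANK_LEN = 60

#: default scaffold-length model: lognormal, ~27 scaffolds per chromosome,
#: median ~15 kb -> chromosomes of roughly 0.5 Mb (a scaled-down stand-in
#: for the 10^4-scaffold, 487-Mb real assembly)
DEFAULT_LENGTH_MODEL = {"n_scaffolds": 27, "mean_log_bp": np.log(15_000.0), "sigma_log": 0.7}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def simulate_genome(
    n_chromosomes: int = 11,
    scaffold_length_model: dict | None = None,
    gap_length: int = 100,
    seed: int = 0,
) -> TrueGenome:
    """Simulate chromosomes tiled by scaffolds of known order and orientation.

    Each chromosome is a random ACGT sequence; scaffolds tile it left to
    right separated by ``gap_length`` bp of (sequence-filled) gap, with
    orientation drawn uniformly from {+,-}.  The scaffold *sequence* is the
    chromosome slice, reverse-complemented for '-' scaffolds, so assembly
    tools see scaffolds in arbitrary orientation, as in a real draft.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    if gap_length < 0:
        raise ValueError("gap_length must be >= 0")
    model = dict(DEFAULT_LENGTH_MODEL)
    if scaffold_length_model:
        model.update(scaffold_length_model)
    rng = np.random.default_rng(seed)

    chromosomes: dict[str, str] = {}
    scaffolds: list[ScaffoldRecord] = []
    for ci in range(1, n_chromosomes + 1):
        chrom_id = f"Chr{ci:02d}"
        n_scaf = int(model["n_scaffolds"])
        lengths = np.rint(
            rng.lognormal(model["mean_log_bp"], model["sigma_log"], size=n_scaf)
        ).astype(int)
        if (lengths <= 0).any():
            raise ValueError("scaffold length model produced non-positive lengths")
        total = int(lengths.sum()) + gap_length * (n_scaf - 1)
        seq = _random_sequence(rng, total)
        chromosomes[chrom_id] = seq
        pos = 1
        for si, length in enumerate(lengths, start=1):
            orientation = "+" if rng.random() < 0.5 else "-"
            scaffolds.append(
                ScaffoldRecord(
                    scaffold_id=f"scaffold_{ci:02d}_{si:03d}",
                    chromosome_id=chrom_id,
                    start=pos,
                    end=pos + int(length) - 1,
                    orientation=orientation,
                )
            )
            pos += int(length) + gap_length
    return TrueGenome(chromosomes=chromosomes, scaffolds=scaffolds)


def simulate_panel(
    genome: TrueGenome,
    n_classes: int = 9,
    varieties_per_class: int = 2,
    snp_density: float = 0.003,
    class_divergence: float = 0.3,
    missing_rate: float = 0.02,
    seed: int = 0,
) -> PanelVariants:
    """Simulate a variety panel with market-class structure over ``genome``.

    SNP sites arise as a Bernoulli(``snp_density``) process per scaffold bp
    (~3 SNPs/kb at the default).  With probability ``class_divergence`` a SNP
    is class-differentiated: each market class is near-fixed for one allele;
    otherwise every class shares a common allele frequency.  Varieties are
    inbred, so calls are homozygous apart from missing data.  SNPs whose
    60-nt flank would run past a scaffold end are skipped and logged; SNPs
    monomorphic in the realized panel are dropped (not polymorphic => not a
    discoverable SNP).
    """
    for name, val in [
        ("snp_density", snp_density),
        ("class_divergence", class_divergence),
        ("missing_rate", missing_rate),
    ]:
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if not genome.scaffolds:
        raise ValueError("genome has no scaffolds")
    rng = np.random.default_rng(seed)

    varieties = []
    market_class: dict[str, str] = {}
    classes = [f"class_{k + 1}" for k in range(n_classes)]
    for vi in range(n_classes * varieties_per_class):
        vid = f"var_{vi + 1:02d}"
        varieties.append(vid)
        market_class[vid] = classes[vi % n_classes]  # round-robin
    gene_pool = {
        c: ("Middle_American" if k < (n_classes + 1) // 2 else "Andean")
        for k, c in enumerate(classes)
    }

    variants: list[SnpCandidate] = []
    calls_rows: list[np.ndarray] = []
    skip_log: list[tuple[str, str]] = []
    counter = 0
    for rec in genome.scaffolds:
        seq = genome.scaffold_sequence(rec.scaffold_id)
        n_sites = rng.binomial(len(seq), snp_density)
        sites = np.sort(rng.choice(len(seq), size=n_sites, replace=False)) + 1
        for pos in sites:
            counter += 1
            snp_id = f"snp_{counter:06d}"
            if pos - FLANK_LEN < 1 or pos + FLANK_LEN > len(seq):
                skip_log.append((snp_id, "flank_out_of_scaffold"))
                continue
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            # per-class alt-allele frequencies
            if rng.random() < class_divergence:
                p_class = np.where(rng.random(n_classes) < 0.5, 0.05, 0.95)
            else:
                p_class = np.full(n_classes, rng.uniform(0.1, 0.9))
            cls_idx = np.array([classes.index(market_class[v]) for v in varieties])
            alleles = rng.random(len(varieties)) < p_class[cls_idx]
            if alleles.all() or (~alleles).all():
                skip_log.append((snp_id, "monomorphic_in_panel"))
                continue
            call_codes = np.where(alleles, 1, 0)  # 0=ref hom, 1=alt hom
            missing = rng.random(len(varieties)) < missing_rate
            call_codes = np.where(missing, -9, call_codes)
            variants.append(
                SnpCandidate(
                    id=snp_id,
                    scaffold_id=rec.scaffold_id,
                    position=int(pos),
                    ref_allele=ref,
                    alt_allele=str(alt),
                    flank_left=seq[pos - 1 - FLANK_LEN : pos - 1],
                    flank_right=seq[pos : pos + FLANK_LEN],
                )
            )
            calls_rows.append(call_codes)

    code_to_call = {0: "ref", 1: "alt", -9: "missing"}
    matrix = pd.DataFrame(
        [[code_to_call[c] for c in row] for row in np.array(calls_rows).T]
        if calls_rows
        else [],
        index=varieties if calls_rows else [],
        columns=[v.id for v in variants],
    )
    panel = PanelVariants(
        variants=variants,
        genotypes=matrix,
        market_class=market_class,
        gene_pool=gene_pool,
        skip_log=skip_log,
    )
    _annotate_panel_stats(panel)
    return panel


def _annotate_panel_stats(panel: PanelVariants) -> None:
    """Fill per-variant MAF and per-class polymorphism flags from the matrix."""
    if not panel.variants:
        return
    classes = sorted(set(panel.market_class.values()))
    varieties = list(panel.genotypes.index)
    vals = panel.genotypes.to_numpy()  # varieties x variants
    has_ref = np.isin(vals, ("ref", "het"))
    has_alt = np.isin(vals, ("alt", "het"))
    nonmiss = vals != "missing"
    n_alt = 2 * (vals == "alt").sum(axis=0) + (vals == "het").sum(axis=0)
    n_tot = 2 * nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_tot > 0, n_alt / np.maximum(n_tot, 1), 0.0)
    mafs = np.minimum(freq, 1.0 - freq)
    class_rows = {
        c: np.array([panel.market_class[v] == c for v in varieties]) for c in classes
    }
    poly = {
        c: has_ref[rows].any(axis=0) & has_alt[rows].any(axis=0)
        for c, rows in class_rows.items()
    }
    for j, var in enumerate(panel.variants):
        var.calls = {v: vals[i, j] for i, v in enumerate(varieties)}
        var.maf = float(mafs[j])
        var.class_polymorphism = {c: bool(poly[c][j]) for c in classes}


def true_map_from_genome(
    panel: PanelVariants, genome: TrueGenome, cm_per_chromosome: float = 94.7
) -> pd.DataFrame:
    """Project each variant to chromosome bp and assign a true cM position.

    The genetic map is linear in physical position, scaled so each
    chromosome spans ``cm_per_chromosome`` (default: the per-group mean of
    an 11-group, 1042-cM consensus bean map).
    """
    placements = {r.scaffold_id: r for r in genome.scaffolds}
    chrom_len = {cid: len(seq) for cid, seq in genome.chromosomes.items()}
    rows = []
    for var in panel.variants:
        rec = placements[var.scaffold_id]
        if rec.orientation == "+":
            bp = rec.start + var.position - 1
        else:
            bp = rec.end - var.position + 1
        cm = cm_per_chromosome * (bp - 1) / max(chrom_len[rec.chromosome_id] - 1, 1)
        rows.append((var.id, rec.chromosome_id, float(cm), var.scaffold_id, var.position))
    return pd.DataFrame(
        rows, columns=["marker", "chromosome", "cM", "scaffold_id", "position"]
    ).set_index("marker")


def simulate_f2(
    panel: PanelVariants,
    parent_a: str,
    parent_b: str,
    true_map: pd.DataFrame,
    n_plants: int = 267,
    missing_rate: float = 0.02,
    error_rate: float = 0.002,
    seed: int = 0,
) -> F2Population:
    """Simulate an F2 population from two inbred panel varieties.

    Only markers homozygous-polymorphic between the parents are retained.
    Each F2 plant is the union of two independent F1 gametes; each gamete is
    generated by a no-interference (Poisson) crossover process on the true
    genetic map: crossover count per chromosome ~ Poisson(map length in
    Morgans), crossover positions uniform in cM.  Symmetric genotyping
    errors and missing calls are then applied.
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    rng = np.random.default_rng(seed)

    geno = panel.genotypes
    keep = [
        v.id
        for v in panel.variants
        if v.id in true_map.index
        and {geno.at[parent_a, v.id], geno.at[parent_b, v.id]} == {"ref", "alt"}
    ]
    if not keep:
        raise ValueError(f"no markers polymorphic between {parent_a} and {parent_b}")
    truth = true_map.loc[keep].copy()
    truth = truth.sort_values(["chromosome", "cM", "scaffold_id", "position"])
    markers = list(truth.index)

    calls = np.empty((n_plants, len(markers)), dtype=np.int8)
    col = 0
    for chrom, sub in truth.groupby("chromosome", sort=True):
        cm = sub["cM"].to_numpy()
        length = float(cm[-1] - cm[0]) if len(cm) > 1 else 0.0
        rel = cm - cm[0]
        m = len(cm)
        gametes = np.empty((2, n_plants, m), dtype=np.int8)
        for g in range(2):
            for p in range(n_plants):
                gametes[g, p] = _gamete(rng, rel, length)
        calls[:, col : col + m] = gametes[0] + gametes[1]  # 0=AA,1=AB,2=BB
        col += m

    # symmetric call-swap errors: replace with one of the two other states
    err = rng.random(calls.shape) < error_rate
    if err.any():
        shift = rng.integers(1, 3, size=err.sum())
        calls[err] = (calls[err] + shift) % 3
    miss = rng.random(calls.shape) < missing_rate
    calls[miss] = MISSING

    frame = pd.DataFrame(
        calls, index=[f"plant_{i + 1:03d}" for i in range(n_plants)], columns=markers
    )
    return F2Population(
        parent_a_id=parent_a,
        parent_b_id=parent_b,
        calls=frame,
        truth=truth,
        missing_rate=missing_rate,
        error_rate=error_rate,
        seed=seed,
    )


def _gamete(rng: np.random.Generator, rel_cm: np.ndarray, length_cm: float) -> np.ndarray:
    """One F1 gamete: haplotype indicator (0=parent A, 1=parent B) per marker."""
    start = int(rng.integers(0, 2))
    if length_cm <= 0:
        return np.full(rel_cm.size, start, dtype=np.int8)
    n_xo = rng.poisson(length_cm / 100.0)
    if n_xo == 0:
        return np.full(rel_cm.size, start, dtype=np.int8)
    breaks = np.sort(rng.uniform(0.0, length_cm, size=n_xo))
    n_before = np.searchsorted(breaks, rel_cm, side="right")
    return ((start + n_before) % 2).astype(np.int8)
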