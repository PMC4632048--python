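"""Readers and writers for the pipeline's on-disk formats.

FASTA (scaffolds / pseudomolecules), VCF (panel variants with genotypes and
60-nt flanks in INFO), TSV (truth tables, F2 matrices in A/H/B/U coding,
genetic maps).  All coordinates on disk are 1-based inclusive.
"""

from __future__ import annotations

import pandas as pd
import pysam
from pyfaidx import Fasta

from .types import (
    CALL_TO_LETTER,
    LETTER_TO_CALL,
    GeneticMap,
    PanelVariants,
    SnpCandidate,
)

_WRAP = 70


def write_fasta(sequences: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), _WRAP):
                fh.write(seq[i : i + _WRAP] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    with Fasta(path, as_raw=True, rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_truth_table(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


_GT = {"ref": (0, 0), "alt": (1, 1), "het": (0, 1), "missing": (None, None)}
_GT_BACK = {(0, 0): "ref", (1, 1): "alt", (0, 1): "het", (1, 0): "het"}


def write_panel_vcf(panel: PanelVariants, path: str, contig_lengths: dict[str, int] | None = None) -> None:
    """Write panel variants + genotypes as VCF with FLANK_L/FLANK_R INFO."""
    header = pysam.VariantHeader()
    contigs = contig_lengths or {}
    seen = {v.scaffold_id for v in panel.variants}
    for sid in sorted(seen | set(contigs)):
        header.contigs.add(sid, length=contigs.get(sid))
    header.info.add("FLANK_L", 1, "String", "60-nt flank left of the variant")
    header.info.add("FLANK_R", 1, "String", "60-nt flank right of the variant")
    header.formats.add("GT", 1, "String", "Genotype")
    varieties = list(panel.genotypes.index)
    for v in varieties:
        header.add_sample(v)
    with pysam.VariantFile(path, "w", header=header) as out:
        for var in panel.variants:
            rec = out.new_record(
                contig=var.scaffold_id,
                start=var.position - 1,
                stop=var.position,
                alleles=(var.ref_allele, var.alt_allele),
                id=var.id,
            )
            rec.info["FLANK_L"] = var.flank_left or "."
            rec.info["FLANK_R"] = var.flank_right or "."
            for s in varieties:
                rec.samples[s]["GT"] = _GT[panel.genotypes.at[s, var.id]]
            out.write(rec)


def read_panel_vcf(path: str) -> tuple[list[SnpCandidate], pd.DataFrame]:
    """Read variants and a varieties x variants call matrix from VCF."""
    variants: list[SnpCandidate] = []
    columns: dict[str, list[str]] = {}
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            var = SnpCandidate(
                id=rec.id or f"{rec.contig}:{rec.pos}",
                scaffold_id=rec.contig,
                position=rec.pos,
                ref_allele=rec.ref,
                alt_allele=rec.alts[0],
                flank_left=str(rec.info.get("FLANK_L", "")).replace(".", ""),
                flank_right=str(rec.info.get("FLANK_R", "")).replace(".", ""),
            )
            calls = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                calls.append(_GT_BACK.get(gt, "missing") if gt and None not in gt else "missing")
            variants.append(var)
            columns[var.id] = calls
    matrix = pd.DataFrame(columns, index=samples)
    return variants, matrix


def write_f2_tsv(calls: pd.DataFrame, path: str) -> None:
    """F2 matrix TSV: rows = plants, columns = markers, calls A/H/B/U."""
    letters = calls.map(lambda c: CALL_TO_LETTER[int(c)])
    letters.to_csv(path, sep="\t", index_label="plant")


def read_f2_tsv(path: str) -> pd.DataFrame:
    letters = pd.read_csv(path, sep="\t", index_col="plant", dtype=str)
    return letters.map(lambda c: LETTER_TO_CALL[c]).astype("int8")


def write_map_tsv(gmap: GeneticMap, path: str) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_map_tsv(path: str) -> GeneticMap:
    return GeneticMap(table=pd.read_csv(path, sep="\t"))
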