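"""Summary arithmetic: validation rates, table totals, and MAF.

Every printed percentage in pipeline reports is recomputed from the
underlying integers through these functions (single source of truth);
rounding is half-up at the printed precision, matching how such summary
tables are conventionally typeset.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def validation_rate(n_validated: int, n_bead_types: int, decimals: int = 1) -> float:
    """Percent of manufactured bead types that validated, half-up rounded."""
    if n_bead_types <= 0:
        raise ValueError("n_bead_types must be positive")
    if not 0 <= n_validated <= n_bead_types:
        raise ValueError("n_validated must be within [0, n_bead_types]")
    return round_half_up(100.0 * n_validated / n_bead_types, decimals)


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """General percentage with half-up rounding at the printed precision."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


def table_totals(
    table: pd.DataFrame, total_label: str = "Total", label_column: str | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Recompute column totals of a summary table and check stored totals.

    ``table`` may or may not contain a totals row (identified by
    ``total_label`` in ``label_column`` or the index).  Returns
    (recomputed totals over non-total rows, per-cell verdict frame with
    columns stored/recomputed/consistent for every stored total).
    """
    if label_column is not None:
        is_total = table[label_column].astype(str) == total_label
        body = table.loc[~is_total]
        stored = table.loc[is_total]
    else:
        is_total = table.index.astype(str) == total_label
        body = table.loc[~is_total]
        stored = table.loc[is_total]
    numeric = body.select_dtypes("number")
    totals = numeric.sum()
    verdicts = []
    if len(stored):
        for col in numeric.columns:
            stored_val = float(stored.iloc[0][col])
            recomputed = float(totals[col])
            verdicts.append((col, stored_val, recomputed, bool(abs(stored_val - recomputed) < 0.05)))
    verdict = pd.DataFrame(verdicts, columns=["column", "stored", "recomputed", "consistent"])
    return totals, verdict


def maf(calls: list[str] | pd.Series) -> float:
    """Minor allele frequency over diploid panel calls.

    Calls are in {ref, alt, het, missing}; a het contributes one copy of
    each allele; missing calls are excluded from the denominator.
    """
    calls = pd.Series(list(calls))
    nonmiss = calls[calls != "missing"]
    if nonmiss.empty:
        raise ValueError("all calls missing")
    n_alt = 2 * (nonmiss == "alt").sum() + (nonmiss == "het").sum()
    freq = n_alt / (2 * len(nonmiss))
    return float(min(freq, 1.0 - freq))
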