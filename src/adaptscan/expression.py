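"""RPKM normalisation and cured-vs-infected fold changes for defense genes.

RPKM (reads per kilobase per million mapped reads) for a gene of length
``L`` bp with ``c`` mapped reads in a library of ``N`` mapped reads is

    RPKM = c / ((L / 1000) * (N / 1e6))

The fold increase in the virus-cured strain is ``RPKM_cured /
RPKM_infected``, rounded half-up to two decimals, matching the dominant
convention of published defense-gene tables.  What counts as "total mapped
reads" (reads on coding sequences vs. genome-wide) is supplied by the
caller as the library size, not guessed here.
"""
from __future__ import annotations

import math
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import pandas as pd

#: Reported RPKM levels of antiviral defense genes in a chronically infected
#: Haloferax strain (infected) and its virus-cured derivative (cured), with
#: the published fold increase.  Used as worked-example input; the fold
#: column is recomputable from the RPKM pairs for the rounding-consistent
#: rows (see ``CONSISTENT_ROUNDING_GENES``).
DEFENSE_GENE_RPKM = pd.DataFrame(
    [
        ("cas7", "CRISPR-associated protein Cas7", 205.31, 53.85, 3.81),
        ("cas5", "CRISPR-associated protein Cas5", 146.69, 25.36, 5.79),
        ("cas4", "CRISPR-associated protein Cas4", 95.30, 20.38, 4.68),
        ("cas2", "CRISPR-associated protein Cas2", 126.33, 7.35, 17.19),
        ("cbass1_cyclase", "CBASS_1 cyclase", 45.85, 5.53, 8.29),
        ("cbass1_effector", "CBASS_1 effector", 66.68, 23.89, 2.79),
        ("cbass2_cyclase", "CBASS_2 cyclase", 343.63, 23.56, 14.58),
        ("hachiman_a", "DUF1837 domain-containing protein / Hachiman A", 347.90, 13.25, 26.25),
        ("hachiman_b", "DEAD/DEAH box helicase / Hachiman B", 222.52, 30.53, 7.29),
    ],
    columns=["gene_id", "description", "rpkm_cured", "rpkm_infected", "reported_fold"],
)

#: Rows of :data:`DEFENSE_GENE_RPKM` whose printed fold value is reproduced
#: exactly by half-up rounding of the printed RPKM pair.  The remaining rows
#: (cas5, cbass2_cyclase, hachiman_a) differ in the last digit, consistent
#: with truncation or pre-rounding inputs; they are documented, not chased.
CONSISTENT_ROUNDING_GENES = (
    "cas7", "cas4", "cas2", "cbass1_cyclase", "cbass1_effector", "hachiman_b",
)


def rpkm(count: float, gene_length_bp: float, total_mapped: float) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if total_mapped <= 0:
        raise ValueError("library size must be positive")
    if count < 0:
        raise ValueError("counts cannot be negative")
    return count / ((gene_length_bp / 1_000.0) * (total_mapped / 1e6))


def fold_change(rpkm_cured: float, rpkm_infected: float) -> float | None:
    """Cured / infected RPKM ratio, rounded half-up to two decimals.

    Returns ``None`` (undefined) when the infected level is zero.
    """
    if rpkm_infected == 0:
        return None
    ratio = float(rpkm_cured) / float(rpkm_infected)
    return float(Decimal(repr(ratio)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def expression_table(
    counts: pd.DataFrame,
    library_sizes: Mapping[str, float],
    cured: str = "cured",
    infected: str = "infected",
) -> pd.DataFrame:
    """Compute per-condition RPKM and the cured fold increase from counts.

    ``counts`` needs columns ``gene_id``, ``length`` and ``count_<condition>``
    for every condition named in ``library_sizes``.
    """
    out = counts.copy()
    for condition, total in library_sizes.items():
        out[f"rpkm_{condition}"] = [
            rpkm(c, l, total) for c, l in zip(out[f"count_{condition}"], out["length"])
        ]
    if cured in library_sizes and infected in library_sizes:
        out["fold_increase_cured"] = [
            fold_change(c, i)
            for c, i in zip(out[f"rpkm_{cured}"], out[f"rpkm_{infected}"])
        ]
    return out


def defense_report(
    records: pd.DataFrame,
    gene_list: Sequence[str],
) -> pd.DataFrame:
    """Rows for the requested genes, in the supplied order, with fold changes.

    ``records`` needs ``gene_id``, ``rpkm_cured`` and ``rpkm_infected``
    columns.  Genes absent from ``records`` are emitted with missing-value
    markers rather than dropped.
    """
    indexed = records.set_index("gene_id")
    rows = []
    for gene in gene_list:
        if gene in indexed.index:
            rec = indexed.loc[gene]
            cured = float(rec["rpkm_cured"])
            infected = float(rec["rpkm_infected"])
            fold = fold_change(cured, infected)
            rows.append((gene, rec.get("description", ""), cured, infected,
                         math.nan if fold is None else fold))
        else:
            rows.append((gene, "", math.nan, math.nan, math.nan))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "description", "rpkm_cured", "rpkm_infected",
                 "fold_increase_cured"],
    )
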