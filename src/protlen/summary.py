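"""Descriptive length statistics, gene-based GC content and cross-species
correlations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LengthSummary",
    "PearsonResult",
    "length_summary",
    "gc_content",
    "cross_species_correlation",
    "compare_groups",
    "species_summary_table",
]

DEFAULT_PERCENTILES: tuple[int, ...] = (10, 25, 50, 75, 90)


@dataclass(frozen=True)
class LengthSummary:
    """Protein count, mean/SD and percentiles of length (all in aa).

    ``sd`` is the sample standard deviation (divisor n-1) and is ``None``
    for a single protein.  Percentiles use linear interpolation between
    order statistics at position h = (n-1) p + 1.
    """

    n: int
    mean: float
    sd: float | None
    percentiles: dict[int, float]


@dataclass(frozen=True)
class PearsonResult:
    r: float
    n: int
    p_value: float


def length_summary(lengths, percentiles: Sequence[int] = DEFAULT_PERCENTILES) -> LengthSummary:
    """Mean, sample SD and interpolated percentiles of a length sample."""
    z = np.asarray(lengths, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("length_summary requires at least one length")
    n = int(z.size)
    sd = float(z.std(ddof=1)) if n > 1 else None
    pcts = np.percentile(z, list(percentiles))  # linear interpolation, h=(n-1)p+1
    return LengthSummary(
        n=n,
        mean=float(z.mean()),
        sd=sd,
        percentiles={int(p): float(v) for p, v in zip(percentiles, pcts)},
    )


def gc_content(nucleotide_records: Iterable) -> float:
    """Pooled gene-based GC fraction over all CDS records of a species.

    Counts (G + C) / (A + C + G + T) over the concatenated coding sequence;
    ambiguous bases are excluded from numerator and denominator.
    """
    counts = {b: 0 for b in "ACGT"}
    for rec in nucleotide_records:
        seq = rec.sequence if hasattr(rec, "sequence") else str(rec)
        for base in "ACGT":
            counts[base] += seq.upper().count(base)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous A/C/G/T bases found")
    return (counts["G"] + counts["C"]) / total


def cross_species_correlation(
    table: pd.DataFrame,
    x_field: str,
    y_field: str,
    taxon: str | None = None,
    group_field: str = "taxon_group",
) -> PearsonResult:
    """Pearson correlation between two per-species quantities.

    ``taxon`` optionally subsets rows by ``group_field``.  The two-sided
    p-value comes from the t transform with n-2 degrees of freedom (the
    default of :func:`scipy.stats.pearsonr`).
    """
    df = table
    if taxon is not None:
        df = df[df[group_field] == taxon]
    df = df[[x_field, y_field]].dropna()
    n = len(df)
    if n < 3:
        raise ValueError(f"need >= 3 species, got {n}")
    x = df[x_field].to_numpy(dtype=float)
    y = df[y_field].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant field")
    res = stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), n=n, p_value=float(res.pvalue))


def compare_groups(values_a, values_b, test: str = "welch") -> tuple[float, float]:
    """Two-sample comparison of species-level values; (statistic, p-value).

    ``test`` is ``"welch"`` (unequal-variance t, the default) or
    ``"mannwhitney"``; both two-sided.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def species_summary_table(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Assemble the per-species summary table.

    Each row mapping provides species_code and optionally species_name,
    taxon_group, a :class:`LengthSummary` under ``summary``, and gc.
    """
    out = []
    for row in rows:
        s: LengthSummary = row["summary"]
        out.append(
            {
                "species_code": row["species_code"],
                "species_name": row.get("species_name", ""),
                "taxon_group": row.get("taxon_group", ""),
                "mean": s.mean,
                "sd": s.sd,
                **{f"p{p}": v for p, v in sorted(s.percentiles.items())},
                "n": s.n,
                "gc": row.get("gc"),
            }
        )
    return pd.DataFrame(out)
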