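"""Amino-acid composition and its correlation with protein length.

Per protein, the percentage of each of the 20 standard residues is computed
over standard residues only (ambiguous symbols such as X/B/Z/U/O are
tallied separately).  Per species, each residue's percentage is correlated
(Pearson) with raw protein length; species-level r values are then averaged
within taxon groups with a standard error across species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "STANDARD_AA",
    "CompositionVector",
    "BiasProfile",
    "composition_percent",
    "length_bias_correlations",
    "group_bias_summary",
    "bias_table",
]

STANDARD_AA: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
_AA_CODES = np.frombuffer("".join(STANDARD_AA).encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class CompositionVector:
    """Percentage composition of one protein over standard residues.

    ``percent`` is ``None`` when the protein has no standard residue
    (undefined composition).
    """

    percent: dict[str, float] | None
    n_standard: int
    n_ambiguous: int


def _aa_counts(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return np.bincount(arr, minlength=256)[_AA_CODES]


def composition_percent(sequence: str) -> CompositionVector:
    """Percentage of each standard amino acid in one sequence."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    counts = _aa_counts(sequence)
    n_std = int(counts.sum())
    n_amb = len(sequence) - n_std
    if n_std == 0:
        return CompositionVector(percent=None, n_standard=0, n_ambiguous=n_amb)
    pct = counts * (100.0 / n_std)
    return CompositionVector(
        percent={aa: float(p) for aa, p in zip(STANDARD_AA, pct)},
        n_standard=n_std,
        n_ambiguous=n_amb,
    )


@dataclass(frozen=True)
class BiasProfile:
    """Per-species Pearson r of each residue's percentage vs protein length.

    Residues whose percentage is constant across the proteome get ``nan``.
    """

    r_by_aa: dict[str, float]
    n: int


def length_bias_correlations(proteome, min_proteins: int = 3) -> BiasProfile:
    """Correlate each amino acid's percentage with raw protein length.

    ``proteome`` is a :class:`~protlen.io.Proteome` or an iterable of
    records.  Proteins with undefined composition are dropped.
    """
    records = getattr(proteome, "records", proteome)
    rows: list[np.ndarray] = []
    lengths: list[int] = []
    for rec in records:
        counts = _aa_counts(rec.sequence)
        n_std = counts.sum()
        if n_std == 0:
            continue
        rows.append(counts * (100.0 / n_std))
        lengths.append(rec.length)
    n = len(rows)
    if n < min_proteins:
        raise ValueError(f"need >= {min_proteins} proteins with defined composition, got {n}")
    z = np.asarray(lengths, dtype=float)
    if np.ptp(z) == 0:
        raise ValueError("protein lengths are constant; correlation undefined")
    pct = np.vstack(rows)
    zc = z - z.mean()
    pc = pct - pct.mean(axis=0)
    sz = np.sqrt(np.sum(zc**2))
    sp = np.sqrt(np.sum(pc**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc.T @ zc) / (sp * sz)
    r[sp == 0] = np.nan
    return BiasProfile(r_by_aa={aa: float(v) for aa, v in zip(STANDARD_AA, r)}, n=n)


def group_bias_summary(
    profiles: Mapping[str, BiasProfile],
    grouping: Mapping[str, str],
) -> pd.DataFrame:
    """Average species-level r within taxon groups.

    Returns a tidy frame with columns group, aa, mean_r, se_r, n_species;
    se_r is the sample SD across species divided by sqrt(n_species) and is
    ``nan`` for singleton groups.
    """
    if not profiles:
        raise ValueError("no bias profiles supplied")
    rows = []
    by_group: dict[str, list[str]] = {}
    for sp in profiles:
        by_group.setdefault(grouping.get(sp, "all"), []).append(sp)
    for group, species in sorted(by_group.items()):
        species = sorted(species)  # insertion-order independent output
        for aa in STANDARD_AA:
            vals = np.array(
                [profiles[sp].r_by_aa[aa] for sp in species], dtype=float
            )
            vals = vals[~np.isnan(vals)]
            k = vals.size
            if k == 0:
                mean_r, se_r = np.nan, np.nan
            else:
                mean_r = float(vals.mean())
                se_r = float(vals.std(ddof=1) / np.sqrt(k)) if k > 1 else np.nan
            rows.append(
                {"group": group, "aa": aa, "mean_r": mean_r, "se_r": se_r, "n_species": k}
            )
    return pd.DataFrame(rows)


def bias_table(profiles: Mapping[str, BiasProfile]) -> pd.DataFrame:
    """Species-by-residue table of r values (rows = species, 20 columns)."""
    return pd.DataFrame(
        {sp: prof.r_by_aa for sp, prof in profiles.items()}
    ).T.reindex(columns=list(STANDARD_AA))
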