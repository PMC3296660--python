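"""Random-ORF length theory under GC-biased base composition.

With independent, identically distributed bases at frequencies
A = T = (1 - g)/2 and G = C = g/2 for genomic GC fraction g, the per-codon
probability of a stop triplet (TAA, TAG or TGA) is

    p(g) = P(TAA) + P(TAG) + P(TGA) = a^3 + 2 a^2 (g/2),  a = (1 - g)/2,

which equals 3/64 at g = 1/2.  The number of codons scanned up to and
including the first stop is geometric with mean 1/p, so a random open
reading frame spans 1/p codons (~21 aa, i.e. 64 nucleotides, at uniform
composition; ~14 aa at 35% GC; ~31 aa at 60% GC).  Because stops are
AT-rich, the expectation increases with GC content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CodonModel",
    "stop_probability",
    "expected_orf_length",
    "simulate_random_orfs",
    "orf_expectation_table",
]

STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")


def stop_probability(gc: float) -> float:
    """Per-codon stop probability under i.i.d. bases at GC fraction ``gc``."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must lie in [0, 1], got {gc}")
    a = (1.0 - gc) / 2.0  # frequency of A (and of T)
    return a * a * (a + gc)  # a^3 + 2 a^2 (g/2)


@dataclass(frozen=True)
class CodonModel:
    """I.i.d.-base codon model at one GC fraction."""

    gc: float

    @property
    def base_freqs(self) -> dict[str, float]:
        at = (1.0 - self.gc) / 2.0
        gcf = self.gc / 2.0
        return {"A": at, "T": at, "G": gcf, "C": gcf}

    @property
    def p_stop(self) -> float:
        return stop_probability(self.gc)

    @property
    def expected_codons(self) -> float:
        p = self.p_stop
        if p == 0.0:
            raise ValueError("stop probability is zero; expected length is infinite")
        return 1.0 / p


def expected_orf_length(gc: float, unit: str = "aa", rounded: bool = True) -> float | int:
    """Expected random-ORF length at GC fraction ``gc``.

    The convention is codons scanned up to and including the first stop,
    i.e. 1/p_stop codons; ``unit`` is ``"aa"``/``"codons"`` (equivalent) or
    ``"nucleotides"`` (3x).  ``rounded`` returns the nearest integer.
    """
    codons = CodonModel(gc).expected_codons
    if unit in ("aa", "codons"):
        value = codons
    elif unit == "nucleotides":
        value = 3.0 * codons
    else:
        raise ValueError(f"unknown unit {unit!r}")
    return int(round(value)) if rounded else value


def simulate_random_orfs(gc: float, n: int, seed=None) -> np.ndarray:
    """Sample ``n`` random-ORF lengths in codons (geometric, mean 1/p_stop).

    ``seed`` is an integer seed or a :class:`numpy.random.Generator`; the
    same seed reproduces the sample exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = stop_probability(gc)
    if p == 0.0:
        raise ValueError("stop probability is zero; lengths are unbounded")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.geometric(p, size=n)


def orf_expectation_table(gcs) -> pd.DataFrame:
    """GC fraction -> stop probability and expected ORF length (aa and nt)."""
    rows = []
    for g in gcs:
        p = stop_probability(g)
        rows.append(
            {
                "gc": g,
                "p_stop": p,
                "expected_aa": expected_orf_length(g, "aa", rounded=False),
                "expected_nt": expected_orf_length(g, "nucleotides", rounded=False),
            }
        )
    return pd.DataFrame(rows)
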