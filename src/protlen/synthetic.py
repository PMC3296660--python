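"""Synthetic proteome generator with ground-truth bookkeeping.

Each simulated proteome draws integer protein lengths from one of the
candidate length laws, then draws residues position-by-position from a
baseline amino-acid frequency vector optionally tilted linearly in protein
length (the mechanism behind composition-vs-length correlations).  On top
of that background the generator can inject the artifacts the analysis is
meant to detect: exact-duplicate and subsequence-duplicate records, excess
records at one exact length (gene-family duplication peaks), a hard
minimum-length cutoff, and records tagged with a transposon keyword.
Every injection is recorded in a ledger so tests can check recovery against
known truth.  Generation is fully deterministic given the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .composition import STANDARD_AA
from .distributions import params_from_dict, params_to_dict
from .io import ProteinRecord, Proteome

__all__ = [
    "BASELINE_AA_FREQS",
    "SyntheticSpec",
    "simulate_lengths",
    "simulate_proteome",
]

#: Baseline residue frequencies, close to the averages seen across curated
#: protein databases; normalised to sum exactly to 1.
BASELINE_AA_FREQS: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}
_total = sum(BASELINE_AA_FREQS.values())
BASELINE_AA_FREQS = {aa: f / _total for aa, f in BASELINE_AA_FREQS.items()}

_AA_ARRAY = np.array(sorted(STANDARD_AA))

# minimum excised-substring length for injected subsequence duplicates:
# long enough that a random 20-letter string of this length essentially
# never recurs by chance in a desk-scale proteome
_MIN_SUB_LEN = 15


@dataclass(frozen=True)
class SyntheticSpec:
    """Complete recipe for one simulated proteome.

    ``aa_bias`` maps residues to the linear slope of their baseline
    frequency per aa of protein length (centred on the realised mean
    length); ``peaks`` lists (length, extra record count) injections;
    ``duplicates`` is (n_exact, n_subsequence).
    """

    species_code: str = "SYN_SP"
    taxon_group: str = "SYNTHETIC"
    model: str = "gamma_free"
    params_dict: Mapping[str, float] = field(
        default_factory=lambda: {"shape": 2.3, "rate": 0.005}
    )
    n: int = 10_000
    seed: int = 0
    min_length: int = 1
    baseline_freqs: Mapping[str, float] = field(default_factory=lambda: dict(BASELINE_AA_FREQS))
    aa_bias: Mapping[str, float] = field(default_factory=dict)
    peaks: tuple[tuple[int, int], ...] = ()
    duplicates: tuple[int, int] = (0, 0)
    transposon_fraction: float = 0.0
    transposon_keyword: str = "transposon"

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        total = sum(self.baseline_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("baseline frequencies must sum to 1")

    @property
    def params(self) -> object:
        return params_from_dict(self.model, self.params_dict)

    def to_json(self, path: str | Path) -> None:
        d = {
            "species_code": self.species_code,
            "taxon_group": self.taxon_group,
            "model": self.model,
            "params": dict(self.params_dict),
            "n": self.n,
            "seed": self.seed,
            "min_length": self.min_length,
            "baseline_freqs": dict(self.baseline_freqs),
            "aa_bias": dict(self.aa_bias),
            "peaks": [list(p) for p in self.peaks],
            "duplicates": list(self.duplicates),
            "transposon_fraction": self.transposon_fraction,
            "transposon_keyword": self.transposon_keyword,
        }
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        d = json.loads(Path(path).read_text())
        return cls(
            species_code=d["species_code"],
            taxon_group=d.get("taxon_group", "SYNTHETIC"),
            model=d["model"],
            params_dict=d["params"],
            n=d["n"],
            seed=d["seed"],
            min_length=d.get("min_length", 1),
            baseline_freqs=d.get("baseline_freqs", dict(BASELINE_AA_FREQS)),
            aa_bias=d.get("aa_bias", {}),
            peaks=tuple(tuple(p) for p in d.get("peaks", [])),
            duplicates=tuple(d.get("duplicates", (0, 0))),
            transposon_fraction=d.get("transposon_fraction", 0.0),
            transposon_keyword=d.get("transposon_keyword", "transposon"),
        )


def simulate_lengths(model: str, params: object, n: int, seed=None, min_length: int = 1) -> np.ndarray:
    """Draw ``n`` integer protein lengths from a continuous length law.

    Continuous draws are rounded to the nearest integer; draws below
    ``min_length`` are redrawn (annotation-cutoff emulation).  ``seed`` is
    an integer or a :class:`numpy.random.Generator`.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(n, dtype=np.int64)
    if n == 0:
        return out

    def draw(size: int) -> np.ndarray:
        if model in ("gamma_free", "gamma_fixed2"):
            return rng.gamma(params.shape, 1.0 / params.rate, size=size)
        if model == "lognormal":
            return rng.lognormal(params.meanlog, params.sdlog, size=size)
        if model == "sexp":
            return rng.exponential(1.0 / params.alpha, size=size) + rng.exponential(
                1.0 / params.beta, size=size
            )
        if model == "pareto":
            return params.zm * (1.0 + rng.pareto(params.shape, size=size))
        raise ValueError(f"unknown model {model!r}")

    pending = np.arange(n)
    for _ in range(1000):
        vals = np.rint(draw(pending.size)).astype(np.int64)
        ok = vals >= min_length
        out[pending[ok]] = vals[ok]
        pending = pending[~ok]
        if pending.size == 0:
            return out
    raise RuntimeError("min_length rejection sampling did not terminate")


def _protein_freqs(spec: SyntheticSpec, length: int, mean_length: float) -> np.ndarray:
    base = np.array([spec.baseline_freqs[aa] for aa in _AA_ARRAY])
    if spec.aa_bias:
        slope = np.array([spec.aa_bias.get(aa, 0.0) for aa in _AA_ARRAY])
        base = base + slope * (length - mean_length)
    if np.any(base < 0.0):
        raise ValueError(
            f"aa_bias produces a negative residue frequency at length {length}"
        )
    return base / base.sum()


def _random_sequence(rng: np.random.Generator, freqs: np.ndarray, length: int) -> str:
    return "".join(rng.choice(_AA_ARRAY, size=length, p=freqs))


def simulate_proteome(spec: SyntheticSpec) -> tuple[Proteome, dict]:
    """Generate a proteome per ``spec``; returns it with its truth ledger.

    The ledger records every injected artifact (peak positions and counts,
    duplicate record ids, transposon-tagged ids) plus the background model,
    for oracle-based testing of the analysis stages.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = simulate_lengths(spec.model, spec.params, spec.n, rng, spec.min_length)
    mean_len = float(lengths.mean()) if spec.n > 0 else 0.0

    records: list[ProteinRecord] = []
    for i, L in enumerate(lengths):
        freqs = _protein_freqs(spec, int(L), mean_len)
        seq = _random_sequence(rng, freqs, int(L))
        records.append(
            ProteinRecord(
                id=f"{spec.species_code}|{i:06d}",
                sequence=seq,
                description="synthetic protein",
            )
        )

    # transposon tagging of background records
    n_transposon = int(round(spec.transposon_fraction * spec.n))
    transposon_ids: list[str] = []
    if n_transposon > 0:
        tagged = rng.choice(spec.n, size=n_transposon, replace=False)
        for idx in sorted(tagged):
            rec = records[idx]
            records[idx] = ProteinRecord(
                id=rec.id,
                sequence=rec.sequence,
                description=f"putative {spec.transposon_keyword} protein",
            )
            transposon_ids.append(rec.id)

    # gene-family duplication peaks: extra records at one exact length
    peak_ledger = []
    counter = len(records)
    for position, extra in spec.peaks:
        freqs = _protein_freqs(spec, position, mean_len)
        for _ in range(extra):
            records.append(
                ProteinRecord(
                    id=f"{spec.species_code}|{counter:06d}",
                    sequence=_random_sequence(rng, freqs, position),
                    description="synthetic protein (family expansion)",
                )
            )
            counter += 1
        peak_ledger.append({"position": int(position), "count": int(extra)})

    # redundancy injections, drawn from the records generated so far
    n_exact, n_sub = spec.duplicates
    duplicate_ids: list[str] = []
    pool = len(records)
    if (n_exact or n_sub) and pool == 0:
        raise ValueError("cannot inject duplicates into an empty proteome")
    for _ in range(n_exact):
        src = records[int(rng.integers(pool))]
        rec = ProteinRecord(
            id=f"{spec.species_code}|{counter:06d}",
            sequence=src.sequence,
            description=f"synthetic exact duplicate of {src.id}",
        )
        records.append(rec)
        duplicate_ids.append(rec.id)
        counter += 1
    eligible = [r for r in records[:pool] if r.length > _MIN_SUB_LEN]
    if n_sub and not eligible:
        raise ValueError(
            f"subsequence duplicates need source proteins longer than {_MIN_SUB_LEN} aa"
        )
    for _ in range(n_sub):
        src = eligible[int(rng.integers(len(eligible)))]
        sub_len = int(rng.integers(_MIN_SUB_LEN, src.length))
        start = int(rng.integers(0, src.length - sub_len + 1))
        rec = ProteinRecord(
            id=f"{spec.species_code}|{counter:06d}",
            sequence=src.sequence[start:start + sub_len],
            description=f"synthetic subsequence duplicate of {src.id}",
        )
        records.append(rec)
        duplicate_ids.append(rec.id)
        counter += 1

    proteome = Proteome(
        species_code=spec.species_code,
        records=records,
        taxon_group=spec.taxon_group,
        source=f"synthetic:{spec.model}:seed={spec.seed}",
    )
    ledger = {
        "species_code": spec.species_code,
        "model": spec.model,
        "params": params_to_dict(spec.model, spec.params),
        "seed": int(spec.seed),
        "n_background": int(spec.n),
        "min_length": int(spec.min_length),
        "background_mean_length": mean_len,
        "aa_bias": dict(spec.aa_bias),
        "peaks": peak_ledger,
        "n_exact_duplicates": int(n_exact),
        "n_subsequence_duplicates": int(n_sub),
        "duplicate_ids": duplicate_ids,
        "transposon_ids": transposon_ids,
        "n_total": len(records),
    }
    return proteome, ledger
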