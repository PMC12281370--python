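"""TCR-beta clonotype-table statistics.

A repertoire is a table of clonotypes — identity key (CDR3 amino-acid
sequence, V gene) with a read/cell count — and the derived frequency vector
F summing to 1.  Implemented statistics:

* richness: number of unique clonotypes
* Shannon entropy: ``-sum F_i * log2(F_i)`` (bits)
* clonality: ``1 - H / log(n)`` (one minus the Pielou evenness;
  base-invariant), defined as 1 for a monoclonal repertoire
* D50: minimal number of top clonotypes whose cumulative frequency
  reaches 50%
* clone-size (homeostasis) bins: small / medium / large / hyperexpanded by
  per-clonotype frequency
* pairwise overlap: shared clonotype keys (plus Jaccard)
* top-clonotype tracking across samples

Input is an AIRR-rearrangement-style TSV (junction_aa, v_call,
duplicate_count) or a simple 3-column CSV; read processing and V(D)J
alignment are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Clonotype",
    "Repertoire",
    "richness",
    "shannon_entropy",
    "clonality",
    "d50",
    "clone_size_bins",
    "overlap",
    "track_top",
    "read_airr",
    "write_airr",
    "DEFAULT_BIN_EDGES",
]

#: homeostasis bin upper edges on the frequency scale; a clonotype with
#: frequency f falls in the first bin whose edge satisfies f <= edge
DEFAULT_BIN_EDGES: tuple[tuple[str, float], ...] = (
    ("small", 1e-4),
    ("medium", 1e-3),
    ("large", 1e-2),
    ("hyperexpanded", 1.0),
)


@dataclass(frozen=True)
class Clonotype:
    cdr3_aa: str
    v_gene: str
    count: int

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        if self.count < 1:
            raise ValueError("count must be >= 1")

    @property
    def key(self) -> tuple[str, str]:
        return (self.cdr3_aa, self.v_gene)


class Repertoire:
    """Deduplicated clonotype table with derived frequencies.

    Rows sharing an identity key are merged (counts summed) preserving first
    appearance order, so downstream tie-breaks are deterministic.
    """

    def __init__(self, clonotypes: Sequence[Clonotype], sample_id: str = ""):
        if not clonotypes:
            raise ValueError("a repertoire must contain at least one clonotype")
        merged: dict[tuple[str, str], int] = {}
        for c in clonotypes:
            merged[c.key] = merged.get(c.key, 0) + c.count
        self.sample_id = sample_id
        self.clonotypes: tuple[Clonotype, ...] = tuple(
            Clonotype(k[0], k[1], n) for k, n in merged.items()
        )
        total = sum(merged.values())
        self.frequencies = np.array([c.count / total for c in self.clonotypes])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sample_id: str = "") -> "Repertoire":
        cols = _resolve_columns(frame)
        clonotypes = [
            Clonotype(str(r[cols[0]]), str(r[cols[1]]), int(r[cols[2]]))
            for _, r in frame.iterrows()
        ]
        return cls(clonotypes, sample_id=sample_id)

    @property
    def n(self) -> int:
        return len(self.clonotypes)

    def keys(self) -> set[tuple[str, str]]:
        return {c.key for c in self.clonotypes}

    def frequency_of(self, key: tuple[str, str]) -> float:
        for c, f in zip(self.clonotypes, self.frequencies):
            if c.key == key:
                return float(f)
        return 0.0


def _resolve_columns(frame: pd.DataFrame) -> tuple[str, str, str]:
    airr = ("junction_aa", "v_call", "duplicate_count")
    simple = ("cdr3_aa", "v_gene", "count")
    for cols in (airr, simple):
        if set(cols) <= set(frame.columns):
            return cols
    raise ValueError(
        "clonotype table needs columns junction_aa/v_call/duplicate_count "
        "or cdr3_aa/v_gene/count"
    )


def richness(rep: Repertoire) -> int:
    """Number of unique (CDR3 aa, V gene) clonotypes."""
    return rep.n


def shannon_entropy(rep: Repertoire) -> float:
    """Shannon entropy of the frequency vector in bits; 0*log(0) := 0."""
    f = rep.frequencies
    if not math.isclose(float(f.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("frequencies must sum to 1")
    nz = f[f > 0]
    return float(-(nz * np.log2(nz)).sum())


def clonality(rep: Repertoire) -> float:
    """One minus the Pielou evenness, in [0, 1].

    ``1 - H / log(n)`` with entropy and normaliser in the same base (the
    value is base-invariant); a monoclonal repertoire (n = 1, Pielou
    undefined) is maximally clonal and returns 1.
    """
    if rep.n == 1:
        return 1.0
    value = 1.0 - shannon_entropy(rep) / math.log2(rep.n)
    return min(1.0, max(0.0, value))


def d50(rep: Repertoire) -> int:
    """Minimal number of top clonotypes whose cumulative frequency >= 0.5.

    Frequency ties are broken by stable input order.
    """
    order = np.argsort(-rep.frequencies, kind="stable")
    cum = np.cumsum(rep.frequencies[order])
    return int(np.searchsorted(cum, 0.5 - 1e-12) + 1)


def clone_size_bins(
    rep: Repertoire, edges: tuple[tuple[str, float], ...] = DEFAULT_BIN_EDGES
) -> dict[str, float]:
    """Total frequency mass per homeostasis bin; masses sum to 1."""
    masses = {name: 0.0 for name, _ in edges}
    for f in rep.frequencies:
        for name, hi in edges:
            if f <= hi:
                masses[name] += float(f)
                break
    return masses


def overlap(rep_a: Repertoire, rep_b: Repertoire) -> tuple[int, float]:
    """Shared clonotype keys between two repertoires, plus Jaccard index."""
    a, b = rep_a.keys(), rep_b.keys()
    shared = len(a & b)
    union = len(a | b)
    return shared, shared / union if union else 0.0


def track_top(
    reference: Repertoire, samples: Sequence[Repertoire], k: int = 10
) -> pd.DataFrame:
    """Frequencies of the reference's top-k clonotypes in each sample.

    Rows are the reference's k most frequent clonotypes (stable ties);
    columns are the samples (reference first); a clonotype absent from a
    sample reads 0.
    """
    if k > reference.n:
        raise ValueError(f"k={k} exceeds reference richness {reference.n}")
    order = np.argsort(-reference.frequencies, kind="stable")[:k]
    top = [reference.clonotypes[i] for i in order]
    index = pd.MultiIndex.from_tuples([c.key for c in top], names=["cdr3_aa", "v_gene"])
    data = {}
    labels = []
    for j, rep in enumerate([reference, *samples]):
        label = rep.sample_id or ("reference" if j == 0 else f"sample_{j}")
        labels.append(label)
        data[label] = [rep.frequency_of(c.key) for c in top]
    return pd.DataFrame(data, index=index, columns=labels)


def metrics(rep: Repertoire) -> dict[str, float]:
    """All scalar diversity metrics of one repertoire."""
    out: dict[str, float] = {
        "richness": float(richness(rep)),
        "shannon_entropy_bits": shannon_entropy(rep),
        "clonality": clonality(rep),
        "d50": float(d50(rep)),
    }
    out.update({f"mass_{k}": v for k, v in clone_size_bins(rep).items()})
    return out


# ---------------------------------------------------------------------------
# I/O

def read_airr(path, sample_id: str = "") -> Repertoire:
    """Read an AIRR-style TSV or a simple CSV clonotype table."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep)
    return Repertoire.from_frame(frame, sample_id=sample_id or str(path))


def write_airr(rep: Repertoire, path) -> None:
    """Write a repertoire as AIRR-style TSV (or CSV by file extension)."""
    frame = pd.DataFrame(
        {
            "junction_aa": [c.cdr3_aa for c in rep.clonotypes],
            "v_call": [c.v_gene for c in rep.clonotypes],
            "duplicate_count": [c.count for c in rep.clonotypes],
        }
    )
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame.to_csv(path, sep=sep, index=False)
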