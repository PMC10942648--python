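"""Core containers for mSTARR-seq analyses.

All genomic coordinates are 0-based, half-open (BED convention), end-to-end.
Windows carry an opaque id of the form ``chrom:start-end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class Molecule(str, Enum):
    DNA = "DNA"
    RNA = "RNA"


class Methylation(str, Enum):
    unmethylated = "unmethylated"
    methylated = "methylated"


TREATMENTS = ("baseline", "IFNA", "dex")


@dataclass(frozen=True)
class GenomicWindow:
    """A fixed-width genomic tile; ``partial`` marks a short terminal window."""

    chrom: str
    start: int
    end: int
    partial: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid window {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def window_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def width(self) -> int:
        return self.end - self.start

    @classmethod
    def from_id(cls, window_id: str, partial: bool = False) -> "GenomicWindow":
        chrom, span = window_id.rsplit(":", 1)
        start, end = span.split("-")
        return cls(chrom, int(start), int(end), partial)


@dataclass
class SampleMeta:
    """Per-library metadata.

    ``pair_id`` links the DNA and RNA library from one transfection replicate;
    the pair shares methylation condition and treatment.
    """

    sample_id: str
    molecule: str
    methylation: str
    treatment: str
    pair_id: str
    library_size: int = 0

    def __post_init__(self) -> None:
        self.molecule = Molecule(self.molecule).value
        self.methylation = Methylation(self.methylation).value
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.library_size < 0:
            raise ValueError("library_size must be positive")


def meta_frame(samples: Sequence[SampleMeta]) -> pd.DataFrame:
    """Tabulate sample metadata (one row per sample, indexed by sample_id)."""
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "molecule": [s.molecule for s in samples],
            "methylation": [s.methylation for s in samples],
            "treatment": [s.treatment for s in samples],
            "pair_id": [s.pair_id for s in samples],
            "library_size": [s.library_size for s in samples],
        }
    )
    return df.set_index("sample_id", drop=False)


def validate_pairing(samples: Sequence[SampleMeta]) -> None:
    """Each pair_id must hold exactly one DNA and one RNA sample with
    identical methylation condition and treatment."""
    by_pair: dict[str, list[SampleMeta]] = {}
    for s in samples:
        by_pair.setdefault(s.pair_id, []).append(s)
    for pid, members in by_pair.items():
        mols = sorted(m.molecule for m in members)
        if mols != ["DNA", "RNA"]:
            raise ValueError(f"pair {pid!r} does not hold one DNA and one RNA sample")
        a, b = members
        if a.methylation != b.methylation or a.treatment != b.treatment:
            raise ValueError(f"pair {pid!r} mixes methylation/treatment labels")


@dataclass
class CountMatrix:
    """Window x sample integer fragment counts with sample metadata."""

    windows: list[GenomicWindow]
    samples: list[SampleMeta]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.windows), len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.windows)} windows x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        ids = [w.window_id for w in self.windows]
        if len(set(ids)) != len(ids):
            raise ValueError("window ids not unique")

    @property
    def window_ids(self) -> list[str]:
        return [w.window_id for w in self.windows]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def library_sizes(self) -> np.ndarray:
        """Per-sample library sizes; falls back to column sums when absent."""
        sizes = np.array([s.library_size for s in self.samples], dtype=float)
        missing = sizes <= 0
        if missing.any():
            sizes[missing] = self.counts.sum(axis=0)[missing]
        return sizes

    def subset_samples(self, keep: Iterable[str] | np.ndarray) -> "CountMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            wanted = set(keep)
            idx = np.array(
                [i for i, s in enumerate(self.samples) if s.sample_id in wanted],
                dtype=int,
            )
        return CountMatrix(
            self.windows,
            [self.samples[i] for i in idx],
            self.counts[:, idx],
        )

    def subset_windows(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            [self.windows[i] for i in idx], self.samples, self.counts[idx, :]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.window_ids, columns=self.sample_ids
        )


@dataclass
class AnnotationSet:
    """A named collection of genomic intervals or CpG point positions.

    ``records`` is a DataFrame: intervals carry chrom/start/end(/label),
    points carry chrom/pos. Sorted within chromosome.
    """

    name: str
    kind: str  # "intervals" | "points"
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("intervals", "points"):
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        cols = ["chrom", "start", "end"] if self.kind == "intervals" else ["chrom", "pos"]
        for c in cols:
            if c not in self.records.columns:
                raise ValueError(f"annotation set missing column {c!r}")
        by = ["chrom", "start"] if self.kind == "intervals" else ["chrom", "pos"]
        self.records = self.records.sort_values(by).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)
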