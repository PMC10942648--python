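"""Readers and writers for the plain-text formats the pipeline consumes.

BED3/BED4 for intervals and tracks, two-column chrom/pos files for CpG
points, TSV for count tables, metadata and results.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import AnnotationSet, CountMatrix, GenomicWindow, SampleMeta, validate_pairing

log = logging.getLogger("mstarr")

_META_COLS = ("sample_id", "molecule", "methylation", "treatment", "pair_id")


class ParseError(ValueError):
    pass


def _is_header(line: str) -> bool:
    s = line.strip()
    return (not s) or s.startswith(("#", "track", "browser"))


def read_intervals(path: str | Path, kind: str = "intervals") -> AnnotationSet:
    """Parse a BED3+ interval file or a two-column chrom/pos point file.

    Track/browser/comment header lines are skipped. Raises ParseError with
    the offending line number on malformed input.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_header(line):
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                if kind == "intervals":
                    if len(parts) < 3:
                        raise ValueError("fewer than 3 columns")
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    if end <= start or start < 0:
                        raise ValueError(f"invalid interval [{start},{end})")
                    rec = {"chrom": chrom, "start": start, "end": end}
                    if len(parts) > 3:
                        rec["label"] = parts[3]
                    rows.append(rec)
                elif kind == "points":
                    if len(parts) < 2:
                        raise ValueError("fewer than 2 columns")
                    pos = int(parts[1])
                    if pos < 0:
                        raise ValueError("negative position")
                    rows.append({"chrom": parts[0], "pos": pos})
                else:
                    raise ParseError(f"unknown kind {kind!r}")
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    cols = ["chrom", "start", "end"] if kind == "intervals" else ["chrom", "pos"]
    df = pd.DataFrame(rows) if rows else pd.DataFrame(columns=cols)
    return AnnotationSet(name=path.stem, kind=kind, records=df)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_header(line):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected chrom and length")
            sizes[parts[0]] = int(parts[1])
    return sizes


def read_count_table(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Load a window x sample TSV plus a sample-metadata TSV.

    The first column of the count table is the window id. Samples are
    matched to metadata rows by sample_id; library_size defaults to the
    column sum when the metadata lacks that column.
    """
    tab = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"pair_id": str})
    for c in _META_COLS:
        if c not in meta.columns:
            raise ParseError(f"metadata missing required column {c!r}")
    meta = meta.set_index("sample_id", drop=False)

    missing = [s for s in tab.columns if s not in meta.index]
    if missing:
        raise ParseError(f"samples missing from metadata: {', '.join(missing)}")
    if (tab.values < 0).any():
        raise ParseError("negative count in count table")

    col_sums = tab.sum(axis=0)
    samples = []
    for sid in tab.columns:
        row = meta.loc[sid]
        lib = int(row["library_size"]) if "library_size" in meta.columns else int(col_sums[sid])
        samples.append(
            SampleMeta(
                sample_id=sid,
                molecule=row["molecule"],
                methylation=row["methylation"],
                treatment=row["treatment"],
                pair_id=str(row["pair_id"]),
                library_size=lib,
            )
        )
    validate_pairing(samples)
    windows = [GenomicWindow.from_id(w) for w in tab.index]
    return CountMatrix(windows=windows, samples=samples, counts=tab.values.astype(np.int64))


def write_count_table(cm: CountMatrix, path: str | Path, meta_path: str | Path) -> None:
    cm.to_frame().rename_axis("window_id").to_csv(path, sep="\t")
    rows = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "molecule": s.molecule,
                "methylation": s.methylation,
                "treatment": s.treatment,
                "pair_id": s.pair_id,
                "library_size": s.library_size,
            }
            for s in cm.samples
        ]
    )
    rows.to_csv(meta_path, sep="\t", index=False)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a tabular result set as TSV; round-trip stable via read_results."""
    if len(results) == 0:
        log.warning("writing empty result set to %s", path)
    results.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_track(windows, flags, path: str | Path, name: str = "mstarr") -> None:
    """Write a BED4 track; the name column encodes the classification flag.

    ``windows`` is a sequence of GenomicWindow, ``flags`` a matching sequence
    of strings (e.g. "regulatory", "MD"). Only flagged (truthy) windows are
    emitted.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write(f'track name="{name}"\n')
        for w, f in zip(windows, flags):
            if f:
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{f}\n")
                n += 1
    if n == 0:
        log.warning("track %s contains no records", path)


def write_annotation(ann: AnnotationSet, path: str | Path) -> None:
    if ann.kind == "intervals":
        cols = ["chrom", "start", "end"] + (["label"] if "label" in ann.records else [])
        ann.records[cols].to_csv(path, sep="\t", index=False, header=False)
    else:
        ann.records[["chrom", "pos"]].to_csv(path, sep="\t", index=False, header=False)
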