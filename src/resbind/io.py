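"""Sequence/label/prediction file IO, dataset splitting and run configuration.

File formats are deliberately plain: FASTA for sequences, headerless
three-column TSV for labels, five-column TSV (with header) for
predictions, and a flat YAML mapping for configuration.  Positions are
1-based on disk and converted at this boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import DatasetSplit, LabelTrack, PredictionRow, PredictionTable, ProteinRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "read_predictions",
    "write_predictions",
    "load_config",
    "save_config",
    "split_dataset",
    "kfold_indices",
    "setup_logging",
]

log = logging.getLogger("resbind")


def setup_logging(path: str | Path | None = None, seed: int | None = None, level=logging.INFO):
    """Configure the package logger; echoes the seed so runs are traceable."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if path is not None:
        handlers.append(logging.FileHandler(path))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    log.setLevel(level)
    log.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        log.addHandler(h)
    if seed is not None:
        log.info("seed=%d", seed)
    return log


class ParseError(ValueError):
    """Raised for malformed input files; message carries the line number."""


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into protein records.

    The parser is intentionally strict: duplicate ids, headerless
    sequence lines and empty records are rejected with the offending
    line number (errors the usual lenient readers silently absorb).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush():
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{header_line}: record {current_id!r} has no sequence")
        if seq != seq.upper():
            log.warning("sequence of %s contained lowercase letters; uppercased", current_id)
        records.append(ProteinRecord(current_id, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                if name in seen:
                    raise ParseError(f"{path}:{lineno}: duplicate protein id {name!r}")
                seen.add(name)
                current_id, chunks, header_line = name, [], lineno
            else:
                if current_id is None:
                    raise ParseError(f"{path}:{lineno}: sequence data before any header")
                chunks.append(line)
    flush()
    return records


def write_fasta(records, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_labels(path: str | Path, proteins) -> dict:
    """Read a (protein_id, 1-based position, label) TSV into label tracks.

    Positions absent from the file get ``mask=0``; they carry no
    annotation and are ignored downstream.
    """
    by_id = {p.id: p for p in proteins}
    tracks = {
        p.id: LabelTrack(p.id, np.zeros(len(p), dtype=np.int8), np.zeros(len(p), dtype=np.int8))
        for p in proteins
    }
    df = pd.read_csv(path, sep="\t", header=None, names=["protein_id", "position", "label"],
                     dtype={"protein_id": str}, comment="#")
    if df.empty:
        return tracks
    for row in df.itertuples(index=False):
        pid = row.protein_id
        if pid not in by_id:
            raise ParseError(f"{path}: unknown protein id {pid!r}")
        pos = int(row.position)
        if not 1 <= pos <= len(by_id[pid]):
            raise ParseError(f"{path}: position {pos} out of range for {pid!r} (length {len(by_id[pid])})")
        lab = int(row.label)
        if lab not in (0, 1):
            raise ParseError(f"{path}: label must be 0 or 1, got {lab}")
        tracks[pid].labels[pos - 1] = lab
        tracks[pid].mask[pos - 1] = 1
    return tracks


def write_labels(tracks: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in tracks:
            track = tracks[pid]
            for i in range(len(track)):
                if track.mask[i]:
                    fh.write(f"{pid}\t{i + 1}\t{int(track.labels[i])}\n")


_PRED_COLUMNS = ["protein_id", "position", "residue", "probability", "call"]


def write_predictions(table: PredictionTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.protein_id, r.position + 1, r.residue, r.probability, r.call) for r in table.rows],
        columns=_PRED_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_predictions(path: str | Path) -> PredictionTable:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str})
    missing = set(_PRED_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing prediction columns {sorted(missing)}")
    rows = [
        PredictionRow(r.protein_id, int(r.position) - 1, r.residue, float(r.probability), int(r.call))
        for r in df.itertuples(index=False)
    ]
    return PredictionTable(rows)


def load_config(path: str | Path) -> "RunConfig":
    """Load a flat YAML mapping; missing keys take package defaults."""
    from .datamodel import RunConfig

    with open(path) as fh:
        values = yaml.safe_load(fh) or {}
    if not isinstance(values, dict):
        raise ParseError(f"{path}: config must be a flat key-value mapping")
    return RunConfig.from_dict(values)


def save_config(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def split_dataset(ids, fractions, seed: int) -> DatasetSplit:
    """Randomly partition ids by the given fractions (2 or 3 parts).

    Sizes are floored shares of ``len(ids)`` with the remainder assigned
    to the largest-fraction part; the shuffle is a pure function of
    (sorted ids, seed).
    """
    ids = sorted(ids)
    fractions = [float(f) for f in fractions]
    if not 2 <= len(fractions) <= 3:
        raise ValueError("fractions must have 2 or 3 entries")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_parts = sum(1 for f in fractions if f > 0)
    if len(ids) < n_parts:
        raise ValueError(f"cannot split {len(ids)} ids into {n_parts} nonempty parts")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    sizes = [int(np.floor(f * len(ids))) for f in fractions]
    sizes[int(np.argmax(fractions))] += len(ids) - sum(sizes)
    parts, start = [], 0
    for size in sizes:
        parts.append(tuple(ids[i] for i in order[start:start + size]))
        start += size
    while len(parts) < 3:
        parts.append(())
    return DatasetSplit(train_ids=parts[0], valid_ids=parts[1], test_ids=parts[2], seed=seed)


def kfold_indices(ids, K: int, seed: int) -> list[DatasetSplit]:
    """K-fold assignment: each id validates exactly once; folds within ±1."""
    ids = sorted(ids)
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > len(ids):
        raise ValueError(f"K={K} exceeds the number of ids ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = np.array_split(order, K)
    splits = []
    for fold in folds:
        valid = tuple(ids[i] for i in fold)
        train = tuple(ids[i] for i in order if ids[i] not in set(valid))
        splits.append(DatasetSplit(train_ids=train, valid_ids=valid, test_ids=(), seed=seed))
    return splits
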