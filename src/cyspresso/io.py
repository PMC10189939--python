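"""Reading and writing the external formats of the expressibility pipeline.

The pipeline consumes (a) a peptide label table (accession, amino-acid
sequence, knottin flag, expression label), (b) a hierarchical array
container holding per-residue representation blocks keyed by accession,
and emits prediction tables and key-value metric reports.  All readers
are strict about shapes and column names; malformed input raises a
:class:`FormatError` naming the offending piece rather than silently
coercing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .representations import (
    BLOCK_WIDTHS,
    PLDDTTrack,
    ResidueRepresentation,
    reduce_pair,
)

logger = logging.getLogger("cyspresso")

#: the 20 standard amino-acid one-letter codes
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: admissible sequence length range for the pipeline
LENGTH_RANGE = (30, 50)

REQUIRED_COLUMNS = ("accession", "sequence", "knottin", "expressed")


class FormatError(ValueError):
    """A file does not match the expected external format."""


class ShapeError(ValueError):
    """An array block has the wrong shape for its declared record."""


@dataclass(frozen=True)
class PeptideRecord:
    """One cysteine-dense peptide with its metadata.

    ``expressed`` may be ``None`` for prediction-only records (e.g. loaded
    from FASTA without labels).  ``in_length_range`` marks whether the
    sequence falls in the admissible 30-50 aa window; out-of-range records
    are flagged, never dropped.
    """

    accession: str
    sequence: str
    is_knottin: bool | None = None
    expressed: bool | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.accession!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"record {self.accession!r}: non-standard amino acids {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def in_length_range(self) -> bool:
        lo, hi = LENGTH_RANGE
        return lo <= self.length <= hi


@dataclass
class DatasetPartition:
    """Knottin / non-knottin split of a record set."""

    knottins: list[PeptideRecord]
    non_knottins: list[PeptideRecord]

    def summary(self) -> dict[str, dict[str, float | int | None]]:
        """Per-partition expressed counts and percentages (1 decimal).

        Percentage is ``100 * expressed / total``; reported as ``None``
        (absent) for an empty partition.
        """
        out: dict[str, dict[str, float | int | None]] = {}
        for name, recs in (("knottin", self.knottins), ("non_knottin", self.non_knottins)):
            total = len(recs)
            pos = sum(1 for r in recs if r.expressed)
            pct = round(100.0 * pos / total, 1) if total else None
            out[name] = {
                "total": total,
                "expressed": pos,
                "not_expressed": total - pos,
                "expressed_pct": pct,
            }
        return out


def _coerce_flag(value: object) -> bool | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return None
        if value in ("0", "1"):
            return bool(int(value))
        if value.lower() in ("true", "false"):
            return value.lower() == "true"
        raise FormatError(f"flag value {value!r} not in {{0, 1, empty}}")
    return bool(int(value))


def read_label_table(path: str | Path) -> list[PeptideRecord]:
    """Read a peptide label table (CSV or TSV, delimiter auto-detected).

    Requires columns accession, sequence, knottin, expressed.  Records are
    deduplicated on the (accession, sequence) pair, first occurrence kept;
    the number of removed duplicates is logged.  A duplicate accession
    carrying a *different* sequence is kept as a distinct record with a
    warning.  Out-of-range sequence lengths warn but stay in the set.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")

    records: list[PeptideRecord] = []
    seen: set[tuple[str, str]] = set()
    by_accession: dict[str, str] = {}
    n_dups = 0
    n_out_of_range = 0
    for row in df.itertuples(index=False):
        acc = str(getattr(row, "accession")).strip()
        seq = str(getattr(row, "sequence")).strip().upper()
        key = (acc, seq)
        if key in seen:
            n_dups += 1
            continue
        seen.add(key)
        if acc in by_accession and by_accession[acc] != seq:
            warnings.warn(
                f"accession {acc!r} appears with differing sequences; kept as distinct records",
                stacklevel=2,
            )
        by_accession.setdefault(acc, seq)
        rec = PeptideRecord(
            accession=acc,
            sequence=seq,
            is_knottin=_coerce_flag(getattr(row, "knottin")),
            expressed=_coerce_flag(getattr(row, "expressed")),
        )
        if not rec.in_length_range:
            n_out_of_range += 1
        records.append(rec)
    if n_dups:
        logger.info("removed %d duplicate entries, leaving %d records", n_dups, len(records))
    if n_out_of_range:
        warnings.warn(
            f"{n_out_of_range} record(s) outside the {LENGTH_RANGE[0]}-{LENGTH_RANGE[1]} aa "
            "length range; flagged but kept",
            stacklevel=2,
        )
    return records


def write_label_table(records: Sequence[PeptideRecord], path: str | Path) -> None:
    """Write records back to a CSV label table (inverse of read_label_table)."""

    def flag(v: bool | None) -> str:
        return "" if v is None else str(int(v))

    df = pd.DataFrame(
        {
            "accession": [r.accession for r in records],
            "sequence": [r.sequence for r in records],
            "knottin": [flag(r.is_knottin) for r in records],
            "expressed": [flag(r.expressed) for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_fasta_records(path: str | Path) -> list[PeptideRecord]:
    """Read sequences from FASTA into label-free records (prediction-only).

    The accession is the first whitespace-delimited token of each header.
    """
    records = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(PeptideRecord(header, "".join(chunks).upper()))
                header = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if header is not None:
        records.append(PeptideRecord(header, "".join(chunks).upper()))
    return records


def join_fasta_labels(
    fasta_records: Sequence[PeptideRecord], labels: Sequence[PeptideRecord]
) -> list[PeptideRecord]:
    """Attach label-table flags to FASTA records by accession."""
    by_acc = {r.accession: r for r in labels}
    out = []
    for rec in fasta_records:
        lab = by_acc.get(rec.accession)
        if lab is None:
            out.append(rec)
        else:
            out.append(
                PeptideRecord(rec.accession, rec.sequence, lab.is_knottin, lab.expressed)
            )
    return out


def deduplicate(records: Sequence[PeptideRecord]) -> list[PeptideRecord]:
    """Drop repeated (accession, sequence) pairs, first occurrence kept.

    Idempotent: applying twice equals applying once.
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for r in records:
        key = (r.accession, r.sequence)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def partition_dataset(records: Sequence[PeptideRecord]) -> DatasetPartition:
    """Split admitted records into knottin and non-knottin sets.

    Every record must carry ``is_knottin``; the two sets are disjoint and
    their union is the input.
    """
    unknown = [r.accession for r in records if r.is_knottin is None]
    if unknown:
        raise ValueError(f"records without knottin flag: {unknown[:5]}")
    knottins = [r for r in records if r.is_knottin]
    non_knottins = [r for r in records if not r.is_knottin]
    return DatasetPartition(knottins=knottins, non_knottins=non_knottins)


# ---------------------------------------------------------------------------
# representation container (HDF5, one group per accession)
# ---------------------------------------------------------------------------

_CONTAINER_BLOCKS = ("single", "pair", "msa", "structure", "plddt")


def write_representation_container(
    path: str | Path,
    data: Mapping[str, Mapping[str, np.ndarray]],
) -> None:
    """Write per-accession representation blocks to an HDF5 container.

    ``data`` maps accession -> {block name -> array}.  Block names follow
    the container dialect: "single", "pair" (raw LxLx128 or pre-reduced
    Lx128), "msa", "structure", "plddt".  Datasets are written with
    ``track_times=False`` so identical inputs give identical files.
    """
    with h5py.File(path, "w", track_order=True) as fh:
        for acc in data:
            grp = fh.create_group(acc)
            for name, arr in data[acc].items():
                grp.create_dataset(name, data=np.asarray(arr), track_times=False)


def read_representation_container(
    path: str | Path,
    ids: Sequence[str],
    lengths: Mapping[str, int] | None = None,
) -> dict[str, dict[str, ResidueRepresentation | PLDDTTrack]]:
    """Load representation blocks for the requested accessions.

    Returns accession -> {"single": ..., "pair_reduced": ..., "msa": ...,
    "structure": ..., "plddt": PLDDTTrack}.  A raw pair tensor (L, L, 128)
    is reduced to (L, 128) on load and tagged "pair_reduced"; a container
    already holding (L, 128) is accepted as the pre-reduced dialect.

    If ``lengths`` is given, every block's residue dimension is validated
    against the record's sequence length.
    """
    out: dict[str, dict[str, ResidueRepresentation | PLDDTTrack]] = {}
    with h5py.File(path, "r") as fh:
        missing = [acc for acc in ids if acc not in fh]
        if missing:
            raise LookupError(f"container missing accession(s): {missing}")
        for acc in ids:
            grp = fh[acc]
            blocks: dict[str, ResidueRepresentation | PLDDTTrack] = {}
            L_expect = lengths.get(acc) if lengths is not None else None
            for name in ("single", "msa", "structure"):
                arr = np.asarray(grp[name], dtype=np.float64)
                _check_block(acc, name, arr, BLOCK_WIDTHS[name], L_expect)
                blocks[name] = ResidueRepresentation(name, arr)
            pair = np.asarray(grp["pair"], dtype=np.float64)
            if pair.ndim == 3:
                reduced = reduce_pair(pair)
            elif pair.ndim == 2:
                reduced = pair
            else:
                raise ShapeError(f"{acc}: pair block has ndim={pair.ndim}, expected 2 or 3")
            _check_block(acc, "pair_reduced", reduced, BLOCK_WIDTHS["pair_reduced"], L_expect)
            blocks["pair_reduced"] = ResidueRepresentation("pair_reduced", reduced)
            plddt = np.asarray(grp["plddt"], dtype=np.float64)
            if plddt.ndim != 1:
                raise ShapeError(f"{acc}: plddt track must be 1-D")
            if L_expect is not None and plddt.shape[0] != L_expect:
                raise ShapeError(
                    f"{acc}: plddt length {plddt.shape[0]} != sequence length {L_expect}"
                )
            blocks["plddt"] = PLDDTTrack(plddt)
            out[acc] = blocks
    return out


def _check_block(
    acc: str, name: str, arr: np.ndarray, width: int, L_expect: int | None
) -> None:
    if arr.ndim != 2:
        raise ShapeError(f"{acc}: block {name!r} must be 2-D, got ndim={arr.ndim}")
    if arr.shape[1] != width:
        raise ShapeError(
            f"{acc}: block {name!r} has {arr.shape[1]} channels, expected {width}"
        )
    if L_expect is not None and arr.shape[0] != L_expect:
        raise ShapeError(
            f"{acc}: block {name!r} has {arr.shape[0]} residues, "
            f"sequence length is {L_expect}"
        )


# ---------------------------------------------------------------------------
# predictions and reports
# ---------------------------------------------------------------------------

def write_predictions(
    records: Sequence[PeptideRecord],
    scores: Sequence[float],
    path: str | Path,
) -> None:
    """Write per-record expressibility scores as a TSV.

    Columns: accession, partition, score, predicted_label (score >= 0.5),
    true_label (empty when unknown).  Rows follow input order; identical
    inputs produce byte-identical files.
    """
    if len(records) != len(scores):
        raise ValueError("records and scores length mismatch")
    scores = np.asarray(scores, dtype=float)
    if scores.size and (scores.min() < 0.0 or scores.max() > 1.0):
        raise ValueError("scores must lie in [0, 1]")
    with open(path, "w", newline="") as fh:
        fh.write("accession\tpartition\tscore\tpredicted_label\ttrue_label\n")
        for rec, s in zip(records, scores):
            part = (
                ""
                if rec.is_knottin is None
                else ("knottin" if rec.is_knottin else "non_knottin")
            )
            true = "" if rec.expressed is None else str(int(rec.expressed))
            fh.write(f"{rec.accession}\t{part}\t{s:.6f}\t{int(s >= 0.5)}\t{true}\n")


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a predictions TSV back into a DataFrame."""
    return pd.read_csv(path, sep="\t", dtype={"accession": str})


def write_report(report: Mapping[str, object], path: str | Path) -> None:
    """Write a flat mapping as a machine-parsable key=value text report."""
    with open(path, "w") as fh:
        for key, value in report.items():
            fh.write(f"{key}={value}\n")


def read_report(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and "=" in line:
                key, _, value = line.partition("=")
                out[key] = value
    return out
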