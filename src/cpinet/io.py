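"""Readers and writers for every external representation the tool touches.

Bioactivity tables, FASTA sequence files, binary fingerprint matrices,
similarity matrices, ranked prediction lists and network edge lists are all
plain delimited text.  Affinities are converted to micromolar (uM) on ingest
and kept in uM everywhere inside the package; the potency weight
``-log10(affinity / 100 uM)`` is defined against that unit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, DataError

if TYPE_CHECKING:  # pragma: no cover - annotation only, avoids an import cycle
    from .network import BipartiteNetwork
    from .similarity import FingerprintSet, SimilarityMatrix

AFFINITY_TYPES = ("Ki", "IC50")
AFFINITY_UNITS = ("nM", "uM")

#: default column names expected in an interaction table
DEFAULT_COLUMNS = {
    "chemical_id": "chemical_id",
    "protein_id": "protein_id",
    "affinity_type": "affinity_type",
    "affinity_value": "affinity_value",
    "smiles": "smiles",       # optional
    "species": "species",     # optional
}


@dataclass(frozen=True)
class InteractionRecord:
    """One curated bioactivity measurement (affinity stored in uM)."""

    chemical_id: str
    protein_id: str
    affinity_type: str
    affinity_value: float
    smiles: str | None = None
    species: str = ""
    affinity_unit: str = "uM"

    def __post_init__(self) -> None:
        if not self.chemical_id or not self.protein_id:
            raise ValueError("chemical_id and protein_id must be non-empty")
        if self.affinity_type not in AFFINITY_TYPES:
            raise ValueError(
                f"affinity_type must be one of {AFFINITY_TYPES}, got {self.affinity_type!r}"
            )
        if not self.affinity_value > 0:
            raise ValueError("affinity_value must be positive")
        if self.affinity_unit not in AFFINITY_UNITS:
            raise ValueError(f"affinity_unit must be one of {AFFINITY_UNITS}")


@dataclass(frozen=True)
class RankedPrediction:
    """One candidate in a per-query ranked list (rank is 1-based)."""

    query_id: str
    candidate_id: str
    rank: int
    score: float

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be a positive integer")
        if self.score < 0:
            raise ValueError("score must be non-negative")


class RowError(NamedTuple):
    """A malformed input row, reported with its 1-based line number."""

    line: int
    message: str


def _detect_delimiter(path: str, override: str | None = None) -> str:
    if override is not None:
        return override
    with open(path, newline="") as fh:
        first = fh.readline()
    # spreadsheet exports are tab- or comma-separated; prefer tab when present
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_interaction_table(
    path: str,
    column_map: Mapping[str, str] | None = None,
    affinity_unit: str = "uM",
    delimiter: str | None = None,
) -> tuple[list[InteractionRecord], list[RowError]]:
    """Read a delimited bioactivity table into :class:`InteractionRecord` s.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    column_map:
        Maps record fields to column names in the file; unspecified fields
        use :data:`DEFAULT_COLUMNS`.  ``smiles`` and ``species`` columns are
        optional.
    affinity_unit:
        Unit the table's affinity values are expressed in (``"nM"`` or
        ``"uM"``); values are converted to uM internally (nM / 1000).
    delimiter:
        Explicit delimiter; auto-detected among tab/comma when ``None``.

    Returns
    -------
    (records, errors):
        Parsed records plus a list of :class:`RowError` for malformed rows.
        Malformed rows are skipped, not fatal, unless *every* data row fails.
    """
    if affinity_unit not in AFFINITY_UNITS:
        raise ConfigurationError(f"affinity_unit must be one of {AFFINITY_UNITS}")
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    sep = _detect_delimiter(path, delimiter)
    records: list[InteractionRecord] = []
    errors: list[RowError] = []
    n_rows = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        header = reader.fieldnames or []
        required = ["chemical_id", "protein_id", "affinity_type", "affinity_value"]
        for fieldname in required:
            if cols[fieldname] not in header:
                raise ConfigurationError(
                    f"required column {cols[fieldname]!r} (for {fieldname}) "
                    f"not found in header {header}"
                )
        has_smiles = cols["smiles"] in header
        has_species = cols["species"] in header
        for line_no, row in enumerate(reader, start=2):
            n_rows += 1
            raw_value = (row.get(cols["affinity_value"]) or "").strip()
            try:
                value = float(raw_value)
            except ValueError:
                errors.append(RowError(line_no, f"non-numeric affinity {raw_value!r}"))
                continue
            if affinity_unit == "nM":
                value /= 1000.0
            atype = (row.get(cols["affinity_type"]) or "").strip()
            # tolerate common spellings of the two assay readouts
            norm = {"ki": "Ki", "ic50": "IC50"}.get(atype.lower(), atype)
            try:
                rec = InteractionRecord(
                    chemical_id=(row.get(cols["chemical_id"]) or "").strip(),
                    protein_id=(row.get(cols["protein_id"]) or "").strip(),
                    affinity_type=norm,
                    affinity_value=value,
                    smiles=(row.get(cols["smiles"]) or "").strip() or None if has_smiles else None,
                    species=(row.get(cols["species"]) or "").strip() if has_species else "",
                )
            except ValueError as exc:
                errors.append(RowError(line_no, str(exc)))
                continue
            records.append(rec)
    if n_rows and not records:
        raise DataError(f"all {n_rows} rows of {path} failed to parse: {errors[:3]} ...")
    return records, errors


def write_interaction_table(
    records: Iterable[InteractionRecord], path: str, delimiter: str = "\t"
) -> None:
    """Write records as a delimited table (affinities in uM)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(
            ["chemical_id", "protein_id", "affinity_type", "affinity_value", "smiles", "species"]
        )
        for rec in records:
            writer.writerow(
                [
                    rec.chemical_id,
                    rec.protein_id,
                    rec.affinity_type,
                    f"{rec.affinity_value:.6g}",
                    rec.smiles or "",
                    rec.species,
                ]
            )


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into ``{protein_id: sequence}``.

    Ids are the first whitespace-delimited token of the header; sequences are
    uppercased with gaps and whitespace stripped.  Duplicate ids and empty
    sequences are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        pid = record.id
        if pid in sequences:
            raise DataError(f"duplicate FASTA id {pid!r} in {path}")
        seq = str(record.seq).upper().replace("-", "").replace(".", "")
        seq = "".join(seq.split())
        if not seq:
            raise DataError(f"empty sequence for FASTA id {pid!r} in {path}")
        sequences[pid] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_ranked_predictions(
    predictions: Sequence[RankedPrediction], path: str, delimiter: str = "\t"
) -> None:
    """Write a ranked prediction list; byte-deterministic for identical input."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["query_id", "candidate_id", "rank", "score"])
        for p in predictions:
            writer.writerow([p.query_id, p.candidate_id, p.rank, f"{p.score:.6g}"])


def read_ranked_predictions(path: str, delimiter: str | None = None) -> list[RankedPrediction]:
    sep = _detect_delimiter(path, delimiter)
    out: list[RankedPrediction] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter=sep):
            out.append(
                RankedPrediction(
                    query_id=row["query_id"],
                    candidate_id=row["candidate_id"],
                    rank=int(row["rank"]),
                    score=float(row["score"]),
                )
            )
    return out


def write_edge_list(
    network: "BipartiteNetwork",
    path: str,
    include_weights: bool = False,
    fmt: str = "tsv",
) -> None:
    """Export the network's edges.

    ``fmt="tsv"`` writes ``chemical_id <tab> protein_id [<tab> weight]``;
    ``fmt="sif"`` writes the SIF triple ``chemical_id cpi protein_id`` usable
    directly by network-visualization tools.
    """
    if fmt not in ("tsv", "sif"):
        raise ConfigurationError(f"unknown edge-list format {fmt!r}")
    rows = np.argwhere(network.adjacency > 0)
    with open(path, "w") as fh:
        for i, j in rows:
            cid = network.chemical_ids[i]
            pid = network.protein_ids[j]
            if fmt == "sif":
                fh.write(f"{cid}\tcpi\t{pid}\n")
            elif include_weights:
                fh.write(f"{cid}\t{pid}\t{network.weights[i, j]:.6g}\n")
            else:
                fh.write(f"{cid}\t{pid}\n")


def _read_metadata_lines(path: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def write_similarity_matrix(sim: "SimilarityMatrix", path: str, delimiter: str = "\t") -> None:
    """Write a symmetric similarity matrix with id header row/column.

    A leading ``# metric=...`` comment line records how it was computed.
    """
    with open(path, "w") as fh:
        fh.write(f"# metric={sim.metric_name}\n")
        df = pd.DataFrame(sim.values, index=list(sim.ids), columns=list(sim.ids))
        df.to_csv(fh, sep=delimiter, float_format="%.6g")


def read_similarity_matrix(path: str, delimiter: str = "\t") -> "SimilarityMatrix":
    from .similarity import SimilarityMatrix

    meta = _read_metadata_lines(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    values = df.to_numpy(dtype=float)
    # symmetrize away float-formatting asymmetry from the round trip
    values = 0.5 * (values + values.T)
    return SimilarityMatrix(
        ids=tuple(str(i) for i in df.index),
        values=values,
        metric_name=meta.get("metric", "unknown"),
    )


def write_fingerprints(fps: "FingerprintSet", path: str, delimiter: str = "\t") -> None:
    """Write a binary fingerprint matrix: one id column, one column per bit."""
    n_bits = fps.bits.shape[1]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["id"] + [f"bit{i}" for i in range(n_bits)])
        for idx, cid in enumerate(fps.ids):
            writer.writerow([cid] + fps.bits[idx].astype(int).tolist())


def read_fingerprints(path: str, delimiter: str = "\t") -> "FingerprintSet":
    from .similarity import FingerprintSet

    df = pd.read_csv(path, sep=delimiter, index_col=0)
    bits = df.to_numpy()
    if not np.isin(bits, (0, 1)).all():
        raise DataError(f"fingerprint matrix {path} contains non-binary entries")
    return FingerprintSet(
        ids=tuple(str(i) for i in df.index), bits=bits.astype(np.uint8)
    )
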