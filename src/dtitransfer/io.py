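"""Tabular and checkpoint I/O.

Everything the framework reads or writes on disk lives here: activity tables
(CSV/TSV in a configurable column dialect, with a ChEMBL-export-style preset),
embedding tables (TSV: id + d floats), split manifests (two-column CSV), and
model checkpoints (a single .npz archive of per-layer arrays plus a JSON
metadata block, so frozen-weight bit-identity survives save/load).
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError
from .models import FNNParams, LAYER_NAMES

ASSAY_TYPES = ("binding", "functional", "other")
FAMILIES = ("GPCR", "ion_channel", "kinase", "nuclear_receptor",
            "protease", "transporter", "other")
STANDARD_TYPES = ("IC50", "EC50", "AC50", "Ki", "Kd", "Potency", "other")


@dataclass(frozen=True)
class ActivityRecord:
    """One raw bioactivity measurement with all filterable attributes."""

    compound_id: str
    smiles: str
    target_id: str
    target_type: str = "SINGLE PROTEIN"
    taxonomy: str = "human"
    assay_type: str = "binding"
    standard_type: str = "IC50"
    pchembl: float | None = None
    family: str = "other"

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("smiles must be non-empty")
        if self.pchembl is not None and not (
            math.isfinite(self.pchembl) and 0.0 < self.pchembl <= 14.0
        ):
            raise ValueError(f"pchembl {self.pchembl} outside (0, 14]")

    def with_pchembl(self, value: float) -> "ActivityRecord":
        return dataclasses.replace(self, pchembl=value)


@dataclass
class EmbeddingTable:
    """compound_id -> fixed-length real vector (default dimension 300)."""

    dimension: int
    vectors: dict[str, np.ndarray]


#: Field name -> column header in a typical ChEMBL web-export CSV.
CHEMBL_EXPORT_DIALECT: dict[str, str] = {
    "compound_id": "Molecule ChEMBL ID",
    "smiles": "Smiles",
    "target_id": "Target ChEMBL ID",
    "target_type": "Target Type",
    "taxonomy": "Target Organism",
    "assay_type": "Assay Type",
    "standard_type": "Standard Type",
    "pchembl": "pChEMBL Value",
    "family": "Protein Family",
}

#: Identity dialect: column headers equal the field names.
PLAIN_DIALECT: dict[str, str] = {k: k for k in CHEMBL_EXPORT_DIALECT}

_ASSAY_ALIASES = {"b": "binding", "binding": "binding",
                  "f": "functional", "functional": "functional"}
_TAXONOMY_ALIASES = {"homo sapiens": "human", "human": "human"}


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_activity_table(
    path, dialect: Mapping[str, str] | None = None
) -> list[ActivityRecord]:
    """Parse an activity table into records.

    Missing pChEMBL cells become ``None`` (never zero). Unknown categorical
    values map to "other"; assay-type and taxonomy spellings common in ChEMBL
    exports ("B"/"F", "Homo sapiens") are normalized.
    """
    path = Path(path)
    dialect = dict(dialect or PLAIN_DIALECT)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    for field_name, column in dialect.items():
        if column not in df.columns:
            raise FormatError(f"mandatory column {column!r} (field {field_name!r}) "
                              f"missing from {path.name}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        get = lambda f: row[df.columns.get_loc(dialect[f])]
        raw_p = get("pchembl")
        if raw_p is None or (isinstance(raw_p, float) and math.isnan(raw_p)) or str(raw_p).strip() == "":
            pchembl = None
        else:
            try:
                pchembl = float(raw_p)
            except ValueError:
                raise FormatError(f"row {i}: unparseable pChEMBL value {raw_p!r}") from None
        assay = _ASSAY_ALIASES.get(str(get("assay_type")).strip().lower(), "other")
        taxonomy = _TAXONOMY_ALIASES.get(str(get("taxonomy")).strip().lower(),
                                         str(get("taxonomy")).strip())
        family = str(get("family")).strip()
        if family not in FAMILIES:
            family = "other"
        standard_type = str(get("standard_type")).strip()
        if standard_type not in STANDARD_TYPES:
            standard_type = "other"
        try:
            records.append(
                ActivityRecord(
                    compound_id=str(get("compound_id")),
                    smiles=str(get("smiles")),
                    target_id=str(get("target_id")),
                    target_type=str(get("target_type")).strip(),
                    taxonomy=taxonomy,
                    assay_type=assay,
                    standard_type=standard_type,
                    pchembl=pchembl,
                    family=family,
                )
            )
        except ValueError as exc:
            raise FormatError(f"row {i}: {exc}") from None
    return records


def write_activity_table(records: Iterable[ActivityRecord], path,
                         dialect: Mapping[str, str] | None = None) -> None:
    dialect = dict(dialect or PLAIN_DIALECT)
    rows = []
    for rec in records:
        rows.append({dialect[f]: getattr(rec, f) for f in dialect})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_embeddings(path) -> EmbeddingTable:
    """Read a TSV/CSV embedding table: first field compound id, rest floats.

    The dimension is inferred from the first row; ragged rows are format
    errors naming the offending (1-based) row.
    """
    path = Path(path)
    sep = _detect_sep(path)
    vectors: dict[str, np.ndarray] = {}
    dimension: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(sep)
            cid, values = parts[0], parts[1:]
            if dimension is None:
                dimension = len(values)
                if dimension == 0:
                    raise FormatError(f"row {i}: no numeric fields")
            elif len(values) != dimension:
                raise FormatError(
                    f"row {i}: {len(values)} values, expected {dimension}"
                )
            try:
                vectors[cid] = np.asarray([float(v) for v in values], dtype=np.float32)
            except ValueError:
                raise FormatError(f"row {i}: non-numeric embedding value") from None
    if dimension is None:
        raise FormatError(f"{path.name} is empty")
    return EmbeddingTable(dimension=dimension, vectors=vectors)


def write_embeddings(table: EmbeddingTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid, vec in table.vectors.items():
            fh.write(cid + "\t" + "\t".join(repr(float(v)) for v in vec) + "\n")


def write_split_manifest(split, path) -> None:
    """Write a DatasetSplit as a two-column CSV (compound_id, partition)."""
    rows = [{"compound_id": cid, "partition": "train"} for cid in sorted(split.train_ids)]
    rows += [{"compound_id": cid, "partition": "test"} for cid in sorted(split.test_ids)]
    df = pd.DataFrame(rows, columns=["compound_id", "partition"])
    df.attrs = {}
    header_meta = f"# seed={split.seed} test_fraction={split.test_fraction!r}\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header_meta)
        df.to_csv(fh, index=False)


def read_split_manifest(path):
    from .split import DatasetSplit  # local import to avoid a cycle

    path = Path(path)
    seed, test_fraction = 0, 1 / 6
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                key, _, val = token.partition("=")
                if key == "seed":
                    seed = int(val)
                elif key == "test_fraction":
                    test_fraction = float(val)
            df = pd.read_csv(fh, dtype=str)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, dtype=str)
    if set(df.columns) != {"compound_id", "partition"}:
        raise FormatError("split manifest needs columns compound_id, partition")
    train = set(df.loc[df["partition"] == "train", "compound_id"])
    test = set(df.loc[df["partition"] == "test", "compound_id"])
    overlap = train & test
    if overlap:
        raise IntegrityError(f"ids in both partitions: {sorted(overlap)[:5]}")
    if not test:
        warnings.warn("split manifest has an empty test partition", UserWarning,
                      stacklevel=2)
    return DatasetSplit(train_ids=frozenset(train), test_ids=frozenset(test),
                        seed=seed, test_fraction=test_fraction)


def save_checkpoint(params: FNNParams, path, metadata: Mapping | None = None) -> None:
    """Serialize FNNParams to a single-file archive, bit-exactly recoverable."""
    meta = {
        "provenance": params.provenance,
        "layer_sizes": [int(params.weights[n].shape[1]) for n in LAYER_NAMES],
        "input_dim": int(params.weights["L1"].shape[0]),
    }
    if metadata:
        meta.update(metadata)
    arrays = {f"W_{n}": params.weights[n] for n in LAYER_NAMES}
    arrays |= {f"b_{n}": params.biases[n] for n in LAYER_NAMES}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> tuple[FNNParams, dict]:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        params = FNNParams(
            weights={n: archive[f"W_{n}"] for n in LAYER_NAMES},
            biases={n: archive[f"b_{n}"] for n in LAYER_NAMES},
            provenance=meta.get("provenance", "scratch"),
        )
    return params, meta
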