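"""Bioactivity curation: attribute filtering, duplicate aggregation, activity labeling.

Raw bioactivity tables mix assay formats, organisms and measurement types.
Curation keeps single-protein human binding assays with XC50-class standard
types, collapses repeated measurements of the same compound-target pair to
their median pChEMBL value, and labels compounds active when the aggregated
pChEMBL reaches the activity threshold (default 7.0, i.e. XC50 = 100 nM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import yaml

from .io import ActivityRecord

DEFAULT_THRESHOLD = 7.0

ACTIVE = "active"
INACTIVE = "inactive"


@dataclass(frozen=True)
class CurationConfig:
    """Filtering and labeling rules applied to raw activity records."""

    pchembl_threshold: float = DEFAULT_THRESHOLD
    allowed_target_types: frozenset[str] = frozenset({"SINGLE PROTEIN"})
    allowed_taxonomy: frozenset[str] = frozenset({"human"})
    allowed_assay_types: frozenset[str] = frozenset({"binding"})
    allowed_standard_types: frozenset[str] = frozenset(
        {"IC50", "EC50", "AC50", "Ki", "Kd", "Potency"}
    )
    require_pchembl: bool = True
    # Boundary convention: a compound at exactly the threshold is ACTIVE.
    active_at_threshold: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.pchembl_threshold < 14.0):
            raise ValueError("pchembl_threshold must lie in (0, 14)")
        for name in ("allowed_target_types", "allowed_taxonomy",
                     "allowed_assay_types", "allowed_standard_types"):
            value = frozenset(getattr(self, name))
            object.__setattr__(self, name, value)
            if not value:
                raise ValueError(f"{name} must be non-empty")

    @classmethod
    def from_dict(cls, block: Mapping) -> "CurationConfig":
        kwargs = dict(block)
        for name in ("allowed_target_types", "allowed_taxonomy",
                     "allowed_assay_types", "allowed_standard_types"):
            if name in kwargs:
                kwargs[name] = frozenset(kwargs[name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "CurationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc.get("curation", doc))


@dataclass(frozen=True)
class LabeledCompound:
    """A curated compound: aggregated pChEMBL value plus its binary activity label."""

    compound_id: str
    smiles: str
    family: str
    pchembl: float
    label: str  # "active" | "inactive"


def write_labeled_compounds(compounds: Sequence[LabeledCompound], path) -> None:
    """Write a curated family dataset as CSV (round-trips exactly)."""
    import pandas as pd

    pd.DataFrame([c.__dict__ for c in compounds]).to_csv(path, index=False)


def read_labeled_compounds(path) -> list[LabeledCompound]:
    import pandas as pd

    df = pd.read_csv(path, dtype={"compound_id": str, "smiles": str,
                                  "family": str, "label": str})
    required = {"compound_id", "smiles", "family", "pchembl", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curated dataset missing columns: {sorted(missing)}")
    return [
        LabeledCompound(str(r.compound_id), str(r.smiles), str(r.family),
                        float(r.pchembl), str(r.label))
        for r in df.itertuples(index=False)
    ]


def apply_filters(
    records: Iterable[ActivityRecord], config: CurationConfig | None = None
) -> list[ActivityRecord]:
    """Keep records that satisfy every configured attribute filter.

    Order-preserving and side-effect free; an empty result is legal.
    """
    config = config or CurationConfig()
    out = []
    for rec in records:
        if rec.target_type not in config.allowed_target_types:
            continue
        if rec.taxonomy not in config.allowed_taxonomy:
            continue
        if rec.assay_type not in config.allowed_assay_types:
            continue
        if rec.standard_type not in config.allowed_standard_types:
            continue
        if config.require_pchembl and rec.pchembl is None:
            continue
        out.append(rec)
    return out


def aggregate_duplicates(records: Sequence[ActivityRecord]) -> list[ActivityRecord]:
    """Collapse repeated (compound, target) measurements to their median pChEMBL.

    All other fields are carried over from the group's first record in input
    order; output keeps first-occurrence order. Every input record must carry
    a pChEMBL value (run the presence filter first).
    """
    groups: dict[tuple[str, str], list[ActivityRecord]] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        if rec.pchembl is None:
            raise ValueError(
                f"record {rec.compound_id}/{rec.target_id} lacks a pChEMBL value; "
                "aggregation requires numeric values"
            )
        key = (rec.compound_id, rec.target_id)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    out = []
    for key in order:
        group = groups[key]
        first = group[0]
        agg = median(r.pchembl for r in group)
        out.append(first if len(group) == 1 and first.pchembl == agg
                   else first.with_pchembl(float(agg)))
    return out


def label_activity(
    pchembl: float, threshold: float = DEFAULT_THRESHOLD, active_at_threshold: bool = True
) -> str:
    """Binary activity call: active iff pchembl >= threshold (> if the switch is off)."""
    if not (math.isfinite(pchembl) and math.isfinite(threshold)):
        raise ValueError("pchembl and threshold must be finite")
    if active_at_threshold:
        return ACTIVE if pchembl >= threshold else INACTIVE
    return ACTIVE if pchembl > threshold else INACTIVE


def pchembl_to_xc50(pchembl: float) -> float:
    """Convert a pChEMBL value to the corresponding XC50 in nM: 10**(9 - pChEMBL)."""
    if not math.isfinite(pchembl):
        raise ValueError("pchembl must be finite")
    return 10.0 ** (9.0 - pchembl)


def curate(
    records: Iterable[ActivityRecord], config: CurationConfig | None = None
) -> dict[str, list[LabeledCompound]]:
    """Full pipeline: attribute filters -> median aggregation -> labeling, per family.

    The pChEMBL-presence filter runs before aggregation because the median is
    only defined over numeric values. Families partition the output.
    """
    config = config or CurationConfig()
    filtered = apply_filters(records, config)
    aggregated = aggregate_duplicates(filtered)
    by_family: dict[str, list[LabeledCompound]] = {}
    for rec in aggregated:
        label = label_activity(rec.pchembl, config.pchembl_threshold,
                               config.active_at_threshold)
        by_family.setdefault(rec.family, []).append(
            LabeledCompound(
                compound_id=rec.compound_id,
                smiles=rec.smiles,
                family=rec.family,
                pchembl=rec.pchembl,
                label=label,
            )
        )
    return by_family
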