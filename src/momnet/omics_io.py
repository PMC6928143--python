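"""Omics dataset ingestion and identifier hygiene.

A meta-analysis study pools differentially expressed gene/protein lists
(with signed fold-changes) and presence-only "mapping" inventories
(proteins, nitroproteins, phosphoproteins) from several source
publications.  This module defines the dataset data model, reads the
per-dataset TSV tables, and applies the two identifier rules every
downstream stage depends on:

* duplicate identifiers collapse to a single record — the largest
  |fold-change| wins for quantitative data, the first occurrence wins for
  presence-only data;
* only identifiers matched to the knowledge base are "network-eligible"
  and admitted to pathway/network analysis.

Fold-changes use the signed convention: a ratio t/c >= 1 is reported as
is, a ratio below 1 is reported as -(c/t), so magnitudes are symmetric
about +/-1 and the open interval (-1, 1) is not a valid value.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .knowledge_base import KnowledgeBase

__all__ = [
    "Direction",
    "DatasetKind",
    "DatasetGroup",
    "MoleculeRecord",
    "OmicsDataset",
    "IdClassification",
    "FormatError",
    "ValidationError",
    "ConfigurationError",
    "load_dataset",
    "deduplicate",
    "classify_ids",
]


class FormatError(ValueError):
    """Malformed input file (missing columns, bad tokens)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


class ConfigurationError(ValueError):
    """Unusable configuration (e.g. an empty knowledge base)."""


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"
    PRESENT = "present"


class DatasetKind(str, enum.Enum):
    QUANT_TRANSCRIPTOMICS = "quant_transcriptomics"
    QUANT_PROTEOMICS = "quant_proteomics"
    MAPPING_PROTEIN = "mapping_protein"
    MAPPING_NITRATION = "mapping_nitration"
    MAPPING_PHOSPHO = "mapping_phospho"

    @property
    def quantitative(self) -> bool:
        return self in (
            DatasetKind.QUANT_TRANSCRIPTOMICS,
            DatasetKind.QUANT_PROTEOMICS,
        )


class DatasetGroup(str, enum.Enum):
    NFPA = "nfpa"
    INVASIVE_NFPA = "invasive_nfpa"
    CONTROL = "control"


#: Default serial -> group layout: serials 1-4 compare tumor vs control,
#: 5-6 invasive vs non-invasive tumor, 7-9 inventory the control tissue.
DEFAULT_GROUP_LAYOUT: dict[int, DatasetGroup] = {
    1: DatasetGroup.NFPA,
    2: DatasetGroup.NFPA,
    3: DatasetGroup.NFPA,
    4: DatasetGroup.NFPA,
    5: DatasetGroup.INVASIVE_NFPA,
    6: DatasetGroup.INVASIVE_NFPA,
    7: DatasetGroup.CONTROL,
    8: DatasetGroup.CONTROL,
    9: DatasetGroup.CONTROL,
}


@dataclass(frozen=True)
class MoleculeRecord:
    """One row of an omics dataset: a molecule and, optionally, its change.

    ``fold_change`` follows the signed convention (|fc| >= 1, sign gives
    the direction); presence-only records carry no fold-change and
    ``direction == Direction.PRESENT``.
    """

    identifier: str
    display_name: str = ""
    fold_change: Optional[float] = None
    direction: Direction = Direction.PRESENT
    modification_note: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValidationError("molecule identifier must be non-empty")
        if self.fold_change is not None:
            if not math.isfinite(self.fold_change) or abs(self.fold_change) < 1:
                raise ValidationError(
                    f"{self.identifier}: signed fold-change must satisfy "
                    f"|fc| >= 1, got {self.fold_change!r}"
                )
            want = Direction.UP if self.fold_change > 0 else Direction.DOWN
            if self.fold_change != 0 and self.direction != want:
                raise ValidationError(
                    f"{self.identifier}: direction {self.direction.value!r} "
                    f"inconsistent with fold-change {self.fold_change}"
                )
        elif self.direction != Direction.PRESENT:
            raise ValidationError(
                f"{self.identifier}: records without a fold-change must have "
                "direction 'present'"
            )


@dataclass(frozen=True)
class OmicsDataset:
    """One of the study's input molecule collections, ordered as loaded."""

    serial: int
    kind: DatasetKind
    group: DatasetGroup
    records: tuple[MoleculeRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 1 <= self.serial <= 9:
            raise ValidationError(f"dataset serial must be in 1..9, got {self.serial}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def identifiers(self) -> list[str]:
        return [r.identifier for r in self.records]

    def n_by_direction(self, direction: Direction) -> int:
        return sum(1 for r in self.records if r.direction is direction)


@dataclass(frozen=True)
class IdClassification:
    """Partition of a dataset's identifiers against a knowledge base.

    Mirrors the matched/unmatched bookkeeping a pathway-analysis platform
    produces: ``all_ids`` splits into ``mapped_ids`` (known to the KB) and
    ``unmapped_ids``; ``network_eligible_ids`` are the mapped identifiers
    after de-duplication and are the ones admitted to enrichment and
    network construction.  The functions/pathways-eligible list is modelled
    as identical to the network-eligible list.
    """

    all_ids: frozenset[str]
    unmapped_ids: frozenset[str]
    mapped_ids: frozenset[str]
    network_eligible_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.mapped_ids | self.unmapped_ids != self.all_ids:
            raise ValidationError("mapped and unmapped ids must partition all ids")
        if self.mapped_ids & self.unmapped_ids:
            raise ValidationError("mapped and unmapped ids overlap")
        if not self.network_eligible_ids <= self.mapped_ids:
            raise ValidationError("network-eligible ids must be mapped")

    @property
    def pathway_eligible_ids(self) -> frozenset[str]:
        return self.network_eligible_ids


def _parse_fold_change(token: object, row: int) -> Optional[float]:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    text = str(token).strip()
    if text == "":
        return None
    # accept the typographic minus used by journal tables
    text = text.replace("−", "-").replace("–", "-")
    try:
        value = float(text)
    except ValueError as exc:
        raise FormatError(f"row {row}: unparseable fold_change {token!r}") from exc
    if abs(value) < 1:
        raise ValidationError(
            f"row {row}: fold-change {value} lies in the excluded interval (-1, 1)"
        )
    return value


def load_dataset(
    path: str | Path,
    serial: int,
    kind: DatasetKind | str,
    group: DatasetGroup | str,
) -> OmicsDataset:
    """Read one dataset TSV into an :class:`OmicsDataset`.

    The file must be UTF-8 TSV with a header row; column ``identifier`` is
    required, ``fold_change``, ``direction`` and ``modification_note`` are
    optional.  Identifiers are canonicalized to uppercase; row order is
    preserved; duplicates are kept (collapse them with :func:`deduplicate`).
    """
    kind = DatasetKind(kind)
    group = DatasetGroup(group)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "identifier" not in frame.columns:
        raise FormatError(f"{path}: missing required column 'identifier'")

    records: list[MoleculeRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        raw = dict(zip(frame.columns, row))
        ident = raw["identifier"].strip().upper()
        if not ident:
            raise ValidationError(f"{path}: row {i}: empty identifier")
        fc = _parse_fold_change(raw.get("fold_change"), i) if kind.quantitative else None
        direction_token = (raw.get("direction") or "").strip().lower()
        if fc is not None:
            direction = Direction.UP if fc > 0 else Direction.DOWN
            if direction_token and direction_token != direction.value:
                raise ValidationError(
                    f"{path}: row {i}: direction {direction_token!r} contradicts "
                    f"fold-change {fc}"
                )
        elif direction_token in ("up", "down"):
            raise ValidationError(
                f"{path}: row {i}: direction {direction_token!r} requires a fold-change"
            )
        else:
            direction = Direction.PRESENT
        note = (raw.get("modification_note") or "").strip() or None
        display = (raw.get("display_name") or "").strip() or ident
        records.append(
            MoleculeRecord(
                identifier=ident,
                display_name=display,
                fold_change=fc,
                direction=direction,
                modification_note=note,
            )
        )
    return OmicsDataset(serial=serial, kind=kind, group=group, records=tuple(records))


def deduplicate(dataset: OmicsDataset) -> OmicsDataset:
    """Collapse duplicate identifiers to one record each.

    Quantitative datasets keep the record with the largest |fold-change|
    (sign retained); presence-only datasets keep the first occurrence.
    Output order is first-occurrence order, so the operation is idempotent.
    """
    best: dict[str, MoleculeRecord] = {}
    order: list[str] = []
    for record in dataset.records:
        ident = record.identifier
        if ident not in best:
            best[ident] = record
            order.append(ident)
        elif dataset.kind.quantitative:
            incumbent = best[ident]
            new_mag = abs(record.fold_change) if record.fold_change is not None else 0.0
            old_mag = (
                abs(incumbent.fold_change) if incumbent.fold_change is not None else 0.0
            )
            if new_mag > old_mag:
                best[ident] = record
        # mapping kinds: first occurrence already stored
    return replace(dataset, records=tuple(best[i] for i in order))


def classify_ids(dataset: OmicsDataset, kb: "KnowledgeBase") -> IdClassification:
    """Partition a dataset's identifiers against the knowledge base.

    An identifier is *mapped* when the KB knows it (graph node or pathway
    member); the mapped set, de-duplicated, is the network-eligible set.
    De-duplication is applied internally, so raw datasets are accepted.
    """
    if kb.is_empty():
        raise ConfigurationError("knowledge base has no nodes and no pathways")
    deduped = deduplicate(dataset)
    all_ids = frozenset(r.identifier for r in dataset.records)
    known = kb.known_identifiers()
    mapped = frozenset(i for i in all_ids if i in known)
    eligible = frozenset(r.identifier for r in deduped.records if r.identifier in known)
    return IdClassification(
        all_ids=all_ids,
        unmapped_ids=all_ids - mapped,
        mapped_ids=mapped,
        network_eligible_ids=eligible,
    )


def eligible_fold_changes(dataset: OmicsDataset, eligible: Iterable[str]) -> dict[str, float]:
    """Map eligible identifiers to their (post-dedup) signed fold-changes."""
    deduped = deduplicate(dataset)
    wanted = set(eligible)
    return {
        r.identifier: r.fold_change
        for r in deduped.records
        if r.identifier in wanted and r.fold_change is not None
    }
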