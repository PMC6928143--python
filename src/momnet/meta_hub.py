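"""Cross-dataset hub meta-analysis.

Hubs extracted per dataset are pooled into function-based panels, scored
by frequency (the number of distinct tumor-group datasets, serials 1-6,
in which a molecule is a hub), filtered at frequency >= 3 into the
high-frequency hub list, and cross-tabulated against phosphoproteomics
(PTMScan-style) detections with a |signed fold-change| >= 2.5 magnitude
flag.  The percent-detected summary is truncated (not rounded) to one
decimal, the convention under which 25/57 prints as 43.8%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .omics_io import ConfigurationError

__all__ = [
    "HubOccurrence",
    "HubPanel",
    "HubFrequencyRecord",
    "CrosstabSummary",
    "assemble_panels",
    "hub_frequency",
    "high_frequency_filter",
    "ptm_crosstab",
    "load_table1_fixture",
    "table1_occurrences",
    "table1_ptm_hits",
    "NFPA_GROUP_SERIALS",
    "MIN_FREQUENCY",
    "FC_THRESHOLD",
]

log = logging.getLogger(__name__)

#: Serials of the tumor-group datasets counted for hub frequency.
NFPA_GROUP_SERIALS = frozenset({1, 2, 3, 4, 5, 6})
MIN_FREQUENCY = 3
FC_THRESHOLD = 2.5

UNASSIGNED_PANEL = "unassigned"


@dataclass(frozen=True)
class HubOccurrence:
    identifier: str
    dataset_serial: int
    panel_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not 1 <= self.dataset_serial <= 9:
            raise ValueError(f"dataset serial must be in 1..9, got {self.dataset_serial}")


@dataclass(frozen=True)
class HubPanel:
    """Hubs of one primary-function panel, listed per source dataset."""

    panel_label: str
    category_label: str
    members_by_dataset: Mapping[int, frozenset[str]]

    @property
    def n_members(self) -> int:
        return sum(len(m) for m in self.members_by_dataset.values())


@dataclass(frozen=True)
class HubFrequencyRecord:
    """One row of the high-frequency hub table."""

    identifier: str
    frequency: int
    dataset_serials: tuple[int, ...]
    ptm_detected: Optional[bool] = None
    ptm_large_change: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.frequency != len(self.dataset_serials):
            raise ValueError("frequency must equal the number of dataset serials")
        if self.ptm_large_change and not self.ptm_detected:
            raise ValueError("large-change flag requires PTM detection")


@dataclass(frozen=True)
class CrosstabSummary:
    n_records: int
    n_detected: int
    n_large_change: int
    percent_detected: float


def assemble_panels(
    occurrences: Iterable[HubOccurrence],
    function_map: Mapping[str, tuple[str, str]],
) -> list[HubPanel]:
    """Group hub occurrences into primary-function panels.

    ``function_map`` maps a hub identifier to (panel_label,
    category_label).  Hubs missing from the map are logged and collected
    into an ``unassigned`` panel.  Panels are sorted by label.
    """
    occurrences = list(occurrences)
    if occurrences and not function_map:
        raise ConfigurationError("function map is empty but hub occurrences exist")
    buckets: dict[str, tuple[str, dict[int, set[str]]]] = {}
    for occ in occurrences:
        if occ.identifier in function_map:
            panel, category = function_map[occ.identifier]
        else:
            log.warning("hub %s missing from function map", occ.identifier)
            panel, category = UNASSIGNED_PANEL, UNASSIGNED_PANEL
        _, by_dataset = buckets.setdefault(panel, (category, {}))
        by_dataset.setdefault(occ.dataset_serial, set()).add(occ.identifier)
    return [
        HubPanel(
            panel_label=label,
            category_label=category,
            members_by_dataset={s: frozenset(m) for s, m in sorted(by_dataset.items())},
        )
        for label, (category, by_dataset) in sorted(buckets.items())
    ]


def hub_frequency(
    occurrences: Iterable[HubOccurrence],
    counted_serials: frozenset[int] = NFPA_GROUP_SERIALS,
) -> list[HubFrequencyRecord]:
    """Per-molecule count of distinct counted datasets in which it is a hub.

    Multiple networks or panels within one dataset count once.  Records
    are sorted by frequency descending, then identifier.
    """
    serials_by_id: dict[str, set[int]] = {}
    for occ in occurrences:
        if occ.dataset_serial in counted_serials:
            serials_by_id.setdefault(occ.identifier, set()).add(occ.dataset_serial)
    records = [
        HubFrequencyRecord(
            identifier=ident,
            frequency=len(serials),
            dataset_serials=tuple(sorted(serials)),
        )
        for ident, serials in serials_by_id.items()
    ]
    records.sort(key=lambda r: (-r.frequency, r.identifier))
    return records


def high_frequency_filter(
    records: Iterable[HubFrequencyRecord],
    min_freq: int = MIN_FREQUENCY,
) -> list[HubFrequencyRecord]:
    """Keep records with frequency >= ``min_freq`` (order preserved)."""
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    return [r for r in records if r.frequency >= min_freq]


def _truncate_one_decimal(value: float) -> float:
    return int(value * 10) / 10


def ptm_crosstab(
    records: Iterable[HubFrequencyRecord],
    ptm_hits: Mapping[str, float],
    threshold: float = FC_THRESHOLD,
) -> tuple[list[HubFrequencyRecord], CrosstabSummary]:
    """Cross-tabulate high-frequency hubs against PTM quantification.

    ``ptm_hits`` maps a molecule to the maximum |signed ratio| observed
    for any of its modified peptides.  A record is PTM-detected when
    present in the map and large-change when the maximum magnitude is at
    least ``threshold``.  Percent detected is truncated toward zero to
    one decimal.
    """
    if threshold < 1:
        raise ValueError("fold-change threshold must be >= 1")
    for ident, ratio in ptm_hits.items():
        if abs(ratio) < 1:
            raise ValueError(f"PTM ratio magnitude below 1 for {ident!r}")
    annotated: list[HubFrequencyRecord] = []
    for record in records:
        detected = record.identifier in ptm_hits
        large = detected and abs(ptm_hits[record.identifier]) >= threshold
        annotated.append(replace(record, ptm_detected=detected, ptm_large_change=large))
    n = len(annotated)
    n_detected = sum(1 for r in annotated if r.ptm_detected)
    n_large = sum(1 for r in annotated if r.ptm_large_change)
    percent = _truncate_one_decimal(100.0 * n_detected / n) if n else 0.0
    return annotated, CrosstabSummary(
        n_records=n,
        n_detected=n_detected,
        n_large_change=n_large,
        percent_detected=percent,
    )


# ---------------------------------------------------------------------------
# packaged high-frequency hub table fixture


def load_table1_fixture(path: str | Path | None = None) -> list[HubFrequencyRecord]:
    """Load the packaged high-frequency hub table (data/table1_hubs.tsv).

    The fixture transcribes the published cross-dataset hub table:
    identifier, frequency, comma-joined dataset serials, and the printed
    PTM detection / large-change flags (Y, N, or blank for undetected).
    """
    if path is None:
        source = resources.files("momnet.data").joinpath("table1_hubs.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    records: list[HubFrequencyRecord] = []
    for line in lines[1:]:
        fields = dict(zip(header, line.split("\t")))
        serials = tuple(int(s) for s in fields["dataset_serials"].split(","))
        detected_token = (fields.get("ptm_detected") or "").strip()
        large_token = (fields.get("large_change") or "").strip()
        detected: Optional[bool] = True if detected_token == "Y" else (None if not detected_token else False)
        large: Optional[bool]
        if large_token == "Y":
            large = True
        elif large_token == "N":
            large = False
        else:
            large = None
        records.append(
            HubFrequencyRecord(
                identifier=fields["identifier"],
                frequency=int(fields["frequency"]),
                dataset_serials=serials,
                ptm_detected=detected,
                ptm_large_change=large,
            )
        )
    return records


def table1_occurrences(records: Iterable[HubFrequencyRecord]) -> list[HubOccurrence]:
    """Expand frequency records back into per-dataset hub occurrences."""
    return [
        HubOccurrence(identifier=r.identifier, dataset_serial=s)
        for r in records
        for s in r.dataset_serials
    ]


def table1_ptm_hits(
    records: Iterable[HubFrequencyRecord],
    large_magnitude: float = 2.5,
    small_magnitude: float = 1.8,
) -> dict[str, float]:
    """Encode the fixture's printed PTM classes as a max-|ratio| map.

    Detected hubs flagged as changing at least 2.5-fold are assigned the
    threshold magnitude; detected hubs reported in the 1-2.5-fold band
    get a representative in-band magnitude.  Undetected hubs are absent.
    """
    hits: dict[str, float] = {}
    for record in records:
        if record.ptm_detected:
            hits[record.identifier] = (
                large_magnitude if record.ptm_large_change else small_magnitude
            )
    return hits
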