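"""Post-search phosphopeptide quantification.

Label-free immunoaffinity phosphoproteomics compares summed peptide peak
areas between a pooled tumor group and a pooled control group, each
injected twice.  Ratios use the signed fold-change convention: t/c when
the tumor area is at least the control area, -(c/t) otherwise, so a
ratio never falls in the open interval (-1, 1) and a 2.5-fold decrease
prints as -2.5.  Peptide-spectrum matches are accepted at a 5% target-
decoy false-discovery rate.  Spectral processing and database searching
themselves are upstream of this module; inputs are post-search tables.

Modified-peptide strings mark oxidized methionine with a trailing ``#``
(e.g. ``NLLHVTDTGVGM#TR`` = oxidation at position 12 of the plain
sequence); phospho-site positions arrive as separate site annotations,
with ambiguous localizations flagged non-confident.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .omics_io import FormatError

__all__ = [
    "SiteAnnotation",
    "PhosphoPeptideMeasurement",
    "PsmRecord",
    "parse_modified_peptide",
    "parse_site_token",
    "signed_ratio",
    "classify_magnitude",
    "decoy_fdr_threshold",
    "quantify_table",
    "DECOY_FDR_ALPHA",
]

log = logging.getLogger(__name__)

DECOY_FDR_ALPHA = 0.05

_SITE_RE = re.compile(r"^([A-Z])(\d+)(\?)?$")


@dataclass(frozen=True)
class SiteAnnotation:
    """A modification site: residue letter, 1-based position, confidence."""

    residue: str
    position: int
    confident: bool = True


@dataclass(frozen=True)
class PhosphoPeptideMeasurement:
    protein_name: str
    gene_symbol: str
    peptide: str
    sites: tuple[SiteAnnotation, ...]
    area_tumor: float
    area_control: float
    signed_ratio: float

    def __post_init__(self) -> None:
        positions = [s.position for s in self.sites]
        if positions != sorted(positions):
            raise ValueError("site positions must be ascending")
        if self.area_tumor <= 0 or self.area_control <= 0:
            raise ValueError("group areas must be positive")


@dataclass(frozen=True)
class PsmRecord:
    score: float
    is_decoy: bool


def parse_modified_peptide(text: str) -> tuple[str, list[tuple[int, str]]]:
    """Strip modification marks from a peptide string.

    Residues are A-Z; a ``#`` suffix on a methionine marks oxidation.
    Returns the plain sequence and a list of (1-based position, "oxidation")
    pairs indexed on the plain sequence.
    """
    if not text:
        raise FormatError("empty peptide string")
    sequence: list[str] = []
    mods: list[tuple[int, str]] = []
    for ch in text:
        if ch == "#":
            if not sequence:
                raise FormatError(f"{text!r}: '#' with no preceding residue")
            if sequence[-1] != "M":
                raise FormatError(
                    f"{text!r}: oxidation mark after non-methionine "
                    f"{sequence[-1]!r} at position {len(sequence)}"
                )
            mods.append((len(sequence), "oxidation"))
        elif "A" <= ch <= "Z":
            sequence.append(ch)
        else:
            raise FormatError(f"{text!r}: invalid character {ch!r}")
    return "".join(sequence), mods


def parse_site_token(token: str) -> SiteAnnotation:
    """Parse a site token like ``S236`` or ``S236?`` (ambiguous)."""
    match = _SITE_RE.match(token.strip())
    if not match:
        raise FormatError(f"malformed site token {token!r}")
    residue, position, ambiguous = match.groups()
    return SiteAnnotation(
        residue=residue, position=int(position), confident=ambiguous is None
    )


def signed_ratio(area_tumor: float, area_control: float) -> float:
    """Signed tumor:control fold-change; |result| >= 1 always."""
    if area_tumor <= 0 or area_control <= 0:
        raise ValueError("areas must be positive")
    quotient = area_tumor / area_control
    return quotient if quotient >= 1 else -(area_control / area_tumor)


def classify_magnitude(ratio: float, threshold: float = 2.5) -> bool:
    """True when the signed ratio reaches the magnitude threshold."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if abs(ratio) < 1:
        raise ValueError("signed ratios never lie in (-1, 1)")
    return ratio >= threshold or ratio <= -threshold


def decoy_fdr_threshold(
    psms: Iterable[PsmRecord], alpha: float = DECOY_FDR_ALPHA
) -> Optional[float]:
    """Score cutoff controlling the target-decoy FDR at ``alpha``.

    Scanning candidate cutoffs (the observed scores) from the highest
    down, the FDR at a cutoff is #decoys >= cutoff divided by #targets >=
    cutoff (undefined with zero targets, skipped).  Returns the cutoff
    accepting the most targets subject to FDR <= alpha — the lowest
    qualifying score, ties at the cutoff included.  None when no cutoff
    qualifies or the input is empty.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    records = sorted(psms, key=lambda r: r.score, reverse=True)
    if not records:
        return None
    best: Optional[tuple[int, float]] = None  # (n_targets, cutoff)
    n_targets = n_decoys = 0
    for i, record in enumerate(records):
        if record.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        # evaluate only at the last record of a tie group
        if i + 1 < len(records) and records[i + 1].score == record.score:
            continue
        if n_targets == 0:
            continue
        if n_decoys / n_targets <= alpha:
            # >= keeps the lowest qualifying cutoff at equal target counts
            if best is None or n_targets >= best[0]:
                best = (n_targets, record.score)
    return None if best is None else best[1]


def quantify_table(
    rows: pd.DataFrame | Sequence[Mapping[str, object]],
) -> tuple[list[PhosphoPeptideMeasurement], list[str]]:
    """Quantify a post-search peptide table with per-injection areas.

    Expected columns: ``protein``, ``gene``, ``peptide``, ``sites``
    (semicolon-joined tokens like ``S236`` or ``S236?``; may be empty)
    and per-injection area columns ``tumor_1``, ``tumor_2``,
    ``control_1``, ``control_2`` (missing injections blank).  Group areas
    are summed over available injections; rows without a positive area in
    each group are dropped with a warning.  Returns the measurements and
    a rejects report (one message per dropped row).
    """
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict("records")
    measurements: list[PhosphoPeptideMeasurement] = []
    rejects: list[str] = []
    for i, row in enumerate(rows, start=1):
        peptide = str(row.get("peptide", "")).strip()
        try:
            parse_modified_peptide(peptide)
            site_text = str(row.get("sites", "") or "").strip()
            sites = tuple(
                sorted(
                    (parse_site_token(tok) for tok in site_text.split(";") if tok.strip()),
                    key=lambda s: s.position,
                )
            )
        except FormatError as exc:
            rejects.append(f"row {i}: {exc}")
            continue

        def group_area(prefix: str) -> float:
            total = 0.0
            for key, value in row.items():
                if str(key).startswith(prefix):
                    text = str(value).strip() if value is not None else ""
                    if text and text.lower() != "nan":
                        total += float(text)
            return total

        tumor = group_area("tumor")
        control = group_area("control")
        if tumor <= 0 or control <= 0:
            rejects.append(f"row {i}: non-positive group area ({peptide})")
            log.warning("dropping row %d (%s): non-positive group area", i, peptide)
            continue
        measurements.append(
            PhosphoPeptideMeasurement(
                protein_name=str(row.get("protein", "")).strip(),
                gene_symbol=str(row.get("gene", "")).strip().upper(),
                peptide=peptide,
                sites=sites,
                area_tumor=tumor,
                area_control=control,
                signed_ratio=signed_ratio(tumor, control),
            )
        )
    return measurements, rejects


def max_ratio_by_gene(
    measurements: Iterable[PhosphoPeptideMeasurement],
) -> dict[str, float]:
    """Per gene, the signed ratio of largest magnitude across its peptides."""
    best: dict[str, float] = {}
    for m in measurements:
        if m.gene_symbol not in best or abs(m.signed_ratio) > abs(best[m.gene_symbol]):
            best[m.gene_symbol] = m.signed_ratio
    return best
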