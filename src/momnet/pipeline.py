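"""End-to-end pipeline orchestration and report writing.

Runs load -> de-duplicate -> classify -> enrich -> build networks ->
extract hubs -> cross-dataset frequency -> PTM cross-tabulation from a
single declarative YAML config, writes one TSV report per stage plus a
JSON summary, and logs a run manifest (config hash, seed, versions) for
reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    ALPHA,
    EnrichmentResult,
    SharedPathwayRecord,
    enrich_dataset,
    shared_pathways,
)
from .knowledge_base import KnowledgeBase, load_gene_sets, load_interactions
from .meta_hub import (
    FC_THRESHOLD,
    MIN_FREQUENCY,
    CrosstabSummary,
    HubFrequencyRecord,
    HubOccurrence,
    assemble_panels,
    high_frequency_filter,
    hub_frequency,
    ptm_crosstab,
)
from .network_builder import (
    MAX_NETWORK_SIZE,
    MIN_HUB_LINKS,
    attach_score,
    build_networks,
    coverage_percent,
    extract_hubs,
)
from .omics_io import (
    ConfigurationError,
    DatasetGroup,
    DatasetKind,
    OmicsDataset,
    classify_ids,
    deduplicate,
    load_dataset,
)
from .ptm_quant import max_ratio_by_gene, quantify_table

__all__ = [
    "DatasetDescriptor",
    "PipelineConfig",
    "SummaryReport",
    "run_pipeline",
    "aggregate_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DatasetDescriptor:
    path: Path
    serial: int
    kind: DatasetKind
    group: DatasetGroup


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    gene_sets_path: Path
    interactions_path: Path
    datasets: tuple[DatasetDescriptor, ...]
    function_map_path: Optional[Path] = None
    ptm_table_path: Optional[Path] = None
    out_dir: Path = Path("momnet_out")
    min_links: int = MIN_HUB_LINKS
    min_freq: int = MIN_FREQUENCY
    max_network_size: int = MAX_NETWORK_SIZE
    min_datasets: int = 2
    alpha: float = ALPHA
    fc_threshold: float = FC_THRESHOLD
    seed: int = 1

    def __post_init__(self) -> None:
        for p in (self.gene_sets_path, self.interactions_path):
            if not Path(p).exists():
                raise ConfigurationError(f"missing input file: {p}")
        for d in self.datasets:
            if not Path(d.path).exists():
                raise ConfigurationError(f"missing dataset file: {d.path}")
        for optional in (self.function_map_path, self.ptm_table_path):
            if optional is not None and not Path(optional).exists():
                raise ConfigurationError(f"missing input file: {optional}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        base = Path(path).parent
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))

        def resolve(p: Optional[str]) -> Optional[Path]:
            if p is None:
                return None
            p = Path(p)
            return p if p.is_absolute() else base / p

        datasets = tuple(
            DatasetDescriptor(
                path=resolve(d["path"]),
                serial=int(d["serial"]),
                kind=DatasetKind(d["kind"]),
                group=DatasetGroup(d["group"]),
            )
            for d in raw.get("datasets", [])
        )
        kwargs = dict(
            gene_sets_path=resolve(raw["gene_sets"]),
            interactions_path=resolve(raw["interactions"]),
            datasets=datasets,
            function_map_path=resolve(raw.get("function_map")),
            ptm_table_path=resolve(raw.get("ptm_table")),
            out_dir=resolve(raw.get("out_dir", "momnet_out")),
        )
        for key in ("min_links", "min_freq", "max_network_size", "min_datasets", "seed"):
            if key in raw:
                kwargs[key] = int(raw[key])
        for key in ("alpha", "fc_threshold"):
            if key in raw:
                kwargs[key] = float(raw[key])
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class DatasetCounts:
    n_records: int = 0
    n_eligible: int = 0
    n_networks: int = 0
    n_significant_pathways: int = 0
    n_hubs: int = 0


@dataclass(frozen=True)
class SummaryReport:
    """Per-dataset stage counts and their cross-dataset aggregates."""

    per_dataset: Mapping[int, DatasetCounts]
    total_networks: int
    total_significant_pathways: int
    n_shared_pathways: int = 0
    n_high_frequency_hubs: int = 0
    n_ptm_detected: int = 0
    n_large_change: int = 0
    percent_detected: float = 0.0

    def to_dict(self) -> dict:
        return {
            "per_dataset": {
                str(serial): dataclasses.asdict(counts)
                for serial, counts in sorted(self.per_dataset.items())
            },
            "total_networks": self.total_networks,
            "total_significant_pathways": self.total_significant_pathways,
            "n_shared_pathways": self.n_shared_pathways,
            "n_high_frequency_hubs": self.n_high_frequency_hubs,
            "n_ptm_detected": self.n_ptm_detected,
            "n_large_change": self.n_large_change,
            "percent_detected": self.percent_detected,
        }


def aggregate_summary(
    per_dataset: Mapping[int, DatasetCounts | Mapping[str, int]],
    crosstab: Optional[CrosstabSummary] = None,
    n_shared_pathways: int = 0,
) -> SummaryReport:
    """Sum per-dataset stage counts into the study-level totals."""
    counts: dict[int, DatasetCounts] = {}
    expected = set(range(1, 10))
    for serial, value in per_dataset.items():
        counts[serial] = (
            value if isinstance(value, DatasetCounts) else DatasetCounts(**value)
        )
    missing = expected - set(counts)
    if missing:
        log.warning("missing dataset serials in summary: %s", sorted(missing))
    return SummaryReport(
        per_dataset=counts,
        total_networks=sum(c.n_networks for c in counts.values()),
        total_significant_pathways=sum(
            c.n_significant_pathways for c in counts.values()
        ),
        n_shared_pathways=n_shared_pathways,
        n_high_frequency_hubs=crosstab.n_records if crosstab else 0,
        n_ptm_detected=crosstab.n_detected if crosstab else 0,
        n_large_change=crosstab.n_large_change if crosstab else 0,
        percent_detected=crosstab.percent_detected if crosstab else 0.0,
    )


# ---------------------------------------------------------------------------
# report writers


def _write_enrichment_tsv(path: Path, results: Sequence[EnrichmentResult]) -> None:
    frame = pd.DataFrame(
        [
            {
                "pathway": r.pathway_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": f"{r.p_value:.6g}",
                "adjusted_p": f"{r.adjusted_p:.6g}",
                "significant": r.significant,
                "overlap_members": ";".join(sorted(r.overlap_members)),
            }
            for r in results
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def _write_shared_tsv(path: Path, records: Sequence[SharedPathwayRecord]) -> None:
    frame = pd.DataFrame(
        [
            {
                "pathway": r.pathway_name,
                "dataset_serials": ",".join(str(s) for s in sorted(r.dataset_serials)),
                "n_datasets": r.n_datasets,
                "cancer_related": r.cancer_related,
                "panel": r.panel_label or "",
            }
            for r in records
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def _write_hub_table_tsv(path: Path, records: Sequence[HubFrequencyRecord]) -> None:
    def flag(value: Optional[bool], yes: str = "Y", no: str = "N") -> str:
        if value is None:
            return ""
        return yes if value else no

    frame = pd.DataFrame(
        [
            {
                "identifier": r.identifier,
                "frequency": r.frequency,
                "dataset_serials": ",".join(str(s) for s in r.dataset_serials),
                "ptm_detected": flag(r.ptm_detected, no=""),
                "large_change": flag(r.ptm_large_change) if r.ptm_detected else "",
            }
            for r in records
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def _load_function_map(path: Path) -> dict[str, tuple[str, str]]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {
        row["identifier"]: (row["panel_label"], row["category_label"])
        for _, row in frame.iterrows()
    }


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Execute every stage and write all reports under ``config.out_dir``."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str) -> None:
        log.info("[%6.1fs] %s", time.perf_counter() - t0, name)

    stage("loading knowledge base")
    pathways = load_gene_sets(config.gene_sets_path)
    graph = load_interactions(config.interactions_path)
    kb = KnowledgeBase(graph=graph, pathways=pathways)

    per_dataset_counts: dict[int, DatasetCounts] = {}
    per_dataset_results: dict[int, list[EnrichmentResult]] = {}
    occurrences: list[HubOccurrence] = []
    network_summaries: list[dict] = []

    networks_path = out / "networks.jsonl"
    with open(networks_path, "w", encoding="utf-8") as net_out:
        for descriptor in sorted(config.datasets, key=lambda d: d.serial):
            serial = descriptor.serial
            stage(f"dataset {serial}: load + classify")
            dataset = load_dataset(
                descriptor.path, serial, descriptor.kind, descriptor.group
            )
            deduped = deduplicate(dataset)
            classification = classify_ids(dataset, kb)
            eligible = classification.network_eligible_ids

            stage(f"dataset {serial}: enrichment over {len(kb.pathways)} pathways")
            results = enrich_dataset(eligible, kb, alpha=config.alpha)
            per_dataset_results[serial] = results
            _write_enrichment_tsv(out / f"enrichment_dataset_{serial}.tsv", results)

            stage(f"dataset {serial}: network construction ({len(eligible)} eligible)")
            networks = build_networks(eligible, kb.graph, config.max_network_size)
            networks = [attach_score(n, eligible, kb) for n in networks]
            n_hubs = 0
            for network in networks:
                hubs = extract_hubs(
                    network, kb.graph, config.min_links, dataset_serial=serial
                )
                n_hubs += len(hubs)
                occurrences.extend(
                    HubOccurrence(identifier=h.identifier, dataset_serial=serial)
                    for h in hubs
                )
                net_out.write(
                    json.dumps(
                        {
                            "dataset_serial": serial,
                            "network_id": network.network_id,
                            "score": round(network.score, 1),
                            "coverage_percent": coverage_percent(network),
                            "nodes": sorted(network.nodes),
                            "eligible_nodes": sorted(network.eligible_nodes),
                            "hubs": [
                                {"identifier": h.identifier, "degree": h.degree}
                                for h in hubs
                            ],
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
            network_summaries.append(
                {
                    "dataset_serial": serial,
                    "n_networks": len(networks),
                    "n_nodes": sum(len(n.nodes) for n in networks),
                    "n_eligible_in_networks": sum(
                        len(n.eligible_nodes) for n in networks
                    ),
                    "max_score": round(max((n.score for n in networks), default=0.0), 1),
                    "n_hubs": n_hubs,
                }
            )
            per_dataset_counts[serial] = DatasetCounts(
                n_records=len(dataset),
                n_eligible=len(eligible),
                n_networks=len(networks),
                n_significant_pathways=sum(1 for r in results if r.significant),
                n_hubs=n_hubs,
            )

    pd.DataFrame(network_summaries).to_csv(
        out / "network_summary.tsv", sep="\t", index=False
    )

    stage("shared pathways")
    shared = shared_pathways(
        per_dataset_results,
        min_datasets=config.min_datasets,
        labels=kb.pathway_labels(),
    )
    _write_shared_tsv(out / "shared_pathways.tsv", shared)

    stage("hub panels and frequency")
    if config.function_map_path is not None:
        function_map = _load_function_map(Path(config.function_map_path))
        panels = assemble_panels(occurrences, function_map)
        pd.DataFrame(
            [
                {
                    "panel": p.panel_label,
                    "category": p.category_label,
                    "dataset_serial": serial,
                    "members": ";".join(sorted(members)),
                }
                for p in panels
                for serial, members in p.members_by_dataset.items()
            ]
        ).to_csv(out / "hub_panels.tsv", sep="\t", index=False)

    frequency = hub_frequency(occurrences)
    high_frequency = high_frequency_filter(frequency, config.min_freq)

    crosstab_summary: Optional[CrosstabSummary] = None
    if config.ptm_table_path is not None:
        stage("PTM quantification + cross-tab")
        table = pd.read_csv(
            config.ptm_table_path, sep="\t", dtype=str, keep_default_na=False
        )
        measurements, rejects = quantify_table(table)
        if rejects:
            (out / "ptm_rejects.txt").write_text("\n".join(rejects) + "\n", "utf-8")
        pd.DataFrame(
            [
                {
                    "protein": m.protein_name,
                    "gene": m.gene_symbol,
                    "peptide": m.peptide,
                    "sites": ";".join(
                        f"{s.residue}{s.position}{'' if s.confident else '?'}"
                        for s in m.sites
                    ),
                    "signed_ratio": f"{m.signed_ratio:.1f}",
                    "large_change": abs(m.signed_ratio) >= config.fc_threshold,
                }
                for m in measurements
            ]
        ).to_csv(out / "ptm_quantified.tsv", sep="\t", index=False)
        ptm_hits = max_ratio_by_gene(measurements)
        high_frequency, crosstab_summary = ptm_crosstab(
            high_frequency, ptm_hits, threshold=config.fc_threshold
        )
    _write_hub_table_tsv(out / "high_frequency_hubs.tsv", high_frequency)

    report = aggregate_summary(
        per_dataset_counts, crosstab_summary, n_shared_pathways=len(shared)
    )
    (out / "summary.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n", "utf-8"
    )

    manifest = {
        "momnet_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        # hash covers analytic inputs and thresholds, not the output location
        "config_sha256": hashlib.sha256(
            json.dumps(
                {
                    k: str(v)
                    for k, v in dataclasses.asdict(config).items()
                    if k != "out_dir"
                },
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "thresholds": {
            "min_links": config.min_links,
            "min_freq": config.min_freq,
            "max_network_size": config.max_network_size,
            "min_datasets": config.min_datasets,
            "alpha": config.alpha,
            "fc_threshold": config.fc_threshold,
        },
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", "utf-8"
    )
    stage("done")
    return report
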