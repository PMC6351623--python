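"""End-to-end orchestration: simulate → count → DE → DR → cluster → report.

A single RunConfig drives every stage; all randomness flows from one
root seed that is stream-split per stage, so a fixed config yields
byte-identical output tables. Each stage writes its intermediate TSVs,
so stages can be re-run individually from files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, intron_dr, synthetic_data
from .counting import CountMatrix, FeatureIndex, count_reads
from .diffexpr import FilterSpec, de_analysis, size_factors_median_of_ratios, \
    size_factors_total_count
from .synthetic_data import SimulationScenario, simulate_annotation, \
    simulate_counts, simulate_reads

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full synthetic-study run."""

    seed: int = 0
    scenario: SimulationScenario = field(default_factory=SimulationScenario)
    control: str = "ku70"
    lfc_threshold: float = diffexpr.DEFAULT_LFC_THRESHOLD
    alpha: float = diffexpr.DEFAULT_ALPHA
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    normalization: str = "median_of_ratios"  # or 'total_count'
    count_from_reads: bool = False  # route counts through the SAM/assignment stage
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.scenario.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scen_kwargs = raw.pop("scenario", {})
        strains = scen_kwargs.pop("strains", None)
        scenario = SimulationScenario(**scen_kwargs)
        if strains:
            scenario.strains = {
                name: synthetic_data.StrainEffects(**eff)
                for name, eff in strains.items()
            }
        filt = raw.pop("filter_spec", {})
        return cls(scenario=scenario, filter_spec=FilterSpec(**filt), **raw)


@dataclass
class RunReport:
    """In-memory bundle of one pipeline run."""

    gene_matrix: CountMatrix
    intron_matrix: CountMatrix
    truth: synthetic_data.SimulationTruth
    gene_de: dict[str, pd.DataFrame]
    dr_results: dict[str, pd.DataFrame]
    dr_union: list[str]
    fc_matrix: pd.DataFrame
    dr_non_de: dict[str, list[str]]
    row_clustering: intron_dr.ClusterResult | None
    col_clustering: intron_dr.ClusterResult | None
    library_clustering: intron_dr.ClusterResult
    summary: dict


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline on a simulated study.

    Any stage failure aborts with the stage name and cause. Results and
    a machine-readable summary (counts of up/down genes and DR introns
    per comparison) are returned, and written under ``config.out_dir``
    when set.
    """
    scenario = config.scenario
    mutants = [s for s in scenario.strains if s != config.control]
    if config.control not in scenario.strains:
        raise ValueError(f"control strain {config.control!r} not in scenario")

    stage = "simulate"
    try:
        genes, introns = simulate_annotation(scenario)
        gene_cm, intron_cm, truth = simulate_counts(scenario, genes, introns)

        if config.count_from_reads:
            stage = "count"
            gene_streams = simulate_reads(scenario, genes, gene_cm)
            gene_index = FeatureIndex(genes)
            gene_cm, _ = count_reads(gene_streams, gene_index, scenario.meta())
            intron_streams = simulate_reads(scenario, introns, intron_cm)
            intron_index = FeatureIndex(introns)
            intron_cm, _ = count_reads(intron_streams, intron_index,
                                       scenario.meta())

        stage = "gene DE"
        kept, _ = diffexpr.low_count_filter(gene_cm, config.filter_spec)
        gene_sub = gene_cm.subset_features(kept)
        if config.normalization == "median_of_ratios":
            size_factors = size_factors_median_of_ratios(gene_sub)
        elif config.normalization == "total_count":
            size_factors = size_factors_total_count(gene_sub)
        else:
            raise ValueError(f"unknown normalization {config.normalization!r}")
        gene_de = {
            m: de_analysis(gene_cm, config.control, m,
                           filter_spec=config.filter_spec,
                           size_factors=size_factors,
                           lfc_threshold=config.lfc_threshold,
                           alpha=config.alpha)
            for m in mutants
        }

        stage = "intron DR"
        dr_results, dr_union, fc = intron_dr.dr_analysis(
            intron_cm, size_factors, config.control, mutants,
            filter_spec=config.filter_spec,
            lfc_threshold=config.lfc_threshold, alpha=config.alpha,
        )
        hosts = pd.Series({i.intron_id: i.gene_id for i in introns})
        dr_non_de = {}
        for m in mutants:
            sig = [i for i in dr_union if dr_results[m].loc[i, "significant"]]
            dr_non_de[m] = intron_dr.restrict_to_nonde(sig, hosts, gene_de[m])

        stage = "clustering"
        if len(dr_union) >= 2:
            rows, cols = intron_dr.cluster_fold_changes(fc)
        else:
            rows = cols = None
        _, lib_clust = intron_dr.coa_library_clustering(gene_cm)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "seed": config.seed,
        "control": config.control,
        "n_genes": len(genes),
        "n_introns": len(introns),
        "comparisons": {
            m: {
                "up": int((gene_de[m]["status"] == "up").sum()),
                "down": int((gene_de[m]["status"] == "down").sum()),
                "dr": int(dr_results[m]["significant"].sum()),
                "dr_non_de": len(dr_non_de[m]),
            }
            for m in mutants
        },
        "dr_union": len(dr_union),
    }

    report = RunReport(
        gene_matrix=gene_cm, intron_matrix=intron_cm, truth=truth,
        gene_de=gene_de, dr_results=dr_results, dr_union=dr_union,
        fc_matrix=fc, dr_non_de=dr_non_de, row_clustering=rows,
        col_clustering=cols, library_clustering=lib_clust, summary=summary,
    )
    if config.out_dir:
        _write_report(config, report)
    return report


def _write_report(config: RunConfig, report: RunReport) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.gene_matrix.to_tsv(out / "genes.counts.tsv")
    report.intron_matrix.to_tsv(out / "introns.counts.tsv")
    for m, df in report.gene_de.items():
        df.to_csv(out / f"de_{m}.tsv", sep="\t")
    for m, df in report.dr_results.items():
        df.to_csv(out / f"dr_{m}.tsv", sep="\t")
    report.fc_matrix.to_csv(out / "dr_union_fold_changes.tsv", sep="\t")
    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def scenario_to_yaml(scenario: SimulationScenario, path: str | Path) -> None:
    """Serialize a scenario (including strain effects) to YAML."""
    d = dataclasses.asdict(scenario)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
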