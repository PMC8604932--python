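"""End-to-end orchestration of the two analysis modes.

The *conservative* analysis compares wildtype and deletion cells over all
cells of each strain; the *progressive* analysis first co-clusters the two
strains to remove cell-cycle heterogeneity and compares within clusters
(Bonferroni-adjusted, at-least-one-cluster aggregation).  Genes significant
in both modes form the consistency set, the most reliable candidates.

A run reads a count matrix, cell metadata and a regulation matrix, executes
filter -> size factors -> (clustering) -> per-strain model fits ->
differential tests -> classification -> enrichment -> interaction calls,
and writes every table under one output directory together with a manifest
echoing the configuration and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    CountMatrix,
    GeneSet,
    RegulationMatrix,
    read_cell_meta,
    read_count_matrix,
    read_regulation_matrix,
    restrict_evidence,
)
from .model import ModelSpec
from .differential import PairComparison, compare_pair, call_sets
from .clustering import (
    DEFAULT_K,
    DEFAULT_MIN_CELLS,
    DEFAULT_N_PCS,
    DEFAULT_RESOLUTION,
    PerClusterCalls,
    build_snn_graph,
    louvain_cluster,
    per_cluster_compare,
)
from .enrichment import (
    call_interactions,
    fisher_enrichment,
    interaction_table,
    shared_downstream,
)
from .model import estimate_size_factors

logger = logging.getLogger("compnoise")

__all__ = ["PipelineConfig", "ComparisonResult", "RunReport", "run_pipeline", "evaluate_against_truth"]

MODES = ("conservative", "progressive", "both")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; YAML-serializable."""

    counts_path: str = ""
    meta_path: str = ""
    regulation_path: str = ""
    wildtype: str = "WT"
    comparisons: tuple[str, ...] = ()
    mode: str = "conservative"
    # enrichment groups: name -> list of regulators whose shared targets form the target set
    groups: dict = field(default_factory=dict)
    # deletion strain -> regulator gene id (for Known/Novel interaction calls)
    regulator_of: dict = field(default_factory=dict)
    evidence_allowed: tuple[str, ...] | None = None
    model: ModelSpec = field(default_factory=ModelSpec)
    efdr_target: float = 0.01
    tau0: float = 0.4
    omega0: float = 0.4
    min_detect_fraction: float = 0.01
    snn_k: int = DEFAULT_K
    n_pcs: int = DEFAULT_N_PCS
    resolution: float = DEFAULT_RESOLUTION
    min_cells: int = DEFAULT_MIN_CELLS
    pool_sizes: tuple[int, ...] | None = None
    output_dir: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if isinstance(self.model, dict):
            self.model = ModelSpec(**self.model)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class ComparisonResult:
    """Results of one wildtype-vs-deletion comparison."""

    strain: str
    conservative: PairComparison | None = None
    progressive: PerClusterCalls | None = None
    cluster_labels: pd.Series | None = None
    enrichment: pd.DataFrame | None = None
    interactions: pd.DataFrame | None = None
    consistency: GeneSet | None = None

    def call_counts(self) -> dict[str, int]:
        if self.conservative is None:
            return {}
        counts = self.conservative.table["call"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in ("MeanChange", "NoiseOnly", "NoChange", "Excluded")}


@dataclass
class RunReport:
    comparisons: dict[str, ComparisonResult]
    config: PipelineConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": _jsonable(self.config.to_dict()),
            "seed": self.config.seed,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        summary_rows = []
        for strain, res in self.comparisons.items():
            d = outdir / strain
            d.mkdir(exist_ok=True)
            if res.conservative is not None:
                res.conservative.table.to_csv(d / "differential.tsv", sep="\t")
                cal = pd.DataFrame(
                    [
                        {"statistic": "mean", **asdict(res.conservative.cal_mean)},
                        {"statistic": "noise", **asdict(res.conservative.cal_noise)},
                    ]
                )
                cal.to_csv(d / "calibration.tsv", sep="\t", index=False)
            if res.progressive is not None:
                res.progressive.calls.to_csv(d / "per_cluster_calls.tsv", sep="\t")
            if res.cluster_labels is not None:
                res.cluster_labels.rename("cluster").rename_axis("cell_id").to_csv(
                    d / "clusters.tsv", sep="\t"
                )
            if res.enrichment is not None:
                res.enrichment.to_csv(d / "enrichment.tsv", sep="\t", index=False)
            if res.interactions is not None:
                res.interactions.to_csv(d / "interactions.tsv", sep="\t", index=False)
            if res.consistency is not None:
                pd.Series(sorted(res.consistency.members), name="gene").to_csv(
                    d / "consistency.tsv", sep="\t", index=False
                )
            summary_rows.append({"comparison": strain, **res.call_counts()})
        pd.DataFrame(summary_rows).to_csv(outdir / "summary.tsv", sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(
    cfg: PipelineConfig,
    cm: CountMatrix | None = None,
    meta: pd.DataFrame | None = None,
    rm: RegulationMatrix | None = None,
) -> RunReport:
    """Execute the configured analysis; inputs may be passed in memory.

    Stage errors propagate annotated with the stage name and comparison.
    """
    if cm is None:
        cm = read_count_matrix(cfg.counts_path)
    if meta is None:
        meta = read_cell_meta(cfg.meta_path)
    if rm is None and cfg.regulation_path:
        rm = read_regulation_matrix(cfg.regulation_path)
    if rm is not None and cfg.evidence_allowed is not None:
        rm = restrict_evidence(rm, cfg.evidence_allowed)

    strains_present = set(meta["strain"])
    for st in (cfg.wildtype, *cfg.comparisons):
        if st not in strains_present:
            raise ValueError(f"strain {st!r} referenced in config but absent from metadata")

    strain_of = dict(zip(meta["cell_id"], meta["strain"]))
    results: dict[str, ComparisonResult] = {}
    for strain in cfg.comparisons:
        res = ComparisonResult(strain=strain)
        pair = (cfg.wildtype, strain)
        pair_cells = [c for c in cm.cell_ids if strain_of[c] in pair]
        sub = cm.subset_cells(pair_cells)
        t0 = time.time()
        try:
            if cfg.mode in ("conservative", "both"):
                res.conservative = compare_pair(
                    sub, meta, pair, cfg.model, cfg.efdr_target,
                    cfg.min_detect_fraction, cfg.tau0, cfg.omega0, cfg.pool_sizes,
                )
                logger.info(
                    "stage=conservative comparison=%s genes=%d elapsed=%.1fs counts=%s",
                    strain, len(res.conservative.genes), time.time() - t0, res.call_counts(),
                )
            if cfg.mode in ("progressive", "both"):
                t0 = time.time()
                sfac = estimate_size_factors(sub, cfg.pool_sizes)
                graph = build_snn_graph(sub, sfac, cfg.snn_k, cfg.n_pcs, cfg.seed)
                ca = louvain_cluster(graph, cfg.resolution, cfg.seed)
                res.cluster_labels = ca.labels
                res.progressive = per_cluster_compare(
                    sub, meta, ca, pair, cfg.model, cfg.min_cells, cfg.efdr_target,
                    cfg.min_detect_fraction, cfg.tau0, cfg.omega0, cfg.pool_sizes,
                )
                logger.info(
                    "stage=progressive comparison=%s clusters=%d skipped=%d elapsed=%.1fs",
                    strain, ca.n_clusters, len(res.progressive.skipped), time.time() - t0,
                )
        except Exception as exc:
            raise RuntimeError(f"stage failure in comparison {strain!r}: {exc}") from exc

        # consistency set for mode=both: significant in both analyses
        if res.conservative is not None and res.progressive is not None:
            cons_sets = call_sets(res.conservative.table)
            cons_sig = cons_sets["MeanChange"].members | cons_sets["NoiseOnly"].members
            res.consistency = GeneSet(
                "consistency", cons_sig & res.progressive.candidates.members
            )

        # enrichment and interaction calls need a regulation matrix
        if rm is not None and res.conservative is not None:
            universe = res.conservative.genes
            sets = call_sets(res.conservative.table)
            rows = []
            for gname, regulators in cfg.groups.items():
                target = shared_downstream(rm, regulators)
                for cls in ("MeanChange", "NoiseOnly"):
                    p, tab = fisher_enrichment(sets[cls], target, universe)
                    rows.append(
                        {
                            "comparison": strain, "group": gname, "class": cls,
                            "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
                            "p_value": p,
                        }
                    )
            res.enrichment = pd.DataFrame(rows)
            regulator = cfg.regulator_of.get(strain, strain)
            res.interactions = interaction_table(
                call_interactions(regulator, res.conservative.table, rm)
            )
        results[strain] = res

    report = RunReport(results, cfg)
    if cfg.output_dir:
        report.write(cfg.output_dir)
    return report


def evaluate_against_truth(report: RunReport, truth: pd.DataFrame) -> pd.DataFrame:
    """Confusion matrix and per-class metrics of calls against planted truth.

    ``truth`` is the generator's table (gene, strain, class).  For each
    comparison, planted classes are matched with conservative calls.  A
    planted *Both* gene is expected to be called MeanChange (mean change
    takes precedence).  Sensitivity is the fraction of planted genes of a
    class receiving the expected call among those tested; the
    false-discovery proportion of a call class is the fraction of its calls
    whose planted class does not match.
    """
    rows = []
    for strain, res in report.comparisons.items():
        if res.conservative is None:
            continue
        dt = res.conservative.table
        tr = truth[truth["strain"] == strain].set_index("gene")["class"]
        missing = set(dt.index) - set(tr.index)
        if missing:
            raise ValueError(f"truth table lacks genes {sorted(missing)[:5]} for {strain}")
        expected = tr.replace({"Both": "MeanChange"})
        for planted in ("Null", "MeanChange", "NoiseOnly", "Both"):
            genes = tr.index[tr == planted].intersection(dt.index)
            tested = [g for g in genes if dt.loc[g, "call"] != "Excluded"]
            if not genes.size:
                continue
            want = "NoChange" if planted == "Null" else (
                "MeanChange" if planted in ("MeanChange", "Both") else "NoiseOnly"
            )
            hits = sum(dt.loc[g, "call"] == want for g in tested)
            rows.append(
                {
                    "comparison": strain, "planted": planted, "n_planted": int(genes.size),
                    "n_tested": len(tested),
                    "sensitivity": hits / len(tested) if tested else np.nan,
                }
            )
        for call in ("MeanChange", "NoiseOnly"):
            called = dt.index[dt["call"] == call]
            if not called.size:
                rows.append({"comparison": strain, "planted": f"FDP:{call}",
                             "n_planted": 0, "n_tested": 0, "sensitivity": np.nan})
                continue
            wrong = sum(expected.get(g, "NoChange") != call for g in called)
            rows.append(
                {
                    "comparison": strain, "planted": f"FDP:{call}",
                    "n_planted": int(called.size), "n_tested": int(called.size),
                    "sensitivity": wrong / called.size,
                }
            )
    return pd.DataFrame(rows)
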