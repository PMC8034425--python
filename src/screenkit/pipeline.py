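"""End-to-end orchestration: run every analysis stage from one config.

The pipeline wires the stages in dependency order — descriptors, screen
analysis, COMPARE, target consensus, genomics, network — over synthetic
inputs (or files, where paths are given), writes one CSV per stage plus a
run-metadata record, and can render a consolidated plain-text report.
Results are deterministic given (config, seed): two runs with the same
config produce byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .molgraph import load_fixture
from .descriptors import compute_descriptors, lipinski
from .dose_response import summarize_screen
from .compare_fp import rank_library
from .target_consensus import (
    consensus_rank,
    consensus_table,
    venn_membership,
)
from .genomics_stats import (
    alteration_frequency,
    cooccurrence_enrichment,
    km_curve,
    logrank_test,
)
from .network_enrich import graph_summary, hub_nodes, set_enrichment
from . import synthetic_data as synth

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "descriptors", "screen", "compare", "consensus", "genomics", "network",
)


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # stage inputs; None means "generate synthetically"
    structure: str | None = None          # molfile path; default packaged fixture
    logp: float | None = None
    molar_refractivity: float | None = None
    plates_path: str | None = None
    n_lines: int = 60
    library_size: int = 100
    min_common: int = 3
    top_k: int = 15
    min_predictors: int = 3
    index_gene: str = "EGFR"
    n_samples: int = 5000
    confidence_min: float = 0.9
    enrichment_background: int = 20531

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A stage failed; carries the stage name. Partial outputs are kept."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns a bundle of output paths/tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config, "outputs": {}, "tables": {}}

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            table = _STAGE_FUNCS[stage](config, bundle)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        path = out / f"{stage}.csv"
        _write_csv(table, path)
        bundle["outputs"][stage] = str(path)
        bundle["tables"][stage] = table
        logger.info(
            "stage %s finished in %.2fs -> %s",
            stage, time.perf_counter() - t0, path,
        )

    meta = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(config.stages),
        "screenkit_version": __version__,
        "python": sys.version.split()[0],
    }
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    bundle["outputs"]["metadata"] = str(meta_path)
    return bundle


# ---------------------------------------------------------------------------
# Stage implementations

def _stage_descriptors(config: PipelineConfig, bundle: dict) -> pd.DataFrame:
    if config.structure is not None:
        from .molgraph import perceive, read_molfile

        mol = perceive(read_molfile(Path(config.structure).read_text()))
    else:
        mol = load_fixture("nsc765598")
    d = compute_descriptors(
        mol, logp=config.logp, molar_refractivity=config.molar_refractivity
    )
    verdict = lipinski(d)
    return pd.DataFrame(
        [
            {
                "name": mol.name,
                "mw": d.mw,
                "n_hbd": d.n_hbd,
                "n_hba": d.n_hba,
                "tpsa": d.tpsa,
                "frac_csp3": d.frac_csp3,
                "n_rotatable": d.n_rotatable,
                "logp": d.logp,
                "molar_refractivity": d.molar_refractivity,
                "lipinski_pass": verdict.passed,
                "violations": "; ".join(verdict.violations),
            }
        ]
    )


def _stage_screen(config: PipelineConfig, bundle: dict) -> pd.DataFrame:
    if config.plates_path is not None:
        from .dose_response import read_plates_tsv

        plates = read_plates_tsv(config.plates_path)
    else:
        plates, truth = synth.gen_dose_plates(
            n_lines=config.n_lines, seed=config.seed
        )
        bundle["tables"]["screen_truth"] = truth
    params, ranges = summarize_screen(plates)
    bundle["tables"]["panel_ranges"] = ranges
    out = Path(config.out_dir) / "screen_panel_ranges.csv"
    _write_csv(ranges, out)
    bundle["outputs"]["screen_panel_ranges"] = str(out)
    return params


def _stage_compare(config: PipelineConfig, bundle: dict) -> pd.DataFrame:
    seed_fp, library, truth = synth.gen_fingerprint_library(
        n_compounds=config.library_size, seed=config.seed
    )
    bundle["tables"]["compare_truth"] = truth
    return rank_library(
        seed_fp, library, min_common=config.min_common, top_k=config.top_k
    )


def _stage_consensus(config: PipelineConfig, bundle: dict) -> pd.DataFrame:
    lists = synth.predictor_fixture_lists()
    membership, subset_sizes = venn_membership(lists)
    venn_json = {
        "|".join(sorted(k)): v for k, v in sorted(
            subset_sizes.items(), key=lambda kv: "|".join(sorted(kv[0]))
        )
    }
    venn_path = Path(config.out_dir) / "consensus_venn.json"
    venn_path.write_text(json.dumps(venn_json, indent=2) + "\n")
    bundle["outputs"]["consensus_venn"] = str(venn_path)

    entries, truth = synth.gen_predictor_outputs(
        true_targets=sorted(
            t for t, preds in membership.items() if len(preds) == len(lists)
        ),
        seed=config.seed,
    )
    bundle["tables"]["consensus_truth"] = truth
    targets = consensus_rank(entries, min_predictors=config.min_predictors)
    return consensus_table(targets)


def _stage_genomics(config: PipelineConfig, bundle: dict) -> pd.DataFrame:
    matrix, truth = synth.gen_alteration_matrix(
        n_samples=config.n_samples,
        index_gene=config.index_gene,
        planted_odds_ratios={"G000": 8.0, "G001": 4.0},
        seed=config.seed,
    )
    bundle["tables"]["genomics_truth"] = truth
    freq = alteration_frequency(matrix, config.index_gene)
    bundle["tables"]["index_frequency"] = pd.DataFrame([freq])

    records, surv_truth = synth.gen_survival(seed=config.seed)
    low = [r for r in records if r.group == "low"]
    high = [r for r in records if r.group == "high"]
    lr = logrank_test(high, low)
    km_low, km_high = km_curve(low), km_curve(high)
    bundle["tables"]["survival"] = pd.DataFrame(
        [
            {
                "chi2": lr.chi2,
                "p": lr.p,
                "hr": lr.hr,
                "hr_lo": lr.hr_ci[0],
                "hr_hi": lr.hr_ci[1],
                "median_low_months": km_low.median_survival(),
                "median_high_months": km_high.median_survival(),
                "true_hr": surv_truth["hazard_ratio"],
            }
        ]
    )
    out = Path(config.out_dir) / "genomics_survival.csv"
    _write_csv(bundle["tables"]["survival"], out)
    bundle["outputs"]["genomics_survival"] = str(out)
    return cooccurrence_enrichment(matrix, config.index_gene)


def _stage_network(config: PipelineConfig, bundle: dict) -> pd.DataFrame:
    g = synth.ppi_fixture()
    summary = graph_summary(g, confidence_min=config.confidence_min)
    hubs = hub_nodes(g, 3)
    query = set(g.nodes)
    gene_sets = {
        "pathway_core": set(list(sorted(query))[:10]),
        "pathway_half": set(list(sorted(query))[::2]),
        "pathway_unrelated": {f"ZZZ{i}" for i in range(40)},
    }
    enrich = set_enrichment(
        query, gene_sets, background_size=config.enrichment_background
    )
    bundle["tables"]["network_enrichment"] = enrich
    out = Path(config.out_dir) / "network_enrichment.csv"
    _write_csv(enrich, out)
    bundle["outputs"]["network_enrichment"] = str(out)
    return pd.DataFrame(
        [
            {
                "n_nodes": summary.n_nodes,
                "n_edges": summary.n_edges,
                "avg_degree": summary.avg_degree,
                "avg_local_clustering": summary.avg_local_clustering,
                "hubs": "; ".join(f"{n}({d})" for n, d in hubs),
            }
        ]
    )


_STAGE_FUNCS = {
    "descriptors": _stage_descriptors,
    "screen": _stage_screen,
    "compare": _stage_compare,
    "consensus": _stage_consensus,
    "genomics": _stage_genomics,
    "network": _stage_network,
}


def render_report(bundle: dict) -> str:
    """Deterministic plain-text summary of a pipeline bundle."""
    lines = ["# screenkit pipeline report", ""]
    config: PipelineConfig = bundle["config"]
    lines.append(f"seed: {config.seed}   config: {config.config_hash()}")
    lines.append("")
    for stage in ALL_STAGES:
        if stage not in bundle["tables"]:
            continue
        table = bundle["tables"][stage]
        lines.append(f"## {stage}")
        lines.append(table.head(15).to_string(index=False))
        lines.append("")
    return "\n".join(lines)
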