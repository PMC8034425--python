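"""Synthetic inputs with known ground truth for every analysis stage.

Every generator is a pure function of its arguments plus a root seed: the
root seed fans out to per-generator child streams through fixed offsets
(``default_rng([seed, offset])``), so generators are reproducible and
mutually independent. Truth tables are returned alongside the data so
downstream recovery tests never peek at the generating code.

The defaults emulate the study conditions of a five-dose NCI60-style
screen (five 10-fold dose steps spanning 0.01-100 uM, low-micromolar
potencies, a few percent signal noise), a ~50-cell-line COMPARE library,
a ten-thousand-sample pan-cancer alteration cohort with a ~7% index-gene
rate, exponential survival with multiplicative group hazards, and three
heterogeneous target predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dose_response import DosePlate
from .compare_fp import Fingerprint
from .genomics_stats import AlterationMatrix, SurvivalRecord

# fixed child-stream offsets for the root-seed fan-out
_STREAM = {
    "plates": 1, "library": 2, "alterations": 3, "survival": 4, "predictors": 5,
}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[stream]])


#: Five test concentrations in molar: 0.01-100 uM in 10-fold steps.
DEFAULT_CONC_GRID = (1e-8, 1e-7, 1e-6, 1e-5, 1e-4)

DEFAULT_PANELS = (
    "NSCLC", "Leukemia", "Melanoma", "Renal", "Colon",
    "Breast", "CNS", "Ovarian", "Prostate",
)


def _hill_pg(conc: float, midpoint: float, hill: float, floor: float) -> float:
    return floor + (100.0 - floor) / (1.0 + (conc / midpoint) ** hill)


def _hill_crossing(
    level: float, midpoint: float, hill: float, floor: float
) -> float:
    """Analytic concentration where the noiseless curve crosses ``level``."""
    if level <= floor:
        return math.nan  # the curve never reaches this level
    return midpoint * ((100.0 - level) / (level - floor)) ** (1.0 / hill)


def gen_dose_plates(
    n_lines: int = 60,
    conc_grid: tuple[float, ...] = DEFAULT_CONC_GRID,
    gi50_range: tuple[float, float] = (3e-7, 2e-5),
    hill_range: tuple[float, float] = (0.5, 3.0),
    lethality_fraction: float = 0.3,
    noise_sd: float = 0.03,
    seed: int = 0,
    panels: tuple[str, ...] = DEFAULT_PANELS,
) -> tuple[list[DosePlate], pd.DataFrame]:
    """Hill-shaped growth plates plus the analytic endpoint truth table.

    Each line gets a growth curve running from 100% down to a floor
    (negative floors emulate lethality, drawn for a ``lethality_fraction``
    share of lines); ``noise_sd`` is Gaussian noise on the percent-growth
    scale as a fraction of 100 (0.03 = 3 PG points). Truth columns
    ``gi50_M / tgi_M / lc50_M`` hold the noiseless crossings (NaN when the
    curve never reaches the level).
    """
    rng = child_rng(seed, "plates")
    tz, control = 0.2, 0.6
    plates, truth_rows = [], []
    for i in range(n_lines):
        gi50 = float(
            10 ** rng.uniform(math.log10(gi50_range[0]), math.log10(gi50_range[1]))
        )
        hill = float(rng.uniform(*hill_range))
        if rng.uniform() < lethality_fraction:
            floor = float(rng.uniform(-100.0, -60.0))
        else:
            floor = float(rng.uniform(0.0, 40.0))
        midpoint = gi50 / (((100.0 - floor) / (50.0 - floor)) - 1.0) ** (1.0 / hill)

        doses = []
        for conc in conc_grid:
            pg = _hill_pg(conc, midpoint, hill, floor)
            pg += float(rng.normal(0.0, noise_sd * 100.0))
            if pg >= 0:
                ti = tz + pg / 100.0 * (control - tz)
            else:
                ti = tz * (1.0 + pg / 100.0)
            doses.append((conc, max(ti, 0.0)))
        cell_line = f"CL{i:03d}"
        panel = panels[i % len(panels)]
        plates.append(
            DosePlate(cell_line=cell_line, panel=panel, tz=tz, c=control, doses=doses)
        )
        truth_rows.append(
            {
                "cell_line": cell_line,
                "panel": panel,
                "hill": hill,
                "floor": floor,
                "gi50_M": _hill_crossing(50.0, midpoint, hill, floor),
                "tgi_M": _hill_crossing(0.0, midpoint, hill, floor),
                "lc50_M": _hill_crossing(-50.0, midpoint, hill, floor),
            }
        )
    return plates, pd.DataFrame(truth_rows)


def gen_fingerprint_library(
    n_compounds: int = 100,
    n_lines: int = 50,
    n_correlated: int = 1,
    correlation_noise_sd: float = 0.08,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> tuple[Fingerprint, list[Fingerprint], pd.DataFrame]:
    """A seed fingerprint plus a library with planted similars.

    The first ``n_correlated`` compounds are the seed vector plus Gaussian
    noise whose sd grows linearly (compound i gets
    ``correlation_noise_sd * (i + 1)``), giving a graded planted-similarity
    ladder; remaining compounds are independent. Cells go missing uniformly
    at ``missing_rate``. Truth records each compound's noise sd and the
    population correlation with the seed implied by it.
    """
    if n_correlated > n_compounds:
        raise ValueError("n_correlated cannot exceed n_compounds")
    rng = child_rng(seed, "library")
    lines = [f"CL{i:03d}" for i in range(n_lines)]
    signal_sd = 0.8
    seed_vec = rng.normal(5.5, signal_sd, n_lines)
    seed_fp = Fingerprint("seed", "GI50", pd.Series(seed_vec, index=lines))

    library, truth_rows = [], []
    for i in range(n_compounds):
        cid = f"NSC{i:05d}"
        if i < n_correlated:
            noise = correlation_noise_sd * (i + 1)
            values = seed_vec + rng.normal(0.0, noise, n_lines)
            expected_r = signal_sd / math.sqrt(signal_sd**2 + noise**2)
            planted = True
        else:
            noise = math.nan
            values = rng.normal(5.5, signal_sd, n_lines)
            expected_r = 0.0
            planted = False
        values = np.where(rng.uniform(size=n_lines) < missing_rate, np.nan, values)
        library.append(Fingerprint(cid, "GI50", pd.Series(values, index=lines)))
        truth_rows.append(
            {
                "compound_id": cid,
                "planted": planted,
                "noise_sd": noise,
                "expected_r": expected_r,
            }
        )
    return seed_fp, library, pd.DataFrame(truth_rows)


def gen_alteration_matrix(
    n_samples: int = 10_000,
    gene_base_rates: dict[str, float] | None = None,
    index_gene: str = "EGFR",
    index_rate: float = 0.07,
    planted_odds_ratios: dict[str, float] | None = None,
    cancer_type_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[AlterationMatrix, pd.DataFrame]:
    """Binary alteration matrix with planted index-gene co-occurrence.

    Every gene is Bernoulli at its base rate; for genes with a planted odds
    ratio the odds are multiplied by that ratio within index-altered
    samples. Truth records each gene's base rate and planted OR.
    """
    if gene_base_rates is None:
        gene_base_rates = {f"G{i:03d}": 0.02 + 0.01 * (i % 5) for i in range(20)}
    if planted_odds_ratios is None:
        planted_odds_ratios = {}
    if cancer_type_mix is None:
        cancer_type_mix = {"LUAD": 0.4, "GBM": 0.3, "BRCA": 0.3}
    bad = [g for g, r in gene_base_rates.items() if not 0 < r < 1]
    if bad or not 0 < index_rate < 1:
        raise ValueError("alteration rates must lie in (0, 1)")

    rng = child_rng(seed, "alterations")
    samples = [f"S{i:05d}" for i in range(n_samples)]
    types = rng.choice(
        list(cancer_type_mix), p=list(cancer_type_mix.values()), size=n_samples
    )
    index_calls = (rng.uniform(size=n_samples) < index_rate).astype(int)

    data = {index_gene: index_calls}
    truth_rows = [
        {"gene": index_gene, "base_rate": index_rate, "planted_or": math.nan}
    ]
    for gene, base in gene_base_rates.items():
        odds_ratio = planted_odds_ratios.get(gene, 1.0)
        odds = base / (1.0 - base)
        p_alt = (odds * odds_ratio) / (1.0 + odds * odds_ratio)
        p = np.where(index_calls == 1, p_alt, base)
        data[gene] = (rng.uniform(size=n_samples) < p).astype(int)
        truth_rows.append(
            {"gene": gene, "base_rate": base, "planted_or": odds_ratio}
        )
    matrix = AlterationMatrix(
        calls=pd.DataFrame(data, index=samples),
        cancer_types=pd.Series(types, index=samples, name="cancer_type"),
    )
    return matrix, pd.DataFrame(truth_rows)


def gen_survival(
    n_per_group: int = 300,
    baseline_rate: float = 0.03,
    hazard_ratio: float = 2.0,
    censor_rate: float = 0.005,
    seed: int = 0,
) -> tuple[list[SurvivalRecord], dict]:
    """Two-group exponential survival with independent exponential censoring.

    Group "low" has hazard ``baseline_rate`` (events per month); group
    "high" has hazard ``baseline_rate * hazard_ratio``. Truth carries the
    generating parameters and the analytic median survival per group.
    """
    rng = child_rng(seed, "survival")
    records = []
    for group, rate in (
        ("low", baseline_rate),
        ("high", baseline_rate * hazard_ratio),
    ):
        event_t = rng.exponential(1.0 / rate, n_per_group)
        if censor_rate > 0:
            censor_t = rng.exponential(1.0 / censor_rate, n_per_group)
        else:
            censor_t = np.full(n_per_group, np.inf)
        for et, ct in zip(event_t, censor_t):
            records.append(
                SurvivalRecord(
                    time=float(min(et, ct)),
                    event=int(et <= ct),
                    group=group,
                )
            )
    truth = {
        "baseline_rate": baseline_rate,
        "hazard_ratio": hazard_ratio,
        "censor_rate": censor_rate,
        "median_low": math.log(2) / baseline_rate,
        "median_high": math.log(2) / (baseline_rate * hazard_ratio),
    }
    return records, truth


DEFAULT_PREDICTORS = {
    "PASS": "pa_pi",
    "SwissTarget": "probability",
    "PharmMapper": "pharmacophore",
}


def gen_predictor_outputs(
    true_targets: list[str],
    n_decoys: int = 30,
    predictors: dict[str, str] | None = None,
    score_noise: float = 0.05,
    drop_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list, pd.DataFrame]:
    """Per-predictor score entries with planted true targets.

    True targets draw high base activity scores (0.6-0.95), decoys low ones
    (0.05-0.4); ``score_noise`` is Gaussian on that scale. Each predictor
    independently drops each target with probability ``drop_rate`` so the
    Venn structure is non-trivial. With no noise and no drops the
    triple-intersection equals ``true_targets`` exactly.
    """
    from .target_consensus import PredictorEntry

    if predictors is None:
        predictors = dict(DEFAULT_PREDICTORS)
    rng = child_rng(seed, "predictors")
    decoys = [f"DECOY{i:03d}" for i in range(n_decoys)]
    base = {}
    for t in true_targets:
        base[t] = float(rng.uniform(0.6, 0.95))
    for d in decoys:
        base[d] = float(rng.uniform(0.05, 0.4))

    entries = []
    truth_rows = [
        {"target": t, "is_true": t in true_targets, "base_score": s}
        for t, s in base.items()
    ]
    for predictor, kind in predictors.items():
        for target, s0 in base.items():
            if drop_rate > 0 and rng.uniform() < drop_rate:
                continue
            s = float(np.clip(s0 + rng.normal(0.0, score_noise), 0.01, 0.99))
            if kind == "pa_pi":
                entries.append(
                    PredictorEntry(
                        predictor, target, "pa_pi",
                        pa=(1 + s) / 2, pi=(1 - s) / 2,
                    )
                )
            elif kind == "probability":
                entries.append(
                    PredictorEntry(predictor, target, "probability", probability=s)
                )
            else:
                entries.append(
                    PredictorEntry(
                        predictor, target, "pharmacophore",
                        fit_score=0.7 + 0.3 * s, z=float(rng.uniform(0.1, 0.65)),
                    )
                )
    return entries, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Constructed study-shaped fixtures

def predictor_fixture_lists() -> dict[str, list[str]]:
    """Three 20-gene predictor lists with a 6-gene triple intersection and a
    2-gene exactly-two region ({STAT, MTOR}), mirroring a three-algorithm
    consensus structure. All other genes are predictor-unique."""
    triple = ["NOS2", "TGFB1", "KDR", "FGFR1", "EGFR", "MAPK2"]
    pass_unique = [
        "CTGF", "PDGFRB", "HGF", "TNF", "PTGS2", "ALOX5", "CA2",
        "ESR1", "AR", "PPARG", "ABL1", "SRC", "LCK",
    ]
    swiss_unique = [
        "CDK2", "CHEK1", "IGF1R", "BRAF", "JAK2", "KIT",
        "FLT3", "RET", "MET", "PIK3CA", "AKT1", "PLK1",
    ]
    pharm_unique = [
        "GSTP1", "ALB", "HSP90AA1", "MAPK14", "REN", "F2", "THRB",
        "DHFR", "PNP", "SHBG", "TTR", "RARB", "CDK5",
    ]
    return {
        "PASS": triple + ["STAT"] + pass_unique,
        "SwissTarget": triple + ["STAT", "MTOR"] + swiss_unique,
        "PharmMapper": triple + ["MTOR"] + pharm_unique,
    }


#: Degree plans for the synthetic PPI fixtures. A 26-node simple graph
#: cannot simultaneously carry 176 edges (degree sum 352) and keep
#: 23/14/13 as the three largest degrees (the other 23 nodes would need
#: degree sum 302 but cap at 13 x 23 = 299), so the two published
#: constraint sets are realized as two separate graphs.
_PPI_COUNT_PLAN = [
    ("MTOR", 23), ("MAP2K1", 14), ("EGFR", 13),
    ("NOS2", 14), ("PIK3CA", 14), ("PTEN", 14), ("RAF1", 14), ("RHEB", 14),
    ("RICTOR", 14), ("RPTOR", 14), ("RPS6KB1", 14), ("SOS1", 14),
    ("STAT3", 14), ("TGFB1", 14), ("TSC2", 14), ("VEGFA", 14),
    ("AKT1", 12), ("BRAF", 12), ("EGF", 12), ("EIF4EBP1", 12),
    ("FGFR1", 12), ("GRB2", 12), ("HRAS", 12), ("IGF1R", 12),
    ("LAMTOR1", 12), ("MAPKAP1", 12),
]

_PPI_HUB_PLAN = [
    ("MTOR", 23), ("MAP2K1", 14), ("EGFR", 13),
    # degree-13 peers all sort alphabetically after EGFR
    ("GRB2", 13), ("HRAS", 13), ("IGF1R", 13), ("LAMTOR1", 13),
    ("MAPKAP1", 13), ("NOS2", 13), ("PIK3CA", 13), ("PTEN", 13),
    ("RAF1", 13), ("RHEB", 13), ("RICTOR", 13), ("RPTOR", 13),
    ("RPS6KB1", 13), ("SOS1", 13), ("STAT3", 13), ("TGFB1", 13),
    ("TSC2", 13), ("VEGFA", 13),
    ("AKT1", 12), ("BRAF", 12), ("EGF", 12), ("EIF4EBP1", 12),
    ("FGFR1", 12),
]


def _graph_from_plan(plan: list[tuple[str, int]]) -> nx.Graph:
    g0 = nx.havel_hakimi_graph([d for _, d in plan])
    g = nx.relabel_nodes(g0, dict(enumerate(n for n, _ in plan)))
    for n, d in plan:
        if g.degree[n] != d:
            raise AssertionError(f"fixture degree mismatch for {n}")
    nx.set_edge_attributes(g, 0.95, "confidence")
    return g


def ppi_fixture() -> nx.Graph:
    """Synthetic 26-node / 176-edge PPI graph (average degree 13.5).

    The true database edge list is not public; this is a deterministic
    Havel-Hakimi realization with uniform edge confidence 0.95.
    """
    return _graph_from_plan(_PPI_COUNT_PLAN)


def ppi_hub_fixture() -> nx.Graph:
    """Synthetic 26-node PPI graph whose top-3 hubs by degree are exactly
    MTOR (23), MAP2K1 (14) and EGFR (13); 172 edges (see the degree-plan
    note for why the full 176-edge count is incompatible with that hub
    ordering)."""
    return _graph_from_plan(_PPI_HUB_PLAN)
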