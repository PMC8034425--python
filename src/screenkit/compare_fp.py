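"""COMPARE-style anticancer fingerprint correlation.

A fingerprint is one compound's vector of per-cell-line potencies
(-log10 of the molar endpoint concentration; larger = more potent) for one
of the GI50 / TGI / LC50 endpoints. A seed compound is correlated against a
library by Pearson correlation over the cell lines present in *both*
fingerprints (pairwise-complete, no imputation); the overlap size is the
common-cell-line count (CCLC). High correlation between fingerprints is the
classic signal of a shared mechanism of action.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import Censor

ENDPOINTS = ("GI50", "TGI", "LC50")

#: Default minimum overlap: real NCI60 runs overlap on ~44-57 lines, and a
#: high r over a handful of lines is noise, not mechanism.
DEFAULT_MIN_COMMON = 25


@dataclass
class Fingerprint:
    compound_id: str
    endpoint: str
    values: pd.Series  # index: cell line, values: -log10(molar); NaN = missing

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        self.values = self.values.astype(float)
        present = self.values.dropna()
        if not np.isfinite(present.to_numpy()).all():
            raise ValueError("fingerprint values must be finite where present")


@dataclass(frozen=True)
class CompareHit:
    compound_id: str
    r: float
    n_common: int


def to_fingerprint(
    params_table: pd.DataFrame, endpoint: str, compound_id: str = "seed"
) -> Fingerprint:
    """Build a potency fingerprint from a screen summary table.

    Exact endpoint concentrations become -log10(molar); censored endpoints
    become missing cells.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    col = endpoint.lower()
    values = {}
    for _, row in params_table.iterrows():
        if row[f"{col}_censor"] == Censor.EXACT.value:
            values[row["cell_line"]] = -math.log10(row[f"{col}_uM"] * 1e-6)
        else:
            values[row["cell_line"]] = np.nan
    return Fingerprint(compound_id, endpoint, pd.Series(values))


def pairwise_correlation(
    seed: Fingerprint,
    other: Fingerprint,
    min_common: int = DEFAULT_MIN_COMMON,
) -> CompareHit | None:
    """Pearson correlation over cell lines present in both fingerprints.

    Returns ``None`` (a rejection, not an error) when fewer than
    ``min_common`` lines overlap or either restricted vector is constant.
    Endpoint mismatch is an error.
    """
    if seed.endpoint != other.endpoint:
        raise ValueError(
            f"endpoint mismatch: {seed.endpoint} vs {other.endpoint}"
        )
    joined = pd.concat([seed.values, other.values], axis=1, join="inner").dropna()
    n = len(joined)
    if n < max(min_common, 2):
        return None
    x = joined.iloc[:, 0].to_numpy()
    y = joined.iloc[:, 1].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return CompareHit(other.compound_id, r, n)


def rank_library(
    seed: Fingerprint,
    library: list[Fingerprint],
    min_common: int = DEFAULT_MIN_COMMON,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Rank a compound library by fingerprint correlation with the seed.

    Rows sorted by r descending, ties broken by n_common descending then
    compound id; rejected comparisons are dropped. Columns: rank,
    compound_id, r, n_common.
    """
    hits = []
    for fp in library:
        hit = pairwise_correlation(seed, fp, min_common=min_common)
        if hit is not None:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.r, -h.n_common, h.compound_id))
    if top_k is not None:
        hits = hits[:top_k]
    return pd.DataFrame(
        {
            "rank": range(1, len(hits) + 1),
            "compound_id": [h.compound_id for h in hits],
            "r": [h.r for h in hits],
            "n_common": [h.n_common for h in hits],
        }
    )


def library_from_matrix(matrix: pd.DataFrame, endpoint: str = "GI50") -> list[Fingerprint]:
    """Fingerprints from a CSV-style matrix (rows compounds, cols cell lines)."""
    return [
        Fingerprint(str(cid), endpoint, row)
        for cid, row in matrix.iterrows()
    ]
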