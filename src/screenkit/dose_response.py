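"""NCI60 five-dose screening mathematics.

Percent growth from the three sulforhodamine-B absorbance signals
(time-zero Tz, control C, treated Ti), the three endpoint concentrations
(GI50 at +50% growth, TGI at 0, LC50 at -50%), and per-panel summaries.

Percent growth is the standard piecewise normalization::

    PG = 100 * (Ti - Tz) / (C - Tz)   if Ti >= Tz   (growth inhibition)
    PG = 100 * (Ti - Tz) / Tz         if Ti <  Tz   (lethality)

Endpoint concentrations are located by linear interpolation of PG against
log10(concentration), matching the log-spaced five-dose design. Endpoints
not bracketed by the tested range are censored and reported as
``"> max"`` / ``"< min"``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


class Censor(enum.Enum):
    EXACT = "exact"
    ABOVE_MAX = "above_max"
    BELOW_MIN = "below_min"


@dataclass(frozen=True)
class EndpointEstimate:
    """A single endpoint concentration in molar, possibly censored.

    For censored estimates ``value`` holds the censoring bound (the max or
    min tested concentration).
    """

    value: float
    censor: Censor

    def as_uM_string(self, sig: int = 3) -> str:
        um = self.value * 1e6
        if self.censor is Censor.ABOVE_MAX:
            return f"> {um:.{sig}g}"
        if self.censor is Censor.BELOW_MIN:
            return f"< {um:.{sig}g}"
        return f"{um:.{sig}g}"


@dataclass
class DosePlate:
    """One cell line's raw five-dose record (molar concentrations)."""

    cell_line: str
    panel: str
    tz: float
    c: float
    doses: list[tuple[float, float]]  # (concentration_M, ti)

    def __post_init__(self) -> None:
        if len(self.doses) < 2:
            raise ValueError("a plate needs at least 2 doses")
        concs = [c for c, _ in self.doses]
        if any(c <= 0 for c in concs) or any(
            b <= a for a, b in zip(concs, concs[1:])
        ):
            raise ValueError("concentrations must be positive and strictly increasing")
        if min(self.tz, self.c) < 0 or any(ti < 0 for _, ti in self.doses):
            raise ValueError("signals must be non-negative")
        if self.c == self.tz:
            raise ValueError("control equals time-zero: undefined growth window")


@dataclass
class ResponseCurve:
    concentrations: list[float]  # molar, ascending
    pg: list[float]              # percent growth, may be < 0


@dataclass
class ResponseParams:
    cell_line: str
    panel: str
    gi50: EndpointEstimate
    tgi: EndpointEstimate
    lc50: EndpointEstimate


GI50_LEVEL, TGI_LEVEL, LC50_LEVEL = 50.0, 0.0, -50.0


def percent_growth(ti: float, tz: float, c: float) -> float:
    """Piecewise percent growth; continuous (=0) at Ti == Tz."""
    if c == tz:
        raise ValueError("control equals time-zero: percent growth undefined")
    if ti >= tz:
        return 100.0 * (ti - tz) / (c - tz)
    return 100.0 * (ti - tz) / tz


def growth_inhibition(growth_value: float) -> tuple[float, bool]:
    """Convert a single-dose growth value to percent growth inhibition.

    Returns ``(inhibition, lethal)``. Positive growth values convert as
    100 - growth (a growth of 60 means 40% inhibition); negative values
    indicate net cell kill and are returned unchanged with ``lethal=True``.
    """
    if growth_value < 0:
        return growth_value, True
    return 100.0 - growth_value, False


def endpoint_concentration(curve: ResponseCurve, level: float) -> EndpointEstimate:
    """Lowest concentration where PG crosses ``level``.

    Linear interpolation of PG vs log10(concentration) between the first
    bracketing pair, scanning from the low-concentration side (conservative
    under noise-induced non-monotonicity). Exact grid hits are returned
    as-is. A curve entirely above the level is censored ``> max``; one that
    is already at or below the level at the lowest dose (or entirely below)
    is censored ``< min``.
    """
    concs, pg = curve.concentrations, curve.pg
    if not concs:
        raise ValueError("empty response curve")
    if any(not math.isfinite(v) for v in pg):
        raise ValueError("non-finite percent-growth values")

    if pg[0] == level:
        return EndpointEstimate(concs[0], Censor.EXACT)
    if pg[0] < level:
        return EndpointEstimate(concs[0], Censor.BELOW_MIN)
    for i in range(1, len(concs)):
        if pg[i] == level:
            return EndpointEstimate(concs[i], Censor.EXACT)
        if pg[i] < level:
            x0, x1 = math.log10(concs[i - 1]), math.log10(concs[i])
            frac = (pg[i - 1] - level) / (pg[i - 1] - pg[i])
            return EndpointEstimate(10 ** (x0 + frac * (x1 - x0)), Censor.EXACT)
    return EndpointEstimate(concs[-1], Censor.ABOVE_MAX)


def analyze_plate(plate: DosePlate) -> ResponseParams:
    """Percent growth per dose, then GI50 / TGI / LC50."""
    curve = ResponseCurve(
        concentrations=[c for c, _ in plate.doses],
        pg=[percent_growth(ti, plate.tz, plate.c) for _, ti in plate.doses],
    )
    return ResponseParams(
        cell_line=plate.cell_line,
        panel=plate.panel,
        gi50=endpoint_concentration(curve, GI50_LEVEL),
        tgi=endpoint_concentration(curve, TGI_LEVEL),
        lc50=endpoint_concentration(curve, LC50_LEVEL),
    )


_ENDPOINTS = ("gi50", "tgi", "lc50")


def summarize_screen(
    plates: list[DosePlate],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze every plate and summarize endpoint ranges per panel.

    Returns ``(params, panel_ranges)``. ``params`` has one row per cell line
    with endpoint values in uM plus censor flags. ``panel_ranges`` has one
    row per (panel, endpoint) with the [min, max] over exact values and the
    number of censored lines (censored values are excluded from ranges).
    """
    if not plates:
        raise ValueError("no plates supplied")
    rows = []
    for plate in plates:
        params = analyze_plate(plate)
        row: dict = {"cell_line": params.cell_line, "panel": params.panel}
        for name in _ENDPOINTS:
            est: EndpointEstimate = getattr(params, name)
            row[f"{name}_uM"] = est.value * 1e6
            row[f"{name}_censor"] = est.censor.value
            row[f"{name}_report"] = est.as_uM_string()
        rows.append(row)
    params_df = pd.DataFrame(rows)

    range_rows = []
    for panel, group in params_df.groupby("panel", sort=True):
        for name in _ENDPOINTS:
            exact = group.loc[
                group[f"{name}_censor"] == Censor.EXACT.value, f"{name}_uM"
            ]
            range_rows.append(
                {
                    "panel": panel,
                    "endpoint": name.upper(),
                    "min_uM": exact.min() if len(exact) else np.nan,
                    "max_uM": exact.max() if len(exact) else np.nan,
                    "n_exact": int(len(exact)),
                    "n_censored": int(len(group) - len(exact)),
                }
            )
    return params_df, pd.DataFrame(range_rows)


def read_plates_tsv(path) -> list[DosePlate]:
    """Read plates from long-format TSV: cell_line, panel, tz, c, conc_M, ti."""
    df = pd.read_csv(path, sep="\t")
    plates = []
    for (cell_line, panel, tz, c), grp in df.groupby(
        ["cell_line", "panel", "tz", "c"], sort=False
    ):
        grp = grp.sort_values("conc_M")
        plates.append(
            DosePlate(
                cell_line=cell_line,
                panel=panel,
                tz=float(tz),
                c=float(c),
                doses=list(zip(grp["conc_M"].astype(float), grp["ti"].astype(float))),
            )
        )
    return plates
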