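"""Trend-model classification against Stockholm Convention milestones.

Each colony x HFR class fit maps to one of five trend models (or "no
significant model"):

IT   increasing trend: a breakpoint with rising concentrations after it
LI   listing improvement: breakpoint after the listing year, then decline
NI   nomination improvement: breakpoint after nomination (up to and
     including listing), then decline
EI   early improvement: breakpoint before nomination, then decline
CT   consistent trend: no breakpoint; a significant monotone slope
NS   no significant model

The milestone registry carries, per HFR class, the year the chemical class
was nominated to Annex A of the Stockholm Convention and the year it was
listed.  ln-scale slopes convert to percent annual change via
(exp(beta) - 1) x 100.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from hfrtrends.segmented import SegmentedFit

__all__ = [
    "MilestoneRegistry",
    "TREND_LABELS",
    "classify",
    "classify_row",
    "percent_annual_change",
    "percent_annual_change_rounded",
    "load_reference_fits",
    "tabulate",
]

TREND_LABELS = ("IT", "LI", "NI", "EI", "CT", "NS")


@dataclass(frozen=True)
class MilestoneRegistry:
    """hfr_class -> (nomination year, listing year) under Annex A."""

    table: tuple[tuple[str, int, int], ...] = (
        # For the PBDE sum the earlier of the two commercial-mixture
        # nominations (penta 2005, octa 2006) is the registry default.
        ("Sum11PBDE", 2005, 2009),
        ("HBCDD", 2008, 2013),
        ("BDE209", 2013, 2017),
        ("SumDP", 2019, 2023),
    )

    def __post_init__(self) -> None:
        for cls, nom, lst in self.table:
            if nom > lst:
                raise ValueError(
                    f"{cls}: nomination year {nom} after listing year {lst}")

    def years(self, hfr_class: str) -> tuple[int, int]:
        for cls, nom, lst in self.table:
            if cls == hfr_class:
                return nom, lst
        raise KeyError(f"no milestone entry for HFR class {hfr_class!r}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MilestoneRegistry":
        df = pd.read_csv(path)
        return cls(tuple(
            (r.hfr_class, int(r.nomination_year), int(r.listing_year))
            for r in df.itertuples()))

    @classmethod
    def default(cls) -> "MilestoneRegistry":
        with importlib.resources.as_file(
                importlib.resources.files("hfrtrends.data") / "milestones.csv"
        ) as p:
            return cls.from_csv(p)


def classify_row(fit_type: str, psi: float | None, slope_after: float | None,
                 slope: float, p_value: float, hfr_class: str,
                 milestones: MilestoneRegistry, alpha: float = 0.05) -> str:
    """Label one fit row; total and deterministic over its input domain.

    ``slope`` is the single slope of a linear fit (ignored for segmented
    rows); significance is gated on ``p_value`` at ``alpha``.  Breakpoints
    on a milestone boundary resolve inclusively upward: psi equal to the
    listing year (or the nomination year) counts as within the
    nomination-to-listing window (NI).
    """
    if not np.isfinite(p_value) or p_value > alpha:
        return "NS"
    if fit_type == "segmented":
        if psi is None or slope_after is None:
            raise ValueError("segmented row needs psi and slope_after")
        if slope_after > 0:
            return "IT"
        nomination, listing = milestones.years(hfr_class)
        if psi > listing:
            return "LI"
        if psi >= nomination:
            return "NI"
        return "EI"
    if fit_type == "linear":
        return "CT"
    return "NS"  # failed fits carry no significant model


def classify(fit: SegmentedFit, hfr_class: str,
             milestones: MilestoneRegistry | None = None,
             alpha: float = 0.05) -> str:
    """Label a :class:`SegmentedFit` under the milestone registry."""
    milestones = milestones or MilestoneRegistry()
    return classify_row(fit.fit_type, fit.psi, fit.slope_after,
                        fit.slope_before, fit.p_value, hfr_class,
                        milestones, alpha)


def percent_annual_change(beta: float) -> float:
    """Signed percent change per year implied by a ln-scale slope."""
    if not np.isfinite(beta):
        raise ValueError("slope must be finite")
    return (np.exp(beta) - 1.0) * 100.0


def percent_annual_change_rounded(beta: float) -> int:
    """Integer percent magnitude, rounded half away from zero.

    The direction is carried by the sign of ``beta``; the returned value is
    the magnitude as printed in monitoring reports ("an annual decrease of
    34%" for beta = -0.42).
    """
    pct = abs(float(percent_annual_change(beta)))
    return int(Decimal(repr(pct)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def load_reference_fits() -> pd.DataFrame:
    """Published per-colony trend-fit summaries, 2008-2023 herring gull
    monitoring programs (17 colonies x 4 HFR classes).

    Columns mirror the program's trend tables: breakpoint year +- SE,
    segment slopes +- SE (single slope for linear fits), the reported t and
    p, and the published trend-model label (empty when no model was
    significant).
    """
    with importlib.resources.as_file(
            importlib.resources.files("hfrtrends.data")
            / "reference_trend_fits.csv") as p:
        df = pd.read_csv(p)
    df["label"] = df["label"].fillna("")
    return df


def tabulate(fits: pd.DataFrame, milestones: MilestoneRegistry | None = None,
             alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Classify a table of fits and tally the trend models.

    ``fits`` needs columns hfr_class, colony, fit_type, psi, slope_before,
    slope_after, p_value (one row per colony x class; duplicates raise).
    Returns the table with an ``assigned_label`` column plus a tally dict:
    total comparisons, per-label counts, the non-significant count and
    per-class consistent-decline counts.
    """
    milestones = milestones or MilestoneRegistry()
    if fits.duplicated(["hfr_class", "colony"]).any():
        dup = fits[fits.duplicated(["hfr_class", "colony"])].iloc[0]
        raise ValueError(f"duplicate fit for ({dup['hfr_class']}, {dup['colony']})")
    out = fits.copy()
    out["assigned_label"] = [
        classify_row(r.fit_type,
                     None if pd.isna(r.psi) else float(r.psi),
                     None if pd.isna(r.slope_after) else float(r.slope_after),
                     float(r.slope_before), float(r.p_value),
                     r.hfr_class, milestones, alpha)
        for r in out.itertuples()
    ]
    label_counts = {lab: int((out["assigned_label"] == lab).sum())
                    for lab in TREND_LABELS}
    ct_declines = out[(out["assigned_label"] == "CT")
                      & (out["slope_before"] < 0)]
    tallies = {
        "total": int(len(out)),
        "labels": label_counts,
        "n_not_significant": label_counts["NS"],
        "n_ct_declines": int(len(ct_declines)),
        "ct_declines_by_class": {
            cls: int((ct_declines["hfr_class"] == cls).sum())
            for cls in out["hfr_class"].unique()
        },
    }
    return out, tallies
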