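"""Rendering of descriptive and decomposition tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decomposition import DecompositionReport
from .estimation import proportion_diff_test
from .survey import MicroData, ModelSpec, NONPOOR, POOR

__all__ = ["render_descriptive_table", "render_decomposition_table", "format_table"]


def render_descriptive_table(
    micro: MicroData,
    spec: ModelSpec,
    digits: int = 3,
    cluster: bool = False,
) -> pd.DataFrame:
    """Descriptive statistics by wealth group, one row per variable level.

    Cells are weighted means with (binomial) standard deviations, the
    nonpoor-minus-poor differential with its standard error and significance
    stars at the 10/5/1% levels.  Group observation counts are attached as
    ``df.attrs["n_poor"]`` / ``df.attrs["n_nonpoor"]``.
    """
    rows = []

    def add(variable, level):
        t = proportion_diff_test(micro, spec, variable, level=level, cluster=cluster)
        rows.append(
            {
                "variable": variable,
                "level": str(t.level),
                "poor_mean": round(t.poor_share, digits),
                "poor_sd": round(t.poor_sd, digits),
                "nonpoor_mean": round(t.nonpoor_share, digits),
                "nonpoor_sd": round(t.nonpoor_sd, digits),
                "differential": round(t.differential, digits),
                "se": round(t.se, digits),
                "stars": t.stars,
            }
        )

    add(spec.outcome_name, None)
    for block in spec.blocks:
        if block.kind == "binary":
            add(block.name, block.coded_levels[0])
        else:
            for lv in block.levels:
                add(block.name, lv)

    df = pd.DataFrame(rows)
    grp = micro.frame["group"]
    df.attrs["n_poor"] = int((grp == POOR).sum())
    df.attrs["n_nonpoor"] = int((grp == NONPOOR).sum())
    return df


def render_decomposition_table(
    report: DecompositionReport,
    digits_points: int = 3,
    digits_pct: int = 2,
) -> pd.DataFrame:
    """Flat table: one row per block per benchmark plus totals rows.

    Probability-point columns are rounded to ``digits_points``, percent
    shares to ``digits_pct``.  The totals rows carry the aggregate explained
    and unexplained portions.
    """
    df = report.to_frame().copy()
    df["contribution"] = df["contribution"].round(digits_points)
    df["se"] = df["se"].round(digits_points)
    df["percent_of_gap"] = df["percent_of_gap"].round(digits_pct)
    return df


def format_table(df: pd.DataFrame, footer: str | None = None) -> str:
    """Plain-text rendering with an optional footer line."""
    text = df.to_string(index=False, na_rep="")
    if footer is None and ("n_poor" in df.attrs):
        footer = f"Obs. poor: {df.attrs['n_poor']}, nonpoor: {df.attrs['n_nonpoor']}"
    if footer:
        text += "\n" + footer
    return text
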