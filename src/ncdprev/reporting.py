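"""Summary artefacts: absolute/relative change tables and trend plots.

Changes are computed on the prevalence percentage scale: the absolute
change is the difference in percentage points between a comparison year
and a base year, the relative change is 100 x absolute / base.  Relative
changes are computed from unrounded prevalences and rounded only on
output, so a table recomputed from its own unrounded cells reproduces
itself exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datasets import SEX_LABELS


@dataclass(frozen=True)
class ChangeSummary:
    indicator: str
    sex: int
    base_year: int
    comparison_year: int
    base_prevalence_pct: float
    absolute_change_pp: float
    relative_change_pct: float | None


def relative_change(base_pct: float, absolute_pp: float) -> float | None:
    """100 x absolute change / base prevalence; None when the base is 0."""
    if base_pct == 0:
        return None
    return 100.0 * absolute_pp / base_pct


def change_table(series: pd.DataFrame, base_year: int,
                 comparison_years: list[int],
                 decimals: int = 1) -> pd.DataFrame:
    """Absolute and relative changes from *base_year* per indicator and
    sex.  *series* is a prevalence series (proportions); output is on the
    percentage scale, rounded to *decimals* for display with relative
    changes computed from unrounded values."""
    idx = series.set_index(["indicator", "sex", "year"])["prevalence"]
    rows = []
    for (ind, sex) in sorted({(i, s) for i, s, _ in idx.index}):
        if (ind, sex, base_year) not in idx.index:
            raise ValueError(f"series lacks base year {base_year} for {ind}/{sex}")
        base = 100.0 * float(idx.loc[(ind, sex, base_year)])
        for cy in comparison_years:
            if (ind, sex, cy) not in idx.index:
                raise ValueError(f"series lacks year {cy} for {ind}/{sex}")
            comp = 100.0 * float(idx.loc[(ind, sex, cy)])
            abs_pp = comp - base
            rel = relative_change(base, abs_pp)
            if rel is None:
                import warnings

                warnings.warn(f"base prevalence 0 for {ind}/{sex}; "
                              "relative change undefined")
            rows.append(ChangeSummary(ind, int(sex), base_year, cy,
                                      round(base, decimals),
                                      round(abs_pp, decimals),
                                      None if rel is None else round(rel, decimals)))
    return pd.DataFrame([r.__dict__ for r in rows])


def change_table_markdown(table: pd.DataFrame) -> str:
    """Render a change table as GitHub-flavoured Markdown."""
    header = ("| Indicator | Sex | Base year | Year | Base (%) | "
              "Absolute change (pp) | Relative change (%) |")
    sep = "|" + "---|" * 7
    lines = [header, sep]
    for _, r in table.iterrows():
        rel = "" if pd.isna(r["relative_change_pct"]) else f"{r['relative_change_pct']:+.1f}"
        lines.append(
            f"| {r['indicator']} | {SEX_LABELS.get(r['sex'], r['sex'])} | "
            f"{r['base_year']} | {r['comparison_year']} | "
            f"{r['base_prevalence_pct']:.1f} | {r['absolute_change_pp']:+.1f} | {rel} |")
    return "\n".join(lines)


def trend_plot(series: pd.DataFrame, indicators: list[str], out_path: str,
               last_observed_year: int | None = None) -> str:
    """Per-sex prevalence curves over observed and projected years with
    shaded prediction bands and a visual break at the last observed
    wave.  Returns the output path."""
    known = set(series["indicator"])
    for ind in indicators:
        if ind not in known:
            raise ValueError(f"unknown indicator {ind!r}; series has {sorted(known)}")
    fig, axes = plt.subplots(1, len(indicators),
                             figsize=(4.2 * len(indicators), 3.6),
                             squeeze=False, sharey=False)
    colors = {0: "tab:blue", 1: "tab:red"}
    for ax, ind in zip(axes[0], indicators):
        sub = series[series["indicator"] == ind]
        for sex, g in sub.groupby("sex"):
            g = g.sort_values("year")
            ax.plot(g["year"], 100 * g["prevalence"], color=colors.get(sex, "k"),
                    label=SEX_LABELS.get(sex, str(sex)))
            ax.fill_between(g["year"], 100 * g["interval_low"],
                            100 * g["interval_high"],
                            color=colors.get(sex, "k"), alpha=0.2, linewidth=0)
        if last_observed_year is not None and (sub["year"] > last_observed_year).any():
            ax.axvline(last_observed_year, color="grey", linestyle=":", linewidth=1)
        ax.set_title(ind)
        ax.set_xlabel("year")
        ax.set_ylabel("prevalence (%)")
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
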