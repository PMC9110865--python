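"""Center-level safety, efficacy and accuracy metrics, and the data behind
the five standard refractive-surgery outcome panels.

Definitions (decimal visual acuity throughout):

* safety index   = mean of per-eye post-CDVA / pre-CDVA (with sample SD);
* efficacy index = mean of per-eye post-UDVA / pre-CDVA;
* CDVA line change = (logMAR pre - logMAR post) / 0.1, rounded;
  positive values are lines gained;
* accuracy within +/- t D = share of eyes whose 3-month SE is within t of
  the attempted target (plano by default, or a per-eye ``target`` column).

``standard_graphs`` assembles the conventional five panels: cumulative UDVA
distribution over Snellen bins, CDVA line-change histogram, attempted vs
achieved SE correction pairs, SE accuracy histogram, and the refractive
astigmatism (cylinder magnitude) histogram.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data_model import Cohort, decimal_to_logmar

__all__ = [
    "OutcomeSummary",
    "safety_index",
    "efficacy_index",
    "cdva_line_change",
    "accuracy_within",
    "standard_graphs",
    "SNELLEN_BINS",
]

#: Panel A bins: (label, decimal-acuity threshold); cumulative "x or better".
SNELLEN_BINS: tuple[tuple[str, float], ...] = (
    ("20/12.5", 1.6),
    ("20/16", 1.25),
    ("20/20", 1.0),
    ("20/25", 0.8),
    ("20/32", 0.63),
    ("20/40", 0.5),
)

_SE_HIST_EDGES = (-2.0, -1.5, -1.0, -0.5, -0.25, 0.25, 0.5, 1.0, 1.5, 2.0)
_CYL_HIST_EDGES = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0)

_EPS = 1e-9


@dataclasses.dataclass
class OutcomeSummary:
    """One center's scalar outcome indices plus the five panel tabulations."""

    center: str
    n_eyes: int
    safety_index_mean: float
    safety_index_sd: float
    efficacy_index_mean: float
    efficacy_index_sd: float
    pct_udva_2020_or_better: float
    pct_udva_ge_preop_cdva: float
    pct_within_050: float
    pct_within_100: float
    cdva_line_change_histogram: dict[int, int]
    panels: dict[str, object]


def _frame(records) -> pd.DataFrame:
    if isinstance(records, Cohort):
        return records.df
    df = pd.DataFrame(records)
    if len(df) == 0:
        raise ValueError("empty record collection")
    return df


def _mean_sd(ratios: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    return mean, sd


def safety_index(records) -> tuple[float, float]:
    """Mean and sample SD of per-eye post-CDVA / pre-CDVA (decimal)."""
    df = _frame(records)
    if np.any(df["pre_cdva"] <= 0) or np.any(df["post_cdva"] <= 0):
        raise ValueError("acuities must be positive")
    return _mean_sd((df["post_cdva"] / df["pre_cdva"]).to_numpy(dtype=float))


def efficacy_index(records) -> tuple[float, float]:
    """Mean and sample SD of per-eye post-UDVA / pre-CDVA (decimal)."""
    df = _frame(records)
    if np.any(df["pre_cdva"] <= 0) or np.any(df["post_udva"] <= 0):
        raise ValueError("acuities must be positive")
    return _mean_sd((df["post_udva"] / df["pre_cdva"]).to_numpy(dtype=float))


def cdva_line_change(records) -> dict[int, int]:
    """Histogram of CDVA logMAR line changes (positive = gained)."""
    df = _frame(records)
    lines = np.rint(
        (decimal_to_logmar(df["pre_cdva"].to_numpy(dtype=float))
         - decimal_to_logmar(df["post_cdva"].to_numpy(dtype=float))) / 0.1
    ).astype(int)
    values, counts = np.unique(lines, return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts)}


def accuracy_within(records, tolerance: float) -> float:
    """Percent of eyes whose 3-month SE is within ``tolerance`` D of target.

    The target is plano (0 D residual) unless the records carry a per-eye
    ``target`` column.
    """
    df = _frame(records)
    target = df["target"].to_numpy(dtype=float) if "target" in df.columns else 0.0
    residual = df["post_se_3m"].to_numpy(dtype=float) - target
    return float(100.0 * np.mean(np.abs(residual) <= tolerance + _EPS))


def _udva_panel(post_udva: np.ndarray) -> list[dict[str, float]]:
    rows = []
    n = post_udva.size
    for label, threshold in SNELLEN_BINS:
        rows.append({
            "acuity": label,
            "cum_pct": float(100.0 * np.mean(post_udva >= threshold - _EPS)),
        })
    rows.append({"acuity": "worse", "cum_pct": 100.0})
    assert all(rows[i]["cum_pct"] <= rows[i + 1]["cum_pct"] + _EPS
               for i in range(len(rows) - 1))
    del n
    return rows


def _histogram(values: np.ndarray, edges: tuple[float, ...]) -> list[dict[str, object]]:
    full = np.concatenate(([-np.inf], edges, [np.inf]))
    counts, _ = np.histogram(values, bins=full)
    labels = ([f"< {edges[0]:g}"]
              + [f"[{a:g}, {b:g})" for a, b in zip(edges[:-1], edges[1:])]
              + [f">= {edges[-1]:g}"])
    return [{"bin": lab, "count": int(c)} for lab, c in zip(labels, counts)]


def standard_graphs(records, center: str | None = None) -> OutcomeSummary:
    """Assemble the five standard outcome panels and scalar indices.

    Panel E tabulates the magnitude of the refractive cylinder: the
    postoperative ``post_cd`` column when present, otherwise the
    preoperative cylinder (the per-eye schema carries no postoperative
    cylinder by default).
    """
    df = _frame(records)
    n = len(df)
    center = center if center is not None else str(df["center_id"].iloc[0]) \
        if "center_id" in df.columns else "?"

    s_mean, s_sd = safety_index(df)
    e_mean, e_sd = efficacy_index(df)
    post_udva = df["post_udva"].to_numpy(dtype=float)
    line_hist = cdva_line_change(df)

    target = df["target"].to_numpy(dtype=float) if "target" in df.columns else 0.0
    residual = df["post_se_3m"].to_numpy(dtype=float) - target
    attempted = target - df["pre_se"].to_numpy(dtype=float)
    achieved = (df["post_se_3m"] - df["pre_se"]).to_numpy(dtype=float)

    cyl_col = "post_cd" if "post_cd" in df.columns else "pre_cd"
    cyl = np.abs(df[cyl_col].to_numpy(dtype=float))

    panels = {
        "udva_cumulative": _udva_panel(post_udva),
        "cdva_line_change": {str(k): v for k, v in sorted(line_hist.items())},
        "attempted_vs_achieved": [
            {"attempted": float(a), "achieved": float(b)}
            for a, b in zip(attempted, achieved)
        ],
        "se_accuracy_histogram": _histogram(residual, _SE_HIST_EDGES),
        "astigmatism_histogram": {
            "cylinder_source": cyl_col,
            "bins": _histogram(cyl, _CYL_HIST_EDGES),
        },
    }
    return OutcomeSummary(
        center=center,
        n_eyes=n,
        safety_index_mean=s_mean,
        safety_index_sd=s_sd,
        efficacy_index_mean=e_mean,
        efficacy_index_sd=e_sd,
        pct_udva_2020_or_better=float(100.0 * np.mean(post_udva >= 1.0 - _EPS)),
        pct_udva_ge_preop_cdva=float(100.0 * np.mean(
            post_udva >= df["pre_cdva"].to_numpy(dtype=float) - _EPS)),
        pct_within_050=accuracy_within(df, 0.50),
        pct_within_100=accuracy_within(df, 1.00),
        cdva_line_change_histogram=line_hist,
        panels=panels,
    )
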