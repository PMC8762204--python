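"""Agreement statistics for validating event detections against raters.

Implements the two-way mixed-effects intraclass correlation coefficient
(single rater, consistency form by default) from the two-way ANOVA mean
squares, the conventional reliability bands (poor < 0.5, moderate 0.5-0.75,
good 0.75-0.9, excellent >= 0.9), Bland-Altman bias and 95% limits of
agreement, detection-count comparison across sources, and Pearson
correlation with the usual strength labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementResult", "icc_two_way_mixed", "classify_icc", "bland_altman",
    "BlandAltmanResult", "compare_detection_counts", "pearson_r",
    "correlation_strength", "agreement_by_muscle", "bland_altman_plot",
]


@dataclass
class AgreementResult:
    """ICC + Bland-Altman summary for one paired event-time series."""

    icc: float
    icc_class: str
    p_value: float
    bias: float
    loa_low: float
    loa_high: float
    n_pairs: int
    n_dropped: int = 0


@dataclass
class BlandAltmanResult:
    """Bias, limits of agreement, and the plotting payload (means vs diffs)."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n_pairs: int
    means: np.ndarray
    diffs: np.ndarray


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok], int((~ok).sum())


def icc_two_way_mixed(x, y, form: str = "consistency") -> tuple[float, float]:
    """Two-way mixed-effects, single-rater ICC of two paired series.

    ``form='consistency'`` (ICC(3,1)) treats a systematic offset between the
    raters as irrelevant — appropriate when fixed raters are compared and the
    offset is reported separately as the Bland-Altman bias. ``form='agreement'``
    (absolute agreement, ICC(2,1)-style mean squares with fixed raters)
    penalizes the offset. Pairs with a missing member are dropped.

    Returns (icc, p) where p comes from the F test of the between-target
    mean square against the residual. Zero variance in both series makes the
    ICC undefined (NaN, p = NaN).
    """
    if form not in ("consistency", "agreement"):
        raise ValueError("form must be 'consistency' or 'agreement'")
    x, y, _ = _pairwise_complete(x, y)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if mse < 1e-12 * max(msr, msc, 1.0):  # clamp catastrophic cancellation
        mse = 0.0
    if ss_total == 0:
        return float("nan"), float("nan")
    if form == "consistency":
        denom = msr + (k - 1) * mse
        icc = (msr - mse) / denom if denom > 0 else float("nan")
    else:
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        icc = (msr - mse) / denom if denom > 0 else float("nan")
    if mse == 0:
        p = 0.0 if msr > 0 else float("nan")
    else:
        f = msr / mse
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


def classify_icc(icc: float) -> str:
    """Reliability band: poor < 0.5 <= moderate < 0.75 <= good < 0.9 <= excellent."""
    if not np.isfinite(icc):
        return "undefined"
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def bland_altman(x, y) -> BlandAltmanResult:
    """Bias (mean of x - y) and 95% limits of agreement (bias +/- 1.96 SD)."""
    x, y, _ = _pairwise_complete(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 complete pairs")
    diffs = x - y
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        sd_diff=sd, n_pairs=x.size, means=(x + y) / 2.0, diffs=diffs)


def pearson_r(a, b) -> tuple[float, float]:
    """Product-moment correlation and two-sided p; zero variance -> NaN."""
    a, b, _ = _pairwise_complete(a, b)
    if a.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def correlation_strength(r: float) -> str:
    """Label |r|: small 0.1-0.3, medium 0.3-0.5, large 0.5-1."""
    a = abs(r)
    if not np.isfinite(a):
        return "undefined"
    if a < 0.1:
        return "negligible"
    if a < 0.3:
        return "small"
    if a < 0.5:
        return "medium"
    return "large"


def compare_detection_counts(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Count non-missing onsets per muscle for each source.

    ``tables`` maps a source label (e.g. 'algorithm', 'assessor1') to an
    event table in the events-CSV schema. Returns muscles x sources counts.
    """
    counts: dict[str, pd.Series] = {}
    for source, tbl in tables.items():
        onsets = tbl[(tbl["event_kind"] == "onset") & (~tbl["missing"])]
        counts[source] = onsets.groupby("muscle").size()
    out = pd.DataFrame(counts).fillna(0).astype(int)
    out.index.name = "muscle"
    return out


def agreement_by_muscle(table_a: pd.DataFrame, table_b: pd.DataFrame,
                        event_kind: str = "onset",
                        form: str = "consistency") -> pd.DataFrame:
    """Per-muscle ICC + Bland-Altman between two event tables.

    Tables follow the events-CSV schema; rows are matched on (participant,
    muscle, breath_index, event_kind) and pairs with either member missing
    are dropped (their count is reported as n_dropped).
    """
    keys = ["participant", "muscle", "breath_index", "event_kind"]
    a = table_a[table_a["event_kind"] == event_kind]
    b = table_b[table_b["event_kind"] == event_kind]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    rows = []
    for muscle, grp in merged.groupby("muscle"):
        x = grp["time_ms_a"].to_numpy(dtype=float)
        y = grp["time_ms_b"].to_numpy(dtype=float)
        xs, ys, dropped = _pairwise_complete(x, y)
        if xs.size < 2:
            rows.append({"muscle": muscle, "icc": np.nan, "icc_class": "undefined",
                         "p_value": np.nan, "bias": np.nan, "loa_low": np.nan,
                         "loa_high": np.nan, "n_pairs": int(xs.size),
                         "n_dropped": dropped})
            continue
        icc, p = icc_two_way_mixed(xs, ys, form=form)
        ba = bland_altman(xs, ys)
        rows.append({"muscle": muscle, "icc": icc, "icc_class": classify_icc(icc),
                     "p_value": p, "bias": ba.bias, "loa_low": ba.loa_low,
                     "loa_high": ba.loa_high, "n_pairs": ba.n_pairs,
                     "n_dropped": dropped})
    return pd.DataFrame(rows, columns=["muscle", "icc", "icc_class", "p_value",
                                       "bias", "loa_low", "loa_high",
                                       "n_pairs", "n_dropped"])


def relative_to_breaths(events: pd.DataFrame, breaths: pd.DataFrame) -> pd.DataFrame:
    """Re-express event times as phase differences from breath landmarks.

    Onset rows become dPon (time minus the breath's inspiratory onset),
    offset rows dPoff (time minus the inspiratory offset). Agreement between
    raters is conventionally computed on these phase differences, not on
    absolute session times, so that between-breath spacing does not inflate
    the correlation. ``breaths`` needs breath_index, insp_onset, insp_offset.
    """
    ref = breaths.set_index("breath_index")
    out = events.copy()
    anchor = out.apply(
        lambda r: ref.loc[r["breath_index"],
                          "insp_onset" if r["event_kind"] == "onset" else "insp_offset"],
        axis=1)
    out["time_ms"] = out["time_ms"] - anchor.astype(float)
    return out


def bland_altman_plot(result: BlandAltmanResult, path: str, title: str = "") -> None:
    """Write a Bland-Altman scatter (means vs differences) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=12, alpha=0.6)
    ax.axhline(result.bias, color="k", lw=1, label=f"bias {result.bias:.1f}")
    for y, lbl in ((result.loa_low, "LL"), (result.loa_high, "UL")):
        ax.axhline(y, color="k", lw=1, ls="--")
        ax.annotate(f"{lbl} {y:.1f}", xy=(0.99, y), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=8)
    ax.set_xlabel("mean of pair (ms)")
    ax.set_ylabel("difference (ms)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
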