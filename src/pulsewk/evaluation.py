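"""Agreement and trend statistics between measured and estimated stroke volume.

Agreement is summarised Bland-Altman style: the distribution of per-beat
differences (measured minus estimated, so a positive median means the
method underestimates) reported as the median with the 5th-95th percentile
range.  Trend tracking over induced SV changes (e.g. a PEEP recruitment
manoeuvre) is quantified by the zero-lag Pearson cross-correlation between
the two beat-indexed SV series over a designated region of beats.

Quantiles use linear interpolation between closest order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AgreementSummary:
    """Median and 5th/95th percentiles of measured-minus-estimated SV (ml)."""

    median_diff: float
    p5_diff: float
    p95_diff: float
    n_beats: int


@dataclass(frozen=True)
class TrendCorrelation:
    """Zero-lag Pearson correlation over a half-open beat-index region."""

    r: float
    region: tuple  # (start_beat, end_beat)


def bland_altman(sv_est, sv_meas) -> AgreementSummary:
    """Summarise per-beat differences d = measured - estimated."""
    est = np.asarray(sv_est, dtype=float)
    meas = np.asarray(sv_meas, dtype=float)
    if est.shape != meas.shape or est.ndim != 1:
        raise ValueError("paired series must be 1-D with equal length")
    if est.size < 2:
        raise ValueError("need at least 2 paired beats")
    d = meas - est
    p5, med, p95 = np.percentile(d, [5.0, 50.0, 95.0])
    return AgreementSummary(median_diff=float(med), p5_diff=float(p5),
                            p95_diff=float(p95), n_beats=int(d.size))


def zero_lag_crosscorr(sv_est, sv_meas, region=None) -> TrendCorrelation:
    """Pearson correlation at lag zero over ``region = (start, end)`` beats.

    The region is half-open on beat indices; ``None`` uses the full series.
    """
    est = np.asarray(sv_est, dtype=float)
    meas = np.asarray(sv_meas, dtype=float)
    if est.shape != meas.shape or est.ndim != 1:
        raise ValueError("paired series must be 1-D with equal length")
    if region is None:
        region = (0, est.size)
    start, end = int(region[0]), int(region[1])
    if start < 0 or end > est.size or end - start < 3:
        raise ValueError(f"region {region} invalid for series of length {est.size}")
    x = est[start:end]
    y = meas[start:end]
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("undefined correlation: zero variance in region")
    r = float(np.corrcoef(x, y)[0, 1])
    return TrendCorrelation(r=r, region=(start, end))


def evaluate_run(table: pd.DataFrame, regions=(), meas_col: str = "sv_measured_ml",
                 est_cols=None, plot_dir=None) -> dict:
    """Full evaluation of a per-beat result table.

    Parameters
    ----------
    table : DataFrame
        Per-beat table containing ``meas_col`` and one or more estimated-SV
        columns (by default every column starting with ``sv_`` other than
        the measured one).  Rows with NaN in either column are dropped
        per estimator.
    regions : sequence of (start_beat, end_beat[, label])
        Beat-index regions (half-open, positional) for trend correlations.
    plot_dir : path, optional
        When given, a Bland-Altman scatter per estimator is written there.

    Returns
    -------
    dict mapping estimator column -> {"agreement": AgreementSummary,
    "trend": {label: TrendCorrelation}}.
    """
    if meas_col not in table.columns:
        raise ValueError(f"table lacks measured-SV column {meas_col!r}")
    if est_cols is None:
        est_cols = [c for c in table.columns
                    if c.startswith("sv_") and c != meas_col]
    if not est_cols:
        raise ValueError("table has no estimated-SV columns")

    report = {}
    for col in est_cols:
        sub = table[[col, meas_col]].dropna()
        if len(sub) < 2:
            raise ValueError(f"no converged beats for estimator {col!r}")
        est = sub[col].to_numpy()
        meas = sub[meas_col].to_numpy()
        trends = {}
        for reg in regions:
            start, end = int(reg[0]), int(reg[1])
            label = str(reg[2]) if len(reg) > 2 else f"beats_{start}_{end}"
            # regions index rows of the full per-beat table; non-converged
            # beats inside the region are then dropped pairwise
            win = table.iloc[start:end][[col, meas_col]].dropna()
            tc = zero_lag_crosscorr(win[col].to_numpy(),
                                    win[meas_col].to_numpy())
            trends[label] = TrendCorrelation(r=tc.r, region=(start, end))
        report[col] = {"agreement": bland_altman(est, meas), "trend": trends}
        if plot_dir is not None:
            _plot_bland_altman(est, meas, col, plot_dir)
    return report


def _plot_bland_altman(est, meas, name, plot_dir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    d = meas - est
    mean = 0.5 * (meas + est)
    p5, med, p95 = np.percentile(d, [5.0, 50.0, 95.0])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, d, s=8, alpha=0.6)
    for y, style in ((med, "-"), (p5, "--"), (p95, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=0.8)
    ax.set_xlabel("mean of measured and estimated SV (ml)")
    ax.set_ylabel("measured - estimated SV (ml)")
    ax.set_title(f"Bland-Altman: {name}")
    fig.tight_layout()
    out = Path(plot_dir) / f"bland_altman_{name}.png"
    fig.savefig(out, dpi=120)
    plt.close(fig)


def report_to_dict(report: dict) -> dict:
    """Flatten an :func:`evaluate_run` report into plain YAML/JSON-able types."""
    out = {}
    for col, entry in report.items():
        agr = entry["agreement"]
        out[col] = {
            "median_diff_ml": agr.median_diff,
            "p5_diff_ml": agr.p5_diff,
            "p95_diff_ml": agr.p95_diff,
            "n_beats": agr.n_beats,
            "trend": {label: {"r": tc.r, "start_beat": tc.region[0],
                              "end_beat": tc.region[1]}
                      for label, tc in entry["trend"].items()},
        }
    return out
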