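"""Accuracy metrics and agreement statistics.

Point metrics are percentage errors (Err% = 100 * (P - T) / T) of AIF
peak values and of fitted ktrans; agreement between estimates and
targets is summarised by the Pearson correlation, the least-squares line
of estimate on target, and Bland-Altman bias with 1.96-SD limits of
agreement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .grid import ConcentrationCurve
from .pk_fitting import ktrans_errors

__all__ = [
    "EvaluationReport",
    "percent_error",
    "peak_errors",
    "evaluate_dataset",
    "bland_altman",
    "plot_agreement",
]


def percent_error(estimate: float, target: float) -> float:
    """Signed percentage error 100 * (P - T) / T."""
    if target == 0:
        raise ZeroDivisionError("percent error undefined for a zero target")
    return 100.0 * (estimate - target) / target


def peak_errors(estimates: np.ndarray, truths: np.ndarray) -> np.ndarray:
    """Per-curve peak percentage errors for (n, T) curve arrays.

    The peak is the maximum sample on the grid (no sub-sample
    interpolation).
    """
    est_pk = np.asarray(estimates).max(axis=-1)
    tru_pk = np.asarray(truths).max(axis=-1)
    return 100.0 * (est_pk - tru_pk) / tru_pk


def bland_altman(estimates: np.ndarray, targets: np.ndarray) -> tuple[float, float, float]:
    """Mean difference (bias) and mean +/- 1.96 SD limits of agreement."""
    diff = np.asarray(estimates, float) - np.asarray(targets, float)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


@dataclass
class EvaluationReport:
    """Aggregate accuracy of estimated AIFs against the truth."""

    peak_error_mean: float
    peak_error_sd: float
    ktrans_error_mean: float | None
    ktrans_error_sd: float | None
    pearson_r: float
    fit_slope: float
    fit_intercept: float
    bland_altman_bias: float
    bland_altman_loa_low: float
    bland_altman_loa_high: float
    n_sets: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=1)

    def __str__(self) -> str:
        lines = [
            f"n sets                 {self.n_sets}",
            f"AIF peak error         {self.peak_error_mean:+.1f} +/- {self.peak_error_sd:.1f} %",
        ]
        if self.ktrans_error_mean is not None:
            lines.append(
                f"ktrans error           {self.ktrans_error_mean:+.1f} +/- {self.ktrans_error_sd:.1f} %"
            )
        lines += [
            f"Pearson r              {self.pearson_r:.4f}",
            f"linear fit             y = {self.fit_slope:.3f} x + {self.fit_intercept:.3f}",
            f"Bland-Altman           bias {self.bland_altman_bias:+.4f} "
            f"LoA [{self.bland_altman_loa_low:+.4f}, {self.bland_altman_loa_high:+.4f}]",
        ]
        return "\n".join(lines)


def plot_agreement(estimates: np.ndarray, targets: np.ndarray, path_prefix: str) -> list[str]:
    """Write error-bar, correlation and Bland-Altman plots as PNG files.

    ``estimates``/``targets`` are aligned 1-D value arrays (AIF peaks or
    ktrans).  Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    estimates = np.asarray(estimates, float)
    targets = np.asarray(targets, float)
    errors = 100.0 * (estimates - targets) / targets
    written = []

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar([0], [errors.mean()], yerr=[errors.std(ddof=1)], fmt="o", capsize=4)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("percent error")
    ax.set_xticks([])
    fig.tight_layout()
    path = f"{path_prefix}_errorbar.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    slope, intercept = np.polyfit(targets, estimates, 1)
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.scatter(targets, estimates, s=10, alpha=0.6)
    xs = np.array([targets.min(), targets.max()])
    ax.plot(xs, slope * xs + intercept, "r-", label=f"y = {slope:.2f}x + {intercept:.2f}")
    ax.plot(xs, xs, "k:", label="identity")
    ax.set_xlabel("target")
    ax.set_ylabel("estimate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    path = f"{path_prefix}_correlation.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    bias, lo, hi = bland_altman(estimates, targets)
    fig, ax = plt.subplots(figsize=(4, 3))
    mean_vals = 0.5 * (estimates + targets)
    ax.scatter(mean_vals, estimates - targets, s=10, alpha=0.6)
    for y, style in ((bias, "r-"), (lo, "r--"), (hi, "r--")):
        ax.axhline(y, ls=style[1:], color="r", lw=0.8)
    ax.set_xlabel("mean of estimate and target")
    ax.set_ylabel("difference")
    fig.tight_layout()
    path = f"{path_prefix}_bland_altman.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written


def evaluate_dataset(
    est_aifs: np.ndarray,
    true_aifs: np.ndarray,
    grid=None,
    tissue: np.ndarray | None = None,
    true_ktrans: np.ndarray | None = None,
    ktrans_subset: int | None = None,
    multi_start: bool = True,
) -> EvaluationReport:
    """Evaluate estimated against true AIFs over a dataset split.

    ``est_aifs``/``true_aifs`` are (n, T) arrays.  When tissue curves
    (n, N, T) and generating ktrans values (n, N) are supplied, every
    tissue curve is refitted against the estimated AIF and the ktrans
    percentage errors are aggregated over all curves of all sets
    (optionally the first ``ktrans_subset`` sets to bound runtime).
    Correlation/agreement statistics compare ktrans estimates with
    targets when fits are available, otherwise AIF peak values.
    """
    est_aifs = np.asarray(est_aifs, float)
    true_aifs = np.asarray(true_aifs, float)
    pk_err = peak_errors(est_aifs, true_aifs)

    kt_mean = kt_sd = None
    if tissue is not None and true_ktrans is not None:
        if grid is None:
            raise ValueError("fitting ktrans requires the time grid")
        n_fit = est_aifs.shape[0] if ktrans_subset is None else min(ktrans_subset, est_aifs.shape[0])
        all_errors = []
        est_vals, target_vals = [], []
        for i in range(n_fit):
            est_curve = ConcentrationCurve(grid, est_aifs[i])
            tissues = [ConcentrationCurve(grid, tissue[i, j]) for j in range(tissue.shape[1])]
            errs = ktrans_errors(est_curve, tissues, list(true_ktrans[i]), multi_start=multi_start)
            all_errors.append(errs)
            target_vals.extend(true_ktrans[i])
            est_vals.extend(true_ktrans[i] * (1.0 + errs / 100.0))
        all_errors = np.concatenate(all_errors)
        kt_mean = float(all_errors.mean())
        kt_sd = float(all_errors.std(ddof=1)) if all_errors.size > 1 else 0.0
        compare_est = np.asarray(est_vals)
        compare_tgt = np.asarray(target_vals)
    else:
        compare_est = est_aifs.max(axis=-1)
        compare_tgt = true_aifs.max(axis=-1)

    if np.ptp(compare_tgt) > 0 and np.ptp(compare_est) > 0:
        r = float(stats.pearsonr(compare_est, compare_tgt).statistic)
        slope, intercept = np.polyfit(compare_tgt, compare_est, 1)
    else:
        r, slope, intercept = 1.0, 1.0, 0.0
    bias, lo, hi = bland_altman(compare_est, compare_tgt)
    return EvaluationReport(
        peak_error_mean=float(pk_err.mean()),
        peak_error_sd=float(pk_err.std(ddof=1)) if pk_err.size > 1 else 0.0,
        ktrans_error_mean=kt_mean,
        ktrans_error_sd=kt_sd,
        pearson_r=r,
        fit_slope=float(slope),
        fit_intercept=float(intercept),
        bland_altman_bias=bias,
        bland_altman_loa_low=lo,
        bland_altman_loa_high=hi,
        n_sets=int(est_aifs.shape[0]),
    )
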