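"""Agreement metrics between measured and model-predicted mean kurtosis.

Pearson's R measures precision (how well the pairs fall on a line), Lin's
concordance correlation coefficient additionally penalises departure from
the identity line (accuracy), and the Bland-Altman decomposition reports the
bias and its 1.96-SD limits of agreement.  Lin's CCC is interpreted through
McBride's categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "AgreementSummary",
    "lin_ccc",
    "mcbride_category",
    "bland_altman",
    "fit_quality_report",
]


@dataclass(frozen=True)
class AgreementSummary:
    group: str
    n: int
    pearson_r: float
    lin_ccc: float
    rmse: float
    bland_altman_bias: float
    bland_altman_lower: float
    bland_altman_upper: float
    outlier_fraction: float
    mcbride_category: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    ``CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D sequences of length >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/n)
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both sequences are constant with equal means")
    return float(2.0 * cov / denom)


def mcbride_category(ccc: float) -> str:
    """McBride's agreement category for a concordance coefficient.

    poor (< 0.90), moderate (0.90-0.95), substantial (0.95-0.99),
    almost perfect (> 0.99); each printed lower bound is included in its
    category (left-closed intervals).
    """
    if ccc > 1.0:
        raise ValueError("CCC cannot exceed 1")
    if ccc >= 0.99:
        # 0.99 itself is the upper edge of "substantial" (0.95-0.99)
        return "almost perfect" if ccc > 0.99 else "substantial"
    if ccc >= 0.95:
        return "substantial"
    if ccc >= 0.90:
        return "moderate"
    return "poor"


def bland_altman(x, y) -> tuple[float, float, float, float]:
    """Bias, limits of agreement and outlier fraction of the differences.

    Differences ``d = x - y``; bias = mean(d); limits = bias +/- 1.96 SD(d);
    the returned fraction counts pairs outside the limits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("bland_altman needs two equal-length sequences, n >= 2")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std())  # population SD, consistent with the CCC convention
    lower, upper = bias - 1.96 * sd, bias + 1.96 * sd
    if sd == 0:
        frac = 0.0
    else:
        frac = float(np.mean((d < lower) | (d > upper)))
    return bias, lower, upper, frac


def _summarise(group: str, measured: np.ndarray, fitted: np.ndarray) -> AgreementSummary:
    if np.ptp(measured) == 0 or np.ptp(fitted) == 0:
        r = 1.0 if np.allclose(measured, fitted) else 0.0
    else:
        r = float(pearsonr(measured, fitted).statistic)
    ccc = lin_ccc(measured, fitted)
    rmse = float(np.sqrt(np.mean((measured - fitted) ** 2)))
    bias, lower, upper, frac = bland_altman(fitted, measured)
    return AgreementSummary(
        group=group,
        n=len(measured),
        pearson_r=r,
        lin_ccc=ccc,
        rmse=rmse,
        bland_altman_bias=bias,
        bland_altman_lower=lower,
        bland_altman_upper=upper,
        outlier_fraction=frac,
        mcbride_category=mcbride_category(ccc),
    )


def fit_quality_report(
    measured: pd.DataFrame,
    fitted: pd.DataFrame,
    group_by: str | None = None,
) -> list[AgreementSummary]:
    """Overall (and optionally per-group) agreement between paired MK tables.

    Both tables need columns (roi_label, waveform_label, mk); pairing is per
    (roi, waveform) point.  Unmatched keys raise with the offending keys
    listed.
    """
    keys = ["roi_label", "waveform_label"]
    m = measured.set_index(keys)
    f = fitted.set_index(keys)
    missing = m.index.difference(f.index).tolist() + f.index.difference(m.index).tolist()
    if missing:
        raise ValueError(f"unmatched (roi, waveform) keys: {missing[:10]}"
                         + (" ..." if len(missing) > 10 else ""))
    joined = m.join(f, lsuffix="_meas", rsuffix="_fit")
    out = [_summarise("all", joined["mk_meas"].to_numpy(), joined["mk_fit"].to_numpy())]
    if group_by is not None:
        col = f"{group_by}_meas" if f"{group_by}_meas" in joined else group_by
        for g, sub in joined.groupby(col):
            out.append(_summarise(str(g), sub["mk_meas"].to_numpy(), sub["mk_fit"].to_numpy()))
    return out


def plot_agreement(measured, fitted, path=None):
    """Density scatter + Bland-Altman panel; optional artifact, never required."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    measured = np.asarray(measured, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.hexbin(measured, fitted, gridsize=40, mincnt=1, cmap="viridis")
    lims = [min(measured.min(), fitted.min()), max(measured.max(), fitted.max())]
    ax1.plot(lims, lims, "k--", lw=1)
    ax1.set_xlabel("measured MK")
    ax1.set_ylabel("fitted MK")
    bias, lower, upper, _ = bland_altman(fitted, measured)
    mean_pair = (measured + fitted) / 2
    ax2.scatter(mean_pair, fitted - measured, s=6, alpha=0.5)
    for yv, style in ((bias, "-"), (lower, "--"), (upper, "--")):
        ax2.axhline(yv, color="k", ls=style, lw=1)
    ax2.set_xlabel("mean of fitted and measured MK")
    ax2.set_ylabel("fitted - measured")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
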