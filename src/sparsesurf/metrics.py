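"""Agreement statistics for multi-rater segmentation studies.

Spatial overlap between two segmentations is measured with the Jaccard
index JI = |A∩B| / |A∪B| and the Dice similarity coefficient
DSC = 2TP/(2TP + FP + FN) = 2·JI/(1 + JI).  For more than two raters the
generalized conformity index CIgen extends Jaccard as the ratio of the sum
of pairwise intersections to the sum of pairwise unions.

Volumetric agreement uses the intraclass correlation coefficient from a
two-way ANOVA with an *absolute agreement* definition (single measure),
which penalizes systematic rater offsets and not only inconsistency:

    ICC = (MSR - MSE) / (MSR + (k-1)·MSE + k/n·(MSC - MSE))

with MSR/MSC/MSE the subject/rater/error mean squares, n subjects and k
raters.  Bland-Altman analysis reports the mean paired difference, its SD
and standard error, 95% limits of agreement (mean ± 1.96·SD) and a
two-sided paired t-test of zero mean difference.

Qualitative interpretation bands: JI or CIgen > 0.7 and DSC > 0.8 count as
excellent overlap; ICC < 0.40 is poor, 0.40-0.74 fair to good, >= 0.75
excellent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .mask_io import LabelMask

__all__ = [
    "jaccard",
    "dice",
    "cigen",
    "icc_absolute",
    "bland_altman",
    "BlandAltman",
    "AgreementReport",
    "compute_agreement",
    "classify_agreement",
    "band_overlap",
    "band_dice",
    "band_icc",
    "pool_hemispheres",
]


def _check_pair(a: LabelMask, b: LabelMask) -> tuple[np.ndarray, np.ndarray]:
    if not a.same_grid(b):
        raise ValueError("masks are on different grids")
    fa, fb = a.data.astype(bool), b.data.astype(bool)
    if not fa.any() and not fb.any():
        raise ValueError("overlap of two empty masks is undefined")
    return fa, fb


def jaccard(a: LabelMask, b: LabelMask) -> float:
    """Jaccard index |A∩B| / |A∪B| of two masks on the same grid."""
    fa, fb = _check_pair(a, b)
    inter = np.count_nonzero(fa & fb)
    union = np.count_nonzero(fa | fb)
    return inter / union


def dice(a: LabelMask, b: LabelMask) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN)."""
    fa, fb = _check_pair(a, b)
    inter = np.count_nonzero(fa & fb)
    return 2 * inter / (np.count_nonzero(fa) + np.count_nonzero(fb))


def cigen(masks: list[LabelMask]) -> float:
    """Generalized conformity index over >= 2 raters.

    Sum of pairwise intersection volumes over sum of pairwise union volumes;
    reduces to the Jaccard index for exactly two raters.
    """
    if len(masks) < 2:
        raise ValueError("CIgen needs at least 2 masks")
    first = masks[0]
    for m in masks[1:]:
        if not first.same_grid(m):
            raise ValueError("masks are on different grids")
    fgs = [m.data.astype(bool) for m in masks]
    if not any(f.any() for f in fgs):
        raise ValueError("CIgen of all-empty masks is undefined")
    inter_sum = 0
    union_sum = 0
    for fa, fb in combinations(fgs, 2):
        inter_sum += np.count_nonzero(fa & fb)
        union_sum += np.count_nonzero(fa | fb)
    return inter_sum / union_sum


def icc_absolute(volumes: np.ndarray, model: str = "mixed") -> float:
    """Two-way absolute-agreement single-measure ICC of a subjects x raters matrix.

    ``model`` is "mixed" (raters fixed) or "random"; the point estimate is
    identical for both — the distinction only affects inference, which is
    not computed here.
    """
    if model not in ("mixed", "random"):
        raise ValueError("model must be 'mixed' or 'random'")
    x = np.asarray(volumes, dtype=float)
    if x.ndim != 2:
        raise ValueError("volumes must be a 2D subjects x raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0:
        raise ValueError("zero total variance; ICC undefined")
    return (msr - mse) / denom


@dataclass
class BlandAltman:
    """Bland-Altman agreement block for paired volume measurements."""

    diff: np.ndarray
    mean: np.ndarray
    mu_diff: float
    sd: float
    se: float
    p_value: float  # NaN when SD = 0 (degenerate paired t-test)
    loa_lower: float
    loa_upper: float
    n: int
    degenerate: bool = False
    groups: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"mean": self.mean, "diff": self.diff})
        if self.groups is not None:
            df["group"] = self.groups
        return df


def bland_altman(a, b, groups=None) -> BlandAltman:
    """Paired-difference agreement of two measurement series.

    Differences are ``a - b`` plotted against ``(a + b) / 2``; reports the
    mean difference, its SD and SE, 95% limits of agreement and a two-sided
    paired t-test p-value (NaN-flagged degenerate when SD = 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1D arrays of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 paired measurements")
    diff = a - b
    mean = (a + b) / 2
    mu = float(diff.mean())
    sd = float(diff.std(ddof=1))
    se = sd / np.sqrt(n)
    if sd == 0:
        p, degenerate = float("nan"), True
    else:
        p = float(stats.ttest_rel(a, b).pvalue)
        degenerate = False
    return BlandAltman(
        diff=diff,
        mean=mean,
        mu_diff=mu,
        sd=sd,
        se=se,
        p_value=p,
        loa_lower=mu - 1.96 * sd,
        loa_upper=mu + 1.96 * sd,
        n=n,
        degenerate=degenerate,
        groups=None if groups is None else np.asarray(groups),
    )


def plot_bland_altman(ba: BlandAltman, ax=None, group_colors=None):
    """Scatter of paired differences vs means with bias and limits of agreement."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if ba.groups is not None:
        for g in np.unique(ba.groups):
            sel = ba.groups == g
            color = None if group_colors is None else group_colors.get(g)
            ax.scatter(ba.mean[sel], ba.diff[sel], label=str(g), color=color, s=20)
        ax.legend()
    else:
        ax.scatter(ba.mean, ba.diff, s=20)
    for y, style in ((ba.mu_diff, "-"), (ba.loa_lower, "--"), (ba.loa_upper, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of pair (mL)")
    ax.set_ylabel("difference (mL)")
    return ax


# ---------------------------------------------------------------------------
# Interpretation bands
# ---------------------------------------------------------------------------


def band_overlap(value: float) -> str:
    """JI / CIgen band: strictly above 0.7 is excellent."""
    return "excellent" if value > 0.7 else "not excellent"


def band_dice(value: float) -> str:
    """DSC band: strictly above 0.8 is excellent."""
    return "excellent" if value > 0.8 else "not excellent"


def band_icc(value: float) -> str:
    """Altman's ICC bands: < 0.40 poor, 0.40-0.74 fair to good, >= 0.75 excellent."""
    if value < 0.40:
        return "poor"
    if value < 0.75:
        return "fair to good"
    return "excellent"


@dataclass
class AgreementReport:
    """Agreement statistics for a set of segmentations of one structure."""

    pairwise: pd.DataFrame  # columns: i, j, ji, dsc
    cigen: float
    icc: float | None = None
    bland_altman: BlandAltman | None = None
    bands: dict = field(default_factory=dict)

    @property
    def mean_ji(self) -> float:
        return float(self.pairwise["ji"].mean())

    @property
    def mean_dsc(self) -> float:
        return float(self.pairwise["dsc"].mean())


def compute_agreement(
    masks: list[LabelMask], volumes: np.ndarray | None = None
) -> AgreementReport:
    """Pairwise JI/DSC and CIgen for a rater set, plus ICC on a volume matrix.

    ``volumes`` is an optional subjects x raters matrix; when omitted and
    only one subject's masks are given, ICC (which needs >= 2 subjects) is
    left unset.
    """
    rows = [
        {"i": i, "j": j, "ji": jaccard(masks[i], masks[j]), "dsc": dice(masks[i], masks[j])}
        for i, j in combinations(range(len(masks)), 2)
    ]
    report = AgreementReport(pairwise=pd.DataFrame(rows), cigen=cigen(masks))
    if volumes is not None:
        report.icc = icc_absolute(volumes)
    return report


def classify_agreement(report: AgreementReport) -> AgreementReport:
    """Attach qualitative bands to a computed report."""
    report.bands = {
        "ji": band_overlap(report.mean_ji),
        "dsc": band_dice(report.mean_dsc),
        "cigen": band_overlap(report.cigen),
    }
    if report.icc is not None:
        report.bands["icc"] = band_icc(report.icc)
    return report


def pool_hemispheres(df: pd.DataFrame) -> pd.DataFrame:
    """Add pooled "both" rows to a per-hemisphere results table.

    Overlap-metric columns (ji, dsc, cigen, icc) are averaged across
    hemispheres; volume columns (any column starting with "volume") are
    summed, mirroring per-structure bilateral reporting.  Per-hemisphere
    rows are kept alongside the pooled ones.
    """
    if "hemisphere" not in df.columns or "structure" not in df.columns:
        raise ValueError("table needs 'structure' and 'hemisphere' columns")
    value_cols = [c for c in df.columns if c not in ("structure", "hemisphere")]
    agg = {
        c: ("sum" if c.startswith("volume") else "mean") for c in value_cols
    }
    pooled = df.groupby("structure", as_index=False).agg(agg)
    pooled["hemisphere"] = "both"
    return pd.concat([df, pooled[df.columns]], ignore_index=True)
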