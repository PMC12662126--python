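"""Agreement and comparison statistics.

Implements the chance-corrected agreement measures and nonparametric tests
used to compare late-enhancement CT readings with the cardiac-MRI reference:
Cohen's (weighted) kappa with ordinal interpretation bins, the
total/partial/no concordance taxonomy, median/IQR summaries, the Wilcoxon
signed-rank test, plus the Monte-Carlo simulation quantifying how much the
atlas-map median filter suppresses Gaussian noise.

Weighted kappa defaults to linear weights; for the binary segment vectors
used here every weighting scheme coincides with the unweighted statistic.
Pooled kappa across segments and patients is appropriate because
within-patient dependence of segment calls is negligible in this setting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .maps import median_filter_matrix

#: kappa interpretation bins (lower edge inclusive); the top bin starts at
#: 0.89 as printed in the agreement scale this package follows, so values in
#: [0.89, 0.90) bin as "almost perfect".
KAPPA_BINS = (
    (0.20, "no agreement"),
    (0.40, "minimal"),
    (0.60, "weak"),
    (0.80, "moderate"),
    (0.89, "strong"),
    (np.inf, "almost perfect"),
)


class UndefinedKappaError(ValueError):
    """Both raters are constant and identical: expected agreement is 1."""


@dataclass
class AgreementResult:
    kappa: float
    interpretation: str
    observed_agreement: float
    expected_agreement: float


@dataclass
class PairedCalls:
    """Two aligned binary call vectors (e.g. CT vs MRI-LGE) for one patient."""

    a: np.ndarray
    b: np.ndarray
    labels: tuple[str, str] = ("CT", "MRI")

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a)
        self.b = np.asarray(self.b)
        if self.a.shape != self.b.shape:
            raise ValueError("paired call vectors must have equal length")
        if not set(np.unique(np.concatenate([self.a, self.b]))) <= {0, 1}:
            raise ValueError("call vectors must be binary")


def interpret_kappa(kappa: float) -> str:
    for upper, name in KAPPA_BINS:
        if kappa < upper:
            return name
    return KAPPA_BINS[-1][1]


def cohens_kappa(a, b, weights: str = "linear") -> AgreementResult:
    """Cohen's kappa, optionally weighted for ordinal categories.

    kappa = (p_o - p_e) / (1 - p_e), where observed and expected agreement
    are weighted sums over the confusion matrix with agreement weights
    ``1 - |i - j|/(k-1)`` (linear), ``1 - (|i - j|/(k-1))^2`` (quadratic) or
    the identity (none).  Raises :class:`UndefinedKappaError` when both
    raters are constant and identical (p_e = 1).
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape or a.size == 0:
        raise ValueError("a and b must be non-empty vectors of equal length")
    cats, a_idx = np.unique(a, return_inverse=True)
    cats_b, b_idx = np.unique(b, return_inverse=True)
    all_cats = np.unique(np.concatenate([cats, cats_b]))
    k = len(all_cats)
    if k == 1:
        raise UndefinedKappaError("both raters give a single identical category")
    a_idx = np.searchsorted(all_cats, a)
    b_idx = np.searchsorted(all_cats, b)
    conf = np.zeros((k, k))
    np.add.at(conf, (a_idx, b_idx), 1.0)
    conf /= a.size
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    diff = np.abs(i - j) / (k - 1)
    if weights == "linear":
        w = 1.0 - diff
    elif weights == "quadratic":
        w = 1.0 - diff**2
    elif weights == "none":
        w = (i == j).astype(float)
    else:
        raise ValueError(f"unknown weighting scheme {weights!r}")
    p_o = float((w * conf).sum())
    p_e = float((w * np.outer(conf.sum(axis=1), conf.sum(axis=0))).sum())
    if p_e >= 1.0:
        raise UndefinedKappaError("expected agreement is 1; kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(kappa, interpret_kappa(kappa), p_o, p_e)


def concordance_category(ct_segments, mri_segments) -> str:
    """Total/partial/no concordance of two pathologic-segment sets.

    *Total*: identical sets (two empty sets agree vacuously).  *None*: CT
    identified none of the reference segments although the reference found
    some.  *Partial*: anything else (more or fewer segments, with overlap).
    """
    ct = set(ct_segments)
    mri = set(mri_segments)
    if ct == mri:
        return "total"
    if not (ct & mri) and mri:
        return "none"
    return "partial"


def median_iqr(values, quartile_method: str = "linear") -> tuple[float, float, float]:
    """Median and quartiles (q1, q3) of a non-empty numeric sample.

    The quartile convention is configurable (any numpy percentile method);
    the default interpolates linearly between order statistics.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("median_iqr requires a non-empty sample")
    q1, q3 = np.percentile(v, [25, 75], method=quartile_method)
    return float(np.median(v)), float(q1), float(q3)


def wilcoxon_signed_rank(x, y, paired: bool = True) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (classic policy); the exact null
    distribution is used for n <= 25 untied differences, the tie-corrected
    normal approximation otherwise.  If every difference is zero the test is
    vacuous: returns p = 1 with a warning.
    """
    if not paired:
        raise ValueError("wilcoxon_signed_rank is a paired test; got paired=False")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p-value is 1", stacklevel=2)
        return 0.0, 1.0
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"), method=method)
    return float(res.statistic), float(res.pvalue)


def median_noise_reduction_closed_form(kernel: int) -> float:
    """Asymptotic noise-reduction factor of a kernel x kernel median on
    i.i.d. Gaussian noise: sqrt(2 n / pi) with n = kernel^2 samples."""
    return float(np.sqrt(2.0 * kernel * kernel / np.pi))


def simulate_filter_noise_reduction(
    kernel: int, n_cells: int = 10**6, sigma: float = 1.0, seed: int = 0
) -> float:
    """Monte-Carlo noise-reduction factor of the atlas-map median filter.

    Generates an i.i.d. Gaussian matrix of about ``n_cells`` cells, filters
    it with :func:`median_filter_matrix`, and returns input std / output std
    over interior cells only (a margin of one kernel width avoids boundary
    effects).
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be a positive odd integer, got {kernel}")
    if n_cells < 10**4:
        warnings.warn(
            f"n_cells={n_cells} is small; the reduction-factor estimate will be noisy",
            stacklevel=2,
        )
    side = int(np.ceil(np.sqrt(n_cells)))
    rng = np.random.default_rng(seed)
    matrix = rng.normal(0.0, sigma, size=(side, side))
    filtered = median_filter_matrix(matrix, kernel)
    m = kernel if side > 4 * kernel else kernel // 2
    interior = np.s_[m : side - m, m : side - m]
    return float(matrix[interior].std(ddof=1) / filtered[interior].std(ddof=1))


def load_segment_counts(phase: str = "acute") -> pd.DataFrame:
    """Per-participant pathologic-segment counts from the SCAD study cohort.

    ``phase`` is ``'acute'`` or ``'follow_up'``.  Columns: participant,
    ct_segments (late-enhancement CT, out of 32 segment-bands),
    lge_segments (LGE MRI, out of 16), concordance (total/partial/none) and
    edema_segments (T2-based MRI edema, out of 16).
    """
    names = {"acute": "acute_phase_segments.csv", "follow_up": "follow_up_segments.csv"}
    if phase not in names:
        raise ValueError(f"phase must be one of {sorted(names)}, got {phase!r}")
    with resources.files("ecvatlas.data").joinpath(names[phase]).open("r") as fh:
        return pd.read_csv(fh)
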