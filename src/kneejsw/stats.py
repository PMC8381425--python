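"""Cross-modality agreement statistics.

Cohort tables hold one row per subject and timepoint with the four
measurements of the most affected compartment: weight-bearing projectional
JSW ("xray_jsw"), MRI-style mean cartilage thickness ("mri_thickness"),
3D perpendicular median JSW ("ct3d_jsw") and non-weight-bearing
projectional JSW ("ct2d_jsw"), all in mm.

The analysis is Pearson correlation between every pair of techniques,
done two ways: cross-sectionally (both timepoints of every subject pooled
into one comparison) and longitudinally (per-subject 2-year changes,
follow-up minus baseline).  Correlation strength is labelled on the Evans
scale and two-sided p-values come from the exact t transform
``t = R sqrt(n-2) / sqrt(1-R^2)``.  Achieved power for a correlation test
is available by seeded Monte Carlo over bivariate normal samples or by a
bias-corrected Fisher-z approximation.

`JswAgreementModel` wraps the whole analysis in a fit/results object:

>>> model = JswAgreementModel.from_dataframe(table)
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import MeasurementError, ValidationError

logger = logging.getLogger(__name__)

#: Measurement columns of a cohort table, in reporting order.
MEASURES = ("xray_jsw", "mri_thickness", "ct3d_jsw", "ct2d_jsw")

MEASURE_LABELS = {
    "xray_jsw": "X-ray JSW",
    "mri_thickness": "MRI thickness",
    "ct3d_jsw": "3D CT JSW",
    "ct2d_jsw": "2D CT JSW",
}

#: Evans (1996) verbal bands for |R|, as half-open intervals.
EVANS_BANDS = (
    (0.2, "very weak"),
    (0.4, "weak"),
    (0.6, "moderate"),
    (0.8, "strong"),
    (np.inf, "very strong"),
)


def evans_label(r: float) -> str:
    """Verbal strength of a correlation per the Evans scale (on |R|)."""
    if not -1 <= r <= 1:
        raise ValidationError(f"correlation must be in [-1, 1], got {r}")
    a = abs(r)
    for upper, label in EVANS_BANDS:
        if a < upper:
            return label
    return "very strong"


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; errors on n < 3 or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1D arrays of equal length")
    if x.size < 3:
        raise ValidationError(f"need n >= 3 for a correlation, got n={x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in one of the variables")
    return float(sps.pearsonr(x, y).statistic)


def p_from_r(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation via the t transform."""
    if n < 3:
        raise ValidationError(f"need n >= 3, got {n}")
    if not -1 < r < 1:
        raise ValidationError(f"|R| must be < 1 for the t transform, got {r}")
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * sps.t.sf(abs(t), n - 2))


def power_pearson(
    rho: float,
    n: int,
    alpha: float = 0.05,
    method: str = "montecarlo",
    reps: int = 100_000,
    seed: int | None = None,
) -> float:
    """Power of the two-sided Pearson correlation test at true correlation rho.

    ``montecarlo`` draws ``reps`` bivariate normal samples of size ``n`` at
    correlation ``rho`` and reports the fraction whose p-value falls below
    ``alpha``.  ``fisher_bias_corrected`` uses the normal approximation on
    the Fisher z scale with the mean-bias correction rho / (2 (n - 1)).
    """
    if not 0 <= abs(rho) < 1:
        raise ValidationError(f"|rho| must be in [0, 1), got {rho}")
    if n < 4:
        raise ValidationError(f"need n >= 4, got {n}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")

    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal((reps, n, 2)) @ chol.T
        x, y = z[..., 0], z[..., 1]
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        r = (xc * yc).sum(axis=1) / denom
        r = np.clip(r, -0.999999999, 0.999999999)
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        p = 2 * sps.t.sf(np.abs(t), n - 2)
        return float((p < alpha).mean())
    if method == "fisher_bias_corrected":
        t_crit = sps.t.isf(alpha / 2, n - 2)
        r_crit = t_crit / np.sqrt(n - 2 + t_crit**2)
        se = 1.0 / np.sqrt(n - 3)
        mean_z = np.arctanh(rho) + rho / (2 * (n - 1))
        z_crit = np.arctanh(r_crit)
        return float(
            sps.norm.sf((z_crit - mean_z) / se) + sps.norm.cdf((-z_crit - mean_z) / se)
        )
    raise ValidationError(f"unknown power method {method!r}")


def determine_mac(
    baseline_jsw: dict[str, float] | pd.Series,
) -> str:
    """Most affected compartment from baseline weight-bearing JSW per side.

    The compartment with the smaller baseline weight-bearing JSW is the
    most affected; exact ties go to medial (logged).
    """
    medial = baseline_jsw.get("medial", np.nan)
    lateral = baseline_jsw.get("lateral", np.nan)
    if np.isnan(medial) and np.isnan(lateral):
        raise MeasurementError("baseline JSW missing for both compartments")
    if np.isnan(medial):
        return "lateral"
    if np.isnan(lateral):
        return "medial"
    if medial == lateral:
        logger.info("baseline JSW tie (%.3f mm); MAC defaults to medial", medial)
        return "medial"
    return "medial" if medial < lateral else "lateral"


#: Exclusion flags in the order they are applied (a subject with several
#: flags is counted once, in the first applicable category).
EXCLUSION_ORDER = ("converted_treatment", "missing_ct", "motion_artefact")


def apply_exclusions(manifest: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the patient-flow exclusion cascade to an enrollment manifest.

    ``manifest`` has one row per enrolled subject with boolean columns
    ``converted_treatment``, ``missing_ct`` and ``motion_artefact``.
    Returns the retained (complete-case) manifest and a flow report with
    the enrolled count, each exclusion count, and the analyzed count.
    """
    for colname in EXCLUSION_ORDER:
        if colname not in manifest.columns:
            raise ValidationError(f"manifest lacks exclusion column {colname!r}")
    flow: dict[str, int] = {"enrolled": int(len(manifest))}
    remaining = manifest.copy()
    for colname in EXCLUSION_ORDER:
        flagged = remaining[colname].astype(bool)
        flow[colname] = int(flagged.sum())
        remaining = remaining[~flagged]
    flow["analyzed"] = int(len(remaining))
    return remaining, flow


@dataclass
class CorrelationResult:
    """Pearson correlation between two measurement techniques."""

    measure_x: str
    measure_y: str
    n: int
    r: float
    p: float
    evans: str

    @classmethod
    def from_data(cls, name_x: str, x: np.ndarray, name_y: str, y: np.ndarray):
        r = pearson_r(x, y)
        p = p_from_r(r, len(x)) if abs(r) < 1 else 0.0
        return cls(name_x, name_y, int(len(x)), r, p, evans_label(r))


def _pairs(measures=MEASURES):
    out = []
    for i, a in enumerate(measures):
        for b in measures[i + 1 :]:
            out.append((a, b))
    return out


def validate_cohort_table(table: pd.DataFrame) -> None:
    """Check the complete-case two-timepoint contract of a cohort table."""
    required = {"subject", "timepoint", *MEASURES}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"cohort table lacks columns: {sorted(missing)}")
    counts = table.groupby("subject")["timepoint"].nunique()
    if (counts != 2).any():
        bad = counts[counts != 2].index.tolist()
        raise ValidationError(f"subjects without exactly 2 timepoints: {bad}")
    if table[list(MEASURES)].isna().any().any():
        raise ValidationError("cohort table is not complete-case (NaNs present)")


def cross_sectional_matrix(table: pd.DataFrame) -> list[CorrelationResult]:
    """All pairwise correlations pooling both timepoints (n = 2 x subjects)."""
    validate_cohort_table(table)
    return [
        CorrelationResult.from_data(a, table[a].to_numpy(), b, table[b].to_numpy())
        for a, b in _pairs()
    ]


def longitudinal_deltas(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject 2-year changes (follow-up minus baseline) per measure."""
    validate_cohort_table(table)
    wide = table.pivot(index="subject", columns="timepoint", values=list(MEASURES))
    deltas = {}
    for m in MEASURES:
        deltas[m] = wide[(m, "2yr")] - wide[(m, "baseline")]
    return pd.DataFrame(deltas)


def longitudinal_matrix(table: pd.DataFrame) -> list[CorrelationResult]:
    """All pairwise correlations of 2-year changes (n = subjects)."""
    d = longitudinal_deltas(table)
    return [
        CorrelationResult.from_data(a, d[a].to_numpy(), b, d[b].to_numpy())
        for a, b in _pairs()
    ]


class JswAgreementModel:
    """Agreement analysis between the four JSW/thickness techniques.

    Parameters
    ----------
    table : pandas.DataFrame
        Complete-case cohort table: one row per subject x timepoint with
        columns ``subject``, ``timepoint`` ('baseline' | '2yr') and the
        four measures of `MEASURES` (mm).
    """

    def __init__(self, table: pd.DataFrame):
        validate_cohort_table(table)
        self.table = table.copy()
        self.n_subjects = int(table["subject"].nunique())

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame) -> "JswAgreementModel":
        return cls(table)

    @classmethod
    def from_csv(cls, path) -> "JswAgreementModel":
        return cls(pd.read_csv(path))

    def fit(self, alpha: float = 0.05) -> "JswAgreementResults":
        cross = cross_sectional_matrix(self.table)
        try:
            longi = longitudinal_matrix(self.table)
        except ValidationError as exc:
            # e.g. zero-variance deltas with n=2 subjects or no effect
            raise MeasurementError(f"longitudinal correlations unavailable: {exc}")
        return JswAgreementResults(self, cross, longi, alpha)


class JswAgreementResults:
    """Fitted correlation matrices with labels, p-values and power."""

    def __init__(self, model, cross, longitudinal, alpha):
        self.model = model
        self.cross_sectional = cross
        self.longitudinal = longitudinal
        self.alpha = alpha

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, results in (
            ("cross-sectional", self.cross_sectional),
            ("longitudinal", self.longitudinal),
        ):
            for res in results:
                rows.append(
                    {
                        "analysis": kind,
                        "pair": f"{MEASURE_LABELS[res.measure_x]} vs "
                        f"{MEASURE_LABELS[res.measure_y]}",
                        "n": res.n,
                        "R": res.r,
                        "p": res.p,
                        "strength": res.evans,
                        "significant": res.p < self.alpha,
                    }
                )
        return pd.DataFrame(rows)

    def achieved_power(
        self, pair: tuple[str, str], kind: str = "longitudinal", **kwargs
    ) -> float:
        """Post-hoc power at the observed R of one pair."""
        results = self.longitudinal if kind == "longitudinal" else self.cross_sectional
        for res in results:
            if {res.measure_x, res.measure_y} == set(pair):
                return power_pearson(res.r, res.n, self.alpha, **kwargs)
        raise ValidationError(f"unknown pair {pair}")

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Joint-space width / cartilage thickness agreement",
            f"subjects: {self.model.n_subjects}   alpha: {self.alpha}",
            "",
        ]
        with pd.option_context("display.float_format", lambda v: f"{v:0.3f}"):
            lines.append(df.to_string(index=False))
        return "\n".join(lines)

    def plot_scatter_matrix(self, kind: str = "cross-sectional", path=None):
        """Scatterplot matrix of the four measures (or their deltas)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if kind == "cross-sectional":
            data = self.model.table[list(MEASURES)]
        else:
            data = longitudinal_deltas(self.model.table)
        axes = pd.plotting.scatter_matrix(data, figsize=(8, 8))
        fig = axes[0, 0].get_figure()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
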