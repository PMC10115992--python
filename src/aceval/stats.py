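"""Log-scale paired agreement statistics with repeated-measures correction.

Paired clinical metrics (reference vs test attenuation correction) are
analysed on the log scale: per-scan differences ``d = ln(test) - ln(ref)``
are summarized as an exponentiated mean percent difference, a 95% confidence
interval for the mean, and 95% Bland-Altman limits of agreement,

    CI  = 100 * (exp(dbar +/- 1.96 * SD_d / sqrt(n)) - 1),
    LoA = 100 * (exp(dbar +/- 1.96 * SD_d) - 1),

where SD_d uses a one-way ANOVA variance decomposition when subjects
contribute repeated scans (between-subject variance of subject means plus
within-subject variance), so follow-up examinations do not artificially
narrow the limits.  With one scan per subject the correction reduces exactly
to the ordinary standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import r2_score as _sk_r2_score

__all__ = [
    "PairedSample",
    "AgreementSummary",
    "r2_score",
    "shapiro_wilk",
    "paired_t_log",
    "agreement_summary",
    "invert_loa",
    "bland_altman_table",
    "bland_altman_points",
]

Z_95 = 1.96


@dataclass
class PairedSample:
    """Paired reference/test observations grouped by subject.

    All values must be strictly positive (the analysis is on the log scale);
    ``subject`` ids group repeated scans of one patient.
    """

    subject: np.ndarray
    ref: np.ndarray
    test: np.ndarray
    timepoint: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.subject = np.asarray(self.subject)
        self.ref = np.asarray(self.ref, dtype=float)
        self.test = np.asarray(self.test, dtype=float)
        if not (len(self.subject) == len(self.ref) == len(self.test)):
            raise ValueError("subject, ref and test must have equal length")
        if (self.ref <= 0).any() or (self.test <= 0).any():
            raise ValueError("paired values must be strictly positive (log scale)")
        if self.timepoint is not None:
            self.timepoint = np.asarray(self.timepoint)

    @property
    def d(self) -> np.ndarray:
        """Per-observation log difference ln(test) - ln(ref)."""
        return np.log(self.test) - np.log(self.ref)

    @property
    def n_obs(self) -> int:
        return len(self.ref)

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.subject))


@dataclass
class AgreementSummary:
    """Exponentiated mean difference, CI and limits of agreement (percent)."""

    mean_pct: float
    ci_low_pct: float
    ci_high_pct: float
    loa_low_pct: float
    loa_high_pct: float
    p_value: float
    n_obs: int
    n_subjects: int
    sd_log: float


def r2_score(ref, test) -> float:
    """Coefficient of determination of test values against the reference."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if len(ref) < 2:
        raise ValueError("R^2 needs at least 2 observations")
    if np.ptp(ref) == 0:
        raise ValueError("R^2 is undefined for a constant reference")
    return float(_sk_r2_score(ref, test))


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (statistic, p-value)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def paired_t_log(sample: PairedSample) -> float:
    """Two-sided one-sample t-test of the log differences against zero.

    Identical pairs (zero variance) return a NaN sentinel with a warning
    rather than an error, so identity pipelines stay runnable end to end.
    """
    d = sample.d
    if len(d) < 2:
        raise ValueError("paired t-test needs at least 2 observations")
    if np.allclose(d, d.mean(), rtol=0.0, atol=1e-12):
        warnings.warn("zero variance of log differences; p-value undefined")
        return float("nan")
    return float(sps.ttest_1samp(d, 0.0).pvalue)


def _repeated_measures_sd(sample: PairedSample) -> float:
    """SD of d with one-way ANOVA correction for repeated scans per subject.

    Total variance = between-subject variance of subject means + within-
    subject variance, with the between component estimated as
    ``(MSB - MSW) / m0`` (clipped at zero) where ``m0`` is the effective
    group size.  With one observation per subject this reduces exactly to
    ``std(d, ddof=1)``.
    """
    d = sample.d
    subjects = np.unique(sample.subject)
    counts = np.array([(sample.subject == s).sum() for s in subjects])
    n, k = len(d), len(subjects)
    if k < 2:
        raise ValueError("repeated-measures SD needs at least 2 subjects")
    if (counts == 1).all():
        return float(np.std(d, ddof=1))
    grand = d.mean()
    means = np.array([d[sample.subject == s].mean() for s in subjects])
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(sum(((d[sample.subject == s] - m) ** 2).sum()
                          for s, m in zip(subjects, means)))
    msb = ss_between / (k - 1)
    msw = ss_within / (n - k) if n > k else 0.0
    m0 = (n - (counts ** 2).sum() / n) / (k - 1)
    var_between = max((msb - msw) / m0, 0.0)
    return float(np.sqrt(var_between + msw))


def agreement_summary(sample: PairedSample, ci_uses_subjects: bool = True
                      ) -> AgreementSummary:
    """Exponentiated log-scale agreement summary of a paired sample.

    ``mean_pct = 100 * (exp(dbar) - 1)``; the CI divides SD_d by the square
    root of the number of subjects (default) or scans, the LoA use SD_d
    directly.  SD_d carries the repeated-measures correction whenever any
    subject contributes more than one scan.
    """
    if sample.n_obs < 2:
        raise ValueError("agreement summary needs at least 2 observations")
    if sample.n_subjects < 2:
        raise ValueError("CI is undefined with a single subject")
    d = sample.d
    dbar = float(d.mean())
    sd = _repeated_measures_sd(sample)
    n_eff = sample.n_subjects if ci_uses_subjects else sample.n_obs
    se = sd / np.sqrt(n_eff)
    to_pct = lambda v: float(100.0 * (np.exp(v) - 1.0))
    return AgreementSummary(
        mean_pct=to_pct(dbar),
        ci_low_pct=to_pct(dbar - Z_95 * se),
        ci_high_pct=to_pct(dbar + Z_95 * se),
        loa_low_pct=to_pct(dbar - Z_95 * sd),
        loa_high_pct=to_pct(dbar + Z_95 * sd),
        p_value=paired_t_log(sample),
        n_obs=sample.n_obs,
        n_subjects=sample.n_subjects,
        sd_log=sd,
    )


def invert_loa(loa_low_pct: float, loa_high_pct: float) -> float:
    """Recover the mean percent difference from its limits of agreement.

    The LoA are symmetric around dbar on the log scale, so
    ``dbar = 0.5 * ln((1 + lo/100) * (1 + hi/100))``; returns
    ``100 * (exp(dbar) - 1)``.  Used as an internal-consistency check of the
    exponentiated-LoA construction.
    """
    if loa_low_pct <= -100.0:
        raise ValueError("lower limit of agreement must exceed -100%")
    dbar = 0.5 * np.log((1.0 + loa_low_pct / 100.0) * (1.0 + loa_high_pct / 100.0))
    return float(100.0 * (np.exp(dbar) - 1.0))


TABLE_COLUMNS = ["metric", "mean_pct", "ci_low_pct", "ci_high_pct",
                 "loa_low_pct", "loa_high_pct", "p_value", "n_obs", "n_subjects"]


def bland_altman_table(samples: dict[str, PairedSample]) -> pd.DataFrame:
    """One agreement-summary row per metric, in stable column order."""
    if not samples:
        raise ValueError("no samples given")
    rows = []
    for metric, sample in samples.items():
        s = agreement_summary(sample)
        rows.append({"metric": metric, "mean_pct": s.mean_pct,
                     "ci_low_pct": s.ci_low_pct, "ci_high_pct": s.ci_high_pct,
                     "loa_low_pct": s.loa_low_pct, "loa_high_pct": s.loa_high_pct,
                     "p_value": s.p_value, "n_obs": s.n_obs,
                     "n_subjects": s.n_subjects})
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def bland_altman_points(sample: PairedSample) -> pd.DataFrame:
    """Plot data for a Bland-Altman panel: pair means vs percent differences."""
    return pd.DataFrame({
        "mean_value": (sample.ref + sample.test) / 2.0,
        "diff_pct": 100.0 * (sample.test / sample.ref - 1.0),
        "subject": sample.subject,
    })
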