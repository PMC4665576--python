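"""Core domain types for factorial diagnostic-trial analysis.

The central objects mirror the flow of a predictive-value analysis:

* :class:`TestResultsTable` — per-subject binary outcomes of ``M`` diagnostic
  modalities plus a gold-standard disease label.
* :class:`AccuracySummary` — sensitivity/specificity vectors and the joint
  covariance of their estimators.
* :class:`PrevalenceSpec` — per-risk-group prevalence estimates (from prior
  studies) with sampling variances.
* :class:`PVResult` — risk-group-specific PPV or NPV vector with its
  delta-method covariance, the input needed by interval and test routines.
* :class:`IntervalSet` / :class:`ATSResult` — interval estimates and the
  ANOVA-type test summary.

All covariances are on the finite-sample scale, i.e. ``Cov`` of the estimator
itself; the asymptotic (root-N normalised) covariance is this matrix times N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TestResultsTable",
    "PrevalenceSpec",
    "AccuracySummary",
    "PVResult",
    "IntervalSet",
    "ATSResult",
    "INTERVAL_METHODS",
]

#: Recognised confidence-interval method tags.  ``mercaldo-*`` variants treat
#: the prevalence as a known constant (its variance contribution is dropped).
INTERVAL_METHODS = (
    "additive-normal",
    "additive-t",
    "logistic-normal",
    "logistic-t",
    "mercaldo-additive",
    "mercaldo-logistic",
)


def _as_binary(a, name: str) -> np.ndarray:
    arr = np.asarray(a)
    if arr.size and not np.isin(arr, (0, 1)).all():
        bad = np.unique(arr[~np.isin(arr, (0, 1))])
        raise ValueError(f"{name} must be binary (0/1); found {bad.tolist()}")
    return arr.astype(np.int8)


@dataclass
class TestResultsTable:
    """Subject-level results of ``M`` diagnostic tests plus gold standard.

    Parameters
    ----------
    subject_id : array-like
        Opaque per-subject identifiers (unique).
    gold : array-like of {0, 1}
        Gold-standard disease status; 1 = diseased, 0 = non-diseased.
    results : array-like of {0, 1}, shape (n_subjects, M)
        Binary test outcomes, one column per modality (or per flattened
        reader x method cell); 1 = positive.
    modality_labels : sequence of str, optional
        Column labels; defaults to ``mod1 .. modM``.
    """

    subject_id: np.ndarray
    gold: np.ndarray
    results: np.ndarray
    modality_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id)
        self.gold = _as_binary(self.gold, "gold")
        results = np.asarray(self.results)
        if results.ndim == 1:
            results = results[:, None]
        self.results = _as_binary(results, "results")
        n, M = self.results.shape
        if self.modality_labels is None:
            self.modality_labels = [f"mod{m + 1}" for m in range(M)]
        self.modality_labels = list(map(str, self.modality_labels))
        if len(self.modality_labels) != M:
            raise ValueError("modality_labels length does not match results")
        if len(self.subject_id) != n or len(self.gold) != n:
            raise ValueError("subject_id, gold and results have unequal lengths")
        if len(np.unique(self.subject_id)) != n:
            raise ValueError("duplicate subject_id values")
        if n == 0:
            raise ValueError("empty table: no subjects")
        if self.n1 < 1 or self.n0 < 1:
            raise ValueError(
                "need at least one diseased (gold=1) and one non-diseased "
                f"(gold=0) subject; got n1={self.n1}, n0={self.n0}"
            )

    # -- basic dimensions -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.results.shape[0]

    @property
    def n_modalities(self) -> int:
        return self.results.shape[1]

    @property
    def n1(self) -> int:
        """Number of diseased subjects."""
        return int(self.gold.sum())

    @property
    def n0(self) -> int:
        """Number of non-diseased subjects."""
        return int((1 - self.gold).sum())

    @classmethod
    def from_counts(
        cls,
        tp: int,
        fp: int,
        fn: int,
        tn: int,
        label: str = "mod1",
    ) -> "TestResultsTable":
        """Build a single-modality table from 2x2 contingency counts.

        ``tp``/``fn`` are positives/negatives among diseased subjects,
        ``fp``/``tn`` among non-diseased subjects.
        """
        gold = np.repeat([1, 1, 0, 0], [tp, fn, fp, tn])
        res = np.repeat([1, 0, 1, 0], [tp, fn, fp, tn])
        ids = np.array([f"s{i + 1}" for i in range(gold.size)])
        return cls(ids, gold, res[:, None], [label])


@dataclass
class PrevalenceSpec:
    """Per-risk-group prevalence of disease, estimated or fixed.

    Estimated groups carry ``pi_hat = k/m`` with binomial variance
    ``pi_hat (1 - pi_hat) / m``; groups flagged fixed are treated as known
    constants with variance 0 (the classical fixed-prevalence convention).
    """

    group_labels: list[str]
    k: np.ndarray  # NaN for fixed groups
    m: np.ndarray  # NaN for fixed groups
    pi_hat: np.ndarray
    var_pi: np.ndarray
    fixed: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group_labels = list(map(str, self.group_labels))
        self.k = np.asarray(self.k, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        self.pi_hat = np.asarray(self.pi_hat, dtype=float)
        self.var_pi = np.asarray(self.var_pi, dtype=float)
        self.fixed = np.asarray(self.fixed, dtype=bool)
        G = len(self.group_labels)
        if len(set(self.group_labels)) != G:
            raise ValueError("duplicate risk-group labels")
        for a in (self.k, self.m, self.pi_hat, self.var_pi, self.fixed):
            if len(a) != G:
                raise ValueError("prevalence field lengths disagree")
        if np.any((self.pi_hat <= 0) | (self.pi_hat >= 1)):
            raise ValueError(
                "prevalence must lie strictly inside (0, 1): boundary values "
                "violate the open-interval assumption of the asymptotics"
            )
        if not np.all((self.var_pi == 0) == self.fixed):
            raise ValueError("var_pi must be 0 exactly for fixed groups")

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def index(self, group: str | int) -> int:
        if isinstance(group, (int, np.integer)):
            return int(group)
        try:
            return self.group_labels.index(str(group))
        except ValueError:
            raise KeyError(
                f"unknown risk group {group!r}; have {self.group_labels}"
            ) from None


@dataclass
class AccuracySummary:
    """Sensitivity/specificity vectors with the estimator covariance.

    ``cov_se`` and ``cov_sp`` are finite-sample covariance matrices of the
    estimators.  The diseased and non-diseased groups are independent, so the
    cross-covariance between ``se`` and ``sp`` estimators is identically zero.
    When the summary was built from marginal inputs only (no subject-level
    data), the off-diagonal entries are unknown and stored as NaN with
    ``has_cross_covariance = False``; multi-modality tests and difference
    intervals then refuse to run.
    """

    se: np.ndarray
    sp: np.ndarray
    n1: int
    n0: int
    cov_se: np.ndarray
    cov_sp: np.ndarray
    modality_labels: list[str] = None  # type: ignore[assignment]
    has_cross_covariance: bool = True

    def __post_init__(self) -> None:
        self.se = np.atleast_1d(np.asarray(self.se, dtype=float))
        self.sp = np.atleast_1d(np.asarray(self.sp, dtype=float))
        self.cov_se = np.atleast_2d(np.asarray(self.cov_se, dtype=float))
        self.cov_sp = np.atleast_2d(np.asarray(self.cov_sp, dtype=float))
        M = self.se.size
        if self.sp.size != M:
            raise ValueError("se and sp must have equal length")
        for c in (self.cov_se, self.cov_sp):
            if c.shape != (M, M):
                raise ValueError("covariance shape does not match M")
        if self.modality_labels is None:
            self.modality_labels = [f"mod{m + 1}" for m in range(M)]
        self.modality_labels = list(map(str, self.modality_labels))
        self.n1 = int(self.n1)
        self.n0 = int(self.n0)
        if self.n1 < 1 or self.n0 < 1:
            raise ValueError("n1 and n0 must be >= 1")
        if np.any((self.se < 0) | (self.se > 1) | (self.sp < 0) | (self.sp > 1)):
            raise ValueError("se and sp must lie in [0, 1]")
        if np.any((self.se <= 0) | (self.se >= 1) | (self.sp <= 0) | (self.sp >= 1)):
            warnings.warn(
                "sensitivity or specificity estimated at 0 or 1: downstream "
                "asymptotics assume values strictly inside (0, 1)",
                stacklevel=2,
            )

    @property
    def n_modalities(self) -> int:
        return self.se.size

    def modality_index(self, modality: str | int) -> int:
        if isinstance(modality, (int, np.integer)):
            return int(modality)
        return self.modality_labels.index(str(modality))


@dataclass
class PVResult:
    """A risk group's PPV or NPV vector with delta-method covariance.

    ``components`` splits ``cov`` into the three additive variance sources
    (sensitivity, specificity, prevalence); they are needed for the
    Satterthwaite degrees of freedom and the fixed-prevalence intervals.
    """

    group_label: str
    side: str  # "ppv" | "npv"
    estimates: np.ndarray
    cov: np.ndarray
    components: dict[str, np.ndarray]
    accuracy: AccuracySummary
    pi: float
    var_pi: float
    m_g: float  # NaN when the prevalence is fixed / counts unknown
    modality_labels: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.side = str(self.side).lower()
        if self.side not in ("ppv", "npv"):
            raise ValueError("side must be 'ppv' or 'npv'")
        self.estimates = np.atleast_1d(np.asarray(self.estimates, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.modality_labels is None:
            self.modality_labels = list(self.accuracy.modality_labels)

    @property
    def n_modalities(self) -> int:
        return self.estimates.size

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of boundary point estimates (0 or 1)."""
        return (self.estimates <= 0) | (self.estimates >= 1)


@dataclass
class IntervalSet:
    """Per-modality confidence bounds for one method variant."""

    method: str
    alpha: float
    estimates: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    failed: np.ndarray
    df: np.ndarray | None = None
    modality_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.method not in INTERVAL_METHODS:
            raise ValueError(
                f"unknown interval method {self.method!r}; "
                f"choose one of {INTERVAL_METHODS}"
            )
        for name in ("estimates", "lower", "upper"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        self.failed = np.atleast_1d(np.asarray(self.failed, bool))

    @property
    def length(self) -> np.ndarray:
        return self.upper - self.lower


@dataclass
class ATSResult:
    """ANOVA-type test of equal predictive values across modalities.

    The statistic is referred to a scaled chi-square distribution
    ``chi2(f) / f`` with estimated degrees of freedom ``f``.
    """

    statistic: float
    df: float
    p_value: float
    contrast: np.ndarray
    scale: str  # "additive" | "logit"
    side: str
    group_label: str
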