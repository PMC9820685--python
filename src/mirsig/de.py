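"""Two-group differential expression with BH-FDR and signature expansion.

Endogenous probes are tested one at a time with Welch's unequal-variance
t-test on log2(normalized value + 1), comparing metastatic against primary
samples; two-sided p-values are corrected by Benjamini–Hochberg, and
significant probes are expanded to one row per annotated miRNA (a probe
shared by two identical-sequence miRNAs yields two rows). "Up" means higher
in metastasis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DesignError, DomainError
from .io import NormalizedDataset

DE_COLUMNS = [
    "mean_log2_primary",
    "mean_log2_metastasis",
    "log2fc",
    "p_value",
    "fdr",
    "significant",
    "direction",
]


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``q_(i) = min_{j >= i} m * p_(j) / j``, capped at 1 and mapped back to
    the input order. Raises :class:`~mirsig.errors.DomainError` for values
    outside [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise DomainError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t-test along axis 1; returns (t, two-sided p).

    Zero variance in both groups is resolved by convention: p = 1 when the
    group means coincide, p = 0 when they differ (a deterministic separation
    is treated as infinitely significant).
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    both_zero = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    equal_means = np.isclose(m1, m2, rtol=1e-12, atol=0.0)
    p = np.where(both_zero, np.where(equal_means, 1.0, 0.0), p)
    with np.errstate(invalid="ignore"):
        t = np.where(
            both_zero, np.where(equal_means, 0.0, np.inf * np.sign(m2 - m1)), t
        )
    return t, p


class WelchDifferentialExpression(BaseEstimator):
    """Per-feature Welch t-test with BH-FDR, sklearn-estimator-shaped.

    ``fit(X, y)`` takes samples as rows and probes as columns; ``y`` holds
    tissue labels. Values are log2(x + log_offset)-transformed internally.

    Parameters
    ----------
    alpha : float, default 0.05
        FDR significance threshold.
    log_offset : float, default 1.0
        Offset added before the log2 transform (avoids log(0) on counts).
    positive_class, reference_class : str
        Labels of the two groups; ``log2fc`` is positive minus reference,
        so "up" means higher in the positive (metastatic) class.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per feature, ranked by p ascending: group means on the log2
        scale, log2fc, p_value, fdr, significant, direction.
    """

    def __init__(self, alpha: float = 0.05, log_offset: float = 1.0,
                 positive_class: str = "metastasis",
                 reference_class: str = "primary"):
        self.alpha = alpha
        self.log_offset = log_offset
        self.positive_class = positive_class
        self.reference_class = reference_class

    def fit(self, X, y):
        if not 0.0 < self.alpha < 1.0:
            raise DomainError("alpha must be in (0, 1)")
        feature_names = (
            X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(np.shape(X)[1])
        )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise DataError("non-finite expression values")
        labels = set(unique_labels(y))
        if labels != {self.positive_class, self.reference_class}:
            raise DesignError(
                f"y must contain exactly the classes "
                f"{{{self.reference_class!r}, {self.positive_class!r}}}, got {labels}"
            )
        ref = X[y == self.reference_class]
        pos = X[y == self.positive_class]
        if len(ref) < 2 or len(pos) < 2:
            raise DesignError("each group needs >= 2 samples")
        self.n_features_in_ = X.shape[1]

        log_ref = np.log2(ref + self.log_offset)
        log_pos = np.log2(pos + self.log_offset)
        t, p = _welch(log_ref.T, log_pos.T)
        fdr = bh_adjust(p)
        log2fc = log_pos.mean(axis=0) - log_ref.mean(axis=0)
        significant = fdr < self.alpha
        direction = np.where(
            significant, np.where(log2fc > 0, "up", "down"), "none"
        )
        self.results_ = pd.DataFrame(
            {
                "mean_log2_primary": log_ref.mean(axis=0),
                "mean_log2_metastasis": log_pos.mean(axis=0),
                "log2fc": log2fc,
                "p_value": p,
                "fdr": fdr,
                "significant": significant,
                "direction": direction,
            },
            index=feature_names,
        ).sort_values("p_value", kind="stable")
        return self

    def significant_features(self) -> pd.Index:
        check_is_fitted(self, "results_")
        return self.results_.index[self.results_["significant"]]


@dataclass
class DEResult:
    """Ranked per-probe differential-expression table at a given alpha."""

    table: pd.DataFrame  # indexed by probe_id, columns DE_COLUMNS, p-ascending
    alpha: float

    @property
    def significant_probes(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def de_test(norm: NormalizedDataset, alpha: float = 0.05) -> DEResult:
    """Welch DE over the endogenous probes of a normalized dataset.

    Controls are excluded from both the tests and the BH family.
    """
    endo = norm.endogenous_probes
    X = norm.values.loc[endo].T  # samples x probes
    y = norm.sample_meta["tissue_class"].to_numpy()
    est = WelchDifferentialExpression(alpha=alpha).fit(X, y)
    return DEResult(table=est.results_, alpha=alpha)


def call_signature(de: DEResult, probe_info: pd.DataFrame,
                   alpha: float | None = None) -> pd.DataFrame:
    """Expand significant probes into a per-miRNA signature table.

    One row per (significant probe x annotated miRNA); direction and
    statistics are inherited from the probe. Returns an empty table when
    nothing is significant.
    """
    if alpha is not None and alpha != de.alpha:
        raise DomainError(
            f"signature alpha {alpha} differs from DE alpha {de.alpha}"
        )
    rows = []
    sig = de.table[de.table["significant"]]
    for probe_id, row in sig.iterrows():
        for mirna in probe_info.loc[probe_id, "annotated_mirnas"]:
            rows.append(
                (mirna, probe_id, row["direction"], row["log2fc"], row["fdr"])
            )
    return pd.DataFrame(
        rows, columns=["mirna", "probe_id", "direction", "log2fc", "fdr"]
    )
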