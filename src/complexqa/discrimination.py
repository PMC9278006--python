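"""Score-discrimination statistics: how well a per-model score separates CAPRI classes.

Given a table of models with CAPRI labels and score columns, this module
computes ROC AUC (the Mann–Whitney probability with midrank tie handling) for
binary class groupings, 95% confidence intervals from stratified bootstrap
resampling, macro one-vs-rest multiclass AUC, optimal score cutpoints by
maximization of sensitivity + specificity, and the comparison statistics used
alongside (two-sided rank-sum test, Pearson correlation, significance stars).

Every score column carries a direction flag — higher-is-better (pTM, pLDDT) or
lower-is-better (PAE, energy scores) — so orientation is explicit rather than
baked into sign conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .capri import CAPRI_CLASSES

logger = logging.getLogger("complexqa")

DEFAULT_N_BOOT = 2000

#: default orientation of the score columns this toolkit produces
DEFAULT_DIRECTIONS = {
    "ptm": "higher",
    "iptm": "higher",
    "interface_plddt": "higher",
    "average_plddt": "higher",
    "average_resolved_plddt": "higher",
    "interface_pae": "lower",
    "n_interface_residues": "higher",
}


class DiscriminationError(ValueError):
    pass


@dataclass
class ScoreTable:
    """Per-model rows (case, rank, capri_class, score columns) with directions."""

    frame: pd.DataFrame
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"case", "rank", "capri_class"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DiscriminationError(f"missing columns: {sorted(missing)}")
        bad = set(self.frame["capri_class"]) - set(CAPRI_CLASSES)
        if bad:
            raise DiscriminationError(f"unknown CAPRI classes: {sorted(bad)}")
        if self.frame.duplicated(subset=["case", "rank"]).any():
            raise DiscriminationError("duplicated (case, rank) rows")
        for col in self.score_columns:
            self.directions.setdefault(col, DEFAULT_DIRECTIONS.get(col, "higher"))

    @property
    def score_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("case", "rank", "capri_class")]

    def direction(self, column: str) -> str:
        d = self.directions.get(column, "higher")
        if d not in ("higher", "lower"):
            raise DiscriminationError(f"direction for {column} must be 'higher' or 'lower'")
        return d

    @classmethod
    def from_tsv(cls, path, directions: dict[str, str] | None = None) -> "ScoreTable":
        return cls(pd.read_csv(path, sep="\t"), directions or {})

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def _groups(self, column: str, positives: set[str], negatives: set[str]):
        """Oriented score arrays for the two class groups (NaN rows dropped)."""
        df = self.frame.dropna(subset=[column])
        n_dropped = len(self.frame) - len(df)
        if n_dropped:
            logger.info("%s: %d rows without a value excluded", column, n_dropped)
        sign = 1.0 if self.direction(column) == "higher" else -1.0
        pos = sign * df.loc[df["capri_class"].isin(positives), column].to_numpy(float)
        neg = sign * df.loc[df["capri_class"].isin(negatives), column].to_numpy(float)
        return pos, neg


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    curve: np.ndarray  # ordered (1 - specificity, sensitivity) points


@dataclass
class CutpointResult:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def objective(self) -> float:
        return self.sensitivity + self.specificity


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the Mann–Whitney probability, ties counted half, via midranks."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _roc_curve(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """(1-specificity, sensitivity) points over descending score thresholds."""
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    # step only at distinct score values
    distinct = np.nonzero(np.diff(scores))[0]
    idx = np.concatenate([distinct, [len(scores) - 1]])
    tp = np.cumsum(labels)[idx]
    fp = np.cumsum(1 - labels)[idx]
    fpr = np.concatenate([[0.0], fp / len(neg)])
    tpr = np.concatenate([[0.0], tp / len(pos)])
    return np.column_stack([fpr, tpr])


def binary_auc(table: ScoreTable, column: str,
               positives: set[str], negatives: set[str],
               n_boot: int = DEFAULT_N_BOOT, seed: int | None = None) -> RocResult:
    """ROC AUC of ``column`` for positives vs negatives, with bootstrap 95% CI.

    The column's direction flag orients the score so that better scores for
    positives give AUC > 0.5. Pass ``n_boot=0`` to skip the CI.
    """
    pos, neg = table._groups(column, set(positives), set(negatives))
    if len(pos) == 0 or len(neg) == 0:
        raise DiscriminationError("both class groups must be non-empty")
    if np.ptp(np.concatenate([pos, neg])) == 0:
        logger.warning("%s: constant score column, AUC is 0.5", column)
    auc = _auc_mann_whitney(pos, neg)
    if n_boot > 0 and len(pos) >= 2 and len(neg) >= 2:
        ci_low, ci_high = bootstrap_ci(table, column, set(positives), set(negatives),
                                       n_boot=n_boot, seed=seed)
    else:
        ci_low = ci_high = auc
    return RocResult(auc=auc, ci_low=ci_low, ci_high=ci_high,
                     n_pos=len(pos), n_neg=len(neg), curve=_roc_curve(pos, neg))


def bootstrap_ci(table: ScoreTable, column: str,
                 positives: set[str], negatives: set[str],
                 n_boot: int = DEFAULT_N_BOOT, seed: int | None = None,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Percentile 95% CI of the AUC over stratified bootstrap resampling.

    Positives and negatives are resampled separately with their group sizes
    preserved (stratified scheme, default 2000 replicates). Degenerate
    replicates cannot occur under stratification since both strata stay
    non-empty.
    """
    pos, neg = table._groups(column, set(positives), set(negatives))
    if len(pos) < 2 or len(neg) < 2:
        raise DiscriminationError("both groups need >= 2 members for a bootstrap CI")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos, size=len(pos), replace=True)
        n = rng.choice(neg, size=len(neg), replace=True)
        aucs[b] = _auc_mann_whitney(p, n)
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    point = _auc_mann_whitney(pos, neg)
    # percentile intervals on small samples can exclude the point estimate;
    # clamp so the reported interval always contains it
    return float(min(lo, point)), float(max(hi, point))


#: CAPRI classes in increasing accuracy order
_CLASS_ORDER = ("incorrect", "acceptable", "medium", "high")


def multiclass_auc(table: ScoreTable, column: str,
                   n_boot: int = DEFAULT_N_BOOT, seed: int | None = None,
                   average: str = "macro") -> RocResult:
    """Multiclass AUC over the ordered CAPRI classes, with bootstrap 95% CI.

    The CAPRI classes are ordinal, so a single score column is binarized at
    each adjacent class boundary (incorrect | acceptable-or-better, and so on
    up the ladder); each split yields a Mann-Whitney AUC oriented by the
    column's direction flag, and the splits are averaged — unweighted
    ("macro", default) or weighted by split size ("micro"). A two-class table
    reduces to the plain binary AUC, and perfectly class-ordered scores give
    1.0. Classes with fewer than 2 members are excluded with a warning. The
    CI resamples each class stratum separately.
    """
    df = table.frame.dropna(subset=[column])
    counts = df["capri_class"].value_counts()
    classes = [c for c in _CLASS_ORDER if counts.get(c, 0) >= 2]
    skipped = [c for c in _CLASS_ORDER if 0 < counts.get(c, 0) < 2]
    if skipped:
        logger.warning("classes with <2 members excluded: %s", skipped)
    if len(classes) < 2:
        raise DiscriminationError("need >= 2 classes with >= 2 members")
    sign = 1.0 if table.direction(column) == "higher" else -1.0
    keep = df["capri_class"].isin(classes).to_numpy()
    scores = sign * df[column].to_numpy(float)[keep]
    levels = df["capri_class"].map({c: i for i, c in enumerate(classes)}).to_numpy()[keep]

    def split_auc(scores_, levels_):
        aucs, weights = [], []
        for cut in range(1, len(classes)):
            hi_mask = levels_ >= cut
            if not hi_mask.any() or hi_mask.all():
                continue
            aucs.append(_auc_mann_whitney(scores_[hi_mask], scores_[~hi_mask]))
            weights.append(len(scores_))
        if not aucs:
            return np.nan
        if average == "micro":
            return float(np.average(aucs, weights=weights))
        return float(np.mean(aucs))

    auc = split_auc(scores, levels)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = []
        idx_by_level = [np.nonzero(levels == i)[0] for i in range(len(classes))]
        while len(reps) < n_boot:
            take = np.concatenate([
                rng.choice(idx, size=len(idx), replace=True) for idx in idx_by_level
            ])
            rep = split_auc(scores[take], levels[take])
            if not np.isnan(rep):
                reps.append(rep)
        lo, hi = np.quantile(reps, [0.025, 0.975])
        lo, hi = float(min(lo, auc)), float(max(hi, auc))
    else:
        lo = hi = auc
    n_best = int(counts.get(classes[-1], 0))
    return RocResult(auc=auc, ci_low=lo, ci_high=hi,
                     n_pos=n_best, n_neg=int(sum(counts.get(c, 0) for c in classes)) - n_best,
                     curve=np.empty((0, 2)))


def optimal_cutpoint(table: ScoreTable, column: str,
                     positives: set[str], negatives: set[str]) -> CutpointResult:
    """Observed-score threshold maximizing sensitivity + specificity.

    With a higher-is-better column, a model is called positive when its score
    is >= the threshold (<= for lower-is-better). Ties on the objective are
    broken toward higher specificity, then the more permissive threshold.
    The reported threshold is an achieved observed value, not a midpoint.
    """
    pos, neg = table._groups(column, set(positives), set(negatives))
    if len(pos) == 0 or len(neg) == 0:
        raise DiscriminationError("both class groups must be non-empty")
    sign = 1.0 if table.direction(column) == "higher" else -1.0
    best = None
    for t in np.unique(np.concatenate([pos, neg])):
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        key = (sens + spec, spec, -t)  # permissive = lower oriented threshold
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, t, sens, spec = best
    return CutpointResult(threshold=float(sign * t), sensitivity=sens, specificity=spec)


def rank_sum_test(x, y) -> float:
    """Two-sided Mann–Whitney rank-sum p-value.

    Exact enumeration when both samples have n <= 8 and no ties; the normal
    approximation with tie and continuity corrections otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DiscriminationError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == combined.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation and its t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise DiscriminationError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DiscriminationError("constant vector has no defined correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional label: ns, *, **, ***."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value must be in [0, 1]")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"
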