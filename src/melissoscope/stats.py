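"""Statistical machinery: Tukey grouping, factor analysis, discrimination.

Three stages mirror the study design:

1. Per-descriptor one-way ANOVA followed by all-pairs Tukey HSD
   (Tukey–Kramer for unequal group sizes) summarized as a compact letter
   display: taxa sharing a letter are not significantly different at the
   chosen alpha.
2. Factor analysis as the eigendecomposition of the correlation matrix of
   the standardized descriptors (no rotation).  Retained factors are those
   with eigenvalue > 1 plus every factor that carries the maximum squared
   correlation (loading²) with at least one original variable.
3. Linear discriminant analysis on the standardized retained factor
   scores: eigenvectors of within⁻¹·between, axes scaled to unit
   within-class variance so that nearest-centroid Euclidean assignment is
   the standard discriminant rule.  Success is reported as a confusion
   matrix (true taxa in rows) and the correct classification rate (CCR),
   resubstitution by default.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ContractViolation, DegenerateDataError
from .stackio import FeatureTable

# ---------------------------------------------------------------------------
# Tukey HSD + compact letter display
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TukeyGrouping:
    """All-pairs Tukey result for one descriptor, with grouping letters."""

    descriptor: str
    alpha: float
    groups: List[str]                    # group (taxon) names
    means: Dict[str, float]
    sds: Dict[str, float]
    ns: Dict[str, int]
    letters: Dict[str, str]              # taxon -> letter string
    pvalues: Dict[Tuple[str, str], float]

    def significantly_different(self, a: str, b: str) -> bool:
        key = (a, b) if (a, b) in self.pvalues else (b, a)
        return self.pvalues[key] < self.alpha


def _compact_letter_display(groups: Sequence[str],
                            distinct: Dict[Tuple[str, str], bool]
                            ) -> Dict[str, str]:
    """Insert-and-absorb algorithm for compact letter displays.

    Starts from one column containing every group; for each significantly
    different pair present in a column, the column is duplicated and the
    two members split; duplicate (absorbed) columns are removed.  Columns
    are then mapped to letters a, b, c, … in order of their best mean rank.
    """
    columns: List[set] = [set(groups)]
    for (a, b), diff in distinct.items():
        if not diff:
            continue
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            ca, cb = col - {b}, col - {a}
            for c in (ca, cb):
                if not any(c <= other for other in columns):
                    columns.append(c)
        # absorb: drop any column that is a subset of another
        columns = [c for c in columns
                   if not any(c < other for other in columns)]
    # deterministic letter order: columns sorted by their first group's
    # position in the caller-supplied order
    order = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda c: min(order[g] for g in c))
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        ch = chr(ord("a") + i)
        for g in col:
            letters[g] += ch
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def tukey_letters(table: FeatureTable, descriptor: str,
                  alpha: float = 0.05) -> TukeyGrouping:
    """ANOVA + all-pairs Tukey HSD + compact letter display for one descriptor.

    Groups are the taxa of the table; unequal group sizes use the
    Tukey–Kramer adjustment.
    """
    values = table.frame[descriptor].to_numpy(float)
    labels = table.taxa.to_numpy()
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ContractViolation("Tukey grouping needs at least 2 taxa")
    ns = {g: int((labels == g).sum()) for g in groups}
    if min(ns.values()) < 2:
        raise ContractViolation("every taxon needs n >= 2")
    within_var = sum(values[labels == g].var(ddof=1) for g in groups)
    if within_var == 0:
        raise DegenerateDataError("zero within-group variance everywhere")

    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:],
                         columns=res.summary().data[0])
    pvalues: Dict[Tuple[str, str], float] = {}
    distinct: Dict[Tuple[str, str], bool] = {}
    for _, row in frame.iterrows():
        pair = (str(row["group1"]), str(row["group2"]))
        p = float(row["p-adj"])
        pvalues[pair] = p
        distinct[pair] = p < alpha

    means = {g: float(values[labels == g].mean()) for g in groups}
    sds = {g: float(values[labels == g].std(ddof=1)) for g in groups}
    # letters assigned over groups ordered by descending mean, the usual
    # table convention (best group gets 'a')
    ordered = sorted(groups, key=lambda g: -means[g])
    letters = _compact_letter_display(ordered, distinct)
    return TukeyGrouping(descriptor=descriptor, alpha=alpha, groups=groups,
                         means=means, sds=sds, ns=ns, letters=letters,
                         pvalues=pvalues)


# ---------------------------------------------------------------------------
# factor analysis
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FactorModel:
    """Principal-axis factor model of a standardized feature matrix."""

    variables: List[str]
    correlation: np.ndarray       # (p, p)
    eigenvalues: np.ndarray       # (p,) descending
    eigenvectors: np.ndarray      # (p, p), column j is factor j's axis
    loadings: np.ndarray          # (p, p), sqrt(eigval_j) * eigvec[:, j]
    scores: np.ndarray            # (n, p) raw projections of standardized data
    column_means: np.ndarray
    column_sds: np.ndarray

    @property
    def p(self) -> int:
        return len(self.variables)

    def standardized_scores(self, retained: Optional[Sequence[int]] = None
                            ) -> np.ndarray:
        """Factor scores scaled to unit variance (score_j / sqrt(eigval_j))."""
        idx = np.arange(self.p) if retained is None else np.asarray(retained)
        lam = np.sqrt(np.maximum(self.eigenvalues[idx], 1e-12))
        return self.scores[:, idx] / lam


def fit_factor_model(table: FeatureTable | np.ndarray,
                     variables: Optional[Sequence[str]] = None) -> FactorModel:
    """Eigendecompose the correlation matrix of the descriptor columns.

    Columns are standardized (zero mean, unit sample SD); constant columns
    are rejected by name.  Eigenvector signs are fixed so the largest-
    magnitude component of each factor is positive (determinism).
    """
    if isinstance(table, FeatureTable):
        data = table.values()
        names = list(table.descriptors.columns)
    else:
        data = np.asarray(table, float)
        names = list(variables) if variables is not None else [
            f"x{i}" for i in range(data.shape[1])]
    n, p = data.shape
    means = data.mean(axis=0)
    sds = data.std(axis=0, ddof=1)
    constant = [names[j] for j in range(p) if sds[j] == 0]
    if constant:
        raise DegenerateDataError(f"constant column(s): {constant}")
    z = (data - means) / sds
    corr = (z.T @ z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0),
                          np.arange(p)])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip
    loadings = eigvec * np.sqrt(eigval)
    scores = z @ eigvec
    return FactorModel(variables=names, correlation=corr,
                       eigenvalues=eigval, eigenvectors=eigvec,
                       loadings=loadings, scores=scores,
                       column_means=means, column_sds=sds)


def retain_factors(model: FactorModel) -> List[int]:
    """Indices (ascending) of the retained factors.

    Retained = factors with eigenvalue > 1, plus every factor that is the
    argmax of some variable's squared loading.
    """
    keep = set(np.flatnonzero(model.eigenvalues > 1.0).tolist())
    sq = model.loadings ** 2
    keep.update(int(j) for j in np.argmax(sq, axis=1))
    return sorted(keep)


# ---------------------------------------------------------------------------
# linear discriminant analysis
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class LDAModel:
    """Discriminant axes of within⁻¹·between and class centroids."""

    classes: List[str]
    within_scatter: np.ndarray     # pooled within-class scatter (SSCP)
    between_scatter: np.ndarray    # between-class scatter (SSCP)
    eigenvalues: np.ndarray        # descending scatter-ratio eigenvalues
    axes: np.ndarray               # (q, n_axes); unit within-class variance
    centroids: np.ndarray          # (k, n_axes) class means in axis space

    def transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, float))
        if scores.shape[1] != self.axes.shape[0]:
            raise ContractViolation(
                f"expected {self.axes.shape[0]} features, got {scores.shape[1]}")
        return scores @ self.axes


def fit_lda(scores: np.ndarray, labels: Sequence[str]) -> LDAModel:
    """Fit discriminant axes from labelled score vectors.

    Solves the generalized eigenproblem ``Sb v = λ Sw v`` on the raw
    within-class and between-class scatter (SSCP) matrices (ridge ε·trace
    added to ``Sw`` when singular).  The eigenvalues are the classical
    scatter-ratio "discriminatory power" values (near zero when labels
    carry no structure); axes with eigenvalue > 1e-10 are kept, at most
    min(q, k−1), and rescaled to unit pooled within-class variance so
    Euclidean nearest-centroid assignment equals the discriminant rule.
    """
    x = np.asarray(scores, float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    k = len(classes)
    n, q = x.shape
    if q < 1 or any((labels == c).sum() < 2 for c in classes):
        raise ContractViolation("each class needs n >= 2 and q >= 1")
    grand = x.mean(axis=0)
    sw = np.zeros((q, q))
    sb = np.zeros((q, q))
    for c in classes:
        xc = x[labels == c]
        mc = xc.mean(axis=0)
        d = xc - mc
        sw += d.T @ d
        sb += len(xc) * np.outer(mc - grand, mc - grand)
    try:
        np.linalg.cholesky(sw)
    except np.linalg.LinAlgError:
        sw = sw + np.eye(q) * 1e-8 * np.trace(sw)
    eigval, eigvec = scipy.linalg.eigh(sb, sw)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]        # Sw-orthonormal: v' Sw v = 1
    n_axes = min(q, k - 1)
    keep = [j for j in range(n_axes) if eigval[j] > 1e-10]
    if not keep:
        keep = [0]
    # v' Sw v = 1 on the scatter => multiply by sqrt(n-k) for unit
    # pooled within-class *variance* along each axis
    axes = eigvec[:, keep] * math.sqrt(max(n - k, 1))
    centroids = np.stack([x[labels == c].mean(axis=0) @ axes for c in classes])
    return LDAModel(classes=classes, within_scatter=sw, between_scatter=sb,
                    eigenvalues=eigval[keep], axes=axes, centroids=centroids)


def classify(model: LDAModel, scores: np.ndarray) -> np.ndarray:
    """Assign each score vector to the nearest centroid (Euclidean, in
    discriminant space); ties resolve to the lexicographically first label."""
    proj = model.transform(scores)
    d2 = ((proj[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    # classes are sorted, and argmin takes the first minimum: tie rule holds
    idx = np.argmin(d2, axis=1)
    return np.asarray(model.classes)[idx]


@dataclasses.dataclass
class ConfusionMatrix:
    """k×k counts (rows = true taxa, columns = assigned) with CCRs in %."""

    classes: List[str]
    counts: np.ndarray
    per_class_ccr: Dict[str, float]
    overall_ccr: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes,
                            columns=self.classes)


def confusion_and_ccr(true_labels: Sequence[str],
                      predicted_labels: Sequence[str],
                      classes: Optional[Sequence[str]] = None) -> ConfusionMatrix:
    """Confusion matrix and correct classification rates in percent."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if len(t) != len(p):
        raise ContractViolation("label vectors must have equal length")
    cls = sorted(set(t.tolist())) if classes is None else list(classes)
    outside = set(p.tolist()) - set(cls)
    if outside or (set(t.tolist()) - set(cls)):
        raise ContractViolation(f"labels outside the class set: {outside}")
    index = {c: i for i, c in enumerate(cls)}
    counts = np.zeros((len(cls), len(cls)), int)
    for a, b in zip(t, p):
        counts[index[a], index[b]] += 1
    row_sums = counts.sum(axis=1)
    per_class = {c: (100.0 * counts[i, i] / row_sums[i]) if row_sums[i] else 0.0
                 for i, c in enumerate(cls)}
    overall = 100.0 * np.trace(counts) / max(counts.sum(), 1)
    return ConfusionMatrix(classes=cls, counts=counts,
                           per_class_ccr=per_class, overall_ccr=overall)


# ---------------------------------------------------------------------------
# end-to-end: factor retention + discriminant classification
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ClassificationReport:
    """Bundle of the full retain→LDA→classify chain on one feature table."""

    factor_model: FactorModel
    retained: List[int]
    lda: LDAModel
    confusion: ConfusionMatrix
    cross_validated: bool = False


def classify_pipeline(table: FeatureTable, cross_validate: bool = False,
                      n_folds: int = 5, rng_seed: int = 0
                      ) -> ClassificationReport:
    """Standardize → factor analysis → retention rule → LDA → CCR.

    Resubstitution CCR by default (the training rows are classified);
    ``cross_validate`` switches to stratification-free k-fold CV where the
    whole chain is refit per fold.
    """
    labels = table.taxa.to_numpy()
    fm = fit_factor_model(table)
    retained = retain_factors(fm)
    scores = fm.standardized_scores(retained)
    lda = fit_lda(scores, labels)
    if not cross_validate:
        pred = classify(lda, scores)
        conf = confusion_and_ccr(labels, pred, classes=lda.classes)
        return ClassificationReport(fm, retained, lda, conf, False)

    rng = np.random.default_rng(rng_seed)
    n = len(table)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    pred = np.empty(n, dtype=object)
    data = table.values()
    for fold in folds:
        train = np.setdiff1d(order, fold)
        fm_f = fit_factor_model(data[train], variables=fm.variables)
        ret_f = retain_factors(fm_f)
        z_train = fm_f.standardized_scores(ret_f)
        lda_f = fit_lda(z_train, labels[train])
        z_test = ((data[fold] - fm_f.column_means) / fm_f.column_sds
                  @ fm_f.eigenvectors[:, ret_f]
                  / np.sqrt(np.maximum(fm_f.eigenvalues[ret_f], 1e-12)))
        pred[fold] = classify(lda_f, z_test)
    conf = confusion_and_ccr(labels, pred.astype(str), classes=lda.classes)
    return ClassificationReport(fm, retained, lda, conf, True)
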