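"""Statistical validation of a morphometric grouping.

Two independent checks of how well the variety labels separate in shape
space. (1) Pairwise one-way MANOVA on the leading weighted-PCA scores:
Wilks' lambda = det(W) / det(W + B) from the within- and between-group
cross-product matrices, converted to an F statistic by Rao's
approximation (exact for two groups). (2) A repeated blind test: the
assemblage is split at random into halves, a linear discriminant
classifier is fitted on one half's scores and labels the other half;
accumulated over many runs, the per-seed label distribution shows which
seeds are stably identified.

Both operate on the first few weighted-PCA scores rather than the raw 42
features: with ~5-8 seeds per half-group a 42-variable within-group
covariance is singular, so dimension reduction is a statistical necessity,
not a convenience.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import pca_embed
from .errors import ContractError, ParameterError
from .features import FeatureVector

#: ridge added to the pooled covariance, as a fraction of its mean diagonal
RIDGE = 1e-6


@dataclass
class ManovaResult:
    """Pairwise Wilks-lambda tests between all variety groups."""

    p_values: pd.DataFrame  # symmetric, 1.0 on the diagonal
    details: pd.DataFrame  # one row per pair: lambda, F, df1, df2, p, m_used

    def __post_init__(self) -> None:
        p = self.p_values.to_numpy()
        if not np.allclose(p, p.T):
            raise ContractError("p-value matrix must be symmetric")


@dataclass
class DAReport:
    """Accumulated labels from the repeated half-split blind test."""

    seed_ids: list[str]
    true_labels: list[str]
    class_names: list[str]
    counts: np.ndarray  # (n_seeds, n_classes) assignment counts
    n_sampled: np.ndarray  # (n_seeds,) times each seed was in the sample half
    n_runs: int
    rng_seed: int
    n_redrawn: int = 0

    def fractions(self) -> pd.DataFrame:
        """Per-seed assigned-label fractions (rows sum to 1)."""
        with np.errstate(invalid="ignore"):
            frac = self.counts / self.n_sampled[:, None]
        return pd.DataFrame(
            frac, index=self.seed_ids, columns=self.class_names
        )

    def correct_fraction(self) -> pd.Series:
        frac = self.fractions()
        return pd.Series(
            [frac.loc[s, t] for s, t in zip(self.seed_ids, self.true_labels)],
            index=self.seed_ids,
        )


def _wilks_rao(W: np.ndarray, B: np.ndarray, n: int, g: int) -> tuple:
    """Wilks' lambda and Rao's F approximation for one-way MANOVA."""
    p = W.shape[0]
    lam = np.linalg.det(W) / np.linalg.det(W + B)
    lam = min(max(lam, np.finfo(float).tiny), 1.0)
    q = g - 1
    if p * p + q * q - 5 > 0:
        t = np.sqrt((p * p * q * q - 4.0) / (p * p + q * q - 5.0))
    else:
        t = 1.0
    w = (n - g) + q - (p + q + 1) / 2.0
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2.0
    if df2 <= 0:
        return lam, np.nan, df1, df2, np.nan
    lam_t = lam ** (1.0 / t)
    f_stat = (1.0 - lam_t) / lam_t * df2 / df1
    p_val = float(stats.f.sf(f_stat, df1, df2))
    return lam, f_stat, df1, df2, p_val


def manova_pairwise(
    scores: pd.DataFrame | np.ndarray,
    labels: Sequence[str],
    m_components: int = 5,
) -> ManovaResult:
    """One-way MANOVA for every pair of groups on the first m scores.

    If the within-group cross-product matrix of a pair is singular, the
    dimensionality is reduced for that pair until it is invertible; the
    reduction is recorded in the per-pair details.
    """
    if m_components < 1:
        raise ParameterError("m_components must be >= 1")
    x = np.asarray(scores, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != len(x):
        raise ContractError("labels and scores length mismatch")
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ContractError("need at least two groups")
    m_max = min(m_components, x.shape[1])
    rows = []
    pmat = pd.DataFrame(1.0, index=groups, columns=groups)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            xa, xb = x[labels == ga, :m_max], x[labels == gb, :m_max]
            n = len(xa) + len(xb)
            m_pair = m_max
            while m_pair >= 1:
                a, b = xa[:, :m_pair], xb[:, :m_pair]
                if min(len(a), len(b)) < m_pair + 2:
                    m_pair -= 1
                    continue
                mu_a, mu_b = a.mean(0), b.mean(0)
                mu = np.vstack([a, b]).mean(0)
                W = (a - mu_a).T @ (a - mu_a) + (b - mu_b).T @ (b - mu_b)
                B = len(a) * np.outer(mu_a - mu, mu_a - mu) + len(b) * np.outer(
                    mu_b - mu, mu_b - mu
                )
                sign, logdet = np.linalg.slogdet(W)
                if sign <= 0 or np.linalg.cond(W) > 1e12:
                    m_pair -= 1
                    continue
                lam, f_stat, df1, df2, p_val = _wilks_rao(W, B, n, 2)
                if np.isfinite(p_val):
                    break
                m_pair -= 1
            else:
                raise ContractError(
                    f"groups {ga}/{gb}: too few members for MANOVA at any "
                    "dimensionality"
                )
            rows.append(
                dict(
                    group_a=ga,
                    group_b=gb,
                    wilks_lambda=lam,
                    F=f_stat,
                    df1=df1,
                    df2=df2,
                    p_value=p_val,
                    m_used=m_pair,
                )
            )
            pmat.loc[ga, gb] = pmat.loc[gb, ga] = p_val
    return ManovaResult(p_values=pmat, details=pd.DataFrame(rows))


def _lda_fit(x: np.ndarray, y: np.ndarray, classes: list[str], ridge: float):
    """Pooled-covariance linear discriminant; returns scoring function."""
    means = np.vstack([x[y == c].mean(0) for c in classes])
    priors = np.array([(y == c).sum() for c in classes], dtype=float)
    priors /= priors.sum()
    n, g = len(x), len(classes)
    pooled = np.zeros((x.shape[1], x.shape[1]))
    for c, mu in zip(classes, means):
        xc = x[y == c] - mu
        pooled += xc.T @ xc
    pooled /= max(n - g, 1)
    pooled = pooled + ridge * np.trace(pooled) / x.shape[1] * np.eye(x.shape[1])
    inv = np.linalg.inv(pooled)

    def scores(z: np.ndarray) -> np.ndarray:
        lin = z @ inv @ means.T
        const = -0.5 * np.einsum("ij,jk,ik->i", means, inv, means)
        return lin + const + np.log(priors)

    return scores


def da_blind_test(
    features: Sequence[FeatureVector] | pd.DataFrame,
    labels: Sequence[str],
    omega: np.ndarray | None = None,
    n_runs: int = 1000,
    m_components: int = 5,
    rng_seed: int = 0,
    ridge: float = RIDGE,
) -> DAReport:
    """Repeated stratified half-split discriminant blind test.

    Weighted-PCA scores are computed once for the whole assemblage (the
    embedding is unsupervised, so no label information leaks); each run
    splits every group about in half (floor/ceil alternating across runs),
    fits the pooled-covariance linear discriminant on the training half's
    first ``m_components`` scores and labels the sample half. Counts of
    assigned labels per seed accumulate over runs; fixed ``rng_seed``
    makes the whole report reproducible.
    """
    labels = [str(l) for l in labels]
    if isinstance(features, pd.DataFrame):
        scores_all = features.to_numpy()[:, :m_components]
        ids = [str(i) for i in features.index]
    else:
        if omega is None:
            raise ParameterError("omega is required with raw feature vectors")
        m = min(m_components, len(features) - 1, 42)
        pca = pca_embed(features, omega, n_components=m)
        scores_all = pca.scores.to_numpy()
        ids = [str(i) for i in pca.scores.index]
    if len(labels) != len(scores_all):
        raise ContractError("labels and features length mismatch")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ContractError("need at least two groups")
    counts_per = {c: labels.count(c) for c in classes}
    if min(counts_per.values()) < 4:
        raise ContractError("every group needs at least 4 members")

    y = np.asarray(labels)
    rng = np.random.default_rng(rng_seed)
    n_seeds = len(y)
    counts = np.zeros((n_seeds, len(classes)), dtype=np.int64)
    n_sampled = np.zeros(n_seeds, dtype=np.int64)
    cls_index = {c: j for j, c in enumerate(classes)}
    group_idx = {c: np.flatnonzero(y == c) for c in classes}
    n_redrawn = 0

    for run in range(n_runs):
        train_mask = np.zeros(n_seeds, dtype=bool)
        for c in classes:
            idx = group_idx[c]
            g = len(idx)
            n_train = g // 2 if run % 2 == 0 else (g + 1) // 2
            n_train = min(max(n_train, 1), g - 1)
            chosen = rng.choice(idx, size=n_train, replace=False)
            train_mask[chosen] = True
        # precondition (>= 4 per group) guarantees both halves keep every
        # group; the guard below only fires on contract violations
        if len(set(y[train_mask])) < len(classes):
            n_redrawn += 1
            continue
        score_fn = _lda_fit(
            scores_all[train_mask], y[train_mask], classes, ridge
        )
        test_idx = np.flatnonzero(~train_mask)
        assigned = np.argmax(score_fn(scores_all[test_idx]), axis=1)
        counts[test_idx, assigned] += 1
        n_sampled[test_idx] += 1

    return DAReport(
        seed_ids=ids,
        true_labels=list(labels),
        class_names=classes,
        counts=counts,
        n_sampled=n_sampled,
        n_runs=n_runs,
        rng_seed=rng_seed,
        n_redrawn=n_redrawn,
    )


def misid_summary(report: DAReport, threshold: float = 0.6) -> pd.DataFrame:
    """Seeds whose wrong-label fraction exceeds ``threshold``.

    Returns one row per flagged seed with its true label, the wrong-label
    fraction, and the modal wrong label.
    """
    if not 0 <= threshold <= 1:
        raise ParameterError("threshold must lie in [0, 1]")
    frac = report.fractions()
    rows = []
    for sid, true in zip(report.seed_ids, report.true_labels):
        if report.n_sampled[report.seed_ids.index(sid)] == 0:
            continue
        row = frac.loc[sid]
        wrong = 1.0 - row[true]
        if wrong > threshold:
            others = row.drop(true)
            rows.append(
                dict(
                    seed_id=sid,
                    true_label=true,
                    wrong_fraction=wrong,
                    modal_wrong_label=others.idxmax(),
                )
            )
    return pd.DataFrame(
        rows, columns=["seed_id", "true_label", "wrong_fraction", "modal_wrong_label"]
    )
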