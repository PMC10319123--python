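"""Neural-congruency components: pooled covariances, the generalized
eigenvalue decomposition, per-subject congruency scores, forward models and
temporal profiles.

Model
-----
For a reference group of S participants with concatenated epoch matrices
``X_i`` (channels x columns, equal column counts), define pairwise
cross-covariances ``R_ij = X_i X_j' / K`` (K = column count), the pooled
between-subject covariance ``Rb`` (average over all ordered pairs i != j)
and within-subject covariance ``Rw`` (average of the S auto-covariances).
The ratio

    rho(w) = (w' Rb w) / (w' Rw w)

is the average between-subject correlation of the data projected onto the
spatial filter ``w``; its stationary points are the generalized eigenvectors
of the pencil (Rb, Rw).  Components are returned in descending eigenvalue
order; ``rho(w_k) = lambda_k`` exactly.

A subject ``s`` is scored against the reference group on component k by the
between/within ratio of their own cross- and auto-covariances with the
group (the congruency score); a subject identical to every group member
scores exactly 1, an independent subject scores ~0.

Average-referenced EEG makes Rw rank-deficient (rank <= D-1), so Rw is
shrunk toward the scaled identity before inversion:
``Rw <- (1-gamma) Rw + gamma (tr(Rw)/D) I`` with gamma = 0.05 by default.
The pencil is solved by symmetric whitening, guaranteeing real eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ConcatMatrix, FRPSet

DEFAULT_SHRINKAGE = 0.05


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, ConcatMatrix):
        return x.X
    return np.asarray(x, dtype=float)


def pairwise_cross_covariance(xi, xj) -> np.ndarray:
    """R_ij = X_i X_j' / K with K the shared column count."""
    xi, xj = _as_matrix(xi), _as_matrix(xj)
    if xi.shape[1] != xj.shape[1]:
        raise ValueError(
            f"column mismatch: {xi.shape[1]} vs {xj.shape[1]} "
            "(participants must be truncated to a common epoch count)"
        )
    return xi @ xj.T / xi.shape[1]


class CovarianceTable:
    """All pairwise cross-covariances of a cohort, computed in one pass.

    Stores ``R[i, j] = X_i X_j' / K`` for every ordered pair as an
    (S, S, D, D) array.  Pooling, leave-one-out component extraction and
    subject scoring all reduce to cheap averages over blocks of this table,
    so the expensive data-size matrix products happen exactly once per
    condition.
    """

    def __init__(self, x_list):
        mats = [_as_matrix(x) for x in x_list]
        n_cols = {m.shape[1] for m in mats}
        if len(n_cols) != 1:
            raise ValueError(f"unequal column counts across participants: {sorted(n_cols)}")
        self.n_cols = n_cols.pop()
        d = mats[0].shape[0]
        if any(m.shape[0] != d for m in mats):
            raise ValueError("unequal channel counts across participants")
        s = len(mats)
        stacked = np.concatenate(mats, axis=0)  # (S*D, K)
        gram = stacked @ stacked.T / self.n_cols
        self.R = gram.reshape(s, d, s, d).transpose(0, 2, 1, 3).copy()
        self.n_subjects, self.n_channels = s, d


@dataclass
class PooledCovariances:
    """Between- and within-subject pooled covariance matrices of a group."""

    rb: np.ndarray
    rw: np.ndarray
    shrinkage: float
    subject_ids: tuple = ()

    @property
    def rw_shrunk(self) -> np.ndarray:
        d = self.rw.shape[0]
        return (1.0 - self.shrinkage) * self.rw + self.shrinkage * (
            np.trace(self.rw) / d
        ) * np.eye(d)


def pooled_covariances(x_list, shrinkage: float = DEFAULT_SHRINKAGE, subject_ids=None):
    """Pool Rb (ordered pairs i != j) and Rw (auto-covariances) of a group.

    ``x_list`` is either a list of concatenated epoch matrices or a
    :class:`CovarianceTable` (optionally restricted to ``subject_ids``).
    """
    if isinstance(x_list, CovarianceTable):
        ids = tuple(range(x_list.n_subjects)) if subject_ids is None else tuple(subject_ids)
        s = len(ids)
        if s < 2:
            raise ValueError("need at least 2 subjects to pool covariances")
        sub = x_list.R[np.ix_(ids, ids)]
        rw = sub[range(s), range(s)].mean(axis=0)
        rb = (sub.sum(axis=(0, 1)) - sub[range(s), range(s)].sum(axis=0)) / (s * (s - 1))
    else:
        mats = [_as_matrix(x) for x in x_list]
        s = len(mats)
        if s < 2:
            raise ValueError("need at least 2 subjects to pool covariances")
        table = CovarianceTable(mats)
        return pooled_covariances(table, shrinkage=shrinkage)
    rb = (rb + rb.T) / 2.0
    rw = (rw + rw.T) / 2.0
    return PooledCovariances(rb=rb, rw=rw, shrinkage=shrinkage, subject_ids=ids)


def forward_model(rw: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Scalp topography of a component: a = Rw w / (w' Rw w)."""
    w = np.asarray(w, dtype=float)
    if not np.any(w):
        raise ValueError("w must be nonzero")
    rww = rw @ w
    denom = float(w @ rww)
    if abs(denom) < 1e-15 * max(1.0, float(np.abs(rw).max())):
        raise ValueError("w lies in the null space of Rw; cannot form forward model")
    return rww / denom


def _solve_pencil(rb: np.ndarray, rw_shrunk: np.ndarray, n_components: int):
    """Whitened symmetric-definite GEVD; returns (W, lambdas) descending."""
    try:
        evals, evecs = linalg.eigh(rw_shrunk)
    except linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("Rw eigendecomposition failed") from exc
    tol = evals.max() * 1e-10 if evals.size else 0.0
    if evals.min() <= tol:
        raise ValueError(
            "Rw is singular; increase the shrinkage parameter (gamma > 0)"
        )
    whitener = evecs @ np.diag(evals**-0.5) @ evecs.T
    m = whitener @ rb @ whitener
    m = (m + m.T) / 2.0
    lam, v = linalg.eigh(m)
    order = np.argsort(lam)[::-1][:n_components]
    lam = lam[order]
    w = whitener @ v[:, order]
    w /= np.linalg.norm(w, axis=0, keepdims=True)
    return w, lam


class CorrelatedComponents(BaseEstimator, TransformerMixin):
    """Spatial filters maximizing between-subject correlation (GEVD).

    Parameters
    ----------
    n_components : int
        Number of components K to keep (descending eigenvalue order).
    shrinkage : float
        Shrinkage gamma of Rw toward the scaled identity; needed whenever
        Rw is rank-deficient (always true after average referencing).

    Attributes
    ----------
    filters_ : ndarray (D, K)
        Unit-norm spatial filters w_k, sign fixed so the largest-magnitude
        entry of each forward model is positive.
    eigenvalues_ : ndarray (K,)
        Generalized eigenvalues lambda_k, descending.
    rhos_ : ndarray (K,)
        Rayleigh quotients rho(w_k) = (w' Rb w)/(w' Rw w); equal to
        ``eigenvalues_`` up to numerical precision.
    forward_models_ : ndarray (D, K)
        Component topographies a_k = Rw w_k / (w_k' Rw w_k).
    rb_, rw_ : ndarray (D, D)
        The pooled covariances the fit used (Rw before shrinkage).

    Examples
    --------
    >>> cca = CorrelatedComponents(n_components=3).fit([x1, x2, x3])
    >>> projected = cca.transform(x_new)          # doctest: +SKIP
    """

    def __init__(self, n_components: int = 10, shrinkage: float = DEFAULT_SHRINKAGE):
        self.n_components = n_components
        self.shrinkage = shrinkage

    def fit(self, X, y=None):
        """Fit on a reference group.

        ``X`` may be a list of concatenated epoch matrices (D x columns,
        equal column counts), a :class:`CovarianceTable`, or a
        :class:`PooledCovariances`.
        """
        if isinstance(X, PooledCovariances):
            pc = X
        else:
            pc = pooled_covariances(X, shrinkage=self.shrinkage)
        d = pc.rb.shape[0]
        if self.n_components > d:
            raise ValueError(f"n_components={self.n_components} exceeds n_channels={d}")
        w, lam = _solve_pencil(pc.rb, pc.rw_shrunk, self.n_components)
        rw_s = pc.rw_shrunk
        a = np.empty_like(w)
        for k in range(w.shape[1]):
            a[:, k] = forward_model(rw_s, w[:, k])
            peak = np.argmax(np.abs(a[:, k]))
            if a[peak, k] < 0:
                a[:, k] *= -1.0
                w[:, k] *= -1.0
        num = np.einsum("dk,de,ek->k", w, pc.rb, w)
        den = np.einsum("dk,de,ek->k", w, rw_s, w)
        self.filters_ = w
        self.eigenvalues_ = lam
        self.rhos_ = num / den
        self.forward_models_ = a
        self.rb_, self.rw_ = pc.rb, pc.rw
        self.rw_shrunk_ = rw_s
        self.n_features_in_ = d
        return self

    def transform(self, X):
        """Project channels onto the fitted components.

        Accepts a (D, N) matrix, an (D, T, F) epoch stack, or a list of
        either; channel dimension must match the fit.
        """
        if isinstance(X, (list, tuple)):
            return [self.transform(x) for x in X]
        x = _as_matrix(X) if not isinstance(X, np.ndarray) else X
        if x.shape[0] != self.n_features_in_:
            raise ValueError("channel dimension mismatch")
        return np.tensordot(self.filters_.T, x, axes=(1, 0))


def subject_congruency_scores(
    table: CovarianceTable, s: int, ref_ids, filters, shrinkage: float = 0.0
) -> np.ndarray:
    """Congruency of subject ``s`` with the reference group, per component.

    score_k = (w_k' R_sb w_k) / (w_k' R_sw w_k) with
    R_sb = mean_i (R_si + R_is), R_sw = mean_i (R_ss + R_ii) over the
    reference members i.  ``shrinkage`` applies the same scaled-identity
    regularization to the within-covariance denominator as is used when the
    components are extracted — required whenever R_sw is rank-deficient
    (average-referenced data) and a filter can fall in its null space; with
    ``shrinkage=0`` the ratio is exact.
    """
    ref_ids = [i for i in ref_ids]
    if s in ref_ids:
        raise ValueError("reference group must not contain the scored subject")
    if len(ref_ids) < 1:
        raise ValueError("empty reference group")
    r = table.R
    r_sb = (r[s, ref_ids].sum(axis=0) + r[ref_ids, s].sum(axis=0)) / len(ref_ids)
    r_sw = r[s, s] + r[ref_ids, ref_ids].mean(axis=0)
    if shrinkage:
        d = r_sw.shape[0]
        r_sw = (1.0 - shrinkage) * r_sw + shrinkage * (np.trace(r_sw) / d) * np.eye(d)
    w = np.asarray(filters)
    num = np.einsum("dk,de,ek->k", w, r_sb, w)
    den = np.einsum("dk,de,ek->k", w, r_sw, w)
    if np.any(np.abs(den) < 1e-12 * max(np.abs(np.trace(r_sw)), 1e-30)):
        raise ValueError(
            "zero within-covariance denominator; use shrinkage > 0 with "
            "rank-deficient (average-referenced) data"
        )
    return num / den


def congruency_features(
    table: CovarianceTable,
    labels,
    reference_label: str = "CAC",
    n_components: int = 10,
    shrinkage: float = DEFAULT_SHRINKAGE,
    return_bases: bool = False,
):
    """Leave-one-out congruency feature vectors for every participant.

    For each participant s, components are extracted from the reference-group
    members *excluding s* (when s carries the reference label); s is then
    scored against that same exclusion group on the top ``n_components``
    components.  This guarantees a participant's own data never influences
    the basis used to score them.

    Reference-size matching: a participant outside the reference group is
    also scored against a reference of size S-1 — one reference member,
    chosen deterministically in rotation, is dropped.  Without this, members
    are scored against S-1 references and non-members against S, and that
    systematic difference (slightly different basis noise and pooling) is a
    group-coded artifact a downstream classifier can exploit even when no
    real group difference exists.  Matching the reference size for every
    scored participant removes it; it is the standard fair-comparison device
    when scoring out-of-group individuals against a normative cohort.

    Returns an (S, K) feature matrix (rows in participant order, columns in
    descending eigenvalue order) and, optionally, the per-participant fitted
    :class:`CorrelatedComponents` bases.
    """
    labels = list(labels)
    ref_all = [i for i, g in enumerate(labels) if g == reference_label]
    features = np.empty((len(labels), n_components))
    bases = {}
    n_out = 0  # rotation counter over non-reference participants
    for s in range(len(labels)):
        if s in ref_all:
            ref = [i for i in ref_all if i != s]
        else:
            drop = ref_all[n_out % len(ref_all)]
            ref = [i for i in ref_all if i != drop]
            n_out += 1
        if len(ref) < 2:
            raise ValueError(
                f"reference group too small after excluding participant {s}"
            )
        pc = pooled_covariances(table, shrinkage=shrinkage, subject_ids=ref)
        est = CorrelatedComponents(n_components=n_components, shrinkage=shrinkage).fit(pc)
        features[s] = subject_congruency_scores(
            table, s, ref, est.filters_, shrinkage=shrinkage
        )
        if return_bases:
            bases[s] = est
    return (features, bases) if return_bases else features


def temporal_profiles(filters: np.ndarray, frp_sets_by_group: dict) -> dict:
    """Grand-average projected time course of each component, per group.

    For each group: average over all epochs of all members of
    ``w_k' sFRP(t)``; returns group -> (K, T) array in projected uV.
    """
    w = np.asarray(filters)
    out = {}
    for group, frp_sets in frp_sets_by_group.items():
        stacks = [f.epochs for f in frp_sets if f.n_fixations > 0]
        if not stacks:
            raise ValueError(f"group {group} has no epochs")
        total = np.zeros((w.shape[1], stacks[0].shape[1]))
        n = 0
        for ep in stacks:
            # sum over fixations of projected epochs
            total += np.tensordot(w.T, ep.sum(axis=2), axes=(1, 0))
            n += ep.shape[2]
        out[group] = total / n
    return out


__all__ = [
    "CovarianceTable",
    "PooledCovariances",
    "CorrelatedComponents",
    "pairwise_cross_covariance",
    "pooled_covariances",
    "forward_model",
    "subject_congruency_scores",
    "congruency_features",
    "temporal_profiles",
]
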