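"""Instrument construction and validation.

Candidate instruments are either single genetic variants or *polygenic
factors* — low-rank summaries of the whole genotype matrix (principal
components of centered dosages, or correspondence-analysis axes of the
genotype indicator expansion). Factors aggregate many small genetic effects
and therefore tend to carry a stronger first-stage association than any
single variant.

Instruments are assigned to omic entities by first-stage F statistic
(exclusively: one instrument serves at most one entity), and screened for
pleiotropy with the conditional-independence property Mj _|_ IV | Mi: a valid
instrument for the edge Mi -> Mj must affect Mj only through Mi. The concrete
test is the t-test of the IV coefficient in the regression of Mj on (Mi, IV),
which is equivalent to testing the partial correlation of Mj and IV given Mi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import add_intercept, ols
from .errors import DataError, ParameterError
from .synthetic import GenotypeMatrix

__all__ = [
    "PolygenicFactors",
    "InstrumentRecord",
    "InstrumentSet",
    "build_polygenic_factors",
    "assign_instruments",
    "pleiotropy_test",
]

logger = logging.getLogger(__name__)


@dataclass
class PolygenicFactors:
    """Orthogonal genotype-derived scores usable as instruments."""

    factor_ids: list[str]
    scores: np.ndarray  # samples x factors, mutually orthogonal in-sample
    loadings: np.ndarray  # variants x factors
    variance_explained: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    variant_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        idx = self.sample_ids or range(self.scores.shape[0])
        return pd.DataFrame(self.scores, index=idx, columns=self.factor_ids)


@dataclass
class InstrumentRecord:
    instrument_id: str
    source: str  # "variant" | "factor"
    f_statistic: float
    pleiotropy_checked_against: list[str] = field(default_factory=list)
    failed_pairs: list[str] = field(default_factory=list)
    valid: bool = True

    def record_pleiotropy(self, other_entity: str, passed: bool) -> None:
        self.pleiotropy_checked_against.append(other_entity)
        if not passed:
            self.failed_pairs.append(other_entity)

    def valid_for(self, other_entity: str) -> bool:
        return self.valid and other_entity not in self.failed_pairs


@dataclass
class InstrumentSet:
    """Per-entity validated instruments; an instrument serves one entity only."""

    assignments: dict[str, list[InstrumentRecord]] = field(default_factory=dict)

    def __post_init__(self):
        seen: dict[str, str] = {}
        for entity, recs in self.assignments.items():
            for r in recs:
                if r.instrument_id in seen:
                    raise DataError(
                        f"instrument {r.instrument_id!r} assigned to both "
                        f"{seen[r.instrument_id]!r} and {entity!r}"
                    )
                seen[r.instrument_id] = entity

    def entities(self) -> list[str]:
        return list(self.assignments)

    def best_instrument(self, entity: str, for_pair: str | None = None) -> InstrumentRecord | None:
        """Strongest valid instrument of an entity (optionally valid for a pair)."""
        recs = [r for r in self.assignments.get(entity, []) if r.valid]
        if for_pair is not None:
            recs = [r for r in recs if r.valid_for(for_pair)]
        return max(recs, key=lambda r: r.f_statistic, default=None)

    def n_candidates(self) -> int:
        return sum(len(v) for v in self.assignments.values())

    def n_valid(self) -> int:
        return sum(r.valid for v in self.assignments.values() for r in v)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for entity, recs in self.assignments.items():
            for r in recs:
                rows.append(
                    {
                        "entity": entity,
                        "instrument_id": r.instrument_id,
                        "source": r.source,
                        "F": r.f_statistic,
                        "valid": r.valid,
                        "failed_pairs": ";".join(r.failed_pairs),
                    }
                )
        return pd.DataFrame(
            rows, columns=["entity", "instrument_id", "source", "F", "valid", "failed_pairs"]
        )


def _fix_signs(scores: np.ndarray, loadings: np.ndarray):
    """Deterministic sign convention: the largest-|loading| entry is positive."""
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col.size == 0:
            continue
        pivot = int(np.argmax(np.abs(col)))
        if col[pivot] < 0:
            loadings[:, k] = -col
            scores[:, k] = -scores[:, k]
    return scores, loadings


def build_polygenic_factors(
    genotypes: GenotypeMatrix, n_factors: int, method: str = "pca"
) -> PolygenicFactors:
    """Extract orthogonal polygenic factors from a genotype matrix.

    ``pca`` takes principal components of the centered dosage matrix; ``mca``
    runs correspondence analysis on the one-hot indicator expansion of the
    genotype classes {0, 1, 2} (unobserved classes are dropped per variant).
    Constant variant columns are removed with a logged warning first.
    """
    X = genotypes.dosages.astype(float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [v for v, k in zip(genotypes.variant_ids, keep) if not k]
        logger.warning("dropping %d constant variant columns: %s", len(dropped), dropped)
        X = X[:, keep]
    variant_ids = [v for v, k in zip(genotypes.variant_ids, keep) if k]
    n, m = X.shape
    if n_factors < 1 or n_factors > min(n, m):
        raise ParameterError("n_factors must be in [1, min(samples, variants)]")

    if method == "pca":
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        total = float((s**2).sum())
        scores = U[:, :n_factors] * s[:n_factors]
        loadings = Vt[:n_factors].T
        var_exp = (s[:n_factors] ** 2) / total if total > 0 else np.zeros(n_factors)
    elif method == "mca":
        scores, loadings, var_exp = _mca(X, n_factors)
    else:
        raise ParameterError(f"unknown method {method!r}; use 'pca' or 'mca'")

    scores, loadings = _fix_signs(scores, loadings)
    ids = [f"{method}{k + 1}" for k in range(n_factors)]
    return PolygenicFactors(
        factor_ids=ids,
        scores=scores,
        loadings=loadings,
        variance_explained=np.asarray(var_exp, dtype=float),
        sample_ids=list(genotypes.sample_ids),
        variant_ids=variant_ids,
    )


def _mca(X: np.ndarray, n_factors: int):
    """Correspondence analysis of the genotype indicator matrix.

    Row masses are uniform (each sample activates one category per variant),
    so the row principal coordinates are orthogonal in-sample.
    """
    n, m = X.shape
    blocks = []
    col_owner = []
    for j in range(m):
        classes = np.unique(X[:, j])
        Z = (X[:, j][:, None] == classes[None, :]).astype(float)
        blocks.append(Z)
        col_owner.extend([j] * len(classes))
    Z = np.hstack(blocks)
    grand = Z.sum()
    P = Z / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    # drop trivial null dimensions
    nz = s > 1e-12
    U, s, Vt = U[:, nz], s[nz], Vt[nz]
    k = min(n_factors, s.size)
    row_coords = (U[:, :k] * s[:k]) / np.sqrt(r)[:, None]
    inertia = s**2
    var_exp = inertia[:k] / inertia.sum() if inertia.sum() > 0 else np.zeros(k)
    # aggregate category loadings back to variants by summing |column coords|
    col_coords = (Vt[:k].T * s[:k]) / np.sqrt(c)[:, None]
    loadings = np.zeros((m, k))
    for col, owner in enumerate(col_owner):
        loadings[owner] += np.abs(col_coords[col])
    if k < n_factors:
        pad = n_factors - k
        row_coords = np.hstack([row_coords, np.zeros((n, pad))])
        loadings = np.hstack([loadings, np.zeros((m, pad))])
        var_exp = np.concatenate([var_exp, np.zeros(pad)])
    return row_coords, loadings, var_exp


def _univariate_f(candidates: np.ndarray, omics: np.ndarray) -> np.ndarray:
    """(candidates x entities) matrix of simple-regression F statistics."""
    n = candidates.shape[0]
    C = candidates - candidates.mean(axis=0)
    M = omics - omics.mean(axis=0)
    sc = np.sqrt((C**2).sum(axis=0))
    sm = np.sqrt((M**2).sum(axis=0))
    denom = np.outer(sc, sm)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (C.T @ M) / denom
    r = np.nan_to_num(np.clip(r, -1.0, 1.0))
    r2 = r**2
    with np.errstate(divide="ignore"):
        F = (n - 2) * r2 / (1.0 - r2)
    F[r2 >= 1.0] = np.inf
    return F


def assign_instruments(
    candidates: PolygenicFactors | GenotypeMatrix,
    omics: pd.DataFrame,
    strength_threshold: float = 10.0,
) -> InstrumentSet:
    """Rank candidates per entity by first-stage F and assign exclusively.

    Each candidate instrument goes to the entity where its F is highest (ties
    broken lexicographically by entity id), provided F clears the threshold.
    Entities may end up with no instrument; they are retained downstream and
    surface as bidirected edges.
    """
    if isinstance(candidates, PolygenicFactors):
        values = candidates.scores
        ids = candidates.factor_ids
        source = "factor"
        samples = candidates.sample_ids
    else:
        values = candidates.dosages.astype(float)
        ids = candidates.variant_ids
        source = "variant"
        samples = candidates.sample_ids
    if samples and list(omics.index) != list(samples):
        raise DataError("candidates and omics must cover the same samples, in order")
    entities = list(omics.columns)
    F = _univariate_f(values, omics.to_numpy(dtype=float))
    assignments: dict[str, list[InstrumentRecord]] = {e: [] for e in entities}
    for g, gid in enumerate(ids):
        row = F[g]
        best = np.max(row)
        if not best >= strength_threshold:  # handles -inf / nan
            continue
        # lexicographic tie-break on entity id
        tied = [entities[j] for j in np.flatnonzero(row == best)]
        entity = min(tied)
        assignments[entity].append(
            InstrumentRecord(instrument_id=gid, source=source, f_statistic=float(best))
        )
    for e in assignments:
        assignments[e].sort(key=lambda r: (-r.f_statistic, r.instrument_id))
    return InstrumentSet(assignments=assignments)


def pleiotropy_test(
    iv_values: np.ndarray,
    mi: np.ndarray,
    mj: np.ndarray,
    alpha_level: float = 0.05,
) -> tuple[float, float, bool]:
    """Screen for pleiotropy on the candidate relation Mi -> Mj.

    Tests the IV coefficient in Mj ~ Mi + IV (a t-test, equivalently the
    partial correlation of Mj and IV given Mi). A *pass* (p >= alpha) means
    the IV's effect on Mj is fully mediated by Mi, so the IV qualifies for the
    causal claim Mi -> Mj; a failing IV is excluded for this pair.

    Returns (t statistic, p-value, pass flag).
    """
    iv = np.asarray(iv_values, dtype=float).ravel()
    mi = np.asarray(mi, dtype=float).ravel()
    mj = np.asarray(mj, dtype=float).ravel()
    if not (iv.size == mi.size == mj.size):
        raise DataError("iv, mi and mj must have equal lengths")
    if not (0.0 < alpha_level < 1.0):
        raise ParameterError("alpha_level must lie in (0, 1)")
    for name, v in (("iv", iv), ("mi", mi), ("mj", mj)):
        if np.std(v) == 0:
            raise DataError(f"{name} is constant; the test is undefined")
        if not np.isfinite(v).all():
            raise DataError(f"{name} contains non-finite values")
    X = add_intercept(np.column_stack([mi, iv]), iv.size)
    coef, se, _, _, _ = ols(mj, X)
    t = coef[2] / se[2] if se[2] > 0 else np.inf * np.sign(coef[2])
    dof = iv.size - 3
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return float(t), p, p >= alpha_level
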