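"""Synthetic genotype + linear-Gaussian SEM simulator.

Every other module in the package is exercised against data generated here,
where the causal ground truth (the DAG, the instrument effects, the latent
confounders, injected pleiotropy and a downstream trait) is known exactly.

The data model is a linear additive structural equation model over a DAG:
entity j is generated in topological order as

    M_j = sum_i w_ij * M_i + sum_h alpha_h * IV_h + sum_u lambda_uj * U_u + eps_j

with Hardy-Weinberg genotype dosages as instruments, standard-Normal latent
confounders U, and Gaussian noise. The closed-form covariance of the system,
(I - W)^-T S (I - W)^-1 with S the exogenous-input covariance, is exposed so
that tests can compare empirical moments against an analytic oracle.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, SpecificationError

__all__ = [
    "GenotypeMatrix",
    "SemSpec",
    "TraitSpec",
    "simulate_genotypes",
    "sample_random_dag",
    "attach_instruments",
    "simulate_sem",
    "simulate_dataset",
    "inject_pleiotropy",
    "simulate_outcome",
    "make_two_sample",
    "summary_for_entity",
    "sem_covariance",
    "joint_covariance",
]


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with minor-allele frequencies."""

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray  # (n_samples, n_variants), values in {0, 1, 2}
    maf: np.ndarray  # (n_variants,), each in (0, 0.5]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        self.maf = np.asarray(self.maf, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise SpecificationError("dosage shape does not match id lists")
        if m != self.maf.size:
            raise SpecificationError("maf length does not match variant count")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise SpecificationError("dosages must lie in {0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_ids.index(variant_id)].astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.variant_ids)


@dataclass
class SemSpec:
    """Weighted-DAG structural model with instruments and latent confounders.

    ``adjacency[i, j]`` is the direct effect of entity i on entity j.
    ``iv_map`` assigns each instrumented entity its instrument ids and their
    first-stage effects alpha. ``confounder_loadings`` has one row per latent
    standard-Normal factor U and one column per entity. ``pleiotropy_edges``
    lists deliberate instrument-validity violations as
    (instrument id, off-target entity, effect).
    """

    entity_ids: list[str]
    adjacency: np.ndarray
    iv_map: dict[str, tuple[list[str], np.ndarray]] = field(default_factory=dict)
    confounder_loadings: np.ndarray | None = None
    noise_sd: np.ndarray | None = None
    pleiotropy_edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self):
        p = len(self.entity_ids)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if self.adjacency.shape != (p, p):
            raise SpecificationError("adjacency must be square over entity_ids")
        if self.noise_sd is None:
            self.noise_sd = np.ones(p)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if self.noise_sd.shape != (p,) or (self.noise_sd <= 0).any():
            raise SpecificationError("noise_sd must be strictly positive per entity")
        if self.confounder_loadings is not None:
            self.confounder_loadings = np.asarray(self.confounder_loadings, dtype=float)
            if self.confounder_loadings.ndim != 2 or self.confounder_loadings.shape[1] != p:
                raise SpecificationError("confounder_loadings must be (factors x entities)")
        self.iv_map = {
            e: (list(ids), np.asarray(alpha, dtype=float).ravel())
            for e, (ids, alpha) in self.iv_map.items()
        }
        for e, (ids, alpha) in self.iv_map.items():
            if e not in self.entity_ids:
                raise SpecificationError(f"iv_map references unknown entity {e!r}")
            if len(ids) != alpha.size:
                raise SpecificationError(f"alpha length mismatch for entity {e!r}")
        assigned = self.instrument_targets()
        for iv, target, _ in self.pleiotropy_edges:
            if target not in self.entity_ids:
                raise SpecificationError(f"pleiotropy edge targets unknown entity {target!r}")
            if assigned.get(iv) == target:
                raise SpecificationError(
                    f"pleiotropy edge for {iv!r} targets its own entity {target!r}"
                )
        self.topological_order()  # raises on cycles

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    def instrument_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ids, _ in self.iv_map.values():
            for g in ids:
                seen.setdefault(g)
        for iv, _, _ in self.pleiotropy_edges:
            seen.setdefault(iv)
        return list(seen)

    def instrument_targets(self) -> dict[str, str]:
        """Instrument id -> the entity it is assigned to in iv_map."""
        out: dict[str, str] = {}
        for e, (ids, _) in self.iv_map.items():
            for g in ids:
                out[g] = e
        return out

    def topological_order(self) -> list[int]:
        """Kahn topological order of entity indices; raises on cycles."""
        p = self.n_entities
        A = self.adjacency != 0
        indeg = A.sum(axis=0).astype(int)
        order: list[int] = []
        ready = sorted(np.flatnonzero(indeg == 0).tolist())
        while ready:
            v = ready.pop(0)
            order.append(v)
            for w in np.flatnonzero(A[v]):
                indeg[w] -= 1
                if indeg[w] == 0:
                    ready.append(int(w))
            ready.sort()
        if len(order) != p:
            raise SpecificationError("adjacency contains a directed cycle")
        return order

    def true_edges(self) -> list[tuple[str, str, float]]:
        ii, jj = np.nonzero(self.adjacency)
        return [
            (self.entity_ids[i], self.entity_ids[j], float(self.adjacency[i, j]))
            for i, j in zip(ii, jj)
        ]


@dataclass
class TraitSpec:
    """A downstream trait with a small set of direct causal parents."""

    parent_entities: list[str]
    effects: np.ndarray
    noise_sd: float = 1.0

    def __post_init__(self):
        self.effects = np.asarray(self.effects, dtype=float).ravel()
        if self.effects.size != len(self.parent_entities):
            raise SpecificationError("effects must match parent_entities in length")
        if self.noise_sd <= 0:
            raise SpecificationError("trait noise_sd must be positive")


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    maf: np.ndarray | None = None,
    variant_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Hardy-Weinberg dosages: each value is the sum of two Bernoulli(maf) draws.

    Per-variant minor-allele frequencies are drawn uniformly from ``maf_range``
    unless an explicit ``maf`` vector is supplied.
    """
    if n_samples < 1 or n_variants < 1:
        raise ParameterError("n_samples and n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    if maf is None:
        lo, hi = maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must be within (0, 0.5]")
        maf = rng.uniform(lo, hi, size=n_variants)
    maf = np.asarray(maf, dtype=float).ravel()
    if maf.size != n_variants:
        raise ParameterError("maf vector length must equal n_variants")
    if ((maf <= 0) | (maf > 0.5)).any():
        raise ParameterError("each maf must lie in (0, 0.5]")
    dosages = rng.binomial(2, maf, size=(n_samples, n_variants))
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(n_variants)]
    sample_ids = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(sample_ids, list(variant_ids), dosages, maf)


def sample_random_dag(
    n_entities: int,
    expected_out_degree: float,
    weight_range: tuple[float, float] = (0.3, 0.9),
    seed: int = 0,
    entity_ids: list[str] | None = None,
) -> SemSpec:
    """Random weighted DAG: uniform permutation + Bernoulli per ordered slot.

    A uniform permutation fixes a causal order; each of the C(n,2) slots from
    an earlier to a later node receives an edge independently with probability
    p = min(1, expected_out_degree / (n - 1)), so the expected edge count is
    p * n * (n - 1) / 2 (= expected_out_degree * n / 2 when p < 1). Nonzero
    weights are uniform in magnitude on ``weight_range`` with random sign.
    """
    if n_entities < 2:
        raise ParameterError("n_entities must be >= 2")
    if expected_out_degree < 0:
        raise ParameterError("expected_out_degree must be non-negative")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_entities)
    p_edge = min(1.0, expected_out_degree / (n_entities - 1))
    lo, hi = weight_range
    if not (0 < lo <= hi):
        raise ParameterError("weight_range must be positive and ordered")
    W = np.zeros((n_entities, n_entities))
    for a in range(n_entities):
        for b in range(a + 1, n_entities):
            if rng.random() < p_edge:
                w = rng.uniform(lo, hi) * rng.choice((-1.0, 1.0))
                W[order[a], order[b]] = w
    if entity_ids is None:
        entity_ids = [f"M{i}" for i in range(n_entities)]
    return SemSpec(entity_ids=list(entity_ids), adjacency=W)


def attach_instruments(
    spec: SemSpec,
    alpha: float | np.ndarray = 0.5,
    entities: list[str] | None = None,
    prefix: str = "iv",
) -> SemSpec:
    """Return a copy of ``spec`` with one instrument per entity (id ``iv_<entity>``)."""
    spec = copy.deepcopy(spec)
    entities = list(spec.entity_ids) if entities is None else list(entities)
    alphas = np.broadcast_to(np.asarray(alpha, dtype=float), (len(entities),))
    for e, a in zip(entities, alphas):
        spec.iv_map[e] = ([f"{prefix}_{e}"], np.array([a]))
    return SemSpec(**_spec_kwargs(spec))


def _spec_kwargs(spec: SemSpec) -> dict:
    return dict(
        entity_ids=list(spec.entity_ids),
        adjacency=spec.adjacency.copy(),
        iv_map={e: (list(ids), a.copy()) for e, (ids, a) in spec.iv_map.items()},
        confounder_loadings=None
        if spec.confounder_loadings is None
        else spec.confounder_loadings.copy(),
        noise_sd=spec.noise_sd.copy(),
        pleiotropy_edges=list(spec.pleiotropy_edges),
    )


def _instrument_loading_matrix(spec: SemSpec, instrument_ids: list[str]) -> np.ndarray:
    """(instruments x entities) matrix of direct genetic effects incl. pleiotropy."""
    g = len(instrument_ids)
    p = spec.n_entities
    gidx = {v: k for k, v in enumerate(instrument_ids)}
    eidx = {e: k for k, e in enumerate(spec.entity_ids)}
    A = np.zeros((g, p))
    for e, (ids, alpha) in spec.iv_map.items():
        for vid, a in zip(ids, alpha):
            A[gidx[vid], eidx[e]] += a
    for vid, target, eff in spec.pleiotropy_edges:
        A[gidx[vid], eidx[target]] += eff
    return A


def simulate_sem(
    spec: SemSpec,
    genotypes: GenotypeMatrix | None,
    seed: int = 0,
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Draw an omics matrix (samples x entities) from the structural model.

    Entities are generated in topological order. If the spec references
    instruments, ``genotypes`` must contain them (raw dosages enter the model).
    """
    needed = spec.instrument_ids()
    if needed and genotypes is None:
        raise SpecificationError("spec references instruments but no genotypes given")
    if genotypes is not None:
        missing = [v for v in needed if v not in genotypes.variant_ids]
        if missing:
            raise SpecificationError(f"genotypes missing instruments: {missing}")
        if n_samples is None:
            n_samples = genotypes.n_samples
        elif n_samples != genotypes.n_samples:
            raise SpecificationError("n_samples must match genotype rows")
    elif n_samples is None:
        raise ParameterError("n_samples required when no genotypes are given")

    rng = np.random.default_rng(seed)
    p = spec.n_entities
    M = np.zeros((n_samples, p))
    L = spec.confounder_loadings
    U = rng.standard_normal((n_samples, L.shape[0])) if L is not None else None
    eps = rng.standard_normal((n_samples, p)) * spec.noise_sd
    A = None
    G = None
    if needed:
        A = _instrument_loading_matrix(spec, needed)
        G = np.column_stack([genotypes.column(v) for v in needed])
    genetic = G @ A if A is not None else None
    for j in spec.topological_order():
        col = eps[:, j].copy()
        parents = np.flatnonzero(spec.adjacency[:, j])
        if parents.size:
            col += M[:, parents] @ spec.adjacency[parents, j]
        if genetic is not None:
            col += genetic[:, j]
        if U is not None:
            col += U @ L[:, j]
        M[:, j] = col
    index = genotypes.sample_ids if genotypes is not None else [f"s{i}" for i in range(n_samples)]
    return pd.DataFrame(M, index=index, columns=spec.entity_ids)


def simulate_dataset(
    spec: SemSpec,
    n_samples: int,
    seed: int = 0,
    maf: float | np.ndarray = 0.3,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Convenience: simulate genotypes for all of the spec's instruments, then omics.

    Child streams for the genotype and SEM draws are spawned from ``seed`` so a
    single integer reproduces the whole dataset.
    """
    ids = spec.instrument_ids()
    ss = np.random.SeedSequence(seed).spawn(2)
    g_seed, m_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss)
    maf_vec = np.broadcast_to(np.asarray(maf, dtype=float), (max(len(ids), 1),)).copy()
    if not ids:  # no instruments anywhere: still return an (empty-width) matrix
        geno = None
        omics = simulate_sem(spec, None, seed=m_seed, n_samples=n_samples)
        return geno, omics
    geno = simulate_genotypes(
        n_samples, len(ids), seed=g_seed, maf=maf_vec[: len(ids)], variant_ids=ids
    )
    omics = simulate_sem(spec, geno, seed=m_seed)
    return geno, omics


def inject_pleiotropy(
    spec: SemSpec, instrument: str, off_target: str, effect: float
) -> SemSpec:
    """Copy of ``spec`` with a direct instrument -> off-target effect appended."""
    targets = spec.instrument_targets()
    if instrument not in targets:
        raise ParameterError(f"instrument {instrument!r} is not assigned to any entity")
    if targets[instrument] == off_target:
        raise ParameterError(
            f"off_target {off_target!r} is the instrument's own entity; "
            "a pleiotropy edge must bypass the assigned exposure"
        )
    kwargs = _spec_kwargs(spec)
    kwargs["pleiotropy_edges"] = kwargs["pleiotropy_edges"] + [
        (instrument, off_target, float(effect))
    ]
    return SemSpec(**kwargs)


def simulate_outcome(omics: pd.DataFrame, trait: TraitSpec, seed: int = 0) -> pd.Series:
    """trait = sum(effects * parent) + Gaussian noise, aligned with omics rows."""
    missing = [p for p in trait.parent_entities if p not in omics.columns]
    if missing:
        raise SpecificationError(f"trait parents missing from omics: {missing}")
    rng = np.random.default_rng(seed)
    vals = omics[trait.parent_entities].to_numpy() @ trait.effects
    vals = vals + rng.standard_normal(len(omics)) * trait.noise_sd
    return pd.Series(vals, index=omics.index, name="trait")


def _marginal_summary(pheno: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant simple-regression slope and classical standard error."""
    n = len(pheno)
    gc = G - G.mean(axis=0)
    yc = pheno - pheno.mean()
    ss = (gc**2).sum(axis=0)
    beta = gc.T @ yc / ss
    resid_ss = (yc**2).sum() - beta**2 * ss
    sigma2 = resid_ss / (n - 2)
    se = np.sqrt(sigma2 / ss)
    return beta, se


def make_two_sample(
    spec: SemSpec,
    trait: TraitSpec,
    n1: int,
    n2: int,
    seeds: tuple[int, int],
    maf: float | np.ndarray = 0.3,
) -> tuple[dict, dict, dict]:
    """Two disjoint cohorts from one spec, plus marginal summary statistics.

    Cohort 1 carries genotypes + omics (exposure side); cohort 2 carries
    genotypes + the trait. Genotypes are regenerated from the same MAF vector
    in each cohort, never resampled, so the cohorts are fully independent.

    Returns ``(cohort1, cohort2, summaries)`` where ``summaries`` holds
    ``exposure`` (long table: variant_id, entity, beta, se, n over cohort 1)
    and ``outcome`` (variant_id, beta, se, n for the trait over cohort 2).
    """
    if n1 < 1 or n2 < 1:
        raise ParameterError("cohort sizes must be >= 1")
    s1, s2 = seeds
    if s1 == s2:
        raise ParameterError("cohort seeds must differ: cohorts must be independent")
    geno1, omics1 = simulate_dataset(spec, n1, seed=s1, maf=maf)
    geno2, omics2 = simulate_dataset(spec, n2, seed=s2, maf=maf)
    trait2 = simulate_outcome(omics2, trait, seed=s2 + 1)

    G1 = geno1.dosages.astype(float)
    rows = []
    for entity in spec.entity_ids:
        beta, se = _marginal_summary(omics1[entity].to_numpy(), G1)
        for vid, b, s in zip(geno1.variant_ids, beta, se):
            rows.append((vid, entity, b, s, n1))
    exposure = pd.DataFrame(rows, columns=["variant_id", "entity", "beta", "se", "n"])

    beta2, se2 = _marginal_summary(trait2.to_numpy(), geno2.dosages.astype(float))
    outcome = pd.DataFrame(
        {"variant_id": geno2.variant_ids, "beta": beta2, "se": se2, "n": n2}
    )
    cohort1 = {"genotypes": geno1, "omics": omics1}
    cohort2 = {"genotypes": geno2, "trait": trait2}
    return cohort1, cohort2, {"exposure": exposure, "outcome": outcome}


def summary_for_entity(exposure_table: pd.DataFrame, entity: str) -> pd.DataFrame:
    """Extract one entity's per-variant summary rows (variant_id, beta, se, n)."""
    sub = exposure_table.loc[exposure_table["entity"] == entity]
    if sub.empty:
        raise ParameterError(f"no summary rows for entity {entity!r}")
    return sub[["variant_id", "beta", "se", "n"]].reset_index(drop=True)


def _exogenous_covariance(spec: SemSpec, instrument_var: np.ndarray, A: np.ndarray) -> np.ndarray:
    S = np.diag(spec.noise_sd**2).astype(float)
    if spec.confounder_loadings is not None:
        L = spec.confounder_loadings
        S = S + L.T @ L
    if A.size:
        S = S + A.T @ (instrument_var[:, None] * A)
    return S


def sem_covariance(spec: SemSpec, maf: dict[str, float] | float | None = None) -> pd.DataFrame:
    """Closed-form entity covariance (I - W)^-T S (I - W)^-1.

    S collects the exogenous inputs: noise variances, latent-confounder
    loadings, and (when ``maf`` is given) instrument contributions with
    Hardy-Weinberg dosage variance 2 * maf * (1 - maf).
    """
    ids = spec.instrument_ids()
    A = _instrument_loading_matrix(spec, ids)
    var = _instrument_variances(ids, maf)
    S = _exogenous_covariance(spec, var, A)
    I_W = np.eye(spec.n_entities) - spec.adjacency
    inv = np.linalg.inv(I_W)
    cov = inv.T @ S @ inv
    return pd.DataFrame(cov, index=spec.entity_ids, columns=spec.entity_ids)


def _instrument_variances(ids: list[str], maf) -> np.ndarray:
    if not ids:
        return np.zeros(0)
    if maf is None:
        raise ParameterError("maf required when the spec references instruments")
    if isinstance(maf, dict):
        f = np.array([maf[v] for v in ids], dtype=float)
    else:
        f = np.broadcast_to(np.asarray(maf, dtype=float), (len(ids),))
    return 2.0 * f * (1.0 - f)


def joint_covariance(
    spec: SemSpec, maf: dict[str, float] | float
) -> pd.DataFrame:
    """Population covariance over [instruments..., entities...].

    Treating independent dosages IV with Var = 2*maf*(1-maf) and the SEM
    reduced form M = (I - W^T)^-1 (A^T IV + L^T U + eps):
    Cov(IV, M) = diag(var) A (I - W)^-1.
    """
    ids = spec.instrument_ids()
    A = _instrument_loading_matrix(spec, ids)
    var = _instrument_variances(ids, maf)
    p = spec.n_entities
    g = len(ids)
    inv = np.linalg.inv(np.eye(p) - spec.adjacency)
    S = _exogenous_covariance(spec, var, A)
    cov = np.zeros((g + p, g + p))
    cov[:g, :g] = np.diag(var)
    cov[g:, g:] = inv.T @ S @ inv
    cross = (var[:, None] * A) @ inv if g else np.zeros((0, p))
    cov[:g, g:] = cross
    cov[g:, :g] = cross.T
    names = list(ids) + list(spec.entity_ids)
    return pd.DataFrame(cov, index=names, columns=names)
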