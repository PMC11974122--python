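"""Relationship matrices and animal-model BLUP with known heritabilities.

Three flavours of breeding value estimation are supported, differing
only in the relationship (covariance) structure plugged into the same
single-trait animal-model mixed-model equations:

* pedigree BLUP      - numerator relationship matrix A (tabular method),
* GBLUP              - genomic relationship matrix G (first method of
                       VanRaden: dosages centred by 2p, cross-products
                       scaled by 2 sum p(1-p)),
* single-step GBLUP  - H^-1 combining A^-1 with a blended G on the
                       genotyped block.

Heritabilities are treated as known, the overall mean is the only fixed
effect, and repeated records enter through a record-to-animal incidence
structure with independent residuals (no permanent environment).
Evaluations are single-trait; traits are combined downstream by the
selection index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "PedigreeTable",
    "RelationshipMatrix",
    "EvaluationResult",
    "build_A",
    "build_G",
    "blend_G",
    "build_H_inverse",
    "solve_ebv",
    "empirical_reliability",
    "read_dosages_vcf",
]


@dataclass(frozen=True)
class PedigreeTable:
    """Chronologically ordered pedigree; unknown parents coded as None."""

    ids: tuple
    sires: tuple
    dams: tuple

    def __post_init__(self) -> None:
        seen = {}
        for k, i in enumerate(self.ids):
            seen[i] = k
        for k, (s, d) in enumerate(zip(self.sires, self.dams)):
            for p in (s, d):
                if p is not None and seen.get(p, len(self.ids)) >= k:
                    raise ValueError(f"parent {p} does not precede animal {self.ids[k]}")

    @classmethod
    def from_individuals(cls, individuals: list) -> "PedigreeTable":
        return cls(
            ids=tuple(i.id for i in individuals),
            sires=tuple(i.sire_id for i in individuals),
            dams=tuple(i.dam_id for i in individuals),
        )


@dataclass
class RelationshipMatrix:
    kind: str  # "A", "G" or "H_inverse"
    ids: tuple
    values: np.ndarray

    def subset(self, ids) -> "RelationshipMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        sel = np.array([pos[i] for i in ids])
        return RelationshipMatrix(self.kind, tuple(ids),
                                  self.values[np.ix_(sel, sel)])


@dataclass
class EvaluationResult:
    method: str
    ids: tuple
    ebv: np.ndarray  # n x n_traits
    reliability: dict = field(default_factory=dict)  # cohort -> per-trait r2
    training_ids: tuple = ()

    def ebv_of(self, ids) -> np.ndarray:
        pos = {i: k for k, i in enumerate(self.ids)}
        return self.ebv[[pos[i] for i in ids]]


def build_A(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method; founders are
    unrelated and non-inbred."""
    n = len(ped.ids)
    pos = {i: k for k, i in enumerate(ped.ids)}
    A = np.zeros((n, n))
    for k in range(n):
        s = pos.get(ped.sires[k], -1) if ped.sires[k] is not None else -1
        d = pos.get(ped.dams[k], -1) if ped.dams[k] is not None else -1
        if s >= 0 and d >= 0:
            A[k, :k] = 0.5 * (A[s, :k] + A[d, :k])
            A[k, k] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = max(s, d)
            A[k, :k] = 0.5 * A[p, :k]
            A[k, k] = 1.0
        else:
            A[k, k] = 1.0
        A[:k, k] = A[k, :k]
    return RelationshipMatrix("A", ped.ids, A)


def build_G(
    dosages: np.ndarray,
    ids: tuple,
    frequencies: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Genomic relationship matrix, first method of VanRaden.

    Dosages are centred by twice the allele frequency (computed from the
    genotyped set itself unless given) and cross-products are divided by
    2 sum p(1-p).
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim != 2 or dosages.shape[0] < 2 or dosages.shape[1] < 1:
        raise ValueError("need at least 2 individuals and 1 locus")
    p = dosages.mean(axis=0) / 2.0 if frequencies is None else np.asarray(frequencies)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ZeroDivisionError("all loci monomorphic: G scaling undefined")
    M = dosages - 2.0 * p
    return RelationshipMatrix("G", tuple(ids), (M @ M.T) / denom)


def blend_G(
    G: RelationshipMatrix,
    A22: RelationshipMatrix,
    weight: float = 0.95,
) -> RelationshipMatrix:
    """Rescale G so its mean diagonal and mean off-diagonal match the
    pedigree block A22 (base-compatibility adjustment), then blend
    ``weight * G_adj + (1 - weight) * A22`` to guarantee invertibility."""
    if G.ids != A22.ids:
        raise ValueError("G and A22 must be indexed identically")
    g, a = G.values, A22.values
    n = g.shape[0]
    off = ~np.eye(n, dtype=bool)
    md_g, md_a = g.diagonal().mean(), a.diagonal().mean()
    if n > 1:
        mo_g, mo_a = g[off].mean(), a[off].mean()
    else:
        mo_g = mo_a = 0.0
    if abs(md_g - mo_g) > 1e-12:
        beta = (md_a - mo_a) / (md_g - mo_g)
        alpha = md_a - beta * md_g
    else:  # degenerate G (e.g. identical genotypes): shift only
        beta, alpha = 1.0, md_a - md_g
    g_adj = alpha + beta * g
    return RelationshipMatrix("G", G.ids, weight * g_adj + (1.0 - weight) * a)


def _inv_pd(m: np.ndarray, what: str) -> np.ndarray:
    try:
        c, low = scipy.linalg.cho_factor(m)
        return scipy.linalg.cho_solve((c, low), np.eye(m.shape[0]))
    except scipy.linalg.LinAlgError as exc:
        cond = np.linalg.cond(m)
        raise np.linalg.LinAlgError(
            f"{what} not positive definite (condition number {cond:.3g})"
        ) from exc


def build_H_inverse(
    A: RelationshipMatrix,
    G: RelationshipMatrix | None,
    genotyped_ids,
    blend_weight: float = 0.95,
) -> RelationshipMatrix:
    """Single-step inverse relationship matrix.

    H^-1 = A^-1 augmented on the genotyped block by
    G_blended^-1 - A22^-1, with G blended against A22 (``blend_G``).
    With no genotyped animals this degenerates to A^-1.
    """
    Ainv = _inv_pd(A.values, "A")
    H = RelationshipMatrix("H_inverse", A.ids, Ainv)
    genotyped_ids = tuple(genotyped_ids)
    if not genotyped_ids:
        return H
    pos = {i: k for k, i in enumerate(A.ids)}
    sel = np.array([pos[i] for i in genotyped_ids])
    A22 = RelationshipMatrix("A", genotyped_ids, A.values[np.ix_(sel, sel)])
    if G is None or tuple(G.ids) != genotyped_ids:
        raise ValueError("G must be indexed by genotyped_ids")
    Gb = blend_G(G, A22, weight=blend_weight)
    delta = _inv_pd(Gb.values, "blended G") - _inv_pd(A22.values, "A22")
    H.values[np.ix_(sel, sel)] += delta
    return H


def solve_ebv(
    records,
    K: RelationshipMatrix,
    h2: np.ndarray,
    method: str = "blup",
    n_traits: int = 9,
) -> EvaluationResult:
    """Solve single-trait animal-model mixed-model equations per trait.

    ``records`` is an iterable of objects with ``owner``, ``trait`` and
    ``value`` attributes (e.g. PhenotypeRecord).  ``K`` is a relationship
    matrix (kind A or G) or its inverse (kind H_inverse) over the animals
    to evaluate; every record owner must be indexed.  The only fixed
    effect is an overall mean; the variance ratio is (1-h2)/h2 per trait
    on the phenotypic-variance scale.  Returns EBVs for every indexed
    animal, phenotyped or not.
    """
    ids = tuple(K.ids)
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    h2 = np.asarray(h2, dtype=float)
    if K.kind == "H_inverse":
        Kinv = K.values
    else:
        Kinv = _inv_pd(K.values, K.kind)
    by_trait: dict[int, list] = {}
    for r in records:
        if r.owner not in pos:
            raise KeyError(f"record owner {r.owner} not in relationship index")
        by_trait.setdefault(r.trait, []).append(r)
    ebv = np.zeros((n, n_traits))
    for t in range(n_traits):
        recs = by_trait.get(t, [])
        if not recs:
            warnings.warn(f"no records for trait {t}; EBVs set to 0")
            continue
        owners = np.array([pos[r.owner] for r in recs])
        y = np.array([r.value for r in recs])
        lam = (1.0 - h2[t]) / h2[t]
        counts = np.bincount(owners, minlength=n).astype(float)
        zy = np.bincount(owners, weights=y, minlength=n)
        C = np.empty((n + 1, n + 1))
        C[0, 0] = len(y)
        C[0, 1:] = counts
        C[1:, 0] = counts
        C[1:, 1:] = lam * Kinv
        C[np.arange(1, n + 1), np.arange(1, n + 1)] += counts
        rhs = np.concatenate([[y.sum()], zy])
        sol = scipy.linalg.solve(C, rhs, assume_a="pos")
        ebv[:, t] = sol[1:]
    return EvaluationResult(method=method, ids=ids, ebv=ebv)


def empirical_reliability(
    cohort_ids,
    estimates: np.ndarray,
    truth: np.ndarray,
) -> np.ndarray:
    """Per-trait squared correlation between true and estimated breeding
    values (or phenotypes) within a cohort, clamped to [0, 1]."""
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if estimates.shape[0] < 3:
        raise ValueError("need at least 3 cohort members")
    out = np.zeros(estimates.shape[1])
    for t in range(estimates.shape[1]):
        e, g = estimates[:, t], truth[:, t]
        if e.std() == 0 or g.std() == 0:
            warnings.warn(f"zero variance for trait {t}; reliability set to 0")
            continue
        r = np.corrcoef(e, g)[0, 1]
        out[t] = min(max(r * r, 0.0), 1.0)
    return out


def read_dosages_vcf(path) -> tuple[np.ndarray, tuple]:
    """Load a 0/1/2 dosage matrix (individuals x loci) from the GT field
    of a VCF; interoperability helper for externally stored genotypes."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    cols = [np.asarray(v.genotypes)[:, :2].sum(axis=1) for v in vcf]
    return np.stack(cols, axis=1), samples
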