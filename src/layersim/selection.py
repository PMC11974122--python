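"""Multi-trait index selection, optimum contributions and mating.

Selection ranks candidates on a linear index over per-trait EBVs (or
phenotype deviations).  Index weights combine the economic weights with
the genetic covariance structure and shrink towards less reliable
traits:

    b = (R C R + D)^-1 R C w,   R = diag(sqrt(r2)),
    D = diag((1 - r2_i) C_ii),

where C is the additive genetic covariance matrix, w the economic
weights and r2 the per-trait reliabilities of the evaluation.  With
uncorrelated traits and equal reliabilities this degenerates to b
proportional to w.

Optimum contribution selection (OCS) here minimizes mean kinship of the
contribution vector over the truncation-selected parents (the
"min.sKin" flavour): minimize c'Kc subject to the contributions of each
sex summing to 1/2 and 0 <= c_i <= c_max.  Matings never pair full or
half siblings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .genome import FEMALE, MALE, GeneticMap, Individual, make_offspring

__all__ = [
    "SelectionIndex",
    "ContributionPlan",
    "index_weights",
    "truncation_select",
    "ocs_contributions",
    "mate_and_reproduce",
]


@dataclass(frozen=True)
class SelectionIndex:
    weights: np.ndarray  # applied to per-trait EBVs or phenotype deviations
    source: str  # "ebv" or "phenotype"
    reliabilities: np.ndarray

    def score(self, trait_values: np.ndarray) -> np.ndarray:
        return np.asarray(trait_values) @ self.weights


@dataclass
class ContributionPlan:
    ids: tuple
    sexes: tuple
    contributions: np.ndarray  # per candidate, each sex sums to 0.5
    matings: list = field(default_factory=list)  # (sire_id, dam_id, n)


def index_weights(
    ew: np.ndarray,
    genetic_cov: np.ndarray,
    reliabilities: np.ndarray,
    source: str = "ebv",
) -> SelectionIndex:
    """Reliability-scaled economic index weights (see module docstring)."""
    ew = np.asarray(ew, dtype=float)
    C = np.asarray(genetic_cov, dtype=float)
    r2 = np.clip(np.asarray(reliabilities, dtype=float), 0.0, 1.0)
    R = np.diag(np.sqrt(r2))
    D = np.diag((1.0 - r2) * np.diag(C))
    try:
        b = np.linalg.solve(R @ C @ R + D, R @ C @ ew)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular index system; falling back to economic weights")
        b = ew.copy()
    return SelectionIndex(weights=b, source=source, reliabilities=r2)


def truncation_select(ids, index_values, n_keep: int):
    """Top ``n_keep`` candidates by index value; ties broken by lower id."""
    ids = np.asarray(ids)
    vals = np.asarray(index_values, dtype=float)
    if n_keep > len(ids):
        raise ValueError("cannot keep more candidates than offered")
    order = np.lexsort((ids, -vals))
    return ids[order[:n_keep]]


def ocs_contributions(
    candidates,
    kinship: np.ndarray,
    index_values,
    n_males: int,
    n_females: int,
    c_max: float | None = None,
) -> ContributionPlan:
    """Minimum-kinship optimum contributions over pre-selected parents.

    ``candidates`` is a sequence of (id, sex) in the same order as the
    rows of ``kinship`` (a pedigree-based kinship matrix) and of
    ``index_values``.  Truncation first picks the top ``n_males`` /
    ``n_females`` per sex, then the quadratic program min c'Kc is solved
    over that set with per-sex sum constraints and 0 <= c <= c_max
    (default 4x the uniform share).
    """
    ids = np.array([c[0] for c in candidates])
    sexes = np.array([c[1] for c in candidates])
    vals = np.asarray(index_values, dtype=float)
    keep_ids = set()
    for sex, n in ((MALE, n_males), (FEMALE, n_females)):
        mask = sexes == sex
        keep_ids.update(truncation_select(ids[mask], vals[mask], n).tolist())
    sel = np.array([k for k, i in enumerate(ids) if i in keep_ids])
    K = np.asarray(kinship, dtype=float)[np.ix_(sel, sel)]
    sid, ssex = ids[sel], sexes[sel]
    n = len(sel)
    male_mask = ssex == MALE
    c0 = np.empty(n)
    caps = np.empty(n)
    for mask, n_sex in ((male_mask, n_males), (~male_mask, n_females)):
        cap = 4.0 * 0.5 / n_sex if c_max is None else float(c_max)
        if cap * n_sex < 0.5 - 1e-12:
            raise ValueError("contribution cap infeasible: c_max * n_sex < 0.5")
        c0[mask] = 0.5 / n_sex
        caps[mask] = cap
    cons = [
        {"type": "eq", "fun": lambda c, m=male_mask: c[m].sum() - 0.5,
         "jac": lambda c, m=male_mask: m.astype(float)},
        {"type": "eq", "fun": lambda c, m=~male_mask: c[m].sum() - 0.5,
         "jac": lambda c, m=~male_mask: m.astype(float)},
    ]
    res = scipy.optimize.minimize(
        lambda c: c @ K @ c, c0, jac=lambda c: 2.0 * K @ c,
        bounds=[(0.0, cap) for cap in caps], constraints=cons,
        method="SLSQP", options={"maxiter": 500, "ftol": 1e-12},
    )
    c = np.clip(res.x, 0.0, caps)
    # renormalize per sex to absorb solver slack
    for mask in (male_mask, ~male_mask):
        c[mask] *= 0.5 / c[mask].sum()
    # QP optimality sanity: never worse than uniform contributions
    if c @ K @ c > c0 @ K @ c0 + 1e-9:
        c = c0
    return ContributionPlan(ids=tuple(sid), sexes=tuple(ssex), contributions=c)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer quotas summing to ``total`` proportional to ``weights``."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def _banned(a: Individual, b: Individual, ban: str) -> bool:
    if ban == "none":
        return False
    pa = {p for p in (a.sire_id, a.dam_id) if p is not None}
    pb = {p for p in (b.sire_id, b.dam_id) if p is not None}
    if ban == "fullsib":
        return len(pa) == 2 and pa == pb
    return bool(pa & pb)


def mate_and_reproduce(
    sires: list,
    dams: list,
    n_male_offspring: int,
    n_female_offspring: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    id_start: int,
    birth_week: float = 0.0,
    plan: ContributionPlan | None = None,
    max_rejects: int = 1000,
    ban: str = "halfsib",
) -> list:
    """Create the next cohort, banning full- and half-sib matings.

    Without a plan, sire/dam pairs are drawn uniformly with replacement;
    pairs sharing a parent are rejected and redrawn, which is realized
    exactly as uniform sampling over the permissible pairs.  With an OCS
    plan, contributions become integer gamete quotas by largest-remainder
    rounding and parent slots are consumed in random order, repairing
    banned pairs by slot swaps (``max_rejects`` consecutive failures
    abort).  ``ban`` is ``"halfsib"`` (default: full and half siblings),
    ``"fullsib"`` or ``"none"``.
    """
    if not sires or not dams:
        raise ValueError("need selected parents of both sexes")
    total = n_male_offspring + n_female_offspring
    allowed = np.array([[not _banned(s, d, ban) for d in dams] for s in sires])
    if not allowed.any():
        raise RuntimeError("no permissible mating found (sib-mating ban)")
    offspring = []
    mating_count: dict[tuple, int] = {}
    next_id = id_start
    if plan is None:
        ok_pairs = np.argwhere(allowed)
        picks = ok_pairs[rng.integers(len(ok_pairs), size=total)]
        pairs = [(sires[i], dams[j]) for i, j in picks]
    else:
        by_id = {i.id: i for i in sires + dams}
        cm = np.array([plan.contributions[k] for k, s in enumerate(plan.sexes)
                       if s == MALE])
        cf = np.array([plan.contributions[k] for k, s in enumerate(plan.sexes)
                       if s == FEMALE])
        mids = [i for i, s in zip(plan.ids, plan.sexes) if s == MALE]
        fids = [i for i, s in zip(plan.ids, plan.sexes) if s == FEMALE]
        sire_slots = list(np.repeat(mids, _largest_remainder(cm, total)))
        dam_slots = list(np.repeat(fids, _largest_remainder(cf, total)))
        rng.shuffle(sire_slots)
        rng.shuffle(dam_slots)
        pairs = []
        rejects = 0
        for k in range(total):
            while _banned(by_id[sire_slots[k]], by_id[dam_slots[k]], ban):
                rejects += 1
                if rejects >= max_rejects:
                    raise RuntimeError(
                        "no permissible mating found (sib-mating ban)")
                j = int(rng.integers(k, len(dam_slots)))
                dam_slots[k], dam_slots[j] = dam_slots[j], dam_slots[k]
            rejects = 0
            pairs.append((by_id[sire_slots[k]], by_id[dam_slots[k]]))
    for k, (sire, dam) in enumerate(pairs):
        sex = MALE if k < n_male_offspring else FEMALE
        offspring.append(
            make_offspring(next_id, sire, dam, sex, birth_week, gmap, rng)
        )
        mating_count[(sire.id, dam.id)] = mating_count.get((sire.id, dam.id), 0) + 1
        next_id += 1
    if plan is not None:
        plan.matings = [(s, d, n) for (s, d), n in sorted(mating_count.items())]
    return offspring
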