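"""Breeding-program scheduler: cohorts, evaluations, selection, mating.

A breeding program is executed as a chronological sequence of *birth
events*.  At each event a new candidate cohort is created from parents
selected 12 weeks earlier: dams from the cohort born one female
generation interval before, sires from the cohort born one male
generation interval before.  With equal generation intervals (63 or
31.5 weeks) sires and dams come from the same cohort; in the
two-subpopulation design the population is split into two half-size
subpopulations time-shifted by 31.5 weeks, and the newly selected young
males (19.5 weeks old) of one subpopulation are mated to the older
females (51 weeks) of the other, halving the male generation interval
only.

Phenotype availability is driven purely by recording weeks: hens record
at 51 and 72 weeks of age, so under the 63-week interval a hen's first
records are visible at her own selection, under the 31.5-week interval
they are not, and a subpopulation's female phenotypes can never inform
the selection of its own (younger) male candidates.

The training set of every evaluation consists of all cohorts born
within three female generation intervals before the birth event, which
includes the candidate cohorts themselves; with full genotyping this
reproduces the bookkeeping of 18,900 genotyped animals per evaluation
at full population size.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import ebv as ebv_mod
from . import selection as sel_mod
from .genome import (FEMALE, MALE, GeneticMap, Individual, build_genetic_map,
                     burn_in, dosage, ibd_inbreeding, sample_founders)
from .traits import (TRAITS_AGE_51, RECORDING_AGES, TraitParams,
                     assign_tbv, build_architecture, genetic_covariance,
                     record_phenotypes_batch, residual_correlations)

__all__ = [
    "ScenarioConfig",
    "SCENARIOS",
    "load_scenario",
    "BasePopulation",
    "make_base",
    "Cohort",
    "SchedulerState",
    "RunResult",
    "training_cohorts",
    "visible_records",
    "run_scenario",
    "SELECTION_LAG_WEEKS",
]

# weeks between selection of the parents and hatch of their offspring
SELECTION_LAG_WEEKS = 12.0


@dataclass(frozen=True)
class ScenarioConfig:
    """One executable breeding-program design (a row of the scenario grid).

    Counts are full-scale per cycle; in the two-subpopulation design
    they apply per subpopulation (half the single-population values).
    """

    scenario_id: int
    acronym: str
    gi_male: float  # weeks
    gi_female: float  # weeks
    male_method: str  # pedigree | ssgblup | gblup
    female_method: str  # phenotypic | pedigree | ssgblup | gblup
    genotyped_males: str  # none | candidates
    genotyped_females: str  # none | selected | random600 | candidates
    ocs: bool = False
    two_subpops: bool = False
    n_male_candidates: int = 800
    n_female_candidates: int = 5500
    n_males_selected: int = 60
    n_females_selected: int = 600

    def __post_init__(self) -> None:
        if self.two_subpops and not (self.gi_male == 31.5 and self.gi_female == 63.0):
            raise ValueError("two-subpopulation design halves the male interval only")


def _long(i, acr, mm, fm, gm, gf, ocs=False):
    return ScenarioConfig(i, acr, 63.0, 63.0, mm, fm, gm, gf, ocs=ocs)


def _2sp(i, acr, mm, fm, gm, gf, ocs=False):
    return ScenarioConfig(i, acr, 31.5, 63.0, mm, fm, gm, gf, ocs=ocs,
                          two_subpops=True, n_male_candidates=400,
                          n_female_candidates=2750, n_males_selected=30,
                          n_females_selected=300)


def _short(i, acr, mm, fm, gm, gf, ocs=False, nf=5500):
    return ScenarioConfig(i, acr, 31.5, 31.5, mm, fm, gm, gf, ocs=ocs,
                          n_female_candidates=nf)


SCENARIOS: dict[int, ScenarioConfig] = {c.scenario_id: c for c in [
    _long(1, "longGI-m:Ped-f:Pheno", "pedigree", "phenotypic", "none", "none"),
    _long(2, "longGI-m:Ped-f:Ped", "pedigree", "pedigree", "none", "none"),
    _long(3, "longGI-m:ssGBLUP-f:Pheno-Geno:M", "ssgblup", "phenotypic",
          "candidates", "none"),
    _long(4, "longGI-m:ssGBLUP-f:Pheno-Geno:M&Fsel", "ssgblup", "phenotypic",
          "candidates", "selected"),
    _long(5, "longGI-m:ssGBLUP-f:ssGBLUP-Geno:M&Fsel", "ssgblup", "ssgblup",
          "candidates", "selected"),
    _long(6, "longGI-m:ssGBLUP-f:Pheno-Geno:M&F600", "ssgblup", "phenotypic",
          "candidates", "random600"),
    _long(7, "longGI-m:GBLUP-f:Pheno-Geno:M&F", "gblup", "phenotypic",
          "candidates", "candidates"),
    _long(8, "longGI-m:GBLUP-f:GBLUP-Geno:M&F", "gblup", "gblup",
          "candidates", "candidates"),
    _long(9, "longGI-m:GBLUP-f:GBLUP-Geno:M&F-OCS", "gblup", "gblup",
          "candidates", "candidates", ocs=True),
    _2sp(10, "2SP-m:ssGBLUP-f:Pheno-Geno:M&Fsel", "ssgblup", "phenotypic",
         "candidates", "selected"),
    _2sp(11, "2SP-m:ssGBLUP-f:ssGBLUP-Geno:M&Fsel", "ssgblup", "ssgblup",
         "candidates", "selected"),
    _2sp(12, "2SP-m:GBLUP-f:GBLUP-Geno:M&F", "gblup", "gblup",
         "candidates", "candidates"),
    _2sp(13, "2SP-m:GBLUP-f:GBLUP-Geno:M&F-OCS", "gblup", "gblup",
         "candidates", "candidates", ocs=True),
    _short(14, "shortGI-m:ssGBLUP-f:Ped-Geno:M", "ssgblup", "pedigree",
           "candidates", "none"),
    _short(15, "shortGI-m:ssGBLUP-f:ssGBLUP-Geno:M", "ssgblup", "ssgblup",
           "candidates", "none"),
    _short(16, "shortGI-m:GBLUP-f:GBLUP-Geno:M&F", "gblup", "gblup",
           "candidates", "candidates"),
    _short(17, "shortGI-m:GBLUP-f:GBLUP-Geno:M&F-OCS", "gblup", "gblup",
           "candidates", "candidates", ocs=True),
    _short(18, "shortGI-m:GBLUP-f:GBLUP-Geno:M&F-n/2", "gblup", "gblup",
           "candidates", "candidates", nf=2750),
]}


def load_scenario(key) -> ScenarioConfig:
    """Look up a scenario by numeric id (1-18) or acronym."""
    if isinstance(key, int) or (isinstance(key, str) and key.isdigit()):
        k = int(key)
        if k not in SCENARIOS:
            raise KeyError(f"unknown scenario id {k}")
        return SCENARIOS[k]
    for c in SCENARIOS.values():
        if c.acronym == key:
            return c
    raise KeyError(f"unknown scenario acronym {key!r}")


def scaled(n: int, scale: float) -> int:
    """Apply the global scale factor to a per-sex count (minimum 2)."""
    return max(2, int(round(n * scale)))


@dataclass
class BasePopulation:
    """Shared burn-in product: genome, trait machinery and base animals."""

    gmap: GeneticMap
    params: TraitParams
    rE: np.ndarray
    arch: object
    males: list
    females: list
    next_id: int
    scale: float
    seed: int

    def fresh_copy(self) -> "BasePopulation":
        """Clone with per-scenario-mutable individual state reset.

        Haplotype and TBV arrays are shared (read-only downstream);
        phenotype lists and genotyping flags are per scenario.
        """
        def clone(ind: Individual) -> Individual:
            c = copy.copy(ind)
            c.phenotypes = []
            c.genotyped = False
            return c

        return replace(self, males=[clone(i) for i in self.males],
                       females=[clone(i) for i in self.females])


def make_base(
    seed: int,
    scale: float = 1.0,
    params: TraitParams | None = None,
    n_chromosomes: int = 10,
    loci_per_chromosome: int = 5000,
    morgan_per_chromosome: float = 1.0,
    n_qtl: int = 1000,
    n_founder_males: int = 200,
    n_founder_females: int = 1000,
    burn_in_generations: int = 10,
    n_base_males: int = 800,
    n_base_females: int = 5500,
) -> BasePopulation:
    """Simulate founders, burn-in and the base breeding population.

    All counts (including loci and QTL) are multiplied by ``scale``.
    """
    params = params or TraitParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1910]))
    gmap = build_genetic_map(
        n_chromosomes, max(10, int(round(loci_per_chromosome * scale))),
        morgan_per_chromosome, rng,
    )
    pool = sample_founders(gmap, scaled(n_founder_males, scale),
                           scaled(n_founder_females, scale), rng)
    base = burn_in(pool, burn_in_generations, scaled(n_base_males, scale),
                   scaled(n_base_females, scale), gmap, rng)
    arch = build_architecture(gmap, params,
                              base, max(10, int(round(n_qtl * scale))), rng)
    assign_tbv(base, arch)
    males = [i for i in base if i.sex == MALE]
    females = [i for i in base if i.sex == FEMALE]
    return BasePopulation(
        gmap=gmap, params=params, rE=residual_correlations(params), arch=arch,
        males=males, females=females,
        next_id=max(i.id for i in base) + 1, scale=scale, seed=seed,
    )


@dataclass
class Cohort:
    birth_week: float
    subpop: str | None
    males: list
    females: list
    recorded_ages: set = field(default_factory=set)
    selected_male_ids: tuple = ()
    selected_female_ids: tuple = ()

    @property
    def members(self) -> list:
        return self.males + self.females


@dataclass
class SchedulerState:
    base: BasePopulation
    config: ScenarioConfig
    scale: float
    cohorts: list = field(default_factory=list)
    registry: dict = field(default_factory=dict)
    next_id: int = 0
    cohort_rows: list = field(default_factory=list)
    accuracy_rows: list = field(default_factory=list)

    def cohort_at(self, birth_week: float, subpop: str | None) -> Cohort | None:
        for ch in self.cohorts:
            if abs(ch.birth_week - birth_week) < 1e-6 and ch.subpop == subpop:
                return ch
        return None

    def add_cohort(self, ch: Cohort) -> None:
        self.cohorts.append(ch)
        for ind in ch.members:
            ind.cohort_id = f"{ch.subpop or 'P'}@{ch.birth_week:g}"
            ind.subpop = ch.subpop
            self.registry[ind.id] = ind
        ew = self.base.params.ew
        tbv = np.stack([i.tbv for i in ch.members])
        fs = [ibd_inbreeding(i, self.base.gmap) for i in ch.members]
        self.cohort_rows.append({
            "birth_week": ch.birth_week, "subpop": ch.subpop or "P",
            "n": len(ch.members), "mean_index_tbv": float((tbv @ ew).mean()),
            "mean_F": float(np.mean(fs)),
        })


@dataclass
class RunResult:
    config: ScenarioConfig
    scale: float
    seed: int
    horizon_weeks: float
    cohort_log: pd.DataFrame
    accuracy_log: pd.DataFrame
    state: "SchedulerState | None" = None


def training_cohorts(cohorts, birth_week: float, gi_female: float) -> list:
    """Evaluation window: every cohort born within three female
    generation intervals before the birth event (candidate cohorts
    included)."""
    lo = birth_week - 3.0 * gi_female
    return [ch for ch in cohorts
            if lo - 1e-6 <= ch.birth_week < birth_week - 1e-6]


def visible_records(cohorts, selection_week: float) -> list:
    """All phenotype records of the given cohorts recorded by
    ``selection_week`` (records never look into the future)."""
    return [r for ch in cohorts for hen in ch.females for r in hen.phenotypes
            if r.recorded_week <= selection_week + 1e-9]


def _record_due_phenotypes(state: SchedulerState, week: float,
                           rng: np.random.Generator) -> None:
    for ch in state.cohorts:
        for age in RECORDING_AGES:
            if age not in ch.recorded_ages and ch.birth_week + age <= week + 1e-9:
                if ch.females:
                    recs = record_phenotypes_batch(
                        ch.females, state.base.params, state.base.rE, age, rng)
                    for r in recs:
                        state.registry[r.owner].phenotypes.append(r)
                ch.recorded_ages.add(age)


def _ancestor_closure(state: SchedulerState, members: list) -> list:
    """Members plus all registered ancestors, in birth order (pedigree
    founders are the base-population animals)."""
    seen = {i.id: i for i in members}
    stack = list(members)
    while stack:
        ind = stack.pop()
        for p in (ind.sire_id, ind.dam_id):
            if p is not None and p in state.registry and p not in seen:
                seen[p] = state.registry[p]
                stack.append(state.registry[p])
    return sorted(seen.values(), key=lambda i: (i.birth_week, i.id))


def _pedigree(state: SchedulerState, inds: list) -> ebv_mod.PedigreeTable:
    present = {i.id for i in inds}
    return ebv_mod.PedigreeTable(
        ids=tuple(i.id for i in inds),
        sires=tuple(i.sire_id if i.sire_id in present else None for i in inds),
        dams=tuple(i.dam_id if i.dam_id in present else None for i in inds),
    )


def _build_A_closure(state: SchedulerState, members: list) -> ebv_mod.RelationshipMatrix:
    closure = _ancestor_closure(state, members)
    return ebv_mod.build_A(_pedigree(state, closure))


def _genotyped_G(genotyped: list) -> ebv_mod.RelationshipMatrix:
    dos = np.stack([dosage(i) for i in genotyped]).astype(np.float32)
    return ebv_mod.build_G(dos, tuple(i.id for i in genotyped))


def _evaluate(method: str, state: SchedulerState, index_cohorts: list,
              selection_week: float) -> ebv_mod.EvaluationResult:
    """Run one breeding value evaluation over the training window."""
    params = state.base.params
    members = [i for ch in index_cohorts for i in ch.members]
    recs = visible_records(index_cohorts, selection_week)
    member_ids = {i.id for i in members}
    recs = [r for r in recs if r.owner in member_ids]
    genotyped = [i for i in members if i.genotyped]
    import warnings
    if method == "gblup":
        if len(genotyped) < 2:
            raise RuntimeError("GBLUP evaluation without genotyped animals")
        G = _genotyped_G(genotyped)
        A = _build_A_closure(state, genotyped)
        A22 = A.subset(G.ids)
        K = ebv_mod.blend_G(G, A22)
        gen_ids = set(G.ids)
        recs = [r for r in recs if r.owner in gen_ids]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return ebv_mod.solve_ebv(recs, K, params.h2, method="gblup")
    A = _build_A_closure(state, members)
    if method == "pedigree" or not genotyped:
        K = A if method == "pedigree" else ebv_mod.build_H_inverse(A, None, ())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return ebv_mod.solve_ebv(recs, K, params.h2, method=method)
    if method != "ssgblup":
        raise ValueError(f"unknown evaluation method {method!r}")
    G = _genotyped_G(genotyped)
    H = ebv_mod.build_H_inverse(A, G, G.ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ebv_mod.solve_ebv(recs, H, params.h2, method="ssgblup")


def _phenotype_criterion(hens: list, selection_week: float,
                         params: TraitParams) -> tuple[np.ndarray, np.ndarray]:
    """Own age-51 phenotype deviations as the selection criterion.

    Returns (criterion matrix n x 9 with zeros for unrecorded traits,
    per-trait reliabilities = h2 for recorded traits else 0).
    """
    n = len(hens)
    crit = np.zeros((n, 9))
    have = np.zeros(9, dtype=bool)
    for k, hen in enumerate(hens):
        for r in hen.phenotypes:
            if (r.recorded_week <= selection_week + 1e-9
                    and abs(r.recorded_week - hen.birth_week - 51.0) < 1e-6):
                crit[k, r.trait] = r.value
                have[r.trait] = True
    crit[:, have] -= crit[:, have].mean(axis=0)
    crit[:, ~have] = 0.0
    r2 = np.where(have, params.h2, 0.0)
    return crit, r2


def _candidate_criterion(sex_cands: list, method: str, evals: dict,
                         selection_week: float, state: SchedulerState):
    params = state.base.params
    if method == "phenotypic":
        return _phenotype_criterion(sex_cands, selection_week, params)
    res = evals[method]
    crit = res.ebv_of([i.id for i in sex_cands])
    tbv = np.stack([i.tbv for i in sex_cands])
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r2 = ebv_mod.empirical_reliability([i.id for i in sex_cands], crit, tbv)
    return crit, r2


def _process_event(state: SchedulerState, birth_week: float, subpop: str | None,
                   rng: np.random.Generator) -> None:
    cfg = state.config
    w = birth_week - SELECTION_LAG_WEEKS
    dam_sub = subpop
    sire_sub = ({"A": "B", "B": "A"}[subpop] if cfg.two_subpops else subpop)
    dam_cohort = state.cohort_at(birth_week - cfg.gi_female, dam_sub)
    sire_cohort = state.cohort_at(birth_week - cfg.gi_male, sire_sub)
    if dam_cohort is None or sire_cohort is None:
        raise RuntimeError(f"missing parent cohort for event at week {birth_week}")
    _record_due_phenotypes(state, w, rng)
    index_cohorts = training_cohorts(state.cohorts, birth_week, cfg.gi_female)
    male_cands = sire_cohort.males
    female_cands = dam_cohort.females
    # genotyping before selection
    if cfg.genotyped_males == "candidates":
        for i in male_cands:
            i.genotyped = True
    if cfg.genotyped_females == "candidates":
        for i in female_cands:
            i.genotyped = True
    elif cfg.genotyped_females == "random600":
        k = min(len(female_cands), scaled(600, state.scale))
        for j in rng.choice(len(female_cands), size=k, replace=False):
            female_cands[j].genotyped = True
    # evaluations (one per distinct method)
    methods = {m for m in (cfg.male_method, cfg.female_method)
               if m != "phenotypic"}
    evals = {m: _evaluate(m, state, index_cohorts, w) for m in methods}
    C = genetic_covariance(state.base.params)
    ew = state.base.params.ew
    selected: dict[str, list] = {}
    index_values: dict[int, float] = {}
    for sex, cands, method, n_keep in (
        (MALE, male_cands, cfg.male_method, scaled(cfg.n_males_selected, state.scale)),
        (FEMALE, female_cands, cfg.female_method,
         scaled(cfg.n_females_selected, state.scale)),
    ):
        crit, r2 = _candidate_criterion(cands, method, evals, w, state)
        idx = sel_mod.index_weights(ew, C, r2,
                                    source="phenotype" if method == "phenotypic"
                                    else "ebv")
        scores = idx.score(crit)
        tbv = np.stack([i.tbv for i in cands])
        tv, cv = tbv @ idx.weights, scores
        acc = (float(np.corrcoef(tv, cv)[0, 1])
               if tv.std() > 0 and cv.std() > 0 else np.nan)
        state.accuracy_rows.append({
            "selection_week": w, "sex": sex, "subpop": subpop or "P",
            "accuracy": acc, "n": len(cands), "method": method,
        })
        ids = [i.id for i in cands]
        index_values.update(zip(ids, scores))
        keep = set(sel_mod.truncation_select(ids, scores, min(n_keep, len(ids))))
        selected[sex] = [i for i in cands if i.id in keep]
    sire_cohort.selected_male_ids = tuple(i.id for i in selected[MALE])
    dam_cohort.selected_female_ids = tuple(i.id for i in selected[FEMALE])
    plan = None
    if cfg.ocs:
        chosen = selected[MALE] + selected[FEMALE]
        A = _build_A_closure(state, chosen)
        kin = A.subset(tuple(i.id for i in chosen)).values / 2.0
        plan = sel_mod.ocs_contributions(
            [(i.id, i.sex) for i in chosen], kin,
            [index_values[i.id] for i in chosen],
            len(selected[MALE]), len(selected[FEMALE]),
        )
    if cfg.genotyped_females == "selected":
        for i in selected[FEMALE]:
            i.genotyped = True
    nm = scaled(cfg.n_male_candidates, state.scale)
    nf = scaled(cfg.n_female_candidates, state.scale)
    # at heavily scaled-down sizes the few selected parents can be one big
    # sib group; relax the mating ban stepwise rather than dead-locking
    offspring = None
    for ban in ("halfsib", "fullsib", "none"):
        try:
            offspring = sel_mod.mate_and_reproduce(
                selected[MALE], selected[FEMALE], nm, nf, state.base.gmap, rng,
                id_start=state.next_id, birth_week=birth_week, plan=plan,
                ban=ban,
            )
            break
        except RuntimeError:
            import warnings
            warnings.warn(f"week {birth_week:g}: no {ban}-permissible mating; "
                          "relaxing the sib ban for this cohort")
    state.next_id += len(offspring)
    assign_tbv(offspring, state.base.arch)
    state.add_cohort(Cohort(
        birth_week=birth_week, subpop=subpop,
        males=[i for i in offspring if i.sex == MALE],
        females=[i for i in offspring if i.sex == FEMALE],
    ))


def _event_schedule(cfg: ScenarioConfig, horizon: float):
    """Birth events (week, subpop) in chronological order."""
    events = []
    if cfg.two_subpops:
        k = 1
        while k * 63.0 <= horizon + 1e-9:
            events.append((k * 63.0, "A"))
            k += 1
        k = 1
        while k * 63.0 + 31.5 <= horizon + 1e-9:
            events.append((k * 63.0 + 31.5, "B"))
            k += 1
    else:
        step = cfg.gi_female
        k = 1
        while k * step <= horizon + 1e-9:
            events.append((k * step, None))
            k += 1
    return sorted(events)


def run_scenario(
    config: ScenarioConfig,
    base: BasePopulation | None = None,
    seed: int = 0,
    scale: float = 1.0,
    horizon_weeks: float = 630.0,
    params: TraitParams | None = None,
    keep_state: bool = False,
) -> RunResult:
    """Execute one replicate of a scenario over ``horizon_weeks``.

    With a shared ``base`` (common random numbers across scenarios) the
    burn-in is reused; the scenario-specific stream is seeded from
    (seed, scenario_id) so replicates are reproducible bit for bit.
    """
    if base is None:
        base = make_base(seed, scale=scale, params=params)
    else:
        base = base.fresh_copy()
    rng = np.random.default_rng(
        np.random.SeedSequence([base.seed if base else seed, seed,
                                config.scenario_id]))
    state = SchedulerState(base=base, config=config, scale=base.scale,
                           next_id=base.next_id)
    nm = scaled(config.n_male_candidates, base.scale)
    nf = scaled(config.n_female_candidates, base.scale)
    if config.two_subpops:
        # the shared base is split into the two time-shifted halves; count
        # rounding at small scales is absorbed here
        nm = min(nm, len(base.males) // 2)
        nf = min(nf, len(base.females) // 2)
        if nm < 2 or nf < 2:
            raise ValueError("base population too small for two subpopulations")
        state.add_cohort(Cohort(0.0, "A", base.males[:nm], base.females[:nf]))
        state.add_cohort(Cohort(31.5, "B", base.males[nm:2 * nm],
                                base.females[nf:2 * nf]))
    else:
        state.add_cohort(Cohort(0.0, None, base.males[:nm], base.females[:nf]))
    for week, sub in _event_schedule(config, horizon_weeks):
        _process_event(state, week, sub, rng)
    return RunResult(
        config=config, scale=base.scale, seed=seed, horizon_weeks=horizon_weeks,
        cohort_log=pd.DataFrame(state.cohort_rows),
        accuracy_log=pd.DataFrame(state.accuracy_rows),
        state=state if keep_state else None,
    )
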