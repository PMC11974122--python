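"""Nine-trait pleiotropic QTL architecture and age-structured phenotypes.

The trait complex of a commercial white-egg layer line: four laying
performance periods, egg weight, feed consumption, egg shell strength,
hatchability and mortality.  All are modelled as purely additive
polygenic traits driven by one shared set of QTL (pleiotropy).  Genetic
correlations are induced by mixing independent standard-normal QTL
effects through the lower Cholesky factor of the genetic correlation
matrix, and each trait is rescaled so its realized additive variance in
the base population hits h2 * sdP^2.

Phenotypes are sex-limited (hens only) and recorded at two ages, 51 and
72 weeks.  Laying performance 1-2 belong to the first recording, laying
performance 3-4 to the second, and the five remaining traits are
recorded at both ages with independent residuals (no permanent
environmental effect).  Mortality is a Gaussian trait like the others;
no birds are removed from the simulation because of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import FEMALE, GeneticMap, Individual, dosage

__all__ = [
    "TraitParams",
    "TraitArchitecture",
    "PhenotypeRecord",
    "TRAITS_AGE_51",
    "TRAITS_AGE_72",
    "RECORDING_AGES",
    "nearest_psd_correlation",
    "residual_correlations",
    "genetic_covariance",
    "build_architecture",
    "true_breeding_values",
    "assign_tbv",
    "record_phenotypes",
    "record_phenotypes_batch",
    "save_trait_params",
    "load_trait_params",
    "write_phenotypes_csv",
]

N_TRAITS = 9

TRAIT_NAMES = (
    "laying_performance_1",
    "laying_performance_2",
    "laying_performance_3",
    "laying_performance_4",
    "egg_weight",
    "feed_consumption",
    "egg_shell_strength",
    "hatchability",
    "mortality",
)

# heritabilities, phenotypic SDs (trait units) and relative economic
# weights (per trait unit) of the reference layer breeding goal
_H2 = np.array([0.35, 0.10, 0.12, 0.20, 0.75, 0.50, 0.35, 0.26, 0.03])
_SDP = np.array([22.7, 4.8, 7.0, 7.3, 3.8, 10.0, 7.0, 5.8, 0.2])
_EW = np.array([3.0, 6.0, 6.0, 9.0, 18.0, -12.0, 7.0, 22.0, -3.0])

# genetic correlations (upper triangle, row by row)
_RG_UPPER = [
    [0.16, -0.05, -0.10, -0.20, -0.14, -0.06, 0.05, 0.05],
    [0.73, 0.58, -0.30, 0.05, -0.05, 0.15, -0.05],
    [0.85, -0.20, 0.09, -0.08, 0.15, -0.05],
    [-0.20, 0.10, -0.12, 0.20, -0.08],
    [0.64, -0.20, -0.40, 0.02],
    [-0.05, -0.24, 0.01],
    [0.08, 0.02],
    [-0.01],
]
# phenotypic correlations (lower triangle, row by row, rows 2..9)
_RP_LOWER = [
    [0.06],
    [-0.01, 0.47],
    [-0.07, 0.27, 0.32],
    [-0.18, -0.08, -0.04, -0.06],
    [-0.05, 0.08, 0.07, 0.01, 0.43],
    [0.05, 0.13, 0.11, 0.10, -0.12, -0.04],
    [0.05, 0.13, 0.09, 0.07, -0.25, -0.13, 0.09],
    [0.02, -0.03, -0.04, -0.05, 0.01, 0.01, -0.01, -0.01],
]


def _corr_from_triangles(upper, lower) -> tuple[np.ndarray, np.ndarray]:
    rg = np.eye(N_TRAITS)
    rp = np.eye(N_TRAITS)
    for i, row in enumerate(upper):
        rg[i, i + 1:] = row
        rg[i + 1:, i] = row
    for i, row in enumerate(lower):
        rp[i + 1, : i + 1] = row
        rp[: i + 1, i + 1] = row
    return rg, rp


_RG, _RP = _corr_from_triangles(_RG_UPPER, _RP_LOWER)

# trait indices (0-based) recorded at each age; laying performance 1-2
# only early, 3-4 only late, the rest at both ages
TRAITS_AGE_51 = (0, 1, 4, 5, 6, 7, 8)
TRAITS_AGE_72 = (2, 3, 4, 5, 6, 7, 8)
RECORDING_AGES = (51.0, 72.0)


@dataclass(frozen=True)
class TraitParams:
    names: tuple = TRAIT_NAMES
    h2: np.ndarray = field(default_factory=lambda: _H2.copy())
    sdP: np.ndarray = field(default_factory=lambda: _SDP.copy())
    ew: np.ndarray = field(default_factory=lambda: _EW.copy())
    rG: np.ndarray = field(default_factory=lambda: _RG.copy())
    rP: np.ndarray = field(default_factory=lambda: _RP.copy())

    def __post_init__(self) -> None:
        if np.any(self.h2 <= 0) or np.any(self.h2 > 1):
            raise ValueError("heritabilities must lie in (0, 1]")
        if not np.allclose(self.rG, self.rG.T) or not np.allclose(self.rP, self.rP.T):
            raise ValueError("correlation matrices must be symmetric")


@dataclass(frozen=True)
class TraitArchitecture:
    qtl_indices: np.ndarray  # locus indices into the SNP map
    effects: np.ndarray  # n_qtl x 9 allele-substitution effects
    scale: np.ndarray  # 9-vector, trait-variance calibration
    intercept: np.ndarray  # 9-vector, centres base-population mean at 0


@dataclass(frozen=True)
class PhenotypeRecord:
    trait: int  # 0-based trait index
    value: float
    recorded_week: float
    owner: int


def nearest_psd_correlation(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive semi-definite
    correlation matrix by eigenvalue clipping and diagonal renormalization."""
    w, v = np.linalg.eigh((corr + corr.T) / 2.0)
    if w.min() >= eps:
        return corr
    m = (v * np.maximum(w, eps)) @ v.T
    d = np.sqrt(np.diag(m))
    return m / np.outer(d, d)


def residual_correlations(params: TraitParams) -> np.ndarray:
    """Residual correlation matrix implied by the genetic and phenotypic
    correlations: rE_ij = (rP_ij - rG_ij sqrt(h2_i h2_j)) /
    sqrt((1-h2_i)(1-h2_j)), repaired to PSD if the plug-in matrix is not."""
    h2 = params.h2
    at_one = h2 >= 1.0
    if np.any(at_one):
        bad = np.ix_(at_one, ~at_one)
        if not np.allclose(params.rP[bad], params.rG[bad] * 0):
            raise ValueError("h2=1 traits cannot carry residual correlation")
    denom = np.sqrt(np.outer(1.0 - h2, 1.0 - h2))
    denom[denom == 0] = np.inf
    num = params.rP - params.rG * np.sqrt(np.outer(h2, h2))
    re = num / denom
    np.fill_diagonal(re, 1.0)
    return nearest_psd_correlation(re)


def genetic_covariance(params: TraitParams) -> np.ndarray:
    """Additive genetic covariance matrix implied by rG, h2 and sdP."""
    sd_a = np.sqrt(params.h2) * params.sdP
    return params.rG * np.outer(sd_a, sd_a)


def build_architecture(
    gmap: GeneticMap,
    params: TraitParams,
    base_population: list,
    n_qtl: int,
    rng: np.random.Generator,
) -> TraitArchitecture:
    """Sample the shared QTL set and correlated effects, then calibrate.

    QTL positions are a random subset of the SNP loci (the QTL stay in the
    marker panel used for genomic evaluation).  Effects are i.i.d. standard
    normals mixed by the lower Cholesky factor of rG, then each trait
    column is rescaled so the realized additive variance across the base
    population equals h2 * sdP^2.
    """
    if n_qtl > gmap.n_loci:
        raise ValueError("cannot place more QTL than loci")
    if not base_population:
        raise ValueError("base population must be nonempty")
    qtl = np.sort(rng.choice(gmap.n_loci, size=n_qtl, replace=False))
    rg = nearest_psd_correlation(params.rG)
    try:
        L = np.linalg.cholesky(rg + 1e-12 * np.eye(N_TRAITS))
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(
            f"genetic correlation matrix not decomposable: {exc}"
        ) from exc
    z = rng.standard_normal((n_qtl, N_TRAITS))
    effects = z @ L.T
    dose = np.stack([dosage(ind)[qtl] for ind in base_population]).astype(float)
    raw = dose @ effects
    var = raw.var(axis=0, ddof=0)
    target = params.h2 * params.sdP**2
    if np.any(var <= 0):
        raise ValueError("degenerate base population: zero genotypic variance")
    scale = np.sqrt(target / var)
    intercept = -(raw * scale).mean(axis=0)
    return TraitArchitecture(qtl_indices=qtl, effects=effects, scale=scale,
                             intercept=intercept)


def true_breeding_values(ind: Individual, arch: TraitArchitecture) -> np.ndarray:
    """Additive genetic merit: calibrated QTL-dosage score per trait,
    centred so the base-population mean is zero."""
    d = dosage(ind)[arch.qtl_indices].astype(float)
    return d @ arch.effects * arch.scale + arch.intercept


def assign_tbv(individuals: list, arch: TraitArchitecture) -> None:
    """Compute and attach true breeding values for a batch of animals."""
    if not individuals:
        return
    d = np.stack([dosage(i)[arch.qtl_indices] for i in individuals]).astype(float)
    tbv = d @ arch.effects * arch.scale + arch.intercept
    for k, ind in enumerate(individuals):
        ind.tbv = tbv[k]


def record_phenotypes(
    ind: Individual,
    params: TraitParams,
    rE: np.ndarray,
    recording_age: float,
    rng: np.random.Generator,
) -> list:
    """Generate one phenotype record per trait scheduled at this age.

    Records are tbv + e with residuals drawn from a multivariate normal
    whose correlation is rE restricted to the recorded traits and whose
    variances are (1-h2) sdP^2; residuals of different recording ages are
    independent.  Hens only.
    """
    return record_phenotypes_batch([ind], params, rE, recording_age, rng)


def _residual_chol(params: TraitParams, rE: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sd_e = np.sqrt(1.0 - params.h2[idx]) * params.sdP[idx]
    cov = rE[np.ix_(idx, idx)] * np.outer(sd_e, sd_e)
    return np.linalg.cholesky(cov + 1e-10 * np.eye(len(idx)))


def record_phenotypes_batch(
    hens: list,
    params: TraitParams,
    rE: np.ndarray,
    recording_age: float,
    rng: np.random.Generator,
) -> list:
    """Vectorized phenotype generation for a cohort of hens at one age."""
    for ind in hens:
        if ind.sex != FEMALE:
            raise ValueError("phenotypes are recorded for females only")
        if ind.tbv is None:
            raise ValueError("true breeding values must be assigned first")
    traits = TRAITS_AGE_51 if recording_age == RECORDING_AGES[0] else TRAITS_AGE_72
    idx = np.array(traits)
    chol = _residual_chol(params, rE, idx)
    e = rng.standard_normal((len(hens), len(idx))) @ chol.T
    out = []
    for i, ind in enumerate(hens):
        week = ind.birth_week + recording_age
        out.extend(
            PhenotypeRecord(trait=int(t), value=float(ind.tbv[t] + e[i, k]),
                            recorded_week=week, owner=ind.id)
            for k, t in enumerate(idx)
        )
    return out


def save_trait_params(params: TraitParams, path) -> None:
    """Persist trait parameters as YAML (h2, sdP, ew, rG upper triangle,
    rP lower triangle)."""
    import yaml

    iu = np.triu_indices(N_TRAITS, 1)
    il = np.tril_indices(N_TRAITS, -1)
    doc = {
        "names": list(params.names),
        "h2": params.h2.tolist(),
        "sdP": params.sdP.tolist(),
        "ew": params.ew.tolist(),
        "rG_upper": params.rG[iu].tolist(),
        "rP_lower": params.rP[il].tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_trait_params(path) -> TraitParams:
    """Load trait parameters from the YAML schema of ``save_trait_params``."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    rg = np.eye(N_TRAITS)
    rp = np.eye(N_TRAITS)
    rg[np.triu_indices(N_TRAITS, 1)] = doc["rG_upper"]
    rg = rg + rg.T - np.eye(N_TRAITS)
    rp[np.tril_indices(N_TRAITS, -1)] = doc["rP_lower"]
    rp = rp + rp.T - np.eye(N_TRAITS)
    return TraitParams(
        names=tuple(doc["names"]),
        h2=np.asarray(doc["h2"], dtype=float),
        sdP=np.asarray(doc["sdP"], dtype=float),
        ew=np.asarray(doc["ew"], dtype=float),
        rG=rg, rP=rp,
    )


def write_phenotypes_csv(path, individuals) -> None:
    """Long-format phenotype export: id, trait, week, value."""
    with open(path, "w") as fh:
        fh.write("id,trait,week,value\n")
        for ind in individuals:
            for r in ind.phenotypes:
                fh.write(f"{r.owner},{TRAIT_NAMES[r.trait]},"
                         f"{r.recorded_week:g},{r.value:.6g}\n")
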