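"""Founder genomes, meiosis and identity-by-descent tracking.

The simulated genome is a set of autosomes with biallelic SNP loci placed
on a genetic (Morgan) map.  Haplotypes carry two layers of information:

* a 0/1 allele vector over the SNP loci, and
* a piecewise-constant *founder-origin* labelling of the chromosome,
  stored as segments on the genetic map rather than per marker.

Every founder gamete receives a globally unique origin label.  Meiosis
recombines both layers, so any descendant chromosome can be decomposed
into founder segments exactly.  Inbreeding is then measured as the
genetic-length share of the genome at which the two homologues carry the
same founder-gamete label (genomic identity-by-descent), which is exact
rather than a marker-grid approximation.

Recombination follows the Haldane model: crossover counts per chromosome
are Poisson with mean equal to the map length in Morgan, positions are
uniform, and there is no interference and no mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "GeneticMap",
    "Haplotype",
    "Individual",
    "FounderPool",
    "build_genetic_map",
    "sample_founders",
    "meiosis",
    "make_offspring",
    "burn_in",
    "ibd_inbreeding",
    "dosage",
    "write_pedigree_csv",
    "write_vcf",
    "save_haplotypes_h5",
    "load_haplotypes_h5",
]

MALE = "M"
FEMALE = "F"


@dataclass(frozen=True)
class GeneticMap:
    """Genetic map of biallelic loci on a set of autosomes.

    Positions are kept on a single concatenated Morgan axis: chromosome
    ``c`` occupies ``[chrom_starts[c], chrom_starts[c] + chrom_lengths[c])``.
    """

    chrom_lengths: np.ndarray  # Morgan, one entry per chromosome
    locus_chrom: np.ndarray  # chromosome index per locus
    locus_pos: np.ndarray  # global Morgan coordinate per locus, sorted

    def __post_init__(self) -> None:
        if len(self.chrom_lengths) == 0 or len(self.locus_pos) == 0:
            raise ValueError("map needs at least one chromosome and one locus")
        if np.any(np.diff(self.locus_pos) <= 0) and len(self.locus_pos) > 1:
            # strictly increasing within chromosome implies globally strict
            # on the concatenated axis
            raise ValueError("locus positions must be strictly increasing")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths)

    @property
    def n_loci(self) -> int:
        return len(self.locus_pos)

    @property
    def chrom_starts(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.chrom_lengths)[:-1]])

    @property
    def total_length(self) -> float:
        return float(np.sum(self.chrom_lengths))


@dataclass
class Haplotype:
    """One gametic chromosome set: SNP alleles plus founder-origin segments.

    ``seg_starts[i]`` opens the half-open interval carrying origin label
    ``seg_labels[i]``; the interval closes at ``seg_starts[i+1]`` (or the
    end of the map for the last segment).
    """

    alleles: np.ndarray  # uint8, length n_loci
    seg_starts: np.ndarray  # float64, ascending, seg_starts[0] == 0
    seg_labels: np.ndarray  # int64 founder-gamete labels


@dataclass
class Individual:
    id: int
    sex: str  # MALE or FEMALE
    birth_week: float
    sire_id: int | None
    dam_id: int | None
    hap_paternal: Haplotype
    hap_maternal: Haplotype
    tbv: np.ndarray | None = None
    phenotypes: list = field(default_factory=list)
    genotyped: bool = False
    cohort_id: str = ""
    subpop: str | None = None

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None


@dataclass
class FounderPool:
    males: list
    females: list
    allele_freq: np.ndarray

    @property
    def all(self) -> list:
        return self.males + self.females


def build_genetic_map(
    n_chromosomes: int,
    loci_per_chromosome: int,
    morgan_per_chromosome: float,
    rng: np.random.Generator | None = None,
) -> GeneticMap:
    """Place ``loci_per_chromosome`` loci uniformly at random on each of
    ``n_chromosomes`` chromosomes of equal genetic length."""
    if n_chromosomes < 1 or loci_per_chromosome < 1 or morgan_per_chromosome <= 0:
        raise ValueError("chromosome count, locus count and length must be positive")
    rng = np.random.default_rng(0) if rng is None else rng
    lengths = np.full(n_chromosomes, float(morgan_per_chromosome))
    starts = np.concatenate([[0.0], np.cumsum(lengths)[:-1]])
    pos_chunks = []
    chrom_idx = []
    for c in range(n_chromosomes):
        # resample until strictly increasing (ties have probability ~0 but
        # the invariant is hard)
        while True:
            p = np.sort(rng.uniform(0.0, morgan_per_chromosome, loci_per_chromosome))
            if loci_per_chromosome == 1 or np.all(np.diff(p) > 0):
                break
        pos_chunks.append(p + starts[c])
        chrom_idx.append(np.full(loci_per_chromosome, c))
    return GeneticMap(
        chrom_lengths=lengths,
        locus_chrom=np.concatenate(chrom_idx),
        locus_pos=np.concatenate(pos_chunks),
    )


def _founder_haplotype(freq: np.ndarray, label: int, total_length: float,
                       rng: np.random.Generator) -> Haplotype:
    alleles = (rng.random(len(freq)) < freq).astype(np.uint8)
    return Haplotype(
        alleles=alleles,
        seg_starts=np.array([0.0]),
        seg_labels=np.array([label], dtype=np.int64),
    )


def sample_founders(
    gmap: GeneticMap,
    n_males: int,
    n_females: int,
    rng: np.random.Generator,
    freq_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    id_start: int = 0,
) -> FounderPool:
    """Draw unrelated founders with per-locus allele frequencies shared by
    the whole pool and haplotypes sampled independently per gamete."""
    if n_males < 1 or n_females < 1:
        raise ValueError("need at least one founder of each sex")
    if freq_sampler is None:
        freq = rng.uniform(0.05, 0.95, gmap.n_loci)
    else:
        freq = np.asarray(freq_sampler(rng, gmap.n_loci), dtype=float)
    label = 0
    next_id = id_start
    males, females = [], []
    for sex, n, out in ((MALE, n_males, males), (FEMALE, n_females, females)):
        for _ in range(n):
            hp = _founder_haplotype(freq, label, gmap.total_length, rng)
            hm = _founder_haplotype(freq, label + 1, gmap.total_length, rng)
            label += 2
            out.append(
                Individual(
                    id=next_id, sex=sex, birth_week=0.0,
                    sire_id=None, dam_id=None,
                    hap_paternal=hp, hap_maternal=hm,
                )
            )
            next_id += 1
    return FounderPool(males=males, females=females, allele_freq=freq)


def _segments_in_window(hap: Haplotype, lo: float, hi: float):
    """Origin segments of ``hap`` clipped to ``[lo, hi)``."""
    starts, labels = hap.seg_starts, hap.seg_labels
    i = int(np.searchsorted(starts, lo, side="right") - 1)
    j = int(np.searchsorted(starts, hi, side="left"))
    s = starts[i:j].copy()
    s[0] = lo
    return s, labels[i:j]


def meiosis(parent: Individual, gmap: GeneticMap, rng: np.random.Generator) -> Haplotype:
    """Produce one gamete from ``parent`` under the Haldane model.

    Crossover counts are Poisson(map length) per chromosome with uniform
    positions; the starting homologue of each chromosome is chosen fairly
    (independent assortment).  Alleles and origin segments are copied
    segment-wise from the two parental haplotypes.
    """
    haps = (parent.hap_paternal, parent.hap_maternal)
    starts = gmap.chrom_starts
    lengths = gmap.chrom_lengths
    pos = gmap.locus_pos
    alleles = np.empty(gmap.n_loci, dtype=np.uint8)
    out_starts: list[np.ndarray] = []
    out_labels: list[np.ndarray] = []
    for c in range(gmap.n_chromosomes):
        lo, L = starts[c], lengths[c]
        hi = lo + L
        n_xo = rng.poisson(L)
        cuts = np.sort(rng.uniform(lo, hi, n_xo)) if n_xo else np.empty(0)
        source = int(rng.integers(2))
        if L == 0.0:
            # degenerate zero-length chromosome: unrecombined copy
            hap = haps[source]
            sel = gmap.locus_chrom == c
            alleles[sel] = hap.alleles[sel]
            i = int(np.searchsorted(hap.seg_starts, lo, side="right") - 1)
            out_starts.append(np.array([lo]))
            out_labels.append(hap.seg_labels[i:i + 1])
            continue
        bounds = np.concatenate([[lo], cuts, [hi]])
        for k in range(len(bounds) - 1):
            a, b = bounds[k], bounds[k + 1]
            hap = haps[(source + k) % 2]
            li = int(np.searchsorted(pos, a, side="left"))
            lj = int(np.searchsorted(pos, b, side="left"))
            alleles[li:lj] = hap.alleles[li:lj]
            if a < b:
                s, lab = _segments_in_window(hap, a, b)
                out_starts.append(s)
                out_labels.append(lab)
    seg_starts = np.concatenate(out_starts)
    seg_labels = np.concatenate(out_labels)
    # merge adjacent segments with identical labels
    keep = np.concatenate([[True], seg_labels[1:] != seg_labels[:-1]])
    return Haplotype(alleles=alleles, seg_starts=seg_starts[keep],
                     seg_labels=seg_labels[keep])


def make_offspring(
    new_id: int,
    sire: Individual,
    dam: Individual,
    sex: str,
    birth_week: float,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> Individual:
    return Individual(
        id=new_id, sex=sex, birth_week=birth_week,
        sire_id=sire.id, dam_id=dam.id,
        hap_paternal=meiosis(sire, gmap, rng),
        hap_maternal=meiosis(dam, gmap, rng),
    )


def burn_in(
    pool: FounderPool,
    generations: int,
    out_males: int,
    out_females: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    id_start: int | None = None,
) -> list:
    """Random mating from the founder pool for ``generations`` rounds.

    Intermediate generations keep the founder-pool sizes; the final
    generation is expanded to ``out_males``/``out_females`` animals, the
    base breeding population.  Sires and dams are drawn with replacement.
    """
    if generations < 1:
        raise ValueError("need at least one burn-in generation")
    if not pool.males or not pool.females:
        raise ValueError("founder pool must contain both sexes")
    next_id = (max(i.id for i in pool.all) + 1) if id_start is None else id_start
    males, females = pool.males, pool.females
    for g in range(generations):
        last = g == generations - 1
        nm = out_males if last else len(pool.males)
        nf = out_females if last else len(pool.females)
        new_m, new_f = [], []
        for sex, n, out in ((MALE, nm, new_m), (FEMALE, nf, new_f)):
            for _ in range(n):
                sire = males[rng.integers(len(males))]
                dam = females[rng.integers(len(females))]
                out.append(make_offspring(next_id, sire, dam, sex, 0.0, gmap, rng))
                next_id += 1
        males, females = new_m, new_f
    return males + females


def ibd_inbreeding(ind: Individual, gmap: GeneticMap) -> float:
    """Genomic inbreeding: genetic-length fraction of the genome at which
    the paternal and maternal founder-origin labels coincide."""
    p, m = ind.hap_paternal, ind.hap_maternal
    total = gmap.total_length
    bounds = np.union1d(p.seg_starts, m.seg_starts)
    ends = np.concatenate([bounds[1:], [total]])
    ip = np.searchsorted(p.seg_starts, bounds, side="right") - 1
    im = np.searchsorted(m.seg_starts, bounds, side="right") - 1
    same = p.seg_labels[ip] == m.seg_labels[im]
    return float(np.sum((ends - bounds)[same]) / total)


def dosage(ind: Individual) -> np.ndarray:
    """0/1/2 genotype vector, the per-locus sum of the two haplotypes."""
    return ind.hap_paternal.alleles.astype(np.int8) + ind.hap_maternal.alleles


def write_pedigree_csv(path, individuals: Iterable[Individual]) -> None:
    """Three-column pedigree export (id, sire, dam); unknown parents blank."""
    with open(path, "w") as fh:
        fh.write("id,sire,dam\n")
        for ind in individuals:
            s = "" if ind.sire_id is None else ind.sire_id
            d = "" if ind.dam_id is None else ind.dam_id
            fh.write(f"{ind.id},{s},{d}\n")


def write_vcf(path, individuals: Sequence[Individual], gmap: GeneticMap) -> None:
    """Export phased diploid genotypes as a minimal VCF (one contig per
    chromosome, positions in units of 10^-6 Morgan rounded to 1-based bp)."""
    inds = list(individuals)
    rel_pos = gmap.locus_pos - gmap.chrom_starts[gmap.locus_chrom]
    bp = np.maximum(1, np.round(rel_pos * 1e6).astype(np.int64))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in range(gmap.n_chromosomes):
            fh.write(f"##contig=<ID=chr{c + 1}>\n")
        cols = "\t".join(f"ind{ind.id}" for ind in inds)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + cols + "\n")
        pat = np.stack([i.hap_paternal.alleles for i in inds])
        mat = np.stack([i.hap_maternal.alleles for i in inds])
        for j in range(gmap.n_loci):
            gts = "\t".join(f"{pat[i, j]}|{mat[i, j]}" for i in range(len(inds)))
            fh.write(
                f"chr{gmap.locus_chrom[j] + 1}\t{bp[j]}\tsnp{j}\tA\tG\t.\tPASS\t.\tGT\t"
                + gts + "\n"
            )


def save_haplotypes_h5(path, individuals: Iterable[Individual]) -> None:
    """Binary haplotype store keyed by individual id (alleles plus
    founder-origin segments for both gametes)."""
    import h5py

    with h5py.File(path, "w") as fh:
        for ind in individuals:
            grp = fh.create_group(str(ind.id))
            for tag, hap in (("pat", ind.hap_paternal), ("mat", ind.hap_maternal)):
                grp.create_dataset(f"{tag}_alleles", data=hap.alleles,
                                   compression="gzip")
                grp.create_dataset(f"{tag}_starts", data=hap.seg_starts)
                grp.create_dataset(f"{tag}_labels", data=hap.seg_labels)


def load_haplotypes_h5(path) -> dict:
    """Load the haplotype pairs written by ``save_haplotypes_h5``."""
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        for key in fh:
            grp = fh[key]
            out[int(key)] = tuple(
                Haplotype(alleles=grp[f"{tag}_alleles"][:],
                          seg_starts=grp[f"{tag}_starts"][:],
                          seg_labels=grp[f"{tag}_labels"][:])
                for tag in ("pat", "mat"))
    return out
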