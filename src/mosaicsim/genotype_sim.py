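"""Synthetic genotypes as mosaics of imperfectly copied reference segments.

Each synthetic haplotype is a concatenation of segments copied from
haplotypes of a phased reference panel (a Li–Stephens-style copying model).
Per segment the model draws

* a donor ancestry group (fixed label, or i.i.d. from a proportion vector),
* a donor haplotype, uniform among that group's haplotypes,
* a coalescence age ``T ~ Gamma(shape 2, rate Ns/Ne)`` where Ns is the
  number of reference haplotypes in the donor group and Ne the group's
  effective population size — so E[T] = 2*Ne/Ns: a larger panel implies a
  genealogically closer nearest donor and hence older-looking, longer
  segments are NOT needed to explain the data,
* a segment length ``l ~ Exp(rate 2*T*rho)`` in centimorgans, where rho is
  the group's recombination-intensity parameter.

Alleles are imperfectly copied: the alternate allele at variant i survives
only if ``T <= m_i`` (the variant's mutation age); younger variants are
suppressed to the reference allele. Two independent haplotypes are summed
element-wise into a diploid dosage in {0, 1, 2}.

Reproducibility contract: every (sample, haplotype) pair owns an
independent random substream derived from ``SeedSequence(seed,
spawn_key=(sample, hap))``, so output is a pure function of (inputs, seed)
— identical across batch sizes and worker counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference_io import (
    GeneticMap,
    GenotypeMatrix,
    MutationAges,
    ReferencePanel,
    interpolate_cm,
    write_genotypes,
)

__all__ = [
    "SimParams",
    "MosaicPlan",
    "sample_coalescence_age",
    "sample_segment_length",
    "plan_mosaic",
    "copy_segment",
    "synthesize_cohort",
]

# draws are made in fixed-size blocks so the stream consumption pattern is a
# constant of the implementation, independent of batching/threading
_DRAW_BLOCK = 64


@dataclass
class SimParams:
    """Parameters of the mosaic copying model.

    rho, ne : float or dict ancestry-label -> float
        Recombination intensity (1 / (time * cM)) and effective population
        size per ancestry group; scalars apply to every group. Defaults are
        the fixed-parameter benchmark setting rho = 2.185, Ne = 500.
    ancestry : str or dict label -> proportion
        Either a single donor group, or admixture proportions (>= 0,
        summing to 1) from which a donor group is drawn i.i.d. per segment.
    """

    n_samples: int = 100
    rho: float | dict = 2.185
    ne: float | dict = 500.0
    ancestry: str | dict | None = None
    seed: int = 0
    batch_size: int = 64

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        for name, val in (("rho", self.rho), ("ne", self.ne)):
            vals = val.values() if isinstance(val, dict) else [val]
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be positive")
        if isinstance(self.ancestry, dict):
            props = np.array(list(self.ancestry.values()), dtype=float)
            if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
                raise ValueError("ancestry proportions must be >= 0 and sum to 1")

    def rho_of(self, group: str) -> float:
        return float(self.rho[group] if isinstance(self.rho, dict) else self.rho)

    def ne_of(self, group: str) -> float:
        return float(self.ne[group] if isinstance(self.ne, dict) else self.ne)


@dataclass
class MosaicPlan:
    """An ordered tiling of one chromosome by copy segments.

    Segments are half-open cM intervals [start, end), contiguous and
    non-overlapping; the first start and last end coincide with the
    chromosome's map span. ``ages[i]`` is the coalescence age T of segment i.
    """

    chrom: str
    donors: np.ndarray       # donor haplotype index per segment
    starts: np.ndarray       # cM
    ends: np.ndarray         # cM
    ages: np.ndarray         # T per segment
    groups: np.ndarray = field(default=None)  # donor ancestry label per segment

    @property
    def n_segments(self) -> int:
        return len(self.donors)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def validate(self, span: tuple[float, float]) -> None:
        if self.n_segments == 0:
            raise ValueError("empty mosaic plan")
        if not np.isclose(self.starts[0], span[0]) or not np.isclose(self.ends[-1], span[1]):
            raise ValueError("plan does not span the chromosome")
        if not np.allclose(self.starts[1:], self.ends[:-1]):
            raise ValueError("segments not contiguous")
        if (self.ages <= 0).any():
            raise ValueError("coalescence ages must be positive")


def sample_coalescence_age(params: SimParams, group: str, n_ref_haps: int,
                           rng: np.random.Generator) -> float:
    """Draw the coalescence age T of one segment.

    T ~ Gamma(shape 2, rate Ns/Ne), i.e. scale Ne/Ns, so E[T] = 2*Ne/Ns and
    Var[T] = 2*(Ne/Ns)^2.
    """
    if n_ref_haps < 1:
        raise ValueError("need at least one reference haplotype in the group")
    ne = params.ne_of(group)
    return float(rng.gamma(shape=2.0, scale=ne / n_ref_haps))


def sample_segment_length(T: float, rho: float, rng: np.random.Generator) -> float:
    """Draw a segment length in cM: l ~ Exp(rate 2*T*rho), mean 1/(2*T*rho)."""
    if T <= 0 or rho <= 0:
        raise ValueError("T and rho must be positive")
    return float(rng.exponential(1.0 / (2.0 * T * rho)))


def _donor_pools(panel: ReferencePanel, params: SimParams):
    """Resolve the ancestry mode into (labels, proportions, hap-index pools)."""
    if params.ancestry is None:
        labels = panel.ancestry_groups()
        if len(labels) != 1:
            raise ValueError(
                "panel has multiple ancestry groups; set SimParams.ancestry"
            )
        props = np.array([1.0])
    elif isinstance(params.ancestry, dict):
        labels = [l for l, p in params.ancestry.items() if p > 0]
        props = np.array([params.ancestry[l] for l in labels], dtype=float)
        props = props / props.sum()
    else:
        labels = [params.ancestry]
        props = np.array([1.0])
    pools = [panel.group_haplotypes(l) for l in labels]  # raises if empty
    return labels, props, pools


def plan_mosaic(panel: ReferencePanel, gmap: GeneticMap, params: SimParams,
                chrom, rng: np.random.Generator) -> MosaicPlan:
    """Tile one chromosome with copy segments drawn from the stochastic model.

    Walks from the chromosome's start cM; per segment draws donor group,
    donor haplotype, T, then l; the final segment is truncated at the
    chromosome's end cM.
    """
    chrom = str(chrom)
    labels, props, pools = _donor_pools(panel, params)
    lo, hi = gmap.span_cm(chrom)
    span = hi - lo
    scales = np.array([params.ne_of(l) / len(pools[l_i])
                       for l_i, l in enumerate(labels)])
    rhos = np.array([params.rho_of(l) for l in labels])

    donors, groups, ages, lens = [], [], [], []
    total = 0.0
    while total < span or not donors:
        gi = (np.zeros(_DRAW_BLOCK, dtype=np.intp) if len(labels) == 1
              else rng.choice(len(labels), size=_DRAW_BLOCK, p=props))
        u = rng.random(_DRAW_BLOCK)
        t = rng.gamma(shape=2.0, scale=scales[gi])
        l = rng.exponential(1.0 / (2.0 * t * rhos[gi]))
        for j in range(_DRAW_BLOCK):
            pool = pools[gi[j]]
            donors.append(pool[int(u[j] * len(pool))])
            groups.append(labels[gi[j]])
            ages.append(t[j])
            lens.append(l[j])
            total += l[j]
            if total >= span:
                break
        if total >= span:
            break

    ends = lo + np.minimum(np.cumsum(lens), span)
    starts = np.concatenate(([lo], ends[:-1]))
    ends[-1] = hi
    return MosaicPlan(chrom=chrom, donors=np.asarray(donors, dtype=np.intp),
                      starts=starts, ends=ends,
                      ages=np.asarray(ages, dtype=float),
                      groups=np.asarray(groups, dtype=object))


def copy_segment(panel: ReferencePanel, ages: MutationAges,
                 segment: tuple, gmap: GeneticMap, chrom=None) -> np.ndarray:
    """Imperfectly copy one segment's alleles from its donor haplotype.

    ``segment`` is (donor haplotype index, (start_cm, end_cm), T). A variant
    falls in the segment if its interpolated cM position lies in the
    half-open interval [start, end). Each alternate allele is copied only if
    T <= m_i; variants with missing age (m_i = +inf) are always copied.
    Suppressed variants revert to allele 0.
    """
    donor, (start_cm, end_cm), T = segment
    chrom = str(chrom) if chrom is not None else str(panel.variants["chrom"].iloc[0])
    cols = panel.variant_index(chrom)
    cm = interpolate_cm(gmap, chrom, panel.variants["pos"].to_numpy()[cols])
    inside = cols[(cm >= start_cm) & (cm < end_cm)]
    alleles = panel.haplotypes[donor, inside].copy()
    keep = T <= ages.ages[inside]
    return (alleles & keep).astype(np.uint8)


def _build_haplotype(panel: ReferencePanel, gmap: GeneticMap, ages: MutationAges,
                     params: SimParams, chrom_cols: dict, chrom_cm: dict,
                     rng: np.random.Generator) -> np.ndarray:
    """One full synthetic haplotype across all chromosomes (panel variant order)."""
    out = np.empty(panel.n_variants, dtype=np.uint8)
    for chrom, cols in chrom_cols.items():
        plan = plan_mosaic(panel, gmap, params, chrom, rng)
        cm = chrom_cm[chrom]
        seg = np.clip(np.searchsorted(plan.starts, cm, side="right") - 1,
                      0, plan.n_segments - 1)
        alleles = panel.haplotypes[plan.donors[seg], cols]
        keep = plan.ages[seg] <= ages.ages[cols]
        out[cols] = alleles & keep
    return out


def synthesize_cohort(panel: ReferencePanel, gmap: GeneticMap,
                      ages: MutationAges | None, params: SimParams,
                      out_path=None, format: str = "plink-bed",
                      sample_prefix: str = "syn") -> GenotypeMatrix:
    """Generate a cohort of ``params.n_samples`` synthetic diploid genotypes.

    For each individual, two independent mosaic haplotypes are built and
    summed into dosages g = h1 + h2. Samples are processed in batches of
    ``params.batch_size``; because every (sample, haplotype) pair draws from
    its own seed-derived substream, batch size cannot change the output.
    If ``out_path`` is given the matrix is also written in ``format``.
    """
    if ages is None:
        ages = MutationAges.all_missing(panel.n_variants)
    if len(ages.ages) != panel.n_variants:
        raise ValueError("mutation-age vector length does not match panel")
    chroms = [c for c in dict.fromkeys(panel.variants["chrom"].astype(str))]
    missing = [c for c in chroms if c not in gmap.knots]
    if missing:
        raise ValueError(f"genetic map missing chromosomes: {missing}")
    chrom_cols = {c: panel.variant_index(c) for c in chroms}
    chrom_cm = {
        c: interpolate_cm(gmap, c, panel.variants["pos"].to_numpy()[cols])
        for c, cols in chrom_cols.items()
    }

    n = params.n_samples
    dosages = np.empty((n, panel.n_variants), dtype=np.uint8)
    for start in range(0, n, params.batch_size):
        for i in range(start, min(start + params.batch_size, n)):
            haps = []
            for j in (0, 1):
                rng = np.random.default_rng(
                    np.random.SeedSequence(params.seed, spawn_key=(i, j))
                )
                haps.append(_build_haplotype(panel, gmap, ages, params,
                                             chrom_cols, chrom_cm, rng))
            dosages[i] = haps[0] + haps[1]

    matrix = GenotypeMatrix(
        dosages=dosages,
        sample_ids=[f"{sample_prefix}{i}" for i in range(n)],
        variants=panel.variants.reset_index(drop=True),
    )
    if out_path is not None:
        write_genotypes(matrix, out_path, format=format, gmap=gmap)
    return matrix
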