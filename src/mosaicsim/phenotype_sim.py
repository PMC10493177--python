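"""Polygenic phenotype simulation on top of synthetic genotypes.

A trait is assembled as the sum of a genetic component (a weighted sum of
raw causal allele counts), an optional covariate component, and Gaussian
environmental noise. Per causal SNP i the effect size is drawn from a
zero-mean (mixture of) normal(s) whose variance scales as

    Var(beta_i)  ∝  [p_i (1 - p_i)]^a  *  r_i^b  *  s_i^c

with p_i the MAF, r_i a local LD score (1 + sum of r^2 to neighbours within
a cM window), and s_i an optional functional-annotation score. The power
parameters a, b, c encode the strength of negative selection on each axis;
the defaults a = -0.25, b = -0.25, c = 0 (with s_i ≡ 1 when no annotation
is supplied) are configuration placeholders in the spirit of empirical
MAF/LD-dependent architectures, not estimates — expose and change them per
study.

Variance calibration is empirical: each component is rescaled by its
realized standard deviation so the realized variance shares equal h2,
covariate_fraction and 1 - h2 - covariate_fraction on every run. Binary
traits threshold the liability at the empirical prevalence quantile (top
``prevalence`` fraction = cases, coded 2), which yields the configured case
fraction exactly.

Multi-trait and multi-ancestry support: in "shared-causals" mode one causal
set is reused across traits (and ancestry groups) with effect vectors drawn
from a multivariate normal with the configured trait x trait (or population
x population) correlation; "independent-causals" draws disjoint sets per
trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference_io import GeneticMap, GenotypeMatrix, interpolate_cm

__all__ = [
    "TraitModel",
    "PhenotypeTable",
    "compute_maf",
    "compute_ld_scores",
    "sample_causal_set",
    "draw_effect_sizes",
    "draw_cross_population_effects",
    "assemble_traits",
    "write_phenotypes",
    "simulate_traits",
]


@dataclass
class TraitModel:
    """Genetic-architecture parameters for one (set of) simulated trait(s)."""

    h2: float = 0.5
    polygenicity: float = 0.005
    a: float = -0.25
    b: float = -0.25
    c: float = 0.0
    mixture: list = field(default_factory=lambda: [(1.0, 1.0)])
    prevalence: float | None = None
    covariate_fraction: float = 0.0
    n_traits: int = 1
    trait_corr: np.ndarray | None = None
    pop_corr: np.ndarray | None = None
    pleiotropy_mode: str = "shared-causals"

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must be in [0, 1]")
        if not (0.0 < self.polygenicity <= 1.0):
            raise ValueError("polygenicity must be in (0, 1]")
        if not (0.0 <= self.covariate_fraction < 1.0):
            raise ValueError("covariate_fraction must be in [0, 1)")
        if self.h2 + self.covariate_fraction > 1.0:
            raise ValueError("h2 + covariate_fraction must be <= 1")
        w = sum(w for w, _ in self.mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.prevalence is not None and not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if self.pleiotropy_mode not in ("shared-causals", "independent-causals"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        for mat in (self.trait_corr, self.pop_corr):
            if mat is not None:
                _check_correlation(np.asarray(mat, dtype=float))


@dataclass
class PhenotypeTable:
    """Realized per-sample traits (and covariates), one row per individual."""

    fid: list
    iid: list
    traits: pd.DataFrame
    covariates: pd.DataFrame | None = None
    # realized (already rescaled) genetic/covariate/noise components per
    # trait, kept so realized variance shares can be measured directly
    components: dict | None = None

    def __post_init__(self) -> None:
        if len(self.traits) != len(self.iid):
            raise ValueError("one row per sample required")

    def realized_h2(self, trait: str) -> float:
        """Var(genetic component) / Var(liability) for one trait."""
        comp = self.components[trait]
        liability = comp["genetic"] + comp["noise"] + comp.get(
            "covariate", np.zeros_like(comp["genetic"]))
        return float(comp["genetic"].var() / liability.var())


def _check_correlation(mat: np.ndarray) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(np.diag(mat), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    if not np.allclose(mat, mat.T):
        raise ValueError("correlation matrix must be symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -1e-8:
        raise ValueError("correlation matrix must be positive semi-definite")


def _psd_factor(mat: np.ndarray) -> np.ndarray:
    """Symmetric square root; tolerates singular (rank-deficient) matrices."""
    w, v = np.linalg.eigh(mat)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T


def compute_maf(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency: min(f, 1 - f), f = mean dosage / 2."""
    if genotypes.n_samples < 1:
        raise ValueError("empty genotype matrix")
    f = genotypes.dosages.mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def compute_ld_scores(genotypes: GenotypeMatrix, gmap: GeneticMap | None = None,
                      window_cm: float = 1.0) -> np.ndarray:
    """LD score per SNP: 1 + sum of squared dosage correlations r^2 to every
    other SNP within ``window_cm`` on the same chromosome.

    The +1 is the SNP's self term. Monomorphic SNPs get score 1. Without a
    map, the window is interpreted in Mb on bp positions.
    """
    if window_cm <= 0:
        raise ValueError("window must be positive")
    X = genotypes.dosages.astype(float)
    n = X.shape[0]
    scores = np.ones(genotypes.n_variants)
    sd = X.std(axis=0)
    for chrom, grp in genotypes.variants.reset_index(drop=True).groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        pos = grp["pos"].to_numpy(float)
        coord = (interpolate_cm(gmap, chrom, pos) if gmap is not None
                 else pos / 1e6)
        Z = X[:, cols]
        Z = Z - Z.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = np.where(sd[cols] > 0, Z / sd[cols], 0.0)
        for a, i in enumerate(cols):
            if sd[i] == 0:
                continue
            lo = np.searchsorted(coord, coord[a] - window_cm, side="left")
            hi = np.searchsorted(coord, coord[a] + window_cm, side="right")
            r = Z[:, lo:hi].T @ Z[:, a] / n
            # exact self term: 1 + sum over neighbours j != i of r^2
            scores[i] = 1.0 + float(np.sum(r**2) - r[a - lo] ** 2)
    return scores


def sample_causal_set(n_variants: int, polygenicity: float,
                      eligible: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly sample the causal SNP set among eligible (polymorphic) SNPs.

    Size = round(polygenicity * n_eligible), at least 1.
    """
    idx = np.flatnonzero(np.asarray(eligible, dtype=bool)[:n_variants])
    if idx.size == 0:
        raise ValueError("no eligible SNPs to draw causals from")
    n_causal = max(1, int(round(polygenicity * idx.size)))
    return np.sort(rng.choice(idx, size=n_causal, replace=False))


def _architecture_sd(p: np.ndarray, r: np.ndarray, s: np.ndarray,
                     model: TraitModel) -> np.ndarray:
    """Per-SNP marginal effect sd (single mixture component, unit rel-var)."""
    if (p <= 0).any():
        raise ValueError("causal SNPs must be polymorphic (p > 0)")
    var = (p * (1.0 - p)) ** model.a * r ** model.b * s ** model.c
    return np.sqrt(var)


def draw_effect_sizes(p: np.ndarray, r: np.ndarray, s: np.ndarray,
                      model: TraitModel, causal: np.ndarray,
                      rng: np.random.Generator,
                      n_variants: int | None = None) -> np.ndarray:
    """Draw the full-length effect-size vector beta (zeros off the causal set).

    Causal effects come from the configured mixture of zero-mean normals:
    a component is picked by weight per SNP and its variance is the
    component's relative variance times [p(1-p)]^a * r^b * s^c.
    """
    p, r, s = (np.asarray(x, dtype=float) for x in (p, r, s))
    if n_variants is None:
        n_variants = len(p)
    beta = np.zeros(n_variants)
    sd = _architecture_sd(p[causal], r[causal], s[causal], model)
    weights = np.array([w for w, _ in model.mixture])
    relvar = np.array([v for _, v in model.mixture])
    comp = rng.choice(len(weights), size=len(causal), p=weights)
    beta[causal] = rng.standard_normal(len(causal)) * sd * np.sqrt(relvar[comp])
    return beta


def draw_cross_population_effects(p_by_pop: dict, r_by_pop: dict,
                                  s: np.ndarray, model: TraitModel,
                                  causal: np.ndarray, pop_corr: np.ndarray,
                                  rng: np.random.Generator,
                                  n_variants: int | None = None) -> dict:
    """Correlated per-population effect vectors for shared causal SNPs.

    For each causal SNP the vector of per-population effects is multivariate
    zero-mean normal with correlation ``pop_corr`` and marginal variances
    given by the architecture formula under each population's own p and r.
    Returns a dict population -> full-length beta vector.
    """
    pops = list(p_by_pop)
    _check_correlation(pop_corr)
    if pop_corr.shape[0] != len(pops):
        raise ValueError("pop_corr dimension does not match population count")
    if n_variants is None:
        n_variants = len(next(iter(p_by_pop.values())))
    A = _psd_factor(pop_corr)
    z = rng.standard_normal((len(causal), len(pops))) @ A.T  # unit marginals
    weights = np.array([w for w, _ in model.mixture])
    relvar = np.array([v for _, v in model.mixture])
    comp = rng.choice(len(weights), size=len(causal), p=weights)
    scale_mix = np.sqrt(relvar[comp])
    out = {}
    for k, pop in enumerate(pops):
        sd = _architecture_sd(np.asarray(p_by_pop[pop])[causal],
                              np.asarray(r_by_pop[pop])[causal],
                              np.asarray(s)[causal], model)
        beta = np.zeros(n_variants)
        beta[causal] = z[:, k] * sd * scale_mix
        out[pop] = beta
    return out


def _scale_to(x: np.ndarray, target_sd: float) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        if target_sd > 0:
            raise ValueError("zero-variance component with positive target share")
        return np.zeros_like(x)
    return x * (target_sd / sd)


def assemble_traits(genotypes: GenotypeMatrix, betas: np.ndarray | list,
                    model: TraitModel, rng: np.random.Generator,
                    covariates: np.ndarray | None = None,
                    covariate_weights: np.ndarray | None = None,
                    trait_names: list | None = None) -> PhenotypeTable:
    """Sum genetic, covariate and noise components into realized traits.

    The genetic component is G @ beta on raw allele counts; each component is
    rescaled by its empirical standard deviation so realized variance shares
    equal h2 / covariate_fraction / remainder. Binary traits (prevalence
    set) code the top ``prevalence`` fraction of the liability as cases (2),
    the rest as controls (1); ties break by sample order.
    """
    beta_list = betas if isinstance(betas, list) else [betas]
    G = genotypes.dosages.astype(float)
    n = genotypes.n_samples
    env_share = 1.0 - model.h2 - model.covariate_fraction
    cov_component = None
    if model.covariate_fraction > 0:
        if covariates is None:
            raise ValueError("covariate_fraction > 0 but no covariates supplied")
        w = (np.ones(covariates.shape[1]) if covariate_weights is None
             else np.asarray(covariate_weights, dtype=float))
        cov_component = covariates @ w

    columns = {}
    components = {}
    names = trait_names or [f"trait{t + 1}" for t in range(len(beta_list))]
    for name, beta in zip(names, beta_list):
        if len(beta) != genotypes.n_variants:
            raise ValueError("beta length does not match variant count")
        g = _scale_to(G @ beta, np.sqrt(model.h2))
        e = _scale_to(rng.standard_normal(n), np.sqrt(env_share)) if env_share > 0 \
            else np.zeros(n)
        y = g + e
        components[name] = {"genetic": g, "noise": e}
        if cov_component is not None:
            cv = _scale_to(cov_component, np.sqrt(model.covariate_fraction))
            y = y + cv
            components[name]["covariate"] = cv
        if model.prevalence is not None:
            n_cases = int(round(model.prevalence * n))
            order = np.argsort(-y, kind="stable")
            coded = np.ones(n, dtype=int)
            coded[order[:n_cases]] = 2
            columns[name] = coded
        else:
            columns[name] = y
    ids = [str(s) for s in genotypes.sample_ids]
    cov_df = (pd.DataFrame(covariates,
                           columns=[f"cov{j + 1}" for j in range(covariates.shape[1])])
              if covariates is not None else None)
    return PhenotypeTable(fid=ids, iid=ids, traits=pd.DataFrame(columns),
                          covariates=cov_df, components=components)


def write_phenotypes(table: PhenotypeTable, path) -> None:
    """Write a GWAS-ready whitespace-delimited file: FID IID trait1 ..."""
    if table.traits.shape[1] == 0:
        raise ValueError("phenotype table has no traits")
    df = pd.DataFrame({"FID": table.fid, "IID": table.iid})
    for col in table.traits.columns:
        df[col] = table.traits[col].to_numpy()
    if table.covariates is not None:
        for col in table.covariates.columns:
            df[col] = table.covariates[col].to_numpy()
    df.to_csv(path, sep=" ", index=False, float_format="%.10g")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+")


def simulate_traits(genotypes: GenotypeMatrix, model: TraitModel,
                    rng: np.random.Generator, gmap: GeneticMap | None = None,
                    s_annot: np.ndarray | None = None,
                    covariates: np.ndarray | None = None,
                    ld_window_cm: float = 1.0) -> tuple[PhenotypeTable, pd.DataFrame]:
    """End-to-end single-population trait simulation.

    Computes MAF and LD scores, samples causal SNPs, draws (possibly
    correlated multi-trait) effects and assembles traits. Returns the
    phenotype table and an effect-size sidecar table (one beta column per
    trait) for truth tracking.
    """
    p = compute_maf(genotypes)
    need_r = model.b != 0.0
    r = compute_ld_scores(genotypes, gmap, ld_window_cm) if need_r \
        else np.ones(genotypes.n_variants)
    s = np.ones(genotypes.n_variants) if s_annot is None else np.asarray(s_annot)
    eligible = p > 0
    betas = []
    if model.n_traits > 1 and model.pleiotropy_mode == "shared-causals":
        corr = (np.asarray(model.trait_corr, dtype=float)
                if model.trait_corr is not None else np.eye(model.n_traits))
        causal = sample_causal_set(genotypes.n_variants, model.polygenicity,
                                   eligible, rng)
        per = draw_cross_population_effects(
            {f"t{t}": p for t in range(model.n_traits)},
            {f"t{t}": r for t in range(model.n_traits)},
            s, model, causal, corr, rng, genotypes.n_variants)
        betas = list(per.values())
    else:
        for _ in range(model.n_traits):
            causal = sample_causal_set(genotypes.n_variants, model.polygenicity,
                                       eligible, rng)
            betas.append(draw_effect_sizes(p, r, s, model, causal, rng,
                                           genotypes.n_variants))
    table = assemble_traits(genotypes, betas, model, rng, covariates=covariates)
    sidecar = genotypes.variants[["chrom", "pos", "ref", "alt"]].copy()
    for t, beta in enumerate(betas):
        sidecar[f"beta_trait{t + 1}"] = beta
    return table, sidecar
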