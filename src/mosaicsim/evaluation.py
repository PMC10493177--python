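"""Fidelity, generalizability and diversity metrics for synthetic genotypes.

Fidelity compares a synthetic cohort with its reference on four axes:
MAF divergence (mean absolute per-SNP MAF difference), LD decay (mean r^2
per distance bin and the Euclidean distance between the two curves),
population structure (mean absolute cosine similarity between the first
n PC variant-loading vectors of each dataset), and nearest-neighbour
adversarial accuracy (average of TPR and TNR of a 1-NN real-vs-synthetic
discriminator; 0.5 = indistinguishable, 0 = the synthetic samples are
copies).

Generalizability and diversity are kinship-based: pairs are classified with
the KING-robust between-family estimator

    phi = (N_Aa,Aa - 2 * N_AA,aa) / (N_Aa,i + N_Aa,j)

using the standard degree thresholds (duplicate/MZ phi > 2^-1.5,
first-degree (2^-2.5, 2^-1.5], second-degree (2^-3.5, 2^-2.5]). With
Ncross the number of closely related (duplicate/MZ or first-degree)
reference-synthetic pairs and Npairs the ordered count of such pairs within
the synthetic set,

    generalizability % = (1 - Ncross / (Nsyn * Nref)) * 100
    diversity %        = (1 - Npairs / (Nsyn^2 - Nsyn)) * 100

The diversity denominator counts ordered pairs, so unordered related-pair
counts are doubled before the formula is applied.

All metrics are deterministic functions of their inputs (no internal RNG).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference_io import GeneticMap, GenotypeMatrix, interpolate_cm

__all__ = [
    "EvalReport",
    "maf_divergence",
    "ld_decay",
    "ld_divergence",
    "pc_alignment",
    "kinship",
    "kinship_matrix",
    "relatedness_counts",
    "generalizability_pct",
    "diversity_pct",
    "adversarial_accuracy",
    "build_report",
    "KINSHIP_THRESHOLDS",
]

# duplicate/MZ, first-degree, second-degree lower bounds
KINSHIP_THRESHOLDS = (2.0 ** -1.5, 2.0 ** -2.5, 2.0 ** -3.5)


@dataclass
class EvalReport:
    """Named metric values from one reference-vs-synthetic comparison."""

    maf_divergence: float
    ld_divergence: float
    pc_alignment: float
    adversarial_accuracy: float
    relatedness_cross: tuple        # (dup/MZ, first-degree, second-degree)
    relatedness_within: tuple
    generalizability_pct: float
    diversity_pct: float
    ld_bins: np.ndarray = field(default=None)
    ld_curve_ref: np.ndarray = field(default=None)
    ld_curve_syn: np.ndarray = field(default=None)
    warnings: list = field(default_factory=list)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"maf_divergence\t{self.maf_divergence:.10g}\n")
            fh.write(f"ld_divergence\t{self.ld_divergence:.10g}\n")
            fh.write(f"pc_alignment\t{self.pc_alignment:.10g}\n")
            fh.write(f"adversarial_accuracy\t{self.adversarial_accuracy:.10g}\n")
            for name, tup in (("cross", self.relatedness_cross),
                              ("within", self.relatedness_within)):
                fh.write(f"relatedness_{name}\t{tup[0]}\t{tup[1]}\t{tup[2]}\n")
            fh.write(f"generalizability_pct\t{self.generalizability_pct:.10g}\n")
            fh.write(f"diversity_pct\t{self.diversity_pct:.10g}\n")
            for w in self.warnings:
                fh.write(f"warning\t{w}\n")

    @classmethod
    def from_file(cls, path) -> "EvalReport":
        vals, warns = {}, []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "warning":
                    warns.append(parts[1])
                elif parts[0].startswith("relatedness_"):
                    vals[parts[0]] = tuple(int(x) for x in parts[1:4])
                else:
                    vals[parts[0]] = float(parts[1])
        return cls(maf_divergence=vals["maf_divergence"],
                   ld_divergence=vals["ld_divergence"],
                   pc_alignment=vals["pc_alignment"],
                   adversarial_accuracy=vals["adversarial_accuracy"],
                   relatedness_cross=vals["relatedness_cross"],
                   relatedness_within=vals["relatedness_within"],
                   generalizability_pct=vals["generalizability_pct"],
                   diversity_pct=vals["diversity_pct"],
                   warnings=warns)


def _check_shared_variants(a: GenotypeMatrix, b: GenotypeMatrix) -> None:
    if a.n_variants != b.n_variants:
        raise ValueError("datasets must share the variant set")
    if not (a.variants["pos"].to_numpy() == b.variants["pos"].to_numpy()).all():
        raise ValueError("variant positions differ between datasets")


def maf_divergence(ref: GenotypeMatrix, syn: GenotypeMatrix) -> float:
    """Mean absolute per-SNP MAF difference between two datasets."""
    from .phenotype_sim import compute_maf

    _check_shared_variants(ref, syn)
    return float(np.abs(compute_maf(ref) - compute_maf(syn)).mean())


def ld_decay(genotypes: GenotypeMatrix, gmap: GeneticMap | None = None,
             bins: np.ndarray | None = None, maf_min: float = 0.001) -> tuple:
    """Mean r^2 per pairwise-distance bin (the LD decay curve).

    SNPs with MAF < ``maf_min`` are excluded. Distances are in cM when a map
    is supplied, otherwise Mb. Default bins: 50 equal-width bins over [0, 1].
    Returns (bin_edges, curve) with NaN for bins containing no pair.
    """
    from .phenotype_sim import compute_maf

    if bins is None:
        bins = np.linspace(0.0, 1.0, 51)
    bins = np.asarray(bins, dtype=float)
    maf = compute_maf(genotypes)
    keep = maf >= maf_min
    if keep.sum() < 2:
        raise ValueError("fewer than 2 SNPs pass the MAF filter")
    X = genotypes.dosages[:, keep].astype(float)
    variants = genotypes.variants.reset_index(drop=True)[keep.tolist()]
    n = X.shape[0]
    Z = X - X.mean(axis=0)
    sd = X.std(axis=0)
    Z = Z / sd
    max_d = bins[-1]
    sums = np.zeros(len(bins) - 1)
    counts = np.zeros(len(bins) - 1, dtype=np.int64)
    col = 0
    for chrom, grp in variants.groupby("chrom", sort=False):
        m = len(grp)
        pos = grp["pos"].to_numpy(float)
        coord = (interpolate_cm(gmap, chrom, pos) if gmap is not None
                 else pos / 1e6)
        Zc = Z[:, col:col + m]
        for a in range(m):
            hi = np.searchsorted(coord, coord[a] + max_d, side="right")
            if hi <= a + 1:
                continue
            r = Zc[:, a + 1:hi].T @ Zc[:, a] / n
            d = coord[a + 1:hi] - coord[a]
            which = np.digitize(d, bins) - 1
            ok = (which >= 0) & (which < len(sums))
            np.add.at(sums, which[ok], r[ok] ** 2)
            np.add.at(counts, which[ok], 1)
        col += m
    with np.errstate(invalid="ignore"):
        curve = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return bins, curve


def ld_divergence(curve_ref: np.ndarray, curve_syn: np.ndarray) -> float:
    """Euclidean distance between two LD decay curves over bins non-missing
    in both."""
    a = np.asarray(curve_ref, dtype=float)
    b = np.asarray(curve_syn, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must share the bin grid")
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.any():
        raise ValueError("no bins populated in both curves")
    return float(np.sqrt(np.sum((a[ok] - b[ok]) ** 2)))


def _pca_loadings(X: np.ndarray, n_pcs: int) -> np.ndarray:
    """Variant-loading vectors of the first n PCs of standardized dosages."""
    from sklearn.decomposition import PCA

    Z = X - X.mean(axis=0)
    sd = X.std(axis=0)
    Z = np.where(sd > 0, Z / np.where(sd > 0, sd, 1.0), 0.0)
    p = PCA(n_components=n_pcs, svd_solver="full").fit(Z)
    return p.components_  # (n_pcs, K)


def pc_alignment(ref: GenotypeMatrix, syn: GenotypeMatrix, n_pcs: int = 20) -> float:
    """Mean |cosine similarity| between corresponding PC loading vectors.

    PCs are computed independently on each dataset over the shared variant
    set; the absolute value absorbs the sign indeterminacy of eigenvectors.
    Returns a score in [0, 1]; identical datasets score 1.
    """
    _check_shared_variants(ref, syn)
    if min(ref.n_samples, syn.n_samples) <= n_pcs:
        raise ValueError(f"need more than {n_pcs} samples in both datasets")
    L_ref = _pca_loadings(ref.dosages.astype(float), n_pcs)
    L_syn = _pca_loadings(syn.dosages.astype(float), n_pcs)
    num = np.abs(np.sum(L_ref * L_syn, axis=1))
    den = np.linalg.norm(L_ref, axis=1) * np.linalg.norm(L_syn, axis=1)
    return float(np.mean(num / den))


def kinship(gi: np.ndarray, gj: np.ndarray) -> float:
    """KING-robust between-family kinship estimate for one pair.

    phi = (N_Aa,Aa - 2*N_AA,aa) / (N_Aa,i + N_Aa,j); 0.5 for duplicates/MZ,
    ~0.25 first degree, ~0.125 second degree, ~0 unrelated (can go negative
    for ancestry-discordant pairs).
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    het_i = gi == 1
    het_j = gj == 1
    n_het = int(het_i.sum() + het_j.sum())
    if n_het == 0:
        raise ValueError("kinship undefined: no heterozygous site in either sample")
    n_both_het = int((het_i & het_j).sum())
    n_opp = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())
    return (n_both_het - 2.0 * n_opp) / n_het


def kinship_matrix(A: GenotypeMatrix, B: GenotypeMatrix) -> np.ndarray:
    """All-pairs KING-robust kinship between rows of A and rows of B."""
    _check_shared_variants(A, B)
    ha = (A.dosages == 1)
    hb = (B.dosages == 1)
    both_het = ha.astype(np.float64) @ hb.T.astype(np.float64)
    a0 = (A.dosages == 0).astype(np.float64)
    a2 = (A.dosages == 2).astype(np.float64)
    b0 = (B.dosages == 0).astype(np.float64)
    b2 = (B.dosages == 2).astype(np.float64)
    opp = a0 @ b2.T + a2 @ b0.T
    het_sum = ha.sum(axis=1)[:, None] + hb.sum(axis=1)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (both_het - 2.0 * opp) / het_sum
    return phi


def relatedness_counts(A: GenotypeMatrix, B: GenotypeMatrix | None = None,
                       thresholds: tuple = KINSHIP_THRESHOLDS) -> tuple:
    """Count (duplicate/MZ, first-degree, second-degree) pairs by kinship.

    With ``B`` given, every cross pair (a, b) is classified; with ``B`` None,
    unordered within-A pairs are classified.
    """
    dup_t, first_t, second_t = thresholds
    if B is None:
        phi = kinship_matrix(A, A)
        iu = np.triu_indices(A.n_samples, k=1)
        phi = phi[iu]
    else:
        phi = kinship_matrix(A, B).ravel()
    phi = phi[~np.isnan(phi)]
    n_dup = int((phi > dup_t).sum())
    n_first = int(((phi > first_t) & (phi <= dup_t)).sum())
    n_second = int(((phi > second_t) & (phi <= first_t)).sum())
    return n_dup, n_first, n_second


def generalizability_pct(n_cross: int, n_syn: int, n_ref: int) -> float:
    """(1 - Ncross / (Nsyn * Nref)) * 100 — absence of close relatives
    between the synthetic and reference datasets."""
    if n_cross < 0 or n_syn < 0 or n_ref < 0:
        raise ValueError("counts must be non-negative")
    if n_cross > n_syn * n_ref:
        raise ValueError("n_cross exceeds the number of cross pairs")
    return (1.0 - n_cross / (n_syn * n_ref)) * 100.0


def diversity_pct(n_pairs_ordered: int, n_syn: int) -> float:
    """(1 - Npairs / (Nsyn^2 - Nsyn)) * 100 — absence of close relatives
    within the synthetic cohort.

    ``n_pairs_ordered`` counts ORDERED pairs (double an unordered count) to
    match the Nsyn^2 - Nsyn denominator.
    """
    if n_syn < 2:
        raise ValueError("diversity requires at least 2 synthetic samples")
    if n_pairs_ordered < 0:
        raise ValueError("counts must be non-negative")
    return (1.0 - n_pairs_ordered / (n_syn**2 - n_syn)) * 100.0


def adversarial_accuracy(ref: GenotypeMatrix, syn: GenotypeMatrix) -> float:
    """Nearest-neighbour adversarial accuracy, in [0, 1].

    AA = 1/2 [ (1/Nr) sum_x 1{d(x, nearest syn) > d(x, nearest other real)}
             + (1/Ns) sum_y 1{d(y, nearest real) > d(y, nearest other syn)} ]

    with d the mean absolute dosage difference and self excluded from the
    within-set nearest neighbour. 0.5 means the 1-NN discriminator is at
    chance (indistinguishable sets); 0 means every sample's closest
    neighbour is in the other set (e.g. exact copies).
    """
    from scipy.spatial.distance import cdist

    _check_shared_variants(ref, syn)
    if ref.n_samples < 2 or syn.n_samples < 2:
        raise ValueError("need at least 2 samples in each dataset")
    k = ref.n_variants
    Xr = ref.dosages.astype(np.float32)
    Xs = syn.dosages.astype(np.float32)
    d_cross = cdist(Xr, Xs, metric="cityblock") / k
    d_rr = cdist(Xr, Xr, metric="cityblock") / k
    d_ss = cdist(Xs, Xs, metric="cityblock") / k
    np.fill_diagonal(d_rr, np.inf)
    np.fill_diagonal(d_ss, np.inf)
    tpr = float(np.mean(d_cross.min(axis=1) > d_rr.min(axis=1)))
    tnr = float(np.mean(d_cross.min(axis=0) > d_ss.min(axis=1)))
    return 0.5 * (tpr + tnr)


def build_report(ref: GenotypeMatrix, syn: GenotypeMatrix,
                 gmap: GeneticMap | None = None,
                 bins: np.ndarray | None = None, n_pcs: int = 20,
                 maf_min: float = 0.001, out_path=None) -> EvalReport:
    """Run the full metric suite and optionally serialize the report.

    Without a genetic map, LD decay falls back to bp-distance (Mb) bins and
    the report records a warning.
    """
    warnings = []
    if gmap is None:
        warnings.append("no genetic map supplied; LD decay binned on Mb distances")
    b, curve_ref = ld_decay(ref, gmap, bins, maf_min)
    _, curve_syn = ld_decay(syn, gmap, bins, maf_min)
    cross = relatedness_counts(syn, ref)
    within = relatedness_counts(syn)
    n_close_cross = cross[0] + cross[1]
    n_close_within_ordered = 2 * (within[0] + within[1])
    report = EvalReport(
        maf_divergence=maf_divergence(ref, syn),
        ld_divergence=ld_divergence(curve_ref, curve_syn),
        pc_alignment=pc_alignment(ref, syn, n_pcs),
        adversarial_accuracy=adversarial_accuracy(ref, syn),
        relatedness_cross=cross,
        relatedness_within=within,
        generalizability_pct=generalizability_pct(
            n_close_cross, syn.n_samples, ref.n_samples),
        diversity_pct=diversity_pct(n_close_within_ordered, syn.n_samples),
        ld_bins=b, ld_curve_ref=curve_ref, ld_curve_syn=curve_syn,
        warnings=warnings,
    )
    if out_path is not None:
        report.to_file(out_path)
        _write_ld_table(str(out_path) + ".ld.tsv", b, curve_ref, curve_syn)
    return report


def _write_ld_table(path, bins, curve_ref, curve_syn) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\tmean_r2_ref\tmean_r2_syn\n")
        for i in range(len(curve_ref)):
            fh.write(f"{bins[i]:.6g}\t{bins[i + 1]:.6g}\t"
                     f"{curve_ref[i]:.8g}\t{curve_syn[i]:.8g}\n")
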