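"""Reading and writing of haplotype panels, genetic maps, mutation ages and genotypes.

Supported on-disk formats
-------------------------
* phased VCF (panel input; read via cyvcf2) and plain unphased VCF (synthetic output)
* HAP/LEGEND/SAMPLE triplet (Oxford-style phased haplotypes)
* PLINK1 ``.bed/.bim/.fam`` (bit-exact v1 byte layout, variant-major)
* tab-separated genetic map (chrom, bp, cM)
* tab-separated mutation-age table (chrom, bp, ref, alt, age)
* tab-separated ancestry table (sample id, ancestry label)

Coordinate conventions: bp positions are 1-based (VCF/BIM convention), all
internal variant indices are 0-based, and segment intervals are half-open
in cM. Genetic-map lookups outside the knot span clamp to the terminal
knot's cM (constant extrapolation), so chromosome ends never produce
negative or runaway genetic positions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReferencePanel",
    "GeneticMap",
    "MutationAges",
    "GenotypeMatrix",
    "load_panel",
    "get_haplotype_slice",
    "interpolate_cm",
    "write_genotypes",
    "read_genotypes",
    "write_panel",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


@dataclass
class ReferencePanel:
    """A phased reference haplotype panel.

    Attributes
    ----------
    haplotypes : ndarray of uint8, shape (H, K)
        Allele matrix, 0 = reference allele, 1 = alternate allele.
        H = 2 x number of samples; haplotype ``2*i + phase`` belongs to
        sample ``i``.
    variants : DataFrame with columns chrom, pos, ref, alt
        Per-variant records; ``pos`` is the 1-based bp position, strictly
        increasing within each chromosome.
    samples : DataFrame with columns sample_id, ancestry
        Per-individual records. Ancestry labels are free strings declared
        by the user (a continental set such as AFR/AMR/EAS/EUR/CSA/MID is
        a convention, not a constraint).
    """

    haplotypes: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2D (H x K) array")
        h, k = self.haplotypes.shape
        if h != 2 * len(self.samples):
            raise ValueError(
                f"haplotype count {h} != 2 x sample count {len(self.samples)}"
            )
        if k != len(self.variants):
            raise ValueError(f"variant count {len(self.variants)} != matrix width {k}")
        bad = ~np.isin(self.haplotypes, (0, 1))
        if bad.any():
            raise ValueError("panel alleles must all be 0 or 1")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"bp positions not strictly increasing on {chrom}")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def hap_to_sample(self, hap_index: int) -> tuple[int, int]:
        """Map a haplotype index to (sample index, phase in {0, 1})."""
        return hap_index // 2, hap_index % 2

    def ancestry_groups(self) -> list[str]:
        return list(dict.fromkeys(self.samples["ancestry"]))

    def group_haplotypes(self, label: str) -> np.ndarray:
        """Indices of the haplotypes carried by samples with ancestry ``label``."""
        samp = np.flatnonzero((self.samples["ancestry"] == label).to_numpy())
        if samp.size == 0:
            raise ValueError(f"no samples with ancestry label {label!r}")
        return np.ravel(np.column_stack([2 * samp, 2 * samp + 1]))

    def variant_index(self, chrom) -> np.ndarray:
        """0-based column indices of the variants on ``chrom``."""
        return np.flatnonzero((self.variants["chrom"].astype(str) == str(chrom)).to_numpy())

    def as_genotypes(self) -> "GenotypeMatrix":
        """Collapse the phased panel to diploid dosages (h1 + h2 per sample)."""
        dos = (
            self.haplotypes[0::2].astype(np.uint8) + self.haplotypes[1::2]
        )
        return GenotypeMatrix(
            dosages=dos,
            sample_ids=list(self.samples["sample_id"]),
            variants=self.variants.reset_index(drop=True),
        )


@dataclass
class GeneticMap:
    """Piecewise-linear bp <-> cM map, one knot table per chromosome.

    ``knots[chrom] = (bp array, cM array)``, both strictly/weakly increasing;
    at least two knots per chromosome.
    """

    knots: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for chrom, (bp, cm) in self.knots.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size < 2:
                raise ValueError(f"genetic map for {chrom} needs >= 2 knots")
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"map bp positions must strictly increase on {chrom}")
            if not np.all(np.diff(cm) >= 0):
                raise ValueError(f"map cM must be non-decreasing on {chrom}")
            clean[str(chrom)] = (bp, cm)
        self.knots = clean

    def chromosomes(self) -> list[str]:
        return list(self.knots)

    def span_cm(self, chrom) -> tuple[float, float]:
        bp, cm = self.knots[str(chrom)]
        return float(cm[0]), float(cm[-1])

    @classmethod
    def from_table(cls, path) -> "GeneticMap":
        tab = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                          names=["chrom", "bp", "cm"])
        knots = {
            str(chrom): (grp["bp"].to_numpy(float), grp["cm"].to_numpy(float))
            for chrom, grp in tab.groupby("chrom", sort=False)
        }
        return cls(knots)

    def to_table(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, (bp, cm) in self.knots.items():
                for b, c in zip(bp, cm):
                    fh.write(f"{chrom}\t{int(b)}\t{c:.8g}\n")


def interpolate_cm(gmap: GeneticMap, chrom, bp) -> np.ndarray | float:
    """Convert bp position(s) to cM by piecewise-linear interpolation.

    Exact at knots, monotone non-decreasing in bp, constant beyond the
    terminal knots (clamped extrapolation).
    """
    kb, kc = gmap.knots[str(chrom)]
    out = np.interp(np.asarray(bp, dtype=float), kb, kc)
    return float(out) if np.isscalar(bp) else out


@dataclass
class MutationAges:
    """Per-variant mutation ages on the same time scale as coalescence ages T.

    Missing ages are stored as ``+inf``: a variant with no dating evidence is
    always copied, making the age filter strictly opt-in per variant.
    """

    ages: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        finite = self.ages[np.isfinite(self.ages)]
        if (finite < 0).any():
            raise ValueError("mutation ages must be >= 0")

    @classmethod
    def all_missing(cls, n_variants: int) -> "MutationAges":
        return cls(np.full(n_variants, np.inf))

    @classmethod
    def from_table(cls, path, variants: pd.DataFrame, age_scale: float = 1.0) -> "MutationAges":
        """Load a (chrom, bp, ref, alt, age) table aligned to ``variants``.

        ``age_scale`` is a single scalar multiplying every age at load time,
        the contract that puts published mutation ages on the same time
        scale as the simulator's Gamma-distributed coalescence ages.
        Variants absent from the table get +inf (always copied).
        """
        tab = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                          names=["chrom", "pos", "ref", "alt", "age"])
        key = pd.MultiIndex.from_frame(
            tab[["chrom", "pos", "ref", "alt"]].astype({"chrom": str})
        )
        lut = pd.Series(tab["age"].to_numpy(float), index=key)
        want = pd.MultiIndex.from_frame(
            variants[["chrom", "pos", "ref", "alt"]].astype({"chrom": str})
        )
        ages = lut.reindex(want).to_numpy(float)
        ages = np.where(np.isnan(ages), np.inf, ages * age_scale)
        return cls(ages)

    def to_table(self, path, variants: pd.DataFrame) -> None:
        with open(path, "w") as fh:
            for (_, v), age in zip(variants.iterrows(), self.ages):
                if np.isfinite(age):
                    fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{age:.8g}\n")


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix: N samples x K variants, entries in {0, 1, 2}."""

    dosages: np.ndarray
    sample_ids: list
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.ascontiguousarray(self.dosages, dtype=np.uint8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2D (N x K)")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("sample id count does not match dosage rows")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant count does not match dosage columns")
        if self.dosages.size and self.dosages.max() > 2:
            raise ValueError("dosages must be in {0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


# ---------------------------------------------------------------------------
# panel loading


def load_panel(path, format: str = "vcf", ancestry_table=None) -> ReferencePanel:
    """Load a phased reference panel from disk.

    Parameters
    ----------
    path
        VCF path, or the common prefix of a ``.hap/.legend/.sample`` triplet.
    format
        ``"vcf"`` or ``"hap-legend-sample"``.
    ancestry_table
        Optional path to a two-column (sample id, ancestry label) table;
        without it every sample is labelled ``"ALL"``.

    Unphased or multiallelic records are rejected with an error naming the
    offending record — never silently coerced.
    """
    if format == "vcf":
        panel = _load_panel_vcf(path)
    elif format == "hap-legend-sample":
        panel = _load_panel_hls(path)
    else:
        raise ValueError(f"unknown panel format {format!r}")
    if ancestry_table is not None:
        tab = pd.read_csv(ancestry_table, sep=r"\s+", header=None,
                          names=["sample_id", "ancestry"], dtype=str)
        lut = dict(zip(tab["sample_id"], tab["ancestry"]))
        missing = set(lut) - set(panel.samples["sample_id"])
        if missing:
            raise ValueError(
                f"ancestry table lists samples absent from the panel: {sorted(missing)}"
            )
        panel.samples["ancestry"] = [
            lut.get(s, "ALL") for s in panel.samples["sample_id"]
        ]
    return panel


def _load_panel_vcf(path) -> ReferencePanel:
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    hap_cols: list[np.ndarray] = []
    records = []
    seen = set()
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {var.CHROM}:{var.POS} not supported"
            )
        key = (var.CHROM, var.POS)
        if key in seen:
            raise ValueError(f"duplicate variant position {var.CHROM}:{var.POS}")
        seen.add(key)
        gts = np.asarray(var.genotype.array())  # (N, 3): a0, a1, phased flag
        if not np.all(gts[:, 2] == 1):
            bad = sample_ids[int(np.flatnonzero(gts[:, 2] != 1)[0])]
            raise ValueError(
                f"unphased genotype at {var.CHROM}:{var.POS} (sample {bad}); "
                "panel input requires phased GT"
            )
        alleles = gts[:, :2]
        if alleles.min() < 0 or alleles.max() > 1:
            raise ValueError(f"missing or non-biallelic allele at {var.CHROM}:{var.POS}")
        hap_cols.append(alleles.reshape(-1).astype(np.uint8))
        records.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    if not records:
        raise ValueError(f"no variants in {path}")
    haplotypes = np.column_stack(hap_cols)
    variants = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt"])
    samples = pd.DataFrame({"sample_id": sample_ids, "ancestry": "ALL"})
    return ReferencePanel(haplotypes, variants, samples)


def _load_panel_hls(prefix) -> ReferencePanel:
    prefix = str(prefix)
    for ext in (".hap", ".legend", ".sample"):
        if not os.path.exists(prefix + ext):
            raise FileNotFoundError(prefix + ext)
    legend = pd.read_csv(prefix + ".legend", sep=r"\s+")
    # legend columns: id position a0 a1 (optionally chrom)
    chrom = legend["chrom"].astype(str) if "chrom" in legend else pd.Series(
        ["1"] * len(legend)
    )
    variants = pd.DataFrame({
        "chrom": chrom,
        "pos": legend["position"].astype(int),
        "ref": legend["a0"],
        "alt": legend["a1"],
    })
    hap = np.loadtxt(prefix + ".hap", dtype=np.uint8)
    hap = np.atleast_2d(hap)
    if hap.shape[0] != len(variants):
        raise ValueError(".hap row count does not match .legend")
    samp = pd.read_csv(prefix + ".sample", sep=r"\s+")
    ids = samp.iloc[:, 0].astype(str).tolist()
    if hap.shape[1] != 2 * len(ids):
        raise ValueError(".hap column count != 2 x .sample rows")
    samples = pd.DataFrame({"sample_id": ids, "ancestry": "ALL"})
    return ReferencePanel(hap.T, variants, samples)


def write_panel(panel: ReferencePanel, prefix, format: str = "hap-legend-sample",
                ancestry_table: bool = True) -> None:
    """Write a phased panel to disk (HAP/LEGEND/SAMPLE or phased VCF)."""
    prefix = str(prefix)
    if format == "hap-legend-sample":
        np.savetxt(prefix + ".hap", panel.haplotypes.T, fmt="%d")
        with open(prefix + ".legend", "w") as fh:
            fh.write("id position a0 a1 chrom\n")
            for i, v in panel.variants.iterrows():
                fh.write(f"snp{i} {v.pos} {v.ref} {v.alt} {v.chrom}\n")
        with open(prefix + ".sample", "w") as fh:
            fh.write("sample\n")
            for s in panel.samples["sample_id"]:
                fh.write(f"{s}\n")
    elif format == "vcf":
        _write_vcf(prefix if prefix.endswith(".vcf") else prefix + ".vcf",
                   panel.variants, list(panel.samples["sample_id"]),
                   haplotypes=panel.haplotypes)
    else:
        raise ValueError(f"unknown panel format {format!r}")
    if ancestry_table:
        base = prefix[:-4] if prefix.endswith(".vcf") else prefix
        panel.samples.to_csv(base + ".ancestry.tsv", sep="\t", header=False,
                             index=False)


# ---------------------------------------------------------------------------
# random access


def get_haplotype_slice(panel: ReferencePanel, hap_index: int,
                        variant_range: tuple[int, int]) -> np.ndarray:
    """Alleles of one haplotype over a half-open variant-index interval.

    Cost is independent of panel width outside the requested range; repeated
    calls return identical values.
    """
    lo, hi = variant_range
    h, k = panel.haplotypes.shape
    if not 0 <= hap_index < h:
        raise IndexError(f"haplotype index {hap_index} out of range [0, {h})")
    if not (0 <= lo <= hi <= k):
        raise IndexError(f"variant range [{lo}, {hi}) outside [0, {k})")
    return panel.haplotypes[hap_index, lo:hi].copy()


# ---------------------------------------------------------------------------
# genotype output / input


def write_genotypes(matrix: GenotypeMatrix, path, format: str = "plink-bed",
                    gmap: GeneticMap | None = None) -> None:
    """Write a dosage matrix to PLINK1 bed/bim/fam or unphased VCF.

    PLINK output follows the v1 binary spec exactly: magic bytes 0x6c 0x1b,
    mode byte 0x01 (variant-major), two bits per sample with A1 = the alt
    allele (00 hom-alt, 10 het, 11 hom-ref), rows padded to whole bytes.
    """
    path = str(path)
    if format == "plink-bed":
        base = path[:-4] if path.endswith(".bed") else path
        _write_bed(matrix, base, gmap)
    elif format == "vcf":
        if not path.endswith(".vcf"):
            path = path + ".vcf"
        _write_vcf(path, matrix.variants, list(matrix.sample_ids),
                   dosages=matrix.dosages)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def read_genotypes(path, format: str = "plink-bed") -> GenotypeMatrix:
    """Read dosages back from PLINK1 bed/bim/fam or a VCF."""
    path = str(path)
    if format == "plink-bed":
        base = path[:-4] if path.endswith(".bed") else path
        return _read_bed(base)
    if format == "vcf":
        return _read_vcf_genotypes(path)
    raise ValueError(f"unknown genotype format {format!r}")


# dosage (count of alt = A1) -> PLINK 2-bit code: 2 -> 00, 1 -> 10, 0 -> 11
_DOSAGE_TO_BED = np.array([3, 2, 0], dtype=np.uint8)
_BED_TO_DOSAGE = np.array([2, 255, 1, 0], dtype=np.uint8)  # 255 = missing, rejected


def _write_bed(matrix: GenotypeMatrix, base: str, gmap: GeneticMap | None) -> None:
    n, k = matrix.dosages.shape
    codes = _DOSAGE_TO_BED[matrix.dosages]  # (N, K)
    width = (n + 3) // 4
    with open(base + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        if n > 0:
            full = np.zeros((width * 4, k), dtype=np.uint8)
            full[:n] = codes
            # pack 4 samples per byte, sample 0 in the low bits
            by = (full[0::4] | (full[1::4] << 2) | (full[2::4] << 4)
                  | (full[3::4] << 6)).astype(np.uint8)  # (width, K)
            fh.write(by.T.tobytes())  # variant-major
    with open(base + ".bim", "w") as fh:
        for i, v in matrix.variants.reset_index(drop=True).iterrows():
            cm = interpolate_cm(gmap, v.chrom, v.pos) if gmap is not None else 0
            fh.write(f"{v.chrom}\tsnp{i}\t{cm:.8g}\t{v.pos}\t{v.alt}\t{v.ref}\n")
    with open(base + ".fam", "w") as fh:
        for s in matrix.sample_ids:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")


def _read_bed(base: str) -> GenotypeMatrix:
    bim = pd.read_csv(base + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "alt", "ref"],
                      dtype={"chrom": str})
    fam = pd.read_csv(base + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"iid": str})
    n, k = len(fam), len(bim)
    with open(base + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{base}.bed is not a variant-major PLINK1 file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    width = (n + 3) // 4
    if raw.size != width * k:
        raise ValueError(f"{base}.bed payload size mismatch")
    raw = raw.reshape(k, width)
    codes = np.empty((k, width * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (raw >> (2 * shift)) & 0b11
    dos = _BED_TO_DOSAGE[codes[:, :n]]
    if (dos == 255).any():
        raise ValueError("missing genotypes not supported")
    variants = bim[["chrom", "pos", "ref", "alt"]].copy()
    return GenotypeMatrix(dos.T, list(fam["iid"]), variants)


def _write_vcf(path: str, variants: pd.DataFrame, sample_ids: list,
               dosages: np.ndarray | None = None,
               haplotypes: np.ndarray | None = None) -> None:
    """Write a minimal VCF 4.2: phased GT from haplotypes, else unphased
    0/0, 0/1, 1/1 from dosages."""
    gt_unphased = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = list(dict.fromkeys(variants["chrom"].astype(str)))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in sample_ids) + "\n")
        for j, (_, v) in enumerate(variants.iterrows()):
            if haplotypes is not None:
                gts = [f"{haplotypes[2 * i, j]}|{haplotypes[2 * i + 1, j]}"
                       for i in range(len(sample_ids))]
            else:
                gts = [gt_unphased[int(d)] for d in dosages[:, j]]
            fh.write(f"{v.chrom}\t{v.pos}\tsnp{j}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def _read_vcf_genotypes(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    cols, records = [], []
    for var in vcf:
        gts = np.asarray(var.genotype.array())[:, :2]
        cols.append(gts.sum(axis=1).astype(np.uint8))
        records.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    variants = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(np.column_stack(cols), ids, variants)
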