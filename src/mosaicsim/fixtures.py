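"""Small synthetic reference panels with controllable LD-block structure.

The generator builds phased toy panels so every stage of the pipeline can be
exercised without downloading a real reference. The construction is a
founder-pool-with-noise scheme rather than a coalescent simulation: the
chromosome is divided into ``n_blocks`` contiguous blocks, each block gets a
small pool of founder haplotypes (allele frequencies Beta-distributed per
site), and every panel haplotype picks one founder per block and then flips
each site independently with a small probability. This yields strong
within-block LD, ~zero between-block LD, and is analytically checkable.
Distinct ancestry groups use independent founder pools, which makes them
separable in PCA space.

These panels are test scaffolding: they have block-uniform recombination,
no demographic history and exchangeable samples, so passing tests show
correctness of the machinery, not population-genetic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference_io import GeneticMap, MutationAges, ReferencePanel

__all__ = ["FixtureSpec", "generate_panel", "write_fixture"]


@dataclass
class FixtureSpec:
    """Recipe for a toy phased panel.

    n_hap : dict ancestry-label -> haplotype count (or int for one group "POP")
    n_snp, n_blocks : panel width and number of LD blocks
    within_block_pool : founder haplotypes per block (smaller = stronger LD)
    mutation_noise : per-site flip probability in [0, 0.5)
    freq_beta : (alpha, beta) of the founder allele-frequency distribution
    map_rate : cM per Mb (uniform map)
    snp_spacing_bp : distance between adjacent SNPs
    age_mean : mean of the i.i.d. exponential mutation-age distribution,
        on the same time scale as coalescence ages T
    """

    n_hap: int | dict = 200
    n_snp: int = 2000
    n_blocks: int = 20
    within_block_pool: int = 4
    mutation_noise: float = 0.01
    freq_beta: tuple = (0.8, 0.8)
    map_rate: float = 1.0
    snp_spacing_bp: int = 10_000
    age_mean: float = 20.0
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_hap, int):
            self.n_hap = {"POP": self.n_hap}
        if not (self.n_snp >= self.n_blocks >= 1):
            raise ValueError("need n_snp >= n_blocks >= 1")
        if not (0 <= self.mutation_noise < 0.5):
            raise ValueError("mutation_noise must be in [0, 0.5)")
        if self.within_block_pool < 1 or any(h < 2 for h in self.n_hap.values()):
            raise ValueError("counts must be >= 1 (and >= 2 haplotypes per group)")
        if any(h % 2 for h in self.n_hap.values()):
            raise ValueError("haplotype counts must be even (phased pairs)")


def generate_panel(spec: FixtureSpec,
                   rng: np.random.Generator | None = None
                   ) -> tuple[ReferencePanel, GeneticMap, MutationAges]:
    """Generate (panel, genetic map, mutation ages) from a fixture recipe."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    block_of = np.minimum(
        np.arange(spec.n_snp) * spec.n_blocks // spec.n_snp, spec.n_blocks - 1
    )
    hap_rows, sample_rows = [], []
    sample_counter = 0
    for label, n_hap in spec.n_hap.items():
        # independent founder pools per group -> separable PCA structure
        freqs = rng.beta(*spec.freq_beta, size=spec.n_snp)
        founders = (
            rng.random((spec.n_blocks, spec.within_block_pool, spec.n_snp)) < freqs
        ).astype(np.uint8)
        choice = rng.integers(spec.within_block_pool, size=(n_hap, spec.n_blocks))
        haps = founders[block_of, choice[:, block_of], np.arange(spec.n_snp)]
        flips = rng.random((n_hap, spec.n_snp)) < spec.mutation_noise
        haps = haps ^ flips.astype(np.uint8)
        hap_rows.append(haps)
        for _ in range(n_hap // 2):
            sample_rows.append((f"{label}_s{sample_counter}", label))
            sample_counter += 1
    haplotypes = np.vstack(hap_rows)

    pos = (np.arange(spec.n_snp) + 1) * spec.snp_spacing_bp
    variants = pd.DataFrame({
        "chrom": spec.chrom, "pos": pos, "ref": "A", "alt": "G",
    })
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "ancestry"])
    panel = ReferencePanel(haplotypes, variants, samples)

    knot_bp = np.array([1.0, float(pos[-1] + spec.snp_spacing_bp)])
    knot_cm = (knot_bp - 1.0) * spec.map_rate / 1e6
    gmap = GeneticMap({spec.chrom: (knot_bp, knot_cm)})

    ages = MutationAges(rng.exponential(spec.age_mean, size=spec.n_snp))
    return panel, gmap, ages


def write_fixture(spec: FixtureSpec, out_dir, prefix: str = "fixture",
                  panel_format: str = "vcf") -> dict:
    """Generate a fixture and write it through the standard on-disk formats.

    Returns a dict of the written paths (panel, map, ages, ancestry table).
    """
    import os

    from .reference_io import write_panel

    panel, gmap, ages = generate_panel(spec)
    os.makedirs(out_dir, exist_ok=True)
    base = os.path.join(str(out_dir), prefix)
    write_panel(panel, base + (".vcf" if panel_format == "vcf" else ""),
                format=panel_format)
    gmap.to_table(base + ".map.tsv")
    ages.to_table(base + ".ages.tsv", panel.variants)
    paths = {
        "panel": base + (".vcf" if panel_format == "vcf" else ""),
        "map": base + ".map.tsv",
        "ages": base + ".ages.tsv",
        "ancestry": base + ".ancestry.tsv",
    }
    return paths
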