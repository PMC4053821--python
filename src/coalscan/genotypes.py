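"""Biallelic genotype matrices over a taxon panel.

The substrate for D statistics and divergence scans: per-site 0/1
(ancestral/derived relative to the simulated root, or REF/ALT for
imported data) states for every taxon, with genomic coordinates and an
optional window/block index.  Haploid matrices have ploidy 1; diploid
matrices carry both alleles of each individual.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]

MISSING = -1


class GenotypeMatrix:
    """Sites x taxa x ploidy array of biallelic allele states.

    ``geno`` holds 0 (ancestral/REF), 1 (derived/ALT) or -1 (missing);
    ``pos`` is 0-based internally (1-based in VCF/pileup I/O); ``window``
    maps each site to a simulation window / jackknife block (-1 when
    unknown).
    """

    def __init__(
        self,
        taxa: Sequence[str],
        chrom: np.ndarray,
        pos: np.ndarray,
        geno: np.ndarray,
        window: Optional[np.ndarray] = None,
    ):
        self.taxa = tuple(taxa)
        self.chrom = np.asarray(chrom)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.geno = np.asarray(geno, dtype=np.int8)
        if self.geno.ndim == 2:
            self.geno = self.geno[:, :, None]
        n = len(self.pos)
        if self.geno.shape[:2] != (n, len(self.taxa)):
            raise ValueError("geno shape must be (n_sites, n_taxa[, ploidy])")
        self.window = (
            np.asarray(window, dtype=np.int32)
            if window is not None
            else np.full(n, -1, dtype=np.int32)
        )

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def ploidy(self) -> int:
        return self.geno.shape[2]

    def taxon_index(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise KeyError(f"unknown taxon {label!r}") from None

    # -- transforms --------------------------------------------------------
    def pseudo_haploid(self, seed: int) -> "GenotypeMatrix":
        """One allele sampled per genotype with a seeded RNG.

        Homozygous and haploid calls are unchanged; heterozygotes resolve
        to a random one of their two alleles.  Deterministic given seed.
        """
        if self.ploidy == 1:
            return self
        rng = np.random.default_rng(seed)
        pick = rng.integers(0, self.ploidy, size=self.geno.shape[:2])
        out = np.take_along_axis(self.geno, pick[:, :, None], axis=2)[:, :, 0]
        # a genotype with any missing allele is missing entirely
        out[np.any(self.geno == MISSING, axis=2)] = MISSING
        return GenotypeMatrix(self.taxa, self.chrom, self.pos, out, self.window)

    def derived_fraction(self) -> np.ndarray:
        """Per-site, per-taxon derived allele fraction in [0,1]; NaN missing."""
        if self.ploidy == 1:
            g = self.geno[:, :, 0].astype(np.float64)
            g[self.geno[:, :, 0] == MISSING] = np.nan
            return g
        g = self.geno.astype(np.float64)
        g[self.geno == MISSING] = np.nan
        return g.mean(axis=2)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        cols = {"chrom": self.chrom, "pos": self.pos + 1, "window": self.window}
        for j, tx in enumerate(self.taxa):
            if self.ploidy == 1:
                vals = np.where(self.geno[:, j, 0] == MISSING, ".",
                                self.geno[:, j, 0].astype(str))
            else:
                a = self.geno[:, j, 0].astype(object)
                b = self.geno[:, j, 1].astype(object)
                vals = np.array(
                    ["." if MISSING in (x, y) else f"{x}/{y}" for x, y in zip(a, b)],
                    dtype=object,
                )
            cols[tx] = vals
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        taxa = [c for c in df.columns if c not in ("chrom", "pos", "window")]
        first = str(df[taxa[0]].iloc[0]) if len(df) else "0"
        ploidy = 2 if "/" in first else 1
        geno = np.full((len(df), len(taxa), ploidy), MISSING, dtype=np.int8)
        for j, tx in enumerate(taxa):
            for i, v in enumerate(df[tx].astype(str)):
                if v == ".":
                    continue
                if ploidy == 1:
                    geno[i, j, 0] = int(v)
                else:
                    a, b = v.split("/")
                    geno[i, j, 0] = int(a)
                    geno[i, j, 1] = int(b)
        window = df["window"].to_numpy() if "window" in df else None
        return cls(taxa, df["chrom"].to_numpy(), df["pos"].to_numpy() - 1, geno, window)

    def to_vcf(self, path, ref: str = "A", alt: str = "T") -> None:
        """Minimal biallelic-SNP VCF (GT only).  The simulated 0/1 states
        are written as placeholder REF/ALT bases."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for c in pd.unique(self.chrom):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.taxa) + "\n")
            sep = "/"
            for i in range(self.n_sites):
                gts = []
                for j in range(len(self.taxa)):
                    alleles = self.geno[i, j]
                    gts.append(sep.join("." if a == MISSING else str(a) for a in alleles))
                fh.write(
                    f"{self.chrom[i]}\t{self.pos[i] + 1}\t.\t{ref}\t{alt}\t.\tPASS\t"
                    f"WIN={self.window[i]}\tGT\t" + "\t".join(gts) + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read biallelic SNPs from a VCF via cyvcf2; multi-allelic records
        are skipped (their count is available as ``.n_skipped``)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        taxa = list(vcf.samples)
        chrom, pos, rows, windows = [], [], [], []
        n_skipped = 0
        for var in vcf:
            if len(var.ALT) != 1 or not var.is_snp:
                n_skipped += 1
                continue
            g = np.array([gt[:2] for gt in var.genotypes], dtype=np.int8)
            g[g < 0] = MISSING
            rows.append(g)
            chrom.append(var.CHROM)
            pos.append(var.POS - 1)
            w = var.INFO.get("WIN")
            windows.append(int(w) if w is not None else -1)
        geno = np.stack(rows) if rows else np.zeros((0, len(taxa), 2), dtype=np.int8)
        out = cls(taxa, np.array(chrom), np.array(pos, dtype=np.int64), geno,
                  np.array(windows, dtype=np.int32))
        out.n_skipped = n_skipped
        return out
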