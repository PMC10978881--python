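"""Genotype container and plain-text genotype I/O (VCF and a TSV dosage dialect)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["snp", "chrom", "pos", "ref", "alt", "af", "info"]


@dataclass
class GenotypeSet:
    """Dosage matrix plus variant table for one cohort or reference panel.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_snps)`` array of alternate-allele dosages in
        ``{0, 1, 2}``; ``NaN`` marks a missing call.
    variants
        Table with columns ``snp, chrom, pos, ref, alt, af, info``. ``af`` is
        the alternate-allele frequency; ``info`` is an imputation-quality
        score (1.0 for directly simulated genotypes).
    samples
        Individual identifiers, aligned with the dosage rows.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns but "
                f"{len(self.variants)} variant rows"
            )
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("sample list does not match dosage rows")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        self.variants = self.variants.reset_index(drop=True)
        self._index = {s: i for i, s in enumerate(self.variants["snp"])}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self, snp: str) -> int:
        try:
            return self._index[snp]
        except KeyError:
            raise KeyError(f"SNP {snp!r} not in genotype set") from None

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def dosage(self, snp: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp)]

    def subset(self, indices: np.ndarray) -> "GenotypeSet":
        """New GenotypeSet restricted to the given variant indices (order kept)."""
        indices = np.asarray(indices, dtype=int)
        return GenotypeSet(
            dosages=self.dosages[:, indices].copy(),
            variants=self.variants.iloc[indices].reset_index(drop=True),
            samples=list(self.samples),
        )

    def realized_af(self) -> np.ndarray:
        """Alternate-allele frequency from the observed dosages (NaN-aware)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


def write_vcf(genos: GenotypeSet, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write hard-call genotypes as an uncompressed VCF (GT field only).

    Non-integer dosages are rounded to the nearest hard call; NaN becomes ``./.``.
    """
    path = Path(path)
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for line in header_lines or []:
            fh.write(f"##{line}\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genos.samples)
            + "\n"
        )
        dos = genos.dosages
        for j, row in genos.variants.iterrows():
            calls = []
            for d in dos[:, j]:
                if np.isnan(d):
                    calls.append("./.")
                else:
                    calls.append(gt_codes[int(round(d))])
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t{row.snp}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeSet:
    """Read GT-coded genotypes from an uncompressed VCF."""
    path = Path(path)
    samples: list[str] = []
    rows = []
    dosage_rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, pos, snp, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            dose = np.empty(len(samples))
            for k, call in enumerate(parts[9:]):
                gt = call.split(":")[gt_i].replace("|", "/")
                if "." in gt:
                    dose[k] = np.nan
                else:
                    a, b = gt.split("/")
                    dose[k] = int(a) + int(b)
            rows.append((snp, chrom, pos, ref, alt))
            dosage_rows.append(dose)
    dosages = np.array(dosage_rows).T if dosage_rows else np.empty((len(samples), 0))
    variants = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "ref", "alt"])
    with np.errstate(invalid="ignore"):
        variants["af"] = np.nanmean(dosages, axis=0) / 2.0 if len(rows) else []
    variants["info"] = 1.0
    return GenotypeSet(dosages=dosages, variants=variants, samples=samples)


def write_dosage_tsv(genos: GenotypeSet, path: str | Path) -> None:
    """TSV dosage dialect: variant columns then one dosage column per individual."""
    df = genos.variants[VARIANT_COLUMNS].copy()
    dos = pd.DataFrame(genos.dosages.T, columns=genos.samples)
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dosage_tsv(path: str | Path) -> GenotypeSet:
    df = pd.read_csv(path, sep="\t")
    samples = [c for c in df.columns if c not in VARIANT_COLUMNS]
    dosages = df[samples].to_numpy(dtype=float).T
    return GenotypeSet(
        dosages=dosages, variants=df[VARIANT_COLUMNS].copy(), samples=samples
    )
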