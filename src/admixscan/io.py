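"""Cohort container and file formats.

A :class:`CohortBundle` holds the four aligned tables the scan consumes:
genotype dosages (individuals x markers, values in [0, 2]), hard-called
local-ancestry diplotypes (two-letter categories), a marker map (chromosome,
1-based bp, cM) and a phenotype table (trait, covariates, global ancestry).
Readers validate alignment and reject malformed input rather than repairing
it; in particular missing dosages are disallowed (inputs are expected to be
imputed upstream).

On disk the bundle is a directory of TSV files (``dosages.tsv``,
``ancestry.tsv``, ``phenotypes.tsv``, ``markers.tsv``); genotypes may instead
come from a VCF with GT or DS fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ANCESTRY_FILE = "ancestry.tsv"
_DOSAGE_FILE = "dosages.tsv"
_PHENOTYPE_FILE = "phenotypes.tsv"
_MARKER_FILE = "markers.tsv"

#: p-values and statistics are written in scientific notation, 4 significant digits
P_FORMAT = "%.3e"


@dataclass
class CohortBundle:
    """Aligned genotype / local-ancestry / marker / phenotype tables.

    ``truth`` optionally records the generating model and seed for simulated
    cohorts; ``haplotypes`` optionally carries phase-resolved simulation
    truth (an ``(n, 2, n_markers)`` array of population indices).
    """

    genotypes: pd.DataFrame
    diplotypes: pd.DataFrame
    marker_map: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: dict | None = None
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def markers(self) -> pd.Index:
        return self.genotypes.columns

    def validate(self) -> None:
        if not self.genotypes.index.equals(self.diplotypes.index):
            raise ValueError("genotype and local-ancestry tables disagree on individual IDs")
        if not self.genotypes.columns.equals(self.diplotypes.columns):
            raise ValueError("genotype and local-ancestry tables disagree on marker IDs/order")
        if not self.genotypes.columns.equals(self.marker_map.index):
            raise ValueError("marker map disagrees with genotype marker IDs/order")
        if not self.genotypes.index.equals(self.phenotypes.index):
            raise ValueError("phenotype table disagrees with genotype individual IDs")
        vals = self.genotypes.to_numpy(dtype=float)
        if np.isnan(vals).any():
            i, j = np.argwhere(np.isnan(vals))[0]
            raise ValueError(
                f"missing dosage for individual {self.genotypes.index[i]!r} at "
                f"marker {self.genotypes.columns[j]!r}; inputs must be imputed upstream"
            )
        if (vals < 0).any() or (vals > 2).any():
            i, j = np.argwhere((vals < 0) | (vals > 2))[0]
            raise ValueError(
                f"dosage outside [0, 2] for individual {self.genotypes.index[i]!r} at "
                f"marker {self.genotypes.columns[j]!r}: {vals[i, j]!r}"
            )
        for col in ("chrom", "bp", "cm"):
            if col not in self.marker_map.columns:
                raise ValueError(f"marker map missing column {col!r}")
        for chrom, sub in self.marker_map.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy()
            if (bp < 1).any():
                raise ValueError(f"bp positions must be 1-based positive on chromosome {chrom}")
            if (np.diff(bp) <= 0).any():
                k = int(np.argwhere(np.diff(bp) <= 0)[0][0])
                raise ValueError(
                    f"bp positions not strictly increasing on chromosome {chrom} "
                    f"near marker {sub.index[k + 1]!r}"
                )
        from admixscan.ancestry import CATEGORIES

        dvals = self.diplotypes.to_numpy(dtype=object)
        bad = ~np.isin(dvals, CATEGORIES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid local-ancestry code {dvals[i, j]!r} for individual "
                f"{self.diplotypes.index[i]!r} at marker {self.diplotypes.columns[j]!r}"
            )

    def log_trait(self, trait: str = "trait") -> np.ndarray:
        """Natural log of a strictly positive trait column."""
        y = self.phenotypes[trait].to_numpy(dtype=float)
        if np.any(~np.isfinite(y)) or np.any(y <= 0):
            raise ValueError(f"trait {trait!r} must be strictly positive and finite")
        return np.log(y)


def write_cohort(bundle: CohortBundle, out_dir) -> Path:
    """Write a bundle as four TSV files; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.genotypes.to_csv(out / _DOSAGE_FILE, sep="\t", float_format="%.6g")
    bundle.diplotypes.to_csv(out / _ANCESTRY_FILE, sep="\t")
    bundle.phenotypes.to_csv(out / _PHENOTYPE_FILE, sep="\t", float_format="%.10g")
    bundle.marker_map.to_csv(out / _MARKER_FILE, sep="\t", float_format="%.10g")
    return out


def read_cohort(path, vcf: str | Path | None = None) -> CohortBundle:
    """Read a bundle from a directory of TSVs (optionally genotypes from a VCF).

    Individuals present in the genotype table but absent from the phenotype
    table are dropped with a logged count; the reverse is an error.
    """
    path = Path(path)
    diplotypes = _read_ancestry_tsv(path / _ANCESTRY_FILE)
    marker_map = pd.read_csv(path / _MARKER_FILE, sep="\t", index_col=0, dtype={"chrom": str})
    phenotypes = pd.read_csv(path / _PHENOTYPE_FILE, sep="\t", index_col=0)
    if vcf is not None:
        genotypes = read_vcf_dosages(vcf)
    else:
        genotypes = pd.read_csv(path / _DOSAGE_FILE, sep="\t", index_col=0)

    missing_pheno = genotypes.index.difference(phenotypes.index)
    if len(missing_pheno):
        logger.info(
            "dropping %d individual(s) without phenotype data", len(missing_pheno)
        )
        keep = genotypes.index.intersection(phenotypes.index)
        genotypes = genotypes.loc[keep]
        diplotypes = diplotypes.loc[keep]
    extra = phenotypes.index.difference(genotypes.index)
    if len(extra):
        raise ValueError(f"{len(extra)} phenotype row(s) without genotype data: {list(extra[:5])}")
    phenotypes = phenotypes.loc[genotypes.index]
    return CohortBundle(
        genotypes=genotypes,
        diplotypes=diplotypes.loc[genotypes.index, genotypes.columns],
        marker_map=marker_map.loc[genotypes.columns],
        phenotypes=phenotypes,
    )


def _read_ancestry_tsv(path) -> pd.DataFrame:
    from admixscan.ancestry import read_local_ancestry

    return read_local_ancestry(path)


def read_vcf_dosages(path) -> pd.DataFrame:
    """Minor-allele dosages from a VCF (DS format field if present, else GT counts).

    One ALT allele per record is required; records are returned in file order
    with IDs taken from the ID column (or ``chrom:pos`` when missing).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, cols = [], []
    for var in vcf:
        if var.ALT is None or len(var.ALT) != 1:
            raise ValueError(f"multi-allelic or ALT-less record at {var.CHROM}:{var.POS}")
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dosage = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.asarray(var.genotype.array())[:, :2]
            if (gt < 0).any():
                raise ValueError(f"missing genotype at {name}; inputs must be imputed upstream")
            dosage = gt.sum(axis=1).astype(float)
        ids.append(name)
        cols.append(dosage)
    vcf.close()
    return pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="individual"),
        columns=pd.Index(ids, name="marker"),
    )


def write_vcf(bundle: CohortBundle, path) -> Path:
    """Write genotype dosages as a minimal single-ALT VCF with a DS FORMAT field."""
    path = Path(path)
    inds = list(bundle.genotypes.index)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Minor allele dosage">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(inds),
    ]
    geno = bundle.genotypes.to_numpy(dtype=float)
    for j, marker in enumerate(bundle.markers):
        row = bundle.marker_map.loc[marker]
        fields = [
            str(row["chrom"]), str(int(row["bp"])), str(marker), "A", "G", ".", "PASS", ".", "DS",
        ] + [f"{geno[i, j]:.4g}" for i in range(len(inds))]
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def format_pvalues(frame: pd.DataFrame, columns) -> pd.DataFrame:
    """Render the named columns in fixed scientific notation for deterministic diffs."""
    out = frame.copy()
    for col in columns:
        out[col] = [P_FORMAT % v if np.isfinite(v) else "NA" for v in frame[col]]
    return out


__all__ = [
    "CohortBundle",
    "format_pvalues",
    "read_cohort",
    "read_vcf_dosages",
    "write_cohort",
    "write_vcf",
]
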