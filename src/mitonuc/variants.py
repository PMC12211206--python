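"""Genotype matrices and the hard-filter cascade for SNP calls.

The cascade mirrors a VCFtools-style iterative loci/individual filtering
strategy: a Phred site-quality cut, a lenient site filter (call rate and
minor allele count), removal of high-missingness individuals, per-genotype
depth masking, and a stringent site filter (call rate, minor allele
frequency, allele count).  Every stage is logged as a funnel record.

Dosages are stored as ``int8`` with :data:`MISSING` (= -1) for uncalled
genotypes.  Multi-allelic records are kept on input (dosage counted against
the first ALT) together with their allele count so the ``max-alleles``
filter can remove them later.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

MISSING: int = -1

MITOCHONDRIAL = "mitochondrial"
NUCLEAR = "nuclear"
UNASSIGNED = "unassigned"


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass
class VariantMatrix:
    """Loci x individuals dosage matrix with site and genotype annotations.

    Attributes
    ----------
    loci : pandas.DataFrame
        Columns ``contig``, ``pos`` (1-based), ``ref``, ``alt`` (first ALT),
        ``n_alleles`` (REF + ALTs).
    samples : list of str
    genotypes : int8 array, loci x individuals, values {0,1,2,MISSING}
    site_qual : float array per locus (Phred site quality)
    depth : int32 array, loci x individuals, read depth per genotype
    compartment : object array per locus in {mitochondrial, nuclear, unassigned}
    """

    loci: pd.DataFrame
    samples: list[str]
    genotypes: np.ndarray
    site_qual: np.ndarray
    depth: np.ndarray
    compartment: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n_loci = len(self.loci)
        n_ind = len(self.samples)
        if self.genotypes.shape != (n_loci, n_ind):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != ({n_loci}, {n_ind})"
            )
        if self.depth.shape != (n_loci, n_ind):
            raise ValueError("depth shape mismatch")
        if len(self.site_qual) != n_loci:
            raise ValueError("site_qual length mismatch")
        if self.compartment is None:
            self.compartment = np.full(n_loci, UNASSIGNED, dtype=object)
        if (self.loci["pos"] <= 0).any():
            raise ValueError("positions must be 1-based positive")
        allowed = {0, 1, 2, MISSING}
        vals = set(np.unique(self.genotypes).tolist())
        if not vals <= allowed:
            raise ValueError(f"dosages outside {allowed}: {vals - allowed}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    def take_loci(self, mask: np.ndarray) -> "VariantMatrix":
        """Subset loci by boolean mask, preserving order."""
        idx = np.flatnonzero(mask)
        return VariantMatrix(
            loci=self.loci.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            genotypes=self.genotypes[idx],
            site_qual=self.site_qual[idx],
            depth=self.depth[idx],
            compartment=self.compartment[idx],
        )

    def take_individuals(self, keep: Sequence[int]) -> "VariantMatrix":
        keep = list(keep)
        return VariantMatrix(
            loci=self.loci.reset_index(drop=True),
            samples=[self.samples[i] for i in keep],
            genotypes=self.genotypes[:, keep],
            site_qual=self.site_qual.copy(),
            depth=self.depth[:, keep],
            compartment=self.compartment.copy(),
        )

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING


@dataclass
class FilterParams:
    """Thresholds of the five-stage filter cascade (VCFtools semantics)."""

    min_qual: float = 30.0
    stage1_max_missing: float = 0.5
    mac_min: int = 3
    indiv_max_missing: float = 0.27
    stage2_max_missing: float = 0.95
    maf_min: float = 0.05
    min_dp: int = 10
    max_alleles: int = 2

    def __post_init__(self) -> None:
        for name in ("stage1_max_missing", "indiv_max_missing", "stage2_max_missing", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_qual < 0 or self.min_dp < 0 or self.mac_min < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class FilterStageRecord:
    stage: str
    loci_in: int
    loci_out: int
    individuals_in: int
    individuals_out: int


@dataclass
class FilterLog:
    """Ordered funnel of per-stage survivor counts."""

    stages: list[FilterStageRecord] = field(default_factory=list)

    def add(self, stage: str, loci_in: int, loci_out: int, ind_in: int, ind_out: int) -> None:
        if loci_out > loci_in or ind_out > ind_in:
            raise ValueError(f"stage {stage}: survivors exceed input")
        self.stages.append(FilterStageRecord(stage, loci_in, loci_out, ind_in, ind_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.stage, s.loci_in, s.loci_out, s.individuals_in, s.individuals_out) for s in self.stages],
            columns=["stage", "loci_in", "loci_out", "individuals_in", "individuals_out"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_frame().to_dict(orient="records"), indent=2)


# ---------------------------------------------------------------------------
# VCF I/O


def _dosage_from_gt(gt: tuple) -> int:
    """Dosage of the first ALT allele; MISSING if any allele uncalled."""
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return MISSING
    return sum(1 for a in gt if a == 1)


def read_vcf(path: str | Path) -> VariantMatrix:
    """Read an uncompressed or bgzipped VCF into a :class:`VariantMatrix`.

    QUAL is kept as the Phred site score (missing QUAL becomes 0), FORMAT/DP
    as per-genotype depth (missing DP becomes 0), and any genotype with an
    uncalled allele becomes :data:`MISSING`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    recs = []
    gts: list[list[int]] = []
    dps: list[list[int]] = []
    quals: list[float] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for i, rec in enumerate(vf.fetch() if path.suffix == ".gz" else vf):
            try:
                alts = rec.alts or ()
                recs.append(
                    (rec.chrom, rec.pos, rec.ref or "N", alts[0] if alts else ".", 1 + len(alts))
                )
                quals.append(float(rec.qual) if rec.qual is not None else 0.0)
                row_gt = []
                row_dp = []
                for s in samples:
                    sd = rec.samples[s]
                    row_gt.append(_dosage_from_gt(sd.get("GT")))
                    dp = sd.get("DP")
                    row_dp.append(int(dp) if dp is not None else 0)
                gts.append(row_gt)
                dps.append(row_dp)
            except (ValueError, KeyError, TypeError) as exc:  # pragma: no cover
                raise VcfParseError(f"record #{i + 1} at {rec.chrom}:{rec.pos}: {exc}") from exc
    loci = pd.DataFrame(recs, columns=["contig", "pos", "ref", "alt", "n_alleles"])
    n, m = len(loci), len(samples)
    return VariantMatrix(
        loci=loci,
        samples=samples,
        genotypes=np.asarray(gts, dtype=np.int8).reshape(n, m),
        site_qual=np.asarray(quals, dtype=float),
        depth=np.asarray(dps, dtype=np.int32).reshape(n, m),
    )


def write_vcf(v: VariantMatrix, path: str | Path, diploid_mask: np.ndarray | None = None) -> None:
    """Write a VariantMatrix as a minimal VCF v4.2 text file.

    Dosages 0/1/2 become 0/0, 0/1, 1/1; MISSING becomes ./. .  Only the
    first ALT is represented; multi-allelic input records are therefore
    collapsed on write (the reader keeps ``n_alleles`` for filtering, but a
    written record is biallelic).
    """
    path = Path(path)
    contigs = list(dict.fromkeys(v.loci["contig"]))
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(v.samples) + "\n")
        for i in range(v.n_loci):
            row = v.loci.iloc[i]
            cells = [
                f"{gt_codes[int(g)]}:{int(d)}"
                for g, d in zip(v.genotypes[i], v.depth[i])
            ]
            fh.write(
                f"{row['contig']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{v.site_qual[i]:.2f}\t.\t.\tGT:DP\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Filter stages


def filter_site_quality(v: VariantMatrix, min_qual: float) -> VariantMatrix:
    """Drop loci with Phred site quality strictly below ``min_qual``."""
    if min_qual < 0:
        raise ValueError("min_qual must be >= 0")
    return v.take_loci(v.site_qual >= min_qual)


def apply_min_depth(v: VariantMatrix, min_dp: int) -> VariantMatrix:
    """Mask genotype cells with depth below ``min_dp`` (loci are retained)."""
    if min_dp < 0:
        raise ValueError("min_dp must be >= 0")
    gt = v.genotypes.copy()
    gt[v.depth < min_dp] = MISSING
    return replace(v, genotypes=gt)


def _allele_counts(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (ALT allele count, called allele total) over non-missing cells."""
    called = gt != MISSING
    alt = np.where(called, gt, 0).sum(axis=1)
    total = 2 * called.sum(axis=1)
    return alt, total


def filter_sites(
    v: VariantMatrix,
    max_missing: float,
    mac_min: int | None = None,
    maf_min: float | None = None,
    max_alleles: int | None = None,
) -> VariantMatrix:
    """Site filter: call rate >= max_missing, MAC/MAF/allele-count thresholds.

    ``max_missing`` follows VCFtools semantics: the fraction of individuals
    genotyped must be at least this value.  MAC and MAF are computed over
    non-missing genotypes only; the minor allele is the less frequent one
    (frequency min(p, 1-p), so an exact tie gives MAF 0.5).
    """
    gt = v.genotypes
    called = gt != MISSING
    n_ind = v.n_individuals
    call_rate = called.sum(axis=1) / n_ind if n_ind else np.zeros(v.n_loci)
    keep = call_rate >= max_missing
    alt, total = _allele_counts(gt)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    minor_count = np.minimum(alt, total - alt)
    minor_freq = np.minimum(p_alt, 1.0 - p_alt)
    if mac_min is not None:
        keep &= minor_count >= mac_min
    if maf_min is not None:
        keep &= (total > 0) & (minor_freq >= maf_min)
    if max_alleles is not None:
        keep &= v.loci["n_alleles"].to_numpy() <= max_alleles
    return v.take_loci(keep)


def drop_high_missing_individuals(
    v: VariantMatrix, indiv_max_missing: float
) -> tuple[VariantMatrix, list[str]]:
    """Remove individuals whose missing fraction is strictly above the cutoff."""
    if not 0.0 <= indiv_max_missing <= 1.0:
        raise ValueError("indiv_max_missing outside [0, 1]")
    if v.n_loci == 0:
        return v, []
    miss_frac = (v.genotypes == MISSING).sum(axis=0) / v.n_loci
    keep = miss_frac <= indiv_max_missing
    if not keep.any():
        raise ValueError("all individuals exceed the missingness cutoff; nothing to analyze")
    removed = [s for s, k in zip(v.samples, keep) if not k]
    return v.take_individuals(np.flatnonzero(keep)), removed


def partition_compartments(
    v: VariantMatrix, compartment_table: pd.DataFrame
) -> tuple[VariantMatrix, VariantMatrix]:
    """Split loci into (mitochondrial, nuclear) by contig.

    Contigs absent from the table count as nuclear — the "no hit in the
    mitochondrial database" rule.
    """
    mito_contigs = set(
        compartment_table.loc[
            compartment_table["compartment"] == MITOCHONDRIAL, "contig_id"
        ]
    )
    is_mito = v.loci["contig"].isin(mito_contigs).to_numpy()
    mito = v.take_loci(is_mito)
    nuc = v.take_loci(~is_mito)
    mito.compartment = np.full(mito.n_loci, MITOCHONDRIAL, dtype=object)
    nuc.compartment = np.full(nuc.n_loci, NUCLEAR, dtype=object)
    return mito, nuc


def run_filter_cascade(
    v: VariantMatrix, p: FilterParams | None = None
) -> tuple[VariantMatrix, FilterLog]:
    """Run the five-stage cascade in its fixed order and log the funnel.

    Order: site quality -> stage-1 sites (call rate, MAC) -> individual
    drop -> minDP masking -> stage-2 sites (call rate, MAF, max-alleles).
    Depth masking sits inside the second filtering step, immediately before
    the stage-2 site predicates, so stage-2 missingness sees masked cells.
    """
    p = p or FilterParams()
    log = FilterLog()

    cur = filter_site_quality(v, p.min_qual)
    log.add("site_quality", v.n_loci, cur.n_loci, v.n_individuals, cur.n_individuals)

    nxt = filter_sites(cur, p.stage1_max_missing, mac_min=p.mac_min)
    log.add("stage1_sites", cur.n_loci, nxt.n_loci, cur.n_individuals, nxt.n_individuals)
    cur = nxt

    nxt, _removed = drop_high_missing_individuals(cur, p.indiv_max_missing)
    log.add("individuals", cur.n_loci, nxt.n_loci, cur.n_individuals, nxt.n_individuals)
    cur = nxt

    nxt = apply_min_depth(cur, p.min_dp)
    log.add("min_depth_mask", cur.n_loci, nxt.n_loci, cur.n_individuals, nxt.n_individuals)
    cur = nxt

    nxt = filter_sites(
        cur, p.stage2_max_missing, maf_min=p.maf_min, max_alleles=p.max_alleles
    )
    log.add("stage2_sites", cur.n_loci, nxt.n_loci, cur.n_individuals, nxt.n_individuals)
    return nxt, log
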