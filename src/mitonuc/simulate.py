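"""Synthetic expression, genotype and metadata generator.

Emulates the statistical structure of the study system: 15 expression
samples grouped three ways over the same individuals (station 5/5/5,
mitotype 2/7/3/3, nuclear type 10/5), a larger 27-individual genotype
cohort with weak nuclear station structure (Balding-Nichols allele
frequencies) and a strong mitochondrial split between h1- and h2-carrying
mitotype clusters, negative-binomial counts with planted group effects,
and VCF/TSV fixtures that round-trip through the package readers.

Mitotype labels: h1h1 and h2h2 are homoplasmic, h1h3 and h2h3 are
heteroplasmic (a second, divergent haplotype h3 coexists in the same
individual).  Mitochondrial genotypes are clonal: homozygous calls for the
carrier cluster's allele, with heteroplasmic individuals showing
intermediate (heterozygous-coded) dosages at a configured fraction of the
cluster-diagnostic sites to mimic minor-haplotype admixture.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .variants import MISSING, MITOCHONDRIAL, NUCLEAR, VariantMatrix, write_vcf

HETEROPLASMIC = ("h1h3", "h2h3")
H1_CLUSTER_PREFIX = "h1"

_DEFAULT_DESIGN: dict[str, list[tuple[str, int]]] = {
    "station": [("Base", 5), ("Glacier", 5), ("Faro", 5)],
    "mitotype": [("h1h1", 2), ("h2h2", 7), ("h1h3", 3), ("h2h3", 3)],
    "nuclear_type": [("NucA", 10), ("NucB", 5)],
}


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    Defaults encode the study design: 15 expression samples with the three
    original groupings, ~5% of genes planted per contrast at |log2FC| = 2,
    NB dispersion 0.2, and a 27-individual genotype cohort with nuclear
    F_ST 0.03 between stations.
    """

    n_genes: int = 2000
    group_design: dict[str, list[tuple[str, int]]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_DESIGN.items()}
    )
    de_fraction: float = 0.05
    effect_log2fc: float = 2.0
    dispersion: float = 0.2
    libsize_range: tuple[float, float] = (0.5, 2.0)
    baseline_meanlog: float = 4.0
    baseline_sdlog: float = 1.0
    n_loci_nuclear: int = 1000
    n_loci_mito: int = 145
    fst_nuclear: float = 0.03
    mito_divergence: float = 0.8
    heteroplasmy_admixture: float = 0.3
    missing_rate: float = 0.02
    depth_mean: float = 30.0
    n_extra_individuals: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.de_fraction < 1.0:
            raise ValueError("de_fraction outside [0, 1)")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0.0 <= self.fst_nuclear < 1.0:
            raise ValueError(f"fst_nuclear {self.fst_nuclear} outside [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate outside [0, 1)")
        if self.libsize_range[0] <= 0 or self.libsize_range[1] < self.libsize_range[0]:
            raise ValueError("libsize_range must be positive and ordered")
        totals = {g: sum(sz for _, sz in pairs) for g, pairs in self.group_design.items()}
        if len(set(totals.values())) > 1:
            a, b = list(totals.items())[:2]
            raise ValueError(
                f"group designs disagree on sample total: {a[0]}={a[1]} vs {b[0]}={b[1]}"
            )

    @property
    def n_samples(self) -> int:
        first = next(iter(self.group_design.values()))
        return sum(sz for _, sz in first)

    def n_planted_per_contrast(self) -> int:
        n = int(round(self.de_fraction * self.n_genes))
        if n * len(self.group_design) > self.n_genes:
            raise ValueError(
                f"{n} planted genes x {len(self.group_design)} contrasts exceed n_genes"
            )
        return n


@dataclass
class TruthSet:
    """Planted effects: per-contrast DE genes with signed log2FC and genotype truth."""

    de_genes: dict[str, dict[str, float]]
    contrast_groups: dict[str, list[str]]
    locus_fst: dict[str, float]
    mitotype_assignment: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "de_genes": self.de_genes,
                "contrast_groups": self.contrast_groups,
                "locus_fst": self.locus_fst,
                "mitotype_assignment": self.mitotype_assignment,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        d = json.loads(text)
        return cls(
            de_genes=d["de_genes"],
            contrast_groups=d["contrast_groups"],
            locus_fst=d["locus_fst"],
            mitotype_assignment=d["mitotype_assignment"],
        )


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    # stable per-stream substream: crc32 is deterministic across processes
    key = zlib.crc32(stream.encode()) % (2**31)
    ss = np.random.SeedSequence(config.seed, spawn_key=(key,))
    return np.random.default_rng(ss)


def simulate_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Expression-cohort sample table: one row per sample, one column per grouping.

    Label-to-sample assignment is shuffled independently per grouping (with
    the configured seed) so that groupings are not artificially confounded;
    each grouping column carries exactly the configured number of samples
    per label.
    """
    n = config.n_samples
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    table: dict[str, list[str]] = {"sample_id": sample_ids}
    rng = _rng(config, "metadata")
    for gname, pairs in config.group_design.items():
        labels: list[str] = []
        for lbl, size in pairs:
            labels.extend([lbl] * size)
        order = rng.permutation(n)
        col = [""] * n
        for pos, lab in zip(order, labels):
            col[pos] = lab
        table[gname] = col
    return pd.DataFrame(table)


def _contrast_samples(config: SimulationConfig, metadata: pd.DataFrame) -> dict[str, list[str]]:
    """One planted contrast per grouping.

    Station-like groupings contrast the first listed group against the
    rest; the mitotype grouping contrasts heteroplasmic (h1h3/h2h3)
    carriers against homoplasmic ones when those labels are present.
    """
    out: dict[str, list[str]] = {}
    for gname, pairs in config.group_design.items():
        labels = [lbl for lbl, _ in pairs]
        if any(l in HETEROPLASMIC for l in labels):
            affected = [l for l in labels if l in HETEROPLASMIC]
        else:
            affected = [labels[0]]
        mask = metadata[gname].isin(affected)
        out[gname] = metadata.loc[mask, "sample_id"].tolist()
    return out


def simulate_counts(
    config: SimulationConfig, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, TruthSet]:
    """NB count matrix with planted group effects, plus its truth set.

    Counts are NB(mean = baseline * libsize * 2^(+-effect), dispersion
    alpha) with log-normal gene baselines and log-uniform library sizes.
    Planted gene sets are disjoint across the per-grouping contrasts; the
    planted sign is random per gene.
    """
    rng = _rng(config, "counts")
    n_genes, n_samples = config.n_genes, len(metadata)
    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    sample_ids = metadata["sample_id"].tolist()

    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=n_genes)
    lo, hi = config.libsize_range
    libsize = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    mean = baseline[:, None] * libsize[None, :]
    n_planted = config.n_planted_per_contrast()
    contrasts = _contrast_samples(config, metadata)
    de_genes: dict[str, dict[str, float]] = {g: {} for g in config.group_design}
    if n_planted > 0:
        pool = rng.permutation(n_genes)
        offset = 0
        sample_pos = {s: i for i, s in enumerate(sample_ids)}
        for gname in config.group_design:
            chosen = pool[offset : offset + n_planted]
            offset += n_planted
            signs = rng.choice([-1.0, 1.0], size=n_planted)
            cols = [sample_pos[s] for s in contrasts[gname]]
            for gi, sg in zip(chosen, signs):
                lfc = sg * config.effect_log2fc
                de_genes[gname][gene_ids[gi]] = float(lfc)
                mean[gi, cols] *= 2.0**lfc

    r = 1.0 / config.dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)
    frame = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    truth = TruthSet(
        de_genes=de_genes,
        contrast_groups=contrasts,
        locus_fst={},
        mitotype_assignment=dict(zip(metadata["sample_id"], metadata["mitotype"]))
        if "mitotype" in metadata
        else {},
    )
    return frame, truth


def extend_cohort(config: SimulationConfig, metadata: pd.DataFrame) -> pd.DataFrame:
    """Genotype cohort: expression samples plus extra genotype-only individuals.

    Extras cycle through the stations and the homoplasmic mitotypes and
    alternate nuclear types, giving the larger SNP cohort the same label
    vocabulary as the expression subset.
    """
    stations = [lbl for lbl, _ in config.group_design.get("station", [("A", 1)])]
    nuclear = [lbl for lbl, _ in config.group_design.get("nuclear_type", [("NucA", 1)])]
    mito_homo = [
        lbl for lbl, _ in config.group_design.get("mitotype", [("h1h1", 1)])
        if lbl not in HETEROPLASMIC
    ] or ["h1h1"]
    rows = []
    for i in range(config.n_extra_individuals):
        rows.append(
            {
                "sample_id": f"G{i + 1:02d}",
                "station": stations[i % len(stations)],
                "mitotype": mito_homo[i % len(mito_homo)],
                "nuclear_type": nuclear[i % len(nuclear)],
            }
        )
    extra = pd.DataFrame(rows, columns=metadata.columns)
    return pd.concat([metadata, extra], ignore_index=True)


def simulate_genotypes(config: SimulationConfig, metadata: pd.DataFrame) -> VariantMatrix:
    """Genotype matrix: Balding-Nichols nuclear loci + clonal mitochondrial loci.

    Nuclear loci draw per-station allele frequencies from the
    Balding-Nichols beta model at ``fst_nuclear`` around a uniform ancestral
    frequency, then diploid genotypes binomially.  A fraction
    ``mito_divergence`` of mitochondrial loci is fixed between the h1- and
    h2-carrying clusters; heteroplasmic individuals show intermediate
    dosage at a fraction ``heteroplasmy_admixture`` of those sites.  Site
    Phred quality is uniform on [20, 60] (so a Phred >= 30 cut removes
    about a quarter of sites), per-genotype depth is Poisson(depth_mean),
    and genotypes are set missing at ``missing_rate``.
    """
    rng = _rng(config, "genotypes")
    samples = metadata["sample_id"].tolist()
    stations = metadata["station"].to_numpy() if "station" in metadata else np.zeros(len(samples))
    mitotypes = (
        metadata["mitotype"].to_numpy()
        if "mitotype" in metadata
        else np.array(["h1h1"] * len(samples))
    )
    n_ind = len(samples)
    f = config.fst_nuclear

    # nuclear loci
    n_nuc = config.n_loci_nuclear
    p_anc = rng.uniform(0.1, 0.9, size=n_nuc)
    station_labels = pd.unique(stations)
    geno_nuc = np.empty((n_nuc, n_ind), dtype=np.int8)
    for st in station_labels:
        cols = np.flatnonzero(stations == st)
        if f > 0:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            p_st = rng.beta(a, b)
        else:
            p_st = p_anc
        geno_nuc[:, cols] = rng.binomial(2, p_st[:, None], size=(n_nuc, len(cols))).astype(np.int8)

    # mitochondrial loci: clonal per mitotype cluster
    n_mit = config.n_loci_mito
    n_div = int(round(config.mito_divergence * n_mit))
    is_h1 = np.array([str(m).startswith(H1_CLUSTER_PREFIX) for m in mitotypes])
    is_het = np.isin(mitotypes, HETEROPLASMIC)
    geno_mit = np.empty((n_mit, n_ind), dtype=np.int8)
    # divergent sites: h1 cluster carries REF (0), h2 cluster carries ALT (2)
    geno_mit[:n_div, :] = np.where(is_h1[None, :], 0, 2)
    for j in np.flatnonzero(is_het):
        n_adm = int(round(config.heteroplasmy_admixture * n_div))
        if n_adm > 0:
            sites = rng.choice(n_div, size=n_adm, replace=False)
            geno_mit[sites, j] = 1
    # remaining mito sites: shared low-frequency clonal variation
    n_rest = n_mit - n_div
    if n_rest > 0:
        p_rest = rng.uniform(0.05, 0.3, size=n_rest)
        carrier = rng.random((n_rest, n_ind)) < p_rest[:, None]
        geno_mit[n_div:, :] = np.where(carrier, 2, 0).astype(np.int8)

    genotypes = np.vstack([geno_mit, geno_nuc])
    n_loci = genotypes.shape[0]

    miss = rng.random((n_loci, n_ind)) < config.missing_rate
    genotypes = np.where(miss, np.int8(MISSING), genotypes).astype(np.int8)

    site_qual = rng.uniform(20.0, 60.0, size=n_loci)
    depth = rng.poisson(config.depth_mean, size=(n_loci, n_ind)).astype(np.int32)

    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n_loci)
    alt_i = (ref_i + rng.integers(1, 4, size=n_loci)) % 4

    contigs = ["contig_mito"] * n_mit
    positions = list(rng.choice(np.arange(1, 18001), size=n_mit, replace=False))
    positions.sort()
    loci_per_contig = 5
    for i in range(config.n_loci_nuclear):
        contigs.append(f"contig_{i // loci_per_contig + 1:05d}")
        positions.append(100 + 37 * (i % loci_per_contig))
    loci = pd.DataFrame(
        {
            "contig": contigs,
            "pos": positions,
            "ref": bases[ref_i],
            "alt": bases[alt_i],
            "n_alleles": 2,
        }
    )
    compartment = np.array([MITOCHONDRIAL] * n_mit + [NUCLEAR] * config.n_loci_nuclear, dtype=object)
    return VariantMatrix(
        loci=loci,
        samples=samples,
        genotypes=genotypes,
        site_qual=site_qual,
        depth=depth,
        compartment=compartment,
    )


def compartment_table(v: VariantMatrix) -> pd.DataFrame:
    """Contig -> compartment table (the mitochondrial-database hit list)."""
    df = pd.DataFrame({"contig_id": v.loci["contig"], "compartment": v.compartment})
    return df.drop_duplicates("contig_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fixture I/O


def write_fixture_set(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write the full fixture set and a manifest; returns the manifest dict.

    Files: counts.tsv (expression subset), metadata.tsv (genotype cohort,
    superset of the expression samples), genotypes.vcf, compartments.tsv,
    truth.json, manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = simulate_metadata(config)
    counts, truth = simulate_counts(config, meta)
    cohort = extend_cohort(config, meta)
    v = simulate_genotypes(config, cohort)
    truth.locus_fst = {
        f"{c}:{p}": (config.fst_nuclear if comp == NUCLEAR else 1.0)
        for c, p, comp in zip(v.loci["contig"], v.loci["pos"], v.compartment)
    }

    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "vcf": outdir / "genotypes.vcf",
        "compartments": outdir / "compartments.tsv",
        "truth": outdir / "truth.json",
        "manifest": outdir / "manifest.json",
    }
    counts.to_csv(paths["counts"], sep="\t")
    cohort.to_csv(paths["metadata"], sep="\t", index=False)
    write_vcf(v, paths["vcf"])
    compartment_table(v).to_csv(paths["compartments"], sep="\t", index=False)
    paths["truth"].write_text(truth.to_json())
    manifest = {
        "seed": config.seed,
        "files": {k: p.name for k, p in paths.items()},
        "n_genes": config.n_genes,
        "n_samples": int(len(meta)),
        "n_individuals": int(len(cohort)),
        "n_loci": int(v.n_loci),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_compartments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_truth(path: str | Path) -> TruthSet:
    return TruthSet.from_json(Path(path).read_text())
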