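"""Synthetic diel-transcription study generator with known ground truth.

Emulates the two sampling designs of the study: a field design with 24
inbreds sampled every 2 h over 24 h (hours 6..28, one plant per
timepoint) and a growth-chamber design with a few genotypes sampled every
3 h over 30 h with two replicates.  Expression follows

    y(t) = M + A * sin(2*pi*t/24 + phi) + eps,  eps ~ N(0, sigma^2), y >= 0

with the amplitude depending on promoter haplotype for DDR genes and
shared within a gene otherwise.  Promoters are i.i.d. background sequence
of configurable GC content into which the Evening Element (AAATATCT by
default) is planted for rhythmic alleles; GWAS p-values are uniform with
a Beta-distributed spike near DDR genes; genotypes are drawn in
Hardy-Weinberg proportions at their minor-allele frequency.

Every generator is deterministic under the configuration seed.  The truth
ledger records per-allele sinusoid parameters, DDR flags, haplotype
amplitude maps, planted motif positions and causal SNP ids so downstream
stages can be scored against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import GeneRecord, PanGene

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_pangenome",
    "simulate_expression",
    "simulate_promoters",
    "simulate_snps",
    "simulate_dataset",
    "write_dataset",
]

FIELD_TIMES = tuple(np.arange(6.0, 30.0, 2.0))       # 12 samples, 6am..4am
CHAMBER_TIMES = tuple(np.arange(0.0, 31.0, 3.0))     # 11 samples, 0h..30h


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator (defaults = the
    field/chamber designs; amplitudes and noise sized for the DDR
    recovery experiments)."""

    n_inbreds: int = 24
    n_pangenes: int = 180
    core_fraction: float = 0.85
    frac_rhythmic: float = 0.10
    frac_ddr: float = 0.15
    chamber_genotypes: int = 3
    chamber_replicates: int = 2
    period: float = 24.0
    ddr_amplitudes: tuple = (0.0, 3.0)   # per-haplotype A for DDR genes
    amp_range: tuple = (1.5, 3.0)        # shared A for other rhythmic genes
    mesor_log_mean: float = float(np.log(200.0))
    mesor_log_sd: float = 0.4
    mesor_genotype_cv: float = 0.0   # per-inbred baseline jitter (log-sd)
    sigma: float = 0.3
    motif: str = "AAATATCT"
    promoter_len: int = 1500
    gc_content: float = 0.5
    n_snps: int = 4000
    n_individuals: int = 200
    spike_beta_a: float = 0.1            # Beta(a, 1) spike near DDR genes
    spike_flank: int = 1000
    p_adapt: float = 0.5
    adapt_background_rate: float = 0.01
    maf_range: tuple = (0.05, 0.5)
    gene_length: int = 3000
    gene_spacing: int = 6000
    seed: int = 0

    def __post_init__(self):
        for name in ("core_fraction", "frac_rhythmic", "frac_ddr",
                     "gc_content", "p_adapt", "adapt_background_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_inbreds", "n_pangenes", "n_snps", "n_individuals",
                     "chamber_genotypes", "chamber_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_inbreds < 2:
            raise ValueError("n_inbreds must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if len(self.motif) > self.promoter_len:
            raise ValueError("motif longer than promoter sequence")

    @property
    def inbreds(self) -> list[str]:
        return [f"I{i:02d}" for i in range(self.n_inbreds)]

    @property
    def chamber_inbreds(self) -> list[str]:
        return self.inbreds[: self.chamber_genotypes]


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for scoring downstream stages."""

    # per (pangene, genotype): A, phi, M, rhythmic flag
    params: pd.DataFrame = field(default_factory=pd.DataFrame)
    ddr_genes: set = field(default_factory=set)
    rhythmic_genes: set = field(default_factory=set)
    hap_amplitude: dict = field(default_factory=dict)  # (pg, hap) -> A
    motif_positions: dict = field(default_factory=dict)  # seq name -> [pos]
    causal_snps: set = field(default_factory=set)
    adaptation_snps: set = field(default_factory=set)

    def is_rhythmic(self, pangene: str, genotype: str) -> bool:
        sub = self.params
        row = sub[(sub.pangene_id == pangene)
                  & (sub.genotype_id == genotype)]
        return bool(len(row)) and bool(row.iloc[0].A > 0)

    def to_json(self, path) -> None:
        payload = {
            "params": self.params.to_dict(orient="list"),
            "ddr_genes": sorted(self.ddr_genes),
            "rhythmic_genes": sorted(self.rhythmic_genes),
            "hap_amplitude": {f"{pg}|{h}": a for (pg, h), a
                              in self.hap_amplitude.items()},
            "motif_positions": {k: list(map(int, v)) for k, v
                                in self.motif_positions.items()},
            "causal_snps": sorted(self.causal_snps),
            "adaptation_snps": sorted(self.adaptation_snps),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        hap_amp = {tuple(k.rsplit("|", 1)): v
                   for k, v in d["hap_amplitude"].items()}
        return cls(params=pd.DataFrame(d["params"]),
                   ddr_genes=set(d["ddr_genes"]),
                   rhythmic_genes=set(d["rhythmic_genes"]),
                   hap_amplitude=hap_amp,
                   motif_positions={k: list(v) for k, v
                                    in d["motif_positions"].items()},
                   causal_snps=set(d["causal_snps"]),
                   adaptation_snps=set(d["adaptation_snps"]))


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    pangenes: list
    haplotypes: pd.DataFrame
    genes: list
    field_expression: pd.DataFrame
    chamber_expression: pd.DataFrame
    promoters: dict
    snps: pd.DataFrame
    truth: SyntheticTruth


def _spawn(cfg: SimulationConfig, n: int):
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(cfg.seed).spawn(n)]


def simulate_pangenome(cfg: SimulationConfig, rng=None):
    """Pan-genes, promoter haplotypes, gene coordinates and the truth
    skeleton (DDR flags, per-allele sinusoid parameters)."""
    if cfg.n_inbreds < 2:
        raise ValueError("n_inbreds must be >= 2")
    rng = rng or _spawn(cfg, 5)[0]
    inbreds = cfg.inbreds
    n = cfg.n_pangenes
    pangene_ids = [f"pg{i:04d}" for i in range(n)]

    core = rng.random(n) < cfg.core_fraction
    n_ddr = int(round(cfg.frac_ddr * n))
    core_idx = np.flatnonzero(core)
    if len(core_idx) < n_ddr:  # DDR genes need full membership
        extra = np.flatnonzero(~core)[: n_ddr - len(core_idx)]
        core[extra] = True
        core_idx = np.flatnonzero(core)
    ddr_idx = set(rng.choice(core_idx, size=n_ddr, replace=False).tolist())
    non_ddr = [i for i in range(n) if i not in ddr_idx]
    n_rhyt = min(int(round(cfg.frac_rhythmic * n)), len(non_ddr))
    rhyt_idx = set(rng.choice(non_ddr, size=n_rhyt, replace=False).tolist())

    pangenes, hap_rows, genes = [], [], []
    truth = SyntheticTruth()
    param_rows = []
    for i, pg in enumerate(pangene_ids):
        if core[i]:
            members = list(inbreds)
        else:
            size = int(rng.integers(2, cfg.n_inbreds))
            members = sorted(rng.choice(inbreds, size=size,
                                        replace=False).tolist())
        pangenes.append(PanGene(pg, {g: f"{pg}:{g}" for g in members}))

        if i in ddr_idx:
            haps = rng.integers(0, 2, size=len(members))
            if len(np.unique(haps)) < 2:
                haps[-1] = 1 - haps[-1]
            amps = dict(enumerate(cfg.ddr_amplitudes))
            truth.ddr_genes.add(pg)
        else:
            n_hap = int(rng.integers(1, 5))
            haps = rng.integers(0, n_hap, size=len(members))
            if i in rhyt_idx:
                shared_a = float(rng.uniform(*cfg.amp_range))
                truth.rhythmic_genes.add(pg)
            else:
                shared_a = 0.0
            amps = {h: shared_a for h in range(n_hap)}
        for h, a in amps.items():
            truth.hap_amplitude[(pg, f"H{h}")] = a
        phi = float(rng.uniform(0, 2 * np.pi))
        # MESOR is drawn per pan-gene and shared across inbreds (the
        # amplitude-difference test pools genotypes within a haplotype
        # group under a common baseline); optional per-inbred jitter
        gene_mesor = float(rng.lognormal(cfg.mesor_log_mean,
                                         cfg.mesor_log_sd))
        for g, h in zip(members, haps):
            hap_rows.append((pg, g, f"H{h}"))
            mesor = gene_mesor
            if cfg.mesor_genotype_cv > 0:
                mesor *= float(rng.lognormal(0.0, cfg.mesor_genotype_cv))
            param_rows.append((pg, g, amps[int(h)], phi, mesor))

        start = 1000 + i * cfg.gene_spacing
        end = start + cfg.gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else end
        genes.append(GeneRecord(pg, "chr1", tss, strand, start, end))

    truth.params = pd.DataFrame(
        param_rows,
        columns=["pangene_id", "genotype_id", "A", "phi", "M"])
    haplotypes = pd.DataFrame(
        hap_rows, columns=["pangene_id", "genotype_id", "haplotype_id"])
    return pangenes, haplotypes, genes, truth


def simulate_expression(cfg: SimulationConfig, truth: SyntheticTruth,
                        design: str = "field", rng=None) -> pd.DataFrame:
    """Long expression table for one sampling design.

    ``norm_value`` carries the exact model draw (Gaussian noise on the
    normalized scale, clipped at zero); ``count`` is a rounded raw-count
    rendering under a per-sample library size factor.
    """
    rng = rng or _spawn(cfg, 5)[1 if design == "field" else 2]
    if design == "field":
        times = np.asarray(FIELD_TIMES)
        reps = 1
        genotypes = None
    elif design == "chamber":
        times = np.asarray(CHAMBER_TIMES)
        reps = cfg.chamber_replicates
        genotypes = set(cfg.chamber_inbreds)
    else:
        raise ValueError(f"unknown design {design!r}")

    params = truth.params
    if genotypes is not None:
        params = params[params.genotype_id.isin(genotypes)]
    w = 2 * np.pi / cfg.period

    # per (genotype, rep, time) library size factor, shared across genes
    keys = sorted(set(params.genotype_id))
    sf = {}
    for g in keys:
        for r in range(reps):
            for t in times:
                sf[(g, r, t)] = float(rng.lognormal(0.0, 0.15))

    rows = []
    for rec in params.itertuples(index=False):
        signal = rec.M + rec.A * np.sin(w * times + rec.phi)
        for r in range(reps):
            noise = rng.normal(0.0, cfg.sigma, size=len(times))
            y = np.clip(signal + noise, 0.0, None)
            for t, v in zip(times, y):
                factor = sf[(rec.genotype_id, r, t)]
                rows.append((rec.pangene_id, rec.genotype_id, r, t,
                             float(np.rint(v * factor)), v))
    return pd.DataFrame(rows, columns=["gene_id", "genotype_id",
                                       "replicate", "time_h", "count",
                                       "norm_value"])


_BASES = np.array(list("ACGT"))


def _random_seq(rng, length, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def simulate_promoters(cfg: SimulationConfig, truth: SyntheticTruth,
                       haplotypes: pd.DataFrame, rng=None) -> dict:
    """Per-(pangene, haplotype) promoter sequences with planted motifs.

    Rhythmic alleles (haplotype amplitude > 0) receive 1-3 copies of the
    planted motif at uniform random positions; planted positions are
    recorded in ``truth.motif_positions`` keyed by ``pangene|haplotype``.
    """
    if len(cfg.motif) > cfg.promoter_len:
        raise ValueError("motif longer than promoter sequence")
    rng = rng or _spawn(cfg, 5)[3]
    seqs = {}
    pairs = haplotypes[["pangene_id", "haplotype_id"]].drop_duplicates()
    for pg, hap in pairs.itertuples(index=False):
        name = f"{pg}|{hap}"
        seq = list(_random_seq(rng, cfg.promoter_len, cfg.gc_content))
        positions = []
        if truth.hap_amplitude.get((pg, hap), 0.0) > 0:
            n_copies = int(rng.integers(1, 4))
            while len(positions) < n_copies:
                pos = int(rng.integers(0, cfg.promoter_len
                                       - len(cfg.motif) + 1))
                # keep copies non-overlapping so each stays intact
                if any(abs(pos - q) < len(cfg.motif) for q in positions):
                    continue
                seq[pos:pos + len(cfg.motif)] = list(cfg.motif)
                positions.append(pos)
        seqs[name] = "".join(seq)
        truth.motif_positions[name] = positions
    return seqs


def simulate_snps(cfg: SimulationConfig, truth: SyntheticTruth,
                  genes: list, rng=None) -> pd.DataFrame:
    """SNP table with GWAS p-values, MAF, HWE genotypes and adaptation set.

    Background p-values are Uniform(0, 1); SNPs within ``spike_flank`` of
    a DDR gene are drawn from Beta(spike_beta_a, 1) and recorded as
    causal.  The adaptation SNP set takes spiked SNPs with probability
    ``p_adapt`` plus background SNPs at ``adapt_background_rate``.
    """
    rng = rng or _spawn(cfg, 5)[4]
    chrom_len = 2000 + cfg.n_pangenes * cfg.gene_spacing
    pos = np.sort(rng.choice(chrom_len, size=cfg.n_snps, replace=False))

    near_ddr = np.zeros(cfg.n_snps, dtype=bool)
    for g in genes:
        if g.gene_id in truth.ddr_genes:
            lo = max(g.gene_start - cfg.spike_flank, 0)
            hi = g.gene_end + cfg.spike_flank
            near_ddr |= (pos >= lo) & (pos < hi)

    pvals = rng.uniform(0.0, 1.0, size=cfg.n_snps)
    if cfg.spike_beta_a > 0:
        spiked = rng.beta(cfg.spike_beta_a, 1.0, size=int(near_ddr.sum()))
        pvals[near_ddr] = np.clip(spiked, np.finfo(float).tiny, 1.0)
    maf = rng.uniform(*cfg.maf_range, size=cfg.n_snps)

    snp_ids = [f"s{i:05d}" for i in range(cfg.n_snps)]
    df = pd.DataFrame({"snp_id": snp_ids, "chrom": "chr1",
                       "pos": pos.astype(int), "maf": maf,
                       "pvalue": pvals})
    # HWE genotypes at the (minor) allele frequency
    probs = np.stack([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2],
                     axis=1)
    u = rng.random((cfg.n_snps, cfg.n_individuals))
    cum = np.cumsum(probs, axis=1)
    dosage = (u[:, :, None] > cum[:, None, :]).sum(axis=2)
    gt = pd.DataFrame(
        dosage.astype(float),
        columns=[f"gt_ind{j:03d}" for j in range(cfg.n_individuals)])
    df = pd.concat([df, gt], axis=1)

    truth.causal_snps = set(np.asarray(snp_ids)[near_ddr].tolist())
    adapt = (near_ddr & (rng.random(cfg.n_snps) < cfg.p_adapt)) | \
            (~near_ddr & (rng.random(cfg.n_snps)
                          < cfg.adapt_background_rate))
    truth.adaptation_snps = set(np.asarray(snp_ids)[adapt].tolist())
    return df


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Run every generator under one seed and bundle the outputs."""
    rngs = _spawn(cfg, 5)
    pangenes, haplotypes, genes, truth = simulate_pangenome(cfg, rngs[0])
    field = simulate_expression(cfg, truth, "field", rngs[1])
    chamber = simulate_expression(cfg, truth, "chamber", rngs[2])
    promoters = simulate_promoters(cfg, truth, haplotypes, rngs[3])
    snps = simulate_snps(cfg, truth, genes, rngs[4])
    return SyntheticDataset(cfg, pangenes, haplotypes, genes, field,
                            chamber, promoters, snps, truth)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write all standard-format files plus the truth ledger."""
    from . import io as dio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dio.write_expression(ds.field_expression, outdir / "field_expr.tsv")
    dio.write_expression(ds.chamber_expression,
                         outdir / "chamber_expr.tsv")
    dio.write_haplotypes(ds.haplotypes, outdir / "haplotypes.tsv")
    dio.write_genes_bed(ds.genes, outdir / "genes.bed")
    dio.write_genes_tsv(ds.genes, outdir / "genes.tsv")
    dio.write_snps(ds.snps, outdir / "snps.tsv")
    dio.write_fasta(ds.promoters, outdir / "promoters.fa")
    ds.truth.to_json(outdir / "truth.json")
    adapt = ds.snps[ds.snps["snp_id"].isin(ds.truth.adaptation_snps)]
    cols = ["snp_id", "chrom", "pos", "maf", "pvalue"]
    adapt[cols].to_csv(outdir / "adaptation_snps.tsv", sep="\t",
                       index=False)
    (outdir / "config.json").write_text(
        json.dumps(asdict(ds.config), indent=1))
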