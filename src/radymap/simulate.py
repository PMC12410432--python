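"""Ground-truthed simulation of a RADseq sex-marker study.

Emulates the structure of the empirical design this package analyses: a
panel of sexed adults scored for per-locus read depth, an F1 family (two
parents, many offspring) genotyped at testcross SNPs, a terminal
non-recombining Y-linked region on one chromosome whose loci are present
only on the paternal Y haplotype, paralogous locus pairs, and a homologous
reference genome in which every locus is embedded.

The male is the heterogametic sex.  Offspring inherit one recombinant
paternal haplotype per chromosome (no crossover interference, so Haldane
distances are recoverable); whoever receives the Y-carrying haplotype at
the terminal sex-determining position carries every Y-linked locus, subject
to per-locus dropout.  Females (and non-carrier offspring) show reads at a
Y locus only through contamination.

Depth model: a truly present locus yields Poisson(mean_depth) reads
truncated at 1 (presence guarantees at least one read), zero-inflated by
``dropout_rate``; contamination yields a small residual count
1 + Poisson(1).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genofilter import FamilyGenotypes
from .sexassoc import CoverageMatrix

__all__ = ["SimConfig", "SimTruth", "FamilyData", "simulate_truth",
           "simulate_adult_coverage", "simulate_family", "emit_sequences",
           "write_truth_json"]

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class SimConfig:
    n_chromosomes: int = 12
    loci_per_chromosome: int = 60
    chrom_length_cM: float = 50.0
    y_region_span_cM: float = 5.0
    n_y_loci: int = 20
    n_males: int = 30
    n_females: int = 30
    n_offspring: int = 158
    mean_depth: float = 20.0
    dropout_rate: float = 0.05
    contamination_rate: float = 0.01
    paralog_pairs: int = 10
    paralog_identity: float = 0.85
    locus_length_bp: int = 140
    seed: int = 0
    # secondary structure knobs
    sex_chromosome_index: int = 8  #: 1-based; which chromosome carries the Y region
    snps_per_locus: int = 2
    maternal_snp_prob: float = 0.10
    geno_missing_rate: float = 0.02
    n_noise_snps: int = 18
    ref_mutation_rate: float = 0.0
    ref_spacer_bp: int = 100

    def validate(self) -> None:
        for f in ("n_chromosomes", "loci_per_chromosome", "n_males", "n_females",
                  "n_offspring", "locus_length_bp"):
            if getattr(self, f) <= 0:
                raise ConfigError(f"{f} must be positive, got {getattr(self, f)}")
        for f in ("n_y_loci", "paralog_pairs", "n_noise_snps"):
            if getattr(self, f) < 0:
                raise ConfigError(f"{f} must be non-negative")
        for f in ("dropout_rate", "contamination_rate", "paralog_identity",
                  "maternal_snp_prob", "geno_missing_rate", "ref_mutation_rate"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{f} must be a probability in [0,1], got {v}")
        if self.chrom_length_cM <= 0:
            raise ConfigError("chrom_length_cM must be positive")
        if not 0 <= self.y_region_span_cM <= self.chrom_length_cM:
            raise ConfigError(
                "y_region_span_cM must lie in [0, chrom_length_cM], got "
                f"{self.y_region_span_cM}"
            )
        if not 1 <= self.sex_chromosome_index <= self.n_chromosomes:
            raise ConfigError("sex_chromosome_index out of range")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if self.snps_per_locus < 1:
            raise ConfigError("snps_per_locus must be >= 1")

    @property
    def sex_chromosome(self) -> str:
        return _chrom_name(self.sex_chromosome_index)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config fields: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _chrom_name(i: int) -> str:
    return f"sim{i:02d}"


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stage]))


@dataclass
class SimTruth:
    """Ground truth: the locus registry, the chromosome homology map, and
    (after family simulation) each offspring's Y-haplotype flag."""

    loci: pd.DataFrame  # locus_id, chromosome, cm, is_y, paralog_partner, sequence
    homology: dict[str, str]  # simulated chromosome -> reference record id
    offspring_y: np.ndarray | None = None

    def y_locus_ids(self) -> list[str]:
        return list(self.loci.loc[self.loci["is_y"], "locus_id"])

    def autosomal_locus_ids(self) -> list[str]:
        return list(self.loci.loc[~self.loci["is_y"], "locus_id"])


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mutate_to_identity(rng, seq: str, identity: float) -> str:
    n = len(seq)
    k = int(round((1.0 - identity) * n))
    pos = rng.choice(n, size=k, replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw the locus registry and chromosome homology map.

    Testcross loci get uniform-random cM positions on their chromosome;
    Y-linked loci lie in the terminal ``y_region_span_cM`` of the designated
    sex chromosome.  Paralog pairs are created by copying one member's
    sequence into the other at the configured identity.
    """
    config.validate()
    rng = _rng(config, 1)
    rows = []
    counter = 0
    for ci in range(1, config.n_chromosomes + 1):
        chrom = _chrom_name(ci)
        pos = np.sort(rng.uniform(0, config.chrom_length_cM, config.loci_per_chromosome))
        for p in pos:
            counter += 1
            rows.append((f"L{counter:06d}", chrom, float(p), False))
    # Y-restricted loci in the terminal region of the sex chromosome
    lo = config.chrom_length_cM - config.y_region_span_cM
    ypos = np.sort(rng.uniform(lo, config.chrom_length_cM, config.n_y_loci))
    for p in ypos:
        counter += 1
        rows.append((f"L{counter:06d}", config.sex_chromosome, float(p), True))
    loci = pd.DataFrame(rows, columns=["locus_id", "chromosome", "cm", "is_y"])
    loci["sequence"] = [_random_seq(rng, config.locus_length_bp) for _ in range(len(loci))]
    loci["paralog_partner"] = None
    # paralog pairs among non-Y loci: partner sequence = mutated copy
    auto_idx = loci.index[~loci["is_y"]].to_numpy()
    n_pairs = min(config.paralog_pairs, len(auto_idx) // 2)
    if n_pairs:
        chosen = rng.choice(auto_idx, size=2 * n_pairs, replace=False)
        for a, b in chosen.reshape(-1, 2):
            loci.loc[b, "sequence"] = _mutate_to_identity(
                rng, loci.loc[a, "sequence"], config.paralog_identity
            )
            loci.loc[a, "paralog_partner"] = loci.loc[b, "locus_id"]
            loci.loc[b, "paralog_partner"] = loci.loc[a, "locus_id"]
    # bijective homology: simulated chromosome i -> a permuted reference record
    perm = rng.permutation(config.n_chromosomes) + 1
    homology = {
        _chrom_name(i + 1): f"PW_chr{perm[i]:02d}" for i in range(config.n_chromosomes)
    }
    return SimTruth(loci=loci, homology=homology)


# ---------------------------------------------------------------------------
# adult coverage
# ---------------------------------------------------------------------------

def _present_depth(rng, shape, mean_depth):
    return np.maximum(1, rng.poisson(mean_depth, size=shape))


def simulate_adult_coverage(truth: SimTruth, config: SimConfig) -> CoverageMatrix:
    """Locus × sample read-depth matrix for the sexed adult panel."""
    config.validate()
    rng = _rng(config, 2)
    males = [f"M{i:02d}" for i in range(1, config.n_males + 1)]
    females = [f"F{i:02d}" for i in range(1, config.n_females + 1)]
    samples = males + females
    sexes = pd.Series(["M"] * len(males) + ["F"] * len(females), index=samples)
    n_loci = len(truth.loci)
    n_s = len(samples)
    is_y = truth.loci["is_y"].to_numpy()
    depth = np.zeros((n_loci, n_s), dtype=np.int64)

    present = rng.random((n_loci, n_s)) >= config.dropout_rate
    depth[present] = _present_depth(rng, int(present.sum()), config.mean_depth)
    # Y loci are truly absent in females: overwrite with contamination-only reads
    fcols = np.arange(len(males), n_s)
    ysub = np.ix_(np.where(is_y)[0], fcols)
    contaminated = rng.random((int(is_y.sum()), len(fcols))) < config.contamination_rate
    ydepth = np.zeros_like(depth[ysub])
    ydepth[contaminated] = 1 + rng.poisson(1.0, size=int(contaminated.sum()))
    depth[ysub] = ydepth

    df = pd.DataFrame(depth, index=truth.loci["locus_id"].to_numpy(), columns=samples)
    return CoverageMatrix(depths=df, sexes=sexes)


# ---------------------------------------------------------------------------
# family
# ---------------------------------------------------------------------------

@dataclass
class FamilyData:
    """Family genotypes plus the Y-locus presence/absence table."""

    genotypes: FamilyGenotypes
    y_presence: pd.DataFrame  # offspring × y-locus, values in {present, absent}
    offspring_y: np.ndarray = field(repr=False)


def _paternal_gametes(rng, positions: np.ndarray, n_offspring: int) -> np.ndarray:
    """Inherited paternal haplotype (0/1) at each ordered position for each
    offspring; Markov switching with Haldane recombination per gap."""
    k = len(positions)
    out = np.empty((n_offspring, k), dtype=np.int8)
    start = rng.integers(0, 2, n_offspring, dtype=np.int8)
    out[:, 0] = start
    if k > 1:
        d = np.diff(positions)
        r = 0.5 * -np.expm1(-2.0 * d / 100.0)  # Haldane inverse
        switch = (rng.random((n_offspring, k - 1)) < r[None, :]).astype(np.int8)
        parity = np.cumsum(switch, axis=1) % 2
        out[:, 1:] = (start[:, None] + parity) % 2
    return out


def simulate_family(truth: SimTruth, config: SimConfig) -> FamilyData:
    """Simulate the mapping family: paternal meioses with Haldane-consistent
    recombination, testcross SNP calls per locus, and per-offspring Y-locus
    presence subject to dropout/contamination.

    Also records the per-offspring Y-haplotype flag into ``truth``.
    """
    config.validate()
    rng = _rng(config, 3)
    n_off = config.n_offspring
    offspring = [f"off{i:03d}" for i in range(1, n_off + 1)]
    samples = ["father", "mother"] + offspring

    variant_rows = []  # (marker_id, locus_id, pos, ref, alt, is_indel)
    geno_rows = []  # int8 arrays over samples

    def add_variant(marker, locus, pos, ref, alt, father, mother, off_calls):
        variant_rows.append((marker, locus, int(pos), ref, alt,
                             len(ref) > 1 or len(alt) > 1))
        geno_rows.append(np.concatenate(([father, mother], off_calls)).astype(np.int8))

    def snp_alleles():
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        return str(ref), str(alt)

    offspring_y = np.zeros(n_off, dtype=bool)
    for chrom, sub in truth.loci.groupby("chromosome", sort=True):
        test_loci = sub[~sub["is_y"]]
        positions = test_loci["cm"].to_numpy()
        is_sex = chrom == config.sex_chromosome
        if is_sex:
            # virtual sex-determining locus at the chromosome end; haplotype 1
            # is the Y-carrying haplotype
            positions = np.append(positions, config.chrom_length_cM)
        gam = _paternal_gametes(rng, positions, n_off)
        if is_sex:
            offspring_y = gam[:, -1].astype(bool)
            gam = gam[:, :-1]
        for li, (_, locus) in enumerate(test_loci.iterrows()):
            used = set()
            for s in range(config.snps_per_locus):
                pos = int(rng.integers(1, config.locus_length_bp + 1))
                while pos in used:
                    pos = int(rng.integers(1, config.locus_length_bp + 1))
                used.add(pos)
                phase = int(rng.integers(0, 2))
                calls = (gam[:, li] ^ phase).astype(np.int8)
                miss = rng.random(n_off) < config.geno_missing_rate
                calls[miss] = -1
                ref, alt = snp_alleles()
                add_variant(f"{locus.locus_id}_{pos}", locus.locus_id, pos,
                            ref, alt, 1, 0, calls)
            if rng.random() < config.maternal_snp_prob:
                pos = int(rng.integers(1, config.locus_length_bp + 1))
                while pos in used:
                    pos = int(rng.integers(1, config.locus_length_bp + 1))
                calls = rng.integers(0, 2, n_off).astype(np.int8)
                miss = rng.random(n_off) < config.geno_missing_rate
                calls[miss] = -1
                ref, alt = snp_alleles()
                add_variant(f"{locus.locus_id}_{pos}m", locus.locus_id, pos,
                            ref, alt, 0, 1, calls)

    # records that exist only to be filtered out: indels, rare-allele sites,
    # high-missingness sites
    noise_targets = truth.loci.loc[~truth.loci["is_y"], "locus_id"].to_numpy()
    for i in range(config.n_noise_snps):
        locus = str(rng.choice(noise_targets))
        pos = int(rng.integers(1, config.locus_length_bp + 1))
        kind = i % 3
        if kind == 0:  # indel
            calls = rng.integers(0, 2, n_off).astype(np.int8)
            add_variant(f"{locus}_{pos}i", locus, pos, "AT", "A", 1, 0, calls)
        elif kind == 1:  # heavily distorted site: minor allele frequency << 0.2
            calls = (rng.random(n_off) < 0.02).astype(np.int8)
            ref, alt = snp_alleles()
            add_variant(f"{locus}_{pos}r", locus, pos, ref, alt, 1, 0, calls)
        else:  # >5% missing
            calls = rng.integers(0, 2, n_off).astype(np.int8)
            calls[rng.random(n_off) < 0.12] = -1
            ref, alt = snp_alleles()
            add_variant(f"{locus}_{pos}x", locus, pos, ref, alt, 1, 0, calls)

    variants = pd.DataFrame(
        variant_rows, columns=["marker_id", "locus_id", "pos", "ref", "alt", "is_indel"]
    )
    geno = np.vstack(geno_rows) if geno_rows else np.empty((0, len(samples)), np.int8)
    fam = FamilyGenotypes(
        variants=variants, genotypes=geno, samples=samples,
        father="father", mother="mother",
    )

    # Y-locus presence per offspring: carriers drop out at dropout_rate,
    # non-carriers amplify only through contamination
    yids = truth.y_locus_ids()
    pres = np.zeros((n_off, len(yids)), dtype=bool)
    if yids:
        carrier = offspring_y[:, None]
        keep = rng.random(pres.shape) >= config.dropout_rate
        contam = rng.random(pres.shape) < config.contamination_rate
        pres = np.where(carrier, keep, contam)
    y_presence = pd.DataFrame(
        np.where(pres, "present", "absent"), index=offspring, columns=yids
    )
    truth.offspring_y = offspring_y
    return FamilyData(genotypes=fam, y_presence=y_presence, offspring_y=offspring_y)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def emit_sequences(truth: SimTruth, config: SimConfig,
                   catalog_path, reference_path) -> pd.DataFrame:
    """Write the locus catalog FASTA and the homologous reference FASTA.

    Each locus is embedded once in its homologous reference chromosome, in
    cM order, separated by random spacers; embedding strand is random, and
    ``ref_mutation_rate`` optionally degrades the embedded copy.  Returns a
    table of embedding coordinates (locus_id, ref_chrom, start_1based,
    strand) — ground truth for planted-signal tests.
    """
    config.validate()
    rng = _rng(config, 4)
    catalog_path, reference_path = Path(catalog_path), Path(reference_path)
    with open(catalog_path, "w") as fh:
        for _, row in truth.loci.iterrows():
            fh.write(f">{row.locus_id}\n{row.sequence}\n")

    rows = []
    records = {}
    for chrom in sorted(truth.loci["chromosome"].unique()):
        ref_name = truth.homology[chrom]
        sub = truth.loci[truth.loci["chromosome"] == chrom].sort_values(
            ["cm", "locus_id"]
        )
        parts = []
        cursor = 0
        for _, row in sub.iterrows():
            spacer = _random_seq(rng, config.ref_spacer_bp)
            parts.append(spacer)
            cursor += len(spacer)
            seq = row.sequence
            if config.ref_mutation_rate > 0:
                seq = _mutate_to_identity(rng, seq, 1.0 - config.ref_mutation_rate)
            strand = "+" if rng.random() < 0.5 else "-"
            emb = seq if strand == "+" else _revcomp(seq)
            parts.append(emb)
            rows.append((row.locus_id, ref_name, cursor + 1, strand))
            cursor += len(emb)
        parts.append(_random_seq(rng, config.ref_spacer_bp))
        records[ref_name] = "".join(parts)

    with open(reference_path, "w") as fh:
        for name in sorted(records):
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    return pd.DataFrame(rows, columns=["locus_id", "ref_chrom", "start", "strand"])


def write_truth_json(truth: SimTruth, path) -> None:
    payload = {
        "loci": truth.loci.drop(columns=["sequence"]).to_dict(orient="records"),
        "homology": truth.homology,
        "offspring_y": None if truth.offspring_y is None
        else [bool(x) for x in truth.offspring_y],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
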