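"""Family-genotype filtering and presence/absence pseudo-SNP encoding.

The mapping family is two parents plus F1 offspring.  SNP records are
filtered the way the source VCF was in the study design: indels out, then
sites with >5% missing calls, mean depth < 10 (when depth is recorded) or
minor allele frequency < 0.2, and finally one SNP per RAD locus.

Y-linked presence/absence markers enter the map disguised as testcross
SNPs: the father is given the heterozygous genotype AT and the mother AA;
an offspring in which the marker amplified is AT, one in which it did not
is AA, and an ambiguous assay result becomes a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "FamilyGenotypes",
    "FilterConfig",
    "filter_snps",
    "thin_per_locus",
    "encode_pseudosnp",
    "append_pseudosnps",
]

MISSING = -1

PRESENCE_STATUSES = {"present", "absent", "ambiguous"}
_STATUS_TO_CALL = {"present": 1, "absent": 0, "ambiguous": MISSING}


@dataclass
class FamilyGenotypes:
    """Biallelic genotype calls for one family (father, mother, offspring).

    ``genotypes`` is (variants × samples) int8 with 0 = hom-ref, 1 = het,
    2 = hom-alt, -1 = missing.  ``variants`` columns: marker_id, locus_id,
    pos, ref, alt, is_indel.  ``depths`` (optional) parallels ``genotypes``.
    """

    variants: pd.DataFrame = field(repr=False)
    genotypes: np.ndarray = field(repr=False)
    samples: list[str] = field(default_factory=list)
    father: str = "father"
    mother: str = "mother"
    depths: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise ValueError("genotype matrix shape does not match variants/samples")
        for parent in (self.father, self.mother):
            if parent not in self.samples:
                raise ValueError(f"parent sample {parent!r} absent from samples")
        bad = ~np.isin(self.genotypes, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    # -- convenience ------------------------------------------------------
    @property
    def offspring(self) -> list[str]:
        return [s for s in self.samples if s not in (self.father, self.mother)]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def offspring_calls(self) -> np.ndarray:
        idx = [self.sample_index(s) for s in self.offspring]
        return self.genotypes[:, idx]

    def paternal_testcross_mask(self) -> np.ndarray:
        """Markers where the father is heterozygous and the mother homozygous
        — the only configuration informative for a paternal map."""
        fa = self.genotypes[:, self.sample_index(self.father)]
        mo = self.genotypes[:, self.sample_index(self.mother)]
        return (fa == 1) & ((mo == 0) | (mo == 2))

    def subset(self, mask) -> "FamilyGenotypes":
        mask = np.asarray(mask)
        return replace(
            self,
            variants=self.variants.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[mask],
            depths=None if self.depths is None else self.depths[mask],
        )

    # -- VCF I/O ----------------------------------------------------------
    def write_vcf(self, path, contig_length: int = 10000) -> None:
        """Serialize as an uncompressed VCF v4.2 with GT-only FORMAT;
        CHROM is the RAD locus id, ID the marker id."""
        header = pysam.VariantHeader()
        header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                         ("Type", "String"),
                                         ("Description", "Genotype")])
        for contig in pd.unique(self.variants["locus_id"]):
            header.contigs.add(str(contig), length=contig_length)
        for s in self.samples:
            header.add_sample(s)
        _gt = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for i, row in enumerate(self.variants.itertuples(index=False)):
                rec = vf.new_record(
                    contig=str(row.locus_id), start=int(row.pos) - 1,
                    alleles=(str(row.ref), str(row.alt)), id=str(row.marker_id),
                )
                for j, s in enumerate(self.samples):
                    rec.samples[s]["GT"] = _gt[int(self.genotypes[i, j])]
                    rec.samples[s].phased = False
                vf.write(rec)

    @classmethod
    def from_vcf(cls, path, father: str = "father", mother: str = "mother"
                 ) -> "FamilyGenotypes":
        rows, geno_rows, depth_rows = [], [], []
        any_depth = False
        with pysam.VariantFile(str(path)) as vf:
            samples = list(vf.header.samples)
            for rec in vf:
                if len(rec.alts or ()) != 1:
                    raise ValueError(
                        f"non-biallelic record {rec.id} at {rec.chrom}:{rec.pos}"
                    )
                alt = rec.alts[0]
                rows.append((
                    rec.id or f"{rec.chrom}_{rec.pos}", rec.chrom, rec.pos,
                    rec.ref, alt, len(rec.ref) > 1 or len(alt) > 1,
                ))
                calls, dps = [], []
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        calls.append(MISSING)
                    else:
                        calls.append(int(sum(gt)))
                    dp = rec.samples[s].get("DP")
                    dps.append(-1 if dp is None else int(dp))
                    any_depth |= dp is not None
                geno_rows.append(calls)
                depth_rows.append(dps)
        variants = pd.DataFrame(
            rows, columns=["marker_id", "locus_id", "pos", "ref", "alt", "is_indel"]
        )
        geno = np.asarray(geno_rows, dtype=np.int8).reshape(len(variants), len(samples))
        depths = np.asarray(depth_rows, dtype=np.int64) if any_depth else None
        return cls(variants=variants, genotypes=geno, samples=samples,
                   father=father, mother=mother, depths=depths)


@dataclass
class FilterConfig:
    max_missing_frac: float = 0.05
    min_mean_depth: float = 10.0
    min_maf: float = 0.2
    thin_per_locus: bool = True

    def __post_init__(self) -> None:
        for f in ("max_missing_frac", "min_maf"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0,1], got {v}")


def _maf(genotypes: np.ndarray) -> np.ndarray:
    """Minor allele frequency per variant across all non-missing calls."""
    called = genotypes >= 0
    alt = np.where(called, genotypes, 0).sum(axis=1)
    total = 2.0 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    return np.minimum(af, 1.0 - af)


def filter_snps(geno: FamilyGenotypes, cfg: FilterConfig | None = None
                ) -> tuple[FamilyGenotypes, dict]:
    """Apply the SNP quality filters; returns the retained set and a report
    of per-rule removal counts (rules overlap; ``removed_total`` is the
    union)."""
    cfg = cfg or FilterConfig()
    g = geno.genotypes
    n_samples = len(geno.samples)
    indel = geno.variants["is_indel"].to_numpy(dtype=bool)
    missing_frac = (g == MISSING).sum(axis=1) / n_samples
    too_missing = missing_frac > cfg.max_missing_frac + 1e-12
    low_maf = _maf(g) < cfg.min_maf - 1e-12
    if geno.depths is not None:
        valid = geno.depths >= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_depth = np.where(
                valid.any(axis=1),
                np.where(valid, geno.depths, 0).sum(axis=1) / np.maximum(valid.sum(axis=1), 1),
                np.inf,
            )
        low_depth = mean_depth < cfg.min_mean_depth
    else:
        low_depth = np.zeros(len(g), dtype=bool)
    drop = indel | too_missing | low_maf | low_depth
    report = {
        "n_input": int(len(g)),
        "removed_indel": int(indel.sum()),
        "removed_missing": int(too_missing.sum()),
        "removed_maf": int(low_maf.sum()),
        "removed_depth": int(low_depth.sum()),
        "removed_total": int(drop.sum()),
        "n_retained": int((~drop).sum()),
        "depth_rule_applied": geno.depths is not None,
    }
    return geno.subset(~drop), report


def thin_per_locus(geno: FamilyGenotypes) -> FamilyGenotypes:
    """Keep exactly one SNP per RAD locus: the first by position, ties broken
    by marker id."""
    v = geno.variants.reset_index()
    keep_idx = (
        v.sort_values(["locus_id", "pos", "marker_id"], kind="mergesort")
        .groupby("locus_id", sort=False)
        .head(1)["index"]
        .to_numpy()
    )
    mask = np.zeros(len(v), dtype=bool)
    mask[keep_idx] = True
    return geno.subset(mask)


def encode_pseudosnp(presence: dict[str, str] | pd.Series, marker_id: str,
                     offspring: list[str]) -> pd.DataFrame:
    """Encode one Y marker's presence/absence as an artificial SNP.

    Father AT (het), mother AA (hom); offspring AT when the marker
    amplified, AA when it did not, missing when ambiguous.  Returns a
    one-row DataFrame of calls indexed by marker id, columns father,
    mother, then offspring.
    """
    presence = dict(presence)
    unknown = set(presence.values()) - PRESENCE_STATUSES
    if unknown:
        raise ValueError(f"unknown presence status tokens: {sorted(unknown)}")
    missing_off = [o for o in offspring if o not in presence]
    if missing_off:
        raise ValueError(f"no presence status for offspring: {missing_off[:5]}")
    calls = [1, 0] + [_STATUS_TO_CALL[presence[o]] for o in offspring]
    cols = ["father", "mother"] + list(offspring)
    return pd.DataFrame([calls], index=[marker_id], columns=cols, dtype=np.int8)


def append_pseudosnp_markers(geno: FamilyGenotypes, y_presence: pd.DataFrame
                             ) -> FamilyGenotypes:
    """Append one AT/AA pseudo-SNP per Y marker to a filtered genotype set.

    ``y_presence``: offspring × marker table of status tokens.  The pseudo
    records carry ref A / alt T and position 1 on a contig named after the
    marker.
    """
    off = geno.offspring
    new_rows, new_geno = [], []
    fa_i, mo_i = geno.sample_index(geno.father), geno.sample_index(geno.mother)
    off_i = [geno.sample_index(o) for o in off]
    for marker in y_presence.columns:
        enc = encode_pseudosnp(y_presence[marker], marker, off)
        row = np.full(len(geno.samples), MISSING, dtype=np.int8)
        row[fa_i] = 1
        row[mo_i] = 0
        for oi, o in zip(off_i, off):
            row[oi] = enc.loc[marker, o]
        new_rows.append((marker, marker, 1, "A", "T", False))
        new_geno.append(row)
    variants = pd.concat(
        [geno.variants,
         pd.DataFrame(new_rows, columns=list(geno.variants.columns))],
        ignore_index=True,
    )
    genotypes = np.vstack([geno.genotypes, np.asarray(new_geno, dtype=np.int8)]) \
        if new_geno else geno.genotypes
    return replace(geno, variants=variants, genotypes=genotypes, depths=None)


# back-compat style alias matching the operation name
append_pseudosnps = append_pseudosnp_markers
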