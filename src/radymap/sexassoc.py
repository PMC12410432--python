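"""Candidate Y-linked locus discovery from a sexed coverage matrix.

A locus restricted to the Y chromosome shows reads in (nearly) all males
and (nearly) no females.  Candidates are loci present in at least 90% of
male samples and absent in at least 90% of females (both thresholds
inclusive and configurable), then screened for paralogs against the full
locus catalog and ranked: fewest residual female reads first, then fewest
paralogs, then highest mean male depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoverageMatrix",
    "SexAssocConfig",
    "presence_matrix",
    "select_candidates",
    "paralog_screen",
    "rank_candidates",
    "build_candidate_table",
]


@dataclass
class CoverageMatrix:
    """Integer read depths per (locus, sample) plus per-sample sex labels."""

    depths: pd.DataFrame = field(repr=False)  # index: locus ids; columns: sample ids
    sexes: pd.Series = field(repr=False)  # index: sample ids; values in {M, F}

    def __post_init__(self) -> None:
        missing = [s for s in self.depths.columns if s not in self.sexes.index]
        if missing:
            raise ValueError(f"samples without sex label: {missing}")
        bad_sex = set(self.sexes.unique()) - {"M", "F"}
        if bad_sex:
            raise ValueError(f"sex labels must be M or F, got {sorted(bad_sex)}")
        arr = self.depths.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                rows, cols = np.nonzero(~np.isclose(arr, np.round(arr)))
                cell = (self.depths.index[rows[0]], self.depths.columns[cols[0]])
                raise ValueError(f"non-integer depth at {cell}")
            self.depths = self.depths.astype(np.int64)
            arr = self.depths.to_numpy()
        if (arr < 0).any():
            rows, cols = np.nonzero(arr < 0)
            cell = (self.depths.index[rows[0]], self.depths.columns[cols[0]])
            raise ValueError(f"negative depth at {cell}")
        self.sexes = self.sexes.loc[self.depths.columns]

    @property
    def males(self) -> list[str]:
        return list(self.sexes.index[self.sexes == "M"])

    @property
    def females(self) -> list[str]:
        return list(self.sexes.index[self.sexes == "F"])

    def to_tsv(self, depth_path, sex_path) -> None:
        self.depths.to_csv(depth_path, sep="\t", index_label="locus")
        self.sexes.rename("sex").to_csv(sex_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, depth_path, sex_path) -> "CoverageMatrix":
        depths = pd.read_csv(depth_path, sep="\t", index_col="locus")
        sexes = pd.read_csv(sex_path, sep="\t", index_col="sample")["sex"]
        return cls(depths=depths, sexes=sexes)


@dataclass
class SexAssocConfig:
    min_depth_present: int = 1
    male_present_frac: float = 0.90
    female_absent_frac: float = 0.90
    paralog_identity: float = 0.80
    paralog_qcov: float = 0.25

    def __post_init__(self) -> None:
        for f in ("male_present_frac", "female_absent_frac",
                  "paralog_identity", "paralog_qcov"):
            v = getattr(self, f)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{f} must be in (0, 1], got {v}")
        if self.min_depth_present < 1:
            raise ValueError("min_depth_present must be >= 1")


def presence_matrix(cov: CoverageMatrix, min_depth_present: int = 1) -> pd.DataFrame:
    """Binarise depths: a locus is present in a sample iff depth >= threshold."""
    if min_depth_present < 1:
        raise ValueError("min_depth_present must be >= 1")
    return cov.depths >= min_depth_present


def select_candidates(pres: pd.DataFrame, sexes: pd.Series,
                      cfg: SexAssocConfig | None = None) -> list[str]:
    """Loci present in >= male_present_frac of males AND absent in
    >= female_absent_frac of females (inclusive comparisons)."""
    cfg = cfg or SexAssocConfig()
    males = sexes.index[sexes == "M"]
    females = sexes.index[sexes == "F"]
    if len(males) == 0 or len(females) == 0:
        raise ValueError("need at least one male and one female sample")
    male_frac = pres[males].mean(axis=1)
    female_absent = 1.0 - pres[females].mean(axis=1)
    # nudge for exact threshold comparisons under float division
    eps = 1e-9
    keep = (male_frac >= cfg.male_present_frac - eps) & (
        female_absent >= cfg.female_absent_frac - eps
    )
    return list(pres.index[keep])


def paralog_screen(candidates, catalog: dict[str, str],
                   cfg: SexAssocConfig | None = None) -> pd.Series:
    """Count catalog loci paralogous to each candidate.

    A non-self catalog locus counts as a paralog when its best local
    alignment to the candidate has identity > paralog_identity AND aligned
    query coverage > paralog_qcov (both strict, both strands searched).
    """
    from .synteny import AlignConfig, local_align

    cfg = cfg or SexAssocConfig()
    acfg = AlignConfig()
    counts = {}
    for cid in candidates:
        if cid not in catalog:
            raise KeyError(f"candidate {cid!r} not in catalog")
        query = catalog[cid]
        n = 0
        for oid, seq in catalog.items():
            if oid == cid:
                continue
            aln = local_align(query, seq, acfg)
            if aln is None:
                continue
            if aln.identity > cfg.paralog_identity and aln.query_coverage > cfg.paralog_qcov:
                n += 1
        counts[cid] = n
    return pd.Series(counts, name="paralog_count")


def rank_candidates(table: pd.DataFrame) -> pd.DataFrame:
    """Rank candidates lexicographically: residual_female_reads ascending,
    paralog_count ascending, mean_male_depth descending, locus id ascending;
    rank 1 is best."""
    required = {"residual_female_reads", "paralog_count", "mean_male_depth"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing metrics: {sorted(missing)}")
    if table[sorted(required)].isna().any().any():
        raise ValueError("metrics contain missing values")
    # mergesort is stable; pre-sort by locus id gives the final tie-break
    out = (
        table.copy()
        .assign(_neg_depth=lambda d: -d["mean_male_depth"])
        .sort_index()
        .sort_values(
            ["residual_female_reads", "paralog_count", "_neg_depth"],
            kind="mergesort",
        )
        .drop(columns="_neg_depth")
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def build_candidate_table(cov: CoverageMatrix, catalog: dict[str, str] | None = None,
                          cfg: SexAssocConfig | None = None) -> pd.DataFrame:
    """Full discovery stage: filter, (optionally) paralog-screen, rank.

    Returns a DataFrame indexed by locus id with columns
    male_present_count, female_present_count, residual_female_reads,
    paralog_count, mean_male_depth, rank.
    """
    cfg = cfg or SexAssocConfig()
    pres = presence_matrix(cov, cfg.min_depth_present)
    cands = select_candidates(pres, cov.sexes, cfg)
    males, females = cov.males, cov.females
    sub = cov.depths.loc[cands]
    table = pd.DataFrame(
        {
            "male_present_count": pres.loc[cands, males].sum(axis=1).astype(int),
            "female_present_count": pres.loc[cands, females].sum(axis=1).astype(int),
            "residual_female_reads": sub[females].sum(axis=1).astype(int),
            "mean_male_depth": sub[males].mean(axis=1),
        }
    )
    if catalog is not None and len(cands):
        table["paralog_count"] = paralog_screen(cands, catalog, cfg)
    else:
        table["paralog_count"] = 0
    return rank_candidates(table)
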