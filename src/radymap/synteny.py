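"""Marker-to-reference alignment, E-value filtering and chromosome homology.

Mapped marker sequences are aligned to a reference genome from a related
species with a word-seeded local aligner (exact affine-gap alignment inside
seeded windows, both strands).  Significance follows the Karlin–Altschul
form E = K·m·n·exp(-λ·S).  Per query, only a hit at least
``magnitude_factor`` (default 1e5) more significant than the runner-up is
trusted — a uniqueness filter that discards ambiguous, likely paralogous
placements.  Accepted hits vote per linkage group; the majority reference
chromosome is the group's homolog, flagged reciprocal when that chromosome
returns the favour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "AlignConfig",
    "LocalAlignment",
    "AlignHit",
    "local_align",
    "evalue",
    "search",
    "magnitude_filter",
    "assign_homology",
    "oxford_points",
    "plot_oxford",
]

E_FLOOR = 1e-300
_ALPHABET = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _check_seq(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    seq = seq.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"invalid characters in {name} sequence: {sorted(bad)}")
    return seq


@dataclass
class AlignConfig:
    word_size: int = 11
    e_max: float = 1e-20
    match_score: float = 1.0
    mismatch_score: float = -2.0
    gap_open: float = 5.0  #: cost of opening a gap (added to first extension)
    gap_extend: float = 2.0
    karlin_lambda: float = 1.28
    karlin_k: float = 0.46
    magnitude_factor: float = 1e5
    #: subjects at most this long are aligned exactly without seeding
    exact_max_subject: int = 10_000
    seed_margin: int = 30

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")
        if self.magnitude_factor <= 1:
            raise ValueError("magnitude_factor must exceed 1")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match_score
        a.mismatch_score = self.mismatch_score
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -self.gap_extend
        return a


@dataclass
class LocalAlignment:
    score: float
    identity: float  #: identities / aligned columns (gaps included)
    query_coverage: float  #: aligned query span / query length
    subject_start: int  #: 1-based, inclusive, forward strand
    subject_end: int  #: 1-based, inclusive
    strand: str  #: '+' or '-' (query orientation)


@dataclass
class AlignHit:
    query: str
    chrom: str
    subject_start: int
    subject_end: int
    strand: str
    score: float
    identity: float
    query_coverage: float
    e_value: float


def _best_alignment(aligner, subject: str, query: str):
    alns = aligner.align(subject, query)
    try:
        aln = alns[0]
    except IndexError:
        return None
    if aln.score <= 0:
        return None
    return aln


def _summarise(aln, query_len: int, subject_offset: int, subject_len: int,
               strand: str) -> LocalAlignment:
    counts = aln.counts()
    aligned_cols = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    tblocks = aln.aligned[0]
    qblocks = aln.aligned[1]
    qspan = int(qblocks[-1][1] - qblocks[0][0])
    s0 = int(tblocks[0][0]) + subject_offset
    s1 = int(tblocks[-1][1]) + subject_offset
    if strand == "-":
        # coordinates were computed on the reverse-complemented query; the
        # subject span is unchanged, only the query orientation differs
        pass
    return LocalAlignment(
        score=float(aln.score),
        identity=identity,
        query_coverage=qspan / query_len,
        subject_start=s0 + 1,
        subject_end=s1,
        strand=strand,
    )


def local_align(query: str, subject: str, cfg: AlignConfig | None = None
                ) -> LocalAlignment | None:
    """Best local alignment of ``query`` against ``subject``, both strands.

    Exact affine-gap optimum for subjects up to ``exact_max_subject``;
    longer subjects are handled by word-seeded windows (see :func:`search`).
    Returns None when no positive-scoring alignment exists.
    """
    cfg = cfg or AlignConfig()
    query = _check_seq(query, "query")
    subject = _check_seq(subject, "subject")
    if len(subject) > cfg.exact_max_subject:
        hits = _seeded_chrom_hits(query, "subject", subject,
                                  _kmer_index(subject, cfg.word_size), cfg)
        if not hits:
            return None
        return max(hits, key=lambda h: (h.score, -h.subject_start))
    aligner = cfg.aligner()
    best = None
    for strand, q in (("+", query), ("-", _revcomp(query))):
        aln = _best_alignment(aligner, subject, q)
        if aln is None:
            continue
        cand = _summarise(aln, len(query), 0, len(subject), strand)
        if best is None or cand.score > best.score:
            best = cand
    return best


def evalue(score: float, query_len: int, subject_total_len: int,
           cfg: AlignConfig | None = None) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(-λ·S), floored at 1e-300."""
    cfg = cfg or AlignConfig()
    if score <= 0:
        raise ValueError("score must be positive")
    log_e = (
        math.log(cfg.karlin_k) + math.log(query_len)
        + math.log(subject_total_len) - cfg.karlin_lambda * score
    )
    if log_e < math.log(E_FLOOR):
        return E_FLOOR
    return max(math.exp(log_e), E_FLOOR)


# ---------------------------------------------------------------------------
# seeded search
# ---------------------------------------------------------------------------

def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i:i + k], []).append(i)
    return idx


def _merge_windows(starts, width, margin):
    """Merge seed-implied windows [s - margin, s + width + margin) that
    overlap; yields (lo, hi) pairs."""
    out = []
    for s in sorted(starts):
        lo, hi = max(0, s - margin), s + width + margin
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def _seeded_chrom_hits(query: str, chrom: str, seq: str, index, cfg) -> list[LocalAlignment]:
    """Seed-and-extend hits of one query (both strands) on one chromosome."""
    aligner = cfg.aligner()
    k = cfg.word_size
    results = []
    for strand, q in (("+", query), ("-", _revcomp(query))):
        diag_starts = set()
        for qi in range(len(q) - k + 1):
            for si in index.get(q[qi:qi + k], ()):
                diag_starts.add(si - qi)
        if not diag_starts:
            continue
        for lo, hi in _merge_windows(diag_starts, len(q), cfg.seed_margin):
            window = seq[lo:hi]
            aln = _best_alignment(aligner, window, q)
            if aln is None:
                continue
            results.append(_summarise(aln, len(query), lo, len(seq), strand))
    return results


def search(catalog: dict[str, str], reference: dict[str, str],
           cfg: AlignConfig | None = None) -> pd.DataFrame:
    """Align every catalog sequence to the reference; keep hits with
    E <= e_max, sorted ascending by E within each query.

    Returns a DataFrame with columns query, chrom, subject_start,
    subject_end, strand, score, identity, query_coverage, evalue.
    """
    cfg = cfg or AlignConfig()
    if not reference:
        raise ValueError("reference has no chromosome records")
    reference = {c: _check_seq(s, c) for c, s in reference.items()}
    total_len = sum(len(s) for s in reference.values())
    indexes = {c: _kmer_index(s, cfg.word_size) for c, s in reference.items()}
    rows = []
    for qid, qseq in catalog.items():
        qseq = _check_seq(qseq, qid)
        for chrom in sorted(reference):
            for la in _seeded_chrom_hits(qseq, chrom, reference[chrom],
                                         indexes[chrom], cfg):
                e = evalue(la.score, len(qseq), total_len, cfg)
                if e <= cfg.e_max:
                    rows.append((qid, chrom, la.subject_start, la.subject_end,
                                 la.strand, la.score, la.identity,
                                 la.query_coverage, e))
    df = pd.DataFrame(rows, columns=[
        "query", "chrom", "subject_start", "subject_end", "strand",
        "score", "identity", "query_coverage", "evalue",
    ])
    if len(df):
        df = df.sort_values(["query", "evalue", "chrom", "subject_start"],
                            kind="mergesort").reset_index(drop=True)
    return df


def magnitude_filter(hits: pd.DataFrame, magnitude_factor: float = 1e5
                     ) -> pd.DataFrame:
    """Keep, per query, only a best hit at least ``magnitude_factor`` times
    more significant than the runner-up (inclusive); a solitary hit is
    always kept.  Equal-E ties fail the filter."""
    kept = []
    for _, sub in hits.groupby("query", sort=False):
        sub = sub.sort_values(["evalue", "chrom", "subject_start"], kind="mergesort")
        if len(sub) == 1:
            kept.append(sub.iloc[0])
        else:
            e_best, e_next = sub["evalue"].iloc[0], sub["evalue"].iloc[1]
            if e_best <= e_next / magnitude_factor:
                kept.append(sub.iloc[0])
    if not kept:
        return hits.iloc[0:0]
    return pd.DataFrame(kept).reset_index(drop=True)


# ---------------------------------------------------------------------------
# homology assignment
# ---------------------------------------------------------------------------

def assign_homology(lmap, accepted: pd.DataFrame):
    """Majority-vote chromosome assignment per linkage group.

    Returns ``(homology, oxford)``: homology has one row per linkage group
    with the majority reference chromosome (or <NA> when the group has no
    accepted hits), hit counts and a reciprocal flag (true when that
    chromosome's plurality of accepted hits comes from the same group);
    oxford holds the (group, cM, chromosome, subject position) points for
    plotting.
    """
    table = lmap.table.merge(accepted, left_on="marker", right_on="query",
                             how="left")
    hits = table.dropna(subset=["chrom"])
    rows = []
    # majority group per chromosome, for the reciprocal check
    chrom_major = {}
    for chrom, sub in hits.groupby("chrom"):
        counts = sub.groupby("group").size().sort_index()
        chrom_major[chrom] = int(counts.idxmax())
    for gid in sorted(lmap.table["group"].unique()):
        sub = hits[hits["group"] == gid]
        if len(sub) == 0:
            rows.append((int(gid), pd.NA, 0, 0, False))
            continue
        counts = sub.groupby("chrom").size().sort_index()
        chrom = str(counts.idxmax())
        rows.append((
            int(gid), chrom, int(counts.max()), int(len(sub)),
            chrom_major.get(chrom) == int(gid),
        ))
    homology = pd.DataFrame(
        rows, columns=["group", "chrom", "n_hits_major", "n_hits_total",
                       "reciprocal"],
    )
    oxford = oxford_points(hits)
    return homology, oxford


def oxford_points(hits_with_map: pd.DataFrame) -> pd.DataFrame:
    cols = ["group", "marker", "cm", "y_flag", "chrom", "subject_start"]
    return hits_with_map[cols].reset_index(drop=True)


def plot_oxford(oxford: pd.DataFrame, path) -> None:
    """Grid scatter of marker map position vs reference position; homology
    shows up as dense blocks on the (group, chromosome) diagonal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(oxford["group"].unique())
    chroms = sorted(oxford["chrom"].unique())
    fig, axes = plt.subplots(
        len(chroms), len(groups), figsize=(1.1 * len(groups), 1.1 * len(chroms)),
        sharex="col", sharey="row", squeeze=False,
    )
    for ci, chrom in enumerate(chroms):
        for gi, gid in enumerate(groups):
            ax = axes[len(chroms) - 1 - ci][gi]
            sub = oxford[(oxford["group"] == gid) & (oxford["chrom"] == chrom)]
            colors = np.where(sub["y_flag"], "red", "black")
            ax.scatter(sub["cm"], sub["subject_start"], s=4, c=colors)
            ax.set_xticks([])
            ax.set_yticks([])
            if ci == 0:
                ax.set_xlabel(f"LG{gid}", fontsize=6)
            if gi == 0:
                ax.set_ylabel(chrom, fontsize=6, rotation=0, ha="right")
    fig.suptitle("Linkage groups vs reference chromosomes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
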