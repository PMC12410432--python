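"""Two-point linkage mapping for a paternal pseudo-testcross.

Markers are biallelic testcross calls on F1 offspring: the father is
heterozygous and the mother homozygous, so each offspring call reveals which
paternal haplotype it inherited (coded 1 for the heterozygous class, 0 for
the homozygous class, -1 missing).  All linkage information therefore comes
from paternal meioses and a single (paternal) map is produced.

The pipeline follows the classic two-point design: pairwise recombination
fractions and LOD scores, linkage groups as connected components above a
grouping LOD threshold, a second lower-threshold pass attaching leftover
singletons, greedy seriation with relocation polishing within each group,
and cumulative Haldane distances.

Presence/absence pseudo-SNP markers carry a known assay error rate (a
dropped-out marker in a carrier is miscalled).  ``error_rates`` lets the
caller declare that rate per marker; observed discordance is then corrected
before being converted to map distance, and adjacent markers whose
discordance is statistically indistinguishable from the error floor are
co-located.  With an error rate of zero this reduces exactly to "identical
calls are co-located".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chisquare

__all__ = [
    "MapConfig",
    "TwoPointResult",
    "LinkageMap",
    "haldane",
    "haldane_inverse",
    "kosambi",
    "twopoint",
    "twopoint_matrices",
    "corrected_r",
    "group_markers",
    "join_singles",
    "order_group",
    "build_linkage_map",
    "locate_y_region",
    "distortion_report",
]

LOG10_2 = np.log10(2.0)


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def haldane(r):
    """Map distance in cM from recombination fraction, assuming no
    interference: d = -50 ln(1 - 2r)."""
    r = np.asarray(r, dtype=float)
    return -50.0 * np.log1p(-2.0 * r)


def haldane_inverse(d):
    """Recombination fraction from Haldane distance in cM."""
    d = np.asarray(d, dtype=float)
    return 0.5 * -np.expm1(-d / 50.0)


def kosambi(r):
    """Kosambi map distance in cM (interference-aware alternative)."""
    r = np.asarray(r, dtype=float)
    return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))


_MAP_FUNCTIONS = {"haldane": haldane, "kosambi": kosambi}


# ---------------------------------------------------------------------------
# configuration & containers
# ---------------------------------------------------------------------------

@dataclass
class MapConfig:
    """Linkage-map construction parameters.

    lod_group / lod_join follow the study design: groups are formed at a
    high LOD threshold (20) and leftover markers attached at a lower one
    (15).  Pairs observed in fewer than ``min_informative`` offspring are
    too noisy to group on and are ignored at the grouping stage.
    """

    lod_group: float = 20.0
    lod_join: float = 15.0
    min_informative: int = 20
    max_gap_cM: float = 100.0
    map_function: str = "haldane"
    #: one-sided z for declaring discordance above the error floor;
    #: three-sigma guards the many adjacent pairs examined per group
    collapse_z: float = 3.0
    max_polish_passes: int = 25

    def __post_init__(self) -> None:
        if self.map_function not in _MAP_FUNCTIONS:
            raise ValueError(f"unknown map function {self.map_function!r}")


@dataclass
class TwoPointResult:
    marker_i: str
    marker_j: str
    n_informative: int
    R: int
    r_hat: float
    lod: float


@dataclass
class LinkageMap:
    """Ordered linkage groups with cM positions, plus unplaced markers.

    ``table`` columns: group (int, 1-based), order_index, marker, cm,
    y_flag (bool).  Positions within a group start at 0 and are
    non-decreasing.
    """

    table: pd.DataFrame
    unplaced: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return int(self.table["group"].nunique())

    def group_markers_list(self, group: int) -> list[str]:
        sub = self.table[self.table["group"] == group].sort_values("order_index")
        return list(sub["marker"])

    def total_length_cM(self) -> float:
        return float(self.table.groupby("group")["cm"].max().sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LinkageMap":
        df = pd.read_csv(path, sep="\t", dtype={"marker": str})
        df["y_flag"] = df["y_flag"].astype(bool)
        return cls(df)


# ---------------------------------------------------------------------------
# two-point statistics
# ---------------------------------------------------------------------------

def _pair_lod(R, n):
    """LOD for R recombinants in n meioses at r̂ = R/n (phase resolved),
    against free recombination (r = 0.5); 0·log10(0) taken as 0."""
    R = np.asarray(R, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n > 0, R / np.maximum(n, 1), 0.5)
        t1 = np.where(R > 0, R * np.log10(np.where(r > 0, r, 1.0)), 0.0)
        t2 = np.where(n - R > 0, (n - R) * np.log10(np.where(r < 1, 1 - r, 1.0)), 0.0)
    lod = t1 + t2 + n * LOG10_2
    return np.maximum(lod, 0.0)


def twopoint(calls_i, calls_j, marker_i: str = "i", marker_j: str = "j") -> TwoPointResult:
    """Two-point recombination estimate and LOD for one marker pair.

    ``calls_*`` are offspring testcross calls in {0, 1, -1 (missing)}.
    Recombinants are counted under the better of the two parental phases,
    i.e. R = min(#discordant, n - #discordant).
    """
    a = np.asarray(calls_i, dtype=np.int8)
    b = np.asarray(calls_j, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("call vectors differ in length")
    valid = (a >= 0) & (b >= 0)
    n = int(valid.sum())
    if n == 0:
        raise ValueError(
            f"no informative offspring for pair ({marker_i}, {marker_j})"
        )
    disc = int((a[valid] != b[valid]).sum())
    R = min(disc, n - disc)
    r_hat = R / n
    lod = float(_pair_lod(R, n))
    return TwoPointResult(marker_i, marker_j, n, R, r_hat, lod)


def twopoint_matrices(calls: np.ndarray):
    """All-pairs two-point statistics, vectorised.

    ``calls`` is (markers × offspring) int8 in {0, 1, -1}.  Returns
    ``(R, N, r_hat, lod)`` square matrices; R is the phase-resolved
    recombinant count, N the informative-offspring count.
    """
    calls = np.asarray(calls, dtype=np.int8)
    V = (calls >= 0)
    A = ((calls == 1) & V).astype(np.float32)
    B = ((calls == 0) & V).astype(np.float32)
    Vf = V.astype(np.float32)
    concordant = A @ A.T + B @ B.T
    N = Vf @ Vf.T
    D = N - concordant
    R = np.minimum(D, N - D)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_hat = np.where(N > 0, R / np.maximum(N, 1), 0.5)
    lod = _pair_lod(R, N)
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(r_hat, 0.0)
    return R.astype(np.int64), N.astype(np.int64), r_hat, lod


def corrected_r(R, N, error_rates=None, collapse_z: float = 3.0):
    """Error-corrected recombination fractions for distance estimation.

    For markers with per-call miscall probabilities e_i, e_j, a fraction
    c = e_i(1-e_j) + e_j(1-e_i) of offspring are expected discordant even at
    r = 0.  The corrected estimate is (q̂ - c) / (1 - 2c) clipped to
    [0, 0.5]; pairs whose discordance does not exceed c by more than
    ``collapse_z`` binomial standard errors are co-located (r = 0).
    With e = 0 this is simply q̂, and co-location requires identical calls.
    """
    R = np.asarray(R, dtype=float)
    N = np.asarray(N, dtype=float)
    q = np.where(N > 0, R / np.maximum(N, 1), 0.5)
    if error_rates is None:
        return np.clip(q, 0.0, 0.5)
    e = np.asarray(error_rates, dtype=float)
    c = e[:, None] + e[None, :] - 2.0 * np.outer(e, e)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(np.maximum(c * (1 - c), 0.0) / np.maximum(N, 1))
        r = (q - c) / np.maximum(1.0 - 2.0 * c, 1e-12)
    r = np.clip(r, 0.0, 0.5)
    r[q <= c + collapse_z * se] = 0.0
    return r


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def group_markers(lod: np.ndarray, lod_limit: float = 20.0,
                  informative: np.ndarray | None = None,
                  min_informative: int = 0):
    """Linkage groups as connected components of the pairwise-LOD graph.

    Edges require lod >= lod_limit (and, if ``informative`` is given,
    at least ``min_informative`` shared offspring).  Singleton components
    are returned as unplaced.  Returns (groups, unplaced): groups is a list
    of sorted index lists, ordered by size descending then smallest index.
    """
    lod = np.asarray(lod, dtype=float)
    if lod.ndim != 2 or lod.shape[0] != lod.shape[1]:
        raise ValueError("lod matrix must be square")
    if not np.allclose(lod, lod.T, atol=1e-8):
        raise ValueError("lod matrix must be symmetric")
    m = lod.shape[0]
    adj = lod >= lod_limit
    if informative is not None and min_informative > 0:
        adj &= np.asarray(informative) >= min_informative
    np.fill_diagonal(adj, False)
    g = nx.from_numpy_array(adj)
    comps = [sorted(c) for c in nx.connected_components(g)]
    groups = sorted((c for c in comps if len(c) > 1), key=lambda c: (-len(c), c[0]))
    unplaced = sorted(i for c in comps if len(c) == 1 for i in c)
    return groups, unplaced


def join_singles(groups, unplaced, lod: np.ndarray, lod_limit: float = 15.0,
                 informative: np.ndarray | None = None,
                 min_informative: int = 0):
    """Attach unplaced markers to the group of their best-LOD partner.

    A single pass over the original grouping: marker joins iff its best LOD
    to any grouped marker is >= lod_limit; ties break toward the lower group
    id.  Never merges or splits existing groups.
    """
    lod = np.asarray(lod, dtype=float)
    ok = np.ones_like(lod, dtype=bool)
    if informative is not None and min_informative > 0:
        ok = np.asarray(informative) >= min_informative
    new_groups = [list(g) for g in groups]
    still = []
    for u in unplaced:
        best = (-np.inf, None)
        for gi, g in enumerate(groups):
            cand = [lod[u, v] for v in g if ok[u, v]]
            if not cand:
                continue
            top = max(cand)
            if top > best[0]:
                best = (top, gi)
        if best[1] is not None and best[0] >= lod_limit:
            new_groups[best[1]].append(u)
        else:
            still.append(u)
    return [sorted(g) for g in new_groups], still


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------

def _path_cost(order, r):
    return float(sum(r[order[i], order[i + 1]] for i in range(len(order) - 1)))


def order_group(members, r: np.ndarray, max_polish_passes: int = 25):
    """Greedy seriation of one linkage group on pairwise r̂.

    Starts from the tightest pair, repeatedly appends the marker closest to
    either end of the growing path, then polishes by single-marker
    relocation until the sum of adjacent r̂ stops decreasing.  Orientation
    is canonicalised (smaller first index) so output is deterministic.
    """
    members = list(members)
    k = len(members)
    if k == 0:
        raise ValueError("empty group")
    if k == 1:
        return members
    sub = r[np.ix_(members, members)]
    # tightest pair, deterministic tie-break on indices
    iu, ju = np.triu_indices(k, 1)
    best = np.lexsort((ju, iu, sub[iu, ju]))[0]
    path = [int(iu[best]), int(ju[best])]
    remaining = set(range(k)) - set(path)
    while remaining:
        cands = sorted(remaining)
        dists_head = [sub[path[0], c] for c in cands]
        dists_tail = [sub[path[-1], c] for c in cands]
        hi = int(np.argmin(dists_head))
        ti = int(np.argmin(dists_tail))
        if dists_head[hi] < dists_tail[ti]:
            path.insert(0, cands[hi])
            remaining.discard(cands[hi])
        else:
            path.append(cands[ti])
            remaining.discard(cands[ti])
    # relocation polishing
    for _ in range(max_polish_passes):
        improved = False
        cost = _path_cost(path, sub)
        for idx in range(k):
            node = path[idx]
            rest = path[:idx] + path[idx + 1:]
            best_cost, best_pos = cost, None
            for pos in range(k):
                if pos == idx:
                    continue
                trial = rest[:pos] + [node] + rest[pos:]
                tc = _path_cost(trial, sub)
                if tc < best_cost - 1e-12:
                    best_cost, best_pos = tc, pos
            if best_pos is not None:
                path = rest[:best_pos] + [node] + rest[best_pos:]
                cost = best_cost
                improved = True
        if not improved:
            break
    if path[0] > path[-1]:
        path = path[::-1]
    return [members[i] for i in path]


def positions_from_order(order, r, cfg: MapConfig):
    """Cumulative map positions (cM) along an ordered path of marker indices."""
    mapfun = _MAP_FUNCTIONS[cfg.map_function]
    pos = [0.0]
    for a, b in zip(order[:-1], order[1:]):
        rv = float(r[a, b])
        if rv >= 0.5:
            warnings.warn(
                f"adjacent markers {a},{b} appear unlinked (r̂=0.5); "
                f"gap capped at {cfg.max_gap_cM} cM"
            )
            d = cfg.max_gap_cM
        else:
            d = min(float(mapfun(rv)), cfg.max_gap_cM)
        pos.append(pos[-1] + d)
    return pos


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_linkage_map(calls: np.ndarray, marker_ids, y_flags=None,
                      error_rates=None, cfg: MapConfig | None = None) -> LinkageMap:
    """Full two-point pipeline: group at lod_group, attach singles at
    lod_join, order each group and assign Haldane positions.

    ``calls``: (markers × offspring) testcross calls {0,1,-1};
    ``error_rates``: optional per-marker miscall probability (pseudo-SNP
    markers carry their assay error; SNP markers 0).
    """
    cfg = cfg or MapConfig()
    marker_ids = list(marker_ids)
    y_flags = np.zeros(len(marker_ids), bool) if y_flags is None else np.asarray(y_flags, bool)
    R, N, r_hat, lod = twopoint_matrices(calls)
    groups, unplaced = group_markers(lod, cfg.lod_group, N, cfg.min_informative)
    groups, unplaced = join_singles(groups, unplaced, lod, cfg.lod_join, N, cfg.min_informative)
    r_dist = corrected_r(R, N, error_rates, cfg.collapse_z)
    rows = []
    for gid, members in enumerate(groups, start=1):
        order = order_group(members, r_dist, cfg.max_polish_passes)
        pos = positions_from_order(order, r_dist, cfg)
        for oi, (mi, cm) in enumerate(zip(order, pos)):
            rows.append((gid, oi, marker_ids[mi], cm, bool(y_flags[mi])))
    table = pd.DataFrame(rows, columns=["group", "order_index", "marker", "cm", "y_flag"])
    meta = {
        "map_function": cfg.map_function,
        "lod_group": cfg.lod_group,
        "lod_join": cfg.lod_join,
        "parent": "paternal (testcross: father heterozygous)",
        "n_markers": len(marker_ids),
        "n_groups": len(groups),
    }
    return LinkageMap(table, [marker_ids[i] for i in unplaced], meta)


def locate_y_region(lmap: LinkageMap) -> pd.DataFrame:
    """Where do the Y-flagged pseudo-SNP markers sit on the map?

    One row per linkage group containing Y-flagged markers: marker count,
    cM span covered, whether the span touches a group end, and the largest
    number co-located at a single position.
    """
    ytab = lmap.table[lmap.table["y_flag"]]
    if len(ytab) == 0:
        warnings.warn("map contains no Y-flagged markers")
        return pd.DataFrame(
            columns=["group", "n_y_markers", "span_cm", "touches_end", "max_colocated"]
        )
    rows = []
    for gid, sub in ytab.groupby("group"):
        full = lmap.table[lmap.table["group"] == gid]
        lo, hi = sub["cm"].min(), sub["cm"].max()
        touches = bool(
            np.isclose(lo, full["cm"].min()) or np.isclose(hi, full["cm"].max())
        )
        coloc = int(sub.groupby(sub["cm"].round(6)).size().max())
        rows.append((int(gid), len(sub), float(hi - lo), touches, coloc))
    return pd.DataFrame(
        rows, columns=["group", "n_y_markers", "span_cm", "touches_end", "max_colocated"]
    )


def distortion_report(calls: np.ndarray, marker_ids) -> pd.DataFrame:
    """Per-marker segregation-distortion chi-square against the expected 1:1
    testcross ratio (diagnostic only; grouping does not use it)."""
    calls = np.asarray(calls)
    rows = []
    for mid, row in zip(marker_ids, calls):
        n1 = int((row == 1).sum())
        n0 = int((row == 0).sum())
        if n0 + n1 == 0:
            rows.append((mid, n0, n1, np.nan, np.nan))
            continue
        stat, p = chisquare([n0, n1])
        rows.append((mid, n0, n1, float(stat), float(p)))
    return pd.DataFrame(rows, columns=["marker", "n_hom", "n_het", "chi2", "p"])
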