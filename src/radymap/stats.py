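"""Exact sex-ratio statistics and screening-panel summaries.

The offspring sets genotyped for a Y-linked marker should contain males and
females in equal proportion; an excess of marker-positive (putatively male)
individuals is assessed with an exact two-tailed binomial test against a 1:1
null.  The PCR screening panel records, per (marker, primer pair) and taxon,
whether amplification was male-specific, occurred in both sexes, or failed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "binom_twotailed",
    "summarize_fraction",
    "PcrPanel",
    "tally_pcr_panel",
    "load_table1",
]

#: closed vocabulary for PCR outcomes
PCR_STATUSES = frozenset({"male_specific", "both_sexes", "no_amplification", "untested"})

_STATUS_CODES = {
    "+": "male_specific",
    "o": "both_sexes",
    "x": "no_amplification",
    ".": "untested",
}


def binom_twotailed(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-tailed binomial p-value by the minimum-likelihood method.

    Sums the probability of every outcome no more likely than the observed
    count ``k`` under Binomial(``n``, ``p0``).  Probabilities are compared
    with a relative tolerance of 1e-12 to guard against floating-point
    near-ties; for ``p0 = 0.5`` the result coincides with twice the smaller
    tail (capped at 1).  Log-space evaluation keeps the test exact for
    ``n`` up to about a million.
    """
    k = int(k)
    n = int(n)
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    i = np.arange(n + 1)
    logpmf = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * np.log(p0)
        + (n - i) * np.log1p(-p0)
    )
    cutoff = logpmf[k] + np.log1p(1e-12)
    included = logpmf <= cutoff
    if included.all():
        return 1.0
    # log-sum-exp over the included outcomes
    m = logpmf[included].max()
    p = float(np.exp(m) * np.exp(logpmf[included] - m).sum())
    return min(p, 1.0)


def summarize_fraction(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-to-even."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return round(100.0 * numerator / denominator, decimals)


@dataclass
class PcrPanel:
    """Per-(marker, primer pair) PCR amplification outcomes across taxa.

    ``table`` is indexed by (marker, pair) with one column per taxon and
    cell values from :data:`PCR_STATUSES`.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        bad = set(self.table.to_numpy().ravel()) - PCR_STATUSES
        if bad:
            raise ValueError(f"unknown PCR status values: {sorted(bad)}")

    @property
    def taxa(self) -> list[str]:
        return list(self.table.columns)

    @classmethod
    def from_tsv(cls, path) -> "PcrPanel":
        """Read a panel TSV: columns ``marker``, ``pair``, then one column per
        taxon with status codes ``+`` (male-specific), ``o`` (both sexes),
        ``x`` (no amplification), ``.`` (untested)."""
        df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
        df = df.set_index(["marker", "pair"])
        decoded = df.map(lambda c: _STATUS_CODES.get(c.strip(), c.strip()))
        return cls(decoded)


def tally_pcr_panel(panel: PcrPanel, taxa: list[str]) -> tuple[int, int]:
    """Count primer pairs male-specific in *every* listed taxon.

    Returns ``(n_pairs, n_markers)`` where ``n_markers`` is the number of
    distinct markers among the qualifying pairs.
    """
    unknown = [t for t in taxa if t not in panel.table.columns]
    if unknown:
        raise KeyError(f"taxa not in panel: {unknown}")
    if not taxa:
        raise ValueError("at least one taxon required")
    if len(panel.table) == 0:
        return 0, 0
    sub = panel.table[list(taxa)]
    ok = (sub == "male_specific").all(axis=1)
    n_pairs = int(ok.sum())
    n_markers = int(sub.index.get_level_values("marker")[ok].nunique()) if n_pairs else 0
    return n_pairs, n_markers


def load_table1() -> PcrPanel:
    """The packaged PCR screening panel for the *Triturus* candidate markers
    (synthesis of the published screening table; blank cells are untested
    because screening was staged)."""
    ref = importlib.resources.files("radymap").joinpath("data/table1.tsv")
    with importlib.resources.as_file(ref) as path:
        return PcrPanel.from_tsv(path)
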