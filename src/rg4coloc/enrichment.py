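"""Gene-set overlap statistics: Fisher exact, chi-square, BH adjustment.

Flat gene-set enrichment against an explicit gene universe. The 2x2 table
convention is (in-set & bound, in-set & unbound, out-set & bound,
out-set & unbound); the odds ratio is the sample odds ratio a*d / (b*c),
reported as inf when b*c = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int  # in-set & bound
    b: int  # in-set & unbound
    c: int  # out-set & bound
    d: int  # out-set & unbound

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.N == 0:
            raise ValueError("all-zero contingency table")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact(
    t: ContingencyTable2x2, sided: str = "two-sided"
) -> tuple[float, float]:
    """Exact hypergeometric test on a 2x2 table.

    Two-sided P sums the probabilities of all fixed-margin tables whose
    probability does not exceed the observed table's (minimum-likelihood
    rule). Returns (odds_ratio, p)."""
    alternative = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[
        sided
    ]
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative=alternative)
    odds = (t.a * t.d) / (t.b * t.c) if t.b * t.c else math.inf
    return odds, float(p)


def chi_square_proportions(t: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square for unequal proportions, 1 df, no continuity
    correction: N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    margins = (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)
    if 0 in margins:
        raise ValueError("chi-square undefined with an all-zero margin")
    stat = t.N * (t.a * t.d - t.b * t.c) ** 2 / math.prod(margins)
    return stat, float(stats.chi2.sf(stat, df=1))


def set_overlap_report(
    bound_genes: set[str],
    annotation_sets: Mapping[str, set[str]],
    universe: set[str],
    adjust: str = "BH",
) -> pd.DataFrame:
    """Per-set overlap with a bound-gene list: Fisher test vs the universe.

    Columns: name, k (overlap count), fraction (k / |bound|), odds_ratio,
    p, p_adj (Benjamini-Hochberg across sets when adjust="BH")."""
    if not universe:
        raise ValueError("empty universe")
    if not bound_genes:
        raise ValueError("empty bound gene set")
    if not bound_genes <= universe:
        raise ValueError("bound_genes must be a subset of the universe")
    rows = []
    for name in sorted(annotation_sets):
        gset = annotation_sets[name]
        if not gset <= universe:
            raise ValueError(f"gene set {name!r} not a subset of the universe")
        a = len(gset & bound_genes)
        b = len(gset - bound_genes)
        c = len(bound_genes - gset)
        d = len(universe) - a - b - c
        odds, p = fisher_exact(ContingencyTable2x2(a, b, c, d))
        rows.append((name, a, a / len(bound_genes), odds, p))
    df = pd.DataFrame(rows, columns=["name", "k", "fraction", "odds_ratio", "p"])
    if adjust == "BH":
        df["p_adj"] = stats.false_discovery_control(df["p"], method="bh")
    elif adjust == "none":
        df["p_adj"] = df["p"]
    else:
        raise ValueError(f"unknown adjust method {adjust!r}")
    return df


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Gene sets from GMT (name, description, genes...) or two-column TSV
    (set_name, gene_id)."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if path.suffix.lower() == ".gmt":
                if len(f) < 3:
                    raise ValueError(f"line {lineno}: GMT needs >= 3 columns")
                sets.setdefault(f[0], set()).update(g for g in f[2:] if g)
            else:
                if len(f) != 2:
                    raise ValueError(f"line {lineno}: expected 2 columns")
                sets.setdefault(f[0], set()).add(f[1])
    return sets
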