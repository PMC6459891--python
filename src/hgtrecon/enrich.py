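"""Hypergeometric term enrichment with Benjamini-Hochberg FDR control.

A foreground set of protein families is tested term by term against a
background annotation universe: the p-value is the upper-tail
hypergeometric probability of drawing at least the observed number of
term-annotated families in a foreground of the given size.  Terms with
zero overlap are reported with p = 1 (not omitted) so FDR ranks stay
stable.  Enrichment only; depletion is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AnnotationTable:
    """term id -> annotated family ids, over a background universe."""

    terms: dict[str, frozenset]
    universe: frozenset
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for term, fams in self.terms.items():
            stray = fams - self.universe
            if stray:
                raise ValueError(
                    f"term {term}: annotated families outside universe: {sorted(stray)[:5]}"
                )

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame,
                        universe: Iterable[str] | None = None) -> "AnnotationTable":
        """Long-format table with columns term_id, term_name, family_id.
        The universe defaults to all annotated families."""
        terms: dict[str, set] = {}
        desc: dict[str, str] = {}
        for r in df.itertuples():
            terms.setdefault(str(r.term_id), set()).add(str(r.family_id))
            desc.setdefault(str(r.term_id), str(getattr(r, "term_name", "")))
        uni = frozenset(str(u) for u in universe) if universe is not None else \
            frozenset().union(*terms.values())
        return cls({t: frozenset(f) for t, f in terms.items()}, uni, desc)

    @classmethod
    def from_tsv(cls, path, universe: Iterable[str] | None = None) -> "AnnotationTable":
        return cls.from_long_frame(pd.read_csv(path, sep="\t"), universe)


def hypergeom_enrich(foreground: Iterable[str],
                     table: AnnotationTable) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of every term.

    Returns one row per term: overlap count k, term size, p-value
    P(X >= k) for X ~ Hypergeom(universe, term size, foreground size),
    and BH-adjusted FDR; sorted by p then term id.
    """
    fg = frozenset(str(f) for f in foreground)
    stray = fg - table.universe
    if stray:
        raise ValueError(f"foreground families outside universe: {sorted(stray)}")
    M, n = len(table.universe), len(fg)
    term_ids = sorted(table.terms)
    K = np.array([len(table.terms[t]) for t in term_ids])
    k = np.array([len(table.terms[t] & fg) for t in term_ids])
    pvals = sps.hypergeom.sf(k - 1, M, K, n)
    out = pd.DataFrame({
        "term_id": term_ids,
        "count": k,
        "term_size": K,
        "p_value": np.clip(pvals, 0.0, 1.0),
    })
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["description"] = [table.descriptions.get(t, "") for t in term_ids]
    return out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in p-rank)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return sps.false_discovery_control(p, method="bh")
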