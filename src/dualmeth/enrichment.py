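"""Permutation over/under-representation of significant loci across genomic
structures and CpG-island relations, and chi-square gene-set overlap tests.

The permutation procedure compares, per annotation label, the observed
("actual") count of label occurrences among significant loci with counts
from repeatedly drawing the same number of loci uniformly without
replacement from a universe (all tested loci, or an alternate universe such
as the other assay's significant set) and re-expanding annotations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ISLAND_RELATIONS, REGION_GROUPS

REGION_LABELS = REGION_GROUPS + ("intergenic",)


@dataclass
class OverlapTest:
    """Yates-corrected chi-square on a 2x2 membership table."""

    a: int  # in both sets
    b: int  # set1 only
    c: int  # set2 only
    d: int  # neither
    chi2: float
    p: float


def _labels_for(entries, intergenic_label: str = "intergenic") -> set[str]:
    return {g for _, g in entries} or {intergenic_label}


def expand_annotations(loci, annotation: pd.DataFrame, kind: str = "region") -> Counter:
    """Multiset of annotation labels over a set of loci.

    ``kind="region"``: each distinct region group of a locus contributes one
    occurrence; loci without genes contribute ``intergenic``.
    ``kind="island"``: the (single-valued) island relation of each locus.
    """
    loci = list(loci)
    missing = [p for p in loci if p not in annotation.index]
    if missing:
        raise ValueError(f"loci absent from annotation: {missing[:5]}")
    counts: Counter = Counter()
    if kind == "region":
        for entries in annotation.loc[loci, "gene_entries"]:
            counts.update(_labels_for(entries))
    elif kind == "island":
        counts.update(annotation.loc[loci, "island_relation"])
    else:
        raise ValueError(f"unknown annotation kind {kind!r}")
    return counts


def _label_matrix(universe, annotation, kind):
    """0/1 multiplicity matrix (loci x labels) for fast resampling."""
    labels = list(REGION_LABELS if kind == "region" else ISLAND_RELATIONS)
    col = {lab: j for j, lab in enumerate(labels)}
    M = np.zeros((len(universe), len(labels)), dtype=np.int16)
    if kind == "region":
        for i, entries in enumerate(annotation.loc[universe, "gene_entries"]):
            for lab in _labels_for(entries):
                M[i, col[lab]] += 1
    else:
        for i, rel in enumerate(annotation.loc[universe, "island_relation"]):
            M[i, col[rel]] += 1
    return M, labels


def permutation_enrichment(
    observed_loci,
    universe_loci,
    annotation: pd.DataFrame,
    kind: str = "region",
    n_perm: int = 100_000,
    alpha: float = 0.01,
    seed: int = 0,
    legacy_p: bool = False,
    strict_tie: bool = False,
) -> pd.DataFrame:
    """Permutation over/under-representation per annotation label.

    Draws ``len(observed_loci)`` loci without replacement from the universe
    ``n_perm`` times and tallies per-label counts.  By default p-values use
    the add-one rule ``(1 + #extreme) / (n_perm + 1)`` with weak (>= / <=)
    tie handling; ``legacy_p`` divides the raw exceedance count by
    ``n_perm`` (possibly yielding 0), and ``strict_tie`` counts strict
    inequalities.  Deterministic given ``seed``.
    """
    observed = list(dict.fromkeys(observed_loci))
    universe = list(dict.fromkeys(universe_loci))
    if not set(observed) <= set(universe):
        raise ValueError("observed loci must be a subset of the universe")
    return _permutation_core(
        observed, universe, annotation, kind, n_perm, alpha, seed, legacy_p, strict_tie
    )


def _permutation_core(
    observed, frame, annotation, kind, n_perm, alpha, seed, legacy_p, strict_tie
) -> pd.DataFrame:
    """Shared machinery: actual counts from ``observed``, permuted counts by
    drawing |observed| loci without replacement from ``frame``."""
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if not observed:
        raise ValueError("observed locus set is empty")
    m, N = len(observed), len(frame)
    M, labels = _label_matrix(frame, annotation, kind)
    obs_counter = expand_annotations(observed, annotation, kind=kind)
    actual = np.array([obs_counter.get(lab, 0) for lab in labels], dtype=np.int64)

    rng = np.random.default_rng(seed)
    ge = np.zeros(len(labels), dtype=np.int64)
    gt = np.zeros(len(labels), dtype=np.int64)
    le = np.zeros(len(labels), dtype=np.int64)
    lt = np.zeros(len(labels), dtype=np.int64)
    perm_sum = np.zeros(len(labels), dtype=np.float64)
    # chunked without-replacement sampling via random-key partial sort
    budget = 40_000_000  # floats per chunk
    chunk = max(1, min(n_perm, budget // max(N, 1)))
    done = 0
    while done < n_perm:
        B = min(chunk, n_perm - done)
        keys = rng.random((B, N))
        part = np.argpartition(keys, m - 1, axis=1)[:, :m] if m < N else np.tile(
            np.arange(N), (B, 1)
        )
        counts = M[part].sum(axis=1)  # (B, L)
        ge += (counts >= actual).sum(axis=0)
        gt += (counts > actual).sum(axis=0)
        le += (counts <= actual).sum(axis=0)
        lt += (counts < actual).sum(axis=0)
        perm_sum += counts.sum(axis=0)
        done += B

    over_n = gt if strict_tie else ge
    under_n = lt if strict_tie else le
    if legacy_p:
        p_over = over_n / n_perm
        p_under = under_n / n_perm
    else:
        p_over = (1.0 + over_n) / (n_perm + 1.0)
        p_under = (1.0 + under_n) / (n_perm + 1.0)
    call = np.where(p_over < alpha, "over", np.where(p_under < alpha, "under", "none"))
    return pd.DataFrame(
        {
            "label": labels,
            "actual": actual,
            "perm_mean": perm_sum / n_perm,
            "p_over": p_over,
            "p_under": p_under,
            "call": call,
        }
    ).set_index("label")


def permutation_enrichment_vs_set(
    observed_loci,
    alternate_universe_loci,
    annotation: pd.DataFrame,
    **kwargs,
) -> pd.DataFrame:
    """Enrichment with an alternate sampling frame (e.g. the other assay's
    significant loci) instead of the full tested universe."""
    observed = list(dict.fromkeys(observed_loci))
    alt = list(dict.fromkeys(alternate_universe_loci))
    if len(observed) > len(alt):
        raise ValueError(
            f"observed set ({len(observed)}) larger than alternate universe ({len(alt)})"
        )
    defaults = dict(kind="region", n_perm=100_000, alpha=0.01, seed=0,
                    legacy_p=False, strict_tie=False)
    defaults.update(kwargs)
    return _permutation_core(observed, alt, annotation, **defaults)


def chisq_overlap(set1, set2, universe) -> OverlapTest:
    """Pearson chi-square with Yates continuity correction on the 2x2 table
    of membership in two sets within a universe."""
    set1, set2, universe = set(set1), set(set2), set(universe)
    if not set1 <= universe or not set2 <= universe:
        raise ValueError("both sets must be subsets of the universe")
    a = len(set1 & set2)
    b = len(set1 - set2)
    c = len(set2 - set1)
    d = len(universe - set1 - set2)
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(mg == 0 for mg in margins):
        raise ValueError(f"chi-square undefined: zero margin in table {(a, b, c, d)}")
    num = n * max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    chi2 = num / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return OverlapTest(a=a, b=b, c=c, d=d, chi2=float(chi2), p=p)


def neuronal_term_enrichment(observed_terms, universe_terms, reference_terms) -> OverlapTest:
    """Chi-square overlap of observed ontology terms with a reference term
    list (e.g. neuronal/immunological terms), within a term universe."""
    universe = set(universe_terms)
    return chisq_overlap(set(observed_terms), set(reference_terms) & universe, universe)
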