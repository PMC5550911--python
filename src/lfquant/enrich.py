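"""Annotation-category overrepresentation analysis.

For each category, a 2x2 table (in/out of the DE set x in/out of the
category) is built over the quantified-protein reference list and scored
with the exact two-sided hypergeometric (Fisher) test; Benjamini-Hochberg
correction is applied across categories. Both over- and under-represented
categories are reported. Terms are flat labels — no ontology-graph
propagation is performed; supply a pre-propagated annotation map if
true-path closure is wanted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .destats import bh_qvalues

__all__ = ["EnrichError", "load_annotation_tsv", "overrepresentation"]

log = logging.getLogger(__name__)


class EnrichError(ValueError):
    pass


def load_annotation_tsv(path) -> dict[str, set[str]]:
    """Read a two-column (protein_id, term) TSV into an annotation map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["protein", "term"], dtype=str)
    ann: dict[str, set[str]] = {}
    for protein, term in zip(df["protein"], df["term"]):
        ann.setdefault(protein, set()).add(term)
    return ann


def overrepresentation(
    de_list,
    reference_list,
    annotations: dict[str, set[str]],
    alpha: float = 0.05,
    method: str = "fisher",
    include_unannotated: bool = True,
) -> pd.DataFrame:
    """Score every annotation category for over/under-representation.

    Parameters
    ----------
    de_list, reference_list
        The differentially expressed proteins and the full quantified
        reference they were drawn from; ``de_list`` must be a subset.
    annotations
        protein id -> set of category terms; proteins absent from the map
        count as unannotated and, by default, stay in the totals (they are
        real quantified proteins).
    method
        ``"fisher"`` (exact hypergeometric, two-sided) or ``"binomial"``
        (two-sided binomial approximation, for comparison with web tools
        that use it).

    Returns a table with observed/expected counts, fold enrichment,
    direction (``over``/``under``/``none``), p, BH q and a significance
    flag at ``alpha``, sorted by p.
    """
    de = list(dict.fromkeys(de_list))
    ref = list(dict.fromkeys(reference_list))
    if not ref:
        raise EnrichError("reference list is empty")
    offenders = sorted(set(de) - set(ref))
    if offenders:
        raise EnrichError(f"DE proteins not in the reference list: {offenders}")
    if method not in ("fisher", "binomial"):
        raise EnrichError(f"unknown method {method!r}")

    if not include_unannotated:
        annotated = set(annotations)
        ref = [p for p in ref if p in annotated]
        de = [p for p in de if p in annotated]
        if not ref:
            raise EnrichError("no annotated proteins in the reference list")

    N = len(ref)
    n_de = len(de)
    de_set = set(de)
    categories: dict[str, set[str]] = {}
    for p in ref:
        for term in annotations.get(p, ()):  # unannotated contribute no terms
            categories.setdefault(term, set()).add(p)

    rows = []
    for term in sorted(categories):
        members = categories[term]
        K = len(members)
        k = len(members & de_set)
        expected = n_de * K / N
        if method == "fisher":
            table = [[k, n_de - k], [K - k, (N - K) - (n_de - k)]]
            p_val = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            p_val = float(stats.binomtest(k, n_de, K / N, alternative="two-sided").pvalue)
        direction = "over" if k > expected else ("under" if k < expected else "none")
        rows.append(
            {
                "category": term,
                "n_de_in_cat": k,
                "n_ref_in_cat": K,
                "n_de_total": n_de,
                "n_ref_total": N,
                "expected": expected,
                "fold_enrichment": k / expected if expected > 0 else np.nan,
                "direction": direction,
                "p": p_val,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "category", "n_de_in_cat", "n_ref_in_cat", "n_de_total", "n_ref_total",
            "expected", "fold_enrichment", "direction", "p",
        ],
    )
    if len(out):
        out["q"] = bh_qvalues(out["p"].to_numpy())
        out["significant"] = out["q"] < alpha
        out = out.sort_values(["p", "category"], kind="mergesort").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
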